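"""Similarity-threshold applicability domain for the consensus model.

The domain is defined by the threshold ``D_T = gamma_bar + z * sigma`` where
``gamma_bar`` and ``sigma`` are the mean and standard deviation of all
unordered pairwise Tanimoto similarities (ECFP) within the training set.
A query is in-domain (ID) when the Tanimoto similarities of its K most
similar training molecules all reach the threshold, otherwise out-of-domain
(OD).  ``K`` and ``z`` are chosen by a coverage-constrained grid search that
maximizes AUC over the ID portion of a labeled test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

IN_DOMAIN = "ID"
OUT_OF_DOMAIN = "OD"


@dataclass(frozen=True)
class ADParams:
    """Fitted applicability-domain parameters.

    ``d_t`` is derived, never stored, so the identity
    ``d_t == gamma_bar + z * sigma`` holds to full precision.
    """

    gamma_bar: float
    sigma: float
    z: float
    k: int

    def __post_init__(self):
        if not 0.0 <= self.gamma_bar <= 1.0:
            raise ValueError("gamma_bar must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k < 1:
            raise ValueError("K must be >= 1")

    @property
    def d_t(self) -> float:
        return similarity_threshold(self.gamma_bar, self.sigma, self.z)

    def as_dict(self) -> dict:
        return {
            "gamma_bar": self.gamma_bar,
            "sigma": self.sigma,
            "z": self.z,
            "K": self.k,
            "D_T": self.d_t,
        }


def similarity_threshold(gamma_bar: float, sigma: float, z: float) -> float:
    """The similarity threshold D_T = gamma_bar + z * sigma."""
    return gamma_bar + z * sigma


def tanimoto_matrix(query: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Tanimoto similarity of each query row against each training row.

    Inputs are 0/1 fingerprint matrices; similarity of two all-zero vectors
    is defined as 0.
    """
    q = np.asarray(query, dtype=np.float64)
    t = np.asarray(train, dtype=np.float64)
    inter = q @ t.T
    union = q.sum(axis=1)[:, None] + t.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def pairwise_similarities(train: np.ndarray) -> np.ndarray:
    """All unordered pairwise Tanimoto similarities of the training set."""
    sim = tanimoto_matrix(train, train)
    iu = np.triu_indices(sim.shape[0], k=1)
    return sim[iu]


def fit_ad(
    train_fps: np.ndarray, z: float, k: int, sample_std: bool = False
) -> ADParams:
    """Fit gamma_bar and sigma over all training pairs and form D_T.

    ``sample_std`` switches sigma from the population (ddof=0, default) to
    the sample (ddof=1) standard deviation.  If D_T exceeds 1 the domain may
    be empty; a warning is issued and the threshold is left unclamped.
    """
    train_fps = np.asarray(train_fps)
    if train_fps.shape[0] < 2:
        raise ValueError("need at least 2 training molecules")
    sims = pairwise_similarities(train_fps)
    gamma_bar = float(np.mean(sims))
    sigma = float(np.std(sims, ddof=1 if sample_std else 0))
    params = ADParams(gamma_bar=gamma_bar, sigma=sigma, z=float(z), k=int(k))
    if params.d_t > 1.0:
        warnings.warn(
            f"D_T = {params.d_t:.3f} exceeds 1; the applicability domain may be empty",
            stacklevel=2,
        )
    return params


def top_k_similarities(
    query_fps: np.ndarray, train_fps: np.ndarray, k: int
) -> np.ndarray:
    """The K largest training similarities per query, descending, shape (nq, k)."""
    train_fps = np.asarray(train_fps)
    if k > train_fps.shape[0]:
        raise ValueError(f"K={k} exceeds training size {train_fps.shape[0]}")
    sim = tanimoto_matrix(np.atleast_2d(query_fps), train_fps)
    part = np.partition(sim, sim.shape[1] - k, axis=1)[:, -k:]
    return np.sort(part, axis=1)[:, ::-1]


def classify(
    query_fps: np.ndarray, train_fps: np.ndarray, params: ADParams
) -> tuple[list[str], np.ndarray]:
    """ID/OD call per query plus its top-K similarities.

    A query is ID when its K-th largest similarity meets D_T (inclusive
    comparison; the boundary case is measure-zero but documented).
    """
    topk = top_k_similarities(query_fps, train_fps, params.k)
    status = [
        IN_DOMAIN if row[-1] >= params.d_t else OUT_OF_DOMAIN for row in topk
    ]
    return status, topk


def coverage(query_fps: np.ndarray, train_fps: np.ndarray, params: ADParams) -> float:
    status, _ = classify(query_fps, train_fps, params)
    return sum(s == IN_DOMAIN for s in status) / len(status)


def grid_search_ad(
    model,
    train_fps: np.ndarray,
    test_dataset,
    test_fps: np.ndarray,
    k_grid: Sequence[int],
    z_grid: Sequence[float],
    min_coverage: float = 0.75,
    sample_std: bool = False,
) -> tuple[ADParams, dict]:
    """Coverage-constrained grid search over (K, z).

    Among grid points whose ID coverage of the test set is at least
    ``min_coverage``, the pair maximizing consensus AUC on the ID compounds
    wins; ties go to larger coverage, then smaller z, then smaller K.
    Raises if no point meets the coverage floor, reporting the best
    attainable coverage.
    """
    from sklearn.metrics import roc_auc_score

    from .chem_io import POSITIVE

    probs = model.predict_proba([r.smiles for r in test_dataset])
    y = np.array([1 if r.label == POSITIVE else 0 for r in test_dataset])
    base = fit_ad(train_fps, z=0.0, k=1, sample_std=sample_std)

    candidates = []
    best_cov = 0.0
    for k in k_grid:
        topk = top_k_similarities(test_fps, train_fps, k)
        kth = topk[:, -1]
        for z in z_grid:
            params = ADParams(base.gamma_bar, base.sigma, float(z), int(k))
            mask = kth >= params.d_t
            cov = float(mask.mean())
            best_cov = max(best_cov, cov)
            if cov < min_coverage:
                continue
            if len(np.unique(y[mask])) < 2:
                continue
            auc = float(roc_auc_score(y[mask], probs[mask]))
            candidates.append(((auc, cov, -z, -k), params, {"auc": auc, "coverage": cov}))
    if not candidates:
        raise ValueError(
            f"no (K, z) grid point reaches coverage {min_coverage:.2f}; "
            f"best attainable coverage is {best_cov:.3f}"
        )
    candidates.sort(key=lambda c: c[0], reverse=True)
    _, params, info = candidates[0]
    return params, info
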