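"""Apply transformation rules to Ames-positive molecules.

A rule matches a molecule where some fragmentation's variable part equals
the rule's left-hand side (up to attachment renumbering) and the
constant-side attachment environment digest at the chosen minimum radius is
one the rule was derived in.  Each symmetry-distinct site is transformed
exactly once, by zipping the constant part with the rule's right-hand side;
products failing valence sanitization are dropped and logged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

from . import applicability_domain as ad
from .chem_io import LabeledDataset, MoleculeRecord, NEGATIVE, POSITIVE
from .mmpa_engine import (
    RADII,
    TransformationRule,
    _relabel_smiles,
    enumerate_fragmentations,
    environment_digests,
    map_permutations,
    reassemble,
)
from .mutagenicity_model import ConsensusModel, featurize_many

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratedCompound:
    """One transformed product with its domain status and model verdict."""

    parent_id: str
    rule_id: str
    min_radius: int
    product: str
    domain_status: str | None = None
    predicted_label: str | None = None
    probability: float | None = None


class _SiteIndex:
    """Per-molecule lookup from rule LHS to applicable constant parts.

    All fragmentations (size filters off, so large leaving groups still
    match) are expanded over attachment-map renumberings; each variant
    variable string maps to the consistently renumbered constant part.
    """

    def __init__(self, mol_or_smiles, max_cuts: int = 3):
        self.variants: dict[str, set[str]] = defaultdict(set)
        frags = enumerate_fragmentations(
            mol_or_smiles, max_cuts, apply_size_filters=False
        )
        for f in frags:
            for perm in map_permutations(f.cut_count):
                var = _relabel_smiles(f.variable_part, perm)
                const = _relabel_smiles(f.constant_part, perm)
                self.variants[var].add(const)

    def sites(self, lhs: str) -> list[str]:
        return sorted(self.variants.get(lhs, ()))


def match_sites(
    molecule: str,
    rule: TransformationRule,
    min_radius: int = 0,
    index: _SiteIndex | None = None,
) -> list[str]:
    """Constant parts of the molecule where the rule applies.

    A site qualifies when the fragmentation's variable part equals the
    rule's LHS and the constant part's environment digest at ``min_radius``
    was recorded for the rule.  Symmetry-equivalent sites share a canonical
    constant part and therefore collapse.
    """
    if min_radius not in RADII:
        raise ValueError(f"min_radius must be in {RADII}, got {min_radius}")
    if index is None:
        index = _SiteIndex(molecule, max_cuts=rule.cut_count)
    allowed = rule.env_hashes.get(min_radius, frozenset())
    out = []
    for const in index.sites(rule.lhs):
        digest = environment_digests(const, radii=(min_radius,))[min_radius]
        if digest in allowed:
            out.append(const)
    return out


def apply_rule(
    molecule: str,
    rule: TransformationRule,
    min_radius: int = 0,
    parent_id: str = "",
    index: _SiteIndex | None = None,
) -> list[GeneratedCompound]:
    """Transform each matching site once; canonical, sanitized, deduplicated.

    Products identical to the parent are discarded, as are products that
    fail valence sanitization (logged at debug level).
    """
    parent_canon = Chem.CanonSmiles(molecule)
    products: list[GeneratedCompound] = []
    seen: set[str] = set()
    for const in match_sites(molecule, rule, min_radius, index=index):
        try:
            prod = reassemble(const, rule.rhs)
        except Exception as exc:
            logger.debug("dropped invalid product of %s at %s: %s", rule.rule_id, const, exc)
            continue
        if prod == parent_canon or prod in seen:
            continue
        seen.add(prod)
        products.append(GeneratedCompound(parent_id, rule.rule_id, min_radius, prod))
    return products


def generate_candidates(
    positives: Sequence[MoleculeRecord] | LabeledDataset,
    rules: Sequence[TransformationRule],
    min_radius: int,
    model: ConsensusModel | None = None,
    ad_params: ad.ADParams | None = None,
    train_fps=None,
) -> tuple[list[GeneratedCompound], dict]:
    """Expand every positive with every applicable rule and score products.

    Each product is classified ID/OD against the training fingerprints and,
    when in-domain, scored by the consensus model.  The tally mirrors the
    generation bookkeeping: ``N_pos`` input positives, ``N_trans`` positives
    with at least one applicable rule, ``N_gen`` products, ``N_ID``
    in-domain products, and the ID predicted positive/negative split.
    """
    records = list(positives)
    raw: list[GeneratedCompound] = []
    transformed_parents: set[str] = set()
    max_cuts = max((r.cut_count for r in rules), default=1)
    for rec in records:
        index = _SiteIndex(rec.smiles, max_cuts=max_cuts)
        for rule in rules:
            prods = apply_rule(
                rec.smiles, rule, min_radius, parent_id=rec.record_id, index=index
            )
            if prods:
                transformed_parents.add(rec.record_id)
                raw.extend(prods)

    raw.sort(key=lambda g: (g.parent_id, g.rule_id, g.product))
    scored: list[GeneratedCompound] = []
    n_id = n_id_pos = n_id_neg = 0
    if raw and model is not None and ad_params is not None and train_fps is not None:
        fps = featurize_many([g.product for g in raw], "ecfp")
        status, _ = ad.classify(fps, train_fps, ad_params)
        id_idx = [i for i, s in enumerate(status) if s == ad.IN_DOMAIN]
        probs = {}
        if id_idx:
            p = model.predict_proba([raw[i].product for i in id_idx])
            probs = dict(zip(id_idx, p))
        for i, g in enumerate(raw):
            if status[i] == ad.IN_DOMAIN:
                prob = float(probs[i])
                label = POSITIVE if prob >= model.threshold else NEGATIVE
                n_id += 1
                if label == POSITIVE:
                    n_id_pos += 1
                else:
                    n_id_neg += 1
                scored.append(
                    GeneratedCompound(
                        g.parent_id, g.rule_id, g.min_radius, g.product,
                        ad.IN_DOMAIN, label, prob,
                    )
                )
            else:
                scored.append(
                    GeneratedCompound(
                        g.parent_id, g.rule_id, g.min_radius, g.product,
                        ad.OUT_OF_DOMAIN, None, None,
                    )
                )
    else:
        scored = raw

    tally = {
        "N_pos": len(records),
        "N_trans": len(transformed_parents),
        "N_gen": len(scored),
        "N_ID": n_id,
        "N_ID_pos": n_id_pos,
        "N_ID_neg": n_id_neg,
    }
    return scored, tally


def generated_to_frame(generated: Iterable[GeneratedCompound]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent_id": g.parent_id,
                "rule_id": g.rule_id,
                "min_radius": g.min_radius,
                "product": g.product,
                "domain_status": g.domain_status,
                "predicted_label": g.predicted_label,
                "probability": g.probability,
            }
            for g in generated
        ],
        columns=[
            "parent_id",
            "rule_id",
            "min_radius",
            "product",
            "domain_status",
            "predicted_label",
            "probability",
        ],
    )
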