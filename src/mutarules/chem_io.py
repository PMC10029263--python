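"""Reading, standardization, deduplication and splitting of labeled molecule sets.

Every downstream stage (matched-pair mining, model training, rule scoring)
consumes the :class:`LabeledDataset` produced here.  Standardization keeps the
largest carbon-containing component of a salt, neutralizes simple charges, and
rejects mixtures (two or more carbon-containing components) and inorganics
(no carbon at all).  Labels are binary Ames calls: ``"positive"`` (revertant
growth induced in at least one strain) or ``"negative"``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)

_UNCHARGER = rdMolStandardize.Uncharger()


class RejectionReason(str, enum.Enum):
    """Why a raw SMILES record was dropped during standardization."""

    PARSE = "parse"
    MIXTURE = "mixture"
    INORGANIC = "inorganic"


class StandardizationError(ValueError):
    """Raised when a raw SMILES cannot be standardized; carries a reason code."""

    def __init__(self, reason: RejectionReason, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason.value}: {detail}" if detail else reason.value)


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def standardize(raw_smiles: str) -> str:
    """Return the canonical isomeric SMILES of the parent organic component.

    Salts are reduced to their carbon-containing component with charges
    neutralized where a simple proton transfer suffices (carboxylates back to
    acids, ammonium back to amines).  Raises :class:`StandardizationError`
    with reason ``parse`` (unparseable), ``mixture`` (>=2 carbon-containing
    components) or ``inorganic`` (no carbon-containing component).
    """
    if raw_smiles is None or not str(raw_smiles).strip():
        raise StandardizationError(RejectionReason.PARSE, "empty SMILES")
    mol = Chem.MolFromSmiles(str(raw_smiles))
    if mol is None:
        raise StandardizationError(RejectionReason.PARSE, str(raw_smiles))
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if _has_carbon(f)]
    if not organic:
        raise StandardizationError(RejectionReason.INORGANIC, str(raw_smiles))
    if len(organic) >= 2:
        raise StandardizationError(RejectionReason.MIXTURE, str(raw_smiles))
    parent = _UNCHARGER.uncharge(organic[0])
    Chem.SanitizeMol(parent)
    return Chem.MolToSmiles(parent)


def canonicalize(smiles: str) -> str:
    """Canonical isomeric SMILES (idempotent; raises on unparseable input)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StandardizationError(RejectionReason.PARSE, smiles)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One standardized molecule with its binary Ames label and provenance."""

    record_id: str
    smiles: str
    label: str
    source: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class LabeledDataset:
    """Ordered collection of :class:`MoleculeRecord` with unique ids and structures."""

    records: tuple[MoleculeRecord, ...]
    name: str = ""

    def __post_init__(self):
        self.records = tuple(self.records)
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("record_id values must be unique")
        smis = [r.smiles for r in self.records]
        if len(set(smis)) != len(smis):
            raise ValueError("canonical SMILES must be unique; deduplicate first")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> Mapping[str, str]:
        return {r.record_id: r.label for r in self.records}

    def subset(self, ids: Iterable[str], name: str = "") -> "LabeledDataset":
        wanted = set(ids)
        return LabeledDataset(
            tuple(r for r in self.records if r.record_id in wanted),
            name or self.name,
        )

    def positives(self) -> tuple[MoleculeRecord, ...]:
        return tuple(r for r in self.records if r.label == POSITIVE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.record_id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


def curate(
    raw: Iterable[tuple[str, str, str, str]], name: str = ""
) -> tuple[LabeledDataset, list[tuple[str, str, str]]]:
    """Standardize and deduplicate raw (id, smiles, label, source) rows.

    Returns the curated dataset plus a rejection log of
    ``(record_id, reason_code, raw_smiles)`` tuples.
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[str, str, str]] = []
    for rid, smi, label, source in raw:
        try:
            canon = standardize(smi)
        except StandardizationError as exc:
            rejected.append((str(rid), exc.reason.value, str(smi)))
            continue
        kept.append(MoleculeRecord(str(rid), canon, str(label), str(source)))
    return deduplicate(kept, name=name), rejected


def deduplicate(records: Sequence[MoleculeRecord], name: str = "") -> LabeledDataset:
    """Collapse records sharing a canonical SMILES to one record.

    The merged label is the majority vote over duplicates; ties resolve to
    positive (the conservative toxicology convention: a structure flagged
    mutagenic in any source stays flagged).  Source tags are concatenated
    with ``;`` preserving first-seen order.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.smiles not in groups:
            groups[rec.smiles] = []
            order.append(rec.smiles)
        groups[rec.smiles].append(rec)
    merged: list[MoleculeRecord] = []
    for smi in order:
        group = groups[smi]
        n_pos = sum(1 for r in group if r.label == POSITIVE)
        label = POSITIVE if 2 * n_pos >= len(group) else NEGATIVE
        sources: list[str] = []
        for r in group:
            if r.source and r.source not in sources:
                sources.append(r.source)
        merged.append(
            MoleculeRecord(group[0].record_id, smi, label, ";".join(sources))
        )
    return LabeledDataset(tuple(merged), name=name)


def split(
    dataset: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random disjoint train/test partition with ``|test| = round(f * N)``.

    Simple (non-stratified) sampling; reproducible for a given seed.  The
    original record order is preserved within each side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    test_idx = set(rng.permutation(n)[:n_test].tolist())
    train_recs = tuple(r for i, r in enumerate(dataset.records) if i not in test_idx)
    test_recs = tuple(r for i, r in enumerate(dataset.records) if i in test_idx)
    suffix = dataset.name + "/" if dataset.name else ""
    return (
        LabeledDataset(train_recs, name=f"{suffix}train"),
        LabeledDataset(test_recs, name=f"{suffix}test"),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O


def read_molecule_table(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read raw (id, smiles, label, source) rows from delimited text or .smi.

    Delimited files need header columns ``id, smiles, label, source`` (comma
    or tab separated).  ``.smi`` files are ``SMILES<TAB>id`` and require a
    sidecar ``<stem>.labels`` delimited file with columns ``id, label``.
    """
    path = Path(path)
    if path.suffix == ".smi":
        rows: list[tuple[str, str, str, str]] = []
        sidecar = path.with_suffix(".labels")
        labels = pd.read_csv(sidecar, sep=None, engine="python", dtype=str)
        label_map = dict(zip(labels["id"], labels["label"]))
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            smi, rid = parts[0], parts[1] if len(parts) > 1 else parts[0]
            rows.append((rid, smi, label_map[rid], path.stem))
        return rows
    df = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    missing = {"id", "smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = ""
    return list(df[["id", "smiles", "label", "source"]].itertuples(index=False, name=None))


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path: str | Path, name: str = "") -> LabeledDataset:
    df = pd.read_csv(path, dtype=str).fillna("")
    recs = tuple(
        MoleculeRecord(row.id, row.smiles, row.label, row.source)
        for row in df.itertuples(index=False)
    )
    return LabeledDataset(recs, name=name or Path(path).stem)


def write_rejections(rejections: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(rejections, columns=["id", "reason", "raw_smiles"]).to_csv(
        path, index=False
    )
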