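"""Seeded synthetic molecule sets with planted structural-alert chemistry.

The generator decorates small scaffolds (benzene, toluene, pyridine,
naphthalene, short alkyl chains) with one or two substituents drawn from an
alert list (nitro, N-nitrosamine, epoxide, aliphatic bromide, aromatic azo
-- classic mutagenicity structural alerts) and a benign list (H, methyl,
hydroxyl, methoxy, carboxyl, amide).  The Ames label is positive exactly
when an alert is present, then flipped with a small noise probability;
ground truth is kept in a manifest so planted alert-removal rules can be
checked end to end.  Because substituted and unsubstituted variants share
scaffolds, matched molecular pairs are guaranteed to exist.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import LabeledDataset, MoleculeRecord, NEGATIVE, POSITIVE

DEFAULT_SCAFFOLDS: dict[str, str] = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "pyridine": "c1ccncc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "butane": "CCCC",
    "hexane": "CCCCCC",
}

# attachment-ready fragments; [*:1] marks the bond to the scaffold
DEFAULT_ALERTS: dict[str, str] = {
    "nitro": "[*:1][N+](=O)[O-]",
    "nitrosamine": "[*:1]N(C)N=O",
    "epoxide": "[*:1]CC1CO1",
    "aliphatic_bromide": "[*:1]CCBr",
    "azo": "[*:1]N=Nc1ccccc1",
}

DEFAULT_BENIGN: dict[str, str | None] = {
    "hydrogen": None,  # no substitution
    "methyl": "[*:1]C",
    "hydroxyl": "[*:1]O",
    "methoxy": "[*:1]OC",
    "carboxyl": "[*:1]C(=O)O",
    "amide": "[*:1]C(=O)N",
}

# published structures of the two nitro-drug case studies
NIFURTIMOX = "CC1CS(=O)(=O)CCN1/N=C/c1ccc([N+](=O)[O-])o1"
METRONIDAZOLE = "Cc1ncc([N+](=O)[O-])n1CCO"


@dataclass
class FixtureSpec:
    """Parameters of the synthetic labeled molecule set."""

    n_molecules: int = 400
    scaffolds: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SCAFFOLDS))
    alerts: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ALERTS))
    benign: dict[str, str | None] = field(default_factory=lambda: dict(DEFAULT_BENIGN))
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for name, smi in {**self.alerts, **{k: v for k, v in self.benign.items() if v}}.items():
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid substituent SMILES for {name!r}: {smi!r}")


def _attachment_atoms(mol: Chem.Mol) -> list[int]:
    """Carbon atoms with a free hydrogen, eligible for substitution."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1
    ]


def _attach(scaffold: Chem.Mol, atom_idx: int, substituent: str) -> Chem.Mol | None:
    """Bond a [*:1]-tagged substituent fragment to the given scaffold atom."""
    rw = Chem.RWMol(scaffold)
    dummy = Chem.Atom(0)
    dummy.SetAtomMapNum(1)
    di = rw.AddAtom(dummy)
    rw.AddBond(atom_idx, di, Chem.BondType.SINGLE)
    sub = Chem.MolFromSmiles(substituent)
    combo = Chem.CombineMols(rw.GetMol(), sub)
    try:
        merged = Chem.molzip(combo)
        Chem.SanitizeMol(merged)
    except Exception:
        return None
    return merged


def generate(spec: FixtureSpec) -> tuple[LabeledDataset, dict]:
    """Build the labeled dataset and its ground-truth manifest.

    Fully deterministic for a given seed.  The manifest records, per record,
    the scaffold, substituents, true alert content, the noiseless label and
    whether noise flipped it, plus the scaffold groups within which
    substituent swaps form matched pairs.
    """
    if spec.n_molecules < 10:
        raise ValueError("n_molecules must be >= 10 (too small for cross-validation)")
    rng = np.random.default_rng(spec.seed)
    scaffold_names = sorted(spec.scaffolds)
    alert_names = sorted(spec.alerts)
    benign_names = sorted(spec.benign)

    records: list[MoleculeRecord] = []
    manifest_records: dict[str, dict] = {}
    seen_smiles: set[str] = set()
    scaffold_of: dict[str, str] = {}
    attempts = 0
    while len(records) < spec.n_molecules and attempts < 200 * spec.n_molecules:
        attempts += 1
        scaffold_name = scaffold_names[rng.integers(len(scaffold_names))]
        mol = Chem.MolFromSmiles(spec.scaffolds[scaffold_name])
        # first substituent: alert with probability 1/2, else benign;
        # optional second substituent always benign, keeping classes balanced
        subs: list[str] = []
        if alert_names and rng.random() < 0.5:
            subs.append(alert_names[rng.integers(len(alert_names))])
        else:
            subs.append(benign_names[rng.integers(len(benign_names))])
        if rng.random() < 0.4:
            subs.append(benign_names[rng.integers(len(benign_names))])

        ok = True
        for name in subs:
            frag = spec.alerts.get(name) or spec.benign.get(name)
            if frag is None:
                continue  # "hydrogen": leave the scaffold untouched
            sites = _attachment_atoms(mol)
            if not sites:
                ok = False
                break
            mol2 = _attach(mol, sites[rng.integers(len(sites))], frag)
            if mol2 is None:
                ok = False
                break
            mol = mol2
        if not ok:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen_smiles:
            continue
        seen_smiles.add(smiles)

        alerts_present = sorted(set(subs) & set(alert_names))
        true_label = POSITIVE if alerts_present else NEGATIVE
        flipped = bool(rng.random() < spec.label_noise)
        label = (
            (NEGATIVE if true_label == POSITIVE else POSITIVE) if flipped else true_label
        )
        rid = f"M{len(records):04d}"
        records.append(MoleculeRecord(rid, smiles, label, source="synthetic"))
        scaffold_of[rid] = scaffold_name
        manifest_records[rid] = {
            "scaffold": scaffold_name,
            "substituents": subs,
            "alerts": alerts_present,
            "true_label": true_label,
            "label": label,
            "flipped": flipped,
        }
    if len(records) < spec.n_molecules:
        raise RuntimeError(
            f"could only build {len(records)} distinct molecules of {spec.n_molecules}"
        )

    scaffold_groups: dict[str, list[str]] = {}
    for rid, sc in scaffold_of.items():
        scaffold_groups.setdefault(sc, []).append(rid)
    manifest = {
        "spec": {
            "n_molecules": spec.n_molecules,
            "label_noise": spec.label_noise,
            "seed": spec.seed,
            "scaffolds": spec.scaffolds,
            "alerts": spec.alerts,
            "benign": {k: (v or "") for k, v in spec.benign.items()},
        },
        "records": manifest_records,
        "scaffold_groups": scaffold_groups,
    }
    return LabeledDataset(tuple(records), name=f"fixture-seed{spec.seed}"), manifest


def case_study_molecules() -> tuple[MoleculeRecord, MoleculeRecord]:
    """Nifurtimox and metronidazole, two marketed nitro drugs with reported
    mutagenic potential, packaged as Ames-positive demo records."""
    return (
        MoleculeRecord(
            "nifurtimox", Chem.CanonSmiles(NIFURTIMOX), POSITIVE, "case-study"
        ),
        MoleculeRecord(
            "metronidazole", Chem.CanonSmiles(METRONIDAZOLE), POSITIVE, "case-study"
        ),
    )


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
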