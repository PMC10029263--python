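"""Matched-molecular-pair fragmentation, indexing, and transformation rules.

The engine cuts 1-3 acyclic single bonds between heavy atoms (Hussain-Rea
style fragment indexing).  A fragmentation splits a molecule into a
*constant part* and a single connected *variable part*; both carry the same
number of numbered attachment points ``[*:n]``.  Two molecules sharing a
constant part with different variable parts form a matched molecular pair
(MMP).  Pairs whose members carry opposite Ames labels yield directional
transformation rules ``positive_variable >> negative_variable`` in SMIRKS
form, with the local chemical environment of the constant-side attachment
atoms recorded as SHA-256 digests at radii 0-5.

Size conventions for the variable part: between 2 and 15 heavy atoms and at
most half the parent's heavy atoms; a bare hydrogen ``[*:1][H]`` is
additionally allowed on single cuts so hydrogen-replacement rules such as
nitro -> H are expressible.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem

HYDROGEN_VARIABLE = "[H][*:1]"  # canonical SMILES of a one-hydrogen variable part
RADII = tuple(range(6))

CATEGORY_BY_CUTS = {1: "single-cut", 2: "double-cut", 3: "triple-cut"}
CATEGORIES = tuple(CATEGORY_BY_CUTS[k] for k in (1, 2, 3))

# frequency buckets of the rule-summary contingency table
SUMMARY_BUCKETS = ("1", "2-4", "5-9", "10+")


@dataclass(frozen=True)
class Fragmentation:
    """One cut decomposition of a parent molecule."""

    parent_id: str
    cut_count: int
    constant_part: str
    variable_part: str
    variable_heavy_atoms: int


@dataclass(frozen=True)
class MMP:
    """Two molecules sharing a constant part with different variable parts."""

    left_id: str
    right_id: str
    constant_part: str
    left_variable: str
    right_variable: str
    cut_count: int


@dataclass
class TransformationRule:
    """Directional SMIRKS rule with category, frequency and environment digests.

    ``env_hashes[r]`` is the set of radius-``r`` attachment-environment
    digests observed across all supporting MMP occurrences; application of
    the rule at minimum radius ``r`` requires the target's digest to be in
    this set.
    """

    rule_id: str
    smirks: str
    category: str
    frequency: int
    env_hashes: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def lhs(self) -> str:
        return self.smirks.split(">>")[0]

    @property
    def rhs(self) -> str:
        return self.smirks.split(">>")[1]

    @property
    def cut_count(self) -> int:
        return {v: k for k, v in CATEGORY_BY_CUTS.items()}[self.category]


# ---------------------------------------------------------------------------
# Fragment canonicalization helpers


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable fragment SMILES: {smiles!r}")
    return mol


def _relabel_smiles(smiles: str, perm: Mapping[int, int]) -> str:
    """Renumber ``[*:i]`` attachment maps according to ``perm`` and canonicalize."""
    mol = Chem.RWMol(_mol(smiles))
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            atom.SetAtomMapNum(perm[atom.GetAtomMapNum()])
    return Chem.MolToSmiles(mol.GetMol())


def map_permutations(k: int) -> list[dict[int, int]]:
    """All renumberings of attachment maps 1..k."""
    return [
        {i + 1: p for i, p in enumerate(perm)}
        for perm in itertools.permutations(range(1, k + 1))
    ]


def _canonical_pair(constant: Chem.Mol, variable: Chem.Mol, k: int) -> tuple[str, str]:
    """Deterministic numbered form: lexicographic minimum of
    (constant SMILES, variable SMILES) over all k! attachment renumberings."""
    best: tuple[str, str] | None = None
    for perm in map_permutations(k):
        cs = _relabel_mol_smiles(constant, perm)
        vs = _relabel_mol_smiles(variable, perm)
        if best is None or (cs, vs) < best:
            best = (cs, vs)
    assert best is not None
    return best


def _relabel_mol_smiles(mol: Chem.Mol, perm: Mapping[int, int]) -> str:
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            atom.SetAtomMapNum(perm[atom.GetAtomMapNum()])
    return Chem.MolToSmiles(out.GetMol())


def _isotopes_to_maps(mol: Chem.Mol) -> Chem.Mol:
    """FragmentOnBonds labels dummies by isotope; convert to atom maps."""
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope():
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    return out.GetMol()


def _n_attachment_points(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def _heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Cuttable bonds: acyclic single bonds between two heavy atoms."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


def reassemble(constant_part: str, variable_part: str) -> str:
    """Rejoin a constant and variable part at their numbered attachment
    points and return the parent's canonical SMILES."""
    combo = Chem.MolFromSmiles(constant_part + "." + variable_part, sanitize=False)
    if combo is None:
        raise ValueError(f"cannot parse {constant_part!r} + {variable_part!r}")
    merged = Chem.molzip(combo)
    merged = Chem.RemoveHs(merged, sanitize=False)
    Chem.SanitizeMol(merged)
    return Chem.MolToSmiles(merged)


# ---------------------------------------------------------------------------
# Enumeration


def enumerate_fragmentations(
    mol: Chem.Mol | str,
    max_cuts: int = 3,
    *,
    parent_id: str = "",
    min_variable_heavy: int = 2,
    max_variable_heavy: int = 15,
    enforce_half: bool = True,
    apply_size_filters: bool = True,
    include_hydrogen: bool = True,
) -> list[Fragmentation]:
    """All 1..max_cuts fragmentations of a standardized molecule.

    The variable part must be a single connected fragment carrying all cut
    attachment points (for double/triple cuts this selects linker and
    scaffold exchanges); for single cuts both orientations are emitted.
    Chirality flags survive cutting.  With ``apply_size_filters`` the
    2..15 heavy-atom window and the at-most-half-the-parent constraint are
    applied to non-hydrogen variable parts.  Single-cut hydrogen
    fragmentations (variable part ``[*:1][H]``) are emitted when
    ``include_hydrogen`` so hydrogen-replacement rules are expressible.
    """
    if isinstance(mol, str):
        mol = _mol(mol)
    if not 1 <= max_cuts <= 3:
        raise ValueError("max_cuts must be 1, 2 or 3")
    parent_heavy = _heavy_atoms(mol)
    bonds = eligible_bonds(mol)
    seen: set[tuple[int, str, str]] = set()
    out: list[Fragmentation] = []

    def _accept(k: int, constant: str, variable: str, var_heavy: int) -> None:
        key = (k, constant, variable)
        if key in seen:
            return
        seen.add(key)
        out.append(Fragmentation(parent_id, k, constant, variable, var_heavy))

    for k in range(1, max_cuts + 1):
        for subset in itertools.combinations(bonds, k):
            labels = [(i + 1, i + 1) for i in range(k)]
            frag = Chem.FragmentOnBonds(
                mol, list(subset), addDummies=True, dummyLabels=labels
            )
            try:
                pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
            except Exception:
                continue
            pieces = [_isotopes_to_maps(p) for p in pieces]
            for i, piece in enumerate(pieces):
                if _n_attachment_points(piece) != k:
                    continue  # variable part must touch every cut
                var_heavy = _heavy_atoms(piece)
                if apply_size_filters:
                    if not (min_variable_heavy <= var_heavy <= max_variable_heavy):
                        continue
                    if enforce_half and 2 * var_heavy > parent_heavy:
                        continue
                rest = [p for j, p in enumerate(pieces) if j != i]
                constant = rest[0]
                for extra in rest[1:]:
                    constant = Chem.CombineMols(constant, extra)
                cs, vs = _canonical_pair(constant, piece, k)
                _accept(k, cs, vs, var_heavy)

    if include_hydrogen:
        for frag in _hydrogen_fragmentations(mol, parent_id):
            _accept(1, frag.constant_part, frag.variable_part, 0)
    return out


def _hydrogen_fragmentations(mol: Chem.Mol, parent_id: str) -> list[Fragmentation]:
    """Single-cut fragmentations whose variable part is one hydrogen atom."""
    out: list[Fragmentation] = []
    if _heavy_atoms(mol) < 2:
        return out  # a lone heavy atom has nothing constant to keep
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() < 1:
            continue
        rw = Chem.RWMol(mol)
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(1)
        di = rw.AddAtom(dummy)
        rw.AddBond(atom.GetIdx(), di, Chem.BondType.SINGLE)
        candidate = rw.GetMol()
        try:
            Chem.SanitizeMol(candidate)
        except Exception:
            continue
        out.append(
            Fragmentation(
                parent_id, 1, Chem.MolToSmiles(candidate), HYDROGEN_VARIABLE, 0
            )
        )
    return out


# ---------------------------------------------------------------------------
# Environment fingerprints


def environment_digests(
    constant_part: str, radii: Sequence[int] = RADII
) -> dict[int, str]:
    """SHA-256 digest of the circular environment of the constant-side
    attachment atoms, one digest per radius.

    For each attachment point, in map-number order, the radius-``r``
    neighborhood of the atom bonded to the dummy is rendered as a rooted
    canonical SMILES; the per-site strings are joined and hashed.  The
    digest is a pure function of (constant part, radius).
    """
    mol = _mol(constant_part)
    dummies = sorted(
        (a for a in mol.GetAtoms() if a.GetAtomicNum() == 0),
        key=lambda a: a.GetAtomMapNum(),
    )
    attach = [d.GetNeighbors()[0].GetIdx() for d in dummies]
    out: dict[int, str] = {}
    for r in radii:
        if not 0 <= r <= max(RADII):
            raise ValueError(f"radius must be in {RADII}, got {r}")
        parts: list[str] = []
        for idx in attach:
            if r == 0:
                parts.append(Chem.MolFragmentToSmiles(mol, atomsToUse=[idx]))
                continue
            # when r exceeds the site's eccentricity the env comes back
            # empty; fall back to the largest available sphere so larger
            # radii stay at least as strict as smaller ones
            env = ()
            for rr in range(r, 0, -1):
                env = Chem.FindAtomEnvironmentOfRadiusN(mol, rr, idx)
                if env:
                    break
            if not env:
                parts.append(Chem.MolFragmentToSmiles(mol, atomsToUse=[idx]))
                continue
            amap: dict[int, int] = {}
            sub = Chem.PathToSubmol(mol, env, atomMap=amap)
            parts.append(Chem.MolToSmiles(sub, rootedAtAtom=amap[idx]))
        out[r] = hashlib.sha256("|".join(parts).encode("utf-8")).hexdigest()
    return out


# ---------------------------------------------------------------------------
# Pair indexing and rule derivation


def fragment_dataset(
    dataset, max_cuts: int = 3, **kwargs
) -> list[Fragmentation]:
    """Enumerate fragmentations for every record of a dataset."""
    out: list[Fragmentation] = []
    for rec in dataset:
        out.extend(
            enumerate_fragmentations(
                rec.smiles, max_cuts, parent_id=rec.record_id, **kwargs
            )
        )
    return out


def index_pairs(fragmentations: Iterable[Fragmentation]) -> list[MMP]:
    """Index fragmentations by constant part and emit all cross pairs.

    For every constant part shared by >=2 molecules, each unordered pair of
    molecules with distinct variable parts yields one MMP per fragmentation
    pattern.  Pair orientation is normalized by record id so output is
    deterministic.
    """
    by_constant: dict[tuple[int, str], dict[str, str]] = defaultdict(dict)
    for f in fragmentations:
        by_constant[(f.cut_count, f.constant_part)][f.parent_id] = f.variable_part
    pairs: list[MMP] = []
    for (k, constant), members in sorted(by_constant.items()):
        if len(members) < 2:
            continue
        items = sorted(members.items())
        for (id_a, var_a), (id_b, var_b) in itertools.combinations(items, 2):
            if var_a == var_b:
                continue
            pairs.append(MMP(id_a, id_b, constant, var_a, var_b, k))
    return pairs


def _canonical_smirks(
    lhs: str, rhs: str, constant: str, k: int
) -> tuple[str, str, str]:
    """Canonicalize a rule: renumber attachment maps jointly on LHS/RHS (and
    consistently on the supporting constant part) minimizing (LHS, RHS)."""
    best: tuple[str, str, str] | None = None
    for perm in map_permutations(k):
        ls = _relabel_smiles(lhs, perm)
        rs = _relabel_smiles(rhs, perm)
        cs = _relabel_smiles(constant, perm)
        if best is None or (ls, rs) < (best[0], best[1]):
            best = (ls, rs, cs)
    assert best is not None
    return best


def canonical_smirks(lhs: str, rhs: str, cut_count: int) -> str:
    """Unique SMIRKS string for an (LHS, RHS) fragment pair: attachment maps
    are renumbered jointly, minimizing (LHS, RHS) lexicographically."""
    dummy_constant = ".".join(f"[*:{i + 1}]C" for i in range(cut_count))
    ls, rs, _ = _canonical_smirks(lhs, rhs, dummy_constant, cut_count)
    return f"{ls}>>{rs}"


def derive_rules(
    mmps: Iterable[MMP], labels: Mapping[str, str]
) -> list[TransformationRule]:
    """Directional rules from opposite-label pairs.

    Only pairs with one Ames-positive and one Ames-negative member produce a
    rule, oriented positive-side variable >> negative-side variable.  Rules
    are merged across supporting MMPs: frequency is the count of distinct
    supporting pairs and environment digests accumulate per radius.  Rules
    are sorted by (frequency desc, smirks) and assigned sequential ids.
    """
    from .chem_io import NEGATIVE, POSITIVE

    support: dict[tuple[str, int], set[tuple[str, str]]] = defaultdict(set)
    env: dict[tuple[str, int], dict[int, set[str]]] = defaultdict(
        lambda: {r: set() for r in RADII}
    )
    for mmp in mmps:
        try:
            la, lb = labels[mmp.left_id], labels[mmp.right_id]
        except KeyError as exc:
            raise ValueError(f"missing label for record {exc.args[0]!r}") from exc
        if {la, lb} != {POSITIVE, NEGATIVE}:
            continue
        if la == POSITIVE:
            lhs, rhs = mmp.left_variable, mmp.right_variable
        else:
            lhs, rhs = mmp.right_variable, mmp.left_variable
        ls, rs, cs = _canonical_smirks(lhs, rhs, mmp.constant_part, mmp.cut_count)
        key = (f"{ls}>>{rs}", mmp.cut_count)
        support[key].add(tuple(sorted((mmp.left_id, mmp.right_id))))
        digests = environment_digests(cs)
        for r, d in digests.items():
            env[key][r].add(d)

    ordered = sorted(support.items(), key=lambda kv: (-len(kv[1]), kv[0][0]))
    rules: list[TransformationRule] = []
    for i, ((smirks, k), pairs) in enumerate(ordered):
        rules.append(
            TransformationRule(
                rule_id=f"R{i + 1:05d}",
                smirks=smirks,
                category=CATEGORY_BY_CUTS[k],
                frequency=len(pairs),
                env_hashes={r: frozenset(v) for r, v in env[(smirks, k)].items()},
            )
        )
    return rules


# ---------------------------------------------------------------------------
# Summary table and rules I/O


def frequency_bucket(freq: int) -> str:
    if freq >= 10:
        return "10+"
    if freq >= 5:
        return "5-9"
    if freq >= 2:
        return "2-4"
    return "1"


def summarize_rules(rules: Sequence[TransformationRule]) -> pd.DataFrame:
    """Frequency-bucket x category contingency table with margins.

    Rows are frequency buckets ``1, 2-4, 5-9, 10+`` plus ``Total``; columns
    the three cut categories plus ``Total`` and ``pct`` (share of the grand
    total per row, in percent).
    """
    counts = pd.DataFrame(0, index=list(SUMMARY_BUCKETS), columns=list(CATEGORIES))
    for rule in rules:
        counts.loc[frequency_bucket(rule.frequency), rule.category] += 1
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)
    grand = counts.loc["Total", "Total"]
    counts["pct"] = (
        100.0 * counts["Total"] / grand if grand else 0.0
    )
    return counts


def rules_to_frame(rules: Sequence[TransformationRule]) -> pd.DataFrame:
    rows = []
    for r in rules:
        row = {
            "rule_id": r.rule_id,
            "smirks": r.smirks,
            "category": r.category,
            "frequency": r.frequency,
        }
        for radius in RADII:
            row[f"env_r{radius}"] = ";".join(sorted(r.env_hashes.get(radius, ())))
        rows.append(row)
    return pd.DataFrame(rows)


def write_rules(rules: Sequence[TransformationRule], path: str | Path) -> None:
    rules_to_frame(rules).to_csv(path, index=False)


def read_rules(path: str | Path) -> list[TransformationRule]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out: list[TransformationRule] = []
    for row in df.itertuples(index=False):
        env = {
            r: frozenset(
                d for d in getattr(row, f"env_r{r}").split(";") if d
            )
            for r in RADII
        }
        out.append(
            TransformationRule(
                rule_id=row.rule_id,
                smirks=row.smirks,
                category=row.category,
                frequency=int(row.frequency),
                env_hashes=env,
            )
        )
    return out
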