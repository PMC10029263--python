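"""Independent brute-force oracles used to cross-check the MMP engine.

The fragmentation oracle enumerates every subset of up to three cuttable
bonds directly with RDKit's FragmentOnBonds (default dummy labeling) and
normalizes fragments by *stripping* attachment labels, whereas the engine
assigns canonical map numbers.  Comparing the two label-free projections
checks the cut enumeration and size filtering along a different code path.
"""

from __future__ import annotations

import itertools

from rdkit import Chem


def _strip_attachments(mol: Chem.Mol) -> str:
    out = Chem.RWMol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(out.GetMol())


def strip_fragment_labels(smiles: str) -> str:
    """Label-free canonical form; multi-piece fragments are sorted."""
    pieces = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        pieces.append(_strip_attachments(mol))
    return ".".join(sorted(pieces))


def brute_force_fragmentations(
    smiles: str,
    max_cuts: int = 3,
    min_variable_heavy: int = 2,
    max_variable_heavy: int = 15,
    enforce_half: bool = True,
    apply_size_filters: bool = True,
) -> set[tuple[int, str, str]]:
    """All (cut_count, constant, variable) triples, attachment labels stripped.

    The variable part is the single connected piece carrying all cut points;
    for single cuts both orientations count.
    """
    mol = Chem.MolFromSmiles(smiles)
    parent_heavy = mol.GetNumHeavyAtoms()
    bonds = [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]
    found: set[tuple[int, str, str]] = set()
    for k in range(1, max_cuts + 1):
        for subset in itertools.combinations(bonds, k):
            cut = Chem.FragmentOnBonds(mol, list(subset), addDummies=True)
            try:
                pieces = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=True)
            except Exception:
                continue
            for i, piece in enumerate(pieces):
                n_attach = sum(1 for a in piece.GetAtoms() if a.GetAtomicNum() == 0)
                if n_attach != k:
                    continue
                var_heavy = sum(
                    1 for a in piece.GetAtoms() if a.GetAtomicNum() > 1
                )
                if apply_size_filters:
                    if not min_variable_heavy <= var_heavy <= max_variable_heavy:
                        continue
                    if enforce_half and 2 * var_heavy > parent_heavy:
                        continue
                variable = _strip_attachments(piece)
                constant = ".".join(
                    sorted(
                        _strip_attachments(p) for j, p in enumerate(pieces) if j != i
                    )
                )
                found.add((k, constant, variable))
    return found
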