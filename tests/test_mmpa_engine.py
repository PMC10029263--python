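import pytest
from rdkit import Chem

from mutarules.chem_io import LabeledDataset, MoleculeRecord, NEGATIVE, POSITIVE
from mutarules.mmpa_engine import (
    HYDROGEN_VARIABLE,
    canonical_smirks,
    derive_rules,
    enumerate_fragmentations,
    environment_digests,
    fragment_dataset,
    frequency_bucket,
    index_pairs,
    read_rules,
    reassemble,
    summarize_rules,
    write_rules,
)
from oracles import brute_force_fragmentations, strip_fragment_labels


def canon(smiles: str) -> str:
    return Chem.CanonSmiles(smiles)


def _dataset(pairs):
    return LabeledDataset(
        tuple(MoleculeRecord(rid, canon(smi), lab) for rid, smi, lab in pairs)
    )


class TestEnumerate:
    def test_methane_empty(self):
        assert enumerate_fragmentations("C", 3) == []

    def test_ethanol_single_cuts_unfiltered(self):
        frags = enumerate_fragmentations(
            "CCO", 1, apply_size_filters=False, include_hydrogen=False
        )
        # two cuttable bonds (C-C, C-O), each yielding both orientations
        assert len(frags) == 4
        assert {f.cut_count for f in frags} == {1}

    def test_size_window_enforced(self):
        # variable parts of one heavy atom are excluded by the 2..15 window
        frags = enumerate_fragmentations("CCO", 1, include_hydrogen=False)
        assert all(2 <= f.variable_heavy_atoms <= 15 for f in frags)

    def test_half_molecule_constraint(self):
        for f in enumerate_fragmentations("CCCCCCCCc1ccccc1", 2, include_hydrogen=False):
            parent_heavy = Chem.MolFromSmiles("CCCCCCCCc1ccccc1").GetNumHeavyAtoms()
            assert 2 * f.variable_heavy_atoms <= parent_heavy

    def test_hydrogen_fragmentations_on_benzene(self):
        frags = enumerate_fragmentations("c1ccccc1", 1)
        # no acyclic bonds, but every aromatic CH offers a hydrogen cut;
        # all six positions are symmetry-equivalent
        assert len(frags) == 1
        assert frags[0].variable_part == HYDROGEN_VARIABLE

    def test_roundtrip_reassembly(self, fixture_small):
        dataset, _ = fixture_small
        for rec in list(dataset)[:40]:
            for f in enumerate_fragmentations(rec.smiles, 3):
                assert reassemble(f.constant_part, f.variable_part) == rec.smiles

    def test_attachment_counts_match_cut_count(self):
        for f in enumerate_fragmentations("CCCCc1ccc(CCN)cc1", 3, apply_size_filters=False):
            for part in (f.constant_part, f.variable_part):
                mol = Chem.MolFromSmiles(part, sanitize=False)
                n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
                assert n_attach == f.cut_count

    def test_chirality_preserved(self):
        frags = enumerate_fragmentations(
            canon("C[C@H](N)CCCC"), 1, apply_size_filters=False, include_hydrogen=False
        )
        assert any("@" in f.constant_part or "@" in f.variable_part for f in frags)

    def test_oracle_equivalence_small_molecules(self, fixture_small):
        dataset, _ = fixture_small
        mols = [
            r.smiles
            for r in dataset
            if Chem.MolFromSmiles(r.smiles).GetNumHeavyAtoms() <= 12
        ][:40]
        assert len(mols) >= 10
        for smi in mols:
            engine = {
                (
                    f.cut_count,
                    strip_fragment_labels(f.constant_part),
                    strip_fragment_labels(f.variable_part),
                )
                for f in enumerate_fragmentations(smi, 3, include_hydrogen=False)
            }
            assert engine == brute_force_fragmentations(smi, 3), smi


class TestIndexPairs:
    def test_nitrobenzene_aniline_pair(self):
        ds = _dataset(
            [
                ("nb", "c1ccccc1[N+](=O)[O-]", POSITIVE),
                ("an", "c1ccccc1N", NEGATIVE),
            ]
        )
        pairs = index_pairs(
            fragment_dataset(ds, apply_size_filters=False, include_hydrogen=False)
        )
        assert len(pairs) == 1
        p = pairs[0]
        assert p.cut_count == 1
        assert {p.left_variable, p.right_variable} == {
            canon("[*:1][N+](=O)[O-]"),
            canon("[*:1]N"),
        }

    def test_identical_structures_no_pair(self):
        # same structure under two ids: variable parts always coincide
        frags = enumerate_fragmentations(
            "CCCCO", 3, parent_id="a"
        ) + enumerate_fragmentations("CCCCO", 3, parent_id="b")
        assert index_pairs(frags) == []

    def test_unrelated_structures_no_pair(self):
        ds = _dataset([("a", "OC(=O)CCCCC(=O)O", POSITIVE), ("b", "c1ccncc1", NEGATIVE)])
        assert index_pairs(fragment_dataset(ds)) == []


class TestDeriveRules:
    def _nitro_dataset(self):
        return _dataset(
            [
                ("nb", "c1ccccc1[N+](=O)[O-]", POSITIVE),
                ("bz", "c1ccccc1", NEGATIVE),
            ]
        )

    def test_nitro_to_hydrogen_rule(self):
        ds = self._nitro_dataset()
        rules = derive_rules(index_pairs(fragment_dataset(ds)), ds.labels)
        assert len(rules) == 1
        rule = rules[0]
        assert rule.lhs == canon("[*:1][N+](=O)[O-]")
        assert rule.rhs == canon("[*:1][H]")
        assert rule.category == "single-cut"
        assert rule.frequency == 1

    def test_same_label_pairs_emit_nothing(self):
        ds = _dataset(
            [
                ("nb", "c1ccccc1[N+](=O)[O-]", POSITIVE),
                ("cl", "c1ccccc1Cl", POSITIVE),
            ]
        )
        assert derive_rules(index_pairs(fragment_dataset(ds)), ds.labels) == []

    def test_missing_label_raises(self):
        ds = self._nitro_dataset()
        pairs = index_pairs(fragment_dataset(ds))
        with pytest.raises(ValueError):
            derive_rules(pairs, {"nb": POSITIVE})

    def test_frequency_counts_distinct_pairs(self):
        # three scaffolds each present as nitro-compound and bare parent
        ds = _dataset(
            [
                ("p1", "Cc1ccc(cc1)[N+](=O)[O-]", POSITIVE),
                ("n1", "Cc1ccccc1", NEGATIVE),
                ("p2", "CCc1ccc(cc1)[N+](=O)[O-]", POSITIVE),
                ("n2", "CCc1ccccc1", NEGATIVE),
                ("p3", "OCc1ccc(cc1)[N+](=O)[O-]", POSITIVE),
                ("n3", "OCc1ccccc1", NEGATIVE),
            ]
        )
        rules = derive_rules(index_pairs(fragment_dataset(ds)), ds.labels)
        nitro = canon("[*:1][N+](=O)[O-]")
        freq = {r.smirks: r.frequency for r in rules}
        assert freq[f"{nitro}>>{canon('[*:1][H]')}"] == 3

    def test_relabeling_swaps_direction(self, fixture_small):
        dataset, _ = fixture_small
        sub = LabeledDataset(dataset.records[:60])
        pairs = index_pairs(fragment_dataset(sub))
        forward = derive_rules(pairs, sub.labels)
        flipped = {
            k: (NEGATIVE if v == POSITIVE else POSITIVE)
            for k, v in sub.labels.items()
        }
        backward = derive_rules(pairs, flipped)
        fwd = {r.smirks for r in forward}
        rev = {
            canonical_smirks(r.rhs, r.lhs, r.cut_count) for r in backward
        }
        assert fwd == rev

    def test_env_hash_deterministic(self):
        c = "Cc1ccc([*:1])cc1"
        assert environment_digests(c) == environment_digests(c)
        assert len(set(environment_digests(c).values())) > 1


class TestSummary:
    def test_empty(self):
        table = summarize_rules([])
        assert table.loc["Total", "Total"] == 0

    def test_constructed_counts(self):
        from mutarules.mmpa_engine import TransformationRule

        rules = [
            TransformationRule("r1", "a>>b", "single-cut", 1),
            TransformationRule("r2", "c>>d", "single-cut", 3),
            TransformationRule("r3", "e>>f", "double-cut", 7),
            TransformationRule("r4", "g>>h", "triple-cut", 12),
        ]
        table = summarize_rules(rules)
        assert table.loc["1", "single-cut"] == 1
        assert table.loc["2-4", "single-cut"] == 1
        assert table.loc["5-9", "double-cut"] == 1
        assert table.loc["10+", "triple-cut"] == 1
        assert table.loc["Total", "Total"] == 4
        assert table.loc["Total", "pct"] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "freq, bucket", [(1, "1"), (2, "2-4"), (4, "2-4"), (5, "5-9"), (9, "5-9"), (10, "10+"), (172, "10+")]
    )
    def test_buckets(self, freq, bucket):
        assert frequency_bucket(freq) == bucket


def test_rules_roundtrip_io(tmp_path, fixture_small):
    dataset, _ = fixture_small
    sub = LabeledDataset(dataset.records[:60])
    rules = derive_rules(index_pairs(fragment_dataset(sub)), sub.labels)
    assert rules, "fixture should yield at least one rule"
    path = tmp_path / "rules.csv"
    write_rules(rules, path)
    back = read_rules(path)
    assert [(r.rule_id, r.smirks, r.category, r.frequency) for r in back] == [
        (r.rule_id, r.smirks, r.category, r.frequency) for r in rules
    ]
    assert all(a.env_hashes == b.env_hashes for a, b in zip(back, rules))
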