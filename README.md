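# mutarules

Chemical rules for reversing Ames mutagenicity, mined by matched molecular
pairs analysis (MMPA) and validated with a stacked machine-learning
classifier.

Mutagenicity flagged by the Ames assay is a frequent show-stopper in lead
optimization, and medicinal chemists lack systematic guidance for which
substructure edits actually remove it. `mutarules` derives that guidance
from data: given a table of molecules with binary Ames labels it

1. standardizes and deduplicates the structures,
2. enumerates single/double/triple-cut fragmentations, indexes matched
   molecular pairs (molecules differing in one localized fragment), and
   keeps the directional transformations that turn an Ames-positive member
   into an Ames-negative one as SMIRKS rules
   (e.g. `[*:1][N+](=O)[O-]>>[*:1][H]`, nitro removal), recording the
   attachment environment at radii 0–5 as SHA-256 digests,
3. trains a consensus mutagenicity classifier — SVM, random forest,
   XGBoost, LightGBM and gradient boosting over MACCS/RDK/ECFP
   fingerprints, stacked by logistic regression on out-of-fold
   probabilities — with a Tanimoto-similarity applicability domain

   D_T = γ̄ + z·σ

   (γ̄, σ: mean and SD of all pairwise training similarities; a query is
   in-domain when its K nearest training similarities all reach D_T), and
4. applies every rule to every Ames-positive molecule and scores each rule's
   validity

   S_validity = N_neg / N_total

   the fraction of its in-domain products the model predicts Ames-negative,
   stratified by environment radius, rule frequency and cut category.

A seeded synthetic-fixture generator plants classic structural alerts
(nitro, N-nitrosamine, epoxide, aliphatic bromide, azo) on shared scaffolds
so the whole pipeline runs and is testable without any external dataset.

## Worked example

```python
from rdkit import Chem
from mutarules import (
    LabeledDataset, MoleculeRecord, derive_rules, fragment_dataset,
    index_pairs, apply_rule, similarity_threshold,
)

ds = LabeledDataset((
    MoleculeRecord("nb", Chem.CanonSmiles("c1ccccc1[N+](=O)[O-]"), "positive"),
    MoleculeRecord("bz", "c1ccccc1", "negative"),
))
rules = derive_rules(index_pairs(fragment_dataset(ds)), ds.labels)
print(rules[0].smirks, rules[0].category, rules[0].frequency)
# O=[N+]([O-])[*:1]>>[H][*:1] single-cut 1

products = apply_rule(Chem.CanonSmiles("Cc1ccc(cc1)[N+](=O)[O-]"), rules[0], min_radius=0)
print(products[0].product)
# Cc1ccccc1

print(round(similarity_threshold(gamma_bar=0.0880, sigma=0.0625, z=4), 3))
# 0.338
```

The nitrobenzene/benzene pair yields the directional nitro-removal rule;
applied to 4-nitrotoluene under a radius-0 environment constraint it
produces toluene (the two symmetric match sites of a symmetric substrate
collapse to one product).  The last line is the similarity threshold of an
applicability domain with mean pairwise training similarity 0.0880,
standard deviation 0.0625 and significance multiplier z = 4.

## Command line

```bash
mutarules fixture --n 400 --seed 7 --noise 0.05 --out fixture.csv --manifest manifest.json
mutarules run-all --seed 7 --n 400 --out run/
```

`run-all` executes curate → mmpa → train/stack → ad-fit → optimize →
evaluate and writes every table plus `report.md` (rule summary, generation
tally, per-radius/frequency/category validity) into the run directory.
Individual stages (`curate`, `mmpa`, `train`, `ad-fit`, `optimize`,
`evaluate`) are also exposed and re-runnable.

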