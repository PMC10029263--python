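# Methods

## Curation

Raw SMILES are parsed with RDKit and reduced to their parent structure:
components without carbon are treated as counter-ions and dropped, a single
remaining carbon-containing component is neutralized with RDKit's Uncharger
(simple proton transfers only, e.g. carboxylate → acid), and the result is
written as canonical isomeric SMILES.  Two or more carbon-containing
components constitute a mixture and are rejected; zero constitute an
inorganic and are rejected.  No tautomer canonicalization is attempted —
the simplest reproducible convention — so tautomer pairs are distinct
records.  Duplicates (identical canonical SMILES) collapse by majority
vote over labels with ties resolved to positive, matching the conservative
Ames convention that a compound mutagenic in any strain is called positive.
Train/test splitting is simple random with `|test| = round(f·N)`; for
N = 8576 at f = 0.1 this gives 858/7718, which differs by 2 from the
widely used 7720/856 partition of the same size — the reference assignment
procedure is not specified, so we document the divergence rather than
reverse-engineer it.

## Fragmentation and matched pairs

Cuttable bonds are acyclic single bonds between two heavy atoms; ring bonds
are never cut.  For k = 1..3 cut bonds the molecule splits into k+1 pieces.
The *variable part* must be a single connected piece carrying all k
attachment points; the *constant part* is the union of the remaining
pieces.  For single cuts both orientations are emitted.  For double and
triple cuts this convention admits only "linker" and "star/scaffold"
topologies: a 3-cut path decomposition has no piece touching all three
cuts and is therefore not a valid matched-pair decomposition here.  The
half-molecule constraint is `2·(variable heavy atoms) ≤ parent heavy
atoms`, and the size window is 2–15 heavy atoms for non-hydrogen variable
parts.  A bare hydrogen variable (`[H][*:1]`) is additionally emitted for
every heavy atom bearing a hydrogen (molecules with ≥ 2 heavy atoms), so
hydrogen-replacement rules such as nitro → H are expressible; this is the
deliberate exception to the 2-atom minimum that the flagship rule requires.
Chirality flags survive cutting, so stereo-only exchanges remain distinct.

Attachment numbering must be unique for rule merging to work.  Rather than
a two-step "canonical order of the constant, then tie-break" procedure, we
renumber the k ≤ 3 attachment maps over all k! permutations and keep the
labeling that lexicographically minimizes the (constant SMILES, variable
SMILES) pair; rules are canonicalized the same way over (LHS, RHS).  This
single rule is deterministic, symmetric-case-safe, and cheap.

Pairs are indexed Hussain–Rea style: fragmentations are grouped by
(cut count, constant part); every unordered pair of distinct molecules
with distinct variable parts under one constant yields one matched pair
per fragmentation pattern.  Pairs with one positive and one negative
member produce a directional rule `positive variable >> negative
variable`; same-label pairs produce nothing.  Rule frequency counts
distinct supporting pairs.

## Attachment environments

For each constant part the circular environment of each attachment atom is
rendered as a rooted canonical SMILES at radii 0–5 (radius 0: the atom
itself), concatenated over attachment points in map order, and hashed with
SHA-256.  When a requested radius exceeds the site's eccentricity the
largest available sphere is used instead of falling back to the bare atom;
this keeps larger radii at least as strict as smaller ones, so the set of
sites a rule matches can only shrink as the minimum radius grows.  Rule
application requires the target's digest at exactly the chosen minimum
radius to be among the digests recorded for the rule at that radius
(per-radius strata are the analysis unit, so radii are not pooled).

## Rule application

A rule matches a molecule where some fragmentation (size filters off, so
large leaving groups still match) has a variable part equal to the rule's
LHS up to attachment renumbering, with the environment digest admissible.
Each symmetry-distinct site — distinct canonical constant part — is
transformed once by zipping the constant part with the rule's RHS on atom
maps; products are sanitized, canonicalized and deduplicated, products
identical to the parent are discarded, and valence failures are dropped
and logged rather than repaired.  Output ordering is canonical
(parent id, rule id, product SMILES), making generation runs byte-stable.

## Consensus model

Fingerprints: MACCS keys (166 bits, bit 0 dropped), RDKit path
fingerprints (2048 bits), Morgan/ECFP radius 2 (1024 bits).  The default
roster pairs each algorithm with the fingerprint it performs best with:
RF+RDK, SVM+ECFP, LightGBM+RDK, XGBoost+MACCS, GB+MACCS.  Hyper-parameters
come from small documented grids (`DEFAULT_GRIDS`) searched under
stratified k-fold cross-validation (default 5 folds), selecting on mean
AUC with mean sensitivity as tie-break — sensitivity matters more than
specificity in toxicity screening.  A graph-neural-network base classifier
is deliberately out of scope; the stack accepts any ≥ 2 configured bases.

The meta-learner is logistic regression over base-classifier
probabilities.  Meta-features are out-of-fold cross-validated
probabilities on the training set — in-sample probabilities would leak the
training labels into the meta-fit — after which the bases are refitted on
the full training set.  The decision threshold is 0.5 on the consensus
probability.  All estimators run single-threaded with fixed seeds, so a
fixed config seed reproduces coefficients and metrics exactly.

Metrics follow the standard confusion identities (SE = TP/(TP+FN),
SP = TN/(TN+FP), ACC, F1) with AUC as the mid-rank statistic; AUC is
reported missing on single-class data.

## Applicability domain

γ̄ and σ are the mean and *population* standard deviation (a sample-SD
switch is exposed) of all unordered pairwise Tanimoto similarities of the
training-set ECFP fingerprints; they are statistics of the whole training
set, independent of K.  The threshold is D_T = γ̄ + z·σ, held as an exact
identity (D_T is derived, never stored).  A query is in-domain when its
K-th largest training similarity is ≥ D_T; the inclusive comparison
matters only on a measure-zero boundary.  D_T > 1 triggers a warning, not
clamping.  (K, z) are selected by grid search constrained to ID coverage
of a labeled test set ≥ `min_coverage` (default 0.75, i.e. retaining
roughly three quarters of the test set), maximizing AUC over the ID
compounds, with ties resolved toward larger coverage, then smaller z, then
smaller K.  Coverage is provably non-increasing in both z (threshold
grows) and K (the K-th largest similarity is non-increasing in K).

## Rule validity

S_validity = N_neg/N_total over a rule's *in-domain* products only; rules
with no ID products are flagged unevaluable and excluded from proportion
denominators.  High quality means S_validity strictly greater than 0.5; a
rule at exactly 0.5 is not high quality.  A product generated by several
rules counts once per generating rule (usage is a per-rule notion).  The
usage filter keeps rules with ≥ `min_usage` (default 10) ID products.
Stratified transformation validity S_t.v. = N_neg/N_gen is computed per
environment radius, per rule-frequency bucket ({1}, {2–3}, {>3} for the
frequency analysis; {1}, {2–4}, {5–9}, {10+} for the summary table), and
per cut category.

In the default workflow, rules are mined from the full curated set while
the model is trained on the train split only; the split exists to tune and
evaluate the classifier, whereas rule mining benefits from all labeled
structures.

## Synthetic fixtures

The generator emulates the *logical* structure of an Ames SAR dataset, not
its chemistry-space statistics: small scaffolds (benzene, toluene,
pyridine, naphthalene, butane, hexane) are decorated with one or two
substituents; the first is a structural alert with probability 1/2 (nitro,
N-nitrosamine, epoxide, aliphatic bromide, aromatic azo — all classic
mutagenicity alerts), any second substituent is benign (H, methyl,
hydroxyl, methoxy, carboxyl, amide).  The label is positive iff an alert
is present, then flipped with probability 0.05 (default); noise perturbs
labels, never structures, so the manifest's ground truth stays exact.
Defaults are n = 400 molecules and 5% noise, giving near 1:1 class balance
and guaranteed matched pairs (substituted and bare variants share
scaffolds).  Decoration is attachment-point concatenation with
post-sanitization — deterministic per seed, byte-identical across runs.

What passing tests on these fixtures do show: the fragmentation/indexing
machinery is exact (checked against an independent brute force), rules
planted by construction are recovered with high S_validity while
label-neutral decoys are not, and the whole pipeline is deterministic.
What they do not show: performance on real Ames data, whose chemical
diversity, label noise structure, and alert interactions are far richer;
absolute rule counts and model AUCs on public benchmarks are outside the
scope of this package's tests.

## Problem sizes and numerical choices

The validation suite runs the full pipeline once at the default conditions
(n = 400, 5% noise, 5-fold CV, five-member stack) for the planted-rule
check, a 120-molecule set for unit-scale chemistry tests, and a pair of
150-molecule, 3-fold runs for the byte-identity check — sizes chosen so
the suite completes in minutes on one CPU while still exercising every
stage.  Ties in grid search resolve to the first-seen parameter
combination in sorted-key order; duplicate fragmentations deduplicate on
(cut count, constant, variable); all randomness flows from explicit seeds
(the pipeline derives per-stage seeds as config seed + stage offset).

## Known limitations

Single-step transformations only (no sequential rule application); no
ADMET co-optimization of generated structures; no ring-cut or fuzzy
matched-pair variants; desk-scale pair indexing (in-memory dictionaries,
not a database); no tautomer awareness; the applicability domain is purely
similarity-based (no leverage/density/conformal alternatives).
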