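# Methods

This note documents the models, numerical choices and limitations of
`gpcrscreen`. It covers what each component assumes, which parameters
matter and why their defaults are what they are, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Conformational-selectivity scores

`ΔAffinity_r = ΔG_active,r − ΔG_inactive,r` (kcal/mol) is computed from
the best-pose binding free energies of a ligand docked to both conformers
of receptor *r*. Exactly one best-pose energy per
(ligand, receptor, conformer) is accepted; duplicates are an ingestion
error, because pose selection belongs to the docking engine, not to this
package. A ligand lacking one conformer's energy on a receptor
contributes nothing to that receptor and is skipped with a logged
warning (not an error): partially docked panels are a normal occurrence.

**Borderline band.** Ligands with |ΔAffinity| ≤ 0.3 kcal/mol on the
target show no reliable conformer preference — the difference is inside
docking-score noise — and are excluded from training, except ids the
caller explicitly protects (e.g. the endogenous agonist, retained for
physiological relevance). The band is closed (`≤ 0.3`), and the screening
filter that keeps inactive-preferring compounds is strict (`> 0.3`), so
the two rules partition the axis with no gap and applying them in
sequence is idempotent.

**Off-target score** is the sum of |ΔAffinity_r| over all panel
receptors except the target. It is invariant to receptor order and to
the sign of each term; an empty panel scores 0 with a warning. Higher
values flag promiscuous binders.

## Feature representation

A ligand's features are, in fixed column order:
`MW, LogP, HBD, HBA, TPSA, DeltaAffinity, bit_0000 … bit_2047`.

Descriptors are **inputs**, not computed: the conventions of upstream
databases (XLogP3 for LogP in particular) are not reproducible in-house
without silent divergence, so the package refuses to guess them.

Fingerprints are radius-2 circular (Morgan/ECFP4) vectors folded to 2048
bits, computed with RDKit's connectivity invariants (element, degree,
charge, H count, ring membership, aromaticity). Stereochemistry is
ignored by default (`use_chirality` flag available): labels of opposite
enantiomers are rarely curated consistently, and the hashing of chiral
invariants differs more across toolchains than the achiral set. Bit
indices are implementation-specific — the pipeline always refers to
"top-k bits" positionally and maps them to fragment SMILES via the
recorded bit → atom-environment table for interpretation; absolute bit
numbers are not comparable across fingerprinting software.

Lipinski counting uses the classic four rules (MW > 500, LogP > 5,
HBD > 5, HBA > 10); library pre-filters conventionally keep compounds
with at most one violation.

## Classifier protocol

* stratified 80/20 split, split seed 42 (test size = ceil(0.2·n); a
  144-row set yields 115/29);
* per-fold standardization inside stratified 5-fold CV; the final
  scaler is fitted on the full training set only, never on test rows
  (verified by a perturbation test);
* exhaustive grid search over C ∈ {0.1, 1, 10} × gamma ∈ {scale, auto},
  RBF kernel; ties resolved by declared grid order (C outer, gamma
  inner);
* refit on the full training set with the winner.

**Probability calibration.** Probabilities of antagonism come from Platt
scaling fitted on *out-of-fold* decision values: the training set is
split into stratified folds (5, or fewer if a class is tiny), each
fold's decision values are produced by an SVM trained on the remaining
folds, and the sigmoid `P(antagonist|f) = 1/(1 + exp(a·f + b))` is fitted
to those values by regularized maximum likelihood (the standard smoothed
targets `(N₊+1)/(N₊+2)` and `1/(N₋+2)`). This keeps calibration free of
training optimism and makes every probability an exact closed form of
the decision value — which also permits a fast BLAS evaluation path used
by attribution on large hybrid batches. The predicted class is
`P ≥ 0.5`, so labels and probabilities never disagree.

**Confidence.** The confidence score defaults to the calibrated
probability of the predicted class; the |decision-function| margin is
available via `confidence_mode="margin"`. With a calibrated sigmoid the
two orderings coincide, so percentile selection is insensitive to the
choice. The confidence *percentile* is the weak within-batch rank
(fraction of batch scores ≤ the score); selection keeps records with
percentile strictly above the cut, which makes the selected count
exactly `ceil((100−pct)/100 · n)` for distinct scores (9 of 87 at the
90th percentile; exactly the maximum of 10) while fully tied batches
share percentile 1.0 and are all selected, with a warning.

## Evaluation

Confusion metrics use the standard definitions: accuracy (TP+TN)/n,
sensitivity TP/(TP+FN), specificity TN/(TN+FP). Undefined ratios
(zero denominators) are reported as NaN, never coerced to 0. AUC is the
rank statistic (Mann–Whitney U / n₊n₋, ties half), checked in tests
against a brute-force pairwise oracle.

The permutation test shuffles labels `n_perm` times (default 1000) and
re-runs the full stratified CV at the chosen hyperparameters each time;
p is the fraction of permuted accuracies ≥ the observed one. A raw p of
0 is additionally reported as "< 1/n_perm" to avoid overclaiming.

The bootstrap resamples test rows with replacement (default 1000) and
takes the percentile CI of the AUC distribution. Single-class resamples
are skipped and logged — not redrawn — so the effective count can be
below `n_boot`; redrawing would condition on separability and bias the
interval.

## Attribution (KernelSHAP)

The explained output is the calibrated probability of antagonism
(configurable to the raw margin — probabilities were chosen because they
are the quantity the screening funnel consumes). The background is the
K = 10 K-means *medoids* of the feature matrix (the member row nearest
each centroid), so backgrounds are real ligands; withheld features take
background values under the marginal (interventional) expectation.

Coalitions are enumerated fully when d ≤ 14 (in which case the
constrained weighted least squares with the Shapley kernel weight
`(d−1)/(C(d,|z|)·|z|·(d−|z|))` reproduces exact Shapley values, verified
against an independent enumeration oracle to 1e-6), otherwise sampled:
coalition sizes drawn from the normalized kernel size distribution,
membership uniform, default budget `2d + 2048` evaluations. The
local-accuracy constraint (base value + Σφ = model output) is enforced
exactly in both modes by eliminating one feature. The coalition design
is shared across explained rows so the normal equations are factorized
once (a 1e-10·tr(A)/d ridge guards conditioning; hybrid model
evaluations use float32 in sampled mode, where Monte-Carlo error is
orders of magnitude larger than single precision).

At the full 2048-bit width, the default sampled budget gives only a few
evaluations per feature, so individual bit rankings carry visible
Monte-Carlo noise; parameter-recovery studies therefore run at a reduced
width (256 bits, ~10 evaluations per feature), where the planted
driver bits are recovered reliably. A `grouped` mode excludes bits never
set anywhere in the matrix (their Shapley values are identically zero).

Ranking uses mean |Shapley value| over the explained set (first 50 rows
by default, unscaled values retained for display); top-k bit selection
breaks ties toward the lower bit index and omits zero-attribution bits.

## Screening funnel

Stages, each only shrinking the candidate set: any-of-top-5-bits filter
→ ΔAffinity > 0.3 → SVM prediction (keep antagonists) → top-10%
confidence percentile → ascending off-target score (ties: descending
target ΔAffinity, then id) → Spearman correlation of informative-bit
presence (prevalence strictly inside (0,1)) against the off-target
score, top 20 by |r|, positive r flagged promiscuity-associated,
negative r selectivity-associated (r < −0.4 marked strongly selective).
Bits that cannot be mapped to a substructure are dropped with a log.

**Any-of vs all-of.** The bit filter defaults to *any-of*: an all-of
rule empties realistic libraries (pass rate p⁵ for independent bits vs
1−(1−p)⁵), and observed pass rates in practice (~25%) are consistent
only with any-of. The mode is switchable.

## Surface areas

Shrake–Rupley with a 1.4 Å probe and 240 test points per atom on a
deterministic golden-spiral lattice (no RNG — results are
bit-reproducible). Van der Waals radii are the Bondi set (H 1.20, C 1.70,
N 1.55, O 1.52, S/P 1.80, F 1.47, Cl 1.75, Br 1.85, I 1.98; unknown
elements fall back to 1.70 Å with a warning). Isolated-sphere areas are
exact at any point count; two-sphere overlaps agree with the analytic
spherical-cap formula within 2% at 240 points, and totals change by
< 1% between 240 and 960 points on fixture complexes. Translation
invariance is exact; *rotation* invariance holds only to discretization
error (~1% at 240 points) because the lattice orientation is fixed —
the price of determinism, shared by standard SASA implementations.
Hydrogens are used if present in the input; none are added. PDB reading
takes the first altloc and prefers the element column, falling back to
atom names.

ΔSASA of a pose is `SASA_receptor + SASA_ligand − SASA_complex`;
Differential SASA between conformers is `ΔSASA_inactive − ΔSASA_active`
and is validated as a *sign/ordering* behaviour (bulkier or deeper-posed
ligands bury more surface) on constructed fixtures, not as absolute
areas: absolute values depend on the radii set and point algorithm of
the reference tool, which are not standardized.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

* 144 ligands, 66 agonists / 78 antagonists (exact counts under the
  default deterministic-count mode; Bernoulli draws optional);
* five planted driver bits with prevalence 0.8 in antagonists vs 0.1 in
  agonists, over i.i.d. background bits at rate 0.02 per bit
  (≈ 40 background bits per ligand, the density of drug-like ECFP4);
* molecular weight Normal(310, 80) for agonists vs Normal(420, 80) for
  antagonists (antagonists heavier — the regularity the classifier is
  expected to pick up); LogP, HBD, HBA, TPSA from shared families;
* target-receptor ΔAffinity Normal(0, 1) for agonists vs Normal(+2.5, 1)
  for antagonists; off-target ΔAffinity Normal(0, 1.5) on an
  11-receptor off-target panel; ΔG_active Normal(−6.5, 1) and
  ΔG_inactive = ΔG_active − ΔAffinity, so pairing reproduces the plant
  exactly by construction;
* screening libraries: a 25% antagonist-like / 75% decoy mixture with
  hidden truth labels retained for enrichment scoring;
* toy 3D complexes: a spherical carbon shell with a conical pocket and a
  ligand at its centre ("deep") or mouth ("shallow").

What the generator does **not** emulate: correlated fingerprint bits
(real substructures co-occur), descriptor–fingerprint dependence,
docking-score error structure, receptor-family covariance of off-target
scores, or any actual chemistry (synthetic compounds carry fingerprints
directly, with a small curated set of real SMILES exercising the
SMILES path). Passing tests therefore demonstrate that the pipeline
recovers planted signal of realistic magnitude under clean conditions —
not that it would achieve the same operating characteristics on curated
pharmacology data.

## Problem sizes used in tests

The default end-to-end run uses the full conditions (144 ligands,
2048 bits, 1000 permutations and bootstrap resamples, 500-compound
library) and completes in a few minutes on one CPU. Multi-seed
calibration studies (20 seeds) run at 256-bit width and reduced
resampling counts — chosen so the whole suite stays interactive while
keeping every per-seed problem statistically equivalent.

## Known limitations

* Descriptors must be supplied; no in-package LogP/TPSA computation.
* Fingerprint bit indices are not comparable across fingerprinting
  software; only positional "top-k" semantics are stable.
* Sampled KernelSHAP rankings at full width are Monte-Carlo noisy at the
  default budget (see above).
* SASA treats structures as rigid; induced-fit effects make absolute
  burial values model-dependent, so only relative comparisons between
  analogs are meaningful.
* The permutation test re-fits the SVM ~5·n_perm times; on noise labels
  libsvm converges slowly, making this the dominant pipeline cost.
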