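# gpcrscreen

Conformational-docking scores, SVM ligand classification, Shapley
attribution and screening prioritization for GPCR antagonist discovery.

## The problem

HCAR1 (GPR81) is a lactate-sensing Class A G protein-coupled receptor
implicated in tumour metabolism; selective antagonists for it are scarce.
A practical route to candidates combines three signals:

1. **Conformational selectivity from docking.** Each ligand is docked
   against the *active* (G-protein-coupled) and *inactive* (resting)
   conformer of a receptor. The difference of the best-pose binding free
   energies,

   ```
   ΔAffinity_r = ΔG_active,r − ΔG_inactive,r        [kcal/mol]
   ```

   is positive when the ligand prefers the inactive state — the behaviour
   expected of an antagonist. Promiscuity across a receptor panel is
   summarized by the off-target score,

   ```
   OffTarget = Σ_{r ≠ target} |ΔAffinity_r|
   ```

2. **A calibrated RBF-SVM classifier** over ligand features — five
   physicochemical descriptors (MW, LogP, HBD, HBA, TPSA), the target
   ΔAffinity, and a 2048-bit radius-2 circular (Morgan/ECFP4) fingerprint —
   trained on agonist/antagonist-labelled GPCR ligands with a stratified
   80/20 split, train-only standardization and 5-fold grid-search CV over
   C ∈ {0.1, 1, 10} × gamma ∈ {scale, auto}.

3. **KernelSHAP attribution** of the probability of antagonism, which
   extracts the fingerprint bits (substructures) that drive antagonist
   predictions; those bits seed a multi-stage screening funnel
   (bit filter → ΔAffinity filter → SVM confidence percentile →
   off-target prioritization → bit–selectivity Spearman correlation).

The package also implements a Shrake–Rupley solvent-accessible surface
area (SASA) module for quantifying ligand burial:
`ΔSASA = SASA_receptor + SASA_ligand − SASA_complex` and
`Differential SASA = ΔSASA_inactive − ΔSASA_active` (positive ⇒ deeper
burial in the inactive state).

Docking itself is out of scope: the package ingests docking tables (CSV,
or AutoDock Vina log excerpts) and ligand descriptor tables; it never
runs a docking engine. A first-class synthetic-data module generates
ligand sets, docking tables, screening libraries and toy 3D structures
with the statistical structure the pipeline assumes, so everything is
testable offline.

## Worked example

```python
from gpcrscreen import (
    GeneratorConfig, generate_training_set, pair_docking_records,
    apply_borderline_exclusion, build_feature_matrix,
    SplitSpec, stratified_split, grid_search_cv, fit_final, predict,
    confusion, metrics, roc_auc,
)
import numpy as np

cfg = GeneratorConfig(seed=42)            # 144 ligands, 66/78 classes
ligands, docking = generate_training_set(cfg)

affinities = pair_docking_records(docking)
target = [a for a in affinities if a.receptor_id == "HCAR1"]
target = apply_borderline_exclusion(target)          # drop |Δ| <= 0.3
ids = {a.ligand_id for a in target}
kept = [l for l in ligands if l.ligand_id in ids]

X = build_feature_matrix(kept, {a.ligand_id: a.delta_affinity for a in target})
y = np.array([l.label for l in kept])

tr, te = stratified_split(X, y, SplitSpec(seed=42))
best, cv_acc = grid_search_cv(X.iloc[tr], y[tr], seed=42)
model = fit_final(X.iloc[tr], y[tr], best, seed=42)
preds = predict(model, X.iloc[te])

cm = confusion([p.predicted_class for p in preds], y[te])
print(best, round(cv_acc, 3))
print(cm, metrics(cm))
print("AUC", round(roc_auc([p.prob_antagonist for p in preds], y[te]), 3))
```

prints

```
HyperParams(C=10.0, gamma='auto', kernel='rbf') 0.66
ConfusionMatrix(tp=13, tn=9, fp=2, fn=2) MetricSet(accuracy=0.846..., sensitivity=0.867..., specificity=0.818...)
AUC 0.933
```

i.e. on the default synthetic conditions the tuned model separates the
held-out classes with AUC ≈ 0.93: 13 of 15 antagonists and 9 of 11
agonists are called correctly.

The whole workflow — featurize → score → split → tune → evaluate
(permutation test, bootstrap AUC) → attribute → screen → prioritize →
correlate — runs end-to-end with

```bash
gpcrscreen run-all --out pipeline_out --seed 42
```

which writes per-stage CSV artifacts, a JSON report and a manifest
(resolved config + seeds + input hashes) sufficient to reproduce the run.

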