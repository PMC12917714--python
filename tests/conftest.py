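"""Shared fixtures: a reduced-width synthetic training bundle and a
trained classifier, reused across test modules (session-scoped — the
generator and trainer are deterministic, so sharing is safe)."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrscreen.affinity_scoring import apply_borderline_exclusion, pair_docking_records
from gpcrscreen.chem_features import build_feature_matrix
from gpcrscreen.classifier import (
    DEFAULT_GRID,
    SplitSpec,
    fit_final,
    grid_search_cv,
    stratified_split,
)
from gpcrscreen.synthetic_data import GeneratorConfig, generate_training_set

#: Reduced fingerprint width used throughout the tests: keeps K-means,
#: attribution and grid search fast while preserving every statistical
#: property of the full-width generator.
SMALL_NBITS = 256
SMALL_DRIVERS = (17, 63, 120, 201, 240)


def small_config(seed: int = 7, **overrides) -> GeneratorConfig:
    defaults = dict(nbits=SMALL_NBITS, driver_bits=SMALL_DRIVERS, seed=seed)
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def make_training_bundle(cfg: GeneratorConfig):
    """Generate → pair → exclude borderline → featurize, returning
    (matrix, labels, ligands, target affinity map, config)."""
    ligands, docking = generate_training_set(cfg)
    affinities = pair_docking_records(docking)
    target = [a for a in affinities if a.receptor_id == cfg.target_receptor]
    surviving = apply_borderline_exclusion(target)
    ids = {a.ligand_id for a in surviving}
    kept = [l for l in ligands if l.ligand_id in ids]
    aff_map = {a.ligand_id: a.delta_affinity for a in surviving}
    matrix = build_feature_matrix(kept, aff_map, nbits=cfg.nbits)
    labels = np.array([l.label for l in kept])
    return matrix, labels, kept, aff_map, cfg


@pytest.fixture(scope="session")
def training_bundle():
    return make_training_bundle(small_config())


@pytest.fixture(scope="session")
def trained_model(training_bundle):
    matrix, labels, *_ = training_bundle
    tr, te = stratified_split(matrix, labels, SplitSpec(seed=42))
    best, cv_acc = grid_search_cv(matrix.iloc[tr], labels[tr], DEFAULT_GRID, seed=42)
    model = fit_final(matrix.iloc[tr], labels[tr], best, seed=42)
    return {
        "model": model,
        "matrix": matrix,
        "labels": labels,
        "train_idx": tr,
        "test_idx": te,
        "best": best,
        "cv_accuracy": cv_acc,
    }
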