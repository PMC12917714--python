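"""Model-agnostic Shapley-value attribution (KernelSHAP).

The SVM has no model-specific Shapley explainer, so per-feature
attributions are estimated with the KernelSHAP weighted-regression
scheme: feature coalitions z ∈ {0,1}^d are enumerated (small d) or
sampled, the model is evaluated at hybrid points where "absent" features
are replaced by background values (marginal/interventional expectation
over a K-means background set of representative ligands), and the
Shapley values are the solution of a weighted least squares with the
Shapley kernel weight

    w(z) = (d − 1) / (C(d, |z|) · |z| · (d − |z|)),

constrained so that base_value + Σ_i φ_i equals the model output at the
explained point (local accuracy).  With full coalition enumeration this
recovers the exact Shapley values of the interventional game.

The explained model output is the calibrated probability of antagonism
by default; any scalar model function can be supplied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "BackgroundSet",
    "AttributionResult",
    "TopBits",
    "kmeans_background",
    "kernel_shap",
    "explain_model",
    "summarize",
    "top_k_bits",
]

logger = logging.getLogger(__name__)

EXHAUSTIVE_MAX_D = 14


@dataclass
class BackgroundSet:
    """K representative rows (medoids of K-means clusters) used as the
    reference distribution when features are withheld."""

    rows: np.ndarray           # (k, d)
    indices: np.ndarray        # row indices into the source matrix
    k: int
    seed: int


@dataclass
class AttributionResult:
    """Per-sample, per-feature Shapley values in model-output units."""

    values: np.ndarray         # (n_samples, d)
    base_value: float          # expected model output over the background
    feature_names: list[str]
    sample_ids: list[str]
    model_outputs: np.ndarray  # (n_samples,) f(x) at each explained row

    def block_mask(self, block: str) -> np.ndarray:
        """Boolean mask selecting the 'descriptors' or 'fingerprints' block."""
        is_bit = np.array([n.startswith("bit_") for n in self.feature_names])
        if block == "fingerprints":
            return is_bit
        if block == "descriptors":
            return ~is_bit
        raise ValueError(f"unknown block {block!r}")


@dataclass
class TopBits:
    """Fingerprint bits ranked by mean |Shapley value| (descending; ties by
    bit index)."""

    bits: list[int]
    mean_abs_shap: list[float]

    def __iter__(self):
        return iter(self.bits)

    def __len__(self):
        return len(self.bits)


def kmeans_background(matrix, k: int = 10, seed: int = 42) -> BackgroundSet:
    """Select k representative rows via K-means, medoid convention.

    Lloyd iterations with seeded initialization; each cluster is then
    represented by the member row nearest its centroid, so backgrounds are
    real ligands rather than fractional averages.
    """
    X = np.asarray(matrix, float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {X.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(X)
    indices = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(assign == c)
        dists = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        indices[c] = members[dists.argmin()]
    indices = np.sort(indices)
    return BackgroundSet(rows=X[indices], indices=indices, k=k, seed=seed)


def _shapley_kernel_weight(d: int, s: int) -> float:
    return (d - 1) / (math.comb(d, s) * s * (d - s))


def _exhaustive_coalitions(d: int) -> tuple[np.ndarray, np.ndarray]:
    """All coalitions 0 < |z| < d with exact Shapley kernel weights."""
    rows, weights = [], []
    for s in range(1, d):
        w = _shapley_kernel_weight(d, s)
        for comb in combinations(range(d), s):
            z = np.zeros(d)
            z[list(comb)] = 1.0
            rows.append(z)
            weights.append(w)
    return np.asarray(rows), np.asarray(weights)


def _sampled_coalitions(
    d: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n coalitions with size drawn from the normalized Shapley-kernel
    size distribution and uniform membership within a size; equal WLS weights
    (the kernel is accounted for by the sampling distribution)."""
    sizes = np.arange(1, d)
    p = (d - 1) / (sizes * (d - sizes))
    p = p / p.sum()
    Z = np.zeros((n, d))
    drawn = rng.choice(sizes, size=n, p=p)
    for i, s in enumerate(drawn):
        Z[i, rng.choice(d, size=s, replace=False)] = 1.0
    return Z, np.ones(n)


def _coalition_values(
    model_fn: Callable[[np.ndarray], np.ndarray],
    Z: np.ndarray,
    x: np.ndarray,
    background: np.ndarray,
    chunk: int = 512,
    dtype=np.float64,
) -> np.ndarray:
    """v(z) = mean_b f(z⊙x + (1−z)⊙b) for every coalition row of Z.

    Hybrid rows are built in ``dtype``: float64 where Shapley values are
    checked against exact enumeration, float32 for large sampled designs
    (whose Monte-Carlo error dwarfs single precision).
    """
    m, d = Z.shape
    n_bg = background.shape[0]
    x = x.astype(dtype, copy=False)
    background = background.astype(dtype, copy=False)
    mask = Z.astype(bool)
    out = np.empty(m)
    for start in range(0, m, chunk):
        mb = mask[start:start + chunk]                    # (c, d)
        hybrid = np.where(mb[:, None, :], x[None, None, :], background[None, :, :])
        preds = model_fn(hybrid.reshape(-1, d))
        out[start:start + chunk] = preds.reshape(len(mb), n_bg).mean(axis=1)
    return out


def kernel_shap(
    model_fn: Callable[[np.ndarray], np.ndarray],
    background: BackgroundSet | np.ndarray,
    X,
    n_coalitions: int | None = None,
    exhaustive: bool | None = None,
    seed: int = 42,
    feature_names: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> AttributionResult:
    """KernelSHAP attributions for one or more rows.

    Parameters
    ----------
    model_fn:
        Vectorized scalar model: (n, d) array -> (n,) outputs.  Must be
        deterministic for the duration of the call.
    background:
        Reference rows for withheld features (a BackgroundSet or raw array).
    X:
        Row(s) to explain, (d,) or (n, d).
    n_coalitions:
        Sampled-mode budget; default 2d + 2048.  Must be >= d + 2.
    exhaustive:
        Force (or forbid) full 2^d enumeration; by default enumeration is
        used when d <= 14.

    The same coalition design is shared across all explained rows, so the
    weighted least squares is factorized once.
    """
    bg = background.rows if isinstance(background, BackgroundSet) else np.asarray(background, float)
    X = np.atleast_2d(np.asarray(X, float))
    n_samples, d = X.shape
    if bg.shape[1] != d:
        raise ValueError(f"background dim {bg.shape[1]} != sample dim {d}")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]
    ids = list(map(str, sample_ids)) if sample_ids is not None else [str(i) for i in range(n_samples)]

    base = float(np.mean(model_fn(bg)))
    fx = np.asarray(model_fn(X), float)

    if d == 1:
        values = (fx - base)[:, None]
        return AttributionResult(values, base, names, ids, fx)

    if exhaustive is None:
        exhaustive = d <= EXHAUSTIVE_MAX_D
    if exhaustive:
        Z, w = _exhaustive_coalitions(d)
    else:
        if n_coalitions is None:
            n_coalitions = 2 * d + 2048
        if n_coalitions < d + 2:
            raise ValueError(
                f"n_coalitions={n_coalitions} underdetermines d={d} features (need >= d+2)"
            )
        rng = np.random.default_rng(seed)
        Z, w = _sampled_coalitions(d, n_coalitions, rng)

    # Constrained WLS: eliminate the last feature using the local-accuracy
    # constraint sum(phi) = f(x) - base, then solve for the rest.  The
    # coalition design is shared across samples, so the normal equations
    # are factorized once.
    from scipy.linalg import cho_factor, cho_solve

    sqrt_w = np.sqrt(w)
    etmp = (Z[:, :-1] - Z[:, -1:]) * sqrt_w[:, None]          # (m, d-1)
    A = etmp.T @ etmp
    A[np.diag_indices_from(A)] += 1e-10 * np.trace(A) / A.shape[0]
    factor = cho_factor(A)
    values = np.empty((n_samples, d))
    value_dtype = np.float64 if exhaustive else np.float32
    for i in range(n_samples):
        v = _coalition_values(model_fn, Z, X[i], bg, dtype=value_dtype)
        delta = fx[i] - base
        ey = (v - base - Z[:, -1] * delta) * sqrt_w
        phi_head = cho_solve(factor, etmp.T @ ey)
        values[i, :-1] = phi_head
        values[i, -1] = delta - phi_head.sum()
    return AttributionResult(values, base, names, ids, fx)


def explain_model(
    model,
    matrix: pd.DataFrame,
    n_explain: int = 50,
    background_k: int = 10,
    n_coalitions: int | None = None,
    seed: int = 42,
    grouped: bool = True,
) -> AttributionResult:
    """Pipeline-level attribution of the probability of antagonism.

    The background set is chosen by K-means over the full matrix; the first
    ``n_explain`` rows are explained.  In ``grouped`` mode only the
    descriptor columns and fingerprint bits that are ever set in the matrix
    are treated as free features (a bit absent everywhere is identical in
    sample and background, so its Shapley value is identically zero); the
    zero attributions are re-expanded so the result still spans every column.
    """
    X = matrix.to_numpy(float)
    cols = list(matrix.columns)
    bg = kmeans_background(X, k=background_k, seed=seed)
    explain_rows = X[:n_explain]
    ids = [str(i) for i in matrix.index[:n_explain]]
    model_fn = model.prob_antagonist_fn if hasattr(model, "prob_antagonist_fn") else model

    if not grouped:
        return kernel_shap(
            model_fn, bg, explain_rows, n_coalitions=n_coalitions, seed=seed,
            feature_names=cols, sample_ids=ids,
        )

    is_bit = np.array([c.startswith("bit_") for c in cols])
    ever_varying = (X.max(axis=0) > X.min(axis=0)) | ~is_bit
    active = np.flatnonzero(ever_varying)
    inactive = np.flatnonzero(~ever_varying)
    if inactive.size:
        logger.info("grouped attribution: %d constant fingerprint bits fixed at zero value",
                    inactive.size)

    if not inactive.size:
        return kernel_shap(
            model_fn, bg, explain_rows, n_coalitions=n_coalitions, seed=seed,
            feature_names=cols, sample_ids=ids,
        )

    frozen = X[0, inactive]

    def reduced_fn(Xr: np.ndarray) -> np.ndarray:
        full = np.empty((Xr.shape[0], X.shape[1]), dtype=Xr.dtype)
        full[:, active] = Xr
        full[:, inactive] = frozen
        return model_fn(full)

    bg_reduced = BackgroundSet(rows=bg.rows[:, active], indices=bg.indices,
                               k=bg.k, seed=bg.seed)
    res = kernel_shap(
        reduced_fn, bg_reduced, explain_rows[:, active],
        n_coalitions=n_coalitions, seed=seed,
        feature_names=[cols[j] for j in active], sample_ids=ids,
    )
    values = np.zeros((len(ids), len(cols)))
    values[:, active] = res.values
    return AttributionResult(values, res.base_value, cols, ids, res.model_outputs)


def summarize(attr: AttributionResult, block: str) -> pd.DataFrame:
    """Ranked feature table for one block: mean |Shapley| plus the signed
    distribution summary used for summary plots."""
    if attr.values.size == 0:
        raise ValueError("empty attribution result")
    mask = attr.block_mask(block)
    names = [n for n, m in zip(attr.feature_names, mask) if m]
    vals = attr.values[:, mask]
    df = pd.DataFrame(
        {
            "feature": names,
            "mean_abs_shap": np.abs(vals).mean(axis=0),
            "mean_shap": vals.mean(axis=0),
            "min_shap": vals.min(axis=0),
            "max_shap": vals.max(axis=0),
        }
    )
    return df.sort_values("mean_abs_shap", ascending=False, kind="mergesort").reset_index(drop=True)


def top_k_bits(attr: AttributionResult, k: int = 5) -> TopBits:
    """The k fingerprint bits with the highest mean |Shapley value|.

    Ties break toward the lower bit index.  Bits with zero attribution are
    omitted, so the list truncates when fewer than k bits carry signal.
    """
    mask = attr.block_mask("fingerprints")
    bit_names = [n for n, m in zip(attr.feature_names, mask) if m]
    bit_idx = np.array([int(n.split("_")[1]) for n in bit_names])
    mean_abs = np.abs(attr.values[:, mask]).mean(axis=0)
    ranked = np.lexsort((bit_idx, -mean_abs))
    order = [o for o in ranked if mean_abs[o] > 0][:k]
    return TopBits(
        bits=[int(bit_idx[o]) for o in order],
        mean_abs_shap=[float(mean_abs[o]) for o in order],
    )
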