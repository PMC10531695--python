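"""Pairwise model comparison via adaptive standard error of prediction.

Marker effects of each fitted model are standardized and resampled with
replacement under a N(0, 1) null; markers whose standardized effects reject
a Benjamini-Hochberg screen at FDR 0.05 are the "far from normal" set.  The
adaptive SE for a model pair is the bootstrap standard error of the paired
difference in squared prediction errors on the common test partition; a
pair is declared different when the normal test of the mean paired
difference rejects after BH adjustment across pairs.  Raw values are
min-max normalized to [-0.2, 1] for the heat-map convention (self
comparisons land on the lower bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

NORM_LOW, NORM_HIGH = -0.2, 1.0


@dataclass
class ComparisonMatrix:
    labels: list[str]
    raw: np.ndarray  # bootstrap SE of paired error differences
    normalized: np.ndarray  # min-max rescaled to [-0.2, 1]
    mean_diff: np.ndarray
    declared_different: np.ndarray  # BH-adjusted decisions at fdr_threshold
    n_resamples: int
    fdr_threshold: float
    n_far_from_normal: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.labels)
        for m in (self.raw, self.normalized, self.declared_different):
            if m.shape != (k, k):
                raise ValueError("comparison matrices must be square over labels")
        if ((self.normalized < NORM_LOW - 1e-9) | (self.normalized > NORM_HIGH + 1e-9)).any():
            raise ValueError("normalized entries outside [-0.2, 1]")


def null_effect_resampling(
    effects: np.ndarray, n_resamples: int = 2000, seed: int = 0
) -> np.ndarray:
    """Per-marker SE of standardized effects resampled under the N(0,1) null.

    Effects are standardized to zero mean / unit SD, then resampled with
    replacement ``n_resamples`` times; the per-marker standard error is the
    SD of the resampled values at each marker position.
    """
    effects = np.asarray(effects, dtype=float).ravel()
    m = effects.size
    if m < 10:
        raise ValueError("need at least 10 marker effects")
    sd = effects.std()
    z = (effects - effects.mean()) / sd if sd > 0 else np.zeros(m)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_resamples, m))
    draws = z[idx]
    return draws.std(axis=0)


def effect_null_pvalues(effects: np.ndarray) -> np.ndarray:
    """Two-sided N(0,1) p-values of standardized marker effects."""
    effects = np.asarray(effects, dtype=float).ravel()
    sd = effects.std()
    z = (effects - effects.mean()) / sd if sd > 0 else np.zeros(effects.size)
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def pseudo_marker_effects(
    gebv: np.ndarray, Xc: np.ndarray, ridge: float = 1e-3
) -> np.ndarray:
    """Ridge back-projection of GEBVs onto the coded marker matrix.

    Gives marker-level pseudo-effects for kernel/ensemble fits that have
    none of their own.
    """
    Xc = np.asarray(Xc, dtype=float)
    n = Xc.shape[0]
    H = Xc @ Xc.T + ridge * n * np.eye(n)
    return Xc.T @ np.linalg.solve(H, np.asarray(gebv, dtype=float))


def adaptive_se_matrix(
    errors: dict[str, np.ndarray],
    effects: dict[str, np.ndarray] | None = None,
    n_resamples: int = 2000,
    fdr: float = 0.05,
    seed: int = 0,
) -> ComparisonMatrix:
    """Pairwise adaptive-SE matrix over models sharing a test partition.

    ``errors`` maps model label to per-genotype squared prediction errors
    (aligned across models); ``effects`` optionally maps labels to marker
    (or pseudo) effects for the far-from-normal FDR screen.
    """
    labels = list(errors)
    if len(labels) < 2:
        raise ValueError("need at least 2 models to compare")
    n = len(next(iter(errors.values())))
    for lab, e in errors.items():
        if len(e) != n:
            raise ValueError(f"model {lab!r} has a different test partition size")
    if n == 0:
        raise ValueError("no common test genotypes")

    rng = np.random.default_rng(seed)
    k = len(labels)
    raw = np.zeros((k, k))
    mean_diff = np.zeros((k, k))
    pvals = []
    pairs = []
    boot_idx = rng.integers(0, n, size=(n_resamples, n))
    for i in range(k):
        for j in range(i + 1, k):
            d = np.asarray(errors[labels[i]]) - np.asarray(errors[labels[j]])
            boot_means = d[boot_idx].mean(axis=1)
            se = float(boot_means.std(ddof=1))
            raw[i, j] = raw[j, i] = se
            md = float(d.mean())
            mean_diff[i, j] = md
            mean_diff[j, i] = -md
            if se > 0:
                p = 2.0 * stats.norm.sf(abs(md) / se)
            else:
                p = 1.0 if md == 0 else 0.0
            pvals.append(p)
            pairs.append((i, j))

    declared = np.zeros((k, k), dtype=bool)
    if pvals:
        reject, _ = bh_fdr(np.array(pvals), q=fdr)
        for (i, j), rej in zip(pairs, reject):
            declared[i, j] = declared[j, i] = bool(rej)

    span = raw.max() - raw.min()
    if span > 0:
        normalized = NORM_LOW + (NORM_HIGH - NORM_LOW) * (raw - raw.min()) / span
    else:
        normalized = np.full_like(raw, NORM_LOW)

    far_counts = {}
    if effects:
        for lab, eff in effects.items():
            rej, _ = bh_fdr(effect_null_pvalues(eff), q=fdr)
            far_counts[lab] = int(rej.sum())

    return ComparisonMatrix(
        labels=labels,
        raw=raw,
        normalized=normalized,
        mean_diff=mean_diff,
        declared_different=declared,
        n_resamples=n_resamples,
        fdr_threshold=fdr,
        n_far_from_normal=far_counts,
    )
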