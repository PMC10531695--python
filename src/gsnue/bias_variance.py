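"""Bias-variance decomposition over a model-complexity grid.

A KNN reference family traces the classical tradeoff: small k gives low bias
and high variance, large k the reverse.  In synthetic mode the generator
draws fresh training sets (the truth at the fixed test points is known and
the irreducible error is the generator's noise variance); on fixed data the
resamples are nonparametric bootstraps and the target is the held-out
phenotype.  Expected loss is Monte-Carlo MSE, which decomposes as
bias^2 + variance + irreducible error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass
class DecompositionRow:
    label: str
    complexity: float
    bias2: float
    variance: float
    expected_loss: float
    irreducible_error: float
    n_resamples: int
    identity_gap_se: float = 0.0  # MC standard error of loss - (bias2 + var)

    def __post_init__(self) -> None:
        for name in ("bias2", "variance", "expected_loss", "irreducible_error"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SyntheticSource:
    """Fresh-training-set resampling with known truth at fixed test points."""

    test_x: np.ndarray
    test_target: np.ndarray  # true (noise-free) response at test_x
    sigma2_e: float
    draw_training_set: Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]]


@dataclass
class FixedSource:
    """Bootstrap resampling of a fixed dataset; truth is the held-out phenotype."""

    train_x: np.ndarray
    train_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray


def knn_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, k: int
) -> np.ndarray:
    """Mean response of the k nearest training genotypes (Euclidean metric).

    Distance ties are broken toward the lowest training index.
    """
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    if train_x.ndim == 1:
        train_x = train_x[:, None]
    if test_x.ndim == 0:
        test_x = test_x[None, None]
    elif test_x.ndim == 1:
        test_x = test_x[:, None]
    train_y = np.asarray(train_y, dtype=float)
    n = train_y.size
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    from scipy.spatial.distance import cdist

    d = cdist(test_x, train_x)
    # stable sort: equal distances keep ascending training-index order
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return train_y[order].mean(axis=1)


def knn_family(k: int) -> Callable:
    def _fit_predict(train_x, train_y, test_x):
        return knn_predict(train_x, train_y, test_x, k)

    return _fit_predict


def decompose_bias_variance(
    predictor: Callable[[np.ndarray, np.ndarray, np.ndarray, float], np.ndarray],
    source: SyntheticSource | FixedSource,
    complexity_grid: list[float],
    n_resamples: int = 200,
    seed: int = 0,
    label: str = "KNN",
) -> list[DecompositionRow]:
    """Resampling bias-variance decomposition across a complexity grid.

    ``predictor(train_x, train_y, test_x, complexity)`` returns predictions
    at the test points.  Rows come back sorted by complexity.
    """
    if n_resamples < 10:
        raise ValueError("n_resamples must be >= 10")
    rng = np.random.default_rng(seed)
    synthetic = isinstance(source, SyntheticSource)
    if synthetic:
        test_x, target = source.test_x, source.test_target
        sig_e = np.sqrt(source.sigma2_e)
    else:
        test_x, target = source.test_x, source.test_y

    # draw all training sets once so every complexity sees the same resamples
    train_sets = []
    test_obs = []
    for _ in range(n_resamples):
        if synthetic:
            train_sets.append(source.draw_training_set(rng))
            test_obs.append(target + rng.normal(0.0, sig_e, size=target.size))
        else:
            idx = rng.integers(0, source.train_y.size, size=source.train_y.size)
            train_sets.append((source.train_x[idx], source.train_y[idx]))
            test_obs.append(target)

    rows = []
    for c in sorted(complexity_grid):
        preds = np.array(
            [predictor(tx, ty, test_x, c) for tx, ty in train_sets]
        )  # B x n_test
        mean_pred = preds.mean(axis=0)
        bias2 = float(np.mean((mean_pred - target) ** 2))
        variance = float(np.mean(preds.var(axis=0)))
        obs = np.array(test_obs)
        loss_b = np.mean((preds - obs) ** 2, axis=1)  # per-resample MSE
        exp_loss = float(loss_b.mean())
        # per-resample systematic part; its mean is bias^2 + variance, so the
        # SE of (loss_b - sys_b) bounds the MC error of the identity gap
        sys_b = np.mean((preds - target) ** 2, axis=1)
        gap_se = float(np.std(loss_b - sys_b, ddof=1) / np.sqrt(n_resamples))
        ie = float(source.sigma2_e) if synthetic else max(
            exp_loss - bias2 - variance, 0.0
        )
        rows.append(
            DecompositionRow(
                label=f"{label}_k{c:g}" if label == "KNN" else label,
                complexity=float(c),
                bias2=bias2,
                variance=variance,
                expected_loss=exp_loss,
                irreducible_error=ie,
                n_resamples=n_resamples,
                identity_gap_se=gap_se,
            )
        )
    return rows


def estimate_irreducible_error(
    source: SyntheticSource | None = None,
    replicates: np.ndarray | None = None,
    decomposition_row: DecompositionRow | None = None,
) -> float:
    """Irreducible error by the first admissible mode.

    Synthetic mode returns the generator's true noise variance; replicate
    mode the mean within-genotype replicate variance (rows = genotypes,
    columns = replicates); residual mode Exp.Loss - bias^2 - variance floored
    at zero.
    """
    if source is not None:
        return float(source.sigma2_e)
    if replicates is not None:
        reps = np.asarray(replicates, dtype=float)
        if reps.ndim != 2 or reps.shape[1] < 2:
            raise ValueError("replicate mode needs >= 2 replicates per genotype")
        return float(np.mean(reps.var(axis=1, ddof=1)))
    if decomposition_row is not None:
        import warnings

        warnings.warn(
            "irreducible error from the decomposition residual is a floor-at-zero "
            "approximation",
            UserWarning,
        )
        r = decomposition_row
        return max(r.expected_loss - r.bias2 - r.variance, 0.0)
    raise ValueError("no admissible irreducible-error mode")


def rows_to_frame(rows: list[DecompositionRow]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": r.label,
                "complexity": r.complexity,
                "bias2": r.bias2,
                "variance": r.variance,
                "expected_loss": r.expected_loss,
                "irreducible_error": r.irreducible_error,
                "n_resamples": r.n_resamples,
            }
            for r in rows
        ]
    )
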