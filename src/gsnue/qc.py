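"""Marker quality control: MAF and Hardy-Weinberg filtering, call rate,
mean imputation, and the (-1, 0, +1) recoding used by the linear models.

Filtering mirrors chip-panel practice: markers with MAF at or below the
threshold are removed (inclusive boundary), then markers deviating from
Hardy-Weinberg proportions, then poorly called markers.  Removal reasons are
assigned by the first failing rule in that order so report counts add up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gsnue.data import GenotypeMatrix


class EmptyPanelError(ValueError):
    """All markers were removed by QC."""


@dataclass
class QCReport:
    n_markers_in: int
    n_removed_maf: int
    n_removed_hwe: int
    n_removed_callrate: int
    n_markers_out: int
    per_marker: pd.DataFrame  # marker_id, maf, hwe_chisq, hwe_p, call_rate, removed_by

    def __post_init__(self) -> None:
        removed = self.n_removed_maf + self.n_removed_hwe + self.n_removed_callrate
        if self.n_markers_out != self.n_markers_in - removed:
            raise ValueError("QC report counts are inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_markers_in": [self.n_markers_in],
                "n_removed_maf": [self.n_removed_maf],
                "n_removed_hwe": [self.n_removed_hwe],
                "n_removed_callrate": [self.n_removed_callrate],
                "n_markers_out": [self.n_markers_out],
            }
        )


def alt_allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """Unfolded alternate-allele frequency per marker, missing excluded.

    All-missing markers get ``nan``.
    """
    d = G.dosage
    with np.errstate(invalid="ignore"):
        n_obs = np.sum(~np.isnan(d), axis=0)
        total = np.nansum(d, axis=0)
        f = np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return f


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency: alternate-allele frequency folded at 0.5."""
    f = alt_allele_freq(G)
    return np.minimum(f, 1.0 - f)


def hwe_chisq(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """One-df chi-square against p^2 : 2pq : q^2 genotype proportions.

    Returns (chisq, p_value) per marker; monomorphic markers (p in {0, 1})
    and all-missing markers get nan in both.
    """
    d = G.dosage
    n0 = np.sum(d == 0, axis=0).astype(float)
    n1 = np.sum(d == 1, axis=0).astype(float)
    n2 = np.sum(d == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    p = alt_allele_freq(G)
    q = 1.0 - p

    with np.errstate(invalid="ignore", divide="ignore"):
        e0, e1, e2 = n * q**2, n * 2 * p * q, n * p**2
        chisq = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    undef = np.isnan(p) | (p <= 0) | (p >= 1) | (n == 0)
    chisq = np.where(undef, np.nan, chisq)
    pval = np.where(np.isnan(chisq), np.nan, stats.chi2.sf(chisq, df=1))
    return chisq, pval


def call_rate(G: GenotypeMatrix) -> np.ndarray:
    return np.mean(~np.isnan(G.dosage), axis=0)


def apply_qc(
    G: GenotypeMatrix,
    maf_threshold: float = 0.05,
    hwe_alpha: float | None = 1e-4,
    min_call_rate: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers and mean-impute remaining missing calls.

    Removes markers with MAF <= ``maf_threshold`` (inclusive boundary), then
    HWE p < ``hwe_alpha`` (skipped when ``hwe_alpha`` is None), then call
    rate < ``min_call_rate``.  Monomorphic markers have MAF 0 and are caught
    by any threshold >= 0.  Returns the filtered matrix with a complete
    (imputed) dosage table and the per-marker report.
    """
    if not (0.0 <= maf_threshold < 0.5):
        raise ValueError("maf_threshold must lie in [0, 0.5)")
    if hwe_alpha is not None and not (0.0 < hwe_alpha < 1.0):
        raise ValueError("hwe_alpha must lie in (0, 1)")
    if not (0.0 <= min_call_rate <= 1.0):
        raise ValueError("min_call_rate must lie in [0, 1]")

    maf = compute_maf(G)
    chisq, hwe_p = hwe_chisq(G)
    cr = call_rate(G)

    # nan MAF (all-missing marker) is not a MAF failure; it falls through to
    # the call-rate rule, which catches call rate 0.
    fail_maf = np.nan_to_num(maf, nan=1.0) <= maf_threshold
    fail_hwe = (
        np.zeros_like(fail_maf)
        if hwe_alpha is None
        else np.nan_to_num(hwe_p, nan=1.0) < hwe_alpha
    )
    fail_cr = cr < min_call_rate

    removed_by = np.full(G.n_markers, "", dtype=object)
    removed_by[fail_cr] = "call_rate"
    removed_by[fail_hwe] = "hwe"
    removed_by[fail_maf] = "maf"  # precedence MAF > HWE > call rate

    keep = removed_by == ""
    if not keep.any():
        raise EmptyPanelError("QC removed every marker")

    out = G.subset_markers(keep)
    out.imputed = True
    if hasattr(G, "subpop_labels"):
        out.subpop_labels = G.subpop_labels
    miss = np.isnan(out.dosage)
    if miss.any():
        col_mean = np.nanmean(out.dosage, axis=0)
        r, c = np.where(miss)
        out.dosage[r, c] = col_mean[c]

    per_marker = pd.DataFrame(
        {
            "marker_id": G.marker_ids,
            "maf": maf,
            "hwe_chisq": chisq,
            "hwe_p": hwe_p,
            "call_rate": cr,
            "removed_by": removed_by,
        }
    )
    report = QCReport(
        n_markers_in=G.n_markers,
        n_removed_maf=int((removed_by == "maf").sum()),
        n_removed_hwe=int((removed_by == "hwe").sum()),
        n_removed_callrate=int((removed_by == "call_rate").sum()),
        n_markers_out=int(keep.sum()),
        per_marker=per_marker,
    )
    return out, report


def recode_centered(G: GenotypeMatrix) -> np.ndarray:
    """Recode dosage {0,1,2} to {-1,0,+1} (dosage minus one).

    Requires a complete matrix, i.e. QC/imputation applied first.  Imputed
    fractional dosages shift the same way.
    """
    if np.isnan(G.dosage).any():
        raise ValueError("missing dosages present; run apply_qc first")
    return G.dosage - 1.0
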