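"""Expected genetic selection gain, model power and relative efficiency.

The model-power term beta is the normalized log-determinant of Henderson's
mixed-model-equation coefficient matrix

    C = [[X'X, X'Z], [Z'X, Z'Z + G^{-1} sigma2_e / sigma2_u]]

an information-content measure of the fitted design: more genotypes or a
better-conditioned relationship matrix raise it.  Expected gain follows the
breeder's-equation form R = i * r * y * beta with selection intensity i,
prediction accuracy r and breeding-cycle count y; relative efficiency is
RE = r / R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gsnue.data import GenotypeMatrix
from gsnue.qc import alt_allele_freq


@dataclass
class GainReport:
    beta_power: float
    selection_intensity: float
    accuracy: dict[str, float]  # per N level
    years: int
    delta_g: dict[str, float]
    expected_gain: dict[str, float]
    relative_efficiency: dict[str, float]
    top_genotypes: pd.DataFrame
    overlap: list[str]
    allele_contrast: pd.DataFrame


def mme_power(
    X: np.ndarray,
    Z: np.ndarray,
    Ginv: np.ndarray,
    sigma2_e: float,
    sigma2_u: float = 1.0,
    jitter: float = 0.0,
    max_escalations: int = 8,
) -> float:
    """Model power beta = logdet(C) / dim(C) of the MME coefficient matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Ginv = np.asarray(Ginv, dtype=float)
    if X.shape[0] != Z.shape[0]:
        raise ValueError("X and Z must have the same number of observations")
    if sigma2_u <= 0 or sigma2_e < 0:
        raise ValueError("variances must be positive")
    if not np.any(Z):
        raise np.linalg.LinAlgError("degenerate all-zero random-effect design")
    shrink = Ginv * (sigma2_e / sigma2_u)
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + shrink]])
    q = C.shape[0]
    j = jitter
    for step in range(max_escalations + 1):
        sign, logdet = np.linalg.slogdet(C + (j * np.eye(q) if j > 0 else 0.0))
        if sign > 0 and np.isfinite(logdet):
            return float(logdet / q)
        j = 1e-8 * 10**step if j == 0 else j * 10
    raise np.linalg.LinAlgError("MME coefficient matrix singular after jitter escalation")


def selection_intensity(selected_fraction: float) -> float:
    """Standardized selection differential i = phi(z) / p under normality."""
    p = float(selected_fraction)
    if not (0 < p < 1):
        raise ValueError("selected fraction must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def genetic_gain(
    gsi_or_i: float,
    r: float,
    y_years: int,
    beta_power: float,
    sigma_e: float,
    per_year: bool = False,
) -> tuple[float, float]:
    """Genetic gain Delta_G = gsi * beta * sigma_e and expected gain
    R = i * r * y * beta (optionally divided by y)."""
    if y_years < 1:
        raise ValueError("y_years must be >= 1")
    if not (-1.0 <= r <= 1.0):
        raise ValueError("accuracy r must lie in [-1, 1]")
    delta_g = gsi_or_i * beta_power * sigma_e
    R = gsi_or_i * r * y_years * beta_power
    if per_year:
        R = R / y_years
    return float(delta_g), float(R)


def relative_efficiency(r: float, R: float) -> float:
    """RE = r / R^2; undefined at R = 0."""
    if R == 0:
        raise ZeroDivisionError("relative efficiency undefined for R = 0")
    return float(r / R**2)


def rank_top_genotypes(
    gebvs: dict[str, pd.Series], k: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Top-k genotypes per N level (ties broken by genotype id) and the
    cross-level overlap set."""
    rows = []
    tops: dict[str, list[str]] = {}
    for level, ser in gebvs.items():
        if k > ser.size:
            raise ValueError(f"k={k} exceeds population size {ser.size}")
        df = ser.rename("gebv").rename_axis("genotype_id").reset_index()
        df = df.sort_values(["gebv", "genotype_id"], ascending=[False, True]).head(k)
        df["n_level"] = level
        df["rank"] = np.arange(1, k + 1)
        rows.append(df)
        tops[level] = df["genotype_id"].tolist()
    table = pd.concat(rows, ignore_index=True)
    levels = list(gebvs)
    overlap = sorted(set(tops[levels[0]]).intersection(*[set(tops[lv]) for lv in levels[1:]]))
    return table[["n_level", "rank", "genotype_id", "gebv"]], overlap


def allele_content_contrast(
    G: GenotypeMatrix, top_ids: list[str]
) -> pd.DataFrame:
    """Welch contrast of per-genotype mean minor/major allele counts:
    top set versus the whole population."""
    if not top_ids:
        raise ValueError("top set is empty")
    missing = set(top_ids) - set(G.genotype_ids)
    if missing:
        raise ValueError(f"top ids not in genotype matrix: {sorted(missing)}")
    f = alt_allele_freq(G)
    d = G.dosage.copy()
    col_mean = np.nanmean(d, axis=0)
    r, c = np.where(np.isnan(d))
    d[r, c] = col_mean[c]
    # minor-allele count per genotype: dosage where alt is minor, else 2 - dosage
    alt_is_minor = f <= 0.5
    minor = np.where(alt_is_minor, d, 2.0 - d)
    minor_mean = minor.mean(axis=1)
    major_mean = 2.0 - minor_mean  # complementary counts

    idx = [G.genotype_ids.index(g) for g in top_ids]
    rows = []
    for name, vals in (("minor", minor_mean), ("major", major_mean)):
        top_vals = vals[idx]
        if np.array_equal(np.sort(idx), np.arange(G.n_genotypes)):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(top_vals, vals, equal_var=False)
        rows.append(
            {
                "allele_class": name,
                "top_mean": float(top_vals.mean()),
                "population_mean": float(vals.mean()),
                "difference": float(top_vals.mean() - vals.mean()),
                "t": float(t),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def gain_report(
    gebvs: dict[str, pd.Series],
    accuracy: dict[str, float],
    G: GenotypeMatrix,
    X: np.ndarray,
    Z: np.ndarray,
    Ginv: np.ndarray,
    sigma2_e: dict[str, float],
    sigma2_u: dict[str, float],
    selected_fraction: float = 10 / 221,
    years: int = 1,
    k_top: int = 10,
    k_contrast: int = 6,
) -> GainReport:
    """Assemble the full selection-gain report for both N levels."""
    i_sel = selection_intensity(selected_fraction)
    beta = {
        lv: mme_power(X, Z, Ginv, sigma2_e[lv], sigma2_u[lv]) for lv in gebvs
    }
    delta_g, R, RE = {}, {}, {}
    for lv in gebvs:
        dg, r_gain = genetic_gain(
            i_sel, accuracy[lv], years, beta[lv], np.sqrt(sigma2_e[lv])
        )
        delta_g[lv], R[lv] = dg, r_gain
        RE[lv] = relative_efficiency(accuracy[lv], r_gain)

    top, overlap = rank_top_genotypes(gebvs, k=k_top)
    # display convention: each top genotype's RE% is its share of the top-set
    # GEBV total scaled by the population-level RE
    re_pct = []
    for lv in gebvs:
        sub = top[top["n_level"] == lv]
        shifted = sub["gebv"] - sub["gebv"].min()
        total = shifted.sum()
        share = shifted / total if total > 0 else pd.Series(1.0 / len(sub), index=sub.index)
        re_pct.append(100.0 * RE[lv] * share)
    top = top.assign(re_pct=pd.concat(re_pct))

    # contrast the cross-level duplicates when there are enough of them,
    # else the overall top set of the first level
    if len(overlap) >= 2:
        contrast_ids = overlap[:k_contrast]
    else:
        first = top[top["n_level"] == list(gebvs)[0]]
        contrast_ids = first["genotype_id"].head(k_contrast).tolist()
    contrast = allele_content_contrast(G, contrast_ids)
    mean_beta = float(np.mean(list(beta.values())))
    return GainReport(
        beta_power=mean_beta,
        selection_intensity=i_sel,
        accuracy=accuracy,
        years=years,
        delta_g=delta_g,
        expected_gain=R,
        relative_efficiency=RE,
        top_genotypes=top,
        overlap=overlap,
        allele_contrast=contrast,
    )
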