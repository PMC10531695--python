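"""Synthetic wheat-like population generator.

Emulates the data shape of the motivating study: ~221 genotypes scored on a
dense biallelic SNP panel with three subpopulation clusters, and a
quantitative nitrogen-use-efficiency (NUE) trait measured under a low-N and
a high-N environment at configurable narrow-sense heritabilities.

Model
-----
Ancestral minor-allele frequencies are drawn uniformly in
``[maf_low, maf_high]``; subpopulation frequencies diverge from them by a
Balding-Nichols drift parameter F (``subpop_divergence``).  Linkage
disequilibrium is produced by blockwise haplotype copying: within a block of
``ld_block_len`` markers each gamete copies its previous allele with
probability ``1 - ld_flip_prob``, otherwise redraws from the subpopulation
frequency.  Phenotypes are additive, ``y = mu + sum_q w_q a_q + e``, with QTL
effects at the two N levels drawn from a bivariate normal with correlation
``genetic_corr_n_levels`` and the noise scale set so that
``sigma2_a / (sigma2_a + sigma2_e)`` equals the per-level h2 target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gsnue.data import GenotypeMatrix, PhenotypeTable

# Baseline trait scale per N level: mean NUE (unitless GY/Ns), phenotypic SD,
# and nitrogen supplied (g N / m2).  High N supply lowers NUE, the usual
# dilution pattern in wheat N-response trials.
TRAIT_SCALE = {
    "LN": {"mean": 40.0, "sd": 6.0, "Ns": 10.0},
    "HN": {"mean": 15.0, "sd": 2.25, "Ns": 25.0},
}


class ConfigurationError(ValueError):
    """Raised when a population or run configuration violates its bounds."""


@dataclass
class PopulationConfig:
    """Parameters of the simulated population; defaults mirror the study shape."""

    n_genotypes: int = 221
    n_markers: int = 5000
    n_subpops: int = 3
    subpop_divergence: float = 0.15
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_len: int = 5
    ld_flip_prob: float = 0.1
    n_qtl: int = 200
    h2_low_n: float = 0.45
    h2_high_n: float = 0.60
    genetic_corr_n_levels: float = 0.8
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genotypes, self.n_markers, self.n_subpops, self.ld_block_len) < 1:
            raise ConfigurationError("counts and block length must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
        if self.subpop_divergence < 0:
            raise ConfigurationError("subpop_divergence must be >= 0")
        if not (1 <= self.n_qtl <= self.n_markers):
            raise ConfigurationError("need 1 <= n_qtl <= n_markers")
        for h2 in (self.h2_low_n, self.h2_high_n):
            if not (0.0 <= h2 <= 1.0):
                raise ConfigurationError("heritability targets must lie in [0, 1]")
        if not (-1.0 <= self.genetic_corr_n_levels <= 1.0):
            raise ConfigurationError("genetic_corr_n_levels must lie in [-1, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.ld_flip_prob <= 1.0):
            raise ConfigurationError("ld_flip_prob must lie in [0, 1]")


@dataclass
class TrueArchitecture:
    """Ground-truth genetic architecture backing a simulated phenotype."""

    qtl_indices: np.ndarray
    effects_low_n: np.ndarray
    effects_high_n: np.ndarray
    sigma2_a: dict[str, float]
    sigma2_e: dict[str, float]
    true_gebv: pd.DataFrame  # index genotype_id, columns LN / HN
    subpop_labels: np.ndarray = field(default=None)

    def h2(self, n_level: str) -> float:
        a, e = self.sigma2_a[n_level], self.sigma2_e[n_level]
        return a / (a + e) if (a + e) > 0 else 0.0


def _subpop_assignment(n: int, k: int) -> np.ndarray:
    """Near-equal deterministic split of n genotypes over k subpopulations."""
    return np.arange(n) % k


def simulate_genotypes(config: PopulationConfig) -> GenotypeMatrix:
    """Simulate the dosage matrix; deterministic under ``config.seed``.

    Realized per-marker minor-allele frequency (ignoring injected missingness)
    is reported in ``marker_meta['realized_maf']``.
    """
    rng = np.random.default_rng([config.seed, 101])
    n, m, k = config.n_genotypes, config.n_markers, config.n_subpops

    maf = rng.uniform(config.maf_low, config.maf_high, size=m)
    flip = rng.random(m) < 0.5  # which allele is the alternate one
    p_anc = np.where(flip, 1.0 - maf, maf)

    F = config.subpop_divergence
    if F > 0 and k > 1:  # drift is between-subpopulation divergence
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(np.tile(a, (k, 1)), np.tile(b, (k, 1)))
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)
    else:
        p_sub = np.tile(p_anc, (k, 1))

    labels = _subpop_assignment(n, k)
    freq = p_sub[labels, :]  # n x m per-individual allele frequency

    hap = np.empty((n, 2, m), dtype=np.int8)
    keep_prob = 1.0 - config.ld_flip_prob
    for j in range(m):
        draw = (rng.random((n, 2)) < freq[:, j][:, None]).astype(np.int8)
        if j % config.ld_block_len == 0:
            hap[:, :, j] = draw
        else:
            copy = rng.random((n, 2)) < keep_prob
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], draw)

    dosage = hap.sum(axis=1).astype(float)

    f_alt = dosage.mean(axis=0) / 2.0
    realized_maf = np.minimum(f_alt, 1.0 - f_alt)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = np.nan

    meta = pd.DataFrame(
        {
            "chrom": 1 + (np.arange(m) * 21) // m,  # 21 wheat chromosomes
            "pos": 1 + np.arange(m) * 1000,
            "realized_maf": realized_maf,
            "subpop_fst": F,
        }
    )
    gm = GenotypeMatrix(
        genotype_ids=[f"G{i + 1:03d}" for i in range(n)],
        marker_ids=[f"M{j + 1:05d}" for j in range(m)],
        dosage=dosage,
        marker_meta=meta,
    )
    gm.subpop_labels = labels
    return gm


def _scaled_genetic_values(
    w_qtl: np.ndarray, effects: np.ndarray, h2: float, sd_p: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale raw QTL effects so the genetic sample variance is h2 * sd_p^2."""
    g_raw = w_qtl @ effects
    var_raw = g_raw.var()
    if h2 == 0.0 or var_raw == 0.0:
        return np.zeros_like(g_raw), np.zeros_like(effects), 0.0
    s = np.sqrt(h2 * sd_p**2 / var_raw)
    return g_raw * s, effects * s, h2 * sd_p**2


def simulate_phenotypes(
    G: GenotypeMatrix, config: PopulationConfig
) -> tuple[PhenotypeTable, TrueArchitecture]:
    """Simulate the NUE trait at both N levels on top of a genotype matrix."""
    rng = np.random.default_rng([config.seed, 202])
    if config.n_qtl > G.n_markers:
        raise ConfigurationError(
            f"n_qtl={config.n_qtl} exceeds available markers ({G.n_markers})"
        )
    if np.isnan(G.dosage).all(axis=0).any():
        raise ValueError("genotype matrix contains all-missing markers")

    # mean-impute missing dosages for the generative model, then column-center
    W = G.dosage.copy()
    col_mean = np.nanmean(W, axis=0)
    nan_r, nan_c = np.where(np.isnan(W))
    W[nan_r, nan_c] = col_mean[nan_c]
    W = W - W.mean(axis=0)

    qtl = rng.choice(G.n_markers, size=config.n_qtl, replace=False)
    qtl.sort()
    rho = config.genetic_corr_n_levels
    cov = np.array([[1.0, rho], [rho, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=config.n_qtl)

    w_qtl = W[:, qtl]
    n = G.n_genotypes
    rows = []
    sigma2_a: dict[str, float] = {}
    sigma2_e: dict[str, float] = {}
    gebv = {}
    scaled_eff = {}
    for level, h2, raw in (
        ("LN", config.h2_low_n, eff[:, 0]),
        ("HN", config.h2_high_n, eff[:, 1]),
    ):
        scale = TRAIT_SCALE[level]
        g, a_scaled, s2a = _scaled_genetic_values(w_qtl, raw, h2, scale["sd"])
        s2e = (1.0 - h2) * scale["sd"] ** 2 if h2 > 0 else scale["sd"] ** 2
        e = rng.normal(0.0, np.sqrt(s2e), size=n) if s2e > 0 else np.zeros(n)
        nue = scale["mean"] + g + e
        ns = scale["Ns"]
        gy = nue * ns
        uptake = np.clip(rng.normal(0.7, 0.05, size=n), 0.05, 1.0)
        nt = ns * uptake
        sigma2_a[level] = s2a
        sigma2_e[level] = s2e
        gebv[level] = g
        scaled_eff[level] = a_scaled
        for i, gid in enumerate(G.genotype_ids):
            rows.append(
                {
                    "genotype_id": gid,
                    "n_level": level,
                    "GY": gy[i],
                    "Ns": ns,
                    "Nt": nt[i],
                    "NUE": nue[i],
                }
            )

    pheno = PhenotypeTable(pd.DataFrame(rows))
    arch = TrueArchitecture(
        qtl_indices=qtl,
        effects_low_n=scaled_eff["LN"],
        effects_high_n=scaled_eff["HN"],
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        true_gebv=pd.DataFrame(gebv, index=list(G.genotype_ids)),
        subpop_labels=getattr(G, "subpop_labels", None),
    )
    return pheno, arch


def compute_nue(GY: float, Ns: float, Nt: float | None = None) -> float:
    """Nitrogen use efficiency: GY / Ns.

    When ``Nt`` (total plant N) is supplied the factored form
    ``(Nt / Ns) * (GY / Nt)`` — uptake efficiency times utilisation
    efficiency — is used; it is algebraically identical.
    """
    if Ns <= 0:
        raise ValueError(f"Ns must be positive, got {Ns}")
    if Nt is not None:
        if Nt <= 0:
            raise ValueError(f"Nt must be positive, got {Nt}")
        return (Nt / Ns) * (GY / Nt)
    return GY / Ns
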