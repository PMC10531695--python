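"""Synthetic population generator: determinism, allele-frequency and
heritability construction, LD and subpopulation structure."""

import numpy as np
import pytest

from gsnue.simulate import (
    ConfigurationError,
    PopulationConfig,
    compute_nue,
    simulate_genotypes,
    simulate_phenotypes,
)


def test_same_seed_is_bitwise_identical():
    cfg = PopulationConfig(n_genotypes=60, n_markers=120, n_qtl=40, seed=4)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(
        PopulationConfig(n_genotypes=60, n_markers=120, n_qtl=40, seed=4)
    )
    np.testing.assert_array_equal(a.dosage, b.dosage)
    pa, aa = simulate_phenotypes(a, cfg)
    pb, ab = simulate_phenotypes(b, cfg)
    np.testing.assert_array_equal(pa.table["NUE"], pb.table["NUE"])
    np.testing.assert_array_equal(aa.qtl_indices, ab.qtl_indices)


def test_unlinked_markers_are_uncorrelated():
    cfg = PopulationConfig(
        n_genotypes=300, n_markers=200, n_subpops=1, ld_block_len=1,
        missing_rate=0.0, seed=9,
    )
    G = simulate_genotypes(cfg)
    rng = np.random.default_rng(0)
    cors = []
    for _ in range(100):
        i, j = rng.choice(G.n_markers, size=2, replace=False)
        a, b = G.dosage[:, i], G.dosage[:, j]
        if a.std() > 0 and b.std() > 0:
            cors.append(abs(np.corrcoef(a, b)[0, 1]))
    assert np.mean(cors) <= 0.1


def test_ld_blocks_induce_positive_adjacent_correlation():
    cfg = PopulationConfig(
        n_genotypes=400, n_markers=200, n_subpops=1, ld_block_len=10,
        ld_flip_prob=0.05, missing_rate=0.0, seed=2,
    )
    G = simulate_genotypes(cfg)
    cors = []
    for j in range(0, 190):
        if j % 10 == 9:  # skip block boundaries
            continue
        a, b = G.dosage[:, j], G.dosage[:, j + 1]
        if a.std() > 0 and b.std() > 0:
            cors.append(np.corrcoef(a, b)[0, 1])
    assert np.mean(cors) > 0.5


def test_realized_maf_matches_independent_allele_tally():
    cfg = PopulationConfig(
        n_genotypes=200, n_markers=300, n_subpops=1,
        maf_low=0.5, maf_high=0.5, missing_rate=0.0, ld_block_len=1, seed=5,
    )
    G = simulate_genotypes(cfg)
    # independent brute-force tally of alternate alleles
    mafs = []
    for j in range(G.n_markers):
        alt = int(G.dosage[:, j].sum())
        f = alt / (2 * G.n_genotypes)
        mafs.append(min(f, 1 - f))
    assert abs(np.mean(mafs) - 0.5) <= 0.05
    np.testing.assert_allclose(
        np.array(mafs), G.marker_meta["realized_maf"].to_numpy(), atol=1e-12
    )


def test_missingness_rate_and_reporting():
    cfg = PopulationConfig(n_genotypes=200, n_markers=200, missing_rate=0.1, seed=3)
    G = simulate_genotypes(cfg)
    frac = np.isnan(G.dosage).mean()
    assert 0.08 < frac < 0.12


def test_noise_free_phenotype_equals_true_gebv():
    cfg = PopulationConfig(n_genotypes=120, n_markers=300, h2_low_n=1.0,
                           missing_rate=0.0, seed=8)
    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)
    y = pheno.trait("LN", G.genotype_ids)
    r = np.corrcoef(y, arch.true_gebv["LN"])[0, 1]
    assert r > 1 - 1e-10


def test_pure_noise_phenotype_uncorrelated_with_genetics():
    cfg = PopulationConfig(n_genotypes=500, n_markers=300, h2_low_n=0.0,
                           missing_rate=0.0, seed=8)
    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)
    y = pheno.trait("LN", G.genotype_ids)
    # h2=0 zeroes the genetic values; correlate against the unscaled QTL burden
    burden = G.dosage[:, arch.qtl_indices].sum(axis=1)
    assert np.corrcoef(y, burden)[0, 1] ** 2 <= 0.05
    assert arch.sigma2_a["LN"] == 0.0


def test_variance_ratio_recomputed_independently():
    cfg = PopulationConfig(
        n_genotypes=400, n_markers=500, n_qtl=200, h2_low_n=0.5,
        missing_rate=0.0, seed=6,
    )
    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)
    y = pheno.trait("LN", G.genotype_ids)
    g = arch.true_gebv["LN"].to_numpy()
    ratio = g.var() / y.var()  # independent direct variance tally
    assert abs(ratio - 0.5) <= 0.08


def test_heritability_construction_is_exact_and_sample_converges():
    cfg = PopulationConfig(n_genotypes=1000, n_markers=400, h2_low_n=0.45,
                           h2_high_n=0.6, missing_rate=0.0, seed=10)
    G = simulate_genotypes(cfg)
    pheno, arch = simulate_phenotypes(G, cfg)
    # population-level construction is exact
    assert arch.h2("LN") == pytest.approx(0.45, abs=1e-12)
    assert arch.h2("HN") == pytest.approx(0.6, abs=1e-12)
    # sample estimate converges at n=1000
    for level, target in (("LN", 0.45), ("HN", 0.6)):
        y = pheno.trait(level, G.genotype_ids)
        g = arch.true_gebv[level].to_numpy()
        assert abs(g.var() / y.var() - target) <= 0.05


def test_qtl_effect_correlation_across_n_levels():
    cfg = PopulationConfig(n_genotypes=50, n_markers=3000, n_qtl=2000,
                           genetic_corr_n_levels=0.8, seed=1)
    G = simulate_genotypes(cfg)
    _, arch = simulate_phenotypes(G, cfg)
    r = np.corrcoef(arch.effects_low_n, arch.effects_high_n)[0, 1]
    assert abs(r - 0.8) < 0.05


def test_subpopulation_structure_separates_on_leading_pcs():
    cfg = PopulationConfig(n_genotypes=180, n_markers=600, n_subpops=3,
                           subpop_divergence=0.1, missing_rate=0.0, seed=14)
    G = simulate_genotypes(cfg)
    X = G.dosage - G.dosage.mean(axis=0)
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    pcs = PCA(n_components=2).fit_transform(X)
    pred = KMeans(n_clusters=3, n_init=10, random_state=0).fit_predict(pcs)
    purity = 0
    for c in range(3):
        labels = G.subpop_labels[pred == c]
        if labels.size:
            purity += np.bincount(labels).max()
    assert purity / G.n_genotypes >= 0.9


@pytest.mark.parametrize(
    "kwargs",
    [
        {"maf_low": 0.3, "maf_high": 0.2},
        {"n_qtl": 99999},
        {"h2_low_n": 1.5},
        {"missing_rate": 1.0},
        {"n_genotypes": 0},
        {"genetic_corr_n_levels": -2},
    ],
)
def test_invalid_config_raises(kwargs):
    with pytest.raises(ConfigurationError):
        PopulationConfig(**kwargs)


class TestComputeNUE:
    def test_direct_ratio(self):
        assert compute_nue(500, 100) == 5.0

    def test_factored_form_identity(self):
        assert compute_nue(500, 100, Nt=250) == pytest.approx(5.0, abs=1e-12)

    def test_nonpositive_supply_raises(self):
        with pytest.raises(ValueError):
            compute_nue(500, 0)
        with pytest.raises(ValueError):
            compute_nue(500, 100, Nt=-1)
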