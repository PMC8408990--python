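"""Generator correctness: LD structure, heritability, truth recording, GWAS Z."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from xtwas.simulate import (
    ConfigError,
    SimulationConfig,
    copula_dosage_correlation,
    inverse_normal_transform,
    preprocess_expression,
    simulate_expression,
    simulate_genotypes,
    simulate_gwas,
)


def _cfg(**kw) -> SimulationConfig:
    base = dict(seed=5, n_ref=400, n_gwas=10_000, n_snps_per_gene=6, n_genes=4,
                n_tissues=2, causal_gene_frac=0.5, gene_effect_sd=0.1,
                tissue_sample_fracs=(0.8, 0.6))
    base.update(kw)
    return SimulationConfig(**base)


@pytest.mark.parametrize(
    "field,value",
    [
        ("maf_range", (0.0, 0.3)),
        ("maf_range", (0.1, 0.6)),
        ("ld_rho", 1.0),
        ("h2_expr", 1.5),
        ("n_genes", 0),
        ("tissue_sample_fracs", (0.5,)),
        ("n_causal_eqtl", 9),
    ],
)
def test_invalid_config_names_field(field, value):
    with pytest.raises(ConfigError):
        _cfg(**{field: value})


def test_genotypes_deterministic_and_freq_consistent():
    cfg = _cfg()
    p1 = simulate_genotypes(cfg)
    p2 = simulate_genotypes(cfg)
    np.testing.assert_array_equal(p1.dosages, p2.dosages)
    assert p1.snp_meta.equals(p2.snp_meta)
    np.testing.assert_allclose(
        p1.snp_meta["freq"].to_numpy(), p1.dosages.mean(axis=0) / 2, atol=1e-8
    )
    assert p1.snp_meta["snp_id"].is_unique
    assert p1.dosages.min() >= 0 and p1.dosages.max() <= 2


def test_independent_snps_nearly_uncorrelated():
    cfg = _cfg(ld_rho=0.0, n_ref=4000, n_snps_per_gene=10, n_genes=2)
    panel = simulate_genotypes(cfg)
    rs = []
    for g in range(cfg.n_genes):
        blk = panel.dosages[:, g * 10:(g + 1) * 10]
        for j in range(9):
            rs.append(np.corrcoef(blk[:, j], blk[:, j + 1])[0, 1])
    assert np.max(np.abs(rs)) < 3.0 / np.sqrt(cfg.n_ref)


def test_ld_matches_copula_monte_carlo_oracle():
    """Adjacent-SNP dosage correlation equals the copula-implied value."""
    cfg = _cfg(ld_rho=0.9, n_ref=2000, maf_range=(0.3, 0.3),
               n_snps_per_gene=10, n_genes=3)
    panel = simulate_genotypes(cfg)
    expected = copula_dosage_correlation(0.9, 0.3, 0.3, n_mc=10**6, seed=99)
    rs = []
    for g in range(cfg.n_genes):
        blk = panel.dosages[:, g * 10:(g + 1) * 10]
        for j in range(9):
            rs.append(np.corrcoef(blk[:, j], blk[:, j + 1])[0, 1])
    assert abs(np.mean(rs) - expected) < 0.05


def test_zero_heritability_gives_pure_noise_and_zero_weights():
    cfg = _cfg(h2_expr=0.0)
    panel = simulate_genotypes(cfg)
    tissue_sets, truth = simulate_expression(panel, cfg)
    for w in truth.true_weights.values():
        assert np.all(w == 0.0)
    for ts in tissue_sets:
        assert abs(ts.expression.var() - 1.0) < 0.2


def test_perfect_cross_tissue_sharing_gives_identical_effects():
    cfg = _cfg(cross_tissue_cor=1.0, h2_expr=0.4)
    panel = simulate_genotypes(cfg)
    _, truth = simulate_expression(panel, cfg)
    tissues = cfg.tissue_names()
    for gene in cfg.gene_names():
        ref = truth.true_weights[(gene, tissues[0])]
        for t in tissues[1:]:
            np.testing.assert_allclose(truth.true_weights[(gene, t)], ref, atol=1e-12)


def test_heritability_recovered_by_variance_decomposition():
    """R^2 of expression on the true genetic score matches h2_expr."""
    cfg = _cfg(h2_expr=0.5, n_ref=2000, n_genes=6, n_snps_per_gene=8,
               tissue_sample_fracs=(1.0, 1.0))
    panel = simulate_genotypes(cfg)
    tissue_sets, truth = simulate_expression(panel, cfg)
    r2s = []
    ts = tissue_sets[0]
    for g, gene in enumerate(cfg.gene_names()):
        X = panel.dosages[ts.sample_idx][:, panel.gene_block(gene)]
        score = X @ truth.true_weights[(gene, ts.tissue)]
        r2s.append(np.corrcoef(score, ts.expression[:, g])[0, 1] ** 2)
    assert abs(np.mean(r2s) - 0.5) < 0.05


def test_causal_eqtl_indices_within_block():
    cfg = _cfg()
    panel = simulate_genotypes(cfg)
    _, truth = simulate_expression(panel, cfg)
    for gene, idx in truth.causal_eqtl_idx.items():
        assert np.all((idx >= 0) & (idx < cfg.n_snps_per_gene))
    for gene, a in truth.gene_trait_effects.items():
        if gene not in truth.causal_genes:
            assert a == 0.0


def test_int_matches_quantile_oracle():
    """n = 3 values (5, 1, 9): Blom scores at ranks 2, 1, 3."""
    got = inverse_normal_transform(np.array([5.0, 1.0, 9.0]))
    expected = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_preprocess_centres_and_residualizes(rng):
    raw = rng.standard_normal((50, 3))
    cov = np.column_stack([np.ones(50), rng.standard_normal(50)])
    out = preprocess_expression(raw, cov)
    assert np.all(np.abs(out.mean(axis=0)) < 1e-8)
    for j in range(out.shape[1]):
        assert abs(np.corrcoef(out[:, j], cov[:, 1])[0, 1]) < 1e-8


def test_preprocess_constant_covariate_only(rng):
    raw = rng.standard_normal((30, 2))
    out = preprocess_expression(raw, np.ones((30, 1)))
    scores = np.column_stack([inverse_normal_transform(raw[:, j]) for j in range(2)])
    np.testing.assert_allclose(out, scores - scores.mean(axis=0), atol=1e-10)


def test_preprocess_covariate_column_residual_is_zero(rng):
    # INT preserves ranks, so a gene equal to a covariate column becomes
    # exactly collinear with that covariate's INT scores after transformation
    c = rng.standard_normal(40)
    cov = np.column_stack([np.ones(40), inverse_normal_transform(c)])
    resid = preprocess_expression(c[:, None], cov)
    assert np.all(np.abs(resid) < 1e-8)


def test_preprocess_rank_deficient_covariates_identified(rng):
    c = rng.standard_normal(20)
    cov = np.column_stack([np.ones(20), c, 2 * c])
    with pytest.raises(ValueError, match="collinear"):
        preprocess_expression(rng.standard_normal((20, 1)), cov)


def test_null_gwas_z_calibrated():
    cfg = _cfg(causal_gene_frac=0.0, n_genes=40, n_snps_per_gene=10, ld_rho=0.0)
    panel = simulate_genotypes(cfg)
    _, truth = simulate_expression(panel, cfg)
    ss = simulate_gwas(panel, truth, cfg)
    z = ss["Z"].to_numpy()
    frac = np.mean(np.abs(z) > 1.96)
    se = np.sqrt(0.05 * 0.95 / len(z))
    assert abs(frac - 0.05) < 4 * se
    assert np.all(truth.marginal_snp_effects == 0.0)


def test_gwas_deterministic(tiny_cfg, tiny_study):
    panel, _, truth = tiny_study
    z1 = simulate_gwas(panel, truth, tiny_cfg)["Z"].to_numpy()
    z2 = simulate_gwas(panel, truth, tiny_cfg)["Z"].to_numpy()
    np.testing.assert_array_equal(z1, z2)


def test_single_causal_snp_mean_z_matches_oracle():
    """Mean Z at an isolated causal SNP tracks sqrt(n) * gamma over replicates."""
    n_rep = 200
    zs, gammas = [], []
    for rep in range(n_rep):
        cfg = _cfg(seed=rep, ld_rho=0.0, n_genes=1, n_snps_per_gene=4,
                   n_causal_eqtl=1, causal_gene_frac=1.0, gene_effect_sd=0.05,
                   h2_expr=0.5, n_gwas=5_000)
        panel = simulate_genotypes(cfg)
        _, truth = simulate_expression(panel, cfg)
        ss = simulate_gwas(panel, truth, cfg)
        j = truth.causal_eqtl_idx["GENE0000"][0]
        zs.append(ss["Z"].to_numpy()[j] - np.sqrt(cfg.n_gwas) * truth.marginal_snp_effects[j])
    # residual about the predicted mean is standard normal
    assert abs(np.mean(zs)) < 3.0 / np.sqrt(n_rep)


def test_effect_scale_propagates_to_marginal_effects():
    """Doubling gene_effect_sd doubles the induced marginal effects."""
    cfg1 = _cfg(gene_effect_sd=0.05, causal_gene_frac=1.0, h2_expr=0.5)
    cfg2 = dataclasses.replace(cfg1, gene_effect_sd=0.10)
    panel = simulate_genotypes(cfg1)
    _, truth1 = simulate_expression(panel, cfg1)
    _, truth2 = simulate_expression(simulate_genotypes(cfg2), cfg2)
    simulate_gwas(panel, truth1, cfg1)
    simulate_gwas(simulate_genotypes(cfg2), truth2, cfg2)
    g1 = np.abs(truth1.marginal_snp_effects).mean()
    g2 = np.abs(truth2.marginal_snp_effects).mean()
    assert g2 / g1 == pytest.approx(2.0, rel=0.05)
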