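import numpy as np
import pytest

from multimarker import (
    build_ar1,
    build_cs,
    build_generator,
    calibrate_latent,
    dominant_genotypes,
    fit_joint_bernoulli,
    genotype_level,
    sample_case_control,
    sample_haplotypes,
)
from multimarker.simulate import (
    DiseaseModel,
    bvn_upper,
    causal_unit_freq,
    latent_correlation,
)


def test_bvn_upper_independence_and_symmetry():
    assert bvn_upper(0.5, -0.3, 0.0) == pytest.approx(
        (1 - 0.691462) * 0.617911, abs=1e-5
    )
    assert bvn_upper(0.4, 1.1, 0.6) == pytest.approx(bvn_upper(1.1, 0.4, 0.6),
                                                     abs=1e-12)
    # comonotone limit: P(X>h, X>k) -> sf(max(h,k))
    from scipy.stats import norm
    assert bvn_upper(0.3, 1.0, 0.999999) == pytest.approx(norm.sf(1.0), abs=1e-4)


def test_latent_correlation_fixed_points():
    assert latent_correlation(0.3, 0.4, 0.0) == 0.0
    assert latent_correlation(0.25, 0.25, 1.0) == 1.0


def test_latent_correlation_monte_carlo_inversion():
    """The calibrated latent value reproduces the target binary correlation."""
    rho = latent_correlation(0.25, 0.25, 0.5)
    rng = np.random.default_rng(0)
    n = 2_000_000
    x = rng.standard_normal(n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    from scipy.special import ndtri

    t = ndtri(1 - 0.25)
    emp = np.corrcoef(x > t, y > t)[0, 1]
    assert emp == pytest.approx(0.5, abs=0.003)


def test_calibrate_latent_parametric_blocks_need_no_repair():
    for blk in (build_cs(5, 0.4, freq=0.25), build_ar1(5, 0.6, freq=0.05)):
        model = calibrate_latent(blk)
        assert not model.repaired
        assert model.max_abs_repair < 1e-6


def test_calibrate_latent_fixture_repair_logged(block1):
    model = calibrate_latent(block1)
    assert model.repaired
    assert model.max_abs_repair > 0.01  # near-boundary LD forces a large repair


def test_joint_bernoulli_exact_on_parametric_block():
    blk = build_cs(5, 0.4, freq=0.25)
    model = fit_joint_bernoulli(blk)
    assert model.max_abs_repair < 2e-3  # only the interior nudge remains
    p = model.probs
    x = model.patterns.astype(float)
    np.testing.assert_allclose(p @ x, blk.freq, atol=1e-6)


def test_joint_bernoulli_fixtures_match_printed_moments(block1, block2):
    """Only the provably Fréchet-infeasible pairs deviate beyond 0.003."""
    for blk, bad_pair in ((block1, (0, 1)), (block2, (1, 2))):
        model = fit_joint_bernoulli(blk)
        p = model.probs
        x = model.patterns.astype(float)
        freq = p @ x
        cov = (x.T * p) @ x - np.outer(freq, freq)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        gaps = np.abs(corr - blk.corr)
        np.fill_diagonal(gaps, 0.0)
        assert model.max_abs_repair < 0.015
        big = {tuple(sorted(ij)) for ij in zip(*np.where(gaps > 0.003))}
        assert big == {bad_pair}
        np.testing.assert_allclose(freq, blk.freq, atol=1e-3)


def test_sampling_is_deterministic_and_converges(block1):
    model = build_generator(block1)
    h1 = sample_haplotypes(model, 1000, np.random.default_rng(42))
    h2 = sample_haplotypes(model, 1000, np.random.default_rng(42))
    np.testing.assert_array_equal(h1, h2)

    h = sample_haplotypes(model, 400_000, np.random.default_rng(1))
    se = np.sqrt(block1.freq * (1 - block1.freq) / 400_000)
    assert (np.abs(h.mean(0) - block1.freq) < 4 * se + model.max_abs_repair).all()


def test_rare_allele_marginal_convergence():
    model = build_generator(build_cs(3, 0.2, freq=0.05))
    h = sample_haplotypes(model, 400_000, np.random.default_rng(2))
    se = np.sqrt(0.05 * 0.95 / 400_000)
    assert np.abs(h.mean(0) - 0.05).max() < 4 * se + 2e-3


def test_dominant_genotypes_match_analytic_block():
    blk = build_cs(5, 0.6, freq=0.25)
    g_an = genotype_level(blk)
    model = build_generator(blk)
    g = dominant_genotypes(model, 200_000, np.random.default_rng(3))
    np.testing.assert_allclose(g.mean(0), 1 - 0.75**2, atol=0.004)
    np.testing.assert_allclose(np.corrcoef(g.T), g_an.corr, atol=0.01)


def test_disease_model_prevalence_and_validation():
    dm = DiseaseModel.from_prevalence(1, 1.7, 0.0975, prevalence=0.1)
    from scipy.special import expit

    prev = 0.9025 * expit(dm.baseline_log_odds) + 0.0975 * expit(
        dm.baseline_log_odds + dm.theta
    )
    assert prev == pytest.approx(0.1, abs=1e-10)
    with pytest.raises(ValueError, match="positive"):
        DiseaseModel(1, -2.0, 0.0)
    with pytest.raises(ValueError, match="prevalence"):
        DiseaseModel.from_prevalence(1, 1.5, 0.2, prevalence=1.2)


def test_case_control_null_has_no_frequency_contrast():
    blk = build_cs(4, 0.3, freq=0.2)
    model = build_generator(blk)
    disease = DiseaseModel.from_prevalence(2, 1.0, 0.2, 0.1)
    rng = np.random.default_rng(4)
    data = sample_case_control(model, disease, 4000, 4000, rng, units="haplotype")
    case = data.genotypes[data.phenotype == 1].mean(0)
    ctrl = data.genotypes[data.phenotype == 0].mean(0)
    assert np.abs(case - ctrl).max() < 4 * np.sqrt(2 * 0.2 * 0.8 / 4000)


def test_case_control_units_and_quotas():
    blk = build_cs(3, 0.2, freq=0.3)
    model = build_generator(blk)
    disease = DiseaseModel.from_prevalence(1, 1.5, 0.3, 0.1)
    rng = np.random.default_rng(5)
    data = sample_case_control(model, disease, 120, 80, rng, units="haplotype")
    assert data.n_case == 120 and data.n_control == 80
    assert causal_unit_freq(model, 1, "haplotype") == pytest.approx(0.3)
    assert causal_unit_freq(model, 1, "subject") == pytest.approx(1 - 0.7**2)
    with pytest.raises(ValueError, match="units"):
        sample_case_control(model, disease, 10, 10, rng, units="chromosome")


def test_uncorrelated_marker_shows_no_induced_association():
    """A marker in linkage equilibrium with the causal one stays at OR ~ 1."""
    blk = build_cs(2, 0.0, freq=0.3)
    model = build_generator(blk)
    disease = DiseaseModel.from_prevalence(1, 2.0, 0.3, 0.1)
    rng = np.random.default_rng(6)
    ors = []
    for _ in range(40):
        data = sample_case_control(model, disease, 1000, 1000, rng,
                                   units="haplotype")
        g = data.genotypes[:, 1]
        x = data.phenotype
        a = ((g == 1) & (x == 1)).sum() * ((g == 0) & (x == 0)).sum()
        b = ((g == 1) & (x == 0)).sum() * ((g == 0) & (x == 1)).sum()
        ors.append(np.log(a / b))
    assert abs(np.mean(ors)) < 3.5 * np.std(ors) / np.sqrt(len(ors)) + 0.01


def test_sampler_guard_against_nonterminating_loop():
    blk = build_cs(2, 0.0, freq=0.3)
    model = build_generator(blk)
    # absurd baseline: essentially nobody is ever a case
    disease = DiseaseModel(causal_marker=1, odds_ratio=1.0,
                           baseline_log_odds=-40.0)
    with pytest.raises(RuntimeError, match="exceeded"):
        sample_case_control(model, disease, 5, 5, np.random.default_rng(7))
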