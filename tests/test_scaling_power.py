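"""Quartile rescaling of per-kb ORs and minimum-detectable-OR power."""

import numpy as np
import pytest
from scipy import integrate, stats

from telomr.errors import DomainError
from telomr.scaling_power import (
    PowerSpec,
    QuartileSimConfig,
    min_detectable_or,
    quartile_shift,
    rescale_or,
)


def quartile_shift_quadrature(mean_bp, sd_bp):
    """1-D quadrature oracle for E[X | X>q75] - E[X | X<q25]."""
    q25 = stats.norm.ppf(0.25, mean_bp, sd_bp)
    q75 = stats.norm.ppf(0.75, mean_bp, sd_bp)
    f = lambda x: x * stats.norm.pdf(x, mean_bp, sd_bp)
    upper, _ = integrate.quad(f, q75, mean_bp + 12 * sd_bp)
    lower, _ = integrate.quad(f, mean_bp - 12 * sd_bp, q25)
    return upper / 0.25 - lower / 0.25


# MC SD of the n=1e6 statistic, measured across independent seeds during
# oracle construction; scales linearly in sd_bp.
MC_SD_PER_SD_BP = 1.5e-3


class TestQuartileShift:
    def test_degenerate_distribution(self):
        assert quartile_shift(QuartileSimConfig(sd_bp=0.0, seed=1)) == 0.0

    def test_reproducible_under_fixed_seed(self):
        cfg = QuartileSimConfig(sd_bp=500, seed=42)
        assert quartile_shift(cfg) == quartile_shift(cfg)

    @pytest.mark.parametrize("sd_bp", [400.0, 700.0])
    def test_matches_quadrature_oracle(self, sd_bp):
        sim = quartile_shift(QuartileSimConfig(sd_bp=sd_bp, seed=2024))
        exact = quartile_shift_quadrature(6000.0, sd_bp)
        assert sim == pytest.approx(exact, abs=3 * MC_SD_PER_SD_BP * sd_bp)

    def test_affine_equivariance(self):
        """shift(sigma)/sigma is constant across sigma (normal family)."""
        r1 = quartile_shift(QuartileSimConfig(sd_bp=300, seed=5)) / 300
        r2 = quartile_shift(QuartileSimConfig(sd_bp=900, seed=6)) / 900
        assert r1 == pytest.approx(r2, rel=1e-2)
        assert r1 == pytest.approx(2.5422, abs=0.02)

    def test_validation(self):
        with pytest.raises(DomainError):
            QuartileSimConfig(sd_bp=-1.0)
        with pytest.raises(DomainError):
            QuartileSimConfig(n_draws=2)


class TestRescaleOr:
    def test_per_kb_contrast_is_identity(self):
        assert rescale_or(1.65, 1000.0) == pytest.approx(1.65)

    def test_half_contrast_is_square_root(self):
        assert rescale_or(2.0, 500.0) == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_group_action(self):
        """rescale(rescale(or, a), b*1000/a) == rescale(or, b)."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            o = rng.uniform(0.3, 5.0)
            a, b = rng.uniform(200, 3000, 2)
            assert rescale_or(rescale_or(o, a), b * 1000 / a) == \
                pytest.approx(rescale_or(o, b), rel=1e-12)

    def test_requires_positive_or(self):
        with pytest.raises(DomainError):
            rescale_or(0.0, 1000.0)


def simulated_power(or_per_sd, r2, n_cases, n_controls, n_reps=800, seed=99):
    """Independent oracle: retrospective case-control simulation.

    An instrument score Z ~ N(0,1) explains r2 of the exposure; the causal
    per-SD log-odds is ln(or_per_sd), so the per-unit-Z log-odds is
    b = ln(or_per_sd) * sqrt(r2).  Cases and controls are drawn exactly
    from their conditional Z distributions by rejection sampling and the
    score test of b = 0 is applied at the 5% level.
    """
    b = np.log(or_per_sd) * np.sqrt(r2)
    a = stats.norm.ppf(0.10)  # logistic intercept => ~10% prevalence
    rng = np.random.default_rng(seed)

    def sample_conditional(n, case):
        out = np.empty(0)
        bound = 1.0  # expit <= 1 and 1-expit <= 1: safe envelope
        while out.size < n:
            z = rng.normal(size=4 * n)
            p = 1.0 / (1.0 + np.exp(-(a + b * z)))
            w = p if case else 1.0 - p
            keep = rng.random(z.size) * bound < w
            out = np.concatenate([out, z[keep]])
        return out[:n]

    rejections = 0
    for _ in range(n_reps):
        z = np.concatenate([sample_conditional(n_cases, True),
                            sample_conditional(n_controls, False)])
        d = np.r_[np.ones(n_cases), np.zeros(n_controls)]
        n = d.size
        score_z = np.sqrt(n) * np.corrcoef(d, z)[0, 1]
        rejections += abs(score_z) > stats.norm.isf(0.025)
    return rejections / n_reps


class TestMinDetectableOr:
    def test_detectable_or_achieves_nominal_power_in_simulation(self):
        spec = PowerSpec(n_cases=2000, n_controls=2000, r2=0.05)
        or_sd, _ = min_detectable_or(spec)
        power = simulated_power(or_sd, 0.05, 2000, 2000)
        assert power == pytest.approx(0.80, abs=0.05)

    def test_quadrupling_n_halves_the_detectable_log_or(self):
        small = min_detectable_or(PowerSpec(n_cases=2500, n_controls=2500))
        big = min_detectable_or(PowerSpec(n_cases=10000, n_controls=10000))
        assert np.log(big[0]) == pytest.approx(np.log(small[0]) / 2,
                                               rel=1e-9)

    def test_doubling_r2_shrinks_log_or_by_sqrt2(self):
        r1 = min_detectable_or(PowerSpec(n_cases=5000, n_controls=5000,
                                         r2=0.01))
        r2 = min_detectable_or(PowerSpec(n_cases=5000, n_controls=5000,
                                         r2=0.02))
        assert np.log(r2[0]) == pytest.approx(np.log(r1[0]) / np.sqrt(2),
                                              rel=1e-9)

    @pytest.mark.parametrize("field, lo, hi", [
        ("n_cases", 2000, 4000),
        ("r2", 0.01, 0.02),
        ("alpha", 0.01, 0.05),
    ])
    def test_monotone_decreasing(self, field, lo, hi):
        base = dict(n_cases=3000, n_controls=9000, r2=0.01, alpha=0.05)
        weak = min_detectable_or(PowerSpec(**{**base, field: lo}))
        strong = min_detectable_or(PowerSpec(**{**base, field: hi}))
        assert strong[0] < weak[0]

    def test_exponent_modes(self):
        spec_p = PowerSpec(n_cases=5000, n_controls=5000, r2=0.01,
                           exponent_mode="paper")
        spec_c = PowerSpec(n_cases=5000, n_controls=5000, r2=0.01,
                           exponent_mode="consistent", sd_bp=500.0)
        or_sd, or_kb_paper = min_detectable_or(spec_p)
        _, or_kb_consistent = min_detectable_or(spec_c)
        assert or_kb_paper == pytest.approx(or_sd ** 0.5, rel=1e-12)
        assert or_kb_consistent == pytest.approx(or_sd ** 2.0, rel=1e-12)

    def test_validation(self):
        with pytest.raises(DomainError):
            PowerSpec(n_cases=100, n_controls=100, r2=1.5)
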