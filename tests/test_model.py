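import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntskew.genome_io import LAGGING, LEADING
from ntskew import model


class TestForwardSkew:
    def test_no_bias_no_selection(self):
        assert model.forward_skew(0.0, 0.0, LEADING) == 0
        assert model.forward_skew(0.0, 0.0, LAGGING) == 0

    def test_pure_mutational_skew(self):
        # without selection the equilibrium skew equals the mutational bias,
        # with opposite sign on the lagging strand
        assert model.forward_skew(0.2, 0.0, LEADING) == pytest.approx(0.2)
        assert model.forward_skew(0.2, 0.0, LAGGING) == pytest.approx(-0.2)

    def test_closed_form_value(self):
        assert model.forward_skew(0.2, -0.5, LEADING) == pytest.approx(-0.047233, abs=1e-6)
        assert model.forward_skew(0.2, -0.5, LAGGING) == pytest.approx(-0.424142, abs=1e-6)

    def test_monotone_in_S_and_mu(self):
        S = np.linspace(-3, 3, 25)
        g = model.forward_skew(0.1, S, LEADING)
        assert np.all(np.diff(g) > 0)
        mu = np.linspace(-0.9, 0.9, 25)
        g = model.forward_skew(mu, -0.4, LEADING)
        assert np.all(np.diff(g) > 0)

    def test_output_strictly_inside_unit_interval(self):
        for mu in (-0.9, 0.0, 0.9):
            for S in (-5, 0, 5):
                for strand in (LEADING, LAGGING):
                    assert abs(model.forward_skew(mu, S, strand)) < 1

    def test_antisymmetry_between_strands(self):
        # reading the complementary strand flips the skew sign and the
        # direction of selection, while the leading/lagging mutational
        # machinery stays in place: lead(mu, S) = -lag(mu, -S)
        for mu, S in [(0.3, -1.2), (-0.5, 0.7), (0.05, 0.0)]:
            assert model.forward_skew(mu, S, LEADING) == pytest.approx(
                -model.forward_skew(mu, -S, LAGGING)
            )
            # and jointly negating bias and selection negates the skew
            for strand in (LEADING, LAGGING):
                assert model.forward_skew(-mu, -S, strand) == pytest.approx(
                    -model.forward_skew(mu, S, strand)
                )

    def test_mu_domain_guard(self):
        with pytest.raises(ValueError):
            model.forward_skew(1.0, 0.0, LEADING)


class TestEquilibriumProb:
    def test_neutral_is_half(self):
        assert model.equilibrium_prob(0.0, 0.0, LEADING) == 0.5

    def test_closed_form(self):
        assert model.equilibrium_prob(0.2, -0.5, LEADING) == pytest.approx(0.476384, abs=1e-6)

    def test_strong_selection_limit(self):
        assert model.equilibrium_prob(0.0, 50.0, LEADING) == pytest.approx(1.0, abs=1e-12)


class TestInversions:
    def test_opposite_skews_mean_no_selection(self):
        assert model.invert_S(0.3, -0.3) == pytest.approx(0.0)
        assert model.invert_S(0.0, 0.0) == 0.0

    def test_round_trip_of_worked_example(self):
        assert model.invert_S(-0.047233, -0.424142) == pytest.approx(-0.5, abs=1e-5)
        assert model.invert_mu(-0.047233, -0.424142) == pytest.approx(0.2, abs=1e-5)

    def test_symmetric_skews_mean_no_bias(self):
        assert model.invert_mu(0.2, -0.2) == pytest.approx(0.2)
        assert model.invert_mu(0.0, 0.0) == 0.0

    def test_single_strand_consistency(self):
        assert model.S_from_single_strand(0.2, 0.2, LEADING) == pytest.approx(0.0)
        assert model.S_from_single_strand(-0.047233, 0.2, LEADING) == pytest.approx(-0.5, abs=1e-5)
        assert model.S_from_single_strand(-0.424142, 0.2, LAGGING) == pytest.approx(-0.5, abs=1e-5)

    def test_boundary_skew_rejected(self):
        with pytest.raises(ValueError):
            model.invert_S(1.0, 0.2)

    @settings(max_examples=200, deadline=None)
    @given(
        mu=st.floats(-0.9, 0.9),
        S=st.floats(-5, 5),
    )
    def test_exact_round_trip_property(self, mu, S):
        gl = model.forward_skew(mu, S, LEADING)
        gg = model.forward_skew(mu, S, LAGGING)
        assert model.invert_S(gl, gg) == pytest.approx(S, abs=1e-9)
        assert model.invert_mu(gl, gg) == pytest.approx(mu, abs=1e-9)
        assert model.S_from_single_strand(gl, mu, LEADING) == pytest.approx(S, abs=1e-9)
        assert model.S_from_single_strand(gg, mu, LAGGING) == pytest.approx(S, abs=1e-9)


class TestMonteCarloAgreement:
    def test_two_state_sampling_recovers_parameters(self, rng):
        mu, S, n = 0.2, -0.5, 100_000
        pl = model.equilibrium_prob(mu, S, LEADING)
        pg = model.equilibrium_prob(mu, S, LAGGING)
        gl = 2 * rng.binomial(n, pl) / n - 1
        gg = 2 * rng.binomial(n, pg) / n - 1
        se = 2 * np.sqrt(pl * (1 - pl) / n) + 2 * np.sqrt(pg * (1 - pg) / n)
        S_hat = model.invert_S(gl, gg)
        mu_hat = model.invert_mu(gl, gg)
        # within 3 aggregated binomial standard errors on the skew scale,
        # propagated conservatively through the logit-based inverses
        assert abs(S_hat - S) < 3 * se / (1 - max(abs(gl), abs(gg)) ** 2)
        assert abs(mu_hat - mu) < 3 * se / (1 - max(abs(gl), abs(gg)) ** 2)


class TestEstimateTau:
    def test_exact_proportionality(self):
        x = np.array([0.1, -0.2, 0.05])
        fit = model.estimate_tau(x, 1.5 * x)
        assert fit.value == pytest.approx(1.5)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_hand_least_squares(self):
        fit = model.estimate_tau([0.1, 0.2, -0.1], [0.15, 0.35, -0.16])
        assert fit.value == pytest.approx(0.101 / 0.06, abs=1e-12)

    def test_single_pair_has_no_ci(self):
        fit = model.estimate_tau([0.2], [0.3])
        assert fit.value == pytest.approx(1.5)
        assert np.isnan(fit.ci_low) and np.isnan(fit.ci_high)

    def test_all_zero_predictor_errors(self):
        with pytest.raises(ValueError):
            model.estimate_tau([0.0, 0.0], [0.1, 0.2])

    def test_ci_coverage_under_noise(self):
        # genomes share one global tau; per-genome noise on both axes
        rng = np.random.default_rng(7)
        tau, hits, runs = 1.6, 0, 200
        for _ in range(runs):
            mu_io = rng.uniform(-0.3, 0.3, size=40)
            mu_4s = tau * mu_io + rng.normal(0, 0.02, size=40)
            fit = model.estimate_tau(mu_io, mu_4s)
            hits += fit.ci_low <= tau <= fit.ci_high
        assert hits / runs >= 0.90


class TestEstimateF:
    def test_noise_free_exact_inversion(self):
        rng = np.random.default_rng(3)
        mu_io = rng.uniform(-0.2, 0.2, size=30)
        tau, f_true, S = 1.5, 0.5, 0.4
        gl = f_true * model.forward_skew(tau * mu_io, S, LEADING)
        gg = f_true * model.forward_skew(tau * mu_io, S, LAGGING)
        fit = model.estimate_f(gl, gg, mu_io, tau, n_boot=0)
        assert fit.value == pytest.approx(f_true, abs=1e-4)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(4)
        mu_io = rng.uniform(-0.2, 0.2, size=25)
        gl = 0.35 * model.forward_skew(1.5 * mu_io, 0.5, LEADING) + rng.normal(0, 0.01, 25)
        gg = 0.35 * model.forward_skew(1.5 * mu_io, 0.5, LAGGING) + rng.normal(0, 0.01, 25)
        fit = model.estimate_f(gl, gg, mu_io, 1.5, n_boot=60, seed=9)
        assert fit.ci_low <= fit.value <= fit.ci_high

    def test_empty_usable_set_errors(self):
        with pytest.raises(ValueError):
            model.estimate_f([np.nan], [np.nan], [0.1], 1.5, n_boot=0)


class TestDecomposeSelection:
    def test_noise_free_additivity(self, small_truth):
        # exact forward-model skews with f = 1: S_AA = S_total - S_RNA exactly
        from ntskew.sites import FOURFOLD, INTEROPERONIC, NS, SiteCounts, SkewSet
        from ntskew.sites import Skew

        mu, tau, s_rna, s_tot = 0.05, 1.0, -0.3, 0.4
        ss = SkewSet("x")
        for pair in ("AT", "GC"):
            ss.skews[(pair, INTEROPERONIC, LEADING)] = Skew(mu, 10**6)
            for strand in (LEADING, LAGGING):
                ss.skews[(pair, FOURFOLD, strand)] = Skew(
                    float(model.forward_skew(mu, s_rna, strand)), 10**6)
                ss.skews[(pair, NS, strand)] = Skew(
                    float(model.forward_skew(mu, s_tot, strand)), 10**6)
        p = model.decompose_selection(ss, {"AT": tau, "GC": tau}, {"AT": 1.0, "GC": 1.0})
        for pair in ("AT", "GC"):
            for strand in (LEADING, LAGGING, "mean"):
                assert p.s_rna[(pair, strand)] == pytest.approx(s_rna, abs=1e-9)
                assert p.s_aa[(pair, strand)] == pytest.approx(s_tot - s_rna, abs=1e-9)

    def test_domain_guard_flags_genome(self):
        from ntskew.sites import FOURFOLD, INTEROPERONIC, NS, Skew, SkewSet

        ss = SkewSet("x")
        for pair in ("AT", "GC"):
            ss.skews[(pair, INTEROPERONIC, LEADING)] = Skew(0.05, 1000)
            for strand in (LEADING, LAGGING):
                ss.skews[(pair, FOURFOLD, strand)] = Skew(0.1, 1000)
                ss.skews[(pair, NS, strand)] = Skew(0.8, 1000)  # |0.8/0.35| > 1
        p = model.decompose_selection(ss, {"AT": 1.5, "GC": 1.5}, {"AT": 0.35, "GC": 0.35})
        assert np.isnan(p.s_total[("AT", LEADING)])
        assert np.isnan(p.s_aa[("AT", "mean")])
        assert np.isfinite(p.s_rna[("AT", LEADING)])
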