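"""Probabilistic sensitivity analysis: sampling, reruns, acceptability curves."""
import numpy as np
import pandas as pd
import pytest

from renalcea import HealthState, baseline_config, run_base_case
from renalcea.parameters import BetaSpec, GammaSpec
from renalcea.psa import (
    ceac,
    crossover_threshold,
    default_threshold_grid,
    incremental_scatter,
    optimal_probabilities,
    run_psa,
    sample_parameters,
)

S = HealthState


def collapse_to_point_masses(config, blowup: float = 1e8):
    """Blow up every distribution's effective sample size so draws collapse
    onto the deterministic base values (Gammas re-centred on the base value,
    absorbing the <=2% rounding gap between printed means and Gamma moments)."""
    from renalcea import get_parameter

    out = config.copy()
    for name, spec in out.psa.gammas.items():
        shape = spec.shape * blowup
        out.psa.gammas[name] = GammaSpec(shape, get_parameter(config, name) / shape)
    beta = out.psa.home_hd_stay
    total = beta.alpha + beta.beta
    out.psa.home_hd_stay = BetaSpec(
        beta.alpha / total * blowup, beta.beta / total * blowup
    )
    for origin, counts in out.psa.dirichlet_counts.items():
        out.psa.dirichlet_counts[origin] = {k: int(v * 1e6) for k, v in counts.items()}
        row = out.clinical.switch_row(origin)
        row.counts = None
    return out


class TestSampling:
    def test_seed_determinism(self, baseline):
        a = sample_parameters(baseline, np.random.default_rng(7))
        b = sample_parameters(baseline, np.random.default_rng(7))
        assert a == b
        c = sample_parameters(baseline, np.random.default_rng(8))
        assert c != a

    def test_input_never_mutated(self, baseline):
        reference = baseline_config()
        sample_parameters(baseline, np.random.default_rng(0))
        assert baseline == reference

    def test_sampled_rows_are_valid_distributions(self, baseline):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sampled = sample_parameters(baseline, rng)
            for row in sampled.clinical.switch_rows:
                assert sum(row.probabilities.values()) == pytest.approx(1.0, abs=1e-9)
                assert all(p >= 0 for p in row.probabilities.values())
            assert sampled.clinical.switch_row(S.HOME_HD).probabilities[S.PD] == 0.0
            for d in sampled.utilities.disutilities.values():
                assert 0.0 <= d <= 1.0

    def test_dirichlet_mean_matches_count_ratios(self, baseline):
        rng = np.random.default_rng(11)
        draws = [sample_parameters(baseline, rng) for _ in range(2000)]
        pd_rows = np.array(
            [
                [d.clinical.switch_row(S.PD).probabilities[dest] for dest in (S.PD, S.HOSP_HD, S.HOME_HD)]
                for d in draws
            ]
        )
        np.testing.assert_allclose(pd_rows.mean(axis=0), [159 / 179, 19 / 179, 1 / 179], atol=0.01)

    def test_gamma_mean_matches_printed_disutility(self, baseline):
        rng = np.random.default_rng(12)
        vals = np.array(
            [
                sample_parameters(baseline, rng).utilities.disutilities[S.HOSP_HD]
                for _ in range(2000)
            ]
        )
        # Gamma(5.58, 0.048) has mean 0.268 against the printed 0.269
        assert vals.mean() == pytest.approx(0.268, abs=0.01)

    def test_mortality_and_transplant_rates_held_fixed(self, baseline):
        sampled = sample_parameters(baseline, np.random.default_rng(5))
        assert sampled.clinical.mortality_rates == baseline.clinical.mortality_rates
        assert sampled.clinical.transplant_rate == baseline.clinical.transplant_rate


class TestRunPSA:
    def test_reproducible_under_seed(self, baseline):
        a = run_psa(baseline, 25, seed=42)
        b = run_psa(baseline, 25, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = run_psa(baseline, 25, seed=43)
        assert not a.equals(c)

    def test_point_mass_psa_recovers_base_case(self, baseline):
        collapsed = collapse_to_point_masses(baseline)
        # align the deterministic rows with the count ratios the collapsed
        # Dirichlet concentrates on (printed rows are 3-dp roundings)
        for origin, counts in baseline.psa.dirichlet_counts.items():
            total = sum(counts.values())
            collapsed.clinical.switch_row(origin).probabilities = {
                d: n / total for d, n in counts.items()
            }
        base = run_base_case(collapsed)
        draws = run_psa(collapsed, 3, seed=0)
        for strategy in (S.PD, S.HOME_HD, S.HOSP_HD):
            sub = draws[draws.strategy == strategy.value]
            # residual Gamma noise at blown-up shape is ~1/sqrt(shape) relative
            assert sub.cost.std() == pytest.approx(0.0, abs=50.0)
            assert sub.cost.mean() == pytest.approx(base[strategy].cost, rel=2e-3)
            assert sub.qalys.mean() == pytest.approx(base[strategy].qalys, rel=2e-3)

    def test_mean_psa_cost_near_base_case(self, baseline):
        draws = run_psa(baseline, 600, seed=9)
        base = run_base_case(baseline)
        pd_cost = draws[draws.strategy == "PD"].cost.mean()
        assert pd_cost == pytest.approx(base[S.PD].cost, rel=0.05)

    def test_invalid_draw_count(self, baseline):
        with pytest.raises(ValueError):
            run_psa(baseline, 0, seed=1)


@pytest.fixture(scope="module")
def samples():
    return run_psa(baseline_config(), 800, seed=100)


class TestCEAC:
    def test_probabilities_sum_to_one_everywhere(self, samples):
        curve = ceac(samples)
        sums = curve.groupby("threshold").probability.sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_threshold_limits(self, samples):
        probs0 = optimal_probabilities(samples, 1e-9)
        cheapest = samples.groupby("strategy").cost.mean().idxmin()
        assert probs0[cheapest] > 0.9
        probs_inf = optimal_probabilities(samples, 1e9)
        most_effective = samples.groupby("strategy").qalys.mean().idxmax()
        assert probs_inf[most_effective] > 0.9

    def test_single_crossover_shape_at_baseline(self, samples):
        grid = np.arange(0, 60_001, 2000, dtype=float)
        curve = ceac(samples, grid)
        home = curve[curve.strategy == "HOME_HD"].probability.to_numpy()
        pd_p = curve[curve.strategy == "PD"].probability.to_numpy()
        assert (np.diff(home) >= -0.02).all()  # Monte-Carlo wiggle tolerance
        assert (np.diff(pd_p) <= 0.02).all()
        assert crossover_threshold(curve) is not None

    def test_hospital_hd_never_optimal(self, samples):
        curve = ceac(samples)
        hosp = curve[curve.strategy == "HOSP_HD"].probability
        assert hosp.max() < 0.01

    def test_grid_contains_opportunity_cost_thresholds(self):
        grid = default_threshold_grid()
        assert 18_609.0 in grid and 20_223.0 in grid

    def test_scatter_has_one_row_per_draw(self, samples):
        sc = incremental_scatter(samples)
        assert len(sc) == samples.draw.nunique()
        assert (sc.incremental_qalys > 0).mean() > 0.9  # home HD gains QALYs

    def test_beta_sample_size_reconstruction_is_qualitatively_stable(self):
        """The home-HD stay Beta's effective sample size (reconstructed) does
        not change which strategies matter: hospital HD stays dominated and
        home HD stays favoured at the opportunity-cost threshold."""
        for ess in (50, 412, 1000):
            cfg = baseline_config()
            cfg.psa.home_hd_stay = BetaSpec(0.95 * ess, 0.05 * ess)
            probs = optimal_probabilities(run_psa(cfg, 300, seed=21), 18_609.0)
            assert probs["HOSP_HD"] < 0.01
            assert probs["HOME_HD"] > probs["PD"]
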