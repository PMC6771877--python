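import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from isobarrier.core import CourtshipTable, EstimationError
from isobarrier.courtship import (
    color_preference_fit,
    color_x,
    courtship_rate_fit,
    courtship_x,
)
from isobarrier.synthetic import SimulationConfig, gen_courtship


def _events(rows):
    return pd.DataFrame(rows, columns=["comparison", "n_own", "n_alt"])


class TestColorPreference:
    def test_even_counts_not_significant(self):
        fit = color_preference_fit(_events([("E_vs_Pb", 50, 50)]))
        est = fit.estimates[0]
        assert est.probability == 0.5
        assert not est.significant

    def test_complete_preference(self):
        fit = color_preference_fit(_events([("E_vs_Pb", 30, 0)]))
        est = fit.estimates[0]
        assert est.probability == 1.0
        assert est.ci[0] > 0.5 and est.ci[1] == 1.0
        assert est.significant

    def test_closed_form_equals_pooled_proportion(self):
        """Saturated binomial model = pooled proportion with logit-Wald CI."""
        k, n = 37, 60
        fit = color_preference_fit(_events([("a_vs_b", k, n - k)]))
        est = fit.estimates[0]
        assert est.probability == pytest.approx(k / n)
        p = k / n
        se = np.sqrt(1 / k + 1 / (n - k))
        z = norm.ppf(0.975)
        logit = np.log(p / (1 - p))
        lo = 1 / (1 + np.exp(-(logit - z * se)))
        assert est.ci[0] == pytest.approx(lo, abs=1e-9)

    def test_simulated_recovery(self, rng):
        p_true = 0.7
        k = rng.binomial(200, p_true)
        fit = color_preference_fit(_events([("a_vs_b", k, 200 - k)]))
        se = np.sqrt(p_true * (1 - p_true) / 200)
        assert abs(fit.estimates[0].probability - p_true) <= 3 * se

    def test_location_lrt_reported(self, rng):
        df = pd.DataFrame(
            {
                "comparison": ["a_vs_b"] * 2 + ["a_vs_c"] * 2,
                "location": ["peru", "uk"] * 2,
                "n_own": rng.binomial(50, 0.6, size=4),
                "n_alt": rng.binomial(50, 0.4, size=4),
            }
        )
        fit = color_preference_fit(df)
        stat, dof, p = fit.location_lrt
        assert dof == 1
        assert 0 <= p <= 1

    def test_zero_event_comparison_skipped(self):
        fit = color_preference_fit(
            _events([("a_vs_b", 0, 0), ("a_vs_c", 10, 5)])
        )
        assert [e.comparison for e in fit.estimates] == ["a_vs_c"]


class TestColorX:
    def test_indifference_gives_half(self):
        assert color_x({"E": 0.5, "Pb": 0.5}, ("E", "Pb")) == 0.5

    def test_complete_preference_gives_zero(self):
        assert color_x({"E": 1.0, "Pb": 1.0}, ("E", "Pb")) == 0.0

    def test_missing_estimate_errors(self):
        with pytest.raises(EstimationError):
            color_x({"E": 1.0}, ("E", "Pb"))


class TestCourtshipRateFit:
    def test_single_trial_errors(self):
        table = CourtshipTable(
            pd.DataFrame(
                [("t1", "E", "E", "hover", 3)],
                columns=["trial_id", "female_taxon", "male_taxon", "behavior", "count"],
            )
        )
        with pytest.raises(EstimationError):
            courtship_rate_fit(table, "E")

    def test_all_zero_counts_flagged(self):
        rows = [(f"t{i}", "E", m, "hover", 0) for i in range(4) for m in ("E", "Pb")]
        table = CourtshipTable(
            pd.DataFrame(
                rows,
                columns=["trial_id", "female_taxon", "male_taxon", "behavior", "count"],
            )
        )
        with pytest.raises(EstimationError, match="no 'hover' events"):
            courtship_rate_fit(table, "E")

    def test_rate_recovery(self):
        cfg = SimulationConfig(
            seed=13,
            n_courtship_trials={"E": 200, "Pb": 4, "Ps": 4},
            courtship_rates={
                "E": {"E": 5.0, "Pb": 1.0, "Ps": 1.0},
                "Pb": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
                "Ps": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
            },
        )
        fit = courtship_rate_fit(gen_courtship(cfg), "E")
        exp = fit.expected.set_index("male_taxon")["expected_per_trial"]
        for m, rate in cfg.courtship_rates["E"].items():
            se = np.sqrt((rate + rate**2 * np.expm1(cfg.courtship_female_sd**2)) / 200)
            assert abs(exp[m] - rate) <= 3 * se + 0.15 * rate

    def test_preference_contrast_detected(self):
        """5x own-taxon hover rate over 24 trials is detected."""
        cfg = SimulationConfig(
            seed=14,
            courtship_rates={
                "E": {"E": 5.0, "Pb": 1.0, "Ps": 1.0},
                "Pb": {"E": 1.0, "Pb": 5.0, "Ps": 1.0},
                "Ps": {"E": 1.0, "Pb": 1.0, "Ps": 5.0},
            },
        )
        fit = courtship_rate_fit(gen_courtship(cfg), "E")
        own_contrasts = fit.contrasts[fit.contrasts["contrast"].str.contains("E")]
        assert (own_contrasts["pvalue_bonferroni"] < 0.05).any()

    def test_power_of_detection(self):
        hits = 0
        n_reps = 10
        for i in range(n_reps):
            cfg = SimulationConfig(
                seed=100 + i,
                courtship_rates={
                    "E": {"E": 5.0, "Pb": 1.0, "Ps": 1.0},
                    "Pb": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
                    "Ps": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
                },
            )
            fit = courtship_rate_fit(gen_courtship(cfg), "E")
            c = fit.contrasts.set_index("contrast")
            hits += (
                c.loc["E - Pb", "pvalue_bonferroni"] < 0.05
                and c.loc["E - Ps", "pvalue_bonferroni"] < 0.05
            )
        assert hits / n_reps > 0.8

    def test_no_difference_type_i(self):
        rejections = 0
        n_reps = 20
        for i in range(n_reps):
            cfg = SimulationConfig(
                seed=200 + i,
                n_courtship_trials={"E": 30, "Pb": 2, "Ps": 2},
                courtship_rates={
                    "E": {"E": 2.0, "Pb": 2.0, "Ps": 2.0},
                    "Pb": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
                    "Ps": {"E": 1.0, "Pb": 1.0, "Ps": 1.0},
                },
            )
            fit = courtship_rate_fit(gen_courtship(cfg), "E")
            rejections += (fit.contrasts["pvalue"] < 0.05).any()
        # 3 contrasts at alpha = 0.05: families with any rejection should be rare
        assert rejections <= 6


class TestCourtshipX:
    def _table(self, counts):
        rows = []
        for i, (fem, male, c) in enumerate(counts):
            rows.append((f"t{i}", fem, male, "hover", c))
        return CourtshipTable(
            pd.DataFrame(
                rows,
                columns=["trial_id", "female_taxon", "male_taxon", "behavior", "count"],
            )
        )

    def test_all_conspecific_x_zero(self):
        table = self._table([("E", "E", 10), ("Pb", "Pb", 8)])
        x, prov = courtship_x(table, ("E", "Pb"))
        assert x == 0.0 and prov == "both_directions"

    def test_hand_computation(self):
        # toward E females: 6 E-male + 2 Pb-male events -> share 0.25
        # toward Pb females: 3 Pb-male + 3 E-male events -> share 0.5
        table = self._table(
            [("E", "E", 6), ("E", "Pb", 2), ("Pb", "Pb", 3), ("Pb", "E", 3)]
        )
        x, _ = courtship_x(table, ("E", "Pb"))
        assert x == pytest.approx((0.25 + 0.5) / 2)

    def test_one_direction_flagged(self):
        table = self._table([("E", "E", 6), ("E", "Pb", 2)])
        x, prov = courtship_x(table, ("E", "Pb"))
        assert x == 0.25 and prov == "one_direction:E"

    def test_no_events_errors(self):
        table = self._table([("Ps", "Ps", 4)])
        with pytest.raises(EstimationError):
            courtship_x(table, ("E", "Pb"))
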