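"""MCID estimation and two-arm sample-size calculations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proval as pv

from conftest import moment_sample


class TestMcid:
    def test_rounding_to_integer_scale(self):
        res = pv.estimate_mcid(moment_sample(21.3, 19.0, 5))
        assert res.value == 21
        assert res.raw_mean == pytest.approx(21.3)

    def test_one_decimal_scale(self):
        res = pv.estimate_mcid(moment_sample(-1.02, 2.1, 40), decimals=1)
        assert res.value == pytest.approx(1.0)

    def test_absolute_value_of_worsening(self):
        res = pv.estimate_mcid(moment_sample(-5.3, 5.0, 15))
        assert res.value == 5

    def test_zero_change_flagged_unusable(self):
        res = pv.estimate_mcid(np.zeros(10))
        assert res.value == 0 and res.flag == "zero_mcid"

    def test_empty_group_undefined(self):
        assert pv.estimate_mcid([]).flag == "empty_group"


class TestTrialSampleSize:
    @pytest.mark.parametrize("mcid,sd,power,expected", [
        (21, 19, 0.80, 26),
        (21, 19, 0.90, 36),
        (5, 5, 0.80, 32),     # mcid == sd
        (1.0, 2.1, 0.80, 140),
        (2.3, 1.5, 0.80, 14),
        (1.4, 1.8, 0.80, 52),
    ])
    def test_normal_approximation_cells(self, mcid, sd, power, expected):
        assert pv.trial_sample_size(mcid, sd, power) == expected

    def test_result_is_even_total(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = pv.trial_sample_size(rng.uniform(0.5, 30), rng.uniform(0.5, 30),
                                     rng.uniform(0.5, 0.99))
            assert n > 0 and n % 2 == 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pv.trial_sample_size(0, 5)
        with pytest.raises(ValueError):
            pv.trial_sample_size(5, 0)
        with pytest.raises(ValueError):
            pv.trial_sample_size(5, 5, power=1.2)

    @settings(max_examples=100, deadline=None)
    @given(mcid=st.floats(0.5, 30), sd=st.floats(0.5, 30),
           power=st.floats(0.55, 0.95))
    def test_monotonicity_and_scale_invariance(self, mcid, sd, power):
        n = pv.trial_sample_size(mcid, sd, power)
        # decreasing in MCID, increasing in SD and power (weakly, post-rounding)
        assert pv.trial_sample_size(mcid * 1.5, sd, power) <= n
        assert pv.trial_sample_size(mcid, sd * 1.5, power) >= n
        assert pv.trial_sample_size(mcid, sd, min(0.99, power + 0.04)) >= n
        # sigma/delta scale invariance: doubling both leaves n unchanged
        assert pv.trial_sample_size(2 * mcid, 2 * sd, power) == n

    def test_against_independent_power_oracle(self):
        """Per-arm n agrees with statsmodels' normal-approximation solver."""
        sm_power = pytest.importorskip("statsmodels.stats.power")
        solver = sm_power.NormalIndPower()
        rng = np.random.default_rng(42)
        for _ in range(120):
            # moderate effect sizes, where the two-sided normal power and the
            # one-tailed z-formula agree to far below one participant
            mcid = rng.uniform(1.0, 8.0)
            sd = rng.uniform(6.0, 20.0)
            power = rng.uniform(0.55, 0.95)
            oracle_arm = solver.solve_power(effect_size=mcid / sd, power=power,
                                            alpha=0.05, ratio=1.0,
                                            alternative="two-sided")
            expected = oracle_arm * 2  # total, both arms, before rounding
            got = pv.trial_sample_size(mcid, sd, power)
            # even-ceiling adds at most 2; the solver's inclusion of the
            # opposite rejection tail shifts n by well under 0.5%
            assert expected - 0.01 <= got <= expected * 1.005 + 2.01


class TestAdjustment:
    @pytest.mark.parametrize("n,r,expected", [
        (140, 0.63, 86),
        (52, 0.63, 32),
        (100, 0.0, 100),
    ])
    def test_one_minus_r_squared(self, n, r, expected):
        assert pv.adjust_sample_size(n, r) == expected

    def test_r_bounds(self):
        with pytest.raises(ValueError):
            pv.adjust_sample_size(100, 1.0)

    def test_adjustment_never_increases(self):
        rng = np.random.default_rng(43)
        for _ in range(50):
            n = 2 * rng.integers(1, 2000)
            r = rng.uniform(-0.99, 0.99)
            assert pv.adjust_sample_size(int(n), r) <= n

    def test_ratio_converges_to_factor(self):
        r = 0.63
        n = 2_000_000
        assert pv.adjust_sample_size(n, r) / n == pytest.approx(1 - r ** 2,
                                                                abs=1e-4)


class TestSampleSizeTable:
    def test_grid_combinatorics(self, big_change_table):
        table = pv.sample_size_table(big_change_table,
                                     r_map={"total": 0.27, "sarcf": 0.63})
        assert len(table) == 12
        ncols = [c for c in table.columns if c.startswith("n_")
                 and not c.startswith("n_group")]
        assert len(ncols) == 4
        ok = table[table.flag.isna()]
        assert (ok.n_adjusted_80 <= ok.n_unadjusted_80).all()
        assert (ok.n_unadjusted_90 >= ok.n_unadjusted_80).all()

    def test_doubling_changes_leaves_n_unchanged(self):
        """sigma/delta scale invariance holds through the whole table when the
        group statistics stay exact under the per-instrument rounding."""
        import pandas as pd
        groups = [("slightly better", 20.0, 10.0, -1.2, 2.0, 12),
                  ("slightly worse", -10.0, 8.0, 0.8, 1.5, 12),
                  ("about the same", 0.0, 6.0, 0.0, 1.0, 12)]
        frames = []
        for cat, mu_t, sd_t, mu_s, sd_s, n in groups:
            frames.append(pd.DataFrame({
                "anchor_fitness": cat, "anchor_qol": cat,
                "any_improvement_fitness": cat == "slightly better",
                "any_improvement_qol": cat == "slightly better",
                "change_total": moment_sample(mu_t, sd_t, n),
                "change_sarcf": moment_sample(mu_s, sd_s, n)}))
        ct = pd.concat(frames, ignore_index=True)
        doubled = ct.copy()
        doubled["change_total"] *= 2
        doubled["change_sarcf"] *= 2
        r_map = {"total": 0.27, "sarcf": 0.63}
        a = pv.sample_size_table(ct, r_map)
        b = pv.sample_size_table(doubled, r_map)
        assert np.allclose(b.mcid, 2 * a.mcid, equal_nan=True)
        for col in ("n_unadjusted_80", "n_adjusted_80", "n_unadjusted_90",
                    "n_adjusted_90"):
            assert (a[col] == b[col]).all()
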