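"""Attitude shifts, exposure cells, national mixing and cases averted."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import fgmsim as f
from fgmsim.errors import ValidationError
from fgmsim.impact import ExposureCell, baseline_cell_probabilities


def _supporters(n_support, n_total, community_id=0):
    return pd.DataFrame(
        {
            "community_id": community_id,
            "supports_fgm": [1] * n_support + [0] * (n_total - n_support),
        }
    )


class TestFlipAttitudes:
    def test_expectation_mode_mass(self):
        # 100 supporters at effect 0.710: support mass drops to 29.0
        out = f.flip_attitudes(_supporters(100, 100), 0.710)
        assert out["supports_fgm"].sum() == pytest.approx(29.0)

    def test_zero_effect_is_identity(self):
        df = _supporters(60, 100)
        out = f.flip_attitudes(df, 0.0)
        pd.testing.assert_frame_equal(out, df, check_dtype=False)

    def test_nonsupporters_never_change(self):
        df = _supporters(40, 100)
        out = f.flip_attitudes(df, 1.0)
        assert (out.loc[df["supports_fgm"] == 0, "supports_fgm"] == 0).all()

    def test_sampling_mode_mean_matches_binomial(self):
        # 1,000 supporters at 0.446 over 200 seeds: mean flips within 3 SE of 446
        df = _supporters(1000, 1000)
        flips = []
        for seed in range(200):
            out = f.flip_attitudes(
                df, 0.446, mode="sampling", rng=np.random.default_rng(seed)
            )
            flips.append(1000 - out["supports_fgm"].sum())
        se_mean = np.sqrt(1000 * 0.446 * 0.554) / np.sqrt(200)
        assert abs(np.mean(flips) - 446) < 3 * se_mean

    def test_effect_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="effect"):
            f.flip_attitudes(_supporters(5, 5), 1.2)


class TestRecomputeCommunitySupport:
    def test_full_flip_zeroes_support(self):
        out = f.flip_attitudes(_supporters(10, 10), 1.0)
        assert f.recompute_community_support(out).iloc[0] == 0.0

    def test_fractional_mean(self):
        # 6 of 10 supporters at effect 0.5 in expectation mode: support 0.30
        out = f.flip_attitudes(_supporters(6, 10), 0.5)
        assert f.recompute_community_support(out).iloc[0] == pytest.approx(0.30)

    def test_matches_groupwise_mean_oracle(self, small_microdata):
        shifted = f.flip_attitudes(small_microdata, 0.3)
        got = f.recompute_community_support(shifted)
        expected = shifted.groupby("community_id")["supports_fgm"].mean()
        pd.testing.assert_series_equal(got, expected, check_names=False)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            f.recompute_community_support(
                pd.DataFrame({"community_id": [], "supports_fgm": []})
            )


class TestCellProbability:
    def test_none_cell_is_baseline_mean(self, small_microdata, fitted_model):
        effects = f.EffectSizes()
        base = f.community_support(small_microdata)
        eligible = small_microdata[base > 0.5]
        expected = f.predict_frame(fitted_model, eligible).mean()
        got = f.cell_probability(
            fitted_model, small_microdata, ExposureCell(True, "none"), effects
        )
        assert got == pytest.approx(expected)

    def test_zero_effects_collapse_to_baseline(self, small_microdata, fitted_model):
        effects = f.EffectSizes(direct=0.0, indirect=0.0)
        probs = [
            f.cell_probability(
                fitted_model, small_microdata, ExposureCell(True, e), effects
            )
            for e in ("direct", "indirect", "none")
        ]
        assert probs[0] == pytest.approx(probs[2])
        assert probs[1] == pytest.approx(probs[2])

    def test_matches_literal_microsimulation(self, small_microdata, fitted_model):
        # apply the multi-step procedure by hand: select eligible communities,
        # scale supporter attitudes, recompute community means, evaluate the
        # logistic expression per woman, average
        effects = f.EffectSizes()
        base = small_microdata.groupby("community_id")["supports_fgm"].mean()
        ids = base.index[base > 0.5]
        sub = small_microdata[small_microdata["community_id"].isin(ids)].copy()
        sub["supports_fgm"] = sub["supports_fgm"] * (1 - effects.direct)
        comm = sub.groupby("community_id")["supports_fgm"].transform("mean")
        eta = fitted_model.linear_predictor(
            sub["supports_fgm"].to_numpy(), comm.to_numpy(), sub
        )
        expected = expit(eta).mean()
        got = f.cell_probability(
            fitted_model, small_microdata, ExposureCell(True, "direct"), effects
        )
        assert got == pytest.approx(expected)

    def test_direct_beats_indirect_beats_none(self, small_microdata, fitted_model):
        effects = f.EffectSizes()
        p = {
            e: f.cell_probability(
                fitted_model, small_microdata, ExposureCell(True, e), effects
            )
            for e in ("direct", "indirect", "none")
        }
        assert p["direct"] < p["indirect"] < p["none"]

    def test_intervention_in_noneligible_cell_rejected(self, small_microdata, fitted_model):
        with pytest.raises(ValidationError, match="50%"):
            f.cell_probability(
                fitted_model, small_microdata, ExposureCell(False, "direct"),
                f.EffectSizes(),
            )


class TestNationalProbability:
    def _cells(self):
        return {
            (True, "direct"): 0.2,
            (True, "indirect"): 0.3,
            (True, "none"): 0.5,
            (False, "none"): 0.1,
        }

    def test_zero_coverage_is_baseline(self):
        cells = self._cells()
        got = f.national_probability(cells, 0.0, f.EffectSizes(), 0.6)
        assert got == pytest.approx(0.6 * 0.5 + 0.4 * 0.1)

    def test_quarter_coverage_ratio_three_saturates_eligible(self):
        # direct 25% + indirect 3 x 25% = full coverage of eligible pool
        cells = self._cells()
        got = f.national_probability(cells, 0.25, f.EffectSizes(), 1.0)
        assert got == pytest.approx(0.25 * 0.2 + 0.75 * 0.3)

    def test_matches_longhand_weighted_average(self):
        cells = self._cells()
        effects = f.EffectSizes(indirect_ratio=2.0)
        dc, share = 0.2, 0.7
        w_i = min(1 - dc, 2.0 * dc)
        expected = share * (dc * 0.2 + w_i * 0.3 + (1 - dc - w_i) * 0.5) + (1 - share) * 0.1
        assert f.national_probability(cells, dc, effects, share) == pytest.approx(expected)

    @pytest.mark.parametrize("share", [0.0, 0.5, 1.0])
    def test_nonincreasing_in_coverage(self, share):
        cells = self._cells()
        grid = [
            f.national_probability(cells, dc, f.EffectSizes(), share)
            for dc in np.linspace(0, 1, 21)
        ]
        assert np.all(np.diff(grid) <= 1e-12)

    def test_weights_valid_across_grid(self):
        # mixing weights stay in [0, 1] and sum to 1 for any coverage/ratio
        for ratio in (0.0, 1.0, 3.0, 10.0):
            for dc in np.linspace(0, 1, 11):
                w_i = min(1 - dc, ratio * dc)
                w_n = 1 - dc - w_i
                assert -1e-12 <= w_i <= 1 and -1e-12 <= w_n <= 1
                assert dc + w_i + w_n == pytest.approx(1.0)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValidationError):
            f.national_probability(self._cells(), 1.5, f.EffectSizes(), 0.5)


class TestImpactFraction:
    def test_arithmetic(self):
        assert f.impact_fraction(0.40, 0.30) == pytest.approx(0.25)

    def test_no_change_is_zero(self):
        assert f.impact_fraction(0.4, 0.4) == 0.0

    def test_elimination_is_one(self):
        assert f.impact_fraction(0.4, 0.0) == 1.0

    def test_zero_original_rejected(self):
        with pytest.raises(ValidationError):
            f.impact_fraction(0.0, 0.0)


class TestCasesAverted:
    def _counterfactual(self):
        return f.trended_incidence(
            np.full(15, 0.01), range(2006, 2051), 0.0, 2020
        )

    def test_identical_surfaces_avert_nothing(self):
        cf = self._counterfactual()
        res = f.cases_averted(cf, cf.copy(), np.full(15, 1e4))
        assert res.averted_2020_2030 == 0.0
        assert res.averted_2031_2050 == 0.0

    def test_full_impact_averts_everything(self):
        cf = self._counterfactual()
        mult = {y: 0.0 for y in range(2020, 2051)}
        scenario = f.apply_impact(cf, mult)
        res = f.cases_averted(cf, scenario, np.full(15, 1e4))
        cases_per_year = 15 * 0.01 * 1e4
        assert res.averted_2020_2030 == pytest.approx(cases_per_year * 11)
        assert res.averted_2031_2050 == pytest.approx(cases_per_year * 20)

    def test_window_split_sums_to_total(self):
        cf = self._counterfactual()
        mult = {y: 0.6 for y in range(2020, 2051)}
        res = f.cases_averted(cf, f.apply_impact(cf, mult), np.full(15, 1e4))
        total = res.annual.loc[2020:2050, "averted"].sum()
        assert res.averted_total == pytest.approx(total)

    def test_horizon_mismatch_rejected(self):
        cf = self._counterfactual()
        other = f.trended_incidence(np.full(15, 0.01), range(2006, 2050), 0.0, 2020)
        with pytest.raises(ValidationError):
            f.cases_averted(cf, other, np.full(15, 1e4))


class TestExpectationVsSampling:
    def test_zero_effect_modes_coincide(self, small_microdata, fitted_model):
        effects = f.EffectSizes(direct=0.0)
        exp = f.cell_probability(
            fitted_model, small_microdata, ExposureCell(True, "direct"), effects
        )
        samp = f.cell_probability(
            fitted_model, small_microdata, ExposureCell(True, "direct"),
            effects, mode="sampling", rng=np.random.default_rng(0),
        )
        assert samp == pytest.approx(exp)

    def test_sampling_mode_reproducible_and_below_baseline(
        self, small_microdata, fitted_model
    ):
        effects = f.EffectSizes()
        base = f.cell_probability(
            fitted_model, small_microdata, ExposureCell(True, "none"), effects
        )
        draws = [
            f.cell_probability(
                fitted_model, small_microdata, ExposureCell(True, "direct"),
                effects, mode="sampling", rng=np.random.default_rng(7),
            )
            for _ in range(2)
        ]
        assert draws[0] == draws[1]
        assert draws[0] < base
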