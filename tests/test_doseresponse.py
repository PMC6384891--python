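"""EC50 fitting, activity tiers, replicate summaries, and library screening."""

import numpy as np
import pandas as pd
import pytest

from mshts.doseresponse import (
    COMPOUND_CUT,
    EXTRACT_TIERS,
    ControlFailureError,
    DoseResponseCurve,
    InsufficientDataError,
    classify_activity,
    fit_ec50,
    four_pl,
    percent_inhibition,
    screen_library,
    summarize_replicates,
    tier_counts,
)

SD_POS, SD_NEG = 3000.0, 1600.0


def make_curve(ec50=50.0, hill=1.0, n=8, top_conc=600.0, factor=5.0, noise_sd=0.0,
               rng=None, sample_id="S"):
    """SD-level synthetic curve: inhibition from the 4PL law mapped back to SD."""
    concs = top_conc / factor ** np.arange(n)
    inhibition = four_pl(concs, ec50, hill)
    sd = SD_POS - (SD_POS - SD_NEG) * inhibition / 100.0
    if noise_sd:
        sd = sd + (rng or np.random.default_rng(0)).normal(0, noise_sd, n)
    points = [(float(c), float(s), "pass") for c, s in zip(concs, sd)]
    return DoseResponseCurve(sample_id=sample_id, points=points,
                             sd_pos=SD_POS, sd_neg=SD_NEG)


class TestPercentInhibition:
    def test_anchors_and_linearity(self):
        assert percent_inhibition(SD_POS, SD_POS, SD_NEG) == pytest.approx(0.0)
        assert percent_inhibition(SD_NEG, SD_POS, SD_NEG) == pytest.approx(100.0)
        mid = (SD_POS + SD_NEG) / 2
        assert percent_inhibition(mid, SD_POS, SD_NEG) == pytest.approx(50.0)

    def test_control_failure_raises(self):
        with pytest.raises(ControlFailureError):
            percent_inhibition(2000.0, 1500.0, 1600.0)


class TestFitEC50:
    def test_noiseless_self_consistency(self):
        fit = fit_ec50(make_curve(ec50=50.0, hill=1.0))
        assert fit.status == "determinable"
        assert fit.ec50 == pytest.approx(50.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)

    @pytest.mark.parametrize("hill", [0.7, 1.5, 2.5])
    def test_recovers_hill_slopes(self, hill):
        fit = fit_ec50(make_curve(ec50=20.0, hill=hill))
        assert fit.ec50 == pytest.approx(20.0, rel=1e-4)
        assert fit.hill == pytest.approx(hill, rel=1e-3)

    def test_agrees_with_grid_search_oracle_on_noisy_curves(self):
        """Independent oracle: dense log-grid minimisation of the same
        least-squares residual, no derivative-based optimisation."""
        rng = np.random.default_rng(7)
        log_grid = np.linspace(np.log10(0.05), np.log10(6000), 2500)
        hill_grid = np.linspace(0.3, 5.0, 120)
        n_checked = 0
        for _ in range(50):
            true_e = float(10 ** rng.uniform(0.5, 2.3))
            curve = make_curve(ec50=true_e, hill=1.0, noise_sd=40.0, rng=rng)
            fit = fit_ec50(curve)
            if fit.status != "determinable":
                continue
            pts = curve.usable_points()
            conc = pts[:, 0]
            y = percent_inhibition(pts[:, 1], curve.sd_pos, curve.sd_neg)
            # broadcast residuals over the (ec50, hill) grid in one shot
            e = (10.0 ** log_grid)[:, None, None]
            h = hill_grid[None, :, None]
            c = conc[None, None, :]
            pred = 100.0 * c**h / (e**h + c**h)
            sse = ((pred - y[None, None, :]) ** 2).sum(axis=-1)
            i, _ = np.unravel_index(np.argmin(sse), sse.shape)
            oracle_e = 10.0 ** log_grid[i]
            if conc.min() <= oracle_e <= conc.max():
                assert fit.ec50 == pytest.approx(oracle_e, rel=0.01)
                n_checked += 1
        assert n_checked >= 30

    def test_reference_inhibitor_curve_brackets_ec50(self):
        # inhibition seen at 300 and 60 µM but not 12 µM -> EC50 in (12, 60)
        concs = [300.0, 60.0, 12.0, 2.4, 0.48]
        inhibition = [95.0, 75.0, 30.0, 8.0, 1.0]
        sd = [SD_POS - (SD_POS - SD_NEG) * i / 100 for i in inhibition]
        curve = DoseResponseCurve("RA", [(c, s, "pass") for c, s in zip(concs, sd)],
                                  sd_pos=SD_POS, sd_neg=SD_NEG)
        fit = fit_ec50(curve)
        assert fit.status == "determinable"
        assert 12.0 < fit.ec50 < 60.0

    def test_not_active_when_inhibition_below_half(self):
        fit = fit_ec50(make_curve(ec50=1e5))  # EC50 far above tested range
        assert fit.status == "not_active"
        assert fit.ec50 is None

    def test_below_range_when_even_lowest_dose_inhibits(self):
        fit = fit_ec50(make_curve(ec50=0.001))
        assert fit.status == "below_range"
        assert fit.ec50 is None

    def test_insufficient_points_raises(self):
        curve = make_curve(n=8)
        curve.points = curve.points[:3]
        curve.points[0] = (curve.points[0][0], curve.points[0][1], "fail_bright")
        with pytest.raises(InsufficientDataError):
            fit_ec50(curve)

    def test_qc_flagged_points_excluded_by_default(self):
        curve = make_curve(ec50=50.0)
        # corrupt one point but flag it: fit should ignore it entirely
        conc, _, _ = curve.points[2]
        curve.points[2] = (conc, 9999.0, "fail_bright")
        fit = fit_ec50(curve)
        assert fit.ec50 == pytest.approx(50.0, rel=1e-6)

    def test_invariant_to_uniform_sd_rescaling(self):
        curve = make_curve(ec50=35.0, noise_sd=30.0, rng=np.random.default_rng(3))
        scaled = DoseResponseCurve(
            sample_id="S",
            points=[(c, s * 3.7, v) for c, s, v in curve.points],
            sd_pos=curve.sd_pos * 3.7, sd_neg=curve.sd_neg * 3.7,
        )
        assert fit_ec50(scaled).ec50 == pytest.approx(fit_ec50(curve).ec50, rel=1e-6)

    def test_interpolation_agrees_with_four_pl_on_clean_curves(self):
        for ec50 in (5.0, 30.0, 120.0):
            curve = make_curve(ec50=ec50, hill=1.0)
            a = fit_ec50(curve, method="fourPL").ec50
            b = fit_ec50(curve, method="interpolation").ec50
            assert b == pytest.approx(a, rel=0.10)


class TestClassifyActivity:
    @pytest.mark.parametrize(
        "ec50, tier",
        [
            (0.012, "high_red"),
            (EXTRACT_TIERS[0], "high_red"),          # boundary closed on active side
            (EXTRACT_TIERS[0] + 1e-9, "active_yellow"),
            (0.03, "active_yellow"),
            (EXTRACT_TIERS[1], "active_yellow"),
            (EXTRACT_TIERS[2], "listed"),
            (0.2, "inactive"),
            (None, "inactive"),
        ],
    )
    def test_extract_tiers(self, ec50, tier):
        assert classify_activity(ec50, "extract") == tier

    @pytest.mark.parametrize(
        "ec50, tier",
        [(150.0, "active"), (COMPOUND_CUT, "active"), (201.0, "inactive"),
         (None, "inactive")],
    )
    def test_compound_cut(self, ec50, tier):
        assert classify_activity(ec50, "compound") == tier

    def test_not_active_fit_is_inactive(self):
        fit = fit_ec50(make_curve(ec50=1e5))
        assert classify_activity(fit, "extract") == "inactive"

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_activity(0.01, "metabolite")


class TestSummarizeReplicates:
    def test_mean_and_sample_sd(self):
        s = summarize_replicates([1.0, 2.0, 3.0])
        assert (s.n, s.mean_ec50, s.sd_ec50) == (3, 2.0, 1.0)

    def test_single_value(self):
        s = summarize_replicates([26.9])
        assert s.n == 1 and s.mean_ec50 == 26.9 and np.isnan(s.sd_ec50)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_replicates([])

    def test_replicate_recovery_at_reference_activity(self):
        """61 noisy replicate fits at a 26.9 µM truth recover the mean
        within 15%."""
        rng = np.random.default_rng(61)
        ec50s = []
        for i in range(61):
            fit = fit_ec50(make_curve(ec50=26.9, noise_sd=0.10 * (SD_POS - SD_NEG),
                                      rng=rng, sample_id=f"rep{i}"))
            if fit.status == "determinable":
                ec50s.append(fit.ec50)
        summary = summarize_replicates(ec50s)
        assert summary.n >= 55
        assert summary.mean_ec50 == pytest.approx(26.9, rel=0.15)


class TestScreenLibrary:
    def _table(self):
        return pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "ec50": [0.01, 0.09, np.nan],
            "status": ["determinable", "determinable", "not_active"],
        })

    def test_ranking_and_tier_counts(self):
        ranked, counts, _ = screen_library(self._table())
        assert list(ranked["rank"]) == [1, 2, 3]
        assert list(ranked["sample_id"]) == ["a", "b", "c"]
        assert counts == {"high_red": 1, "active_yellow": 0, "listed": 1,
                          "inactive": 1}

    def test_group_fraction(self):
        df = self._table()
        groups = {"a": "rosids", "b": "rosids", "c": "monocots"}
        _, _, frac = screen_library(df, group_labels=groups)
        assert frac["rosids"] == pytest.approx(0.5)
        assert frac["monocots"] == 0.0

    def test_ranking_invariant_to_input_order(self, rng):
        df = self._table()
        shuffled = df.sample(frac=1, random_state=5).reset_index(drop=True)
        a, _, _ = screen_library(df)
        b, _, _ = screen_library(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_sample_rejected(self):
        df = self._table()
        df.loc[2, "sample_id"] = "a"
        with pytest.raises(ValueError, match="duplicate"):
            screen_library(df)

    def test_tier_counts_helper(self):
        counts = tier_counts([0.01, 0.03, 0.07, 0.5, None], "extract")
        assert counts == {"high_red": 1, "active_yellow": 1, "listed": 1,
                          "inactive": 2}
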