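import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deltarad.stats_model import feature_auc
from deltarad.synthetic_cohort import (
    CohortConfig,
    DecayParams,
    regression_trajectory,
    simulate_cohort,
    simulate_labels,
    summarize_cohort,
)


class TestRegressionTrajectory:
    def test_no_decay_constant(self):
        assert regression_trajectory(1000.0, [0, 0, 0], 3) == 1000.0

    def test_closed_form_half_decay(self):
        assert regression_trajectory(1000.0, [0.5, 0.5, 0.5], 2) == pytest.approx(250.0)

    @given(
        v0=st.floats(min_value=1.0, max_value=1e5),
        decay=st.lists(st.floats(min_value=0.0, max_value=0.99), min_size=1, max_size=6),
    )
    @settings(max_examples=50)
    def test_monotone_non_increasing(self, v0, decay):
        vols = [regression_trajectory(v0, decay, t) for t in range(len(decay) + 1)]
        assert all(b <= a for a, b in zip(vols, vols[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            regression_trajectory(-1.0, [0.1], 1)
        with pytest.raises(ValueError):
            regression_trajectory(100.0, [1.5], 1)


class TestConfigValidation:
    def test_bad_values(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=1)
        with pytest.raises(ValueError):
            CohortConfig(event_prevalence=0.0)
        with pytest.raises(ValueError):
            CohortConfig(n_timepoints=1)
        with pytest.raises(ValueError):
            CohortConfig(voxel_spacing=(1.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            CohortConfig(signal_timepoint=6)

    def test_bed_levels_default(self):
        assert CohortConfig().bed_levels() == [0.0, 13.0, 26.0, 40.0, 54.0, 67.0]


class TestDeterminism:
    def test_identical_config_bit_identical_cohort(self):
        cfg = CohortConfig(n_patients=3, rng_seed=5)
        s1, r1 = simulate_cohort(cfg)
        s2, r2 = simulate_cohort(cfg)
        for a, b in zip(s1, s2):
            for va, vb in zip(a.volumes, b.volumes):
                np.testing.assert_array_equal(va, vb)
            for ma, mb in zip(a.masks, b.masks):
                np.testing.assert_array_equal(ma, mb)
        assert [r.outcome_2ydfs for r in r1] == [r.outcome_2ydfs for r in r2]

    def test_per_patient_streams_are_prefix_stable(self):
        # growing the cohort must not reshuffle earlier patients' imaging
        s4, _ = simulate_cohort(CohortConfig(n_patients=4, rng_seed=7))
        s6, _ = simulate_cohort(CohortConfig(n_patients=6, rng_seed=7))
        for a, b in zip(s4, s6):
            for ma, mb in zip(a.masks, b.masks):
                np.testing.assert_array_equal(ma, mb)

    def test_labels_match_full_simulation(self):
        cfg = CohortConfig(n_patients=5, rng_seed=3)
        _, r_full = simulate_cohort(cfg)
        r_fast, _ = simulate_labels(cfg)
        assert [r.outcome_2ydfs for r in r_full] == [r.outcome_2ydfs for r in r_fast]


class TestSeriesStructure:
    def test_series_invariants(self, small_cohort):
        _, series, _ = small_cohort
        for s in series:
            assert s.n_timepoints == 6
            assert all(m.any() for m in s.masks)
            assert np.all(np.diff(s.bed_levels) > 0)

    def test_masks_shrink_on_average(self, small_cohort):
        _, series, _ = small_cohort
        for s in series:
            vols = s.mask_volumes_mm3()
            assert vols[-1] < vols[0]

    def test_clamped_mask_flagged(self):
        # enough aggressive-decay timepoints to shrink the ROI below one voxel
        cfg = CohortConfig(
            n_patients=2,
            rng_seed=0,
            n_timepoints=12,
            image_shape=(24, 24, 24),
            responder_decay=DecayParams(base=0.69, noise_sd=0.0, signal_gain=0.0, post_noise_sd=0.0),
        )
        with pytest.warns(UserWarning, match="clamped"):
            series, _ = simulate_cohort(cfg)
        assert all(m.any() for s in series for m in s.masks)


class TestStatisticalStructure:
    def test_prevalence_calibration(self):
        fracs = []
        for seed in range(50):
            recs, _ = simulate_labels(
                CohortConfig(n_patients=200, event_prevalence=1 / 6, rng_seed=seed)
            )
            fracs.append(np.mean([1 - r.outcome_2ydfs for r in recs]))
        assert abs(np.mean(fracs) - 1 / 6) < 0.03

    def test_zero_effect_null_auc(self):
        aucs = []
        for seed in range(15):
            recs, _ = simulate_labels(
                CohortConfig(n_patients=200, effect_size=0.0, rng_seed=seed)
            )
            pred = np.array([r.truth_predictor for r in recs])
            event = np.array([1 - r.outcome_2ydfs for r in recs], dtype=bool)
            aucs.append(feature_auc(pred, event).raw)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_signal_localized_at_timepoint_4(self):
        # point-biserial association of outcome with the analytic delta-AV
        # must peak at the configured signal timepoint
        corr_by_tp = np.zeros(5)
        for seed in range(12):
            recs, truth = simulate_labels(
                CohortConfig(n_patients=150, event_prevalence=0.3, rng_seed=seed)
            )
            event = np.array([1 - r.outcome_2ydfs for r in recs], dtype=float)
            for k in range(1, 6):
                corr_by_tp[k - 1] += np.corrcoef(
                    truth[f"log_delta_av_t{k}"], event
                )[0, 1]
        assert np.argmax(np.abs(corr_by_tp)) == 3  # t4

    def test_expected_event_count_48_patients(self):
        cfg = CohortConfig(n_patients=48, event_prevalence=1 / 6, rng_seed=1)
        recs, _ = simulate_labels(cfg)
        n_events = sum(1 - r.outcome_2ydfs for r in recs)
        # expectation is 8; allow binomial spread
        assert 2 <= n_events <= 15


class TestSummarizeCohort:
    def _records(self, n, n_events, n_cr=0):
        recs, _ = simulate_labels(CohortConfig(n_patients=n, rng_seed=0))
        for i, r in enumerate(recs):
            r.outcome_2ydfs = 0 if i < n_events else 1
            r.complete_response = 1 if i < n_cr else 0
        return recs

    def test_event_percentage_printed(self):
        summary = summarize_cohort(self._records(48, 8))
        row = summary[(summary.variable == "2yDFS") & (summary.level == "No")]
        assert row["n"].item() == 8
        assert row["percent"].item() == 16.7

    def test_complete_response_percentage(self):
        summary = summarize_cohort(self._records(48, 8, n_cr=16))
        row = summary[(summary.variable == "pCR/cCR") & (summary.level == "Yes")]
        assert row["n"].item() == 16
        assert row["percent"].item() == 33.3

    def test_single_record_100_percent(self):
        recs = self._records(2, 0)[:1]
        summary = summarize_cohort(recs)
        row = summary[(summary.variable == "2yDFS") & (summary.level == "Yes")]
        assert row["percent"].item() == 100.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_continuous_rows_have_median_range(self):
        summary = summarize_cohort(self._records(10, 2))
        age = summary[summary.variable == "Age"]
        assert "(" in age["summary"].item()
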