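"""FIR/event design construction and OLS fitting."""

import numpy as np
import pytest

from transrev import glm_fir


class TestFirDesign:
    def test_single_event_unmodulated(self):
        d = glm_fir.build_fir_design(np.array([10.0]), None, n_scans=30, tr=2.0,
                                     add_constant=False)
        assert d.matrix.shape == (30, 9)
        for b in range(9):
            col = d.matrix[:, b]
            assert col.sum() == 1.0
            assert col[5 + b] == 1.0

    def test_constant_modulator_centers_to_zero(self):
        d = glm_fir.build_fir_design(
            np.array([4.0, 20.0, 40.0]), {"m": np.array([2.0, 2.0, 2.0])}, n_scans=40, tr=2.0
        )
        cols = d.column_index(kind="fir", modulator="m")
        assert np.allclose(d.matrix[:, cols], 0.0)

    def test_column_counting_rule(self):
        # 3 events, 2 modulators, 2 nuisance: 9*(1+2) + 2 (+ constant)
        d = glm_fir.build_fir_design(
            np.array([4.0, 20.0, 40.0]),
            {"a": np.arange(3.0), "b": np.ones(3) * 2},
            n_scans=40,
            tr=2.0,
            nuisance={"n1": np.zeros(40), "n2": np.arange(40.0)},
        )
        assert d.matrix.shape[1] == 9 * 3 + 2 + 1

    def test_event_past_run_end_rejected(self):
        with pytest.raises(ValueError, match="past run end"):
            glm_fir.build_fir_design(np.array([4.0, 100.0]), None, n_scans=30, tr=2.0)

    def test_nuisance_length_checked(self):
        with pytest.raises(ValueError, match="n_scans"):
            glm_fir.build_fir_design(np.array([4.0]), None, n_scans=30, tr=2.0,
                                     nuisance={"x": np.zeros(10)})

    def test_nan_modulator_contributes_nothing(self):
        vals = np.array([1.0, np.nan, 3.0])
        d = glm_fir.build_fir_design(np.array([4.0, 20.0, 40.0]), {"m": vals}, n_scans=40, tr=2.0)
        cols = d.column_index(kind="fir", modulator="m", bin=1)
        col = d.matrix[:, cols[0]]
        assert col[10] == 0.0  # the NaN event's scan
        assert col[2] == pytest.approx(1.0 - 2.0)  # centered over defined values

    def test_metadata_round_trips(self):
        d = glm_fir.build_fir_design(np.array([4.0]), {"m": np.array([1.0])}, n_scans=30, tr=2.0)
        assert len(d.column_index(kind="fir", modulator="m")) == 9
        assert len(d.column_index(kind="constant")) == 1


class TestEventDesign:
    def _events(self, n):
        return [
            {"onset": 6.0 + 14 * t, "duration": 4.0, "name": f"trial_{t:03d}"} for t in range(n)
        ]

    def test_single_trial_column_count(self):
        evs = self._events(10) + [{"onset": 11.0 + 14 * t, "duration": 0.0, "name": "us"}
                                  for t in range(10)]
        d = glm_fir.build_event_design(evs, n_scans=90, tr=2.0,
                                       nuisance={"sniff": np.zeros(90)})
        assert d.matrix.shape[1] == 10 + 1 + 1 + 1  # trials + us + nuisance + constant

    def test_zero_duration_is_impulse(self):
        d = glm_fir.build_event_design([{"onset": 10.0, "duration": 0.0, "name": "x"}],
                                       n_scans=30, tr=2.0, add_constant=False)
        col = d.matrix[:, 0]
        assert col[:5].sum() == 0.0
        assert col.max() > 0

    def test_duplicate_events_rejected(self):
        evs = [{"onset": 10.0, "duration": 1.0, "name": "x"}] * 2
        with pytest.raises(ValueError, match="duplicate"):
            glm_fir.build_event_design(evs, n_scans=30, tr=2.0)


class TestOls:
    def test_exact_recovery_without_noise(self, rng):
        d = glm_fir.build_fir_design(
            np.array([4.0, 30.0, 60.0]), {"m": np.array([0.2, -1.0, 0.8])}, n_scans=50, tr=2.0
        )
        beta_true = rng.standard_normal((d.matrix.shape[1], 3))
        data = (d.matrix @ beta_true).T
        fit = glm_fir.fit_ols(data, d)
        assert np.allclose(fit.betas, beta_true, atol=1e-8)
        assert not fit.rank_deficient

    def test_all_nan_voxel_flagged(self):
        d = glm_fir.build_fir_design(np.array([4.0]), None, n_scans=30, tr=2.0)
        data = np.zeros((2, 30))
        data[1] = np.nan
        fit = glm_fir.fit_ols(data, d)
        assert list(fit.excluded_voxels) == [1]
        assert np.isnan(fit.betas[:, 1]).all()

    def test_time_length_checked(self):
        d = glm_fir.build_fir_design(np.array([4.0]), None, n_scans=30, tr=2.0)
        with pytest.raises(ValueError, match="time points"):
            glm_fir.fit_ols(np.zeros((2, 29)), d)

    def test_vif_reported_finite(self):
        d = glm_fir.build_fir_design(
            np.array([4.0, 20.0, 40.0]), {"a": np.array([1.0, 2.0, 3.0])}, n_scans=40, tr=2.0
        )
        v = d.vif()
        assert np.isfinite(v[np.array([m["kind"] == "fir" for m in d.columns])]).all()


class TestBinAverage:
    def _fit(self):
        d = glm_fir.build_fir_design(np.array([0.0]), {"m": np.array([1.0])}, n_scans=20, tr=2.0,
                                     add_constant=False)
        fit = glm_fir.fit_ols(np.zeros((1, 20)), d)
        # plant known bin betas for the unmodulated set
        for b, val in zip((3, 4, 5), (1.0, 2.0, 3.0)):
            fit.betas[d.column_index(kind="fir", name="us", bin=b, modulator=None)[0], 0] = val
        return fit

    def test_mean_of_bins_3_4_5(self):
        assert glm_fir.bin_average_contrast(self._fit(), None)[0] == pytest.approx(2.0)

    def test_single_bin(self):
        assert glm_fir.bin_average_contrast(self._fit(), None, bins=(3,))[0] == pytest.approx(1.0)

    def test_missing_modulator_rejected(self):
        with pytest.raises(ValueError, match="no FIR column"):
            glm_fir.bin_average_contrast(self._fit(), "nope")

    def test_fir_kernel_normalised_at_peak_bins(self):
        k = glm_fir.fir_hrf_kernel(tr=2.0)
        assert np.mean(k[[2, 3, 4]]) == pytest.approx(1.0)
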