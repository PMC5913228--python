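"""Template-correlation MVPA: Fisher z, templates, similarity, searchlight."""

import numpy as np
import pytest

from transrev import pattern_analysis as pa
from transrev.task_design import enumerate_states, state_relation


class TestFisherZ:
    def test_fixed_point_at_zero(self):
        assert pa.fisher_z(0.0) == 0.0

    def test_printed_formula_value(self):
        assert pa.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 20)
        assert np.allclose(pa.fisher_z(-r), -pa.fisher_z(r))

    def test_unit_r_requires_clipping(self):
        with pytest.raises(ValueError):
            pa.fisher_z(1.0, clip=False)
        assert np.isfinite(pa.fisher_z(1.0))  # clipped path


class TestTemplates:
    def _patterns(self, rng, n_vox=30):
        pats = rng.standard_normal((8, n_vox))
        states = np.repeat(np.arange(4), 2)
        return pats, states

    def test_identical_patterns_decorrelate_to_zero(self):
        pats = np.ones((8, 10))
        states = np.repeat(np.arange(4), 2)
        t = pa.build_templates(pats, states)
        assert np.allclose(t, 0.0)

    def test_per_voxel_sum_is_zero(self, rng):
        pats, states = self._patterns(rng)
        t = pa.build_templates(pats, states)
        assert np.allclose(t.sum(axis=0), 0.0, atol=1e-10)

    def test_missing_state_rejected(self, rng):
        pats, states = self._patterns(rng)
        with pytest.raises(ValueError, match="state 3"):
            pa.build_templates(pats[:6], states[:6])

    def test_orthogonal_patterns_stay_orthogonal_up_to_mean_removal(self):
        # planted orthonormal patterns: after rank-1 mean removal the Gram
        # matrix is I - (1/4) J, as linear algebra dictates
        base = np.eye(4, 40)
        states = np.arange(4)
        t = pa.build_templates(base, states)
        gram = t @ t.T
        expected = np.eye(4) - np.full((4, 4), 0.25)
        assert np.allclose(gram, expected, atol=1e-12)


class TestTrialSimilarity:
    def _templates(self, rng):
        return pa.build_templates(rng.standard_normal((8, 50)), np.repeat(np.arange(4), 2))

    def test_self_similarity_is_largest(self, rng):
        t = self._templates(rng)
        out = pa.trial_similarity(t[2], t, trial_state_id=2)
        assert out["by_label"]["SISV"] == max(out["z_state"])

    def test_labels_each_occur_once(self, rng):
        t = self._templates(rng)
        for state in range(4):
            out = pa.trial_similarity(rng.standard_normal(50), t, state)
            assert sorted(out["labels"]) == ["DIDV", "DISV", "SIDV", "SISV"]

    def test_orthogonal_pattern_near_zero(self, rng):
        t = self._templates(rng)
        test = rng.standard_normal(50) * 1e-8 + 5.0
        test[0] += 1e-6  # non-constant but uncorrelated
        out = pa.trial_similarity(test, t, 0)
        assert np.all(np.abs(out["z_state"]) < 0.9)

    def test_zero_variance_pattern_rejected(self, rng):
        t = self._templates(rng)
        with pytest.raises(ValueError, match="zero-variance"):
            pa.trial_similarity(np.ones(50), t, 0)

    def test_identity_coded_pattern_ordering(self, rng):
        # templates built from identity-only coding: same-identity templates
        # correlate equally, different-identity equally less
        ident = rng.standard_normal((2, 60))
        pats = np.array([ident[0], ident[0], ident[1], ident[1]]) + 0.1 * rng.standard_normal((4, 60))
        t = pa.build_templates(pats, np.arange(4))
        out = pa.trial_similarity(ident[0], t, trial_state_id=0)
        z = out["by_label"]
        assert z["SISV"] == pytest.approx(z["SIDV"], abs=0.15)
        assert z["DISV"] == pytest.approx(z["DIDV"], abs=0.15)
        assert min(z["SISV"], z["SIDV"]) > max(z["DISV"], z["DIDV"]) + 0.5


class TestFoldStructure:
    def test_fold_symmetry_templates_ignore_run_order(self, rng):
        pats1, pats2 = rng.standard_normal((2, 8, 40))
        states = np.repeat(np.arange(4), 2)
        t_ab = pa.build_templates(np.concatenate([pats1, pats2]), np.concatenate([states, states]))
        t_ba = pa.build_templates(np.concatenate([pats2, pats1]), np.concatenate([states, states]))
        assert np.allclose(t_ab, t_ba)

    def test_sphere_offsets_radius3(self):
        off = pa.sphere_offsets(3.0)
        assert off.shape[0] == 123  # Euclidean ball of radius 3 on the voxel grid
        assert (off == 0).all(axis=1).sum() == 1


class TestSearchlight:
    def test_isolated_voxel_skipped_and_planted_contrast_localises(self, tiny_neural_cohort):
        _, subjects, _ = tiny_neural_cohort
        s = subjects[0]
        # degenerate mask: single voxel sphere has < 10 voxels
        lone = np.zeros_like(s.masks["brain"])
        lone[8, 8, 8] = True
        res_deg = pa.searchlight_run(s, radius=3.0, mask=lone)
        assert (8, 8, 8) in res_deg.meta["skipped_centers"]
        assert np.isnan(res_deg["SISV"][8, 8, 8])

    def test_roi_similarity_ordering_on_planted_identity_code(self, tiny_neural_cohort):
        _, subjects, _ = tiny_neural_cohort
        means = {lab: [] for lab in pa.LABELS}
        for s in subjects:
            table = pa.roi_similarity_table(s, np.argwhere(s.masks["ofc"]))
            # every trial carries exactly one z per relation label
            for lab in pa.LABELS:
                assert table[f"z_{lab}"].notna().all()
                means[lab].append(table[f"z_{lab}"].mean())
        sisv, sidv = np.mean(means["SISV"]), np.mean(means["SIDV"])
        disv, didv = np.mean(means["DISV"]), np.mean(means["DIDV"])
        assert min(sisv, sidv) > max(disv, didv)

    def test_label_contrast_identities(self, rng):
        m = {"SISV": rng.standard_normal((4, 4, 4)), "DISV": rng.standard_normal((4, 4, 4))}
        assert np.allclose(pa.label_contrast(m, "SISV", "SISV"), 0.0)
        with pytest.raises(ValueError):
            pa.label_contrast(m, "SISV", "SIDV")
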