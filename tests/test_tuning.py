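"""Functional-index tests: vector-sum selectivity, paired indices, chirp
quantities, cluster SI table and composition analysis."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import spearmanr

from colliclust import tuning as tn
from colliclust import preprocess as pp
from conftest import kept_dffs


class TestDsiOsi:
    def test_single_direction_fully_selective(self):
        R = np.zeros(12)
        R[3] = 1.0
        dsi, osi = tn.dsi_osi(R)
        assert dsi == pytest.approx(1.0)
        assert osi == pytest.approx(1.0)

    def test_uniform_responses_cancel(self):
        dsi, osi = tn.dsi_osi(np.ones(12))
        assert dsi == pytest.approx(0.0, abs=1e-12)
        assert osi == pytest.approx(0.0, abs=1e-12)

    def test_one_bump_over_uniform_is_one_thirteenth(self):
        # complex-sum oracle: 12 evenly spaced unit vectors sum to zero, so
        # only the extra response of 1 contributes: DSI = 1 / 13
        R = np.array([2.0] + [1.0] * 11)
        dsi, osi = tn.dsi_osi(R)
        assert dsi == pytest.approx(1.0 / 13.0)
        assert osi == pytest.approx(1.0 / 13.0)

    @given(scale=hst.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        R = rng.uniform(0.1, 2.0, 12)
        assert tn.dsi_osi(R * scale) == pytest.approx(tn.dsi_osi(R))

    def test_all_zero_flagged(self):
        dsi, osi = tn.dsi_osi(np.zeros(12))
        assert np.isnan(dsi) and np.isnan(osi)

    def test_negative_responses_rectified(self):
        with pytest.warns(UserWarning, match="rectified"):
            tn.dsi_osi(np.array([1.0] * 11 + [-0.5]))


class TestPairedIndex:
    @pytest.mark.parametrize("a,b,expected", [
        (1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (3.0, 1.0, 0.5),
    ])
    def test_values(self, a, b, expected):
        assert tn.paired_index(a, b) == pytest.approx(expected)

    def test_zero_sum_flagged(self):
        assert np.isnan(tn.paired_index(0.0, 0.0))

    @given(a=hst.floats(min_value=0.0, max_value=10.0),
           b=hst.floats(min_value=0.001, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_antisymmetry(self, a, b):
        assert tn.paired_index(a, b) == pytest.approx(-tn.paired_index(b, a))


class TestChirp:
    def make_schedule(self):
        from colliclust.synthgen import default_battery

        return default_battery(4.8)["chirp"]

    def test_sustained_unit_response_pfsi_zero(self):
        sched = self.make_schedule()
        fr = 4.8
        n_t = int(round(sched["duration"] * fr))
        trace = np.zeros(n_t)
        segs = {s["name"]: s for s in sched["segments"]}
        w = slice(int(round(segs["white"]["t0"] * fr)),
                  int(round(segs["white"]["t1"] * fr)))
        trace[w] = 1.0  # perfectly sustained during the white flash
        q = tn.chirp_derived(trace, sched, fr)
        pfsi = tn.paired_index(q["R_peak"][0], q["R_final"][0])
        assert pfsi == pytest.approx(0.0)

    def test_impulse_at_white_onset_csi_one(self):
        sched = self.make_schedule()
        fr = 4.8
        n_t = int(round(sched["duration"] * fr))
        trace = np.zeros(n_t)
        segs = {s["name"]: s for s in sched["segments"]}
        trace[int(round(segs["white"]["t0"] * fr)) + 1] = 2.0
        q = tn.chirp_derived(trace, sched, fr)
        assert q["R_On"][0] > 0 and q["R_Off"][0] == 0
        assert tn.paired_index(q["R_On"][0], q["R_Off"][0]) == 1.0

    def test_low_pass_neuron_positive_fsi(self, tiny_session, tiny_dffs):
        gt = tiny_session.ground_truth.iloc[tiny_dffs.kept].reset_index()
        prof = tn.compute_profiles(kept_dffs(tiny_dffs))
        low_pass = gt.fsi_true > 0.3
        assert (prof.FSI[low_pass.to_numpy()] > 0).mean() > 0.9


class TestBssRtm:
    def test_argmax_size(self):
        q = tn.bss_rtm(np.array([[0.0, 0.0, 5.0, 1.0, 0.0]]),
                       np.array([1.0]))
        assert q["BSS"][0] == 8.0

    def test_tie_takes_smallest_diameter(self):
        q = tn.bss_rtm(np.array([[3.0, 3.0, 1.0, 0.0, 0.0]]),
                       np.array([1.0]))
        assert q["BSS"][0] == 2.0

    def test_rtm_keeps_sign(self):
        # motion-suppressed: largest-magnitude modulation is negative
        tm = np.zeros((1, 40, 3))
        tm[0, 20, :] = -0.4
        tm[0, 5, :] = 0.2
        sched = {"segments": [{"t0": 0.5, "t1": 8.0}]}
        rtm = tn.bar_rtm(tm, sched, 4.8)
        assert rtm[0] == pytest.approx(-0.4)


class TestRsi:
    def test_reference_values(self):
        prof = dict(tn.RSI_REFERENCES)
        out = tn.rsi(prof)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_dsi_at_reference(self):
        out = tn.rsi({"DSI": 0.15})
        assert out["DSI"] == pytest.approx(0.0)

    def test_rfs_offset(self):
        out = tn.rsi({"RFS": 100.0})
        assert out["RFS"] == pytest.approx(10.0)


class TestClusterSiTable:
    def test_symmetric_values_masked(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.3, 50)])
        vals = np.concatenate([vals, -vals])  # exactly symmetric about 0
        prof = pd.DataFrame({"DSI": vals + tn.RSI_REFERENCES["DSI"]})
        means, norm, mask = tn.cluster_si_table(prof, np.zeros(100, int))
        assert mask.loc[0, "DSI"]

    def test_degenerate_constant_cluster_masked(self):
        prof = pd.DataFrame({"DSI": np.full(10, 0.45)})
        means, norm, mask = tn.cluster_si_table(prof, np.zeros(10, int))
        assert mask.loc[0, "DSI"]
        assert means.loc[0, "DSI"] == pytest.approx(0.30)

    def test_planted_high_dsi_cluster_unmasked_positive(self):
        rng = np.random.default_rng(1)
        prof = pd.DataFrame({
            "DSI": np.concatenate([rng.normal(0.6, 0.05, 40),
                                   rng.normal(0.15, 0.02, 40)]),
        })
        labels = np.repeat([0, 1], 40)
        means, norm, mask = tn.cluster_si_table(prof, labels)
        assert not mask.loc[0, "DSI"]
        assert means.loc[0, "DSI"] > 0.3
        assert abs(norm.loc[0, "DSI"]) == pytest.approx(1.0)


class TestComposition:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        contrib, cum, _ = tn.composition_analysis(
            rng.integers(0, 4, 200), rng.integers(0, 6, 200), n_perm=50)
        np.testing.assert_allclose(contrib.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(cum.iloc[:, -1], 100.0, atol=1e-6)

    def test_perfect_nesting_minimal_pvalue(self):
        labels = np.repeat(np.arange(4), 30)
        _, _, ptab = tn.composition_analysis(labels, labels.copy(),
                                             n_perm=200, seed=0)
        assert (ptab.p_perm <= 1.0 / 201.0 + 1e-12).all()

    def test_independent_labels_not_flagged(self):
        rng = np.random.default_rng(3)
        cl = rng.integers(0, 4, 400)
        ty = rng.integers(0, 5, 400)
        _, _, ptab = tn.composition_analysis(cl, ty, n_perm=200, seed=1)
        # under independence p-values are roughly uniform
        assert ptab.p_perm.min() > 0.001
        assert 0.1 < ptab.p_perm.mean() < 0.95

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            tn.composition_analysis(np.zeros(5), np.zeros(6))


class TestParameterRecovery:
    def test_dsi_rank_correlation_at_calibration_noise(self, tiny_session,
                                                       tiny_dffs):
        gt = tiny_session.ground_truth.iloc[tiny_dffs.kept].reset_index()
        prof = tn.compute_profiles(kept_dffs(tiny_dffs))
        rho = spearmanr(prof.DSI, gt.dsi_true, nan_policy="omit").statistic
        assert rho >= 0.9

    def test_surround_suppressed_neurons(self, tiny_session, tiny_dffs):
        gt = tiny_session.ground_truth.iloc[tiny_dffs.kept].reset_index()
        prof = tn.compute_profiles(kept_dffs(tiny_dffs))
        small_pref = (gt.size_pref <= 4).to_numpy()
        if small_pref.any():
            assert (prof.BSS[small_pref] <= 8).mean() > 0.9
            assert (prof.SSI[small_pref] > 0).mean() > 0.9
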