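"""Pre-onset ERPs and the left-minus-right lateralization topography."""

import numpy as np
import pytest

from headbci import RotationEvent
from headbci.erp import ERPResult, baseline_epochs, lateralization_difference, pre_onset_erp
from headbci.montage import CHANNELS_32
from headbci.utils import substream

RATE = 128.0


class TestBaseline:
    def test_constant_epoch_baselines_to_zero(self):
        ep = np.full((4, 3, 20), 7.5)
        np.testing.assert_allclose(baseline_epochs(ep), 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ep = rng.normal(0, 1, (5, 3, 40))
        once = baseline_epochs(ep)
        twice = baseline_epochs(once)
        np.testing.assert_allclose(once, twice)

    def test_only_an_offset_is_removed(self):
        ep = np.zeros((1, 1, 10))
        ep[0, 0] = np.arange(10, dtype=float)
        out = baseline_epochs(ep, baseline_frames=3)
        np.testing.assert_allclose(out[0, 0], np.arange(10) - 1.0)  # mean of 0,1,2


class TestPreOnsetErp:
    def test_ramp_recovered_in_closed_form(self):
        # Plant an exact linear ramp from 0 at (onset - lead) to -A at onset on
        # one channel; the baselined pre-onset mean over the last `lead`
        # seconds is -A/2 relative to the flat baseline.
        lead, amp = 0.45, 20.0
        n = int(30 * RATE)
        eeg = np.zeros((2, n))
        events = [RotationEvent(t, "left", t + 0.3) for t in (5.0, 12.0, 19.0, 26.0)]
        t_axis = np.arange(n) / RATE
        for e in events:
            m = (t_axis >= e.onset - lead) & (t_axis < e.onset)
            eeg[0, m] = -amp * (t_axis[m] - (e.onset - lead)) / lead
        erp = pre_onset_erp(eeg, events, rate=RATE, channels=("A", "B"))
        assert erp.n_events == 4
        tc = erp.timecourse[0]
        in_ramp = erp.times >= -lead
        ramp_mean = tc[in_ramp].mean()
        assert ramp_mean == pytest.approx(-amp / 2, rel=0.05)
        assert np.allclose(erp.timecourse[1], 0.0)
        assert erp.window_mean[0] == pytest.approx(tc.mean())

    def test_uncovered_and_offcenter_events_skipped(self):
        eeg = np.zeros((1, int(10 * RATE)))
        events = [
            RotationEvent(0.5, "left", 0.8),                     # no 1 s pre-onset coverage
            RotationEvent(5.0, "left", 5.3, from_center=False),  # not scored
            RotationEvent(8.0, "left", 8.3),
        ]
        erp = pre_onset_erp(eeg, events, rate=RATE, channels=("A",))
        assert erp.n_events == 1
        with pytest.raises(ValueError, match="coverage"):
            pre_onset_erp(eeg, events[:1], rate=RATE, channels=("A",))

    def test_noise_erp_averages_toward_zero(self):
        rng = np.random.default_rng(1)
        n_events = 200
        eeg = rng.normal(0, 5.0, (3, int((n_events * 2 + 4) * RATE)))
        events = [RotationEvent(2.0 + 2.0 * k, "right", 2.3 + 2.0 * k) for k in range(n_events)]
        erp = pre_onset_erp(eeg, events, rate=RATE, channels=("A", "B", "C"))
        # per-point sem is ~ 5*sqrt(2)/sqrt(200); the mean ERP stays within 5 sem
        sem = 5.0 * np.sqrt(2) / np.sqrt(n_events)
        assert np.max(np.abs(erp.timecourse)) < 5 * sem


class TestLateralization:
    def _erp(self, values, n_events, channels=("A", "B")):
        ep = np.tile(np.asarray(values, dtype=float)[None, :, None], (n_events, 1, 8))
        return ERPResult(epochs=ep, times=np.arange(8) / RATE - 1.0, channels=channels, n_events=n_events)

    def test_difference_of_constant_maps(self):
        left = self._erp([-4.0, 1.0], 10)
        right = self._erp([-1.0, 4.0], 7)
        topo = lateralization_difference([(left, right)], substream(0, "t"))
        assert topo["A"] == pytest.approx(-3.0)
        assert topo["B"] == pytest.approx(-3.0)
        assert topo.n_events_per_side == [7]  # subsampled to the smaller side

    def test_swapping_sides_negates_the_map(self):
        left = self._erp([-4.0, 1.0], 9)
        right = self._erp([-1.0, 4.0], 9)
        a = lateralization_difference([(left, right)], substream(1, "t"))
        b = lateralization_difference([(right, left)], substream(1, "t"))
        np.testing.assert_allclose(a.values, -b.values)

    def test_participants_weigh_equally(self):
        p1 = (self._erp([2.0, 0.0], 100), self._erp([0.0, 0.0], 100))
        p2 = (self._erp([-4.0, 0.0], 3), self._erp([0.0, 0.0], 3))
        topo = lateralization_difference([p1, p2], substream(2, "t"))
        assert topo["A"] == pytest.approx((2.0 - 4.0) / 2)

    def test_missing_side_excluded_and_all_missing_is_an_error(self):
        good = (self._erp([1.0, 0.0], 5), self._erp([0.0, 0.0], 5))
        empty = ERPResult(epochs=np.zeros((0, 2, 8)), times=np.arange(8) / RATE, channels=("A", "B"), n_events=0)
        topo = lateralization_difference([good, (empty, good[1])], substream(3, "t"))
        assert topo.n_events_per_side == [5]
        with pytest.raises(ValueError, match="no participant"):
            lateralization_difference([(empty, empty)], substream(3, "t"))

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        topo = lateralization_difference(
            [(self._erp([1.0, -1.0], 4), self._erp([0.5, 0.5], 4))], substream(4, "t")
        )
        p = tmp_path / "topo.tsv"
        topo.write_tsv(p)
        df = pd.read_csv(p, sep="\t")
        assert list(df["electrode"]) == ["A", "B"]
        np.testing.assert_allclose(df["value"], topo.values)


def _difference_sem(pair, channels):
    """Standard error of the left-minus-right per-electrode window mean."""
    sems = {}
    for ch in channels:
        var = 0.0
        for erp in pair:
            i = list(erp.channels).index(ch)
            means = erp.epochs[:, i, :].mean(axis=1)  # per-event window mean
            var += means.var(ddof=1) / means.size
        sems[ch] = np.sqrt(var)
    return sems


class TestOnSyntheticRun:
    def test_noise_free_map_is_exactly_antisymmetric(self):
        # Without noise the left-minus-right map is fixed by the generator and
        # the (linear) filter: homologous lateral sites mirror each other and
        # posterior sites carry exactly nothing.
        from headbci import SynthConfig, generate_session, preprocess_session

        cfg = SynthConfig(block_duration=400.0, noise_sd=0.0, artifact_rate=0.0, seed=31)
        sess = generate_session(cfg)
        eeg = preprocess_session(sess.eeg, sess.eeg_rate)
        pair = tuple(
            pre_onset_erp(eeg, sess.ground_truth.events, direction=d) for d in ("left", "right")
        )
        topo = lateralization_difference([pair], substream(0, "erp-sub"))
        assert set(topo.channels) == set(CHANNELS_32)
        scale = np.max(np.abs(topo.values))
        assert scale > 0
        for a, b in (("C3", "C4"), ("FC1", "FC2"), ("F3", "F4")):
            assert abs(topo[a] + topo[b]) < 0.1 * scale  # mirror pairs cancel
            assert abs(topo[a]) > 0.5 * scale            # and are the strong sites
        for post in ("O1", "Oz", "O2", "PO3", "PO4"):
            assert topo[post] == 0.0
        assert abs(topo["Cz"]) < 0.1 * scale  # midline: ramp only, no lateral part

    def test_planted_lateralization_detectable_on_noisy_run(self, strong_run):
        _cfg, res = strong_run
        topo = lateralization_difference([res["erp_pair"]], substream(0, "erp-sub"))
        sems = _difference_sem(res["erp_pair"], ("C3", "C4", "O1", "Oz", "O2"))
        # the antisymmetric contrast (C3 - C4)/2 concentrates the planted
        # effect; its sign is fixed by the noise-free oracle above
        contrast = (topo["C3"] - topo["C4"]) / 2
        sem_contrast = np.sqrt(sems["C3"] ** 2 + sems["C4"] ** 2) / 2
        assert contrast < -2 * sem_contrast
        # posterior sites stay within sampling noise of zero
        for post in ("O1", "Oz", "O2"):
            assert abs(topo[post]) < 4 * sems[post]

    def test_no_lateralization_when_none_planted(self, nolat_runs):
        # lateralization_fraction 0: pooled left-minus-right map stays within
        # sampling noise of zero even at the lateral sites.
        pairs = [res["erp_pair"] for res in nolat_runs]
        topo = lateralization_difference(pairs, substream(1, "erp-sub"))
        for ch in ("C3", "C4", "FC1", "FC2"):
            # pooled sem over participants (equal weights)
            sem = np.sqrt(np.mean([_difference_sem(p, (ch,))[ch] ** 2 for p in pairs]) / len(pairs))
            assert abs(topo[ch]) < 4 * sem
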