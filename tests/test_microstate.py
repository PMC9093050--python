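"""GFP, peak selection, modified k-means, back-fitting, and features."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from zolpiscope import microstate as ms
from zolpiscope.io_montage import Recording, canonical_maps
from zolpiscope.synthetic import gen_microstate_eeg


def _avg_ref(data, fs=250.0, labels=None, segments=None):
    data = np.asarray(data, dtype=float)
    data = data - data.mean(axis=0, keepdims=True)
    labels = labels or [f"CH{i + 1}" for i in range(data.shape[0])]
    return Recording(data, fs, labels, segments=segments,
                     reference="common_average")


def _orthogonal_templates(k, n_ch, rng):
    q, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    t = q[:, :k].T
    t -= t.mean(axis=1, keepdims=True)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


class TestGfp:
    def test_two_channel_example(self):
        rec = _avg_ref(np.array([[1.0], [-1.0]]))
        assert ms.gfp(rec)[0] == pytest.approx(1.0)

    def test_zero_sample(self):
        rec = _avg_ref(np.zeros((4, 3)))
        assert np.all(ms.gfp(rec) == 0.0)

    def test_homogeneity(self, rng):
        data = rng.standard_normal((6, 20))
        a = ms.gfp(_avg_ref(data))
        b = ms.gfp(_avg_ref(-2.5 * data))
        assert np.allclose(b, 2.5 * a)


class TestSelectPeakMaps:
    def _peaky_recording(self, heights):
        """GFP with one strict local maximum per given height."""
        n = len(heights) * 2 + 1
        wave = np.zeros(n)
        wave[1::2] = heights
        data = np.vstack([wave, -wave])
        return Recording(data, 250.0, ["A", "B"], reference="common_average")

    def test_equal_peaks_lowest_fraction_removed(self):
        rec = self._peaky_recording(np.ones(100))
        g = ms.gfp(rec)
        maps, idx = ms.select_peak_maps(g, rec)
        # 15 dropped by the lowest-15% rule, none by the 3-SD rule
        assert idx.size == 85

    def test_outlier_removed_by_sd_rule(self):
        heights = np.ones(100)
        heights[40] = 10.0
        rec = self._peaky_recording(heights)
        g = ms.gfp(rec)
        maps, idx = ms.select_peak_maps(g, rec)
        # 100 peaks: 15 dropped by the lowest-15% rule, the outlier by 3-SD
        assert idx.size == 84
        assert g[idx].max() < 5.0

    def test_monotone_ramp_has_no_peaks(self):
        data = np.vstack([np.linspace(0, 1, 50), -np.linspace(0, 1, 50)])
        rec = Recording(data, 250.0, ["A", "B"], reference="common_average")
        with pytest.raises(ValueError, match="peaks"):
            ms.select_peak_maps(ms.gfp(rec), rec)


class TestModifiedKmeans:
    def test_noiseless_fixed_point(self, rng):
        truth = _orthogonal_templates(4, 12, rng)
        coeff = rng.choice([-2.0, -1.0, 1.0, 2.0], size=200)
        assign = rng.integers(4, size=200)
        maps = coeff[:, None] * truth[assign]
        tmpl, got, gev = ms.modified_kmeans(maps, k=4, restarts=5, seed=0)
        corr = np.abs(ms.spatial_correlation(tmpl.maps, truth))
        r, c = linear_sum_assignment(-corr)
        assert np.allclose(corr[r, c], 1.0, atol=1e-9)
        assert gev == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance(self, rng):
        truth = _orthogonal_templates(3, 10, rng)
        maps = truth[rng.integers(3, size=120)] * rng.uniform(0.5, 2.0, size=(120, 1))
        flips = rng.choice([-1.0, 1.0], size=(120, 1))
        t1, a1, g1 = ms.modified_kmeans(maps, k=3, restarts=3, seed=1)
        t2, a2, g2 = ms.modified_kmeans(maps * flips, k=3, restarts=3, seed=1)
        assert g1 == pytest.approx(g2, abs=1e-12)
        assert np.array_equal(a1, a2)

    def test_recovery_from_noisy_microstate_eeg(self):
        rec, truth = gen_microstate_eeg(k=4, snr=5.0, duration_s=40.0, seed=3)
        g = ms.gfp(rec)
        maps, _ = ms.select_peak_maps(g, rec)
        tmpl, _a, _gev = ms.modified_kmeans(maps, k=4, restarts=5, seed=0)
        corr = np.abs(ms.spatial_correlation(tmpl.maps, truth.templates))
        r, c = linear_sum_assignment(-corr)
        assert np.all(corr[r, c] > 0.95)

    def test_too_few_maps(self, rng):
        with pytest.raises(ValueError, match="at least"):
            ms.modified_kmeans(rng.standard_normal((3, 8)), k=4)


class TestGroupTemplates:
    def test_degenerate_pooling(self, rng):
        shared = _orthogonal_templates(4, 59, rng)
        recs = [ms.MicrostateTemplates(shared.copy(), list("ABCD"))
                for _ in range(3)]
        group = ms.group_templates(recs, seed=0)
        corr = np.abs(ms.spatial_correlation(group.maps, shared))
        r, c = linear_sum_assignment(-corr)
        assert np.allclose(corr[r, c], 1.0, atol=1e-9)

    def test_canonical_labelling(self, rng):
        ref_maps, ref_names = canonical_maps()
        noisy = [ms.MicrostateTemplates(
            ref_maps + 0.02 * rng.standard_normal(ref_maps.shape), list("ABCD"))
            for _ in range(3)]
        group = ms.group_templates(noisy, seed=0)
        assert group.class_names == ["A", "B", "C", "D"]
        corr = np.abs(ms.spatial_correlation(group.maps, ref_maps))
        assert np.all(np.diag(corr) > 0.95)

    def test_single_recording_rejected(self, rng):
        one = ms.MicrostateTemplates(_orthogonal_templates(4, 59, rng), list("ABCD"))
        with pytest.raises(ValueError, match="2 recordings"):
            ms.group_templates([one])


class TestBackfitSmooth:
    def test_noiseless_boundaries_exact(self):
        rec, truth = gen_microstate_eeg(k=4, snr=1e12, duration_s=20.0, seed=5)
        tmpl = ms.MicrostateTemplates(truth.templates, list("ABCD"))
        seq = ms.backfit_smooth(rec, tmpl, min_dur_ms=30.0)
        assert np.array_equal(seq.labels, truth.label_sequence)

    def test_one_sample_spur_absorbed(self, rng):
        t = _orthogonal_templates(2, 10, rng)
        cols = [t[0]] * 20 + [t[1]] + [t[0]] * 20
        rec = _avg_ref(np.array(cols).T)
        tmpl = ms.MicrostateTemplates(t, ["A", "B"])
        seq = ms.backfit_smooth(rec, tmpl, min_dur_ms=30.0)
        assert np.all(seq.labels == 0)

    def test_min_duration_floor_is_ceil(self, rng):
        # 30 ms at 250 Hz -> ceil(7.5) = 8 samples
        t = _orthogonal_templates(2, 10, rng)
        for n_b, absorbed in [(7, True), (8, False)]:
            cols = [t[0]] * 20 + [t[1]] * n_b + [t[0]] * 20
            rec = _avg_ref(np.array(cols).T)
            tmpl = ms.MicrostateTemplates(t, ["A", "B"])
            seq = ms.backfit_smooth(rec, tmpl, min_dur_ms=30.0)
            assert (1 not in seq.labels) == absorbed

    def test_truncated_flags(self, rng):
        t = _orthogonal_templates(2, 10, rng)
        cols = [t[0]] * 20 + [t[1]] * 20 + [t[0]] * 20
        rec = _avg_ref(np.array(cols).T)
        seq = ms.backfit_smooth(rec, ms.MicrostateTemplates(t, ["A", "B"]),
                                min_dur_ms=30.0)
        assert seq.truncated == [True, False, True]


def _manual_sequence(labels, fs, k, rec):
    """Build a MicrostateSequence from a label array (one continuity seg)."""
    labels = np.asarray(labels, dtype=int)
    cuts = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], cuts))
    ends = np.concatenate((cuts, [labels.size]))
    segs = [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]
    trunc = [False] * len(segs)
    trunc[0] = trunc[-1] = True
    return ms.MicrostateSequence(labels=labels, segments=segs,
                                 truncated=trunc, fs=fs, k=k)


class TestMicrostateFeatures:
    def test_mean_interval_printed_equation(self, rng):
        # class-0 segments at (0,96), (200,296), (400,496) ms; fs = 1000
        fs = 1000.0
        labels = np.ones(600, dtype=int)
        for a, b in [(0, 96), (200, 296), (400, 496)]:
            labels[a:b] = 0
        t = _orthogonal_templates(2, 10, rng)
        rec = _avg_ref(t[labels].T, fs=fs)
        seq = _manual_sequence(labels, fs, 2, rec)
        feats = ms.microstate_features(seq, ms.gfp(rec),
                                       ms.MicrostateTemplates(t, ["A", "B"]), rec)
        assert feats.mean_interval[0] == pytest.approx(104.0)

    def test_occurrence_rate(self, rng):
        # 5 interior class-0 segments in 10 s -> 0.5 / s
        fs = 100.0
        labels = np.ones(1000, dtype=int)
        for start in (100, 260, 420, 580, 740):
            labels[start:start + 60] = 0
        t = _orthogonal_templates(2, 8, rng)
        rec = _avg_ref(t[labels].T, fs=fs)
        seq = _manual_sequence(labels, fs, 2, rec)
        feats = ms.microstate_features(seq, ms.gfp(rec),
                                       ms.MicrostateTemplates(t, ["A", "B"]), rec)
        assert feats.occurrence[0] == pytest.approx(0.5)
        assert feats.mean_duration[0] == pytest.approx(600.0)

    def test_perfect_fit_gev_and_sc(self, rng):
        t = _orthogonal_templates(2, 10, rng)
        # GEV over all labelled samples: a pure class-0 recording gives 1
        labels_all = np.zeros(50, dtype=int)
        rec = _avg_ref(t[labels_all].T)
        seq = _manual_sequence(labels_all, 250.0, 2, rec)
        feats = ms.microstate_features(seq, ms.gfp(rec),
                                       ms.MicrostateTemplates(t, ["A", "B"]), rec)
        assert feats.gev[0] == pytest.approx(1.0)
        # SC_AA = 1 needs an interior (non-truncated) class-0 segment
        labels_mix = np.concatenate([np.ones(20), np.zeros(20), np.ones(20)]).astype(int)
        rec2 = _avg_ref(t[labels_mix].T)
        seq2 = _manual_sequence(labels_mix, 250.0, 2, rec2)
        feats2 = ms.microstate_features(seq2, ms.gfp(rec2),
                                        ms.MicrostateTemplates(t, ["A", "B"]), rec2)
        assert feats2.sc[0, 0] == pytest.approx(1.0)

    def test_absent_class_reported_missing(self, rng):
        t = _orthogonal_templates(3, 10, rng)
        labels = np.concatenate([np.zeros(30), np.ones(30), np.zeros(30)]).astype(int)
        rec = _avg_ref(t[labels].T)
        seq = _manual_sequence(labels, 250.0, 3, rec)
        feats = ms.microstate_features(seq, ms.gfp(rec),
                                       ms.MicrostateTemplates(t, ["A", "B", "C"]), rec)
        assert np.isnan(feats.mean_duration[2])
        assert np.isnan(feats.occurrence[2])

    def test_matches_segment_walking_oracle(self, rng):
        """Random sequence: features equal an independent oracle that walks
        the segment list."""
        fs = 250.0
        k = 3
        t = _orthogonal_templates(k, 12, rng)
        labels = rng.integers(k, size=400)
        # make maps = noisy template of the label so corr is nontrivial
        data = t[labels].T + 0.3 * rng.standard_normal((12, 400))
        rec = _avg_ref(data, fs=fs)
        seq = _manual_sequence(labels, fs, k, rec)
        gfp_values = ms.gfp(rec)
        tmpl = ms.MicrostateTemplates(t, ["A", "B", "C"])
        feats = ms.microstate_features(seq, gfp_values, tmpl, rec)

        corr = ms.spatial_correlation(rec.data.T, tmpl.maps)
        nt = [(s, e, c) for (s, e, c), tr in zip(seq.segments, seq.truncated)
              if not tr]
        total_time = labels.size / fs
        total_nt = sum(e - s for s, e, _ in nt)
        for cls in range(k):
            own = [(s, e) for s, e, c in nt if c == cls]
            durs = [e - s for s, e in own]
            assert feats.mean_duration[cls] == pytest.approx(
                np.mean(durs) / fs * 1000.0, abs=1e-9)
            assert feats.occurrence[cls] == pytest.approx(
                len(own) / total_time, abs=1e-9)
            assert feats.coverage[cls] == pytest.approx(
                sum(durs) / total_nt, abs=1e-9)
            gaps = [n_s - p_e for (p_s, p_e), (n_s, n_e) in zip(own, own[1:])]
            if gaps:
                assert feats.mean_interval[cls] == pytest.approx(
                    np.mean(gaps) / fs * 1000.0, abs=1e-9)
            samp = [i for s, e in own for i in range(s, e)]
            assert feats.mean_gfp[cls] == pytest.approx(
                gfp_values[samp].mean(), abs=1e-9)
            # GEV over all labelled samples of the class
            num = sum((gfp_values[i] * corr[i, cls]) ** 2
                      for i in range(labels.size) if labels[i] == cls)
            den = sum(gfp_values[i] ** 2 for i in range(labels.size))
            assert feats.gev[cls] == pytest.approx(num / den, abs=1e-9)
            for other in range(k):
                other_samp = [i for s, e, c in nt if c == other
                              for i in range(s, e)]
                assert feats.sc[cls, other] == pytest.approx(
                    np.mean(np.abs(corr[other_samp, cls])), abs=1e-9)
        # transition probabilities from consecutive non-truncated segments
        counts = np.zeros((k, k))
        for i in range(1, len(seq.segments) - 2):
            a, b = seq.segments[i], seq.segments[i + 1]
            counts[a[2], b[2]] += 1
        for cls in range(k):
            if counts[cls].sum() > 0:
                assert np.allclose(feats.tp[cls],
                                   counts[cls] / counts[cls].sum(), atol=1e-12)
                assert feats.tp[cls].sum() == pytest.approx(1.0)

    def test_coverage_sums_to_one(self):
        rec, _truth = gen_microstate_eeg(k=4, snr=8.0, duration_s=20.0, seed=9)
        g = ms.gfp(rec)
        maps, _ = ms.select_peak_maps(g, rec)
        tmpl, _a, _g = ms.modified_kmeans(maps, k=4, restarts=3, seed=0)
        seq = ms.backfit_smooth(rec, tmpl, 30.0)
        feats = ms.microstate_features(seq, g, tmpl, rec)
        assert feats.coverage.sum() == pytest.approx(1.0)


def test_polarity_invariance_end_to_end():
    """Flipping the sign of the whole recording changes no feature."""
    rec, _truth = gen_microstate_eeg(k=4, snr=6.0, duration_s=20.0, seed=11)
    flipped = rec.copy_with(data=-rec.data)
    out = []
    for r in (rec, flipped):
        g = ms.gfp(r)
        maps, _ = ms.select_peak_maps(g, r)
        tmpl, _a, _gev = ms.modified_kmeans(maps, k=4, restarts=3, seed=2)
        seq = ms.backfit_smooth(r, tmpl, 30.0)
        out.append(ms.microstate_features(seq, g, tmpl, r))
    a, b = out
    for field in ("gev", "mean_duration", "occurrence", "coverage",
                  "mean_interval", "mean_gfp", "sc", "tp"):
        va, vb = getattr(a, field), getattr(b, field)
        assert np.allclose(np.nan_to_num(va), np.nan_to_num(vb), atol=1e-9)
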