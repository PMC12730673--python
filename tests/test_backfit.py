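"""Back-fitting, minimum-duration smoothing, parameters, fit metrics."""

import numpy as np
import pytest

import msdual as md
from msdual.backfit import (UNASSIGNED, Segmentation, _run_lengths, backfit,
                            fit_metrics, microstate_parameters,
                            smooth_segmentation)
from msdual.clustering import TemplateSet
from msdual.io import EEGRecording
from msdual import simulate as sim


def _templates(n_ch=8, K=3, seed=0):
    rng = np.random.default_rng(seed)
    maps = rng.normal(size=(K, n_ch))
    maps -= maps.mean(axis=1, keepdims=True)
    maps /= np.sqrt(np.mean(maps**2, axis=1, keepdims=True))
    return TemplateSet(maps, labels=list(range(K)),
                       ch_names=[f"c{i}" for i in range(n_ch)])


def _recording_from_labels(templates, labels, fs=250.0, amp=5.0):
    data = amp * templates.maps[np.asarray(labels)].T
    return EEGRecording(data, fs, templates.ch_names, reference="average")


class TestBackfit:
    def test_exact_template_copies(self):
        ts = _templates()
        labels = [0, 0, 1, 2, 2, 1]
        rec = _recording_from_labels(ts, labels)
        seg = backfit(rec, ts)
        assert np.array_equal(seg.labels, labels)
        assert np.allclose(seg.correlation, 1.0)

    def test_sign_flip_invariance(self):
        ts = _templates()
        labels = [0, 1, 2, 1, 0]
        rec = _recording_from_labels(ts, labels)
        flipped = EEGRecording(-rec.data, rec.fs, rec.ch_names,
                               reference="average")
        assert np.array_equal(backfit(rec, ts).labels,
                              backfit(flipped, ts).labels)

    def test_tie_goes_to_lower_class_index(self):
        ts = _templates(K=2)
        midpoint = ts.maps[0] + ts.maps[1]
        midpoint -= midpoint.mean()
        rec = EEGRecording(midpoint[:, None], 250.0, ts.ch_names,
                           reference="average")
        seg = backfit(rec, ts)
        r0 = md.abs_spatial_correlation(midpoint, ts.maps[0])
        r1 = md.abs_spatial_correlation(midpoint, ts.maps[1])
        assert r0 == pytest.approx(r1, abs=1e-12)
        assert seg.labels[0] == 0

    def test_zero_gfp_sample_unassigned(self):
        ts = _templates()
        rec = _recording_from_labels(ts, [0, 1])
        rec.data[:, 1] = 0.0
        seg = backfit(rec, ts)
        assert seg.labels[1] == UNASSIGNED
        assert seg.correlation[1] == 0.0

    def test_montage_mismatch_rejected(self, canonical):
        rec = EEGRecording(np.zeros((8, 10)) + np.random.default_rng(0)
                           .normal(size=(8, 10)), 250.0,
                           [f"c{i}" for i in range(8)], reference="average")
        with pytest.raises(ValueError):
            backfit(md.average_reference(rec), canonical)


class TestSmoothing:
    def test_single_sample_blip_absorbed(self):
        ts = _templates()
        labels = [0] * 20 + [1] + [0] * 20
        rec = _recording_from_labels(ts, labels)
        seg = backfit(rec, ts)
        out = smooth_segmentation(seg, rec, ts, min_duration_ms=30.0)
        assert np.all(out.labels == 0)

    def test_noop_when_all_segments_long(self):
        ts = _templates()
        labels = [0] * 20 + [1] * 20 + [2] * 20
        rec = _recording_from_labels(ts, labels)
        seg = backfit(rec, ts)
        out = smooth_segmentation(seg, rec, ts, min_duration_ms=30.0)
        assert np.array_equal(out.labels, seg.labels)

    def test_threshold_respected_and_monotone(self, noisy_recording, canonical):
        rec, _ = noisy_recording
        seg = backfit(rec, canonical)
        out = smooth_segmentation(seg, rec, canonical, min_duration_ms=30.0)
        table = out.segment_table()
        interior = table.iloc[1:-1]
        min_len = np.ceil(30.0 * rec.fs / 1000.0)
        assert (interior["end"] - interior["start"]).min() >= min_len
        # segment count never increases; mean duration never decreases
        before = seg.segment_table()
        assert len(table) <= len(before)
        assert table["duration_ms"].mean() >= before["duration_ms"].mean()

    def test_alternating_labels_vs_bruteforce_oracle(self):
        # 20-sample alternating sequence, threshold 3 samples
        ts = _templates(K=2)
        labels = np.array([0, 1] * 10)
        rec = _recording_from_labels(ts, labels)
        rec.data += np.random.default_rng(0).normal(
            scale=0.5, size=rec.data.shape)
        rec.data -= rec.data.mean(axis=0, keepdims=True)
        seg = backfit(rec, ts)
        fs = rec.fs
        thr_ms = 3 * 1000.0 / fs

        out = smooth_segmentation(seg, rec, ts, min_duration_ms=thr_ms)

        # independent slow oracle: explicit segment objects, one short
        # interior segment removed per pass (leftmost), edge walk-in rule
        r = np.abs(np.stack(
            [[md.spatial_correlation(rec.data[:, t], m) for m in ts.maps]
             for t in range(rec.n_samples)]))
        lab = list(seg.labels)

        def segments(ls):
            segs, start = [], 0
            for i in range(1, len(ls) + 1):
                if i == len(ls) or ls[i] != ls[start]:
                    segs.append((start, i, ls[start]))
                    start = i
            return segs

        while True:
            segs = segments(lab)
            short = [j for j in range(1, len(segs) - 1)
                     if segs[j][1] - segs[j][0] < 3]
            if not short:
                break
            j = short[0]
            s, e, _ = segs[j]
            left, right = segs[j - 1][2], segs[j + 1][2]
            split = e
            for t in range(s, e):
                if r[t, left] < r[t, right]:
                    split = t
                    break
            for t in range(s, split):
                lab[t] = left
            for t in range(split, e):
                lab[t] = right

        assert np.array_equal(out.labels, np.array(lab))

    def test_negative_threshold_rejected(self, noisy_recording, canonical):
        rec, _ = noisy_recording
        seg = backfit(rec, canonical)
        with pytest.raises(ValueError):
            smooth_segmentation(seg, rec, canonical, min_duration_ms=-1)


class TestParameters:
    def test_single_class_whole_recording(self):
        ts = _templates(K=2)
        fs = 100.0
        labels = [0] * 1000  # 10 s
        rec = _recording_from_labels(ts, labels, fs=fs)
        seg = backfit(rec, ts)
        p = microstate_parameters(seg, rec, fs)
        assert p.loc[0, "coverage"] == pytest.approx(100.0)
        assert p.loc[0, "duration_ms"] == pytest.approx(10000.0)
        assert p.loc[0, "occurrence"] == pytest.approx(0.1)
        assert p.loc[1, "coverage"] == 0.0 and p.loc[1, "gfp"] == 0.0

    def test_strict_alternation_closed_form(self):
        ts = _templates(K=2)
        fs = 500.0
        block = int(0.1 * fs)  # 100 ms
        labels = np.tile([0] * block + [1] * block, 50)  # 10 s
        rec = _recording_from_labels(ts, labels, fs=fs)
        seg = Segmentation(labels=np.array(labels),
                           correlation=np.ones(labels.size), fs=fs, n_classes=2)
        p = microstate_parameters(seg, rec, fs)
        for k in (0, 1):
            assert p.loc[k, "coverage"] == pytest.approx(50.0)
            assert p.loc[k, "duration_ms"] == pytest.approx(100.0)
            assert p.loc[k, "occurrence"] == pytest.approx(5.0)

    def test_coverage_conservation(self, noisy_recording, canonical):
        rec, _ = noisy_recording
        seg = backfit(rec, canonical)
        p = microstate_parameters(seg, rec)
        assert p["coverage"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_mean_gfp_tracks_generator_amplitudes(self, clean_recording,
                                                  canonical, hc_profile):
        rec, truth = clean_recording
        seg = backfit(rec, canonical)
        p = microstate_parameters(seg, rec)
        for k, cls in enumerate("ABCD"):
            if p.loc[k, "coverage"] > 0:
                assert p.loc[k, "gfp"] == pytest.approx(
                    hc_profile.gfp_uv[cls], rel=0.10)


class TestFitMetrics:
    def test_noise_free_perfect_fit(self, clean_recording, canonical):
        rec, _ = clean_recording
        seg = backfit(rec, canonical)
        fm = fit_metrics(seg, rec, canonical)
        assert fm.r2 == pytest.approx(1.0, abs=1e-9)
        assert fm.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_templates_zero_r2(self):
        ts = _templates(n_ch=8, K=2, seed=1)
        rng = np.random.default_rng(2)
        # build samples orthogonal to both (centered) templates
        M = ts.maps - ts.maps.mean(axis=1, keepdims=True)
        basis = np.linalg.svd(M, full_matrices=True)[2][2:]
        ones = np.ones(8) / np.sqrt(8)
        basis = basis - (basis @ ones)[:, None] * ones  # keep average-referenced
        data = (rng.normal(size=(50, basis.shape[0])) @ basis).T
        data -= data.mean(axis=0, keepdims=True)
        rec = EEGRecording(data, 100.0, ts.ch_names, reference="average")
        seg = backfit(rec, ts)
        fm = fit_metrics(seg, rec, ts)
        assert fm.r2 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fixture_regression(self, noisy_recording, canonical):
        rec, _ = noisy_recording
        seg = backfit(rec, canonical)
        fm = fit_metrics(seg, rec, canonical)
        # pinned-seed regression values (computed once from this fixture)
        assert 0.8 < fm.r2 < 1.0
        assert fm.residual_sd > 0

    def test_r2_nondecreasing_with_nested_templates(self, noisy_recording,
                                                    canonical):
        rec, _ = noisy_recording
        r2s = []
        for K in (2, 3, 4):
            sub = TemplateSet(canonical.maps[:K], labels=list("ABCD"[:K]),
                              ch_names=canonical.ch_names)
            seg = backfit(rec, sub)
            r2s.append(fit_metrics(seg, rec, sub).r2)
        assert np.all(np.diff(r2s) >= -1e-9)


class TestFullRecovery:
    def test_noise_free_parameters_equal_ground_truth(self, clean_recording,
                                                      canonical):
        rec, truth = clean_recording
        seg = backfit(rec, canonical)
        p = microstate_parameters(seg, rec)
        cov_true = truth.coverage(4) * 100
        dwell_true = truth.mean_dwell_ms(4)
        for k in range(4):
            assert p.loc[k, "coverage"] == pytest.approx(cov_true[k], abs=1e-9)
            assert p.loc[k, "duration_ms"] == pytest.approx(dwell_true[k],
                                                            abs=1e-9)
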