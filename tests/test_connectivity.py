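"""Analytic phase, pairwise PLV, matrices and averaging."""

import numpy as np
import pytest

import groupplv as gp
from groupplv.preprocess import BAND_BY_NAME, Segment

from conftest import tone

FS = 128.0


def _brute_force_plv_matrix(phases: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit double loop over channel pairs."""
    n = phases.shape[0]
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = phases[i] - phases[j]
            m[i, j] = m[j, i] = np.hypot(np.mean(np.sin(d)), np.mean(np.cos(d)))
    return m


class TestAnalyticPhase:
    def test_phase_slope_of_integer_cycle_tone(self):
        x = np.cos(2 * np.pi * 8.0 * np.arange(384) / FS)
        ph = gp.analytic_phase(x, FS).phase
        slope = np.diff(np.unwrap(ph))[32:-32] * FS  # rad/s away from edges
        np.testing.assert_allclose(slope, 2 * np.pi * 8.0, atol=1e-6)

    def test_unit_tone_amplitude(self):
        amp = gp.analytic_phase(tone(8.0, 3.0), FS).amplitude
        np.testing.assert_allclose(amp[32:-32], 1.0, atol=1e-3)

    def test_phase_range(self, rng):
        ph = gp.analytic_phase(rng.standard_normal(500), FS).phase
        assert np.all(ph >= -np.pi) and np.all(ph <= np.pi)

    def test_all_zero_signal_errors(self):
        with pytest.raises(ValueError):
            gp.analytic_phase(np.zeros(100), FS)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            gp.analytic_phase(np.array([1.0]), FS)


class TestRelativePhase:
    def test_identical_inputs_give_zero(self, rng):
        p = rng.uniform(-np.pi, np.pi, 100)
        np.testing.assert_array_equal(gp.relative_phase(p, p), 0.0)

    def test_constant_offset(self, rng):
        p = rng.uniform(-np.pi, np.pi, 100)
        np.testing.assert_allclose(gp.relative_phase(p + 0.7, p), 0.7)

    def test_antisymmetry(self, rng):
        a, b = rng.uniform(-np.pi, np.pi, (2, 50))
        np.testing.assert_array_equal(
            gp.relative_phase(a, b), -gp.relative_phase(b, a))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            gp.relative_phase(np.zeros(3), np.zeros(4))


class TestPlvPair:
    def test_constant_difference_is_one(self):
        assert gp.plv_pair(np.full(384, 1.234)) == pytest.approx(1.0)

    def test_full_cycle_uniform_phases_cancel(self):
        n = 128
        d = 2 * np.pi * np.arange(n) / n  # N-th roots of unity
        assert gp.plv_pair(d) == pytest.approx(0.0, abs=1e-12)

    def test_iid_uniform_phases_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [gp.plv_pair(rng.uniform(-np.pi, np.pi, 10_000)) for _ in range(100)]
        assert np.mean(vals) < 0.02  # O(N^-1/2) magnitude

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gp.plv_pair(np.array([]))

    def test_global_phase_shift_invariance(self, rng):
        d = rng.uniform(-np.pi, np.pi, 400)
        assert gp.plv_pair(d) == pytest.approx(gp.plv_pair(d + 2.1), abs=1e-12)


def _filtered_segment(rng, n_channels=6, band="alpha"):
    seg = Segment(participant=1, video=2, index=3,
                  signals=rng.standard_normal((n_channels, 384)), fs=FS)
    return gp.bandpass(seg, BAND_BY_NAME[band])


class TestPlvMatrix:
    def test_matches_brute_force_pairwise_oracle(self, rng):
        seg = _filtered_segment(rng)
        got = gp.plv_matrix(seg).values
        phases = np.array([gp.analytic_phase(ch, FS).phase for ch in seg.signals])
        np.testing.assert_allclose(got, _brute_force_plv_matrix(phases), atol=1e-12)

    def test_invariants(self, rng):
        m = gp.plv_matrix(_filtered_segment(rng)).values
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 1.0)
        assert np.all((m >= 0) & (m <= 1))

    def test_unfiltered_segment_rejected(self, rng):
        seg = Segment(participant=0, video=0, index=0,
                      signals=rng.standard_normal((3, 384)), fs=FS)
        with pytest.raises(ValueError):
            gp.plv_matrix(seg)

    def test_constant_offset_tones_lock_perfectly(self):
        x = np.stack([tone(10.0, 3.0, phase=p) for p in (0.0, 0.5, 1.0)])
        seg = Segment(participant=0, video=0, index=0, signals=x, fs=FS)
        m = gp.plv_matrix(gp.bandpass(seg, BAND_BY_NAME["alpha"])).values
        np.testing.assert_allclose(m, 1.0, atol=0.02)

    def test_provenance_carried(self, rng):
        pm = gp.plv_matrix(_filtered_segment(rng))
        assert (pm.participant, pm.video, pm.segment) == (1, 2, 3)
        assert pm.level == "individual" and pm.band.name == "alpha"


def _matrix(values, video=0, segment=0, participant=0):
    return gp.PLVMatrix(values=values, band=BAND_BY_NAME["gamma"],
                        participant=participant, video=video, segment=segment)


class TestGroupAverage:
    def test_idempotent_on_identical_matrices(self, rng):
        seg = _filtered_segment(rng)
        m = gp.plv_matrix(seg)
        out = gp.group_average([m] * 32)
        np.testing.assert_allclose(out.values, m.values)
        assert out.level == "group"

    def test_elementwise_mean(self):
        a = np.eye(2); a[0, 1] = a[1, 0] = 0.2
        b = np.eye(2); b[0, 1] = b[1, 0] = 0.8
        out = gp.group_average([_matrix(a, participant=0), _matrix(b, participant=1)])
        assert out.values[0, 1] == pytest.approx(0.5)

    def test_invariants_preserved(self, rng):
        ms = [gp.plv_matrix(_filtered_segment(np.random.default_rng(k)))
              for k in range(5)]
        v = gp.group_average(ms).values
        assert np.all((v >= 0) & (v <= 1))
        np.testing.assert_array_equal(np.diag(v), 1.0)

    def test_mixed_provenance_rejected(self):
        a = _matrix(np.eye(2), video=0)
        b = _matrix(np.eye(2), video=1)
        with pytest.raises(ValueError):
            gp.group_average([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gp.group_average([])


class TestConditionAverage:
    def _dataset(self, rng, labels):
        ms = [gp.plv_matrix(_filtered_segment(np.random.default_rng(k), band="gamma"))
              for k in range(len(labels))]
        return gp.LabeledDataset(matrices=ms, labels=list(labels),
                                 dimension="arousal", level="individual",
                                 band=BAND_BY_NAME["gamma"])

    def test_single_item(self, rng):
        ds = self._dataset(rng, ["high"])
        np.testing.assert_array_equal(
            gp.condition_average(ds, "high").values, ds.matrices[0].values)

    def test_equals_brute_force_mean(self, rng):
        ds = self._dataset(rng, ["high", "low", "high", "low", "high"])
        expect = np.mean([m.values for m, l in zip(ds.matrices, ds.labels)
                          if l == "low"], axis=0)
        np.testing.assert_allclose(gp.condition_average(ds, "low").values, expect)

    def test_missing_label_errors(self, rng):
        with pytest.raises(ValueError):
            gp.condition_average(self._dataset(rng, ["high"]), "low")

    def test_coupled_condition_has_larger_entries(self, tiny_corpus):
        # gamma coupling is strong in the high condition, washed out in low
        cfg, corpus = tiny_corpus
        recs = [r for recs in corpus for r in recs]
        mats = gp.extract_individual_matrices(recs, "gamma")
        labels = [cfg.condition_of(m.video) for m in mats]
        ds = gp.LabeledDataset(matrices=mats, labels=labels, dimension="arousal",
                               level="individual", band=BAND_BY_NAME["gamma"])
        hi = gp.condition_average(ds, "high").values
        lo = gp.condition_average(ds, "low").values
        part = cfg.communities["high"]["gamma"]
        within = np.zeros_like(hi, dtype=bool)
        for grp_idx in part:
            within[np.ix_(grp_idx, grp_idx)] = True
        np.fill_diagonal(within, False)
        assert np.all(hi[within] > lo[within])


def test_estimator_consistency_more_segments_closer_to_theory():
    """|empirical - exp(-s^2/2)| is non-increasing (in expectation) as the
    number of averaged segments grows.

    The segment PLV estimator has a small positive bias (the resultant of
    finitely many correlated phase samples has a noise floor), so the
    error converges to that bias rather than to zero; averaging more
    segments can only shrink it (convexity), never grow it.  Both levels
    must also sit inside the +/-0.10 recovery band.
    """
    cfg = gp.SynthConfig(
        n_participants=1, n_videos=1, n_channels=2, duration=303.0,
        bands=(gp.SynthBand("gamma", 30, 45, 37.0),),
        communities=[[0, 1]], jitter_sd=1.0 / np.sqrt(2), noise_sd=0.0, seed=21)
    rec = gp.simulate_recording(cfg, 0, 0)
    segs = [gp.bandpass(s, BAND_BY_NAME["gamma"])
            for s in gp.segment_recording(gp.trim_baseline(rec), 3.0)]
    vals = np.array([gp.plv_matrix(s).values[0, 1] for s in segs])
    theory = np.exp(-0.5)
    # expected error of 10-segment averages (over the ten disjoint blocks)
    # vs. the single 100-segment average
    err10 = np.mean([abs(vals[k * 10:(k + 1) * 10].mean() - theory)
                     for k in range(10)])
    err100 = abs(vals.mean() - theory)
    assert err100 <= err10 + 1e-12
    assert err10 <= 0.10 and err100 <= 0.10
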