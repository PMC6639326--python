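"""Detector: ensemble training/voting, sieve filter, runs, DP validation."""

import itertools
from dataclasses import replace
from datetime import date as Date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nystagdet import (
    DetectorConfig,
    EnsembleModel,
    EventSpec,
    FrameLabelSequence,
    FrameSpec,
    GeneratorConfig,
    classify_frames,
    detect_day,
    dp_sawtooth_score,
    dtw_score,
    extract_runs,
    frame_labels,
    sawtooth_event,
    sieve_filter,
    synthesize_day,
    train_ensemble,
    validate_runs,
)
from nystagdet.features import FrameFeatureMatrix, extract_features

FS = 41.5


def _feature_matrix(values):
    spec = FrameSpec()
    freqs = spec.retained_bins(FS) * spec.bin_spacing(FS)
    values = np.asarray(values, dtype=float)
    return FrameFeatureMatrix(
        values=values,
        frame_start_times=np.arange(len(values)) * spec.hop / FS,
        bin_frequencies=freqs,
        sampling_rate=FS,
        spec=spec,
    )


def _blob_features(n_per_class=200, seed=0):
    """Linearly separable synthetic frames: background at the origin,
    nystagmus shifted along every bin."""
    rng = np.random.default_rng(seed)
    neg = np.abs(rng.normal(0.0, 0.05, size=(n_per_class, 82)))
    pos = np.abs(rng.normal(1.0, 0.05, size=(n_per_class, 82)))
    X = np.vstack([neg, pos])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return _feature_matrix(X), y


class TestEnsemble:
    def test_members_separate_separable_blobs(self):
        feats, y = _blob_features()
        model = train_ensemble([feats], [y], seed=0)
        Xs = model.scaler.transform(feats.values)
        for name, member in model.members.items():
            assert (member.predict(Xs) == y).all(), name

    def test_single_class_training_rejected(self):
        feats, y = _blob_features()
        with pytest.raises(ValueError):
            train_ensemble([feats], [np.zeros_like(y)], seed=0)

    def test_training_is_deterministic(self):
        feats, y = _blob_features()
        a = train_ensemble([feats], [y], seed=3)
        b = train_ensemble([feats], [y], seed=3)
        votes_a = classify_frames(a, feats).votes
        votes_b = classify_frames(b, feats).votes
        np.testing.assert_array_equal(votes_a, votes_b)
        np.testing.assert_array_equal(
            a.svm.dual_coef_, b.svm.dual_coef_
        )
        np.testing.assert_array_equal(a.lda.coef_, b.lda.coef_)

    def test_model_roundtrip_through_file(self, tmp_path):
        feats, y = _blob_features()
        model = train_ensemble([feats], [y], seed=0)
        model.save(tmp_path / "model.joblib")
        loaded = EnsembleModel.load(tmp_path / "model.joblib")
        np.testing.assert_array_equal(
            classify_frames(model, feats).labels,
            classify_frames(loaded, feats).labels,
        )

    def test_majority_vote_is_median_of_members(self):
        # enumerate all 8 member-vote patterns: label = majority = median
        for votes in itertools.product([0, 1], repeat=3):
            label = int(sum(votes) >= 2)
            assert label == int(np.median(votes))

    def test_zero_frames_classified_background(self):
        feats, y = _blob_features()
        model = train_ensemble([feats], [y], seed=0)
        zeros = _feature_matrix(np.zeros((5, 82)))
        assert classify_frames(model, zeros).labels.sum() == 0

    def test_dimension_mismatch_rejected(self):
        feats, y = _blob_features()
        model = train_ensemble([feats], [y], seed=0)
        bad = _feature_matrix(np.zeros((2, 82)))
        bad.values = np.zeros((2, 40))
        with pytest.raises(ValueError):
            classify_frames(model, bad)

    def test_frame_labels_require_half_window_overlap(self, quiet_config):
        cfg = replace(
            quiet_config,
            day_length=300.0,
            event_schedule=(EventSpec(100.0, 30.0, 1.0, "right"),),
        )
        day = synthesize_day(cfg)
        labels = frame_labels(day)
        spec = FrameSpec()
        win_s = spec.window_duration_s(FS)
        starts = np.arange(len(labels)) * spec.hop / FS
        overlap = np.minimum(starts + win_s, 130.0) - np.maximum(starts, 100.0)
        np.testing.assert_array_equal(labels, (overlap >= 0.5 * win_s).astype(int))
        assert 0 < labels.sum() < len(labels)


# --- sieve filter ---------------------------------------------------------


def _sieve_oracle(bits, min_run, max_gap):
    """Position-by-position reference: closing then opening."""
    n = len(bits)
    # closing: a zero flips if it sits in an interior zero-run of length
    # <= max_gap with ones on both sides
    closed = list(bits)
    i = 0
    while i < n:
        if bits[i] == 0:
            j = i
            while j < n and bits[j] == 0:
                j += 1
            if i > 0 and j < n and (j - i) <= max_gap:
                for k in range(i, j):
                    closed[k] = 1
            i = j
        else:
            i = i + 1
    # opening: ones survive only in runs of length >= min_run
    opened = [0] * n
    i = 0
    while i < n:
        if closed[i] == 1:
            j = i
            while j < n and closed[j] == 1:
                j += 1
            if (j - i) >= min_run:
                for k in range(i, j):
                    opened[k] = 1
            i = j
        else:
            i += 1
    return opened


class TestSieveFilter:
    @pytest.mark.parametrize(
        "bits,min_run,max_gap,expected",
        [
            ([0, 0, 1, 0, 0], 2, 0, [0, 0, 0, 0, 0]),
            ([1, 1, 0, 1, 1], 2, 1, [1, 1, 1, 1, 1]),
            ([1, 1, 1, 1], 2, 1, [1, 1, 1, 1]),
        ],
    )
    def test_reference_cases(self, bits, min_run, max_gap, expected):
        assert sieve_filter(bits, min_run, max_gap).tolist() == expected
        assert _sieve_oracle(bits, min_run, max_gap) == expected

    @pytest.mark.parametrize("min_run,max_gap", [(1, 0), (2, 1), (3, 2), (2, 3)])
    def test_matches_exhaustive_oracle_up_to_length_12(self, min_run, max_gap):
        for n in range(1, 13):
            for bits in itertools.product([0, 1], repeat=n):
                got = sieve_filter(list(bits), min_run, max_gap).tolist()
                assert got == _sieve_oracle(bits, min_run, max_gap), (
                    bits,
                    min_run,
                    max_gap,
                )

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=40),
        st.integers(1, 4),
        st.integers(0, 3),
    )
    def test_idempotent_and_ordered(self, bits, min_run, max_gap):
        once = sieve_filter(bits, min_run, max_gap)
        twice = sieve_filter(once, min_run, max_gap)
        np.testing.assert_array_equal(once, twice)
        # opening-after-closing lies between the opening and the closing
        closing = sieve_filter(bits, 1, max_gap)
        assert (once <= closing).all()

    def test_frame_label_sequence_passthrough(self):
        seq = FrameLabelSequence(
            labels=[0, 1, 0, 1, 1, 1, 0],
            votes=[0, 2, 1, 3, 3, 2, 0],
            frame_times=np.arange(7) * 100 / FS,
        )
        out = sieve_filter(seq, min_run=3, max_gap=0)
        assert isinstance(out, FrameLabelSequence)
        assert out.labels.tolist() == [0, 0, 0, 1, 1, 1, 0]
        np.testing.assert_array_equal(out.votes, seq.votes)


class TestExtractRuns:
    def test_runs_and_times(self):
        seq = FrameLabelSequence(
            labels=[0, 1, 1, 0, 1],
            votes=[0, 3, 3, 0, 2],
            frame_times=np.arange(5) * 100 / FS,
        )
        runs = extract_runs(seq, FrameSpec(), FS)
        assert [(r.start_frame, r.end_frame) for r in runs] == [(1, 2), (4, 4)]
        assert runs[0].start_s == pytest.approx(100 / FS)
        assert runs[0].end_s == pytest.approx(200 / FS + 500 / FS)

    def test_empty_and_full(self):
        empty = FrameLabelSequence([0, 0, 0], [0] * 3, np.arange(3.0))
        assert extract_runs(empty, FrameSpec(), FS) == []
        full = FrameLabelSequence([1] * 5, [3] * 5, np.arange(5.0))
        runs = extract_runs(full, FrameSpec(), FS)
        assert [(r.start_frame, r.end_frame) for r in runs] == [(0, 4)]


# --- DP sawtooth score ----------------------------------------------------


class TestDpSawtoothScore:
    def test_dtw_self_alignment_is_zero(self):
        x = sawtooth_event(1.0, 5.0, "right", 1.0, 0.8, FS)
        assert dtw_score(x, x) == 0.0

    def test_degenerate_single_point_template_is_mad(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = np.array([0.3])
        assert dtw_score(x, y, band_fraction=1.0) == pytest.approx(
            np.mean(np.abs(x - y[0]))
        )

    def test_exact_template_scores_near_zero(self):
        x = sawtooth_event(1.0, 10.0, "right", 1.0, 0.8, FS)
        assert dp_sawtooth_score(x, 1.0, FS, detrend_window=1) < 0.02

    def test_phase_offset_beats_white_noise_100_of_100(self):
        rng = np.random.default_rng(12345)
        tpl = sawtooth_event(1.0, 6.0, "right", 1.0, 0.8, FS)
        shifted = sawtooth_event(1.0, 6.5, "right", 1.0, 0.8, FS)
        shifted = shifted[int(0.13 * FS) : int(0.13 * FS) + len(tpl)]
        s_shift = dp_sawtooth_score(shifted, 1.0, FS)
        wins = 0
        for _ in range(100):
            noise = rng.normal(size=len(tpl))
            if s_shift < dp_sawtooth_score(noise, 1.0, FS):
                wins += 1
        assert wins == 100

    @settings(max_examples=20, deadline=None)
    @given(
        st.floats(0.1, 50.0),
        st.floats(-20.0, 20.0),
        st.integers(0, 2**31 - 1),
    )
    def test_affine_amplitude_invariance(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        x = sawtooth_event(1.0, 5.0, "right", 1.0, 0.8, FS)
        x = x + rng.normal(0, 0.1, len(x))
        a = dp_sawtooth_score(x, 1.0, FS)
        b = dp_sawtooth_score(scale * x + offset, 1.0, FS)
        assert a == pytest.approx(b, abs=1e-9)

    def test_mirror_polarity_invariance(self):
        x = sawtooth_event(0.8, 10.0, "left", 1.0, 0.8, FS)
        y = sawtooth_event(0.8, 10.0, "right", 1.0, 0.8, FS)
        assert dp_sawtooth_score(x, 0.8, FS) == pytest.approx(
            dp_sawtooth_score(y, 0.8, FS)
        )

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            dp_sawtooth_score(np.zeros(20), 1.0, FS)


class TestValidateRuns:
    def test_clean_event_run_accepted(self, quiet_config):
        cfg = replace(
            quiet_config,
            day_length=200.0,
            event_schedule=(EventSpec(80.0, 30.0, 1.0, "right"),),
        )
        day = synthesize_day(cfg)
        from nystagdet.detector import CandidateRun

        run = CandidateRun(0, 0, 78.0, 112.0)
        out = validate_runs([run], day)
        assert out[0].accepted
        assert out[0].dp_score < 0.18
        assert out[0].modal_frequency == pytest.approx(1.0, abs=0.05)

    def test_locomotion_burst_rejected_by_band_prefilter(self):
        from nystagdet import ArtifactBurst
        from nystagdet.detector import CandidateRun

        cfg = GeneratorConfig(
            day_length=200.0,
            noise_sigma=0.0,
            drift_sigma=0.0,
            saccade_rate=0.0,
            artifact_bursts=(ArtifactBurst(80.0, 30.0, 2.5, 1.0),),
        )
        day = synthesize_day(cfg)
        out = validate_runs([CandidateRun(0, 0, 80.0, 110.0)], day)
        assert not out[0].accepted
        assert out[0].modal_frequency == pytest.approx(2.5, abs=0.05)

    def test_short_run_rejected_by_duration_prefilter(self, quiet_config):
        from nystagdet.detector import CandidateRun

        cfg = replace(
            quiet_config,
            day_length=100.0,
            event_schedule=(EventSpec(40.0, 30.0, 1.0, "right"),),
        )
        day = synthesize_day(cfg)
        out = validate_runs([CandidateRun(0, 0, 45.0, 50.0)], day)
        assert not out[0].accepted and out[0].dp_score is None

    def test_empty_run_list(self, quiet_config):
        day = synthesize_day(replace(quiet_config, day_length=60.0))
        assert validate_runs([], day) == []


class TestEndToEnd:
    def test_noisefree_days_detected_exactly(self, small_model, noisefree_config):
        """Every scheduled event yields exactly one accepted run overlapping
        it; background-only noise-free days yield none."""
        for seed in range(3):
            cfg = replace(
                noisefree_config,
                day_length=600.0,
                seed=seed,
                event_schedule=(EventSpec(200.0, 30.0, 1.0, "right"),),
            )
            day = synthesize_day(cfg, participant_id=f"E{seed}")
            accepted = [r for r in detect_day(small_model, day) if r.accepted]
            assert len(accepted) == 1
            assert accepted[0].start_s < 230.0 and accepted[0].end_s > 200.0
            bg = synthesize_day(
                replace(noisefree_config, day_length=600.0, seed=seed + 50),
                participant_id=f"B{seed}",
            )
            assert [r for r in detect_day(small_model, bg) if r.accepted] == []

    def test_background_days_rarely_alarm(self, small_model):
        """At default noise, >= 95% of background-only days produce no
        accepted detection (50 seeded days)."""
        clean = 0
        for seed in range(50):
            cfg = GeneratorConfig(day_length=300.0, seed=9000 + seed)
            day = synthesize_day(cfg, participant_id=f"N{seed}")
            runs = [r for r in detect_day(small_model, day) if r.accepted]
            clean += not runs
        assert clean >= 48
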