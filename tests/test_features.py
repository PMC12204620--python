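import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from towheesong import features, spectro, synth

from conftest import make_tone_spec, segment_recording


def _mask_measure(mask):
    return features.SyllableMeasure(
        duration_ms=10.0 * mask.shape[1], f_upper_hz=5000.0, f_lower_hz=2000.0, mask=mask
    )


class TestMeasureSyllables:
    def test_tone_band_recovered(self):
        spec = make_tone_spec(n_tones=1, f_low=4000.0, f_high=4100.0)
        rec = synth.synthesize_song(spec)
        # Tight dynamic range so window side lobes stay out of the mask.
        p = spectro.SegmentationParams(dynamic_range_db=30.0)
        sg, intervals, masks = segment_recording(rec, params=p)
        ms = features.measure_syllables(sg, intervals, masks)
        bin_hz = 44100 / 512
        assert ms[0].f_lower_hz == pytest.approx(4000.0, abs=bin_hz)
        assert ms[0].f_upper_hz == pytest.approx(4100.0, abs=bin_hz)

    def test_chirp_band_recovered(self):
        # Slow chirp: the syllable-level amplitude taper trims a little of
        # each band edge, so the tolerance is a few bins.
        syl = synth.Syllable(0, 150.0, 800.0, 3000.0, 8000.0, "chirp")
        spec = synth.SongSpec("spotted", -110.0, 40.0, 5, [syl])
        rec = synth.synthesize_song(spec)
        sg, intervals, masks = segment_recording(rec)
        ms = features.measure_syllables(sg, intervals, masks)
        assert ms[0].f_lower_hz == pytest.approx(3000.0, abs=300.0)
        assert ms[0].f_upper_hz == pytest.approx(8000.0, abs=300.0)

    def test_identical_masks_identical_measures(self):
        mask = np.zeros((32, 10), dtype=bool)
        mask[5:10, 2:8] = True
        freq = np.arange(32) * 100.0 + 500.0
        time = (np.arange(10) + 1) * 3.0
        sg = spectro.Spectrogram(np.full((32, 10), -50.0), freq, time,
                                 {"window": 512, "hop": 128, "sample_rate": 44100,
                                  "hp_hz": None, "lp_hz": None})
        ivs = [spectro.SyllableInterval(0.0, 30.0, 0, 10),
               spectro.SyllableInterval(40.0, 70.0, 0, 10)]
        a, b = features.measure_syllables(sg, ivs, [mask, mask.copy()])
        assert (a.f_lower_hz, a.f_upper_hz) == (b.f_lower_hz, b.f_upper_hz)


class TestSyllableSimilarity:
    def test_identical_masks_100(self, rng):
        mask = rng.random((20, 15)) > 0.6
        mask[3, 4] = True
        m = _mask_measure(mask)
        assert features.syllable_similarity(m, m) == pytest.approx(100.0)

    def test_disjoint_bands_zero(self):
        a = np.zeros((20, 10), dtype=bool)
        b = np.zeros((20, 10), dtype=bool)
        a[2:5, :] = True
        b[12:15, :] = True
        assert features.syllable_similarity(_mask_measure(a), _mask_measure(b)) == 0.0

    def test_half_deleted_gives_two_thirds(self):
        # |shared| = n/2, mean size = 3n/4 -> 100 * (n/2)/(3n/4) = 66.67.
        a = np.zeros((10, 8), dtype=bool)
        a[4, :] = True  # n = 8 elements in one row
        b = a.copy()
        b[4, ::2] = False  # delete half
        sim = features.syllable_similarity(_mask_measure(a), _mask_measure(b))
        assert sim == pytest.approx(100 * 4 / 6, abs=1e-9)

    def test_symmetry(self, rng):
        a = _mask_measure(rng.random((16, 12)) > 0.5)
        b = _mask_measure(rng.random((16, 9)) > 0.5)
        if not (a.mask.any() and b.mask.any()):
            pytest.skip("degenerate draw")
        assert features.syllable_similarity(a, b) == pytest.approx(
            features.syllable_similarity(b, a)
        )

    def test_lag_alignment_finds_shift(self):
        a = np.zeros((12, 10), dtype=bool)
        a[4:7, 2:6] = True
        b = np.zeros((12, 10), dtype=bool)
        b[4:7, 5:9] = True  # same pattern shifted by 3 columns
        assert features.syllable_similarity(_mask_measure(a), _mask_measure(b)) == pytest.approx(100.0)


class TestAssignTypes:
    def test_identical_trill_one_type(self, rng):
        mask = rng.random((20, 8)) > 0.5
        mask[4, 4] = True
        ms = [_mask_measure(mask.copy()) for _ in range(8)]
        assert features.assign_syllable_types(ms) == [0] * 8

    def test_intros_plus_trill_four_types(self):
        ms = []
        for band in range(3):  # disjoint bands
            m = np.zeros((40, 8), dtype=bool)
            m[band * 10 : band * 10 + 4, :] = True
            ms.append(_mask_measure(m))
        trill = np.zeros((40, 8), dtype=bool)
        trill[34:38, :] = True
        ms += [_mask_measure(trill.copy()) for _ in range(6)]
        labels = features.assign_syllable_types(ms)
        assert labels == [0, 1, 2] + [3] * 6

    def test_threshold_inclusive_at_boundary(self):
        # similarity exactly 50 with threshold 50 -> same type.
        a = np.zeros((10, 4), dtype=bool)
        a[2:4, :] = True  # 8 elements
        b = np.zeros((10, 4), dtype=bool)
        b[2:3, :] = True  # 4 elements; shared 4; mean 6 -> 66.7
        sim = features.syllable_similarity(_mask_measure(a), _mask_measure(b))
        p = features.TypingParams(similarity_threshold_percent=sim)
        assert features.assign_syllable_types([_mask_measure(a), _mask_measure(b)], p) == [0, 0]

    def test_per_species_thresholds(self):
        assert features.TypingParams.for_species("spotted").similarity_threshold_percent == 26.6
        assert features.TypingParams.for_species("eastern").similarity_threshold_percent == 25.5
        assert features.TypingParams.for_species("hybrid_unsure").similarity_threshold_percent == 25.0


class TestComputeFeatureVector:
    def _measures(self, durations, bands, types, gap=50.0):
        ms, ivs = [], []
        t = 0.0
        for d, (lo, hi) in zip(durations, bands):
            mask = np.ones((4, 4), dtype=bool)
            ms.append(features.SyllableMeasure(d, hi, lo, mask))
            ivs.append(spectro.SyllableInterval(t, t + d))
            t += d + gap
        return ms, types, ivs

    def test_rate_arithmetic(self):
        # 10 syllables spanning exactly 2000 ms.
        ms, types, ivs = self._measures([150.0] * 10, [(3000.0, 4000.0)] * 10,
                                        list(range(10)), gap=(2000.0 - 1500.0) / 9 - 0.0)
        # Recompute the gap so the bout is exactly 2000 ms.
        ivs = []
        t = 0.0
        for k in range(10):
            ivs.append(spectro.SyllableInterval(t, t + 150.0))
            t += 150.0 + (2000.0 - 10 * 150.0) / 9
        fv = features.compute_feature_vector(ms, types, ivs)
        assert fv.bout_duration_ms == pytest.approx(2000.0)
        assert fv.syllable_rate_per_ms == pytest.approx(0.005)

    def test_repetition_arithmetic(self):
        ms, types, ivs = self._measures([100.0] * 8, [(3000.0, 4000.0)] * 8,
                                        [0, 1] * 4)
        fv = features.compute_feature_vector(ms, types, ivs)
        assert fv.syllable_repetition == pytest.approx(4.0)
        assert fv.n_unique_syllables == 2

    def test_single_fused_trill(self):
        ms, types, ivs = self._measures([900.0], [(3000.0, 7000.0)], [0])
        fv = features.compute_feature_vector(ms, types, ivs)
        assert fv.n_syllables == 1
        assert fv.n_unique_syllables == 1
        assert fv.syllable_repetition == 1
        assert fv.bout_duration_ms == pytest.approx(900.0)

    def test_zero_syllables_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            features.compute_feature_vector([], [], [])

    def test_freq_features(self):
        ms, types, ivs = self._measures([100.0, 100.0], [(3000.0, 4000.0), (2500.0, 6000.0)],
                                        [0, 1])
        fv = features.compute_feature_vector(ms, types, ivs)
        assert fv.max_freq_hz == 6000.0
        assert fv.min_freq_hz == 2500.0
        assert fv.overall_freq_range_hz == 3500.0
        assert fv.largest_syll_freq_range_hz == 3500.0
        assert fv.smallest_syll_freq_range_hz == 1000.0
        assert fv.avg_syll_freq_range_hz == 2250.0


class TestLogTransform:
    def test_values(self):
        df = pd.DataFrame({"a": [1.0, np.e], "b": [np.e**2, 1.0]})
        out = features.log_transform_features(df)
        assert out["a"].tolist() == pytest.approx([0.0, 1.0])
        assert out["b"].tolist() == pytest.approx([2.0, 0.0])

    def test_roundtrip(self, rng):
        x = rng.uniform(0.1, 10, size=(5, 3))
        assert np.allclose(np.exp(features.log_transform_features(x)), x)

    def test_nonpositive_rejected_with_name(self):
        df = pd.DataFrame({"good": [1.0, 2.0], "bad": [1.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            features.log_transform_features(df)


class TestFeatureRecoveryInvariant:
    def test_recovery_against_generator_truth(self):
        """n_syllables / bout / rate / frequency bounds vs truth on clean songs.

        Counts are exact or off by one; bout duration within one analysis
        window per edge; frequency bounds within one bin plus the chirp
        sweep-rate smear of the STFT window.
        """
        model = synth.PopulationModel(n_recordings=40, hybrid_fraction=0.0)
        pop = synth.sample_population(model, seed=99)
        win_ms = 512 / 44100 * 1000
        bin_hz = 44100 / 512
        bad = 0
        for spec, rec in pop:
            recording = synth.synthesize_song(spec)
            sg, intervals, masks = segment_recording(recording, species=rec.species)
            truth_fv = features.feature_vector_from_spec(spec)
            if len(intervals) != len(spec.syllables):
                bad += abs(len(intervals) - len(spec.syllables)) > 1
                continue
            ms = features.measure_syllables(sg, intervals, masks)
            types = features.assign_syllable_types(
                ms, features.TypingParams.for_species(rec.species)
            )
            fv = features.compute_feature_vector(ms, types, intervals)
            smear = max(
                (s.f_high_hz - s.f_low_hz) / s.duration_ms * win_ms / 2
                for s in spec.syllables
            )
            ok = (
                fv.n_syllables == truth_fv.n_syllables
                and abs(fv.bout_duration_ms - truth_fv.bout_duration_ms) < 2 * win_ms
                and abs(fv.max_freq_hz - truth_fv.max_freq_hz) < bin_hz + smear
                and abs(fv.min_freq_hz - truth_fv.min_freq_hz) < bin_hz + smear
            )
            bad += not ok
        assert bad / len(pop) <= 0.05

    def test_species_mean_separation_recovered(self):
        # Downstream mean syllable duration per species tracks the truth
        # means within 2 SE (paired comparison over the same songs).
        model = synth.PopulationModel(n_recordings=60, hybrid_fraction=0.0)
        pop = synth.sample_population(model, seed=41)
        diffs = {"spotted": [], "eastern": []}
        for spec, rec in pop:
            recording = synth.synthesize_song(spec)
            sg, intervals, masks = segment_recording(recording, species=rec.species)
            if not intervals:
                continue
            ms = features.measure_syllables(sg, intervals, masks)
            types = features.assign_syllable_types(ms)
            fv = features.compute_feature_vector(ms, types, intervals)
            truth_fv = features.feature_vector_from_spec(spec)
            diffs[rec.species].append(fv.mean_syllable_ms - truth_fv.mean_syllable_ms)
        for species, d in diffs.items():
            d = np.asarray(d)
            se = d.std(ddof=1) / np.sqrt(len(d))
            # Allow a small systematic windowing offset alongside 2 SE.
            assert abs(d.mean()) < 2 * se + win_offset_allowance()


def win_offset_allowance():
    return 512 / 44100 * 1000  # one analysis window in ms


@settings(max_examples=30, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=12),
    n_types=st.integers(min_value=1, max_value=5),
    data=st.data(),
)
def test_algebraic_identities_property(n, n_types, data):
    n_types = min(n_types, n)
    types = list(range(n_types)) + [
        data.draw(st.integers(min_value=0, max_value=n_types - 1)) for _ in range(n - n_types)
    ]
    rng = np.random.default_rng(data.draw(st.integers(min_value=0, max_value=2**31)))
    ms, ivs = [], []
    t = 0.0
    for _ in range(n):
        d = rng.uniform(20, 200)
        lo = rng.uniform(1000, 5000)
        hi = lo + rng.uniform(100, 4000)
        ms.append(features.SyllableMeasure(d, hi, lo, np.ones((3, 3), dtype=bool)))
        ivs.append(spectro.SyllableInterval(t, t + d))
        t += d + rng.uniform(10, 100)
    fv = features.compute_feature_vector(ms, types, ivs)
    assert fv.syllable_repetition * fv.n_unique_syllables == pytest.approx(fv.n_syllables)
    assert fv.overall_freq_range_hz == pytest.approx(fv.max_freq_hz - fv.min_freq_hz)
    assert fv.smallest_syll_freq_range_hz <= fv.avg_syll_freq_range_hz <= fv.largest_syll_freq_range_hz
    assert fv.n_unique_syllables <= fv.n_syllables
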