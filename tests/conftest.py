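import numpy as np
import pandas as pd
import pytest

from towheesong import features, spectro, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone_spec(n_tones=3, duration_ms=100.0, gap_ms=50.0, f_low=3950.0, f_high=4050.0, seed=7):
    """SongSpec with n identical tones separated by fixed gaps."""
    sylls = []
    t = 150.0
    for _ in range(n_tones):
        sylls.append(synth.Syllable(0, t, duration_ms, f_low, f_high, "tone"))
        t += duration_ms + gap_ms
    return synth.SongSpec("eastern", -80.0, 40.0, seed, sylls)


@pytest.fixture
def three_tone_spec():
    return make_tone_spec()


def segment_recording(recording, species=None, params=None):
    """Full segmentation path: spectrogram -> intervals -> noise filter."""
    params = params or spectro.SegmentationParams.for_species(species)
    spec = spectro.compute_spectrogram(recording.waveform)
    intervals = spectro.segment_syllables(spec, params)
    intervals, masks = spectro.filter_noise_components(spec, intervals, params)
    return spec, intervals, masks


def match_intervals(truth, detected, min_overlap=0.5):
    """Greedy one-to-one interval matching at >= min_overlap fractional overlap."""
    used = set()
    matched = 0
    for a, b in truth:
        for j, iv in enumerate(detected):
            if j in used:
                continue
            ov = min(b, iv.offset_ms) - max(a, iv.onset_ms)
            if ov > 0 and ov >= min_overlap * min(b - a, iv.duration_ms):
                used.add(j)
                matched += 1
                break
    return matched, len(detected) - len(used)


def truth_feature_frame(population, relabel_hybrids_rng=None):
    """Feature table from ground-truth specs (fast path, no audio)."""
    from towheesong.geo import HYBRID_LABEL

    rows = []
    for spec, rec in population:
        fv = features.feature_vector_from_spec(spec)
        species = rec.species
        if species == HYBRID_LABEL and relabel_hybrids_rng is not None:
            species = relabel_hybrids_rng.choice(["spotted", "eastern"])
        rows.append(
            {
                "id": rec.id,
                "species": species,
                "date": rec.date,
                "longitude": rec.longitude,
                "latitude": rec.latitude,
                "conversion_status": rec.conversion_status,
                **fv.as_dict(),
            }
        )
    return pd.DataFrame(rows)
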