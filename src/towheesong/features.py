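"""Per-syllable measurements, syllable typing, and the 16 song features."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .spectro import Spectrogram, SyllableInterval

#: Fixed column order of the 16 song features.
FEATURE_NAMES = [
    "bout_duration_ms",
    "n_syllables",
    "syllable_rate_per_ms",
    "smallest_syllable_ms",
    "largest_syllable_ms",
    "mean_syllable_ms",
    "n_unique_syllables",
    "syllable_repetition",
    "avg_upper_freq_hz",
    "avg_lower_freq_hz",
    "max_freq_hz",
    "min_freq_hz",
    "overall_freq_range_hz",
    "largest_syll_freq_range_hz",
    "smallest_syll_freq_range_hz",
    "avg_syll_freq_range_hz",
]

#: Percent-overlap similarity thresholds for syllable typing, by species.
SIMILARITY_THRESHOLDS = {"spotted": 26.6, "eastern": 25.5, "hybrid_unsure": 25.0, None: 25.0}


@dataclass
class TypingParams:
    similarity_threshold_percent: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 < self.similarity_threshold_percent < 100.0:
            raise ValueError("similarity threshold must be in (0, 100)")

    @classmethod
    def for_species(cls, species: str | None) -> "TypingParams":
        return cls(SIMILARITY_THRESHOLDS.get(species, SIMILARITY_THRESHOLDS[None]))


@dataclass
class SyllableMeasure:
    """Duration, frequency bounds, and retained mask for one syllable."""

    duration_ms: float
    f_upper_hz: float
    f_lower_hz: float
    mask: np.ndarray  # bool, (n_freq_bins, n_time_cols)

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not self.f_upper_hz > self.f_lower_hz:
            raise ValueError("f_upper must exceed f_lower")


@dataclass
class SongFeatureVector:
    bout_duration_ms: float
    n_syllables: float
    syllable_rate_per_ms: float
    smallest_syllable_ms: float
    largest_syllable_ms: float
    mean_syllable_ms: float
    n_unique_syllables: float
    syllable_repetition: float
    avg_upper_freq_hz: float
    avg_lower_freq_hz: float
    max_freq_hz: float
    min_freq_hz: float
    overall_freq_range_hz: float
    largest_syll_freq_range_hz: float
    smallest_syll_freq_range_hz: float
    avg_syll_freq_range_hz: float

    def as_array(self) -> np.ndarray:
        d = asdict(self)
        return np.array([d[name] for name in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def measure_syllables(
    spec: Spectrogram,
    intervals: list[SyllableInterval],
    masks: list[np.ndarray],
) -> list[SyllableMeasure]:
    """Duration and frequency bounds per syllable from retained masks.

    f_upper / f_lower are the highest / lowest frequency-bin centers that
    contain retained mask elements within the interval.
    """
    if len(intervals) != len(masks):
        raise ValueError("intervals and masks must pair up")
    out = []
    for iv, mask in zip(intervals, masks):
        if not mask.any():
            raise AssertionError("empty mask reached measurement stage")
        rows = np.flatnonzero(mask.any(axis=1))
        # A single-bin mask still has a nonzero band: widen by half a bin.
        f_lo = float(spec.freq_axis[rows[0]])
        f_hi = float(spec.freq_axis[rows[-1]])
        if f_hi == f_lo:
            half_bin = float(np.diff(spec.freq_axis).mean()) / 2.0
            f_lo, f_hi = f_lo - half_bin, f_hi + half_bin
        out.append(SyllableMeasure(iv.duration_ms, f_hi, f_lo, mask))
    return out


def syllable_similarity(a: SyllableMeasure, b: SyllableMeasure) -> float:
    """Percent mask overlap, maximized over integer time-lags.

    Frequency alignment is fixed; the score is ``100 * max over lags of
    |shared on-elements| / mean(|a|, |b|)``.  Symmetric by construction.
    """
    ma = a.mask.astype(np.float64)
    mb = b.mask.astype(np.float64)
    if not ma.any() or not mb.any():
        raise ValueError("similarity of empty masks is undefined")
    if ma.shape[0] != mb.shape[0]:
        raise ValueError("masks must share the frequency axis")
    corr = sp_signal.correlate(ma, mb, mode="full")
    # Row at zero frequency-lag; columns run over all time-lags.
    shared = corr[ma.shape[0] - 1, :].max()
    denom = (ma.sum() + mb.sum()) / 2.0
    return float(100.0 * np.round(shared) / denom)


def assign_syllable_types(
    measures: list[SyllableMeasure], p: TypingParams | None = None
) -> list[int]:
    """Greedy founder-based typing with dense labels.

    The first syllable founds type 0; each later syllable joins the
    earliest-founded type whose *founder* similarity is >= the threshold
    (inclusive), else founds a new type.
    """
    if not measures:
        raise ValueError("need at least one syllable")
    p = p or TypingParams()
    founders: list[SyllableMeasure] = []
    labels: list[int] = []
    for m in measures:
        for t, founder in enumerate(founders):
            if syllable_similarity(m, founder) >= p.similarity_threshold_percent:
                labels.append(t)
                break
        else:
            labels.append(len(founders))
            founders.append(m)
    return labels


def compute_feature_vector(
    measures: list[SyllableMeasure],
    types: list[int],
    intervals: list[SyllableInterval],
) -> SongFeatureVector:
    """The 16 song features from measured syllables and their type labels."""
    if not measures:
        raise ValueError("zero syllables: song excluded")
    if not (len(measures) == len(types) == len(intervals)):
        raise ValueError("measures, types, and intervals must pair up")
    n = len(measures)
    bout = intervals[-1].offset_ms - intervals[0].onset_ms
    durations = np.array([m.duration_ms for m in measures])
    uppers = np.array([m.f_upper_hz for m in measures])
    lowers = np.array([m.f_lower_hz for m in measures])
    ranges = uppers - lowers
    n_unique = len(set(types))
    return SongFeatureVector(
        bout_duration_ms=bout,
        n_syllables=float(n),
        syllable_rate_per_ms=n / bout,
        smallest_syllable_ms=float(durations.min()),
        largest_syllable_ms=float(durations.max()),
        mean_syllable_ms=float(durations.mean()),
        n_unique_syllables=float(n_unique),
        syllable_repetition=n / n_unique,
        avg_upper_freq_hz=float(uppers.mean()),
        avg_lower_freq_hz=float(lowers.mean()),
        max_freq_hz=float(uppers.max()),
        min_freq_hz=float(lowers.min()),
        overall_freq_range_hz=float(uppers.max() - lowers.min()),
        largest_syll_freq_range_hz=float(ranges.max()),
        smallest_syll_freq_range_hz=float(ranges.min()),
        # Clamp: the float mean of identical ranges can exceed max by 1 ulp.
        avg_syll_freq_range_hz=float(np.clip(ranges.mean(), ranges.min(), ranges.max())),
    )


def feature_vector_from_spec(spec) -> SongFeatureVector:
    """Ground-truth 16-feature vector computed from a planned song.

    Operates on the synthesizer's planned syllable list (a
    :class:`towheesong.synth.SongSpec`) rather than audio; used as the fast
    path and oracle for large statistical simulations.
    """
    sylls = spec.syllables
    if not sylls:
        raise ValueError("zero syllables: song excluded")
    n = len(sylls)
    onsets = np.array([s.onset_ms for s in sylls])
    durations = np.array([s.duration_ms for s in sylls])
    uppers = np.array([s.f_high_hz for s in sylls])
    lowers = np.array([s.f_low_hz for s in sylls])
    ranges = uppers - lowers
    bout = (onsets[-1] + durations[-1]) - onsets[0]
    n_unique = len({s.type_id for s in sylls})
    return SongFeatureVector(
        bout_duration_ms=float(bout),
        n_syllables=float(n),
        syllable_rate_per_ms=n / bout,
        smallest_syllable_ms=float(durations.min()),
        largest_syllable_ms=float(durations.max()),
        mean_syllable_ms=float(durations.mean()),
        n_unique_syllables=float(n_unique),
        syllable_repetition=n / n_unique,
        avg_upper_freq_hz=float(uppers.mean()),
        avg_lower_freq_hz=float(lowers.mean()),
        max_freq_hz=float(uppers.max()),
        min_freq_hz=float(lowers.min()),
        overall_freq_range_hz=float(uppers.max() - lowers.min()),
        largest_syll_freq_range_hz=float(ranges.max()),
        smallest_syll_freq_range_hz=float(ranges.min()),
        # Clamp: the float mean of identical ranges can exceed max by 1 ulp.
        avg_syll_freq_range_hz=float(np.clip(ranges.mean(), ranges.min(), ranges.max())),
    )


def log_transform_features(vectors: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Element-wise natural log; rejects non-positive entries by name."""
    if isinstance(vectors, pd.DataFrame):
        bad = [c for c in vectors.columns if (vectors[c] <= 0).any()]
        if bad:
            raise ValueError(f"non-positive values in features: {bad}")
        return np.log(vectors)
    arr = np.asarray(vectors, dtype=float)
    if (arr <= 0).any():
        cols = np.flatnonzero((arr <= 0).any(axis=0)) if arr.ndim == 2 else []
        names = [FEATURE_NAMES[c] for c in cols if c < len(FEATURE_NAMES)]
        raise ValueError(f"non-positive values in features: {names or 'input'}")
    return np.log(arr)
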