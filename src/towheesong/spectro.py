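"""Spectrogram computation and syllable segmentation.

A song bout is segmented into syllables -- periods of sound separated by
periods of silence -- by binarizing a peak-normalized dB spectrogram at a
power quantile, reducing the binary mask to a per-frame presence profile,
and applying minimum-silence / minimum-syllable duration rules.  A second
pass removes small connected components of the mask as noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

TARGET_RATE = 44100

#: Minimum connected-component size (matrix elements) for a note to be kept,
#: by species label; ``None`` key is the global fallback.
NOISE_ELEMENT_THRESHOLDS = {"spotted": 87, "eastern": 70, "hybrid_unsure": 65, None: 65}

#: Per-species percent-overlap thresholds used by the typing stage live in
#: :mod:`towheesong.features`; segmentation params here.

_DB_FLOOR = -200.0


@dataclass
class SegmentationParams:
    """Tunable segmentation knobs.

    ``signal_quantile`` is the fraction of in-band spectrogram elements kept
    as signal (binarization at the ``1 - signal_quantile`` power quantile).
    ``presence_factor`` scales the by-chance expected per-column element
    count to decide whether a frame counts as sound, which suppresses
    speckle columns.  ``min_contrast_db`` is the minimum height of the
    binarization threshold above the median in-band power for the
    spectrogram to be treated as containing signal at all; a quantile
    threshold on pure noise sits only a few dB above the median, so
    signal-free input yields zero intervals.
    """

    signal_quantile: float = 0.10
    min_syllable_ms: float = 12.0
    min_silence_ms: float = 10.0
    hp_hz: float = 1000.0
    lp_hz: float = 10000.0
    noise_element_threshold: int = 65
    presence_factor: float = 0.5
    min_contrast_db: float = 25.0
    dynamic_range_db: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_quantile < 1.0:
            raise ValueError("signal_quantile must be in (0, 1)")
        if self.min_syllable_ms <= 0 or self.min_silence_ms <= 0:
            raise ValueError("minimum durations must be positive")
        if not self.hp_hz < self.lp_hz:
            raise ValueError("hp_hz must be below lp_hz")
        if self.noise_element_threshold < 1:
            raise ValueError("noise_element_threshold must be >= 1")

    @classmethod
    def for_species(cls, species: str | None, **overrides) -> "SegmentationParams":
        thr = NOISE_ELEMENT_THRESHOLDS.get(species, NOISE_ELEMENT_THRESHOLDS[None])
        overrides.setdefault("noise_element_threshold", thr)
        return cls(**overrides)


@dataclass
class Spectrogram:
    """dB power spectrogram: frequency bins x time frames."""

    power: np.ndarray  # (n_freq, n_time), dB
    freq_axis: np.ndarray  # Hz per bin, strictly increasing
    time_axis: np.ndarray  # ms per frame center, strictly increasing
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freq_axis), len(self.time_axis)):
            raise ValueError("power shape does not match axes")
        if np.any(np.diff(self.freq_axis) <= 0) or np.any(np.diff(self.time_axis) <= 0):
            raise ValueError("axes must be strictly increasing")

    @property
    def hop_ms(self) -> float:
        return self.params["hop"] / self.params["sample_rate"] * 1000.0

    @property
    def band_mask(self) -> np.ndarray:
        """Boolean frequency-bin mask of the retained band-pass band."""
        hp = self.params.get("hp_hz")
        lp = self.params.get("lp_hz")
        mask = np.ones(len(self.freq_axis), dtype=bool)
        if hp is not None:
            mask &= self.freq_axis >= hp
        if lp is not None:
            mask &= self.freq_axis <= lp
        return mask


@dataclass
class SyllableInterval:
    """Half-open [onset, offset) interval measured from bout start (ms)."""

    onset_ms: float
    offset_ms: float
    onset_col: int = 0
    offset_col: int = 0

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def resample_to_44100(waveform: np.ndarray, in_rate: int) -> np.ndarray:
    """Resample to 44,100 Hz with anti-alias low-pass at the lower Nyquist."""
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty waveform")
    if in_rate <= 0:
        raise ValueError("in_rate must be positive")
    if in_rate == TARGET_RATE:
        return x.copy()
    g = math.gcd(TARGET_RATE, int(in_rate))
    up, down = TARGET_RATE // g, int(in_rate) // g
    # resample_poly's polyphase FIR cuts at min(1/up, 1/down) * Nyquist,
    # i.e. at half the lower of the two sampling rates.
    return signal.resample_poly(x, up, down)


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate: int = TARGET_RATE,
    window: int = 512,
    hop: int = 128,
    hp_hz: float | None = None,
    lp_hz: float | None = None,
) -> Spectrogram:
    """Peak-normalized short-time Fourier magnitude in dB.

    The waveform is peak-normalized before the transform (per-song amplitude
    normalization).  When a band-pass is requested the out-of-band bins are
    forced to the dB floor.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty waveform")
    if x.size < window:
        raise ValueError("window longer than waveform")
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    freqs, times, stft = signal.stft(
        x,
        fs=sample_rate,
        window="hann",
        nperseg=window,
        noverlap=window - hop,
        boundary=None,
        padded=False,
    )
    power = 20.0 * np.log10(np.abs(stft) + 1e-12)
    power = np.maximum(power, _DB_FLOOR)
    params = {
        "window": window,
        "hop": hop,
        "sample_rate": sample_rate,
        "hp_hz": hp_hz,
        "lp_hz": lp_hz,
    }
    spec = Spectrogram(power, freqs, times * 1000.0, params)
    if hp_hz is not None or lp_hz is not None:
        spec.power = spec.power.copy()
        spec.power[~spec.band_mask, :] = _DB_FLOOR
    return spec


def binary_mask(spec: Spectrogram, p: SegmentationParams) -> tuple[np.ndarray, float]:
    """Boolean signal mask plus the spectrogram's dB contrast.

    The threshold is the ``1 - signal_quantile`` quantile of the in-band
    dB values, so the top ``signal_quantile`` fraction of in-band elements
    is kept.  The returned contrast (max minus median in-band power) is
    ~10 dB for signal-free noise and tens of dB for real songs; it backs
    the ``min_contrast_db`` signal-free short-circuit.
    """
    band = spec.band_mask.copy()
    band &= (spec.freq_axis >= p.hp_hz) & (spec.freq_axis <= p.lp_hz)
    if not band.any():
        raise ValueError("band-pass removes every frequency bin")
    inband = spec.power[band, :]
    # Quantile threshold, floored so weak side lobes far below the peak
    # never count as signal however sparse the song is.
    thr = max(
        np.quantile(inband, 1.0 - p.signal_quantile),
        inband.max() - p.dynamic_range_db,
    )
    contrast = float(inband.max() - np.median(inband))
    mask = np.zeros_like(spec.power, dtype=bool)
    mask[band, :] = inband >= thr
    return mask, contrast


def _presence_profile(mask: np.ndarray, spec: Spectrogram, p: SegmentationParams) -> np.ndarray:
    colsum = mask.sum(axis=0)
    # Expected per-column count if kept elements were uniform speckle.
    chance = mask.sum() / mask.shape[1]
    presence_min = max(1, int(math.ceil(p.presence_factor * chance)))
    return colsum >= presence_min


def _runs(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_1d.view(np.int8), [0]))))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def segment_syllables(spec: Spectrogram, p: SegmentationParams) -> list[SyllableInterval]:
    """Segment a spectrogram into sorted, disjoint syllable intervals.

    Silences shorter than ``min_silence_ms`` are merged into flanking sound;
    sounds shorter than ``min_syllable_ms`` are then discarded.  An empty
    list is a valid result.
    """
    mask, contrast = binary_mask(spec, p)
    if contrast < p.min_contrast_db:
        return []  # signal-free: threshold sits inside the noise bulk
    presence = _presence_profile(mask, spec, p)
    hop_ms = spec.hop_ms
    min_silence_cols = max(1, int(round(p.min_silence_ms / hop_ms)))
    min_syllable_cols = max(1, int(round(p.min_syllable_ms / hop_ms)))

    runs = _runs(presence)
    if not runs:
        return []
    # Merge runs separated by short silences.
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < min_silence_cols:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    out: list[SyllableInterval] = []
    win_ms = spec.params["window"] / spec.params["sample_rate"] * 1000.0
    for start, stop in merged:
        if stop - start < min_syllable_cols:
            continue
        onset_ms = start * hop_ms + win_ms / 2.0
        offset_ms = stop * hop_ms + win_ms / 2.0
        out.append(SyllableInterval(onset_ms, offset_ms, start, stop))
    return out


def filter_noise_components(
    spec: Spectrogram,
    intervals: list[SyllableInterval],
    p: SegmentationParams,
) -> tuple[list[SyllableInterval], list[np.ndarray]]:
    """Drop small connected mask components within each interval as noise.

    Connected components (8-connectivity) of the binary mask restricted to
    each interval are counted; components with fewer than
    ``noise_element_threshold`` elements are removed.  Intervals whose mask
    becomes empty are dropped; surviving intervals are trimmed to the time
    extent of the retained mask and re-validated against ``min_syllable_ms``.

    Returns the retained intervals and, per interval, the retained boolean
    mask (full frequency height x interval width).
    """
    mask, _ = binary_mask(spec, p)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    hop_ms = spec.hop_ms
    win_ms = spec.params["window"] / spec.params["sample_rate"] * 1000.0
    kept: list[SyllableInterval] = []
    masks: list[np.ndarray] = []
    for iv in intervals:
        sub = mask[:, iv.onset_col : iv.offset_col].copy()
        labels, n = ndimage.label(sub, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())[1:]
        drop = np.flatnonzero(counts < p.noise_element_threshold) + 1
        if len(drop):
            sub[np.isin(labels, drop)] = False
        if not sub.any():
            continue
        cols = np.flatnonzero(sub.any(axis=0))
        c0, c1 = int(cols[0]), int(cols[-1]) + 1
        width_ms = (c1 - c0) * hop_ms
        if width_ms < p.min_syllable_ms:
            continue
        start = iv.onset_col + c0
        stop = iv.onset_col + c1
        kept.append(
            SyllableInterval(
                start * hop_ms + win_ms / 2.0,
                stop * hop_ms + win_ms / 2.0,
                start,
                stop,
            )
        )
        masks.append(sub[:, c0:c1])
    return kept, masks


def export_spectrogram_image(
    waveform: np.ndarray,
    out_path: str | Path,
    sample_rate: int = TARGET_RATE,
    size: tuple[int, int] = (224, 224),
    cmap: str = "magma",
) -> Path:
    """Render a band-passed [1000, 10000] Hz spectrogram to an RGB PNG.

    The image is ``size`` pixels (default 224 x 224), three color channels,
    deterministic color map, no axes or margins.
    """
    from matplotlib import colormaps
    from PIL import Image

    spec = compute_spectrogram(
        np.asarray(waveform, dtype=np.float64),
        sample_rate=sample_rate,
        hp_hz=1000.0,
        lp_hz=10000.0,
    )
    band = spec.band_mask
    img = spec.power[band, :]
    lo, hi = img.min(), img.max()
    norm = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    rgba = colormaps[cmap](norm[::-1, :])  # low freq at bottom
    rgb8 = (rgba[:, :, :3] * 255).round().astype(np.uint8)
    out = Image.fromarray(rgb8).resize(size, resample=Image.BILINEAR)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out.save(out_path, format="PNG")
    return out_path


def segmentation_to_json(
    intervals: list[SyllableInterval],
    params: SegmentationParams,
    component_counts: list[int] | None = None,
) -> str:
    """Serialize a segmentation result (params echoed) to JSON."""
    payload = {
        "params": asdict(params),
        "intervals": [
            {"onset_ms": iv.onset_ms, "offset_ms": iv.offset_ms} for iv in intervals
        ],
        "retained_component_counts": component_counts,
    }
    return json.dumps(payload, sort_keys=True)
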