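"""Synthetic towhee-like songs, geographic sampling, and sequence alignments.

Every downstream stage is testable without downloads: songs are planned as
an explicit syllable list (the ground truth), rendered to audio as
Hann-windowed tones / linear chirps over white noise, and sampled across a
longitudinal two-species cline with a configurable zone of co-occurrence
and a hybrid fraction inside it.  A companion generator emits
two-population nucleotide alignments with tunable between/within diversity.

The generated songs follow the canonical structure of short introductory
notes followed by a fast trill; the western species occasionally fuses its
trill into one unbroken syllable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .geo import HYBRID_LABEL, DEFAULT_OVERLAP_ZONE, GeoRecord, OverlapZone
from .popgen import Alignment

SAMPLE_RATE = 44100

_MONTH_DAYS = {1: 31, 2: 28, 3: 31, 4: 30, 5: 31, 6: 30, 7: 31, 8: 31,
               9: 30, 10: 31, 11: 30, 12: 31}


@dataclass(frozen=True)
class Syllable:
    """One planned syllable: type id, timing (ms), band (Hz), and shape."""

    type_id: int
    onset_ms: float
    duration_ms: float
    f_low_hz: float
    f_high_hz: float
    shape: str  # "tone" | "chirp"

    def __post_init__(self) -> None:
        if self.shape not in {"tone", "chirp"}:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.f_low_hz < self.f_high_hz < SAMPLE_RATE / 2:
            raise ValueError("need 0 < f_low < f_high < Nyquist")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class SpeciesProfile:
    """Song-parameter distributions for one species."""

    label: str
    intro_count_range: tuple[int, int] = (2, 4)
    trill_count_range: tuple[int, int] = (6, 12)
    trill_syllable_ms: tuple[float, float] = (45.0, 6.0)  # mean, sd
    trill_gap_ms: tuple[float, float] = (35.0, 6.0)
    f_low_hz: tuple[float, float] = (2600.0, 200.0)
    f_high_hz: tuple[float, float] = (6000.0, 250.0)
    n_types: float = 4.0
    cline_slope: dict[str, float] = field(default_factory=dict)
    single_syllable_trill_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.f_low_hz[0] < self.f_high_hz[0] < SAMPLE_RATE / 2:
            raise ValueError("need 0 < f_low < f_high < Nyquist")
        if self.trill_syllable_ms[0] <= 0 or self.trill_gap_ms[0] <= 0:
            raise ValueError("durations and gaps must be positive")
        if not 0.0 <= self.single_syllable_trill_prob <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")

    def shifted(self, longitude: float, ref_lon: float) -> "SpeciesProfile":
        """Profile with means shifted by cline_slope * (lon - ref)."""
        if not self.cline_slope:
            return self
        delta = longitude - ref_lon
        out = dataclasses.replace(self)
        for name, slope in self.cline_slope.items():
            value = getattr(out, name)
            if isinstance(value, tuple):
                setattr(out, name, (value[0] + slope * delta, value[1]))
            else:
                setattr(out, name, value + slope * delta)
        return out


def midpoint_profile(a: SpeciesProfile, b: SpeciesProfile, label: str = HYBRID_LABEL) -> SpeciesProfile:
    """Hybrid profile: parameter means midway between the two species."""
    def mid(x, y):
        return ((x[0] + y[0]) / 2.0, (x[1] + y[1]) / 2.0)

    slopes = {
        k: (a.cline_slope.get(k, 0.0) + b.cline_slope.get(k, 0.0)) / 2.0
        for k in set(a.cline_slope) | set(b.cline_slope)
    }
    return SpeciesProfile(
        label=label,
        intro_count_range=(
            round((a.intro_count_range[0] + b.intro_count_range[0]) / 2),
            round((a.intro_count_range[1] + b.intro_count_range[1]) / 2),
        ),
        trill_count_range=(
            round((a.trill_count_range[0] + b.trill_count_range[0]) / 2),
            round((a.trill_count_range[1] + b.trill_count_range[1]) / 2),
        ),
        trill_syllable_ms=mid(a.trill_syllable_ms, b.trill_syllable_ms),
        trill_gap_ms=mid(a.trill_gap_ms, b.trill_gap_ms),
        f_low_hz=mid(a.f_low_hz, b.f_low_hz),
        f_high_hz=mid(a.f_high_hz, b.f_high_hz),
        n_types=(a.n_types + b.n_types) / 2.0,
        cline_slope=slopes,
        single_syllable_trill_prob=(a.single_syllable_trill_prob + b.single_syllable_trill_prob) / 2.0,
    )


#: Western species: fewer or no intro notes, faster trill, occasional fused trill.
SPOTTED_PROFILE = SpeciesProfile(
    label="spotted",
    intro_count_range=(0, 2),
    trill_count_range=(8, 16),
    trill_syllable_ms=(30.0, 4.0),
    trill_gap_ms=(26.0, 4.0),
    f_low_hz=(3100.0, 200.0),
    f_high_hz=(6800.0, 250.0),
    n_types=3.0,
    single_syllable_trill_prob=0.10,
)

#: Eastern species: more intro notes, slower trill.
EASTERN_PROFILE = SpeciesProfile(
    label="eastern",
    intro_count_range=(2, 4),
    trill_count_range=(6, 12),
    trill_syllable_ms=(45.0, 6.0),
    trill_gap_ms=(38.0, 6.0),
    f_low_hz=(2600.0, 200.0),
    f_high_hz=(6000.0, 250.0),
    n_types=4.0,
)


@dataclass
class SongSpec:
    """A planned song: species label, location, seed, and syllable list."""

    species: str
    longitude: float
    latitude: float
    seed: int
    syllables: list[Syllable]

    def __post_init__(self) -> None:
        onsets = [s.onset_ms for s in self.syllables]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onsets must be strictly increasing")
        for a, b in zip(self.syllables, self.syllables[1:]):
            if b.onset_ms < a.offset_ms:
                raise ValueError("syllable intervals must not overlap")
        type_ids = sorted({s.type_id for s in self.syllables})
        if type_ids and type_ids != list(range(len(type_ids))):
            raise ValueError("type ids must be dense from 0")

    @property
    def end_ms(self) -> float:
        return self.syllables[-1].offset_ms if self.syllables else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species,
                "longitude": self.longitude,
                "latitude": self.latitude,
                "seed": self.seed,
                "syllables": [dataclasses.asdict(s) for s in self.syllables],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SongSpec":
        d = json.loads(text)
        sylls = [Syllable(**s) for s in d.pop("syllables")]
        return cls(syllables=sylls, **d)


@dataclass
class SyntheticRecording:
    """Rendered waveform plus the spec that produced it and its metadata."""

    waveform: np.ndarray
    sample_rate: int
    truth: SongSpec
    metadata: GeoRecord | None = None

    def __post_init__(self) -> None:
        if np.max(np.abs(self.waveform)) > 1.0 + 1e-9:
            raise ValueError("waveform amplitude must stay in [-1, 1]")
        dur_ms = len(self.waveform) / self.sample_rate * 1000.0
        if self.truth.end_ms > dur_ms + 1e-6:
            raise ValueError("truth intervals extend past the waveform")


@dataclass
class PopulationModel:
    """Two-species longitudinal cline with a zone of co-occurrence."""

    profiles: tuple[SpeciesProfile, SpeciesProfile] = (SPOTTED_PROFILE, EASTERN_PROFILE)
    range_west: tuple[float, float] = (-125.0, -91.0)
    range_east: tuple[float, float] = (-102.0, -67.0)
    overlap_zone: OverlapZone = DEFAULT_OVERLAP_ZONE
    hybrid_fraction: float = 0.025
    n_recordings: int = 200
    noise_floor_db: float = -50.0
    lat_range: tuple[float, float] = (30.0, 48.0)
    off_season_fraction: float = 0.0
    converted_fraction: float = 0.3
    year: int = 2020

    def __post_init__(self) -> None:
        if not 0.0 <= self.hybrid_fraction <= 1.0:
            raise ValueError("hybrid_fraction must be in [0, 1]")
        lo = min(self.range_west[0], self.range_east[0])
        hi = max(self.range_west[1], self.range_east[1])
        if not (lo <= self.overlap_zone.west_deg and self.overlap_zone.east_deg <= hi):
            raise ValueError("overlap zone must lie inside the union of ranges")

    @property
    def west_profile(self) -> SpeciesProfile:
        return self.profiles[0]

    @property
    def east_profile(self) -> SpeciesProfile:
        return self.profiles[1]


@dataclass
class GeneticModel:
    """Two-population alignment generator settings."""

    n_per_pop: tuple[int, int] = (10, 10)
    seq_length: int = 600
    fixed_diffs: int = 10
    within_poly_rate: float = 0.01
    seed: int = 0
    pop_labels: tuple[str, str] = ("west", "east")
    coord_centers: tuple[tuple[float, float], tuple[float, float]] = ((40.0, -115.0), (38.0, -80.0))

    def __post_init__(self) -> None:
        if self.fixed_diffs > self.seq_length:
            raise ValueError("fixed_diffs cannot exceed seq_length")
        if not 0.0 <= self.within_poly_rate <= 1.0:
            raise ValueError("within_poly_rate must be in [0, 1]")
        if min(self.n_per_pop) < 1:
            raise ValueError("each population needs at least one sequence")


def build_song_spec(
    profile: SpeciesProfile,
    longitude: float,
    latitude: float,
    seed: int,
    ref_lon: float = -96.5,
) -> SongSpec:
    """Plan one song from a species profile (cline applied at ``longitude``)."""
    rng = np.random.default_rng(seed)
    prof = profile.shifted(longitude, ref_lon)

    f_lo = max(300.0, rng.normal(*prof.f_low_hz))
    f_hi = rng.normal(*prof.f_high_hz)
    f_hi = max(f_hi, f_lo + 800.0)

    sylls: list[Syllable] = []
    t = 100.0
    n_intro = int(rng.integers(prof.intro_count_range[0], prof.intro_count_range[1] + 1))
    span = f_hi - f_lo
    for i in range(n_intro):
        center = f_lo + (i + 0.7) * span / (n_intro + 1) + rng.normal(0, 40)
        dur = max(40.0, rng.normal(85.0, 14.0))
        if rng.random() < 0.5:
            syl = Syllable(i, t, dur, max(300.0, center - 50.0), center + 50.0, "tone")
        else:
            half = max(150.0, rng.normal(300.0, 60.0))
            syl = Syllable(i, t, dur, max(300.0, center - half), center + half, "chirp")
        sylls.append(syl)
        t += dur + max(30.0, rng.normal(65.0, 14.0))

    n_trill = int(rng.integers(prof.trill_count_range[0], prof.trill_count_range[1] + 1))
    trill_dur = max(14.0, rng.normal(*prof.trill_syllable_ms))
    trill_gap = max(16.0, rng.normal(*prof.trill_gap_ms))
    trill_type = n_intro
    if rng.random() < prof.single_syllable_trill_prob:
        fused = n_trill * trill_dur + (n_trill - 1) * trill_gap
        sylls.append(Syllable(trill_type, t, fused, f_lo, f_hi, "chirp"))
    else:
        for _ in range(n_trill):
            sylls.append(Syllable(trill_type, t, trill_dur, f_lo, f_hi, "chirp"))
            t += trill_dur + trill_gap
    return SongSpec(profile.label, longitude, latitude, int(seed), sylls)


def synthesize_song(
    spec: SongSpec,
    noise_floor_db: float = -50.0,
    duration_ms: float | None = None,
    sample_rate: int = SAMPLE_RATE,
) -> SyntheticRecording:
    """Render a planned song to a peak-normalized mono waveform.

    Each syllable is a Hann-windowed constant tone (at the band midpoint) or
    linear chirp (f_low -> f_high); additive white noise sits at
    ``noise_floor_db`` relative to the peak syllable amplitude, and the
    final waveform is peak-normalized to 0.9.
    """
    if duration_ms is None:
        duration_ms = spec.end_ms + 120.0
    if spec.syllables and spec.end_ms > duration_ms:
        raise ValueError("syllables extend past requested bout duration")
    n = int(round(duration_ms / 1000.0 * sample_rate))
    clean = np.zeros(n)
    for s in spec.syllables:
        i0 = int(round(s.onset_ms / 1000.0 * sample_rate))
        i1 = int(round(s.offset_ms / 1000.0 * sample_rate))
        i1 = min(i1, n)
        m = i1 - i0
        if m <= 0:
            continue
        tt = np.arange(m) / sample_rate
        if s.shape == "tone":
            f0 = (s.f_low_hz + s.f_high_hz) / 2.0
            tone = np.sin(2 * np.pi * f0 * tt)
        else:
            sweep = (s.f_high_hz - s.f_low_hz) / (m / sample_rate)
            phase = 2 * np.pi * (s.f_low_hz * tt + 0.5 * sweep * tt**2)
            tone = np.sin(phase)
        clean[i0:i1] += np.hanning(m) * tone
    peak = np.max(np.abs(clean)) if spec.syllables else 1.0
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, peak * 10 ** (noise_floor_db / 20.0), size=n)
    wave = clean + noise
    wave = wave / np.max(np.abs(wave)) * 0.9
    return SyntheticRecording(wave, sample_rate, spec)


def _draw_date(rng: np.random.Generator, year: int, off_season: bool) -> str:
    months = [m for m in range(1, 13) if (m < 4 or m > 8) == off_season]
    month = int(rng.choice(months))
    day = int(rng.integers(1, _MONTH_DAYS[month] + 1))
    return f"{year:04d}-{month:02d}-{day:02d}"


def sample_population(
    model: PopulationModel,
    seed: int,
    n: int | None = None,
) -> list[tuple[SongSpec, GeoRecord]]:
    """Draw a corpus of planned songs with metadata from the cline model.

    Species are drawn by longitude: pure western species west of the
    overlap zone, pure eastern species east of it, and a linear mixture
    inside; hybrids (parameter-midpoint songs, labelled ``hybrid_unsure``)
    are drawn with ``hybrid_fraction`` inside the zone only.
    """
    n = model.n_recordings if n is None else n
    if n <= 0:
        raise ValueError("n_recordings must be positive")
    rng = np.random.default_rng(seed)
    zone = model.overlap_zone
    west_p, east_p = model.west_profile, model.east_profile
    hybrid_p = midpoint_profile(west_p, east_p)
    ref_lon = (zone.west_deg + zone.east_deg) / 2.0
    lo = min(model.range_west[0], model.range_east[0])
    hi = max(model.range_west[1], model.range_east[1])
    out = []
    for i in range(n):
        lon = float(rng.uniform(lo, hi))
        lat = float(rng.uniform(*model.lat_range))
        if lon < zone.west_deg:
            profile = west_p
        elif lon >= zone.east_deg:
            profile = east_p
        else:
            if rng.random() < model.hybrid_fraction:
                profile = hybrid_p
            else:
                p_east = (lon - zone.west_deg) / (zone.east_deg - zone.west_deg)
                profile = east_p if rng.random() < p_east else west_p
        song_seed = int(rng.integers(0, 2**31 - 1))
        spec = build_song_spec(profile, lon, lat, song_seed, ref_lon=ref_lon)
        off_season = rng.random() < model.off_season_fraction
        record = GeoRecord(
            id=f"syn{i:05d}",
            species=profile.label,
            date=_draw_date(rng, model.year, off_season),
            latitude=lat,
            longitude=lon,
            conversion_status="converted" if rng.random() < model.converted_fraction else "unconverted",
        )
        out.append((spec, record))
    return out


def generate_dataset(
    model: PopulationModel,
    seed: int,
    out_dir: str | Path,
    n: int | None = None,
) -> pd.DataFrame:
    """Render a corpus to disk: WAVs, truth JSONs, and a metadata CSV.

    Returns the metadata table (one row per recording, including the
    truth-file path).  Deterministic for a fixed (model, seed).
    """
    out_dir = Path(out_dir)
    audio_dir = out_dir / "audio"
    truth_dir = out_dir / "truth"
    try:
        audio_dir.mkdir(parents=True, exist_ok=True)
        truth_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for spec, record in sample_population(model, seed, n=n):
        rec = synthesize_song(spec, noise_floor_db=model.noise_floor_db)
        wav_path = audio_dir / f"{record.id}.wav"
        truth_path = truth_dir / f"{record.id}.json"
        try:
            wavfile.write(str(wav_path), rec.sample_rate, (rec.waveform * 32767).astype(np.int16))
            truth_path.write_text(spec.to_json())
        except OSError as exc:
            raise OSError(f"failed writing {wav_path}: {exc}") from exc
        rows.append(
            {
                "id": record.id,
                "species": record.species,
                "date": record.date,
                "latitude": record.latitude,
                "longitude": record.longitude,
                "conversion_status": record.conversion_status,
                "audio_path": str(wav_path),
                "truth_path": str(truth_path),
            }
        )
    meta = pd.DataFrame(rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    return meta


def generate_alignment(gm: GeneticModel) -> Alignment:
    """Two-population alignment from a shared random ancestor.

    ``fixed_diffs`` sites are flipped in every member of population 2;
    each individual then mutates each site independently with probability
    ``within_poly_rate``.
    """
    rng = np.random.default_rng(gm.seed)
    bases = np.array(list("ACGT"))
    ancestor = rng.choice(bases, size=gm.seq_length)
    fixed_sites = rng.choice(gm.seq_length, size=gm.fixed_diffs, replace=False)
    pop2_base = ancestor.copy()
    for j in fixed_sites:
        alternatives = bases[bases != ancestor[j]]
        pop2_base[j] = rng.choice(alternatives)

    ids, seqs, labels, coords = [], [], [], []
    for pop_idx, (n_pop, base_seq) in enumerate(zip(gm.n_per_pop, (ancestor, pop2_base))):
        label = gm.pop_labels[pop_idx]
        lat0, lon0 = gm.coord_centers[pop_idx]
        for k in range(n_pop):
            seq = base_seq.copy()
            hits = np.flatnonzero(rng.random(gm.seq_length) < gm.within_poly_rate)
            for j in hits:
                alternatives = bases[bases != seq[j]]
                seq[j] = rng.choice(alternatives)
            ids.append(f"{label}_{k:02d}")
            seqs.append("".join(seq))
            labels.append(label)
            coords.append((lat0 + float(rng.normal(0, 1.5)), lon0 + float(rng.normal(0, 2.5))))
    return Alignment(ids, seqs, labels, coords)
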