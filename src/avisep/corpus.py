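"""Clip ingestion, standardization and synthetic birdsong fixtures.

Passive acoustic monitoring pipelines work on short fixed-length clips: every
recording is resampled to a canonical 16 kHz mono representation and cut into
4-second segments before mixing, training or scoring.  This module owns that
standardization, the group-aware train/valid/test partitioning (clips cut from
the same recording must never straddle partitions), and a fully synthetic
corpus generator — band-limited frequency-modulated songs plus wind / rain /
insect background noise — so the whole pipeline can be exercised without any
field recordings.

Two built-in species profiles mirror the vocal bands of a nocturnal ardeid
(fundamental between 1 and 2 kHz) and a diurnal wagtail-like passerine
(3–7 kHz); two more fill intermediate bands so that mixtures of up to four
acoustically distinct species can be simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfilt

CANONICAL_RATE = 16_000
CLIP_SECONDS = 4.0
#: crops below this RMS are treated as silence and dropped (automatic stand-in
#: for manual spectrogram screening of low-quality segments)
RMS_GATE = 1e-4

__all__ = [
    "CANONICAL_RATE",
    "CLIP_SECONDS",
    "AudioClip",
    "SpeciesProfile",
    "SplitAssignment",
    "DEFAULT_PROFILES",
    "resample_mono",
    "standardize_clip_set",
    "synth_song",
    "synth_noise",
    "partition_dataset",
    "make_synthetic_corpus",
    "read_wav",
    "write_wav",
]


@dataclass
class AudioClip:
    """A fixed-length mono waveform in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int = CANONICAL_RATE
    recording_id: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip holds mono waveforms")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def validate(self) -> "AudioClip":
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-12:
            raise ValueError("samples exceed [-1, 1]")
        return self


@dataclass
class SpeciesProfile:
    """Parametric syllable model for one synthetic species.

    ``band`` bounds the fundamental; syllables are linear chirps whose slope,
    duration, and spacing are drawn from the stated ranges.
    """

    name: str
    band: tuple[float, float]
    chirp_slope: tuple[float, float] = (-2000.0, 2000.0)  # Hz per second
    syllable_dur: tuple[float, float] = (0.05, 0.15)  # seconds
    gap_dur: tuple[float, float] = (0.03, 0.12)  # seconds
    harmonics: int = 1

    def validate(self, sample_rate: int = CANONICAL_RATE) -> "SpeciesProfile":
        lo, hi = self.band
        if not (0.0 < lo < hi < sample_rate / 2):
            raise ValueError(f"band {self.band} outside (0, Nyquist) at {sample_rate} Hz")
        return self


#: four acoustically distinct synthetic species; the first emulates the 1–2 kHz
#: nocturnal heron band and the last the 3–7 kHz diurnal wagtail band.
DEFAULT_PROFILES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("night_heron", (1000.0, 2000.0), chirp_slope=(-800.0, 800.0),
                   syllable_dur=(0.08, 0.2), gap_dur=(0.1, 0.3)),
    SpeciesProfile("reed_warbler", (2200.0, 3200.0)),
    SpeciesProfile("bulbul", (3500.0, 5000.0), chirp_slope=(-4000.0, 4000.0)),
    SpeciesProfile("white_wagtail", (5200.0, 7000.0), chirp_slope=(-6000.0, 6000.0),
                   syllable_dur=(0.04, 0.1), gap_dur=(0.02, 0.08)),
)


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive item -> partition mapping honouring recording groups."""

    assignment: dict[str, str]
    ratios: tuple[float, ...] = (7.0, 2.0, 1.0)
    partitions: tuple[str, ...] = ("train", "valid", "test")

    def items_in(self, partition: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == partition]

    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in self.partitions}
        for v in self.assignment.values():
            out[v] += 1
        return out


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def resample_mono(waveform: np.ndarray, src_rate: int,
                  target_rate: int = CANONICAL_RATE) -> AudioClip:
    """Average channels to mono and band-limit-resample to ``target_rate``.

    Uses a polyphase windowed-sinc filter, so anti-aliasing is built in; a
    source already at the target rate passes through untouched.
    """
    wav = np.asarray(waveform, dtype=np.float64)
    if wav.size == 0:
        raise ValueError("empty waveform")
    if src_rate <= 0:
        raise ValueError("sample rate must be positive")
    if wav.ndim == 2:
        wav = wav.mean(axis=1)
    elif wav.ndim != 1:
        raise ValueError("waveform must be 1-D or 2-D (frames x channels)")
    if src_rate != target_rate:
        ratio = Fraction(target_rate, int(src_rate))
        wav = resample_poly(wav, ratio.numerator, ratio.denominator)
    return AudioClip(np.clip(wav, -1.0, 1.0), sample_rate=target_rate)


def standardize_clip_set(recording: AudioClip, rng_seed: int,
                         clip_seconds: float = CLIP_SECONDS) -> list[AudioClip]:
    """Cut a standardized recording into independent fixed-length crops.

    Long files are truncated to 16 s and yield two independent crops; files
    between 4 and 8 s yield one; anything shorter is discarded.  Crops under
    the silence gate (RMS < 1e-4) are dropped.
    """
    if recording.sample_rate != CANONICAL_RATE:
        raise ValueError("standardize_clip_set expects a 16 kHz recording")
    rng = np.random.default_rng(rng_seed)
    sr = recording.sample_rate
    clip_len = int(round(clip_seconds * sr))
    samples = recording.samples
    max_len = int(round(16.0 * sr))
    if len(samples) > max_len:
        samples = samples[:max_len]
    dur = len(samples) / sr
    if dur < clip_seconds:
        return []
    n_crops = 1 if dur <= 2 * clip_seconds else 2
    clips: list[AudioClip] = []
    for _ in range(n_crops):
        start = int(rng.integers(0, len(samples) - clip_len + 1))
        crop = samples[start:start + clip_len].copy()
        if math.sqrt(float(np.mean(crop ** 2))) < RMS_GATE:
            continue
        clips.append(AudioClip(crop, sample_rate=sr,
                               recording_id=recording.recording_id,
                               species=recording.species))
    return clips


# ---------------------------------------------------------------------------
# synthetic songs and noise
# ---------------------------------------------------------------------------

def synth_song(profile: SpeciesProfile, duration: float, rng_seed: int,
               sample_rate: int = CANONICAL_RATE) -> AudioClip:
    """Render a synthetic song: chirped syllables confined to the species band.

    Each syllable is a Hann-windowed linear chirp whose instantaneous frequency
    stays inside ``profile.band``; weak harmonics are added only when they also
    fit under the band ceiling, keeping ≥90% of spectral energy in band.
    """
    profile.validate(sample_rate)
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * sample_rate))
    out = np.zeros(n)
    f_lo, f_hi = profile.band
    margin = 0.05 * (f_hi - f_lo)
    t_cursor = rng.uniform(0.0, min(0.1, duration / 4))
    n_syllables = 0
    while True:
        syl_dur = rng.uniform(*profile.syllable_dur)
        if t_cursor + syl_dur > duration and n_syllables > 0:
            break
        syl_dur = min(syl_dur, duration - t_cursor)
        if syl_dur * sample_rate < 8:
            break
        m = int(round(syl_dur * sample_rate))
        t = np.arange(m) / sample_rate
        slope = rng.uniform(*profile.chirp_slope)
        f0 = rng.uniform(f_lo + margin, f_hi - margin)
        # clamp the sweep inside the band
        f_inst = np.clip(f0 + slope * t, f_lo + margin / 2, f_hi - margin / 2)
        phase = 2 * np.pi * np.cumsum(f_inst) / sample_rate + rng.uniform(0, 2 * np.pi)
        syl = np.sin(phase)
        for h in range(2, profile.harmonics + 1):
            if f_inst.max() * h < f_hi:
                syl = syl + (0.3 / h) * np.sin(h * phase)
        syl *= np.hanning(m)
        start = int(round(t_cursor * sample_rate))
        stop = min(start + m, n)
        out[start:stop] += syl[:stop - start]
        n_syllables += 1
        t_cursor += syl_dur + rng.uniform(*profile.gap_dur)
        if t_cursor >= duration:
            break
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= rng.uniform(0.5, 0.95) / peak
    return AudioClip(out, sample_rate=sample_rate, species=profile.name)


def synth_noise(kind: str, duration: float, rng_seed: int,
                sample_rate: int = CANONICAL_RATE) -> AudioClip:
    """Synthetic background noise: ``wind`` (low-passed), ``rain`` (impulsive
    broadband) or ``insect`` (amplitude-modulated tone in the 3–7 kHz band,
    deliberately colliding with the wagtail-like species)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration * sample_rate))
    if kind == "wind":
        sos = butter(4, 300.0, btype="low", fs=sample_rate, output="sos")
        out = sosfilt(sos, rng.normal(size=n))
        # slow amplitude gusts
        gust = 0.5 + 0.5 * np.abs(np.sin(2 * np.pi * rng.uniform(0.1, 0.5)
                                         * np.arange(n) / sample_rate))
        out *= gust
    elif kind == "rain":
        out = 0.3 * rng.normal(size=n)
        n_drops = max(1, int(duration * 400))
        pos = rng.integers(0, n, size=n_drops)
        amp = rng.uniform(0.5, 1.5, size=n_drops)
        decay = np.exp(-np.arange(32) / 6.0)
        for p, a in zip(pos, amp):
            stop = min(p + 32, n)
            out[p:stop] += a * decay[:stop - p] * rng.normal(size=stop - p)
    elif kind == "insect":
        f_c = rng.uniform(3500.0, 6000.0)
        f_m = rng.uniform(30.0, 200.0)
        t = np.arange(n) / sample_rate
        am = 0.5 * (1 + np.sin(2 * np.pi * f_m * t))
        out = am * np.sin(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi))
        out += 0.05 * rng.normal(size=n)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= 0.9 / peak
    return AudioClip(out, sample_rate=sample_rate, species=None)


# ---------------------------------------------------------------------------
# dataset partitioning
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, ratios: tuple[float, ...]) -> list[int]:
    weights = np.asarray(ratios, dtype=float)
    shares = total * weights / weights.sum()
    floors = np.floor(shares).astype(int)
    rem = total - floors.sum()
    order = np.argsort(-(shares - floors))
    for i in range(rem):
        floors[order[i]] += 1
    return floors.tolist()


def partition_dataset(items: pd.DataFrame | list, ratios=(7, 2, 1),
                      rng_seed: int = 0,
                      partitions=("train", "valid", "test")) -> SplitAssignment:
    """Group-aware split: items sharing a recording_id land in one partition.

    ``items`` is a DataFrame with columns ``item_id`` and ``recording_id`` (or
    a list of (item_id, recording_id) pairs).  Partition quotas follow
    largest-remainder rounding of the ratios; groups are shuffled then greedily
    packed into the partition with the largest unfilled quota, which makes the
    singleton-group case exact.
    """
    if isinstance(items, pd.DataFrame):
        pairs = list(zip(items["item_id"].astype(str), items["recording_id"].astype(str)))
    else:
        pairs = [(str(a), str(b)) for a, b in items]
    if not pairs:
        raise ValueError("no items to partition")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    groups: dict[str, list[str]] = {}
    for item_id, rec_id in pairs:
        groups.setdefault(rec_id, []).append(item_id)
    quotas = _largest_remainder(len(pairs), tuple(ratios))
    rng = np.random.default_rng(rng_seed)
    names = list(groups)
    rng.shuffle(names)
    # big groups first so the greedy fill can still hit the quotas
    names.sort(key=lambda g: -len(groups[g]))
    remaining = list(quotas)
    assignment: dict[str, str] = {}
    for gname in names:
        size = len(groups[gname])
        j = int(np.argmax(remaining))
        if size > max(remaining):
            import warnings

            warnings.warn(
                f"recording group {gname!r} ({size} items) exceeds the largest "
                "remaining partition quota; assigning anyway", stacklevel=2)
        remaining[j] -= size
        for item in groups[gname]:
            assignment[item] = partitions[j]
    return SplitAssignment(assignment, tuple(float(r) for r in ratios), tuple(partitions))


# ---------------------------------------------------------------------------
# synthetic corpus + manifest
# ---------------------------------------------------------------------------

def make_synthetic_corpus(profiles=DEFAULT_PROFILES, n_per_species: int = 20,
                          duration: float = CLIP_SECONDS, seed: int = 0,
                          sample_rate: int = CANONICAL_RATE
                          ) -> tuple[list[AudioClip], pd.DataFrame]:
    """Generate a labelled clip corpus and its manifest.

    Every clip gets its own recording_id (synthetic clips are independent
    renders, not crops of a shared file).
    """
    clips: list[AudioClip] = []
    rows = []
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1,
                                                 size=len(profiles) * n_per_species)
    k = 0
    for profile in profiles:
        for i in range(n_per_species):
            clip = synth_song(profile, duration, int(seeds[k]), sample_rate)
            k += 1
            clip.recording_id = f"{profile.name}_{i:04d}"
            clips.append(clip)
            rows.append({
                "clip_id": f"{profile.name}_{i:04d}",
                "recording_id": clip.recording_id,
                "species": profile.name,
                "path": "",
                "duration_s": clip.duration,
                "sample_rate": sample_rate,
                "split": "",
            })
    return clips, pd.DataFrame(rows)


def write_corpus(clips: list[AudioClip], manifest: pd.DataFrame, out_dir) -> pd.DataFrame:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for clip, (idx, row) in zip(clips, manifest.iterrows()):
        path = out_dir / f"{row['clip_id']}.wav"
        write_wav(path, clip)
        manifest.loc[idx, "path"] = str(path)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_wav(path) -> AudioClip:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        wav = data / 32768.0
    elif data.dtype == np.int32:
        wav = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        wav = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV dtype {data.dtype}")
    if wav.ndim == 2:
        wav = wav.mean(axis=1)
    return AudioClip(np.clip(wav, -1.0, 1.0), sample_rate=int(rate))


def write_wav(path, clip: AudioClip) -> None:
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (pcm * 32767.0).astype(np.int16))
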