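"""SNR-weighted mixing of 1–4 birdsong clips with anti-clipping normalization.

A supervised mixture is built in three steps.  Each source ``data_i`` is scaled
by an amplitude weight ``w_i = 10^(SNR_i/20)`` and summed::

    mixed[n] = sum_i w_i * data_i[n]

A single scale factor then constrains the mixture *and* every individual
source to a 0.9 peak, so the clean references stay aligned with the mixture::

    scale = 0.9 / max(|mixed|, |data_1|, ..., |data_N|)
    mixed_norm = mixed * scale          data_i_norm = data_i * scale

Background noise (wind / rain / insect) is optionally added afterwards to the
mixture channel only, at a target SNR between the bird mixture's RMS and the
noise RMS, so the normalized sources remain valid separation targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import AudioClip, partition_dataset, synth_noise

PEAK_TARGET = 0.9
SOURCE_SNR_RANGE = (-5.0, 5.0)
NOISE_SNR_RANGE = (-5.0, 10.0)

__all__ = [
    "MixtureExample",
    "snr_weight",
    "mix_sources",
    "normalize_mixture",
    "add_background_noise",
    "build_mixture_dataset",
    "render_mixture",
]


@dataclass
class MixtureExample:
    """One supervised training unit: N weighted sources and their mixture."""

    sources: list[np.ndarray]  # normalized clean references (data_i_norm)
    species: list[str]
    snr_db: list[float]
    weights: list[float]
    mixture: np.ndarray  # normalized mixture (plus noise if added)
    scale: float
    n_sources: int
    noise_kind: str | None = None
    noise_snr_db: float | None = None
    clipped: bool = False
    seed: int = 0

    def validate(self) -> "MixtureExample":
        if any(len(s) != len(self.mixture) for s in self.sources):
            raise ValueError("source/mixture length mismatch")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be pairwise distinct")
        return self


def snr_weight(snr_db: float) -> float:
    """Amplitude weight 10^(SNR/20) for one source."""
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    return float(10.0 ** (snr_db / 20.0))


def mix_sources(raw_sources: list[np.ndarray], snr_db: list[float]) -> np.ndarray:
    """Weighted sum of the raw sources (sample-exact linear mixing)."""
    if len(raw_sources) != len(snr_db) or not raw_sources:
        raise ValueError("need one SNR offset per source")
    lengths = {len(s) for s in raw_sources}
    if len(lengths) != 1:
        raise ValueError("sources must share one length")
    mixed = np.zeros(lengths.pop())
    for src, snr in zip(raw_sources, snr_db):
        mixed += snr_weight(snr) * np.asarray(src, dtype=np.float64)
    return mixed


def normalize_mixture(mixed: np.ndarray, raw_sources: list[np.ndarray]
                      ) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Scale mixture and sources jointly so the global peak is exactly 0.9."""
    peak = max(
        float(np.max(np.abs(mixed))),
        *(float(np.max(np.abs(np.asarray(s)))) for s in raw_sources),
    )
    if peak == 0.0:
        raise ValueError("all-zero mixture and sources cannot be normalized")
    scale = PEAK_TARGET / peak
    return mixed * scale, [np.asarray(s, dtype=np.float64) * scale for s in raw_sources], scale


def add_background_noise(example: MixtureExample, noise: AudioClip,
                         snr_db: float, rng_seed: int = 0) -> MixtureExample:
    """Add noise to the mixture channel at a given bird-to-noise RMS SNR.

    The clean source references are left untouched.  If the noisy mixture
    exceeds full scale it is hard-clamped and flagged, keeping references
    aligned instead of re-normalizing.
    """
    n = len(example.mixture)
    noise_wav = np.asarray(noise.samples, dtype=np.float64)
    if len(noise_wav) < n:
        reps = int(np.ceil(n / len(noise_wav)))
        noise_wav = np.tile(noise_wav, reps)
    if len(noise_wav) > n:
        start = int(np.random.default_rng(rng_seed).integers(0, len(noise_wav) - n + 1))
        noise_wav = noise_wav[start:start + n]
    noise_rms = float(np.sqrt(np.mean(noise_wav ** 2)))
    if noise_rms == 0.0:
        raise ValueError("noise clip has zero energy")
    mix_rms = float(np.sqrt(np.mean(example.mixture ** 2)))
    target_noise_rms = mix_rms / (10.0 ** (snr_db / 20.0))
    noisy = example.mixture + noise_wav * (target_noise_rms / noise_rms)
    clipped = bool(np.max(np.abs(noisy)) > 1.0)
    if clipped:
        noisy = np.clip(noisy, -1.0, 1.0)
    example.mixture = noisy
    example.noise_kind = noise.species or "noise"
    example.noise_snr_db = float(snr_db)
    example.clipped = clipped
    return example


def render_mixture(clips: list[AudioClip], snr_db: list[float], seed: int = 0,
                   noise_kind: str | None = None,
                   noise_snr_db: float | None = None) -> MixtureExample:
    """Build a :class:`MixtureExample` from labelled clips (Eq-style pipeline)."""
    raw = [c.samples for c in clips]
    mixed = mix_sources(raw, snr_db)
    mixed_norm, sources_norm, scale = normalize_mixture(mixed, raw)
    example = MixtureExample(
        sources=sources_norm,
        species=[c.species or f"src{i}" for i, c in enumerate(clips)],
        snr_db=[float(s) for s in snr_db],
        weights=[snr_weight(s) for s in snr_db],
        mixture=mixed_norm,
        scale=scale,
        n_sources=len(clips),
        seed=seed,
    ).validate()
    if noise_kind is not None:
        rng = np.random.default_rng(seed)
        if noise_snr_db is None:
            noise_snr_db = float(rng.uniform(*NOISE_SNR_RANGE))
        sr = clips[0].sample_rate
        noise = synth_noise(noise_kind, len(example.mixture) / sr,
                            int(rng.integers(0, 2 ** 31 - 1)), sr)
        noise.species = noise_kind
        add_background_noise(example, noise, noise_snr_db,
                             rng_seed=int(rng.integers(0, 2 ** 31 - 1)))
    return example


def build_mixture_dataset(manifest: pd.DataFrame, n_examples: int,
                          n_sources_range=(2, 3, 4), seed: int = 0,
                          noise_prob: float = 1.0,
                          split_ratios=(7, 2, 1)) -> pd.DataFrame:
    """Draw a mixture manifest: per row, N distinct species, one clip each,
    i.i.d. per-source SNR offsets in [-5, +5] dB and an optional noise layer.

    Returns the manifest only; waveforms are rendered on demand with
    :func:`render_mixture` (audio rendering at 50 k scale is deferred to the
    CLI).  The 7:2:1 split is applied per mixture (each mixture is its own
    recording group).
    """
    species = sorted(manifest["species"].unique())
    if len(species) < max(n_sources_range):
        raise ValueError(
            f"corpus has {len(species)} species; need >= {max(n_sources_range)}")
    rng = np.random.default_rng(seed)
    by_species = {s: manifest.loc[manifest["species"] == s, "clip_id"].tolist()
                  for s in species}
    noise_kinds = ("wind", "rain", "insect")
    rows = []
    for i in range(n_examples):
        n = int(rng.choice(list(n_sources_range)))
        chosen = list(rng.choice(species, size=n, replace=False))
        clip_ids = [by_species[s][int(rng.integers(0, len(by_species[s])))]
                    for s in chosen]
        snrs = [float(rng.uniform(*SOURCE_SNR_RANGE)) for _ in range(n)]
        with_noise = bool(rng.random() < noise_prob)
        rows.append({
            "mixture_id": f"mix_{i:06d}",
            "n_sources": n,
            "species": "|".join(chosen),
            "clip_ids": "|".join(clip_ids),
            "snr_db": "|".join(f"{s:.4f}" for s in snrs),
            "noise_kind": str(rng.choice(noise_kinds)) if with_noise else "",
            "noise_snr_db": float(rng.uniform(*NOISE_SNR_RANGE)) if with_noise else np.nan,
            "seed": int(rng.integers(0, 2 ** 31 - 1)),
        })
    table = pd.DataFrame(rows)
    split = partition_dataset(
        [(m, m) for m in table["mixture_id"]], ratios=split_ratios, rng_seed=seed)
    table["split"] = table["mixture_id"].map(split.assignment)
    return table


def render_from_manifest(row: pd.Series, clip_lookup: dict[str, AudioClip]
                         ) -> MixtureExample:
    """Materialize one mixture-manifest row against an in-memory clip corpus."""
    clip_ids = row["clip_ids"].split("|")
    snrs = [float(x) for x in row["snr_db"].split("|")]
    clips = [clip_lookup[c] for c in clip_ids]
    raw_kind = row.get("noise_kind")
    noise_kind = None if (pd.isna(raw_kind) or raw_kind == "") else str(raw_kind)
    noise_snr = None if pd.isna(row.get("noise_snr_db")) else float(row["noise_snr_db"])
    return render_mixture(clips, snrs, seed=int(row["seed"]),
                          noise_kind=noise_kind, noise_snr_db=noise_snr)
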