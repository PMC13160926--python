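"""SNR-weighted mixing, anti-clipping normalization and noise augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avisep.corpus import AudioClip, make_synthetic_corpus, synth_noise
from avisep.mixture import (
    add_background_noise,
    build_mixture_dataset,
    mix_sources,
    normalize_mixture,
    render_mixture,
    snr_weight,
)


class TestSnrWeight:
    @pytest.mark.parametrize("snr,expected", [
        (0.0, 1.0),
        (20.0, 10.0),
        (-5.0, 10 ** (-0.25)),  # 0.5623413251903491
    ])
    def test_values(self, snr, expected):
        assert snr_weight(snr) == pytest.approx(expected, abs=1e-12)

    def test_monotone_and_finite_required(self):
        assert snr_weight(1.0) > snr_weight(0.0)
        with pytest.raises(ValueError):
            snr_weight(float("nan"))


class TestMixSources:
    def test_single_source_identity(self):
        s = np.array([0.1, -0.2, 0.3])
        np.testing.assert_allclose(mix_sources([s], [0.0]), s)

    def test_hand_case(self):
        out = mix_sources([np.array([1.0, 0.0]), np.array([0.0, 1.0])], [0.0, 20.0])
        np.testing.assert_allclose(out, [1.0, 10.0])

    def test_linearity(self):
        s = np.array([0.2, -0.1, 0.4])
        np.testing.assert_allclose(mix_sources([s, s], [0.0, 0.0]), 2 * s)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mix_sources([np.zeros(3), np.zeros(4)], [0.0, 0.0])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_loop_oracle(self, seed):
        # independent elementwise evaluation of the weighted-sum definition
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        sources = [rng.normal(size=16) for _ in range(n)]
        snrs = rng.uniform(-5, 5, size=n).tolist()
        expected = np.zeros(16)
        for i in range(16):
            for src, snr in zip(sources, snrs):
                expected[i] += 10 ** (snr / 20) * src[i]
        np.testing.assert_array_equal(mix_sources(sources, snrs), expected)


class TestNormalize:
    def test_scale_from_peak(self):
        mixed = np.array([1.8, 0.0])
        src = [np.array([0.5, 0.2])]
        mnorm, snorm, scale = normalize_mixture(mixed, src)
        assert scale == pytest.approx(0.5)
        assert np.max(np.abs(mnorm)) == pytest.approx(0.9)

    def test_fixed_point(self):
        mixed = np.array([0.9, -0.3])
        mnorm, snorm, scale = normalize_mixture(mixed, [np.array([0.1, 0.2])])
        assert scale == pytest.approx(1.0)
        np.testing.assert_allclose(mnorm, mixed)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_mixture(np.zeros(4), [np.zeros(4)])

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_amplitude_bound(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 5))
        sources = [rng.normal(size=64) * rng.uniform(0.1, 2.0) for _ in range(n)]
        snrs = rng.uniform(-5, 5, size=n).tolist()
        mixed = mix_sources(sources, snrs)
        mnorm, snorm, scale = normalize_mixture(mixed, sources)
        peak = max(np.max(np.abs(mnorm)), *(np.max(np.abs(s)) for s in snorm))
        assert peak == pytest.approx(0.9, abs=1e-7)
        # linearity survives normalization sample-exactly
        recon = sum(10 ** (snr / 20) * s * scale for s, snr in zip(sources, snrs))
        np.testing.assert_array_equal(mnorm, mixed * scale)
        np.testing.assert_allclose(mnorm, recon, atol=1e-12)


class TestNoise:
    def _example(self, level=1.0):
        rng = np.random.default_rng(0)
        clips = [AudioClip(rng.normal(size=4000) * 0.3, species=f"s{i}")
                 for i in range(2)]
        ex = render_mixture(clips, [0.0, 0.0])
        # keep headroom so the noisy mixture stays inside [-1, 1]; the RMS
        # contract holds pre-clamp only
        ex.mixture = ex.mixture * level
        ex.sources = [s * level for s in ex.sources]
        return ex

    @pytest.mark.parametrize("snr", [0.0, 10.0, -5.0])
    def test_noise_rms_ratio(self, snr):
        ex = self._example(level=0.2)
        clean = ex.mixture.copy()
        noise = synth_noise("wind", len(clean) / 16_000, rng_seed=1)
        add_background_noise(ex, noise, snr_db=snr)
        added = ex.mixture - clean
        assert not ex.clipped
        ratio = 20 * np.log10(np.sqrt(np.mean(clean ** 2))
                              / np.sqrt(np.mean(added ** 2)))
        assert ratio == pytest.approx(snr, abs=1e-6)

    def test_sources_stay_clean(self):
        ex = self._example()
        refs = [s.copy() for s in ex.sources]
        noise = synth_noise("insect", len(ex.mixture) / 16_000, rng_seed=2)
        add_background_noise(ex, noise, snr_db=0.0)
        for before, after in zip(refs, ex.sources):
            np.testing.assert_array_equal(before, after)

    def test_zero_noise_rejected(self):
        ex = self._example()
        with pytest.raises(ValueError):
            add_background_noise(ex, AudioClip(np.zeros(4000)), snr_db=0.0)


class TestSnrMonotonicity:
    def test_energy_share_increases_with_snr(self):
        rng = np.random.default_rng(3)
        s1, s2 = rng.normal(size=500), rng.normal(size=500)

        def share(snr1):
            mixed = mix_sources([s1, s2], [snr1, 0.0])
            w1 = snr_weight(snr1)
            return np.sum((w1 * s1) ** 2) / np.sum(mixed ** 2)

        shares = [share(snr) for snr in (-5, 0, 5)]
        assert shares[0] < shares[1] < shares[2]


@pytest.fixture(scope="module")
def manifest():
    _, manifest = make_synthetic_corpus(n_per_species=4, duration=0.25, seed=1)
    return manifest


class TestDatasetBuilder:

    def test_split_sizes_at_scale(self, manifest):
        table = build_mixture_dataset(manifest, 50_000, seed=0)
        sizes = table["split"].value_counts()
        assert sizes["train"] == 35_000
        assert sizes["valid"] == 10_000
        assert sizes["test"] == 5_000

    def test_distinct_species_per_row(self, manifest):
        table = build_mixture_dataset(manifest, 10, n_sources_range=(2,), seed=2)
        for row in table.itertuples():
            species = row.species.split("|")
            assert len(species) == 2 and len(set(species)) == 2

    def test_deterministic_manifest(self, manifest):
        a = build_mixture_dataset(manifest, 25, seed=9)
        b = build_mixture_dataset(manifest, 25, seed=9)
        assert a.equals(b)

    def test_render_after_csv_roundtrip_without_noise(self, manifest, tmp_path):
        # an empty noise column reads back as NaN; rendering must treat it as
        # "no noise layer"
        from avisep.corpus import make_synthetic_corpus
        from avisep.mixture import render_from_manifest

        clips, _ = make_synthetic_corpus(n_per_species=4, duration=0.25, seed=1)
        lookup = {c.recording_id: c for c in clips}
        table = build_mixture_dataset(manifest, 3, n_sources_range=(2,),
                                      seed=4, noise_prob=0.0)
        path = tmp_path / "mixtures.csv"
        table.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        ex = render_from_manifest(back.iloc[0], lookup)
        assert ex.noise_kind is None

    def test_insufficient_species(self, manifest):
        small = manifest.loc[manifest["species"] == manifest["species"].iloc[0]]
        with pytest.raises(ValueError):
            build_mixture_dataset(small, 5, n_sources_range=(2,), seed=0)


def test_mixture_example_distinct_species_enforced():
    rng = np.random.default_rng(0)
    clips = [AudioClip(rng.normal(size=100) * 0.1, species="same") for _ in range(2)]
    with pytest.raises(ValueError):
        render_mixture(clips, [0.0, 0.0])
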