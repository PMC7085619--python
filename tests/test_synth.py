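"""Synthetic-data generator: seeding, moment recovery, spectral fidelity."""
import numpy as np
import pandas as pd
import pytest

from cyclesense import features, preprocess, profiles, synth
from cyclesense.ingest import assemble_segments

from conftest import bruteforce_band_power


def exact_profile(**kw):
    """A profile whose band means sum exactly to 1 (no renormalization shift)."""
    defaults = dict(class_id="c1", band_means=(0.4, 0.4, 0.15, 0.05),
                    band_stds=(0.0, 0.0, 0.0, 0.0), hr_mean_bpm=130.0,
                    hr_std_bpm=0.0, position="Spine2")
    defaults.update(kw)
    return profiles.ClassProfile(**defaults)


class TestFeatureSamples:
    def test_degenerate_noise_returns_the_means(self):
        prof = exact_profile()
        df = synth.gen_feature_samples(prof, 3, seed=0)
        assert len(df) == 3
        for _, row in df.iterrows():
            np.testing.assert_allclose(
                row[list(features.BAND_NAMES)], prof.band_means, atol=1e-15)
            assert row["HR"] == prof.hr_mean_bpm

    def test_seeded_reproducibility(self):
        prof = profiles.table_profile("Spine2", "c1")
        a = synth.gen_feature_samples(prof, 50, seed=7)
        b = synth.gen_feature_samples(prof, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = synth.gen_feature_samples(prof, 50, seed=8)
        assert not a.equals(c)

    def test_rows_lie_on_the_unit_simplex(self):
        prof = profiles.table_profile("LeftLeg", "c2")
        df = synth.gen_feature_samples(prof, 500, seed=3)
        bands = df[list(features.BAND_NAMES)].to_numpy()
        assert (bands >= 0).all() and (bands <= 1).all()
        np.testing.assert_allclose(bands.sum(axis=1), 1.0, atol=1e-12)

    def test_spine2_c1_moment_recovery_at_n_10000(self):
        """Sample means recover the published Spine2/c1 statistics to 4 SE."""
        prof = profiles.table_profile("Spine2", "c1")
        n = 10_000
        df = synth.gen_feature_samples(prof, n, seed=123)
        mus = list(prof.band_means) + [prof.hr_mean_bpm]
        sds = list(prof.band_stds) + [prof.hr_std_bpm]
        # expected stds after projection onto the simplex (first order):
        # var(x_i / s) = sigma_i^2 (1 - m_i)^2 + m_i^2 sum_{j != i} sigma_j^2
        var_all = np.sum(np.square(prof.band_stds))
        exp_sds = [
            np.sqrt(sd**2 * (1 - mu) ** 2 + mu**2 * (var_all - sd**2))
            for mu, sd in zip(prof.band_means, prof.band_stds)
        ] + [prof.hr_std_bpm]
        for name, mu, sd, esd in zip(features.FEATURE_NAMES, mus, sds, exp_sds):
            assert abs(df[name].mean() - mu) < 4.0 * sd / np.sqrt(n), name
            assert abs(df[name].std(ddof=1) - esd) < max(
                4.0 * esd / np.sqrt(2 * n), 0.05 * esd), name

    def test_invalid_inputs_rejected(self):
        prof = profiles.table_profile("Spine2", "c1")
        with pytest.raises(ValueError):
            synth.gen_feature_samples(prof, 0, seed=0)
        with pytest.raises(ValueError, match="nonnegative"):
            profiles.ClassProfile(class_id="c1", band_means=(0.4, 0.4, 0.15, 0.05),
                                  band_stds=(-0.01, 0, 0, 0),
                                  hr_mean_bpm=130, hr_std_bpm=5)


class TestRawSegment:
    @pytest.mark.parametrize("targets,dominant,floor", [
        ((1.0, 0.0, 0.0, 0.0), 0, 0.95),
        ((0.0, 1.0, 0.0, 0.0), 1, 0.95),
        ((0.0, 0.0, 1.0, 0.0), 2, 0.95),
    ])
    def test_pure_band_targets(self, targets, dominant, floor):
        """A one-band target yields a modulus whose power sits in that band,
        verified by an explicitly-summed DFT oracle after preprocessing."""
        prof = profiles.table_profile("Spine2", "c1")
        cfg = synth.SynthConfig(segment_duration_s=10.0)
        seg = synth.gen_raw_segment(prof, cfg, seed=5,
                                    band_targets=np.array(targets))
        us = preprocess.make_uniform_segment(seg, cfg.preprocess)
        y = us.modulus - us.modulus.mean()
        pv = bruteforce_band_power(y, us.fs_hz,
                                   features.BandSpec().bands[dominant],
                                   nyquist_closed=(dominant == 3))
        assert pv >= floor

    def test_table_targets_delivered_within_tolerance(self):
        """The published Spine2/c1 fractions survive the full chain to 0.02."""
        prof = profiles.table_profile("Spine2", "c1")
        cfg = synth.SynthConfig()
        targets = np.array([0.39, 0.41, 0.16, 0.04])
        seg = synth.gen_raw_segment(prof, cfg, seed=11, band_targets=targets)
        us = preprocess.make_uniform_segment(seg, cfg.preprocess)
        fv = features.segment_features(us)
        np.testing.assert_allclose(fv[:4], targets, atol=0.02)

    def test_slope_mean_recovery(self):
        """1000 drawn segments recover the HillUp mean slope within 0.5 %."""
        prof = profiles.table_profile("Spine2", "c1")  # slope 10.3 +- 3.3
        cfg = synth.SynthConfig(segment_duration_s=4.0)
        slopes = []
        for i in range(1000):
            seg = synth.gen_raw_segment(prof, cfg, seed=2000 + i)
            alt = seg.track["alt_m"].to_numpy()
            dist = seg.track["dist_m"].to_numpy()
            slopes.append(100.0 * (alt[-1] - alt[0]) / (dist[-1] - dist[0]))
        assert abs(np.mean(slopes) - 10.3) < 0.5

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            synth.SynthConfig(segment_duration_s=1.0)


class TestDataset:
    def test_minimal_dataset_roundtrip(self, tmp_path):
        """One segment per (position, class) cell: 28 segments, lossless manifest."""
        cfg = synth.SynthConfig(segments_per_class_per_position=1,
                                bad_segment_rate=0.0,
                                segment_duration_s=6.0, seed=4)
        paths = synth.gen_dataset(cfg, tmp_path / "data")
        manifest = pd.read_csv(paths.manifest)
        assert len(manifest) == 28
        assembled = assemble_segments(paths.manifest, paths.root,
                                      paths.root / "track.csv")
        assert not assembled.problems
        assert len(assembled.segments) == 28
        assert assembled.counts_by_position == {p: 4 for p in profiles.POSITIONS}
        classes = sorted(s.class_id for s in assembled.segments
                         if s.position == "Neck")
        assert classes == ["c1", "c2", "c3", "c4"]

    def test_byte_identical_datasets_for_same_seed(self, tmp_path):
        cfg = synth.SynthConfig(positions=("Spine2",),
                                counts_per_position={"Spine2": 4},
                                rejected_per_position={"Spine2": 1},
                                segment_duration_s=6.0, seed=9)
        a = synth.gen_dataset(cfg, tmp_path / "a")
        b = synth.gen_dataset(cfg, tmp_path / "b")
        for rel in ("manifest.csv", "track.csv", "accel/seg0000.csv",
                    "accel/seg0003.csv"):
            assert (a.root / rel).read_bytes() == (b.root / rel).read_bytes(), rel

    def test_injected_unstable_segments_fail_qc(self, tmp_path):
        cfg = synth.SynthConfig(positions=("Spine2", "Neck"),
                                counts_per_position={"Spine2": 8, "Neck": 8},
                                rejected_per_position={"Spine2": 2, "Neck": 1},
                                segment_duration_s=6.0, seed=2)
        paths = synth.gen_dataset(cfg, tmp_path / "d")
        manifest = pd.read_csv(paths.manifest)
        flagged = set(manifest.loc[manifest["speed_unstable"] == 1, "segment_id"])
        assert len(flagged) == 3
        assembled = assemble_segments(paths.manifest, paths.root,
                                      paths.root / "track.csv")
        qc = preprocess.qc_filter(assembled.segments, alpha=0.5)
        rejected_ids = {seg.segment_id for seg, _ in qc.rejected}
        assert rejected_ids == flagged

    def test_missing_profile_rejected(self, tmp_path):
        cfg = synth.SynthConfig(positions=("Spine2",),
                                counts_per_position={"Spine2": 4},
                                segment_duration_s=6.0)
        profs = {k: v for k, v in profiles.all_profiles().items()
                 if k != ("Spine2", "c3")}
        with pytest.raises(KeyError, match="Spine2.*c3"):
            synth.gen_dataset(cfg, tmp_path / "x", profiles=profs)
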