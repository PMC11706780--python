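"""Morphometry: segmentation, measurement, exclusions, FWHM, 3D, summaries."""

import numpy as np
import pandas as pd
import pytest

from nanopearl import (
    IntensityProfile,
    PearlChainSpec,
    RadiusProfile,
    apply_exclusions,
    cohort_dimension_means,
    fwhm_length,
    gen_pearl_profile,
    gen_population,
    gen_serial_sections,
    measure_profile,
    measure_segments,
    reconstruct_3d,
    segment_profile,
    spacing_periodicity,
    summarize,
)

from conftest import ACUTE, DISSOCIATED, ORGANOTYPIC


class TestSegmentation:
    def test_cosine_chain_analytic_inflections(self, cosine_profile):
        """r = rbar + dr cos(2 pi x / lambda): boundaries at lambda/4 + k lambda/2."""
        profile, lam = cosine_profile
        segments = segment_profile(profile)
        nsv = [s for s in segments if s.kind == "nsv"]
        assert len(nsv) >= 4
        for s in nsv:
            assert s.length == pytest.approx(lam / 2, abs=profile.spacing)
            # boundaries sit at lambda/4 modulo lambda/2
            assert (s.start - lam / 4) % (lam / 2) == pytest.approx(0.0, abs=profile.spacing) or (
                s.start - lam / 4
            ) % (lam / 2) == pytest.approx(lam / 2, abs=profile.spacing)

    def test_constant_cylinder_has_no_segments(self):
        x = np.arange(0.0, 5000.0, 5.0)
        profile = RadiusProfile(x, np.full_like(x, 75.0))
        assert segment_profile(profile) == []

    def test_segments_alternate_kinds(self, dissociated_profile):
        profile, _ = dissociated_profile
        segments = segment_profile(profile)
        kinds = [s.kind for s in segments]
        assert kinds[::2] == ["nsv"] * len(kinds[::2])
        assert kinds[1::2] == ["connector"] * len(kinds[1::2])

    @pytest.mark.parametrize("dims", [DISSOCIATED, ORGANOTYPIC, ACUTE])
    def test_noiseless_round_trip_within_one_sample(self, dims):
        """Measured dimensions match generator ground truth within 5 nm."""
        profile, truth = gen_pearl_profile(PearlChainSpec(*dims, n_periods=10, seed=1))
        segments = segment_profile(profile)
        spacing = profile.spacing
        nsv = [s for s in segments if s.kind == "nsv"]
        conn = [s for s in segments if s.kind == "connector"]
        assert np.mean([s.length for s in nsv]) == pytest.approx(dims[0], abs=spacing)
        assert np.mean([s.width for s in nsv]) == pytest.approx(dims[1], abs=spacing)
        assert np.mean([s.length for s in conn]) == pytest.approx(dims[2], abs=spacing)
        assert np.mean([s.width for s in conn]) == pytest.approx(dims[3], abs=spacing)

    def test_round_trip_many_random_specs(self):
        """Ground-truth recovery holds across 40 random pearl specs."""
        rng = np.random.default_rng(0)
        for trial in range(40):
            nl = rng.uniform(250.0, 750.0)
            cw = rng.uniform(50.0, 180.0)
            nw = rng.uniform(cw + 60.0, 400.0)
            cl = rng.uniform(220.0, 700.0)
            profile, truth = gen_pearl_profile(
                PearlChainSpec(nl, nw, cl, cw, n_periods=5, seed=trial)
            )
            segments = segment_profile(profile)
            nsv = [s for s in segments if s.kind == "nsv"]
            assert len(nsv) == 5, (nl, nw, cl, cw)
            assert np.mean([s.length for s in nsv]) == pytest.approx(nl, abs=profile.spacing)
            assert np.mean([s.width for s in nsv]) == pytest.approx(nw, abs=profile.spacing)

    def test_translation_and_reflection_invariance(self, dissociated_profile):
        profile, _ = dissociated_profile
        ref = segment_profile(profile)
        shifted = RadiusProfile(profile.x + 12345.0, profile.r)
        seg_shift = segment_profile(shifted)
        assert len(seg_shift) == len(ref)
        for a, b in zip(ref, seg_shift):
            assert b.start - a.start == pytest.approx(12345.0, abs=1e-6)
            assert b.width == pytest.approx(a.width, abs=1e-9)
        mirrored = RadiusProfile(profile.x, profile.r[::-1].copy())
        seg_mirror = segment_profile(mirrored)
        widths = sorted(round(s.width, 3) for s in ref if s.kind == "nsv")
        widths_m = sorted(round(s.width, 3) for s in seg_mirror if s.kind == "nsv")
        assert widths == widths_m

    def test_smoothing_window_monotone_boundary_count(self):
        """Boundary count never increases as the smoothing window grows."""
        profile, _ = gen_pearl_profile(
            PearlChainSpec(*DISSOCIATED, n_periods=8, jitter_cv=0.05, noise_sd=3.0, seed=11)
        )
        counts = []
        for window in (10.0, 20.0, 40.0, 70.0, 100.0):
            counts.append(len(segment_profile(profile, smoothing_window=window)))
        assert all(a >= b for a, b in zip(counts, counts[1:])), counts

    def test_window_below_two_samples_rejected(self, dissociated_profile):
        profile, _ = dissociated_profile
        with pytest.raises(ValueError):
            segment_profile(profile, smoothing_window=profile.spacing)

    def test_nonuniform_spacing_rejected(self):
        x = np.concatenate([np.arange(0, 500, 5.0), np.arange(500, 1000, 7.0)])
        with pytest.raises(ValueError):
            RadiusProfile(x, np.full_like(x, 50.0))


class TestMeasurement:
    def test_single_bump_width_is_peak_diameter(self):
        profile, _ = gen_pearl_profile(PearlChainSpec(*ORGANOTYPIC, n_periods=1, seed=0))
        rec = measure_segments(segment_profile(profile))
        assert len(rec.nsv) == 1
        assert rec.nsv[0][1] == pytest.approx(177.0, abs=2.0)

    def test_uniform_connector_width_estimator_independent(self):
        """A flat connector's width equals its diameter for any estimator."""
        profile, _ = gen_pearl_profile(PearlChainSpec(*DISSOCIATED, n_periods=4, seed=0))
        segments = segment_profile(profile)
        for s in segments:
            if s.kind == "connector":
                assert s.width == pytest.approx(127.0, abs=0.5)

    def test_empty_segments_empty_record(self):
        rec = measure_segments([])
        assert rec.nsv == [] and rec.connector == []
        assert np.isnan(rec.summary()["nsv_length_mean_nm"])

    def test_cohort_means_match_dissociated_row(self):
        """A Table-style cohort reproduces its own generating means."""
        means = np.array(DISSOCIATED)
        sds = np.array([50.0, 30.0, 80.0, 15.0])
        profiles, _, _ = gen_population(means, sds, 40, seed=5, n_periods=6)
        records = [measure_profile(p) for p in profiles]
        df = summarize(records, ["cohort"] * len(records))
        for dim, mu in zip(
            ("nsv_length", "nsv_width", "connector_length", "connector_width"), means
        ):
            row = df[df.dimension == dim].iloc[0]
            assert abs(row.mean_nm - mu) < max(3 * row.sem_nm, 5.0), dim


class TestExclusions:
    def test_synaptic_varicosities_removed(self, dissociated_profile):
        profile, _ = dissociated_profile
        profile = RadiusProfile(
            profile.x, profile.r,
            is_synaptic=np.array([True] * 3 + [False] * 7),
            axon_max_diameter=311.0,
        )
        rec = measure_profile(profile)
        kept, counts = apply_exclusions([rec])
        assert counts["varicosities_removed"] == 3
        assert len(kept[0].nsv) == 7

    def test_wide_structure_without_terminal_excluded(self):
        rec = measure_profile(
            gen_pearl_profile(PearlChainSpec(*DISSOCIATED, n_periods=3, seed=0))[0]
        )
        rec.axon_max_diameter = 1200.0
        rec.has_presynaptic_terminal = False
        kept, counts = apply_exclusions([rec])
        assert kept == [] and counts["axons_removed"] == 1
        rec.has_presynaptic_terminal = True
        kept, counts = apply_exclusions([rec])
        assert len(kept) == 1 and counts["axons_removed"] == 0

    def test_no_flags_identity(self, dissociated_profile):
        profile, _ = dissociated_profile
        rec = measure_profile(profile)
        kept, counts = apply_exclusions([rec])
        assert counts == {"axons_removed": 0, "varicosities_removed": 0}
        assert kept[0].nsv == rec.nsv


class TestFWHM:
    def test_triangle_peak(self):
        x = np.arange(0.0, 1000.0, 5.0)
        y = np.maximum(0.0, 1.0 - np.abs(x - 500.0) / 100.0)
        assert fwhm_length(IntensityProfile(x, y)) == pytest.approx([100.0])

    def test_gaussian_closed_form(self):
        x = np.arange(0.0, 2000.0, 5.0)
        sd = 50.0
        y = np.exp(-((x - 1000.0) ** 2) / (2 * sd**2))
        (w,) = fwhm_length(IntensityProfile(x, y))
        assert w == pytest.approx(2.3548 * sd, rel=0.01)

    def test_flat_profile_no_peaks(self):
        x = np.arange(0.0, 1000.0, 5.0)
        assert fwhm_length(IntensityProfile(x, np.ones_like(x))).size == 0


class TestPeriodicity:
    def test_exact_190nm_grid(self):
        _, _, frac = spacing_periodicity(np.arange(0.0, 1900.0, 190.0))
        assert frac == 1.0

    def test_pearl_period_far_from_mps(self):
        """Dissociated pearl spacing (~1,152 nm) shares nothing with 190 nm."""
        centers = np.arange(0.0, 11520.0, 1152.0)
        _, _, frac = spacing_periodicity(centers)
        assert frac == 0.0

    def test_uniform_random_spacings_fraction(self):
        rng = np.random.default_rng(0)
        spacings = rng.uniform(300.0, 1500.0, 1200)
        centers = np.concatenate([[0.0], np.cumsum(spacings)])
        _, _, frac = spacing_periodicity(centers)
        # interval [171, 209] covers 38/1200 of [300, 1500] -> 0 by construction
        assert frac == 0.0
        spac2 = rng.uniform(100.0, 1300.0, 1200)
        centers2 = np.concatenate([[0.0], np.cumsum(spac2)])
        _, _, frac2 = spacing_periodicity(centers2)
        expected = 38.0 / 1200.0
        assert frac2 == pytest.approx(expected, abs=3 * np.sqrt(expected / 1200))

    def test_fewer_than_two_centers_rejected(self):
        with pytest.raises(ValueError):
            spacing_periodicity([100.0])


class TestReconstruct3D:
    def test_known_cases(self):
        stack = gen_serial_sections(300.0, 2, 40.0, seed=0)
        assert reconstruct_3d(stack, 300.0) == pytest.approx(302.65, abs=0.01)
        stack6 = gen_serial_sections(0.0, 6, 40.0, seed=0)
        assert reconstruct_3d(stack6) == pytest.approx(200.0)

    def test_matches_generator_ground_truth(self):
        for seed in range(5):
            stack = gen_serial_sections(421.0, 7, 40.0, seed=seed)
            assert reconstruct_3d(stack) == pytest.approx(stack.true_3d_length, rel=1e-12)

    def test_negative_inplane_rejected(self):
        stack = gen_serial_sections(100.0, 3, 40.0, seed=0)
        with pytest.raises(ValueError):
            reconstruct_3d(stack, -5.0)


class TestSummaries:
    def test_single_axon_single_nsv(self):
        profile, _ = gen_pearl_profile(PearlChainSpec(*DISSOCIATED, n_periods=1, seed=0))
        df = summarize([measure_profile(profile)], ["g"])
        row = df[df.dimension == "nsv_length"].iloc[0]
        assert row.n == 1 and row.sem_nm == 0.0
        assert row.mean_nm == pytest.approx(600.0, abs=5.0)

    def test_identical_groups_identical_summaries(self, dissociated_profile):
        profile, _ = dissociated_profile
        rec = measure_profile(profile)
        df = summarize([rec, rec], ["a", "b"])
        a = df[df.group == "a"].drop(columns="group").reset_index(drop=True)
        b = df[df.group == "b"].drop(columns="group").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_warns_and_omitted(self):
        x = np.arange(0.0, 5000.0, 5.0)
        flat = measure_profile(RadiusProfile(x, np.full_like(x, 60.0)))
        with pytest.warns(UserWarning):
            df = summarize([flat], ["empty"])
        assert df.empty


class TestNoiseRobustness:
    def test_bias_corrected_cohort_means_within_five_percent(self):
        """Radius noise at 5% of connector radius: cohort means shift < 5%."""
        dims = DISSOCIATED
        noise = 0.05 * dims[3] / 2.0
        profiles, truths = [], []
        for a in range(15):
            p, t = gen_pearl_profile(
                PearlChainSpec(*dims, n_periods=10, jitter_cv=0.05, noise_sd=noise, seed=500 + a)
            )
            profiles.append(p)
            truths.append(t)
        out = cohort_dimension_means(profiles, seed=1)
        true_means = {
            "nsv_length": np.mean([l for t in truths for l, _ in t.nsv_dims]),
            "nsv_width": np.mean([w for t in truths for _, w in t.nsv_dims]),
            "connector_length": np.mean([l for t in truths for l, _ in t.connector_dims]),
            "connector_width": np.mean([w for t in truths for _, w in t.connector_dims]),
        }
        for key, mu in true_means.items():
            assert abs(out[f"{key}_nm"] - mu) / mu < 0.05, key
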