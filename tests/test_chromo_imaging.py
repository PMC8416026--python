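"""Segmentation, intensity quantification, surface area, and foci counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscale.chromo_imaging import (ImageStack, count_cenpa_foci,
                                      individualization_frequency, otsu_threshold,
                                      quantify_if, surface_area_3d, _interpolate_z)
from mitoscale.image_synth import Ellipsoid, Focus, SceneSpec, render


def flood_fill_components(mask):
    """Pure-python BFS labeling with full (8/26) connectivity: the oracle."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [d for d in np.ndindex(*(3,) * mask.ndim)
               if any(v != 1 for v in d)]
    offsets = [tuple(v - 1 for v in d) for d in offsets]
    for idx in np.ndindex(*mask.shape):
        if mask[idx] and labels[idx] == 0:
            current += 1
            stack = [idx]
            labels[idx] = current
            while stack:
                p = stack.pop()
                for off in offsets:
                    q = tuple(a + b for a, b in zip(p, off))
                    if all(0 <= a < s for a, s in zip(q, mask.shape)):
                        if mask[q] and labels[q] == 0:
                            labels[q] = current
                            stack.append(q)
    return labels, current


class TestOtsu:
    def test_bimodal_image_threshold_separates_modes(self):
        img = np.concatenate([np.full(1000, 10.0), np.full(1000, 200.0)])
        t = otsu_threshold(img)
        assert 10 < t < 200

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_maximizes_between_class_variance_exhaustively(self, seed):
        """The returned threshold achieves the exhaustive-search maximum of
        the between-class variance (empty gap bins create exact ties, so the
        check is on the attained variance, not the tie-broken cut)."""
        rng = np.random.default_rng(seed)
        img = np.concatenate([
            rng.normal(20, 3, 400), rng.normal(120, 10, 150),
            rng.normal(60, 5, 80),
        ])
        t = otsu_threshold(img)
        counts, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        total = counts.sum()

        def variance_at(cut):
            w0 = counts[:cut].sum()
            w1 = total - w0
            if w0 == 0 or w1 == 0:
                return -np.inf
            mu0 = (counts[:cut] * centers[:cut]).sum() / w0
            mu1 = (counts[cut:] * centers[cut:]).sum() / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        best = max(variance_at(c) for c in range(1, 256))
        cut_of_t = int(np.searchsorted(centers, t, side="left")) + 1
        assert variance_at(cut_of_t) == pytest.approx(best, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_affine_equivariance(self, a, b):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(10, 2, 300), rng.normal(80, 6, 200)])
        t0 = otsu_threshold(img)
        t1 = otsu_threshold(a * img + b)
        assert t1 == pytest.approx(a * t0 + b, rel=1e-9, abs=1e-6)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(np.full((10, 10), 3.0))


class TestImageStack:
    def test_congruent_shapes_enforced(self):
        with pytest.raises(ValueError, match="congruent"):
            ImageStack({"DNA": np.zeros((2, 4, 4)), "m": np.zeros((2, 5, 4))})

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ImageStack({"DNA": np.full((1, 2, 2), -1.0)})

    def test_max_dna_slice_selection(self):
        dna = np.zeros((3, 4, 4))
        dna[1] = 5.0
        st_ = ImageStack({"DNA": dna})
        assert st_.max_dna_slice() == 1


class TestQuantifyIF:
    def _two_mass_stack(self, ratios, noise=0.0, seed=0):
        spec = SceneSpec(shape=(6, 200, 200), masses=(
            Ellipsoid(center=(2.5, 60, 100), semiaxes=(2.4, 25, 25), intensity=150),
            Ellipsoid(center=(2.5, 140, 100), semiaxes=(2.4, 25, 25), intensity=150)),
            marker_ratios=dict(enumerate(ratios)), noise_sigma=noise, seed=seed)
        return render(spec)[0]

    def test_marker_equal_to_dna_gives_unit_ratio(self):
        stack = self._two_mass_stack([1.0, 1.0])
        df = quantify_if(stack, "marker")
        assert np.allclose(df["ratio"], 1.0, atol=1e-9)

    def test_marker_twice_dna_gives_ratio_two(self):
        stack = self._two_mass_stack([2.0, 2.0])
        df = quantify_if(stack, "marker")
        assert np.allclose(df["ratio"], 2.0, atol=1e-9)

    def test_known_ratios_recovered_under_noise(self):
        stack = self._two_mass_stack([0.5, 1.5], noise=5.0, seed=3)
        df = quantify_if(stack, "marker").sort_values("ratio")
        assert df["ratio"].to_numpy() == pytest.approx([0.5, 1.5], rel=0.05)

    def test_common_scaling_leaves_ratios_unchanged(self):
        stack = self._two_mass_stack([0.5, 1.5], noise=5.0, seed=3)
        scaled = ImageStack({k: 3.7 * v for k, v in stack.channels.items()},
                            xy_nm=stack.xy_nm, z_nm=stack.z_nm)
        r1 = quantify_if(stack, "marker")["ratio"].to_numpy()
        r2 = quantify_if(scaled, "marker")["ratio"].to_numpy()
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_empty_stack_raises(self):
        stack = ImageStack({"DNA": np.random.default_rng(0).random((3, 32, 32)),
                            "marker": np.zeros((3, 32, 32))})
        # all-noise DNA has no clear mass but Otsu still yields a mask; a
        # truly empty (all-equal) DNA channel must raise
        flat = ImageStack({"DNA": np.full((3, 32, 32), 2.0),
                           "marker": np.zeros((3, 32, 32))})
        with pytest.raises(ValueError):
            quantify_if(flat, "marker")


class TestSurfaceArea:
    def test_interpolated_slice_count_follows_target_spacing(self):
        # 11 slices at 200 nm span 2000 nm -> ceil(2000/67)+1 = 31 slices
        vol = np.random.default_rng(0).random((11, 8, 8))
        out = _interpolate_z(vol, 200.0, 67.0)
        assert out.shape[0] == 31

    def test_size_filter_is_strictly_greater_than(self):
        def one_component(n_target):
            vol = np.full((40, 80, 80), 0.05)
            # one connected component of exactly n_target voxels: full
            # 20 x 25 x-slabs plus a partial slab of whole and part columns
            nx = n_target // 500
            rem = n_target - 500 * nx
            cols, part = divmod(rem, 20)
            vol[5:25, 5:30, 5:5 + nx] = 1.0
            vol[5:25, 5:5 + cols, 5 + nx] = 1.0
            vol[5:5 + part, 5 + cols, 5 + nx] = 1.0
            stack = ImageStack({"DNA": vol}, z_nm=67.0)
            df = surface_area_3d(stack, target_z_nm=67.0, min_voxels=10_000)
            return len(df)

        assert one_component(10_001) == 1
        assert one_component(10_000) == 0
        assert one_component(9_999) == 0

    def test_digital_ball_area_within_five_percent_of_sphere(self):
        r = 20
        spec = SceneSpec(shape=(46, 46, 46), xy_nm=67.0, z_nm=67.0,
                         masses=(Ellipsoid(center=(22, 22, 22),
                                           semiaxes=(r, r, r), intensity=100),))
        stack, _ = render(spec)
        df = surface_area_3d(stack, target_z_nm=67.0, min_voxels=100)
        analytic = 4 * np.pi * (r * 0.067) ** 2
        assert df["surface_area_um2"][0] == pytest.approx(analytic, rel=0.05)

    def test_voxel_face_mode_bounds_mesh_area_from_above(self):
        spec = SceneSpec(shape=(24, 24, 24), xy_nm=67.0, z_nm=67.0,
                         masses=(Ellipsoid(center=(11, 11, 11),
                                           semiaxes=(8, 8, 8), intensity=100),))
        stack, _ = render(spec)
        mesh = surface_area_3d(stack, target_z_nm=67.0, min_voxels=10)
        voxel = surface_area_3d(stack, target_z_nm=67.0, min_voxels=10, method="voxel")
        # voxel-face counting overestimates smooth surfaces (Manhattan bound)
        assert voxel["surface_area_um2"][0] > mesh["surface_area_um2"][0]

    def test_dilation_never_decreases_convex_surface_area(self):
        from scipy import ndimage
        r = 10
        spec = SceneSpec(shape=(30, 30, 30), xy_nm=67.0, z_nm=67.0,
                         masses=(Ellipsoid(center=(14, 14, 14),
                                           semiaxes=(r, r, r), intensity=100),))
        stack, _ = render(spec)
        a0 = surface_area_3d(stack, target_z_nm=67.0, min_voxels=10)["surface_area_um2"][0]
        dil = ndimage.binary_dilation(stack.channel("DNA") > 50).astype(float) * 100
        stack2 = ImageStack({"DNA": dil}, xy_nm=67.0, z_nm=67.0)
        a1 = surface_area_3d(stack2, target_z_nm=67.0, min_voxels=10)["surface_area_um2"][0]
        assert a1 >= a0

    def test_voxel_budget_guard(self):
        stack = ImageStack({"DNA": np.random.default_rng(0).random((5, 64, 64))},
                           z_nm=200.0)
        with pytest.raises(ValueError, match="downsample"):
            surface_area_3d(stack, target_z_nm=67.0, max_voxels=1_000)

    def test_finer_z_than_target_rejected(self):
        stack = ImageStack({"DNA": np.random.default_rng(0).random((5, 16, 16))},
                           z_nm=50.0)
        with pytest.raises(ValueError, match="finer"):
            surface_area_3d(stack, target_z_nm=67.0)


class TestFociCounting:
    def test_three_foci_mass_is_individualized_four_is_not(self):
        for n_foci, expected in ((3, True), (4, False)):
            foci = tuple(Focus(mass=0, position=(3.5, 100, 60 + 12 * k), amplitude=150)
                         for k in range(n_foci))
            spec = SceneSpec(shape=(8, 200, 200), masses=(
                Ellipsoid(center=(3.5, 100, 90), semiaxes=(3.4, 35, 70), intensity=120),),
                foci=foci, noise_sigma=8.0, seed=5)
            stack, _ = render(spec)
            rec = count_cenpa_foci(stack)
            assert len(rec) == 1
            assert rec["n_cenpa_foci"][0] == n_foci
            assert bool(rec["individualized"][0]) is expected

    def test_seven_planted_foci_counted_exactly_at_snr_ten(self):
        offsets = [(0, 0), (0, 12), (0, -12), (12, 0), (-12, 0), (12, 12), (-12, -12)]
        foci = tuple(Focus(mass=0, position=(3.5, 100 + dy, 100 + dx), amplitude=120)
                     for dy, dx in offsets)
        spec = SceneSpec(shape=(8, 200, 200), masses=(
            Ellipsoid(center=(3.5, 100, 100), semiaxes=(3.4, 40, 40), intensity=140),),
            foci=foci, noise_sigma=12.0, seed=8)  # SNR = 10
        stack, truth = render(spec)
        rec = count_cenpa_foci(stack)
        assert rec["n_cenpa_foci"].tolist() == [7]

    def test_counts_match_flood_fill_oracle_on_small_stack(self):
        spec = SceneSpec(shape=(6, 64, 64), masses=(
            Ellipsoid(center=(2.5, 20, 20), semiaxes=(2.4, 11, 11), intensity=120),
            Ellipsoid(center=(2.5, 44, 44), semiaxes=(2.4, 11, 11), intensity=120)),
            foci=(Focus(mass=0, position=(2.5, 20, 20), amplitude=120),
                  Focus(mass=1, position=(2.5, 40, 40), amplitude=120),
                  Focus(mass=1, position=(2.5, 50, 48), amplitude=120)),
            noise_sigma=6.0, seed=2)
        stack, _ = render(spec)
        rec = count_cenpa_foci(stack)
        # oracle: flood fill on the same thresholded slice images
        from scipy import ndimage as ndi
        z = stack.max_dna_slice()
        dna = stack.channel("DNA")[z]
        cen = ndi.gaussian_filter(stack.channel("CENP-A")[z], 1.0)
        dna_mask = dna > otsu_threshold(dna)
        cen_mask = cen > otsu_threshold(cen)
        dna_lab, n_masses = flood_fill_components(dna_mask)
        cen_lab, n_foci = flood_fill_components(cen_mask)
        counts = {lab: 0 for lab in range(1, n_masses + 1)}
        for f in range(1, n_foci + 1):
            ys, xs = np.nonzero(cen_lab == f)
            if len(ys) < 2:  # speck filter mirror
                continue
            cy, cx = int(round(ys.mean())), int(round(xs.mean()))
            lab = dna_lab[cy, cx]
            if lab > 0:
                counts[lab] += 1
        assert sorted(rec["n_cenpa_foci"]) == sorted(counts.values())
        assert len(rec) == n_masses

    def test_doublet_merged_as_single_focus(self):
        # two spots 2 px apart (below the 3 px merge radius) count once
        spec = SceneSpec(shape=(8, 120, 120), masses=(
            Ellipsoid(center=(3.5, 60, 60), semiaxes=(3.4, 30, 30), intensity=120),),
            foci=(Focus(mass=0, position=(3.5, 60, 59), amplitude=100),
                  Focus(mass=0, position=(3.5, 60, 61), amplitude=100)),
            noise_sigma=0.0, seed=0)
        stack, _ = render(spec)
        rec = count_cenpa_foci(stack)
        assert rec["n_cenpa_foci"].tolist() == [1]

    def test_no_foci_channel_gives_zero_counts(self):
        spec = SceneSpec(shape=(6, 80, 80), masses=(
            Ellipsoid(center=(2.5, 40, 40), semiaxes=(2.4, 20, 20), intensity=120),),
            noise_sigma=0.0, seed=0)
        stack, _ = render(spec)
        rec = count_cenpa_foci(stack)
        assert rec["n_cenpa_foci"].tolist() == [0]
        assert bool(rec["individualized"][0]) is True


class TestIndividualizationFrequency:
    def test_all_individualized_is_100_percent(self):
        import pandas as pd
        rec = pd.DataFrame({"individualized": [True] * 5})
        assert individualization_frequency(rec) == 100.0

    def test_counts_1_2_5_9_give_50_percent(self):
        import pandas as pd
        rec = pd.DataFrame({"n_cenpa_foci": [1, 2, 5, 9]})
        rec["individualized"] = rec["n_cenpa_foci"] < 4
        assert individualization_frequency(rec) == 50.0

    def test_per_replicate_frequencies(self):
        import pandas as pd
        rec = pd.DataFrame({"individualized": [True, False, True, True],
                            "replicate": ["a", "a", "b", "b"]})
        out = individualization_frequency(rec, by_replicate=True)
        assert out["a"] == 50.0 and out["b"] == 100.0

    def test_empty_records_raise(self):
        import pandas as pd
        with pytest.raises(ValueError, match="no cluster"):
            individualization_frequency(pd.DataFrame({"individualized": []}))
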