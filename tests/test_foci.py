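"""Segmentation, assignment and summarization against independent oracles."""

from dataclasses import replace

import numpy as np
import pytest

from xiquant import simulate
from xiquant.foci import (
    FocusObject,
    ImageStack3D,
    NucleusObject,
    SegmentationParams,
    assign_foci,
    batch_process,
    otsu_threshold,
    otsu_threshold_array,
    pairwise_distances,
    process_stack,
    segment_foci,
    segment_nuclei,
    summarize_nuclei,
)

SPACING = (0.2, 0.1, 0.1)


def exhaustive_otsu(counts, values):
    """O(L^2) scan of every cut point maximizing between-class variance."""
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(values)
    counts, values = counts[order], values[order]
    # degenerate (single populated bin) -> threshold at that value, empty foreground
    best_t, best_v = values[counts > 0].max(), -1.0
    for i in range(len(values) - 1):
        c0, c1 = counts[: i + 1], counts[i + 1:]
        w0, w1 = c0.sum(), c1.sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (c0 * values[: i + 1]).sum() / w0
        mu1 = (c1 * values[i + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, values[i]
    return best_t


class TestOtsu:
    def test_bimodal_histogram_separates_modes(self):
        t = otsu_threshold(np.array([50, 50]), np.array([0, 10]))
        assert 0 <= t < 10  # foreground (> t) is exactly the intensity-10 mode

    def test_single_valued_histogram_sentinel(self):
        t = otsu_threshold(np.array([100]), np.array([7]))
        assert t == 7  # mask "> t" is empty

    def test_constant_image_empty_foreground(self):
        img = np.full((4, 8, 8), 3.0)
        t = otsu_threshold_array(img)
        assert not np.any(img > t)

    def test_matches_exhaustive_scan_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n_bins = rng.integers(2, 12)
            counts = rng.integers(0, 50, size=n_bins)
            counts[rng.integers(0, n_bins)] += 1  # ensure nonzero
            values = np.sort(rng.choice(100, size=n_bins, replace=False)).astype(float)
            assert otsu_threshold(counts, values) == exhaustive_otsu(counts, values)

    def test_agrees_with_skimage_on_random_image(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(1)
        img = np.concatenate([rng.normal(10, 2, 500), rng.normal(60, 5, 300)])
        ours = otsu_threshold_array(img, nbins=256)
        ref = threshold_otsu(img, nbins=256)
        bin_width = (img.max() - img.min()) / 256
        assert abs(ours - ref) <= bin_width

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.array([0, 0]), np.array([1, 2]))


def _ellipsoid_stack(centers_um, axes_um, shape=(24, 64, 64), amp=1000.0):
    """Noise-free DAPI-like stack with analytic ellipsoids, plus truth masks."""
    dz, dy, dx = SPACING
    vol = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    zz = (np.arange(shape[0]) + 0.5) * dz
    yy = (np.arange(shape[1]) + 0.5) * dy
    xx = (np.arange(shape[2]) + 0.5) * dx
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    for c, a in zip(centers_um, axes_um):
        inside = (
            ((Z - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((X - c[2]) / a[2]) ** 2
        ) <= 1
        vol[inside] = amp
        mask |= inside
    voxels = np.stack([vol, np.zeros_like(vol)], axis=-1)
    return ImageStack3D(voxels=voxels, spacing=SPACING, channel_names=["dapi", "fish"]), mask


class TestSegmentNuclei:
    def test_all_zero_stack_returns_empty(self):
        stack = ImageStack3D(np.zeros((8, 32, 32, 2)), SPACING)
        assert segment_nuclei(stack, 0) == []

    def test_two_ellipsoids_recovered_with_accurate_volume(self):
        stack, _ = _ellipsoid_stack(
            [(2.4, 1.8, 1.8), (2.4, 4.6, 4.6)], [(1.2, 1.2, 1.2)] * 2
        )
        nuclei = segment_nuclei(stack, 0)
        assert len(nuclei) == 2
        true_vol = (4 / 3) * np.pi * 1.2**3 / (0.2 * 0.1 * 0.1)
        for n in nuclei:
            assert abs(n.volume_vox - true_vol) / true_vol < 0.15

    def test_edge_touching_nucleus_excluded(self):
        stack, _ = _ellipsoid_stack([(2.4, 3.2, 0.0)], [(1.2, 1.2, 1.2)])
        assert segment_nuclei(stack, 0) == []

    def test_small_components_removed(self):
        stack, _ = _ellipsoid_stack([(2.4, 3.2, 3.2)], [(0.3, 0.3, 0.3)])
        # ~3k um^-3 * 0.113 um^3 = ~56 voxels, below the 500-voxel minimum
        assert segment_nuclei(stack, 0) == []

    def test_edge_rule_holds_on_simulated_edge_nucleus(self, small_image_params):
        p = replace(small_image_params, n_nuclei=1, edge_nucleus=True)
        stacks, truths = simulate.sim_image_population(p, 1, seed=8)
        nuclei = segment_nuclei(stacks[0], 0)
        shape = stacks[0].shape_zyx
        assert len(nuclei) == 1  # the interior nucleus only
        for n in nuclei:
            zz, yy, xx = np.nonzero(n.label_volume == n.label)
            assert yy.min() > 0 and yy.max() < shape[1] - 1
            assert xx.min() > 0 and xx.max() < shape[2] - 1


class TestSegmentFoci:
    def test_zero_fish_channel_empty(self):
        stack = ImageStack3D(np.zeros((8, 32, 32, 2)), SPACING)
        assert segment_foci(stack, 1) == []

    def test_merged_territory_gives_single_focus(self, small_image_params):
        p = replace(
            small_image_params, n_nuclei=1, territory_radius=0.05, dispersed_fraction=0.0
        )
        stacks, _ = simulate.sim_image_population(p, 1, seed=9)
        foci = segment_foci(stacks[0], 1)
        assert len(foci) == 1

    def test_dispersed_counts_recovered_per_nucleus(self):
        from conftest import match_truth_to_segmented

        # full-size field: nuclei are large enough that dispersed transcripts
        # sit clear of each other at the optical merge scale
        p = replace(simulate.ImageSimParams(), dispersed_fraction=1.0)
        stacks, truths = simulate.sim_image_population(p, 2, seed=10)
        ok = total = 0
        for stack, truth in zip(stacks, truths):
            summaries, nuclei, _, _ = process_stack(stack)
            for nt, s, _n in match_truth_to_segmented(truth, summaries, nuclei):
                total += 1
                if abs(s.n_foci - nt.n_resolvable) <= 0.2 * nt.n_resolvable:
                    ok += 1
        assert total >= 4
        assert ok / total >= 0.9

    def test_raising_min_volume_never_increases_counts(self, small_image_params):
        stacks, _ = simulate.sim_image_population(small_image_params, 1, seed=11)
        stack = stacks[0]
        loose = SegmentationParams(min_focus_volume_vox=1)
        strict = SegmentationParams(min_focus_volume_vox=6)

        def per_nucleus_counts(params):
            nuclei = segment_nuclei(stack, 0, params)
            foci = segment_foci(stack, 1, params)
            assign_foci(foci, nuclei)
            summaries, _ = summarize_nuclei(nuclei, foci)
            return {s.nucleus_id: s.n_foci for s in summaries}

        a, b = per_nucleus_counts(loose), per_nucleus_counts(strict)
        for k in a:
            assert b.get(k, 0) <= a[k]


def _toy_labels(shape, rng, n_labels):
    v = rng.integers(0, n_labels + 1, size=shape)
    return v


class TestAssignFoci:
    def _make(self, label_volume, focus_voxels):
        nuclei = [
            NucleusObject(
                label=int(l), volume_vox=int((label_volume == l).sum()),
                volume_um3=0.0, centroid_um=(0, 0, 0), touches_xy_edge=False,
                label_volume=label_volume,
            )
            for l in np.unique(label_volume) if l > 0
        ]
        foci = [
            FocusObject(label=i + 1, volume_vox=len(vox[0]), centroid_um=(0, 0, 0),
                        integrated_intensity=0.0, voxel_indices=vox)
            for i, vox in enumerate(focus_voxels)
        ]
        return nuclei, foci

    def test_focus_inside_nucleus_assigned(self):
        lv = np.zeros((5, 5, 5), dtype=np.int16)
        lv[1:4, 1:4, 1:4] = 1
        nuclei, foci = self._make(lv, [tuple(np.array([[2], [2], [2]]))])
        assign_foci(foci, nuclei)
        assert foci[0].assigned_nucleus == 1

    def test_max_overlap_wins(self):
        lv = np.zeros((3, 8, 8), dtype=np.int16)
        lv[:, :, :4] = 1
        lv[:, :, 4:] = 2
        # 10 voxels in nucleus 1, 3 in nucleus 2
        zz = np.zeros(13, dtype=int)
        yy = np.arange(13) % 3
        xx = np.array([0, 1, 2, 3] * 2 + [0, 1] + [4, 5, 6])
        nuclei, foci = self._make(lv, [(zz, yy, xx)])
        assign_foci(foci, nuclei)
        assert foci[0].assigned_nucleus == 1

    def test_zero_overlap_unassigned(self):
        lv = np.zeros((3, 4, 4), dtype=np.int16)
        lv[0, 0, 0] = 1
        nuclei, foci = self._make(lv, [tuple(np.array([[2], [3], [3]]))])
        assign_foci(foci, nuclei)
        assert foci[0].assigned_nucleus == "unassigned"

    def test_tie_breaks_to_smaller_label(self):
        lv = np.zeros((1, 2, 2), dtype=np.int16)
        lv[0, 0, 0] = 2
        lv[0, 0, 1] = 1
        vox = (np.array([0, 0]), np.array([0, 0]), np.array([0, 1]))
        nuclei, foci = self._make(lv, [vox])
        assign_foci(foci, nuclei)
        assert foci[0].assigned_nucleus == 1

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lv = rng.integers(0, 4, size=(5, 5, 5)).astype(np.int16)
            if lv.max() == 0:
                continue
            n_foci = rng.integers(1, 4)
            focus_voxels = []
            for _f in range(n_foci):
                n_vox = rng.integers(1, 10)
                idx = rng.integers(0, 5, size=(n_vox, 3))
                focus_voxels.append((idx[:, 0], idx[:, 1], idx[:, 2]))
            nuclei, foci = self._make(lv, focus_voxels)
            assign_foci(foci, nuclei)
            for f in foci:
                tally = {}
                for z, y, x in zip(*f.voxel_indices):
                    l = int(lv[z, y, x])
                    if l > 0:
                        tally[l] = tally.get(l, 0) + 1
                if not tally:
                    assert f.assigned_nucleus == "unassigned"
                else:
                    best = max(tally.values())
                    expect = min(l for l, c in tally.items() if c == best)
                    assert f.assigned_nucleus == expect


class TestDistancesAndSummaries:
    def _focus(self, label, centroid):
        return FocusObject(label=label, volume_vox=1, centroid_um=centroid,
                           integrated_intensity=0.0)

    def test_single_focus_zero_matrix(self):
        d = pairwise_distances([self._focus(1, (0, 0, 0))])
        assert d.shape == (1, 1) and d[0, 0] == 0

    def test_anisotropic_distance(self):
        # 5 z-voxels at dz = 0.2 um -> 1.0 um apart
        a = self._focus(1, (0.0, 0.0, 0.0))
        b = self._focus(2, (5 * 0.2, 0.0, 0.0))
        d = pairwise_distances([a, b])
        assert d[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        foci = [self._focus(i, tuple(rng.uniform(0, 10, 3))) for i in range(12)]
        d = pairwise_distances(foci)
        for i in range(12):
            for j in range(12):
                ref = np.linalg.norm(
                    np.array(foci[i].centroid_um) - np.array(foci[j].centroid_um)
                )
                assert d[i, j] == pytest.approx(ref)
        assert np.allclose(d, d.T)
        # triangle inequality on sampled triples
        for _ in range(30):
            i, j, k = rng.integers(0, 12, 3)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_counts_match_brute_force_group_by(self):
        rng = np.random.default_rng(5)
        lv = np.zeros((2, 2, 2), dtype=np.int16)
        nuclei = [
            NucleusObject(label=l, volume_vox=1, volume_um3=0.0, centroid_um=(0, 0, 0),
                          touches_xy_edge=False, label_volume=lv)
            for l in (1, 2, 3)
        ]
        foci = [self._focus(i, tuple(rng.uniform(0, 5, 3))) for i in range(20)]
        assignments = rng.choice([1, 2, 3, "unassigned"], size=20)
        for f, a in zip(foci, assignments):
            f.assigned_nucleus = a if a == "unassigned" else int(a)
        summaries, n_un = summarize_nuclei(nuclei, foci)
        expected = {l: sum(1 for a in assignments if a == str(l)) for l in (1, 2, 3)}
        for s in summaries:
            assert s.n_foci == expected[s.nucleus_id]
        assert n_un == sum(1 for a in assignments if a == "unassigned")
        assert sum(s.n_foci for s in summaries) + n_un == 20

    def test_three_foci_one_nucleus(self):
        lv = np.zeros((2, 2, 2), dtype=np.int16)
        nuclei = [NucleusObject(label=1, volume_vox=1, volume_um3=0.0,
                                centroid_um=(0, 0, 0), touches_xy_edge=False,
                                label_volume=lv)]
        foci = [self._focus(i, (float(i), 0, 0)) for i in range(3)]
        for f in foci:
            f.assigned_nucleus = 1
        summaries, _ = summarize_nuclei(nuclei, foci)
        assert summaries[0].n_foci == 3
        assert summaries[0].mean_nn_um == pytest.approx(1.0)

    def test_no_foci_gives_undefined_nn(self):
        lv = np.zeros((2, 2, 2), dtype=np.int16)
        nuclei = [NucleusObject(label=1, volume_vox=1, volume_um3=0.0,
                                centroid_um=(0, 0, 0), touches_xy_edge=False,
                                label_volume=lv)]
        summaries, n_un = summarize_nuclei(nuclei, [])
        assert summaries[0].n_foci == 0 and summaries[0].mean_nn_um is None
        assert n_un == 0


class TestBatch:
    def test_empty_manifest(self, tmp_path):
        import pandas as pd

        m = pd.DataFrame(columns=["path", "genotype", "replicate", "dapi_channel", "fish_channel"])
        table, log = batch_process(m)
        assert table.empty and log["n_images"] == 0

    def test_round_trip_through_ome_tiff(self, tmp_path, small_image_params):
        import pandas as pd

        stacks, _ = simulate.sim_image_population(small_image_params, 2, seed=12)
        rows = []
        for i, s in enumerate(stacks):
            p = tmp_path / f"im{i}.ome.tif"
            simulate.write_stack_ome_tiff(s, p)
            rows.append({"path": str(p), "genotype": "wt", "replicate": 1,
                         "dapi_channel": 0, "fish_channel": 1})
        rows.append({"path": str(tmp_path / "missing.tif"), "genotype": "wt",
                     "replicate": 1, "dapi_channel": 0, "fish_channel": 1})
        table, log = batch_process(pd.DataFrame(rows))
        assert log["n_images"] == 3 and log["n_failed"] == 1
        assert len(table) == 2 * small_image_params.n_nuclei
        assert set(table["genotype"]) == {"wt"}
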