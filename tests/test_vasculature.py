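import numpy as np
import pytest
from scipy import ndimage

from vesselleak import vasculature as vas
from vesselleak.core import ImageStack4D
from vesselleak.phantom import PhantomSpec, make_vascular_phantom

from conftest import voxelize_cylinder

ISO = (1.0, 1.0, 1.0)


def tube_mask(shape=(40, 21, 21), radius=3.0, axis="z"):
    """Straight tube through the volume center, isotropic voxels."""
    zz, yy, xx = np.indices(shape)
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    if axis == "z":
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    else:
        cz = (shape[0] - 1) / 2
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2
    return d2 <= radius**2


class TestSegmentVessels:
    def test_otsu_on_noiseless_phantom_dice(self):
        spec = PhantomSpec(volume_shape=(16, 72, 72), seed=2, capillary_density=10.0)
        mask, truth = make_vascular_phantom(spec)
        img = np.where(mask, 100.0, 5.0)
        stack = ImageStack4D(img, voxel_size_um=spec.voxel_size_um)
        seg = vas.segment_vessels(stack, method="otsu")
        dice = 2 * np.count_nonzero(seg & mask) / (seg.sum() + mask.sum())
        assert dice >= 0.95

    def test_all_zero_stack_empty_mask(self):
        stack = ImageStack4D(np.zeros((8, 16, 16)), voxel_size_um=ISO)
        with pytest.warns(UserWarning):
            seg = vas.segment_vessels(stack, method="fixed_threshold", threshold=1.0)
        assert not seg.any()

    def test_external_mask_passthrough(self):
        mask = tube_mask()
        stack = ImageStack4D(np.zeros(mask.shape), voxel_size_um=ISO)
        out = vas.segment_vessels(stack, method="external_mask", external_mask=mask)
        assert np.array_equal(out, mask)

    def test_unknown_method(self):
        stack = ImageStack4D(np.zeros((4, 8, 8)), voxel_size_um=ISO)
        with pytest.raises(vas.SegmentationMethodError):
            vas.segment_vessels(stack, method="weka")


class TestSkeletonGraph:
    def test_single_tube_one_edge_two_endpoints(self):
        vg = vas.skeletonize_and_graph(tube_mask(), ISO)
        assert vg.n_edges == 1
        assert vg.n_nodes == 2
        degrees = [d for _, d in vg.graph.degree()]
        assert sorted(degrees) == [1, 1]

    def test_y_tube_three_edges_one_junction(self):
        # Y: vertical trunk plus an oblique branch from the middle
        shape = (50, 41, 41)
        zz, yy, xx = np.indices(shape)
        trunk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 9
        t = np.clip((zz - 25), 0, None)
        branch = ((yy - 20 - 0.8 * t) ** 2 + (xx - 20) ** 2 <= 9) & (zz >= 25)
        vg = vas.skeletonize_and_graph(trunk | branch, ISO)
        assert vg.n_edges == 3
        junctions = [n for n, d in vg.graph.degree() if d >= 3]
        assert len(junctions) == 1

    def test_two_disjoint_tubes_two_components(self):
        m1 = tube_mask((40, 41, 41), 3.0)
        m2 = np.roll(m1, 15, axis=1)
        m1 = np.roll(m1, -10, axis=1)
        vg = vas.skeletonize_and_graph(m1 | m2, ISO)
        assert vg.n_components == 2

    def test_empty_mask_empty_graph(self):
        vg = vas.skeletonize_and_graph(np.zeros((8, 8, 8), bool), ISO)
        assert vg.n_edges == 0 and vg.n_nodes == 0

    def test_euler_consistency(self):
        # |E| - |V| + |C| = cycle count; a simple loop has exactly one
        shape = (5, 41, 41)
        zz, yy, xx = np.indices(shape)
        r = np.sqrt((yy - 20.0) ** 2 + (xx - 20.0) ** 2)
        torus = (np.abs(r - 12) <= 3) & (zz == 2)
        vg = vas.skeletonize_and_graph(torus, ISO)
        cycles = vg.n_edges - vg.n_nodes + vg.n_components
        assert cycles == 1


class TestDiameterMap:
    def test_cylinder_radius4_recovered(self):
        # DERIVED: exact EDT oracle on the voxelized cylinder
        voxel = (2.0, 0.692, 0.692)
        mask = voxelize_cylinder(4.0, voxel, shape=(20, 61, 61))
        vg = vas.skeletonize_and_graph(mask, voxel)
        vas.diameter_map(mask, vg)
        diam = np.concatenate([d["diameters_um"] for _, _, d in vg.edge_items()])
        assert np.mean(diam) == pytest.approx(8.0, abs=0.7)

    def test_one_voxel_line(self):
        mask = np.zeros((3, 3, 30), bool)
        mask[1, 1, 2:28] = True
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        diam = np.concatenate([d["diameters_um"] for _, _, d in vg.edge_items()])
        assert np.all(diam <= 2.0 + 1e-9)
        assert np.all(diam > 0)

    def test_voxel_size_covariance(self):
        mask = voxelize_cylinder(4.0, (2.0, 0.692, 0.692), shape=(16, 41, 41))
        vg1 = vas.skeletonize_and_graph(mask, (2.0, 0.692, 0.692))
        vas.diameter_map(mask, vg1)
        vg2 = vas.skeletonize_and_graph(mask, (4.0, 1.384, 1.384))
        vas.diameter_map(mask, vg2)
        d1 = np.mean(np.concatenate([d["diameters_um"] for _, _, d in vg1.edge_items()]))
        d2 = np.mean(np.concatenate([d["diameters_um"] for _, _, d in vg2.edge_items()]))
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_skeleton_outside_mask_raises(self):
        mask = tube_mask()
        vg = vas.skeletonize_and_graph(mask, ISO)
        bad = mask.copy()
        bad[:] = False
        bad[0, 0, 0] = True
        with pytest.raises(vas.GraphIntegrityError):
            vas.diameter_map(bad, vg)


def grown_tree_mask():
    """Vertical thick trunk with two branch generations, isotropic voxels."""
    shape = (60, 64, 64)
    zz, yy, xx = np.indices(shape)
    trunk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 25  # r=5
    t1 = np.clip(zz - 20, 0, None)
    b1 = (((yy - 32 - 0.9 * t1) ** 2 + (xx - 32) ** 2 <= 9) & (zz >= 20) & (zz <= 45))
    t2 = np.clip(zz - 32, 0, None)
    b2 = (((yy - 32 - 0.9 * np.clip(zz - 20, 0, None)) ** 2
           + (xx - 32 - 0.9 * t2) ** 2 <= 4) & (zz >= 32) & (zz <= 48))
    return trunk | b1 | b2


class TestClassifyVessels:
    def test_tree_orders_propagate(self):
        mask = grown_tree_mask()
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        # seed the thickest vertical segment's id
        thick = max(vg.edge_items(), key=lambda it: it[2]["mean_diameter_um"])[0]
        segs = vas.classify_vessels(vg, {thick: "arteriole"})
        orders = sorted(s.order for s in segs if isinstance(s.order, int))
        assert orders[0] == 0
        assert set(orders) <= {0, 1, 2}
        assert all(s.vessel_class == "arteriole" for s in segs
                   if isinstance(s.order, int))

    def test_isolated_5um_segment_is_capillary(self):
        mask = voxelize_cylinder(2.5, ISO, shape=(30, 21, 21))
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        segs = vas.classify_vessels(vg, {})
        assert all(s.vessel_class == "capillary" for s in segs)

    def test_isolated_7um_unlabeled(self):
        mask = voxelize_cylinder(3.5, ISO, shape=(30, 21, 21))
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        segs = vas.classify_vessels(vg, {})
        assert all(s.vessel_class == "unlabeled" for s in segs)

    def test_seed_on_missing_segment_raises(self):
        mask = tube_mask()
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        with pytest.raises(vas.SeedLabelError):
            vas.classify_vessels(vg, {999: "arteriole"})

    def test_conflicting_seeds_raise(self):
        mask = grown_tree_mask()
        vg = vas.skeletonize_and_graph(mask, ISO)
        vas.diameter_map(mask, vg)
        sids = [sid for sid, _, _ in vg.edge_items()]
        with pytest.raises(vas.SeedLabelError):
            vas.classify_vessels(vg, {sids[0]: "arteriole", sids[1]: "venule"})

    def test_confusion_matrix_diagonal_on_phantom(self):
        # noiseless phantom: penetrating trees perfectly recovered from
        # truth labels, capillary recall >= 95%
        spec = PhantomSpec(volume_shape=(20, 96, 96), seed=6, capillary_density=30.0)
        mask, truth = make_vascular_phantom(spec)
        vg = vas.skeletonize_and_graph(mask, spec.voxel_size_um)
        vas.diameter_map(mask, vg)
        # map each graph edge to its majority truth segment, seed the roots
        seeds = {}
        truth_class = dict(zip(truth.segment_table["id"],
                               truth.segment_table["vessel_class"]))
        truth_order = dict(zip(truth.segment_table["id"], truth.segment_table["order"]))
        edge_truth = {}
        for sid, _, data in vg.edge_items():
            p = data["path"]
            owners = truth.labels[p[:, 0], p[:, 1], p[:, 2]]
            owners = owners[owners > 0]
            if owners.size:
                edge_truth[sid] = np.bincount(owners).argmax()
        for sid, tid in edge_truth.items():
            if truth_order[tid] == 0 and truth_class[tid] in ("arteriole", "venule"):
                seeds.setdefault(sid, truth_class[tid])
        segs = vas.classify_vessels(vg, seeds)
        matched = [(s, truth_class[edge_truth[s.id]]) for s in segs if s.id in edge_truth]
        cap = [(s, t) for s, t in matched if t == "capillary"]
        cap_ok = sum(s.vessel_class == "capillary" for s, _ in cap)
        assert cap and cap_ok / len(cap) >= 0.95
        av = [(s, t) for s, t in matched if t in ("arteriole", "venule")
              and isinstance(s.order, int)]
        assert av and all(s.vessel_class == t for s, t in av)


class TestPerivascularShells:
    def test_annulus_volume_matches_analytic(self):
        # DERIVED: pi*((r+15)^2 - (r+5)^2)*L for r=3, L=50 at 0.5 um voxels
        voxel = (0.5, 0.5, 0.5)
        shape = (100, 81, 81)
        mask = voxelize_cylinder(3.0, voxel, shape=shape)
        labels = mask.astype(np.int32)
        rois, shell = vas.perivascular_shells(mask, labels, voxel)
        analytic = np.pi * ((3 + 15) ** 2 - (3 + 5) ** 2) * 50.0
        measured = rois[1].volume_um3 * (50.0 / (shape[0] * 0.5))  # per 50 um length
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_distance_band_membership(self, small_truth):
        rois, shell = vas.perivascular_shells(
            small_truth.lumen_mask, small_truth.labels, small_truth.voxel_size_um)
        dist = ndimage.distance_transform_edt(
            ~small_truth.lumen_mask, sampling=small_truth.voxel_size_um)
        in_shell = shell > 0
        assert np.all(dist[in_shell] > 5.0)
        assert np.all(dist[in_shell] <= 15.0)
        assert not np.any(in_shell & small_truth.lumen_mask)

    def test_pairwise_disjoint_and_nearest_owner(self):
        # two parallel tubes 12 um apart: ownership splits at the midplane
        voxel = (1.0, 1.0, 1.0)
        shape = (30, 61, 61)
        zz, yy, xx = np.indices(shape)
        m1 = (yy - 24) ** 2 + (xx - 30) ** 2 <= 4
        m2 = (yy - 36) ** 2 + (xx - 30) ** 2 <= 4
        labels = np.where(m1, 1, np.where(m2, 2, 0)).astype(np.int32)
        rois, shell = vas.perivascular_shells(m1 | m2, labels, voxel)
        assert set(rois) == {1, 2}
        own1 = shell == 1
        own2 = shell == 2
        assert not np.any(own1 & own2)
        # strictly-closer voxels belong to the closer tube
        d1 = ndimage.distance_transform_edt(~m1, sampling=voxel)
        d2 = ndimage.distance_transform_edt(~m2, sampling=voxel)
        assert np.all(d1[own1 & (d1 != d2)] < d2[own1 & (d1 != d2)])
        assert np.all(d2[own2 & (d1 != d2)] < d1[own2 & (d1 != d2)])

    def test_bad_radii_rejected(self, small_truth):
        with pytest.raises(ValueError):
            vas.perivascular_shells(small_truth.lumen_mask, small_truth.labels,
                                    small_truth.voxel_size_um, r_in_um=15, r_out_um=5)

    def test_shell_never_intersects_lumen(self, small_truth):
        _, shell = vas.perivascular_shells(
            small_truth.lumen_mask, small_truth.labels, small_truth.voxel_size_um)
        assert not np.any((shell > 0) & small_truth.lumen_mask)
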