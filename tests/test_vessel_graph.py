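"""Centerline I/O and voxel-graph construction."""

import json

import nibabel as nib
import numpy as np
import pytest

from emboflow.errors import EmptyCenterlineError, FormatError, GraphError
from emboflow.graph import (
    VascularGraph,
    build_components,
    build_graph,
    classify_nodes,
    edge_geometry,
    paint_nodes,
    select_largest,
)
from emboflow.volume import CenterlineVolume, read_centerline

from conftest import make_volume


class TestReadCenterline:
    def test_reads_values_and_counts_centerline_voxels(self, tmp_path):
        values = np.zeros((5, 5, 5))
        values[1, 1, 1] = 0.8
        values[2, 2, 2] = 1.0
        values[3, 3, 3] = 1.2
        p = tmp_path / "c.nii.gz"
        nib.save(nib.Nifti1Image(values, np.eye(4)), str(p))
        vol = read_centerline(p)
        assert vol.n_centerline == 3
        assert vol.values[2, 2, 2] == pytest.approx(1.0)

    def test_all_zero_volume_is_an_error(self, tmp_path):
        p = tmp_path / "z.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), np.eye(4)), str(p))
        with pytest.raises(EmptyCenterlineError):
            read_centerline(p)

    def test_non_3d_volume_is_a_format_error(self, tmp_path):
        p = tmp_path / "4d.nii.gz"
        nib.save(nib.Nifti1Image(np.ones((3, 3, 3, 2)), np.eye(4)), str(p))
        with pytest.raises(FormatError):
            read_centerline(p)

    def test_anisotropic_spacing_from_affine(self, tmp_path):
        # CT-like geometry: 0.8 mm in-plane, 0.5 mm slices
        affine = np.diag([0.8, 0.8, 0.5, 1.0])
        values = np.zeros((4, 4, 4))
        values[1, 1, 1] = 1.0
        p = tmp_path / "a.nii.gz"
        nib.save(nib.Nifti1Image(values, affine), str(p))
        vol = read_centerline(p)
        assert vol.spacing == pytest.approx([0.8, 0.8, 0.5])


class TestBuildComponents:
    def test_collinear_chain_gives_two_unit_edges(self):
        values = np.zeros((5, 5, 5))
        values[1:4, 2, 2] = 1.0
        comps = build_components(make_volume(values))
        assert len(comps) == 1
        vg = comps[0]
        assert vg.n_nodes == 3
        lengths = [d["length_mm"] for _, _, d in vg.g.edges(data=True)]
        # 26-connectivity also links the two ends of the chain? no: they are
        # 2 voxels apart, so exactly the two unit steps remain
        assert sorted(lengths) == pytest.approx([1.0, 1.0])

    def test_in_plane_diagonal_neighbors_connect_with_euclidean_length(self):
        values = np.zeros((4, 4, 4))
        values[1, 1, 1] = 1.0
        values[2, 2, 1] = 1.0
        vol = make_volume(values, spacing=(0.8, 0.8, 0.8))
        comps = build_components(vol)
        assert len(comps) == 1
        (_, _, d), = comps[0].g.edges(data=True)
        assert d["length_mm"] == pytest.approx(0.8 * np.sqrt(2))

    def test_separated_clusters_form_two_components_sorted_by_size(self):
        values = np.zeros((12, 4, 4))
        values[0:5, 1, 1] = 1.0
        values[9:12, 1, 1] = 1.0
        comps = build_components(make_volume(values))
        assert [c.n_nodes for c in comps] == [5, 3]

    def test_component_sizes_partition_the_nonzero_voxels(self):
        rng = np.random.default_rng(7)
        values = (rng.random((10, 10, 10)) < 0.1).astype(float)
        if values.sum() == 0:
            values[0, 0, 0] = 1.0
        comps = build_components(make_volume(values))
        assert sum(c.n_nodes for c in comps) == int(np.count_nonzero(values))
        all_ids = [n for c in comps for n in c.nodes]
        assert len(all_ids) == len(set(all_ids))

    def test_adjacency_is_symmetric_and_lengths_bounded_by_voxel_diagonal(self):
        rng = np.random.default_rng(3)
        values = (rng.random((8, 8, 8)) < 0.15).astype(float)
        vol = make_volume(values, spacing=(0.8, 0.8, 0.5))
        for c in build_components(vol):
            for i, j, d in c.g.edges(data=True):
                assert c.g.has_edge(j, i)
                assert 0.5 - 1e-12 <= d["length_mm"] <= np.linalg.norm([0.8, 0.8, 0.5]) + 1e-12

    def test_rebuild_is_deterministic(self):
        rng = np.random.default_rng(5)
        values = (rng.random((8, 8, 8)) < 0.2).astype(float)
        vol = make_volume(values)
        a = select_largest(build_components(vol))
        b = select_largest(build_components(vol))
        edge_geometry(a)
        edge_geometry(b)
        assert a.to_json() == b.to_json()


class TestSelectLargest:
    def test_picks_most_voxels(self):
        values = np.zeros((20, 4, 4))
        values[0:7, 1, 1] = 1.0
        values[10:13, 1, 1] = 1.0
        values[16:18, 1, 1] = 1.0
        vg = select_largest(build_components(make_volume(values)))
        assert vg.n_nodes == 7

    def test_tie_breaks_to_lowest_linear_index(self):
        values = np.zeros((10, 4, 4))
        values[6:9, 1, 1] = 1.0  # higher linear indices
        values[0:3, 2, 2] = 1.0  # contains the lowest linear index
        vg = select_largest(build_components(make_volume(values)))
        assert min(vg.nodes) == int(np.ravel_multi_index((0, 2, 2), (10, 4, 4)))

    def test_empty_list_is_an_error(self):
        with pytest.raises(GraphError):
            select_largest([])


class TestClassifyNodes:
    def _path(self, n):
        values = np.zeros((n + 2, 3, 3))
        values[1:n + 1, 1, 1] = 1.0
        return select_largest(build_components(make_volume(values)))

    def test_path_roles(self):
        vg = self._path(4)
        root = min(vg.nodes)
        classify_nodes(vg, root)
        roles = [vg.g.nodes[n]["role"] for n in vg.nodes]
        assert roles.count("root") == 1
        assert roles.count("interior") == 2
        assert roles.count("terminal") == 1

    def test_y_tree_roles(self):
        values = np.zeros((5, 5, 3))
        values[0, 2, 1] = values[1, 2, 1] = 1.0  # stem
        values[2, 1, 1] = values[2, 3, 1] = 1.0  # two tips off the junction
        vg = select_largest(build_components(make_volume(values)))
        root = int(np.ravel_multi_index((0, 2, 1), (5, 5, 3)))
        classify_nodes(vg, root)
        roles = sorted(vg.g.nodes[n]["role"] for n in vg.nodes)
        assert roles == ["interior", "root", "terminal", "terminal"]

    def test_high_degree_root_rejected(self):
        values = np.zeros((5, 5, 3))
        values[2, 2, 1] = 1.0
        values[1, 2, 1] = values[3, 2, 1] = values[2, 1, 1] = 1.0
        vg = select_largest(build_components(make_volume(values)))
        hub = int(np.ravel_multi_index((2, 2, 1), (5, 5, 3)))
        with pytest.raises(GraphError):
            classify_nodes(vg, hub)


class TestEdgeGeometry:
    def test_edge_radius_is_mean_of_endpoints(self):
        values = np.zeros((4, 3, 3))
        values[1, 1, 1] = 1.0
        values[2, 1, 1] = 2.0
        vg = select_largest(build_components(make_volume(values)))
        edge_geometry(vg)
        (_, _, d), = vg.g.edges(data=True)
        assert d["radius_mm"] == pytest.approx(1.5)

    def test_slice_spacing_sets_axial_edge_length(self):
        values = np.zeros((3, 3, 4))
        values[1, 1, 1] = values[1, 1, 2] = 1.0
        vol = make_volume(values, spacing=(0.8, 0.8, 0.5))
        vg = select_largest(build_components(vol))
        (_, _, d), = vg.g.edges(data=True)
        assert d["length_mm"] == pytest.approx(0.5)

    def test_zero_radius_voxel_rejected(self):
        values = np.zeros((4, 3, 3))
        values[1, 1, 1] = 1.0
        values[2, 1, 1] = 1.0
        vg = select_largest(build_components(make_volume(values)))
        vg.g.nodes[vg.nodes[0]]["radius"] = 0.0
        with pytest.raises(GraphError):
            edge_geometry(vg)


class TestSerialization:
    def test_json_round_trip_preserves_graph(self):
        values = np.zeros((6, 4, 3))
        values[1:5, 1, 1] = 1.0
        vg = build_graph(make_volume(values))
        text = vg.to_json()
        back = VascularGraph.from_json(text)
        assert back.root == vg.root
        assert back.nodes == vg.nodes
        assert sorted(back.g.edges) == sorted(vg.g.edges)
        assert json.loads(back.to_json()) == json.loads(text)

    def test_paint_nodes_inverts_voxel_mapping(self):
        values = np.zeros((6, 4, 3))
        values[1:5, 1, 1] = 1.0
        vg = build_graph(make_volume(values))
        painted = paint_nodes(vg, {n: 1.0 for n in vg.nodes})
        assert np.array_equal(painted > 0, values > 0)
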