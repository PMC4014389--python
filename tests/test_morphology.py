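"""SWC ingestion and tree metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgnet import morphology as m
from dgnet.synthetic import generate_population

from conftest import write_swc


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.5, max_value=80.0), min_size=1, max_size=12))
def test_chain_path_distance_is_sum_of_segments(segments):
    """Path distance along any unbranched chain equals the segment sum."""
    n = len(segments) + 1
    y = np.concatenate([[0.0], np.cumsum(segments)])
    tree = m.MorphTree(
        structure=np.array([1] + [4] * (n - 1)),
        xyz=np.column_stack([np.zeros(n), y, np.zeros(n)]),
        radius=np.full(n, 1.0),
        parent=np.arange(-1, n - 1),
    )
    assert m.path_distance(tree, n - 1) == pytest.approx(sum(segments))
    assert m.max_dendritic_extent(tree) == pytest.approx(sum(segments))


class TestReadSWC:
    def test_three_node_cable(self, tmp_path):
        p = write_swc(tmp_path / "cable.swc", [
            (1, 1, 0, 0, 0, 6.0, -1),
            (2, 4, 0, 25, 0, 1.0, 1),
            (3, 4, 0, 50, 0, 0.8, 2),
        ])
        tree = m.read_swc(p)
        assert tree.n_nodes == 3
        assert int(np.sum(tree.parent < 0)) == 1
        assert m.max_dendritic_extent(tree) == pytest.approx(50.0)

    def test_orphan_parent_is_structure_error(self, tmp_path):
        p = write_swc(tmp_path / "bad.swc", [
            (1, 1, 0, 0, 0, 6.0, -1),
            (2, 4, 0, 25, 0, 1.0, 7),
        ])
        with pytest.raises(m.StructureError):
            m.read_swc(p)

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "mal.swc"
        p.write_text("1 1 0 0 0 6.0 -1\n2 4 0 25\n")
        with pytest.raises(m.SWCParseError, match="line 2"):
            m.read_swc(p)

    def test_round_trip_is_lossless(self, tmp_path, y_tree):
        p = tmp_path / "rt.swc"
        m.write_swc(y_tree, p)
        back = m.read_swc(p)
        np.testing.assert_array_equal(back.structure, y_tree.structure)
        np.testing.assert_allclose(back.xyz, y_tree.xyz, rtol=1e-6)
        np.testing.assert_allclose(back.radius, y_tree.radius, rtol=1e-6)
        np.testing.assert_array_equal(back.parent, y_tree.parent)

    def test_multi_point_soma_collapses_to_centroid(self, tmp_path):
        p = write_swc(tmp_path / "soma3.swc", [
            (1, 1, 0, 0, 0, 5.0, -1),
            (2, 1, 0, 6, 0, 5.0, 1),
            (3, 1, 0, -6, 0, 5.0, 1),
            (4, 4, 0, 30, 0, 1.0, 2),
        ])
        tree = m.read_swc(p)
        assert int(np.sum(tree.structure == m.SOMA)) == 1
        np.testing.assert_allclose(tree.soma_center, [0.0, 0.0, 0.0])
        assert tree.n_nodes == 2  # collapsed soma + 1 apical node


class TestPathDistance:
    def test_soma_root_is_zero(self, chain_tree):
        assert m.path_distance(chain_tree, 0) == 0.0

    def test_chain_additivity(self, chain_tree):
        assert m.path_distance(chain_tree, 2) == pytest.approx(50.0)

    def test_missing_node_raises(self, chain_tree):
        with pytest.raises(KeyError):
            m.path_distance(chain_tree, 99)

    def test_matches_parent_walk_oracle_on_random_trees(self):
        for tree in generate_population("mature", 5, seed=42):
            pl = tree.path_lengths()
            for node in range(tree.n_nodes):
                # independent oracle: walk the parent chain summing segments
                d, i = 0.0, node
                while tree.parent[i] >= 0:
                    d += float(np.linalg.norm(tree.xyz[i] - tree.xyz[tree.parent[i]]))
                    i = tree.parent[i]
                assert pl[node] == pytest.approx(d, abs=1e-9)

    def test_monotone_along_root_to_terminal_paths(self):
        tree = generate_population("young_control", 3, seed=5)[0]
        pl = tree.path_lengths()
        for i in range(1, tree.n_nodes):
            assert pl[i] >= pl[tree.parent[i]]


class TestMaxExtent:
    def test_single_cable(self, chain_tree):
        assert m.max_dendritic_extent(chain_tree) == pytest.approx(50.0)

    def test_y_tree_takes_longest_branch(self, y_tree):
        pl = y_tree.path_lengths()
        terminals = y_tree.children_counts() == 0
        assert m.max_dendritic_extent(y_tree) == pytest.approx(pl[terminals].max())

    def test_population_matches_exhaustive_terminal_scan(self):
        for tree in generate_population("mature", 5, seed=9):
            pl = tree.path_lengths()
            apical_terms = [
                pl[i] for i in range(tree.n_nodes)
                if tree.structure[i] == m.APICAL and tree.children_counts()[i] == 0
            ]
            assert m.max_dendritic_extent(tree) == pytest.approx(max(apical_terms))

    def test_no_apical_nodes_is_error(self):
        soma_only = m.MorphTree(
            np.array([1]), np.zeros((1, 3)), np.array([5.0]), np.array([-1])
        )
        with pytest.raises(ValueError):
            m.max_dendritic_extent(soma_only)


class TestSectionize:
    def test_unbranched_cable_is_one_section(self, chain_tree):
        secs = m.sectionize(chain_tree)
        assert len(secs) == 1
        assert secs[0].path_start == 0.0
        assert secs[0].path_end == pytest.approx(50.0)

    def test_single_y_branch_gives_three_sections(self, y_tree):
        assert len(m.sectionize(y_tree)) == 3

    def test_section_count_matches_degree_oracle(self):
        for tree in generate_population("young_control", 5, seed=13):
            nchild = tree.children_counts()
            dend = tree.is_dendrite()
            # oracle: one section per dendritic branch-start (child of soma,
            # or child of a node with >= 2 children)
            expected = 0
            for i in range(1, tree.n_nodes):
                if not dend[i]:
                    continue
                p = tree.parent[i]
                if p == 0 or nchild[p] >= 2:
                    expected += 1
            assert len(m.sectionize(tree)) == expected

    def test_sections_partition_dendritic_nodes(self):
        tree = generate_population("mature", 2, seed=21)[1]
        covered = [n for s in m.sectionize(tree) for n in s.nodes]
        dendritic = [i for i in range(tree.n_nodes) if tree.is_dendrite()[i]]
        assert sorted(covered) == sorted(dendritic)
        assert len(covered) == len(set(covered))

    def test_section_table_export(self, y_tree):
        df = m.section_table(y_tree)
        assert list(df.columns) == [
            "section_id", "parent", "structure", "path_start", "path_end", "n_nodes"
        ]
        assert len(df) == 3
        assert (df.path_end > df.path_start).all()
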