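"""Adjacency construction and permutation statistics, checked against
brute-force pairwise scans and exhaustive label enumeration."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from inflarch import spatialstats as ss
from inflarch import synthdata as sd

from conftest import make_point_map


class TestBuildAdjacencyPoints:
    def test_single_cell_has_no_edges(self):
        cm = make_point_map([(50.0, 50.0, "A")])
        g = ss.build_adjacency(cm)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 1

    def test_boundary_gap_cut_at_threshold(self):
        # radius-4 disks: centre distance 12 -> gap 4 (edge), 13 -> gap 5 (none)
        near = make_point_map([(50.0, 50.0, "A"), (62.0, 50.0, "B")])
        far = make_point_map([(50.0, 50.0, "A"), (63.0, 50.0, "B")])
        assert ss.build_adjacency(near, threshold_px=4).number_of_edges() == 1
        assert ss.build_adjacency(far, threshold_px=4).number_of_edges() == 0

    def test_zymosan_participates_as_node(self):
        cm = make_point_map([(50.0, 50.0, "A")], zymosan=[(57.0, 50.0, 2.0)])
        g = ss.build_adjacency(cm)
        assert ("zymosan", 1) in g.nodes
        assert g.nodes[("zymosan", 1)]["label"] == "zymosan"
        assert g.has_edge(("cell", 1), ("zymosan", 1))  # gap 1 px

    def test_negative_threshold_rejected(self, default_map):
        with pytest.raises(ValueError, match="threshold"):
            ss.build_adjacency(default_map, threshold_px=-1)

    def test_matches_brute_force_on_generated_map(self, default_map, default_graph):
        cells = default_map.cells
        radius = np.sqrt(cells["area"].to_numpy() / math.pi)
        xy = cells[["x", "y"]].to_numpy()
        expected = set()
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                gap = np.hypot(*(xy[i] - xy[j])) - radius[i] - radius[j]
                if gap <= 4.0:
                    expected.add(
                        (int(cells["cell_id"].iloc[i]), int(cells["cell_id"].iloc[j]))
                    )
        got = {
            tuple(sorted((u[1], v[1])))
            for u, v in default_graph.edges
            if u[0] == "cell" and v[0] == "cell"
        }
        assert got == expected


class TestBuildAdjacencyMask:
    def test_single_pixel_cells_four_versus_five_gap(self):
        mask = np.zeros((11, 11), dtype=np.int32)
        mask[5, 0], mask[5, 5] = 1, 2  # 4 empty pixels between boundaries
        assert ss.build_adjacency(mask, threshold_px=4).number_of_edges() == 1
        mask2 = np.zeros((11, 11), dtype=np.int32)
        mask2[5, 0], mask2[5, 6] = 1, 2  # 5 empty pixels
        assert ss.build_adjacency(mask2, threshold_px=4).number_of_edges() == 0

    def test_matches_pairwise_pixel_distance_oracle(self):
        from skimage.draw import disk

        rng = np.random.default_rng(4)
        mask = np.zeros((120, 120), dtype=np.int32)
        centers = rng.uniform(8, 112, size=(20, 2))
        for i, (y, x) in enumerate(centers, start=1):
            rr, cc = disk((y, x), rng.uniform(2, 5), shape=mask.shape)
            mask[rr, cc] = i
        g = ss.build_adjacency(mask, threshold_px=4)

        pix = {
            int(l): np.argwhere(mask == l).astype(float) for l in np.unique(mask) if l
        }
        expected = set()
        for a, b in itertools.combinations(sorted(pix), 2):
            dmin = min(
                np.hypot(*(pa - pb)) for pa in pix[a] for pb in pix[b]
            )
            if dmin - 1.0 <= 4.0:  # unit-square pixels: boundary gap = centre dist - 1
                expected.add((a, b))
        got = {tuple(sorted((u[1], v[1]))) for u, v in g.edges}
        assert got == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no objects"):
            ss.build_adjacency(np.zeros((8, 8), dtype=np.int32))

    def test_zymosan_mask_nodes_are_fixed_references(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:8, 5:8] = 1
        zym = np.zeros((20, 20), dtype=np.int32)
        zym[9:11, 5:8] = 1
        g = ss.adjacency_from_mask(mask, 4.0, zymosan_mask=zym)
        assert g.nodes[("zymosan", 1)]["kind"] == "zymosan"
        assert g.has_edge(("cell", 1), ("zymosan", 1))


class TestInteractionLikelihood:
    def test_maximal_enrichment_scores_zero(self, enrichment_map):
        g = ss.build_adjacency(enrichment_map)
        r = ss.interaction_likelihood(g, "zymosan", "A", n_perm=1000, seed=7)
        assert r.count_obs == 5
        assert r.d == 0.0 and r.L == 1.0

    def test_maximal_avoidance_scores_two(self, enrichment_map):
        g = ss.build_adjacency(enrichment_map)
        r = ss.interaction_likelihood(g, "zymosan", "B", n_perm=1000, seed=7)
        assert r.count_obs == 0
        assert r.d == 2.0 and r.L == 0.0

    def test_symmetry_in_type_order(self, enrichment_map):
        g = ss.build_adjacency(enrichment_map)
        ab = ss.interaction_likelihood(g, "A", "B", n_perm=500, seed=3)
        ba = ss.interaction_likelihood(g, "B", "A", n_perm=500, seed=3)
        assert ab.count_obs == ba.count_obs and ab.d == ba.d

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """On a 6-cell map the Monte-Carlo mid-p converges to the exact
        likelihood from full label enumeration."""
        cells = [
            (10.0, 10.0, "A"), (14.0, 10.0, "A"), (30.0, 30.0, "B"),
            (31.0, 35.0, "B"), (50.0, 50.0, "A"), (60.0, 10.0, "B"),
        ]
        cm = make_point_map(cells, zymosan=[(12.0, 12.0, 3.0)], cell_radius=2.0)
        g = ss.build_adjacency(cm)
        nodes = list(g.nodes)
        cell_nodes = [n for n in nodes if g.nodes[n]["kind"] != "zymosan"]
        base = [g.nodes[n]["label"] for n in cell_nodes]

        def count(assignment):
            lab = dict(zip(cell_nodes, assignment))
            lab.update({n: "zymosan" for n in nodes if n not in lab})
            return sum(
                1 for u, v in g.edges if {lab[u], lab[v]} == {"zymosan", "A"}
            )

        obs = count(base)
        all_counts = [count(p) for p in itertools.permutations(base)]
        exact = (
            sum(c < obs for c in all_counts) + 0.5 * sum(c == obs for c in all_counts)
        ) / len(all_counts)
        mc = ss.interaction_likelihood(g, "zymosan", "A", n_perm=10_000, seed=5)
        assert mc.count_obs == obs
        assert abs(mc.L - exact) < 0.02

    def test_absent_type_error_names_the_type(self, enrichment_map):
        g = ss.build_adjacency(enrichment_map)
        with pytest.raises(ValueError, match="'C'"):
            ss.interaction_likelihood(g, "zymosan", "C", n_perm=10, seed=0)

    def test_degenerate_single_type_null_is_neutral(self):
        cm = make_point_map(
            [(10.0, 10.0, "A"), (15.0, 10.0, "A")], zymosan=[(10.0, 16.0, 2.0)]
        )
        g = ss.build_adjacency(cm)
        with pytest.warns(UserWarning, match="degenerate"):
            r = ss.interaction_likelihood(g, "zymosan", "A", n_perm=100, seed=0)
        assert r.L == 0.5 and r.d == 1.0

    def test_result_invariants_on_generated_map(self, default_graph):
        r = ss.interaction_likelihood(default_graph, "zymosan", "M1-like", n_perm=300, seed=1)
        assert 0.0 <= r.L <= 1.0 and 0.0 <= r.d <= 2.0
        assert r.n_less + r.n_ties <= r.n_perm
        assert r.d == pytest.approx(2.0 * (1.0 - r.L))

    def test_reproducible_given_seed(self, default_graph):
        a = ss.interaction_likelihood(default_graph, "zymosan", "M2-like", n_perm=200, seed=9)
        b = ss.interaction_likelihood(default_graph, "zymosan", "M2-like", n_perm=200, seed=9)
        assert a.L == b.L and a.count_obs == b.count_obs


def csr_config(seed: int) -> sd.SyntheticTissueConfig:
    dens = {p: {r: 3.0 for r in sd.REGIONS} for p in sd.DEFAULT_DENSITIES}
    return sd.SyntheticTissueConfig(
        field_size=(256, 256), densities=dens, n_zymosan=15, seed=seed
    )


class TestDistanceMap:
    def test_spatially_random_phenotypes_average_to_neutral(self):
        """With uniformly random phenotypes the mid-p is exchangeable, so the
        relative distance averages to 1 over maps (single maps scatter)."""
        vals = []
        for seed in range(20):
            cm = sd.generate_tissue_map(csr_config(seed))
            dm = ss.distance_map(cm, n_perm=300, seed=900 + seed)
            vals.extend(dm.distances.values())
        assert 0.85 <= float(np.mean(vals)) <= 1.15

    def test_core_pi_ai_layering_orders_distances(self, default_map):
        dm = ss.distance_map(default_map, n_perm=500, seed=202)
        d = dm.distances
        assert d["neutrophil"] < d["M1-like"] < d["M2-like"]

    def test_absent_phenotype_flagged_not_scored(self, default_map):
        dm = ss.distance_map(
            default_map, phenotypes=["neutrophil", "mast"], n_perm=50, seed=0
        )
        assert dm.absent == ["mast"]
        assert "mast" not in dm.entries and "neutrophil" in dm.entries

    def test_missing_center_rejected(self, default_map):
        with pytest.raises(ValueError, match="center"):
            ss.distance_map(default_map, center="mast", n_perm=10, seed=0)

    def test_csv_export_round_trip(self, default_map, tmp_path):
        dm = ss.distance_map(default_map, n_perm=50, seed=0)
        path = tmp_path / "dm.csv"
        dm.to_csv(path)
        back = pd.read_csv(path)
        assert set(back["phenotype"]) == set(dm.entries)
        assert back["d"].between(0, 2).all()


class TestPiRegionSize:
    def test_projection_of_m2_entry(self, default_map):
        dm = ss.distance_map(default_map, n_perm=200, seed=3)
        assert ss.pi_region_size(dm) == dm.entries["M2-like"].d

    def test_missing_m2_entry_rejected(self, default_map):
        dm = ss.distance_map(default_map, phenotypes=["neutrophil"], n_perm=20, seed=0)
        with pytest.raises(ValueError, match="M2-like"):
            ss.pi_region_size(dm)

    def test_m2_ring_abutting_core_shrinks_pi_region(self):
        """A map whose AI ring is displaced onto the core scores a smaller
        PI size than the default layered architecture."""
        sizes = {}
        for offset in (0.0, -90.0):
            cfg = sd.SyntheticTissueConfig(seed=4, ring_offsets={"M2-like": offset})
            cm = sd.generate_tissue_map(cfg)
            r = ss.interaction_likelihood(
                ss.build_adjacency(cm), "zymosan", "M2-like", n_perm=300, seed=504
            )
            sizes[offset] = r.d
        assert sizes[-90.0] < sizes[0.0]


class TestPercentOfControl:
    @pytest.mark.parametrize(
        "d_int,d_ctrl,expected", [(1.0, 2.0, 50.0), (2.0, 2.0, 100.0), (0.7, 1.4, 50.0)]
    )
    def test_ratio(self, d_int, d_ctrl, expected):
        assert ss.percent_of_control(d_int, d_ctrl) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ss.percent_of_control(1.0, 0.0)


class TestDualNetwork:
    def test_center_self_distance_is_zero(self, default_map):
        net = ss.dual_network(default_map, n_perm=150, seed=5)
        assert net.graph.nodes["M2-like"]["d_to_b"] == 0.0

    def test_neutrophils_sit_near_zymosan_axis_origin(self, default_map):
        net = ss.dual_network(default_map, n_perm=150, seed=5)
        coords = net.coordinates()
        assert coords["neutrophil"][0] < coords["M2-like"][0]

    def test_identical_centers_rejected(self, default_map):
        with pytest.raises(ValueError, match="differ"):
            ss.dual_network(default_map, center_a="zymosan", center_b="zymosan")

    def test_random_phenotypes_center_near_neutral_point(self):
        """Averaged over CSR maps, node coordinates approach (1, 1)."""
        xs, ys = [], []
        for seed in range(12):
            cm = sd.generate_tissue_map(csr_config(seed))
            net = ss.dual_network(cm, n_perm=150, seed=700 + seed)
            x, y = net.coordinates()["DC"]
            xs.append(x)
            ys.append(y)
        assert abs(np.mean(xs) - 1.0) < 0.45 and abs(np.mean(ys) - 1.0) < 0.45

    def test_graphml_export(self, default_map, tmp_path):
        net = ss.dual_network(default_map, n_perm=100, seed=1)
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.graph.nodes)
        for n in back.nodes:
            assert 0.0 <= float(back.nodes[n]["x"]) <= 2.0
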