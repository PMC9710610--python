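import numpy as np
import pandas as pd
import pytest

from screpsim.dynamics import SimulationParams, run_simulation
from screpsim.shm import ShmModel
from screpsim.spatial import (
    annotate_cell_types,
    assign_clones,
    estimate_density,
    make_synthetic_spots,
    trajectory_edges,
)


class TestAnnotateCellTypes:
    def counts(self, data):
        genes = ["Cd3e", "Cd4", "Cd8a", "Cd19", "Sdc1", "Xbp1"]
        return pd.DataFrame(data, index=genes).astype(float)

    def test_zero_marker_counts_other(self):
        c = self.counts({"s1": [0, 0, 0, 0, 0, 0]})
        assert annotate_cell_types(c)["s1"] == "other"

    def test_cd3e_only_is_t(self):
        c = self.counts({"s1": [7, 0, 0, 0, 0, 0]})
        assert annotate_cell_types(c)["s1"] == "T"

    def test_exact_tie_is_other(self):
        c = self.counts({"s1": [5, 0, 0, 5, 0, 0]})
        assert annotate_cell_types(c)["s1"] == "other"

    def test_missing_panel_errors(self):
        c = pd.DataFrame({"s1": [3.0]}, index=["Cd19"])
        with pytest.raises(ValueError, match="T-cell markers"):
            annotate_cell_types(c)

    def test_synthetic_image_recovered(self, rng):
        spots, counts = make_synthetic_spots(300, rng)
        kinds = annotate_cell_types(counts)
        assert (kinds == "B").sum() > 100
        assert (kinds == "T").sum() > 70


class TestEstimateDensity:
    def test_single_spot(self):
        d = estimate_density(np.array([[3.0, 4.0]]))
        assert d.shape == (1,) and d[0] > 0

    def test_symmetric_clusters_balanced(self, rng):
        a = rng.normal((0, 0), 1.0, size=(50, 2))
        b = rng.normal((100, 0), 1.0, size=(50, 2))
        xy = np.vstack([a, b])
        d = estimate_density(xy)
        mean_a, mean_b = d[:50].mean(), d[50:].mean()
        assert abs(mean_a - mean_b) / max(mean_a, mean_b) < 0.1
        # maxima sit inside the clusters, not between them
        mid = estimate_density(xy, np.array([[50.0, 0.0]]))
        assert d.max() > 10 * mid[0]

    def test_uniform_grid_flat_interior(self):
        g = np.arange(10, dtype=float)
        xy = np.array([(x, y) for x in g for y in g])
        d = estimate_density(xy)
        interior = np.array(
            [v for (x, y), v in zip(xy, d) if 2 <= x <= 7 and 2 <= y <= 7]
        )
        assert interior.max() / interior.min() < 1.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_density(np.empty((0, 2)))


def line_spots(xs, celltype="B"):
    return pd.DataFrame(
        {
            "barcode": [f"S{i}" for i in range(len(xs))],
            "x": list(map(float, xs)),
            "y": [0.0] * len(xs),
            "celltype": celltype,
        }
    )


def simulate_cells(settings, n_clones=3, n_steps=6, seed=0, shm=True, **kw):
    params = SimulationParams(
        init_clones=n_clones, n_steps=n_steps, p_new_clone=0.0, p_death=0.0,
        seed=seed, **kw,
    )
    return run_simulation(params, shm_model=ShmModel() if shm else None, settings=settings)


class _ForcedChoiceRng:
    """Deterministic stand-in whose first categorical draw returns a fixed
    index (used to pin the founder spot)."""

    def __init__(self, forced_index):
        self.forced = forced_index

    def choice(self, n, p=None, **kw):
        return self.forced


class TestAssignClones:
    def test_single_cell_lands_on_matching_spot(self, fast_settings, rng):
        state = simulate_cells(fast_settings, n_clones=1, n_steps=0)
        spots = line_spots([0, 1, 2, 3])
        for method in ("random", "density", "germline"):
            a = assign_clones(state, spots, method, np.random.default_rng(0))
            assert len(a.table) == 1
            assert a.table["spot_barcode"].iloc[0] in set(spots["barcode"])

    def test_germline_members_take_nearest_ascending(self, fast_settings):
        """Founder pinned at x=0: a 4-cell clone occupies x=1,2,3 (not 9)."""
        state = simulate_cells(
            fast_settings, n_clones=1, n_steps=2, p_div0=1.0, p_max=1.0, shm=False
        )
        cells = state.alive_cells()
        assert len(cells) == 4
        spots = line_spots([0, 1, 2, 3, 9])
        a = assign_clones(state, spots, "germline", _ForcedChoiceRng(0))
        assert sorted(a.table["x"]) == [0.0, 1.0, 2.0, 3.0]

    def test_injective_and_celltype_consistent(self, fast_settings, rng):
        state = simulate_cells(fast_settings, n_clones=4, n_steps=4)
        spots, counts = make_synthetic_spots(400, rng)
        spots = spots.assign(celltype=annotate_cell_types(counts).to_numpy())
        for method in ("random", "density", "germline"):
            a = assign_clones(state, spots, method, np.random.default_rng(1))
            assert a.table["spot_barcode"].is_unique
            kinds = spots.set_index("barcode")["celltype"]
            assert (kinds.loc[a.table["spot_barcode"]] == "B").all()

    def test_insufficient_spots_error(self, fast_settings):
        state = simulate_cells(fast_settings, n_clones=3, n_steps=0)
        spots = line_spots([0, 1])
        with pytest.raises(ValueError, match="short by 1"):
            assign_clones(state, spots, "random", np.random.default_rng(0))

    def test_germline_tighter_than_random(self, fast_settings):
        """Mean intra-clone pairwise spot distance: germline < random,
        averaged over 5 seeds on a 500-spot synthetic image."""
        means = {"germline": [], "random": []}
        for seed in range(5):
            state = simulate_cells(fast_settings, n_clones=4, n_steps=4, seed=seed)
            spots, counts = make_synthetic_spots(500, np.random.default_rng(seed))
            spots = spots.assign(celltype=annotate_cell_types(counts).to_numpy())
            for method in means:
                a = assign_clones(state, spots, method, np.random.default_rng(seed))
                dists = []
                for _, sub in a.table.groupby("clone_id"):
                    if len(sub) < 2:
                        continue
                    xy = sub[["x", "y"]].to_numpy()
                    from scipy.spatial.distance import pdist

                    dists.append(pdist(xy).mean())
                means[method].append(np.mean(dists))
        assert np.mean(means["germline"]) < np.mean(means["random"])

    def test_density_targets_dense_regions(self, fast_settings):
        """Density method places the largest clone in higher-density spots
        than random, on average over seeds."""
        diffs = []
        for seed in range(5):
            state = simulate_cells(fast_settings, n_clones=3, n_steps=4, seed=seed)
            spots, counts = make_synthetic_spots(500, np.random.default_rng(100 + seed))
            spots = spots.assign(celltype=annotate_cell_types(counts).to_numpy())
            b = spots.loc[spots["celltype"] == "B"]
            dens = pd.Series(
                estimate_density(b[["x", "y"]].to_numpy()), index=b["barcode"].to_numpy()
            )
            sizes = state.clone_sizes()
            top = max(sizes, key=sizes.get)
            vals = {}
            for method in ("density", "random"):
                a = assign_clones(state, spots, method, np.random.default_rng(seed))
                sub = a.table.loc[a.table["clone_id"] == top]
                vals[method] = dens.loc[sub["spot_barcode"]].mean()
            diffs.append(vals["density"] - vals["random"])
        assert np.mean(diffs) > 0


class TestTrajectoryEdges:
    def make_assignment(self, fast_settings, seed=0):
        state = simulate_cells(fast_settings, n_clones=2, n_steps=5, seed=seed)
        spots = line_spots(np.arange(len(state.alive_cells()) + 10))
        a = assign_clones(state, spots, "random", np.random.default_rng(seed))
        return state, a

    def test_single_variant_clone_no_edges(self, fast_settings):
        state = simulate_cells(fast_settings, n_clones=1, n_steps=0)
        spots = line_spots([0, 1])
        a = assign_clones(state, spots, "random", np.random.default_rng(0))
        edges = trajectory_edges(a, state.networks, mode="all")
        assert edges.empty

    def test_all_mode_links_every_parent_cell(self):
        """3 parent cells, 1 child: 3 edges in 'all', 1 nearest edge from
        the minimal-distance parent (ties to smallest spot barcode)."""
        from screpsim.lineage import LineageNetwork, record_mutation
        from screpsim.spatial import SpatialAssignment

        net = LineageNetwork(0, "AAAA|CCCC")
        record_mutation(net, 0, "AATA|CCCC")
        table = pd.DataFrame(
            {
                "cell_barcode": ["p1", "p2", "p3", "ch"],
                "spot_barcode": ["S1", "S2", "S3", "S4"],
                "x": [0.0, 5.0, 10.0, 6.0],
                "y": [0.0, 0.0, 0.0, 0.0],
                "clone_id": [0, 0, 0, 0],
                "variant_id": [0, 0, 0, 1],
            }
        )
        a = SpatialAssignment(method="random", table=table)
        all_edges = trajectory_edges(a, {0: net}, mode="all")
        assert len(all_edges) == 3
        nearest = trajectory_edges(a, {0: net}, mode="nearest")
        assert len(nearest) == 1
        assert nearest["from_barcode"].iloc[0] == "p2"  # |5-6| = 1 is minimal

    def test_nearest_subset_of_all(self, fast_settings):
        state, a = self.make_assignment(fast_settings)
        all_e = trajectory_edges(a, state.networks, mode="all")
        near_e = trajectory_edges(a, state.networks, mode="nearest")
        key = ["from_barcode", "to_barcode"]
        all_pairs = set(map(tuple, all_e[key].to_numpy()))
        near_pairs = set(map(tuple, near_e[key].to_numpy()))
        assert near_pairs <= all_pairs
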