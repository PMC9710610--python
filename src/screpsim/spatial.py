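"""Spatial integration: spot annotation, kernel density, clonotype
assignment and evolutionary trajectory edges.

Spots (barcoded capture locations with x/y image coordinates, origin
top-left, y increasing downward) are annotated as B or T cells from
marker expression; simulated receptor-bearing cells are then mapped onto
spots of the matching cell type by one of three methods: uniform random,
density-weighted (expanded clones preferentially land in dense regions,
density re-estimated over unassigned spots after each clone) or
germline-based (a clone's founder is placed by density, remaining members
take the nearest unassigned spots by Euclidean distance from the
founder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

T_MARKERS = ["Cd3e", "Cd4", "Cd8a"]
B_MARKERS = ["Cd19", "Sdc1", "Xbp1"]


def annotate_cell_types(
    counts: pd.DataFrame,
    t_markers: list[str] = T_MARKERS,
    b_markers: list[str] = B_MARKERS,
) -> pd.Series:
    """Classify each spot (column of ``counts``, genes x spots) as B/T/other.

    Counts are normalized to unit sum per spot and log1p-transformed; each
    spot is scored by the summed normalized expression of the marker panel
    and labelled by the larger score.  Zero or exactly tied scores give
    ``other``.  Missing markers warn and are dropped; a panel with no
    marker present is an error.
    """

    def present(markers: list[str], cls: str) -> list[str]:
        found = [m for m in markers if m in counts.index]
        for m in set(markers) - set(found):
            logger.warning("%s marker %s missing from gene list; dropped", cls, m)
        if not found:
            raise ValueError(f"no {cls}-cell markers present in the gene list")
        return found

    t_found, b_found = present(t_markers, "T"), present(b_markers, "B")
    totals = counts.sum(axis=0).replace(0, 1.0)
    norm = np.log1p(counts / totals)
    s_t = norm.loc[t_found].sum(axis=0)
    s_b = norm.loc[b_found].sum(axis=0)
    out = pd.Series("other", index=counts.columns, dtype=object)
    out[(s_t > s_b) & (s_t > 0)] = "T"
    out[(s_b > s_t) & (s_b > 0)] = "B"
    return out


def estimate_density(xy: np.ndarray, eval_xy: np.ndarray | None = None) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel density with Scott's-rule bandwidth.

    Evaluated at ``eval_xy`` (defaults to the input points).  Degenerate
    inputs (a single spot, zero spread) fall back to a unit bandwidth so a
    finite positive density is always returned.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 1:
        raise ValueError("xy must be an (n, 2) array with n >= 1")
    if eval_xy is None:
        eval_xy = xy
    n = xy.shape[0]
    sigma = float(np.sqrt(xy.var(axis=0).mean()))
    h = sigma * n ** (-1.0 / 6.0)  # Scott's rule, d=2
    if h <= 0:
        h = 1.0
    d2 = cdist(eval_xy, xy, "sqeuclidean")
    return np.exp(-d2 / (2 * h * h)).sum(axis=1) / (n * 2 * np.pi * h * h)


@dataclass
class SpatialAssignment:
    """Injective map from simulated cells to spots of the matching type."""

    method: str
    table: pd.DataFrame  # cell_barcode, spot_barcode, x, y, clone_id, variant_id

    @property
    def mapping(self) -> dict[str, str]:
        return dict(zip(self.table["cell_barcode"], self.table["spot_barcode"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _founder_cell(state, cells):
    """The clone member closest to the germline root (depth, then age)."""
    net = state.networks[cells[0].clone_id]
    return min(cells, key=lambda c: (net.depth_of(c.variant_id), c.birth_step, c.barcode))


def assign_clones(
    state,
    spots: pd.DataFrame,
    method: str,
    rng: np.random.Generator,
    celltype: str = "B",
) -> SpatialAssignment:
    """Assign every alive simulated cell to a distinct annotated spot.

    ``spots`` needs columns barcode, x, y, celltype.  Clones are processed
    in descending alive-cell count (ties by clone id); see the module
    docstring for the three methods.
    """
    if method not in ("random", "density", "germline"):
        raise ValueError(f"unknown assignment method {method!r}")
    pool = spots.loc[spots["celltype"] == celltype].reset_index(drop=True)
    cells = state.alive_cells()
    if len(cells) > len(pool):
        raise ValueError(
            f"{len(cells)} cells but only {len(pool)} {celltype} spots "
            f"(short by {len(cells) - len(pool)})"
        )
    coords = pool[["x", "y"]].to_numpy(dtype=float)
    unassigned = list(range(len(pool)))
    rows = []

    def take(idx: int, cell) -> None:
        unassigned.remove(idx)
        rows.append(
            {
                "cell_barcode": cell.barcode,
                "spot_barcode": pool.at[idx, "barcode"],
                "x": float(coords[idx, 0]),
                "y": float(coords[idx, 1]),
                "clone_id": cell.clone_id,
                "variant_id": cell.variant_id,
            }
        )

    if method == "random":
        order = rng.choice(len(pool), size=len(cells), replace=False)
        for cell, idx in zip(cells, order):
            take(int(idx), cell)
    else:
        by_clone: dict[int, list] = {}
        for c in cells:
            by_clone.setdefault(c.clone_id, []).append(c)
        clone_order = sorted(by_clone, key=lambda cid: (-len(by_clone[cid]), cid))
        for cid in clone_order:
            members = by_clone[cid]
            dens = estimate_density(coords[unassigned])
            if method == "density":
                for cell in members:
                    probs = dens / dens.sum()
                    pick = int(rng.choice(len(unassigned), p=probs))
                    idx = unassigned[pick]
                    dens = np.delete(dens, pick)
                    take(idx, cell)
            else:  # germline
                founder = _founder_cell(state, members)
                probs = dens / dens.sum()
                pick = int(rng.choice(len(unassigned), p=probs))
                f_idx = unassigned[pick]
                take(f_idx, founder)
                rest = [c for c in members if c.barcode != founder.barcode]
                if rest:
                    dist = cdist(coords[unassigned], coords[f_idx][None, :]).ravel()
                    order_ = np.argsort(dist, kind="stable")[: len(rest)]
                    spot_ids = [unassigned[int(k)] for k in order_]
                    for cell, idx in zip(rest, spot_ids):
                        take(idx, cell)
    return SpatialAssignment(method=method, table=pd.DataFrame(rows))


def trajectory_edges(
    assignment: SpatialAssignment, networks: dict, mode: str = "nearest"
) -> pd.DataFrame:
    """Directed evolution edges in image coordinates.

    For each assigned cell whose variant has a parent in its clone's
    lineage network, draw edges from the assigned cells carrying the
    parent variant: all of them (``mode='all'``) or only the geometrically
    nearest (``mode='nearest'``, ties to the lexicographically smallest
    spot barcode).  Cells whose parent variant has no living assigned cell
    are skipped.
    """
    if mode not in ("nearest", "all"):
        raise ValueError(f"unknown trajectory mode {mode!r}")
    t = assignment.table
    rows = []
    for clone_id, sub in t.groupby("clone_id"):
        net = networks[clone_id]
        by_variant: dict[int, pd.DataFrame] = {
            int(v): g for v, g in sub.groupby("variant_id")
        }
        for _, cell_row in sub.iterrows():
            parent = net.nodes[int(cell_row["variant_id"])].parent
            if parent is None:
                continue
            parents = by_variant.get(int(parent))
            if parents is None:
                logger.debug(
                    "clone %s: parent variant %s of %s has no assigned cell",
                    clone_id, parent, cell_row["cell_barcode"],
                )
                continue
            if mode == "all":
                chosen = parents
            else:
                d = np.hypot(
                    parents["x"] - cell_row["x"], parents["y"] - cell_row["y"]
                )
                dmin = d.min()
                candidates = parents.loc[d <= dmin]
                chosen = candidates.loc[[candidates["spot_barcode"].idxmin()]]
            for _, p_row in chosen.iterrows():
                rows.append(
                    {
                        "clone_id": clone_id,
                        "from_barcode": p_row["cell_barcode"],
                        "to_barcode": cell_row["cell_barcode"],
                        "x0": p_row["x"],
                        "y0": p_row["y"],
                        "x1": cell_row["x"],
                        "y1": cell_row["y"],
                        "parent_variant": int(parent),
                        "child_variant": int(cell_row["variant_id"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id", "from_barcode", "to_barcode",
            "x0", "y0", "x1", "y1", "parent_variant", "child_variant",
        ],
    )


def make_synthetic_spots(
    n_spots: int,
    rng: np.random.Generator,
    b_frac: float = 0.45,
    t_frac: float = 0.35,
    extent: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic tissue image: clustered B and T regions plus background.

    Returns (spot table with barcode/x/y, marker count matrix genes x
    spots) such that :func:`annotate_cell_types` recovers the intended
    classes.  B spots cluster around one focus and T spots around another,
    mimicking segregated zones of a lymph node section.
    """
    n_b = int(n_spots * b_frac)
    n_t = int(n_spots * t_frac)
    n_o = n_spots - n_b - n_t
    centers = {"B": (0.3 * extent, 0.35 * extent), "T": (0.7 * extent, 0.65 * extent)}
    xy = []
    kinds = []
    for kind, n in (("B", n_b), ("T", n_t)):
        cx, cy = centers[kind]
        pts = rng.normal((cx, cy), 0.12 * extent, size=(n, 2))
        xy.append(pts)
        kinds += [kind] * n
    xy.append(rng.uniform(0, extent, size=(n_o, 2)))
    kinds += ["other"] * n_o
    xy = np.clip(np.vstack(xy), 0, extent)
    spots = pd.DataFrame(
        {
            "barcode": [f"SPOT{i:05d}-1" for i in range(n_spots)],
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
    genes = T_MARKERS + B_MARKERS + [f"Bg{i}" for i in range(10)]
    counts = pd.DataFrame(
        rng.poisson(1.0, size=(len(genes), n_spots)),
        index=genes,
        columns=spots["barcode"],
    )
    for j, kind in enumerate(kinds):
        markers = B_MARKERS if kind == "B" else T_MARKERS if kind == "T" else []
        for m in markers:
            counts.loc[m, spots["barcode"][j]] += rng.poisson(20)
    return spots, counts
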