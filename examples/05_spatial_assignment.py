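"""Place simulated clonotypes onto a synthetic tissue image.

Annotates spots as B/T cells from marker expression, assigns simulated
cells to B spots by the three methods, and derives evolutionary
trajectory edges in image coordinates.
"""

import numpy as np
from scipy.spatial.distance import pdist

from screpsim import (
    ShmModel,
    SimulationParams,
    annotate_cell_types,
    assign_clones,
    make_synthetic_spots,
    run_simulation,
    trajectory_edges,
)

rng = np.random.default_rng(5)
spots, counts = make_synthetic_spots(500, rng)
spots["celltype"] = annotate_cell_types(counts).to_numpy()
print(spots["celltype"].value_counts().to_dict())

params = SimulationParams(init_clones=4, n_steps=4, p_new_clone=0.0, p_death=0.0, seed=5)
state = run_simulation(params, shm_model=ShmModel())

for method in ("random", "density", "germline"):
    a = assign_clones(state, spots, method, np.random.default_rng(5))
    spread = np.mean([
        pdist(sub[["x", "y"]].to_numpy()).mean()
        for _, sub in a.table.groupby("clone_id") if len(sub) > 1
    ])
    print(f"{method:>8}: mean intra-clone spot distance {spread:.1f}")

a = assign_clones(state, spots, "germline", np.random.default_rng(5))
edges = trajectory_edges(a, state.networks, mode="nearest")
print(f"trajectory edges (nearest-parent): {len(edges)}")
# Germline assignment clusters each clone around its founder, so its
# intra-clone distances are the smallest; trajectory edges point from a
# parent variant's position to its mutated descendant on the image.
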