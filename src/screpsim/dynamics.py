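"""Time-stepped clonal dynamics: expansion, death, influx, class switching,
phenotype transitions, variant selection and SHM-driven lineage growth.

Each step processes, in this fixed order: (1) possible founding of one new
clone, (2) division of alive cells — each daughter may acquire SHM, which
grows the clone's lineage network, (3) isotype and phenotype transitions,
(4) cell death.  Newborn daughters are exempt from switching and death in
their birth step.  All events are appended to a replayable log.

Division probability follows a clone-size feedback law
``clamp(p_div0 + beta_div*(n-1), 0, p_max)``; selected variants multiply it
by ``sel_multiplier`` (capped at 1).  Clone sizes used in a step are
snapshotted at the start of the division phase so results do not depend on
cell iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .germline import PairedReceptor, RecombinationSettings, simulate_initial_repertoire
from .lineage import CHAIN_SEP, LineageNetwork, record_mutation
from .shm import ShmModel, mutate_sequence

ISOTYPES = ("IGHM", "IGHD", "IGHG", "IGHA", "IGHE")
PHENOTYPES = ("Naive", "GC", "Memory", "Plasma")

_BASES = "ACGT"
_MIX = 0x9E3779B9 | 1  # odd -> bijection mod 4**16 == 2**32


def make_barcode(index: int) -> str:
    """Deterministic, collision-free 10x-style barcode (16-mer + '-1')."""
    h = (index * _MIX) % (1 << 32)
    chars = []
    for _ in range(16):
        chars.append(_BASES[h & 3])
        h >>= 2
    return "".join(chars) + "-1"


def default_isotype_matrix() -> np.ndarray:
    """Upper-triangular per-step class-switch matrix in the order
    IGHM, IGHD, IGHG, IGHA, IGHE.

    Switch masses are small per step so that a default-length run ends with
    the biological frequency ordering IgM > IgG > IgA > IgE; switching is
    irreversible (no mass below the diagonal).
    """
    return np.array(
        [
            [0.950, 0.003, 0.032, 0.012, 0.003],
            [0.000, 0.950, 0.035, 0.012, 0.003],
            [0.000, 0.000, 0.990, 0.008, 0.002],
            [0.000, 0.000, 0.000, 0.998, 0.002],
            [0.000, 0.000, 0.000, 0.000, 1.000],
        ]
    )


def default_phenotype_matrix() -> np.ndarray:
    """Per-step phenotype transitions over (Naive, GC, Memory, Plasma)."""
    return np.array(
        [
            [0.90, 0.08, 0.01, 0.01],
            [0.00, 0.85, 0.10, 0.05],
            [0.00, 0.02, 0.93, 0.05],
            [0.00, 0.00, 0.00, 1.00],
        ]
    )


def plasma_biased_phenotype_matrix() -> np.ndarray:
    """Alternative transition rows for selected variants: plasma-absorbing."""
    return np.array(
        [
            [0.55, 0.10, 0.05, 0.30],
            [0.00, 0.50, 0.10, 0.40],
            [0.00, 0.02, 0.58, 0.40],
            [0.00, 0.00, 0.00, 1.00],
        ]
    )


def _check_stochastic(m: np.ndarray, n: int, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}")
    if (m < 0).any():
        raise ValueError(f"{name} has a negative entry")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} rows must each sum to 1")
    return m


@dataclass
class SimulationParams:
    """All rates and transition structure of one simulation run.

    Defaults describe a moderately expanding B-cell repertoire over 15
    steps: per-step division 0.2 with weak positive clone-size feedback,
    2% death, 20% per-division SHM with ~5 mutations per event handled by
    the SHM model, and slow irreversible class switching from IgM.
    """

    n_steps: int = 15
    init_clones: int = 200
    p_new_clone: float = 0.05
    p_div0: float = 0.2
    beta_div: float = 0.005
    p_death: float = 0.02
    p_max: float = 0.5
    isotype_T: np.ndarray = field(default_factory=default_isotype_matrix)
    phenotype_T: np.ndarray = field(default_factory=default_phenotype_matrix)
    phenotype_T_selected: np.ndarray | None = None
    phenotypes: tuple[str, ...] = PHENOTYPES
    initial_phenotype: str = "Naive"
    selection_mode: str = "none"  # none | random | germline | cdr3_length
    selection_param: Any = None
    selection_step: int = 0
    sel_multiplier: float = 1.0
    shm_prob_by_isotype: dict[str, float] = field(default_factory=dict)
    shm_prob_by_phenotype: dict[str, float] = field(default_factory=dict)
    shm_prob_default: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_new_clone", "p_div0", "p_death", "p_max", "shm_prob_default"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for m in (self.shm_prob_by_isotype, self.shm_prob_by_phenotype):
            for k, v in m.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"SHM probability {k}={v} outside [0, 1]")
        self.isotype_T = _check_stochastic(self.isotype_T, len(ISOTYPES), "isotype_T")
        self.phenotype_T = _check_stochastic(
            self.phenotype_T, len(self.phenotypes), "phenotype_T"
        )
        if self.phenotype_T_selected is not None:
            self.phenotype_T_selected = _check_stochastic(
                self.phenotype_T_selected, len(self.phenotypes), "phenotype_T_selected"
            )
        if self.selection_mode not in ("none", "random", "germline", "cdr3_length"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")


def replication_probability(clone_size: int, params: SimulationParams) -> float:
    """clamp(p_div0 + beta_div*(clone_size-1), 0, p_max)."""
    if clone_size < 1:
        raise ValueError("clone_size must be >= 1")
    p = params.p_div0 + params.beta_div * (clone_size - 1)
    return float(min(max(p, 0.0), params.p_max))


def class_switch(isotype: str, isotype_T: np.ndarray, rng: np.random.Generator) -> str:
    """Sample the next isotype from the transition row of the current one."""
    row = isotype_T[ISOTYPES.index(isotype)]
    return ISOTYPES[int(rng.choice(len(ISOTYPES), p=row))]


@dataclass
class Cell:
    barcode: str
    clone_id: int
    variant_id: int
    isotype: str
    phenotype: str
    alive: bool = True
    birth_step: int = 0
    death_step: int | None = None


@dataclass
class CloneInfo:
    founder: PairedReceptor
    selected: set[int] = field(default_factory=set)  # variant ids under selection
    selected_seqs: set[str] = field(default_factory=set)


class RepertoireState:
    """Cells, clones, lineage networks and the append-only event log."""

    def __init__(self, settings: RecombinationSettings, params: SimulationParams):
        self.settings = settings
        self.params = params
        self.step_index = 0
        self.cells: list[Cell] = []
        self.cells_by_barcode: dict[str, Cell] = {}
        self.clones: dict[int, CloneInfo] = {}
        self.networks: dict[int, LineageNetwork] = {}
        self.event_log: list[tuple[int, str, int, str, int, dict]] = []
        self._n_barcodes = 0

    # -- bookkeeping -------------------------------------------------------
    def _new_barcode(self) -> str:
        bc = make_barcode(self._n_barcodes)
        self._n_barcodes += 1
        return bc

    def log(self, event: str, clone_id: int, barcode: str, variant_id: int, payload: dict) -> None:
        self.event_log.append(
            (self.step_index, event, clone_id, barcode, variant_id, payload)
        )

    def alive_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.alive]

    def alive_count(self, clone_id: int) -> int:
        return sum(1 for c in self.cells if c.alive and c.clone_id == clone_id)

    def clone_sizes(self) -> dict[int, int]:
        sizes = {cid: 0 for cid in self.clones}
        for c in self.cells:
            if c.alive:
                sizes[c.clone_id] += 1
        return sizes

    def variant_seq(self, cell: Cell) -> str:
        return self.networks[cell.clone_id].nodes[cell.variant_id].seq

    def _add_cell(self, cell: Cell) -> None:
        self.cells.append(cell)
        self.cells_by_barcode[cell.barcode] = cell

    def found_clone(self, founder: PairedReceptor, rng: np.random.Generator) -> Cell:
        cid = founder.clone_id
        self.clones[cid] = CloneInfo(founder=founder)
        root_seq = founder.heavy.nt_seq + CHAIN_SEP + founder.light.nt_seq
        self.networks[cid] = LineageNetwork(clone_id=cid, root_seq=root_seq)
        cell = Cell(
            barcode=self._new_barcode(),
            clone_id=cid,
            variant_id=0,
            isotype="IGHM",
            phenotype=self.params.initial_phenotype,
            birth_step=self.step_index,
        )
        self._add_cell(cell)
        self.log(
            "found_clone",
            cid,
            cell.barcode,
            0,
            {"isotype": cell.isotype, "phenotype": cell.phenotype},
        )
        return cell

    def finalize(self) -> None:
        """Fill per-variant isotype counts and historical flags."""
        for net in self.networks.values():
            for node in net.nodes.values():
                node.cell_counts.clear()
        for cell in self.cells:
            if cell.alive:
                net = self.networks[cell.clone_id]
                net.nodes[cell.variant_id].cell_counts[cell.isotype] += 1
        for net in self.networks.values():
            for node in net.nodes.values():
                node.historical = sum(node.cell_counts.values()) == 0


def select_variants(
    state: RepertoireState,
    clone_id: int,
    mode: str,
    selection_param: Any,
    rng: np.random.Generator,
) -> set[int]:
    """Mark variants of one clone as selected for preferential expansion.

    Modes: ``none`` (empty set), ``random`` (uniform sample of up to
    ``selection_param`` variants), ``germline`` (all variants of clones
    founded with the given V-segment id) and ``cdr3_length`` (variants
    whose heavy-chain junction is at least ``selection_param`` nt long).
    Selection is stored on the clone; later descendants with an identical
    receptor sequence inherit it.
    """
    if clone_id not in state.clones:
        raise KeyError(f"unknown clone {clone_id}")
    info = state.clones[clone_id]
    net = state.networks[clone_id]
    if mode == "none":
        selected: set[int] = set()
    elif mode == "random":
        k = int(selection_param)
        vids = sorted(net.nodes)
        take = min(k, len(vids))
        selected = set(int(v) for v in rng.choice(vids, size=take, replace=False))
    elif mode == "germline":
        if selection_param not in state.settings.reference:
            raise ValueError(f"unknown V segment id {selection_param!r}")
        if info.founder.heavy.v_id == selection_param:
            selected = set(net.nodes)
        else:
            selected = set()
    elif mode == "cdr3_length":
        thr = int(selection_param)
        h = info.founder.heavy
        # substitution-only SHM preserves junction coordinates for every variant
        selected = set(net.nodes) if len(h.junction_nt) >= thr else set()
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    info.selected |= selected
    info.selected_seqs |= {net.nodes[v].seq for v in selected}
    return selected


def _is_selected(state: RepertoireState, cell: Cell) -> bool:
    info = state.clones[cell.clone_id]
    if cell.variant_id in info.selected:
        return True
    # inheritance by sequence identity
    if info.selected_seqs and state.variant_seq(cell) in info.selected_seqs:
        info.selected.add(cell.variant_id)
        return True
    return False


def _shm_probability(cell: Cell, params: SimulationParams) -> float:
    p_iso = params.shm_prob_by_isotype.get(cell.isotype, params.shm_prob_default)
    p_phen = params.shm_prob_by_phenotype.get(cell.phenotype, params.shm_prob_default)
    return max(p_iso, p_phen)


def step(
    state: RepertoireState,
    params: SimulationParams,
    shm_model: ShmModel | None,
    rng: np.random.Generator,
) -> RepertoireState:
    """Advance the repertoire by one time step (see module docstring for
    the phase order)."""
    is_b = state.settings.receptor == "B"
    # (1) new-clone influx
    if params.p_new_clone > 0 and rng.random() < params.p_new_clone:
        next_id = max(state.clones, default=-1) + 1
        (founder,) = simulate_initial_repertoire(1, state.settings, rng)
        founder.clone_id = next_id
        state.found_clone(founder, rng)
        if params.selection_mode != "none" and state.step_index >= params.selection_step:
            select_variants(state, next_id, params.selection_mode, params.selection_param, rng)

    # (2) division + SHM; clone sizes snapshotted at phase start
    sizes = state.clone_sizes()
    newborns: set[str] = set()
    for cell in list(state.cells):
        if not cell.alive or cell.barcode in newborns:
            continue
        p = replication_probability(max(sizes.get(cell.clone_id, 1), 1), params)
        if _is_selected(state, cell):
            p = min(p * params.sel_multiplier, 1.0)
        if rng.random() >= p:
            continue
        daughter = Cell(
            barcode=state._new_barcode(),
            clone_id=cell.clone_id,
            variant_id=cell.variant_id,
            isotype=cell.isotype,
            phenotype=cell.phenotype,
            birth_step=state.step_index,
        )
        state._add_cell(daughter)
        newborns.add(daughter.barcode)
        state.log(
            "division", cell.clone_id, daughter.barcode, daughter.variant_id,
            {"mother": cell.barcode},
        )
        if is_b and shm_model is not None and rng.random() < _shm_probability(daughter, params):
            net = state.networks[cell.clone_id]
            parent_seq = net.nodes[daughter.variant_id].seq
            child_seq, events = mutate_sequence(parent_seq, shm_model, rng)
            if events:
                node = record_mutation(net, daughter.variant_id, child_seq)
                parent_variant = daughter.variant_id
                daughter.variant_id = node.variant_id
                state.log(
                    "shm", cell.clone_id, daughter.barcode, node.variant_id,
                    {
                        "parent_variant": parent_variant,
                        "mutations": [[p_, r, a] for p_, r, a in events],
                    },
                )

    # (3) isotype and phenotype transitions (newborns exempt)
    phen_index = {p: i for i, p in enumerate(params.phenotypes)}
    for cell in state.cells:
        if not cell.alive or cell.barcode in newborns:
            continue
        if is_b:
            new_iso = class_switch(cell.isotype, params.isotype_T, rng)
            if new_iso != cell.isotype:
                state.log(
                    "isotype_switch", cell.clone_id, cell.barcode, cell.variant_id,
                    {"from": cell.isotype, "to": new_iso},
                )
                cell.isotype = new_iso
        T = params.phenotype_T
        if params.phenotype_T_selected is not None and _is_selected(state, cell):
            T = params.phenotype_T_selected
        row = T[phen_index[cell.phenotype]]
        new_phen = params.phenotypes[int(rng.choice(len(row), p=row))]
        if new_phen != cell.phenotype:
            state.log(
                "phenotype_switch", cell.clone_id, cell.barcode, cell.variant_id,
                {"from": cell.phenotype, "to": new_phen},
            )
            cell.phenotype = new_phen

    # (4) death (newborns exempt)
    if params.p_death > 0:
        for cell in state.cells:
            if not cell.alive or cell.barcode in newborns:
                continue
            if rng.random() < params.p_death:
                cell.alive = False
                cell.death_step = state.step_index
                state.log("death", cell.clone_id, cell.barcode, cell.variant_id, {})

    state.step_index += 1
    return state


def run_simulation(
    params: SimulationParams,
    shm_model: ShmModel | None = None,
    settings: RecombinationSettings | None = None,
    reference=None,
    rng: np.random.Generator | None = None,
) -> RepertoireState:
    """Found ``init_clones`` clones and advance ``n_steps`` steps.

    Either a full :class:`RecombinationSettings` or a bare reference may be
    given; the seed in ``params`` drives all randomness unless an external
    generator is supplied.
    """
    if settings is None:
        if reference is None:
            from .germline import load_default_reference

            reference = load_default_reference()
        settings = RecombinationSettings(reference=reference)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = RepertoireState(settings=settings, params=params)
    founders = simulate_initial_repertoire(params.init_clones, settings, rng)
    for founder in founders:
        state.found_clone(founder, rng)
    if params.selection_mode != "none" and params.selection_step <= 0:
        for cid in sorted(state.clones):
            select_variants(state, cid, params.selection_mode, params.selection_param, rng)
    for i in range(params.n_steps):
        if (
            params.selection_mode != "none"
            and params.selection_step == i
            and params.selection_step > 0
        ):
            for cid in sorted(state.clones):
                select_variants(state, cid, params.selection_mode, params.selection_param, rng)
        step(state, params, shm_model, rng)
    state.finalize()
    return state


def replay_event_log(
    log: list[tuple[int, str, int, str, int, dict]],
) -> dict[str, tuple[int, int, str, str, bool, int, int | None]]:
    """Re-execute an event log against an empty state.

    Returns barcode -> (clone_id, variant_id, isotype, phenotype, alive,
    birth_step, death_step); identical to the final cell table of the run
    that produced the log.
    """
    cells: dict[str, list] = {}
    for step_i, event, clone_id, barcode, variant_id, payload in log:
        if event == "found_clone":
            cells[barcode] = [clone_id, 0, payload["isotype"], payload["phenotype"], True, step_i, None]
        elif event == "division":
            mother = cells[payload["mother"]]
            cells[barcode] = [clone_id, mother[1], mother[2], mother[3], True, step_i, None]
        elif event == "shm":
            cells[barcode][1] = variant_id
        elif event == "isotype_switch":
            cells[barcode][2] = payload["to"]
        elif event == "phenotype_switch":
            cells[barcode][3] = payload["to"]
        elif event == "death":
            cells[barcode][4] = False
            cells[barcode][6] = step_i
    return {bc: tuple(v) for bc, v in cells.items()}
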