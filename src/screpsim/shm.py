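"""Somatic hypermutation models.

Three substitution-only mutation models with distinct positional and
substitution behaviour:

``poisson``
    uniform position choice, uniform substitution over the three
    alternative bases.
``data_driven``
    positions weighted by user-configurable region multipliers (e.g. to
    concentrate mutations in CDRs), substitutions favouring transitions
    over transversions by a weight ``kappa``.
``motif``
    positions weighted by the mutability of the 5-mer centred on each
    site, substitutions drawn from the 5-mer's substitution distribution
    (an experimentally derived table may be supplied as TSV; the packaged
    default is a synthetic table concentrating mutability on WRC/GYW
    hotspot motifs).

The number of mutations per SHM event is Poisson(``lam``) truncated at
the sequence length; positions are drawn without replacement within one
event, with replacement across events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

BASES = ("A", "C", "G", "T")
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

logger = logging.getLogger(__name__)


@dataclass
class ShmModel:
    name: str = "poisson"
    lam: float = 5.0
    kappa: float = 3.0
    #: list of (start, end, multiplier) half-open intervals (data_driven)
    region_weights: list[tuple[int, int, float]] = field(default_factory=list)
    #: 5-mer -> (mutability weight, substitution distribution over A,C,G,T)
    fivemer_table: dict[str, tuple[float, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        if self.name not in ("poisson", "data_driven", "motif"):
            raise ValueError(f"unknown SHM model {self.name!r}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.name == "motif" and self.fivemer_table is None:
            self.fivemer_table = default_fivemer_table()
        if self.fivemer_table is not None:
            for fm, (mut, dist) in self.fivemer_table.items():
                if mut < 0:
                    raise ValueError(f"negative mutability for 5-mer {fm}")
                dist = np.asarray(dist, dtype=float)
                if abs(dist.sum() - 1.0) > 1e-9:
                    raise ValueError(f"substitution distribution for {fm} does not sum to 1")
                if fm[2] in _BASE_IDX and dist[_BASE_IDX[fm[2]]] != 0:
                    raise ValueError(f"self-substitution must be 0 for 5-mer {fm}")

    @property
    def _mean_mutability(self) -> float:
        return float(np.mean([m for m, _ in self.fivemer_table.values()]))


def default_fivemer_table(hotspot_weight: float = 8.0) -> dict[str, tuple[float, np.ndarray]]:
    """Synthetic 5-mer table with hotspot-like concentration on WRC/GYW motifs.

    The classic AID hotspots: a C preceded by W=A/T then R=A/G (WRC, read
    5'->3' ending at the mutated C) and its reverse complement GYW on the
    same strand.  Hotspot 5-mers get ``hotspot_weight`` x the baseline
    mutability; substitutions favour transitions 2:1:1.
    """
    table: dict[str, tuple[float, np.ndarray]] = {}
    W, R, Y = set("AT"), set("AG"), set("CT")
    for fm in ("".join(p) for p in product(BASES, repeat=5)):
        center = fm[2]
        is_wrc = center == "C" and fm[0] in W and fm[1] in R
        is_gyw = center == "G" and fm[3] in Y and fm[4] in W
        mut = hotspot_weight if (is_wrc or is_gyw) else 1.0
        dist = np.zeros(4)
        for b in BASES:
            if b == center:
                continue
            dist[_BASE_IDX[b]] = 2.0 if b == TRANSITION[center] else 1.0
        table[fm] = (mut, dist / dist.sum())
    return table


def flat_fivemer_table() -> dict[str, tuple[float, np.ndarray]]:
    """Uniform-mutability, uniform-substitution table (for reductions)."""
    table = {}
    for fm in ("".join(p) for p in product(BASES, repeat=5)):
        dist = np.array([0.0 if b == fm[2] else 1 / 3 for b in BASES])
        table[fm] = (1.0, dist)
    return table


def load_fivemer_tsv(path: str | Path) -> dict[str, tuple[float, np.ndarray]]:
    """Read a 5-mer table TSV: fivemer, mutability, p_to_A..p_to_T."""
    table = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["fivemer", "mutability", "p_to_A", "p_to_C", "p_to_G", "p_to_T"]
        if header != expected:
            raise ValueError(f"bad 5-mer TSV header {header}, expected {expected}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            table[parts[0]] = (float(parts[1]), np.array([float(x) for x in parts[2:6]]))
    return table


def write_fivemer_tsv(table: dict[str, tuple[float, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fivemer\tmutability\tp_to_A\tp_to_C\tp_to_G\tp_to_T\n")
        for fm in sorted(table):
            mut, dist = table[fm]
            fh.write(f"{fm}\t{mut:g}\t" + "\t".join(f"{p:.6g}" for p in dist) + "\n")


def _context_5mer(seq: str, i: int) -> str:
    padded = "NN" + seq + "NN"
    return padded[i : i + 5]


def positional_weights(seq: str, model: ShmModel) -> np.ndarray:
    """Normalized per-position mutation weights for one SHM event."""
    n = len(seq)
    if n < 1:
        raise ValueError("sequence must be non-empty")
    if model.name == "poisson":
        w = np.ones(n)
    elif model.name == "data_driven":
        w = np.ones(n)
        for start, end, mult in model.region_weights:
            if start < 0 or end > n:
                raise ValueError(f"region ({start},{end}) outside sequence of length {n}")
            w[start:end] *= mult
    else:  # motif
        # flank positions lack a full 5-mer context and are not mutable;
        # 5-mers absent from an incomplete user table take the table mean
        w = np.empty(n)
        for i in range(n):
            fm = _context_5mer(seq, i)
            if "N" in fm:
                w[i] = 0.0
            elif fm not in model.fivemer_table:
                w[i] = model._mean_mutability
            else:
                w[i] = model.fivemer_table[fm][0]
    # non-ACGT positions (e.g. chain separators) are never mutable
    mask = np.fromiter((c in _BASE_IDX for c in seq), dtype=bool, count=n)
    w = np.where(mask, w, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("no mutable positions")
    return w / total


def substitute_base(
    base: str, context_5mer: str, model: ShmModel, rng: np.random.Generator
) -> str:
    """Draw a replacement base (always different from the input base)."""
    if base not in _BASE_IDX:
        raise ValueError(f"cannot substitute base {base!r}")
    alternatives = [b for b in BASES if b != base]
    if model.name == "poisson":
        probs = np.full(3, 1 / 3)
    elif model.name == "data_driven":
        probs = np.array(
            [model.kappa if b == TRANSITION[base] else 1.0 for b in alternatives]
        )
        probs = probs / probs.sum()
    else:  # motif
        entry = None
        if "N" not in context_5mer:
            entry = model.fivemer_table.get(context_5mer)
        if entry is None:
            logger.debug("5-mer %s absent from table; uniform substitution", context_5mer)
            probs = np.full(3, 1 / 3)
        else:
            dist = entry[1]
            probs = np.array([dist[_BASE_IDX[b]] for b in alternatives])
            total = probs.sum()
            probs = np.full(3, 1 / 3) if total <= 0 else probs / total
    return alternatives[int(rng.choice(3, p=probs))]


def mutate_sequence(
    seq: str, model: ShmModel, rng: np.random.Generator, n_mut: int | None = None
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply one SHM event; returns the mutated sequence and its events.

    The mutation count is Poisson(``model.lam``) truncated at the number of
    mutable positions unless ``n_mut`` forces it.  Events are (position,
    reference base, alternative base) and are sufficient to reconstruct
    either sequence from the other.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    weights = positional_weights(seq, model)
    n_mutable = int((weights > 0).sum())
    m = int(rng.poisson(model.lam)) if n_mut is None else n_mut
    m = min(m, n_mutable)
    if m == 0:
        return seq, []
    positions = rng.choice(len(seq), size=m, replace=False, p=weights)
    chars = list(seq)
    events = []
    for pos in sorted(int(p) for p in positions):
        ref = seq[pos]
        alt = substitute_base(ref, _context_5mer(seq, pos), model, rng)
        chars[pos] = alt
        events.append((pos, ref, alt))
    return "".join(chars), events
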