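"""Germline gene-segment references and paired V(D)J recombination.

A receptor chain is built by appending a sampled V, (D,) and J germline
segment, trimming each segment end that flanks a junction by an
exonuclease-like deletion, and filling the junction with non-templated
insertions.  Every stochastic draw is recorded on the chain so the
sequence can be reconstructed from its provenance, and productivity
(reading frame plus absence of stop codons) can be enforced by rejection
sampling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

LOCI = ("IGH", "IGK", "IGL", "TRB", "TRA")
D_LOCI = frozenset({"IGH", "TRB"})
STYPES = ("V", "D", "J")
BASES = ("A", "C", "G", "T")

#: heavy/light locus pairs per receptor class
HEAVY_LOCUS = {"B": "IGH", "T": "TRB"}
LIGHT_LOCUS = {"B": "IGK", "T": "TRA"}

_STOP_FREE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)


class ReferenceError(ValueError):
    """Raised for malformed germline references."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline gene segment (V, D or J) of a locus."""

    id: str
    locus: str
    stype: str
    seq: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ReferenceError(f"unknown locus {self.locus!r} for segment {self.id!r}")
        if self.stype not in STYPES:
            raise ReferenceError(f"unknown segment type {self.stype!r} for {self.id!r}")
        if self.stype == "D" and self.locus not in D_LOCI:
            raise ReferenceError(f"D segment {self.id!r} not permitted on locus {self.locus}")
        if not self.seq:
            raise ReferenceError(f"segment {self.id!r} has an empty sequence")
        bad = set(self.seq) - set(BASES)
        if bad:
            raise ReferenceError(
                f"segment {self.id!r} contains non-ACGT character(s) {sorted(bad)}"
            )


class GermlineReference:
    """Container of germline segments indexed by id and by (locus, stype)."""

    def __init__(self, segments: list[GermlineSegment]):
        self.by_id: dict[str, GermlineSegment] = {}
        self._by_group: dict[tuple[str, str], list[GermlineSegment]] = {}
        for seg in segments:
            if seg.id in self.by_id:
                raise ReferenceError(f"duplicate segment id {seg.id!r}")
            self.by_id[seg.id] = seg
            self._by_group.setdefault((seg.locus, seg.stype), []).append(seg)
        if not self.by_id:
            raise ReferenceError("no segments found")

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self.by_id

    def segments(self, locus: str, stype: str) -> list[GermlineSegment]:
        return list(self._by_group.get((locus, stype), []))

    def counts_by_stype(self, locus: str | None = None) -> dict[str, int]:
        out: dict[str, int] = {}
        for (loc, st), segs in self._by_group.items():
            if locus is None or loc == locus:
                out[st] = out.get(st, 0) + len(segs)
        return out


def _parse_header(header: str) -> tuple[str, str, str]:
    """Parse ``ID|LOCUS|STYPE`` or IMGT-style pipe-separated headers.

    IMGT FASTA headers carry the gene name in field 2; the segment type is
    the V/D/J letter following the locus prefix (e.g. ``IGHV1-11`` -> IGH, V).
    """
    fields = header.split("|")
    if len(fields) >= 3 and fields[1] in LOCI and fields[2].strip() in STYPES:
        return fields[0].strip(), fields[1], fields[2].strip()
    seg_id = fields[1].strip() if len(fields) >= 2 else fields[0].strip()
    if len(seg_id) < 4 or seg_id[:3] not in LOCI or seg_id[3] not in STYPES:
        raise ReferenceError(
            f"cannot infer locus/segment type from header {header!r}"
        )
    return seg_id, seg_id[:3], seg_id[3]


def load_reference(path: str | Path) -> GermlineReference:
    """Load a germline segment reference from FASTA.

    Headers follow either the ``>ID|LOCUS|STYPE`` dialect or IMGT-style
    pipe-separated headers with the gene id in field 2.  Sequences are
    uppercased and validated over {A,C,G,T}; duplicate ids, unresolvable
    segment types and non-ACGT characters are hard errors.
    """
    segments = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seg_id, locus, stype = _parse_header(rec.description)
        segments.append(GermlineSegment(seg_id, locus, stype, str(rec.seq).upper()))
    return GermlineReference(segments)


def write_reference(reference: GermlineReference, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in reference.by_id.values():
            fh.write(f">{seg.id}|{seg.locus}|{seg.stype}\n")
            for i in range(0, len(seg.seq), 60):
                fh.write(seg.seq[i : i + 60] + "\n")


def load_default_reference() -> GermlineReference:
    """Packaged synthetic germline reference (no external download needed)."""
    with resources.as_file(
        resources.files("screpsim.data") / "germline_synthetic.fasta"
    ) as p:
        return load_reference(p)


def generate_synthetic_reference(
    rng: np.random.Generator,
    loci: tuple[str, ...] = LOCI,
    n_v: int = 12,
    n_d: int = 6,
    n_j: int = 5,
) -> GermlineReference:
    """Generate a synthetic germline reference with realistic segment lengths.

    V (~295 nt) and J (~50 nt) segments are drawn codon-wise from the 61
    stop-free codons so that in-frame rearrangements are usually free of
    premature stops, as real germline genes are; D segments (~15 nt) are
    unconstrained.
    """

    def stopfree(n_codons: int) -> str:
        idx = rng.integers(0, len(_STOP_FREE_CODONS), size=n_codons)
        return "".join(_STOP_FREE_CODONS[i] for i in idx)

    segments = []
    for locus in loci:
        for i in range(n_v):
            n_cod = int(rng.integers(96, 101))  # 288..300 nt
            segments.append(GermlineSegment(f"{locus}V1-{i + 1}", locus, "V", stopfree(n_cod)))
        if locus in D_LOCI:
            for i in range(n_d):
                length = int(rng.integers(12, 19))
                seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
                segments.append(GermlineSegment(f"{locus}D1-{i + 1}", locus, "D", seq))
        for i in range(n_j):
            n_cod = int(rng.integers(15, 18))  # 45..51 nt
            segments.append(GermlineSegment(f"{locus}J{i + 1}", locus, "J", stopfree(n_cod)))
    return GermlineReference(segments)


@dataclass
class UsageDistribution:
    """Per-segment-type sampling weights for one locus.

    ``weights`` maps segment type ("V"/"D"/"J") to a {segment id: probability}
    map.  Each map must sum to one and reference only segments present in the
    reference it is validated against.
    """

    locus: str
    weights: dict[str, dict[str, float]]

    def validate(self, reference: GermlineReference) -> None:
        for stype, wmap in self.weights.items():
            if not wmap:
                raise ValueError(f"empty usage map for {self.locus}/{stype}")
            total = 0.0
            for seg_id, w in wmap.items():
                if w < 0:
                    raise ValueError(f"negative usage weight for {seg_id}")
                if seg_id not in reference:
                    raise ValueError(f"usage references unknown segment {seg_id!r}")
                total += w
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"usage weights for {self.locus}/{stype} sum to {total}, not 1"
                )

    @classmethod
    def uniform(cls, reference: GermlineReference, locus: str) -> "UsageDistribution":
        weights = {}
        for stype in STYPES:
            segs = reference.segments(locus, stype)
            if segs:
                weights[stype] = {s.id: 1.0 / len(segs) for s in segs}
        return cls(locus=locus, weights=weights)

    def sample(self, stype: str, rng: np.random.Generator) -> str:
        wmap = self.weights[stype]
        ids = sorted(wmap)
        probs = np.array([wmap[i] for i in ids], dtype=float)
        return ids[rng.choice(len(ids), p=probs / probs.sum())]


@dataclass
class JunctionModel:
    """Junctional diversification model.

    Deletion lengths are drawn independently for each segment end flanking a
    junction; insertion lengths and inserted bases are drawn per junction.
    Defaults: insertions uniform on 0..6 nt, deletions uniform on 0..3 nt,
    inserted bases uniform over ACGT.
    """

    ins_len_dist: np.ndarray = field(default_factory=lambda: np.full(7, 1 / 7))
    del_len_dist: np.ndarray = field(default_factory=lambda: np.full(4, 1 / 4))
    ins_base_dist: np.ndarray = field(default_factory=lambda: np.full(4, 1 / 4))

    def __post_init__(self) -> None:
        for name in ("ins_len_dist", "del_len_dist", "ins_base_dist"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.ndim != 1 or v.size == 0 or (v < 0).any():
                raise ValueError(f"{name} must be a non-negative 1-D probability vector")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {v.sum()}, not 1")
        if self.ins_base_dist.size != 4:
            raise ValueError("ins_base_dist must have 4 entries (A,C,G,T)")

    def draw_deletion(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.del_len_dist.size, p=self.del_len_dist))

    def draw_insertion(self, rng: np.random.Generator) -> str:
        n = int(rng.choice(self.ins_len_dist.size, p=self.ins_len_dist))
        idx = rng.choice(4, size=n, p=self.ins_base_dist)
        return "".join(BASES[i] for i in idx)

    @classmethod
    def zero_diversification(cls) -> "JunctionModel":
        """All probability mass on length-0 insertions and deletions."""
        return cls(
            ins_len_dist=np.array([1.0]),
            del_len_dist=np.array([1.0]),
            ins_base_dist=np.full(4, 1 / 4),
        )


@dataclass
class ReceptorChain:
    """One recombined receptor chain with full draw provenance."""

    locus: str
    v_id: str
    j_id: str
    nt_seq: str
    junction_nt: str
    junction_start: int
    junction_end: int
    productive: bool
    d_id: str | None = None
    # provenance: deletion lengths per trimmed end and inserted strings
    v_del3: int = 0
    d_del5: int = 0
    d_del3: int = 0
    j_del5: int = 0
    ins_vd: str = ""
    ins_dj: str = ""

    def __post_init__(self) -> None:
        assert self.junction_nt == self.nt_seq[self.junction_start : self.junction_end]


@dataclass
class PairedReceptor:
    """A paired heavy (VDJ) + light (VJ) receptor of one clone."""

    heavy: ReceptorChain
    light: ReceptorChain
    clone_id: int


def check_productive(chain: ReceptorChain | str) -> bool:
    """Frame-preserving (length multiple of 3 from position 0) and stop-free.

    A deliberately self-contained productivity rule: real annotation tools
    additionally locate the reading frame from the V gene and check conserved
    anchors, which is out of scope here.
    """
    seq = chain if isinstance(chain, str) else chain.nt_seq
    if len(seq) == 0 or len(seq) % 3 != 0:
        return False
    return "*" not in str(Seq(seq).translate())


def recombine_chain(
    reference: GermlineReference,
    usage: UsageDistribution,
    junction: JunctionModel,
    has_d: bool,
    rng: np.random.Generator,
    max_retries: int = 50,
) -> ReceptorChain:
    """Simulate one V(D)J (or VJ) recombination event.

    The chain is ``trim3'(V) + ins + [trim5'3'(D) + ins +] trim5'(J)``; the
    junction proxy for CDR3 spans the 3'-most 3 nt of the trimmed V through
    the 5'-most 3 nt of the trimmed J.  Deletions that would consume an entire
    segment are re-drawn up to ``max_retries`` times.
    """
    v = reference.by_id[usage.sample("V", rng)]
    j = reference.by_id[usage.sample("J", rng)]
    d = reference.by_id[usage.sample("D", rng)] if has_d else None

    def bounded_del(seg_len: int, budget_used: int = 0) -> int:
        for _ in range(max_retries):
            dl = junction.draw_deletion(rng)
            if dl + budget_used < seg_len:
                return dl
        raise ValueError(
            f"could not draw a deletion shorter than segment length {seg_len}"
        )

    v_del3 = bounded_del(len(v.seq))
    j_del5 = bounded_del(len(j.seq))
    v_part = v.seq[: len(v.seq) - v_del3]
    j_part = j.seq[j_del5:]

    if d is not None:
        d_del5 = bounded_del(len(d.seq))
        d_del3 = bounded_del(len(d.seq), budget_used=d_del5)
        d_part = d.seq[d_del5 : len(d.seq) - d_del3]
        ins_vd = junction.draw_insertion(rng)
        ins_dj = junction.draw_insertion(rng)
        nt_seq = v_part + ins_vd + d_part + ins_dj + j_part
    else:
        d_del5 = d_del3 = 0
        d_part = ""
        ins_vd = junction.draw_insertion(rng)
        ins_dj = ""
        nt_seq = v_part + ins_vd + j_part

    junction_start = max(0, len(v_part) - 3)
    junction_end = min(len(nt_seq), len(nt_seq) - len(j_part) + 3)
    chain = ReceptorChain(
        locus=usage.locus,
        v_id=v.id,
        d_id=d.id if d else None,
        j_id=j.id,
        nt_seq=nt_seq,
        junction_nt=nt_seq[junction_start:junction_end],
        junction_start=junction_start,
        junction_end=junction_end,
        productive=False,
        v_del3=v_del3,
        d_del5=d_del5,
        d_del3=d_del3,
        j_del5=j_del5,
        ins_vd=ins_vd,
        ins_dj=ins_dj,
    )
    chain.productive = check_productive(chain)
    return chain


def reconstruct_chain(chain: ReceptorChain, reference: GermlineReference) -> str:
    """Re-append the recorded segments with recorded trims/inserts."""
    v = reference.by_id[chain.v_id].seq
    j = reference.by_id[chain.j_id].seq
    out = v[: len(v) - chain.v_del3] + chain.ins_vd
    if chain.d_id is not None:
        d = reference.by_id[chain.d_id].seq
        out += d[chain.d_del5 : len(d) - chain.d_del3] + chain.ins_dj
    out += j[chain.j_del5 :]
    return out


def germline_concatenation(chain: ReceptorChain, reference: GermlineReference) -> str:
    """The pure appended V(+D)+J concatenation without junctional alterations."""
    v = reference.by_id[chain.v_id].seq
    j = reference.by_id[chain.j_id].seq
    d = reference.by_id[chain.d_id].seq if chain.d_id is not None else ""
    return v + d + j


@dataclass
class RecombinationSettings:
    """Everything needed to found a clone: reference, usage, junction models.

    Heavy/light usage default to uniform over the loci of the chosen receptor
    class (B: IGH + IGK, T: TRB + TRA).  Heavy and light segments are sampled
    independently; a joint V-J pairing table is not modelled.
    """

    reference: GermlineReference
    receptor: str = "B"
    heavy_usage: UsageDistribution | None = None
    light_usage: UsageDistribution | None = None
    heavy_junction: JunctionModel = field(default_factory=JunctionModel)
    light_junction: JunctionModel = field(default_factory=JunctionModel)
    productive_only: bool = True
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.receptor not in ("B", "T"):
            raise ValueError("receptor must be 'B' or 'T'")
        if self.heavy_usage is None:
            self.heavy_usage = UsageDistribution.uniform(
                self.reference, HEAVY_LOCUS[self.receptor]
            )
        if self.light_usage is None:
            self.light_usage = UsageDistribution.uniform(
                self.reference, LIGHT_LOCUS[self.receptor]
            )
        self.heavy_usage.validate(self.reference)
        self.light_usage.validate(self.reference)


def _sample_chain(
    settings: RecombinationSettings,
    usage: UsageDistribution,
    junction: JunctionModel,
    has_d: bool,
    rng: np.random.Generator,
) -> ReceptorChain:
    for _ in range(settings.max_attempts):
        chain = recombine_chain(settings.reference, usage, junction, has_d, rng)
        if not settings.productive_only or chain.productive:
            return chain
    raise RuntimeError(
        f"no productive {usage.locus} chain in {settings.max_attempts} attempts"
    )


def simulate_initial_repertoire(
    n_clones: int,
    settings: RecombinationSettings,
    rng: np.random.Generator,
) -> list[PairedReceptor]:
    """Found ``n_clones`` clones by independent paired recombination events.

    With ``productive_only`` each chain is rejection-sampled until it passes
    :func:`check_productive` (bounded by ``settings.max_attempts``).
    Clone ids run 0..n_clones-1.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    out = []
    for clone_id in range(n_clones):
        heavy = _sample_chain(
            settings, settings.heavy_usage, settings.heavy_junction, True, rng
        )
        light = _sample_chain(
            settings, settings.light_usage, settings.light_junction, False, rng
        )
        out.append(PairedReceptor(heavy=heavy, light=light, clone_id=clone_id))
    return out
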