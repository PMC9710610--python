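"""Cellranger-style output writers and their round-trip readers.

``write_vdj_outputs`` emits ``filtered_contig_annotations.csv``,
``filtered_contig.fasta`` and ``clonotypes.csv`` in the layout of the 10x
Genomics cellranger vdj pipeline so downstream tools (Platypus, Seurat
helpers, scirpy) can consume simulated repertoires unchanged.
``write_expression_matrix`` emits the MatrixMarket triplet +
barcodes/features layout of the cellranger filtered gene-count matrix.
``write_ground_truth`` persists the event log, lineage edge lists,
variant sequences and the exact configuration for replay.

The reads/umis columns are synthetic sequencing-depth placeholders
(umis ~ 1 + Poisson(3), reads = umis * (1 + Poisson(30))) present only
for format compatibility.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml
from Bio.Seq import Seq

from .germline import check_productive
from .lineage import CHAIN_SEP, LineageNetwork, edit_distance
from .transcriptome import ExpressionMatrix

CONTIG_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id", "raw_consensus_id",
]

_LIGHT_CONSTANT = {"IGK": "IGKC", "IGL": "IGLC1", "TRA": "TRAC"}


def _translate(nt: str) -> str:
    usable = nt[: len(nt) // 3 * 3]
    return str(Seq(usable).translate()) if usable else ""


def contig_table(state, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Two contig rows (heavy + light) per alive cell."""
    if rng is None:
        rng = np.random.default_rng(state.params.seed + 2)
    rows = []
    for cell in state.alive_cells():
        info = state.clones[cell.clone_id]
        variant_seq = state.variant_seq(cell)
        heavy_nt, light_nt = variant_seq.split(CHAIN_SEP)
        for k, (chain_obj, nt) in enumerate(
            ((info.founder.heavy, heavy_nt), (info.founder.light, light_nt))
        ):
            cdr3_nt = nt[chain_obj.junction_start : chain_obj.junction_end]
            umis = 1 + int(rng.poisson(3))
            reads = umis * (1 + int(rng.poisson(30)))
            c_gene = (
                cell.isotype
                if chain_obj.locus in ("IGH", "TRB")
                else _LIGHT_CONSTANT[chain_obj.locus]
            )
            rows.append(
                {
                    "barcode": cell.barcode,
                    "is_cell": True,
                    "contig_id": f"{cell.barcode}_contig_{k + 1}",
                    "high_confidence": True,
                    "length": len(nt),
                    "chain": chain_obj.locus,
                    "v_gene": chain_obj.v_id,
                    "d_gene": chain_obj.d_id or "None",
                    "j_gene": chain_obj.j_id,
                    "c_gene": c_gene,
                    "full_length": True,
                    "productive": check_productive(nt),
                    "cdr3": _translate(cdr3_nt),
                    "cdr3_nt": cdr3_nt,
                    "reads": reads,
                    "umis": umis,
                    "raw_clonotype_id": f"clonotype{cell.clone_id + 1}",
                    "raw_consensus_id": f"clonotype{cell.clone_id + 1}_consensus_{k + 1}",
                    "_nt_seq": nt,
                }
            )
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS + ["_nt_seq"])


def write_vdj_outputs(state, outdir: str | Path) -> dict[str, Path]:
    """Write the cellranger-vdj triple; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = contig_table(state)
    csv_path = outdir / "filtered_contig_annotations.csv"
    table[CONTIG_COLUMNS].to_csv(csv_path, index=False)

    fasta_path = outdir / "filtered_contig.fasta"
    with open(fasta_path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(f">{row['contig_id']}\n")
            seq = row["_nt_seq"]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    # clonotype summary over alive cells
    alive = state.alive_cells()
    counts: dict[int, int] = {}
    for cell in alive:
        counts[cell.clone_id] = counts.get(cell.clone_id, 0) + 1
    total = sum(counts.values())
    rows = []
    for cid in sorted(counts, key=lambda c: (-counts[c], c)):
        info = state.clones[cid]
        cdr3s = (
            f"{info.founder.heavy.locus}:{info.founder.heavy.junction_nt};"
            f"{info.founder.light.locus}:{info.founder.light.junction_nt}"
        )
        rows.append(
            {
                "clonotype_id": f"clonotype{cid + 1}",
                "frequency": counts[cid],
                "proportion": counts[cid] / total if total else 0.0,
                "cdr3s_nt": cdr3s,
            }
        )
    clono_path = outdir / "clonotypes.csv"
    pd.DataFrame(rows, columns=["clonotype_id", "frequency", "proportion", "cdr3s_nt"]).to_csv(
        clono_path, index=False
    )
    return {"annotations": csv_path, "fasta": fasta_path, "clonotypes": clono_path}


def read_contig_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_expression_matrix(matrix: ExpressionMatrix, outdir: str | Path) -> dict[str, Path]:
    """MatrixMarket triplet + barcodes/features lists (cellranger layout)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mtx = outdir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), matrix.counts.astype(np.int64), field="integer")
    bc = outdir / "barcodes.tsv"
    bc.write_text("".join(b + "\n" for b in matrix.barcodes))
    feat = outdir / "features.tsv"
    feat.write_text("".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes))
    return {"matrix": mtx, "barcodes": bc, "features": feat}


def read_expression_matrix(outdir: str | Path) -> ExpressionMatrix:
    outdir = Path(outdir)
    counts = sp.csc_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")))
    barcodes = (outdir / "barcodes.tsv").read_text().splitlines()
    genes = [line.split("\t")[0] for line in (outdir / "features.tsv").read_text().splitlines()]
    return ExpressionMatrix(genes=genes, barcodes=barcodes, counts=counts)


def write_ground_truth(state, outdir: str | Path, config: dict | None = None) -> dict[str, Path]:
    """Persist event log, lineage edge lists, variant FASTA and config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "event_log.tsv"
    with open(log_path, "w") as fh:
        fh.write("step\tevent\tclone_id\tcell_barcode\tvariant_id\tpayload\n")
        for step_i, event, cid, bc, vid, payload in state.event_log:
            fh.write(
                f"{step_i}\t{event}\t{cid}\t{bc}\t{vid}\t"
                f"{json.dumps(payload, sort_keys=True)}\n"
            )

    edges_path = outdir / "lineage_edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("clone_id\tparent_variant\tchild_variant\tedit_distance\thistorical\n")
        for cid in sorted(state.networks):
            net = state.networks[cid]
            for parent, child in net.edges():
                d = edit_distance(net.nodes[parent].seq, net.nodes[child].seq)
                fh.write(
                    f"{cid}\t{parent}\t{child}\t{d}\t{net.nodes[child].historical}\n"
                )

    fasta_path = outdir / "variants.fasta"
    with open(fasta_path, "w") as fh:
        for cid in sorted(state.networks):
            net = state.networks[cid]
            for vid in sorted(net.nodes):
                heavy, light = net.nodes[vid].seq.split(CHAIN_SEP)
                for chain_name, seq in (("heavy", heavy), ("light", light)):
                    fh.write(f">clone{cid}_variant{vid}_{chain_name}\n")
                    for i in range(0, len(seq), 60):
                        fh.write(seq[i : i + 60] + "\n")

    params_path = outdir / "params_echo.yaml"
    echo = config if config is not None else {}
    echo = dict(echo)
    echo.setdefault("seed", state.params.seed)
    with open(params_path, "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return {
        "event_log": log_path,
        "lineage_edges": edges_path,
        "variants": fasta_path,
        "params_echo": params_path,
    }


def read_event_log(path: str | Path) -> list[tuple[int, str, int, str, int, dict]]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            step_i, event, cid, bc, vid, payload = line.rstrip("\n").split("\t")
            out.append((int(step_i), event, int(cid), bc, int(vid), json.loads(payload)))
    return out


def read_lineage_networks(edges_path: str | Path, fasta_path: str | Path) -> dict[int, LineageNetwork]:
    """Rebuild per-clone lineage networks from the ground-truth files."""
    seqs: dict[int, dict[int, dict[str, str]]] = {}
    name = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        stem, chain_name = name.rsplit("_", 1)
        cid = int(stem.split("_")[0][5:])
        vid = int(stem.split("_")[1][7:])
        seqs.setdefault(cid, {}).setdefault(vid, {})[chain_name] = "".join(chunks)

    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                name, chunks = line[1:], []
            else:
                chunks.append(line)
        flush()

    edges = pd.read_csv(edges_path, sep="\t")
    networks: dict[int, LineageNetwork] = {}
    for cid, variants in seqs.items():
        root_seq = variants[0]["heavy"] + CHAIN_SEP + variants[0]["light"]
        net = LineageNetwork(clone_id=cid, root_seq=root_seq)
        sub = edges.loc[edges["clone_id"] == cid]
        # insert children in ascending variant id: parents always precede
        from .lineage import LineageNode

        for _, row in sub.sort_values("child_variant").iterrows():
            vid = int(row["child_variant"])
            seq = variants[vid]["heavy"] + CHAIN_SEP + variants[vid]["light"]
            node = LineageNode(
                variant_id=vid,
                seq=seq,
                parent=int(row["parent_variant"]),
                historical=bool(row["historical"]),
            )
            net._add_node(node)
        networks[cid] = net
    return networks
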