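"""Phenotype-conditioned gene-expression simulation.

Each cell's counts are drawn around its phenotype's base expression
vector: a per-cell lognormal scaling factor ``s = exp(N(0, noise_sd^2))``
models library-size/technical variability, and per-gene counts are
``Poisson(s * base_g)``.  The packaged default profiles cover the four
B-cell phenotypes (Naive, GC, Memory, Plasma) over ~200 synthetic genes
including the named markers Cd19, Fas, Cd38, Sdc1 (Cd138), Taci and Xbp1
with means that mirror the standard phenotype orderings (e.g. Sdc1 high
only in plasma cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: marker genes expected high per packaged phenotype
DEFAULT_MARKERS = {
    "Naive": ["Cd19"],
    "GC": ["Fas", "Cd38"],
    "Memory": ["Taci", "Cd19"],
    "Plasma": ["Sdc1", "Xbp1", "Cd38"],
}


class PhenotypeProfiles:
    """Base expression vectors per phenotype over a shared gene list."""

    def __init__(self, table: pd.DataFrame, markers: dict[str, list[str]] | None = None):
        if (table.values < 0).any():
            raise ValueError("base expression means must be non-negative")
        self.table = table
        self.markers = markers or {}

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.table.columns)

    def base(self, phenotype: str) -> np.ndarray:
        if phenotype not in self.table.columns:
            raise KeyError(f"no expression profile for phenotype {phenotype!r}")
        return self.table[phenotype].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, markers=None) -> "PhenotypeProfiles":
        return cls(pd.read_csv(path, index_col=0), markers=markers)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path)


def default_profiles() -> PhenotypeProfiles:
    """Packaged default 4-phenotype profiles (synthetic, CSV-shipped)."""
    with resources.as_file(
        resources.files("screpsim.data") / "phenotype_profiles.csv"
    ) as p:
        return PhenotypeProfiles.from_csv(p, markers=DEFAULT_MARKERS)


def sample_cell_expression(
    base: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One cell's integer count vector: Poisson(exp(N(0, sd^2)) * base)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = np.asarray(base, dtype=float)
    if (base < 0).any():
        raise ValueError("base expression means must be non-negative")
    s = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
    return rng.poisson(s * base)


@dataclass
class ExpressionMatrix:
    """Genes x cells integer count matrix aligned to repertoire barcodes."""

    genes: list[str]
    barcodes: list[str]
    counts: sp.csc_matrix

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_anndata(self):
        """AnnData view (cells x genes) for scanpy-style downstream use."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=self.barcodes),
            var=pd.DataFrame(index=self.genes),
        )


def simulate_expression_matrix(
    state,
    profiles: PhenotypeProfiles,
    noise_sd: float = 0.3,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """One count column per alive cell, in repertoire barcode order."""
    if rng is None:
        rng = np.random.default_rng(state.params.seed + 1)
    cells = state.alive_cells()
    missing = {c.phenotype for c in cells} - set(profiles.phenotypes)
    if missing:
        raise ValueError(f"no expression profile for phenotype(s) {sorted(missing)}")
    cols = np.empty((len(profiles.genes), len(cells)), dtype=np.int64)
    for j, cell in enumerate(cells):
        cols[:, j] = sample_cell_expression(profiles.base(cell.phenotype), noise_sd, rng)
    return ExpressionMatrix(
        genes=profiles.genes,
        barcodes=[c.barcode for c in cells],
        counts=sp.csc_matrix(cols),
    )


def nearest_centroid_accuracy(
    matrix: ExpressionMatrix, labels: list[str], train_frac: float = 0.5,
    rng: np.random.Generator | None = None,
) -> float:
    """Phenotype recovery by a nearest-centroid classifier on normalized,
    log1p-transformed counts — a separability diagnostic for profile sets."""
    if rng is None:
        rng = np.random.default_rng(0)
    x = matrix.to_dense().astype(float).T  # cells x genes
    lib = x.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    x = np.log1p(x / lib * 1e4)
    labels_arr = np.asarray(labels)
    n = len(labels_arr)
    perm = rng.permutation(n)
    train = perm[: int(n * train_frac)]
    test = perm[int(n * train_frac) :]
    classes = sorted(set(labels))
    centroids = np.stack([x[train][labels_arr[train] == c].mean(axis=0) for c in classes])
    d = ((x[test][:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = np.array(classes)[d.argmin(axis=1)]
    return float((pred == labels_arr[test]).mean())
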