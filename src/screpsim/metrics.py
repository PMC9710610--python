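"""Repertoire-level summary metrics."""

from __future__ import annotations

import numpy as np

_ALPHABET = ("A", "C", "G", "T", "-")


def positionwise_kld(
    rep_a: list[str], rep_b: list[str], pseudocount: float = 0.01
) -> float:
    """Kullback-Leibler divergence of position-wise base frequencies.

    Sequences are right-padded with a gap symbol to the longer
    repertoire's maximum length; per position the base frequencies over
    {A, C, G, T, -} get ``pseudocount`` added and are renormalized, and
    KL(P_pos || Q_pos) is summed over bases and averaged over positions.
    Asymmetric in its arguments, zero iff the per-position frequency
    profiles coincide.
    """
    if not rep_a or not rep_b:
        raise ValueError("both repertoires must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    length = max(max(len(s) for s in rep_a), max(len(s) for s in rep_b))
    idx = {b: i for i, b in enumerate(_ALPHABET)}

    def freqs(rep: list[str]) -> np.ndarray:
        counts = np.zeros((length, len(_ALPHABET)))
        for s in rep:
            padded = s.upper() + "-" * (length - len(s))
            for pos, c in enumerate(padded):
                counts[pos, idx.get(c, idx["-"])] += 1
        counts += pseudocount
        return counts / counts.sum(axis=1, keepdims=True)

    p, q = freqs(rep_a), freqs(rep_b)
    return float(np.mean(np.sum(p * np.log(p / q), axis=1)))


def gini_coefficient(sizes) -> float:
    """Gini coefficient of a clone-size distribution (0 = even, ->1 skewed)."""
    x = np.sort(np.asarray(sizes, dtype=float))
    if x.size == 0 or x.sum() == 0:
        return 0.0
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1).dot(x) / (n * x.sum()))
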