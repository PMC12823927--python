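"""Linkage-disequilibrium summary matrices and their model-input layouts.

An LD matrix here is the scaled Gram matrix (1/n) X^T X of standardized
genotype rows. Three layouts feed the different model families: the upper
triangle as a flat vector (fully connected nets), non-overlapping diagonal
blocks (convolutional nets and transformers on large p), and sliding-window
index intervals (per-window transformer encoders on individual-level data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDMatrix",
    "LDBlockSet",
    "Windows",
    "compute_ld",
    "partition_blocks",
    "upper_triangle",
    "from_upper_triangle",
    "window_slices",
    "write_ld",
    "read_ld",
]


@dataclass
class LDMatrix:
    values: np.ndarray
    snp_ids: list[str]
    n_source: int

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass
class LDBlockSet:
    """Consecutive diagonal blocks of an LD matrix, all of size b×b.

    When p is not divisible by b the final block is zero-padded up to b
    and ``padded`` is set.
    """

    blocks: list[np.ndarray]
    block_size: int
    index_ranges: list[tuple[int, int]]
    padded: bool = False

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def as_array(self) -> np.ndarray:
        return np.stack(self.blocks, axis=0)


@dataclass
class Windows:
    """Sliding-window index intervals [start, stop) over p SNPs."""

    intervals: list[tuple[int, int]]
    tail_appended: bool = False

    @property
    def n_full(self) -> int:
        return len(self.intervals) - (1 if self.tail_appended else 0)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


def compute_ld(Gstd, rows=None) -> LDMatrix:
    """(1/|rows|) X^T X over the selected sample rows (all rows if None)."""
    values = Gstd.values if rows is None else Gstd.values[np.asarray(rows)]
    if values.shape[0] == 0:
        raise ValueError("empty sample row set")
    n = values.shape[0]
    ld = values.T @ values / n
    ld = (ld + ld.T) / 2.0  # enforce exact symmetry against fp noise
    return LDMatrix(ld, list(Gstd.snp_ids), n)


def partition_blocks(ld: LDMatrix, block_size: int) -> LDBlockSet:
    """Cut the diagonal into consecutive block_size×block_size submatrices."""
    p = ld.p
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if block_size > p:
        raise ValueError(f"block_size {block_size} exceeds p={p}")
    blocks, ranges = [], []
    padded = False
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        sub = ld.values[start:stop, start:stop]
        if stop - start < block_size:
            padded = True
            full = np.zeros((block_size, block_size), dtype=ld.values.dtype)
            full[:stop - start, :stop - start] = sub
            sub = full
        blocks.append(sub)
        ranges.append((start, stop))
    return LDBlockSet(blocks, block_size, ranges, padded)


def upper_triangle(ld: LDMatrix, include_diagonal: bool = True) -> np.ndarray:
    """Row-major upper-triangle entries; length p(p+1)/2 with the diagonal."""
    iu = np.triu_indices(ld.p, k=0 if include_diagonal else 1)
    return ld.values[iu]


def from_upper_triangle(vec: np.ndarray, p: int,
                        include_diagonal: bool = True) -> np.ndarray:
    """Inverse of :func:`upper_triangle` under symmetry."""
    out = np.zeros((p, p), dtype=np.asarray(vec).dtype)
    iu = np.triu_indices(p, k=0 if include_diagonal else 1)
    out[iu] = vec
    out = out + np.triu(out, k=1).T
    return out


def window_slices(p: int, window: int, stride: int,
                  strict: bool = False) -> Windows:
    """Intervals [s, s+window) for s = 0, stride, ... while s+window <= p.

    If the last full window stops short of p and ``strict`` is False, one
    extra interval [p-window, p) is appended (flagged) so no SNP is
    silently dropped; ``strict=True`` keeps only the full grid.
    """
    if window > p:
        raise ValueError(f"window {window} exceeds p={p}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    starts = list(range(0, p - window + 1, stride))
    intervals = [(s, s + window) for s in starts]
    tail = False
    if not strict and intervals[-1][1] < p:
        intervals.append((p - window, p))
        tail = True
    return Windows(intervals, tail)


def write_ld(path, ld: LDMatrix, delimiter: str = "\t") -> None:
    """Plain-text matrix with a header line carrying p and n_source."""
    with open(path, "w") as fh:
        fh.write(f"# p={ld.p} n_source={ld.n_source}\n")
        fh.write("# " + delimiter.join(ld.snp_ids) + "\n")
        np.savetxt(fh, ld.values, delimiter=delimiter, fmt="%.10g")


def read_ld(path, delimiter: str = "\t") -> LDMatrix:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        snp_ids = fh.readline().strip().lstrip("# ").split(delimiter)
        values = np.loadtxt(fh, delimiter=delimiter, ndmin=2)
    p = int(meta["p"])
    if values.shape != (p, p):
        raise ValueError(f"expected {p}x{p} matrix, got {values.shape}")
    return LDMatrix(values, snp_ids, int(meta["n_source"]))
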