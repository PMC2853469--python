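"""Accumulation of ordered residue-pair counts over chains.

Counts are indexed by (type_i, type_j, orientation, distance bin). Every
ordered pair (i, j) with i != j — sequence neighbours included, since no
minimal sequence separation is imposed — contributes one count when its
Cbeta-Cbeta distance is below the binning cutoff. Non-oriented tables use a
single orientation slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .aminoacids import AA1, N_TYPES
from .geometry import (
    OUT_OF_RANGE,
    DistanceBinning,
    OrientationClass,
    distance_bins,
    orientation_classes,
)
from .structure_io import ChainModel

__all__ = ["PairCountTable", "accumulate_counts", "merge_counts", "write_counts", "read_counts"]


@dataclass
class PairCountTable:
    """Observed ordered-pair counts plus bookkeeping for reference states."""

    counts: np.ndarray  # (20, 20, n_orient, n_bins) int64
    binning: DistanceBinning
    oriented: bool
    n_chains: int = 0
    composition: list[np.ndarray] = field(default_factory=list)  # per-chain 20-vectors
    n_pairs_skipped: int = 0

    @property
    def n_orient(self) -> int:
        return self.counts.shape[2]

    @property
    def totals_by_condition(self) -> np.ndarray:
        """Counts summed over type pairs, per (orientation, bin)."""
        return self.counts.sum(axis=(0, 1))

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def same_index_space(self, other: "PairCountTable") -> bool:
        return self.counts.shape == other.counts.shape and self.binning == other.binning


def empty_table(binning: DistanceBinning, oriented: bool) -> PairCountTable:
    n_orient = 3 if oriented else 1
    return PairCountTable(
        counts=np.zeros((N_TYPES, N_TYPES, n_orient, binning.n_bins), dtype=np.int64),
        binning=binning,
        oriented=oriented,
    )


def chain_pair_conditions(
    chain: ChainModel, binning: DistanceBinning, oriented: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """In-range ordered pairs of a chain as flat index arrays.

    Returns (p_idx, q_idx, cond, n_skipped) where ``cond`` is
    orientation * n_bins + bin (orientation fixed at 0 when not oriented) and
    n_skipped counts pairs dropped for degenerate orientation geometry.
    """
    n = chain.length
    if n < 2:
        return (np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0, np.intp), 0)
    ca, cb = chain.coords()
    d = cdist(cb, cb)
    bins = distance_bins(d, binning)
    np.fill_diagonal(bins, OUT_OF_RANGE)
    in_range = bins != OUT_OF_RANGE

    n_skipped = 0
    if oriented:
        a = cb - ca
        a_len = np.linalg.norm(a, axis=1)
        ca_sep = cdist(ca, ca)
        ok_i = a_len > 1e-9
        valid = ok_i[:, None] & ok_i[None, :] & (ca_sep > 1e-9)
        np.fill_diagonal(valid, True)  # diagonal excluded anyway
        orient = orientation_classes(ca, cb)
        n_skipped = int(np.count_nonzero(in_range & ~valid))
        in_range &= valid
    else:
        orient = np.zeros((n, n), dtype=int)

    p_idx, q_idx = np.nonzero(in_range)
    cond = orient[p_idx, q_idx] * binning.n_bins + bins[p_idx, q_idx]
    return p_idx, q_idx, cond.astype(np.intp), n_skipped


def accumulate_counts(
    chain: ChainModel, binning: DistanceBinning, oriented: bool = True
) -> PairCountTable:
    """Count every in-range ordered residue pair of one chain."""
    table = empty_table(binning, oriented)
    table.n_chains = 1
    types = chain.types()
    comp = np.bincount(types, minlength=N_TYPES).astype(np.int64)
    table.composition = [comp]
    if chain.length < 2:
        return table

    p_idx, q_idx, cond, n_skipped = chain_pair_conditions(chain, binning, oriented)
    table.n_pairs_skipped = n_skipped
    n_cond = table.n_orient * binning.n_bins
    flat = (types[p_idx] * N_TYPES + types[q_idx]) * n_cond + cond
    table.counts += np.bincount(flat, minlength=table.counts.size).reshape(table.counts.shape)
    return table


def merge_counts(tables: list[PairCountTable]) -> PairCountTable:
    """Elementwise sum of count tables sharing an index space."""
    if not tables:
        raise ValueError("no tables to merge")
    first = tables[0]
    out = PairCountTable(
        counts=first.counts.copy(),
        binning=first.binning,
        oriented=first.oriented,
        n_chains=first.n_chains,
        composition=list(first.composition),
        n_pairs_skipped=first.n_pairs_skipped,
    )
    for t in tables[1:]:
        if not first.same_index_space(t) or first.oriented != t.oriented:
            raise ValueError("count-table dimension mismatch")
        out.counts += t.counts
        out.n_chains += t.n_chains
        out.composition.extend(t.composition)
        out.n_pairs_skipped += t.n_pairs_skipped
    return out


def counts_for_chains(
    chains: list[ChainModel], binning: DistanceBinning, oriented: bool = True
) -> PairCountTable:
    return merge_counts([accumulate_counts(c, binning, oriented) for c in chains])


_ORIENT_NAMES = {int(o): o.name for o in OrientationClass}
_ORIENT_BY_NAME = {o.name: int(o) for o in OrientationClass}
_ORIENT_BY_NAME["NONE"] = 0


def write_counts(table: PairCountTable, sink) -> None:
    """Tabular text dump (type_i, type_j, orientation, bin, count); zero rows skipped."""
    sink.write("type_i\ttype_j\torientation\tbin\tcount\n")
    idx = np.argwhere(table.counts > 0)
    for i, j, o, b in idx:
        oname = _ORIENT_NAMES[int(o)] if table.oriented else "NONE"
        sink.write(f"{AA1[i]}\t{AA1[j]}\t{oname}\t{b}\t{table.counts[i, j, o, b]}\n")


def read_counts(source, binning: DistanceBinning, oriented: bool) -> PairCountTable:
    table = empty_table(binning, oriented)
    header = source.readline()
    if not header.startswith("type_i"):
        raise ValueError("missing counts header")
    from .aminoacids import AA_INDEX

    for lineno, line in enumerate(source, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 5:
            raise ValueError(f"malformed counts row at line {lineno}")
        i, j = AA_INDEX[parts[0]], AA_INDEX[parts[1]]
        o = _ORIENT_BY_NAME[parts[2]]
        table.counts[i, j, o, int(parts[3])] = int(parts[4])
    return table
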