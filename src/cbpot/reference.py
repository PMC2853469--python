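"""Reference (expected) count tables.

Two families are supported:

* the classic reference obtained by averaging over all residue types — every
  type pair is assigned the same distance/orientation profile, scaled by the
  pair's share of all counted pairs;
* the shuffled reference, in which residue identities are permuted within each
  chain while every interaction-centre coordinate stays fixed. It is available
  both as a Monte-Carlo average over repeated shuffles and as the exact
  closed-form expectation of the same randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .aminoacids import N_TYPES
from .counts import PairCountTable, chain_pair_conditions, counts_for_chains
from .geometry import DistanceBinning
from .structure_io import ChainModel

__all__ = [
    "ReferenceMethod",
    "ExpectedTable",
    "classic_reference",
    "shuffled_reference_mc",
    "shuffled_reference_exact",
]


class ReferenceMethod(str, Enum):
    CLASSIC = "CLASSIC"
    SRS_MC = "SRS_MC"
    SRS_EXACT = "SRS_EXACT"


@dataclass
class ExpectedTable:
    expected: np.ndarray  # (20, 20, n_orient, n_bins) float
    binning: DistanceBinning
    oriented: bool
    method: ReferenceMethod
    n_shuffles: int | None = None
    seed: int | None = None
    n_chains: int = 0
    composition: list[np.ndarray] = field(default_factory=list)

    @property
    def n_orient(self) -> int:
        return self.expected.shape[2]

    @property
    def totals_by_condition(self) -> np.ndarray:
        return self.expected.sum(axis=(0, 1))


def classic_reference(obs: PairCountTable) -> ExpectedTable:
    """Expected counts by averaging over all residue types.

    expected[i, j, o, b] = totals_by_condition[o, b] * w_ij with w_ij = x_i x_j
    the composition-derived weight of the ordered type pair (x is the pooled
    residue-type frequency over all training chains), so the
    distance/orientation shape is type-independent and per-condition totals are
    conserved by construction.
    """
    grand = obs.grand_total
    if grand == 0:
        raise ValueError("empty count table")
    if obs.composition:
        comp = np.sum(obs.composition, axis=0).astype(float)
    else:
        comp = obs.counts.sum(axis=(1, 2, 3)).astype(float)
    x = comp / comp.sum()
    w = np.outer(x, x)  # (20, 20)
    expected = w[:, :, None, None] * obs.totals_by_condition[None, None, :, :].astype(float)
    return ExpectedTable(
        expected=expected,
        binning=obs.binning,
        oriented=obs.oriented,
        method=ReferenceMethod.CLASSIC,
        n_chains=obs.n_chains,
        composition=list(obs.composition),
    )


def shuffle_chain_labels(chain: ChainModel, rng: np.random.Generator) -> ChainModel:
    """New ChainModel with the same coordinates and a uniformly permuted type labelling."""
    from .structure_io import Residue

    perm = rng.permutation(chain.length)
    residues = [
        Residue(
            type_code=chain.residues[src].type_code,
            ca=chain.residues[pos].ca,
            cb=chain.residues[pos].cb,
            seq_index=pos,
            author_resseq=chain.residues[pos].author_resseq,
        )
        for pos, src in enumerate(perm)
    ]
    return ChainModel(chain_id=chain.chain_id, residues=residues)


def shuffled_reference_mc(
    chains: list[ChainModel],
    binning: DistanceBinning,
    oriented: bool = True,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ExpectedTable:
    """Monte-Carlo shuffled reference: mean count table over ``n_shuffles``
    independent within-chain label permutations (coordinates fixed).

    Per-shuffle seeds are derived deterministically from the master ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not chains:
        raise ValueError("no chains")

    n_orient = 3 if oriented else 1
    n_cond = n_orient * binning.n_bins
    size = N_TYPES * N_TYPES * n_cond
    acc = np.zeros(size, dtype=float)

    # precompute pair geometry once per chain; only labels move between shuffles
    pre = []
    for chain in chains:
        p_idx, q_idx, cond, _ = chain_pair_conditions(chain, binning, oriented)
        pre.append((chain.types(), p_idx, q_idx, cond))

    children = np.random.SeedSequence(seed).spawn(n_shuffles)
    for child in children:
        rng = np.random.default_rng(child)
        for types, p_idx, q_idx, cond in pre:
            t = types[rng.permutation(len(types))]
            flat = (t[p_idx] * N_TYPES + t[q_idx]) * n_cond + cond
            acc += np.bincount(flat, minlength=size)
    acc /= n_shuffles

    comp = [np.bincount(c.types(), minlength=N_TYPES).astype(np.int64) for c in chains]
    return ExpectedTable(
        expected=acc.reshape(N_TYPES, N_TYPES, n_orient, binning.n_bins),
        binning=binning,
        oriented=oriented,
        method=ReferenceMethod.SRS_MC,
        n_shuffles=n_shuffles,
        seed=seed,
        n_chains=len(chains),
        composition=comp,
    )


def shuffled_reference_exact(
    chains: list[ChainModel], binning: DistanceBinning, oriented: bool = True
) -> ExpectedTable:
    """Exact expectation of the within-chain label shuffle.

    For a chain of length n with composition c, every ordered position pair
    carries type pair (i, j) with probability c_i c_j / (n (n-1)) for i != j and
    c_i (c_i - 1) / (n (n-1)) for i == j, independent of the pair's geometry, so
    expected[i, j, o, b] = H[o, b] * P[i, j] with H the chain's geometry
    histogram.
    """
    if not chains:
        raise ValueError("no chains")
    n_orient = 3 if oriented else 1
    n_cond = n_orient * binning.n_bins
    expected = np.zeros((N_TYPES, N_TYPES, n_orient, binning.n_bins), dtype=float)
    comp_list = []
    for chain in chains:
        types = chain.types()
        c = np.bincount(types, minlength=N_TYPES).astype(float)
        comp_list.append(c.astype(np.int64))
        n = chain.length
        if n < 2:
            continue
        _, _, cond, _ = chain_pair_conditions(chain, binning, oriented)
        hist = np.bincount(cond, minlength=n_cond).astype(float)
        prob = np.outer(c, c)
        np.fill_diagonal(prob, c * (c - 1.0))
        prob /= n * (n - 1.0)
        expected += prob[:, :, None, None] * hist.reshape(n_orient, binning.n_bins)[None, None]
    return ExpectedTable(
        expected=expected,
        binning=binning,
        oriented=oriented,
        method=ReferenceMethod.SRS_EXACT,
        n_chains=len(chains),
        composition=comp_list,
    )


def observed_counts(
    chains: list[ChainModel], binning: DistanceBinning, oriented: bool = True
) -> PairCountTable:
    """Convenience re-export: observed counts over the same chains."""
    return counts_for_chains(chains, binning, oriented)
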