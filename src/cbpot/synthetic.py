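"""Synthetic chains, interacting ensembles with known pair energies, and
synthetic decoy benchmarks.

The ensemble generator keeps chain coordinates fixed and resamples type labels
with composition-preserving label-swap Metropolis moves targeting
P(labels) proportional to exp(-sum over ordered pairs of pair_energy[...]).
Because label swaps preserve each chain's composition, the shuffled reference
conditions on exactly the ensemble the sampler explores, which makes energy
recovery a clean end-to-end oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aminoacids import N_TYPES
from .counts import chain_pair_conditions
from .geometry import DistanceBinning
from .structure_io import CB_BOND_LENGTH, ChainModel, Residue
from .benchmark import DecoyRecord, DecoySet

__all__ = [
    "GroundTruth",
    "EnsembleDiagnostics",
    "generate_chain",
    "generate_interacting_ensemble",
    "generate_decoy_benchmark",
    "uniform_composition",
    "pair_condition_matrix",
    "padded_energy",
    "total_label_energy",
    "run_label_swap",
]


def uniform_composition(n_used_types: int = N_TYPES) -> np.ndarray:
    """Uniform composition over the first ``n_used_types`` letters of the alphabet."""
    comp = np.zeros(N_TYPES)
    comp[:n_used_types] = 1.0 / n_used_types
    return comp


@dataclass
class GroundTruth:
    """Known pair energies driving the synthetic ensemble."""

    pair_energy: np.ndarray  # (20, 20, n_orient, n_bins), kT
    composition: np.ndarray  # (20,) type frequencies
    chain_length: int
    n_chains: int
    seed: int
    binning: DistanceBinning = field(default_factory=DistanceBinning)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.pair_energy)):
            raise ValueError("pair energies must be finite")
        if not np.allclose(self.pair_energy, np.swapaxes(self.pair_energy, 0, 1)):
            raise ValueError("pair_energy must be symmetric in (type_i, type_j)")

    @property
    def oriented(self) -> bool:
        return self.pair_energy.shape[2] == 3


@dataclass
class EnsembleDiagnostics:
    acceptance_rate: float
    energy_trace: np.ndarray  # (n_sweeps + 1, n_chains)


def _random_unit_vectors(rng: np.random.Generator, n: int, bias: float = 0.0) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    if bias > 0:
        v[:, 2] += bias * np.linalg.norm(v, axis=1)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_chain(
    n: int,
    composition: np.ndarray | None = None,
    compactness: float = 1.0,
    seed: int | np.random.Generator = 0,
    target_nn_distance: float = 5.0,
    min_separation: float = 3.2,
    orientation_bias: float = 0.0,
    chain_id: str = "A",
) -> ChainModel:
    """Self-avoiding random placement of n labelled interaction centres.

    Cbeta centres are placed uniformly inside a sphere sized so the mean
    nearest-neighbour distance is about ``target_nn_distance`` (scaled by
    ``compactness``; < 1 is denser), with a hard minimum separation. Calpha
    sits at the fixed 1.53 A bond offset from each Cbeta in a random direction
    (optionally biased along +z to give orientation classes recoverable
    signal). Types are drawn from ``composition``.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = uniform_composition() if composition is None else np.asarray(composition, float)
    comp = comp / comp.sum()

    # Poisson mean NN distance is ~0.554 * density^(-1/3)
    density = (0.55396 / target_nn_distance) ** 3
    radius = compactness * (3.0 * n / (4.0 * math.pi * density)) ** (1.0 / 3.0)

    # random sequential addition of hard spheres saturates near 38% packing
    packing = n * (min_separation / 2.0) ** 3 / radius**3
    if packing > 0.3:
        raise RuntimeError("infeasible density: could not place chain")

    for _attempt in range(10):
        pts = np.empty((n, 3))
        placed = 0
        tries = 0
        while placed < n and tries < 400 * n:
            tries += 1
            p = rng.uniform(-radius, radius, size=3)
            if p @ p > radius * radius:
                continue
            if placed and np.min(np.linalg.norm(pts[:placed] - p, axis=1)) < min_separation:
                continue
            pts[placed] = p
            placed += 1
        if placed == n:
            break
    else:
        raise RuntimeError("infeasible density: could not place chain")

    dirs = _random_unit_vectors(rng, n, orientation_bias)
    cb = pts
    ca = cb - CB_BOND_LENGTH * dirs
    types = rng.choice(N_TYPES, size=n, p=comp)

    from .aminoacids import AA1

    residues = [
        Residue(type_code=AA1[t], ca=ca[k], cb=cb[k], seq_index=k)
        for k, t in enumerate(types)
    ]
    return ChainModel(chain_id=chain_id, residues=residues)


def pair_condition_matrix(
    chain: ChainModel, binning: DistanceBinning, oriented: bool
) -> np.ndarray:
    """(n, n) matrix of flat condition indices (orientation * n_bins + bin);
    out-of-range pairs and the diagonal hold the sentinel value n_conditions."""
    n = chain.length
    n_cond = (3 if oriented else 1) * binning.n_bins
    g = np.full((n, n), n_cond, dtype=np.intp)
    p_idx, q_idx, cond, _ = chain_pair_conditions(chain, binning, oriented)
    g[p_idx, q_idx] = cond
    return g


def padded_energy(pair_energy: np.ndarray) -> np.ndarray:
    """Energy array extended with a zero 'condition' slot for sentinel lookups."""
    t1, t2, n_orient, n_bins = pair_energy.shape
    flat = pair_energy.reshape(t1, t2, n_orient * n_bins)
    return np.concatenate([flat, np.zeros((t1, t2, 1))], axis=2)


def total_label_energy(labels: np.ndarray, gmat: np.ndarray, epad: np.ndarray) -> np.ndarray:
    """Total ordered-pair energy of each chain; labels (C, n), gmat (C, n, n)."""
    return epad[labels[:, :, None], labels[:, None, :], gmat].sum(axis=(1, 2))


def run_label_swap(
    labels: np.ndarray,
    gmat: np.ndarray,
    epad: np.ndarray,
    n_proposals: int,
    rng: np.random.Generator,
) -> int:
    """Composition-preserving label-swap Metropolis moves, applied in place.

    One proposal per chain per step, vectorised across chains. Returns the
    number of accepted swaps (label-changing proposals only).
    """
    C, n = labels.shape
    ci = np.arange(C)
    accepted = 0
    for _ in range(n_proposals):
        p = rng.integers(n, size=C)
        q = rng.integers(n, size=C)
        tp = labels[ci, p]
        tq = labels[ci, q]
        gp_out = gmat[ci, p, :]
        gp_in = gmat[ci, :, p]
        gq_out = gmat[ci, q, :]
        gq_in = gmat[ci, :, q]
        gpq = gmat[ci, p, q]
        gqp = gmat[ci, q, p]

        def row_sum(t, g_out, g_in):
            return (
                epad[t[:, None], labels, g_out].sum(axis=1)
                + epad[labels, t[:, None], g_in].sum(axis=1)
            )

        # neighbour sums excluding the p-q cross terms, for old and new labels
        s_p_old = row_sum(tp, gp_out, gp_in) - (epad[tp, tq, gpq] + epad[tq, tp, gqp])
        s_p_new = row_sum(tq, gp_out, gp_in) - (epad[tq, tq, gpq] + epad[tq, tq, gqp])
        s_q_old = row_sum(tq, gq_out, gq_in) - (epad[tq, tp, gqp] + epad[tp, tq, gpq])
        s_q_new = row_sum(tp, gq_out, gq_in) - (epad[tp, tp, gqp] + epad[tp, tp, gpq])
        cross_old = epad[tp, tq, gpq] + epad[tq, tp, gqp]
        cross_new = epad[tq, tp, gpq] + epad[tp, tq, gqp]
        delta = (s_p_new - s_p_old) + (s_q_new - s_q_old) + (cross_new - cross_old)

        changing = (p != q) & (tp != tq)
        u = rng.random(C)
        accept = changing & ((delta <= 0) | (u < np.exp(-np.clip(delta, -700, 700))))
        idx = ci[accept]
        labels[idx, p[accept]] = tq[accept]
        labels[idx, q[accept]] = tp[accept]
        accepted += int(accept.sum())
    return accepted


def generate_interacting_ensemble(
    truth: GroundTruth,
    burn_in_sweeps: int = 80,
    trace_every: int = 10,
    **chain_kwargs,
) -> tuple[list[ChainModel], EnsembleDiagnostics]:
    """Chains whose labels are Boltzmann-distributed under the ground-truth
    pair energies, one independent equilibrated sample per chain.
    Extra keyword arguments are forwarded to :func:`generate_chain`."""
    ss = np.random.SeedSequence(truth.seed)
    seed_chains, seed_mcmc = ss.spawn(2)
    chain_rng = np.random.default_rng(seed_chains)
    chains = [
        generate_chain(truth.chain_length, truth.composition, seed=chain_rng, **chain_kwargs)
        for _ in range(truth.n_chains)
    ]

    n = truth.chain_length
    gmat = np.stack(
        [pair_condition_matrix(c, truth.binning, truth.oriented) for c in chains]
    )
    epad = padded_energy(truth.pair_energy)
    labels = np.stack([c.types() for c in chains])

    rng = np.random.default_rng(seed_mcmc)
    trace = [total_label_energy(labels, gmat, epad)]
    accepted = 0
    for sweep in range(burn_in_sweeps):
        accepted += run_label_swap(labels, gmat, epad, n, rng)
        if (sweep + 1) % trace_every == 0:
            trace.append(total_label_energy(labels, gmat, epad))

    from .aminoacids import AA1

    out = []
    for k, chain in enumerate(chains):
        residues = [
            Residue(
                type_code=AA1[labels[k, r]],
                ca=res.ca,
                cb=res.cb,
                seq_index=res.seq_index,
            )
            for r, res in enumerate(chain.residues)
        ]
        out.append(ChainModel(chain_id=chain.chain_id, residues=residues))
    diag = EnsembleDiagnostics(
        acceptance_rate=accepted / (burn_in_sweeps * n * truth.n_chains),
        energy_trace=np.stack(trace),
    )
    return out, diag


def generate_decoy_benchmark(
    n_targets: int,
    models_per_target: int,
    quality_range: tuple[float, float] = (40.0, 90.0),
    rho: float = 1.0,
    seed: int = 0,
    include_native: bool = False,
) -> list[DecoySet]:
    """Synthetic decoy sets whose energies correlate with quality at level rho.

    GDT_TS values are uniform over ``quality_range`` with at least one model at
    65.0 or better per target; energies are
    -rho * standardized(GDT_TS) + sqrt(1 - rho^2) * noise.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = quality_range
    sets = []
    for t in range(n_targets):
        tid = f"T{t:04d}"
        g = rng.uniform(lo, hi, size=models_per_target)
        if g.max() < 65.0:
            g[rng.integers(models_per_target)] = rng.uniform(65.0, max(hi, 66.0))
        z = (g - g.mean()) / max(g.std(), 1e-12)
        noise = rng.normal(size=models_per_target)
        e = -rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise
        records = [
            DecoyRecord(model_id=f"{tid}_m{k:03d}", gdt_ts=float(g[k]), energy=float(e[k]))
            for k in range(models_per_target)
        ]
        if include_native:
            z_nat = (100.0 - g.mean()) / max(g.std(), 1e-12)
            e_nat = -rho * z_nat + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()
            records.append(
                DecoyRecord(model_id=f"{tid}_native", gdt_ts=100.0, energy=float(e_nat), is_native=True)
            )
        sets.append(DecoySet(target_id=tid, records=records))
    return sets
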