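"""Decoy-ranking benchmark machinery.

Model quality is measured by GDT_TS; within a decoy set, scores are binned in
2.5-unit steps anchored at the set's best score, and the bin number is the
model's rank (rank 1 = indistinguishable from the best). A scoring function is
evaluated by the rank of its minimum-energy pick, averaged over targets. When
the native structure (GDT_TS 100 by definition) is present and a non-native
model is picked, the best non-native is assigned rank 2 regardless of the bin
gap to the native, so mispredictions are not over-penalised.

Scoring functions are compared pairwise with a one-tailed Wilcoxon signed-rank
test (exact null distribution up to 25 effective pairs, normal approximation
with continuity and tie corrections above).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DecoyRecord",
    "DecoySet",
    "RankSummary",
    "WilcoxonResult",
    "CandidateModel",
    "SelectionResult",
    "gdt_ts",
    "assign_ranks",
    "rank_of_selection",
    "summarize",
    "wilcoxon_one_tailed",
    "select_decoys",
    "read_manifest",
    "write_manifest",
    "read_scores",
    "write_scores",
]

DEFAULT_BIN_WIDTH = 2.5
NATIVE_GDT = 100.0


def gdt_ts(p1: float, p2: float, p4: float, p8: float) -> float:
    """Combine per-cutoff percentages: (GDT_P1 + GDT_P2 + GDT_P4 + GDT_P8) / 4."""
    vals = (p1, p2, p4, p8)
    for v in vals:
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"GDT_Pn out of [0, 100]: {v}")
    if not (p1 <= p2 <= p4 <= p8):
        raise ValueError("inconsistent cutoff percents: require p1 <= p2 <= p4 <= p8")
    return (p1 + p2 + p4 + p8) / 4.0


@dataclass
class DecoyRecord:
    model_id: str
    gdt_ts: float
    energy: float | None = None
    is_native: bool = False

    def __post_init__(self) -> None:
        if self.is_native and abs(self.gdt_ts - NATIVE_GDT) > 1e-9:
            raise ValueError("native records have GDT_TS = 100 by definition")


@dataclass
class DecoySet:
    target_id: str
    records: list[DecoyRecord]

    def __post_init__(self) -> None:
        natives = [r for r in self.records if r.is_native]
        if len(natives) > 1:
            raise ValueError("at most one native record per decoy set")
        if not [r for r in self.records if not r.is_native]:
            raise ValueError("decoy set needs at least one non-native model")

    @property
    def native(self) -> DecoyRecord | None:
        for r in self.records:
            if r.is_native:
                return r
        return None

    def non_natives(self) -> list[DecoyRecord]:
        return [r for r in self.records if not r.is_native]


def assign_ranks(
    decoy_set: DecoySet | list[DecoyRecord], bin_width: float = DEFAULT_BIN_WIDTH
) -> dict[str, int]:
    """Binned ranks anchored at the set's highest GDT_TS.

    rank(model) = 1 + floor((G_max - gdt) / bin_width); everything within one
    bin width of the top shares rank 1.
    """
    records = decoy_set.records if isinstance(decoy_set, DecoySet) else decoy_set
    if not records:
        raise ValueError("empty decoy set")
    g_max = max(r.gdt_ts for r in records)
    eps = 1e-9  # guard float noise at exact bin edges
    return {
        r.model_id: 1 + int(math.floor((g_max - r.gdt_ts) / bin_width + eps))
        for r in records
    }


def _resolve_energies(
    records: list[DecoyRecord], energies: dict[str, float] | None
) -> dict[str, float]:
    out = {}
    for r in records:
        if energies is not None:
            if r.model_id not in energies:
                raise KeyError(f"no energy for model {r.model_id!r}")
            out[r.model_id] = energies[r.model_id]
        else:
            if r.energy is None:
                raise ValueError(f"record {r.model_id!r} has no energy")
            out[r.model_id] = r.energy
    return out


def _select_min_energy(records: list[DecoyRecord], energy: dict[str, float]) -> DecoyRecord:
    # ties broken lexicographically by model_id (never by GDT_TS, which would leak the answer)
    return min(records, key=lambda r: (energy[r.model_id], r.model_id))


def rank_of_selection(
    decoy_set: DecoySet,
    energies: dict[str, float] | None = None,
    mode: str = "without_native",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> int:
    """Rank of the minimum-energy record.

    without_native: ranks are assigned over the non-native models only.
    with_native: picking the native gives rank 1; otherwise non-native ranks
    are computed among non-natives and shifted by +1, so the best non-native
    gets rank 2 regardless of its bin distance to the native.
    """
    if mode not in ("without_native", "with_native"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "with_native":
        if decoy_set.native is None:
            raise ValueError(f"target {decoy_set.target_id}: no native record in with_native mode")
        scope = decoy_set.records
    else:
        scope = decoy_set.non_natives()
    energy = _resolve_energies(scope, energies)
    picked = _select_min_energy(scope, energy)

    if mode == "with_native":
        if picked.is_native:
            return 1
        ranks = assign_ranks(decoy_set.non_natives(), bin_width)
        return ranks[picked.model_id] + 1
    ranks = assign_ranks(scope, bin_width)
    return ranks[picked.model_id]


@dataclass
class RankSummary:
    per_target_rank: dict[str, int]
    average_rank: float
    ranked_1_count: int
    mode: str


def summarize(
    sets: list[DecoySet],
    energies: dict[str, dict[str, float]] | None = None,
    mode: str = "without_native",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> RankSummary:
    """Per-target selection ranks, their average, and the number of targets
    where the selection is rank 1 (the native itself in with_native mode)."""
    if not sets:
        raise ValueError("no decoy sets")
    per_target = {}
    for ds in sets:
        e = energies.get(ds.target_id) if energies is not None else None
        per_target[ds.target_id] = rank_of_selection(ds, e, mode, bin_width)
    ranks = list(per_target.values())
    return RankSummary(
        per_target_rank=per_target,
        average_rank=float(np.mean(ranks)),
        ranked_1_count=sum(1 for r in ranks if r == 1),
        mode=mode,
    )


@dataclass
class WilcoxonResult:
    p_value: float
    n_effective: int
    direction: str
    statistic: float
    method: str


def _exact_signed_rank_cdf(ranks2: np.ndarray, w2_obs: int) -> float:
    """P(W+ <= w_obs) under the signed-rank null, by dynamic programming over
    the 2^n equiprobable sign assignments. ``ranks2`` are doubled midranks so
    tied ranks stay integral."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    return float(dist[: w2_obs + 1].sum())


def wilcoxon_one_tailed(ranks_a, ranks_b, exact_limit: int = 25) -> WilcoxonResult:
    """Paired one-sided Wilcoxon signed-rank test of 'a tends lower than b'.

    Zero differences are dropped; with everything zero the test is degenerate
    and p = 1 is returned with a warning. Ties in |difference| get midranks.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; no evidence of a difference")
        return WilcoxonResult(1.0, 0, "a<b", 0.0, "degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_limit:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        w2 = int(round(2.0 * w_plus))
        p = _exact_signed_rank_cdf(ranks2, w2)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        z = (w_plus - mean + 0.5) / math.sqrt(var)
        p = float(stats.norm.cdf(z))
        method = "normal"
    return WilcoxonResult(min(1.0, p), n, "a<b", w_plus, method)


@dataclass
class CandidateModel:
    model_id: str
    gdt_ts: float
    length: int
    is_all_atom: bool = True


@dataclass
class SelectionResult:
    target_id: str
    accepted: bool
    reason: str | None
    records: list[DecoyRecord] = field(default_factory=list)


def select_decoys(
    target_id: str,
    candidates: list[CandidateModel],
    seed: int = 0,
    min_best_gdt: float = 65.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> SelectionResult:
    """Representative-decoy selection for one target: (i) all-atom models only;
    (ii) reject the target unless some model reaches ``min_best_gdt``;
    (iii) keep the most populated exact-length cluster (ties -> longer);
    (iv) keep one seeded-random representative per occupied 2.5-unit GDT_TS bin."""
    if not candidates:
        raise ValueError("no candidate models")
    all_atom = [c for c in candidates if c.is_all_atom]
    if not all_atom:
        return SelectionResult(target_id, False, "no_all_atom_models")
    if max(c.gdt_ts for c in all_atom) < min_best_gdt:
        return SelectionResult(target_id, False, "best_model_below_threshold")

    by_length: dict[int, list[CandidateModel]] = {}
    for c in all_atom:
        by_length.setdefault(c.length, []).append(c)
    best_len = max(by_length, key=lambda L: (len(by_length[L]), L))
    cluster = by_length[best_len]

    g_max = max(c.gdt_ts for c in cluster)
    bins: dict[int, list[CandidateModel]] = {}
    for c in cluster:
        k = int(math.floor((g_max - c.gdt_ts) / bin_width + 1e-9))
        bins.setdefault(k, []).append(c)
    rng = np.random.default_rng(seed)
    records = []
    for k in sorted(bins):
        members = sorted(bins[k], key=lambda c: c.model_id)
        pick = members[rng.integers(len(members))]
        records.append(DecoyRecord(model_id=pick.model_id, gdt_ts=pick.gdt_ts))
    return SelectionResult(target_id, True, None, records)


# ---------------------------------------------------------------------------
# plain-text I/O: decoy manifests and score files

def write_manifest(sets: list[DecoySet], sink) -> None:
    sink.write("target_id\tmodel_id\tgdt_ts\tis_native\tenergy\n")
    for ds in sets:
        for r in ds.records:
            e = "" if r.energy is None else repr(float(r.energy))
            sink.write(
                f"{ds.target_id}\t{r.model_id}\t{float(r.gdt_ts)!r}\t{int(r.is_native)}\t{e}\n"
            )


def read_manifest(source) -> list[DecoySet]:
    reader = csv.DictReader(source, delimiter="\t")
    required = {"target_id", "model_id", "gdt_ts", "is_native"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    by_target: dict[str, list[DecoyRecord]] = {}
    order: list[str] = []
    for row in reader:
        tid = row["target_id"]
        if tid not in by_target:
            by_target[tid] = []
            order.append(tid)
        energy = row.get("energy")
        by_target[tid].append(
            DecoyRecord(
                model_id=row["model_id"],
                gdt_ts=float(row["gdt_ts"]),
                energy=float(energy) if energy not in (None, "") else None,
                is_native=bool(int(row["is_native"])),
            )
        )
    return [DecoySet(tid, recs) for tid, recs in ((t, by_target[t]) for t in order)]


def write_scores(scores: dict[str, float], sink, extra: dict[str, int] | None = None) -> None:
    sink.write("model_id\tenergy\tn_pairs_scored\n")
    for model_id, e in scores.items():
        n = extra.get(model_id, "") if extra else ""
        sink.write(f"{model_id}\t{float(e)!r}\t{n}\n")


def read_scores(source) -> dict[str, float]:
    reader = csv.DictReader(source, delimiter="\t")
    if reader.fieldnames is None or "model_id" not in reader.fieldnames or "energy" not in reader.fieldnames:
        raise ValueError("score file must have model_id and energy columns")
    return {row["model_id"]: float(row["energy"]) for row in reader}
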