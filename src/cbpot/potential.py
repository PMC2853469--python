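"""Energy tables by Boltzmann inversion of observed vs reference frequencies.

Four variants are produced from the same machinery:

==============  ===========  ============
variant         reference    orientations
==============  ===========  ============
RF_CB           classic      1
RF_CB_OD        classic      3
RF_CB_SRS       shuffled     1
RF_CB_SRS_OD    shuffled     3
==============  ===========  ============

Observed frequencies are smoothed against the reference with the sparse-count
weighting f' = (1/(1+m*sigma)) g + (m*sigma/(1+m*sigma)) f_obs, where m is the
number of observations behind the profile; an empty profile therefore falls
back to the reference exactly. Energies are E = -ln(f'/g) in kT units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aminoacids import AA1, AA_INDEX, N_TYPES
from .counts import PairCountTable, chain_pair_conditions
from .geometry import DistanceBinning, OrientationClass
from .reference import ExpectedTable, ReferenceMethod
from .structure_io import ChainModel

__all__ = [
    "VARIANTS",
    "SmoothingParams",
    "EnergyTable",
    "ModelScore",
    "smooth_frequencies",
    "build_energy_table",
    "score_model",
    "write_table",
    "read_table",
]

VARIANTS = ("RF_CB", "RF_CB_OD", "RF_CB_SRS", "RF_CB_SRS_OD")

_FORMAT_NAME = "cbpot-energy-table"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SmoothingParams:
    """Sparse-count smoothing weight; ``sigma`` is the per-observation weight."""

    sigma: float = 1.0 / 50.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class EnergyTable:
    energy: np.ndarray  # (20, 20, n_orient, n_bins), kT
    variant: str
    binning: DistanceBinning
    smoothing: SmoothingParams
    n_chains: int = 0
    n_shuffles: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def oriented(self) -> bool:
        return self.variant.endswith("_OD")

    @property
    def n_orient(self) -> int:
        return self.energy.shape[2]


@dataclass
class ModelScore:
    total_energy: float
    n_pairs_scored: int
    n_pairs_skipped: int


def variant_is_oriented(variant: str) -> bool:
    return variant.endswith("_OD")


def variant_reference(variant: str) -> str:
    return "SRS" if "_SRS" in variant else "CLASSIC"


def smooth_frequencies(
    f_obs: np.ndarray, m: float, g: np.ndarray, params: SmoothingParams
) -> np.ndarray:
    """Blend an observed bin distribution with the reference one.

    f' = (1/(1+m*sigma)) g + (m*sigma/(1+m*sigma)) f_obs. With m = 0 the result
    is the reference; as m grows it converges to the observed distribution.
    """
    if m < 0:
        raise ValueError("observation count must be >= 0")
    w = m * params.sigma
    return (np.asarray(g, float) + w * np.asarray(f_obs, float)) / (1.0 + w)


def build_energy_table(
    obs: PairCountTable,
    expected: ExpectedTable,
    params: SmoothingParams = SmoothingParams(),
    variant: str = "RF_CB_SRS_OD",
    normalization: str = "conditional",
) -> EnergyTable:
    """Boltzmann inversion of observed vs reference counts.

    With the default ``conditional`` normalisation, frequencies are
    distributions over distance bins within each (type_i, type_j, orientation)
    profile; ``joint`` normalises over the whole index space instead.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if obs.counts.shape != expected.expected.shape or obs.binning != expected.binning:
        raise ValueError("observed and expected tables do not share an index space")
    oriented = variant_is_oriented(variant)
    if oriented != obs.oriented:
        raise ValueError(f"variant {variant} needs oriented={oriented} counts")
    ref_kind = variant_reference(variant)
    if ref_kind == "SRS" and expected.method == ReferenceMethod.CLASSIC:
        raise ValueError("SRS variants require a shuffled reference")
    if ref_kind == "CLASSIC" and expected.method != ReferenceMethod.CLASSIC:
        raise ValueError("non-SRS variants require the classic reference")
    if normalization not in ("conditional", "joint"):
        raise ValueError("normalization must be 'conditional' or 'joint'")

    cnt = obs.counts.astype(float)
    exp = expected.expected.astype(float)

    if normalization == "conditional":
        m = cnt.sum(axis=3, keepdims=True)  # observations per (i, j, o) profile
        e_sum = exp.sum(axis=3, keepdims=True)
        bad = (e_sum == 0) & (m > 0)
        if np.any(bad):
            i, j, o, _ = np.argwhere(bad)[0]
            raise ValueError(
                f"reference mass zero for profile ({AA1[i]}, {AA1[j]}, orientation {o}) "
                "with observed counts present"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            f_obs = np.where(m > 0, cnt / np.where(m > 0, m, 1.0), 0.0)
            g = np.where(e_sum > 0, exp / np.where(e_sum > 0, e_sum, 1.0), 0.0)
    else:
        m = np.broadcast_to(cnt.sum(), cnt.shape[:3] + (1,))
        f_obs = cnt / max(cnt.sum(), 1.0)
        g = exp / max(exp.sum(), 1.0)

    w = m * params.sigma
    f_smooth = (g + w * f_obs) / (1.0 + w)

    bad_bin = (g == 0) & (f_smooth > 0)
    if np.any(bad_bin):
        i, j, o, b = np.argwhere(bad_bin)[0]
        raise ValueError(
            f"reference mass zero at ({AA1[i]}, {AA1[j]}, orientation {o}, bin {b}) "
            "with observed mass nonzero"
        )
    energy = np.zeros_like(cnt)
    ok = (g > 0) & (f_smooth > 0)
    energy[ok] = -np.log(f_smooth[ok] / g[ok])

    return EnergyTable(
        energy=energy,
        variant=variant,
        binning=obs.binning,
        smoothing=params,
        n_chains=obs.n_chains,
        n_shuffles=expected.n_shuffles,
        seed=expected.seed,
    )


def score_model(chain: ChainModel, table: EnergyTable) -> ModelScore:
    """Total energy of a model: sum over in-range ordered residue pairs of the
    table entry at (type_i, type_j, orientation, bin). Out-of-range pairs and
    pairs with degenerate orientation geometry are skipped and tallied."""
    n = chain.length
    total_pairs = n * (n - 1)
    if n < 2:
        return ModelScore(0.0, 0, 0)
    p_idx, q_idx, cond, n_degenerate = chain_pair_conditions(
        chain, table.binning, table.oriented
    )
    types = chain.types()
    n_cond = table.n_orient * table.binning.n_bins
    flat = (types[p_idx] * N_TYPES + types[q_idx]) * n_cond + cond
    total = float(table.energy.reshape(-1)[flat].sum())
    n_scored = len(p_idx)
    return ModelScore(
        total_energy=total,
        n_pairs_scored=n_scored,
        n_pairs_skipped=total_pairs - n_scored,
    )


_ORIENT_NAMES = {int(o): o.name for o in OrientationClass}
_ORIENT_INDEX = {o.name: int(o) for o in OrientationClass}
_ORIENT_INDEX["NONE"] = 0


def write_table(table: EnergyTable, sink) -> None:
    """Serialise an energy table as self-describing tabular text."""
    b = table.binning
    sink.write(f"#%format: {_FORMAT_NAME} {_FORMAT_VERSION}\n")
    sink.write(f"#%variant: {table.variant}\n")
    sink.write(f"#%alphabet: {AA1}\n")
    sink.write(f"#%first_bin_upper: {b.first_bin_upper!r}\n")
    sink.write(f"#%bin_width: {b.bin_width!r}\n")
    sink.write(f"#%max_distance: {b.max_distance!r}\n")
    sink.write(f"#%sigma: {table.smoothing.sigma!r}\n")
    sink.write(f"#%n_chains: {table.n_chains}\n")
    sink.write(f"#%n_shuffles: {table.n_shuffles if table.n_shuffles is not None else ''}\n")
    sink.write(f"#%seed: {table.seed if table.seed is not None else ''}\n")
    sink.write("type_i\ttype_j\torientation\tbin_lo\tbin_hi\tenergy\n")
    edges = b.edges()
    for i in range(N_TYPES):
        for j in range(N_TYPES):
            for o in range(table.n_orient):
                oname = _ORIENT_NAMES[o] if table.oriented else "NONE"
                for k in range(b.n_bins):
                    sink.write(
                        f"{AA1[i]}\t{AA1[j]}\t{oname}\t{edges[k]:g}\t{edges[k + 1]:g}\t"
                        f"{float(table.energy[i, j, o, k])!r}\n"
                    )


def read_table(source) -> EnergyTable:
    """Parse :func:`write_table` output; raises with a line number on malformed input."""
    header: dict[str, str] = {}
    lineno = 0
    line = source.readline()
    lineno += 1
    if not line.startswith(f"#%format: {_FORMAT_NAME} "):
        raise ValueError(f"line {lineno}: not a {_FORMAT_NAME} file")
    version = line.split()[-1]
    if version != str(_FORMAT_VERSION):
        raise ValueError(f"line {lineno}: unsupported format version {version}")
    while True:
        line = source.readline()
        lineno += 1
        if not line:
            raise ValueError(f"line {lineno}: unexpected end of header")
        if line.startswith("#%"):
            key, _, val = line[2:].partition(":")
            header[key.strip()] = val.strip()
            continue
        if line.startswith("type_i"):
            break
        raise ValueError(f"line {lineno}: malformed header line")

    variant = header["variant"]
    binning = DistanceBinning(
        first_bin_upper=float(header["first_bin_upper"]),
        bin_width=float(header["bin_width"]),
        max_distance=float(header["max_distance"]),
    )
    oriented = variant_is_oriented(variant)
    n_orient = 3 if oriented else 1
    energy = np.full((N_TYPES, N_TYPES, n_orient, binning.n_bins), math.nan)
    n_rows = 0
    for line in source:
        lineno += 1
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        try:
            i, j = AA_INDEX[parts[0]], AA_INDEX[parts[1]]
            o = _ORIENT_INDEX[parts[2]]
            lo = float(parts[3])
            val = float(parts[5])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
        b = 0 if lo < binning.first_bin_upper else 1 + int(
            round((lo - binning.first_bin_upper) / binning.bin_width)
        )
        if not (0 <= b < binning.n_bins):
            raise ValueError(f"line {lineno}: bin edge {lo} out of range")
        energy[i, j, o, b] = val
        n_rows += 1

    expected_rows = N_TYPES * N_TYPES * n_orient * binning.n_bins
    if n_rows != expected_rows or np.isnan(energy).any():
        raise ValueError(
            f"row count mismatch: expected {expected_rows} rows, read {n_rows}"
        )
    return EnergyTable(
        energy=energy,
        variant=variant,
        binning=binning,
        smoothing=SmoothingParams(sigma=float(header["sigma"])),
        n_chains=int(header.get("n_chains") or 0),
        n_shuffles=int(header["n_shuffles"]) if header.get("n_shuffles") else None,
        seed=int(header["seed"]) if header.get("seed") else None,
    )
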