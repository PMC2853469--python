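"""PDB chain ingestion into the Cbeta-centred representation, plus training-set filters.

Each residue is reduced to a single interaction centre, its Cbeta atom (built
virtually for glycine, and for any residue whose CB atom is absent but whose
backbone N/CA/C are present). Chains carry the metadata needed by the
training-set selection filters: experimental method, crystallographic
resolution, R-value and completeness flags.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser

from .aminoacids import AA1, ONE_TO_THREE, THREE_TO_ONE
from .geometry import DegenerateGeometryError

__all__ = [
    "Residue",
    "ChainFlags",
    "ChainModel",
    "FilterReport",
    "MetadataIncompleteError",
    "build_virtual_cb",
    "read_chain",
    "write_chain_pdb",
    "passes_training_filters",
    "cull_by_identity",
    "write_filter_reports",
]

# Canonical virtual-Cbeta geometry: CA-CB bond and N-CA-CB angle.
CB_BOND_LENGTH = 1.53
N_CA_CB_ANGLE_DEG = 110.5

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class MetadataIncompleteError(ValueError):
    """A training filter needed a metadata field that is absent."""


@dataclass
class Residue:
    """One residue reduced to its Calpha/Cbeta pair.

    ``cb`` is always populated; for glycine it is the virtual Cbeta built from
    the backbone frame.
    """

    type_code: str
    ca: np.ndarray
    cb: np.ndarray
    seq_index: int
    author_resseq: int | None = None

    def __post_init__(self) -> None:
        if self.type_code not in AA1:
            raise ValueError(f"unknown residue type {self.type_code!r}")
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        d = float(np.linalg.norm(self.cb - self.ca))
        if not (0.5 < d < 3.0):
            raise ValueError(f"|cb - ca| = {d:.3f} A outside (0.5, 3.0)")


@dataclass
class ChainFlags:
    """Completeness flags collected while reading a chain; they feed the filters."""

    incomplete_residues: list[str] = field(default_factory=list)
    nonstandard_residues: list[str] = field(default_factory=list)
    internal_missing: bool = False
    has_ions: bool = False


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue]
    resolution: float | None = None
    r_value: float | None = None
    experimental_method: str | None = None
    flags: ChainFlags = field(default_factory=ChainFlags)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.type_code for r in self.residues)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(ca, cb) coordinate arrays, each (n, 3)."""
        if not self.residues:
            return np.zeros((0, 3)), np.zeros((0, 3))
        ca = np.stack([r.ca for r in self.residues])
        cb = np.stack([r.cb for r in self.residues])
        return ca, cb

    def types(self) -> np.ndarray:
        from .aminoacids import AA_INDEX

        return np.array([AA_INDEX[r.type_code] for r in self.residues], dtype=np.intp)


@dataclass
class FilterReport:
    passed: bool
    reasons: list[str]

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


def build_virtual_cb(n, ca, c) -> np.ndarray:
    """Place an ideal Cbeta from the N-CA-C backbone frame.

    Bond CA-CB is 1.53 A, angle N-CA-CB is 110.5 deg, and the Cbeta sits out of
    the backbone plane on the side giving L-amino-acid chirality (positive
    signed volume of (N-CA, C-CA, CB-CA)).
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    v_n = n - ca
    v_c = c - ca
    ln = np.linalg.norm(v_n)
    lc = np.linalg.norm(v_c)
    if ln < 1e-9 or lc < 1e-9:
        raise DegenerateGeometryError("degenerate backbone geometry")
    nh = v_n / ln
    ch = v_c / lc
    normal = np.cross(nh, ch)
    lnorm = np.linalg.norm(normal)
    if lnorm < 1e-9:
        raise DegenerateGeometryError("degenerate backbone geometry")
    e3 = normal / lnorm
    bis = -(nh + ch)
    e1 = bis / np.linalg.norm(bis)
    # angle(nh, d) must equal the ideal N-CA-CB angle, with d = cos(phi) e1 + sin(phi) e3
    s = float(np.dot(nh, ch))
    cos_target = math.cos(math.radians(N_CA_CB_ANGLE_DEG))
    cos_phi = -cos_target / math.sqrt((1.0 + s) / 2.0)
    if cos_phi >= 1.0 - 1e-12:
        # N-CA-C angle too wide to place the Cbeta off-plane at the ideal angle
        raise DegenerateGeometryError("degenerate backbone geometry")
    sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    d = cos_phi * e1 + sin_phi * e3
    return ca + CB_BOND_LENGTH * d


def _parse_header_metadata(text: str) -> tuple[float | None, float | None, str | None]:
    """Resolution, R-value and experimental method from raw PDB text."""
    resolution = None
    r_value = None
    method = None
    m = re.search(r"^REMARK   2 RESOLUTION\.\s+([\d.]+)\s+ANGSTROM", text, re.M)
    if m:
        resolution = float(m.group(1))
    m = re.search(
        r"^REMARK   3\s+R VALUE\s+\(WORKING SET(?:, NO CUTOFF)?\)\s*:\s*([\d.]+)",
        text,
        re.M,
    )
    if m is None:
        m = re.search(r"^REMARK   3\s+R VALUE\s*:\s*([\d.]+)", text, re.M)
    if m:
        r_value = float(m.group(1))
    m = re.search(r"^EXPDTA\s+(.+?)\s*$", text, re.M)
    if m:
        method = m.group(1).strip()
    return resolution, r_value, method


def _pick_altloc(atom):
    """Highest-occupancy altloc; ties broken by file order."""
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        occ_b = best.get_occupancy() or 0.0
        occ_c = child.get_occupancy() or 0.0
        if occ_c > occ_b:
            best = child
    return best


def read_chain(pdb_source: str, chain_id: str) -> ChainModel:
    """Read one chain from PDB-format text (or a file path) into a ChainModel.

    Residues missing the atoms needed to place a Cbeta are flagged incomplete
    and omitted from the residue list; nonstandard residues and monoatomic
    HETATM species (ions) are flagged for the training filters.
    """
    if hasattr(pdb_source, "__fspath__") or "\n" not in pdb_source:
        with open(pdb_source) as fh:
            text = fh.read()
    else:
        text = pdb_source

    resolution, r_value, method = _parse_header_metadata(text)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("chain", io.StringIO(text))
    model = next(structure.get_models())
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain not found: {chain_id!r}")
    chain = model[chain_id]

    flags = ChainFlags()
    residues: list[Residue] = []
    observed_resseq: list[int] = []
    seq_index = 0
    for res in chain:
        hetfield, resseq, icode = res.get_id()
        resname = res.get_resname().strip().upper()
        if hetfield == "W" or resname in _WATER_NAMES:
            continue
        if hetfield.strip():
            # HETATM residue: monoatomic species are co-crystallised ions
            if len(list(res.get_atoms())) == 1:
                flags.has_ions = True
            else:
                flags.nonstandard_residues.append(f"{resname}{resseq}")
            continue
        if resname not in THREE_TO_ONE:
            flags.nonstandard_residues.append(f"{resname}{resseq}")
            continue

        atoms = {name: _pick_altloc(res[name]) for name in ("N", "CA", "C", "CB") if name in res}
        label = f"{resname}{resseq}"
        missing_backbone = [a for a in ("N", "CA", "C") if a not in atoms]
        if missing_backbone:
            flags.incomplete_residues.append(label)
        if "CB" not in atoms and resname != "GLY" and not missing_backbone:
            flags.incomplete_residues.append(label)

        if "CA" not in atoms:
            continue
        ca = np.array(atoms["CA"].get_coord(), dtype=float)
        if "CB" in atoms:
            cb = np.array(atoms["CB"].get_coord(), dtype=float)
        elif not missing_backbone:
            cb = build_virtual_cb(
                np.array(atoms["N"].get_coord(), dtype=float),
                ca,
                np.array(atoms["C"].get_coord(), dtype=float),
            )
        else:
            continue

        residues.append(
            Residue(
                type_code=THREE_TO_ONE[resname],
                ca=ca,
                cb=cb,
                seq_index=seq_index,
                author_resseq=resseq,
            )
        )
        observed_resseq.append(resseq)
        seq_index += 1

    # gaps in author numbering between the first and last observed residues
    for prev, nxt in zip(observed_resseq, observed_resseq[1:]):
        if nxt - prev > 1:
            flags.internal_missing = True
            break

    return ChainModel(
        chain_id=chain_id,
        residues=residues,
        resolution=resolution,
        r_value=r_value,
        experimental_method=method,
        flags=flags,
    )


def write_chain_pdb(chain: ChainModel) -> str:
    """Serialise the Cbeta-centred chain back to minimal PDB text (CA + CB atoms)."""
    lines = []
    serial = 1
    for res in chain.residues:
        resname = ONE_TO_THREE[res.type_code]
        resseq = res.author_resseq if res.author_resseq is not None else res.seq_index + 1
        for name, xyz in (("CA", res.ca), ("CB", res.cb)):
            lines.append(
                f"ATOM  {serial:>5} {name:^4} {resname:<3} {chain.chain_id:1}{resseq:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def passes_training_filters(
    chain: ChainModel,
    flags: ChainFlags | None = None,
    *,
    max_resolution: float = 2.1,
    max_r_value: float = 0.2,
    min_length: int = 50,
) -> FilterReport:
    """Training-set selection: X-ray, resolution and R-value strictly better than
    the cutoffs, at least ``min_length`` residues, no incomplete/nonstandard
    residues, missing residues at termini only, no co-crystallised ions."""
    flags = flags if flags is not None else chain.flags
    if chain.experimental_method is None or chain.resolution is None or chain.r_value is None:
        raise MetadataIncompleteError("metadata incomplete")

    reasons = []
    if "X-RAY" not in chain.experimental_method.upper():
        reasons.append("not_xray")
    if not chain.resolution < max_resolution:
        reasons.append("resolution")
    if not chain.r_value < max_r_value:
        reasons.append("r_value")
    if chain.length < min_length:
        reasons.append("length")
    if flags.incomplete_residues:
        reasons.append("incomplete_residues")
    if flags.nonstandard_residues:
        reasons.append("nonstandard_residues")
    if flags.internal_missing:
        reasons.append("internal_missing_residues")
    if flags.has_ions:
        reasons.append("ions")
    return FilterReport(passed=not reasons, reasons=reasons)


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical aligned positions / shorter length."""
    if not seq_a or not seq_b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def cull_by_identity(chains: list[ChainModel], threshold: float = 0.4) -> list[ChainModel]:
    """Greedy redundancy removal: process chains best-resolution first and keep a
    chain only if its identity to every retained chain is below ``threshold``."""
    if not chains:
        raise ValueError("no chains given")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(
        range(len(chains)),
        key=lambda k: (chains[k].resolution if chains[k].resolution is not None else math.inf, k),
    )
    retained: list[ChainModel] = []
    for k in order:
        cand = chains[k]
        if all(sequence_identity(cand.sequence, kept.sequence) < threshold for kept in retained):
            retained.append(cand)
    return retained


def write_filter_reports(reports: dict[str, FilterReport], sink) -> None:
    """Tab-separated filter report: chain_id, passed, comma-joined reasons."""
    sink.write("chain_id\tpassed\treasons\n")
    for chain_id, rep in reports.items():
        sink.write(f"{chain_id}\t{str(rep.passed).lower()}\t{','.join(rep.reasons)}\n")
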