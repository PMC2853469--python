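"""Shared fixtures: hand-built chains and minimal PDB text."""

from __future__ import annotations

import numpy as np
import pytest

from cbpot.structure_io import ChainModel, Residue


def make_chain(types: str, cb: np.ndarray, ca: np.ndarray | None = None,
               chain_id: str = "A") -> ChainModel:
    """ChainModel from a type string and Cbeta coordinates; Calpha defaults to a
    unit offset along -x from each Cbeta."""
    cb = np.asarray(cb, dtype=float)
    if ca is None:
        ca = cb - np.array([1.53, 0.0, 0.0])
    residues = [
        Residue(type_code=t, ca=np.asarray(ca[k], float), cb=cb[k], seq_index=k)
        for k, t in enumerate(types)
    ]
    return ChainModel(chain_id=chain_id, residues=residues)


def random_chain(rng: np.random.Generator, n: int, types: str = "ACDE",
                 box: float = 12.0) -> ChainModel:
    """Random small chain with random Calpha offsets (length ~1.5 A)."""
    cb = rng.uniform(0, box, size=(n, 3))
    offs = rng.normal(size=(n, 3))
    offs = 1.5 * offs / np.linalg.norm(offs, axis=1, keepdims=True)
    ca = cb - offs
    seq = "".join(rng.choice(list(types), size=n))
    return make_chain(seq, cb, ca)


def _atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
               xyz, element: str | None = None, record: str = "ATOM") -> str:
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:^4} {resname:<3} {chain}{resseq:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2}"
    )


def pdb_header(resolution: float = 2.0, r_value: float = 0.19,
               method: str = "X-RAY DIFFRACTION") -> list[str]:
    return [
        "HEADER    TEST PROTEIN                            01-JAN-00   XXXX",
        f"EXPDTA    {method}",
        f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.",
        f"REMARK   3   R VALUE            (WORKING SET) : {r_value:.3f}",
    ]


# idealised residue template: N, CA, C, CB around the origin (L-configuration)
_RES_TEMPLATE = {
    "N": np.array([-0.572, 1.337, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.517, 0.0, 0.0]),
    "CB": np.array([-0.540, -0.763, -1.203]),
}


def residue_atoms(origin, with_cb: bool = True, skip=()) -> dict[str, np.ndarray]:
    origin = np.asarray(origin, float)
    out = {}
    for name, off in _RES_TEMPLATE.items():
        if name == "CB" and not with_cb:
            continue
        if name in skip:
            continue
        out[name] = origin + off
    return out


def build_pdb(residues: list[tuple[str, int, dict[str, np.ndarray]]],
              chain: str = "A", header: list[str] | None = None,
              het_lines: list[str] | None = None) -> str:
    """Minimal PDB text from (resname, resseq, {atom: xyz}) triples."""
    lines = list(header if header is not None else pdb_header())
    serial = 1
    for resname, resseq, atoms in residues:
        for name in ("N", "CA", "C", "CB"):
            if name in atoms:
                lines.append(_atom_line(serial, name, resname, chain, resseq, atoms[name]))
                serial += 1
    if het_lines:
        lines.extend(het_lines)
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def het_ion_line(resseq: int = 900, chain: str = "A") -> str:
    return _atom_line(9000, "ZN", "ZN", chain, resseq, (30.0, 30.0, 30.0),
                      element="ZN", record="HETATM")


@pytest.fixture
def three_residue_pdb() -> str:
    """Ala-Gly-Ser with full backbone; Gly has no CB atom."""
    residues = [
        ("ALA", 1, residue_atoms((0.0, 0.0, 0.0))),
        ("GLY", 2, residue_atoms((4.0, 0.0, 0.0), with_cb=False)),
        ("SER", 3, residue_atoms((8.0, 0.0, 0.0))),
    ]
    return build_pdb(residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
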