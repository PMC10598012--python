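"""Structure, sequence and tabular I/O.

Structures are read with gemmi (PDB and mmCIF ATOM records, CRYST1 unit
cell and space group when present) into a light record from which Cα
chains are extracted with 0-based residue indexing; generated backbones
are written as CA-only PDB files (1-based numbering, chain A).  Writes
are atomic (temporary file + rename).  Sequence masses use standard
average residue masses plus one water, matching the kDa values quoted
for purified constructs.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

__all__ = [
    "IOError_",
    "StructureRecord",
    "read_structure",
    "ca_chain",
    "residue_count",
    "write_ca_pdb",
    "read_fasta",
    "sequence_mass",
    "read_xy_csv",
    "read_force_curve_csv",
    "write_force_curve_csv",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class IOError_(ValueError):
    """Raised for malformed or inconsistent files."""


@dataclass(frozen=True)
class StructureRecord:
    """Parsed structure: per-chain residues and crystal metadata."""

    chains: dict[str, list[tuple[int, str, dict[str, np.ndarray]]]]
    unit_cell: tuple[float, float, float, float, float, float] | None
    space_group: str | None
    name: str = ""

    def chain_ids(self) -> list[str]:
        return list(self.chains)


def read_structure(path) -> StructureRecord:
    """Read a PDB/mmCIF file into a StructureRecord (first model only)."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such structure file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError_(f"failed to parse {path}: {exc}") from exc
    st.setup_entities()
    chains: dict[str, list] = {}
    if len(st) == 0:
        raise IOError_(f"{path}: no models")
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            residues.append((res.seqid.num, res.name, atoms))
        chains[chain.name] = residues
    cell = st.cell
    unit_cell = None
    if cell is not None and cell.a > 1.0:  # gemmi uses a=1 placeholder cell
        unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    sg = st.spacegroup_hm or None
    return StructureRecord(chains, unit_cell, sg, name=path.stem)


def ca_chain(record: StructureRecord, chain: str | None = None) -> np.ndarray:
    """Ordered Cα coordinates (Å) of one chain, 0-based in memory."""
    if chain is None:
        if not record.chains:
            raise IOError_("structure has no chains")
        chain = next(iter(record.chains))
    if chain not in record.chains:
        raise IOError_(f"unknown chain {chain!r}; have {record.chain_ids()}")
    coords = [atoms["CA"] for _, _, atoms in record.chains[chain] if "CA" in atoms]
    if not coords:
        return np.zeros((0, 3))
    return np.vstack(coords)


def residue_count(record: StructureRecord, chain: str | None = None) -> int:
    """Number of amino-acid residues with a Cα atom in the chain."""
    return int(ca_chain(record, chain).shape[0])


def _atomic_write(path: Path, text: str):
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_ca_pdb(chain_coords, path, chain_id: str = "A",
                 residue_name: str = "ALA", unit_cell=None):
    """Write a Cα trace as a CA-only PDB file (atomic write).

    Residues are numbered from 1 on disk; occupancy 1.00, B-factor 0.00.
    """
    coords = np.asarray(chain_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise IOError_("chain coordinates must be (n, 3)")
    lines = []
    if unit_cell is not None:
        a, b, c, al, be, ga = unit_cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1"
        )
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  {residue_name} {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (identifier, sequence) pairs."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such FASTA file: {path}")
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def sequence_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a protein sequence.

    Sum of standard average residue masses plus one water; matches the
    molecular weights quoted in kDa for expressed constructs.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - STANDARD_AA
    if bad:
        raise IOError_(f"nonstandard residue letters: {sorted(bad)}")
    if not seq:
        raise IOError_("empty sequence")
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_xy_csv(path, x_col: str, y_col: str) -> tuple[np.ndarray, np.ndarray]:
    """Two named numeric columns from a CSV with a header row."""
    df = pd.read_csv(path, comment="#")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise IOError_(f"{path}: missing column {col!r}; have {list(df.columns)}")
    return df[x_col].to_numpy(float), df[y_col].to_numpy(float)


def read_force_curve_csv(path):
    """Force curve CSV: '# key=value' metadata header + extension/force.

    Required metadata: velocity_nm_s, spring_constant_pN_nm.  Columns:
    extension_nm, force_pN.
    """
    from .smfs import ForceCurve

    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = float(val)
    x, F = read_xy_csv(path, "extension_nm", "force_pN")
    try:
        return ForceCurve(x, F, meta["velocity_nm_s"], meta["spring_constant_pN_nm"])
    except KeyError as exc:
        raise IOError_(f"{path}: missing metadata {exc}") from exc


def write_force_curve_csv(curve, path):
    lines = [
        f"# velocity_nm_s = {curve.velocity}",
        f"# spring_constant_pN_nm = {curve.spring_constant}",
        "extension_nm,force_pN",
    ]
    for x, F in zip(curve.extension, curve.force):
        lines.append(f"{x:.4f},{F:.4f}")
    _atomic_write(Path(path), "\n".join(lines) + "\n")
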