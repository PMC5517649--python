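"""Atomic structure and sequence I/O.

Structures are held in a deliberately small hierarchical container
(chains -> residues -> atoms) built on top of gemmi's PDB parser.  The
container preserves file order, resolves alternate locations by a fixed
policy (highest occupancy wins, ties go to the first copy in the file),
and exposes the two views every downstream stage needs: a C-alpha trace
and a one-letter sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "SequenceRecord",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "ca_trace",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
]

# Standard residues plus the common selenomethionine special case.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(ValueError):
    """Malformed or unusable structural input."""


@dataclasses.dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    position: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclasses.dataclass
class Residue:
    resname: str
    resseq: int
    icode: str = ""
    het: bool = False
    atoms: list[AtomRecord] = dataclasses.field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.resseq, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_NAMES

    def one_letter(self, selenomet: bool = True) -> str:
        if self.resname in THREE_TO_ONE:
            return THREE_TO_ONE[self.resname]
        if selenomet and self.resname == "MSE":
            return "M"
        return "X"


@dataclasses.dataclass
class SequenceRecord:
    id: str
    residues: str
    first_resseq: int | None = None  # numbering offset so residue 0 conventions survive

    def __len__(self) -> int:
        return len(self.residues)


class Structure:
    """Ordered chains of ordered residues; iteration order is file order."""

    def __init__(self, entry_id: str = "", source: str = "") -> None:
        self.entry_id = entry_id
        self.source = source
        self.metadata: dict = {}
        self._chains: dict[str, list[Residue]] = {}

    @property
    def chain_ids(self) -> list[str]:
        return list(self._chains)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self._chains:
            raise KeyError(f"chain {chain_id!r} not in structure (have {self.chain_ids})")
        return self._chains[chain_id]

    def add_residue(self, chain_id: str, residue: Residue) -> None:
        residues = self._chains.setdefault(chain_id, [])
        if any(r.key == residue.key for r in residues):
            raise StructureError(
                f"duplicate residue key {residue.key} in chain {chain_id}"
            )
        residues.append(residue)

    def residues(self, chain_id: str | None = None, protein_only: bool = True) -> Iterator[Residue]:
        chains = [chain_id] if chain_id is not None else self.chain_ids
        for cid in chains:
            for res in self.chain(cid):
                if protein_only and (res.is_water or res.het):
                    continue
                yield res

    def atoms(self, protein_only: bool = False) -> Iterator[AtomRecord]:
        for cid in self.chain_ids:
            for res in self.chain(cid):
                if protein_only and (res.is_water or res.het):
                    continue
                yield from res.atoms

    def coordinates(self, protein_only: bool = True) -> np.ndarray:
        pts = [a.position for a in self.atoms(protein_only=protein_only)]
        if not pts:
            return np.zeros((0, 3))
        return np.vstack(pts)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one copy per atom name: highest occupancy, ties by file order."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    out = []
    for name in order:
        a = best[name]
        a = dataclasses.replace(a, altloc="")
        out.append(a)
    return out


def read_pdb(path: str | Path, altloc_policy: str = "occupancy", model_index: int = 0) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    altloc_policy: "occupancy" (default; highest occupancy wins, ties by file
    order) or "all" (keep every altloc copy).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if model_index >= len(st):
        raise StructureError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    out = Structure(entry_id=st.name or path.stem, source=str(path))
    n_atom_records = 0
    serial = 0
    for chain in model:
        cid = chain.name
        for res in chain:
            het = res.het_flag == "H"
            residue = Residue(
                resname=res.name,
                resseq=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                het=het,
            )
            recs = []
            for atom in res:
                serial += 1
                recs.append(
                    AtomRecord(
                        serial=serial,
                        name=atom.name,
                        altloc=(atom.altloc or "").strip(),
                        resname=res.name,
                        chain=cid,
                        resseq=res.seqid.num,
                        icode=residue.icode,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        bfactor=atom.b_iso,
                        element=atom.element.name,
                        het=het,
                    )
                )
                if not het:
                    n_atom_records += 1
            if altloc_policy == "occupancy":
                recs = _resolve_altlocs(recs)
            elif altloc_policy != "all":
                raise ValueError(f"unknown altloc policy {altloc_policy!r}")
            residue.atoms = recs
            out.add_residue(cid, residue)
    if n_atom_records == 0 and not any(True for _ in out.atoms()):
        raise StructureError(f"{path}: no ATOM records")
    if n_atom_records == 0:
        raise StructureError(f"{path}: no protein ATOM records")
    return out


def _format_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.het else "ATOM  "
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{record}{serial:5d} {name}{a.altloc or ' ':1s}{a.resname:>3s} "
        f"{a.chain[:1]:1s}{a.resseq:4d}{a.icode or ' ':1s}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: Structure, path: str | Path, remarks: Sequence[str] = ()) -> None:
    """Write a Structure in fixed-column PDB format (coordinates to 3 decimals)."""
    lines = [f"REMARK 999 {r}" for r in remarks]
    serial = 0
    for cid in structure.chain_ids:
        for res in structure.chain(cid):
            for a in res.atoms:
                serial += 1
                lines.append(_format_atom_line(a, serial))
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_sequence(
    structure: Structure, chain: str, selenomet: bool = True
) -> SequenceRecord:
    """One-letter sequence of a chain in residue order (X for non-standard).

    ``first_resseq`` records the numbering offset so conventions such as
    "the initiator methionine is numbered zero" can be honoured downstream.
    """
    residues = [r for r in structure.chain(chain) if not (r.is_water or (r.het and r.resname not in THREE_TO_ONE and r.resname != "MSE"))]
    if not residues:
        raise KeyError(f"chain {chain} has no polymer residues")
    letters = "".join(r.one_letter(selenomet=selenomet) for r in residues)
    return SequenceRecord(id=f"{structure.entry_id}_{chain}", residues=letters,
                          first_resseq=residues[0].resseq)


def ca_trace(
    structure: Structure,
    chain: str,
    ranges: Iterable[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, np.ndarray]], list[int]]:
    """Ordered (resseq, CA position) pairs for a chain, optionally restricted
    to inclusive resseq ranges.  Residues lacking a CA atom are reported in
    the second return value, never silently skipped."""
    residues = [r for r in structure.chain(chain) if not r.is_water]
    if ranges is not None:
        ranges = list(ranges)
        residues = [
            r for r in residues if any(lo <= r.resseq <= hi for lo, hi in ranges)
        ]
    if not residues:
        raise ValueError(f"empty selection for chain {chain} ranges {ranges}")
    trace: list[tuple[int, np.ndarray]] = []
    missing: list[int] = []
    for r in residues:
        ca = r.atom("CA")
        if ca is None:
            missing.append(r.resseq)
        else:
            trace.append((r.resseq, ca.position))
    return trace, missing


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    from Bio import SeqIO

    return [SequenceRecord(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.residues
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def structure_from_ca(
    coords: np.ndarray,
    sequence: str | None = None,
    chain: str = "A",
    entry_id: str = "model",
    first_resseq: int = 1,
) -> Structure:
    """Build a C-alpha-only Structure from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    st = Structure(entry_id=entry_id)
    for i, xyz in enumerate(coords):
        resseq = first_resseq + i
        resname = ONE_TO_THREE.get(sequence[i], "GLY") if sequence else "GLY"
        res = Residue(resname=resname, resseq=resseq)
        res.atoms.append(
            AtomRecord(
                serial=i + 1, name="CA", altloc="", resname=resname,
                chain=chain, resseq=resseq, icode="", position=xyz, element="C",
            )
        )
        st.add_residue(chain, res)
    return st
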