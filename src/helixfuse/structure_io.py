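"""Macromolecular structure I/O and the coordinate data model.

A deliberately small hierarchy — :class:`Structure` / :class:`Chain` /
:class:`Residue` / :class:`Atom` — carries exactly what the design and
measurement operations need: author residue numbering (which may be
offset, e.g. Lys1218 in a second fused component), insertion codes,
heavy-atom coordinates and occupancies.  Parsing and serialization of
PDB and mmCIF are delegated to gemmi; FASTA is written directly.

Author numbering is never silently renumbered here: renumbering is an
explicit step of the fusion-design module.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "read_structure",
    "write_structure",
    "chain_sequence",
    "write_fasta",
    "three_to_one",
    "STANDARD_AA3",
]

# 3-letter -> 1-letter code for the 20 standard amino acids.
_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_AA3 = frozenset(_AA3_TO_1)
_AA1_TO_3 = {v: k for k, v in _AA3_TO_1.items()}


def three_to_one(res_name: str) -> str:
    """One-letter code for a 3-letter residue name; nonstandard -> ``"X"``."""
    return _AA3_TO_1.get(res_name.upper(), "X")


def one_to_three(code: str) -> str:
    """3-letter residue name for a one-letter code; unknown -> ``"UNK"``."""
    return _AA1_TO_3.get(code.upper(), "UNK")


@dataclass
class Atom:
    """A single (heavy) atom with PDB-convention name and element symbol."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"residue {self.res_name} {self.chain_id}{self.seq_number}: no atom "
            f"{name!r} (has {[a.name for a in self.atoms]})"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def ca(self) -> Atom:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        return three_to_one(self.res_name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seq_number: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"chain {self.id}: no residue {seq_number}{insertion_code}")

    def has_residue(self, seq_number: int, insertion_code: str = "") -> bool:
        return any(
            r.seq_number == seq_number and r.insertion_code == insertion_code
            for r in self.residues
        )


@dataclass
class Structure:
    id: str = ""
    chains: list[Chain] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"structure {self.id!r}: no chain {chain_id!r} "
                       f"(has {[c.id for c in self.chains]})")

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def coords(self) -> np.ndarray:
        """All atom coordinates, atoms in deposition order, shape (n, 3)."""
        return np.array([a.coord for _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy: x -> R @ x + t."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for _, a in out.iter_atoms():
            a.coord = R @ a.coord + t
        return out

    def validate(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"structure {self.id!r}: duplicate chain ids {ids}")
        for c in self.chains:
            keys = [r.key for r in c.residues]
            if len(keys) != len(set(keys)):
                raise ValueError(f"chain {c.id}: duplicate residue keys")


# ---------------------------------------------------------------------------
# gemmi-backed parsing / serialization


def _gemmi_format(fmt: str) -> gemmi.CoorFormat:
    table = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    try:
        return table[fmt]
    except KeyError:
        raise ValueError(f"unknown structure format {fmt!r}; expected pdb, mmcif or auto")


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    """Highest occupancy wins; ties broken by altloc letter order."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "~"))


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the package's :class:`Structure`.

    Only the first model of multi-model entries is kept.  Alternate
    conformers are resolved to the highest-occupancy one (ties broken by
    altloc letter).  Hydrogens and waters are dropped; author residue
    numbering and insertion codes are preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    fmt = _gemmi_format(format)
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path} as {format}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    out = Structure(id=st.name or path.stem,
                    metadata={"source_format": format, "source_path": str(path)})
    model = st[0]
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            if gres.name == "HOH":
                continue
            # group alternate conformers by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(Atom(
                    name=name,
                    element=ga.element.name,
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=ga.b_iso,
                    is_hetero=gres.het_flag == "H",
                ))
            if atoms:
                chain.residues.append(Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    res_name=gres.name,
                    atoms=atoms,
                ))
        if chain.residues:
            out.chains.append(chain)
    out.validate()
    return out


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "model"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "H" if any(a.is_hetero for a in res.atoms) else "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*np.round(atom.coord, 3))
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Serialize at PDB precision (3 decimals on coordinates).

    The fixed-column PDB format cannot hold residue numbers above 9999;
    such structures must be written as mmCIF.
    """
    if not structure.chains or structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    path = Path(path)
    if format == "pdb":
        worst = max(r.seq_number for r in structure.iter_residues())
        if worst > 9999:
            raise ValueError(
                f"residue number {worst} does not fit PDB fixed-width columns; "
                "write mmCIF instead (format='mmcif')"
            )
        _to_gemmi(structure).write_pdb(str(path))
    elif format == "mmcif":
        doc = _to_gemmi(structure).make_mmcif_document()
        doc.write_file(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}; expected pdb or mmcif")


def chain_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain, in residue order.

    Nonstandard residues map to ``"X"``; numbering gaps do not insert
    placeholder letters (the sequence reflects modelled residues only).
    """
    chain = structure.chain(chain_id)
    return "".join(r.one_letter for r in chain.residues)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` records as FASTA with 60-column wrapping."""
    records = list(records)
    seen: set[str] = set()
    lines = []
    for rec_id, seq in records:
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        if not seq or not seq.isalpha():
            raise ValueError(f"record {rec_id!r}: sequence must be non-empty and alphabetic")
        lines.append(f">{rec_id}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal FASTA reader (inverse of :func:`write_fasta`)."""
    records: list[tuple[str, str]] = []
    rec_id, parts = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if rec_id is not None:
                records.append((rec_id, "".join(parts)))
            rec_id, parts = line[1:].split()[0], []
        else:
            parts.append(line)
    if rec_id is not None:
        records.append((rec_id, "".join(parts)))
    return records
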