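"""EY-CBS staple sites: cross-linker model, i/i+11 cysteine placement,
mutation application, and design-record validation.

EY-CBS (3,3′-ethyne-1,2-diylbis-{6-[(chloroacetyl)amino]benzenesulfonic
acid}) is a rigid bifunctional cross-linker whose two chloroacetyl ends
react with cysteine thiols spaced 11 residues apart on one face of an
α-helix (three full turns, so i and i+11 point the same way).  Stapling
a fusion helix with it locks the helical conformation across the
junction between the two fused domains.  Reaction with the staple is
also a conformational probe: only a genuinely continuous helix presents
both cysteines at the right spacing and Cα–Cα distance (~16.8 Å).

Residues at i+4 and i+7 sit under the cross-linker's phenyl rings and
are mutated to alanine so that long side chains cannot collide with it;
this masking is reported, not enforced, because published designs vary
on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .fusion_design import FusionDesign
from .helix_geometry import HelixSegment, fit_helix_axis, ideal_cb, place_atom
from .structure_io import Atom, Residue, Structure

__all__ = [
    "CrosslinkerSpec",
    "EY_CBS",
    "StapleSite",
    "DesignRecord",
    "ValidationReport",
    "crosslinker_mw",
    "find_staple_sites",
    "apply_staple_mutations",
    "exposure_score",
    "validate_design_record",
    "parse_design_table",
    "load_packaged_design_table",
]


def crosslinker_mw(formula: dict[str, int]) -> float:
    """Molecular weight (Da) from an element→count map, using standard
    atomic weights."""
    total = 0.0
    for symbol, count in formula.items():
        el = gemmi.Element(symbol)
        if el.name == "X" or el.weight <= 0:
            raise ValueError(f"unknown element symbol {symbol!r}")
        total += el.weight * count
    return total


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Descriptor of a helix-stapling cross-linker.

    ``spacing`` is the residue offset between the two anchor cysteines
    (11 for EY-CBS: three helical turns, same helix face);
    ``anchor_ca_distance`` is the target Cα–Cα separation the reacted
    staple enforces, with ``anchor_ca_window`` the acceptance band for
    candidate sites; ``masked_offsets`` are the positions (relative to
    the first anchor) mutated to alanine to clear the linker's footprint.
    """

    name: str = "EY-CBS"
    formula: tuple[tuple[str, int], ...] = ()
    spacing: int = 11
    anchor_ca_distance: float = 16.8
    anchor_ca_window: tuple[float, float] = (15.5, 18.1)
    masked_offsets: tuple[int, ...] = (4, 7)

    def __post_init__(self):
        if self.spacing < 1:
            raise ValueError("anchor spacing must be ≥ 1")
        lo, hi = self.anchor_ca_window
        if not lo <= self.anchor_ca_distance <= hi:
            raise ValueError("anchor_ca_window must contain anchor_ca_distance")

    @property
    def molecular_weight(self) -> float:
        return crosslinker_mw(dict(self.formula))


#: EY-CBS: two 6-(chloroacetamido)benzenesulfonic acid halves bridged by an
#: ethyne — C18H14Cl2N2O8S2, 521 Da.
EY_CBS = CrosslinkerSpec(
    name="EY-CBS",
    formula=(("C", 18), ("H", 14), ("Cl", 2), ("N", 2), ("O", 8), ("S", 2)),
)


@dataclass
class StapleSite:
    """An i / i+spacing cysteine pair on the fusion helix."""

    i_position: int
    j_position: int
    ca_distance: float
    exposure_i: int
    exposure_j: int
    face_angle: float  # deg between the two anchors' radial vectors
    mutations: list = field(default_factory=list)  # (position, from_aa, to_aa)

    @property
    def score(self) -> tuple:
        return (abs(self.ca_distance), self.exposure_i + self.exposure_j)


def exposure_score(model: Structure, position: tuple[str, int],
                   radius: float = 10.0, min_separation: int = 4) -> int:
    """Burial proxy: heavy atoms within ``radius`` Å of the position's Cβ,
    excluding residues within ``min_separation`` in sequence on the same
    chain (lower = more exposed).

    The own helical turn always fills the neighborhood, so it is not
    informative about whether the helix face is packed against the rest
    of the structure; only more distant residues are counted.  Gly uses
    a pseudo-Cβ built from its backbone.
    """
    chain_id, seq_number = position
    res = model.chain(chain_id).residue(seq_number)
    if res.has_atom("CB"):
        cb = res.atom("CB").coord
    else:
        cb = ideal_cb(res.atom("N").coord, res.atom("CA").coord, res.atom("C").coord)
    count = 0
    for r in model.iter_residues():
        if r.chain_id == chain_id and abs(r.seq_number - seq_number) <= min_separation:
            continue
        for a in r.atoms:
            if a.element.upper() != "H" and np.linalg.norm(a.coord - cb) <= radius:
                count += 1
    return count


def find_staple_sites(model: Structure, fusion_helix: HelixSegment,
                      junction_position: int,
                      linker: CrosslinkerSpec = EY_CBS,
                      exposure_threshold: int = 22) -> list[StapleSite]:
    """Candidate cysteine pairs spanning the fusion junction, ranked.

    A candidate (i, i+spacing) must straddle the junction (one anchor
    per parent domain: i ≤ junction < i+spacing), fall inside the
    linker's Cα–Cα distance window, and have both positions at least as
    exposed as ``exposure_threshold`` allows.  Ranking is by deviation
    from the linker's target anchor distance, ties by total burial.

    Returns an empty list (and stores per-filter rejection counts on
    the list via :func:`find_staple_sites.last_rejections`) when no pair
    passes.
    """
    if fusion_helix.n_residues < linker.spacing + 3:
        raise ValueError(
            f"fusion helix of {fusion_helix.n_residues} residues is too short for "
            f"an i/i+{linker.spacing} staple"
        )
    if not fusion_helix.start <= junction_position <= fusion_helix.end:
        raise ValueError(
            f"junction {junction_position} outside fusion helix "
            f"{fusion_helix.start}–{fusion_helix.end}"
        )
    chain = model.chain(fusion_helix.chain_id)
    span = [r for r in chain.residues
            if fusion_helix.start <= r.seq_number <= fusion_helix.end]
    fit = fit_helix_axis([r.ca.coord for r in span])
    rejections = {"junction": 0, "distance": 0, "exposure": 0}
    sites: list[StapleSite] = []
    for res_i in span:
        i = res_i.seq_number
        j = i + linker.spacing
        if not chain.has_residue(j) or j > fusion_helix.end:
            continue
        if not (i <= junction_position < j):
            rejections["junction"] += 1
            continue
        res_j = chain.residue(j)
        d = float(np.linalg.norm(res_i.ca.coord - res_j.ca.coord))
        if not linker.anchor_ca_window[0] <= d <= linker.anchor_ca_window[1]:
            rejections["distance"] += 1
            continue
        exp_i = exposure_score(model, (fusion_helix.chain_id, i))
        exp_j = exposure_score(model, (fusion_helix.chain_id, j))
        if exp_i > exposure_threshold or exp_j > exposure_threshold:
            rejections["exposure"] += 1
            continue

        def radial(r: Residue) -> np.ndarray:
            v = r.ca.coord - fit.axis_point
            v = v - np.dot(v, fit.axis_direction) * fit.axis_direction
            return v / np.linalg.norm(v)

        face = math.degrees(math.acos(np.clip(
            np.dot(radial(res_i), radial(res_j)), -1.0, 1.0)))
        muts = [(i, res_i.one_letter, "C"), (j, res_j.one_letter, "C")]
        for off in linker.masked_offsets:
            pos = i + off
            if chain.has_residue(pos):
                aa = chain.residue(pos).one_letter
                if aa not in ("A", "G"):
                    muts.append((pos, aa, "A"))
        sites.append(StapleSite(
            i_position=i, j_position=j, ca_distance=d,
            exposure_i=exp_i, exposure_j=exp_j, face_angle=face,
            mutations=muts))
    sites.sort(key=lambda s: (abs(s.ca_distance - linker.anchor_ca_distance),
                              s.exposure_i + s.exposure_j))
    find_staple_sites.last_rejections = rejections  # type: ignore[attr-defined]
    return sites


# Cys side-chain geometry for the modelled staple anchors
_CB_SG_BOND = 1.808
_CA_CB_SG_ANGLE = 114.4
_CHI1 = -60.0

_SIDE_CHAIN_KEEP = {"N", "CA", "C", "O", "CB"}


def _mutate_residue(res: Residue, to_aa: str) -> Optional[str]:
    """Trim the side chain past Cβ and rename; Cys gains an SG at χ1=−60°.

    Returns a note when a pseudo-Cβ had to be constructed for Gly."""
    from .structure_io import one_to_three
    note = None
    res.atoms = [a for a in res.atoms if a.name in _SIDE_CHAIN_KEEP]
    if not res.has_atom("CB"):
        cb = ideal_cb(res.atom("N").coord, res.atom("CA").coord, res.atom("C").coord)
        res.atoms.append(Atom("CB", "C", cb))
        note = f"residue {res.seq_number}: Cβ constructed from backbone (was Gly)"
    if to_aa == "C":
        sg = place_atom(res.atom("N").coord, res.atom("CA").coord, res.atom("CB").coord,
                        _CB_SG_BOND, _CA_CB_SG_ANGLE, _CHI1)
        res.atoms = [a for a in res.atoms if a.name != "SG"]
        res.atoms.append(Atom("SG", "S", sg))
    res.res_name = one_to_three(to_aa)
    return note


def apply_staple_mutations(design: FusionDesign, site: StapleSite
                           ) -> tuple[str, Structure]:
    """Apply a staple site's mutations to the fused model.

    Cysteines are modelled to Cβ+SG (ideal χ1 = −60°); alanine masking
    trims side chains past Cβ.  Mutations never touch residues outside
    the fusion helix.  The operation is idempotent.  Returns the
    mutated fusion-helix sequence and the mutated model (the design's
    ``fused_model`` is replaced).
    """
    if design.fused_model is None:
        raise ValueError("design must be built before stapling")
    lo, hi = design.fusion_span
    for pos, _, _ in site.mutations:
        if not lo <= pos <= hi:
            raise ValueError(f"mutation at {pos} outside fusion helix {lo}–{hi}")
    model = design.fused_model.copy()
    chain = model.chains[0]
    notes = []
    targets = {pos: to for pos, _, to in site.mutations}
    for res in chain.residues:
        if res.seq_number in targets:
            note = _mutate_residue(res, targets[res.seq_number])
            if note:
                notes.append(note)
    model.metadata.setdefault("staple_notes", []).extend(notes)
    model.metadata["staple_site"] = (site.i_position, site.j_position)
    design.fused_model = model
    return design.fusion_helix_sequence(), model


# ---------------------------------------------------------------------------
# design records (delimited-table rows describing one chimera each)


@dataclass
class DesignRecord:
    name: str
    first_protein: str
    second_protein: str
    first_junction_residue: int
    second_junction_residue: int
    fusion_helix_sequence: str

    def __post_init__(self):
        self.fusion_helix_sequence = self.fusion_helix_sequence.strip().upper()
        if self.fusion_helix_sequence and not self.fusion_helix_sequence.isalpha():
            raise ValueError(f"record {self.name!r}: sequence must be alphabetic")
        if self.first_junction_residue <= 0 or self.second_junction_residue <= 0:
            raise ValueError(f"record {self.name!r}: junction residues must be positive")


@dataclass
class ValidationReport:
    name: str
    n_cys: int
    cys_positions: list[int]       # 1-based positions in the fusion helix
    spacing_ok: bool
    ala_i4_ok: bool
    ala_i7_ok: bool
    length: int
    notes: list[str] = field(default_factory=list)


def validate_design_record(record: DesignRecord,
                           linker: CrosslinkerSpec = EY_CBS) -> ValidationReport:
    """Check a design record against the staple geometry rules.

    ``spacing_ok`` requires exactly two Cys separated by the linker
    spacing; the i+4/i+7 alanine flags are informational (published
    designs violate them without abandoning the staple).
    """
    seq = record.fusion_helix_sequence
    if not seq:
        raise ValueError(f"record {record.name!r} has an empty sequence")
    cys = [k + 1 for k, aa in enumerate(seq) if aa == "C"]
    spacing_ok = len(cys) == 2 and cys[1] - cys[0] == linker.spacing
    notes = []
    ala4 = ala7 = False
    if spacing_ok:
        i = cys[0]
        for off, flag_name in zip(linker.masked_offsets, ("i4", "i7")):
            pos = i + off
            ok = pos <= len(seq) and seq[pos - 1] in ("A", "G")
            if flag_name == "i4":
                ala4 = ok
            else:
                ala7 = ok
            if not ok and pos <= len(seq):
                notes.append(f"position i+{off} is {seq[pos - 1]}, not Ala")
    else:
        notes.append(f"{len(cys)} Cys at {cys}; need exactly 2 at offset {linker.spacing}")
    return ValidationReport(
        name=record.name, n_cys=len(cys), cys_positions=cys,
        spacing_ok=spacing_ok, ala_i4_ok=ala4, ala_i7_ok=ala7,
        length=len(seq), notes=notes)


_REQUIRED_COLUMNS = ("name", "first_protein", "second_protein",
                     "first_junction_residue", "second_junction_residue",
                     "fusion_helix_sequence")


def parse_design_table(path: str | Path, sep: Optional[str] = None) -> list[DesignRecord]:
    """Parse a delimited design table (TSV/CSV with a header row)."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []
    return [
        DesignRecord(
            name=str(row["name"]),
            first_protein=str(row["first_protein"]),
            second_protein=str(row["second_protein"]),
            first_junction_residue=int(row["first_junction_residue"]),
            second_junction_residue=int(row["second_junction_residue"]),
            fusion_helix_sequence=str(row["fusion_helix_sequence"]),
        )
        for _, row in df.iterrows()
    ]


def load_packaged_design_table() -> list[DesignRecord]:
    """The 21 published fusion-helix design records shipped with the package."""
    with resources.as_file(resources.files("helixfuse.data") / "table1.tsv") as p:
        return parse_design_table(p, sep="\t")
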