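"""Rigid chimera construction around a shared fusion α-helix.

A chimera is built by merging the C-terminal helix of a *donor* domain
and the N-terminal helix of an *acceptor* domain onto one ideal helix
template: each parent helix is least-squares superposed onto its
register on the template, and the corresponding whole domain is carried
along rigidly.  No refinement or repacking touches the parents — the
model is pure rigid geometry, which is exactly what makes the outcome
predictable: because an α-helix advances ~1.5 Å and ~100° per residue,
inserting k residues between the junctions rotates the acceptor domain
by ~k·100° about the fusion-helix axis.

A second mode inserts an adaptor domain into an internal loop of a
target protein: only the adaptor's C-terminal helix is rigidly fused
(onto the target helix that follows the loop); the N-side is bridged by
a flexible linker (default GGGGS) that is recorded in the designed
sequence but deliberately not modelled — in crystal structures it is
disordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .helix_geometry import (
    HelixSegment,
    IdealHelixParams,
    build_ideal_helix,
    fit_helix_axis,
    segment_from_residues,
    superpose,
)
from .structure_io import Atom, Chain, Residue, Structure, one_to_three

__all__ = [
    "FusionDesign",
    "ClashReport",
    "OrientationDelta",
    "plan_terminal_fusion",
    "plan_loop_insertion",
    "build_fusion_model",
    "detect_clashes",
    "scan_insertions",
    "relative_orientation",
    "VDW_RADII",
]

#: acceptor residues are also reported with this author-style offset, so a
#: second-component residue 218 appears as 1218 in reports.
ACCEPTOR_AUTHOR_OFFSET = 1000


@dataclass
class FusionDesign:
    """Complete recipe for one chimera; ``fused_model`` is set by build."""

    donor_structure: Structure
    donor_helix: HelixSegment
    donor_junction: int
    acceptor_structure: Structure
    acceptor_helix: HelixSegment
    acceptor_junction: int
    n_insert: int = 0
    insert_sequence: str = ""
    mode: str = "terminal_fusion"
    flexible_linker: Optional[str] = None
    # loop-insertion bookkeeping (target N-part kept up to loop_start)
    loop_start: Optional[int] = None
    loop_end: Optional[int] = None
    # filled by planning
    register_map: dict = field(default_factory=dict)
    fusion_span: tuple[int, int] = (0, 0)      # fused numbering, inclusive
    junction_fused: int = 0                    # fused number of last donor residue
    disordered_segments: list = field(default_factory=list)
    # filled by build
    fused_model: Optional[Structure] = None
    donor_transform: Optional[tuple[np.ndarray, np.ndarray]] = None
    acceptor_transform: Optional[tuple[np.ndarray, np.ndarray]] = None
    superposition_rmsds: dict = field(default_factory=dict)

    def fused_number(self, component: str, seq_number: int) -> int:
        return self.register_map[(component, seq_number)]

    def original_residue(self, fused_number: int) -> tuple[str, int]:
        for key, num in self.register_map.items():
            if num == fused_number:
                return key
        raise KeyError(f"no component residue maps to fused number {fused_number}")

    def author_label(self, component: str, seq_number: int) -> int:
        """Author-style number: second (acceptor) component offset by +1000."""
        if component == "acceptor":
            return seq_number + ACCEPTOR_AUTHOR_OFFSET
        return seq_number

    @property
    def fusion_helix_length(self) -> int:
        return self.fusion_span[1] - self.fusion_span[0] + 1

    def fusion_helix_sequence(self) -> str:
        """Designed one-letter sequence of the fusion-helix span."""
        if self.fused_model is None:
            raise ValueError("design not built yet")
        chain = self.fused_model.chains[0]
        lo, hi = self.fusion_span
        return "".join(r.one_letter for r in chain.residues
                       if lo <= r.seq_number <= hi)

    def designed_sequence(self) -> str:
        """Full designed sequence including unmodelled flexible linkers."""
        if self.fused_model is None:
            raise ValueError("design not built yet")
        chain = self.fused_model.chains[0]
        by_num = {r.seq_number: r.one_letter for r in chain.residues}
        linker = {}
        for start, end, seq in self.disordered_segments:
            for k, aa in zip(range(start, end + 1), seq):
                linker[k] = aa
        nums = sorted(set(by_num) | set(linker))
        return "".join(by_num.get(n, linker.get(n, "")) for n in nums)


def _helix_chain(structure: Structure, helix: HelixSegment) -> Chain:
    return structure.chain(helix.chain_id)


def plan_terminal_fusion(donor: Structure, donor_helix: HelixSegment,
                         donor_junction: int,
                         acceptor: Structure, acceptor_helix: HelixSegment,
                         acceptor_junction: int,
                         n_insert: int = 0,
                         insert_sequence: Optional[str] = None) -> FusionDesign:
    """Plan a terminal fusion: donor residues ≤ donor_junction, then
    ``n_insert`` inserted residues, then acceptor residues ≥ acceptor_junction.

    Both junctions must lie inside their helices — the whole point is
    that the seam is helical on both sides.  Fused numbering is
    contiguous from 1; the register map records where every parent
    residue lands.
    """
    if n_insert < 0:
        raise ValueError("n_insert must be ≥ 0")
    if insert_sequence is None:
        insert_sequence = "A" * n_insert
    if len(insert_sequence) != n_insert:
        raise ValueError(f"insert_sequence length {len(insert_sequence)} != n_insert {n_insert}")
    if not donor_helix.start <= donor_junction <= donor_helix.end:
        raise ValueError(
            f"donor junction {donor_junction} outside donor helix "
            f"{donor_helix.start}–{donor_helix.end}"
        )
    if not acceptor_helix.start <= acceptor_junction <= acceptor_helix.end:
        raise ValueError(
            f"acceptor junction {acceptor_junction} outside acceptor helix "
            f"{acceptor_helix.start}–{acceptor_helix.end}"
        )
    design = FusionDesign(
        donor_structure=donor, donor_helix=donor_helix, donor_junction=donor_junction,
        acceptor_structure=acceptor, acceptor_helix=acceptor_helix,
        acceptor_junction=acceptor_junction,
        n_insert=n_insert, insert_sequence=insert_sequence, mode="terminal_fusion",
    )
    dchain = _helix_chain(donor, donor_helix)
    achain = _helix_chain(acceptor, acceptor_helix)
    donor_res = [r for r in dchain.residues if r.seq_number <= donor_junction]
    acceptor_res = [r for r in achain.residues if r.seq_number >= acceptor_junction]
    reg: dict = {}
    num = 0
    for r in donor_res:
        num += 1
        reg[("donor", r.seq_number)] = num
    design.junction_fused = num
    for k in range(n_insert):
        num += 1
        reg[("insert", k)] = num
    for r in acceptor_res:
        num += 1
        reg[("acceptor", r.seq_number)] = num
    design.register_map = reg
    design.fusion_span = (reg[("donor", donor_helix.start)],
                          reg[("acceptor", acceptor_helix.end)])
    return design


def plan_loop_insertion(target: Structure, loop_start: int, loop_end: int,
                        following_helix: HelixSegment,
                        adaptor: Structure, adaptor_cterm_helix: HelixSegment,
                        n_insert: int = 0,
                        flexible_linker: str = "GGGGS") -> FusionDesign:
    """Plan insertion of an adaptor domain into an internal loop.

    The rigid connection is built only on the helix-fusion side: the
    adaptor's C-terminal helix is merged with the target helix that
    follows the loop.  The N-side flexible linker is recorded in the
    designed sequence but its atoms are omitted and flagged disordered.
    """
    if loop_end - loop_start + 1 < 2:
        raise ValueError(f"loop {loop_start}–{loop_end} is shorter than 2 residues")
    if following_helix.start < loop_end:
        raise ValueError(
            f"following helix ({following_helix.start}–{following_helix.end}) must "
            f"begin at/after the loop end {loop_end}"
        )
    achain = _helix_chain(adaptor, adaptor_cterm_helix)
    if adaptor_cterm_helix.end != achain.residues[-1].seq_number:
        raise ValueError("adaptor helix must be the C-terminal helix of the adaptor")
    design = FusionDesign(
        donor_structure=adaptor, donor_helix=adaptor_cterm_helix,
        donor_junction=adaptor_cterm_helix.end,
        acceptor_structure=target, acceptor_helix=following_helix,
        acceptor_junction=following_helix.start,
        n_insert=n_insert, insert_sequence="A" * n_insert,
        mode="loop_insertion", flexible_linker=flexible_linker,
        loop_start=loop_start, loop_end=loop_end,
    )
    tchain = _helix_chain(target, following_helix)
    n_part = [r for r in tchain.residues if r.seq_number <= loop_start]
    adaptor_res = list(achain.residues)
    c_part = [r for r in tchain.residues if r.seq_number >= following_helix.start]
    reg: dict = {}
    num = 0
    for r in n_part:
        num += 1
        reg[("target_n", r.seq_number)] = num
    linker_span = (num + 1, num + len(flexible_linker))
    num += len(flexible_linker)
    design.disordered_segments.append((linker_span[0], linker_span[1], flexible_linker))
    for r in adaptor_res:
        num += 1
        reg[("donor", r.seq_number)] = num
    design.junction_fused = num
    for k in range(n_insert):
        num += 1
        reg[("insert", k)] = num
    for r in c_part:
        num += 1
        reg[("acceptor", r.seq_number)] = num
    design.register_map = reg
    design.fusion_span = (reg[("donor", adaptor_cterm_helix.start)],
                          reg[("acceptor", following_helix.end)])
    return design


_BACKBONE_FIT_ATOMS = ("N", "CA", "C")


def _backbone_coords(residues: Sequence[Residue]) -> np.ndarray:
    return np.array([r.atom(name).coord for r in residues for name in _BACKBONE_FIT_ATOMS])


def _renumbered(res: Residue, new_number: int, chain_id: str = "A") -> Residue:
    atoms = [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.b_factor, a.is_hetero)
             for a in res.atoms]
    return Residue(chain_id=chain_id, seq_number=new_number, res_name=res.res_name,
                   atoms=atoms, insertion_code="")


def build_fusion_model(design: FusionDesign,
                       params: Optional[IdealHelixParams] = None,
                       rmsd_threshold: float = 1.0) -> Structure:
    """Build the rigid chimeric model for a planned design.

    An ideal helix template spanning the full fusion helix is built;
    the donor helix backbone is superposed onto its N-terminal register
    and the acceptor helix onto its C-terminal register (offset by the
    donor contribution plus the insertion), and each whole parent is
    transformed rigidly.  Insert residues are taken verbatim from the
    template.  A superposition RMSD above ``rmsd_threshold`` means the
    parent helix is too distorted to splice and raises.
    """
    params = params or IdealHelixParams()
    dchain = _helix_chain(design.donor_structure, design.donor_helix)
    achain = _helix_chain(design.acceptor_structure, design.acceptor_helix)
    donor_span = [r for r in dchain.residues
                  if design.donor_helix.start <= r.seq_number <= design.donor_junction]
    acceptor_span = [r for r in achain.residues
                     if design.acceptor_junction <= r.seq_number <= design.acceptor_helix.end]
    if len(donor_span) < 5 or len(acceptor_span) < 5:
        raise ValueError(
            f"need ≥ 5 helix residues on each side of the seam "
            f"(donor {len(donor_span)}, acceptor {len(acceptor_span)})"
        )
    L_d, L_a = len(donor_span), len(acceptor_span)
    L = L_d + design.n_insert + L_a
    template_seq = ("A" * L_d) + (design.insert_sequence or "") + ("A" * L_a)
    template = build_ideal_helix(L, params, sequence=template_seq, mode="dihedral")
    tres = template.chains[0].residues

    sup_d = superpose(_backbone_coords(donor_span), _backbone_coords(tres[:L_d]))
    sup_a = superpose(_backbone_coords(acceptor_span),
                      _backbone_coords(tres[L_d + design.n_insert:]))
    design.superposition_rmsds = {"donor": sup_d.rmsd, "acceptor": sup_a.rmsd}
    for side, sup in (("donor", sup_d), ("acceptor", sup_a)):
        if sup.rmsd > rmsd_threshold:
            raise ValueError(
                f"{side} helix deviates from the ideal template by "
                f"{sup.rmsd:.2f} Å RMSD (> {rmsd_threshold} Å); not helical enough to splice"
            )
    donor_moved = design.donor_structure.transformed(sup_d.rotation, sup_d.translation)
    acceptor_moved = design.acceptor_structure.transformed(sup_a.rotation, sup_a.translation)
    design.donor_transform = (sup_d.rotation, sup_d.translation)
    design.acceptor_transform = (sup_a.rotation, sup_a.translation)

    dchain_m = donor_moved.chain(design.donor_helix.chain_id)
    achain_m = acceptor_moved.chain(design.acceptor_helix.chain_id)
    fused = Chain(id="A")
    for (component, orig), num in sorted(design.register_map.items(), key=lambda kv: kv[1]):
        if component in ("donor",):
            fused.residues.append(_renumbered(dchain_m.residue(orig), num))
        elif component in ("acceptor",):
            fused.residues.append(_renumbered(achain_m.residue(orig), num))
        elif component == "target_n":
            fused.residues.append(_renumbered(achain_m.residue(orig), num))
        elif component == "insert":
            fused.residues.append(_renumbered(tres[L_d + orig], num))
    fused.residues.sort(key=lambda r: r.seq_number)
    model = Structure(id=f"fusion_{design.donor_structure.id}_{design.acceptor_structure.id}",
                      chains=[fused],
                      metadata={"mode": design.mode, "n_insert": design.n_insert})
    design.fused_model = model
    return model


# ---------------------------------------------------------------------------
# clash detection

#: van der Waals radii (Å) by element symbol (Bondi-type values)
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "CL": 1.75, "F": 1.47, "BR": 1.85, "SE": 1.90}
_VDW_DEFAULT = 1.70
_SOFT_SLACK = 0.4  # subtracted from the vdW-radius sum for the soft cutoff


@dataclass
class ClashReport:
    pairs: list  # ((res_key_a, atom_a), (res_key_b, atom_b), distance)
    n_hard: int
    n_soft: int
    worst: Optional[float]

    @property
    def clash_free(self) -> bool:
        return self.n_hard == 0


def _select_atoms(model: Structure, selection) -> list[tuple[tuple, str, np.ndarray, float]]:
    """Resolve a selection to (residue key, atom name, coord, vdW radius)."""
    if callable(selection):
        pred = selection
    else:
        keys = set()
        for item in selection:
            if isinstance(item, tuple):
                keys.add(item)
            else:
                raise TypeError("selection items must be (chain_id, seq_number) tuples")
        pred = lambda r: (r.chain_id, r.seq_number) in keys  # noqa: E731
    out = []
    for r in model.iter_residues():
        if pred(r):
            for a in r.atoms:
                if a.element.upper() == "H":
                    continue
                rad = VDW_RADII.get(a.element.upper(), _VDW_DEFAULT)
                out.append(((r.chain_id, r.seq_number), a.name, a.coord, rad))
    return out


def detect_clashes(model: Structure, group_a, group_b,
                   soft_cutoff: Optional[float] = None,
                   hard_cutoff: float = 2.5) -> ClashReport:
    """Inter-group heavy-atom contacts below the cutoffs.

    ``soft_cutoff=None`` uses the per-pair vdW-radius sum minus 0.4 Å;
    a float applies one fixed soft cutoff to every pair.  Selections
    are sets of ``(chain_id, seq_number)`` keys or residue predicates,
    and must be disjoint.  A k-d tree prunes the pair search; counts
    equal the brute-force all-pairs result.
    """
    atoms_a = _select_atoms(model, group_a)
    atoms_b = _select_atoms(model, group_b)
    keys_a = {ra[0] for ra in atoms_a}
    keys_b = {rb[0] for rb in atoms_b}
    if keys_a & keys_b:
        raise ValueError(f"selections overlap on residues {sorted(keys_a & keys_b)[:5]}")
    max_soft = soft_cutoff if soft_cutoff is not None else (
        2 * max(VDW_RADII.values()) - _SOFT_SLACK)
    if hard_cutoff > max_soft:
        raise ValueError(f"hard cutoff {hard_cutoff} exceeds soft cutoff {max_soft}")
    pairs = []
    n_hard = 0
    worst = None
    if atoms_a and atoms_b:
        xa = np.array([c for _, _, c, _ in atoms_a])
        xb = np.array([c for _, _, c, _ in atoms_b])
        tree_b = cKDTree(xb)
        for ia, js in enumerate(cKDTree(xa).query_ball_tree(tree_b, r=max_soft)):
            ka, na, ca, rada = atoms_a[ia]
            for j in js:
                kb, nb, cb, radb = atoms_b[j]
                d = float(np.linalg.norm(ca - cb))
                soft = soft_cutoff if soft_cutoff is not None else rada + radb - _SOFT_SLACK
                if d < soft:
                    pairs.append(((ka, na), (kb, nb), d))
                    if d < hard_cutoff:
                        n_hard += 1
                    worst = d if worst is None else min(worst, d)
    pairs.sort(key=lambda p: p[2])
    return ClashReport(pairs=pairs, n_hard=n_hard, n_soft=len(pairs), worst=worst)


def _domain_selection(design: FusionDesign, component: str) -> set[tuple[str, int]]:
    """Fused-model residue keys of one parent domain outside the fusion helix."""
    lo, hi = design.fusion_span
    keys = set()
    comps = {"donor": ("donor",), "acceptor": ("acceptor", "target_n")}[component]
    for (comp, _), num in design.register_map.items():
        if comp in comps and not (lo <= num <= hi):
            keys.add(("A", num))
    return keys


@dataclass
class ScanEntry:
    n_insert: int
    n_hard: int
    n_soft: int
    worst: Optional[float]
    rotation_deg: float
    axis_translation: float
    clash_free: bool


def scan_insertions(base_design: FusionDesign, n_insert_range: Sequence[int],
                    params: Optional[IdealHelixParams] = None) -> list[ScanEntry]:
    """Build one model per insertion count; report clashes between the two
    domain bodies and the rotation of the acceptor relative to the base."""
    ns = sorted(set(int(n) for n in n_insert_range))
    if not ns:
        raise ValueError("empty insertion range")
    if any(n < 0 for n in ns):
        raise ValueError("insertion counts must be ≥ 0")
    designs = []
    for n in ns:
        d = plan_terminal_fusion(
            base_design.donor_structure, base_design.donor_helix,
            base_design.donor_junction,
            base_design.acceptor_structure, base_design.acceptor_helix,
            base_design.acceptor_junction, n_insert=n)
        build_fusion_model(d, params)
        designs.append(d)
    base = designs[0]
    entries = []
    for d in designs:
        rep = detect_clashes(d.fused_model, _domain_selection(d, "donor"),
                             _domain_selection(d, "acceptor"))
        delta = relative_orientation(base, d)
        entries.append(ScanEntry(
            n_insert=d.n_insert, n_hard=rep.n_hard, n_soft=rep.n_soft,
            worst=rep.worst, rotation_deg=delta.rotation_deg,
            axis_translation=delta.axis_translation, clash_free=rep.clash_free))
    return entries


# ---------------------------------------------------------------------------
# relative orientation


@dataclass
class OrientationDelta:
    """How the acceptor domain moves between two designs sharing a donor.

    ``rotation_deg`` is the signed rotation about the fusion-helix axis
    (N→C, right-hand rule), reported in [0, 360).  ``axis_translation``
    is the displacement of the acceptor junction Cα along that axis.
    ``centroid_displacement`` is the total (off-axis included) movement
    of the acceptor centroid — for large domains this can far exceed the
    axial rise, which is why both are reported.
    """

    rotation_deg: float
    axis_translation: float
    centroid_displacement: float


def _component_atom_coords(design: FusionDesign, comps: tuple[str, ...]
                           ) -> dict[tuple, np.ndarray]:
    model = design.fused_model
    chain = model.chains[0]
    by_num = {r.seq_number: r for r in chain.residues}
    out = {}
    for (comp, orig), num in design.register_map.items():
        if comp in comps and num in by_num:
            for a in by_num[num].atoms:
                out[(comp, orig, a.name)] = a.coord
    return out


def relative_orientation(design_a: FusionDesign, design_b: FusionDesign) -> OrientationDelta:
    """Rotation/translation of B's acceptor relative to A's, after
    superposing the shared donor domains.

    Both designs must be built and share the same donor component; the
    rotation is decomposed about the fusion-helix axis of design A.
    """
    for d in (design_a, design_b):
        if d.fused_model is None:
            raise ValueError("both designs must be built before comparing orientations")
    if (design_a.donor_structure.id != design_b.donor_structure.id
            or design_a.donor_junction != design_b.donor_junction):
        raise ValueError("designs must share the same donor component and junction")

    donor_a = _component_atom_coords(design_a, ("donor",))
    donor_b = _component_atom_coords(design_b, ("donor",))
    shared_d = sorted(set(donor_a) & set(donor_b))
    sup = superpose([donor_b[k] for k in shared_d], [donor_a[k] for k in shared_d])

    acc_a = _component_atom_coords(design_a, ("acceptor", "target_n"))
    acc_b = _component_atom_coords(design_b, ("acceptor", "target_n"))
    shared = sorted(set(acc_a) & set(acc_b))
    if len(shared) < 3:
        raise ValueError("acceptor components share too few atoms to compare")
    A = np.array([acc_a[k] for k in shared])
    B = sup.apply(np.array([acc_b[k] for k in shared]))
    rel = superpose(A, B)

    # fusion-helix axis of design A (N→C)
    lo, hi = design_a.fusion_span
    chain = design_a.fused_model.chains[0]
    span = [r for r in chain.residues if lo <= r.seq_number <= hi]
    axis = fit_helix_axis([r.ca.coord for r in span]).axis_direction

    rotvec = Rotation.from_matrix(rel.rotation).as_rotvec()
    angle = math.degrees(np.linalg.norm(rotvec))
    if angle < 1e-9:
        signed = 0.0
    else:
        signed = angle * math.copysign(1.0, float(np.dot(rotvec / np.linalg.norm(rotvec), axis)))
    rotation_deg = signed % 360.0

    # displacement of the acceptor junction Cα along the axis
    ja = acc_a.get(("acceptor", design_a.acceptor_junction, "CA"))
    jb = acc_b.get(("acceptor", design_b.acceptor_junction, "CA"))
    if ja is None or jb is None:
        axis_translation = 0.0
    else:
        axis_translation = float(np.dot(sup.rotation @ jb + sup.translation - ja, axis))
    centroid = float(np.linalg.norm(B.mean(axis=0) - A.mean(axis=0)))
    return OrientationDelta(rotation_deg=rotation_deg,
                            axis_translation=axis_translation,
                            centroid_displacement=centroid)
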