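"""Structural measurements on designed or solved fusion proteins, and
report rendering.

The measurements mirror how a crystallographer would judge whether a
designed fusion helix actually formed: the Cα–Cα distance of the staple
cysteines (~16.8 Å when the cross-linker is bound), the bend of the
fusion helix relative to ideal, its per-residue rise/twist, named
contact distances at the seam, and — for crystals with several
independent copies — whether the copies cluster into consistent groups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .helix_geometry import fit_helix_axis, helix_bend_angle, superpose
from .structure_io import Structure

__all__ = [
    "MeasurementReport",
    "residue_pair_distance",
    "measure_fusion_helix",
    "copy_rmsd_groups",
    "CopyGroups",
    "render_report",
]

_BACKBONE = {"N", "CA", "C", "O"}


@dataclass
class MeasurementReport:
    structure_id: str
    fusion_helix_span: Optional[tuple[int, int]] = None
    cys_ca_distance: Optional[float] = None
    bend_angle: Optional[float] = None
    rise: Optional[float] = None
    twist: Optional[float] = None
    fit_rmsd: Optional[float] = None
    named_distances: list = field(default_factory=list)
    copy_groups: Optional[dict] = None
    design_sequence: Optional[str] = None
    mutations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _resolve_selection(structure: Structure, sel: tuple) -> list:
    """(chain, residue, atom-name-or-mode) -> list of Atom."""
    chain_id, seq_number, atom = sel
    res = structure.chain(chain_id).residue(seq_number)
    if atom in ("min_sidechain_heavy", "sidechain"):
        atoms = [a for a in res.atoms if a.name not in _BACKBONE
                 and a.element.upper() != "H"]
    elif atom in ("min_any_heavy", "any"):
        atoms = [a for a in res.atoms if a.element.upper() != "H"]
    else:
        atoms = [a for a in res.atoms if a.name == atom]
    if not atoms:
        raise ValueError(
            f"selection {sel} resolves to no atoms; residue has "
            f"{[a.name for a in res.atoms]}"
        )
    return atoms


def residue_pair_distance(structure: Structure, sel_a: tuple, sel_b: tuple,
                          mode: str = "atom") -> tuple[float, tuple[str, str]]:
    """Distance (Å) between two selections, with the achieving atom pair.

    Selections are ``(chain_id, seq_number, atom_name)``; with
    ``mode="min_sidechain_heavy"`` or ``"min_any_heavy"`` the atom-name
    field is ignored and the minimum over the respective atom sets is
    returned.  Reporting the achieving pair keeps min-mode results
    inspectable when the intended atoms are not stated.
    """
    if mode != "atom":
        sel_a = (sel_a[0], sel_a[1], mode)
        sel_b = (sel_b[0], sel_b[1], mode)
    atoms_a = _resolve_selection(structure, sel_a)
    atoms_b = _resolve_selection(structure, sel_b)
    best = None
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.coord - b.coord))
            if best is None or d < best[0]:
                best = (d, (a.name, b.name))
    return best


def measure_fusion_helix(structure: Structure, helix_span: tuple[str, int, int],
                         cys_positions: Optional[tuple[int, int]] = None
                         ) -> MeasurementReport:
    """Measure the fusion helix of a model or crystal structure.

    ``helix_span`` is (chain_id, first_residue, last_residue); all span
    residues must have a Cα.  Reports the staple Cα–Cα distance (when
    cysteine positions are given), fitted rise/twist, cylinder fit RMSD
    and the bend angle between the two helix halves.
    """
    chain_id, lo, hi = helix_span
    chain = structure.chain(chain_id)
    span = [r for r in chain.residues if lo <= r.seq_number <= hi]
    if not span:
        raise ValueError(f"no residues in span {lo}–{hi} of chain {chain_id}")
    missing = [r.seq_number for r in span if not r.has_atom("CA")]
    if missing:
        raise ValueError(f"residues {missing} in the helix span lack Cα atoms")
    ca = np.array([r.ca.coord for r in span])
    fit = fit_helix_axis(ca)
    report = MeasurementReport(
        structure_id=structure.id,
        fusion_helix_span=(lo, hi),
        rise=fit.rise, twist=fit.twist, fit_rmsd=fit.fit_rmsd,
        bend_angle=helix_bend_angle(ca) if len(ca) >= 10 else None,
    )
    if cys_positions is not None:
        i, j = cys_positions
        d, _ = residue_pair_distance(structure, (chain_id, i, "CA"),
                                     (chain_id, j, "CA"))
        report.cys_ca_distance = d
    return report


# ---------------------------------------------------------------------------
# NCS copy grouping


@dataclass
class CopyGroups:
    copy_ids: list[str]
    rmsd_matrix: np.ndarray
    labels: list[int]                 # group index per copy, 1-based
    within_group_rmsd: Optional[float]
    cross_group_rmsd: Optional[float]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(set(self.labels))

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in zip(self.copy_ids, self.labels):
            out.setdefault(lab, []).append(cid)
        return out


def _copy_ca_arrays(structure: Structure, min_residues: int = 30,
                    min_identity: float = 0.9) -> tuple[dict, list[str]]:
    """Discover comparable copies: chains whose sequences are ≥ 90%
    identical to the first qualifying chain over the shared residue set."""
    chains = [c for c in structure.chains
              if sum(1 for r in c.residues if r.has_atom("CA")) >= min(min_residues, 3)]
    if not chains:
        return {}, []
    ref = chains[0]
    ref_seq = {r.seq_number: r.one_letter for r in ref.residues if r.has_atom("CA")}
    copies, excluded = {}, []
    for c in chains:
        seq = {r.seq_number: r.one_letter for r in c.residues if r.has_atom("CA")}
        shared = sorted(set(seq) & set(ref_seq))
        if len(shared) < 3:
            excluded.append(c.id)
            continue
        ident = sum(seq[n] == ref_seq[n] for n in shared) / len(shared)
        if ident < min_identity:
            excluded.append(c.id)
            continue
        copies[c.id] = {r.seq_number: r.ca.coord for r in c.residues if r.has_atom("CA")}
    return copies, excluded


def copy_rmsd_groups(structure: Structure, k_groups: Optional[int] = None,
                     threshold: float = 1.0, min_residues: int = 30
                     ) -> CopyGroups:
    """All-vs-all Cα RMSD of independent copies, single-linkage grouped.

    Copies are chains with near-identical sequences (≥ 90% over the
    shared numbering).  Each pair is superposed independently (Kabsch)
    over its shared Cα set.  Grouping cuts the single-linkage tree at
    ``threshold`` Å, or into exactly ``k_groups``.
    """
    copies, excluded = _copy_ca_arrays(structure, min_residues=min_residues)
    ids = sorted(copies)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need ≥ 2 comparable copies, found {n} (excluded: {excluded})")
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sorted(set(copies[ids[i]]) & set(copies[ids[j]]))
            if len(shared) < 3:
                M[i, j] = M[j, i] = np.nan
                continue
            A = np.array([copies[ids[i]][s] for s in shared])
            B = np.array([copies[ids[j]][s] for s in shared])
            M[i, j] = M[j, i] = superpose(B, A).rmsd
    condensed = squareform(M, checks=False)
    Z = linkage(condensed, method="single")
    if k_groups is not None:
        labels = fcluster(Z, t=k_groups, criterion="maxclust")
    else:
        labels = fcluster(Z, t=threshold, criterion="distance")
    labels = list(map(int, labels))
    within, cross = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else cross).append(M[i, j])
    return CopyGroups(
        copy_ids=ids, rmsd_matrix=M, labels=labels,
        within_group_rmsd=float(np.mean(within)) if within else None,
        cross_group_rmsd=float(np.mean(cross)) if cross else None,
        excluded=excluded)


# ---------------------------------------------------------------------------
# rendering


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def render_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a measurement report or design summary.

    JSON is lossless for the report fields; TSV flattens scalar fields;
    markdown is a human summary with the design sequence (mutated
    positions highlighted in brackets when mutations are present).
    """
    path = Path(path)
    if isinstance(report, MeasurementReport):
        data = report.to_dict()
    elif hasattr(report, "to_dict"):
        data = report.to_dict()
    elif isinstance(report, dict):
        data = dict(report)
    else:
        data = asdict(report)
    data = _jsonable(data)
    if format == "json":
        path.write_text(json.dumps(data, indent=1, allow_nan=True) + "\n")
    elif format == "tsv":
        scalars = {k: v for k, v in data.items()
                   if isinstance(v, (int, float, str, bool)) or v is None}
        lines = ["\t".join(scalars)] + [
            "\t".join("" if v is None else str(v) for v in scalars.values())]
        path.write_text("\n".join(lines) + "\n")
    elif format == "markdown":
        lines = [f"# Report: {data.get('structure_id', data.get('name', ''))}", ""]
        seq = data.get("design_sequence")
        if seq:
            muts = {m[0] for m in data.get("mutations", [])}
            if muts:
                span = data.get("fusion_helix_span") or (1, len(seq))
                marked = "".join(
                    f"[{aa}]" if (span[0] + k) in muts else aa
                    for k, aa in enumerate(seq))
                lines += [f"Design sequence: `{marked}`", ""]
            else:
                lines += [f"Design sequence: `{seq}`", ""]
        for k, v in data.items():
            if k in ("design_sequence",):
                continue
            if isinstance(v, (int, str, bool)) or v is None:
                lines.append(f"- **{k}**: {v}")
            elif isinstance(v, float):
                lines.append(f"- **{k}**: {v:.3f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}; expected json, tsv or markdown")


def load_report(path: str | Path) -> dict:
    """Read back a JSON report (inverse of :func:`render_report`)."""
    return json.loads(Path(path).read_text())
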