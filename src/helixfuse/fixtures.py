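"""Synthetic test structures: ideal/kinked helices and toy helical domains.

These generators stand in for real crystal structures so that every
geometric operation in the package can be exercised — and its parameter
recovery verified against known ground truth — without downloading
anything.  Each generator is deterministic given its spec and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .helix_geometry import (
    IdealHelixParams,
    build_ideal_helix,
    fit_helix_axis,
    ideal_cb,
)
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "make_ideal_helix",
    "make_kinked_helix",
    "make_two_helix_domain",
    "make_blocking_domain",
    "perturb",
]


@dataclass
class FixtureSpec:
    """Reproducible recipe for a synthetic structure."""

    kind: str  # ideal_helix | kinked_helix | two_helix_domain | blocking_domain
    n_residues: int = 20
    sequence: Optional[str] = None
    kink_angle_deg: float = 0.0
    kink_position: int = 10
    helix_lengths: tuple[int, int] = (12, 12)
    packing_angle_deg: float = 180.0
    offset: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def make_fixture(spec: FixtureSpec) -> Structure:
    if spec.kind == "ideal_helix":
        st = make_ideal_helix(spec.n_residues, sequence=spec.sequence)
    elif spec.kind == "kinked_helix":
        st = make_kinked_helix(spec.n_residues, spec.kink_angle_deg,
                               spec.kink_position, noise_sigma=0.0, seed=spec.seed)
    elif spec.kind == "two_helix_domain":
        st = make_two_helix_domain(spec.helix_lengths, spec.packing_angle_deg,
                                   spec.offset, seed=spec.seed)
    elif spec.kind == "blocking_domain":
        st = make_blocking_domain(seed=spec.seed)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.noise_sigma > 0:
        st = perturb(st, spec.noise_sigma, spec.seed)
    return st


def make_ideal_helix(n: int, sequence: Optional[str] = None,
                     params: Optional[IdealHelixParams] = None) -> Structure:
    """Plain ideal helix (thin wrapper kept for fixture-spec symmetry)."""
    return build_ideal_helix(n, params, sequence=sequence, mode="dihedral")


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)


def make_kinked_helix(n: int, kink_angle_deg: float, kink_position: int,
                      params: Optional[IdealHelixParams] = None,
                      noise_sigma: float = 0.0, seed: int = 0) -> Structure:
    """Ideal helix with its second half rotated by ``kink_angle_deg`` about
    an axis perpendicular to the first half's axis, hinged at the Cα of the
    (0-based) ``kink_position`` residue."""
    if not 0 <= kink_angle_deg < 90:
        raise ValueError(f"kink angle {kink_angle_deg} outside [0, 90)")
    if not 5 <= kink_position <= n - 5:
        raise ValueError(f"kink position {kink_position} must leave ≥ 5 residues per half")
    st = build_ideal_helix(n, params, mode="dihedral")
    chain = st.chains[0]
    ca = np.array([r.ca.coord for r in chain.residues])
    axis1 = fit_helix_axis(ca[:kink_position + 1]).axis_direction
    # a perpendicular hinge axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis1)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    hinge = np.cross(axis1, ref)
    hinge /= np.linalg.norm(hinge)
    R = _rotation_about(hinge, kink_angle_deg)
    pivot = ca[kink_position]
    for r in chain.residues:
        if r.seq_number - 1 > kink_position:  # seq numbers are 1-based
            for a in r.atoms:
                a.coord = R @ (a.coord - pivot) + pivot
    st.id = f"kinked_helix_{kink_angle_deg:g}"
    if noise_sigma > 0:
        st = perturb(st, noise_sigma, seed)
    return st


def _loop_trace(start_c: np.ndarray, end_n: np.ndarray, n_res: int,
                bow: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Geometric (non-helical) connecting loop: Cα on a bowed path between
    two anchors, N/C/O placed at small offsets along the path."""
    out = []
    for k in range(n_res):
        t0 = (k + 1) / (n_res + 1)
        base = (1 - t0) * start_c + t0 * end_n + bow * math.sin(math.pi * t0)
        step = (end_n - start_c) / (n_res + 1)
        ca = base
        nn = base - 0.38 * step
        cc = base + 0.38 * step
        oo = cc + np.array([0.0, 0.0, 1.23])
        out.append({"N": nn, "CA": ca, "C": cc, "O": oo})
    return out


def make_two_helix_domain(helix_lengths: tuple[int, int] = (12, 12),
                          packing_angle_deg: float = 180.0,
                          offset: float = 10.0, seed: int = 0,
                          params: Optional[IdealHelixParams] = None,
                          chain_id: str = "A",
                          sequence: Optional[str] = None) -> Structure:
    """Toy helical domain: two ideal helices packed at ``packing_angle_deg``
    (default antiparallel) and ``offset`` Å apart, joined by a 3-residue
    geometric loop.  The C-terminal helix is exposed for fusion.

    The chain is poly-Ala unless ``sequence`` (length = n1 + 3 + n2) is
    given.  The construction is validated by the package's own
    detectors: exactly two helical segments and no internal hard
    clashes at the default packing.
    """
    n1, n2 = helix_lengths
    if n1 < 8 or n2 < 8:
        raise ValueError("each helix needs ≥ 8 residues")
    if offset < 6.0:
        raise ValueError(f"offset {offset} Å would clash the helices")
    n_loop = 3
    total = n1 + n_loop + n2
    if sequence is not None and len(sequence) != total:
        raise ValueError(f"sequence length {len(sequence)} != {total} (n1+3+n2)")
    seq = sequence or "A" * total

    h1 = build_ideal_helix(n1, params, sequence=seq[:n1], mode="dihedral")
    h2 = build_ideal_helix(n2, params, sequence=seq[n1 + n_loop:], mode="dihedral")

    # place helix 1 with its axis along +z starting at the origin
    def aligned(st: Structure) -> Structure:
        ca = np.array([r.ca.coord for r in st.chains[0].residues])
        fit = fit_helix_axis(ca)
        z = fit.axis_direction
        x = np.array([1.0, 0.0, 0.0])
        x = x - np.dot(x, z) * z
        if np.linalg.norm(x) < 1e-6:
            x = np.array([0.0, 1.0, 0.0]) - np.dot(np.array([0.0, 1.0, 0.0]), z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        R = np.vstack([x, y, z])  # world -> helix frame
        t = -R @ fit.axis_point
        return st.transformed(R, t)

    h1 = aligned(h1)
    h2 = aligned(h2)
    # helix 2: rotate by the packing angle about x (180° → antiparallel),
    # shift sideways by the offset, and slide so its N terminus sits near
    # the top (C-terminal end) of helix 1
    Rp = _rotation_about(np.array([1.0, 0.0, 0.0]), packing_angle_deg)
    z1_top = max(r.ca.coord[2] for r in h1.chains[0].residues)
    h2 = h2.transformed(Rp, np.array([offset, 0.0, 0.0]))
    z2_start = h2.chains[0].residues[0].ca.coord[2]
    h2 = h2.transformed(np.eye(3), np.array([0.0, 0.0, z1_top - z2_start]))

    chain = Chain(id=chain_id)
    num = 0
    for r in h1.chains[0].residues:
        num += 1
        chain.residues.append(Residue(chain_id, num, r.res_name,
                                      [Atom(a.name, a.element, a.coord.copy())
                                       for a in r.atoms]))
    start_c = h1.chains[0].residues[-1].atom("C").coord
    end_n = h2.chains[0].residues[0].atom("N").coord
    bow = np.array([offset / 2, 4.0, 3.0])
    for k, atoms in enumerate(_loop_trace(start_c, end_n, n_loop, bow)):
        num += 1
        aa = seq[n1 + k]
        alist = [Atom(n, "N" if n == "N" else ("O" if n == "O" else "C"), atoms[n])
                 for n in ("N", "CA", "C", "O")]
        if aa != "G":
            alist.append(Atom("CB", "C", ideal_cb(atoms["N"], atoms["CA"], atoms["C"])))
        from .structure_io import one_to_three
        chain.residues.append(Residue(chain_id, num, one_to_three(aa), alist))
    for r in h2.chains[0].residues:
        num += 1
        chain.residues.append(Residue(chain_id, num, r.res_name,
                                      [Atom(a.name, a.element, a.coord.copy())
                                       for a in r.atoms]))
    return Structure(id="two_helix_domain", chains=[chain],
                     metadata={"helix_lengths": (n1, n2), "loop": n_loop,
                               "packing_angle_deg": packing_angle_deg,
                               "offset": offset})


def make_blocking_domain(center: np.ndarray | None = None, n_atoms: int = 60,
                         radius: float = 4.0, seed: int = 0,
                         chain_id: str = "Z") -> Structure:
    """A dense pseudo-atom ball used to bury a position in exposure tests."""
    rng = np.random.default_rng(seed)
    center = np.zeros(3) if center is None else np.asarray(center, float)
    pts = center + rng.normal(scale=radius / 2, size=(n_atoms, 3))
    res = Residue(chain_id, 1, "UNK",
                  [Atom(f"X{i}", "C", p, is_hetero=True) for i, p in enumerate(pts)])
    return Structure(id="blocking_domain", chains=[Chain(chain_id, [res])])


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add i.i.d. Gaussian displacement (std ``sigma`` Å per coordinate)."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    out = structure.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, a in out.iter_atoms():
        a.coord = a.coord + rng.normal(scale=sigma, size=3)
    return out


def write_fixture_set(specs: list[FixtureSpec], out_dir: str | Path) -> Path:
    """Emit PDB files plus a JSON manifest of true parameters."""
    from .structure_io import write_structure
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, spec in enumerate(specs):
        st = make_fixture(spec)
        name = f"{spec.kind}_{i:02d}.pdb"
        write_structure(st, out_dir / name, format="pdb")
        manifest.append({"file": name, **asdict(spec)})
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
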