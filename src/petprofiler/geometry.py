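"""Backbone dihedral geometry: phi/psi/omega profiling and reconstruction.

The two engines here are inverses of each other:

* :func:`backbone_torsions` reads phi/psi/omega off a structure's backbone
  coordinates (the primitive underlying Ramachandran-space comparison of
  homologous enzymes), and
* :func:`build_backbone` rebuilds N/CA/C coordinates from a torsion list by
  sequential internal-coordinate (natural-extension-reference-frame) placement
  with idealized bond lengths and angles.

The round trip ``backbone_torsions(build_backbone(T)) == T`` (interior
residues, ~1e-6 degrees) is the package's core geometric invariant and the
oracle behind the synthetic-structure generators.

Angles are degrees in (-180, 180] everywhere. Sign convention: the dihedral
p1-p2-p3-p4 is the angle by which the p1-p2 bond must rotate about p2-p3 to
eclipse p3-p4, clockwise positive viewed from p2 towards p3 (IUPAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from petprofiler.structure_io import AtomRecord, Residue, Structure

__all__ = [
    "TorsionEntry", "TorsionProfile", "BackboneGeometryParams",
    "dihedral", "backbone_torsions", "build_backbone", "wrap_angle",
    "UndefinedDihedralError",
]

#: cross-product norm below this fraction of the segment-norm product means
#: three points are collinear and the dihedral is undefined
COLLINEARITY_TOL = 1e-9


class UndefinedDihedralError(ValueError):
    """Three consecutive points are (numerically) collinear."""


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Map angle(s) in degrees onto (-180, 180]."""
    wrapped = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    if np.ndim(a) == 0:
        return float(wrapped)
    return wrapped


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if (np.linalg.norm(n1) < COLLINEARITY_TOL * np.linalg.norm(b1) * np.linalg.norm(b2)
            or np.linalg.norm(n2) < COLLINEARITY_TOL * np.linalg.norm(b2) * np.linalg.norm(b3)):
        raise UndefinedDihedralError("collinear points: dihedral undefined")
    b2n = np.linalg.norm(b2)
    if b2n == 0.0:
        raise UndefinedDihedralError("coincident central points: dihedral undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    return wrap_angle(math.degrees(math.atan2(y, x)))


@dataclass
class TorsionEntry:
    key: tuple[int, str]          # (author_number, insertion_code)
    name3: str = "UNK"
    phi: float | None = None
    psi: float | None = None
    omega: float | None = None


@dataclass
class TorsionProfile:
    """Ordered per-residue (phi, psi, omega) for one chain.

    phi is undefined at each chain/break start; psi and omega at each
    chain/break end; any angle is undefined when a constituent atom is
    missing.
    """

    chain_id: str
    entries: list[TorsionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_position(self, pos: int) -> TorsionEntry:
        """Entry at 1-based residue position in the chain."""
        return self.entries[pos - 1]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chain\tresnum\ticode\tname\tphi\tpsi\tomega\n")
            for e in self.entries:
                fmt = lambda v: "" if v is None else f"{v:.4f}"
                fh.write(
                    f"{self.chain_id}\t{e.key[0]}\t{e.key[1]}\t{e.name3}\t"
                    f"{fmt(e.phi)}\t{fmt(e.psi)}\t{fmt(e.omega)}\n"
                )


@dataclass
class BackboneGeometryParams:
    """Idealized backbone internal coordinates for synthetic builds.

    Defaults are standard small-molecule-library (Engh/Huber-like) values.
    Lengths in Angstrom, angles in degrees.
    """

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n"):
            v = getattr(self, name)
            if not 1.0 < v < 2.0:
                raise ValueError(f"bond length {name}={v} outside (1.0, 2.0) A")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca"):
            v = getattr(self, name)
            if not 90.0 < v < 150.0:
                raise ValueError(f"bond angle {name}={v} outside (90, 150) deg")


def _safe_dihedral(*points) -> float | None:
    if any(p is None for p in points):
        return None
    try:
        return dihedral(*points)
    except UndefinedDihedralError:
        return None


def backbone_torsions(s: Structure, chain_id: str) -> TorsionProfile:
    """Compute phi/psi/omega for every residue of a chain.

    phi(i) = dihedral(C(i-1), N(i), CA(i), C(i));
    psi(i) = dihedral(N(i), CA(i), C(i), N(i+1));
    omega(i) = dihedral(CA(i), C(i), N(i+1), CA(i+1)).
    An angle is undefined where an atom is missing or where a flagged chain
    break intervenes between the residues it spans.
    """
    residues = s.chain(chain_id)
    profile = TorsionProfile(chain_id=chain_id)
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        if prev_res is not None and prev_res.chain_break_after:
            prev_res = None
        if res.chain_break_after:
            next_res = None
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        phi = psi = omega = None
        if prev_res is not None:
            phi = _safe_dihedral(prev_res.coord("C"), n, ca, c)
        if next_res is not None:
            psi = _safe_dihedral(n, ca, c, next_res.coord("N"))
            omega = _safe_dihedral(ca, c, next_res.coord("N"), next_res.coord("CA"))
        profile.entries.append(
            TorsionEntry(key=res.key, name3=res.name3, phi=phi, psi=psi, omega=omega)
        )
    return profile


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A, B, C given C-D bond, B-C-D angle, A-B-C-D torsion."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise UndefinedDihedralError("collinear reference atoms: cannot place atom")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    torsions: Sequence[tuple[float | None, float | None, float | None]],
    params: BackboneGeometryParams | None = None,
    chain_id: str = "A",
    structure_id: str = "synthetic",
    first_residue_number: int = 1,
) -> Structure:
    """Build an N/CA/C backbone from per-residue (phi, psi, omega) torsions.

    The first three atoms sit in a canonical frame: N at the origin, CA on +x,
    C in the xy-plane. Each subsequent atom is placed from the previous three
    by its ideal bond length, bond angle and the supplied torsion. Unused
    boundary torsions (phi of the first residue, psi/omega of the last) may be
    ``None``.
    """
    params = params or BackboneGeometryParams()
    n_res = len(torsions)
    if n_res < 2:
        raise ValueError("need at least 2 residues to build a backbone")

    coords: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = np.array([params.n_ca, 0.0, 0.0])
    theta = math.radians(params.ang_n_ca_c)
    c0 = ca0 + params.ca_c * np.array([-math.cos(theta), math.sin(theta), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        psi_prev = torsions[i - 1][1]
        omega_prev = torsions[i - 1][2]
        phi_i = torsions[i][0]
        if psi_prev is None or omega_prev is None or phi_i is None:
            raise ValueError(
                f"torsions spanning residues {i - 1}-{i} must be defined "
                "(only terminal boundary angles may be None)"
            )
        prev = coords[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          params.c_n, params.ang_ca_c_n, psi_prev)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           params.n_ca, params.ang_c_n_ca, omega_prev)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          params.ca_c, params.ang_n_ca_c, phi_i)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues = [
        Residue(
            author_number=first_residue_number + i,
            name3="ALA",
            backbone={label: AtomRecord(name=label, coords=xyz)
                      for label, xyz in atom_map.items()},
        )
        for i, atom_map in enumerate(coords)
    ]
    return Structure(
        id=structure_id,
        chains=[(chain_id, residues)],
        metadata={"source": "build_backbone"},
    )
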