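"""Conformational parameters of RNA backbones and sugars.

All angles are reported in degrees on the half-open interval (-180, 180]
(pseudorotation phase on [0, 360)), following the usual crystallographic
convention, with the IUPAC sign rule: looking from the second towards the
third atom, a clockwise rotation of the far bond is positive.

Besides the six backbone torsions alpha..zeta and the glycosidic angle chi,
the module computes the pseudotorsions eta and theta, which reduce each
residue's backbone to the two atoms P and C4' of consecutive residues:

    eta(n)   = C4'(n-1) - P(n)   - C4'(n) - P(n+1)
    theta(n) = P(n)     - C4'(n) - P(n+1) - C4'(n+1)

and Altona-Sundaralingam sugar-pucker parameters (phase P, amplitude) from
the five ribose ring torsions nu0..nu4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "TorsionProfile",
    "dihedral",
    "backbone_torsions",
    "pseudotorsions",
    "sugar_pucker",
    "torsion_table",
]

PURINES = {"A", "G"}


@dataclass
class TorsionProfile:
    """Per-residue conformational parameters; ``None`` marks undefined values."""

    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None
    eta: float | None = None
    theta: float | None = None
    pucker_phase: float | None = None
    pucker_amplitude: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _wrap(deg: float) -> float:
    """Map an angle in degrees onto (-180, 180]."""
    deg = math.fmod(deg, 360.0)
    if deg <= -180.0:
        deg += 360.0
    elif deg > 180.0:
        deg -= 360.0
    return deg


def dihedral(p1, p2, p3, p4) -> float | None:
    """Torsion angle of four points, degrees in (-180, 180].

    Returns ``None`` for degenerate geometry (coincident consecutive points or
    three collinear consecutive points).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    x = float(np.dot(n1, n2))
    return _wrap(math.degrees(math.atan2(y, x)))


def _atoms(residue, *names):
    """Fetch named atom coordinates, or None when any is absent."""
    if residue is None:
        return None
    out = []
    for n in names:
        c = residue.atoms.get(n)
        if c is None:
            return None
        out.append(c)
    return out


def _dihedral_of(*groups) -> float | None:
    pts = []
    for g in groups:
        if g is None:
            return None
        pts.extend(g)
    return dihedral(*pts)


def backbone_torsions(residues, i: int) -> TorsionProfile:
    """Backbone torsions alpha..zeta and glycosidic chi of ``residues[i]``.

    ``residues`` is an ordered 5'->3' strand (objects with an ``atoms`` mapping
    and a ``parent`` letter); neighbours beyond the strand, or lacking the
    required atoms, yield ``None`` for the torsions that need them.
    """
    res = residues[i]
    prev = residues[i - 1] if i > 0 else None
    nxt = residues[i + 1] if i + 1 < len(residues) else None

    prof = TorsionProfile()
    prof.alpha = _dihedral_of(_atoms(prev, "O3'"), _atoms(res, "P", "O5'", "C5'"))
    prof.beta = _dihedral_of(_atoms(res, "P", "O5'", "C5'", "C4'"))
    prof.gamma = _dihedral_of(_atoms(res, "O5'", "C5'", "C4'", "C3'"))
    prof.delta = _dihedral_of(_atoms(res, "C5'", "C4'", "C3'", "O3'"))
    prof.epsilon = _dihedral_of(_atoms(res, "C4'", "C3'", "O3'"), _atoms(nxt, "P"))
    prof.zeta = _dihedral_of(_atoms(res, "C3'", "O3'"), _atoms(nxt, "P", "O5'"))
    if getattr(res, "parent", None) in PURINES or "N9" in res.atoms:
        prof.chi = _dihedral_of(_atoms(res, "O4'", "C1'", "N9", "C4"))
    else:
        prof.chi = _dihedral_of(_atoms(res, "O4'", "C1'", "N1", "C2"))
    return prof


def pseudotorsions(residues) -> list[tuple[float | None, float | None]]:
    """Per-residue (eta, theta) pseudotorsions along a 5'->3' strand.

    Values are ``None`` at strand termini and wherever a defining P or C4'
    atom (including on a neighbouring residue) is absent.
    """
    out: list[tuple[float | None, float | None]] = []
    for i in range(len(residues)):
        prev = residues[i - 1] if i > 0 else None
        res = residues[i]
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        eta = _dihedral_of(
            _atoms(prev, "C4'"), _atoms(res, "P", "C4'"), _atoms(nxt, "P")
        )
        theta = _dihedral_of(
            _atoms(res, "P", "C4'"), _atoms(nxt, "P", "C4'")
        )
        out.append((eta, theta))
    return out


_NU_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
]

_AS_DENOM = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))


def sugar_pucker(residue) -> tuple[float | None, float | None]:
    """Altona-Sundaralingam pseudorotation ``(phase P, amplitude)`` in degrees.

    ``tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))`` with
    ``amplitude = nu2 / cos P``; P is shifted into [0, 360).  A planar ring
    returns ``(None, 0.0)``; a ring with missing atoms ``(None, None)``.
    """
    nus = []
    for quad in _NU_ATOMS:
        pts = _atoms(residue, *quad)
        if pts is None:
            return None, None
        nu = dihedral(*pts)
        if nu is None:
            return None, None
        nus.append(nu)
    nu0, nu1, nu2, nu3, nu4 = nus
    num = (nu4 + nu1) - (nu3 + nu0)
    den = nu2 * _AS_DENOM
    if abs(num) < 1e-6 and abs(den) < 1e-6:
        return None, 0.0
    p = math.degrees(math.atan2(num, den))
    amplitude = nu2 / math.cos(math.radians(p))
    return p % 360.0, amplitude


def torsion_table(residues) -> list[TorsionProfile]:
    """Full conformational profile for every residue of a 5'->3' strand."""
    profiles = [backbone_torsions(residues, i) for i in range(len(residues))]
    for prof, (eta, theta), res in zip(profiles, pseudotorsions(residues), residues):
        prof.eta, prof.theta = eta, theta
        prof.pucker_phase, prof.pucker_amplitude = sugar_pucker(res)
    return profiles
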