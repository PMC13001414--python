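"""Backbone geometry: torsion angles and internal-coordinate chain building.

Torsions follow the IUPAC convention (right-handed; a planar trans
arrangement is 180 deg, planar cis is 0 deg). Chains are realised from
(phi, psi, omega) by sequential natural-extension-reference-frame (NeRF)
placement using fixed ideal bond lengths and angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BackboneGeometry",
    "IDEAL_GEOMETRY",
    "dihedral",
    "place_atom",
    "build_backbone",
    "wrap_angle",
]


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone bond lengths (A) and angles (deg) for chain building."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5

    def __post_init__(self):
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


IDEAL_GEOMETRY = BackboneGeometry()

# Terminal torsions a DihedralSeries does not carry (psi of residue 1, phi of
# residue L) are fixed to extended-region values when building coordinates.
TERMINAL_PSI1 = 150.0
TERMINAL_PHI_L = -135.0


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed torsion angle(s) in degrees for points of shape (..., 3).

    Uses the numerically stable projection/atan2 formulation; returns values
    in (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |c-d| = bond, angle(b,c,d) = angle,
    torsion(a,b,c,d) = torsion."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


# Fixed-coefficient ideal CB reconstruction from backbone N, CA, C
# (tetrahedral L-configuration; CA-CB ~ 1.53 A).
_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def pseudo_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry CB position from backbone atoms of one residue."""
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    ka, kb, kc = _CB_COEFF
    return ca + ka * a + kb * b + kc * cvec


def build_backbone(
    phi: np.ndarray,
    psi: np.ndarray,
    omega: float | np.ndarray = 180.0,
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
) -> dict[str, np.ndarray]:
    """Build backbone coordinates for an L-residue chain from torsions.

    Parameters
    ----------
    phi, psi
        Length-L arrays in degrees. ``phi[0]`` is geometrically unused
        (no preceding carbonyl); NaN entries for ``psi[0]`` / ``phi[-1]``
        are replaced with fixed extended-region defaults.
    omega
        Peptide-bond torsion, scalar or length-(L-1) array; 180 = trans.

    Returns
    -------
    dict with arrays ``N``, ``CA``, ``C``, ``O`` of shape (L, 3).
    """
    phi = np.array(phi, dtype=float)
    psi = np.array(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1:
        raise ValueError("phi and psi must be 1-D arrays of equal length")
    L = len(phi)
    if L < 2:
        raise ValueError("need at least 2 residues")
    phi[0] = 0.0  # unused
    if np.isnan(psi[0]):
        psi[0] = TERMINAL_PSI1
    if np.isnan(phi[-1]):
        phi[-1] = TERMINAL_PHI_L
    if not (np.isfinite(phi).all() and np.isfinite(psi[:-1]).all()):
        raise ValueError("non-finite dihedral angle")
    omega = np.broadcast_to(np.asarray(omega, dtype=float), (L - 1,))

    g = geometry
    N = np.empty((L, 3))
    CA = np.empty((L, 3))
    C = np.empty((L, 3))
    O = np.empty((L, 3))

    # First residue in a canonical frame.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (g.bond_n_ca, 0.0, 0.0)
    th = np.radians(g.angle_n_ca_c)
    C[0] = CA[0] + g.bond_ca_c * np.array([-np.cos(th), np.sin(th), 0.0])

    for i in range(L - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], g.bond_c_n, g.angle_ca_c_n, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], g.bond_n_ca, g.angle_c_n_ca, omega[i])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], g.bond_ca_c, g.angle_n_ca_c, phi[i + 1])

    # Carbonyl oxygens: in the peptide plane, anti to the next amide nitrogen.
    psi_for_o = psi.copy()
    if np.isnan(psi_for_o[-1]):
        psi_for_o[-1] = TERMINAL_PSI1
    for i in range(L):
        O[i] = place_atom(
            N[i], CA[i], C[i], g.bond_c_o, g.angle_ca_c_o, wrap_angle(psi_for_o[i] + 180.0)
        )
    return {"N": N, "CA": CA, "C": C, "O": O}


def backbone_dihedrals(N: np.ndarray, CA: np.ndarray, C: np.ndarray):
    """(phi, psi) in degrees for residues of one conformation.

    phi[0] and psi[-1] are NaN (undefined at the termini). Accepts arrays of
    shape (L, 3) or batched (..., L, 3).
    """
    phi = np.full(N.shape[:-1], np.nan)
    psi = np.full(N.shape[:-1], np.nan)
    phi[..., 1:] = dihedral(C[..., :-1, :], N[..., 1:, :], CA[..., 1:, :], C[..., 1:, :])
    psi[..., :-1] = dihedral(N[..., :-1, :], CA[..., :-1, :], C[..., :-1, :], N[..., 1:, :])
    return phi, psi
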