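"""Per-frame compactness observables and replica-structured summaries.

Radius of gyration, CA-CA end-to-end distance, and Shrake-Rupley solvent
accessible surface area, with ensemble summaries computed replica-first:
replica means, then the grand mean and spread across replica means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ATOMIC_MASSES",
    "BONDI_RADII",
    "radius_of_gyration",
    "end_to_end_distance",
    "sasa_shrake_rupley",
    "compactness_table",
    "EnsembleSummary",
    "summarize_by_replica",
]

#: Standard atomic masses (u) for the elements the generator produces.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

#: Bondi van der Waals radii (A).
BONDI_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration (A) of one conformation.

    ``masses=None`` uses unit weights.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n_atoms, 3) array")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    if (masses <= 0).any():
        raise ValueError("masses must be positive")
    center = np.average(coords, axis=0, weights=masses)
    sq = np.sum((coords - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def end_to_end_distance(ca_coords: np.ndarray) -> float:
    """Distance (A) between the first and last CA of one conformation."""
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[0] < 2:
        raise ValueError("need CA coordinates of >= 2 residues")
    return float(np.linalg.norm(ca[-1] - ca[0]))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic spiral (golden-angle) lattice of n points on the unit
    sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa_shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> float:
    """Shrake-Rupley solvent accessible surface area (A^2).

    Each atom is expanded by the probe radius and covered with a
    deterministic spiral lattice of test points; points inside any
    neighbour's expanded sphere are buried. SASA is the exposed point
    fraction times the expanded-sphere area, summed over atoms.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    if probe < 0:
        raise ValueError("probe must be non-negative")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32 (accuracy floor)")
    n_atoms = coords.shape[0]
    expanded = radii + probe
    unit = _sphere_points(n_sphere_points)
    # neighbour lists from pairwise distances
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    total = 0.0
    for i in range(n_atoms):
        cutoff = expanded[i] + expanded
        neigh = np.where((d[i] < cutoff) & (np.arange(n_atoms) != i))[0]
        pts = coords[i] + expanded[i] * unit
        exposed = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= dj >= expanded[j]
            if not exposed.any():
                break
        total += exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return float(total)


def compactness_table(
    ensemble,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    sasa: bool = True,
    sasa_stride: int = 1,
    mass_weighted: bool = True,
) -> pd.DataFrame:
    """Per-frame Rg, end-to-end and (optionally strided) SASA for an
    Ensemble.

    Returns a tidy table (variant, replica, frame, rg, ree, sasa); SASA is
    NaN on frames skipped by ``sasa_stride``.
    """
    masses = (
        np.array([ATOMIC_MASSES[e] for e in ensemble.atom_elements])
        if mass_weighted
        else None
    )
    radii = np.array([BONDI_RADII[e] for e in ensemble.atom_elements])
    ca = ensemble.backbone_coords("CA")
    rows = []
    for f in range(ensemble.n_frames):
        frame = ensemble.xyz[f]
        s = np.nan
        if sasa and f % sasa_stride == 0:
            s = sasa_shrake_rupley(frame, radii, probe, n_sphere_points)
        rows.append(
            (
                ensemble.variant_label,
                int(ensemble.replica_ids[f]),
                f,
                radius_of_gyration(frame, masses),
                end_to_end_distance(ca[f]),
                s,
            )
        )
    return pd.DataFrame(rows, columns=["variant", "replica", "frame", "rg", "ree", "sasa"])


@dataclass
class EnsembleSummary:
    """Replica-first summary of one metric across an ensemble."""

    metric: str
    replica_means: dict[int, float]
    grand_mean: float
    std: float  # std of replica means (ddof=1)
    sem: float  # std / sqrt(n_replicas)


def summarize_by_replica(
    table: pd.DataFrame, metrics: tuple[str, ...] = ("rg", "ree", "sasa")
) -> dict[str, EnsembleSummary]:
    """Replica means first, then grand mean and spread across replica means.

    Empty replicas (all-NaN for a metric) are skipped with a warning.
    """
    if "replica" not in table.columns:
        raise ValueError("table must carry a 'replica' column")
    out = {}
    for metric in metrics:
        if metric not in table.columns:
            continue
        means = {}
        for rep, sub in table.groupby("replica"):
            vals = sub[metric].dropna()
            if vals.empty:
                logger.warning("replica %s has no %s values; skipped", rep, metric)
                continue
            means[int(rep)] = float(vals.mean())
        if not means:
            raise ValueError(f"no replica has values for metric {metric!r}")
        vals = np.array(list(means.values()))
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[metric] = EnsembleSummary(
            metric=metric,
            replica_means=means,
            grand_mean=float(vals.mean()),
            std=std,
            sem=std / np.sqrt(len(vals)),
        )
    return out
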