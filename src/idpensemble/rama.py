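"""Ramachandran-region classification and per-residue occupancy statistics.

Each interior residue of each frame is assigned to one of five secondary
structure motifs — right-handed alpha helix (alphaR), left-handed alpha
helix (alphaL), beta sheet, polyproline II helix (PPII), or unassigned —
from its backbone (phi, psi) pair. Occupancies (fractions of frames spent
in each motif) are computed per replica, averaged across replicas, and
compared between variants as deviation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import backbone_dihedrals, wrap_angle

__all__ = [
    "CLASSES",
    "RegionMap",
    "DEFAULT_REGION_MAP",
    "DihedralSeries",
    "OccupancyProfile",
    "AveragedProfile",
    "DeviationProfile",
    "classify",
    "compute_dihedrals",
    "occupancy",
    "average_profiles",
    "deviation_profile",
    "profiles_to_frame",
]

#: Fixed class order used by every occupancy array in the package.
CLASSES = ("alphaR", "alphaL", "beta", "PPII", "unassigned")

UNASSIGNED = CLASSES.index("unassigned")


def _interval_contains(value, lo, hi):
    """Half-open membership on the wrapped circle: lo inclusive, hi exclusive.

    ``hi`` may exceed 180 to denote an interval crossing the wrap point
    (e.g. [100, 200) covers psi >= 100 or psi < -160).
    """
    return (value - lo) % 360.0 < (hi - lo)


@dataclass(frozen=True)
class RegionMap:
    """Named Ramachandran regions as axis-aligned rectangles on the torus.

    ``regions`` maps each explicit class name to a list of rectangles
    (phi_lo, phi_hi, psi_lo, psi_hi); the implicit fifth class
    "unassigned" is the complement. Rectangles use the half-open
    lower-inclusive convention after wrapping angles into (-180, 180].
    """

    regions: dict[str, list[tuple[float, float, float, float]]]

    def __post_init__(self):
        expected = set(CLASSES[:-1])
        if set(self.regions) != expected:
            raise ValueError(
                f"region map must define exactly {sorted(expected)}, "
                f"got {sorted(self.regions)}"
            )
        for name, rects in self.regions.items():
            for lo_p, hi_p, lo_s, hi_s in rects:
                if not (hi_p > lo_p and hi_s > lo_s):
                    raise ValueError(f"degenerate rectangle in region {name}")
                if hi_p - lo_p > 360 or hi_s - lo_s > 360:
                    raise ValueError(f"rectangle wider than the torus in {name}")

    def validate_disjoint(self, resolution: float = 1.0) -> None:
        """Dense grid scan asserting regions are pairwise disjoint."""
        grid = np.arange(-180.0 + resolution / 2, 180.0, resolution)
        phi, psi = np.meshgrid(grid, grid, indexing="ij")
        hits = np.zeros(phi.shape, dtype=int)
        for rects in self.regions.values():
            inside = np.zeros(phi.shape, dtype=bool)
            for lo_p, hi_p, lo_s, hi_s in rects:
                inside |= _interval_contains(phi, lo_p, hi_p) & _interval_contains(
                    psi, lo_s, hi_s
                )
            hits += inside.astype(int)
        if hits.max() > 1:
            raise ValueError("region map has overlapping regions")

    def to_dict(self) -> dict:
        return {k: [list(map(float, r)) for r in v] for k, v in self.regions.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionMap":
        return cls({k: [tuple(r) for r in v] for k, v in d.items()})


#: Default region boundaries (degrees). The beta and PPII psi interval
#: [100, 200) wraps: it covers psi >= 100 together with psi < -160.
DEFAULT_REGION_MAP = RegionMap(
    {
        "alphaR": [(-160.0, -20.0, -120.0, 50.0)],
        "alphaL": [(20.0, 160.0, -50.0, 120.0)],
        "beta": [(-180.0, -100.0, 100.0, 200.0)],
        "PPII": [(-100.0, -20.0, 100.0, 200.0)],
    }
)


def classify(phi, psi, region_map: RegionMap = DEFAULT_REGION_MAP) -> np.ndarray:
    """Classify (phi, psi) in degrees into one of the five classes.

    Returns integer codes indexing :data:`CLASSES`; scalar inputs give a
    0-d array. Total: every finite angle pair receives exactly one label.
    """
    phi = wrap_angle(np.asarray(phi, dtype=float))
    psi = wrap_angle(np.asarray(psi, dtype=float))
    out = np.full(np.shape(phi), UNASSIGNED, dtype=np.int8)
    for ci, name in enumerate(CLASSES[:-1]):
        inside = np.zeros(np.shape(phi), dtype=bool)
        for lo_p, hi_p, lo_s, hi_s in region_map.regions[name]:
            inside |= _interval_contains(phi, lo_p, hi_p) & _interval_contains(
                psi, lo_s, hi_s
            )
        out[inside] = ci
    return out


@dataclass
class DihedralSeries:
    """Backbone (phi, psi) pairs for the interior residues of an ensemble.

    ``angles`` has shape (n_frames, n_interior, 2) in degrees, wrapped into
    (-180, 180]. Terminal residues carry incomplete dihedrals and are
    excluded; ``residue_indices`` are the 1-based indices 2..L-1.
    """

    angles: np.ndarray
    residue_indices: np.ndarray
    replica_ids: np.ndarray
    variant_label: str = ""

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.replica_ids = np.asarray(self.replica_ids, dtype=int)
        if self.angles.ndim != 3 or self.angles.shape[2] != 2:
            raise ValueError("angles must have shape (frames, residues, 2)")
        if self.angles.shape[1] != len(self.residue_indices):
            raise ValueError("residue_indices length mismatch")
        if self.angles.shape[0] != len(self.replica_ids):
            raise ValueError("replica_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    @property
    def n_residues(self) -> int:
        return self.angles.shape[1]

    @property
    def replicas(self) -> np.ndarray:
        return np.unique(self.replica_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: frame, replica, residue_index, phi, psi."""
        f, r = np.meshgrid(
            np.arange(self.n_frames), self.residue_indices, indexing="ij"
        )
        return pd.DataFrame(
            {
                "frame": f.ravel(),
                "replica": np.repeat(self.replica_ids, self.n_residues),
                "residue_index": r.ravel(),
                "phi": self.angles[:, :, 0].ravel(),
                "psi": self.angles[:, :, 1].ravel(),
            }
        )


def compute_dihedrals(ensemble) -> DihedralSeries:
    """Extract interior-residue (phi, psi) from an Ensemble's coordinates."""
    N, CA, C = (ensemble.backbone_coords(a) for a in ("N", "CA", "C"))
    phi, psi = backbone_dihedrals(N, CA, C)
    angles = np.stack([phi[:, 1:-1], psi[:, 1:-1]], axis=-1)
    L = N.shape[1]
    return DihedralSeries(
        angles=angles,
        residue_indices=np.arange(2, L),
        replica_ids=ensemble.replica_ids,
        variant_label=ensemble.variant_label,
    )


@dataclass
class OccupancyProfile:
    """Per-residue fractions of frames in each of the five classes."""

    fractions: np.ndarray  # (n_residues, 5)
    residue_indices: np.ndarray
    n_frames: int
    replica_id: int | str = 0
    variant_label: str = ""

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.fractions.shape != (len(self.residue_indices), len(CLASSES)):
            raise ValueError("fractions must be (n_residues, 5)")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        rows = self.fractions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12, rtol=0):
            raise ValueError("per-residue fractions must sum to 1")


def occupancy(
    series: DihedralSeries, region_map: RegionMap = DEFAULT_REGION_MAP
) -> list[OccupancyProfile]:
    """Per-replica occupancy profiles from a dihedral series."""
    if series.n_frames == 0:
        raise ValueError("empty dihedral series")
    labels = classify(series.angles[:, :, 0], series.angles[:, :, 1], region_map)
    profiles = []
    for rep in series.replicas:
        sub = labels[series.replica_ids == rep]
        counts = np.stack(
            [(sub == ci).sum(axis=0) for ci in range(len(CLASSES))], axis=1
        ).astype(float)
        profiles.append(
            OccupancyProfile(
                fractions=counts / sub.shape[0],
                residue_indices=series.residue_indices,
                n_frames=sub.shape[0],
                replica_id=int(rep),
                variant_label=series.variant_label,
            )
        )
    return profiles


@dataclass
class AveragedProfile:
    """Replica-mean occupancy with between-replica spread (std and SEM)."""

    mean: OccupancyProfile
    std: np.ndarray
    sem: np.ndarray
    n_replicas: int


def average_profiles(profiles: list[OccupancyProfile]) -> AveragedProfile:
    """Unweighted mean over replica profiles; spread across replica values."""
    if not profiles:
        raise ValueError("no profiles to average")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_indices, ref.residue_indices):
            raise ValueError("profiles cover different residue ranges")
    stack = np.stack([p.fractions for p in profiles])  # (n_rep, R, 5)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    sem = std / np.sqrt(n)
    mean_profile = OccupancyProfile(
        fractions=mean,
        residue_indices=ref.residue_indices,
        n_frames=sum(p.n_frames for p in profiles),
        replica_id="mean",
        variant_label=ref.variant_label,
    )
    return AveragedProfile(mean=mean_profile, std=std, sem=sem, n_replicas=n)


@dataclass
class DeviationProfile:
    """Per residue/class occupancy difference (variant - wild type)."""

    delta: np.ndarray  # (n_residues, 5)
    uncertainty: np.ndarray
    residue_indices: np.ndarray
    variant_label: str = ""
    reference_label: str = ""


def deviation_profile(
    variant: AveragedProfile, wild_type: AveragedProfile
) -> DeviationProfile:
    """Delta occupancy with combined SEM uncertainty per residue/class."""
    if not np.array_equal(
        variant.mean.residue_indices, wild_type.mean.residue_indices
    ):
        raise ValueError("variant and wild-type profiles have mismatched shapes")
    delta = variant.mean.fractions - wild_type.mean.fractions
    unc = np.sqrt(variant.sem**2 + wild_type.sem**2)
    return DeviationProfile(
        delta=delta,
        uncertainty=unc,
        residue_indices=variant.mean.residue_indices,
        variant_label=variant.mean.variant_label,
        reference_label=wild_type.mean.variant_label,
    )


def profiles_to_frame(profiles: list[OccupancyProfile]) -> pd.DataFrame:
    """Tidy table: variant, replica, residue, class, fraction."""
    rows = []
    for p in profiles:
        for ri, res in enumerate(p.residue_indices):
            for ci, cname in enumerate(CLASSES):
                rows.append(
                    (p.variant_label, p.replica_id, int(res), cname, p.fractions[ri, ci])
                )
    return pd.DataFrame(
        rows, columns=["variant", "replica", "residue", "class", "fraction"]
    )
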