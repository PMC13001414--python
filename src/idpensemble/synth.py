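"""Synthetic disordered-peptide conformational ensembles.

Emulates the statistical structure of replica MD data for a short
intrinsically disordered peptide: per residue, each frame's (phi, psi)
pair is drawn from a mixture of wrapped Gaussian Ramachandran basins with
controllable per-residue propensities, and frames are realised as backbone
coordinates by internal-coordinate chain building. The default study
layout is 16 replicas per variant, matching common parallel-replica
designs for disordered peptides.

Frames are i.i.d. by default (ensemble statistics are time averages, which
i.i.d. sampling reproduces in expectation); an optional first-order hold
probability adds autocorrelation for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BackboneGeometry, IDEAL_GEOMETRY, build_backbone, pseudo_cb
from .rama import CLASSES, DEFAULT_REGION_MAP, DihedralSeries, RegionMap, classify
from .variants import PeptideSequence

__all__ = [
    "BasinSpec",
    "DEFAULT_BASINS",
    "PropensityProfile",
    "uniform_profile",
    "default_profile",
    "Ensemble",
    "sample_dihedrals",
    "generate_dihedral_ensemble",
    "generate_ensemble",
    "realize_coordinates",
]

UNASSIGNED = CLASSES.index("unassigned")


@dataclass(frozen=True)
class BasinSpec:
    """A wrapped bivariate-normal Ramachandran basin for one class."""

    class_label: str
    center: tuple[float, float]  # (phi, psi) degrees
    spread: tuple[float, float]  # (sigma_phi, sigma_psi) degrees

    def __post_init__(self):
        if self.class_label not in CLASSES[:-1]:
            raise ValueError(f"unknown basin class {self.class_label!r}")
        if min(self.spread) <= 0:
            raise ValueError("basin spreads must be positive")

    def validate_center(self, region_map: RegionMap) -> None:
        label = CLASSES[int(classify(*self.center, region_map))]
        if label != self.class_label:
            raise ValueError(
                f"basin center {self.center} classifies as {label}, "
                f"not {self.class_label}"
            )


#: Default basins, centred well inside the default region rectangles.
DEFAULT_BASINS: dict[str, BasinSpec] = {
    "alphaR": BasinSpec("alphaR", (-60.0, -45.0), (11.0, 11.0)),
    "alphaL": BasinSpec("alphaL", (60.0, 45.0), (11.0, 11.0)),
    "beta": BasinSpec("beta", (-140.0, 145.0), (11.0, 11.0)),
    "PPII": BasinSpec("PPII", (-65.0, 150.0), (10.0, 11.0)),
}

#: Proline's ring restricts phi to ~ -65 +/- 8 deg; basins for classes a
#: proline residue samples are overridden accordingly. The beta region
#: (phi < -100) is inaccessible, so default proline profiles carry no
#: beta weight.
PROLINE_PHI = (-65.0, 8.0)


@dataclass
class PropensityProfile:
    """Per-interior-residue weights over the five Ramachandran classes.

    ``weights`` has shape (n_interior, 5) in the :data:`CLASSES` order;
    rows are non-negative and sum to 1. ``residue_indices`` are 1-based.
    """

    weights: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(CLASSES):
            raise ValueError("weights must be (n_residues, 5)")
        if self.weights.shape[0] != len(self.residue_indices):
            raise ValueError("residue_indices length mismatch")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9, rtol=0):
            raise ValueError("each residue's weights must sum to 1")

    @property
    def n_residues(self) -> int:
        return self.weights.shape[0]

    def shifted(self, residue_index: int, class_name: str, delta: float) -> "PropensityProfile":
        """Return a copy with `delta` added to one class at one residue,
        removed proportionally from the other classes."""
        w = self.weights.copy()
        (ri,) = np.where(self.residue_indices == residue_index)[0]
        ci = CLASSES.index(class_name)
        if w[ri, ci] + delta < 0 or w[ri, ci] + delta > 1:
            raise ValueError("shift leaves [0, 1]")
        others = np.ones(len(CLASSES), dtype=bool)
        others[ci] = False
        w[ri, others] *= (1.0 - w[ri, ci] - delta) / w[ri, others].sum()
        w[ri, ci] += delta
        return PropensityProfile(w, self.residue_indices.copy())


def uniform_profile(
    sequence_length: int, weights: dict[str, float] | None = None
) -> PropensityProfile:
    """Same class weights at every interior residue (2..L-1)."""
    if weights is None:
        weights = {"alphaR": 0.15, "alphaL": 0.05, "beta": 0.35, "PPII": 0.35, "unassigned": 0.10}
    w = np.array([weights.get(c, 0.0) for c in CLASSES], dtype=float)
    w = w / w.sum()
    n = sequence_length - 2
    return PropensityProfile(
        np.tile(w, (n, 1)), np.arange(2, sequence_length)
    )


# Relative right-handed-helix propensity by residue type, loosely following
# experimental host-guest helix scales (Ala most helix-forming; Gly and Pro
# strong breakers). Used only to give sequence variants distinguishable
# default ensembles; fully overridable.
_ALPHA_WEIGHT = {
    "A": 0.30, "L": 0.26, "M": 0.25, "R": 0.23, "K": 0.22, "Q": 0.22,
    "E": 0.22, "I": 0.20, "W": 0.19, "F": 0.18, "S": 0.15, "H": 0.15,
    "C": 0.15, "Y": 0.14, "V": 0.13, "N": 0.13, "T": 0.12, "D": 0.12,
    "G": 0.07, "P": 0.12,
}


def default_profile(
    sequence: PeptideSequence | str,
) -> tuple[PropensityProfile, dict[int, dict[str, BasinSpec]]]:
    """Residue-type-aware default propensities for a sequence.

    Ensembles are dominated by beta/PPII (disordered baseline) with
    transient helicity graded by residue type; glycine gains alphaL
    access and proline is PPII-biased with a restricted phi basin.

    Returns the profile and a per-residue basin-override map (1-based
    residue index -> class -> BasinSpec) carrying the proline phi
    restriction.
    """
    seq = str(sequence)
    rows = []
    overrides: dict[int, dict[str, BasinSpec]] = {}
    for idx in range(2, len(seq)):
        aa = seq[idx - 1]
        wa = _ALPHA_WEIGHT[aa]
        if aa == "P":
            rest = 1.0 - wa
            row = {"alphaR": wa, "alphaL": 0.0, "beta": 0.0,
                   "PPII": 0.70 * rest, "unassigned": 0.30 * rest}
            phi0, sphi = PROLINE_PHI
            overrides[idx] = {
                "alphaR": BasinSpec("alphaR", (phi0, -40.0), (sphi, 11.0)),
                "PPII": BasinSpec("PPII", (phi0, 150.0), (sphi, 11.0)),
            }
        elif aa == "G":
            rest = 1.0 - wa
            row = {"alphaR": wa, "alphaL": 0.18 * rest, "beta": 0.30 * rest,
                   "PPII": 0.30 * rest, "unassigned": 0.22 * rest}
        else:
            rest = 1.0 - wa
            row = {"alphaR": wa, "alphaL": 0.06 * rest, "beta": 0.38 * rest,
                   "PPII": 0.38 * rest, "unassigned": 0.18 * rest}
        rows.append([row[c] for c in CLASSES])
    return (
        PropensityProfile(np.array(rows), np.arange(2, len(seq))),
        overrides,
    )


def _sample_unassigned(rng, n, region_map):
    """Uniform draws from the complement region by rejection sampling."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-180.0, 180.0, size=(max(2 * (n - filled), 64), 2))
        keep = classify(cand[:, 0], cand[:, 1], region_map) == UNASSIGNED
        cand = cand[keep]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def sample_dihedrals(
    profile: PropensityProfile,
    basins: dict[str, BasinSpec] | None = None,
    n_frames: int = 1000,
    seed: int = 0,
    region_map: RegionMap = DEFAULT_REGION_MAP,
    residue_basins: dict[int, dict[str, BasinSpec]] | None = None,
    hold_probability: float = 0.0,
    replica_id: int = 0,
    variant_label: str = "",
) -> DihedralSeries:
    """Draw an i.i.d. dihedral series from per-residue basin mixtures.

    Per frame and residue a class is drawn from the profile weights;
    basin classes sample a wrapped bivariate normal, "unassigned" samples
    uniformly from the complement region. ``hold_probability`` > 0 holds
    the previous frame's class with that probability (first-order mixing).
    Same seed, same output.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not 0.0 <= hold_probability < 1.0:
        raise ValueError("hold_probability must be in [0, 1)")
    if basins is None:
        basins = DEFAULT_BASINS
    residue_basins = residue_basins or {}

    def basin_for(res_idx: int, cname: str) -> BasinSpec:
        return residue_basins.get(res_idx, {}).get(cname, basins.get(cname))

    for ri, res in enumerate(profile.residue_indices):
        for ci, cname in enumerate(CLASSES[:-1]):
            if profile.weights[ri, ci] > 0:
                b = basin_for(int(res), cname)
                if b is None:
                    raise ValueError(
                        f"residue {res}: class {cname} has weight but no basin"
                    )
                b.validate_center(region_map)

    rng = np.random.default_rng(seed)
    R = profile.n_residues
    cum = np.cumsum(profile.weights, axis=1)  # (R, 5)

    u = rng.random((n_frames, R))
    labels = (u[:, :, None] >= cum[None, :, :]).sum(axis=2).astype(np.int8)
    if hold_probability > 0.0:
        hold = rng.random((n_frames, R)) < hold_probability
        for t in range(1, n_frames):
            labels[t] = np.where(hold[t], labels[t - 1], labels[t])

    angles = np.empty((n_frames, R, 2))
    for ri, res in enumerate(profile.residue_indices):
        col = labels[:, ri]
        for ci, cname in enumerate(CLASSES[:-1]):
            mask = col == ci
            k = int(mask.sum())
            if k == 0:
                continue
            b = basin_for(int(res), cname)
            draws = rng.normal(
                loc=b.center, scale=b.spread, size=(k, 2)
            )
            angles[mask, ri, :] = -(((-draws) + 180.0) % 360.0 - 180.0)
        mask = col == UNASSIGNED
        k = int(mask.sum())
        if k:
            angles[mask, ri, :] = _sample_unassigned(rng, k, region_map)

    return DihedralSeries(
        angles=angles,
        residue_indices=profile.residue_indices.copy(),
        replica_ids=np.full(n_frames, replica_id),
        variant_label=variant_label,
    )


# ---------------------------------------------------------------------------
# Coordinate-level ensembles


@dataclass
class Ensemble:
    """An ordered set of conformations with replica and variant labels.

    ``xyz`` has shape (n_frames, n_atoms, 3) in Angstrom. Atom metadata is
    columnar: ``atom_names``, ``atom_elements`` and 1-based
    ``atom_residues``. Atoms per residue are N, CA, C, O plus a CB-like
    pseudo-atom for non-glycine residues (side chains are not built).
    """

    sequence: PeptideSequence
    xyz: np.ndarray
    atom_names: list[str]
    atom_elements: list[str]
    atom_residues: np.ndarray
    replica_ids: np.ndarray
    variant_label: str = ""

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.atom_residues = np.asarray(self.atom_residues, dtype=int)
        self.replica_ids = np.asarray(self.replica_ids, dtype=int)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must be (frames, atoms, 3)")
        if self.xyz.shape[1] != len(self.atom_names):
            raise ValueError("atom metadata length mismatch")
        if self.xyz.shape[0] != len(self.replica_ids):
            raise ValueError("replica_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def replicas(self) -> np.ndarray:
        return np.unique(self.replica_ids)

    def backbone_coords(self, name: str) -> np.ndarray:
        """Coordinates of one backbone atom type, shape (frames, L, 3)."""
        idx = [i for i, n in enumerate(self.atom_names) if n == name]
        if len(idx) != self.n_residues:
            raise ValueError(f"atom {name!r} missing for some residues")
        return self.xyz[:, idx, :]

    def frame(self, i: int) -> np.ndarray:
        return self.xyz[i]


def _atom_layout(sequence: PeptideSequence):
    names, elements, residues = [], [], []
    for i, aa in enumerate(sequence, start=1):
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            names.append(nm)
            elements.append(el)
            residues.append(i)
        if aa != "G":
            names.append("CB")
            elements.append("C")
            residues.append(i)
    return names, elements, np.array(residues)


def realize_coordinates(
    sequence: PeptideSequence,
    series: DihedralSeries,
    geometry: BackboneGeometry = IDEAL_GEOMETRY,
) -> Ensemble:
    """Build backbone (+ pseudo-CB) coordinates for every frame of a series."""
    L = len(sequence)
    if not np.array_equal(series.residue_indices, np.arange(2, L)):
        raise ValueError("series residues do not match the sequence interior")
    names, elements, residues = _atom_layout(sequence)
    xyz = np.empty((series.n_frames, len(names), 3))
    phi_full = np.full(L, np.nan)
    psi_full = np.full(L, np.nan)
    for f in range(series.n_frames):
        phi_full[1:-1] = series.angles[f, :, 0]
        psi_full[1:-1] = series.angles[f, :, 1]
        phi_full[0] = 0.0
        psi_full[-1] = np.nan
        bb = build_backbone(phi_full.copy(), psi_full.copy(), geometry=geometry)
        a = 0
        for i, aa in enumerate(sequence):
            xyz[f, a] = bb["N"][i]
            xyz[f, a + 1] = bb["CA"][i]
            xyz[f, a + 2] = bb["C"][i]
            xyz[f, a + 3] = bb["O"][i]
            a += 4
            if aa != "G":
                xyz[f, a] = pseudo_cb(bb["N"][i], bb["CA"][i], bb["C"][i])
                a += 1
    return Ensemble(
        sequence=sequence,
        xyz=xyz,
        atom_names=names,
        atom_elements=elements,
        atom_residues=residues,
        replica_ids=series.replica_ids.copy(),
        variant_label=series.variant_label,
    )


def generate_dihedral_ensemble(
    variant: PeptideSequence,
    profile: PropensityProfile | None = None,
    n_replicas: int = 16,
    n_frames: int = 1000,
    seed: int = 0,
    basins: dict[str, BasinSpec] | None = None,
    residue_basins: dict[int, dict[str, BasinSpec]] | None = None,
    region_map: RegionMap = DEFAULT_REGION_MAP,
    hold_probability: float = 0.0,
) -> DihedralSeries:
    """Multi-replica dihedral series; replica i uses seed = seed + i."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if profile is None:
        profile, auto_overrides = default_profile(variant)
        if residue_basins is None:
            residue_basins = auto_overrides
    parts = [
        sample_dihedrals(
            profile,
            basins=basins,
            n_frames=n_frames,
            seed=seed + i,
            region_map=region_map,
            residue_basins=residue_basins,
            hold_probability=hold_probability,
            replica_id=i,
            variant_label=variant.label or str(variant),
        )
        for i in range(n_replicas)
    ]
    return DihedralSeries(
        angles=np.concatenate([p.angles for p in parts]),
        residue_indices=parts[0].residue_indices,
        replica_ids=np.concatenate([p.replica_ids for p in parts]),
        variant_label=parts[0].variant_label,
    )


def generate_ensemble(
    variant: PeptideSequence,
    profile: PropensityProfile | None = None,
    n_replicas: int = 16,
    n_frames: int = 1000,
    seed: int = 0,
    **kwargs,
) -> Ensemble:
    """Generate a coordinate-level synthetic ensemble for one variant."""
    series = generate_dihedral_ensemble(
        variant, profile, n_replicas=n_replicas, n_frames=n_frames, seed=seed, **kwargs
    )
    return realize_coordinates(variant, series)
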