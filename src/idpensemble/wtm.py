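"""Toy-scale well-tempered metadynamics (WTM) with convergence diagnostics.

Implements the WTM loop on one-dimensional model free-energy landscapes
sampled by overdamped Langevin dynamics: Gaussian hills are deposited
along a collective variable (CV) with heights damped by the accumulated
bias (bias factor gamma), and the potential of mean force (PMF) is
reconstructed from the bias at successive fractions of the run,

    F(s) = -((T + dT) / dT) * V_bias(s) + C,   dT = (gamma - 1) T.

The CV mirrors the alpha-helical content of a peptide: a smooth Gaussian
membership bump around the right-handed-helix Ramachandran center,
averaged over interior residues, in [0, 1]. A hidden slow orthogonal
coordinate can be added to demonstrate the non-convergence signature of an
insufficient CV.

Units: energies in kcal/mol, temperature in K (k_B = 0.0019872041
kcal/mol/K), CV dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "KB_KCAL",
    "HelicityCV",
    "helicity",
    "Hill",
    "HillTrace",
    "deposit_hill",
    "bias_potential",
    "langevin_wtm",
    "reconstruct_pmf",
    "PMFProfile",
    "convergence_series",
    "ConvergenceReport",
    "make_double_well",
    "boltzmann_delta_f",
    "landscape_from_series",
]

KB_KCAL = 0.0019872041  # kcal/mol/K


# ---------------------------------------------------------------------------
# Collective variable


@dataclass(frozen=True)
class HelicityCV:
    """Smooth per-residue helix membership averaged over interior residues.

    Membership is a separable Gaussian bump around the alphaR reference
    (phi0, psi0) with widths (sigma_phi, sigma_psi); the mean over
    residues lies in [0, 1]. Differentiable, unlike the hard region
    classifier, as biasing requires.
    """

    center: tuple[float, float] = (-60.0, -45.0)
    widths: tuple[float, float] = (15.0, 15.0)

    def membership(self, phi, psi) -> np.ndarray:
        dphi = wrap_angle(np.asarray(phi, float) - self.center[0])
        dpsi = wrap_angle(np.asarray(psi, float) - self.center[1])
        sp, ss = self.widths
        return np.exp(-(dphi**2) / (2 * sp**2)) * np.exp(-(dpsi**2) / (2 * ss**2))


def helicity(frame_angles: np.ndarray, cv: HelicityCV = HelicityCV()) -> float:
    """Helical-content CV of one frame: mean membership over residues.

    ``frame_angles`` is (n_interior, 2) degrees.
    """
    frame_angles = np.asarray(frame_angles, dtype=float)
    if frame_angles.ndim != 2 or frame_angles.shape[0] < 1:
        raise ValueError("need at least one interior residue")
    return float(np.mean(cv.membership(frame_angles[:, 0], frame_angles[:, 1])))


# ---------------------------------------------------------------------------
# Hills and bias


@dataclass(frozen=True)
class Hill:
    """One deposited Gaussian hill."""

    time_index: int
    center: float
    width: float
    height: float  # deposited (damped) height

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("hill width must be positive")
        if self.height <= 0:
            raise ValueError("deposited height must be positive")


@dataclass
class HillTrace:
    """An ordered WTM hill record with its deposition parameters."""

    nominal_height: float
    width: float
    bias_factor: float
    temperature: float = 310.0
    hills: list[Hill] = field(default_factory=list)

    def __post_init__(self):
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must exceed 1 for well-tempering")
        if self.nominal_height <= 0 or self.width <= 0:
            raise ValueError("hill height and width must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def delta_T(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature

    def __len__(self) -> int:
        return len(self.hills)


def bias_potential(trace: HillTrace, s) -> np.ndarray:
    """Accumulated bias V(s) = sum of deposited Gaussians, vectorised in s."""
    s = np.asarray(s, dtype=float)
    out = np.zeros(s.shape if s.ndim else ())
    for h in trace.hills:
        out = out + h.height * np.exp(-((s - h.center) ** 2) / (2 * h.width**2))
    return out if out.ndim else float(out)


def deposit_hill(trace: HillTrace, s_now: float, bias_now: float | None = None) -> HillTrace:
    """Append a well-tempered hill at ``s_now`` (mutates and returns trace).

    The deposited height is h * exp(-V(s_now) / (k_B dT)); passing
    ``bias_now`` avoids re-summing the trace when the caller maintains the
    bias on a grid.
    """
    if not np.isfinite(s_now):
        raise ValueError("CV value must be finite")
    if bias_now is None:
        bias_now = float(bias_potential(trace, s_now))
    h_dep = trace.nominal_height * np.exp(
        -bias_now / (KB_KCAL * trace.delta_T)
    )
    trace.hills.append(
        Hill(time_index=len(trace.hills), center=float(s_now), width=trace.width, height=float(h_dep))
    )
    return trace


# ---------------------------------------------------------------------------
# Langevin WTM sampler


def langevin_wtm(
    potential: Callable[[np.ndarray], np.ndarray],
    n_steps: int = 200_000,
    dt: float = 1.0e-3,
    diffusion: float = 0.05,
    temperature: float = 310.0,
    seed: int = 0,
    hill_height: float = 0.5,
    hill_width: float = 0.05,
    bias_factor: float = 10.0,
    deposit_stride: int = 500,
    domain: tuple[float, float] = (0.0, 1.0),
    s0: float | None = None,
    n_grid: int = 2001,
    hidden_potential: Callable[[np.ndarray, float], np.ndarray] | None = None,
    hidden_hop_rate: float = 0.0,
    hidden_switch_step: int | None = None,
    initial_trace: HillTrace | None = None,
) -> tuple[np.ndarray, HillTrace]:
    """Overdamped Langevin dynamics on U(s) with WTM biasing of s.

    The update is s <- s - (D / k_B T) d(U + V_bias)/ds dt + sqrt(2 D dt) xi
    with reflecting boundaries at the domain edges; a hill is deposited
    every ``deposit_stride`` steps. Forces are taken from a dense grid
    (linear interpolation), and the bias grid is updated at each
    deposition.

    ``hidden_potential(s, z)`` models an insufficient CV: a slow unbiased
    binary coordinate z in {0, 1} reshapes the landscape the CV cannot
    see. z hops stochastically with per-step probability
    ``hidden_hop_rate``, and/or flips once deterministically at
    ``hidden_switch_step`` (a quasi-static slow mode).

    Returns the CV trajectory (one value per step) and the HillTrace.
    Divergence (non-finite s) raises RuntimeError with the step index.
    """
    if dt <= 0 or diffusion <= 0 or temperature <= 0:
        raise ValueError("dt, diffusion and temperature must be positive")
    lo, hi = domain
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * temperature

    grid = np.linspace(lo, hi, n_grid)
    dx = grid[1] - grid[0]

    z = 0
    if hidden_potential is not None:
        u_grid_by_z = {zz: np.asarray(hidden_potential(grid, zz), float) for zz in (0, 1)}
        u_grid = u_grid_by_z[z]
    else:
        u_grid = np.asarray(potential(grid), dtype=float)
    du_grid = np.gradient(u_grid, dx)

    bias_grid = np.zeros(n_grid)
    dbias_grid = np.zeros(n_grid)

    trace = HillTrace(
        nominal_height=hill_height,
        width=hill_width,
        bias_factor=bias_factor,
        temperature=temperature,
    )
    if initial_trace is not None:
        # continue from an earlier stage (e.g. coarse hills before a fine
        # refinement): inherit the accumulated bias and the hill record
        trace.hills = list(initial_trace.hills)
        bias_grid = np.asarray(bias_potential(initial_trace, grid), float).copy()
        for h in initial_trace.hills:
            dbias_grid += (
                h.height
                * np.exp(-((grid - h.center) ** 2) / (2 * h.width**2))
                * (-(grid - h.center) / h.width**2)
            )

    s = float(rng.uniform(lo, hi)) if s0 is None else float(s0)
    traj = np.empty(n_steps)
    noise = rng.standard_normal(n_steps)
    sqrt_term = np.sqrt(2.0 * diffusion * dt)
    mob = diffusion / kT * dt

    for step in range(n_steps):
        if hidden_potential is not None:
            flip = hidden_switch_step is not None and step == hidden_switch_step
            if hidden_hop_rate > 0.0 and rng.random() < hidden_hop_rate:
                flip = True
            if flip:
                z = 1 - z
                u_grid = u_grid_by_z[z]
                du_grid = np.gradient(u_grid, dx)
        # linear interpolation of forces
        x = (s - lo) / dx
        i0 = min(int(x), n_grid - 2)
        w = x - i0
        force = (1 - w) * (du_grid[i0] + dbias_grid[i0]) + w * (
            du_grid[i0 + 1] + dbias_grid[i0 + 1]
        )
        s = s - mob * force + sqrt_term * noise[step]
        # reflecting boundaries
        while s < lo or s > hi:
            if s < lo:
                s = 2 * lo - s
            else:
                s = 2 * hi - s
        if not np.isfinite(s):
            raise RuntimeError(f"trajectory diverged at step {step}")
        traj[step] = s
        if (step + 1) % deposit_stride == 0:
            x = (s - lo) / dx
            i0 = min(int(x), n_grid - 2)
            w = x - i0
            v_now = (1 - w) * bias_grid[i0] + w * bias_grid[i0 + 1]
            deposit_hill(trace, s, bias_now=float(v_now))
            h = trace.hills[-1]
            gauss = h.height * np.exp(-((grid - h.center) ** 2) / (2 * h.width**2))
            bias_grid += gauss
            dbias_grid += gauss * (-(grid - h.center) / h.width**2)
    return traj, trace


# ---------------------------------------------------------------------------
# PMF reconstruction and convergence


@dataclass
class PMFProfile:
    """A min-shifted free-energy profile on a CV grid."""

    grid: np.ndarray
    values: np.ndarray  # kcal/mol, min = 0
    fraction: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid/values shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("PMF contains non-finite values")


def reconstruct_pmf(trace: HillTrace, grid: np.ndarray, fraction: float = 1.0) -> PMFProfile:
    """PMF from the bias accumulated over the first ``fraction`` of hills.

    F(s) = -((T + dT)/dT) V_bias(s), min-shifted to zero.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = int(np.ceil(fraction * len(trace.hills)))
    if n == 0:
        raise ValueError("no hills in the truncated trace")
    grid = np.asarray(grid, dtype=float)
    sub = HillTrace(
        nominal_height=trace.nominal_height,
        width=trace.width,
        bias_factor=trace.bias_factor,
        temperature=trace.temperature,
        hills=trace.hills[:n],
    )
    v = bias_potential(sub, grid)
    scale = (trace.temperature + trace.delta_T) / trace.delta_T
    f = -scale * v
    return PMFProfile(grid=grid, values=f - f.min(), fraction=fraction)


@dataclass
class ConvergenceReport:
    """RMS deviation of fractional PMFs from the final PMF.

    Profiles are mean-aligned over the low-free-energy window of the
    final PMF before comparison; ``converged`` is False when the
    last-quarter RMS deviation exceeds ``threshold``.
    """

    fractions: tuple[float, ...]
    rms: tuple[float, ...]
    profiles: list[PMFProfile]
    window: np.ndarray
    threshold: float
    converged: bool


def convergence_series(
    trace: HillTrace,
    grid: np.ndarray,
    fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    window_cutoff_kT: float = 3.0,
    threshold: float = 0.3,
) -> ConvergenceReport:
    """Time-resolved PMFs and their RMS deviation from the final PMF.

    ``window_cutoff_kT`` selects the comparison window {s : F_final(s) <
    cutoff * k_B T}; each profile is aligned by subtracting its window
    mean. ``threshold`` (kcal/mol) flags non-convergence on the RMS
    deviation of the largest fraction below 1 (the last quarter of the
    run by default).
    """
    fractions = tuple(fractions)
    if any(f2 <= f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    if not 0.0 < fractions[-1] <= 1.0:
        raise ValueError("fractions must lie in (0, 1]")
    grid = np.asarray(grid, dtype=float)
    profiles = [reconstruct_pmf(trace, grid, f) for f in fractions]
    final = profiles[-1] if fractions[-1] == 1.0 else reconstruct_pmf(trace, grid, 1.0)
    kT = KB_KCAL * trace.temperature
    window = final.values < window_cutoff_kT * kT
    if not window.any():
        raise ValueError("empty low-free-energy window")

    def aligned(p: PMFProfile) -> np.ndarray:
        return p.values - p.values[window].mean()

    ref = aligned(final)
    rms = tuple(
        float(np.sqrt(np.mean((aligned(p)[window] - ref[window]) ** 2)))
        for p in profiles
    )
    below_one = [i for i, f in enumerate(fractions) if f < 1.0]
    last_quarter_rms = rms[below_one[-1]] if below_one else 0.0
    return ConvergenceReport(
        fractions=fractions,
        rms=rms,
        profiles=profiles,
        window=window,
        threshold=threshold,
        converged=bool(last_quarter_rms <= threshold),
    )


# ---------------------------------------------------------------------------
# Model landscapes


def make_double_well(
    minima: tuple[float, float] = (0.2, 0.8),
    barrier: float = 3.0,
    tilt: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Quartic double well on [0, 1] with a linear tilt (kcal/mol).

    The untilted barrier at the midpoint is ``barrier``; U includes a
    ``-tilt * s`` term, so positive tilt deepens the right-hand well.
    """
    a, b = minima
    mid = 0.5 * (a + b)
    scale = barrier / ((mid - a) ** 2 * (mid - b) ** 2)

    def u(s):
        s = np.asarray(s, dtype=float)
        return scale * (s - a) ** 2 * (s - b) ** 2 - tilt * s

    return u


def boltzmann_delta_f(
    potential: Callable[[np.ndarray], np.ndarray],
    split: float,
    temperature: float = 310.0,
    domain: tuple[float, float] = (0.0, 1.0),
    n: int = 20001,
) -> float:
    """Free-energy difference F(right basin) - F(left basin) by quadrature.

    Basin free energies are -kT log of the Boltzmann integral over each
    side of ``split``.
    """
    kT = KB_KCAL * temperature
    s = np.linspace(*domain, n)
    w = np.exp(-(np.asarray(potential(s)) - np.min(potential(s))) / kT)
    left = np.trapezoid(np.where(s < split, w, 0.0), s)
    right = np.trapezoid(np.where(s >= split, w, 0.0), s)
    return float(-kT * (np.log(right) - np.log(left)))


def pmf_delta_f(profile: PMFProfile, split: float, temperature: float = 310.0) -> float:
    """Basin free-energy difference of a reconstructed PMF by the same
    Boltzmann integration used for analytic landscapes."""
    kT = KB_KCAL * temperature
    w = np.exp(-profile.values / kT)
    left = np.trapezoid(np.where(profile.grid < split, w, 0.0), profile.grid)
    right = np.trapezoid(np.where(profile.grid >= split, w, 0.0), profile.grid)
    return float(-kT * (np.log(right) - np.log(left)))


def landscape_from_series(
    series,
    cv: HelicityCV = HelicityCV(),
    temperature: float = 310.0,
    n_bins: int = 50,
) -> tuple[Callable[[np.ndarray], np.ndarray], np.ndarray]:
    """Empirical free-energy landscape of the helicity CV of an ensemble.

    Histograms the per-frame CV values of a DihedralSeries and returns
    U(s) = -kT log p(s) (linear interpolation, clipped at the occupied
    range) together with the per-frame CV values. This lets the toy WTM
    machinery run on a landscape derived from the CV itself.
    """
    kT = KB_KCAL * temperature
    values = np.array([helicity(frame, cv) for frame in series.angles])
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = hist > 0
    f = np.full(n_bins, np.nan)
    f[occupied] = -kT * np.log(hist[occupied] / hist.sum())
    fmax = np.nanmax(f) + 2.0 * kT  # penalty plateau for unvisited bins
    f[~occupied] = fmax
    f -= f.min()

    def u(s):
        return np.interp(np.asarray(s, dtype=float), centers, f)

    return u, values
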