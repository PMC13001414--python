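"""Well-tempered metadynamics: CV, hills, sampler, PMF reconstruction."""

import numpy as np
import pytest
from scipy import integrate

from idpensemble.rama import CLASSES, classify
from idpensemble.wtm import (
    KB_KCAL,
    HelicityCV,
    HillTrace,
    bias_potential,
    convergence_series,
    deposit_hill,
    helicity,
    landscape_from_series,
    langevin_wtm,
    make_double_well,
    boltzmann_delta_f,
    reconstruct_pmf,
)
from idpensemble.synth import generate_dihedral_ensemble
from idpensemble.variants import PeptideSequence


def test_helicity_extremes():
    cv = HelicityCV()
    at_center = np.tile(cv.center, (5, 1))
    assert helicity(at_center, cv) == pytest.approx(1.0, abs=1e-12)
    far = np.tile([cv.center[0] + 120.0, cv.center[1] + 120.0], (5, 1))
    assert helicity(far, cv) < 1e-3
    half = np.vstack([at_center[:2], far[:2]])
    assert helicity(half, cv) == pytest.approx(0.5, abs=1e-3)


def test_helicity_bump_majority_implies_alphaR_label(rng):
    cv = HelicityCV()
    phi = rng.uniform(-180, 180, 4000)
    psi = rng.uniform(-180, 180, 4000)
    member = cv.membership(phi, psi)
    labels = classify(phi, psi)
    strong = member >= 0.5
    assert strong.any()
    assert (labels[strong] == CLASSES.index("alphaR")).all()


def test_first_hill_has_nominal_height():
    trace = HillTrace(nominal_height=0.5, width=0.05, bias_factor=10.0)
    deposit_hill(trace, 0.3)
    assert trace.hills[0].height == pytest.approx(0.5, rel=1e-15)


def test_repeated_deposition_strictly_decreasing():
    trace = HillTrace(nominal_height=0.5, width=0.05, bias_factor=5.0)
    for _ in range(10):
        deposit_hill(trace, 0.3)
    heights = [h.height for h in trace.hills]
    assert all(b < a for a, b in zip(heights, heights[1:]))


def test_large_gamma_recovers_ordinary_metadynamics():
    trace = HillTrace(nominal_height=0.5, width=0.05, bias_factor=1e9)
    for _ in range(5):
        deposit_hill(trace, 0.3)
    assert all(h.height == pytest.approx(0.5, rel=1e-6) for h in trace.hills)


def test_gamma_must_exceed_one():
    with pytest.raises(ValueError):
        HillTrace(nominal_height=0.5, width=0.05, bias_factor=1.0)


def test_bias_potential_oracle(rng):
    trace = HillTrace(nominal_height=0.3, width=0.07, bias_factor=8.0)
    for _ in range(20):
        deposit_hill(trace, float(rng.uniform(0, 1)))
    grid = np.linspace(0, 1, 101)
    direct = np.zeros_like(grid)
    for h in trace.hills:
        direct += h.height * np.exp(-((grid - h.center) ** 2) / (2 * h.width**2))
    assert np.abs(bias_potential(trace, grid) - direct).max() < 1e-12
    empty = HillTrace(nominal_height=0.3, width=0.07, bias_factor=8.0)
    assert np.all(bias_potential(empty, grid) == 0)
    one = HillTrace(nominal_height=0.3, width=0.07, bias_factor=8.0)
    deposit_hill(one, 0.4)
    assert bias_potential(one, 0.4) == pytest.approx(one.hills[0].height, rel=1e-12)


def test_langevin_seeded_determinism():
    u = make_double_well()
    t1, tr1 = langevin_wtm(u, n_steps=5000, seed=3)
    t2, tr2 = langevin_wtm(u, n_steps=5000, seed=3)
    assert np.array_equal(t1, t2)
    assert [h.center for h in tr1.hills] == [h.center for h in tr2.hills]


def test_flat_potential_unbiased_is_uniform():
    traj, _ = langevin_wtm(
        lambda s: np.zeros_like(np.asarray(s, float)),
        n_steps=200_000,
        diffusion=2.0,  # fast mixing: ~250-step domain-crossing time
        hill_height=1e-9,  # negligible bias
        deposit_stride=10**9,
        seed=1,
    )
    samples = traj[10_000::500]  # decorrelated
    counts, _ = np.histogram(samples, bins=10, range=(0, 1))
    expected = len(samples) / 10
    chi2 = ((counts - expected) ** 2 / expected).sum()
    assert chi2 < 27.9  # chi2_{9, 0.999}


def test_steep_well_mean_matches_boltzmann_average():
    kT = KB_KCAL * 310
    u = lambda s: 50.0 * (np.asarray(s, float) - 0.4) ** 2
    traj, _ = langevin_wtm(
        u, n_steps=300_000, hill_height=1e-9, deposit_stride=10**9, seed=2
    )
    num = integrate.quad(lambda s: s * np.exp(-u(s) / kT), 0, 1)[0]
    den = integrate.quad(lambda s: np.exp(-u(s) / kT), 0, 1)[0]
    assert abs(traj[30_000:].mean() - num / den) < 0.01


def test_reconstruct_pmf_basic_contracts():
    trace = HillTrace(nominal_height=0.2, width=0.05, bias_factor=6.0)
    for c in (0.2, 0.5, 0.8):
        deposit_hill(trace, c)
    grid = np.linspace(0, 1, 201)
    pmf = reconstruct_pmf(trace, grid, 1.0)
    assert pmf.values.min() == pytest.approx(0.0, abs=1e-14)
    with pytest.raises(ValueError):
        reconstruct_pmf(trace, grid, 0.0)
    # hill order does not matter
    shuffled = HillTrace(nominal_height=0.2, width=0.05, bias_factor=6.0)
    shuffled.hills = list(reversed(trace.hills))
    pmf2 = reconstruct_pmf(shuffled, grid, 1.0)
    assert np.abs(pmf.values - pmf2.values).max() < 1e-12


def test_convergence_single_fraction_rms_zero():
    trace = HillTrace(nominal_height=0.2, width=0.05, bias_factor=6.0)
    for c in (0.2, 0.5, 0.8):
        deposit_hill(trace, c)
    rep = convergence_series(trace, np.linspace(0, 1, 101), fractions=(1.0,))
    assert rep.rms == (0.0,)
    assert rep.converged


def test_double_well_delta_f_recovered_over_seeds():
    """Long toy WTM runs recover the quadrature basin dF within 0.3 kT
    (mean over seeds)."""
    u = make_double_well()
    ref = boltzmann_delta_f(u, split=0.5)
    kT = KB_KCAL * 310
    grid = np.linspace(0, 1, 400)
    from idpensemble.wtm import pmf_delta_f

    errs = []
    for seed in range(3):
        _, trace = langevin_wtm(
            u,
            n_steps=1_200_000,
            deposit_stride=400,
            hill_height=0.1,
            hill_width=0.05,
            bias_factor=6.0,
            seed=seed,
        )
        pmf = reconstruct_pmf(trace, grid, 1.0)
        errs.append((pmf_delta_f(pmf, split=0.5) - ref) / kT)
    assert abs(np.mean(errs)) < 0.3


def test_sublinear_bias_growth_well_tempered():
    trace = HillTrace(nominal_height=0.5, width=0.05, bias_factor=5.0)
    marks = []
    for i in range(200):
        deposit_hill(trace, 0.5)
        if i in (49, 99, 199):
            marks.append(float(bias_potential(trace, 0.5)))
    # per-hill growth rate decreases: sublinear accumulation
    rate_50_100 = (marks[1] - marks[0]) / 50
    rate_100_200 = (marks[2] - marks[1]) / 100
    assert rate_100_200 < rate_50_100


def test_insufficient_cv_raises_nonconvergence_flag():
    def hidden(s, z):
        s = np.asarray(s, float)
        base = 3.0 / ((0.3 * 0.3) ** 2) * (s - 0.2) ** 2 * (s - 0.8) ** 2
        return base + (2.5 * s if z == 0 else -2.5 * s)

    _, trace = langevin_wtm(
        lambda s: hidden(s, 0),
        n_steps=400_000,
        deposit_stride=400,
        hill_height=0.1,
        hill_width=0.05,
        bias_factor=6.0,
        seed=0,
        hidden_potential=hidden,
        hidden_switch_step=280_000,
    )
    rep = convergence_series(trace, np.linspace(0, 1, 400))
    assert not rep.converged


def test_landscape_from_series_runs_on_the_cv_itself(wild_type):
    series = generate_dihedral_ensemble(wild_type, n_replicas=2, n_frames=300, seed=7)
    u, values = landscape_from_series(series)
    assert values.min() >= 0 and values.max() <= 1
    grid = np.linspace(0, 1, 50)
    assert np.isfinite(u(grid)).all()
    # low-helicity states are favoured for the disordered default profile
    assert u(0.05) < u(0.9)


def rugged_landscape(s):
    """Double well plus two sub-hill-width barrier spikes (rugged toy)."""
    s = np.asarray(s, float)
    base = make_double_well()(s)
    return (
        base
        + 2.0 * np.exp(-((s - 0.5) ** 2) / (2 * 0.015**2))
        + 1.5 * np.exp(-((s - 0.35) ** 2) / (2 * 0.012**2))
    )


def test_refinement_stage_improves_convergence_metric():
    """A fine-hill refinement stage after a coarse stage settles the PMF:
    the final RMS convergence metric drops well below the coarse-only run
    (mean over seeds, equal total hill count)."""
    grid = np.linspace(0, 1, 400)
    common = dict(diffusion=0.05, bias_factor=6.0, deposit_stride=300)
    rms = {"coarse": [], "refined": []}
    for seed in range(3):
        _, tr = langevin_wtm(
            rugged_landscape, n_steps=1200 * 300, hill_height=0.5, hill_width=0.05,
            seed=seed, **common,
        )
        rms["coarse"].append(convergence_series(tr, grid).rms[-2])
        t1, tr1 = langevin_wtm(
            rugged_landscape, n_steps=600 * 300, hill_height=0.5, hill_width=0.05,
            seed=seed, **common,
        )
        _, tr2 = langevin_wtm(
            rugged_landscape, n_steps=600 * 300, hill_height=0.1, hill_width=0.01,
            seed=seed + 50_000, s0=t1[-1], initial_trace=tr1, **common,
        )
        rms["refined"].append(convergence_series(tr2, grid).rms[-2])
    assert np.mean(rms["refined"]) < np.mean(rms["coarse"])


def test_initial_trace_continuation_matches_manual_bias():
    u = make_double_well()
    _, stage1 = langevin_wtm(u, n_steps=20_000, deposit_stride=500, seed=1)
    n1 = len(stage1)
    _, stage2 = langevin_wtm(
        u, n_steps=20_000, deposit_stride=500, hill_height=0.1, hill_width=0.01,
        seed=2, initial_trace=stage1,
    )
    assert len(stage2) == n1 + 40
    # earlier hills preserved verbatim, widths per stage
    assert stage2.hills[:n1] == stage1.hills
    assert all(h.width == 0.01 for h in stage2.hills[n1:])
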