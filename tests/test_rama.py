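"""Region classification, occupancy statistics and deviation profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpensemble.rama import (
    CLASSES,
    DEFAULT_REGION_MAP,
    DihedralSeries,
    OccupancyProfile,
    RegionMap,
    average_profiles,
    classify,
    compute_dihedrals,
    deviation_profile,
    occupancy,
)
from idpensemble.synth import generate_dihedral_ensemble, generate_ensemble, uniform_profile, sample_dihedrals
from idpensemble.variants import PeptideSequence


def idx(name):
    return CLASSES.index(name)


@pytest.mark.parametrize(
    "phi,psi,expected",
    [
        (-60, -45, "alphaR"),
        (-75, 150, "PPII"),
        (-130, 140, "beta"),
        (60, 45, "alphaL"),
        (-170, -170, "beta"),  # wrapped psi branch of the beta strip
        (0, 0, "unassigned"),
    ],
)
def test_classify_canonical_points(phi, psi, expected):
    assert CLASSES[int(classify(phi, psi))] == expected


def test_classify_boundary_half_open():
    # lower edges inclusive, upper exclusive (alphaR: phi [-160,-20), psi [-120,50))
    assert CLASSES[int(classify(-160, 0))] == "alphaR"
    assert CLASSES[int(classify(-20, 0))] == "unassigned"
    assert CLASSES[int(classify(-60, 50))] == "unassigned"
    assert CLASSES[int(classify(-60, -120))] == "alphaR"


def test_dense_grid_each_point_single_label_and_areas():
    grid = np.arange(-179.5, 180.0, 1.0)
    phi, psi = np.meshgrid(grid, grid, indexing="ij")
    labels = classify(phi, psi)
    counts = np.bincount(labels.ravel(), minlength=5)
    assert counts.sum() == labels.size  # total function
    # label counts equal region areas at grid resolution (1 deg^2 cells)
    areas = {
        "alphaR": 140 * 170,
        "alphaL": 140 * 170,
        "beta": 80 * 100,
        "PPII": 80 * 100,
    }
    for name, area in areas.items():
        assert counts[idx(name)] == area
    DEFAULT_REGION_MAP.validate_disjoint()


@settings(max_examples=200, deadline=None)
@given(
    phi=st.floats(min_value=-1000, max_value=1000, allow_nan=False),
    psi=st.floats(min_value=-1000, max_value=1000, allow_nan=False),
)
def test_classify_total_and_pure(phi, psi):
    a = int(classify(phi, psi))
    b = int(classify(phi, psi))
    assert a == b and 0 <= a < 5


def test_overlapping_region_map_rejected():
    bad = {
        "alphaR": [(-160.0, -20.0, -120.0, 50.0)],
        "alphaL": [(-30.0, 160.0, -50.0, 120.0)],  # overlaps alphaR
        "beta": [(-180.0, -100.0, 100.0, 200.0)],
        "PPII": [(-100.0, -20.0, 100.0, 200.0)],
    }
    with pytest.raises(ValueError, match="overlap"):
        RegionMap(bad).validate_disjoint()


def make_series(angles, replica_ids=None):
    angles = np.asarray(angles, float)
    n, r, _ = angles.shape
    return DihedralSeries(
        angles=angles,
        residue_indices=np.arange(2, 2 + r),
        replica_ids=np.zeros(n, int) if replica_ids is None else np.asarray(replica_ids),
    )


def test_occupancy_all_alphaR():
    s = make_series(np.tile([[-60.0, -45.0]], (10, 3, 1)))
    (prof,) = occupancy(s)
    assert np.allclose(prof.fractions[:, idx("alphaR")], 1.0)
    assert np.allclose(prof.fractions.sum(axis=1), 1.0)


def test_occupancy_alternating_half_half():
    frames = np.empty((10, 2, 2))
    frames[0::2] = [-60.0, -45.0]  # alphaR
    frames[1::2] = [-130.0, 140.0]  # beta
    (prof,) = occupancy(make_series(frames))
    assert np.allclose(prof.fractions[:, idx("alphaR")], 0.5)
    assert np.allclose(prof.fractions[:, idx("beta")], 0.5)


def test_occupancy_empty_series_rejected():
    with pytest.raises(ValueError):
        occupancy(
            DihedralSeries(
                angles=np.empty((0, 2, 2)),
                residue_indices=np.array([2, 3]),
                replica_ids=np.empty(0, int),
            )
        )


def test_occupancy_recovers_generator_weights():
    prof = uniform_profile(8, {"alphaR": 0.3, "beta": 0.3, "PPII": 0.2, "unassigned": 0.2})
    s = sample_dihedrals(prof, n_frames=20000, seed=21)
    (est,) = occupancy(s)
    assert np.abs(est.fractions - prof.weights).max() < 0.02


def test_average_profiles_hand_arithmetic():
    res = np.array([2, 3])

    def prof(a):
        fr = np.zeros((2, 5))
        fr[:, idx("alphaR")] = a
        fr[:, idx("beta")] = 1 - a
        return OccupancyProfile(fr, res, n_frames=10, replica_id=0)

    avg = average_profiles([prof(0.2), prof(0.4)])
    assert np.allclose(avg.mean.fractions[:, idx("alphaR")], 0.3)
    assert np.allclose(avg.std[:, idx("alphaR")], 0.1414213562, atol=1e-9)
    assert np.allclose(avg.sem[:, idx("alphaR")], 0.1, atol=1e-12)
    assert np.allclose(avg.mean.fractions.sum(axis=1), 1.0)


def test_average_identical_profiles_zero_spread():
    res = np.array([2, 3, 4])
    fr = np.full((3, 5), 0.2)
    profs = [OccupancyProfile(fr, res, 5, i) for i in range(16)]
    avg = average_profiles(profs)
    assert np.allclose(avg.mean.fractions, fr, atol=1e-15, rtol=0)
    assert np.all(avg.std < 1e-15) and np.all(avg.sem < 1e-15)


def test_deviation_self_is_zero(wild_type):
    series = generate_dihedral_ensemble(wild_type, n_replicas=3, n_frames=50, seed=1)
    avg = average_profiles(occupancy(series))
    dev = deviation_profile(avg, avg)
    assert np.all(dev.delta == 0)
    assert np.allclose(dev.delta.sum(axis=1), 0, atol=1e-12)


def test_deviation_rows_sum_to_zero(wild_type):
    a = average_profiles(
        occupancy(generate_dihedral_ensemble(wild_type, n_replicas=3, n_frames=50, seed=1))
    )
    b = average_profiles(
        occupancy(generate_dihedral_ensemble(wild_type, n_replicas=3, n_frames=50, seed=2))
    )
    dev = deviation_profile(a, b)
    assert np.abs(dev.delta.sum(axis=1)).max() < 1e-12
    assert (dev.uncertainty >= 0).all()


def test_injected_alphaR_shift_recovered(wild_type):
    base = uniform_profile(len(wild_type))
    shifted = base.shifted(2, "alphaR", 0.15)
    wt = average_profiles(
        occupancy(generate_dihedral_ensemble(wild_type, profile=base, n_replicas=4, n_frames=500, seed=10))
    )
    var = average_profiles(
        occupancy(generate_dihedral_ensemble(wild_type, profile=shifted, n_replicas=4, n_frames=500, seed=60))
    )
    dev = deviation_profile(var, wt)
    row = list(dev.residue_indices).index(2)
    assert abs(dev.delta[row, idx("alphaR")] - 0.15) < 0.03


def test_compute_dihedrals_matches_generated_series(wild_type):
    ens = generate_ensemble(wild_type, n_replicas=1, n_frames=10, seed=4)
    series = compute_dihedrals(ens)
    ref = generate_dihedral_ensemble(wild_type, n_replicas=1, n_frames=10, seed=4)
    assert np.abs(series.angles - ref.angles).max() < 1e-3
    assert np.array_equal(series.residue_indices, np.arange(2, len(wild_type)))
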