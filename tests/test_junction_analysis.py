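"""Junction angle conventions, isomer labels, biasing and WHAM unbiasing."""

import numpy as np
import pytest

from origametry import cg_io, junction_analysis as ja, synthetic_data as sd
from origametry.errors import AnalysisError
from origametry.geometry import circular_difference_deg

from conftest import random_rigid


def _fake_arm_frame(points_by_arm):
    """Frame whose nucleotide pairs coincide with given arm midpoints."""
    pts = np.vstack([np.repeat(p, 2, axis=0) for p in points_by_arm])
    n = pts.shape[0]
    versors = np.tile([0.0, 0.0, 1.0], (n, 1))
    v2 = np.tile([1.0, 0.0, 0.0], (n, 1))
    return cg_io.Frame(0.0, np.array([100.0] * 3), pts, versors, v2)


def _arm(label, start_index, n):
    return ja.Arm(label, tuple((start_index + 2 * k, start_index + 2 * k + 1)
                               for k in range(n)))


def test_arm_axis_recovers_straight_direction():
    d = np.array([1.0, 2.0, -0.5])
    d /= np.linalg.norm(d)
    pts = np.outer(np.arange(12) * 0.34, d) + np.array([3.0, -1.0, 0.5])
    frame = _fake_arm_frame([pts])
    axis = ja.arm_axis(frame, _arm("A", 0, 12), fit_length=8, exclusion=2)
    assert np.degrees(np.arccos(np.clip(np.dot(axis, d), -1, 1))) < 0.5


def test_arm_axis_bent_arm_distal_fit():
    """A 10-degree kink at the arm midpoint: a distal fit sees only the
    distal direction."""
    d1 = np.array([1.0, 0.0, 0.0])
    ang = np.radians(10.0)
    d2 = np.array([np.cos(ang), np.sin(ang), 0.0])
    prox = np.outer(np.arange(8) * 0.34, d1)
    dist = prox[-1] + np.outer((np.arange(8) + 1) * 0.34, d2)
    pts = np.vstack([prox, dist])
    frame = _fake_arm_frame([pts])
    axis = ja.arm_axis(frame, _arm("A", 0, 16), fit_length=8, exclusion=8)
    err = np.degrees(np.arccos(np.clip(np.dot(axis, d2), -1, 1)))
    assert err < 1.0


def test_arm_axis_too_short_raises():
    pts = np.outer(np.arange(3) * 0.34, [1.0, 0.0, 0.0])
    frame = _fake_arm_frame([pts])
    with pytest.raises(AnalysisError):
        ja.arm_axis(frame, _arm("A", 0, 3), fit_length=8, exclusion=2)


def test_junction_plane_planar_construct():
    _, frame, spec, _ = sd.construct_junction(180.0, 0.0)
    point, normal = ja.junction_plane(frame, spec)
    for arm in spec.arms:
        axis = ja.arm_axis(frame, arm)
        off_plane = np.degrees(np.arcsin(abs(float(np.dot(axis, normal)))))
        assert off_plane < 0.5


def test_junction_plane_tilted_construct():
    _, frame, spec, _ = sd.construct_junction(180.0, 5.0)
    _, normal = ja.junction_plane(frame, spec)
    # normal still along the duplex-separation axis of the construction
    assert abs(abs(float(normal[2])) - 1.0) < 1e-3


def test_junction_plane_collinear_arms_degenerate():
    # all four arms on one line, stacks coincident
    line = np.outer(np.arange(16) * 0.34, [1.0, 0.0, 0.0])
    frame = _fake_arm_frame([line, -line, line, -line])
    arms = tuple(_arm(l, 32 * k, 16) for k, l in enumerate("ABCD"))
    spec = ja.JunctionSpec(arms=arms, exchanging_strands=(3, 4),
                           continuing_strands=(1, 2),
                           midpoint_nucleotides=(0, 32, 64, 96))
    with pytest.raises(AnalysisError):
        ja.junction_plane(frame, spec)


@pytest.mark.parametrize(
    "phi_true",
    [0.0, 45.0, 95.5, 120.0, 180.0, 210.0, 300.0],
)
def test_phi_round_trip(phi_true):
    """The analyzer recovers the constructed twist, including the printed
    anchors: 0 for parallel, 180 for anti-parallel junctions."""
    _, frame, spec, _ = sd.construct_junction(phi_true, 0.0)
    phi_meas = ja.phi(frame, spec)
    assert abs(circular_difference_deg(phi_meas, phi_true)) < 0.5


@pytest.mark.parametrize("theta_true", [-8.0, -5.0, 0.0, 2.5, 5.0, 10.0])
def test_theta_round_trip(theta_true):
    _, frame, spec, _ = sd.construct_junction(170.0, theta_true)
    s = ja.junction_angles(frame, spec)
    tol = 0.3 if theta_true == 0.0 else 0.5
    assert abs(s.theta - theta_true) < tol


def test_phi_theta_rigid_motion_invariant(rng):
    _, frame, spec, _ = sd.construct_junction(130.0, 4.0)
    ref = ja.junction_angles(frame, spec)
    for _ in range(5):
        R, t = random_rigid(rng)
        s = ja.junction_angles(frame.transformed(R, t), spec)
        assert abs(circular_difference_deg(s.phi, ref.phi)) < 1e-6
        assert abs(s.theta - ref.theta) < 1e-6


def test_mirror_image_flips_chirality():
    """phi of a construct and its mirror image sum to 360 degrees."""
    _, frame, spec, _ = sd.construct_junction(140.0, 3.0)
    mirror = cg_io.Frame(
        0.0, frame.box.copy(),
        frame.positions * np.array([1.0, 1.0, -1.0]),
        frame.a1 * np.array([1.0, 1.0, -1.0]),
        frame.a3 * np.array([1.0, 1.0, -1.0]),
    )
    p1 = ja.phi(frame, spec)
    p2 = ja.phi(mirror, spec)
    assert abs(circular_difference_deg(p1 + p2, 360.0)) < 1.0


def test_classify_isomer_labels():
    _, frame, spec, _ = sd.construct_junction(95.5, 2.5)
    assert ja.classify_isomer(frame, spec) == "I"
    # relabel the arms so the declared stacking no longer matches geometry
    a, b, c, d = spec.arms
    swapped = ja.JunctionSpec(arms=(a, c, b, d),
                              exchanging_strands=spec.exchanging_strands,
                              continuing_strands=spec.continuing_strands,
                              midpoint_nucleotides=spec.midpoint_nucleotides)
    assert ja.classify_isomer(frame, swapped) == "II"


def test_classify_isomer_open():
    dirs = [
        np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
        np.array([-1.0, 0.0, 0.0]), np.array([0.0, -1.0, 0.0]),
    ]
    # arms at 90 degrees: no pair of outward axes is anti-aligned enough
    pts = [np.outer((np.arange(16) + 1) * 0.34, d) for d in dirs]
    # make outward axes pairwise at 90 deg: A=+x, B=+y, C=-x, D=-y... but
    # A/C are anti-aligned; tilt two of them out of plane instead
    pts[1] = np.outer((np.arange(16) + 1) * 0.34,
                      np.array([0.0, np.cos(np.pi / 4), np.sin(np.pi / 4)]))
    pts[3] = np.outer((np.arange(16) + 1) * 0.34,
                      np.array([0.0, -np.cos(np.pi / 4), np.sin(np.pi / 4)]))
    frame = _fake_arm_frame(pts)
    arms = tuple(_arm(l, 32 * k, 16) for k, l in enumerate("ABCD"))
    spec = ja.JunctionSpec(arms=arms, exchanging_strands=(3, 4),
                           continuing_strands=(1, 2),
                           midpoint_nucleotides=(0, 32, 64, 96))
    assert ja.classify_isomer(frame, spec) == "open"


# ---------------------------------------------------------------------------
# bias and WHAM


def test_bias_energy_values():
    w = ja.BiasWindow(center=10.0, stiffness=0.05, window_id=0)
    assert ja.bias_energy(10.0, w) == 0.0
    assert ja.bias_energy(123.0, ja.BiasWindow(0.0, 0.0, 1)) == 0.0
    # circular wrap: 350 vs 10 is a 20-degree difference
    assert ja.bias_energy(350.0, w) == pytest.approx(0.5 * 0.05 * 400.0)


def test_bias_window_negative_stiffness_rejected():
    with pytest.raises(ValueError):
        ja.BiasWindow(center=0.0, stiffness=-1.0, window_id=0)


def _angle_samples(phis, thetas, window_id=None):
    return [
        ja.AngleSample(phi=float(p), theta=float(t), phi1=float(p), phi2=float(p),
                       theta1=float(t), theta2=float(t), window_id=window_id)
        for p, t in zip(phis, thetas)
    ]


def test_wham_single_unbiased_window_is_histogram(rng):
    phis = rng.uniform(100.0, 140.0, size=4000)
    thetas = rng.normal(0.0, 5.0, size=4000)
    samples = _angle_samples(phis, thetas)
    ls = ja.wham(samples)
    H, _, _ = np.histogram2d(phis, thetas,
                             bins=(ls.phi_edges, ls.theta_edges))
    occ = H > 0
    expect = -np.log(H[occ] / H.sum())
    got = ls.F[occ] + ls.norm_offset
    assert np.abs(got - expect).max() < 1e-9
    assert ls.probability().sum() == pytest.approx(1.0, abs=1e-9)
    assert ls.F[ls.occupied].min() == 0.0


def test_wham_duplicated_window_idempotent(rng):
    dens = sd.GaussianAngleDensity(120.0, 10.0, 0.0, 4.0)
    w0 = ja.BiasWindow(center=120.0, stiffness=0.05, window_id=0)
    w1 = ja.BiasWindow(center=120.0, stiffness=0.05, window_id=1)
    samples = sd.sample_angles(dens, [w0, w1], 4000, rng)
    ls2 = ja.wham(samples, [w0, w1])
    merged = [
        ja.AngleSample(s.phi, s.theta, s.phi1, s.phi2, s.theta1, s.theta2, 0)
        for s in samples
    ]
    ls1 = ja.wham(merged, [w0])
    occ = ls1.occupied & ls2.occupied
    assert np.abs(ls1.F[occ] - ls2.F[occ]).max() < 1e-6


def test_wham_gaussian_parameter_recovery(rng):
    """Windowed sampling of a known Gaussian density unbiases to the
    analytic free energy."""
    dens = sd.GaussianAngleDensity(120.0, 15.0, 0.0, 5.0)
    windows = [ja.BiasWindow(92.5 + 5.0 * k, 0.1, k) for k in range(12)]
    samples = sd.sample_angles(dens, windows, 15000, rng)
    ls = ja.wham(samples, windows, theta_edges=np.arange(-90.0, 90.01, 2.0))
    pm, tm = ls.minimum(refine=True)
    assert abs(pm - 120.0) <= 2.0
    assert abs(tm) <= 2.0
    occ = ls.counts >= 50
    PP, TT = np.meshgrid(ls.phi_centers, ls.theta_centers, indexing="ij")
    Fa = dens.analytic_free_energy(PP, TT)
    diff = ls.F[occ] - Fa[occ]
    diff -= np.average(diff, weights=ls.counts[occ])
    rms = np.sqrt(np.average(diff**2, weights=ls.counts[occ]))
    # per-bin sampling noise at the 50-count threshold is ~0.14 kT
    assert rms < 0.2
    assert ls.probability().sum() == pytest.approx(1.0, abs=1e-9)


def test_wham_disconnected_windows_flagged(rng):
    w0 = ja.BiasWindow(50.0, 0.5, 0)
    w1 = ja.BiasWindow(250.0, 0.5, 1)
    s0 = _angle_samples(rng.normal(50.0, 1.0, 500), rng.normal(0, 2, 500), 0)
    s1 = _angle_samples(rng.normal(250.0, 1.0, 500), rng.normal(0, 2, 500), 1)
    with pytest.warns(UserWarning, match="disconnected"):
        ls = ja.wham(s0 + s1, [w0, w1])
    assert ls.disconnected


def test_wham_no_samples_raises():
    with pytest.raises(AnalysisError):
        ja.wham([])


def test_marginal_profiles(rng):
    dens = sd.GaussianAngleDensity(120.0, 15.0, 0.0, 5.0)
    samples = sd.sample_angles(dens, None, 30000, rng)
    ls = ja.wham(samples)
    centers, prof = ja.marginal_profile(ls, "theta")
    # separable density: theta marginal minimum at 0 within one bin
    assert abs(centers[np.nanargmin(prof)]) <= 1.0
    # restriction to the full range equals the unrestricted marginal
    c2, prof2 = ja.marginal_profile(ls, "theta", restrict=(0.0, 360.0))
    assert np.allclose(prof, prof2, equal_nan=True)
    # restriction to a single phi row equals that row minus its minimum
    i = int(np.argmin(np.abs(ls.phi_centers - 120.0)))
    lo, hi = ls.phi_edges[i] + 0.01, ls.phi_edges[i + 1] - 0.01
    _, prof3 = ja.marginal_profile(ls, "theta", restrict=(lo, hi))
    row = ls.F[i].copy()
    occ = ls.occupied[i]
    expect = row[occ] - row[occ].min()
    assert np.abs(prof3[occ] - expect).max() < 1e-9
    with pytest.raises(AnalysisError):
        ja.marginal_profile(ls, "theta", restrict=(361.0, 362.0))


def test_restricted_theta_profile_from_junction_landscape(rng):
    """The 160-180 degree phi subregion yields its own theta profile."""
    dens = sd.GaussianAngleDensity(170.0, 10.0, 3.0, 4.0)
    samples = sd.sample_angles(dens, None, 20000, rng)
    ls = ja.wham(samples)
    centers, prof = ja.marginal_profile(ls, "theta", restrict=(160.0, 180.0))
    assert abs(centers[np.nanargmin(prof)] - 3.0) <= 1.5


def test_angle_sample_export(rng):
    _, traj, gt = sd.make_junction_ensemble(
        arm_bp=12, density=sd.GaussianAngleDensity(150, 5, 0, 2),
        n_samples=5, seed=3,
    )
    samples = ja.compute_angle_samples(traj, gt.junction_spec)
    df = ja.samples_to_dataframe(samples)
    assert list(df.columns) == [
        "frame", "window", "phi1", "phi2", "phi", "theta1", "theta2",
        "theta", "isomer",
    ]
    assert len(df) == 5


def test_branch_migration_guard(duplex16):
    _, traj, gt = sd.make_junction_ensemble(
        arm_bp=12, density=sd.GaussianAngleDensity(150, 5, 0, 2),
        n_samples=3, seed=4,
    )
    spec = gt.junction_spec
    good = cg_io.BasePairMap(
        pairs=[arm.pairs[0] for arm in spec.arms], provenance="design-derived"
    )
    migrated = cg_io.BasePairMap(pairs=[], provenance="design-derived")
    mask = ja.branch_migration_mask(traj, spec, [good, migrated, good])
    assert mask.tolist() == [True, False, True]
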