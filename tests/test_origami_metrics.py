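"""Weave/corrugation metrics against generator ground truth."""

import numpy as np
import pytest

from origametry import cg_io, origami_metrics as om, synthetic_data as sd
from origametry.errors import AnalysisError
from origametry.geometry import DEFAULT_GEOMETRY

from conftest import random_rigid


def _tile_axes(topo, traj, gt):
    return om.trajectory_axes(traj, gt.helix_pairs)


def test_triangular_theta_worked_example():
    """1.5 nm amplitude over 16 bp at 0.34 nm/bp gives 7.85 degrees."""
    assert om.triangular_theta(1.5, 16, 0.34) == pytest.approx(7.85, abs=0.05)


def test_triangular_theta_zero_amplitude():
    assert om.triangular_theta(0.0, 16, 0.34) == 0.0


def test_triangular_theta_algebraic_inverse():
    amp = 2.0 * (16 * 0.34) * np.tan(np.radians(5.0))
    assert om.triangular_theta(amp, 16, 0.34) == pytest.approx(5.0, abs=1e-9)


def test_triangular_theta_invalid_args():
    with pytest.raises(ValueError):
        om.triangular_theta(1.5, 0, 0.34)
    with pytest.raises(ValueError):
        om.triangular_theta(1.5, 16, -1.0)


# ---------------------------------------------------------------------------
# helix axes


def test_helix_axes_ideal_duplex_collinear(duplex16):
    topo, frame, gt = duplex16
    axes = om.helix_axes(frame, gt.helix_pairs)
    pts = axes["0"].points
    centred = pts - pts.mean(axis=0)
    _, s, _ = np.linalg.svd(centred)
    assert s[1] < 0.05  # off-axis scatter below 0.05 nm
    assert np.abs(pts - np.asarray(gt.centerlines["0"])).max() < 1e-9


def test_helix_axes_masks_frayed_pairs(duplex16):
    topo, frame, gt = duplex16
    full = cg_io.detect_base_pairs(frame, topo)
    frayed = cg_io.BasePairMap(pairs=full.pairs[2:], provenance="geometry-derived")
    axes = om.helix_axes(frame, gt.helix_pairs, pair_map=frayed)
    mask = axes["0"].mask
    assert (~mask[:2]).all() and mask[2:].all()


def test_helix_axes_excludes_sparse_helix(duplex16):
    topo, frame, gt = duplex16
    few = cg_io.BasePairMap(pairs=[(0, 31), (1, 30)], provenance="geometry-derived")
    with pytest.warns(UserWarning, match="excluded"):
        axes = om.helix_axes(frame, gt.helix_pairs, pair_map=few)
    assert "0" not in axes


def test_helix_axes_follow_generator_centerline():
    topo, traj, gt = sd.make_tile(n_helices=4, bp_per_helix=64,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  seed=0)
    axes = om.helix_axes(traj[0], gt.helix_pairs)
    for label, ax in axes.items():
        assert np.abs(ax.points - np.asarray(gt.centerlines[label])).max() < 0.1


# ---------------------------------------------------------------------------
# weave


def test_weave_flat_parallel_helices():
    geom = DEFAULT_GEOMETRY.with_(inter_helix_spacing=2.6)
    topo, traj, gt = sd.make_tile(n_helices=2, bp_per_helix=64,
                                  junction_spacing=32, weave_amplitude=0.0,
                                  seed=0, geom=geom)
    axes = _tile_axes(topo, traj, gt)
    prof = om.weave_profile(axes, [("0", "1")])[0]
    assert np.allclose(prof.mean, 2.6, atol=1e-9)
    assert np.allclose(prof.std, 0.0, atol=1e-12)


def test_weave_triangular_amplitude_and_minima():
    topo, traj, gt = sd.make_tile(n_helices=4, bp_per_helix=96,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  seed=0)
    axes = _tile_axes(topo, traj, gt)
    prof = om.weave_profile(axes, [("1", "2")])[0]
    assert np.nanmax(prof.mean) - np.nanmin(prof.mean) == pytest.approx(1.5, abs=0.02)
    stats = om.weave_waveform_stats(prof.mean)
    crossings = gt.crossovers["1"]  # pair (1,2) is group 1
    assert set(stats.minima.tolist()) <= set(crossings)


def test_weave_noise_std_matches_propagation(rng):
    """Axis-point noise sigma propagates to sqrt(2) sigma distance spread."""
    sigma = 0.2
    topo, traj, gt = sd.make_tile(n_helices=3, bp_per_helix=64,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  noise_sigma=sigma, n_frames=300, seed=7)
    axes = _tile_axes(topo, traj, gt)
    prof = om.weave_profile(axes, [("0", "1")])[0]
    expect = np.sqrt(2.0) * sigma
    assert np.nanmean(prof.std) == pytest.approx(expect, rel=0.15)


def test_weave_pair_order_symmetric():
    topo, traj, gt = sd.make_tile(n_helices=3, bp_per_helix=64, seed=1)
    axes = _tile_axes(topo, traj, gt)
    p_ab = om.weave_profile(axes, [("0", "1")])[0]
    p_ba = om.weave_profile(axes, [("1", "0")])[0]
    assert np.allclose(p_ab.mean, p_ba.mean, equal_nan=True)


def test_waveform_stats_periods():
    i = np.arange(96)
    tri = sd._triangle_wave(i, 32)
    st = om.weave_waveform_stats(2.6 + 0.75 * tri)
    assert st.period_bp == pytest.approx(32, abs=1)
    assert st.amplitude == pytest.approx(1.5, abs=0.05)

    sine = 2.6 + 0.5 * np.sin(2 * np.pi * np.arange(84) / 21.0)
    st2 = om.weave_waveform_stats(sine)
    assert st2.period_bp == pytest.approx(21, abs=1)

    st3 = om.weave_waveform_stats(np.full(64, 2.6))
    assert st3.aperiodic


# ---------------------------------------------------------------------------
# corrugation


def test_corrugation_planar_tile_is_flat():
    topo, traj, gt = sd.make_tile(n_helices=6, bp_per_helix=128,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  corrugation_twist=0.0, seed=2)
    axes = _tile_axes(topo, traj, gt)
    prof = om.corrugation_profile(axes, gt.junctions, max_offset=8)
    assert np.nanmax(np.abs(prof.mean_curve)) < 0.2


@pytest.mark.parametrize("delta", [1.0, 3.0, 5.0])
def test_corrugation_twist_recovered(delta):
    """Junction twist 2*delta appears as an antisymmetric profile
    reaching -delta on one side and +delta on the other."""
    topo, traj, gt = sd.make_tile(n_helices=6, bp_per_helix=128,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  corrugation_twist=2 * delta, seed=3)
    axes = _tile_axes(topo, traj, gt)
    prof = om.corrugation_profile(axes, gt.junctions, max_offset=8)
    m = prof.mean_curve
    pos = prof.offsets > 0
    neg = prof.offsets < 0
    assert np.nanmin(m[pos]) == pytest.approx(-delta, abs=0.5)
    assert np.nanmax(m[neg]) == pytest.approx(delta, abs=0.5)
    # antisymmetry about the junction midpoint
    assert np.nanmax(np.abs(m + m[::-1])) < 0.2


def test_corrugation_mirror_negates():
    topo, traj, gt = sd.make_tile(n_helices=6, bp_per_helix=128,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  corrugation_twist=6.0, seed=4)
    axes = _tile_axes(topo, traj, gt)
    prof = om.corrugation_profile(axes, gt.junctions, max_offset=8)
    mirrored = [
        {
            lbl: om.HelixAxis(lbl, ax.indices, ax.points * [1.0, 1.0, -1.0], ax.mask)
            for lbl, ax in fr.items()
        }
        for fr in axes
    ]
    prof_m = om.corrugation_profile(mirrored, gt.junctions, max_offset=8)
    assert np.allclose(prof.mean_curve, -prof_m.mean_curve, atol=1e-9,
                       equal_nan=True)


def test_corrugation_requires_junctions():
    topo, traj, gt = sd.make_tile(n_helices=4, bp_per_helix=64, seed=5)
    axes = _tile_axes(topo, traj, gt)
    edge_only = [j for j in gt.junctions if j.edge]
    with pytest.raises(AnalysisError):
        om.corrugation_profile(axes, edge_only, canonical_only=True)


def test_seam_doubles_group_opening():
    topo, traj, gt = sd.make_tile(n_helices=6, bp_per_helix=160,
                                  junction_spacing=32, weave_amplitude=1.0,
                                  seam=True, seed=6)
    assert any(j.seam for j in gt.junctions)
    axes = _tile_axes(topo, traj, gt)
    prof0 = om.weave_profile(axes, [("2", "3")])[0]  # a group-0 pair
    seam_idx = gt.spec.params["seam_index"]
    # the group with the removed crossover opens beyond the normal maximum
    normal_max = DEFAULT_GEOMETRY.inter_helix_spacing + 0.5 * 1.0
    assert np.nanmax(prof0.mean[seam_idx - 16 : seam_idx + 16]) > normal_max + 0.2


def test_splay_round_trip_through_waveform():
    """Generator splay -> weave amplitude -> triangular_theta recovery."""
    for splay in [2.0, 5.0, 8.0, 12.0]:
        amp = 2.0 * 16 * DEFAULT_GEOMETRY.rise * np.tan(np.radians(splay))
        topo, traj, gt = sd.make_tile(n_helices=4, bp_per_helix=96,
                                      junction_spacing=32,
                                      weave_amplitude=amp, seed=8)
        axes = _tile_axes(topo, traj, gt)
        prof = om.weave_profile(axes, [("1", "2")])[0]
        stats = om.weave_waveform_stats(prof.mean)
        est = om.triangular_theta(stats.amplitude, stats.period_bp / 2.0,
                                  DEFAULT_GEOMETRY.rise)
        assert est == pytest.approx(splay, abs=0.3)


def test_profiles_rigid_motion_invariant(rng):
    topo, traj, gt = sd.make_tile(n_helices=4, bp_per_helix=64,
                                  junction_spacing=32, weave_amplitude=1.5,
                                  corrugation_twist=4.0, seed=9)
    axes = _tile_axes(topo, traj, gt)
    w_ref = om.weave_profile(axes, [("1", "2")])[0].mean
    c_ref = om.corrugation_profile(axes, gt.junctions, max_offset=6).mean_curve
    R, t = random_rigid(rng)
    moved = cg_io.Trajectory(
        topology=topo, frames=[fr.transformed(R, t) for fr in traj.frames]
    )
    axes_m = om.trajectory_axes(moved, gt.helix_pairs)
    w_m = om.weave_profile(axes_m, [("1", "2")])[0].mean
    c_m = om.corrugation_profile(axes_m, gt.junctions, max_offset=6).mean_curve
    assert np.allclose(w_ref, w_m, rtol=1e-6, atol=1e-9, equal_nan=True)
    assert np.allclose(c_ref, c_m, rtol=1e-6, atol=1e-6, equal_nan=True)
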