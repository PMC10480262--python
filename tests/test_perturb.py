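"""The six scenario operators: identities, sign conventions and invariants."""

import numpy as np
import pytest

import brachyrobust as br
from brachyrobust.case import Structure
from brachyrobust.needles import build_needle_path, nearest_path_index
from brachyrobust.perturb import ContourCollapseError


def circle_structure(radius, z_levels, n=24, cx=0.0, cy=0.0, width=None):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    slices = [
        np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang),
                         np.full(n, z)])
        for z in z_levels
    ]
    if width is None:
        width = z_levels[1] - z_levels[0] if len(z_levels) > 1 else 1.0
    return Structure(slices, width)


def sphere_structure(radius, width=1.0, n=48):
    z = np.arange(-radius + width / 2, radius, width)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    slices = []
    for zz in z:
        r = np.sqrt(radius**2 - zz**2)
        slices.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(n, zz)]))
    return Structure(slices, width)


def arc_coordinates(dwells, paths):
    out = []
    for i, path in enumerate(paths):
        for p in dwells.positions[i]:
            out.append(path.arclengths[nearest_path_index(path, p)])
    return np.array(out)


# -- parameter 1 ------------------------------------------------------------


def test_shift_zero_is_identity(small_case, small_paths):
    shifted = br.shift_dwells_along_needle(small_case.dwells, small_paths, 0.0)
    for a, b in zip(shifted.positions, small_case.dwells.positions):
        assert np.max(np.linalg.norm(a - b, axis=1)) < 0.01


def test_shift_positive_moves_toward_tip():
    tip = np.array([0.0, 0.0, 0.0])
    dwells = br.DwellSet([[[0, 0, -5.0], [0, 0, -10.0]]], [[1.0, 1.0]], [tip])
    path = build_needle_path(tip, dwells.positions[0])
    shifted = br.shift_dwells_along_needle(dwells, [path], 2.0)
    # dwell formerly 5 mm from the tip ends up 3 mm from it
    assert np.linalg.norm(shifted.positions[0][0] - tip) == pytest.approx(3.0, abs=0.02)


def test_shift_decreases_arc_coordinates_on_phantom(small_case, small_paths):
    before = arc_coordinates(small_case.dwells, small_paths)
    shifted = br.shift_dwells_along_needle(small_case.dwells, small_paths, 2.47)
    after = arc_coordinates(shifted, small_paths)
    # the worst-case superior move: every arc-length coordinate drops by 2.47
    np.testing.assert_allclose(before - after, 2.47, atol=0.02)


def test_shift_clamps_at_path_end_with_warning():
    tip = np.array([0.0, 0.0, 0.0])
    dwells = br.DwellSet([[[0, 0, -1.0]]], [[1.0]], [tip])
    path = build_needle_path(tip, dwells.positions[0])
    with pytest.warns(UserWarning, match="clamped"):
        shifted = br.shift_dwells_along_needle(dwells, [path], 5.0)
    np.testing.assert_allclose(shifted.positions[0][0], tip, atol=1e-9)


# -- parameter 2 ------------------------------------------------------------


def test_scale_prostate_zero_is_identity():
    s = sphere_structure(15.0, width=2.5)
    out = br.scale_prostate(s, 0.0)
    assert out.n_slices == s.n_slices
    for a, b in zip(out.slices, s.slices):
        assert np.max(np.linalg.norm(a - b, axis=1)) < 0.05


def test_scale_prostate_sphere_radii():
    s = sphere_structure(20.0, width=2.0)
    out = br.scale_prostate(s, 2.0)
    centre = s.centroid()
    for sl in out.slices:
        r = np.linalg.norm(sl - centre, axis=1)
        np.testing.assert_allclose(r, 22.0, atol=0.1)
    # slice spacing and centring preserved
    assert np.allclose(np.diff(out.slice_z()), 2.0, atol=1e-6)


def test_scale_prostate_enlarges_volume(small_case):
    import shapely

    def stacked_volume(s):
        return sum(shapely.Polygon(sl[:, :2]).area for sl in s.slices) * s.slice_width

    s = small_case.contours["prostate"]
    grown = br.scale_prostate(s, 1.65)
    assert stacked_volume(grown) > stacked_volume(s)


def test_scale_prostate_collapse_raises():
    s = sphere_structure(5.0, width=1.0)
    with pytest.raises(ContourCollapseError):
        br.scale_prostate(s, -6.0)


# -- parameter 3 ------------------------------------------------------------


def test_slicewise_circle_exact():
    s = circle_structure(2.5, [0.0, 1.0, 2.0])
    out = br.scale_structure_slicewise(s, 0.5)
    for sl in out.slices:
        c = sl.mean(axis=0)
        np.testing.assert_allclose(np.linalg.norm(sl - c, axis=1), 3.0, atol=1e-9)
        np.testing.assert_allclose(sl[:, 2], sl[0, 2])  # z untouched


def test_slicewise_zero_identity():
    s = circle_structure(4.0, [0.0, 2.0])
    out = br.scale_structure_slicewise(s, 0.0)
    for a, b in zip(out.slices, s.slices):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_slicewise_ellipse_contraction_moves_each_vertex_inward(rng):
    ang = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    sl = np.column_stack([8 * np.cos(ang), 5 * np.sin(ang), np.zeros(32)])
    s = Structure([sl], 1.0)
    out = br.scale_structure_slicewise(s, -0.3)
    c = sl.mean(axis=0)
    before = np.linalg.norm(sl - c, axis=1)
    after = np.linalg.norm(out.slices[0] - out.slices[0].mean(axis=0), axis=1)
    np.testing.assert_allclose(before - after, 0.3, atol=1e-9)


def test_slicewise_roundtrip_exact():
    s = circle_structure(4.0, [0.0, 1.5, 3.0])
    back = br.scale_structure_slicewise(br.scale_structure_slicewise(s, 0.7), -0.7)
    for a, b in zip(back.slices, s.slices):
        np.testing.assert_allclose(a, b, atol=1e-9)


def test_slicewise_collapse_names_slice():
    s = circle_structure(1.0, [0.0, 1.0])
    with pytest.raises(ContourCollapseError, match="slice 0"):
        br.scale_structure_slicewise(s, -1.5)


# -- parameter 4 ------------------------------------------------------------


def test_translate_needles(small_case):
    n = small_case.dwells.n_needles
    vecs = np.zeros((n, 2))
    vecs[0] = [1.0, -2.0]
    out = br.translate_needles_transverse(small_case.dwells, vecs)
    d = out.positions[0] - small_case.dwells.positions[0]
    np.testing.assert_allclose(d, [[1.0, -2.0, 0.0]] * len(d))
    for i in range(1, n):
        np.testing.assert_allclose(out.positions[i], small_case.dwells.positions[i])


def test_translate_zero_identity_and_count_mismatch(small_case):
    n = small_case.dwells.n_needles
    out = br.translate_needles_transverse(small_case.dwells, np.zeros((n, 2)))
    for a, b in zip(out.positions, small_case.dwells.positions):
        np.testing.assert_allclose(a, b)
    with pytest.raises(ValueError, match="vectors"):
        br.translate_needles_transverse(small_case.dwells, np.zeros((n + 1, 2)))


def test_translate_posterior_shift(small_case):
    n = small_case.dwells.n_needles
    out = br.translate_needles_transverse(small_case.dwells, np.tile([0.0, 0.82], (n, 1)))
    for a, b in zip(out.positions, small_case.dwells.positions):
        np.testing.assert_allclose(a[:, 1] - b[:, 1], 0.82)
        np.testing.assert_allclose(a[:, 2], b[:, 2])


# -- parameter 5 ------------------------------------------------------------


def test_adjust_times():
    out, clipped = br.adjust_dwell_times([np.array([10.0])], 1.072, 0.0)
    assert out[0][0] == pytest.approx(10.72)
    assert clipped == 0
    out, clipped = br.adjust_dwell_times([np.array([1.0, 2.0])], 1.0, 0.0)
    np.testing.assert_allclose(out[0], [1.0, 2.0])
    out, clipped = br.adjust_dwell_times([np.array([0.03])], 1.0, -0.06)
    assert out[0][0] == 0.0
    assert clipped == 1
    with pytest.raises(ValueError):
        br.adjust_dwell_times([np.array([1.0])], 0.0, 0.0)


# -- parameter 6 ------------------------------------------------------------


def test_rigid_move_targets(small_case):
    v = np.array([0.1, 0.5, 0.0])
    out = br.rigid_move(small_case, v)
    for name in ("prostate", "urethra"):
        np.testing.assert_allclose(
            out.contours[name].centroid() - small_case.contours[name].centroid(), v,
            atol=1e-12)
    np.testing.assert_allclose(
        out.contours["rectum"].centroid(), small_case.contours["rectum"].centroid())
    np.testing.assert_allclose(
        out.dwells.all_positions() - small_case.dwells.all_positions(),
        np.tile(v, (small_case.dwells.n_dwells, 1)))


def test_rigid_move_preserves_relative_geometry(small_case, rng):
    v = rng.normal(size=3)
    out = br.rigid_move(small_case, v)
    a = np.vstack([small_case.dwells.all_positions(),
                   small_case.contours["prostate"].all_points()[:50]])
    b = np.vstack([out.dwells.all_positions(),
                   out.contours["prostate"].all_points()[:50]])
    ia, ib = a[::7], b[::7]
    da = np.linalg.norm(ia[:, None] - ia[None, :], axis=2)
    db = np.linalg.norm(ib[:, None] - ib[None, :], axis=2)
    np.testing.assert_allclose(da, db, atol=1e-9)


# -- composition ------------------------------------------------------------


def test_apply_scenario_never_mutates_input(small_case, small_paths):
    h = small_case.content_hash()
    params = br.ScenarioParams(
        p1_shift=1.0, p2_prostate=0.5, p3_urethra=0.2, p3_rectum=-0.3,
        p4_transverse=np.ones((small_case.dwells.n_needles, 2)),
        p5_scale=1.05, p5_offset=0.02, p6_rigid=[0.1, 0.2, 0.0],
    )
    br.apply_scenario(small_case, small_paths, params)
    assert small_case.content_hash() == h


def test_apply_scenario_zero_params_is_identity(small_case, small_paths):
    out = br.apply_scenario(small_case, small_paths, br.ScenarioParams())
    np.testing.assert_allclose(out.dwells.all_positions(),
                               small_case.dwells.all_positions())
    for name in ("prostate", "urethra", "rectum"):
        for a, b in zip(out.contours[name].slices, small_case.contours[name].slices):
            np.testing.assert_allclose(a, b)


def test_scenario_params_validation():
    with pytest.raises(ValueError):
        br.ScenarioParams(p5_scale=0.0)
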