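import numpy as np
import pytest

from mapmorph.density import MapGrid, calc_model_map, AtomDensityModel
from mapmorph.model_io import Atom, Chain, Residue, Structure, UnitCell
from mapmorph.morph_engine import (
    EmptyNeighborhoodError, MorphConfig, extract_shift, local_cc,
    local_model_map, overlap_function, residue_shift_search,
)
from mapmorph.synthetic import make_helix

from conftest import make_residue


def brute_force_overlap(local: np.ndarray, target: np.ndarray) -> np.ndarray:
    """O(x) = sum_g local(g - x) target(g), by explicit cyclic shifts."""
    dims = local.shape
    out = np.zeros(dims)
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                out[i, j, k] = np.sum(np.roll(local, (i, j, k), axis=(0, 1, 2)) * target)
    return out


def signed_offsets(grid: MapGrid):
    """Independent origin-wrapped offset vectors for every grid point."""
    dims = grid.dims
    out = np.zeros(dims + (3,))
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                f = np.array([i / dims[0], j / dims[1], k / dims[2]])
                f[f > 0.5] -= 1.0
                out[i, j, k] = grid.cell.orth_matrix @ f
    return out


# -------------------------------------------------------- overlap_function

@pytest.mark.parametrize("n", [8, 12])
def test_overlap_fft_equals_brute_force(n):
    rng = np.random.default_rng(n)
    cell = UnitCell(float(n), float(n), float(n))
    local = MapGrid(cell, rng.normal(size=(n, n, n)))
    target = MapGrid(cell, rng.normal(size=(n, n, n)))
    o = overlap_function(local, target).values
    o_bf = brute_force_overlap(local.values, target.values)
    assert np.abs(o - o_bf).max() <= 1e-6 * np.abs(o_bf).max()


def test_overlap_self_peaks_at_origin():
    rng = np.random.default_rng(0)
    cell = UnitCell(12, 12, 12)
    m = MapGrid(cell, rng.normal(size=(12, 12, 12)))
    o = overlap_function(m, m).values
    assert np.unravel_index(np.argmax(o), o.shape) == (0, 0, 0)


def test_overlap_translation_equivariance():
    rng = np.random.default_rng(1)
    cell = UnitCell(12, 12, 12)
    base = rng.normal(size=(12, 12, 12))
    local = MapGrid(cell, base)
    shift = (3, 1, 5)
    target = MapGrid(cell, np.roll(base, shift, axis=(0, 1, 2)))
    o = overlap_function(local, target).values
    assert np.unravel_index(np.argmax(o), o.shape) == shift


def test_overlap_dimension_mismatch():
    cell = UnitCell(12, 12, 12)
    a = MapGrid(cell, np.zeros((12, 12, 12)))
    b = MapGrid(cell, np.zeros((8, 8, 8)))
    with pytest.raises(ValueError):
        overlap_function(a, b)


# ----------------------------------------------------------- extract_shift

def test_extract_shift_delta_spike():
    cell = UnitCell(16, 16, 16)
    vals = np.zeros((16, 16, 16))
    vals[1, 0, 0] = 5.0
    o = MapGrid(cell, vals)
    dx_max, dx_cent, no_peak = extract_shift(o, r_max=2.0)
    assert not no_peak
    np.testing.assert_allclose(dx_max, [1.0, 0.0, 0.0])
    np.testing.assert_allclose(dx_cent, [1.0, 0.0, 0.0], atol=1e-12)


def test_extract_shift_symmetric_centroid_at_origin():
    cell = UnitCell(16, 16, 16)
    m = MapGrid(cell, np.zeros((16, 16, 16)))
    offs = signed_offsets(m)
    r2 = np.einsum("...i,...i->...", offs, offs)
    vals = np.exp(-r2 / 2.0)
    o = MapGrid(cell, vals)
    dx_max, dx_cent, no_peak = extract_shift(o, r_max=2.0)
    np.testing.assert_allclose(dx_max, [0.0, 0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(dx_cent, [0.0, 0.0, 0.0], atol=1e-9)


def test_extract_shift_respects_r_max_and_matches_brute_force():
    """A strong optimum outside r_max must not be chosen; the in-ball argmax must."""
    rng = np.random.default_rng(4)
    cell = UnitCell(16, 16, 16)
    vals = rng.random((16, 16, 16))
    vals[5, 0, 0] = 50.0  # 5 A from origin, outside r_max = 2
    o = MapGrid(cell, vals)
    dx_max, dx_cent, no_peak = extract_shift(o, r_max=2.0)
    assert np.linalg.norm(dx_max) <= 2.0 + 1e-9
    assert np.linalg.norm(dx_cent) <= 2.0 + 1e-9
    # brute-force argmax over the ball
    offs = signed_offsets(o)
    r2 = np.einsum("...i,...i->...", offs, offs)
    ball = r2 <= 4.0
    bf_idx = np.unravel_index(np.argmax(np.where(ball, vals, -np.inf)), vals.shape)
    np.testing.assert_allclose(dx_max, offs[bf_idx], atol=1e-9)


def test_extract_shift_no_positive_overlap():
    cell = UnitCell(16, 16, 16)
    o = MapGrid(cell, -np.ones((16, 16, 16)))
    dx_max, dx_cent, no_peak = extract_shift(o, r_max=2.0)
    assert no_peak
    np.testing.assert_allclose(dx_max, 0.0)
    np.testing.assert_allclose(dx_cent, 0.0)


def test_extract_shift_radius_vs_cell_guard():
    cell = UnitCell(8, 8, 8)
    o = MapGrid(cell, np.ones((8, 8, 8)))
    with pytest.raises(ValueError, match="half"):
        extract_shift(o, r_max=4.5)


# --------------------------------------------------------- local_model_map

@pytest.fixture(scope="module")
def centered_atom():
    res = Residue(1, "ALA", [Atom("CA", "C", np.array([15.0, 15.0, 15.0]))])
    s = Structure([Chain("A", [res])], UnitCell(30, 30, 30))
    template = calc_model_map(s, d_min=3.0)
    return s, template


def test_local_map_zero_mean_inside(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    offs = local.min_image_offsets(center)
    inside = np.einsum("...i,...i->...", offs, offs) <= 36.0
    rms = np.sqrt(np.mean(local.values[inside] ** 2))
    assert abs(local.values[inside].mean()) <= 1e-10 * rms


def test_local_map_zero_outside_sphere(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    offs = local.min_image_offsets(center)
    outside = np.einsum("...i,...i->...", offs, offs) > 36.0
    assert np.all(local.values[outside] == 0.0)


def test_local_map_matches_gaussian_profile(centered_atom):
    """One atom at the centre: in-sphere profile = atom Gaussian minus its mean."""
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    offs = local.min_image_offsets(center)
    r2 = np.einsum("...i,...i->...", offs, offs)
    inside = r2 <= 36.0
    model = AtomDensityModel.for_atom(6, b=20.0, occ=1.0, d_min=3.0)
    expected = model.peak_height() * np.exp(-r2[inside] / (2 * model.sigma**2))
    expected -= expected.mean()
    # the implementation truncates the Gaussian at 4.5 sigma; tolerance covers it
    assert np.abs(local.values[inside] - expected).max() <= 1e-4 * model.peak_height()


def test_local_map_empty_neighborhood(centered_atom):
    s, template = centered_atom
    with pytest.raises(EmptyNeighborhoodError):
        local_model_map(s, np.array([2.0, 2.0, 2.0]), 6.0, template)


# ---------------------------------------------------------------- local_cc

def test_local_cc_self_match(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    cc = local_cc(template, local, np.zeros(3), 6.0, center)
    assert cc >= 0.99


def test_local_cc_scale_invariance(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    cc1 = local_cc(template, local, np.zeros(3), 6.0, center)
    scaled = MapGrid(local.cell, 7.3 * local.values, d_min=local.d_min)
    cc2 = local_cc(template, scaled, np.zeros(3), 6.0, center)
    assert cc1 == pytest.approx(cc2, abs=1e-12)


def test_local_cc_white_noise_small(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    n_below = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        noise = MapGrid(template.cell, rng.normal(size=template.dims))
        if abs(local_cc(noise, local, np.zeros(3), 6.0, center)) < 0.1:
            n_below += 1
    assert n_below >= 9


def test_local_cc_zero_variance_returns_zero(centered_atom):
    s, template = centered_atom
    center = np.array([15.0, 15.0, 15.0])
    local = local_model_map(s, center, 6.0, template)
    flat = MapGrid(template.cell, np.zeros(template.dims))
    assert local_cc(flat, local, np.zeros(3), 6.0, center) == 0.0


# ----------------------------------------------------- residue_shift_search

def test_search_self_consistency(helix20):
    target = calc_model_map(helix20, d_min=3.0)
    config = MorphConfig()
    shifts = residue_shift_search(helix20, target, config)
    assert len(shifts) == 20
    spacing = max(target.spacing)
    small = [np.linalg.norm(s.dx_max) <= spacing + 1e-9 for s in shifts]
    assert np.mean(small) >= 0.95
    assert all(-1.0 <= s.cc_local <= 1.0 for s in shifts)
    assert all(np.linalg.norm(s.dx_max) <= config.r_max + 1e-9 for s in shifts)


def test_search_recovers_rigid_translation(rigid_case):
    case = rigid_case
    t = case.field.translation
    shifts = residue_shift_search(case.start_model, case.target_map, case.config)
    errs = [np.linalg.norm(s.dx_cent - (-t)) for s in shifts]
    half_spacing = max(case.target_map.spacing) / 2
    assert np.median(errs) <= half_spacing


def test_search_shift_covariance(rigid_case):
    """Translating model and target by the same cell-commensurate vector
    leaves every shift unchanged."""
    case = rigid_case
    target = case.target_map
    k = 4  # grid steps along a
    tvec = target.orth_from_frac(np.array([k / target.dims[0], 0.0, 0.0]))
    moved = case.start_model.copy()
    moved.set_coords(moved.coords() + tvec)
    target2 = MapGrid(target.cell, np.roll(target.values, k, axis=0), d_min=target.d_min)
    s1 = residue_shift_search(case.start_model, target, case.config)
    s2 = residue_shift_search(moved, target2, case.config)
    for a, b in zip(s1, s2):
        np.testing.assert_allclose(a.dx_max, b.dx_max, atol=1e-9)
        np.testing.assert_allclose(a.dx_cent, b.dx_cent, atol=1e-6)
        assert a.cc_local == pytest.approx(b.cc_local, abs=1e-9)


def test_isolated_residue_excluded(helix20):
    target = calc_model_map(helix20, d_min=3.0)
    # a lone CA far from all density, in an empty map corner
    lone = Residue(100, "ALA", [Atom("CA", "C", np.array([2.0, 2.0, 2.0]))])
    s = Structure([Chain("Z", [lone])], helix20.cell)
    shifts = residue_shift_search(s, target, MorphConfig())
    assert len(shifts) == 1
    assert not shifts[0].included


def test_residue_without_center_atom_skipped(helix20):
    target = calc_model_map(helix20, d_min=3.0)
    no_ca = Residue(1, "ALA", [Atom("N", "N", np.array([15.0, 15.0, 15.0]))])
    s = Structure([Chain("A", [no_ca])], helix20.cell)
    assert residue_shift_search(s, target, MorphConfig()) == []


def test_config_validation():
    with pytest.raises(ValueError):
        MorphConfig(window=10)
    with pytest.raises(ValueError):
        MorphConfig(r_morph=-1.0)
    with pytest.raises(ValueError):
        MorphConfig(smooth_on="nope")
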