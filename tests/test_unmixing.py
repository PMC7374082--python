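"""NNLS unmixing: oracles, pipeline identity, noise recovery, residuals."""

import numpy as np
import pytest

import brightmux as bm

from conftest import absorbance_of


def grid_search_2dye(E2, a, c_max=3.0, step=1e-3):
    """Exhaustive minimizer of ||E c - a|| over the non-negative grid."""
    g = np.arange(0.0, c_max + 1e-9, step)
    Q = E2.T @ E2
    b = E2.T @ a
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    obj = (
        Q[0, 0] * G1**2
        + 2 * Q[0, 1] * G1 * G2
        + Q[1, 1] * G2**2
        - 2 * (b[0] * G1 + b[1] * G2)
    )
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return np.array([g[i], g[j]])


def test_identity_matrix_returns_input():
    cs = bm.ChannelSet(
        (bm.LightChannel("510", 510.0, 15.0), bm.LightChannel("620", 620.0, 19.0))
    )
    E = bm.ExtinctionMatrix(
        cs, (bm.Chromogen("a", "510"), bm.Chromogen("b", "620")), np.eye(2)
    )
    np.testing.assert_allclose(
        bm.unmix_pixel(np.array([0.3, 0.7]), E), [0.3, 0.7], atol=1e-12
    )


def test_one_dye_pixel_recovers_unit_vector(table1):
    a = table1.E @ np.array([1.0, 0, 0, 0, 0, 0])
    c = bm.unmix_pixel(a, table1)
    np.testing.assert_allclose(c, [1, 0, 0, 0, 0, 0], atol=1e-9)


def test_nnls_matches_exhaustive_grid_search(table1):
    """On a 2-dye subproblem with a deliberately inconsistent observation,
    NNLS agrees with a brute-force grid minimizer to grid resolution."""
    E2 = table1.select_chromogens(["dabsyl", "TAMRA"])
    a = np.full(6, 0.5)
    c_nnls = bm.unmix_pixel(a, E2)
    c_grid = grid_search_2dye(E2.E, a)
    np.testing.assert_allclose(c_nnls, c_grid, atol=2e-3)


def test_rank_deficient_matrix_names_collinear_columns(table1):
    cs = table1.channel_set
    col = table1.E[:, [0]]
    E = bm.ExtinctionMatrix(
        cs,
        (bm.Chromogen("dup1", "438"), bm.Chromogen("dup2", "438")),
        np.hstack([col, col]),
    )
    with pytest.raises(ValueError, match="dup1"):
        bm.unmix_pixel(np.full(6, 0.2), E)


def test_underdetermined_system_raises(table1):
    E_sub = table1.select_channels(["438", "549"])  # 2 channels, 6 chromogens
    with pytest.raises(ValueError, match="underdetermined"):
        bm.unmix_pixel(np.array([0.1, 0.2]), E_sub)


def test_noiseless_pipeline_identity(table1, exact_detector):
    """Phantom -> counts -> transmission -> absorbance -> NNLS returns the
    ground-truth concentration fields to numerical precision."""
    layout = bm.SceneLayout(shape=(96, 96), n_cells=10)
    scene = bm.make_scene(layout, table1, seed=11)
    A = absorbance_of(scene, exact_detector)
    assert (scene.truth.reshape(-1, 6) @ table1.E.T).max() < bm.ABSORBANCE_CEILING
    result = bm.unmix_stack(A, table1)
    np.testing.assert_allclose(result.values, scene.truth, atol=1e-6)
    assert result.residual.max() < 1e-8


def test_all_zero_stack_gives_zero_abundance(table1):
    A = bm.ImageStack(np.zeros((4, 4, 6)), "absorbance", table1.channel_set)
    result = bm.unmix_stack(A, table1)
    np.testing.assert_array_equal(result.values, 0.0)
    np.testing.assert_array_equal(result.residual, 0.0)


def test_noisy_recovery_of_biomarker_medians(table2):
    """8-bit shot-noise acquisition on the 12-channel LED system: stained-
    region median abundance of each biomarker chromogen is recovered within
    5%; the broad-spectrum counterstain, which takes the brunt of the NNLS
    non-negativity bias, within 10%."""
    E4 = table2.select_chromogens(["dabsyl", "Rhod110", "TAMRA", "HTX", "Cy5"])
    scene = bm.make_scene(bm.SceneLayout(), E4, seed=1)
    A = absorbance_of(scene, bm.DetectorModel(noise="poisson", quantize=True))
    result = bm.unmix_stack(A, E4)
    for k, name in enumerate(scene.chromogens):
        truth = scene.truth[:, :, k]
        stained = truth > 0
        ratio = np.median(result.values[:, :, k][stained]) / np.median(
            truth[stained]
        )
        tol = 0.10 if name == "HTX" else 0.05
        assert abs(ratio - 1) < tol, f"{name}: median ratio {ratio:.3f}"


def test_channel_subset_unmixing(table1, exact_detector):
    """A stack acquired on a declared subset of the matrix channels unmixes
    against the matching rows (C >= K still enforced)."""
    E3 = table1.select_chromogens(["dabsyl", "TAMRA", "Cy5"])
    scene = bm.make_scene(
        bm.SceneLayout(shape=(64, 64), n_cells=12, counterstain=None), E3, seed=4
    )
    A = absorbance_of(scene, exact_detector)
    labels = ["438", "549", "620", "676"]
    sub = bm.ImageStack(
        A.pixels[:, :, [table1.channel_set.index(l) for l in labels]],
        "absorbance",
        table1.channel_set.subset(labels),
    )
    result = bm.unmix_stack(sub, E3)
    np.testing.assert_allclose(result.values, scene.truth, atol=1e-6)
    with pytest.raises(ValueError, match="subset"):
        bm.unmix_stack(
            bm.ImageStack(A.pixels[:, :, :3], "absorbance",
                          bm.ChannelSet((bm.LightChannel("400", 400, 10),
                                         bm.LightChannel("500", 500, 10),
                                         bm.LightChannel("600", 600, 10)))),
            E3,
        )


def test_unmixing_linearity(table1):
    c1 = np.array([0.4, 0, 0.2, 0, 0.1, 0])
    c2 = np.array([0.1, 0.3, 0, 0.2, 0, 0.5])
    a = table1.E @ (c1 + c2)
    np.testing.assert_allclose(bm.unmix_pixel(a, table1), c1 + c2, atol=1e-9)


def test_chromogen_permutation_permutes_planes(table1, exact_detector):
    scene = bm.make_scene(bm.SceneLayout(shape=(48, 48), n_cells=8), table1, seed=9)
    A = absorbance_of(scene, exact_detector)
    base = bm.unmix_stack(A, table1)
    perm = list(table1.chromogen_names[::-1])
    permuted = bm.unmix_stack(A, table1.select_chromogens(perm))
    for name in perm:
        np.testing.assert_allclose(
            permuted.plane(name), base.plane(name), atol=1e-9
        )


def test_abundances_always_non_negative(table2, noisy_detector):
    scene = bm.make_scene(bm.SceneLayout(shape=(64, 64), n_cells=30), table2, seed=6)
    A = absorbance_of(scene, noisy_detector)
    for solver in (bm.unmix_stack, bm.pinv_unmix_stack):
        assert solver(A, table2).values.min() >= 0.0


# ---------------------------------------------------------------------------
# pseudo-inverse alternative
# ---------------------------------------------------------------------------


def test_pinv_agrees_with_nnls_on_interior_pixels(table1):
    """Where the NNLS solution is strictly positive the unconstrained
    pseudo-inverse solution coincides (KKT stationarity)."""
    c_true = np.array([0.5, 0.4, 0.6, 0.3, 0.2, 0.7])
    A = bm.ImageStack(
        np.tile(table1.E @ c_true, (2, 2, 1)), "absorbance", table1.channel_set
    )
    nnls_map = bm.unmix_stack(A, table1)
    pinv_map = bm.pinv_unmix_stack(A, table1)
    assert nnls_map.values.min() > 0
    np.testing.assert_allclose(pinv_map.values, nnls_map.values, atol=1e-9)


def test_pinv_one_dye_pixel_exact(table1):
    A = bm.ImageStack(
        table1.E[:, 2].reshape(1, 1, 6), "absorbance", table1.channel_set
    )
    c = bm.pinv_unmix_stack(A, table1).values[0, 0]
    np.testing.assert_allclose(c, np.eye(6)[2], atol=1e-9)


def test_pinv_error_not_better_than_nnls_on_noisy_phantom(table2, noisy_detector):
    scene = bm.make_scene(bm.SceneLayout(shape=(96, 96), n_cells=40), table2, seed=13)
    A = absorbance_of(scene, noisy_detector)
    err_nnls = np.abs(bm.unmix_stack(A, table2).values - scene.truth).mean()
    err_pinv = np.abs(bm.pinv_unmix_stack(A, table2).values - scene.truth).mean()
    assert err_pinv >= err_nnls


# ---------------------------------------------------------------------------
# residual metrics
# ---------------------------------------------------------------------------


def test_residual_metrics_noiseless_phantom_near_zero(table1, exact_detector):
    scene = bm.make_scene(bm.SceneLayout(shape=(64, 64), n_cells=6), table1, seed=21)
    A = absorbance_of(scene, exact_detector)
    assert (scene.truth.reshape(-1, 6) @ table1.E.T).max() < bm.ABSORBANCE_CEILING
    result = bm.unmix_stack(A, table1)
    m = bm.residual_metrics(A, result, table1)
    assert m.mean_abs_error <= 1e-9
    assert m.relative_error_pct <= 1e-7


def test_residual_of_all_zero_abundance_is_mean_absorbance(table1):
    rng = np.random.default_rng(5)
    px = rng.random((8, 8, 6))
    A = bm.ImageStack(px, "absorbance", table1.channel_set)
    zero_map = bm.AbundanceMap(
        np.zeros((8, 8, 6)), table1.chromogen_names
    )
    m = bm.residual_metrics(A, zero_map, table1)
    np.testing.assert_allclose(m.mean_abs_error, px.mean(), atol=1e-12)


def test_residual_metrics_rejects_empty_selection(table1):
    A = bm.ImageStack(
        np.ones((2, 2, 6)),
        "absorbance",
        table1.channel_set,
        valid=np.zeros((2, 2, 6), dtype=bool),
    )
    result = bm.unmix_stack(A, table1)
    with pytest.raises(ValueError, match="no unflagged"):
        bm.residual_metrics(A, result, table1, exclude_flagged=True)


def test_abundance_map_tiff_round_trip(tmp_path, table1, exact_detector):
    scene = bm.make_scene(bm.SceneLayout(shape=(32, 32), n_cells=5), table1, seed=2)
    result = bm.unmix_stack(absorbance_of(scene, exact_detector), table1)
    bm.write_abundance_map(result, tmp_path / "map.tif")
    back = bm.read_abundance_map(tmp_path / "map.tif")
    np.testing.assert_allclose(back.values, result.values, atol=1e-6)
    assert back.chromogens == result.chromogens
    np.testing.assert_allclose(back.residual, result.residual, atol=1e-6)
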