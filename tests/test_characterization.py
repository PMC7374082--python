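"""Auto-exposure, flat-field RMSD, knife-edge MTF and resolution."""

import numpy as np
import pytest

import brightmux as bm
from brightmux.characterization import ExposureError


# ---------------------------------------------------------------------------
# auto exposure
# ---------------------------------------------------------------------------


def linear_detector(gain, full=255.0, shape=(64, 64)):
    def capture(exposure):
        return np.clip(np.round(np.full(shape, gain * exposure)), 0, full)

    return capture


def test_auto_exposure_linear_detector_hits_target():
    """Closed-form oracle: a noiseless linear detector converges to a mean
    within tolerance of 0.875 * 255 = 223.1 counts."""
    r = bm.auto_exposure(linear_detector(13.7), 0.875, 1e-4, 8)
    assert abs(r.mean_intensity - 223.125) <= 0.02 * 255
    assert r.saturated_fraction <= 1e-4
    assert r.iterations <= 50
    # oracle: exposure such that gain * e = target
    assert r.exposure_ms == pytest.approx(223.125 / 13.7, rel=0.03)


def test_auto_exposure_immediate_when_already_at_target():
    r = bm.auto_exposure(lambda e: np.full((8, 8), 223.0), 0.875, 1e-4, 8)
    assert r.iterations == 1


def test_auto_exposure_overexposed_start_recovers():
    r = bm.auto_exposure(
        linear_detector(5000.0), 0.875, 1e-4, 8, initial_exposure=10.0
    )
    assert abs(r.mean_intensity - 223.125) <= 0.02 * 255


def test_auto_exposure_poisson_detector_reseeded_runs():
    """With shot noise (12-bit headroom), five independently seeded runs all
    converge within 2% of the target mean."""
    target = 0.875 * 4095
    for s in range(5):
        rng = np.random.default_rng(s)
        capture = lambda e: np.clip(
            rng.poisson(np.full((128, 128), 900.0 * e)), 0, 4095
        )
        r = bm.auto_exposure(capture, 0.875, 1e-4, 12)
        assert abs(r.mean_intensity / target - 1) < 0.02


def test_auto_exposure_all_saturated_raises():
    with pytest.raises(ExposureError, match="saturated"):
        bm.auto_exposure(
            lambda e: np.full((8, 8), 255.0), 0.875, 1e-4, 8,
            initial_exposure=1e-6,
        )


def test_auto_exposure_nonconvergence_reports_trace():
    # capture ignores exposure and sits far from target: cannot converge
    with pytest.raises(ExposureError, match="trace"):
        bm.auto_exposure(lambda e: np.full((8, 8), 100.0), 0.875, 1e-4, 8)


# ---------------------------------------------------------------------------
# flat-field RMSD
# ---------------------------------------------------------------------------


def _counts(values, channel_set):
    return bm.ImageStack(np.asarray(values, float), "counts", channel_set,
                         bit_depth=8)


def test_rmsd_constant_field_is_zero(mono_channel):
    assert bm.flatness_rmsd(_counts(np.full((8, 8, 1), 57.0), mono_channel)) == 0


def test_rmsd_half_and_half_closed_form(mono_channel):
    field = np.zeros((4, 4, 1))
    field[:2] = 2.0
    np.testing.assert_allclose(
        bm.flatness_rmsd(_counts(field, mono_channel)), [1.0]
    )


def test_rmsd_translation_invariant(mono_channel):
    rng = np.random.default_rng(2)
    field = rng.random((16, 16, 1)) * 30
    r0 = bm.flatness_rmsd(_counts(field, mono_channel))
    r1 = bm.flatness_rmsd(_counts(field + 100.0, mono_channel))
    np.testing.assert_allclose(r0, r1, atol=1e-9)


def test_rmsd_of_default_vignetted_blank(table1):
    """The default quadratic vignette (15% mid-edge falloff, ~220-count full
    scale) yields per-channel RMSDs in the tens of counts."""
    scene = bm.make_scene(bm.SceneLayout(n_cells=0), table1, seed=5)
    _, blank = bm.forward_model(scene, bm.DetectorModel())
    rmsd = bm.flatness_rmsd(blank)
    assert (rmsd > 10).all() and (rmsd < 30).all()


def test_rmsd_empty_image_raises(mono_channel):
    with pytest.raises(ValueError, match="empty"):
        bm.flatness_rmsd(_counts(np.empty((0, 0, 1)), mono_channel))


# ---------------------------------------------------------------------------
# knife-edge MTF and resolution
# ---------------------------------------------------------------------------


GAUSS_SIGMA = 2.0
F_CUTOFF_ANALYTIC = np.sqrt(np.log(1 / 0.03) / (2 * np.pi**2 * GAUSS_SIGMA**2))


@pytest.fixture(scope="module")
def gaussian_edge_curve(mono_channel):
    det = bm.DetectorModel(noise="none", quantize=False, illumination="flat")
    edge = bm.make_knife_edge(
        det, mono_channel, (128, 128), 64.37, GAUSS_SIGMA, seed=0
    )
    return bm.knife_edge_mtf(edge, "549")


def test_mtf_matches_gaussian_closed_form(gaussian_edge_curve):
    """For a Gaussian PSF of width sigma the MTF is exp(-2 pi^2 sigma^2 f^2);
    the estimator tracks it to 0.02 contrast at low-to-mid frequencies."""
    f = gaussian_edge_curve.frequencies
    sel = f <= 0.25
    oracle = np.exp(-2 * np.pi**2 * GAUSS_SIGMA**2 * f[sel] ** 2)
    assert np.abs(gaussian_edge_curve.contrast[sel] - oracle).max() <= 0.02


def test_mtf_zero_frequency_is_one(gaussian_edge_curve):
    assert gaussian_edge_curve.contrast[0] == 1.0
    assert gaussian_edge_curve.frequencies[0] == 0.0


def test_ideal_step_mtf_above_pixel_aperture_envelope(mono_channel):
    det = bm.DetectorModel(noise="none", quantize=False, illumination="flat")
    edge = bm.make_knife_edge(det, mono_channel, (128, 128), 64.37, 0.0, seed=0)
    curve = bm.knife_edge_mtf(edge, "549")
    envelope = np.abs(np.sinc(curve.frequencies))
    assert (curve.contrast >= envelope - 0.05).all()


def test_resolution_matches_analytic_cutoff(gaussian_edge_curve):
    """3% cutoff of a sigma=2 px Gaussian: f_c ~ 0.2107 cycles/px, i.e.
    ~1.33 um at a 0.28 um pixel pitch; pipeline within 2%."""
    res = bm.resolution_from_mtf(gaussian_edge_curve, 0.03, 0.28)
    assert res == pytest.approx(0.28 / F_CUTOFF_ANALYTIC, rel=0.02)


def test_resolution_invariant_to_edge_position_and_angle(mono_channel):
    det = bm.DetectorModel(noise="none", quantize=False, illumination="flat")
    reference = 1.0 / F_CUTOFF_ANALYTIC
    for pos, angle in [(40.1, 0.0), (90.77, 0.0), (64.37, -5.0), (64.37, 5.0)]:
        edge = bm.make_knife_edge(
            det, mono_channel, (128, 128), pos, GAUSS_SIGMA, seed=0,
            angle_deg=angle,
        )
        res = bm.resolution_from_mtf(bm.knife_edge_mtf(edge, "549"), 0.03, 1.0)
        assert res == pytest.approx(reference, rel=0.02)


def test_halving_sigma_doubles_cutoff_frequency(mono_channel):
    det = bm.DetectorModel(noise="none", quantize=False, illumination="flat")
    res = {}
    for sigma in (1.0, 2.0):
        edge = bm.make_knife_edge(
            det, mono_channel, (128, 128), 64.37, sigma, seed=0, angle_deg=4.0
        )
        res[sigma] = bm.resolution_from_mtf(
            bm.knife_edge_mtf(edge, "549"), 0.03, 1.0
        )
    assert res[2.0] / res[1.0] == pytest.approx(2.0, rel=0.05)


def test_cutoff_at_unity_contrast_raises(gaussian_edge_curve):
    with pytest.raises(ValueError, match="zero"):
        bm.resolution_from_mtf(gaussian_edge_curve, 1.0)


def test_curve_never_below_cutoff_raises():
    curve = bm.MTFCurve(np.linspace(0, 0.5, 11), np.linspace(1, 0.5, 11))
    with pytest.raises(ValueError, match="never drops"):
        bm.resolution_from_mtf(curve, 0.03)


def test_featureless_image_raises(mono_channel):
    flat = bm.ImageStack(
        np.full((32, 32, 1), 200.0), "counts", mono_channel, bit_depth=8
    )
    with pytest.raises(ValueError, match="no detectable edge"):
        bm.knife_edge_mtf(flat, "549")
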