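"""Shift-and-sum refocusing, perspective views, and depth mapping."""

import numpy as np
import pytest

from clm import OpticalConfig, estimate_gamma, visibility
from clm.correlation import CorrelationTensor, FrameStack
from clm.geometry import gamma_geometric
from clm.optics import detector_coords, simulate_arrays
from clm.phantoms import ThickSample, TransmissionMask, triple_slit
from clm.refocus import RefocusedImage, depth_map, refocus, refocus_stack, viewpoint

from tests.conftest import granule_mask, pinhole_mask


@pytest.fixture(scope="module")
def defocused_slit(config):
    """Wave-simulated stack of a d = 30 µm triple slit at z = -400 µm."""
    n, dx = 256, config.band_limit_spacing
    mask = triple_slit(30e-6, fov=n * dx, spacing=dx)
    sample = ThickSample(planes=((-400e-6, mask),))
    ia, ib, ca, cb = simulate_arrays(
        sample, config, 1500, seed=41, sim_size=n, bin_a=4, bin_b=16
    )
    return estimate_gamma(FrameStack(ia, ib, ca, cb)), ca


class TestRefocus:
    def test_focal_plane_refocus_equals_summed_correlation(self, focused_slit_gamma, config):
        ref = refocus(focused_slit_gamma, config.objective_focal, config)
        nb2 = len(focused_slit_gamma.coords_b) ** 2
        want = focused_slit_gamma.correlation_image() / nb2
        np.testing.assert_allclose(ref.values, want, rtol=1e-6)
        assert ref.z == 0.0

    def test_linear_in_tensor(self, focused_slit_gamma, config):
        scaled = CorrelationTensor(
            3.5 * focused_slit_gamma.values,
            focused_slit_gamma.coords_a,
            focused_slit_gamma.coords_b,
        )
        a = refocus(focused_slit_gamma, config.objective_focal + 1e-4, config)
        b = refocus(scaled, config.objective_focal + 1e-4, config)
        np.testing.assert_allclose(b.values, 3.5 * a.values, rtol=1e-12)

    def test_nonpositive_f_rejected(self, focused_slit_gamma, config):
        with pytest.raises(ValueError, match="f must be > 0"):
            refocus(focused_slit_gamma, 0.0, config)

    def test_fully_off_detector_remap_rejected(self, focused_slit_gamma, config):
        # f far below f_O scales coordinates so every sample leaves the ROI
        with pytest.raises(ValueError, match="outside the arm-a detector"):
            refocus(focused_slit_gamma, config.objective_focal * 1e-4, config)

    def test_defocused_slit_recovered_only_by_refocusing(self, defocused_slit, config):
        """A slit mask 400 µm out of focus: invisible in the raw correlation
        image, resolved after the shift-and-sum remap."""
        gamma, ca = defocused_slit
        d = 30e-6
        expected = np.array([-d, 0.0, d]) * config.magnification
        raw = gamma.correlation_image().mean(axis=0)
        rep_raw = visibility(raw / raw.max(), expected, coords=ca)
        ref = refocus(gamma, config.objective_focal - 400e-6, config)
        prof = ref.values.mean(axis=0)
        rep = visibility(prof / prof.max(), expected, coords=ca)
        assert rep.resolved and rep.visibility >= 0.10
        assert (rep_raw.visibility is None) or rep_raw.visibility < rep.visibility / 2

    def test_uniform_object_refocuses_flat(self, config):
        """Edge-overlap normalization: a laterally uniform object refocused
        off-plane stays flat (CV <= 2 % inside the FOV)."""
        n, dx = 128, config.band_limit_spacing
        vals = np.ones((n, n))
        sample = ThickSample(planes=((200e-6, TransmissionMask(vals, dx, n * dx)),))
        ca, cb = detector_coords(config, n, dx, 2, 8)
        # narrower arm-a ROI so every remapped argument stays on the mask, and
        # viewpoint cells restricted to the square inscribed in the pupil so
        # every cell carries unit transmission
        ca = ca[len(ca) // 4 : -len(ca) // 4]
        r_b = config.lens_arm_magnification * config.pupil_radius
        cb = cb[np.abs(cb) <= 0.9 * r_b / np.sqrt(2)]
        g = gamma_geometric(sample, config, ca, cb)
        ref = refocus(g, config.objective_focal + 200e-6, config)
        inner = ref.values[4:-4, 4:-4]
        assert inner.std() / inner.mean() <= 0.02


class TestViewpoint:
    def test_patch_outside_roi_rejected(self, focused_slit_gamma):
        cb = focused_slit_gamma.coords_b
        with pytest.raises(ValueError, match="patch"):
            viewpoint(focused_slit_gamma, (cb[0], cb[0]), patch=7)

    def test_three_granule_parallax_signs(self, config):
        """Perspective behavior of three granules: one at focus does not move;
        one between lens and focal plane shifts with the viewpoint; one beyond
        the focal plane shifts against it (detector coordinates)."""
        n, dx = 256, config.band_limit_spacing
        planes = (
            (-350e-6, pinhole_mask(n, dx, x0=-80e-6)),
            (0.0, pinhole_mask(n, dx, x0=0.0)),
            (350e-6, pinhole_mask(n, dx, x0=80e-6)),
        )
        sample = ThickSample(planes=planes)
        ca, cb = detector_coords(config, n, dx, 2, 8)
        g = gamma_geometric(sample, config, ca, cb)
        step = cb[1] - cb[0]
        views = [viewpoint(g, (jb * step, 0.0), patch=4, config=config) for jb in (-8, 8)]
        d_lens = views[1].lens_point[0] - views[0].lens_point[0]
        pitch = ca[1] - ca[0]

        def centroid_near(view, x_expected, half=28):
            iy = len(ca) // 2
            ix = int(np.argmin(np.abs(ca - x_expected)))
            lo = max(ix - half, 0)
            sl = view.values[iy - 3 : iy + 4, lo : ix + half].sum(axis=0)
            return (sl * ca[lo : ix + half]).sum() / sl.sum()

        shifts = {}
        for z0, x0 in ((-350e-6, -80e-6), (0.0, 0.0), (350e-6, 80e-6)):
            f = config.objective_focal + z0
            pos = []
            for v in views:
                x_exp = -(config.tube_focal / f) * (
                    x0
                    + (1 - f / config.objective_focal)
                    * v.center_b[0]
                    / config.lens_arm_magnification
                )
                pos.append(centroid_near(v, x_exp))
            shifts[z0] = pos[1] - pos[0]
        assert abs(shifts[0.0]) < 0.5 * pitch  # focal-plane granule pinned
        assert np.sign(shifts[-350e-6]) == np.sign(d_lens)  # before focus: same
        assert np.sign(shifts[350e-6]) == -np.sign(d_lens)  # beyond focus: opposite


class TestRefocusStackAndDepth:
    def test_single_element_stack_reduces_to_refocus(self, focused_slit_gamma, config):
        z = 150e-6
        one = refocus_stack(focused_slit_gamma, [z], config)
        direct = refocus(focused_slit_gamma, config.objective_focal + z, config)
        assert len(one) == 1
        np.testing.assert_array_equal(one[0].values, direct.values)

    def test_plane_order_preserved(self, focused_slit_gamma, config):
        zs = [-2e-4, 0.0, 2e-4]
        stack = refocus_stack(focused_slit_gamma, zs, config)
        assert [im.z for im in stack] == pytest.approx(zs)

    def test_wave_granule_depth_recovered(self, config):
        """A wave-simulated granule at z = -150 µm is localized by the focus
        metric within the axial resolution a / NA0 of its diameter."""
        n, dx = 256, config.band_limit_spacing
        x0 = 40e-6
        r0 = 20e-6
        sample = ThickSample(planes=((-150e-6, granule_mask(n, dx, x0=x0, r0=r0)),))
        ia, ib, ca, cb = simulate_arrays(
            sample, config, 2000, seed=13, sim_size=n, bin_a=4, bin_b=16
        )
        g = estimate_gamma(FrameStack(ia, ib, ca, cb))
        zs = np.linspace(-300e-6, 300e-6, 9)
        stack = refocus_stack(g, zs, config)
        zmap = depth_map(stack, window=15)
        ix = int(np.argmin(np.abs(ca + config.magnification * x0)))
        iy = len(ca) // 2
        tol = 2 * r0 / config.numerical_aperture
        assert abs(zmap[iy, ix] - (-150e-6)) <= tol

    def test_two_granule_depths_with_correct_signs(self, config):
        """Two granules straddling the focal plane (z = -310 µm and +200 µm)
        are both recovered with the right signs from one refocused stack."""
        n, dx = 256, config.band_limit_spacing
        r0 = 20e-6
        planes = (
            (-310e-6, granule_mask(n, dx, x0=-60e-6, r0=r0)),
            (200e-6, granule_mask(n, dx, x0=60e-6, r0=r0)),
        )
        sample = ThickSample(planes=planes)
        ca, cb = detector_coords(config, n, dx, 2, 16)
        g = gamma_geometric(sample, config, ca, cb)
        zs = np.linspace(-400e-6, 400e-6, 9)
        stack = refocus_stack(g, zs, config)
        zmap = depth_map(stack, window=19, smooth=1.0)
        iy = len(ca) // 2
        tol = 2 * r0 / config.numerical_aperture
        for z0, x0 in ((-310e-6, -60e-6), (200e-6, 60e-6)):
            ix = int(np.argmin(np.abs(ca + config.magnification * x0)))
            got = zmap[iy, ix]
            assert np.isfinite(got)
            assert np.sign(got) == np.sign(z0)
            assert abs(got - z0) <= tol

    def test_uniform_input_is_undefined_everywhere(self, config):
        flat = np.ones((32, 32))
        ca = np.arange(32) * 1e-6
        stack = [
            RefocusedImage(flat, ca, config.objective_focal + z, z, np.ones_like(flat))
            for z in (-1e-4, 0.0, 1e-4)
        ]
        zmap = depth_map(stack, window=5)
        assert np.all(np.isnan(zmap))

    def test_too_few_planes_rejected(self, config):
        flat = np.ones((8, 8))
        im = RefocusedImage(flat, np.arange(8.0), 0.03, 0.0, np.ones_like(flat))
        with pytest.raises(ValueError, match="at least 3"):
            depth_map([im, im])


class TestSnrScaling:
    def test_refocused_snr_grows_with_viewpoint_count(self, focused_slit_stack, config):
        """Summing k viewpoints with statistically independent noise raises
        the slit-profile SNR consistent with sqrt(k).  The estimator noise is
        measured directly as the difference between two independent
        half-stack estimates."""
        from clm import estimate_gamma

        halves = [
            estimate_gamma(focused_slit_stack.subset(slice(0, 4000))),
            estimate_gamma(focused_slit_stack.subset(slice(4000, 8000))),
        ]
        ca = halves[0].coords_a
        nb = len(halves[0].coords_b)
        cells = [(j // nb, j % nb) for j in range(nb * nb)]
        rng = np.random.default_rng(77)
        order = rng.permutation(len(cells))
        d = 30e-6
        m = config.magnification
        peak_sel = np.min(
            np.abs(ca[:, None] - (np.array([-d, 0, d]) * m)[None, :]), axis=1
        ) < 5e-6 * m
        snrs = {}
        for k in (4, 16, 64):
            vals = []
            for start in range(0, len(order) - k + 1, k):  # disjoint subsets
                profs = []
                for g in halves:
                    acc = np.zeros((len(ca), len(ca)))
                    for idx in order[start : start + k]:
                        jy, jx = cells[idx]
                        acc += g.values[:, :, jy, jx]
                    profs.append(acc.mean(axis=0))
                noise = np.sqrt(np.mean((profs[0] - profs[1]) ** 2) / 2)
                signal = ((profs[0] + profs[1]) / 2)[peak_sel].mean()
                vals.append(signal / noise)
            snrs[k] = np.mean(vals)
        r1 = snrs[16] / snrs[4]
        r2 = snrs[64] / snrs[16]
        assert 2 / 1.5 <= r1 <= 2 * 1.5
        assert 2 / 1.5 <= r2 <= 2 * 1.5
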