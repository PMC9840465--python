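"""EDF fusion, tile registration and mosaic stitching."""

import numpy as np
import pytest
from scipy import ndimage

from domescope.reconstruction import (
    edf_compose,
    focus_measure,
    register_tiles,
    stitch,
)
from domescope.scene import (
    ScenePars,
    ZStack,
    generate_scene,
    random_tile_jitter,
    render_zstack,
    tile_mosaic,
)


class TestFocusMeasure:
    def test_constant_image_scores_zero(self):
        img = np.full((32, 32), 7.0)
        assert np.all(focus_measure(img, "variance") == 0)
        assert np.allclose(focus_measure(img, "tenengrad"), 0)

    @pytest.mark.parametrize("method", ["variance", "tenengrad"])
    def test_sharp_beats_blurred(self, method):
        board = np.indices((64, 64)).sum(0) % 2 * 100.0
        blurred = ndimage.gaussian_filter(board, 2.0)
        assert focus_measure(board, method).mean() > \
            focus_measure(blurred, method).mean()

    def test_translation_equivariance_interior(self, textured_image):
        img = textured_image
        shifted = np.roll(img, (3, 5), axis=(0, 1))
        s1 = focus_measure(img)
        s2 = focus_measure(shifted)
        inner = (slice(10, -10), slice(10, -10))
        assert np.allclose(np.roll(s1, (3, 5), axis=(0, 1))[inner], s2[inner])

    def test_window_validation(self):
        img = np.zeros((16, 16))
        with pytest.raises(ValueError):
            focus_measure(img, window_px=4)
        with pytest.raises(ValueError):
            focus_measure(img, window_px=17)


class TestEdfCompose:
    @staticmethod
    def _stack_with_sharp_plane(texture, k, n_planes=4):
        planes = [
            texture if i == k else ndimage.gaussian_filter(texture, 2.5)
            for i in range(n_planes)
        ]
        return ZStack(data=np.stack(planes).astype(np.float32),
                      z_step_um=5.0, pixel_size_um=1.0)

    def test_sharp_plane_wins_almost_everywhere(self, textured_image):
        k = 2
        stack = self._stack_with_sharp_plane(textured_image, k)
        res = edf_compose(stack)
        fm = focus_measure(textured_image)
        textured = fm >= 0.25 * fm.mean()
        assert (res.height_map[textured] == k).mean() >= 0.99

    def test_identical_planes_tie_break_to_plane_zero(self, textured_image):
        data = np.stack([textured_image] * 3).astype(np.float32)
        stack = ZStack(data=data, z_step_um=5.0, pixel_size_um=1.0)
        res = edf_compose(stack)
        assert np.all(res.height_map == 0)

    def test_single_plane_passthrough_with_warning(self, textured_image):
        stack = ZStack(data=textured_image[None].astype(np.float32),
                       z_step_um=5.0, pixel_size_um=1.0)
        with pytest.warns(RuntimeWarning, match="single-plane"):
            res = edf_compose(stack)
        assert np.all(res.height_map == 0)
        assert np.allclose(res.composite, textured_image)

    def test_dome_apex_height_recovered(self, small_dome_scene):
        pars, gt, surface, ideal = small_dome_scene
        stack = render_zstack(ideal["brightfield"], surface, pars)
        res = edf_compose(stack)
        (cx, cy), r, apex = gt.domes[0]
        X, Y = np.meshgrid(*(np.arange(192) + 0.5,) * 2)
        apex_disc = (X - cx) ** 2 + (Y - cy) ** 2 <= (0.25 * r) ** 2
        mean_height = res.height_map[apex_disc].mean()
        base_plane = 0.0
        assert mean_height - base_plane == pytest.approx(
            apex / pars.z_step_um, abs=1.0
        )

    def test_height_map_fidelity_within_one_plane(self, small_dome_scene):
        pars, _, surface, ideal = small_dome_scene
        stack = render_zstack(ideal["brightfield"], surface, pars)
        res = edf_compose(stack)
        true_q = np.round(surface.height_um / pars.z_step_um).astype(int)
        fm = focus_measure(ideal["brightfield"])
        textured = fm >= 0.25 * fm.mean()
        frac = (np.abs(res.height_map - true_q) <= 1)[textured].mean()
        assert frac >= 0.95

    def test_noise_never_improves_height_accuracy(self, small_dome_scene):
        from dataclasses import replace

        pars, _, surface, ideal = small_dome_scene
        true_q = np.round(surface.height_um / pars.z_step_um).astype(int)
        fracs = []
        for noise in [(0.0, 0.0), (3.0, 1.0), (10.0, 0.25)]:
            p = replace(pars, noise=noise)
            stack = render_zstack(ideal["brightfield"], surface, p)
            res = edf_compose(stack)
            fracs.append((res.height_map == true_q).mean())
        assert fracs[0] >= fracs[1] >= fracs[2]


def _noise_free_tiles(seed=0, field=288.0, jitter_px=0):
    pars = ScenePars(
        field_size_um=field, n_planes=6, seed=seed,
        dome_specs=(((field / 2, field / 2), 40.0, 24.0),),
    )
    _, surface, ideal = generate_scene(pars)
    stack = render_zstack(ideal["brightfield"], surface, pars, add_noise=False)
    rng = np.random.default_rng(seed + 100)
    jit = (
        random_tile_jitter(stack, (2, 2), 0.2, jitter_px, rng)
        if jitter_px
        else np.zeros((2, 2, 2), dtype=int)
    )
    tiles = tile_mosaic(stack, (2, 2), 0.2, jitter=jit)
    comps = [edf_compose(t.stack) for t in tiles]
    nominal = [t.nominal_offset for t in tiles]
    return stack, tiles, comps, nominal, jit


class TestRegisterTiles:
    def test_exact_cuts_recover_zero_residuals(self):
        _, tiles, comps, nominal, _ = _noise_free_tiles()
        offs = register_tiles([c.composite for c in comps], nominal)
        assert np.array_equal(offs.residuals, np.zeros((4, 2), dtype=int))
        assert not offs.flagged.any()

    def test_injected_jitter_recovered_within_one_px(self):
        _, tiles, comps, nominal, jit = _noise_free_tiles(seed=3, jitter_px=3)
        offs = register_tiles([c.composite for c in comps], nominal)
        assert np.abs(offs.residuals - jit.reshape(4, 2)).max() <= 1

    def test_blank_tiles_fall_back_to_nominal_and_flag(self):
        blanks = [np.zeros((64, 64)) for _ in range(4)]
        nominal = [(0, 0), (0, 48), (48, 0), (48, 48)]
        offs = register_tiles(blanks, nominal)
        assert np.array_equal(offs.residuals, np.zeros((4, 2), dtype=int))
        # every non-anchor tile had no usable correlation
        assert offs.flagged.sum() == 3


class TestStitch:
    def test_single_tile_identity(self, textured_image):
        mosaic = stitch([textured_image], [(0, 0)], blend="nearest")
        assert np.array_equal(mosaic.composite, textured_image)

    def test_round_trip_is_bit_exact_with_nearest(self):
        stack, tiles, comps, nominal, _ = _noise_free_tiles()
        full = edf_compose(stack)
        offs = register_tiles([c.composite for c in comps], nominal)
        mosaic = stitch(comps, nominal, offs, blend="nearest")
        assert np.array_equal(mosaic.composite, full.composite)
        assert np.array_equal(mosaic.height_map, full.height_map)

    def test_feather_round_trip_high_correlation_on_noisy(self):
        pars = ScenePars(field_size_um=288.0, n_planes=6, seed=9,
                         dome_specs=(((144.0, 144.0), 40.0, 24.0),))
        _, surface, ideal = generate_scene(pars)
        stack = render_zstack(ideal["brightfield"], surface, pars)
        full = edf_compose(stack)
        tiles = tile_mosaic(stack, (2, 2), 0.2)
        comps = [edf_compose(t.stack) for t in tiles]
        nominal = [t.nominal_offset for t in tiles]
        offs = register_tiles([c.composite for c in comps], nominal)
        mosaic = stitch(comps, nominal, offs, blend="feather")
        r = np.corrcoef(mosaic.composite.ravel(), full.composite.ravel())[0, 1]
        assert r >= 0.999

    def test_height_mosaic_contains_only_input_plane_indices(self):
        _, tiles, comps, nominal, _ = _noise_free_tiles(seed=5, jitter_px=2)
        offs = register_tiles([c.composite for c in comps], nominal)
        mosaic = stitch(comps, nominal, offs, blend="nearest")
        in_vals = np.unique(np.concatenate([c.height_map.ravel() for c in comps]))
        assert set(np.unique(mosaic.height_map)) <= set(in_vals)

    def test_interior_gap_raises_with_location(self, textured_image):
        t = textured_image[:32, :32]
        with pytest.raises(ValueError, match="uncovered"):
            stitch([t, t], [(0, 0), (0, 40)], blend="nearest")

    def test_provenance_is_single_sourced(self):
        _, tiles, comps, nominal, _ = _noise_free_tiles()
        mosaic = stitch(comps, nominal, blend="nearest")
        assert mosaic.provenance.min() >= 0
        assert mosaic.provenance.max() <= 3
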