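"""Full model intensity: limits, mode agreement, contrast conservation."""

from dataclasses import replace

import numpy as np
import pytest

from vesiclesaxs.model import (
    BilayerProfile,
    QGrid,
    SizeDistribution,
    StackSpec,
    model_intensity,
    paracrystal_sf,
)


@pytest.fixture(scope="module")
def grid():
    return QGrid.default(n=120)


class TestLimits:
    def test_zero_scale_gives_flat_background(self, grid, etho_wi):
        m = replace(etho_wi, scale=1e-300, background=0.7)
        for mode in ("separated", "exact_sphere"):
            I = model_intensity(grid, m, mode=mode)
            assert np.allclose(I, 0.7, atol=1e-250)

    def test_zero_contrast_gives_flat_background(self, grid, etho_wi):
        rho_s = etho_wi.solvent.electron_density
        matched = BilayerProfile(0.66, 1.03, 0.16, rho_s, rho_s, rho_s)
        m = replace(etho_wi, bilayer=matched, background=0.3)
        for mode in ("separated", "exact_sphere"):
            I = model_intensity(grid, m, mode=mode)
            assert np.allclose(I, 0.3)

    def test_intensity_finite_and_at_least_background(self, grid, etho_wi, lipo_ei):
        for m in (etho_wi, lipo_ei):
            for mode in ("separated", "exact_sphere"):
                I = model_intensity(grid, m, mode=mode)
                assert np.all(np.isfinite(I))
                assert np.all(I >= m.background)

    def test_unilamellar_reduces_to_no_structure_factor(self, grid, etho_wi):
        # at N = 1 the paracrystal factor is identically one, so g_c is inert
        a = replace(etho_wi, stack=StackSpec(1, 14.0, 0.01))
        b = replace(etho_wi, stack=StackSpec(1, 14.0, 0.9))
        assert np.allclose(
            model_intensity(grid, a), model_intensity(grid, b), rtol=1e-12
        )

    def test_unknown_mode_rejected(self, grid, etho_wi):
        with pytest.raises(ValueError):
            model_intensity(grid, etho_wi, mode="spherical_cow")


class TestMultilamellarPeak:
    def test_local_maximum_near_first_order_position(self, etho_wi):
        # N = 5, low distortion: the lamellar interference produces a local
        # intensity maximum close to Q = 2 pi / c; the decaying form-factor
        # envelope shifts the apex slightly below the ideal position
        grid = QGrid.default(n=200)
        q = grid.values
        I = model_intensity(grid, etho_wi, mode="separated")
        q0 = 2 * np.pi / etho_wi.stack.c
        interior = np.arange(1, len(q) - 1)
        local = interior[(I[interior] >= I[interior - 1]) & (I[interior] >= I[interior + 1])]
        assert local.size >= 1
        assert np.min(np.abs(q[local] - q0)) <= 0.05 * q0


class TestModeAgreement:
    @pytest.mark.parametrize("r0", [200.0, 500.0])
    def test_exact_sphere_vs_separated_unilamellar(self, r0, etho_wi):
        # once polydispersity damps the core-radius fringes the planar
        # factorisation reproduces the coherent spherical sum
        grid = QGrid.default(n=100)
        m = replace(
            etho_wi,
            stack=StackSpec(1, 14.0, 0.14),
            size=SizeDistribution(r0, 0.1),
        )
        Ie = model_intensity(grid, m, mode="exact_sphere")
        Is = model_intensity(grid, m, mode="separated")
        assert np.max(np.abs(Ie / Is - 1)) < 0.02

    def test_multilamellar_modes_agree_band_integrated(self, etho_wi):
        # exact spherical stacking is a perfect lattice while the separated
        # mode damps interference minima paracrystallinally, so the pointwise
        # ratio oscillates; the band-integrated intensities must still match
        grid = QGrid.default(n=120)
        m = replace(
            etho_wi,
            stack=StackSpec(3, 14.0, 0.05),
            size=SizeDistribution(500.0, 0.1),
        )
        Ie = model_intensity(grid, m, mode="exact_sphere")
        Is = model_intensity(grid, m, mode="separated")
        q = grid.values
        ratio = np.trapezoid(Ie, q) / np.trapezoid(Is, q)
        assert 0.7 < ratio < 1.4
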