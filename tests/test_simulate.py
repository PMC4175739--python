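"""Mechanistic simulator: closed forms, bleach semantics, rendering, tables."""
import numpy as np
import pytest

from pcmfrap.exceptions import PcmFrapError
from pcmfrap.images import BleachEvent, ImageStack
from pcmfrap.simulate import (MechanisticParams, OpticsParams,
                              closed_form_distributed, default_distributed_params,
                              default_flux_params, render_movie,
                              simulate_bead_image, simulate_fixed_cell_table,
                              simulate_paired_rates, simulate_ring_chain,
                              steady_state_flux)


def flux3(J=1.0, a=0.1, k=0.01):
    return MechanisticParams(model_kind="flux", n_rings=3, ring_width=1.0,
                             J=J, transfer_rate=a, k_loss=k)


class TestRingChain:
    def test_steady_state_worked_example(self):
        # J=1, a=0.1, k=0.01: C1 = 1/0.11, C2 = C1*10/11, C3 = C2*10
        ss = steady_state_flux(flux3())
        assert np.allclose(ss, [1/0.11, (1/0.11)*(0.1/0.11), (1/0.11)*(0.1/0.11)*10])
        assert np.isclose(ss.sum(), 100.0)  # total mass J / k_loss

    def test_zero_influx_steady_state_is_empty(self):
        st = simulate_ring_chain(flux3(J=0.0), [0.0, 50.0], initial="zero")
        assert np.allclose(st.total, 0.0)

    def test_integration_converges_to_steady_state(self):
        p = flux3()
        st = simulate_ring_chain(p, [0.0, 4000.0], initial="zero")
        assert np.allclose(st.total[-1], steady_state_flux(p), rtol=1e-8)

    def test_full_bleach_zeroes_fluorescent_pool_only(self):
        p = flux3()
        ev = BleachEvent(time=0.0, center=(0.0, 0.0), radius=10.0, efficiency=1.0)
        st = simulate_ring_chain(p, [0.0, 1.0], [ev])
        assert np.allclose(st.fluorescent[0], 0.0)
        assert np.allclose(st.total[0], steady_state_flux(p))

    def test_partial_bleach_scales_by_area_overlap(self):
        p = flux3()
        # disk of radius 1.5 covers ring 1 fully and ring 2 by (1.5^2-1)/3
        ev = BleachEvent(time=0.0, center=(0.0, 0.0), radius=1.5, efficiency=1.0)
        st = simulate_ring_chain(p, [0.0], [ev])
        ss = steady_state_flux(p)
        frac2 = (1.5**2 - 1.0) / (2.0**2 - 1.0)
        assert np.isclose(st.fluorescent[0][0], 0.0)
        assert np.isclose(st.fluorescent[0][1], ss[1] * (1 - frac2))
        assert np.isclose(st.fluorescent[0][2], ss[2])

    def test_mass_conserved_on_closed_chain(self):
        p = MechanisticParams(model_kind="flux", n_rings=5, ring_width=0.5,
                              J=0.0, transfer_rate=0.07, k_loss=0.0)
        rng = np.random.default_rng(42)
        for _ in range(5):
            load = rng.uniform(0.1, 9.0, size=5)
            st = simulate_ring_chain(p, np.linspace(0, 800, 7), initial=load)
            assert np.allclose(st.total.sum(axis=1), load.sum(), rtol=1e-12)

    def test_fluorescent_never_exceeds_total(self):
        ev = BleachEvent(time=10.0, center=(0.0, 0.0), radius=1.2, efficiency=0.7)
        st = simulate_ring_chain(flux3(), np.linspace(0, 400, 21), [ev])
        assert np.all(st.fluorescent <= st.total + 1e-12)

    def test_distributed_matches_closed_form_after_full_bleach(self):
        p = default_distributed_params()
        ev = BleachEvent(time=0.0, center=(0.0, 0.0), radius=10.0, efficiency=1.0)
        times = np.array([0.0, 25.0, 100.0, 400.0])
        st = simulate_ring_chain(p, times, [ev])
        frac = st.fluorescent_fraction()
        for i, t in enumerate(times):
            assert np.allclose(frac[i], closed_form_distributed(p, t), rtol=1e-9)

    def test_sample_at_bleach_time_reports_post_bleach_state(self):
        ev = BleachEvent(time=5.0, center=(0.0, 0.0), radius=10.0, efficiency=0.5)
        st = simulate_ring_chain(flux3(), [0.0, 5.0], [ev])
        assert np.allclose(st.fluorescent[1], 0.5 * st.total[1])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MechanisticParams(model_kind="flux", n_rings=3, ring_width=1.0)
        with pytest.raises(ValueError):
            MechanisticParams(model_kind="distributed", n_rings=3, ring_width=1.0,
                              rho=np.ones(3), k_ex=0.1, J=1.0)
        with pytest.raises(ValueError):
            simulate_ring_chain(flux3(), [0.0, 1.0],
                                [BleachEvent(time=9.0, center=(0, 0), radius=1,
                                             efficiency=0.5)])
        with pytest.raises(PcmFrapError):
            steady_state_flux(MechanisticParams(model_kind="flux", n_rings=3,
                                                ring_width=1.0, J=1.0,
                                                transfer_rate=0.1, k_loss=0.0))


class TestRendering:
    def test_noise_free_render_conserves_mass(self):
        p = default_flux_params()
        st = simulate_ring_chain(p, [0.0])
        optics = OpticsParams()
        mv = render_movie(st, optics, [(3.8, 3.8)], noise=False)
        total_counts = mv.frames[0].sum() - optics.background * mv.frames[0].size
        expected = optics.gain * st.fluorescent[0].sum()
        assert np.isclose(total_counts, expected, rtol=5e-3)

    def test_render_is_deterministic_for_a_seed(self):
        p = default_flux_params()
        st = simulate_ring_chain(p, [0.0, 10.0])
        a = render_movie(st, OpticsParams(), [(3.8, 3.8)], rng=7)
        b = render_movie(st, OpticsParams(), [(3.8, 3.8)], rng=7)
        assert np.array_equal(a.frames, b.frames)

    def test_centrosome_outside_field_rejected(self):
        st = simulate_ring_chain(default_flux_params(), [0.0])
        with pytest.raises(ValueError):
            render_movie(st, OpticsParams(), [(0.5, 0.5)], noise=False,
                         field_shape=(40, 40))

    def test_bead_image_peaks_at_centre(self):
        img = simulate_bead_image(OpticsParams(), noise=False)
        ny, nx = img.pixels.shape
        assert (ny % 2, nx % 2) == (1, 1)
        i, j = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert (i, j) == (ny // 2, nx // 2)


class TestTables:
    def test_fixed_cell_table_structure_and_moments(self):
        specs = {("wt", "mitotic"): (100.0, 10.0), ("mut", "mitotic"): (30.0, 10.0)}
        tab = simulate_fixed_cell_table(specs, n_brains=4, cells_per_brain=200,
                                        rng=1)
        assert list(tab.columns) == ["centrosome_id", "brain_id", "genotype",
                                     "phase", "marker", "intensity"]
        assert len(tab) == 2 * 4 * 200
        assert (tab["intensity"] >= 0).all()
        wt = tab.loc[tab["genotype"] == "wt", "intensity"]
        assert abs(wt.mean() - 100.0) < 2.0

    def test_fixed_cell_table_zero_sd_is_constant(self):
        tab = simulate_fixed_cell_table({("g", "p"): (5.0, 0.0)}, 2, 3, rng=0)
        assert (tab["intensity"] == 5.0).all()

    def test_paired_rates_implant_reduction(self):
        tab = simulate_paired_rates(2000, control_mean=10.0, reduction=0.75,
                                    noise_cv=0.1, rng=3)
        ratio = tab["experimental_rate"].mean() / tab["control_rate"].mean()
        assert abs(ratio - 0.25) < 0.01
        with pytest.raises(ValueError):
            simulate_paired_rates(5, 10.0, reduction=1.5, noise_cv=0.1)
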