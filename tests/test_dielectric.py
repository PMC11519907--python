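"""Forward-model unit and property tests.

Oracles: hand arithmetic for complex permittivity and CM values, an
independently coded Maxwell-Garnett rearrangement, shell-splitting
composition identities, and the exact single-Debye (Maxwell-Wagner)
closed form for a homogeneous sphere.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cytoshell import (
    EPS0,
    CMSpectrum,
    DielectricMaterial,
    FrequencyGrid,
    HomogeneousParticle,
    ShellLayer,
    ShelledParticle,
    clausius_mossotti,
    cm_spectrum,
    complex_permittivity,
    effective_permittivity,
    mg_mixture,
    relaxation_frequency,
    shell_collapse,
)

# ---------------------------------------------------------------------------
# complex_permittivity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "eps_r,sigma,f,expected",
    [
        (78.0, 0.0, 1e6, 78.0 * EPS0),  # zero conductivity: purely real
        (2.55, 0.0, 500e6, 2.55 * EPS0),  # lossless solid, any frequency
    ],
)
def test_complex_permittivity_lossless(eps_r, sigma, f, expected):
    val = complex_permittivity(DielectricMaterial(eps_r, sigma), f)
    assert val == pytest.approx(expected + 0j)


def test_complex_permittivity_conductive_imaginary_part():
    # hand arithmetic: Im = -sigma/(2 pi f)
    val = complex_permittivity(DielectricMaterial(78.0, 2.9), 1e6)
    assert val.imag == pytest.approx(-2.9 / (2 * np.pi * 1e6))
    assert val.real == pytest.approx(78.0 * EPS0)


def test_complex_permittivity_rejects_nonpositive_frequency():
    with pytest.raises(ValueError):
        complex_permittivity(DielectricMaterial(78.0, 0.1), 0.0)


# ---------------------------------------------------------------------------
# clausius_mossotti
# ---------------------------------------------------------------------------

def test_cm_factor_examples():
    m = 78 * EPS0 - 1j * 1e-3
    assert clausius_mossotti(m, m) == 0
    # insulating sphere in a conductive medium at low frequency -> -1/2
    eps_m = complex_permittivity(DielectricMaterial(78.0, 2.9), 1e3)
    eps_p = complex_permittivity(DielectricMaterial(2.55, 0.0), 1e3)
    assert clausius_mossotti(eps_p, eps_m) == pytest.approx(-0.5, abs=1e-4)
    # symbolic arithmetic: eps_p = 2 eps_m -> (2-1)/(2+2) = 1/4
    assert clausius_mossotti(2 * m, m) == pytest.approx(0.25)


def test_cm_factor_degenerate_denominator():
    with pytest.raises(ZeroDivisionError):
        clausius_mossotti(-2.0 + 0j, 1.0 + 0j)


# ---------------------------------------------------------------------------
# mg_mixture
# ---------------------------------------------------------------------------

def _mg_independent(host, inc, phi):
    # independently coded rearrangement of the Maxwell-Garnett formula
    return host * (inc + 2 * host + 2 * phi * (inc - host)) / (
        inc + 2 * host - phi * (inc - host)
    )


def test_mg_mixture_endpoint_identities():
    host, inc = 63 * EPS0 - 0.3j, 2.2 * EPS0 - 1e-9j
    assert mg_mixture(host, inc, 0.0) == host
    assert mg_mixture(host, inc, 1.0) == pytest.approx(inc)


def test_mg_mixture_against_independent_form():
    host = complex_permittivity(DielectricMaterial(63.0, 1.12), 1e7)
    inc = complex_permittivity(DielectricMaterial(2.2, 1e-6), 1e7)
    got = mg_mixture(host, inc, 0.20)
    assert got == pytest.approx(_mg_independent(host, inc, 0.20), rel=1e-12)


def test_mg_mixture_rejects_bad_fraction():
    with pytest.raises(ValueError):
        mg_mixture(1 + 0j, 2 + 0j, 1.5)


# ---------------------------------------------------------------------------
# shell_collapse
# ---------------------------------------------------------------------------

def test_shell_collapse_identities():
    inner = 60 * EPS0 - 0.5j
    assert shell_collapse(inner, inner, 1e-6, 2e-6) == pytest.approx(inner)
    # vanishing shell: r_out -> r_in+
    shell = 6 * EPS0 - 1e-4j
    thin = shell_collapse(inner, shell, 1e-6, 1e-6 * (1 + 1e-12))
    assert thin == pytest.approx(inner, rel=1e-6)
    with pytest.raises(ValueError):
        shell_collapse(inner, shell, 2e-6, 1e-6)


@given(
    st.floats(1, 80),
    st.floats(0, 3),
    st.floats(1, 80),
    st.floats(0, 3),
    st.floats(1.05, 1.5),
    st.floats(1.05, 1.5),
)
def test_shell_collapse_subdivision_invariance(e_i, s_i, e_s, s_s, g1, g2):
    """Splitting one shell into two same-material sub-shells changes nothing."""
    f = 1e7
    inner = complex_permittivity(DielectricMaterial(e_i, s_i), f)
    shell = complex_permittivity(DielectricMaterial(e_s, s_s), f)
    r0 = 1e-6
    r1, r2 = r0 * g1, r0 * g1 * g2
    direct = shell_collapse(inner, shell, r0, r2)
    stepwise = shell_collapse(shell_collapse(inner, shell, r0, r1), shell, r1, r2)
    assert stepwise == pytest.approx(direct, rel=1e-10)


# ---------------------------------------------------------------------------
# effective_permittivity / cm_spectrum
# ---------------------------------------------------------------------------

def test_effective_permittivity_degenerate_shells_equal_core():
    core = DielectricMaterial(63.0, 1.12)
    p = ShelledParticle(
        outer_radius=2.5e-6,
        core_host=core,
        lipid=DielectricMaterial(63.0, 1.12),
        lipid_fraction=0.0,
        shells=(ShellLayer(core, 5e-9), ShellLayer(core, 100e-9)),
    )
    f = 1e7
    assert effective_permittivity(p, f) == pytest.approx(
        complex_permittivity(core, f), rel=1e-12
    )


def test_homogeneous_bead_is_frequency_independent():
    p = HomogeneousParticle(1e-6, DielectricMaterial(2.55, 0.0))
    assert effective_permittivity(p, 1e6) == effective_permittivity(p, 5e8)


def test_cell_is_near_insulating_at_low_frequency(cell, medium):
    """At 1 MHz the membrane isolates the core: CM close to the -1/2 bound."""
    fcm = clausius_mossotti(
        effective_permittivity(cell, 1e6), complex_permittivity(medium, 1e6)
    )
    assert fcm.real == pytest.approx(-0.5, abs=0.05)


def test_cm_spectrum_matched_particle_is_zero(grid, medium):
    p = HomogeneousParticle(1e-6, medium)
    s = cm_spectrum(p, medium, grid)
    assert np.allclose(s.values, 0)


def test_cm_spectrum_low_frequency_approaches_minus_half(cell, medium, grid):
    s = cm_spectrum(cell, medium, grid)
    assert s.values.real[0] == pytest.approx(-0.5, abs=0.05)
    # dispersion: real part rises with frequency through the band
    assert s.values.real[-1] > s.values.real[0] + 0.1


# ---------------------------------------------------------------------------
# Maxwell-Wagner closed form (single-Debye oracle)
# ---------------------------------------------------------------------------

def _debye_cm(p: DielectricMaterial, m: DielectricMaterial, f: np.ndarray) -> np.ndarray:
    """Exact CM factor of a homogeneous sphere as a single Debye relaxation."""
    cm_0 = (p.conductivity - m.conductivity) / (p.conductivity + 2 * m.conductivity)
    cm_inf = (p.relative_permittivity - m.relative_permittivity) / (
        p.relative_permittivity + 2 * m.relative_permittivity
    )
    tau = (
        EPS0
        * (p.relative_permittivity + 2 * m.relative_permittivity)
        / (p.conductivity + 2 * m.conductivity)
    )
    return cm_inf + (cm_0 - cm_inf) / (1 + 1j * 2 * np.pi * f * tau)


def test_homogeneous_sphere_matches_debye_closed_form(medium):
    p_mat = DielectricMaterial(50.0, 0.01)
    grid = FrequencyGrid.log_spaced(1e6, 1e11, 80)
    s = cm_spectrum(HomogeneousParticle(1e-6, p_mat), medium, grid)
    expected = _debye_cm(p_mat, medium, grid.frequencies)
    np.testing.assert_allclose(s.values, expected, rtol=1e-12)


def test_relaxation_frequency_matches_maxwell_wagner(medium):
    p_mat = DielectricMaterial(50.0, 0.01)
    tau = EPS0 * (50.0 + 2 * 78.0) / (0.01 + 2 * 2.9)
    f_analytic = 1.0 / (2 * np.pi * tau)
    grid = FrequencyGrid.log_spaced(f_analytic / 300, f_analytic * 300, 60)
    s = cm_spectrum(HomogeneousParticle(1e-6, p_mat), medium, grid)
    for method in ("imag_peak", "real_max_gradient"):
        f_est = relaxation_frequency(s, method)
        assert f_est == pytest.approx(f_analytic, rel=0.02)


def test_relaxation_frequency_flat_spectrum_errors(grid):
    flat = CMSpectrum(grid, np.full(len(grid), -0.5 + 0j))
    with pytest.raises(ValueError, match="no relaxation"):
        relaxation_frequency(flat, "imag_peak")
    with pytest.raises(ValueError):
        relaxation_frequency(flat, "real_max_gradient")


def test_relaxation_frequency_needs_enough_points(medium):
    g = FrequencyGrid.log_spaced(1e6, 1e9, 5)
    s = cm_spectrum(HomogeneousParticle(1e-6, DielectricMaterial(50.0, 0.01)), medium, g)
    with pytest.raises(ValueError):
        relaxation_frequency(s)


# ---------------------------------------------------------------------------
# Passivity bounds and band-limit properties
# ---------------------------------------------------------------------------

@given(
    st.floats(1, 100),
    st.floats(0, 5),
    st.floats(1, 100),
    st.floats(1e-3, 5),
)
def test_cm_real_part_bounded_for_passive_materials(e_p, s_p, e_m, s_m):
    grid = FrequencyGrid.log_spaced(1e3, 1e12, 40)
    p = HomogeneousParticle(1e-6, DielectricMaterial(e_p, s_p))
    s = cm_spectrum(p, DielectricMaterial(e_m, s_m), grid)
    assert np.all(s.values.real >= -0.5 - 1e-9)
    assert np.all(s.values.real <= 1.0 + 1e-9)


def test_cm_shelled_particle_real_part_bounded(cell, medium):
    grid = FrequencyGrid.log_spaced(1e3, 1e12, 200)
    s = cm_spectrum(cell, medium, grid)
    assert np.all(s.values.real >= -0.5 - 1e-9)
    assert np.all(s.values.real <= 1.0 + 1e-9)


def test_cm_band_limits_reduce_to_single_contrast(medium):
    """Far below/above the relaxation the CM factor is set by conductivity
    alone / permittivity alone respectively."""
    p_mat = DielectricMaterial(50.0, 0.01)
    tau = EPS0 * (50.0 + 2 * 78.0) / (0.01 + 2 * 2.9)
    f_relax = 1.0 / (2 * np.pi * tau)
    lo, hi = f_relax * 1e-3, f_relax * 1e3
    p = HomogeneousParticle(1e-6, p_mat)
    cm_lo = clausius_mossotti(effective_permittivity(p, lo), complex_permittivity(medium, lo))
    cm_hi = clausius_mossotti(effective_permittivity(p, hi), complex_permittivity(medium, hi))
    cm_sigma = (0.01 - 2.9) / (0.01 + 2 * 2.9)
    cm_eps = (50.0 - 78.0) / (50.0 + 2 * 78.0)
    assert cm_lo.real == pytest.approx(cm_sigma, rel=0.01)
    assert cm_hi.real == pytest.approx(cm_eps, rel=0.01)
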