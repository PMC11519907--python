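"""Forward dielectric model: Clausius-Mossotti spectra of shelled particles.

The polarisability contrast between a particle and its suspending medium is
summarised by the complex Clausius-Mossotti (CM) factor

    f_CM(w) = (eps_p* - eps_m*) / (eps_p* + 2 eps_m*),

with complex permittivities eps* = eps_r eps0 - j sigma / w under the
e^{+j w t} sign convention.  A multi-layered cell is reduced to an
equivalent homogeneous sphere by Maxwell-Garnett mixing of the core
(lipid vesicles in cytoplasm) followed by layer-by-layer shell collapse
(membrane, then scale layer), so the same CM expression applies to beads,
microplastics and cells alike.

Interfacial (Maxwell-Wagner) relaxations appear as peaks in Im f_CM and
as the steepest rise of Re f_CM against log-frequency;
:func:`relaxation_frequency` extracts them from a sampled spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import (
    EPS0,
    DielectricMaterial,
    FrequencyGrid,
    HomogeneousParticle,
    ShelledParticle,
)

__all__ = [
    "CMSpectrum",
    "complex_permittivity",
    "clausius_mossotti",
    "mg_mixture",
    "shell_collapse",
    "effective_permittivity",
    "cm_spectrum",
    "relaxation_frequency",
]


@dataclass(frozen=True)
class CMSpectrum:
    """Complex Clausius-Mossotti factor sampled on a frequency grid."""

    grid: FrequencyGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.shape != self.grid.frequencies.shape:
            raise ValueError("spectrum values must match grid length")
        object.__setattr__(self, "values", v)

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies


def complex_permittivity(m: DielectricMaterial, f):
    """Complex absolute permittivity eps_r eps0 - j sigma/(2 pi f), in F/m.

    ``f`` may be a scalar or array of frequencies in Hz; all must be > 0.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = m.relative_permittivity * EPS0 - 1j * m.conductivity / (2.0 * np.pi * f)
    return complex(out) if np.ndim(out) == 0 else out


def clausius_mossotti(eps_p, eps_m):
    """CM factor (eps_p - eps_m)/(eps_p + 2 eps_m) for complex permittivities."""
    denom = eps_p + 2.0 * eps_m
    if np.any(denom == 0):
        raise ZeroDivisionError("degenerate CM denominator eps_p + 2 eps_m = 0")
    return (eps_p - eps_m) / denom


def mg_mixture(host, inclusion, phi: float):
    """Maxwell-Garnett effective permittivity of dilute spherical inclusions.

    eps_mix = host (1 + 2 phi F) / (1 - phi F) with
    F = (inclusion - host)/(inclusion + 2 host).  Exact at phi = 0 (host)
    and phi = 1 (inclusion).
    """
    if not 0 <= phi <= 1:
        raise ValueError(f"inclusion volume fraction must lie in [0, 1], got {phi}")
    f_cm = clausius_mossotti(inclusion, host)
    return host * (1.0 + 2.0 * phi * f_cm) / (1.0 - phi * f_cm)


def shell_collapse(inner, shell, r_in: float, r_out: float):
    """Equivalent permittivity of a core ``inner`` coated by a ``shell``.

    The coated sphere (core radius ``r_in``, outer radius ``r_out``) is
    replaced by a homogeneous sphere of radius ``r_out`` with

        eps_eq = shell (g^3 + 2 G) / (g^3 - G),

    g = r_out/r_in and G the core/shell CM factor.  Applied repeatedly it
    reduces any number of concentric layers, innermost first.
    """
    if not 0 < r_in < r_out:
        raise ValueError(f"need 0 < r_in < r_out, got r_in={r_in}, r_out={r_out}")
    gamma3 = (r_out / r_in) ** 3
    g = clausius_mossotti(inner, shell)
    return shell * (gamma3 + 2.0 * g) / (gamma3 - g)


def effective_permittivity(p: ShelledParticle | HomogeneousParticle, f):
    """Complex permittivity of the equivalent homogeneous sphere at ``f`` Hz."""
    if isinstance(p, HomogeneousParticle):
        return complex_permittivity(p.material, f)
    eps = mg_mixture(
        complex_permittivity(p.core_host, f),
        complex_permittivity(p.lipid, f),
        p.lipid_fraction,
    )
    radii = p.interface_radii()
    for layer, r_in, r_out in zip(p.shells, radii[:-1], radii[1:]):
        eps = shell_collapse(eps, complex_permittivity(layer.material, f), r_in, r_out)
    return eps


def cm_spectrum(
    p: ShelledParticle | HomogeneousParticle,
    medium: DielectricMaterial,
    grid: FrequencyGrid,
) -> CMSpectrum:
    """CM factor of particle ``p`` in ``medium`` across a frequency grid."""
    f = grid.frequencies
    values = clausius_mossotti(effective_permittivity(p, f), complex_permittivity(medium, f))
    return CMSpectrum(grid, values)


def _quadratic_peak_logf(logf: np.ndarray, y: np.ndarray, i: int) -> float:
    """Refine a discrete peak at index i by a 3-point parabola in log10(f)."""
    if i == 0 or i == len(y) - 1:
        return logf[i]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return logf[i]
    # vertex offset in grid units, clipped to the bracketing interval
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    return logf[i] + delta * (logf[i + 1] - logf[i] if delta >= 0 else logf[i] - logf[i - 1])


def relaxation_frequency(s: CMSpectrum, method: str = "imag_peak") -> float:
    """Frequency (Hz) of a dielectric relaxation in a CM spectrum.

    ``imag_peak`` locates the maximum of Im f_CM; ``real_max_gradient``
    locates the maximum of d(Re f_CM)/d(log f).  Both refine the grid
    maximum with a 3-point quadratic fit on log10-frequency and require
    the extremum to be interior to the grid.

    Raises
    ------
    ValueError
        If the grid is too short (< 10 points) or no interior extremum
        exists (flat or monotone spectrum).
    """
    if len(s.grid) < 10:
        raise ValueError("need at least 10 grid points to locate a relaxation")
    logf = np.log10(s.frequencies)
    if method == "imag_peak":
        y = np.imag(s.values)
        i = int(np.argmax(y))
        if i in (0, len(y) - 1) or np.ptp(y) == 0:
            raise ValueError("no relaxation found: imaginary part has no interior peak")
        return 10.0 ** _quadratic_peak_logf(logf, y, i)
    if method == "real_max_gradient":
        re = np.real(s.values)
        grad = np.gradient(re, logf)
        i = int(np.argmax(grad))
        if np.ptp(re) == 0 or grad[i] <= 0:
            raise ValueError("no relaxation found: real part has no rising dispersion")
        if i in (0, len(grad) - 1):
            return 10.0 ** logf[i]
        return 10.0 ** _quadratic_peak_logf(logf, grad, i)
    raise ValueError(f"unknown method {method!r}; use 'imag_peak' or 'real_max_gradient'")
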