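"""Population-spectrum normalisation and double-shell model fitting.

A population-averaged current spectrum is turned into an (unscaled)
Clausius-Mossotti spectrum by referencing it to a calibration-bead
measurement at a single frequency: the bead's CM factor is known from its
material, so multiplying the cell/bead current ratio by it removes the
electronics gain while leaving a cell/bead volume ratio behind.  That
residual ratio is absorbed by a multiplicative nuisance ``scale`` during
fitting.

Fitting minimises the mean squared error between model and observation,
summed over real and imaginary components, with a bounded derivative-free
compass (pattern) search: poll +/- one step along each coordinate, accept
any improving move, halve the step after a full failed poll, stop when the
step shrinks below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .dielectric import cm_spectrum, complex_permittivity, clausius_mossotti, effective_permittivity
from .materials import (
    DielectricMaterial,
    FrequencyGrid,
    HomogeneousParticle,
    ShellLayer,
    ShelledParticle,
)

__all__ = [
    "PopulationSpectrum",
    "FitSpec",
    "FitResult",
    "PARAM_NAMES",
    "apply_params",
    "normalize_population_spectrum",
    "model_prediction",
    "mse_objective",
    "compass_search",
    "fit_shell_model",
]


@dataclass(frozen=True)
class PopulationSpectrum:
    """Bead-referenced population-mean spectrum.

    ``observed`` is the dimensionless complex quantity plotted in the
    spectroscopy experiment: CM factor times an unknown cell/bead volume
    ratio.  ``reference`` records the bead diameter (um) and reference
    frequency (Hz) used for normalisation.
    """

    grid: FrequencyGrid
    observed: np.ndarray
    n_cells: int
    reference: tuple[float, float]  # (bead_diameter_um, ref_frequency_hz)

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=complex)
        if obs.shape != self.grid.frequencies.shape:
            raise ValueError("observed spectrum length must match the grid")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        object.__setattr__(self, "observed", obs)


@dataclass
class FitSpec:
    """Free/fixed parameter layout and optimiser settings for a fit.

    ``free`` maps parameter name -> (lower, upper, initial); ``fixed``
    overrides template values without fitting them.  ``include_scale``
    adds a multiplicative nuisance scale ("scale") as a free parameter
    if it is not already listed.
    """

    free: dict[str, tuple[float, float, float]]
    fixed: dict[str, float] = field(default_factory=dict)
    include_scale: bool = True
    tolerance: float = 1e-6
    max_evals: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        for name, (lo, up, init) in self.free.items():
            if not lo < init < up:
                raise ValueError(f"parameter {name!r}: need lower < initial < upper, got {(lo, up, init)}")


@dataclass(frozen=True)
class FitResult:
    fitted: dict[str, float]
    scale: float
    mse: float
    n_evals: int
    converged: bool


#: Names accepted by :func:`apply_params`, mapped onto the double-shell template.
PARAM_NAMES = (
    "radius",
    "eps_core",
    "sigma_core",
    "lipid_fraction",
    "eps_lipid",
    "sigma_lipid",
    "eps_membrane",
    "sigma_membrane",
    "thickness_membrane",
    "eps_scale",
    "sigma_scale",
    "thickness_scale",
)


def apply_params(template: ShelledParticle, params: Mapping[str, float]) -> ShelledParticle:
    """Return a copy of ``template`` with named parameters substituted.

    The template must carry exactly two shells (membrane, scale).  Unknown
    parameter names raise; "scale" (the nuisance amplitude) is not a
    particle parameter and is rejected here.
    """
    unknown = set(params) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
    if len(template.shells) != 2:
        raise ValueError("template must have exactly two shells (membrane, scale)")

    def get(name: str, default: float) -> float:
        return float(params.get(name, default))

    mem, scale_layer = template.shells
    return ShelledParticle(
        outer_radius=get("radius", template.outer_radius),
        core_host=DielectricMaterial(
            get("eps_core", template.core_host.relative_permittivity),
            get("sigma_core", template.core_host.conductivity),
        ),
        lipid=DielectricMaterial(
            get("eps_lipid", template.lipid.relative_permittivity),
            get("sigma_lipid", template.lipid.conductivity),
        ),
        lipid_fraction=get("lipid_fraction", template.lipid_fraction),
        shells=(
            ShellLayer(
                DielectricMaterial(
                    get("eps_membrane", mem.material.relative_permittivity),
                    get("sigma_membrane", mem.material.conductivity),
                ),
                get("thickness_membrane", mem.thickness),
            ),
            ShellLayer(
                DielectricMaterial(
                    get("eps_scale", scale_layer.material.relative_permittivity),
                    get("sigma_scale", scale_layer.material.conductivity),
                ),
                get("thickness_scale", scale_layer.thickness),
            ),
        ),
    )


def normalize_population_spectrum(
    grid: FrequencyGrid,
    cell_mean_current: np.ndarray,
    bead_mean_current_at_ref: complex,
    bead: HomogeneousParticle,
    medium: DielectricMaterial,
    ref_frequency: float,
    n_cells: int = 10000,
) -> PopulationSpectrum:
    """Reference a population-mean current spectrum to a calibration bead.

    observed(f) = f_CM_bead(ref) * cell_mean_current(f) / bead_mean_current_at_ref
    """
    if bead_mean_current_at_ref == 0:
        raise ZeroDivisionError("bead reference current is zero; cannot normalize")
    cell = np.asarray(cell_mean_current, dtype=complex)
    if cell.shape != grid.frequencies.shape:
        raise ValueError("cell current length must match the grid")
    fcm_bead = clausius_mossotti(
        effective_permittivity(bead, ref_frequency),
        complex_permittivity(medium, ref_frequency),
    )
    observed = fcm_bead * cell / bead_mean_current_at_ref
    return PopulationSpectrum(grid, observed, n_cells, (bead.radius * 2e6, ref_frequency))


def model_prediction(
    params: Mapping[str, float],
    template: ShelledParticle,
    medium: DielectricMaterial,
    grid: FrequencyGrid,
    scale: float = 1.0,
) -> np.ndarray:
    """scale * CM spectrum of the template with ``params`` substituted."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    particle = apply_params(template, params)
    return scale * cm_spectrum(particle, medium, grid).values


def mse_objective(pred: np.ndarray, obs: np.ndarray) -> float:
    """Mean over frequencies of squared real + squared imaginary residuals."""
    pred = np.asarray(pred, dtype=complex)
    obs = np.asarray(obs, dtype=complex)
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation lengths differ")
    r = pred - obs
    return float(np.mean(r.real**2 + r.imag**2))


def compass_search(
    objective: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    init: np.ndarray,
    init_step: float = 0.25,
    tolerance: float = 1e-6,
    max_evals: int = 20000,
    seed: int = 0,
) -> tuple[np.ndarray, float, list[tuple[np.ndarray, float]]]:
    """Bounded compass (pattern) search minimisation.

    Polls +/- one step along each coordinate (step = fraction of that
    coordinate's box range, starting at ``init_step``); any improving move
    is accepted immediately; a full unsuccessful poll halves the step.
    Terminates when the step fraction drops below ``tolerance`` or the
    evaluation budget is spent.  Returns (argmin, value, trace) where
    ``trace`` lists every accepted iterate with its objective value
    (non-increasing by construction).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    x = np.asarray(init, dtype=float).copy()
    if lower.shape != upper.shape or x.shape != lower.shape:
        raise ValueError("bounds and init must have identical shapes")
    if np.any(lower >= upper):
        raise ValueError("lower bounds must be strictly below upper bounds")
    if np.any(x < lower) or np.any(x > upper):
        raise ValueError("initial point must lie inside the box")

    rng = np.random.default_rng(seed)
    ranges = upper - lower
    n = x.size
    f_x = float(objective(x))
    if not np.isfinite(f_x):
        raise ValueError("objective is not finite at the initial point")
    n_evals = 1
    trace: list[tuple[np.ndarray, float]] = [(x.copy(), f_x)]
    frac = float(init_step)

    while frac >= tolerance and n_evals < max_evals:
        improved = False
        order = rng.permutation(2 * n)  # randomised poll order, seeded
        for move in order:
            i, sign = divmod(move, 2)
            cand = x.copy()
            cand[i] = np.clip(x[i] + (1 if sign else -1) * frac * ranges[i], lower[i], upper[i])
            if cand[i] == x[i]:
                continue
            f_c = float(objective(cand))
            n_evals += 1
            if f_c < f_x:
                x, f_x = cand, f_c
                trace.append((x.copy(), f_x))
                improved = True
                break
            if n_evals >= max_evals:
                break
        if not improved:
            frac /= 2.0
    return x, f_x, trace


def fit_shell_model(
    spectrum: PopulationSpectrum,
    spec: FitSpec,
    template: ShelledParticle,
    medium: DielectricMaterial,
) -> FitResult:
    """Fit free double-shell parameters to a bead-referenced spectrum.

    Minimises :func:`mse_objective` between :func:`model_prediction` and the
    observed spectrum with :func:`compass_search`.  The nuisance amplitude
    "scale" is appended as a free parameter when ``spec.include_scale`` is
    set and not already present (bounds 0.1-10, initial 1).
    """
    free = dict(spec.free)
    if spec.include_scale and "scale" not in free:
        free["scale"] = (0.1, 10.0, 1.0)
    names = list(free)
    lower = np.array([free[n][0] for n in names])
    upper = np.array([free[n][1] for n in names])
    init = np.array([free[n][2] for n in names])

    base = apply_params(template, spec.fixed)
    obs = spectrum.observed

    def objective(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        scale = params.pop("scale", 1.0)
        pred = model_prediction(params, base, medium, spectrum.grid, scale=scale)
        return mse_objective(pred, obs)

    if not np.isfinite(objective(init)):
        raise ValueError("objective is not finite at the initial point")

    n_evals = 0

    def counted(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return objective(x)

    x, f_x, _trace = compass_search(
        counted,
        lower,
        upper,
        init,
        tolerance=spec.tolerance,
        max_evals=spec.max_evals,
        seed=spec.seed,
    )
    fitted = dict(zip(names, (float(v) for v in x)))
    scale = fitted.pop("scale", 1.0)
    # step-size convergence (budget left over) vs. evaluation-budget exhaustion
    converged = n_evals < spec.max_evals
    return FitResult(fitted=fitted, scale=scale, mse=f_x, n_evals=n_evals, converged=converged)
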