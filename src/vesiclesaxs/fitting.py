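"""Weighted least-squares fitting of the vesicle model to a SAXS curve.

The objective is the sigma-weighted residual sum chi^2 =
sum_i ((I_obs_i - I_model_i) / sigma_i)^2, minimised with bounded
trust-region least squares (through lmfit).  The lamellarity N is discrete
and, when freed, is optimised over a small integer grid with a continuous
fit at each candidate.  Parameter uncertainties follow a parametric
perturbation procedure: every observed intensity is redrawn from
N(I_obs_i, sigma_i), the fit is repeated (20 replicates by default), and
the per-parameter mean and standard deviation over replicate fits are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .curves import ScatteringCurve
from .model import (
    BilayerProfile,
    SizeDistribution,
    SolventSpec,
    StackSpec,
    VesicleModel,
    model_intensity,
)

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "chi2",
    "fit",
    "perturbation_uncertainty",
    "model_to_dict",
    "dict_to_model",
    "fit_report",
]

#: Flat parameter names of a VesicleModel, in report order.
PARAM_NAMES = (
    "R1", "R2", "R3", "rho1", "rho2", "rho3",
    "N", "c", "g_c", "R0_mean", "xi_R0",
    "water_fraction", "rho_water", "rho_ethanol",
    "scale", "background",
)

#: Default free set: bilayer geometry, stack spacing/disorder and plumbing.
DEFAULT_FREE = frozenset({"scale", "background", "R1", "R2", "R3", "c", "g_c"})

#: Physically sensible default bounds (nm, e/nm^3, dimensionless).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "R1": (0.2, 1.5),
    "R2": (0.4, 2.0),
    "R3": (0.05, 0.6),
    "rho1": (330.0, 450.0),
    "rho2": (260.0, 340.0),
    "rho3": (240.0, 330.0),
    "N": (1, 8),
    "c": (4.0, 60.0),
    "g_c": (0.01, 1.5),
    "R0_mean": (100.0, 1000.0),
    "xi_R0": (0.0, 0.5),
    "water_fraction": (0.0, 1.0),
    "rho_water": (300.0, 360.0),
    "rho_ethanol": (260.0, 310.0),
    "scale": (1e-12, 1e-4),
    "background": (0.0, 10.0),
}


def model_to_dict(model: VesicleModel) -> dict[str, float]:
    """Flatten a VesicleModel into the canonical parameter dictionary."""
    return {
        "R1": model.bilayer.R1, "R2": model.bilayer.R2, "R3": model.bilayer.R3,
        "rho1": model.bilayer.rho1, "rho2": model.bilayer.rho2, "rho3": model.bilayer.rho3,
        "N": float(model.stack.N), "c": model.stack.c, "g_c": model.stack.g_c,
        "R0_mean": model.size.R0_mean, "xi_R0": model.size.xi_R0,
        "water_fraction": model.solvent.water_volume_fraction,
        "rho_water": model.solvent.rho_water, "rho_ethanol": model.solvent.rho_ethanol,
        "scale": model.scale, "background": model.background,
    }


def dict_to_model(d: dict[str, float]) -> VesicleModel:
    """Rebuild a VesicleModel from the canonical parameter dictionary."""
    return VesicleModel(
        size=SizeDistribution(R0_mean=d["R0_mean"], xi_R0=d["xi_R0"]),
        bilayer=BilayerProfile(
            R1=d["R1"], R2=d["R2"], R3=d["R3"],
            rho1=d["rho1"], rho2=d["rho2"], rho3=d["rho3"],
        ),
        stack=StackSpec(N=int(round(d["N"])), c=d["c"], g_c=d["g_c"]),
        solvent=SolventSpec(
            water_volume_fraction=d["water_fraction"],
            rho_water=d["rho_water"], rho_ethanol=d["rho_ethanol"],
        ),
        scale=d["scale"],
        background=d["background"],
    )


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one fit: free set, bounds, fixed overrides, strategy.

    Electron densities and the solvent composition are fixed by default;
    ``fixed_values`` overrides the initial model for any non-free parameter.
    ``n_starts > 1`` adds seeded random restarts drawn uniformly inside the
    bounds to mitigate local minima.
    """

    free: frozenset = DEFAULT_FREE
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed_values: dict[str, float] = field(default_factory=dict)
    mode: str = "separated"
    max_iterations: int = 2000
    tolerance: float = 1e-10
    seed: int = 0
    n_starts: int = 1

    def __post_init__(self) -> None:
        unknown = (set(self.free) | set(self.bounds) | set(self.fixed_values)) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        overlap = set(self.free) & set(self.fixed_values)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    """Best-fit model, chi^2 and (optionally) replicate statistics."""

    model: VesicleModel
    chi2: float
    n_points: int
    success: bool
    message: str = ""
    parameter_stats: dict[str, tuple[float, float]] | None = None
    n_replicates: int = 0
    n_failed_replicates: int = 0

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_points, 1)


def chi2(curve: ScatteringCurve, model: VesicleModel, mode: str = "separated") -> float:
    """Sigma-weighted residual sum; zero iff the model reproduces the data."""
    sigma = curve.sigma
    if np.any(sigma <= 0):
        raise ValueError("chi2 requires strictly positive per-point sigma")
    pred = model_intensity(curve.grid, model, mode=mode)
    return float(np.sum(((curve.intensity - pred) / sigma) ** 2))


def _start_dict(initial: VesicleModel, config: FitConfig) -> dict[str, float]:
    values = model_to_dict(initial)
    values.update(config.fixed_values)
    for name in config.free:
        lo, hi = config.bound(name)
        if not (lo <= values[name] <= hi):
            raise ValueError(
                f"initial value of {name} ({values[name]}) outside bounds [{lo}, {hi}]"
            )
    return values


def _fit_continuous(
    curve: ScatteringCurve,
    values: dict[str, float],
    free: list[str],
    config: FitConfig,
) -> tuple[dict[str, float], float, bool, str]:
    """One bounded least-squares run over the continuous free parameters."""
    params = lmfit.Parameters()
    for name in free:
        lo, hi = config.bound(name)
        params.add(name, value=values[name], min=lo, max=hi)

    fixed = {k: v for k, v in values.items() if k not in free}

    def residual(p: lmfit.Parameters) -> np.ndarray:
        d = dict(fixed)
        for name in free:
            d[name] = p[name].value
        pred = model_intensity(curve.grid, dict_to_model(d), mode=config.mode)
        r = (curve.intensity - pred) / curve.sigma
        # keep the optimizer finite even for degenerate (near-zero) sigma
        return np.clip(np.nan_to_num(r, nan=1e100, posinf=1e100, neginf=-1e100), -1e100, 1e100)

    out = lmfit.minimize(
        residual,
        params,
        method="least_squares",
        max_nfev=config.max_iterations,
        ftol=config.tolerance,
        xtol=config.tolerance,
        gtol=config.tolerance,
    )
    best = dict(values)
    for name in free:
        best[name] = float(out.params[name].value)
    return best, float(out.chisqr), bool(out.success), str(out.message)


def fit(
    curve: ScatteringCurve,
    initial: VesicleModel,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the vesicle model to a curve by bounded weighted least squares.

    The lamellarity N, when in the free set, is searched over the integers
    inside its bounds with a continuous fit at each candidate.  The returned
    chi^2 never exceeds the chi^2 of the initial model; non-convergence is
    flagged on the result rather than raised.
    """
    config = config or FitConfig()
    values = _start_dict(initial, config)
    chi2_init = chi2(curve, dict_to_model(values), mode=config.mode)

    continuous = sorted(set(config.free) - {"N"})
    if "N" in config.free:
        lo, hi = config.bound("N")
        n_candidates = list(range(int(np.ceil(lo)), int(np.floor(hi)) + 1))
    else:
        n_candidates = [int(round(values["N"]))]

    rng = np.random.default_rng(config.seed)
    starts = [dict(values)]
    for _ in range(config.n_starts - 1):
        s = dict(values)
        for name in continuous:
            b_lo, b_hi = config.bound(name)
            s[name] = float(rng.uniform(b_lo, b_hi))
        starts.append(s)

    best: tuple[dict[str, float], float, bool, str] | None = None
    for n_val in n_candidates:
        for start in starts:
            trial = dict(start)
            trial["N"] = float(n_val)
            result = _fit_continuous(curve, trial, continuous, config)
            if best is None or result[1] < best[1]:
                best = result
    assert best is not None
    values_best, chisq, success, message = best
    if chisq > chi2_init:
        # the optimizer wandered; the initial point is itself admissible,
        # so report it (convergence status comes from the optimizer)
        values_best, chisq = values, chi2_init
        message = f"kept initial point; {message}"
    return FitResult(
        model=dict_to_model(values_best),
        chi2=chisq,
        n_points=len(curve),
        success=success,
        message=message,
    )


def perturbation_uncertainty(
    curve: ScatteringCurve,
    initial: VesicleModel,
    config: FitConfig | None = None,
    n_replicates: int = 20,
) -> FitResult:
    """Parameter uncertainties by refitting Gaussian-perturbed replicas.

    Each replicate redraws every observed intensity from N(I_obs_i, sigma_i)
    and repeats the fit from the same start; the per-parameter mean and
    standard deviation over the replicate best fits estimate the parameter
    uncertainty.  Per-replicate random streams are spawned from the master
    seed, so increasing ``n_replicates`` extends rather than reshuffles the
    replicate set.  Non-converged replicates are excluded and counted.
    """
    config = config or FitConfig()
    if n_replicates < 2:
        raise ValueError(f"n_replicates must be >= 2, got {n_replicates}")
    base = fit(curve, initial, config)

    tracked = sorted(config.free)
    master = np.random.SeedSequence(config.seed)
    draws: dict[str, list[float]] = {name: [] for name in tracked}
    n_failed = 0
    for child in master.spawn(n_replicates):
        rng = np.random.default_rng(child)
        perturbed = curve.with_intensity(
            curve.intensity + rng.normal(size=len(curve)) * curve.sigma
        )
        res = fit(perturbed, initial, config)
        if not res.success:
            n_failed += 1
            warnings.warn(
                f"replicate fit did not converge ({res.message}); excluded",
                stacklevel=2,
            )
            continue
        d = model_to_dict(res.model)
        for name in tracked:
            draws[name].append(d[name])

    stats: dict[str, tuple[float, float]] = {}
    for name in tracked:
        arr = np.asarray(draws[name])
        if arr.size >= 2:
            stats[name] = (float(arr.mean()), float(arr.std(ddof=1)))
        elif arr.size == 1:
            stats[name] = (float(arr[0]), 0.0)
    return replace(
        base,
        parameter_stats=stats,
        n_replicates=n_replicates - n_failed,
        n_failed_replicates=n_failed,
    )


def fit_report(result: FitResult) -> str:
    """Delimited-text parameter table (parameter, best, mean, s.d.)."""
    d = model_to_dict(result.model)
    lines = ["parameter\tbest\tmean\ts.d."]
    for name in PARAM_NAMES:
        if result.parameter_stats and name in result.parameter_stats:
            mean, sd = result.parameter_stats[name]
            lines.append(f"{name}\t{d[name]:.6g}\t{mean:.6g}\t{sd:.3g}")
        else:
            lines.append(f"{name}\t{d[name]:.6g}\t-\t-")
    lines.append(f"chi2\t{result.chi2:.6g}\t-\t-")
    lines.append(f"n_points\t{result.n_points}\t-\t-")
    if result.n_replicates:
        lines.append(f"n_replicates\t{result.n_replicates}\t-\t-")
    if result.n_failed_replicates:
        lines.append(f"n_failed_replicates\t{result.n_failed_replicates}\t-\t-")
    return "\n".join(lines) + "\n"
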