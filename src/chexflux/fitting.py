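"""Global weighted least-squares fitting of CEST and zz-exchange data.

The objective is the standard chi-square with per-point experimental
sigmas, ``sum(((y_obs - y_model)/sigma)**2)``, minimized over named,
bounded parameters (lmfit) with a trust-region least-squares driver and
an optional Latin-hypercube multi-start.  Two network parameterizations
are supported:

``rates``
    Free one-way rate constants ``k_<i>_<j>``; equilibrium populations
    are derived from the rate matrix.  Natural for zz-exchange fits of
    tree topologies (e.g. the two-state U<->B binding step).

``kex_pop``
    Free per-edge exchange rates ``kex_<i>_<j>`` plus state populations
    through a softmax transform of free log-weights ``logp_<state>``
    (fix one log-weight to pin the gauge).  Detailed balance then fixes
    the one-way rates per edge.  This mirrors global CEST fits, where
    ``k_ex`` per edge is well determined but populations may not be.

Uncertainties come from a point-level bootstrap: points are resampled
with replacement independently within each profile, preserving each
profile's point count, and every replicate is refit starting from the
original best fit.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import lmfit
import numpy as np
import scipy.linalg
from scipy.stats import qmc

from chexflux.bloch_mcconnell import CestDataset, ZzDataset
from chexflux.exchange_model import (
    ExchangeNetwork,
    SpinProbe,
    ValidationError,
    build_rate_matrix,
)

__all__ = [
    "ParameterSpec",
    "NetworkSpec",
    "FitResult",
    "Chi2Surface",
    "BootstrapResult",
    "fit_model",
    "chi2_surface_1d",
    "bootstrap",
    "build_network_from_params",
    "build_probe_from_params",
    "population_distributions",
]

Dataset = Union[CestDataset, ZzDataset]


@dataclass(frozen=True)
class ParameterSpec:
    """One named fit parameter with bounds and a fixed/free flag.

    ``role`` distinguishes quantities shared across all profiles
    (``"global"``: rates, populations) from per-profile ones
    (``"local"``: e.g. a zz amplitude scale).  The role is bookkeeping
    only; sharing is expressed by the parameter name itself.
    """

    name: str
    value: float
    min: float = -math.inf
    max: float = math.inf
    vary: bool = True
    role: str = "global"

    def __post_init__(self):
        if not (self.min <= self.value <= self.max):
            raise ValidationError(
                f"parameter {self.name}: initial value {self.value} outside "
                f"bounds [{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """Topology + parameterization of the exchange model being fit."""

    states: Tuple[str, ...]
    edges: Tuple[Tuple[str, str], ...]
    parameterization: str = "rates"  # "rates" | "kex_pop"
    ligand_conc: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if self.parameterization not in ("rates", "kex_pop"):
            raise ValidationError(
                f"unknown parameterization {self.parameterization!r}"
            )
        for i, j in self.edges:
            if i not in self.states or j not in self.states:
                raise ValidationError(f"edge {i}-{j} references unknown state")


def build_network_from_params(
    spec: NetworkSpec, params: Mapping[str, float]
) -> ExchangeNetwork:
    """Instantiate the ExchangeNetwork described by a parameter vector."""
    if spec.parameterization == "rates":
        rates = {}
        for i, j in spec.edges:
            rates[(i, j)] = float(params[f"k_{i}_{j}"])
            rates[(j, i)] = float(params[f"k_{j}_{i}"])
        return ExchangeNetwork(spec.states, rates, ligand_conc=spec.ligand_conc)
    # kex_pop
    logp = np.array([float(params[f"logp_{s}"]) for s in spec.states])
    w = np.exp(logp - logp.max())
    pops = w / w.sum()
    kex = {(i, j): float(params[f"kex_{i}_{j}"]) for i, j in spec.edges}
    return ExchangeNetwork.from_kex(
        spec.states, pops, kex, ligand_conc=spec.ligand_conc
    )


def build_probe_from_params(
    spec: NetworkSpec, probe_name: str, params: Mapping[str, float]
) -> SpinProbe:
    """Probe built from ``shift_<probe>_<state>``, ``r1_<probe>`` /
    ``r2_<probe>`` (optionally overridden per state by
    ``r1_<probe>_<state>``) parameters.  Missing shifts default to 0 ppm,
    which is harmless for zz-only fits where shifts never enter."""
    shifts, r1, r2 = {}, {}, {}
    for s in spec.states:
        shifts[s] = float(params.get(f"shift_{probe_name}_{s}", 0.0))
        r1[s] = float(
            params.get(f"r1_{probe_name}_{s}", params.get(f"r1_{probe_name}", 1.0))
        )
        r2[s] = float(
            params.get(
                f"r2_{probe_name}_{s}", params.get(f"r2_{probe_name}", r1[s])
            )
        )
    return SpinProbe(probe_name, shifts, r1, r2)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def _model_cest(dataset: CestDataset, network, probe) -> np.ndarray:
    from chexflux.bloch_mcconnell import simulate_cest_profile

    return simulate_cest_profile(network, probe, dataset.schedule, dataset.observed_state)


def _model_zz(dataset: ZzDataset, network, probe, scale: float) -> np.ndarray:
    K = build_rate_matrix(network)
    L = K - np.diag(probe.r1_vector(network))
    times, inv = np.unique(dataset.t_mix_s, return_inverse=True)
    P = scipy.linalg.expm(L[None, :, :] * times[:, None, None])
    oi = np.array([network.index(s) for s in dataset.origin_state])
    di = np.array([network.index(s) for s in dataset.destination_state])
    pops = network.populations
    return scale * P[inv, di, oi] * pops[oi]


def _evaluate(
    datasets: Sequence[Dataset], spec: NetworkSpec, values: Mapping[str, float]
) -> List[np.ndarray]:
    network = build_network_from_params(spec, values)
    out = []
    for ds in datasets:
        probe = build_probe_from_params(spec, ds.probe, values)
        if isinstance(ds, CestDataset):
            out.append(_model_cest(ds, network, probe))
        else:
            scale = float(values.get(f"scale_{ds.dataset_id}", 1.0))
            out.append(_model_zz(ds, network, probe, scale))
    return out


def _residual_vector(params: lmfit.Parameters, datasets, spec) -> np.ndarray:
    values = params.valuesdict()
    try:
        models = _evaluate(datasets, spec, values)
    except ValidationError:
        # infeasible parameter combination during optimization: large residual
        n = sum(ds.n_points for ds in datasets)
        return np.full(n, 1e6)
    res = [
        (ds.intensity - m) / ds.sigma for ds, m in zip(datasets, models)
    ]
    return np.concatenate(res)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Best-fit parameters, reduced chi-square and diagnostics.

    ``params`` holds every parameter (free and fixed) at its final value;
    ``stderr`` holds covariance-based standard errors where available
    (bootstrap errors are usually preferred).  ``at_bounds`` lists free
    parameters pinned at a bound, ``warnings`` carries identifiability
    and convergence flags, and ``success`` is False when no optimizer
    start converged (a flagged result, not an exception).
    """

    params: Dict[str, float]
    stderr: Dict[str, Optional[float]]
    chisqr: float
    redchi: float
    ndata: int
    nfree: int
    residuals_by_dataset: Dict[str, np.ndarray]
    at_bounds: List[str]
    warnings: List[str]
    success: bool
    datasets: Sequence[Dataset] = field(repr=False, default=())
    network_spec: Optional[NetworkSpec] = field(repr=False, default=None)
    parameter_specs: Tuple[ParameterSpec, ...] = field(repr=False, default=())

    def network(self) -> ExchangeNetwork:
        return build_network_from_params(self.network_spec, self.params)

    def free_names(self) -> List[str]:
        return [p.name for p in self.parameter_specs if p.vary]

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "stderr": self.stderr,
            "chisqr": self.chisqr,
            "redchi": self.redchi,
            "ndata": self.ndata,
            "nfree": self.nfree,
            "at_bounds": self.at_bounds,
            "warnings": self.warnings,
            "success": self.success,
        }


def _make_lmfit_params(parameter_specs: Sequence[ParameterSpec]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for p in parameter_specs:
        params.add(p.name, value=p.value, min=p.min, max=p.max, vary=p.vary)
    return params


def _lhs_starts(
    parameter_specs: Sequence[ParameterSpec], n_starts: int, seed: int
) -> List[Dict[str, float]]:
    """Initial-value sets: the user's initial values first, then LHS draws
    over the finite-bounded free parameters (log-spaced when both bounds
    are positive, as rates span decades)."""
    starts: List[Dict[str, float]] = [{p.name: p.value for p in parameter_specs}]
    if n_starts <= 1:
        return starts
    sampled = [
        p for p in parameter_specs if p.vary and np.isfinite(p.min) and np.isfinite(p.max)
    ]
    if not sampled:
        return starts
    sampler = qmc.LatinHypercube(d=len(sampled), seed=seed)
    unit = sampler.random(n=n_starts - 1)
    for row in unit:
        start = {p.name: p.value for p in parameter_specs}
        for u, p in zip(row, sampled):
            if p.min > 0 and p.max > 0:
                lo, hi = math.log(p.min), math.log(p.max)
                start[p.name] = math.exp(lo + u * (hi - lo))
            else:
                start[p.name] = p.min + u * (p.max - p.min)
        starts.append(start)
    return starts


def fit_model(
    datasets: Sequence[Dataset],
    network_spec: NetworkSpec,
    parameter_specs: Sequence[ParameterSpec],
    n_starts: int = 10,
    seed: int = 0,
    xtol: float = 1e-10,
    max_nfev: Optional[int] = None,
) -> FitResult:
    """Global fit of one or more CEST/zz datasets to an exchange model.

    Runs ``n_starts`` local trust-region least-squares optimizations (the
    first from the supplied initial values, the rest from a seeded
    Latin-hypercube over the bounded free parameters) and keeps the best
    chi-square; ties are broken by start order, so the result is
    deterministic given identical inputs and seed.
    """
    if not datasets:
        raise ValidationError("fit_model needs at least one dataset")
    parameter_specs = tuple(parameter_specs)
    ndata = sum(ds.n_points for ds in datasets)
    nfree = sum(1 for p in parameter_specs if p.vary)
    warns: List[str] = []
    if nfree == 0:
        # nothing to optimize: evaluate the objective (used when profiling
        # the only free parameter of a fit)
        values = {p.name: p.value for p in parameter_specs}
        models = _evaluate(datasets, network_spec, values)
        residuals = {
            ds.dataset_id: ds.intensity - m for ds, m in zip(datasets, models)
        }
        chisqr = float(
            sum(
                (((ds.intensity - m) / ds.sigma) ** 2).sum()
                for ds, m in zip(datasets, models)
            )
        )
        return FitResult(
            params=values,
            stderr={p.name: None for p in parameter_specs},
            chisqr=chisqr,
            redchi=chisqr / max(ndata, 1),
            ndata=ndata,
            nfree=0,
            residuals_by_dataset=residuals,
            at_bounds=[],
            warnings=warns,
            success=True,
            datasets=tuple(datasets),
            network_spec=network_spec,
            parameter_specs=parameter_specs,
        )
    if ndata < 3 * nfree:
        warns.append(
            f"possibly underdetermined: {ndata} points for {nfree} free parameters"
        )

    starts = _lhs_starts(parameter_specs, n_starts, seed)
    best = None
    for start in starts:
        params = _make_lmfit_params(parameter_specs)
        for name, v in start.items():
            if params[name].vary:
                params[name].value = v
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                result = lmfit.minimize(
                    _residual_vector,
                    params,
                    args=(datasets, network_spec),
                    method="least_squares",
                    xtol=xtol,
                    ftol=xtol,
                    gtol=xtol,
                    max_nfev=max_nfev,
                )
        except Exception:  # noqa: BLE001 - optimizer failure is a flagged result
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result

    if best is None:
        return FitResult(
            params={p.name: p.value for p in parameter_specs},
            stderr={p.name: None for p in parameter_specs},
            chisqr=math.nan,
            redchi=math.nan,
            ndata=ndata,
            nfree=nfree,
            residuals_by_dataset={},
            at_bounds=[],
            warnings=warns + ["optimizer failed to converge from every start"],
            success=False,
            datasets=tuple(datasets),
            network_spec=network_spec,
            parameter_specs=parameter_specs,
        )

    values = {k: float(v) for k, v in best.params.valuesdict().items()}
    stderr = {
        k: (float(best.params[k].stderr) if best.params[k].stderr is not None else None)
        for k in values
    }
    at_bounds = []
    for p in parameter_specs:
        if not p.vary:
            continue
        v = values[p.name]
        span = (p.max - p.min) if np.isfinite(p.max - p.min) else max(abs(v), 1.0)
        if (np.isfinite(p.min) and abs(v - p.min) < 1e-8 * span) or (
            np.isfinite(p.max) and abs(v - p.max) < 1e-8 * span
        ):
            at_bounds.append(p.name)
            warns.append(f"parameter {p.name} pinned at a bound")

    models = _evaluate(datasets, network_spec, values)
    residuals = {
        ds.dataset_id: ds.intensity - m for ds, m in zip(datasets, models)
    }
    dof = max(ndata - nfree, 1)
    chisqr = float(best.chisqr)
    return FitResult(
        params=values,
        stderr=stderr,
        chisqr=chisqr,
        redchi=chisqr / dof,
        ndata=ndata,
        nfree=nfree,
        residuals_by_dataset=residuals,
        at_bounds=at_bounds,
        warnings=warns,
        success=bool(best.success),
        datasets=tuple(datasets),
        network_spec=network_spec,
        parameter_specs=parameter_specs,
    )


# ---------------------------------------------------------------------------
# 1D reduced chi-square surfaces
# ---------------------------------------------------------------------------


@dataclass
class Chi2Surface:
    """Profile of reduced chi-square over a grid of one parameter.

    ``shallow`` is True when the surface varies by less than 0.2 in
    reduced chi-square across the whole grid, the signature of a poorly
    determined parameter (as seen for populations in CEST-only fits).
    """

    parameter: str
    grid: np.ndarray
    redchi: np.ndarray
    shallow: bool

    def minimum(self) -> Tuple[float, float]:
        i = int(np.argmin(self.redchi))
        return float(self.grid[i]), float(self.redchi[i])

    def points(self) -> List[Tuple[float, float]]:
        return list(zip(self.grid.tolist(), self.redchi.tolist()))


def chi2_surface_1d(
    fit_result: FitResult,
    parameter_name: str,
    grid: Sequence[float],
    n_starts: int = 1,
    shallow_threshold: float = 0.2,
) -> Chi2Surface:
    """Reduced chi-square profile: fix one parameter at each grid value and
    re-optimize all remaining free parameters (from the best-fit start)."""
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("chi2_surface_1d needs a non-empty grid")
    free = {p.name for p in fit_result.parameter_specs if p.vary}
    if parameter_name not in free:
        raise ValidationError(f"parameter {parameter_name!r} is not free in the fit")

    redchi = np.empty(grid.size)
    ndata = fit_result.ndata
    dof = max(ndata - (fit_result.nfree - 1), 1)
    for a, g in enumerate(grid):
        specs = []
        for p in fit_result.parameter_specs:
            v = fit_result.params[p.name]
            if p.name == parameter_name:
                specs.append(replace(p, value=float(g), min=-math.inf, max=math.inf, vary=False))
            else:
                v = min(max(v, p.min), p.max)
                specs.append(replace(p, value=v))
        sub = fit_model(
            fit_result.datasets,
            fit_result.network_spec,
            specs,
            n_starts=n_starts,
            seed=0,
        )
        redchi[a] = sub.chisqr / dof
    shallow = bool(redchi.max() - redchi.min() < shallow_threshold)
    return Chi2Surface(parameter_name, grid, redchi, shallow)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap distributions and their summary moments."""

    distributions: Dict[str, np.ndarray]
    mean: Dict[str, float]
    sd: Dict[str, float]
    n_replicates: int
    n_failed: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
        }


def bootstrap(
    datasets: Sequence[Dataset],
    network_spec: NetworkSpec,
    parameter_specs: Sequence[ParameterSpec],
    n_replicates: int = 1000,
    seed: int = 0,
    start_from: Optional[Mapping[str, float]] = None,
    max_failure_fraction: float = 0.2,
    progress: Optional[Callable[[int, int], None]] = None,
) -> BootstrapResult:
    """Point-level bootstrap of a global fit.

    For each replicate every profile is resampled with replacement at the
    data-point level, preserving its own point count, and the model is
    refit starting from ``start_from`` (typically the original best fit).
    Failed replicate fits are dropped and counted; more than
    ``max_failure_fraction`` failures raises.
    """
    if n_replicates < 2:
        raise ValidationError("bootstrap needs n_replicates >= 2")
    rng = np.random.default_rng(seed)
    if start_from is not None:
        parameter_specs = tuple(
            replace(
                p,
                value=min(max(float(start_from.get(p.name, p.value)), p.min), p.max),
            )
            for p in parameter_specs
        )
    else:
        parameter_specs = tuple(parameter_specs)
    free = [p.name for p in parameter_specs if p.vary]
    draws: Dict[str, List[float]] = {name: [] for name in free}
    n_failed = 0
    for rep in range(n_replicates):
        resampled = []
        for ds in datasets:
            idx = rng.integers(0, ds.n_points, ds.n_points)
            resampled.append(ds.subset(idx))
        fit = fit_model(
            resampled, network_spec, parameter_specs, n_starts=1, seed=seed
        )
        if not fit.success or not math.isfinite(fit.chisqr):
            n_failed += 1
        else:
            for name in free:
                draws[name].append(fit.params[name])
        if progress is not None:
            progress(rep + 1, n_replicates)
    if n_failed > max_failure_fraction * n_replicates:
        raise ValidationError(
            f"bootstrap: {n_failed}/{n_replicates} replicate fits failed"
        )
    dists = {k: np.asarray(v) for k, v in draws.items()}
    return BootstrapResult(
        distributions=dists,
        mean={k: float(v.mean()) for k, v in dists.items()},
        sd={k: float(v.std(ddof=1)) for k, v in dists.items()},
        n_replicates=n_replicates,
        n_failed=n_failed,
    )


def population_distributions(
    network_spec: NetworkSpec, boot: BootstrapResult, fixed: Mapping[str, float]
) -> Dict[str, np.ndarray]:
    """Per-state population draws implied by a kex_pop bootstrap.

    ``fixed`` supplies values for any non-varying ``logp_`` parameters
    (e.g. the gauge-fixing one), typically ``fit_result.params``.
    """
    if network_spec.parameterization != "kex_pop":
        raise ValidationError("population draws require the kex_pop parameterization")
    n = min(
        (len(v) for k, v in boot.distributions.items() if k.startswith("logp_")),
        default=None,
    )
    cols = []
    for s in network_spec.states:
        name = f"logp_{s}"
        if name in boot.distributions:
            cols.append(np.asarray(boot.distributions[name]))
        else:
            if n is None:
                raise ValidationError("no logp_ draws in bootstrap result")
            cols.append(np.full(n, float(fixed[name])))
    logp = np.column_stack(cols)
    w = np.exp(logp - logp.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    return {s: p[:, i] for i, s in enumerate(network_spec.states)}
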