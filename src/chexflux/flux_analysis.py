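"""Flux partitioning between conformational-selection and induced-fit paths.

At equilibrium the flux into the bound state ``UK`` along a pathway is the
rate-limiting forward flow through that pathway, in units of
population-fraction per second (total protein concentration normalizes
out when comparing pathways).  The partitioning ratio is

    Theta = F_CS / F_IF = (k_UB / k_NB) * (p_U / p_N)

for one-way (zz-derived) rates.  CEST fits determine per-edge exchange
rates ``k_ex = k_forward + k_reverse`` instead; with detailed balance the
one-way rates follow from populations and Theta becomes

    Theta = (k_ex,UB / k_ex,NB) * Xi,
    Xi = [p_U * (p_N + p_B)] / [p_N * (p_U + p_B)],

so whenever p_N is close to p_U the population factor Xi is close to 1
and Theta reduces to the ratio of exchange rates.

Rates for pathways whose cross-peaks are invisible can only be bounded
from above by asking how fast the exchange could be before the missing
cross-peak would have risen above the noise floor
(:func:`upper_bound_rate`).  A Theta computed with an upper-bound
denominator is a lower bound and is flagged as such.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np

from chexflux.bloch_mcconnell import ZzSchedule, simulate_zz_intensities
from chexflux.exchange_model import (
    ExchangeNetwork,
    SpinProbe,
    ValidationError,
    bimolecular_from_pseudo,
)

__all__ = [
    "PathwayFlux",
    "FluxReport",
    "theta_from_zz",
    "theta_from_cest",
    "xi",
    "bimolecular_kon",
    "upper_bound_rate",
    "flux_report",
]


@dataclass(frozen=True)
class PathwayFlux:
    """Flux through one binding pathway, possibly only a bound."""

    pathway: str  # e.g. "U->UK"
    flux: float  # fraction * s^-1
    bound: Optional[str] = None  # None (exact), "upper" or "lower"

    def label(self) -> str:
        tag = {None: "", "upper": " (upper bound)", "lower": " (lower bound)"}[self.bound]
        return f"{self.pathway}{tag}"


def theta_from_zz(k_UB: float, k_NB: float, p_U: float, p_N: float) -> float:
    """CS/IF flux ratio from one-way rates: (k_UB/k_NB)*(p_U/p_N).

    Populations may be given as fractions or percentages; only their
    ratio enters.  When ``k_NB`` is an upper bound the returned Theta is
    a lower bound.  ``k_NB = 0`` yields +inf.
    """
    if k_UB <= 0 or p_U <= 0 or p_N <= 0:
        raise ValidationError("theta_from_zz requires k_UB, p_U, p_N > 0")
    if k_NB < 0:
        raise ValidationError("k_NB must be >= 0")
    if k_NB == 0:
        return math.inf
    return (k_UB / k_NB) * (p_U / p_N)


def xi(p_N, p_U, p_B):
    """Population factor relating Theta to the ratio of exchange rates.

    Xi = [p_U*(p_N+p_B)] / [p_N*(p_U+p_B)]; equals 1 when p_N == p_U.
    Accepts scalars or arrays (elementwise).
    """
    p_N = np.asarray(p_N, dtype=float)
    p_U = np.asarray(p_U, dtype=float)
    p_B = np.asarray(p_B, dtype=float)
    if np.any(p_N <= 0) or np.any(p_U <= 0) or np.any(p_B <= 0):
        raise ValidationError("xi requires all populations > 0")
    out = (p_U * (p_N + p_B)) / (p_N * (p_U + p_B))
    return float(out) if out.ndim == 0 else out


def theta_from_cest(
    k_ex_UB: float, k_ex_NB: float, p_N: float, p_U: float, p_B: float
) -> float:
    """CS/IF flux ratio from per-edge exchange rates:
    (k_ex,UB/k_ex,NB) * Xi(p_N, p_U, p_B)."""
    if k_ex_UB <= 0:
        raise ValidationError("k_ex_UB must be > 0")
    if k_ex_NB < 0:
        raise ValidationError("k_ex_NB must be >= 0")
    if k_ex_NB == 0:
        return math.inf
    return (k_ex_UB / k_ex_NB) * xi(p_N, p_U, p_B)


def bimolecular_kon(k_pseudo: float, ligand_conc: float) -> float:
    """Bimolecular on-rate k_on = k_pseudo / [L] in M^-1 s^-1."""
    if k_pseudo < 0:
        raise ValidationError("k_pseudo must be >= 0")
    return bimolecular_from_pseudo(k_pseudo, ligand_conc)


def upper_bound_rate(
    R1_origin: float,
    R1_dest: float,
    p_origin: float,
    p_dest: float,
    t_mix_grid: Sequence[float],
    diag_intensity_scale: float,
    noise_level: float,
    k_max_search: float = 10.0,
    rel_tol: float = 1e-4,
) -> float:
    """Largest forward rate consistent with an invisible cross-peak.

    Simulates the two-state zz-exchange cross-peak between two states of
    the given populations (the reverse rate follows from detailed
    balance) and intensity scale ``diag_intensity_scale`` per unit
    population, and finds, by bisection, the largest forward rate whose
    maximal cross-peak over the mixing-time grid stays at or below
    ``noise_level``.  Returns +inf when even ``k_max_search`` keeps the
    cross-peak below the noise (unbounded), and 0 for zero noise.
    """
    if noise_level < 0:
        raise ValidationError("noise_level must be >= 0")
    if p_origin <= 0 or p_dest <= 0:
        raise ValidationError("populations must be > 0")
    if noise_level == 0.0:
        return 0.0
    times = np.asarray(sorted(t_mix_grid), dtype=float)
    schedule = ZzSchedule(tuple(times))

    def max_cross(k_forward: float) -> float:
        k_back = k_forward * p_origin / p_dest  # detailed balance
        total = p_origin + p_dest
        net = ExchangeNetwork(
            ("O", "D"),
            {("O", "D"): k_forward, ("D", "O"): k_back},
            populations=np.array([p_origin / total, p_dest / total]),
        )
        probe = SpinProbe(
            "bound_probe",
            {"O": 0.0, "D": 0.0},
            {"O": R1_origin, "D": R1_dest},
            {"O": max(R1_origin, R1_dest), "D": max(R1_origin, R1_dest)},
        )
        curves = simulate_zz_intensities(net, probe, schedule)
        # populations inside the 2-state system are normalized; rescale to
        # the absolute fractions of the full network
        cross = curves[("O", "D")] * total * diag_intensity_scale
        return float(cross.max())

    if max_cross(k_max_search) <= noise_level:
        return math.inf
    lo, hi = 0.0, k_max_search
    while hi - lo > rel_tol * max(hi, 1e-12):
        mid = 0.5 * (lo + hi)
        if max_cross(mid) <= noise_level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class FluxReport:
    """Pathway fluxes, Theta/Xi partitioning and the bimolecular on-rate.

    Fluxes are in population-fraction * s^-1; multiply by the total
    protein concentration for molar flux.  Entries derived from
    upper-bound rates carry the corresponding bound flag, as does Theta
    when its denominator pathway is only bounded.
    """

    pathways: List[PathwayFlux]
    theta: Optional[float] = None
    theta_bound: Optional[str] = None  # "lower" when k_NB is an upper bound
    theta_route: Optional[str] = None  # "zz" | "cest"
    xi_value: Optional[float] = None
    k_on: Optional[float] = None  # M^-1 s^-1

    @property
    def f_cs(self) -> float:
        return sum(p.flux for p in self.pathways if p.pathway.startswith("U->"))

    @property
    def f_if(self) -> float:
        return sum(p.flux for p in self.pathways if "NK" in p.pathway)

    def to_dict(self) -> dict:
        return {
            "pathways": [
                {"pathway": p.pathway, "flux": p.flux, "bound": p.bound}
                for p in self.pathways
            ],
            "theta": self.theta,
            "theta_bound": self.theta_bound,
            "theta_route": self.theta_route,
            "xi": self.xi_value,
            "k_on": self.k_on,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "FluxReport":
        """Parse and structurally validate a serialized report."""
        data = json.loads(text)
        required = {"pathways", "theta", "theta_bound", "theta_route", "xi", "k_on"}
        missing = required - set(data)
        if missing:
            raise ValidationError(f"flux report JSON missing keys: {sorted(missing)}")
        pathways = []
        for entry in data["pathways"]:
            if not {"pathway", "flux", "bound"} <= set(entry):
                raise ValidationError(f"malformed pathway entry: {entry}")
            if entry["bound"] not in (None, "upper", "lower"):
                raise ValidationError(f"invalid bound flag: {entry['bound']!r}")
            if not isinstance(entry["flux"], (int, float)) or entry["flux"] < 0:
                raise ValidationError(f"invalid flux value: {entry['flux']!r}")
            pathways.append(
                PathwayFlux(entry["pathway"], float(entry["flux"]), entry["bound"])
            )
        return cls(
            pathways=pathways,
            theta=data["theta"],
            theta_bound=data["theta_bound"],
            theta_route=data["theta_route"],
            xi_value=data["xi"],
            k_on=data["k_on"],
        )

    def to_table(self) -> str:
        lines = ["pathway\tflux_fraction_per_s\tbound"]
        for p in self.pathways:
            lines.append(f"{p.pathway}\t{p.flux:.6g}\t{p.bound or 'exact'}")
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        out = ["Flux report", "-----------"]
        for p in self.pathways:
            out.append(f"  {p.label():<28s} {p.flux:.4g} fraction/s")
        if self.theta is not None:
            cmp = {"lower": "> ", "upper": "< ", None: "= "}[self.theta_bound]
            out.append(f"  Theta (F_CS/F_IF, {self.theta_route}) {cmp}{self.theta:.4g}")
        if self.xi_value is not None:
            out.append(f"  Xi = {self.xi_value:.4g}")
        if self.k_on is not None:
            out.append(f"  k_on = {self.k_on:.4g} M^-1 s^-1")
        return "\n".join(out)


def flux_report(
    rates: Mapping[str, float],
    populations: Mapping[str, float],
    ligand_conc: Optional[float] = None,
    bounds: Mapping[str, str] = (),
    route: str = "zz",
    kex_rates: Optional[Mapping[str, float]] = None,
) -> FluxReport:
    """Assemble a FluxReport from fitted rates and populations.

    Parameters
    ----------
    rates:
        One-way rate constants keyed ``"k_UB"``, ``"k_NU"``, ``"k_NB"``
        (s^-1); any that are only bounds should also appear in ``bounds``.
    populations:
        State fractions keyed ``"N"``, ``"U"``, ``"B"``.
    bounds:
        Mapping rate-name -> ``"upper"``/``"lower"`` for rates known only
        as bounds (e.g. ``{"k_NB": "upper", "k_NU": "upper"}``).
    route:
        ``"zz"`` uses one-way rates for Theta; ``"cest"`` uses
        ``kex_rates`` (``"k_ex_UB"``, ``"k_ex_NB"``) and the Xi factor.

    Pathway fluxes at equilibrium (fraction * s^-1):

    * ``U->UK``: ``k_UB * p_U``;
    * ``N->U->UK``: ``min(k_NU * p_N, k_UB * p_U)`` (rate-limiting step);
    * ``N->NK->UK``: ``k_NB * p_N`` (the NK intermediate is folded into
      the single observable N->B step).
    """
    bounds = dict(bounds)
    for name in ("k_UB", "k_NB", "k_NU"):
        if name not in rates:
            raise ValidationError(f"flux_report: missing required rate {name!r}")
    for s in ("N", "U", "B"):
        if s not in populations:
            raise ValidationError(f"flux_report: missing population for state {s!r}")
    k_UB, k_NB, k_NU = rates["k_UB"], rates["k_NB"], rates["k_NU"]
    p_N, p_U, p_B = populations["N"], populations["U"], populations["B"]

    def _propagate(*names: str) -> Optional[str]:
        flags = {bounds.get(n) for n in names if n in bounds}
        flags.discard(None)
        if not flags:
            return None
        if flags == {"upper"}:
            return "upper"
        if flags == {"lower"}:
            return "lower"
        raise ValidationError(f"conflicting bound flags for {names}")

    cs_direct = PathwayFlux("U->UK", k_UB * p_U, _propagate("k_UB"))
    nu_flux = k_NU * p_N
    ub_flux = k_UB * p_U
    cs_via_n = PathwayFlux(
        "N->U->UK",
        min(nu_flux, ub_flux),
        _propagate("k_NU", "k_UB") if nu_flux <= ub_flux else _propagate("k_UB"),
    )
    if_path = PathwayFlux("N->NK->UK", k_NB * p_N, _propagate("k_NB"))

    if route == "zz":
        theta = theta_from_zz(k_UB, k_NB, p_U, p_N) if k_NB >= 0 else None
        xi_val = None
    elif route == "cest":
        if kex_rates is None:
            raise ValidationError("route='cest' requires kex_rates")
        for name in ("k_ex_UB", "k_ex_NB"):
            if name not in kex_rates:
                raise ValidationError(f"flux_report: missing exchange rate {name!r}")
        xi_val = xi(p_N, p_U, p_B)
        theta = theta_from_cest(
            kex_rates["k_ex_UB"], kex_rates["k_ex_NB"], p_N, p_U, p_B
        )
    else:
        raise ValidationError(f"unknown Theta route {route!r}")
    theta_bound = {"upper": "lower", "lower": "upper", None: None}[
        bounds.get("k_NB" if route == "zz" else "k_ex_NB")
    ]

    k_on = None
    if ligand_conc is not None:
        k_on = bimolecular_kon(k_UB, ligand_conc)

    return FluxReport(
        pathways=[cs_direct, cs_via_n, if_path],
        theta=theta,
        theta_bound=theta_bound,
        theta_route=route,
        xi_value=xi_val,
        k_on=k_on,
    )
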