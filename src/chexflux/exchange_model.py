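"""Exchange-network topologies, rate matrices and population algebra.

An :class:`ExchangeNetwork` is a set of named kinetic states (e.g. native
``N``, unfolded ``U``, chaperone-bound ``B``) connected by first-order rate
constants.  Bimolecular binding steps are folded in as pseudo-first-order
constants at a fixed free-ligand concentration, ``k_UB = k_on * [L]``.  All
networks in scope are equilibrium networks, so detailed balance
(``p_i * k_ij == p_j * k_ji`` for every connected pair) is enforced at
construction, not merely warned about.

Populations are handled internally as fractions summing to 1; percentages
appear only in reporting helpers such as
:func:`solve_three_state_populations`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg

__all__ = [
    "ExchangeNetwork",
    "SpinProbe",
    "ValidationError",
    "build_rate_matrix",
    "equilibrium_populations",
    "solve_three_state_populations",
    "pseudo_first_order",
    "bimolecular_from_pseudo",
]

RateKey = Tuple[str, str]


class ValidationError(ValueError):
    """An exchange model violates one of its structural invariants."""


def _connected_components(states: Sequence[str], rates: Mapping[RateKey, float]):
    """Components of the undirected graph induced by nonzero rates."""
    adj: Dict[str, set] = {s: set() for s in states}
    for (i, j), k in rates.items():
        if k > 0.0:
            adj[i].add(j)
            adj[j].add(i)
    seen: set = set()
    comps = []
    for s in states:
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.append(sorted(comp, key=list(states).index))
    return comps


@dataclass(frozen=True)
class ExchangeNetwork:
    """Named kinetic states with first-order exchange rates between them.

    Parameters
    ----------
    states:
        Ordered state labels, e.g. ``("N", "U", "B")``.
    rates:
        Mapping ``(i, j) -> k_ij`` in s^-1 for the *i -> j* conversion.
        Binding steps are pseudo-first-order (``k_on * [L]``).  Whenever a
        directed rate is given, the reverse key must be present too (an
        explicit zero is allowed only when both directions are zero).
    ligand_conc:
        Free-ligand (chaperone) concentration in M, if any binding step is
        pseudo-first-order.  Optional; only needed by bimolecular helpers.
    populations:
        Equilibrium fractions in state order.  If omitted they are derived
        from the rate matrix, which requires a connected network.
    """

    states: Tuple[str, ...]
    rates: Mapping[RateKey, float]
    ligand_conc: Optional[float] = None
    populations: Optional[np.ndarray] = None

    def __post_init__(self):
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(set(states)) != len(states):
            raise ValidationError(f"duplicate state labels in {states}")
        rates = dict(self.rates)
        for (i, j), k in rates.items():
            if i not in states or j not in states:
                raise ValidationError(f"rate {i}->{j} references unknown state")
            if i == j:
                raise ValidationError(f"self-rate {i}->{i} is not allowed")
            if not np.isfinite(k) or k < 0.0:
                raise ValidationError(f"rate {i}->{j} = {k} must be finite and >= 0")
            if (j, i) not in rates:
                raise ValidationError(
                    f"rate {i}->{j} given without the reverse {j}->{i} "
                    "(use an explicit zero if needed)"
                )
        object.__setattr__(self, "rates", rates)
        if self.ligand_conc is not None and self.ligand_conc <= 0.0:
            raise ValidationError("ligand_conc must be > 0 when given")

        if self.populations is None:
            if any(k > 0 for k in rates.values()):
                pops = equilibrium_populations(self, _validate=False)
            else:
                pops = np.full(len(states), 1.0 / len(states))
            object.__setattr__(self, "populations", pops)
        else:
            pops = np.asarray(self.populations, dtype=float)
            if pops.shape != (len(states),):
                raise ValidationError(
                    f"populations must have length {len(states)}, got {pops.shape}"
                )
            if np.any(pops < 0.0):
                raise ValidationError("populations must be >= 0")
            if abs(pops.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"populations must sum to 1 within 1e-9 (sum={pops.sum()!r})"
                )
            object.__setattr__(self, "populations", pops)
        self._check_detailed_balance()

    def _check_detailed_balance(self, rtol: float = 1e-6):
        p = dict(zip(self.states, self.populations))
        for (i, j), kij in self.rates.items():
            kji = self.rates[(j, i)]
            fwd, rev = p[i] * kij, p[j] * kji
            scale = max(fwd, rev)
            if scale > 0 and abs(fwd - rev) > rtol * scale:
                raise ValidationError(
                    f"detailed balance violated on {i}<->{j}: "
                    f"p_{i}*k = {fwd:.6g} vs p_{j}*k = {rev:.6g}"
                )

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_kex(
        cls,
        states: Sequence[str],
        populations: Sequence[float],
        kex: Mapping[Union[RateKey, frozenset], float],
        ligand_conc: Optional[float] = None,
    ) -> "ExchangeNetwork":
        """Build a network from per-edge exchange rates and populations.

        For an edge *i-j* with exchange rate ``k_ex = k_ij + k_ji``,
        detailed balance fixes the one-way rates as
        ``k_ij = k_ex * p_j / (p_i + p_j)`` and symmetrically for the
        reverse.  This is the natural parameterization of CEST fits, where
        ``k_ex`` per edge is well determined but one-way rates are not.
        """
        pops = np.asarray(populations, dtype=float)
        p = dict(zip(states, pops))
        rates: Dict[RateKey, float] = {}
        for key, k in kex.items():
            i, j = tuple(key)
            denom = p[i] + p[j]
            if denom <= 0:
                raise ValidationError(f"edge {i}-{j} has zero total population")
            rates[(i, j)] = k * p[j] / denom
            rates[(j, i)] = k * p[i] / denom
        return cls(tuple(states), rates, ligand_conc=ligand_conc, populations=pops)

    # -- accessors ----------------------------------------------------------------

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValidationError(
                f"state {state!r} not in network {self.states}"
            ) from None

    def rate(self, i: str, j: str) -> float:
        return float(self.rates.get((i, j), 0.0))

    def kex(self, i: str, j: str) -> float:
        """Exchange rate ``k_ij + k_ji`` for the *i-j* edge."""
        return self.rate(i, j) + self.rate(j, i)

    def population(self, state: str) -> float:
        return float(self.populations[self.index(state)])


@dataclass(frozen=True)
class SpinProbe:
    """One methyl 1H reporter: per-state shifts and relaxation rates.

    ``shift_ppm`` maps state label -> 1H chemical shift in ppm; ``r1`` and
    ``r2`` map state label -> longitudinal/transverse relaxation rate in
    s^-1.  A single apparent R1 (and R2) per resonance is the common
    experimental situation; use :meth:`shared` for that case.
    """

    probe_name: str
    shift_ppm: Mapping[str, float]
    r1: Mapping[str, float]
    r2: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "shift_ppm", dict(self.shift_ppm))
        object.__setattr__(self, "r1", dict(self.r1))
        object.__setattr__(self, "r2", dict(self.r2))
        for s, v in self.r1.items():
            if v <= 0:
                raise ValidationError(f"{self.probe_name}: R1[{s}] must be > 0")
        for s, v in self.r2.items():
            if s in self.r1 and v < self.r1[s]:
                raise ValidationError(
                    f"{self.probe_name}: R2[{s}] = {v} < R1[{s}] = {self.r1[s]}"
                )

    @classmethod
    def shared(
        cls,
        probe_name: str,
        shift_ppm: Mapping[str, float],
        r1: float,
        r2: float,
    ) -> "SpinProbe":
        """Probe with one R1 and one R2 shared across all states."""
        states = list(shift_ppm)
        return cls(
            probe_name,
            dict(shift_ppm),
            {s: float(r1) for s in states},
            {s: float(r2) for s in states},
        )

    def check_covers(self, network: ExchangeNetwork):
        missing = [s for s in network.states if s not in self.shift_ppm]
        if missing:
            raise ValidationError(
                f"probe {self.probe_name!r} lacks shifts for states {missing}"
            )
        for attr in ("r1", "r2"):
            vals = getattr(self, attr)
            missing = [s for s in network.states if s not in vals]
            if missing:
                raise ValidationError(
                    f"probe {self.probe_name!r} lacks {attr} for states {missing}"
                )

    def shifts(self, network: ExchangeNetwork) -> np.ndarray:
        return np.array([self.shift_ppm[s] for s in network.states])

    def r1_vector(self, network: ExchangeNetwork) -> np.ndarray:
        return np.array([self.r1[s] for s in network.states])

    def r2_vector(self, network: ExchangeNetwork) -> np.ndarray:
        return np.array([self.r2[s] for s in network.states])


def build_rate_matrix(network: ExchangeNetwork) -> np.ndarray:
    """Exchange rate matrix K with ``K[j, i] = k_ij`` and conserving columns.

    The convention is ``dp/dt = K @ p`` for the state-population vector
    ``p``, so each column sums to zero (probability conservation) and the
    diagonal carries the total outflow ``K[i, i] = -sum_j k_ij``.
    """
    n = len(network.states)
    idx = {s: a for a, s in enumerate(network.states)}
    K = np.zeros((n, n))
    for (i, j), k in network.rates.items():
        K[idx[j], idx[i]] += k
        K[idx[i], idx[i]] -= k
    return K


def equilibrium_populations(
    network: ExchangeNetwork, _validate: bool = True
) -> np.ndarray:
    """Stationary populations p with ``K @ p = 0`` and ``sum(p) = 1``.

    Requires a connected network; for a disconnected one the stationary
    distribution is not unique and the offending components are named in
    the error.
    """
    comps = _connected_components(network.states, network.rates)
    if len(comps) > 1:
        raise ValidationError(
            "network is disconnected; cannot derive unique equilibrium "
            f"populations (components: {comps})"
        )
    K = build_rate_matrix(network)
    ns = scipy.linalg.null_space(K)
    if ns.shape[1] != 1:  # pragma: no cover - guarded by connectivity check
        raise ValidationError("rate matrix null space is not one-dimensional")
    p = ns[:, 0]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise ValidationError("equilibrium populations came out negative")
    return np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum()


def solve_three_state_populations(
    ratio_N_over_U: float, ratio_U_over_B: float
) -> Tuple[float, float, float]:
    """(p_N, p_U, p_B) in percent from the two measured population ratios.

    The native/unfolded ratio typically comes from relative peak
    intensities in the first zz-exchange plane, and the unfolded/bound
    ratio from the fitted rate constants (``p_U/p_B = k_BU/k_UB``).
    """
    if ratio_N_over_U <= 0 or ratio_U_over_B <= 0:
        raise ValidationError("population ratios must be > 0")
    p_b = 1.0
    p_u = ratio_U_over_B * p_b
    p_n = ratio_N_over_U * p_u
    total = p_n + p_u + p_b
    return (100.0 * p_n / total, 100.0 * p_u / total, 100.0 * p_b / total)


def pseudo_first_order(k_on: float, ligand_conc: float) -> float:
    """Pseudo-first-order binding rate ``k_on * [L]`` in s^-1."""
    if ligand_conc <= 0:
        raise ValidationError("ligand_conc must be > 0")
    return k_on * ligand_conc


def bimolecular_from_pseudo(k_pseudo: float, ligand_conc: float) -> float:
    """Bimolecular on-rate ``k_pseudo / [L]`` in M^-1 s^-1."""
    if ligand_conc <= 0:
        raise ValidationError("ligand_conc must be > 0")
    return k_pseudo / ligand_conc
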