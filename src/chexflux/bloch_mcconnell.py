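"""Bloch-McConnell simulation of CEST profiles and zz-exchange curves.

The magnetization of each exchanging state is a three-vector
``(Mx, My, Mz)``; chemical exchange couples corresponding components of
different states at the first-order rates of the network, while within a
state the usual Bloch terms act: precession at the resonance offset
``Omega_i = 2*pi*nu0_MHz*(delta_i - delta_rf)`` rad/s (ppm * MHz = Hz),
nutation by the saturation field ``omega1 = 2*pi*B1`` applied along x, and
relaxation ``-R2`` on the transverse and ``-R1`` on the longitudinal
component.  The equation of motion is homogeneous (no return-to-thermal
term): over the short exchange periods used here the measured observable
is referenced to a ``T_EX = 0`` plane, so a far off-resonance profile
decays as ``exp(-R1*T_EX)`` rather than returning to 1.

zz-exchange mixing involves longitudinal order only, so its evolution
matrix is simply the exchange matrix minus ``diag(R1)``.

Propagation uses the dense matrix exponential (scaling and squaring);
networks in scope have at most ~6 states, i.e. <= 18 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

from chexflux.exchange_model import (
    ExchangeNetwork,
    SpinProbe,
    ValidationError,
    build_rate_matrix,
)

__all__ = [
    "CestSchedule",
    "ZzSchedule",
    "CestDataset",
    "ZzDataset",
    "NoeDip",
    "cest_evolution_matrix",
    "simulate_cest_profile",
    "simulate_zz_intensities",
    "fit_r1_decay",
    "R1FitResult",
    "populations_from_first_plane",
    "default_cest_schedule",
    "default_zz_schedule",
]


@dataclass(frozen=True)
class CestSchedule:
    """Saturation schedule: rf offsets, B1 amplitude, duration, field.

    ``spectrometer_mhz`` is the 1H Larmor frequency used for the ppm <-> Hz
    conversion (one ppm equals ``spectrometer_mhz`` Hz).
    """

    offsets_ppm: Tuple[float, ...]
    b1_hz: float = 20.3
    t_ex_s: float = 0.150
    spectrometer_mhz: float = 800.0
    includes_reference: bool = True

    def __post_init__(self):
        object.__setattr__(self, "offsets_ppm", tuple(float(o) for o in self.offsets_ppm))
        if self.b1_hz <= 0:
            raise ValidationError("b1_hz must be > 0")
        if self.t_ex_s < 0:
            raise ValidationError("t_ex_s must be >= 0")
        if self.spectrometer_mhz <= 0:
            raise ValidationError("spectrometer_mhz must be > 0")


@dataclass(frozen=True)
class ZzSchedule:
    """Mixing-time schedule for zz-exchange, strictly increasing, in s."""

    mixing_times_s: Tuple[float, ...]

    def __post_init__(self):
        t = tuple(float(x) for x in self.mixing_times_s)
        object.__setattr__(self, "mixing_times_s", t)
        arr = np.asarray(t)
        if np.any(arr < 0):
            raise ValidationError("mixing times must be >= 0")
        if np.any(np.diff(arr) <= 0):
            raise ValidationError("mixing times must be strictly increasing")


def default_cest_schedule(
    n_offsets: int = 40,
    span_ppm: Tuple[float, float] = (1.0, -0.2),
    b1_hz: float = 20.3,
    t_ex_s: float = 0.150,
    spectrometer_mhz: float = 800.0,
) -> CestSchedule:
    """The standard Ile-methyl 1H CEST acquisition: 40 offsets, 1.0 to
    -0.2 ppm, B1 = 20.3 Hz, T_EX = 150 ms at 800 MHz."""
    offsets = np.linspace(span_ppm[0], span_ppm[1], n_offsets)
    return CestSchedule(tuple(offsets), b1_hz, t_ex_s, spectrometer_mhz)


def default_zz_schedule(
    n_times: int = 13, span_s: Tuple[float, float] = (0.025, 0.800)
) -> ZzSchedule:
    """13 mixing times from 25 to 800 ms, evenly spaced."""
    return ZzSchedule(tuple(np.linspace(span_s[0], span_s[1], n_times)))


@dataclass(frozen=True)
class NoeDip:
    """A longitudinal cross-relaxation contamination of a CEST profile.

    A non-exchanging pseudo-spin resonating at ``partner_shift_ppm`` is
    coupled to the Mz channel of ``target_state`` with symmetric rate
    ``sigma_noe_s``.  Saturating the partner therefore carves a spurious
    minor dip at its shift into the target-state profile that does *not*
    report chemical exchange.
    """

    target_state: str
    partner_shift_ppm: float
    sigma_noe_s: float

    def __post_init__(self):
        if self.sigma_noe_s < 0:
            raise ValidationError("sigma_noe_s must be >= 0")


@dataclass
class CestDataset:
    """One measured or simulated CEST profile for one probe in one state."""

    probe: str
    observed_state: str
    schedule: CestSchedule
    intensity: np.ndarray  # I/I0 per offset
    sigma: np.ndarray
    dataset_id: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.schedule.offsets_ppm)
        if self.intensity.shape != (n,) or self.sigma.shape != (n,):
            raise ValidationError(
                f"CEST dataset arrays must match the {n}-point schedule"
            )
        if np.any(self.sigma <= 0):
            raise ValidationError("uncertainties must be > 0")
        if np.any(self.intensity > 1.0 + 5.0 * self.sigma):
            raise ValidationError("CEST intensity ratios exceed 1 + 5*sigma")
        if not self.dataset_id:
            self.dataset_id = f"cest_{self.probe}_{self.observed_state}"

    @property
    def n_points(self) -> int:
        return self.intensity.size

    def subset(self, idx: np.ndarray) -> "CestDataset":
        """Dataset restricted to (possibly repeated) point indices."""
        sched = replace(
            self.schedule,
            offsets_ppm=tuple(np.asarray(self.schedule.offsets_ppm)[idx]),
        )
        return CestDataset(
            self.probe,
            self.observed_state,
            sched,
            self.intensity[idx],
            self.sigma[idx],
            dataset_id=self.dataset_id,
        )


@dataclass
class ZzDataset:
    """zz-exchange peak intensities in long form.

    Each row is one (origin, destination, mixing time) triple; origin ==
    destination rows are diagonal peaks, the rest are cross-peaks.
    Intensities are in arbitrary units on a common scale within the
    dataset.
    """

    probe: str
    origin_state: np.ndarray
    destination_state: np.ndarray
    t_mix_s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    dataset_id: str = ""

    def __post_init__(self):
        self.origin_state = np.asarray(self.origin_state, dtype=object)
        self.destination_state = np.asarray(self.destination_state, dtype=object)
        self.t_mix_s = np.asarray(self.t_mix_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.t_mix_s.size
        for arr in (self.origin_state, self.destination_state, self.intensity, self.sigma):
            if arr.shape != (n,):
                raise ValidationError("zz dataset columns must have equal length")
        if np.any(self.sigma <= 0):
            raise ValidationError("uncertainties must be > 0")
        if not self.dataset_id:
            self.dataset_id = f"zz_{self.probe}"

    @property
    def n_points(self) -> int:
        return self.t_mix_s.size

    def subset(self, idx: np.ndarray) -> "ZzDataset":
        return ZzDataset(
            self.probe,
            self.origin_state[idx],
            self.destination_state[idx],
            self.t_mix_s[idx],
            self.intensity[idx],
            self.sigma[idx],
            dataset_id=self.dataset_id,
        )


# ---------------------------------------------------------------------------
# evolution matrices and propagation
# ---------------------------------------------------------------------------


def _spin_layout(network: ExchangeNetwork, noe_dips: Sequence[NoeDip] = ()):
    """Total spin count and per-spin (shift source, R1/R2 source) layout."""
    n_states = len(network.states)
    n_spins = n_states + len(noe_dips)
    return n_states, n_spins


def cest_evolution_matrix(
    network: ExchangeNetwork,
    probe: SpinProbe,
    offset_ppm: float,
    b1_hz: float,
    spectrometer_mhz: float,
    noe_dips: Sequence[NoeDip] = (),
) -> np.ndarray:
    """3N x 3N Bloch-McConnell evolution matrix at one rf offset.

    Spin ordering is state-major: ``(Mx, My, Mz)`` for state 0, then state
    1, etc.; NOE pseudo-spins, if any, follow the real states.
    """
    A = _cest_matrices(
        network, probe, np.array([offset_ppm]), b1_hz, spectrometer_mhz, noe_dips
    )
    return A[0]


def _cest_matrices(
    network: ExchangeNetwork,
    probe: SpinProbe,
    offsets_ppm: np.ndarray,
    b1_hz: float,
    spectrometer_mhz: float,
    noe_dips: Sequence[NoeDip] = (),
) -> np.ndarray:
    """Stacked evolution matrices, one per rf offset: shape (n_off, 3m, 3m)."""
    probe.check_covers(network)
    n_states, n_spins = _spin_layout(network, noe_dips)
    shifts = list(probe.shifts(network))
    r1 = list(probe.r1_vector(network))
    r2 = list(probe.r2_vector(network))
    for dip in noe_dips:
        t = network.index(dip.target_state)
        shifts.append(dip.partner_shift_ppm)
        r1.append(r1[t])
        r2.append(r2[t])
    shifts = np.asarray(shifts)
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)

    offsets_ppm = np.asarray(offsets_ppm, dtype=float)
    n_off = offsets_ppm.size
    omega1 = 2.0 * np.pi * b1_hz
    # ppm difference * MHz = Hz; Omega in rad/s
    Omega = 2.0 * np.pi * spectrometer_mhz * (shifts[None, :] - offsets_ppm[:, None])

    dim = 3 * n_spins
    A = np.zeros((n_off, dim, dim))
    for s in range(n_spins):
        x, y, z = 3 * s, 3 * s + 1, 3 * s + 2
        A[:, x, x] = -r2[s]
        A[:, y, y] = -r2[s]
        A[:, z, z] = -r1[s]
        A[:, x, y] = -Omega[:, s]
        A[:, y, x] = Omega[:, s]
        A[:, y, z] = omega1
        A[:, z, y] = -omega1
    # chemical exchange: couples corresponding components of the real states
    K = build_rate_matrix(network)
    for i in range(n_states):
        for j in range(n_states):
            if i == j or K[j, i] != 0.0:
                for c in range(3):
                    A[:, 3 * j + c, 3 * i + c] += K[j, i]
    # NOE cross-relaxation: Mz channel only, symmetric, magnetization-exchanging
    for d, dip in enumerate(noe_dips):
        t = network.index(dip.target_state)
        pz = 3 * (n_states + d) + 2
        tz = 3 * t + 2
        s = dip.sigma_noe_s
        A[:, tz, tz] -= s
        A[:, pz, pz] -= s
        A[:, tz, pz] += s
        A[:, pz, tz] += s
    return A


def simulate_cest_profile(
    network: ExchangeNetwork,
    probe: SpinProbe,
    schedule: CestSchedule,
    observed_state: str,
    noe_dips: Sequence[NoeDip] = (),
) -> np.ndarray:
    """I/I0 of the observed state's peak at every offset of the schedule.

    The initial condition is thermal equilibrium: ``Mz`` equal to the
    state populations (NOE pseudo-spins start at their target state's
    population), transverse components zero.  ``I`` is the observed
    state's ``Mz`` after ``t_ex_s``; ``I0`` is its value at ``T_EX = 0``,
    i.e. its equilibrium population.
    """
    obs = network.index(observed_state)
    n_states, n_spins = _spin_layout(network, noe_dips)
    offsets = np.asarray(schedule.offsets_ppm)
    A = _cest_matrices(
        network, probe, offsets, schedule.b1_hz, schedule.spectrometer_mhz, noe_dips
    )
    m0 = np.zeros(3 * n_spins)
    m0[2::3][:n_states] = network.populations
    for d, dip in enumerate(noe_dips):
        m0[3 * (n_states + d) + 2] = network.population(dip.target_state)
    P = scipy.linalg.expm(A * schedule.t_ex_s)
    mz = P[:, 3 * obs + 2, :] @ m0
    i0 = network.populations[obs]
    if i0 <= 0:
        raise ValidationError(f"observed state {observed_state!r} has zero population")
    return mz / i0


def simulate_zz_intensities(
    network: ExchangeNetwork,
    probe: SpinProbe,
    zz_schedule: ZzSchedule,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Diagonal and cross-peak intensity curves over the mixing schedule.

    Only longitudinal order evolves during mixing, so the propagator is
    ``expm((K - diag(R1)) * t)`` and the curve for origin *o*, destination
    *d* is ``[expm(L t)]_{d,o} * p_o``: diagonal peaks decay from the
    origin population, cross-peaks build up from zero.  Returns every
    ordered (origin, destination) pair.
    """
    probe.check_covers(network)
    K = build_rate_matrix(network)
    L = K - np.diag(probe.r1_vector(network))
    times = np.asarray(zz_schedule.mixing_times_s)
    P = scipy.linalg.expm(L[None, :, :] * times[:, None, None])  # (t, d, o)
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for oi, o in enumerate(network.states):
        for di, d in enumerate(network.states):
            out[(o, d)] = P[:, di, oi] * network.populations[oi]
    return out


def populations_from_first_plane(
    zz_dataset: ZzDataset, state_a: str, state_b: str
) -> float:
    """Ratio p_a/p_b estimated from diagonal intensities at the shortest
    mixing time.

    This mirrors the common practice of reading relative populations off
    the first plane of a pseudo-3D zz dataset.  It is approximate: during
    the shortest mixing time (typically 25 ms) relaxation and exchange
    already attenuate the two peaks differently.
    """
    t0 = zz_dataset.t_mix_s.min()
    sel = zz_dataset.t_mix_s == t0
    diag = sel & (zz_dataset.origin_state == zz_dataset.destination_state)
    ia = zz_dataset.intensity[diag & (zz_dataset.origin_state == state_a)]
    ib = zz_dataset.intensity[diag & (zz_dataset.origin_state == state_b)]
    if ia.size == 0 or ib.size == 0:
        raise ValidationError(
            f"first plane lacks diagonal peaks for {state_a!r} and/or {state_b!r}"
        )
    return float(ia.mean() / ib.mean())


# ---------------------------------------------------------------------------
# R1 decay fitting
# ---------------------------------------------------------------------------


@dataclass
class R1FitResult:
    """Single-exponential decay fit ``I = I0 * exp(-R1 * t)``."""

    i0: float
    r1: float
    residuals: np.ndarray

    def __iter__(self):
        return iter((self.i0, self.r1))


def fit_r1_decay(times_s: Sequence[float], intensities: Sequence[float]) -> R1FitResult:
    """Least-squares fit of a single-exponential longitudinal decay.

    Used for the 1H R1 measurements that anchor CEST fits: intensities
    from an inversion-comparison experiment at several relaxation delays
    are fit to ``I = I0 * exp(-R1 * T_EX)``.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size < 3:
        raise ValidationError("R1 fit needs at least 3 points")
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    if not np.all(np.isfinite(y)):
        raise ValidationError("intensities must be finite")

    # log-linear start when all intensities are positive, else crude guess
    if np.all(y > 0):
        slope, icpt = np.polyfit(t, np.log(y), 1)
        p0 = (float(np.exp(icpt)), float(max(-slope, 0.0)))
    else:
        p0 = (float(y[0]), 1.0)

    def model(t, i0, r1):
        return i0 * np.exp(-r1 * t)

    import warnings

    with warnings.catch_warnings():
        # a singular covariance (e.g. constant data, R1 = 0) is fine here:
        # only the point estimates are used
        warnings.simplefilter("ignore", scipy.optimize.OptimizeWarning)
        popt, _ = scipy.optimize.curve_fit(model, t, y, p0=p0, maxfev=10000)
    i0, r1 = float(popt[0]), float(popt[1])
    return R1FitResult(i0, r1, residuals=y - model(t, i0, r1))
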