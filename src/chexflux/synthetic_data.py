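"""Synthetic CEST and zz-exchange datasets with known ground truth.

The generators reproduce the statistical structure the fitting stage
assumes: a known exchange network and probe, the standard acquisition
schedules (40-offset 1H CEST from 1.0 to -0.2 ppm with B1 = 20.3 Hz and
T_EX = 150 ms at 800 MHz; 13 zz mixing times from 25 to 800 ms), additive
i.i.d. Gaussian noise on intensity (ratios), and optionally NOE
contamination dips from longitudinal cross-relaxation to a non-exchanging
pseudo-spin.  Everything is bit-reproducible given the scenario seed.

Two reference scenarios are shipped:

* :func:`r17_zz_scenario` - the two-state U<->B binding step of a
  marginally stable three-helix-bundle client to its chaperone, with the
  pseudo-first-order on-rate 0.8 s^-1, off-rate 2.7 s^-1 and 500 uM free
  chaperone.
* :func:`sh3_cest4_scenario` - a four-state N/U/B1/B2 network for a
  slow-folding SH3-domain client with two bound conformations, with
  near-equal native and unfolded populations (so the Xi factor is close
  to 1) and per-edge exchange rates chosen so the two bound arms have
  CS/IF flux ratios of about 4 and 21.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from chexflux.bloch_mcconnell import (
    CestDataset,
    CestSchedule,
    NoeDip,
    ZzDataset,
    ZzSchedule,
    default_cest_schedule,
    default_zz_schedule,
    simulate_cest_profile,
    simulate_zz_intensities,
)
from chexflux.exchange_model import ExchangeNetwork, SpinProbe, ValidationError

__all__ = [
    "TruthScenario",
    "NoeDip",
    "generate_cest_dataset",
    "generate_zz_dataset",
    "inject_noe_dip",
    "r17_zz_scenario",
    "sh3_cest4_scenario",
]


@dataclass(frozen=True)
class TruthScenario:
    """A ground-truth model plus acquisition schedule and noise level.

    ``noise_sd`` is the Gaussian noise standard deviation as a fraction
    of the reference intensity (for CEST this is the I/I0 scale; for zz
    it is the unit-population intensity scale).  ``observed_states``
    selects which profiles a CEST acquisition records (default: every
    network state).
    """

    name: str
    network: ExchangeNetwork
    probe: SpinProbe
    schedule: Union[CestSchedule, ZzSchedule]
    noise_sd: float = 0.01
    seed: int = 0
    noe_dips: Tuple[NoeDip, ...] = ()
    observed_states: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 <= int(self.seed) < 2**63):
            raise ValidationError("seed must be a fixed-width nonnegative integer")

    def with_seed(self, seed: int) -> "TruthScenario":
        return replace(self, seed=seed)


def generate_cest_dataset(scenario: TruthScenario) -> Dict[str, CestDataset]:
    """Simulate noisy CEST profiles for every observed state.

    Returns a mapping observed-state -> dataset.  Intensities are the
    noiseless Bloch-McConnell profiles plus i.i.d. Gaussian noise of SD
    ``noise_sd``; the sigma column records that SD.  With ``noise_sd = 0``
    the datasets equal the simulation exactly.
    """
    if not isinstance(scenario.schedule, CestSchedule):
        raise ValidationError("generate_cest_dataset needs a CestSchedule")
    rng = np.random.default_rng(scenario.seed)
    states = scenario.observed_states or scenario.network.states
    out: Dict[str, CestDataset] = {}
    sigma = scenario.noise_sd if scenario.noise_sd > 0 else 1e-6
    for state in states:
        clean = simulate_cest_profile(
            scenario.network,
            scenario.probe,
            scenario.schedule,
            state,
            noe_dips=scenario.noe_dips,
        )
        noisy = clean + rng.normal(0.0, scenario.noise_sd, clean.shape)
        out[state] = CestDataset(
            probe=scenario.probe.probe_name,
            observed_state=state,
            schedule=scenario.schedule,
            intensity=np.minimum(noisy, 1.0 + 4.9 * sigma),
            sigma=np.full_like(clean, sigma),
            dataset_id=f"{scenario.name}_cest_{scenario.probe.probe_name}_{state}",
        )
    return out


def generate_zz_dataset(
    scenario: TruthScenario, peaks: Optional[Sequence[Tuple[str, str]]] = None
) -> ZzDataset:
    """Simulate a noisy zz-exchange dataset over the mixing schedule.

    ``peaks`` selects the (origin, destination) curves recorded; the
    default records every ordered pair (all diagonal and cross peaks).
    """
    if not isinstance(scenario.schedule, ZzSchedule):
        raise ValidationError("generate_zz_dataset needs a ZzSchedule")
    rng = np.random.default_rng(scenario.seed)
    curves = simulate_zz_intensities(scenario.network, scenario.probe, scenario.schedule)
    if peaks is None:
        peaks = [
            (o, d)
            for o in scenario.network.states
            for d in scenario.network.states
        ]
    times = np.asarray(scenario.schedule.mixing_times_s)
    origin, dest, t, y = [], [], [], []
    for o, d in peaks:
        origin.extend([o] * times.size)
        dest.extend([d] * times.size)
        t.extend(times)
        y.extend(curves[(o, d)])
    y = np.asarray(y)
    sigma = scenario.noise_sd if scenario.noise_sd > 0 else 1e-6
    y = y + rng.normal(0.0, scenario.noise_sd, y.shape)
    return ZzDataset(
        probe=scenario.probe.probe_name,
        origin_state=np.asarray(origin, dtype=object),
        destination_state=np.asarray(dest, dtype=object),
        t_mix_s=np.asarray(t),
        intensity=y,
        sigma=np.full_like(y, sigma),
        dataset_id=f"{scenario.name}_zz_{scenario.probe.probe_name}",
    )


def inject_noe_dip(
    network: ExchangeNetwork,
    probe: SpinProbe,
    partner_shift_ppm: float,
    sigma_noe: float,
    target_state: Optional[str] = None,
) -> Tuple[ExchangeNetwork, SpinProbe, Tuple[NoeDip, ...]]:
    """Augment a CEST model with a longitudinal cross-relaxation partner.

    The partner is a non-exchanging pseudo-spin at ``partner_shift_ppm``
    coupled symmetrically (rate ``sigma_noe`` s^-1) to the Mz channel of
    ``target_state`` (default: the first network state).  Passing the
    returned tuple's dips to :func:`simulate_cest_profile` (or putting
    them in a :class:`TruthScenario`) produces a spurious minor dip at
    the partner shift that does not report chemical exchange.
    """
    if sigma_noe < 0:
        raise ValidationError("sigma_noe must be >= 0")
    target = target_state or network.states[0]
    network.index(target)  # validates
    dip = NoeDip(target, partner_shift_ppm, sigma_noe)
    return network, probe, (dip,)


# ---------------------------------------------------------------------------
# shipped reference scenarios
# ---------------------------------------------------------------------------


def r17_zz_scenario(
    noise_sd: float = 0.01, seed: int = 0, r1_s: float = 2.0
) -> TruthScenario:
    """Two-state U<->B zz-exchange truth for a weakly bound client.

    Rates: k_UB = 0.8 s^-1 (pseudo-first-order at 500 uM free chaperone,
    i.e. k_on = 1600 M^-1 s^-1) and k_BU = 2.7 s^-1, giving
    p_U/p_B = 3.375.  R1 is shared (methyl 1H longitudinal relaxation);
    the 1H shifts are only used by CEST-style simulations.
    """
    network = ExchangeNetwork(
        ("U", "B"),
        {("U", "B"): 0.8, ("B", "U"): 2.7},
        ligand_conc=500e-6,
    )
    probe = SpinProbe.shared("Met26", {"U": 1.85, "B": 1.95}, r1=r1_s, r2=20.0)
    return TruthScenario(
        name="R17_zz",
        network=network,
        probe=probe,
        schedule=default_zz_schedule(),
        noise_sd=noise_sd,
        seed=seed,
    )


def sh3_cest4_scenario(noise_sd: float = 0.01, seed: int = 0) -> TruthScenario:
    """Four-state N/U/B1/B2 CEST truth with two bound conformations.

    Populations are chosen with p_N = p_U (so Xi = 1 exactly at truth)
    and sparse bound states; per-edge exchange rates give CS/IF flux
    ratios Theta1 = k_ex,UB1/k_ex,NB1 * Xi = 4 and Theta2 = 21 for the
    two bound arms, and a slow N<->U interconversion of ~1 s^-1, all
    squarely in the slow-exchange regime the experiment addresses.
    """
    states = ("N", "U", "B1", "B2")
    pops = np.array([0.44, 0.44, 0.08, 0.04])
    kex = {
        ("N", "U"): 1.0,
        ("U", "B1"): 3.0,
        ("N", "B1"): 0.75,
        ("U", "B2"): 4.2,
        ("N", "B2"): 0.2,
    }
    network = ExchangeNetwork.from_kex(states, pops, kex, ligand_conc=500e-6)
    probe = SpinProbe.shared(
        "Ile27",
        {"N": 0.55, "U": 0.70, "B1": 0.20, "B2": 0.35},
        r1=1.5,
        r2=25.0,
    )
    return TruthScenario(
        name="SH3_cest4",
        network=network,
        probe=probe,
        schedule=default_cest_schedule(),
        noise_sd=noise_sd,
        seed=seed,
    )
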