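"""Kinetic parameters, rate laws and environmental activity modulation.

Rate constants of the individual cleavage steps are not identifiable from
the published experiments, so they are sampled log-uniformly from a
seeded generator within documented physical ranges; slow-substrate
peptides receive tight-binding / low-turnover overrides so that they
occupy their target enzyme and act as effective reversible inhibitors.

Multiple substrates of one enzyme compete for the same active-site pool,
which under the quasi-steady-state assumption gives the shared-denominator
competitive Michaelis-Menten law

    v_i = a * kcat_i * E_tot * (S_i/KM_i) / (1 + sum_m S_m/KM_m)

where ``a`` in [0, 1] is the environment-dependent activity of the enzyme
(an Arrhenius factor times a thermal-denaturation sigmoid in temperature,
times a double-protonation bell in pH, normalized so the enzyme's optimum
maps to 1).  Blue-light forcing is modelled as photoacid-driven pH
relaxation: first-order decay toward ``baseline - ph_drop`` while the
light is on and back toward the baseline while it is off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from .network import ReactionNetwork

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1


# ---------------------------------------------------------------------------
# kinetic parameter sampling

@dataclass(frozen=True)
class KineticsConfig:
    """Sampling ranges (log-uniform) and enzyme loadings.

    ``kcat`` in s^-1, ``KM`` and enzyme totals in uM.  Slow-substrate
    overrides give the intact peptide a KM and kcat well below the
    population medians of the main ranges, the tight-binding/low-turnover
    regime that produces effective reversible inhibition.
    """

    kcat_range: tuple[float, float] = (1e-3, 10.0)
    km_range: tuple[float, float] = (1.0, 100.0)
    slow_kcat_range: tuple[float, float] = (1e-3, 1e-2)
    slow_km_range: tuple[float, float] = (1.0, 10.0)
    enzyme_total_um: float = 1.0
    slow_pairs: tuple[tuple[str, str], ...] = ()  # (sequence, enzyme)


@dataclass
class KineticParams:
    """Per-reaction kcat/KM aligned with ``network.reactions`` order."""

    kcat: np.ndarray
    km: np.ndarray
    e_tot: dict[str, float]
    seed: int

    def __post_init__(self):
        if np.any(self.kcat < 0):
            raise ValueError("kcat must be >= 0")
        if np.any(self.km <= 0):
            raise ValueError("KM must be > 0")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def assign_kinetics(
    network: ReactionNetwork,
    seed: int,
    config: KineticsConfig = KineticsConfig(),
    enzyme_scales: Mapping[str, float] | None = None,
) -> KineticParams:
    """Sample kcat/KM for every reaction, deterministically from ``seed``."""
    rng = np.random.default_rng(seed)
    reactions = network.reactions
    n = len(reactions)
    kcat = _log_uniform(rng, *config.kcat_range, n)
    km = _log_uniform(rng, *config.km_range, n)
    slow = dict(config.slow_pairs)
    for i, rxn in enumerate(reactions):
        if slow.get(rxn.parent) == rxn.enzyme:
            kcat[i] = _log_uniform(rng, *config.slow_kcat_range, 1)[0]
            km[i] = _log_uniform(rng, *config.slow_km_range, 1)[0]
        if enzyme_scales:
            kcat[i] *= enzyme_scales.get(rxn.enzyme, 1.0)
    enzymes = sorted({r.enzyme for r in reactions})
    e_tot = {e: config.enzyme_total_um for e in enzymes}
    return KineticParams(kcat=kcat, km=km, e_tot=e_tot, seed=seed)


# ---------------------------------------------------------------------------
# rate law

def competitive_rates(
    substrate_concs: np.ndarray,
    kcat: np.ndarray,
    km: np.ndarray,
    e_tot: float,
    activity: float = 1.0,
) -> np.ndarray:
    """Shared-denominator competitive Michaelis-Menten rates (uM s^-1).

    Reduces to single-substrate MM when only one substrate is present.
    """
    s = np.asarray(substrate_concs, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative substrate concentration")
    load = s / np.asarray(km, dtype=float)
    denom = 1.0 + load.sum()
    return activity * np.asarray(kcat, dtype=float) * e_tot * load / denom


# ---------------------------------------------------------------------------
# temperature / pH activity

@dataclass(frozen=True)
class EnvironmentResponse:
    """Temperature and pH response of one enzyme.

    Temperature: Arrhenius acceleration (``activation_energy_kj`` about a
    reference temperature) truncated by a denaturation sigmoid with
    midpoint ``denature_midpoint_c`` and width ``denature_width_c``.
    pH: double-protonation bell ``1 / (1 + 10^(pKa_acid - pH) +
    10^(pH - pKa_base))``.  Both factors are normalized to 1 at the
    enzyme's optimum, so the product is an activity multiplier in [0, 1].
    """

    activation_energy_kj: float = 50.0
    t_ref_c: float = 37.0
    denature_midpoint_c: float = 60.0
    denature_width_c: float = 2.0
    pka_acid: float = 6.5
    pka_base: float = 9.5

    def _temp_raw(self, t_c):
        t_k = np.asarray(t_c, dtype=float) + 273.15
        t_ref_k = self.t_ref_c + 273.15
        arrh = np.exp(-self.activation_energy_kj / GAS_CONSTANT_KJ * (1.0 / t_k - 1.0 / t_ref_k))
        denat = 1.0 / (1.0 + np.exp((np.asarray(t_c, dtype=float) - self.denature_midpoint_c) / self.denature_width_c))
        return arrh * denat

    def _ph_raw(self, ph):
        ph = np.asarray(ph, dtype=float)
        return 1.0 / (1.0 + 10.0 ** (self.pka_acid - ph) + 10.0 ** (ph - self.pka_base))

    @property
    def ph_opt(self) -> float:
        return 0.5 * (self.pka_acid + self.pka_base)

    @property
    def t_opt(self) -> float:
        return _temp_optimum(self)[0]


@lru_cache(maxsize=128)
def _temp_optimum(env: EnvironmentResponse) -> tuple[float, float]:
    """(argmax, max) of the raw temperature factor on a fine 0-100 C grid."""
    grid = np.linspace(0.0, 100.0, 4001)
    vals = env._temp_raw(grid)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])


def activity_modifier(t_c, ph, env: EnvironmentResponse):
    """Activity multiplier in [0, 1]; equals 1 at (env.t_opt, env.ph_opt)."""
    _, t_max = _temp_optimum(env)
    ph_max = env._ph_raw(env.ph_opt)
    value = (env._temp_raw(t_c) / t_max) * (env._ph_raw(ph) / ph_max)
    return np.minimum(value, 1.0) if np.ndim(value) else min(float(value), 1.0)


#: per-enzyme defaults: distinct optima and stabilities so the network's
#: connection strengths shift with temperature and pH (thermolysin is
#: thermostable; thrombin and prolyl endopeptidase denature inside the
#: 25-55 C test window; alkaline phosphatase has an alkaline pH optimum).
DEFAULT_ENVIRONMENT_RESPONSES: dict[str, EnvironmentResponse] = {
    "trypsin": EnvironmentResponse(50.0, 37.0, 65.0, 2.5, 6.5, 9.5),
    "chymotrypsin": EnvironmentResponse(45.0, 37.0, 55.0, 2.0, 6.8, 9.0),
    "elastase": EnvironmentResponse(40.0, 37.0, 60.0, 3.0, 7.0, 9.5),
    "thermolysin": EnvironmentResponse(60.0, 37.0, 85.0, 3.0, 5.5, 8.5),
    "thrombin": EnvironmentResponse(50.0, 37.0, 50.0, 2.0, 6.5, 9.0),
    "prolyl_endopeptidase": EnvironmentResponse(55.0, 37.0, 48.0, 2.5, 6.0, 8.5),
    "alkaline_phosphatase": EnvironmentResponse(45.0, 37.0, 70.0, 3.0, 8.0, 11.0),
}


# ---------------------------------------------------------------------------
# photoacid light forcing

@dataclass(frozen=True)
class PhotoacidParams:
    """Merocyanine/spiropyran photoswitch pH kinetics.

    Sustained illumination drives the pH ``ph_drop`` units below the dark
    baseline; acidification (tau_on) is faster than thermal reversion
    (tau_off).
    """

    ph_drop: float = 3.5
    tau_on_s: float = 10.0
    tau_off_s: float = 60.0


@dataclass(frozen=True)
class LightSchedule:
    """Periodic on/off illumination: on during the first ``duty`` fraction
    of every period, for ``duration_min`` minutes in total."""

    period_s: float
    duty: float = 0.5
    duration_min: float = 15.0

    def __post_init__(self):
        if not (0.0 < self.duty < 1.0):
            raise ValueError("duty must be in (0, 1)")
        if self.period_s <= 0:
            raise ValueError("period must be positive")

    def switch_times(self) -> np.ndarray:
        """Ascending segment boundaries (s) over the full duration."""
        total = self.duration_min * 60.0
        times = [0.0]
        t = 0.0
        while t < total - 1e-9:
            on_end = t + self.duty * self.period_s
            if on_end < total:
                times.append(on_end)
            t += self.period_s
            if t < total:
                times.append(t)
        times.append(total)
        return np.array(times)

    def is_on(self, t_s: float) -> bool:
        if t_s >= self.duration_min * 60.0 or t_s < 0:
            return False
        return (t_s % self.period_s) < self.duty * self.period_s - 1e-12


class LightPHTrace:
    """pH(t) under a pulsed-light schedule: piecewise-exponential
    relaxation, continuous at the switching times."""

    def __init__(self, schedule: LightSchedule, photo: PhotoacidParams, baseline_ph: float):
        self.schedule = schedule
        self.photo = photo
        self.baseline_ph = baseline_ph
        bounds = schedule.switch_times()
        self._bounds = bounds
        ph0 = baseline_ph
        starts = [ph0]
        self._targets = []
        self._taus = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            on = schedule.is_on(0.5 * (a + b))
            target = baseline_ph - photo.ph_drop if on else baseline_ph
            tau = photo.tau_on_s if on else photo.tau_off_s
            self._targets.append(target)
            self._taus.append(tau)
            ph0 = target + (ph0 - target) * math.exp(-(b - a) / tau)
            starts.append(ph0)
        self._starts = np.array(starts)
        self._targets = np.array(self._targets)
        self._taus = np.array(self._taus)

    def __call__(self, t_s):
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        out = np.full(t.shape, self.baseline_ph)
        inside = (t >= self._bounds[0]) & (t <= self._bounds[-1])
        idx = np.clip(np.searchsorted(self._bounds, t[inside], side="right") - 1,
                      0, len(self._targets) - 1)
        a = self._bounds[idx]
        tgt = self._targets[idx]
        tau = self._taus[idx]
        ph0 = self._starts[idx]
        out[inside] = tgt + (ph0 - tgt) * np.exp(-(t[inside] - a) / tau)
        if t.shape != np.shape(t_s):
            return float(out[0])
        return out if np.ndim(t_s) else float(out[0])


def light_ph_trace(
    schedule: LightSchedule | None,
    photo: PhotoacidParams,
    baseline_ph: float,
    t_grid_s: np.ndarray,
) -> np.ndarray:
    """pH evaluated on ``t_grid_s``; constant baseline without a schedule."""
    t = np.asarray(t_grid_s, dtype=float)
    if schedule is None:
        return np.full(t.shape, baseline_ph)
    return LightPHTrace(schedule, photo, baseline_ph)(t)


def slow_pairs_from_peptides(peptides) -> tuple[tuple[str, str], ...]:
    """Extract (sequence, enzyme) slow-substrate pairs from role tags."""
    pairs = []
    for p in peptides:
        for tag in p.role_tags:
            if tag.startswith("slow_substrate:"):
                pairs.append((p.sequence, tag.split(":", 1)[1]))
    return tuple(pairs)


def with_slow_pairs(config: KineticsConfig, peptides) -> KineticsConfig:
    return replace(config, slow_pairs=slow_pairs_from_peptides(peptides))
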