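"""CSTR simulation of a cleavage network with competitive kinetics.

The reactor is a well-mixed vessel of volume V (default 100 ul) with a
constant combined inflow phi (default 400 ul/h).  Enzymes are immobilized
on beads, so only peptide species flow: for every species i

    dS_i/dt = (phi/V) (S_i,in - S_i) + production_i - consumption_i

with the reaction fluxes given by the shared-denominator competitive
Michaelis-Menten law of :mod:`enzyres.kinetics`.  Temperature and pH act
through per-enzyme activity multipliers; pulsed blue light acts through a
photoacid pH trace.  Steady state is declared when the largest normalized
concentration derivative falls below a tolerance at the end of the
equilibration period (with automatic horizon extension), and the measured
output of a run is the time average of a configured feature subset over
the final averaging window, passed through a multiplicative measurement
model (fixed per-feature response factors plus log-normal noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .kinetics import (
    DEFAULT_ENVIRONMENT_RESPONSES,
    EnvironmentResponse,
    KineticParams,
    LightPHTrace,
    LightSchedule,
    PhotoacidParams,
    activity_modifier,
)
from .network import ReactionNetwork


class SimulationError(RuntimeError):
    """Integrator failure, with diagnostics in the message."""


@dataclass(frozen=True)
class ReactorConfig:
    volume_ul: float = 100.0
    total_flow_ul_h: float = 400.0
    equilibration_time_min: float = 60.0
    averaging_window_min: float = 10.0

    def __post_init__(self):
        if min(self.volume_ul, self.total_flow_ul_h, self.equilibration_time_min,
               self.averaging_window_min) <= 0:
            raise ValueError("reactor parameters must be strictly positive")
        if self.averaging_window_min > self.equilibration_time_min:
            raise ValueError("averaging window cannot exceed the equilibration time")

    @property
    def dilution_rate_s(self) -> float:
        """phi / V in s^-1."""
        return self.total_flow_ul_h / self.volume_ul / 3600.0


@dataclass(frozen=True)
class InputCondition:
    """One experimental input: substrate channels plus environment."""

    s1_um: float = 70.0
    s2_um: float = 45.0
    fixed_um: tuple[tuple[str, float], ...] = (("6", 160.0), ("7", 160.0))
    temperature_c: float = 37.0
    ph: float = 7.4
    light_schedule: LightSchedule | None = None

    def __post_init__(self):
        if self.s1_um < 0 or self.s2_um < 0:
            raise ValueError("concentrations must be >= 0")
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError("pH out of [0, 14]")

    def channel_conc(self, channel: str, label: str) -> float:
        if channel == "s1":
            return self.s1_um
        if channel == "s2":
            return self.s2_um
        if channel == "fixed":
            return dict(self.fixed_um).get(label, 0.0)
        raise KeyError(f"unknown input channel {channel!r}")


#: default syringe layout: peptide label -> channel
DEFAULT_INPUT_MAP: dict[str, str] = {
    "1": "s1", "2": "s1", "3": "s2", "4": "s2", "5": "s2", "6": "fixed", "7": "fixed",
}


@dataclass
class Trajectory:
    t_min: np.ndarray
    states: np.ndarray  # (n_times, n_species), uM
    species: list[str]
    temperature_c: float
    ph: np.ndarray  # per time point
    steady: bool = False
    residual: float = math.nan

    def final_window_average(self, window_min: float) -> pd.Series:
        mask = self.t_min >= self.t_min[-1] - window_min + 1e-9
        return pd.Series(self.states[mask].mean(axis=0), index=self.species)


class CSTRModel:
    """Precompiled right-hand side of the reactor ODE for one network."""

    def __init__(
        self,
        network: ReactionNetwork,
        params: KineticParams,
        env: Mapping[str, EnvironmentResponse] | None = None,
        reactor: ReactorConfig = ReactorConfig(),
        input_map: Mapping[str, str] | None = None,
        peptide_labels: Mapping[str, str] | None = None,
        photo: PhotoacidParams = PhotoacidParams(),
    ):
        self.network = network
        self.params = params
        self.env = dict(DEFAULT_ENVIRONMENT_RESPONSES if env is None else env)
        self.reactor = reactor
        self.photo = photo
        self.species = list(network.species)
        self.index = {s: i for i, s in enumerate(self.species)}
        # peptide label -> sequence (for inflow construction)
        self.peptide_labels = dict(peptide_labels or {})
        self.input_map = dict(DEFAULT_INPUT_MAP if input_map is None else input_map)

        reactions = network.reactions
        n_rxn = len(reactions)
        if len(params.kcat) != n_rxn:
            raise ValueError("kinetic parameter arrays do not match the network")
        # group reactions by enzyme for the shared-denominator rate law
        self._groups = []
        by_enzyme: dict[str, list[int]] = {}
        for i, rxn in enumerate(reactions):
            by_enzyme.setdefault(rxn.enzyme, []).append(i)
        for enzyme, idx in by_enzyme.items():
            idx = np.array(idx)
            parents = np.array([self.index[reactions[i].parent] for i in idx])
            prods: list[list[int]] = []
            for i in idx:
                r = reactions[i]
                if hasattr(r, "products"):
                    prods.append([self.index[p] for p in r.products])
                else:
                    prods.append([self.index[r.product]])
            self._groups.append(
                dict(
                    enzyme=enzyme,
                    parents=parents,
                    products=prods,
                    kcat=params.kcat[idx],
                    km=params.km[idx],
                    e_tot=params.e_tot.get(enzyme, 0.0),
                )
            )

    # -- inflow -------------------------------------------------------------
    def inflow_vector(self, condition: InputCondition) -> np.ndarray:
        s_in = np.zeros(len(self.species))
        for label, channel in self.input_map.items():
            seq = self.peptide_labels.get(label, label)
            if seq in self.index:
                s_in[self.index[seq]] = condition.channel_conc(channel, label)
        return s_in

    # -- RHS ----------------------------------------------------------------
    def reaction_term(self, s: np.ndarray, activities: Mapping[str, float]) -> np.ndarray:
        ds = np.zeros_like(s)
        sc = np.maximum(s, 0.0)
        for g in self._groups:
            load = sc[g["parents"]] / g["km"]
            denom = 1.0 + load.sum()
            v = activities[g["enzyme"]] * g["kcat"] * g["e_tot"] * load / denom
            np.subtract.at(ds, g["parents"], v)
            for vi, prods in zip(v, g["products"]):
                for p in prods:
                    ds[p] += vi
        return ds

    def activities(self, t_c: float, ph: float) -> dict[str, float]:
        return {
            g["enzyme"]: activity_modifier(t_c, ph, self.env[g["enzyme"]])
            for g in self._groups
        }

    def rhs(self, s, s_in, activities, dilution=None):
        k = self.reactor.dilution_rate_s if dilution is None else dilution
        return k * (s_in - s) + self.reaction_term(s, activities)

    def _jac_sparsity(self):
        n = len(self.species)
        j = lil_matrix((n, n), dtype=float)
        j.setdiag(1.0)
        for g in self._groups:
            rows = set(g["parents"].tolist())
            for prods in g["products"]:
                rows.update(prods)
            cols = list(set(g["parents"].tolist()))
            for r in rows:
                j[r, cols] = 1.0
        return j.tocsr()


def _integrate(model, s0, s_in_fn, act_fn, t_span_s, t_eval_s, knots_s=()):
    """BDF integration with breakpoints at forcing discontinuities."""
    def fun(t, s):
        return model.reactor.dilution_rate_s * (s_in_fn(t) - s) + model.reaction_term(
            s, act_fn(t)
        )

    sparsity = model._jac_sparsity()
    edges = np.unique(np.concatenate([np.asarray(t_span_s, float), np.asarray(knots_s, float)]))
    edges = edges[(edges >= t_span_s[0]) & (edges <= t_span_s[1])]
    states = []
    times = []
    s = np.asarray(s0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        te = t_eval_s[(t_eval_s >= a) & (t_eval_s <= b)]
        te = np.unique(np.concatenate([[a], te, [b]]))
        sol = solve_ivp(
            fun, (a, b), s, method="BDF", t_eval=te,
            rtol=1e-6, atol=1e-9, jac_sparsity=sparsity,
        )
        if not sol.success:
            raise SimulationError(f"integrator failed on [{a:.1f}, {b:.1f}] s: {sol.message}")
        keep = (sol.t >= a) & (sol.t <= b)
        times.append(sol.t[keep])
        states.append(sol.y[:, keep].T)
        s = sol.y[:, -1]
    t = np.concatenate(times)
    y = np.vstack(states)
    # deduplicate the shared edge points
    _, uniq = np.unique(np.round(t, 9), return_index=True)
    return t[uniq], y[uniq]


def simulate_to_steady_state(
    model: CSTRModel,
    condition: InputCondition,
    tol: float = 1e-6,
    max_extension_min: float = 240.0,
) -> Trajectory:
    """Integrate from an empty reactor until the equilibration criterion.

    The criterion is max |dS/dt| / S_scale < ``tol`` (s^-1), with S_scale
    the largest inflow concentration, checked at the end of the
    equilibration period and re-checked after doubling the horizon up to
    ``max_extension_min``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    s_in = model.inflow_vector(condition)
    acts = model.activities(condition.temperature_c, condition.ph)
    scale = max(s_in.max(), 1.0)
    t_end = model.reactor.equilibration_time_min * 60.0
    dt_eval = 30.0
    s = np.zeros(len(model.species))
    times = [np.array([0.0])]
    states = [s[None, :]]
    t0 = 0.0
    steady = False
    residual = math.inf
    while True:
        t_eval = np.arange(t0, t_end + 1e-6, dt_eval)
        t, y = _integrate(model, s, lambda _t: s_in, lambda _t: acts, (t0, t_end), t_eval)
        times.append(t[1:])
        states.append(y[1:])
        s = y[-1]
        residual = float(np.max(np.abs(model.rhs(s, s_in, acts))) / scale)
        if residual < tol:
            steady = True
            break
        if t_end >= max_extension_min * 60.0 - 1e-6:
            break
        t0 = t_end
        t_end = min(2.0 * t_end, max_extension_min * 60.0)
    t_all = np.concatenate(times)
    y_all = np.vstack(states)
    return Trajectory(
        t_min=t_all / 60.0,
        states=y_all,
        species=model.species,
        temperature_c=condition.temperature_c,
        ph=np.full(t_all.shape, condition.ph),
        steady=steady,
        residual=residual,
    )


def simulate_dynamic(
    model: CSTRModel,
    condition: InputCondition,
    total_min: float,
    sample_every_min: float = 1.0,
    inflow_modulation: Callable[[float], dict] | None = None,
    s0: np.ndarray | None = None,
) -> Trajectory:
    """Piecewise-forced integration under time-dependent inputs.

    ``inflow_modulation(t_s)`` may return per-channel concentration
    overrides (e.g. ``{"s1": value}``) to impose a sine-modulated inflow;
    ``condition.light_schedule`` imposes photoacid pH forcing.  With
    neither, the endpoint reproduces the steady-state simulation.
    """
    t_total = total_min * 60.0
    t_eval = np.arange(0.0, t_total + 1e-6, sample_every_min * 60.0)
    schedule = condition.light_schedule
    knots: np.ndarray = np.array([])
    if schedule is not None:
        ph_trace = LightPHTrace(schedule, model.photo, condition.ph)
        knots = schedule.switch_times()
        def act_fn(t):
            return model.activities(condition.temperature_c, float(ph_trace(t)))
    else:
        ph_trace = None
        acts = model.activities(condition.temperature_c, condition.ph)
        def act_fn(_t):
            return acts

    base_in = model.inflow_vector(condition)
    if inflow_modulation is None:
        def s_in_fn(_t):
            return base_in
    else:
        chan_idx: dict[str, list[int]] = {}
        for label, channel in model.input_map.items():
            seq = model.peptide_labels.get(label, label)
            if seq in model.index:
                chan_idx.setdefault(channel, []).append(model.index[seq])
        def s_in_fn(t):
            s_in = base_in.copy()
            for channel, value in inflow_modulation(t).items():
                for i in chan_idx.get(channel, []):
                    s_in[i] = value
            return s_in

    start = np.zeros(len(model.species)) if s0 is None else np.asarray(s0, float)
    t, y = _integrate(model, start, s_in_fn, act_fn, (0.0, t_total), t_eval, knots_s=knots)
    # keep only the requested sampling grid
    keep = np.isin(np.round(t, 6), np.round(t_eval, 6))
    t, y = t[keep], y[keep]
    ph = (
        np.full(t.shape, condition.ph)
        if ph_trace is None
        else np.asarray(ph_trace(t), dtype=float)
    )
    return Trajectory(
        t_min=t / 60.0,
        states=y,
        species=model.species,
        temperature_c=condition.temperature_c,
        ph=ph,
    )


# ---------------------------------------------------------------------------
# measurement model

@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative measurement model.

    Per-feature response factors (log-normal, ``response_sigma``) emulate
    unequal ionization efficiencies and are fixed by ``response_seed`` so
    they are shared across all samples of a dataset; per-measurement
    log-normal noise has coefficient of variation ``noise_cv``.
    """

    noise_cv: float = 0.05
    response_sigma: float = 0.3
    response_seed: int = 902140


def measure(
    trajectory: Trajectory,
    reactor: ReactorConfig,
    feature_subset: Sequence[str],
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    window_min: float | None = None,
) -> pd.Series:
    """Averaged, noisy feature intensities for one run (deterministic per seed)."""
    window = reactor.averaging_window_min if window_min is None else window_min
    avg = trajectory.final_window_average(window)
    missing = [f for f in feature_subset if f not in avg.index]
    if missing:
        raise KeyError(f"features not simulated: {missing}")
    values = avg[list(feature_subset)].to_numpy(dtype=float)
    k = len(feature_subset)
    if noise.response_sigma > 0:
        rf_rng = np.random.default_rng(noise.response_seed)
        factors = np.exp(noise.response_sigma * rf_rng.standard_normal(k))
        values = values * factors
    if noise.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.noise_cv**2))
        rng = np.random.default_rng(seed)
        values = values * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=k))
    return pd.Series(values, index=list(feature_subset))
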