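"""Study-condition generators: the synthetic datasets of each experiment.

Each scenario mirrors one experimental campaign: random two-channel
substrate inputs for the chemical classification tasks (60 samples,
S1 in 40-100 uM, S2 in 15-75 uM), random temperature x pH sampling for the
physicochemical classifications, a 21-level temperature grid in
quadruplicate for the general information-processing battery, a
sine-modulated inflow sampled every 4.5 min over 7 h for forecasting, and
17 light-pulse periodicities between 30 s and 600 s in duplicate for the
light-switch task.  All randomness is seeded; replicate scatter comes
from the measurement model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_ENVIRONMENT_RESPONSES,
    KineticParams,
    KineticsConfig,
    LightSchedule,
    assign_kinetics,
    with_slow_pairs,
)
from .library import make_enzymes, make_peptides
from .network import ReactionNetwork, generate_fragment_network
from .reactor import (
    CSTRModel,
    InputCondition,
    NoiseParams,
    ReactorConfig,
    Trajectory,
    measure,
    simulate_dynamic,
    simulate_to_steady_state,
)
from .table import FeatureTable

S1_RANGE = (40.0, 100.0)
S2_RANGE = (15.0, 75.0)
TEMPERATURE_RANGE = (25.0, 55.0)
PH_LEVELS = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5)
FORECAST_SAMPLE_MIN = 4.5


def temperature_grid() -> np.ndarray:
    """The 21-level temperature grid, 25.5-55 C."""
    return np.linspace(25.5, 55.0, 21)


def light_period_grid(n: int = 17) -> np.ndarray:
    """17 light-pulse periodicities between 30 s and 600 s (log-spaced)."""
    return np.geomspace(30.0, 600.0, n)


@dataclass
class Reservoir:
    """A fully parameterized surrogate reservoir ready to simulate."""

    network: ReactionNetwork
    params: KineticParams
    model: CSTRModel
    feature_names: list[str]
    noise: NoiseParams
    seed: int

    def steady_sample(self, condition: InputCondition, sample_seed: int) -> pd.Series:
        traj = simulate_to_steady_state(self.model, condition)
        return measure(traj, self.model.reactor, self.feature_names, self.noise, sample_seed)

    def steady_trajectory(self, condition: InputCondition) -> Trajectory:
        return simulate_to_steady_state(self.model, condition)


def build_reservoir(
    seed: int = 0,
    enzyme_names: list[str] | None = None,
    reactor: ReactorConfig = ReactorConfig(),
    kinetics_config: KineticsConfig = KineticsConfig(),
    noise: NoiseParams = NoiseParams(),
    max_depth: int = 6,
) -> Reservoir:
    """Assemble network + sampled kinetics + reactor into a Reservoir.

    ``enzyme_names`` restricts the catalyst set (the enzyme-subset
    ablation); the feature set is every fragment species, i.e. everything
    except the seven intact input peptides.
    """
    peptides = make_peptides()
    enzymes = make_enzymes(names=enzyme_names)
    network = generate_fragment_network(peptides, enzymes, max_depth=max_depth)
    config = with_slow_pairs(kinetics_config, peptides)
    params = assign_kinetics(network, seed=seed, config=config)
    labels = {p.label: p.sequence for p in peptides}
    model = CSTRModel(
        network,
        params,
        env=DEFAULT_ENVIRONMENT_RESPONSES,
        reactor=reactor,
        peptide_labels=labels,
    )
    features = network.fragments(labels.values())
    return Reservoir(network, params, model, features, noise, seed)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _collect(reservoir: Reservoir, conditions: list[tuple[dict, InputCondition]],
             seed: int) -> FeatureTable:
    seeds = _spawn_seeds(seed, len(conditions))
    rows = []
    for s, (meta, cond) in zip(seeds, conditions):
        rows.append((meta, reservoir.steady_sample(cond, s)))
    return FeatureTable.from_samples(rows)


def classification_scenario(
    reservoir: Reservoir,
    n_samples: int = 60,
    seed: int = 1,
    temperature_c: float = 37.0,
    ph: float = 7.4,
) -> FeatureTable:
    """Random (S1, S2) substrate inputs at fixed temperature and pH."""
    rng = np.random.default_rng(seed)
    s1 = rng.uniform(*S1_RANGE, size=n_samples)
    s2 = rng.uniform(*S2_RANGE, size=n_samples)
    conds = []
    for a, b in zip(s1, s2):
        meta = {"s1_uM": a, "s2_uM": b, "T_C": temperature_c, "pH": ph}
        conds.append((meta, InputCondition(s1_um=a, s2_um=b,
                                           temperature_c=temperature_c, ph=ph)))
    return _collect(reservoir, conds, seed)


def ph_temperature_scenario(
    reservoir: Reservoir,
    n_temperatures: int = 10,
    seed: int = 1,
) -> FeatureTable:
    """Random temperatures crossed with the six buffer pH levels (60 inputs)."""
    rng = np.random.default_rng(seed)
    temps = rng.uniform(*TEMPERATURE_RANGE, size=n_temperatures)
    conds = []
    for t in temps:
        for ph in PH_LEVELS:
            meta = {"s1_uM": 70.0, "s2_uM": 45.0, "T_C": t, "pH": ph}
            conds.append((meta, InputCondition(temperature_c=t, ph=ph)))
    return _collect(reservoir, conds, seed)


def temperature_scenario(
    reservoir: Reservoir,
    replicates: int = 4,
    seed: int = 1,
    ph: float = 7.4,
) -> FeatureTable:
    """21 temperature levels x quadruplicate measurements (84 rows).

    One kinetic trajectory is simulated per level; replicate scatter is
    drawn from the measurement model, emulating repeat runs across
    reactors and days.
    """
    grid = temperature_grid()
    seeds = _spawn_seeds(seed, len(grid) * replicates)
    rows = []
    k = 0
    for t in grid:
        cond = InputCondition(temperature_c=t, ph=ph)
        traj = reservoir.steady_trajectory(cond)
        for r in range(replicates):
            feats = measure(traj, reservoir.model.reactor, reservoir.feature_names,
                            reservoir.noise, seeds[k])
            k += 1
            rows.append(({"s1_uM": 70.0, "s2_uM": 45.0, "T_C": t, "pH": ph,
                          "replicate": r}, feats))
    return FeatureTable.from_samples(rows)


def light_scenario(
    reservoir: Reservoir,
    periods_s: np.ndarray | None = None,
    repeats: int = 2,
    duration_min: float = 15.0,
    seed: int = 1,
    temperature_c: float = 30.0,
    ph: float = 7.4,
) -> FeatureTable:
    """Pulsed-light runs (800 ul/h flow): one row per period x repeat.

    The measured output is the time average over the whole illuminated
    window — the cumulative dynamic response to the pulse train.
    """
    if periods_s is None:
        periods_s = light_period_grid()
    fast = replace(reservoir.model.reactor, total_flow_ul_h=800.0)
    model = reservoir.model
    old_reactor = model.reactor
    seeds = _spawn_seeds(seed, len(periods_s) * repeats)
    rows = []
    k = 0
    try:
        model.reactor = fast
        for period in periods_s:
            schedule = LightSchedule(period_s=float(period), duration_min=duration_min)
            cond = InputCondition(temperature_c=temperature_c, ph=ph,
                                  light_schedule=schedule)
            start = simulate_to_steady_state(model, replace(cond, light_schedule=None))
            traj = simulate_dynamic(model, cond, total_min=duration_min,
                                    sample_every_min=0.25, s0=start.states[-1])
            for r in range(repeats):
                feats = measure(traj, fast, reservoir.feature_names, reservoir.noise,
                                seeds[k], window_min=duration_min)
                k += 1
                rows.append(({"T_C": temperature_c, "pH": ph,
                              "light_period_s": float(period), "replicate": r}, feats))
    finally:
        model.reactor = old_reactor
    return FeatureTable.from_samples(rows)


def sine_forecast_scenario(
    reservoir: Reservoir,
    total_h: float = 7.0,
    sample_every_min: float = FORECAST_SAMPLE_MIN,
    period_min: float = 60.0,
    seed: int = 1,
    amplitude_um: float = 30.0,
    mean_um: float = 70.0,
) -> FeatureTable:
    """Sine-modulated S1 inflow sampled every 4.5 min over 7 h.

    ``meta_input_uM`` records the instantaneous inflow set-point, the
    signal the forecasting task must predict ahead in time.
    """
    def modulation(t_s: float) -> dict:
        return {"s1": mean_um + amplitude_um * np.sin(2 * np.pi * t_s / (period_min * 60.0))}

    cond = InputCondition()
    traj = simulate_dynamic(reservoir.model, cond, total_min=total_h * 60.0,
                            sample_every_min=sample_every_min,
                            inflow_modulation=modulation)
    seeds = _spawn_seeds(seed, len(traj.t_min))
    rows = []
    for i, t in enumerate(traj.t_min):
        feats = pd.Series(traj.states[i], index=traj.species)[reservoir.feature_names]
        noisy = _apply_noise(feats, reservoir.noise, seeds[i])
        u = modulation(t * 60.0)["s1"]
        rows.append(({"t_min": float(t), "input_uM": float(u)}, noisy))
    return FeatureTable.from_samples(rows)


def _apply_noise(feats: pd.Series, noise: NoiseParams, seed: int) -> pd.Series:
    values = feats.to_numpy(dtype=float)
    k = len(values)
    if noise.response_sigma > 0:
        rf = np.random.default_rng(noise.response_seed)
        values = values * np.exp(noise.response_sigma * rf.standard_normal(k))
    if noise.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise.noise_cv**2))
        rng = np.random.default_rng(seed)
        values = values * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=k))
    return pd.Series(values, index=feats.index)
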