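"""The task battery: target functions over normalized input spaces.

Every task maps physical inputs (substrate concentrations, temperature,
pH, light-pulse period), first normalized affinely to [0, 1], to a binary
label or a continuous target in [0, 1]:

* XOR / circle / hourglass — the three nonlinear classification
  geometries on a 2-D input space;
* sensing — identity on temperature (linear regression target);
* activation — logistic step, y = 1 / (1 + exp(-k (T - T0)));
* tuning — the factor-4-scaled logistic bell,
  y = 4 sigma (1 - sigma), the gradient of activation rescaled to peak
  at 1 instead of 0.25;
* threshold (decision-making) — the inclusive step, y = 1 iff T >= T0;
* light periodicity switch — y = 1 iff period >= P0 (same inclusive
  boundary convention);
* forecasting — predict a dynamic input signal a fixed lead time ahead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

#: circle radius giving a 50/50 class split on the unit square (pi r^2 = 1/2)
CIRCLE_RADIUS_BALANCED = float(np.sqrt(0.5 / np.pi))


def normalize_input(u_physical, lo: float, hi: float):
    """Affine map of a physical input onto [0, 1]; clamps with a warning."""
    if not hi > lo:
        raise ValueError("degenerate input range")
    u = (np.asarray(u_physical, dtype=float) - lo) / (hi - lo)
    if np.any(u < -1e-12) or np.any(u > 1 + 1e-12):
        warnings.warn("input outside its stated physical range; clamping", stacklevel=2)
        u = np.clip(u, 0.0, 1.0)
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# binary geometries on [0, 1]^2

def xor_label(u1, u2):
    """1 iff exactly one input exceeds 1/2."""
    a = np.asarray(u1) > 0.5
    b = np.asarray(u2) > 0.5
    return (a ^ b).astype(int)


def circle_label(u1, u2, radius: float = CIRCLE_RADIUS_BALANCED):
    """1 inside the centred disc (default radius balances the classes)."""
    r2 = (np.asarray(u1) - 0.5) ** 2 + (np.asarray(u2) - 0.5) ** 2
    return (r2 <= radius**2).astype(int)


def hourglass_label(u1, u2):
    """1 in the vertical wedge pair: |u2 - 1/2| > |u1 - 1/2|."""
    return (np.abs(np.asarray(u2) - 0.5) > np.abs(np.asarray(u1) - 0.5)).astype(int)


# ---------------------------------------------------------------------------
# temperature battery

def activation_target(t_c, t0: float, k: float = 1.0):
    """Logistic activation, midpoint t0, sharpness k (per deg C)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(t_c, dtype=float) - t0)))


def tuning_target(t_c, t0: float, k: float = 1.0):
    """Scaled logistic bell 4 sigma (1 - sigma); maximum value 1 at t0."""
    s = activation_target(t_c, t0, k)
    return 4.0 * s * (1.0 - s)


def threshold_target(t_c, t0: float):
    """Inclusive decision step: 1 iff T >= T0."""
    return (np.asarray(t_c, dtype=float) >= t0).astype(int)


def sensing_target(t_c):
    """Identity: the sensor must report the temperature itself."""
    return np.asarray(t_c, dtype=float)


def t0_grid() -> np.ndarray:
    """Task-boundary grid: from 30.75 C in 1.5 C steps up to 51 C (14 values)."""
    return np.arange(30.75, 51.0 + 1e-9, 1.5)


# ---------------------------------------------------------------------------
# light and forecasting

def light_periodicity_label(period_s, p0_s: float):
    """1 iff the pulse period is >= the boundary P0 (inclusive)."""
    return (np.asarray(period_s, dtype=float) >= p0_s).astype(int)


def forecast_target(signal: np.ndarray, lead_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Pair each sample index with the signal ``lead_steps`` later.

    Returns (kept sample indices, target values); a series of length n
    with shift s yields n - s training pairs.
    """
    signal = np.asarray(signal, dtype=float)
    if lead_steps < 0:
        raise ValueError("lead must be >= 0")
    n = len(signal)
    if lead_steps == 0:
        return np.arange(n), signal.copy()
    return np.arange(n - lead_steps), signal[lead_steps:]


def lead_steps(lead_min: float, sample_every_min: float = 4.5) -> int:
    """Convert a lead time to sample steps; must be a grid multiple."""
    steps = lead_min / sample_every_min
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"lead {lead_min} min is not a multiple of the {sample_every_min}-min grid"
        )
    return int(round(steps))


# ---------------------------------------------------------------------------
# task registry

@dataclass(frozen=True)
class TaskSpec:
    """A named target function over named, range-normalized inputs.

    ``input_dims`` maps metadata keys (without the ``meta_`` prefix) to
    physical (lo, hi) ranges, or to ``None`` for inputs used raw (the
    sensing and light tasks operate on the physical value directly).
    """

    name: str
    kind: str  # "binary" | "continuous" | "forecast"
    input_dims: tuple[tuple[str, tuple[float, float] | None], ...]
    fn: Callable = field(compare=False)
    params: tuple[tuple[str, float], ...] = ()

    def targets(self, metadata: pd.DataFrame) -> np.ndarray:
        """Evaluate the target function on a table's metadata."""
        args = []
        for key, rng in self.input_dims:
            col = f"meta_{key}" if f"meta_{key}" in metadata.columns else key
            if col not in metadata.columns:
                raise KeyError(f"task {self.name!r} needs metadata column {col!r}")
            vals = metadata[col].to_numpy(dtype=float)
            args.append(normalize_input(vals, *rng) if rng is not None else vals)
        return np.asarray(self.fn(*args, **dict(self.params)))


_S1S2 = (("s1_uM", (40.0, 100.0)), ("s2_uM", (15.0, 75.0)))
_PHT = (("pH", (6.0, 8.5)), ("T_C", (25.0, 55.0)))


def make_task(name: str, inputs: str = "s1s2", **params) -> TaskSpec:
    """Look up a task by name.

    ``inputs`` selects the 2-D input space of the classification
    geometries: ``"s1s2"`` (substrate channels) or ``"ph_t"`` (pH x
    temperature).  Temperature-battery tasks take ``t0`` (and ``k``);
    the light switch takes ``p0_s``.
    """
    dims2 = {"s1s2": _S1S2, "ph_t": _PHT}
    if name in ("xor", "circle", "hourglass"):
        fn = {"xor": xor_label, "circle": circle_label, "hourglass": hourglass_label}[name]
        return TaskSpec(name, "binary", dims2[inputs], fn,
                        tuple(sorted(params.items())))
    if name == "sensing":
        return TaskSpec(name, "continuous", (("T_C", None),), sensing_target)
    if name in ("activation", "tuning"):
        fn = {"activation": activation_target, "tuning": tuning_target}[name]
        p = {"t0": 40.0, "k": 1.0}
        p.update(params)
        return TaskSpec(name, "continuous", (("T_C", None),), fn,
                        tuple(sorted(p.items())))
    if name == "threshold":
        p = {"t0": 40.0}
        p.update(params)
        return TaskSpec(name, "binary", (("T_C", None),), threshold_target,
                        tuple(sorted(p.items())))
    if name == "light_switch":
        p = {"p0_s": 120.0}
        p.update(params)
        return TaskSpec(name, "binary", (("light_period_s", None),),
                        light_periodicity_label, tuple(sorted(p.items())))
    raise KeyError(f"unknown task {name!r}")
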