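"""Fixed-step integration of a circuit model driven by a stimulus protocol.

Two deterministic fixed-step schemes are provided: forward Euler (the
workhorse, at dt = 0.01 by default) and the classical fourth-order
Runge–Kutta scheme used as an accuracy benchmark.  Input channels are
rectangular pulse trains, so their values are pre-sampled on the step grid
(Euler) or the half-step grid (RK4, whose stages fall on t, t+dt/2, t+dt).

There is no adaptivity and no event detection: peaks and classifications are
extracted from the recorded trajectory afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocols import Protocol

__all__ = [
    "IntegratorSettings",
    "Trajectory",
    "IntegrationError",
    "ConfigurationError",
    "integrate",
    "convergence_check",
]

log = logging.getLogger(__name__)

# undershoot below this is treated as instability, not roundoff
NEGATIVE_TOL = -1e-9


class IntegrationError(RuntimeError):
    """Raised when the state leaves the admissible region mid-run."""


class ConfigurationError(ValueError):
    """Raised for inconsistent integrator / grid configuration."""


@dataclass(frozen=True)
class IntegratorSettings:
    method: str = "euler"
    dt: float = 0.01
    record_stride: int = 1

    def __post_init__(self):
        if self.method not in ("euler", "rk4"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.record_stride < 1 or int(self.record_stride) != self.record_stride:
            raise ConfigurationError(
                f"record_stride must be a positive integer, got {self.record_stride}"
            )


@dataclass
class Trajectory:
    """One integration run: sampled times, states and applied inputs."""

    times: np.ndarray
    states: np.ndarray        # (n_samples, n_state)
    inputs: np.ndarray        # (n_samples, n_channels)
    state_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    model: str = ""
    settings: IntegratorSettings | None = None

    def __post_init__(self):
        if not (len(self.times) == len(self.states) == len(self.inputs)):
            raise ValueError("times, states and inputs must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for i, n in enumerate(self.state_names):
            df[n] = self.states[:, i]
        for i, n in enumerate(self.channel_names):
            df[n] = self.inputs[:, i]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, n_state: int | None = None, model: str = "") -> "Trajectory":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        cols = list(df.columns)
        if cols[0] != "time":
            raise ValueError("first column of a trajectory file must be 'time'")
        if n_state is None:
            n_state = len(cols) - 1  # no way to tell states from inputs
        state_names = tuple(cols[1:1 + n_state])
        channel_names = tuple(cols[1 + n_state:])
        return cls(
            times=df["time"].to_numpy(),
            states=df[list(state_names)].to_numpy(),
            inputs=df[list(channel_names)].to_numpy() if channel_names else
            np.zeros((len(df), 0)),
            state_names=state_names,
            channel_names=channel_names,
            model=model,
        )


def _n_steps(horizon: float, dt: float) -> int:
    n = round(horizon / dt)
    if n < 1 or abs(n * dt - horizon) > 1e-6 * dt:
        raise ConfigurationError(
            f"dt={dt} does not divide the horizon {horizon} into whole steps"
        )
    return int(n)


def integrate(
    rhs,
    state0,
    protocol: Protocol,
    settings: IntegratorSettings = IntegratorSettings(),
    params=None,
    channels=None,
    state_names=None,
    model: str = "",
) -> Trajectory:
    """Integrate ``d(state)/dt = rhs(state, inputs, params)`` over the protocol.

    ``rhs`` may take ``(state, inputs)`` or ``(state, inputs, params)`` if
    ``params`` is given.  ``channels`` fixes the order in which protocol
    channels are passed to ``rhs``; it defaults to the protocol's sorted
    channel list.

    Raises :class:`IntegrationError` if any state component becomes
    non-finite or undershoots below −1e−9 (roundoff-scale undershoot is
    tolerated; anything larger signals an unstable step size).
    """
    if channels is None:
        channels = protocol.channels
    state = np.asarray(state0, dtype=float).copy()
    if state.ndim != 1:
        raise ValueError("state0 must be a flat vector")
    if not np.all(np.isfinite(state)) or np.any(state < 0):
        raise ValueError(f"state0 must be finite and non-negative, got {state0!r}")
    dt = settings.dt
    n = _n_steps(protocol.horizon, dt)
    stride = settings.record_stride

    f = rhs if params is None else (lambda s, u: rhs(s, u, params))

    rk4 = settings.method == "rk4"
    # pre-sample inputs: Euler needs step times, RK4 also the midpoints
    grid_dt = dt / 2.0 if rk4 else dt
    grid = np.arange(2 * n + 1 if rk4 else n + 1) * grid_dt
    grid[-1] = min(grid[-1], protocol.horizon)
    U = protocol.sample(grid, channels)

    rec_idx = list(range(0, n + 1, stride))
    if rec_idx[-1] != n:
        rec_idx.append(n)
    rec_set = set(rec_idx)

    times = np.array([i * dt for i in rec_idx])
    states_out = np.empty((len(rec_idx), state.size))
    inputs_out = np.empty((len(rec_idx), len(channels)))
    k = 0
    if 0 in rec_set:
        states_out[0] = state
        inputs_out[0] = U[0]
        k = 1

    for i in range(n):
        if rk4:
            u0 = tuple(U[2 * i])
            um = tuple(U[2 * i + 1])
            u1 = tuple(U[2 * i + 2])
            k1 = f(state, u0)
            k2 = f(state + 0.5 * dt * k1, um)
            k3 = f(state + 0.5 * dt * k2, um)
            k4 = f(state + dt * k3, u1)
            state = state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        else:
            state = state + dt * f(state, tuple(U[i]))
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state at t={(i + 1) * dt:.6g}: {state}"
            )
        lo = state.min()
        if lo < NEGATIVE_TOL:
            raise IntegrationError(
                f"state undershoot {lo:.3e} at t={(i + 1) * dt:.6g}; "
                "reduce dt (states are not clamped)"
            )
        if (i + 1) in rec_set:
            states_out[k] = state
            inputs_out[k] = U[2 * (i + 1)] if rk4 else U[i + 1]
            k += 1

    return Trajectory(
        times=times,
        states=states_out,
        inputs=inputs_out,
        state_names=tuple(state_names) if state_names else
        tuple(f"s{i}" for i in range(state.size)),
        channel_names=tuple(channels),
        model=model,
        settings=settings,
    )


def convergence_check(
    rhs,
    state0,
    protocol: Protocol,
    dts,
    method: str = "euler",
    params=None,
    channels=None,
) -> pd.DataFrame:
    """Step-refinement study: sup-norm deviation of each run from the finest.

    ``dts`` must be in decreasing order and each must be an integer multiple
    of the finest so that the time grids align exactly.  Returns a DataFrame
    with one row per coarse step size and the sup-norm deviation over all
    state components on the common grid; for a convergent scheme on these
    protocols the deviations shrink monotonically with dt.
    """
    dts = list(dts)
    if len(dts) < 2:
        raise ConfigurationError("need at least two step sizes")
    if any(d2 > d1 for d1, d2 in zip(dts, dts[1:])):
        raise ConfigurationError("step sizes must be non-increasing")
    finest = dts[-1]
    ratios = []
    for d in dts:
        r = d / finest
        if abs(r - round(r)) > 1e-9:
            raise ConfigurationError(
                f"dt={d} is not an integer multiple of the finest dt={finest}"
            )
        ratios.append(int(round(r)))

    runs = {
        d: integrate(rhs, state0, protocol,
                     IntegratorSettings(method=method, dt=d),
                     params=params, channels=channels)
        for d in dts
    }
    ref = runs[finest]
    rows = []
    for d, r in zip(dts[:-1], ratios[:-1]):
        coarse = runs[d]
        sub = ref.states[::r]
        dev = float(np.max(np.abs(coarse.states - sub)))
        rows.append({"dt": d, "sup_deviation": dev})
    return pd.DataFrame(rows)
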