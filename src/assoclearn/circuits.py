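"""Kinetic models of two molecular circuits for associative learning.

Two circuit families are implemented, each in a dimensional and a
dimensionless form:

* A Hebbian-style circuit in which slowly decaying "weight" molecules
  (``w1``, ``w2``) gate the production of a response protein ``p``.  Each
  stimulus channel ``uj`` sequesters a repressor ``rj`` that otherwise blocks
  both the response and the weight genes; pairing the two stimuli lets the
  response feed back onto the weight of the conditioned channel, which is the
  molecular analogue of a Hebbian weight update.

* A feed-forward "forced dissociation" circuit with response ``y``,
  moderator ``u`` and inhibitor ``v``.  The conditioned stimulus ``x`` drives
  both the response and the inhibitor; the unconditioned stimulus ``z`` drives
  the response and, during pairing, blocks inhibitor production while ``x``
  builds up the moderator ``u``, which slows inhibitor recovery.  Repeated
  cuing of ``x`` alone re-accumulates ``v`` and actively shuts the learned
  response down.  An adjusted variant gives ``z`` its own operator site,
  decoupling the unconditioned pathway from ``x`` and ``v``.

All regulation uses Hill kinetics.  In the dimensionless forms every Hill
constant equals 1, the response degradation rate equals 1, and time is
measured in units of the response lifetime.

State-vector conventions (used by every RHS and by the integrator):

* Hebbian circuit: ``[p, w1, w2]``, inputs ``(u1, u2)``;
* forced-dissociation circuits: ``[y, u, v]``, inputs ``(x, z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np

__all__ = [
    "hill_act",
    "hill_rep",
    "FernandoParams",
    "FernandoDimensionalParams",
    "FernandoState",
    "FDParams",
    "FDDimensionalParams",
    "AdjustedFDParams",
    "FDState",
    "fernando_rhs",
    "fernando_dimensional_rhs",
    "fd_rhs",
    "fd_dimensional_rhs",
    "adjusted_fd_rhs",
    "nondimensionalize_fernando",
    "nondimensionalize_fd",
    "FernandoScaling",
    "FDScaling",
    "MODELS",
    "ModelSpec",
]


# ---------------------------------------------------------------------------
# Hill primitives
# ---------------------------------------------------------------------------

def _check_coeff(a: int, name: str = "a") -> None:
    if isinstance(a, bool) or not isinstance(a, (int, np.integer)):
        raise ValueError(f"Hill coefficient {name} must be a positive integer, got {a!r}")
    if a < 1:
        raise ValueError(f"Hill coefficient {name} must be >= 1, got {a}")


def hill_act(x: float, a: int) -> float:
    """Activating Hill term ``x**a / (1 + x**a)`` (dimensionless K = 1).

    Strictly increasing in ``x``; 0 at ``x = 0`` and 0.5 at ``x = 1`` for
    every cooperativity ``a``.
    """
    _check_coeff(a)
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"Hill input must be non-negative, got {x!r}")
    xa = x ** a
    return xa / (1.0 + xa)


def hill_rep(x: float, a: int) -> float:
    """Repressing Hill term ``1 / (1 + x**a)``; complements :func:`hill_act`."""
    _check_coeff(a)
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"Hill input must be non-negative, got {x!r}")
    return 1.0 / (1.0 + x ** a)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


class _ParamBase:
    """Shared dict round-trip for the flat key-value config interface."""

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "_ParamBase":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown parameter keys for {cls.__name__}: {sorted(unknown)}"
            )
        merged = {f.name: d.get(f.name, getattr(cls, f.name, None)) for f in fields(cls)}
        missing = [k for k, v in merged.items() if v is None]
        if missing:
            raise ValueError(f"missing parameter keys for {cls.__name__}: {missing}")
        for key in ("a", "b"):
            if key in merged and isinstance(merged[key], float) and merged[key].is_integer():
                merged[key] = int(merged[key])
        return cls(**merged)

    def replace(self, **changes) -> "_ParamBase":
        d = self.to_dict()
        unknown = set(changes) - set(d)
        if unknown:
            raise ValueError(f"unknown parameter(s) {sorted(unknown)} for {type(self).__name__}")
        d.update(changes)
        return type(self).from_dict(d)


def _require_positive(obj, names) -> None:
    for n in names:
        v = getattr(obj, n)
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{n} must be finite and > 0, got {v!r}")


def _require_nonneg(obj, names) -> None:
    for n in names:
        v = getattr(obj, n)
        if v < 0 or not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{n} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class FernandoParams(_ParamBase):
    """Dimensionless parameters of the Hebbian-style circuit.

    ``alpha``/``beta`` are the production strengths of the response and the
    weights, ``theta`` the weight-to-response degradation ratio, ``tau1``/
    ``tau2`` the basal weight growth (only the unconditioned channel is
    constitutively maintained by default), ``S`` the basal repressor level,
    and ``a``/``b`` the Hill coefficients of the weight and response/repressor
    terms respectively.
    """

    alpha: float = 1.0
    beta: float = 0.8
    theta: float = 0.02
    tau1: float = 0.1
    tau2: float = 0.0
    S: float = 10.0
    a: int = 4
    b: int = 2

    def __post_init__(self):
        _require_positive(self, ("alpha", "beta", "theta", "S"))
        _require_nonneg(self, ("tau1", "tau2"))
        _check_coeff(self.a, "a")
        _check_coeff(self.b, "b")


@dataclass(frozen=True)
class FernandoDimensionalParams(_ParamBase):
    """Dimensional parameters of the Hebbian-style circuit (units in docs)."""

    v_p: float = 1.0
    v_w: float = 1.0
    delta_p: float = 1.0
    delta_w: float = 1.0
    K_w: float = 1.0
    K_r: float = 1.0
    K_p: float = 1.0
    R: float = 1.0
    k: float = 1.0
    eps1: float = 0.0
    eps2: float = 0.0
    a: int = 4
    b: int = 2

    def __post_init__(self):
        _require_positive(
            self, ("v_p", "v_w", "delta_p", "delta_w", "K_w", "K_r", "K_p", "R", "k")
        )
        _require_nonneg(self, ("eps1", "eps2"))
        _check_coeff(self.a, "a")
        _check_coeff(self.b, "b")


@dataclass(frozen=True)
class FDParams(_ParamBase):
    """Dimensionless parameters of the forced-dissociation circuit."""

    alpha_yx: float = 2.0
    alpha_yz: float = 4.0
    alpha_xyz: float = 4.0
    alpha_ux: float = 0.6
    alpha_vx: float = 1.5
    beta_u: float = 0.1
    beta_v: float = 0.02
    a: int = 2

    def __post_init__(self):
        _require_positive(
            self,
            ("alpha_yx", "alpha_yz", "alpha_xyz", "alpha_ux", "alpha_vx", "beta_u", "beta_v"),
        )
        _check_coeff(self.a, "a")


@dataclass(frozen=True)
class FDDimensionalParams(_ParamBase):
    """Dimensional parameters of the forced-dissociation circuit."""

    alpha_yx: float = 2.0
    alpha_yz: float = 4.0
    alpha_xyz: float = 4.0
    alpha_ux: float = 0.6
    alpha_vx: float = 1.5
    delta_y: float = 1.0
    delta_u: float = 0.1
    delta_v: float = 0.02
    K_x: float = 1.0
    K_z: float = 1.0
    K_v: float = 1.0
    K_u: float = 1.0
    a: int = 2

    def __post_init__(self):
        _require_positive(
            self,
            (
                "alpha_yx", "alpha_yz", "alpha_xyz", "alpha_ux", "alpha_vx",
                "delta_y", "delta_u", "delta_v", "K_x", "K_z", "K_v", "K_u",
            ),
        )
        _check_coeff(self.a, "a")


@dataclass(frozen=True)
class AdjustedFDParams(_ParamBase):
    """Adjusted forced-dissociation circuit: ``z`` has its own operator site,
    so the combined x·z production term disappears."""

    alpha_yx: float = 4.0
    alpha_yz: float = 1.0
    alpha_ux: float = 0.6
    alpha_vx: float = 1.0
    beta_u: float = 0.1
    beta_v: float = 0.02
    a: int = 2

    def __post_init__(self):
        _require_positive(
            self, ("alpha_yx", "alpha_yz", "alpha_ux", "alpha_vx", "beta_u", "beta_v")
        )
        _check_coeff(self.a, "a")


# ---------------------------------------------------------------------------
# State containers (thin named views over the integrator's flat vectors)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FernandoState:
    p: float = 0.0
    w1: float = 0.0
    w2: float = 0.0

    def __post_init__(self):
        if min(self.p, self.w1, self.w2) < 0:
            raise ValueError("initial concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.w1, self.w2], dtype=float)


@dataclass(frozen=True)
class FDState:
    y: float = 0.0
    u: float = 0.0
    v: float = 0.0

    def __post_init__(self):
        if min(self.y, self.u, self.v) < 0:
            raise ValueError("initial concentrations must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.y, self.u, self.v], dtype=float)


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _check_finite(state, inputs) -> None:
    for v in state:
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite state encountered: {tuple(state)}")
    for v in inputs:
        if not math.isfinite(v):
            raise FloatingPointError(f"non-finite input encountered: {tuple(inputs)}")


def fernando_rhs(state, inputs, params: FernandoParams) -> np.ndarray:
    """Dimensionless Hebbian-circuit derivative at ``state = [p, w1, w2]``.

    Repressors are algebraic, ``rj = S / (1 + uj)``: input binding sequesters
    the repressor rather than being integrated as a state.  The response sums
    one Hill-gated production term per channel; each weight grows only when
    the response is high *and* its channel's repressor is sequestered.
    """
    _check_finite(state, inputs)
    p = state[0]
    a, b = params.a, params.b
    pb = p ** b
    act_p = pb / (1.0 + pb)
    dp = -p
    deriv = np.empty(len(state))
    taus = (params.tau1, params.tau2)
    for j, (w, u) in enumerate(zip(state[1:], inputs)):
        r = params.S / (1.0 + u)
        rep = 1.0 / (1.0 + r ** b)
        wa = w ** a
        dp += params.alpha * (wa / (1.0 + wa)) * rep
        deriv[1 + j] = params.beta * act_p * rep - params.theta * w + taus[j]
    deriv[0] = dp
    return deriv


def fernando_dimensional_rhs(state, inputs, params: FernandoDimensionalParams) -> np.ndarray:
    """Dimensional Hebbian-circuit derivative; ``rj = R / (1 + k·uj)``."""
    _check_finite(state, inputs)
    p = state[0]
    a, b = params.a, params.b
    Kpb = params.K_p ** b
    Krb = params.K_r ** b
    Kwa = params.K_w ** a
    pb = p ** b
    act_p = pb / (Kpb + pb)
    dp = -params.delta_p * p
    deriv = np.empty(len(state))
    epss = (params.eps1, params.eps2)
    for j, (w, u) in enumerate(zip(state[1:], inputs)):
        r = params.R / (1.0 + params.k * u)
        rep = Krb / (Krb + r ** b)
        wa = w ** a
        dp += params.v_p * (wa / (Kwa + wa)) * rep
        deriv[1 + j] = params.v_w * act_p * rep - params.delta_w * w + epss[j]
    deriv[0] = dp
    return deriv


def fd_rhs(state, inputs, params: FDParams) -> np.ndarray:
    """Dimensionless forced-dissociation derivative at ``state = [y, u, v]``.

    The response gene has three Hill-gated production routes — x alone,
    z alone, and x·z jointly — all blocked by the inhibitor v.  The moderator
    u is driven by x only; the inhibitor v is driven by x but blocked by both
    u and z, which is what makes pairing (x with z) deplete v and repeated
    x-alone cuing restore it.
    """
    _check_finite(state, inputs)
    y, u, v = state
    x, z = inputs
    a = params.a
    xa, za = x ** a, z ** a
    ax, az = xa / (1.0 + xa), za / (1.0 + za)
    rx, rz = 1.0 / (1.0 + xa), 1.0 / (1.0 + za)
    rv = 1.0 / (1.0 + v ** a)
    ru = 1.0 / (1.0 + u ** a)
    dy = (
        params.alpha_yx * ax * rz * rv
        + params.alpha_yz * rx * az * rv
        + params.alpha_xyz * ax * az * rv
        - y
    )
    du = params.alpha_ux * ax - params.beta_u * u
    dv = params.alpha_vx * ax * ru * rz - params.beta_v * v
    return np.array([dy, du, dv])


def fd_dimensional_rhs(state, inputs, params: FDDimensionalParams) -> np.ndarray:
    """Dimensional forced-dissociation derivative (Hill constants explicit)."""
    _check_finite(state, inputs)
    y, u, v = state
    x, z = inputs
    a = params.a
    xa, za = x ** a, z ** a
    Kxa, Kza = params.K_x ** a, params.K_z ** a
    Kua, Kva = params.K_u ** a, params.K_v ** a
    ax = xa / (Kxa + xa)
    az = za / (Kza + za)
    rx = Kxa / (Kxa + xa)
    rz = Kza / (Kza + za)
    rv = Kva / (Kva + v ** a)
    ru = Kua / (Kua + u ** a)
    dy = (
        params.alpha_yx * ax * rz * rv
        + params.alpha_yz * rx * az * rv
        + params.alpha_xyz * ax * az * rv
        - params.delta_y * y
    )
    du = params.alpha_ux * ax - params.delta_u * u
    dv = params.alpha_vx * ax * ru * rz - params.delta_v * v
    return np.array([dy, du, dv])


def adjusted_fd_rhs(state, inputs, params: AdjustedFDParams) -> np.ndarray:
    """Adjusted circuit: the z pathway is its own term, untouched by x or v."""
    _check_finite(state, inputs)
    y, u, v = state
    x, z = inputs
    a = params.a
    xa, za = x ** a, z ** a
    ax, az = xa / (1.0 + xa), za / (1.0 + za)
    rv = 1.0 / (1.0 + v ** a)
    ru = 1.0 / (1.0 + u ** a)
    rz = 1.0 / (1.0 + za)
    dy = params.alpha_yx * ax * rv + params.alpha_yz * az - y
    du = params.alpha_ux * ax - params.beta_u * u
    dv = params.alpha_vx * ax * ru * rz - params.beta_v * v
    return np.array([dy, du, dv])


# ---------------------------------------------------------------------------
# Nondimensionalisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FernandoScaling:
    """Invertible maps between the dimensional and dimensionless Hebbian model.

    Concentrations scale by their Hill constants (p by K_p, weights by K_w,
    repressors by K_r), time by the response lifetime 1/δ_p, and inputs by
    the binding coefficient k.
    """

    K_p: float
    K_w: float
    K_r: float
    delta_p: float
    k: float

    def to_dimensionless_state(self, state) -> np.ndarray:
        s = np.asarray(state, dtype=float)
        out = s.copy()
        out[..., 0] = s[..., 0] / self.K_p
        out[..., 1:] = s[..., 1:] / self.K_w
        return out

    def to_dimensional_state(self, state) -> np.ndarray:
        s = np.asarray(state, dtype=float)
        out = s.copy()
        out[..., 0] = s[..., 0] * self.K_p
        out[..., 1:] = s[..., 1:] * self.K_w
        return out

    def to_dimensionless_time(self, t):
        return np.asarray(t, dtype=float) * self.delta_p

    def to_dimensional_time(self, t):
        return np.asarray(t, dtype=float) / self.delta_p

    def to_dimensionless_inputs(self, u):
        return np.asarray(u, dtype=float) * self.k

    def to_dimensional_inputs(self, u):
        return np.asarray(u, dtype=float) / self.k


def nondimensionalize_fernando(
    params: FernandoDimensionalParams,
) -> tuple[FernandoParams, FernandoScaling]:
    """Reduce the dimensional Hebbian model to its dimensionless form.

    With p̄ = p/K_p, ω̄ = ω/K_ω, t̄ = δ_p t and ū = k·u the chain rule gives
    α = v_p/(K_p δ_p), β = v_ω/(K_ω δ_p), θ = δ_ω/δ_p, τ = ε/(K_ω δ_p) and
    S = R/K_r; Hill coefficients are untouched.
    """
    dimless = FernandoParams(
        alpha=params.v_p / (params.K_p * params.delta_p),
        beta=params.v_w / (params.K_w * params.delta_p),
        theta=params.delta_w / params.delta_p,
        tau1=params.eps1 / (params.K_w * params.delta_p),
        tau2=params.eps2 / (params.K_w * params.delta_p),
        S=params.R / params.K_r,
        a=params.a,
        b=params.b,
    )
    scaling = FernandoScaling(
        K_p=params.K_p, K_w=params.K_w, K_r=params.K_r,
        delta_p=params.delta_p, k=params.k,
    )
    return dimless, scaling


@dataclass(frozen=True)
class FDScaling:
    """Maps between the dimensional and dimensionless dissociation model.

    Inputs and the u, v states scale by their Hill constants, time by the
    response lifetime 1/δ_y.  The response y is left unscaled: nothing
    downstream reads y through a Hill term, so it has no natural constant.
    """

    K_x: float
    K_z: float
    K_u: float
    K_v: float
    delta_y: float

    def to_dimensionless_state(self, state) -> np.ndarray:
        s = np.asarray(state, dtype=float)
        out = s.copy()
        out[..., 1] = s[..., 1] / self.K_u
        out[..., 2] = s[..., 2] / self.K_v
        return out

    def to_dimensional_state(self, state) -> np.ndarray:
        s = np.asarray(state, dtype=float)
        out = s.copy()
        out[..., 1] = s[..., 1] * self.K_u
        out[..., 2] = s[..., 2] * self.K_v
        return out

    def to_dimensionless_time(self, t):
        return np.asarray(t, dtype=float) * self.delta_y

    def to_dimensional_time(self, t):
        return np.asarray(t, dtype=float) / self.delta_y

    def to_dimensionless_inputs(self, xz):
        xz = np.asarray(xz, dtype=float)
        return xz / np.array([self.K_x, self.K_z])

    def to_dimensional_inputs(self, xz):
        xz = np.asarray(xz, dtype=float)
        return xz * np.array([self.K_x, self.K_z])


def nondimensionalize_fd(params: FDDimensionalParams) -> tuple[FDParams, FDScaling]:
    """Reduce the dimensional dissociation model to its dimensionless form.

    With t̄ = δ_y t, x̄ = x/K_x, z̄ = z/K_z, ū = u/K_u, v̄ = v/K_v and ȳ = y:
    the response production strengths divide by δ_y, the u and v productions
    additionally divide by their Hill constants, and β_u = δ_u/δ_y,
    β_v = δ_v/δ_y.
    """
    d = params
    dimless = FDParams(
        alpha_yx=d.alpha_yx / d.delta_y,
        alpha_yz=d.alpha_yz / d.delta_y,
        alpha_xyz=d.alpha_xyz / d.delta_y,
        alpha_ux=d.alpha_ux / (d.K_u * d.delta_y),
        alpha_vx=d.alpha_vx / (d.K_v * d.delta_y),
        beta_u=d.delta_u / d.delta_y,
        beta_v=d.delta_v / d.delta_y,
        a=d.a,
    )
    scaling = FDScaling(
        K_x=d.K_x, K_z=d.K_z, K_u=d.K_u, K_v=d.K_v, delta_y=d.delta_y
    )
    return dimless, scaling


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Everything the integrator and classifiers need to know about a model."""

    tag: str
    rhs: Callable
    params_cls: type
    state_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    response_index: int = 0


MODELS: dict[str, ModelSpec] = {
    m.tag: m
    for m in (
        ModelSpec("fernando", fernando_rhs, FernandoParams,
                  ("p", "w1", "w2"), ("u1", "u2")),
        ModelSpec("fernando_dimensional", fernando_dimensional_rhs,
                  FernandoDimensionalParams, ("p", "w1", "w2"), ("u1", "u2")),
        ModelSpec("fd", fd_rhs, FDParams, ("y", "u", "v"), ("x", "z")),
        ModelSpec("fd_dimensional", fd_dimensional_rhs, FDDimensionalParams,
                  ("y", "u", "v"), ("x", "z")),
        ModelSpec("adjusted_fd", adjusted_fd_rhs, AdjustedFDParams,
                  ("y", "u", "v"), ("x", "z")),
    )
}
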