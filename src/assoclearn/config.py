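"""YAML run configuration: model, parameters, protocol, integrator, tolerances.

The config format is a single YAML mapping.  Unknown keys are rejected with
field-level messages so a typo in a rate constant never silently falls back
to a default.  Example::

    model: fd
    params: {alpha_ux: 0.45}          # unspecified keys keep table defaults
    initial_state: [0, 0, 5]
    protocol:
      factory: fd_conditioning       # or an inline pulse list (see below)
      overrides: {interval: 25}
    integrator: {method: euler, dt: 0.01}
    tolerances: {rel: 0.05, baseline_eps: 0.05}

An inline protocol replaces ``factory`` with::

    protocol:
      horizon: 200
      pulses:
        - {channel: x, start: 10, duration: 2.1, amplitude: 3.2}
      labels: [CS_only]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import protocols as prot
from .behavior import Tolerances, default_initial_state
from .circuits import MODELS
from .integrate import IntegratorSettings
from .protocols import Protocol

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


PROTOCOL_FACTORIES = {
    "fernando_conditioning": prot.fernando_conditioning_protocol,
    "fd_conditioning": prot.fd_conditioning_protocol,
    "fd_no_conditioning": prot.fd_no_conditioning_protocol,
}

_TOP_KEYS = {"model", "params", "initial_state", "protocol", "integrator", "tolerances"}


@dataclass
class RunConfig:
    model: str
    params: object
    initial_state: np.ndarray
    protocol: Protocol
    settings: IntegratorSettings
    tolerances: Tolerances = field(default_factory=Tolerances)


def _reject_unknown(d: dict, allowed, where: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")


def _build_protocol(block, where="protocol") -> Protocol:
    if not isinstance(block, dict):
        raise ConfigError(f"{where}: expected a mapping")
    if "factory" in block:
        _reject_unknown(block, {"factory", "overrides"}, where)
        name = block["factory"]
        if name not in PROTOCOL_FACTORIES:
            raise ConfigError(
                f"{where}.factory: unknown factory {name!r}; "
                f"known: {sorted(PROTOCOL_FACTORIES)}"
            )
        overrides = block.get("overrides", {}) or {}
        if not isinstance(overrides, dict):
            raise ConfigError(f"{where}.overrides: expected a mapping")
        if "widened" in overrides:
            overrides = {**overrides, "widened": tuple(overrides["widened"])}
        try:
            return PROTOCOL_FACTORIES[name](**overrides)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{where}.overrides: {e}") from e
    _reject_unknown(block, {"pulses", "horizon", "labels"}, where)
    try:
        pulses = block["pulses"]
        horizon = block["horizon"]
    except KeyError as e:
        raise ConfigError(f"{where}: missing key {e.args[0]!r}") from e
    if not pulses:
        raise ConfigError(f"{where}.pulses: protocol must contain at least one pulse")
    try:
        return Protocol.from_records(pulses, horizon, labels=block.get("labels"))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


def parse_config(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "config")
    try:
        model = doc["model"]
    except KeyError:
        raise ConfigError("config: missing key 'model'") from None
    if model not in MODELS:
        raise ConfigError(f"model: unknown model {model!r}; known: {sorted(MODELS)}")
    spec = MODELS[model]

    try:
        params = spec.params_cls.from_dict(doc.get("params", {}) or {})
    except ValueError as e:
        raise ConfigError(f"params: {e}") from e

    state = doc.get("initial_state")
    if state is None:
        state = default_initial_state(model)
    state = np.asarray(state, dtype=float)
    if state.shape != (len(spec.state_names),):
        raise ConfigError(
            f"initial_state: expected {len(spec.state_names)} values "
            f"({', '.join(spec.state_names)}), got shape {state.shape}"
        )
    if not np.all(np.isfinite(state)) or np.any(state < 0):
        raise ConfigError("initial_state: values must be finite and non-negative")

    if "protocol" in doc:
        protocol = _build_protocol(doc["protocol"])
    else:
        from .behavior import default_protocol

        protocol = default_protocol(model)
    extraneous = set(protocol.channels) - set(spec.channel_names)
    if extraneous:
        raise ConfigError(
            f"protocol: channel(s) {sorted(extraneous)} not driven by model "
            f"{model!r} (channels: {spec.channel_names})"
        )

    integ = doc.get("integrator", {}) or {}
    _reject_unknown(integ, {"method", "dt", "record_stride"}, "integrator")
    try:
        settings = IntegratorSettings(**integ)
    except ValueError as e:
        raise ConfigError(f"integrator: {e}") from e

    tols = doc.get("tolerances", {}) or {}
    _reject_unknown(tols, {"rel", "baseline_eps"}, "tolerances")
    tolerances = Tolerances(**tols)
    if not (0 <= tolerances.rel < 1) or tolerances.baseline_eps <= 0:
        raise ConfigError("tolerances: rel must be in [0,1), baseline_eps > 0")

    return RunConfig(
        model=model,
        params=params,
        initial_state=state,
        protocol=protocol,
        settings=settings,
        tolerances=tolerances,
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"not valid YAML: {e}") from e
    return parse_config(doc)
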