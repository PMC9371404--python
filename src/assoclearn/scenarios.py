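"""Canned study scenarios: the calibrated conditioning experiments and sweeps.

Each scenario bundles a model, its table defaults, the calibrated protocol
and the classification step into a single reproducible run.  Scenarios have
descriptive names; the short ids (``fig3a`` … ``fig9``) are stable aliases
for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .behavior import (
    PerturbationResult,
    Tolerances,
    hill_sweep,
    perturb_and_classify,
    simulate_and_classify,
)
from .integrate import IntegratorSettings
from .protocols import fd_no_conditioning_protocol

__all__ = ["SCENARIOS", "SCENARIO_ALIASES", "run_scenario", "ScenarioResult"]


@dataclass
class ScenarioResult:
    name: str
    trajectory: object = None
    spikes: pd.DataFrame | None = None
    report: object = None
    sweep: pd.DataFrame | None = None
    perturbation: PerturbationResult | None = None


def _single(model, name, settings, tolerances, protocol=None, params=None):
    traj, spikes, report = simulate_and_classify(
        model, params=params, protocol=protocol, settings=settings,
        tolerances=tolerances,
    )
    return ScenarioResult(name, trajectory=traj, spikes=spikes, report=report)


def _fernando_conditioning(settings, tol):
    return _single("fernando", "fernando-conditioning", settings, tol)


def _fd_conditioning(settings, tol):
    return _single("fd", "fd-conditioning", settings, tol)


def _fd_no_conditioning(settings, tol):
    return _single("fd", "fd-no-conditioning", settings, tol,
                   protocol=fd_no_conditioning_protocol())


def _adjusted_conditioning(settings, tol):
    return _single("adjusted_fd", "adjusted-conditioning", settings, tol)


def _fernando_sweep_a(settings, tol):
    sweep = hill_sweep("fernando", a_values=(1, 2, 3, 4), b_values=(2,),
                       settings=settings, tolerances=tol)
    return ScenarioResult("fernando-sweep-a", sweep=sweep)


def _fernando_sweep_ab(settings, tol):
    sweep = hill_sweep("fernando", a_values=(1, 2, 3, 4), tie_b_to_a=True,
                       settings=settings, tolerances=tol)
    return ScenarioResult("fernando-sweep-ab", sweep=sweep)


def _fd_sweep_a(settings, tol):
    sweep = hill_sweep("fd", a_values=(1, 2, 3, 4), settings=settings,
                       tolerances=tol)
    return ScenarioResult("fd-sweep-a", sweep=sweep)


def _adjusted_sweep_a(settings, tol):
    sweep = hill_sweep("adjusted_fd", a_values=(1, 2, 3, 4), settings=settings,
                       tolerances=tol)
    return ScenarioResult("adjusted-sweep-a", sweep=sweep)


def _fd_perturbed(settings, tol):
    pert = perturb_and_classify("fd", "alpha_ux", 0.45, settings=settings,
                                tolerances=tol)
    return ScenarioResult("fd-perturbed", perturbation=pert,
                          spikes=pert.spikes, report=pert.report)


SCENARIOS = {
    "fernando-conditioning": _fernando_conditioning,
    "fd-conditioning": _fd_conditioning,
    "fernando-sweep-a": _fernando_sweep_a,
    "fernando-sweep-ab": _fernando_sweep_ab,
    "fd-no-conditioning": _fd_no_conditioning,
    "adjusted-conditioning": _adjusted_conditioning,
    "fd-sweep-a": _fd_sweep_a,
    "adjusted-sweep-a": _adjusted_sweep_a,
    "fd-perturbed": _fd_perturbed,
}

#: short stable ids accepted everywhere a scenario name is
SCENARIO_ALIASES = {
    "fig3a": "fernando-conditioning",
    "fig3b": "fd-conditioning",
    "fig4": "fernando-sweep-a",
    "fig5": "fernando-sweep-ab",
    "fig6a": "fd-no-conditioning",
    "fig6b": "adjusted-conditioning",
    "fig7": "fd-sweep-a",
    "fig8": "adjusted-sweep-a",
    "fig9": "fd-perturbed",
}


def run_scenario(
    name: str,
    settings: IntegratorSettings = IntegratorSettings(),
    tolerances: Tolerances = Tolerances(),
) -> ScenarioResult:
    """Run a named scenario (descriptive name or short alias)."""
    key = SCENARIO_ALIASES.get(name, name)
    if key not in SCENARIOS:
        known = sorted(SCENARIOS) + sorted(SCENARIO_ALIASES)
        raise KeyError(f"unknown scenario {name!r}; known: {known}")
    return SCENARIOS[key](settings, tolerances)
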