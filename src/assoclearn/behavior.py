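"""Per-event response peaks and conditioning-phenotype classification.

The circuits are judged on classical-conditioning vocabulary: did pairing
the conditioned with the unconditioned stimulus create a learned response
(*learning formed*), did it grow with repeated conditioning (*reinforced*),
did rapid cuing of the conditioned stimulus alone push it back to the naive
level (*forced dissociation*), does the response relax to baseline between
stimulations (*baseline return*), and are the paired responses significantly
larger than the unconditioned response alone (*conditioning dominant*)?

All verdicts are computed from a spike table — one response peak per
stimulation event — with explicit relative tolerances, so a report is a pure
deterministic function of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import protocols as prot
from .circuits import MODELS, ModelSpec
from .integrate import IntegratorSettings, Trajectory, integrate
from .protocols import CS_ONLY, PAIRED, US_ONLY, Protocol

__all__ = [
    "SpikeTable",
    "Tolerances",
    "BehaviorReport",
    "detect_response_peaks",
    "classify",
    "simulate_and_classify",
    "hill_sweep",
    "perturb_and_classify",
    "default_initial_state",
    "default_protocol",
]

#: columns of a spike table, one row per stimulation event
SPIKE_COLUMNS = ("event", "label", "peak", "peak_time", "baseline")

SpikeTable = pd.DataFrame


@dataclass(frozen=True)
class Tolerances:
    """Relative margins used by :func:`classify`.

    ``rel``: two peaks are "the same" when they differ by less than this
    fraction, and an increase only counts when it exceeds it.
    ``baseline_eps``: absolute response level below which the circuit is
    considered "back at baseline"; 0.05 is five percent of the O(1)
    conditioned response and sits well above the repressor leak floor of the
    Hebbian circuit (~0.02 with both weights saturated).
    """

    rel: float = 0.05
    baseline_eps: float = 0.05


@dataclass(frozen=True)
class BehaviorReport:
    learning_formed: bool
    reinforced: bool
    forced_dissociation: bool
    baseline_return: bool
    conditioning_dominant: bool
    amplitudes: Mapping[str, float]
    tolerances: Tolerances

    @property
    def desirable(self) -> bool:
        """Full associative-learning phenotype: the conjunction of learning,
        reinforcement, forced dissociation and conditioning dominance."""
        return (
            self.learning_formed
            and self.reinforced
            and self.forced_dissociation
            and self.conditioning_dominant
        )

    def to_text(self) -> str:
        lines = [
            f"learning_formed\t{self.learning_formed}",
            f"reinforced\t{self.reinforced}",
            f"forced_dissociation\t{self.forced_dissociation}",
            f"baseline_return\t{self.baseline_return}",
            f"conditioning_dominant\t{self.conditioning_dominant}",
            f"desirable\t{self.desirable}",
            f"tol_rel\t{self.tolerances.rel:.17g}",
            f"baseline_eps\t{self.tolerances.baseline_eps:.17g}",
        ]
        for k, v in self.amplitudes.items():
            lines.append(f"amplitude.{k}\t{v:.17g}")
        return "\n".join(lines) + "\n"


class ClassificationError(ValueError):
    """Raised when a spike table lacks the labels a classifier needs."""


def detect_response_peaks(
    trajectory: Trajectory, protocol: Protocol, response_index: int = 0
) -> SpikeTable:
    """Extract the response peak for every stimulation event.

    Each event owns the half-open window from its onset to the next event's
    onset (the last event extends to the horizon).  The peak is the maximum
    recorded response sample in the window and the baseline is the response
    at the window's first sample; with disjoint windows and pulse-driven
    dynamics this is unambiguous and deterministic.
    """
    if not protocol.events:
        raise ClassificationError("protocol has no stimulation events")
    t = trajectory.times
    resp = trajectory.states[:, response_index]
    rows = []
    for ev, (start, end) in zip(protocol.events, protocol.event_windows()):
        mask = (t >= start) & (t < end)
        if not mask.any():
            raise ClassificationError(
                f"trajectory has no samples in event window [{start}, {end})"
            )
        seg = resp[mask]
        imax = int(np.argmax(seg))
        rows.append(
            {
                "event": ev.index + 1,
                "label": ev.label,
                "peak": float(seg[imax]),
                "peak_time": float(t[mask][imax]),
                "baseline": float(seg[0]),
            }
        )
    return pd.DataFrame(rows, columns=list(SPIKE_COLUMNS))


def _learned_peaks(spikes: SpikeTable) -> list[float]:
    """CS-alone peaks immediately following each paired event."""
    labels = list(spikes["label"])
    peaks = list(spikes["peak"])
    learned = []
    for i, lab in enumerate(labels):
        if lab == PAIRED:
            for j in range(i + 1, len(labels)):
                if labels[j] == CS_ONLY:
                    learned.append(peaks[j])
                    break
                if labels[j] == PAIRED:
                    break
    return learned


def classify(spikes: SpikeTable, tolerances: Tolerances = Tolerances()) -> BehaviorReport:
    """Derive the conditioning verdicts from a labelled spike table.

    * ``learning_formed``: the first CS-alone peak after conditioning exceeds
      the pre-conditioning CS-alone peak by more than ``rel``.
    * ``reinforced``: the learned peak after the second conditioning round
      exceeds the one after the first by more than ``rel``.
    * ``forced_dissociation``: the final CS-alone peak is back within ``rel``
      of (or below) the pre-conditioning CS-alone peak.
    * ``baseline_return``: the response has relaxed below ``baseline_eps`` at
      the start of every event window after the first.
    * ``conditioning_dominant``: every paired peak exceeds the unconditioned
      peak by more than ``rel`` — conditioning visibly adds to the response
      rather than merely reproducing it.

    Verdicts degrade conservatively on sparse protocols: with no paired
    events there are no learned peaks, so learning and reinforcement are
    ``False`` and dominance is vacuously ``True``.
    """
    tol = tolerances.rel
    labels = list(spikes["label"])
    peaks = list(spikes["peak"])
    if US_ONLY not in labels and PAIRED not in labels:
        raise ClassificationError("spike table has no US or paired events")

    paired_idx = [i for i, l in enumerate(labels) if l == PAIRED]
    first_paired = paired_idx[0] if paired_idx else len(labels)
    pre_cs = next(
        (peaks[i] for i, l in enumerate(labels[:first_paired]) if l == CS_ONLY), None
    )
    us_peak = next((peaks[i] for i, l in enumerate(labels) if l == US_ONLY), None)
    learned = _learned_peaks(spikes)
    post_cs = [peaks[i] for i, l in enumerate(labels) if l == CS_ONLY and i > first_paired]

    amplitudes: dict[str, float] = {}
    if us_peak is not None:
        amplitudes["us_peak"] = us_peak
    if pre_cs is not None:
        amplitudes["pre_cs_peak"] = pre_cs
    for k, v in enumerate(learned):
        amplitudes[f"learned_peak_{k + 1}"] = v
    for k, i in enumerate(paired_idx):
        amplitudes[f"paired_peak_{k + 1}"] = peaks[i]
    if post_cs:
        amplitudes["final_cs_peak"] = post_cs[-1]

    learning_formed = bool(
        learned and pre_cs is not None and learned[0] > pre_cs * (1 + tol)
    )
    reinforced = bool(len(learned) >= 2 and learned[1] > learned[0] * (1 + tol))
    forced_dissociation = bool(
        post_cs and pre_cs is not None and post_cs[-1] <= pre_cs * (1 + tol)
    )
    baseline_return = bool(
        (spikes["baseline"].iloc[1:] < tolerances.baseline_eps).all()
    )
    conditioning_dominant = bool(
        us_peak is None
        or all(peaks[i] > us_peak * (1 + tol) for i in paired_idx)
    )
    return BehaviorReport(
        learning_formed=learning_formed,
        reinforced=reinforced,
        forced_dissociation=forced_dissociation,
        baseline_return=baseline_return,
        conditioning_dominant=conditioning_dominant,
        amplitudes=amplitudes,
        tolerances=tolerances,
    )


# ---------------------------------------------------------------------------
# Default study conditions per model
# ---------------------------------------------------------------------------

#: calibrated initial states: the Hebbian circuit starts with the
#: unconditioned weight at its basal fixed point tau/theta = 5 and a small
#: conditioned weight (0.3) that yields the visible-but-small naive CS spike;
#: the dissociation circuit starts with the inhibitor stocked at v = 5, the
#: level that must be replenished before each experiment.
DEFAULT_INITIAL_STATE = {
    "fernando": (0.0, 5.0, 0.3),
    "fernando_dimensional": (0.0, 5.0, 0.3),
    "fd": (0.0, 0.0, 5.0),
    "fd_dimensional": (0.0, 0.0, 5.0),
    "adjusted_fd": (0.0, 0.0, 5.0),
}

_DEFAULT_PROTOCOL_FACTORY = {
    "fernando": prot.fernando_conditioning_protocol,
    "fernando_dimensional": prot.fernando_conditioning_protocol,
    "fd": prot.fd_conditioning_protocol,
    "fd_dimensional": prot.fd_conditioning_protocol,
    "adjusted_fd": prot.fd_conditioning_protocol,
}


def default_initial_state(model: str) -> np.ndarray:
    return np.array(DEFAULT_INITIAL_STATE[model], dtype=float)


def default_protocol(model: str, **overrides) -> Protocol:
    return _DEFAULT_PROTOCOL_FACTORY[model](**overrides)


def simulate_and_classify(
    model: str,
    params=None,
    protocol: Protocol | None = None,
    initial_state=None,
    settings: IntegratorSettings = IntegratorSettings(),
    tolerances: Tolerances = Tolerances(),
):
    """Run one full scenario: integrate, extract peaks, classify.

    Returns ``(trajectory, spikes, report)``.
    """
    spec: ModelSpec = MODELS[model]
    if params is None:
        params = spec.params_cls()
    if protocol is None:
        protocol = default_protocol(model)
    if initial_state is None:
        initial_state = default_initial_state(model)
    traj = integrate(
        spec.rhs,
        initial_state,
        protocol,
        settings,
        params=params,
        channels=spec.channel_names,
        state_names=spec.state_names,
        model=model,
    )
    spikes = detect_response_peaks(traj, protocol, spec.response_index)
    report = classify(spikes, tolerances)
    return traj, spikes, report


def hill_sweep(
    model: str,
    a_values,
    b_values=None,
    tie_b_to_a: bool = False,
    params=None,
    protocol: Protocol | None = None,
    initial_state=None,
    settings: IntegratorSettings = IntegratorSettings(),
    tolerances: Tolerances = Tolerances(),
) -> pd.DataFrame:
    """Simulate and classify over a grid of Hill coefficients.

    ``b_values`` applies only to the Hebbian circuit (which has two
    coefficients); ``tie_b_to_a`` sweeps the diagonal a = b.  Returns one row
    per grid point with the verdicts and the key peak amplitudes.
    """
    spec = MODELS[model]
    if params is None:
        params = spec.params_cls()
    has_b = hasattr(params, "b")
    if tie_b_to_a and b_values is not None:
        raise ValueError("give either b_values or tie_b_to_a, not both")
    if (tie_b_to_a or b_values is not None) and not has_b:
        raise ValueError(f"model {model!r} has a single Hill coefficient")

    grid = []
    for a in a_values:
        if tie_b_to_a:
            grid.append((a, a))
        elif b_values is not None:
            for b in b_values:
                grid.append((a, b))
        else:
            grid.append((a, None))

    rows = []
    for a, b in grid:
        p = params.replace(a=a, **({"b": b} if b is not None else {}))
        _, spikes, rep = simulate_and_classify(
            model, p, protocol, initial_state, settings, tolerances
        )
        row = {"a": a}
        if b is not None:
            row["b"] = b
        row.update(
            learning_formed=rep.learning_formed,
            reinforced=rep.reinforced,
            forced_dissociation=rep.forced_dissociation,
            baseline_return=rep.baseline_return,
            conditioning_dominant=rep.conditioning_dominant,
            desirable=rep.desirable,
        )
        for k in ("us_peak", "pre_cs_peak", "learned_peak_1", "learned_peak_2",
                  "final_cs_peak"):
            if k in rep.amplitudes:
                row[k] = rep.amplitudes[k]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PerturbationResult:
    parameter: str
    base_value: float
    new_value: float
    report: BehaviorReport
    base_report: BehaviorReport
    flipped_verdicts: tuple[str, ...]
    equalised_spikes: tuple[tuple[int, int], ...]
    spikes: SpikeTable = field(repr=False, default=None)


def perturb_and_classify(
    model: str,
    parameter: str,
    new_value: float,
    params=None,
    protocol: Protocol | None = None,
    initial_state=None,
    settings: IntegratorSettings = IntegratorSettings(),
    tolerances: Tolerances = Tolerances(),
) -> PerturbationResult:
    """Re-run a scenario with one kinetic parameter substituted.

    Reports which classifier verdicts flipped relative to the unperturbed
    run and which event-peak pairs became equal within tolerance that were
    not equal before (the signature of a sensitivity-induced degeneracy,
    e.g. the unconditioned spike matching the first paired spike).
    """
    spec = MODELS[model]
    if params is None:
        params = spec.params_cls()
    if not hasattr(params, parameter):
        raise ValueError(
            f"model {model!r} has no parameter {parameter!r}; "
            f"known: {sorted(params.to_dict())}"
        )
    base_value = getattr(params, parameter)
    perturbed = params.replace(**{parameter: new_value})

    _, base_spikes, base_rep = simulate_and_classify(
        model, params, protocol, initial_state, settings, tolerances
    )
    _, spikes, rep = simulate_and_classify(
        model, perturbed, protocol, initial_state, settings, tolerances
    )

    verdict_names = (
        "learning_formed", "reinforced", "forced_dissociation",
        "baseline_return", "conditioning_dominant",
    )
    flipped = tuple(
        n for n in verdict_names if getattr(rep, n) != getattr(base_rep, n)
    )

    def equal_pairs(tab: SpikeTable) -> set[tuple[int, int]]:
        pk = list(tab["peak"])
        out = set()
        for i in range(len(pk)):
            for j in range(i + 1, len(pk)):
                if abs(pk[i] - pk[j]) <= tolerances.rel * max(pk[i], pk[j]):
                    out.add((i + 1, j + 1))
        return out

    newly_equal = sorted(equal_pairs(spikes) - equal_pairs(base_spikes))
    return PerturbationResult(
        parameter=parameter,
        base_value=base_value,
        new_value=new_value,
        report=rep,
        base_report=base_rep,
        flipped_verdicts=flipped,
        equalised_spikes=tuple(newly_equal),
        spikes=spikes,
    )
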