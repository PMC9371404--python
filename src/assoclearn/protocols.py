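"""Rectangular pulse-train stimulus protocols.

A :class:`Protocol` is an ordered set of rectangular pulses on named input
channels together with a simulation horizon and one label per *stimulation
event* (pulses sharing an onset).  Labels follow classical-conditioning
vocabulary: ``US_only`` (unconditioned stimulus alone), ``CS_only``
(conditioned stimulus alone), or ``paired`` (both channels simultaneously).

Factory functions build the calibrated training schedules used throughout
the package: neither the pulse timings nor the amplitudes are physical
measurements — they are calibration choices, chosen once so that the
circuits display their documented conditioning behaviour, and every one of
them can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Pulse",
    "Event",
    "Protocol",
    "US_ONLY",
    "CS_ONLY",
    "PAIRED",
    "fernando_conditioning_protocol",
    "fd_conditioning_protocol",
    "fd_no_conditioning_protocol",
    "scale_protocol",
]

US_ONLY = "US_only"
CS_ONLY = "CS_only"
PAIRED = "paired"


@dataclass(frozen=True)
class Pulse:
    """One rectangular pulse: ``amplitude`` on ``channel`` over the half-open
    window ``[start, start + duration)``."""

    channel: str
    start: float
    duration: float
    amplitude: float

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"pulse start must be >= 0, got {self.start}")
        if not self.duration > 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration}")
        if self.amplitude < 0:
            raise ValueError(f"pulse amplitude must be >= 0, got {self.amplitude}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Event:
    """A stimulation event: all pulses sharing one onset time."""

    index: int
    start: float
    label: str
    channels: tuple[str, ...]


class Protocol:
    """An ordered pulse train on named channels, queryable at any time.

    Pulses with identical ``(start, duration)`` on different channels form a
    single *paired* event; otherwise each pulse is its own event.  Event
    labels may be given explicitly (one per event, in event order) or are
    inferred from a ``us_channel``/``cs_channel`` assignment.
    """

    def __init__(
        self,
        pulses,
        horizon: float,
        labels=None,
        us_channel: str | None = None,
        cs_channel: str | None = None,
    ):
        pulses = tuple(sorted(pulses, key=lambda p: (p.start, p.channel)))
        if not horizon > 0:
            raise ValueError(f"horizon must be > 0, got {horizon}")
        for p in pulses:
            if p.end > horizon + 1e-12:
                raise ValueError(
                    f"pulse on {p.channel!r} ends at {p.end} after horizon {horizon}"
                )
        self.pulses = pulses
        self.horizon = float(horizon)
        self.channels = tuple(sorted({p.channel for p in pulses}))
        self.events = self._build_events(labels, us_channel, cs_channel)
        # per-channel pulse lists for fast point queries
        self._by_channel = {
            c: sorted((p for p in pulses if p.channel == c), key=lambda p: p.start)
            for c in self.channels
        }

    def _build_events(self, labels, us_channel, cs_channel):
        groups: dict[float, list[Pulse]] = {}
        for p in self.pulses:
            groups.setdefault(p.start, []).append(p)
        starts = sorted(groups)
        events = []
        for i, s in enumerate(starts):
            chans = tuple(sorted(p.channel for p in groups[s]))
            if labels is not None:
                label = labels[i]
                if label not in (US_ONLY, CS_ONLY, PAIRED):
                    raise ValueError(f"unknown event label {label!r}")
            elif len(chans) > 1:
                label = PAIRED
            elif us_channel is not None and chans[0] == us_channel:
                label = US_ONLY
            elif cs_channel is not None and chans[0] == cs_channel:
                label = CS_ONLY
            else:
                label = CS_ONLY
            events.append(Event(index=i, start=s, label=label, channels=chans))
        if labels is not None and len(labels) != len(events):
            raise ValueError(
                f"got {len(labels)} labels for {len(events)} events"
            )
        return tuple(events)

    # -- queries ------------------------------------------------------------

    def value(self, t: float) -> dict[str, float]:
        """Channel levels at time ``t`` (max over overlapping pulses)."""
        if t < 0 or t > self.horizon:
            raise ValueError(f"t={t} outside [0, {self.horizon}]")
        out = {}
        for c, plist in self._by_channel.items():
            level = 0.0
            for p in plist:
                if p.start <= t < p.end:
                    level = max(level, p.amplitude)
                elif p.start > t:
                    break
            out[c] = level
        return out

    def values(self, t: float, channels) -> tuple[float, ...]:
        v = self.value(t)
        return tuple(v.get(c, 0.0) for c in channels)

    def sample(self, times, channels) -> np.ndarray:
        """Vectorised channel levels on a time grid (shape len(times) × len(channels))."""
        times = np.asarray(times, dtype=float)
        out = np.zeros((times.size, len(channels)))
        for j, c in enumerate(channels):
            for p in self._by_channel.get(c, ()):
                mask = (times >= p.start) & (times < p.end)
                out[mask, j] = np.maximum(out[mask, j], p.amplitude)
        return out

    def event_windows(self) -> list[tuple[float, float]]:
        """Half-open analysis windows, one per event: [event start, next
        event start), the final event owning the remainder of the horizon."""
        starts = [e.start for e in self.events]
        return [
            (s, starts[i + 1] if i + 1 < len(starts) else self.horizon)
            for i, s in enumerate(starts)
        ]

    # -- transforms ----------------------------------------------------------

    def with_labels(self, labels) -> "Protocol":
        return Protocol(self.pulses, self.horizon, labels=list(labels))

    def to_records(self) -> list[dict]:
        return [
            {"channel": p.channel, "start": p.start,
             "duration": p.duration, "amplitude": p.amplitude}
            for p in self.pulses
        ]

    @classmethod
    def from_records(cls, records, horizon, labels=None, **kw) -> "Protocol":
        pulses = [Pulse(**r) for r in records]
        return cls(pulses, horizon, labels=labels, **kw)

    def __eq__(self, other):
        return (
            isinstance(other, Protocol)
            and self.pulses == other.pulses
            and self.horizon == other.horizon
            and self.events == other.events
        )

    def __repr__(self):
        return (
            f"Protocol({len(self.pulses)} pulses, {len(self.events)} events, "
            f"horizon={self.horizon})"
        )


def scale_protocol(protocol: Protocol, time_factor: float, amplitude_factors) -> Protocol:
    """Rescale a protocol (times × ``time_factor``, amplitudes per channel).

    Used to drive a dimensional and a dimensionless model with corresponding
    stimuli when checking scaling equivalence.
    """
    pulses = [
        replace(
            p,
            start=p.start * time_factor,
            duration=p.duration * time_factor,
            amplitude=p.amplitude * amplitude_factors.get(p.channel, 1.0),
        )
        for p in protocol.pulses
    ]
    return Protocol(
        pulses,
        protocol.horizon * time_factor,
        labels=[e.label for e in protocol.events],
    )


# ---------------------------------------------------------------------------
# Calibrated factory schedules
# ---------------------------------------------------------------------------


def _train(channel_events, duration, amplitudes, horizon, labels):
    pulses = []
    for start, chans in channel_events:
        for c in chans:
            pulses.append(Pulse(c, start, duration, amplitudes[c]))
    return Protocol(pulses, horizon, labels=labels)


def _per_channel(amplitude, channels) -> dict:
    if isinstance(amplitude, dict):
        unknown = set(amplitude) - set(channels)
        if unknown:
            raise ValueError(f"unknown channels in amplitude map: {sorted(unknown)}")
        return {c: float(amplitude[c]) for c in channels}
    return {c: float(amplitude) for c in channels}


def fernando_conditioning_protocol(
    *,
    start: float = 10.0,
    duration: float = 4.0,
    amplitude: float = 100.0,
    interval: float = 15.0,
    widened: tuple[float, float] = (60.0, 90.0),
    tail: float = 250.0,
) -> Protocol:
    """Ten-event training schedule for the Hebbian circuit.

    Order: US alone; CS alone (probing the naive response); two
    conditioning rounds each followed by a CS-alone test; three further CS
    probes at the short ``interval``; and two final CS probes after
    progressively ``widened`` gaps, which is where this circuit's learned
    response decays by passage of time rather than by cuing.
    """
    u1, u2 = "u1", "u2"
    starts = [start + i * interval for i in range(8)]
    starts.append(starts[7] + widened[0])
    starts.append(starts[8] + widened[1])
    chans = [(u1,), (u2,), (u1, u2), (u2,), (u1, u2), (u2,), (u2,), (u2,), (u2,), (u2,)]
    labels = [US_ONLY, CS_ONLY, PAIRED, CS_ONLY, PAIRED,
              CS_ONLY, CS_ONLY, CS_ONLY, CS_ONLY, CS_ONLY]
    horizon = starts[-1] + duration + tail
    return _train(
        list(zip(starts, chans)), duration, _per_channel(amplitude, (u1, u2)),
        horizon, labels,
    )


def fd_conditioning_protocol(
    *,
    start: float = 26.0,
    duration: float = 2.1,
    amplitude: dict | float = None,
    interval: float = 21.0,
    probe_interval: float = 10.0,
    tail: float = 250.0,
) -> Protocol:
    """Eight-event training schedule for the forced-dissociation circuit.

    Order: US (z) alone; CS (x) alone; two conditioning rounds each followed
    by a CS test; then two rapid CS-alone probes at ``probe_interval`` — the
    forced-dissociation probe, which should drive the learned response back
    to its naive level.

    The default amplitudes sit near the Hill constant (x: 3.2, z: 5 in units
    of K) rather than deep in saturation: the contrast between Hill
    coefficients — what makes a = 2, 3 succeed while a = 1 and a = 4 fail in
    characteristic ways — lives in the graded part of the binding curve.
    ``amplitude`` may be a single level or a per-channel mapping.
    """
    x, z = "x", "z"
    if amplitude is None:
        amplitude = {x: 3.2, z: 5.0}
    starts = [start + i * interval for i in range(6)]
    starts.append(starts[5] + probe_interval)
    starts.append(starts[6] + probe_interval)
    chans = [(z,), (x,), (x, z), (x,), (x, z), (x,), (x,), (x,)]
    labels = [US_ONLY, CS_ONLY, PAIRED, CS_ONLY, PAIRED, CS_ONLY, CS_ONLY, CS_ONLY]
    horizon = starts[-1] + duration + tail
    return _train(
        list(zip(starts, chans)), duration, _per_channel(amplitude, (x, z)),
        horizon, labels,
    )


def fd_no_conditioning_protocol(**kw) -> Protocol:
    """Control schedule: the conditioning z pulses are removed, so events 3
    and 5 become CS-alone and no reinforcement should occur."""
    base = fd_conditioning_protocol(**kw)
    paired_starts = {e.start for e in base.events if e.label == PAIRED}
    pulses = [
        p for p in base.pulses
        if not (p.channel == "z" and p.start in paired_starts)
    ]
    labels = [CS_ONLY if e.label == PAIRED else e.label for e in base.events]
    return Protocol(pulses, base.horizon, labels=labels)
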