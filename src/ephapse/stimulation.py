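"""Stimulus protocols: boxcar impulses and seeded Poisson spike trains.

Every stimulated impulse is a brief, localized boxcar current: amplitude
``I = 2`` applied to one axon (or continuum column) for 2 time units over
the inlet window ``z in [0, 4]`` by default.  Protocols are plain data and
serialize losslessly to JSON so a result archive can echo exactly what
drove the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "ProtocolError",
    "impulse_protocol",
    "poisson_train_protocol",
    "evaluate_stimulus",
]

DEFAULT_DURATION = 2.0
DEFAULT_AMPLITUDE = 2.0
DEFAULT_Z_WINDOW = (0.0, 4.0)
#: minimum inter-onset gap enforced in trains: boxcar duration plus a
#: refractory floor, so consecutive boxcars on one axon never merge
REFRACTORY_FLOOR = 5.0


class ProtocolError(ValueError):
    """Raised for stimulus specifications that cannot be realized."""


@dataclass(frozen=True)
class StimulusEvent:
    """One boxcar current injection.

    ``lateral_index`` is 1-based (axon/column number as in figure labels).
    """

    lateral_index: int
    onset: float
    duration: float = DEFAULT_DURATION
    amplitude: float = DEFAULT_AMPLITUDE
    z_window: tuple = DEFAULT_Z_WINDOW

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ProtocolError(f"duration must be > 0, got {self.duration}")
        if not np.isfinite(self.amplitude):
            raise ProtocolError("amplitude must be finite")
        if self.z_window[1] < self.z_window[0]:
            raise ProtocolError(f"empty z_window {self.z_window}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered list of stimulus events plus provenance."""

    events: tuple
    seed: int | None = None
    generator: str = "manual"

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.events, key=lambda e: (e.onset, e.lateral_index)))
        object.__setattr__(self, "events", ordered)

    @property
    def t_last(self) -> float:
        if not self.events:
            return 0.0
        return max(e.onset + e.duration for e in self.events)

    def to_json(self) -> str:
        payload = {
            "generator": self.generator,
            "seed": self.seed,
            "events": [
                {
                    "lateral_index": e.lateral_index,
                    "onset": e.onset,
                    "duration": e.duration,
                    "amplitude": e.amplitude,
                    "z_window": list(e.z_window),
                }
                for e in self.events
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        payload = json.loads(text)
        events = tuple(
            StimulusEvent(
                lateral_index=e["lateral_index"],
                onset=e["onset"],
                duration=e["duration"],
                amplitude=e["amplitude"],
                z_window=tuple(e["z_window"]),
            )
            for e in payload["events"]
        )
        return cls(events=events, seed=payload.get("seed"),
                   generator=payload.get("generator", "manual"))


def impulse_protocol(pairs, n_lateral: int | None = None) -> StimulusProtocol:
    """Default-shaped impulse per ``(lateral_index, onset)`` pair.

    The two-impulse standard scenario of the sheet model is
    ``impulse_protocol([(30, 0), (20, 10)])``: axons 30 and 20 stimulated
    at t = 0 and t = 10.
    """
    events = []
    for lateral_index, onset in pairs:
        if lateral_index < 1 or (n_lateral is not None and lateral_index > n_lateral):
            raise ProtocolError(
                f"lateral index {lateral_index} outside [1, {n_lateral}]"
            )
        events.append(StimulusEvent(lateral_index=int(lateral_index), onset=float(onset)))
    return StimulusProtocol(events=tuple(events), generator="manual")


def poisson_train_protocol(
    n_lateral: int,
    n_impulses: int = 10,
    mean_interval: float = 10.0,
    seed: int = 0,
    randomize_count: bool = False,
) -> StimulusProtocol:
    """Seeded Poisson spike train on every axon.

    For each of the ``n_lateral`` axons the first onset is drawn uniformly
    in ``[0, mean_interval]`` and the remaining ``n_impulses - 1``
    inter-onset intervals are i.i.d. draws of a dead-time-corrected
    Poisson process: a hard minimum gap (boxcar duration + refractory
    floor, 7 time units at the defaults, so stimuli never merge on one
    axon) plus an exponential with scale ``mean_interval - min_gap``.
    By memorylessness this equals resampling sub-floor exponentials while
    keeping the realized mean interval exactly at ``mean_interval``.
    ``randomize_count=True`` draws the per-axon count from a Poisson
    distribution with mean ``n_impulses`` (at least 1) instead of using
    it verbatim.
    """
    if n_impulses < 1:
        raise ProtocolError(f"n_impulses must be >= 1, got {n_impulses}")
    min_gap = DEFAULT_DURATION + REFRACTORY_FLOOR
    if mean_interval <= min_gap and n_impulses > 1:
        raise ProtocolError(
            f"mean_interval={mean_interval} <= minimum gap {min_gap}; "
            "train cannot be realized"
        )
    rng = np.random.default_rng(seed)
    events = []
    for lateral_index in range(1, n_lateral + 1):
        count = n_impulses
        if randomize_count:
            count = max(1, int(rng.poisson(n_impulses)))
        t = float(rng.uniform(0.0, mean_interval))
        events.append(StimulusEvent(lateral_index=lateral_index, onset=t))
        for _ in range(count - 1):
            t += min_gap + float(rng.exponential(mean_interval - min_gap))
            events.append(StimulusEvent(lateral_index=lateral_index, onset=t))
    return StimulusProtocol(events=tuple(events), seed=int(seed),
                            generator="poisson_train")


def evaluate_stimulus(protocol: StimulusProtocol, t: float, grid) -> np.ndarray:
    """Additive current field I(lateral, z) at time ``t`` on ``grid``.

    Each event contributes its amplitude on the nodes of its axon whose
    axial coordinate lies in ``z_window`` (inclusive), for
    ``t in [onset, onset + duration)``.  Overlapping events sum.
    """
    field_ = np.zeros((grid.n_lateral, grid.n_z))
    z = grid.z_coords
    for e in protocol.events:
        if e.onset <= t < e.onset + e.duration:
            mask = (z >= e.z_window[0]) & (z <= e.z_window[1])
            field_[e.lateral_index - 1, mask] += e.amplitude
    return field_
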