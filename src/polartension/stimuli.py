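"""Stimulus rate fields k_s(x, y, t).

A stimulus enters the Rac equations as an extra GDP→GTP activation rate
k_s·v.  Two spatial forms are used: a *graded* field, linear along one of
the four grid axes and spanning [0, 2R·ks_amp] across the cell, and a
*local random* field, uniform noise U(0,1)·ks_amp on a band of width
``region_fraction·R`` beside the cell-centered axis.  Coordinates are
cell-centered; ``direction`` ∈ {0, 90, 180, 270} degrees selects the
stimulated side (0 = +x pole).  All randomness is drawn from the protocol
seed; random patterns are drawn per grid point at each event onset and
frozen for the event's duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Optional, Sequence

import numpy as np

from .geometry import PhaseFieldGeometry

AXIS_DIRECTIONS = (0, 90, 180, 270)


@dataclass
class StimulusEvent:
    onset: float
    ks_amp: float
    ks_dur: float
    direction: int
    kind: str = "graded"          # "graded" or "local_random"

    @property
    def offset(self) -> float:
        return self.onset + self.ks_dur


@dataclass
class StimulusProtocol:
    """Declarative description of k_s(x, y, t).

    kinds: ``graded``, ``local_random``, ``switching_sequence``,
    ``dual_gradient``, ``none``.  For ``switching_sequence`` supply
    ``schedule``; for ``dual_gradient``, ``ks_amp2`` is the weaker opposite
    stimulus.  ``repeat_until`` re-draws a local_random pattern every
    ``ks_dur`` until that time (sustained sub-threshold noise).
    """

    kind: str = "none"
    ks_amp: float = 0.0
    ks_dur: float = 1.0
    direction: int = 0
    region_fraction: float = 0.25
    seed: int = 0
    R: float = 10.0
    t_on: float = 0.0
    schedule: Optional[list] = None
    ks_amp2: float = 0.0
    repeat_until: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ks_amp < 0 or self.ks_amp2 < 0:
            raise ValueError("stimulus amplitude must be non-negative")
        if self.ks_dur <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.kind in ("graded", "local_random", "dual_gradient") \
                and self.direction not in AXIS_DIRECTIONS:
            raise ValueError(f"direction must be one of {AXIS_DIRECTIONS}")
        if self.kind == "switching_sequence":
            sched = self.schedule or []
            for a, b_ in zip(sched, sched[1:]):
                if b_.onset < a.offset:
                    raise ValueError("overlapping events in schedule")


def _axis_coordinate(geometry: PhaseFieldGeometry, direction: int) -> np.ndarray:
    """Signed cell-centered coordinate increasing toward the stimulated pole."""
    X, Y = geometry.meshgrid()
    return {0: X, 90: Y, 180: -X, 270: -Y}[direction]


def graded_pattern(geometry: PhaseFieldGeometry, ks_amp: float, R: float,
                   direction: int) -> np.ndarray:
    """Static spatial part ks_amp·(R + ξ) on the cell support, ξ ∈ [−R, R]."""
    xi = _axis_coordinate(geometry, direction)
    pat = ks_amp * (R + xi)
    pat[pat < 0] = 0.0
    pat *= geometry.interior_mask()
    return pat


def local_random_pattern(geometry: PhaseFieldGeometry, ks_amp: float, R: float,
                         direction: int, region_fraction: float,
                         rng: np.random.Generator) -> np.ndarray:
    """ks_amp·U(0,1) per grid point on the band 0 ≤ ξ ≤ region_fraction·R."""
    xi = _axis_coordinate(geometry, direction)
    band = (xi >= 0) & (xi <= region_fraction * R) & geometry.interior_mask()
    pat = np.zeros_like(geometry.phi)
    pat[band] = ks_amp * rng.uniform(0.0, 1.0, size=int(band.sum()))
    return pat


def graded_field(protocol: StimulusProtocol, geometry: PhaseFieldGeometry,
                 t: float) -> np.ndarray:
    """Graded stimulus field at time t (zero after the duration elapses)."""
    if protocol.kind != "graded":
        raise ValueError("protocol kind must be 'graded'")
    if protocol.t_on < t <= protocol.t_on + protocol.ks_dur:
        return graded_pattern(geometry, protocol.ks_amp, protocol.R,
                              protocol.direction)
    return np.zeros_like(geometry.phi)


def local_random_field(protocol: StimulusProtocol, geometry: PhaseFieldGeometry,
                       t: float) -> np.ndarray:
    """Local random stimulus field at time t; reproducible under the seed."""
    if protocol.kind != "local_random":
        raise ValueError("protocol kind must be 'local_random'")
    fn = make_ks_function(protocol, geometry)
    out = fn(t)
    return out if isinstance(out, np.ndarray) else np.zeros_like(geometry.phi)


def make_ks_function(protocol: StimulusProtocol, geometry: PhaseFieldGeometry):
    """Compile a protocol into ``ks(t) -> field or 0.0`` with frozen patterns."""
    rng = np.random.default_rng(protocol.seed)
    events: list[tuple[float, float, np.ndarray]] = []   # (onset, offset, pattern)

    if protocol.kind == "none":
        pass
    elif protocol.kind == "graded":
        events.append((protocol.t_on, protocol.t_on + protocol.ks_dur,
                       graded_pattern(geometry, protocol.ks_amp, protocol.R,
                                      protocol.direction)))
    elif protocol.kind == "dual_gradient":
        # two competing stimuli on opposite sides; each gradient is
        # restricted to its own polar cap (ξ > R/4) so the two drives are
        # spatially distinct arcs (their full-field superposition would be
        # one uniform drive plus a weak net gradient)
        opposite = (protocol.direction + 180) % 360
        on, off = protocol.t_on, protocol.t_on + protocol.ks_dur
        for amp, direc in ((protocol.ks_amp, protocol.direction),
                           (protocol.ks_amp2, opposite)):
            if amp <= 0:
                continue
            pat = graded_pattern(geometry, amp, protocol.R, direc)
            pat = pat * (_axis_coordinate(geometry, direc) > protocol.R / 4)
            events.append((on, off, pat))
    elif protocol.kind == "local_random":
        t_stop = protocol.repeat_until
        onset = protocol.t_on
        while True:
            events.append((onset, onset + protocol.ks_dur,
                           local_random_pattern(geometry, protocol.ks_amp,
                                                protocol.R, protocol.direction,
                                                protocol.region_fraction, rng)))
            onset += protocol.ks_dur
            if t_stop is None or onset >= t_stop:
                break
    elif protocol.kind == "switching_sequence":
        for ev in protocol.schedule or []:
            if ev.kind == "graded":
                pat = graded_pattern(geometry, ev.ks_amp, protocol.R,
                                     ev.direction)
            else:
                pat = local_random_pattern(geometry, ev.ks_amp, protocol.R,
                                           ev.direction,
                                           protocol.region_fraction, rng)
            events.append((ev.onset, ev.offset, pat))
    else:
        raise ValueError(f"unknown stimulus kind {protocol.kind!r}")

    def ks(t: float):
        out = None
        for on, off, pat in events:
            if on < t <= off:
                out = pat if out is None else out + pat
        return 0.0 if out is None else out

    return ks


def switching_schedule(seed: int, n_events: int,
                       amp_range: tuple[float, float],
                       dur_range: tuple[float, float],
                       t_start: float = 0.0, gap: float = 25.0,
                       directions: Sequence[int] = AXIS_DIRECTIONS,
                       ) -> list[StimulusEvent]:
    """Random switching schedule: direction uniform on the four axes,
    amplitude and duration uniform on the given ranges, sequential onsets
    separated by ``gap`` seconds of recovery after each event."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if min(amp_range) < 0 or min(dur_range) <= 0:
        raise ValueError("ranges must be positive")
    rng = np.random.default_rng(seed)
    t = t_start
    sched = []
    for _ in range(n_events):
        amp = float(rng.uniform(*amp_range))
        dur = float(rng.uniform(*dur_range))
        direction = int(rng.choice(directions))
        sched.append(StimulusEvent(onset=t, ks_amp=amp, ks_dur=dur,
                                   direction=direction))
        t += dur + gap
    return sched


def count_direction_changes(schedule: Sequence[StimulusEvent],
                            initial_direction: Optional[float] = None) -> int:
    """n_s: events whose direction differs from the previous event's
    (the first event is compared with ``initial_direction`` when given)."""
    n = 0
    prev = initial_direction
    for ev in schedule:
        if prev is not None and not math.isclose(ev.direction % 360, prev % 360):
            n += 1
        prev = ev.direction
    return n
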