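"""Time-dependent extracellular-cAMP stimulus protocols.

A protocol is an ordered list of segments tiling [0, t_end] without gaps or
overlaps; evaluation is right-continuous at segment boundaries.  Segment
kinds: constant holds, instantaneous steps, endpoint-normalized exponential
ramps, and ideal rectangular pulse trains (instantaneous edges, matching
microfluidic switching).

Named presets encode the stimulus designs used throughout the study:
sub-threshold steps, fold-change double steps, slow exponential ramps, and
entrainment pulse trains.  Presets use the convention 1 model time unit (T)
per experimental minute and 1 model concentration unit per nanomolar; both
scales are arguments so other mappings can be configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Segment",
    "StimulusProtocol",
    "build_protocol",
    "evaluate_protocol",
    "constant_protocol",
    "step_protocol",
    "ramp_protocol",
    "pulse_train_protocol",
    "preset",
    "PRESET_NAMES",
]

_KINDS = ("hold", "step_to", "exp_ramp", "pulse_train")


@dataclass(frozen=True)
class Segment:
    """One piece of a stimulus protocol on [t_start, t_end).

    Parameters by kind:
      hold / step_to : level
      exp_ramp       : start, target, tau (exponential time constant;
                       defaults to a quarter of the segment length)
      pulse_train    : amplitude, width, period, count (pulses start at
                       t_start + k*period, k = 0..count-1; value is
                       amplitude on [onset, onset+width), 0 otherwise)
    """

    t_start: float
    t_end: float
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"segment needs t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        p = dict(self.params)
        if self.kind in ("hold", "step_to"):
            if p.get("level", 0.0) < 0:
                raise ValueError("negative concentration in hold/step segment")
        elif self.kind == "exp_ramp":
            if "tau" not in p:
                p["tau"] = (self.t_end - self.t_start) / 4.0
                object.__setattr__(self, "params", p)
            if p["start"] < 0 or p["target"] < 0:
                raise ValueError("negative concentration in exp_ramp segment")
            if p["tau"] <= 0:
                raise ValueError("exp_ramp tau must be > 0")
        elif self.kind == "pulse_train":
            for key in ("amplitude", "width", "period"):
                if p[key] < 0:
                    raise ValueError(f"pulse_train {key} must be >= 0")
            if p["width"] > p["period"]:
                raise ValueError("pulse width must not exceed pulse period")
            if int(p["count"]) < 1:
                raise ValueError("pulse_train count must be >= 1")

    def value(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the segment at times t (array, within [t_start, t_end])."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind in ("hold", "step_to"):
            return np.full_like(t, float(p.get("level", 0.0)))
        if self.kind == "exp_ramp":
            start, target, tau = p["start"], p["target"], p["tau"]
            span = self.t_end - self.t_start
            # normalized so the target is reached exactly at the segment end
            norm = -np.expm1(-span / tau)
            frac = -np.expm1(-(t - self.t_start) / tau) / norm
            # geometric (exponential-growth) interpolation: the ramp climbs
            # the same number of decades per unit time, which is the shape
            # that is "slow" for a fold-change sensor.  A zero start is
            # replaced by the sensor-threshold floor; a zero target falls
            # back to linear interpolation.
            start_eff = max(start, p.get("floor", 1e-5))
            if target > 0 and start_eff > 0:
                return start_eff * (target / start_eff) ** frac
            return start + (target - start) * frac
        # pulse_train
        amp, width, period = p["amplitude"], p["width"], p["period"]
        count = int(p["count"])
        phase = t - self.t_start
        k = np.floor(phase / period)
        in_pulse = (k >= 0) & (k < count) & (phase - k * period < width)
        return np.where(in_pulse, amp, 0.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Validated piecewise extracellular-cAMP concentration vs time."""

    segments: tuple[Segment, ...]

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    def __call__(self, t):
        scalar = np.isscalar(t)
        out = evaluate_protocol(self, np.atleast_1d(np.asarray(t, dtype=float)))
        return float(out[0]) if scalar else out

    def values(self, times: np.ndarray) -> np.ndarray:
        return evaluate_protocol(self, times)

    def pulse_onsets(self) -> np.ndarray:
        """Onset times of every pulse in pulse_train segments."""
        onsets = []
        for seg in self.segments:
            if seg.kind == "pulse_train":
                count = int(seg.params["count"])
                period = seg.params["period"]
                onsets.extend(seg.t_start + k * period for k in range(count))
        return np.asarray(onsets)

    def asdict(self) -> dict:
        return {
            "segments": [
                {"t_start": s.t_start, "t_end": s.t_end, "kind": s.kind,
                 "params": dict(s.params)}
                for s in self.segments
            ]
        }


def build_protocol(spec: Sequence[Segment | dict]) -> StimulusProtocol:
    """Validate a segment list into a protocol.

    Segments must tile [0, t_end] without gaps or overlaps.  Raises
    ValueError naming the offending segment index otherwise.
    """
    if len(spec) == 0:
        raise ValueError("empty protocol specification")
    segs = tuple(
        s if isinstance(s, Segment) else Segment(**s) for s in spec
    )
    if abs(segs[0].t_start) > 1e-12:
        raise ValueError("segment 0 must start at t=0")
    for i in range(1, len(segs)):
        if abs(segs[i].t_start - segs[i - 1].t_end) > 1e-9:
            raise ValueError(
                f"segment {i} starts at {segs[i].t_start}, "
                f"segment {i - 1} ends at {segs[i - 1].t_end}: gap or overlap"
            )
    return StimulusProtocol(segs)


def evaluate_protocol(protocol: StimulusProtocol, t: np.ndarray) -> np.ndarray:
    """Piecewise evaluation, right-continuous at segment boundaries."""
    t = np.asarray(t, dtype=float)
    if t.size and (t.min() < -1e-9 or t.max() > protocol.t_end + 1e-9):
        raise ValueError(
            f"time outside protocol domain [0, {protocol.t_end}]: "
            f"[{t.min()}, {t.max()}]"
        )
    out = np.empty_like(t)
    edges = np.array([s.t_start for s in protocol.segments] + [protocol.t_end])
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                  len(protocol.segments) - 1)
    for i, seg in enumerate(protocol.segments):
        mask = idx == i
        if mask.any():
            out[mask] = seg.value(t[mask])
    return out


# ---------------------------------------------------------------------------
# Convenience constructors


def constant_protocol(level: float, t_end: float) -> StimulusProtocol:
    return build_protocol([Segment(0.0, t_end, "hold", {"level": level})])


def step_protocol(level: float, t_step: float, t_end: float,
                  baseline: float = 0.0) -> StimulusProtocol:
    """Hold at `baseline`, then step to `level` at t_step."""
    segs = []
    if t_step > 0:
        segs.append(Segment(0.0, t_step, "hold", {"level": baseline}))
    segs.append(Segment(t_step, t_end, "step_to", {"level": level}))
    return build_protocol(segs)


def ramp_protocol(target: float, t_ramp_start: float, t_ramp_end: float,
                  t_end: float | None = None, start: float = 0.0,
                  tau: float | None = None) -> StimulusProtocol:
    """Hold at `start`, exponential ramp to `target`, then hold at target."""
    t_end = t_ramp_end if t_end is None else t_end
    segs = []
    if t_ramp_start > 0:
        segs.append(Segment(0.0, t_ramp_start, "hold", {"level": start}))
    ramp = {"start": start, "target": target}
    if tau is not None:
        ramp["tau"] = tau
    segs.append(Segment(t_ramp_start, t_ramp_end, "exp_ramp", ramp))
    if t_end > t_ramp_end:
        segs.append(Segment(t_ramp_end, t_end, "hold", {"level": target}))
    return build_protocol(segs)


def pulse_train_protocol(amplitude: float, width: float, period: float,
                         count: int, t_first: float = 0.0,
                         t_end: float | None = None) -> StimulusProtocol:
    """Rectangular pulse train; pulses start at t_first + k*period."""
    train_end = t_first + count * period
    t_end = train_end if t_end is None else t_end
    segs = []
    if t_first > 0:
        segs.append(Segment(0.0, t_first, "hold", {"level": 0.0}))
    segs.append(Segment(t_first, train_end, "pulse_train",
                        {"amplitude": amplitude, "width": width,
                         "period": period, "count": count}))
    if t_end > train_end:
        segs.append(Segment(train_end, t_end, "hold", {"level": 0.0}))
    return build_protocol(segs)


# ---------------------------------------------------------------------------
# Named presets

#: raw model time units per experimental minute.  The study's time unit "T"
#: is the single cell's minimum oscillation period (~28.9 raw units for the
#: default parameters; recompute via metrics.calibrate_units); one T
#: corresponds to one experimental minute.
TIME_UNITS_PER_MIN = 28.9


def preset(name: str, t_end: float = 60.0,
           time_units_per_min: float = TIME_UNITS_PER_MIN,
           nM_per_unit: float = 1.0) -> StimulusProtocol:
    """Named stimulus presets used by the in-silico experiment suites.

    Times are in experimental minutes (t_end included), converted at
    `time_units_per_min` raw model units per minute; concentrations in nM.

    step-<c>nM        : hold 0 for 5 min then step to c nM
    foldchange-1-2nM  : 1 nM step at 5 min, doubled to 2 nM at 30 min
    foldchange-5-10nM : 5 nM step at 5 min, doubled to 10 nM at 30 min
    ramp-1nM          : slow exponential ramp to 1 nM over 5-65 min
    ramp-300nM        : 3 nM pre-step (25-40 min) then exponential ramp to
                        300 nM over the 40-100 min window
    pulses-<w>min-<p>min : 10 nM pulses of width w with period p, from 5 min
    """
    m = time_units_per_min   # model time units per experimental minute
    c = 1.0 / nM_per_unit    # model concentration units per nM

    if name.startswith("step-") and name.endswith("nM"):
        level = float(name[len("step-"):-2])
        return step_protocol(level * c, 5.0 * m, t_end * m)
    if name == "foldchange-1-2nM":
        return build_protocol([
            Segment(0.0, 5.0 * m, "hold", {"level": 0.0}),
            Segment(5.0 * m, 30.0 * m, "step_to", {"level": 1.0 * c}),
            Segment(30.0 * m, t_end * m, "step_to", {"level": 2.0 * c}),
        ])
    if name == "foldchange-5-10nM":
        return build_protocol([
            Segment(0.0, 5.0 * m, "hold", {"level": 0.0}),
            Segment(5.0 * m, 30.0 * m, "step_to", {"level": 5.0 * c}),
            Segment(30.0 * m, t_end * m, "step_to", {"level": 10.0 * c}),
        ])
    if name == "ramp-1nM":
        return ramp_protocol(1.0 * c, 5.0 * m, 65.0 * m,
                             t_end=max(t_end, 65.0) * m, tau=15.0 * m)
    if name == "ramp-300nM":
        return build_protocol([
            Segment(0.0, 25.0 * m, "hold", {"level": 0.0}),
            Segment(25.0 * m, 40.0 * m, "step_to", {"level": 3.0 * c}),
            Segment(40.0 * m, 100.0 * m, "exp_ramp",
                    {"start": 3.0 * c, "target": 300.0 * c, "tau": 15.0 * m}),
            Segment(100.0 * m, max(t_end, 100.0) * m, "hold",
                    {"level": 300.0 * c}),
        ])
    if name.startswith("pulses-"):
        parts = name[len("pulses-"):].split("-")
        width = float(parts[0][:-3])
        period = float(parts[1][:-3])
        count = int((t_end - 5.0) // period)
        return pulse_train_protocol(10.0 * c, width * m, period * m, count,
                                    t_first=5.0 * m, t_end=t_end * m)
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "step-1nM", "step-10nM", "step-100nM", "step-1000nM", "step-10000nM",
    "foldchange-1-2nM", "foldchange-5-10nM",
    "ramp-1nM", "ramp-300nM",
    "pulses-1min-6min", "pulses-5min-6min",
)
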