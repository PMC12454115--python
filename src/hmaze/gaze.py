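"""Rule-based gaze classification for maze decisions, plus a schematic
synthetic gaze generator.

A *hierarchical saccade* is an early left/right commitment of gaze: the
x-position leaves a 2-dva window around fixation before the third auditory
cue while staying inside a 10-dva region of interest in both axes.  A
*switch* (counterfactual eye movement) is a post-third-cue crossing of gaze
to the opposite side beyond the same 2-dva bound, within the same region of
interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from hmaze.strategies import Decision

__all__ = ["GazeTrace", "preprocess", "classify_hierarchical_saccade",
           "detect_switch", "synth_gaze"]

SACCADE_BOUND = 2.0   # dva from fixation that counts as a commitment
ROI_BOUND = 10.0      # dva region-of-interest half-width (both axes)
MEDIAN_FILTER_S = 0.025  # artefact-removal median filter window


@dataclass
class GazeTrace:
    """Gaze samples (dva, fixation at the origin) with auditory cue times."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cue_times: tuple[float, float, float]
    rate: float = 1000.0

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.t.size == 0:
            raise ValueError("empty gaze trace")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (self.t[0] <= self.cue_times[0] and
                self.cue_times[2] <= self.t[-1]):
            raise ValueError("cue times must lie within the trace span")


def preprocess(trace: GazeTrace) -> GazeTrace:
    """Median-filter x and y to remove high-frequency artefacts (25 ms window)."""
    k = int(round(MEDIAN_FILTER_S * trace.rate))
    k = max(k + (1 - k % 2), 1)  # odd kernel
    if k < 3 or k >= trace.t.size:
        return trace
    return GazeTrace(trace.t, medfilt(trace.x, k), medfilt(trace.y, k),
                     trace.cue_times, trace.rate)


def _qualifying(trace: GazeTrace) -> np.ndarray:
    """Samples beyond the saccade bound and inside the region of interest."""
    return ((np.abs(trace.x) > SACCADE_BOUND) &
            (np.abs(trace.x) <= ROI_BOUND) &
            (np.abs(trace.y) <= ROI_BOUND))


def classify_hierarchical_saccade(trace: GazeTrace,
                                  filter_trace: bool = True) -> str:
    """Side ('left'/'right') of the first pre-third-cue gaze commitment,
    or 'none' when no sample qualifies.

    The earliest sample with |x| > 2 dva inside the 10-dva region of
    interest, before the third cue, defines the saccade side by its sign
    (negative x = left).
    """
    if filter_trace:
        trace = preprocess(trace)
    pre = trace.t < trace.cue_times[2]
    ok = _qualifying(trace) & pre
    if not ok.any():
        return "none"
    first = np.flatnonzero(ok)[0]
    return "left" if trace.x[first] < 0 else "right"


def detect_switch(trace: GazeTrace, cue3_time: float | None = None,
                  filter_trace: bool = True) -> bool:
    """True when gaze crosses to the side opposite the hierarchical saccade
    after the third cue, beyond the 2-dva bound and inside the region of
    interest.  False when no pre-cue-3 saccade side was assigned.
    """
    side = classify_hierarchical_saccade(trace, filter_trace)
    if side == "none":
        return False
    if filter_trace:
        trace = preprocess(trace)
    cue3 = trace.cue_times[2] if cue3_time is None else cue3_time
    post = trace.t >= cue3
    ok = _qualifying(trace) & post
    if side == "left":
        return bool(np.any(ok & (trace.x > SACCADE_BOUND)))
    return bool(np.any(ok & (trace.x < -SACCADE_BOUND)))


def synth_gaze(
    decision: Decision,
    rng: np.random.Generator,
    noise_sd: float = 0.3,
    rate: float = 250.0,
    saccade_x: float = 5.0,
    latency: float = 0.15,
) -> GazeTrace:
    """Schematic gaze trace consistent with a maze decision.

    The trace fixates at the origin, saccades to the first-choice side
    shortly after the second cue and, if the decision was revised, jumps to
    the opposite side after the third cue.  Gaussian sample noise with sd
    ``noise_sd`` dva is added throughout.
    """
    cue_times = (0.5, 1.0, 1.6)
    t_end = 2.4
    t = np.arange(0.0, t_end, 1.0 / rate)
    x = np.zeros_like(t)
    first_sign = -1.0 if decision.first_choice == "L" else 1.0
    x[t >= cue_times[1] + latency] = first_sign * saccade_x
    if decision.revised:
        x[t >= cue_times[2] + latency] = -first_sign * saccade_x
    y = np.zeros_like(t)
    x = x + noise_sd * rng.standard_normal(t.shape)
    y = y + noise_sd * rng.standard_normal(t.shape)
    return GazeTrace(t, x, y, cue_times, rate)
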