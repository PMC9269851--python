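"""Initial-contact detection, side labelling, cycle splitting and
time normalization of the anterior-posterior acceleration.

At the lower back, each initial contact produces a positive AP peak, so
contacts are detected as AP peaks above an adaptive (median + k*MAD)
threshold, gated by the dominant step period from the AP power spectrum.
Sides are attributed from the sign of the mediolateral acceleration around
each contact (the trunk sways toward the stance limb), with alternation
enforced.  A gait cycle (stride) runs from one contact to the next
ipsilateral contact; each cycle's AP profile is linearly resampled onto a
fixed percent-of-cycle grid and averaged per side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)


class NoGaitError(ValueError):
    """No dominant gait periodicity found in the AP signal."""


class SidesIndeterminateError(ValueError):
    """Mediolateral signal too weak to attribute contact sides."""


class SegmentationError(ValueError):
    pass


@dataclass
class GaitEvent:
    sample_index: int
    time: float  # s
    side: str | None = None  # 'left' | 'right' | None


@dataclass
class GaitCycle:
    side: str
    start_index: int
    end_index: int  # half-open [start, end)
    duration: float  # s


@dataclass
class NormalizedCycle:
    side: str
    waveform: np.ndarray  # P values over 0..100% of the cycle


@dataclass
class SideMeanWaveform:
    side: str
    waveform: np.ndarray
    n_cycles: int


def dominant_step_period(ap: np.ndarray, fs: float,
                         band: tuple = (0.5, 4.0),
                         prominence_floor: float = 5.0) -> float:
    """Dominant step period (s) from the AP power spectrum.

    Raises :class:`NoGaitError` when the strongest in-band spectral line is
    not at least ``prominence_floor`` times the median in-band power.
    """
    ap = np.asarray(ap, float)
    if ap.std() == 0:
        raise NoGaitError("constant AP signal: no gait detected")
    # Welch averaging: segment-averaged spectra keep genuine spectral lines
    # far above the floor while flattening broadband noise, whose raw
    # periodogram maxima would otherwise exceed any median-relative floor.
    nperseg = min(len(ap), int(round(4 * fs)))
    freqs, pxx = signal.welch(ap - ap.mean(), fs=fs, nperseg=nperseg)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise NoGaitError("signal too short to resolve the gait band")
    f_band, p_band = freqs[sel], pxx[sel]
    med = np.median(p_band)
    peak_idx = int(np.argmax(p_band))
    if med <= 0 or p_band[peak_idx] < prominence_floor * med:
        raise NoGaitError("no dominant periodicity in the gait band: no gait detected")
    return 1.0 / float(f_band[peak_idx])


def detect_initial_contacts(ap: np.ndarray, v: np.ndarray | None, fs: float,
                            k_mad: float = 1.5,
                            min_separation_frac: float = 0.35,
                            prominence_floor: float = 5.0) -> list[GaitEvent]:
    """Detect initial contacts as positive AP peaks (sides unset).

    Threshold = median + ``k_mad`` * MAD of the AP series; peaks closer than
    ``min_separation_frac`` of the dominant step period are suppressed.
    ``v`` is accepted for interface symmetry with the earth-frame trace and
    reserved for cross-validation of the detector; it is not used here.
    """
    ap = np.asarray(ap, float)
    if len(ap) < 2 * fs:
        raise NoGaitError("need at least 2 s of signal for contact detection")
    period = dominant_step_period(ap, fs, prominence_floor=prominence_floor)
    med = float(np.median(ap))
    mad = float(np.median(np.abs(ap - med)))
    height = med + k_mad * mad
    distance = max(1, int(round(min_separation_frac * period * fs)))
    idx, _props = signal.find_peaks(ap, height=height, distance=distance)
    if len(idx) == 0:
        raise NoGaitError("no contacts above the adaptive threshold")
    return [GaitEvent(int(i), float(i / fs)) for i in idx]


def label_sides(events: list[GaitEvent], ml: np.ndarray, fs: float,
                window_s: float = 0.05, positive_is_right: bool = True,
                ml_floor: float = 0.01) -> list[GaitEvent]:
    """Attribute a side to each contact from the local mediolateral sway.

    Evidence per contact is the mean ML acceleration in a +-``window_s``
    window around it (positive = right under the default convention).
    Contacts must strictly alternate, so the two candidate alternating
    assignments are scored by their total signed evidence and the better
    one is kept.
    """
    if len(events) < 2:
        raise SegmentationError("need at least 2 events to label sides")
    ml = np.asarray(ml, float)
    half = max(1, int(round(window_s * fs)))
    means = np.empty(len(events))
    for i, ev in enumerate(events):
        lo = max(0, ev.sample_index - half)
        hi = min(len(ml), ev.sample_index + half + 1)
        means[i] = ml[lo:hi].mean()
    if np.all(np.abs(means) < ml_floor):
        raise SidesIndeterminateError(
            "mean ML acceleration near zero at every contact; sides indeterminate")
    sign_right = 1.0 if positive_is_right else -1.0
    # Contacts must strictly alternate, so only two assignments are possible
    # (starting right or starting left); pick the one with the larger total
    # signed ML evidence.
    parity = np.where(np.arange(len(events)) % 2 == 0, 1.0, -1.0)
    score_right_first = float(np.sum(parity * means * sign_right))
    first = "right" if score_right_first >= 0 else "left"
    second = "left" if first == "right" else "right"
    labels = np.where(parity > 0, first, second).astype(object)
    out = []
    for ev, side in zip(events, labels):
        out.append(GaitEvent(ev.sample_index, ev.time, str(side)))
    return out


def trim_edge_events(events: list[GaitEvent], n_trim: int = 1) -> list[GaitEvent]:
    """Drop the first and last ``n_trim`` contacts.

    Gait initiation and termination strides are not steady-state walking
    (and carry filter edge transients), so the boundary contacts are removed
    before cycles are formed.
    """
    if n_trim <= 0:
        return list(events)
    if len(events) <= 2 * n_trim:
        raise SegmentationError("too few events left after edge trimming")
    return list(events[n_trim:len(events) - n_trim])


def split_cycles(events: list[GaitEvent], fs: float,
                 duration_gate: tuple = (0.6, 2.5)) -> list[GaitCycle]:
    """One cycle per contact, to the next ipsilateral contact.

    Cycles outside the duration gate (missed or spurious contacts) are
    dropped with a logged reason.
    """
    if len(events) < 3:
        raise SegmentationError("need at least 3 events to form cycles")
    if any(ev.side not in ("left", "right") for ev in events):
        raise SegmentationError("events must be side-labelled before splitting")
    cycles: list[GaitCycle] = []
    by_side: dict[str, list[GaitEvent]] = {"left": [], "right": []}
    for ev in events:
        by_side[ev.side].append(ev)
    dropped = 0
    for side, evs in by_side.items():
        for a, b in zip(evs[:-1], evs[1:]):
            duration = (b.sample_index - a.sample_index) / fs
            if not (duration_gate[0] <= duration <= duration_gate[1]):
                dropped += 1
                log.info("dropped %s cycle at sample %d: duration %.3f s outside gate %s",
                         side, a.sample_index, duration, duration_gate)
                continue
            cycles.append(GaitCycle(side, a.sample_index, b.sample_index, duration))
    cycles.sort(key=lambda c: c.start_index)
    n_left = sum(c.side == "left" for c in cycles)
    n_right = len(cycles) - n_left
    if n_left < 1 or n_right < 1:
        raise SegmentationError(
            f"fewer than one valid cycle per side (left={n_left}, right={n_right}, "
            f"dropped={dropped})")
    return cycles


def time_normalize(ap: np.ndarray, cycle: GaitCycle, n_points: int = 101) -> NormalizedCycle:
    """Linearly resample one cycle's AP samples onto a percent-of-cycle grid.

    The grid spans the cycle's samples (first point = the value at the
    contact), so a cycle of exactly ``n_points`` samples is returned
    unchanged.
    """
    ap = np.asarray(ap, float)
    if cycle.start_index < 0 or cycle.end_index > len(ap):
        raise SegmentationError("cycle out of signal bounds")
    seg = ap[cycle.start_index:cycle.end_index]
    if len(seg) < 4:
        raise SegmentationError("cycle too short to resample (need >= 4 samples)")
    grid = np.linspace(0.0, len(seg) - 1.0, n_points)
    wave = np.interp(grid, np.arange(len(seg)), seg)
    return NormalizedCycle(cycle.side, wave)


def mean_waveform(cycles: list[NormalizedCycle], side: str,
                  min_cycles: int = 5) -> SideMeanWaveform:
    """Pointwise mean of a side's normalized cycles.

    Logs a warning when the trial contributed fewer than ``min_cycles``
    cycles in total (quality flag, not an error).
    """
    own = [c for c in cycles if c.side == side]
    if not own:
        raise SegmentationError(f"no {side} cycles to average")
    if len(cycles) < min_cycles:
        log.warning("only %d cycles in trial (< %d): quality flag", len(cycles), min_cycles)
    waves = np.stack([c.waveform for c in own])
    return SideMeanWaveform(side, waves.mean(axis=0), len(own))
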