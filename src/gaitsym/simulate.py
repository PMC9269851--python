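"""Synthetic lumbar-accelerometer gait signals with known ground truth.

No public dataset of raw trunk accelerations across the 6-84 year age range
exists, so every downstream stage of the package is exercised against a
generator whose events, waveforms and asymmetry are known exactly.

The signal model is a harmonic series locked to the stride: each *step*
(initial contact to contralateral initial contact) carries an
anterior-posterior (AP) template built from cosine-phased harmonics so that
its global maximum sits exactly at the contact, the mediolateral (ML)
component is a stride-frequency sinusoid whose sign at contact encodes the
side, and the vertical (V) component is dominated by twice the stride
frequency (one oscillation per step).  Left/right asymmetry is injected
through a smooth within-step envelope ``1 + side * alpha * sin^2(pi * tau)``
(amplitude mode) and/or a smooth within-step time warp (phase mode); both
vanish at the contacts, so the synthetic signal stays continuous and the
contact peaks remain unbiased landmarks for event detection.

Gravity under a static sensor tilt, per-step harmonic-amplitude jitter
(stride-to-stride waveform variability), stride-time jitter and white sensor
noise complete the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .preprocess import RawTrace

G = 9.81

CONDITIONS = ("Slow", "Comfortable", "Fast")

#: stride frequencies (Hz) and walking speeds (m/s) per condition, chosen to
#: sit in the range reported for 10 m overground walking at self-selected
#: slow/comfortable/fast paces.
CONDITION_STRIDE_HZ = {"Slow": 0.75, "Comfortable": 0.9, "Fast": 1.05}
CONDITION_SPEED_MPS = {"Slow": 0.8, "Comfortable": 1.15, "Fast": 1.55}

#: default harmonics per axis as (order, amplitude m/s^2, phase rad).
#: Orders are integer multiples of the stride frequency.  AP uses even orders
#: (step-periodic) with cosine phase so the template peaks at each contact;
#: V is dominated by order 2 (one burst per step); ML is the stride-frequency
#: side-to-side sway, phased so ML < 0 at left contacts.
DEFAULT_HARMONICS = {
    "ap": [(2, 1.0, math.pi / 2), (4, 0.5, math.pi / 2), (6, 0.2, math.pi / 2)],
    "ml": [(1, 0.8, -math.pi / 2)],
    "v": [(2, 1.5, math.pi / 2)],
}


class SimulationError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of one simulated walking trial."""

    stride_frequency: float = 0.9  # Hz
    n_strides: int = 8
    harmonics: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_HARMONICS.items()})
    asymmetry_alpha: float = 0.0  # dimensionless, in [0, 1]
    asymmetry_mode: str = "amplitude"  # amplitude | phase | both
    stride_jitter_cv: float = 0.0  # CV of stride time
    harmonic_jitter_sd: float = 0.0  # per-step, per-harmonic amplitude CV
    tilt_pitch: float = 0.0  # rad
    tilt_roll: float = 0.0  # rad
    noise_sd: float = 0.0  # m/s^2, white, per axis
    fs: float = 100.0  # Hz
    g: float = G
    walk_speed: float = 1.15  # m/s, the trial's true mean speed
    pad_s: float = 1.5  # quiet standing before/after the walk

    def validate(self) -> None:
        if not (0.0 <= self.asymmetry_alpha <= 1.0):
            raise SimulationError(f"asymmetry_alpha must be in [0, 1], got {self.asymmetry_alpha}")
        if self.asymmetry_mode not in ("amplitude", "phase", "both"):
            raise SimulationError(f"unknown asymmetry_mode {self.asymmetry_mode!r}")
        if self.stride_jitter_cv < 0 or self.harmonic_jitter_sd < 0 or self.noise_sd < 0:
            raise SimulationError("jitter and noise parameters must be non-negative")
        if self.fs <= 0:
            raise SimulationError("fs must be positive")
        if self.n_strides < 1:
            raise SimulationError("n_strides must be >= 1")
        if self.stride_frequency <= 0 or self.walk_speed <= 0:
            raise SimulationError("stride_frequency and walk_speed must be positive")
        for name in ("stride_frequency", "asymmetry_alpha", "stride_jitter_cv",
                     "harmonic_jitter_sd", "tilt_pitch", "tilt_roll", "noise_sd",
                     "fs", "walk_speed"):
            if not np.isfinite(getattr(self, name)):
                raise SimulationError(f"{name} must be finite")
        if abs(self.tilt_pitch) >= math.pi / 2 or abs(self.tilt_roll) >= math.pi / 2:
            raise SimulationError("tilt angles must satisfy |angle| < pi/2")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    ic_times: dict  # side -> ordered contact times (s)
    step_templates: dict  # side -> noiseless AP step waveform (101 points)
    cycle_templates: dict  # side -> noiseless AP full-cycle waveform (101 points)
    true_mean_speed: float  # m/s
    stride_durations: np.ndarray  # s, one per stride


# ---------------------------------------------------------------------------
# analytic templates
# ---------------------------------------------------------------------------

def _step_phase_warp(tau: np.ndarray, alpha: float, mode: str, side_sign: float) -> np.ndarray:
    """Within-step time warp implementing the phase asymmetry mode.

    The warp shifts the fundamental by at most ``alpha * pi / 8`` radians at
    mid-step and vanishes at the contacts, keeping the signal continuous.
    """
    if mode in ("phase", "both") and alpha > 0:
        return tau + side_sign * (alpha / 16.0) * np.sin(np.pi * tau) ** 2
    return tau


def _amp_envelope(tau: np.ndarray, alpha: float, mode: str, side_sign: float) -> np.ndarray:
    if mode in ("amplitude", "both") and alpha > 0:
        return 1.0 + side_sign * alpha * np.sin(np.pi * tau) ** 2
    return np.ones_like(tau)


def ap_step_template(params: GaitSimParams, side: str, tau: np.ndarray,
                     amp_scale: np.ndarray | None = None) -> np.ndarray:
    """Noiseless AP waveform of one step of the given side at phases ``tau``.

    ``tau`` runs from 0 (this side's contact) to 1 (the contralateral
    contact).  ``amp_scale`` optionally scales each harmonic's amplitude
    (used for stride-to-stride variability).
    """
    side_sign = 1.0 if side == "left" else -1.0
    alpha, mode = params.asymmetry_alpha, params.asymmetry_mode
    tau_w = _step_phase_warp(np.asarray(tau, float), alpha, mode, side_sign)
    env = _amp_envelope(np.asarray(tau, float), alpha, mode, side_sign)
    out = np.zeros_like(tau_w)
    for i, (order, amp, phase) in enumerate(params.harmonics["ap"]):
        a = amp if amp_scale is None else amp * amp_scale[i]
        # AP orders are stride multiples; tau is step phase = stride/2.
        out += a * np.sin(2 * np.pi * order * tau_w / 2.0 + phase)
    return out * env


def cycle_template(params: GaitSimParams, side: str, n_points: int = 101,
                   tau_max: float = 1.0) -> np.ndarray:
    """Noiseless AP waveform of one full gait cycle (stride) of ``side``.

    The cycle runs from this side's contact to the next ipsilateral contact
    and therefore concatenates an ipsilateral and a contralateral step.
    ``tau_max`` < 1 reproduces a grid that stops short of the next contact.
    """
    tau_c = np.linspace(0.0, tau_max, n_points)
    other = "right" if side == "left" else "left"
    first = tau_c < 0.5
    tau_step = np.where(first, 2 * tau_c, 2 * tau_c - 1.0)
    tau_step = np.mod(tau_step, 1.0 + 1e-15)
    out = np.empty_like(tau_c)
    out[first] = ap_step_template(params, side, tau_step[first])
    out[~first] = ap_step_template(params, other, tau_step[~first])
    return out


def _harmonic_signal(harmonics, tau_stride: np.ndarray) -> np.ndarray:
    out = np.zeros_like(tau_stride)
    for order, amp, phase in harmonics:
        out += amp * np.sin(2 * np.pi * order * tau_stride + phase)
    return out


def _tilt_rotation(pitch: float, roll: float) -> np.ndarray:
    """Rotation matrix sensor->earth, R = Ry(pitch) @ Rx(roll)."""
    cp, sp = math.cos(pitch), math.sin(pitch)
    cr, sr = math.cos(roll), math.sin(roll)
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    return ry @ rx


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

def simulate_trace(params: GaitSimParams, seed: int) -> tuple[RawTrace, GroundTruth]:
    """Simulate one sensor-frame trial and its ground truth.

    The trace is ``rotate(gravity + gait signal) + noise``: quiet-standing
    pads, a faded half-step lead-in, ``n_strides`` steady strides whose
    contacts populate the ground truth, and a faded half-step lead-out.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fs, n = params.fs, params.n_strides
    mean_stride = 1.0 / params.stride_frequency

    if params.stride_jitter_cv > 0:
        strides = mean_stride * rng.normal(1.0, params.stride_jitter_cv, size=n)
        strides = np.clip(strides, 0.3 * mean_stride, 3.0 * mean_stride)
    else:
        strides = np.full(n, mean_stride)

    left_ics = np.concatenate([[0.0], np.cumsum(strides)[:-1]])
    right_ics = left_ics + strides / 2.0

    # step boundaries: faded lead-in (virtual right step), the 2n real steps,
    # faded lead-out (virtual right step).
    lead_in = strides[0] / 2.0
    boundaries = [-lead_in]
    for k in range(n):
        boundaries += [left_ics[k], right_ics[k]]
    boundaries.append(left_ics[-1] + strides[-1])  # virtual terminal left contact
    boundaries = np.asarray(boundaries)
    step_sides = ["right"] + ["left", "right"] * n  # lead-in, then L/R per stride

    t_walk0 = boundaries[0]
    t_walk1 = boundaries[-1]
    t0 = t_walk0 - params.pad_s
    t1 = t_walk1 + params.pad_s
    n_samples = int(round((t1 - t0) * fs)) + 1
    # sample grid aligned so that t = 0 (first left contact) is on a sample
    t = t0 + np.arange(n_samples) / fs
    offset = -t[np.argmin(np.abs(t))]
    t = t + offset  # exact sample at t = 0

    ap = np.zeros(n_samples)
    ml = np.zeros(n_samples)
    v = np.zeros(n_samples)

    n_h = len(params.harmonics["ap"])

    for k in range(len(boundaries) - 1):
        a, b = boundaries[k], boundaries[k + 1]
        side = step_sides[k]
        sel = (t >= a - 1e-12) & (t < b - 1e-12)
        if not np.any(sel):
            continue
        tau = (t[sel] - a) / (b - a)
        if params.harmonic_jitter_sd > 0:
            amp_scale = 1.0 + rng.normal(0.0, params.harmonic_jitter_sd, size=n_h)
        else:
            amp_scale = None
        ap[sel] = ap_step_template(params, side, tau, amp_scale=amp_scale)
        # stride phase for ML/V: left steps are the first half of a stride
        tau_stride = tau / 2.0 if side == "left" else 0.5 + tau / 2.0
        ml[sel] = _harmonic_signal(params.harmonics["ml"], tau_stride)
        v[sel] = _harmonic_signal(params.harmonics["v"], tau_stride)
        if k == 0:  # lead-in fade 0 -> 1
            env = np.sin(0.5 * np.pi * tau) ** 2
            ap[sel] *= env; ml[sel] *= env; v[sel] *= env
        elif k == len(boundaries) - 2:  # lead-out fade 1 -> 0
            env = np.cos(0.5 * np.pi * tau) ** 2
            ap[sel] *= env; ml[sel] *= env; v[sel] *= env

    earth = np.column_stack([ap, ml, v + params.g])
    rot = _tilt_rotation(params.tilt_pitch, params.tilt_roll)
    sensor = earth @ rot  # row-wise R^T @ e
    if params.noise_sd > 0:
        sensor = sensor + rng.normal(0.0, params.noise_sd, size=sensor.shape)

    tau101 = np.linspace(0.0, 1.0, 101)
    gt = GroundTruth(
        ic_times={"left": left_ics - t[0], "right": right_ics - t[0]},
        step_templates={s: ap_step_template(params, s, tau101) for s in ("left", "right")},
        cycle_templates={s: cycle_template(params, s, 101) for s in ("left", "right")},
        true_mean_speed=params.walk_speed,
        stride_durations=strides,
    )
    return RawTrace(fs=fs, data=sensor), gt


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

#: group label -> (age range, n, n males, weight mean/sd kg, height mean/sd cm)
GROUP_TABLE = {
    "Children":     ((6, 12),  19,  9, (37.5, 12.3),  (140.8, 11.4)),
    "Teenagers":    ((13, 18), 20, 10, (62.3, 10.1),  (167.5, 9.9)),
    "Young Adults": ((19, 35), 20, 10, (67.3, 13.1),  (169.0, 10.6)),
    "Adults":       ((36, 50), 20, 10, (68.1, 10.7),  (166.2, 8.9)),
    "Middle-Aged":  ((51, 60), 20, 10, (70.0, 12.67), (167.3, 9.1)),
    "Senior":       ((61, 70), 20, 10, (76.5, 13.3),  (164.8, 8.0)),
    "Elderly":      ((71, 84), 18,  9, (69.0, 11.1),  (160.3, 10.7)),
}

GROUPS = tuple(GROUP_TABLE)

#: groups whose symmetry degrades at fast speed (the age-dependent pattern
#: the cohort design emulates: stable young/mid adults, reduced symmetry at
#: fast pace during maturation and ageing).
FAST_AFFECTED_GROUPS = ("Children", "Teenagers", "Middle-Aged", "Senior", "Elderly")

#: baseline asymmetry per group and the fast-condition increment for affected
#: groups.  Calibrated once so that simulated group-mean SI spans ~93-98
#: (see docs/methods.md).
BASE_ALPHA = {
    "Children": 0.30, "Teenagers": 0.15, "Young Adults": 0.20, "Adults": 0.22,
    "Middle-Aged": 0.25, "Senior": 0.28, "Elderly": 0.32,
}
FAST_ALPHA_INCREMENT = 0.28


def paper_asymmetry_profile(group: str, condition: str) -> float:
    alpha = BASE_ALPHA[group]
    if condition == "Fast" and group in FAST_AFFECTED_GROUPS:
        alpha += FAST_ALPHA_INCREMENT
    return alpha


def null_asymmetry_profile(group: str, condition: str) -> float:
    """Constant asymmetry everywhere: the global-null cohort."""
    return 0.25


@dataclass(frozen=True)
class CohortDesign:
    """Study design: 7 age groups x 3 speed conditions x 3 trials of 10 m."""

    groups: dict = field(default_factory=lambda: dict(GROUP_TABLE))
    conditions: tuple = CONDITIONS
    trials_per_condition: int = 3
    path_m: float = 10.0
    asymmetry_profile: object = paper_asymmetry_profile  # (group, condition) -> alpha
    subject_alpha_sd: float = 0.08  # between-subject spread of alpha
    stride_jitter_cv: float = 0.04
    harmonic_jitter_sd: float = 0.35
    noise_sd: float = 0.3
    speed_cv: float = 0.06  # residual (anthropometry-independent) speed spread
    tilt_sd_deg: float = 5.0  # per-participant static sensor tilt spread

    def validate(self) -> None:
        for label, (_rng, size, males, (wm, wsd), (hm, hsd)) in self.groups.items():
            if size < 1 or not (0 <= males <= size):
                raise SimulationError(f"bad group size for {label}")
            if wsd <= 0 or hsd <= 0:
                raise SimulationError(f"SDs must be > 0 for {label}")

    @property
    def n_participants(self) -> int:
        return sum(size for (_r, size, _m, _w, _h) in self.groups.values())

    def scaled(self, per_group: int) -> "CohortDesign":
        """Same design with ``per_group`` participants per group (for speed)."""
        groups = {
            label: (rng_, per_group, per_group // 2, w, h)
            for label, (rng_, _n, _m, w, h) in self.groups.items()
        }
        return replace(self, groups=groups)


@dataclass
class Participant:
    participant_id: str
    group: str
    age: float
    sex: str
    weight_kg: float
    height_cm: float


@dataclass
class TrialRecord:
    participant_id: str
    group: str
    condition: str
    trial: int
    path_m: float
    duration_s: float
    params: GaitSimParams
    seed: int


def _participant_rng(seed: int, group: str, index: int) -> np.random.Generator:
    """One reproducible stream per participant, independent of insertion order."""
    gid = GROUPS.index(group) if group in GROUPS else hash(group) % 1000
    return np.random.default_rng(np.random.SeedSequence([int(seed), gid, int(index)]))


def _draw_truncnorm(rng, mean, sd, floor):
    lo = max(mean - 3 * sd, floor)
    hi = mean + 3 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_participant(group_label: str, seed: int, index: int = 0,
                         design: CohortDesign | None = None) -> Participant:
    """Draw one participant's anthropometrics for a group.

    Weight and height are truncated normals (+-3 SD, physiologic floors of
    10 kg and 90 cm); age is uniform over the group's range.
    """
    design = design or CohortDesign()
    if group_label not in design.groups:
        raise SimulationError(f"unknown group label {group_label!r}")
    (age_lo, age_hi), size, n_males, (wm, wsd), (hm, hsd) = design.groups[group_label]
    rng = _participant_rng(seed, group_label, index)
    age = float(rng.uniform(age_lo, age_hi))
    weight = _draw_truncnorm(rng, wm, wsd, 10.0) if wsd > 0 else wm
    height = _draw_truncnorm(rng, hm, hsd, 90.0) if hsd > 0 else hm
    sex = "M" if index < n_males else "F"
    short = group_label.replace(" ", "").replace("-", "")[:3].upper()
    return Participant(f"{short}{index:02d}", group_label, age, sex, weight, height)


def _trial_params(design: CohortDesign, p: Participant, condition: str,
                  alpha: float, rng: np.random.Generator) -> GaitSimParams:
    base_speed = CONDITION_SPEED_MPS[condition]
    speed = base_speed * math.sqrt(p.height_cm / 167.0) * float(np.exp(rng.normal(0.0, design.speed_cv)))
    f_stride = CONDITION_STRIDE_HZ[condition] * float(rng.normal(1.0, 0.04))
    stride_len = speed / f_stride
    n_strides = max(6, int(round(design.path_m / stride_len)))
    return GaitSimParams(
        stride_frequency=f_stride,
        n_strides=n_strides,
        asymmetry_alpha=float(np.clip(alpha, 0.0, 1.0)),
        asymmetry_mode="amplitude",
        stride_jitter_cv=design.stride_jitter_cv,
        harmonic_jitter_sd=design.harmonic_jitter_sd,
        tilt_pitch=float(rng.normal(0.0, math.radians(design.tilt_sd_deg))),
        tilt_roll=float(rng.normal(0.0, math.radians(design.tilt_sd_deg))),
        noise_sd=design.noise_sd,
        walk_speed=speed,
    )


def simulate_cohort(design: CohortDesign | None = None, seed: int = 0):
    """Simulate the whole study: participants and trial records.

    Returns ``(participants, trials)``; traces are synthesised lazily from
    each TrialRecord's params/seed via :func:`simulate_trace` so that a full
    cohort does not have to be held in memory.
    """
    design = design or CohortDesign()
    design.validate()
    participants: list[Participant] = []
    trials: list[TrialRecord] = []
    for group in design.groups:
        (_ar, size, _m, _w, _h) = design.groups[group]
        for idx in range(size):
            p = simulate_participant(group, seed, index=idx, design=design)
            participants.append(p)
            rng = _participant_rng(seed, group, idx)
            rng.uniform()  # advance past the anthropometric draws deterministically
            subj_offset = float(rng.normal(0.0, design.subject_alpha_sd))
            for condition in design.conditions:
                alpha = design.asymmetry_profile(group, condition) + subj_offset
                for trial_idx in range(design.trials_per_condition):
                    params = _trial_params(design, p, condition, alpha, rng)
                    duration = design.path_m / params.walk_speed
                    trial_seed = int(rng.integers(0, 2**31 - 1))
                    trials.append(TrialRecord(
                        p.participant_id, group, condition, trial_idx,
                        design.path_m, duration, params, trial_seed))
    return participants, trials


def trial_trace(trial: TrialRecord) -> tuple[RawTrace, GroundTruth]:
    return simulate_trace(trial.params, trial.seed)


# ---------------------------------------------------------------------------
# template-level cohort simulator (fast path for replicate studies)
# ---------------------------------------------------------------------------

def simulate_si_table(design: CohortDesign | None = None, seed: int = 0,
                      n_cycles: int = 6):
    """Cohort table of per-trial SI drawn directly from the generator model.

    Shares the statistical model of :func:`simulate_trace` (analytic cycle
    templates, per-step harmonic-amplitude jitter averaged over ``n_cycles``
    cycles per side) but skips raw-trace synthesis and event detection,
    which makes replicate studies of the cohort statistics tractable.  Returns a long-format DataFrame with one
    row per participant x condition x trial.
    """
    import pandas as pd

    design = design or CohortDesign()
    design.validate()
    rows = []
    tau_c = np.linspace(0.0, 1.0, 101)
    first = tau_c < 0.5
    tau_step = np.mod(np.where(first, 2 * tau_c, 2 * tau_c - 1.0), 1.0 + 1e-15)
    env = np.sin(np.pi * tau_step) ** 2
    base_h = DEFAULT_HARMONICS["ap"]
    # harmonic basis on the cycle grid (step phase, stride orders are even)
    basis = np.stack([amp * np.sin(2 * np.pi * order * tau_step / 2.0 + phase)
                      for order, amp, phase in base_h])  # (n_h, 101)
    n_h = basis.shape[0]
    sign_first = np.where(first, 1.0, -1.0)  # modulation sign of the cycle's own side

    for group in design.groups:
        (_ar, size, _m, _w, _h) = design.groups[group]
        for idx in range(size):
            p = simulate_participant(group, seed, index=idx, design=design)
            rng = _participant_rng(seed, group, idx)
            rng.uniform()
            subj_offset = float(rng.normal(0.0, design.subject_alpha_sd))
            for condition in design.conditions:
                alpha = float(np.clip(
                    design.asymmetry_profile(group, condition) + subj_offset, 0.0, 1.0))
                for trial_idx in range(design.trials_per_condition):
                    speed = (CONDITION_SPEED_MPS[condition]
                             * math.sqrt(p.height_cm / 167.0)
                             * float(np.exp(rng.normal(0.0, design.speed_cv))))
                    waves = {}
                    for side_sign, side in ((1.0, "left"), (-1.0, "right")):
                        mod = 1.0 + side_sign * alpha * env * sign_first
                        scale = 1.0 + rng.normal(
                            0.0, design.harmonic_jitter_sd / math.sqrt(n_cycles),
                            size=(n_h, 1))
                        waves[side] = ((scale * basis).sum(axis=0)) * mod
                    l = waves["left"] - waves["left"].mean()
                    r = waves["right"] - waves["right"].mean()
                    denom = math.sqrt(float(l @ l) * float(r @ r))
                    r_lr = float(l @ r) / denom
                    rows.append({
                        "participant_id": p.participant_id, "group": group,
                        "condition": condition, "trial": trial_idx,
                        "age": p.age, "weight_kg": p.weight_kg, "height_cm": p.height_cm,
                        "si": (r_lr + 1.0) * 50.0,
                        "observed_speed": speed,
                    })
    return pd.DataFrame(rows)
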