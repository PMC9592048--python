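"""Synthetic inpatient-rehabilitation cohort generator.

Emulates a small post-stroke cohort of the kind the prognosis pipeline is
built for: each patient has demographics and stroke characteristics, admission
functional-assessment scores, a 10 m walk and a six-minute walk recorded by
three body-worn IMUs (pelvis and bilateral ankles), and an ambulation label at
admission and discharge derived from the 10 m walk speed (household < 0.4 m/s,
community >= 0.4 m/s).

The cohort splits into three transition groups: household->household,
community->community, and household->community (patients who regain
community-level walking during the inpatient stay).  Gait-signal structure —
swing amplitude, pelvis acceleration amplitude, and cycle irregularity — is
drawn conditional on the *discharge* class, encoding the working premise that
movement quality at admission carries prognostic information beyond the
admission walking speed.  Patient information is drawn independently of class
by default, so that PI-only models perform near chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .features import PLACEMENTS, ACC_RANGE_G, GYRO_RANGE_DPS, SensorRecording

HOUSEHOLD = "household"
COMMUNITY = "community"
GROUPS = ("household_stable", "community_stable", "household_to_community")

DEFAULT_FS_HZ = 31.25
DEFAULT_LABEL_THRESHOLD = 0.4
SIX_MINUTE_DURATION_S = 360.0


def assign_ambulation_class(speed: float, threshold: float = DEFAULT_LABEL_THRESHOLD) -> str:
    """Household/community stratification of a 10 m walk speed (m/s).

    Community ambulation iff ``speed >= threshold`` (default 0.4 m/s).
    """
    if speed < 0:
        raise ValueError("gait speed must be nonnegative")
    return COMMUNITY if speed >= threshold else HOUSEHOLD


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated normal sampler used for all class-conditional parameters."""

    mean: float
    sd: float
    low: float
    high: float

    def _dist(self):
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm(a, b, loc=self.mean, scale=self.sd)

    def rvs(self, rng: np.random.Generator, size=None):
        return self._dist().rvs(size=size, random_state=rng)

    def true_mean(self) -> float:
        """Analytic mean of the truncated distribution."""
        return float(self._dist().mean())

    def true_sd(self) -> float:
        return float(self._dist().std())


@dataclass
class GaitProfile:
    """Per-patient gait parameters that drive the signal simulator.

    Speeds in m/s, cadence in steps/s, swing amplitude as peak ankle angular
    velocity (deg/s), pelvis acceleration amplitude in g.  ``irregularity``
    (0-1) controls cycle-to-cycle timing/amplitude jitter and hence sample
    entropy; ``asymmetry`` (0-1) is the affected-side amplitude deficit;
    ``fatigue_drift`` is the fractional speed decay per minute over a
    six-minute bout.
    """

    gait_speed_adm: float
    gait_speed_dis: float
    cadence: float
    swing_amplitude: float
    pelvis_acc_amplitude: float
    irregularity: float
    asymmetry: float
    fatigue_drift: float

    def __post_init__(self) -> None:
        if self.gait_speed_adm < 0 or self.gait_speed_dis < 0:
            raise ValueError("gait speeds must be nonnegative")
        if self.swing_amplitude < 0 or self.pelvis_acc_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        for name in ("irregularity", "asymmetry"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")


# Class-conditional defaults.  Speeds are per transition group; the gait
# "quality" parameters are per discharge class: community-bound patients show
# larger, more complex (higher-entropy) and more symmetric motion already at
# admission.
DEFAULT_SPEEDS: dict[str, dict[str, TruncatedNormal]] = {
    "household_stable": {
        "adm": TruncatedNormal(0.22, 0.08, 0.05, 0.39),
        "dis": TruncatedNormal(0.27, 0.07, 0.05, 0.399),
    },
    "community_stable": {
        "adm": TruncatedNormal(0.85, 0.25, 0.40, 1.80),
        "dis": TruncatedNormal(1.00, 0.25, 0.40, 1.80),
    },
    "household_to_community": {
        "adm": TruncatedNormal(0.24, 0.07, 0.05, 0.39),
        "dis": TruncatedNormal(0.82, 0.30, 0.40, 1.80),
    },
}

DEFAULT_PROFILES: dict[str, dict[str, TruncatedNormal]] = {
    COMMUNITY: {
        "swing_amplitude": TruncatedNormal(170.0, 25.0, 40.0, 400.0),
        "pelvis_acc_amplitude": TruncatedNormal(0.25, 0.05, 0.02, 1.0),
        "irregularity": TruncatedNormal(0.35, 0.08, 0.0, 1.0),
        "asymmetry": TruncatedNormal(0.20, 0.08, 0.0, 1.0),
        "fatigue_drift": TruncatedNormal(0.03, 0.015, 0.0, 0.5),
    },
    HOUSEHOLD: {
        "swing_amplitude": TruncatedNormal(95.0, 20.0, 20.0, 400.0),
        "pelvis_acc_amplitude": TruncatedNormal(0.12, 0.03, 0.02, 1.0),
        "irregularity": TruncatedNormal(0.12, 0.04, 0.0, 1.0),
        "asymmetry": TruncatedNormal(0.40, 0.10, 0.0, 1.0),
        "fatigue_drift": TruncatedNormal(0.03, 0.015, 0.0, 0.5),
    },
}


@dataclass
class CohortConfig:
    """Cohort composition and class-conditional generating distributions.

    The default composition (6 household-stable, 23 community-stable, 4
    household-to-community) yields 33 patients with 27 community and 6
    household ambulators at discharge.
    """

    n_household_stable: int = 6
    n_community_stable: int = 23
    n_household_to_community: int = 4
    label_threshold: float = DEFAULT_LABEL_THRESHOLD
    seed: int = 0
    fs_hz: float = DEFAULT_FS_HZ
    speeds: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SPEEDS.items()})
    profiles: dict = field(default_factory=lambda: {c: dict(v) for c, v in DEFAULT_PROFILES.items()})
    pi_class_informative: bool = False
    p_unable_6mwt: float = 0.0
    noise_acc_g: float = 0.02
    noise_gyro_dps: float = 2.0
    six_minute_duration_s: float = SIX_MINUTE_DURATION_S

    def __post_init__(self) -> None:
        for n in (self.n_household_stable, self.n_community_stable, self.n_household_to_community):
            if n < 0:
                raise ValueError("group counts must be nonnegative")

    @property
    def n_patients(self) -> int:
        return self.n_household_stable + self.n_community_stable + self.n_household_to_community


def sample_profile(group: str, config: CohortConfig, rng: np.random.Generator) -> GaitProfile:
    """Draw one patient's gait profile for the given transition group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    speeds = config.speeds[group]
    v_adm = float(speeds["adm"].rvs(rng))
    v_dis = float(speeds["dis"].rvs(rng))
    dis_class = assign_ambulation_class(v_dis, config.label_threshold)
    params = config.profiles[dis_class]
    cadence = float(np.clip(0.9 + 0.9 * v_adm + rng.normal(0.0, 0.08), 0.5, 3.0))
    return GaitProfile(
        gait_speed_adm=v_adm,
        gait_speed_dis=v_dis,
        cadence=cadence,
        swing_amplitude=float(params["swing_amplitude"].rvs(rng)),
        pelvis_acc_amplitude=float(params["pelvis_acc_amplitude"].rvs(rng)),
        irregularity=float(params["irregularity"].rvs(rng)),
        asymmetry=float(params["asymmetry"].rvs(rng)),
        fatigue_drift=float(params["fatigue_drift"].rvs(rng)),
    )


# ---------------------------------------------------------------------------
# Signal simulation


def _cycle_waveform(phase: np.ndarray, harmonic_phase: float = 0.7) -> np.ndarray:
    """Normalized quasi-gait cycle: two harmonics, peak magnitude 1."""
    w = np.sin(2 * np.pi * phase) + 0.35 * np.sin(4 * np.pi * phase + harmonic_phase)
    return w / 1.35


def _jittered_cycles(
    rng: np.random.Generator,
    base_period: float,
    base_amplitude: float,
    irregularity: float,
    duration_s: float,
    fatigue_drift: float,
    apply_fatigue: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cycle start times, per-cycle periods and amplitudes over a bout."""
    starts = [0.0]
    periods = []
    amplitudes = []
    t = 0.0
    while t <= duration_s:
        if apply_fatigue:
            decay = max(1.0 - fatigue_drift * (t / 60.0), 0.3)
            irr = min(1.0, irregularity + fatigue_drift * (t / 60.0))
        else:
            decay = 1.0
            irr = irregularity
        period = base_period / decay * (1.0 + irr * float(np.clip(rng.normal(0.0, 0.30), -0.85, 0.85)))
        amp = base_amplitude * decay * (1.0 + irr * float(np.clip(rng.normal(0.0, 0.40), -0.85, 0.85)))
        periods.append(period)
        amplitudes.append(amp)
        t += period
        starts.append(t)
    return np.array(starts), np.array(periods), np.array(amplitudes)


def _quasi_periodic(
    rng: np.random.Generator,
    t: np.ndarray,
    freq_hz: float,
    amplitude: float,
    irregularity: float,
    fatigue_drift: float,
    apply_fatigue: bool,
    harmonic_phase: float,
) -> np.ndarray:
    """A jittered sum-of-harmonics oscillation sampled at times ``t``."""
    starts, periods, amps = _jittered_cycles(
        rng, 1.0 / freq_hz, amplitude, irregularity, float(t[-1]) if t.size else 0.0,
        fatigue_drift, apply_fatigue,
    )
    k = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(periods) - 1)
    local_phase = (t - starts[k]) / periods[k]
    return amps[k] * _cycle_waveform(local_phase, harmonic_phase)


def simulate_gait_recording(
    profile: GaitProfile,
    placement: str,
    duration_s: float,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int = 0,
    noise_acc_g: float = 0.02,
    noise_gyro_dps: float = 2.0,
    apply_fatigue: bool = False,
) -> SensorRecording:
    """Simulate one sensor's tri-axial recording of a walking bout.

    The ankle gyroscope is dominated by a quasi-periodic oscillation at the
    stride frequency (cadence/2) with peak ~= ``swing_amplitude`` (scaled down
    by ``asymmetry`` on the affected side); the pelvis accelerometer
    oscillates at the step frequency around a constant 1 g gravity offset on
    its vertical axis.  Cycle period and amplitude are jittered per cycle in
    proportion to ``irregularity``; additive Gaussian sensor noise is applied
    to every channel.  Deterministic given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if placement not in PLACEMENTS:
        raise ValueError(f"unknown placement {placement!r}")

    rng = np.random.default_rng(seed)
    n = int(math.floor(duration_s * fs_hz))
    if n < 1:
        raise ValueError("duration too short for a single sample at this rate")
    t = np.arange(n) / fs_hz

    stride_freq = profile.cadence / 2.0
    step_freq = profile.cadence
    drift = profile.fatigue_drift

    def osc(freq, amp, phase):
        return _quasi_periodic(rng, t, freq, amp, profile.irregularity, drift, apply_fatigue, phase)

    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    if placement == "pelvis":
        amp = profile.pelvis_acc_amplitude
        acc[:, 0] = osc(step_freq, 0.5 * amp, 0.3)
        acc[:, 1] = osc(step_freq, 0.3 * amp, 1.1)
        acc[:, 2] = 1.0 + osc(step_freq, amp, 0.7)  # vertical axis carries gravity
        g_amp = 0.15 * profile.swing_amplitude
        gyro[:, 0] = osc(step_freq, 0.6 * g_amp, 0.2)
        gyro[:, 1] = osc(step_freq, g_amp, 0.9)
        gyro[:, 2] = osc(step_freq, 0.4 * g_amp, 1.6)
    else:
        deficit = 1.0 - profile.asymmetry if placement == "ankle_affected" else 1.0
        g_amp = profile.swing_amplitude * deficit
        gyro[:, 0] = osc(stride_freq, 0.3 * g_amp, 0.4)
        gyro[:, 1] = osc(stride_freq, 0.2 * g_amp, 1.2)
        gyro[:, 2] = osc(stride_freq, g_amp, 0.7)  # sagittal-plane swing
        a_amp = 2.0 * profile.pelvis_acc_amplitude * deficit
        acc[:, 0] = 1.0 + osc(stride_freq, 0.5 * a_amp, 0.5)  # rotated sensor: gravity on x
        acc[:, 1] = osc(stride_freq, a_amp, 1.0)
        acc[:, 2] = osc(stride_freq, 0.6 * a_amp, 1.8)

    if noise_acc_g > 0:
        acc += rng.normal(0.0, noise_acc_g, size=acc.shape)
    if noise_gyro_dps > 0:
        gyro += rng.normal(0.0, noise_gyro_dps, size=gyro.shape)

    np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G, out=acc)
    np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS, out=gyro)
    return SensorRecording(placement=placement, fs_hz=fs_hz, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# Cohort assembly


def _sample_patient_info(rng: np.random.Generator, dis_class: str, informative: bool) -> dict:
    age = rng.normal(62.0, 12.0)
    if informative and dis_class == COMMUNITY:
        age -= 8.0
    height = rng.normal(170.0, 10.0)
    weight = rng.normal(80.0, 15.0)
    return {
        "age": float(np.clip(age, 18.0, 95.0)),
        "sex": "M" if rng.random() < 0.5 else "F",
        "height_cm": float(np.clip(height, 140.0, 210.0)),
        "weight_kg": float(np.clip(weight, 40.0, 160.0)),
        "bmi": float(np.clip(weight, 40.0, 160.0)) / (np.clip(height, 140.0, 210.0) / 100.0) ** 2,
        "days_post_stroke": float(np.clip(rng.lognormal(math.log(14.0), 0.5), 2.0, 120.0)),
        "stroke_type": "ischemic" if rng.random() < 0.85 else "hemorrhagic",
        "affected_side": "left" if rng.random() < 0.5 else "right",
        "assistive_device": "yes" if rng.random() < 0.3 else "no",
    }


def _sample_assessments(rng: np.random.Generator, profile: GaitProfile, p_unable_6mwt: float) -> dict:
    v = profile.gait_speed_adm
    six_mwt = max(0.0, 360.0 * v * (1.0 - 0.15 * profile.fatigue_drift * 3.0) + rng.normal(0.0, 20.0))
    if rng.random() < p_unable_6mwt:
        six_mwt = np.nan
    return {
        "10MWT_adm_mps": v,
        "6MWT_adm_m": six_mwt,
        "BBS_adm": float(np.clip(round(56.0 * (v / 1.2) ** 0.6 + rng.normal(0.0, 4.0)), 0, 56)),
        "TUG_adm_s": float(np.clip(8.0 + 6.0 / max(v, 0.05) + rng.normal(0.0, 2.0), 5.0, 120.0)),
        "FIMmotor_adm": float(np.clip(round(13.0 + 60.0 * v + rng.normal(0.0, 6.0)), 13, 91)),
    }


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict[str, dict[str, dict[str, SensorRecording]]]]:
    """Generate the cohort table and all per-patient sensor recordings.

    Returns
    -------
    cohort : DataFrame indexed by patient id
        Patient information, admission assessment scores, discharge 10 m walk
        speed, transition group, and derived admission/discharge labels.
    recordings : dict
        ``recordings[pid]["10mwt" | "6mwt"][placement]`` ->
        :class:`~gaitprognosis.features.SensorRecording`.  The 10 m bout lasts
        ``10 / gait_speed_adm`` seconds at constant speed; the six-minute bout
        lasts 360 s with the patient's fatigue drift applied.  Patients with
        zero admission speed are flagged non-ambulatory and get no recordings.
    """
    group_plan = (
        [("household_stable", i) for i in range(config.n_household_stable)]
        + [("community_stable", i) for i in range(config.n_community_stable)]
        + [("household_to_community", i) for i in range(config.n_household_to_community)]
    )
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(group_plan))

    rows = {}
    recordings: dict[str, dict[str, dict[str, SensorRecording]]] = {}
    for idx, ((group, _), child) in enumerate(zip(group_plan, children)):
        pid = f"P{idx + 1:03d}"
        seeds = child.generate_state(8) % (2**31 - 1)
        rng = np.random.default_rng(int(seeds[0]))
        profile = sample_profile(group, config, rng)
        dis_class = assign_ambulation_class(profile.gait_speed_dis, config.label_threshold)
        adm_class = assign_ambulation_class(profile.gait_speed_adm, config.label_threshold)
        ambulatory = profile.gait_speed_adm > 0.0

        row = {"group": group, "ambulatory_adm": ambulatory}
        row.update(_sample_patient_info(rng, dis_class, config.pi_class_informative))
        row.update(_sample_assessments(rng, profile, config.p_unable_6mwt))
        row["10MWT_dis_mps"] = profile.gait_speed_dis
        row["label_adm"] = adm_class
        row["label_dis"] = dis_class
        rows[pid] = row

        if not ambulatory:
            continue
        patient_recs: dict[str, dict[str, SensorRecording]] = {"10mwt": {}, "6mwt": {}}
        ten_m_duration = 10.0 / profile.gait_speed_adm
        for j, placement in enumerate(PLACEMENTS):
            patient_recs["10mwt"][placement] = simulate_gait_recording(
                profile, placement, ten_m_duration, config.fs_hz,
                seed=int(seeds[1 + j]),
                noise_acc_g=config.noise_acc_g, noise_gyro_dps=config.noise_gyro_dps,
            )
            patient_recs["6mwt"][placement] = simulate_gait_recording(
                profile, placement, config.six_minute_duration_s, config.fs_hz,
                seed=int(seeds[4 + j]),
                noise_acc_g=config.noise_acc_g, noise_gyro_dps=config.noise_gyro_dps,
                apply_fatigue=True,
            )
        recordings[pid] = patient_recs

    cohort = pd.DataFrame.from_dict(rows, orient="index")
    cohort.index.name = "patient_id"
    return cohort, recordings
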