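"""Signal-level feature extraction from body-worn inertial sensors.

Converts raw tri-axial accelerometer/gyroscope recordings from the pelvis and
bilateral ankles into the per-patient feature tables used for ambulation
prognosis.  All inertial features are computed on the Euclidean magnitude of
the tri-axial signals, which makes them invariant to sensor orientation, and
cover general signal statistics, cumulative angular displacement ("amount of
motion"), and sample entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

logger = logging.getLogger(__name__)

#: Sensor placements used throughout the pipeline.
PLACEMENTS = ("pelvis", "ankle_affected", "ankle_unaffected")

#: Device limits: accelerometer +/-4 g, gyroscope +/-2000 deg/s.
ACC_RANGE_G = 4.0
GYRO_RANGE_DPS = 2000.0

#: Walking durations (s) supported by the fixed-duration paradigm.
FIXED_DURATIONS_S = (10, 20, 30, 60, 90, 120, 180, 240, 300, 360)

#: Integer codes for categorical patient-information fields.  Tree ensembles
#: are invariant to the particular monotone coding chosen.
CATEGORY_CODES = {
    "sex": {"F": 0, "M": 1},
    "stroke_type": {"ischemic": 0, "hemorrhagic": 1},
    "affected_side": {"left": 0, "right": 1},
    "assistive_device": {"no": 0, "yes": 1},
}


@dataclass
class SensorRecording:
    """One body-worn IMU stream: tri-axial acceleration and angular velocity.

    Parameters
    ----------
    placement : str
        One of ``pelvis``, ``ankle_affected``, ``ankle_unaffected``.
    fs_hz : float
        Sampling rate in Hz (the reference device samples at 31.25 Hz).
    acc : ndarray of shape (n, 3)
        Acceleration in g, within the +/-4 g device range.
    gyro : ndarray of shape (n, 3)
        Angular velocity in deg/s, within the +/-2000 deg/s device range.
    """

    placement: str
    fs_hz: float
    acc: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        if self.gyro.shape != self.acc.shape:
            raise ValueError("acc and gyro must have equal shape")
        if self.acc.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if np.abs(self.acc).max() > ACC_RANGE_G + 1e-9:
            raise ValueError("acceleration exceeds the +/-4 g device range")
        if np.abs(self.gyro).max() > GYRO_RANGE_DPS + 1e-9:
            raise ValueError("angular velocity exceeds the +/-2000 deg/s device range")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def slice(self, n: int) -> "SensorRecording":
        """First ``n`` samples as a new recording."""
        return SensorRecording(self.placement, self.fs_hz, self.acc[:n].copy(), self.gyro[:n].copy())


@dataclass
class BoutSpec:
    """Which portion of a walking assessment the features are computed on.

    ``fixed_distance`` uses the 10 m walk (whole trial, or the first
    ``distance_m / gait_speed`` seconds of a longer synthetic recording);
    ``fixed_duration`` uses the first ``duration_s`` seconds of the six-minute
    walk, with ``duration_s`` drawn from :data:`FIXED_DURATIONS_S`.
    """

    paradigm: str
    distance_m: float = 10.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in ("fixed_distance", "fixed_duration"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.paradigm == "fixed_duration":
            if self.duration_s not in FIXED_DURATIONS_S:
                raise ValueError(
                    f"duration_s must be one of {FIXED_DURATIONS_S}, got {self.duration_s}"
                )
        elif self.distance_m <= 0:
            raise ValueError("distance_m must be positive")

    @property
    def tag(self) -> str:
        if self.paradigm == "fixed_duration":
            return f"fixed_duration_{int(self.duration_s)}s"
        return "fixed_distance"


# ---------------------------------------------------------------------------
# Feature catalog


_IMU_STATISTICS = ("mean", "sd", "skewness", "kurtosis", "rms", "range", "iqr", "median", "sampen")
_PI_FIELDS = (
    "age", "sex", "height_cm", "weight_kg", "bmi",
    "days_post_stroke", "stroke_type", "affected_side", "assistive_device",
)
_FA_FIELDS = ("10MWT_adm", "6MWT_adm", "BBS_adm", "TUG_adm", "FIMmotor_adm")


@dataclass
class FeatureCatalog:
    """Ordered, namespaced feature list (``PI.*``, ``FA.*``, ``IMU.*``).

    The default catalog has 71 features: 9 patient-information fields, 5
    admission functional-assessment scores, and 57 inertial features (3
    sensors x 2 signals x 9 magnitude statistics, plus amount of motion per
    sensor).
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    @classmethod
    def default(cls) -> "FeatureCatalog":
        names = [f"PI.{f}" for f in _PI_FIELDS]
        names += [f"FA.{f}" for f in _FA_FIELDS]
        for placement in PLACEMENTS:
            for signal in ("acc", "gyro"):
                for stat in _IMU_STATISTICS:
                    names.append(f"IMU.{placement}.{signal}.{stat}")
        names += [f"IMU.{placement}.gyro.aom" for placement in PLACEMENTS]
        return cls(tuple(names))

    def subset(self, namespaces: tuple[str, ...] | list[str]) -> "FeatureCatalog":
        """Restrict to the given namespaces, e.g. ``("PI", "IMU")``."""
        keep = tuple(n for n in self.names if n.split(".", 1)[0] in namespaces)
        return FeatureCatalog(keep)


# ---------------------------------------------------------------------------
# Elementary signal operations


def magnitude(triaxial: np.ndarray) -> np.ndarray:
    """Sample-wise Euclidean norm of a tri-axial signal of shape (n, 3)."""
    arr = np.asarray(triaxial, dtype=float)
    if arr.ndim == 1:
        raise ValueError("expected a (n, 3) tri-axial array")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"expected shape (n, 3), got {arr.shape}")
    return np.linalg.norm(arr, axis=1)


def amount_of_motion(gyro: np.ndarray, fs_hz: float) -> float:
    """Cumulative angular displacement (deg): time-integral of gyro magnitude.

    Rectangular rule: ``sum(|gyro_t|) / fs``.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    mag = magnitude(gyro)
    if mag.size == 0:
        raise ValueError("empty gyroscope series")
    return float(mag.sum() / fs_hz)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy of a 1-D series.

    SampEn(m, r) = -ln(A / B), where B counts pairs of length-``m`` templates
    whose Chebyshev distance is <= ``r * SD(x)`` (self-matches excluded) and A
    is the analogous count for length ``m + 1``.  A constant series returns
    0.0 by convention; if no length-(m+1) template pair matches, ``inf`` is
    returned.  ``r`` is a fraction of the series SD, which makes the result
    invariant to affine amplitude scaling.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m + 1 = {m + 1}")
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    tol = r * sd

    n_templates = n - m  # same count for lengths m and m+1
    # Embeddings: rows are overlapping templates.
    idx = np.arange(n_templates)[:, None] + np.arange(m + 1)[None, :]
    emb = x[idx]  # (n_templates, m+1)
    emb_m = emb[:, :m]
    last = emb[:, m]

    b_count = 0
    a_count = 0
    block = 256
    for start in range(0, n_templates, block):
        stop = min(start + block, n_templates)
        # Chebyshev distance of each template in the block to all later ones.
        d_m = np.abs(emb_m[start:stop, None, :] - emb_m[None, :, :]).max(axis=2)
        d_last = np.abs(last[start:stop, None] - last[None, :])
        # Only count unordered pairs (i < j).
        cols = np.arange(n_templates)[None, :]
        rows = np.arange(start, stop)[:, None]
        upper = cols > rows
        match_m = (d_m <= tol) & upper
        b_count += int(match_m.sum())
        a_count += int((match_m & (d_last <= tol)).sum())

    if b_count == 0 or a_count == 0:
        return math.inf
    return float(-math.log(a_count / b_count))


def statistical_features(x: np.ndarray, sampen_m: int = 2, sampen_r: float = 0.2) -> dict[str, float]:
    """Summary statistics of a 1-D (magnitude) series.

    Returns mean, SD (n-1 denominator), skewness, excess kurtosis, RMS,
    range, interquartile range, median, and sample entropy.  Skewness and
    kurtosis of a zero-variance series are defined as 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 samples for the statistical features")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x))  # excess (Fisher) kurtosis
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "mean": float(x.mean()),
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "rms": float(np.sqrt(np.mean(x**2))),
        "range": float(x.max() - x.min()),
        "iqr": float(q75 - q25),
        "median": float(np.median(x)),
        "sampen": sample_entropy(x, m=sampen_m, r=sampen_r),
    }


def segment_bout(
    recording: SensorRecording,
    spec: BoutSpec,
    gait_speed: float | None = None,
) -> SensorRecording:
    """Slice the analysis bout out of a recording.

    fixed_duration keeps the first ``floor(duration_s * fs)`` samples;
    fixed_distance keeps the first ``floor((distance_m / gait_speed) * fs)``
    samples, or the whole recording when ``gait_speed`` is None (a real
    annotated 10 m trial is already exactly the bout).
    """
    if spec.paradigm == "fixed_duration":
        n = int(math.floor(spec.duration_s * recording.fs_hz))
    else:
        if gait_speed is None:
            return recording.slice(recording.n_samples)
        if gait_speed <= 0:
            raise ValueError("gait_speed must be positive for a fixed-distance bout")
        n = int(math.floor((spec.distance_m / gait_speed) * recording.fs_hz))
    if n > recording.n_samples:
        raise ValueError(
            f"recording has {recording.n_samples} samples but the bout needs {n} "
            f"({n - recording.n_samples} short)"
        )
    if n < 1:
        raise ValueError("requested bout is empty")
    return recording.slice(n)


# ---------------------------------------------------------------------------
# Feature table assembly


def _encode_pi(row: pd.Series, field_name: str) -> float:
    value = row[field_name]
    if field_name in CATEGORY_CODES:
        return float(CATEGORY_CODES[field_name][value])
    return float(value)


def imu_features(
    recordings: dict[str, SensorRecording],
    spec: BoutSpec,
    gait_speed: float | None,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
) -> dict[str, float]:
    """All inertial features for one patient's three sensors."""
    out: dict[str, float] = {}
    for placement in PLACEMENTS:
        bout = segment_bout(recordings[placement], spec, gait_speed)
        for signal_name, signal in (("acc", bout.acc), ("gyro", bout.gyro)):
            stats = statistical_features(magnitude(signal), sampen_m, sampen_r)
            for stat, value in stats.items():
                out[f"IMU.{placement}.{signal_name}.{stat}"] = value
        out[f"IMU.{placement}.gyro.aom"] = amount_of_motion(bout.gyro, bout.fs_hz)
    return out


def extract_feature_table(
    cohort: pd.DataFrame,
    recordings: dict[str, dict[str, dict[str, SensorRecording]]],
    spec: BoutSpec,
    catalog: FeatureCatalog | None = None,
    sampen_m: int = 2,
    sampen_r: float = 0.2,
) -> pd.DataFrame:
    """Build the patients x features table for one paradigm.

    Parameters
    ----------
    cohort : DataFrame
        One row per patient, indexed by patient id, with the patient
        information and admission assessment columns written by the cohort
        simulator.
    recordings : mapping
        ``recordings[patient_id][assessment][placement]`` ->
        :class:`SensorRecording`, with assessment ``"10mwt"`` or ``"6mwt"``.
    spec : BoutSpec
        Which assessment/slice the inertial features are computed on.
    catalog : FeatureCatalog, optional
        Feature list and ordering; defaults to the full 71-feature catalog.
        Patients missing a required recording are excluded (with a logged
        reason); missing assessment scores are imputed as 0.

    Returns
    -------
    DataFrame with one row per included patient, columns in catalog order;
    ``.attrs["paradigm"]`` carries the bout tag and ``.attrs["exclusions"]``
    the list of (patient_id, reason) pairs.
    """
    if catalog is None:
        catalog = FeatureCatalog.default()
    assessment = "10mwt" if spec.paradigm == "fixed_distance" else "6mwt"
    need_imu = any(name.startswith("IMU.") for name in catalog)

    rows = {}
    exclusions: list[tuple[str, str]] = []
    for pid, row in cohort.iterrows():
        values: dict[str, float] = {}
        if need_imu:
            patient_recs = recordings.get(pid, {}).get(assessment)
            if not patient_recs or any(p not in patient_recs for p in PLACEMENTS):
                exclusions.append((pid, f"incomplete sensor data for {assessment}"))
                logger.warning("excluding %s: incomplete sensor data for %s", pid, assessment)
                continue
            gait_speed = float(row["10MWT_adm_mps"]) if spec.paradigm == "fixed_distance" else None
            try:
                values.update(
                    imu_features(patient_recs, spec, gait_speed, sampen_m, sampen_r)
                )
            except ValueError as exc:
                exclusions.append((pid, str(exc)))
                logger.warning("excluding %s: %s", pid, exc)
                continue
        for name in catalog:
            namespace, rest = name.split(".", 1)
            if namespace == "PI":
                values[name] = _encode_pi(row, rest)
            elif namespace == "FA":
                raw = row[f"{rest}_mps" if rest == "10MWT_adm" else _fa_column(rest)]
                # Patients unable to complete an assessment score 0.
                values[name] = 0.0 if pd.isna(raw) else float(raw)
        rows[pid] = [values[name] for name in catalog]

    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(catalog))
    table.index.name = cohort.index.name or "patient_id"
    table.attrs["paradigm"] = spec.tag
    table.attrs["exclusions"] = exclusions
    return table


def _fa_column(rest: str) -> str:
    return {
        "6MWT_adm": "6MWT_adm_m",
        "BBS_adm": "BBS_adm",
        "TUG_adm": "TUG_adm_s",
        "FIMmotor_adm": "FIMmotor_adm",
    }[rest]
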