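"""Signal features: magnitude, bout segmentation, AoM, SampEn, statistics."""

import math

import numpy as np
import pytest

from gaitprognosis.cohort import simulate_gait_recording
from gaitprognosis.features import (
    BoutSpec,
    FeatureCatalog,
    SensorRecording,
    amount_of_motion,
    extract_feature_table,
    magnitude,
    sample_entropy,
    segment_bout,
    statistical_features,
)

from conftest import make_profile


# --------------------------------------------------------------------- oracles


def sampen_brute(x, m=2, r=0.2):
    """Exhaustive O(n^2) template-counting reference for sample entropy."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= tol:
                b += 1
                if max(d_m, abs(x[i + m] - x[j + m])) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


# ------------------------------------------------------------------- magnitude


@pytest.mark.parametrize("vec, expected", [((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((1, 2, 2), 3.0)])
def test_magnitude_pythagorean(vec, expected):
    assert magnitude(np.array([vec]))[0] == pytest.approx(expected)


def test_magnitude_shape_checks():
    with pytest.raises(ValueError):
        magnitude(np.ones(5))
    with pytest.raises(ValueError):
        magnitude(np.ones((5, 2)))


def test_magnitude_features_rotation_invariant():
    # A fixed 3D rotation of the tri-axial signal must leave every
    # magnitude-based feature unchanged (device-orientation independence).
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(0)
    sig = rng.normal(size=(400, 3))
    rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
    f_orig = statistical_features(magnitude(sig))
    f_rot = statistical_features(magnitude(sig @ rot.T))
    for key in f_orig:
        assert f_rot[key] == pytest.approx(f_orig[key], abs=1e-9)
    assert amount_of_motion(sig @ rot.T, 31.25) == pytest.approx(
        amount_of_motion(sig, 31.25), abs=1e-9
    )


# ---------------------------------------------------------------- segmentation


def _recording(n, fs=31.25):
    rng = np.random.default_rng(1)
    return SensorRecording("pelvis", fs, rng.normal(0, 0.1, (n, 3)), rng.normal(0, 5, (n, 3)))


@pytest.mark.parametrize(
    "spec, speed, expected",
    [
        (BoutSpec("fixed_duration", duration_s=60), None, 1875),
        (BoutSpec("fixed_duration", duration_s=10), None, 312),
        (BoutSpec("fixed_distance"), 0.5, 625),
    ],
)
def test_segment_bout_sample_counts(spec, speed, expected):
    rec = _recording(12000)
    assert segment_bout(rec, spec, speed).n_samples == expected


def test_segment_bout_whole_trial_when_no_speed():
    rec = _recording(500)
    assert segment_bout(rec, BoutSpec("fixed_distance"), None).n_samples == 500


def test_segment_bout_truncation_error_names_shortfall():
    rec = _recording(100)
    with pytest.raises(ValueError, match="short"):
        segment_bout(rec, BoutSpec("fixed_duration", duration_s=60), None)


def test_bout_spec_validates_duration_set():
    with pytest.raises(ValueError):
        BoutSpec("fixed_duration", duration_s=45)
    with pytest.raises(ValueError):
        BoutSpec("sliding_window")


# ------------------------------------------------------------ amount of motion


def test_aom_rectangle_rule():
    gyro = np.zeros((312, 3))
    gyro[:, 0] = 10.0  # constant 10 deg/s magnitude for ~10 s
    fs = 31.2
    assert amount_of_motion(gyro, fs) == pytest.approx(312 * 10.0 / fs)


def test_aom_zero_signal():
    assert amount_of_motion(np.zeros((50, 3)), 31.25) == 0.0


def test_aom_matches_summation_oracle():
    fs = 31.25
    t = np.arange(int(10 * fs)) / fs
    gyro = np.zeros((len(t), 3))
    gyro[:, 1] = 100 * np.sin(2 * np.pi * t)  # |mag| = |100 sin|
    expected = np.abs(100 * np.sin(2 * np.pi * t)).sum() / fs
    assert amount_of_motion(gyro, fs) == pytest.approx(expected, abs=1e-9)


def test_aom_additive_over_segments():
    rng = np.random.default_rng(3)
    gyro = rng.normal(0, 50, (600, 3))
    whole = amount_of_motion(gyro, 31.25)
    parts = amount_of_motion(gyro[:200], 31.25) + amount_of_motion(gyro[200:], 31.25)
    assert whole == pytest.approx(parts, rel=1e-12)


def test_aom_empty_series_rejected():
    with pytest.raises(ValueError):
        amount_of_motion(np.empty((0, 3)), 31.25)


# --------------------------------------------------------------- sample entropy


def test_sampen_constant_series_is_zero():
    assert sample_entropy(np.full(50, 3.7)) == 0.0


def test_sampen_alternating_series_matches_brute_force():
    x = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
    assert sample_entropy(x, m=2, r=0.5) == pytest.approx(sampen_brute(x, 2, 0.5), abs=1e-12)


def test_sampen_white_noise_exceeds_sine():
    rng = np.random.default_rng(11)
    noise = rng.normal(size=500)
    t = np.arange(500)
    sine = np.sin(2 * np.pi * t / 25)
    sine = sine / sine.std() * noise.std()
    assert sample_entropy(noise) > sample_entropy(sine)


def test_sampen_affine_invariance():
    rng = np.random.default_rng(4)
    x = rng.normal(size=300)
    assert sample_entropy(5.0 * x - 2.0) == pytest.approx(sample_entropy(x), abs=1e-12)


@pytest.mark.parametrize("n", [10, 17, 33, 64])
@pytest.mark.parametrize("m", [1, 2, 3])
def test_sampen_matches_brute_force(n, m):
    rng = np.random.default_rng(100 * n + m)
    x = rng.normal(size=n)
    expected = sampen_brute(x, m, 0.2)
    got = sample_entropy(x, m=m, r=0.2)
    if math.isinf(expected):
        assert math.isinf(got)
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_sampen_short_series_rejected():
    with pytest.raises(ValueError):
        sample_entropy(np.arange(3), m=2)


# --------------------------------------------------------- statistical features


def test_statistics_constant_series():
    f = statistical_features(np.full(10, 2.5))
    assert f["mean"] == 2.5
    assert f["sd"] == 0.0
    assert f["range"] == 0.0
    assert f["rms"] == 2.5
    assert f["skewness"] == 0.0
    assert f["sampen"] == 0.0


def test_statistics_hand_computed_values():
    f = statistical_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert f["sd"] == pytest.approx(math.sqrt(2.5))
    assert f["median"] == 3.0
    assert f["mean"] == 3.0
    assert f["range"] == 4.0
    assert f["iqr"] == 2.0
    assert f["rms"] == pytest.approx(math.sqrt(11.0))


def test_statistics_symmetric_series_zero_skew():
    x = np.concatenate([np.arange(10.0), -np.arange(10.0)])
    assert statistical_features(x)["skewness"] == pytest.approx(0.0, abs=1e-12)


def test_statistics_short_series_rejected():
    with pytest.raises(ValueError):
        statistical_features(np.array([1.0, 2.0, 3.0]))


# ------------------------------------------------------------- feature table


def test_feature_catalog_default_has_71_features():
    catalog = FeatureCatalog.default()
    assert len(catalog) == 71
    assert len([n for n in catalog if n.startswith("PI.")]) == 9
    assert len([n for n in catalog if n.startswith("FA.")]) == 5
    assert len([n for n in catalog if n.startswith("IMU.")]) == 57


def test_full_table_shape(fixed_distance_table):
    assert fixed_distance_table.shape == (33, 71)
    assert not fixed_distance_table.isna().any().any()
    assert fixed_distance_table.attrs["paradigm"] == "fixed_distance"


def test_fa_only_catalog(default_cohort):
    cohort, recordings = default_cohort
    catalog = FeatureCatalog.default().subset(("FA",))
    table = extract_feature_table(cohort, recordings, BoutSpec("fixed_distance"), catalog)
    assert list(table.columns) == [
        "FA.10MWT_adm", "FA.6MWT_adm", "FA.BBS_adm", "FA.TUG_adm", "FA.FIMmotor_adm",
    ]
    assert table.shape == (33, 5)


def test_missing_assessment_imputed_as_zero(default_cohort):
    cohort, recordings = default_cohort
    cohort = cohort.copy()
    pid = cohort.index[0]
    cohort.loc[pid, "6MWT_adm_m"] = np.nan
    catalog = FeatureCatalog.default().subset(("FA",))
    table = extract_feature_table(cohort, recordings, BoutSpec("fixed_distance"), catalog)
    assert table.loc[pid, "FA.6MWT_adm"] == 0.0


def test_patient_with_missing_recording_excluded(default_cohort):
    cohort, recordings = default_cohort
    recordings = {pid: recs for pid, recs in recordings.items()}
    dropped = cohort.index[0]
    recordings[dropped] = {"10mwt": {}, "6mwt": {}}
    catalog = FeatureCatalog.default().subset(("PI", "IMU"))
    # restrict to 3 patients to keep extraction cheap
    sub = cohort.iloc[:3]
    table = extract_feature_table(sub, recordings, BoutSpec("fixed_distance"), catalog)
    assert dropped not in table.index
    assert len(table) == 2
    assert table.attrs["exclusions"][0][0] == dropped


def test_extraction_deterministic(default_cohort):
    cohort, recordings = default_cohort
    sub = cohort.iloc[:2]
    catalog = FeatureCatalog.default().subset(("IMU",))
    a = extract_feature_table(sub, recordings, BoutSpec("fixed_distance"), catalog)
    b = extract_feature_table(sub, recordings, BoutSpec("fixed_distance"), catalog)
    assert a.equals(b)
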