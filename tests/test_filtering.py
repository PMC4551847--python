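import numpy as np
import pandas as pd
import pytest

from lmmspline import (TimeCourseExperiment, classify_informative,
                       compute_filter_statistics, filter_experiment)
from lmmspline.filtering import (LABEL_DEGENERATE, LABEL_EXCLUDED,
                                 LABEL_INFORMATIVE, LABEL_NONINFORMATIVE)


def _oracle_stats(y: np.ndarray, times, subjects):
    """Direct evaluation of the three SD formulas on one profile."""
    y = np.asarray(y, dtype=float)
    per_time = []
    for t in np.unique(times):
        vals = y[np.asarray(times) == t]
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            per_time.append(np.sqrt(((vals - vals.mean()) ** 2).sum()
                                    / (vals.size - 1)))
    per_subj = []
    for s in np.unique(subjects):
        vals = y[np.asarray(subjects) == s]
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            per_subj.append(np.sqrt(((vals - vals.mean()) ** 2).sum()
                                    / (vals.size - 1)))
    present = y[np.isfinite(y)]
    s_T = np.mean(per_time)
    s_I = np.mean(per_subj)
    s_M = np.sqrt(((present - present.mean()) ** 2).sum()
                  / (present.size - 1))
    return s_T, s_I, s_M


def test_statistics_match_direct_formula_evaluation(toy_experiment):
    stats = compute_filter_statistics(toy_experiment).table
    times = toy_experiment.times
    subjects = toy_experiment.samples["subject"].to_numpy()
    y = toy_experiment.values.loc["m1"].to_numpy()
    s_T, s_I, s_M = _oracle_stats(y, times, subjects)
    row = stats.loc["m1"]
    assert row["s_T"] == pytest.approx(s_T)
    assert row["s_I"] == pytest.approx(s_I)
    assert row["s_M"] == pytest.approx(s_M)
    assert row["R_T"] == pytest.approx(s_T / s_M)
    assert row["R_I"] == pytest.approx(1 - s_I / s_M)


def test_time_varying_profile_has_zero_RT(toy_experiment):
    # m3 is identical across subjects at every time but varies over time
    stats = compute_filter_statistics(toy_experiment).table
    assert stats.loc["m3", "s_T"] == 0.0
    assert stats.loc["m3", "R_T"] == 0.0


def test_constant_profile_is_degenerate(toy_experiment):
    stats = compute_filter_statistics(toy_experiment).table
    assert stats.loc["m2", "s_M"] == 0.0
    assert stats.loc["m2", "label"] == LABEL_DEGENERATE
    assert not stats.loc["m2", "informative"]


def test_missing_cells_reduce_denominators():
    samples = pd.DataFrame({
        "subject": ["A", "A", "A", "B", "B", "B", "C", "C", "C"],
        "time": [0.0, 1.0, 2.0] * 3,
    }, index=pd.Index([f"s{i}" for i in range(9)], name="sample"))
    y = np.array([1.0, 2.0, np.nan, 2.0, 1.0, 4.0, 3.0, np.nan, 5.0])
    values = pd.DataFrame([y], index=pd.Index(["m"], name="molecule"),
                          columns=samples.index)
    exp = TimeCourseExperiment(values, samples)
    stats = compute_filter_statistics(exp).table
    s_T, s_I, s_M = _oracle_stats(y, samples["time"], samples["subject"])
    assert stats.loc["m", "s_T"] == pytest.approx(s_T)
    assert stats.loc["m", "s_I"] == pytest.approx(s_I)
    assert stats.loc["m", "s_M"] == pytest.approx(s_M)
    assert stats.loc["m", "missing_fraction"] == pytest.approx(2 / 9)


def _blob_stats(seed=0):
    rng = np.random.default_rng(seed)
    informative = rng.normal([0.35, 0.05], 0.05, size=(100, 2))
    noisy = rng.normal([0.95, 0.40], 0.05, size=(100, 2))
    pts = np.vstack([informative, noisy])
    table = pd.DataFrame({
        "s_T": 1.0, "s_I": 1.0, "s_M": 1.0,
        "R_T": pts[:, 0], "R_I": pts[:, 1],
        "missing_fraction": 0.0, "label": "", "informative": True,
    }, index=[f"m{i}" for i in range(200)])
    from lmmspline.filtering import FilterStatistics
    return FilterStatistics(table)


def test_two_blob_classification_recovers_generating_labels():
    out = classify_informative(_blob_stats(), seed=0).table
    lab = out["label"].to_numpy()
    assert (lab[:100] == LABEL_INFORMATIVE).mean() >= 0.95
    assert (lab[100:] == LABEL_NONINFORMATIVE).mean() >= 0.95


def test_identical_ratios_fall_back_to_informative():
    from lmmspline.filtering import FilterStatistics
    table = pd.DataFrame({
        "s_T": 1.0, "s_I": 1.0, "s_M": 1.0, "R_T": 0.5, "R_I": 0.1,
        "missing_fraction": 0.0, "label": "", "informative": True,
    }, index=[f"m{i}" for i in range(10)])
    out = classify_informative(FilterStatistics(table), seed=0)
    assert (out.table["label"] == LABEL_INFORMATIVE).all()
    assert out.warnings


def _noise_experiment(n_mol, n_subj=20, times=(0, 1, 2, 3, 4, 5), seed=0,
                      signal_rows=0, slope=0.0, noise_sd=1.0):
    rng = np.random.default_rng(seed)
    subj = np.repeat([f"S{i}" for i in range(n_subj)], len(times))
    t = np.tile(np.asarray(times, float), n_subj)
    samples = pd.DataFrame({"subject": subj, "time": t},
                           index=pd.Index([f"s{i}" for i in range(t.size)],
                                          name="sample"))
    values = rng.normal(0.0, noise_sd, size=(n_mol, t.size))
    values[:signal_rows] += slope * t
    frame = pd.DataFrame(values, columns=samples.index,
                         index=pd.Index([f"m{i}" for i in range(n_mol)],
                                        name="molecule"))
    return TimeCourseExperiment(frame, samples)


def test_pure_noise_ratio_distribution():
    """R_T concentrates near 1 and R_I near 0 for i.i.d. noise profiles."""
    exp = _noise_experiment(1000, seed=11)
    stats = compute_filter_statistics(exp).table
    assert abs(stats["R_T"].mean() - 1.0) < 0.05
    assert abs(stats["R_I"].mean() - 0.0) < 0.05


def test_strong_trend_gives_low_RT():
    exp = _noise_experiment(200, seed=3, signal_rows=200, slope=1.0,
                            noise_sd=0.1)
    stats = compute_filter_statistics(exp).table
    assert (stats["R_T"] < 0.5).mean() >= 0.99


def test_missing_rule_removes_sparse_molecules(toy_experiment):
    exp = toy_experiment
    exp.values.loc["m1", ["s1", "s2", "s3", "s4"]] = np.nan  # 4/6 missing
    filtered, report = filter_experiment(exp, seed=0)
    assert report.table.loc["m1", "label"] == LABEL_EXCLUDED
    assert "m1" not in filtered.molecule_ids


def test_per_group_keeps_molecule_informative_in_one_group():
    """Non-informative in one condition, informative in the other: kept."""
    rng = np.random.default_rng(5)
    n_subj, times = 6, (0.0, 1.0, 2.0, 3.0)
    subj = np.repeat([f"S{i}" for i in range(2 * n_subj)], len(times))
    t = np.tile(np.asarray(times), 2 * n_subj)
    grp = np.repeat(["G1"] * n_subj + ["G2"] * n_subj, len(times))
    samples = pd.DataFrame(
        {"subject": subj, "time": t, "group": grp},
        index=pd.Index([f"s{i}" for i in range(t.size)], name="sample"))
    n_mol = 60
    values = rng.normal(0.0, 1.0, size=(n_mol, t.size))
    # molecules 0..9: strong trend in G1 only; 10..19: trend in both
    g1 = grp == "G1"
    values[:10, g1] += 5.0 * t[g1] + rng.normal(0, 0.05, (10, g1.sum()))
    values[10:20] += 5.0 * t
    frame = pd.DataFrame(values, columns=samples.index,
                         index=pd.Index([f"m{i}" for i in range(n_mol)],
                                        name="molecule"))
    exp = TimeCourseExperiment(frame, samples)
    filtered, report = filter_experiment(exp, per_group=True, seed=0)
    kept = set(filtered.molecule_ids)
    assert {f"m{i}" for i in range(20)} <= kept
    tab = report.table
    assert (tab.loc["m0", "label_G1"] == LABEL_INFORMATIVE)
    assert (tab.loc["m0", "label_G2"] == LABEL_NONINFORMATIVE)


def test_pooled_classification_on_grouped_experiment(grouped_experiment):
    # per_group=False must ignore groups entirely
    _, report = filter_experiment(grouped_experiment, per_group=False,
                                  seed=0)
    assert "label_G1" not in report.table.columns


def test_filtering_is_idempotent():
    exp = _noise_experiment(100, seed=2, signal_rows=40, slope=1.0,
                            noise_sd=0.2)
    filtered, _ = filter_experiment(exp, seed=0)
    refiltered, report = filter_experiment(filtered, seed=0)
    assert list(refiltered.molecule_ids) == list(filtered.molecule_ids)
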