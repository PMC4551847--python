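import numpy as np
import pandas as pd
import pytest

from lmmspline import TimeCourseExperiment


@pytest.fixture
def toy_experiment() -> TimeCourseExperiment:
    """2 subjects x 3 times, 3 molecules; includes the hand-checked profile."""
    samples = pd.DataFrame({
        "subject": ["A", "A", "A", "B", "B", "B"],
        "time": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
    }, index=pd.Index([f"s{i}" for i in range(6)], name="sample"))
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 1.0, 4.0, 3.0],
         [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],
         [0.0, 1.0, 2.0, 0.0, 1.0, 2.0]],
        index=pd.Index(["m1", "m2", "m3"], name="molecule"),
        columns=samples.index)
    return TimeCourseExperiment(values, samples)


@pytest.fixture
def grouped_experiment() -> TimeCourseExperiment:
    """4 subjects in 2 groups x 3 times, 2 molecules."""
    rows = []
    for subj, grp in [("A", "G1"), ("B", "G1"), ("C", "G2"), ("D", "G2")]:
        for t in (0.0, 1.0, 2.0):
            rows.append((f"{subj}t{t:g}", subj, t, grp))
    samples = pd.DataFrame(rows, columns=["sample", "subject", "time",
                                          "group"]).set_index("sample")
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.normal(size=(2, len(samples))),
                          index=pd.Index(["m1", "m2"], name="molecule"),
                          columns=samples.index)
    return TimeCourseExperiment(values, samples)


def simulate_profiles(n_molecules, n_subjects, times, mean_fn, noise_sd,
                      seed, subject_sd=0.0):
    """Long-format profiles y = mean_fn(t) + subject offset + noise."""
    rng = np.random.default_rng(seed)
    base = pd.DataFrame(
        [(f"S{s}", t) for s in range(n_subjects) for t in times],
        columns=["subject", "time"])
    out = []
    for m in range(n_molecules):
        p = base.copy()
        offsets = dict(zip(p["subject"].unique(),
                           rng.normal(0.0, subject_sd, n_subjects)
                           if subject_sd else np.zeros(n_subjects)))
        p["value"] = (mean_fn(p["time"].to_numpy())
                      + p["subject"].map(offsets)
                      + rng.normal(0.0, noise_sd, len(p)))
        p["molecule"] = f"mol{m}"
        out.append(p)
    return pd.concat(out, ignore_index=True)
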