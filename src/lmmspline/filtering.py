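"""Noise-based profile filtering for time-course experiments.

For every molecule three standard deviations are computed, skipping
missing cells and reducing denominators accordingly:

* ``s_T`` — mean over time points of the SD across samples sharing that
  exact time value,
* ``s_I`` — mean over subjects of the SD across that subject's
  observations,
* ``s_M`` — the overall SD of all present cells.

The filter ratios ``R_T = s_T / s_M`` and ``R_I = 1 - s_I / s_M``
discriminate pure-noise profiles (``R_T`` near 1, ``R_I`` near 0) from
profiles with a genuine time signal (``R_T`` well below 1).  A
2-component Gaussian mixture on the (R_T, R_I) plane separates
informative from non-informative molecules without a hand-set threshold;
the component with the larger mean ``R_T`` is the non-informative one.

Molecules with more than 50% missing cells are removed up front (their
ratios are unreliable), and in multi-group designs a molecule is dropped
only when it is non-informative in *every* group, so that profiles flat
within one condition but different between conditions survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .timecourse import TimeCourseExperiment, split_by_group

logger = logging.getLogger(__name__)

LABEL_INFORMATIVE = "informative"
LABEL_NONINFORMATIVE = "noninformative"
LABEL_EXCLUDED = "excluded_missing"
LABEL_DEGENERATE = "degenerate"


@dataclass
class FilterStatistics:
    """Per-molecule filter statistics and classification.

    ``table`` has one row per molecule with columns
    ``s_T, s_I, s_M, R_T, R_I, missing_fraction, label, informative``
    (plus ``label_<group>`` columns for per-group filtering).
    """

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def _warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


def _sd_means(values: pd.DataFrame, by: pd.Series) -> pd.Series:
    """Mean over levels of `by` of the per-level SD (ddof=1) per molecule.

    Levels with fewer than 2 present cells contribute nothing; if all
    levels are skipped the result is NaN.
    """
    sds = []
    for _, cols in values.T.groupby(by.to_numpy()):
        block = cols.T
        count = block.notna().sum(axis=1)
        sd = block.std(axis=1, ddof=1)
        sds.append(sd.where(count >= 2))
    mat = pd.concat(sds, axis=1)
    return mat.mean(axis=1, skipna=True)


def compute_filter_statistics(exp: TimeCourseExperiment) -> FilterStatistics:
    """Compute s_T, s_I, s_M and the ratios R_T, R_I for every molecule.

    Samples are matched to a time point by exact time value; the approach
    expects shared sampling times across subjects with at least three
    samples per time point (no binning is performed here).
    """
    v = exp.values
    s_T = _sd_means(v, exp.samples["time"])
    s_I = _sd_means(v, exp.samples["subject"])
    count = v.notna().sum(axis=1)
    s_M = v.std(axis=1, ddof=1).where(count >= 2)
    missing_fraction = 1.0 - count / v.shape[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        R_T = s_T / s_M
        R_I = 1.0 - s_I / s_M
    degenerate = (s_M.isna() | (s_M == 0) | s_T.isna() | s_I.isna())
    R_T = R_T.where(~degenerate)
    R_I = R_I.where(~degenerate)

    table = pd.DataFrame({
        "s_T": s_T, "s_I": s_I, "s_M": s_M,
        "R_T": R_T, "R_I": R_I,
        "missing_fraction": missing_fraction,
        "label": np.where(degenerate, LABEL_DEGENERATE, ""),
        "informative": ~degenerate,
    }, index=v.index)
    return FilterStatistics(table)


def classify_informative(stats: FilterStatistics, seed: int = 0,
                         n_init: int = 5) -> FilterStatistics:
    """Label molecules by a 2-component Gaussian mixture on (R_T, R_I).

    Full covariances, best of ``n_init`` seeded initializations.  The
    component with the larger mean R_T (ties: larger mean R_I) is the
    non-informative one; assignment is by maximum posterior
    responsibility.  Degenerate fits — all points identical, a
    non-converged mixture, or a ratio cloud that a single component
    explains better by BIC (forcing two clusters onto a homogeneous
    cloud would split it arbitrarily) — fall back to labelling
    everything informative, with a warning recorded.
    """
    t = stats.table
    usable = t["R_T"].notna() & t["R_I"].notna() & \
        (t["label"] != LABEL_EXCLUDED)
    pts = t.loc[usable, ["R_T", "R_I"]].to_numpy(float)
    labels = pd.Series("", index=t.index, dtype=object)
    labels[t["label"] == LABEL_DEGENERATE] = LABEL_DEGENERATE
    labels[t["label"] == LABEL_EXCLUDED] = LABEL_EXCLUDED

    ok = False
    if usable.sum() >= 2 and np.unique(pts, axis=0).shape[0] >= 2:
        gmm = GaussianMixture(n_components=2, covariance_type="full",
                              n_init=n_init, random_state=seed,
                              reg_covar=1e-8)
        try:
            gmm.fit(pts)
            ok = bool(gmm.converged_)
            if ok:
                single = GaussianMixture(n_components=1,
                                         covariance_type="full",
                                         random_state=seed,
                                         reg_covar=1e-8).fit(pts)
                ok = gmm.bic(pts) < single.bic(pts)
        except Exception:       # singular clusters etc.
            ok = False
    if ok:
        means = gmm.means_
        # non-informative component: larger mean R_T, R_I breaks ties
        order = np.lexsort((means[:, 1], means[:, 0]))
        noninf_comp = order[-1]
        assign = gmm.predict(pts)
        lab = np.where(assign == noninf_comp,
                       LABEL_NONINFORMATIVE, LABEL_INFORMATIVE)
        labels[usable] = lab
    else:
        labels[usable] = LABEL_INFORMATIVE
        stats._warn("mixture classification degenerate or non-converged; "
                    "all molecules kept as informative")

    out = t.copy()
    out["label"] = labels
    out["informative"] = labels == LABEL_INFORMATIVE
    return FilterStatistics(out, list(stats.warnings))


def filter_experiment(exp: TimeCourseExperiment, per_group: bool = False,
                      max_missing: float = 0.5, seed: int = 0,
                      ) -> tuple[TimeCourseExperiment, FilterStatistics]:
    """Remove non-informative molecules; return survivors plus full report.

    Molecules above ``max_missing`` missingness go first.  With
    ``per_group`` the statistics and mixture classification run within
    every group level and a molecule is removed only when non-informative
    in all of them.  The report keeps statistics for removed molecules.
    """
    if per_group and not exp.has_groups:
        raise ValueError("per_group filtering requires a group annotation")

    pooled = compute_filter_statistics(exp)
    table = pooled.table
    excl = table["missing_fraction"] > max_missing
    table.loc[excl, "label"] = LABEL_EXCLUDED
    table.loc[excl, "informative"] = False
    kept_ids = table.index[~excl]
    warnings = list(pooled.warnings)

    if per_group:
        sub = exp.subset_molecules(kept_ids)
        any_informative = pd.Series(False, index=kept_ids)
        for level, part in split_by_group(sub).items():
            st = classify_informative(compute_filter_statistics(part),
                                      seed=seed)
            warnings.extend(st.warnings)
            table.loc[kept_ids, f"label_{level}"] = st.table["label"]
            any_informative |= st.table["informative"]
        table.loc[kept_ids, "label"] = np.where(
            any_informative, LABEL_INFORMATIVE, LABEL_NONINFORMATIVE)
        deg = table.loc[kept_ids, "s_M"].isna() | \
            (table.loc[kept_ids, "s_M"] == 0)
        table.loc[kept_ids[deg & ~any_informative], "label"] = \
            LABEL_DEGENERATE
        table.loc[kept_ids, "informative"] = any_informative
    else:
        sub = exp.subset_molecules(kept_ids)
        st = classify_informative(compute_filter_statistics(sub), seed=seed)
        warnings.extend(st.warnings)
        table.loc[kept_ids, "label"] = st.table["label"]
        table.loc[kept_ids, "informative"] = st.table["informative"]

    report = FilterStatistics(table, warnings)
    survivors = table.index[table["informative"]]
    if len(survivors) == 0:
        report._warn("no molecules survive filtering; returning an empty "
                     "experiment")
    filtered = exp.subset_molecules(survivors)
    return filtered, report
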