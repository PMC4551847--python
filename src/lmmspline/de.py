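"""Trajectory-level differential expression testing (LMMSDE).

The group-aware mean-curve model for molecule expression is

    f_h(t) = beta0 + beta1 t + sum_k u_k (t - kappa_k)_+
             + sum_{r>=2} h_r (alpha_0r + alpha_1r t)
             + sum_{r>=2} h_r sum_k v_rk (t - kappa_k)_+,

where h_r indicates membership of group r (the first group is the
reference), alpha_0r / alpha_1r are group offsets in intercept and slope
and v_rk are group offsets in the spline coefficients.  Three nested-model
likelihood ratio tests are derived from it (ML likelihoods, chi-square
reference):

* time:        full = intercept + slope + spline;  null = intercept only.
* group:       full = intercept + spline + group intercept offsets;
               null drops the offsets.  Following the model description
               the linear slope is excluded from both (beta1 = 0,
               alpha_1 = 0); ``keep_slope=True`` restores it for
               sensitivity analysis.
* interaction: full = the complete model above; null keeps a common curve
               plus group intercept offsets ("effects over time do not
               differ between groups").

Spline blocks (u_k and each group's v_rk) are penalized coefficients —
random effects with one variance parameter per block — so the default
degree-of-freedom accounting charges 1 df per spline block ("random"
mode); a "fixed" mode treats them as ordinary fixed effects with K df per
block.  All tests can carry a subject random intercept (default when any
subject is measured more than once) or random intercept + slope.

Multiple testing is corrected per effect across molecules with the
Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import LmmDesign
from .filtering import filter_experiment
from .modelling import SplineBasis
from .timecourse import TimeCourseExperiment

logger = logging.getLogger(__name__)

EFFECTS = ("time", "group", "interaction")


@dataclass
class EffectTest:
    """One molecule's likelihood ratio test for one effect."""

    effect: str
    stat: float
    df: int
    p: float
    loglik_full: float
    loglik_null: float
    converged: bool


@dataclass
class DEDesign:
    """Pre-built fixed/random designs for one effect, shared by molecules."""

    effect: str
    full: LmmDesign
    null: LmmDesign
    df: int
    full_names: list[str]
    null_names: list[str]


def _random_structure(subject: np.ndarray, requested: str) -> str:
    if requested != "auto":
        return requested
    counts = pd.Series(subject).value_counts()
    return "intercept" if (counts >= 2).any() else "none"


def _subject_blocks(subject: np.ndarray, t: np.ndarray, structure: str):
    blocks = []
    if structure == "none":
        return blocks
    levels, idx = np.unique(subject, return_inverse=True)
    S = np.zeros((t.size, levels.size))
    S[np.arange(t.size), idx] = 1.0
    blocks.append(("subj_intercept", S))
    if structure == "intercept_slope":
        blocks.append(("subj_slope", S * t[:, None]))
    return blocks


def _group_dummies(group: np.ndarray):
    """Indicator columns for every non-reference level (sorted order)."""
    levels = sorted(pd.unique(group))
    dummies = [(lev, (group == lev).astype(float)) for lev in levels[1:]]
    return levels, dummies


def build_design(t: np.ndarray, subject: np.ndarray,
                 group: np.ndarray | None, effect: str,
                 basis: SplineBasis, random_structure: str = "auto",
                 spline_df: str = "random",
                 keep_slope: bool = False) -> DEDesign:
    """Assemble the full and null designs for one LMMSDE effect."""
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    t = np.asarray(t, dtype=float)
    ones = np.ones_like(t)
    B = basis.design(t)
    structure = _random_structure(subject, random_structure)
    rand = _subject_blocks(subject, t, structure)
    as_fixed = spline_df == "fixed"

    if effect == "time":
        if np.unique(t).size < 2:
            raise ValueError("time test needs >=2 distinct times")
        Xf, Zf = [ones, t], [("spline", B)]
        Xn, Zn = [ones], []
        df = 1 + (basis.K if as_fixed else 1)
    else:
        if group is None:
            raise ValueError(f"{effect} test needs a group annotation")
        levels, dummies = _group_dummies(np.asarray(group, dtype=str))
        R = len(levels)
        if R < 2:
            raise ValueError(f"{effect} test needs >=2 groups")
        small = [lev for lev in levels
                 if pd.Series(subject[np.asarray(group, str) == lev])
                 .nunique() < 2]
        if small:
            logger.warning("group(s) %s have fewer than 2 subjects", small)
        if effect == "group":
            Xf = [ones] + ([t] if keep_slope else []) \
                + [d for _, d in dummies]
            Zf = [("spline", B)]
            Xn = [ones] + ([t] if keep_slope else [])
            Zn = [("spline", B)]
            df = R - 1
        else:  # interaction
            Xf = [ones, t] + [d for _, d in dummies] \
                + [d * t for _, d in dummies]
            Zf = [("spline", B)] + [(f"spline_{lev}", B * d[:, None])
                                    for lev, d in dummies]
            Xn = [ones, t] + [d for _, d in dummies]
            Zn = [("spline", B)]
            df = (R - 1) * (1 + (basis.K if as_fixed else 1))

    def finish(Xcols, Zblocks):
        names = [n for n, _ in Zblocks] + [n for n, _ in rand]
        mats = [m for _, m in Zblocks] + [m for _, m in rand]
        if as_fixed:
            Xcols = Xcols + [m for _, m in Zblocks]
            names = [n for n, _ in rand]
            mats = [m for _, m in rand]
        X = np.column_stack(Xcols)
        return LmmDesign(X, mats), names

    full, full_names = finish(Xf, Zf)
    null, null_names = finish(Xn, Zn)
    return DEDesign(effect, full, null, df, full_names, null_names)


def lrt(design: DEDesign, y: np.ndarray) -> EffectTest:
    """Fit null and full models for one molecule and form the LRT."""
    null = design.null.fit(y)
    theta_by_name = dict(zip(design.null_names, null.theta))
    theta0 = np.array([theta_by_name.get(n, -6.0)
                       for n in design.full_names])
    full = design.full.fit(y, theta0=theta0 if theta0.size else None)
    converged = null.converged and full.converged
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    if converged:
        p = float(stats.chi2.sf(stat, df=design.df))
    else:
        p = np.nan
        logger.warning("non-converged %s test; p recorded missing",
                       design.effect)
    return EffectTest(design.effect, stat, design.df, p,
                      full.loglik, null.loglik, converged)


def lrt_batch(design: DEDesign, Y: np.ndarray) -> pd.DataFrame:
    """Vectorized LRT over many complete (no-missing) profiles.

    The null model is fitted first; its optimal variance ratios warm-start
    the full model (new blocks effectively switched off), preserving the
    nested-likelihood ordering.
    """
    ll_null, th_null = design.null.fit_batch(Y)
    by_name = dict(zip(design.null_names, th_null.T))
    warm = np.column_stack(
        [by_name.get(n, np.full(Y.shape[0], -30.0))
         for n in design.full_names]) if design.full_names else None
    ll_full, _ = design.full.fit_batch(Y, warm_thetas=warm)
    stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(stat, df=design.df)
    return pd.DataFrame({"stat": stat, "df": design.df, "p": p,
                         "converged": True})


def _profile_design(profile: pd.DataFrame, effect: str, basis, **kw):
    p = profile.dropna(subset=["value"])
    t = p["time"].to_numpy(float)
    subject = p["subject"].to_numpy(str)
    group = p["group"].to_numpy(str) if "group" in p.columns else None
    if basis is None:
        basis = SplineBasis.from_times(t)
    return build_design(t, subject, group, effect, basis, **kw), \
        p["value"].to_numpy(float)


def test_time(profile: pd.DataFrame, basis: SplineBasis | None = None,
              **kw) -> EffectTest:
    """Does the trajectory change over time at all?"""
    design, y = _profile_design(profile, "time", basis, **kw)
    return lrt(design, y)


def test_group(profile: pd.DataFrame, basis: SplineBasis | None = None,
               **kw) -> EffectTest:
    """Do the groups differ in overall level?"""
    design, y = _profile_design(profile, "group", basis, **kw)
    return lrt(design, y)


def test_interaction(profile: pd.DataFrame,
                     basis: SplineBasis | None = None, **kw) -> EffectTest:
    """Do the groups differ in their behaviour over time?"""
    design, y = _profile_design(profile, "interaction", basis, **kw)
    return lrt(design, y)


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * m / j over the ranked p-values, capped
    at 1.  Missing entries are excluded from the procedure and reinserted
    as missing.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        pm = p[mask]
        m = pm.size
        order = np.argsort(pm, kind="stable")
        ranked = pm[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(adj, 1.0)
        out[mask] = vals
    return out


def de_pipeline(exp: TimeCourseExperiment, effects=("time",),
                random_structure: str = "auto", alpha_fdr: float = 0.05,
                filter_first: bool = False, spline_df: str = "random",
                keep_slope: bool = False, seed: int = 0) -> pd.DataFrame:
    """Run LMMSDE tests for the requested effects over all molecules.

    Returns a long table (molecule, effect, stat, df, p, adj_p,
    significant, converged); BH adjustment is applied within each effect
    across molecules, significance is adj_p < ``alpha_fdr``.  With
    ``filter_first`` the noise filter (multi-condition rule when groups
    are present) runs before testing.
    """
    effects = list(effects)
    if not effects:
        raise ValueError("no effects requested")
    for e in effects:
        if e not in EFFECTS:
            raise ValueError(f"unknown effect {e!r}")
    if any(e in ("group", "interaction") for e in effects) \
            and not exp.has_groups:
        raise ValueError("group/interaction tests need a group annotation")
    if filter_first:
        exp, _ = filter_experiment(exp, per_group=exp.has_groups, seed=seed)

    t = exp.times
    subject = exp.samples["subject"].to_numpy(str)
    group = exp.samples["group"].to_numpy(str) if exp.has_groups else None
    basis = SplineBasis.from_times(t)
    Y = exp.values.to_numpy(float)

    frames = []
    for effect in effects:
        design = build_design(t, subject, group, effect, basis,
                              random_structure=random_structure,
                              spline_df=spline_df, keep_slope=keep_slope)
        if np.isfinite(Y).all():
            tab = lrt_batch(design, Y)
        else:
            recs = [lrt(design, Y[i]) for i in range(Y.shape[0])]
            tab = pd.DataFrame({
                "stat": [r.stat for r in recs],
                "df": [r.df for r in recs],
                "p": [r.p for r in recs],
                "converged": [r.converged for r in recs],
            })
        tab.insert(0, "molecule", exp.molecule_ids.to_numpy())
        tab.insert(1, "effect", effect)
        tab["adj_p"] = adjust_bh(tab["p"])
        tab["significant"] = tab["adj_p"] < alpha_fdr
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
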