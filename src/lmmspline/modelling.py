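"""Serial fitting of linear mixed model splines (LMMS) per molecule.

Four nested models of increasing complexity are considered for each
molecular profile y_ij(t_ij) (subject i, time t_ij):

* class 0 (LIN):  straight line, ordinary least squares.
* class 1 (SPL):  penalized spline on a truncated line basis,
  f(t) = beta0 + beta1 t + sum_k u_k (t - kappa_k)_+, where the spline
  coefficients u_k are i.i.d. N(0, sigma_u^2) random effects — the mixed
  model representation of a penalized spline, with implied penalty
  lambda = sigma_eps^2 / sigma_u^2 chosen by maximum likelihood.
* class 2 (SSI):  adds a subject-specific random intercept U_i ~
  N(0, sigma_U^2), giving subject curves parallel to the population curve.
* class 3 (SSIS): subject-specific random intercepts and slopes
  (a_i0, a_i1) with a diagonal covariance (independent intercept/slope).

A molecule is promoted from one class to the next only when a likelihood
ratio test (ML likelihoods, chi-square reference with 1 df per step, no
boundary correction — deliberately conservative for variance-component
tests) rejects the simpler model at level ``alpha``.

The derivative of the fitted population curve (DLMMS) is piecewise
constant: f'(t) = beta1 + sum_k u_k 1[t >= kappa_k]; for a class-0 fit it
is the constant estimated slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import LmmDesign, LmmResult, ols_loglik
from .timecourse import TimeCourseExperiment, to_long

logger = logging.getLogger(__name__)

MODEL_NAMES = {0: "LIN", 1: "SPL", 2: "SSI", 3: "SSIS"}


def knot_count(T: int) -> int:
    """Number of spline knots from the number of distinct time points T.

    K = max(5, min(floor(T/4), 40)).
    """
    T = int(T)
    if T < 2:
        raise ValueError("need at least 2 distinct time points")
    return max(5, min(T // 4, 40))


def truncated_line_basis(t, knots) -> np.ndarray:
    """Truncated line basis (t - kappa_k)_+ evaluated at times ``t``.

    Returns an array of shape (len(t), len(knots)); component k is
    t - kappa_k where that is positive and 0 otherwise.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    knots = np.asarray(knots, dtype=float)
    d = t[:, None] - knots[None, :]
    return np.where(d > 0, d, 0.0)


@dataclass(frozen=True)
class SplineBasis:
    """Knot set for the truncated line basis."""

    knots: tuple[float, ...]

    @property
    def K(self) -> int:
        return len(self.knots)

    @classmethod
    def from_times(cls, times) -> "SplineBasis":
        """Knots at equally spaced empirical quantiles of observed times.

        The knot count comes from ``knot_count`` applied to the number of
        distinct times; positions are type-7 (linear interpolation)
        quantiles at probabilities k/(K+1) of the raw time values
        (replicate multiplicity included).  Duplicate knots and knots on
        or outside the boundary of the observed range are dropped: a knot
        at the minimum time yields a basis column collinear with the
        linear term and a knot at the maximum a zero column.
        """
        times = np.asarray(times, dtype=float)
        T = np.unique(times).size
        K = knot_count(T)
        probs = np.arange(1, K + 1) / (K + 1)
        knots = np.unique(np.quantile(times, probs))
        lo, hi = times.min(), times.max()
        knots = knots[(knots > lo) & (knots < hi)]
        if knots.size < K:
            logger.debug("knot set reduced from %d to %d after "
                         "deduplication/boundary removal", K, knots.size)
        return cls(tuple(knots))

    def design(self, t) -> np.ndarray:
        return truncated_line_basis(t, self.knots)


@dataclass
class LmmsFit:
    """One molecule's fitted model of a given class."""

    model_class: int
    beta0: float
    beta1: float
    u: np.ndarray                   # BLUPs of the spline coefficients
    sigma2_eps: float
    sigma2_u: float | None          # spline coefficient variance (class >=1)
    sigma2_subject: float | None    # sigma_U^2 (class 2) / sigma_a0^2 (class 3)
    sigma2_slope: float | None      # sigma_a1^2 (class 3)
    loglik_ml: float
    basis: SplineBasis
    n_obs: int
    converged: bool
    subject_effects: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return MODEL_NAMES[self.model_class]


@dataclass
class SerialSelectionResult:
    """Outcome of the serial (nested LRT) model selection."""

    chosen: LmmsFit
    steps: list[tuple[int, int, float, int, float]]  # (null, alt, stat, df, p)
    alpha: float


def _profile_arrays(profile: pd.DataFrame):
    p = profile.dropna(subset=["value"])
    return (p["subject"].to_numpy(str), p["time"].to_numpy(float),
            p["value"].to_numpy(float))


def _design_blocks(t, subj, basis: SplineBasis, model_class: int):
    X = np.column_stack([np.ones_like(t), t])
    blocks = []
    if model_class >= 1:
        blocks.append(basis.design(t))
    if model_class >= 2:
        levels, idx = np.unique(subj, return_inverse=True)
        S = np.zeros((t.size, levels.size))
        S[np.arange(t.size), idx] = 1.0
        blocks.append(S)
        if model_class >= 3:
            blocks.append(S * t[:, None])
    return X, blocks


def fit_model(profile: pd.DataFrame, model_class: int,
              basis: SplineBasis | None = None,
              theta0=None) -> LmmsFit:
    """Fit one of the four model classes to a molecule's records.

    ``profile`` has columns subject/time/value (missing values dropped).
    Class 0 is plain OLS; classes 1-3 are variance-component mixed models
    fitted by ML, with the spline coefficients predicted as BLUPs.
    """
    subj, t, y = _profile_arrays(profile)
    if basis is None:
        basis = SplineBasis.from_times(t)
    n_subj = np.unique(subj).size
    if model_class >= 2 and n_subj < 2:
        raise ValueError("subject random effects need at least 2 subjects")
    if model_class >= 3:
        counts = pd.Series(subj).value_counts()
        if (counts >= 2).sum() < 2:
            raise ValueError("random slopes need >=2 observations for >=2 "
                             "subjects")
    if y.size < 3:
        raise ValueError("too few observations")

    if model_class == 0:
        X = np.column_stack([np.ones_like(t), t])
        beta, sigma2, ll = ols_loglik(y, X)
        return LmmsFit(0, beta[0], beta[1], np.zeros(basis.K), sigma2,
                       None, None, None, ll, basis, y.size, True)

    X, blocks = _design_blocks(t, subj, basis, model_class)
    design = LmmDesign(X, blocks)
    res = design.fit(y, theta0=theta0)
    s2 = list(res.sigma2_blocks) + [None, None]
    subject_effects = {}
    if model_class >= 2:
        levels = np.unique(subj)
        subject_effects["intercept"] = dict(zip(levels, res.u[1]))
        if model_class >= 3:
            subject_effects["slope"] = dict(zip(levels, res.u[2]))
    return LmmsFit(model_class, res.beta[0], res.beta[1], res.u[0],
                   res.sigma2_eps, s2[0],
                   s2[1] if model_class >= 2 else None,
                   s2[2] if model_class >= 3 else None,
                   res.loglik, basis, y.size, res.converged,
                   subject_effects)


def select_model(profile: pd.DataFrame, basis: SplineBasis | None = None,
                 alpha: float = 0.05) -> SerialSelectionResult:
    """Serial model selection by likelihood ratio tests.

    Fits class 0, then successively tests 1 vs 0, 2 vs 1, 3 vs 2 (ML
    likelihoods, chi2 with 1 df per promotion), stopping at the first
    non-rejection.  A non-converged alternative counts as non-promotion.
    """
    subj, t, y = _profile_arrays(profile)
    if basis is None:
        basis = SplineBasis.from_times(t)
    n_subj = np.unique(subj).size
    counts = pd.Series(subj).value_counts()
    max_class = 1
    if n_subj >= 2:
        max_class = 2
        if (counts >= 2).sum() >= 2:
            max_class = 3

    prof = pd.DataFrame({"subject": subj, "time": t, "value": y})
    current = fit_model(prof, 0, basis)
    steps: list[tuple[int, int, float, int, float]] = []
    theta_prev: np.ndarray | None = None
    for alt in range(1, max_class + 1):
        theta0 = None
        if theta_prev is not None:
            theta0 = np.append(theta_prev, -6.0)    # new block nearly off
        try:
            cand = fit_model(prof, alt, basis, theta0=theta0)
        except ValueError:
            break
        stat = max(2.0 * (cand.loglik_ml - current.loglik_ml), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        steps.append((alt - 1, alt, stat, 1, p))
        if not cand.converged:
            logger.warning("class %d fit did not converge; keeping class %d",
                           alt, current.model_class)
            break
        if p >= alpha:
            break
        current = cand
        theta_prev = _theta_of(cand)
    return SerialSelectionResult(current, steps, alpha)


def _theta_of(fit: LmmsFit) -> np.ndarray:
    ratios = [fit.sigma2_u]
    if fit.model_class >= 2:
        ratios.append(fit.sigma2_subject)
    if fit.model_class >= 3:
        ratios.append(fit.sigma2_slope)
    eps = max(fit.sigma2_eps, 1e-12)
    return np.log(np.maximum(np.asarray(ratios, float) / eps, 1e-12))


def predict_curve(fit: LmmsFit, times) -> np.ndarray:
    """Fitted population curve f(t) = beta0 + beta1 t + sum u_k (t-k)_+."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    f = fit.beta0 + fit.beta1 * t
    if fit.model_class >= 1 and fit.basis.K:
        f = f + fit.basis.design(t) @ fit.u
    return f


def derivative(fit: LmmsFit, times) -> np.ndarray:
    """Piecewise-constant derivative of the fitted population curve."""
    t = np.atleast_1d(np.asarray(times, dtype=float))
    d = np.full(t.shape, fit.beta1, dtype=float)
    if fit.model_class >= 1 and fit.basis.K:
        ind = (t[:, None] - np.asarray(fit.basis.knots)[None, :]) >= 0
        d = d + ind @ fit.u
    return d


@dataclass
class ModelledProfiles:
    """Fitted curves for a whole experiment."""

    curves: pd.DataFrame                 # molecules x grid
    derivatives: pd.DataFrame | None
    selections: dict[str, SerialSelectionResult]
    failed: list[str]

    @property
    def class_counts(self) -> pd.Series:
        counts = pd.Series(
            [sel.chosen.name for sel in self.selections.values()],
            dtype=object).value_counts()
        return counts.reindex([MODEL_NAMES[c] for c in range(4)],
                              fill_value=0)


def model_all(exp: TimeCourseExperiment, alpha: float = 0.05,
              grid=None, with_derivative: bool = False) -> ModelledProfiles:
    """Serially model every molecule and evaluate the fitted curves.

    ``grid`` defaults to the sorted distinct observed times.  Molecules
    whose fits fail are dropped from the output with a warning.
    """
    if grid is None:
        grid = exp.distinct_times
    grid = np.asarray(grid, dtype=float)
    basis = SplineBasis.from_times(exp.times)
    long = to_long(exp)
    selections: dict[str, SerialSelectionResult] = {}
    failed: list[str] = []
    rows, drows = [], []
    for mol, prof in long.groupby("molecule", sort=False):
        try:
            sel = select_model(prof, basis=basis, alpha=alpha)
        except (ValueError, FloatingPointError) as err:
            logger.warning("molecule %s could not be modelled: %s", mol, err)
            failed.append(mol)
            continue
        selections[mol] = sel
        rows.append(pd.Series(predict_curve(sel.chosen, grid), index=grid,
                              name=mol))
        if with_derivative:
            drows.append(pd.Series(derivative(sel.chosen, grid), index=grid,
                                   name=mol))
    curves = pd.DataFrame(rows)
    derivs = pd.DataFrame(drows) if with_derivative else None
    return ModelledProfiles(curves, derivs, selections, failed)
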