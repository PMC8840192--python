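"""Imputation-based natural effect models for a multi-categorical exposure.

The total effect of the exposure (here, a 5-level group label) on a
continuous outcome (a genus's CLR abundance) is decomposed into a natural
indirect effect transmitted through one mediator (a dietary factor) and a
natural direct effect, per non-reference group, by:

1. fitting a working outcome regression ``Y ~ exposure + mediator +
   confounders`` (the imputation model);
2. expanding the data so each subject contributes one row per hypothetical
   exposure level ``x0``, keeping the mediator-driving exposure ``x1`` at
   the observed level, and imputing the counterfactual outcome
   ``Yhat = E[Y | x0, M_i, C_i]`` from the working model;
3. fitting the natural effect model ``Yhat ~ x0 + x1 + confounders`` on the
   expanded data: the ``x0 = k`` coefficient is the natural direct effect
   of group k versus the reference, the ``x1 = k`` coefficient the natural
   indirect effect, and their sum the total effect.

With a linear working model and no exposure-mediator interaction this
estimator coincides exactly with the product-of-coefficients decomposition
(mediator coefficient from the outcome model times the group coefficient
from ``M ~ exposure + confounders``), which serves as an independent oracle
in the tests. Standard errors come from resampling subjects with
replacement (stratified by exposure group) and refitting the whole
procedure; p-values use the two-sided normal approximation z = estimate/SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .factors import DietFactorSpec

__all__ = [
    "ImputationFit",
    "ExpandedData",
    "NaturalEffects",
    "MediationEstimate",
    "fit_imputation_model",
    "expand_counterfactuals",
    "fit_natural_effect_model",
    "estimate_natural_effects",
    "bootstrap_mediation",
    "percent_mediated",
    "bonferroni_threshold",
    "transform_mediator",
]


def _as_1d(x) -> np.ndarray:
    return np.asarray(x).reshape(-1)


def _as_2d(x, n) -> np.ndarray:
    if x is None:
        return np.empty((n, 0))
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _levels_and_codes(exposure, reference):
    labels = _as_1d(exposure)
    uniq = pd.unique(labels)
    if reference not in uniq:
        raise ValueError(f"reference level {reference!r} absent from the data")
    levels = [reference] + sorted(str(u) for u in uniq if u != reference)
    lookup = {lev: i for i, lev in enumerate(levels)}
    codes = np.array([lookup[str(v)] for v in labels])
    return levels, codes


def _collinear_columns(X: np.ndarray, names=None) -> list[str]:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    bad = sorted(piv[rank:])
    return [names[i] if names else f"column {i}" for i in bad]


def _ols(X: np.ndarray, y: np.ndarray, names=None) -> np.ndarray:
    """Least squares with a collinearity check naming offending columns.

    Solves the normal equations via Cholesky (the designs here are small and
    well-scaled; this is the bootstrap hot path). A singular Gram matrix
    falls back to pivoted QR purely to identify the dependent columns.
    """
    gram = X.T @ X
    try:
        cho = linalg.cho_factor(gram, check_finite=False)
        coef = linalg.cho_solve(cho, X.T @ y, check_finite=False)
    except linalg.LinAlgError:
        cols = _collinear_columns(X, names)
        raise ValueError(
            f"design matrix is collinear; offending columns: {cols}") from None
    if not np.all(np.isfinite(coef)):
        cols = _collinear_columns(X, names)
        raise ValueError(f"design matrix is collinear; offending columns: {cols}")
    return coef


@dataclass
class ImputationFit:
    """Fitted working outcome regression Y ~ exposure + mediator + confounders."""

    levels: list[str]          # reference first
    intercept: float
    exposure_coefs: np.ndarray  # length L, entry 0 (reference) fixed at 0
    mediator_coef: float
    confounder_coefs: np.ndarray

    @property
    def reference(self) -> str:
        return self.levels[0]

    def predict(self, exposure_codes, mediator, confounders=None) -> np.ndarray:
        codes = np.asarray(exposure_codes)
        if codes.min() < 0 or codes.max() >= len(self.levels):
            raise ValueError("unseen exposure level at prediction")
        m = _as_1d(mediator).astype(float)
        C = _as_2d(confounders, len(m))
        return (self.intercept + self.exposure_coefs[codes]
                + self.mediator_coef * m + C @ self.confounder_coefs)


def fit_imputation_model(
    outcome, exposure, mediator, confounders=None, reference=None,
    confounder_names=None,
) -> ImputationFit:
    """OLS of the outcome on exposure dummies + mediator + confounders.

    ``reference`` (default: first label in sorted order) is the omitted
    exposure level. Raises on a constant mediator or a collinear design.
    """
    y = _as_1d(outcome).astype(float)
    m = _as_1d(mediator).astype(float)
    if np.ptp(m) == 0:
        raise ValueError("mediator is constant")
    if reference is None:
        reference = sorted(str(u) for u in pd.unique(_as_1d(exposure)))[0]
    levels, codes = _levels_and_codes(exposure, reference)
    L = len(levels)
    if L < 2:
        raise ValueError("need at least two exposure levels")
    C = _as_2d(confounders, len(y))
    n = len(y)
    D = np.zeros((n, L - 1))
    D[np.arange(n), codes - 1] = codes > 0
    X = np.column_stack([np.ones(n), D, m, C])
    names = (["intercept"] + [f"exposure[{lev}]" for lev in levels[1:]]
             + ["mediator"]
             + list(confounder_names or [f"confounder_{j}" for j in range(C.shape[1])]))
    coef = _ols(X, y, names)
    return ImputationFit(
        levels=levels,
        intercept=float(coef[0]),
        exposure_coefs=np.concatenate([[0.0], coef[1:L]]),
        mediator_coef=float(coef[L]),
        confounder_coefs=coef[L + 1:],
    )


@dataclass
class ExpandedData:
    """Counterfactual-expanded data: one row per subject per x0 level.

    ``x1`` is the subject's observed exposure (constant within subject);
    ``yhat`` the imputed counterfactual outcome Y(x0, M(x1)).
    """

    levels: list[str]
    subject: np.ndarray   # n*L ints, subject index
    x0: np.ndarray        # n*L codes into levels
    x1: np.ndarray        # n*L codes into levels
    yhat: np.ndarray
    confounders: np.ndarray

    @property
    def reference(self) -> str:
        return self.levels[0]


def expand_counterfactuals(exposure, mediator, fit: ImputationFit,
                           confounders=None) -> ExpandedData:
    """Expand each subject over all hypothetical exposure levels.

    For subject i and level x0, the imputed outcome is the working model's
    prediction at (x0, M_i, C_i); the row at x0 = observed exposure equals
    the subject's fitted value.
    """
    labels = _as_1d(exposure)
    lookup = {lev: i for i, lev in enumerate(fit.levels)}
    try:
        x1 = np.array([lookup[str(v)] for v in labels])
    except KeyError as exc:
        raise ValueError(f"unseen exposure level at prediction: {exc}") from exc
    m = _as_1d(mediator).astype(float)
    n, L = len(labels), len(fit.levels)
    C = _as_2d(confounders, n)
    subject = np.repeat(np.arange(n), L)
    x0 = np.tile(np.arange(L), n)
    yhat = fit.predict(x0, m[subject], C[subject])
    return ExpandedData(
        levels=fit.levels, subject=subject, x0=x0, x1=x1[subject],
        yhat=yhat, confounders=C[subject],
    )


@dataclass
class NaturalEffects:
    """Natural direct/indirect/total effects per non-reference group."""

    reference: str
    nde: pd.Series
    nie: pd.Series
    te: pd.Series

    def __post_init__(self) -> None:
        # decomposition identity: the total effect is defined as the sum
        assert np.allclose(self.te, self.nde + self.nie, atol=1e-10)


def fit_natural_effect_model(expanded: ExpandedData) -> NaturalEffects:
    """OLS of the imputed outcome on x0 dummies + x1 dummies + confounders.

    The x0 = k coefficient is nde_k, the x1 = k coefficient nie_k, and
    te_k = nde_k + nie_k (reference = the expansion's reference level).
    """
    L = len(expanded.levels)
    if not np.any(expanded.x1 == 0):
        raise ValueError(
            f"reference level {expanded.reference!r} absent from the expanded data")
    rows = len(expanded.yhat)
    D0 = np.zeros((rows, L - 1))
    D0[np.arange(rows), expanded.x0 - 1] = expanded.x0 > 0
    D1 = np.zeros((rows, L - 1))
    D1[np.arange(rows), expanded.x1 - 1] = expanded.x1 > 0
    X = np.column_stack([np.ones(rows), D0, D1, expanded.confounders])
    names = (["intercept"] + [f"x0[{lev}]" for lev in expanded.levels[1:]]
             + [f"x1[{lev}]" for lev in expanded.levels[1:]]
             + [f"confounder_{j}" for j in range(expanded.confounders.shape[1])])
    coef = _ols(X, expanded.yhat, names)
    idx = pd.Index(expanded.levels[1:], name="group")
    nde = pd.Series(coef[1:L], index=idx, name="nde")
    nie = pd.Series(coef[L:2 * L - 1], index=idx, name="nie")
    return NaturalEffects(reference=expanded.reference, nde=nde, nie=nie,
                          te=(nde + nie).rename("te"))


def estimate_natural_effects(outcome, exposure, mediator, confounders=None,
                             reference=None) -> NaturalEffects:
    """Full point-estimation chain: impute, expand, fit the natural effect model."""
    fit = fit_imputation_model(outcome, exposure, mediator, confounders, reference)
    expanded = expand_counterfactuals(exposure, mediator, fit, confounders)
    return fit_natural_effect_model(expanded)


@dataclass
class MediationEstimate:
    """Point estimates with bootstrap SEs and normal-approximation p-values.

    ``effects`` is indexed by non-reference group with columns te, nde, nie,
    se_te, se_nde, se_nie, p_te, p_nde, p_nie and percent_mediated.
    """

    reference: str
    effects: pd.DataFrame
    n_boot: int
    seed: int | None = None


def _core_natural_effects(y, codes, m, C, L):
    """Label-free refit path used inside the bootstrap loop.

    Same computation as fit_imputation_model -> expand_counterfactuals ->
    fit_natural_effect_model, on pre-encoded exposure codes (reference = 0).
    Returns (nde, nie) arrays over the L-1 non-reference levels.
    """
    n = len(y)
    D = np.zeros((n, L - 1))
    D[np.arange(n), codes - 1] = codes > 0
    X1 = np.column_stack([np.ones(n), D, m, C])
    coef = _ols(X1, y)
    bX = np.concatenate([[0.0], coef[1:L]])
    base = coef[0] + coef[L] * m + C @ coef[L + 1:]
    yhat = (base[:, None] + bX[None, :]).ravel()
    D0 = np.tile(np.eye(L)[:, 1:], (n, 1))
    D1 = np.repeat(D, L, axis=0)
    X2 = np.column_stack([np.ones(n * L), D0, D1, np.repeat(C, L, axis=0)])
    coef2 = _ols(X2, yhat)
    return coef2[1:L], coef2[L:2 * L - 1]


def _stratified_resample(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for code in np.unique(codes):
        members = np.flatnonzero(codes == code)
        idx.append(members[rng.integers(0, len(members), len(members))])
    return np.concatenate(idx)


def bootstrap_mediation(
    outcome, exposure, mediator, confounders=None, reference=None,
    n_boot: int = 100, seed: int | None = None, stratify: bool = True,
    max_redraw: int = 10,
) -> MediationEstimate:
    """Natural effect decomposition with bootstrap inference.

    Subjects are resampled with replacement within exposure groups
    (``stratify=True``, the default, guarantees every level survives every
    replicate); the SE of each coefficient is the SD of its ``n_boot``
    replicate values and p-values use z = estimate / SE two-sided. With
    ``stratify=False`` a replicate that loses an entire exposure level is
    redrawn, at most ``max_redraw`` times per replicate.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    y = _as_1d(outcome).astype(float)
    labels = _as_1d(exposure)
    m = _as_1d(mediator).astype(float)
    C = _as_2d(confounders, len(y))
    point = estimate_natural_effects(y, labels, m, C, reference)
    levels, codes = _levels_and_codes(labels, point.reference)

    rng = np.random.default_rng(seed)
    L = len(levels)
    reps = np.empty((n_boot, 2, L - 1))  # (replicate, nde/nie, group)
    for b in range(n_boot):
        for attempt in range(max_redraw + 1):
            idx = (_stratified_resample(codes, rng) if stratify
                   else rng.integers(0, len(y), len(y)))
            if len(np.unique(codes[idx])) == L:
                break
        else:
            raise RuntimeError(
                f"bootstrap replicate lost an exposure level {max_redraw + 1} times")
        reps[b, 0], reps[b, 1] = _core_natural_effects(
            y[idx], codes[idx], m[idx], C[idx], L)

    se_nde = reps[:, 0].std(axis=0, ddof=1)
    se_nie = reps[:, 1].std(axis=0, ddof=1)
    se_te = (reps[:, 0] + reps[:, 1]).std(axis=0, ddof=1)

    def _pvals(est, se):
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf * np.sign(est))
        return 2 * stats.norm.sf(np.abs(z))

    effects = pd.DataFrame({
        "te": point.te, "nde": point.nde, "nie": point.nie,
        "se_te": se_te, "se_nde": se_nde, "se_nie": se_nie,
        "p_te": _pvals(point.te.to_numpy(), se_te),
        "p_nde": _pvals(point.nde.to_numpy(), se_nde),
        "p_nie": _pvals(point.nie.to_numpy(), se_nie),
    })
    effects["percent_mediated"] = [
        percent_mediated(r.nie, r.te) for r in effects.itertuples()
    ]
    return MediationEstimate(reference=point.reference, effects=effects,
                             n_boot=n_boot, seed=seed)


def percent_mediated(nie: float, te: float, tol: float = 1e-12) -> float:
    """100 * nie / te; NaN (not applicable) when the total effect is ~0."""
    if abs(te) < tol:
        return float("nan")
    return 100.0 * nie / te


def bonferroni_threshold(alpha: float, n_genera: int, n_factors: int,
                         n_comparisons: int) -> float:
    """Familywise per-test threshold alpha / (genera * factors * comparisons)."""
    for name, v in [("alpha", alpha), ("n_genera", n_genera),
                    ("n_factors", n_factors), ("n_comparisons", n_comparisons)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return alpha / (n_genera * n_factors * n_comparisons)


def transform_mediator(values, spec: DietFactorSpec) -> np.ndarray:
    """Put a dietary factor on its modelling scale.

    Log for intake amounts, identity for the diet-quality index. Zeros are
    offset by half the smallest positive observed value before the log
    (configurable upstream by pre-offsetting); negative values are invalid.
    """
    v = _as_1d(values).astype(float)
    if not spec.log_transform:
        return v
    if (v < 0).any():
        raise ValueError(f"{spec.name}: negative intake values cannot be log-transformed")
    if (v == 0).any():
        positive = v[v > 0]
        if positive.size == 0:
            raise ValueError(f"{spec.name}: all intake values are zero")
        v = v + positive.min() / 2.0
    return np.log(v)
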