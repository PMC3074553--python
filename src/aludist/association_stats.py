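"""Regression and enrichment statistics.

Two-step motif regression: because a large fraction of genes have zero intron
Alu density, a single linear model on (log) density is unusable.  Instead,
per chromosome:

  Model-1 (logistic):  z = 1{Di > 0}  ~  mu + alpha * log10_size + beta * Mi
  Model-2 (OLS, Di>0): Di             ~  mu* + alpha* * log10_size + beta* * Mi

with the beta p-values Benjamini-Hochberg adjusted across chromosomes
separately per model, and the motif's contribution measured as the increase
in Nagelkerke pseudo-R^2 (Model-1) or plain R^2 (Model-2) over the reduced
model containing log10_size only.

Mutation-class associations reuse the Model-1 form with the class indicator
as response and (Di, log10_size) as default covariates.  Cluster-vs-class
enrichment uses Fisher's exact test (two-sided, point-probability method).

Fits go through statsmodels (GLM-Binomial IRLS / OLS); Wald tests per term.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmFit",
    "TwoStepResult",
    "AssociationResult",
    "fit_logistic",
    "fit_linear",
    "nagelkerke_r2",
    "nagelkerke_contribution",
    "bh_adjust",
    "two_step_motif_analysis",
    "class_association",
    "fisher_exact_2x2",
    "SeparationWarning",
    "AssociationError",
]

# report-generation wording thresholds
EXTREME_P = 0.001
MARGINAL_P = 0.05


class AssociationError(ValueError):
    pass


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation: estimates finite but unstable."""


@dataclass(frozen=True)
class GlmFit:
    """One fitted model: per-term coefficients, SEs, Wald p-values, log-likelihood."""

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    loglik: float
    n: int
    r_squared: float | None = None  # OLS only
    separation: bool = False


def _design(X: pd.DataFrame) -> pd.DataFrame:
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    return Xd


def fit_logistic(y, X: pd.DataFrame) -> GlmFit:
    """Logistic regression by IRLS with an intercept added automatically.

    *y* must be binary with both classes present; *X* a DataFrame of named
    covariates with full column rank.  Perfect separation is flagged with
    :class:`SeparationWarning` and finite (iteration-capped) estimates.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise AssociationError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise AssociationError("response is single-class; logistic fit undefined")
    Xd = _design(X)
    if np.linalg.matrix_rank(Xd.values) < Xd.shape[1]:
        raise AssociationError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xd, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-10)
    mu = res.fittedvalues
    separation = bool(np.any(np.abs(res.params) > 15) or np.any(mu * (1 - mu) < 1e-10))
    if separation:
        warnings.warn(
            "perfect or quasi-perfect separation detected; estimates capped at "
            "the iteration limit",
            SeparationWarning,
            stacklevel=2,
        )
    return GlmFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        loglik=float(res.llf),
        n=int(len(y)),
        separation=separation,
    )


def fit_linear(y, X: pd.DataFrame) -> GlmFit:
    """Ordinary least squares with intercept; t-test p-values and R^2."""
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    if len(y) <= Xd.shape[1]:
        raise AssociationError("need more observations than model terms")
    if np.linalg.matrix_rank(Xd.values) < Xd.shape[1]:
        raise AssociationError("design matrix is rank deficient")
    res = sm.OLS(y, Xd).fit()
    return GlmFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        loglik=float(res.llf),
        n=int(len(y)),
        r_squared=float(res.rsquared),
    )


def nagelkerke_r2(model: GlmFit, null: GlmFit) -> float:
    """Nagelkerke pseudo-R^2 of *model* against the intercept-only *null*.

    R^2_CS = 1 - exp((2/n)(ll_null - ll_model)), normalized by its maximum
    1 - exp((2/n) ll_null).
    """
    if model.n != null.n:
        raise AssociationError("models fitted on different numbers of observations")
    n = model.n
    r2_cs = 1.0 - math.exp((2.0 / n) * (null.loglik - model.loglik))
    r2_max = 1.0 - math.exp((2.0 / n) * null.loglik)
    return r2_cs / r2_max


def nagelkerke_contribution(full: GlmFit, reduced: GlmFit, null: GlmFit) -> float:
    """Increase in Nagelkerke R^2 from *reduced* to the nesting *full* model.

    Clipped at 0 if numerically negative.
    """
    if not (full.n == reduced.n == null.n):
        raise AssociationError("models fitted on different numbers of observations")
    return max(0.0, nagelkerke_r2(full, null) - nagelkerke_r2(reduced, null))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise AssociationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TwoStepResult:
    """Per-chromosome two-step regression outcome."""

    group: str
    model1: GlmFit | None
    model2: GlmFit | None
    contribution1: float | None  # Nagelkerke increase from adding Mi
    contribution2: float | None  # R^2 increase from adding Mi
    p1: float | None
    p2: float | None
    padj1: float | None = None
    padj2: float | None = None
    note: str = ""


def _with_adjusted(res: TwoStepResult, padj1, padj2) -> TwoStepResult:
    return TwoStepResult(
        group=res.group,
        model1=res.model1,
        model2=res.model2,
        contribution1=res.contribution1,
        contribution2=res.contribution2,
        p1=res.p1,
        p2=res.p2,
        padj1=padj1,
        padj2=padj2,
        note=res.note,
    )


def two_step_motif_analysis(
    features: pd.DataFrame,
    group_col: str = "chrom",
    min_genes: int = 10,
) -> list[TwoStepResult]:
    """Run the two-step motif regression per chromosome and BH-adjust across them.

    *features* needs columns ``Di``, ``Mi``, ``log10_size`` and *group_col*.
    Groups with fewer than *min_genes* genes are skipped; a group whose
    Alu-containing subset is smaller than *min_genes* (or has no Di > 0 at
    all) gets Model-1 only, with a diagnostic note.
    """
    results: list[TwoStepResult] = []
    for group, sub in features.groupby(group_col, sort=False):
        if len(sub) < min_genes:
            results.append(
                TwoStepResult(str(group), None, None, None, None, None, None,
                              note=f"skipped: only {len(sub)} genes")
            )
            continue
        z = (sub["Di"] > 0).astype(float).values
        note = ""
        m1 = c1 = p1 = None
        if len(np.unique(z)) == 2:
            X_full = sub[["log10_size", "Mi"]]
            X_red = sub[["log10_size"]]
            m1 = fit_logistic(z, X_full)
            m1_red = fit_logistic(z, X_red)
            m1_null = _fit_logistic_null(z)
            c1 = nagelkerke_contribution(m1, m1_red, m1_null)
            p1 = m1.pvalues["Mi"]
        else:
            note = "Model-1 skipped: Alu presence is constant"
        pos = sub[sub["Di"] > 0]
        m2 = c2 = p2 = None
        if len(pos) >= min_genes:
            m2 = fit_linear(pos["Di"].values, pos[["log10_size", "Mi"]])
            m2_red = fit_linear(pos["Di"].values, pos[["log10_size"]])
            c2 = max(0.0, (m2.r_squared or 0.0) - (m2_red.r_squared or 0.0))
            p2 = m2.pvalues["Mi"]
        else:
            note = (note + "; " if note else "") + (
                f"Model-2 skipped: only {len(pos)} Alu-containing genes"
            )
        results.append(TwoStepResult(str(group), m1, m2, c1, c2, p1, p2, note=note))

    # BH across chromosomes, separately per model
    idx1 = [i for i, r in enumerate(results) if r.p1 is not None]
    idx2 = [i for i, r in enumerate(results) if r.p2 is not None]
    padj1 = bh_adjust([results[i].p1 for i in idx1]) if idx1 else []
    padj2 = bh_adjust([results[i].p2 for i in idx2]) if idx2 else []
    adj1 = {i: v for i, v in zip(idx1, padj1)}
    adj2 = {i: v for i, v in zip(idx2, padj2)}
    return [
        _with_adjusted(r, adj1.get(i), adj2.get(i)) for i, r in enumerate(results)
    ]


def _fit_logistic_null(y) -> GlmFit:
    """Intercept-only logistic fit (closed form through GLM for consistency)."""
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(index=range(len(y)))
    Xd = sm.add_constant(X, has_constant="add")
    res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit()
    return GlmFit(
        params=dict(res.params),
        bse=dict(res.bse),
        pvalues=dict(res.pvalues),
        loglik=float(res.llf),
        n=int(len(y)),
    )


@dataclass(frozen=True)
class AssociationResult:
    """Logistic association between a binary gene classification and Alu features."""

    classification: str
    fit: GlmFit
    verdicts: dict[str, str] = field(default_factory=dict)


def class_association(
    features: pd.DataFrame,
    labels,
    classification: str = "class",
    covariates: tuple[str, ...] = ("Di", "log10_size"),
) -> AssociationResult:
    """Logistic fit of a binary class label on the chosen feature covariates.

    Default covariates are intron Alu density and log10 gene size; exon Alu
    density or nearest fragile-site distance can be added by name.
    """
    labels = np.asarray(labels, dtype=float)
    if len(labels) != len(features):
        raise AssociationError("labels and features differ in length")
    missing = [c for c in covariates if c not in features.columns]
    if missing:
        raise AssociationError(f"missing covariate columns: {missing}")
    fit = fit_logistic(labels, features[list(covariates)])
    verdicts = {}
    for term in covariates:
        p = fit.pvalues[term]
        if p < EXTREME_P:
            verdicts[term] = "extremely significant"
        elif p < MARGINAL_P:
            verdicts[term] = "marginally significant"
        else:
            verdicts[term] = "not significant"
    return AssociationResult(classification=classification, fit=fit, verdicts=verdicts)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(p, odds_ratio)``: the point-probability two-sided p (sum of
    hypergeometric table probabilities not exceeding the observed one) and
    the sample odds ratio ad/(bc) (inf when bc = 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise AssociationError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise AssociationError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise AssociationError("all table margins must be positive")
    a, b = t[0]
    c, d = t[1]
    p = float(stats.fisher_exact(t.astype(int), alternative="two-sided").pvalue)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return p, odds
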