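"""Regression layer: IRLS oracle agreement, BH, Nagelkerke, Fisher enumeration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from aludist import (
    AssociationError,
    bh_adjust,
    class_association,
    fisher_exact_2x2,
    fit_linear,
    fit_logistic,
    nagelkerke_contribution,
    nagelkerke_r2,
    simulate_class_labels,
    two_step_motif_analysis,
)
from aludist.association_stats import SeparationWarning, _fit_logistic_null


def _irls_logit(y, X, n_iter=100):
    """Independent hand-rolled IRLS oracle for logistic ML."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(n_iter):
        eta = Xd @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        beta_new = np.linalg.solve(Xd.T @ (W[:, None] * Xd), Xd.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


# -- logistic --------------------------------------------------------------


def test_logistic_matches_irls_oracle():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 2))
    eta = 0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
    y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(y, pd.DataFrame(X, columns=["a", "b"]))
    oracle = _irls_logit(y, X)
    assert fit.params["const"] == pytest.approx(oracle[0], abs=1e-8)
    assert fit.params["a"] == pytest.approx(oracle[1], abs=1e-8)
    assert fit.params["b"] == pytest.approx(oracle[2], abs=1e-8)


def test_logistic_recovers_true_beta_within_3se():
    rng = np.random.default_rng(1)
    x = rng.normal(size=2000)
    y = (rng.random(2000) < 1 / (1 + np.exp(-(0.0 + 1.0 * x)))).astype(float)
    fit = fit_logistic(y, pd.DataFrame({"x": x}))
    assert abs(fit.params["x"] - 1.0) <= 3 * fit.bse["x"]


def test_logistic_rejects_degenerate_inputs():
    with pytest.raises(AssociationError):
        fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10)}))
    with pytest.raises(AssociationError):
        fit_logistic(np.array([0, 1, 2, 1]), pd.DataFrame({"x": np.arange(4)}))


def test_perfect_separation_flagged_finite():
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
    with pytest.warns(SeparationWarning):
        fit = fit_logistic(y, X)
    assert fit.separation
    assert np.isfinite(fit.params["x"])


# -- linear ----------------------------------------------------------------


def test_ols_exact_line():
    x = np.arange(10, dtype=float)
    fit = fit_linear(2 * x, pd.DataFrame({"x": x}))
    assert fit.params["x"] == pytest.approx(2.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 2))
    y = 1.0 + 0.5 * X[:, 0] - 2.0 * X[:, 1] + rng.normal(scale=0.3, size=50)
    fit = fit_linear(y, pd.DataFrame(X, columns=["a", "b"]))
    Xd = np.column_stack([np.ones(50), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    for name, val in zip(["const", "a", "b"], beta):
        assert fit.params[name] == pytest.approx(val, abs=1e-8)


def test_ols_collinear_rejected():
    x = np.arange(10, dtype=float)
    with pytest.raises(AssociationError):
        fit_linear(x, pd.DataFrame({"a": x, "b": 2 * x}))


# -- Nagelkerke ------------------------------------------------------------


def test_nagelkerke_contribution_zero_when_models_equal():
    rng = np.random.default_rng(3)
    y = (rng.random(100) < 0.5).astype(float)
    x = rng.normal(size=100)
    fit = fit_logistic(y, pd.DataFrame({"x": x}))
    null = _fit_logistic_null(y)
    assert nagelkerke_contribution(fit, fit, null) == 0.0


def test_nagelkerke_agrees_with_direct_formula():
    rng = np.random.default_rng(4)
    x = rng.normal(size=300)
    y = (rng.random(300) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
    full = fit_logistic(y, pd.DataFrame({"x": x}))
    null = _fit_logistic_null(y)
    n = 300
    r2_direct = (1 - math.exp(2 / n * (null.loglik - full.loglik))) / (
        1 - math.exp(2 / n * null.loglik)
    )
    assert nagelkerke_r2(full, null) == pytest.approx(r2_direct, abs=1e-10)


def test_nagelkerke_mismatched_n_rejected():
    rng = np.random.default_rng(5)
    y1 = (rng.random(50) < 0.5).astype(float)
    y2 = (rng.random(60) < 0.5).astype(float)
    f1 = _fit_logistic_null(y1)
    f2 = _fit_logistic_null(y2)
    with pytest.raises(AssociationError):
        nagelkerke_contribution(f1, f1, f2)


def test_strong_coupling_contribution_near_one_third():
    """Small-chromosome regime with strong motif-presence coupling: the motif
    term's Nagelkerke contribution lands in the vicinity of 0.33."""
    import warnings

    rng = np.random.default_rng(6)
    contribs = []
    for _ in range(60):
        n = 93
        size = rng.normal(4.4, 0.35, n)
        mi = rng.gamma(2.0, 0.5, n)
        # ~31% of genes Alu-containing, strong motif coupling on the logit
        eta = -0.8 + 2.0 * (mi - mi.mean())
        z = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        if len(np.unique(z)) < 2:
            continue
        X_full = pd.DataFrame({"log10_size": size, "Mi": mi})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            full = fit_logistic(z, X_full)
            red = fit_logistic(z, X_full[["log10_size"]])
        null = _fit_logistic_null(z)
        contribs.append(nagelkerke_contribution(full, red, null))
    assert np.median(contribs) == pytest.approx(0.33, abs=0.12)


# -- BH --------------------------------------------------------------------


def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_single_p_unchanged():
    assert bh_adjust([0.2]) == pytest.approx([0.2])


def test_bh_monotone_and_dominates_raw():
    rng = np.random.default_rng(7)
    p = rng.random(50)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(AssociationError):
        bh_adjust([0.5, 1.5])


# -- two-step analysis -----------------------------------------------------


def _synthetic_features(rng, n, coupling_presence=0.0, coupling_intensity=0.0, chrom="chr1"):
    size = rng.normal(4.4, 0.35, n)
    mi = rng.gamma(2.0, 0.5, n)
    eta = 0.8 + coupling_presence * (mi - mi.mean())
    z = rng.random(n) < 1 / (1 + np.exp(-eta))
    di = np.where(z, rng.gamma(0.615, 1.303, n) + coupling_intensity * mi, 0.0)
    return pd.DataFrame({"chrom": chrom, "Di": di, "Mi": mi, "log10_size": size})


def test_two_step_detects_coupled_chromosomes():
    rng = np.random.default_rng(8)
    frames = [
        _synthetic_features(rng, 400, coupling_presence=2.0, coupling_intensity=0.8, chrom="chrA"),
        _synthetic_features(rng, 400, chrom="chrB"),
    ]
    results = two_step_motif_analysis(pd.concat(frames, ignore_index=True))
    by = {r.group: r for r in results}
    assert by["chrA"].padj1 < 0.05 and by["chrA"].padj2 < 0.05
    assert by["chrA"].model1.params["Mi"] > 0


def test_presence_only_coupling_hits_model1_not_model2():
    rng = np.random.default_rng(9)
    frames = [
        _synthetic_features(rng, 600, coupling_presence=2.0, chrom="chrA"),
        _synthetic_features(rng, 600, chrom="chrB"),
    ]
    results = two_step_motif_analysis(pd.concat(frames, ignore_index=True))
    by = {r.group: r for r in results}
    assert by["chrA"].padj1 < 0.05
    assert by["chrA"].padj2 > 0.05


def test_single_group_bh_is_identity():
    rng = np.random.default_rng(10)
    results = two_step_motif_analysis(_synthetic_features(rng, 200))
    (res,) = results
    assert res.padj1 == pytest.approx(res.p1)
    assert res.padj2 == pytest.approx(res.p2)


def test_all_zero_group_skips_model2():
    rng = np.random.default_rng(11)
    df = _synthetic_features(rng, 100, chrom="chrZ")
    df["Di"] = 0.0
    df2 = _synthetic_features(rng, 100, chrom="chrA")
    results = two_step_motif_analysis(pd.concat([df, df2], ignore_index=True))
    by = {r.group: r for r in results}
    assert by["chrZ"].model2 is None
    assert "Model-2 skipped" in by["chrZ"].note


# -- class association -----------------------------------------------------


def test_class_association_recovers_di_effect():
    rng = np.random.default_rng(12)
    n = 2000
    feats = pd.DataFrame(
        {"Di": rng.gamma(0.615, 1.303, n), "log10_size": rng.normal(4.4, 0.35, n)}
    )
    labels = simulate_class_labels(feats, intercept=-1.0, beta_di=1.5, beta_size=0.0, seed=13)
    res = class_association(feats, labels)
    assert res.fit.params["Di"] > 0
    assert res.fit.pvalues["Di"] < 0.001
    assert res.verdicts["Di"] == "extremely significant"


def test_class_association_single_class_rejected():
    feats = pd.DataFrame({"Di": [0.1, 0.2], "log10_size": [4.0, 4.5]})
    with pytest.raises(AssociationError):
        class_association(feats, [1, 1])


# -- Fisher ----------------------------------------------------------------


def _fisher_enumeration(table):
    """Brute-force two-sided Fisher p: enumerate all tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (
            special.comb(r1, aa, exact=True)
            * special.comb(r2, c1 - aa, exact=True)
            / special.comb(n, c1, exact=True)
        )

    p_obs = prob(a)
    return sum(prob(aa) for aa in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(aa) <= p_obs * (1 + 1e-9))


def test_fisher_published_table():
    p, odds = fisher_exact_2x2([[22, 26], [53, 249]])
    assert p == pytest.approx(_fisher_enumeration([[22, 26], [53, 249]]), rel=1e-9)
    assert odds == pytest.approx((22 * 249) / (26 * 53))


def test_fisher_balanced_table_p_one():
    p, odds = fisher_exact_2x2([[1, 1], [1, 1]])
    assert p == 1.0 and odds == 1.0


def test_fisher_diagonal_table():
    p, _ = fisher_exact_2x2([[5, 0], [0, 5]])
    assert p == pytest.approx(2 / 252)


def test_fisher_agrees_with_enumeration_small_totals():
    """Exhaustive check against hypergeometric enumeration, all margins, total <= 40."""
    rng = np.random.default_rng(14)
    checked = 0
    for total in (8, 12, 20, 30, 40):
        for _ in range(40):
            cuts = sorted(rng.integers(0, total + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            t = [[a, b], [c, d]]
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p, _ = fisher_exact_2x2(t)
            assert p == pytest.approx(_fisher_enumeration(t), rel=1e-9), t
            checked += 1
    assert checked > 100


def test_fisher_input_validation():
    with pytest.raises(AssociationError):
        fisher_exact_2x2([[1.5, 2], [3, 4]])
    with pytest.raises(AssociationError):
        fisher_exact_2x2([[-1, 2], [3, 4]])
    with pytest.raises(AssociationError):
        fisher_exact_2x2([[0, 0], [3, 4]])
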