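"""Robust statistical battery for group comparisons of CR/nVol measures.

The population distributions of contrast ratios and normalized volumes are
skewed and heteroscedastic, so group comparisons use trimmed means
(trimming fraction gamma = 0.2 by default) with winsorized variances:

* one-way heteroscedastic (Welch-type) ANOVA on trimmed means; at
  ``gamma = 0`` the statistic reduces exactly to Welch's ANOVA;
* two-way mixed (between x within) trimmed-means ANOVA using Johansen's
  approximation, for group-by-side, group-by-region and group-by-sequence
  designs;
* percentile-bootstrap post hoc comparisons of trimmed means (default 500
  resamples) with an explicit seed;
* a robust heteroscedastic generalization of Cohen's d (trimmed-mean
  difference scaled by rescaled winsorized SD, consistent for the classical
  d under normality);
* Pearson chi-square (two groups) and tie-corrected Kruskal-Wallis (three
  groups) for the categorical clinical variables;
* Bonferroni and Hochberg multiple-testing adjustment;
* Huber M-regression with robust (sandwich) Wald tests, and an
  all-relevant shadow-feature selector (Boruta scheme) in front of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "trimmed_mean",
    "winsorized_variance",
    "pearson_chi2",
    "kruskal_wallis",
    "yuen_t",
    "trimmed_anova_1way",
    "mixed_anova_2way",
    "bootstrap_posthoc",
    "robust_cohens_d",
    "adjust_pvalues",
    "huber_regression",
    "wald_test",
    "boruta_select",
    "counts_to_coded_samples",
]

DEFAULT_TRIM = 0.2


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...] | float | None
    p: float
    method: str
    p_adjusted: float | None = None
    effect_size: float | None = None
    ci: tuple[float, float] | None = None
    estimate: float | None = None
    flags: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trimmed/winsorized primitives
# ---------------------------------------------------------------------------


def trimmed_mean(x: np.ndarray, trim: float = DEFAULT_TRIM) -> float:
    x = np.asarray(x, dtype=float)
    return float(sps.trim_mean(x, trim)) if trim > 0 else float(x.mean())


def _winsorize(x: np.ndarray, trim: float) -> np.ndarray:
    x = np.sort(np.asarray(x, dtype=float))
    g = int(np.floor(trim * len(x)))
    if g > 0:
        x[:g] = x[g]
        x[len(x) - g :] = x[len(x) - g - 1]
    return x


def winsorized_variance(x: np.ndarray, trim: float = DEFAULT_TRIM) -> float:
    w = _winsorize(x, trim)
    return float(np.var(w, ddof=1))


def _winsorized_column(x: np.ndarray, trim: float) -> np.ndarray:
    """Winsorize values in place order (not sorted), per column."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    g = int(np.floor(trim * n))
    if g == 0:
        return x.copy()
    s = np.sort(x)
    lo, hi = s[g], s[n - g - 1]
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# categorical tests
# ---------------------------------------------------------------------------


def pearson_chi2(table: np.ndarray) -> TestResult:
    """Pearson chi-square of independence, no continuity correction.

    Used for the 2-group categorical clinical comparisons; raises for
    tables with a zero margin.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2D nonnegative count matrix")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(dof), float(p), "pearson-chi2")


def counts_to_coded_samples(counts: list[tuple[int, ...]]) -> list[np.ndarray]:
    """Expand per-group category counts into coded value vectors.

    ``counts[g][c]`` is the number of group-g subjects in category c; the
    returned vectors code category membership as 0, 1, 2, ... so that rank
    tests can be applied to printed contingency tables.
    """
    return [
        np.concatenate([np.full(n, c, dtype=float) for c, n in enumerate(row)])
        for row in counts
    ]


def kruskal_wallis(samples: list[np.ndarray]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across >= 3 groups.

    For binary data H equals ``(N-1)/N`` times the Pearson chi-square of
    the collapsed 2 x k table.  All-identical values give H = 0 with a
    flag instead of an error.
    """
    if len(samples) < 3:
        raise ValueError("kruskal_wallis expects >= 3 groups (use yuen_t/chi2 for 2)")
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    if np.ptp(pooled) == 0:
        return TestResult(0.0, float(len(samples) - 1), 1.0, "kruskal-wallis",
                          flags="all_identical")
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), float(len(samples) - 1), float(p), "kruskal-wallis")


# ---------------------------------------------------------------------------
# trimmed-mean ANOVAs
# ---------------------------------------------------------------------------


def _group_quantities(samples: list[np.ndarray], trim: float):
    n = np.array([len(s) for s in samples], dtype=float)
    g = np.floor(trim * n)
    h = n - 2 * g
    if (h < 2).any():
        raise ValueError("a group is degenerate after trimming (h < 2)")
    tmeans = np.array([trimmed_mean(s, trim) for s in samples])
    wvars = np.array([winsorized_variance(s, trim) for s in samples])
    d = (n - 1) * wvars / (h * (h - 1))
    return n, h, tmeans, wvars, d


def trimmed_anova_1way(
    samples: list[np.ndarray], trim: float = DEFAULT_TRIM
) -> TestResult:
    """Heteroscedastic one-way ANOVA on trimmed means.

    Welch-type F on 20%-trimmed means with winsorized variances and
    fractional error df; with ``trim = 0`` this is exactly Welch's ANOVA.
    """
    J = len(samples)
    if J < 2:
        raise ValueError("need >= 2 groups")
    _, h, tmeans, _, d = _group_quantities(samples, trim)
    if (d <= 0).any():
        raise ValueError("zero winsorized variance in a group")
    w = 1.0 / d
    U = w.sum()
    xtilde = float((w * tmeans).sum() / U)
    A = float((w * (tmeans - xtilde) ** 2).sum() / (J - 1))
    term = float((((1 - w / U) ** 2) / (h - 1)).sum())
    B = 2.0 * (J - 2) / (J**2 - 1) * term
    F = A / (1.0 + B)
    df2 = np.inf if term == 0 else 1.0 / (3.0 / (J**2 - 1) * term)
    p = float(sps.f.sf(F, J - 1, df2))
    return TestResult(float(F), (float(J - 1), float(df2)), p, "trimmed-anova-1way")


def yuen_t(
    x: np.ndarray, y: np.ndarray, trim: float = DEFAULT_TRIM
) -> TestResult:
    """Yuen's two-sample trimmed-means t test (heteroscedastic)."""
    n1, n2 = len(x), len(y)
    h1 = n1 - 2 * int(np.floor(trim * n1))
    h2 = n2 - 2 * int(np.floor(trim * n2))
    if min(h1, h2) < 2:
        raise ValueError("degenerate group after trimming")
    d1 = (n1 - 1) * winsorized_variance(x, trim) / (h1 * (h1 - 1))
    d2 = (n2 - 1) * winsorized_variance(y, trim) / (h2 * (h2 - 1))
    diff = trimmed_mean(x, trim) - trimmed_mean(y, trim)
    se = np.sqrt(d1 + d2)
    if se == 0:
        return TestResult(0.0, float(h1 + h2 - 2), 1.0, "yuen-t",
                          estimate=diff, flags="zero_variance")
    t = diff / se
    df = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, "yuen-t", estimate=float(diff))


def _difference_matrix(k: int) -> np.ndarray:
    d = np.zeros((k - 1, k))
    for i in range(k - 1):
        d[i, i] = 1.0
        d[i, i + 1] = -1.0
    return d


def _johansen(
    cmat: np.ndarray,
    theta: np.ndarray,
    v: np.ndarray,
    h: np.ndarray,
    K: int,
) -> TestResult:
    """Johansen's approximate F for linear hypotheses on trimmed means.

    ``v`` is the block-diagonal covariance of the stacked trimmed means,
    ``h`` the effective (post-trim) sample sizes per group.
    """
    r = cmat.shape[0]
    yv = cmat @ theta
    vm = cmat @ v @ cmat.T
    vm_inv = np.linalg.pinv(vm)
    T = float(yv @ vm_inv @ yv)
    mat = v @ cmat.T @ vm_inv @ cmat
    A = 0.0
    for j, hj in enumerate(h):
        sel = np.zeros(len(theta))
        sel[j * K : (j + 1) * K] = 1.0
        Q = np.diag(sel)
        MQ = mat @ Q
        A += (np.trace(MQ @ MQ) + np.trace(MQ) ** 2) / (hj - 1)
    A *= 0.5
    cval = r + 2 * A - 6 * A / (r + 2)
    F = T / cval
    df2 = np.inf if A == 0 else r * (r + 2) / (3 * A)
    p = float(sps.f.sf(F, r, df2))
    return TestResult(float(F), (float(r), float(df2)), p, "johansen-trimmed")


def mixed_anova_2way(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    within: str = "within",
    subject: str = "subject_id",
    trim: float = DEFAULT_TRIM,
) -> dict[str, TestResult]:
    """Robust two-way mixed ANOVA (between: group, within: side/region/sequence).

    Trimmed means per cell with winsorized covariance per group; Johansen's
    approximation for the group and within main effects and the
    interaction.  Subjects missing a within level are dropped (count in the
    ``n_dropped`` entry of each result's ``extra``).
    """
    wide = data.pivot_table(
        index=[subject, group], columns=within, values=value, aggfunc="first"
    )
    n_dropped = int(wide.isna().any(axis=1).sum())
    wide = wide.dropna()
    levels = list(wide.columns)
    K = len(levels)
    if K < 2:
        raise ValueError("within factor needs >= 2 levels")
    groups = sorted(wide.index.get_level_values(group).unique())
    J = len(groups)
    if J < 2:
        raise ValueError("need >= 2 groups")

    theta = []
    blocks = []
    h = []
    for gname in groups:
        sub = wide.xs(gname, level=group).to_numpy(dtype=float)
        nj = len(sub)
        gj = int(np.floor(trim * nj))
        hj = nj - 2 * gj
        if hj < 2:
            raise ValueError(f"group {gname} degenerate after trimming")
        theta.extend(trimmed_mean(sub[:, k], trim) for k in range(K))
        wins = np.column_stack(
            [_winsorized_column(sub[:, k], trim) for k in range(K)]
        )
        Sw = np.cov(wins, rowvar=False, ddof=1).reshape(K, K)
        blocks.append(Sw * (nj - 1) / (hj * (hj - 1)))
        h.append(hj)
    theta_arr = np.array(theta)
    v = np.zeros((J * K, J * K))
    for j, b in enumerate(blocks):
        v[j * K : (j + 1) * K, j * K : (j + 1) * K] = b
    h_arr = np.array(h, dtype=float)

    dJ = _difference_matrix(J)
    dK = _difference_matrix(K)
    onesJ = np.full((1, J), 1.0 / J)
    onesK = np.full((1, K), 1.0 / K)
    contrasts = {
        "group": np.kron(dJ, onesK),
        "within": np.kron(onesJ, dK),
        "interaction": np.kron(dJ, dK),
    }
    out = {}
    for name, C in contrasts.items():
        res = _johansen(C, theta_arr, v, h_arr, K)
        res.extra["n_dropped"] = n_dropped
        res.extra["groups"] = groups
        res.extra["within_levels"] = levels
        out[name] = res
    return out


# ---------------------------------------------------------------------------
# bootstrap post hoc and robust effect size
# ---------------------------------------------------------------------------


def bootstrap_posthoc(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 500,
    trim: float = DEFAULT_TRIM,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> TestResult:
    """Percentile-bootstrap comparison of two trimmed means.

    Each group is resampled independently ``n_boot`` times; the p value is
    the doubled tail probability of the bootstrap difference distribution
    around zero and the CI the percentile interval.  Deterministic for a
    fixed seed.
    """
    flags = ""
    if n_boot < 100:
        flags = "few_bootstrap_samples"
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    est = trimmed_mean(x, trim) - trimmed_mean(y, trim)
    xb = rng.choice(x, size=(n_boot, len(x)), replace=True)
    yb = rng.choice(y, size=(n_boot, len(y)), replace=True)
    diffs = np.array(
        [trimmed_mean(xb[b], trim) - trimmed_mean(yb[b], trim) for b in range(n_boot)]
    )
    p_star = (np.sum(diffs > 0) + 0.5 * np.sum(diffs == 0)) / n_boot
    p = float(2 * min(p_star, 1 - p_star))
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return TestResult(
        float(est), None, p, "bootstrap-trimmed-posthoc",
        ci=(float(lo), float(hi)), estimate=float(est), flags=flags,
        extra={"n_boot": n_boot, "seed": seed},
    )


def _winsorized_sd_constant(trim: float) -> float:
    """SD of the gamma-winsorized standard normal; rescales winsorized SD
    so the robust d estimates the classical d under normality (0.642 at
    gamma = 0.2)."""
    if trim == 0:
        return 1.0
    q = sps.norm.ppf(1 - trim)
    var = (1 - 2 * trim) - 2 * q * sps.norm.pdf(q) + 2 * trim * q**2
    return float(np.sqrt(var))


def robust_cohens_d(
    x: np.ndarray, y: np.ndarray, trim: float = DEFAULT_TRIM
) -> float:
    """Robust heteroscedastic generalization of Cohen's d (AKP variant).

    Trimmed-mean difference over the pooled winsorized SD, rescaled by the
    normal winsorization constant; equals classical d in large normal
    samples.  Antisymmetric in (x, y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(len(x), len(y)) < 10:
        raise ValueError("robust_cohens_d needs n >= 10 per group")
    s1, s2 = winsorized_variance(x, trim), winsorized_variance(y, trim)
    sp = ((len(x) - 1) * s1 + (len(y) - 1) * s2) / (len(x) + len(y) - 2)
    if sp <= 0:
        raise ValueError("zero pooled winsorized variance")
    const = _winsorized_sd_constant(trim)
    return float(const * (trimmed_mean(x, trim) - trimmed_mean(y, trim)) / np.sqrt(sp))


def adjust_pvalues(p: np.ndarray, method: str = "hochberg") -> np.ndarray:
    """Bonferroni or Hochberg step-up adjustment (monotone, >= raw)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    key = {"bonferroni": "bonferroni", "hochberg": "simes-hochberg"}[method]
    return multipletests(p, method=key)[1]


# ---------------------------------------------------------------------------
# robust regression
# ---------------------------------------------------------------------------


@dataclass
class HuberFit:
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    scale: float
    wald: dict[str, TestResult]
    n_obs: int
    results: object  # the underlying statsmodels fit


def _check_design(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offending columns via pivoted QR
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def huber_regression(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    add_intercept: bool = True,
    tuning: float = 1.345,
) -> HuberFit:
    """Huber M-regression (IRLS, MAD scale) with robust Wald tests.

    Tuning constant 1.345 gives 95% efficiency under normality while
    bounding the influence of outlying residuals.  Per-coefficient Wald
    tests use the Huber-corrected (sandwich-type) covariance.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(X) <= X.shape[1]:
        raise ValueError("need n > number of predictors")
    _check_design(X)
    model = sm.RLM(np.asarray(y, float), X, M=sm.robust.norms.HuberT(t=tuning))
    res = model.fit(cov="H1")
    cov = pd.DataFrame(res.bcov_scaled, index=X.columns, columns=X.columns)
    wald = {}
    for name in X.columns:
        if name == "const":
            continue
        wald[name] = wald_test(res.params, cov, [name])
    return HuberFit(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        cov=cov,
        scale=float(res.scale),
        wald=wald,
        n_obs=len(X),
        results=res,
    )


def wald_test(
    params: pd.Series | np.ndarray,
    cov: pd.DataFrame,
    block: list[str],
) -> TestResult:
    """Wald chi-square test that a block of coefficients is jointly zero."""
    params = pd.Series(params, index=cov.index) if not isinstance(params, pd.Series) else params
    b = params.loc[block].to_numpy()
    V = cov.loc[block, block].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    r = len(block)
    return TestResult(stat, float(r), float(sps.chi2.sf(stat, r)), "robust-wald")


# ---------------------------------------------------------------------------
# all-relevant feature selection (shadow-feature scheme)
# ---------------------------------------------------------------------------


def boruta_select(
    y: np.ndarray,
    X: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 20,
    alpha: float = 0.05,
    n_estimators: int = 50,
    n_shadow_copies: int = 2,
    task: str = "auto",
) -> dict[str, str]:
    """All-relevant feature selection against permuted shadow features.

    Each iteration appends ``n_shadow_copies`` column-permuted copies of
    every candidate feature, fits a random forest on a random half of the
    rows and scores
    held-out permutation importance on the other half; a feature scores a
    *hit* when its importance exceeds the best shadow importance
    (out-of-sample importance keeps in-sample chance correlations of noise
    features from accumulating systematic hits).  Hit counts are tested
    against Binomial(iterations, 1/2) at a Bonferroni-adjusted two-sided
    alpha; features are labelled ``confirmed``/``rejected``/``tentative``,
    rejected ones dropping out of later iterations.  Features still
    tentative at ``max_iter`` are resolved by comparing their median
    importance history against the median best-shadow importance (the
    usual rough fix).
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
    from sklearn.inspection import permutation_importance

    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 candidate features")
    y = np.asarray(y)
    if task == "auto":
        yi = np.unique(y)
        task = "classify" if len(yi) <= 10 and np.allclose(yi, yi.astype(int)) else "regress"
    rng = np.random.default_rng(seed)
    status = {c: "tentative" for c in X.columns}
    hits = {c: 0 for c in X.columns}
    rounds = {c: 0 for c in X.columns}
    history: dict[str, list[float]] = {c: [] for c in X.columns}
    shadow_history: list[float] = []
    n_all = X.shape[1]
    n = len(y)

    for it in range(max_iter):
        active = [c for c, s in status.items() if s == "tentative"]
        if not active:
            break
        Xa = X[active].to_numpy()
        shadows = []
        for _ in range(n_shadow_copies):
            sh = Xa.copy()
            for j in range(sh.shape[1]):
                rng.shuffle(sh[:, j])
            shadows.append(sh)
        design = np.hstack([Xa, *shadows])
        cls = RandomForestClassifier if task == "classify" else RandomForestRegressor
        forest = cls(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31 - 1)),
            max_features="sqrt",
            n_jobs=1,
        )
        idx = rng.permutation(n)
        train, test = idx[: n // 2], idx[n // 2 :]
        forest.fit(design[train], y[train])
        pi = permutation_importance(
            forest,
            design[test],
            y[test],
            n_repeats=3,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        imp = pi.importances_mean
        best_shadow = imp[len(active) :].max()
        shadow_history.append(float(best_shadow))
        for j, c in enumerate(active):
            rounds[c] += 1
            history[c].append(float(imp[j]))
            if imp[j] > best_shadow:
                hits[c] += 1
        if it >= 4:
            for c in active:
                k, nr = hits[c], rounds[c]
                p_hi = sps.binom.sf(k - 1, nr, 0.5)  # evidence of relevance
                p_lo = sps.binom.cdf(k, nr, 0.5)     # evidence of irrelevance
                thresh = alpha / n_all
                if p_hi < thresh:
                    status[c] = "confirmed"
                elif p_lo < thresh:
                    status[c] = "rejected"
    median_shadow = float(np.median(shadow_history)) if shadow_history else 0.0
    for c, s in status.items():
        if s == "tentative" and history[c]:
            status[c] = (
                "confirmed" if np.median(history[c]) > median_shadow else "rejected"
            )
    # constant features carry no information
    for c in X.columns:
        if X[c].nunique() <= 1:
            status[c] = "rejected"
    return status
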