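"""ROC / logistic-regression diagnostic ladder.

The eight quantitative brainstem read-outs (SNc NM CR/nVol, LC NM CR/nVol,
SNc iron CR/nVol, RN iron CR/nVol) are evaluated as diagnostic markers,
individually and combined through binary logistic regression in models of
increasing complexity:

* M1: LC NM {CR, nVol}
* M2: M1 + RN iron {CR, nVol}
* M3: M2 + SNc NM {CR, nVol}
* M4: M3 + SNc iron {CR, nVol}  (complete model)

AUC is the Mann-Whitney statistic (ties count one half), identical to the
probability that a random positive outscores a random negative; 95%
confidence intervals come from stratified case bootstrap (1000 resamples by
default).  AUCs are in-sample: the ladder quantifies the separation the
measures achieve on the cohort itself, not out-of-sample generalization
(an optional cross-validated mode exists but is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "MODEL_LADDER",
    "SINGLE_STRUCTURE_MODELS",
    "ROCResult",
    "fit_logistic",
    "roc_auc",
    "bootstrap_auc_ci",
    "run_ladder",
]

FEATURES = (
    "snc_nm_cr", "snc_nm_nvol",
    "lc_nm_cr", "lc_nm_nvol",
    "snc_iron_cr", "snc_iron_nvol",
    "rn_iron_cr", "rn_iron_nvol",
)

MODEL_LADDER: dict[str, tuple[str, ...]] = {
    "M1_lc_nm": ("lc_nm_cr", "lc_nm_nvol"),
    "M2_plus_rn_iron": ("lc_nm_cr", "lc_nm_nvol", "rn_iron_cr", "rn_iron_nvol"),
    "M3_plus_snc_nm": (
        "lc_nm_cr", "lc_nm_nvol", "rn_iron_cr", "rn_iron_nvol",
        "snc_nm_cr", "snc_nm_nvol",
    ),
    "M4_complete": (
        "lc_nm_cr", "lc_nm_nvol", "rn_iron_cr", "rn_iron_nvol",
        "snc_nm_cr", "snc_nm_nvol", "snc_iron_cr", "snc_iron_nvol",
    ),
}

SINGLE_STRUCTURE_MODELS: dict[str, tuple[str, ...]] = {
    "snc_nm": ("snc_nm_cr", "snc_nm_nvol"),
    "lc_nm": ("lc_nm_cr", "lc_nm_nvol"),
    "snc_iron": ("snc_iron_cr", "snc_iron_nvol"),
    "rn_iron": ("rn_iron_cr", "rn_iron_nvol"),
}


@dataclass
class ROCResult:
    model: str
    contrast: str
    auc: float
    ci: tuple[float, float] | None
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int
    flags: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class LogisticModel:
    """Fitted binary logistic score function.

    Features are z-scored internally (CR is O(0.1), nVol O(1e-4); on raw
    scales a penalized fall-back fit would simply ignore the small-scale
    features); ``params`` refer to the standardized features.
    """

    feature_names: tuple[str, ...]
    params: np.ndarray  # intercept first, standardized scale
    center: np.ndarray
    scale: np.ndarray
    conf_int: np.ndarray | None = None  # per-parameter 95% CI (ML fits only)
    flags: str = ""

    def predict_proba(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X)[list(self.feature_names)], dtype=float) \
            if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        Z = (X - self.center) / self.scale
        eta = self.params[0] + Z @ self.params[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def fit_logistic(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
    min_per_class: int = 10,
) -> LogisticModel:
    """Maximum-likelihood binary logistic regression.

    Perfect separation (or a rank-deficient design, e.g. duplicated
    features) is flagged and the fit falls back to a weakly ridge-penalized
    solution, which keeps the score function defined.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(features)
    if feature_names is not None:
        X = X[list(feature_names)]
    names = tuple(X.columns.astype(str))
    y = np.asarray(labels).astype(float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    y01 = (y == classes.max()).astype(float)
    smallest = int(min((y01 == 0).sum(), (y01 == 1).sum()))
    if smallest < min_per_class:
        raise ValueError(f"need >= {min_per_class} subjects per class")
    raw = X.to_numpy(dtype=float)
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    scale[scale == 0] = 1.0
    design = sm.add_constant((raw - center) / scale, has_constant="add")
    flags = ""
    conf = None
    if np.linalg.matrix_rank(design) < design.shape[1]:
        flags = "rank_deficient"
    import warnings

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y01, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params)
        # huge coefficients are the footprint of (quasi-)separation
        if not np.all(np.isfinite(params)) or np.abs(params[1:]).max() > 1e4:
            raise ValueError("separation")
        conf = np.asarray(res.conf_int())
    except Exception:
        # (quasi-)separation or singular design: weak ridge keeps the
        # score function defined; no Wald CIs in that regime
        from sklearn.linear_model import LogisticRegression

        flags = (flags + ";" if flags else "") + "separation_penalized"
        lr = LogisticRegression(C=10.0, max_iter=2000)
        lr.fit((raw - center) / scale, y01)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return LogisticModel(
        feature_names=names, params=params, center=center, scale=scale,
        conf_int=conf, flags=flags,
    )


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    model: str = "",
    contrast: str = "",
) -> ROCResult:
    """AUC via the Mann-Whitney rank statistic with half-weight ties, plus
    the ROC curve over all distinct thresholds."""
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("roc_auc needs both classes present")
    pos = y == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    fpr, tpr, thr = roc_curve(pos.astype(int), scores)
    return ROCResult(
        model=model,
        contrast=contrast,
        auc=auc,
        ci=None,
        thresholds=thr,
        sensitivity=tpr,
        specificity=1 - fpr,
        n_pos=n1,
        n_neg=n0,
    )


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC, stratified by class.

    Cases are resampled within each class so no resample loses a class.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    pos_scores = scores[y == classes.max()]
    neg_scores = scores[y != classes.max()]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos_scores, size=len(pos_scores), replace=True)
        ns = rng.choice(neg_scores, size=len(neg_scores), replace=True)
        ranks = sps.rankdata(np.concatenate([ps, ns]))
        u = ranks[: len(ps)].sum() - len(ps) * (len(ps) + 1) / 2.0
        aucs[b] = u / (len(ps) * len(ns))
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _pairwise_contrasts(groups: pd.Series) -> dict[str, tuple]:
    """One-vs-one contrasts plus HC-vs-all-PD when HC is present."""
    names = sorted(groups.unique())
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}_vs_{b}"] = (a, b)
    if "HC" in names and len(names) > 2:
        out["HC_vs_PD"] = ("HC", tuple(n for n in names if n != "HC"))
    return out


def run_ladder(
    measures: pd.DataFrame,
    contrasts: dict[str, tuple] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_duration: float | None = None,
    min_per_class: int = 3,
    cv: str | None = None,
) -> pd.DataFrame:
    """Evaluate the model ladder and single-structure models per contrast.

    ``measures`` is a wide per-subject table with a ``group`` column and
    the eight feature columns; ``max_duration`` restricts PD subjects to an
    early-stage sub-cohort (``disease_duration`` strictly below the cut,
    in years).  Returns a tidy table with one row per model x contrast.

    By default AUCs are in-sample.  ``cv="loo"`` scores each subject with
    a model fitted on the remaining subjects (leave-one-out): at small
    cohort sizes in-sample logistic scores are perfectly separable for
    any feature pair, so only out-of-fold AUCs can rank models.
    """
    missing = [c for c in FEATURES if c not in measures.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    df = measures.copy()
    if max_duration is not None:
        early = (df["group"] == "HC") | (df["disease_duration"] < max_duration)
        df = df[early]
    contrasts = contrasts or _pairwise_contrasts(df["group"])
    models = {**SINGLE_STRUCTURE_MODELS, **MODEL_LADDER}
    rows = []
    rng = np.random.default_rng(seed)
    for cname, (a, b) in contrasts.items():
        b_groups = (b,) if isinstance(b, str) else tuple(b)
        sub = df[df["group"].isin((a, *b_groups))].dropna(subset=list(FEATURES))
        labels = (sub["group"] != a).astype(int).to_numpy()
        if len(np.unique(labels)) < 2 or min(
            (labels == 0).sum(), (labels == 1).sum()
        ) < min_per_class:
            continue
        small_n = min((labels == 0).sum(), (labels == 1).sum()) < 10
        for mname, feats in models.items():
            model = fit_logistic(
                sub, labels, feature_names=feats, min_per_class=min_per_class
            )
            if cv == "loo":
                p = np.empty(len(sub))
                for i in range(len(sub)):
                    keep = np.arange(len(sub)) != i
                    if len(np.unique(labels[keep])) < 2:
                        p[i] = 0.5
                        continue
                    fold = fit_logistic(
                        sub.iloc[keep], labels[keep],
                        feature_names=feats, min_per_class=2,
                    )
                    p[i] = fold.predict_proba(sub.iloc[[i]])[0]
            else:
                p = model.predict_proba(sub)
            roc = roc_auc(p, labels, model=mname, contrast=cname)
            ci = bootstrap_auc_ci(
                p, labels, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
            )
            rows.append(
                {
                    "contrast": cname,
                    "model": mname,
                    "n_features": len(feats),
                    "auc": roc.auc,
                    "auc_lo": ci[0],
                    "auc_hi": ci[1],
                    "n_pos": roc.n_pos,
                    "n_neg": roc.n_neg,
                    "flags": ";".join(filter(None, [model.flags,
                                                    "small_n" if small_n else ""])),
                }
            )
    return pd.DataFrame(rows)
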