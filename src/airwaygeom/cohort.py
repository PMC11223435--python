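"""Cohort statistics: matching, group comparison, and bootstrap ML evaluation.

The protocol mirrors a case-control navigation-failure analysis:

* propensity-score matching (1:1 greedy nearest neighbor on the logit, with
  a caliper expressed in SDs of the logit) to balance covariates, verified
  by standardized mean differences (SMD < 0.2 considered balanced);
* per-feature two-sample t-tests (continuous) and chi-square tests
  (categorical), reported as "mean (SD)" with raw p-values;
* feature stability as the selection frequency of an L1-regularized
  logistic model over bootstrap resamples;
* classifier evaluation by repeated stratified hold-out: per iteration a
  70/30 split, standardization fitted on the training part only, and
  accuracy / sensitivity / specificity / AUC on both phases, with the
  failure class as positive.  Aggregates are mean (SD) over iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "AnalysisError",
    "BootstrapResult",
    "propensity_match",
    "compare_groups",
    "lasso_selection_frequency",
    "bootstrap_evaluate",
]

METRICS = ("accuracy", "sensitivity", "specificity", "auc")


class AnalysisError(RuntimeError):
    """A statistical stage failed (degenerate inputs, missing class, ...)."""


def _standardized_mean_difference(x0: np.ndarray, x1: np.ndarray) -> float:
    pooled = np.sqrt((np.var(x0, ddof=1) + np.var(x1, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(x1.mean() - x0.mean()) / pooled)


def propensity_match(
    table: pd.DataFrame,
    covariates: list[str],
    outcome: str = "failure",
    caliper: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1:1 greedy nearest-neighbor matching on the propensity logit.

    The propensity score is a plain (non-parsimonious) logistic regression of
    the outcome group on the covariates.  ``caliper`` is in units of the SD
    of the logit; pairs farther apart are not formed.  Returns the matched
    table and an SMD report (pre/post per covariate).  Zero pairs within the
    caliper yields an empty match with a warning entry, never a silent
    success.
    """
    y = table[outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise AnalysisError("both outcome groups must be nonempty")
    X = table[covariates].to_numpy(dtype=float)
    lr = LogisticRegression(penalty=None, max_iter=2000)
    lr.fit(X, y)
    ps = np.clip(lr.predict_proba(X)[:, 1], 1e-9, 1 - 1e-9)
    logit = np.log(ps / (1 - ps))
    cal = caliper * logit.std(ddof=1)

    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    available = set(neg.tolist())
    pairs: list[tuple[int, int]] = []
    for i in pos[order]:
        if not available:
            break
        cand = np.array(sorted(available))
        d = np.abs(logit[cand] - logit[i])
        j = int(cand[np.argmin(d)])
        if d.min() <= cal:
            pairs.append((i, j))
            available.discard(j)

    smd_rows = []
    matched_idx = [i for pair in pairs for i in pair]
    matched = table.iloc[matched_idx].reset_index(drop=True)
    for cov in covariates:
        x0 = table.loc[y == 0, cov].to_numpy(float)
        x1 = table.loc[y == 1, cov].to_numpy(float)
        pre = _standardized_mean_difference(x0, x1)
        if pairs:
            m0 = matched.loc[matched[outcome] == 0, cov].to_numpy(float)
            m1 = matched.loc[matched[outcome] == 1, cov].to_numpy(float)
            post = _standardized_mean_difference(m0, m1)
        else:
            post = np.nan
        smd_rows.append({"covariate": cov, "smd_pre": pre, "smd_post": post})
    report = pd.DataFrame(smd_rows)
    report.attrs["n_pairs"] = len(pairs)
    report.attrs["balanced"] = bool(pairs) and bool((report["smd_post"] < 0.2).all())
    if not pairs:
        report.attrs["warning"] = "no pairs within caliper; match is empty"
    return matched, report


def compare_groups(
    table: pd.DataFrame,
    features: list[str],
    outcome: str = "failure",
    categorical: list[str] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature group comparison formatted as "mean (SD)" plus p-values.

    Continuous features get two-sample t-tests, categorical ones chi-square
    tests on the contingency table.  Zero variance in both groups yields
    p = 1 with a flag.  ``adjust`` adds a Benjamini-Hochberg column (raw
    p-values stay the primary report).
    """
    categorical = set(categorical or [])
    y = table[outcome].to_numpy()
    g0 = table[y == 0]
    g1 = table[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise AnalysisError("each group needs at least 2 cases")
    rows = []
    for feat in features:
        if feat in categorical:
            ct = pd.crosstab(table[feat], table[outcome])
            chi2, p, _, _ = stats.chi2_contingency(ct)
            rows.append({
                "feature": feat, "success": None, "failure": None,
                "p_value": float(p), "test": "chi-square", "flag": "",
            })
            continue
        x0 = g0[feat].to_numpy(float)
        x1 = g1[feat].to_numpy(float)
        if np.var(x0) == 0 and np.var(x1) == 0:
            p, flag = 1.0, "zero variance in both groups"
        else:
            _, p = stats.ttest_ind(x0, x1)
            flag = ""
        rows.append({
            "feature": feat,
            "success": f"{x0.mean():.3f} ({x0.std(ddof=1):.3f})",
            "failure": f"{x1.mean():.3f} ({x1.std(ddof=1):.3f})",
            "p_value": float(p), "test": "t-test", "flag": flag,
        })
    out = pd.DataFrame(rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def _fit_l1_logistic(X: np.ndarray, y: np.ndarray, seed: int) -> LogisticRegressionCV:
    """L1 logistic fit with the penalty chosen by internal cross-validation.

    The C grid is capped at ~3 — on standardized features of these cohort
    sizes larger C means a near-unpenalized fit that selects everything,
    which defeats the purpose of a selection-frequency analysis.
    """
    model = LogisticRegressionCV(
        Cs=np.logspace(-2, 0.5, 6), cv=5, penalty="l1", solver="liblinear",
        scoring="roc_auc", max_iter=2000, random_state=seed, refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def lasso_selection_frequency(
    table: pd.DataFrame,
    features: list[str],
    outcome: str = "failure",
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Selection frequency of an L1-logistic model over bootstrap resamples.

    Per iteration the cases are resampled with replacement (single-class
    draws are redrawn and counted), features are standardized on the
    bootstrap sample, and the penalty is chosen by internal cross-validation.
    A feature is selected when its coefficient is nonzero.  Returns one row
    per feature with ``selection_frequency``, the mean nonzero coefficient,
    and its sign.
    """
    X = table[features].to_numpy(float)
    y = table[outcome].to_numpy()
    n = len(y)
    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(n_boot)
    selected = np.zeros(len(features))
    coef_sum = np.zeros(len(features))
    coef_count = np.zeros(len(features))
    n_redraws = 0
    for it in range(n_boot):
        rng = np.random.default_rng(iter_seeds[it])
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_redraws += 1
        else:
            raise AnalysisError("could not draw a two-class bootstrap sample")
        Xb, yb = X[idx], y[idx]
        mu, sd = Xb.mean(axis=0), Xb.std(axis=0)
        sd[sd == 0] = 1.0
        Xb = (Xb - mu) / sd
        model = _fit_l1_logistic(Xb, yb, seed=int(iter_seeds[it] % (2**31 - 1)))
        coef = model.coef_.ravel()
        nz = np.abs(coef) > 1e-10
        selected += nz
        coef_sum += np.where(nz, coef, 0.0)
        coef_count += nz
    mean_coef = np.divide(coef_sum, coef_count, out=np.zeros_like(coef_sum),
                          where=coef_count > 0)
    out = pd.DataFrame({
        "feature": features,
        "selection_frequency": selected / n_boot,
        "mean_nonzero_coef": mean_coef,
        "coef_sign": np.sign(mean_coef),
    })
    out.attrs["n_boot"] = n_boot
    out.attrs["n_redraws"] = n_redraws
    return out


@dataclass
class BootstrapResult:
    """Repeated hold-out evaluation of one classifier."""

    model: str
    n_iterations: int
    holdout_ratio: float
    seed: int
    per_iteration: dict[str, np.ndarray]   # "<phase>_<metric>" -> (n_boot,)
    aggregate: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aggregate:
            self.aggregate = {
                key: (float(v.mean()), float(v.std(ddof=1)))
                for key, v in self.per_iteration.items()
            }

    def summary(self) -> pd.DataFrame:
        rows = []
        for phase in ("train", "test"):
            row = {"phase": phase}
            for metric in METRICS:
                mean, sd = self.aggregate[f"{phase}_{metric}"]
                row[metric] = f"{mean:.3f} ({sd:.3f})"
            rows.append(row)
        return pd.DataFrame(rows)


def _stratified_split(y: np.ndarray, holdout: float, rng: np.random.Generator):
    test_idx = []
    train_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = rng.permutation(members)
        n_test = max(int(round(holdout * len(members))), 1)
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _make_model(name: str, Xtr: np.ndarray, ytr: np.ndarray, seed: int):
    """Fit one classifier; returns (fitted model, score function)."""
    if name == "svm":
        # small internal CV over C and gamma, AUC-scored
        best = (-np.inf, None)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for C in (0.1, 1.0, 10.0):
            for gamma in ("scale", 0.1):
                aucs = []
                for tr, va in skf.split(Xtr, ytr):
                    if len(np.unique(ytr[va])) < 2:
                        continue
                    m = SVC(kernel="rbf", C=C, gamma=gamma)
                    m.fit(Xtr[tr], ytr[tr])
                    aucs.append(roc_auc_score(ytr[va], m.decision_function(Xtr[va])))
                score = np.mean(aucs) if aucs else -np.inf
                if score > best[0]:
                    best = (score, (C, gamma))
        C, gamma = best[1] if best[1] else (1.0, "scale")
        model = SVC(kernel="rbf", C=C, gamma=gamma)
        model.fit(Xtr, ytr)
        return model, model.decision_function, 0.0
    if name == "rf":
        model = RandomForestClassifier(
            n_estimators=512, max_features="sqrt", random_state=seed, n_jobs=1
        )
        model.fit(Xtr, ytr)
        return model, lambda X: model.predict_proba(X)[:, 1], 0.5
    if name == "lasso":
        model = _fit_l1_logistic(Xtr, ytr, seed)
        return model, model.decision_function, 0.0
    raise AnalysisError(f"unknown model {name!r}; choose svm, rf or lasso")


def _confusion_metrics(y: np.ndarray, scores: np.ndarray, threshold: float) -> dict:
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "auc": roc_auc_score(y, scores),
    }


def bootstrap_evaluate(
    table: pd.DataFrame,
    features: list[str],
    model: str,
    outcome: str = "failure",
    n_boot: int = 1000,
    holdout: float = 0.3,
    seed: int = 0,
    rf_trees: int = 512,
) -> BootstrapResult:
    """Repeated stratified hold-out evaluation (70/30 by default).

    Standardization statistics come from the training split only.  The
    positive class is failure (outcome == 1); accuracy, sensitivity and
    specificity use a fixed threshold (0.5 probability / 0 decision value),
    AUC uses the continuous score.  Identical seeds give bit-identical
    results.
    """
    X = table[features].to_numpy(float)
    y = table[outcome].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise AnalysisError("both classes must be present")
    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(n_boot)
    per = {f"{phase}_{m}": np.empty(n_boot) for phase in ("train", "test") for m in METRICS}
    for it in range(n_boot):
        rng = np.random.default_rng(iter_seeds[it])
        for _ in range(100):
            tr, te = _stratified_split(y, holdout, rng)
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
        else:
            raise AnalysisError("could not form a two-class test split")
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        mseed = int(iter_seeds[it] % (2**31 - 1))
        if model == "rf":
            fitted = RandomForestClassifier(
                n_estimators=rf_trees, max_features="sqrt",
                random_state=mseed, n_jobs=1,
            )
            fitted.fit(Xtr, y[tr])
            score_fn, thr = (lambda Z: fitted.predict_proba(Z)[:, 1]), 0.5
        else:
            fitted, score_fn, thr = _make_model(model, Xtr, y[tr], mseed)
        for phase, idx, Z in (("train", tr, Xtr), ("test", te, Xte)):
            m = _confusion_metrics(y[idx], score_fn(Z), thr)
            for name, val in m.items():
                per[f"{phase}_{name}"][it] = val
    return BootstrapResult(
        model=model, n_iterations=n_boot, holdout_ratio=holdout, seed=seed,
        per_iteration=per,
    )
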