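"""Downstream cohort inference on slide-level nuHIF tables.

Covers the analysis battery applied to the morphology features:
standardization (plain and robust z-scores), median-z heatmaps with
average-linkage hierarchical clustering, stratified cross-validated binary
classification scored by AUROC (default learner: a 100-tree random forest
with balanced class weights), whole-genome-doubling binarization and
prediction with impurity-based feature importances, Cox
proportional-hazards survival screening with age and ordinal stage as
covariates, Kaplan–Meier median-split analysis, per-gene Spearman
association screens, and hypergeometric gene-set overlap enrichment.
Multiple testing is corrected per screen with Benjamini–Hochberg, never
pooled across screens.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscore_columns",
    "robust_zscore",
    "median_z_heatmap",
    "CVResult",
    "mann_whitney_auroc",
    "cv_binary_auroc",
    "one_vs_all_cv",
    "wgd_binarize",
    "predict_wgd",
    "spearman",
    "pearson",
    "bh_fdr",
    "survival_screen",
    "km_median_split",
    "gene_association",
    "select_gene_sets",
    "overlap_enrichment",
    "prepare_umap_input",
]

#: IQR of the standard normal; dividing the IQR by this makes the robust
#: z-score's scale match one SD under normality.
ROBUST_Z_IQR_SCALE = 1.349

Q_CUTOFF = 0.05
RHO_CUTOFF = 0.15


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def zscore_columns(frame: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """(x − mean)/SD per column.  Constant columns are flagged and returned
    untouched rather than divided by zero."""
    out = frame.copy()
    flagged: list[str] = []
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        sd = np.nanstd(v, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            flagged.append(col)
            continue
        out[col] = (v - np.nanmean(v)) / sd
    return out, flagged


def robust_zscore(column: pd.Series | np.ndarray) -> np.ndarray:
    """(x − median) / (IQR / 1.349): outlier-resistant standardization whose
    unit approximates one SD under normality."""
    v = np.asarray(column, dtype=float)
    med = np.nanmedian(v)
    q75, q25 = np.nanpercentile(v, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("robust z-score undefined: interquartile range is 0")
    return (v - med) / (iqr / ROBUST_Z_IQR_SCALE)


# ---------------------------------------------------------------------------
# Heatmap / clustering summary
# ---------------------------------------------------------------------------

def median_z_heatmap(
    frame: pd.DataFrame, group_col: str, feature_cols: list[str] | None = None
) -> dict:
    """Group × feature matrix of median z-scores with hierarchical
    clustering orders (Euclidean distance, average linkage; leaf order
    deterministic, ties following input order).

    Returns a dict with ``matrix`` (groups × features DataFrame),
    ``row_order``/``col_order`` (leaf orders), and the two linkage arrays.
    """
    groups = frame[group_col]
    if groups.nunique() < 2:
        raise ValueError("median_z_heatmap requires at least 2 groups")
    if feature_cols is None:
        feature_cols = [
            c for c in frame.columns
            if c != group_col and pd.api.types.is_numeric_dtype(frame[c])
        ]
    z, flagged = zscore_columns(frame[feature_cols])
    use = [c for c in feature_cols if c not in flagged]
    med = z[use].groupby(groups, observed=True, sort=True).median()
    row_link = hierarchy.linkage(med.to_numpy(), method="average",
                                 metric="euclidean")
    col_link = hierarchy.linkage(med.to_numpy().T, method="average",
                                 metric="euclidean")
    return {
        "matrix": med,
        "row_order": hierarchy.leaves_list(row_link).tolist(),
        "col_order": hierarchy.leaves_list(col_link).tolist(),
        "row_linkage": row_link,
        "col_linkage": col_link,
        "flagged_columns": flagged,
    }


# ---------------------------------------------------------------------------
# Cross-validated classification
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-fold AUROCs with their mean, held-out predictions, and mean
    impurity-decrease feature importances across folds."""

    fold_aurocs: list[float]
    mean_auroc: float
    predictions: pd.DataFrame  # columns: fold, index, y_true, score
    feature_importances: dict[str, float] = field(default_factory=dict)

    def top_importances(self, k: int = 5) -> list[tuple[str, float]]:
        ranked = sorted(self.feature_importances.items(),
                        key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


def mann_whitney_auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUROC via the rank (Mann–Whitney U) formulation with tie midranks:
    (R₁ − n₁(n₁+1)/2) / (n₁ n₀) where R₁ is the positive rank sum."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = stats.rankdata(scores)
    r1 = ranks[y].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def default_learner(seed: int | None = 0) -> RandomForestClassifier:
    """100-tree random forest with balanced class weights (scikit-learn
    defaults otherwise)."""
    return RandomForestClassifier(
        n_estimators=100, class_weight="balanced", random_state=seed
    )


def cv_binary_auroc(
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    learner=None,
) -> CVResult:
    """Stratified k-fold cross-validated binary classification scored by
    held-out AUROC.

    Folds are deterministic given ``seed``.  ``learner`` may be any
    fit/predict_proba estimator; by default a fresh
    :func:`default_learner` (seeded) is cloned per fold.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if not np.all(np.isfinite(X.to_numpy(dtype=float))):
        raise ValueError("X contains non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} members; need >= k = {k}"
        )
    y_bin = (y == classes[1]).astype(int)
    if learner is None:
        learner = default_learner(seed)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aurocs: list[float] = []
    pred_rows = []
    importances = np.zeros(X.shape[1])
    have_importance = True
    for fold, (tr, te) in enumerate(skf.split(X, y_bin)):
        est = clone(learner)
        est.fit(X.iloc[tr], y_bin[tr])
        scores = est.predict_proba(X.iloc[te])[:, 1]
        fold_aurocs.append(mann_whitney_auroc(scores, y_bin[te]))
        for idx, yt, s in zip(X.index[te], y_bin[te], scores):
            pred_rows.append({"fold": fold, "index": idx, "y_true": int(yt),
                              "score": float(s)})
        if hasattr(est, "feature_importances_"):
            importances += est.feature_importances_
        else:
            have_importance = False
    fi = (
        dict(zip(X.columns, (importances / k).tolist()))
        if have_importance
        else {}
    )
    return CVResult(
        fold_aurocs=fold_aurocs,
        mean_auroc=float(np.mean(fold_aurocs)),
        predictions=pd.DataFrame(pred_rows),
        feature_importances=fi,
    )


def one_vs_all_cv(
    X: pd.DataFrame, subtype_labels, k: int = 5, seed: int = 0, learner=None
) -> dict[str, CVResult]:
    """One binary CV per subtype (subtype vs rest).  Subtypes with fewer
    than ``k`` members are skipped with a warning."""
    subtype_labels = np.asarray(subtype_labels)
    subtypes = np.unique(subtype_labels)
    if len(subtypes) < 2:
        raise ValueError("one_vs_all_cv requires at least 2 subtypes")
    out: dict[str, CVResult] = {}
    for st in subtypes:
        y = (subtype_labels == st).astype(int)
        if y.sum() < k or (len(y) - y.sum()) < k:
            warnings.warn(f"subtype {st!r} has < {k} members; skipped",
                          stacklevel=2)
            continue
        out[str(st)] = cv_binary_auroc(X, y, k=k, seed=seed, learner=learner)
    return out


def wgd_binarize(wgd_count) -> np.ndarray:
    """Whole-genome-doubling count to binary label: 1–2 doublings → 1,
    no doublings → 0."""
    c = np.asarray(wgd_count)
    if not np.isin(c, [0, 1, 2]).all():
        bad = np.unique(c[~np.isin(c, [0, 1, 2])])
        raise ValueError(f"wgd_count must be in {{0, 1, 2}}; got {bad}")
    return (c >= 1).astype(int)


def predict_wgd(
    X: pd.DataFrame, wgd_count, seed: int = 0, k: int = 5, learner=None
) -> tuple[CVResult, list[tuple[str, float]]]:
    """Cross-validated prediction of binarized WGD; returns the CV result
    and the top-5 mean impurity-decrease importances."""
    y = wgd_binarize(wgd_count)
    res = cv_binary_auroc(X, y, k=k, seed=seed, learner=learner)
    return res, res.top_importances(5)


# ---------------------------------------------------------------------------
# Correlation and multiple testing
# ---------------------------------------------------------------------------

def _check_corr_input(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")


def _rho_t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with the usual t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_input(x, y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson on midranks.  Two-sided p-value
    by the t approximation for n ≥ 10 and by exact permutation enumeration
    for n < 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_corr_input(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n >= 10:
        return rho, _rho_t_pvalue(rho, n)
    # exact permutation null over all n! orderings of one rank vector
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        p_arr = np.asarray(perm)
        p_c = p_arr - p_arr.mean()
        rho_perm = (rx_c @ p_c) / (denom * np.sqrt((p_c**2).sum()))
        if abs(rho_perm) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def _clean_survival_frame(
    frame: pd.DataFrame, time: str, event: str, covariates
) -> tuple[pd.DataFrame, int]:
    needed = [time, event, *covariates]
    mask = frame[needed].notna().all(axis=1)
    excluded = int((~mask).sum())
    df = frame.loc[mask].copy()
    if (df[time] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df[event].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df, excluded


def survival_screen(
    frame: pd.DataFrame,
    features: list[str],
    time: str = "surv_time",
    event: str = "surv_event",
    covariates: tuple[str, ...] = ("age", "stage"),
) -> tuple[pd.DataFrame, int]:
    """Cox proportional-hazards screen of each feature, adjusted for the
    clinical covariates.

    Each feature is robust-z-scored, then fit jointly with the covariates
    by partial likelihood; the row reports the feature's hazard ratio,
    Wald 95% CI and p-value, and a BH q-value computed across the screened
    features.  Rows with missing covariates/survival are excluded (their
    count is returned); non-converging fits are flagged in the
    ``converged`` column rather than silently dropped.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df, n_excluded = _clean_survival_frame(frame, time, event, covariates)
    rows = []
    for feat in features:
        sub = df[[feat, *covariates, time, event]].dropna().copy()
        row = {"feature": feat, "n": len(sub), "converged": True}
        try:
            sub["_z"] = robust_zscore(sub[feat])
            cph = CoxPHFitter()
            cph.fit(
                sub[["_z", *covariates, time, event]],
                duration_col=time,
                event_col=event,
            )
            row.update(
                hazard_ratio=float(np.exp(cph.params_["_z"])),
                ci_low=float(np.exp(cph.confidence_intervals_.loc["_z"].iloc[0])),
                ci_high=float(np.exp(cph.confidence_intervals_.loc["_z"].iloc[1])),
                p_value=float(cph.summary.loc["_z", "p"]),
            )
        except (ConvergenceError, ValueError) as exc:
            row.update(hazard_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                       p_value=np.nan, converged=False, reason=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = out["p_value"].notna()
    out["q_value"] = np.nan
    if ok.any():
        out.loc[ok, "q_value"] = bh_fdr(out.loc[ok, "p_value"].to_numpy())
    return out, n_excluded


def km_median_split(
    frame: pd.DataFrame,
    feature: str,
    time: str = "surv_time",
    event: str = "surv_event",
) -> dict:
    """Kaplan–Meier comparison of the cohort split at the feature median
    (ties, i.e. values equal to the median, go to the high group), with the
    log-rank test and a Cox hazard ratio on the binary high/low indicator
    (no covariates)."""
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df, _ = _clean_survival_frame(frame, time, event, [feature])
    med = df[feature].median()
    high = df[feature] >= med
    if high.all() or not high.any():
        raise ValueError("degenerate median split: all samples in one group")

    curves = {}
    for name, sel in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(df.loc[sel, time], df.loc[sel, event], label=name)
        sf = km.survival_function_
        curves[name] = {
            "times": sf.index.to_numpy(dtype=float),
            "survival": sf[name].to_numpy(dtype=float),
        }

    lr = logrank_test(
        df.loc[high, time], df.loc[~high, time],
        df.loc[high, event], df.loc[~high, event],
    )
    cox_df = pd.DataFrame(
        {"high": high.astype(int), time: df[time], event: df[event]}
    )
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col=time, event_col=event)
    with np.errstate(over="ignore"):  # degenerate toy CIs may overflow exp
        return {
            "curves": curves,
            "median_value": float(med),
            "logrank_p": float(lr.p_value),
            "hazard_ratio": float(np.exp(cph.params_["high"])),
            "ci_low": float(np.exp(cph.confidence_intervals_.loc["high"].iloc[0])),
            "ci_high": float(np.exp(cph.confidence_intervals_.loc["high"].iloc[1])),
            "cox_p": float(cph.summary.loc["high", "p"]),
        }


# ---------------------------------------------------------------------------
# Gene association and enrichment
# ---------------------------------------------------------------------------

def gene_association(
    feature: pd.Series, expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression (samples × genes)
    against one nuHIF, with BH correction across all genes.

    Sample ids must match between the feature vector and the expression
    index.  The p-value uses the t approximation (the vectorized screen
    targets cohort-scale n).
    """
    if not feature.index.equals(expression.index):
        if set(feature.index) != set(expression.index):
            raise ValueError("sample ids of feature and expression differ")
        expression = expression.loc[feature.index]
    n = len(feature)
    if n < 3:
        raise ValueError("need at least 3 samples")
    rf = stats.rankdata(feature.to_numpy(dtype=float))
    rE = stats.rankdata(expression.to_numpy(dtype=float), axis=0)
    rf_c = rf - rf.mean()
    rE_c = rE - rE.mean(axis=0)
    denom = np.sqrt((rf_c**2).sum() * (rE_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rf_c @ rE_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    p = np.array([_rho_t_pvalue(r, n) if np.isfinite(r) else np.nan
                  for r in rho])
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    q[ok] = bh_fdr(p[ok])
    return pd.DataFrame(
        {"gene": expression.columns, "spearman_rho": rho, "p": p, "q": q}
    )


def select_gene_sets(
    assoc: pd.DataFrame,
    q_cutoff: float = Q_CUTOFF,
    rho_cutoff: float = RHO_CUTOFF,
) -> tuple[list[str], list[str]]:
    """Positive/negative gene sets: q < cutoff and rho strictly above
    +cutoff (resp. strictly below −cutoff)."""
    sig = assoc["q"] < q_cutoff
    pos = assoc.loc[sig & (assoc["spearman_rho"] > rho_cutoff), "gene"]
    neg = assoc.loc[sig & (assoc["spearman_rho"] < -rho_cutoff), "gene"]
    return pos.tolist(), neg.tolist()


def overlap_enrichment(
    gene_set,
    pathway_collection: dict,
    universe,
    q_cutoff: float = Q_CUTOFF,
    top: int = 10,
) -> pd.DataFrame:
    """One-sided hypergeometric overlap enrichment of a query gene set
    against a pathway collection, BH-corrected across pathways, sorted by
    p, truncated to the ``top`` hits with q < cutoff."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(gene_set) & universe
    M = len(universe)
    rows = []
    for name in sorted(pathway_collection):
        members = set(pathway_collection[name]) & universe
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(M, |pathway|, |query|)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), len(query)))
        rows.append({"set_name": name, "overlap": k, "set_size": len(members),
                     "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    return out.loc[out["q"] < q_cutoff].head(top).reset_index(drop=True)


# ---------------------------------------------------------------------------
# UMAP input preparation (embedding itself is delegated)
# ---------------------------------------------------------------------------

UMAP_PARAMS = {"n_neighbors": 100, "n_components": 2, "metric": "euclidean"}


def prepare_umap_input(
    frame: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Z-scored feature matrix plus the recorded embedding parameters
    (100 neighbors, 2 output dimensions, Euclidean metric) to hand to an
    external embedder."""
    if feature_cols is None:
        feature_cols = [c for c in frame.columns
                        if pd.api.types.is_numeric_dtype(frame[c])]
    sub = frame[feature_cols]
    if sub.isna().any().any():
        raise ValueError("missing values present; apply an imputation policy first")
    z, flagged = zscore_columns(sub)
    return z[[c for c in feature_cols if c not in flagged]], dict(UMAP_PARAMS)
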