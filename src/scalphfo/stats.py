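"""Epoch-association statistics for clustered scalp HFOs.

Covers the inferential stage of the pipeline: the cluster-by-epoch
contingency table with a Pearson chi-square test, multinomial logistic
regression predicting the EEG epoch (ictal in active disease, interictal
in active disease, interictal in seizure-free disease) from cluster
membership, Tukey-Kramer honestly-significant-difference comparisons of
feature means across groups, and ordinary least squares for single
features with optional age adjustment.  Report writers emit the
cross-tabulation and regression tables as CSV/JSON.

In the saturated single-factor multinomial design (one categorical
predictor, one categorical outcome) the MLE reproduces the empirical
cell proportions, and each fitted odds ratio equals the corresponding
cross-product ratio of counts — properties the test suite exploits as
an independent oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import (
    EPOCH_LABELS,
    ICTAL_ACTIVE,
    INTERICTAL_ACTIVE,
    INTERICTAL_SEIZURE_FREE,
)

#: Column order of the published cross-tabulation.
EPOCH_ORDER = [INTERICTAL_SEIZURE_FREE, INTERICTAL_ACTIVE, ICTAL_ACTIVE]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Contingency table + chi-square
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    counts: pd.DataFrame      # clusters x epochs, integer counts

    @property
    def row_percentages(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0) * 100.0

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_contingency(clusters, epochs) -> ContingencyTable:
    """Cross-tabulate cluster labels against epoch labels."""
    cl = np.asarray(clusters)
    ep = np.asarray(epochs)
    if cl.size == 0 or cl.size != ep.size:
        raise StatsError("cluster and epoch vectors must be non-empty, equal length")
    bad = set(ep) - set(EPOCH_LABELS)
    if bad:
        raise StatsError(f"unknown epoch labels {sorted(bad)}")
    rows = sorted(set(int(c) for c in cl))
    cols = [e for e in EPOCH_ORDER if e in set(ep)] or EPOCH_ORDER
    counts = pd.DataFrame(0, index=[f"Cluster {r}" for r in rows], columns=cols)
    for c, e in zip(cl, ep):
        counts.loc[f"Cluster {int(c)}", e] += 1
    return ContingencyTable(counts)


def table_from_counts(counts: np.ndarray) -> ContingencyTable:
    """Wrap a ready-made clusters-by-epochs count matrix."""
    arr = np.asarray(counts, dtype=int)
    return ContingencyTable(
        pd.DataFrame(
            arr,
            index=[f"Cluster {i + 1}" for i in range(arr.shape[0])],
            columns=EPOCH_ORDER[: arr.shape[1]],
        )
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square_test(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square on the cluster-by-epoch counts, no continuity
    correction; expected counts from the row/column margins."""
    arr = table.counts.to_numpy()
    if arr.sum() == 0:
        raise StatsError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("zero margin in contingency table")
    res = sps.chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

@dataclass
class MultinomialFit:
    outcome_ref: str
    predictor_ref: str
    table: pd.DataFrame       # outcome, predictor, beta, se, odds_ratio, ci, p
    log_likelihood: float
    converged: bool
    separable: bool           # a zero cell makes some OR diverge
    cell_probs: pd.DataFrame  # fitted P(outcome | predictor level)


def multinomial_logit(
    outcome,
    predictor,
    outcome_ref: str = INTERICTAL_SEIZURE_FREE,
    predictor_ref=1,
    ci_level: float = 0.95,
) -> MultinomialFit:
    """Multinomial logit of epoch on dummy-coded cluster membership.

    Maximum likelihood via Newton iterations; odds ratios are exp(beta)
    with Wald confidence intervals on the log-odds scale.  A zero cell is
    flagged as separable (the corresponding OR estimate diverges) rather
    than silently failing.
    """
    y = pd.Series(outcome).astype(str)
    x = pd.Series(predictor)
    if outcome_ref not in set(y):
        raise StatsError(f"outcome reference {outcome_ref!r} not observed")
    if predictor_ref not in set(x):
        raise StatsError(f"predictor reference {predictor_ref!r} not observed")
    out_levels = [outcome_ref] + sorted(set(y) - {str(outcome_ref)})
    pred_levels = [predictor_ref] + sorted(set(x) - {predictor_ref})

    cross = pd.crosstab(x, y)
    separable = (cross.to_numpy() == 0).any()

    codes = pd.Categorical(y, categories=out_levels).codes
    design = pd.DataFrame({"const": np.ones(len(x))})
    for lev in pred_levels[1:]:
        design[f"level_{lev}"] = (x == lev).astype(float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(codes, design.to_numpy()).fit(
            method="newton", maxiter=500, disp=0
        )

    zcrit = sps.norm.ppf(0.5 + ci_level / 2)
    rows = []
    for j, out_lev in enumerate(out_levels[1:]):
        for i, pred_lev in enumerate(pred_levels[1:], start=1):
            params = np.atleast_2d(fit.params)   # k_exog x (J-1)
            bse = np.atleast_2d(fit.bse)
            beta = float(params[i, j])
            se = float(bse[i, j])
            with np.errstate(over="ignore"):
                or_, lo, hi = (
                    float(np.exp(beta)),
                    float(np.exp(beta - zcrit * se)),
                    float(np.exp(beta + zcrit * se)),
                )
            rows.append(
                {
                    "outcome": out_lev,
                    "predictor": pred_lev,
                    "beta": beta,
                    "se": se,
                    "odds_ratio": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else np.nan,
                }
            )
    # fitted P(outcome | predictor level), one design row per level
    uniq = pd.DataFrame({"const": np.ones(len(pred_levels))})
    for lev in pred_levels[1:]:
        uniq[f"level_{lev}"] = [float(p == lev) for p in pred_levels]
    probs = fit.predict(uniq.to_numpy())
    cell_probs = pd.DataFrame(probs, index=pred_levels, columns=out_levels)
    return MultinomialFit(
        outcome_ref=str(outcome_ref),
        predictor_ref=predictor_ref,
        table=pd.DataFrame(rows),
        log_likelihood=float(fit.llf),
        converged=bool(fit.mle_retvals.get("converged", True)),
        separable=bool(separable),
        cell_probs=cell_probs,
    )


def cross_product_ratio(
    table: ContingencyTable, cluster: int, epoch: str,
    cluster_ref: int = 1, epoch_ref: str = INTERICTAL_SEIZURE_FREE,
) -> float:
    """Closed-form OR of the 2x2 sub-table — the saturated-model value."""
    c = table.counts
    a = c.loc[f"Cluster {cluster}", epoch]
    b = c.loc[f"Cluster {cluster}", epoch_ref]
    d = c.loc[f"Cluster {cluster_ref}", epoch]
    e = c.loc[f"Cluster {cluster_ref}", epoch_ref]
    return float((a * e) / (b * d))


# ---------------------------------------------------------------------------
# Tukey-Kramer HSD
# ---------------------------------------------------------------------------

@dataclass
class HsdResult:
    table: pd.DataFrame    # group_a, group_b, mean_diff, q, p_adjusted
    mse: float
    df: int


def tukey_kramer_hsd(values, groups) -> HsdResult:
    """All-pairs comparison of group means with the studentized range.

    q_ij = |mean_i - mean_j| / sqrt(MSE/2 x (1/n_i + 1/n_j)); adjusted p
    from the studentized-range distribution with N - g error df.  Valid
    for unequal group sizes (the Kramer extension); with equal sizes it
    reduces to Tukey's HSD.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise StatsError("need at least two groups")
    sizes = {lev: int(np.sum(g == lev)) for lev in levels}
    if min(sizes.values()) < 2:
        raise StatsError("every group needs at least two observations")
    means = {lev: v[g == lev].mean() for lev in levels}
    n_total = v.size
    df = n_total - len(levels)
    sse = sum(np.sum((v[g == lev] - means[lev]) ** 2) for lev in levels)
    mse = sse / df
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            diff = means[b] - means[a]
            se = np.sqrt(mse / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, len(levels), df))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": float(diff),
                 "q": float(q), "p_adjusted": min(max(p, 0.0), 1.0)}
            )
    return HsdResult(pd.DataFrame(rows), float(mse), int(df))


# ---------------------------------------------------------------------------
# OLS with optional age adjustment
# ---------------------------------------------------------------------------

@dataclass
class OlsFit:
    table: pd.DataFrame     # term, beta, ci_low, ci_high, std_beta, p_value
    adjusted: bool
    r_squared: float
    residual_df: int


def ols_regression(
    response,
    epoch,
    age=None,
    epoch_ref: str = INTERICTAL_SEIZURE_FREE,
    ci_level: float = 0.95,
) -> OlsFit:
    """OLS of a feature on epoch dummies (reference = seizure-free
    interictal), optionally adjusted for age at the recording.

    Standardized coefficients are beta x SD(predictor)/SD(response).
    """
    y = np.asarray(response, dtype=float)
    ep = pd.Series(epoch).astype(str)
    if epoch_ref not in set(ep):
        raise StatsError(f"reference epoch {epoch_ref!r} not observed")
    levels = [epoch_ref] + [e for e in EPOCH_ORDER if e in set(ep) and e != epoch_ref]
    extra = sorted(set(ep) - set(levels))
    levels += extra
    design = pd.DataFrame({"const": np.ones(y.size)})
    for lev in levels[1:]:
        design[lev] = (ep == lev).astype(float).to_numpy()
    if age is not None:
        design["age"] = np.asarray(age, dtype=float)
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=1 - ci_level)
    sd_y = y.std(ddof=0)
    rows = []
    for j, term in enumerate(design.columns):
        if term == "const":
            continue
        sd_x = design[term].std(ddof=0)
        rows.append(
            {
                "term": term,
                "beta": float(fit.params[j]),
                "ci_low": float(ci[j][0]),
                "ci_high": float(ci[j][1]),
                "std_beta": float(fit.params[j] * sd_x / sd_y) if sd_y > 0 else np.nan,
                "p_value": float(fit.pvalues[j]),
            }
        )
    return OlsFit(
        table=pd.DataFrame(rows),
        adjusted=age is not None,
        r_squared=float(fit.rsquared),
        residual_df=int(fit.df_resid),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Three decimals, floored at '<0.001' (report style)."""
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def epoch_association_report(
    table: ContingencyTable, fit: MultinomialFit | None = None
) -> pd.DataFrame:
    """Cross-tabulation report: counts with row percentages and, when a
    multinomial fit is supplied, OR [95% CI] and p per non-reference cell."""
    pct = table.row_percentages
    rows = []
    for cluster in table.counts.index:
        row: dict = {"cluster": cluster}
        for ep in table.counts.columns:
            n = int(table.counts.loc[cluster, ep])
            row[f"{ep}_n"] = n
            row[f"{ep}_pct"] = round(float(pct.loc[cluster, ep]), 1)
        if int(table.counts.loc[cluster].sum()) == 0:
            row["warning"] = "empty cluster"
        rows.append(row)
    report = pd.DataFrame(rows)
    if fit is not None:
        for _, r in fit.table.iterrows():
            cl = f"Cluster {r['predictor']}"
            pre = f"{r['outcome']}_"
            report.loc[report["cluster"] == cl, pre + "or"] = round(r["odds_ratio"], 2)
            report.loc[report["cluster"] == cl, pre + "ci"] = (
                f"{r['ci_low']:.2f}-{r['ci_high']:.2f}"
            )
            report.loc[report["cluster"] == cl, pre + "p"] = format_p(r["p_value"])
    return report


def feature_regression_report(
    features: pd.DataFrame,
    age: np.ndarray | None = None,
    feature_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Crude and (when age is given) age-adjusted OLS of each feature on
    the epoch, mirroring the published regression table layout."""
    feature_cols = feature_cols or {
        "avg_frequency_hz": "average_frequency",
        "duration_ms": "duration",
        "log_amplitude": "log_amplitude",
        "log_n_cycles": "log_n_cycles",
    }
    work = features.copy()
    if "log_amplitude" not in work:
        work["log_amplitude"] = np.log(work["amplitude_z"])
    if "log_n_cycles" not in work:
        work["log_n_cycles"] = np.log(work["n_cycles"])
    rows = []
    for col, name in feature_cols.items():
        variants = [("crude", None)]
        if age is not None:
            variants.append(("age_adjusted", age))
        for variant, a in variants:
            fit = ols_regression(work[col], work["epoch"], age=a)
            for _, r in fit.table.iterrows():
                rows.append(
                    {
                        "feature": name,
                        "model": variant,
                        "term": r["term"],
                        "beta": round(r["beta"], 4),
                        "ci_low": round(r["ci_low"], 4),
                        "ci_high": round(r["ci_high"], 4),
                        "std_beta": round(r["std_beta"], 4),
                        "p": format_p(r["p_value"]),
                    }
                )
    return pd.DataFrame(rows)


def make_reports(
    table: ContingencyTable,
    fit: MultinomialFit | None,
    chi2: ChiSquareResult,
    features: pd.DataFrame | None,
    out_dir,
    age: np.ndarray | None = None,
) -> dict[str, str]:
    """Write table2.csv (cross-tabulation + ORs), table3.csv (feature
    regressions) and stats.json; byte-identical for identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    t2 = epoch_association_report(table, fit)
    t2_path = out / "table2.csv"
    t2.to_csv(t2_path, index=False)
    paths["table2"] = str(t2_path)
    if features is not None and "epoch" in features:
        t3 = feature_regression_report(features, age=age)
        t3_path = out / "table3.csv"
        t3.to_csv(t3_path, index=False)
        paths["table3"] = str(t3_path)
    payload = {
        "chi_square": {
            "statistic": round(chi2.statistic, 4),
            "df": chi2.df,
            "p": format_p(chi2.p_value),
        },
        "grand_total": table.grand_total,
        "multinomial": None
        if fit is None
        else {
            "outcome_ref": fit.outcome_ref,
            "predictor_ref": str(fit.predictor_ref),
            "converged": fit.converged,
            "separable": fit.separable,
            "log_likelihood": round(fit.log_likelihood, 6),
            "odds_ratios": [
                {
                    "outcome": r["outcome"],
                    "predictor": str(r["predictor"]),
                    "or": None if not np.isfinite(r["odds_ratio"]) else round(r["odds_ratio"], 4),
                    "ci": [round(r["ci_low"], 4), round(r["ci_high"], 4)],
                    "p": format_p(r["p_value"]),
                }
                for _, r in fit.table.iterrows()
            ],
        },
    }
    js_path = out / "stats.json"
    js_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["stats"] = str(js_path)
    return paths
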