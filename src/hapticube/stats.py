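"""Group-level statistics over the per-trial metrics table.

The discrimination stage tests whether the haptic exploration profile
separates the CB / LB / SI groups: a one-way MANOVA summarized by Roy's
largest root (the top eigenvalue of W^-1 B, W and B the within- and
between-group SSCP matrices), a follow-up Fisher linear discriminant
analysis on the same eigenproblem, univariate ANOVAs with Welch pairwise
post-hocs under Benjamini-Hochberg FDR, a BIC-approximated Bayes factor for
recognition accuracy after a Box-Cox transformation, and one-tailed Pearson
correlations between exploration speed indices and duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# accuracy: Box-Cox + BIC Bayes factor


def boxcox_mle_grid(x: np.ndarray, lo: float = -2.0, hi: float = 2.0, step: float = 0.01) -> float:
    """Maximum-likelihood Box-Cox exponent on a fixed grid."""
    lambdas = np.arange(lo, hi + step / 2, step)
    llf = np.array([sps.boxcox_llf(lmb, x) for lmb in lambdas])
    return float(lambdas[int(np.argmax(llf))])


def _ols_bic(y: np.ndarray, design: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ beta) ** 2))
    k = design.shape[1] + 1  # coefficients + error variance
    return n * np.log(rss / n) + k * np.log(n)


def accuracy_bayes_factor(accuracy: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """BF01 for a group effect on (Box-Cox transformed) accuracy.

    Values > 1 favor the no-group-effect model. Zero accuracies are shifted
    by 1e-3 before the transform (Box-Cox needs positive inputs). The Bayes
    factor is the BIC approximation exp((BIC_group - BIC_null) / 2).
    Returns (BF01, lambda).
    """
    x = np.asarray(accuracy, dtype=float)
    g = np.asarray(groups)
    if np.ptp(x) == 0:
        raise ValidationError("accuracy is constant; Bayes factor undefined")
    if (x <= 0).any():
        x = x + 1e-3
    lmb = boxcox_mle_grid(x)
    y = sps.boxcox(x, lmbda=lmb)
    levels = np.unique(g)
    dummies = np.column_stack([np.ones_like(y)] + [(g == lv).astype(float) for lv in levels[1:]])
    bic_group = _ols_bic(y, dummies)
    bic_null = _ols_bic(y, np.ones((len(y), 1)))
    return float(np.exp((bic_group - bic_null) / 2.0)), lmb


# ---------------------------------------------------------------------------
# MANOVA (Roy's largest root) and LDA: eigenstructure of W^-1 B


def _sscp(table: pd.DataFrame, variables: list[str], group: str) -> tuple[np.ndarray, np.ndarray, int, int]:
    x = table[variables].to_numpy(dtype=float)
    g = table[group].to_numpy()
    if np.isnan(x).any():
        raise ValidationError("analyzed columns contain missing values")
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    grand = x.mean(axis=0)
    b = np.zeros((x.shape[1], x.shape[1]))
    w = np.zeros_like(b)
    for lv in levels:
        xi = x[g == lv]
        d = xi.mean(axis=0) - grand
        b += len(xi) * np.outer(d, d)
        c = xi - xi.mean(axis=0)
        w += c.T @ c
    return b, w, len(x), len(levels)


def _check_w(w: np.ndarray, variables: list[str]) -> None:
    if np.linalg.matrix_rank(w) < w.shape[0]:
        diag = np.sqrt(np.diag(w))
        corr = w / np.outer(diag, diag)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"within-group SSCP is singular; check collinear columns "
            f"(|r| largest for {variables[i]} ~ {variables[j]})"
        )


@dataclass(frozen=True)
class ManovaRoyResult:
    roy: float
    f_value: float
    df1: int
    df2: int
    p_value: float


def manova_roy(table: pd.DataFrame, variables: list[str], group: str = "group") -> ManovaRoyResult:
    """Roy's largest root with its union-intersection F approximation.

    Roy's statistic is the largest eigenvalue of W^-1 B. The F approximation
    (an upper bound on significance, as conventionally reported) uses
    r = max(p, g - 1): F = roy * (n - g - r + g - 1) / r on (r, n - g - r + g - 1)
    degrees of freedom.
    """
    b, w, n, g = _sscp(table, variables, group)
    _check_w(w, variables)
    eigvals = linalg.eigvals(np.linalg.solve(w, b))
    roy = float(np.max(eigvals.real))
    p = len(variables)
    q = g - 1
    r = max(p, q)
    df1 = r
    df2 = n - g - r + q
    f_value = roy * df2 / df1
    p_value = float(sps.f.sf(f_value, df1, df2))
    return ManovaRoyResult(roy=roy, f_value=f_value, df1=df1, df2=df2, p_value=p_value)


@dataclass
class LdaResult:
    """Fisher discriminants of the group structure.

    ``coefficients`` is a (p, k) frame (variables x discriminants) scaled so
    the within-group covariance of the scores is the identity (normalized
    coefficients); ``proportion`` is each discriminant's share of the
    between/within eigenvalue trace (percent, sums to 100); ``scores`` holds
    the per-row projections; ``group_means`` the centroid of each group on
    each discriminant.
    """

    coefficients: pd.DataFrame
    eigenvalues: np.ndarray
    proportion: np.ndarray
    scores: pd.DataFrame
    group_means: pd.DataFrame


def lda_fit(table: pd.DataFrame, variables: list[str], group: str = "group") -> LdaResult:
    """Fisher LDA from the W^-1 B eigenproblem (same as Roy's root).

    The number of discriminants is min(groups - 1, variables). Each
    discriminant's sign is fixed so its largest-|coefficient| entry is
    positive.
    """
    b, w, n, g = _sscp(table, variables, group)
    _check_w(w, variables)
    p = len(variables)
    k = min(g - 1, p)
    # generalized symmetric eigenproblem B a = lambda W a, W positive definite
    eigvals, eigvecs = linalg.eigh(b, w)
    order = np.argsort(eigvals)[::-1][:k]
    lam = eigvals[order]
    vecs = eigvecs[:, order]  # scipy returns a' W a = I
    # spherical within-group covariance of scores: a' (W / (n - g)) a = 1
    vecs = vecs * np.sqrt(n - g)
    for j in range(k):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] *= -1.0
    names = [f"LD{j + 1}" for j in range(k)]
    coef = pd.DataFrame(vecs, index=variables, columns=names)
    x = table[variables].to_numpy(dtype=float)
    scores_arr = (x - x.mean(axis=0)) @ vecs
    scores = pd.DataFrame(scores_arr, columns=names, index=table.index)
    scores[group] = table[group].to_numpy()
    means = scores.groupby(group, observed=True)[names].mean()
    proportion = lam / lam.sum() * 100.0 if lam.sum() > 0 else np.zeros(k)
    return LdaResult(
        coefficients=coef,
        eigenvalues=lam,
        proportion=proportion,
        scores=scores,
        group_means=means,
    )


# ---------------------------------------------------------------------------
# univariate follow-up: ANOVA + Welch post-hocs + BH-FDR


@dataclass
class FollowupResult:
    variable: str
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    posthoc: pd.DataFrame  # pairwise Welch tests with BH-adjusted p


def univariate_followup(table: pd.DataFrame, variable: str, group: str = "group") -> FollowupResult:
    """One-way ANOVA plus pairwise Welch t-tests, BH-adjusted as one family."""
    g = table[group].to_numpy()
    levels = list(np.unique(g))
    samples = [table.loc[g == lv, variable].to_numpy(dtype=float) for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValidationError("every group needs at least two observations")
    f_value, p_value = sps.f_oneway(*samples)
    n = sum(len(s) for s in samples)
    rows = []
    for (i, a), (j, b) in combinations(enumerate(levels), 2):
        res = sps.ttest_ind(samples[i], samples[j], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(res.statistic),
                "df": float(res.df),
                "p_raw": float(res.pvalue),
            }
        )
    posthoc = pd.DataFrame(rows)
    posthoc["p_fdr"] = multipletests(posthoc["p_raw"], method="fdr_bh")[1]
    posthoc["significant"] = posthoc["p_fdr"] < ALPHA
    return FollowupResult(
        variable=variable,
        anova_f=float(f_value),
        anova_df=(len(levels) - 1, n - len(levels)),
        anova_p=float(p_value),
        posthoc=posthoc,
    )


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up), for a declared family."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# directed correlations


def one_tailed_pearson(x: np.ndarray, y: np.ndarray, direction: str) -> tuple[float, float]:
    """Pearson r with a one-tailed p in the declared direction.

    ``direction`` is 'negative' (alternative r < 0) or 'positive'.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in input")
    alternative = {"negative": "less", "positive": "greater"}[direction]
    res = sps.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# orchestration


def aggregate_by_participant(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Participant-mean metrics table (one row per participant)."""
    keep = ["participant_id", "group"]
    agg = table.groupby(keep, observed=True)[variables].mean().reset_index()
    return agg


def analyze(
    metrics: pd.DataFrame,
    accuracy: pd.DataFrame | None = None,
    variables: list[str] | None = None,
    unit: str = "trial",
    n_followup: int = 3,
) -> dict:
    """Full group-discrimination analysis of a metrics table.

    ``unit`` selects the observation unit: 'trial' (default; matches the
    per-trial MetricsRow) or 'participant' (participant means; appropriate
    when trials within a participant are strongly clustered). Follow-up
    ANOVAs are run on the ``n_followup`` variables with the largest |LD1|
    coefficients. Correlations pair mean SMC (positive tail) and mean active
    cells (negative tail) with exploration duration, BH-corrected as one
    family.
    """
    from .pipeline import METRIC_COLUMNS

    variables = list(variables or METRIC_COLUMNS)
    table = metrics if unit == "trial" else aggregate_by_participant(metrics, variables)
    manova = manova_roy(table, variables)
    lda = lda_fit(table, variables)
    top = lda.coefficients["LD1"].abs().sort_values(ascending=False).index[:n_followup]
    followups = {v: univariate_followup(table, v) for v in top}

    correlations = None
    if {"mean_smc", "mean_active_cells", "exploration_duration"} <= set(variables):
        r_smc, p_smc = one_tailed_pearson(
            table["mean_smc"], table["exploration_duration"], "positive"
        )
        r_cells, p_cells = one_tailed_pearson(
            table["mean_active_cells"], table["exploration_duration"], "negative"
        )
        p_fdr = benjamini_hochberg([p_smc, p_cells])
        correlations = pd.DataFrame(
            {
                "x": ["mean_smc", "mean_active_cells"],
                "y": ["exploration_duration"] * 2,
                "direction": ["positive", "negative"],
                "r": [r_smc, r_cells],
                "p_raw": [p_smc, p_cells],
                "p_fdr": p_fdr,
            }
        )

    bayes = None
    if accuracy is not None and len(accuracy) and accuracy["accuracy"].nunique() > 1:
        bf01, lmb = accuracy_bayes_factor(
            accuracy["accuracy"].to_numpy(), accuracy["group"].to_numpy()
        )
        bayes = {"BF01": bf01, "boxcox_lambda": lmb}

    return {
        "unit": unit,
        "variables": variables,
        "manova": manova,
        "lda": lda,
        "followups": followups,
        "correlations": correlations,
        "accuracy_bayes": bayes,
    }
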