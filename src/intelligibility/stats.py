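"""Statistical analyses for listener-ASR agreement studies.

The analysis layer mirrors the study design: Pearson correlations between
listener and ASR scores; an unbalanced two-way ANOVA (Type III sums of
squares, sum-to-zero coding) of agreement on language x group with partial
eta squared; a split-plot (mixed) ANOVA with stimulus type within subjects
and group between subjects; estimated-marginal-mean pairwise contrasts with
Tukey(-Kramer) HSD adjustment; per-subgroup OLS regressions of agreement on
listener intelligibility with Holm-Bonferroni correction; and a
skewness/kurtosis normality screen.

Under a full-interaction fixed-effects model the estimated marginal mean of
a cell is the raw cell mean, so the contrast machinery here accepts cell
summary statistics (means, SDs, ns) directly as well as fitted models —
printed summary tables are sufficient input to reproduce contrast
estimates and pooled standard errors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError

__all__ = [
    "CorrelationResult",
    "AnovaEffect",
    "FactorialAnovaResult",
    "SplitPlotAnovaResult",
    "ContrastRow",
    "RegressionResult",
    "NormalityScreen",
    "pearson",
    "two_way_anova",
    "split_plot_anova",
    "emm_pairwise",
    "cell_means_contrasts",
    "pooled_error_variance",
    "tukey_p",
    "holm_adjust",
    "subgroup_regressions",
    "normality_screen",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n)


# ---------------------------------------------------------------------------
# factorial ANOVA


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    ss: float
    df: float
    F: float
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class FactorialAnovaResult:
    """Type III two-way ANOVA with the data needed for EMM contrasts."""

    effects: dict[str, AnovaEffect]
    ss_error: float
    df_error: float
    mse: float
    cell_means: dict[str, float]
    cell_ns: dict[str, int]
    degenerate: bool = False


def two_way_anova(y, factor_a, factor_b, names: tuple[str, str] = ("A", "B")) -> FactorialAnovaResult:
    """Unbalanced two-way ANOVA, Type III SS with sum-to-zero factor coding.

    Every cell of the A x B cross must be non-empty.  A design whose
    within-cell variance is zero is returned flagged as degenerate (F and p
    are NaN) rather than raising, so simulation sweeps keep running.
    """
    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    )
    counts = df.groupby(["a", "b"], observed=True).size()
    n_cells = df["a"].nunique() * df["b"].nunique()
    if len(counts) < n_cells:
        raise DegenerateInputError("empty cell in two-way design")
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    ss_error = float(model.ssr)
    df_error = float(model.df_resid)
    degenerate = ss_error <= 1e-12 * max(1.0, float(np.sum(df["y"] ** 2)))
    table = sm.stats.anova_lm(model, typ=3)
    effects: dict[str, AnovaEffect] = {}
    term_map = {
        "C(a, Sum)": names[0],
        "C(b, Sum)": names[1],
        "C(a, Sum):C(b, Sum)": f"{names[0]}:{names[1]}",
    }
    for term, label in term_map.items():
        ss = float(table.loc[term, "sum_sq"])
        dfe = float(table.loc[term, "df"])
        if degenerate:
            F = p = float("nan")
        else:
            F = float(table.loc[term, "F"])
            p = float(table.loc[term, "PR(>F)"])
        eta = ss / (ss + ss_error) if (ss + ss_error) > 0 else float("nan")
        effects[label] = AnovaEffect(name=label, ss=ss, df=dfe, F=F, p=p, partial_eta_sq=eta)
    means = df.groupby(["a", "b"], observed=True)["y"].mean()
    cell_means = {f"{a} {b}": float(m) for (a, b), m in means.items()}
    cell_ns = {f"{a} {b}": int(c) for (a, b), c in counts.items()}
    return FactorialAnovaResult(
        effects=effects,
        ss_error=ss_error,
        df_error=df_error,
        mse=ss_error / df_error if df_error > 0 else float("nan"),
        cell_means=cell_means,
        cell_ns=cell_ns,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# split-plot (mixed) ANOVA


@dataclass(frozen=True)
class SplitPlotAnovaResult:
    """Classical split-plot decomposition: between and within error strata."""

    effects: dict[str, AnovaEffect]
    ss_subject_error: float
    df_subject_error: float
    ss_within_error: float
    df_within_error: float
    n_subjects: int
    n_dropped: int
    cell_means: dict[str, float]
    cell_ns: dict[str, int]
    ms_subject_error: float = field(init=False)
    ms_within_error: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "ms_subject_error", self.ss_subject_error / self.df_subject_error
        )
        object.__setattr__(
            self, "ms_within_error", self.ss_within_error / self.df_within_error
        )

    @property
    def ss_total(self) -> float:
        return (
            sum(e.ss for e in self.effects.values())
            + self.ss_subject_error
            + self.ss_within_error
        )


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def split_plot_anova(
    y, between, within, subject, names: tuple[str, str] = ("group", "stimulus")
) -> SplitPlotAnovaResult:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    Subjects missing any within level are dropped (complete cases) with a
    logged count.  Sums of squares come from sequential nested linear-model
    fits (grand mean, +group, +subjects, +stimulus, +interaction), which is
    the classical decomposition: subjects-within-groups is the error term
    for the between factor, and the within-by-subject residual is the error
    term for the within factor and the interaction.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "g": np.asarray(between).astype(str),
            "w": np.asarray(within).astype(str),
            "s": np.asarray(subject).astype(str),
        }
    )
    w_levels = sorted(df["w"].unique())
    complete = df.groupby("s")["w"].nunique() == len(w_levels)
    dropped = int((~complete).sum())
    if dropped:
        log.warning("split_plot_anova: dropping %d subjects missing a within level", dropped)
    df = df[df["s"].map(complete)].reset_index(drop=True)
    n_subj = df["s"].nunique()
    n_groups = df["g"].nunique()
    if n_subj <= n_groups:
        raise DegenerateInputError("not enough complete subjects for a split-plot fit")

    yv = df["y"].to_numpy()
    one = np.ones((len(df), 1))
    Xg = pd.get_dummies(df["g"], drop_first=True, dtype=float).to_numpy()
    Xs = pd.get_dummies(df["s"], drop_first=True, dtype=float).to_numpy()
    Xw = pd.get_dummies(df["w"], drop_first=True, dtype=float).to_numpy()
    # group:within interaction columns
    Xgw = np.column_stack(
        [Xg[:, i] * Xw[:, j] for i in range(Xg.shape[1]) for j in range(Xw.shape[1])]
    ) if Xg.shape[1] and Xw.shape[1] else np.empty((len(df), 0))

    rss0 = _rss(yv, one)
    rss_g = _rss(yv, np.hstack([one, Xg]))
    rss_s = _rss(yv, np.hstack([one, Xs]))  # subjects absorb group
    rss_sw = _rss(yv, np.hstack([one, Xs, Xw]))
    rss_full = _rss(yv, np.hstack([one, Xs, Xw, Xgw]))

    ss_group = rss0 - rss_g
    ss_subj = rss_g - rss_s
    ss_within = rss_s - rss_sw
    ss_inter = rss_sw - rss_full
    ss_resid = rss_full

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_within = len(w_levels) - 1
    df_inter = df_group * df_within
    df_resid = df_subj * df_within

    ms_subj = ss_subj / df_subj
    ms_resid = ss_resid / df_resid

    def effect(name, ss, dfe, ms_err, df_err):
        F = (ss / dfe) / ms_err if ms_err > 0 else float("nan")
        p = float(sps.f.sf(F, dfe, df_err)) if ms_err > 0 else float("nan")
        err_ss = ms_err * df_err
        eta = ss / (ss + err_ss) if (ss + err_ss) > 0 else float("nan")
        return AnovaEffect(name=name, ss=ss, df=dfe, F=F, p=p, partial_eta_sq=eta)

    effects = {
        names[0]: effect(names[0], ss_group, df_group, ms_subj, df_subj),
        names[1]: effect(names[1], ss_within, df_within, ms_resid, df_resid),
        f"{names[0]}:{names[1]}": effect(
            f"{names[0]}:{names[1]}", ss_inter, df_inter, ms_resid, df_resid
        ),
    }
    means = df.groupby(["g", "w"])["y"].mean()
    ns = df.groupby(["g", "w"])["y"].size()
    return SplitPlotAnovaResult(
        effects=effects,
        ss_subject_error=ss_subj,
        df_subject_error=df_subj,
        ss_within_error=ss_resid,
        df_within_error=df_resid,
        n_subjects=n_subj,
        n_dropped=dropped,
        cell_means={f"{g} {w}": float(m) for (g, w), m in means.items()},
        cell_ns={f"{g} {w}": int(c) for (g, w), c in ns.items()},
    )


# ---------------------------------------------------------------------------
# estimated marginal means and pairwise contrasts


@dataclass(frozen=True)
class ContrastRow:
    """One pairwise estimated-marginal-means contrast (a Table-2-style row)."""

    label: str
    estimate: float
    se: float
    df: float
    t_ratio: float
    p_adj: float


def tukey_p(t_ratio: float, k: int, df: float) -> float:
    """Tukey(-Kramer) HSD adjusted p from the studentized-range distribution."""
    q = abs(t_ratio) * math.sqrt(2.0)
    return float(sps.studentized_range.sf(q, k, df))


def pooled_error_variance(sds, ns) -> tuple[float, float]:
    """Pooled within-cell error variance (MSE) and its df from cell SDs/ns."""
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    df = float(np.sum(ns - 1))
    mse = float(np.sum((ns - 1) * sds**2) / df)
    return mse, df


def cell_means_contrasts(
    means: dict[str, float],
    ns: dict[str, int],
    mse: float,
    df_error: float,
    pairs: list[tuple[str, str]] | None = None,
    k: int | None = None,
) -> list[ContrastRow]:
    """Pairwise EMM contrasts from cell summary statistics.

    Under a full-interaction model each cell's estimated marginal mean is
    its raw mean, so a contrast estimate is a difference of cell means; the
    SE is sqrt(MSE * (1/n_i + 1/n_j)) and the Tukey-Kramer adjustment uses
    the studentized range with ``k`` groups (all cells by default) on the
    error df.
    """
    labels = list(means)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    if k is None:
        k = len(labels)
    rows = []
    for a, b in pairs:
        est = means[a] - means[b]
        se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
        t = est / se
        rows.append(
            ContrastRow(
                label=f"{a} - {b}",
                estimate=est,
                se=se,
                df=df_error,
                t_ratio=t,
                p_adj=min(1.0, tukey_p(t, k, df_error)),
            )
        )
    return rows


def emm_pairwise(
    model: FactorialAnovaResult | SplitPlotAnovaResult,
    pairs: list[tuple[str, str]] | None = None,
) -> list[ContrastRow]:
    """Pairwise EMM contrasts with Tukey HSD from a fitted ANOVA.

    For the factorial model the error variance is the residual MSE.  For
    the split-plot model the variance of a contrast mixes the two error
    strata: a within-subject comparison uses the within-error MS alone,
    while a between-subject comparison uses (MS_subject + (w-1) MS_within)/w
    with Satterthwaite df.  Contrast estimates are cell-mean differences in
    either case.
    """
    if isinstance(model, FactorialAnovaResult):
        return cell_means_contrasts(
            model.cell_means, model.cell_ns, model.mse, model.df_error, pairs=pairs
        )
    means, ns = model.cell_means, model.cell_ns
    labels = list(means)
    if pairs is None:
        pairs = list(itertools.combinations(labels, 2))
    k = len(labels)
    w = 2  # within factor levels in a contrastable split-plot cell table
    rows = []
    for a, b in pairs:
        est = means[a] - means[b]
        ga, wa = a.rsplit(" ", 1)
        gb, wb = b.rsplit(" ", 1)
        coef = 1.0 / ns[a] + 1.0 / ns[b]
        if ga == gb:  # within-subject comparison inside one group
            var = model.ms_within_error * 2.0 / ns[a]
            dfc = model.df_within_error
        else:
            c_subj = (1.0 / w) * coef
            c_with = ((w - 1.0) / w) * coef
            v1 = c_subj * model.ms_subject_error
            v2 = c_with * model.ms_within_error
            var = v1 + v2
            dfc = (v1 + v2) ** 2 / (
                v1**2 / model.df_subject_error + v2**2 / model.df_within_error
            )
        se = math.sqrt(var)
        t = est / se
        rows.append(
            ContrastRow(
                label=f"{a} - {b}",
                estimate=est,
                se=se,
                df=dfc,
                t_ratio=t,
                p_adj=min(1.0, tukey_p(t, k, dfc)),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# regressions with Holm-Bonferroni


@dataclass(frozen=True)
class RegressionResult:
    label: str
    slope: float
    intercept: float
    r_sq: float
    p_slope: float
    p_adj: float
    n: int


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def subgroup_regressions(x, y, labels) -> list[RegressionResult]:
    """Per-subgroup OLS of y on x, slope p-values Holm-adjusted as a family.

    The family is the set of subgroups passed in one call (e.g. the four
    language-by-group word models, or the two sentence models).
    """
    df = pd.DataFrame(
        {"x": np.asarray(x, float), "y": np.asarray(y, float), "lab": np.asarray(labels)}
    )
    partial = []
    for lab, sub in df.groupby("lab", sort=True):
        if len(sub) < 3:
            raise ValueError(f"subgroup {lab!r} has fewer than 3 points")
        if np.ptp(sub["x"].to_numpy()) == 0:
            raise DegenerateInputError(f"subgroup {lab!r} has zero x-variance")
        fit = sps.linregress(sub["x"], sub["y"])
        r_sq = float(fit.rvalue**2)
        p = float(fit.pvalue)
        if np.ptp(sub["y"].to_numpy()) == 0:  # flat response: slope 0, no evidence
            r_sq, p = 0.0, 1.0
        partial.append((str(lab), float(fit.slope), float(fit.intercept), r_sq, p, len(sub)))
    adj = holm_adjust([p[4] for p in partial])
    return [
        RegressionResult(
            label=lab, slope=b, intercept=a, r_sq=r2, p_slope=p, p_adj=float(pa), n=n
        )
        for (lab, b, a, r2, p, n), pa in zip(partial, adj)
    ]


# ---------------------------------------------------------------------------
# normality screen


@dataclass(frozen=True)
class NormalityScreen:
    skewness: float
    kurtosis: float  # excess kurtosis (normal -> 0)
    pass_skew: bool
    pass_kurt: bool
    n: int


def normality_screen(
    values, skew_limit: float = 2.0, kurt_limit: float = 7.0
) -> NormalityScreen:
    """Skewness/excess-kurtosis screen with small-sample bias correction.

    The conventional screening thresholds (|skew| <= 2, |excess kurtosis|
    <= 7) flag only marked departures from normality.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations for the screen")
    if np.ptp(v) == 0:  # constant data: moments undefined, nothing to screen
        return NormalityScreen(
            skewness=float("nan"), kurtosis=float("nan"),
            pass_skew=False, pass_kurt=False, n=int(v.size),
        )
    skew = float(sps.skew(v, bias=False))
    kurt = float(sps.kurtosis(v, fisher=True, bias=False))
    return NormalityScreen(
        skewness=skew,
        kurtosis=kurt,
        pass_skew=abs(skew) <= skew_limit,
        pass_kurt=abs(kurt) <= kurt_limit,
        n=int(v.size),
    )
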