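"""Statistical analyses for the repeated-measures treatment design.

The analysis families, all with two-tailed p-values:

* cross-sectional OLS of baseline task measures on the three symptom
  dimensions, controlling for age, gender and education;
* random-intercept linear mixed models of pre/post change (time coded
  baseline=0, follow-up=1), fit by maximum likelihood with Wald p-values;
* time x between-person-covariate interaction models (the covariate is a
  single value per person: a change score, a baseline score, an engagement
  measure, or a category);
* Pearson correlation of per-person change scores;
* group x time ANOVA as Wald block tests on a random-intercept model
  (sum-to-zero group contrasts), reported with the observation-level
  denominator df convention (819 participants x 2 timepoints and a
  group*time model give denominator df 1632);
* demographic comparison tests computable from printed summaries: Pearson
  chi-square without continuity correction, the Freeman-Halton exact test
  for r x c tables (full enumeration of the margin-fixed table space, with a
  permutation Monte-Carlo fallback for large tables), Welch's t from means
  and SDs, one-way ANOVA and Tukey HSD from group summaries;
* a Fisher-z power/sample-size calculation for correlation effects.

Continuous regressors and outcomes are z-scored so coefficients are
standardised betas; dummy-coded categorical regressors are left on their
0/1 scale by default (``strict_zscore_dummies=True`` z-scores them too).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from math import lgamma
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TermResult",
    "ModelResult",
    "ContingencyTable",
    "zscore",
    "cross_sectional_regression",
    "mixed_change_model",
    "time_by_covariate_interaction",
    "change_correlation",
    "group_time_anova",
    "welch_t_from_summary",
    "chi_square_independence",
    "fisher_exact",
    "oneway_anova_from_summary",
    "tukey_hsd_from_summary",
    "power_sample_size_correlation",
]

EDUCATION_REFERENCE = "above_undergraduate"
GENDER_REFERENCE = "Female"


@dataclass(frozen=True)
class TermResult:
    term: str
    estimate: float | None = None
    se: float | None = None
    stat: float | None = None
    df1: float | None = None
    df2: float | None = None
    p: float | None = None


@dataclass
class ModelResult:
    """A fitted model summarised as one row per reported term."""

    model: str
    terms: list[TermResult]
    n: int

    def __getitem__(self, term: str) -> TermResult:
        for t in self.terms:
            if t.term == term:
                return t
        raise KeyError(f"no term {term!r} in model {self.model!r}; "
                       f"have {[t.term for t in self.terms]}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": self.model,
                "term": t.term,
                "estimate": t.estimate,
                "se": t.se,
                "stat": t.stat,
                "df1": t.df1,
                "df2": t.df2,
                "p": t.p,
                "n": self.n,
            }
            for t in self.terms
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or min(c.shape) < 1 or max(c.shape) < 2:
            raise ValueError("contingency table must be at least 2 in one dimension")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")


def zscore(values: Iterable[float]) -> np.ndarray:
    """Standardise to mean 0, SD 1 (ddof=1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance vector")
    return (x - x.mean()) / sd


def _design_columns(
    data: pd.DataFrame,
    predictors: Sequence[str],
    covariates: Sequence[str],
    strict_zscore_dummies: bool,
) -> pd.DataFrame:
    """z-scored numeric columns plus dummy-coded categoricals."""
    X = pd.DataFrame(index=data.index)
    for col in list(predictors) + list(covariates):
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            X[col] = zscore(s)
        elif pd.api.types.is_numeric_dtype(s):
            X[col] = s.astype(float)
            if strict_zscore_dummies:
                X[col] = zscore(X[col])
        else:
            levels = list(pd.unique(s))
            ref = None
            for candidate in (EDUCATION_REFERENCE, GENDER_REFERENCE):
                if candidate in levels:
                    ref = candidate
                    break
            if ref is None:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                dummy = (s == lev).astype(float)
                if strict_zscore_dummies and dummy.nunique() > 1:
                    dummy = pd.Series(zscore(dummy), index=s.index)
                X[f"{col}[{lev}]"] = dummy
    return X


def cross_sectional_regression(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = (),
    strict_zscore_dummies: bool = False,
    name: str | None = None,
) -> ModelResult:
    """OLS of a z-scored outcome on z-scored predictors plus covariates."""
    data = data.dropna(subset=[outcome, *predictors, *covariates])
    y = zscore(data[outcome])
    X = _design_columns(data, predictors, covariates, strict_zscore_dummies)
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if not corr.empty else ("?", "?")
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"most collinear pair: {worst}"
        )
    fit = sm.OLS(y, Xc).fit()
    terms = [
        TermResult(
            term=t,
            estimate=float(fit.params[t]),
            se=float(fit.bse[t]),
            stat=float(fit.tvalues[t]),
            df2=float(fit.df_resid),
            p=float(fit.pvalues[t]),
        )
        for t in X.columns
    ]
    return ModelResult(model=name or f"ols:{outcome}", terms=terms, n=len(data))


def _long_zscore(data: pd.DataFrame, outcome: str) -> pd.DataFrame:
    d = data.copy()
    d["_y"] = zscore(d[outcome])
    return d


def _require_two_timepoints(data: pd.DataFrame, id_col: str, time_col: str) -> pd.DataFrame:
    counts = data.groupby(id_col)[time_col].nunique()
    keep = counts[counts == 2].index
    dropped = len(counts) - len(keep)
    if dropped:
        import warnings

        warnings.warn(
            f"dropping {dropped} participant(s) without both timepoints "
            "(completer design)",
            stacklevel=3,
        )
    return data[data[id_col].isin(keep)]


def mixed_change_model(
    data: pd.DataFrame,
    outcome: str,
    id_col: str = "participant_id",
    time_col: str = "time",
    name: str | None = None,
) -> ModelResult:
    """Random-intercept model of a z-scored outcome on time (0/1), ML fit.

    The fixed effect of time is the standardised within-person change; for
    exactly two timepoints it coincides with the paired-difference estimate.
    """
    data = _require_two_timepoints(data.dropna(subset=[outcome]), id_col, time_col)
    d = _long_zscore(data, outcome)
    model = sm.MixedLM(
        d["_y"], sm.add_constant(d[[time_col]].astype(float)), groups=d[id_col]
    )
    fit = model.fit(reml=False)
    t = time_col
    terms = [
        TermResult(
            term="time",
            estimate=float(fit.params[t]),
            se=float(fit.bse[t]),
            stat=float(fit.params[t] / fit.bse[t]),
            p=float(fit.pvalues[t]),
        )
    ]
    return ModelResult(model=name or f"mixed:{outcome}~time", terms=terms,
                       n=int(d[id_col].nunique()))


def time_by_covariate_interaction(
    data: pd.DataFrame,
    outcome: str,
    covariate: str,
    extra_covariates: Sequence[str] = (),
    id_col: str = "participant_id",
    time_col: str = "time",
    name: str | None = None,
) -> ModelResult:
    """Random-intercept model: outcome ~ time * covariate (+ extras * time).

    The covariate is between-person (one value per participant, e.g. an
    anxious-depression change score); a covariate that varies within person
    violates the contract.  Numeric covariates are z-scored; categorical
    covariates are dummy-coded against their first level and one interaction
    term is reported per non-reference level.
    """
    cols = [outcome, covariate, *extra_covariates]
    data = _require_two_timepoints(data.dropna(subset=cols), id_col, time_col)
    for cov in (covariate, *extra_covariates):
        within = data.groupby(id_col)[cov].nunique()
        if (within > 1).any():
            bad = within[within > 1].index[:3].tolist()
            raise ValueError(
                f"covariate {cov!r} varies within person (e.g. {bad}); "
                "it must be a single value per participant"
            )
    d = _long_zscore(data, outcome)
    d["_t"] = d[time_col].astype(float)

    X = pd.DataFrame(index=d.index)
    X["time"] = d["_t"]
    inter_terms = []

    def add_cov(cov: str, with_interaction: bool) -> None:
        s = d[cov]
        if pd.api.types.is_numeric_dtype(s):
            base = zscore(s) if s.nunique() > 2 else s.astype(float).to_numpy()
            X[cov] = base
            if with_interaction:
                X[f"time:{cov}"] = X["time"] * base
                inter_terms.append(f"time:{cov}")
        else:
            levels = list(pd.unique(s))
            for lev in levels[1:]:
                dummy = (s == lev).astype(float).to_numpy()
                X[f"{cov}[{lev}]"] = dummy
                if with_interaction:
                    X[f"time:{cov}[{lev}]"] = X["time"] * dummy
                    inter_terms.append(f"time:{cov}[{lev}]")

    add_cov(covariate, with_interaction=True)
    for cov in extra_covariates:
        add_cov(cov, with_interaction=True)

    fit = sm.MixedLM(d["_y"], sm.add_constant(X), groups=d[id_col]).fit(reml=False)
    terms = []
    for t in X.columns:
        terms.append(
            TermResult(
                term=t,
                estimate=float(fit.params[t]),
                se=float(fit.bse[t]),
                stat=float(fit.params[t] / fit.bse[t]),
                p=float(fit.pvalues[t]),
            )
        )
    return ModelResult(
        model=name or f"mixed:{outcome}~time*{covariate}",
        terms=terms,
        n=int(d[id_col].nunique()),
    )


def change_correlation(x_change: Iterable[float], y_change: Iterable[float]):
    """Pearson r between two per-person change scores: (r, df, two-tailed p)."""
    x = np.asarray(list(x_change), float)
    y = np.asarray(list(y_change), float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need matched change vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("change correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), int(x.size - 2), float(p)


def group_time_anova(
    data: pd.DataFrame,
    outcome: str,
    group_col: str = "arm",
    time_col: str = "time",
    covariate: str | None = None,
    id_col: str = "participant_id",
    name: str | None = None,
) -> ModelResult:
    """Group x time (x covariate) ANOVA on the repeated-measures data.

    Effects are Wald block tests (sum-to-zero group contrasts) on a
    random-intercept mixed model, so within-person terms are tested against
    within-person variability; each F is reported with the observation-level
    denominator df convention (total observations minus fixed parameters,
    e.g. 1632 for 819 participants x 2 timepoints in the group*time model).
    """
    cols = [outcome, group_col, time_col] + ([covariate] if covariate else [])
    d = data.dropna(subset=cols).copy()
    if d[group_col].nunique() < 2:
        raise ValueError("need at least two groups")
    for g, sub in d.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
    labels = {
        "C(_grp, Sum)": "group",
        "_time": "time",
        "C(_grp, Sum):_time": "group:time",
    }
    if covariate is not None:
        labels.update(
            {
                "_cov": covariate,
                "C(_grp, Sum):_cov": f"group:{covariate}",
                "_time:_cov": f"time:{covariate}",
                "C(_grp, Sum):_time:_cov": f"group:time:{covariate}",
            }
        )
    if d[outcome].std(ddof=1) == 0:
        # a flat outcome carries no effects at all
        terms = [TermResult(term=t, stat=0.0, p=1.0) for t in labels.values()]
        return ModelResult(model=name or f"anova:{outcome}", terms=terms, n=len(d))
    d["_y"] = zscore(d[outcome])
    d["_grp"] = d[group_col].astype(str)
    d["_time"] = d[time_col].astype(float)
    d["_pid"] = d[id_col]
    rhs = "C(_grp, Sum) * _time"
    if covariate is not None:
        d["_cov"] = zscore(d[covariate])
        rhs = "C(_grp, Sum) * _time * _cov"
    fit = smf.mixedlm(f"_y ~ {rhs}", data=d, groups=d["_pid"]).fit(reml=False)
    wald = fit.wald_test_terms(scalar=True).table
    df2 = float(len(d) - len(fit.fe_params))
    terms = []
    for raw, pretty in labels.items():
        q = float(wald.loc[raw, "df_constraint"])
        F = float(wald.loc[raw, "statistic"]) / q
        terms.append(
            TermResult(
                term=pretty,
                stat=F,
                df1=q,
                df2=df2,
                p=float(sps.f.sf(F, q, df2)),
            )
        )
    return ModelResult(model=name or f"anova:{outcome}", terms=terms, n=len(d))


def welch_t_from_summary(m1, s1, n1, m2, s2, n2):
    """Welch's t from group summaries: (t, df, two-tailed p)."""
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_independence(table: ContingencyTable | np.ndarray):
    """Pearson chi-square without continuity correction: (chi2, df, p)."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("table has a zero margin; expected counts undefined")
    chi2, p, df, _ = sps.chi2_contingency(c, correction=False)
    return float(chi2), int(df), float(p)


def _log_table_prob(counts: np.ndarray, row_marg, col_marg, log_n_fact) -> float:
    lp = sum(lgamma(r + 1) for r in row_marg) + sum(lgamma(c + 1) for c in col_marg)
    lp -= log_n_fact
    lp -= sum(lgamma(int(x) + 1) for x in counts.flat)
    return lp


def _enumerate_tables(row_marg, col_marg):
    """Yield all non-negative integer tables with the given margins."""
    n_rows = len(row_marg)

    def rec(row_idx, remaining_cols, rows):
        if row_idx == n_rows - 1:
            last = np.asarray(remaining_cols)
            if np.all(last >= 0) and last.sum() == row_marg[-1]:
                yield rows + [last]
            return
        target = row_marg[row_idx]

        def fill(col_idx, left, current):
            if col_idx == len(remaining_cols) - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield current + [left]
                return
            hi = min(left, remaining_cols[col_idx])
            for v in range(hi + 1):
                yield from fill(col_idx + 1, left - v, current + [v])

        for row in fill(0, target, []):
            row_arr = np.asarray(row)
            yield from rec(
                row_idx + 1, [c - v for c, v in zip(remaining_cols, row)], rows + [row_arr]
            )

    yield from rec(0, list(col_marg), [])


def _table_space_size(row_marg, col_marg) -> float:
    # upper bound: product over free cells of (min margin + 1)
    size = 1.0
    for r in row_marg[:-1]:
        for c in col_marg[:-1]:
            size *= min(r, c) + 1
    return size


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    max_tables: float = 2e6,
    method: str = "enumerate",
    n_monte_carlo: int = 100_000,
    seed: int = 0,
):
    """Freeman-Halton exact test for an r x c table; returns the two-sided p.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one (within a
    1e-12 tolerance), under the multivariate hypergeometric null.  For
    tables whose margin-fixed space exceeds ``max_tables`` an error suggests
    ``method="monte-carlo"``, which estimates the same p by permutation.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    c = table.counts
    row_marg = c.sum(axis=1)
    col_marg = c.sum(axis=0)
    if min(c.shape) == 1:
        return 1.0  # margins determine the table completely
    n = int(c.sum())
    log_n_fact = lgamma(n + 1)
    lp_obs = _log_table_prob(c, row_marg, col_marg, log_n_fact)
    if method == "auto":
        method = (
            "enumerate"
            if _table_space_size(row_marg, col_marg) <= max_tables
            else "monte-carlo"
        )
    if method == "enumerate":
        if _table_space_size(row_marg, col_marg) > max_tables:
            raise ValueError(
                "margin-fixed table space too large for enumeration; "
                'call fisher_exact(..., method="monte-carlo")'
            )
        total = 0.0
        for t in _enumerate_tables(row_marg, col_marg):
            lp = _log_table_prob(np.asarray(t), row_marg, col_marg, log_n_fact)
            if lp <= lp_obs + 1e-12:
                total += math.exp(lp)
        return float(min(total, 1.0))
    if method == "monte-carlo":
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(len(row_marg)), row_marg)
        cols = np.repeat(np.arange(len(col_marg)), col_marg)
        hits = 0
        for _ in range(n_monte_carlo):
            perm = rng.permutation(cols)
            t = np.zeros_like(c)
            np.add.at(t, (rows, perm), 1)
            if _log_table_prob(t, row_marg, col_marg, log_n_fact) <= lp_obs + 1e-12:
                hits += 1
        return float((hits + 1) / (n_monte_carlo + 1))
    raise ValueError(f"unknown method {method!r}")


def _summaries_ok(groups):
    groups = [(float(m), float(s), int(n)) for m, s, n in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for m, s, n in groups:
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if s < 0:
            raise ValueError("SDs must be non-negative")
    return groups


def oneway_anova_from_summary(groups: Sequence[tuple[float, float, int]]):
    """One-way ANOVA from (mean, SD, n) triples: (F, df1, df2, p)."""
    groups = _summaries_ok(groups)
    k = len(groups)
    ns = np.array([g[2] for g in groups])
    ms = np.array([g[0] for g in groups])
    ss = np.array([g[1] for g in groups])
    N = ns.sum()
    grand = (ns * ms).sum() / N
    ss_between = float((ns * (ms - grand) ** 2).sum())
    ss_within = float(((ns - 1) * ss**2).sum())
    df1, df2 = k - 1, int(N - k)
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), int(df1), int(df2), p


def tukey_hsd_from_summary(groups: Sequence[tuple[float, float, int]], labels=None):
    """Tukey-Kramer adjusted pairwise p-values from (mean, SD, n) triples.

    Returns a DataFrame with one row per pair: group_1, group_2,
    mean_difference, q, p_adjusted (studentized-range distribution).
    """
    groups = _summaries_ok(groups)
    k = len(groups)
    labels = list(labels) if labels is not None else [f"g{i+1}" for i in range(k)]
    ns = np.array([g[2] for g in groups])
    ss = np.array([g[1] for g in groups])
    N = int(ns.sum())
    df = N - k
    msw = float(((ns - 1) * ss**2).sum()) / df
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = groups[i][0] - groups[j][0]
        se = math.sqrt(msw / 2 * (1 / ns[i] + 1 / ns[j]))
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df))
        rows.append(
            {
                "group_1": labels[i],
                "group_2": labels[j],
                "mean_difference": diff,
                "q": q,
                "p_adjusted": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def power_sample_size_correlation(
    effect_r: float, power: float = 0.80, alpha: float = 0.05
) -> int:
    """Smallest n detecting a correlation with the given power (Fisher z).

    Two-tailed test of r != 0; power computed from the normal approximation
    to the Fisher-z transform with SE 1/sqrt(n - 3).
    """
    if not 0 < abs(effect_r) < 1:
        raise ValueError("effect_r must be in (0, 1) in magnitude")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    z_eff = abs(math.atanh(effect_r))
    z_a = sps.norm.ppf(1 - alpha / 2)

    def achieved(n: int) -> float:
        se = 1 / math.sqrt(n - 3)
        return float(sps.norm.sf(z_a - z_eff / se) + sps.norm.cdf(-z_a - z_eff / se))

    # closed-form start, then local search for the exact threshold
    n = max(4, math.ceil(((z_a + sps.norm.ppf(power)) / z_eff) ** 2 + 3) - 5)
    while achieved(n) < power:
        n += 1
    while n > 4 and achieved(n - 1) >= power:
        n -= 1
    return n
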