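"""Association and survival statistics.

Fisher's exact test (2x2 via the hypergeometric point-probability rule;
r x c via full enumeration of the conditional distribution for 2 x c tables,
Monte-Carlo otherwise), Kaplan-Meier estimation, k-group log-rank, pairwise
log-rank with Benjamini-Hochberg adjustment, and Cox proportional-hazards
regression with Efron tie handling.  KM / log-rank / Cox are backed by
lifelines; BH by statsmodels.

Survival analyses are truncated at a 120-month horizon by default so that
curves and tests describe 10-year outcomes; pass ``horizon_months=None`` to
disable.
"""

from __future__ import annotations

import itertools
import logging
from math import lgamma, log

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from statsmodels.stats.multitest import multipletests

from .types import MISSING, ContingencyTable, CoxLevelResult, KmCurve, SurvivalRecord, TestResult

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_MONTHS = 120.0
# relative tolerance when comparing point probabilities to the observed one
# (the convention of R's fisher.test)
_REL_EPS = 1e-7

EXACT_FISHER_MAX_N = 1000
MC_FISHER_DRAWS = 1_000_000


def _as_counts(table: ContingencyTable | np.ndarray) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = np.asarray(table, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined: table has a zero margin")
    return counts


def _log_point_prob_terms(counts: np.ndarray) -> tuple[float, float]:
    """(log constant from margins, log point probability of the table)."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    log_const = (
        sum(lgamma(r + 1) for r in rows)
        + sum(lgamma(c + 1) for c in cols)
        - lgamma(n + 1)
    )
    logp = log_const - sum(lgamma(x + 1) for x in counts.ravel())
    return log_const, logp


def _fisher_2xc_exact(counts: np.ndarray) -> float:
    """Two-sided exact p for a 2 x c table by full enumeration.

    Conditional on the margins, every table is determined by its first row
    (x_1..x_c); the p-value sums the probabilities of all tables whose point
    probability does not exceed the observed one.
    """
    r1 = int(counts[0].sum())
    cols = counts.sum(axis=0).astype(int)
    c = len(cols)
    log_const, logp_obs = _log_point_prob_terms(counts)
    threshold = logp_obs + log(1 + _REL_EPS)

    # per-column lookup: -lgamma(x+1) - lgamma(col-x+1) for x = 0..col
    col_terms = [
        np.array([-lgamma(x + 1) - lgamma(cols[j] - x + 1) for x in range(cols[j] + 1)])
        for j in range(c)
    ]
    # suffix bounds for feasibility pruning
    suffix_cap = np.concatenate([np.cumsum(cols[::-1])[::-1], [0]])

    total = 0.0

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == c - 2:
            lo = max(0, remaining - cols[j + 1])
            hi = min(cols[j], remaining)
            if lo > hi:
                return
            x = np.arange(lo, hi + 1)
            logp = (
                log_const
                + acc
                + col_terms[j][x]
                + col_terms[j + 1][remaining - x]
            )
            total += float(np.exp(logp[logp <= threshold]).sum())
            return
        lo = max(0, remaining - int(suffix_cap[j + 1]))
        hi = min(cols[j], remaining)
        for x in range(lo, hi + 1):
            recurse(j + 1, remaining - x, acc + col_terms[j][x])

    recurse(0, r1, 0.0)
    return min(total, 1.0)


def _fisher_rxc_montecarlo(counts: np.ndarray, n_draws: int, seed: int) -> float:
    """Monte-Carlo two-sided p: fraction of margin-preserving random tables
    at most as probable as the observed one (Patefield sampler)."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    _, logp_obs = _log_point_prob_terms(counts)
    threshold = logp_obs + log(1 + _REL_EPS)
    log_const, _ = _log_point_prob_terms(counts)
    rng = np.random.default_rng(seed)
    sampler = scipy.stats.random_table(rows, cols)
    hits = 1  # include the observed table (guarantees p > 0)
    chunk = 100_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        draws = sampler.rvs(m, method="patefield", random_state=rng)
        cell_term = scipy.special.gammaln(draws.reshape(m, -1) + 1.0).sum(axis=1)
        hits += int((log_const - cell_term <= threshold).sum())
        done += m
    return min(1.0, hits / (n_draws + 1))


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    exact_max_n: int = EXACT_FISHER_MAX_N,
    mc_draws: int = MC_FISHER_DRAWS,
    seed: int = 0,
) -> TestResult:
    """Two-sided Fisher's exact test for an r x c table.

    2x2 tables use scipy's exact test (two-sided p = sum of hypergeometric
    point probabilities at most as large as the observed table's) and report
    the sample odds ratio as the statistic.  Larger tables with one dimension
    of size 2 and total n <= ``exact_max_n`` are enumerated exactly;
    otherwise a seeded Monte-Carlo estimate over margin-preserving tables is
    returned, with the method recorded in the result.
    """
    counts = _as_counts(table)
    r, c = counts.shape
    if (r, c) == (2, 2):
        res = scipy.stats.fisher_exact(counts, alternative="two-sided")
        return TestResult(float(res.statistic), float(res.pvalue), "fisher_exact_2x2")
    work = counts if r == 2 else counts.T
    if work.shape[0] == 2 and counts.sum() <= exact_max_n:
        p = _fisher_2xc_exact(work)
        return TestResult(float("nan"), p, "fisher_exact_enumeration")
    p = _fisher_rxc_montecarlo(counts, mc_draws, seed)
    return TestResult(float("nan"), p, f"fisher_montecarlo_{mc_draws}")


def apply_horizon(
    records: list[SurvivalRecord], horizon_months: float | None
) -> list[SurvivalRecord]:
    """Administratively censor follow-up at the horizon (no-op if None/0)."""
    if not horizon_months:
        return list(records)
    out = []
    for rec in records:
        if rec.time > horizon_months:
            out.append(
                SurvivalRecord(rec.sample_id, horizon_months, 0, dict(rec.covariates))
            )
        else:
            out.append(rec)
    return out


def _to_arrays(records: list[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_curve(
    records: list[SurvivalRecord],
    horizon_months: float | None = DEFAULT_HORIZON_MONTHS,
) -> KmCurve:
    """Kaplan-Meier product-limit estimate (events-first at tied times)."""
    if not records:
        raise ValueError("no survival records")
    records = apply_horizon(records, horizon_months)
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    grid = event_rows.index.to_numpy(dtype=float)
    return KmCurve(
        times=grid,
        survival=surv.loc[event_rows.index].to_numpy(dtype=float),
        n_at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        n_events=event_rows["observed"].to_numpy(dtype=int),
    )


def median_survival(records: list[SurvivalRecord],
                    horizon_months: float | None = None) -> float:
    """Median survival time (months); inf if the curve stays above 0.5."""
    records = apply_horizon(records, horizon_months)
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter().fit(times, events)
    return float(kmf.median_survival_time_)


def logrank(
    records: list[SurvivalRecord],
    group_labels: dict[str, str] | pd.Series,
    horizon_months: float | None = DEFAULT_HORIZON_MONTHS,
) -> TestResult:
    """k-group log-rank test (chi-square with k-1 df)."""
    labels = dict(group_labels)
    records = [r for r in records if r.sample_id in labels]
    groups = sorted({labels[r.sample_id] for r in records})
    if len(groups) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    records = apply_horizon(records, horizon_months)
    times, events = _to_arrays(records)
    g = np.array([labels[r.sample_id] for r in records])
    res = multivariate_logrank_test(times, g, events)
    return TestResult(
        float(res.test_statistic), float(res.p_value), "logrank", df=len(groups) - 1
    )


def pairwise_logrank_bh(
    records: list[SurvivalRecord],
    group_labels: dict[str, str] | pd.Series,
    horizon_months: float | None = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """All pairwise log-rank p-values, BH-adjusted over the set of pairs.

    Returns a symmetric DataFrame with NaN on the diagonal; the adjustment
    family is the pairs of this one analysis only (6 values for 4 groups).
    """
    labels = dict(group_labels)
    groups = sorted({labels[s] for s in labels})
    if len(groups) < 3:
        raise ValueError("pairwise comparison needs at least 3 groups")
    pairs = list(itertools.combinations(groups, 2))
    raw = []
    for a, b in pairs:
        sub_labels = {s: l for s, l in labels.items() if l in (a, b)}
        sub_records = [r for r in records if r.sample_id in sub_labels]
        raw.append(logrank(sub_records, sub_labels, horizon_months).p_value)
    adj = bh_adjust(raw)
    mat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = p
        mat.loc[b, a] = p
    return mat


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def cox_fit(
    records: list[SurvivalRecord],
    factors: list[str],
    reference_levels: dict[str, str] | None = None,
    horizon_months: float | None = None,
) -> list[CoxLevelResult]:
    """Cox proportional-hazards fit on categorical factors (Efron ties).

    One factor gives the univariate model; several give the joint
    (multivariate) model.  Records missing any used factor are dropped
    (complete-case; count logged).  Wald 95% CIs: exp(beta +/- 1.96 SE).
    """
    reference_levels = reference_levels or {}
    records = apply_horizon(records, horizon_months)
    rows, kept = [], []
    for rec in records:
        vals = {f: rec.covariates.get(f, MISSING) for f in factors}
        if MISSING in vals.values():
            continue
        rows.append(vals)
        kept.append(rec)
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("cox_fit: dropped %d records with missing factor values", dropped)
    if not kept:
        raise ValueError("no complete-case records")
    if not any(r.event for r in kept):
        raise ValueError("no events among complete-case records")

    df = pd.DataFrame(rows, index=[r.sample_id for r in kept])
    design = pd.DataFrame(index=df.index)
    level_map: list[tuple[str, str, str]] = []  # (column, factor, level)
    for f in factors:
        levels = sorted(df[f].unique())
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
        ref = reference_levels.get(f, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not observed for {f!r}")
        for lev in levels:
            if lev == ref:
                continue
            col = f"{f}[{lev}]"
            design[col] = (df[f] == lev).astype(float)
            level_map.append((col, f, lev))
    design["time"] = [r.time for r in kept]
    design["event"] = [r.event for r in kept]

    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(f"Cox model did not converge: {exc}") from exc

    out = []
    for col, f, lev in level_map:
        beta = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        ref = reference_levels.get(f, sorted(df[f].unique())[0])
        out.append(
            CoxLevelResult(
                factor=f,
                level=lev,
                reference_level=ref,
                hazard_ratio=float(np.exp(beta)),
                ci95_low=float(np.exp(beta - 1.96 * se)),
                ci95_high=float(np.exp(beta + 1.96 * se)),
                p_value=float(cph.summary.loc[col, "p"]),
            )
        )
    return out
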