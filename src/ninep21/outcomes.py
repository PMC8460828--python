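"""Exact contingency statistics for immunotherapy response and the composite
response score.

Response-rate claims are all backed by contingency tables of responder
(CR/PR, or durable clinical benefit) counts per stratum.  The workhorse is
the two-sided Fisher exact test with the sum-of-small-probabilities rule:
the p-value sums the hypergeometric probabilities of every table with the
observed margins whose point probability is no larger than the observed
one (relative tolerance 1e-7).  For r x c tables the Freeman-Halton
generalization enumerates all margin-preserving tables, with a seeded
Monte-Carlo fallback when enumeration would be too large.

The composite response score combines three pre-treatment biomarkers with
integer weights proportional to their logistic-regression coefficients:
2 points for TMB above the cohort median, 1 point for the hi_hi expression
surrogate of intact 9p21, and 1 point for high immune-cell PD-L1 (IC2+,
>= 5% staining).  Tiers: low (0), intermediate (1-2), high (3-4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .errors import AnalysisError


@dataclass
class TestResult:
    method: str  # "fisher_2x2" | "fisher_rxc" | "lr_chisq"
    statistic: float  # NA (nan) for exact tests
    p: float


def derive_dcb(response: str, pfs_time: float | None = None):
    """Durable clinical benefit: CR/PR, or SD lasting more than 6 months.

    SD with missing PFS time is indeterminate (NA).  PD/NE are False.
    """
    if pd.isna(response):
        return pd.NA
    if response in ("CR", "PR"):
        return True
    if response == "SD":
        if pfs_time is None or pd.isna(pfs_time):
            return pd.NA
        return bool(pfs_time > 6.0)
    return False


def build_contingency(labels_a: pd.Series, labels_b: pd.Series) -> pd.DataFrame:
    """Cross-tabulate two per-sample label series (rows = a, columns = b).

    Samples missing from either series, or NA in either, are dropped with a
    reported count.
    """
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise AnalysisError("label series share no sample ids")
    a = labels_a.loc[common]
    b = labels_b.loc[common]
    ok = a.notna() & b.notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"{dropped} sample(s) with NA label dropped from contingency")
    table = pd.crosstab(a[ok], b[ok])
    return table


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric (fixed-margins multinomial) probability of a table."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def fisher_exact_2x2(
    table: pd.DataFrame | np.ndarray, alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test for a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all margin-preserving
    tables whose point probability is <= observed x (1 + 1e-7).  A zero row
    or column margin makes every table equally (un)informative: p = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise AnalysisError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any():
        raise AnalysisError("negative count in contingency table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1")
        return TestResult("fisher_2x2", float("nan"), 1.0)
    p = float(stats.fisher_exact(t, alternative=alternative)[1])
    return TestResult("fisher_2x2", float("nan"), min(p, 1.0))


def _enumerate_rxc(row_sums, col_sums, lp_obs, log_tol):
    """Sum probabilities of margin-preserving tables with lp <= lp_obs + tol.

    Depth-first over rows; each partial row assignment updates remaining
    column sums.  Returns (p_sum, n_tables).
    """
    r = len(row_sums)
    lg = gammaln(np.arange(max(row_sums) + max(col_sums) + 2) + 1.0)
    const = (
        sum(lg[x] for x in row_sums)
        + sum(lg[x] for x in col_sums)
        - gammaln(sum(row_sums) + 1.0)
    )

    total = 0.0
    count = 0

    def fill_row(i, rem_cols, acc):
        nonlocal total, count
        if i == r - 1:
            # last row is forced
            lp = const + acc - sum(lg[x] for x in rem_cols)
            count += 1
            if lp <= lp_obs + log_tol:
                total += np.exp(lp)
            return
        # enumerate compositions of row_sums[i] into len(rem_cols) cells
        def fill_cell(j, left, rem, acc_row):
            if j == len(rem_cols) - 1:
                if left <= rem[j]:
                    rem2 = list(rem)
                    rem2[j] -= left
                    fill_row(i + 1, rem2, acc + acc_row - lg[left])
                return
            hi = min(left, rem[j])
            for x in range(hi + 1):
                rem2 = list(rem)
                rem2[j] -= x
                fill_cell(j + 1, left - x, rem2, acc_row - lg[x])

        fill_cell(0, row_sums[i], rem_cols, 0.0)

    fill_row(0, list(col_sums), 0.0)
    return total, count


def _count_tables(row_sums, col_sums, cap):
    """Loose upper bound on the number of margin-preserving tables."""
    est = 1.0
    for rs in row_sums[:-1]:
        for cs in col_sums[:-1]:
            est *= min(rs, cs) + 1
            if est > cap:
                return est
    return est


def fisher_exact_rxc(
    table: pd.DataFrame | np.ndarray,
    max_tables: float = 1e7,
    monte_carlo: bool = False,
    n_draws: int = 200_000,
    seed: int | None = None,
) -> TestResult:
    """Freeman-Halton exact test for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (relative tolerance 1e-7); for a 2x2 table this equals
    :func:`fisher_exact_2x2`.  If the enumeration bound exceeds
    ``max_tables``, an error suggests the seeded Monte-Carlo mode, which
    estimates the same tail by sampling margin-preserving tables (Patefield
    sampling via the hypergeometric row-by-row construction).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or min(t.shape) < 2:
        raise AnalysisError(f"expected an r x c table with r,c >= 2, got {t.shape}")
    if (t < 0).any():
        raise AnalysisError("negative count in contingency table")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn("zero margin in r x c table; p = 1")
        return TestResult("fisher_rxc", float("nan"), 1.0)
    lp_obs = _log_table_prob(t)
    log_tol = np.log1p(1e-7)
    if monte_carlo:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_draws):
            draw = _sample_table(row_sums, col_sums, rng)
            if _log_table_prob(draw) <= lp_obs + log_tol:
                hits += 1
        # add-one estimate keeps p > 0
        return TestResult("fisher_rxc", float("nan"), (hits + 1) / (n_draws + 1))
    if _count_tables(list(row_sums), list(col_sums), max_tables) > max_tables:
        raise AnalysisError(
            "table space exceeds max_tables; use monte_carlo=True with a seed"
        )
    p, _ = _enumerate_rxc(list(row_sums), list(col_sums), lp_obs, log_tol)
    return TestResult("fisher_rxc", float("nan"), min(p, 1.0))


def _sample_table(row_sums, col_sums, rng) -> np.ndarray:
    """Draw a table uniformly from the fixed-margins hypergeometric model."""
    r, c = len(row_sums), len(col_sums)
    out = np.zeros((r, c), dtype=np.int64)
    rem_cols = np.array(col_sums, dtype=np.int64)
    rem_total = int(np.sum(row_sums))
    for i in range(r):
        left = int(row_sums[i])
        rem_row_total = rem_total
        for j in range(c - 1):
            # multivariate hypergeometric, one margin at a time
            good = int(rem_cols[j])
            bad = int(rem_row_total - good)
            x = rng.hypergeometric(good, bad, left) if left > 0 else 0
            out[i, j] = x
            left -= x
            rem_row_total -= good
        out[i, c - 1] = left
        rem_cols -= out[i]
        rem_total -= int(row_sums[i])
    return out


def lr_chisq_test(table: pd.DataFrame | np.ndarray) -> TestResult:
    """Likelihood-ratio chi-squared (G) test for an r x c table.

    G^2 = 2 sum O ln(O/E) with 0 ln 0 = 0; p from chi^2 with (r-1)(c-1) df.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise AnalysisError(f"expected an r x c table, got {t.shape}")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise AnalysisError("zero margin in table for likelihood-ratio test")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    g2 = float(2.0 * terms.sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return TestResult("lr_chisq", g2, float(stats.chi2.sf(g2, df)))


def response_rates_compare(
    outcomes: pd.Series, strata: pd.Series, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Responder rates in two strata plus the Fisher 2x2 comparison.

    ``outcomes`` is a boolean responder flag per sample; NA outcomes are
    dropped with a report.  Returns one row per stratum with columns
    stratum, responders, total, rate, rate_ratio, p (rate_ratio is
    larger rate / smaller rate, repeated on both rows).
    """
    common = outcomes.index.intersection(strata.index)
    o = outcomes.loc[common]
    s = strata.loc[common]
    ok = o.notna() & s.notna()
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"{dropped} sample(s) with NA outcome or stratum dropped")
    o, s = o[ok], s[ok]
    rows = []
    counts = []
    for stratum in contrast:
        mask = s == stratum
        if not mask.any():
            raise AnalysisError(f"stratum {stratum!r} is empty")
        resp = int(o[mask].sum())
        total = int(mask.sum())
        counts.append((resp, total - resp))
        rows.append({"stratum": stratum, "responders": resp, "total": total,
                     "rate": resp / total})
    rates = [r["rate"] for r in rows]
    if min(rates) == 0:
        ratio = float("inf") if max(rates) > 0 else 1.0
    else:
        ratio = max(rates) / min(rates)
    test = fisher_exact_2x2(np.array(counts))
    out = pd.DataFrame(rows)
    out["rate_ratio"] = ratio
    out["p"] = test.p
    return out


def compute_response_score(
    tmb: float,
    tmb_median: float,
    surrogate: str,
    pdl1_ic: str,
) -> dict:
    """Composite response score for one sample (0-4 points).

    2 points for TMB strictly above the cohort median (ties at the median are
    low), 1 point for the hi_hi expression surrogate, 1 point for immune-cell
    PD-L1 IC2+ (>= 5%).  Any NA component excludes the sample (raises).
    Tier: low (0), intermediate (1-2), high (3-4).
    """
    if pd.isna(tmb) or pd.isna(surrogate) or pd.isna(pdl1_ic):
        raise AnalysisError("NA component; sample excluded from response score")
    tmb_high = bool(tmb > tmb_median)
    hi_hi = surrogate == "hi_hi"
    pdl1_high = pdl1_ic == "IC2+"
    points = 2 * tmb_high + 1 * hi_hi + 1 * pdl1_high
    tier = "low" if points == 0 else ("intermediate" if points <= 2 else "high")
    return {
        "points": int(points),
        "tier": tier,
        "tmb_high": tmb_high,
        "surrogate_hi_hi": hi_hi,
        "pdl1_ic_high": pdl1_high,
    }


def score_cohort(clinical: pd.DataFrame, surrogate: pd.Series) -> pd.DataFrame:
    """Response score for every scoreable sample in a cohort.

    Needs clinical columns ``tmb`` and ``pdl1_ic`` plus the surrogate label
    series.  The TMB median is computed over the samples with non-NA TMB.
    Samples missing any component are excluded with a reported count.
    """
    common = clinical.index.intersection(surrogate.index)
    tmb_median = clinical.loc[common, "tmb"].median(skipna=True)
    rows = {}
    excluded = 0
    for sid in common:
        try:
            rows[sid] = compute_response_score(
                clinical.at[sid, "tmb"], tmb_median,
                surrogate[sid], clinical.at[sid, "pdl1_ic"],
            )
        except AnalysisError:
            excluded += 1
    if excluded:
        warnings.warn(f"{excluded} sample(s) excluded from response score (NA component)")
    if not rows:
        raise AnalysisError("no sample has all three score components")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def fit_logistic(outcome: pd.Series, covariates: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of a binary outcome on factors.

    Returns per-factor coefficient, standard error, and Wald p, plus a
    ``converged`` flag on the frame attrs.  Perfect separation triggers an
    L2-penalized refit, flagged in ``attrs['penalized']``.
    """
    common = outcome.index.intersection(covariates.index)
    y = outcome.loc[common].astype(float)
    X = covariates.loc[common].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    y, X = y[keep], X[keep]
    if len(y) < 10:
        raise AnalysisError(f"logistic fit needs >=10 complete samples, got {len(y)}")
    if y.nunique() < 2:
        raise AnalysisError("outcome has a single class")
    Xc = sm.add_constant(X, has_constant="add")
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        fit = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
        converged = True
        penalized = True
    out = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    ).drop(index="const")
    out.attrs["converged"] = converged
    out.attrs["penalized"] = penalized
    return out


def derive_score_weights(coefficients: pd.Series) -> pd.Series:
    """Integer points per factor from logistic coefficients.

    points_i = round(|beta_i| / min_j |beta_j|), floored at 1.  All
    coefficients must be oriented toward response (same sign direction).
    """
    beta = coefficients.astype(float).abs()
    if len(beta) < 2:
        raise AnalysisError("need >=2 factors to derive weights")
    if (beta == 0).any():
        raise AnalysisError("zero coefficient; weights undefined")
    pts = np.maximum(1, np.round(beta / beta.min())).astype(int)
    return pd.Series(pts, index=coefficients.index, name="points")
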