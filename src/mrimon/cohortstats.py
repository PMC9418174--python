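"""Cohort-level statistics: normality gating, two-group tests, summaries.

The testing policy mirrors common practice in preclinical phenotyping
reports: each group is screened for normality with a Kolmogorov–Smirnov
test (Lilliefors-corrected by default, since mean and sd are estimated from
the data); if both groups pass, an unpaired two-tailed t test compares
them, otherwise a two-tailed Mann–Whitney test.  P values are annotated
with the conventional stars (*, p <= 0.05; **, p <= 0.01; ***, p <= 0.001)
and no multiple-testing correction is applied by default (an optional
Benjamini–Hochberg flag is provided).

The Mann–Whitney p value is computed by full enumeration of rank
assignments when both groups have at most eight observations (exact even
under ties, via midranks), and by the tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

NORMAL, NON_NORMAL = "normal", "non_normal"
EXACT_MW_MAX_N = 8


def stars_from_p(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def normality_gate(
    values, *, alpha: float = 0.05, lilliefors_correction: bool = True
) -> str:
    """KS-based normality screen against a normal with estimated mean/sd.

    Returns ``"normal"`` unless the test rejects at ``alpha``.  The
    Lilliefors correction accounts for the estimated parameters (the naive
    KS test with plugged-in estimates is anticonservative); the Lilliefors
    table needs n >= 4, so n = 3 falls back to the uncorrected test.
    Zero-variance samples are reported non-normal (a point mass).
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise ValueError("normality gate needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return NON_NORMAL
    if lilliefors_correction and x.size >= 4:
        _, p = lilliefors(x, dist="norm")
    else:
        _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return NON_NORMAL if p <= alpha else NORMAL


# ---------------------------------------------------------------------------
# exact Mann–Whitney


@lru_cache(maxsize=64)
def _exact_u_distribution_no_ties(n1: int, n2: int) -> tuple:
    """P(U = u) for tie-free samples, by enumeration of rank subsets."""
    ranks = tuple(range(1, n1 + n2 + 1))
    counts: dict[float, int] = {}
    base = n1 * (n1 + 1) / 2.0
    for subset in combinations(ranks, n1):
        u = sum(subset) - base
        counts[u] = counts.get(u, 0) + 1
    total = comb(n1 + n2, n1)
    return tuple(sorted((u, c / total) for u, c in counts.items()))


def _exact_u_distribution(pooled_ranks: np.ndarray, n1: int) -> tuple:
    """Null distribution of U for the observed (mid)ranks; exact under ties."""
    n = pooled_ranks.size
    if np.unique(pooled_ranks).size == n:
        return _exact_u_distribution_no_ties(n1, n - n1)
    counts: dict[float, int] = {}
    base = n1 * (n1 + 1) / 2.0
    for subset in combinations(range(n), n1):
        u = float(pooled_ranks[list(subset)].sum()) - base
        counts[u] = counts.get(u, 0) + 1
    total = comb(n, n1)
    return tuple(sorted((u, c / total) for u, c in counts.items()))


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-tailed Mann–Whitney test; returns (U statistic of group a, p).

    Exact enumeration when both n <= 8: two-sided p is
    min(1, 2·min(P(U <= u), P(U >= u))) over the permutation-null of the
    observed midranks.  Larger samples use the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 <= EXACT_MW_MAX_N and n2 <= EXACT_MW_MAX_N:
        dist = _exact_u_distribution(ranks, n1)
        p_le = sum(p for u, p in dist if u <= u1 + 1e-12)
        p_ge = sum(p for u, p in dist if u >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u1, p

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(sigma2)
    return u1, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# two-group comparison


@dataclass
class TestResult:
    measurement: str
    timepoint: float | None
    grouping: str
    test: str
    statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def compare_groups(
    a,
    b,
    *,
    ids_a=None,
    ids_b=None,
    alpha: float = 0.05,
    measurement: str = "",
    timepoint: float | None = None,
    grouping: str = "",
    lilliefors_correction: bool = True,
    force: str | None = None,
) -> TestResult:
    """Normality-gated unpaired two-group comparison.

    If both groups pass the normality gate, an unpaired two-tailed t test;
    otherwise (or when either group has zero variance, where t is
    undefined) the two-tailed Mann–Whitney test.  ``force`` overrides the
    gate with ``"t"`` or ``"mann_whitney"``.  Overlapping animal ids between
    the groups violate the unpaired design and raise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if ids_a is not None and ids_b is not None:
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise ValueError(f"groups share animal ids (unpaired design): {sorted(overlap)}")

    if force is not None:
        use_t = force == "t"
        if force not in ("t", "mann_whitney"):
            raise ValueError("force must be 't' or 'mann_whitney'")
    else:
        degenerate = a.std(ddof=1) == 0 or b.std(ddof=1) == 0
        use_t = (
            not degenerate
            and a.size >= 3 and b.size >= 3
            and normality_gate(a, alpha=alpha, lilliefors_correction=lilliefors_correction) == NORMAL
            and normality_gate(b, alpha=alpha, lilliefors_correction=lilliefors_correction) == NORMAL
        )

    if use_t:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        test = "t"
        stat = float(stat)
        p = float(p)
    else:
        stat, p = mann_whitney(a, b)
        test = "mann_whitney"
    return TestResult(
        measurement=measurement, timepoint=timepoint, grouping=grouping,
        test=test, statistic=stat, p_value=p, stars=stars_from_p(p),
        n_a=int(a.size), n_b=int(b.size),
    )


# ---------------------------------------------------------------------------
# summaries and longitudinal report


def group_summary(
    table: pd.DataFrame, measurement: str, timepoint: float
) -> pd.DataFrame:
    """Mean ± sd and n per sex x genotype cell, excluded records dropped.

    Exclusion reasons of dropped records are aggregated into the
    ``exclusions`` column so the report carries the audit trail.  Empty
    cells appear with n = 0.
    """
    if measurement not in set(table["measurement"]):
        raise ValueError(f"unknown measurement {measurement!r}")
    sub = table[(table["measurement"] == measurement) & (table["timepoint"] == timepoint)]
    rows = []
    for sex in ("f", "m"):
        for geno in ("mutant", "control"):
            cell = sub[(sub["sex"] == sex) & (sub["genotype"] == geno)]
            kept = cell[~cell["excluded"].astype(bool)]
            dropped = cell[cell["excluded"].astype(bool)]
            vals = kept["value"].to_numpy(float)
            rows.append(
                {
                    "measurement": measurement, "timepoint": timepoint,
                    "sex": sex, "genotype": geno, "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "exclusions": "; ".join(
                        f"{r.animal}: {r.exclusion_reason or 'excluded'}"
                        for r in dropped.itertuples()
                    ),
                }
            )
    return pd.DataFrame(rows)


def longitudinal_report(
    table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    mtc: str = "none",
    lilliefors_correction: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-measurement, per-timepoint summary and comparison tables.

    For every measurement and timepoint: genotype comparisons within each
    sex and sex comparisons within each genotype, wherever both sides have
    n >= 2 after exclusions.  Returns (summaries, tests) DataFrames; with
    ``mtc="bh"`` a Benjamini–Hochberg-adjusted p column and re-derived
    stars are added.
    """
    if mtc not in ("none", "bh"):
        raise ValueError("mtc must be 'none' or 'bh'")
    kept = table[~table["excluded"].astype(bool)]
    summaries = []
    tests = []
    for measurement in sorted(kept["measurement"].unique()):
        msub = kept[kept["measurement"] == measurement]
        for tp in sorted(msub["timepoint"].unique()):
            summaries.append(group_summary(table, measurement, tp))
            sub = msub[msub["timepoint"] == tp]

            def _cell(sex=None, geno=None):
                c = sub
                if sex is not None:
                    c = c[c["sex"] == sex]
                if geno is not None:
                    c = c[c["genotype"] == geno]
                return c["value"].to_numpy(float), c["animal"].tolist()

            comparisons = [
                ("genotype_within_f", _cell("f", "mutant"), _cell("f", "control")),
                ("genotype_within_m", _cell("m", "mutant"), _cell("m", "control")),
                ("sex_within_mutant", _cell("f", "mutant"), _cell("m", "mutant")),
                ("sex_within_control", _cell("f", "control"), _cell("m", "control")),
            ]
            for grouping, (va, ia), (vb, ib) in comparisons:
                if va.size < 2 or vb.size < 2:
                    continue
                res = compare_groups(
                    va, vb, ids_a=ia, ids_b=ib, alpha=alpha,
                    measurement=measurement, timepoint=tp, grouping=grouping,
                    lilliefors_correction=lilliefors_correction,
                )
                tests.append(res.__dict__)

    summary_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    tests_df = pd.DataFrame(tests)
    if mtc == "bh" and len(tests_df):
        _, p_adj, _, _ = multipletests(tests_df["p_value"], method="fdr_bh")
        tests_df["p_adjusted"] = p_adj
        tests_df["stars_adjusted"] = [stars_from_p(p) for p in p_adj]
    return summary_df, tests_df


def report_to_markdown(summary_df: pd.DataFrame, tests_df: pd.DataFrame) -> str:
    """Human-readable report: mean ± sd per cell and starred comparisons."""
    lines = ["# Cohort report", "", "## Group summaries (mean ± sd, n)", ""]
    for _, r in summary_df.iterrows():
        if r["n"]:
            lines.append(
                f"- {r['measurement']} @ {r['timepoint']} mo, {r['sex']}/{r['genotype']}: "
                f"{r['mean']:.3g} ± {0.0 if np.isnan(r['sd']) else r['sd']:.3g} (n={r['n']})"
            )
    lines += ["", "## Comparisons", ""]
    for _, r in tests_df.iterrows():
        lines.append(
            f"- {r['measurement']} @ {r['timepoint']} mo [{r['grouping']}] "
            f"{r['test']}: p = {r['p_value']:.4g} {r['stars']}"
        )
    return "\n".join(lines) + "\n"
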