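"""Cohort-level analyses of deployed-panel assignments.

Covers the field-application half of the workflow: per-individual
missing-data filtering, per-year stock-composition tables with hybrid
summaries, within-year and across-year contingency tests on class
proportions, and fork-length comparisons among assigned classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crosses import CLASSES
from .datatypes import GenotypeMatrix

__all__ = [
    "filter_individuals_by_missingness",
    "stock_composition",
    "within_year_class_test",
    "across_year_class_test",
    "fork_length_comparison",
    "ChiSquareResult",
    "AnovaResult",
]

_HYBRID = ("F1", "F2", "BC0", "BC1")
_ADVANCED = ("F2", "BC0", "BC1")


def filter_individuals_by_missingness(
    matrix: GenotypeMatrix, max_missing: float = 0.25
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop individuals with strictly more than ``max_missing`` missing calls.

    An individual at exactly the threshold is kept (the filter removes
    "> 25% missing data", not ">="). Returns the filtered matrix and the
    boolean keep-mask over the original rows.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    frac = matrix.individual_missing_fraction()
    keep = frac <= max_missing
    return matrix.subset_individuals(np.flatnonzero(keep)), keep


def stock_composition(assigned_classes, years) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-year stock-composition table plus hybrid summary.

    Returns ``(composition, summary)``. ``composition`` has one row per
    (year, class) with counts and within-year proportions; ``summary`` has
    one row per year with total n, hybrid fraction (F1 + F2 + both
    backcrosses over n) and the advanced-hybrid fraction among hybrids
    (F2 + backcrosses over all hybrids). Proportions are exact; rounding is
    left to presentation.
    """
    assigned = list(assigned_classes)
    years = list(years)
    if len(assigned) != len(years):
        raise ValueError("assignments and year labels must have equal length")
    bad = set(assigned) - set(CLASSES)
    if bad:
        raise ValueError(f"labels outside the six classes: {sorted(bad)}")

    df = pd.DataFrame({"year": years, "class": assigned})
    counts = (
        df.groupby(["year", "class"], sort=True).size().rename("count").reset_index()
    )
    full = (
        counts.set_index(["year", "class"])
        .reindex(
            pd.MultiIndex.from_product(
                [sorted(set(years)), CLASSES], names=["year", "class"]
            ),
            fill_value=0,
        )
        .reset_index()
    )
    totals = full.groupby("year")["count"].transform("sum")
    full["proportion"] = full["count"] / totals

    rows = []
    for year, sub in full.groupby("year"):
        cnt = sub.set_index("class")["count"]
        n = int(cnt.sum())
        n_hybrid = int(cnt[list(_HYBRID)].sum())
        n_advanced = int(cnt[list(_ADVANCED)].sum())
        rows.append(
            {
                "year": year,
                "n": n,
                "hybrid_fraction": n_hybrid / n if n else np.nan,
                "advanced_fraction_of_hybrids": n_advanced / n_hybrid
                if n_hybrid
                else np.nan,
            }
        )
    return full, pd.DataFrame(rows)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    p_exact: float | None = None


def within_year_class_test(
    class_counts, n_monte_carlo: int = 0, seed: int | None = None
) -> ChiSquareResult:
    """Goodness-of-fit test of equal class proportions within one year.

    Pearson chi-square against the uniform expectation over the six classes
    (df = 5). With ``n_monte_carlo > 0`` a seeded Monte-Carlo exact p-value
    (multinomial resampling under the uniform null) is also reported.
    """
    counts = np.asarray(class_counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("total count must be positive")
    k = counts.size
    expected = np.full(k, n / k)
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))

    p_exact = None
    if n_monte_carlo > 0:
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(int(n), np.full(k, 1 / k), size=n_monte_carlo)
        stat = ((sims - expected) ** 2 / expected).sum(axis=1)
        p_exact = float((1 + np.sum(stat >= chi2 - 1e-12)) / (1 + n_monte_carlo))
    return ChiSquareResult(chi2, df, p, p_exact)


def across_year_class_test(
    class_counts_by_year, totals_by_year, n_monte_carlo: int = 0, seed: int | None = None
) -> ChiSquareResult:
    """Test whether one class's proportion differs across sample years.

    Chi-square on the years x (class, not-class) contingency table
    (df = years - 1, no continuity correction); optionally a seeded
    Monte-Carlo exact p-value in the style of Fisher's exact test.
    """
    in_class = np.asarray(class_counts_by_year, dtype=int)
    totals = np.asarray(totals_by_year, dtype=int)
    if in_class.size != totals.size or in_class.size < 2:
        raise ValueError("need counts and totals for at least 2 years")
    if np.any(totals <= 0):
        raise ValueError("every year must have a positive total")
    if np.any(in_class > totals) or np.any(in_class < 0):
        raise ValueError("class counts must lie in [0, total] per year")

    table = np.column_stack([in_class, totals - in_class])
    if table.sum(axis=0).min() == 0:
        # class absent (or universal) in every year: no heterogeneity testable
        return ChiSquareResult(0.0, int(len(totals) - 1), 1.0, None)
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)

    p_exact = None
    if n_monte_carlo > 0:
        rng = np.random.default_rng(seed)
        pooled = in_class.sum() / totals.sum()
        sims = rng.binomial(totals[None, :], pooled, size=(n_monte_carlo, totals.size))
        exp = totals * pooled
        exp2 = totals * (1 - pooled)
        stat = ((sims - exp) ** 2 / exp + (totals - sims - exp2) ** 2 / exp2).sum(axis=1)
        p_exact = float((1 + np.sum(stat >= chi2 - 1e-12)) / (1 + n_monte_carlo))
    return ChiSquareResult(float(chi2), int(df), float(p), p_exact)


@dataclass
class AnovaResult:
    f_stat: float
    p: float
    tukey: pd.DataFrame


def fork_length_comparison(lengths, classes) -> AnovaResult:
    """One-way ANOVA of fork length across assigned classes, with Tukey HSD.

    Returns the ANOVA F statistic and p-value plus the pairwise Tukey table
    (``group1, group2, meandiff, p_adj, lower, upper, reject``). Requires at
    least two groups with at least two observations each.
    """
    lengths = np.asarray(lengths, dtype=float)
    classes = np.asarray(classes)
    if lengths.size != classes.size:
        raise ValueError("lengths and classes must have equal length")
    groups = [lengths[classes == c] for c in pd.unique(classes)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")

    f_stat, p = sps.f_oneway(*groups)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(lengths, classes)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return AnovaResult(float(f_stat), float(p), tukey)
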