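"""Per-locus population-genetic statistics for the candidate-locus filter chain.

Implements call rate, minor allele frequency, observed heterozygosity,
Wright's inbreeding coefficient Fis, the exact conditional Hardy-Weinberg
test, the two-population Weir & Cockerham (1984) theta estimator of Fst, and
a genotypic linkage-disequilibrium G-test with a permutation null.

Missing genotypes are excluded pairwise everywhere: every denominator counts
called genotypes only. Statistics that are undefined for a given input (e.g.
Fis at a monomorphic locus) are returned as ``nan`` rather than raising.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GenotypeMatrix, ReferencePanel

__all__ = [
    "LocusStats",
    "locus_summary",
    "weir_cockerham_theta",
    "theta_by_locus",
    "hwe_exact_test",
    "ld_genotypic_test",
    "LdTestResult",
    "stats_table",
    "pairwise_ld_pvalues",
]


@dataclass
class LocusStats:
    """Summary statistics for one biallelic locus in two populations."""

    call_rate_pop0: float
    call_rate_pop1: float
    maf_pooled: float
    hobs_pop0: float
    hobs_pop1: float
    fis_pop0: float
    fis_pop1: float
    hwe_p_pop0: float
    hwe_p_pop1: float
    theta: float


def _called(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    return g[g >= 0]


def _pop_counts(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n_called, alt_allele_count, het_count) for an (n, L) matrix."""
    called = G >= 0
    n = called.sum(axis=0)
    alt = np.where(called, G, 0).sum(axis=0)
    het = (G == 1).sum(axis=0)
    return n, alt, het


def locus_summary(genotypes_pop0, genotypes_pop1) -> LocusStats:
    """Compute :class:`LocusStats` for one locus from two genotype vectors.

    Fis is ``1 - Hobs/Hexp`` with ``Hexp = 2p(1-p)`` estimated from the same
    sample; it is ``nan`` when ``Hexp = 0``. An all-missing population yields
    ``nan`` statistics (never an exception).
    """
    g0 = np.asarray(genotypes_pop0)
    g1 = np.asarray(genotypes_pop1)
    if g0.size == 0 or g1.size == 0:
        raise ValueError("genotype vectors must be nonempty")

    out = {}
    pooled_alt = 0
    pooled_n = 0
    for name, g in (("pop0", g0), ("pop1", g1)):
        c = _called(g)
        out[f"call_rate_{name}"] = c.size / g.size
        if c.size == 0:
            out[f"hobs_{name}"] = np.nan
            out[f"fis_{name}"] = np.nan
            out[f"hwe_p_{name}"] = np.nan
            continue
        p = c.sum() / (2 * c.size)
        hobs = float(np.mean(c == 1))
        hexp = 2 * p * (1 - p)
        out[f"hobs_{name}"] = hobs
        out[f"fis_{name}"] = 1 - hobs / hexp if hexp > 0 else np.nan
        out[f"hwe_p_{name}"] = hwe_exact_test(
            int(np.sum(c == 0)), int(np.sum(c == 1)), int(np.sum(c == 2))
        )
        pooled_alt += int(c.sum())
        pooled_n += c.size

    if pooled_n > 0:
        p_pool = pooled_alt / (2 * pooled_n)
        out["maf_pooled"] = min(p_pool, 1 - p_pool)
    else:
        out["maf_pooled"] = np.nan

    n0, n1 = _called(g0).size, _called(g1).size
    if n0 >= 2 and n1 >= 2:
        out["theta"] = float(theta_by_locus(g0.reshape(-1, 1), g1.reshape(-1, 1))[0])
    else:
        out["theta"] = np.nan
    return LocusStats(**out)


def theta_by_locus(G0: np.ndarray, G1: np.ndarray) -> np.ndarray:
    """Vectorised two-population Weir & Cockerham (1984) theta per locus.

    Parameters
    ----------
    G0, G1
        Genotype matrices ``(n_individuals, n_loci)`` for the two populations.

    Returns
    -------
    ndarray of shape ``(n_loci,)``; ``nan`` where either population has fewer
    than 2 called genotypes or where the a+b+c denominator is zero (locus
    monomorphic in both samples).
    """
    G0 = np.asarray(G0)
    G1 = np.asarray(G1)
    n0, alt0, het0 = _pop_counts(G0)
    n1, alt1, het1 = _pop_counts(G1)
    valid = (n0 >= 2) & (n1 >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        n0f = np.where(valid, n0, 2).astype(float)
        n1f = np.where(valid, n1, 2).astype(float)
        p0 = alt0 / (2 * n0f)
        p1 = alt1 / (2 * n1f)
        h0 = het0 / n0f
        h1 = het1 / n1f

        r = 2.0
        nbar = (n0f + n1f) / r
        nc = (r * nbar - (n0f**2 + n1f**2) / (r * nbar)) / (r - 1)
        pbar = (n0f * p0 + n1f * p1) / (r * nbar)
        s2 = (n0f * (p0 - pbar) ** 2 + n1f * (p1 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n0f * h0 + n1f * h1) / (r * nbar)

        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

        denom = a + b + c
        theta = np.where((denom != 0) & valid, a / np.where(denom == 0, 1, denom), np.nan)
    # the ratio can overshoot the parameter space by floating-point error
    # (e.g. exactly fixed differences); truncate to [-1, 1]
    return np.clip(theta, -1.0, 1.0)


def weir_cockerham_theta(genotypes_pop0, genotypes_pop1) -> float:
    """Weir & Cockerham theta (a/(a+b+c)) for a single locus.

    Raises ``ValueError`` with fewer than 2 called genotypes in either
    population; returns ``nan`` when the locus is monomorphic in both
    samples (zero denominator).
    """
    g0 = np.asarray(genotypes_pop0)
    g1 = np.asarray(genotypes_pop1)
    if _called(g0).size < 2 or _called(g1).size < 2:
        raise ValueError("need >= 2 called genotypes per population")
    return float(theta_by_locus(g0.reshape(-1, 1), g1.reshape(-1, 1))[0])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (enumeration over heterozygote
    counts given the observed allele counts).

    The p-value is the total conditional probability of all heterozygote
    configurations no more probable than the observed one (the standard
    two-sided convention for this test). Monomorphic samples return 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("total genotype count must be >= 1")

    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0

    # log P(het | n, n_rare) up to a shared constant:
    #   het*log 2 - log(hom_rare!) - log(het!) - log(hom_common!)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_rare + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Genotypic linkage-disequilibrium test
# ---------------------------------------------------------------------------

class LdTestResult(NamedTuple):
    p: float
    g_stat: float
    degenerate: bool


def _g_statistic(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    obs = table[table > 0]
    exp = expected[table > 0]
    return float(2 * np.sum(obs * np.log(obs / exp)))


def ld_genotypic_test(
    genotypes_a, genotypes_b, n_permutations: int = 999, seed: int | None = None
) -> LdTestResult:
    """Permutation G-test of genotypic association between two loci.

    Builds the 3x3 genotype contingency table over individuals called at both
    loci and compares the observed log-likelihood-ratio statistic against
    ``n_permutations`` label shuffles;
    ``p = (1 + #{G_perm >= G_obs}) / (1 + n_permutations)``.

    A locus with fewer than two distinct genotype categories yields
    ``p = 1`` with the ``degenerate`` flag set.
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    mask = (a >= 0) & (b >= 0)
    a, b = a[mask], b[mask]
    if a.size == 0 or np.unique(a).size < 2 or np.unique(b).size < 2:
        return LdTestResult(1.0, 0.0, True)

    def table(x, y):
        return np.bincount(3 * x + y, minlength=9).reshape(3, 3)

    g_obs = _g_statistic(table(a, b))
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        g_perm = _g_statistic(table(a, rng.permutation(b)))
        if g_perm >= g_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return LdTestResult(float(p), g_obs, False)


# ---------------------------------------------------------------------------
# Whole-panel helpers
# ---------------------------------------------------------------------------

def stats_table(panel: ReferencePanel) -> pd.DataFrame:
    """Per-locus statistics table for a two-population reference panel.

    Returns a DataFrame indexed by locus id with the :class:`LocusStats`
    fields plus ``tag_length``/``snp_pos`` from the locus records.
    """
    G0 = panel.pop0.genotypes
    G1 = panel.pop1.genotypes
    n0, alt0, het0 = _pop_counts(G0)
    n1, alt1, het1 = _pop_counts(G1)

    with np.errstate(divide="ignore", invalid="ignore"):
        cr0 = n0 / G0.shape[0]
        cr1 = n1 / G1.shape[0]
        p_pool = (alt0 + alt1) / (2 * (n0 + n1))
        maf = np.minimum(p_pool, 1 - p_pool)
        p0 = np.where(n0 > 0, alt0 / np.maximum(2 * n0, 1), np.nan)
        p1 = np.where(n1 > 0, alt1 / np.maximum(2 * n1, 1), np.nan)
        hobs0 = np.where(n0 > 0, het0 / np.maximum(n0, 1), np.nan)
        hobs1 = np.where(n1 > 0, het1 / np.maximum(n1, 1), np.nan)
        hexp0 = 2 * p0 * (1 - p0)
        hexp1 = 2 * p1 * (1 - p1)
        fis0 = np.where(hexp0 > 0, 1 - hobs0 / np.where(hexp0 > 0, hexp0, 1), np.nan)
        fis1 = np.where(hexp1 > 0, 1 - hobs1 / np.where(hexp1 > 0, hexp1, 1), np.nan)

    hwe0 = np.array([
        hwe_exact_test(int(np.sum(c == 0)), int(np.sum(c == 1)), int(np.sum(c == 2)))
        if c.size else np.nan
        for c in (_called(G0[:, j]) for j in range(G0.shape[1]))
    ])
    hwe1 = np.array([
        hwe_exact_test(int(np.sum(c == 0)), int(np.sum(c == 1)), int(np.sum(c == 2)))
        if c.size else np.nan
        for c in (_called(G1[:, j]) for j in range(G1.shape[1]))
    ])

    df = pd.DataFrame(
        {
            "call_rate_pop0": cr0,
            "call_rate_pop1": cr1,
            "maf_pooled": maf,
            "hobs_pop0": hobs0,
            "hobs_pop1": hobs1,
            "fis_pop0": fis0,
            "fis_pop1": fis1,
            "hwe_p_pop0": hwe0,
            "hwe_p_pop1": hwe1,
            "theta": theta_by_locus(G0, G1),
        },
        index=pd.Index(panel.loci, name="locus_id"),
    )
    if panel.records:
        df["tag_length"] = [r.tag_length for r in panel.records]
        df["snp_pos"] = [r.snp_pos for r in panel.records]
    return df


def pairwise_ld_pvalues(gm: GenotypeMatrix) -> pd.DataFrame:
    """Asymptotic G-test p-values for genotypic LD between all locus pairs.

    One-hot encodes genotypes (missing rows drop out of pair tables
    automatically) and builds all 3x3 pair tables with a single matrix
    product, then evaluates the G statistic against its chi-square reference
    with degrees of freedom from the nonzero table margins.

    Returns a long-format DataFrame ``(locus_a, locus_b, g_stat, df, p)``
    with ``locus_a`` earlier in ``gm.loci`` than ``locus_b``. Degenerate
    pairs (a locus with < 2 observed genotype categories) get ``p = 1``.
    """
    G = gm.genotypes.astype(np.int64)
    n, L = G.shape
    onehot = np.zeros((L, 3, n))
    for k in range(3):
        onehot[:, k, :] = (G.T == k)
    flat = onehot.reshape(L * 3, n)
    T = flat @ flat.T  # (3L, 3L)
    tables = T.reshape(L, 3, L, 3).transpose(0, 2, 1, 3)  # (L, L, 3, 3)

    rowsum = tables.sum(axis=3)  # (L, L, 3)
    colsum = tables.sum(axis=2)
    total = rowsum.sum(axis=2)  # (L, L)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rowsum[..., :, None] * colsum[..., None, :] / total[..., None, None]
        ratio = np.where(tables > 0, tables / np.where(expected > 0, expected, 1), 1.0)
        g = 2 * np.sum(tables * np.log(ratio), axis=(2, 3))

    nrows = (rowsum > 0).sum(axis=2)
    ncols = (colsum > 0).sum(axis=2)
    dof = (nrows - 1) * (ncols - 1)
    degenerate = dof < 1
    p = np.where(degenerate, 1.0, sps.chi2.sf(g, np.maximum(dof, 1)))

    iu, ju = np.triu_indices(L, k=1)
    loci = np.asarray(gm.loci)
    return pd.DataFrame(
        {
            "locus_a": loci[iu],
            "locus_b": loci[ju],
            "g_stat": g[iu, ju],
            "df": dof[iu, ju],
            "p": p[iu, ju],
        }
    )
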