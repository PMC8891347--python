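"""Candidate-locus filter chain and panel optimisation.

Stages, in order: quality filters (call rate, MAF) -> homeolog filter
(excess heterozygosity / negative Fis in both populations) -> Hardy-Weinberg
filter -> tag-position filter + theta ranking (top 650) -> LD pruning (to
600 candidates) -> primer-dropout modelling down to the deployed panel.

Each stage records entering/surviving counts and the first removal reason
per locus in a :class:`FilterReport`; the counts are conserved across the
chain (removed + survived = entered at every stage).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, ReferencePanel
from .popgen import pairwise_ld_pvalues, stats_table

__all__ = [
    "FilterConfig",
    "FilterReport",
    "apply_quality_filters",
    "homeolog_filter",
    "hwe_filter",
    "position_and_rank",
    "ld_prune",
    "model_primer_dropout",
    "design_panel",
]


@dataclass
class FilterConfig:
    """Thresholds of the filter chain.

    ``min_call_rate`` is inclusive ("at least 60%"); ``min_maf`` is strict
    ("greater than 0.05"); the tag-position window is inclusive on both
    ends (ordinal base pairs 40..70). The LD test defaults to an asymptotic
    genotypic G-test with Bonferroni correction across the tested pairs
    (``ld_correction="bonferroni"``); set ``ld_correction="none"`` for raw
    per-pair alpha.
    """

    min_call_rate: float = 0.60
    min_maf: float = 0.05
    homeolog_hobs_max: float = 0.5
    hwe_alpha: float = 0.05
    position_window: tuple[int, int] = (40, 70)
    top_n_fst: int = 650
    ld_alpha: float = 0.05
    ld_correction: str = "bonferroni"
    n_candidates: int = 600

    def __post_init__(self) -> None:
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        if self.position_window[0] < 1 or self.position_window[0] > self.position_window[1]:
            raise ValueError("invalid position_window")
        if self.ld_correction not in ("bonferroni", "none"):
            raise ValueError("ld_correction must be 'bonferroni' or 'none'")


@dataclass
class FilterReport:
    """Per-stage bookkeeping of the filter chain."""

    stages: list[dict] = field(default_factory=list)
    removal_reason: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def add_stage(self, name: str, entered, kept) -> None:
        entered = list(entered)
        kept_set = set(kept)
        removed = [l for l in entered if l not in kept_set]
        if self.stages and self.stages[-1]["n_survived"] != len(entered):
            raise ValueError(
                f"stage {name!r} entered {len(entered)} loci but previous stage "
                f"survived {self.stages[-1]['n_survived']}"
            )
        for locus in removed:
            self.removal_reason.setdefault(locus, name)
        self.stages.append(
            {
                "stage": name,
                "n_entered": len(entered),
                "n_removed": len(removed),
                "n_survived": len(entered) - len(removed),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _report(report: FilterReport | None) -> FilterReport:
    return report if report is not None else FilterReport()


def apply_quality_filters(
    stats: pd.DataFrame, config: FilterConfig, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Call-rate and MAF filter.

    Keeps loci called in at least ``min_call_rate`` of individuals in BOTH
    populations with pooled minor allele frequency strictly greater than
    ``min_maf``.
    """
    report = _report(report)
    cr_ok = (stats["call_rate_pop0"] >= config.min_call_rate) & (
        stats["call_rate_pop1"] >= config.min_call_rate
    )
    maf_ok = stats["maf_pooled"] > config.min_maf
    kept = stats[cr_ok & maf_ok]
    # split bookkeeping: call-rate failures recorded first
    for locus in stats.index[~cr_ok]:
        report.removal_reason.setdefault(locus, "call_rate")
    for locus in stats.index[cr_ok & ~maf_ok]:
        report.removal_reason.setdefault(locus, "maf")
    report.add_stage("quality", stats.index, kept.index)
    return kept, report


def homeolog_filter(
    stats: pd.DataFrame, config: FilterConfig, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove suspected collapsed homeologs.

    A locus is removed iff (Fis < 0 OR Hobs > ``homeolog_hobs_max``) holds
    in BOTH reference populations — the signature of a duplicated locus
    genotyped as one. An undefined Fis (monomorphic sample) counts as not
    satisfying the condition in that population (conservative keep) and is
    flagged.
    """
    report = _report(report)
    with np.errstate(invalid="ignore"):
        cond0 = (stats["fis_pop0"] < 0) | (stats["hobs_pop0"] > config.homeolog_hobs_max)
        cond1 = (stats["fis_pop1"] < 0) | (stats["hobs_pop1"] > config.homeolog_hobs_max)
    undefined = stats["fis_pop0"].isna() | stats["fis_pop1"].isna()
    for locus in stats.index[undefined]:
        report.flags.append(f"homeolog_filter: undefined Fis at {locus}, kept")
    kept = stats[~(cond0 & cond1)]
    for locus in stats.index[cond0 & cond1]:
        report.removal_reason.setdefault(locus, "homeolog")
    report.add_stage("homeolog", stats.index, kept.index)
    return kept, report


def hwe_filter(
    stats: pd.DataFrame, config: FilterConfig, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove loci out of Hardy-Weinberg equilibrium.

    A locus is removed when its exact-test p-value falls below ``hwe_alpha``
    in EITHER reference population. ``hwe_alpha = 0`` disables the filter.
    """
    report = _report(report)
    with np.errstate(invalid="ignore"):
        fail = (stats["hwe_p_pop0"] < config.hwe_alpha) | (
            stats["hwe_p_pop1"] < config.hwe_alpha
        )
    kept = stats[~fail.fillna(False)]
    for locus in stats.index[fail.fillna(False)]:
        report.removal_reason.setdefault(locus, "hwe")
    report.add_stage("hwe", stats.index, kept.index)
    return kept, report


def position_and_rank(
    stats: pd.DataFrame, config: FilterConfig, report: FilterReport | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Tag-position filter and differentiation ranking.

    Keeps loci whose SNP sits within the inclusive ``position_window`` of
    the RAD tag (enough flanking sequence for primer design), sorts by theta
    descending and truncates to the ``top_n_fst`` most differentiated loci.
    Theta ties are broken lexicographically by locus id and flagged; loci
    with undefined theta are dropped. If fewer than ``top_n_fst`` loci
    remain, all are returned with a warning.
    """
    report = _report(report)
    lo, hi = config.position_window
    in_window = (stats["snp_pos"] >= lo) & (stats["snp_pos"] <= hi)
    theta_ok = stats["theta"].notna()
    pool = stats[in_window & theta_ok]
    for locus in stats.index[~in_window]:
        report.removal_reason.setdefault(locus, "position")
    for locus in stats.index[in_window & ~theta_ok]:
        report.removal_reason.setdefault(locus, "theta_undefined")
    report.add_stage("position", stats.index, pool.index)

    # theta descending; ties broken lexicographically by locus id (stable
    # mergesort over an id-sorted frame)
    ranked = pool.sort_index().sort_values("theta", ascending=False, kind="mergesort")
    if len(ranked) < config.top_n_fst:
        warnings.warn(
            f"only {len(ranked)} loci available for top-{config.top_n_fst} selection"
        )
    top = ranked.head(config.top_n_fst)
    if len(ranked) > config.top_n_fst:
        cut = top["theta"].iloc[-1]
        if (ranked["theta"] == cut).sum() > 1:
            report.flags.append(f"rank: theta tie at cutoff ({cut:.6g}), broken by locus id")
    report.add_stage("rank_top_fst", ranked.index, top.index)
    return top, report


def ld_prune(
    candidates: pd.DataFrame,
    genotypes: ReferencePanel | list[GenotypeMatrix],
    config: FilterConfig,
    report: FilterReport | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove linked loci, keeping the higher-theta member of each pair.

    Pairs are tested for genotypic association WITHIN each reference
    population (a pooled test would read population structure as
    association and strip exactly the most differentiated loci); per-pair G
    statistics and degrees of freedom are summed over populations and
    referred to chi-square, Bonferroni-corrected across pairs by default.
    Significant pairs are processed in order of increasing p; the
    lower-theta member is removed (theta tie: the lexicographically later
    id), repeating until no significant pair survives. The result is then
    truncated to ``n_candidates`` by theta rank. Deterministic; ``seed`` is
    accepted for interface symmetry with the stochastic stages.
    """
    from scipy import stats as sps

    report = _report(report)
    ids = list(candidates.index)
    pops = (
        [genotypes.pop0, genotypes.pop1]
        if isinstance(genotypes, ReferencePanel)
        else list(genotypes)
    )
    g_tot = None
    for gm in pops:
        part = pairwise_ld_pvalues(gm.subset_loci(ids))
        if g_tot is None:
            g_tot = part[["locus_a", "locus_b"]].copy()
            g_tot["g_stat"] = 0.0
            g_tot["df"] = 0
        g_tot["g_stat"] += part["g_stat"]
        g_tot["df"] += part["df"]
    pairs = g_tot
    pairs["p"] = np.where(
        pairs["df"] < 1, 1.0, sps.chi2.sf(pairs["g_stat"], np.maximum(pairs["df"], 1))
    )
    alpha = config.ld_alpha
    if config.ld_correction == "bonferroni" and len(pairs):
        alpha = alpha / len(pairs)
    sig = pairs[pairs["p"] < alpha].sort_values(
        ["p", "locus_a", "locus_b"], kind="mergesort"
    )

    theta = candidates["theta"]
    alive = set(ids)
    for _, row in sig.iterrows():
        a, b = row["locus_a"], row["locus_b"]
        if a not in alive or b not in alive:
            continue
        if theta[a] > theta[b]:
            drop = b
        elif theta[b] > theta[a]:
            drop = a
        else:
            drop = max(a, b)
        alive.discard(drop)
        report.removal_reason.setdefault(drop, "ld")
    pruned = candidates.loc[[l for l in ids if l in alive]]
    report.add_stage("ld_prune", ids, pruned.index)

    final = pruned.head(config.n_candidates)
    report.add_stage("truncate_candidates", pruned.index, final.index)
    return final, report


def model_primer_dropout(
    candidates: pd.DataFrame,
    mode: str,
    params: dict | None = None,
    seed: int | None = None,
    report: FilterReport | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Model multiplex-primer dropout, producing the deployed panel.

    Modes
    -----
    ``random_subset``
        Draw ``params["k"]`` loci without replacement (seeded), emulating a
        random forecast of which primers survive optimisation.
    ``drop_list``
        Remove the named loci (``params["drop"]``), emulating an empirical
        dropout list from wet-lab optimisation rounds.
    ``read_share``
        Remove loci whose share of total raw reads exceeds
        ``params.get("max_share", 0.02)`` strictly (overrepresented
        amplicons); ``params["shares"]`` maps locus id -> read share.
    """
    report = _report(report)
    params = params or {}
    ids = list(candidates.index)
    if not ids:
        raise ValueError("candidate panel is empty")

    if mode == "random_subset":
        k = int(params["k"])
        if k > len(ids):
            raise ValueError(f"k={k} exceeds panel size {len(ids)}")
        rng = np.random.default_rng(seed)
        chosen = set(rng.choice(len(ids), size=k, replace=False).tolist())
        kept = candidates.loc[[l for i, l in enumerate(ids) if i in chosen]]
        reason = "dropout_random"
    elif mode == "drop_list":
        drop = list(params["drop"])
        unknown = set(drop) - set(ids)
        if unknown:
            raise KeyError(f"drop_list names unknown loci: {sorted(unknown)[:5]}")
        kept = candidates.drop(index=drop)
        reason = "dropout_listed"
    elif mode == "read_share":
        shares = params["shares"]
        max_share = float(params.get("max_share", 0.02))
        over = [l for l in ids if shares.get(l, 0.0) > max_share]
        kept = candidates.drop(index=over)
        reason = "dropout_overrepresented"
    else:
        raise ValueError(f"unknown dropout mode {mode!r}")

    for locus in candidates.index.difference(kept.index):
        report.removal_reason.setdefault(locus, reason)
    report.add_stage(f"dropout_{mode}", ids, kept.index)
    return kept, report


def design_panel(
    panel: ReferencePanel,
    config: FilterConfig | None = None,
    stats: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterReport, pd.DataFrame]:
    """Run the full filter chain on a reference panel.

    Returns ``(candidates, report, stats)``: the final candidate table
    (theta-ranked, at most ``n_candidates`` loci), the stage-by-stage
    :class:`FilterReport`, and the full per-locus statistics table.
    """
    config = config or FilterConfig()
    if stats is None:
        stats = stats_table(panel)
    report = FilterReport()
    kept, report = apply_quality_filters(stats, config, report)
    kept, report = homeolog_filter(kept, config, report)
    kept, report = hwe_filter(kept, config, report)
    kept, report = position_and_rank(kept, config, report)
    kept, report = ld_prune(kept, panel, config, report)
    return kept, report, stats
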