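"""Tests of the candidate-locus filter chain and dropout modelling."""
import numpy as np
import pandas as pd
import pytest

import hybridpanel as hp
from hybridpanel.datatypes import GenotypeMatrix, ReferencePanel
from hybridpanel.design import (
    FilterConfig,
    FilterReport,
    apply_quality_filters,
    homeolog_filter,
    hwe_filter,
    ld_prune,
    model_primer_dropout,
    position_and_rank,
)


def stats_frame(rows: dict[str, dict]) -> pd.DataFrame:
    defaults = {
        "call_rate_pop0": 1.0,
        "call_rate_pop1": 1.0,
        "maf_pooled": 0.3,
        "hobs_pop0": 0.3,
        "hobs_pop1": 0.3,
        "fis_pop0": 0.1,
        "fis_pop1": 0.1,
        "hwe_p_pop0": 0.5,
        "hwe_p_pop1": 0.5,
        "theta": 0.2,
        "tag_length": 90,
        "snp_pos": 50,
    }
    df = pd.DataFrame(
        {lid: {**defaults, **vals} for lid, vals in rows.items()}
    ).T
    df.index.name = "locus_id"
    return df


class TestQualityFilters:
    def test_call_rate_boundary_inclusive(self):
        stats = stats_frame(
            {
                "A": {"call_rate_pop0": 0.59, "call_rate_pop1": 0.95},
                "B": {"call_rate_pop0": 0.60, "call_rate_pop1": 0.60},
            }
        )
        kept, rep = apply_quality_filters(stats, FilterConfig())
        assert list(kept.index) == ["B"]
        assert rep.removal_reason["A"] == "call_rate"

    def test_maf_strictly_greater_than_threshold(self):
        stats = stats_frame({"A": {"maf_pooled": 0.05}, "B": {"maf_pooled": 0.0501}})
        kept, rep = apply_quality_filters(stats, FilterConfig())
        assert list(kept.index) == ["B"]
        assert rep.removal_reason["A"] == "maf"

    def test_survivor_count_matches_construction(self):
        rows = {f"L{i}": {} for i in range(50)}
        for i in range(5):  # plant 10% failing loci
            rows[f"L{i}"] = {"call_rate_pop0": 0.4}
        kept, _ = apply_quality_filters(stats_frame(rows), FilterConfig())
        assert len(kept) == 45


class TestHomeologFilter:
    def test_full_heterozygosity_in_both_removed(self):
        stats = stats_frame({"A": {"hobs_pop0": 1.0, "hobs_pop1": 1.0}})
        kept, rep = homeolog_filter(stats, FilterConfig())
        assert len(kept) == 0
        assert rep.removal_reason["A"] == "homeolog"

    def test_condition_in_single_population_kept(self):
        stats = stats_frame(
            {"A": {"fis_pop0": -0.2, "fis_pop1": 0.3, "hobs_pop0": 0.4, "hobs_pop1": 0.4}}
        )
        kept, _ = homeolog_filter(stats, FilterConfig())
        assert list(kept.index) == ["A"]

    def test_negative_fis_in_both_removed(self):
        stats = stats_frame({"A": {"fis_pop0": -0.1, "fis_pop1": -0.1}})
        kept, _ = homeolog_filter(stats, FilterConfig())
        assert len(kept) == 0

    def test_undefined_fis_conservative_keep(self):
        stats = stats_frame(
            {"A": {"fis_pop0": np.nan, "hobs_pop0": 0.0, "fis_pop1": -0.5}}
        )
        kept, rep = homeolog_filter(stats, FilterConfig())
        assert list(kept.index) == ["A"]
        assert any("undefined Fis" in f for f in rep.flags)


class TestHweFilter:
    def test_failure_in_either_population_removes(self):
        stats = stats_frame(
            {"A": {"hwe_p_pop0": 0.001, "hwe_p_pop1": 0.8}, "B": {}}
        )
        kept, rep = hwe_filter(stats, FilterConfig(hwe_alpha=0.05))
        assert list(kept.index) == ["B"]
        assert rep.removal_reason["A"] == "hwe"

    def test_zero_alpha_disables_filter(self):
        stats = stats_frame({"A": {"hwe_p_pop0": 1e-10}})
        kept, _ = hwe_filter(stats, FilterConfig(hwe_alpha=0.0))
        assert list(kept.index) == ["A"]


class TestPositionAndRank:
    def test_window_boundaries_inclusive(self):
        stats = stats_frame(
            {
                "A": {"snp_pos": 39},
                "B": {"snp_pos": 40},
                "C": {"snp_pos": 70},
                "D": {"snp_pos": 71},
            }
        )
        kept, rep = position_and_rank(stats, FilterConfig(top_n_fst=10))
        assert sorted(kept.index) == ["B", "C"]
        assert rep.removal_reason["A"] == "position"

    def test_top_n_selection_is_exact_sort(self, rng):
        rows = {f"L{i:03d}": {"theta": t} for i, t in enumerate(rng.uniform(0, 1, 100))}
        stats = stats_frame(rows)
        kept, _ = position_and_rank(stats, FilterConfig(top_n_fst=30))
        assert len(kept) == 30
        expected = stats["theta"].nlargest(30).sort_values(ascending=False)
        assert list(kept.index) == list(expected.index)
        assert (np.diff(kept["theta"].to_numpy()) <= 0).all()

    def test_theta_tie_at_cutoff_deterministic_and_flagged(self):
        stats = stats_frame(
            {"B": {"theta": 0.5}, "A": {"theta": 0.5}, "C": {"theta": 0.9}}
        )
        kept, rep = position_and_rank(stats, FilterConfig(top_n_fst=2))
        assert list(kept.index) == ["C", "A"]  # tie broken by id
        assert any("tie" in f for f in rep.flags)

    def test_fewer_loci_than_requested_warns(self):
        stats = stats_frame({"A": {}, "B": {}})
        with pytest.warns(UserWarning):
            kept, _ = position_and_rank(stats, FilterConfig(top_n_fst=10))
        assert len(kept) == 2


def build_panel_with_duplicate(seed=3, L=30, n0=25, n1=25):
    """Reference panel whose first two loci are exact duplicates; the
    duplicate pair is internally polymorphic in each population."""
    rng = np.random.default_rng(seed)
    loci = [f"L{j:02d}" for j in range(L)]
    G0 = rng.binomial(2, rng.uniform(0.2, 0.8, L), (n0, L)).astype(np.int8)
    G1 = rng.binomial(2, rng.uniform(0.2, 0.8, L), (n1, L)).astype(np.int8)
    G0[:, 1] = G0[:, 0]
    G1[:, 1] = G1[:, 0]
    return ReferencePanel(
        GenotypeMatrix(G0, [f"a{i}" for i in range(n0)], loci),
        GenotypeMatrix(G1, [f"b{i}" for i in range(n1)], loci),
    )


class TestLdPrune:
    def test_planted_duplicate_lower_theta_member_removed(self):
        panel = build_panel_with_duplicate()
        theta = hp.stats_table(panel)["theta"]
        stats = stats_frame({l: {"theta": theta[l]} for l in panel.loci})
        stats.loc["L00", "theta"] = 0.6
        stats.loc["L01", "theta"] = 0.4
        kept, rep = ld_prune(stats, panel, FilterConfig(n_candidates=50))
        assert "L00" in kept.index and "L01" not in kept.index
        assert rep.removal_reason["L01"] == "ld"

    def test_independent_loci_not_removed(self):
        rng = np.random.default_rng(8)
        L = 20
        loci = [f"L{j:02d}" for j in range(L)]
        G0 = rng.binomial(2, 0.4, (30, L)).astype(np.int8)
        G1 = rng.binomial(2, 0.6, (30, L)).astype(np.int8)
        panel = ReferencePanel(
            GenotypeMatrix(G0, [f"a{i}" for i in range(30)], loci),
            GenotypeMatrix(G1, [f"b{i}" for i in range(30)], loci),
        )
        stats = stats_frame({l: {"theta": 0.1 + 0.01 * j} for j, l in enumerate(loci)})
        kept, _ = ld_prune(stats, panel, FilterConfig(n_candidates=50))
        assert len(kept) == L

    def test_truncation_to_candidate_count(self):
        panel = build_panel_with_duplicate(L=40)
        stats = stats_frame(
            {l: {"theta": 0.9 - 0.01 * j} for j, l in enumerate(panel.loci)}
        )
        kept, _ = ld_prune(stats, panel, FilterConfig(n_candidates=25))
        assert len(kept) == 25


class TestPrimerDropout:
    @pytest.fixture()
    def panel600(self):
        return stats_frame({f"L{i:03d}": {"theta": 1 - i / 600} for i in range(600)})

    def test_random_subset_reproducible(self, panel600):
        k1, _ = model_primer_dropout(panel600, "random_subset", {"k": 350}, seed=5)
        k2, _ = model_primer_dropout(panel600, "random_subset", {"k": 350}, seed=5)
        assert len(k1) == 350
        assert list(k1.index) == list(k2.index)

    def test_read_share_strict_threshold(self, panel600):
        shares = {l: 0.001 for l in panel600.index}
        shares["L000"] = 0.03
        shares["L001"] = 0.02  # exactly 2%: kept (strict >)
        kept, rep = model_primer_dropout(panel600, "read_share", {"shares": shares})
        assert "L000" not in kept.index and "L001" in kept.index
        assert rep.removal_reason["L000"] == "dropout_overrepresented"

    def test_drop_list_yields_deployed_panel_size(self, panel600):
        drop = [f"L{i:03d}" for i in range(258)]
        kept, _ = model_primer_dropout(panel600, "drop_list", {"drop": drop})
        assert len(kept) == 342

    def test_oversized_subset_raises(self, panel600):
        with pytest.raises(ValueError):
            model_primer_dropout(panel600, "random_subset", {"k": 601}, seed=1)

    def test_unknown_drop_id_raises(self, panel600):
        with pytest.raises(KeyError):
            model_primer_dropout(panel600, "drop_list", {"drop": ["nope"]})


class TestFullChain:
    def test_report_counts_conserved(self, small_panel):
        _, report, _ = hp.design_panel(small_panel)
        stages = report.stages
        for stage in stages:
            assert stage["n_entered"] == stage["n_removed"] + stage["n_survived"]
        for prev, nxt in zip(stages, stages[1:]):
            assert nxt["n_entered"] == prev["n_survived"]

    def test_removal_reasons_unique_per_locus(self, small_panel):
        candidates, report, stats = hp.design_panel(small_panel)
        removed = set(report.removal_reason)
        assert removed.isdisjoint(set(candidates.index))

    def test_chain_deterministic(self, small_panel):
        c1, _, _ = hp.design_panel(small_panel)
        c2, _, _ = hp.design_panel(small_panel)
        pd.testing.assert_frame_equal(c1, c2)

    def test_forced_homeologs_removed_by_chain(self, small_panel):
        _, report, _ = hp.design_panel(small_panel)
        kinds = small_panel.locus_kind
        loci = np.asarray(small_panel.loci)
        homeologs = loci[kinds == "homeolog"]
        # forced all-heterozygote loci can never reach the candidate list
        for locus in homeologs:
            assert report.removal_reason.get(locus) in {"homeolog", "call_rate", "maf"}
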