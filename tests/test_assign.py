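"""Tests of reference-frequency estimation and class assignment."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridpanel as hp
from hybridpanel.assign import (
    assign_gibbs,
    assign_plugin,
    class_genotype_prob,
    estimate_reference_frequencies,
)
from hybridpanel.crosses import CLASSES, PHI
from hybridpanel.datatypes import GenotypeMatrix, ReferencePanel


def make_ref_panel(G0, G1):
    L = G0.shape[1]
    loci = [f"L{j}" for j in range(L)]
    return ReferencePanel(
        GenotypeMatrix(G0, [f"a{i}" for i in range(G0.shape[0])], loci),
        GenotypeMatrix(G1, [f"b{i}" for i in range(G1.shape[0])], loci),
    )


def genotype_prob_enumeration(phi, p0, p1, g):
    """Brute-force P(genotype = g): enumerate ordered gene-copy origins and
    alleles; the unordered phi01 mass splits evenly over the two orders."""
    origins = {(0, 0): phi[0], (0, 1): phi[1] / 2, (1, 0): phi[1] / 2, (1, 1): phi[2]}
    freqs = (p0, p1)
    total = 0.0
    for (o1, o2), w in origins.items():
        for a1, a2 in itertools.product((0, 1), repeat=2):
            if a1 + a2 != g:
                continue
            pr1 = freqs[o1] if a1 else 1 - freqs[o1]
            pr2 = freqs[o2] if a2 else 1 - freqs[o2]
            total += w * pr1 * pr2
    return total


class TestReferenceFrequencies:
    def test_smoothing_formula(self):
        # 20 individuals all hom-ref: 0 of 40 alt alleles, pseudocount 0.5
        G0 = np.zeros((20, 1), dtype=np.int8)
        G1 = np.full((20, 1), 2, dtype=np.int8)
        fr = estimate_reference_frequencies(make_ref_panel(G0, G1), pseudocount=0.5)
        assert fr.p0[0] == pytest.approx(0.5 / 41)
        assert fr.p1[0] == pytest.approx(40.5 / 41)

    def test_zero_pseudocount_plain_frequency(self):
        G0 = np.array([[0], [1], [2], [1]], dtype=np.int8)
        fr = estimate_reference_frequencies(make_ref_panel(G0, G0), pseudocount=0.0)
        assert fr.p0[0] == pytest.approx(4 / 8)

    def test_all_missing_locus_flagged(self):
        G0 = np.full((4, 1), -1, dtype=np.int8)
        G1 = np.array([[0], [1], [2], [2]], dtype=np.int8)
        fr = estimate_reference_frequencies(make_ref_panel(G0, G1))
        assert fr.p0[0] == 0.5
        assert bool(fr.uninformative[0])


class TestClassGenotypeProb:
    def test_f1_diagnostic_limit(self):
        eps = 1e-6
        probs = class_genotype_prob(PHI["F1"], 1 - eps, eps)
        assert probs[1] == pytest.approx(1.0, abs=1e-5)

    def test_f2_at_equal_half_frequencies(self):
        probs = class_genotype_prob(PHI["F2"], 0.5, 0.5)
        assert np.allclose(probs, [0.25, 0.5, 0.25])

    @pytest.mark.parametrize("name", CLASSES)
    @pytest.mark.parametrize("p0,p1", [(0.9, 0.1), (0.3, 0.7), (0.5, 0.5), (0.99, 0.2)])
    def test_matches_gene_copy_enumeration(self, name, p0, p1):
        probs = class_genotype_prob(PHI[name], p0, p1)
        for g in (0, 1, 2):
            assert probs[g] == pytest.approx(
                genotype_prob_enumeration(PHI[name], p0, p1, g), abs=1e-12
            )
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        p0=st.floats(0.01, 0.99),
        p1=st.floats(0.01, 0.99),
        w=st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_probabilities_sum_to_one(self, p0, p1, w):
        s = sum(w)
        if s == 0:
            return
        phi = tuple(x / s for x in w)
        probs = class_genotype_prob(phi, p0, p1)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs >= 0)


def make_freqs(p0, p1):
    loci = [f"L{j}" for j in range(len(p0))]
    return hp.ReferenceFrequencies(
        np.asarray(p0, dtype=float),
        np.asarray(p1, dtype=float),
        loci,
        0.5,
        np.zeros(len(p0), dtype=bool),
    )


def make_cohort(geno):
    geno = np.asarray(geno, dtype=np.int8)
    return GenotypeMatrix(
        geno,
        [f"ind{i}" for i in range(geno.shape[0])],
        [f"L{j}" for j in range(geno.shape[1])],
    )


class TestAssignPlugin:
    def test_diagnostic_heterozygote_is_f1(self):
        L = 100
        fr = make_freqs([1 - 1e-3] * L, [1e-3] * L)
        res = assign_plugin(make_cohort(np.ones((1, L))), fr)
        assert res.loc[0, "assigned_class"] == "F1"
        assert res.loc[0, "P_F1"] > 0.999

    def test_diagnostic_homozygote_is_pure(self):
        L = 100
        fr = make_freqs([1 - 1e-3] * L, [1e-3] * L)
        res = assign_plugin(make_cohort(np.full((1, L), 2)), fr)
        assert res.loc[0, "P_pure0"] > 0.999

    def test_three_locus_hand_oracle(self):
        p0 = [0.9, 0.2, 0.6]
        p1 = [0.1, 0.8, 0.5]
        geno = [[2, 0, 1], [1, 1, -1]]
        fr = make_freqs(p0, p1)
        res = assign_plugin(make_cohort(geno), fr)
        for i, g in enumerate(geno):
            liks = []
            for name in CLASSES:
                lik = 1.0
                for j, gj in enumerate(g):
                    if gj < 0:
                        continue
                    lik *= genotype_prob_enumeration(PHI[name], p0[j], p1[j], gj)
                liks.append(lik / 6)
            expected = np.array(liks) / sum(liks)
            observed = res.loc[i, [f"P_{c}" for c in CLASSES]].to_numpy(dtype=float)
            assert np.allclose(observed, expected, atol=1e-12)

    def test_posteriors_normalised(self, rng):
        fr = make_freqs(rng.uniform(0.1, 0.9, 20), rng.uniform(0.1, 0.9, 20))
        geno = rng.integers(-1, 3, (15, 20))
        res = assign_plugin(make_cohort(geno), fr)
        sums = res[[f"P_{c}" for c in CLASSES]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_called_loci_uniform_and_flagged(self):
        fr = make_freqs([0.7, 0.3], [0.2, 0.9])
        res = assign_plugin(make_cohort([[-1, -1]]), fr)
        assert res.loc[0, "tie"]
        assert res.loc[0, "loci_used"] == 0
        assert np.allclose(
            res.loc[0, [f"P_{c}" for c in CLASSES]].to_numpy(dtype=float), 1 / 6
        )

    def test_label_swap_symmetry(self, rng):
        """Swapping references permutes posteriors pure0<->pure1, BC0<->BC1."""
        p0 = rng.uniform(0.1, 0.9, 40)
        p1 = rng.uniform(0.1, 0.9, 40)
        geno = rng.integers(-1, 3, (10, 40))
        res_a = assign_plugin(make_cohort(geno), make_freqs(p0, p1))
        res_b = assign_plugin(make_cohort(geno), make_freqs(p1, p0))
        pairs = [
            ("P_pure0", "P_pure1"),
            ("P_pure1", "P_pure0"),
            ("P_F1", "P_F1"),
            ("P_F2", "P_F2"),
            ("P_BC0", "P_BC1"),
            ("P_BC1", "P_BC0"),
        ]
        for col_a, col_b in pairs:
            assert np.allclose(res_a[col_a], res_b[col_b], atol=1e-9)

    def test_uninformative_locus_leaves_posteriors_unchanged(self, rng):
        p0 = rng.uniform(0.2, 0.8, 25)
        p1 = rng.uniform(0.2, 0.8, 25)
        geno = rng.integers(0, 3, (8, 25))
        base = assign_plugin(make_cohort(geno), make_freqs(p0, p1))
        p0x = np.append(p0, 0.37)
        p1x = np.append(p1, 0.37)
        genox = np.column_stack([geno, rng.integers(0, 3, 8)])
        ext = assign_plugin(make_cohort(genox), make_freqs(p0x, p1x))
        cols = [f"P_{c}" for c in CLASSES]
        assert np.allclose(base[cols].to_numpy(), ext[cols].to_numpy(), atol=1e-12)

    def test_misaligned_loci_raise(self):
        fr = make_freqs([0.5], [0.5])
        gm = GenotypeMatrix(np.zeros((1, 1), dtype=np.int8), ["i"], ["other"])
        with pytest.raises(ValueError):
            assign_plugin(gm, fr)


class TestAssignGibbs:
    def _diagnostic_panel(self, L=30):
        G0 = np.full((15, L), 2, dtype=np.int8)
        G1 = np.zeros((15, L), dtype=np.int8)
        return make_ref_panel(G0, G1)

    def test_diagnostic_f1_recovered(self):
        panel = self._diagnostic_panel()
        cohort = make_cohort(np.ones((2, 30)))
        res = assign_gibbs(cohort, panel, n_burnin=300, n_sweeps=1500, seed=4)
        assert (res["P_F1"] >= 0.99).all()

    def test_determinism_given_seed(self):
        panel = self._diagnostic_panel()
        cohort = make_cohort(np.ones((2, 30)))
        r1 = assign_gibbs(cohort, panel, n_burnin=100, n_sweeps=400, seed=11)
        r2 = assign_gibbs(cohort, panel, n_burnin=100, n_sweeps=400, seed=11)
        pd.testing.assert_frame_equal(r1, r2)

    def test_agrees_with_plugin_on_separated_data(self, small_panel):
        top = hp.stats_table(small_panel).nlargest(60, "theta")
        sub = small_panel.subset_loci(list(top.index))
        fr = estimate_reference_frequencies(sub)
        sim, labels = hp.simulate_cohort(
            fr.p0, fr.p1, {c: 3 for c in CLASSES}, seed=21, loci=sub.loci
        )
        plugin = assign_plugin(sim, fr)
        gibbs = assign_gibbs(sim, sub, n_burnin=500, n_sweeps=2000, seed=22)
        agreement = np.mean(
            plugin["assigned_class"].to_numpy() == gibbs["assigned_class"].to_numpy()
        )
        assert agreement >= 0.9
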