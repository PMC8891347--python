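"""Synthetic RAD-like reference panels and test cohorts.

The generator emulates the statistical structure the panel-design chain
assumes in its input: two parental reference populations (default sample
sizes 20 and 35) genotyped at thousands of biallelic RAD SNPs, with

* population differentiation following the Balding-Nichols model (per-locus
  population frequencies drawn from a Beta centred on an ancestral frequency
  with variance governed by a per-locus differentiation parameter): a
  genome-wide background at ``divergence_F`` plus a small fraction of
  divergence-outlier loci at ``outlier_F``, emulating the L-shaped Fst
  distribution with a tail of highly differentiated (near-diagnostic)
  markers that differentiation scans of ecotype pairs routinely show;
* uniformly missing genotype calls;
* a small number of near-duplicate locus pairs (to exercise LD pruning);
* homeolog-like loci forced to all-heterozygote in both populations (the
  signature of collapsed salmonid paralogs);
* a uniformly distributed SNP position within a fixed-length RAD tag.

It stands in for empirical RAD genotype data; it models genotypes only (no
reads, no sequencing error).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import crosses
from .datatypes import MISSING, GenotypeMatrix, LocusRecord, ReferencePanel

__all__ = ["PopulationModel", "simulate_rad_dataset", "simulate_cohort"]


@dataclass
class PopulationModel:
    """Parameters of the synthetic RAD dataset.

    Defaults mirror the case-study reference data: pop0 sample size 20
    (resident form), pop1 sample size 35 (anadromous form), ~3000 candidate
    SNPs with moderate genome-wide differentiation (F = 0.15).
    """

    n_loci: int = 3000
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    divergence_F: float = 0.15
    outlier_fraction: float = 0.05
    outlier_F: float = 0.8
    n_pop0: int = 20
    n_pop1: int = 35
    missing_rate: float = 0.05
    n_linked_pairs: int = 10
    n_homeolog_like: int = 50
    tag_length: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.divergence_F < 1:
            raise ValueError("divergence_F must be in (0, 1)")
        if not 0 < self.outlier_F < 1:
            raise ValueError("outlier_F must be in (0, 1)")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_pop0 < 2 or self.n_pop1 < 2:
            raise ValueError("sample sizes must be >= 2")
        lo, hi = self.ancestral_freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo <= hi < 1")
        if self.n_loci < 1 or self.tag_length < 1:
            raise ValueError("n_loci and tag_length must be positive")
        if self.n_linked_pairs + self.n_homeolog_like > self.n_loci:
            raise ValueError("linked + homeolog loci exceed n_loci")


def _balding_nichols(rng, p_anc: np.ndarray, F: np.ndarray | float) -> np.ndarray:
    shape = (1 - np.asarray(F, dtype=float)) / F
    return rng.beta(p_anc * shape, (1 - p_anc) * shape)


def simulate_rad_dataset(model: PopulationModel) -> tuple[ReferencePanel, list[LocusRecord]]:
    """Generate a two-population reference panel under ``model``.

    Returns the :class:`ReferencePanel` (which carries the simulated-truth
    allele frequencies) and its locus records. Deterministic given
    ``model.seed``. Loci monomorphic in both samples are redrawn so the
    panel contains no fully uninformative markers.
    """
    rng = np.random.default_rng(model.seed)
    L = model.n_loci
    n_base = L - model.n_homeolog_like - model.n_linked_pairs

    lo, hi = model.ancestral_freq_range
    p0 = np.empty(n_base)
    p1 = np.empty(n_base)
    G0 = np.empty((model.n_pop0, n_base), dtype=np.int8)
    G1 = np.empty((model.n_pop1, n_base), dtype=np.int8)

    # per-locus differentiation: genome-wide background plus divergence
    # outliers, shared between the two populations
    F_locus = np.where(
        rng.random(n_base) < model.outlier_fraction,
        model.outlier_F,
        model.divergence_F,
    )

    todo = np.arange(n_base)
    for _ in range(100):
        k = todo.size
        p_anc = rng.uniform(lo, hi, k)
        p0[todo] = _balding_nichols(rng, p_anc, F_locus[todo])
        p1[todo] = _balding_nichols(rng, p_anc, F_locus[todo])
        G0[:, todo] = rng.binomial(2, p0[todo][None, :], (model.n_pop0, k)).astype(np.int8)
        G1[:, todo] = rng.binomial(2, p1[todo][None, :], (model.n_pop1, k)).astype(np.int8)
        pooled = G0[:, todo].sum(0) + G1[:, todo].sum(0)
        mono = (pooled == 0) | (pooled == 2 * (model.n_pop0 + model.n_pop1))
        todo = todo[mono]
        if todo.size == 0:
            break

    # near-duplicates of the first n_linked_pairs base loci (>= 95% identity)
    dup_src = np.arange(model.n_linked_pairs)
    D0 = G0[:, dup_src].copy()
    D1 = G1[:, dup_src].copy()
    for D in (D0, D1):
        flip = rng.random(D.shape) < 0.03
        D[flip] = rng.integers(0, 3, int(flip.sum()), dtype=np.int8)

    # homeolog-like loci: every individual heterozygous in both populations
    H0 = np.ones((model.n_pop0, model.n_homeolog_like), dtype=np.int8)
    H1 = np.ones((model.n_pop1, model.n_homeolog_like), dtype=np.int8)

    G0 = np.concatenate([G0, D0, H0], axis=1)
    G1 = np.concatenate([G1, D1, H1], axis=1)
    f0 = np.concatenate([p0, p0[dup_src], np.full(model.n_homeolog_like, 0.5)])
    f1 = np.concatenate([p1, p1[dup_src], np.full(model.n_homeolog_like, 0.5)])

    # shuffle locus order so construction artefacts carry no positional signal
    order = rng.permutation(L)
    G0, G1, f0, f1 = G0[:, order], G1[:, order], f0[order], f1[order]
    kind = np.concatenate(
        [
            np.repeat("snp", n_base),
            np.repeat("dup", model.n_linked_pairs),
            np.repeat("homeolog", model.n_homeolog_like),
        ]
    )[order]
    # map duplicate -> source column index after shuffling
    inv = np.empty(L, dtype=int)
    inv[order] = np.arange(L)
    dup_of = np.full(L, -1)
    for j, src in enumerate(dup_src):
        dup_of[inv[n_base + j]] = inv[src]

    if model.missing_rate > 0:
        for G in (G0, G1):
            G[rng.random(G.shape) < model.missing_rate] = MISSING

    snp_pos = rng.integers(1, model.tag_length + 1, L)
    records = [
        LocusRecord(f"L{j:05d}", model.tag_length, int(snp_pos[j])) for j in range(L)
    ]
    loci = [r.locus_id for r in records]
    panel = ReferencePanel(
        GenotypeMatrix(G0, [f"pop0_{i:03d}" for i in range(model.n_pop0)], loci),
        GenotypeMatrix(G1, [f"pop1_{i:03d}" for i in range(model.n_pop1)], loci),
        records,
        true_freq0=f0,
        true_freq1=f1,
    )
    # stash construction truth for tests and filter diagnostics
    panel.locus_kind = kind  # type: ignore[attr-defined]
    panel.duplicate_of = dup_of  # type: ignore[attr-defined]
    return panel, records


def simulate_cohort(
    freqs0: np.ndarray,
    freqs1: np.ndarray,
    class_counts: dict[str, int],
    missing_rate: float = 0.0,
    seed: int | None = 0,
    loci: list[str] | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Simulate a mixed-class cohort with known true labels.

    Individuals of each class are produced by Mendelian pedigree crossing
    (:func:`hybridpanel.crosses.simulate_class_individuals`) at the supplied
    reference allele frequencies; missing calls are then inserted uniformly
    at ``missing_rate``. Returns the cohort genotype matrix and the true
    class label of every individual, in matrix row order.
    """
    unknown = set(class_counts) - set(crosses.CLASSES)
    if unknown:
        raise KeyError(f"unknown class name(s): {sorted(unknown)}")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    blocks: list[np.ndarray] = []
    inds: list[str] = []
    labels: list[str] = []
    for name in crosses.CLASSES:
        n = int(class_counts.get(name, 0))
        if n == 0:
            continue
        gm = crosses.simulate_class_individuals(
            name, n, freqs0, freqs1, seed=rng, loci=loci
        )
        blocks.append(gm.genotypes)
        inds.extend(gm.individuals)
        labels.extend([name] * n)
        used_loci = gm.loci
    if not blocks:
        raise ValueError("class_counts must request at least one individual")

    geno = np.concatenate(blocks, axis=0)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = MISSING
    return GenotypeMatrix(geno, inds, used_loci), labels
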