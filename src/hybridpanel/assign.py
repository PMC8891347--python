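"""Bayesian genotype-frequency-class assignment.

Each individual is assigned to one of six classes (pure0, pure1, F1, F2,
BC0, BC1). Under the class model, the two gene copies at a locus originate
from (pop0,pop0), (pop0,pop1) or (pop1,pop1) with class-specific
probabilities phi, and each copy is an independent draw from its origin
population's allele frequency. The per-locus genotype probabilities are
therefore a phi-weighted mixture over origins, and loci multiply
independently (unlinked panel).

Two modes are provided:

* :func:`assign_plugin` — deterministic plug-in posterior using smoothed
  point estimates of the reference allele frequencies.
* :func:`assign_gibbs` — Gibbs sampler that integrates over reference
  allele-frequency uncertainty (Beta posteriors from the reference
  genotypes) and the cohort mixture proportions (Dirichlet(1,...,1) prior,
  updated from test individuals only; reference individuals inform
  frequencies but are not mixture members, mirroring known-genotype
  reference flags in class-assignment software).

Missing genotypes are marginalised by omission (likelihood factor 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .crosses import CLASSES, PHI
from .datatypes import GenotypeMatrix, ReferencePanel

__all__ = [
    "ReferenceFrequencies",
    "estimate_reference_frequencies",
    "class_genotype_prob",
    "genotype_log_prob_table",
    "assign_plugin",
    "assign_gibbs",
]

_POSTERIOR_COLS = [f"P_{c}" for c in CLASSES]


@dataclass
class ReferenceFrequencies:
    """Smoothed per-locus alternate-allele frequencies of the two references.

    Frequencies are strictly inside (0, 1) after pseudocount smoothing so no
    class can be annihilated by a single genotype at a locus fixed in a
    reference sample. ``uninformative`` flags loci where a reference
    population had no called genotypes (frequency falls back to 0.5).
    """

    p0: np.ndarray
    p1: np.ndarray
    loci: list[str]
    pseudocount: float
    uninformative: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(self.p0 > 0) and np.all(self.p0 < 1)):
            raise ValueError("p0 must be strictly inside (0, 1)")
        if not (np.all(self.p1 > 0) and np.all(self.p1 < 1)):
            raise ValueError("p1 must be strictly inside (0, 1)")


def _alt_counts(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = G >= 0
    return np.where(called, G, 0).sum(axis=0), called.sum(axis=0)


def estimate_reference_frequencies(
    ref_panel: ReferencePanel, pseudocount: float = 0.5
) -> ReferenceFrequencies:
    """Smoothed allele-frequency estimates from the reference panel.

    ``freq = (alt_count + pseudocount) / (2 n_called + 2 pseudocount)`` per
    population (pseudocount 0.5 is a Jeffreys-style default). A locus with
    zero called genotypes in a population gets frequency 0.5 and is flagged
    uninformative.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    out = []
    flags = []
    for gm in (ref_panel.pop0, ref_panel.pop1):
        alt, n = _alt_counts(gm.genotypes)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = (alt + pseudocount) / (2 * n + 2 * pseudocount)
        empty = n == 0
        p = np.where(empty, 0.5, p)
        if pseudocount == 0:
            # unsmoothed estimates may hit 0/1; nudge to the open interval
            p = np.clip(p, 1e-12, 1 - 1e-12)
        out.append(p)
        flags.append(empty)
    return ReferenceFrequencies(
        out[0], out[1], list(ref_panel.loci), pseudocount, flags[0] | flags[1]
    )


def class_genotype_prob(phi, p0, p1) -> np.ndarray:
    """Genotype probability triple(s) P(g = 0, 1, 2) for one class.

    ``phi`` is the (phi00, phi01, phi11) origin-pair distribution; ``p0`` and
    ``p1`` are alternate-allele frequencies (scalars or equal-length arrays).
    Returns an array of shape ``(..., 3)`` summing to 1 along the last axis.
    """
    f00, f01, f11 = phi
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    q0, q1 = 1 - p0, 1 - p1
    g2 = f00 * p0**2 + f01 * p0 * p1 + f11 * p1**2
    g1 = f00 * 2 * p0 * q0 + f01 * (p0 * q1 + p1 * q0) + f11 * 2 * p1 * q1
    g0 = f00 * q0**2 + f01 * q0 * q1 + f11 * q1**2
    return np.stack([g0, g1, g2], axis=-1)


def genotype_log_prob_table(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Log genotype probabilities, shape ``(n_classes, n_loci, 3)``."""
    probs = np.stack([class_genotype_prob(PHI[c], p0, p1) for c in CLASSES])
    return np.log(np.clip(probs, 1e-300, None))


def _loglik_matrix(G: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Per-individual per-class log-likelihood (missing loci skipped)."""
    miss = G < 0
    Gsafe = np.where(miss, 0, G)
    # (L, 3, C) lookup -> (N, L, C)
    lut = table.transpose(1, 2, 0)
    contrib = lut[np.arange(G.shape[1])[None, :], Gsafe]
    contrib[miss] = 0.0
    return contrib.sum(axis=1)


def _results_frame(
    post: np.ndarray, individuals: list[str], loci_used: np.ndarray, ties: np.ndarray
) -> pd.DataFrame:
    best = post.argmax(axis=1)
    df = pd.DataFrame(post, columns=_POSTERIOR_COLS)
    df.insert(0, "individual", individuals)
    df["assigned_class"] = [CLASSES[b] for b in best]
    df["max_posterior"] = post.max(axis=1)
    df["loci_used"] = loci_used
    df["tie"] = ties
    return df


def assign_plugin(
    genotypes: GenotypeMatrix,
    ref_freqs: ReferenceFrequencies,
    prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Deterministic plug-in class posteriors.

    Per individual: ``log L(class) = sum over called loci of the log class
    genotype probability``; posteriors are ``prior x likelihood`` normalised
    in log space. The class prior defaults to uniform. Ties in the maximum
    posterior are flagged and broken by the fixed class order
    ``pure0, pure1, F1, F2, BC0, BC1``. An individual with zero called loci
    receives the (normalised) prior and a tie flag.

    Returns a DataFrame with one row per individual: six posterior columns,
    assigned class, max posterior, number of loci used, tie flag.
    """
    if genotypes.loci != ref_freqs.loci:
        raise ValueError("cohort loci are not aligned to the reference frequencies")
    prior = np.full(6, 1 / 6) if prior is None else np.asarray(prior, dtype=float)
    if prior.shape != (6,) or np.any(prior < 0) or prior.sum() == 0:
        raise ValueError("prior must be 6 nonnegative weights")

    table = genotype_log_prob_table(ref_freqs.p0, ref_freqs.p1)
    ll = _loglik_matrix(genotypes.genotypes, table)
    logpost = ll + np.log(prior / prior.sum())
    post = np.exp(logpost - logsumexp(logpost, axis=1, keepdims=True))

    loci_used = (genotypes.genotypes >= 0).sum(axis=1)
    top = np.sort(post, axis=1)[:, -2:]
    ties = (top[:, 1] - top[:, 0] <= 1e-12) | (loci_used == 0)
    return _results_frame(post, genotypes.individuals, loci_used, ties)


def assign_gibbs(
    genotypes: GenotypeMatrix,
    ref_panel: ReferencePanel,
    n_burnin: int = 10_000,
    n_sweeps: int = 50_000,
    seed: int | None = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Gibbs-sampling class posteriors.

    Sampled quantities per sweep: reference allele frequencies (Beta
    posteriors from reference genotype counts with a symmetric
    ``pseudocount`` prior), latent class labels for each test individual
    (categorical given the mixture weights and genotype likelihood), and the
    mixture proportions (Dirichlet(1,...,1) prior updated from the test
    individuals' labels). The reported posterior is the fraction of
    post-burn-in sweeps spent in each class. Reproducible given ``seed``.
    """
    if genotypes.loci != ref_panel.loci:
        raise ValueError("cohort loci are not aligned to the reference panel")
    rng = np.random.default_rng(seed)

    alt0, n0 = _alt_counts(ref_panel.pop0.genotypes)
    alt1, n1 = _alt_counts(ref_panel.pop1.genotypes)
    a0, b0 = alt0 + pseudocount, 2 * n0 - alt0 + pseudocount
    a1, b1 = alt1 + pseudocount, 2 * n1 - alt1 + pseudocount

    G = genotypes.genotypes
    N, L = G.shape
    miss = G < 0
    Gsafe = np.where(miss, 0, G)
    lidx = np.arange(L)[None, :]

    counts = np.zeros((N, 6))
    log_pi = np.full(6, np.log(1 / 6))
    eps = 1e-9
    for sweep in range(n_burnin + n_sweeps):
        p0 = np.clip(rng.beta(a0, b0), eps, 1 - eps)
        p1 = np.clip(rng.beta(a1, b1), eps, 1 - eps)
        table = genotype_log_prob_table(p0, p1)
        lut = table.transpose(1, 2, 0)
        contrib = lut[lidx, Gsafe]
        contrib[miss] = 0.0
        ll = contrib.sum(axis=1)  # (N, 6)

        logits = ll + log_pi
        gumbel = rng.gumbel(size=(N, 6))
        z = (logits + gumbel).argmax(axis=1)
        cnt = np.bincount(z, minlength=6)
        log_pi = np.log(rng.dirichlet(1 + cnt))
        if sweep >= n_burnin:
            counts[np.arange(N), z] += 1

    post = counts / n_sweeps
    loci_used = (~miss).sum(axis=1)
    top = np.sort(post, axis=1)[:, -2:]
    ties = (top[:, 1] - top[:, 0] <= 1e-12) | (loci_used == 0)
    return _results_frame(post, genotypes.individuals, loci_used, ties)
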