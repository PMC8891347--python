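"""Mendelian simulation of the six genotype-frequency classes.

The six classes are the generation-2 categories used in hybrid-class
assignment: the two pure parental forms, F1, F2 and the two first
backcrosses (F1 x pure). Each class is characterised by phi = (phi00,
phi01, phi11), the probability that a locus's two gene copies originate
(both from pop0, one from each, both from pop1). Loci are treated as
unlinked, which matches an LD-pruned SNP panel, so gametes segregate
independently per locus.
"""
from __future__ import annotations

import numpy as np

from .datatypes import GenotypeMatrix

#: Canonical class order; also the tie-break order used in assignment.
CLASSES: tuple[str, ...] = ("pure0", "pure1", "F1", "F2", "BC0", "BC1")

#: Human-readable aliases for the case-study system (pop0 = kokanee,
#: pop1 = sockeye; BC0/BC1 are the first backcrosses to each pure form).
CLASS_ALIASES: dict[str, str] = {
    "pure0": "kokanee",
    "pure1": "sockeye",
    "F1": "F1",
    "F2": "F2",
    "BC0": "B2_kokanee",
    "BC1": "B2_sockeye",
}

#: Probability that a gamete from a parent of the given class carries a
#: pop0-origin gene copy (parents of F2/BC crosses are F1 or pure).
_GAMETE_P0: dict[str, float] = {"pure0": 1.0, "pure1": 0.0, "F1": 0.5}

#: Parental pair producing each class.
PEDIGREE: dict[str, tuple[str, str]] = {
    "pure0": ("pure0", "pure0"),
    "pure1": ("pure1", "pure1"),
    "F1": ("pure0", "pure1"),
    "F2": ("F1", "F1"),
    "BC0": ("F1", "pure0"),
    "BC1": ("F1", "pure1"),
}

PHI: dict[str, tuple[float, float, float]] = {
    "pure0": (1.0, 0.0, 0.0),
    "pure1": (0.0, 0.0, 1.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC0": (0.5, 0.5, 0.0),
    "BC1": (0.0, 0.5, 0.5),
}


def class_phi(name: str) -> tuple[float, float, float]:
    """Ancestry-pair proportions (phi00, phi01, phi11) for a class.

    Equal to the outer product of the two parental gamete-origin
    distributions, marginalised to unordered origin pairs.
    """
    if name not in PHI:
        raise KeyError(f"unknown hybrid class {name!r}; expected one of {CLASSES}")
    return PHI[name]


def pedigree_phi(name: str) -> tuple[float, float, float]:
    """Derive phi from the pedigree's gamete-origin distributions."""
    mother, father = PEDIGREE[name]
    m0, f0 = _GAMETE_P0[mother], _GAMETE_P0[father]
    return (m0 * f0, m0 * (1 - f0) + (1 - m0) * f0, (1 - m0) * (1 - f0))


def simulate_class_individuals(
    name: str,
    n: int,
    freqs0: np.ndarray,
    freqs1: np.ndarray,
    seed: int | np.random.Generator | None = None,
    individual_prefix: str | None = None,
    loci: list[str] | None = None,
) -> GenotypeMatrix:
    """Simulate ``n`` individuals of one genotype-frequency class.

    Each individual receives two gametes per locus; each gamete's population
    of origin follows the parental gamete distribution for the class
    (explicit pedigree crossing: F1 = pure0 x pure1, F2 = F1 x F1, BC0 =
    F1 x pure0, BC1 = F1 x pure1), and its allele is drawn from the origin
    population's allele frequency (parents in Hardy-Weinberg proportions).
    Genotypes are alternate-allele counts; no missing data is introduced
    here.
    """
    if name not in PEDIGREE:
        raise KeyError(f"unknown hybrid class {name!r}; expected one of {CLASSES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    p0 = np.asarray(freqs0, dtype=float)
    p1 = np.asarray(freqs1, dtype=float)
    if p0.shape != p1.shape:
        raise ValueError("freqs0 and freqs1 must have equal length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = p0.size
    mother, father = PEDIGREE[name]
    geno = np.zeros((n, L), dtype=np.int8)
    for parent in (mother, father):
        origin0 = rng.random((n, L)) < _GAMETE_P0[parent]
        freq = np.where(origin0, p0[None, :], p1[None, :])
        geno += (rng.random((n, L)) < freq).astype(np.int8)

    prefix = individual_prefix or name
    inds = [f"{prefix}_{i:04d}" for i in range(n)]
    if loci is None:
        loci = [f"L{j:05d}" for j in range(L)]
    elif len(loci) != L:
        raise ValueError("loci list length must match frequency vectors")
    return GenotypeMatrix(geno, inds, list(loci))
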