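"""Core containers for diploid biallelic genotype data.

Genotypes are coded as alternate-allele counts (0, 1, 2); missing calls are
coded :data:`MISSING` (-1). All downstream statistics use pairwise deletion:
missing genotypes are excluded from every denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of diploid biallelic genotypes.

    Parameters
    ----------
    genotypes
        Integer array of shape ``(n_individuals, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}`` (alternate-allele counts).
    individuals
        Sample identifiers, one per row.
    loci
        Locus identifiers, one per column.
    """

    genotypes: np.ndarray
    individuals: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D array (individuals x loci)")
        codes = set(np.unique(g).tolist())
        if not codes <= _VALID_CODES:
            raise ValueError(f"invalid genotype codes: {sorted(codes - _VALID_CODES)}")
        self.genotypes = g.astype(np.int8, copy=False)
        self.individuals = list(self.individuals)
        self.loci = list(self.loci)
        if g.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"shape {g.shape} does not match {len(self.individuals)} "
                f"individuals x {len(self.loci)} loci"
            )
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicated locus ids")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``genotypes``."""
        return self.genotypes == MISSING

    def individual_missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        return self.missing_mask().mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def _locus_indices(self, locus_ids) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.loci)}
        try:
            return np.array([pos[l] for l in locus_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown locus id {e.args[0]!r}") from None

    def subset_loci(self, locus_ids) -> "GenotypeMatrix":
        idx = self._locus_indices(locus_ids)
        return GenotypeMatrix(self.genotypes[:, idx], self.individuals, list(locus_ids))

    def subset_individuals(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.genotypes[idx, :], [self.individuals[i] for i in idx], self.loci
        )

    def column(self, locus_id: str) -> np.ndarray:
        """Genotype vector for one locus."""
        return self.genotypes[:, self.loci.index(locus_id)]


@dataclass
class LocusRecord:
    """Identity and tag metadata for one SNP locus.

    ``snp_pos`` is the 1-based position of the SNP within its RAD tag of
    length ``tag_length`` base pairs; both are used by the flanking-sequence
    filter during panel design.
    """

    locus_id: str
    tag_length: int
    snp_pos: int
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self) -> None:
        if self.tag_length > 0 and not (1 <= self.snp_pos <= self.tag_length):
            raise ValueError(
                f"{self.locus_id}: snp_pos {self.snp_pos} outside [1, {self.tag_length}]"
            )


@dataclass
class ReferencePanel:
    """Two parental reference populations genotyped at a shared locus set."""

    pop0: GenotypeMatrix
    pop1: GenotypeMatrix
    records: list[LocusRecord] = field(default_factory=list)
    #: Simulated-truth allele frequencies (populated by the generator only).
    true_freq0: np.ndarray | None = None
    true_freq1: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pop0.loci != self.pop1.loci:
            raise ValueError("reference populations must share an identical locus list")
        if self.records and [r.locus_id for r in self.records] != self.pop0.loci:
            raise ValueError("records out of order with genotype loci")

    @property
    def loci(self) -> list[str]:
        return self.pop0.loci

    @property
    def n_loci(self) -> int:
        return self.pop0.n_loci

    def subset_loci(self, locus_ids) -> "ReferencePanel":
        idx = self.pop0._locus_indices(locus_ids)
        recs = [self.records[i] for i in idx] if self.records else []
        return ReferencePanel(
            self.pop0.subset_loci(locus_ids),
            self.pop1.subset_loci(locus_ids),
            recs,
            None if self.true_freq0 is None else self.true_freq0[idx],
            None if self.true_freq1 is None else self.true_freq1[idx],
        )
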