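"""Readers and writers for genotype matrices, locus metadata and results.

Supported formats:

* VCF v4.2 (1-based positions): biallelic SNP records only, missing calls
  as ``./.``, genotypes coded as alternate-allele counts. Read via cyvcf2;
  written as plain text.
* A simple TSV genotype dialect: rows = individuals, columns = loci, cells
  in ``{0, 1, 2, NA}``.
* A tab-separated locus-metadata sidecar (``locus_id, tag_length,
  snp_pos``).
* A NEWHYBRIDS-format exporter for cross-validation against the original
  assignment program (this package never shells out to it).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, LocusRecord, ReferencePanel

__all__ = [
    "read_genotypes",
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_locus_metadata",
    "write_locus_metadata",
    "write_reference_panel",
    "read_reference_panel",
    "write_newhybrids",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_genotypes(path, format: str | None = None) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    """Read a genotype matrix from VCF or TSV (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("tsv" if path.suffix in {".tsv", ".txt"} else "vcf")
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "tsv":
        gm = read_genotype_tsv(path)
        records = [LocusRecord(l, 0, 1) for l in gm.loci]
        return gm, records
    raise ValueError(f"unknown format {fmt!r}")


def read_vcf(path) -> tuple[GenotypeMatrix, list[LocusRecord]]:
    """Read biallelic SNP genotypes from a VCF file.

    Multi-allelic or non-SNP records are skipped (one summary warning);
    duplicated locus ids raise. Locus ids come from the ID column (falling
    back to ``CHROM:POS``); ``snp_pos`` is taken from POS. Tag lengths are
    not stored in VCF — merge them from the metadata sidecar.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    codes = []
    records: list[LocusRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        locus_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        if locus_id in seen:
            raise ValueError(f"duplicated locus id {locus_id!r}")
        seen.add(locus_id)
        gt = np.asarray(v.gt_types)
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        codes.append(col.astype(np.int8))
        records.append(LocusRecord(locus_id, 0, int(v.POS), v.REF, v.ALT[0]))
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP record(s)")
    if not records:
        raise ValueError(f"no biallelic SNP records in {path}")
    geno = np.stack(codes, axis=1)
    return GenotypeMatrix(geno, samples, [r.locus_id for r in records]), records


def write_vcf(gm: GenotypeMatrix, records: list[LocusRecord], path, stamp: str | None = None) -> None:
    """Write a genotype matrix as VCF v4.2 (CHROM = locus id, POS = SNP
    position within the tag, 1-based)."""
    if [r.locus_id for r in records] != gm.loci:
        raise ValueError("records do not match matrix loci")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridpanel\n")
        if stamp:
            fh.write(f"##hybridpanel_run={stamp}\n")
        for r in records:
            length = r.tag_length if r.tag_length > 0 else r.snp_pos
            fh.write(f"##contig=<ID={r.locus_id},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j, r in enumerate(records):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{r.locus_id}\t{r.snp_pos}\t{r.locus_id}\t{r.ref}\t{r.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotype_tsv(gm: GenotypeMatrix, path, stamp: str | None = None) -> None:
    cells = np.where(gm.genotypes == MISSING, "NA", gm.genotypes.astype(object))
    df = pd.DataFrame(cells, index=gm.individuals, columns=gm.loci)
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index_label="individual")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])
    geno = df.to_numpy(dtype=float)
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return GenotypeMatrix(geno, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_locus_metadata(records: list[LocusRecord], path, stamp: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "locus_id": [r.locus_id for r in records],
            "tag_length": [r.tag_length for r in records],
            "snp_pos": [r.snp_pos for r in records],
        }
    )
    with open(path, "w") as fh:
        if stamp:
            fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_locus_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#").set_index("locus_id")


def attach_metadata(records: list[LocusRecord], meta: pd.DataFrame) -> list[LocusRecord]:
    """Fill tag lengths / SNP positions from a metadata sidecar table."""
    out = []
    for r in records:
        if r.locus_id in meta.index:
            row = meta.loc[r.locus_id]
            out.append(
                LocusRecord(r.locus_id, int(row["tag_length"]), int(row["snp_pos"]), r.ref, r.alt)
            )
        else:
            out.append(r)
    return out


def write_reference_panel(panel: ReferencePanel, vcf_path, meta_path, popmap_path=None,
                          stamp: str | None = None) -> None:
    """Write a two-population reference panel: one VCF with all samples, the
    locus-metadata sidecar, and an optional sample->population map TSV."""
    merged = GenotypeMatrix(
        np.concatenate([panel.pop0.genotypes, panel.pop1.genotypes], axis=0),
        panel.pop0.individuals + panel.pop1.individuals,
        panel.loci,
    )
    write_vcf(merged, panel.records, vcf_path, stamp=stamp)
    write_locus_metadata(panel.records, meta_path, stamp=stamp)
    if popmap_path is not None:
        with open(popmap_path, "w") as fh:
            fh.write("individual\tpopulation\n")
            for ind in panel.pop0.individuals:
                fh.write(f"{ind}\tpop0\n")
            for ind in panel.pop1.individuals:
                fh.write(f"{ind}\tpop1\n")


def read_reference_panel(vcf_path, meta_path=None, popmap_path=None) -> ReferencePanel:
    """Read a reference panel written by :func:`write_reference_panel`."""
    gm, records = read_vcf(vcf_path)
    if meta_path is not None:
        records = attach_metadata(records, read_locus_metadata(meta_path))
    if popmap_path is not None:
        popmap = pd.read_csv(popmap_path, sep="\t").set_index("individual")["population"]
        pops = [popmap[ind] for ind in gm.individuals]
    else:
        pops = ["pop0" if ind.startswith("pop0") else "pop1" for ind in gm.individuals]
    idx0 = [i for i, p in enumerate(pops) if p == "pop0"]
    idx1 = [i for i, p in enumerate(pops) if p == "pop1"]
    return ReferencePanel(gm.subset_individuals(idx0), gm.subset_individuals(idx1), records)


def write_newhybrids(
    test: GenotypeMatrix,
    ref_pop0: GenotypeMatrix | None,
    ref_pop1: GenotypeMatrix | None,
    path,
) -> None:
    """Export genotypes in NEWHYBRIDS input format (Lumped, 1-digit alleles).

    Reference individuals, when given, are appended after the test
    individuals with ``z0``/``z1`` known-origin flags so the original
    program can reproduce the known-genotype reference semantics used here.
    """
    blocks: list[tuple[GenotypeMatrix, str | None]] = [(test, None)]
    if ref_pop0 is not None:
        blocks.append((ref_pop0, "z0"))
    if ref_pop1 is not None:
        blocks.append((ref_pop1, "z1"))
    n_total = sum(b.n_individuals for b, _ in blocks)

    code = {0: "11", 1: "12", 2: "22", MISSING: "0"}
    with open(path, "w") as fh:
        fh.write(f"NumIndivs {n_total}\n")
        fh.write(f"NumLoci {test.n_loci}\n")
        fh.write("Digits 1\nFormat Lumped\n\n")
        fh.write("LocusNames " + " ".join(test.loci) + "\n\n")
        idx = 1
        for gm, zflag in blocks:
            if gm.loci != test.loci:
                raise ValueError("all blocks must share the test locus list")
            for i in range(gm.n_individuals):
                fields = [str(idx)]
                if zflag:
                    fields.append(zflag)
                fields.extend(code[int(g)] for g in gm.genotypes[i])
                fh.write(" ".join(fields) + "\n")
                idx += 1
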