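"""Readers and writers for the pipeline's external formats.

Genotypes are read from VCF (biallelic SNPs only) or a simple TSV dialect
with header ``snp_id  chrom  pos  ref  alt  <sample...>`` and calls coded
0/1/NA. Heterozygous VCF calls are converted to missing — the accession
panels this pipeline targets are inbred lines — and the number of such
conversions is logged. Annotation comes from GFF3 (``gene`` records, ID
attribute) or BED (0-based half-open, converted to 1-based inclusive on
input). Phenotypes are CSV replicate tables of paired control/treatment
fresh masses in mg.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    PHENOTYPE_COLUMNS,
    AssociationResult,
    GeneAnnotation,
    GenotypeDataset,
    PeakGene,
    PeakRegion,
    PhenotypeTable,
)
from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_TSV_FIXED = ["snp_id", "chrom", "pos", "ref", "alt"]


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str | None = None) -> GenotypeDataset:
    """Read a genotype matrix from ``vcf`` or ``tsv`` (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeDataset:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_FIXED)] != _TSV_FIXED:
            raise ParseError(
                f"expected header starting with {_TSV_FIXED}, got {header[:5]}", line=1
            )
        samples = header[len(_TSV_FIXED):]
        if not samples:
            raise ParseError("no sample columns", line=1)
        snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"expected {len(header)} fields, got {len(parts)}", line=lineno
                )
            snp_ids.append(parts[0])
            chroms.append(parts[1])
            try:
                poss.append(int(parts[2]))
            except ValueError:
                raise ParseError(f"position not an integer: {parts[2]!r}", line=lineno)
            refs.append(parts[3])
            alts.append(parts[4])
            row = np.empty(len(samples), dtype=np.int8)
            for j, v in enumerate(parts[5:]):
                if v == "0":
                    row[j] = 0
                elif v == "1":
                    row[j] = 1
                elif v in ("NA", "", "."):
                    row[j] = MISSING
                else:
                    raise ParseError(f"bad call {v!r} (expected 0/1/NA)", line=lineno)
            rows.append(row)
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeDataset.create(samples, snp_ids, chroms, poss, refs, alts, calls)


def _read_genotypes_vcf(path: Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_het = 0
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValidationError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={var.ALT}); only biallelic SNPs are supported"
            )
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types)
        row = np.full(len(samples), MISSING, dtype=np.int8)
        row[gt == 0] = 0
        row[gt == 2] = 1
        n_het += int((gt == 1).sum())
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(row)
    if n_het:
        logger.warning(
            "converted %d heterozygous calls to missing (inbred-line convention)", n_het
        )
    calls = np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int8)
    ds = GenotypeDataset.create(samples, snp_ids, chroms, poss, refs, alts, calls)
    return ds


def write_genotypes_tsv(ds: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIXED + list(ds.sample_ids)) + "\n")
        for j in range(ds.n_snps):
            vals = [
                "NA" if c == MISSING else str(int(c)) for c in ds.calls[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        str(ds.snp_ids[j]),
                        str(ds.chrom[j]),
                        str(ds.pos[j]),
                        str(ds.ref[j]),
                        str(ds.alt[j]),
                    ]
                    + vals
                )
                + "\n"
            )


def write_genotypes_vcf(ds: GenotypeDataset, path, chrom_lengths: dict | None = None) -> None:
    """Write a minimal VCF 4.2 with homozygous GT calls (0/0, 1/1, ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mampscan\n")
        if chrom_lengths:
            for c, ln in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        code = {0: "0/0", 1: "1/1", MISSING: "./."}
        for j in range(ds.n_snps):
            gts = "\t".join(code[int(c)] for c in ds.calls[:, j])
            fh.write(
                f"{ds.chrom[j]}\t{ds.pos[j]}\t{ds.snp_ids[j]}\t{ds.ref[j]}\t"
                f"{ds.alt[j]}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path, format: str | None = None) -> GeneAnnotation:
    """Read gene intervals from ``gff3`` or ``bed``."""
    path = Path(path)
    if format is None:
        format = "bed" if path.suffix == ".bed" else "gff3"
    if format == "gff3":
        return _read_annotation_gff3(path)
    if format == "bed":
        return _read_annotation_bed(path)
    raise ValueError(f"unknown annotation format: {format!r}")


def _read_annotation_gff3(path: Path) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", from_string=False,
    )
    ids, chroms, starts, ends, strands = [], [], [], [], []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [None])[0]
        if gid is None:
            raise ValidationError(
                f"gene without ID attribute at {feat.seqid}:{feat.start}-{feat.end}"
            )
        ids.append(gid)
        chroms.append(feat.seqid)
        starts.append(feat.start)
        ends.append(feat.end)
        strands.append(feat.strand if feat.strand in "+-" else "unknown")
    return GeneAnnotation.create(ids, chroms, starts, ends, strands)


def _read_annotation_bed(path: Path) -> GeneAnnotation:
    ids, chroms, starts, ends, strands = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split()
            if len(parts) < 4:
                raise ParseError("BED line needs >= 4 fields (chrom start end name)", lineno)
            chroms.append(parts[0])
            # BED is 0-based half-open; internal coordinates 1-based inclusive
            starts.append(int(parts[1]) + 1)
            ends.append(int(parts[2]))
            ids.append(parts[3])
            strands.append(parts[5] if len(parts) > 5 and parts[5] in "+-" else "unknown")
    return GeneAnnotation.create(ids, chroms, starts, ends, strands)


def write_annotation_gff3(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(ann.n_genes):
            strand = ann.strand[i] if ann.strand[i] in "+-" else "."
            fh.write(
                f"{ann.chrom[i]}\tmampscan\tgene\t{ann.start[i]}\t{ann.end[i]}\t.\t"
                f"{strand}\t.\tID={ann.gene_id[i]}\n"
            )


def write_annotation_bed(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for i in range(ann.n_genes):
            fh.write(
                f"{ann.chrom[i]}\t{ann.start[i] - 1}\t{ann.end[i]}\t{ann.gene_id[i]}\n"
            )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"phenotype CSV missing columns: {sorted(missing)}", line=1)
    return PhenotypeTable.create(df)


def write_phenotypes(tbl: PhenotypeTable, path) -> None:
    tbl.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results

ASSOC_COLUMNS = ["snp_id", "chrom", "pos", "maf", "rare_flag", "beta", "se", "stat", "p", "n_used"]


def write_association_tsv(res: AssociationResult, path) -> None:
    res.table.loc[:, ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_association_tsv(path, trait: str | None = None) -> AssociationResult:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"association TSV missing columns: {sorted(missing)}", line=1)
    return AssociationResult(table=df, trait=trait)


def write_peaks_tsv(peaks: list[PeakRegion], path) -> None:
    rows = [
        {
            "trait": p.trait,
            "peak_index": i,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "apex_snp": p.apex_snp,
            "apex_pos": p.apex_pos,
            "apex_p": p.apex_p,
            "n_members": len(p.members),
            "members": ",".join(p.members),
        }
        for i, p in enumerate(peaks)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peaks_tsv(path) -> list[PeakRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "members": str})
    peaks = []
    for _, r in df.iterrows():
        members = [] if pd.isna(r["members"]) or r["members"] == "" else str(r["members"]).split(",")
        peaks.append(
            PeakRegion(
                trait=r["trait"],
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                apex_snp=str(r["apex_snp"]),
                apex_pos=int(r["apex_pos"]),
                apex_p=float(r["apex_p"]),
                members=members,
            )
        )
    return peaks


def write_peaks_bed(peaks: list[PeakRegion], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.trait}_peak{i}\n")


def write_peak_genes_tsv(peak_genes: list[PeakGene], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "trait": g.trait,
            "peak_index": g.peak_index,
            "distance": g.distance,
            "apex_p": g.apex_p,
        }
        for g in peak_genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """Plain-text gene list, one id per line; '#' comments allowed."""
    out = set()
    with open(path) as fh:
        for raw in fh:
            name = raw.split("#", 1)[0].strip()
            if name:
                out.add(name)
    return out
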