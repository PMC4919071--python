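"""Core in-memory containers for the pipeline.

Genotypes follow the inbred-line convention: accessions are homozygous, so a
call is a single allele count in {0, 1} (0 = reference, 1 = alternate) with an
explicit missing sentinel. Coordinates are 1-based inclusive throughout
(GFF convention); BED input is converted at the boundary. Chromosome labels
are matched by exact string equality — no "chr" prefix normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Sentinel for a missing genotype call.
MISSING: int = -1

MAMP_CLASSES = ("elf18", "flg22")


@dataclass
class GenotypeDataset:
    """Sample x SNP allele-count matrix with a physical map.

    ``calls`` has shape (n_samples, n_snps) with entries in {0, 1, MISSING}.
    SNPs are sorted by (chrom, pos) at construction time; duplicate
    (chrom, pos) pairs are rejected.
    """

    sample_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    #: Optional per-sample group labels (e.g. simulated subpopulations).
    sample_groups: np.ndarray | None = None

    @classmethod
    def create(
        cls,
        sample_ids,
        snp_ids,
        chrom,
        pos,
        ref,
        alt,
        calls,
        sample_groups=None,
    ) -> "GenotypeDataset":
        """Validate, sort by (chrom, pos) and build a dataset."""
        snp_ids = np.asarray(snp_ids, dtype=object)
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        ref = np.asarray(ref, dtype=object)
        alt = np.asarray(alt, dtype=object)
        calls = np.asarray(calls, dtype=np.int8)
        sample_ids = list(sample_ids)
        if calls.shape != (len(sample_ids), len(snp_ids)):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(sample_ids)} samples x {len(snp_ids)} SNPs"
            )
        ok = np.isin(calls, (0, 1, MISSING))
        if not ok.all():
            bad = np.unique(calls[~ok])
            raise ValidationError(f"calls contain values outside {{0,1,{MISSING}}}: {bad}")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        key = pd.MultiIndex.from_arrays([chrom, pos])
        if key.duplicated().any():
            dup = key[key.duplicated()][0]
            raise ValidationError(f"duplicate (chrom, pos) pair: {dup}")
        order = np.lexsort((pos, chrom))
        if sample_groups is not None:
            sample_groups = np.asarray(sample_groups)
        return cls(
            sample_ids=sample_ids,
            snp_ids=snp_ids[order],
            chrom=chrom[order],
            pos=pos[order],
            ref=ref[order],
            alt=alt[order],
            calls=np.ascontiguousarray(calls[:, order]),
            sample_groups=sample_groups,
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        """Return a dataset restricted to the SNPs where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            calls=np.ascontiguousarray(self.calls[:, mask]),
            sample_groups=self.sample_groups,
        )


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, with unique ids."""

    gene_id: np.ndarray
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray

    @classmethod
    def create(cls, gene_id, chrom, start, end, strand=None) -> "GeneAnnotation":
        gene_id = np.asarray(gene_id, dtype=object)
        chrom = np.asarray(chrom, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if strand is None:
            strand = np.full(len(gene_id), "unknown", dtype=object)
        strand = np.asarray(strand, dtype=object)
        if len(np.unique(gene_id)) != len(gene_id):
            ids, counts = np.unique(gene_id, return_counts=True)
            raise ValidationError(f"duplicate gene ids: {ids[counts > 1][:5]}")
        if (start > end).any():
            bad = gene_id[start > end][0]
            raise ValidationError(f"gene {bad}: start > end")
        if (start < 1).any():
            raise ValidationError("gene start < 1 (coordinates are 1-based)")
        order = np.lexsort((start, chrom))
        return cls(gene_id[order], chrom[order], start[order], end[order], strand[order])

    @property
    def n_genes(self) -> int:
        return len(self.gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "strand": self.strand,
            }
        )


PHENOTYPE_COLUMNS = [
    "genotype_id",
    "mamp_id",
    "mamp_class",
    "replicate",
    "control_mass_mg",
    "treated_mass_mg",
]


@dataclass
class PhenotypeTable:
    """Paired control/treatment fresh-mass replicates.

    One row per (genotype, MAMP variant, replicate pair); masses in mg.
    """

    records: pd.DataFrame

    @classmethod
    def create(cls, records: pd.DataFrame) -> "PhenotypeTable":
        df = records.loc[:, PHENOTYPE_COLUMNS].copy()
        df["replicate"] = df["replicate"].astype(int)
        df["control_mass_mg"] = df["control_mass_mg"].astype(float)
        df["treated_mass_mg"] = df["treated_mass_mg"].astype(float)
        bad_class = ~df["mamp_class"].isin(MAMP_CLASSES)
        if bad_class.any():
            raise ValidationError(
                f"unknown mamp_class: {sorted(df.loc[bad_class, 'mamp_class'].unique())}"
            )
        if (df["control_mass_mg"] <= 0).any():
            raise ValidationError("control_mass_mg must be > 0 (SGI undefined otherwise)")
        if (df["treated_mass_mg"] < 0).any():
            raise ValidationError("treated_mass_mg must be >= 0")
        key = ["genotype_id", "mamp_id", "replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(f"duplicate (genotype, mamp, replicate): {first}")
        classes = df.groupby("mamp_id")["mamp_class"].nunique()
        if (classes > 1).any():
            raise ValidationError("a mamp_id maps to more than one mamp_class")
        return cls(df.reset_index(drop=True))

    @property
    def mamp_class_of(self) -> dict[str, str]:
        return dict(
            self.records.drop_duplicates("mamp_id")[["mamp_id", "mamp_class"]].values
        )


@dataclass
class SGITable:
    """Genotype x MAMP matrix of mean seedling growth inhibition (percent).

    ``means`` and ``counts`` are DataFrames indexed by genotype with one
    column per MAMP variant; cells with fewer than ``min_replicates``
    replicate pairs are unusable (NaN in ``means``). ``insensitive`` is
    genotype x class with values True/False/NaN (NaN: no usable variant).
    """

    means: pd.DataFrame
    counts: pd.DataFrame
    mamp_class: dict[str, str]
    insensitive: pd.DataFrame
    min_replicates: int = 3

    @property
    def genotypes(self) -> list[str]:
        return list(self.means.index)

    def class_columns(self, mamp_class: str) -> list[str]:
        return [m for m in self.means.columns if self.mamp_class[m] == mamp_class]

    def trait(self, mamp_id: str) -> pd.Series:
        """Usable genotype-mean SGI for one MAMP variant (NaN dropped)."""
        return self.means[mamp_id].dropna()


@dataclass
class VarianceComponents:
    """REML fit of y = mu + u + e with u ~ (0, sA2 K), e ~ (0, sE2 I)."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    loglik: float
    delta: float
    unidentifiable: bool = False
    #: (eigenvalues, squared rotated phenotype) backing the delta profile
    profile: tuple | None = None


@dataclass
class AssociationResult:
    """Per-SNP mixed-model scan results (one row per SNP passing MAF filter)."""

    table: pd.DataFrame  # snp_id, chrom, pos, maf, rare_flag, beta, se, stat, p, n_used
    trait: str | None = None
    method: str = "emmax"
    kinship_method: str | None = None

    @property
    def n_snps(self) -> int:
        return len(self.table)


@dataclass
class PeakRegion:
    """Apex-centred window over the 0.1% tail SNPs of one trait."""

    trait: str
    chrom: str
    start: int
    end: int
    apex_snp: str
    apex_pos: int
    apex_p: float
    members: list[str] = field(default_factory=list)


@dataclass
class PeakGene:
    """A gene co-localising with a peak region."""

    gene_id: str
    trait: str
    peak_index: int
    distance: int
    apex_p: float


@dataclass
class ResamplingResult:
    """Observed statistic plus its permutation distribution."""

    observed: float
    permuted: np.ndarray
    empirical_p: float
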