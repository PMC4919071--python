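"""Tail selection, peak clumping and gene co-localisation.

SNPs in the 0.1% tail of ranked association p-values are clustered into
peak regions: repeatedly take the unassigned tail SNP with the smallest
p-value as an apex and absorb every unassigned tail SNP within 15 kb on the
same chromosome. Regions extend 15 kb to either side of the apex (clipped
to the chromosome) and may overlap without merging; memberships stay
disjoint. Genes intersecting a region are candidates, reported with the
signed gap between apex SNP and gene body (0 when the apex lies inside the
gene; positive when the apex is left of the gene start; negative when it is
right of the gene end).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .datatypes import AssociationResult, GeneAnnotation, PeakGene, PeakRegion
from .errors import ConfigError, ValidationError

PEAK_HALF_WIDTH = 15_000
TAIL_FRACTION = 0.001


def round_half_up(x: float) -> int:
    """Round with .5 going away from zero (school rounding)."""
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def select_tail(
    assoc: AssociationResult, fraction: float = TAIL_FRACTION
) -> tuple[pd.DataFrame, float]:
    """The floor(n * fraction) smallest-p SNPs, ties broken by (chrom, pos).

    Returns the tail rows and the threshold p (largest selected p-value).
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigError(f"tail fraction must be in (0, 1), got {fraction}")
    n = assoc.n_snps
    k = math.floor(n * fraction)
    if k < 1:
        raise ConfigError(f"{n} SNPs with fraction {fraction} selects an empty tail")
    df = assoc.table.sort_values(["p", "chrom", "pos"], kind="mergesort")
    tail = df.head(k).copy()
    return tail, float(tail["p"].max())


def cluster_peaks(
    tail: pd.DataFrame,
    chrom_lengths: dict[str, int],
    trait: str = "",
    half_width: int = PEAK_HALF_WIDTH,
) -> list[PeakRegion]:
    """Greedy apex-first clumping of tail SNPs into peak regions."""
    if len(tail) == 0:
        raise ValidationError("tail is empty")
    df = tail.reset_index(drop=True)
    for _, row in df.iterrows():
        length = chrom_lengths.get(str(row["chrom"]))
        if length is None:
            raise ValidationError(f"chromosome {row['chrom']} has no length")
        if row["pos"] > length:
            raise ValidationError(
                f"SNP {row['snp_id']} at {row['chrom']}:{row['pos']} beyond "
                f"chromosome length {length}"
            )
    order = df.sort_values(["p", "chrom", "pos"], kind="mergesort").index.to_numpy()
    assigned = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy()
    peaks: list[PeakRegion] = []
    for i in order:
        if assigned[i]:
            continue
        apex_chrom, apex_pos = chrom[i], int(pos[i])
        members = np.flatnonzero(
            ~assigned & (chrom == apex_chrom) & (np.abs(pos - apex_pos) <= half_width)
        )
        assigned[members] = True
        peaks.append(
            PeakRegion(
                trait=trait,
                chrom=apex_chrom,
                start=max(1, apex_pos - half_width),
                end=min(int(chrom_lengths[apex_chrom]), apex_pos + half_width),
                apex_snp=str(df.loc[i, "snp_id"]),
                apex_pos=apex_pos,
                apex_p=float(df.loc[i, "p"]),
                members=[str(s) for s in df.loc[members, "snp_id"]],
            )
        )
    return peaks


def signed_distance(apex_pos: int, gene_start: int, gene_end: int) -> int:
    """Gap in bp between apex SNP and gene body; 0 when the apex is inside."""
    if gene_start <= apex_pos <= gene_end:
        return 0
    if apex_pos < gene_start:
        return gene_start - apex_pos
    return -(apex_pos - gene_end)


def map_genes_to_peaks(
    peaks: list[PeakRegion], annotation: GeneAnnotation
) -> list[PeakGene]:
    """Genes whose bodies intersect a peak region.

    Within each trait, a gene hit by several peaks is reported once with
    the smallest apex p-value.
    """
    best: dict[tuple[str, str], PeakGene] = {}
    starts, ends = annotation.start, annotation.end
    for idx, peak in enumerate(peaks):
        on = (
            (annotation.chrom == peak.chrom)
            & (starts <= peak.end)
            & (ends >= peak.start)
        )
        for g in np.flatnonzero(on):
            gid = str(annotation.gene_id[g])
            cand = PeakGene(
                gene_id=gid,
                trait=peak.trait,
                peak_index=idx,
                distance=signed_distance(peak.apex_pos, int(starts[g]), int(ends[g])),
                apex_p=peak.apex_p,
            )
            key = (peak.trait, gid)
            if key not in best or cand.apex_p < best[key].apex_p:
                best[key] = cand
    return sorted(best.values(), key=lambda g: (g.trait, g.peak_index, g.gene_id))


def genes_near_gene(
    annotation: GeneAnnotation, gene_id: str, half_width: int = PEAK_HALF_WIDTH
) -> tuple[int, int, str]:
    """Window anchored on a gene's boundaries extended by ``half_width``.

    Convenience for gene-anchored lookups (e.g. which SNPs fall within
    15 kb of a receptor gene); returns (start, end, chrom), start clipped
    at 1.
    """
    hit = np.flatnonzero(annotation.gene_id == gene_id)
    if hit.size == 0:
        raise ValidationError(f"gene {gene_id} not in annotation")
    g = hit[0]
    return (
        max(1, int(annotation.start[g]) - half_width),
        int(annotation.end[g]) + half_width,
        str(annotation.chrom[g]),
    )
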