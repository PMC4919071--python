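"""Permutation analyses and mutant-validation statistics.

Three resampling procedures:

* **A priori enrichment** — the fraction of genes under a trait's peak
  regions that belong to a literature-curated candidate list, compared
  against a circular-shift null: all peak windows on a chromosome are slid
  by one random offset with wrap-around, preserving peak count and spacing
  (and hence the local gene-density structure the windows sample).
* **Shared-peak overlap** — the number of 30 kb peak regions two traits
  have in common, compared against re-running the full scan -> tail ->
  clump pipeline on phenotypes shuffled across genotypes.
* **Mutant validation** — two-sided Wilcoxon rank-sum tests of mutant vs
  wild-type SGI replicates with Benjamini-Hochberg FDR across the batch;
  a gene is confirmed at q <= 0.05.

Empirical p-values are r/n (the count of permutations reaching the
observed statistic over the number of permutations), so zero is attainable;
the (r+1)/(n+1) variant is available via ``add_one=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneAnnotation, GenotypeDataset, PeakRegion, SGITable
from .errors import ConfigError, ValidationError
from . import mixed_model, peaks as peaks_mod

logger = logging.getLogger(__name__)

SHARED_REGION_SIZE = 30_000
DEFAULT_N_PERM = 100


# ---------------------------------------------------------------------------
# a priori candidate enrichment


@dataclass
class EnrichmentResult:
    trait: str
    n_peaks: int
    n_genes: int
    n_apriori: int
    frequency: float
    permuted: np.ndarray
    empirical_p: float


def apriori_frequency(peak_genes: set[str], apriori: set[str]) -> tuple[int, int, float]:
    """(n found, n genes, frequency) of a priori candidates among peak genes."""
    n_genes = len(peak_genes)
    n_found = len(peak_genes & apriori)
    if n_genes == 0:
        logger.warning("empty peak gene set; frequency reported as 0")
        return 0, 0, 0.0
    return n_found, n_genes, n_found / n_genes


def circular_shift_peaks(
    peaks: list[PeakRegion],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    offsets: dict[str, int] | None = None,
) -> list[tuple[str, list[tuple[int, int]]]]:
    """Slide every peak window by one random per-chromosome offset, wrapping.

    A window straddling the chromosome end splits into two sub-intervals.
    Returns one (chrom, [(start, end), ...]) entry per input peak; peak
    count and within-chromosome spacing (mod length) are preserved.
    ``offsets`` overrides the random draw (for testing).
    """
    if offsets is None:
        offsets = {
            c: int(rng.integers(0, length)) for c, length in chrom_lengths.items()
        }
    out = []
    for p in peaks:
        length = int(chrom_lengths[p.chrom])
        d = offsets[p.chrom] % length
        s = (p.start - 1 + d) % length + 1
        e = (p.end - 1 + d) % length + 1
        if s <= e:
            out.append((p.chrom, [(s, e)]))
        else:
            out.append((p.chrom, [(s, length), (1, e)]))
    return out


def _genes_in_intervals(
    intervals: list[tuple[str, list[tuple[int, int]]]], annotation: GeneAnnotation
) -> set[str]:
    hit = np.zeros(annotation.n_genes, dtype=bool)
    for chrom, parts in intervals:
        on_chrom = annotation.chrom == chrom
        for s, e in parts:
            hit |= on_chrom & (annotation.start <= e) & (annotation.end >= s)
    return set(annotation.gene_id[hit])


def genes_under_peaks(peaks: list[PeakRegion], annotation: GeneAnnotation) -> set[str]:
    """Deduplicated gene set intersecting any of the peak windows."""
    return _genes_in_intervals(
        [(p.chrom, [(p.start, p.end)]) for p in peaks], annotation
    )


def enrichment_test(
    peaks: list[PeakRegion],
    annotation: GeneAnnotation,
    apriori: set[str],
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    chrom_lengths: dict[str, int] | None = None,
    add_one: bool = False,
) -> EnrichmentResult:
    """Circular-shift enrichment of a priori candidates under peak regions."""
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    if chrom_lengths is None:
        chrom_lengths = _lengths_from_annotation(annotation, peaks)
    observed_genes = genes_under_peaks(peaks, annotation)
    _, n_genes, freq = apriori_frequency(observed_genes, apriori)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        shifted = circular_shift_peaks(peaks, chrom_lengths, rng)
        genes_b = _genes_in_intervals(shifted, annotation)
        _, _, permuted[b] = apriori_frequency(genes_b, apriori)
    r = int((permuted >= freq).sum())
    p = (r + 1) / (n_perm + 1) if add_one else r / n_perm
    return EnrichmentResult(
        trait=peaks[0].trait if peaks else "",
        n_peaks=len(peaks),
        n_genes=n_genes,
        n_apriori=len(observed_genes & apriori),
        frequency=freq,
        permuted=permuted,
        empirical_p=float(p),
    )


def _lengths_from_annotation(
    annotation: GeneAnnotation, peaks: list[PeakRegion]
) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for chrom in set(annotation.chrom) | {p.chrom for p in peaks}:
        ends = [int(annotation.end[annotation.chrom == chrom].max())] if (
            annotation.chrom == chrom
        ).any() else [0]
        ends += [p.end for p in peaks if p.chrom == chrom]
        lengths[chrom] = max(ends)
    return lengths


# ---------------------------------------------------------------------------
# shared peaks and the randomized-phenotype null


@dataclass
class OverlapResult:
    trait_pair: tuple[str, str]
    observed: int
    permuted: np.ndarray
    empirical_p: float
    significant: bool
    bonferroni_alpha: float


def _shared_interval(p: PeakRegion, size: int) -> tuple[str, int, int]:
    half = size // 2
    return (p.chrom, p.apex_pos - half, p.apex_pos + half)


def count_shared_peaks(
    peaks_a: list[PeakRegion],
    peaks_b: list[PeakRegion],
    region_size: int = SHARED_REGION_SIZE,
) -> int:
    """Greedy one-to-one matching of intersecting apex-centred regions.

    Each peak contributes an interval of ``region_size`` centred on its
    apex; an A-peak is shared when its interval intersects an unused
    B-interval. Matching processes intervals by right endpoint and pairs
    each with the earliest-ending compatible partner, so the count never
    double-uses a B-peak and is symmetric in its arguments.
    """
    a = sorted((_shared_interval(p, region_size) for p in peaks_a), key=lambda t: (t[0], t[2]))
    b = sorted((_shared_interval(p, region_size) for p in peaks_b), key=lambda t: (t[0], t[2]))
    used = np.zeros(len(b), dtype=bool)
    count = 0
    for chrom, s, e in a:
        best_j = -1
        for j, (cb, sb, eb) in enumerate(b):
            if used[j] or cb != chrom:
                continue
            if sb <= e and eb >= s:
                best_j = j
                break  # b sorted by end: first compatible has earliest end
        if best_j >= 0:
            used[best_j] = True
            count += 1
    return count


def overlap_null_test(
    sgi: SGITable,
    genotypes: GenotypeDataset,
    K,
    trait_pair: tuple[str, str],
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    chrom_lengths: dict[str, int] | None = None,
    tail_fraction: float = peaks_mod.TAIL_FRACTION,
    region_size: int = SHARED_REGION_SIZE,
    n_pairs_tested: int = 21,
    add_one: bool = False,
) -> OverlapResult:
    """Shared-peak count of two traits against a randomized-phenotype null.

    Each permutation independently shuffles each trait's genotype-mean SGI
    across genotypes, reruns the EMMAX scan, tail selection and clumping
    for both traits, and counts shared peaks. The significance flag applies
    a Bonferroni threshold of 0.05 / ``n_pairs_tested`` (0.002 for the 21
    pairwise comparisons of seven MAMP variants).

    ``genotypes`` may be unfiltered; the MAF >= 0.05 filter is applied
    here. Genotypes are restricted to accessions with usable means for
    both traits.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    t_a, t_b = trait_pair
    y_a_all, y_b_all = sgi.trait(t_a), sgi.trait(t_b)
    common = [
        s for s in genotypes.sample_ids if s in y_a_all.index and s in y_b_all.index
    ]
    if len(common) < 10:
        raise ValidationError("fewer than 10 accessions shared by the trait pair")
    idx = [genotypes.sample_ids.index(s) for s in common]
    sub = GenotypeDataset(
        sample_ids=common,
        snp_ids=genotypes.snp_ids, chrom=genotypes.chrom, pos=genotypes.pos,
        ref=genotypes.ref, alt=genotypes.alt,
        calls=np.ascontiguousarray(genotypes.calls[idx]),
    )
    k = mixed_model._as_kinship_array(K)
    if k.shape[0] == genotypes.n_samples:
        k = k[np.ix_(idx, idx)]
    elif k.shape[0] != len(common):
        raise ValidationError("kinship dimension matches neither full nor common samples")
    filtered, maf, rare = mixed_model.maf_filter(sub)
    if chrom_lengths is None:
        chrom_lengths = {
            str(c): int(filtered.pos[filtered.chrom == c].max())
            for c in set(filtered.chrom)
        }
    engine = mixed_model.ScanEngine(filtered, k, maf=maf, rare_flag=rare)
    y_a = y_a_all.reindex(common).to_numpy(dtype=float)
    y_b = y_b_all.reindex(common).to_numpy(dtype=float)

    def _peaks_for(y: np.ndarray, trait: str) -> list[PeakRegion]:
        res = engine.scan(y)
        res.trait = trait
        tail, _ = peaks_mod.select_tail(res, tail_fraction)
        return peaks_mod.cluster_peaks(tail, chrom_lengths, trait=trait)

    observed = count_shared_peaks(
        _peaks_for(y_a, t_a), _peaks_for(y_b, t_b), region_size
    )
    permuted = np.empty(n_perm, dtype=int)
    for bi in range(n_perm):
        pa = _peaks_for(rng.permutation(y_a), t_a)
        pb = _peaks_for(rng.permutation(y_b), t_b)
        permuted[bi] = count_shared_peaks(pa, pb, region_size)
    r = int((permuted >= observed).sum())
    p = (r + 1) / (n_perm + 1) if add_one else r / n_perm
    alpha = 0.05 / n_pairs_tested
    return OverlapResult(
        trait_pair=(t_a, t_b),
        observed=observed,
        permuted=permuted,
        empirical_p=float(p),
        significant=bool(p <= alpha),
        bonferroni_alpha=alpha,
    )


# ---------------------------------------------------------------------------
# mutant validation


@dataclass
class ValidationResult:
    gene: str
    mamp: str
    n_mutant: int
    n_wildtype: int
    statistic: float
    p: float
    q: float = np.nan
    direction: str = ""
    confirmed: bool = False


def wilcoxon_validation(
    measurements: pd.DataFrame, q_threshold: float = 0.05
) -> list[ValidationResult]:
    """Rank-sum tests of mutant vs wild-type SGI with BH correction.

    ``measurements`` needs columns gene_id, mamp_id, arm ("mutant" or
    "wildtype") and sgi; one test per (gene, MAMP) with both arms present
    (n >= 3 each). Direction is "+" when the mutant's median SGI exceeds
    the wild type's. q-values are Benjamini-Hochberg across the whole
    batch; confirmation requires q <= ``q_threshold``.
    """
    required = {"gene_id", "mamp_id", "arm", "sgi"}
    if not required.issubset(measurements.columns):
        raise ValidationError(f"measurements need columns {sorted(required)}")
    bad = ~measurements["arm"].isin(["mutant", "wildtype"])
    if bad.any():
        raise ValidationError(
            f"unknown arm labels: {sorted(measurements.loc[bad, 'arm'].unique())}"
        )
    results: list[ValidationResult] = []
    for (gene, mamp), grp in measurements.groupby(["gene_id", "mamp_id"], sort=True):
        mut = grp.loc[grp["arm"] == "mutant", "sgi"].to_numpy(dtype=float)
        wt = grp.loc[grp["arm"] == "wildtype", "sgi"].to_numpy(dtype=float)
        if len(mut) < 3 or len(wt) < 3:
            raise ValidationError(f"({gene}, {mamp}): each arm needs n >= 3")
        if np.ptp(np.concatenate([mut, wt])) == 0.0:
            stat, p = float(len(mut) * len(wt) / 2.0), 1.0
        else:
            stat, p = stats.mannwhitneyu(mut, wt, alternative="two-sided")
        diff = float(np.median(mut) - np.median(wt))
        results.append(
            ValidationResult(
                gene=str(gene), mamp=str(mamp),
                n_mutant=len(mut), n_wildtype=len(wt),
                statistic=float(stat), p=float(p),
                direction="+" if diff > 0 else ("-" if diff < 0 else "0"),
            )
        )
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.confirmed = bool(q <= q_threshold)
    return results
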