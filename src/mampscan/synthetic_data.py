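"""Synthetic study generator.

Emulates the design of a MAMP-response association panel: ~186 inbred
accessions genotyped genome-wide, challenged with several peptide variants
from two MAMP classes (elf18, flg22), each scored as paired control/treated
seedling fresh masses with at least three replicate pairs.

Genotypes follow the Balding–Nichols model: ancestral allele frequencies are
uniform on (0.05, 0.95) and each of ``n_subpops`` subpopulations draws its
frequency from a Beta distribution with mean p and variance fst·p(1−p),
giving the population structure that the kinship correction in the mixed
model exists to absorb.

The trait model is additive. Each MAMP variant has a baseline SGI (percent),
class-shared and variant-specific major loci (each realized through a single
tag SNP inside its causal gene), and a polygenic background drawn as a
multivariate normal with covariance proportional to the realized
standardized kinship — so the REML model downstream is correctly specified.
The polygenic variance is calibrated so that the narrow-sense heritability
of genotype-mean SGI (major loci + polygenic over total including expected
replicate-mean noise) equals ``polygenic_h2``. A small fraction of
accessions carry a class-specific receptor loss of function: their true SGI
for every variant of that class is drawn uniform on (0, 10) percent, while
the other class is untouched.

Replicate pairs realize true SGI as masses: control fresh mass is
log-normal, treated fresh mass is CFM·(1 − SGI/100)·(1 + ε) with
ε ~ N(0, mass_noise_cv), floored at zero.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import GeneAnnotation, GenotypeDataset, PhenotypeTable
from .errors import ConfigError
from . import io_formats

logger = logging.getLogger(__name__)


@dataclass
class TraitConfig:
    """Architecture of one MAMP variant's SGI response."""

    mamp_id: str
    mamp_class: str
    major_loci: list[tuple[str, float]] = field(default_factory=list)
    polygenic_h2: float = 0.29
    baseline_sgi: float = 40.0


@dataclass
class SimulationConfig:
    """Desk-scale study configuration (defaults emulate the real design)."""

    n_samples: int = 186
    n_snps: int = 5000
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {str(c): 2_000_000 for c in range(1, 6)}
    )
    n_subpops: int = 3
    fst: float = 0.1
    n_genes: int = 500
    gene_length: int = 3000
    traits: list[TraitConfig] = field(default_factory=lambda: default_traits())
    #: genes causal for every variant of a class: class -> [(gene_id, effect %)]
    shared_loci: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: default_shared_loci()
    )
    #: class -> fraction of samples with a class-specific loss of function
    lof_fraction: dict[str, float] = field(
        default_factory=lambda: {"elf18": 2 / 186, "flg22": 10 / 186}
    )
    n_replicates: int = 5
    mass_noise_cv: float = 0.15
    mean_control_mass_mg: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ConfigError(f"fst must be in (0, 1), got {self.fst}")
        if self.n_replicates < 3:
            raise ConfigError("n_replicates must be >= 3")
        for cls, frac in self.lof_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigError(f"lof_fraction[{cls}] outside [0, 1]")
        for t in self.traits:
            if not (0.0 <= t.polygenic_h2 < 1.0):
                raise ConfigError(f"{t.mamp_id}: polygenic_h2 outside [0, 1)")
            if t.mamp_class not in ("elf18", "flg22"):
                raise ConfigError(f"{t.mamp_id}: unknown class {t.mamp_class}")
        if self.n_subpops < 1 or self.n_subpops > self.n_samples:
            raise ConfigError("n_subpops must be in [1, n_samples]")
        min_len = min(self.chromosome_lengths.values())
        if self.gene_length > min_len:
            raise ConfigError("gene_length exceeds shortest chromosome")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = [dataclasses.asdict(t) for t in self.traits]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "traits" in d:
            d["traits"] = [
                TraitConfig(
                    mamp_id=t["mamp_id"],
                    mamp_class=t["mamp_class"],
                    major_loci=[(g, float(e)) for g, e in t.get("major_loci", [])],
                    polygenic_h2=float(t.get("polygenic_h2", 0.29)),
                    baseline_sgi=float(t.get("baseline_sgi", 40.0)),
                )
                for t in d["traits"]
            ]
        if "shared_loci" in d:
            d["shared_loci"] = {
                k: [(g, float(e)) for g, e in v] for k, v in d["shared_loci"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _gene_id(k: int) -> str:
    return f"g{k:04d}"


def default_shared_loci() -> dict[str, list[tuple[str, float]]]:
    # two class-shared loci per MAMP class, on different chromosomes
    return {
        "elf18": [(_gene_id(20), 8.0), (_gene_id(140), 8.0)],
        "flg22": [(_gene_id(250), 8.0), (_gene_id(370), 8.0)],
    }


def default_traits() -> list[TraitConfig]:
    """Seven MAMP variants: three elf18 and four flg22 peptides.

    elf18_DC carries one large-effect receptor-like locus; flg22_Pv is the
    barely-perceived variant (low baseline, heritability ~0).
    """
    return [
        TraitConfig("elf18_DC", "elf18", [(_gene_id(440), 12.0)], 0.29, 45.0),
        TraitConfig("elf18_Ps", "elf18", [(_gene_id(60), 6.0)], 0.29, 40.0),
        TraitConfig("elf18_Pv", "elf18", [(_gene_id(160), 6.0)], 0.29, 50.0),
        TraitConfig("flg22_Pa", "flg22", [(_gene_id(300), 6.0)], 0.29, 40.0),
        TraitConfig("flg22_PsHRm", "flg22", [(_gene_id(410), 6.0)], 0.29, 38.0),
        TraitConfig("flg22_PsHRp", "flg22", [(_gene_id(480), 6.0)], 0.29, 38.0),
        TraitConfig("flg22_Pv", "flg22", [], 0.0, 6.0),
    ]


# ---------------------------------------------------------------------------
# genotypes


def _assign_subpops(n_samples: int, n_subpops: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.resize(np.arange(n_subpops), n_samples)
    rng.shuffle(labels)
    return labels


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeDataset:
    """Balding–Nichols structured genotypes, haploid 0/1 coding."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    # SNPs allocated proportionally to chromosome length
    n_per = np.floor(lengths / lengths.sum() * config.n_snps).astype(int)
    n_per[: config.n_snps - n_per.sum()] += 1

    chrom_col, pos_col = [], []
    for c, n_c in zip(chroms, n_per):
        L = config.chromosome_lengths[c]
        pos = np.sort(rng.choice(L, size=n_c, replace=False)) + 1
        chrom_col.append(np.full(n_c, c, dtype=object))
        pos_col.append(pos.astype(np.int64))
    chrom_col = np.concatenate(chrom_col)
    pos_col = np.concatenate(pos_col)
    m = len(pos_col)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    p_sub = rng.beta(a, b, size=(config.n_subpops, m))

    subpops = _assign_subpops(config.n_samples, config.n_subpops, rng)
    calls = (rng.random((config.n_samples, m)) < p_sub[subpops, :]).astype(np.int8)

    snp_ids = np.array(
        [f"snp_{c}_{p}" for c, p in zip(chrom_col, pos_col)], dtype=object
    )
    ref = np.full(m, "A", dtype=object)
    alt = np.full(m, "T", dtype=object)
    return GenotypeDataset.create(
        [f"acc{i:04d}" for i in range(config.n_samples)],
        snp_ids, chrom_col, pos_col, ref, alt, calls,
        sample_groups=subpops,
    )


# ---------------------------------------------------------------------------
# annotation


def tile_genes(config: SimulationConfig) -> GeneAnnotation:
    """Uniformly tiled, non-overlapping genes; deterministic given config."""
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    n_per = np.floor(lengths / lengths.sum() * config.n_genes).astype(int)
    n_per[: config.n_genes - n_per.sum()] += 1
    ids, cc, ss, ee = [], [], [], []
    k = 0
    for c, n_c in zip(chroms, n_per):
        L = config.chromosome_lengths[c]
        if n_c * config.gene_length > L:
            raise ConfigError(f"gene tiling exceeds chromosome {c} length")
        spacing = L // max(n_c, 1)
        for i in range(n_c):
            start = i * spacing + 1
            end = start + config.gene_length - 1
            ids.append(_gene_id(k))
            cc.append(c)
            ss.append(start)
            ee.append(end)
            k += 1
    strand = np.where(np.arange(k) % 2 == 0, "+", "-")
    return GeneAnnotation.create(ids, cc, ss, ee, strand)


# ---------------------------------------------------------------------------
# phenotypes


def _standardized_kinship(calls: np.ndarray) -> np.ndarray:
    """Allele-frequency standardized kinship of a 0/1 call matrix (no missing)."""
    p = calls.mean(axis=0)
    poly = (p > 0) & (p < 1)
    z = (calls[:, poly] - p[poly]) / np.sqrt(p[poly] * (1.0 - p[poly]))
    return z @ z.T / poly.sum()


def _causal_snp_index(ds: GenotypeDataset, ann: GeneAnnotation, gene_id: str) -> int:
    """Index of the SNP nearest the gene midpoint, within the gene body."""
    gi = np.flatnonzero(ann.gene_id == gene_id)
    if gi.size == 0:
        raise ConfigError(f"causal gene {gene_id} not in annotation")
    gi = gi[0]
    inside = np.flatnonzero(
        (ds.chrom == ann.chrom[gi]) & (ds.pos >= ann.start[gi]) & (ds.pos <= ann.end[gi])
    )
    if inside.size == 0:
        raise ConfigError(f"causal gene {gene_id} contains no SNP")
    mid = (ann.start[gi] + ann.end[gi]) // 2
    return int(inside[np.argmin(np.abs(ds.pos[inside] - mid))])


def _all_causal_genes(config: SimulationConfig) -> list[str]:
    genes = [g for t in config.traits for g, _ in t.major_loci]
    genes += [g for v in config.shared_loci.values() for g, _ in v]
    return sorted(set(genes))


def simulate_phenotypes(
    genotypes: GenotypeDataset,
    annotation: GeneAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, dict]:
    """Realize trait architectures as replicate fresh-mass pairs.

    Returns the replicate table and a ground-truth dict with per-trait
    causal SNPs/effects, realized polygenic variance, and per-class
    loss-of-function carrier ids.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    n = genotypes.n_samples
    samples = genotypes.sample_ids
    cv = config.mass_noise_cv
    R = config.n_replicates

    calls = genotypes.calls.astype(float)
    calls[genotypes.calls < 0] = np.nan
    col_mean = np.nanmean(calls, axis=0)
    inds = np.where(np.isnan(calls))
    calls[inds] = np.take(col_mean, inds[1])

    K = _standardized_kinship(genotypes.calls.clip(min=0))
    # Cholesky with a small ridge so near-PSD realized kinship factors cleanly
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    # class-specific loss-of-function carriers, disjoint between classes
    classes = sorted({t.mamp_class for t in config.traits})
    lof: dict[str, list[str]] = {}
    pool = rng.permutation(n)
    used = 0
    for cls in classes:
        k = int(round(config.lof_fraction.get(cls, 0.0) * n))
        if config.lof_fraction.get(cls, 0.0) > 0 and k < 1:
            logger.info("lof_fraction for %s yields zero carriers at n=%d", cls, n)
        lof[cls] = [samples[i] for i in pool[used : used + k]]
        used += k

    # one shared polygenic draw per class, scaled per trait
    class_poly = {cls: L @ rng.standard_normal(n) for cls in classes}

    truth: dict = {
        "causal": {},
        "polygenic_h2": {t.mamp_id: t.polygenic_h2 for t in config.traits},
        "polygenic_var": {},
        "lof_samples": lof,
        "true_sgi": {},
    }
    rows = []
    n_clipped = 0
    for t in config.traits:
        loci = list(t.major_loci) + list(config.shared_loci.get(t.mamp_class, []))
        g_val = np.zeros(n)
        causal = []
        for gene, effect in loci:
            j = _causal_snp_index(genotypes, annotation, gene)
            g_val += effect * calls[:, j]
            causal.append(
                {"gene_id": gene, "snp_id": str(genotypes.snp_ids[j]), "effect": effect}
            )
        v_major = float(np.var(g_val))
        # expected replicate-mean noise variance of SGI, from the mass model
        v_env = (100.0 - t.baseline_sgi) ** 2 * cv**2 / R
        # Polygenic variance calibrated so the kinship-captured share of
        # genotype-mean variance is polygenic_h2, given the major-locus
        # variance (which genome-wide kinship absorbs only marginally):
        # v_poly / (v_poly + v_major + v_env) = polygenic_h2.
        h2 = t.polygenic_h2
        v_poly = h2 / (1.0 - h2) * (v_major + v_env) if h2 > 0 else 0.0
        sgi_true = t.baseline_sgi + g_val + np.sqrt(v_poly) * class_poly[t.mamp_class]

        lof_idx = [samples.index(s) for s in lof.get(t.mamp_class, [])]
        if lof_idx:
            sgi_true[lof_idx] = rng.uniform(0.0, 10.0, size=len(lof_idx))
        over = sgi_true > 100.0
        if over.any():
            n_clipped += int(over.sum())
            sgi_true = np.minimum(sgi_true, 100.0)

        truth["causal"][t.mamp_id] = causal
        truth["polygenic_var"][t.mamp_id] = v_poly
        truth["true_sgi"][t.mamp_id] = {s: float(v) for s, v in zip(samples, sgi_true)}

        cfm = rng.lognormal(np.log(config.mean_control_mass_mg), cv, size=(n, R))
        eps = rng.normal(0.0, cv, size=(n, R))
        tfm = np.maximum(0.0, cfm * (1.0 - sgi_true[:, None] / 100.0) * (1.0 + eps))
        for i, s in enumerate(samples):
            for r in range(R):
                rows.append(
                    (s, t.mamp_id, t.mamp_class, r + 1, cfm[i, r], tfm[i, r])
                )
    if n_clipped:
        logger.warning("clipped %d true SGI values to 100%%", n_clipped)

    df = pd.DataFrame(
        rows,
        columns=[
            "genotype_id", "mamp_id", "mamp_class", "replicate",
            "control_mass_mg", "treated_mass_mg",
        ],
    )
    return PhenotypeTable.create(df), truth


# ---------------------------------------------------------------------------
# full study


@dataclass
class SimulatedStudy:
    genotypes: GenotypeDataset
    annotation: GeneAnnotation
    phenotypes: PhenotypeTable
    truth: dict
    config: SimulationConfig


def simulate_study(config: SimulationConfig, out_dir=None) -> SimulatedStudy:
    """Generate a full synthetic study; optionally write all artifacts.

    Ensures every causal gene contains at least one SNP by relocating the
    nearest SNP into the gene body when the uniform draw left it empty.
    """
    config.validate()
    annotation = tile_genes(config)
    genotypes = simulate_genotypes(config)
    genotypes = _ensure_causal_snps(genotypes, annotation, config)
    phenotypes, truth = simulate_phenotypes(genotypes, annotation, config)
    truth["subpops"] = (
        genotypes.sample_groups.tolist() if genotypes.sample_groups is not None else None
    )
    study = SimulatedStudy(genotypes, annotation, phenotypes, truth, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
        io_formats.write_genotypes_vcf(
            genotypes, out / "genotypes.vcf", config.chromosome_lengths
        )
        io_formats.write_annotation_gff3(annotation, out / "genes.gff3")
        io_formats.write_phenotypes(phenotypes, out / "phenotypes.csv")
        config.to_yaml(out / "config.yaml")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return study


def _ensure_causal_snps(
    genotypes: GenotypeDataset, annotation: GeneAnnotation, config: SimulationConfig
) -> GenotypeDataset:
    pos = genotypes.pos.copy()
    snp_ids = genotypes.snp_ids.copy()
    moved = False
    for gene in _all_causal_genes(config):
        gi = np.flatnonzero(annotation.gene_id == gene)
        if gi.size == 0:
            raise ConfigError(f"causal gene {gene} not in annotation")
        gi = gi[0]
        on_chrom = genotypes.chrom == annotation.chrom[gi]
        inside = on_chrom & (pos >= annotation.start[gi]) & (pos <= annotation.end[gi])
        if inside.any():
            continue
        mid = (annotation.start[gi] + annotation.end[gi]) // 2
        cand = np.flatnonzero(on_chrom)
        j = cand[np.argmin(np.abs(pos[cand] - mid))]
        pos[j] = mid
        snp_ids[j] = f"snp_{annotation.chrom[gi]}_{mid}"
        moved = True
        logger.debug("relocated SNP into causal gene %s", gene)
    if not moved:
        return genotypes
    return GenotypeDataset.create(
        genotypes.sample_ids, snp_ids, genotypes.chrom, pos,
        genotypes.ref, genotypes.alt, genotypes.calls,
        sample_groups=genotypes.sample_groups,
    )
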