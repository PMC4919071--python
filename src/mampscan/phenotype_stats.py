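"""Seedling growth inhibition (SGI) phenotyping statistics.

SGI is the relative reduction of treated fresh mass against its paired
control: 100 * (CFM - TFM) / CFM, in percent. Replicate pairs are converted
to SGI individually and then averaged per (genotype, MAMP variant); cells
with fewer than three replicate pairs are unusable downstream. A genotype is
"insensitive" to a MAMP class when its mean over that class's usable variant
means is strictly below 15 percent; such natural mutants are excluded from
the correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MAMP_CLASSES, PhenotypeTable, SGITable

logger = logging.getLogger(__name__)

#: Class-mean SGI below this (strictly) marks a genotype insensitive.
INSENSITIVITY_THRESHOLD = 15.0


def compute_sgi(control_mass, treated_mass):
    """SGI in percent from paired masses; control must be positive.

    Accepts scalars or arrays. Negative SGI (growth promotion) is allowed.
    """
    cfm = np.asarray(control_mass, dtype=float)
    tfm = np.asarray(treated_mass, dtype=float)
    if (cfm <= 0).any():
        raise ValueError("control mass must be > 0 (SGI undefined)")
    out = 100.0 * (cfm - tfm) / cfm
    return float(out) if out.ndim == 0 else out


def genotype_mean_sgi(
    phenotypes: PhenotypeTable, min_replicates: int = 3
) -> SGITable:
    """Per-replicate SGI averaged per (genotype, MAMP variant).

    Cells with fewer than ``min_replicates`` pairs are marked unusable
    (NaN mean) and counted in the log.
    """
    df = phenotypes.records.copy()
    df["sgi"] = compute_sgi(df["control_mass_mg"], df["treated_mass_mg"])
    means = df.pivot_table(index="genotype_id", columns="mamp_id", values="sgi", aggfunc="mean")
    counts = (
        df.pivot_table(index="genotype_id", columns="mamp_id", values="sgi", aggfunc="count")
        .fillna(0)
        .astype(int)
    )
    unusable = counts < min_replicates
    n_unusable = int((unusable & means.notna()).to_numpy().sum())
    if n_unusable:
        logger.info(
            "%d genotype x MAMP cells have < %d replicate pairs and are excluded",
            n_unusable, min_replicates,
        )
    means = means.mask(unusable)
    mamp_class = phenotypes.mamp_class_of
    table = SGITable(
        means=means,
        counts=counts,
        mamp_class=mamp_class,
        insensitive=pd.DataFrame(index=means.index, columns=list(MAMP_CLASSES), dtype=object),
        min_replicates=min_replicates,
    )
    table.insensitive = classify_insensitive(table)
    return table


def classify_insensitive(
    sgi: SGITable, threshold: float = INSENSITIVITY_THRESHOLD
) -> pd.DataFrame:
    """Flag (genotype, class) pairs with class-mean SGI strictly below threshold.

    The class mean averages the genotype's usable variant means within the
    class. A genotype with no usable variant in a class gets NaN (undefined).
    """
    classes = sorted({c for c in sgi.mamp_class.values()})
    out = pd.DataFrame(index=sgi.means.index, columns=classes, dtype=object)
    for cls in classes:
        cols = sgi.class_columns(cls)
        class_mean = sgi.means[cols].mean(axis=1, skipna=True)
        flags = class_mean < threshold
        flags = flags.astype(object).mask(class_mean.isna())
        n_undef = int(class_mean.isna().sum())
        if n_undef:
            logger.info("%d genotypes have no usable %s variant; flag undefined", n_undef, cls)
        out[cls] = flags
    return out


@dataclass
class CorrelationReport:
    """Pairwise Pearson structure of genotype-mean SGI across MAMP variants."""

    r: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n: pd.DataFrame
    within_class_mean_r: float
    between_class_mean_r: float
    excluded_genotypes: list[str]


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or not np.isfinite(r) or abs(r) >= 1.0:
        # CI degenerates at |r| = 1 or tiny n
        return (r, r) if abs(r) >= 1.0 else (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - q * se)), float(np.tanh(z + q * se))


def correlation_matrix(sgi: SGITable, ci_level: float = 0.95) -> CorrelationReport:
    """Pearson correlations between variants after excluding insensitive genotypes.

    Excludes every genotype flagged insensitive for either class, uses
    pairwise-complete observations, and attaches Fisher-z confidence
    intervals. Within-class and between-class mean r summarise the block
    structure.
    """
    flags = sgi.insensitive
    excluded = sorted(
        flags.index[(flags == True).any(axis=1)].tolist()  # noqa: E712 (NaN-safe)
    )
    means = sgi.means.drop(index=excluded)
    if len(means) < 3:
        raise ValueError("fewer than 3 genotypes remain after exclusion")
    cols = list(means.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    lo = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    hi = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i in range(k):
        nmat.iloc[i, i] = int(means[cols[i]].notna().sum())
        for j in range(i + 1, k):
            pair = means[[cols[i], cols[j]]].dropna()
            n = len(pair)
            nmat.iloc[i, j] = nmat.iloc[j, i] = n
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                rij = np.nan
                logger.info("correlation undefined for (%s, %s)", cols[i], cols[j])
            else:
                rij = float(np.corrcoef(x, y)[0, 1])
            r.iloc[i, j] = r.iloc[j, i] = rij
            l, h = _fisher_ci(rij, n, ci_level) if np.isfinite(rij) else (np.nan, np.nan)
            lo.iloc[i, j] = lo.iloc[j, i] = l
            hi.iloc[i, j] = hi.iloc[j, i] = h
    within, between = [], []
    for i in range(k):
        for j in range(i + 1, k):
            val = r.iloc[i, j]
            if not np.isfinite(val):
                continue
            same = sgi.mamp_class[cols[i]] == sgi.mamp_class[cols[j]]
            (within if same else between).append(val)
    return CorrelationReport(
        r=r,
        ci_low=lo,
        ci_high=hi,
        n=nmat,
        within_class_mean_r=float(np.mean(within)) if within else np.nan,
        between_class_mean_r=float(np.mean(between)) if between else np.nan,
        excluded_genotypes=excluded,
    )


def welch_compare(sgi_a, sgi_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test between two sets of genotype means.

    Returns (t, Satterthwaite df, two-sided p). With zero variance in both
    groups and equal means, returns (0, n-2 df, 1) by convention.
    """
    a = np.asarray(sgi_a, dtype=float)
    b = np.asarray(sgi_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(len(a) + len(b) - 2), 0.0
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
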