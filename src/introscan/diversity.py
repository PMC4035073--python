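"""Allele frequencies and marker informativeness statistics per population.

Implements minor allele frequency, expected heterozygosity (gene diversity)
and polymorphism information content (PIC), averaged over markers for a
population, together with a resampling-based sample-size adjustment: each
statistic is recomputed as the mean over replicate subsamples of a fixed size
drawn without replacement, so populations of unequal size become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Group, PopulationPanel

__all__ = [
    "allele_frequency",
    "alt_allele_frequencies",
    "maf",
    "expected_heterozygosity",
    "pic",
    "DiversitySummary",
    "diversity_summary",
    "size_adjusted_summary",
    "diversity_table",
]


def alt_allele_frequencies(
    geno: GenotypeMatrix, cultivars: Sequence[str] | None = None
) -> np.ndarray:
    """Alt-allele frequency per marker over a cultivar subset.

    Allele counting: homozygotes contribute two copies, heterozygotes one of
    each; missing calls are excluded from the denominator.  Markers with no
    non-missing call get NaN (undefined), never zero.
    """
    rows = (
        np.arange(geno.n_cultivars)
        if cultivars is None
        else geno.cultivar_rows(cultivars)
    )
    calls = geno.calls[rows]
    alt_copies = (
        2 * (calls == HOM_ALT).sum(axis=0) + (calls == HET).sum(axis=0)
    ).astype(float)
    total = 2.0 * (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, alt_copies / np.maximum(total, 1), np.nan)
    freq[total == 0] = np.nan
    return freq


def allele_frequency(
    geno: GenotypeMatrix, cultivars: Sequence[str], marker_id: str
) -> dict[str, float] | None:
    """Per-allele frequencies at one marker; ``None`` if every call is missing."""
    j = geno.marker_cols([marker_id])[0]
    sub = geno.subset(cultivars=list(cultivars), marker_ids=[marker_id])
    p_alt = alt_allele_frequencies(sub)[0]
    if np.isnan(p_alt):
        return None
    ref, alt = geno.alleles[j]
    return {ref: 1.0 - p_alt, alt: p_alt}


def _as_freq_vector(freqs) -> np.ndarray:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must be non-negative and sum to 1")
    return p


def maf(freqs) -> float:
    """Minor allele frequency: the smallest allele frequency in the vector."""
    return float(np.min(_as_freq_vector(freqs)))


def expected_heterozygosity(freqs) -> float:
    """Gene diversity He = 1 - sum(p_i^2)."""
    p = _as_freq_vector(freqs)
    return float(1.0 - np.sum(p**2))


def pic(freqs) -> float:
    """Polymorphism information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _as_freq_vector(freqs)
    s2 = np.sum(p**2)
    s4 = np.sum(p**4)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p_i^2)^2 - sum p_i^4
    return float(1.0 - s2 - (s2**2 - s4))


def _biallelic_stats(p_alt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker (maf, He, PIC) for biallelic alt frequencies."""
    maf_v = np.minimum(p_alt, 1.0 - p_alt)
    he = 1.0 - (p_alt**2 + (1.0 - p_alt) ** 2)
    pq2 = (p_alt * (1.0 - p_alt)) ** 2
    pic_v = he - 2.0 * pq2
    return maf_v, he, pic_v


@dataclass
class DiversitySummary:
    """Mean marker statistics for one population.

    Per-marker vectors are aligned with the genotype matrix marker order;
    markers with no non-missing call in the population are NaN and excluded
    from means.  ``adjusted_*`` are the resampling-based versions (None until
    computed).
    """

    population: str
    n_cultivars: int
    maf_per_marker: np.ndarray
    he_per_marker: np.ndarray
    pic_per_marker: np.ndarray
    mean_maf: float
    mean_he: float
    mean_pic: float
    adjusted_mean_maf: float | None = None
    adjusted_mean_he: float | None = None
    adjusted_mean_pic: float | None = None


def diversity_summary(
    geno: GenotypeMatrix, cultivars: Sequence[str], population: str = ""
) -> DiversitySummary:
    """Unadjusted per-marker and mean MAF/He/PIC for a cultivar set.

    Markers monomorphic within the population are included and contribute
    zero to the means; all-missing markers are excluded (NaN).
    """
    p_alt = alt_allele_frequencies(geno, cultivars)
    maf_v, he, pic_v = _biallelic_stats(p_alt)
    return DiversitySummary(
        population=population,
        n_cultivars=len(list(cultivars)),
        maf_per_marker=maf_v,
        he_per_marker=he,
        pic_per_marker=pic_v,
        mean_maf=float(np.nanmean(maf_v)),
        mean_he=float(np.nanmean(he)),
        mean_pic=float(np.nanmean(pic_v)),
    )


def size_adjusted_summary(
    geno: GenotypeMatrix,
    cultivars: Sequence[str],
    n_sub: int = 14,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
    population: str = "",
) -> DiversitySummary:
    """Sample-size-adjusted diversity means.

    Draws ``reps`` subsets of ``n_sub`` cultivars without replacement and
    reports each mean statistic averaged over the replicate subsets, removing
    the dependence of diversity means on population size.
    """
    cultivars = list(cultivars)
    if len(cultivars) < n_sub:
        raise ValueError(
            f"population of size {len(cultivars)} smaller than n_sub={n_sub}; "
            "skip the sample-size adjustment for this population"
        )
    rng = np.random.default_rng(seed)
    rep_maf, rep_he, rep_pic = [], [], []
    for _ in range(reps):
        pick = rng.choice(len(cultivars), size=n_sub, replace=False)
        sub = [cultivars[i] for i in pick]
        s = diversity_summary(geno, sub)
        rep_maf.append(s.mean_maf)
        rep_he.append(s.mean_he)
        rep_pic.append(s.mean_pic)
    out = diversity_summary(geno, cultivars, population=population)
    out.adjusted_mean_maf = float(np.mean(rep_maf))
    out.adjusted_mean_he = float(np.mean(rep_he))
    out.adjusted_mean_pic = float(np.mean(rep_pic))
    return out


def diversity_table(
    geno: GenotypeMatrix,
    panel: PopulationPanel,
    populations: Sequence[Group | str] | None = None,
    adjust_n: int = 14,
    reps: int = 10,
    seed: int = 0,
    include_all: bool = True,
) -> pd.DataFrame:
    """Per-population diversity table (one row per group, plus "All").

    "All" is the union of every panel group present.  Populations smaller
    than ``adjust_n`` report NaN for the adjusted columns.
    """
    if populations is None:
        populations = sorted(
            {g for g in panel.assignments.values()}, key=lambda g: g.value
        )
    rows = []
    pops: list[tuple[str, list[str]]] = [
        (Group(g).value, panel.members(g)) for g in populations
    ]
    if include_all:
        pops.append(("All", panel.cultivar_ids))
    rng = np.random.default_rng(seed)
    for name, members in pops:
        members = [c for c in members if c in geno._cultivar_index]
        if not members:
            continue
        if len(members) >= adjust_n:
            s = size_adjusted_summary(
                geno, members, n_sub=adjust_n, reps=reps, seed=rng, population=name
            )
        else:
            s = diversity_summary(geno, members, population=name)
        rows.append(
            {
                "population": name,
                "n_cultivars": s.n_cultivars,
                "mean_maf": s.mean_maf,
                "mean_he": s.mean_he,
                "mean_pic": s.mean_pic,
                "adjusted_mean_maf": s.adjusted_mean_maf,
                "adjusted_mean_he": s.adjusted_mean_he,
                "adjusted_mean_pic": s.adjusted_mean_pic,
            }
        )
    return pd.DataFrame(rows)
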