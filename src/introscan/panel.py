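"""Informative-SNP filtering and LD-based panel-size simulation.

A genotyping panel for inbred cultivars is designed in two passes: a core
screen on a small set of founder cultivars (no missing calls, minor allele
carried by at least three cultivars), then a whole-collection screen (known
map position, at most 5% heterozygous-or-missing calls, minor allele
frequency above 2%).  The size of the working panel is chosen from a
simulated curve of mean "complete LD": for random marker subsets of
increasing size, the mean adjacent-pair Delta-squared restricted to the open
interval (0, 1) rises and plateaus once markers are dense relative to the LD
decay length.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .data import HET, HOM_ALT, HOM_REF, MISSING, NO_POSITION, GenotypeMatrix
from .diversity import alt_allele_frequencies

__all__ = [
    "filter_core_informative",
    "filter_panel_informative",
    "delta_squared",
    "adjacent_pair_delta_squared",
    "ld_subset_curve",
    "select_panel",
]


def filter_core_informative(
    geno: GenotypeMatrix, core_cultivars: Sequence[str]
) -> list[str]:
    """Markers informative in the founder screen.

    Keeps markers with zero missing calls among the core cultivars and whose
    minor allele is carried by at least three of them (a heterozygote carries
    both alleles; monomorphic markers fail because the absent allele has zero
    carriers).
    """
    rows = geno.cultivar_rows(core_cultivars)
    calls = geno.calls[rows]
    no_missing = ~(calls == MISSING).any(axis=0)
    ref_carriers = ((calls == HOM_REF) | (calls == HET)).sum(axis=0)
    alt_carriers = ((calls == HOM_ALT) | (calls == HET)).sum(axis=0)
    min_carriers = np.minimum(ref_carriers, alt_carriers)
    keep = no_missing & (min_carriers >= 3)
    return list(geno.markers.marker_ids[keep])


def filter_panel_informative(
    geno: GenotypeMatrix,
    max_het_missing_frac: float = 0.05,
    min_maf: float = 0.02,
) -> list[str]:
    """Markers informative across the whole collection.

    Excludes markers (1) with no known genome position, (2) heterozygous or
    missing in more than ``max_het_missing_frac`` of accessions, or (3) with
    minor allele frequency at or below ``min_maf`` (the boundary itself is
    excluded).
    """
    calls = geno.calls
    n = calls.shape[0]
    has_pos = geno.markers.positions != NO_POSITION
    het_missing = ((calls == HET) | (calls == MISSING)).sum(axis=0) / n
    p_alt = alt_allele_frequencies(geno)
    with np.errstate(invalid="ignore"):
        maf_v = np.minimum(p_alt, 1.0 - p_alt)
    keep = has_pos & (het_missing <= max_het_missing_frac) & (maf_v > min_maf)
    keep &= ~np.isnan(p_alt)
    return list(geno.markers.marker_ids[keep])


def _pair_delta_squared(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Delta-squared from two call columns; NaN when undefined.

    Haplotypes are read directly from homozygous inbred genotypes:
    heterozygous or missing calls at either marker drop the cultivar
    pairwise.  Undefined (fewer than two usable cultivars, or either marker
    monomorphic in the usable subset) returns NaN rather than zero.
    """
    mask = (
        ((col_a == HOM_REF) | (col_a == HOM_ALT))
        & ((col_b == HOM_REF) | (col_b == HOM_ALT))
    )
    if mask.sum() < 2:
        return np.nan
    a = (col_a[mask] == HOM_ALT).astype(float)
    b = (col_b[mask] == HOM_ALT).astype(float)
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0.0 or vb == 0.0:
        return np.nan
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (va * vb))


def delta_squared(
    geno: GenotypeMatrix,
    cultivars: Sequence[str] | None,
    marker_a: str,
    marker_b: str,
) -> float:
    """Squared correlation of allele indicators between two markers.

    Computed over cultivars with non-missing homozygous calls at both
    markers (pairwise-complete); returns NaN when either marker is
    monomorphic in that subset.
    """
    rows = (
        np.arange(geno.n_cultivars)
        if cultivars is None
        else geno.cultivar_rows(cultivars)
    )
    ja, jb = geno.marker_cols([marker_a, marker_b])
    return _pair_delta_squared(geno.calls[rows, ja], geno.calls[rows, jb])


def adjacent_pair_delta_squared(
    geno: GenotypeMatrix,
    cultivars: Sequence[str] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Delta-squared for every within-chromosome adjacent marker pair.

    Pairs never span a chromosome boundary.  ``marker_ids`` restricts the
    panel (adjacency is then within the restricted, position-sorted set).
    """
    sub = geno.subset(
        cultivars=None if cultivars is None else list(cultivars),
        marker_ids=None if marker_ids is None else list(marker_ids),
    )
    chroms = sub.markers.chromosomes
    mids = sub.markers.marker_ids
    rows = []
    for j in range(sub.n_markers - 1):
        if chroms[j] != chroms[j + 1]:
            continue
        d2 = _pair_delta_squared(sub.calls[:, j], sub.calls[:, j + 1])
        rows.append(
            {
                "marker_a": mids[j],
                "marker_b": mids[j + 1],
                "chromosome": chroms[j],
                "delta_squared": d2,
            }
        )
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "chromosome", "delta_squared"])


def _mean_complete_ld(d2: np.ndarray, mode: str) -> tuple[float, int]:
    d2 = d2[~np.isnan(d2)]
    if mode == "open-interval":
        d2 = d2[(d2 > 0.0) & (d2 < 1.0)]
    elif mode != "all":
        raise ValueError(f"unknown ld mean mode {mode!r}")
    if len(d2) == 0:
        return np.nan, 0
    return float(d2.mean()), int(len(d2))


def ld_subset_curve(
    geno: GenotypeMatrix,
    cultivars: Sequence[str] | None,
    sizes: Sequence[int],
    reps: int = 10,
    seed: int = 0,
    marker_ids: Sequence[str] | None = None,
    mean_mode: str = "open-interval",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean complete-LD curve over random marker subsets of growing size.

    For each panel size and replicate a uniform random subset is drawn,
    sorted by position, and the within-chromosome adjacent-pair
    Delta-squared values are averaged over pairs strictly inside (0, 1)
    (``mean_mode="all"`` averages every defined pair instead).  Returns
    ``(points, summary)``: one row per (size, replicate), and per-size mean
    with standard error across replicates.  Replicates with no usable pair
    are flagged NaN, warned about and excluded from the summary.
    """
    pool = list(marker_ids) if marker_ids is not None else list(geno.markers.marker_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"panel size {size} exceeds {len(pool)} available markers")
        for rep in range(reps):
            chosen = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]
            pairs = adjacent_pair_delta_squared(geno, cultivars, chosen)
            mean_ld, n_pairs = _mean_complete_ld(
                pairs["delta_squared"].to_numpy(float), mean_mode
            )
            if n_pairs == 0:
                warnings.warn(
                    f"size {size} replicate {rep}: no adjacent pairs with usable "
                    "delta-squared; replicate excluded from the mean",
                    stacklevel=2,
                )
            rows.append(
                {
                    "panel_size": size,
                    "replicate": rep,
                    "mean_complete_ld": mean_ld,
                    "n_pairs_used": n_pairs,
                }
            )
    points = pd.DataFrame(rows)
    grouped = points.dropna(subset=["mean_complete_ld"]).groupby("panel_size")
    summary = grouped["mean_complete_ld"].agg(["mean", "sem", "count"]).reset_index()
    summary.columns = ["panel_size", "mean_complete_ld", "standard_error", "n_replicates"]
    return points, summary


def select_panel(
    marker_ids: Sequence[str],
    target_size: int,
    seed: int = 0,
    geno: GenotypeMatrix | None = None,
) -> list[str]:
    """Uniform random marker subset of the requested size.

    Order of the returned list follows map position when ``geno`` is given,
    otherwise the input order.
    """
    marker_ids = list(marker_ids)
    if target_size > len(marker_ids):
        raise ValueError(
            f"target size {target_size} exceeds {len(marker_ids)} available markers"
        )
    rng = np.random.default_rng(seed)
    pick = sorted(rng.choice(len(marker_ids), size=target_size, replace=False))
    chosen = [marker_ids[i] for i in pick]
    if geno is not None:
        cols = geno.marker_cols(chosen)
        chosen = [chosen[i] for i in np.argsort(cols)]
    return chosen
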