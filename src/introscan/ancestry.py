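"""Parental-origin scanning of admixed cultivars with the adjusted-HY statistic.

Markers whose allele frequency differs by more than a threshold (default 0.7)
between the domestic japonica parents (PD) and the overseas indica parents
(PO-indica) discriminate the two ancestries.  At each such marker the
indica-allele frequency in the admixed high-yielding group (HY) is corrected
for the parental frequencies:

    adjusted HY = HY - PD - (1 - PO-indica)

which is 0 when HY matches the japonica parents and 1 under complete indica
introgression with fully diverged parents.  Adjusted-HY values are summarized
in consecutive five-SNP windows (median and quartiles); windows whose median
falls strictly outside the genome-wide 25th-75th percentile band are called
skewed toward indica or japonica, and adjacent same-class windows are merged
into candidate introgression intervals.  Cultivars are classified JA / IN /
MX from their genome-wide indica-allele fraction at discriminating markers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix, Group, PopulationPanel
from .diversity import alt_allele_frequencies

logger = logging.getLogger("introscan.ancestry")

__all__ = [
    "INDICA_SKEWED",
    "JAPONICA_SKEWED",
    "NEUTRAL",
    "find_discriminating_snps",
    "adjusted_hy_frequency",
    "window_summary",
    "call_skewed_regions",
    "AncestryProfile",
    "ancestry_profile",
    "classify_genome_types",
    "graphical_genotypes",
]

INDICA_SKEWED = "INDICA_SKEWED"
JAPONICA_SKEWED = "JAPONICA_SKEWED"
NEUTRAL = "NEUTRAL"


def find_discriminating_snps(
    geno: GenotypeMatrix,
    panel: PopulationPanel,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Markers separating the two parental pools, with indica-allele frequencies.

    A marker is discriminating when the absolute allele-frequency difference
    between PD and PO-indica exceeds ``threshold`` (strict).  The tracked
    indica allele is the PO-indica major allele (frequency ties broken by
    alphabetical allele symbol, with a warning).  Markers with an undefined
    frequency in either parental pool are excluded and logged.

    Returns a DataFrame with marker_id, chromosome, position_bp,
    indica_allele, freq_po_indica, freq_pd, freq_hy, maf_diff.
    """
    pd_members = [c for c in panel.members(Group.PD) if c in geno._cultivar_index]
    po_members = [c for c in panel.members(Group.PO_INDICA) if c in geno._cultivar_index]
    hy_members = [c for c in panel.members(Group.HY) if c in geno._cultivar_index]
    for name, members in (("PD", pd_members), ("PO_INDICA", po_members), ("HY", hy_members)):
        if not members:
            raise ValueError(f"group {name} is empty; cannot scan ancestry")

    p_pd = alt_allele_frequencies(geno, pd_members)
    p_po = alt_allele_frequencies(geno, po_members)
    p_hy = alt_allele_frequencies(geno, hy_members)

    undefined = np.isnan(p_pd) | np.isnan(p_po) | np.isnan(p_hy)
    if undefined.any():
        logger.info(
            "%d marker(s) excluded: undefined frequency in a required group",
            int(undefined.sum()),
        )
    diff = np.abs(p_pd - p_po)
    keep = (~undefined) & (diff > threshold)

    rows = []
    for j in np.flatnonzero(keep):
        ref, alt = geno.alleles[j]
        if p_po[j] > 0.5:
            indica_allele, flip = alt, False
        elif p_po[j] < 0.5:
            indica_allele, flip = ref, True
        else:
            indica_allele = min(ref, alt)
            flip = indica_allele == ref
            warnings.warn(
                f"marker {geno.markers.marker_ids[j]}: PO-indica major allele tied "
                f"at 0.5; broke tie alphabetically to {indica_allele!r}",
                stacklevel=2,
            )
        def f(p: float) -> float:
            return float(1.0 - p) if flip else float(p)

        rows.append(
            {
                "marker_id": geno.markers.marker_ids[j],
                "chromosome": geno.markers.chromosomes[j],
                "position_bp": int(geno.markers.positions[j]),
                "indica_allele": indica_allele,
                "freq_po_indica": f(p_po[j]),
                "freq_pd": f(p_pd[j]),
                "freq_hy": f(p_hy[j]),
                "maf_diff": float(diff[j]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "chromosome",
            "position_bp",
            "indica_allele",
            "freq_po_indica",
            "freq_pd",
            "freq_hy",
            "maf_diff",
        ],
    )


def adjusted_hy_frequency(freq_hy, freq_pd, freq_po_indica):
    """Adjusted HY = HY - PD - (1 - PO-indica); unclamped, array-friendly."""
    return np.asarray(freq_hy, float) - np.asarray(freq_pd, float) - (
        1.0 - np.asarray(freq_po_indica, float)
    )


def window_summary(
    discriminating: pd.DataFrame, window: int = 5
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tile consecutive runs of ``window`` discriminating SNPs per chromosome.

    Windows never span chromosomes; a terminal remainder of fewer than
    ``window`` SNPs becomes a window flagged ``partial``.  Each window
    reports the median and 25th/75th percentile of adjusted HY (linear
    interpolation).  Returns (windows, window_index_per_marker) with the
    second aligned to the input row order.
    """
    if "adjusted_hy" not in discriminating.columns:
        discriminating = discriminating.assign(
            adjusted_hy=adjusted_hy_frequency(
                discriminating["freq_hy"],
                discriminating["freq_pd"],
                discriminating["freq_po_indica"],
            )
        )
    win_rows = []
    marker_window = np.full(len(discriminating), -1, dtype=int)
    wid = 0
    for chrom, sub in discriminating.groupby("chromosome", sort=False):
        sub = sub.sort_values("position_bp")
        idx = sub.index.to_numpy()
        vals = sub["adjusted_hy"].to_numpy(float)
        pos = sub["position_bp"].to_numpy()
        for start in range(0, len(sub), window):
            stop = min(start + window, len(sub))
            v = vals[start:stop]
            q25, med, q75 = np.percentile(v, [25, 50, 75])
            win_rows.append(
                {
                    "window_id": wid,
                    "chromosome": chrom,
                    "start_bp": int(pos[start]),
                    "end_bp": int(pos[stop - 1]),
                    "n_snps": stop - start,
                    "median": med,
                    "q25": q25,
                    "q75": q75,
                    "partial": stop - start < window,
                }
            )
            pos_in_df = discriminating.index.get_indexer(idx[start:stop])
            marker_window[pos_in_df] = wid
            wid += 1
    return pd.DataFrame(win_rows), marker_window


def call_skewed_regions(
    windows: pd.DataFrame,
    band: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[float, float]]:
    """Classify windows against the genome-wide quartile band and merge runs.

    ``band`` defaults to the 25th/75th percentile of all window medians.
    A window strictly above the 75th percentile is INDICA_SKEWED, strictly
    below the 25th JAPONICA_SKEWED, otherwise NEUTRAL (a degenerate band
    therefore yields all-NEUTRAL).  Adjacent same-class skewed windows on a
    chromosome merge into intervals bounded by their first/last member SNP.
    """
    medians = windows["median"].to_numpy(float)
    if band is None:
        band = tuple(np.percentile(medians, [25, 75]))
    lo, hi = band
    skew = np.where(
        medians > hi, INDICA_SKEWED, np.where(medians < lo, JAPONICA_SKEWED, NEUTRAL)
    )
    windows = windows.assign(skew_class=skew)

    intervals = []
    for chrom, sub in windows.groupby("chromosome", sort=False):
        sub = sub.sort_values("start_bp")
        current: dict | None = None
        for row in sub.itertuples(index=False):
            if row.skew_class == NEUTRAL:
                if current is not None:
                    intervals.append(current)
                    current = None
                continue
            if current is not None and current["skew_class"] == row.skew_class:
                current["end_bp"] = row.end_bp
                current["n_windows"] += 1
            else:
                if current is not None:
                    intervals.append(current)
                current = {
                    "chromosome": chrom,
                    "start_bp": row.start_bp,
                    "end_bp": row.end_bp,
                    "skew_class": row.skew_class,
                    "n_windows": 1,
                }
        if current is not None:
            intervals.append(current)
    interval_df = pd.DataFrame(
        intervals, columns=["chromosome", "start_bp", "end_bp", "skew_class", "n_windows"]
    )
    return windows, interval_df, (float(lo), float(hi))


@dataclass
class AncestryProfile:
    """Full ancestry-scan result.

    ``discriminating`` carries per-marker indica-allele frequencies,
    adjusted HY, window membership and the window's skew call; ``windows``
    the tiled summaries with their skew class; ``intervals`` the merged
    skewed regions; ``band`` the genome-wide (q25, q75) of window medians.
    """

    discriminating: pd.DataFrame
    windows: pd.DataFrame
    intervals: pd.DataFrame
    band: tuple[float, float]
    window_size: int

    def marker_skew(self) -> pd.Series:
        """Per-marker skew call (the marker's window class), indexed by marker_id."""
        return self.discriminating.set_index("marker_id")["skew_class"]


def ancestry_profile(
    geno: GenotypeMatrix,
    panel: PopulationPanel,
    threshold: float = 0.7,
    window: int = 5,
    band_source: str = "window_median",
) -> AncestryProfile:
    """Run the full scan: discriminating SNPs -> adjusted HY -> windows -> skew.

    ``band_source`` selects what the genome-wide quartile band is computed
    over: ``"window_median"`` (default) or ``"markers"`` (per-SNP adjusted-HY
    values).
    """
    disc = find_discriminating_snps(geno, panel, threshold=threshold)
    if disc.empty:
        raise ValueError("no discriminating SNPs at this threshold")
    disc = disc.assign(
        adjusted_hy=adjusted_hy_frequency(
            disc["freq_hy"], disc["freq_pd"], disc["freq_po_indica"]
        )
    )
    windows, marker_window = window_summary(disc, window=window)
    if band_source == "window_median":
        band = None
    elif band_source == "markers":
        band = tuple(np.percentile(disc["adjusted_hy"].to_numpy(float), [25, 75]))
    else:
        raise ValueError(f"unknown band_source {band_source!r}")
    windows, intervals, band = call_skewed_regions(windows, band=band)
    disc = disc.assign(window_id=marker_window)
    disc = disc.merge(windows[["window_id", "skew_class"]], on="window_id", how="left")
    return AncestryProfile(
        discriminating=disc,
        windows=windows,
        intervals=intervals,
        band=band,
        window_size=window,
    )


def _origin_scores(
    geno: GenotypeMatrix, discriminating: pd.DataFrame, cultivars: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cultivar x marker indica scores (1/0.5/0, NaN missing)."""
    cols = geno.marker_cols(discriminating["marker_id"])
    rows = geno.cultivar_rows(cultivars)
    calls = geno.calls[np.ix_(rows, cols)]
    alt_is_indica = (
        discriminating["indica_allele"].to_numpy() == geno.alleles[cols, 1]
    )
    score = np.full(calls.shape, np.nan)
    score[calls == HET] = 0.5
    hom_alt = calls == HOM_ALT
    hom_ref = calls == HOM_REF
    score[hom_alt] = np.broadcast_to(alt_is_indica, calls.shape)[hom_alt]
    score[hom_ref] = np.broadcast_to(~alt_is_indica, calls.shape)[hom_ref]
    return score, calls


def classify_genome_types(
    geno: GenotypeMatrix,
    discriminating: pd.DataFrame,
    cultivars: Sequence[str],
    ja_max: float = 0.3,
    in_min: float = 0.7,
) -> pd.DataFrame:
    """JA / IN / MX genome-type calls from the indica-allele fraction.

    The fraction counts indica-allele copies at discriminating SNPs
    (homozygote 1, heterozygote 0.5, missing excluded); at most ``ja_max``
    is JA, at least ``in_min`` IN, in between MX.  The thresholds are
    configuration defaults, not biology, and are echoed in the output.
    Cultivars missing at more than half the discriminating SNPs are flagged
    low-confidence.
    """
    score, calls = _origin_scores(geno, discriminating, cultivars)
    n_called = (~np.isnan(score)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        frac = np.nanmean(score, axis=1)
    rows = []
    for i, cid in enumerate(cultivars):
        if n_called[i] == 0:
            rows.append(
                {
                    "cultivar_id": cid,
                    "indica_fraction": np.nan,
                    "genome_type": pd.NA,
                    "n_markers_called": 0,
                    "low_confidence": True,
                }
            )
            continue
        f = float(frac[i])
        cls = "JA" if f <= ja_max else ("IN" if f >= in_min else "MX")
        rows.append(
            {
                "cultivar_id": cid,
                "indica_fraction": f,
                "genome_type": cls,
                "n_markers_called": int(n_called[i]),
                "low_confidence": bool(n_called[i] < 0.5 * score.shape[1]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ja_max"] = ja_max
    out.attrs["in_min"] = in_min
    return out


def graphical_genotypes(
    geno: GenotypeMatrix,
    discriminating: pd.DataFrame,
    cultivars: Sequence[str],
) -> pd.DataFrame:
    """Per-cultivar parental-origin track at discriminating SNPs.

    Values: "I" indica homozygote, "J" japonica homozygote, "H"
    heterozygote, "N" missing.  Columns follow map order of the
    discriminating table; suitable for plotting a graphical genotype.
    """
    score, _ = _origin_scores(geno, discriminating, cultivars)
    out = np.full(score.shape, "N", dtype="U1")
    out[score == 1.0] = "I"
    out[score == 0.0] = "J"
    out[score == 0.5] = "H"
    return pd.DataFrame(
        out, index=list(cultivars), columns=discriminating["marker_id"].tolist()
    )
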