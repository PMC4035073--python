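"""End-to-end orchestration: ancestry scan -> association -> annotation.

Chains the stages the way the study design intends: find discriminating
SNPs and skewed introgression regions, run the permutation-calibrated MLM
scan per trait on markers representing those frequently introgressed
regions, intersect significant markers with the skew calls, and annotate
the survivors against a feature catalog.  A scoring helper compares a run
against a synthetic :class:`~introscan.simulate.TruthSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .ancestry import NEUTRAL, AncestryProfile, ancestry_profile, classify_genome_types
from .association import (
    KinshipMatrix,
    allele_effect_table,
    candidate_lookup,
    intersect_with_skew,
    kinship,
    permutation_p,
)
from .data import FeatureCatalog, GenotypeMatrix, Group, PhenotypeTable, PopulationPanel
from .simulate import TruthSet

__all__ = ["PipelineResult", "run_pipeline", "score_against_truth"]


@dataclass
class PipelineResult:
    profile: AncestryProfile
    genome_types: pd.DataFrame
    kinship: KinshipMatrix
    association: dict[str, pd.DataFrame]  # trait -> full scan with perm_p
    hits: dict[str, pd.DataFrame]  # trait -> significant & skewed markers
    candidates: dict[str, pd.DataFrame]  # trait -> feature lookups
    allele_effects: dict[str, pd.DataFrame]
    association_marker_ids: list[str]


def run_pipeline(
    geno: GenotypeMatrix,
    panel: PopulationPanel,
    phenotypes: PhenotypeTable,
    features: FeatureCatalog | None = None,
    traits: Sequence[str] | None = None,
    threshold: float = 0.7,
    window: int = 5,
    alpha: float = 0.01,
    n_perm: int = 500,
    seed: int = 0,
    association_markers: str | Sequence[str] = "skewed",
    window_bp: int = 4_000_000,
) -> PipelineResult:
    """Run the full introgression-to-phenotype pipeline.

    ``association_markers`` selects the marker set the MLM scan tests:
    ``"skewed"`` (default) restricts to discriminating SNPs whose window is
    skewed — the study logic of testing SNPs that represent frequently
    introgressed regions — ``"all"`` tests every marker passing the
    MAF/call-rate filter, and an explicit list is used as-is.  Phenotypes
    are taken from HY cultivars; permutation P-values use ``n_perm``
    max-statistic permutations seeded from ``seed``.
    """
    profile = ancestry_profile(geno, panel, threshold=threshold, window=window)
    hy = [c for c in panel.members(Group.HY) if c in geno._cultivar_index]
    genome_types = classify_genome_types(geno, profile.discriminating, hy)
    k = kinship(geno, hy)
    marker_skew = profile.marker_skew()
    if isinstance(association_markers, str):
        if association_markers == "skewed":
            assoc_ids = marker_skew[marker_skew != NEUTRAL].index.tolist()
        elif association_markers == "all":
            assoc_ids = None
        else:
            raise ValueError(f"unknown association marker mode {association_markers!r}")
    else:
        assoc_ids = list(association_markers)

    traits = list(traits) if traits is not None else phenotypes.traits
    association: dict[str, pd.DataFrame] = {}
    hits: dict[str, pd.DataFrame] = {}
    candidates: dict[str, pd.DataFrame] = {}
    effects: dict[str, pd.DataFrame] = {}
    for i, trait in enumerate(traits):
        y = phenotypes.trait(trait)
        res = permutation_p(
            y, geno, k, n_perm=n_perm, seed=seed + i, marker_ids=assoc_ids
        )
        trait_hits = intersect_with_skew(res, marker_skew, alpha=alpha)
        disc_alleles = profile.discriminating[["marker_id", "indica_allele"]]
        trait_hits = trait_hits.merge(disc_alleles, on="marker_id", how="left")
        association[trait] = res
        hits[trait] = trait_hits
        effects[trait] = allele_effect_table(trait_hits, y, geno)
        if features is not None:
            candidates[trait] = candidate_lookup(
                trait_hits, features, trait_category=trait, window_bp=window_bp
            )
    resolved_assoc = (
        assoc_ids
        if assoc_ids is not None
        else list(geno.markers.marker_ids)
    )
    return PipelineResult(
        profile=profile,
        genome_types=genome_types,
        kinship=k,
        association=association,
        hits=hits,
        candidates=candidates,
        allele_effects=effects,
        association_marker_ids=resolved_assoc,
    )


def score_against_truth(result: PipelineResult, truth: TruthSet) -> dict:
    """Score a pipeline run against the generator's ground truth.

    Returns counts of planted skew regions overlapped by a called interval
    of the matching class, planted QTL markers that are significant and
    skewed for their trait, and planted QTLs whose gene feature was
    reported by the candidate lookup.
    """
    iv = result.profile.intervals
    regions_hit = 0
    for region in truth.skew_regions:
        klass = (
            "INDICA_SKEWED" if region.target_indica_freq >= 0.5 else "JAPONICA_SKEWED"
        )
        overlap = (
            (iv["chromosome"] == region.chromosome)
            & (iv["start_bp"] <= region.end_bp)
            & (iv["end_bp"] >= region.start_bp)
            & (iv["skew_class"] == klass)
        )
        regions_hit += int(overlap.any())

    qtl_hits = 0
    genes_found = 0
    for rec in truth.qtls.itertuples(index=False):
        trait_hits = result.hits.get(rec.trait)
        if trait_hits is not None and rec.marker_id in set(trait_hits["marker_id"]):
            qtl_hits += 1
        cand = result.candidates.get(rec.trait)
        if cand is not None and f"GENE_{rec.trait}" in set(cand["feature_id"]):
            genes_found += 1

    return {
        "n_skew_regions_planted": len(truth.skew_regions),
        "n_skew_regions_recovered": regions_hit,
        "n_qtls_planted": len(truth.qtls),
        "n_qtls_significant_and_skewed": qtl_hits,
        "n_candidate_genes_recovered": genes_found,
    }
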