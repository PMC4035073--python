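"""Synthetic breeding-population generator with ground truth.

Emulates the data structure the analysis assumes: two diverged, essentially
homozygous parental pools (overseas indica and domestic japonica), admixed
high-yielding progeny whose genomes are recombination mosaics of the two
origins, regional selection skew (intervals where the indica-origin
frequency across progeny is pushed to a target), and quantitative traits
driven by QTLs plus a polygenic term.  Every draw is reproducible from the
config seed, and a :class:`TruthSet` records the planted intervals, QTLs and
per-cultivar origin tracks so each pipeline stage can be scored without
re-reading the config.

Selection at skewed regions is modeled by resampling the origin of the whole
region per cultivar toward the target frequency rather than by explicit
multi-generation truncation selection: the analysis only consumes the
resulting frequency skew, not the breeding dynamics.  Recombination mosaics
use exponential block lengths (Markovian ancestry), a standard first-order
approximation for pedigree mosaics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    FeatureCatalog,
    GenotypeMatrix,
    Group,
    MarkerMap,
    PhenotypeTable,
    PopulationPanel,
    write_features,
    write_genotypes_tabular,
    write_genotypes_vcf,
    write_panel,
    write_phenotypes,
)
from .association import kinship

__all__ = [
    "SkewRegion",
    "QTLSpec",
    "SimulationConfig",
    "TruthSet",
    "FixtureBundle",
    "simulate_parents",
    "simulate_admixed",
    "simulate_phenotypes",
    "generate_fixture",
]


@dataclass(frozen=True)
class SkewRegion:
    """Interval where the indica-origin frequency across HY lines is forced."""

    chromosome: str
    start_bp: int
    end_bp: int
    target_indica_freq: float


@dataclass(frozen=True)
class QTLSpec:
    """A planted causal locus: placed at the nearest suitable marker.

    ``var_explained`` is the target fraction of trait variance attributable
    to the QTL (the regression coefficient is derived from the realized
    dosage variance).
    """

    chromosome: str
    position_bp: int
    var_explained: float
    trait: str


def _default_skew_regions() -> list[SkewRegion]:
    return [
        SkewRegion("chr01", 5_000_000, 9_000_000, 0.9),
        SkewRegion("chr07", 10_000_000, 14_000_000, 0.9),
        SkewRegion("chr11", 18_000_000, 22_000_000, 0.9),
    ]


def _default_qtls() -> list[QTLSpec]:
    return [
        QTLSpec("chr01", 7_000_000, 0.30, "heading_date"),
        QTLSpec("chr07", 12_000_000, 0.30, "seed_surface_area"),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror a small rice breeding panel.

    12 chromosomes of 30 Mb genotyped at 1200 markers; 14 parents per pool
    (the size of the founder screen); 60 admixed lines; 70% of markers with
    a fixed allele-frequency difference between the pools and the remainder
    with Beta(2,2)-distributed partial divergence; 5-Mb mean ancestry
    blocks over a 30% genome-wide indica background; three 4-Mb regions
    skewed to 0.9 indica frequency; two QTLs inside skewed regions, each
    targeting 30% of the variance of its trait at heritability 0.5.
    """

    n_chromosomes: int = 12
    chromosome_length_bp: int = 30_000_000
    n_markers: int = 1200
    n_po_indica: int = 14
    n_pd: int = 14
    n_hy: int = 60
    fixed_diff_fraction: float = 0.7
    partial_divergence_beta: tuple[float, float] = (2.0, 2.0)
    background_indica_freq: float = 0.3
    block_length_mean_bp: float = 5_000_000.0
    skew_regions: list[SkewRegion] = field(default_factory=_default_skew_regions)
    qtls: list[QTLSpec] = field(default_factory=_default_qtls)
    heritability: float = 0.5
    het_rate: float = 0.005
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.skew_regions = [
            r if isinstance(r, SkewRegion) else SkewRegion(*r) for r in self.skew_regions
        ]
        self.qtls = [q if isinstance(q, QTLSpec) else QTLSpec(*q) for q in self.qtls]
        if self.n_markers < self.n_chromosomes:
            raise ValueError("need at least one marker per chromosome")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")
        for r in self.skew_regions:
            if not 0.0 <= r.target_indica_freq <= 1.0:
                raise ValueError("skew target frequency must be in [0, 1]")
        if not 0.0 <= self.background_indica_freq <= 1.0:
            raise ValueError("background indica frequency must be in [0, 1]")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chromosomes)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "skew_regions" in raw:
            raw["skew_regions"] = [SkewRegion(**r) for r in raw["skew_regions"]]
        if "qtls" in raw:
            raw["qtls"] = [QTLSpec(**q) for q in raw["qtls"]]
        if "partial_divergence_beta" in raw:
            raw["partial_divergence_beta"] = tuple(raw["partial_divergence_beta"])
        return cls(**raw)


@dataclass
class TruthSet:
    """Ground truth sufficient to score every pipeline stage."""

    skew_regions: list[SkewRegion]
    qtls: pd.DataFrame  # marker_id, chromosome, position_bp, trait, var_explained, beta
    origin_tracks: pd.DataFrame  # HY cultivar x marker, 1 = indica origin
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "skew_regions": [dataclasses.asdict(r) for r in self.skew_regions],
            "qtls": self.qtls.to_dict(orient="records"),
            "config": dataclasses.asdict(self.config),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=list)


@dataclass
class FixtureBundle:
    geno: GenotypeMatrix  # parents + HY, one matrix
    panel: PopulationPanel
    phenotypes: PhenotypeTable
    features: FeatureCatalog
    truth: TruthSet


# ---------------------------------------------------------------------------


def _marker_layout(config: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    """Markers allocated as evenly as possible, uniform positions per chromosome."""
    chroms = config.chromosome_names()
    base, extra = divmod(config.n_markers, config.n_chromosomes)
    ids, chrom_col, pos_col = [], [], []
    for i, chrom in enumerate(chroms):
        n = base + (1 if i < extra else 0)
        pos = np.sort(rng.integers(1, config.chromosome_length_bp + 1, size=n))
        while len(np.unique(pos)) < n:  # resolve rare collisions
            pos = np.unique(pos)
            pos = np.sort(
                np.concatenate(
                    [pos, rng.integers(1, config.chromosome_length_bp + 1, size=n - len(pos))]
                )
            )
        ids.extend(f"{chrom}_M{k:04d}" for k in range(n))
        chrom_col.extend([chrom] * n)
        pos_col.extend(int(p) for p in pos)
    return MarkerMap.from_arrays(ids, chrom_col, pos_col)


def simulate_parents(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationPanel, np.ndarray]:
    """Two homozygous parental pools with the configured divergence.

    Returns (genotypes, panel, is_fixed_difference) where the boolean vector
    marks markers with a fixed allele-frequency difference between pools
    (the alt allele is always the indica-enriched allele).
    """
    rng = np.random.default_rng([config.seed, 1])
    markers = _marker_layout(config, rng)
    m = len(markers)

    is_fixed = rng.random(m) < config.fixed_diff_fraction
    a, b = config.partial_divergence_beta
    diff = np.where(is_fixed, 1.0, rng.beta(a, b, size=m))
    p_jap = np.where(is_fixed, 0.0, rng.uniform(0.0, 1.0, size=m) * (1.0 - diff))
    p_ind = p_jap + diff

    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    alleles = np.stack([bases[ref_idx], bases[(ref_idx + alt_shift) % 4]], axis=1)

    po_calls = np.where(
        rng.random((config.n_po_indica, m)) < p_ind, HOM_ALT, HOM_REF
    ).astype(np.int8)
    pd_calls = np.where(rng.random((config.n_pd, m)) < p_jap, HOM_ALT, HOM_REF).astype(
        np.int8
    )

    po_ids = [f"PO_IND_{i + 1:02d}" for i in range(config.n_po_indica)]
    pd_ids = [f"PD_{i + 1:02d}" for i in range(config.n_pd)]
    geno = GenotypeMatrix(
        markers=markers,
        cultivar_ids=po_ids + pd_ids,
        calls=np.vstack([po_calls, pd_calls]),
        alleles=alleles,
    )
    panel = PopulationPanel(
        {**{c: Group.PO_INDICA for c in po_ids}, **{c: Group.PD for c in pd_ids}}
    )
    return geno, panel, is_fixed


def _mosaic_tracks(
    config: SimulationConfig,
    markers: MarkerMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """HY x marker parental-origin matrix (1 = indica), before skew overwrite."""
    m = len(markers)
    origins = np.zeros((config.n_hy, m), dtype=np.int8)
    chroms = markers.chromosomes
    positions = markers.positions
    for chrom in config.chromosome_names():
        cols = np.flatnonzero(chroms == chrom)
        if len(cols) == 0:
            continue
        pos = positions[cols]
        length = config.chromosome_length_bp
        for i in range(config.n_hy):
            cut = 0.0
            while cut < length:
                seg_len = rng.exponential(config.block_length_mean_bp)
                origin = int(rng.random() < config.background_indica_freq)
                in_seg = (pos > cut) & (pos <= cut + seg_len)
                origins[i, cols[in_seg]] = origin
                cut += seg_len
    # selection skew: resample whole-region origin per cultivar
    for region in config.skew_regions:
        cols = np.flatnonzero(
            (chroms == region.chromosome)
            & (positions >= region.start_bp)
            & (positions <= region.end_bp)
        )
        if region.start_bp < 1 or region.end_bp > config.chromosome_length_bp:
            raise ValueError(f"skew region {region} outside chromosome bounds")
        if len(cols) == 0:
            continue
        region_origin = (rng.random(config.n_hy) < region.target_indica_freq).astype(
            np.int8
        )
        origins[:, cols] = region_origin[:, None]
    return origins


def simulate_admixed(
    parents: GenotypeMatrix,
    panel: PopulationPanel,
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Mosaic HY progeny: each marker copies a random cultivar of its origin pool.

    Returns (HY genotypes on the parents' marker map, origin tracks).
    Heterozygous and missing calls are sprinkled in last at the configured
    rates.
    """
    rng = np.random.default_rng([config.seed, 2])
    origins = _mosaic_tracks(config, parents.markers, rng)
    n_hy, m = origins.shape

    po_rows = parents.cultivar_rows(panel.members(Group.PO_INDICA))
    pd_rows = parents.cultivar_rows(panel.members(Group.PD))
    pick_po = po_rows[rng.integers(0, len(po_rows), size=(n_hy, m))]
    pick_pd = pd_rows[rng.integers(0, len(pd_rows), size=(n_hy, m))]
    col = np.arange(m)[None, :]
    calls = np.where(
        origins == 1, parents.calls[pick_po, col], parents.calls[pick_pd, col]
    ).astype(np.int8)

    het_mask = rng.random((n_hy, m)) < config.het_rate
    calls[het_mask] = HET
    missing_mask = rng.random((n_hy, m)) < config.missing_rate
    calls[missing_mask] = MISSING

    hy_ids = [f"HY_{i + 1:03d}" for i in range(n_hy)]
    hy_geno = GenotypeMatrix(
        markers=MarkerMap(parents.markers.table.copy()),
        cultivar_ids=hy_ids,
        calls=calls,
        alleles=parents.alleles.copy(),
    )
    return hy_geno, origins


def _resolve_qtl_markers(
    config: SimulationConfig,
    hy_geno: GenotypeMatrix,
    is_fixed: np.ndarray,
    min_maf: float = 0.05,
) -> list[str]:
    """Nearest fixed-difference marker to each requested QTL position.

    Only markers that actually segregate in the progeny (minor-allele
    frequency >= ``min_maf`` among HY lines) are eligible: a planted causal
    locus that does not segregate in the mapping population carries no
    mappable signal, so such markers cannot host a QTL.
    """
    markers = hy_geno.markers
    with np.errstate(invalid="ignore"):
        d = hy_geno.dosage()
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(d, axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
    segregating = np.nan_to_num(maf, nan=0.0) >= min_maf
    out = []
    for q in config.qtls:
        cols = np.flatnonzero(
            (markers.chromosomes == q.chromosome) & is_fixed & segregating
        )
        if len(cols) == 0:
            raise ValueError(
                f"no segregating fixed-difference marker on {q.chromosome} for {q}"
            )
        j = cols[np.argmin(np.abs(markers.positions[cols] - q.position_bp))]
        out.append(markers.marker_ids[j])
    return out


def simulate_phenotypes(
    hy_geno: GenotypeMatrix,
    config: SimulationConfig,
    qtl_marker_ids: list[str] | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """QTL + polygenic + noise traits with controlled variance fractions.

    Each trait is built on unit total-variance scale: every QTL contributes
    its target variance fraction, a kinship-distributed polygenic term fills
    the remaining heritability, and Gaussian noise supplies 1 - h^2.  Each
    component is rescaled to its target sample variance, and the polygenic
    and noise components are made in-sample orthogonal to the QTL dosages,
    so the realized variance decomposition matches the configured one.
    ``heritability = 0`` yields pure noise.  Returns (phenotypes, qtl truth
    records).
    """
    rng = np.random.default_rng([config.seed, 3])
    if qtl_marker_ids is None:
        # nearest marker regardless of divergence
        qtl_marker_ids = []
        for q in config.qtls:
            cols = np.flatnonzero(hy_geno.markers.chromosomes == q.chromosome)
            j = cols[np.argmin(np.abs(hy_geno.markers.positions[cols] - q.position_bp))]
            qtl_marker_ids.append(hy_geno.markers.marker_ids[j])

    n = hy_geno.n_cultivars
    traits = list(dict.fromkeys(q.trait for q in config.qtls)) or ["null_trait"]
    h2 = config.heritability

    k = kinship(hy_geno).matrix if h2 > 0 else None
    if k is not None:
        chol = np.linalg.cholesky(k + 1e-6 * np.eye(n))

    def _scaled(v: np.ndarray, target_var: float) -> np.ndarray:
        sv = np.var(v)
        if sv <= 0:
            return np.zeros_like(v)
        return (v - v.mean()) * np.sqrt(target_var / sv)

    def _residualize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
        # project out the QTL dosages so non-QTL components cannot erode or
        # inflate the planted marginal variance fractions
        if not basis:
            return v
        b = np.column_stack([np.ones(n)] + basis)
        qmat, _ = np.linalg.qr(b)
        return v - qmat @ (qmat.T @ v)

    qtl_records = []
    values: dict[str, np.ndarray] = {}
    for trait in traits:
        y = np.zeros(n)
        qtl_var = 0.0
        dosages: list[np.ndarray] = []
        for q, mid in zip(config.qtls, qtl_marker_ids):
            if q.trait != trait:
                continue
            j = hy_geno.marker_cols([mid])[0]
            d = hy_geno.dosage()[:, j]
            d = np.where(np.isnan(d), np.nanmean(d), d)
            component = _scaled(d, q.var_explained)
            beta = (
                float(np.sqrt(q.var_explained / np.var(d))) if np.var(d) > 0 else 0.0
            )
            y = y + component
            dosages.append(d)
            qtl_var += q.var_explained
            qtl_records.append(
                {
                    "marker_id": mid,
                    "chromosome": hy_geno.markers.chromosomes[j],
                    "position_bp": int(hy_geno.markers.positions[j]),
                    "trait": trait,
                    "var_explained": q.var_explained,
                    "beta": beta,
                }
            )
        poly_var = max(h2 - qtl_var, 0.0)
        if poly_var > 0 and k is not None:
            y = y + _scaled(
                _residualize(chol @ rng.standard_normal(n), dosages), poly_var
            )
        noise_var = max(1.0 - min(qtl_var + poly_var, 1.0), 0.0)
        if noise_var > 0:
            y = y + _scaled(_residualize(rng.standard_normal(n), dosages), noise_var)
        values[trait] = y

    pheno = PhenotypeTable(pd.DataFrame(values, index=hy_geno.cultivar_ids))
    return pheno, pd.DataFrame(
        qtl_records,
        columns=["marker_id", "chromosome", "position_bp", "trait", "var_explained", "beta"],
    )


def _build_features(
    config: SimulationConfig,
    qtl_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> FeatureCatalog:
    """One GENE at each planted QTL plus decoy features elsewhere."""
    rows = []
    for rec in qtl_truth.itertuples(index=False):
        rows.append(
            {
                "feature_id": f"GENE_{rec.trait}",
                "feature_kind": "GENE",
                "chromosome": rec.chromosome,
                "start_bp": max(1, rec.position_bp - 25_000),
                "end_bp": rec.position_bp + 25_000,
                "trait_category": rec.trait,
            }
        )
    traits = list(qtl_truth["trait"].unique()) or ["none"]
    qtl_chroms = set(qtl_truth["chromosome"])
    for i, chrom in enumerate(config.chromosome_names()):
        pos = int(rng.integers(1, config.chromosome_length_bp))
        # decoys on QTL chromosomes get a foreign category so category
        # filtering, not luck, is what excludes them
        category = "decoy" if chrom in qtl_chroms else traits[i % len(traits)]
        rows.append(
            {
                "feature_id": f"DECOY_GENE_{chrom}",
                "feature_kind": "GENE",
                "chromosome": chrom,
                "start_bp": pos,
                "end_bp": pos + 10_000,
                "trait_category": category,
            }
        )
        qpos = int(rng.integers(1, config.chromosome_length_bp - 2_000_000))
        rows.append(
            {
                "feature_id": f"DECOY_QTL_{chrom}",
                "feature_kind": "QTL",
                "chromosome": chrom,
                "start_bp": qpos,
                "end_bp": qpos + 2_000_000,
                "trait_category": traits[(i + 1) % len(traits)],
            }
        )
    return FeatureCatalog(pd.DataFrame(rows))


def generate_fixture(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> FixtureBundle:
    """Generate the complete bundle; optionally write it to disk.

    The on-disk bundle contains genotypes.tsv, genotypes.vcf, panel.csv,
    phenotypes.csv, features.bed, origin_tracks.tsv and truth.json, all in
    the formats the readers accept, byte-identical across runs at a fixed
    seed.
    """
    config = config or SimulationConfig()
    parents, panel, is_fixed = simulate_parents(config)
    hy_geno, origins = simulate_admixed(parents, panel, config)
    qtl_marker_ids = _resolve_qtl_markers(config, hy_geno, is_fixed)
    pheno, qtl_truth = simulate_phenotypes(hy_geno, config, qtl_marker_ids)

    full_panel = PopulationPanel(
        {**panel.assignments, **{c: Group.HY for c in hy_geno.cultivar_ids}}
    )
    combined = GenotypeMatrix(
        markers=MarkerMap(parents.markers.table.copy()),
        cultivar_ids=parents.cultivar_ids + hy_geno.cultivar_ids,
        calls=np.vstack([parents.calls, hy_geno.calls]),
        alleles=parents.alleles.copy(),
    )
    features = _build_features(
        config, qtl_truth, np.random.default_rng([config.seed, 4])
    )
    truth = TruthSet(
        skew_regions=list(config.skew_regions),
        qtls=qtl_truth,
        origin_tracks=pd.DataFrame(
            origins,
            index=hy_geno.cultivar_ids,
            columns=hy_geno.markers.marker_ids,
        ),
        config=config,
    )
    bundle = FixtureBundle(combined, full_panel, pheno, features, truth)

    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(
                f"output directory {out} is not empty; pass force=True to overwrite"
            )
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes_tabular(combined, out / "genotypes.tsv")
        write_genotypes_vcf(combined, out / "genotypes.vcf")
        write_panel(full_panel, out / "panel.csv")
        write_phenotypes(pheno, out / "phenotypes.csv")
        write_features(features, out / "features.bed")
        truth.origin_tracks.rename_axis("cultivar_id").to_csv(
            out / "origin_tracks.tsv", sep="\t"
        )
        (out / "truth.json").write_text(truth.to_json())
    return bundle
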