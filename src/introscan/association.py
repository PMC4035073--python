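"""Mixed-linear-model marker-trait association with permutation calibration.

The scan fits, per trait, the model

    y = mu + x beta + u + e,   u ~ (0, sg^2 K),   e ~ (0, se^2 I)

with K a VanRaden genomic relationship matrix.  Variance components are
estimated once on the null model by REML profiled over the ratio
lambda = sg^2 / se^2 (the P3D / EMMAX approximation), after which every
marker is tested by generalized least squares, which reduces to ordinary
least squares on whitened data.  Family-wise empirical P-values come from a
max-statistic permutation scheme: the phenotype vector is permuted across
cultivars, the genome-wide maximum F is recorded per permutation, and
perm_p = (1 + #{max F >= observed F}) / (n_perm + 1).

Significant markers are intersected with the ancestry scan's skew calls and
annotated against a user-supplied catalog of candidate genes and QTLs within
a centered genomic window (default 4 Mb).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import HOM_ALT, HOM_REF, FeatureCatalog, GenotypeMatrix

logger = logging.getLogger("introscan.association")

__all__ = [
    "KinshipMatrix",
    "kinship",
    "mlm_scan",
    "permutation_p",
    "intersect_with_skew",
    "candidate_lookup",
    "allele_effect_table",
]


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix with its cultivar order."""

    cultivar_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.cultivar_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kinship matrix shape does not match cultivar list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    def subset(self, cultivars: Sequence[str]) -> "KinshipMatrix":
        index = {c: i for i, c in enumerate(self.cultivar_ids)}
        rows = np.array([index[c] for c in cultivars], dtype=int)
        return KinshipMatrix(list(cultivars), self.matrix[np.ix_(rows, rows)])


def kinship(
    geno: GenotypeMatrix, cultivars: Sequence[str] | None = None
) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    Centered alt-dosage cross-product scaled by sum(2 p (1 - p)) over
    polymorphic markers; missing dosages are mean-imputed per marker for
    this computation only.
    """
    cultivars = (
        list(geno.cultivar_ids) if cultivars is None else list(cultivars)
    )
    if len(cultivars) < 2:
        raise ValueError("kinship needs at least two cultivars")
    d = geno.dosage(cultivars)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic markers for kinship")
    d = d[:, poly]
    p = p[poly]
    nan_mask = np.isnan(d)
    d[nan_mask] = np.broadcast_to(2.0 * p, d.shape)[nan_mask]
    z = d - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return KinshipMatrix(cultivars, (z @ z.T) / denom)


# ---------------------------------------------------------------------------
# REML / GLS machinery


def _reml_lambda(
    y: np.ndarray, x_null: np.ndarray, s: np.ndarray, ut: np.ndarray,
    log10_bounds: tuple[float, float] = (-10.0, 10.0), tol: float = 1e-6,
) -> float:
    """Profile-REML estimate of lambda = sg^2/se^2 on the null model.

    ``s``/``ut`` are the eigenvalues / transposed eigenvectors of K; the
    search is a bounded scalar minimization over log10(lambda).
    """
    yt = ut @ y
    xt = ut @ x_null
    n, p = xt.shape

    def neg_reml(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        dvec = lam * s + 1.0
        w = 1.0 / dvec
        xtw = xt * w[:, None]
        xx = xt.T @ xtw
        try:
            beta = np.linalg.solve(xx, xtw.T @ y_col)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - xt @ beta.ravel()
        rss = float(np.sum(w * r * r))
        if rss <= 0:
            return np.inf
        sign, logdet_xx = np.linalg.slogdet(xx)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rss) + np.sum(np.log(dvec)) + logdet_xx
        )

    y_col = yt[:, None]
    res = optimize.minimize_scalar(
        neg_reml, bounds=log10_bounds, method="bounded",
        options={"xatol": tol},
    )
    return float(10.0**res.x)


def _whiten(lam: float, s: np.ndarray, ut: np.ndarray) -> np.ndarray:
    """Whitening transform W with W V W' = I (up to se^2)."""
    dvec = lam * s + 1.0
    return ut / np.sqrt(dvec)[:, None]


def _gls_f_stats(
    yw: np.ndarray, xw: np.ndarray, cw: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-marker GLS F statistics on whitened data.

    ``yw``: (n, t) whitened phenotypes; ``xw``: (n, m) whitened marker
    dosages; ``cw``: (n, q) whitened nuisance design (intercept and any
    covariates).  Both y and x are residualized on ``cw``; the marker slope
    is then tested with an F(1, n - q - 1) statistic.  Returns
    (beta (m, t), F (m, t), denominator df).
    """
    n, q = cw.shape
    qmat, _ = np.linalg.qr(cw)
    yr = yw - qmat @ (qmat.T @ yw)
    xr = xw - qmat @ (qmat.T @ xw)
    sxx = np.sum(xr * xr, axis=0)  # (m,)
    sxy = xr.T @ yr  # (m, t)
    syy = np.sum(yr * yr, axis=0)  # (t,)
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx[:, None]
        ssr = sxy**2 / sxx[:, None]
        rss = syy[None, :] - ssr
        f = ssr / (rss / df)
    # degenerate cases: monomorphic marker (sxx = 0) or constant phenotype
    beta[sxx == 0.0, :] = np.nan
    f[sxx == 0.0, :] = np.nan
    const_y = syy <= 1e-12 * np.maximum(np.sum(yw * yw, axis=0), 1e-300)
    if const_y.any():
        beta[:, const_y] = 0.0
        f[:, const_y] = 0.0
    f = np.where((f < 0) & np.isfinite(f), 0.0, f)
    return beta, f, df


@dataclass
class _MLMContext:
    cultivars: list[str]
    y: np.ndarray
    marker_ids: list[str]
    chromosomes: np.ndarray
    positions: np.ndarray
    dosages: np.ndarray  # (n, m), mean-imputed
    lam: float
    whitener: np.ndarray  # (n, n)
    cw: np.ndarray  # whitened nuisance design
    skipped: list[str]


def _prepare(
    y: pd.Series,
    geno: GenotypeMatrix,
    k: KinshipMatrix,
    marker_ids: Sequence[str] | None,
    maf_min: float,
    call_rate_min: float,
    covariates: pd.DataFrame | None,
) -> _MLMContext:
    used = [
        c
        for c in k.cultivar_ids
        if c in geno._cultivar_index and c in y.index and np.isfinite(y.get(c, np.nan))
    ]
    if len(used) < 10:
        raise ValueError(
            f"only {len(used)} cultivars with phenotype, genotype and kinship; need >= 10"
        )
    yv = y.loc[used].to_numpy(float)
    ksub = k.subset(used)
    s, u = np.linalg.eigh(ksub.matrix)
    s = np.clip(s, 0.0, None)
    ut = u.T

    cols = (
        np.arange(geno.n_markers)
        if marker_ids is None
        else geno.marker_cols(marker_ids)
    )
    d = geno.dosage(used)[:, cols]
    call_rate = np.mean(~np.isnan(d), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    maf_v = np.minimum(p, 1.0 - p)
    ok = (call_rate >= call_rate_min) & (maf_v >= maf_min) & ~np.isnan(p)
    skipped = [geno.markers.marker_ids[cols[j]] for j in np.flatnonzero(~ok)]
    if skipped:
        logger.info(
            "%d marker(s) skipped by the association filter (monomorphic, "
            "MAF < %.3g or call rate < %.3g)",
            len(skipped), maf_min, call_rate_min,
        )
    cols = cols[ok]
    d = d[:, ok]
    p = p[ok]
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d[nan_mask] = np.broadcast_to(2.0 * p, d.shape)[nan_mask]

    design = [np.ones((len(used), 1))]
    if covariates is not None:
        design.append(covariates.loc[used].to_numpy(float))
    c = np.hstack(design)

    lam = _reml_lambda(yv, c, s, ut)
    w = _whiten(lam, s, ut)
    return _MLMContext(
        cultivars=used,
        y=yv,
        marker_ids=[geno.markers.marker_ids[j] for j in cols],
        chromosomes=geno.markers.chromosomes[cols],
        positions=geno.markers.positions[cols],
        dosages=d,
        lam=lam,
        whitener=w,
        cw=w @ c,
        skipped=skipped,
    )


def mlm_scan(
    y: pd.Series,
    geno: GenotypeMatrix,
    k: KinshipMatrix,
    marker_ids: Sequence[str] | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single-trait MLM scan; returns nominal statistics per marker.

    ``y`` is a Series indexed by cultivar_id (NaN = missing); cultivars are
    intersected with the kinship and genotype matrices.  Markers failing the
    MAF / call-rate filter among the phenotyped lines are skipped and
    logged.  The fitted variance ratio is echoed in ``result.attrs["lambda"]``.
    """
    ctx = _prepare(y, geno, k, marker_ids, maf_min, call_rate_min, covariates)
    yw = (ctx.whitener @ ctx.y)[:, None]
    xw = ctx.whitener @ ctx.dosages
    beta, f, df = _gls_f_stats(yw, xw, ctx.cw)
    f1 = f[:, 0]
    pvals = stats.f.sf(f1, 1, df)
    out = pd.DataFrame(
        {
            "marker_id": ctx.marker_ids,
            "chromosome": ctx.chromosomes,
            "position_bp": ctx.positions,
            "n_used": len(ctx.cultivars),
            "beta": beta[:, 0],
            "f_stat": f1,
            "p_value": pvals,
            "neglog10_p": -np.log10(np.clip(pvals, 1e-300, None)),
        }
    )
    out.attrs["lambda"] = ctx.lam
    out.attrs["df_denominator"] = df
    out.attrs["skipped_markers"] = ctx.skipped
    return out


def permutation_p(
    y: pd.Series,
    geno: GenotypeMatrix,
    k: KinshipMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    marker_ids: Sequence[str] | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Family-wise empirical P-values by max-statistic phenotype permutation.

    The phenotype vector is permuted across cultivars ``n_perm`` times
    (seeded); for each permutation the scan's genome-wide maximum F is
    recorded and perm_p(marker) = (1 + #{max F >= F_obs}) / (n_perm + 1).
    The variance ratio is held at the observed-data null fit (P3D), so each
    permutation costs one whitened OLS pass.  Returns the nominal scan
    augmented with a ``perm_p`` column.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse permutation resolution "
            f"(smallest attainable P = {1.0 / (n_perm + 1):.3g})",
            stacklevel=2,
        )
    ctx = _prepare(y, geno, k, marker_ids, maf_min, call_rate_min, covariates)
    n = len(ctx.y)
    yw = (ctx.whitener @ ctx.y)[:, None]
    xw = ctx.whitener @ ctx.dosages
    beta, f_obs, df = _gls_f_stats(yw, xw, ctx.cw)
    f_obs = f_obs[:, 0]

    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)]).T  # (n, n_perm)
    yperm = ctx.y[perm_idx]
    ywp = ctx.whitener @ yperm
    _, f_perm, _ = _gls_f_stats(ywp, xw, ctx.cw)  # (m, n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_f = np.nanmax(f_perm, axis=0)  # (n_perm,)
    exceed = (max_f[None, :] >= f_obs[:, None]).sum(axis=1)
    perm_p = (1.0 + exceed) / (n_perm + 1.0)

    pvals = stats.f.sf(f_obs, 1, df)
    out = pd.DataFrame(
        {
            "marker_id": ctx.marker_ids,
            "chromosome": ctx.chromosomes,
            "position_bp": ctx.positions,
            "n_used": n,
            "beta": beta[:, 0],
            "f_stat": f_obs,
            "p_value": pvals,
            "neglog10_p": -np.log10(np.clip(pvals, 1e-300, None)),
            "perm_p": perm_p,
        }
    )
    out.attrs["lambda"] = ctx.lam
    out.attrs["n_perm"] = n_perm
    out.attrs["df_denominator"] = df
    return out


def intersect_with_skew(
    results: pd.DataFrame, marker_skew: pd.Series, alpha: float = 0.01
) -> pd.DataFrame:
    """Markers with perm_p strictly below ``alpha`` in a non-neutral window.

    ``marker_skew`` maps marker_id -> skew class (from the ancestry
    profile); markers absent from it are treated as having no skew call and
    are dropped.
    """
    skew = results["marker_id"].map(marker_skew)
    keep = (results["perm_p"] < alpha) & skew.notna() & (skew != "NEUTRAL")
    out = results.loc[keep].copy()
    out["skew_class"] = skew[keep]
    return out


def candidate_lookup(
    hits: pd.DataFrame,
    features: FeatureCatalog,
    trait_category: str | None = None,
    window_bp: int = 4_000_000,
) -> pd.DataFrame:
    """Candidate genes/QTLs within a window centered on each significant SNP.

    The window is [pos - window_bp/2, pos + window_bp/2], closed at both
    ends and clipped at the chromosome start.  GENE features in the matching
    trait category are queried first; only if none overlap are QTL features
    reported.  An unknown trait category drops the category filter with a
    warning.  ``hits`` needs marker_id, chromosome, position_bp columns.
    """
    ft = features.table
    if trait_category is not None:
        if trait_category in set(ft["trait_category"]):
            ft = ft[ft["trait_category"] == trait_category]
        else:
            warnings.warn(
                f"trait category {trait_category!r} not present in the feature "
                "catalog; searching without a category filter",
                stacklevel=2,
            )
    half = window_bp // 2
    rows = []
    for hit in hits.itertuples(index=False):
        pos = int(hit.position_bp)
        lo = max(1, pos - half)
        hi = pos + half
        on_chrom = ft[ft["chromosome"] == hit.chromosome]
        overlap = on_chrom[(on_chrom["start_bp"] <= hi) & (on_chrom["end_bp"] >= lo)]
        genes = overlap[overlap["feature_kind"] == "GENE"]
        chosen = genes if len(genes) else overlap[overlap["feature_kind"] == "QTL"]
        for feat in chosen.itertuples(index=False):
            if feat.start_bp <= pos <= feat.end_bp:
                dist = 0
            else:
                dist = int(min(abs(feat.start_bp - pos), abs(feat.end_bp - pos)))
            rows.append(
                {
                    "marker_id": hit.marker_id,
                    "chromosome": hit.chromosome,
                    "position_bp": pos,
                    "window_start_bp": lo,
                    "window_end_bp": hi,
                    "feature_id": feat.feature_id,
                    "feature_kind": feat.feature_kind,
                    "feature_start_bp": int(feat.start_bp),
                    "feature_end_bp": int(feat.end_bp),
                    "trait_category": feat.trait_category,
                    "distance_bp": dist,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "chromosome",
            "position_bp",
            "window_start_bp",
            "window_end_bp",
            "feature_id",
            "feature_kind",
            "feature_start_bp",
            "feature_end_bp",
            "trait_category",
            "distance_bp",
        ],
    )


def allele_effect_table(
    hits: pd.DataFrame,
    y: pd.Series,
    geno: GenotypeMatrix,
) -> pd.DataFrame:
    """Trait mean +- sample SD per homozygous allele class at each hit.

    Cultivars are grouped by their homozygous genotype at the marker
    (indica-allele homozygotes vs japonica-allele homozygotes when ``hits``
    carries an ``indica_allele`` column, otherwise alt vs ref);
    heterozygotes are excluded.  Groups of fewer than two cultivars report
    an undefined (NaN) SD.
    """
    rows = []
    cultivars = [c for c in y.index if c in geno._cultivar_index and np.isfinite(y[c])]
    yv = y.loc[cultivars].to_numpy(float)
    gi = geno.cultivar_rows(cultivars)
    for hit in hits.itertuples(index=False):
        j = geno.marker_cols([hit.marker_id])[0]
        calls = geno.calls[gi, j]
        ref, alt = geno.alleles[j]
        indica_allele = getattr(hit, "indica_allele", alt)
        if indica_allele == alt:
            ind_mask, jap_mask = calls == HOM_ALT, calls == HOM_REF
        else:
            ind_mask, jap_mask = calls == HOM_REF, calls == HOM_ALT

        def _summ(mask: np.ndarray) -> tuple[float, float, int]:
            vals = yv[mask]
            if len(vals) == 0:
                return np.nan, np.nan, 0
            sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
            return float(np.mean(vals)), sd, int(len(vals))

        im, isd, ni = _summ(ind_mask)
        jm, jsd, nj = _summ(jap_mask)
        rows.append(
            {
                "marker_id": hit.marker_id,
                "indica_allele": indica_allele,
                "indica_mean": im,
                "indica_sd": isd,
                "n_indica": ni,
                "japonica_mean": jm,
                "japonica_sd": jsd,
                "n_japonica": nj,
            }
        )
    return pd.DataFrame(rows)
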