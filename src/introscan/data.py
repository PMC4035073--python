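"""Domain types and file I/O shared by every analysis stage.

The package works on essentially inbred rice cultivars genotyped at biallelic
SNPs.  Genotype calls are stored as a small integer matrix (cultivar x marker)
with codes ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``; marker coordinates are
1-based inclusive base pairs on a named chromosome.  BED input/output converts
to and from 0-based half-open at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "Group",
    "ParseError",
    "MarkerMap",
    "GenotypeMatrix",
    "PopulationPanel",
    "PhenotypeTable",
    "FeatureCatalog",
    "read_genotypes_tabular",
    "write_genotypes_tabular",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_panel",
    "write_panel",
    "read_phenotypes",
    "write_phenotypes",
    "read_features",
    "write_features",
    "validate_panel_against_genotypes",
]

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

#: sentinel for a marker whose genome position is unknown
NO_POSITION: int = -1


class Group(str, Enum):
    """Analysis groups for cultivars.

    HY are the admixed high-yielding cultivars under study, PD the domestic
    japonica parents, PO_INDICA the overseas indica parents.  REF_* are
    subspecies reference accessions; OTHER collects cultivars outside any
    named group (they are carried in the matrix but excluded from group
    statistics).
    """

    HY = "HY"
    PD = "PD"
    PO_INDICA = "PO_INDICA"
    PO_OTHER = "PO_OTHER"
    REF_INDICA = "REF_INDICA"
    REF_JAPONICA = "REF_JAPONICA"
    OTHER = "OTHER"


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _natural_key(chrom: str) -> tuple:
    """Sort key placing chr2 before chr10."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# marker map


@dataclass
class MarkerMap:
    """Marker coordinates: id, chromosome and 1-based position.

    Marker ids are unique and no two markers share a (chromosome, position).
    A map may be constructed in any row order; :class:`GenotypeMatrix`
    applies :meth:`sorted_order` so the working order is always natural
    chromosome order with strictly increasing positions.  A position of
    ``NO_POSITION`` means the marker's genome location is unknown (such
    markers sort last on their chromosome and are dropped by the
    panel-informative filter).
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position_bp

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker_id", "chromosome", "position_bp"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"marker table missing columns {missing}")
        t = t[required].copy()
        t["marker_id"] = t["marker_id"].astype(str)
        t["chromosome"] = t["chromosome"].astype(str)
        t["position_bp"] = t["position_bp"].astype(np.int64)
        dup = t["marker_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate marker ids: {sorted(t.loc[dup, 'marker_id'])[:5]}"
            )
        t = t.reset_index(drop=True)
        known = t[t["position_bp"] != NO_POSITION]
        dup_pos = known.duplicated(subset=["chromosome", "position_bp"])
        if dup_pos.any():
            where = known.loc[dup_pos, ["chromosome", "position_bp"]].iloc[0]
            raise ValueError(
                f"duplicate position {where.position_bp} on {where.chromosome}"
            )
        self.table = t

    def is_sorted(self) -> bool:
        """True when markers follow natural chromosome order and increasing position."""
        return bool(np.array_equal(self.sorted_order(), np.arange(len(self.table))))

    @classmethod
    def from_arrays(
        cls,
        marker_ids: Sequence[str],
        chromosomes: Sequence[str],
        positions: Sequence[int],
    ) -> "MarkerMap":
        return cls(
            pd.DataFrame(
                {
                    "marker_id": list(marker_ids),
                    "chromosome": list(chromosomes),
                    "position_bp": list(positions),
                }
            )
        )

    def sorted_order(self) -> np.ndarray:
        """Index order sorting markers by natural chromosome, then position.

        Unknown positions sort after known ones on the same chromosome,
        preserving input order among themselves.
        """
        t = self.table
        chrom_key = t["chromosome"].map(
            {c: i for i, c in enumerate(sorted(t["chromosome"].unique(), key=_natural_key))}
        )
        pos = t["position_bp"].to_numpy()
        pos_key = np.where(pos == NO_POSITION, np.iinfo(np.int64).max, pos)
        return np.lexsort((np.arange(len(t)), pos_key, chrom_key.to_numpy()))

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# genotype matrix

_BASES = {"A", "C", "G", "T"}


@dataclass
class GenotypeMatrix:
    """Cultivar x marker diploid calls for essentially inbred lines.

    ``calls`` holds ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING`` as int8 with
    shape (n_cultivars, n_markers); ``alleles`` holds the (ref, alt)
    nucleotide per marker.  Construction sorts markers per chromosome by
    position and validates dimensions.
    """

    markers: MarkerMap
    cultivar_ids: list[str]
    calls: np.ndarray
    alleles: np.ndarray  # (n_markers, 2) strings

    def __post_init__(self) -> None:
        self.cultivar_ids = [str(c) for c in self.cultivar_ids]
        if len(set(self.cultivar_ids)) != len(self.cultivar_ids):
            raise ValueError("duplicate cultivar ids")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.alleles = np.asarray(self.alleles, dtype="U8")
        n, m = self.calls.shape
        if n != len(self.cultivar_ids) or m != len(self.markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.cultivar_ids)} cultivars x {len(self.markers)} markers"
            )
        if self.alleles.shape != (m, 2):
            raise ValueError("alleles must have shape (n_markers, 2)")
        bad = ~np.isin(self.calls, [MISSING, HOM_REF, HET, HOM_ALT])
        if bad.any():
            raise ValueError("calls contain undefined codes")
        order = self.markers.sorted_order()
        if not np.array_equal(order, np.arange(m)):
            self.markers = MarkerMap(self.markers.table.iloc[order])
            self.calls = self.calls[:, order]
            self.alleles = self.alleles[order]
        self._cultivar_index = {c: i for i, c in enumerate(self.cultivar_ids)}
        self._marker_index = {mid: j for j, mid in enumerate(self.markers.marker_ids)}

    @property
    def n_cultivars(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def cultivar_rows(self, cultivars: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._cultivar_index[c] for c in cultivars], dtype=int)
        except KeyError as e:
            raise KeyError(f"cultivar {e.args[0]!r} not in genotype matrix") from None

    def marker_cols(self, marker_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._marker_index[m] for m in marker_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"marker {e.args[0]!r} not in genotype matrix") from None

    def subset(
        self,
        cultivars: Sequence[str] | None = None,
        marker_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = (
            np.arange(self.n_cultivars)
            if cultivars is None
            else self.cultivar_rows(cultivars)
        )
        cols = (
            np.arange(self.n_markers)
            if marker_ids is None
            else np.sort(self.marker_cols(marker_ids))
        )
        return GenotypeMatrix(
            markers=MarkerMap(self.markers.table.iloc[cols]),
            cultivar_ids=[self.cultivar_ids[i] for i in rows],
            calls=self.calls[np.ix_(rows, cols)],
            alleles=self.alleles[cols],
        )

    def dosage(self, cultivars: Sequence[str] | None = None) -> np.ndarray:
        """Alt-allele dosage (0/1/2) as float, missing as NaN."""
        rows = (
            np.arange(self.n_cultivars)
            if cultivars is None
            else self.cultivar_rows(cultivars)
        )
        d = self.calls[rows].astype(float)
        d[d == MISSING] = np.nan
        return d


# ---------------------------------------------------------------------------
# panel, phenotypes, features


@dataclass
class PopulationPanel:
    """Assignment of cultivars to analysis groups."""

    assignments: dict[str, Group] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {str(c): Group(g) for c, g in self.assignments.items()}

    def group_of(self, cultivar_id: str) -> Group:
        return self.assignments.get(cultivar_id, Group.OTHER)

    def members(self, group: Group | str) -> list[str]:
        group = Group(group)
        return [c for c, g in self.assignments.items() if g == group]

    def sizes(self) -> dict[Group, int]:
        out: dict[Group, int] = {}
        for g in self.assignments.values():
            out[g] = out.get(g, 0) + 1
        return out

    @property
    def cultivar_ids(self) -> list[str]:
        return list(self.assignments)


@dataclass
class PhenotypeTable:
    """Wide table of trait values, one row per cultivar; NaN marks missing."""

    table: pd.DataFrame  # index: cultivar_id, columns: traits

    def __post_init__(self) -> None:
        t = self.table.copy()
        t.index = t.index.astype(str)
        if t.index.duplicated().any():
            raise ValueError("duplicate cultivar ids in phenotype table")
        self.table = t.astype(float)

    @property
    def traits(self) -> list[str]:
        return list(self.table.columns)

    def trait(self, name: str) -> pd.Series:
        return self.table[name]


@dataclass
class FeatureCatalog:
    """Candidate genes and QTLs with 1-based inclusive intervals."""

    table: pd.DataFrame  # feature_id, feature_kind, chromosome, start_bp, end_bp, trait_category

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = [
            "feature_id",
            "feature_kind",
            "chromosome",
            "start_bp",
            "end_bp",
            "trait_category",
        ]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"feature table missing columns {missing}")
        t = t[required].reset_index(drop=True)
        t["feature_kind"] = t["feature_kind"].astype(str).str.upper()
        bad_kind = ~t["feature_kind"].isin(["GENE", "QTL"])
        if bad_kind.any():
            raise ValueError(
                f"unknown feature kinds: {sorted(t.loc[bad_kind, 'feature_kind'].unique())}"
            )
        t["start_bp"] = t["start_bp"].astype(np.int64)
        t["end_bp"] = t["end_bp"].astype(np.int64)
        if (t["start_bp"] > t["end_bp"]).any():
            raise ValueError("feature with start_bp > end_bp")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# tabular genotype dialect

_CALL_TO_CODE = {"H": HET, "N": MISSING}
_CODE_TO_CALL = {HET: "H", MISSING: "N"}


def read_genotypes_tabular(path: str | Path) -> GenotypeMatrix:
    """Read the tab-separated genotype dialect.

    Header: ``marker_id chromosome position_bp ref alt <cultivar...>``; calls
    are A/C/G/T (homozygote for that base), H (heterozygote), N (missing).
    A position of ``NA``, ``.`` or empty means unknown.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty genotype file", line=1)
        cols = header.split("\t")
        fixed = ["marker_id", "chromosome", "position_bp", "ref", "alt"]
        if cols[: len(fixed)] != fixed:
            raise ParseError(
                f"header must start with {fixed}, got {cols[: len(fixed)]}", line=1
            )
        cultivars = cols[len(fixed) :]
        if not cultivars:
            raise ParseError("no cultivar columns in header", line=1)
        rows: list[tuple] = []
        calls: list[list[int]] = []
        seen: set[str] = set()
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"expected {len(cols)} fields, got {len(fields)}", line=lineno
                )
            mid, chrom, pos_s, ref, alt = fields[:5]
            if mid in seen:
                raise ParseError(f"duplicate marker id {mid!r}", line=lineno)
            seen.add(mid)
            if pos_s in ("", "NA", "."):
                pos = NO_POSITION
            else:
                try:
                    pos = int(pos_s)
                except ValueError:
                    raise ParseError(f"bad position {pos_s!r}", line=lineno) from None
            if ref not in _BASES or alt not in _BASES or ref == alt:
                raise ParseError(f"bad allele pair ({ref!r}, {alt!r})", line=lineno)
            row_calls = []
            for cell in fields[5:]:
                if cell in _CALL_TO_CODE:
                    row_calls.append(_CALL_TO_CODE[cell])
                elif cell == ref:
                    row_calls.append(HOM_REF)
                elif cell == alt:
                    row_calls.append(HOM_ALT)
                else:
                    raise ParseError(
                        f"call {cell!r} is not ref {ref!r}, alt {alt!r}, H or N",
                        line=lineno,
                    )
            rows.append((mid, chrom, pos, ref, alt))
            calls.append(row_calls)
    if not rows:
        raise ParseError("genotype file has no marker rows")
    mm = MarkerMap.from_arrays(
        [r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows]
    )
    return GenotypeMatrix(
        markers=mm,
        cultivar_ids=cultivars,
        calls=np.array(calls, dtype=np.int8).T,
        alleles=np.array([(r[3], r[4]) for r in rows]),
    )


def write_genotypes_tabular(geno: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "\t".join(
                ["marker_id", "chromosome", "position_bp", "ref", "alt"]
                + geno.cultivar_ids
            )
            + "\n"
        )
        for j in range(geno.n_markers):
            ref, alt = geno.alleles[j]
            pos = geno.markers.positions[j]
            cells = []
            for code in geno.calls[:, j]:
                if code == HOM_REF:
                    cells.append(ref)
                elif code == HOM_ALT:
                    cells.append(alt)
                else:
                    cells.append(_CODE_TO_CALL[int(code)])
            fh.write(
                "\t".join(
                    [
                        geno.markers.marker_ids[j],
                        geno.markers.chromosomes[j],
                        "NA" if pos == NO_POSITION else str(pos),
                        ref,
                        alt,
                    ]
                    + cells
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotype calls from a VCF (GT field only).

    Multi-allelic records are rejected.  0/0 maps to HOM_REF, 1/1 to HOM_ALT,
    0/1 and 1/0 to HET, ./. to MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    cultivars = list(vcf.samples)
    if not cultivars:
        raise ParseError("VCF has no sample columns")
    ids, chroms, positions, alleles, calls = [], [], [], [], []
    for i, var in enumerate(vcf):
        if "GT" not in (var.FORMAT or []):
            raise ParseError(f"record {var.CHROM}:{var.POS} has no GT field")
        if len(var.ALT) != 1:
            raise ParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} not supported"
            )
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        alleles.append((var.REF, var.ALT[0]))
        # gts012: 0=hom_ref, 1=het, 2=hom_alt, 3=unknown
        gt = var.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        calls.append(gt)
    vcf.close()
    if not ids:
        raise ParseError("VCF has no records")
    mm = MarkerMap.from_arrays(ids, chroms, positions)
    return GenotypeMatrix(
        markers=mm,
        cultivar_ids=cultivars,
        calls=np.array(calls, dtype=np.int8).T,
        alleles=np.array(alleles),
    )


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only sample columns."""
    code_to_gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(geno.markers.chromosomes):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.cultivar_ids)
            + "\n"
        )
        for j in range(geno.n_markers):
            ref, alt = geno.alleles[j]
            gts = [code_to_gt[int(c)] for c in geno.calls[:, j]]
            fh.write(
                "\t".join(
                    [
                        geno.markers.chromosomes[j],
                        str(geno.markers.positions[j]),
                        geno.markers.marker_ids[j],
                        ref,
                        alt,
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# panel / phenotypes / features I/O


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a 2-column CSV ``cultivar_id,group``; unknown group labels fail."""
    df = pd.read_csv(path, dtype=str)
    if list(df.columns[:2]) != ["cultivar_id", "group"]:
        raise ParseError(
            f"panel header must be 'cultivar_id,group', got {list(df.columns[:2])}",
            line=1,
        )
    if df["cultivar_id"].duplicated().any():
        dups = df.loc[df["cultivar_id"].duplicated(), "cultivar_id"].tolist()
        raise ParseError(f"duplicate cultivars in panel: {dups[:5]}")
    try:
        assignments = {
            row.cultivar_id: Group(row.group) for row in df.itertuples(index=False)
        }
    except ValueError as e:
        raise ParseError(f"unknown group label: {e}") from None
    return PopulationPanel(assignments)


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "cultivar_id": list(panel.assignments),
            "group": [g.value for g in panel.assignments.values()],
        }
    ).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a wide CSV (first column cultivar_id); empty cells become NaN."""
    df = pd.read_csv(path)
    if df.columns[0] != "cultivar_id":
        raise ParseError(
            f"first phenotype column must be 'cultivar_id', got {df.columns[0]!r}",
            line=1,
        )
    return PhenotypeTable(df.set_index("cultivar_id"))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.rename_axis("cultivar_id").to_csv(path)


def read_features(path: str | Path) -> FeatureCatalog:
    """Read a feature catalog.

    ``.bed`` paths are parsed as 6-column BED (chrom, start, end, name,
    feature_kind, trait_category) with 0-based half-open coordinates converted
    to internal 1-based inclusive; anything else is read as CSV with the
    internal column names and 1-based inclusive coordinates.
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        rows = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.rstrip("\n")
                if not raw or raw.startswith(("#", "track", "browser")):
                    continue
                fields = raw.split("\t")
                if len(fields) < 6:
                    raise ParseError(
                        f"expected 6 BED columns, got {len(fields)}", line=lineno
                    )
                chrom, start_s, end_s, name, kind, category = fields[:6]
                start0, end0 = int(start_s), int(end_s)
                if start0 > end0:
                    raise ParseError(
                        f"BED start {start0} > end {end0}", line=lineno
                    )
                rows.append(
                    {
                        "feature_id": name,
                        "feature_kind": kind,
                        "chromosome": chrom,
                        "start_bp": start0 + 1,  # 0-based half-open -> 1-based incl.
                        "end_bp": max(end0, start0 + 1),
                        "trait_category": category,
                    }
                )
        return FeatureCatalog(pd.DataFrame(rows))
    df = pd.read_csv(path, dtype={"chromosome": str})
    return FeatureCatalog(df)


def write_features(features: FeatureCatalog, path: str | Path) -> None:
    """Write a catalog; ``.bed`` paths get 0-based half-open coordinates."""
    path = Path(path)
    t = features.table
    if path.suffix.lower() == ".bed":
        with open(path, "w") as fh:
            for row in t.itertuples(index=False):
                fh.write(
                    "\t".join(
                        [
                            row.chromosome,
                            str(row.start_bp - 1),
                            str(row.end_bp),
                            row.feature_id,
                            row.feature_kind,
                            row.trait_category,
                        ]
                    )
                    + "\n"
                )
    else:
        t.to_csv(path, index=False)


def validate_panel_against_genotypes(
    panel: PopulationPanel, geno: GenotypeMatrix
) -> list[str]:
    """Warn about panel cultivars absent from the genotype matrix.

    Returns the list of absent ids.  Cultivars present in the genotypes but
    absent from the panel are implicitly group OTHER and need no warning.
    """
    absent = [c for c in panel.assignments if c not in geno._cultivar_index]
    if absent:
        warnings.warn(
            f"{len(absent)} panel cultivar(s) absent from genotypes: {absent[:10]}",
            stacklevel=2,
        )
    return absent
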