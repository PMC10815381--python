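"""Tabular I/O for GWAS summary statistics, LD matrices, and gene regions.

Summary statistics are carried as a validated :class:`pandas.DataFrame` inside
:class:`SummaryStats` with a fixed canonical column set.  Files on disk use
GWAS-SSF-like header names (``variant_id``, ``chromosome``,
``base_pair_location``, ``effect_allele``, ``other_allele``,
``effect_allele_frequency``, ``beta``, ``standard_error``, ``p_value``, ``n``);
a ``column_map`` argument rebinds any of them.

Coordinates are 1-based inclusive (GRCh37 / Ensembl convention) internally;
BED region files are converted from half-open 0-based at the boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "EmptyInputError",
    "VariantRecord",
    "GeneRegion",
    "LoadReport",
    "SummaryStats",
    "LDMatrix",
    "DEFAULT_COLUMN_MAP",
    "SUMSTATS_COLUMNS",
    "Z_95",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_regions",
    "write_gene_regions",
    "write_results_table",
]

#: two-sided 95% normal critical value used for every confidence interval
Z_95 = 1.959964

_ALLELE_RE = re.compile(r"^[ACGT]+$")

SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: canonical field -> default on-disk header name
DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class EmptyInputError(ValueError):
    """No parseable record survived validation."""


@dataclass(frozen=True)
class VariantRecord:
    """A genomic variant with its allele coding (GRCh37, 1-based)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval, 1-based inclusive on GRCh37."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class LoadReport:
    """Accounting of a summary-statistics load: input rows = retained + dropped."""

    n_input: int = 0
    n_retained: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryStats:
    """One trait's per-variant marginal GWAS association estimates.

    ``table`` holds the canonical columns of :data:`SUMSTATS_COLUMNS`;
    variant IDs are unique and rows are ordered by (chrom, pos) when
    positions are available.
    """

    trait_id: str
    table: pd.DataFrame
    trait_type: str = "quantitative"
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"SummaryStats table missing columns: {missing}")
        if self.table["variant_id"].duplicated().any():
            dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise FormatError(f"duplicate variant_id in trait {self.trait_id!r}: {dup}")
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> pd.Series:
        return self.table["variant_id"]

    def indexed(self) -> pd.DataFrame:
        """Table indexed by variant_id for O(1) lookup."""
        return self.table.set_index("variant_id", drop=False)

    def region_subset(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Rows with position inside [start, end] on ``chrom`` (inclusive)."""
        t = self.table
        mask = (t["chrom"].astype(str) == str(chrom)) & t["pos"].between(start, end)
        return t.loc[mask]


@dataclass
class LDMatrix:
    """Signed pairwise correlation r over an ordered variant panel."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {n} variant IDs"
            )
        if np.any(np.abs(self.r) > 1.0 + 1e-6):
            raise FormatError("LD matrix has |r| > 1")
        if np.max(np.abs(self.r - self.r.T)) > 1e-6:
            raise FormatError("LD matrix is not symmetric within 1e-6")
        # enforce exact symmetry and unit diagonal
        self.r = 0.5 * (self.r + self.r.T)
        np.clip(self.r, -1.0, 1.0, out=self.r)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != n:
            raise FormatError("duplicate variant IDs in LD panel")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# summary statistics


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str] | None):
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ValueError(f"column_map keys not recognised: {sorted(unknown)}")
        cmap.update(column_map)
    for fieldname in MANDATORY_FIELDS:
        if cmap[fieldname] not in header:
            raise FormatError(f"missing mandatory column {cmap[fieldname]!r} "
                              f"(for field {fieldname!r})")
    return cmap


def read_sumstats(
    path,
    trait_id: str,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
) -> SummaryStats:
    """Read and validate a tab-delimited summary-statistics file.

    Rows violating any record invariant (non-ACGT or identical alleles,
    se <= 0, p outside (0, 1], non-finite beta, eaf outside [0, 1],
    pos < 1, duplicate variant_id) are dropped and counted by reason in the
    load report.  p = 0 is replaced by the smallest positive normal float
    with a warning rather than dropped.  Alleles are upper-cased.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""],
                      keep_default_na=True)
    cmap = _resolve_columns(raw.columns, column_map)
    report = LoadReport(n_input=len(raw))

    df = pd.DataFrame(index=raw.index)
    df["variant_id"] = raw[cmap["variant_id"]].astype(str)
    df["chrom"] = raw[cmap["chrom"]].astype(str) if cmap["chrom"] in raw else pd.NA
    for fld, dtype in (("pos", "Int64"),):
        df[fld] = (pd.to_numeric(raw[cmap[fld]], errors="coerce").astype(dtype)
                   if cmap[fld] in raw else pd.array([pd.NA] * len(raw), dtype=dtype))
    for allele in ("effect_allele", "other_allele"):
        df[allele] = raw[cmap[allele]].astype(str).str.upper()
    for fld in ("eaf", "beta", "se", "pvalue", "n"):
        df[fld] = (pd.to_numeric(raw[cmap[fld]], errors="coerce")
                   if cmap[fld] in raw else np.nan)

    zero_p = df["pvalue"] == 0.0
    if zero_p.any():
        warnings.warn(
            f"{int(zero_p.sum())} p-value(s) of 0 replaced by smallest positive "
            "normal float", stacklevel=2)
        df["pvalue"] = df["pvalue"].mask(zero_p, np.finfo(float).tiny)

    checks = [
        ("bad_allele", ~df["effect_allele"].str.match(_ALLELE_RE)
                       | ~df["other_allele"].str.match(_ALLELE_RE)),
        ("allele_identical", df["effect_allele"] == df["other_allele"]),
        ("bad_beta", ~np.isfinite(df["beta"])),
        ("nonpositive_se", ~(df["se"] > 0) | ~np.isfinite(df["se"])),
        ("bad_pvalue", ~((df["pvalue"] > 0) & (df["pvalue"] <= 1))),
        ("bad_eaf", df["eaf"].notna() & ~df["eaf"].between(0, 1)),
        ("bad_pos", df["pos"].notna() & (df["pos"] < 1)),
        ("duplicate_variant_id", df["variant_id"].duplicated()),
    ]
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks:  # first failing check claims the row
        mask = mask.fillna(False).astype(bool) & ~bad
        if mask.any():
            report.dropped[reason] = int(mask.sum())
            bad |= mask
    out = df.loc[~bad]
    report.n_retained = len(out)
    if report.n_retained == 0:
        raise EmptyInputError(f"no valid record in {path}")
    out = _sort_by_position(out)
    return SummaryStats(trait_id=trait_id, table=out[SUMSTATS_COLUMNS],
                        trait_type=trait_type, load_report=report)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    s = chrom.astype(str).str.removeprefix("chr")
    num = pd.to_numeric(s, errors="coerce")
    return num.fillna(np.inf)


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    if df["pos"].notna().all() and df["chrom"].notna().all():
        key = _chrom_sort_key(df["chrom"])
        order = np.lexsort((df["variant_id"], df["pos"].astype(float), key))
        return df.iloc[order]
    return df


def write_sumstats(ss: SummaryStats, path) -> None:
    """Write with SSF-like headers; 10 significant digits, NA for missing."""
    out = ss.table.rename(columns=DEFAULT_COLUMN_MAP)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# LD matrices


def read_ld_matrix(path) -> LDMatrix:
    """Read a plain square signed-r matrix with a variant-ID header row.

    Mild asymmetry (within 1e-6) is repaired by averaging with the
    transpose; anything larger, any |r| > 1 + 1e-6, or a non-square body is
    a format error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = [h for h in header if h]
        try:
            body = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-numeric LD matrix body in {path}: {exc}") from exc
    if body.shape != (len(ids), len(ids)):
        raise FormatError(
            f"LD matrix in {path} is {body.shape}, expected square of side {len(ids)}")
    return LDMatrix(ids, body)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ld.variant_ids) + "\n")
        np.savetxt(fh, ld.r, delimiter="\t", fmt="%.10g")


# ---------------------------------------------------------------------------
# gene regions


def read_gene_regions(path) -> list[GeneRegion]:
    """Read a BED-style region file (chrom, start, end, gene_id[, score, strand]).

    BED half-open 0-based intervals become 1-based inclusive: (start+1, end).
    Rows with start >= end are rejected with a warning; duplicate gene IDs
    are an error.
    """
    regions: list[GeneRegion] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
            chrom, start_s, end_s, gene_id = parts[:4]
            start0, end0 = int(start_s), int(end_s)
            if start0 >= end0:
                warnings.warn(f"{path}:{lineno}: start >= end, row rejected",
                              stacklevel=2)
                continue
            if gene_id in seen:
                raise FormatError(f"duplicate gene_id {gene_id!r} in {path}")
            seen.add(gene_id)
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "unknown"
            regions.append(GeneRegion(gene_id=gene_id, chrom=chrom,
                                      start=start0 + 1, end=end0, strand=strand))
    return regions


def write_gene_regions(regions: Sequence[GeneRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            strand = r.strand if r.strand in "+-" else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# results table

RESULTS_COLUMNS = [
    "protein", "outcome", "method", "nsnp", "beta", "se",
    "ci_low", "ci_high", "ci_95", "pvalue", "qvalue",
    "pph0", "pph1", "pph2", "pph3", "pph4", "lead_shared_variant",
]


def write_results_table(rows: Sequence[Mapping], path) -> None:
    """Write screen output rows in a deterministic column order.

    CI bounds are beta +/- 1.959964*se; ``ci_95`` is the human-readable
    "low to high" string at 3 decimals.  Absent fields (e.g. coloc
    posteriors for rows without a colocalization run) print as NA.
    """
    records = []
    for row in rows:
        rec = {c: row.get(c, np.nan) for c in RESULTS_COLUMNS}
        beta, se = row.get("beta"), row.get("se")
        if beta is not None and se is not None and np.isfinite(beta) and np.isfinite(se):
            lo, hi = beta - Z_95 * se, beta + Z_95 * se
            rec["ci_low"], rec["ci_high"] = lo, hi
            rec["ci_95"] = f"{lo:.3f} to {hi:.3f}"
        records.append(rec)
    df = pd.DataFrame(records, columns=RESULTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
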