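"""Readers and writers for the external file formats.

All genomic inputs are normalized to 0-based half-open coordinates on
read: BED and bedMethyl are native, Bismark coverage positions are
shifted by -1. Gzip-compressed text is supported transparently for every
reader. Outputs are UTF-8 TSV with header lines beginning ``#``.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    ENV_NONE,
    STRAND_UNKNOWN,
    VALID_STRANDS,
    MethylationCall,
    MethylationMatrix,
    Region,
    RegionSet,
    SampleMeta,
    SnvTable,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input row; message names the file and line number."""


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


@dataclass(frozen=True)
class BedMethylDialect:
    """0-based column indices into a bedMethyl row.

    The default matches the modbam2bed v1.0 extended layout (``-e``):
    BED9+2 followed by canonical / modified / filtered counts.
    """

    chrom: int = 0
    start: int = 1
    strand: int = 5
    n_can: int = 11
    n_mod: int = 12
    n_filt: int = 13

    @property
    def min_columns(self) -> int:
        return max(self.chrom, self.start, self.strand, self.n_can,
                   self.n_mod, self.n_filt) + 1


MODBAM2BED_DIALECT = BedMethylDialect()


def _parse_count(text: str, what: str, where: str) -> int:
    try:
        val = int(text)
    except ValueError:
        raise ParseError(f"{where}: non-numeric {what} {text!r}") from None
    if val < 0:
        raise ParseError(f"{where}: negative {what} {val}")
    return val


def read_bedmethyl(
    path: PathLike, dialect: BedMethylDialect = MODBAM2BED_DIALECT
) -> list[MethylationCall]:
    """Read per-site modified-base calls from a bedMethyl-dialect file.

    Rows with zero total reads are retained. Raises :class:`ParseError`
    on rows with too few columns, non-numeric counts, or a strand symbol
    other than ``+``/``-``.
    """
    calls: list[MethylationCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            where = f"{path}:{lineno}"
            if len(fields) < dialect.min_columns:
                raise ParseError(
                    f"{where}: expected >= {dialect.min_columns} columns, "
                    f"got {len(fields)}"
                )
            strand = fields[dialect.strand]
            if strand not in VALID_STRANDS:
                raise ParseError(f"{where}: unknown strand symbol {strand!r}")
            calls.append(
                MethylationCall(
                    chrom=fields[dialect.chrom],
                    pos=_parse_count(fields[dialect.start], "position", where),
                    strand=strand,
                    n_mod=_parse_count(fields[dialect.n_mod], "n_mod", where),
                    n_can=_parse_count(fields[dialect.n_can], "n_can", where),
                    n_filt=_parse_count(fields[dialect.n_filt], "n_filt", where),
                )
            )
    return calls


def read_bismark_cov(path: PathLike) -> list[MethylationCall]:
    """Read a Bismark coverage file (chrom, 1-based pos, pos, %, nM, nU).

    Positions are shifted to 0-based. The strand is not encoded in this
    format and is recorded as unknown; it is resolved against the CpG
    reference map during strand merging. Counts are authoritative: a
    methylation % inconsistent with them by > 0.1 points only warns.
    """
    calls: list[MethylationCall] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            where = f"{path}:{lineno}"
            if len(fields) != 6:
                raise ParseError(f"{where}: expected 6 columns, got {len(fields)}")
            start = _parse_count(fields[1], "position", where)
            if start < 1:
                raise ParseError(f"{where}: 1-based position < 1")
            n_mod = _parse_count(fields[4], "methylated count", where)
            n_can = _parse_count(fields[5], "unmethylated count", where)
            try:
                pct = float(fields[3])
            except ValueError:
                raise ParseError(f"{where}: non-numeric methylation %") from None
            if n_mod + n_can > 0:
                expected = 100.0 * n_mod / (n_mod + n_can)
                if abs(pct - expected) > 0.1:
                    warnings.warn(
                        f"{where}: stated {pct}% inconsistent with counts "
                        f"{n_mod}/{n_can} (expected {expected:.2f}%); counts kept",
                        stacklevel=2,
                    )
            calls.append(
                MethylationCall(
                    chrom=fields[0],
                    pos=start - 1,
                    strand=STRAND_UNKNOWN,
                    n_mod=n_mod,
                    n_can=n_can,
                    n_filt=0,
                )
            )
    return calls


_META_BOOL = {"true": True, "false": False, "1": True, "0": False,
              "yes": True, "no": False, "": False}


def _parse_sma_type(text: Optional[str]):
    """Split a clinical type token like ``3a`` into (type, subtype, presym)."""
    if text is None or text == "":
        return None, None, False
    text = str(text).strip().lower()
    if text in {"presymptomatic", "presym", "pre"}:
        return None, None, True
    sub = None
    if text[-1] in "abc":
        sub = text[-1]
        text = text[:-1]
    try:
        num = int(text)
    except ValueError:
        raise ParseError(f"unparseable sma_type {text!r}") from None
    return num, sub, False


def read_sample_metadata(path: PathLike) -> list[SampleMeta]:
    """Read the sample/patient metadata TSV into typed records.

    Missing values (empty or ``NA``) stay missing. Duplicate sample ids
    and copy numbers outside 2..5 are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["", "NA"], comment="#")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: no sample_id column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate sample_id {sorted(set(dup))}")

    def _get(row, col):
        if col not in df.columns:
            return None
        val = row[col]
        return None if pd.isna(val) else val

    def _num(row, col, cast=float):
        val = _get(row, col)
        return None if val is None else cast(float(val))

    def _bool(row, col):
        val = _get(row, col)
        if val is None:
            return False
        return _META_BOOL.get(str(val).strip().lower(), False)

    out = []
    for _, row in df.iterrows():
        sma_type, sma_subtype, presym = _parse_sma_type(_get(row, "sma_type"))
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                patient_id=_get(row, "patient_id") or row["sample_id"],
                tissue=_get(row, "tissue") or "blood",
                sex=_get(row, "sex"),
                age_at_sampling=_num(row, "age_at_sampling"),
                age_at_onset=_num(row, "age_at_onset"),
                sma_type=sma_type,
                sma_subtype=sma_subtype,
                presymptomatic=presym,
                smn2_cn=_num(row, "smn2_cn", int),
                naip_cn=_num(row, "naip_cn", int),
                gqn=_num(row, "gqn"),
                library_size_per_smn_copy=_num(row, "library_size_per_smn_copy"),
                smn1_present=_bool(row, "smn1_present"),
                c859_variant=_bool(row, "c859_variant"),
                hfmse_baseline=_num(row, "hfmse_baseline"),
                dhfmse=_num(row, "dhfmse"),
                smn2_fl_expr=_num(row, "smn2_fl_expr"),
                smn2_d7_expr=_num(row, "smn2_d7_expr"),
                smn_as1_expr=_num(row, "smn_as1_expr"),
            )
        )
    return out


def write_sample_metadata(cohort: list[SampleMeta], path: PathLike) -> None:
    rows = []
    for s in cohort:
        row = {k: v for k, v in vars(s).items()}
        row["sma_type"] = (
            "presymptomatic" if s.presymptomatic else s.sma_type_label or ""
        )
        row.pop("sma_subtype")
        row.pop("presymptomatic")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_regions_bed(path: PathLike) -> RegionSet:
    """Read a BED file of target regions (0-based half-open)."""
    regions = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            start = _parse_count(fields[1], "start", f"{path}:{lineno}")
            end = _parse_count(fields[2], "end", f"{path}:{lineno}")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 else ""
            regions.append(Region(fields[0], start, end, label))
    return RegionSet(regions)


def write_regions_bed(regions: RegionSet, path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_snv_table(path: PathLike) -> SnvTable:
    """Read the known-SNV TSV (chrom, pos, ref, alt[, environment_marker])."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     keep_default_na=False, na_values=[""])
    if "environment_marker" not in df.columns:
        df["environment_marker"] = ENV_NONE
    df["environment_marker"] = df["environment_marker"].fillna(ENV_NONE)
    df["pos"] = df["pos"].astype(int)
    return SnvTable(df.reset_index(drop=True))


def write_snv_table(snvs: SnvTable, path: PathLike) -> None:
    snvs.table.to_csv(path, sep="\t", index=False)


# -- matrix round-trip -------------------------------------------------------

def write_matrix(matrix: MethylationMatrix, path: PathLike) -> None:
    """Write the matrix TSV: one row per site (chrom, c_pos, region,
    members), then a percent/depth column pair per sample."""
    cols: dict[str, object] = {
        "chrom": matrix.sites["chrom"],
        "c_pos": matrix.sites["c_pos"],
        "region": matrix.sites["region"].fillna(""),
        "members": matrix.sites["members"].map(
            lambda m: ";".join(m) if isinstance(m, (list, tuple)) else str(m)
        ),
    }
    for s in matrix.samples:
        cols[f"{s}.percent"] = matrix.percent[s]
        cols[f"{s}.depth"] = matrix.depth[s]
    df = pd.DataFrame(cols, index=matrix.percent.index)
    with open(path, "wt", encoding="utf-8") as fh:
        if matrix.filters_applied:
            fh.write("# filters: " + " -> ".join(matrix.filters_applied) + "\n")
        fh.write("# site_id\t" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, na_rep="NA",
                  float_format="%.10g")


def read_matrix(path: PathLike) -> MethylationMatrix:
    """Inverse of :func:`write_matrix` (lossless round-trip)."""
    filters: list[str] = []
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# filters:"):
                filters = line[len("# filters:"):].strip().split(" -> ")
            elif line.startswith("#"):
                header = line[1:].strip().split("\t")
            elif line:
                rows.append(line.split("\t"))
    if header is None:
        raise ParseError(f"{path}: missing header line")
    df = pd.DataFrame(rows, columns=header).set_index("site_id")
    df = df.replace("NA", np.nan)
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "c_pos": df["c_pos"].astype(int),
            "region": df["region"].where(df["region"] != "", np.nan),
            "members": df["members"].map(lambda m: m.split(";")),
        },
        index=df.index,
    )
    sample_ids = [c[: -len(".percent")] for c in header if c.endswith(".percent")]
    percent = pd.DataFrame(
        {s: df[f"{s}.percent"].astype(float) for s in sample_ids}, index=df.index
    )
    depth = pd.DataFrame(
        {s: df[f"{s}.depth"].astype(float).round().astype(int)
         for s in sample_ids},
        index=df.index,
    )
    return MethylationMatrix(percent, depth, sites, filters_applied=filters)


def write_bedmethyl(
    calls: list[MethylationCall], path: PathLike,
    dialect: BedMethylDialect = MODBAM2BED_DIALECT,
) -> None:
    """Write calls in the (default modbam2bed-extended) bedMethyl dialect."""
    ncol = dialect.min_columns
    with open(path, "wt", encoding="utf-8") as fh:
        for c in calls:
            row = ["."] * ncol
            row[dialect.chrom] = c.chrom
            row[dialect.start] = str(c.pos)
            row[2] = str(c.pos + 1)
            row[3] = "5mC"
            row[4] = "0"
            row[dialect.strand] = c.strand
            row[dialect.n_can] = str(c.n_can)
            row[dialect.n_mod] = str(c.n_mod)
            row[dialect.n_filt] = str(c.n_filt)
            fh.write("\t".join(row) + "\n")


def write_bismark_cov(calls: list[MethylationCall], path: PathLike) -> None:
    """Write calls in Bismark coverage format (positions back to 1-based)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in calls:
            total = c.n_mod + c.n_can
            pct = 100.0 * c.n_mod / total if total else 0.0
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.pos + 1}\t{pct:.10g}\t"
                f"{c.n_mod}\t{c.n_can}\n"
            )
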