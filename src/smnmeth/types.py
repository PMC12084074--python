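"""Core domain types shared across the package.

Coordinates are 0-based half-open everywhere. A CpG site is identified by
the position of its forward-strand cytosine ``c_pos``; the paired guanine
sits at ``c_pos + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

STRAND_FWD = "+"
STRAND_REV = "-"
#: Sentinel for records whose source format does not encode strand
#: (Bismark coverage files); resolved against the CpG reference map
#: during strand merging.
STRAND_UNKNOWN = "."

VALID_STRANDS = {STRAND_FWD, STRAND_REV}


@dataclass(frozen=True)
class MethylationCall:
    """One strand-resolved per-site record of modified-base counts.

    ``n_mod`` / ``n_can`` are read counts called 5mC-modified / canonical;
    ``n_filt`` counts ambiguous calls that the caller filtered out and
    that never enter the methylation-percentage formula.
    """

    chrom: str
    pos: int
    strand: str
    n_mod: int
    n_can: int
    n_filt: int = 0

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.strand not in VALID_STRANDS | {STRAND_UNKNOWN}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if min(self.n_mod, self.n_can, self.n_filt) < 0:
            raise ValueError("negative read counts")

    @property
    def depth(self) -> int:
        """Unambiguous call depth (modified + canonical)."""
        return self.n_mod + self.n_can


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region {self.label or self.chrom}: start {self.start} >= end {self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class RegionSet:
    """Labelled half-open genomic intervals (amplicons / regions of interest)."""

    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def label_for(self, chrom: str, pos: int) -> Optional[str]:
        """Label of the first interval containing ``pos``, else None."""
        for r in self.regions:
            if r.contains(chrom, pos):
                return r.label or f"{r.chrom}:{r.start}-{r.end}"
        return None

    def contains(self, chrom: str, pos: int) -> bool:
        return self.label_for(chrom, pos) is not None


ENV_SMN1 = "SMN1-env"
ENV_SMN2 = "SMN2-env"
ENV_NONE = "none"
ENV_MIXED = "mixed/unknown"


@dataclass
class SnvTable:
    """Known single-nucleotide variants, optionally annotated as
    haplotype-environment markers.

    ``environment_marker`` names the genomic environment indicated by the
    ALT allele of the marker; the REF allele indicates the opposite
    environment. Non-marker rows carry ``"none"``.
    """

    table: pd.DataFrame  # columns: chrom, pos, ref, alt, environment_marker

    REQUIRED = ("chrom", "pos", "ref", "alt", "environment_marker")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"SNV table missing columns: {missing}")
        dup = self.table.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError(
                f"duplicate SNV positions: {self.table.loc[dup, 'pos'].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> set[int]:
        sub = self.table[self.table["chrom"] == chrom]
        return set(sub["pos"].astype(int))

    def markers(self) -> pd.DataFrame:
        """Rows carrying an environment-marker annotation."""
        return self.table[self.table["environment_marker"] != ENV_NONE]

    @classmethod
    def empty(cls) -> "SnvTable":
        return cls(
            pd.DataFrame(
                {c: pd.Series(dtype=("int64" if c == "pos" else "object"))
                 for c in cls.REQUIRED}
            )
        )


@dataclass
class SampleMeta:
    """One patient/sample row of covariates, genotype and outcome fields.

    ``sma_type`` is the numeric clinical type (1-4) with an optional
    severity subtype letter; presymptomatic patients carry
    ``presymptomatic=True`` and no numeric type. Optional fields default
    to missing (None) and are never imputed.
    """

    sample_id: str
    patient_id: str = ""
    tissue: str = "blood"  # {blood, fibroblast}
    sex: Optional[str] = None  # {male, female}
    age_at_sampling: Optional[float] = None  # years
    age_at_onset: Optional[float] = None
    sma_type: Optional[int] = None  # 1..4
    sma_subtype: Optional[str] = None  # a/b (c for type 1)
    presymptomatic: bool = False
    smn2_cn: Optional[int] = None  # 2..5
    naip_cn: Optional[int] = None
    gqn: Optional[float] = None
    library_size_per_smn_copy: Optional[float] = None
    smn1_present: bool = False
    c859_variant: bool = False
    hfmse_baseline: Optional[float] = None
    dhfmse: Optional[float] = None
    smn2_fl_expr: Optional[float] = None
    smn2_d7_expr: Optional[float] = None
    smn_as1_expr: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            self.patient_id = self.sample_id
        if self.tissue not in {"blood", "fibroblast"}:
            raise ValueError(f"{self.sample_id}: unknown tissue {self.tissue!r}")
        if self.sex is not None and self.sex not in {"male", "female"}:
            raise ValueError(f"{self.sample_id}: unknown sex {self.sex!r}")
        if self.age_at_sampling is not None and self.age_at_sampling < 0:
            raise ValueError(f"{self.sample_id}: negative age_at_sampling")
        if self.smn2_cn is not None and self.smn2_cn not in {2, 3, 4, 5}:
            raise ValueError(
                f"{self.sample_id}: smn2_cn {self.smn2_cn} outside 2..5"
            )
        if self.sma_type is not None and self.sma_type not in {1, 2, 3, 4}:
            raise ValueError(f"{self.sample_id}: sma_type {self.sma_type}")

    @property
    def sma_type_label(self) -> Optional[str]:
        if self.presymptomatic:
            return "presymptomatic"
        if self.sma_type is None:
            return None
        return f"{self.sma_type}{self.sma_subtype or ''}"


@dataclass(frozen=True)
class CpGSite:
    """A CpG dinucleotide identified by its forward-strand C position."""

    chrom: str
    c_pos: int
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.c_pos < 0:
            raise ValueError("negative c_pos")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.c_pos}"


def site_id(chrom: str, c_pos: int) -> str:
    return f"{chrom}:{c_pos}"


@dataclass
class MethylationMatrix:
    """CpG-sites x samples methylation percentages with paired depths.

    ``percent`` holds values in [0, 100] or NaN (no call / below the
    depth threshold); ``depth`` the unambiguous call depth that produced
    them (retained even where percent was masked). ``sites`` is a
    site-annotation frame indexed like ``percent`` with at least
    ``chrom``, ``c_pos``, ``region`` and ``members`` columns (``members``
    lists collapsed constituents, the site itself for singletons).
    """

    percent: pd.DataFrame
    depth: pd.DataFrame
    sites: pd.DataFrame
    sample_meta: Optional[dict[str, SampleMeta]] = None
    filters_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.percent.index.equals(self.depth.index) or not (
            self.percent.columns.equals(self.depth.columns)
        ):
            raise ValueError("percent/depth dimensions inconsistent")
        if not self.percent.index.equals(self.sites.index):
            raise ValueError("site annotations do not match matrix rows")
        vals = self.percent.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0) < 0 or np.nanmax(vals, initial=0) > 100:
                raise ValueError("percent outside [0, 100]")
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("negative depth")

    @property
    def n_sites(self) -> int:
        return self.percent.shape[0]

    @property
    def n_samples(self) -> int:
        return self.percent.shape[1]

    @property
    def samples(self) -> list[str]:
        return list(self.percent.columns)

    def call_rate(self) -> pd.Series:
        """Per-site fraction of samples with a non-missing percentage."""
        return self.percent.notna().mean(axis=1)

    def copy(self) -> "MethylationMatrix":
        return MethylationMatrix(
            self.percent.copy(),
            self.depth.copy(),
            self.sites.copy(),
            dict(self.sample_meta) if self.sample_meta else None,
            list(self.filters_applied),
        )


@dataclass
class HaplotypeRecord:
    """Per-haplotype methylation calls for one phased gene copy."""

    sample_id: str
    hap_index: int  # 1..5
    calls: list[MethylationCall] = field(default_factory=list)
    environment: str = ENV_MIXED

    def __post_init__(self) -> None:
        if not 1 <= self.hap_index <= 5:
            raise ValueError(f"hap_index {self.hap_index} outside 1..5")

    @property
    def column_id(self) -> str:
        return f"{self.sample_id}|hap{self.hap_index}"


def cpg_map_from_positions(chrom: str, positions: Iterable[int]) -> list[CpGSite]:
    return [CpGSite(chrom, int(p)) for p in sorted(positions)]
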