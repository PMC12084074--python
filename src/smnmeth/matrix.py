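"""Build the filtered CpG-site x sample methylation matrix.

Per-strand calls are merged per CpG dinucleotide, converted to
percentages (modified / (modified + canonical)), and filtered in the
fixed order on-target -> depth -> SNV masking. Filtered-out ambiguous
calls (``n_filt``) never enter the percentage. Works identically per
patient and per phased haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ENV_MIXED,
    ENV_SMN1,
    ENV_SMN2,
    STRAND_FWD,
    STRAND_REV,
    STRAND_UNKNOWN,
    CpGSite,
    HaplotypeRecord,
    MethylationCall,
    MethylationMatrix,
    RegionSet,
    SampleMeta,
    SnvTable,
    site_id,
)


def methylation_percent(n_mod, n_can):
    """Methylation percentage 100 * n_mod / (n_mod + n_can).

    NaN where the unambiguous depth is zero. Accepts scalars or numpy
    arrays; negative counts raise.
    """
    n_mod = np.asarray(n_mod, dtype=float)
    n_can = np.asarray(n_can, dtype=float)
    if (n_mod < 0).any() or (n_can < 0).any():
        raise ValueError("negative counts")
    total = n_mod + n_can
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * n_mod / total, np.nan)
    if pct.ndim == 0:
        return float(pct)
    return pct


@dataclass
class MergeResult:
    """Per-CpG merged counts plus calls that matched no reference CpG."""

    merged: dict[tuple[str, int], MethylationCall]
    off_target: list[MethylationCall] = field(default_factory=list)


def merge_strands(
    calls: Iterable[MethylationCall], cpg_map: Iterable[CpGSite]
) -> MergeResult:
    """Merge forward/reverse calls per CpG site.

    A forward call at ``c_pos`` and a reverse call at ``c_pos + 1`` are
    summed component-wise into the site keyed at ``c_pos``.
    Unknown-strand records are assigned by position (``c_pos`` ->
    forward, ``c_pos + 1`` -> reverse); with a consistent reference map a
    position cannot be both the C of one site and the G of another, so
    this is unambiguous (forward wins if an inconsistent map makes both
    match). Calls matching no reference CpG are reported separately, not
    merged. Two same-strand records at one position are an input error.
    """
    c_positions: dict[str, set[int]] = {}
    for s in cpg_map:
        c_positions.setdefault(s.chrom, set()).add(s.c_pos)

    acc: dict[tuple[str, int], list[int]] = {}
    seen: set[tuple[str, int, str]] = set()
    off_target: list[MethylationCall] = []
    for call in calls:
        sites = c_positions.get(call.chrom, set())
        strand = call.strand
        if strand == STRAND_UNKNOWN:
            if call.pos in sites:
                strand = STRAND_FWD
            elif call.pos - 1 in sites:
                strand = STRAND_REV
            else:
                off_target.append(call)
                continue
        if strand == STRAND_FWD:
            c_pos = call.pos
        else:
            c_pos = call.pos - 1
        if c_pos not in sites:
            off_target.append(call)
            continue
        key = (call.chrom, c_pos, strand)
        if key in seen:
            raise ValueError(
                f"duplicate {strand} record at {call.chrom}:{call.pos}"
            )
        seen.add(key)
        counts = acc.setdefault((call.chrom, c_pos), [0, 0, 0])
        counts[0] += call.n_mod
        counts[1] += call.n_can
        counts[2] += call.n_filt

    merged = {
        (chrom, pos): MethylationCall(chrom, pos, STRAND_FWD, *counts)
        for (chrom, pos), counts in acc.items()
    }
    return MergeResult(merged=merged, off_target=off_target)


def _log_filter(matrix: MethylationMatrix, entry: str) -> None:
    matrix.filters_applied.append(entry)


def filter_depth(matrix: MethylationMatrix, min_depth: int = 100) -> MethylationMatrix:
    """Mask percentages where unambiguous depth < ``min_depth``.

    Depth 100 survives the default threshold ("100x or more"); depths
    are retained for reporting even where the percentage was masked.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    out = matrix.copy()
    out.percent = out.percent.where(out.depth >= min_depth)
    _log_filter(out, f"depth>={min_depth}")
    return out


def restrict_to_regions(
    matrix: MethylationMatrix, regions: RegionSet
) -> MethylationMatrix:
    """Keep only sites whose C position lies on a target interval."""
    labels = [
        regions.label_for(chrom, pos)
        for chrom, pos in zip(matrix.sites["chrom"], matrix.sites["c_pos"])
    ]
    keep = pd.Series([lab is not None for lab in labels], index=matrix.sites.index)
    out = matrix.copy()
    out.percent = out.percent.loc[keep]
    out.depth = out.depth.loc[keep]
    out.sites = out.sites.loc[keep]
    out.sites = out.sites.assign(
        region=[lab for lab in labels if lab is not None]
    )
    _log_filter(out, f"on-target({len(regions)} regions)")
    return out


def mask_snv_cpgs(
    matrix: MethylationMatrix, snvs: SnvTable
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Remove CpG sites whose C or G overlaps a known SNV.

    A variant at either position of the dinucleotide destroys (or masks)
    the CpG on that allele, so bisulfite or modified-base calls there
    mimic unmethylation; such sites are removed outright. Returns the
    filtered matrix and a report of removed sites with the triggering
    SNV.
    """
    removed_rows = []
    keep_mask = []
    for sid, row in matrix.sites.iterrows():
        chrom, c_pos = row["chrom"], int(row["c_pos"])
        positions = snvs.positions(chrom)
        hit = None
        if c_pos in positions:
            hit = c_pos
        elif c_pos + 1 in positions:
            hit = c_pos + 1
        keep_mask.append(hit is None)
        if hit is not None:
            snv = snvs.table[
                (snvs.table["chrom"] == chrom) & (snvs.table["pos"] == hit)
            ].iloc[0]
            removed_rows.append(
                {
                    "site_id": sid,
                    "c_pos": c_pos,
                    "snv_pos": hit,
                    "snv_role": "C" if hit == c_pos else "G",
                    "ref": snv["ref"],
                    "alt": snv["alt"],
                }
            )
    keep = pd.Series(keep_mask, index=matrix.sites.index)
    out = matrix.copy()
    out.percent = out.percent.loc[keep]
    out.depth = out.depth.loc[keep]
    out.sites = out.sites.loc[keep]
    _log_filter(out, f"snv-mask({len(removed_rows)} removed)")
    report = pd.DataFrame(
        removed_rows,
        columns=["site_id", "c_pos", "snv_pos", "snv_role", "ref", "alt"],
    )
    return out, report


def matrix_from_merged(
    merged_per_sample: Mapping[str, MergeResult],
    cpg_map: Sequence[CpGSite],
    sample_meta: Optional[dict[str, SampleMeta]] = None,
) -> MethylationMatrix:
    """Assemble the unfiltered matrix from per-sample merged counts."""
    sites = sorted(cpg_map, key=lambda s: (s.chrom, s.c_pos))
    index = pd.Index([s.site_id for s in sites], name="site_id")
    samples = list(merged_per_sample)
    pct = np.full((len(sites), len(samples)), np.nan)
    dep = np.zeros((len(sites), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        merged = merged_per_sample[sample].merged
        for i, s in enumerate(sites):
            call = merged.get((s.chrom, s.c_pos))
            if call is None:
                continue
            dep[i, j] = call.depth
            pct[i, j] = methylation_percent(call.n_mod, call.n_can)
    site_frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "c_pos": [s.c_pos for s in sites],
            "region": [s.region_label for s in sites],
            "members": [[s.site_id] for s in sites],
        },
        index=index,
    )
    return MethylationMatrix(
        percent=pd.DataFrame(pct, index=index, columns=samples),
        depth=pd.DataFrame(dep, index=index, columns=samples),
        sites=site_frame,
        sample_meta=dict(sample_meta) if sample_meta else None,
    )


def build_matrix(
    call_sets: Mapping[str, Iterable[MethylationCall]],
    cpg_map: Sequence[CpGSite],
    regions: Optional[RegionSet] = None,
    snvs: Optional[SnvTable] = None,
    min_depth: int = 100,
    sample_meta: Optional[dict[str, SampleMeta]] = None,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Merge, assemble and filter: on-target -> depth -> SNV masking.

    Returns the matrix (with per-site call-rate in ``sites['call_rate']``)
    and the removed-site report from SNV masking.
    """
    merged = {s: merge_strands(calls, cpg_map) for s, calls in call_sets.items()}
    mat = matrix_from_merged(merged, cpg_map, sample_meta)
    if regions is not None:
        mat = restrict_to_regions(mat, regions)
    mat = filter_depth(mat, min_depth)
    if snvs is not None:
        mat, removed = mask_snv_cpgs(mat, snvs)
    else:
        removed = pd.DataFrame(
            columns=["site_id", "c_pos", "snv_pos", "snv_role", "ref", "alt"]
        )
    mat.sites = mat.sites.assign(call_rate=mat.call_rate())
    return mat, removed


def haplotype_matrix(
    hap_records: Sequence[HaplotypeRecord],
    cpg_map: Sequence[CpGSite],
    regions: Optional[RegionSet] = None,
    snvs: Optional[SnvTable] = None,
    min_depth: int = 1,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Per-haplotype matrix: one column per (sample, hap_index).

    Identical filter semantics to :func:`build_matrix`; the default
    depth threshold is 1 because phased long-read coverage per copy is
    far below amplicon depths.
    """
    call_sets = {rec.column_id: rec.calls for rec in hap_records}
    if len(call_sets) != len(hap_records):
        raise ValueError("duplicate (sample, hap_index) records")
    return build_matrix(call_sets, cpg_map, regions, snvs, min_depth)


def assign_environment(
    hap_genotypes: Mapping[int, str], snvs: SnvTable, chrom: Optional[str] = None
) -> str:
    """Classify a haplotype's genomic environment from marker SNVs.

    ``hap_genotypes`` maps position -> observed allele on the haplotype.
    Each marker row's annotation names the environment indicated by its
    ALT allele; REF indicates the opposite. The label is assigned only
    when every genotyped marker agrees (unanimity); any discordance, an
    unrecognized allele, or zero genotyped markers yields mixed/unknown.
    """
    markers = snvs.markers()
    if chrom is not None:
        markers = markers[markers["chrom"] == chrom]
    votes: set[str] = set()
    opposite = {ENV_SMN1: ENV_SMN2, ENV_SMN2: ENV_SMN1}
    for _, m in markers.iterrows():
        allele = hap_genotypes.get(int(m["pos"]))
        if allele is None:
            continue
        if allele == m["alt"]:
            votes.add(m["environment_marker"])
        elif allele == m["ref"]:
            votes.add(opposite[m["environment_marker"]])
        else:
            return ENV_MIXED
    if len(votes) == 1:
        return votes.pop()
    return ENV_MIXED
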