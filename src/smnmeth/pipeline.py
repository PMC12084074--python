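"""Stage orchestration: reproducible runs from a single config.

Each ``run_*`` stage validates its inputs up front, computes, writes its
artifacts under the output directory, and appends a machine-readable
provenance record (config echo, package version, input checksums) to
``provenance.jsonl``. Outputs are functions of (config, inputs, seed)
only; re-running an identical config reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .explore import export_heatmap_data, hclust_ward, pca
from .io_formats import (
    read_bismark_cov,
    read_bedmethyl,
    read_matrix,
    read_regions_bed,
    read_sample_metadata,
    read_snv_table,
    write_matrix,
)
from .matrix import build_matrix
from .reduction import reduce_sites
from .simulate import (
    build_truth,
    make_fixture_suite,
    scenario_config,
    simulate_cohort,
    simulate_matrix,
)
from .stats import (
    DesignSpec,
    PowerQuery,
    dma_scan,
    exclude_modifier_genotypes,
    required_sample_size,
    summarize_cohort,
)
from .types import CpGSite, MethylationMatrix


@dataclass
class RunConfig:
    """One run's inputs, thresholds and outputs.

    Threshold defaults are the pipeline's standard analysis settings:
    depth >= 100x, SD-filter at 5 percentage points, Spearman collapse
    at R > 0.9, significance at adjusted p < 0.01.
    """

    out_dir: str = "results"
    seed: int = 0
    # inputs
    metadata: Optional[str] = None
    calls: dict = field(default_factory=dict)  # sample_id -> path
    calls_format: str = "bismark"  # or "bedmethyl"
    regions: Optional[str] = None
    snvs: Optional[str] = None
    matrix_path: Optional[str] = None
    cpg_positions: Optional[list[int]] = None
    chrom: str = "chr5"
    # thresholds
    min_depth: int = 100
    sd_threshold: float = 5.0
    r_threshold: float = 0.9
    alpha_adj: float = 0.01
    # design
    independent: str = "age_at_sampling"
    exclude_modifiers: bool = True
    # simulation
    scenario: Optional[str] = None

    def __post_init__(self) -> None:
        if min(self.min_depth, self.sd_threshold, self.r_threshold, self.alpha_adj) <= 0:
            raise ValueError("thresholds must be positive")
        if not self.alpha_adj < 1:
            raise ValueError("alpha_adj must be below 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(config: RunConfig, stage: str, inputs: list[str], outputs: list[str]) -> None:
    out_dir = Path(config.out_dir)
    record = {
        "stage": stage,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {p: _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": outputs,
    }
    with open(out_dir / "provenance.jsonl", "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"config missing {what} path")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def run_simulate(config: RunConfig) -> Path:
    """Generate the configured scenario's fixture files (or the full
    canned suite when no scenario is named)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario:
        sim = scenario_config(config.scenario)
        cohort = simulate_cohort(sim, config.seed)
        truth = build_truth(sim, cohort, config.seed + 1)
        mat = simulate_matrix(sim, cohort, truth, config.seed + 2)
        from .io_formats import write_sample_metadata

        write_sample_metadata(cohort, out / "samples.tsv")
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t")
        write_matrix(mat, out / "matrix_raw.tsv")
        _log(config, "simulate", [], ["samples.tsv", "truth.tsv", "matrix_raw.tsv"])
    else:
        make_fixture_suite(out / "fixtures", config.seed)
        _log(config, "simulate", [], ["fixtures/"])
    return out


def _load_calls(config: RunConfig):
    reader = read_bismark_cov if config.calls_format == "bismark" else read_bedmethyl
    return {sample: reader(_require(path, f"calls[{sample}]"))
            for sample, path in config.calls.items()}


def run_matrix(config: RunConfig) -> MethylationMatrix:
    """Calls -> merged, filtered matrix (on-target -> depth -> SNV mask)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_path = _require(config.metadata, "metadata")
    cohort = read_sample_metadata(meta_path)
    regions = read_regions_bed(_require(config.regions, "regions")) if config.regions else None
    snvs = read_snv_table(_require(config.snvs, "snvs")) if config.snvs else None
    call_sets = _load_calls(config)
    if config.cpg_positions:
        cpg_map = [CpGSite(config.chrom, p) for p in sorted(config.cpg_positions)]
    else:
        # infer C positions from the observed call coordinates: a CpG is
        # declared wherever adjacent-position records pair up, else the
        # record's own position is taken as the C
        positions = set()
        for calls in call_sets.values():
            seen = {c.pos for c in calls}
            for c in calls:
                if c.strand == "-" or (c.strand == "." and c.pos - 1 in seen):
                    positions.add(c.pos - 1)
                else:
                    positions.add(c.pos)
        cpg_map = [CpGSite(config.chrom, p) for p in sorted(positions)]
    mat, removed = build_matrix(
        call_sets, cpg_map, regions, snvs, config.min_depth,
        sample_meta={s.sample_id: s for s in cohort},
    )
    write_matrix(mat, out / "matrix.tsv")
    removed.to_csv(out / "removed_sites.tsv", sep="\t", index=False)
    _log(config, "matrix",
         [str(meta_path)] + [str(p) for p in config.calls.values()],
         ["matrix.tsv", "removed_sites.tsv"])
    return mat


def _load_matrix(config: RunConfig) -> MethylationMatrix:
    return read_matrix(_require(config.matrix_path, "matrix"))


def run_reduce(config: RunConfig) -> MethylationMatrix:
    """Variance filter then correlation collapsing."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = _load_matrix(config)
    reduced, cmap = reduce_sites(mat, config.sd_threshold, config.r_threshold)
    write_matrix(reduced, out / "matrix_reduced.tsv")
    cmap.to_frame().to_csv(out / "collapse_map.tsv", sep="\t", index=False)
    _log(config, "reduce", [config.matrix_path], ["matrix_reduced.tsv", "collapse_map.tsv"])
    return reduced


def run_dma(config: RunConfig):
    """Per-site covariate-adjusted scan for the configured variable."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = _load_matrix(config)
    cohort = read_sample_metadata(_require(config.metadata, "metadata"))
    if config.exclude_modifiers:
        cohort, excl = exclude_modifier_genotypes(cohort)
        excl.to_csv(out / "excluded_samples.tsv", sep="\t", index=False)
    result = dma_scan(mat, cohort, DesignSpec(config.independent), config.alpha_adj)
    result.table.to_csv(out / f"dma_{config.independent}.tsv", sep="\t", index=False)
    result.volcano_frame().to_csv(
        out / f"volcano_{config.independent}.tsv", sep="\t", index=False
    )
    _log(config, "dma", [config.matrix_path, config.metadata],
         [f"dma_{config.independent}.tsv", f"volcano_{config.independent}.tsv"])
    return result


def run_explore(config: RunConfig):
    """PCA and Ward clustering of the matrix, with heatmap export."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = _load_matrix(config)
    pres = pca(mat)
    clus = hclust_ward(mat)
    pres.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pres.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    export_heatmap_data(mat, clus).to_csv(out / "heatmap_data.tsv", sep="\t")
    (out / "dendrogram.nwk").write_text(clus.to_newick() + "\n")
    _log(config, "explore", [config.matrix_path],
         ["pca_scores.tsv", "pca_loadings.tsv", "heatmap_data.tsv", "dendrogram.nwk"])
    return pres, clus


def run_power(config: RunConfig, query: Optional[PowerQuery] = None) -> int:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    query = query or PowerQuery()
    n = required_sample_size(query)
    (out / "power.json").write_text(
        json.dumps({"f2": query.f2, "u": query.u, "alpha": query.alpha,
                    "power": query.power, "required_n": n}, indent=1)
    )
    _log(config, "power", [], ["power.json"])
    return n


def run_summarize(config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_sample_metadata(_require(config.metadata, "metadata"))
    summary = summarize_cohort(cohort)
    summary.to_frame().to_csv(out / "cohort_summary.tsv", sep="\t")
    _log(config, "summarize", [config.metadata], ["cohort_summary.tsv"])
    return summary
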