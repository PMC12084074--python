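"""Synthetic cohorts and methylation calls with known ground truth.

The generator emulates the statistical structure of a targeted
bisulfite / long-read methylation study of a duplicated locus: a
patient cohort whose copy-number, type, sex and age composition follows
the reference cohort's baseline table (including the age x copy-number
confound), CpG sites laid out on amplicons within a 50-kb window,
per-site baseline methylation on the logit scale with per-cell
biological noise, binomial read sampling at amplicon-scale depths,
planted covariate effects, 2-5 phased gene copies per patient with
environment-marker SNVs, and CpG-destroying SNV artifacts in two modes
(destroyed copies read as canonical, or dropped from coverage).

Planted slopes are specified in percentage points per unit of the
covariate; the generator calibrates the logit-scale coefficient so that
the population least-squares slope over the realized covariate values
(noise included, via Gauss-Hermite quadrature) equals the requested
value, making the planted truth well-defined under the logistic model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .io_formats import (
    write_bedmethyl,
    write_bismark_cov,
    write_regions_bed,
    write_sample_metadata,
    write_snv_table,
)
from .types import (
    ENV_NONE,
    ENV_SMN1,
    ENV_SMN2,
    STRAND_FWD,
    STRAND_REV,
    CpGSite,
    HaplotypeRecord,
    MethylationCall,
    MethylationMatrix,
    Region,
    RegionSet,
    SampleMeta,
    SnvTable,
)

# ---------------------------------------------------------------------------
# Published baseline composition of the bisulfite cohort (counts by SMN2
# copy-number group): totals, males, SMA types, age-at-sampling and
# age-at-onset moments. These constants ARE the default study conditions.

STUDY_WINDOW = ("chr5", 71_375_000, 71_425_000)

STUDY_CN_GROUPS = (2, 3, 4, 5)
STUDY_CN_COUNTS = {2: 15, 3: 215, 4: 122, 5: 7}
STUDY_MALE_COUNTS = {2: 10, 3: 94, 4: 71, 5: 6}
#: counts per copy-number group: type 1, 2, 3, 4, presymptomatic
STUDY_TYPE_COUNTS = {
    2: (15, 0, 0, 0, 0),
    3: (30, 138, 43, 0, 4),
    4: (1, 14, 96, 9, 2),
    5: (0, 0, 5, 1, 1),
}
#: age at sampling mean (SD) per group, years
STUDY_AGE_SAMPLING = {2: (3.57, 4.64), 3: (21.9, 16.9), 4: (35.5, 20.7), 5: (31.2, 14.4)}
#: age at onset mean (SD) per group, years
STUDY_AGE_ONSET = {2: (0.205, 0.153), 3: (1.08, 0.987), 4: (7.39, 9.45), 5: (11.5, 6.23)}
STUDY_ONSET_MISSING = {2: 1 / 15, 3: 11 / 215, 4: 13 / 122, 5: 1 / 7}

#: fraction of the recruited cohort carrying a modifier genotype
#: (an SMN1 copy or c.859G>C); 365 recruited vs 359 analyzed
STUDY_MODIFIER_FRAC = 6 / 365


@dataclass(frozen=True)
class PlantedEffect:
    """A covariate effect planted at a set of sites.

    ``slope_pp`` is the percentage-point change per unit of the encoded
    covariate (per year for age, per level for binary factors)."""

    variable: str
    n_sites: int
    slope_pp: float


@dataclass(frozen=True)
class SnvArtifact:
    """A CpG-destroying SNV planted at one site.

    ``n_destroyed`` gene copies per patient lose the CpG.
    ``mode="counted-as-canonical"``: reads from destroyed copies are
    still sampled and called canonical, diluting pooled methylation to
    m*(K-k)/K. ``mode="dropped"``: destroyed copies contribute no reads
    at the site, leaving the percentage intact at reduced depth."""

    site: int
    n_destroyed: int = 1
    mode: str = "counted-as-canonical"

    def __post_init__(self) -> None:
        if self.mode not in {"counted-as-canonical", "dropped"}:
            raise ValueError(f"unknown artifact mode {self.mode!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults follow the study conditions."""

    n_patients: int = 365
    tissue_fibroblast_frac: float = 0.0  # bisulfite cohort is blood
    cn_weights: tuple[float, ...] = tuple(
        STUDY_CN_COUNTS[cn] for cn in STUDY_CN_GROUPS
    )
    sex_male_frac: float = 0.504
    modifier_frac: float = STUDY_MODIFIER_FRAC
    treated_frac: float = 111 / 337  # HFMSE follow-up among 3x/4x patients

    # genomic layout: amplicons within the 50-kb window
    chrom: str = STUDY_WINDOW[0]
    window: tuple[int, int] = STUDY_WINDOW[1:]
    n_amplicons: int = 15
    n_sites: int = 150

    # generative methylation model (logit scale)
    baseline_mix: tuple[tuple[float, float, float], ...] = (
        (0.25, -2.5, 0.6),  # lowly methylated (promoter-like): weight, mean, sd
        (0.25, 0.0, 0.8),  # intermediate, variable
        (0.50, 2.5, 0.6),  # highly methylated gene body
    )
    bio_sd_logit: float = 0.4  # per-cell biological noise
    age_center: float = 25.0  # years; age effects pivot here
    planted_effects: tuple[PlantedEffect, ...] = ()
    snv_artifacts: tuple[SnvArtifact, ...] = ()

    # read sampling
    depth_median: float = 3000.0  # amplicon bisulfite scale
    depth_sigma_log: float = 0.6
    depth_median_ont: float = 30.0  # per-patient long-read scale
    missing_rate: float = 0.02
    epsilon: float = 0.005  # non-conversion / false-modified rate
    delta: float = 0.01  # missed-modification rate

    # haplotype environments
    n_env_markers: int = 5
    env_smn1_frac: float = 0.3
    env_offset_pp: float = 0.0  # planted environment effect, percentage points

    def __post_init__(self) -> None:
        for frac in (self.tissue_fibroblast_frac, self.sex_male_frac,
                     self.modifier_frac, self.missing_rate, self.epsilon,
                     self.delta, self.env_smn1_frac, self.treated_frac):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        planted = [s for e in self.planted_effects for s in [e.variable]]
        if len(planted) != len(set(planted)):
            raise ValueError("one planted effect per variable")


def amplicon_layout(config: SimulationConfig) -> tuple[RegionSet, list[CpGSite]]:
    """Evenly spaced amplicons across the window, CpG sites evenly
    spread within them (deterministic given the config)."""
    start, end = config.window
    span = end - start
    amp_len = 460
    gap = (span - config.n_amplicons * amp_len) // max(config.n_amplicons, 1)
    regions = []
    sites: list[CpGSite] = []
    per_amp = [config.n_sites // config.n_amplicons] * config.n_amplicons
    for i in range(config.n_sites % config.n_amplicons):
        per_amp[i] += 1
    pos = start
    for a in range(config.n_amplicons):
        label = f"amp{a + 1:02d}"
        regions.append(Region(config.chrom, pos, pos + amp_len, label))
        k = per_amp[a]
        if k:
            step = amp_len // (k + 1)
            for s in range(k):
                sites.append(CpGSite(config.chrom, pos + (s + 1) * step, label))
        pos += amp_len + gap
    return RegionSet(regions), sites


# ---------------------------------------------------------------------------
# cohort

def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


_SUBTYPES = {1: ("a", "b", "c"), 2: ("a", "b"), 3: ("a", "b"), 4: (None,)}


def simulate_cohort(config: SimulationConfig, seed: int) -> list[SampleMeta]:
    """Draw a cohort whose marginals follow the config.

    Copy number, SMA type given copy number, and per-group age
    distributions reproduce the reference cohort's baseline table, including the
    confound that low-copy patients are sampled at younger ages.
    """
    rng = np.random.default_rng(seed)
    n = config.n_patients
    cohort: list[SampleMeta] = []
    cn_p = np.asarray(config.cn_weights, dtype=float)
    cn_p = cn_p / cn_p.sum()
    for i in range(n):
        cn = int(rng.choice(STUDY_CN_GROUPS, p=cn_p))
        type_counts = np.asarray(STUDY_TYPE_COUNTS[cn], dtype=float)
        type_p = type_counts / type_counts.sum()
        t_idx = int(rng.choice(5, p=type_p))
        presym = t_idx == 4
        sma_type = None if presym else t_idx + 1
        subtype = None
        if sma_type in _SUBTYPES and not presym:
            subtype = _SUBTYPES[sma_type][int(rng.integers(len(_SUBTYPES[sma_type])))]
        shape, scale = _gamma_params(*STUDY_AGE_SAMPLING[cn])
        age = float(rng.gamma(shape, scale))
        onset = None
        if not presym and rng.random() > STUDY_ONSET_MISSING[cn]:
            oshape, oscale = _gamma_params(*STUDY_AGE_ONSET[cn])
            onset = float(min(rng.gamma(oshape, oscale), age))
        tissue = "fibroblast" if rng.random() < config.tissue_fibroblast_frac else "blood"
        carrier = rng.random() < config.modifier_frac
        smn1_present = carrier and rng.random() < 0.5
        treated = cn in (3, 4) and rng.random() < config.treated_frac
        hfmse = float(np.clip(rng.normal(28, 16), 0, 66)) if treated else None
        dhfmse = float(np.round(rng.normal(0.5, 3.0))) if treated else None
        cohort.append(
            SampleMeta(
                sample_id=f"S{i + 1:04d}",
                tissue=tissue,
                sex="male" if rng.random() < config.sex_male_frac else "female",
                age_at_sampling=age,
                age_at_onset=onset,
                sma_type=sma_type,
                sma_subtype=subtype,
                presymptomatic=presym,
                smn2_cn=cn,
                naip_cn=int(np.clip(cn - 1 + rng.integers(0, 2), 0, 4)),
                gqn=float(np.clip(rng.normal(7.5, 1.2), 2.0, 10.0)),
                library_size_per_smn_copy=float(rng.lognormal(10.0, 0.35)),
                smn1_present=smn1_present,
                c859_variant=carrier and not smn1_present,
                hfmse_baseline=hfmse,
                dhfmse=dhfmse,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# truth

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _expect_expit(logits: np.ndarray, sd: float) -> np.ndarray:
    """E[expit(l + sd*Z)] for Z ~ N(0,1), by Gauss-Hermite quadrature."""
    if sd == 0:
        return expit(logits)
    shifted = logits[..., None] + sd * _GH_NODES
    return expit(shifted) @ _GH_WEIGHTS


def _covariate_values(cohort: Sequence[SampleMeta], variable: str,
                      age_center: float) -> np.ndarray:
    vals = np.full(len(cohort), np.nan)
    for j, s in enumerate(cohort):
        if variable == "age_at_sampling":
            if s.age_at_sampling is not None:
                vals[j] = s.age_at_sampling - age_center
        elif variable == "tissue":
            vals[j] = 1.0 if s.tissue == "fibroblast" else 0.0
        elif variable == "sex":
            vals[j] = {"male": 0.0, "female": 1.0}[s.sex]
        elif variable == "smn2_cn":
            vals[j] = float(s.smn2_cn)
        else:
            raise ValueError(f"unsupported planted variable {variable!r}")
    return vals


def _calibrate_logit_slope(
    baseline: float, z: np.ndarray, slope_pp: float, bio_sd: float
) -> float:
    """Logit coefficient whose population LS slope on the percentage
    scale over the realized covariate values ``z`` equals ``slope_pp``."""
    z = z[~np.isnan(z)]
    zc = z - z.mean()
    denom = float(zc @ zc)
    if denom == 0 or slope_pp == 0:
        return 0.0

    def ls_slope(c: float) -> float:
        pct = 100.0 * _expect_expit(baseline + c * z, bio_sd)
        return float(zc @ pct) / denom

    lo, hi = sorted((0.0, np.sign(slope_pp) * 1.0))
    # expand the bracket until the LS slope passes the target
    for _ in range(60):
        if (ls_slope(lo) - slope_pp) * (ls_slope(hi) - slope_pp) <= 0:
            break
        lo, hi = lo * 2 if lo else -abs(hi) * 0.5, hi * 2 if hi else abs(lo) * 0.5
    else:
        raise ValueError("cannot calibrate slope; target unreachable")
    return float(brentq(lambda c: ls_slope(c) - slope_pp, lo, hi, xtol=1e-10))


@dataclass
class TruthTable:
    """Everything needed to compute expected methylation analytically."""

    config: SimulationConfig
    sites: pd.DataFrame  # site_id-indexed: chrom, c_pos, region, baseline_logit
    slopes: dict[str, np.ndarray]  # variable -> per-site logit slope
    planted_sites: dict[str, np.ndarray]  # variable -> site indices
    artifacts: tuple[SnvArtifact, ...]
    env_offset_logit: float = 0.0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def cell_logits(self, cohort: Sequence[SampleMeta]) -> np.ndarray:
        """Sites x samples logit surface before biological noise."""
        L = np.repeat(
            self.sites["baseline_logit"].to_numpy()[:, None], len(cohort), axis=1
        )
        for var, slope in self.slopes.items():
            z = _covariate_values(cohort, var, self.config.age_center)
            L += slope[:, None] * np.nan_to_num(z)[None, :]
        return L

    def true_methylation(
        self, site_index: int, sample: SampleMeta, destroyed: bool = False
    ) -> float:
        """Modification probability for one (site, sample/haplotype) cell;
        a destroyed CpG has probability 0."""
        if destroyed:
            return 0.0
        L = self.cell_logits([sample])[site_index, 0]
        return float(expit(L))

    def expected_percent(self, site_index: int, sample: SampleMeta) -> float:
        """Expected observed percentage for the pooled sample, averaging
        over biological noise, call errors and destroyed copies."""
        L = self.cell_logits([sample])[site_index, 0]
        p = float(_expect_expit(np.array(L), self.config.bio_sd_logit))
        q = p * (1 - self.config.delta) + (1 - p) * self.config.epsilon
        for art in self.artifacts:
            if art.site == site_index:
                K = sample.smn2_cn or 2
                k = min(art.n_destroyed, K)
                if art.mode == "counted-as-canonical":
                    q = (K - k) / K * q + k / K * self.config.epsilon
                # dropped mode leaves the percentage expectation intact
        return 100.0 * q

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        for var, slope in self.slopes.items():
            df[f"slope_logit[{var}]"] = slope
        for art in self.artifacts:
            df[f"artifact[{art.mode}]"] = [
                art.n_destroyed if i == art.site else 0 for i in range(len(df))
            ]
        return df


def build_truth(
    config: SimulationConfig, cohort: Sequence[SampleMeta], seed: int
) -> TruthTable:
    """Draw per-site baselines and plant the configured effects.

    Planted site sets are disjoint across variables; age-like slopes are
    calibrated against the cohort's realized covariate values so the
    percentage-scale least-squares slope equals the requested value.
    Planted sites get an intermediate baseline (logit 0 +- 0.3) so the
    slope stays near-linear on the percentage scale across the covariate
    range.
    """
    rng = np.random.default_rng(seed)
    _, sites = amplicon_layout(config)
    S = len(sites)
    weights = np.array([w for w, _, _ in config.baseline_mix])
    comp = rng.choice(len(weights), size=S, p=weights / weights.sum())
    means = np.array([m for _, m, _ in config.baseline_mix])
    sds = np.array([sd for _, _, sd in config.baseline_mix])
    baseline = rng.normal(means[comp], sds[comp])

    slopes: dict[str, np.ndarray] = {}
    planted: dict[str, np.ndarray] = {}
    available = np.arange(S)
    rng.shuffle(available)
    cursor = 0
    for effect in config.planted_effects:
        idx = np.sort(available[cursor:cursor + effect.n_sites])
        if len(idx) < effect.n_sites:
            raise ValueError("more planted sites than sites")
        cursor += effect.n_sites
        baseline[idx] = rng.normal(0.0, 0.3, size=len(idx))
        z = _covariate_values(cohort, effect.variable, config.age_center)
        slope = np.zeros(S)
        for i in idx:
            slope[i] = _calibrate_logit_slope(
                baseline[i], z, effect.slope_pp, config.bio_sd_logit
            )
        slopes[effect.variable] = slope
        planted[effect.variable] = idx

    frame = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "c_pos": [s.c_pos for s in sites],
            "region": [s.region_label for s in sites],
            "baseline_logit": baseline,
        },
        index=pd.Index([s.site_id for s in sites], name="site_id"),
    )
    env_offset_logit = 0.0
    if config.env_offset_pp:
        env_offset_logit = config.env_offset_pp / 25.0  # pp -> logit near p=0.5
    return TruthTable(
        config=config,
        sites=frame,
        slopes=slopes,
        planted_sites=planted,
        artifacts=config.snv_artifacts,
        env_offset_logit=env_offset_logit,
    )


# ---------------------------------------------------------------------------
# read sampling

def _draw_depth(rng, median: float, sigma: float, shape) -> np.ndarray:
    return np.maximum(rng.lognormal(np.log(median), sigma, size=shape), 1.0).round()


def simulate_matrix(
    config: SimulationConfig,
    cohort: Sequence[SampleMeta],
    truth: TruthTable,
    seed: int,
) -> MethylationMatrix:
    """Vectorized pooled-sample matrix: binomial counts at lognormal
    depths from the truth surface, with call errors, missingness and SNV
    artifacts applied. Returns the unfiltered matrix (percent defined
    wherever depth > 0)."""
    rng = np.random.default_rng(seed)
    S, N = truth.n_sites, len(cohort)
    L = truth.cell_logits(cohort)
    L = L + rng.normal(0.0, config.bio_sd_logit, size=(S, N))
    p = expit(L)
    q = p * (1 - config.delta) + (1 - p) * config.epsilon

    depth = _draw_depth(rng, config.depth_median, config.depth_sigma_log, (S, N))
    K = np.array([s.smn2_cn or 2 for s in cohort], dtype=float)
    for art in truth.artifacts:
        k = np.minimum(art.n_destroyed, K)
        if art.mode == "counted-as-canonical":
            q[art.site] = (K - k) / K * q[art.site] + k / K * config.epsilon
        else:  # dropped: intact copies only, at reduced depth
            depth[art.site] = np.round(depth[art.site] * (K - k) / K)
    if config.missing_rate:
        depth[rng.random((S, N)) < config.missing_rate] = 0.0

    n_mod = rng.binomial(depth.astype(int), q)
    depth = depth.astype(int)
    with np.errstate(invalid="ignore"):
        pct = np.where(depth > 0, 100.0 * n_mod / np.maximum(depth, 1), np.nan)

    index = truth.sites.index
    samples = [s.sample_id for s in cohort]
    site_frame = truth.sites[["chrom", "c_pos", "region"]].copy()
    site_frame["members"] = [[sid] for sid in index]
    return MethylationMatrix(
        percent=pd.DataFrame(pct, index=index, columns=samples),
        depth=pd.DataFrame(depth, index=index, columns=samples),
        sites=site_frame,
        sample_meta={s.sample_id: s for s in cohort},
    )


def _calls_from_counts(
    chrom: str, c_pos: np.ndarray, n_mod: np.ndarray, n_can: np.ndarray, rng
) -> list[MethylationCall]:
    """Split pooled per-site counts into forward/reverse strand records."""
    calls = []
    for pos, m, c in zip(c_pos, n_mod, n_can):
        if m + c == 0:
            continue
        mf = rng.binomial(m, 0.5)
        cf = rng.binomial(c, 0.5)
        if mf + cf:
            calls.append(MethylationCall(chrom, int(pos), STRAND_FWD, int(mf), int(cf)))
        mr, cr = m - mf, c - cf
        if mr + cr:
            calls.append(
                MethylationCall(chrom, int(pos) + 1, STRAND_REV, int(mr), int(cr))
            )
    return calls


def simulate_call_sets(
    config: SimulationConfig,
    cohort: Sequence[SampleMeta],
    truth: TruthTable,
    seed: int,
) -> dict[str, list[MethylationCall]]:
    """Per-sample strand-resolved call lists (the file-level view of
    :func:`simulate_matrix`; counts are drawn once and split by strand)."""
    mat = simulate_matrix(config, cohort, truth, seed)
    rng = np.random.default_rng([seed, 1])
    c_pos = truth.sites["c_pos"].to_numpy()
    out = {}
    for sample in mat.samples:
        dep = mat.depth[sample].to_numpy()
        pct = np.nan_to_num(mat.percent[sample].to_numpy())
        n_mod = np.where(dep > 0, np.round(pct * dep / 100.0), 0).astype(int)
        out[sample] = _calls_from_counts(
            config.chrom, c_pos, n_mod, dep - n_mod, rng
        )
    return out


# ---------------------------------------------------------------------------
# haplotypes and environments

def environment_snv_table(config: SimulationConfig, seed: int = 0) -> SnvTable:
    """Marker SNVs (ALT allele = SMN1 environment) plus the declared
    CpG-destroying artifact SNVs (at the G of the affected site)."""
    rng = np.random.default_rng(seed)
    start, end = config.window
    _, sites = amplicon_layout(config)
    taken = {s.c_pos for s in sites} | {s.c_pos + 1 for s in sites}
    rows = []
    pos_pool = iter(rng.permutation(np.arange(start, end)))
    for _ in range(config.n_env_markers):
        pos = next(p for p in pos_pool if p not in taken)
        rows.append(
            {"chrom": config.chrom, "pos": int(pos), "ref": "T", "alt": "A",
             "environment_marker": ENV_SMN1}
        )
    for art in config.snv_artifacts:
        rows.append(
            {
                "chrom": config.chrom,
                "pos": int(sites[art.site].c_pos + 1),
                "ref": "G",
                "alt": "A",
                "environment_marker": ENV_NONE,
            }
        )
    return SnvTable(pd.DataFrame(rows, columns=list(SnvTable.REQUIRED)))


@dataclass
class HaplotypeSim:
    records: list[HaplotypeRecord]
    genotypes: dict[str, dict[int, str]]  # column_id -> marker pos -> allele
    environments: dict[str, str]  # column_id -> true environment
    destroyed: dict[str, set[int]]  # column_id -> destroyed site indices
    pooled: dict[str, list[MethylationCall]]  # per-sample sum over haplotypes


def simulate_haplotypes(
    config: SimulationConfig,
    cohort: Sequence[SampleMeta],
    truth: TruthTable,
    seed: int,
) -> HaplotypeSim:
    """Per-haplotype long-read-scale calls with environment markers.

    Each patient's smn2_cn copies are phased haplotypes; each copy is an
    SMN1-environment copy with probability ``env_smn1_frac`` and carries
    the marker ALT alleles accordingly. Artifact sites destroy the CpG
    on ``n_destroyed`` copies per patient. The pooled per-sample calls
    are the exact per-site sum over haplotypes (complete phasing), so
    count conservation holds by construction.
    """
    rng = np.random.default_rng(seed)
    snvs = environment_snv_table(config)
    marker_pos = [int(p) for p in snvs.markers()["pos"]]
    c_pos = truth.sites["c_pos"].to_numpy()
    S = truth.n_sites

    records, genotypes, environments, destroyed_map, pooled = [], {}, {}, {}, {}
    for sample in cohort:
        K = sample.smn2_cn or 2
        L_sample = truth.cell_logits([sample])[:, 0]
        pooled_counts = np.zeros((S, 2), dtype=int)  # mod, can
        for h in range(1, K + 1):
            env = ENV_SMN1 if rng.random() < config.env_smn1_frac else ENV_SMN2
            destroyed = set()
            for art in truth.artifacts:
                if h <= art.n_destroyed:
                    destroyed.add(art.site)
            L = L_sample + (truth.env_offset_logit if env == ENV_SMN1 else 0.0)
            L = L + rng.normal(0.0, config.bio_sd_logit, size=S)
            p = expit(L)
            p[list(destroyed)] = 0.0
            q = p * (1 - config.delta) + (1 - p) * config.epsilon
            depth = _draw_depth(
                rng, config.depth_median_ont, config.depth_sigma_log, S
            ).astype(int)
            for art in truth.artifacts:
                if art.mode == "dropped" and art.site in destroyed:
                    depth[art.site] = 0
            n_mod = rng.binomial(depth, q)
            rec = HaplotypeRecord(
                sample_id=sample.sample_id, hap_index=h, environment=env,
                calls=_calls_from_counts(config.chrom, c_pos, n_mod, depth - n_mod, rng),
            )
            records.append(rec)
            environments[rec.column_id] = env
            destroyed_map[rec.column_id] = destroyed
            allele = "A" if env == ENV_SMN1 else "T"  # marker alt = SMN1-env
            genotypes[rec.column_id] = {pos: allele for pos in marker_pos}
            pooled_counts[:, 0] += n_mod
            pooled_counts[:, 1] += depth - n_mod
        pooled[sample.sample_id] = _calls_from_counts(
            config.chrom, c_pos, pooled_counts[:, 0], pooled_counts[:, 1], rng
        )
    return HaplotypeSim(records, genotypes, environments, destroyed_map, pooled)


# ---------------------------------------------------------------------------
# canned scenarios

def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Named small scenarios exercising each pipeline stage."""
    presets: dict[str, dict] = {
        "null-cohort": dict(
            n_patients=40, n_sites=60, modifier_frac=0.0, planted_effects=()
        ),
        "age-effect": dict(
            n_patients=300,
            n_sites=121,
            depth_median=2000.0,
            modifier_frac=0.0,
            missing_rate=0.0,
            planted_effects=(PlantedEffect("age_at_sampling", 21, -0.5),),
        ),
        "tissue-effect": dict(
            n_patients=32, n_sites=60, tissue_fibroblast_frac=0.7,
            modifier_frac=0.0,
            planted_effects=(PlantedEffect("tissue", 10, 15.0),),
        ),
        "snv-artifact": dict(
            n_patients=20, n_sites=40, modifier_frac=0.0,
            cn_weights=(1.0, 0.0, 0.0, 0.0),  # two copies each
            # deterministic 80% methylation at every site isolates the
            # dilution mechanism: 1 of 2 destroyed copies -> pooled 40%
            baseline_mix=((1.0, float(logit(0.8)), 0.0),),
            bio_sd_logit=0.0, epsilon=0.0, delta=0.0, missing_rate=0.0,
            snv_artifacts=(SnvArtifact(site=5, n_destroyed=1),),
        ),
        "environment-contrast": dict(
            n_patients=12, n_sites=40, modifier_frac=0.0, env_offset_pp=20.0,
        ),
        "modifier-carriers": dict(
            n_patients=60, n_sites=40, modifier_frac=0.1
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(presets)}")
    params = presets[name]
    params.update(overrides)
    return SimulationConfig(**params)


def age_effect_truth(
    config: SimulationConfig, cohort: Sequence[SampleMeta], seed: int
) -> TruthTable:
    """Truth for the age-effect scenario: 20 sites losing 0.5 percentage
    points per year and one gaining 0.5, mirroring the predominantly
    negative age association with a single positive site."""
    base = replace(
        config,
        planted_effects=(PlantedEffect("age_at_sampling", 21, -0.5),),
    )
    truth = build_truth(base, cohort, seed)
    idx = truth.planted_sites["age_at_sampling"]
    up = idx[-1]
    z = _covariate_values(cohort, "age_at_sampling", config.age_center)
    truth.slopes["age_at_sampling"][up] = _calibrate_logit_slope(
        float(truth.sites["baseline_logit"].iloc[up]), z, +0.5, config.bio_sd_logit
    )
    truth.planted_sites["age_down"] = idx[:-1]
    truth.planted_sites["age_up"] = np.array([up])
    return truth


def make_fixture_suite(output_dir, seed: int = 0) -> dict[str, Path]:
    """Write every canned scenario as parseable files: metadata TSV,
    regions BED, SNV TSV, per-sample Bismark coverage files (bedMethyl
    for the haplotype scenario) and the truth table."""
    output_dir = Path(output_dir)
    written: dict[str, Path] = {}
    for name in ("null-cohort", "age-effect", "tissue-effect", "snv-artifact",
                 "environment-contrast", "modifier-carriers"):
        config = scenario_config(name)
        if name == "age-effect":  # keep the file fixture small
            config = scenario_config(name, n_patients=40, n_sites=40)
        sub = output_dir / name
        sub.mkdir(parents=True, exist_ok=True)
        cohort = simulate_cohort(config, seed)
        if name == "age-effect":
            truth = age_effect_truth(config, cohort, seed + 1)
        else:
            truth = build_truth(config, cohort, seed + 1)
        regions, _ = amplicon_layout(config)
        write_sample_metadata(cohort, sub / "samples.tsv")
        write_regions_bed(regions, sub / "regions.bed")
        write_snv_table(environment_snv_table(config), sub / "snvs.tsv")
        truth.to_frame().to_csv(sub / "truth.tsv", sep="\t")
        (sub / "config.json").write_text(
            json.dumps({"scenario": name, "seed": seed,
                        "n_patients": config.n_patients,
                        "n_sites": config.n_sites}, indent=1)
        )
        if name == "environment-contrast":
            hap = simulate_haplotypes(config, cohort, truth, seed + 2)
            for rec in hap.records:
                write_bedmethyl(
                    rec.calls,
                    sub / f"{rec.sample_id}_hap{rec.hap_index}.bedmethyl.tsv",
                )
        else:
            call_sets = simulate_call_sets(config, cohort, truth, seed + 2)
            for sample, calls in call_sets.items():
                write_bismark_cov(calls, sub / f"{sample}.cov")
        written[name] = sub
    return written
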