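"""Shared definition of the synthetic study that the numbered analysis
scripts re-run: a bisulfite-scale blood cohort with age-associated
methylation planted at 21 of 150 CpG sites (20 declining by 0.5
percentage points per year, one rising — the qualitative sign pattern of
the locus's age association), one CpG-destroying SNV artifact site, and
a handful of modifier-genotype carriers.

Every script derives its randomness from one study seed so the whole
analysis is reproducible end to end.
"""

from pathlib import Path

from smnmeth.simulate import (
    SimulationConfig,
    SnvArtifact,
    age_effect_truth,
    amplicon_layout,
    environment_snv_table,
    simulate_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_SEED = 20240417

CONFIG = SimulationConfig(
    n_patients=365,
    n_sites=150,
    depth_median=3000.0,
    snv_artifacts=(SnvArtifact(site=42, n_destroyed=1),),
)


def study_cohort():
    return simulate_cohort(CONFIG, STUDY_SEED)


def study_truth(cohort):
    # 21 age-associated sites: 20 losing 0.5 pp/year, one gaining
    return age_effect_truth(CONFIG, cohort, STUDY_SEED + 1)


def study_layout():
    regions, sites = amplicon_layout(CONFIG)
    return regions, sites


def study_snvs():
    return environment_snv_table(CONFIG)
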