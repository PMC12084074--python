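#!/usr/bin/env python
"""Generate the synthetic study cohort and its ground truth.

Writes the sample metadata, the truth table, the amplicon layout and the
known-SNV table under results/, and prints the baseline-characteristics
summary of the cohort by copy-number group.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study import CONFIG, RESULTS, study_cohort, study_layout, study_snvs, study_truth

from smnmeth.io_formats import (
    write_regions_bed,
    write_sample_metadata,
    write_snv_table,
)
from smnmeth.stats import summarize_cohort


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = study_cohort()
    truth = study_truth(cohort)
    regions, _ = study_layout()

    write_sample_metadata(cohort, RESULTS / "samples.tsv")
    truth.to_frame().to_csv(RESULTS / "truth.tsv", sep="\t")
    write_regions_bed(regions, RESULTS / "regions.bed")
    write_snv_table(study_snvs(), RESULTS / "snvs.tsv")

    summary = summarize_cohort(cohort)
    summary.to_frame().to_csv(RESULTS / "cohort_summary.tsv", sep="\t")

    n_planted = sum(len(v) for k, v in truth.planted_sites.items()
                    if k in ("age_down", "age_up"))
    print(f"cohort: {len(cohort)} patients, {CONFIG.n_sites} CpG sites "
          f"on {CONFIG.n_amplicons} amplicons")
    print(f"planted: {n_planted} age-associated sites "
          f"({len(truth.planted_sites['age_down'])} negative, "
          f"{len(truth.planted_sites['age_up'])} positive), "
          f"1 CpG-destroying SNV site")
    print("\nBaseline characteristics (counts, % within copy-number group):")
    print(summary.to_frame().to_string())


if __name__ == "__main__":
    main()
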