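#!/usr/bin/env python
"""Unsupervised structure of the reduced matrix: PCA and Ward clustering.

Writes PCA scores/loadings, the sample dendrogram (Newick) and the
heatmap export (samples in leaf order with clinical annotations).
Prints the variance explained by the leading components and the
correlation of PC1 with age, the study's dominant methylation covariate.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study import RESULTS, study_cohort

from smnmeth.explore import export_heatmap_data, hclust_ward, pca
from smnmeth.io_formats import read_matrix


def main() -> None:
    mat = read_matrix(RESULTS / "matrix_reduced.tsv")
    cohort = {s.sample_id: s for s in study_cohort()}

    # at 365 samples nearly every site has at least one missing cell, so
    # site-dropping would empty the matrix; impute the site mean instead
    res = pca(mat, standardize=True, missing="mean")
    res.scores.to_csv(RESULTS / "pca_scores.tsv", sep="\t")
    res.loadings.to_csv(RESULTS / "pca_loadings.tsv", sep="\t")

    clus = hclust_ward(mat, missing="mean")
    (RESULTS / "dendrogram.nwk").write_text(clus.to_newick() + "\n")
    annotations = pd.DataFrame(
        {
            "age": [cohort[s].age_at_sampling for s in mat.samples],
            "sex": [cohort[s].sex for s in mat.samples],
            "smn2_cn": [cohort[s].smn2_cn for s in mat.samples],
        },
        index=mat.samples,
    )
    export_heatmap_data(mat, clus, annotations).to_csv(
        RESULTS / "heatmap_data.tsv", sep="\t"
    )

    ve = res.variance_explained
    print(f"PCA on {res.loadings.shape[0]} complete sites, "
          f"{res.scores.shape[0]} samples")
    print("variance explained: " + ", ".join(
        f"PC{i + 1} {v:.1f}%" for i, v in enumerate(ve[:4])))
    ages = annotations["age"].to_numpy(dtype=float)
    r = np.corrcoef(res.scores["PC1"], ages)[0, 1]
    print(f"corr(PC1, age) = {r:.2f}")


if __name__ == "__main__":
    main()
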