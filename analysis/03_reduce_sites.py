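#!/usr/bin/env python
"""Reduce the site set before testing: drop low-variance CpGs and
collapse highly correlated ones.

Reads results/matrix.tsv, removes sites with between-sample SD < 5
percentage points, collapses connected groups with Spearman R > 0.9,
and writes the reduced matrix and the collapse map.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from study import RESULTS

from smnmeth.io_formats import read_matrix, write_matrix
from smnmeth.reduction import collapse_correlated, filter_low_variance


def main() -> None:
    mat = read_matrix(RESULTS / "matrix.tsv")
    kept = filter_low_variance(mat, 5.0)
    reduced, cmap = collapse_correlated(kept, 0.9)
    write_matrix(reduced, RESULTS / "matrix_reduced.tsv")
    cmap.to_frame().to_csv(RESULTS / "collapse_map.tsv", sep="\t", index=False)

    n_collapsed = sum(1 for m in cmap.groups.values() if len(m) > 1)
    print(f"{mat.n_sites} sites -> {kept.n_sites} after SD filter "
          f"-> {reduced.n_sites} after collapsing "
          f"({n_collapsed} collapsed groups)")


if __name__ == "__main__":
    main()
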