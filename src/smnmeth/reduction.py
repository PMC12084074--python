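"""Site reduction before statistical testing.

Two steps, applied in this order only: drop sites with little
between-sample variation (SD < 5 percentage points), then collapse
groups of highly correlated sites (Spearman R > 0.9) into their
per-sample average. Grouping is by connected components of the pairwise
rule — the parameter-free transitive closure; greedy pairwise
alternatives would give different groupings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import MethylationMatrix


def spearman_r(x, y) -> float:
    """Spearman rank correlation on pairwise-complete observations.

    Average ranks for ties; NaN when fewer than 3 complete pairs remain
    or either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return float("nan")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def filter_low_variance(
    matrix: MethylationMatrix, sd_threshold: float = 5.0
) -> MethylationMatrix:
    """Keep sites whose sample SD (n-1 denominator, non-missing cells)
    is >= ``sd_threshold`` percentage points (strict "< threshold"
    removal, so SD exactly at the threshold is kept). Sites with fewer
    than two calls have no SD and are removed."""
    sd = matrix.percent.std(axis=1, ddof=1)
    keep = sd >= sd_threshold
    out = matrix.copy()
    out.percent = out.percent.loc[keep]
    out.depth = out.depth.loc[keep]
    out.sites = out.sites.loc[keep]
    out.filters_applied.append(f"sd>={sd_threshold}")
    return out


@dataclass
class CollapseMap:
    """collapsed_site_id -> ordered member site ids (singletons allowed)."""

    groups: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def n_members(self) -> int:
        return sum(len(m) for m in self.groups.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "collapsed_site_id": list(self.groups),
                "n_members": [len(m) for m in self.groups.values()],
                "members": [";".join(m) for m in self.groups.values()],
            }
        )


def _components(adjacency: np.ndarray) -> list[list[int]]:
    """Connected components of a boolean adjacency matrix (index order)."""
    n = adjacency.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adjacency[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        comps.append(sorted(comp))
    return comps


def collapse_correlated(
    matrix: MethylationMatrix, r_threshold: float = 0.9
) -> tuple[MethylationMatrix, CollapseMap]:
    """Collapse connected components of sites with Spearman R strictly
    above ``r_threshold`` into one site per component.

    Correlations use pairwise-complete observations (>= 3 pairs); a
    missing correlation is no edge. The collapsed value per sample is
    the unweighted mean of member percentages over non-missing members;
    collapsed depth is the mean member depth. The collapsed site id
    concatenates member ids.
    """
    if matrix.n_sites == 0:
        return matrix.copy(), CollapseMap()
    corr = matrix.percent.T.corr(method="spearman", min_periods=3)
    adj = (corr.to_numpy() > r_threshold) & ~np.eye(matrix.n_sites, dtype=bool)
    adj &= ~np.isnan(corr.to_numpy())
    comps = _components(adj)

    ids = list(matrix.percent.index)
    new_index = []
    pct_rows = []
    dep_rows = []
    site_rows = []
    groups: dict[str, list[str]] = {}
    for comp in comps:
        members = [ids[i] for i in comp]
        # order members genomically for stable collapsed ids
        members.sort(key=lambda sid: (
            matrix.sites.at[sid, "chrom"], matrix.sites.at[sid, "c_pos"]))
        cid = members[0] if len(members) == 1 else ";".join(members)
        groups[cid] = members
        new_index.append(cid)
        pct_rows.append(matrix.percent.loc[members].mean(axis=0, skipna=True))
        dep_rows.append(matrix.depth.loc[members].mean(axis=0))
        first = matrix.sites.loc[members[0]]
        site_rows.append(
            {
                "chrom": first["chrom"],
                "c_pos": int(first["c_pos"]),
                "region": first["region"],
                "members": list(members),
            }
        )
    # sort components by leading coordinate for deterministic output
    order = sorted(range(len(new_index)),
                   key=lambda k: (site_rows[k]["chrom"], site_rows[k]["c_pos"]))
    index = pd.Index([new_index[k] for k in order], name="site_id")
    out = MethylationMatrix(
        percent=pd.DataFrame([pct_rows[k] for k in order], index=index),
        depth=pd.DataFrame([dep_rows[k] for k in order], index=index).round().astype(int),
        sites=pd.DataFrame([site_rows[k] for k in order], index=index),
        sample_meta=dict(matrix.sample_meta) if matrix.sample_meta else None,
        filters_applied=list(matrix.filters_applied)
        + [f"collapse(spearman>{r_threshold})"],
    )
    ordered_groups = {index[k_new]: groups[index[k_new]] for k_new in range(len(index))}
    return out, CollapseMap(ordered_groups)


def reduce_sites(
    matrix: MethylationMatrix,
    sd_threshold: float = 5.0,
    r_threshold: float = 0.9,
) -> tuple[MethylationMatrix, CollapseMap]:
    """The supported pipeline order: variance filter, then collapsing."""
    return collapse_correlated(
        filter_low_variance(matrix, sd_threshold), r_threshold
    )
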