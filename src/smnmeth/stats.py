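"""Per-CpG covariate-adjusted differential methylation and cohort statistics.

For each site an ordinary least-squares model

    methylation % ~ independent variable + covariates

is fitted with an intercept, the two-sided t test on the independent
variable's coefficient gives the per-site p-value, and
Benjamini-Hochberg adjustment across all tested sites of a scan gives
adjusted p-values; a site is called significant when p_adj < 0.01
(strict). Default covariates are age at sampling (dropped when age is
the variable under test), sex, library size per SMN copy and GQN.
Encodings: sex male=0 / female=1; SMA type 1..4 -> 0..3 (presymptomatic
patients carry no rank and are excluded from type contrasts); copy
numbers numeric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .types import MethylationMatrix, SampleMeta

#: severity ordering of clinical type tokens, mildest first
SEVERITY_ORDER_MILD_TO_SEVERE = ["4", "3b", "3a", "2b", "2a", "1c", "1b", "1a"]

SEX_ENCODING = {"male": 0.0, "female": 1.0}
SMA_TYPE_ENCODING = {1: 0.0, 2: 1.0, 3: 2.0, 4: 3.0}

DEFAULT_COVARIATES = ("age_at_sampling", "sex", "library_size_per_smn_copy", "gqn")


def encode_variable(name: str, values: Sequence) -> np.ndarray:
    """Encode a metadata variable as a numeric vector (NaN = missing).

    sex -> {male: 0, female: 1}; sma_type 1..4 -> 0..3 with
    presymptomatic as missing; copy numbers and continuous variables
    pass through as floats.
    """
    out = np.full(len(values), np.nan)
    for i, v in enumerate(values):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if name == "sex":
            out[i] = SEX_ENCODING[v]
        elif name == "sma_type":
            if v in SMA_TYPE_ENCODING:
                out[i] = SMA_TYPE_ENCODING[v]
            # presymptomatic / unknown stays missing for the type contrast
        else:
            out[i] = float(v)
    return out


def _meta_value(s: SampleMeta, name: str):
    if name == "sma_type":
        return None if s.presymptomatic else s.sma_type
    if name == "severity_group":
        grp = severity_group_ont(s.smn2_cn, s.sma_type_label)
        return None if grp is None else {"less severe": 0.0, "more severe": 1.0}[grp]
    if name == "tissue":
        return {"blood": 0.0, "fibroblast": 1.0}[s.tissue]
    return getattr(s, name)


def design_frame(cohort: Sequence[SampleMeta], variables: Sequence[str]) -> pd.DataFrame:
    """Encoded design columns for ``variables``, indexed by sample id."""
    data = {
        name: encode_variable(name, [_meta_value(s, name) for s in cohort])
        for name in variables
    }
    return pd.DataFrame(data, index=[s.sample_id for s in cohort])


def severity_group_ont(
    smn2_cn: Optional[int], sma_type_label: Optional[str]
) -> Optional[str]:
    """Two-group severity split used for small long-read cohorts.

    Severity decreases from type 1a to type 4. Three SMN2 copies: types
    2b and milder -> "less severe", 2a and more severe -> "more severe".
    Four copies: the split moves to 3b (milder -> less) vs 3a and more
    severe. Other copy numbers, presymptomatic patients, or a missing
    subtype where the split needs it -> None.
    """
    if smn2_cn not in (3, 4) or sma_type_label in (None, "presymptomatic"):
        return None
    if sma_type_label not in SEVERITY_ORDER_MILD_TO_SEVERE:
        return None  # subtype required but absent (e.g. bare "2" or "3")
    rank = SEVERITY_ORDER_MILD_TO_SEVERE.index(sma_type_label)  # higher = more severe
    boundary = "2b" if smn2_cn == 3 else "3b"
    return (
        "less severe"
        if rank <= SEVERITY_ORDER_MILD_TO_SEVERE.index(boundary)
        else "more severe"
    )


def exclude_modifier_genotypes(
    cohort: Sequence[SampleMeta],
) -> tuple[list[SampleMeta], pd.DataFrame]:
    """Drop carriers of an SMN1 copy or of the positive modifier c.859G>C.

    These uncommon genotypes likely modify phenotype independently of
    methylation, so they are removed before severity analyses. Returns
    the filtered cohort and an exclusion report.
    """
    kept, rows = [], []
    for s in cohort:
        if s.smn1_present or s.c859_variant:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "smn1_present": s.smn1_present,
                    "c859_variant": s.c859_variant,
                }
            )
        else:
            kept.append(s)
    if not kept:
        import warnings

        warnings.warn("all samples excluded as modifier-genotype carriers")
    return kept, pd.DataFrame(rows, columns=["sample_id", "smn1_present", "c859_variant"])


@dataclass
class SiteFit:
    """OLS result for one site's independent-variable coefficient."""

    estimate: float
    se: float
    t: float
    p: float
    n_used: int
    flag: str = ""

    def is_missing(self) -> bool:
        return math.isnan(self.p)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """QR-based OLS: coefficients, their SEs, and residual df."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    se = np.sqrt(sigma2 * np.sum(Rinv**2, axis=1))
    return beta, se, df


def fit_site_model(
    y: Sequence[float],
    independent: Sequence[float],
    covariates: Optional[Sequence[Sequence[float]]] = None,
) -> SiteFit:
    """OLS fit of one site with intercept; listwise deletion of samples
    missing the response or any design variable.

    The reported p-value is the two-sided t test on the independent
    variable's coefficient with n_used - p_total residual degrees of
    freedom. Rank-deficient designs or zero residual df yield a missing,
    flagged result; a zero-variance response yields estimate 0 with
    missing p.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(independent, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in (covariates or [])]
    design = np.column_stack([np.ones_like(x), x] + covs)
    ok = ~np.isnan(y) & ~np.isnan(design).any(axis=1)
    n_used = int(ok.sum())
    p_total = design.shape[1]
    if n_used <= p_total:
        return SiteFit(np.nan, np.nan, np.nan, np.nan, n_used, "insufficient n")
    X, yy = design[ok], y[ok]
    if np.ptp(yy) == 0:
        return SiteFit(0.0, np.nan, np.nan, np.nan, n_used, "zero-variance y")
    if np.linalg.matrix_rank(X) < p_total:
        return SiteFit(np.nan, np.nan, np.nan, np.nan, n_used, "rank-deficient design")
    beta, se, df = _ols(X, yy)
    est, s = float(beta[1]), float(se[1])
    if s == 0:
        # perfect fit: effect present but no sampling noise
        t = math.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t = est / s
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return SiteFit(est, s, t, p, n_used)


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Missing p-values propagate as missing and do not count toward the
    number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class DesignSpec:
    """Which variable is tested and which are adjusted for.

    When the independent variable is age at sampling, age is dropped
    from the covariates automatically.
    """

    independent: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        covs = tuple(c for c in self.covariates if c != self.independent)
        if self.independent == "age_at_sampling":
            covs = tuple(c for c in covs if c != "age_at_sampling")
        object.__setattr__(self, "covariates", covs)


@dataclass
class DmaResult:
    """Per-site scan output."""

    table: pd.DataFrame  # site_id, chrom, c_pos, estimate, se, t, p, p_adj, n_used, flag
    significant: list[str] = field(default_factory=list)
    alpha_adj: float = 0.01

    def volcano_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        with np.errstate(divide="ignore"):
            df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
        return df[["site_id", "estimate", "p_adj", "neg_log10_p_adj"]]


def dma_scan(
    matrix: MethylationMatrix,
    cohort: Sequence[SampleMeta],
    design: DesignSpec,
    alpha_adj: float = 0.01,
) -> DmaResult:
    """Per-site covariate-adjusted scan with BH correction across the
    scan's tested sites; significant iff p_adj < ``alpha_adj`` strictly.

    Samples absent from the matrix are ignored; results are ordered by
    genomic coordinate (the matrix row order).
    """
    meta = {s.sample_id: s for s in cohort}
    samples = [c for c in matrix.samples if c in meta]
    if not samples:
        raise ValueError("no cohort samples present in the matrix")
    sub = [meta[c] for c in samples]
    dm = design_frame(sub, [design.independent, *design.covariates])
    x = dm[design.independent].to_numpy()
    covs = [dm[c].to_numpy() for c in design.covariates]
    Y = matrix.percent[samples].to_numpy(dtype=float)

    rows = []
    for i, sid in enumerate(matrix.percent.index):
        fit = fit_site_model(Y[i], x, covs)
        rows.append(
            {
                "site_id": sid,
                "chrom": matrix.sites.at[sid, "chrom"],
                "c_pos": int(matrix.sites.at[sid, "c_pos"]),
                "estimate": fit.estimate,
                "se": fit.se,
                "t": fit.t,
                "p": fit.p,
                "n_used": fit.n_used,
                "flag": fit.flag,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    table = table[
        ["site_id", "chrom", "c_pos", "estimate", "se", "t", "p", "p_adj",
         "n_used", "flag"]
    ]
    significant = table.loc[table["p_adj"] < alpha_adj, "site_id"].tolist()
    return DmaResult(table=table, significant=significant, alpha_adj=alpha_adj)


# -- power analysis ----------------------------------------------------------

@dataclass(frozen=True)
class PowerQuery:
    """Linear-model power query in Cohen's f-squared terms."""

    f2: float = 0.15
    u: int = 4
    alpha: float = 0.01
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.f2 <= 0 or self.u < 1 or not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("invalid power query")


def linear_model_power(u: int, v: float, f2: float, alpha: float) -> float:
    """Power of the general-linear-model F test: probability that a
    noncentral F(u, v, lambda = f2*(u+v+1)) exceeds the central critical
    value at ``alpha``."""
    fcrit = sps.f.ppf(1.0 - alpha, u, v)
    lam = f2 * (u + v + 1.0)
    return float(sps.ncf.sf(fcrit, u, v, lam))


def required_sample_size(
    q: PowerQuery, df_convention: str = "n-1", v_ceiling: float = 1e6
) -> int:
    """Smallest sample size achieving the target power.

    Solves the continuous denominator df v* at which power equals the
    target (power is increasing in v), then converts df to sample size.
    ``df_convention`` fixes the conversion: ``"n-1"`` treats the
    denominator df as n - 1 (the conversion in common applied use of
    this power function, and this package's default); ``"n-u-1"`` is the
    strict OLS residual-df convention n = u + v + 1. The returned n is
    the ceiling, so n is the smallest integer meeting the target while
    n - 1 falls short.
    """
    if df_convention not in {"n-1", "n-u-1"}:
        raise ValueError(f"unknown df_convention {df_convention!r}")
    lo = 0.5  # below ~0.5 denominator df the F quantile is numerically unstable
    if linear_model_power(q.u, v_ceiling, q.f2, q.alpha) < q.power:
        raise ValueError("no solution below the df ceiling")
    if linear_model_power(q.u, lo, q.f2, q.alpha) >= q.power:
        v_star = lo
    else:
        v_star = optimize.brentq(
            lambda v: linear_model_power(q.u, v, q.f2, q.alpha) - q.power,
            lo, v_ceiling, xtol=1e-9,
        )
    n_cont = v_star + 1.0 if df_convention == "n-1" else q.u + v_star + 1.0
    return int(math.ceil(n_cont - 1e-9))


def classify_treatment_response(dhfmse: Optional[float]) -> Optional[str]:
    """Group the HFMSE change score: <= -3 decrease, >= 3 increase,
    strictly between -> stabilization; missing -> None."""
    if dhfmse is None or (isinstance(dhfmse, float) and math.isnan(dhfmse)):
        return None
    if dhfmse <= -3:
        return "decrease"
    if dhfmse >= 3:
        return "increase"
    return "stabilization"


# -- cohort summary ----------------------------------------------------------

@dataclass
class CohortSummary:
    """Baseline-characteristics table by SMN2 copy-number group.

    ``counts``/``percent`` hold category rows (sex, SMA type) per group
    column plus an ``overall`` column; percentages are within-column to
    one decimal. ``age_stats`` holds mean/SD/median/min/max/missing for
    age at onset and age at sampling.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    age_stats: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        formatted = self.counts.astype(object).copy()
        for col in formatted.columns:
            formatted[col] = [
                f"{int(c)} ({p}%)" for c, p in zip(self.counts[col], self.percent[col])
            ]
        formatted.loc["total"] = self.counts.loc["total"].astype(int).astype(str)
        return pd.concat([formatted, self.age_stats.astype(object)])


_SUMMARY_CATEGORIES = [
    ("male", lambda s: s.sex == "male"),
    ("female", lambda s: s.sex == "female"),
    ("type_1", lambda s: s.sma_type == 1),
    ("type_2", lambda s: s.sma_type == 2),
    ("type_3", lambda s: s.sma_type == 3),
    ("type_4", lambda s: s.sma_type == 4),
    ("presymptomatic", lambda s: s.presymptomatic),
]


def summarize_cohort(cohort: Sequence[SampleMeta]) -> CohortSummary:
    """Counts and within-group percentages by sex and SMA type per SMN2
    copy-number group, with an overall column, plus age summaries."""
    groups: dict[str, list[SampleMeta]] = {}
    for s in cohort:
        groups.setdefault(f"{s.smn2_cn}xSMN2", []).append(s)
    cols = sorted(groups) + ["overall"]
    groups["overall"] = list(cohort)

    counts = pd.DataFrame(index=["total"] + [c for c, _ in _SUMMARY_CATEGORIES],
                          columns=cols, dtype=float)
    percent = counts.copy()
    age_rows: dict[str, dict[str, str]] = {}
    for col in cols:
        members = groups[col]
        n = len(members)
        counts.at["total", col] = n
        percent.at["total", col] = 100.0
        for cat, pred in _SUMMARY_CATEGORIES:
            k = sum(1 for s in members if pred(s))
            counts.at[cat, col] = k
            percent.at[cat, col] = round(100.0 * k / n, 1) if n else 0.0
        for label, attr in [("age_at_onset", "age_at_onset"),
                            ("age_at_sampling", "age_at_sampling")]:
            vals = np.array([getattr(s, attr) for s in members
                             if getattr(s, attr) is not None], dtype=float)
            missing = n - vals.size
            stats_str = (
                f"{vals.mean():.3g} ({vals.std(ddof=1):.3g})" if vals.size > 1
                else ("-" if vals.size == 0 else f"{vals[0]:.3g} (NA)")
            )
            rng = (f"{np.median(vals):.3g} ({vals.min():.3g}, {vals.max():.3g})"
                   if vals.size else "-")
            age_rows.setdefault(f"{label}_mean_sd", {})[col] = stats_str
            age_rows.setdefault(f"{label}_median_min_max", {})[col] = rng
            age_rows.setdefault(f"{label}_missing", {})[col] = str(missing)
    age_stats = pd.DataFrame(age_rows).T[cols]
    return CohortSummary(counts=counts, percent=percent, age_stats=age_stats)
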