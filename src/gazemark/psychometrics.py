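"""Psychometric evaluation battery for participant-level biomarker tables.

Implements the four evaluation axes on a wide participant x timepoint table:

* construct validity — one-sample t-tests of each task's primary variable
  against its area-based chance level (one-sided for post-flash constriction,
  which is tested against zero);
* six-week stability — intraclass correlations from the two-way
  subjects x occasions decomposition, consistency and absolute-agreement
  variants, with age/IQ subgroup splits;
* group discrimination — linear models with an HC3
  heteroskedasticity-consistent covariance for the group contrast, optionally
  adjusted for age, IQ, site, and battery-wide %Valid Data, reported with the
  classical partial eta squared and the raw pooled-SD standardized mean
  difference;
* clinical correlations — Spearman rank correlations between biomarkers and
  clinical scores, plain and partialed on rank-transformed covariates.

No multiple-comparison adjustment is applied anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: default chance levels for the construct-validity tests (percent scale for
#: gaze variables; constriction is tested against 0 one-sided)
DEFAULT_CHANCE_LEVELS: Dict[str, Tuple[float, str]] = {
    "am_pct_face": (3.2, "two-sided"),
    "si_pct_face": (8.3, "two-sided"),
    "ss_pct_face": (3.9, "two-sided"),
    "bm_pct_bio": (50.0, "two-sided"),
    "plr_constriction": (0.0, "greater"),
}

#: primary variables evaluated by the stability/discrimination tables
PRIMARY_VARIABLES = [
    "omi",
    "am_pct_face",
    "si_pct_face",
    "ss_pct_face",
    "bm_pct_bio",
    "plr_latency_ms",
]

ICC_MODERATE = 0.5
ICC_HIGH = 0.75


@dataclass(frozen=True)
class OneSampleResult:
    n: int
    mean: float
    sd: float
    mu0: float
    t: float
    df: int
    p: float
    d: float


def one_sample_from_summary(
    n: int, mean: float, sd: float, mu0: float, alternative: str = "two-sided"
) -> OneSampleResult:
    """One-sample t-test from summary statistics.

    t = (M - mu0) / (SD / sqrt(n)), df = n - 1, d = (M - mu0) / SD.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd == 0:
        t = math.inf if mean != mu0 else 0.0
        warnings.warn("zero SD in one-sample test; t is infinite")
        return OneSampleResult(n, mean, sd, mu0, t, n - 1, 0.0, math.inf)
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "less":
        p = stats.t.cdf(t, df)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return OneSampleResult(n, mean, sd, mu0, t, df, float(p), (mean - mu0) / sd)


def one_sample_construct_test(
    values: Iterable[float], mu0: float, alternative: str = "two-sided"
) -> OneSampleResult:
    """One-sample t-test of raw values against a chance level."""
    x = np.asarray([v for v in values], dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least two finite values")
    return one_sample_from_summary(
        int(x.size), float(x.mean()), float(x.std(ddof=1)), mu0, alternative
    )


def pooled_cohens_d(group1: Iterable[float], group2: Iterable[float]) -> float:
    """Standardized mean difference with the pooled SD."""
    x = np.asarray(list(group1), dtype=float)
    y = np.asarray(list(group2), dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    return cohens_d_from_summary(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
    )


def cohens_d_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        warnings.warn("zero pooled SD; d undefined")
        return math.nan if m1 == m2 else math.copysign(math.inf, m1 - m2)
    return (m1 - m2) / math.sqrt(sp2)


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    icc_consistency: float
    icc_absolute: float
    n: int
    df: int

    def band(self, variant: str = "absolute") -> str:
        icc = self.icc_absolute if variant == "absolute" else self.icc_consistency
        if icc >= ICC_HIGH:
            return "high"
        if icc >= ICC_MODERATE:
            return "moderate"
        return "low"


def icc_stability(
    t1: Iterable[float], t2: Iterable[float]
) -> IccResult:
    """Two-occasion intraclass correlation from the two-way decomposition.

    Consistency: (MSR - MSE) / (MSR + MSE).
    Absolute agreement: (MSR - MSE) / (MSR + MSE + (2/n)(MSC - MSE)).
    Pairs with a missing value are dropped; needs n >= 3 complete pairs.
    """
    a = np.asarray(list(t1), dtype=float)
    b = np.asarray(list(t2), dtype=float)
    if a.shape != b.shape:
        raise ValueError("occasions must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + mse) if (msr + mse) > 0 else np.nan
    denom_a = msr + mse + (k / n) * (msc - mse)
    icc_a = (msr - mse) / denom_a if denom_a > 0 else np.nan
    return IccResult(
        icc_consistency=float(icc_c),
        icc_absolute=float(icc_a),
        n=int(n),
        df=int(n - 1),
    )


# ---------------------------------------------------------------------------
# group discrimination (HC3 robust linear model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscriminationResult:
    f: float
    df1: int
    df2: int
    p: float
    d: float
    eta_p2: float
    n: int
    group_means: Dict[str, float]
    group_sds: Dict[str, float]
    cov_hc3: Optional[np.ndarray] = None
    params: Optional[np.ndarray] = None
    exog_names: Optional[List[str]] = None


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str]
) -> Tuple[pd.DataFrame, List[str]]:
    """Intercept + group indicator + covariates (categoricals as indicator
    contrasts with the alphabetically first level as reference)."""
    parts: List[pd.DataFrame] = []
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    x = pd.DataFrame(index=df.index)
    x["Intercept"] = 1.0
    # indicator for the second group (alphabetical reference)
    x[f"group[{groups[1]}]"] = (df["group"] == groups[1]).astype(float)
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.dropna()))
            for lv in levels[1:]:
                x[f"{cov}[{lv}]"] = (col == lv).astype(float)
        else:
            x[cov] = col.astype(float)
    parts.append(x)
    out = pd.concat(parts, axis=1)
    arr = out.to_numpy()
    if np.linalg.matrix_rank(arr) < out.shape[1]:
        # greedy scan: name every column adding no rank
        aliased, kept = [], []
        for j, col in enumerate(out.columns):
            if np.linalg.matrix_rank(arr[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(col)
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    return out, [f"group[{groups[1]}]"]


def group_discrimination(
    y: Iterable[float],
    group: Iterable[str],
    covariates: Optional[pd.DataFrame] = None,
) -> DiscriminationResult:
    """Group contrast with HC3-robust Wald F, plus classical effect sizes.

    The robust covariance is the sandwich
    (X'X)^-1 X' diag(e_i^2/(1-h_ii)^2) X (X'X)^-1; the Wald test of the group
    coefficient uses F(1, n - p).  Partial eta squared comes from the
    classical (non-robust) decomposition, and d is the raw pooled-SD
    standardized mean difference.
    """
    df = pd.DataFrame({"y": np.asarray(list(y), dtype=float)})
    df["group"] = np.asarray(list(group))
    cov_names: List[str] = []
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            df[c] = covariates[c].to_numpy()
        cov_names = list(covariates.columns)
    df = df.dropna()
    if df.empty:
        raise ValueError("no complete cases")

    x, group_cols = _design_matrix(df, cov_names)
    model = sm.OLS(df["y"].to_numpy(), x.to_numpy())
    fit = model.fit(cov_type="HC3")
    gi = list(x.columns).index(group_cols[0])
    # Wald F for the single group contrast from the sandwich covariance
    v_gg = float(np.asarray(fit.cov_params())[gi, gi])
    if not np.isfinite(v_gg) or v_gg <= 0:
        raise ValueError("HC3 covariance undefined (leverage 1 observations?)")
    f = float(fit.params[gi] ** 2 / v_gg)
    df1 = 1
    df2 = int(len(df) - x.shape[1])
    p = float(stats.f.sf(f, df1, df2))

    # classical partial eta squared: type-III SS for the group term
    fit_plain = model.fit()
    reduced = sm.OLS(
        df["y"].to_numpy(), x.drop(columns=group_cols).to_numpy()
    ).fit()
    ss_group = float(reduced.ssr - fit_plain.ssr)
    eta_p2 = ss_group / (ss_group + float(fit_plain.ssr))

    groups_sorted = sorted(df["group"].unique())
    g1 = df.loc[df["group"] == groups_sorted[0], "y"]
    g2 = df.loc[df["group"] == groups_sorted[1], "y"]
    d = pooled_cohens_d(g1, g2)
    return DiscriminationResult(
        f=f,
        df1=df1,
        df2=df2,
        p=p,
        d=d,
        eta_p2=float(eta_p2),
        n=int(len(df)),
        group_means={g: float(df.loc[df["group"] == g, "y"].mean()) for g in groups_sorted},
        group_sds={g: float(df.loc[df["group"] == g, "y"].std(ddof=1)) for g in groups_sorted},
        cov_hc3=np.asarray(fit.cov_params()),
        params=np.asarray(fit.params),
        exog_names=list(x.columns),
    )


# ---------------------------------------------------------------------------
# Spearman correlations, plain and partial
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> Tuple[float, float, int]:
    """Spearman correlation (Pearson of mid-ranks) with a t-approximation p."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return math.nan, math.nan, n
    rho = float(np.corrcoef(_midranks(a), _midranks(b))[0, 1])
    p = _rank_t_pvalue(rho, n, 0)
    return rho, p, n


def partial_spearman_rho(
    x: Iterable[float],
    y: Iterable[float],
    covariates: pd.DataFrame,
) -> Tuple[float, float, int]:
    """Partial Spearman: ranks first, then partial Pearson on the ranks."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    z = covariates.to_numpy(dtype=float)
    keep = np.isfinite(a) & np.isfinite(b) & np.isfinite(z).all(axis=1)
    a, b, z = a[keep], b[keep], z[keep]
    n = a.size
    k = z.shape[1]
    if n < 4 + k:
        raise ValueError("too few complete cases for partial correlation")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return math.nan, math.nan, n
    ra, rb = _midranks(a), _midranks(b)
    rz = np.column_stack([_midranks(z[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), rz])
    beta_a, *_ = np.linalg.lstsq(design, ra, rcond=None)
    beta_b, *_ = np.linalg.lstsq(design, rb, rcond=None)
    res_a = ra - design @ beta_a
    res_b = rb - design @ beta_b
    denom = math.sqrt(float(res_a @ res_a) * float(res_b @ res_b))
    if denom == 0:
        return math.nan, math.nan, n
    rho = float(res_a @ res_b) / denom
    p = _rank_t_pvalue(rho, n, k)
    return rho, p, n


def _rank_t_pvalue(rho: float, n: int, n_covariates: int) -> float:
    df = n - 2 - n_covariates
    if df <= 0 or abs(rho) >= 1:
        return math.nan if abs(rho) < 1 else 0.0
    t = rho * math.sqrt(df / (1 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df))


def spearman_matrix(
    table: pd.DataFrame,
    biomarkers: Sequence[str],
    clinical: Sequence[str],
    partial_covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Long-format rho/p table for every biomarker x clinical pair.

    With ``partial_covariates`` the partial (rank-then-partial-Pearson)
    version is computed; pairs default to pairwise complete cases.
    """
    rows = []
    for bm in biomarkers:
        for cl in clinical:
            try:
                if partial_covariates:
                    rho, p, n = partial_spearman_rho(
                        table[bm], table[cl], table[list(partial_covariates)]
                    )
                else:
                    rho, p, n = spearman_rho(table[bm], table[cl])
            except ValueError:
                rho, p, n = math.nan, math.nan, 0
            rows.append(
                {"biomarker": bm, "clinical": cl, "rho": rho, "p": p, "n": n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# battery-level report
# ---------------------------------------------------------------------------

@dataclass
class PsychometricReport:
    construct_validity: pd.DataFrame
    stability: pd.DataFrame
    discrimination: pd.DataFrame
    correlations: pd.DataFrame
    correlations_partial: pd.DataFrame
    meta: Dict[str, object] = field(default_factory=dict)

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "construct_validity": self.construct_validity,
            "stability": self.stability,
            "discrimination": self.discrimination,
            "correlations": self.correlations,
            "correlations_partial": self.correlations_partial,
        }


def construct_validity_table(
    table: pd.DataFrame,
    chance_levels: Dict[str, Tuple[float, str]] = DEFAULT_CHANCE_LEVELS,
    group: str = "TD",
    timepoint: int = 1,
) -> pd.DataFrame:
    """One-sample tests of each primary variable against chance, in the
    reference group at the first timepoint."""
    sub = table[(table["group"] == group) & (table["timepoint"] == timepoint)]
    rows = []
    for var, (mu0, alternative) in chance_levels.items():
        if var not in sub.columns:
            continue
        vals = sub[var].dropna()
        if len(vals) < 2:
            continue
        r = one_sample_construct_test(vals, mu0, alternative)
        rows.append(
            {
                "variable": var,
                "group": group,
                "n": r.n,
                "mean": r.mean,
                "sd": r.sd,
                "mu0": mu0,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "d": r.d,
            }
        )
    return pd.DataFrame(rows)


def _icc_rows(
    table: pd.DataFrame,
    variables: Sequence[str],
    label: str,
    mask: Optional[pd.Series] = None,
) -> List[dict]:
    sub = table if mask is None else table[mask]
    piv: Dict[int, pd.DataFrame] = {
        tp: sub[sub["timepoint"] == tp].set_index("participant_id")
        for tp in (1, 2)
    }
    rows = []
    for var in variables:
        if var not in table.columns:
            continue
        joined = piv[1][[var]].join(
            piv[2][[var]], lsuffix="_t1", rsuffix="_t2", how="inner"
        ).dropna()
        if len(joined) < 3:
            warnings.warn(f"subgroup {label}: fewer than 3 pairs for {var}; omitted")
            continue
        r = icc_stability(joined[f"{var}_t1"], joined[f"{var}_t2"])
        rows.append(
            {
                "subgroup": label,
                "variable": var,
                "icc_absolute": r.icc_absolute,
                "icc_consistency": r.icc_consistency,
                "n": r.n,
                "df": r.df,
                "band": r.band(),
            }
        )
    return rows


def stability_table(
    table: pd.DataFrame,
    variables: Sequence[str] = tuple(PRIMARY_VARIABLES),
    age_split_years: float = 8.5,
    iq_split: float = 75.0,
) -> pd.DataFrame:
    """ICCs per variable for each group and for ASD age/IQ subgroups."""
    rows: List[dict] = []
    for g in sorted(table["group"].unique()):
        rows += _icc_rows(table, variables, g, table["group"] == g)
    asd = table["group"] == "ASD"
    rows += subgroup_analyses(
        table[asd], variables, age_split_years, iq_split
    ).to_dict("records")
    return pd.DataFrame(rows)


def subgroup_analyses(
    table: pd.DataFrame,
    variables: Sequence[str] = tuple(PRIMARY_VARIABLES),
    age_split_years: float = 8.5,
    iq_split: float = 75.0,
) -> pd.DataFrame:
    """Stability reruns within age and IQ subgroups (boundary goes to the
    upper cell: age >= split, IQ >= split)."""
    rows: List[dict] = []
    cells = [
        (f"age<{age_split_years}", table["age_years"] < age_split_years),
        (f"age>={age_split_years}", table["age_years"] >= age_split_years),
        (f"iq<{iq_split:g}", table["iq"] < iq_split),
        (f"iq>={iq_split:g}", table["iq"] >= iq_split),
    ]
    for label, mask in cells:
        if mask.sum() == 0:
            warnings.warn(f"empty subgroup {label}")
            continue
        rows += _icc_rows(table, variables, label, mask)
    return pd.DataFrame(rows)


def discrimination_table(
    table: pd.DataFrame,
    variables: Sequence[str] = tuple(PRIMARY_VARIABLES),
    covariates: Sequence[str] = ("age_years", "iq", "site", "pct_valid_data"),
    timepoint: int = 1,
) -> pd.DataFrame:
    """Unadjusted and covariate-adjusted group contrasts per variable."""
    sub = table[table["timepoint"] == timepoint]
    rows = []
    for var in variables:
        if var not in sub.columns:
            continue
        base = sub[["group", var]].dropna()
        if base["group"].nunique() < 2:
            continue
        for adjusted in (False, True):
            cols = list(covariates) if adjusted else []
            data = sub[["group", var] + cols].dropna()
            try:
                r = group_discrimination(
                    data[var], data["group"], data[cols] if cols else None
                )
            except ValueError as err:
                warnings.warn(f"discrimination failed for {var}: {err}")
                continue
            rows.append(
                {
                    "variable": var,
                    "adjusted": adjusted,
                    "F": r.f,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                    "d": r.d,
                    "eta_p2": r.eta_p2,
                    "n": r.n,
                    **{f"mean_{g}": m for g, m in r.group_means.items()},
                    **{f"sd_{g}": s for g, s in r.group_sds.items()},
                }
            )
    return pd.DataFrame(rows)


def evaluate(
    table: pd.DataFrame,
    chance_levels: Dict[str, Tuple[float, str]] = DEFAULT_CHANCE_LEVELS,
    clinical_columns: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("age_years", "iq", "site", "pct_valid_data"),
    partial_covariates: Sequence[str] = ("age_years", "iq", "pct_valid_data"),
    correlation_group: str = "ASD",
) -> PsychometricReport:
    """Run the full evaluation battery on a biomarker table."""
    if clinical_columns is None:
        known = set(PRIMARY_VARIABLES) | {
            "participant_id", "group", "timepoint", "omi_valid", "pct_valid_data",
            "age_years", "site",
        }
        clinical_columns = [
            c
            for c in table.columns
            if c not in known
            and not c.endswith("_valid")
            and not c.startswith(("am_", "si_", "ss_", "bm_", "plr_"))
            and table[c].dtype != object
        ]
    corr_sub = table[
        (table["group"] == correlation_group) & (table["timepoint"] == 1)
    ]
    return PsychometricReport(
        construct_validity=construct_validity_table(table, chance_levels),
        stability=stability_table(table),
        discrimination=discrimination_table(table, covariates=covariates),
        correlations=spearman_matrix(
            corr_sub, PRIMARY_VARIABLES, clinical_columns
        ),
        correlations_partial=spearman_matrix(
            corr_sub,
            PRIMARY_VARIABLES,
            [c for c in clinical_columns if c not in partial_covariates],
            partial_covariates=partial_covariates,
        ),
        meta={"correlation_group": correlation_group},
    )
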