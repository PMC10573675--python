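"""Inter- and intra-observer agreement statistics for repeated volumetry.

Implements, from their defining formulas, the statistics used to validate a
volumetry tool against repeated measurements by several observers:

* Lin's concordance correlation coefficient (CCC) with its Fisher-z
  large-sample confidence interval — agreement between two observers,
  penalizing location and scale shifts on top of correlation;
* Kendall's coefficient of concordance W with mid-rank tie correction —
  overall agreement among m rankings of n cases;
* the coefficient of variation (CV) of replicate measurements — intra-
  observer repeatability;
* Bland–Altman bias, limits of agreement and repeatability coefficient;
* the paired Student t-test and the Mann–Whitney U test (exact by
  enumeration for small tie-free samples, normal approximation with tie
  correction otherwise).

:func:`agreement_report` runs the complete analysis of a long-format
measurement table (case x observer x replicate) and returns the full
report: pairwise CCCs and Bland–Altman panels, overall W, per-observer CV
and intra-observer W, and subgroup CV comparisons by stone complexity,
homogeneity and multiplicity.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementTable",
    "AgreementReport",
    "lin_ccc",
    "kendall_w",
    "coefficient_of_variation",
    "bland_altman",
    "paired_t_test",
    "mann_whitney_u",
    "agreement_report",
]

#: z quantile used for limits of agreement and the repeatability coefficient.
LOA_Z = 1.96

_METADATA_COLS = ("is_complex", "is_homogeneous", "is_multiple", "location")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def lin_ccc(x, y, alpha: float = 0.05) -> dict[str, float]:
    """Lin's concordance correlation coefficient with confidence interval.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), using population
    (1/n) moments — the standard definition.  The confidence interval uses
    the Fisher z-transform of the CCC with Lin's large-sample variance.

    Returns ``{"ccc", "ci_low", "ci_high", "n"}``.  CCC is 1 for two
    identical constant series and 0 (with a warning) for two unequal
    constant series.
    """
    x, y = _paired(x, y, min_n=3)
    n = x.size
    mx, my = x.mean(), y.mean()
    # population moments (1/n), per the defining formula
    sx2 = x.var(ddof=0)
    sy2 = y.var(ddof=0)
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        # both series constant and equal: perfect agreement
        return {"ccc": 1.0, "ci_low": 1.0, "ci_high": 1.0, "n": n}
    if sx2 == 0.0 or sy2 == 0.0:
        warnings.warn(
            "at least one series is constant; CCC is 0 and no CI is defined",
            stacklevel=2,
        )
        return {"ccc": 0.0, "ci_low": float("nan"), "ci_high": float("nan"), "n": n}
    ccc = 2.0 * sxy / denom
    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 or r == 0.0:
        # perfect agreement: the z-variance degenerates
        return {"ccc": float(np.clip(ccc, -1, 1)), "ci_low": ccc, "ci_high": ccc, "n": n}
    # Lin's large-sample variance of z = atanh(ccc); u is the standardized
    # location shift between the two series.
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = ccc * ccc
    var_z = (
        (1 - r * r) * c2 / ((1 - c2) * r * r)
        + 2 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
        - ccc**4 * u**4 / (2 * r * r * (1 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    zq = stats.norm.ppf(1 - alpha / 2.0)
    z = math.atanh(ccc)
    half = zq * math.sqrt(var_z)
    return {
        "ccc": ccc,
        "ci_low": math.tanh(z - half),
        "ci_high": math.tanh(z + half),
        "n": n,
    }


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def kendall_w(ratings) -> dict[str, float]:
    """Kendall's coefficient of concordance with mid-rank tie correction.

    ``ratings`` is an (n cases x m raters) matrix.  Each rater's column is
    converted to mid-ranks; with rank sums R_i over raters,
    W = 12*S / (m^2*(n^3 - n) - m*T) where S = sum_i (R_i - mean R)^2 and
    T = sum over raters of sum(t^3 - t) over that rater's tie groups.
    The significance test is chi2 = m*(n-1)*W with n-1 degrees of freedom.

    Returns ``{"w", "chi2", "p", "n", "m"}``.  When every rater ties every
    case (0/0) W is defined as 1 with a warning.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D (cases x raters) matrix")
    n, m = ratings.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 cases and 2 raters")
    ranks = np.column_stack([_midranks(ratings[:, j]) for j in range(m)])
    rank_sums = ranks.sum(axis=1)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    t_corr = 0.0
    for j in range(m):
        _, counts = np.unique(ratings[:, j], return_counts=True)
        t_corr += float((counts**3 - counts).sum())
    denom = m * m * (n**3 - n) - m * t_corr
    if denom <= 0.0:
        warnings.warn(
            "all raters rated all cases equal; W is degenerate, defined as 1",
            stacklevel=2,
        )
        w = 1.0
    else:
        w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return {"w": float(w), "chi2": float(chi2), "p": p, "n": n, "m": m}


def coefficient_of_variation(replicates) -> float:
    """CV of one replicate series: sample SD / mean x 100 (%).

    Requires at least two replicates; a non-positive mean makes the CV
    meaningless for volumes and returns NaN.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("CV requires at least 2 replicates")
    mean = reps.mean()
    if mean <= 0:
        return float("nan")
    return float(reps.std(ddof=1) / mean * 100.0)


def bland_altman(x, y) -> dict[str, float]:
    """Bland–Altman agreement summary of paired measurements.

    Differences d = x - y; bias = mean(d); sd_diff = sample SD(d); limits
    of agreement = bias -/+ 1.96*sd_diff; repeatability coefficient
    rc = 1.96*sd_diff.
    """
    x, y = _paired(x, y, min_n=2)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_low": bias - LOA_Z * sd,
        "loa_high": bias + LOA_Z * sd,
        "rc": LOA_Z * sd,
        "n": x.size,
    }


def paired_t_test(x, y) -> dict[str, float]:
    """Two-sided paired Student t-test on the differences x - y."""
    x, y = _paired(x, y, min_n=2)
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("differences have zero variance; the t statistic is undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return {"t": float(t), "p": p, "df": n - 1}


def mann_whitney_u(a, b) -> dict[str, float]:
    """Two-sided Mann–Whitney U test.

    The U statistic of group ``a`` is computed from mid-ranks.  When both
    groups have at most 8 observations and there are no ties the p-value is
    exact, by enumeration of all rank assignments; otherwise the normal
    approximation with tie correction and continuity correction is used.

    Returns ``{"u", "p", "method"}``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size
    if na <= 8 and nb <= 8 and not has_ties:
        p = _mwu_exact_p(na, nb, u_a)
        method = "exact"
    else:
        n = na + nb
        mean_u = na * nb / 2.0
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float((counts**3 - counts).sum())
        var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var_u <= 0:
            p = 1.0
        else:
            # continuity-corrected two-sided normal approximation
            z = (abs(u_a - mean_u) - 0.5) / math.sqrt(var_u)
            p = 2.0 * float(stats.norm.sf(max(z, 0.0)))
        method = "asymptotic"
    return {"u": u_a, "p": min(p, 1.0), "method": method}


def _mwu_exact_p(na: int, nb: int, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of rank assignments (no ties)."""
    n = na + nb
    offset = na * (na + 1) / 2.0
    u_values = [
        sum(c) - offset for c in itertools.combinations(range(1, n + 1), na)
    ]
    u_lo = min(u_obs, na * nb - u_obs)
    u_hi = na * nb - u_lo
    extreme = sum(1 for u in u_values if u <= u_lo or u >= u_hi)
    return extreme / len(u_values)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


class MeasurementTable:
    """Long-format record of repeated volume measurements.

    One row per (case, observer, replicate) with the measured total stone
    volume in mm^3, plus optional per-case metadata columns ``is_complex``,
    ``is_homogeneous``, ``is_multiple`` and ``location``.
    """

    REQUIRED = ("case_id", "observer_id", "replicate", "volume_mm3")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table is missing columns: {missing}")
        df = df.copy()
        df["volume_mm3"] = df["volume_mm3"].astype(float)
        if (df["volume_mm3"] < 0).any():
            raise ValueError("volumes must be non-negative")
        dup = df.duplicated(subset=["case_id", "observer_id", "replicate"])
        if dup.any():
            raise ValueError("(case, observer, replicate) keys must be unique")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def observers(self) -> list:
        return sorted(self.df["observer_id"].unique().tolist())

    @property
    def cases(self) -> list:
        return sorted(self.df["case_id"].unique().tolist())

    @property
    def has_replicates(self) -> bool:
        return (
            self.df.groupby(["case_id", "observer_id"])["replicate"].count().max() >= 2
        )

    def case_metadata(self) -> pd.DataFrame:
        """Per-case metadata (first occurrence wins); may be empty."""
        cols = [c for c in _METADATA_COLS if c in self.df.columns]
        if not cols:
            return pd.DataFrame(index=pd.Index(self.cases, name="case_id"))
        return self.df.groupby("case_id")[cols].first()

    def per_case_medians(self) -> pd.DataFrame:
        """Wide (case x observer) matrix of per-case median volumes."""
        return (
            self.df.groupby(["case_id", "observer_id"])["volume_mm3"]
            .median()
            .unstack("observer_id")
        )

    def per_case_cv(self) -> pd.DataFrame:
        """Long table of per-(case, observer) CVs over replicates (%)."""
        rows = []
        for (case, obs), grp in self.df.groupby(["case_id", "observer_id"]):
            if len(grp) >= 2:
                rows.append(
                    {
                        "case_id": case,
                        "observer_id": obs,
                        "cv_percent": coefficient_of_variation(grp["volume_mm3"]),
                    }
                )
        return pd.DataFrame(rows, columns=["case_id", "observer_id", "cv_percent"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """Complete agreement analysis of one measurement table."""

    aggregation: str
    n_cases: int
    n_observers: int
    pairwise: dict = field(default_factory=dict)
    overall_kendall: dict = field(default_factory=dict)
    per_observer: dict = field(default_factory=dict)
    subgroup: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "aggregation": self.aggregation,
            "n_cases": self.n_cases,
            "n_observers": self.n_observers,
            "pairwise": self.pairwise,
            "overall_kendall": self.overall_kendall,
            "per_observer": self.per_observer,
            "subgroup": self.subgroup,
            "warnings": self.warnings,
        }


def _pair_key(a, b) -> str:
    return f"{a}_vs_{b}"


def agreement_report(
    table: MeasurementTable, aggregation: str = "median"
) -> AgreementReport:
    """Run the full inter-/intra-observer analysis of a measurement table.

    ``aggregation="median"`` collapses replicates to per-case medians before
    the pairwise and overall statistics (the only mode available when each
    (case, observer) cell holds a single summary value); ``"raw"`` pairs the
    raw replicate values by (case, replicate) across observers.

    Intra-observer statistics (CV, replicate-concordance W) always use the
    raw replicates and are skipped when there are none.  Subgroup CV
    comparisons require the corresponding metadata column and at least one
    case on each level; otherwise they are skipped with a warning.
    """
    if aggregation not in ("median", "raw"):
        raise ValueError("aggregation must be 'median' or 'raw'")
    observers = table.observers
    if len(observers) < 2:
        raise ValueError("need at least 2 observers")

    report = AgreementReport(
        aggregation=aggregation,
        n_cases=len(table.cases),
        n_observers=len(observers),
    )

    if aggregation == "median":
        wide = table.per_case_medians()
    else:
        wide = table.df.pivot_table(
            index=["case_id", "replicate"],
            columns="observer_id",
            values="volume_mm3",
            aggfunc="first",
        )
    wide = wide.dropna()

    for a, b in itertools.combinations(observers, 2):
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        entry = {"lin_ccc": lin_ccc(x, y), "bland_altman": bland_altman(x, y)}
        try:
            entry["t_test"] = paired_t_test(x, y)
        except ValueError as exc:
            entry["t_test"] = None
            report.warnings.append(f"t-test {a} vs {b} skipped: {exc}")
        report.pairwise[_pair_key(a, b)] = entry

    report.overall_kendall = kendall_w(wide.to_numpy())

    # intra-observer: replicate-level statistics
    cv_long = table.per_case_cv()
    for obs in observers:
        entry: dict = {}
        obs_cv = cv_long[cv_long["observer_id"] == obs]["cv_percent"].dropna()
        if len(obs_cv):
            entry["cv_percent_mean"] = float(obs_cv.mean())
            entry["cv_percent_median"] = float(obs_cv.median())
        sub = table.df[table.df["observer_id"] == obs]
        reps = sub.pivot_table(
            index="case_id", columns="replicate", values="volume_mm3", aggfunc="first"
        ).dropna()
        if reps.shape[1] >= 2 and reps.shape[0] >= 2:
            # replicate runs act as raters of the cases
            entry["intra_kendall"] = kendall_w(reps.to_numpy())
        if not entry:
            report.warnings.append(
                f"observer {obs}: no replicates, intra-observer statistics skipped"
            )
        report.per_observer[str(obs)] = entry

    # subgroup CV comparisons
    if cv_long.empty:
        report.warnings.append("no replicates: subgroup analyses skipped")
    else:
        meta = table.case_metadata()
        merged = cv_long.merge(meta, left_on="case_id", right_index=True, how="left")
        for col, labels in (
            ("is_complex", ("complex", "non_complex")),
            ("is_homogeneous", ("homogeneous", "heterogeneous")),
            ("is_multiple", ("multiple", "unique")),
        ):
            if col not in merged.columns or merged[col].isna().all():
                report.warnings.append(f"metadata {col} missing: subgroup skipped")
                continue
            yes = merged.loc[merged[col].astype(bool), "cv_percent"].dropna()
            no = merged.loc[~merged[col].astype(bool), "cv_percent"].dropna()
            if len(yes) == 0 or len(no) == 0:
                report.warnings.append(f"subgroup {col}: one level empty, skipped")
                continue
            report.subgroup[col] = {
                labels[0]: {"median_cv": float(yes.median()), "n": int(len(yes))},
                labels[1]: {"median_cv": float(no.median()), "n": int(len(no))},
                "mann_whitney": mann_whitney_u(yes, no),
            }
    return report
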