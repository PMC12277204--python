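"""Nonparametric statistical battery for the two-arm cueing trial.

Implements, from the standard formulas, the three tests the trial design
calls for, on small samples (N = 16) with mid-rank tie handling throughout:

* **Friedman test** for within-group differences of a measure across the
  three timepoints (pretest, posttest, follow-up);
* **Wilcoxon signed-rank test** for within-group first-3-day vs last-3-day
  average movement frequency;
* **Quade rank ANCOVA** for between-group differences in gain scores
  (posttest - pretest; follow-up - pretest) adjusting for age, months from
  stroke onset to treatment, and FTHUE level: rank the response and each
  covariate across all subjects ignoring group, regress response ranks on
  covariate ranks by least squares, and run a one-way ANOVA F test on the
  residuals across groups.

All tests are two-sided with significance flagged at p <= .05 and no
multiplicity correction by default (an optional Holm adjustment is offered
in :func:`analysis_report`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

TIMEPOINTS = ("pretest", "posttest", "follow_up")


class InsufficientDataError(ValueError):
    """Raised when a test's minimal sample-size precondition fails."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic_name`` is chi2, z or F; ``df`` is a float or an (df1, df2)
    pair; ``degenerate`` flags results computed on no usable information
    (for example all-zero paired differences), whose p is reported as 1.
    """

    method: str
    statistic: float
    statistic_name: str
    df: float | tuple[float, float] | None
    p_value: float
    n: int
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= ALPHA)

    def summary(self) -> str:
        df = self.df
        dftxt = (
            f"({df[0]:g}, {df[1]:g})" if isinstance(df, tuple) else f"{df:g}"
            if df is not None
            else "-"
        )
        flag = " *" if self.significant else ""
        note = " [degenerate]" if self.degenerate else ""
        return (
            f"{self.method}: {self.statistic_name} = {self.statistic:.4g}, "
            f"df = {dftxt}, p = {self.p_value:.4g}, n = {self.n}{flag}{note}"
        )

    def to_dict(self) -> dict:
        df = self.df
        return {
            "method": self.method,
            "statistic": float(self.statistic),
            "statistic_name": self.statistic_name,
            "df": list(df) if isinstance(df, tuple) else df,
            "p": float(self.p_value),
            "n": int(self.n),
            "significant": self.significant,
            "degenerate": self.degenerate,
            **self.extras,
        }


# ---------------------------------------------------------------------------
# Friedman test


def friedman(data: np.ndarray | pd.DataFrame) -> TestResult:
    """Friedman rank test over an n-subjects x k-timepoints matrix.

    Rows are ranked with mid-ranks on ties (constant rows contribute equal
    mid-ranks, they are not dropped). The tie-corrected statistic

        Q = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / sum_ij (r_ij - (k+1)/2)^2

    reduces to the classical 12/(nk(k+1)) * sum R_j^2 - 3n(k+1) form when no
    ties occur; p comes from the chi-squared distribution with k-1 df.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D subjects x timepoints matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError(f"need n >= 2 and k >= 2, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("repeated-measures matrix must be listwise complete")
    ranks = sps.rankdata(x, axis=1)
    centered = ranks - (k + 1) / 2.0
    col_dev = centered.sum(axis=0)
    denom = (centered**2).sum()
    if denom == 0.0:  # every row constant: no information
        return TestResult("friedman", 0.0, "chi2", float(k - 1), 1.0, n,
                          degenerate=True)
    q = (k - 1) * (col_dev**2).sum() / denom
    p = float(sps.chi2.sf(q, k - 1))
    return TestResult("friedman", float(q), "chi2", float(k - 1), p, n,
                      extras={"rank_sums": ranks.sum(axis=0).tolist()})


def friedman_exact_p(data: np.ndarray) -> float:
    """Exact Friedman p by enumerating all (k!)^n within-row rank orders.

    Permutation null: each subject's row is independently permuted; p is the
    fraction of assignments whose tie-corrected statistic reaches the
    observed one. Exponential cost — intended for n <= 5, k = 3.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    observed = friedman(x).statistic
    perms = list(itertools.permutations(range(k)))
    hits = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        xp = np.array([x[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman(xp).statistic >= observed - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def wilcoxon_signed_rank(
    first: np.ndarray, last: np.ndarray, exact_max_n: int = 25
) -> TestResult:
    """Paired Wilcoxon signed-rank test of ``last - first``.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks. With no ties and few pairs the p-value is exact (enumeration
    of the 2^n sign patterns via the rank-sum distribution); otherwise it is
    the two-sided normal approximation with tie-corrected variance

        var(W+) = n(n+1)(2n+1)/24 - sum_t (t^3 - t)/48.
    """
    f = np.asarray(first, dtype=float)
    l = np.asarray(last, dtype=float)
    if f.shape != l.shape or f.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    d = l - f
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, "z", None, 1.0, 0,
                          degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = 0.0 if var == 0 else (w_plus - mean) / np.sqrt(var)
    has_ties = bool((tie_counts > 1).any())
    degenerate = n < 2
    if not has_ties and n <= exact_max_n:
        p = _wilcoxon_exact_two_sided(w_plus, n)
        extras = {"exact": True}
    else:
        p = float(2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0
        extras = {"exact": False}
    extras.update({"w_plus": w_plus, "w_minus": w_minus})
    return TestResult("wilcoxon_signed_rank", float(z), "z", None, min(1.0, p),
                      n, degenerate=degenerate, extras=extras)


def _wilcoxon_exact_two_sided(w_plus: float, n: int) -> float:
    """Exact two-sided p for W+ with untied ranks 1..n (sign enumeration).

    The null distribution of W+ is the convolution of independent
    {0, r} coin flips over ranks r = 1..n (2^n equally likely patterns).
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()  # == 2**n
    w = int(round(w_plus))
    lo = counts[: w + 1].sum() / total
    hi = counts[w:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# Quade rank ANCOVA


def quade_ancova(
    gains: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> TestResult:
    """Quade nonparametric ANCOVA of a response across groups.

    Procedure: (1) rank the response over all N subjects ignoring group
    (mid-ranks on ties); (2) rank each covariate the same way; (3) regress
    the response ranks on the covariate ranks (with intercept) by least
    squares, pooled across groups; (4) one-way ANOVA F test on the residuals
    across groups with df = (g - 1, N - g).

    With zero covariates this is exactly a one-way ANOVA on response ranks.
    Zero-variance or rank-collinear covariates are dropped with a warning.
    """
    y = np.asarray(gains, dtype=float)
    g = np.asarray(groups)
    if y.ndim != 1 or g.shape != y.shape:
        raise ValueError("gains and groups must be 1-D and aligned")
    n = y.size
    labels = np.unique(g)
    n_groups = labels.size
    if n_groups < 2:
        raise InsufficientDataError("need at least two groups")

    if covariates is None:
        cov = np.empty((n, 0))
        cov_names: list[str] = []
    else:
        cov_df = (
            covariates
            if isinstance(covariates, pd.DataFrame)
            else pd.DataFrame(np.asarray(covariates, dtype=float))
        )
        cov = cov_df.to_numpy(dtype=float)
        cov_names = [str(c) for c in cov_df.columns]
    if n < cov.shape[1] + n_groups + 1:
        raise InsufficientDataError(
            f"N = {n} too small for {cov.shape[1]} covariates and "
            f"{n_groups} groups"
        )

    keep: list[int] = []
    for j in range(cov.shape[1]):
        if np.ptp(cov[:, j]) == 0.0:
            warnings.warn(
                f"covariate {cov_names[j]!r} has zero variance; dropped",
                UserWarning,
                stacklevel=2,
            )
        else:
            keep.append(j)
    cov = cov[:, keep]
    cov_names = [cov_names[j] for j in keep]

    y_ranks = sps.rankdata(y)
    design = np.ones((n, 1))
    used: list[str] = []
    for j in range(cov.shape[1]):
        col = sps.rankdata(cov[:, j])[:, None]
        cand = np.hstack([design, col])
        if np.linalg.matrix_rank(cand) > design.shape[1]:
            design = cand
            used.append(cov_names[j])
        else:
            warnings.warn(
                f"covariate {cov_names[j]!r} is rank-collinear with earlier "
                "covariates; dropped",
                UserWarning,
                stacklevel=2,
            )

    beta, *_ = np.linalg.lstsq(design, y_ranks, rcond=None)
    resid = y_ranks - design @ beta

    grand = resid.mean()
    ss_between = 0.0
    ss_within = 0.0
    for lab in labels:
        r = resid[g == lab]
        ss_between += r.size * (r.mean() - grand) ** 2
        ss_within += ((r - r.mean()) ** 2).sum()
    df1 = n_groups - 1
    df2 = n - n_groups
    # a covariate that explains the response ranks exactly leaves only
    # floating-point noise in the residuals: report no group effect rather
    # than a 0/0 noise ratio
    if ss_between + ss_within <= 1e-8 * n:
        return TestResult(
            "quade_ancova", 0.0, "F", (float(df1), float(df2)), 1.0, n,
            degenerate=True, extras={"covariates_used": used},
        )
    if ss_within == 0.0:
        f_stat = 0.0 if ss_between == 0.0 else np.inf
        p = 1.0 if ss_between == 0.0 else 0.0
        degenerate = ss_between == 0.0
    else:
        f_stat = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f_stat, df1, df2))
        degenerate = False
    return TestResult(
        "quade_ancova",
        float(f_stat),
        "F",
        (float(df1), float(df2)),
        p,
        n,
        degenerate=degenerate,
        extras={"covariates_used": used},
    )


# ---------------------------------------------------------------------------
# Gain scores and the trial-level report


def gain_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-measure gain scores from a long outcome table.

    gain1 = posttest - pretest; gain2 = follow_up - pretest. Subjects
    missing any timepoint for a measure are excluded from that measure with
    a warning (no imputation). Covariate columns are carried through.
    """
    required = {"subject_id", "timepoint", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["subject_id", "measure"],
        columns="timepoint",
        values="value",
        aggfunc="first",
    )
    have = [t for t in TIMEPOINTS if t in wide.columns]
    if len(have) < 3:
        raise ValueError(f"outcome table lacks timepoints {set(TIMEPOINTS) - set(have)}")
    incomplete = wide[list(TIMEPOINTS)].isna().any(axis=1)
    if incomplete.any():
        for subj, meas in wide.index[incomplete]:
            warnings.warn(
                f"subject {subj!r} excluded from measure {meas!r}: "
                "missing timepoint",
                UserWarning,
                stacklevel=2,
            )
        wide = wide[~incomplete]
    out = pd.DataFrame(
        {
            "gain1": wide["posttest"] - wide["pretest"],
            "gain2": wide["follow_up"] - wide["pretest"],
        }
    ).reset_index()
    meta_cols = [
        c
        for c in ("group", "fthue_level", "age", "onset_months")
        if c in table.columns
    ]
    if meta_cols:
        meta = table.drop_duplicates("subject_id").set_index("subject_id")[meta_cols]
        out = out.join(meta, on="subject_id")
    return out


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def analysis_report(
    outcome_table: pd.DataFrame,
    daily_counts: pd.DataFrame,
    alpha: float = ALPHA,
    holm: bool = False,
) -> dict:
    """Assemble the trial's full statistical report.

    Parameters
    ----------
    outcome_table
        Long table: subject_id, group, fthue_level, age, onset_months,
        timepoint, measure, value.
    daily_counts
        Per-subject daily movement frequency: subject_id, group, day, count.
    holm
        Apply a Holm adjustment across the between-group tests (off by
        default, matching per-test reporting).

    Returns a JSON-serializable dict: within-group Friedman tests per
    measure, within-group Wilcoxon tests on first-3 vs last-3-day movement
    frequency, between-group Quade ANCOVAs on gain1 and gain2 per measure,
    and kinematic summaries per group.
    """
    report: dict = {"alpha": alpha, "within_group": [], "between_group": [],
                    "kinematics": []}

    measures = sorted(outcome_table["measure"].unique())
    groups = sorted(outcome_table["group"].unique())

    for grp in groups:
        sub = outcome_table[outcome_table["group"] == grp]
        for meas in measures:
            block = sub[sub["measure"] == meas].pivot_table(
                index="subject_id", columns="timepoint", values="value",
                aggfunc="first",
            )[list(TIMEPOINTS)]
            res = friedman(block.to_numpy())
            report["within_group"].append(
                {"group": grp, "measure": meas, **res.to_dict()}
            )

    for grp in sorted(daily_counts["group"].unique()):
        sub = daily_counts[daily_counts["group"] == grp]
        wide = sub.pivot_table(index="subject_id", columns="day",
                               values="count", aggfunc="first")
        first3 = wide[[1, 2, 3]].mean(axis=1).to_numpy()
        last3 = wide[[12, 13, 14]].mean(axis=1).to_numpy()
        res = wilcoxon_signed_rank(first3, last3)
        report["within_group"].append(
            {"group": grp, "measure": "movement_frequency_f3l3", **res.to_dict()}
        )
        report["kinematics"].append(
            {
                "group": grp,
                "mean_avg14": float(wide.mean(axis=1).mean()),
                "mean_gain_f3l3": float((last3 - first3).mean()),
                "n": int(wide.shape[0]),
            }
        )

    gains = gain_scores(outcome_table)
    cov_cols = ["age", "onset_months", "fthue_level"]
    for meas in measures:
        block = gains[gains["measure"] == meas]
        for gain_col in ("gain1", "gain2"):
            res = quade_ancova(
                block[gain_col].to_numpy(),
                block["group"].to_numpy(),
                block[cov_cols],
            )
            report["between_group"].append(
                {"measure": meas, "gain": gain_col, **res.to_dict()}
            )

    if holm:
        ps = np.array([row["p"] for row in report["between_group"]])
        for row, padj in zip(report["between_group"], holm_adjust(ps)):
            row["p_holm"] = float(padj)
            row["significant"] = bool(padj <= alpha)
    return report


def report_markdown(report: dict) -> str:
    """Render an analysis report dict as a human-readable table."""
    lines = ["# Trial analysis report", "",
             f"Significance level: p <= {report['alpha']:g}", "",
             "## Within-group tests", "",
             "| group | measure | method | statistic | df | p | n | sig |",
             "|---|---|---|---|---|---|---|---|"]
    for row in report["within_group"]:
        df = row["df"]
        dftxt = ", ".join(f"{v:g}" for v in df) if isinstance(df, list) else (
            f"{df:g}" if df is not None else "-")
        lines.append(
            f"| {row['group']} | {row['measure']} | {row['method']} | "
            f"{row['statistic_name']} = {row['statistic']:.3f} | {dftxt} | "
            f"{row['p']:.4f} | {row['n']} | {'*' if row['significant'] else ''} |"
        )
    lines += ["", "## Between-group tests (gain scores)", "",
              "| measure | gain | method | statistic | df | p | n | sig |",
              "|---|---|---|---|---|---|---|---|"]
    for row in report["between_group"]:
        df = row["df"]
        dftxt = ", ".join(f"{v:g}" for v in df) if isinstance(df, list) else "-"
        lines.append(
            f"| {row['measure']} | {row['gain']} | {row['method']} | "
            f"{row['statistic_name']} = {row['statistic']:.3f} | {dftxt} | "
            f"{row['p']:.4f} | {row['n']} | {'*' if row['significant'] else ''} |"
        )
    lines += ["", "## Kinematic summaries", "",
              "| group | mean 14-day avg count | mean gain (last3-first3) | n |",
              "|---|---|---|---|"]
    for row in report["kinematics"]:
        lines.append(
            f"| {row['group']} | {row['mean_avg14']:.1f} | "
            f"{row['mean_gain_f3l3']:.1f} | {row['n']} |"
        )
    return "\n".join(lines) + "\n"
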