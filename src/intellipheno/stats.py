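"""Statistical battery for the phenotyping pipeline.

Mixed-design (split-plot) repeated-measures ANOVA with one between-subjects
factor (genotype) and one within-subjects factor (day), Mauchly's sphericity
test on the orthonormal-contrast covariance, Bonferroni-corrected per-day
post hoc comparisons gated on a significant interaction, pooled two-sample
t-tests (from raw samples or from printed mean +/- SEM summaries), and
mean +/- SEM descriptives.

The ANOVA uses the classical univariate sums-of-squares decomposition.
With complete data (every subject measured on every day) the five components

    SS_group + SS_subjects(group) + SS_day + SS_day:group + SS_error

are mutually orthogonal even with unequal group sizes, so the decomposition
is exact.  Missing animal-days are handled by listwise deletion before the
fit.  No sphericity correction is applied by default; the Greenhouse-Geisser
epsilon is computed and reported, and applied only on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    """One test: statistic (F or t), degrees of freedom, two-sided p."""

    term: str  # between | within | interaction | pairwise
    statistic: float
    df1: float
    df2: float | None
    p: float
    adjusted_p: float | None = None
    label: str = ""


def significance_marker(p: float) -> str:
    """The ``*`` convention at 0.05 / 0.01 / 0.001 / 0.0001."""
    if np.isnan(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "ns"


@dataclass
class RMDesign:
    """Complete subjects x days response matrix with a 2-level group label.

    ``data[i, j]`` is subject ``i``'s value on day ``j``; rows with any
    missing value are dropped (listwise deletion) at construction.
    """

    data: np.ndarray          # (n_subjects, n_days), complete
    groups: np.ndarray        # (n_subjects,) group labels
    subject_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("need a subjects x days matrix with >= 2 days")
        keep = ~np.isnan(self.data).any(axis=1)
        self.data = self.data[keep]
        self.groups = self.groups[keep]
        if self.subject_ids is not None:
            self.subject_ids = np.asarray(self.subject_ids)[keep]

    @property
    def n_days(self) -> int:
        return self.data.shape[1]

    @property
    def group_levels(self) -> np.ndarray:
        return np.unique(self.groups)

    @classmethod
    def from_metric_table(
        cls, metrics_df: pd.DataFrame, phase: str, metric: str
    ) -> "RMDesign":
        sub = metrics_df[(metrics_df["phase"] == phase) & (metrics_df["metric"] == metric)]
        wide = sub.pivot_table(index="animal_id", columns="day", values="value",
                               aggfunc="first", dropna=False)
        wide = wide.sort_index()
        genos = sub.drop_duplicates("animal_id").set_index("animal_id")["genotype"]
        return cls(
            data=wide.to_numpy(float),
            groups=genos.loc[wide.index].to_numpy(),
            subject_ids=wide.index.to_numpy(),
        )


def _check_design(design: RMDesign) -> None:
    levels, counts = np.unique(design.groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = levels[counts < 2]
        raise ValueError(f"groups {list(small)} have < 2 complete subjects")


def rm_anova(design: RMDesign) -> dict[str, StatResult]:
    """Mixed-design ANOVA: group (between), day (within), group x day.

    F ratios use the split-plot error terms: ``MS_group / MS_subjects(group)``
    for the between factor and ``MS_err(within)`` for day and the
    interaction.  Degrees of freedom: (g-1, N-g), (d-1, (N-g)(d-1)) and
    ((g-1)(d-1), (N-g)(d-1)).
    """
    _check_design(design)
    X = design.data
    groups = design.groups
    levels = design.group_levels
    n, d = X.shape
    g = len(levels)

    grand = X.mean()
    subj_means = X.mean(axis=1)
    day_means = X.mean(axis=0)

    ss_group = 0.0
    ss_subj = 0.0
    ss_inter = 0.0
    ss_err = 0.0
    for lev in levels:
        sel = groups == lev
        n_g = int(sel.sum())
        Xg = X[sel]
        g_mean = Xg.mean()
        cell = Xg.mean(axis=0)  # per-day cell means of this group
        ss_group += d * n_g * (g_mean - grand) ** 2
        ss_subj += d * float(((subj_means[sel] - g_mean) ** 2).sum())
        ss_inter += n_g * float(((cell - g_mean - day_means + grand) ** 2).sum())
        resid = Xg - cell[None, :] - subj_means[sel][:, None] + g_mean
        ss_err += float((resid ** 2).sum())
    ss_day = n * float(((day_means - grand) ** 2).sum())

    df_group, df_sub = g - 1, n - g
    df_day = d - 1
    df_inter = (g - 1) * (d - 1)
    df_err = (n - g) * (d - 1)

    ms_sub = ss_subj / df_sub
    ms_err = ss_err / df_err
    f_group = (ss_group / df_group) / ms_sub if ms_sub > 0 else 0.0
    f_day = (ss_day / df_day) / ms_err if ms_err > 0 else 0.0
    f_inter = (ss_inter / df_inter) / ms_err if ms_err > 0 else 0.0

    return {
        "between": StatResult("between", f_group, df_group, df_sub,
                              float(sps.f.sf(f_group, df_group, df_sub))),
        "within": StatResult("within", f_day, df_day, df_err,
                             float(sps.f.sf(f_day, df_day, df_err))),
        "interaction": StatResult("interaction", f_inter, df_inter, df_err,
                                  float(sps.f.sf(f_inter, df_inter, df_err))),
    }


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(d: int) -> np.ndarray:
    """(d-1) x d matrix of orthonormal contrasts, each orthogonal to 1."""
    basis = np.eye(d) - 1.0 / d
    q, _ = np.linalg.qr(basis)
    return q[:, : d - 1].T


def _pooled_within_cov(design: RMDesign) -> tuple[np.ndarray, int]:
    X, groups = design.data, design.groups
    n, d = X.shape
    g = len(design.group_levels)
    S = np.zeros((d, d))
    for lev in design.group_levels:
        Xg = X[groups == lev]
        dev = Xg - Xg.mean(axis=0)
        S += dev.T @ dev
    return S / (n - g), n - g


def mauchly_test(design: RMDesign) -> dict[str, float]:
    """Mauchly's W on the contrast covariance, chi-square approximation.

    Uses the pooled within-group covariance (error df = N - g).  A single
    within-subject contrast (d = 2) is always spherical: W = 1, p = 1.
    Raises ``np.linalg.LinAlgError`` on a singular contrast covariance.
    """
    levels, counts = np.unique(design.groups, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 complete subjects")
    d = design.n_days
    if d == 2:
        return {"W": 1.0, "chi2": 0.0, "df": 0, "p": 1.0}
    S, n_e = _pooled_within_cov(design)
    C = _orthonormal_contrasts(d)
    T = C @ S @ C.T
    k = d - 1
    det = np.linalg.det(T)
    tr = np.trace(T)
    if det <= 0 or tr <= 0:
        raise np.linalg.LinAlgError("singular contrast covariance")
    W = float(det / (tr / k) ** k)
    f = 1.0 - (2.0 * k * k + k + 2.0) / (6.0 * k * n_e)
    chi2 = float(-n_e * f * np.log(W))
    df = k * (k + 1) // 2 - 1
    # two-term chi-square expansion (Box 1949), as SPSS and pingouin report
    w2 = (
        (k + 2) * (k - 1) * (k - 2) * (2 * k**3 + 6 * k * k + 3 * k + 2)
        / (288.0 * (n_e * k * f) ** 2)
    )
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    return {"W": W, "chi2": chi2, "df": df, "p": float(p1 + w2 * (p2 - p1))}


def greenhouse_geisser_epsilon(design: RMDesign) -> float:
    """GG epsilon from the contrast covariance eigen-structure; 1 under
    perfect sphericity, 1/(d-1) at worst."""
    d = design.n_days
    if d == 2:
        return 1.0
    S, _ = _pooled_within_cov(design)
    C = _orthonormal_contrasts(d)
    T = C @ S @ C.T
    lam = np.linalg.eigvalsh(T)
    return float(lam.sum() ** 2 / ((d - 1) * (lam ** 2).sum()))


# ---------------------------------------------------------------------------
# post hocs and t-tests
# ---------------------------------------------------------------------------

def bonferroni_posthoc(
    design: RMDesign,
    anova: dict[str, StatResult] | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Per-day two-sample pooled t comparisons, Bonferroni-adjusted by the
    number of days; only callable after a significant interaction (the
    gating rule of the analysis plan)."""
    _check_design(design)
    if len(design.group_levels) != 2:
        raise ValueError("post hocs defined for exactly 2 groups")
    if anova is None:
        anova = rm_anova(design)
    if not anova["interaction"].p < alpha:
        raise ValueError(
            f"interaction p = {anova['interaction'].p:.4g} is not below "
            f"alpha = {alpha}; post hoc tests are not licensed"
        )
    a, b = design.group_levels
    d = design.n_days
    results = []
    for j in range(d):
        res = pooled_t_from_data(
            design.data[design.groups == a, j], design.data[design.groups == b, j]
        )
        results.append(
            StatResult(
                "pairwise", res.statistic, res.df1, None, res.p,
                adjusted_p=min(1.0, res.p * d), label=f"day {j + 1}: {a} vs {b}",
            )
        )
    return results


def pooled_t_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int
) -> StatResult:
    """Student's unpaired t from printed mean +/- SEM summaries.

    ``sd_i = sem_i * sqrt(n_i)``; pooled variance, df = n1 + n2 - 2,
    two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    s1 = sem1 * np.sqrt(n1)
    s2 = sem2 * np.sqrt(n2)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    return StatResult("pairwise", float(t), df, None, float(2 * sps.t.sf(abs(t), df)))


def pooled_t_from_data(x1: Sequence[float], x2: Sequence[float]) -> StatResult:
    """Student's unpaired t from the raw samples; identical to
    :func:`pooled_t_from_summary` applied to their own summaries."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need >= 2 values per sample")
    df = len(x1) + len(x2) - 2
    sp2 = ((len(x1) - 1) * x1.var(ddof=1) + (len(x2) - 1) * x2.var(ddof=1)) / df
    if sp2 == 0:
        t = 0.0
    else:
        t = float((x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / len(x1) + 1 / len(x2))))
    return StatResult("pairwise", t, df, None,
                      float(2 * sps.t.sf(abs(t), df)) if sp2 > 0 else 1.0)


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """(mean, SEM) with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


# ---------------------------------------------------------------------------
# the per-phase/metric report
# ---------------------------------------------------------------------------

def analyze_metrics(metrics_df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Run the battery over every (phase, metric) of a long-format table.

    Multi-day metrics get the mixed RM-ANOVA (with Mauchly's test reported
    and post hocs only after a significant interaction); single-window
    metrics get the pooled two-sample t.  Metrics without two complete
    subjects per group are skipped with a logged reason.
    """
    import logging

    log = logging.getLogger("intellipheno.stats")
    rows: list[dict] = []

    def add(phase: str, metric: str, r: StatResult, extra: str = "") -> None:
        rows.append(
            {
                "phase": phase,
                "metric": metric,
                "term": r.label or r.term,
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": r.df2 if r.df2 is not None else "",
                "p": r.p,
                "adjusted_p": r.adjusted_p if r.adjusted_p is not None else "",
                "sig": significance_marker(
                    r.adjusted_p if r.adjusted_p is not None else r.p
                ),
                "note": extra,
            }
        )

    for (phase, metric), sub in metrics_df.groupby(["phase", "metric"], sort=False):
        n_days = sub["day"].nunique()
        try:
            if n_days >= 2:
                design = RMDesign.from_metric_table(metrics_df, phase, metric)
                res = rm_anova(design)
                try:
                    sph = mauchly_test(design)
                    note = f"Mauchly W={sph['W']:.3f}, p={sph['p']:.3f}"
                except np.linalg.LinAlgError:
                    note = "Mauchly: singular contrast covariance"
                for term in ("between", "within", "interaction"):
                    add(phase, metric, res[term], note if term == "between" else "")
                if res["interaction"].p < alpha and len(design.group_levels) == 2:
                    for r in bonferroni_posthoc(design, res, alpha):
                        add(phase, metric, r)
            else:
                wide = sub.dropna(subset=["value"])
                groups = [
                    grp["value"].to_numpy(float)
                    for _, grp in wide.groupby("genotype")
                ]
                if len(groups) != 2:
                    raise ValueError("need exactly 2 genotypes")
                r = pooled_t_from_data(groups[0], groups[1])
                add(phase, metric, r)
        except (ValueError, np.linalg.LinAlgError) as exc:
            log.warning("skipping %s/%s: %s", phase, metric, exc)
    return pd.DataFrame(rows)


def write_stats_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, lineterminator="\n")
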