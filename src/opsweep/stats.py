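"""Group statistics: normality screening, omnibus + post-hoc comparisons
with Bonferroni family-wise control, annotated slope tables and ICC
reliability.

Route selection mirrors the standard two-branch recipe: when every group
passes a Kolmogorov-Smirnov normality screen (Lilliefors-corrected, since
the null moments are estimated from the sample) and Levene's test finds
homogeneous variances, a one-way ANOVA with Bonferroni-adjusted pairwise
t-tests is used; otherwise Kruskal-Wallis with Dunn's rank-based multiple
comparisons.  Each family of pairwise comparisons (a triple within a
sagittal class across vertical patterns, or across sagittal classes within
a vertical pattern) has m = 3 members; adjusted p = min(1, 3 p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from . import tables
from .exceptions import ConfigurationError

__all__ = [
    "NormalityResult", "ComparisonReport", "ReliabilityReport",
    "normality_screen", "compare_groups", "dunn_test", "build_table56",
    "icc", "reliability_report",
]

ALPHA = 0.05

#: letter markers for the two comparison families
INTRA_PAIR_LETTERS = {("hypo", "nor"): "a", ("hypo", "hyper"): "b",
                      ("nor", "hyper"): "c"}
INTER_PAIR_LETTERS = {("I", "II"): "A", ("I", "III"): "B", ("II", "III"): "C"}


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_lilliefors: float
    p_ks: float      # uncorrected KS p against the moment-matched normal
    normal: bool
    degenerate: bool = False


def normality_screen(values: np.ndarray, alpha: float = ALPHA) -> NormalityResult:
    """KS-type normality screen with the Lilliefors correction.

    The uncorrected KS p (normal with sample moments plugged in) is also
    reported.  A constant sample is flagged degenerate and non-normal.
    """
    x = np.asarray(values, float).ravel()
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if x.std(ddof=1) == 0.0:
        return NormalityResult(np.nan, 0.0, 0.0, normal=False, degenerate=True)
    stat, p_lf = lilliefors(x, dist="norm")
    p_ks = float(sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    return NormalityResult(float(stat), float(p_lf), p_ks,
                           normal=bool(p_lf > alpha))


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tied groups; two-sided normal p, unadjusted.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank, i = {}, 0
    for g in names:
        mean_rank[g] = ranks[i:i + sizes[g]].mean()
        i += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - T / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        rows.append({"group_1": a, "group_2": b, "z": float(z),
                     "p_raw": float(2.0 * sps.norm.sf(abs(z)))})
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Omnibus + pairwise comparison of one quantity across groups."""

    groups: dict[str, dict]          # name -> {n, mean, sd}
    route: str                       # 'anova_bonferroni' | 'kruskal_dunn'
    normality: dict[str, NormalityResult]
    levene_stat: float
    levene_p: float
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame           # group_1, group_2, stat, p_raw, p_adj, significant
    alpha: float
    excluded: list[str] = field(default_factory=list)

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.pairwise[self.pairwise["significant"]]
        return [tuple(r) for r in sig[["group_1", "group_2"]].to_numpy()]

    def as_dict(self) -> dict:
        return {
            "groups": self.groups, "route": self.route,
            "levene": {"stat": self.levene_stat, "p": self.levene_p},
            "normality": {g: vars(r) for g, r in self.normality.items()},
            "omnibus": {"stat": self.omnibus_stat, "p": self.omnibus_p},
            "pairwise": self.pairwise.to_dict(orient="records"),
            "alpha": self.alpha, "excluded": self.excluded,
        }


def compare_groups(samples: dict[str, np.ndarray],
                   alpha: float = ALPHA) -> ComparisonReport:
    """Two-branch group comparison with Bonferroni-capped pairwise p values.

    Groups with fewer than 3 observations are excluded with a warning entry;
    at least two usable groups are required.
    """
    usable, excluded = {}, []
    for name, vals in samples.items():
        arr = np.asarray(vals, float).ravel()
        if len(arr) < 3:
            excluded.append(name)
        else:
            usable[name] = arr
    if len(usable) < 2:
        raise ConfigurationError("need at least two groups with n >= 3")
    names = list(usable)
    arrays = [usable[g] for g in names]

    normality = {g: normality_screen(usable[g], alpha)
                 if len(usable[g]) >= 5 else
                 NormalityResult(np.nan, np.nan, np.nan, normal=False)
                 for g in names}
    lev_stat, lev_p = sps.levene(*arrays, center="median")
    parametric = all(r.normal for r in normality.values()) and lev_p > alpha

    m = len(names) * (len(names) - 1) // 2  # comparisons in this family
    if parametric:
        route = "anova_bonferroni"
        omni = sps.f_oneway(*arrays)
        rows = []
        for a, b in itertools.combinations(names, 2):
            t = sps.ttest_ind(usable[a], usable[b], equal_var=True)
            rows.append({"group_1": a, "group_2": b,
                         "stat": float(t.statistic),
                         "p_raw": float(t.pvalue)})
        pw = pd.DataFrame(rows)
    else:
        route = "kruskal_dunn"
        omni = sps.kruskal(*arrays)
        pw = dunn_test(usable).rename(columns={"z": "stat"})
    pw["p_adj"] = np.minimum(1.0, m * pw["p_raw"])
    pw["significant"] = pw["p_adj"] < alpha

    return ComparisonReport(
        groups={g: {"n": len(usable[g]), "mean": float(usable[g].mean()),
                    "sd": float(usable[g].std(ddof=1))} for g in names},
        route=route, normality=normality,
        levene_stat=float(lev_stat), levene_p=float(lev_p),
        omnibus_stat=float(omni.statistic), omnibus_p=float(omni.pvalue),
        pairwise=pw, alpha=alpha, excluded=excluded)


# ---------------------------------------------------------------------------
# annotated slope tables


def _letters_for(report: ComparisonReport, letter_map: dict) -> dict[str, str]:
    """Per-group superscript letters from a family's significant pairs."""
    out = {g: "" for g in report.groups}
    for (g1, g2), letter in letter_map.items():
        if (g1, g2) in report.significant_pairs() or \
           (g2, g1) in report.significant_pairs():
            # mark the second group of the pair, the table convention
            out[g2] = out[g2] + letter if letter not in out[g2] else out[g2]
    return out


def build_table56(slopes_with_labels: pd.DataFrame, quantity: str = "k",
                  alpha: float = ALPHA) -> dict:
    """Slope/intercept summary in the 3x4 reference layout with markers.

    ``slopes_with_labels`` needs columns k, b, sagittal, vertical.  Returns
    {'table': formatted DataFrame, 'comparisons': reports, 'inter_row': ...}.
    Intra-group letters (a, b, c) compare vertical patterns within each
    sagittal class; inter-group letters (A, B, C) compare sagittal classes
    within each vertical pattern; 'N.S' marks families with no significant
    pair.
    """
    if quantity not in ("k", "b"):
        raise ConfigurationError("quantity must be 'k' or 'b'")
    df = slopes_with_labels
    need = {quantity, "sagittal", "vertical"}
    if not need.issubset(df.columns):
        raise ConfigurationError(f"missing columns {need - set(df.columns)}")
    cells_present = {(s, v) for s, v in
                     df[["sagittal", "vertical"]].drop_duplicates().to_numpy()}
    if len(cells_present) < 2:
        raise ConfigurationError("need at least two populated cells")

    comparisons: dict[str, ComparisonReport] = {}
    intra_letters: dict[tuple[str, str], str] = {}
    for s in tables.SAGITTAL:
        sub = df[df.sagittal == s]
        groups = {v: sub[sub.vertical == v][quantity].to_numpy()
                  for v in tables.VERTICAL if (s, v) in cells_present}
        if len(groups) >= 2:
            rep = compare_groups(groups, alpha)
            comparisons[f"intra_{s}"] = rep
            for v, letters in _letters_for(rep, INTRA_PAIR_LETTERS).items():
                intra_letters[(s, v)] = letters
    inter_row: dict[str, str] = {}
    for v in tables.VERTICAL:
        sub = df[df.vertical == v]
        groups = {s: sub[sub.sagittal == s][quantity].to_numpy()
                  for s in tables.SAGITTAL if (s, v) in cells_present}
        if len(groups) >= 2:
            rep = compare_groups(groups, alpha)
            comparisons[f"inter_{v}"] = rep
            letters = sorted({INTER_PAIR_LETTERS[pair] for pair in
                              map(tuple, map(sorted, rep.significant_pairs()))})
            inter_row[v] = ",".join(letters) if letters else "N.S"

    def fmt(sub: pd.DataFrame, letters: str = "") -> str:
        if not len(sub):
            return "-"
        mean = sub[quantity].mean()
        sd = sub[quantity].std(ddof=1) if len(sub) > 1 else 0.0
        sup = f" [{letters}]" if letters else ""
        return f"{mean:.2f} ± {sd:.2f}{sup}"

    out = pd.DataFrame(index=list(tables.SAGITTAL) + ["Total"],
                       columns=list(tables.VERTICAL) + ["Total"], dtype=object)
    for s in tables.SAGITTAL:
        for v in tables.VERTICAL:
            sub = df[(df.sagittal == s) & (df.vertical == v)]
            out.loc[s, v] = fmt(sub, intra_letters.get((s, v), ""))
        out.loc[s, "Total"] = fmt(df[df.sagittal == s])
    for v in tables.VERTICAL:
        out.loc["Total", v] = fmt(df[df.vertical == v])
    out.loc["Total", "Total"] = fmt(df)

    return {"table": out, "comparisons": comparisons, "inter_row": inter_row,
            "quantity": quantity, "alpha": alpha}


# ---------------------------------------------------------------------------
# reliability


@dataclass
class ICCResult:
    value: float
    form: str
    ms_subjects: float
    ms_raters: float
    ms_error: float
    n_subjects: int
    n_raters: int


def icc(ratings: np.ndarray, form: str = "two-way-random-absolute") -> ICCResult:
    """Single-rater ICC from the two-way mean-squares decomposition.

    'two-way-random-absolute' is ICC(2,1) (inter-operator agreement);
    'two-way-mixed-consistency' is ICC(3,1) (intra-operator consistency).
    Missing cells are not supported (no imputation).
    """
    M = np.asarray(ratings, float)
    if M.ndim != 2:
        raise ValueError("ratings must be a subjects x raters matrix")
    if np.any(~np.isfinite(M)):
        raise ValueError("missing or non-finite cells are not supported")
    n, k = M.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    grand = M.mean()
    row_m = M.mean(axis=1)
    col_m = M.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((M - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "two-way-random-absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif form == "two-way-mixed-consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ConfigurationError(f"unknown ICC form {form!r}")
    value = (msr - mse) / denom if denom > 0 else np.nan
    return ICCResult(float(value), form, float(msr), float(msc), float(mse),
                     n, k)


@dataclass
class ReliabilityReport:
    inter_operator: dict[str, float]         # field -> ICC(2,1), session 1
    intra_operator: dict[str, dict[str, float]]  # rater -> field -> ICC(3,1)
    n_subjects: int
    n_raters: int
    n_sessions: int

    def inter_range(self) -> tuple[float, float]:
        vals = list(self.inter_operator.values())
        return (min(vals), max(vals))

    def intra_range(self) -> tuple[float, float]:
        vals = [v for per in self.intra_operator.values()
                for v in per.values()]
        return (min(vals), max(vals))


def reliability_report(ratings: np.ndarray,
                       fields: tuple[str, ...]) -> ReliabilityReport:
    """ICC summary of a (rater, session, record, field) ratings tensor.

    Inter-operator agreement uses the first session across raters
    (two-way random, absolute, single rater); intra-operator consistency
    uses each rater's sessions (two-way mixed, consistency).
    """
    R = np.asarray(ratings, float)
    if R.ndim != 4:
        raise ValueError("ratings must be rater x session x record x field")
    n_raters, n_sessions, n_rec, n_fields = R.shape
    if n_raters < 2:
        raise ConfigurationError("inter-operator ICC needs >= 2 raters")
    inter = {}
    for j, f in enumerate(fields):
        inter[f] = icc(R[:, 0, :, j].T, "two-way-random-absolute").value
    intra = {}
    if n_sessions >= 2:
        for r in range(n_raters):
            intra[f"rater_{r + 1}"] = {
                f: icc(R[r, :, :, j].T, "two-way-mixed-consistency").value
                for j, f in enumerate(fields)}
    return ReliabilityReport(inter, intra, n_rec, n_raters, n_sessions)
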