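"""Two-sample and multi-group comparison battery.

Covers the statistics used to compare mold panels across years and
regions: the Wilcoxon rank-sum test per species (exact enumeration for
small samples, tie-corrected normal approximation otherwise), the
Holm step-down family-wise adjustment across species, Student's t for
the group log-sums and moldiness index, and one-way ANOVA with
Tukey(-Kramer) HSD pairwise comparisons rendered as a compact letter
display ("means followed by the same letter are not significantly
different").

Floored qPCR data are tie-heavy — many homes sit exactly at the
1 CE/mg detection floor — so the exact mode enumerates the permutation
distribution of the mid-rank sum over the observed value multiset
rather than using tie-free closed forms, and the normal mode applies
the variance tie correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import ConcentrationMatrix, MoldPanel
from .scoring import ermi

__all__ = [
    "TwoSampleResult",
    "TukeyResult",
    "ComparisonReport",
    "wilcoxon_rank_sum",
    "holm_bonferroni",
    "student_t",
    "anova_tukey",
    "compact_letter_display",
    "species_comparison_battery",
]

EXACT_LIMIT = 12  # auto mode enumerates when n1 + n2 <= this


@dataclass(frozen=True)
class TwoSampleResult:
    """One two-sample test: statistic, p, sizes, method tag."""

    statistic: float
    p_raw: float
    method: str
    n1: int
    n2: int
    p_adjusted: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs Tukey HSD on a one-way layout, with letter display."""

    labels: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    mse: float
    df_error: int
    pairwise: pd.DataFrame  # columns: a, b, diff, q, p_adjusted, significant
    letters: dict[str, str]
    alpha: float
    anova_f: float
    anova_p: float
    degenerate: bool = False
    small_groups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p for the rank sum of x, by enumeration.

    Enumerates the null distribution of the mid-rank sum over all
    C(n1+n2, n1) assignments of the observed (possibly tied) value
    multiset, via a subset-sum dynamic program on doubled ranks (which
    are integers even under mid-ranking).  Returns (W, p).
    """
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = float(ranks[:n1].sum())
    doubled = np.rint(2 * ranks).astype(int)
    total_sum = int(doubled.sum())

    # dp[k][s] = number of size-k subsets of the doubled ranks with sum s
    dp = np.zeros((n1 + 1, total_sum + 1), dtype=object)
    dp[0][0] = 1
    for r in doubled:
        for k in range(min(n1, n) - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            for s in nz[::-1]:
                dp[k + 1][s + r] += row[s]

    counts = dp[n1]
    total = sum(counts)
    w2 = int(round(2 * w_obs))
    mean2 = Fraction(n1 * (n + 1))  # doubled-scale null mean of W
    dev = abs(Fraction(w2) - mean2)
    tail = sum(
        c for s, c in enumerate(counts) if c and abs(Fraction(s) - mean2) >= dev
    )
    return w_obs, float(Fraction(tail, total))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TwoSampleResult:
    """Two-sided Wilcoxon rank-sum test.

    ``mode``: ``exact`` enumerates the permutation null of the
    mid-rank sum (correct under ties); ``normal`` uses the
    tie-corrected normal approximation with continuity correction;
    ``auto`` picks exact when n1+n2 <= 12.

    The reported statistic is the rank sum W of ``x``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    if mode == "auto":
        mode = "exact" if n1 + n2 <= EXACT_LIMIT else "normal"
    if mode not in ("exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # every assignment gives the same rank sum
        return TwoSampleResult(w, 1.0, f"wilcoxon_{mode}", n1, n2)

    if mode == "exact":
        w, p = _exact_ranksum_p(x, y)
        return TwoSampleResult(w, p, "wilcoxon_exact", n1, n2)

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TwoSampleResult(w, float(res.pvalue), "wilcoxon_normal", n1, n2)


# ---------------------------------------------------------------------------
# Holm-Bonferroni step-down
# ---------------------------------------------------------------------------


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order.

    The k-th smallest raw p is multiplied by (m - k + 1), capped at 1,
    with monotonicity enforced along the sorted order; adjusted values
    never fall below the raw ones.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------


def student_t(
    x: Sequence[float], y: Sequence[float], variant: str = "pooled"
) -> TwoSampleResult:
    """Two-sided two-sample t-test (pooled df = n1+n2-2, or Welch).

    Zero variance in both samples is handled by convention: equal
    means give p = 1; unequal means give the p = 0 separation limit,
    flagged degenerate.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    method = f"t_{variant}"
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TwoSampleResult(0.0, 1.0, method, len(x), len(y), degenerate=True)
        return TwoSampleResult(
            np.inf if x.mean() > y.mean() else -np.inf,
            0.0,
            method,
            len(x),
            len(y),
            degenerate=True,
        )
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TwoSampleResult(
        float(res.statistic), float(res.pvalue), method, len(x), len(y)
    )


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey(-Kramer) HSD + compact letter display
# ---------------------------------------------------------------------------


def compact_letter_display(
    labels: Sequence[str], significant_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so two groups share one iff their pair is non-significant.

    Insert-and-absorb: start with one column holding every group; for
    each significant pair, split every column containing both members
    into two columns (each missing one member), then absorb columns
    that became subsets of others.  Letters follow input group order.
    """
    order = {lab: i for i, lab in enumerate(labels)}
    sig = sorted(
        {tuple(sorted(p, key=order.__getitem__)) for p in significant_pairs},
        key=lambda p: (order[p[0]], order[p[1]]),
    )
    columns: list[set[str]] = [set(labels)]
    for a, b in sig:
        split: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                split.extend((col - {a}, col - {b}))
            else:
                split.append(col)
        # absorb: keep only maximal, distinct, non-empty columns
        columns = []
        for c in split:
            if c and not any(c < d for d in split) and c not in columns:
                columns.append(c)
    columns.sort(key=lambda c: min(order[m] for m in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for i, col in enumerate(columns):
        ch = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for lab in col:
            letters[lab] += ch
    return {lab: "".join(sorted(s)) for lab, s in letters.items()}


def anova_tukey(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """One-way ANOVA with Tukey HSD all-pairs comparisons and letters.

    Pairwise q = |mean_a - mean_b| / sqrt(MSE/2 * (1/n_a + 1/n_b))
    (Tukey-Kramer for unequal n); adjusted p from the studentized-range
    distribution with k groups and N-k error df.  Groups with n < 3
    are listed in ``small_groups`` — their comparisons rest on very
    little information.
    """
    labels = tuple(groups.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {lab: np.asarray(list(groups[lab]), dtype=float) for lab in labels}
    for lab, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    ns = {lab: len(arr) for lab, arr in arrays.items()}
    means = {lab: float(arr.mean()) for lab, arr in arrays.items()}
    sds = {lab: float(arr.std(ddof=1)) for lab, arr in arrays.items()}
    k = len(labels)
    n_total = sum(ns.values())
    df_error = n_total - k
    sse = sum(((arr - arr.mean()) ** 2).sum() for arr in arrays.values())
    mse = float(sse / df_error)
    degenerate = mse == 0.0

    f_stat, f_p = stats.f_oneway(*arrays.values())

    rows = []
    for a, b in itertools.combinations(labels, 2):
        diff = means[a] - means[b]
        if degenerate:
            q = np.inf if diff != 0 else 0.0
            p_adj = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_error))
        rows.append(
            {
                "a": a,
                "b": b,
                "diff": diff,
                "q": float(q),
                "p_adjusted": min(1.0, max(0.0, p_adj)),
                "significant": p_adj <= alpha,
            }
        )
    pairwise = pd.DataFrame(rows)
    sig_pairs = [
        (r["a"], r["b"]) for r in rows if r["significant"]
    ]
    letters = compact_letter_display(labels, sig_pairs)
    return TukeyResult(
        labels=labels,
        means=means,
        sds=sds,
        ns=ns,
        mse=mse,
        df_error=df_error,
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        anova_f=float(f_stat) if not degenerate else np.inf,
        anova_p=float(f_p) if not degenerate else 0.0,
        degenerate=degenerate,
        small_groups=tuple(lab for lab in labels if ns[lab] < 3),
    )


# ---------------------------------------------------------------------------
# Per-species year comparison battery
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Machine twin of a per-species year-comparison table.

    ``species`` has one row per panel species: group membership, yearly
    mean CE/mg, raw and Holm-adjusted Wilcoxon p (or method "NM" for a
    species constant at the same value in both years, which carries no
    information and is excluded from the adjustment family), and a
    significance flag at ``alpha``.  ``group_tests`` holds the
    Student's t comparisons of the per-home group log-sums and the
    moldiness index; these are reported unadjusted.
    """

    species: pd.DataFrame
    group_tests: dict[str, TwoSampleResult]
    alpha: float
    holm_family_size: int = 0

    def to_csv(self, path) -> None:
        out = self.species.copy()
        out.to_csv(path, index=False)


def species_comparison_battery(
    matrix_a: ConcentrationMatrix,
    matrix_b: ConcentrationMatrix,
    panel: MoldPanel,
    alpha: float = 0.05,
    mode: str = "auto",
    holm_family: str = "all",
    paired: bool = False,
) -> ComparisonReport:
    """Compare two year-cohorts species by species and at group level.

    Per species: Wilcoxon rank-sum on the per-home floored CE/mg values
    (signed-rank on home-matched pairs when ``paired``).  Holm
    adjustment over the family of testable species — all of them when
    ``holm_family='all'``, separately within group 1 and group 2 when
    ``'per_group'``.  Group log-sums and the moldiness index are
    compared by pooled Student's t.
    """
    if len(matrix_a) < 2 or len(matrix_b) < 2:
        raise ValueError("each year needs at least 2 homes")
    if holm_family not in ("all", "per_group"):
        raise ValueError(f"unknown holm_family {holm_family!r}")
    if list(matrix_a.species) != list(matrix_b.species):
        raise ValueError("matrices must share the same species columns")

    if paired:
        homes_a = {h for h, _ in matrix_a.rows}
        homes_b = {h for h, _ in matrix_b.rows}
        shared = sorted(homes_a & homes_b)
        if len(shared) < 2:
            raise ValueError("paired mode needs >= 2 homes present in both years")

    rows = []
    for assay in panel.assays:
        sp = assay.species_name
        xa = matrix_a.values[sp].to_numpy(dtype=float)
        xb = matrix_b.values[sp].to_numpy(dtype=float)
        avg_a, avg_b = float(xa.mean()), float(xb.mean())
        combined = np.concatenate([xa, xb])
        if np.all(combined == combined[0]):
            rows.append(
                {
                    "species": sp,
                    "group": assay.group,
                    "avg_a": avg_a,
                    "avg_b": avg_b,
                    "p_raw": np.nan,
                    "method": "NM",
                }
            )
            continue
        if paired:
            pa = matrix_a.values[sp].droplevel("year").loc[shared].to_numpy(float)
            pb = matrix_b.values[sp].droplevel("year").loc[shared].to_numpy(float)
            d = pa - pb
            if np.all(d == 0):
                res = TwoSampleResult(0.0, 1.0, "wilcoxon_signed_rank", len(d), len(d))
            else:
                sr = stats.wilcoxon(pa, pb, zero_method="wilcox", method="auto")
                res = TwoSampleResult(
                    float(sr.statistic),
                    float(sr.pvalue),
                    "wilcoxon_signed_rank",
                    len(d),
                    len(d),
                )
        else:
            res = wilcoxon_rank_sum(xa, xb, mode=mode)
        rows.append(
            {
                "species": sp,
                "group": assay.group,
                "avg_a": avg_a,
                "avg_b": avg_b,
                "p_raw": res.p_raw,
                "method": res.method,
            }
        )

    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    testable = table["method"].ne("NM")
    if holm_family == "all":
        families = [testable]
    else:
        families = [testable & table["group"].eq(g) for g in (1, 2)]
    family_size = int(testable.sum())
    for fam in families:
        if fam.any():
            table.loc[fam, "p_adjusted"] = holm_bonferroni(
                table.loc[fam, "p_raw"].tolist()
            )
    table["significant"] = table["p_adjusted"].le(alpha).fillna(False)

    # group-level log-sums and moldiness index, pooled t, unadjusted
    def _scores(matrix: ConcentrationMatrix) -> pd.DataFrame:
        recs = [
            ermi(row, panel, home_id=h, year=int(y))
            for (h, y), row in matrix.values.iterrows()
        ]
        return pd.DataFrame(
            {
                "sum_logs_g1": [r.sum_logs_g1 for r in recs],
                "sum_logs_g2": [r.sum_logs_g2 for r in recs],
                "ermi": [r.ermi for r in recs],
            }
        )

    sa, sb = _scores(matrix_a), _scores(matrix_b)
    group_tests = {
        name: student_t(sa[name], sb[name], variant="pooled")
        for name in ("sum_logs_g1", "sum_logs_g2", "ermi")
    }

    table = table.rename(columns={"avg_a": "avg_2018", "avg_b": "avg_2019"})
    table = table[
        [
            "species",
            "group",
            "avg_2018",
            "avg_2019",
            "p_raw",
            "p_adjusted",
            "significant",
            "method",
        ]
    ]
    return ComparisonReport(
        species=table,
        group_tests=group_tests,
        alpha=alpha,
        holm_family_size=family_size,
    )
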