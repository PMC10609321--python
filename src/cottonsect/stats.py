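"""Per-line statistics: summaries, ANOVA, pairwise t, Tukey–Kramer HSD.

The inferential battery applied to the canonical fiber table, per
metric, with cotton line as the grouping factor:

1. optional per-line outlier trimming (IQR or z-score rule);
2. descriptive summaries (n, mean, sd, quantiles);
3. one-way ANOVA;
4. unadjusted all-pairs equal-variance Student's t;
5. all-pairs Tukey–Kramer HSD with a compact letter display.

The Tukey–Kramer statistic for groups i, j with pooled mean-square
error MSE is

    q_ij = |m_i − m_j| / sqrt( MSE/2 · (1/n_i + 1/n_j) )

referred to the studentized-range distribution with k groups and
N − k error degrees of freedom; with equal n this is classical Tukey
HSD. Letters come from the maximal cliques of the non-significance
graph, so two lines share a letter iff their difference is not
significant.

Equal variances (pooled MSE) are assumed throughout, matching standard
fixed-effects one-way practice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "StatsError",
    "LineSummary",
    "HSDReport",
    "AnovaResult",
    "trim_outliers",
    "anova_oneway",
    "pairwise_t",
    "tukey_kramer",
    "connecting_letters",
    "summarize_lines",
    "analyze_table",
    "letters_report_text",
]


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class LineSummary:
    """Descriptives of one metric within one line."""

    line: str
    n: int
    mean: float
    sd: float
    min: float
    q25: float
    median: float
    q75: float
    max: float


@dataclass(frozen=True)
class HSDReport:
    """All-pairs Tukey–Kramer result for one metric.

    ``pairs`` has one row per unordered pair with the mean difference,
    q statistic, adjusted p, and significance flag; ``letters`` maps
    each line to its connecting-letter string; ``means`` is sorted in
    descending order as in a standard letters report.
    """

    metric: str
    pairs: pd.DataFrame
    letters: dict[str, str]
    means: "pd.Series[float]"
    alpha: float


def trim_outliers(
    values: Sequence[float], rule: str = "iqr", k: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic outlier removal; returns (kept, removed).

    ``rule='iqr'`` drops points outside [Q1 − k·IQR, Q3 + k·IQR]
    (needs ≥ 4 points, else a warning and no trimming);
    ``rule='zscore'`` drops points with |v − mean|/sd > k. Removed
    values are returned, never silently discarded.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise StatsError("values must be 1-D")
    if rule == "iqr":
        if len(v) < 4:
            warnings.warn("fewer than 4 values: IQR trimming skipped", stacklevel=2)
            return v, np.empty(0)
        q1, q3 = np.percentile(v, [25, 75])
        iqr = q3 - q1
        keep = (v >= q1 - k * iqr) & (v <= q3 + k * iqr)
    elif rule == "zscore":
        if len(v) < 3 or v.std(ddof=1) == 0:
            warnings.warn("too few values or zero spread: z-score trimming skipped", stacklevel=2)
            return v, np.empty(0)
        z = np.abs(v - v.mean()) / v.std(ddof=1)
        keep = z <= k
    else:
        raise StatsError(f"unknown outlier rule {rule!r}")
    return v[keep], v[~keep]


def _check_groups(groups: Mapping[str, Sequence[float]], min_n: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < min_n:
            raise StatsError(f"group {name!r} has n={len(v)} < {min_n}")
        out[str(name)] = v
    return out


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across lines."""
    g = _check_groups(groups)
    arrays = list(g.values())
    N = sum(len(a) for a in arrays)
    k = len(arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        raise StatsError("degenerate data: zero variance everywhere")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", _sps.ConstantInputWarning)
        F, p = _sps.f_oneway(*arrays)
    if not np.isfinite(F):
        raise StatsError("degenerate ANOVA input: zero within-group variance")
    return AnovaResult(F=float(F), df=(k - 1, N - k), p=float(p))


def pairwise_t(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Unadjusted equal-variance Student's t for every pair of lines."""
    g = _check_groups(groups)
    rows = []
    for a, b in itertools.combinations(g, 2):
        t, p = _sps.ttest_ind(g[a], g[b], equal_var=True)
        rows.append(
            {
                "group_i": a,
                "group_j": b,
                "mean_diff": float(np.mean(g[a]) - np.mean(g[b])),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def tukey_kramer(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05, metric: str = ""
) -> HSDReport:
    """All-pairs Tukey–Kramer HSD with connecting letters.

    Unequal group sizes are handled by the Kramer form of the standard
    error; the adjusted p of each pair is the studentized-range tail
    probability of its q statistic at (k, N − k).
    """
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    g = _check_groups(groups)
    names = list(g)
    k = len(names)
    N = sum(len(v) for v in g.values())
    df_err = N - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in g.values()) / df_err
    if mse <= 0:
        raise StatsError("zero within-group variance: HSD undefined")
    means = pd.Series({n: float(g[n].mean()) for n in names}).sort_values(ascending=False)
    rows = []
    sig: dict[frozenset, bool] = {}
    for a, b in itertools.combinations(names, 2):
        diff = float(g[a].mean() - g[b].mean())
        se = np.sqrt(mse / 2.0 * (1.0 / len(g[a]) + 1.0 / len(g[b])))
        q = abs(diff) / se
        p = float(_sps.studentized_range.sf(q, k, df_err))
        is_sig = p < alpha
        sig[frozenset((a, b))] = is_sig
        rows.append(
            {
                "group_i": a,
                "group_j": b,
                "mean_diff": diff,
                "q": float(q),
                "p_adj": p,
                "significant": is_sig,
            }
        )
    letters = connecting_letters(list(means.index), sig)
    return HSDReport(
        metric=metric, pairs=pd.DataFrame(rows), letters=letters, means=means, alpha=alpha
    )


def _maximal_cliques(adj: dict[str, set[str]]) -> list[set[str]]:
    """Bron–Kerbosch with pivoting; fine for the handful of lines used here."""
    cliques: list[set[str]] = []

    def bk(R: set[str], P: set[str], X: set[str]) -> None:
        if not P and not X:
            cliques.append(set(R))
            return
        pivot = max(P | X, key=lambda u: len(adj[u] & P))
        for v in sorted(P - adj[pivot]):
            bk(R | {v}, P & adj[v], X & adj[v])
            P = P - {v}
            X = X | {v}

    bk(set(), set(adj), set())
    return cliques


def connecting_letters(
    names_in_order: Sequence[str], significant: Mapping[frozenset, bool]
) -> dict[str, str]:
    """Compact letter display from a complete pairwise significance map.

    ``names_in_order`` fixes the presentation order (descending mean in
    an HSD report). Each maximal clique of mutually non-significant
    groups receives one letter, in order of its best-ranked member, and
    every group collects the letters of the cliques containing it. Two
    groups share a letter iff their difference is not significant.
    """
    names = list(names_in_order)
    for a, b in itertools.combinations(names, 2):
        if frozenset((a, b)) not in significant:
            raise StatsError(f"missing significance entry for pair ({a!r}, {b!r})")
    adj = {
        n: {m for m in names if m != n and not significant[frozenset((n, m))]} for n in names
    }
    cliques = _maximal_cliques(adj)
    rank = {n: i for i, n in enumerate(names)}
    cliques.sort(key=lambda c: sorted(rank[n] for n in c))
    from .segmentation import candidate_letter_sequence

    labels = candidate_letter_sequence(len(cliques))
    letters = {n: "" for n in names}
    for lab, clique in zip(labels, cliques):
        for n in clique:
            letters[n] += lab
    return letters


def summarize_lines(
    table: pd.DataFrame, metrics: Sequence[str], line_col: str = "Line"
) -> pd.DataFrame:
    """n/mean/sd/quantile summary per line per metric (tidy long form)."""
    if line_col not in table.columns:
        raise StatsError(f"table lacks a {line_col!r} column")
    rows = []
    pairs = [
        (line, metric, grp[metric].to_numpy(dtype=float))
        for line, grp in table.groupby(line_col, sort=True)
        for metric in metrics
    ]
    for line, metric, vals in pairs:
        if len(vals) == 0:
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        rows.append(
            {
                "Line": line,
                "Metric": metric,
                "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                "min": q[0],
                "q25": q[1],
                "median": q[2],
                "q75": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


def analyze_table(
    table: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    trim_rule: Optional[str] = "iqr",
    trim_k: float = 1.5,
    line_col: str = "Line",
) -> tuple[pd.DataFrame, dict[str, AnovaResult], dict[str, HSDReport], pd.DataFrame]:
    """Full battery on a canonical table.

    Returns (summaries, anova per metric, HSD report per metric,
    trimmed-outlier audit). Metrics default to every numeric column.
    """
    if metrics is None:
        metrics = [
            c
            for c in table.columns
            if c not in ("Name", line_col) and pd.api.types.is_numeric_dtype(table[c])
        ]
    trimmed: dict[str, dict[str, np.ndarray]] = {}
    audit_rows = []
    for metric in metrics:
        groups = {}
        for line, grp in table.groupby(line_col, sort=True):
            vals = grp[metric].to_numpy(dtype=float)
            if trim_rule is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vals, removed = trim_outliers(vals, rule=trim_rule, k=trim_k)
                for r in removed:
                    audit_rows.append({"Line": line, "Metric": metric, "value": r})
            groups[str(line)] = vals
        trimmed[metric] = groups
    summary_tbl = pd.concat(
        [
            summarize_lines(
                pd.DataFrame(
                    [(ln, v) for ln, vs in trimmed[m].items() for v in vs],
                    columns=["Line", m],
                ),
                [m],
            )
            for m in metrics
        ],
        ignore_index=True,
    )
    anova = {m: anova_oneway(trimmed[m]) for m in metrics}
    hsd = {m: tukey_kramer(trimmed[m], alpha=alpha, metric=m) for m in metrics}
    audit = pd.DataFrame(audit_rows, columns=["Line", "Metric", "value"])
    return summary_tbl, anova, hsd, audit


def letters_report_text(report: HSDReport) -> str:
    """Plain-text letters table: line, letter columns, mean — sorted by
    descending mean, mirroring a standard connecting-letters report."""
    all_letters = sorted({ch for s in report.letters.values() for ch in s})
    lines = [f"# Tukey-Kramer HSD connecting letters: {report.metric} (alpha={report.alpha:g})"]
    header = ["Line"] + all_letters + ["Mean"]
    lines.append("\t".join(header))
    for name, mean in report.means.items():
        row = [name]
        row += [ch if ch in report.letters[name] else "" for ch in all_letters]
        row.append(f"{mean:.2f}")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
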