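"""Fatty-acid bookkeeping and variety-level statistics.

Works on tidy per-sample tables (pandas DataFrames) holding the 16 acid
columns (relative % of total fatty acids), total fat (% by weight) and a
``variety`` label. Family totals (SFA/MUFA/PUFA) are sums over the fixed
memberships in :mod:`nutspec.varieties`. Variety summaries report mean, SE
and n; grand means are unweighted averages over variety means, the
convention under which within-family shares (e.g. oleic as a fraction of
MUFA) are quoted. Between-variety comparisons use one-way ANOVA with
Tukey-Kramer post-hoc tests and a compact letter display.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .varieties import ALL_ACIDS, FAMILIES, WALNUT_PROFILES

ANALYTES = ("total_fat", "SFA", "MUFA", "PUFA") + ALL_ACIDS


def family_sums(table: pd.DataFrame) -> pd.DataFrame:
    """Append SFA/MUFA/PUFA columns = sums of the member acid columns."""
    missing = [a for a in ALL_ACIDS if a not in table.columns]
    if missing:
        raise ValueError(f"missing acid columns: {missing}")
    out = table.copy()
    for family, members in FAMILIES.items():
        out[family] = out[list(members)].sum(axis=1)
    return out


def sample_family_sums(sample: dict | pd.Series) -> tuple[float, float, float]:
    """(SFA, MUFA, PUFA) totals for a single sample's acid values."""
    missing = [a for a in ALL_ACIDS if a not in sample]
    if missing:
        raise ValueError(f"missing acids: {missing}")
    return tuple(sum(float(sample[a]) for a in FAMILIES[f]) for f in ("SFA", "MUFA", "PUFA"))


def table1_means() -> pd.DataFrame:
    """Reference chemistry means per variety (one row per variety).

    Family totals come from the published per-variety family rows (which
    were measured on unrounded data) rather than re-summed rounded member
    means, so the two can differ in the last printed digit.
    """
    rows = []
    for prof in WALNUT_PROFILES:
        row = {"variety": prof.name, "total_fat": prof.mean_total_fat}
        row.update(prof.fa_means)
        row.update(prof.family_means)
        rows.append(row)
    return pd.DataFrame(rows)


def variety_summary(table: pd.DataFrame, analytes: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-variety mean, SE (= SD / sqrt(n), NaN for n = 1) and n per analyte."""
    if "variety" not in table.columns:
        raise ValueError("table needs a 'variety' column")
    analytes = tuple(a for a in (analytes or ANALYTES) if a in table.columns)
    if not analytes:
        raise ValueError("no analyte columns found")
    records = []
    for variety, grp in table.groupby("variety", sort=True):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty variety {variety}")
        for analyte in analytes:
            vals = grp[analyte].to_numpy(dtype=float)
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            records.append(
                {"variety": variety, "analyte": analyte, "mean": float(vals.mean()),
                 "se": se, "n": n}
            )
    return pd.DataFrame(records)


def grand_means(summary: pd.DataFrame) -> pd.Series:
    """Unweighted average of variety means, per analyte."""
    return summary.groupby("analyte")["mean"].mean()


def mufa_pufa_ratio(summary: pd.DataFrame, variety: str) -> float:
    """Oxidative-stability index: variety mean MUFA over variety mean PUFA."""
    sub = summary[summary["variety"] == variety].set_index("analyte")["mean"]
    if "MUFA" not in sub or "PUFA" not in sub:
        raise ValueError("summary lacks MUFA/PUFA rows")
    if sub["PUFA"] == 0:
        raise ValueError("PUFA mean is zero")
    return float(sub["MUFA"] / sub["PUFA"])


def family_share(summary: pd.DataFrame, acid: str) -> float:
    """Grand-mean share (%) of an acid within its family total."""
    family = next((f for f, members in FAMILIES.items() if acid in members), None)
    if family is None:
        raise ValueError(f"unknown acid {acid!r}")
    gm = grand_means(summary)
    if family not in gm or acid not in gm:
        raise ValueError(f"summary lacks {acid} or {family}")
    if gm[family] == 0:
        raise ValueError(f"{family} grand mean is zero")
    return float(100.0 * gm[acid] / gm[family])


def _compact_letters(means: np.ndarray, different: np.ndarray) -> list[str]:
    """Compact letter display from a pairwise significant-difference matrix.

    Letters label the maximal cliques of the *non*-difference graph, ordered
    by descending clique mean, so 'a' marks the highest group(s); two groups
    share a letter iff they are not significantly different.
    """
    k = means.size
    nodes = range(k)
    nonsig = ~different
    cliques = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(nodes, size):
            if all(nonsig[i, j] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    cliques.sort(key=lambda c: -np.mean(means[list(c)]))
    letters = [""] * k
    for letter, combo in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in combo:
            letters[i] += letter
    return ["".join(sorted(l)) for l in letters]


def anova_tukey(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA plus Tukey-Kramer letters across groups.

    Returns (F, p, letters). Identical values everywhere yield an undefined
    F (NaN) and a single shared letter.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [values[groups == g] for g in labels]
    if all(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 samples in some group")
    means = np.asarray([a.mean() for a in arrays])
    if np.ptp(values) == 0:
        return float("nan"), float("nan"), {g: "a" for g in labels}
    f_stat, p_val = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    different = np.asarray(res.pvalue) < alpha
    np.fill_diagonal(different, False)
    letters = _compact_letters(means, different)
    return float(f_stat), float(p_val), dict(zip(labels, letters))


def summary_with_letters(
    table: pd.DataFrame, analytes: tuple[str, ...] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Variety summary augmented with Tukey letters per analyte."""
    summary = variety_summary(table, analytes)
    letters_col = []
    for analyte in summary["analyte"].unique():
        values = table[analyte].to_numpy(dtype=float)
        groups = table["variety"].to_numpy()
        try:
            _, _, letters = anova_tukey(values, groups, alpha)
        except ValueError:
            letters = {g: "" for g in pd.unique(groups)}
        for _, row in summary[summary["analyte"] == analyte].iterrows():
            letters_col.append((row["variety"], analyte, letters.get(row["variety"], "")))
    lookup = {(v, a): l for v, a, l in letters_col}
    summary["letter"] = [lookup[(r["variety"], r["analyte"])] for _, r in summary.iterrows()]
    return summary
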