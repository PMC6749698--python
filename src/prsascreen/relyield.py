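"""Reference-normalized yield ratios with Bonferroni-corrected t-tests.

In a co-expression screen each amylase is produced with each candidate
chaperone (prsA gene) and once with no added chaperone; the no-chaperone
strain is the reference.  Every cell's replicate activities are divided by
the reference cell's mean, each cell is compared to the reference with a
two-sided t-test (Welch by default), and p-values are Bonferroni-corrected
within the amylase's row — the family is the set of chaperone cells
compared against one reference.  Cells are classed significant (adjusted
p < 0.05), marginal (0.05 <= p < 0.10), or ns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_LABEL = "none"

SIGNIFICANT = "significant"
MARGINAL = "marginal"
NS = "ns"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def normalize_to_reference(
    observations: pd.DataFrame, amylase: str, reference: str = REFERENCE_LABEL
) -> pd.DataFrame:
    """Divide one amylase row's replicate activities by the reference mean.

    ``observations`` is a long table with columns ``amylase, prsa,
    replicate, activity``.  The returned frame carries a ``relative``
    column; the reference cell's relative mean is exactly 1.
    """
    row = observations.loc[observations["amylase"] == amylase]
    ref = row.loc[row["prsa"] == reference, "activity"]
    if len(ref) < 2:
        raise ValueError(
            f"amylase {amylase!r}: reference cell {reference!r} needs >= 2 replicates"
        )
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError(f"amylase {amylase!r}: reference mean must be positive")
    return row.assign(relative=row["activity"] / ref_mean)


def pairwise_test(cell, reference_cell, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t-test of a cell against the reference cell.

    Welch's unequal-variance form is the default; set ``equal_var`` for the
    pooled-variance form.  Degenerate zero-variance inputs are guarded:
    both groups constant with equal means gives p = 1, with unequal means
    p = 0 (flagged), so noiseless synthetic data cannot crash the test.
    """
    x = np.asarray(cell, dtype=float)
    y = np.asarray(reference_cell, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both cells need >= 2 replicates")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(float("inf") if x.mean() > y.mean() else float("-inf"),
                          0.0, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(float(t), float(p))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p -> min(1, m * p).

    ``m`` defaults to the number of p-values; in a screen row it is the
    number of non-reference cells compared against the shared reference.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, m * p)


def classify(p_adjusted: float, alpha: float = 0.05, marginal_bound: float = 0.10) -> str:
    """significant if p < alpha; marginal if alpha <= p < marginal_bound; else ns."""
    if p_adjusted < alpha:
        return SIGNIFICANT
    if p_adjusted < marginal_bound:
        return MARGINAL
    return NS


def build_table(
    observations: pd.DataFrame,
    reference: str = REFERENCE_LABEL,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full relative-yield table for every (amylase, prsa) cell.

    Returns columns ``amylase, prsa, n, mean_ratio, sd, p_raw, p_adj,
    cls``; the Bonferroni family is the amylase's non-reference cells, and
    the reference cell itself carries no test (NaN p, class ns).
    """
    out = []
    for amylase in observations["amylase"].unique():
        rel = normalize_to_reference(observations, amylase, reference)
        ref_values = rel.loc[rel["prsa"] == reference, "relative"].to_numpy()
        cells = [p for p in rel["prsa"].unique() if p != reference]
        m = len(cells)
        rows = []
        for prsa in rel["prsa"].unique():
            values = rel.loc[rel["prsa"] == prsa, "relative"].to_numpy()
            if prsa == reference:
                rows.append((amylase, prsa, values.size, float(values.mean()),
                             float(values.std(ddof=1)), np.nan, np.nan, NS))
            else:
                test = pairwise_test(values, ref_values, equal_var=equal_var)
                rows.append((amylase, prsa, values.size, float(values.mean()),
                             float(values.std(ddof=1)), test.p_value, np.nan, ""))
        df = pd.DataFrame(
            rows,
            columns=["amylase", "prsa", "n", "mean_ratio", "sd", "p_raw", "p_adj", "cls"],
        )
        tested = df["prsa"] != reference
        df.loc[tested, "p_adj"] = bonferroni(df.loc[tested, "p_raw"].to_numpy(), m)
        df.loc[tested, "cls"] = [classify(p) for p in df.loc[tested, "p_adj"]]
        out.append(df)
    return pd.concat(out, ignore_index=True)


def render_table(cells: pd.DataFrame) -> str:
    """Human-readable matrix: amylases as rows, chaperones as columns.

    Each entry shows mean (sd); significant cells are emphasised with
    ``*...*`` and marginal cells carry a trailing asterisk.
    """
    prsas = list(dict.fromkeys(cells["prsa"]))
    amylases = list(dict.fromkeys(cells["amylase"]))
    width = 16
    header = "amylase".ljust(width) + "".join(p.ljust(width) for p in prsas)
    lines = [header]
    for amylase in amylases:
        row = cells.loc[cells["amylase"] == amylase].set_index("prsa")
        parts = [amylase.ljust(width)]
        for prsa in prsas:
            if prsa not in row.index:
                parts.append("-".ljust(width))
                continue
            cell = row.loc[prsa]
            text = f"{cell['mean_ratio']:.2f} ({cell['sd']:.2f})"
            if cell["cls"] == SIGNIFICANT:
                text = f"*{text}*"
            elif cell["cls"] == MARGINAL:
                text = f"{text}*"
            parts.append(text.ljust(width))
        lines.append("".join(parts).rstrip())
    return "\n".join(lines)


def write_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)
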