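"""Two-group differential expression by pooled-count Fisher exact test.

Replicates are pooled per group and each feature is tested on the 2x2 table

    [[count_a, lib_a - count_a],
     [count_b, lib_b - count_b]]

with the two-sided Fisher exact test (point-probability summation), followed
by Benjamini-Hochberg adjustment across features. Fold changes are computed
on normalized expression means with a pseudocount so zero-count features stay
representable. A feature passes the filter when |log2FC| >= 1 (fold change
>= 2) and raw P <= 0.05 by default; both thresholds are configurable and the
adjusted P is always reported alongside.

Pooling means per-replicate biological variance is not modeled: the test is
exact under its own (no-overdispersion) sampling assumptions and
anti-conservative on overdispersed counts. An edgeR-style exact test with a
dispersion estimate is the standard remedy; it is deliberately out of scope
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix


@dataclass(frozen=True)
class DEThresholds:
    """Filter criteria: |log2 fold change| and raw P-value."""

    min_abs_log2fc: float = 1.0
    max_p: float = 0.05


@dataclass
class DERecord:
    """Per-feature differential-expression call (group b over group a)."""

    feature_id: str
    mean_expr_a: float
    mean_expr_b: float
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    direction: str
    passes_filter: bool


def fisher_feature_test(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Two-sided Fisher exact P for one feature's pooled counts.

    ``lib_*`` are the group library sizes (>= the counts); the two-sided P
    sums the point probabilities of all tables, with the observed margins,
    no more probable than the observed one.
    """
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("count exceeds library size")
    if min(count_a, count_b, lib_a, lib_b) < 0:
        raise ValueError("negative count or library size")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def log2fc(mean_a: float, mean_b: float, pseudocount: float = 0.1) -> float:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount))."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("negative means")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    thresholds: DEThresholds = DEThresholds(),
    pseudocount: float = 0.1,
) -> list[DERecord]:
    """One DERecord per feature, sorted by (p_value, feature_id).

    ``expr_a``/``expr_b`` are normalized expression values (class units) for
    the two groups' samples; ``counts_a``/``counts_b`` the matching raw count
    matrices whose replicate columns are pooled for the Fisher test.
    """
    if list(expr_a.index) != list(expr_b.index) or list(expr_a.index) != list(
        counts_a.feature_ids
    ) or list(counts_a.feature_ids) != list(counts_b.feature_ids):
        raise ValueError("feature axes do not match between groups")

    pooled_a = counts_a.counts.sum(axis=1).to_numpy()
    pooled_b = counts_b.counts.sum(axis=1).to_numpy()
    lib_a = int(counts_a.library_size.sum())
    lib_b = int(counts_b.library_size.sum())
    mean_a = expr_a.mean(axis=1).to_numpy()
    mean_b = expr_b.mean(axis=1).to_numpy()

    p_values = np.array(
        [
            fisher_feature_test(int(ca), int(cb), lib_a, lib_b)
            for ca, cb in zip(pooled_a, pooled_b)
        ]
    )
    p_adj = bh_adjust(p_values)

    records = []
    for i, fid in enumerate(expr_a.index):
        lfc = log2fc(float(mean_a[i]), float(mean_b[i]), pseudocount)
        records.append(
            DERecord(
                feature_id=str(fid),
                mean_expr_a=float(mean_a[i]),
                mean_expr_b=float(mean_b[i]),
                log2_fold_change=lfc,
                p_value=float(p_values[i]),
                p_adjusted=float(p_adj[i]),
                direction="up" if lfc > 0 else "down",
                passes_filter=bool(
                    abs(lfc) >= thresholds.min_abs_log2fc
                    and p_values[i] <= thresholds.max_p
                ),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.feature_id))
    return records


def de_table(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "mean_expr_a": [r.mean_expr_a for r in records],
            "mean_expr_b": [r.mean_expr_b for r in records],
            "log2_fold_change": [r.log2_fold_change for r in records],
            "p_value": [r.p_value for r in records],
            "p_adjusted": [r.p_adjusted for r in records],
            "direction": [r.direction for r in records],
            "passes_filter": [r.passes_filter for r in records],
        }
    )


def write_de_table(records: list[DERecord], path: str | Path) -> None:
    de_table(records).to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            feature_id=str(row.feature_id),
            mean_expr_a=float(row.mean_expr_a),
            mean_expr_b=float(row.mean_expr_b),
            log2_fold_change=float(row.log2_fold_change),
            p_value=float(row.p_value),
            p_adjusted=float(row.p_adjusted),
            direction=str(row.direction),
            passes_filter=bool(row.passes_filter),
        )
        for row in df.itertuples()
    ]
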