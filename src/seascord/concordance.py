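"""Agreement analytics over series-by-method classification matrices.

Concordance is unanimous agreement of all methods on one series: positive
when every method calls it seasonal, negative when every method calls it
non-seasonal.  The pattern count N tallies series sharing an exact subset
of seasonal-voting methods; the vote histogram M tallies series by how many
methods voted seasonal regardless of which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .methods import METHODS, TestResult

__all__ = [
    "ClassificationMatrix",
    "ConcordanceSummary",
    "build_matrix",
    "summarize",
    "proportion_spread",
    "median_spread",
    "top_patterns",
    "summary_table",
    "pattern_table",
    "vote_table",
]


@dataclass
class ClassificationMatrix:
    """Series x method boolean seasonality calls at one significance level.

    ``failure_mask`` marks cells where a method failed on a series; those
    series are excluded from agreement statistics and reported separately.
    """

    series_ids: list[str]
    methods: tuple[str, ...]
    alpha: float
    calls: np.ndarray
    failure_mask: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=bool)
        self.failure_mask = np.asarray(self.failure_mask, dtype=bool)
        S, K = self.calls.shape
        if len(self.series_ids) != S or len(self.methods) != K:
            raise ValueError("matrix dimensions do not match labels")
        if len(set(self.series_ids)) != S:
            raise ValueError("duplicate series_id rows")

    @property
    def n_series(self) -> int:
        return len(self.series_ids)


@dataclass
class ConcordanceSummary:
    """Per-method proportions and agreement statistics for one matrix.

    Proportions are fractions in [0, 1]; conversion to percentages happens
    only at the reporting boundary.  ``pattern_counts`` maps the frozenset
    of seasonal-voting methods to N; ``vote_histogram`` maps k in 0..K to
    M(k).  Series with any failed cell are excluded and counted in
    ``n_failed_series``.
    """

    alpha: float
    methods: tuple[str, ...]
    n_series: int
    n_failed_series: int
    per_method_proportion: dict[str, float]
    positive_concordant: int
    negative_concordant: int
    pattern_counts: dict[frozenset, int]
    vote_histogram: dict[int, int]
    label: str = ""

    @property
    def concordance_rate(self) -> float:
        return (self.positive_concordant + self.negative_concordant) / self.n_series

    @property
    def spread(self) -> float:
        p = list(self.per_method_proportion.values())
        return max(p) - min(p)


def build_matrix(
    results: Iterable[TestResult],
    alpha: float,
    methods: Sequence[str] = METHODS,
) -> ClassificationMatrix:
    """Assemble the series x method matrix at one alpha.

    Every (series, method) pair must be present exactly once at that alpha
    (failure results included); a missing pair raises a completeness error
    naming the gap.  Input order is irrelevant: rows are sorted by
    series_id, columns follow the fixed method order.
    """
    cells: dict[tuple[str, str], TestResult] = {}
    series_ids: list[str] = []
    for r in results:
        if r.alpha != alpha:
            continue
        key = (r.series_id, r.method)
        if key in cells:
            raise ValueError(f"duplicate result for {key} at alpha={alpha}")
        cells[key] = r
        if r.series_id not in series_ids:
            series_ids.append(r.series_id)
    series_ids = sorted(series_ids)
    if not series_ids:
        raise ValueError(f"no results at alpha={alpha}")
    S, K = len(series_ids), len(methods)
    calls = np.zeros((S, K), dtype=bool)
    failures = np.zeros((S, K), dtype=bool)
    for i, sid in enumerate(series_ids):
        for j, method in enumerate(methods):
            r = cells.get((sid, method))
            if r is None:
                raise ValueError(
                    f"missing result for series {sid!r}, method {method} "
                    f"at alpha={alpha}"
                )
            if r.seasonal is None:
                failures[i, j] = True
            else:
                calls[i, j] = r.seasonal
    return ClassificationMatrix(
        series_ids=series_ids,
        methods=tuple(methods),
        alpha=alpha,
        calls=calls,
        failure_mask=failures,
    )


def summarize(matrix: ClassificationMatrix, label: str = "") -> ConcordanceSummary:
    """Concordance statistics for one matrix.

    Per-method proportions are computed over the series where that method
    returned a verdict; concordance, pattern counts N and vote histogram M
    are computed over series with no failed cell.
    """
    K = len(matrix.methods)
    ok_rows = ~matrix.failure_mask.any(axis=1)
    n_failed = int((~ok_rows).sum())

    per_method: dict[str, float] = {}
    for j, method in enumerate(matrix.methods):
        valid = ~matrix.failure_mask[:, j]
        denom = int(valid.sum())
        per_method[method] = (
            float(matrix.calls[valid, j].sum() / denom) if denom else float("nan")
        )

    clean = matrix.calls[ok_rows]
    votes = clean.sum(axis=1)
    vote_histogram = {k: int(np.sum(votes == k)) for k in range(K + 1)}

    pattern_counts: dict[frozenset, int] = {}
    for row in clean:
        pat = frozenset(m for m, v in zip(matrix.methods, row) if v)
        pattern_counts[pat] = pattern_counts.get(pat, 0) + 1

    return ConcordanceSummary(
        alpha=matrix.alpha,
        methods=matrix.methods,
        n_series=int(ok_rows.sum()),
        n_failed_series=n_failed,
        per_method_proportion=per_method,
        positive_concordant=vote_histogram.get(K, 0),
        negative_concordant=vote_histogram.get(0, 0),
        pattern_counts=pattern_counts,
        vote_histogram=vote_histogram,
        label=label,
    )


def proportion_spread(summary: ConcordanceSummary) -> tuple[str, str, float, bool]:
    """(argmin method, argmax method, spread, tied) for per-method proportions.

    Ties are broken by the fixed method order and flagged.
    """
    props = summary.per_method_proportion
    lo = min(props.values())
    hi = max(props.values())
    min_methods = [m for m in summary.methods if props[m] == lo]
    max_methods = [m for m in summary.methods if props[m] == hi]
    tied = len(min_methods) > 1 or len(max_methods) > 1
    return min_methods[0], max_methods[0], hi - lo, tied


def median_spread(summaries: Sequence[ConcordanceSummary]) -> float:
    """Median of within-database spreads (midpoint convention on even counts)."""
    if not summaries:
        raise ValueError("median_spread requires at least one summary")
    return float(np.median([s.spread for s in summaries]))


def top_patterns(
    summary: ConcordanceSummary, limit: int
) -> list[tuple[frozenset, int]]:
    """Patterns sorted by N descending, up to ``limit`` entries.

    Ties break by pattern cardinality, then by the fixed method order of
    the membership bitstring, so the output is deterministic.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")

    def bits(pat: frozenset) -> tuple:
        return tuple(0 if m in pat else 1 for m in summary.methods)

    ranked = sorted(
        summary.pattern_counts.items(),
        key=lambda item: (-item[1], len(item[0]), bits(item[0])),
    )
    return ranked[:limit]


# ---------------------------------------------------------------------------
# Reporting tables
# ---------------------------------------------------------------------------

def summary_table(summaries: Sequence[ConcordanceSummary]) -> pd.DataFrame:
    """One row per database: per-method percent-seasonal with min/max marks.

    Mirrors the study's proportion-seasonal matrices: method columns carry
    percentages; ``min_method``/``max_method`` annotate the extremes and
    ``spread_pct`` their difference.
    """
    rows = []
    for s in summaries:
        mn, mx, spread, tied = proportion_spread(s)
        row = {"database": s.label or "corpus", "alpha": s.alpha}
        for m in s.methods:
            row[m] = 100.0 * s.per_method_proportion[m]
        row.update(
            {
                "min_method": mn,
                "max_method": mx,
                "spread_pct": 100.0 * spread,
                "tied_extremes": tied,
                "concordance_pct": 100.0 * s.concordance_rate,
                "n_series": s.n_series,
                "n_failed_series": s.n_failed_series,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pattern_table(summary: ConcordanceSummary, limit: int | None = None) -> pd.DataFrame:
    """Pattern membership table: bitstring over the method order, members, N."""
    limit = limit or len(summary.pattern_counts)
    rows = []
    for pat, n in top_patterns(summary, max(1, limit)):
        bitstring = "".join("1" if m in pat else "0" for m in summary.methods)
        rows.append(
            {
                "pattern": bitstring,
                "members": "+".join(m for m in summary.methods if m in pat) or "-",
                "n_methods": len(pat),
                "N": n,
            }
        )
    return pd.DataFrame(rows, columns=["pattern", "members", "n_methods", "N"])


def vote_table(summary: ConcordanceSummary) -> pd.DataFrame:
    """Vote histogram table: k seasonal votes -> M(k)."""
    return pd.DataFrame(
        {
            "k": list(summary.vote_histogram),
            "M": list(summary.vote_histogram.values()),
        }
    )
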