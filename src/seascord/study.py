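"""Study protocol runner: the full methods x alphas x databases grid.

`SeasonalityStudy` is built from one or more corpora of proportion series
(each corpus standing in for one database); its :meth:`fit` runs every
classification method at every significance level on every series and
returns a :class:`StudyResults` carrying the long results table, the
per-database classification matrices, the concordance summaries and a
machine-readable run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .concordance import (
    ClassificationMatrix,
    ConcordanceSummary,
    build_matrix,
    median_spread,
    pattern_table,
    summarize,
    summary_table,
    vote_table,
)
from .methods import (
    DEFAULT_ALPHAS,
    METHODS,
    TestConfig,
    TestResult,
    classify_all,
    results_to_frame,
)
from .series import ProportionSeries

__all__ = ["SeasonalityStudy", "StudyResults", "RunConfig", "run_grid"]


@dataclass
class RunConfig:
    """Configuration of one grid run (echoed into the manifest)."""

    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    methods: tuple[str, ...] = METHODS
    detrend: str = "ols"
    ed_scale: float = 1000.0
    seed: int | None = None

    def __post_init__(self):
        if not self.methods:
            raise ValueError("methods must be nonempty")
        if not all(0.0 < a < 1.0 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")

    def test_config(self) -> TestConfig:
        return TestConfig(detrend=self.detrend, ed_scale=self.ed_scale)


class SeasonalityStudy:
    """The classification study on a set of corpora ("databases").

    Parameters
    ----------
    corpora
        Mapping from database label to either a sequence of eligible
        :class:`ProportionSeries` or a bare integer series count.  Integer
        corpora support manifest accounting (the protocol arithmetic)
        without classification; :meth:`fit` requires real series.
    config
        Grid options; defaults follow the study protocol (all 8 methods at
        alphas 0.01, 0.05, 0.1, OLS detrending).
    """

    def __init__(
        self,
        corpora: Mapping[str, Sequence[ProportionSeries] | int],
        config: RunConfig | None = None,
    ):
        if not corpora:
            raise ValueError("at least one corpus is required")
        self.corpora = dict(corpora)
        self.config = config or RunConfig()

    @classmethod
    def from_proportion_table(cls, source, label: str = "db", config=None):
        from .series import read_proportions

        return cls({label: list(read_proportions(source).values())}, config)

    @classmethod
    def from_count_table(cls, source, label: str = "db", config=None):
        from .series import build_proportion_series, read_counts

        eligible, _ = build_proportion_series(read_counts(source))
        return cls({label: list(eligible.values())}, config)

    def _corpus_sizes(self) -> dict[str, int]:
        return {
            db: (corpus if isinstance(corpus, int) else len(corpus))
            for db, corpus in self.corpora.items()
        }

    def manifest(self) -> dict:
        """Run accounting: series, evaluation and result-row counts.

        An "evaluation" is one series at one significance level across the
        method set (the study-protocol granularity); ``result_rows`` is the
        finer per-method count.
        """
        sizes = self._corpus_sizes()
        total = sum(sizes.values())
        n_alphas = len(self.config.alphas)
        n_methods = len(self.config.methods)
        return {
            "package_version": __version__,
            "config": asdict(self.config),
            "databases": sizes,
            "n_databases": len(sizes),
            "total_series": total,
            "evaluations": total * n_alphas,
            "result_rows": total * n_alphas * n_methods,
        }

    def fit(self, progress: bool = False) -> "StudyResults":
        """Run the full grid; per-series method failures are annotated, not fatal."""
        tc = self.config.test_config()
        results: dict[str, list[TestResult]] = {}
        for db, corpus in self.corpora.items():
            if isinstance(corpus, int):
                raise TypeError(
                    f"corpus {db!r} is a bare count; real series are required to fit"
                )
            rows: list[TestResult] = []
            for i, series in enumerate(corpus):
                rows.extend(
                    classify_all(series, self.config.alphas, tc, self.config.methods)
                )
                if progress and (i + 1) % 10 == 0:
                    print(f"[{db}] {i + 1}/{len(corpus)} series classified")
            results[db] = rows

        matrices: dict[tuple[str, float], ClassificationMatrix] = {}
        summaries: dict[tuple[str, float], ConcordanceSummary] = {}
        for db, rows in results.items():
            for alpha in self.config.alphas:
                m = build_matrix(rows, alpha, self.config.methods)
                matrices[(db, alpha)] = m
                summaries[(db, alpha)] = summarize(m, label=db)
        return StudyResults(
            study=self,
            results=results,
            matrices=matrices,
            summaries=summaries,
        )


@dataclass
class StudyResults:
    """Everything the grid produced, with writers for the report tables."""

    study: SeasonalityStudy
    results: dict[str, list[TestResult]]
    matrices: dict[tuple[str, float], ClassificationMatrix]
    summaries: dict[tuple[str, float], ConcordanceSummary]

    @property
    def manifest(self) -> dict:
        return self.study.manifest()

    def results_frame(self) -> pd.DataFrame:
        frames = []
        for db, rows in self.results.items():
            f = results_to_frame(rows)
            f.insert(0, "database", db)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self, alpha: float) -> pd.DataFrame:
        rows = [s for (db, a), s in self.summaries.items() if a == alpha]
        return summary_table(rows)

    def median_spread(self, alpha: float) -> float:
        """Median across databases of the max-min per-method proportion gap."""
        return median_spread(
            [s for (db, a), s in self.summaries.items() if a == alpha]
        )

    def summary(self) -> str:
        """Human-readable report: manifest header plus per-alpha tables."""
        man = self.manifest
        lines = [
            "Seasonality classification study",
            f"  databases: {man['n_databases']}  series: {man['total_series']}  "
            f"evaluations: {man['evaluations']}",
            f"  methods: {', '.join(self.study.config.methods)}",
        ]
        for alpha in self.study.config.alphas:
            lines.append(f"\nalpha = {alpha}")
            frame = self.summary_frame(alpha).drop(columns=["alpha"])
            lines.append(frame.to_string(index=False, float_format="%.1f"))
            lines.append(
                f"median within-database spread: "
                f"{100 * self.median_spread(alpha):.1f}%"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the run artifact bundle as delimited text + JSON manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.results_frame().to_csv(out / "results.csv", index=False)
        for alpha in self.study.config.alphas:
            tag = f"{alpha:g}".replace(".", "p")
            self.summary_frame(alpha).to_csv(
                out / f"summary_alpha_{tag}.csv", index=False
            )
        for (db, alpha), s in self.summaries.items():
            tag = f"{db}_alpha_{alpha:g}".replace(".", "p")
            pattern_table(s).to_csv(out / f"patterns_{tag}.csv", index=False)
            vote_table(s).to_csv(out / f"votes_{tag}.csv", index=False)
        spread = {
            f"{alpha:g}": self.median_spread(alpha)
            for alpha in self.study.config.alphas
        }
        (out / "median_spread.json").write_text(json.dumps(spread, indent=2))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def run_grid(
    corpora: Mapping[str, Sequence[ProportionSeries] | int],
    config: RunConfig | None = None,
    outdir=None,
    progress: bool = False,
) -> StudyResults:
    """Convenience wrapper: build the study, fit it, optionally save the bundle."""
    res = SeasonalityStudy(corpora, config).fit(progress=progress)
    if outdir is not None:
        res.save(outdir)
    return res
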