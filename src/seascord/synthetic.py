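"""Synthetic monthly proportion series with controllable seasonal structure.

The generator emulates the proportion series the study pipeline consumes:
persons-per-thousand values over complete calendar years with a harmonic
seasonal component.  The drivers of method agreement are all tunable:

* ``amplitude`` — size of the seasonal peaks (per-thousand units);
* ``amplitude_decay`` — per-year geometric decay of the amplitude, the
  peak-PERSISTENCE control (0 = peaks recur year after year);
* ``phase_jitter_sd`` — standard deviation (months) of a per-year shift of
  the peak month, the peak-CONSISTENCY control (0 = same calendar month
  every year);
* ``peak_sharpness`` — shape exponent of the seasonal curve: 1 gives a
  pure cosine, larger values concentrate the excess into a short spiky
  peak (the epidemic-curve shape of strongly seasonal diagnoses).  A pure
  cosine is itself an ARMA(2,2) process, which short-memory ARIMA models
  absorb; spiky peaks are what makes the model-comparison tests (AR, AA,
  ET) and the month-group tests agree on real strongly-seasonal series;
* ``trend_slope`` — linear trend per month;
* ``noise_sd`` — white observation noise.

Two output families: ``gaussian-proportions`` adds Gaussian noise directly
to the proportion (truncated at 0), ``poisson-counts`` draws monthly event
counts from a Poisson law with mean population * value / 1000 and emits
both the count table and the derived proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .series import MonthlyCountRecord, MonthlyCountSeries, ProportionSeries

__all__ = [
    "SyntheticSpec",
    "generate_series",
    "generate_counts",
    "scenario_corpus",
    "load_scenarios",
    "SCENARIOS_RESOURCE",
]

SCENARIOS_RESOURCE = "scenarios.yaml"

FAMILIES = ("gaussian-proportions", "poisson-counts")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic series; fully determined by ``seed``."""

    years: int = 4
    baseline: float = 5.0
    amplitude: float = 0.0
    peak_month: int = 1
    phase_jitter_sd: float = 0.0
    amplitude_decay: float = 0.0
    peak_sharpness: float = 1.0
    trend_slope: float = 0.0
    noise_sd: float = 0.0
    family: str = "gaussian-proportions"
    population: int = 1_000_000
    seed: int = 0
    series_id: str = "synthetic"
    start_year: int = 2015

    def validate(self) -> None:
        if self.years < 4:
            raise ValueError("years must be >= 4 (eligibility by construction)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.amplitude < 0 or self.noise_sd < 0 or self.phase_jitter_sd < 0:
            raise ValueError("amplitude, noise_sd and phase_jitter_sd must be >= 0")
        if not 0.0 <= self.amplitude_decay <= 1.0:
            raise ValueError("amplitude_decay must be in [0, 1]")
        if not 1 <= self.peak_month <= 12:
            raise ValueError("peak_month must be in 1..12")
        if self.peak_sharpness < 1.0:
            raise ValueError("peak_sharpness must be >= 1")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.population <= 0:
            raise ValueError("population must be positive")


def _mean_curve(spec: SyntheticSpec, jitters: np.ndarray) -> np.ndarray:
    n = 12 * spec.years
    t = np.arange(n, dtype=float)
    months = (t % 12) + 1.0
    years = (t // 12).astype(int)
    amp = spec.amplitude * (1.0 - spec.amplitude_decay) ** years
    phase = 2.0 * np.pi * (months - spec.peak_month - jitters[years]) / 12.0
    # shape: pure cosine at sharpness 1; higher exponents concentrate the
    # peak while keeping the peak-trough distance at 2 * amplitude
    shape = 2.0 * ((1.0 + np.cos(phase)) / 2.0) ** spec.peak_sharpness - 1.0
    return spec.baseline + spec.trend_slope * t + amp * shape


def generate_series(spec: SyntheticSpec) -> ProportionSeries:
    """Draw one proportion series from the spec; deterministic in the seed.

    value_t = baseline + trend*t
              + amplitude * (1-decay)^year(t) * cos(2*pi*(M_t - peak - J_y)/12)
              + eps_t,
    with one phase jitter J_y per year and iid Gaussian noise eps_t.
    Gaussian-family values are truncated at zero (proportions cannot be
    negative); the Poisson family goes through :func:`generate_counts`.
    """
    spec.validate()
    if spec.family == "poisson-counts":
        return counts_to_proportions(generate_counts(spec))
    rng = np.random.default_rng(spec.seed)
    jitters = rng.normal(0.0, spec.phase_jitter_sd, size=spec.years)
    mean = _mean_curve(spec, jitters)
    noise = rng.normal(0.0, spec.noise_sd, size=mean.size) if spec.noise_sd else 0.0
    values = np.maximum(0.0, mean + noise)
    return ProportionSeries(
        series_id=spec.series_id,
        start_year=spec.start_year,
        start_month=1,
        values=values,
    )


def generate_counts(spec: SyntheticSpec) -> MonthlyCountSeries:
    """Draw a monthly count series (Poisson events over a fixed denominator)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    jitters = rng.normal(0.0, spec.phase_jitter_sd, size=spec.years)
    mean = np.maximum(0.0, _mean_curve(spec, jitters))
    lam = spec.population * mean / 1000.0
    events = np.minimum(rng.poisson(lam), spec.population)
    records = []
    for t, ev in enumerate(events):
        records.append(
            MonthlyCountRecord(
                series_id=spec.series_id,
                year=spec.start_year + t // 12,
                month=t % 12 + 1,
                event_persons=int(ev),
                denominator_persons=spec.population,
            )
        )
    return MonthlyCountSeries(series_id=spec.series_id, records=records)


def counts_to_proportions(counts: MonthlyCountSeries) -> ProportionSeries:
    from .series import to_proportion_series

    return to_proportion_series(counts)


def load_scenarios(path=None) -> dict[str, dict]:
    """Scenario definitions from YAML (packaged default or a user file)."""
    if path is None:
        text = resources.files(__package__).joinpath(SCENARIOS_RESOURCE).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return raw["scenarios"]


def _spec_from_config(cfg: dict, seed: int, series_id: str, rng: np.random.Generator) -> SyntheticSpec:
    cfg = dict(cfg)
    peak = cfg.pop("peak_month", 1)
    if peak in ("random", None):
        peak = int(rng.integers(1, 13))
    return SyntheticSpec(seed=seed, series_id=series_id, peak_month=int(peak), **cfg)


def scenario_corpus(
    name: str,
    n_series: int,
    seed: int,
    scenarios: dict | None = None,
) -> list[ProportionSeries]:
    """Draw ``n_series`` independent series from a named scenario.

    Per-series seeds are split off the master seed with a counter-based
    seed sequence, so corpora are reproducible and extendable: the first k
    series of a corpus of n > k are identical to a corpus of k.
    """
    scenarios = scenarios if scenarios is not None else load_scenarios()
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(scenarios))}"
        )
    cfg = scenarios[name]
    out = []
    for i in range(n_series):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        child_seed, peak_seed = (int(s) for s in child.generate_state(2))
        peak_rng = np.random.default_rng(peak_seed)
        spec = _spec_from_config(cfg, child_seed, f"{name}-{i:04d}", peak_rng)
        out.append(generate_series(spec))
    return out
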