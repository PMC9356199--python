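"""Synthetic census-tract data with the structure the index pipeline assumes.

The real source tables behind an area-level opportunity index (claims data,
survey pulls, crime feeds) are restricted, so this module generates
stand-ins: a tract-by-measure table driven by a single latent "opportunity"
factor with domain-clustered correlation, a small fraction of
zero-population tracts, completely-at-random missingness, and outcome
tables (life expectancy, percent Black / minority, an external reference
index) with a monotone gradient in the latent factor.

Generative model, per tract t and measure m in domain d(m):

    value[t, m] = dir(m) * (lambda * L[t] + gamma * D[t, d(m)] + eps[t, m])

then affinely mapped into a plausible range for the measure's units.
``L`` is the latent opportunity factor, ``D`` a domain-specific factor
(giving within-domain correlation above between-domain correlation), and
``dir(m)`` is -1 for deprivation-pointing measures and +1 for reverse-coded
ones, so reverse-coded measures correlate positively with opportunity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .registry import MeasureRegistry, default_registry, subset_by_period

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "TwoPeriodTruth",
    "generate_tract_frame",
    "generate_outcomes",
    "generate_two_periods",
]

#: Fictional state FIPS prefix; real state codes stop at 78.
_STATE_PREFIX = "99"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-tract generator.

    Defaults emulate a statewide tract file: ~3,000 tracts of which a
    handful have zero population, moderate loading of every measure on a
    single latent opportunity factor, 2% missing cells, and a life
    expectancy gradient of 3 years per latent standard deviation around a
    75-year intercept.
    """

    n_tracts: int = 2952
    seed: int = 0
    latent_sd: float = 1.0
    domain_loading: float = 0.6
    domain_factor_sd: float = 0.5
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    zero_pop_fraction: float = 12 / 2952
    outcome_le_intercept: float = 75.0
    outcome_le_slope: float = 3.0
    outcome_noise_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_tracts < 8:
            raise ValueError("n_tracts must be at least 8")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.zero_pop_fraction < 1):
            raise ValueError("zero_pop_fraction must be in [0, 1)")
        if not (0 <= self.domain_loading <= 1):
            raise ValueError("domain_loading must be in [0, 1]")
        for name in ("latent_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outcome_noise_sd < 0 or self.domain_factor_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth echoed back by the generator, for recovery tests."""

    fips: tuple[str, ...]
    latent: np.ndarray
    config: SyntheticConfig

    def __post_init__(self) -> None:
        if len(self.latent) != len(self.fips):
            raise ValueError("latent vector and fips key have different lengths")


@dataclass(frozen=True)
class TwoPeriodTruth:
    """Ground truth for a two-period pair: both latents and the set of
    tracts whose latent was shocked between periods."""

    fips: tuple[str, ...]
    latent_period_1: np.ndarray
    latent_period_2: np.ndarray
    shocked_fips: tuple[str, ...]
    config: SyntheticConfig


def _synthetic_fips(n: int) -> tuple[str, ...]:
    # 11-character GEOIDs under a fictional state prefix, zero-padded.
    return tuple(f"{_STATE_PREFIX}{i:09d}" for i in range(1, n + 1))


# Affine maps from the dimensionless signal onto a plausible scale per unit
# class: (center, spread, lower clip, upper clip).
_UNIT_MAPS = {
    "proportion": (0.15, 0.06, 0.0, 1.0),
    "percent": (20.0, 8.0, 0.0, 100.0),
    "index": (50.0, 15.0, 0.0, 100.0),
    "count": (15.0, 6.0, 0.0, None),
    "rate": (0.02, 0.012, 0.0, None),
    "z-score": (0.0, 1.0, None, None),
}


def _measure_values(signal: np.ndarray, units: str) -> np.ndarray:
    center, spread, lo, hi = _UNIT_MAPS.get(units, (0.0, 1.0, None, None))
    vals = center + spread * signal
    if lo is not None or hi is not None:
        vals = np.clip(vals, lo, hi)
    return vals


def _measure_matrix(
    rng: np.random.Generator,
    latent: np.ndarray,
    registry: MeasureRegistry,
    config: SyntheticConfig,
) -> pd.DataFrame:
    """Draw the tract-by-measure value matrix for one period, with fresh
    measurement noise and fresh domain factors."""
    n = len(latent)
    domain_factors = {
        d: rng.normal(0.0, config.domain_factor_sd, size=n) for d in registry.domains
    }
    cols: dict[str, np.ndarray] = {}
    for m in registry:
        eps = rng.normal(0.0, config.noise_sd, size=n)
        signal = config.domain_loading * latent + domain_factors[m.domain] + eps
        direction = 1.0 if m.reversed else -1.0
        cols[m.measure_id] = _measure_values(direction * signal, m.units)
    return pd.DataFrame(cols)


def _insert_missing(
    rng: np.random.Generator, frame: pd.DataFrame, columns: list[str], rate: float
) -> pd.DataFrame:
    if rate <= 0:
        return frame
    block = frame[columns].to_numpy(dtype=float)
    mask = rng.random(block.shape) < rate
    block[mask] = np.nan
    frame = frame.copy()
    frame[columns] = block
    return frame


def generate_tract_frame(
    config: SyntheticConfig, registry: MeasureRegistry | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic tract-by-measure table and its ground truth.

    Returns a DataFrame with columns ``fips`` (unique 11-character strings),
    ``population`` (with ``round(zero_pop_fraction * n_tracts)`` tracts at
    zero), and one numeric column per registry measure; plus a
    :class:`SyntheticTruth` carrying the latent factor. Fully reproducible
    from ``config.seed``.
    """
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(config.seed)
    n = config.n_tracts
    fips = _synthetic_fips(n)
    latent = rng.normal(0.0, config.latent_sd, size=n)

    population = rng.integers(500, 8000, size=n).astype(np.int64)
    n_zero = int(round(config.zero_pop_fraction * n))
    if n_zero:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        population[zero_idx] = 0

    measures = _measure_matrix(rng, latent, registry, config)
    table = pd.concat(
        [pd.DataFrame({"fips": fips, "population": population}), measures], axis=1
    )
    table = _insert_missing(rng, table, list(registry.measure_ids), config.missing_rate)
    truth = SyntheticTruth(fips=fips, latent=latent, config=config)
    return table, truth


def generate_outcomes(truth: SyntheticTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Generate a tract outcome table keyed to the same FIPS codes.

    ``life_expectancy`` is linear in the latent factor with Gaussian noise;
    ``pct_black`` and ``pct_minority`` follow a logistic link decreasing in
    the latent factor, with ``pct_minority >= pct_black`` in every tract;
    ``reference_index`` is an external-style composite correlated with the
    latent factor, for criterion-validity exercises.
    """
    if len(truth.latent) != len(truth.fips):
        raise ValueError("truth latent and fips lengths differ")
    rng = np.random.default_rng(config.seed + 1)
    z = truth.latent / truth.config.latent_sd
    n = len(z)

    life_expectancy = (
        config.outcome_le_intercept
        + config.outcome_le_slope * truth.latent
        + rng.normal(0.0, config.outcome_noise_sd, size=n)
    )

    def expit(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    pct_black = 100.0 * expit(-1.2 - 0.9 * z + rng.normal(0.0, 0.4, size=n))
    extra = (100.0 - pct_black) * expit(-2.0 - 0.4 * z + rng.normal(0.0, 0.3, size=n))
    pct_minority = np.clip(pct_black + extra, 0.0, 100.0)
    pct_black = np.clip(pct_black, 0.0, 100.0)

    reference_index = 50.0 + 20.0 * z + rng.normal(0.0, 8.0, size=n)

    return pd.DataFrame(
        {
            "fips": truth.fips,
            "life_expectancy": life_expectancy,
            "pct_black": pct_black,
            "pct_minority": pct_minority,
            "reference_index": reference_index,
        }
    )


def generate_two_periods(
    config: SyntheticConfig,
    drift: float,
    shock_fraction: float = 1.0,
    registry: MeasureRegistry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TwoPeriodTruth]:
    """Generate paired tables for two periods sharing tracts.

    The first-period table carries only the earlier period's measures; the
    second-period table carries the full registry. The second-period latent
    is the first-period latent plus ``drift`` times a standard-normal shock
    applied to a random ``shock_fraction`` of tracts, so configured
    tract-level gains and declines exist. Measurement noise is drawn fresh
    in each period.
    """
    if not (0 <= shock_fraction <= 1):
        raise ValueError("shock_fraction must be in [0, 1]")
    registry = registry if registry is not None else default_registry()
    registry_p1 = subset_by_period(registry, "period_1")

    rng = np.random.default_rng(config.seed)
    n = config.n_tracts
    fips = _synthetic_fips(n)
    latent_1 = rng.normal(0.0, config.latent_sd, size=n)

    shock = rng.normal(0.0, 1.0, size=n)
    n_shocked = int(round(shock_fraction * n))
    shocked_idx = rng.choice(n, size=n_shocked, replace=False) if n_shocked else np.array([], dtype=int)
    shock_mask = np.zeros(n, dtype=bool)
    shock_mask[shocked_idx] = True
    latent_2 = latent_1 + drift * shock * shock_mask

    population = rng.integers(500, 8000, size=n).astype(np.int64)
    n_zero = int(round(config.zero_pop_fraction * n))
    if n_zero:
        zero_idx = rng.choice(n, size=n_zero, replace=False)
        population[zero_idx] = 0

    base = pd.DataFrame({"fips": fips, "population": population})
    table_1 = pd.concat([base, _measure_matrix(rng, latent_1, registry_p1, config)], axis=1)
    table_2 = pd.concat([base, _measure_matrix(rng, latent_2, registry, config)], axis=1)
    table_1 = _insert_missing(rng, table_1, list(registry_p1.measure_ids), config.missing_rate)
    table_2 = _insert_missing(rng, table_2, list(registry.measure_ids), config.missing_rate)

    truth = TwoPeriodTruth(
        fips=fips,
        latent_period_1=latent_1,
        latent_period_2=latent_2,
        shocked_fips=tuple(np.asarray(fips)[shock_mask]),
        config=config,
    )
    return table_1, table_2, truth
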