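"""Composite index construction.

The pipeline turns a preprocessed tract-by-measure table into a 0-100
opportunity score per tract:

1. **Standardize** each measure to a z-score, ``Z = (x - mu) / sigma``
   (sample standard deviation, divisor n-1).
2. **Domain averaging** — each tract's z-scores are averaged within each of
   the thematic domains to give domain deprivation scores.
3. **Rank and scale** — within each domain, tracts are ranked by domain
   score (ties take the average rank) and the ranks scaled to [0, 1] via
   ``R = (rank - 1) / (n - 1)``, so the most deprived tract gets exactly 1.
4. **Exponential transformation** — scaled ranks are stretched onto
   [0, 100] by ``X = -delta * ln(1 - R * (1 - exp(-100/delta)))`` with
   ``delta = 23`` by default. The internal constant tracks ``delta`` so the
   endpoints are exactly 0 and 100 for any positive ``delta``; the
   transform is strictly increasing and convex, stretching the deprived
   tail so that greater deprivation scores disproportionately higher.
5. **Equal weighting and reversal** — the composite deprivation score
   ``sum_d w_d * X_d`` (default weights 1/8 per domain) is subtracted from
   100 so that higher means more opportunity, and by default min-max
   rescaled across tracts to span exactly [0, 100].

Tracts are finally grouped into septiles (seven quantile groups); septile 1
is the least advantaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .preprocess import PreprocessLog, preprocess
from .registry import MeasureRegistry

__all__ = [
    "BuildConfig",
    "DomainScorePanel",
    "IndexResult",
    "standardize",
    "domain_score",
    "rank_scale",
    "exponential_transform",
    "compose_index",
    "assign_septiles",
    "build_index",
]

DEFAULT_DELTA = 23.0


@dataclass(frozen=True)
class BuildConfig:
    """Configuration of the deterministic index build.

    Parameters
    ----------
    delta : float
        Constant of the exponential transformation; 23 reproduces the
        classic multiple-deprivation methodology.
    weights : mapping domain -> float, optional
        Domain weights summing to 1. ``None`` means equal weights over the
        domains present in the registry (1/8 for the default registry).
    rescale_final : bool
        If True (default), min-max rescale the composite across tracts so
        scores span exactly [0, 100].
    """

    delta: float = DEFAULT_DELTA
    weights: Mapping[str, float] | None = None
    rescale_final: bool = True

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.weights is not None:
            w = np.asarray(list(self.weights.values()), dtype=float)
            if (w < 0).any():
                raise ValueError("weights must be non-negative")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def resolved_weights(self, domains: Sequence[str]) -> dict[str, float]:
        """Weights for the given domains, defaulting to equal weighting."""
        if self.weights is None:
            return {d: 1.0 / len(domains) for d in domains}
        if set(self.weights) != set(domains):
            raise ValueError(
                f"weight domains {sorted(self.weights)} do not match panel domains "
                f"{sorted(domains)}"
            )
        return dict(self.weights)


@dataclass(frozen=True)
class DomainScorePanel:
    """Per-tract domain values at each transform stage: z-mean domain score,
    scaled rank in [0, 1], and exponential score in [0, 100]."""

    fips: tuple[str, ...]
    z_mean: pd.DataFrame
    scaled_rank: pd.DataFrame
    exp_score: pd.DataFrame


@dataclass(frozen=True)
class IndexResult:
    """Composite score (0-100, higher = more opportunity), septile label
    (1 = least advantaged), and the per-domain exponential scores."""

    fips: tuple[str, ...]
    ocoi_score: np.ndarray
    septile: np.ndarray
    domain_scores: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"fips": self.fips, "ocoi_score": self.ocoi_score, "septile": self.septile})
        for d in self.domain_scores.columns:
            out[f"{d}_score"] = self.domain_scores[d].to_numpy()
        return out

    @property
    def scores(self) -> pd.Series:
        return pd.Series(self.ocoi_score, index=pd.Index(self.fips, name="fips"))


def standardize(column, name: str = "measure") -> np.ndarray:
    """Z-score a vector to mean 0 and sample standard deviation 1.

    A constant column carries no deprivation signal; it maps to all zeros
    with a warning rather than an error.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize requires a 1-d vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite values in {name!r}")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn(f"measure {name!r} is constant; standardized to zeros", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def domain_score(z_table: pd.DataFrame, registry: MeasureRegistry) -> pd.DataFrame:
    """Average z-scores within each domain: tract x domain means."""
    out = {}
    for d in registry.domains:
        ids = [m.measure_id for m in registry.measures_in_domain(d)]
        if not ids:
            raise ValueError(f"domain {d!r} has no measures in the registry")
        missing = [i for i in ids if i not in z_table.columns]
        if missing:
            raise ValueError(f"z-table missing measures {missing} for domain {d!r}")
        out[d] = z_table[ids].mean(axis=1)
    return pd.DataFrame(out, index=z_table.index)


def rank_scale(domain_column) -> np.ndarray:
    """Rank a domain-score vector ascending with deprivation and scale to
    [0, 1] via (rank - 1) / (n - 1); ties take the average rank."""
    x = np.asarray(domain_column, dtype=float)
    if len(x) < 2:
        raise ValueError("rank_scale requires at least 2 tracts")
    ranks = rankdata(x, method="average")
    return (ranks - 1.0) / (len(x) - 1.0)


def exponential_transform(r, delta: float = DEFAULT_DELTA):
    """Map scaled ranks in [0, 1] onto exponential scores in [0, 100].

    ``X = -delta * ln(1 - r * (1 - exp(-100/delta)))``. The constant inside
    the bracket uses 100/delta, so X(0) = 0 and X(1) = 100 exactly for any
    positive delta. Strictly increasing and convex in ``r``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    arr = np.asarray(r, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("scaled ranks must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        x = -delta * np.log(1.0 - arr * (1.0 - np.exp(-100.0 / delta)))
    x = np.where(arr == 1.0, 100.0, x)  # exact analytic endpoint
    x = np.where(arr == 0.0, 0.0, x)
    return float(x) if np.isscalar(r) else x


def compose_index(x_panel: pd.DataFrame, config: BuildConfig | None = None) -> np.ndarray:
    """Combine per-domain exponential scores into the composite.

    Raw composite = 100 - sum_d w_d * X_d (a deprivation average reversed
    so higher = more opportunity); optionally min-max rescaled across
    tracts to span [0, 100].
    """
    config = config or BuildConfig()
    arr = x_panel.to_numpy(dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("domain exponential scores must lie in [0, 100]")
    weights = config.resolved_weights(list(x_panel.columns))
    w = np.array([weights[d] for d in x_panel.columns], dtype=float)
    raw = 100.0 - arr @ w
    if config.rescale_final:
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            raw = 100.0 * (raw - lo) / (hi - lo)
        else:
            raw = np.full_like(raw, 50.0)
    return raw


def assign_septiles(scores, fips=None) -> np.ndarray:
    """Partition tracts into seven quantile groups by composite score.

    Label 1 is the lowest-score (least advantaged) group. Group sizes differ
    by at most one; ties at a boundary are resolved deterministically by
    (score, fips) lexical order so the earlier-keyed tract falls into the
    lower-numbered group.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    if n < 7:
        raise ValueError("septile assignment requires at least 7 tracts")
    keys = np.asarray(fips if fips is not None else np.arange(n), dtype=object)
    order = np.lexsort((keys, s))
    labels = np.empty(n, dtype=np.int64)
    positions = np.arange(n)
    labels[order] = positions * 7 // n + 1
    return labels


def build_index(
    table: pd.DataFrame,
    registry: MeasureRegistry,
    config: BuildConfig | None = None,
) -> tuple[IndexResult, DomainScorePanel, PreprocessLog]:
    """Run the full deterministic pipeline on a raw tract table.

    Orchestrates preprocessing (zero-population filter, median imputation,
    reverse coding), standardization, domain averaging, rank scaling, the
    exponential transformation, composite weighting, and septile
    assignment. Returns the result together with the intermediate domain
    panel and the preprocessing audit log.
    """
    config = config or BuildConfig()
    clean, log = preprocess(table, registry)
    if len(clean) < 2:
        raise ValueError("fewer than 2 tracts remain after preprocessing")
    fips = tuple(str(f) for f in clean["fips"])

    z = pd.DataFrame(
        {mid: standardize(clean[mid].to_numpy(), name=mid) for mid in registry.measure_ids},
        index=clean.index,
    )
    dom = domain_score(z, registry)
    ranks = pd.DataFrame(
        {d: rank_scale(dom[d].to_numpy()) for d in dom.columns}, index=dom.index
    )
    exp_scores = pd.DataFrame(
        {d: exponential_transform(ranks[d].to_numpy(), config.delta) for d in ranks.columns},
        index=ranks.index,
    )
    composite = compose_index(exp_scores, config)
    if len(composite) >= 7:
        septiles = assign_septiles(composite, fips)
    else:
        # too few tracts for a seven-group split; 0 marks "unassigned"
        septiles = np.zeros(len(composite), dtype=np.int64)
        log.warnings.append("fewer than 7 tracts: septiles not assigned")

    panel = DomainScorePanel(fips=fips, z_mean=dom, scaled_rank=ranks, exp_score=exp_scores)
    result = IndexResult(
        fips=fips,
        ocoi_score=composite,
        septile=septiles,
        domain_scores=exp_scores.set_axis(list(exp_scores.columns), axis=1),
    )
    return result, panel, log
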