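"""Catalogue of constituent measures, their domains, direction, and period availability.

The opportunity index aggregates tract-level indicators ("constituent
measures") into eight thematic domains. Each measure carries a direction
flag: most measures point toward deprivation (higher value = less
opportunity), while reverse-coded measures point toward opportunity and are
negated before scoring. Measures also carry period tags, because the two
study periods differ in data availability: the earlier period covers a
subset of the measures available in the later one.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "DOMAINS",
    "PERIODS",
    "MeasureDefinition",
    "MeasureRegistry",
    "RegistryError",
    "load_registry",
    "write_registry",
    "default_registry",
    "subset_by_period",
    "domain_counts",
]

#: The eight thematic domains, in canonical reporting order.
DOMAINS = (
    "family_stability",
    "infant_health",
    "children_health",
    "access",
    "education",
    "housing",
    "environment",
    "criminal_justice",
)

#: Recognised period tags. ``period_1`` is the earlier window with fewer
#: available measures; ``period_2`` is the later, complete window.
PERIODS = ("period_1", "period_2")

_REGISTRY_FIELDS = ("measure_id", "label", "domain", "reversed", "periods", "units")


class RegistryError(ValueError):
    """Raised when a measure registry fails validation."""


@dataclass(frozen=True)
class MeasureDefinition:
    """One constituent measure of the index.

    Parameters
    ----------
    measure_id : str
        Short stable identifier, used as the column name in measure tables.
    label : str
        Human-readable name.
    domain : str
        One of :data:`DOMAINS`.
    reversed : bool
        True when a higher raw value means *more* opportunity; such measures
        are negated during preprocessing so that, after reversal, higher
        always means more deprivation.
    periods : tuple of str
        Subset of :data:`PERIODS` in which the measure is available.
    units : str
        Free-text unit description (proportion, percent, count, index, ...).
    source : str
        Optional free-text provenance note.
    """

    measure_id: str
    label: str
    domain: str
    reversed: bool
    periods: tuple[str, ...]
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.measure_id:
            raise RegistryError("measure_id must be non-empty")
        if self.domain not in DOMAINS:
            raise RegistryError(
                f"unknown domain {self.domain!r} for measure {self.measure_id!r}; "
                f"allowed domains: {', '.join(DOMAINS)}"
            )
        bad = [p for p in self.periods if p not in PERIODS]
        if bad:
            raise RegistryError(
                f"unknown period tag(s) {bad} for measure {self.measure_id!r}; "
                f"allowed: {', '.join(PERIODS)}"
            )
        if not self.periods:
            raise RegistryError(f"measure {self.measure_id!r} has no period tags")


@dataclass(frozen=True)
class MeasureRegistry:
    """Ordered collection of :class:`MeasureDefinition` with a version tag."""

    measures: tuple[MeasureDefinition, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.measures:
            raise RegistryError("registry must contain at least one measure")
        seen: set[str] = set()
        for m in self.measures:
            if m.measure_id in seen:
                raise RegistryError(f"duplicate measure_id {m.measure_id!r}")
            seen.add(m.measure_id)

    def __len__(self) -> int:
        return len(self.measures)

    def __iter__(self) -> Iterator[MeasureDefinition]:
        return iter(self.measures)

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(m.measure_id for m in self.measures)

    @property
    def domains(self) -> tuple[str, ...]:
        """Domains present, in canonical order."""
        present = {m.domain for m in self.measures}
        return tuple(d for d in DOMAINS if d in present)

    @property
    def reversed_ids(self) -> tuple[str, ...]:
        return tuple(m.measure_id for m in self.measures if m.reversed)

    def measures_in_domain(self, domain: str) -> tuple[MeasureDefinition, ...]:
        return tuple(m for m in self.measures if m.domain == domain)

    def __getitem__(self, measure_id: str) -> MeasureDefinition:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(measure_id)


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise RegistryError(f"cannot parse boolean from {value!r}")


def _measure_from_record(rec: Mapping[str, object]) -> MeasureDefinition:
    missing = [f for f in _REGISTRY_FIELDS if f not in rec or rec[f] is None]
    if missing:
        raise RegistryError(f"registry record missing required field(s): {missing}")
    periods = rec["periods"]
    if isinstance(periods, str):
        periods = tuple(p.strip() for p in periods.split(";") if p.strip())
    else:
        periods = tuple(periods)  # type: ignore[arg-type]
    rev = rec["reversed"]
    if isinstance(rev, str):
        rev = _parse_bool(rev)
    return MeasureDefinition(
        measure_id=str(rec["measure_id"]).strip(),
        label=str(rec["label"]),
        domain=str(rec["domain"]).strip(),
        reversed=bool(rev),
        periods=periods,
        units=str(rec.get("units", "") or ""),
        source=str(rec.get("source", "") or ""),
    )


def load_registry(source, version: str = "unversioned") -> MeasureRegistry:
    """Load a registry from a CSV file path, an open text stream, or a
    sequence of mapping records (e.g. a parsed config block).

    The CSV dialect is comma-separated with header
    ``measure_id,label,domain,reversed,periods,units[,source]``;
    ``periods`` is a semicolon-joined list of period tags.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    elif isinstance(source, io.TextIOBase):
        rows = list(csv.DictReader(source))
    else:
        rows = [dict(rec) for rec in source]
    measures = tuple(_measure_from_record(rec) for rec in rows)
    return MeasureRegistry(measures=measures, version=version)


def write_registry(registry: MeasureRegistry, path) -> None:
    """Write a registry to CSV; round-trips exactly through :func:`load_registry`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_REGISTRY_FIELDS) + ["source"])
        for m in registry:
            writer.writerow(
                [m.measure_id, m.label, m.domain, m.reversed, ";".join(m.periods), m.units, m.source]
            )


def default_registry() -> MeasureRegistry:
    """The packaged default registry: 53 measures across the eight domains,
    11 of them reverse-coded, 37 available in the earlier period."""
    ref = resources.files("ocoi.data").joinpath("measures.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        return load_registry(fh, version="default")


def subset_by_period(registry: MeasureRegistry, period: str) -> MeasureRegistry:
    """Restrict a registry to measures carrying the given period tag,
    preserving order and domain assignments."""
    if period not in PERIODS:
        raise RegistryError(f"unknown period tag {period!r}; allowed: {', '.join(PERIODS)}")
    kept = tuple(m for m in registry if period in m.periods)
    if not kept:
        raise RegistryError(f"no measures carry period tag {period!r}")
    return MeasureRegistry(measures=kept, version=f"{registry.version}:{period}")


def domain_counts(registry: MeasureRegistry) -> dict[str, int]:
    """Number of constituent measures per domain, in canonical domain order.

    Only domains present in the registry appear in the result; counts sum to
    the registry size.
    """
    counts: dict[str, int] = {}
    for d in DOMAINS:
        n = sum(1 for m in registry if m.domain == d)
        if n:
            counts[d] = n
    return counts
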