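"""Property-range compliance scoring: the "95% of known drugs" panel and
the #stars violation count.

A :class:`RangePanel` holds per-descriptor ranges (closed on finite ends:
a value equal to a printed endpoint is in range) and the subset of
descriptors whose violations count toward #stars.  Descriptors absent from
a profile are treated according to a missing-value policy: ``skip`` leaves
them out of both the violation count and the evaluated denominator;
``fail`` raises.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import yaml

from .chem_io import CompoundProfile

__all__ = [
    "PropertyRange",
    "RangePanel",
    "ComplianceResult",
    "evaluate_profile",
    "percent_compliance",
    "stars_distribution",
    "load_panel",
    "ComplianceError",
    "MissingDescriptorError",
]


class ComplianceError(ValueError):
    pass


class MissingDescriptorError(ComplianceError):
    def __init__(self, compound_id: str, missing: list[str]):
        self.missing = missing
        super().__init__(f"{compound_id}: missing descriptors {missing}")


@dataclass(frozen=True)
class PropertyRange:
    """Closed range [lower, upper]; use ±inf for one-sided guidance."""

    descriptor: str
    lower: float = -math.inf
    upper: float = math.inf
    note: str = ""

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ComplianceError(
                f"{self.descriptor}: lower {self.lower} > upper {self.upper}"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class RangePanel:
    name: str
    ranges: dict[str, PropertyRange] = field(default_factory=dict)
    star_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for d in self.star_members:
            if d not in self.ranges:
                raise ComplianceError(f"star member {d!r} has no range")
        if len(set(self.star_members)) != len(self.star_members):
            raise ComplianceError("duplicate star members")

    @classmethod
    def from_dict(cls, name: str, raw: dict) -> "RangePanel":
        ranges = {
            d: PropertyRange(
                descriptor=d,
                lower=float(spec.get("lower", -math.inf)),
                upper=float(spec.get("upper", math.inf)),
                note=str(spec.get("note", "")),
            )
            for d, spec in raw["ranges"].items()
        }
        return cls(name=name, ranges=ranges,
                   star_members=tuple(raw.get("star_members", ())))


_DATA_DIR = Path(__file__).parent / "data"
_PANEL_CACHE: dict[str, RangePanel] = {}


def load_panel(name: str = "drugs95", path: str | Path | None = None) -> RangePanel:
    """Load a named panel from the shipped panels file or a user YAML."""
    cache_key = f"{path}:{name}"
    if cache_key not in _PANEL_CACHE:
        with open(path or _DATA_DIR / "panels.yaml") as fh:
            raw = yaml.safe_load(fh)
        if name not in raw:
            raise ComplianceError(
                f"panel {name!r} not found; available: {sorted(raw)}"
            )
        _PANEL_CACHE[cache_key] = RangePanel.from_dict(name, raw[name])
    return _PANEL_CACHE[cache_key]


@dataclass
class ComplianceResult:
    """Per-descriptor status plus the #stars count.

    ``stars`` counts star-panel descriptors whose value falls strictly
    outside its range; ``evaluated`` counts star-panel descriptors for
    which the profile carried a value.
    """

    id: str
    status: dict[str, str] = field(default_factory=dict)
    stars: int = 0
    evaluated: int = 0


def evaluate_profile(
    profile: CompoundProfile,
    panel: RangePanel,
    missing_policy: Literal["skip", "fail"] = "skip",
) -> ComplianceResult:
    """Score one profile against a panel and count #stars violations."""
    status: dict[str, str] = {}
    stars = 0
    evaluated = 0
    missing: list[str] = []
    for desc, rng in panel.ranges.items():
        value = profile.values.get(desc)
        if value is None:
            status[desc] = "missing"
            missing.append(desc)
            continue
        in_range = rng.contains(value)
        status[desc] = "in_range" if in_range else "out_of_range"
        if desc in panel.star_members:
            evaluated += 1
            if not in_range:
                stars += 1
    if missing and missing_policy == "fail":
        raise MissingDescriptorError(profile.id, missing)
    return ComplianceResult(
        id=profile.id, status=status, stars=stars, evaluated=evaluated
    )


def percent_compliance(
    library: Iterable[CompoundProfile],
    descriptor: str,
    panel: RangePanel,
) -> tuple[float, float, int]:
    """Percent of compounds carrying ``descriptor`` whose value is in range.

    Returns ``(percent_2dp, raw_fraction, n_present)``; the denominator is
    the number of compounds that carry the descriptor at all.
    """
    if descriptor not in panel.ranges:
        raise ComplianceError(f"panel {panel.name!r} has no range for {descriptor!r}")
    rng = panel.ranges[descriptor]
    n_present = 0
    n_in = 0
    for p in library:
        v = p.values.get(descriptor)
        if v is None:
            continue
        n_present += 1
        n_in += rng.contains(v)
    if n_present == 0:
        raise ComplianceError(
            f"descriptor {descriptor!r} absent from every compound; "
            "compliance undefined"
        )
    frac = n_in / n_present
    return round(100.0 * frac, 2), frac, n_present


def stars_distribution(
    library: list[CompoundProfile],
    panel: RangePanel,
) -> dict[int, int]:
    """Histogram of #stars values; counts sum to the library size."""
    if not library:
        raise ComplianceError("empty library")
    counts = Counter(
        evaluate_profile(p, panel, missing_policy="skip").stars for p in library
    )
    return dict(sorted(counts.items()))
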