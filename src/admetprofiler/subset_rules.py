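"""Drug-like / lead-like / fragment-like classification and Jorgensen's
Rule of Three.

The shipped subset definitions (data/subsets.yaml) follow the standard
printed inequalities with exact strictness:

* drug-like: MW < 500, logP < 5, HBD ≤ 5, HBA ≤ 10
* lead-like: 150 ≤ MW ≤ 350, logP ≤ 4, HBD ≤ 3, HBA ≤ 6
* fragment-like: MW ≤ 250, −2 ≤ logP ≤ 3, HBD < 3, HBA < 6, NRB < 3

The printed bounds imply lead-like ⊆ drug-like and fragment-like ⊆
drug-like; membership is non-exclusive and a compound is reported in every
subset it satisfies.

The Rule of Three (ro3) scores oral availability on three strict
inequalities: logS_wat > −5.7, Caco-2 permeability > 22 nm/s and fewer
than seven predicted metabolic reactions (mapped to the #metab
descriptor).  Overall compliance is the full conjunction; ``criteria_met``
reports partial compliance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

from .chem_io import CompoundProfile
from .compliance import MissingDescriptorError

__all__ = [
    "Clause",
    "SubsetDefinition",
    "load_subsets",
    "matches",
    "classify_library",
    "ro3_evaluate",
    "RO3_THRESHOLDS",
    "SubsetError",
]


class SubsetError(ValueError):
    pass


_COMPARATORS = {
    "lt": lambda v, c: v < c.bound,
    "le": lambda v, c: v <= c.bound,
    "gt": lambda v, c: v > c.bound,
    "ge": lambda v, c: v >= c.bound,
    "between": lambda v, c: c.lower <= v <= c.upper,
}


@dataclass(frozen=True)
class Clause:
    descriptor: str
    comparator: str  # lt, le, gt, ge, between
    bound: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise SubsetError(f"unknown comparator {self.comparator!r}")
        if self.comparator == "between":
            if self.lower is None or self.upper is None or self.lower > self.upper:
                raise SubsetError(f"{self.descriptor}: bad between bounds")
        elif self.bound is None:
            raise SubsetError(f"{self.descriptor}: bound required")

    def holds(self, value: float) -> bool:
        return _COMPARATORS[self.comparator](value, self)


@dataclass(frozen=True)
class SubsetDefinition:
    name: str
    clauses: tuple[Clause, ...]


_DATA_DIR = Path(__file__).parent / "data"
_SUBSET_CACHE: dict[str, dict[str, SubsetDefinition]] = {}


def load_subsets(path: str | Path | None = None) -> dict[str, SubsetDefinition]:
    """Load subset definitions from the shipped file or a user YAML."""
    key = str(path)
    if key not in _SUBSET_CACHE:
        with open(path or _DATA_DIR / "subsets.yaml") as fh:
            raw = yaml.safe_load(fh)
        defs = {}
        for name, clauses in raw.items():
            defs[name] = SubsetDefinition(
                name=name,
                clauses=tuple(
                    Clause(
                        descriptor=c["descriptor"],
                        comparator=c["comparator"],
                        bound=c.get("bound"),
                        lower=c.get("lower"),
                        upper=c.get("upper"),
                    )
                    for c in clauses
                ),
            )
        _SUBSET_CACHE[key] = defs
    return _SUBSET_CACHE[key]


def matches(profile: CompoundProfile, definition: SubsetDefinition) -> bool:
    """True iff every clause of the definition holds for the profile."""
    missing = [c.descriptor for c in definition.clauses
               if c.descriptor not in profile.values]
    if missing:
        raise MissingDescriptorError(profile.id, sorted(set(missing)))
    return all(c.holds(profile.values[c.descriptor]) for c in definition.clauses)


def classify_library(
    library: Iterable[CompoundProfile],
    definitions: dict[str, SubsetDefinition] | None = None,
) -> dict[str, set[str]]:
    """Map compound id -> set of subset names it satisfies (non-exclusive)."""
    definitions = definitions or load_subsets()
    out: dict[str, set[str]] = {}
    for p in library:
        names = set()
        for d in definitions.values():
            try:
                if matches(p, d):
                    names.add(d.name)
            except MissingDescriptorError as e:
                raise MissingDescriptorError(
                    f"{p.id} (subset {d.name})", e.missing
                ) from None
        out[p.id] = names
    return out


#: strict thresholds of the Rule of Three: (descriptor, direction, value)
RO3_THRESHOLDS = (
    ("logS_wat", ">", -5.7),
    ("caco2", ">", 22.0),
    ("metab", "<", 7.0),
)


def ro3_evaluate(profile: CompoundProfile) -> tuple[int, bool]:
    """Rule-of-Three score: (criteria_met 0–3, compliant).

    Compliant iff all three strict inequalities hold; a value exactly on a
    threshold fails its criterion.
    """
    missing = [d for d, _, _ in RO3_THRESHOLDS if d not in profile.values]
    if missing:
        raise MissingDescriptorError(profile.id, missing)
    met = 0
    for desc, op, thr in RO3_THRESHOLDS:
        v = profile.values[desc]
        met += (v > thr) if op == ">" else (v < thr)
    return met, met == len(RO3_THRESHOLDS)
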