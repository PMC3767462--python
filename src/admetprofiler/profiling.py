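"""Library-level summaries: per-descriptor means, compliance tables and
binned distributions, plus deterministic report rendering.

Histograms are left-closed/right-open with lower-edge labels, the
convention used for the distribution plots: value v lands in bin
floor((v − origin)/width).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .chem_io import CompoundProfile
from .compliance import (
    ComplianceError,
    RangePanel,
    evaluate_profile,
    percent_compliance,
)

__all__ = [
    "LibrarySummary",
    "HistogramSpec",
    "summarize_means",
    "summarize_compliance",
    "histogram",
    "render_report",
    "ProfilingError",
]


class ProfilingError(ValueError):
    pass


@dataclass
class LibrarySummary:
    """Per-library descriptor means and compliance counts.

    ``means`` maps descriptor -> (mean over present values, n_present);
    ``n_compliant`` is the number of compounds with #stars = 0.
    """

    library_name: str
    n_total: int
    n_compliant: int | None = None
    means: dict[str, tuple[float, int]] = field(default_factory=dict)
    compliance_pct: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class HistogramSpec:
    descriptor: str
    bin_width: float = 1.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ProfilingError("bin_width must be > 0")


def summarize_means(
    library: Sequence[CompoundProfile],
    descriptors: Iterable[str],
    library_name: str = "library",
    panel: RangePanel | None = None,
) -> LibrarySummary:
    """Arithmetic means over present values; missing values excluded from
    numerator and denominator.  With a panel, also counts #stars = 0."""
    library = list(library)
    if not library:
        raise ProfilingError("empty library")
    summary = LibrarySummary(library_name=library_name, n_total=len(library))
    for desc in descriptors:
        vals = [p.values[desc] for p in library if desc in p.values]
        if vals:
            summary.means[desc] = (sum(vals) / len(vals), len(vals))
    if panel is not None:
        summary.n_compliant = sum(
            evaluate_profile(p, panel).stars == 0 for p in library
        )
    return summary


def summarize_compliance(
    library: Sequence[CompoundProfile],
    panel: RangePanel,
    subsets: dict[str, set[str]] | None = None,
    descriptors: Iterable[str] | None = None,
) -> dict[str, dict[str, float | None]]:
    """Percent-compliance table: subset name -> descriptor -> percent.

    ``subsets`` maps compound id -> subset names (as from
    subset_rules.classify_library); the whole library is always reported
    under "total".  Adds "stars0_pct" and "stars_le2_pct" summary rows.
    Cells for empty subsets or descriptors nobody carries are None
    (undefined), never 0.
    """
    library = list(library)
    if not library:
        raise ProfilingError("empty library")
    descriptors = list(descriptors) if descriptors else list(panel.ranges)
    groups: dict[str, list[CompoundProfile]] = {"total": library}
    if subsets:
        names = sorted({s for ss in subsets.values() for s in ss})
        for name in names:
            groups[name] = [p for p in library if name in subsets.get(p.id, ())]
    table: dict[str, dict[str, float | None]] = {}
    for gname, members in groups.items():
        row: dict[str, float | None] = {}
        for desc in descriptors:
            if not members:
                row[desc] = None
                continue
            try:
                pct, _, _ = percent_compliance(members, desc, panel)
                row[desc] = pct
            except ComplianceError:
                row[desc] = None
        if members:
            stars = [evaluate_profile(p, panel).stars for p in members]
            row["stars0_pct"] = round(
                100.0 * sum(s == 0 for s in stars) / len(stars), 2
            )
            row["stars_le2_pct"] = round(
                100.0 * sum(s <= 2 for s in stars) / len(stars), 2
            )
        else:
            row["stars0_pct"] = None
            row["stars_le2_pct"] = None
        table[gname] = row
    return table


def histogram(
    values: Sequence[float], spec: HistogramSpec
) -> list[tuple[float, int]]:
    """Bin values left-closed/right-open; returns (lower_edge, count) pairs
    sorted by edge.  Counts conserve the number of input values."""
    values = list(values)
    if not values:
        raise ProfilingError("no values to bin")
    bad = [i for i, v in enumerate(values) if not math.isfinite(v)]
    if bad:
        raise ProfilingError(f"non-finite values at indices {bad}")
    counts: dict[int, int] = {}
    for v in values:
        k = math.floor((v - spec.origin) / spec.bin_width)
        counts[k] = counts.get(k, 0) + 1
    return [
        (spec.origin + k * spec.bin_width, counts[k]) for k in sorted(counts)
    ]


def _summary_payload(s: LibrarySummary) -> dict:
    return {
        "library_name": s.library_name,
        "n_total": s.n_total,
        "n_compliant": s.n_compliant,
        "means": {d: {"mean": round(m, 2), "n": n} for d, (m, n) in s.means.items()},
        "compliance_pct": s.compliance_pct,
    }


def render_report(
    summaries: Sequence[LibrarySummary],
    histograms: dict[str, list[tuple[float, int]]],
    out_dir: str | Path,
    format: Literal["csv", "json", "markdown"] = "json",
) -> list[Path]:
    """Write summary/histogram artifacts; byte-deterministic per input."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "json":
        path = out_dir / "report.json"
        payload = {
            "summaries": [_summary_payload(s) for s in summaries],
            "histograms": {
                k: [[edge, n] for edge, n in bins]
                for k, bins in sorted(histograms.items())
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        written.append(path)
    elif format == "csv":
        path = out_dir / "summary.csv"
        lines = ["library,descriptor,mean,n_present"]
        for s in summaries:
            for d, (m, n) in s.means.items():
                lines.append(f"{s.library_name},{d},{m:.2f},{n}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
        for name, bins in sorted(histograms.items()):
            hpath = out_dir / f"hist_{name}.csv"
            hlines = ["lower_edge,count"]
            hlines += [f"{edge:g},{n}" for edge, n in bins]
            hpath.write_text("\n".join(hlines) + "\n")
            written.append(hpath)
    elif format == "markdown":
        path = out_dir / "report.md"
        lines = []
        for s in summaries:
            lines += [f"## {s.library_name}", "",
                      f"- compounds: {s.n_total}"]
            if s.n_compliant is not None:
                lines.append(f"- fully compliant (#stars = 0): {s.n_compliant}")
            lines += ["", "| descriptor | mean | n |", "|---|---|---|"]
            lines += [f"| {d} | {m:.2f} | {n} |" for d, (m, n) in s.means.items()]
            lines.append("")
        if histograms:
            lines.append("## Distributions")
            for name, bins in sorted(histograms.items()):
                lines += ["", f"### {name}", "", "| lower edge | count |",
                          "|---|---|"]
                lines += [f"| {edge:g} | {n} |" for edge, n in bins]
            lines.append("")
        path.write_text("\n".join(lines))
        written.append(path)
    else:
        raise ProfilingError(f"unknown report format {format!r}")
    return written
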