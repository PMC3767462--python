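"""#stars counting against a brute-force oracle, range semantics, rates."""

import math

import numpy as np
import pytest

from admetprofiler import (
    CompoundProfile,
    PropertyRange,
    RangePanel,
    evaluate_profile,
    load_panel,
    percent_compliance,
    stars_distribution,
)
from admetprofiler.compliance import ComplianceError, MissingDescriptorError

from conftest import random_profiles


def brute_force_stars(profile, panel):
    """Independent per-descriptor count of star-panel violations."""
    n = 0
    for d in panel.star_members:
        if d in profile.values:
            v = profile.values[d]
            lo, hi = panel.ranges[d].lower, panel.ranges[d].upper
            if v < lo or v > hi:
                n += 1
    return n


def midpoint_profile(panel, pid="mid"):
    vals = {}
    for d, r in panel.ranges.items():
        lo = r.lower if math.isfinite(r.lower) else r.upper - 2.0
        hi = r.upper if math.isfinite(r.upper) else r.lower + 2.0
        vals[d] = (lo + hi) / 2.0
    return CompoundProfile(pid, vals)


def test_all_midpoints_give_zero_stars(panel):
    res = evaluate_profile(midpoint_profile(panel), panel)
    assert res.stars == 0
    assert res.evaluated == len(panel.star_members)


def test_single_violation_smol(panel):
    prof = midpoint_profile(panel)
    prof.values["S_mol"] = 1200.0  # above the 300-1000 Å² band
    assert evaluate_profile(prof, panel).stars == 1


def test_closed_bounds_endpoint_in_range(panel):
    prof = midpoint_profile(panel)
    prof.values["S_mol"] = 1000.0
    prof.values["logS_wat"] = -6.0
    assert evaluate_profile(prof, panel).stars == 0


def test_stars_matches_brute_force_on_random_panels():
    rng = np.random.default_rng(42)
    descriptors = [f"d{k}" for k in range(8)]
    for trial in range(20):
        ranges = {}
        for d in descriptors:
            lo = float(rng.uniform(-5, 0))
            ranges[d] = PropertyRange(d, lo, lo + float(rng.uniform(0.5, 6)))
        k = int(rng.integers(1, len(descriptors) + 1))
        members = tuple(rng.choice(descriptors, size=k, replace=False))
        panel = RangePanel("rand", ranges, members)
        for prof in random_profiles(rng, 10, descriptors, -8, 8):
            assert evaluate_profile(prof, panel).stars == brute_force_stars(
                prof, panel
            )


def test_widening_ranges_never_increases_stars(panel):
    rng = np.random.default_rng(7)
    profs = random_profiles(rng, 50, list(panel.ranges), -2000, 2000)
    widened = RangePanel(
        "wide",
        {
            d: PropertyRange(d, r.lower - 10.0, r.upper + 10.0)
            for d, r in panel.ranges.items()
        },
        panel.star_members,
    )
    fewer_members = RangePanel("fewer", dict(panel.ranges),
                               panel.star_members[:-5])
    for p in profs:
        base = evaluate_profile(p, panel).stars
        assert evaluate_profile(p, widened).stars <= base
        assert evaluate_profile(p, fewer_members).stars <= base


def test_missing_policy(panel):
    prof = CompoundProfile("sparse", {"S_mol": 500.0})
    res = evaluate_profile(prof, panel, missing_policy="skip")
    assert res.status["logS_wat"] == "missing"
    assert res.evaluated == 1
    with pytest.raises(MissingDescriptorError, match="logS_wat"):
        evaluate_profile(prof, panel, missing_policy="fail")


def test_percent_compliance(panel):
    lib = [CompoundProfile(f"c{i}", {"logS_wat": -3.0}) for i in range(10)]
    pct, frac, n = percent_compliance(lib, "logS_wat", panel)
    assert (pct, frac, n) == (100.0, 1.0, 10)
    lib[0].values["logS_wat"] = -9.0
    del lib[1].values["logS_wat"]  # absent -> excluded from denominator
    pct, frac, n = percent_compliance(lib, "logS_wat", panel)
    assert n == 9
    assert pct == pytest.approx(round(100 * 8 / 9, 2))
    with pytest.raises(ComplianceError, match="absent"):
        percent_compliance(lib, "glob", panel)


def test_stars_distribution(panel):
    prof0 = midpoint_profile(panel, "a")
    prof1 = midpoint_profile(panel, "b")
    prof1.values["S_mol"] = 5000.0
    prof2 = midpoint_profile(panel, "c")
    prof2.values["S_mol"] = 5000.0
    prof2.values["glob"] = 0.1
    lib = [prof0, midpoint_profile(panel, "d"), prof1, prof2]
    assert stars_distribution(lib, panel) == {0: 2, 1: 1, 2: 1}
    with pytest.raises(ComplianceError):
        stars_distribution([], panel)


def test_distribution_conserves_library_size(panel):
    rng = np.random.default_rng(3)
    lib = random_profiles(rng, 500, list(panel.ranges), -100, 1500)
    dist = stars_distribution(lib, panel)
    assert sum(dist.values()) == 500
    frac0 = dist.get(0, 0)
    frac_le2 = sum(v for k, v in dist.items() if k <= 2)
    assert frac0 <= frac_le2


def test_panel_invariants():
    with pytest.raises(ComplianceError):
        PropertyRange("x", 2.0, 1.0)
    with pytest.raises(ComplianceError, match="no range"):
        RangePanel("p", {"a": PropertyRange("a", 0, 1)}, ("a", "b"))
    with pytest.raises(ComplianceError, match="not found"):
        load_panel("nope")


def test_alternative_panel_variant():
    results = load_panel("drugs95_results")
    assert results.ranges["logK_HSA"].upper == 1.5
    assert results.ranges["logBB"].upper == 1.2
    assert results.ranges["metab"].lower == 1.0
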