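import math

import numpy as np
import pytest

from admetprofiler import (
    CompoundProfile,
    generate_fixture_molecules,
    load_panel,
)


@pytest.fixture(scope="session")
def fixture_mols():
    return {m.id: m for m in generate_fixture_molecules()}


@pytest.fixture(scope="session")
def panel():
    return load_panel("drugs95")


def write_sdf(records, path):
    """Minimal V2000 writer for fixture molecules (text-only test data)."""
    blocks = []
    for rec in records:
        lines = [rec.id, "  test", ""]
        lines.append(
            f"{len(rec.atoms):3d}{len(rec.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
        )
        for a in rec.atoms:
            lines.append(
                f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0"
            )
        for b in rec.bonds:
            order = 4 if b.order == 1.5 else int(b.order)
            lines.append(f"{b.i + 1:3d}{b.j + 1:3d}{order:3d}  0  0  0  0")
        lines.append("M  END")
        for k, v in rec.properties.items():
            lines += [f">  <{k}>", str(v), ""]
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    path.write_text("\n".join(blocks) + "\n")
    return path


def random_profiles(rng, n, descriptors, lo=-10.0, hi=10.0):
    """Uncorrelated uniform profiles for oracle tests."""
    return [
        CompoundProfile(
            id=f"r{i}",
            values={d: float(rng.uniform(lo, hi)) for d in descriptors},
        )
        for i in range(n)
    ]


def two_sphere_sasa(R, d):
    """Closed-form SASA of two equal spheres of radius R, centers d apart."""
    if d >= 2 * R:
        return 2 * 4 * math.pi * R**2
    h = R - d / 2.0  # buried cap height per sphere
    return 2 * (4 * math.pi * R**2 - 2 * math.pi * R * h)


def two_sphere_volume(R, d):
    """Closed-form union volume of two equal spheres (inclusion-exclusion)."""
    v_sphere = 4.0 / 3.0 * math.pi * R**3
    if d >= 2 * R:
        return 2 * v_sphere
    lens = math.pi * (4 * R + d) * (2 * R - d) ** 2 / 12.0
    return 2 * v_sphere - lens
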