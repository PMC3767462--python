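"""Synthetic compound libraries and exact-geometry fixture molecules.

``generate_profiles`` draws per-compound descriptor vectors with
configurable marginal distributions, optional correlations and *planted*
compliance structure: a requested in-range fraction per descriptor, and a
requested fraction of fully compliant compounds (#stars = 0), are achieved
exactly by construction — in/out labels are assigned by quota first, then
values are sampled conditionally inside or outside the panel range.

The default marginals emulate a natural-product screening library: centres
follow the average descriptor values typical of plant secondary metabolites
(heavier and more lipophilic than marketed drugs, MW ≈ 427 Da,
log P ≈ 4.2, ~5–6 H-bond acceptors), with generous spreads.  The vectors
are statistically shaped but not chemically consistent across descriptors
(no structure generation), which is all the downstream analysis stages need.

``generate_fixture_molecules`` returns hand-coded 3D structures (single
atoms, a far pair, an overlapping dimer, methane, water, ethanol, benzene)
with exact coordinates for geometry-descriptor tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .chem_io import Atom, Bond, CompoundProfile, MoleculeRecord
from .compliance import RangePanel, load_panel

__all__ = [
    "MarginalSpec",
    "SyntheticConfig",
    "DEFAULT_MARGINALS",
    "generate_profiles",
    "generate_fixture_molecules",
    "SyntheticError",
]


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class MarginalSpec:
    """One descriptor's marginal: normal or lognormal, optional truncation,
    optional rounding to integer.  ``mean``/``sd`` are on the natural scale
    for both distributions (lognormal parameters are derived so that the
    untruncated mean equals ``mean``)."""

    dist: str = "normal"  # "normal" | "lognormal"
    mean: float = 0.0
    sd: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf
    integer: bool = False

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "lognormal"):
            raise SyntheticError(f"unknown distribution {self.dist!r}")
        if self.sd <= 0:
            raise SyntheticError("sd must be > 0")
        if self.lower > self.upper:
            raise SyntheticError("lower > upper truncation")
        if self.dist == "lognormal" and self.mean <= 0:
            raise SyntheticError("lognormal mean must be > 0")

    def _log_params(self) -> tuple[float, float]:
        sigma2 = math.log1p((self.sd / self.mean) ** 2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)

    def _region(self, lo: float, hi: float):
        """Frozen scipy distribution truncated to [lo, hi] ∩ own truncation,
        plus the probability mass of that region; None if empty/negligible."""
        lo = max(lo, self.lower)
        hi = min(hi, self.upper)
        if lo > hi:
            return None, 0.0
        if self.dist == "normal":
            a = (lo - self.mean) / self.sd
            b = (hi - self.mean) / self.sd
            mass = stats.norm.cdf(b) - stats.norm.cdf(a)
            if mass <= 1e-12 or a >= b:
                return None, 0.0
            return stats.truncnorm(a, b, loc=self.mean, scale=self.sd), mass
        mu, sigma = self._log_params()
        llo = math.log(lo) if lo > 0 else -math.inf
        lhi = math.log(hi) if hi > 0 else None
        if lhi is None:
            return None, 0.0
        a = (llo - mu) / sigma
        b = (lhi - mu) / sigma
        mass = stats.norm.cdf(b) - stats.norm.cdf(a)
        if mass <= 1e-12 or a >= b:
            return None, 0.0
        frozen = stats.truncnorm(a, b, loc=mu, scale=sigma)

        class _LogWrap:
            def rvs(self, size, random_state):
                return np.exp(frozen.rvs(size=size, random_state=random_state))

        return _LogWrap(), mass

    def sample(self, size: int, rng: np.random.Generator,
               lo: float = -math.inf, hi: float = math.inf) -> np.ndarray:
        """Draw from the marginal restricted to [lo, hi]."""
        if self.integer:
            # widen by half a unit so rounding cannot cross the region edge
            if math.isfinite(lo):
                lo = math.ceil(lo) - 0.499
            if math.isfinite(hi):
                hi = math.floor(hi) + 0.499
        dist, mass = self._region(lo, hi)
        if dist is None:
            raise SyntheticError(
                f"region [{lo}, {hi}] has no probability mass under "
                f"{self.dist}(mean={self.mean}, sd={self.sd}, "
                f"trunc=[{self.lower}, {self.upper}])"
            )
        out = np.asarray(dist.rvs(size=size, random_state=rng), dtype=float)
        if self.integer:
            out = np.round(out)
        return out

    def side_masses(self, lo: float, hi: float) -> tuple[float, float]:
        """Probability mass strictly below lo and strictly above hi."""
        eps_lo = 1e-9 * max(1.0, abs(lo)) if math.isfinite(lo) else 0.0
        eps_hi = 1e-9 * max(1.0, abs(hi)) if math.isfinite(hi) else 0.0
        _, below = self._region(-math.inf, lo - eps_lo) if math.isfinite(lo) \
            else (None, 0.0)
        _, above = self._region(hi + eps_hi, math.inf) if math.isfinite(hi) \
            else (None, 0.0)
        return below, above


#: default marginals for a natural-product-like library (see module
#: docstring and docs/methods.md)
DEFAULT_MARGINALS: dict[str, MarginalSpec] = {
    "MW": MarginalSpec("normal", 426.70, 160.0, lower=50.0),
    "logP": MarginalSpec("normal", 4.18, 1.8),
    "HBA": MarginalSpec("normal", 5.85, 2.5, lower=0.0, integer=True),
    "HBD": MarginalSpec("normal", 2.39, 1.8, lower=0.0, integer=True),
    "NRB": MarginalSpec("normal", 5.31, 3.0, lower=0.0, integer=True),
    "logBB": MarginalSpec("normal", -1.30, 1.0),
    "caco2": MarginalSpec("lognormal", 1199.37, 1500.0),
    "S_mol": MarginalSpec("normal", 696.28, 170.0, lower=1.0),
    "S_mol_hfob": MarginalSpec("normal", 409.24, 150.0, lower=0.0),
    "V_mol": MarginalSpec("normal", 1304.41, 320.0, lower=1.0),
    "logS_wat": MarginalSpec("normal", -5.11, 2.0),
    "logK_HSA": MarginalSpec("normal", 0.46, 0.7),
    "mdck": MarginalSpec("lognormal", 661.25, 900.0),
    "ind_coh": MarginalSpec("normal", 0.013, 0.010, lower=0.0),
    "glob": MarginalSpec("normal", 0.84, 0.06, lower=0.3, upper=1.0),
    "polrz": MarginalSpec("normal", 42.47, 12.0, lower=1.0),
    "logHERG": MarginalSpec("normal", -4.64, 1.2),
    "logKp": MarginalSpec("normal", -2.96, 1.5),
    "metab": MarginalSpec("normal", 5.56, 2.6, lower=0.0, integer=True),
    "cns": MarginalSpec("normal", -1.0, 1.0, lower=-2.0, upper=2.0,
                        integer=True),
    "percent_HOA": MarginalSpec("normal", 70.0, 25.0, lower=0.0, upper=100.0),
}


@dataclass
class SyntheticConfig:
    """Recipe for a synthetic descriptor library.

    planted_compliance : descriptor -> exact in-range fraction (w.r.t. the
        panel's range for that descriptor).
    planted_stars0_fraction : exact fraction of compounds with #stars = 0.
    correlations : (descriptor tuple, correlation matrix) applied through a
        Gaussian copula; correlated descriptors cannot also be planted.
    """

    n: int = 1000
    seed: int = 0
    marginals: dict[str, MarginalSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    correlations: tuple[tuple[str, ...], np.ndarray] | None = None
    planted_compliance: dict[str, float] = field(default_factory=dict)
    planted_stars0_fraction: float | None = None
    panel: RangePanel | None = None
    id_prefix: str = "syn"

    def validate(self) -> None:
        if self.n <= 0:
            raise SyntheticError("n must be > 0")
        for d, f in self.planted_compliance.items():
            if d not in self.marginals:
                raise SyntheticError(f"planted descriptor {d!r} has no marginal")
            if not 0.0 <= f <= 1.0:
                raise SyntheticError(f"planted fraction for {d!r} outside [0,1]")
        if self.planted_stars0_fraction is not None and not (
            0.0 <= self.planted_stars0_fraction <= 1.0
        ):
            raise SyntheticError("planted_stars0_fraction outside [0,1]")
        if self.correlations is not None:
            names, mat = self.correlations
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(names), len(names)):
                raise SyntheticError("correlation matrix shape mismatch")
            if not np.allclose(mat, mat.T):
                raise SyntheticError("correlation matrix not symmetric")
            if np.linalg.eigvalsh(mat).min() < -1e-9:
                raise SyntheticError("correlation matrix not PSD")
            overlap = set(names) & set(self.planted_compliance)
            if self.planted_stars0_fraction is not None and self.panel_or_default:
                overlap |= set(names) & set(self.panel_or_default.star_members)
            if overlap:
                raise SyntheticError(
                    f"correlated descriptors cannot be planted: {sorted(overlap)}"
                )

    @property
    def panel_or_default(self) -> RangePanel:
        return self.panel or load_panel("drugs95")


def _out_region_sample(
    spec: MarginalSpec, rng_d, lo: float, hi: float, size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``size`` values strictly outside [lo, hi]."""
    below_mass, above_mass = spec.side_masses(lo, hi)
    total = below_mass + above_mass
    if total <= 0:
        raise SyntheticError(
            f"no probability mass outside [{lo}, {hi}] for a planted "
            "out-of-range draw; planted fraction infeasible under this marginal"
        )
    n_below = rng.binomial(size, below_mass / total) if above_mass > 0 else size
    if below_mass <= 0:
        n_below = 0
    parts = []
    gap = 0.501 if spec.integer else 1e-9 * max(1.0, abs(lo), abs(hi))
    if n_below:
        parts.append(spec.sample(n_below, rng, hi=lo - gap))
    if size - n_below:
        parts.append(spec.sample(size - n_below, rng, lo=hi + gap))
    out = np.concatenate(parts) if parts else np.empty(0)
    return out[rng.permutation(size)]


def generate_profiles(config: SyntheticConfig) -> list[CompoundProfile]:
    """Generate the library; reproducible under a fixed seed.

    With ``planted_stars0_fraction = f0``, exactly round(f0·n) compounds
    carry every star-panel descriptor inside its range, and every other
    compound carries at least one star-panel violation.  Planted
    per-descriptor fractions are honoured exactly at the same time; the
    combination is rejected as infeasible when contradictory.
    """
    config.validate()
    n = config.n
    rng = np.random.default_rng(config.seed)
    panel = config.panel_or_default
    marginals = config.marginals

    # --- assign in/out labels ------------------------------------------
    # labels[d] : boolean out-of-range mask, only for constrained descriptors
    out_mask: dict[str, np.ndarray] = {}
    f0 = config.planted_stars0_fraction
    if f0 is not None:
        n0 = int(round(f0 * n))
        star = [d for d in panel.star_members if d in marginals]
        nonzero_rows = np.arange(n0, n)
        m = len(nonzero_rows)
        order = rng.permutation(nonzero_rows)
        offset = 0
        covered = np.zeros(n, dtype=bool)
        planted_star = sorted(d for d in config.planted_compliance if d in star)
        for d in planted_star:
            k_in = int(round(config.planted_compliance[d] * n))
            o_d = n - k_in
            if o_d > m:
                raise SyntheticError(
                    f"planted fraction for {d!r} incompatible with "
                    f"planted_stars0_fraction (needs {o_d} violating rows, "
                    f"only {m} available)"
                )
            mask = np.zeros(n, dtype=bool)
            rows = [order[(offset + t) % m] for t in range(o_d)] if m else []
            if o_d and not m:
                raise SyntheticError("violations required but all rows stars0")
            mask[rows] = True
            covered |= mask
            out_mask[d] = mask
            offset += o_d
        # every non-stars0 row needs >=1 violation: fill with a free star desc
        need = [r for r in nonzero_rows if not covered[r]]
        if need:
            free = [d for d in star if d not in config.planted_compliance]
            if not free:
                raise SyntheticError(
                    "cannot guarantee violations for non-compliant quota: "
                    "every star descriptor has a planted fraction"
                )
            filler = free[0]
            mask = out_mask.setdefault(filler, np.zeros(n, dtype=bool))
            mask[need] = True
        # unplanted star descriptors must be in-range on stars0 rows
        for d in star:
            if d not in out_mask:
                out_mask[d] = np.zeros(n, dtype=bool)  # all in-range
        # planted fractions for non-star descriptors handled below
        remaining = [d for d in config.planted_compliance if d not in star]
    else:
        remaining = list(config.planted_compliance)

    for d in sorted(remaining):
        k_in = int(round(config.planted_compliance[d] * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n - k_in, replace=False)] = True
        out_mask[d] = mask

    # --- sample values --------------------------------------------------
    values: dict[str, np.ndarray] = {}
    corr_names: tuple[str, ...] = ()
    if config.correlations is not None:
        corr_names, mat = config.correlations
        mat = np.asarray(mat, dtype=float)
        z = rng.multivariate_normal(
            np.zeros(len(corr_names)), mat, size=n, method="cholesky"
        )
        for k, d in enumerate(corr_names):
            spec = marginals[d]
            if spec.dist == "normal":
                v = spec.mean + spec.sd * z[:, k]
            else:
                mu, sigma = spec._log_params()
                v = np.exp(mu + sigma * z[:, k])
            v = np.clip(v, spec.lower, spec.upper)
            values[d] = np.round(v) if spec.integer else v

    for d in marginals:
        if d in values:
            continue
        spec = marginals[d]
        if d in out_mask:
            rng_range = panel.ranges.get(d)
            if rng_range is None:
                raise SyntheticError(f"panel has no range for planted {d!r}")
            lo, hi = rng_range.lower, rng_range.upper
            col = np.empty(n)
            mask = out_mask[d]
            n_out = int(mask.sum())
            if n - n_out:
                col[~mask] = spec.sample(n - n_out, rng, lo=lo, hi=hi)
            if n_out:
                col[mask] = _out_region_sample(spec, None, lo, hi, n_out, rng)
            values[d] = col
        else:
            values[d] = spec.sample(n, rng)

    width = len(str(n))
    profiles = []
    for i in range(n):
        vals = {d: float(values[d][i]) for d in marginals}
        profiles.append(
            CompoundProfile(
                id=f"{config.id_prefix}{i + 1:0{width}d}",
                values=vals,
                provenance={d: "computed" for d in vals},
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Geometry fixtures
# ---------------------------------------------------------------------------

_TET = 1.09 / math.sqrt(3.0)  # C-H 1.09 Å along (±1,±1,±1)


def generate_fixture_molecules() -> list[MoleculeRecord]:
    """Hand-coded molecules with exact coordinates for geometry tests."""
    recs = [
        MoleculeRecord("H_atom", "hydrogen atom", [Atom("H", 0, 0, 0)]),
        MoleculeRecord("C_atom", "carbon atom", [Atom("C", 0, 0, 0)]),
        MoleculeRecord("O_atom", "oxygen atom", [Atom("O", 0, 0, 0)]),
        MoleculeRecord(
            "C2_far", "two distant carbons",
            [Atom("C", 0, 0, 0), Atom("C", 100.0, 0, 0)],
        ),
        MoleculeRecord(
            "C2_dimer", "overlapping carbon dimer (1.5 Å)",
            [Atom("C", 0, 0, 0), Atom("C", 1.5, 0, 0)],
            [Bond(0, 1)],
        ),
        MoleculeRecord(
            "methane", "methane",
            [
                Atom("C", 0, 0, 0),
                Atom("H", _TET, _TET, _TET),
                Atom("H", -_TET, -_TET, _TET),
                Atom("H", -_TET, _TET, -_TET),
                Atom("H", _TET, -_TET, -_TET),
            ],
            [Bond(0, k) for k in range(1, 5)],
        ),
        MoleculeRecord(
            "water", "water",
            [
                Atom("O", 0, 0, 0),
                Atom("H", 0.9572, 0, 0),
                Atom("H", -0.23999, 0.92663, 0),
            ],
            [Bond(0, 1), Bond(0, 2)],
        ),
        MoleculeRecord(
            "ethanol", "ethanol",
            [
                Atom("C", 0.0, 0.0, 0.0),           # methyl C
                Atom("C", 1.512, 0.0, 0.0),         # methylene C
                Atom("O", 2.032, 1.329, 0.0),       # hydroxyl O
                Atom("H", -0.39, -0.63, 0.80),
                Atom("H", -0.39, -0.63, -0.80),
                Atom("H", -0.39, 1.01, 0.0),
                Atom("H", 1.90, -0.52, 0.88),
                Atom("H", 1.90, -0.52, -0.88),
                Atom("H", 2.99, 1.26, 0.0),         # O-H
            ],
            [Bond(0, 1), Bond(1, 2), Bond(0, 3), Bond(0, 4), Bond(0, 5),
             Bond(1, 6), Bond(1, 7), Bond(2, 8)],
        ),
    ]
    # benzene: C hexagon r = 1.397 Å, H at 2.487 Å, aromatic ring bonds
    atoms = []
    for k in range(6):
        ang = math.pi / 3.0 * k
        atoms.append(Atom("C", 1.397 * math.cos(ang), 1.397 * math.sin(ang), 0.0))
    for k in range(6):
        ang = math.pi / 3.0 * k
        atoms.append(Atom("H", 2.487 * math.cos(ang), 2.487 * math.sin(ang), 0.0))
    bonds = [Bond(k, (k + 1) % 6, 1.5) for k in range(6)]
    bonds += [Bond(k, k + 6, 1.0) for k in range(6)]
    recs.append(MoleculeRecord("benzene", "benzene", atoms, bonds))
    return recs
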