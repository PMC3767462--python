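"""Pharmacokinetic decision rules.

* similarity-adjusted property prediction: when a query compound is highly
  similar (Tanimoto S ≥ 0.9 by default) to its nearest analogue in an
  experimental training set, the model prediction P_QP is blended with the
  analogue's experimental value P_exp as

      P_pred = S · P_exp + (1 − S) · P_QP

  and at S = 1 the prediction is exactly the experimental value; below the
  threshold the raw model value is kept;
* maximum transdermal transport rate Jm = Kp × MW × S_wat, from the skin
  permeability coefficient (10^logKp), molecular weight and aqueous
  solubility (10^logS_wat), with the Jm > 100 flag;
* CNS-activity flag on the integer −2..+2 scale (active iff score > 1);
* qualitative oral-absorption class (1 = low, 2 = medium, 3 = high) binned
  from percent human oral absorption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "TrainingSetEntry",
    "SimilarityConfig",
    "tanimoto_similarity",
    "nearest_analogue",
    "similarity_adjusted_prediction",
    "predict_with_training_set",
    "transdermal_rate",
    "jm_exceeds",
    "cns_active",
    "oral_absorption_class",
    "load_training_set",
    "PKRuleError",
]


class PKRuleError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingSetEntry:
    id: str
    smiles: str
    experimental_value: float


@dataclass(frozen=True)
class SimilarityConfig:
    """Similarity metric and blending threshold for adjusted prediction."""

    metric: str = "tanimoto"
    threshold: float = 0.9
    fp_radius: int = 2
    fp_bits: int = 2048

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise PKRuleError("threshold must lie in [0, 1]")


def load_training_set(path: str | Path) -> list[TrainingSetEntry]:
    """Read a training set CSV with columns id, smiles, experimental_value."""
    df = pd.read_csv(path)
    required = {"id", "smiles", "experimental_value"}
    if not required.issubset(df.columns):
        raise PKRuleError(f"training set needs columns {sorted(required)}")
    return [
        TrainingSetEntry(str(r.id), str(r.smiles), float(r.experimental_value))
        for r in df.itertuples()
    ]


def _fingerprint(smiles: str, cfg: SimilarityConfig):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise PKRuleError(f"invalid SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.fp_radius, fpSize=cfg.fp_bits
    )
    return gen.GetFingerprint(mol)


def tanimoto_similarity(
    smiles_a: str, smiles_b: str, cfg: SimilarityConfig | None = None
) -> float:
    """Tanimoto similarity between hashed-substructure fingerprints."""
    from rdkit import DataStructs

    cfg = cfg or SimilarityConfig()
    return float(
        DataStructs.TanimotoSimilarity(
            _fingerprint(smiles_a, cfg), _fingerprint(smiles_b, cfg)
        )
    )


def nearest_analogue(
    smiles: str,
    training_set: list[TrainingSetEntry],
    cfg: SimilarityConfig | None = None,
) -> tuple[TrainingSetEntry, float]:
    """Most similar training-set entry and its similarity to the query."""
    if not training_set:
        raise PKRuleError("empty training set")
    cfg = cfg or SimilarityConfig()
    from rdkit import DataStructs

    query = _fingerprint(smiles, cfg)
    best, best_s = None, -1.0
    for entry in training_set:
        s = DataStructs.TanimotoSimilarity(query, _fingerprint(entry.smiles, cfg))
        if s > best_s:
            best, best_s = entry, s
    return best, float(best_s)


def similarity_adjusted_prediction(
    s: float, p_exp: float, p_qp: float, threshold: float = 0.9
) -> float:
    """Blend the model prediction with the nearest analogue's experimental
    value: P_pred = s·P_exp + (1−s)·P_QP for s ≥ threshold, else P_QP."""
    if not 0.0 <= s <= 1.0:
        raise PKRuleError(f"similarity {s} outside [0, 1]")
    if s < threshold:
        return p_qp
    return s * p_exp + (1.0 - s) * p_qp


def predict_with_training_set(
    smiles: str,
    p_qp: float,
    training_set: list[TrainingSetEntry],
    cfg: SimilarityConfig | None = None,
) -> tuple[float, float, str]:
    """End-to-end similarity-adjusted prediction.

    Returns (adjusted prediction, similarity, nearest analogue id).
    """
    cfg = cfg or SimilarityConfig()
    entry, s = nearest_analogue(smiles, training_set, cfg)
    return (
        similarity_adjusted_prediction(s, entry.experimental_value, p_qp,
                                       cfg.threshold),
        s,
        entry.id,
    )


def transdermal_rate(
    log_kp: float, mw: float, log_s_wat: float, unit_scale: float = 1.0
) -> float:
    """Maximum transdermal transport rate Jm = Kp × MW × S_wat.

    Kp = 10^log_kp (cm/h), S_wat = 10^log_s_wat (mol/L), MW in g/mol;
    ``unit_scale`` converts into the reporting unit (identity by default,
    giving μg cm⁻² h⁻¹ × 10⁻³-scale ambiguity absorbed into the scale —
    see docs/methods.md).  Non-negative, separable, increasing in each
    factor.
    """
    for name, v in (("log_kp", log_kp), ("mw", mw), ("log_s_wat", log_s_wat)):
        if math.isnan(v) or v == math.inf:
            raise PKRuleError(f"non-finite {name}")
    return unit_scale * (10.0 ** log_kp) * mw * (10.0 ** log_s_wat)


def jm_exceeds(jm: float, threshold: float = 100.0) -> bool:
    """Strict high-transdermal-rate flag: Jm > threshold."""
    return jm > threshold


def cns_active(cns_score: int) -> bool:
    """True iff the −2..+2 CNS activity score is > 1 (i.e. exactly +2)."""
    if not -2 <= cns_score <= 2:
        raise PKRuleError(f"CNS score {cns_score} outside -2..+2")
    return cns_score > 1


#: lower edges of the medium and high oral-absorption classes (%)
DEFAULT_HOA_BINS = (25.0, 80.0)


def oral_absorption_class(
    percent_hoa: float, bins: tuple[float, float] = DEFAULT_HOA_BINS
) -> int:
    """Qualitative oral absorption: 1 = low, 2 = medium, 3 = high.

    Default bin edges (<25 low, 25–80 medium, >80 high) are an assumption;
    edges are configurable.
    """
    if not 0.0 <= percent_hoa <= 100.0:
        raise PKRuleError(f"percent HOA {percent_hoa} outside 0..100")
    lo, hi = bins
    if percent_hoa < lo:
        return 1
    if percent_hoa <= hi:
        return 2
    return 3
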