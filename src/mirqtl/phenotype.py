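"""Phenotype and qPCR arithmetic: relative water content, canopy
temperature increase, total chlorophyll (Arnon), and 2^-ddCt fold change
with the signed reporting convention used for qPCR tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .util import round_half_up


@dataclass
class PhenotypeRecord:
    genotype: str
    kind: str  # "IRT" | "RWC" | "chlorophyll" | "enzyme"
    condition: str  # "control" | "drought"
    values: list[float]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("at least one replicate value required")
        if self.kind == "IRT" and any(not 0 <= v <= 60 for v in self.values):
            warnings.warn(
                f"{self.genotype}: canopy temperature outside 0-60 degC", stacklevel=2
            )

    @property
    def mean(self) -> float:
        return sum(self.values) / len(self.values)


@dataclass
class QpcrRecord:
    target_id: str
    ct_target_treat: float
    ct_norm_treat: float
    ct_target_ctrl: float
    ct_norm_ctrl: float

    def __post_init__(self) -> None:
        cts = (self.ct_target_treat, self.ct_norm_treat, self.ct_target_ctrl, self.ct_norm_ctrl)
        if any(ct <= 0 for ct in cts):
            raise ValueError("Ct values must be positive")


def relative_water_content(fresh: float, dry: float, turgid: float) -> float:
    """RWC% = (fresh - dry) / (turgid - dry) * 100.

    Values above 100 (fresh above turgid) are physically suspect and
    flagged with a warning rather than rejected.
    """
    if turgid == dry:
        raise ValueError("turgid weight equals dry weight")
    if turgid < dry or fresh < dry:
        raise ValueError("expected turgid > dry and fresh >= dry")
    rwc = (fresh - dry) / (turgid - dry) * 100.0
    if fresh > turgid:
        warnings.warn("fresh weight exceeds turgid weight (RWC > 100)", stacklevel=2)
    return rwc


def percent_increase(before: float, after: float, decimals: int = 2) -> float:
    """100*(after - before)/before, rounded half-up."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return round_half_up(100.0 * (after - before) / before, decimals)


# Arnon coefficients for total chlorophyll in DMSO extracts (ug/ml).
ARNON_A645 = 20.2
ARNON_A663 = 8.02


def total_chlorophyll(
    a645: float, a663: float, volume_ml: float = 1.0, mass_g: float = 1.0
) -> float:
    """Total chlorophyll from 645/663 nm absorbances of a DMSO extract.

    chl (ug/ml) = 20.2*A645 + 8.02*A663, scaled by extract volume over
    tissue mass: the result is ug chlorophyll per g fresh weight (divide by
    1000 for mg/g). At unit volume and mass the value equals the extract
    concentration in ug/ml.
    """
    if a645 < 0 or a663 < 0:
        raise ValueError("absorbances must be non-negative")
    if mass_g <= 0:
        raise ValueError("tissue mass must be positive")
    ug_per_ml = ARNON_A645 * a645 + ARNON_A663 * a663
    return ug_per_ml * volume_ml / mass_g


def ddct_fold_change(
    ct_target_treat: float,
    ct_norm_treat: float,
    ct_target_ctrl: float,
    ct_norm_ctrl: float,
) -> tuple[float, float]:
    """(fold_change, signed_fold_change) by the 2^-ddCt method.

    ddCt = (Ct_target,treat - Ct_norm,treat) - (Ct_target,ctrl -
    Ct_norm,ctrl); fold = 2^-ddCt. The signed convention reports
    down-regulation as -1/fold (e.g. fold 0.25 prints as -4.0), matching
    how qPCR tables report negative fold values; the raw ratio is always
    returned alongside.
    """
    rec = QpcrRecord("x", ct_target_treat, ct_norm_treat, ct_target_ctrl, ct_norm_ctrl)
    ddct = (rec.ct_target_treat - rec.ct_norm_treat) - (rec.ct_target_ctrl - rec.ct_norm_ctrl)
    fold = 2.0 ** (-ddct)
    signed = fold if fold >= 1.0 else -1.0 / fold
    return fold, signed
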