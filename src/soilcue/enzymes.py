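"""Ecoenzymatic stoichiometry: vector model, limitation classes, indices.

Seven hydrolytic/oxidative activities are measured per site, in
nmol h⁻¹ g⁻¹ soil: the carbon-acquisition enzymes BG (β-1,4-glucosidase),
BX (β-xylosidase), CBH (cellobiose hydrolase) and PPO (polyphenol
oxidase); the nitrogen enzymes NAG (N-acetyl-β-D-glucosaminidase) and LAP
(leucine aminopeptidase); and the phosphorus enzyme ACP (acid
phosphatase).

The vector model summarizes relative resource-acquisition effort:

    x = (BG + CBH) / (BG + CBH + ACP)
    y = (BG + CBH) / (BG + CBH + LAP + NAG)
    Length = sqrt(x² + y²)
    Angle  = degrees(atan2(x, y))

Note the deliberate atan2 argument order ``(x, y)`` — x (the C:P ratio
term) first — so that Angle grows with phosphorus-acquisition effort:
Angle > 45° marks P limitation, < 45° N limitation. Length tracks carbon
versus nutrient acquisition (a relative score; no absolute threshold).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENZYME_NAMES = ("BG", "BX", "CBH", "PPO", "NAG", "LAP", "ACP")


@dataclass
class EnzymePanel:
    """Activities of the seven assayed enzymes, nmol h⁻¹ g⁻¹ soil."""

    BG: float
    BX: float
    CBH: float
    PPO: float
    NAG: float
    LAP: float
    ACP: float

    def __post_init__(self) -> None:
        for name in ENZYME_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"enzyme activity {name} must be non-negative")


@dataclass
class EnzymeVector:
    """Vector-model summary of one panel."""

    x: float
    y: float
    length: float
    angle: float
    limitation_class: str


def compute_xy(panel: EnzymePanel) -> tuple[float, float]:
    """Relative C:P (x) and C:N (y) acquisition ratios, both in [0, 1].

    Returns NaN for a ratio whose denominator is zero (no relevant
    activity measured), with a logged warning.
    """
    c = panel.BG + panel.CBH
    denom_x = c + panel.ACP
    denom_y = c + panel.LAP + panel.NAG
    if denom_x == 0:
        logger.warning("x undefined: BG + CBH + ACP = 0")
        x = float("nan")
    else:
        x = c / denom_x
    if denom_y == 0:
        logger.warning("y undefined: BG + CBH + LAP + NAG = 0")
        y = float("nan")
    else:
        y = c / denom_y
    return x, y


def compute_vector(x: float, y: float) -> tuple[float, float]:
    """Vector length and angle (degrees) for acquisition ratios (x, y).

    The angle uses atan2(x, y) — x first — so it measures rotation away
    from the y (C:N) axis: (x>0, y=0) → 90°, (x=0, y>0) → 0°.
    """
    length = math.hypot(x, y)
    angle = math.degrees(math.atan2(x, y))
    return length, angle


def classify_limitation(angle: float, tolerance: float = 0.0) -> str:
    """Nutrient-limitation class from the vector angle.

    Angle > 45° → ``"P-limited"``; < 45° → ``"N-limited"``; within
    ``tolerance`` of 45° → ``"balanced"``.
    """
    if abs(angle - 45.0) <= tolerance:
        return "balanced"
    return "P-limited" if angle > 45.0 else "N-limited"


def enzyme_vector(panel: EnzymePanel, tolerance: float = 0.0) -> EnzymeVector:
    """Full vector-model summary for one enzyme panel."""
    x, y = compute_xy(panel)
    length, angle = compute_vector(x, y)
    return EnzymeVector(
        x=x, y=y, length=length, angle=angle,
        limitation_class=classify_limitation(angle, tolerance),
    )


def specific_activity(panel: EnzymePanel, mbc: float) -> dict[str, float]:
    """Activities normalized by microbial biomass carbon.

    Removes biomass-driven variation: each activity is divided by MBC
    (units nmol h⁻¹ µg MBC⁻¹). Returns NaNs with a warning when MBC ≤ 0.
    """
    if mbc <= 0:
        logger.warning("non-positive MBC (%.3f): specific activities undefined", mbc)
        return {name: float("nan") for name in ENZYME_NAMES}
    return {name: getattr(panel, name) / mbc for name in ENZYME_NAMES}


def enzyme_activity_index(
    matrix: pd.DataFrame, population_sd: bool = False
) -> pd.Series:
    """Z-score-based composite soil enzyme activity index, one value per site.

    Each enzyme column is z-scored across sites (sample SD, ddof=1, by
    default) and the index is the row mean of the z-scores. Constant
    columns carry no cross-site information and are dropped with a
    warning; unit changes (affine rescaling of a column) leave the index
    unchanged.
    """
    if len(matrix) < 2:
        raise ValueError("enzyme activity index needs at least 2 sites")
    ddof = 0 if population_sd else 1
    sd = matrix.std(ddof=ddof)
    constant = sd[sd == 0].index
    if len(constant) == matrix.shape[1]:
        # no cross-site variation at all: every z-score is zero
        logger.warning("all enzyme columns constant; index is 0 everywhere")
        return pd.Series(0.0, index=matrix.index)
    if len(constant):
        logger.warning("dropping constant enzyme columns: %s", list(constant))
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    z = (matrix - matrix.mean()) / sd
    return z.mean(axis=1)


def vector_table(
    panels: pd.DataFrame, tolerance: float = 0.0
) -> pd.DataFrame:
    """Vector-model summary for a sites × enzymes activity table."""
    records = []
    for site, row in panels.iterrows():
        v = enzyme_vector(EnzymePanel(**{n: row[n] for n in ENZYME_NAMES}), tolerance)
        records.append(
            {"site": site, "x": v.x, "y": v.y, "length": v.length,
             "angle": v.angle, "limitation_class": v.limitation_class}
        )
    return pd.DataFrame.from_records(records).set_index("site")


def specific_activity_table(panels: pd.DataFrame, mbc: pd.Series) -> pd.DataFrame:
    """Per-MBC specific activities for a sites × enzymes table."""
    out = {}
    for site, row in panels.iterrows():
        out[site] = specific_activity(
            EnzymePanel(**{n: row[n] for n in ENZYME_NAMES}), float(mbc.loc[site])
        )
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = panels.index.name
    return df[list(ENZYME_NAMES)]
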