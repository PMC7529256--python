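"""Relative gene expression from qPCR cycle-threshold tables (ddCt method).

Per replicate, dCt = Ct_target - Ct_reference removes loading
differences via the reference gene; ddCt = dCt - mean dCt of the
calibrator gene x genotype group puts everything on the calibrator's
scale; relative expression is E^(-ddCt) with amplification efficiency
E = 2 (perfect doubling) unless an efficiency-corrected value is given.
The calibrator group's mean relative expression is 1 by construction.
Calibrator uncertainty is not propagated into other groups' standard
errors (only the calibrator's mean dCt is used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class CtRecord:
    gene: str
    genotype: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{self.gene}/{self.genotype}: Ct must be finite, > 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class ExpressionSummary:
    gene: str
    genotype: str
    mean: float
    se: float
    n: int


def ddct_relative_expression(
    records: Sequence[CtRecord],
    calibrator: tuple[str, str],
    efficiency: float = 2.0,
) -> list[ExpressionSummary]:
    """Mean relative expression +/- se per gene x genotype group.

    ``calibrator`` names the (gene, genotype) group whose mean dCt anchors
    the scale. Raises if the calibrator is absent from ``records``.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    dct: dict[tuple[str, str], list[float]] = {}
    for r in records:
        dct.setdefault((r.gene, r.genotype), []).append(r.ct_target - r.ct_reference)
    if calibrator not in dct:
        raise ValueError(f"calibrator {calibrator} not present in Ct records")
    cal_mean = float(np.mean(dct[calibrator]))

    out = []
    for key in sorted(dct):
        rel = np.array([efficiency ** (-(d - cal_mean)) for d in dct[key]])
        n = len(rel)
        se = float(np.std(rel, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(ExpressionSummary(key[0], key[1], float(rel.mean()), se, n))
    return out
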