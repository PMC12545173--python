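"""Single-cell and bulk 13C atom-fraction statistics from secondary-ion counts.

Secondary-ion mass spectrometry of Cs-sputtered biomass detects C2- cluster
ions; the carbon isotope fraction of a region of interest (ROI, one cell)
follows from the 12C13C- and 12C2- count totals as

    13C atom fraction = 12C13C / (2*12C2 + 12C13C)

because a 12C13C- ion carries one heavy atom out of two.  The counting
(shot-noise) error of that ratio is the delta-method propagation of Poisson
uncertainties of the two count totals:

    sigma_Pois = sqrt(a^2*b + b^2*a) / (2a + b)^2,   a = 12C2, b = 12C13C

(fractional scale; multiplied by 100 when reported next to atom percent).

A cell counts as significantly 13C-enriched relative to unlabelled control
cells when (1) its atom fraction exceeds the control mean plus three control
standard deviations, and (2) three times its own Poisson counting error is
smaller than its distance from the control mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class IonCountSet:
    """Per-ROI secondary-ion counts."""

    roi_id: str
    c12c12: int
    c12c13: int
    day: str = ""
    c12n14: int | None = None
    p31: int | None = None
    s32: int | None = None

    def __post_init__(self) -> None:
        for name in ("c12c12", "c12c13"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{self.roi_id}: {name} must be a non-negative integer")


@dataclass(frozen=True)
class AtomFraction:
    """13C atom percent with its Poisson counting error (both in percent)."""

    value: float
    poisson_sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 100.0:
            raise ValueError("atom percent outside [0, 100]")
        if self.poisson_sigma < 0:
            raise ValueError("poisson_sigma must be non-negative")


def poisson_sigma(c12c12: float, c12c13: float) -> float:
    """Counting error of the atom fraction, on the fractional (0..1) scale."""
    a, b = float(c12c12), float(c12c13)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    denom = 2.0 * a + b
    if denom <= 0:
        raise ValueError("2*c12c12 + c12c13 must be positive")
    return math.sqrt(a * a * b + b * b * a) / denom ** 2


def atom_percent(counts: IonCountSet) -> AtomFraction:
    """13C atom percent of one ROI from its C2- counts, with Poisson error."""
    a, b = counts.c12c12, counts.c12c13
    denom = 2 * a + b
    if denom <= 0:
        raise ValueError(f"{counts.roi_id}: zero C2- counts")
    value = 100.0 * b / denom
    sigma = 100.0 * poisson_sigma(a, b)
    return AtomFraction(value=value, poisson_sigma=sigma)


def bulk_atom_percent(c13: float, c12: float) -> float:
    """Bulk 13C atom% = 13C/(13C+12C)x100 (e.g. from isotope-ratio MS)."""
    if c13 < 0 or c12 < 0:
        raise ValueError("isotope amounts must be non-negative")
    total = c13 + c12
    if total <= 0:
        raise ValueError("total carbon must be positive")
    return 100.0 * c13 / total


@dataclass(frozen=True)
class EnrichmentCall:
    """Two-criterion significance call for one cell against controls."""

    enriched: bool
    value: float              # atom%
    control_mean: float       # atom%
    control_sd: float         # atom%, sample (n-1) estimator
    difference: float         # value - control_mean
    three_sigma_poisson: float  # 3x the cell's own counting error, atom%


def call_enrichment(cell: AtomFraction,
                    control_cells: Sequence[AtomFraction]) -> EnrichmentCall:
    """Call 13C enrichment of one cell against unlabelled control cells.

    Enriched iff value > control mean + 3*control SD (strict) AND
    3*sigma_Pois(cell) < value - control mean (strict).
    """
    if len(control_cells) < 2:
        raise ValueError("need at least two control cells")
    values = np.array([c.value for c in control_cells], dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    diff = cell.value - mean
    three_sigma = 3.0 * cell.poisson_sigma
    enriched = (cell.value > mean + 3.0 * sd) and (three_sigma < diff)
    return EnrichmentCall(enriched=enriched, value=cell.value,
                          control_mean=mean, control_sd=sd,
                          difference=diff, three_sigma_poisson=three_sigma)
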