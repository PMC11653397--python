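"""Enantiomeric fractions of atropisomeric PCB peak pairs.

On a chiral GC column the two atropisomers of an axially chiral PCB
elute as a partially resolved pair; the enantiomeric fraction
EF = A_E1 / (A_E1 + A_E2) summarizes the first-eluting atropisomer's
share of the total area.  EF = 0.5 is racemic; deviations indicate
enantioselective processes.  A racemic-standard QC check compares a
measured EF against the racemic reference within a tolerance band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: EF of the racemic standard and its 1-sigma repeatability
RACEMIC_REFERENCE = 0.498
RACEMIC_SD = 0.004


@dataclass(frozen=True)
class AtropisomerPeaks:
    """Integrated areas of the two atropisomer peaks of one sample.

    The elution order carries the configuration assignment (the
    second-eluting atropisomer corresponds to aS on the column used here);
    that mapping is metadata only and does not affect the arithmetic.
    """

    sample_id: str
    a_e1: float
    a_e2: float

    def __post_init__(self):
        if self.a_e1 < 0 or self.a_e2 < 0:
            raise ValueError(f"{self.sample_id}: peak areas must be non-negative")
        if self.a_e1 + self.a_e2 == 0:
            raise ValueError(f"{self.sample_id}: both atropisomer areas are zero")


@dataclass(frozen=True)
class EFResult:
    sample_id: str
    ef: float
    racemic: bool

    def __post_init__(self):
        if not 0.0 <= self.ef <= 1.0:
            raise ValueError("EF must lie in [0, 1]")


def compute_ef(peaks: AtropisomerPeaks,
               reference: float = RACEMIC_REFERENCE,
               tol: float = 3 * RACEMIC_SD) -> EFResult:
    """EF = A_E1/(A_E1 + A_E2), with a racemic flag vs the reference band."""
    ef = peaks.a_e1 / (peaks.a_e1 + peaks.a_e2)
    return EFResult(sample_id=peaks.sample_id, ef=ef,
                    racemic=racemic_check(ef, reference, tol))


def racemic_check(ef: float, reference: float = RACEMIC_REFERENCE,
                  tol: float = 3 * RACEMIC_SD) -> bool:
    """True iff ``ef`` lies within ``reference`` +/- ``tol``.

    The default band is three standard deviations of the racemic
    standard's measured EF.
    """
    if not 0.0 <= reference <= 1.0:
        raise ValueError("reference EF must lie in [0, 1]")
    return abs(ef - reference) <= tol


def valley_drop_areas(
    rt: np.ndarray,
    signal: np.ndarray,
) -> tuple[float, float]:
    """Perpendicular-drop integration of a two-peak chromatogram.

    Finds the valley (signal minimum) between the two highest local maxima
    and integrates the trace on either side by the trapezoid rule.  Used
    to turn synthetic two-Gaussian chromatograms into atropisomer area
    pairs; real integration happens upstream of this package.
    """
    rt = np.asarray(rt, dtype=float)
    signal = np.asarray(signal, dtype=float)
    interior = (signal[1:-1] > signal[:-2]) & (signal[1:-1] >= signal[2:])
    peaks = np.where(interior)[0] + 1
    if peaks.size < 2:
        raise ValueError("chromatogram does not contain two resolved peaks")
    top2 = peaks[np.argsort(signal[peaks])[::-1][:2]]
    left, right = np.sort(top2)
    valley = left + int(np.argmin(signal[left:right + 1]))
    a1 = float(np.trapezoid(signal[: valley + 1], rt[: valley + 1]))
    a2 = float(np.trapezoid(signal[valley:], rt[valley:]))
    return a1, a2
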