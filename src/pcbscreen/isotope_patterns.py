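"""Theoretical isotope envelopes and pattern scoring.

Polychlorinated ions have a diagnostic isotope envelope: the ~24.2%
natural abundance of 37Cl produces strong M+2/M+4/M+6 companions whose
ratios identify the chlorine count.  This module computes exact isotope
distributions by multinomial expansion per element and convolution across
elements, aggregates them into nominal (unit-Da) peaks, and scores
observed centroid clusters against the theoretical pattern with a cosine
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chem_core import ELECTRON_MASS, ElementalFormula, IonSpecies

# Isotope masses (Da) and abundance fractions, IUPAC 2021 representative
# values.  Stored as data: envelope computations must not depend on any
# external mass table to stay reproducible.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503, 0.999885), (2.01410178, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335484, 0.0107)],
    "N": [(14.00307401, 0.99636), (15.00010890, 0.00364)],
    "O": [(15.99491462, 0.99757), (16.99913176, 0.00038), (17.99915961, 0.00205)],
    "F": [(18.99840316, 1.0)],
    "S": [(31.97207117, 0.9499), (32.97145891, 0.0075),
          (33.96786701, 0.0425), (35.96708071, 0.0001)],
    "Cl": [(34.96885268, 0.7576), (36.96590260, 0.2424)],
}

_MERGE_TOL_DA = 1e-6


@dataclass(frozen=True)
class IsotopeDistribution:
    """A discrete distribution over isotopologue exact masses."""

    masses: np.ndarray      # strictly increasing, Da
    abundances: np.ndarray  # fractions, sum <= 1 (pruning may trim mass)

    def __post_init__(self):
        object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))

    @classmethod
    def point(cls, mass: float = 0.0, abundance: float = 1.0) -> "IsotopeDistribution":
        return cls(np.array([mass]), np.array([abundance]))


def _merge(masses: np.ndarray, abundances: np.ndarray,
           tol: float = _MERGE_TOL_DA) -> IsotopeDistribution:
    """Sort by mass and sum abundances of entries closer than ``tol``."""
    order = np.argsort(masses)
    masses, abundances = masses[order], abundances[order]
    out_m: list[float] = []
    out_a: list[float] = []
    for m, a in zip(masses, abundances):
        if out_m and m - out_m[-1] <= tol:
            # abundance-weighted mass of the merged entry
            tot = out_a[-1] + a
            out_m[-1] = (out_m[-1] * out_a[-1] + m * a) / tot
            out_a[-1] = tot
        else:
            out_m.append(m)
            out_a.append(a)
    return IsotopeDistribution(np.array(out_m), np.array(out_a))


def element_distribution(element: str, n: int, prune: float = 0.0) -> IsotopeDistribution:
    """Exact multinomial isotope distribution of ``n`` atoms of one element.

    Computed by repeated convolution of the single-atom distribution;
    isotopologues with identical mass sums merge exactly, so the result is
    the multinomial expansion without enumeration.
    """
    if n < 0:
        raise ValueError("atom count must be non-negative")
    if element not in ISOTOPES:
        raise ValueError(f"no isotope data for element {element!r}")
    dist = IsotopeDistribution.point()
    if n == 0:
        return dist
    single = IsotopeDistribution(
        np.array([m for m, _ in ISOTOPES[element]]),
        np.array([a for _, a in ISOTOPES[element]]),
    )
    remaining, power = n, single
    while remaining:
        if remaining & 1:
            dist = convolve(dist, power, prune=prune, renormalize=False)
        remaining >>= 1
        if remaining:
            power = convolve(power, power, prune=prune, renormalize=False)
    return dist


def convolve(a: IsotopeDistribution, b: IsotopeDistribution,
             prune: float = 0.0, renormalize: bool = True) -> IsotopeDistribution:
    """Convolution of two isotope distributions.

    All pairwise mass sums with abundance products, merged within 1e-6 Da,
    entries below ``prune`` dropped.  With ``renormalize`` the surviving
    abundances are rescaled to sum to the pre-pruning total, keeping the
    operation commutative and associative up to the pruning tolerance.
    """
    masses = (a.masses[:, None] + b.masses[None, :]).ravel()
    abund = (a.abundances[:, None] * b.abundances[None, :]).ravel()
    merged = _merge(masses, abund)
    if prune > 0:
        keep = merged.abundances >= prune
        total = merged.abundances.sum()
        m, ab = merged.masses[keep], merged.abundances[keep]
        if renormalize and ab.sum() > 0:
            ab = ab * (total / ab.sum())
        merged = IsotopeDistribution(m, ab)
    return merged


def formula_distribution(formula: Mapping[str, int],
                         prune: float = 1e-6) -> IsotopeDistribution:
    """Full isotope distribution of a formula (uncharged composition)."""
    dist = IsotopeDistribution.point()
    for element, n in sorted(formula.items()):
        dist = convolve(dist, element_distribution(element, n), prune=prune)
    return dist


@dataclass(frozen=True)
class NominalEnvelope:
    """Isotope envelope aggregated to unit-Da nominal peaks.

    ``offsets`` are integer Da offsets from the monoisotopic peak,
    ``mz`` the abundance-weighted exact m/z of each nominal peak, and
    ``rel_intensity`` intensities scaled so the base peak equals 100.
    ``fractions`` keeps the pre-scaling abundance fractions.
    """

    offsets: np.ndarray
    mz: np.ndarray
    rel_intensity: np.ndarray
    fractions: np.ndarray

    @property
    def monoisotopic_mz(self) -> float:
        return float(self.mz[self.offsets == 0][0])

    def top(self, n: int) -> "NominalEnvelope":
        """The ``n`` most intense nominal peaks, in offset order."""
        idx = np.sort(np.argsort(self.rel_intensity)[::-1][:n])
        return NominalEnvelope(self.offsets[idx], self.mz[idx],
                               self.rel_intensity[idx], self.fractions[idx])


def envelope(ion: IonSpecies | Mapping[str, int], charge: int | None = None,
             prune: float = 1e-6) -> NominalEnvelope:
    """Nominal isotope envelope of an ion, base peak scaled to 100.

    Accepts an :class:`IonSpecies` (charge taken from it) or a bare ion
    formula plus ``charge``.  The electron mass of the charge carrier is
    included so the monoisotopic peak lands on the anion m/z.
    """
    if isinstance(ion, IonSpecies):
        ion_formula, z = ion.ion_formula, ion.charge
    else:
        ion_formula = ion if isinstance(ion, ElementalFormula) else ElementalFormula(ion)
        z = -1 if charge is None else charge
    if z == 0:
        raise ValueError("charge must be nonzero")
    dist = formula_distribution(ion_formula, prune=prune)
    # m/z: add one electron mass per negative charge, subtract per positive.
    masses = (dist.masses + (abs(z) * ELECTRON_MASS if z < 0 else -abs(z) * ELECTRON_MASS)) / abs(z)
    mono = masses[0]
    offsets = np.rint(masses - mono).astype(int)
    uniq = np.unique(offsets)
    agg_mz = np.empty(uniq.size)
    agg_ab = np.empty(uniq.size)
    for i, off in enumerate(uniq):
        sel = offsets == off
        ab = dist.abundances[sel]
        agg_ab[i] = ab.sum()
        agg_mz[i] = float(np.average(masses[sel], weights=ab))
    rel = agg_ab / agg_ab.max() * 100.0
    return NominalEnvelope(uniq, agg_mz, rel, agg_ab)


@dataclass(frozen=True)
class PatternScore:
    """Cosine similarity of an observed cluster to a theoretical envelope."""

    score: float
    monoisotopic_matched: bool
    observed: np.ndarray  # matched intensity per theoretical peak

    def __float__(self) -> float:
        return self.score


def pattern_score(theoretical: NominalEnvelope,
                  observed: Sequence[tuple[float, float]],
                  mz_tolerance_ppm: float = 5.0,
                  top_n: int | None = None) -> PatternScore:
    """Score observed (m/z, intensity) peaks against a theoretical envelope.

    Each theoretical nominal peak collects the summed intensity of observed
    peaks within the ppm tolerance of its exact m/z; unmatched peaks
    contribute zero.  The score is the cosine between the matched intensity
    vector and the theoretical one — 1.0 for perfectly proportional
    patterns, scale invariant by construction.  If no observed peak matches
    the monoisotopic position the score is 0 with a flag.
    """
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise ValueError("observed peak list is empty")
    env = theoretical if top_n is None else theoretical.top(top_n)
    if 0 not in env.offsets:  # always check the monoisotopic position
        mono_mz = theoretical.monoisotopic_mz
    else:
        mono_mz = env.mz[env.offsets == 0][0]
    matched = np.zeros(env.mz.size)
    for i, mz in enumerate(env.mz):
        tol = mz * mz_tolerance_ppm * 1e-6
        sel = np.abs(obs[:, 0] - mz) <= tol
        matched[i] = obs[sel, 1].sum()
    mono_tol = mono_mz * mz_tolerance_ppm * 1e-6
    mono_hit = bool(np.any(np.abs(obs[:, 0] - mono_mz) <= mono_tol))
    if not mono_hit:
        return PatternScore(0.0, False, matched)
    norm = np.linalg.norm(matched) * np.linalg.norm(env.rel_intensity)
    score = float(matched @ env.rel_intensity / norm) if norm > 0 else 0.0
    return PatternScore(score, True, matched)


def write_envelope_csv(env: NominalEnvelope, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["offset", "mz", "rel_intensity"])
        for off, mz, rel in zip(env.offsets, env.mz, env.rel_intensity):
            writer.writerow([int(off), f"{mz:.5f}", f"{rel:.4f}"])
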