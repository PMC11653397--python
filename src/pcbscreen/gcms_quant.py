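"""Targeted quantification by internal-standard GC-MS/MS calibration.

Concentrations are computed with the internal-standard method: the
analyte/IS area ratio divided by a relative response factor (RRF) from a
standard mixture gives the analyte amount, which is divided by the sample
wet mass and corrected for the fractional recovery of the matching
surrogate standard.  Analytes without authentic standards are estimated
with the average RRF of the standards sharing their MRM transition group.
Blank-based method detection limits (MDL, mean + 3 SD of method blanks)
and limits of quantification (LOQ, mean + 10 SD of tissue blanks) flag
results near background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import ElementalFormula, monoisotopic_mass

#: default surrogate standard assigned to each analyte class
DEFAULT_SURROGATE_MAP = {
    "parent": "PCB117",
    "oh": "4'-159",
    "conjugate": "4-PCB52-sulfate",
}


@dataclass(frozen=True)
class ResponseFactor:
    """Relative response factor (A_analyte/A_IS)/(m_analyte/m_IS)."""

    analyte: str
    rrf: float
    transition_group: str | None = None

    def __post_init__(self):
        if self.rrf <= 0:
            raise ValueError(f"RRF for {self.analyte} must be positive")


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    analyte: str
    concentration: float  # ng/g wet weight
    recovery_corrected: bool
    estimated: bool = False     # True when a group-average RRF was used
    below_loq: bool | None = None
    below_mdl: bool | None = None


@dataclass(frozen=True)
class BlankStats:
    analyte: str
    mdl: float
    loq: float

    def __post_init__(self):
        if not (self.loq >= self.mdl >= 0):
            raise ValueError(f"{self.analyte}: need LOQ >= MDL >= 0")


def compute_rrf(standards: pd.DataFrame) -> list[ResponseFactor]:
    """RRFs from a standard-mixture table.

    Expected columns: analyte, area, amount, is_area, is_amount and
    optionally transition_group.  Replicate rows per analyte average to a
    single RRF.
    """
    required = {"analyte", "area", "amount", "is_area", "is_amount"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns {sorted(missing)}")
    if (standards["is_area"] <= 0).any():
        raise ValueError("internal-standard area must be positive")
    if (standards["amount"] <= 0).any() or (standards["is_amount"] <= 0).any():
        raise ValueError("standard amounts must be positive")
    df = standards.copy()
    df["rrf"] = (df["area"] / df["is_area"]) / (df["amount"] / df["is_amount"])
    group_col = df["transition_group"] if "transition_group" in df.columns else None
    out = []
    for analyte, sub in df.groupby("analyte", sort=True):
        group = None
        if group_col is not None:
            groups = sub["transition_group"].dropna().unique()
            group = groups[0] if len(groups) else None
        out.append(ResponseFactor(analyte=analyte, rrf=float(sub["rrf"].mean()),
                                  transition_group=group))
    return out


def average_rrf(factors: Sequence[ResponseFactor], transition_group: str) -> float:
    """Mean RRF of all standards in one MRM transition group."""
    vals = [f.rrf for f in factors if f.transition_group == transition_group]
    if not vals:
        raise ValueError(f"no standards in transition group {transition_group!r}")
    return float(np.mean(vals))


def quantify(
    sample_id: str,
    analyte: str,
    area: float,
    is_area: float,
    rrf: float,
    is_amount: float,
    sample_mass: float,
    recovery: float = 1.0,
    recovery_cap: float = 1.5,
    estimated: bool = False,
) -> QuantResult:
    """Internal-standard concentration in ng/g wet weight.

    conc = (A_analyte/A_IS) / RRF x m_IS / sample_mass / recovery.
    Recovery outside (0, ``recovery_cap``] indicates a failed surrogate
    and raises.
    """
    if rrf <= 0 or sample_mass <= 0:
        raise ValueError("RRF and sample mass must be positive")
    if is_area <= 0:
        raise ValueError("internal-standard area must be positive")
    if not (0 < recovery <= recovery_cap):
        raise ValueError(
            f"surrogate recovery {recovery:.3f} for {analyte}/{sample_id} outside "
            f"(0, {recovery_cap}]"
        )
    conc = (area / is_area) / rrf * is_amount / sample_mass / recovery
    return QuantResult(
        sample_id=sample_id, analyte=analyte, concentration=conc,
        recovery_corrected=recovery != 1.0, estimated=estimated,
    )


def estimate_unknown(
    sample_id: str,
    analyte: str,
    area: float,
    is_area: float,
    factors: Sequence[ResponseFactor],
    transition_group: str,
    is_amount: float,
    sample_mass: float,
    recovery: float = 1.0,
) -> QuantResult:
    """Quantify an analyte without an authentic standard via group-average RRF."""
    rrf = average_rrf(factors, transition_group)
    return quantify(sample_id, analyte, area, is_area, rrf, is_amount,
                    sample_mass, recovery, estimated=True)


def blank_limits(
    analyte: str,
    method_blanks: Sequence[float],
    tissue_blanks: Sequence[float] | None = None,
) -> BlankStats:
    """MDL/LOQ from blank concentrations.

    MDL = mean(method blanks) + 3 SD; LOQ = mean(tissue blanks) + 10 SD
    (method blanks reused when no tissue blanks exist).  SD uses the n-1
    denominator; fewer than 3 blanks triggers a warning.
    """
    mb = np.asarray(method_blanks, dtype=float)
    if mb.size == 0:
        raise ValueError(f"{analyte}: no method blanks provided")
    tb = np.asarray(tissue_blanks, dtype=float) if tissue_blanks is not None else mb
    if mb.size < 3 or tb.size < 3:
        warnings.warn(f"{analyte}: fewer than 3 blanks; MDL/LOQ poorly determined")
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    mdl = float(mb.mean()) + 3 * sd(mb)
    loq = float(tb.mean()) + 10 * sd(tb)
    return BlankStats(analyte=analyte, mdl=mdl, loq=max(loq, mdl))


def apply_limits(results: Sequence[QuantResult],
                 limits: Mapping[str, BlankStats]) -> list[QuantResult]:
    """Flag results relative to their analyte's MDL/LOQ (no censoring)."""
    out = []
    for r in results:
        b = limits.get(r.analyte)
        if b is None:
            out.append(r)
            continue
        out.append(QuantResult(
            sample_id=r.sample_id, analyte=r.analyte, concentration=r.concentration,
            recovery_corrected=r.recovery_corrected, estimated=r.estimated,
            below_loq=r.concentration < b.loq, below_mdl=r.concentration < b.mdl,
        ))
    return out


# Nominal molecular masses (g/mol) for molar summaries are derived from the
# monoisotopic formula masses unless the caller supplies averages.
def _default_molar_mass(formula: str) -> float:
    return monoisotopic_mass(ElementalFormula.parse(formula))


def molar_summary(
    results: Sequence[QuantResult],
    formulas: Mapping[str, str],
    parent: str = "PCB95",
    molar_masses: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample parent vs summed-hydroxylated-metabolite molar balance.

    Returns one row per sample with the parent concentration, the summed
    OH-metabolite concentration (all non-parent analytes), the molar
    percentage of each over the {parent, sum-OH} pair (exactly 100 total),
    and the molar fold ratio sum-OH/parent.
    """
    mass = dict(molar_masses or {})
    for analyte, formula in formulas.items():
        mass.setdefault(analyte, _default_molar_mass(formula))
    rows = []
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "analyte": r.analyte, "conc": r.concentration,
    } for r in results])
    for sample_id, sub in df.groupby("sample_id", sort=True):
        parent_conc = float(sub.loc[sub["analyte"] == parent, "conc"].sum())
        oh = sub[sub["analyte"] != parent]
        sum_oh = float(oh["conc"].sum())
        parent_molar = parent_conc / mass[parent]
        oh_molar = float(sum(
            row["conc"] / mass[row["analyte"]] for _, row in oh.iterrows()
        ))
        total = parent_molar + oh_molar
        rows.append({
            "sample_id": sample_id,
            "parent_ng_g": parent_conc,
            "sum_oh_ng_g": sum_oh,
            "parent_molar_pct": 100.0 * parent_molar / total if total else np.nan,
            "sum_oh_molar_pct": 100.0 * oh_molar / total if total else np.nan,
            "fold_oh_over_parent": oh_molar / parent_molar if parent_molar else np.inf,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def quantify_table(
    areas: pd.DataFrame,
    standards: pd.DataFrame,
    sample_masses: Mapping[str, float],
    is_amount: float,
    surrogate_amounts: Mapping[str, float] | None = None,
    analyte_surrogates: Mapping[str, str] | None = None,
    unknown_groups: Mapping[str, str] | None = None,
) -> list[QuantResult]:
    """Quantify a whole area table.

    ``areas`` columns: sample_id, analyte, role (analyte | internal_standard
    | surrogate), area.  Exactly one internal-standard row per sample.
    Surrogate recoveries are computed in-table from the surrogate rows and
    their spiked amounts; ``analyte_surrogates`` maps each analyte to the
    surrogate that corrects it.  Analytes named in ``unknown_groups`` are
    quantified with the average RRF of their transition group.
    """
    factors = compute_rrf(standards)
    by_name = {f.analyte: f for f in factors}
    results: list[QuantResult] = []
    for sample_id, sub in areas.groupby("sample_id", sort=True):
        is_rows = sub[sub["role"] == "internal_standard"]
        if len(is_rows) != 1:
            raise ValueError(f"sample {sample_id}: need exactly one internal-standard row")
        is_area = float(is_rows["area"].iloc[0])
        mass = sample_masses[sample_id]
        # surrogate fractional recoveries for this sample
        recoveries: dict[str, float] = {}
        for _, row in sub[sub["role"] == "surrogate"].iterrows():
            surr = row["analyte"]
            amount = (surrogate_amounts or {}).get(surr)
            f = by_name.get(surr)
            if amount is None or f is None:
                continue
            measured = (row["area"] / is_area) / f.rrf * is_amount
            recoveries[surr] = measured / amount
        for _, row in sub[sub["role"] == "analyte"].iterrows():
            analyte = row["analyte"]
            surr = (analyte_surrogates or {}).get(analyte)
            recovery = recoveries.get(surr, 1.0) if surr else 1.0
            if analyte in by_name:
                results.append(quantify(
                    sample_id, analyte, float(row["area"]), is_area,
                    by_name[analyte].rrf, is_amount, mass, recovery,
                ))
            elif unknown_groups and analyte in unknown_groups:
                results.append(estimate_unknown(
                    sample_id, analyte, float(row["area"]), is_area, factors,
                    unknown_groups[analyte], is_amount, mass, recovery,
                ))
            else:
                raise ValueError(f"no RRF or transition group for analyte {analyte!r}")
    return results


def results_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "analyte": r.analyte,
        "concentration_ng_g": r.concentration,
        "recovery_corrected": r.recovery_corrected,
        "estimated": r.estimated,
        "below_loq": r.below_loq, "below_mdl": r.below_mdl,
    } for r in results])
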