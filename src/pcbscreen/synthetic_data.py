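"""Synthetic study generator with exact ground truth.

Emulates the data a sex x genotype PCB95 exposure study produces:
centroided negative-mode MS1 peak lists in which each planted metabolite
appears as its full chlorine isotope envelope with Gaussian ppm mass
error and log-normal abundance, targeted MS2 scans carrying the expected
neutral-loss fragments, an internal volume-corrector (PFOS) peak in every
sample, decoy background peaks, GC-MS/MS area tables constructed so that
internal-standard quantification inverts exactly in the noise-free case,
atropisomer area pairs with a configured enantiomeric fraction per group,
and blank backgrounds.  Every dataset ships with its ground truth so the
pipeline can be validated closed-loop, without any real animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import (ElementalFormula, SuspectCandidate, enumerate_suspects,
                        ion_mz, monoisotopic_mass)
from .isotope_patterns import envelope
from .lcms_screening import PeakList, SampleMeta, write_meta, write_peaklists

# PFOS anion (C8F17SO3-) serves as the volume corrector in every sample.
PFOS_ION_FORMULA = ElementalFormula.parse("C8F17O3S")
PFOS_MZ = ion_mz(ElementalFormula.parse("C8HF17O3S"), -1)
PFOS_RT = 6.80

#: the fifteen chromatographic species the default study plants, as
#: (class_id, retention time in min, median base-peak intensity)
DEFAULT_SPECIES: tuple[tuple[str, float, float], ...] = (
    ("1.1", 7.77, 2.0e7),
    ("1.2", 6.51, 4.0e6),
    ("1.2", 6.67, 6.0e6),
    ("2", 5.78, 2.5e6),
    ("2", 6.87, 3.0e6),
    ("2", 7.01, 3.5e6),
    ("3", 7.88, 2.0e6),
    ("3", 8.00, 2.5e6),
    ("4", 6.73, 1.5e6),
    ("5", 5.96, 1.2e6),
    ("6", 7.68, 1.0e6),
    ("7", 6.48, 1.4e6),
    ("7", 7.69, 1.8e6),
    ("7", 7.80, 1.6e6),
    ("8", 7.60, 1.1e6),
)

#: classes whose conjugate/phenol fragments are acquired in PRM mode
DEFAULT_MS2_PROB: dict[str, float] = {
    "1.1": 1.0, "1.2": 1.0, "2": 1.0, "3": 1.0, "4": 1.0,
    "5": 0.0, "6": 0.0, "7": 0.0, "8": 0.0,
}

DEFAULT_GROUPS: tuple[tuple[str, str], ...] = (
    ("M", "WT"), ("M", "KO"), ("M", "KI"),
    ("F", "WT"), ("F", "KO"), ("F", "KI"),
)

#: per-group enantiomeric fraction of the parent compound
DEFAULT_EF: dict[tuple[str, str], float] = {
    ("M", "WT"): 0.42, ("M", "KO"): 0.45, ("M", "KI"): 0.43,
    ("F", "WT"): 0.39, ("F", "KO"): 0.41, ("F", "KI"): 0.40,
}

#: GC panel: planted median concentrations, ng/g wet weight
DEFAULT_GC_MEDIANS: dict[str, float] = {
    "PCB95": 60.0,
    "4,5-95": 1200.0, "Y1-95": 500.0, "4'-95": 350.0, "5-95": 250.0,
    "X1-95": 150.0, "4-95": 100.0, "Y3-95": 60.0, "Y2-95": 20.0,
}

#: neutral formulas of the GC panel (methylated OH-PCBs measured as parents)
GC_FORMULAS: dict[str, str] = {
    "PCB95": "C12H5Cl5",
    "4-95": "C12H5Cl5O", "4'-95": "C12H5Cl5O", "5-95": "C12H5Cl5O",
    "X1-95": "C12H5Cl5O",
    "4,5-95": "C12H5Cl5O2", "Y1-95": "C12H5Cl5O2",
    "Y2-95": "C12H5Cl5O2", "Y3-95": "C12H5Cl5O2",
}

#: true relative response factors of the available standards
DEFAULT_RRF: dict[str, float] = {
    "PCB95": 1.05, "4-95": 0.92, "4'-95": 1.10, "5-95": 0.98, "4,5-95": 0.85,
    "PCB117": 1.00, "4'-159": 1.02,
}

#: MRM transition groups; unknowns are estimated from their group average
TRANSITION_GROUPS: dict[str, str] = {
    "PCB95": "parent", "PCB117": "surr-parent",
    "4-95": "mono-OH", "4'-95": "mono-OH", "5-95": "mono-OH", "4'-159": "surr-oh",
    "4,5-95": "di-OH",
}
UNKNOWN_GROUPS: dict[str, str] = {
    "X1-95": "mono-OH", "Y1-95": "di-OH", "Y2-95": "di-OH", "Y3-95": "di-OH",
}
ANALYTE_SURROGATES: dict[str, str] = {
    "PCB95": "PCB117",
    **{a: "4'-159" for a in GC_FORMULAS if a != "PCB95"},
}
SURROGATE_AMOUNTS: dict[str, float] = {"PCB117": 50.0, "4'-159": 50.0}
IS_AMOUNT_NG = 50.0


@dataclass
class StudyConfig:
    """Design of one synthetic exposure study.

    The defaults mirror the study conditions the pipeline was built for:
    six sex x genotype groups of six animals, fifteen planted metabolite
    species across eight classes with log-normal abundances, ~1.5 ppm
    Gaussian mass error, PRM fragments for the conjugate-bearing classes
    only, and decoy background peaks kept at least 25 ppm away from every
    suspect m/z.
    """

    groups: tuple[tuple[str, str], ...] = DEFAULT_GROUPS
    n_per_group: int = 6
    species: tuple[tuple[str, float, float], ...] = DEFAULT_SPECIES
    presence: Mapping[int, float] = field(default_factory=dict)  # species idx -> fraction
    abundance_gsd: float = 2.0
    group_effects: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {"1.1": {("F", "KO"): 0.4}})
    mass_error_ppm_sd: float = 1.5
    rt_jitter_sd: float = 0.02
    ms2_prob: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MS2_PROB))
    ms2_fragment_fraction: float = 0.3
    n_decoys: int = 150
    decoy_min_sep_ppm: float = 25.0
    decoy_mz_range: tuple[float, float] = (160.0, 600.0)
    decoy_median_intensity: float = 5.0e5
    envelope_min_rel: float = 2.0       # % of base peak rendered per species
    pfos_intensity: float = 1.0e7
    n_lc_blanks: int = 0
    blank_level: float = 0.0            # fraction of median intensity in blanks
    ef_by_group: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EF))
    ef_sd: float = 0.01
    gc_medians: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GC_MEDIANS))
    gc_gsd: float = 1.8
    gc_group_effects: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {"PCB95": {("M", "KO"): 2.0}})
    gc_noise_sd: float = 0.10           # multiplicative SD on analyte/IS area ratio
    recovery_parent: float = 0.85
    recovery_oh: float = 0.80
    blank_conc_level: float = 0.5       # ng/g scale of GC blank background
    n_gc_blanks: int = 3


@dataclass
class SyntheticStudy:
    peaklists: list[PeakList]
    metas: dict[str, SampleMeta]
    truth: pd.DataFrame          # one row per planted species x sample
    suspects: list[SuspectCandidate]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peaklists(self.peaklists, outdir / "peaklists.tsv")
        write_meta(self.metas.values(), outdir / "meta.csv")
        self.truth.to_csv(outdir / "lcms_truth.csv", index=False)


@dataclass
class GcStudy:
    areas: pd.DataFrame          # sample_id, analyte, role, area
    standards: pd.DataFrame
    atropisomers: pd.DataFrame   # sample_id, a_e1, a_e2
    method_blanks: pd.DataFrame  # blank_id, analyte, concentration
    tissue_blanks: pd.DataFrame
    truth: pd.DataFrame          # sample_id, analyte, concentration, recovery, ef
    sample_masses: dict[str, float]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.areas.to_csv(outdir / "areas.csv", index=False)
        self.standards.to_csv(outdir / "standards.csv", index=False)
        self.atropisomers.to_csv(outdir / "atropisomers.csv", index=False)
        self.method_blanks.to_csv(outdir / "method_blanks.csv", index=False)
        self.tissue_blanks.to_csv(outdir / "tissue_blanks.csv", index=False)
        self.truth.to_csv(outdir / "gc_truth.csv", index=False)
        pd.DataFrame(
            [{"sample_id": k, "sample_mass": v} for k, v in self.sample_masses.items()]
        ).to_csv(outdir / "sample_masses.csv", index=False)


def _sample_ids(config: StudyConfig) -> list[tuple[str, str, str]]:
    out = []
    for sex, genotype in config.groups:
        for i in range(1, config.n_per_group + 1):
            out.append((f"{sex}_{genotype}_{i:02d}", sex, genotype))
    return out


def generate_study(config: StudyConfig, seed: int = 0) -> SyntheticStudy:
    """Generate MS1/MS2 peak lists, metadata and ground truth for a study."""
    rng = np.random.default_rng(seed)
    suspects = enumerate_suspects(classes_only=True)
    by_class: dict[str, SuspectCandidate] = {c.class_id: c for c in suspects}
    envs = {cid: envelope(c.ion) for cid, c in by_class.items()}

    # forbidden m/z windows for decoys: every envelope peak of every suspect
    forbidden = [PFOS_MZ]
    for cid, env in envs.items():
        forbidden.extend(env.mz[env.rel_intensity >= 1.0])
    forbidden = np.array(sorted(forbidden))

    peaklists: list[PeakList] = []
    metas: dict[str, SampleMeta] = {}
    truth_rows = []

    samples = _sample_ids(config)
    for b in range(1, config.n_lc_blanks + 1):
        samples.append((f"BLANK_{b:02d}", "NA", "BLANK"))

    for sample_id, sex, genotype in samples:
        is_blank = genotype == "BLANK"
        rows = []  # (rt, mz, intensity)

        pfos_int = config.pfos_intensity * rng.lognormal(0.0, 0.1)
        pfos_rt = PFOS_RT + rng.normal(0.0, config.rt_jitter_sd)
        pfos_err = rng.normal(0.0, config.mass_error_ppm_sd) * 1e-6
        rows.append((pfos_rt, PFOS_MZ * (1 + pfos_err), pfos_int))

        mass_g = float(rng.uniform(0.018, 0.033))
        ms2_lists: list[PeakList] = []

        for idx, (cid, rt0, median) in enumerate(config.species):
            if is_blank:
                present = config.blank_level > 0
                mult = config.blank_level
            else:
                present = bool(rng.random() < config.presence.get(idx, 1.0))
                mult = config.group_effects.get(cid, {}).get((sex, genotype), 1.0)
            base = median * mult * rng.lognormal(0.0, np.log(config.abundance_gsd))
            rt = rt0 + rng.normal(0.0, config.rt_jitter_sd)
            env = envs[cid]
            # the screen reports the monoisotopic-peak apex, not the base peak
            mono_int = base * float(env.rel_intensity[env.offsets == 0][0]) / 100.0
            if present:
                keep = env.rel_intensity >= config.envelope_min_rel
                for mz_t, rel in zip(env.mz[keep], env.rel_intensity[keep]):
                    err = rng.normal(0.0, config.mass_error_ppm_sd) * 1e-6
                    rows.append((rt, mz_t * (1 + err), base * rel / 100.0))
                cand = by_class[cid]
                if cand.expected_losses and rng.random() < config.ms2_prob.get(cid, 0.0):
                    frag_rows = []
                    for label, loss in cand.expected_losses:
                        err = rng.normal(0.0, config.mass_error_ppm_sd) * 1e-6
                        frag_rows.append((rt, (cand.theoretical_mz - loss) * (1 + err),
                                          base * config.ms2_fragment_fraction))
                    err = rng.normal(0.0, config.mass_error_ppm_sd) * 1e-6
                    frag_rows.append((rt, cand.theoretical_mz * (1 + err), base * 0.5))
                    ms2_lists.append(PeakList(
                        sample_id=sample_id, level="MS2",
                        precursor_mz=cand.theoretical_mz,
                        peaks=pd.DataFrame(frag_rows,
                                           columns=["rt_min", "mz", "intensity"]),
                    ))
            truth_rows.append({
                "sample_id": sample_id, "species": idx, "class_id": cid,
                "rt": rt, "present": present,
                "intensity": base if present else 0.0,
                "mono_intensity": mono_int if present else 0.0,
                "relative_abundance": (mono_int / (pfos_int * mass_g))
                                      if present else 0.0,
            })

        # decoy background, rejected within +/- decoy_min_sep_ppm of suspects
        n_placed = 0
        while n_placed < config.n_decoys:
            mz = rng.uniform(*config.decoy_mz_range)
            sep = np.min(np.abs(forbidden - mz) / mz) * 1e6
            if sep < config.decoy_min_sep_ppm:
                continue
            rt = rng.uniform(0.5, 10.0)
            inten = config.decoy_median_intensity * rng.lognormal(0.0, 1.0)
            rows.append((rt, mz, inten))
            n_placed += 1

        peaklists.append(PeakList(
            sample_id=sample_id, level="MS1",
            peaks=pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]),
        ))
        peaklists.extend(ms2_lists)
        metas[sample_id] = SampleMeta(
            sample_id=sample_id, sex=sex, genotype=genotype,
            sample_mass=mass_g, pfos_intensity=pfos_int, pfos_rt=pfos_rt,
            is_blank=is_blank,
        )

    return SyntheticStudy(
        peaklists=peaklists, metas=metas,
        truth=pd.DataFrame(truth_rows), suspects=suspects,
    )


def generate_gc_tables(config: StudyConfig, seed: int = 0) -> GcStudy:
    """Generate GC area tables that invert exactly under quantification.

    Analyte areas are constructed from planted concentrations by the same
    internal-standard relation the quantifier applies, so a noise-free run
    round-trips to the planted values; the configured noise enters as a
    zero-mean Gaussian multiplicative factor on the analyte/IS area ratio.
    Unknown analytes are rendered with the group-average RRF the estimator
    will use for them.
    """
    rng = np.random.default_rng(seed)
    rrf_unknown = {
        name: float(np.mean([DEFAULT_RRF[a] for a, g in TRANSITION_GROUPS.items()
                             if g == group and a in DEFAULT_RRF and a not in
                             SURROGATE_AMOUNTS]))
        for name, group in UNKNOWN_GROUPS.items()
    }
    area_rows, truth_rows, atrop_rows = [], [], []
    sample_masses: dict[str, float] = {}

    for sample_id, sex, genotype in _sample_ids(config):
        mass_g = float(rng.uniform(0.018, 0.033))
        sample_masses[sample_id] = mass_g
        is_area = 1.2e6 * rng.lognormal(0.0, 0.05)
        area_rows.append({"sample_id": sample_id, "analyte": "IS",
                          "role": "internal_standard", "area": is_area})
        rec = {"PCB117": config.recovery_parent + rng.normal(0.0, 0.02),
               "4'-159": config.recovery_oh + rng.normal(0.0, 0.02)}
        for surr, recovery in rec.items():
            area = (recovery * SURROGATE_AMOUNTS[surr] / IS_AMOUNT_NG
                    * DEFAULT_RRF[surr] * is_area)
            area_rows.append({"sample_id": sample_id, "analyte": surr,
                              "role": "surrogate", "area": area})
        ef_true = float(np.clip(
            config.ef_by_group.get((sex, genotype), 0.5) + rng.normal(0.0, config.ef_sd),
            0.0, 1.0))
        total_area = 1.0e5 * rng.lognormal(0.0, 0.3)
        atrop_rows.append({"sample_id": sample_id,
                           "a_e1": ef_true * total_area,
                           "a_e2": (1 - ef_true) * total_area})
        for analyte, median in config.gc_medians.items():
            mult = config.gc_group_effects.get(analyte, {}).get((sex, genotype), 1.0)
            conc = median * mult * rng.lognormal(0.0, np.log(config.gc_gsd))
            rrf = DEFAULT_RRF.get(analyte, rrf_unknown.get(analyte))
            recovery = rec[ANALYTE_SURROGATES[analyte]]
            area = conc * recovery * mass_g * rrf * is_area / IS_AMOUNT_NG
            if config.gc_noise_sd > 0:
                area *= 1.0 + rng.normal(0.0, config.gc_noise_sd)
            area_rows.append({"sample_id": sample_id, "analyte": analyte,
                              "role": "analyte", "area": max(area, 0.0)})
            truth_rows.append({"sample_id": sample_id, "analyte": analyte,
                               "concentration": conc, "recovery": recovery,
                               "ef": ef_true})

    standards = pd.DataFrame([{
        "analyte": a, "area": DEFAULT_RRF[a] * 1.0e6, "amount": 50.0,
        "is_area": 1.0e6, "is_amount": 50.0,
        "transition_group": TRANSITION_GROUPS.get(a),
    } for a in sorted(DEFAULT_RRF)])

    def _blanks(n: int, scale: float) -> pd.DataFrame:
        rows = []
        for b in range(1, n + 1):
            for analyte in config.gc_medians:
                rows.append({"blank_id": f"B{b:02d}", "analyte": analyte,
                             "concentration": abs(rng.normal(scale, scale / 2))})
        return pd.DataFrame(rows)

    return GcStudy(
        areas=pd.DataFrame(area_rows),
        standards=standards,
        atropisomers=pd.DataFrame(atrop_rows),
        method_blanks=_blanks(config.n_gc_blanks, config.blank_conc_level),
        tissue_blanks=_blanks(config.n_gc_blanks, 2 * config.blank_conc_level),
        truth=pd.DataFrame(truth_rows),
        sample_masses=sample_masses,
    )
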