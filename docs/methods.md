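# Methods

This note documents the models and procedures `pcbscreen` implements,
the defaults it ships with, and what its synthetic-data validation does
and does not demonstrate.

## Masses and ions

Monoisotopic masses are sums of pinned principal-isotope masses
(¹²C = 12 exactly, ¹H = 1.00782503, ¹⁶O = 15.99491462,
³⁵Cl = 34.96885268, ³²S = 31.97207117, ¹⁹F = 18.99840316 Da), with the
electron mass mₑ = 0.00054858 Da. A deprotonated anion keeps the extra
electron, so m([M−H]⁻) = m(M) − m(¹H) + mₑ. Dropping the electron term
shifts every singly charged anion by ≈ −0.55 mDa — more than the 5-ppm
matching window at m/z 100 and enough to break agreement with published
5-decimal reference masses, which is why a guard test pins it. The
atomic-mass convention itself was chosen because it reproduces those
reference values exactly; sources that tabulate masses to fewer digits
drift in the fifth decimal place.

Mass errors are reported as signed parts-per-million relative to the
theoretical m/z.

## Biotransformation rule engine

A suspect candidate is an elemental formula plus a metabolite-class
label; positional isomers are deliberately indistinguishable because
accurate mass cannot separate them (close-eluting isomers of one class
share one candidate). Rules are element-count deltas with provenance
constraints:

| rule | delta | constraint | cap |
| --- | --- | --- | --- |
| OX (P450 hydroxylation) | +O | ≥1 H present | 3 |
| SULF-O (phenol sulfation) | +SO₃ | ≥1 free hydroxyl from OX | 1 |
| SULFON-C (ring sulfonation) | +SO₃ | parent only | 1 |
| METH (catechol O-methylation) | +CH₂ | ≥2 prior OX | 1 |
| DECHLOR (reductive dechlorination) | −Cl +H | ≥1 Cl | 2 |

Formulas alone cannot see whether two hydroxyls are vicinal, so the
catechol requirement of METH is encoded through provenance (two prior
hydroxylations), reflecting that O-methylation is a COMT reaction on
catechols. SULF-O, SULFON-C and METH are mutually exclusive within one
chain (one conjugation per chain); this keeps the closure at the class
set actually observed for pentachlorobiphenyl metabolism without
combinatorial blow-up, and the caps (OX ≤ 3, DECHLOR ≤ 2) are
configurable. Enumeration is a breadth-first closure over (formula,
applied-rule multiset) states to depth 4, deduplicated by (formula,
class), so rule ordering cannot affect the output. Ring sulfonation is
restricted to the untransformed parent because the mercapturic-acid
route that produces sulfonates starts from the parent compound;
hydroxylated sulfonates still appear as unclassed suspects (OX after
SULFON-C). Because an unclassed suspect can share a composition with a
classed one (e.g. OX+SULFON-C vs the O-sulfate class), the screening
default uses the classed list only (`classes_only=True`); screening the
full closure flags such pairs as ambiguous rather than resolving them.

## Isotope envelopes

Per-element isotope distributions are exact multinomial expansions
(computed by repeated convolution with exact mass merging at 1e-6 Da);
element distributions are convolved into the molecular distribution with
pruning below 1e-6 abundance (renormalized, so the operation stays
commutative/associative to the pruning tolerance). Abundances are IUPAC
2021 representative values stored as data (³⁵Cl/³⁷Cl = 0.7576/0.2424,
¹²C/¹³C = 0.9893/0.0107, …).

Envelopes are aggregated into unit-Da nominal bins relative to the
monoisotopic peak — screening compares M/M+2/M+4/M+6 ratios, not fine
structure — each bin carrying its abundance-weighted exact m/z and an
intensity scaled to base peak 100. For the C₁₂H₄Cl₅O⁻ anion the
full-molecule pattern is 62.1 : 100 : 64.6 : 21.0; a Cl₅-only binomial
gives 62.5 : 100 : 64.0 : 20.5, so at integer precision the two
conventions are indistinguishable at M (62) and differ by at most one
unit at M+4. The package always computes the full-molecule pattern.

Observed clusters are scored by the cosine between the matched
intensity vector (observed peaks within the ppm tolerance of each bin's
exact m/z; missing peaks contribute zero) and the theoretical one,
over the four most intense bins by default. The confirmation threshold
of 0.95 is a configuration default validated on synthetic data: planted
full envelopes score ≥ 0.99 while a bare monoisotopic peak against a
Cl₅ pattern scores ≈ 0.46. A cluster with no peak at the monoisotopic
position scores 0 regardless.

## Semitargeted screen

Per sample, MS1 peaks within 5 ppm of a candidate's theoretical m/z are
grouped into retention-time-contiguous features (maximum gap 0.2 min, a
configurable stand-in for the vendor peak detection the original
workflow used); the feature apex becomes a detection record. Isotope
confirmation uses the MS1 peaks within ±0.05 min of the apex. Fragment
confirmation searches MS2 scans whose precursor matches the candidate
for peaks at (precursor − loss) within tolerance; any confirmed loss
sets confidence level 2, otherwise 3 — fragment evidence upgrades
confidence but is never required for detection, since several classes
are detectable by formula + isotope pattern only. Neutral-loss
assignments follow the class chemistry: methoxylated candidates lose
CH₃•, O-sulfates lose SO₃, other chlorinated phenols lose HCl, ring
sulfonates have no facile loss. Loss masses are computed from the same
atomic-mass table as the precursor masses.

A candidate is retained when detected in strictly more than 50 % of the
(non-blank) samples, with detection counted after isotope confirmation
(exposed as configuration; the alternative—before confirmation—is a
defensible reading). Relative abundance is
intensity / (PFOS intensity × sample mass); blank-sample levels above
10 % of the study median flag the candidate.

## Quantification

conc (ng/g) = (A_analyte/A_IS) / RRF × m_IS / mass_wet / recovery, with
RRF = (A/A_IS)/(m/m_IS) from a standard mixture. Surrogate recoveries
are computed in-table from the surrogate rows and their spiked amounts;
recoveries outside (0, 1.5] raise. Analytes without standards use the
mean RRF of the authentic standards in their MRM transition group
(mono-hydroxylated unknowns: the three mono-OH standards; di-hydroxylated
unknowns: the single di-OH standard); surrogates carry separate group
labels so they never enter these averages. MDL = mean + 3 SD of method
blanks and LOQ = mean + 10 SD of tissue blanks are standard-practice
formulas (the workflow being modeled states only that limits were
blank-based). Below-LOQ results are flagged, never censored; statistics
callers decide on substitution (LOQ/2 by default in the pipeline
configuration, with zero and LOQ/√2 as alternatives). Molar summaries
normalize parent and summed-OH concentrations by formula masses and
report molar percentages (summing to 100 exactly) plus the ΣOH/parent
molar fold ratio.

## Chirality

EF = A_E1/(A_E1 + A_E2) over the two atropisomer peak areas; EF and its
complement under peak swap sum to 1, and EF is invariant to area
rescaling. The racemic QC band is the racemic standard's EF 0.498 ± 3 SD
(SD = 0.004); three SDs is the package's choice of acceptance band, as
the underlying QC value is reported without one. The elution-order →
configuration assignment (second-eluting = aS) is carried as metadata
only. Peak integration itself is out of scope; a perpendicular-drop
helper integrates synthetic two-Gaussian chromatograms for fixtures.

## Statistics

cos θ = p·q/(‖p‖‖q‖) over non-negative profile vectors on a shared
panel; computed on group-mean profiles by default. Two-way sex ×
genotype ANOVA uses Type-II sums of squares (group sizes of 5–7 make
designs mildly unbalanced; the original software default is not
documented, and Type II is the conventional choice for unbalanced
factorials without interaction-driven hypotheses). Pairwise cell
comparisons are pooled-variance t-tests with p-values multiplied by the
number of comparisons and capped at 1; significance at p < 0.05.
Incomplete factor crossings and cells with fewer than two samples are
rejected with the offending cell named. Responses are analyzed
untransformed by default with a log10 option (concentration data span
orders of magnitude; which the original analysis used is not stated).
A vectorized null simulation (`pairwise_bonferroni_null_rate`) verifies
that the family-wise type-I error stays at or below 5 %.

## Synthetic studies

The generator's defaults are the study conditions: six sex × genotype
groups (M/F × WT/KO/KI) of six samples; fifteen planted species across
the eight metabolite classes at the reference retention times; base-peak
intensities log-normal with geometric SD 2 around class medians, with
multiplicative group effects (default: the phenol class reduced to 0.4×
in F/KO); Gaussian m/z error of 1.5 ppm SD per peak (consistent with
sub-5-ppm observed errors); rt jitter 0.02 min SD; PRM fragment emission
probability 1 for the conjugate/methyl classes and 0 for classes with no
facile loss; 150 decoy peaks per sample placed at least 25 ppm from
every suspect envelope peak; a PFOS volume-corrector peak in every
sample; sample wet masses uniform on 18–33 mg. Ground truth (presence,
intensities, normalized abundances, concentrations, recoveries, EF) is
emitted with every dataset.

GC area tables are built by inverting the quantification relation, so a
noise-free run recovers planted concentrations to machine precision.
Measurement noise is a zero-mean Gaussian multiplicative factor (default
SD 0.10) applied to the analyte/IS area *ratio*: the internal standard
is the reference against which the analyte is read, so ratio noise is
the operative error model, and it keeps recovered concentrations exactly
unbiased in expectation. EF per group defaults to 0.39–0.45 (the range
such in vivo studies report), with 0.01 SD per sample.

What passing the closed loop shows: the pipeline's matching,
confirmation, filtering and quantification logic is correct against
known truth at realistic error magnitudes. What it does not show:
robustness to chromatographic peak shape, rt drift across samples,
ion suppression/matrix effects, centroiding artifacts, or isobaric
interferences beyond the planted decoys — none of which the generator
models. Close-eluting isomers of one class (0.11–0.16 min apart) can
merge into one feature under the 0.2 min gap, as they do on a real
column; detection is therefore asserted per candidate ion per sample,
not per isomer.

## Problem sizes

Defaults keep everything desk-scale: the full synthetic study is 36
samples × ~15 species (≈ 360 peak lists, a few seconds to generate and
screen); quantification-bias checks use 1000 replicate single-group
studies; the ANOVA null calibration uses 10,000 vectorized replicates.

## Known limitations

- Only [M−H]⁻ is modeled; the ion-m/z contract accepts other charges
  but the pipeline fixes −1 (negative-mode study).
- No structure handling (SMILES), no positional-isomer prediction, no
  glucuronide/arene-oxide/dihydrodiol/methyl-sulfone mass generation —
  those classes exist in the rule graph only as not-detected context.
- Peak lists are centroided; no profile-mode or resolution-dependent
  peak-shape modeling.
- No cross-sample rt alignment; the screen treats each sample
  independently.
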