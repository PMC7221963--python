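# Methods

This note records the models, conventions and design choices behind
`teaphenol`, in the spirit of a statistical-software methods appendix. It
describes what the code computes and why; every number quoted here is either
a documented constant or something the test suite computes itself.

## Exact-mass arithmetic

All calculated quantities derive from pinned 7-decimal monoisotopic atomic
masses (`data/atomic_masses.tsv`; C 12 exactly, H 1.0078250, N 14.0030740,
O 15.9949146 Da) so results are bit-stable across platforms.

* **[M−H]⁻** is the neutral monoisotopic mass minus the proton mass
  1.007276 Da. The electron mass (~0.00055 Da) is neglected: at *m/z* 300–1050
  it shifts the fourth decimal by less than the rounding step, and this
  convention reproduces 4-decimal reference values for negative-mode QqTOF
  data. The constant is exposed (`PROTON_MASS`) for users who need the
  electron-corrected convention.
* **[M−2H]•⁻** (radical anion) is one hydrogen atom (1.0078250 Da) lighter
  than [M−H]⁻.
* **RDB** (ring-plus-double-bond equivalents) is C − H/2 + N/2 + 1, with
  halogens counted like hydrogen.
* **ppm error** is signed as (found − calc)/calc × 10⁶. Published tables are
  not always internally consistent in sign; this package fixes the convention
  and treats deviations in reference data as errata.
* Report-style rounding is **half-up**: 4 decimals for *m/z*, 1 for ppm —
  matching the formatting of analytical tables (banker's rounding would
  disagree on exact ties).

## Neutral-loss rule engine and compound classes

Fragment evidence is collected in three passes, then combined by a cascade.

**Losses.** Every ordered ion pair (precursor→fragment and heavier→lighter
fragment) is matched against a named loss table whose exact masses are
derived from elemental formulas: glycosyl residues (hexose C₆H₁₀O₅ 162.0528,
deoxyhexose 146.0579, pentose 132.0423), acyl residues (galloyl C₇H₄O₄
152.0110, coumaroyl C₉H₆O₂ 146.0368, coumaric acid 164.0473, gallic acid
170.0215, methylgalloyl 166.0266), small molecules (H₂O, CO₂, ethenone,
formaldehyde, formic acid) and ring-fission losses (flavanol A-ring C₆H₆O₃
126.0317; sugar cross-ring C₂H₄O₂ 60.0211, C₃H₆O₃ 90.0317, C₄H₈O₄ 120.0423).
The default fragment tolerance is ±0.02 Da — measured QqTOF fragment values
deviate from exact residue masses by up to ~15 mDa at low mass — and the
default precursor tolerance for library matching is ±10 ppm; both are
configurable. Fragments below 1% of the base peak are ignored (floor
configurable).

**Diagnostic ions.** Flavanol A-ring *m/z* 125.0244 (heterocyclic ring
fission), the retro-Diels–Alder pair 137.0244/151.0401, catechol B-ring
109.0295, gallate 169.0142, quinate 191.0561, the methylgallate-derived
radical 168.0070, and [A−H]⁻/[A−2H]•⁻ pairs for quercetin
(301.0354/300.0276), kaempferol (285.0405/284.0327), myricetin
(317.0303/316.0225), methylkaempferol (299.0561/298.0483) and apigenin
(269.0455, even-electron only). All but the empirical 168.0070 landmark are
computed from formulas at import time.

**Aglycone identification and position evidence.** Candidates with both ions
of a pair present beat single-ion matches; remaining ties go to summed
intensity (this disambiguates, e.g., a kaempferol pair from a stray ion near
the quercetin radical mass). Strict radical dominance
([A−2H]•⁻ intensity > [A−H]⁻) is reported as 3-*O* glycosylation evidence —
homolytic cleavage of the 3-*O*-glycosidic bond favors the stabilized radical
aglycone — while equality or an even-electron-only match is *indeterminate*.
CH₂O and CH₂O₂ sub-losses from the even-electron aglycone raise a reported
confidence value but never change the call.

**C-glycosides.** At least two distinct cross-ring losses (60/90/120 Da) from
the precursor are required — a single −120 loss also occurs in O-glycoside
spectra — and any whole glycosyl-residue loss terminating at a free aglycone
ion vetoes the call, making C- and O-glycoside calls mutually exclusive on
the same evidence.

**Classification cascade**, first match wins:

1. *amino acid* — requires the optional precursor formula (N-containing,
   RDB < 4); a fragment list alone cannot identify theanine.
2. *phenolic acid/quinate ester* — precursor at the quinate or gallate ion
   mass, or a quinate fragment released by an ester **with precursor
   < 400 Da** (large glycosides can show near-isobaric fragments around
   *m/z* 191).
3. *flavan-3-ol family* — A-ring 125.02 ion, or the full RDA pair. Within the
   family: *proanthocyanidin dimer* if a genuine flavan-3-ol monomer ion
   (afzelechin/catechin/gallocatechin [M−H]⁻) appears whose complement to the
   precursor is a monomer unit (288.0634/304.0583 Da) **and** an A-ring HRF
   loss from the precursor is present; *galloylated* if a
   galloyl/gallic-acid/methylgalloyl loss strips to an intact core (product
   ≥ 200 Da — gallocatechins have low-mass fragments isobaric with a
   methylgalloyl loss) or the gallate/methylgallate-radical ion is present;
   otherwise plain *flavan-3-ol*.
4. *flavone C-glycoside* — per the cross-ring rule.
5. *acylated flavonol glycoside* — the coumaric-acid/coumaroyl loss pair from
   the precursor (acid and acid−H₂O losses together also flag acylation on
   the aglycone-bound sugar, recorded as evidence only), or a lone acyl loss
   whose product minus the detected aglycone decomposes into 1–4 glycosyl
   residues (guards against spurious single-loss matches).
6. *flavonol O-glycoside* — detected aglycone plus either a glycosyl loss or
   a precursor-minus-aglycone residual decomposing into 1–4 glycosyl
   residues (rutinoside-type sugars are often lost en bloc, so no single
   residue loss may be visible).
7. *saccharide* — glycosyl or cross-ring losses with no aromatic diagnostic
   evidence.
8. *unclassified* otherwise.

The **loss chain** reported with each annotation is found by depth-first
search from the precursor (depth ≤ 5, each peak consumed once,
larger-mass rules preferred at ties); among maximal chains the one
terminating at a recognized diagnostic/aglycone ion wins, then the one
explaining the most intensity. The **score** is the fraction of
(floor-filtered) fragment intensity explained by the chain, diagnostic hits
and aglycone ions; annotation is invariant under intensity rescaling.

Retention time is used only as a library-matching tie-breaker (±0.5 min
window) among candidates with equal rounded ppm error — several library pairs
share an elemental formula — never in class logic. Geometric-isomer
discrimination (e.g. catechin vs epicatechin) is retention-based in practice
and out of scope beyond library rt matching.

## Assay metrics

* **Percent inhibition**: (1 − signal/blank) × 100.
* **ID50** (default `interp`): responses are projected onto a non-decreasing
  sequence (isotonic regression) if ordering violations are ≤ 5% of the
  response range — larger violations are a data error, preventing spurious
  multiple crossings. The response is then treated as locally linear in
  log₁₀(dose): when ≥ 3 doses fall in the quasi-linear 20–80% band an OLS
  line through them is solved at 50% (pooling noise across doses, which
  matters for shallow Hill slopes); otherwise the bracketing pair is
  interpolated. If 50% is never crossed the estimate is extrapolated and
  flagged `bracketed=False`. A four-parameter logistic fit (`4pl`) is the
  alternative method tag; interpolation is the default because the assay dose
  grids are sparse (five points over ~16-fold).
* **TEAC** is the potency ratio ID50(Trolox)/ID50(sample); ratios are
  transitive by construction, and ID50 × TEAC is constant (= the Trolox ID50)
  across samples within an assay.
* **ORAC**: curves are normalized by multiplying by blank f(0)/sample f(0);
  AUC = Σᵢ fᵢ/f₀ over all readings **including t = 0** (the sum over readings
  includes the defining first one, contributing exactly 1 — so a flat
  nine-reading curve has AUC 9 and instant quenching gives 1); net AUC =
  AUC(sample) − AUC(blank); Trolox equivalents are the ratio of OLS
  (with-intercept) slopes of net AUC against concentration. Whether a
  laboratory reports slope-based TE or a single-concentration net-AUC ratio
  varies; both are expressible, the slope ratio being the implemented
  default.
* Replicates are averaged before ID50 estimation; replicate SDs are carried
  through for reporting only.

## RACI and clustering

Standard scores use the **sample SD (n − 1)** — the convention under which a
scored column of n = 6 samples has SD exactly 1. Each metric column is
z-scored, lower-is-better columns (ID50s) are negated so that "more
antioxidant" is always positive, and RACI is the per-sample mean of oriented
z-scores. Consequences: every z column has mean 0 and SD 1, RACI sums to 0
across samples, |RACI| ≤ (n−1)/√n (≈ 2.04 for n = 6), and RACI is invariant
under affine rescaling of any metric. Reported RACI magnitudes in the
literature sometimes exceed this bound and then cannot arise from mean
z-scores; this package treats the sample *ordering*, not the magnitudes, as
the reproducible quantity.

Clustering uses Pearson correlation distance D = 1 − r (range [0, 2]) and
unweighted average linkage (UPGMA), computed on the row-scaled matrix for
heatmaps. The implementation maintains inter-cluster means by the
Lance–Williams size-weighted update; ties are broken by the smallest node
index, so results are deterministic. The test suite checks it against an
exhaustive oracle that recomputes every inter-cluster mean from the raw leaf
matrix at each step, and against an independent hierarchical-clustering
library. Dendrograms serialize to newick with branch lengths equal to
merge-height differences.

## Synthetic data: what it emulates, and what it does not

All generators hang off a single master seed; per-operation substreams are
derived by stably hashing the operation name and entry id, so outputs are
bit-reproducible and adding generators never reshuffles existing ones.
Zero-noise settings reduce every generator to an exact identity with
library/closed-form values.

* **Spectra**: precursor = formula [M−H]⁻ with Gaussian ppm error (default
  SD 5 ppm), fragments = library fragments with Gaussian mDa error (default
  SD 10 mDa), intensities log-uniform on [0.05, 1] of the base peak
  (published spectra report relative abundances only sporadically). Where a
  library row contains an aglycone even/radical pair the radical ion is
  forced to be the base peak, reproducing the reported 3-*O*-glycoside
  signature. Five decoy peaks (default) at uniform m/z with intensity up to
  30% of base emulate chimeric/background ions. Not emulated: isotope
  envelopes, chromatographic peak shapes, instrument drift, in-source
  fragmentation — so annotation-recovery results bound performance on clean,
  centroided, deisotoped peak lists, not raw data.
* **Dose–response**: Hill curves R(d) = 100·dʰ/(dʰ + ID50ʰ) on the
  0.78–12.5 µg/mL grid; noise (default SD 2 percentage points) is drawn per
  replicate and averaged over the triplicate design used in such assays
  (n_replicates = 3 default), with replicate SDs retained.
* **ORAC**: logistic decay in time, normalized to f(0); an antioxidant shifts
  the midpoint by `orac_midpoint_shift` × TE × concentration. Parameters were
  fixed once at steepness 0.2 min⁻¹, blank midpoint 25 min and shift
  2.5 min per TE·concentration unit: this yields a realistic lag phase
  (f(0) ≈ f₀) and keeps net AUC linear in the midpoint over the working
  range, so the slope-ratio TE definition is self-consistent (zero-noise
  recovery bias ≤ 0.4% across TE 0.5–6). Only the qualitative delayed-decay
  behavior is matched; real kinetic shapes are not fitted. The Trolox
  concentration grid is configurable (default 1–8 µM style grids in the
  recovery tests) since published protocols vary.
* **Panels**: four metric columns (three lower-better ID50s, one
  higher-better ORAC) with geometric quality spacing along a planted
  ranking, plus optional log-normal jitter.

## Numerical choices and degenerate inputs

Constant vectors are errors for z-scoring and correlation (undefined scale);
zero/negative blanks, non-positive ID50s and non-positive Trolox slopes are
errors; empty spectra cannot be classified; unmatched spectra are retained
with class-only annotation (warning, not error); malformed MGF/CSV records
are skipped with logged warnings, but zero parsable spectra is an error.
Seeds are masked to 31 bits before use.

## Known limitations

* The rule engine is a curated-evidence classifier, not a combinatorial
  in-silico fragmenter; compounds outside the covered classes fall to
  *unclassified*.
* Stereochemistry (catechin/epicatechin, gallocatechin isomers) is not
  distinguishable from fragments; only retention matching separates them.
* ID50 values outside the dose grid are extrapolations and flagged as such.
* TEAC assumes the Trolox and sample ID50s share units and conditions; no
  inter-assay harmonization is attempted.
* The acylation-position flag (acid / acid−H₂O loss co-occurrence) is
  recorded as evidence, not as a structure assignment.
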