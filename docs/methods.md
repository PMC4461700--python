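# Methods

## Assay model and estimator

The screen quantifies methylation at imprinted DMRs from a
methylation-sensitive restriction digest followed by semiquantitative
multiplex PCR. The package models the chain explicitly:

1. **Template.** At a DMR with parental copy numbers (CN_mat, CN_pat) and
   methylated fractions (m_mat, m_pat) of each parental allele, the
   amplifiable template is `CN_mat + CN_pat` in the undigested aliquot and
   `CN_mat·m_mat + CN_pat·m_pat` in the digested aliquot (only methylated
   HpaII sites resist digestion). With incomplete digestion a fraction
   `1 − dc` of the unmethylated copies survives as well. Reference amplicons
   contain no HpaII site and amplify from template 2 in both aliquots; this
   is the structural assumption that makes the statistic meaningful, because
   the digested aliquot keeps a full-strength normalization basis.
2. **Peak areas.** `area = efficiency(amplicon) × template × loading(sample)
   × LogNormal(0, σ)`. Noise is multiplicative lognormal per peak because
   capillary peak areas are positive and scale-proportional; σ defaults to
   0.05 for simulated cohorts (the real assay's noise magnitude is not
   published; the value is exposed in configuration). σ = 0 is exactly
   deterministic.
3. **Relative areas.** Each peak area is divided by a per-sample,
   per-condition denominator. Two modes exist: `ALL_PEAKS` (sum of all
   assigned peak areas — the historical spreadsheet convention) and
   `REFERENCE_ONLY` (sum of reference-amplicon areas). Efficiency and loading
   cancel in both.
4. **Normalization.** Relative areas are divided by the arithmetic mean
   relative areas of a designated control cohort (per condition, per
   amplicon). Controls are always designated explicitly — inferring controls
   from "looking normal" would bias the baseline. A leave-one-out QC pass
   reports controls that fall outside the normal range against the remaining
   controls; they are reported, never auto-excluded.
5. **Per-locus values.** M = normalized digested value, D = normalized
   undigested value, plus M_per_copy = M/D (0, flagged, when D = 0 so that
   complete deletions stay reportable) and the percent loss/gain
   `100·(1 − M)` / `100·(M − 1)`.

`REFERENCE_ONLY` is the quantification default: with it, M is exactly linear
in methylated-copy number, so a mosaic loss of methylation in a fraction c of
cells is recovered as M = 1 − c and a copy-number state as
D = (CN_mat + CN_pat)/2 — the estimator reproduces the published mosaic-loss
percentages (80%, 40%) exactly on noise-free input, which the test suite
asserts at machine precision over a grid of c and CN values. `ALL_PEAKS` is
retained for fidelity and comparison; its denominator shrinks when DMR peaks
shrink, so under LOM it biases M upward (M_ALL ≥ M_REF, tested).

## Classification

Control-normalized values within **1 ± 0.2 inclusive** are normal; both M and
D are classed against the same range. Methylation classes: GOM above 1.2,
partial LOM below 0.8, complete LOM at or below 0.1 (the partial/complete
line is drawn verbally in the clinical literature; 0.1 is this package's
numeric choice, configurable). Mechanism hypotheses per (M, D) combination,
using the panel's parent-of-origin map:

| M class | D class | hypotheses (ordered) |
|---|---|---|
| LOM | normal | epimutation; UPD of the unmethylated parent (order reversed for complete LOM, where whole-tissue UPD is the likelier prior) |
| GOM | normal | UPD of the methylated parent; epimutation (gain) |
| GOM | gain | duplication of the methylated allele |
| LOM or normal | gain | duplication of the unmethylated allele |
| any | loss | deletion |

Ordering is presentation only; hypotheses are never suppressed. Any abnormal
class triggers a confirmation recommendation (MS-MLPA with the
locus-appropriate SALSA kit where established, plus microsatellite
segregation of the parental trio).

The sample-level POSITIVE flag and the multilocus-defect candidate flag
(≥ 2 abnormal loci) are driven by the **methylation** class only: the
published decision rule applies the 0.8–1.2 range to methylation values, and
multilocus defects are defined as methylation defects. Dosage classes are
always computed and reported, drive the mechanism table above, and trigger
recommendations, so no finding is dropped by this choice.

The screen is evaluated blind: classification runs without trio data, and UPD
verdicts are reconciled afterwards, modifying only the mechanism list and
confirmation status — a biparental verdict removes UPD hypotheses (promoting
epimutation by exclusion), a matching UPD verdict confirms one.

## Trio UPD calling

Markers are classified by explanation enumeration rather than
parental-heterozygosity shortcuts: for the child's genotype the caller
enumerates biparental transmissions and maternal/paternal iso- and
heterodisomy, and a marker is decisive only when exactly one family of
explanations survives (both kinds coexisting ⇒ uninformative; none ⇒
Mendelian error). The implementation is verified against a brute-force
enumeration oracle over every trio with alleles in {1..4}. A chromosome-level
UPD verdict needs ≥ 3 concordant single-parent-only markers (configurable;
standard confirmation practice) and not one opposite-parent marker; any
Mendelian error beyond the tolerance (default 0) makes the trio INCONSISTENT
so deviations surface loudly. Triallelic children (e.g. two maternal alleles
plus one paternal — the combined UPD + in-situ duplication pattern) are
duplication evidence, reported per marker and never counted as UPD support.

**Power note.** With k equifrequent alleles, a marker is informative for
heterodisomy exactly when the other parent shares no allele with the child,
probability 21/64 ≈ 0.33 at k = 4. The aggregate verdict therefore has
limited power at small marker counts: P(≥ 3 informative of 8 markers) ≈ 0.52,
and ≥ 99% recovery needs roughly 24 such markers (or markers with ≥ ~10
alleles, or pre-selected informative markers, which is what diagnostic
practice does). The caller never trades this for sensitivity: simulated
heterodisomy trios are either called correctly or INCONCLUSIVE, never given
to the wrong parent (tested over replicated simulations). The test suite
pins the 8-marker rate to the closed-form binomial value.

## Synthetic cohorts

`screening_cohort()` reproduces the study design: 412 patients and 20
controls, the first five patients carrying the published alteration
archetypes — 80% mosaic LOM at *KCNQ1OT1*; paternal 11p15 duplication
(CN_pat = 2 at both *H19* and *KCNQ1OT1*, giving H19 M = 2, D = 1.5 and
KCNQ1OT1 M = 1, D = 1.5); 40% mosaic LOM at *SNRPN*; UPD(14)pat at *MEG3*
(M = 2, D = 1); UPD(14)mat at *MEG3* via copy swap (M = 0, D = 1). Loading
factors (lognormal σ = 0.3) and amplicon efficiencies (lognormal σ = 0.5)
are drawn once per cohort to exercise the scale invariances. All randomness
derives from the cohort seed; identical specifications produce byte-identical
files.

What the generator does **not** emulate: PCR saturation and inter-amplicon
competition, dye pull-up and stutter peaks, allele-size binning, population
allele-frequency spectra (trio alleles are equifrequent), per-site digestion
variability (incomplete digestion is one global fraction), and real
inter-individual baseline variation beyond lognormal peak noise. Passing
tests therefore demonstrate correctness of the estimator and decision logic
under the stated noise model, not the assay's real-world analytical validity,
which requires control material.

**A statistical caveat on the "exactly five positives" cohort scenario:**
with per-peak σ = 0.05, the log of a patient's M value has SD ≈ 0.057 (DMR
peak noise, reference-sum noise, baseline-mean noise), putting the 1.2
boundary ≈ 3.2 SD away; across 407 normal patients × 4 loci about 1–2
false-positive samples are expected on average, so at this noise level a
407-normal screen only comes back perfectly clean for a minority of random
seeds. The shipped scenario is run at a fixed seed where it does; the
per-sample false-positive rate itself (< 5%, in fact ≈ 0.5%) is asserted
separately over 500 simulated normals.

## Numerical and design choices

- Default panel: 4 DMR + 4 reference amplicons, nominal sizes 102–214 bp at
  16 bp spacing with ±2 bp assignment windows. A balanced test/reference
  multiplex is standard for semiquantitative dosage PCR; the sizes are
  placeholders for a real primer design.
- Peak → amplicon assignment uses symmetric size windows; a peak inside two
  windows is an error (never nearest-wins), because silent misassignment
  corrupts the denominator.
- Duplicate runs of one condition are an error, not averaged; no
  replicate-merging rule is defined.
- A missing expected peak is area 0 plus a flag, not an error.
- Minimum control count 5 (configurable); baselines use arithmetic means, no
  trimming. Control CVs are recorded.
- Genomic intervals are 1-based inclusive (clinical array nomenclature);
  span = end − start + 1, reported half-up as integer Kb or one-decimal Mb,
  which reproduces the published 146 Kb and 5.7 Mb from their coordinates.
  (The published "3.1 Mb" for the 11p15.5p15.4(1–3,381,999) duplication does
  not match its own coordinates under any rounding, 3.38 Mb; it is left
  unresolved and unused.)
- Boundary values M ∈ {0.8, 1.2} are NORMAL (inclusive range).
- Allele identity in trios is string equality on repeat labels; no
  stutter/size-binning model. A single-allele genotype is read as homozygous.

## Limitations

- MS-MLPA is modeled only as a recommendation string; imprinting-center
  microdeletions cannot be distinguished from primary epimutations without
  probe-level MLPA data.
- No segmental UPD, no likelihood-based UPD scoring with population allele
  frequencies, no SNP-array ROH input.
- Dosage calls from a 2-amplicon-per-chromosome panel are screening-grade;
  CNV findings need array confirmation (interval arithmetic for reporting is
  provided, CNV calling is not).
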