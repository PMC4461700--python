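# imprintscan

Epimutation screening of imprinted loci from methylation-sensitive-digest
multiplex-PCR fragment data, with trio-based confirmation of uniparental
disomy (UPD).

`imprintscan` is aimed at clinical-genetics and epigenomics labs that screen
patients with unexplained neurodevelopmental phenotypes for methylation
defects at the classic imprinted differentially methylated regions (DMRs) —
*KCNQ1OT1* (11p15), *H19* (11p15), *SNRPN* (15q12) and *MEG3* (14q32) — using
an affordable HpaII digest + semiquantitative multiplex PCR assay read out on
a capillary analyser, rather than arrays or sequencing.

## The measurement model

Each DNA sample is split into a HpaII-digested and an undigested aliquot; both
are amplified with one multiplex containing DMR amplicons (spanning HpaII
sites, so only methylated template survives digestion) and HpaII-site-free
reference amplicons. With peak areas `A_a`, the relative area of amplicon `a`
is

    r_a = A_a / Σ_ref A_ref        (reference-only mode, the default)
    r_a = A_a / Σ_all A_all        (all-peaks mode, the spreadsheet convention)

Relative areas are normalized to the averaged relative areas of a control
cohort. For each DMR locus this yields two control-normalized values:

- **M** — methylation value: normalized `r` of the *digested* aliquot,
- **D** — dosage value: normalized `r` of the *undigested* aliquot.

A normal sample sits at M = D = 1. A mosaic epimutation that demethylates the
normally methylated parental allele in a fraction *c* of cells gives
**M = 1 − c** (reference-only mode, exactly), and a parental copy-number state
(CN_mat, CN_pat) gives **D = (CN_mat + CN_pat)/2**. Values within **1 ± 0.2**
are considered normal; methylation below 0.8 is a partial (or, at ≤ 0.1,
complete) loss of methylation (LOM), above 1.2 a gain (GOM). Each abnormal
(M, D) combination maps to mechanism hypotheses — epimutation, UPD of the
methylated/unmethylated parent, duplication or deletion — ordered by prior
plausibility and resolved by the recommended confirmation assays.

UPD confirmation uses trio microsatellite genotypes: each marker is classified
by enumerating every transmission (biparental, maternal or paternal
iso-/heterodisomy) that explains the child's genotype, and a chromosome-level
verdict requires at least 3 concordant single-parent-only markers with zero
opposite-parent markers. A child with three distinct alleles (two maternal +
one paternal, or vice versa) is duplication evidence and reported separately.

A synthetic-data generator produces peak tables and trio genotypes with
exactly this molecular structure (parental-origin copy numbers, per-allele
mosaic methylation, HpaII survival, amplicon efficiencies, loading factors,
multiplicative lognormal peak noise), so the whole pipeline is testable
without patient material; the five published alteration archetypes ship as a
fixture pack.

## Worked example

Simulate a small cohort (12 patients, the first five carrying the published
alteration archetypes; 20 controls; peak noise σ = 0.05), screen it, and fold
in two trios (a biparental chr11 trio for patient 1, a paternal-heterodisomy
chr14 trio for patient 4):

```python
from imprintscan import screening_cohort, simulate_cohort
from imprintscan.synthetic_data import TrioScenario, simulate_trio, write_trio_table

cohort = screening_cohort(n_patients=12, n_controls=20, noise_sigma=0.05, seed=7)
simulate_cohort(cohort, out_dir="demo")
trios = (simulate_trio(TrioScenario.BIPARENTAL, 10, 6, seed=11, trio_id="patient_1", chrom="11")
         + simulate_trio(TrioScenario.UPD_PAT_HET, 10, 6, seed=12, trio_id="patient_4", chrom="14"))
write_trio_table(trios, "demo/trios.csv")
```

```sh
imprintscan screen --peaks demo/peaks.csv --trios demo/trios.csv --out demo/out
# screened 12 samples against 20 controls: 5 positive (0 multilocus candidates)
```

The abnormal rows of `demo/out/calls.tsv` (columns truncated):

```
sample_id  locus     M      D      methylation_class dosage_class mechanisms                  confirmed_mechanism
patient_1  KCNQ1OT1  0.199  1.035  PARTIAL_LOM       NORMAL       EPIMUTATION                 EPIMUTATION (UPD excluded by segregation)
patient_2  KCNQ1OT1  0.935  1.397  NORMAL            GAIN         CNV_DUP_UNMETHYLATED_ALLELE
patient_2  H19       1.747  1.343  GOM               GAIN         CNV_DUP_METHYLATED_ALLELE
patient_3  SNRPN     0.639  1.007  PARTIAL_LOM       NORMAL       EPIMUTATION;UPD_PATERNAL
patient_4  MEG3      1.902  0.864  GOM               NORMAL       UPD_PATERNAL;EPIMUTATION    UPD_PATERNAL (mixed, 4 supporting markers)
patient_5  MEG3      0.0    1.074  COMPLETE_LOM      NORMAL       UPD_MATERNAL;EPIMUTATION
```

Reading it: patient 1's 80% mosaic LOM at *KCNQ1OT1* is measured as M ≈ 0.2
with normal dosage, and the biparental trio verdict leaves epimutation as the
confirmed mechanism; patient 2's paternal 11p15 duplication shows as *H19*
hypermethylation **with** a dosage gain (duplicated methylated allele) plus a
*KCNQ1OT1* dosage gain at normal methylation (duplicated unmethylated allele);
patient 4's *MEG3* hypermethylation at normal dosage is confirmed as
UPD(14)pat by the trio; patient 5 is the complete-LOM / UPD(14)mat pattern.

The standalone segregation caller is also exposed:

```sh
imprintscan upd --trios demo/trios.csv --out demo/upd
# patient_1 chr11: BIPARENTAL (NA; 4/4 informative markers supporting)
# patient_4 chr14: UPD_PATERNAL (MIXED; 4/4 informative markers supporting)
```

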