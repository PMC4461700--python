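# Default four-locus imprinting screen panel ("panel_imprint4").
#
# The locus -> methylated parent -> syndrome map is the clinically
# established one for the four classic imprinted DMRs.  Amplicon fragment
# sizes are nominal stand-ins for a FAM-labelled multiplex design (evenly
# spaced, non-overlapping +/- 2 bp windows); any real panel should override
# them with the sizes of its own primer design.  Reference amplicons are
# HpaII-site-free single-copy loci that amplify equally from digested and
# undigested aliquots.
name: panel_imprint4
version: "1.0"
amplicons:
  - name: KCNQ1OT1
    locus: KCNQ1OT1
    expected_size: 102
    size_tolerance: 2
    kind: DMR
    chrom_band: 11p15
    methylated_parent: maternal
    hypo_syndrome: Beckwith-Wiedemann syndrome (BWS)
    hyper_syndrome: ""
  - name: H19
    locus: H19
    expected_size: 118
    size_tolerance: 2
    kind: DMR
    chrom_band: 11p15
    methylated_parent: paternal
    hypo_syndrome: Silver-Russell syndrome (SRS)
    hyper_syndrome: Beckwith-Wiedemann syndrome (BWS)
  - name: SNRPN
    locus: SNRPN
    expected_size: 134
    size_tolerance: 2
    kind: DMR
    chrom_band: 15q12
    methylated_parent: maternal
    hypo_syndrome: Angelman syndrome (AS)
    hyper_syndrome: Prader-Willi syndrome (PWS)
  - name: MEG3
    locus: MEG3
    expected_size: 150
    size_tolerance: 2
    kind: DMR
    chrom_band: 14q32
    methylated_parent: paternal
    hypo_syndrome: UPD(14)mat-like syndrome (Temple)
    hyper_syndrome: UPD(14)pat-like syndrome (Kagami-Ogata)
  - name: REF_ACTB
    locus: ACTB
    expected_size: 166
    size_tolerance: 2
    kind: REFERENCE
    chrom_band: 7p22
  - name: REF_ALB
    locus: ALB
    expected_size: 182
    size_tolerance: 2
    kind: REFERENCE
    chrom_band: 4q13
  - name: REF_GAPDH
    locus: GAPDH
    expected_size: 198
    size_tolerance: 2
    kind: REFERENCE
    chrom_band: 12p13
  - name: REF_RPP30
    locus: RPP30
    expected_size: 214
    size_tolerance: 2
    kind: REFERENCE
    chrom_band: 10q23
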