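# Default per-class abundance profiles for the synthetic cohort generator.
#
# mean_abundance values are arbitrary units (coefficients against unit-norm
# references); they are simulator plumbing chosen to reproduce the known
# qualitative contrasts between leukemia blasts and normal counterparts:
#   * AML-M2/M3/M4 vs granulocyte: protein and both lipids up, nucleic acid down
#   * AML-M5 vs monocyte: all four components up
#   * ALL (both Ph- and Ph+) below every AML subtype in both lipid classes;
#     Ph+ above Ph- in unsaturated lipid
#   * among AML subtypes: M3 highest unsaturated lipid, M5 highest saturated
#   * ALL above healthy B cells in protein, nucleic acid and unsaturated lipid
# Radii (pixels) encode the coarse size hierarchy of dissociated cells
# (lymphocytes < granulocytes/monocytes < blasts).  Magnitudes are NOT
# measured values; edit freely.
classes:
  AML-M2:
    mean_abundance: {protein: 0.68, nucleic_acid: 0.28, unsaturated_lipid: 0.40, saturated_lipid: 0.30}
    cv_abundance: 0.12
    mean_radius_px: 8.5
    cv_radius: 0.06
  AML-M3:
    mean_abundance: {protein: 0.75, nucleic_acid: 0.30, unsaturated_lipid: 0.70, saturated_lipid: 0.42}
    cv_abundance: 0.12
    mean_radius_px: 10.0
    cv_radius: 0.06
  AML-M4:
    mean_abundance: {protein: 0.72, nucleic_acid: 0.37, unsaturated_lipid: 0.55, saturated_lipid: 0.42}
    cv_abundance: 0.12
    mean_radius_px: 11.5
    cv_radius: 0.06
  AML-M5:
    mean_abundance: {protein: 0.85, nucleic_acid: 0.50, unsaturated_lipid: 0.55, saturated_lipid: 0.60}
    cv_abundance: 0.12
    mean_radius_px: 13.0
    cv_radius: 0.06
  ALL-Ph-:
    mean_abundance: {protein: 0.60, nucleic_acid: 0.50, unsaturated_lipid: 0.15, saturated_lipid: 0.15}
    cv_abundance: 0.12
    mean_radius_px: 6.0
    cv_radius: 0.06
  ALL-Ph+:
    mean_abundance: {protein: 0.62, nucleic_acid: 0.52, unsaturated_lipid: 0.28, saturated_lipid: 0.16}
    cv_abundance: 0.12
    mean_radius_px: 7.5
    cv_radius: 0.06
  HSPC:
    mean_abundance: {protein: 0.48, nucleic_acid: 0.45, unsaturated_lipid: 0.15, saturated_lipid: 0.15}
    cv_abundance: 0.12
    mean_radius_px: 7.0
    cv_radius: 0.06
  granulocyte:
    mean_abundance: {protein: 0.50, nucleic_acid: 0.40, unsaturated_lipid: 0.20, saturated_lipid: 0.20}
    cv_abundance: 0.12
    mean_radius_px: 8.0
    cv_radius: 0.06
  monocyte:
    mean_abundance: {protein: 0.50, nucleic_acid: 0.40, unsaturated_lipid: 0.22, saturated_lipid: 0.20}
    cv_abundance: 0.12
    mean_radius_px: 9.0
    cv_radius: 0.06
  B_cell:
    mean_abundance: {protein: 0.45, nucleic_acid: 0.40, unsaturated_lipid: 0.10, saturated_lipid: 0.12}
    cv_abundance: 0.12
    mean_radius_px: 6.0
    cv_radius: 0.06
  T_cell:
    mean_abundance: {protein: 0.45, nucleic_acid: 0.42, unsaturated_lipid: 0.10, saturated_lipid: 0.12}
    cv_abundance: 0.12
    mean_radius_px: 6.0
    cv_radius: 0.06
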