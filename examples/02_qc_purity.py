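"""Beta computation and the two methylation-based purity filters.

Recomputes betas from raw intensities, masks low-quality measurements, then
builds the 500-probe leukocyte panel (blood-low / prostate-high probes) and
applies both purity filters to a cohort with two deliberately
blood-contaminated metastases.
"""

from epiclonal import (
    CohortSpec,
    Contamination,
    apply_detection_mask,
    build_leukocyte_panel,
    combine_purity,
    compute_beta,
    generate_blood_reference,
    generate_cohort,
    gstp1_purity_filter,
    leukocyte_filter,
)

contamination = (
    Contamination("P02_PL1", "blood", 0.7),
    Contamination("P05_PL1", "blood", 0.7),
)
spec = CohortSpec(seed=2, contamination=contamination, detection_fail_rate=0.002)
_, intensities, sheet, truth = generate_cohort(spec)

beta = compute_beta(intensities)  # beta = M / (M + U)
beta = apply_detection_mask(beta, intensities.detection_p)  # p > 0.05 -> missing
print(f"masked entries: {int(beta.isna().sum().sum())} of {beta.size}")

blood = generate_blood_reference(96, spec)
an = beta[sheet.loc[sheet.tissue_type == "AN", "sample_id"]]
panel = build_leukocyte_panel(blood, an)  # blood beta <= 0.2, top 500 by AN mean
print(f"leukocyte panel: {len(panel)} probes, matches designed set: "
      f"{set(panel) == set(truth.leukocyte_design_probes)}")

leuko = leukocyte_filter(beta, panel)  # mean over panel < 0.6 -> excluded
tumors = list(sheet.loc[sheet.tissue_type.isin(["T", "PL"]), "sample_id"])
gstp1 = gstp1_purity_filter(beta, truth.gstp1_probes, tumor_samples=tumors)
table = combine_purity(leuko, gstp1)
print(table[table.excluded].to_string())
print()
print("The two planted blood-contaminated metastases score far below the 0.6")
print("leukocyte threshold and are the only exclusions.")
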