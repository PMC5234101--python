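"""Simulate a multifocal-cancer methylation cohort with known ground truth.

Builds the default synthetic cohort (10 patients, 2-4 tumor foci from 2
subclones each, one lymph-node metastasis seeded by one subclone) and shows
what the generator planted.
"""

from epiclonal import CohortSpec, generate_cohort

spec = CohortSpec(seed=1)
beta, intensities, sheet, truth = generate_cohort(spec)

print(f"beta matrix: {beta.shape[0]} probes x {beta.shape[1]} samples")
print(sheet.groupby("tissue_type")["sample_id"].count().to_string())
print()
for pid in ["P01", "P02"]:
    rows = sheet[sheet.patient_id == pid]
    foci = rows[rows.tissue_type == "T"]["sample_id"]
    print(f"{pid}: seeding subclone = {truth.seeding_subclone[pid]}")
    for t in foci:
        print(f"  {t}: subclone {truth.sample_subclone[t]}, truly {truth.focus_true_class[t]}")
print()
print("Each focus inherits its subclone's set of methylation-shifted probes;")
print("the metastasis (PL) carries the seeding subclone's profile, so its")
print("nearest focus in beta space is the truly aggressive one.")
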