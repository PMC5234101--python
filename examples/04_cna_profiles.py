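"""Copy-number profiles from total probe intensity.

Plants a gain (copy ratio 1.5) and a loss (0.5) in one subclone, then
recovers them as intensity log2-ratio segments against the adjacent-normal
reference panel.
"""

import numpy as np

from epiclonal import CNASegment, CohortSpec, IntensityMatrixPair, cna_profile, generate_cohort

segments = (
    (CNASegment(chrom=1, start=100, end=400, copy_ratio=1.5),
     CNASegment(chrom=2, start=0, end=300, copy_ratio=0.5)),
    (),  # second subclone: no alterations
)
spec = CohortSpec(n_patients=1, foci_per_patient=(4, 4), cna_segments=segments, seed=7)
_, intensities, sheet, truth = generate_cohort(spec)

an = list(sheet.loc[sheet.tissue_type == "AN", "sample_id"])
reference = IntensityMatrixPair(intensities.methylated[an], intensities.unmethylated[an])
annotation = spec.probe_annotation()

for sid in sheet.loc[sheet.tissue_type.isin(["T", "PL"]), "sample_id"]:
    profile = cna_profile(intensities, reference, annotation, sid)
    calls = profile.as_frame().query("call != 'neutral'")
    sub = truth.sample_subclone[sid]
    print(f"{sid} (subclone {sub}):")
    print(calls.to_string(index=False) if len(calls) else "  no calls")
print()
print(f"Expected gain mean: log2(1.5) = {np.log2(1.5):.3f}; loss: log2(0.5) = -1.")
print("The alterations appear in every sample of the carrying subclone —")
print("including the metastasis — and in none of the other subclone's foci,")
print("independently confirming the methylation-based clonality assignment.")
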