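"""Generate a synthetic paired cohort and recover the true color shifts.

The generator renders sitting/supine tongue image pairs with known edge
colors and position shifts (specified in CIEDE2000 units); the pipeline then
segments each image, partitions the tongue into edge / posterior / middle /
apex, averages the edge color, and recomputes the shift. Recovered dE00
should track the truth to within ~0.1 at the default pixel noise (sigma = 2
per Lab channel, ~3800 edge pixels).
"""

from tonguecolor import (
    CohortSpec,
    ciede2000,
    generate_paired_cohort,
    partition_regions,
    segment_tongue,
)
from tonguecolor.segmentation import region_mean_lab

cohort = generate_paired_cohort(CohortSpec(n_patients=6, seed=7))

print("patient   true dE00   recovered   |error|")
for t in cohort.truth:
    imgs = cohort.images[t.patient_id]
    # re-segment from pixels rather than reusing the generator's partition
    colors = {}
    for position in ("sitting", "supine"):
        mask = segment_tongue(imgs[position])
        part = partition_regions(mask)
        colors[position] = region_mean_lab(imgs[position], part, "edge")
    rec = ciede2000(colors["sitting"], colors["supine"]).dE00
    print(f"{t.patient_id}   {t.true_dE00:9.2f}   {rec:9.2f}   {abs(rec - t.true_dE00):7.3f}")

print("\nEach row is one synthetic patient; the truth column is the shift the")
print("generator injected, the recovered column what the full image pipeline")
print("measured back from the rendered pixels.")
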