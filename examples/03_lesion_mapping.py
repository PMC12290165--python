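"""Voxel-wise one-vs-rest lesion mapping with maxT FWER control.

Continues from the clustering example: for every behavioral cluster, the
proportion of lesioned patients per voxel is compared against the rest of
the cohort with the pooled-variance two-proportion statistic, permutation
null (cluster labels shuffled), Westfall-Young step-down maxT correction
within each cluster family, and a Bonferroni split of the overall 0.05
level across the five families.
"""

import numpy as np

from nihssnet import (
    density_map,
    gdm_distance,
    generate_cohort,
    gsm_network,
    lesion_volume_comparison,
    one_vs_rest_analysis,
    rsc_partition,
)

scores, volumes, truth = generate_cohort(seed=1)
W = gsm_network(gdm_distance(scores))
labels, _ = rsc_partition(W, 5, N=500, master_seed=1)

results = one_vs_rest_analysis(
    volumes, labels.labels, overall_alpha=0.05, B=5000, seed=1
)
print(f"voxels tested per family: {len(results[0].selected_voxels)} "
      f"(lesioned in >= 5% of {volumes.n} patients)")
print(f"per-family FWER level: {results[0].family_alpha:g}\n")
for res in results:
    dm = density_map(volumes, labels.labels, res.cluster_id)
    peak = tuple(int(i) for i in np.unravel_index(np.argmax(dm), dm.shape))
    H, p = lesion_volume_comparison(volumes, labels.labels, res.cluster_id)
    print(
        f"cluster {res.cluster_id}: {int(res.significant.sum()):4d} significant "
        f"voxels, density peak at {peak}, lesion volume vs rest: "
        f"H = {H:.1f}, p = {p:.2g}"
    )
print(
    "\nSignificant voxels concentrate at each cluster's planted lesion locus;"
    "\nthe small-lesion lacunar-like cluster shows a strongly smaller lesion"
    "\nvolume than the rest of the cohort (large H, small p)."
)
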