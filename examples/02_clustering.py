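"""Repeated spectral clustering with eigengap model selection.

Generates the default synthetic five-syndrome cohort (150 patients, 14
ordinal items), builds the GSM similarity network, selects the number of
clusters from the consensus eigengaps, and partitions the cohort.  The gap
table shows, for each candidate k, the k-th spectral gap of the consensus
matrix C_k against that of the raw network W: the planted five-cluster
structure is invisible in W's gaps but sharp in C_5.
"""

from sklearn.metrics import adjusted_rand_score

from nihssnet import (
    cluster_profile_summary,
    gdm_distance,
    generate_cohort,
    gsm_network,
    rsc_partition,
    select_k,
)

scores, volumes, truth = generate_cohort(seed=1)
W = gsm_network(gdm_distance(scores))

selection = select_k(W, range(2, 9), N=500, master_seed=1)
print("eigengap evidence table:")
print(selection.table.round(3).to_string(index=False))
print(f"\nselected k = {selection.k} (planted: {truth.k})")

labels, consensus = rsc_partition(W, selection.k, N=500, master_seed=1)
ari = adjusted_rand_score(truth.labels, labels.labels)
print(f"adjusted Rand index vs planted labels: {ari:.3f}")

profiles = cluster_profile_summary(scores, labels.labels)
print("\nmedian symptom profile per cluster (items with any deficit):")
medians = profiles.xs("median", level="statistic")
print(medians.loc[:, (medians != 0).any()].to_string())
print(
    "\nEach row is one cluster's median NIHSS profile: the five rows recover"
    "\nthe planted left-motor, visual/inattention, right-motor, lacunar-like"
    "\nand language syndromes."
)
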