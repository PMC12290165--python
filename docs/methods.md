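# Methods

This note documents the statistical machinery implemented in `nihssnet`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Cohort model and filtering

The unit of analysis is a patient × item matrix `X` of integer ordinal
scores with per-item maxima `L_j` (NIHSS-style: 0 is intact, maxima 2–4).
Missing entries are a hard error by design: the one NIHSS item that can
make the remaining items unassessable (level-of-consciousness vigilance)
is handled by the filtering rules instead. Filtering drops, in a fixed
order whose outcome is order-independent (asserted by test): subjects
without a brain scan, subjects with total score 0, subjects with a
positive vigilance score; finally the vigilance column is removed. Every
drop is logged with its reason.

Descriptive statistics are deliberately ordinal: deficit co-occurrence
counts ignore severity; item association uses Spearman's ρ on mid-ranks
with two-sided permutation p-values (one column of the pair permuted,
add-one convention `p = (1 + #{|ρ*| ≥ |ρ|})/(B + 1)`, so p ∈ [1/(B+1), 1])
and Benjamini–Hochberg FDR across the `m(m−1)/2` pairs. Constant items
have undefined ρ; their pairs are excluded from the FDR family (rather
than assigned p = 1, which would dilute the correction) and reported
separately. Cluster profiles are summarized by per-item minimum, median
and maximum only — means and standard deviations are not meaningful on an
ordinal scale. The median of an even-sized group is the lower of the two
central order statistics, which keeps the summary on the integer scale.

## The General Distance Measure

For subjects `a, b` and items `j`, with `σ_abj = sign(x_aj − x_bj)`:

    d_ab = Σ_j [ 1/(2m) − (−σ²_abj + Σ_{c≠a,b} σ_acj σ_bcj) / (2 √(S_a S_b)) ],
    S_a  = Σ_j Σ_c σ²_acj .

Properties the test suite pins down: `d` is symmetric with zero diagonal;
`d ∈ [0, 1]`; identical profiles give `d = 0`; in a two-subject cohort any
difference gives `d = 1`; and the measure is *cohort-dependent* — adding a
subject changes existing pairwise distances, because each comparison is
mediated by rankings against the rest of the cohort. The sum over third
subjects `c` formally excludes `c ∈ {a, b}`, but those terms vanish
(`σ_aaj = 0`), so the vectorized implementation sums over all `c`; it is
verified to 1e−12 against a literal triple-loop oracle. The self-distance
is defined as 0 (the definition degenerates for `a = b`). A subject tying
with every other subject on every item makes its normalizer `S_a = 0`;
this raises an error naming the subjects (it requires an essentially
constant cohort). Distances are checked against [0, 1] with tolerance
1e−9 and clipped; the full computation is two matrix products over the
flattened sign array, so a 500 × 20 cohort takes seconds.

The similarity network is `W = 1 − D` with unit diagonal. A normalized
Manhattan distance is included as a baseline for comparison only.

## Repeated Spectral Clustering

One spectral clustering run is the normalized-symmetric variant: take the
`k` eigenvectors of `L_sym = I − D^{−1/2} W D^{−1/2}` with the smallest
eigenvalues, normalize the rows of the embedding to unit length, run
k-means with `k` clusters. Numerical choices: dense symmetric
eigendecomposition (intended for n ≤ 2000), eigenvalues floored at 0,
zero-norm embedding rows (possible only for pathological graphs) replaced
by a uniform unit vector with a warning, zero-degree nodes rejected with
the node named.

RSC repeats only the k-means stage: the embedding is a deterministic
function of `W`, and the `N` runs (default 500) differ solely in the
centroid initialization, each seeded deterministically from the master
seed. Co-clustering fractions accumulate into the consensus matrix `C`
(stored as fractions; `L_sym` is scale-invariant, so fractions vs counts
is cosmetic — asserted by test). `C` is then itself spectrally clustered
with the same `k`. Final labels are canonicalized by order of first
appearance, so a stable consensus yields identical label vectors across
master seeds, which is how stability is asserted.

k-means details: single initialization per run (the ensemble provides the
restarts), Lloyd iterations with tolerance 1e−6 and at most 300
iterations. The initialization is the *plain* k-means++ scheme — one
uniformly drawn first center, subsequent centers drawn with probability
proportional to squared distance. The greedy multi-trial k-means++ variant
common in library defaults is nearly deterministic on well-separated
embeddings; it would collapse the run-to-run variability that the
consensus stage averages over, making consensus matrices at *wrong* k
artificially sharp and model selection uninformative. Plain k-means++
keeps per-run recovery reliable at the true `k` while letting forced
merges/splits at wrong `k` vary across runs, which is exactly the signal
the consensus spectrum needs.

### Choosing the number of clusters

Two spectral facts drive the choice. First, the number of near-zero
eigenvalues of `L_sym` equals the number of connected components, so a
disconnected `W` announces its own `k`; `select_k` returns that count when
it falls inside the candidate range. Second, for connected noisy networks
the structure is read from the consensus matrices: for each candidate
`k`, the k-th spectral gap `g_k = λ_{k+1} − λ_k` of `C_k` is compared with
the k-th gap of `W`, and the `k` with the largest increase wins (ties
toward smaller `k`). Subtracting `W`'s own gap matters: a cohort with a
coarse super-structure (e.g. a hemispheric split) produces a stable,
perfectly sharp `C_2`, but `W`'s spectrum already exposes that coarse gap,
so the *increase* at `k = 2` is discounted and the finer structure that
only consensus averaging reveals can dominate. The full gap table is
always returned for inspection; on a single cohort realization the
decision between a strong coarse split and a finer structure can be close,
so inspecting the table (and, where possible, replicate cohorts) is
recommended practice — the acceptance script reports the modal selection
over five replicate cohorts for this reason.

## Voxel-wise lesion mapping

Masks are binary volumes on a common grid; loading binarizes at > 0.5 with
a warning for non-binary input, and nothing assumes a specific template —
the same code runs on a 20 × 24 × 20 synthetic grid and on MNI-space data.
Cluster density maps are voxelwise means of the member masks.

Voxel selection keeps voxels lesioned in at least `floor(f·n)` subjects
(threshold promoted to 1 when the floor is 0); with `f = 0.05` and
`n = 172` the threshold is 8. Selection uses pooled counts only — it never
sees cluster labels — so it is shared across the one-vs-rest families.

The per-voxel statistic is the absolute two-proportion difference with
pooled variance (`t_v` above). A pooled proportion of 0 or 1 makes the
denominator vanish, but then both group proportions are equal, so the
statistic is defined as 0 with a warning, never NaN.

The null distribution permutes the one-vs-rest indicator `B` times
(default 5000). Multiplicity within a family is controlled by the
Westfall–Young step-down maxT procedure: voxels ordered by decreasing
observed statistic (ties broken by voxel index), each step comparing
against the permutation distribution of the maximum over the
not-yet-ordered voxels, add-one p-values (the observed labeling is not
counted among the B permutations), and monotonicity enforced along the
ordering. Adjusted p-values therefore dominate raw per-voxel permutation
p-values, and the empirical family-wise error under a global-null
generator stays at or below the nominal level (checked by a 200-dataset
Monte-Carlo calibration in the acceptance suite). Across the `k` cluster
families a Bonferroni split is applied: each family is tested at
`overall_alpha / k` (0.01 for five families at overall 0.05).

Lesion volumes (voxel count × voxel volume from the affine, reported in
mL) are compared cluster-vs-rest with the Kruskal–Wallis rank test (1 df).

## The synthetic cohort generator

The generator emulates the structure of an acute ischemic stroke cohort
assessed with the NIHSS: 14 ordinal items with the standard per-item
maxima, five planted syndrome prototypes (left motor, visual/inattention,
right motor, mild bilateral lacunar-like, language; 30 subjects each by
default), ordinal noise, and per-subject ellipsoidal lesions at
cluster-specific loci on a small grid (20 × 24 × 20 by default, roughly
10⁴ voxels, so full permutation analyses run in minutes) with jittered
centers, random radii and optional background noise voxels. The
lacunar-like cluster receives distinctly smaller lesion radii, giving the
volume comparison a real effect to find. Ordinal noise is a ±1 lattice
step per item with probability `flip_prob` (default 0.1), clipped to the
item range — score space is a lattice, not an interval scale, so Gaussian
noise with rounding would be the wrong model.

Two structural features of the default prototypes are deliberate and
matter for model selection. The two hemispheric pairs (left motor with
visual/inattention; right motor with language) share mild contralesional
deficits, giving the cohort a coarse hemispheric super-structure on top of
the five syndromes — as real cohorts have, where inattention accompanies
left-sided motor deficits and aphasia accompanies right-sided ones. And
the lacunar-like cluster is mild and non-lateralized, sitting between the
hemispheric groups. Together these make the coarse 2/3-way splits visible
in `W`'s own spectrum (hence discounted by the eigengap-increase rule) and
keep the binary merge ambiguous, so the selection lands on the planted
five. The prototypes are illustrative fixtures, not clinical claims.

A second generator produces global-null cohorts: scores independent of
lesions, each subject receiving one spherical lesion near the grid center
so that selection finds voxels while labels carry no signal. It feeds the
FWER calibration.

What passing tests on these cohorts shows: the algebra and algorithms are
implemented correctly, recovery works when the planted structure matches
the model, the error control holds under the null. What they cannot show:
that real NIHSS cohorts contain five clusters, that real cluster
boundaries are as crisp as planted ones, or that the eigengap criterion is
decisive on arbitrary data — on real cohorts the gap table should be read,
not just the argmax.

## Known limitations

- The GDM computation holds the full `n × n × m` sign array in memory;
  fine for cohorts of hundreds, not for tens of thousands.
- Dense eigendecomposition bounds the similarity network at a few thousand
  nodes.
- Soft/probabilistic cluster assignments are not provided; the consensus
  matrix itself is the closest available object.
- No image preprocessing: masks must already be binary, co-registered and
  on a common grid.
- The eigengap selection can be genuinely ambiguous between a strong
  coarse hierarchy and a finer structure on single cohort realizations;
  the gap table and replicate cohorts are the remedy, not the argmax
  alone.
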