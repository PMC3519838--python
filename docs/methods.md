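# Methods

## The problem

Lloyd's k-means spends almost all of its time computing point-to-centroid
distances: every iteration costs `n·k` distance evaluations, even though in
late iterations most clusters have effectively stopped changing.  Per-point
shortcuts (the Overlapped/Enhanced family) attack this one point at a time;
this package implements a *whole-cluster* stopping device: once a cluster is
detected as stable, all of its members skip the assignment scan at once.

The package targets time-course gene-expression matrices (rows = genes,
columns = timepoints, values = normalized log-ratios) but works on any
numeric matrix.

## The metric-matrix mechanism

**Spectral estimate of the optimum.**  For a data matrix `X` (n×d) the
optimal k-means sum of squares is bounded below by
`||X||_F² − Σ_{j=1..k} σ_j²`, where `σ_j` are the largest singular values of
`X`.  Dividing by the first-iteration objective `SSE_1` gives a
dimensionless multiplier `m ∈ [0, 1]`, and `MSE_l ≈ m · MSE_1` estimates the
optimal mean squared error after a single Lloyd pass.  The top-k squared
singular values are computed from the smaller Gram matrix (`XᵀX` when
`d ≤ n`), so the cost is `O(min(n,d)³)` — negligible next to the clustering
itself for expression matrices (`d ≤ ~50`).  Entries past the matrix rank
count as zero, so `k > rank(X)` simply drives the bound (and `m`) to 0.

**MMI detection.**  Freezing clusters early is unsafe, so the mechanism
stays off until the run is demonstrably near its optimum.  The switch-on
iteration (MMI) is the first iteration `i` with
`|MSE_i − m·MSE_1| ≤ ε_eff`, a Cauchy-style closeness criterion, capped at
`⌈MSE_1·k / (m·MSE_1)⌉`.  The same predicate is evaluated online during the
run and by the offline `detect_mmi` rescan, so the two always agree.  If the
run converges before the predicate ever holds, the mechanism simply never
fires and the run is identical to Traditional k-means — this is reported in
the run's MMI state rather than treated as an error.

**Per-cluster stability.**  From iteration MMI onward, each centroid update
is followed by building the k×k "metric matrix" `MM[i,j] = r(pm_i, m_j)` of
Pearson correlations between previous- and current-iteration centroids.
Its eigenvalues (sorted descending; index j maps to cluster j through the
sort) summarize how much the centroid configuration is still rotating.
Cluster j is declared stable when the relative change of its eigenvalue
between consecutive iterations falls within the stability band, and its
members then skip the assignment scan.  Frozen clusters still receive
centroid updates and may gain points from unfrozen clusters; stability
flags are recomputed every iteration, so a cluster can unfreeze if its
eigenvalue moves again.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L0`, `H1` | 0.005, 0.015 | stability band for the relative eigenvalue change (dimensionless fractions, i.e. 0.5%–1.5% — the empirical band within which the spectral bound sits relative to the optimum) |
| `epsilon` | 0.007 | half-width of the MMI detection band |
| `epsilon_mode` | `relative` | `relative`: `ε_eff = ε·MSE_1` (scale-free); `absolute`: `ε_eff = ε` (appropriate when MSE is O(1), as for normalized expression log-ratios) |
| `stability_mode` | `threshold` | `threshold`: stable iff `diff_rel ≤ H1`; `strict_interval`: stable iff `L0 ≤ diff_rel ≤ H1` |
| `distance` | `sq_euclidean` | assignment distance (`euclidean` and `pearson_dissimilarity` = 1−r also available) |
| `init` | `forgy_sample` | k distinct data rows drawn with the config seed; `first_k` takes rows 0..k−1 |
| `max_iter` | 300 | Lloyd iteration cap |

Design choices where the published description left room:

* **Threshold vs strict interval.**  A fully converged cluster has
  eigenvalue change ≈ 0, *below* the band's lower edge, and must count as
  stable; the default test is therefore the upper threshold `diff_rel ≤ H1`.
  The literal two-sided band is available as `strict_interval` for
  comparison.
* **Relative eigenvalue change.**  The band edges are stated as
  percentages, so the eigenvalue difference is scaled by `|pe_j|`
  (floored at 1e-12) rather than used raw.
* **Symmetrization.**  The correlation matrix between two *different*
  centroid sets is not symmetric and can have complex eigenvalues.
  Eigenvalues are taken from `(MM + MMᵀ)/2`, which is exact whenever `MM`
  is symmetric — the converged regime where the test matters — and
  guarantees a real, sortable spectrum.
* **MSE convention.**  `MSE_i` is measured after the assignment step of
  iteration i, against the centroids used for that assignment, and is
  always squared-Euclidean even when assignment uses another distance, so
  objective traces are comparable across configurations.  With
  squared-Euclidean assignment the trace is non-increasing.
* **Ties and empty clusters.**  Nearest-centroid ties go to the lowest
  cluster index (bit-reproducible runs); a cluster that loses all members
  keeps its previous mean with size 0 and is reported, not re-seeded.
  Empty clusters appear routinely when `k > d`, and that behavior is left
  visible on purpose.
* **Negative values.**  The eigenvalue stability band was calibrated on
  non-negative expression values; `run_mmkmeans` warns (but proceeds)
  when the input contains negative entries.

## Baselines

`run_traditional` is plain Lloyd.  `run_enhanced` / `run_overlapped` keep
per-point caches (`clusterid`, `pointdis`): after each centroid update a
point whose distance to its own cluster's new centroid does not exceed the
cached distance keeps its membership at a cost of one evaluation; otherwise
all k centroids are scanned.  Enhanced refreshes the cache on kept points,
Overlapped leaves it anchored at the last full scan — the published account
does not pin the distinction down further, so this refresh-policy reading
is a documented judgment call (everything else is shared code).  Distance
evaluations are counted exactly in every variant; wall-clock timing is
deliberately not used as a cost measure because it is hardware-bound.

A consequence worth knowing: the shortcut variants are *not* Lloyd — a
stale cache can suppress a reassignment Lloyd would have made, so their
per-iteration moved-point counts are not monotone and they can settle in
different local optima than Traditional k-means from the same
initialization.  The test suite demonstrates both effects.

## Synthetic data

`generate_mixture` draws spherical Gaussian components around
deterministically placed means: scaled canonical basis vectors when
`k ≤ d` (every pair of means exactly `separation` apart) or an integer
lattice when `k > d` (adjacent sites `separation` apart).  Defaults
(`noise_sd = 1`, `separation = 8`, uniform weights) give well-separated
clusters, the regime in which whole-cluster stability is expected to
emerge.  `generate_periodic_profiles` produces sinusoids over `d` equally
spaced timepoints with `k` distinct phases — a microarray-like fixture for
the correlation distance.  Neither models array-noise physics (dye bias,
spot artifacts, missing-value structure), so passing tests show algorithmic
correctness on clean geometry, not robustness to real microarray noise.
The published benchmark matrices themselves (the P. falciparum time
courses and the large simulated 50-dimensional sets) are emulated in shape
only; how the originals were simulated is not described, and the generator
is a labeled stand-in.

## What the checks show

The headline checks pair MMk-means against Traditional k-means from shared
Forgy initializations on mixtures of 5,000×50 points with k = 10 (cluster
count far below dimension) and 4,000×16 with k = 15 (cluster count near
dimension), five seeds each, scored by the Hubert-Arabie adjusted Rand
index and summarized by the median.  These sizes run in seconds on one CPU
while preserving the two regimes' k-to-d relationship.

On these proxies MMI frequently never fires (the runs converge before the
MSE enters the detection band); the paired ARI is then exactly 1 by
construction.  When MMI does fire, freezing is observed to be sound: a
full reassignment at termination moves well under 1% of the members of
frozen clusters, and every post-MMI iteration with a frozen, non-empty
cluster costs strictly fewer than `n·k` evaluations.  The soundness audit
is meaningful only under the mechanism's own MMI timing — forcing the
mechanism on in iteration 2 via `mmi_override` freezes clusters long
before the Cauchy criterion would allow and demonstrably mis-assigns
points; `mmi_override` exists for reduction tests (`override ≥ max_iter`
reproduces Traditional k-means bit for bit), not as a tuning knob.

## Limitations

* The ARI between MMk-means and Traditional k-means measures agreement
  with Lloyd, not clustering quality against ground truth; both can agree
  on a bad local optimum.
* MMI detection depends on the spectral estimate being close to the
  achievable optimum; on data where the bound is loose (`m` far below the
  realized `MSE_l/MSE_1`), the band is never entered and the mechanism
  never engages — safe, but no speedup.
* The per-cluster freeze is heuristic: eigenvalue stability of the
  correlation matrix does not strictly imply membership stability, which
  is why the audit above is part of the test suite rather than assumed.
* `d = 1` is rejected for MMk-means (correlations between scalars are
  undefined); use the Traditional or shortcut variants there.
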