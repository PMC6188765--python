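# Methods

## Model

Incomplete multiview data are P symmetric N×N kernels over the same N
samples with a zero-one visibility mask `S` (every sample visible in at
least one view, the minimal requirement for it to be clusterable at all).
The number of clusters K is treated as prior knowledge.

Late fusion proceeds in two stages.

**Per-view clustering.**  For each view the principal sub-kernel of its
visible instances is extracted, double-centered and scaled to unit mean
diagonal (`HKH/s`, `H = I − 11ᵀ/n`, `s = mean diag(HKH)`), and clustered
with kernel k-means.  The sub-kernel — not the full kernel — is
preprocessed, because the sub-kernel is the object actually clustered;
centering a matrix containing imputed zeros would leak the mask structure
into the geometry.  The result is scattered into an N×K indicator `Zʲ`
whose missing rows are all-zero.

**Consensus.**  The decision `Y` and per-(view, cluster) centroids `M_cʲ`
minimize `Σⱼ Σ_c Σᵢ Y_ic S_ij ‖Zᵢʲ − M_cʲ‖²`.  Both coordinate updates are
exact minimizers of their subproblems:

* `Y`-update: sample i joins `argmin_c Σⱼ S_ij ‖Zᵢʲ − M_cʲ‖²` — the
  objective decomposes per sample, so the row-wise argmin is globally
  optimal for fixed M;
* `M`-update: `M_cʲ = Σᵢ Y_ic S_ij Zᵢʲ / Σᵢ Y_ic S_ij` — the subproblem in
  each centroid is an unweighted least-squares mean over its visible
  members, hence convex with this closed-form minimum.

The objective is therefore non-increasing; being bounded below by zero and
piecewise constant over the finite set of decisions, the alternation
reaches a fixed point in finitely many iterations.  M is initialized from
the supplied `Y⁰` before the first `Y`-update.

## Kernel k-means solver

The discrete problem is NP-hard; the classical route relaxes it to
`max tr(UᵀKU), UᵀU = I` (optimum: top-K eigenvectors) and rounds U's rows
back to a partition with k-means.  On small enumerable instances we found
plain rounding — k-means on U, best restart by embedding inertia — to land
away from the enumerated discrete optimum on roughly half of unstructured
random kernels: the embedding whitens the kernel's dominant directions, so
inertia on U is a poor proxy for the kernel-space objective.  The solver
therefore keeps the spectral embedding as the *initializer* and polishes
every restart in kernel space with three exact descent moves applied to the
discrete objective until jointly stable:

1. Lloyd iterations (reassign to the nearest implicit cluster mean,
   distances computed with the kernel trick);
2. single-point moves (Hartigan-style first improvement);
3. pairwise swaps and same-cluster pair relocations (best improvement),
   which escape coordinated local optima that no single move can leave.

The restart with the lowest exact discrete objective supplies the labels.
On 600 random Wishart kernels (n ≤ 8, k = 2, 20 restarts) this matches
exhaustive enumeration of all 2-partitions in every case.  Empty clusters
during Lloyd steps are repaired by seizing the point farthest from its
centroid; moves that would empty a cluster are forbidden.  U is
basis-arbitrary under eigenvalue ties (the deterministic symmetric solver's
order is taken as-is); only the labels are contractual downstream.

## Numerical choices

* **Symmetry tolerance** 1e-8 on `max|K − Kᵀ|`: below it kernels are
  silently symmetrized (absorbs text-I/O rounding), above it a named error
  is raised.  Positive semidefiniteness is checked (smallest eigenvalue)
  and warned about but not enforced — the machinery needs only symmetry.
* **Ties in the Y-update** (within 1e-12) are sticky: the previous cluster
  wins if it is among the minimizers, else the lowest index.  Stickiness
  means Y changes only when the objective strictly decreases, which rules
  out limit cycles and makes "Y unchanged over a full iteration" a sound
  stopping rule.  `max_iter` defaults to 200 as a safety net; every test
  instance converges far earlier.
* **Undefined centroids** (a (view, cluster) pair with no visible members)
  retain their previous value with `defined=False`; their terms are absent
  from the objective, so any stored value is optimal and the convergence
  argument is untouched.  At initialization the fallback is the global mean
  of the view's visible indicator rows.
* **Empty consensus clusters** may persist (nothing in the objective forces
  K nonempty clusters); a warning is logged.
* **Degenerate kernels**: when centering collapses a kernel (mean diagonal
  ≤ 1e-12, e.g. an all-ones kernel), scaling is skipped and a warning
  attached.

## Baselines

All fills preserve visible-visible entries exactly, re-symmetrize, and are
the identity on complete data.  Zero fill zeroes every entry touching a
missing instance.  Mean fill replaces a missing entry (i, l) with the
per-entry mean of the views where both i and l are visible (per-entry, the
most literal reading; entries visible nowhere fall back to 0 with a
warning).  KNN fill measures a missing sample's similarity to candidates by
the per-entry mean of visible-visible kernel entries over its own visible
views, then rebuilds its row/column as the mean of its k (default 5) most
similar visible samples' rows in that view; all fills are computed against
the same zero-filled base so the result does not depend on the order in
which missing samples are processed.  AF fill copies entries of the
averaged zero-filled consensus into missing positions — the
consensus-copy (`af-copy`) reading of alignment-maximization filling; the
full alignment-maximization closed form is intentionally out of scope.

"Multiple kernel k-means" here is uniform-average-kernel k-means: each
completed kernel is centered and scaled, averaged with equal weights, and
clustered.  No kernel-weight learning is attempted — the uniform average is
the minimal deterministic choice and keeps baseline behavior attributable.
The best-single-view baseline is an oracle (it needs ground truth to pick
its view) that completes the chosen view's partition with seeded uniform
random labels; view quality is scored by NMI on visible indices.

## Synthetic data and what it does (not) show

The missingness sampler selects exactly `round(ε·N)` samples; each selected
sample draws `g ∈ [0,1]^P` and loses view p when `g_p < q₀` (default 0.5),
redrawing until at least one view survives.  With `require_missing=True`
(default) the redraw also insists on at least one missing view, so ε is
exactly the fraction of genuinely incomplete samples — the name of the
quantity is honored over the literal protocol, which would leave a selected
sample complete with probability `(1−q₀)^P / (1−q₀^P)`.  Both behaviors are
available and tested against their analytic conditional distributions.

The multiview generator draws balanced latent labels shared across views;
per view, cluster centers are i.i.d. `N(0, separation²/d_j)` per coordinate
(expected squared center distance `2·separation²` independent of the view's
dimension), features add isotropic noise, and kernels are linear or
Gaussian with width = mean pairwise distance.  Defaults (N=300, P=3, K=4,
d=8, separation 4, noise 1, linear kernels) give well-separated but not
trivial views: single complete views score NMI ≈ 0.95–1.0 and degrade
gracefully under masking.  `view_consistency < 1` redraws a fraction of
per-view labels independently, modeling views that disagree about some
samples.  The toy stability study uses three unit-variance 2-D Gaussians
at means (0,0), (4,0), (2,3.5), 100 points each — parameters chosen so the
complete-data clustering is essentially perfect, which makes the
stability-under-deletion property sharp.

These generators emulate the *random* missingness and shared-cluster
structure the method assumes.  They do not emulate informative missingness
(mask correlated with cluster membership), heavy-tailed or manifold-shaped
clusters, or views with systematically conflicting structure; passing tests
say nothing about those regimes.  Real multi-omics kernels also carry
batch structure and heteroscedastic noise absent here.

## Problem sizes in the test suite

The bundled studies run at desk scale, chosen to keep the full suite in the
minutes range while preserving each claim's content: enumeration oracles at
N ≤ 6 (decisions) and n ≤ 8 (2-partitions), 100 fusion runs at N=200 for
the convergence study, 100 repeats per ratio for the toy study, and 50
seeds × 3 incomplete-sample ratios at N=300 for the initialization trend.

## Known limitations

* Eigendecomposition is dense: O(N³) per view.  No approximate solvers are
  provided; the intended regime is N up to a few thousand.
* The consensus objective weights all views equally; a noisy view
  contributes as much as an informative one (visible in the trend study at
  high ε).
* The fusion refines a given `Y⁰`; with a very poor initialization it
  converges to a nearby local optimum, not the global one.
* `best_single_view` requires ground truth and is a reporting baseline,
  not a method.
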