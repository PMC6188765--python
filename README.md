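# latefuse — incomplete multiview clustering via late fusion

Multiview data describe the same N samples through several sources ("views"):
omics layers of the same patients, different feature channels of the same
images, precomputed kernel matrices of the same proteins.  In practice views
are often *incomplete* — a patient skipped a test, a sensor failed — and the
standard answers (impute the missing kernel entries, then cluster) blur the
signal that each view still carries.

`latefuse` takes the opposite, *late-fusion* route:

1. **Cluster what you can see.**  Each view's visible instances are clustered
   with kernel k-means, solved through the spectral relaxation
   `max_U tr(UᵀKU) s.t. UᵀU = I` (top-K eigenvectors), rounded to a
   partition and polished with exact kernel-space descent.  Under the random
   missing assumption the visible instances preserve the view's cluster
   structure, so these partitions are trustworthy.
2. **Fuse the partitions.**  Each view's result is a zero-one indicator
   matrix `Zʲ ∈ {0,1}^{N×K}` (all-zero rows where missing), whose rows act
   as compressed K-dimensional representations.  The consensus decision `Y`
   minimizes the masked sum of per-view k-means objectives

   ```
   min_{Y, M}  Σⱼ Σ_c Σᵢ  Y_ic · S_ij · ‖Zᵢʲ − M_cʲ‖²
   ```

   over one-hot rows of `Y` and per-(view, cluster) centroids `M_cʲ ∈ ℝ^K`,
   where `S` is the N×P visibility mask.  Alternating minimization — an
   exact assignment step for `Y`, an exact mean step for `M` — decreases the
   objective monotonically and converges in finitely many iterations.

The package also provides the classical baselines used to initialize and to
compare against (zero / mean / k-nearest-neighbor / average-consensus kernel
filling followed by uniform multiple kernel k-means, and the best-single-view
oracle), the random view-missingness simulator (incomplete-sample ratio ε,
per-view missing probability q₀), synthetic multiview generators, and the
clustering metrics NMI and ACC.

## Worked example

```python
import latefuse as lf

# 300 samples, 4 clusters shared across 3 views; half the samples incomplete
data = lf.synthetic_multiview(lf.SyntheticSpec(n_samples=300, n_views=3,
                                               n_clusters=4, seed=1))
data.mask = lf.generate_mask(300, 3, lf.MissingnessSpec(epsilon=0.5, seed=2))

assignments = lf.cluster_each_view(data, k=4, seed=0)     # per-view Z^j
y0 = lf.build_initial_decision("zf", data, assignments, k=4, seed=0)
state = lf.fuse(assignments, data.mask, y0)               # consensus Y

print(f"initial NMI {lf.nmi(y0.labels(), data.labels):.3f}")
print(f"fused   NMI {lf.nmi(state.decision.labels(), data.labels):.3f}")
print(f"objective {state.objective_trace[0]:.2f} -> {state.objective_trace[-1]:.2f}"
      f" in {state.n_iterations} iterations")
```

prints

```
initial NMI 0.787
fused   NMI 0.952
objective 71.04 -> 35.59 in 2 iterations
```

The initial decision (zero-filled kernels + multiple kernel k-means) gets
NMI 0.787 against the ground truth; the late-fusion step raises it to 0.952
while monotonically halving its own masked sum-of-squares objective.  The
scripts in `examples/` walk through each capability (the fusion pipeline,
the imputation baselines, the missingness sampler's analytic statistics, the
toy stability study, and a construction where no single view can identify
the partition but the fusion can); a thin CLI (`latefuse --help`) wraps the
same calls for shell use.

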