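"""End-to-end late fusion on synthetic incomplete 3-view data.

Generates 300 samples in 4 shared clusters across 3 views, hides views at
incomplete-sample ratio 0.5, clusters each view's visible instances with
kernel k-means, builds an initial consensus by zero-filling + multiple
kernel k-means, and refines it by late fusion.
"""

import latefuse as lf

spec = lf.SyntheticSpec(n_samples=300, n_views=3, n_clusters=4, seed=1)
data = lf.synthetic_multiview(spec)
data.mask = lf.generate_mask(
    data.n_samples, data.n_views, lf.MissingnessSpec(epsilon=0.5, q0=0.5, seed=2)
)

assignments = lf.cluster_each_view(data, k=4, seed=0)
y0 = lf.build_initial_decision("zf", data, assignments, k=4, seed=0)
state = lf.fuse(assignments, data.mask, y0, init_method="zf")

print(f"incomplete samples: {(data.mask.sum(axis=1) < data.n_views).sum()} of {data.n_samples}")
print(f"initial NMI (zero-fill + MKKM): {lf.nmi(y0.labels(), data.labels):.3f}")
print(f"fused   NMI (late fusion):      {lf.nmi(state.decision.labels(), data.labels):.3f}")
print(
    f"objective {state.objective_trace[0]:.2f} -> {state.objective_trace[-1]:.2f} "
    f"in {state.n_iterations} iterations (converged={state.converged})"
)
# The fused NMI exceeding the initial NMI shows the consensus step
# recovering cluster structure that imputation + early fusion missed.
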