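"""Stability of visible-instance clustering under random missingness.

The premise of late fusion: if instances go missing at random (independently
of cluster membership), the visible instances of a view keep the view's
cluster structure.  Three well-separated 2-D Gaussians are clustered after
deleting 10-50% of the points, 100 times per ratio.
"""

import latefuse as lf

study = lf.random_missing_study(
    n_per_cluster=100, ratios=(0.1, 0.2, 0.3, 0.4, 0.5), n_repeats=100, seed=0
)
print(f"complete-data ACC: {study['complete_acc']:.3f}")
print("ratio  mean visible ACC  mean centroid drift")
for ratio, row in study["per_ratio"].items():
    print(f" {ratio:.1f}   {row['mean_acc']:.3f}             {row['mean_drift']:.3f}")
# Mean ACC staying within a few hundredths of the complete-data ACC, and
# centroid drift far below the ~4.0 gap between cluster means, is what makes
# per-view partitions trustworthy inputs for the consensus step.
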