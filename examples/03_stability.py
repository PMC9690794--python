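"""Bootstrap precision and case-dropping stability of an estimated network.

Edge weights are bootstrapped by resampling respondents; stability of edge
weights and node strength is summarised by the correlation stability (CS)
coefficient: the largest share of the sample that can be dropped while the
re-estimated statistic still correlates >= 0.7 with the original in 95% of
subsamples (>= 0.25 acceptable, >= 0.50 good). Replicate counts here are
kept small so the example runs in about a minute; increase them (the
analysis default is 2500) for publication-grade intervals.
"""

import ordnet

model = ordnet.generate_true_ggm(seed=1)
data = ordnet.sample_ordinal(model, n=1000, seed=2)

eb = ordnet.bootstrap_edges(data, n_boot=100, seed=3)
print(f"edge bootstrap ({eb.n_boot} replicates): sample estimates vs "
      f"bootstrap means correlate at {eb.mean_estimate_correlation():.3f}")
print(eb.table.reindex(eb.table.estimate.abs().nlargest(3).index)[
    ["node_i", "node_j", "estimate", "boot_mean", "ci_low", "ci_high"]
].round(3).to_string(index=False))

grid = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
for stat in ("edges", "strength"):
    res = ordnet.case_dropping_bootstrap(
        data, statistic=stat, drop_grid=grid, n_per_level=30, seed=4
    )
    cs = ordnet.cs_from_result(res)
    print(f"CS({stat}) = {cs}  "
          f"(mean subsample correlation per drop level: "
          f"{res.mean_correlations().round(2).to_dict()})")
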