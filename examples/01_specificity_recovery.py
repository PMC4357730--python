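"""Target-site specificity from binding-position distributions.

Simulates three AFM experiments of protein binding positions on a 549 bp
fragment carrying a G:U mismatch at 46% of its length, with ground-truth
specificity S = 163, then recovers S with the histogram / fixed-width
Gaussian-peak estimator (4% bins, 5% end exclusion, width 3.2%).
"""

import afmscan as a

S_TRUE = 163.0  # ground-truth target-site specificity
N_PER_EXPERIMENT = 371

N = a.considered_sites(549)  # 494 considered binding sites
print(f"considered binding sites on 549 bp (5% end zones excluded): {N}")

fractions = [
    100 * a.sample_positions(N_PER_EXPERIMENT, S_TRUE, N,
                             end_fraction=0.15, peak_center=0.46,
                             peak_width=0.032, rng=sub)
    for sub in a.experiment_seeds(master_seed=1, n_experiments=3)
]
result = a.analyze_positions(fractions, N)

print(f"per-experiment S: "
      + ", ".join(f"{s:.0f}" for s in result.per_experiment_S))
print(f"recovered S = {result.S_mean:.0f} +- {result.S_sd:.0f} "
      f"(ground truth {S_TRUE:.0f})")
print(f"pooled fit: peak at {result.peak_center:.1f}% of fragment length, "
      f"A_spec/A_nsp = {result.A_spec / result.A_nsp:.3f}")
# S ~ 163 means a complex is ~163x more likely to sit on the lesion than
# on any single nonspecific site; S = 1 would mean no preference at all.
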