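"""2-AP base-flipping assay: delta_I at 373 nm from titration spectra.

Simulates duplicate titrations of protein onto 2-AP DNA for an active
base-flipping enzyme and a flipping-deficient variant, subtracts
protein-only reference spectra, and quantifies the fluorescence change
delta_I = I(DNA+protein) - I(DNA) at the 373 nm emission maximum.
"""

import numpy as np

import afmscan as a


def endpoint_deltas(delta_max_cps, n_replicates=2, seed0=10):
    out = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed0 + rep)
        spectra = a.simulate_titration(baseline_cps=1.8e5,
                                       delta_max_cps=delta_max_cps,
                                       rng=rng, replicate=rep)
        corrected = {c: a.subtract_reference(
            s, a.simulate_reference(c, rng=rng, replicate=rep))
            for c, s in spectra.items()}
        out.append(a.delta_I(corrected[0.0], corrected[5.0]))
    return out


wt = endpoint_deltas(1.0e5)
mutant = endpoint_deltas(5.0e3, seed0=20)

for name, d in (("wt", wt), ("mutant", mutant)):
    mean, sd = a.replicate_summary(d)
    print(f"{name:6s}: delta_I = ({mean / 1e5:.2f} +- {sd / 1e5:.2f}) "
          f"x 10^5 CPS")
t, p, cls = a.compare_conditions(wt, mutant)
print(f"wt vs mutant: one-tailed P = {p:.3g} ({cls})")
# a positive delta_I reports unstacking of the base next to the 2-AP
# probe (flipping into the enzyme's active site); the deficient variant
# shows no comparable increase.
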