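"""Intrinsic DNA bending at a lesion site, without protein.

Part 1 decomposes site bend angles drawn from the published protein-free
G:U model (straight 64%, ~30 deg in 36% of molecules) with a folded
double-Gaussian fit.

Part 2 probes simulated worm-like chains with the protein-sized mask
(site-mode bend scan) to show the thermal noise floor of the
measurement: tangents fit across a ~20 nm gap on a 50 nm persistence
length chain fluctuate by ~20-25 deg, which is why narrowly separated
states require either stiffer chains or many molecules to resolve.
"""

import numpy as np

import afmscan as a
from afmscan.presets import INTRINSIC_BENDS

preset = INTRINSIC_BENDS["G:U"]

# --- part 1: state decomposition at the published sample size -------------
angles = a.sample_bend_angles(preset.n, preset.states,
                              preset.shared_sd_deg, rng=4)
mix = a.fit_mixture(a.bin_angles(angles), k=2, fold_at_zero=True)
print(f"site angles, n = {mix.n}:")
for mean, frac in zip(mix.means, mix.fractions_pct):
    label = "straight" if mean < 10 else "slightly bent"
    print(f"  {label:13s} ({mean:4.1f} +- {mix.shared_sd:.0f} deg): "
          f"{frac:.0f}%")
print("generating truth: straight 64%, bent-at-30-deg 36%\n")

# --- part 2: the measurement noise floor of the site scan -----------------
rng = np.random.default_rng(4)
measured = []
for _ in range(200):
    chain = a.generate_wlc_chain(165.0, 50.0, 1.0, rng)
    scan = a.intrinsic_bend_scan(a.PolylineTrace(0, chain),
                                 site_fraction=0.46, mask_radius=5.0,
                                 arm_window=8.0)
    if scan:
        measured.append(scan[0][1])
measured = np.array(measured)
print(f"site-mode scan of {len(measured)} straight (no-kink) chains: "
      f"semi-Gaussian spread {np.sqrt(np.mean(measured ** 2)):.0f} deg")

stiff = []
for _ in range(50):
    chain = a.generate_wlc_chain(165.0, 5000.0, 1.0, rng)
    chain = a.impose_kink(chain, 0.46 * 165.0, 30.0, rng)
    scan = a.intrinsic_bend_scan(a.PolylineTrace(0, chain),
                                 site_fraction=0.46, mask_radius=5.0,
                                 arm_window=8.0)
    stiff.append(scan[0][1])
print(f"30 deg kink on near-rigid chains recovered as "
      f"{np.mean(stiff):.1f} +- {np.std(stiff):.1f} deg")
# thermal tangent fluctuations, not the estimator, set the ~20 deg width
# seen when scanning flexible DNA; on rigid chains the kink is exact.
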