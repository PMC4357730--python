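# afmscan

Single-molecule AFM analysis of protein–DNA complexes, built for studies
of how DNA-repair glycosylases (e.g. thymine-DNA glycosylase or
8-oxoguanine glycosylase) locate and interrogate single target lesions
embedded in long DNA fragments. The package quantifies, from traced DNA
backbones and annotated complex positions:

* **Target-site specificity.** Binding positions (distance to the closer
  fragment end, as % of length) are binned at 4% above a 5% end-exclusion
  zone and fitted with a fixed-width Gaussian peak over a flat background,
  `y(x) = y0 + A·G(x − c) + A·G(x − (100 − c))` (the mirror term accounts
  for folding of near-centre peaks at 50%). With peak area
  `A_spec = A·w·√(2π)`, background area `A_nsp = 45·y0` and `N` considered
  binding sites,

      S = N · A_spec / A_nsp + 1

  so `S = 1` means no site preference and `S ≈ 150–360` the moderate
  lesion specificities typical of glycosylases on mismatch substrates.

* **DNA bend-angle conformational states.** Bend angles
  `β = 180° − α` (α the angle between backbone tangents flanking the
  site) are binned at 8° and decomposed by least squares into k ≤ 3
  Gaussian components with one shared width; a straight-DNA state is a
  semi-Gaussian pinned at 0°. Integrated peak areas give state fractions
  (search complex ~30°, interrogation complex ~70°), compared across
  conditions with a one-tailed Student's t-test.

* **Volume → molecular weight.** AFM particle volumes map to approximate
  MW through the empirical calibration `MW = (V + 5.9)/1.2`, separating
  monomeric from dimeric complexes.

* **2-AP base flipping.** Emission spectra of 2-aminopurine DNA are
  reference-subtracted and the flipping signal is
  `ΔI = I(DNA+protein, 373 nm) − I(DNA, 373 nm)`.

A ground-truthed synthetic generator (2-D equilibrated worm-like-chain
DNA at 50 nm persistence length, rendered height maps with tip dilation,
samplers for positions / bend states / volumes / spectra) emulates the
study conditions so every estimator is validated by parameter recovery —
no instrument data required. An image pipeline (scanline flattening,
skeleton tracing, complex detection, volume integration) automates the
measurements for rendered or real height maps.

## Worked example

Recover a known specificity from simulated binding positions
(`examples/01_specificity_recovery.py`):

```python
import afmscan as a

N = a.considered_sites(549)          # 494 sites after 2 x 5% end zones
fractions = [100 * a.sample_positions(371, 163.0, N, end_fraction=0.15,
                                      peak_center=0.46, peak_width=0.032,
                                      rng=sub)
             for sub in a.experiment_seeds(master_seed=1, n_experiments=3)]
result = a.analyze_positions(fractions, N)
```

prints

```
considered binding sites on 549 bp (5% end zones excluded): 494
per-experiment S: 125, 218, 129
recovered S = 157 +- 53 (ground truth 163)
pooled fit: peak at 46.0% of fragment length, A_spec/A_nsp = 0.315
```

i.e. three experiments of 371 complexes recover the generating
specificity within replicate scatter, with the fitted peak on the lesion
position. Bend-state decomposition
(`examples/02_bend_states.py`) on 128 simulated lesion-complex angles:

```
n = 128 bend angles, R^2 = 0.985
  state at  28.1 +- 8 deg: 32% of complexes
  state at  65.5 +- 8 deg: 68% of complexes
```

recovering the generating 33%/67% search/interrogation split. The other
examples cover the rendered-image round trip (trace, detect, volumes),
the 2-AP flipping contrast between an active and a flipping-deficient
variant, and intrinsic lesion bending in protein-free DNA.

## Command line

`afmscan simulate | measure | analyze-positions | analyze-bends |
analyze-fluor | report` chain the stages over TSV tables, so externally
traced data can replace the simulator at any point. Exit codes: 0 ok,
2 empty result, 3 fit failure, 4 invalid input.

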