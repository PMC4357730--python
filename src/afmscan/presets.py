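"""Published study conditions used as simulation ground truth.

Each preset bundles the fitted parameters reported for one
protein/substrate combination — target-site specificity S with its pooled
sample size, or a bend-angle state mixture (state means, one shared width,
integrated-area fractions, sample size).  The synthetic generator treats
these as ground truth so that every estimator can be validated by
parameter recovery under realistic sample sizes.

Straight-DNA states are pinned at 0 deg in the generator (the folded model
cannot distinguish a -2 deg fit artifact from 0).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SpecificityPreset:
    protein: str
    substrate: str
    S: float  # target-site specificity
    S_sd: float
    n: int  # binding positions per condition


@dataclass(frozen=True)
class BendPreset:
    protein: str  # "none" for intrinsic (protein-free) DNA bending
    substrate: str
    means_deg: tuple[float, ...]  # non-decreasing state means
    shared_sd_deg: float
    weights: tuple[float, ...]  # integrated-area fractions, sum to 1
    n: int
    folded: bool  # leading state is the straight (0 deg) semi-Gaussian

    @property
    def states(self) -> list[tuple[float, float]]:
        return list(zip(self.means_deg, self.weights))


SPECIFICITY: dict[str, SpecificityPreset] = {
    "hTDG-N140A/G:U": SpecificityPreset("hTDG N140A", "G:U", 163.0, 47.0, 371),
    "hTDG-N140A/G:T": SpecificityPreset("hTDG N140A", "G:T", 305.0, 95.0, 364),
    "hTDG-R275A/G:UF": SpecificityPreset("hTDG R275A", "G:UF", 358.0, 101.0, 375),
}

PROTEIN_BENDS: dict[str, BendPreset] = {
    "hTDG-wt/nsp1813": BendPreset(
        "hTDG wt", "nsp DNA 1813 bp", (33.0, 68.0), 11.0, (0.46, 0.54), 442, False),
    "hTDG-N140A/G:U": BendPreset(
        "hTDG N140A", "G:U", (29.0, 68.0), 10.0, (0.33, 0.67), 128, False),
    "hTDG-N140A/G:T": BendPreset(
        "hTDG N140A", "G:T", (26.0, 65.0), 15.0, (0.42, 0.58), 155, False),
    "hTDG-N140A/nsp549": BendPreset(
        "hTDG N140A", "nsp DNA 549 bp", (31.0, 65.0), 12.0, (0.39, 0.61), 247, False),
    "hTDG-R275A/nsp1813": BendPreset(
        "hTDG R275A", "nsp DNA 1813 bp", (0.0, 34.0, 65.0), 13.0,
        (0.57, 0.36, 0.07), 424, True),
    "hTDG-R275A/G:UF": BendPreset(
        "hTDG R275A", "G:UF", (0.0, 37.0, 66.0), 12.0,
        (0.45, 0.40, 0.15), 215, True),
    "hOGG1-wt/nsp1813": BendPreset(
        "hOGG1 wt", "nsp DNA 1813 bp", (0.0, 33.0, 70.0), 9.0,
        (0.44, 0.20, 0.36), 450, True),
}

INTRINSIC_BENDS: dict[str, BendPreset] = {
    "G:U": BendPreset("none", "G:U", (0.0, 30.0), 8.0, (0.64, 0.36), 241, True),
    "G:UF": BendPreset("none", "G:UF", (0.0, 33.0), 12.0, (0.63, 0.37), 198, True),
    "G:T": BendPreset("none", "G:T", (0.0, 31.0), 9.0, (0.68, 0.32), 228, True),
    "8oxoG:C": BendPreset("none", "8oxoG:C", (0.0, 36.0), 15.0, (0.78, 0.22), 181, True),
    "nsp549": BendPreset("none", "nsp DNA 549 bp", (0.0,), 18.0, (1.0,), 209, True),
    "nsp1813": BendPreset("none", "nsp DNA 1813 bp", (0.0,), 23.0, (1.0,), 260, True),
    "nsp-pooled": BendPreset("none", "nsp DNA pooled", (0.0,), 21.0, (1.0,), 469, True),
}

#: measured fragment-length distribution: Gaussian centre and SD, nm
LENGTH_FIT_NM = (165.0, 24.0)
#: lesion position as fraction of fragment length
SITE_FRACTION = 0.46
#: monomer molecular weight of the glycosylase, kDa
MONOMER_MW_KDA = 46.0
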