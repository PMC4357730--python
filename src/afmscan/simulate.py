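"""Ground-truthed synthetic AFM datasets of protein-DNA complexes.

The generator emulates the statistical structure of dried-on-mica AFM
observations of a glycosylase scanning long DNA fragments:

* DNA fragments are 2-D equilibrated worm-like chains (WLC) with a
  persistence length of ~50 nm, deposited flat; a 549 bp fragment at
  0.3005 nm/bp gives the 165 nm measured contour-length scale.
* One protein complex per fragment.  Its binding position is either an
  end-binder (helix fraying attracts repair proteins to fragment ends),
  a specific binder drawn from a Gaussian peak at the lesion site
  (46% of fragment length), or a nonspecific binder uniform along the
  considered interior.  The specific share is controlled by a ground-truth
  specificity S through phi = r / (1 + r), r = (S - 1) / N_sites, which is
  exactly the share the histogram/Gaussian estimator inverts.
* Bend angles at bound sites are drawn from a small mixture of
  conformational states (search complex ~30 deg, interrogation complex
  ~70 deg, straight 0 deg) with one shared Gaussian width, folded at zero
  because AFM bend angles are unsigned.
* Particle volumes follow the inverse of the AFM volume-to-molecular-weight
  calibration V = 1.2 MW - 5.9 for a monomer/dimer Bernoulli mixture.

Every emitted complex has exactly one ground-truth row, so each analysis
stage can be validated by parameter recovery without any instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import ComplexRecord, PolylineTrace, arc_coordinates, contour_length

#: nm of helical rise per base pair as measured on mica (B-form 0.34 nm/bp
#: overestimates surface-measured lengths); 549 bp x 0.3005 = 165 nm
DEFAULT_RISE_PER_BP = 0.3005


@dataclass
class SimulationConfig:
    """Parameters of one synthetic AFM experiment series."""

    n_fragments: int = 371
    fragment_bp: int = 549
    rise_per_bp: float = DEFAULT_RISE_PER_BP
    persistence_length: float = 50.0  # nm
    step_length: float = 2.5  # nm, WLC discretisation
    site_fraction: float = 0.46  # lesion position as fraction of length
    specificity_S_true: float = 163.0
    end_bound_fraction: float = 0.15
    end_zone_fraction: float = 0.05
    position_peak_width: float = 3.2  # % of fragment length (Gaussian sd)
    bend_states: list[tuple[float, float]] = field(
        default_factory=lambda: [(29.0, 0.33), (68.0, 0.67)])
    bend_shared_sd: float = 10.0  # deg
    intrinsic_site_states: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 0.64), (30.0, 0.36)])
    intrinsic_shared_sd: float = 8.0  # deg
    monomer_mw: float = 46.0  # kDa
    dimer_fraction: float = 0.1
    volume_noise_sd: float = 5.0  # nm^3
    n_experiments: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.rise_per_bp <= 0 or self.persistence_length <= 0 \
                or self.step_length <= 0:
            raise InvalidParameterError("geometry parameters must be positive")
        if self.specificity_S_true < 1:
            raise InvalidParameterError("specificity_S_true must be >= 1")
        if not 0 < self.site_fraction < 1:
            raise InvalidParameterError("site_fraction must be in (0, 1)")
        if not 0 <= self.end_bound_fraction <= 1:
            raise InvalidParameterError("end_bound_fraction must be in [0, 1]")
        for states in (self.bend_states, self.intrinsic_site_states):
            _validate_states(states)

    @property
    def contour_length_nm(self) -> float:
        return self.fragment_bp * self.rise_per_bp

    @property
    def n_sites(self) -> int:
        """Considered binding sites after excluding both end zones."""
        from .specificity import considered_sites
        return considered_sites(self.fragment_bp, self.end_zone_fraction)


def _validate_states(states: Sequence[tuple[float, float]]) -> None:
    if not states:
        raise InvalidParameterError("state list must not be empty")
    means = np.array([m for m, _ in states], float)
    weights = np.array([w for _, w in states], float)
    if np.any(means < 0):
        raise InvalidParameterError("state means must be >= 0")
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("state weights must be >= 0 and sum to 1")


def experiment_seeds(master_seed: int, n_experiments: int) -> list[int]:
    """Per-experiment sub-seeds derived from one master seed.

    Fixed increments keep the three-experiment pooling structure
    reproducible while decorrelating the experiments.
    """
    return [(int(master_seed) * 1000 + 7919 * k) % (2**31 - 1)
            for k in range(n_experiments)]


def generate_wlc_chain(
    contour_length_nm: float,
    persistence_length: float,
    step: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a 2-D equilibrated worm-like chain as an (n, 2) polyline (nm).

    Successive turning angles are independent N(0, step / P): in two
    dimensions this gives the tangent correlation <t(0).t(s)> = exp(-s/2P)
    and mean squared end-to-end distance
    4 P L [1 - (2P/L)(1 - exp(-L/2P))].
    """
    if contour_length_nm <= step or step <= 0 or persistence_length <= 0:
        raise InvalidParameterError(
            "require contour_length > step > 0 and persistence_length > 0")
    rng = np.random.default_rng(rng)
    n_steps = int(np.ceil(contour_length_nm / step))
    theta0 = rng.uniform(0, 2 * np.pi)
    turns = rng.normal(0.0, np.sqrt(step / persistence_length), size=n_steps - 1)
    headings = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = step * np.column_stack([np.cos(headings), np.sin(headings)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def impose_kink(points: np.ndarray, s: float, bend_deg: float,
                rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Rigidly rotate the downstream half of a chain to set a kink at arc s.

    The turning angle at the vertex nearest arc position ``s`` is replaced
    by ``+/- bend_deg`` (random sign), modelling a protein-induced or
    intrinsic lesion bend superimposed on the thermal conformation.
    """
    rng = np.random.default_rng(rng)
    pts = np.asarray(points, float).copy()
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    i = int(np.clip(np.argmin(np.abs(arc - s)), 1, len(pts) - 2))
    # current turning angle at vertex i
    d1 = pts[i] - pts[i - 1]
    d2 = pts[i + 1] - pts[i]
    current = np.arctan2(d2[1], d2[0]) - np.arctan2(d1[1], d1[0])
    target = np.deg2rad(bend_deg) * rng.choice([-1.0, 1.0])
    rot = target - current
    c, s_ = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s_], [s_, c]])
    pts[i + 1:] = (pts[i + 1:] - pts[i]) @ R.T + pts[i]
    return pts


def _fold_unit_half(x: np.ndarray) -> np.ndarray:
    """Fold real values into [0, 0.5] (triangular fold: reflect at 0 and 0.5)."""
    x = np.abs(x) % 1.0
    return np.where(x > 0.5, 1.0 - x, x)


def sample_positions(
    n: int,
    S_true: float,
    N_sites: int,
    end_fraction: float = 0.15,
    peak_center: float = 0.46,
    peak_width: float = 0.032,
    end_zone: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample fractional binding positions in [0, 0.5].

    With probability ``end_fraction`` a position falls in the end zone
    [0, end_zone).  Otherwise it is specific with probability
    phi = r / (1 + r), r = (S_true - 1) / N_sites — the exact inverse of the
    specificity statistic S = N A_spec / A_nsp + 1 — drawn from
    N(peak_center, peak_width); nonspecific positions are uniform over
    (end_zone, 0.5].  All draws are folded into [0, 0.5] (positions are
    distances to the closer fragment end).
    """
    if S_true < 1:
        raise InvalidParameterError("S_true must be >= 1")
    if N_sites < 1:
        raise InvalidParameterError("N_sites must be >= 1")
    rng = np.random.default_rng(rng)
    r = (S_true - 1.0) / N_sites
    phi = r / (1.0 + r)
    u = rng.uniform(size=n)
    is_end = u < end_fraction
    is_specific = ~is_end & (rng.uniform(size=n) < phi)
    out = rng.uniform(end_zone, 0.5, size=n)  # nonspecific default
    out[is_end] = rng.uniform(0.0, end_zone, size=int(is_end.sum()))
    out[is_specific] = rng.normal(peak_center, peak_width,
                                  size=int(is_specific.sum()))
    return _fold_unit_half(out)


def sample_bend_angles(
    n: int,
    states: Sequence[tuple[float, float]],
    shared_sd: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample unsigned bend angles (deg) from a folded Gaussian state mixture.

    A state is drawn categorically by weight; the angle is |N(mean, sd)|
    with one shared sd across states, folded at 0 (and at 180, which only
    matters for extreme parameters).  Matches the unsigned bend-angle
    distributions measured from AFM topographs.
    """
    _validate_states(states)
    if shared_sd <= 0:
        raise InvalidParameterError("shared_sd must be > 0")
    rng = np.random.default_rng(rng)
    means = np.array([m for m, _ in states], float)
    weights = np.array([w for _, w in states], float)
    idx = rng.choice(len(states), size=n, p=weights)
    angles = np.abs(rng.normal(means[idx], shared_sd))
    angles = np.where(angles > 180.0, 360.0 - angles, angles)
    return angles


def sample_bend_states(
    n: int,
    states: Sequence[tuple[float, float]],
    shared_sd: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`sample_bend_angles` but also returns the state indices."""
    _validate_states(states)
    rng = np.random.default_rng(rng)
    means = np.array([m for m, _ in states], float)
    weights = np.array([w for _, w in states], float)
    idx = rng.choice(len(states), size=n, p=weights)
    angles = np.abs(rng.normal(means[idx], shared_sd))
    angles = np.where(angles > 180.0, 360.0 - angles, angles)
    return idx, angles


def sample_volumes(
    n: int,
    monomer_mw: float = 46.0,
    dimer_fraction: float = 0.1,
    noise_sd: float = 5.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample AFM particle volumes (nm^3) for a monomer/dimer mixture.

    Each particle is a dimer with probability ``dimer_fraction``; its
    noiseless volume is the inverse calibration V = 1.2 MW - 5.9 with
    MW the monomer or dimer molecular weight, plus N(0, noise_sd).

    Returns (oligomeric_state, volumes) with state 1 = monomer, 2 = dimer.
    """
    if monomer_mw <= 0:
        raise InvalidParameterError("monomer_mw must be > 0")
    if not 0 <= dimer_fraction <= 1:
        raise InvalidParameterError("dimer_fraction must be in [0, 1]")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng)
    state = np.where(rng.uniform(size=n) < dimer_fraction, 2, 1)
    mw = state * monomer_mw
    v = 1.2 * mw - 5.9
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return state, v


def simulate_experiment(
    config: SimulationConfig,
    experiment: int,
    seed: int,
) -> tuple[list[PolylineTrace], list[ComplexRecord], pd.DataFrame]:
    """Simulate one AFM experiment: traces, complexes, and ground truth.

    Each fragment carries one protein complex.  Ground truth records the
    sampled position fraction, bend state and angle, volume and oligomeric
    state for every emitted complex (bijective with the complex list).
    """
    rng = np.random.default_rng(seed)
    L = config.contour_length_nm
    n = config.n_fragments

    fractions = sample_positions(
        n, config.specificity_S_true, config.n_sites,
        end_fraction=config.end_bound_fraction,
        peak_center=config.site_fraction,
        peak_width=config.position_peak_width / 100.0,
        end_zone=config.end_zone_fraction, rng=rng)
    bend_idx, bend_angles = sample_bend_states(
        n, config.bend_states, config.bend_shared_sd, rng=rng)
    intr_idx, intr_angles = sample_bend_states(
        n, config.intrinsic_site_states, config.intrinsic_shared_sd, rng=rng)
    oligo, volumes = sample_volumes(
        n, config.monomer_mw, config.dimer_fraction,
        config.volume_noise_sd, rng=rng)

    peak_w = config.position_peak_width / 100.0
    traces: list[PolylineTrace] = []
    records: list[ComplexRecord] = []
    truth_rows = []
    for i in range(n):
        pts = generate_wlc_chain(L, config.persistence_length,
                                 config.step_length, rng)
        # which end of the chain the "closer end" is: random orientation
        s_frac = fractions[i] if rng.uniform() < 0.5 else 1.0 - fractions[i]
        s = s_frac * contour_length(PolylineTrace(i, pts))
        is_specific_site = abs(fractions[i] - config.site_fraction) <= 2 * peak_w
        # intrinsic lesion bend at the target site, overridden when the
        # protein sits on the site itself
        site_s = config.site_fraction * L
        if not is_specific_site:
            pts = impose_kink(pts, site_s, intr_angles[i], rng)
        pts = impose_kink(pts, s, bend_angles[i], rng)
        trace = PolylineTrace(fragment_id=i, points=pts)
        traces.append(trace)
        records.append(ComplexRecord(
            fragment_id=i, s_nm=s, volume_nm3=volumes[i],
            experiment=experiment))
        truth_rows.append(dict(
            experiment=experiment, fragment_id=i,
            true_position_fraction=fractions[i],
            true_bend_state=int(bend_idx[i]),
            true_bend_deg=float(bend_angles[i]),
            true_intrinsic_state=int(intr_idx[i]),
            true_intrinsic_deg=float(intr_angles[i]),
            true_volume_nm3=float(volumes[i]),
            oligomeric_state=int(oligo[i]),
            true_contour_nm=float(contour_length(trace)),
        ))
    return traces, records, pd.DataFrame(truth_rows)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[int, list[PolylineTrace]], list[ComplexRecord], pd.DataFrame]:
    """Simulate ``config.n_experiments`` experiments from one master seed.

    Returns per-experiment traces, the pooled complex records, and the
    pooled ground-truth table.
    """
    traces_by_exp: dict[int, list[PolylineTrace]] = {}
    records: list[ComplexRecord] = []
    truths = []
    for k, sub in enumerate(experiment_seeds(config.seed,
                                             config.n_experiments)):
        tr, rec, truth = simulate_experiment(config, k, sub)
        traces_by_exp[k] = tr
        records.extend(rec)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return traces_by_exp, records, truth
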