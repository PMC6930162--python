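"""Synthetic biosensor data with known ground truth.

Generates the statistical structure of the live-cell experiments the analysis
modules operate on:

* carbachol-evoked Ca²⁺ transients sampled every 2 s that decay exponentially,
  with per-cell amplitude α and clearance rate θ drawn from discrete profile
  families (blunted through full Gq responses);
* bPAC-pulse cAMP traces sampled every 20 s (pulse at 100 s, 15-min window)
  whose decay back to baseline follows a decreasing logistic, in
  rapid/intermediate/delayed half-life families;
* per-cell ER-stress scores negatively coupled to the Ca²⁺ response maximum;
* two-channel (red expression / green stress) nuclear images with ground-truth
  label masks.

Ground truth is returned alongside every data set and is never consumed by
the analysis modules; all generators draw from one explicit seeded stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .traces import Trace, TraceSet

log = logging.getLogger("sigprof")

__all__ = [
    "ProfileFamily",
    "AcquisitionPlan",
    "GroundTruth",
    "CA_PLAN",
    "CAMP_PLAN",
    "CA_FAMILIES",
    "CAMP_FAMILIES",
    "CAMP_FAMILIES_TWO",
    "gen_ca_traces",
    "gen_camp_traces",
    "gen_stress_correlated_cells",
    "gen_stress_images",
]


@dataclass(frozen=True)
class ProfileFamily:
    """A discrete class of single-cell response shapes.

    ``amplitude_range`` is a ΔF/F interval for α; ``rate_range`` is an s⁻¹
    interval for the decay rate θ (the sigmoid steepness |θ| for logistic
    families); ``t_half_range`` (logistic families only) is the half-life
    interval in seconds; ``weight`` is the family's population fraction.
    """

    name: str
    amplitude_range: Tuple[float, float]
    rate_range: Tuple[float, float]
    shape: str = "exponential_transient"
    weight: float = 1.0
    t_half_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.shape not in ("exponential_transient", "logistic_decay"):
            raise ValueError(f"unknown shape {self.shape!r}")
        a_lo, a_hi = self.amplitude_range
        r_lo, r_hi = self.rate_range
        if a_lo < 0 or a_hi < a_lo:
            raise ValueError("invalid amplitude_range")
        if r_lo <= 0 or r_hi < r_lo:
            raise ValueError("rate_range must have a positive lower bound")
        if not 0 < self.weight <= 1:
            raise ValueError("weight must be in (0, 1]")
        if self.shape == "logistic_decay" and self.t_half_range is None:
            raise ValueError("logistic families need a t_half_range")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Sampling schedule of one imaging run (seconds)."""

    sample_interval: float
    total_duration: float
    stimulus_time: float
    baseline_frames: int

    def __post_init__(self) -> None:
        if self.stimulus_time >= self.total_duration:
            raise ValueError("stimulus_time must precede total_duration")
        if self.baseline_frames * self.sample_interval > self.stimulus_time:
            raise ValueError("baseline frames extend past the stimulus")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.total_duration / self.sample_interval)) + 1
        return np.arange(n) * self.sample_interval


@dataclass
class GroundTruth:
    """Per-cell generative truth, carried next to a data set.

    Never consumed by analysis operations; used only to score them.
    """

    table: pd.DataFrame


#: Ca²⁺ imaging: frames every 2 s, carbachol at 100 s, 300 s total.
CA_PLAN = AcquisitionPlan(sample_interval=2.0, total_duration=300.0,
                          stimulus_time=100.0, baseline_frames=50)

#: cAMP imaging: frames every 20 s, bPAC blue-light pulse at 100 s,
#: 15 min (900 s) post-pulse window.
CAMP_PLAN = AcquisitionPlan(sample_interval=20.0, total_duration=1000.0,
                            stimulus_time=100.0, baseline_frames=5)

#: Four Ca²⁺ response families spanning blunted to full Gq responses.  The
#: families differ jointly in amplitude and clearance kinetics: a blunted
#: fast-clearing spike, a blunted slow (sustained) response, a full response
#: with slow clearance, and a large response with moderate clearance.
CA_FAMILIES = (
    ProfileFamily("blunted_fast", (0.05, 0.25), (0.085, 0.095), "exponential_transient", 0.25),
    ProfileFamily("blunted_sustained", (0.30, 0.60), (0.020, 0.030), "exponential_transient", 0.25),
    ProfileFamily("full_sustained", (0.90, 1.40), (0.035, 0.045), "exponential_transient", 0.25),
    ProfileFamily("full_moderate", (1.80, 2.50), (0.055, 0.065), "exponential_transient", 0.25),
)

#: Three cAMP degradation families: rapid/intermediate/delayed half-lives,
#: all decaying observably within the 900-s post-pulse window.  The bPAC
#: pulse drives every cell to a similar peak, so amplitudes share one narrow
#: band and the families differ in decay kinetics only; steepness bands keep
#: k*t_half >= ~3 so each trace starts near its plateau.
CAMP_FAMILIES = (
    ProfileFamily("rapid", (1.4, 1.9), (0.050, 0.070), "logistic_decay",
                  1 / 3, t_half_range=(60.0, 120.0)),
    ProfileFamily("intermediate", (1.4, 1.9), (0.018, 0.028), "logistic_decay",
                  1 / 3, t_half_range=(180.0, 300.0)),
    ProfileFamily("delayed", (1.4, 1.9), (0.009, 0.013), "logistic_decay",
                  1 / 3, t_half_range=(420.0, 600.0)),
)

#: Two-family variant (rapid vs delayed degradation).
CAMP_FAMILIES_TWO = (
    ProfileFamily("rapid", (1.4, 1.9), (0.050, 0.070), "logistic_decay",
                  0.5, t_half_range=(60.0, 120.0)),
    ProfileFamily("delayed", (1.4, 1.9), (0.009, 0.013), "logistic_decay",
                  0.5, t_half_range=(420.0, 600.0)),
)

_WELLS = ("A1", "A2", "A3")


def _check_families(families: Sequence[ProfileFamily], shape: str) -> None:
    if not families:
        raise ValueError("empty family list")
    total = sum(f.weight for f in families)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"family weights sum to {total!r}, not 1")
    for fam in families:
        if fam.shape != shape:
            raise ValueError(f"family {fam.name!r} has shape {fam.shape!r}, expected {shape!r}")


def _assign(rng, families, n_cells):
    weights = np.array([f.weight for f in families], float)
    return rng.choice(len(families), size=n_cells, p=weights / weights.sum())


def gen_ca_traces(
    families: Sequence[ProfileFamily] = CA_FAMILIES,
    n_cells: int = 800,
    plan: AcquisitionPlan = CA_PLAN,
    noise_sd: float = 0.05,
    seed: int = 0,
    condition: str = "ca",
) -> Tuple[TraceSet, GroundTruth]:
    """Simulate carbachol-evoked Ca²⁺ transients.

    Each trace is flat (baseline noise around 0) before the stimulus, then
    follows α·e^(−θ(t−t_stim)) plus additive Gaussian noise, with (α, θ)
    drawn uniformly from the cell's family ranges.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    _check_families(families, "exponential_transient")
    rng = np.random.default_rng(seed)
    fam_idx = _assign(rng, families, n_cells)
    t = plan.times
    post = t >= plan.stimulus_time
    traces, rows = [], []
    for i in range(n_cells):
        fam = families[fam_idx[i]]
        alpha = rng.uniform(*fam.amplitude_range)
        theta = rng.uniform(*fam.rate_range)
        dff = np.zeros_like(t)
        dff[post] = alpha * np.exp(-theta * (t[post] - plan.stimulus_time))
        if noise_sd > 0:
            dff = dff + rng.normal(0.0, noise_sd, size=t.size)
        cell_id = f"{condition}_{i:05d}"
        traces.append(
            Trace(cell_id=cell_id, time=t, dff=dff,
                  stimulus_time=plan.stimulus_time,
                  well=_wells_for(i), condition=condition)
        )
        rows.append({"cell_id": cell_id, "family": fam.name,
                     "alpha": alpha, "theta": theta})
    return (
        TraceSet(traces, condition=condition),
        GroundTruth(pd.DataFrame(rows)),
    )


def _wells_for(i: int) -> str:
    return _WELLS[i % len(_WELLS)]


def gen_camp_traces(
    families: Sequence[ProfileFamily] = CAMP_FAMILIES,
    n_cells: int = 800,
    plan: AcquisitionPlan = CAMP_PLAN,
    noise_sd: float = 0.05,
    seed: int = 0,
    condition: str = "camp",
) -> Tuple[TraceSet, GroundTruth]:
    """Simulate bPAC-pulse cAMP degradation traces.

    Traces sit at baseline before the light pulse, rise at the pulse, and then
    decay back toward baseline following a decreasing logistic
    α / (1 + β·e^(−θ t')) with θ < 0 and β = e^(θ·t½), t' measured from the
    pulse.  The per-cell true half-life t½ is recorded in the ground truth.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    _check_families(families, "logistic_decay")
    if plan.total_duration - plan.stimulus_time < 900.0 - 1e-9:
        raise ValueError("plan must cover >= 15 min after the pulse")
    rng = np.random.default_rng(seed)
    fam_idx = _assign(rng, families, n_cells)
    t = plan.times
    post = t >= plan.stimulus_time
    tp = t[post] - plan.stimulus_time
    traces, rows = [], []
    for i in range(n_cells):
        fam = families[fam_idx[i]]
        alpha = rng.uniform(*fam.amplitude_range)
        k = rng.uniform(*fam.rate_range)  # sigmoid steepness |theta|
        t_half = rng.uniform(*fam.t_half_range)
        theta = -k
        beta = np.exp(theta * t_half)  # ln(beta)/theta == t_half
        dff = np.zeros_like(t)
        dff[post] = alpha / (1.0 + beta * np.exp(-theta * tp))
        if noise_sd > 0:
            dff = dff + rng.normal(0.0, noise_sd, size=t.size)
        cell_id = f"{condition}_{i:05d}"
        traces.append(
            Trace(cell_id=cell_id, time=t, dff=dff,
                  stimulus_time=plan.stimulus_time,
                  well=_wells_for(i), condition=condition)
        )
        rows.append({"cell_id": cell_id, "family": fam.name, "alpha": alpha,
                     "beta": beta, "theta": theta, "t_half": t_half})
    return (
        TraceSet(traces, condition=condition),
        GroundTruth(pd.DataFrame(rows)),
    )


def gen_stress_correlated_cells(
    n_cells: int = 500,
    slope: float = 1.8,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-cell (stress score, max Ca²⁺ ΔF/F) pairs.

    Stress scores are log-normal; the Ca²⁺ response maximum decreases
    monotonically with stress, max ΔF/F = c0 + slope·e^(−s/s0) + ε, so the
    noiseless pairs are negatively correlated.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    c0, s0 = 0.2, 1.0
    rng = np.random.default_rng(seed)
    stress = rng.lognormal(mean=0.0, sigma=0.5, size=n_cells)
    clean = c0 + slope * np.exp(-stress / s0)
    max_dff = clean + (rng.normal(0.0, noise_sd, size=n_cells) if noise_sd > 0 else 0.0)
    df = pd.DataFrame({"stress_score": stress, "max_dff": max_dff})
    gt = GroundTruth(
        pd.DataFrame({"stress_score": stress, "max_dff_clean": clean})
    )
    return df, gt


def gen_stress_images(
    n_nuclei: int = 50,
    frac_stressed: float = 0.5,
    image_size: int = 512,
    seed: int = 0,
    sigma: float = 4.0,
    background: float = 100.0,
    red_amplitude: float = 3000.0,
    green_amplitude: float = 2500.0,
    poisson_noise: bool = False,
) -> Tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a two-channel nuclear image with ground truth.

    Nuclei are 2-D Gaussian spots (sd ``sigma`` px) on a constant background,
    placed by rejection sampling without overlap (centers at least 8*sigma
    apart).  Every nucleus carries red signal; exactly
    ``round(frac_stressed * n_nuclei)`` of them additionally carry green.
    Returns (image[2, H, W] uint16 with channels (red, green), label mask
    uint16, ground-truth table).
    """
    if not 0.0 <= frac_stressed <= 1.0:
        raise ValueError("frac_stressed must be in [0, 1]")
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h = w = int(image_size)
    margin = 4.0 * sigma
    min_sep = 8.0 * sigma
    centers = []
    attempts = 0
    max_attempts = max(5000, 2000 * max(n_nuclei, 1))
    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n_nuclei} non-overlapping nuclei in a "
                f"{h}x{w} image after {max_attempts} attempts"
            )
        cand = rng.uniform(margin, [h - margin, w - margin])
        if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep**2 for r, c in centers):
            centers.append((float(cand[0]), float(cand[1])))
    n_stressed = int(round(frac_stressed * n_nuclei))
    order = rng.permutation(n_nuclei)
    stressed = np.zeros(n_nuclei, dtype=bool)
    stressed[order[:n_stressed]] = True

    rr, cc = np.mgrid[0:h, 0:w]
    red = np.full((h, w), background, dtype=float)
    green = np.full((h, w), background, dtype=float)
    mask = np.zeros((h, w), dtype=np.uint16)
    radius = 2.0 * sigma
    rows = []
    for label, ((r0, c0), is_stressed) in enumerate(zip(centers, stressed), start=1):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        spot = np.exp(-d2 / (2.0 * sigma**2))
        red += red_amplitude * spot
        if is_stressed:
            green += green_amplitude * spot
        mask[d2 <= radius**2] = label
        rows.append({"label": label, "row": r0, "col": c0,
                     "stressed": bool(is_stressed)})
    img = np.stack([red, green])
    if poisson_noise:
        img = rng.poisson(img).astype(float)
    img = np.clip(np.round(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return img, mask, GroundTruth(pd.DataFrame(rows, columns=["label", "row", "col", "stressed"]))
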