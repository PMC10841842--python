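"""Synthetic data with the statistical structure the mixture model assumes.

Emulates a single-molecule pull-down experiment at the level the analysis
consumes: per-spot photobleaching step counts drawn from sub-populations with
fixed copy numbers, independent per-molecule Bernoulli reporter activity,
zero-truncation (all-dark spots are never detected), one-step-dominated
background contamination, matched background-only control samples, two-color
spot fields with a channel registration offset, and piecewise-constant
intensity traces for the step counter. It does not render images: no PSF,
no camera noise model, no spot detection.

All generators are bit-reproducible from a single seed; independent streams
are derived with ``numpy.random.SeedSequence.spawn`` so adding one stream
never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "SimulatedSample",
    "simulate_counts",
    "simulate_control",
    "simulate_two_color",
    "simulate_traces",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Generative truth for a stoichiometry simulation.

    components : list of ``(copy_number, weight)`` pairs — the sub-population
        copy numbers ``m_i`` and their population proportions ``pi_i``.
    activity : reporter activity ``p``, the probability a single tag
        fluoresces (mNG 0.74, SNAPf 0.78 under the standard calibration).
    background_rate : expected fraction of *retained* spots that are
        background contaminants (dust, non-specific binding).
    background_step_dist : step-count distribution of contaminant spots;
        the default puts all mass at one step, matching the observation that
        control and RNase-resistant spots bleach mostly in a single step.
    """

    components: tuple
    activity: float
    background_rate: float = 0.0
    background_step_dist: Mapping[int, float] = None

    def __post_init__(self):
        comps = tuple((int(m), float(w)) for m, w in self.components)
        sizes = [m for m, _ in comps]
        weights = [w for _, w in comps]
        if not comps:
            raise ValueError("at least one sub-population is required")
        if any(m < 1 for m in sizes) or len(set(sizes)) != len(sizes):
            raise ValueError("copy numbers must be distinct positive integers")
        if any(w < 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError("sub-population weights must sum to 1")
        if not (0.0 < self.activity <= 1.0):
            raise ValueError("activity must lie in (0, 1]")
        if not (0.0 <= self.background_rate < 1.0):
            raise ValueError("background_rate must lie in [0, 1)")
        bg = self.background_step_dist
        if bg is None:
            bg = {1: 1.0}
        bg = {int(k): float(v) for k, v in bg.items()}
        if not bg or any(k < 1 for k in bg) or any(v < 0 for v in bg.values()) \
                or abs(sum(bg.values()) - 1.0) > 1e-12:
            raise ValueError("background_step_dist must be a distribution "
                             "over positive integers")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "background_step_dist", bg)

    @property
    def copy_numbers(self) -> np.ndarray:
        return np.array([m for m, _ in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    def dark_fraction(self) -> float:
        """Expected fraction of signal draws that are all-dark (discarded):
        ``sum_j pi_j (1-p)^(m_j)``."""
        q = 1.0 - self.activity
        return float(sum(w * q ** m for m, w in self.components))


@dataclass
class SimulatedSample:
    """Step counts with their generative truth.

    ``truth_labels[i]`` is the sub-population index of spot i, or -1 for a
    background contaminant. ``n_discarded_zero`` tallies all-dark signal
    draws that a real experiment would simply never detect.
    """

    counts: np.ndarray
    truth_labels: np.ndarray
    n_discarded_zero: int
    seed: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.truth_labels = np.asarray(self.truth_labels, dtype=int)
        if self.counts.shape != self.truth_labels.shape:
            raise ValueError("counts and truth_labels must align")
        if np.any(self.counts < 1):
            raise ValueError("retained counts must all be >= 1")

    def to_frame(self, condition: str = "sim", replicate: int = 1,
                 fluorophore: str = "mNG",
                 step_intensity: float = 1.0) -> pd.DataFrame:
        """Step-count table in the on-disk layout (one row per spot)."""
        return pd.DataFrame({
            "spot_id": np.arange(len(self.counts)),
            "condition": condition,
            "replicate": replicate,
            "fluorophore": fluorophore,
            "n_steps": self.counts,
            "intensity": self.counts * step_intensity,
        })


def _draw_from_dist(dist: Mapping[int, float], n: int,
                    rng: np.random.Generator) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(keys.size, size=n, p=probs)]


def simulate_counts(spec: PopulationSpec, n_target: int,
                    seed: int) -> SimulatedSample:
    """Draw ``n_target`` retained photobleaching step counts.

    Each signal draw picks sub-population j with probability ``pi_j`` and an
    active-molecule count ``Binomial(m_j, p)``; zero draws are discarded and
    tallied (in the real assay those spots simply never appear). Background
    contaminants are injected so their expected share of retained spots is
    ``spec.background_rate``.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    n_bg = int(rng.binomial(n_target, spec.background_rate)) \
        if spec.background_rate > 0 else 0
    n_signal = n_target - n_bg

    sizes, weights = spec.copy_numbers, spec.weights
    all_x: list[np.ndarray] = []
    all_lab: list[np.ndarray] = []
    n_pos = 0
    while n_pos < n_signal and n_signal > 0:
        # oversample to amortize the rejection loop
        todo = n_signal - n_pos
        batch = max(64, int(todo / max(1.0 - spec.dark_fraction(), 1e-9) * 1.2))
        lab = rng.choice(sizes.size, size=batch, p=weights)
        x = rng.binomial(sizes[lab], spec.activity)
        all_x.append(x)
        all_lab.append(lab)
        n_pos += int((x > 0).sum())
    if n_signal > 0:
        x = np.concatenate(all_x)
        lab = np.concatenate(all_lab)
        # draws stop at the n_signal-th detected spot; later draws never happened
        stop = np.flatnonzero(x > 0)[n_signal - 1] + 1
        x, lab = x[:stop], lab[:stop]
        pos = x > 0
        n_zero = int((~pos).sum())
        counts, labels = x[pos], lab[pos]
    else:
        n_zero = 0
        counts, labels = np.empty(0, int), np.empty(0, int)

    if n_bg:
        bg_counts = _draw_from_dist(spec.background_step_dist, n_bg, rng)
        counts = np.concatenate([counts, bg_counts])
        labels = np.concatenate([labels, np.full(n_bg, -1)])
    perm = rng.permutation(counts.size)
    return SimulatedSample(counts=counts[perm], truth_labels=labels[perm],
                           n_discarded_zero=n_zero, seed=seed)


def simulate_control(n_bg: int, background_step_dist: Mapping[int, float] = None,
                     seed: int = 0) -> np.ndarray:
    """Background-only step counts, emulating the non-tagged control strain."""
    if n_bg < 1:
        raise ValueError("n_bg must be >= 1")
    dist = background_step_dist or {1: 1.0}
    dist = {int(k): float(v) for k, v in dist.items()}
    if not dist or any(k < 1 for k in dist) \
            or abs(sum(dist.values()) - 1.0) > 1e-12:
        raise ValueError("background_step_dist must be a distribution over "
                         "positive integers")
    rng = np.random.default_rng(seed)
    return _draw_from_dist(dist, n_bg, rng)


def simulate_two_color(joint_spec: Mapping[tuple, float], p_a: float, p_b: float,
                       field_size: tuple = (512.0, 512.0),
                       offset: tuple = (0.0, 0.0), n_spots: int = 1000,
                       seed: int = 0, step_intensity: float = 1.0,
                       noise_sd: float = 0.1):
    """Simulate a two-channel co-localization field.

    joint_spec maps ``(n_a_molecules, n_b_molecules)`` per complex to its
    population weight. Each complex lands uniformly in the field; it appears
    in a channel iff at least one of its molecules in that channel is active
    (independent Bernoulli per molecule). Channel B coordinates are shifted
    by ``offset`` (the un-registered optical displacement); spot intensity is
    linear in the active-molecule count plus Gaussian noise.

    Returns ``(spots_a, spots_b, truth)``: two spot tables and a DataFrame
    with one row per complex giving its position and per-channel detection.
    """
    if field_size[0] <= 0 or field_size[1] <= 0:
        raise ValueError("field size must be positive")
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    items = [((int(a), int(b)), float(w)) for (a, b), w in joint_spec.items()]
    wsum = sum(w for _, w in items)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError("joint occupancy weights must sum to 1")
    for p, name in ((p_a, "p_a"), (p_b, "p_b")):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1]")

    ss = np.random.SeedSequence(seed)
    rng_pos, rng_act, rng_noise = (np.random.default_rng(s)
                                   for s in ss.spawn(3))
    combos = np.array([c for c, _ in items])
    probs = np.array([w for _, w in items])
    which = rng_pos.choice(len(items), size=n_spots, p=probs)
    n_a_mol, n_b_mol = combos[which, 0], combos[which, 1]
    x = rng_pos.uniform(0, field_size[0], n_spots)
    y = rng_pos.uniform(0, field_size[1], n_spots)
    act_a = rng_act.binomial(n_a_mol, p_a)
    act_b = rng_act.binomial(n_b_mol, p_b)

    truth = pd.DataFrame({
        "complex_id": np.arange(n_spots), "x_px": x, "y_px": y,
        "n_a_molecules": n_a_mol, "n_b_molecules": n_b_mol,
        "active_a": act_a, "active_b": act_b,
        "detected_a": act_a > 0, "detected_b": act_b > 0,
    })

    def _table(active, det, xx, yy, channel):
        ids = np.flatnonzero(det)
        inten = active[ids] * step_intensity \
            + rng_noise.normal(0, noise_sd, ids.size)
        return pd.DataFrame({
            "spot_id": ids, "x_px": xx[ids], "y_px": yy[ids],
            "intensity": np.clip(inten, 0.0, None), "channel": channel,
        })

    spots_a = _table(act_a, act_a > 0, x, y, "A")
    spots_b = _table(act_b, act_b > 0, x + offset[0], y + offset[1], "B")
    return spots_a, spots_b, truth


def simulate_traces(sample: SimulatedSample, frames: int = 400,
                    step_intensity: float = 1.0, bleach_rate: float = 0.02,
                    noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Piecewise-constant photobleaching traces for each spot.

    Every active molecule bleaches at an independent geometric time with
    per-frame hazard ``bleach_rate``; the trace is the number of surviving
    molecules times ``step_intensity`` plus Gaussian noise. ``frames`` must
    be long enough that essentially all molecules bleach within the movie
    (P > 0.99), otherwise the step counter would systematically undercount.

    Returns an ``(n_spots, frames)`` array.
    """
    if frames < 10:
        raise ValueError("frames must be >= 10")
    if step_intensity <= 0:
        raise ValueError("step_intensity must be positive")
    if not (0.0 < bleach_rate < 1.0):
        raise ValueError("bleach_rate must lie in (0, 1)")
    max_count = int(sample.counts.max())
    p_all = (1.0 - (1.0 - bleach_rate) ** frames) ** max_count
    if p_all <= 0.99:
        raise ValueError(
            f"frames={frames} too short: P(all {max_count} molecules bleach) "
            f"= {p_all:.4f} <= 0.99")
    rng = np.random.default_rng(seed)
    n = sample.counts.size
    traces = np.zeros((n, frames))
    t = np.arange(frames)
    for i, c in enumerate(sample.counts):
        bleach_t = rng.geometric(bleach_rate, size=c)  # frame of disappearance
        surviving = (bleach_t[:, None] > t[None, :]).sum(axis=0)
        traces[i] = surviving * step_intensity
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, traces.shape)
    return traces
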