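"""Turn raw per-spot step tables into analysis-ready samples.

The standard workflow: drop spots with zero counted steps, tabulate a step
histogram, subtract the scaled histogram of a non-tagged control sample
(background spots: dust, non-specifically bound protein), and report
per-step percentages with replicate means and standard deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StepHistogram",
    "remove_zero_counts",
    "build_histogram",
    "subtract_control",
    "replicate_summary",
    "normalize_to_reference",
]

log = logging.getLogger(__name__)


@dataclass
class StepHistogram:
    """Per-step spot counts and percentages for one condition/replicate.

    ``counts`` maps step number to (possibly control-corrected, hence real-
    valued) spot count; ``percentages`` always renormalize to 100 over the
    current counts. Provenance records whether a control was subtracted and
    at what scale.
    """

    counts: dict
    condition: str = ""
    replicates: tuple = ()
    control_subtracted: bool = False
    scale: float = 1.0

    def __post_init__(self):
        self.counts = {int(k): float(v) for k, v in sorted(self.counts.items())}
        if any(k < 1 for k in self.counts):
            raise ValueError("histogram steps must be positive integers")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict:
        tot = self.total
        if tot <= 0:
            raise ValueError("degenerate histogram: total count is zero")
        return {k: 100.0 * v / tot for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame({
            "step": list(self.counts),
            "count": list(self.counts.values()),
            "percent": [pct[k] for k in self.counts],
        })


def remove_zero_counts(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows with ``n_steps <= 0`` (spots where no bleaching step was
    counted), returning the cleaned table and the number removed.

    Rows flagged ``excluded`` (overlapping spots removed by the upstream
    spot-table producer) are dropped first and not counted as zeros.
    """
    if "excluded" in table.columns:
        table = table[~table["excluded"].astype(bool)]
    zero = table["n_steps"] <= 0
    n_removed = int(zero.sum())
    out = table[~zero].reset_index(drop=True)
    if out.empty:
        raise ValueError("all spots had zero counted steps; nothing to analyze")
    return out, n_removed


def build_histogram(counts, condition: str = "",
                    replicates: tuple = ()) -> StepHistogram:
    """Tabulate positive integer step counts into a StepHistogram."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty sample")
    if np.any(counts < 1):
        raise ValueError("counts must be positive; run remove_zero_counts first")
    vals, mult = np.unique(counts, return_counts=True)
    return StepHistogram(counts=dict(zip(vals.tolist(), mult.tolist())),
                         condition=condition, replicates=tuple(replicates))


def subtract_control(exp_hist: StepHistogram, ctrl_hist: StepHistogram,
                     scale: float = 1.0) -> StepHistogram:
    """Subtract a scaled non-tagged-control histogram from the experimental
    one, clipping negative corrected counts at zero.

    ``scale`` converts the control counting effort to the experimental one
    (fields imaged × dilution); it must be supplied deliberately — a silently
    mismatched effort is the main failure mode of background subtraction.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    steps = sorted(set(exp_hist.counts) | set(ctrl_hist.counts))
    corrected = {}
    for s in steps:
        e = exp_hist.counts.get(s, 0.0)
        c = scale * ctrl_hist.counts.get(s, 0.0)
        if c > e:
            log.warning("control subtraction clipped step %d: %g - %g -> 0",
                        s, e, c)
        corrected[s] = max(e - c, 0.0)
    if sum(corrected.values()) <= 0:
        raise ValueError("control subtraction removed every spot; "
                         "check the scale factor")
    return StepHistogram(counts=corrected, condition=exp_hist.condition,
                         replicates=exp_hist.replicates,
                         control_subtracted=True, scale=scale)


def replicate_summary(histograms: list[StepHistogram]) -> pd.DataFrame:
    """Per-step mean and standard deviation of percentages across replicates.

    Steps absent in a replicate contribute 0%. SD is the sample standard
    deviation (ddof=1); a single replicate reports SD 0.
    """
    if not histograms:
        raise ValueError("at least one replicate is required")
    steps = sorted({s for h in histograms for s in h.counts})
    mat = np.zeros((len(histograms), len(steps)))
    for i, h in enumerate(histograms):
        pct = h.percentages
        for j, s in enumerate(steps):
            mat[i, j] = pct.get(s, 0.0)
    sd = mat.std(axis=0, ddof=1) if len(histograms) > 1 else np.zeros(len(steps))
    return pd.DataFrame({"step": steps, "mean_percent": mat.mean(axis=0),
                         "sd_percent": sd})


def normalize_to_reference(rbp_spot_count: float, reference_spot_count: float,
                           rbp_dilution: float = 1.0,
                           reference_dilution: float = 1.0) -> float:
    """Spot frequency of an RBP normalized to a co-captured reference
    protein, both counts background-subtracted and dilution-corrected:
    ``(rbp × rbp_dilution) / (reference × reference_dilution)``.
    """
    denom = reference_spot_count * reference_dilution
    if denom <= 0:
        raise ValueError("reference spot count must be positive after "
                         "background subtraction")
    if rbp_spot_count <= 0:
        return 0.0
    return (rbp_spot_count * rbp_dilution) / denom
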