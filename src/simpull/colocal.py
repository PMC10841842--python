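"""Two-color co-localization quantitation.

Pipeline: estimate an affine channel map from fiducial beads (TetraSpeck-
style), map one channel's spot coordinates onto the other, match spots
within a pixel radius (3 px by convention), compute raw and control-
subtracted co-localization frequencies, optionally stratify the reference
spots into single- vs multi-copy classes by intensity, correct single-copy
occupancy for reporter activity, and test intensity–intensity association
between co-occupying proteins by rank correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde, rankdata

__all__ = [
    "AffineMap",
    "ColocResult",
    "estimate_channel_map",
    "match_spots",
    "coloc_frequency",
    "correct_single_copy_occupancy",
    "classify_by_intensity",
    "intensity_association",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffineMap:
    """Affine channel registration ``target = source @ A + t``."""

    matrix: tuple  # 2x2 row tuples
    translation: tuple
    rms_residual: float

    def apply(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ np.asarray(self.matrix) + np.asarray(self.translation)

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(matrix=((1.0, 0.0), (0.0, 1.0)), translation=(0.0, 0.0),
                   rms_residual=0.0)


@dataclass
class ColocResult:
    pairs: pd.DataFrame  # id_a, id_b, distance_px
    raw_frequency: float
    corrected_frequency: float
    match_radius: float
    n_reference: int
    control_frequency: float = 0.0


def estimate_channel_map(bead_pairs) -> AffineMap:
    """Least-squares affine map from >= 3 non-collinear fiducial bead pairs.

    ``bead_pairs`` is an iterable of ``((x_src, y_src), (x_dst, y_dst))`` or
    an (n, 4) array. Returns the transform plus the RMS residual in pixels.
    """
    arr = np.asarray([(sx, sy, dx, dy) for (sx, sy), (dx, dy) in bead_pairs]
                     if not isinstance(bead_pairs, np.ndarray) else bead_pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 3:
        raise ValueError("at least 3 bead coordinate pairs are required")
    src, dst = arr[:, :2], arr[:, 2:]
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("bead positions are collinear; cannot estimate an "
                         "affine map")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    pred = design @ sol
    rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    mat = sol[:2]
    return AffineMap(matrix=tuple(map(tuple, mat.T.T)),
                     translation=tuple(sol[2]), rms_residual=rms)


def match_spots(spots_a: pd.DataFrame, spots_b: pd.DataFrame,
                transform: AffineMap | None = None, max_dist: float = 3.0,
                one_to_one: bool = True) -> pd.DataFrame:
    """Match reference (A) spots to their nearest mapped B spot within
    ``max_dist`` pixels.

    ``transform`` maps B coordinates into the A frame (identity if None).
    With ``one_to_one=True`` (default) a greedy nearest-first assignment
    prevents one B spot from partnering several A spots, ties broken toward
    the smaller spot_id; with ``one_to_one=False`` each A spot simply keeps
    its nearest B spot (the literal per-spot nearest-neighbor rule).
    """
    transform = transform or AffineMap.identity()
    if spots_a.empty or spots_b.empty:
        return pd.DataFrame(columns=["id_a", "id_b", "distance_px"])
    xy_a = spots_a[["x_px", "y_px"]].to_numpy(float)
    xy_b = transform.apply(spots_b[["x_px", "y_px"]].to_numpy(float))
    ids_a = spots_a["spot_id"].to_numpy()
    ids_b = spots_b["spot_id"].to_numpy()

    tree = cKDTree(xy_b)
    if not one_to_one:
        dist, j = tree.query(xy_a, k=1)
        keep = dist <= max_dist
        return pd.DataFrame({"id_a": ids_a[keep], "id_b": ids_b[j[keep]],
                             "distance_px": dist[keep]}
                            ).sort_values("id_a", ignore_index=True)

    cand = tree.query_ball_point(xy_a, r=max_dist)
    rows = [(float(np.hypot(*(xy_a[i] - xy_b[j]))), ids_a[i], ids_b[j], i, j)
            for i, js in enumerate(cand) for j in js]
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    used_a, used_b = set(), set()
    out = []
    for d, ia, ib, i, j in rows:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((ia, ib, d))
    return pd.DataFrame(out, columns=["id_a", "id_b", "distance_px"]
                        ).sort_values("id_a", ignore_index=True)


def coloc_frequency(matches: pd.DataFrame, n_reference_spots: int,
                    control_frequency: float = 0.0) -> tuple[float, float]:
    """Raw and control-subtracted co-localization frequency.

    ``control_frequency`` is the false-positive co-localization rate measured
    in a no-tag control field; the corrected value is clipped at zero.
    """
    if n_reference_spots <= 0:
        raise ValueError("n_reference_spots must be positive")
    raw = len(matches) / n_reference_spots
    corrected = raw - control_frequency
    if corrected < 0:
        log.warning("control frequency %.3f exceeds raw %.3f; clipping to 0",
                    control_frequency, raw)
        corrected = 0.0
    return raw, corrected


def correct_single_copy_occupancy(observed_frequency: float, p: float) -> float:
    """Correct an observed co-localization frequency for reporter activity
    under the single-copy assumption.

    A single-copy partner is seen only with probability ``p`` (its one
    reporter must be active), so the true occupancy is ``observed / p``,
    capped at 1.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("activity p must lie in (0, 1]")
    if not (0.0 <= observed_frequency <= 1.0):
        raise ValueError("observed frequency must lie in [0, 1]")
    return min(observed_frequency / p, 1.0)


def classify_by_intensity(intensities, cutoff: float | None = None,
                          grid_size: int = 512) -> tuple[np.ndarray, float]:
    """Label spots single- vs multi-copy by intensity.

    With an explicit ``cutoff``, a spot is "single" iff intensity <= cutoff.
    In automatic mode a Gaussian KDE of the intensities is scanned for the
    first valley between the first two modes; that cutoff is returned so it
    can always be inspected and overridden. A unimodal histogram raises,
    prompting a manual cutoff.

    Returns ``(labels, cutoff)`` with labels in {"single", "multi"}.
    """
    intensities = np.asarray(intensities, dtype=float).ravel()
    if intensities.size == 0:
        raise ValueError("empty intensity vector")
    if cutoff is None:
        kde = gaussian_kde(intensities)
        grid = np.linspace(intensities.min(), intensities.max(), grid_size)
        dens = kde(grid)
        d = np.diff(dens)
        maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
        if maxima.size < 2:
            raise ValueError("intensity histogram looks unimodal; supply a "
                             "manual cutoff")
        lo, hi = maxima[0], maxima[1]
        cutoff = float(grid[lo + np.argmin(dens[lo:hi + 1])])
    labels = np.where(intensities <= cutoff, "single", "multi")
    return labels, float(cutoff)


def intensity_association(int_a, int_b, n_perm: int = 10_000,
                          seed: int = 0) -> tuple[float, float]:
    """Spearman correlation of log-transformed paired spot intensities, with
    a permutation p-value.

    Asks whether the stoichiometries of two co-occupying proteins co-vary
    (intensity is a proxy for copy number). Requires >= 10 pairs.
    """
    a = np.log(np.asarray(int_a, dtype=float))
    b = np.log(np.asarray(int_b, dtype=float))
    if a.size != b.size:
        raise ValueError("paired intensities must have equal length")
    if a.size < 10:
        raise ValueError("at least 10 co-localized pairs are required")
    ra = rankdata(a)
    rb = rankdata(b)
    ra = (ra - ra.mean()) / ra.std()
    rb = (rb - rb.mean()) / rb.std()
    rho = float(ra @ rb / a.size)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(rb)
        if abs(ra @ perm / a.size) >= abs(rho) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return rho, p
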