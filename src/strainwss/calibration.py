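"""Per-species cutoff calibration from related vs unrelated score distributions.

Related scores come from within-individual longitudinal pairs, unrelated
scores from between-individual pairs.  When the two score distributions are
disjoint the cutoff is the midpoint of the gap; otherwise it is the crossing
point of the two Gaussian kernel density estimates (Silverman bandwidth)
searched on a fixed 512-point grid between the class means.  Calibration is
deterministic given its inputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InputError
from .profile_io import SampleProfile, qc_filter
from .wss import Window, compute_wss

DEFAULT_MIN_PER_CLASS = 5
GRID_POINTS = 512

METHOD_DENSITY = "density_intersection"
METHOD_MIDPOINT = "midpoint"
METHOD_NONE = "none"


@dataclass
class CutoffModel:
    species_id: str
    related_scores: list[float]
    unrelated_scores: list[float]
    cutoff: float | None
    method: str
    n_related: int = field(init=False)
    n_unrelated: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_related = len(self.related_scores)
        self.n_unrelated = len(self.unrelated_scores)
        if (self.cutoff is None) != (self.method == METHOD_NONE):
            raise ValueError("cutoff absent iff method is 'none'")


def collect_calibration_pairs(
    profiles_by_individual: Mapping[str, Sequence[SampleProfile]],
    windows: Sequence[Window],
    **wss_kwargs,
) -> tuple[list[float], list[float]]:
    """Score within-individual (related) and between-individual (unrelated)
    pairs of QC-passing profiles; pairs with no score are skipped."""
    passing = {
        ind: [p for p in profs if qc_filter(p).passed]
        for ind, profs in profiles_by_individual.items()
    }
    related: list[float] = []
    unrelated: list[float] = []
    for ind, profs in passing.items():
        for a, b in itertools.combinations(profs, 2):
            score = compute_wss(a, b, windows, **wss_kwargs).score
            if score is not None:
                related.append(score)
    for ind_a, ind_b in itertools.combinations(sorted(passing), 2):
        for a in passing[ind_a]:
            for b in passing[ind_b]:
                score = compute_wss(a, b, windows, **wss_kwargs).score
                if score is not None:
                    unrelated.append(score)
    return related, unrelated


def _kde_crossing(
    related: np.ndarray, unrelated: np.ndarray, grid_points: int
) -> float | None:
    """Crossing point of the two class KDEs on a grid between the class
    means; among multiple crossings, the one closest to the mean midpoint."""
    mean_r, mean_u = float(related.mean()), float(unrelated.mean())
    lo, hi = min(mean_r, mean_u), max(mean_r, mean_u)
    if hi - lo <= 0 or related.std() == 0 or unrelated.std() == 0:
        return None
    kde_r = gaussian_kde(related, bw_method="silverman")
    kde_u = gaussian_kde(unrelated, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    diff = kde_r(grid) - kde_u(grid)
    signs = np.sign(diff)
    flips = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    exact = np.nonzero(signs == 0)[0]
    candidates = []
    for i in flips:
        x0, x1, y0, y1 = grid[i], grid[i + 1], diff[i], diff[i + 1]
        candidates.append(x0 - y0 * (x1 - x0) / (y1 - y0))
    candidates.extend(grid[exact])
    candidates = [x for x in candidates if lo < x < hi]
    if not candidates:
        return None
    midpoint = 0.5 * (mean_r + mean_u)
    return float(min(candidates, key=lambda x: abs(x - midpoint)))


def calibrate_cutoff(
    related_scores: Sequence[float],
    unrelated_scores: Sequence[float],
    min_per_class: int = DEFAULT_MIN_PER_CLASS,
    species_id: str = "",
    grid_points: int = GRID_POINTS,
) -> CutoffModel:
    """Estimate the related/unrelated decision threshold for one species.

    Under ``min_per_class`` scores in either class -> no cutoff ("CO:NA").
    Disjoint classes -> midpoint of the gap.  Overlapping classes -> KDE
    crossing; if no crossing exists on the grid, fall back to the midpoint
    of the class means.
    """
    related = np.asarray(sorted(related_scores), dtype=float)
    unrelated = np.asarray(sorted(unrelated_scores), dtype=float)
    for name, arr in (("related", related), ("unrelated", unrelated)):
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise InputError(f"{name} scores outside [0,1]")

    def model(cutoff: float | None, method: str) -> CutoffModel:
        return CutoffModel(
            species_id=species_id,
            related_scores=related.tolist(),
            unrelated_scores=unrelated.tolist(),
            cutoff=cutoff,
            method=method,
        )

    if related.size < min_per_class or unrelated.size < min_per_class:
        return model(None, METHOD_NONE)

    if unrelated.max() < related.min():
        return model(0.5 * (unrelated.max() + related.min()), METHOD_MIDPOINT)

    crossing = _kde_crossing(related, unrelated, grid_points)
    if crossing is not None:
        return model(crossing, METHOD_DENSITY)

    mean_r, mean_u = float(related.mean()), float(unrelated.mean())
    if mean_r == mean_u:  # indistinguishable classes: no usable cutoff
        return model(None, METHOD_NONE)
    return model(0.5 * (mean_r + mean_u), METHOD_MIDPOINT)
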