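"""Windowed SNV similarity (WSS) scoring.

The reference is tiled into non-overlapping windows; windows where either
sample of a pair is poorly covered are dropped; per-window similarity is the
fraction of matching genotype states over the union of the pair's variant
positions; the WSS score is the unweighted mean over informative windows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ComparisonError, ParameterError
from .profile_io import DepthTrack, SampleProfile, qc_filter

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 1000
DEFAULT_SITE_DEPTH_MIN = 5
DEFAULT_LOW_FRAC = 0.5
DEFAULT_MIN_WINDOWS = 1

LABEL_RELATED = "related"
LABEL_UNRELATED = "unrelated"
LABEL_NOT_CLASSIFIABLE = "not_classifiable"
LABEL_NO_SCORE = "no_score"


@dataclass(frozen=True)
class Window:
    """0-based half-open interval [start, end) on the reference."""

    index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.index < 0 or self.start < 0 or self.end <= self.start:
            raise ParameterError(f"bad window [{self.start},{self.end}) #{self.index}")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class WindowSimilarity:
    window: Window
    compared_positions: int
    matched_positions: int
    similarity: float | None
    passed_depth_filter: bool


@dataclass
class WSSResult:
    """One unordered sample pair's WSS score (sample_a < sample_b)."""

    sample_a: str
    sample_b: str
    species_id: str
    score: float | None
    windows_used: int
    windows_total: int
    cutoff: float | None
    label: str
    individual_id: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


def label_for(score: float | None, cutoff: float | None) -> str:
    """Related iff score > cutoff (strict); equality is unrelated."""
    if score is None:
        return LABEL_NO_SCORE
    if cutoff is None:
        return LABEL_NOT_CLASSIFIABLE
    return LABEL_RELATED if score > cutoff else LABEL_UNRELATED


def make_windows(
    reference_length: int, window_size: int = DEFAULT_WINDOW_SIZE
) -> list[Window]:
    """Tile [0, reference_length) into ceil(L/size) windows; last may be short."""
    if reference_length < 1:
        raise ParameterError(f"reference_length {reference_length} < 1")
    if window_size < 1:
        raise ParameterError(f"window_size {window_size} < 1")
    return [
        Window(index=i, start=start, end=min(start + window_size, reference_length))
        for i, start in enumerate(range(0, reference_length, window_size))
    ]


def _depth_array(track: DepthTrack | np.ndarray) -> np.ndarray:
    return track.depth if isinstance(track, DepthTrack) else np.asarray(track)


def window_passes_depth(
    depth_a: DepthTrack | np.ndarray,
    depth_b: DepthTrack | np.ndarray,
    window: Window,
    site_depth_min: int = DEFAULT_SITE_DEPTH_MIN,
    low_frac: float = DEFAULT_LOW_FRAC,
) -> bool:
    """Fail iff in EITHER sample strictly more than ``low_frac`` of the
    window's bases have depth < ``site_depth_min``."""
    for track in (depth_a, depth_b):
        d = _depth_array(track)[window.start : window.end]
        if np.count_nonzero(d < site_depth_min) > low_frac * window.size:
            return False
    return True


def _pair_states(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    site_depth_min: int,
    lo: int | None = None,
    hi: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Comparable positions of a pair and both samples' states there.

    Returns (positions, states_a, states_b) restricted to 1-based positions
    in (lo, hi] when bounds are given.  A sample with no call at a position
    is in the reference state (0) when its site depth >= site_depth_min and
    unknowable otherwise; positions unknowable in either sample are dropped.
    """
    pos = np.union1d(profile_a.call_positions, profile_b.call_positions)
    if lo is not None:
        pos = pos[(pos > lo) & (pos <= hi)]
    if pos.size == 0:
        return pos, pos, pos

    def states_and_known(profile: SampleProfile) -> tuple[np.ndarray, np.ndarray]:
        cp, cs = profile.call_positions, profile.call_states
        idx = np.searchsorted(cp, pos)
        idx_c = np.minimum(idx, max(len(cp) - 1, 0))
        has_call = (len(cp) > 0) & (idx < len(cp))
        if len(cp) > 0:
            has_call &= cp[idx_c] == pos
        states = np.where(has_call, cs[idx_c] if len(cs) else 0, 0)
        depth_ok = profile.depth.depth[pos - 1] >= site_depth_min
        return states, has_call | depth_ok

    states_a, known_a = states_and_known(profile_a)
    states_b, known_b = states_and_known(profile_b)
    keep = known_a & known_b
    return pos[keep], states_a[keep], states_b[keep]


def window_similarity(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    window: Window,
    site_depth_min: int = DEFAULT_SITE_DEPTH_MIN,
    low_frac: float = DEFAULT_LOW_FRAC,
) -> WindowSimilarity:
    """Per-window SNV similarity = matched / compared over the union of the
    pair's variant positions inside the window (see :func:`_pair_states`)."""
    _, states_a, states_b = _pair_states(
        profile_a, profile_b, site_depth_min, lo=window.start, hi=window.end
    )
    compared = int(states_a.size)
    matched = int(np.count_nonzero(states_a == states_b))
    return WindowSimilarity(
        window=window,
        compared_positions=compared,
        matched_positions=matched,
        similarity=(matched / compared) if compared > 0 else None,
        passed_depth_filter=window_passes_depth(
            profile_a.depth, profile_b.depth, window, site_depth_min, low_frac
        ),
    )


def compute_wss(
    profile_a: SampleProfile,
    profile_b: SampleProfile,
    windows: Sequence[Window],
    site_depth_min: int = DEFAULT_SITE_DEPTH_MIN,
    low_frac: float = DEFAULT_LOW_FRAC,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> WSSResult:
    """Genome-wide WSS score for one sample pair.

    The score is the unweighted mean of per-window similarities over windows
    that pass the pair depth filter and contain at least one comparable
    position; fewer than ``min_windows`` such windows yields no score.
    """
    if profile_a.reference.sequence_id != profile_b.reference.sequence_id:
        raise ComparisonError(
            f"profiles on different references: "
            f"{profile_a.reference.sequence_id!r} vs "
            f"{profile_b.reference.sequence_id!r}"
        )
    sims = []
    for window in windows:
        if not window_passes_depth(
            profile_a.depth, profile_b.depth, window, site_depth_min, low_frac
        ):
            continue
        ws = window_similarity(profile_a, profile_b, window, site_depth_min, low_frac)
        if ws.compared_positions > 0:
            sims.append(ws.similarity)
    windows_used = len(sims)
    score = float(np.mean(sims)) if windows_used >= min_windows else None
    cutoff = profile_a.reference.cutoff
    a, b = sorted([profile_a.sample_id, profile_b.sample_id])
    individual = (
        profile_a.individual_id
        if profile_a.individual_id == profile_b.individual_id
        else ""
    )
    return WSSResult(
        sample_a=a,
        sample_b=b,
        species_id=profile_a.reference.species_id,
        score=score,
        windows_used=windows_used,
        windows_total=len(windows),
        cutoff=cutoff,
        label=label_for(score, cutoff),
        individual_id=individual,
    )


def pairwise_wss(
    profiles: Iterable[SampleProfile],
    windows: Sequence[Window],
    site_depth_min: int = DEFAULT_SITE_DEPTH_MIN,
    low_frac: float = DEFAULT_LOW_FRAC,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    breadth_min: float | None = None,
    depth_min: float | None = None,
) -> list[WSSResult]:
    """WSS for every unordered pair of QC-passing profiles.

    QC thresholds default to the sample-level filter's defaults; pass
    explicit values to override.  Fewer than 2 passing profiles yields an
    empty list (logged).
    """
    qc_kwargs = {}
    if breadth_min is not None:
        qc_kwargs["breadth_min"] = breadth_min
    if depth_min is not None:
        qc_kwargs["depth_min"] = depth_min
    passing = [p for p in profiles if qc_filter(p, **qc_kwargs).passed]
    passing.sort(key=lambda p: p.sample_id)
    if len(passing) < 2:
        logger.info("fewer than 2 QC-passing profiles; no pairs to compare")
        return []
    return [
        compute_wss(a, b, windows, site_depth_min, low_frac, min_windows)
        for a, b in itertools.combinations(passing, 2)
    ]
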