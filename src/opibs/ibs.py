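"""Classic information-based similarity (IBS) on binarized interval increments.

The predecessor of the ordinal-pattern index: each beat-to-beat increment is
reduced to one bit (1 if the next interval is strictly longer, else 0),
consecutive bits form sliding binary words of length ``D`` (2**D classes,
32 for the default D=5), and two epochs are compared with the same
entropy-weighted rank distance used for ordinal patterns.  Binarization keeps
only the up/down relationship of adjacent beats, so larger-scale temporal
structure — which the ordinal variant captures through coarse-graining and
longer words — is invisible to it.
"""

from __future__ import annotations

import numpy as np

from .ordinal import RankProfile, profile_distance, rank_profile_from_ids
from .preprocess import PPISeries, SegmentSet

__all__ = [
    "binarize",
    "word_ids",
    "word_profile",
    "ibs_distance",
    "recording_ibs",
]


def binarize(ppi) -> np.ndarray:
    """1 where the next interval is strictly longer, 0 otherwise (ties -> 0)."""
    x = ppi.intervals if isinstance(ppi, PPISeries) else np.asarray(ppi, float)
    if len(x) < 2:
        raise ValueError("need at least two intervals to binarize")
    return (np.diff(x) > 0).astype(np.int8)


def word_ids(bits: np.ndarray, D: int = 5) -> np.ndarray:
    """Sliding D-bit words as ids 1..2**D (most significant bit = earliest)."""
    bits = np.asarray(bits)
    if len(bits) < D:
        raise ValueError(f"{len(bits)} bits cannot form a {D}-bit word")
    powers = 2 ** np.arange(D - 1, -1, -1)
    return np.lib.stride_tricks.sliding_window_view(bits, D) @ powers + 1


def word_profile(seg: PPISeries, D: int = 5) -> RankProfile:
    return rank_profile_from_ids(word_ids(binarize(seg), D), 2**D)


def ibs_distance(seg1: PPISeries, seg2: PPISeries, D: int = 5) -> float:
    """Classic IBS distance between two epochs over 2**D binary word classes."""
    return profile_distance(word_profile(seg1, D), word_profile(seg2, D))


def recording_ibs(segs: SegmentSet, D: int = 5, return_pairs: bool = False):
    """Per-recording IBS: mean distance over adjacent usable segment pairs.

    Segments too short to yield at least one word (fewer than D+1 beats) are
    skipped; at least two usable segments are required.
    """
    profiles = [word_profile(seg, D) for seg in segs if len(seg) >= D + 1]
    if len(profiles) < 2:
        raise ValueError(
            f"recording {segs.recording_id!r} has {len(profiles)} usable "
            "segments; need at least 2"
        )
    pairs = [
        profile_distance(profiles[i], profiles[i + 1])
        for i in range(len(profiles) - 1)
    ]
    mean = float(np.mean(pairs))
    return (mean, pairs) if return_pairs else mean
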