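"""Ordinal-pattern information-based similarity (OP_IBS).

The OP_IBS index quantifies how similar the short-term heart-rate dynamics of
adjacent 5-minute pulse-interval epochs are.  Each epoch is mean coarse-grained
with scale factor ``s``, embedded into overlapping words of length ``m`` (time
delay ``tau``), and every word is mapped to its ordinal pattern — the
permutation describing the relative order of its values, ties resolved by time
of appearance.  The ``m!`` pattern classes are ranked by their frequency of
occurrence within the epoch (ties by catalogue serial number), and two epochs
are compared by the entropy-weighted mean absolute rank difference

    D = (1/T) * sum_i |r1(i) - r2(i)| * W(i),
    W(i) = (-p1 log p1 - p2 log p2) / sigma,   sigma = sum_i (...),

with T = m! classes.  D is 0 for identical rank profiles and bounded by
(T-1)/T; the sigma-normalisation makes it independent of the logarithm base.
The per-recording OP_IBS index is the mean of D over all adjacent epoch pairs:
in obstructive sleep apnea the cyclic bradycardia–tachycardia accompanying
apneic events stamps a recurring temporal motif onto every epoch, adjacent
epochs become more alike, and the index falls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial

import numpy as np

from .preprocess import PPISeries, SegmentSet

__all__ = [
    "OPConfig",
    "OrdinalPatternSequence",
    "RankProfile",
    "coarse_grain",
    "ordinal_pattern",
    "pattern_sequence",
    "rank_profile",
    "rank_profile_from_ids",
    "profile_distance",
    "opibs_distance",
    "segment_profiles",
    "recording_opibs",
    "parameter_sweep",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OPConfig:
    """Coarse-graining scale ``s``, word length ``m`` and time delay ``tau``.

    Defaults (s=7, m=5, tau=1) are the operating point with the strongest
    correlation against apnea severity in the parameter sweep over s=4..10,
    m=2..6.
    """

    s: int = 7
    m: int = 5
    tau: int = 1

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("scale factor s must be >= 1")
        if self.m < 2:
            raise ValueError("word length m must be >= 2")
        if self.tau < 1:
            raise ValueError("time delay tau must be >= 1")
        factorial(self.m)  # m! must be representable

    @property
    def n_classes(self) -> int:
        return factorial(self.m)


@dataclass
class OrdinalPatternSequence:
    """Sequence of pattern catalogue indices (1..m!) for one epoch."""

    pattern_ids: np.ndarray
    config: OPConfig

    def __len__(self) -> int:
        return len(self.pattern_ids)


@dataclass
class RankProfile:
    """Per-class probabilities and frequency ranks for one epoch.

    ``probs[i]`` and ``ranks[i]`` refer to pattern id ``i + 1``; ``ranks`` is a
    permutation of 1..T ordered by descending probability, ties broken by
    ascending pattern id.
    """

    probs: np.ndarray
    ranks: np.ndarray
    T: int


def _as_intervals(x) -> np.ndarray:
    if isinstance(x, PPISeries):
        return x.intervals
    return np.asarray(x, dtype=float)


def coarse_grain(ppi, s: int) -> np.ndarray:
    """Mean coarse-grain with scale factor ``s``; the remainder is discarded.

    ``out[i]`` is the mean of block ``i`` of ``s`` consecutive intervals, for
    ``i = 1..floor(n/s)``.  ``s=1`` is the identity.
    """
    x = _as_intervals(ppi)
    n = len(x)
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    if s > n:
        raise ValueError(f"scale factor {s} exceeds series length {n}")
    nb = n // s
    return x[: nb * s].reshape(nb, s).mean(axis=1)


def _lex_rank(perm: np.ndarray) -> np.ndarray:
    """Lexicographic rank (0-based) of permutation tuples over 1..m, rowwise."""
    m = perm.shape[1]
    rank = np.zeros(len(perm), dtype=np.int64)
    for i in range(m - 1):
        smaller_after = (perm[:, i + 1 :] < perm[:, i : i + 1]).sum(axis=1)
        rank += smaller_after * factorial(m - 1 - i)
    return rank


def ordinal_pattern(window) -> int:
    """Catalogue index (1..m!) of the ordinal pattern of one word.

    The pattern tuple (t1..tm) lists, for ascending value rank, the original
    position of the element holding that rank; equal values are ordered by
    time of appearance (stable sort).  The catalogue orders permutation tuples
    lexicographically, so for m=3: (1,2,3)->1 ... (3,1,2)->5, (3,2,1)->6.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or len(w) < 2:
        raise ValueError("window must be one-dimensional with length >= 2")
    perm = np.argsort(w, kind="stable") + 1
    return int(_lex_rank(perm[None, :])[0]) + 1


def pattern_sequence(coarse, cfg: OPConfig) -> OrdinalPatternSequence:
    """Ordinal pattern id at every sliding-window position of a series."""
    x = _as_intervals(coarse)
    span = (cfg.m - 1) * cfg.tau + 1
    if len(x) < span:
        raise ValueError(
            f"series of length {len(x)} too short for m={cfg.m}, tau={cfg.tau}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, span)[:, :: cfg.tau]
    perms = np.argsort(windows, axis=1, kind="stable") + 1
    ids = _lex_rank(perms) + 1
    return OrdinalPatternSequence(pattern_ids=ids, config=cfg)


def rank_profile_from_ids(ids: np.ndarray, T: int) -> RankProfile:
    """Empirical probabilities over all ``T`` classes and their frequency ranks.

    Unobserved classes carry probability zero; ranks order classes by
    descending probability with ties — including the zero block — broken by
    ascending class id (the catalogue serial number).
    """
    ids = np.asarray(ids)
    if len(ids) == 0:
        raise ValueError("cannot profile an empty pattern sequence")
    if ids.min() < 1 or ids.max() > T:
        raise ValueError(f"pattern ids must lie in 1..{T}")
    counts = np.bincount(ids, minlength=T + 1)[1:]
    probs = counts / counts.sum()
    order = np.argsort(-probs, kind="stable")  # stable => serial-number ties
    ranks = np.empty(T, dtype=np.int64)
    ranks[order] = np.arange(1, T + 1)
    return RankProfile(probs=probs, ranks=ranks, T=T)


def rank_profile(ops: OrdinalPatternSequence) -> RankProfile:
    return rank_profile_from_ids(ops.pattern_ids, ops.config.n_classes)


def _plogp(p: np.ndarray, base: float | None) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log(p[nz])
    if base is not None:
        out /= np.log(base)
    return out


def profile_distance(
    p1: RankProfile, p2: RankProfile, log_base: float | None = None
) -> float:
    """Entropy-weighted mean absolute rank difference between two profiles.

    Weights are the summed pointwise Shannon entropy terms of the two
    probability vectors, normalised to unit sum (so the logarithm base
    cancels).  When both profiles are degenerate single-pattern profiles the
    normaliser is zero and uniform weights 1/T are used, reducing the distance
    to the mean absolute rank gap over T.
    """
    if p1.T != p2.T:
        raise ValueError(f"profiles have different class counts: {p1.T} != {p2.T}")
    h = _plogp(p1.probs, log_base) + _plogp(p2.probs, log_base)
    sigma = h.sum()
    w = h / sigma if sigma > 0 else np.full(p1.T, 1.0 / p1.T)
    return float(np.abs(p1.ranks - p2.ranks).dot(w) / p1.T)


#: The OP_IBS distance between two epoch rank profiles.
opibs_distance = profile_distance


def segment_profiles(
    segs: SegmentSet, cfg: OPConfig
) -> list[RankProfile]:
    """Rank profile of every usable segment, in order.

    Segments too short to coarse-grain and embed (fewer than
    ``s * ((m-1)*tau + 1)`` beats) are skipped with a warning.
    """
    need = cfg.s * ((cfg.m - 1) * cfg.tau + 1)
    profiles = []
    for i, seg in enumerate(segs):
        if len(seg) < need:
            log.warning(
                "skipping segment %d of %s: %d beats < %d needed",
                i,
                segs.recording_id or "<recording>",
                len(seg),
                need,
            )
            continue
        profiles.append(rank_profile(pattern_sequence(coarse_grain(seg, cfg.s), cfg)))
    return profiles


def recording_opibs(
    segs: SegmentSet, cfg: OPConfig | None = None, return_pairs: bool = False
):
    """Per-recording OP_IBS: mean distance over adjacent usable segment pairs."""
    cfg = cfg or OPConfig()
    profiles = segment_profiles(segs, cfg)
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


def parameter_sweep(
    recordings: list[SegmentSet],
    ahi: np.ndarray,
    s_range=range(4, 11),
    m_range=range(2, 7),
    tau: int = 1,
):
    """|Pearson R| between per-recording OP_IBS and AHI over an (s, m) grid.

    Returns ``(matrix, best)`` where ``matrix`` is a DataFrame indexed by s
    with one column per m, and ``best`` the (s, m) pair maximising |R|.  Cells
    where the index degenerates to zero variance are NaN (flagged with a
    warning).  Raises for fewer than 3 recordings or zero-variance AHI.
    """
    import pandas as pd
    from scipy import stats

    ahi = np.asarray(ahi, dtype=float)
    if len(recordings) < 3 or len(ahi) != len(recordings):
        raise ValueError("need >= 3 labelled recordings")
    if np.ptp(ahi) == 0:
        raise ValueError("AHI labels have zero variance; correlation undefined")
    mat = pd.DataFrame(index=list(s_range), columns=list(m_range), dtype=float)
    mat.index.name = "s"
    mat.columns.name = "m"
    for s in s_range:
        for m in m_range:
            cfg = OPConfig(s=s, m=m, tau=tau)
            vals = np.array([recording_opibs(r, cfg) for r in recordings])
            if np.ptp(vals) == 0:
                log.warning("OP_IBS constant at s=%d, m=%d; |R| undefined", s, m)
                mat.loc[s, m] = np.nan
                continue
            r, _ = stats.pearsonr(vals, ahi)
            mat.loc[s, m] = abs(r)
    if mat.isna().all().all():
        raise ValueError("correlation undefined for every (s, m) pair")
    flat = mat.stack()
    best = flat.idxmax()
    return mat, (int(best[0]), int(best[1]))
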