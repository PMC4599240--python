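"""Copy-number segmentation, segment filtering and quiescence summaries.

Marker-level log2-ratio tracks are partitioned by recursive binary
segmentation with a permutation test at each candidate split (a desk-scale
stand-in for circular binary segmentation).  Filtered segments keep only
regions with at least ``min_markers`` markers and ``|mean log2| > log2_cut``
(strict), called gain or loss by sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"x", "y", "chrx", "chry", "23", "24"}


@dataclass
class MarkerTrack:
    """Ordered marker positions and log2 ratios per chromosome for one sample."""

    sample_id: str
    chroms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(self, chrom: str, positions: np.ndarray, log2: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        log2 = np.asarray(log2, dtype=float)
        if positions.shape != log2.shape:
            raise ValueError("positions and log2 must have equal length")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError(f"marker positions not strictly increasing on {chrom}")
        if not np.all(np.isfinite(log2)):
            raise ValueError(f"non-finite log2 ratio on {chrom}")
        self.chroms[chrom] = (positions, log2)


@dataclass(frozen=True)
class Segment:
    sample_id: str
    chromosome: str
    start: int  # 0-based inclusive bp
    end: int  # 0-based exclusive bp
    n_markers: int
    mean_log2: float
    call: str = "neutral"  # gain | loss | neutral


@dataclass(frozen=True)
class QuiescenceSummary:
    sample_id: str
    n_filtered_segments: int
    mean_markers_per_segment: float


def is_autosome(chrom: str) -> bool:
    return chrom.strip().lower().removeprefix("chr") not in {"x", "y", "23", "24"}


def _best_arc_stat(x: np.ndarray, min_width: int) -> tuple[int, int, float]:
    """Best arc [i:j) of ``x`` compared against its complement.

    Statistic: |mean_inside - mean_outside| / sqrt(1/k + 1/(n-k)) with
    k = j - i (the pooled SD cancels under permutation).  Both the arc and
    its complement must hold at least ``min_width`` markers.  A boundary arc
    (i = 0 or j = n) is an ordinary binary split.  Ties break to the first
    arc found scanning arc length ascending, then start ascending (an arc
    and its complementary boundary arc induce the same partition, so the
    resulting segmentation is deterministic either way).  Returns
    (i, j, stat); (-1, -1, 0.0) when no admissible arc exists.
    """
    n = x.size
    if n < 2 * min_width:
        return -1, -1, 0.0
    cs = np.concatenate(([0.0], np.cumsum(x)))
    total = cs[-1]
    best = (-1, -1, 0.0)
    for k in range(min_width, n - min_width + 1):
        sums = cs[k:] - cs[: n - k + 1]  # arc sums for every start i
        stat = np.abs(sums / k - (total - sums) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        i = int(np.argmax(stat))  # first maximum: leftmost tie-break
        s = float(stat[i])
        if s > best[2]:
            best = (i, i + k, s)
    return best


def _perm_max_arc_stats(x: np.ndarray, min_width: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Maximum arc statistic for ``n_perm`` within-segment permutations."""
    n = x.size
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)).copy(), axis=1)
    cs = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    total = cs[:, -1:]
    best = np.zeros(n_perm)
    for k in range(min_width, n - min_width + 1):
        sums = cs[:, k:] - cs[:, : n - k + 1]
        stat = np.abs(sums / k - (total - sums) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        np.maximum(best, stat.max(axis=1), out=best)
    return best


def _arc_permutation_p(
    x: np.ndarray,
    stat: float,
    min_width: int,
    n_perm: int,
    alpha: float,
    rng: np.random.Generator,
    block: int = 250,
) -> float:
    """Permutation p-value for the observed max arc statistic.

    Runs permutations in blocks and stops early once the exceedance count
    already rules out significance at ``alpha`` (the returned conservative
    p is then correct for the alpha decision).
    """
    reject_at = alpha * (1 + n_perm)  # e >= this => p > alpha regardless of the rest
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        null = _perm_max_arc_stats(x, min_width, b, rng)
        exceed += int(np.count_nonzero(null >= stat))
        done += b
        if 1 + exceed > reject_at:
            return (1.0 + exceed) / (1.0 + done)
    return (1.0 + exceed) / (1.0 + n_perm)


def segment_track(
    track: MarkerTrack,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[Segment]:
    """Segment each chromosome of ``track`` by recursive arc splitting.

    Each round searches the current segment for the arc [i:j) whose mean
    most differs from the complement's (a boundary arc is an ordinary binary
    split); the arc is cut out when its within-segment permutation p-value
    is <= ``alpha``, and the parts are revisited recursively.  Returned
    segments tile every chromosome in order; the segment mean is the
    arithmetic mean of member log2 ratios.  Deterministic given ``seed``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out: list[Segment] = []
    for chrom in track.chroms:
        positions, log2 = track.chroms[chrom]
        n = positions.size
        if n == 0:
            continue
        if n < min_width:
            logger.info("%s %s: fewer than %d markers, single segment", track.sample_id, chrom, min_width)
            out.append(_make_segment(track.sample_id, chrom, positions, log2, 0, n))
            continue
        # iterative recursion over (lo, hi) marker-index windows
        stack = [(0, n)]
        bounds: list[tuple[int, int]] = []
        while stack:
            lo, hi = stack.pop()
            x = log2[lo:hi]
            i, j, stat = _best_arc_stat(x, min_width)
            accepted = False
            if i >= 0 and stat > 0.0:
                pval = _arc_permutation_p(x, stat, min_width, n_perm, alpha, rng)
                accepted = pval <= alpha
            if accepted:
                for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                    if b > a:
                        stack.append((a, b))
            else:
                bounds.append((lo, hi))
        for lo, hi in sorted(bounds):
            out.append(_make_segment(track.sample_id, chrom, positions, log2, lo, hi))
    return out


def _make_segment(sample_id: str, chrom: str, positions: np.ndarray, log2: np.ndarray, lo: int, hi: int) -> Segment:
    return Segment(
        sample_id=sample_id,
        chromosome=chrom,
        start=int(positions[lo]),
        end=int(positions[hi - 1]) + 1,
        n_markers=hi - lo,
        mean_log2=float(np.mean(log2[lo:hi])),
    )


def filter_segments(
    segments: list[Segment],
    min_markers: int = 8,
    log2_cut: float = 0.5,
    autosomes_only: bool = True,
) -> list[Segment]:
    """Keep gain/loss segments: >= ``min_markers`` markers (inclusive) and
    ``|mean_log2| > log2_cut`` (strict).  Sex chromosomes are excluded by
    default.  Order preserved; idempotent."""
    kept: list[Segment] = []
    for s in segments:
        if autosomes_only and not is_autosome(s.chromosome):
            continue
        if s.n_markers < min_markers:
            continue
        if s.mean_log2 > log2_cut:
            kept.append(Segment(**{**s.__dict__, "call": "gain"}))
        elif s.mean_log2 < -log2_cut:
            kept.append(Segment(**{**s.__dict__, "call": "loss"}))
    return kept


def quiescence_stats(filtered: list[Segment], samples: list[str]) -> list[QuiescenceSummary]:
    """Per-sample count of surviving segments and mean markers per segment.

    Every requested sample appears, including those with zero surviving
    segments (count 0, mean 0).
    """
    by_sample: dict[str, list[Segment]] = {s: [] for s in samples}
    for seg in filtered:
        if seg.sample_id in by_sample:
            by_sample[seg.sample_id].append(seg)
    out = []
    for s in samples:
        segs = by_sample[s]
        n = len(segs)
        mean_markers = float(np.mean([g.n_markers for g in segs])) if n else 0.0
        out.append(QuiescenceSummary(s, n, mean_markers))
    return out
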