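"""Cumulative GC-skew profiles, exact repeats, and ori-region prediction.

Replication changes strand composition: the leading strand is typically
G-rich, so the cumulative (G - C) walk around a circular replicon slopes up
from origin to terminus and down on the way back — its minimum marks the
candidate origin. The per-position increment is mean-centered before
cumulation so the circular walk closes and its extrema are rotation-
equivariant (the raw walk is start-point dependent). Candidate ori regions
are large intergenic regions scored by proximity to a skew minimum and by
local repeat support.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .seq_io import CircularSequence, revcomp

log = logging.getLogger(__name__)


@dataclass
class SkewProfile:
    seq_id: str
    values: np.ndarray  # walk value after each position; closes at ~0
    window: int = 1


@dataclass(frozen=True)
class RepeatHit:
    kind: str  # direct | inverted
    pos1: int
    pos2: int
    rep_len: int
    seq: str


@dataclass
class OriPrediction:
    region: tuple[int, int]  # wrap-aware interval, end may exceed length
    skew_min_pos: int
    dist_to_min: int
    repeat_support: int
    rank: int


def plot_skew(profile: SkewProfile, path, predictions=None) -> None:
    """Write a PNG/SVG of the skew walk with candidate regions shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.values, lw=0.8, color="#1f4e79")
    ax.axhline(0, color="grey", lw=0.5)
    for p in predictions or []:
        a, b = p.region
        ax.axvspan(a, min(b, len(profile.values)), alpha=0.2,
                   color="#d98032" if p.rank == 1 else "#bbbbbb")
        ax.axvline(p.skew_min_pos, color="#d98032", lw=0.8, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("centered cumulative G-C")
    ax.set_title(profile.seq_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def cumulative_skew(seq: CircularSequence, window: int = 1,
                    centered: bool = True) -> SkewProfile:
    """Centered cumulative GC-skew walk, one value per position.

    Increments are +1 (G), -1 (C), 0 (A/T/N); with ``centered`` the mean
    increment is subtracted so the walk starts and ends at 0. ``window`` > 1
    applies a circular moving average.
    """
    if not 1 <= window < seq.length:
        raise ValueError("need length > window >= 1")
    arr = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
    inc = np.zeros(seq.length, dtype=float)
    inc[arr == ord("G")] = 1.0
    inc[arr == ord("C")] = -1.0
    if centered:
        inc -= inc.mean()
    values = np.cumsum(inc)
    if window > 1:
        kernel = np.ones(window) / window
        tiled = np.concatenate([values, values, values])
        values = np.convolve(tiled, kernel, mode="same")[seq.length:2 * seq.length]
    return SkewProfile(seq.id, values, window)


# ---------------------------------------------------------------------------
# exact repeats

_MAX_SEED_OCCURRENCES = 32


def _kmer_positions(s: str, k: int, circular: bool) -> dict[str, list[int]]:
    L = len(s)
    ext = s + s[:k - 1] if circular else s
    table: dict[str, list[int]] = {}
    for i in range(L if circular else L - k + 1):
        table.setdefault(ext[i:i + k], []).append(i)
    return table


def _char(s: str, i: int, circular: bool) -> str | None:
    L = len(s)
    if circular:
        return s[i % L]
    return s[i] if 0 <= i < L else None


def _extend_direct(s: str, i: int, j: int, k: int, circular: bool) -> tuple[int, int, int]:
    L = len(s)
    cap = L - 1  # never extend to the full circle (degenerate)
    # left
    while k < cap:
        a, b = _char(s, i - 1, circular), _char(s, j - 1, circular)
        if a is None or b is None or a != b:
            break
        i, j, k = i - 1, j - 1, k + 1
    while k < cap:
        a, b = _char(s, i + k, circular), _char(s, j + k, circular)
        if a is None or b is None or a != b:
            break
        k += 1
    return i % L if circular else i, j % L if circular else j, k


_COMP = str.maketrans("ACGTN", "TGCAN")


def _extend_inverted(s: str, i: int, j: int, k: int, circular: bool) -> tuple[int, int, int]:
    """Extend copy1 at i (forward) vs copy2 at j (reverse complement)."""
    L = len(s)
    cap = L - 1
    while k < cap:
        a, b = _char(s, i - 1, circular), _char(s, j + k, circular)
        if a is None or b is None or a != b.translate(_COMP):
            break
        i, k = i - 1, k + 1
    while k < cap:
        a, b = _char(s, i + k, circular), _char(s, j - 1, circular)
        if a is None or b is None or a != b.translate(_COMP):
            break
        j, k = j - 1, k + 1
    return i % L if circular else i, j % L if circular else j, k


def find_repeats(seq: CircularSequence, min_len: int = 12,
                 max_pairs: int = 100) -> list[RepeatHit]:
    """Maximal exact direct and inverted repeat pairs, longest first.

    Seed-and-extend over exact ``min_len``-mers, wrap-aware on circular
    sequences. Seeds occurring more than 32 times (low-complexity tracts)
    are subsampled; output is truncated to ``max_pairs``.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    s = seq.residues
    L = seq.length
    table = _kmer_positions(s, min_len, seq.circular)
    found: set[tuple] = set()
    for kmer, positions in table.items():
        positions = positions[:_MAX_SEED_OCCURRENCES]
        # direct pairs
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                i, j, k = _extend_direct(s, positions[x], positions[y],
                                         min_len, seq.circular)
                p1, p2 = sorted((i, j))
                if p1 != p2:
                    found.add(("direct", p1, p2, k))
        rc = revcomp(kmer)
        for i in positions:
            for j in table.get(rc, [])[:_MAX_SEED_OCCURRENCES]:
                if i >= j:
                    continue  # each inverted pair is seeded from both ends
                a, b, k = _extend_inverted(s, i, j, min_len, seq.circular)
                p1, p2 = sorted((a, b))
                found.add(("inverted", p1, p2, k))
    hits = []
    for kind, p1, p2, k in found:
        end = p1 + k
        sub = s[p1:end] if end <= L else s[p1:] + s[:end - L]
        hits.append(RepeatHit(kind, p1, p2, k, sub))
    hits.sort(key=lambda h: (-h.rep_len, h.pos1, h.pos2, h.kind))
    return hits[:max_pairs]


# ---------------------------------------------------------------------------
# intergenic regions and ori prediction

def intergenic_regions(seq: CircularSequence, orfs, min_len: int = 150
                       ) -> list[tuple[int, int]]:
    """Gaps >= min_len in the circular union of ORF intervals."""
    L = seq.length
    mask = np.zeros(L, dtype=bool)
    for o in orfs:
        if o.end <= L:
            mask[o.start:o.end] = True
        else:
            mask[o.start:] = True
            mask[: o.end - L] = True
    if not mask.any():
        return [(0, L)] if L >= min_len else []
    if mask.all():
        return []
    # circular runs of uncovered positions: rotate so position 0 is covered
    shift = int(np.argmax(mask))  # first covered position
    rolled = np.roll(~mask, -shift)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], rolled.view(np.int8), [0]])))
    regions = []
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= min_len:
            regions.append(((a + shift) % L, (a + shift) % L + (b - a)))
    regions.sort()
    return regions


def _circular_dist_to_interval(pos: int, region: tuple[int, int], L: int) -> int:
    a, b = region
    if a <= pos < b or (b > L and pos < b - L):
        return 0
    # circular gap to either boundary
    d1 = min((a - pos) % L, (pos - a) % L)
    bb = b % L
    d2 = min((bb - pos) % L, (pos - bb) % L)
    return min(d1, d2)


def predict_ori(seq: CircularSequence, profile: SkewProfile,
                regions: list[tuple[int, int]], repeats: list[RepeatHit],
                prominence_frac: float = 0.1) -> list[OriPrediction]:
    """Rank intergenic regions as ori candidates.

    Candidate positions are local minima of the circular skew profile with
    prominence >= ``prominence_frac`` of the profile range. Regions are
    ranked by circular distance to the nearest candidate minimum (0 when a
    minimum falls inside), with repeat support inside the region, then
    minimum prominence, breaking ties. All regions are reported so that
    genuinely ambiguous cases (two valleys) stay visible.
    """
    if not regions:
        raise ValueError("no intergenic region >= min_len")
    L = seq.length
    v = profile.values
    vrange = float(v.max() - v.min())
    if vrange <= 0:
        warnings.warn(f"{seq.id}: flat skew profile, no ori prediction", stacklevel=2)
        return []
    tiled = np.concatenate([v, v, v])
    idx, props = find_peaks(-tiled, prominence=prominence_frac * vrange)
    keep = (idx >= L) & (idx < 2 * L)
    minima = idx[keep] - L
    prominences = props["prominences"][keep]
    if minima.size == 0:
        warnings.warn(f"{seq.id}: no prominent skew minimum", stacklevel=2)
        return []

    def _inside(p: int, region: tuple[int, int]) -> bool:
        return _circular_dist_to_interval(p, region, L) == 0

    scored = []
    for region in regions:
        dists = [_circular_dist_to_interval(int(m), region, L) for m in minima]
        best = int(np.argmin(dists))
        # among minima inside the region, prefer the most prominent one
        inside = [(prominences[i], i) for i in range(len(minima)) if dists[i] == 0]
        if inside:
            best = max(inside)[1]
        support = sum(
            1 for r in repeats
            if _inside(r.pos1, region) and _inside(r.pos2, region)
        )
        scored.append((dists[best], -support, -prominences[best], region,
                       int(minima[best])))
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return [
        OriPrediction(region=region, skew_min_pos=mpos, dist_to_min=dist,
                      repeat_support=-nsup, rank=i + 1)
        for i, (dist, nsup, _negprom, region, mpos) in enumerate(scored)
    ]
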