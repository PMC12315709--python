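"""Aggregate (pile-up) O/E analysis at single and pairwise CTCF sites.

Single-site pile-ups average O/E snippets centered on the site's diagonal
bin; pairwise pile-ups center on the off-diagonal pixel of a curated site
pair (same chromosome, same category, separation <= 250 kb).  Motif
orientation is normalized before averaging: '+' motifs point toward
increasing coordinates, and minus-strand snippets are anti-transposed so
the extrusion direction is uniform across sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import MotifSite, ValidationError
from .matrix import OEMatrix


@dataclass(frozen=True)
class SitePair:
    """Two same-chromosome, same-category motifs within the pairing window."""

    upstream: MotifSite
    downstream: MotifSite

    def __post_init__(self) -> None:
        if self.upstream.chrom != self.downstream.chrom:
            raise ValidationError("paired sites must share a chromosome")
        if not self.upstream.center < self.downstream.center:
            raise ValidationError("upstream center must precede downstream center")

    @property
    def separation(self) -> int:
        return self.downstream.center - self.upstream.center

    @property
    def convergent(self) -> bool:
        return self.upstream.strand == "+" and self.downstream.strand == "-"


@dataclass
class PileupMap:
    """Entrywise mean of O/E snippets over sites or pairs."""

    matrix: np.ndarray          # (2w+1, 2w+1)
    bin_size: int
    flank_bins: int
    n_aggregated: int
    n_skipped: int
    mode: str                   # "single" | "pairwise"

    @property
    def center(self) -> float:
        w = self.flank_bins
        return float(self.matrix[w, w])


def curate_pairs(sites: Sequence[MotifSite], max_sep: int = 250_000) -> list[SitePair]:
    """All unordered same-chromosome, same-category site pairs with center
    separation in (0, max_sep]."""
    groups: dict[tuple, list[MotifSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.category), []).append(s)
    pairs: list[SitePair] = []
    for members in groups.values():
        members = sorted(members, key=lambda s: s.center)
        for i, up in enumerate(members):
            for down in members[i + 1:]:
                sep = down.center - up.center
                if sep > max_sep:
                    break
                if sep > 0:
                    pairs.append(SitePair(up, down))
    return pairs


def _nanmean_stack(acc: np.ndarray, norm: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, acc / np.maximum(norm, 1), np.nan)


def aggregate_single(
    oe: OEMatrix,
    sites: Sequence[MotifSite],
    flank_bins: int = 25,
) -> PileupMap:
    """On-diagonal pile-up at oriented single sites.

    Minus-strand snippets are flipped along both axes (anti-transpose), so
    every aggregated site "points" rightward.  Sites within a flank of the
    chromosome edge are skipped and counted.  Missing values (masked bins,
    ignored diagonals) are excluded entrywise, not zero-filled.
    """
    w = flank_bins
    size = 2 * w + 1
    acc = np.zeros((size, size))
    norm = np.zeros((size, size))
    n_used = n_skip = 0
    for site in sites:
        b = site.center // oe.bin_size
        if b - w < 0 or b + w + 1 > oe.n_bins:
            n_skip += 1
            continue
        snip = oe.window(b - w, b + w + 1, b - w, b + w + 1)
        if site.strand == "-":
            snip = snip[::-1, ::-1]
        good = np.isfinite(snip)
        acc[good] += snip[good]
        norm += good
        n_used += 1
    if n_used == 0:
        raise ValidationError("no usable sites for the pile-up")
    return PileupMap(
        matrix=_nanmean_stack(acc, norm), bin_size=oe.bin_size,
        flank_bins=w, n_aggregated=n_used, n_skipped=n_skip, mode="single",
    )


def aggregate_pairwise(
    oe: OEMatrix,
    pairs: Sequence[SitePair],
    flank_bins: int = 10,
) -> PileupMap:
    """Off-diagonal pile-up at curated site pairs.

    The snippet is centered at (upstream bin, downstream bin).  Orientation
    is normalized so every pair looks convergent: an inward-pointing
    upstream motif ('+') keeps its row axis, an outward one is flipped, and
    likewise for the downstream motif's column axis.
    """
    w = flank_bins
    size = 2 * w + 1
    acc = np.zeros((size, size))
    norm = np.zeros((size, size))
    n_used = n_skip = 0
    for pair in pairs:
        bi = pair.upstream.center // oe.bin_size
        bj = pair.downstream.center // oe.bin_size
        if bi - w < 0 or bj + w + 1 > oe.n_bins or bi + w + 1 > oe.n_bins or bj - w < 0:
            n_skip += 1
            continue
        snip = oe.window(bi - w, bi + w + 1, bj - w, bj + w + 1)
        if pair.upstream.strand == "-":
            snip = snip[::-1, :]
        if pair.downstream.strand == "+":
            snip = snip[:, ::-1]
        good = np.isfinite(snip)
        if not good.any():
            n_skip += 1
            continue
        acc[good] += snip[good]
        norm += good
        n_used += 1
    if n_used == 0:
        raise ValidationError("no usable pairs for the pile-up")
    return PileupMap(
        matrix=_nanmean_stack(acc, norm), bin_size=oe.bin_size,
        flank_bins=w, n_aggregated=n_used, n_skipped=n_skip, mode="pairwise",
    )


def score_features(pileup: PileupMap) -> tuple[float, float]:
    """(insulation_score, loop_score) of a pile-up map.

    insulation_score (single mode): log2 of the mean over the two same-side
    blocks within w/2 of the center divided by the mean of the cross block
    (contacts spanning the site).  loop_score (pairwise mode): log2 of the
    mean center 3x3 block over the mean of the frame at Chebyshev distance w
    from the center.  A flat map scores (0, 0).
    """
    m = pileup.matrix
    w = pileup.flank_bins
    c = w
    if pileup.mode == "single":
        r = max(1, w // 2)
        same1 = m[c - r : c, c - r : c]
        same2 = m[c + 1 : c + r + 1, c + 1 : c + r + 1]
        cross = m[c - r : c, c + 1 : c + r + 1]
        same_mean = np.nanmean(np.concatenate([same1.ravel(), same2.ravel()]))
        cross_mean = np.nanmean(cross)
        insulation = float(np.log2(same_mean / cross_mean))
        return insulation, 0.0
    if pileup.mode == "pairwise":
        center = m[c - 1 : c + 2, c - 1 : c + 2]
        frame_mask = np.zeros_like(m, dtype=bool)
        frame_mask[0, :] = frame_mask[-1, :] = True
        frame_mask[:, 0] = frame_mask[:, -1] = True
        loop = float(np.log2(np.nanmean(center) / np.nanmean(m[frame_mask])))
        return 0.0, loop
    raise ValidationError(f"unknown pile-up mode {pileup.mode!r}")
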