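"""Synthetic ATAC-seq fragment libraries around oriented CTCF motifs.

A bound CTCF occupies an ~80 bp protected core around its motif and phases
the flanking nucleosomes into a tight array, so transposase cuts concentrate
at a ladder of accessible linker offsets on either side of the center
(defaults ±40, ±240, ±420, ±600 bp).  Fragments are pairs of cuts weighted
down by ``span_decay`` per protected unit (core or nucleosome) spanned
beyond the first:
core-spanning fragments then concentrate at lengths 80 / 280 / 460 / 640 bp,
reproducing the V-plot arm crossing and the flanking-nucleosome dots.  At
unbound sites cutting is unprotected and uniform, giving short fragments
over the whole window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .core import Fragment, MotifSite, ValidationError

PHASES = ("interphase", "mitotic")


@dataclass(frozen=True)
class FootprintModel:
    """Cut-site geometry of a bound CTCF site.

    ``ladder_offsets`` are accessible cut offsets on each side of the motif
    center; the first equals ``core_half_bp``.  The gaps between consecutive
    ladder offsets are the protected units (CTCF core, then phased
    nucleosomes); fragments spanning ``u`` units carry weight
    ``span_decay ** (u - 1)``.  Beyond the outermost ladder offset cutting is a
    uniform Poisson process at ``distal_rate`` per bp out to ``window_bp``.
    """

    core_half_bp: int = 40
    ladder_offsets: tuple = (40, 240, 420, 600)
    span_decay: float = 0.5
    jitter_sd_bp: float = 2.0
    distal_rate: float = 1.0 / 50.0
    window_bp: int = 1000

    def __post_init__(self) -> None:
        lad = tuple(self.ladder_offsets)
        if lad[0] != self.core_half_bp:
            raise ValidationError("first ladder offset must equal core_half_bp")
        if any(b <= a for a, b in zip(lad, lad[1:])):
            raise ValidationError("ladder offsets must be strictly increasing")
        if not (0 < self.span_decay <= 1):
            raise ValidationError("span_decay must lie in (0, 1]")
        if self.distal_rate <= 0 or self.window_bp <= lad[-1]:
            raise ValidationError("need distal_rate > 0 and window beyond the ladder")


@dataclass(frozen=True)
class SiteState:
    """Per-category binding probabilities by cell-cycle phase.

    Defaults: bookmarked sites stay fully bound in mitosis, reduced sites
    are bound half the time, lost sites not at all (and are occasionally
    unbound already in interphase).
    """

    p_bound: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "bookmarked": {"interphase": 1.0, "mitotic": 1.0},
            "reduced": {"interphase": 1.0, "mitotic": 0.5},
            "lost": {"interphase": 0.8, "mitotic": 0.0},
            "interphase_all": {"interphase": 1.0, "mitotic": 0.5},
        }
    )

    def probability(self, category: str, phase: str) -> float:
        if phase not in PHASES:
            raise ValidationError(f"phase must be one of {PHASES}")
        try:
            p = self.p_bound[category][phase]
        except KeyError:
            raise ValidationError(f"no binding probability for category {category!r}") from None
        if not (0 <= p <= 1):
            raise ValidationError("binding probabilities must lie in [0, 1]")
        return p


@lru_cache(maxsize=8)
def _pair_distribution(model: FootprintModel):
    """Cut-position pairs of the bound-site model with their weights.

    Cut sites are the mirrored ladder plus a 1 bp grid over the distal
    region; ladder sites have unit intensity, distal sites ``distal_rate``.
    A fragment is a pair of *consecutive* cuts of this inhomogeneous
    process, so a pair's weight is the product of the end intensities, a
    survival factor ``exp(-(accessible intensity strictly between))``, and
    ``span_decay`` per protected unit fully contained between the cuts
    beyond the first.
    """
    lad = np.array(model.ladder_offsets, dtype=float)
    edges = np.concatenate([-lad[::-1], lad])          # protected-block edges
    outer = model.ladder_offsets[-1]
    distal = np.concatenate([
        np.arange(-model.window_bp, -outer, dtype=float),
        np.arange(outer + 1, model.window_bp + 1, dtype=float),
    ])
    pos = np.concatenate([edges, distal])
    intensity = np.concatenate([
        np.ones(len(edges)),
        np.full(len(distal), model.distal_rate),
    ])
    order = np.argsort(pos)
    pos, intensity = pos[order], intensity[order]
    cum = np.concatenate([[0.0], np.cumsum(intensity)])

    i, j = np.triu_indices(len(pos), k=1)
    c1, c2 = pos[i], pos[j]
    # units fully inside (c1, c2): block k spans (edges[k], edges[k+1])
    i1 = np.searchsorted(edges, c1, side="left")
    i2 = np.searchsorted(edges, c2, side="right") - 1
    units = np.maximum(0, i2 - i1)
    between = cum[j] - cum[i + 1]      # intensity strictly between the cuts
    # decay applies per protected unit beyond the first: a fragment spanning
    # one block (the core, or one nucleosome) carries full weight
    w = (intensity[i] * intensity[j]
         * model.span_decay ** np.maximum(0, units - 1) * np.exp(-between))
    return c1, c2, w / w.sum()


def simulate_site_fragments(
    model: FootprintModel,
    site: MotifSite,
    bound: bool,
    n_fragments: int,
    seed: int,
) -> list[Fragment]:
    """Fragments around one motif; bound sites use the protected-ladder
    model, unbound sites uniform unprotected cutting."""
    if n_fragments < 1:
        raise ValidationError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    if bound:
        c1, c2, p = _pair_distribution(model)
        pick = rng.choice(len(p), size=n_fragments, p=p)
        lo, hi = c1[pick].copy(), c2[pick].copy()
    else:
        lo = rng.uniform(-model.window_bp, model.window_bp, size=n_fragments)
        hi = lo + np.maximum(1.0, rng.exponential(1.0 / model.distal_rate, size=n_fragments))
    if model.jitter_sd_bp > 0:
        lo = lo + rng.normal(0, model.jitter_sd_bp, size=n_fragments)
        hi = hi + rng.normal(0, model.jitter_sd_bp, size=n_fragments)
    if site.strand == "-":
        lo, hi = -hi, -lo
    start = site.center + np.floor(lo).astype(np.int64)
    end = site.center + np.ceil(hi).astype(np.int64)
    end = np.maximum(end, start + 1)
    return [Fragment(site.chrom, int(s), int(e)) for s, e in zip(start, end)]


@dataclass
class LibraryResult:
    """A simulated library plus its ground-truth run manifest."""

    fragments: list
    sites: list
    bound: list                 # per-site ground truth, aligned with sites
    phase: str
    n_per_site: int
    seed: int

    def manifest(self) -> list[dict]:
        return [
            {
                "chrom": s.chrom,
                "center": s.center,
                "strand": s.strand,
                "category": s.category,
                "bound": bool(b),
            }
            for s, b in zip(self.sites, self.bound)
        ]


def simulate_library(
    model: FootprintModel,
    sites: Sequence[MotifSite],
    state: SiteState,
    phase: str,
    n_per_site: int,
    seed: int,
) -> LibraryResult:
    """Simulate a pooled fragment library over many sites.

    Each site is independently bound with the category/phase probability
    from *state*; exactly ``n_per_site`` fragments are drawn per site, so
    the output holds ``len(sites) * n_per_site`` fragments.
    """
    rng = np.random.default_rng(seed)
    fragments: list[Fragment] = []
    bound_flags: list[bool] = []
    for site in sites:
        p = state.probability(site.category, phase)
        bound = bool(rng.random() < p)
        bound_flags.append(bound)
        child = int(rng.integers(0, 2**31 - 1))
        fragments.extend(simulate_site_fragments(model, site, bound, n_per_site, child))
    return LibraryResult(
        fragments=fragments, sites=list(sites), bound=bound_flags,
        phase=phase, n_per_site=n_per_site, seed=seed,
    )
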