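"""Synthetic Hi-C contact generators.

Two statistical contact-kernel models (not polymer simulations):

* :func:`simulate_mitotic` — a sequence-independent condensin loop array.
  Loop anchors are laid down by a renewal process with Gamma-distributed
  gaps (mean ``mean_loop_bp``).  A contact is intra-loop with probability
  ``w_intra`` (two points inside a size-biased loop, separation drawn from a
  truncated power law with exponent ``alpha_intra``); otherwise it joins two
  loops whose scaffold separation Δk (in loops) follows a shallower power
  law with exponent ``beta_inter``, optionally modulated by a helical-turn
  enrichment at genomic separations near integer multiples of
  ``helix_period_bp``.  Positions never depend on motif annotations.

* :func:`simulate_interphase` — a distance-decay background mixed with a
  cohesin-loop kernel, multiplied by per-category TAD insulation at CTCF
  motif boundaries, Gaussian loop "dots" at convergent motif pairs, and
  one-directional extrusion stripes.  Sampling is exact via importance
  resampling from the separation kernel.

Identical (params, seed) always yield identical contact lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import ContactList, MotifSite, ValidationError


@dataclass(frozen=True)
class LoopArrayParams:
    """Parameters of the mitotic condensin loop-array model."""

    mean_loop_bp: float
    gap_shape: float = 8.0          # Gamma shape of anchor gaps; inf = regular
    alpha_intra: float = 1.5        # intra-loop contact decay exponent
    beta_inter: float = 1.4         # scaffold (inter-loop) decay exponent
    w_intra: float = 0.6            # probability a contact is intra-loop
    helix_period_bp: Optional[float] = None  # nominal period = where the
                                             # secondary derivative peak appears
    helix_amp: float = 0.3
    helix_sigma_bp: Optional[float] = None   # comb width; default period / 12
    helix_shape: str = "gaussian_comb"       # or "cosine"
    helix_pitch_factor: float = 1.3          # underlying turn size relative to
                                             # the nominal period; the derivative
                                             # peak of a bump sits at its left
                                             # inflection, below the crest
    anchor_bias: float = 0.1    # Beta(a, a) position-in-loop for inter-loop
                                # contacts; < 1 concentrates at the scaffold
                                # anchors, 1 = uniform
    n_cells: int = 64           # independent anchor realizations pooled into
                                # one library (population-average map)

    def __post_init__(self) -> None:
        if self.mean_loop_bp <= 0:
            raise ValidationError("mean_loop_bp must be positive")
        if not (self.alpha_intra > self.beta_inter >= 0):
            raise ValidationError("require alpha_intra > beta_inter >= 0")
        if not (0 < self.w_intra < 1):
            raise ValidationError("w_intra must be in (0, 1)")
        if self.helix_amp < 0:
            raise ValidationError("helix_amp must be >= 0")
        if self.helix_shape not in ("gaussian_comb", "cosine"):
            raise ValidationError("helix_shape must be gaussian_comb or cosine")
        if self.anchor_bias <= 0:
            raise ValidationError("anchor_bias must be positive")
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")


def _default_strength(bookmarked: float, reduced: float, lost: float,
                      interphase_all: float) -> Mapping[str, float]:
    return {
        "bookmarked": bookmarked,
        "reduced": reduced,
        "lost": lost,
        "interphase_all": interphase_all,
    }


@dataclass(frozen=True)
class InterphaseParams:
    """Parameters of the interphase TAD / CTCF-loop contact model.

    ``insulation_strength`` maps a site category to the multiplicative
    cross-boundary attenuation per boundary (smaller = stronger insulation);
    defaults order bookmarked < reduced < lost, i.e. insulation is strongest
    at bookmarked sites.  ``dot_strength`` / ``stripe_strength`` are
    enrichment multipliers for convergent-pair loop dots and one-directional
    extrusion stripes.
    """

    bg_exponent: float = 1.1
    cohesin_loop_bp: float = 100_000
    loop_fraction: float = 0.15          # fraction of contacts from the
                                         # cohesin anchor-anchor term
    loop_width_decades: float = 0.15     # log10 width of the loop-scale bump
    tad_boundary_insulation: float = 0.5
    insulation_strength: Mapping[str, float] = field(
        default_factory=lambda: _default_strength(0.35, 0.55, 0.75, 0.5)
    )
    dot_strength: Mapping[str, float] = field(
        default_factory=lambda: _default_strength(4.0, 2.0, 0.8, 3.0)
    )
    stripe_strength: Mapping[str, float] = field(
        default_factory=lambda: _default_strength(1.5, 0.8, 0.3, 1.0)
    )
    dot_sigma_bp: float = 10_000
    dot_max_sep_bp: float = 250_000
    stripe_reach_bp: float = 150_000
    stripe_sigma_bp: float = 10_000
    s_min_bp: float = 1_000

    def __post_init__(self) -> None:
        for table in (self.insulation_strength, self.dot_strength, self.stripe_strength):
            if any(v < 0 for v in table.values()):
                raise ValidationError("strength multipliers must be >= 0")
        if any(not (0 < v <= 1) for v in self.insulation_strength.values()):
            raise ValidationError("insulation attenuations must lie in (0, 1]")
        if not (0 < self.tad_boundary_insulation <= 1):
            raise ValidationError("tad_boundary_insulation must lie in (0, 1]")


# ---------------------------------------------------------------------------
# mitotic loop array


def _draw_anchors(rng: np.random.Generator, params: LoopArrayParams,
                  chrom_length: float) -> np.ndarray:
    """Renewal anchor positions on [0, chrom_length], endpoints included."""
    L = params.mean_loop_bp
    gaps = []
    total = 0.0
    block = max(16, int(2 * chrom_length / L) + 8)
    while total < chrom_length:
        if np.isinf(params.gap_shape):
            g = np.full(block, L)
        else:
            g = rng.gamma(params.gap_shape, L / params.gap_shape, size=block)
        gaps.append(g)
        total += float(g.sum())
    pos = np.cumsum(np.concatenate(gaps))
    pos = pos[pos < chrom_length]
    return np.concatenate([[0.0], pos, [float(chrom_length)]])


def _truncated_power_law(rng: np.random.Generator, alpha: float,
                         s_min: np.ndarray, s_max: np.ndarray) -> np.ndarray:
    """Inverse-CDF samples from p(s) ~ s^-alpha on [s_min, s_max] (alpha != 1)."""
    u = rng.random(len(s_min))
    e = 1.0 - alpha
    return (s_min ** e + u * (s_max ** e - s_min ** e)) ** (1.0 / e)


def _helix_factor(params: LoopArrayParams, dg: np.ndarray) -> np.ndarray:
    if params.helix_period_bp is None or params.helix_amp == 0:
        return np.ones_like(dg)
    period = params.helix_period_bp * params.helix_pitch_factor
    if params.helix_shape == "cosine":
        return 1.0 + params.helix_amp * np.cos(2 * np.pi * dg / period)
    sigma = params.helix_sigma_bp if params.helix_sigma_bp is not None else period / 12.0
    k = np.round(dg / period)
    r = dg - k * period
    bump = np.exp(-0.5 * (r / sigma) ** 2)
    return 1.0 + params.helix_amp * np.where(k >= 1, bump, 0.0)


def _sample_cell(rng: np.random.Generator, params: LoopArrayParams,
                 chrom_length_bp: int, n_contacts: int) -> tuple[np.ndarray, np.ndarray]:
    """Contacts of one cell: one anchor realization of the loop array."""
    anchors = _draw_anchors(rng, params, chrom_length_bp)
    starts, ends = anchors[:-1], anchors[1:]
    lens = ends - starts
    n_loops = len(lens)

    intra = rng.random(n_contacts) < params.w_intra
    if n_loops < 2:
        intra[:] = True
    pos1 = np.empty(n_contacts)
    pos2 = np.empty(n_contacts)

    n_in = int(intra.sum())
    if n_in:
        # size-biased loop choice: longer loops hold more contacts
        p_loop = lens / lens.sum()
        li = rng.choice(n_loops, size=n_in, p=p_loop)
        ll = lens[li]
        smin = np.minimum(100.0, 0.5 * ll)
        s = _truncated_power_law(rng, params.alpha_intra, smin, ll)
        a = starts[li] + rng.random(n_in) * (ll - s)
        pos1[intra] = a
        pos2[intra] = a + s

    n_out = n_contacts - n_in
    if n_out:
        ii, jj = np.triu_indices(n_loops, k=1)
        dk = (jj - ii).astype(float)
        mids = 0.5 * (starts + ends)
        w = dk ** (-params.beta_inter) * _helix_factor(params, mids[jj] - mids[ii])
        w /= w.sum()
        pick = rng.choice(len(ii), size=n_out, p=w)
        # scaffold locality: positions inside each loop are drawn Beta(a, a),
        # concentrating near the anchors for a < 1 (uniform at a = 1)
        ab = params.anchor_bias
        u1 = rng.random(n_out) if ab == 1.0 else rng.beta(ab, ab, size=n_out)
        u2 = rng.random(n_out) if ab == 1.0 else rng.beta(ab, ab, size=n_out)
        a = starts[ii[pick]] + u1 * lens[ii[pick]]
        b = starts[jj[pick]] + u2 * lens[jj[pick]]
        pos1[~intra] = a
        pos2[~intra] = b
    return pos1, pos2


def simulate_mitotic(
    params: LoopArrayParams,
    chrom_length_bp: int,
    n_contacts: int,
    seed: int,
    chrom: str = "simM",
) -> ContactList:
    """Sample contacts from the sequence-independent loop-array model.

    The library pools ``n_cells`` independent anchor realizations, mirroring
    a population-average map: scaffold anchors sit at different genomic
    positions in every cell, so binned coverage is uniform even though each
    cell's contacts concentrate at its own anchors.
    """
    if n_contacts < 1:
        raise ValidationError("n_contacts must be >= 1")
    if params.mean_loop_bp >= chrom_length_bp:
        raise ValidationError("mean loop size must be smaller than the chromosome")
    rng = np.random.default_rng(seed)
    n_cells = min(params.n_cells, n_contacts)
    per_cell = np.full(n_cells, n_contacts // n_cells)
    per_cell[: n_contacts % n_cells] += 1
    parts1, parts2 = [], []
    for n_c in per_cell:
        p1, p2 = _sample_cell(rng, params, chrom_length_bp, int(n_c))
        parts1.append(p1)
        parts2.append(p2)
    pos1 = np.clip(np.concatenate(parts1), 0, chrom_length_bp - 1).astype(np.int64)
    pos2 = np.clip(np.concatenate(parts2), 0, chrom_length_bp - 1).astype(np.int64)
    chroms = np.full(n_contacts, chrom, dtype=object)
    return ContactList(chroms, pos1, chroms, pos2)


# ---------------------------------------------------------------------------
# interphase TAD / CTCF-loop model


def _sample_separations(rng, params: InterphaseParams, g: float, n: int) -> np.ndarray:
    """Draw separations from the interphase mixture via a fine log grid.

    The background component decays as ``s^-bg_exponent``; the cohesin
    component is a lognormal bump of contacts at the loop scale
    (anchor-anchor proximity of extruded loops), holding ``loop_fraction``
    of the mass.  Both are weighted by the ``g - s`` locus-pair count.
    """
    edges = np.geomspace(params.s_min_bp, g, 4097)
    mid = np.sqrt(edges[:-1] * edges[1:])
    pair_w = (g - mid) * np.diff(edges)
    bg = mid ** (-params.bg_exponent) * pair_w
    z = (np.log10(mid) - np.log10(params.cohesin_loop_bp)) / params.loop_width_decades
    loop = np.exp(-0.5 * z * z) / mid * pair_w
    f = params.loop_fraction
    w = (1.0 - f) * bg / bg.sum() + f * loop / loop.sum()
    w = np.clip(w, 0, None)
    cells = rng.choice(len(mid), size=n, p=w / w.sum())
    u = rng.random(n)
    return edges[cells] * (edges[cells + 1] / edges[cells]) ** u


def _modulation(params: InterphaseParams, motifs: Sequence[MotifSite],
                x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Insulation x dot x stripe weight for contacts (x < y)."""
    if not motifs:
        return np.ones_like(x)
    centers = np.array([m.center for m in motifs], dtype=float)
    order = np.argsort(centers)
    centers = centers[order]
    cats = [motifs[i].category for i in order]
    strands = [motifs[i].strand for i in order]

    log_att = np.array([np.log(params.insulation_strength[c]) for c in cats])
    cum = np.concatenate([[0.0], np.cumsum(log_att)])
    k1 = np.searchsorted(centers, x, side="right")
    k2 = np.searchsorted(centers, y, side="left")
    m = np.exp(cum[np.maximum(k2, k1)] - cum[k1])

    sig = params.dot_sigma_bp
    dot = np.zeros_like(x)
    for i in range(len(centers)):
        if strands[i] != "+":
            continue
        for j in range(i + 1, len(centers)):
            if centers[j] - centers[i] > params.dot_max_sep_bp:
                break
            if strands[j] != "-":
                continue
            strength = 0.5 * (params.dot_strength[cats[i]] + params.dot_strength[cats[j]])
            if strength == 0:
                continue
            dx = x - centers[i]
            dy = y - centers[j]
            near = (np.abs(dx) < 5 * sig) & (np.abs(dy) < 5 * sig)
            if near.any():
                dot[near] += strength * np.exp(
                    -0.5 * ((dx[near] / sig) ** 2 + (dy[near] / sig) ** 2)
                )
    m = m * (1.0 + dot)

    ssig = params.stripe_sigma_bp
    reach = params.stripe_reach_bp
    stripe = np.zeros_like(x)
    for i in range(len(centers)):
        st = params.stripe_strength[cats[i]]
        if st == 0:
            continue
        c = centers[i]
        if strands[i] == "+":
            # anchor at x ~ c, partner extruded rightward (y > c)
            near = (np.abs(x - c) < 5 * ssig) & (y > c)
            if near.any():
                stripe[near] += st * np.exp(-0.5 * ((x[near] - c) / ssig) ** 2) * np.exp(
                    -(y[near] - c) / reach
                )
        else:
            near = (np.abs(y - c) < 5 * ssig) & (x < c)
            if near.any():
                stripe[near] += st * np.exp(-0.5 * ((y[near] - c) / ssig) ** 2) * np.exp(
                    -(c - x[near]) / reach
                )
    return m * (1.0 + stripe)


def simulate_interphase(
    params: InterphaseParams,
    motifs: Sequence[MotifSite],
    chrom_length_bp: int,
    n_contacts: int,
    seed: int,
    chrom: str = "simI",
    oversample: float = 2.0,
) -> ContactList:
    """Sample interphase contacts with TAD insulation, loop dots and stripes.

    Proposals are drawn from the pure separation kernel and importance-
    resampled with the motif-dependent modulation weight, which samples the
    product density exactly (duplicate records may occur, as in real pair
    lists).
    """
    if n_contacts < 1:
        raise ValidationError("n_contacts must be >= 1")
    for m in motifs:
        if m.center >= chrom_length_bp:
            raise ValidationError(f"motif center {m.center} beyond chromosome end")
    rng = np.random.default_rng(seed)
    n_prop = int(np.ceil(n_contacts * max(1.0, oversample)))
    s = _sample_separations(rng, params, float(chrom_length_bp), n_prop)
    x = rng.random(n_prop) * (chrom_length_bp - s)
    y = x + s
    w = _modulation(params, list(motifs), x, y)
    if np.allclose(w, w[0]):
        sel = np.arange(n_contacts)
    else:
        sel = rng.choice(n_prop, size=n_contacts, p=w / w.sum(), replace=True)
    p1 = np.clip(x[sel], 0, chrom_length_bp - 1).astype(np.int64)
    p2 = np.clip(y[sel], 0, chrom_length_bp - 1).astype(np.int64)
    chroms = np.full(n_contacts, chrom, dtype=object)
    return ContactList(chroms, p1, chroms, p2)
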