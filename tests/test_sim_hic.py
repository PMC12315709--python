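"""Synthetic Hi-C generators: determinism, kernel behaviour, presets and
parameter recovery."""

import numpy as np
import pytest

from mitoloop.core import ValidationError
from mitoloop.matrix import bin_contacts, expected_by_distance, ice_balance, observed_over_expected
from mitoloop.presets import get_preset, preset_names
from mitoloop.scaling import compute_ps, loop_size_pipeline
from mitoloop.sim_hic import (
    InterphaseParams,
    LoopArrayParams,
    simulate_interphase,
    simulate_mitotic,
)
from tests.conftest import make_site

G = 40_000_000


class TestParams:
    def test_exponent_ordering_enforced(self):
        with pytest.raises(ValidationError):
            LoopArrayParams(mean_loop_bp=1e5, alpha_intra=0.5, beta_inter=0.9)

    def test_w_intra_open_interval(self):
        with pytest.raises(ValidationError):
            LoopArrayParams(mean_loop_bp=1e5, w_intra=1.0)

    def test_insulation_attenuation_bounds(self):
        with pytest.raises(ValidationError):
            InterphaseParams(insulation_strength={"bookmarked": 1.5, "reduced": 1,
                                                  "lost": 1, "interphase_all": 1})


class TestMitotic:
    def test_seed_reproducibility(self):
        p = LoopArrayParams(mean_loop_bp=250_000)
        a = simulate_mitotic(p, G, 50_000, 9)
        b = simulate_mitotic(p, G, 50_000, 9)
        assert a == b

    def test_different_seeds_differ(self):
        p = LoopArrayParams(mean_loop_bp=250_000)
        assert simulate_mitotic(p, G, 5_000, 1) != simulate_mitotic(p, G, 5_000, 2)

    def test_degenerate_loop_size_rejected(self):
        with pytest.raises(ValidationError):
            simulate_mitotic(LoopArrayParams(mean_loop_bp=G), G, 100, 1)

    def test_positions_inside_chromosome(self):
        p = LoopArrayParams(mean_loop_bp=500_000)
        cl = simulate_mitotic(p, G, 20_000, 3)
        assert cl.pos1.min() >= 0 and cl.pos2.max() < G

    def test_single_whole_chromosome_loop_follows_intra_kernel(self):
        # one loop spanning the chromosome, regular gaps: the separation
        # distribution is the pure intra kernel with log-log slope -alpha
        p = LoopArrayParams(mean_loop_bp=G - 1, gap_shape=np.inf,
                            w_intra=0.999, n_cells=1)
        cl = simulate_mitotic(p, G, 400_000, 11)
        ps = compute_ps(cl, {"simM": G}, s_min=20_000, s_max=G / 10)
        sel = np.isfinite(ps.p) & (ps.p > 0)
        coef = np.polyfit(np.log10(ps.centers[sel]), np.log10(ps.p[sel]), 1)
        assert abs(coef[0] + p.alpha_intra) < 0.1

    def test_ps_nonincreasing_outside_loop_scale(self):
        """P(s) decays monotonically except at the loop-scale contact
        enrichment that produces the derivative peak."""
        L = 250_000
        cl = simulate_mitotic(LoopArrayParams(mean_loop_bp=L), G, 1_000_000, 5)
        ps = compute_ps(cl, {"simM": G}, s_min=10_000, s_max=G / 4)
        ok = np.isfinite(ps.p)
        vals, centers = ps.p[ok], ps.centers[ok]

        def outside(c):
            return c < L / 3 or c > 3 * L

        for k in range(2, len(vals)):
            if outside(centers[k]) and outside(centers[k - 1]):
                assert vals[k] < vals[k - 1] * 1.05
        # global decay across the loop scale
        assert vals[-1] < vals[1]

    def test_motif_independence_of_mitotic_maps(self):
        """Mean center O/E at motif positions is category-independent."""
        cl = simulate_mitotic(LoopArrayParams(mean_loop_bp=300_000), G, 1_000_000, 21)
        m = bin_contacts(cl, "simM", G, 10_000)
        ice_balance(m)
        oe = observed_over_expected(m, expected_by_distance(m))
        rng = np.random.default_rng(0)
        means = {}
        for cat, lo in (("bookmarked", 1_000_000), ("lost", 1_200_000)):
            centers = rng.integers(lo, G - 1_000_000, 300)
            vals = []
            for c in centers:
                b = int(c) // 10_000
                w = oe.window(b - 2, b + 3, b - 2, b + 3)
                vals.append(np.nanmean(w))
            means[cat] = np.mean(vals)
        assert abs(means["bookmarked"] - means["lost"]) < 0.1


class TestInterphase:
    def test_seed_reproducibility(self):
        p = InterphaseParams()
        sites = [make_site(5_000_000 + i * 1_000_000, "+", "bookmarked", chrom="simI")
                 for i in range(5)]
        a = simulate_interphase(p, sites, G, 30_000, 4)
        b = simulate_interphase(p, sites, G, 30_000, 4)
        assert a == b

    def test_motif_beyond_end_rejected(self):
        site = make_site(G + 10_000, chrom="simI")
        with pytest.raises(ValidationError):
            simulate_interphase(InterphaseParams(), [site], G, 100, 1)

    def test_null_strengths_give_flat_oe_at_motifs(self):
        p = InterphaseParams(
            insulation_strength={c: 1.0 for c in ("bookmarked", "reduced", "lost", "interphase_all")},
            dot_strength={c: 0.0 for c in ("bookmarked", "reduced", "lost", "interphase_all")},
            stripe_strength={c: 0.0 for c in ("bookmarked", "reduced", "lost", "interphase_all")},
        )
        sites = [make_site(2_000_000 + i * 700_000, "+" if i % 2 else "-",
                           "bookmarked", chrom="simI") for i in range(40)]
        cl = simulate_interphase(p, sites, G, 1_500_000, 8)
        m = bin_contacts(cl, "simI", G, 10_000)
        ice_balance(m)
        oe = observed_over_expected(m, expected_by_distance(m))
        vals = []
        for s in sites:
            b = s.center // 10_000
            w = oe.window(b - 3, b + 4, b - 3, b + 4)
            vals.append(np.nanmean(w))
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_ps_nonincreasing_outside_loop_scale(self):
        L = 100_000
        cl = simulate_interphase(InterphaseParams(), [], G, 1_000_000, 6)
        ps = compute_ps(cl, {"simI": G}, s_min=10_000, s_max=G / 4)
        ok = np.isfinite(ps.p)
        vals, centers = ps.p[ok], ps.centers[ok]

        def outside(c):
            return c < L / 3 or c > 3 * L

        for k in range(2, len(vals)):
            if outside(centers[k]) and outside(centers[k - 1]):
                assert vals[k] < vals[k - 1] * 1.05
        assert vals[-1] < vals[1]


class TestPresets:
    def test_species_preset_loop_sizes(self):
        assert get_preset("chicken").params.mean_loop_bp == 250_000
        assert get_preset("human").params.mean_loop_bp == 450_000
        assert get_preset("mouse").params.mean_loop_bp == 1_250_000
        assert get_preset("mouse").params.helix_period_bp == 10_000_000
        assert get_preset("interphase_reference").params.cohesin_loop_bp == 100_000

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValidationError, match="chicken"):
            get_preset("dog")

    def test_registry_names(self):
        assert set(preset_names()) == {"chicken", "human", "mouse", "interphase_reference"}


RECOVERY_GRID = [
    (250_000, 25_000),
    (450_000, 25_000),
    (700_000, 50_000),
    (1_000_000, 50_000),
    (1_250_000, 50_000),
]


@pytest.fixture(scope="module")
def recovery_estimates():
    out = {}
    for loop_bp, bin_size in RECOVERY_GRID:
        cl = simulate_mitotic(LoopArrayParams(mean_loop_bp=loop_bp),
                              150_000_000, 3_000_000, 31)
        est = loop_size_pipeline(cl, "simM", 150_000_000, bin_size, "mitotic")
        assert est.defined
        out[loop_bp] = est.l_hat
    return out


class TestParameterRecovery:
    """Calibrated estimator recovers the generator's loop size across a grid."""

    def test_recovery_within_25_percent(self, recovery_estimates):
        for truth, l_hat in recovery_estimates.items():
            assert abs(l_hat - truth) / truth < 0.25

    def test_estimator_monotone_in_loop_size(self, recovery_estimates):
        ordered = [recovery_estimates[k] for k, _ in RECOVERY_GRID]
        assert np.all(np.diff(ordered) > 0)
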