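"""Fit the loop-size estimator calibration constants.

Runs the synthetic generators over a grid of loop sizes (three seeds each),
measures the P(s) log-derivative peak through the standard pipeline
(bin, balance, P(s), smoothed derivative, refined peak), and prints the
median ratio s_peak / L per regime.  The resulting constants are frozen in
``mitoloop.presets.CALIBRATION``; rerun this script only when the generator
or the derivative pipeline changes, and update the registry by hand.

Usage:  python scripts/calibrate.py
"""

import numpy as np

from mitoloop.scaling import fit_peak_calibration, loop_size_pipeline
from mitoloop.sim_hic import InterphaseParams, LoopArrayParams, simulate_interphase, simulate_mitotic

CHROM_LENGTH = 150_000_000
N_CONTACTS = 3_000_000
SEEDS = (101, 102, 103)

# loop-size grid (bp) with the analysis bin size recommended at that scale
MITOTIC_GRID = [
    (250_000, 25_000),
    (450_000, 25_000),
    (700_000, 50_000),
    (1_000_000, 50_000),
    (1_250_000, 50_000),
]
INTERPHASE_GRID = [
    (75_000, 10_000),
    (100_000, 10_000),
    (125_000, 10_000),
    (150_000, 10_000),
    (200_000, 10_000),
]


def main() -> None:
    for regime, grid in (("mitotic", MITOTIC_GRID), ("interphase", INTERPHASE_GRID)):
        peaks, truths = [], []
        for loop_bp, bin_size in grid:
            for seed in SEEDS:
                if regime == "mitotic":
                    contacts = simulate_mitotic(
                        LoopArrayParams(mean_loop_bp=loop_bp), CHROM_LENGTH, N_CONTACTS, seed
                    )
                    chrom = "simM"
                else:
                    contacts = simulate_interphase(
                        InterphaseParams(cohesin_loop_bp=loop_bp), [], CHROM_LENGTH, N_CONTACTS, seed
                    )
                    chrom = "simI"
                est = loop_size_pipeline(
                    contacts, chrom, CHROM_LENGTH, bin_size, regime, c_cal=1.0
                )
                if est.s_peak is None:
                    print(f"  {regime} L={loop_bp} seed={seed}: no peak (skipped)")
                    continue
                peaks.append(est.s_peak)
                truths.append(loop_bp)
                print(f"  {regime} L={loop_bp} seed={seed}: s_peak={est.s_peak:.0f} "
                      f"ratio={est.s_peak / loop_bp:.4f}")
        c = fit_peak_calibration(peaks, truths)
        print(f"{regime}: c_cal = {c:.4f}  (n = {len(peaks)})")


if __name__ == "__main__":
    main()
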