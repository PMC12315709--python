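"""Chromosome-arm accounting and mitotic compaction statistics.

The q-arm is by definition the longer arm (centromere to the farther
telomere).  Compaction is expressed as genomic megabases per micrometer of
measured chromatid length; two groups (species / cell lines) are compared
with an unpaired t-test, and mean loop size is related to the longest q-arm
across species by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CompactionRecord, KaryotypeRecord, ValidationError


@dataclass
class ArmSummary:
    table: pd.DataFrame          # chrom, length_bp, p_arm_bp, q_arm_bp
    mean_qarm_bp: float
    max_qarm_bp: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    variant: str


def arm_lengths(karyotype: Sequence[KaryotypeRecord]) -> ArmSummary:
    """Per-chromosome p/q arm lengths; q = max(arm lengths), p + q = length."""
    rows = []
    for rec in karyotype:
        q = max(rec.centromere_bp, rec.length_bp - rec.centromere_bp)
        rows.append((rec.chrom, rec.length_bp, rec.length_bp - q, q))
    df = pd.DataFrame(rows, columns=["chrom", "length_bp", "p_arm_bp", "q_arm_bp"])
    if df.empty:
        raise ValidationError("empty karyotype")
    return ArmSummary(
        table=df,
        mean_qarm_bp=float(df.q_arm_bp.mean()),
        max_qarm_bp=float(df.q_arm_bp.max()),
    )


def compaction_ratio(records: Sequence[CompactionRecord]) -> pd.DataFrame:
    """Per-chromatid Mb/um ratios with per-group mean and SD.

    Returns a tidy frame (group, chromatid_length_um, qarm_mb, mb_per_um);
    group summaries are available via ``df.groupby("group").mb_per_um``.
    """
    if not records:
        raise ValidationError("no compaction records")
    df = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "chromatid_length_um": [r.chromatid_length_um for r in records],
            "qarm_mb": [r.qarm_mb for r in records],
        }
    )
    df["mb_per_um"] = df.qarm_mb / df.chromatid_length_um
    return df


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "student",
    labels: tuple = ("A", "B"),
) -> GroupComparison:
    """Unpaired two-sided t-test on two groups of Mb/um ratios.

    ``variant="student"`` pools variances (df = n_a + n_b - 2);
    ``variant="welch"`` uses the Welch-Satterthwaite correction.  Two
    identical constant groups return t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need n >= 2 per group")
    if variant not in ("student", "welch"):
        raise ValidationError("variant must be 'student' or 'welch'")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
        df = len(a) + len(b) - 2
    else:
        res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        group_a=labels[0], group_b=labels[1],
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b),
        t_statistic=t, df=df, p_value=p, variant=variant,
    )


def loopsize_vs_qarm(table: pd.DataFrame) -> tuple[Optional[float], pd.DataFrame]:
    """Spearman rank correlation of mean loop size against longest q-arm.

    *table* needs columns species, loop_size_bp, longest_qarm_bp and at
    least three rows.  Returns (rho, report) where the report lists species
    sorted by loop size with their rank under each key and an agreement
    flag; rho is None (flagged undefined) when both keys are entirely tied.
    """
    required = {"species", "loop_size_bp", "longest_qarm_bp"}
    if not required.issubset(table.columns):
        raise ValidationError(f"table requires columns {sorted(required)}")
    if len(table) < 3:
        raise ValidationError("need >= 3 species rows")
    df = table.copy()
    df["loop_rank"] = df.loop_size_bp.rank()
    df["qarm_rank"] = df.longest_qarm_bp.rank()
    df["rank_agreement"] = df.loop_rank == df.qarm_rank
    df = df.sort_values("loop_size_bp").reset_index(drop=True)
    if df.loop_size_bp.nunique() == 1 and df.longest_qarm_bp.nunique() == 1:
        return None, df
    rho = float(stats.spearmanr(df.loop_size_bp, df.longest_qarm_bp).statistic)
    return rho, df


def simulate_measurements(
    true_ratios: dict,
    qarm_mb: float,
    n_per_group: int,
    sd: float,
    seed: int,
) -> list[CompactionRecord]:
    """Synthetic chromatid measurements for groups with given true Mb/um.

    Each chromatid's compaction ratio is drawn Normal(true ratio, sd) and
    converted to a physical length for a fixed genomic q-arm size.
    """
    if sd < 0 or n_per_group < 1 or qarm_mb <= 0:
        raise ValidationError("invalid simulation parameters")
    rng = np.random.default_rng(seed)
    records = []
    for group, ratio in true_ratios.items():
        draws = rng.normal(ratio, sd, size=n_per_group)
        draws = np.clip(draws, 0.1 * ratio, None)  # physical ratios stay positive
        for r in draws:
            records.append(CompactionRecord(group, qarm_mb / r, qarm_mb))
    return records
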