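"""Read-through ratio statistics for termination-defect analysis.

Two per-gene statistics quantify polymerase read-through past the 3'-end
processing site (TES):

* nascent-transcription (PRO-seq style) ratio — signal summed over the
  window 500–1000 bp downstream of the TES divided by the signal over the
  50 bp immediately upstream of the TES, on the gene's strand;
* polymerase-occupancy (Pol II ChIP style) ratio — signal from the TES to
  1000 bp downstream divided by the signal from the TSS to 1000 bp
  downstream. The numerator window is a subset of the denominator window,
  so valid values lie in [0, 1].

Both statistics are ratios of sums over the same track, hence invariant
under any global rescaling of the signal (e.g. spike-in normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_io import (
    CoverageTrack,
    GeneModel,
    strand_window,
    window_in_bounds,
)


@dataclass(frozen=True)
class ReadThroughParams:
    """Window constants for the two ratios (all in bases).

    Defaults: downstream nascent window [TES+500, TES+1000), upstream
    denominator 50 bp, occupancy downstream extension 1000 bp.
    """

    pro_down_start: int = 500
    pro_down_end: int = 1000
    pro_up_len: int = 50
    pol_down_len: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.pro_down_start < self.pro_down_end):
            raise ValueError("need 0 <= pro_down_start < pro_down_end")
        if self.pro_up_len <= 0 or self.pol_down_len <= 0:
            raise ValueError("window lengths must be positive")


@dataclass(frozen=True)
class ReadThroughResult:
    gene_id: str
    statistic: str  # "proseq" | "polii"
    numerator: float
    denominator: float
    ratio: float  # NaN when invalid
    valid: bool
    invalid_reason: str  # "zero_denominator" | "window_out_of_bounds" | "none"
    gene_class: str = "other"


@dataclass(frozen=True)
class BoxStats:
    """Tukey box-plot summary: quartiles plus 1.5×IQR whiskers."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass(frozen=True)
class GroupComparison:
    gene_class: str
    condition_a: BoxStats
    condition_b: BoxStats
    t_statistic: float
    p_value: float
    n_excluded_a: int
    n_excluded_b: int


def proseq_readthrough_ratio(
    track: CoverageTrack, gene: GeneModel, params: ReadThroughParams = ReadThroughParams()
) -> ReadThroughResult:
    """Nascent 3'-end read-through ratio for one gene.

    Numerator: strand-specific signal over [TES+500, TES+1000) in transcript
    orientation; denominator: signal over [TES-50, TES). A zero denominator
    or a window beyond the chromosome end yields an invalid result rather
    than an exception.
    """
    num_win = strand_window(gene, params.pro_down_start, params.pro_down_end, "tes")
    den_win = strand_window(gene, -params.pro_up_len, 0, "tes")
    if not (
        window_in_bounds(num_win, track.chrom_sizes)
        and window_in_bounds(den_win, track.chrom_sizes)
    ):
        return ReadThroughResult(
            gene.gene_id, "proseq", np.nan, np.nan, np.nan, False,
            "window_out_of_bounds", gene.gene_class,
        )
    num = track.interval_sum(num_win.chrom, num_win.start, num_win.end, gene.strand)
    den = track.interval_sum(den_win.chrom, den_win.start, den_win.end, gene.strand)
    if den <= 0:
        return ReadThroughResult(
            gene.gene_id, "proseq", num, den, np.nan, False,
            "zero_denominator", gene.gene_class,
        )
    return ReadThroughResult(
        gene.gene_id, "proseq", num, den, num / den, True, "none", gene.gene_class
    )


def polii_readthrough_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    params: ReadThroughParams = ReadThroughParams(),
    strand: str = ".",
) -> ReadThroughResult:
    """Polymerase-occupancy read-through ratio for one gene.

    Numerator: signal over [TES, TES+1000); denominator: signal over
    [TSS, TES+1000). Occupancy ChIP signal is not strand-resolved, so the
    query defaults to both strands (``strand="."``).
    """
    num_win = strand_window(gene, 0, params.pol_down_len, "tes")
    den_win = strand_window(gene, -gene.length, params.pol_down_len, "tes")
    if not window_in_bounds(den_win, track.chrom_sizes):
        return ReadThroughResult(
            gene.gene_id, "polii", np.nan, np.nan, np.nan, False,
            "window_out_of_bounds", gene.gene_class,
        )
    num = track.interval_sum(num_win.chrom, num_win.start, num_win.end, strand)
    den = track.interval_sum(den_win.chrom, den_win.start, den_win.end, strand)
    if den <= 0:
        return ReadThroughResult(
            gene.gene_id, "polii", num, den, np.nan, False,
            "zero_denominator", gene.gene_class,
        )
    return ReadThroughResult(
        gene.gene_id, "polii", num, den, num / den, True, "none", gene.gene_class
    )


def readthrough_table(
    track: CoverageTrack,
    genes: Iterable[GeneModel],
    statistic: str = "proseq",
    params: ReadThroughParams = ReadThroughParams(),
) -> list[ReadThroughResult]:
    if statistic == "proseq":
        return [proseq_readthrough_ratio(track, g, params) for g in genes]
    if statistic == "polii":
        return [polii_readthrough_ratio(track, g, params) for g in genes]
    raise ValueError(f"unknown statistic {statistic!r}")


def _box_stats(values: np.ndarray) -> BoxStats:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo_fence) & (values <= hi_fence)]
    return BoxStats(
        n=values.size,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
    )


def compare_groups(
    results_a: Sequence[ReadThroughResult],
    results_b: Sequence[ReadThroughResult],
    gene_class: str,
    log_transform: bool = False,
    log_epsilon: float = 1e-3,
) -> GroupComparison:
    """Box-plot summaries and a two-sided pooled-variance Student t test.

    Invalid results (zero denominator, out-of-bounds window) are excluded
    from the statistics and counted per condition. With ``log_transform``
    the test runs on log2(ratio + log_epsilon).
    """
    def extract(results: Sequence[ReadThroughResult]) -> tuple[np.ndarray, int]:
        keep = [r for r in results if r.gene_class == gene_class]
        vals = np.array([r.ratio for r in keep if r.valid], dtype=float)
        return vals, len(keep) - vals.size

    vals_a, excl_a = extract(results_a)
    vals_b, excl_b = extract(results_b)
    if vals_a.size < 2 or vals_b.size < 2:
        raise ValueError(
            f"class {gene_class!r}: need >= 2 valid genes per condition "
            f"(got {vals_a.size} and {vals_b.size})"
        )
    test_a = np.log2(vals_a + log_epsilon) if log_transform else vals_a
    test_b = np.log2(vals_b + log_epsilon) if log_transform else vals_b
    t, p = stats.ttest_ind(test_a, test_b, equal_var=True)
    if np.isnan(t) and test_a.mean() == test_b.mean():
        # zero pooled variance with equal means: no evidence of a difference
        t, p = 0.0, 1.0
    return GroupComparison(
        gene_class=gene_class,
        condition_a=_box_stats(vals_a),
        condition_b=_box_stats(vals_b),
        t_statistic=float(t),
        p_value=float(p),
        n_excluded_a=excl_a,
        n_excluded_b=excl_b,
    )


def spike_in_scale(
    track: CoverageTrack, sample_spike_signal: float, reference_spike_signal: float
) -> CoverageTrack:
    """Scale a track by reference/sample spike-in totals (both must be > 0).

    Because both read-through ratios divide sums over the same track, this
    scaling can never change a ratio; it matters only for absolute signal
    comparisons between samples.
    """
    if sample_spike_signal <= 0 or reference_spike_signal <= 0:
        raise ValueError("spike-in totals must be positive")
    return track.scaled(reference_spike_signal / sample_spike_signal)
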