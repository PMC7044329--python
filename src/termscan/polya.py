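"""Aberrant-polyadenylation calling from paired library types.

Transcripts that normally end without a poly(A) tail (replication-dependent
histone mRNAs, snRNAs) appear in polyA-selected RNA-seq libraries only when
3'-end processing fails and transcription runs on to a downstream
polyadenylation signal. A transcript is therefore called *aberrantly
polyadenylated* when it is significantly up in the polyA-selected
differential comparison but not up in the ribo-depleted comparison, which
measures total transcript levels regardless of tail status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .setops import venn_partition

LIBRARY_TYPES = ("polyA_selected", "ribo_depleted")
CALLS = ("aberrant_polyA", "concordant_up", "not_called")


@dataclass(frozen=True)
class CallThresholds:
    """Cutoffs for the dual-library call.

    ``up_log2fc_min`` and ``fdr_max`` define "up" in the polyA-selected
    comparison; ``ribo_not_up_log2fc_max`` is the largest ribo-depleted
    log2 fold change still counted as "unchanged or reduced" (no
    significance requirement on a null effect).
    """

    up_log2fc_min: float = 1.5
    fdr_max: float = 0.05
    ribo_not_up_log2fc_max: float = 0.0

    def __post_init__(self) -> None:
        if self.up_log2fc_min <= 0:
            raise ValueError("up_log2fc_min must be positive")
        if not 0 <= self.fdr_max <= 1:
            raise ValueError("fdr_max must be in [0, 1]")


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _effective_library_sizes(
    mat: np.ndarray, ref_idx: np.ndarray, alt_idx: np.ndarray
) -> np.ndarray:
    """Composition-robust effective library sizes (two-pass median-of-ratios).

    Pass 1 takes, per sample, the median over transcripts detected in every
    sample of the count divided by the per-transcript geometric mean. Rows
    whose provisional between-group fold change exceeds 2-fold are then
    excluded and the medians recomputed: differentially expressed rows sit
    on opposite sides of the per-row reference in the two groups, so even a
    median (or trimmed mean) over all rows is pulled off-center when a
    minority of transcripts shifts strongly in one direction. Factors are
    rescaled to the mean raw library size so CPM values stay on their usual
    scale. Falls back to raw totals when no transcript is detected
    everywhere.
    """
    libsize = mat.sum(axis=0)
    detected = (mat > 0).all(axis=1)
    if not detected.any():
        return libsize

    def median_ratio(rows: np.ndarray) -> np.ndarray:
        logs = np.log(mat[rows])
        ratios = np.exp(logs - logs.mean(axis=1, keepdims=True))
        return np.median(ratios, axis=0)

    provisional = median_ratio(detected)
    norm = mat / provisional
    m = np.log2(norm[:, alt_idx].mean(axis=1) + 0.5) - np.log2(
        norm[:, ref_idx].mean(axis=1) + 0.5
    )
    stable = detected & (np.abs(m) < 1.0)
    factors = median_ratio(stable) if stable.any() else provisional
    return factors * libsize.mean() / factors.mean()


def simple_differential(
    counts: pd.DataFrame,
    group_labels: Sequence[str],
    pseudocount: float = 0.5,
    norm: str = "median_ratio",
) -> pd.DataFrame:
    """Plain two-group differential test on a counts table.

    ``counts`` has transcripts as rows and samples as columns;
    ``group_labels`` gives one of two labels per column (first label seen =
    reference group). Per transcript: counts are converted to CPM with a
    pseudocount, log2 fold change is the difference of group means of
    per-sample log2 CPM, the p value is a two-sample pooled-variance t test
    on log2 CPM, and FDR is Benjamini–Hochberg across transcripts.
    All-zero rows are reported with log2_fc 0 and fdr 1.

    ``norm`` selects the library-size estimate behind the CPM: the default
    ``"median_ratio"`` is robust to a minority of strongly changed
    transcripts; ``"total"`` uses raw column totals. This is deliberately
    minimal plumbing for simulated data, not a replacement for a
    negative-binomial differential framework.
    """
    if counts.shape[1] != len(group_labels):
        raise ValueError("one group label required per counts column")
    if norm not in ("median_ratio", "total"):
        raise ValueError(f"norm must be 'median_ratio' or 'total', got {norm!r}")
    labels = pd.Series(group_labels, index=counts.columns)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    ref_cols = labels[labels == groups[0]].index
    alt_cols = labels[labels == groups[1]].index
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("each group needs >= 2 replicates")

    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    ref_idx = counts.columns.get_indexer(ref_cols)
    alt_idx = counts.columns.get_indexer(alt_cols)
    if norm == "total":
        libsize = mat.sum(axis=0)
    else:
        libsize = _effective_library_sizes(mat, ref_idx, alt_idx)
    log_cpm = np.log2((mat + pseudocount) / libsize * 1e6)
    ref = log_cpm[:, ref_idx]
    alt = log_cpm[:, alt_idx]
    log2_fc = alt.mean(axis=1) - ref.mean(axis=1)
    t, p = stats.ttest_ind(alt, ref, axis=1, equal_var=True)

    all_zero = mat.sum(axis=1) == 0
    log2_fc[all_zero] = 0.0
    p = np.where(np.isnan(p) | all_zero, 1.0, p)
    fdr = bh_fdr(p)
    fdr[all_zero] = 1.0
    return pd.DataFrame(
        {
            "transcript_id": counts.index,
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
        }
    ).set_index("transcript_id")


def call_aberrant_polyadenylation(
    polya: pd.DataFrame,
    ribo: pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
) -> pd.DataFrame:
    """Classify each transcript from its two differential results.

    ``polya`` and ``ribo`` are differential tables indexed by transcript id
    with columns log2_fc and fdr. Transcripts present in only one table are
    excluded (column ``excluded`` on the returned frame's attrs records how
    many). Every transcript with both records receives exactly one call.
    """
    common = polya.index.intersection(ribo.index)
    excluded = len(polya.index.union(ribo.index)) - len(common)
    pa = polya.loc[common]
    rb = ribo.loc[common]
    up_polya = (pa["log2_fc"] >= thresholds.up_log2fc_min) & (
        pa["fdr"] <= thresholds.fdr_max
    )
    up_ribo = (rb["log2_fc"] >= thresholds.up_log2fc_min) & (
        rb["fdr"] <= thresholds.fdr_max
    )
    ribo_not_up = rb["log2_fc"] <= thresholds.ribo_not_up_log2fc_max
    call = np.where(
        up_polya & ribo_not_up,
        "aberrant_polyA",
        np.where(up_polya & up_ribo, "concordant_up", "not_called"),
    )
    out = pd.DataFrame(
        {
            "call": call,
            "polya_log2_fc": pa["log2_fc"],
            "ribo_log2_fc": rb["log2_fc"],
            "polya_fdr": pa["fdr"],
        },
        index=common,
    )
    out.attrs["n_excluded"] = excluded
    return out


def knockdown_set_logic(
    up_sets: Mapping[str, Set[str]],
    include: Sequence[str],
    exclude: Sequence[str] = (),
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Transcripts up in every ``include`` condition and no ``exclude`` one.

    Returns the selected set together with the full exclusive Venn
    partition counts over all conditions (counts sum to the union size).
    """
    for name in list(include) + list(exclude):
        if name not in up_sets:
            raise KeyError(f"unknown condition {name!r}")
    if not include:
        raise ValueError("need at least one include condition")
    selected = set.intersection(*(set(up_sets[n]) for n in include))
    for name in exclude:
        selected -= set(up_sets[name])
    return selected, venn_partition(up_sets)
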