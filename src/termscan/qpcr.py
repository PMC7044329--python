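"""qPCR-derived statistics: unprocessed-transcript fraction and percent input.

The unprocessed fraction of a non-polyadenylated transcript is estimated by
two amplicons: UT spans the 3'-end processing site (amplifies only
read-through transcripts) and CT lies in the coding region (amplifies all
transcripts). Assuming doubling per cycle, the per-replicate ratio is
2^−ΔCt with ΔCt = Ct_UT − Ct_CT. ChIP enrichment is expressed as percent of
input, 100 × 2^(Ct_input − d − Ct_IP) with an optional log2 dilution
adjustment d for diluted input material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

AMPLICONS = ("UT", "CT", "chip_ip", "chip_input")

#: expected columns of a tidy Ct table
CT_COLUMNS = ("sample", "condition", "target", "amplicon", "replicate", "ct")


@dataclass(frozen=True)
class RelativeLevel:
    condition: str
    target: str
    ratios: tuple[float, ...]  # one per paired replicate
    mean: float
    sd: float  # n-1 denominator
    n: int


def _paired_ct(
    ct_table: pd.DataFrame,
    condition: str,
    target: str,
    amplicon_a: str,
    amplicon_b: str,
) -> tuple[np.ndarray, np.ndarray]:
    sub = ct_table[(ct_table["condition"] == condition) & (ct_table["target"] == target)]
    a = sub[sub["amplicon"] == amplicon_a].set_index("replicate")["ct"]
    b = sub[sub["amplicon"] == amplicon_b].set_index("replicate")["ct"]
    if a.empty or b.empty:
        raise ValueError(
            f"missing amplicon for ({condition}, {target}): "
            f"need both {amplicon_a} and {amplicon_b}"
        )
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError(
            f"unpaired replicates for ({condition}, {target}): "
            f"{amplicon_a} has {sorted(a.index)}, {amplicon_b} has {sorted(b.index)}"
        )
    reps = a.index.sort_values()
    return a.loc[reps].to_numpy(float), b.loc[reps].to_numpy(float)


def _summarize(condition: str, target: str, ratios: np.ndarray) -> RelativeLevel:
    return RelativeLevel(
        condition=condition,
        target=target,
        ratios=tuple(float(r) for r in ratios),
        mean=float(ratios.mean()),
        sd=float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
        n=int(ratios.size),
    )


def unprocessed_fraction(
    ct_table: pd.DataFrame, condition: str, target: str
) -> RelativeLevel:
    """Per-replicate 2^−(Ct_UT − Ct_CT), paired by replicate index."""
    ct_ut, ct_ct = _paired_ct(ct_table, condition, target, "UT", "CT")
    ratios = np.exp2(-(ct_ut - ct_ct))
    return _summarize(condition, target, ratios)


def chip_percent_input(
    ct_table: pd.DataFrame,
    condition: str,
    target: str,
    input_dilution_log2: float = 0.0,
) -> RelativeLevel:
    """Per-replicate 100 × 2^((Ct_input − input_dilution_log2) − Ct_IP).

    ``input_dilution_log2`` is log2 of the input dilution factor (e.g.
    log2(10) for a 1:10 diluted input); the default 0 assumes undiluted
    input.
    """
    ct_ip, ct_input = _paired_ct(ct_table, condition, target, "chip_ip", "chip_input")
    percents = 100.0 * np.exp2((ct_input - input_dilution_log2) - ct_ip)
    return _summarize(condition, target, percents)


def condition_ttest(levels_a: RelativeLevel, levels_b: RelativeLevel) -> tuple[float, float]:
    """Two-sided pooled-variance Student t test on per-replicate ratios."""
    if levels_a.n < 2 or levels_b.n < 2:
        raise ValueError("need >= 2 replicates per condition")
    t, p = stats.ttest_ind(levels_a.ratios, levels_b.ratios, equal_var=True)
    if np.isnan(t) and levels_a.mean == levels_b.mean:
        # zero pooled variance with equal means: no evidence of a difference
        return 0.0, 1.0
    return float(t), float(p)
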