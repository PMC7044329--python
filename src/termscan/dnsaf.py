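"""Distributed normalized spectral abundance factors (dNSAF).

Spectral counting estimates protein abundance from the number of MS/MS
spectra matched to a protein's peptides. Peptides shared between proteins
are apportioned among the sharers in proportion to each sharer's *unique*
spectral counts (uSpC): a shared peptide with count c and sharer set M
contributes c × uSpC_i / Σ_{m∈M} uSpC_m to protein i. The distributed
spectral count is length-normalized,

    dSAF_i = (uSpC_i + distributed_shared_i) / Length_i,

and normalized across proteins to sum to one:

    dNSAF_i = dSAF_i / Σ_k dSAF_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class PeptideEvidence:
    peptide_id: str
    protein_ids: frozenset[str]
    spectral_count: int

    def __post_init__(self) -> None:
        if not self.protein_ids:
            raise ValueError(f"peptide {self.peptide_id}: empty protein mapping")
        if self.spectral_count < 0:
            raise ValueError(f"peptide {self.peptide_id}: negative count")

    @property
    def shared(self) -> bool:
        return len(self.protein_ids) > 1


@dataclass
class SpectralCountData:
    """Bipartite peptide↔protein evidence plus protein lengths (residues)."""

    protein_lengths: dict[str, int]
    peptides: list[PeptideEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pid, length in self.protein_lengths.items():
            if length <= 0:
                raise ValueError(f"protein {pid}: non-positive length {length}")
        for pep in self.peptides:
            missing = pep.protein_ids - self.protein_lengths.keys()
            if missing:
                raise ValueError(
                    f"peptide {pep.peptide_id} maps to unknown proteins {sorted(missing)}"
                )

    @property
    def total_spectral_counts(self) -> int:
        return sum(p.spectral_count for p in self.peptides)


def distribute_shared_counts(
    data: SpectralCountData, degenerate: str = "split"
) -> pd.DataFrame:
    """Unique counts plus the distributed share of shared-peptide counts.

    Returns a frame indexed by protein id with columns ``uSpC``,
    ``distributed_shared`` and ``undistributed_flag``. Shared peptides whose
    sharers all have zero unique counts are degenerate (the apportionment
    ratio is 0/0); with ``degenerate="split"`` their counts are divided
    equally among the sharers and those proteins flagged, with
    ``degenerate="drop"`` the counts are discarded (flags still set).
    Apart from dropped degenerate counts, total distributed counts equal
    total observed counts.
    """
    if degenerate not in ("split", "drop"):
        raise ValueError(f"degenerate must be 'split' or 'drop', got {degenerate!r}")
    uspc = {pid: 0.0 for pid in data.protein_lengths}
    for pep in data.peptides:
        if not pep.shared:
            (pid,) = pep.protein_ids
            uspc[pid] += pep.spectral_count
    shared = {pid: 0.0 for pid in data.protein_lengths}
    flagged = {pid: False for pid in data.protein_lengths}
    for pep in data.peptides:
        if not pep.shared:
            continue
        sharers = sorted(pep.protein_ids)
        denom = sum(uspc[m] for m in sharers)
        if denom > 0:
            for m in sharers:
                shared[m] += pep.spectral_count * uspc[m] / denom
        else:
            for m in sharers:
                flagged[m] = True
                if degenerate == "split":
                    shared[m] += pep.spectral_count / len(sharers)
    return pd.DataFrame(
        {
            "uSpC": pd.Series(uspc),
            "distributed_shared": pd.Series(shared),
            "undistributed_flag": pd.Series(flagged),
        }
    )


def compute_dnsaf(distributed: pd.DataFrame, lengths: dict[str, int]) -> pd.DataFrame:
    """Length-normalize distributed counts and normalize across proteins.

    ``distributed`` is the output of :func:`distribute_shared_counts`.
    Returns columns uSpC, distributed_shared, dSAF, dNSAF and
    undistributed_flag; dNSAF sums to 1 whenever any dSAF is positive, and
    an all-zero dataset yields an empty frame.
    """
    missing = [
        pid
        for pid in distributed.index
        if pid not in lengths
        and (distributed.loc[pid, "uSpC"] + distributed.loc[pid, "distributed_shared"]) > 0
    ]
    if missing:
        raise ValueError(f"missing protein lengths for {sorted(missing)}")
    out = distributed.copy()
    length = pd.Series({pid: lengths.get(pid, 1) for pid in out.index}, dtype=float)
    out["dSAF"] = (out["uSpC"] + out["distributed_shared"]) / length
    total = out["dSAF"].sum()
    if total == 0:
        return out.iloc[0:0]
    out["dNSAF"] = out["dSAF"] / total
    return out


def dnsaf_table(data: SpectralCountData, degenerate: str = "split") -> pd.DataFrame:
    """Convenience wrapper: distribute shared counts then compute dNSAF."""
    distributed = distribute_shared_counts(data, degenerate=degenerate)
    return compute_dnsaf(distributed, data.protein_lengths)


def bait_vs_control(
    results_bait: pd.DataFrame,
    results_control: pd.DataFrame,
    fold_min: float = 3.0,
) -> pd.DataFrame:
    """Label proteins bait-specific or background by dNSAF enrichment.

    A protein is ``bait_specific`` when it is absent from (or zero in) the
    negative control, or when its bait/control dNSAF ratio is at least
    ``fold_min``; otherwise ``background``. Proteins detected only in the
    control are labelled background.
    """
    bait = results_bait["dNSAF"] if "dNSAF" in results_bait else pd.Series(dtype=float)
    ctrl = results_control["dNSAF"] if "dNSAF" in results_control else pd.Series(dtype=float)
    universe = bait.index.union(ctrl.index)
    b = bait.reindex(universe, fill_value=0.0)
    c = ctrl.reindex(universe, fill_value=0.0)
    specific = (b > 0) & ((c == 0) | (b / c.where(c > 0) >= fold_min))
    return pd.DataFrame(
        {
            "bait_dnsaf": b,
            "control_dnsaf": c,
            "label": specific.map({True: "bait_specific", False: "background"}),
        }
    )


# ---------------------------------------------------------------------------
# tabular I/O (tab-separated exchange formats)
# ---------------------------------------------------------------------------

def read_spectral_counts(protein_path, peptide_path) -> SpectralCountData:
    """Protein table (protein_id, length) and peptide table
    (peptide_id, semicolon-joined protein ids, spectral_count)."""
    proteins = pd.read_csv(protein_path, sep="\t")
    peptides = pd.read_csv(peptide_path, sep="\t")
    lengths = dict(zip(proteins["protein_id"], proteins["length"].astype(int)))
    evidence = [
        PeptideEvidence(
            str(row.peptide_id),
            frozenset(str(row.protein_ids).split(";")),
            int(row.spectral_count),
        )
        for row in peptides.itertuples()
    ]
    return SpectralCountData(lengths, evidence)


def write_spectral_counts(data: SpectralCountData, protein_path, peptide_path) -> None:
    pd.DataFrame(
        {"protein_id": list(data.protein_lengths), "length": list(data.protein_lengths.values())}
    ).to_csv(protein_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "peptide_id": [p.peptide_id for p in data.peptides],
            "protein_ids": [";".join(sorted(p.protein_ids)) for p in data.peptides],
            "spectral_count": [p.spectral_count for p in data.peptides],
        }
    ).to_csv(peptide_path, sep="\t", index=False)
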