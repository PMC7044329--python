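"""Exclusive Venn partitioning shared by the knockdown and co-occupancy analyses."""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Mapping, Set


def venn_partition(
    sets: Mapping[str, Set[Hashable]]
) -> dict[frozenset[str], int]:
    """Exclusive region sizes of the Venn diagram of named sets.

    Returns a count for every non-empty subset of set names; the count for
    key ``{A, B}`` is the number of elements in exactly A and B and no other
    set. Counts over all 2^k − 1 regions sum to the size of the union.
    """
    names = list(sets)
    if not names:
        return {}
    counts: dict[frozenset[str], int] = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    universe = set().union(*sets.values())
    for element in universe:
        membership = frozenset(n for n in names if element in sets[n])
        counts[membership] += 1
    return counts
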