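"""Exhaustive Venn-region bookkeeping shared by catalog, DE and pathway layers.

A "region" of an n-set Venn diagram is identified by the subset of labels a
feature belongs to. ``venn_regions`` enumerates all 2**n − 1 non-empty
membership patterns explicitly, so downstream counts are exact set algebra
rather than diagram-specific arithmetic.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Iterable, Mapping


def venn_regions(sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, set]:
    """Partition the union of ``sets`` into exclusive Venn regions.

    Parameters
    ----------
    sets
        Mapping from label to a collection of members.

    Returns
    -------
    dict
        Maps each non-empty ``frozenset`` of labels to the set of elements
        belonging to exactly those labels. Regions are present even when
        empty, so counts always cover all 2**n − 1 patterns.
    """
    labels = sorted(sets)
    as_sets = {lab: set(sets[lab]) for lab in labels}
    regions: dict[frozenset, set] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(as_sets[lab] for lab in combo))
            outside = set.union(set(), *(as_sets[lab] for lab in labels if lab not in combo))
            regions[frozenset(combo)] = inside - outside
    return regions


def venn_counts(sets: Mapping[str, Iterable[Hashable]]) -> dict[frozenset, int]:
    """Exclusive region sizes; values sum to ``len(union of all sets)``."""
    return {k: len(v) for k, v in venn_regions(sets).items()}


def shared_elements(sets: Mapping[str, Iterable[Hashable]]) -> set:
    """Elements present in every set (the centre of the diagram)."""
    as_sets = [set(v) for v in sets.values()]
    if not as_sets:
        return set()
    return set.intersection(*as_sets)


def unique_elements(sets: Mapping[str, Iterable[Hashable]], label: str) -> set:
    """Elements of ``sets[label]`` absent from every other set."""
    others = set().union(*(set(v) for k, v in sets.items() if k != label))
    return set(sets[label]) - others
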