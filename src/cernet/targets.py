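"""Canonical miRNA seed-match site detection on circRNAs and mRNA 3'UTRs.

Site classes follow the canonical seed taxonomy used by target-prediction
tools: with the miRNA written 5'→3', the *seed* is nucleotides 2–8.

========  =============================================================
8mer      exact Watson–Crick match to positions 2–8, followed by an A
          opposite miRNA position 1
7mer-m8   exact match to positions 2–8 (no A requirement)
7mer-A1   exact match to positions 2–7, followed by an A
========  =============================================================

Matches are located on the *target* strand, so a site is an occurrence of
the reverse complement of the seed. No pairing energy or context scoring
is applied; the classes themselves carry the specificity ranking
8mer > 7mer-m8 > 7mer-A1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_IUPAC_OK = set("ACGTUN")

SITE_RANK = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1}


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T) spelling."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - _IUPAC_OK
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return normalize_nt(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site in a target sequence.

    ``start_offset`` is 0-based in the target as provided; for circular
    targets sites spanning the junction wrap, and the offset refers to the
    position where the site starts in the linear spelling.
    """

    mir_id: str
    target_id: str
    target_kind: str  # "circRNA" | "3'UTR"
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"
    start_offset: int
    matched_sequence: str

    def __post_init__(self):
        if self.site_type not in SITE_RANK:
            raise ValueError(f"unknown site type {self.site_type!r}")


def seed_sites(
    mir_sequence: str,
    target_sequence: str,
    *,
    mir_id: str = "miR",
    target_id: str = "target",
    target_kind: str = "3'UTR",
    circular: bool = False,
) -> list[SeedSite]:
    """Enumerate all canonical seed sites of one miRNA in one target.

    Overlapping occurrences are all reported, in deterministic
    left-to-right order. A 7mer-A1 occurrence that is the tail of an 8mer
    site is not double-reported. With ``circular=True`` the scan window
    additionally wraps across the junction (last 7 nt joined to the first
    7 nt), honoring the closed-loop topology of circRNAs.
    """
    mir = normalize_nt(mir_sequence)
    if len(mir) < 8:
        raise ValueError(f"miRNA {mir_id!r} shorter than 8 nt")
    target = normalize_nt(target_sequence)

    seed7_rc = reverse_complement(mir[1:8])  # positions 2-8
    seed6_rc = reverse_complement(mir[1:7])  # positions 2-7
    # seed7_rc == complement(position 8) + seed6_rc
    m8_comp = seed7_rc[0]

    n = len(target)
    scan = target
    if circular and n >= 8:
        scan = target + target[:7]  # windows starting in the last 7 nt wrap

    sites: list[SeedSite] = []
    eight_mer_offsets: set[int] = set()

    # 7 nt seed (positions 2-8): 8mer when followed by A, else 7mer-m8
    start = 0
    while (i := scan.find(seed7_rc, start)) != -1:
        start = i + 1
        if i >= n:
            break  # duplicate of an unwrapped occurrence
        if i + 7 < len(scan) and scan[i + 7] == "A":
            sites.append(SeedSite(mir_id, target_id, target_kind, "8mer", i, scan[i : i + 8]))
            eight_mer_offsets.add(i)
        else:
            sites.append(SeedSite(mir_id, target_id, target_kind, "7mer-m8", i, scan[i : i + 7]))

    # 6 nt seed (positions 2-7) + A: 7mer-A1, unless subsumed by an 8mer
    start = 0
    while (i := scan.find(seed6_rc, start)) != -1:
        start = i + 1
        if i >= n:
            break
        if i + 6 >= len(scan) or scan[i + 6] != "A":
            continue
        # the base preceding the 6mer may complete the 2-8 match, making
        # this the tail of an 8mer already reported (possibly wrapped)
        prev = i - 1 if i >= 1 else (n - 1 if circular else None)
        if prev is not None and prev in eight_mer_offsets:
            continue
        sites.append(SeedSite(mir_id, target_id, target_kind, "7mer-A1", i, scan[i : i + 7]))

    sites.sort(key=lambda s: (s.start_offset, -SITE_RANK[s.site_type]))
    return sites


def scan_all(
    mir_seqs: dict[str, str],
    target_seqs: dict[str, str],
    *,
    target_kind: str = "3'UTR",
    circular: bool = False,
) -> pd.DataFrame:
    """Seed sites for every (miRNA, target) pair, as a tidy table."""
    rows = []
    for mir_id in sorted(mir_seqs):
        for tid in sorted(target_seqs):
            for s in seed_sites(
                mir_seqs[mir_id],
                target_seqs[tid],
                mir_id=mir_id,
                target_id=tid,
                target_kind=target_kind,
                circular=circular,
            ):
                rows.append(
                    (s.mir_id, s.target_id, s.target_kind, s.site_type, s.start_offset, s.matched_sequence)
                )
    return pd.DataFrame(
        rows,
        columns=["mir_id", "target_id", "target_kind", "site_type", "start_offset", "matched_sequence"],
    )


def interaction_pairs(
    sites: pd.DataFrame,
    de_mirs: set[str] | None = None,
    de_targets: set[str] | None = None,
) -> pd.DataFrame:
    """Collapse a site table to deduplicated (miRNA, target) pairs.

    A pair is retained only if both endpoints pass their respective DE
    filters (``None`` disables a filter). Output carries the number of
    sites and the best site class per pair.
    """
    cols = ["mir_id", "target_id", "target_kind", "site_count", "best_site_type"]
    if sites.empty:
        return pd.DataFrame(columns=cols)
    df = sites
    if de_mirs is not None:
        df = df[df["mir_id"].isin(de_mirs)]
    if de_targets is not None:
        df = df[df["target_id"].isin(de_targets)]
    if df.empty:
        return pd.DataFrame(columns=cols)

    def _best(types: pd.Series) -> str:
        return max(types, key=lambda t: SITE_RANK[t])

    out = (
        df.groupby(["mir_id", "target_id", "target_kind"], sort=True)
        .agg(site_count=("site_type", "size"), best_site_type=("site_type", _best))
        .reset_index()
    )
    return out[cols]
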