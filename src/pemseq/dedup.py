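"""UMI deduplication: collapse PCR duplicates to molecules.

Anchored junction libraries count molecules, not reads.  Two reads are
duplicates of the same original molecule when they share a junction key
(outcome class, prey reference, prey position rounded to a +/-2 bp
bucket, strand) and their UMIs are identical or within Hamming distance
1 (sequencing error on the UMI).  Collapsing is greedy, most-frequent-
UMI first, the scheme used by directional UMI collapsers.  Reads with
distinct junction keys never merge, whatever their UMIs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Hashable, Sequence, TypeVar

T = TypeVar("T")

#: positions within +/-2 bp share a bucket
_POS_BUCKET = 4


def junction_key(cls: str, ref: str, pos: int, strand: str) -> tuple:
    """Bucketed junction identity used for duplicate grouping."""
    bucket = int(round(pos / _POS_BUCKET)) if pos >= 0 else -1
    return (cls, ref, bucket, strand)


def _umi_close(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return False
    return True


def dedup_umis(calls: Sequence[tuple[str, Hashable]]) -> list[list[int]]:
    """Collapse (umi, junction key) records into molecules.

    Returns a list of molecules, each a list of indices into ``calls``
    (the first index in each group is the representative read).  Within a
    junction key, UMIs are merged greedily starting from the most frequent
    one; a UMI joins an existing molecule if it is within Hamming distance
    1 of that molecule's seed UMI.
    """
    by_key: dict[Hashable, list[int]] = defaultdict(list)
    for i, (umi, key) in enumerate(calls):
        by_key[key].append(i)

    molecules: list[list[int]] = []
    for key, idxs in by_key.items():
        counts = Counter(calls[i][0] for i in idxs)
        # most frequent first; ties by lexicographic UMI for determinism
        order = sorted(counts, key=lambda u: (-counts[u], u))
        seed_of: dict[str, str] = {}
        groups: dict[str, list[int]] = defaultdict(list)
        for umi in order:
            assigned = None
            for seed in groups:
                if _umi_close(umi, seed):
                    assigned = seed
                    break
            seed_of[umi] = assigned if assigned is not None else umi
            if assigned is None:
                groups[umi] = []
        for i in idxs:
            groups[seed_of[calls[i][0]]].append(i)
        for seed in groups:
            molecules.append(sorted(groups[seed]))
    molecules.sort(key=lambda g: g[0])
    return molecules
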