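"""FASTA/FASTQ input and UMI extraction.

The digital read layout is ``[UMI][6-nt spacer ACGCGT][payload]``.  The
spacer is matched with at most one mismatch; reads failing that, or too
short to contain a meaningful payload, are dropped and counted so run
reports can surface losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

from . import defaults as dflt
from ._seq import hamming

#: minimum payload (bait + some prey) required after trimming
_MIN_PAYLOAD = 30


@dataclass(frozen=True)
class ProcessedRead:
    """A read after UMI/spacer trimming."""

    read_id: str
    umi: str
    payload: str
    source_index: int = -1


@dataclass
class ExtractionStats:
    """Counters surfaced in the run report."""

    n_total: int = 0
    n_ok: int = 0
    n_too_short: int = 0
    n_bad_spacer: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_total": self.n_total,
            "reads_passed": self.n_ok,
            "reads_too_short": self.n_too_short,
            "reads_bad_spacer": self.n_bad_spacer,
        }


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file as name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def iter_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ file."""
    for rec in SeqIO.parse(path, "fastq"):
        yield rec.id, str(rec.seq).upper()


def extract_umi(
    read_id: str,
    seq: str,
    umi_length: int = dflt.UMI_LEN,
    spacer: str = dflt.READ_SPACER,
    stats: ExtractionStats | None = None,
    source_index: int = -1,
) -> ProcessedRead | None:
    """Split one read into UMI and payload, or drop it.

    Returns ``None`` for reads shorter than ``umi_length + 6 + 30`` or with
    more than one mismatch in the fixed spacer; the reason is tallied in
    ``stats`` when given.
    """
    if stats is not None:
        stats.n_total += 1
    if len(seq) < umi_length + len(spacer) + _MIN_PAYLOAD:
        if stats is not None:
            stats.n_too_short += 1
        return None
    found = seq[umi_length : umi_length + len(spacer)]
    if hamming(found, spacer) > 1:
        if stats is not None:
            stats.n_bad_spacer += 1
        return None
    if stats is not None:
        stats.n_ok += 1
    return ProcessedRead(
        read_id=read_id,
        umi=seq[:umi_length],
        payload=seq[umi_length + len(spacer) :],
        source_index=source_index,
    )


def extract_all(
    reads: Iterable[tuple[str, str]],
    umi_length: int = dflt.UMI_LEN,
    spacer: str = dflt.READ_SPACER,
) -> tuple[list[ProcessedRead], ExtractionStats]:
    """Run :func:`extract_umi` over a read stream."""
    stats = ExtractionStats()
    out = []
    for i, (rid, seq) in enumerate(reads):
        pr = extract_umi(rid, seq, umi_length, spacer, stats, i)
        if pr is not None:
            out.append(pr)
    return out, stats
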