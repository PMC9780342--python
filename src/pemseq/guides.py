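"""Guide/locus model: protospacer, PAM, cut-site convention, bait anchor.

SpCas9 makes a blunt double-strand cut 3 bp 5' of the NGG PAM.  With a
plus-strand protospacer starting at ``start`` (0-based), the cut falls
between ``start+16`` and ``start+17``; we record ``cut_site = start + 17``,
the coordinate of the first base 3' of the break.  On the minus strand the
convention mirrors: for a 23-mer site occupying ``[s, s+23)`` on forward
coordinates whose reverse complement matches spacer+PAM, the PAM occupies
``[s, s+3)`` and ``cut_site = s + 6``.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import revcomp

#: half-width of the on-target ("bait") window used to separate intra-locus
#: outcomes (indels, large deletions) from translocations
BAIT_WINDOW_HALF = 20_000

#: distance from the nested primer anchor to the protospacer start
BAIT_ANCHOR_OFFSET = 60

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN


def cut_site_for(start: int, strand: str) -> int:
    """Cut coordinate for a 23-mer site at ``start`` on ``strand``."""
    if strand == "+":
        return start + 17
    if strand == "-":
        return start + 6
    raise ValueError(f"bad strand {strand!r}")


@dataclass(frozen=True)
class GuideSpec:
    """A CRISPR guide anchored on a reference, with bait-primer geometry.

    Parameters
    ----------
    protospacer :
        20-nt spacer sequence, reference plus-strand orientation if
        ``strand == '+'``, else its reverse complement occurs on the
        forward reference.
    pam :
        3-nt PAM (NGG for SpCas9) immediately 3' of the spacer.
    chrom, start, strand :
        Location of the protospacer on the reference (0-based start of
        the 23-mer site for '+' guides; for '-' guides ``start`` is the
        forward-coordinate start of the 23-mer, PAM first).
    """

    protospacer: str
    pam: str
    chrom: str
    start: int
    strand: str = "+"
    anchor_offset: int = BAIT_ANCHOR_OFFSET
    window_half: int = BAIT_WINDOW_HALF

    def __post_init__(self) -> None:
        if len(self.protospacer) != SPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN:
            raise ValueError("PAM must be 3 nt")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def site_seq(self) -> str:
        """23-nt spacer+PAM in guide orientation."""
        return self.protospacer + self.pam

    @property
    def cut_site(self) -> int:
        return cut_site_for(self.start, self.strand)

    @property
    def anchor(self) -> int:
        """Nested-primer anchor coordinate (bait 5' end, forward coords)."""
        if self.strand == "+":
            return self.start - self.anchor_offset
        return self.start + SITE_LEN + self.anchor_offset

    @property
    def bait_window(self) -> tuple[int, int]:
        """±window_half interval around the cut site, half-open."""
        return (self.cut_site - self.window_half, self.cut_site + self.window_half)

    def in_bait_window(self, chrom: str, pos: int) -> bool:
        lo, hi = self.bait_window
        return chrom == self.chrom and lo <= pos < hi

    def site_on_forward(self) -> str:
        """Spacer+PAM as it appears on the forward reference strand."""
        return self.site_seq if self.strand == "+" else revcomp(self.site_seq)
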