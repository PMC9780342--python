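"""Off-target discovery from translocation hotspots, plus amplicon indel rates.

An off-target site is called when (i) deduplicated translocation
junctions cluster into a hotspot, (ii) the hotspot sequence contains a
23-mer within 8 mismatches of the guide's spacer+PAM (counted jointly
over the 23 nt), and (iii) the junction cluster sits at the presumable
SpCas9 cut site of that 23-mer (median junction within +/-3 bp).

A brute-force enumeration over every 23-mer on both strands is provided
as the oracle against which hotspot discovery is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import edlib
import numpy as np

from . import defaults as dflt
from ._seq import encode, revcomp
from .guides import SITE_LEN, GuideSpec, cut_site_for


@dataclass(frozen=True)
class OffTargetSite:
    """A discovered off-target: location, similarity, junction support."""

    chrom: str
    start: int
    strand: str
    n_mismatches: int
    cut_site: int
    support: int


# ---------------------------------------------------------------------------
# hotspot binning
# ---------------------------------------------------------------------------


def find_hotspots(
    junctions: list[tuple[str, int]],
    bin_size: int = dflt.HOTSPOT_BIN,
    min_support: int = dflt.HOTSPOT_MIN_SUPPORT,
) -> list[tuple[str, int, int, int]]:
    """Cluster translocation junctions into candidate windows.

    The genome is tiled in ``bin_size`` windows twice, the second tiling
    offset by half a bin (so clusters straddling a bin edge are not
    missed); bins holding >= ``min_support`` molecules become candidates
    and overlapping/adjacent candidate bins are merged.  Returns
    ``(chrom, lo, hi, support)`` sorted by position.
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in junctions:
        by_chrom.setdefault(chrom, []).append(pos)

    out: list[tuple[str, int, int, int]] = []
    half = bin_size // 2
    for chrom, positions in sorted(by_chrom.items()):
        arr = np.asarray(sorted(positions))
        candidate: list[tuple[int, int]] = []
        for offset in (0, half):
            bins = (arr + offset) // bin_size
            uniq, counts = np.unique(bins, return_counts=True)
            for b, c in zip(uniq, counts):
                if c >= min_support:
                    lo = int(b) * bin_size - offset
                    candidate.append((max(0, lo), lo + bin_size))
        if not candidate:
            continue
        candidate.sort()
        merged = [list(candidate[0])]
        for lo, hi in candidate[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            support = int(((arr >= lo) & (arr < hi)).sum())
            if support >= min_support:
                out.append((chrom, lo, hi, support))
    return out


# ---------------------------------------------------------------------------
# guide matching
# ---------------------------------------------------------------------------


def scan_guide_matches(
    chromosomes: dict[str, str], site_seq: str, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """Exhaustive vectorised scan for 23-mers within ``max_mm`` of the guide.

    Compares ``site_seq`` (spacer+PAM) against every placement on both
    strands of every chromosome; returns ``(chrom, start, strand,
    n_mismatches)`` sorted by (n_mismatches, chrom, pos, strand).
    """
    k = len(site_seq)
    fwd = encode(site_seq)
    rev = encode(revcomp(site_seq))
    out: list[tuple[str, int, str, int]] = []
    for chrom in sorted(chromosomes):
        arr = encode(chromosomes[chrom])
        if arr.size < k:
            continue
        sw = np.lib.stride_tricks.sliding_window_view(arr, k)
        mm_fwd = (sw != fwd[None, :]).sum(axis=1)
        mm_rev = (sw != rev[None, :]).sum(axis=1)
        for pos in np.flatnonzero(mm_fwd <= max_mm):
            out.append((chrom, int(pos), "+", int(mm_fwd[pos])))
        for pos in np.flatnonzero(mm_rev <= max_mm):
            out.append((chrom, int(pos), "-", int(mm_rev[pos])))
    out.sort(key=lambda t: (t[3], t[0], t[1], t[2]))
    return out


def match_guide(
    window_seq: str,
    guide: GuideSpec,
    max_mm: int = dflt.MAX_GUIDE_MM,
    require_pam: bool = False,
) -> tuple[int, str, int] | None:
    """Best guide placement inside a candidate window.

    Scans both strands of ``window_seq`` for the 23-mer minimising the
    joint spacer+PAM mismatch count; ties are broken by proximity to the
    window centre, then '+' strand first.  Returns ``(offset, strand,
    n_mismatches)`` with ``offset`` the forward-coordinate start of the
    23-mer within the window, or ``None`` when the minimum exceeds
    ``max_mm``.  With ``require_pam`` the NGG dinucleotide must also be
    intact.
    """
    if len(window_seq) < SITE_LEN:
        raise ValueError("window shorter than 23 nt")
    site = guide.site_seq
    center = (len(window_seq) - SITE_LEN) / 2.0
    best: tuple | None = None
    for strand in "+-":
        seq = window_seq if strand == "+" else revcomp(window_seq)
        n = len(seq)
        for off in range(n - SITE_LEN + 1):
            kmer = seq[off : off + SITE_LEN]
            mm = sum(a != b for a, b in zip(kmer, site))
            if mm > max_mm:
                continue
            if require_pam and kmer[21:23] != "GG":
                continue
            fwd_off = off if strand == "+" else n - SITE_LEN - off
            rank = (mm, abs(fwd_off - center), 0 if strand == "+" else 1)
            if best is None or rank < best[0]:
                best = (rank, (fwd_off, strand, mm))
    return None if best is None else best[1]


def enumerate_offtargets_bruteforce(
    chromosomes: dict[str, str],
    guide: GuideSpec,
    max_mm: int = dflt.MAX_GUIDE_MM,
) -> list[tuple[str, int, str, int]]:
    """All guide-similar sites genome-wide (the enumeration oracle).

    Every 23-mer placement on both strands is compared to spacer+PAM and
    kept when within ``max_mm`` joint mismatches; sorted by
    (n_mismatches, chrom, pos).
    """
    return scan_guide_matches(chromosomes, guide.site_seq, max_mm)


# ---------------------------------------------------------------------------
# cut-site confirmation and site discovery
# ---------------------------------------------------------------------------


def confirm_cut_site(
    site_cut: int,
    junction_positions: list[int],
    tol: int = dflt.CUT_SITE_TOL,
    mh_spans: list[int] | None = None,
) -> bool:
    """True when the median junction lies within ``tol`` bp of the cut site.

    ``mh_spans`` are signed microhomology spans per junction: the
    breakpoint is sequence-ambiguous between ``pos+span`` and ``pos``
    (span < 0) or ``pos`` and ``pos+span`` (span > 0), and is resolved to
    the admissible coordinate closest to the candidate cut site before
    taking the median -- at a guide-similar site the tract shared with
    the bait otherwise biases every '+'-strand junction downstream.
    """
    if not junction_positions:
        return False
    if mh_spans is None:
        eff = list(junction_positions)
    else:
        eff = []
        for pos, span in zip(junction_positions, mh_spans):
            lo, hi = (pos + span, pos) if span < 0 else (pos, pos + span)
            eff.append(min(max(site_cut, lo), hi))
    return abs(median(eff) - site_cut) <= tol


def discover_offtargets(
    chromosomes: dict[str, str],
    guide: GuideSpec,
    junctions: list[tuple],
    bin_size: int = dflt.HOTSPOT_BIN,
    min_support: int = dflt.HOTSPOT_MIN_SUPPORT,
    max_mm: int = dflt.MAX_GUIDE_MM,
    require_pam: bool = False,
    pad: int = 30,
) -> list[OffTargetSite]:
    """Full off-target caller: hotspots -> guide match -> cut-site check.

    ``junctions`` are deduplicated translocation junctions at the
    molecule level: ``(chrom, pos)`` or ``(chrom, pos, mh_span)`` with
    the signed microhomology span used by :func:`confirm_cut_site`.
    Each candidate window is padded by ``pad`` bp, the best guide
    placement located, and the site kept when its mismatch count passes
    ``max_mm`` and the junction cluster median falls at the inferred cut
    site.
    """
    positions = [(j[0], j[1]) for j in junctions]
    sites: list[OffTargetSite] = []
    for chrom, lo, hi, support in find_hotspots(positions, bin_size, min_support):
        seq = chromosomes[chrom]
        w_lo = max(0, lo - pad)
        w_hi = min(len(seq), hi + pad)
        window = seq[w_lo:w_hi]
        if len(window) < SITE_LEN:
            continue
        hit = match_guide(window, guide, max_mm=max_mm, require_pam=require_pam)
        if hit is None:
            continue
        off, strand, n_mm = hit
        start = w_lo + off
        cut = cut_site_for(start, strand)
        cluster = [j for j in junctions if j[0] == chrom and w_lo <= j[1] < w_hi]
        cluster_pos = [j[1] for j in cluster]
        cluster_mh = [j[2] if len(j) > 2 else 0 for j in cluster]
        if not confirm_cut_site(cut, cluster_pos, mh_spans=cluster_mh):
            continue
        sites.append(OffTargetSite(chrom, start, strand, n_mm, cut, support))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# amplicon indel quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmpliconResult:
    """Cut-site indel rate over an amplicon pool."""

    indel_pct: float
    n_reads: int
    n_aligned: int
    n_indel: int
    low_coverage: bool


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def amplicon_indel_rate(
    reads: list,
    reference: str,
    cut: int,
    window: int = 10,
    max_divergence: float = 0.10,
) -> AmpliconResult:
    """Fraction of aligned amplicon reads with an indel at the cut site.

    Reads are aligned end-to-end to the amplicon (edlib, global mode);
    reads diverging from the reference by more than ``max_divergence``
    (edit distance over reference length) are discarded.  A read counts
    as edited when any insertion or deletion in its alignment overlaps
    ``cut +/- window``.  Fewer than 100 aligned reads flags the result
    as low-coverage.
    """
    n_aligned = 0
    n_indel = 0
    reference = reference.upper()
    lo, hi = cut - window, cut + window
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else r.seq
        res = edlib.align(seq.upper(), reference, mode="NW", task="path")
        if res["editDistance"] > max_divergence * len(reference):
            continue
        n_aligned += 1
        ref_pos = 0
        has_indel = False
        for length, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                ref_pos += length
            elif op == "I":  # bases in the read absent from the reference
                if lo <= ref_pos <= hi:
                    has_indel = True
            elif op == "D":  # reference bases missing from the read
                if ref_pos < hi and ref_pos + length > lo:
                    has_indel = True
                ref_pos += length
        if has_indel:
            n_indel += 1
    pct = round(100.0 * n_indel / n_aligned, 2) if n_aligned else float("nan")
    return AmpliconResult(pct, len(reads), n_aligned, n_indel, n_aligned < 100)


def write_sites_bed(sites: list[OffTargetSite], path: str) -> None:
    """BED6 + n_mismatches + support columns."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.start + SITE_LEN}\tOT{i + 1}\t{s.n_mismatches}\t{s.strand}\t{s.n_mismatches}\t{s.support}\n"
            )
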