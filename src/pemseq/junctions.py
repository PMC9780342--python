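"""Bait->prey junction location and outcome classification.

Each processed read begins with the bait: reference sequence from the
nested-primer anchor running toward the cut site.  The junction is the
first payload position that diverges from the colinear reference
(isolated substitutions are re-synchronised and ignored); the remainder
of the read is the prey, which is mapped genome-first, then vector, to
decide the outcome class:

1. no junction, colinear through the cut site  -> uncut
2. inserted segment aligning to the vector     -> AAV integration (buried)
3. prey aligning to the vector                 -> AAV integration (fusion)
4. prey colinear downstream within +/-20 kb    -> indel or large deletion
5. prey within +/-100 bp of an off-target cut  -> off-target translocation
6. anything else (other chromosome, > 20 kb,
   or inverted within the window)              -> general translocation

Reads whose prey is too short or unmappable are binned as ambiguous and
excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import defaults as dflt
from .align import AlignmentHit, ReferenceIndex, seed_extend_align
from .guides import GuideSpec
from .io import ProcessedRead

#: mismatches tolerated over the first 20 nt when anchoring the bait
_ANCHOR_MM = 2

#: query-offset below which the prey is taken to start at its alignment
#: (alignment trimming of an error at the joint), and at or above which an
#: inserted segment is assumed
_INSERT_MIN = 3


@dataclass(frozen=True)
class RawJunction:
    """Output of :func:`locate_junction` before classification."""

    read_id: str
    umi: str
    bait_end: int          # reference coordinate where colinearity ends
    query_div: int         # payload position of the divergence
    prey: str              # payload from the divergence on ("" if none)
    colinear_past_cut: int  # nt of colinear reference beyond the cut site
    has_junction: bool


@dataclass(frozen=True)
class JunctionCall:
    """One classified molecule (or read, before deduplication)."""

    read_id: str
    umi: str
    cls: str               # uncut/indel/large_deletion/offtarget_translocation/
                           # general_translocation/aav_integration/ambiguous
    aav_type: str = "none"  # buried/fusion/none
    prey_ref: str = ""
    prey_pos: int = -1
    prey_strand: str = "."
    deletion_size: int | None = None
    insertion_size: int | None = None
    bait_end: int = -1
    molecule_id: int = -1
    n_reads: int = 1
    #: signed microhomology span: the junction coordinate is sequence-
    #: ambiguous over [prey_pos+mh_span, prey_pos] (negative span, '+' prey)
    #: or [prey_pos, prey_pos+mh_span] (positive span, '-' prey)
    mh_span: int = 0

    @property
    def truth_label(self) -> str:
        """Class name in the simulator's seven-class vocabulary."""
        if self.cls == "aav_integration":
            return "aav_buried" if self.aav_type == "buried" else "aav_fusion"
        return self.cls


def locate_junction(
    read: ProcessedRead,
    guide: GuideSpec,
    reference: str,
) -> RawJunction | None:
    """Walk the payload along the bait reference and find the breakpoint.

    The payload must start at the nested-primer anchor (<= 2 mismatches
    over its first 20 nt), else the read is dropped (wrong locus) and
    ``None`` returned.  Isolated substitutions are tolerated: a mismatch
    whose following 10 nt re-align colinearly (<= 1 mismatch) is treated
    as a sequencing error, not a junction.
    """
    payload = read.payload
    anchor = guide.anchor
    cut = guide.cut_site
    n_ref = len(reference)

    head = payload[:20]
    ref_head = reference[anchor : anchor + 20]
    if len(head) < 20 or sum(a != b for a, b in zip(head, ref_head)) > _ANCHOR_MM:
        return None

    i = 0
    while i < len(payload) and anchor + i < n_ref:
        if payload[i] == reference[anchor + i]:
            i += 1
            continue
        # isolated substitution? look ahead
        look_q = payload[i + 1 : i + 11]
        look_r = reference[anchor + i + 1 : anchor + i + 1 + len(look_q)]
        if len(look_q) >= 6 and sum(a != b for a, b in zip(look_q, look_r)) <= 1:
            i += 1
            continue
        break

    bait_end = anchor + i
    prey = payload[i:]
    has_junction = i < len(payload)
    return RawJunction(
        read_id=read.read_id,
        umi=read.umi,
        bait_end=bait_end,
        query_div=i,
        prey=prey,
        colinear_past_cut=bait_end - cut,
        has_junction=has_junction,
    )


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _microhomology_backtrack(
    bait_ref: str, bait_end: int, prey_ref: str, jct: int, strand: str, cap: int = 15
) -> int:
    """How far (bp) the junction could shift bait-ward by sequence identity.

    The bait walk is maximal, so when the last bait bases also match the
    prey reference just before (after, for '-') the entry point, the true
    breakpoint is ambiguous over that microhomology tract.  The span is
    used when testing junction/cut-site concordance at candidate
    off-targets, whose sequences are guide-like and hence share long
    tracts with the bait.
    """
    k = 0
    while k < cap:
        bi = bait_end - 1 - k
        if bi < 0:
            break
        b = bait_ref[bi]
        if strand == "+":
            pi = jct - 1 - k
            if pi < 0 or prey_ref[pi] != b:
                break
        else:
            pi = jct + k
            if pi >= len(prey_ref) or prey_ref[pi] != _COMP1.get(b):
                break
        k += 1
    return k


def _entry_coordinate(hit: AlignmentHit) -> int:
    """Reference coordinate of the prey's first base, colinearly extended
    through any alignment-trimmed bases at the joint."""
    if hit.strand == "+":
        return hit.ref_start - hit.query_start
    return hit.ref_end + hit.query_start


def _near_offtarget(chrom: str, pos: int, offtargets, window: int) -> bool:
    return any(c == chrom and abs(pos - cut) <= window for c, cut, *_ in offtargets)


def classify(
    raw: RawJunction,
    guide: GuideSpec,
    genome_index: ReferenceIndex,
    vector_index: ReferenceIndex | None,
    offtargets: list[tuple[str, int, str]] | None = None,
    d_large: int = dflt.D_LARGE,
    ot_window: int = dflt.OFFTARGET_WINDOW,
    min_score: int = dflt.MIN_SCORE,
) -> JunctionCall:
    """Assign the outcome class to a located junction.

    ``offtargets`` is a list of ``(chrom, cut_site, strand)`` for known
    off-target sites; it may be empty on a discovery first pass, in which
    case every off-target translocation is (correctly, at that stage)
    reported as general.  Prey mapping follows the genome-then-vector
    remap order: a prey scoring above ``min_score`` on both is assigned
    to the genome.
    """
    offtargets = offtargets or []
    common = dict(read_id=raw.read_id, umi=raw.umi, bait_end=raw.bait_end)

    if not raw.has_junction:
        if raw.colinear_past_cut >= dflt.UNCUT_MIN_COLINEAR:
            return JunctionCall(
                cls="uncut", prey_ref=guide.chrom, prey_pos=guide.cut_site, prey_strand="+", **common
            )
        return JunctionCall(cls="ambiguous", **common)

    if len(raw.prey) < dflt.MIN_PREY_LEN:
        return JunctionCall(cls="ambiguous", **common)

    genome_hits = seed_extend_align(raw.prey, genome_index, min_score)
    best = genome_hits[0] if genome_hits else None

    if best is not None and best.query_start < _INSERT_MIN:
        return _classify_location(
            raw, best, guide, offtargets, d_large, ot_window, common,
            references=genome_index.references,
        )

    if best is not None:
        # unaligned prey prefix = inserted segment; remap genome-first.
        # The insert is a bounded segment, so a short one only needs to
        # match near-perfectly: relax min_score to its own length.
        prefix = raw.prey[: best.query_start]
        ins_len = len(prefix)
        prefix_min_score = min(min_score, ins_len)
        prefix_genome = None
        prefix_vector = None
        if len(prefix) >= genome_index.seed_len:
            hits = seed_extend_align(prefix, genome_index, prefix_min_score)
            prefix_genome = hits[0] if hits else None
            if prefix_genome is None and vector_index is not None:
                vhits = seed_extend_align(prefix, vector_index, prefix_min_score)
                prefix_vector = vhits[0] if vhits else None
        if prefix_vector is not None:
            return JunctionCall(
                cls="aav_integration",
                aav_type="buried",
                prey_ref=prefix_vector.ref_name,
                prey_pos=prefix_vector.junction_coordinate(),
                prey_strand=prefix_vector.strand,
                insertion_size=ins_len,
                **common,
            )
        if ins_len <= dflt.MAX_INSERTION_INDEL:
            # short untemplated (or genome-templated) insertion at the joint;
            # the resume point is the hit itself, not an extrapolation
            # through the inserted bases
            call = _classify_location(
                raw, best, guide, offtargets, d_large, ot_window, common,
                references=genome_index.references, extrapolate=False,
            )
            if call.cls == "indel":
                return JunctionCall(
                    cls="indel",
                    prey_ref=call.prey_ref,
                    prey_pos=call.prey_pos,
                    prey_strand=call.prey_strand,
                    insertion_size=ins_len,
                    **common,
                )
            return call
        return JunctionCall(cls="ambiguous", **common)

    if vector_index is not None:
        vhits = seed_extend_align(raw.prey, vector_index, min_score) if len(raw.prey) >= vector_index.seed_len else []
        vbest = vhits[0] if vhits else None
        if vbest is not None and vbest.query_start <= dflt.MAX_INSERTION_INDEL:
            return JunctionCall(
                cls="aav_integration",
                aav_type="fusion",
                prey_ref=vbest.ref_name,
                prey_pos=vbest.junction_coordinate(),
                prey_strand=vbest.strand,
                **common,
            )

    return JunctionCall(cls="ambiguous", **common)


def _classify_location(
    raw: RawJunction,
    hit: AlignmentHit,
    guide: GuideSpec,
    offtargets,
    d_large: int,
    ot_window: int,
    common: dict,
    references: dict[str, str] | None = None,
    extrapolate: bool = True,
) -> JunctionCall:
    """Rules (4)-(6): genomic prey location relative to the bait window.

    ``extrapolate`` projects alignment-trimmed joint bases back onto the
    reference; it must be off when the unaligned prefix is an insertion.
    """
    if extrapolate:
        jct = _entry_coordinate(hit)
    else:
        jct = hit.ref_start if hit.strand == "+" else hit.ref_end
    mh = 0
    if references is not None:
        k = _microhomology_backtrack(
            references[guide.chrom], raw.bait_end, references[hit.ref_name], jct, hit.strand
        )
        mh = -k if hit.strand == "+" else k
    loc = dict(prey_ref=hit.ref_name, prey_pos=jct, prey_strand=hit.strand, mh_span=mh)

    if guide.in_bait_window(hit.ref_name, jct) and hit.strand == "+":
        delta = jct - raw.bait_end
        if -dflt.MAX_INSERTION_INDEL <= delta <= d_large:
            # small negative delta = the prey re-enters slightly upstream of
            # the bait end: a duplication-like insertion, still an indel
            return JunctionCall(
                cls="indel",
                deletion_size=max(0, delta),
                insertion_size=(-delta if delta < 0 else None),
                **loc,
                **common,
            )
        if d_large < delta <= guide.window_half:
            return JunctionCall(cls="large_deletion", deletion_size=delta, **loc, **common)

    if _near_offtarget(hit.ref_name, jct, offtargets, ot_window):
        return JunctionCall(cls="offtarget_translocation", **loc, **common)

    return JunctionCall(cls="general_translocation", **loc, **common)


def write_calls_tsv(calls: list[JunctionCall], path: str) -> None:
    """Fixed-column TSV of junction calls."""
    cols = (
        "molecule_id\tread_id\tumi\tclass\taav_type\tprey_ref\tprey_pos\tprey_strand\t"
        "deletion_size\tinsertion_size\tbait_end\tn_reads\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            fh.write(
                f"{c.molecule_id}\t{c.read_id}\t{c.umi}\t{c.cls}\t{c.aav_type}\t{c.prey_ref}\t"
                f"{c.prey_pos}\t{c.prey_strand}\t"
                f"{'' if c.deletion_size is None else c.deletion_size}\t"
                f"{'' if c.insertion_size is None else c.insertion_size}\t{c.bait_end}\t{c.n_reads}\n"
            )


def write_translocations_bedpe(calls: list[JunctionCall], guide: GuideSpec, path: str) -> None:
    """Translocation junctions as BEDPE (bait side <-> prey side)."""
    cut = guide.cut_site
    with open(path, "w") as fh:
        for c in calls:
            if c.cls not in ("offtarget_translocation", "general_translocation"):
                continue
            fh.write(
                f"{guide.chrom}\t{max(0, cut - 1)}\t{cut}\t"
                f"{c.prey_ref}\t{max(0, c.prey_pos - 1)}\t{c.prey_pos}\t"
                f"mol{c.molecule_id}\t.\t+\t{c.prey_strand}\n"
            )
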