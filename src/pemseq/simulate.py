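"""Truth-labeled synthetic library generator.

Builds a small two-chromosome genome carrying one on-target SpCas9 site
(the Vegfa-sg1 protospacer+PAM) and a configurable set of planted
off-target sites at exact mismatch distances, a synthetic AAV-like vector
with annotated inverted terminal repeats (ITRs), and single-end FASTQ
libraries with the read architecture the classifier expects:

    [UMI][6-nt spacer][bait from the nested-primer anchor ... prey]

Each emitted read carries a :class:`TruthRecord`, so every downstream
stage (UMI dedup, junction calling, off-target discovery, summary
statistics) can be validated against known ground truth.  With a fixed
seed the generator is byte-deterministic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import defaults as dflt
from ._seq import BASES, random_dna, revcomp
from .guides import SITE_LEN, GuideSpec, cut_site_for
from .offtargets import scan_guide_matches

#: the Vegfa-sg1 guide used as the on-target site of every toy genome
SG1_PROTOSPACER = "GACCCTGGTGGACATCTTCC"
SG1_PAM = "AGG"

CLASSES = (
    "uncut",
    "indel",
    "large_deletion",
    "offtarget_translocation",
    "general_translocation",
    "aav_buried",
    "aav_fusion",
)

_CHROM_SIZES = {"chr1": 60_000, "chr2": 50_000}
_TARGET_CHROM = "chr1"
_TARGET_START = 30_000

VECTOR_NAME = "vector"
_VECTOR_LEN = 4_700
_ITR_LEN = 145


class SimRead(NamedTuple):
    """One emitted FASTQ read."""

    read_id: str
    seq: str
    qual: str


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted read.

    PCR duplicates of the same original molecule share ``molecule_id``
    and ``umi``.  ``prey_ref`` is a chromosome name or ``"vector"``.
    """

    read_id: str
    molecule_id: int
    umi: str
    true_class: str
    prey_ref: str
    prey_pos: int
    prey_strand: str


@dataclass(frozen=True)
class VectorMap:
    """AAV-like vector sequence with annotated ITR and payload intervals.

    Intervals are 0-based half-open.  The two ITRs sit at the vector ends.
    """

    sequence: str
    itr_intervals: tuple[tuple[int, int], tuple[int, int]]
    payload_interval: tuple[int, int]

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.itr_intervals
        if not (0 == a0 < a1 <= b0 < b1 == len(self.sequence)):
            raise ValueError("ITR intervals must be non-overlapping and at the two ends")
        if a1 - a0 < 100 or b1 - b0 < 100:
            raise ValueError("each ITR must be >= 100 bp")

    def in_itr(self, pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in self.itr_intervals)

    @property
    def itr_length(self) -> int:
        return sum(hi - lo for lo, hi in self.itr_intervals)


@dataclass(frozen=True)
class ToyGenome:
    """Synthetic genome with one on-target site and planted off-targets.

    ``planted_offtargets`` holds ``(chrom, start, strand, n_mismatches)``
    tuples, where ``start`` is the forward-coordinate start of the 23-mer
    site and ``n_mismatches`` its exact Hamming distance (spacer+PAM
    jointly) from the guide.
    """

    chromosomes: dict[str, str]
    target_locus: tuple[str, int, str]
    planted_offtargets: tuple[tuple[str, int, str, int], ...]
    seed: int

    @property
    def guide(self) -> GuideSpec:
        chrom, start, strand = self.target_locus
        return GuideSpec(SG1_PROTOSPACER, SG1_PAM, chrom, start, strand)

    def offtarget_cut_sites(self) -> list[tuple[str, int, str]]:
        """(chrom, cut coordinate, strand) for every planted off-target."""
        return [
            (chrom, cut_site_for(start, strand), strand)
            for chrom, start, strand, _ in self.planted_offtargets
        ]


@dataclass(frozen=True)
class SimConfig:
    """Library-simulation parameters.

    ``class_fractions`` must sum to 1; ``pcr_duplication_rate`` is the mean
    number of extra PCR copies per molecule (geometric); ``error_rate`` is
    a per-base substitution probability applied independently to every
    emitted read; ``itr_junction_bias`` is the probability that an AAV
    junction breakpoint falls inside an ITR interval.
    """

    class_fractions: dict[str, float]
    n_molecules: int
    pcr_duplication_rate: float = 0.5
    umi_length: int = dflt.UMI_LEN
    error_rate: float = 0.001
    itr_junction_bias: float = 0.6
    seed: int = 0
    read_length: int = dflt.READ_LEN

    def __post_init__(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown outcome classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1 (got {total})")
        for cls, p in self.class_fractions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"fraction for {cls} outside [0,1]")
        if not 0.0 <= self.itr_junction_bias <= 1.0:
            raise ValueError("itr_junction_bias outside [0,1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate outside [0,1]")


#: mixture used throughout the test-bench: mostly uncut alleles, a realistic
#: indel burden, rare translocations, and a few percent vector capture
DEFAULT_FRACTIONS: dict[str, float] = {
    "uncut": 0.83,
    "indel": 0.10,
    "large_deletion": 0.005,
    "offtarget_translocation": 0.01,
    "general_translocation": 0.005,
    "aav_buried": 0.025,
    "aav_fusion": 0.025,
}


def default_config(seed: int = 0, n_molecules: int = 20_000, **kw) -> SimConfig:
    """The study-condition mixture at the bench scale used for validation."""
    return SimConfig(class_fractions=dict(DEFAULT_FRACTIONS), n_molecules=n_molecules, seed=seed, **kw)


# ---------------------------------------------------------------------------
# genome / vector construction
# ---------------------------------------------------------------------------


def build_vector(seed: int = 0) -> VectorMap:
    """Synthetic 4.7-kb AAV-like vector with two 145-bp terminal ITRs.

    The ITR annotation marks coordinates only; no attempt is made to model
    real ITR palindromic structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAA7]))
    seq = random_dna(rng, _VECTOR_LEN)
    itrs = ((0, _ITR_LEN), (_VECTOR_LEN - _ITR_LEN, _VECTOR_LEN))
    return VectorMap(sequence=seq, itr_intervals=itrs, payload_interval=(_ITR_LEN, _VECTOR_LEN - _ITR_LEN))


def _mutate_site(rng: np.random.Generator, site: str, n_mm: int) -> str:
    """Copy of ``site`` with exactly ``n_mm`` substitutions."""
    pos = rng.choice(len(site), size=n_mm, replace=False)
    chars = list(site)
    for p in pos:
        alt = [b for b in BASES if b != chars[p]]
        chars[p] = alt[rng.integers(0, 3)]
    return "".join(chars)


def build_toy_genome(
    seed: int,
    n_offtargets: int = 3,
    mismatch_counts: tuple[int, ...] | list[int] = (2, 3, 4),
) -> ToyGenome:
    """Random two-chromosome genome with the sg1 site and planted off-targets.

    The on-target protospacer+PAM is embedded once on chr1; each off-target
    is a 23-mer on chr2 at exactly its requested mismatch distance from the
    guide (joint spacer+PAM count), on a random strand.  After planting, the
    genome is scrubbed so that no *other* 23-mer anywhere (either strand)
    lies within 8 mismatches of the guide: planted sites are then exactly
    the enumeration-oracle hits, which downstream hotspot discovery is
    validated against.  Planted distances are re-verified by brute-force
    character comparison before returning.
    """
    mismatch_counts = tuple(int(m) for m in mismatch_counts)
    if n_offtargets != len(mismatch_counts):
        raise ValueError("n_offtargets must equal len(mismatch_counts)")
    for m in mismatch_counts:
        if m > dflt.MAX_GUIDE_MM:
            raise ValueError(f"mismatch count {m} > {dflt.MAX_GUIDE_MM}: such a site could never pass the hotspot similarity filter")
        if m < 1:
            raise ValueError("mismatch count must be >= 1: a 0-mismatch plant would duplicate the on-target site")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70F]))
    site = SG1_PROTOSPACER + SG1_PAM
    chroms = {c: list(random_dna(rng, n)) for c, n in _CHROM_SIZES.items()}

    # embed the on-target site
    chroms[_TARGET_CHROM][_TARGET_START : _TARGET_START + SITE_LEN] = site

    # plant off-targets on chr2, well separated and away from the ends
    n2 = _CHROM_SIZES["chr2"]
    starts: list[int] = []
    while len(starts) < n_offtargets:
        cand = int(rng.integers(2_000, n2 - 2_000))
        if all(abs(cand - s) >= 1_000 for s in starts):
            starts.append(cand)
    planted: list[tuple[str, int, str, int]] = []
    for start, n_mm in zip(starts, mismatch_counts):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        mutated = _mutate_site(rng, site, n_mm)
        placed = mutated if strand == "+" else revcomp(mutated)
        chroms["chr2"][start : start + SITE_LEN] = placed
        planted.append(("chr2", start, strand, n_mm))

    protected = {(_TARGET_CHROM, _TARGET_START)} | {(c, s) for c, s, _, _ in planted}

    # scrub accidental guide lookalikes (<= 8 mismatches) from the random
    # background so planted sites are the complete oracle answer.  Free
    # positions of an offending window are rewritten to bases that
    # mismatch the guide pattern on the offending strand (an offender
    # abutting a protected site owes most of its similarity to fixed
    # bases, so free positions must actively anti-match).  When a shifted
    # window overlapping a *planted* site stays within budget regardless
    # of its flanks, that plant's mutation positions are redrawn instead.
    rc_site = revcomp(site)
    plant_by_pos = {(c, s): i for i, (c, s, _, _) in enumerate(planted)}
    for _ in range(100):
        seqs = {c: "".join(v) for c, v in chroms.items()}
        offenders = [
            (c, p, strand)
            for c, p, strand, _ in scan_guide_matches(seqs, site, dflt.MAX_GUIDE_MM)
            if (c, p) not in protected
        ]
        if not offenders:
            break
        for c, p, strand in offenders:
            overlapped_plant = next(
                (
                    plant_by_pos[(cc, ss)]
                    for (cc, ss) in plant_by_pos
                    if cc == c and abs(ss - p) < SITE_LEN
                ),
                None,
            )
            if overlapped_plant is not None:
                pc, ps, pstrand, pmm = planted[overlapped_plant]
                fresh = _mutate_site(rng, site, pmm)
                chroms[pc][ps : ps + SITE_LEN] = fresh if pstrand == "+" else revcomp(fresh)
            pattern = site if strand == "+" else rc_site
            for j in range(SITE_LEN):
                pos = p + j
                if any(cc == c and ss <= pos < ss + SITE_LEN for cc, ss in protected):
                    continue
                alt = [b for b in BASES if b != pattern[j]]
                chroms[c][pos] = alt[rng.integers(0, 3)]
    else:  # pragma: no cover - redraw loop converges in a few rounds
        raise RuntimeError("could not scrub guide lookalikes from background")

    chromosomes = {c: "".join(v) for c, v in chroms.items()}

    # verify plants by independent character-by-character recount
    for chrom, start, strand, n_mm in planted:
        placed = chromosomes[chrom][start : start + SITE_LEN]
        oriented = placed if strand == "+" else revcomp(placed)
        actual = sum(a != b for a, b in zip(oriented, site))
        if actual != n_mm:
            raise RuntimeError(f"planted off-target at {chrom}:{start} has {actual} mismatches, expected {n_mm}")
    on = chromosomes[_TARGET_CHROM][_TARGET_START : _TARGET_START + SITE_LEN]
    if on != site:
        raise RuntimeError("on-target site was clobbered during scrubbing")

    return ToyGenome(
        chromosomes=chromosomes,
        target_locus=(_TARGET_CHROM, _TARGET_START, "+"),
        planted_offtargets=tuple(planted),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


def _umi_factory(rng: np.random.Generator, length: int):
    """Draw UMIs that are pairwise Hamming distance >= 2 apart.

    Mirrors kits that ship minimum-distance UMI whitelists; keeps molecule
    identity unambiguous under the classifier's Hamming-1 UMI merge rule.
    Two UMIs within distance 1 must agree exactly on one half, so candidate
    collisions are found by hashing the two halves.
    """
    half = length // 2
    seen: list[str] = []
    by_pre: dict[str, list[int]] = {}
    by_suf: dict[str, list[int]] = {}

    def close(a: str, b: str) -> bool:
        mm = 0
        for x, y in zip(a, b):
            if x != y:
                mm += 1
                if mm > 1:
                    return False
        return True

    def draw() -> str:
        while True:
            u = random_dna(rng, length)
            cand = set(by_pre.get(u[:half], ())) | set(by_suf.get(u[half:], ()))
            if any(close(u, seen[i]) for i in cand):
                continue
            idx = len(seen)
            seen.append(u)
            by_pre.setdefault(u[:half], []).append(idx)
            by_suf.setdefault(u[half:], []).append(idx)
            return u

    return draw


def _draw_vector_breakpoint(rng, vector: VectorMap, bias: float, min_room: int) -> int:
    """Vector breakpoint; inside an ITR with probability ``bias``.

    ``min_room`` nt must remain downstream of the breakpoint so the
    junction fragment is mappable.
    """
    n = len(vector.sequence)
    (l0, l1), (r0, r1) = vector.itr_intervals
    if rng.random() < bias:
        if rng.integers(0, 2) == 0:
            return int(rng.integers(l0, l1))
        return int(rng.integers(r0, min(r1, n - min_room)))
    p0, p1 = vector.payload_interval
    return int(rng.integers(p0, p1))


def _general_translocation_site(rng, genome: ToyGenome, prey_len: int) -> tuple[str, int, str]:
    """Uniform random genomic junction far from on- and off-target windows."""
    guide = genome.guide
    ot_cuts = genome.offtarget_cut_sites()
    chrom_names = list(genome.chromosomes)
    sizes = np.array([len(genome.chromosomes[c]) for c in chrom_names], dtype=float)
    while True:
        chrom = chrom_names[int(rng.choice(len(chrom_names), p=sizes / sizes.sum()))]
        n = len(genome.chromosomes[chrom])
        pos = int(rng.integers(1_000, n - 1_000))
        if chrom == guide.chrom and abs(pos - guide.cut_site) < guide.window_half + 500:
            continue
        if any(c == chrom and abs(pos - cut) < dflt.OFFTARGET_WINDOW + 500 for c, cut, _ in ot_cuts):
            continue
        if pos < prey_len + 10 or pos > n - prey_len - 10:
            continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        return chrom, pos, strand


def _prey_from(genome: ToyGenome, chrom: str, pos: int, strand: str, length: int) -> str:
    """Prey sequence reading away from a junction at ``pos``.

    '+' reads the forward strand downstream of ``pos``; '-' reads the
    reverse complement of the sequence upstream of ``pos`` (an inverted
    joint).  The junction coordinate is ``pos`` in both cases.
    """
    seq = genome.chromosomes[chrom]
    if strand == "+":
        return seq[pos : pos + length]
    return revcomp(seq[max(0, pos - length) : pos])


def _apply_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alt = [b for b in BASES if b != chars[i]]
        chars[i] = alt[rng.integers(0, 3)]
    return "".join(chars)


def simulate_library(
    genome: ToyGenome,
    vector: VectorMap | None,
    cfg: SimConfig,
) -> tuple[list[SimRead], list[TruthRecord]]:
    """Simulate one anchored library: FASTQ reads plus per-read ground truth.

    Each molecule draws an outcome class from ``cfg.class_fractions`` and a
    fresh UMI; PCR duplicates (geometric, mean ``cfg.pcr_duplication_rate``)
    replicate the molecule and then acquire independent substitution
    errors.  Read layout::

        [UMI, cfg.umi_length nt][ACGCGT][bait from nested anchor ... prey]

    truncated at ``cfg.read_length``.
    """
    aav_frac = cfg.class_fractions.get("aav_buried", 0.0) + cfg.class_fractions.get("aav_fusion", 0.0)
    if aav_frac > 0 and vector is None:
        raise ValueError("vector is required when any AAV class fraction > 0")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    guide = genome.guide
    chrom_seq = genome.chromosomes[guide.chrom]
    anchor, cut = guide.anchor, guide.cut_site
    bait = chrom_seq[anchor:cut]
    payload_budget = cfg.read_length - cfg.umi_length - len(dflt.READ_SPACER)
    prey_budget = payload_budget - len(bait)
    # buried AAV fragments must leave room for a confidently mappable
    # genomic return (the aligner's default score floor plus slack)
    buried_max = min(500, prey_budget - dflt.MIN_SCORE - 5)

    class_names = [c for c in CLASSES if cfg.class_fractions.get(c, 0.0) > 0]
    probs = np.array([cfg.class_fractions[c] for c in class_names])
    draws = rng.choice(len(class_names), size=cfg.n_molecules, p=probs / probs.sum()) if cfg.n_molecules else np.zeros(0, int)

    reads: list[SimRead] = []
    truth: list[TruthRecord] = []
    ot_cuts = genome.offtarget_cut_sites()
    draw_umi = _umi_factory(rng, cfg.umi_length)

    for mol_id in range(cfg.n_molecules):
        cls = class_names[draws[mol_id]]
        umi = draw_umi()

        if cls == "uncut":
            prey = chrom_seq[cut : cut + prey_budget]
            prey_ref, prey_pos, prey_strand = guide.chrom, cut, "+"
        elif cls == "indel":
            if rng.random() < 0.65:
                d = int(rng.integers(1, dflt.D_LARGE - 3))
                prey = chrom_seq[cut + d : cut + d + prey_budget]
                prey_ref, prey_pos, prey_strand = guide.chrom, cut + d, "+"
            else:
                ins = random_dna(rng, int(rng.integers(3, dflt.MAX_INSERTION_INDEL - 1)))
                prey = ins + chrom_seq[cut : cut + prey_budget]
                prey_ref, prey_pos, prey_strand = guide.chrom, cut, "+"
        elif cls == "large_deletion":
            d = int(rng.integers(dflt.D_LARGE + 10, 19_000))
            prey = chrom_seq[cut + d : cut + d + prey_budget]
            prey_ref, prey_pos, prey_strand = guide.chrom, cut + d, "+"
        elif cls == "offtarget_translocation":
            oc, ocut, _ = ot_cuts[int(rng.integers(0, len(ot_cuts)))]
            prey_strand = "+" if rng.integers(0, 2) == 0 else "-"
            prey = _prey_from(genome, oc, ocut, prey_strand, prey_budget)
            prey_ref, prey_pos = oc, ocut
        elif cls == "general_translocation":
            prey_ref, prey_pos, prey_strand = _general_translocation_site(rng, genome, prey_budget)
            prey = _prey_from(genome, prey_ref, prey_pos, prey_strand, prey_budget)
        elif cls == "aav_buried":
            frag_len = int(rng.integers(dflt.MIN_PREY_LEN, buried_max + 1))
            b = _draw_vector_breakpoint(rng, vector, cfg.itr_junction_bias, frag_len)
            frag = vector.sequence[b : b + frag_len]
            prey = frag + chrom_seq[cut : cut + prey_budget]
            prey_ref, prey_pos, prey_strand = VECTOR_NAME, b, "+"
        else:  # aav_fusion
            b = _draw_vector_breakpoint(rng, vector, cfg.itr_junction_bias, dflt.MIN_PREY_LEN + 5)
            prey = vector.sequence[b : b + prey_budget]
            prey_ref, prey_pos, prey_strand = VECTOR_NAME, b, "+"

        payload = (bait + prey)[:payload_budget]
        clean = umi + dflt.READ_SPACER + payload

        n_copies = 1 + int(rng.geometric(1.0 / (1.0 + cfg.pcr_duplication_rate)) - 1)
        for copy in range(n_copies):
            read_id = f"mol{mol_id}.{copy}"
            seq = _apply_errors(rng, clean, cfg.error_rate)
            reads.append(SimRead(read_id, seq, "I" * len(seq)))
            truth.append(
                TruthRecord(
                    read_id=read_id,
                    molecule_id=mol_id,
                    umi=umi,
                    true_class=cls,
                    prey_ref=prey_ref,
                    prey_pos=prey_pos,
                    prey_strand=prey_strand,
                )
            )
    return reads, truth


# ---------------------------------------------------------------------------
# amplicon pools (for indel-rate quantification)
# ---------------------------------------------------------------------------


def simulate_amplicon_reads(
    reference: str,
    cut: int,
    indel_fraction: float,
    n_reads: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[SimRead]:
    """Amplicon-sequencing pool with a planted cut-site indel fraction.

    Each read spans the whole amplicon; with probability ``indel_fraction``
    it carries a small deletion (1-15 nt) or insertion (1-10 nt) at the cut
    position, otherwise it is the intact reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA3B]))
    reads = []
    for i in range(n_reads):
        if rng.random() < indel_fraction:
            if rng.random() < 0.7:
                d = int(rng.integers(1, 16))
                seq = reference[:cut] + reference[cut + d :]
            else:
                ins = random_dna(rng, int(rng.integers(1, 11)))
                seq = reference[:cut] + ins + reference[cut:]
        else:
            seq = reference
        seq = _apply_errors(rng, seq, error_rate)
        reads.append(SimRead(f"amp{i}", seq, "I" * len(seq)))
    return reads


# ---------------------------------------------------------------------------
# on-disk artifacts (FASTQ / FASTA / TSV / BED)
# ---------------------------------------------------------------------------


def write_fastq(reads: list[SimRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmolecule_id\tumi\ttrue_class\tprey_ref\tprey_pos\tprey_strand\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.molecule_id}\t{t.umi}\t{t.true_class}\t{t.prey_ref}\t{t.prey_pos}\t{t.prey_strand}\n"
            )


def write_planted_bed(genome: ToyGenome, path: str) -> None:
    """Planted off-target sites as BED6 (score column = mismatch count)."""
    with open(path, "w") as fh:
        for i, (chrom, start, strand, n_mm) in enumerate(genome.planted_offtargets):
            fh.write(f"{chrom}\t{start}\t{start + SITE_LEN}\tOT{i + 1}\t{n_mm}\t{strand}\n")


def write_library(outdir: str, genome: ToyGenome, vector: VectorMap | None, cfg: SimConfig) -> dict[str, str]:
    """Simulate and write genome, vector, reads, truth and planted-site BED."""
    os.makedirs(outdir, exist_ok=True)
    reads, truth = simulate_library(genome, vector, cfg)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "reads": os.path.join(outdir, "reads.fastq"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "planted": os.path.join(outdir, "planted_offtargets.bed"),
    }
    write_fasta(genome.chromosomes, paths["genome"])
    if vector is not None:
        paths["vector"] = os.path.join(outdir, "vector.fa")
        write_fasta({VECTOR_NAME: vector.sequence}, paths["vector"])
    write_fastq(reads, paths["reads"])
    write_truth(truth, paths["truth"])
    write_planted_bed(genome, paths["planted"])
    return paths
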