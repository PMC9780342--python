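"""Junction location and outcome classification rules."""

import pytest

import pemseq as pq
from pemseq._seq import revcomp
from pemseq.io import ProcessedRead
from pemseq.junctions import classify, locate_junction


def _read(payload):
    return ProcessedRead(read_id="t", umi="A" * 12, payload=payload)


@pytest.fixture(scope="module")
def ctx(genome, vector, genome_index, vector_index):
    guide = genome.guide
    return {
        "guide": guide,
        "ref": genome.chromosomes[guide.chrom],
        "gi": genome_index,
        "vi": vector_index,
        "genome": genome,
        "vector": vector,
    }


def _call(ctx, payload, offtargets=None, **kw):
    raw = locate_junction(_read(payload), ctx["guide"], ctx["ref"])
    assert raw is not None
    return classify(raw, ctx["guide"], ctx["gi"], ctx["vi"], offtargets=offtargets, **kw)


class TestLocateJunction:
    def test_colinear_read_is_uncut_candidate(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        payload = ref[guide.anchor : guide.cut_site + 30]
        raw = locate_junction(_read(payload), guide, ref)
        assert not raw.has_junction and raw.colinear_past_cut == 30

    def test_wrong_locus_read_dropped(self, ctx):
        assert locate_junction(_read("ACGT" * 40), ctx["guide"], ctx["ref"]) is None

    def test_isolated_substitution_not_a_junction(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        payload = list(ref[guide.anchor : guide.cut_site + 40])
        payload[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[payload[30]]
        raw = locate_junction(_read("".join(payload)), guide, ref)
        assert not raw.has_junction

    def test_deletion_breakpoint_located(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        payload = ref[guide.anchor : cut] + ref[cut + 57 : cut + 57 + 60]
        raw = locate_junction(_read(payload), guide, ref)
        assert raw.has_junction
        assert abs(raw.bait_end - cut) <= 3  # microhomology slack at the joint


class TestClassify:
    def test_uncut(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        call = _call(ctx, ref[guide.anchor : guide.cut_site + 30])
        assert call.cls == "uncut"

    def test_small_deletion_is_indel(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        call = _call(ctx, ref[guide.anchor : cut] + ref[cut + 57 : cut + 57 + 80])
        assert call.cls == "indel"
        assert call.deletion_size == pytest.approx(57, abs=3)

    def test_large_deletion_above_threshold(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        call = _call(ctx, ref[guide.anchor : cut] + ref[cut + 5000 : cut + 5000 + 80])
        assert call.cls == "large_deletion"
        assert call.deletion_size == pytest.approx(5000, abs=3)

    def test_threshold_boundary_three_nt_deletion(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        call = _call(ctx, ref[guide.anchor : cut] + ref[cut + 3 : cut + 3 + 80])
        assert call.cls == "indel"

    def test_other_chromosome_without_offtargets_is_general(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        prey = ctx["genome"].chromosomes["chr2"][5000:5120]
        call = _call(ctx, ref[guide.anchor : guide.cut_site] + prey, offtargets=[])
        assert call.cls == "general_translocation"
        assert call.prey_ref == "chr2"

    def test_offtarget_window_rule_100bp(self, ctx):
        """Junctions within +/-100 bp of a known off-target cut are
        off-target translocations; beyond that they are general."""
        guide, ref = ctx["guide"], ctx["ref"]
        ot = [("chr2", 5000, "+")]
        for offset, expected in [(80, "offtarget_translocation"), (150, "general_translocation")]:
            prey = ctx["genome"].chromosomes["chr2"][5000 + offset : 5000 + offset + 120]
            call = _call(ctx, ref[guide.anchor : guide.cut_site] + prey, offtargets=ot)
            assert call.cls == expected, offset

    def test_inversion_in_window_is_general(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        prey = revcomp(ref[cut + 4000 : cut + 4120])
        call = _call(ctx, ref[guide.anchor : cut] + prey, offtargets=[])
        assert call.cls == "general_translocation"
        assert call.prey_strand == "-"

    def test_vector_fusion(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        prey = ctx["vector"].sequence[300:420]
        call = _call(ctx, ref[guide.anchor : guide.cut_site] + prey)
        assert (call.cls, call.aav_type) == ("aav_integration", "fusion")
        assert call.prey_pos == 300

    def test_buried_vector_fragment(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        frag = ctx["vector"].sequence[60:120]  # 60 nt, inside the left ITR
        payload = ref[guide.anchor : cut] + frag + ref[cut : cut + 80]
        call = _call(ctx, payload)
        assert (call.cls, call.aav_type) == ("aav_integration", "buried")
        assert ctx["vector"].in_itr(call.prey_pos)

    def test_short_untemplated_insertion_is_indel(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        payload = ref[guide.anchor : cut] + "TTAACCGGTTAACC" + ref[cut : cut + 80]
        call = _call(ctx, payload)
        assert call.cls == "indel"
        assert call.insertion_size is not None

    def test_short_prey_is_ambiguous(self, ctx):
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        payload = ref[guide.anchor : cut] + "TTAACCGGTTAA"
        call = _call(ctx, payload)
        assert call.cls == "ambiguous"


class TestClassProperties:
    def test_partition_over_simulated_molecules(self, clean_run, clean_library):
        cfg, _, _ = clean_library
        s = clean_run.summary
        assert s.total_events + s.n_ambiguous == cfg.n_molecules
        for c in clean_run.molecule_calls:
            assert c.cls in {
                "uncut", "indel", "large_deletion", "offtarget_translocation",
                "general_translocation", "aav_integration", "ambiguous",
            }

    def test_offtarget_window_monotonicity(self, genome, vector, clean_library):
        """Enlarging the off-target window only moves general -> off-target."""
        _, reads, _ = clean_library
        ots = genome.offtarget_cut_sites()
        narrow = pq.run_pipeline(reads, genome, vector, known_offtargets=ots, ot_window=100)
        wide = pq.run_pipeline(reads, genome, vector, known_offtargets=ots, ot_window=400)
        n_ot = {c.read_id: c.cls for c in narrow.molecule_calls}
        w_ot = {c.read_id: c.cls for c in wide.molecule_calls}
        for rid, cls in n_ot.items():
            if cls == "offtarget_translocation":
                assert w_ot[rid] == "offtarget_translocation"
        assert wide.summary.n_ot_tx >= narrow.summary.n_ot_tx

    def test_remap_order_genome_removal_only_adds_aav_calls(self, ctx):
        """Genome-first remap order: shrinking the genomic prey search space
        can turn genomic calls ambiguous but never demote an AAV call."""
        guide, ref = ctx["guide"], ctx["ref"]
        cut = guide.cut_site
        payloads = {
            "fusion": ref[guide.anchor : cut] + ctx["vector"].sequence[300:420],
            "buried": ref[guide.anchor : cut] + ctx["vector"].sequence[60:120] + ref[cut : cut + 80],
            "tx": ref[guide.anchor : cut] + ctx["genome"].chromosomes["chr2"][5000:5120],
            "deletion": ref[guide.anchor : cut] + ref[cut + 57 : cut + 137],
        }
        bait_only = pq.ReferenceIndex({guide.chrom: ref})
        aav_full, aav_reduced = set(), set()
        for name, payload in payloads.items():
            raw = locate_junction(_read(payload), guide, ref)
            full = classify(raw, guide, ctx["gi"], ctx["vi"])
            reduced = classify(raw, guide, bait_only, ctx["vi"])
            if full.cls == "aav_integration":
                aav_full.add(name)
            if reduced.cls == "aav_integration":
                aav_reduced.add(name)
        assert {"fusion", "buried"} <= aav_full
        assert aav_full <= aav_reduced
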