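"""End-to-end orchestration: FASTQ -> molecules -> classes -> report."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

from . import defaults as dflt
from .align import ReferenceIndex
from .dedup import dedup_umis, junction_key
from .guides import GuideSpec
from .io import extract_all
from .junctions import JunctionCall, classify, locate_junction, write_calls_tsv, write_translocations_bedpe
from .offtargets import OffTargetSite, discover_offtargets
from .simulate import VECTOR_NAME, ToyGenome, VectorMap
from .summary import EditingSummary, summarize


@dataclass
class PipelineResult:
    """Everything a run produces, ready for reporting."""

    molecule_calls: list[JunctionCall]
    read_calls: list[JunctionCall]
    summary: EditingSummary
    offtarget_sites: list[OffTargetSite]
    stats: dict

    def write_report(self, outdir: str, guide: GuideSpec | None = None) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "calls": os.path.join(outdir, "molecule_calls.tsv"),
            "report_json": os.path.join(outdir, "report.json"),
            "report_tsv": os.path.join(outdir, "report.tsv"),
        }
        write_calls_tsv(self.molecule_calls, paths["calls"])
        payload = {
            "summary": self.summary.as_dict(),
            "offtarget_sites": [vars(s) for s in self.offtarget_sites],
            "stats": self.stats,
        }
        with open(paths["report_json"], "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        with open(paths["report_tsv"], "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in self.summary.as_dict().items():
                fh.write(f"{k}\t{v}\n")
            for k, v in self.stats.items():
                fh.write(f"{k}\t{v}\n")
        if guide is not None:
            paths["bedpe"] = os.path.join(outdir, "translocations.bedpe")
            write_translocations_bedpe(self.molecule_calls, guide, paths["bedpe"])
        return paths


def _reclassify_with_offtargets(
    calls: list[JunctionCall],
    sites: list[OffTargetSite],
    ot_window: int,
) -> list[JunctionCall]:
    """Move general translocations landing at discovered sites to the
    off-target class (window enlargement is monotone by construction)."""
    out = []
    for c in calls:
        if c.cls == "general_translocation" and any(
            s.chrom == c.prey_ref and abs(c.prey_pos - s.cut_site) <= ot_window for s in sites
        ):
            out.append(
                JunctionCall(
                    read_id=c.read_id, umi=c.umi, cls="offtarget_translocation",
                    prey_ref=c.prey_ref, prey_pos=c.prey_pos, prey_strand=c.prey_strand,
                    bait_end=c.bait_end, molecule_id=c.molecule_id, n_reads=c.n_reads,
                )
            )
        else:
            out.append(c)
    return out


def run_pipeline(
    reads,
    genome: ToyGenome | dict[str, str],
    vector: VectorMap | str | None = None,
    guide: GuideSpec | None = None,
    known_offtargets: list[tuple[str, int, str]] | None = None,
    discover: bool = False,
    umi_length: int = dflt.UMI_LEN,
    d_large: int = dflt.D_LARGE,
    ot_window: int = dflt.OFFTARGET_WINDOW,
    min_score: int = dflt.MIN_SCORE,
    hotspot_bin: int = dflt.HOTSPOT_BIN,
    hotspot_min_support: int = dflt.HOTSPOT_MIN_SUPPORT,
    max_guide_mm: int = dflt.MAX_GUIDE_MM,
) -> PipelineResult:
    """Classify an anchored library end to end.

    Parameters
    ----------
    reads :
        Iterable of ``(read_id, sequence)`` (or objects with ``read_id``
        and ``seq``).
    genome :
        A :class:`ToyGenome` (its embedded guide is used unless ``guide``
        is given) or a plain ``{chrom: sequence}`` dict (then ``guide``
        is required).
    vector :
        Vector map or raw sequence; ``None`` disables AAV calling.
    known_offtargets :
        ``(chrom, cut_site, strand)`` triples used during classification;
        with ``discover=True`` they are instead found de novo from
        translocation hotspots and translocations are re-attributed.
    """
    if isinstance(genome, ToyGenome):
        chromosomes = genome.chromosomes
        guide = guide or genome.guide
    else:
        chromosomes = genome
    if guide is None:
        raise ValueError("a GuideSpec is required")
    if isinstance(vector, str):
        vector = VectorMap(vector, ((0, len(vector) // 2), (len(vector) // 2, len(vector))), (0, 0))  # pragma: no cover

    genome_index = ReferenceIndex(chromosomes)
    vector_index = ReferenceIndex({VECTOR_NAME: vector.sequence}) if vector is not None else None
    reference = chromosomes[guide.chrom]

    pairs = [(r[0], r[1]) if isinstance(r, tuple) else (r.read_id, r.seq) for r in reads]
    processed, xstats = extract_all(pairs, umi_length=umi_length)

    read_calls: list[JunctionCall] = []
    n_anchor_drop = 0
    for pr in processed:
        raw = locate_junction(pr, guide, reference)
        if raw is None:
            n_anchor_drop += 1
            continue
        read_calls.append(
            classify(
                raw, guide, genome_index, vector_index,
                offtargets=known_offtargets if not discover else None,
                d_large=d_large, ot_window=ot_window, min_score=min_score,
            )
        )

    keyed = [
        (c.umi, junction_key(c.truth_label, c.prey_ref, c.prey_pos, c.prey_strand))
        for c in read_calls
    ]
    groups = dedup_umis(keyed)
    molecule_calls = []
    for mol_id, group in enumerate(groups):
        rep = read_calls[group[0]]
        molecule_calls.append(
            JunctionCall(
                read_id=rep.read_id, umi=rep.umi, cls=rep.cls, aav_type=rep.aav_type,
                prey_ref=rep.prey_ref, prey_pos=rep.prey_pos, prey_strand=rep.prey_strand,
                deletion_size=rep.deletion_size, insertion_size=rep.insertion_size,
                bait_end=rep.bait_end, molecule_id=mol_id, n_reads=len(group),
                mh_span=rep.mh_span,
            )
        )

    sites: list[OffTargetSite] = []
    if discover:
        junctions = [
            (c.prey_ref, c.prey_pos, c.mh_span)
            for c in molecule_calls
            if c.cls in ("general_translocation", "offtarget_translocation")
        ]
        sites = discover_offtargets(
            chromosomes, guide, junctions,
            bin_size=hotspot_bin, min_support=hotspot_min_support, max_mm=max_guide_mm,
        )
        molecule_calls = _reclassify_with_offtargets(molecule_calls, sites, ot_window)
    elif known_offtargets:
        sites = [
            OffTargetSite(chrom=c, start=-1, strand=s, n_mismatches=-1, cut_site=cut, support=0)
            for c, cut, s in known_offtargets
        ]

    summary = summarize(molecule_calls)
    stats = {
        **xstats.as_dict(),
        "reads_dropped_anchor": n_anchor_drop,
        "reads_classified": len(read_calls),
        "n_molecules": len(molecule_calls),
        "config": {
            "umi_length": umi_length, "d_large": d_large, "ot_window": ot_window,
            "min_score": min_score, "hotspot_bin": hotspot_bin,
            "hotspot_min_support": hotspot_min_support, "max_guide_mm": max_guide_mm,
            "discover": discover,
        },
    }
    return PipelineResult(molecule_calls, read_calls, summary, sites, stats)
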