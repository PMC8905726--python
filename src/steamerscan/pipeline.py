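"""End-to-end orchestration: detect -> classify -> filter -> cluster ->
consensus -> homology recovery -> copy-number -> feature reports -> phylogeny.

Every stage writes its inputs/outputs into a numbered subdirectory of the run
directory, and a machine-readable manifest records the package version, the
seed, the config hash and a checksum per output file.  Given identical inputs
and seed the manifest is byte-identical (timings go to the log, never into
the manifest).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, clade_classifier as clc, cluster_consensus as cc
from . import hit_tools as ht, io as sio, ltr_detector as ld
from . import steamer_features as sf, te_phylogeny as tp
from ._seqs import revcomp

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    run_dir: Path
    candidates: list = field(default_factory=list)
    calls: dict = field(default_factory=dict)
    retained: set = field(default_factory=set)
    consensi: list = field(default_factory=list)
    merged: list = field(default_factory=list)
    report: object = None
    steamer_reports: list = field(default_factory=list)
    tree: object = None
    branches: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _stage_dir(run_dir: Path, idx: int, name: str) -> Path:
    d = run_dir / f"{idx:02d}_{name}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(
    genome: dict[str, str],
    panel: list[clc.PanelEntry],
    config: sio.PipelineConfig,
    run_dir: str | Path,
    species_map: dict[str, str] | None = None,
) -> PipelineResult:
    """Run all stages on an in-memory genome against a labeled domain panel.

    species_map maps phylogeny taxon ids to species; by default an element
    taxon inherits its contig id and a panel taxon its own id.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(run_dir=run_dir)
    outputs: dict[str, str] = {}
    stages_done: list[str] = []
    genome_length = sum(len(s) for s in genome.values())

    def record(stage: str, *paths: Path) -> None:
        for p in paths:
            outputs[str(p.relative_to(run_dir))] = sio.file_sha256(p)
        stages_done.append(stage)
        logger.info("stage %s complete", stage)

    def run_stage(idx: int, name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn(_stage_dir(run_dir, idx, name))
        except Exception as exc:  # halt with stage name, keep partial outputs
            _write_manifest(failed=name)
            raise StageFailure(name, exc) from exc
        logger.info("stage %s took %.2fs", name, time.perf_counter() - t0)
        return out

    def _write_manifest(failed: str | None = None) -> None:
        manifest = {
            "tool": "steamerscan",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "genome_bp": genome_length,
            "stages": stages_done,
            "failed_stage": failed,
            "outputs": outputs,
        }
        sio.write_manifest(manifest, run_dir / "manifest.json")
        result.manifest = manifest

    sio.save_config(config, run_dir / "config.yaml")
    outputs["config.yaml"] = sio.file_sha256(run_dir / "config.yaml")

    # 1. structural detection -------------------------------------------------
    def stage_detect(d: Path):
        cands = ld.find_ltr_pairs(genome, config.detection_params())
        sio.write_gff3(cands, d / "candidates.gff3")
        sio.write_tsv(sio.candidates_to_rows(cands), d / "candidates.tsv",
                      header=sio.CANDIDATE_TSV_HEADER)
        record("detect", d / "candidates.gff3", d / "candidates.tsv")
        return cands

    result.candidates = run_stage(1, "detect", stage_detect)

    # 2. extraction -----------------------------------------------------------
    def stage_extract(d: Path):
        elements = {}
        internals = {}
        for c in result.candidates:
            eid = f"{c.seq_id}:{c.start}-{c.end}"
            element, ltr5, ltr3, internal = ld.extract_regions(c, genome)
            elements[eid] = element
            internals[eid] = internal
        if elements:
            sio.write_fasta(elements, d / "elements.fa")
            sio.write_fasta(internals, d / "internals.fa")
            record("extract", d / "elements.fa", d / "internals.fa")
        else:
            record("extract")
        return elements, internals

    elements, internals = run_stage(2, "extract", stage_extract)

    # 3. superfamily vote + C-clade filter ------------------------------------
    def stage_classify(d: Path):
        calls = {}
        hits_per_query = {}
        rows = []
        for eid, internal in internals.items():
            hits = clc.rank_panel_matches(
                internal, panel, min_evalue=config.evalue_superfamily, query_id=eid
            )
            hits_per_query[eid] = hits
            call = clc.assign_superfamily(hits, top_n=config.vote_top_n)
            calls[eid] = call
            rows.append([eid, call.label, call.n_hits,
                         json.dumps(call.votes, sort_keys=True)])
        retained = {
            eid
            for eid in clc.filter_c_clade(
                hits_per_query, max_evalue=config.evalue_c_clade,
                min_cover_aa=config.min_cover_aa,
            )
            if calls[eid].label == "Gypsy"
        }
        sio.write_tsv(rows, d / "superfamily_calls.tsv",
                      header="element\tlabel\tn_hits\tvotes")
        sio.write_tsv([[e] for e in sorted(retained)], d / "c_clade_retained.ids")
        record("classify", d / "superfamily_calls.tsv", d / "c_clade_retained.ids")
        return calls, retained, hits_per_query

    result.calls, result.retained, hits_per_query = run_stage(3, "classify", stage_classify)

    # 4. clustering + insert-cleaned consensus (iterated) ----------------------
    def stage_cluster(d: Path):
        retained_seqs = {eid: elements[eid] for eid in sorted(result.retained)}
        if not retained_seqs:
            sio.write_tsv([], d / "clusters.tsv")
            record("cluster", d / "clusters.tsv")
            return None, []
        cs, consensi = cc.iterate_cluster_consensus(
            retained_seqs,
            rounds=config.cluster_rounds,
            identity_threshold=config.cluster_identity,
            occupancy_threshold=config.trim_occupancy,
            trim_mode=config.trim_mode,
        )
        rows = [
            [m, cl.centroid_id, cl.strands.get(m, "+"), cl.identities.get(m, "")]
            for cl in cs.clusters for m in cl.members
        ]
        sio.write_tsv(rows, d / "clusters.tsv", header="member\tcentroid\tstrand\tidentity")
        sio.write_fasta(
            [(f"{r.cluster_id}|consensus|n={r.n_members}", r.consensus) for r in consensi],
            d / "consensi.fa",
        )
        record("cluster", d / "clusters.tsv", d / "consensi.fa")
        return cs, consensi

    _, result.consensi = run_stage(4, "cluster", stage_cluster)

    # 5. homology recovery + defragmentation ----------------------------------
    def stage_homology(d: Path):
        library = {r.cluster_id: r.consensus for r in result.consensi}
        if not library:
            sio.write_bed([], d / "merged.bed")
            record("homology", d / "merged.bed")
            return [], []
        hits = ht.similarity_search(library, genome, min_identity=config.min_hit_identity)
        merged = ht.concatenate_hits(hits, max_gap=config.merge_max_gap,
                                     min_len=config.merge_min_len)
        sio.write_bed(hits, d / "hits.bed")
        sio.write_bed(merged, d / "merged.bed")
        masked = ht.mask_genome(genome, merged, soft=config.mask_soft)
        sio.write_fasta(masked, d / "masked.fa")
        record("homology", d / "hits.bed", d / "merged.bed", d / "masked.fa")
        return hits, merged

    _, result.merged = run_stage(5, "homology", stage_homology)

    # 6. copy-number report ----------------------------------------------------
    def stage_copynumber(d: Path):
        report = ht.copy_number_report(
            result.candidates, result.merged, genome_length, subfamily="all"
        )
        sio.write_tsv([ht.report_tsv_row(report).split("\t")], d / "copy_number.tsv",
                      header=ht.REPORT_TSV_HEADER)
        record("copynumber", d / "copy_number.tsv")
        return report

    result.report = run_stage(6, "copynumber", stage_copynumber)

    # 7. steamer feature reports ------------------------------------------------
    def stage_features(d: Path):
        reports = []
        domains = {}
        for c in result.candidates:
            eid = f"{c.seq_id}:{c.start}-{c.end}"
            element, ltr5, ltr3, internal = ld.extract_regions(c, genome)
            if c.strand == "-":
                element = revcomp(element)
                ltr5, ltr3 = revcomp(ltr3), revcomp(ltr5)
                internal = revcomp(internal)
                ltr5_span = (0, len(ltr5))
                ltr3_span = (len(element) - len(ltr3), len(element))
            else:
                ltr5_span = (0, len(ltr5))
                ltr3_span = (len(element) - len(ltr3), len(element))
            m5, m3 = sf.check_ltr_motifs(ltr5, ltr3)
            rep = sf.SteamerReport(
                element_id=eid,
                element_length=len(element),
                ltr5_length=len(ltr5),
                ltr3_length=len(ltr3),
                ltr5_motifs=m5,
                ltr3_motifs=m3,
                pbs=sf.find_pbs(element, ltr5_span, motif=config.pbs_motif,
                                max_mm_last3=config.pbs_max_mm_last3,
                                search_offset_window=config.pbs_offset_window),
                ppt=sf.find_ppt(element, ltr3_span, window=config.ppt_window,
                                min_len=config.ppt_min_len,
                                min_purine=config.ppt_min_purine),
                orf=sf.orf_status(internal),
            )
            hits = hits_per_query.get(eid, [])
            if hits:
                rep.rt_rnaseh_identity = hits[0].identity
                try:
                    dom, _partial = clc.extract_rt_rnaseh(
                        hits[0], panel_length=len(
                            next(p.sequence for p in panel if p.id == hits[0].panel_id)
                        ),
                    )
                    rep.rt_rnaseh_domain = dom
                    domains[eid] = dom
                except clc.ExtractionRefused:
                    pass
            reports.append(rep)
        rows = [
            [r.element_id, r.element_length, r.ltr5_length, r.ltr3_length,
             r.ltr5_motifs.start_mismatches if r.ltr5_motifs else "",
             r.pbs.offset if r.pbs else "absent",
             r.ppt.length if r.ppt else "absent",
             str(r.orf), r.rt_rnaseh_identity if r.rt_rnaseh_identity else ""]
            for r in reports
        ]
        sio.write_tsv(rows, d / "steamer_reports.tsv",
                      header="element\tlength\tltr5\tltr3\tstart_mm\tpbs_offset\tppt_len\torf\trt_identity")
        record("features", d / "steamer_reports.tsv")
        return reports, domains

    result.steamer_reports, domains = run_stage(7, "features", stage_features)

    # 8. phylogeny --------------------------------------------------------------
    def stage_phylo(d: Path):
        taxa: list[tuple[str, str]] = []
        smap: dict[str, str] = {}
        for eid, dom in sorted(domains.items()):
            if eid in result.retained:
                taxa.append((eid, dom))
                smap[eid] = eid.split(":")[0]
        for p in panel:
            if p.clade == "C-clade":
                taxa.append((p.id, p.sequence))
                smap[p.id] = f"panel_{p.id}"
        if species_map:
            smap.update(species_map)
        if len(taxa) < 3:
            sio.write_tsv([], d / "branches.tsv")
            record("phylo", d / "branches.tsv")
            return None, []
        taxa.sort(key=lambda kv: (-len(kv[1]), kv[0]))
        aln = cc.align_cluster(taxa)
        sio.write_fasta(aln, d / "domains.aln.fa")
        sio.write_phylip(tp.pairwise_deletion_pdist(aln), d / "distances.phy")
        tree = tp.bootstrap_support(aln, replicates=config.bootstrap_replicates,
                                    seed=config.seed)
        branches = tp.define_branches(
            tree, smap, min_support=config.branch_min_support,
            min_species=config.branch_min_species,
        )
        sio.write_newick(tree, d / "tree.nwk")
        sio.write_tsv(
            [[b.name, b.support, len(b.members), ";".join(sorted(b.members))]
             for b in branches],
            d / "branches.tsv", header="branch\tsupport\tn_members\tmembers",
        )
        record("phylo", d / "domains.aln.fa", d / "distances.phy",
               d / "tree.nwk", d / "branches.tsv")
        return tree, branches

    result.tree, result.branches = run_stage(8, "phylo", stage_phylo)

    _write_manifest()
    return result
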