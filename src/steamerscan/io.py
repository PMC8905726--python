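"""Readers, writers and pipeline configuration.

FASTA goes through Biopython (60-column wrapping, mixed case preserved so
soft-masking survives round trips).  Interval formats follow the usual
conventions: BED is 0-based half-open, GFF3 is 1-based inclusive with
percent-escaped attributes.  Internally everything is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clade_classifier import PanelEntry
from .hit_tools import MergedHit, RepeatHit
from .ltr_detector import DetectionParams, LTRCandidate
from .simdata import TRUTH_TSV_HEADER, TruthRecord


class ParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> sequence, case preserved. Raises ParseError with the line number
    when content precedes the first header."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
            break
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in items]
    SeqIO.write(recs, str(path), "fasta")


def read_panel_fasta(path: str | Path) -> list[PanelEntry]:
    """Panel records with 'id|superfamily|clade' headers."""
    out = []
    for rid, seq in read_fasta(path).items():
        parts = rid.split("|")
        if len(parts) < 2:
            raise ParseError(f"panel header {rid!r} lacks '|label' fields")
        clade = parts[2] if len(parts) > 2 else "-"
        out.append(PanelEntry(id=parts[0], superfamily=parts[1], clade=clade, sequence=seq))
    return out


def write_panel_fasta(panel: list[PanelEntry], path: str | Path) -> None:
    write_fasta([(f"{p.id}|{p.superfamily}|{p.clade}", p.sequence) for p in panel], path)


# ---------------------------------------------------------------------------
# GFF3 / BED / TSV

def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def write_gff3(
    items: list[LTRCandidate] | list[TruthRecord], path: str | Path, source: str = "steamerscan"
) -> None:
    """Elements as LTR_retrotransposon features with long_terminal_repeat
    children; 0-based half-open spans become 1-based inclusive."""
    lines = ["##gff-version 3"]
    for i, it in enumerate(items):
        if isinstance(it, LTRCandidate):
            seq_id, start, end = it.seq_id, it.start, it.end
            ltr5, ltr3 = it.ltr5, it.ltr3
            strand = it.strand if it.strand in "+-" else "."
            attrs = f"ID=elem{i+1};ltr_identity={it.ltr_identity}"
            if it.note:
                attrs += f";note={_gff3_escape(it.note)}"
        else:
            seq_id, start, end = it.seq_id, it.start, it.end
            ltr5 = (it.ltr5_start, it.ltr5_end)
            ltr3 = (it.ltr3_start, it.ltr3_end)
            strand = it.strand
            attrs = (
                f"ID=elem{i+1};subfamily={_gff3_escape(it.subfamily)};"
                f"is_full_size={int(it.is_full_size)}"
            )
        if start < 0 or end <= start:
            raise ParseError(f"cannot serialize span [{start},{end})")
        lines.append(
            "\t".join(
                [seq_id, source, "LTR_retrotransposon", str(start + 1), str(end),
                 ".", strand, ".", attrs]
            )
        )
        for tag, (s, e) in (("five_prime", ltr5), ("three_prime", ltr3)):
            if e > s:
                lines.append(
                    "\t".join(
                        [seq_id, source, "long_terminal_repeat", str(s + 1), str(e),
                         ".", strand, ".", f"Parent=elem{i+1};ltr={tag}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(items: list[RepeatHit] | list[MergedHit], path: str | Path) -> None:
    lines = []
    for it in items:
        name = it.library_id
        score = getattr(it, "score", 0)
        strand = getattr(it, "strand", ".")
        lines.append(f"{it.seq_id}\t{it.start}\t{it.end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_tsv(rows: list[list | tuple], path: str | Path, header: str | None = None) -> None:
    lines = [header] if header else []
    lines += ["\t".join(str(x) for x in row) for row in rows]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


CANDIDATE_TSV_HEADER = (
    "seq_id\tstart\tend\tltr5_start\tltr5_end\tltr3_start\tltr3_end\tltr_identity\tstrand\tnote"
)


def candidates_to_rows(cands: list[LTRCandidate]) -> list[list]:
    return [
        [c.seq_id, c.start, c.end, c.ltr5[0], c.ltr5[1], c.ltr3[0], c.ltr3[1],
         c.ltr_identity, c.strand, c.note]
        for c in cands
    ]


def read_candidates_tsv(path: str | Path) -> list[LTRCandidate]:
    cands = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        f = line.split("\t")
        cands.append(
            LTRCandidate(
                seq_id=f[0], start=int(f[1]), end=int(f[2]),
                ltr5=(int(f[3]), int(f[4])), ltr3=(int(f[5]), int(f[6])),
                ltr_identity=float(f[7]), strand=f[8],
                note=f[9] if len(f) > 9 else "",
            )
        )
    return cands


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    write_tsv([t.as_tsv_row().split("\t") for t in truth], path, header=TRUTH_TSV_HEADER)


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def write_phylip(dist, path: str | Path) -> None:
    """Square PHYLIP distance matrix (names padded to 10 characters)."""
    lines = [f"{len(dist.ids)}"]
    for name, row in zip(dist.ids, dist.matrix):
        label = name[:10].ljust(10)
        lines.append(label + "  " + "  ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the published defaults."""

    # structural detection
    min_ltr_len: int = 80
    max_ltr_len: int = 1200
    min_dist: int = 2500
    max_dist: int = 11000
    min_similarity: float = 80.0
    seed_k: int = 13
    motif_refine: bool = True
    # homology search / defragmentation
    min_hit_identity: float = 80.0
    merge_max_gap: int = 500
    merge_min_len: int = 300
    mask_soft: bool = False
    # clustering / consensus
    cluster_identity: float = 0.80
    trim_occupancy: float = 0.80
    trim_mode: str = "occupancy"
    cluster_rounds: int = 2
    # classification
    vote_top_n: int = 10
    evalue_superfamily: float = 1e-15
    evalue_c_clade: float = 1e-50
    min_cover_aa: int = 300
    # steamer features
    pbs_motif: str = "TGGTGTCAGAAG"
    pbs_max_mm_last3: int = 2
    pbs_offset_window: int = 3
    ppt_window: int = 50
    ppt_min_len: int = 10
    ppt_min_purine: float = 0.90
    # phylogeny
    bootstrap_replicates: int = 100
    branch_min_support: float = 80.0
    branch_min_species: int = 2
    # global
    seed: int = 0

    def validate(self) -> None:
        DetectionParams(
            min_ltr_len=self.min_ltr_len, max_ltr_len=self.max_ltr_len,
            min_dist=self.min_dist, max_dist=self.max_dist,
            min_similarity=self.min_similarity, seed_k=self.seed_k,
            motif_refine=self.motif_refine,
        ).validate()
        if not 0 < self.cluster_identity <= 1:
            raise ConfigError("cluster_identity must be in (0,1]")
        if not 0 < self.trim_occupancy <= 1:
            raise ConfigError("trim_occupancy must be in (0,1]")
        if self.trim_mode not in ("occupancy", "identity"):
            raise ConfigError("trim_mode must be occupancy or identity")
        if self.cluster_rounds < 1:
            raise ConfigError("cluster_rounds must be >= 1")
        if self.evalue_superfamily <= 0 or self.evalue_c_clade <= 0:
            raise ConfigError("E-value thresholds must be > 0")
        if self.merge_max_gap < 0 or self.merge_min_len < 0:
            raise ConfigError("merge parameters must be >= 0")
        if len(self.pbs_motif) != 12:
            raise ConfigError("pbs_motif must be 12 bp")
        if not 0 < self.ppt_min_purine <= 1:
            raise ConfigError("ppt_min_purine must be in (0,1]")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            min_ltr_len=self.min_ltr_len, max_ltr_len=self.max_ltr_len,
            min_dist=self.min_dist, max_dist=self.max_dist,
            min_similarity=self.min_similarity, seed_k=self.seed_k,
            motif_refine=self.motif_refine,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load YAML config; unknown keys are rejected, values validated."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config file must contain a mapping")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.to_yaml())


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
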