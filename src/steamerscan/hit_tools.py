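"""Homology-based recovery of fragmented element copies and copy-number accounting.

A consensus library is searched against the genome with a seed-and-extend
local search on both strands (a self-contained stand-in for a RepeatMasker
run).  Raw hits are then defragmented by concatenating hits closer than
500 bp and removing merged spans smaller than 300 bp — both inequalities
strict — before masking and per-subfamily copy-number summaries.

Size bins for the summary: ">4 kb" is strict (> 4000 bp) and "2-4 kb" is
(2000, 4000], so the two bins partition all loci above 2 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seqs import cigar_ops, kmer_codes, revcomp


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatHit:
    """One local alignment of a library consensus to the genome.

    start/end are always forward-genome coordinates, whatever the strand.
    """

    library_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: int
    identity: float

    def validate(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"empty hit span [{self.start},{self.end})")
        if not 0 < self.identity <= 100:
            raise ParameterError(f"identity {self.identity} out of (0,100]")


@dataclass(frozen=True)
class MergedHit:
    library_id: str
    seq_id: str
    start: int
    end: int
    n_hits: int
    matched_bp: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberReport:
    """Per-subfamily summary in the style of a copy-number table:
    structural full-size count, homology loci binned by size, masked bp and
    genomic proportion."""

    subfamily: str
    n_full_size: int
    n_gt_4kb: int
    n_2_to_4kb: int
    n_total_loci: int
    bp_masked: int
    genome_length: int
    genomic_proportion: float = field(init=False)
    avg_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.genomic_proportion = (
            round(100.0 * self.bp_masked / self.genome_length, 2) if self.genome_length else 0.0
        )
        self.avg_length = (
            int(round(self.bp_masked / self.n_total_loci)) if self.n_total_loci else 0
        )


# ---------------------------------------------------------------------------
# similarity search

def _seed_clusters(
    lib_pos: dict[int, list[int]],
    gpos: np.ndarray,
    gcodes: np.ndarray,
    k: int,
    max_gap: int,
) -> list[list[tuple[int, int]]]:
    """Cluster (genome_pos, library_pos) seed matches into collinear runs."""
    if not lib_pos:
        return []
    lcode_arr = np.fromiter(lib_pos.keys(), dtype=np.uint64)
    sel = np.isin(gcodes, lcode_arr)
    matches: list[tuple[int, int]] = []
    for gp, gc in zip(gpos[sel], gcodes[sel]):
        for lp in lib_pos[int(gc)]:
            matches.append((int(gp), lp))
    matches.sort()
    clusters: list[list[tuple[int, int]]] = []
    for gp, lp in matches:
        placed = False
        for cl in reversed(clusters):
            lgp, llp = cl[-1]
            if gp - lgp > max_gap:
                break
            # require rough collinearity (diagonal drift bounded by gap size)
            if abs((gp - lp) - (lgp - llp)) <= 100 and gp >= lgp:
                cl.append((gp, lp))
                placed = True
                break
        if not placed:
            clusters.append([(gp, lp)])
    return clusters


def _realign(lib_seq: str, gseq: str, gstart: int, gend: int, lstart: int, lend: int,
             margin: int = 50) -> tuple[int, int, float, int] | None:
    """Realign the library slice against the genome region (HW = infix mode).

    Returns (start, end, identity, score-as-matches) in genome coordinates.
    """
    ls = max(0, lstart - margin)
    le = min(len(lib_seq), lend + margin)
    gs = max(0, gstart - 2 * margin)
    ge = min(len(gseq), gend + 2 * margin)
    query = lib_seq[ls:le].upper()
    target = gseq[gs:ge].upper()
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc0, _ = res["locations"][0]
    # Trim the alignment to its maximal-scoring core so that margin sequence
    # aligned against unrelated flank does not inflate the hit span.
    ops = cigar_ops(res["cigar"])
    col_score: list[int] = []
    col_tadv: list[int] = []  # target advance per column
    for n, op in ops:
        if op == "=":
            col_score.extend([1] * n)
            col_tadv.extend([1] * n)
        elif op in ("X", "M"):
            col_score.extend([-2] * n)
            col_tadv.extend([1] * n)
        elif op == "D":  # deletion in query => consumes target
            col_score.extend([-2] * n)
            col_tadv.extend([1] * n)
        else:  # insertion relative to target
            col_score.extend([-2] * n)
            col_tadv.extend([0] * n)
    # Kadane: best contiguous column window
    best, cur, cur_start, best_span = 0, 0, 0, (0, 0)
    for i, sc in enumerate(col_score):
        if cur <= 0:
            cur, cur_start = 0, i
        cur += sc
        if cur > best:
            best, best_span = cur, (cur_start, i + 1)
    b0, b1 = best_span
    if b1 <= b0:
        return None
    tadv = np.cumsum([0] + col_tadv)
    t0 = loc0 + int(tadv[b0])
    t1 = loc0 + int(tadv[b1])
    core = col_score[b0:b1]
    matches = sum(1 for sc in core if sc == 1)
    cols = len(core)
    identity = 100.0 * matches / cols if cols else 0.0
    if t1 <= t0:
        return None
    return gs + t0, gs + t1, identity, matches


def similarity_search(
    library: dict[str, str] | list[tuple[str, str]],
    genome: dict[str, str] | list[tuple[str, str]],
    min_identity: float = 80.0,
    min_score: int = 30,
    seed_k: int = 13,
    seed_gap: int = 300,
) -> list[RepeatHit]:
    """Search each library consensus against both strands of the genome.

    Seeds on exact k-mers, clusters collinear seeds, and realigns each
    cluster region with an infix global alignment; hits below min_identity
    or with fewer than min_score matched bases are discarded.  Hits are
    reported in forward-genome coordinates with the matching strand.
    """
    lib_items = list(library.items() if isinstance(library, dict) else library)
    if not lib_items:
        raise ParameterError("library must be non-empty")
    gen_items = list(genome.items() if isinstance(genome, dict) else genome)
    hits: list[RepeatHit] = []
    for seq_id, gseq in gen_items:
        glen = len(gseq)
        gpos, gcodes = kmer_codes(gseq, seed_k)
        for lib_id, lib_fwd in lib_items:
            for strand, lib_seq in (("+", lib_fwd), ("-", revcomp(lib_fwd))):
                lpos, lcodes = kmer_codes(lib_seq, seed_k)
                lib_index: dict[int, list[int]] = {}
                for p, c in zip(lpos, lcodes):
                    lib_index.setdefault(int(c), []).append(int(p))
                # drop hyper-repeated library k-mers
                lib_index = {c: ps for c, ps in lib_index.items() if len(ps) <= 8}
                for cl in _seed_clusters(lib_index, gpos, gcodes, seed_k, seed_gap):
                    g0 = cl[0][0]
                    g1 = cl[-1][0] + seed_k
                    l0 = min(lp for _, lp in cl)
                    l1 = max(lp for _, lp in cl) + seed_k
                    if g1 - g0 < seed_k:
                        continue
                    ra = _realign(lib_seq, gseq, g0, g1, l0, l1)
                    if ra is None:
                        continue
                    s, e, ident, matches = ra
                    if ident < min_identity or matches < min_score:
                        continue
                    hit_start, hit_end = s, e  # realigned in forward coords
                    hits.append(
                        RepeatHit(
                            library_id=lib_id,
                            seq_id=seq_id,
                            start=max(0, hit_start),
                            end=min(glen, hit_end),
                            strand=strand,
                            score=matches,
                            identity=round(ident, 2),
                        )
                    )
    hits.sort(key=lambda h: (h.seq_id, h.library_id, h.start, h.end))
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Collapse near-duplicate hits (same locus found from both strands or
    overlapping seed clusters): keep the higher-scoring of two hits whose
    spans overlap by >90% of the shorter."""
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=lambda h: (h.seq_id, h.library_id, -h.score, h.start)):
        dup = False
        for k in kept:
            if k.seq_id != h.seq_id or k.library_id != h.library_id:
                continue
            ov = min(h.end, k.end) - max(h.start, k.start)
            if ov > 0 and ov > 0.9 * min(h.end - h.start, k.end - k.start):
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: (h.seq_id, h.library_id, h.start, h.end))
    return kept


# ---------------------------------------------------------------------------
# defragmentation / masking / reporting

def concatenate_hits(
    hits: list[RepeatHit], max_gap: int = 500, min_len: int = 300
) -> list[MergedHit]:
    """Merge chains of hits with inter-hit gap strictly below max_gap and
    drop merged spans strictly shorter than min_len (per seq_id and library)."""
    for h in hits:
        if h.end <= h.start or h.start < 0:
            raise ParameterError(f"invalid hit span [{h.start},{h.end})")
    groups: dict[tuple[str, str], list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_id, h.library_id), []).append(h)
    merged: list[MergedHit] = []
    for (seq_id, lib_id), group in groups.items():
        group.sort(key=lambda h: (h.start, h.end))
        cur_start, cur_end, n, matched = None, None, 0, 0
        for h in group:
            if cur_end is None:
                cur_start, cur_end, n, matched = h.start, h.end, 1, h.end - h.start
            elif h.start - cur_end < max_gap:  # strictly closer than max_gap
                cur_end = max(cur_end, h.end)
                n += 1
                matched += h.end - h.start
            else:
                if cur_end - cur_start >= min_len:
                    merged.append(MergedHit(lib_id, seq_id, cur_start, cur_end, n, matched))
                cur_start, cur_end, n, matched = h.start, h.end, 1, h.end - h.start
        if cur_end is not None and cur_end - cur_start >= min_len:
            merged.append(MergedHit(lib_id, seq_id, cur_start, cur_end, n, matched))
    merged.sort(key=lambda m: (m.seq_id, m.library_id, m.start))
    return merged


def mask_genome(
    genome: dict[str, str],
    merged: list[MergedHit],
    soft: bool = False,
) -> dict[str, str]:
    """Mask merged spans: hard-mask with N or soft-mask to lower case.

    Overlapping spans across libraries are unioned; unmasked positions are
    byte-identical to the input.
    """
    out: dict[str, str] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in merged:
        spans.setdefault(m.seq_id, []).append((m.start, m.end))
    for seq_id, seq in genome.items():
        todo = spans.get(seq_id)
        if not todo:
            out[seq_id] = seq
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        mask = np.zeros(len(seq), dtype=bool)
        for s, e in todo:
            if s < 0 or e > len(seq):
                raise ParameterError(f"span [{s},{e}) outside {seq_id}")
            mask[s:e] = True
        if soft:
            lower = arr + 32
            is_upper = (arr >= 65) & (arr <= 90)
            arr[mask & is_upper] = lower[mask & is_upper]
        else:
            arr[mask] = ord("N")
        out[seq_id] = arr.tobytes().decode()
    return out


def masked_bp(merged: list[MergedHit]) -> int:
    """Union size of merged spans per sequence (double-count safe)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in merged:
        spans.setdefault(m.seq_id, []).append((m.start, m.end))
    total = 0
    for sp in spans.values():
        sp.sort()
        cur_s, cur_e = None, None
        for s, e in sp:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return total


def copy_number_report(
    candidates: list,
    merged: list[MergedHit],
    genome_length: int,
    subfamily: str = "sub1",
) -> CopyNumberReport:
    """Table-style summary for one subfamily.

    n_full_size counts structural candidates (two LTRs); the homology loci
    are binned strictly above 4 kb and in (2 kb, 4 kb].
    """
    n_gt4 = sum(1 for m in merged if m.length > 4000)
    n_2to4 = sum(1 for m in merged if 2000 < m.length <= 4000)
    return CopyNumberReport(
        subfamily=subfamily,
        n_full_size=len(candidates),
        n_gt_4kb=n_gt4,
        n_2_to_4kb=n_2to4,
        n_total_loci=len(merged),
        bp_masked=masked_bp(merged),
        genome_length=genome_length,
    )


REPORT_TSV_HEADER = (
    "subfamily\tLTRH\tRM_gt4kb\tRM_2to4kb\tRM\tgenomic_proportion_pct\tbp_masked\tavg_length"
)


def report_tsv_row(r: CopyNumberReport) -> str:
    return "\t".join(
        str(x)
        for x in (
            r.subfamily, r.n_full_size, r.n_gt_4kb, r.n_2_to_4kb, r.n_total_loci,
            f"{r.genomic_proportion:.2f}", r.bp_masked, r.avg_length,
        )
    )
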