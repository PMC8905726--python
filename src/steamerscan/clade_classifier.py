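"""Superfamily assignment and C-clade filtering of candidate elements.

Candidate internal regions are translated in six frames and scored against a
labeled RT/RNaseH protein panel with BLOSUM62 local alignments (gapped,
open -11 / extend -1).  Approximate E-values follow the Karlin-Altschul form
E = K*m*n*exp(-lambda*S) with the standard gapped BLOSUM62(11,1) constants;
they are approximations of BLAST's statistics and the thresholds are
configurable.

An element is assigned to a superfamily when at least 9 of its 10 best panel
matches carry the same label ("more than 8 of the first ten"); with fewer
than ten hits a proportional rule applies.  Elements are retained as
C-clade when their best hit is C-clade-tagged with E <= 1e-50 and at least
300 aa of the panel domain covered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._seqs import revcomp

# gapped BLOSUM62(11,1) Karlin-Altschul constants
KA_LAMBDA = 0.267
KA_K = 0.041

STOP = "*"


class ParameterError(ValueError):
    pass


class ExtractionRefused(RuntimeError):
    """Best hit does not cover enough of the panel domain to guide extraction."""


@dataclass(frozen=True)
class PanelEntry:
    id: str
    superfamily: str
    clade: str
    sequence: str


@dataclass(frozen=True)
class DomainHit:
    query_id: str
    panel_id: str
    superfamily: str
    clade: str
    score: float
    evalue: float
    identity: float
    frame: int  # 0..2 forward, 3..5 reverse; -1 for protein queries
    query_aa_range: tuple[int, int]  # within the frame translation
    panel_range: tuple[int, int]
    covered_aa: int  # aligned panel residues
    query_aa: str = ""  # the frame translation the ranges refer to

    def validate(self) -> None:
        if self.evalue <= 0:
            raise ParameterError("E-value must be > 0")
        if self.covered_aa > len(self.query_aa) and self.query_aa:
            raise ParameterError("covered length exceeds query length")


@dataclass(frozen=True)
class SuperfamilyCall:
    label: str  # Gypsy / Copia / BEL/Pao / uncertain / none
    votes: dict[str, int]
    n_hits: int
    short_list: bool = False


def translate_six_frames(dna: str) -> list[str]:
    """Translations of frames +0,+1,+2,-0,-1,-2; stops rendered '*'.

    Sequences shorter than 3 bp give six empty strings.
    """
    if len(dna) < 3:
        return [""] * 6
    out = []
    for strand_seq in (dna, revcomp(dna)):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) // 3 * 3]
            out.append(str(Seq(sub).translate()) if sub else "")
    return out


@lru_cache(maxsize=1)
def _aligner() -> PairwiseAligner:
    a = PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _clean(aa: str) -> str:
    """Replace stops/non-standard residues with X so BLOSUM62 lookups work."""
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c in allowed else "X" for c in aa.upper())


def evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul E = K*m*n*exp(-lambda*S) (floored to avoid exact 0)."""
    if m <= 0 or n <= 0:
        return math.inf
    logE = math.log(KA_K) + math.log(m) + math.log(n) - KA_LAMBDA * score
    return max(math.exp(logE) if logE > -700 else 5e-324, 5e-324)


def local_alignment(query_aa: str, target_aa: str):
    """Best local alignment (or None if empty input); returns
    (score, q_range, t_range, identity, aligned_target_cols)."""
    q, t = _clean(query_aa), _clean(target_aa)
    if not q or not t:
        return None
    alns = _aligner().align(q, t)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    qa, ta = aln.aligned
    q0, q1 = int(qa[0][0]), int(qa[-1][1])
    t0, t1 = int(ta[0][0]), int(ta[-1][1])
    matches = 0
    cols = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        for i in range(qe - qs):
            cols += 1
            if q[qs + i] == t[ts + i]:
                matches += 1
    ident = 100.0 * matches / cols if cols else 0.0
    covered = t1 - t0
    return float(aln.score), (q0, q1), (t0, t1), ident, covered


def rank_panel_matches(
    query: str,
    panel: list[PanelEntry],
    min_evalue: float = 1e-15,
    query_id: str = "query",
    is_protein: bool = False,
) -> list[DomainHit]:
    """Best-frame hit per panel entry, E-value filtered and ranked.

    DNA queries are translated in six frames and frames compete: only the
    best frame per panel entry is kept.  Hits are sorted by ascending
    E-value, then descending score, then panel id (deterministic ties).
    """
    if not panel:
        raise ParameterError("panel must be non-empty")
    frames = [(-1, _clean(query))] if is_protein else list(enumerate(translate_six_frames(query)))
    db_n = sum(len(p.sequence) for p in panel)
    hits: list[DomainHit] = []
    for entry in panel:
        best: DomainHit | None = None
        for frame, aa in frames:
            if not aa:
                continue
            res = local_alignment(aa, entry.sequence)
            if res is None:
                continue
            score, qr, tr, ident, covered = res
            e = evalue(score, len(aa), db_n)
            hit = DomainHit(
                query_id=query_id,
                panel_id=entry.id,
                superfamily=entry.superfamily,
                clade=entry.clade,
                score=score,
                evalue=e,
                identity=round(ident, 2),
                frame=frame,
                query_aa_range=qr,
                panel_range=tr,
                covered_aa=covered,
                query_aa=aa,
            )
            if best is None or hit.score > best.score:
                best = hit
        if best is not None and best.evalue < min_evalue:
            hits.append(best)
    hits.sort(key=lambda h: (h.evalue, -h.score, h.panel_id))
    return hits


def assign_superfamily(ranked_hits: list[DomainHit], top_n: int = 10) -> SuperfamilyCall:
    """Vote over the (up to) ten best hits.

    Ten or more hits: a label wins with >= 9 votes.  Fewer than ten: the
    proportional rule ceil(0.9 * n), flagged as a short list.
    """
    top = ranked_hits[:top_n]
    if not top:
        return SuperfamilyCall(label="none", votes={}, n_hits=0)
    votes: dict[str, int] = {}
    for h in top:
        votes[h.superfamily] = votes.get(h.superfamily, 0) + 1
    n = len(top)
    need = 9 if n >= top_n else math.ceil(0.9 * n)
    label, count = max(votes.items(), key=lambda kv: kv[1])
    if count >= need:
        return SuperfamilyCall(label=label, votes=votes, n_hits=n, short_list=n < top_n)
    return SuperfamilyCall(label="uncertain", votes=votes, n_hits=n, short_list=n < top_n)


def extract_rt_rnaseh(
    best_hit: DomainHit, min_panel_coverage: float = 0.5, panel_length: int | None = None
) -> tuple[str, bool]:
    """Extract the query residues aligned to the panel RT/RNaseH domain.

    Uses the best hit's frame only (after a frameshift the majority frame
    carries the domain); returns (aa sequence, partial flag).  Refused when
    the hit covers under min_panel_coverage of the panel domain.
    """
    plen = panel_length if panel_length is not None else best_hit.panel_range[1]
    if plen <= 0 or best_hit.covered_aa < min_panel_coverage * plen:
        raise ExtractionRefused(
            f"best hit covers {best_hit.covered_aa} aa of a {plen} aa domain "
            f"(< {min_panel_coverage:.0%})"
        )
    q0, q1 = best_hit.query_aa_range
    partial = best_hit.covered_aa < 0.9 * plen
    return best_hit.query_aa[q0:q1], partial


def filter_c_clade(
    hits_per_query: dict[str, list[DomainHit]],
    max_evalue: float = 1e-50,
    min_cover_aa: int = 300,
) -> set[str]:
    """Queries whose best panel hit is C-clade at E <= max_evalue with at
    least min_cover_aa panel residues covered."""
    retained: set[str] = set()
    for qid, hits in hits_per_query.items():
        if not hits:
            continue
        best = hits[0]
        if (
            best.clade == "C-clade"
            and best.evalue <= max_evalue
            and best.covered_aa >= min_cover_aa
        ):
            retained.add(qid)
    return retained


def panel_from_tuples(panel: list[tuple[str, str, str, str]]) -> list[PanelEntry]:
    """Adapter for simdata.make_domain_panel output."""
    return [PanelEntry(*t) for t in panel]
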