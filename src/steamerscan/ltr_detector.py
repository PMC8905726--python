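"""De novo structural detection of full-length LTR-retrotransposon candidates.

The detector looks for pairs of near-identical repeats (the two LTRs of an
intact element) whose lengths fall in [min_ltr_len, max_ltr_len] and whose
start positions are min_dist..max_dist apart.  It seeds on exact 13-mers
repeated within the distance window, clusters seeds by diagonal, extends the
outermost anchors with an ungapped X-drop scan, verifies the LTR pair with a
global alignment, and optionally snaps boundaries to the canonical TG...CA
retroviral termini.

Identity is matches / alignment columns with terminal gaps excluded and
internal gaps counted as mismatches.  min_dist/max_dist constrain the
distance between LTR *start* positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._seqs import global_identity, kmer_codes


class ParameterError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class DetectionParams:
    min_ltr_len: int = 80
    max_ltr_len: int = 1200
    min_dist: int = 2500
    max_dist: int = 11000
    min_similarity: float = 80.0
    seed_k: int = 13
    motif_refine: bool = True
    # canonical terminal motifs used by boundary refinement
    start_motif: str = "TGTAACA"
    end_motif: str = "TTAAACA"
    # implementation knobs (not structural constraints)
    xdrop: int = 15
    mismatch_penalty: int = -3
    diag_band: int = 30
    max_kmer_occ: int = 12
    snap_window: int = 10

    def validate(self) -> None:
        if self.min_ltr_len > self.max_ltr_len:
            raise ParameterError("min_ltr_len must be <= max_ltr_len")
        if self.min_dist > self.max_dist:
            raise ParameterError("min_dist must be <= max_dist")
        if not 0 < self.min_similarity <= 100:
            raise ParameterError("min_similarity must be in (0,100]")
        if self.seed_k < 4 or self.seed_k > 31:
            raise ParameterError("seed_k must be in [4,31]")


@dataclass(frozen=True)
class LTRCandidate:
    """A detected full-length element: [start, end) = [ltr5 start, ltr3 end)."""

    seq_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    strand: str = "unknown"
    note: str = ""

    @property
    def ltr5_len(self) -> int:
        return self.ltr5[1] - self.ltr5[0]

    @property
    def ltr3_len(self) -> int:
        return self.ltr3[1] - self.ltr3[0]

    def validate(self, params: DetectionParams) -> None:
        if self.ltr5[1] > self.ltr3[0]:
            raise CoordinateError("LTR spans overlap")
        for ln in (self.ltr5_len, self.ltr3_len):
            if not params.min_ltr_len <= ln <= params.max_ltr_len:
                raise CoordinateError(f"LTR length {ln} out of range")
        d = self.ltr3[0] - self.ltr5[0]
        if not params.min_dist <= d <= params.max_dist:
            raise CoordinateError(f"LTR start distance {d} out of range")
        if (self.start, self.end) != (self.ltr5[0], self.ltr3[1]):
            raise CoordinateError("element span must be [ltr5.start, ltr3.end)")


def _xdrop_steps(seq: str, i: int, j: int, step: int, params: DetectionParams) -> int:
    """Ungapped extension from (i, j) exclusive; returns steps to the argmax score."""
    n = len(seq)
    score = best = 0
    steps = best_steps = 0
    while True:
        i += step
        j += step
        if i < 0 or j < 0 or i >= n or j >= n:
            break
        steps += 1
        a, b = seq[i], seq[j]
        if a == b and a in "ACGTacgt":
            score += 1
        else:
            score += params.mismatch_penalty
        if score > best:
            best, best_steps = score, steps
        elif score < best - params.xdrop:
            break
    return best_steps


def _seed_pairs(seq: str, params: DetectionParams) -> list[tuple[int, int]]:
    """Positions (p1, p2) of exact k-mer matches with p2-p1 near the distance window."""
    k = params.seed_k
    pos, codes = kmer_codes(seq, k)
    if len(codes) == 0:
        return []
    order = np.argsort(codes, kind="stable")
    codes_s, pos_s = codes[order], pos[order]
    boundaries = np.nonzero(np.diff(codes_s))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(codes_s)]))
    lo = params.min_dist - params.diag_band
    hi = params.max_dist + params.max_ltr_len
    pairs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        m = e - s
        if m < 2 or m > params.max_kmer_occ:
            continue
        ps = np.sort(pos_s[s:e])
        for i in range(m - 1):
            for j in range(i + 1, m):
                d = int(ps[j] - ps[i])
                if lo <= d <= hi:
                    pairs.append((int(ps[i]), int(ps[j])))
    return pairs


def _cluster_pairs(
    pairs: list[tuple[int, int]], params: DetectionParams
) -> list[list[tuple[int, int]]]:
    """Group seed pairs into putative LTR pairs by diagonal and proximity."""
    pairs = sorted(pairs)
    clusters: list[list[tuple[int, int]]] = []
    for p1, p2 in pairs:
        d = p2 - p1
        placed = False
        for cl in reversed(clusters):
            lp1, lp2 = cl[-1]
            if p1 - lp1 > params.max_ltr_len:
                break
            if abs(d - (lp2 - lp1)) <= params.diag_band:
                cl.append((p1, p2))
                placed = True
                break
        if not placed:
            clusters.append([(p1, p2)])
    return clusters


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _strand_hint(ltr5_seq: str, start_motif: str = "TGTAACA") -> str:
    from ._seqs import revcomp

    if len(ltr5_seq) < len(start_motif):
        return "unknown"
    fwd = _hamming(ltr5_seq[: len(start_motif)].upper(), start_motif)
    rev = _hamming(revcomp(ltr5_seq)[: len(start_motif)].upper(), start_motif)
    if fwd <= 2 and fwd < rev:
        return "+"
    if rev <= 2 and rev < fwd:
        return "-"
    return "unknown"


def _candidate_from_cluster(
    seq_id: str, seq: str, cluster: list[tuple[int, int]], params: DetectionParams
) -> LTRCandidate | None:
    k = params.seed_k
    a1, a2 = min(cluster)
    b1, b2 = max(cluster, key=lambda p: p[0] + k)
    left = _xdrop_steps(seq, a1, a2, -1, params)
    right = _xdrop_steps(seq, b1 + k - 1, b2 + k - 1, +1, params)
    s1, s2 = a1 - left, a2 - left
    e1, e2 = b1 + k + right, b2 + k + right
    if e1 > s2:  # LTRs must not overlap
        return None
    len5, len3 = e1 - s1, e2 - s2
    if not (params.min_ltr_len <= len5 <= params.max_ltr_len):
        return None
    if not (params.min_ltr_len <= len3 <= params.max_ltr_len):
        return None
    if not (params.min_dist <= s2 - s1 <= params.max_dist):
        return None
    ident = global_identity(seq[s1:e1], seq[s2:e2])
    if ident < params.min_similarity:
        return None
    cand = LTRCandidate(
        seq_id=seq_id,
        start=s1,
        end=e2,
        ltr5=(s1, e1),
        ltr3=(s2, e2),
        ltr_identity=round(ident, 2),
        strand=_strand_hint(seq[s1:e1]),
    )
    if params.motif_refine:
        cand = refine_boundaries(cand, seq, params)
    return cand


def _snap(seq: str, pos: int, window: int, dinuc: str, anchor: str) -> int | None:
    """Nearest position where the start (anchor='start') or end (anchor='end')
    boundary at pos matches the dinucleotide; None when absent."""
    best = None
    for shift in sorted(range(-window, window + 1), key=lambda s: (abs(s), s)):
        p = pos + shift
        if anchor == "start":
            if 0 <= p and p + 2 <= len(seq) and seq[p : p + 2].upper() == dinuc:
                best = p
                break
        else:
            if 2 <= p <= len(seq) and seq[p - 2 : p].upper() == dinuc:
                best = p
                break
    return best


def _motif_snap(
    seq: str,
    pos_a: int,
    pos_b: int,
    window: int,
    motifs: list[str],
    anchor: str,
    max_total_mm: int = 4,
) -> tuple[int, int] | None:
    """Shift two paired boundaries by one common offset to the position that
    best matches the canonical terminal motif on BOTH LTR copies.

    The two LTRs sit on one diagonal, so their true termini share the shift;
    scoring the full 7-mer on both copies (total Hamming distance against the
    best of the given motifs, ties to the smaller shift) is what
    distinguishes the real terminus from chance dinucleotides inside the
    repeat.  Several motifs let both element orientations compete (a
    minus-strand element shows the reverse complement of the opposite
    terminus).  Returns None when no shift scores max_total_mm or better.
    """
    k = len(motifs[0])

    def window_at(pos: int) -> str:
        if anchor == "start":
            return seq[pos : pos + k].upper() if pos >= 0 else ""
        return seq[pos - k : pos].upper() if pos - k >= 0 else ""

    best: tuple[int, int] | None = None  # (score, shift)
    for shift in range(-window, window + 1):
        wins = [window_at(pos + shift) for pos in (pos_a, pos_b)]
        total = min(
            sum(_hamming(w, motif) if len(w) == k else k for w in wins)
            for motif in motifs
        )
        if best is None or (total, abs(shift)) < (best[0], abs(best[1])):
            best = (total, shift)
    if best is None or best[0] > max_total_mm:
        return None
    return pos_a + best[1], pos_b + best[1]


def refine_boundaries(
    candidate: LTRCandidate, seq: str, params: DetectionParams | None = None
) -> LTRCandidate:
    """Snap LTR boundaries to the canonical TG (start) / CA (end) termini.

    Start and end boundary pairs snap jointly first (same shift, motif
    required on both LTRs, window 1.5x snap_window); boundaries left
    unsnapped fall back to an independent nearest-dinucleotide search within
    +/- snap_window bp.  If the snapped LTR lengths leave
    [min_ltr_len, max_ltr_len] or any structural invariant breaks, the
    original candidate is returned with a note.
    """
    params = params or DetectionParams()
    w = params.snap_window
    joint_w = w + w // 2
    from ._seqs import revcomp

    start_motifs = [params.start_motif, revcomp(params.end_motif)]
    end_motifs = [params.end_motif, revcomp(params.start_motif)]
    starts = _motif_snap(seq, candidate.ltr5[0], candidate.ltr3[0], joint_w,
                         start_motifs, "start")
    ends = _motif_snap(seq, candidate.ltr5[1], candidate.ltr3[1], joint_w,
                       end_motifs, "end")
    if starts is not None:
        s1, s2 = starts
    else:
        s1 = _snap(seq, candidate.ltr5[0], w, "TG", "start")
        s2 = _snap(seq, candidate.ltr3[0], w, "TG", "start")
        s1 = candidate.ltr5[0] if s1 is None else s1
        s2 = candidate.ltr3[0] if s2 is None else s2
    if ends is not None:
        e1, e2 = ends
    else:
        e1 = _snap(seq, candidate.ltr5[1], w, "CA", "end")
        e2 = _snap(seq, candidate.ltr3[1], w, "CA", "end")
        e1 = candidate.ltr5[1] if e1 is None else e1
        e2 = candidate.ltr3[1] if e2 is None else e2
    if (s1, e1, s2, e2) == (*candidate.ltr5, *candidate.ltr3):
        return candidate
    len5, len3 = e1 - s1, e2 - s2
    ok = (
        params.min_ltr_len <= len5 <= params.max_ltr_len
        and params.min_ltr_len <= len3 <= params.max_ltr_len
        and params.min_dist <= s2 - s1 <= params.max_dist
        and e1 <= s2
    )
    if not ok:
        return replace(candidate, note="refinement rejected: invariant violation")
    ident = round(global_identity(seq[s1:e1], seq[s2:e2]), 2)
    if ident < params.min_similarity:
        return replace(candidate, note="refinement rejected: identity drop")
    return LTRCandidate(
        seq_id=candidate.seq_id,
        start=s1,
        end=e2,
        ltr5=(s1, e1),
        ltr3=(s2, e2),
        ltr_identity=ident,
        strand=_strand_hint(seq[s1:e1]),
        note="refined",
    )


def _resolve_overlaps(cands: list[LTRCandidate]) -> list[LTRCandidate]:
    """Among candidates sharing >50% of element span keep the best:
    highest ltr_identity, then longer element, then leftmost."""
    ranked = sorted(
        cands, key=lambda c: (-c.ltr_identity, -(c.end - c.start), c.start)
    )
    kept: list[LTRCandidate] = []
    for c in ranked:
        clen = c.end - c.start
        suppressed = False
        for k in kept:
            if k.seq_id != c.seq_id:
                continue
            ov = min(c.end, k.end) - max(c.start, k.start)
            if ov > 0 and ov > 0.5 * min(clen, k.end - k.start):
                suppressed = True
                break
        if not suppressed:
            kept.append(c)
    return kept


def find_ltr_pairs(
    genome: dict[str, str] | list[tuple[str, str]],
    params: DetectionParams | None = None,
) -> list[LTRCandidate]:
    """Detect full-length LTR-element candidates in one or more sequences.

    Returns candidates sorted by (seq_id, element start); every candidate
    satisfies the structural invariants of LTRCandidate.
    """
    params = params or DetectionParams()
    params.validate()
    items = genome.items() if isinstance(genome, dict) else genome
    out: list[LTRCandidate] = []
    for seq_id, seq in items:
        pairs = _seed_pairs(seq, params)
        if not pairs:
            continue
        cands = []
        for cluster in _cluster_pairs(pairs, params):
            c = _candidate_from_cluster(seq_id, seq, cluster, params)
            if c is not None:
                cands.append(c)
        out.extend(_resolve_overlaps(cands))
    out.sort(key=lambda c: (c.seq_id, c.start))
    return out


def extract_regions(
    candidate: LTRCandidate, genome: dict[str, str] | str
) -> tuple[str, str, str, str]:
    """(element, ltr5, ltr3, internal) sequences for a candidate.

    internal covers everything between the two LTRs, so
    ltr5 + internal + ltr3 == element.
    """
    seq = genome if isinstance(genome, str) else genome[candidate.seq_id]
    if candidate.start < 0 or candidate.end > len(seq):
        raise CoordinateError(
            f"candidate span [{candidate.start},{candidate.end}) outside sequence "
            f"of length {len(seq)}"
        )
    element = seq[candidate.start : candidate.end]
    ltr5 = seq[candidate.ltr5[0] : candidate.ltr5[1]]
    ltr3 = seq[candidate.ltr3[0] : candidate.ltr3[1]]
    internal = seq[candidate.ltr5[1] : candidate.ltr3[0]]
    return element, ltr5, ltr3, internal
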