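"""Structural characterization of elements against the Steamer blueprint.

Checks, per element: the canonical LTR termini (start motif TGTAACA; end
motif compared with both the bivalve majority consensus TTAAACA and the
reference variant ATAAACA), the 12-bp primer binding site immediately after
the 5' LTR (mismatches tolerated only on its last three bases), the
polypurine tract directly upstream of the 3' LTR, the integrity of the
single gag-pol ORF (intact / n frameshifts / corrupted / deleted), and
descriptive statistics across a subfamily.

The PPT has no canonical quantitative definition; the defaults (50 bp
window, run >= 10 bp, purine fraction >= 0.90) are explicit heuristics.
Frameshifts are counted as frame transitions in a chained set of co-linear
local alignments of a reference gag-pol protein across the six reading
frames — the way a single corrupted ORF reads through frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .clade_classifier import local_alignment, translate_six_frames

START_MOTIF = "TGTAACA"
END_MOTIF_CONSENSUS = "TTAAACA"
END_MOTIF_REFERENCE = "ATAAACA"
PBS_MOTIF = "TGGTGTCAGAAG"


class ParameterError(ValueError):
    pass


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a.upper(), b.upper()))


@dataclass(frozen=True)
class MotifReport:
    start_mismatches: int | None  # vs TGTAACA, None when LTR < 7 bp
    end_seq: str
    end_mm_consensus: int | None  # vs TTAAACA
    end_mm_reference: int | None  # vs ATAAACA
    skipped_reason: str = ""


@dataclass(frozen=True)
class PBSRecord:
    offset: int  # bp after the 5' LTR
    sequence: str
    mismatches_total: int
    mismatches_last3: int


@dataclass(frozen=True)
class PPTRecord:
    start: int  # element coordinates
    end: int
    length: int
    purine_fraction: float


@dataclass(frozen=True)
class OrfStatus:
    status: str  # INTACT / FRAMESHIFTED / CORRUPTED / DELETED
    n_frameshifts: int = 0
    coverage: float = 0.0

    def __str__(self) -> str:
        if self.status == "FRAMESHIFTED":
            return f"FRAMESHIFTED({self.n_frameshifts})"
        return self.status


@dataclass
class SteamerReport:
    element_id: str
    element_length: int
    ltr5_length: int
    ltr3_length: int
    ltr5_motifs: MotifReport | None = None
    ltr3_motifs: MotifReport | None = None
    pbs: PBSRecord | None = None
    ppt: PPTRecord | None = None
    orf: OrfStatus | None = None
    rt_rnaseh_identity: float | None = None
    rt_rnaseh_domain: str = ""


def check_ltr_motifs(ltr5: str, ltr3: str) -> tuple[MotifReport, MotifReport]:
    """Hamming mismatches of the first 7 bases vs TGTAACA and the last 7 vs
    TTAAACA / ATAAACA, for each LTR. LTRs under 7 bp are skipped."""
    reports = []
    for ltr in (ltr5, ltr3):
        if len(ltr) < 7:
            reports.append(
                MotifReport(None, "", None, None, skipped_reason=f"LTR of {len(ltr)} bp < 7")
            )
            continue
        end7 = ltr[-7:].upper()
        reports.append(
            MotifReport(
                start_mismatches=_hamming(ltr[:7], START_MOTIF),
                end_seq=end7,
                end_mm_consensus=_hamming(end7, END_MOTIF_CONSENSUS),
                end_mm_reference=_hamming(end7, END_MOTIF_REFERENCE),
            )
        )
    return reports[0], reports[1]


def find_pbs(
    element: str,
    ltr5_span: tuple[int, int],
    motif: str = PBS_MOTIF,
    max_mm_last3: int = 2,
    search_offset_window: int = 3,
    loose: bool = False,
) -> PBSRecord | None:
    """Locate the primer binding site just downstream of the 5' LTR.

    Scans offsets 0..window after the LTR for a 12-mer matching the motif
    exactly on positions 1-9 with at most max_mm_last3 mismatches on the last
    three positions (loose mode instead allows <= 2 mismatches anywhere).
    The nearest qualifying offset wins; absence is a valid result.
    """
    start = ltr5_span[1]
    k = len(motif)
    for offset in range(search_offset_window + 1):
        s = start + offset
        if s + k > len(element):
            break
        window = element[s : s + k].upper()
        mm_head = _hamming(window[:9], motif[:9])
        mm_tail = _hamming(window[9:], motif[9:])
        if loose:
            qualifies = mm_head + mm_tail <= 2
        else:
            qualifies = mm_head == 0 and mm_tail <= max_mm_last3
        if qualifies:
            return PBSRecord(
                offset=offset,
                sequence=window,
                mismatches_total=mm_head + mm_tail,
                mismatches_last3=mm_tail,
            )
    return None


def find_ppt(
    element: str,
    ltr3_span: tuple[int, int],
    window: int = 50,
    min_len: int = 10,
    min_purine: float = 0.90,
) -> PPTRecord | None:
    """Longest purine-rich run in the window immediately 5' of the 3' LTR.

    Qualifying runs have length >= min_len and A/G fraction >= min_purine;
    ties are broken toward the run closest to the LTR.
    """
    w_end = ltr3_span[0]
    w_start = max(0, w_end - window)
    region = element[w_start:w_end].upper()
    best: PPTRecord | None = None
    n = len(region)
    for i in range(n):
        for j in range(n, i + min_len - 1, -1):
            run = region[i:j]
            frac = sum(c in "AG" for c in run) / len(run)
            if frac >= min_purine:
                rec = PPTRecord(
                    start=w_start + i,
                    end=w_start + j,
                    length=j - i,
                    purine_fraction=round(frac, 3),
                )
                if (
                    best is None
                    or rec.length > best.length
                    or (rec.length == best.length and rec.end > best.end)
                ):
                    best = rec
                break  # longest run starting at i found
    return best


def _split_hsp(aln, query: str, target: str, xdrop: float = 30.0, min_score: float = 40.0):
    """Split one local alignment into high-scoring subsegments.

    A net-frame-restoring pair of frameshifts lets the aligner bridge the
    out-of-frame middle as a long mismatch stretch; X-drop segmentation cuts
    the alignment wherever the running score falls xdrop below its maximum,
    so each subsegment stays in genuinely homologous sequence.  Returns
    (t_start, t_end, score) tuples in target (reference) coordinates.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    qa, ta = aln.aligned
    cols: list[tuple[float, int]] = []  # (score, target_pos or -1 for gaps)
    prev_qe = prev_te = None
    for (qs, qe), (ts, te) in zip(qa, ta):
        if prev_qe is not None:
            gap = (qs - prev_qe) + (ts - prev_te)
            if gap:
                cols.append((-11.0 - max(0, gap - 1), ts))
        for i in range(qe - qs):
            q, t = query[qs + i], target[ts + i]
            try:
                s = float(blosum[q, t])
            except KeyError:
                s = -1.0
            cols.append((s, ts + i))
        prev_qe, prev_te = qe, te
    segments = []
    i = 0
    n = len(cols)
    while i < n:
        run = best = 0.0
        best_end = i
        start = i
        j = i
        while j < n:
            run += cols[j][0]
            if run > best:
                best, best_end = run, j
            if run < best - xdrop or run < -xdrop:
                break
            j += 1
        if best >= min_score:
            t0 = cols[start][1]
            t1 = cols[best_end][1] + 1
            if t1 > t0:
                segments.append((t0, t1, best))
        i = max(best_end + 1, start + 1) if best >= min_score else j + 1
    return segments


def _frame_segments(
    internal: str, reference: str, min_score: float = 40.0, max_hsps: int = 4
) -> list[tuple[int, int, int]]:
    """(frame, ref_start, ref_end) local-alignment segments of the reference
    protein against each reading frame; multiple HSPs per frame recovered by
    iterative masking, each HSP X-drop-split into in-register subsegments."""
    from .clade_classifier import _aligner, _clean

    segments: list[tuple[int, int, int]] = []
    frames = translate_six_frames(internal)
    ref_clean = _clean(reference)
    for frame, aa in enumerate(frames):
        q = _clean(aa)
        if not q:
            continue
        masked = list(ref_clean)
        for _ in range(max_hsps):
            target = "".join(masked)
            alns = _aligner().align(q, target)
            if len(alns) == 0 or alns.score < min_score:
                break
            aln = alns[0]
            for t0, t1, _score in _split_hsp(aln, q, target, min_score=min_score):
                segments.append((frame, t0, t1))
            ta = aln.aligned[1]
            for i in range(int(ta[0][0]), int(ta[-1][1])):
                masked[i] = "X"
    return segments


def _best_chain(
    segments: list[tuple[int, int, int]],
    strand_frames: range,
    transition_penalty: float = 25.0,
) -> tuple[int, int]:
    """Highest-scoring co-linear chain over reference coordinates for one
    strand, scored as covered residues minus a per-frame-transition penalty
    (which suppresses spurious short cross-frame segments).

    Returns (covered_ref_residues, n_frame_transitions).
    """
    segs = sorted((s for s in segments if s[0] in strand_frames), key=lambda s: (s[1], s[2]))
    if not segs:
        return 0, 0
    n = len(segs)
    # dp over chain ends; gain of appending i after j = uncovered part of i
    score = [0.0] * n
    cover = [0] * n
    trans = [0] * n
    prev = [-1] * n
    for i, (fi, t0i, t1i) in enumerate(segs):
        score[i] = float(t1i - t0i)
        cover[i] = t1i - t0i
        for j in range(i):
            fj, t0j, t1j = segs[j]
            eff_start = max(t0i, t1j)
            gain = t1i - eff_start
            if gain <= 0:
                continue
            pen = transition_penalty if fi != fj else 0.0
            cand = score[j] + gain - pen
            if cand > score[i]:
                score[i] = cand
                cover[i] = cover[j] + gain
                trans[i] = trans[j] + (1 if fi != fj else 0)
                prev[i] = j
    best = max(range(n), key=lambda i: score[i])
    return cover[best], trans[best]


def orf_status(
    internal: str,
    reference_protein: str | None = None,
    min_coverage: float = 0.80,
    min_internal_len: int = 300,
) -> OrfStatus:
    """Integrity of the single gag-pol ORF in the internal region.

    Reference-guided: chain co-linear local alignments of the reference
    protein across the six frames; INTACT when one frame's chain covers
    >= min_coverage of the reference, FRAMESHIFTED(n) when the best chain
    reaches that coverage through n frame transitions, CORRUPTED otherwise.
    Reference-free: INTACT iff a single stop-free ORF (ATG to stop/end)
    covers >= min_coverage of the internal region.
    """
    if len(internal) < min_internal_len:
        return OrfStatus("DELETED")
    if reference_protein is None:
        best = 0
        for aa in translate_six_frames(internal):
            start = aa.find("M")
            while start != -1:
                stop = aa.find("*", start)
                length = (stop if stop != -1 else len(aa)) - start
                best = max(best, 3 * length)
                start = aa.find("M", start + 1)
        cov = best / len(internal)
        return OrfStatus("INTACT" if cov >= min_coverage else "CORRUPTED", coverage=round(cov, 3))
    segments = _frame_segments(internal, reference_protein)
    if not segments:
        return OrfStatus("CORRUPTED", coverage=0.0)
    rlen = len(reference_protein)
    best_cov, best_tr = 0, 0
    for strand_frames in (range(0, 3), range(3, 6)):
        covered, transitions = _best_chain(segments, strand_frames)
        if covered > best_cov:
            best_cov, best_tr = covered, transitions
    cov = best_cov / rlen
    if cov < min_coverage:
        return OrfStatus("CORRUPTED", coverage=round(cov, 3))
    if best_tr == 0:
        return OrfStatus("INTACT", coverage=round(cov, 3))
    return OrfStatus("FRAMESHIFTED", n_frameshifts=best_tr, coverage=round(cov, 3))


@dataclass
class SubfamilySummary:
    n_elements: int
    ltr_length_min: int
    ltr_length_mean: float
    ltr_length_max: int
    element_length_min: int
    element_length_mean: float
    element_length_max: int
    orf_status_counts: dict[str, int] = field(default_factory=dict)
    rt_identity_min: float | None = None
    rt_identity_mean: float | None = None
    rt_identity_max: float | None = None


def subfamily_stats(reports: list[SteamerReport]) -> SubfamilySummary:
    """Descriptive statistics across a subfamily's elements: LTR and element
    length ranges, ORF status tally, and pairwise RT/RNaseH identity when at
    least two domains are available."""
    if not reports:
        raise ParameterError("subfamily_stats needs at least one report")
    ltr_lengths = [x for r in reports for x in (r.ltr5_length, r.ltr3_length) if x > 0]
    el_lengths = [r.element_length for r in reports]
    counts: dict[str, int] = {}
    for r in reports:
        if r.orf is not None:
            counts[str(r.orf)] = counts.get(str(r.orf), 0) + 1
    summary = SubfamilySummary(
        n_elements=len(reports),
        ltr_length_min=min(ltr_lengths),
        ltr_length_mean=round(sum(ltr_lengths) / len(ltr_lengths), 1),
        ltr_length_max=max(ltr_lengths),
        element_length_min=min(el_lengths),
        element_length_mean=round(sum(el_lengths) / len(el_lengths), 1),
        element_length_max=max(el_lengths),
        orf_status_counts=counts,
    )
    domains = [r.rt_rnaseh_domain for r in reports if r.rt_rnaseh_domain]
    if len(domains) >= 2:
        idents = []
        for i in range(len(domains)):
            for j in range(i + 1, len(domains)):
                res = local_alignment(domains[i], domains[j])
                idents.append(res[3] if res is not None else 0.0)
        summary.rt_identity_min = round(min(idents), 1)
        summary.rt_identity_mean = round(sum(idents) / len(idents), 1)
        summary.rt_identity_max = round(max(idents), 1)
    return summary
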