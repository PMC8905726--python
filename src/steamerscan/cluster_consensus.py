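"""Greedy identity clustering and insert-cleaned consensus building.

Detected elements are clustered at 80% identity with a uclust-like greedy
centroid scheme (inputs sorted by descending length, both strands tested,
identity = matches / shorter sequence length).  Each cluster is multiple
aligned around its centroid (center-star), alignment columns occupied in
fewer than 80% of the rows are trimmed ("insert cleaning"), and a majority
consensus is deduced.  The whole procedure is iterated — by default twice —
re-clustering the insert-cleaned members, which lets copies that were kept
apart by large insertions fall into one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seqs import cigar_ops, revcomp

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class Cluster:
    centroid_id: str
    members: list[str] = field(default_factory=list)  # ids, centroid first
    strands: dict[str, str] = field(default_factory=dict)  # id -> "+"/"-"
    identities: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    def membership(self) -> dict[str, str]:
        return {m: c.centroid_id for c in self.clusters for m in c.members}


@dataclass
class ConsensusRecord:
    cluster_id: str
    consensus: str
    n_members: int
    retained_columns: int
    trimmed_columns: int


def pair_identity_both_strands(a: str, b: str) -> tuple[float, str]:
    """Identity (matches / shorter length, percent) on the best strand."""
    best, strand = 0.0, "+"
    for st, bb in (("+", b), ("-", revcomp(b))):
        res = edlib.align(a.upper(), bb.upper(), mode="NW", task="path")
        matches = sum(n for n, op in cigar_ops(res["cigar"]) if op == "=")
        ident = 100.0 * matches / min(len(a), len(b))
        if ident > best:
            best, strand = ident, st
    return best, strand


def cluster_sequences(
    seqs: dict[str, str] | list[tuple[str, str]],
    identity_threshold: float = 0.80,
    strands: str = "both",
) -> ClusterSet:
    """Greedy centroid clustering, longest-first.

    Each sequence joins the first existing centroid it matches at
    >= identity_threshold (fraction), testing both strands when
    strands="both"; otherwise it founds a new cluster.  Length ties are
    broken lexicographically by id so the partition is order-insensitive.
    """
    items = list(seqs.items() if isinstance(seqs, dict) else seqs)
    if not 0 < identity_threshold <= 1:
        raise ParameterError("identity_threshold must be in (0,1]")
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    by_id = dict(items)
    cs = ClusterSet()
    for sid, seq in items:
        placed = False
        for cl in cs.clusters:
            cseq = by_id[cl.centroid_id]
            if strands == "both":
                ident, strand = pair_identity_both_strands(cseq, seq)
            else:
                res = edlib.align(cseq.upper(), seq.upper(), mode="NW", task="path")
                matches = sum(n for n, op in cigar_ops(res["cigar"]) if op == "=")
                ident, strand = 100.0 * matches / min(len(cseq), len(seq)), "+"
            if ident >= 100.0 * identity_threshold:
                cl.members.append(sid)
                cl.strands[sid] = strand
                cl.identities[sid] = round(ident, 2)
                placed = True
                break
        if not placed:
            cl = Cluster(centroid_id=sid, members=[sid])
            cl.strands[sid] = "+"
            cl.identities[sid] = 100.0
            cs.clusters.append(cl)
    return cs


def _best_split(short: str, long: str) -> int:
    """Split point h of the shorter region sequence that best matches the
    prefix/suffix of the longer one (gap placed between)."""
    q, c = len(short), len(long)
    pre = [0] * (q + 1)
    for i in range(q):
        pre[i + 1] = pre[i] + (short[i] != long[i])
    suf = [0] * (q + 1)
    for i in range(q):
        suf[i + 1] = suf[i] + (short[q - 1 - i] != long[c - 1 - i])
    return min(range(q + 1), key=lambda h: pre[h] + suf[q - h])


def _normalize_gaps(
    ops: list[tuple[int, str]], mseq: str, cseq: str, min_anchor: int = 20
) -> list[tuple[int, str]]:
    """Consolidate gap-dense alignment regions into single indel blocks.

    Unit-cost alignment fragments a long indel by grabbing chance matches
    inside the inserted sequence.  Any stretch of the path whose aligned runs
    between gaps are shorter than min_anchor is re-rendered as one contiguous
    gap flanked by 1:1-aligned blocks, with the split point chosen to
    minimize mismatches against the region ends — so every member places the
    gap at the same (true) insertion boundary.  Match/mismatch distinction is
    dropped: occupancy trimming and majority consensus never need it.
    """
    merged: list[list] = []
    for n, op in ops:
        op = "M" if op in ("=", "X") else op
        if merged and merged[-1][1] == op:
            merged[-1][0] += n
        else:
            merged.append([n, op])
    out: list[list] = []

    def emit(n: int, op: str) -> None:
        if n <= 0:
            return
        if out and out[-1][1] == op:
            out[-1][0] += n
        else:
            out.append([n, op])

    i = 0
    mpos = cpos = 0
    while i < len(merged):
        n, op = merged[i]
        if op == "M":
            emit(n, "M")
            mpos += n
            cpos += n
            i += 1
            continue
        q = c = 0  # member / centroid bases consumed by the region
        j = i
        while j < len(merged):
            nj, oj = merged[j]
            if oj == "M" and nj >= min_anchor:
                break
            if oj == "M":
                q += nj
                c += nj
            elif oj == "I":
                q += nj
            else:
                c += nj
            j += 1
        if q == c:
            emit(q, "M")
        elif q < c:  # net deletion in member
            h = _best_split(mseq[mpos : mpos + q], cseq[cpos : cpos + c]) if q else 0
            emit(h, "M")
            emit(c - q, "D")
            emit(q - h, "M")
        else:  # net insertion in member
            h = _best_split(cseq[cpos : cpos + c], mseq[mpos : mpos + q]) if c else 0
            emit(h, "M")
            emit(q - c, "I")
            emit(c - h, "M")
        mpos += q
        cpos += c
        i = j
    return [(n, op) for n, op in out]


def align_cluster(members: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Center-star multiple alignment around the first (centroid) member.

    members: (id, sequence) with minus-strand members already
    reverse-complemented.  Returns (id, aligned row) with equal row lengths;
    ungapping any row restores the member exactly.
    """
    if not members:
        raise ParameterError("align_cluster needs at least one member")
    if len(members) == 1:
        return [members[0]]
    cid, cseq = members[0]
    L = len(cseq)
    # pairwise alignments member vs centroid
    parsed = []  # per member: (gap mask over centroid pos, insertions {cpos: str})
    for mid, mseq in members[1:]:
        res = edlib.align(mseq.upper(), cseq.upper(), mode="NW", task="path")
        ops = _normalize_gaps(cigar_ops(res["cigar"]), mseq.upper(), cseq.upper())
        cpos = mpos = 0
        gap = np.zeros(L, dtype=bool)
        insertions: dict[int, str] = {}
        for n, op in ops:
            if op in ("=", "X", "M"):
                cpos += n
                mpos += n
            elif op == "I":  # extra residues in the member
                insertions[cpos] = insertions.get(cpos, "") + mseq[mpos : mpos + n]
                mpos += n
            else:  # "D": member lacks these centroid positions
                gap[cpos : cpos + n] = True
                cpos += n
        parsed.append((mid, mseq, gap, insertions))
    ins_len = np.zeros(L + 1, dtype=int)
    for _, _, _, insertions in parsed:
        for p, s in insertions.items():
            ins_len[p] = max(ins_len[p], len(s))

    def render(mseq: str, gap: np.ndarray | None, insertions: dict[int, str]) -> str:
        out = []
        mpos = 0
        for p in range(L + 1):
            block = insertions.get(p, "")
            out.append(block + "-" * (ins_len[p] - len(block)))
            mpos += len(block)
            if p < L:
                if gap is not None and gap[p]:
                    out.append("-")
                else:
                    out.append(mseq[mpos])
                    mpos += 1
        return "".join(out)

    rows = [(cid, render(cseq, None, {}))]
    for mid, mseq, gap, insertions in parsed:
        rows.append((mid, render(mseq, gap, insertions)))
    width = len(rows[0][1])
    assert all(len(r) == width for _, r in rows)
    return rows


def trim_nonconserved(
    alignment: list[tuple[str, str]],
    occupancy_threshold: float = 0.80,
    mode: str = "occupancy",
) -> tuple[list[tuple[str, str]], list[int]]:
    """Remove alignment columns not conserved in at least the given fraction
    of rows.

    mode="occupancy" (default): a column is retained iff non-gap residues
    occupy >= threshold of rows — this deletes insertions carried by a
    minority of copies.  mode="identity": retained iff the modal non-gap
    residue occurs in >= threshold of rows.
    """
    if not 0 < occupancy_threshold <= 1:
        raise ParameterError("occupancy_threshold must be in (0,1]")
    if mode not in ("occupancy", "identity"):
        raise ParameterError(f"unknown trim mode {mode!r}")
    if not alignment:
        return [], []
    ids = [i for i, _ in alignment]
    mat = np.array([list(r) for _, r in alignment])
    nrows = mat.shape[0]
    nongap = mat != "-"
    if mode == "occupancy":
        keep = nongap.sum(axis=0) >= occupancy_threshold * nrows
    else:
        keep = np.zeros(mat.shape[1], dtype=bool)
        for j in range(mat.shape[1]):
            col = mat[nongap[:, j], j]
            if col.size:
                _, counts = np.unique(col, return_counts=True)
                keep[j] = counts.max() >= occupancy_threshold * nrows
    trimmed_cols = [int(j) for j in np.nonzero(~keep)[0]]
    rows = ["".join(r) for r in mat[:, keep]]
    return list(zip(ids, rows)), trimmed_cols


def build_consensus(
    trimmed: list[tuple[str, str]], cluster_id: str = "cluster", n_trimmed: int = 0
) -> ConsensusRecord:
    """Majority (modal non-gap residue) consensus of a trimmed alignment.

    Ties are broken alphabetically (A < C < G < T) with a logged warning.
    """
    if not trimmed:
        raise ParameterError("build_consensus needs a non-empty alignment")
    mat = np.array([list(r) for _, r in trimmed])
    out = []
    ties = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[col != "-"]
        if col.size == 0:
            continue  # cannot occur after occupancy trimming with threshold >.5
        residues, counts = np.unique(col, return_counts=True)
        top = counts.max()
        winners = sorted(residues[counts == top])
        if len(winners) > 1:
            ties += 1
        out.append(winners[0])
    if ties:
        logger.warning("%s: %d consensus columns tied; broke alphabetically", cluster_id, ties)
    cons = "".join(out)
    return ConsensusRecord(
        cluster_id=cluster_id,
        consensus=cons,
        n_members=len(trimmed),
        retained_columns=len(cons),
        trimmed_columns=n_trimmed,
    )


def iterate_cluster_consensus(
    seqs: dict[str, str] | list[tuple[str, str]],
    rounds: int = 2,
    identity_threshold: float = 0.80,
    occupancy_threshold: float = 0.80,
    trim_mode: str = "occupancy",
) -> tuple[ClusterSet, list[ConsensusRecord]]:
    """Cluster -> align -> insert-clean, iterated (default twice), then
    build one majority consensus per final cluster."""
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    current = dict(seqs.items() if isinstance(seqs, dict) else seqs)
    if not current:
        return ClusterSet(), []
    cs = ClusterSet()
    trimmed_per_cluster: dict[str, tuple[list[tuple[str, str]], int]] = {}
    for rnd in range(rounds):
        cs = cluster_sequences(current, identity_threshold)
        logger.info("round %d: %d clusters over %d sequences", rnd + 1, len(cs.clusters), len(current))
        nxt: dict[str, str] = {}
        trimmed_per_cluster = {}
        for cl in cs.clusters:
            members = []
            for mid in cl.members:
                s = current[mid]
                members.append((mid, revcomp(s) if cl.strands.get(mid) == "-" else s))
            aln = align_cluster(members)
            trimmed, cols = trim_nonconserved(aln, occupancy_threshold, trim_mode)
            trimmed_per_cluster[cl.centroid_id] = (trimmed, len(cols))
            for mid, row in trimmed:
                nxt[mid] = row.replace("-", "")
        current = nxt
    consensi = [
        build_consensus(trimmed, cluster_id=cid, n_trimmed=ntrim)
        for cid, (trimmed, ntrim) in trimmed_per_cluster.items()
    ]
    return cs, consensi
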