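"""Synthetic genomes with planted LTR-retrotransposons and ground truth.

The generator emulates the structure of a canonical Steamer-like element:
two identical long terminal repeats (LTRs, 80-1200 bp) whose first seven
bases are TGTAACA and whose last seven are TTAAACA, a 12-bp primer binding
site (PBS) immediately after the 5' LTR, an internal region dominated by a
single stop-free gag-pol ORF, and a polypurine tract (PPT) immediately
before the 3' LTR.  Copies can be diverged (substitutions, indels, planted
frameshifts), truncated, or reverse-complemented, and every insertion is
recorded in a truth table with final-genome coordinates.

All randomness flows through explicit per-call seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seqs import AA_ALPHABET, random_dna, revcomp

# codons by amino acid, standard code (stops excluded)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_ALL_SENSE_CODONS = [c for cs in _CODONS.values() for c in cs]

SUPERFAMILIES = ("Gypsy", "Copia", "BEL/Pao")


class ParameterError(ValueError):
    """A generator parameter violates its documented invariant."""


class PlanError(ValueError):
    """An insertion plan is internally inconsistent (e.g. overlapping sites)."""


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint of a canonical full-length element.

    ``internal_length`` covers everything between the PBS and the 3' LTR
    (ORF + filler + PPT), so the total element length is
    ``2*ltr_length + 12 + internal_length``.

    If ``orf_protein`` is given, the ORF encodes that protein (reverse
    translated with random synonymous codons); otherwise random sense codons
    are sampled.  Either way the ORF starts with ATG and is stop-free in
    frame 0 over ``orf_fraction`` of the internal region.
    """

    ltr_length: int = 177
    ltr_start_motif: str = "TGTAACA"
    ltr_end_motif: str = "TTAAACA"
    internal_length: int = 4602
    pbs_motif: str = "TGGTGTCAGAAG"
    ppt_length: int = 14
    orf_fraction: float = 0.95
    orf_protein: str | None = None
    superfamily_label: str = "Gypsy"
    seed: int = 0

    def validate(self) -> None:
        if not 80 <= self.ltr_length <= 1200:
            raise ParameterError(f"ltr_length must be in [80,1200], got {self.ltr_length}")
        if len(self.pbs_motif) != 12:
            raise ParameterError(f"pbs_motif must be 12 bp, got {len(self.pbs_motif)}")
        if not 0 <= self.orf_fraction <= 1:
            raise ParameterError(f"orf_fraction must be in [0,1], got {self.orf_fraction}")
        if self.superfamily_label not in SUPERFAMILIES:
            raise ParameterError(f"superfamily_label must be one of {SUPERFAMILIES}")
        if self.internal_length < self.ppt_length:
            raise ParameterError("internal_length must accommodate the PPT")
        if len(self.ltr_start_motif) + len(self.ltr_end_motif) > self.ltr_length:
            raise ParameterError("LTR motifs longer than ltr_length")

    @property
    def element_length(self) -> int:
        return 2 * self.ltr_length + len(self.pbs_motif) + self.internal_length


@dataclass(frozen=True)
class MutationParams:
    """Divergence model applied to one copy of a canonical element."""

    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    max_indel_len: int = 10
    n_frameshifts: int = 0
    truncate_5prime: int = 0
    truncate_3prime: int = 0
    revcomp: bool = False
    seed: int = 0

    def validate(self, element_length: int | None = None) -> None:
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if self.n_frameshifts < 0:
            raise ParameterError("n_frameshifts must be >= 0")
        if self.truncate_5prime < 0 or self.truncate_3prime < 0:
            raise ParameterError("truncations must be >= 0")
        if element_length is not None and (
            self.truncate_5prime + self.truncate_3prime >= element_length
        ):
            raise ParameterError("truncations must leave a non-empty element")


@dataclass
class EditLog:
    """Record of the edits applied to one copy."""

    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    indels: list[tuple[int, int, bool]] = field(default_factory=list)  # (pos, len, is_insertion)
    frameshifts: list[tuple[int, int, bool]] = field(default_factory=list)
    truncated_5prime: int = 0
    truncated_3prime: int = 0
    revcomp: bool = False

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_indels(self) -> int:
        return len(self.indels) + len(self.frameshifts)

    @property
    def n_frameshifts(self) -> int:
        return len(self.frameshifts)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted insertion, in final genome coordinates."""

    seq_id: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    subfamily: str
    strand: str
    n_substitutions: int
    n_indels: int
    n_frameshifts: int
    is_full_size: bool

    def as_tsv_row(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.seq_id, self.start, self.end, self.ltr5_start, self.ltr5_end,
                self.ltr3_start, self.ltr3_end, self.subfamily, self.strand,
                self.n_substitutions, self.n_indels, self.n_frameshifts,
                int(self.is_full_size),
            )
        )


TRUTH_TSV_HEADER = (
    "seq_id\tstart\tend\tltr5_start\tltr5_end\tltr3_start\tltr3_end\t"
    "subfamily\tstrand\tn_substitutions\tn_indels\tn_frameshifts\tis_full_size"
)


def _encode_protein(protein: str, rng: np.random.Generator) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS.get(aa)
        if codons is None:
            raise ParameterError(f"orf_protein contains non-standard residue {aa!r}")
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


def make_canonical_element(spec: ElementSpec) -> tuple[str, dict[str, tuple[int, int]]]:
    """Build the canonical (undiverged) element for a spec.

    Returns the sequence and a feature map of 0-based half-open spans within
    the element: ltr5, pbs, orf (absent when orf_fraction == 0), ppt, ltr3.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    mid = spec.ltr_length - len(spec.ltr_start_motif) - len(spec.ltr_end_motif)
    ltr = spec.ltr_start_motif + random_dna(mid, rng) + spec.ltr_end_motif

    orf_len = int(spec.orf_fraction * spec.internal_length) // 3 * 3
    if spec.orf_protein is not None:
        orf = "ATG" + _encode_protein(spec.orf_protein, rng)
        orf_len = len(orf)
        if orf_len > spec.internal_length - spec.ppt_length:
            raise ParameterError("orf_protein too long for internal_length")
    elif orf_len >= 3:
        n_codons = orf_len // 3 - 1
        codons = [_ALL_SENSE_CODONS[i] for i in rng.integers(0, len(_ALL_SENSE_CODONS), n_codons)]
        orf = "ATG" + "".join(codons)
    else:
        orf = ""
        orf_len = 0
    if orf_len > spec.internal_length - spec.ppt_length:
        orf = orf[: (spec.internal_length - spec.ppt_length) // 3 * 3]
        orf_len = len(orf)

    filler_len = spec.internal_length - orf_len - spec.ppt_length
    filler = random_dna(filler_len, rng)
    purines = np.array(["A", "G"])
    ppt = "".join(purines[rng.integers(0, 2, spec.ppt_length)])

    seq = ltr + spec.pbs_motif + orf + filler + ppt + ltr
    L, P = spec.ltr_length, len(spec.pbs_motif)
    features: dict[str, tuple[int, int]] = {
        "ltr5": (0, L),
        "pbs": (L, L + P),
        "ppt": (L + P + spec.internal_length - spec.ppt_length, L + P + spec.internal_length),
        "ltr3": (L + P + spec.internal_length, len(seq)),
    }
    if orf_len > 0:
        features["orf"] = (L + P, L + P + orf_len)
    assert len(seq) == spec.element_length
    return seq, features


def _shift_span(
    span: tuple[int, int], pos: int, length: int, is_insertion: bool
) -> tuple[int, int]:
    """Remap a half-open span through one indel applied at pos."""
    s, e = span
    if is_insertion:
        if pos <= s:
            return s + length, e + length
        if pos < e:
            return s, e + length
        return s, e
    # deletion of [pos, pos+length): x -> x if x <= pos else max(pos, x-length)
    remap = lambda x: x if x <= pos else max(pos, x - length)  # noqa: E731
    return remap(s), remap(e)


def mutate_copy(
    canonical: str,
    features: dict[str, tuple[int, int]],
    params: MutationParams,
) -> tuple[str, EditLog, dict[str, tuple[int, int]]]:
    """Apply substitutions, indels, planted frameshifts and truncations.

    Random indels that land inside the ORF are forced to codon-multiple
    lengths so that exactly ``n_frameshifts`` frame-breaking indels (of
    length 1 or 2, planted explicitly) fall in the ORF span.  Returns the
    mutated sequence, the edit log, and the feature map remapped into the
    mutated copy's coordinates (features lost to truncation are dropped).
    """
    if not canonical:
        raise ParameterError("canonical sequence must be non-empty")
    params.validate(len(canonical))
    if params.n_frameshifts > 0 and "orf" not in features:
        raise ParameterError("frameshifts requested but feature map has no ORF")
    rng = np.random.default_rng(params.seed)
    log = EditLog()

    seq = list(canonical)
    n = len(seq)

    # substitutions
    subs_mask = rng.random(n) < params.substitution_rate
    for pos in np.nonzero(subs_mask)[0]:
        old = seq[pos]
        alt = "ACGT".replace(old.upper(), "") or "ACGT"
        new = alt[rng.integers(0, len(alt))]
        seq[pos] = new
        log.substitutions.append((int(pos), old, new))

    # indels: collect edit positions first, then apply right-to-left so that
    # recorded positions refer to the substituted-but-not-yet-indelled copy
    orf_span = features.get("orf", (0, 0))
    indel_events: list[tuple[int, int, bool, bool]] = []  # pos, len, ins, frameshift
    if params.indel_rate > 0:
        indel_mask = rng.random(n) < params.indel_rate
        for pos in np.nonzero(indel_mask)[0]:
            length = int(rng.integers(1, params.max_indel_len + 1))
            if orf_span[0] <= pos < orf_span[1]:
                length = max(3, length // 3 * 3)  # keep frame inside the ORF
            indel_events.append((int(pos), length, bool(rng.integers(0, 2)), False))
    if params.n_frameshifts:
        s, e = orf_span
        # Frameshifts are planted at jittered quantiles of the ORF so that the
        # coding segments they delimit are each long enough to be individually
        # recognizable (a pair of shifts a few codons apart is indistinguishable
        # from a short indel by any reading-frame analysis).
        margin = max(1, (e - s) // 20)
        lo, hi = s + margin, e - margin
        nf = params.n_frameshifts
        span = hi - lo
        positions = []
        for i in range(nf):
            q = (i + 1) / (nf + 1)
            jitter = rng.integers(-span // (4 * (nf + 1)), span // (4 * (nf + 1)) + 1)
            positions.append(int(lo + q * span + jitter))
        for pos in sorted(positions):
            length = int(rng.integers(1, 3))  # 1 or 2 bp breaks the frame
            indel_events.append((int(pos), length, bool(rng.integers(0, 2)), True))

    feat = dict(features)
    for pos, length, is_ins, is_fs in sorted(indel_events, reverse=True):
        if is_ins:
            ins = random_dna(length, rng)
            seq[pos:pos] = list(ins)
        else:
            del seq[pos : pos + length]
        record = (pos, length, is_ins)
        (log.frameshifts if is_fs else log.indels).append(record)
        feat = {k: _shift_span(v, pos, length, is_ins) for k, v in feat.items()}
    log.indels.reverse()
    log.frameshifts.reverse()

    out = "".join(seq)

    # truncations
    t5, t3 = params.truncate_5prime, params.truncate_3prime
    if t5 + t3 >= len(out):
        raise ParameterError("truncations exceed mutated copy length")
    if t5 or t3:
        out = out[t5 : len(out) - t3]
        log.truncated_5prime, log.truncated_3prime = t5, t3
        new_feat = {}
        for k, (s, e) in feat.items():
            s2, e2 = max(0, s - t5), min(len(out), e - t5)
            if e2 > s2:
                new_feat[k] = (s2, e2)
        feat = new_feat

    if params.revcomp:
        out = revcomp(out)
        log.revcomp = True
        m = len(out)
        feat = {k: (m - e, m - s) for k, (s, e) in feat.items()}

    return out, log, feat


@dataclass(frozen=True)
class Insertion:
    """One planned insertion: a spec (or prebuilt copy) at a background offset."""

    spec: ElementSpec
    position: int
    mutation: MutationParams = MutationParams()
    subfamily: str = "sub1"


def plant_genome(
    background_length: int,
    gc: float,
    plan: list[Insertion],
    seq_id: str = "chr1",
    seed: int = 0,
) -> tuple[str, list[TruthRecord]]:
    """Insert planned element copies into an i.i.d. random background.

    Positions are offsets into the background; the planned footprints
    ``[position, position + element_length)`` must not overlap, which
    guarantees that in the final genome consecutive elements are separated
    by untouched background.  Truth records use final-genome coordinates.
    """
    rng = np.random.default_rng(seed)
    background = random_dna(background_length, rng)

    ordered = sorted(plan, key=lambda ins: ins.position)
    for a, b in zip(ordered, ordered[1:]):
        if a.position + a.spec.element_length > b.position:
            raise PlanError(
                f"overlapping insertions at positions {a.position} and {b.position}"
            )
    if ordered and (
        ordered[0].position < 0
        or ordered[-1].position + ordered[-1].spec.element_length > background_length
    ):
        raise PlanError("insertion footprint outside background bounds")

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    cursor = 0  # background coordinate
    offset = 0  # cumulative inserted length
    for ins in ordered:
        canonical, features = make_canonical_element(ins.spec)
        copy, log, feat = mutate_copy(canonical, features, ins.mutation)
        pieces.append(background[cursor : ins.position])
        start = ins.position + offset
        end = start + len(copy)
        ltr5 = feat.get("ltr5")
        ltr3 = feat.get("ltr3")
        if log.revcomp:  # on the forward axis the 3' LTR comes first
            ltr5, ltr3 = ltr3, ltr5
        full = (
            ltr5 is not None
            and ltr3 is not None
            and ltr5[1] - ltr5[0] >= 80
            and ltr3[1] - ltr3[0] >= 80
        )
        truth.append(
            TruthRecord(
                seq_id=seq_id,
                start=start,
                end=end,
                ltr5_start=start + (ltr5[0] if ltr5 else 0),
                ltr5_end=start + (ltr5[1] if ltr5 else 0),
                ltr3_start=start + (ltr3[0] if ltr3 else len(copy)),
                ltr3_end=start + (ltr3[1] if ltr3 else len(copy)),
                subfamily=ins.subfamily,
                strand="-" if log.revcomp else "+",
                n_substitutions=log.n_substitutions,
                n_indels=log.n_indels,
                n_frameshifts=log.n_frameshifts,
                is_full_size=full,
            )
        )
        pieces.append(copy)
        cursor = ins.position
        offset += len(copy)
    pieces.append(background[cursor:])
    genome = "".join(pieces)
    assert len(genome) == background_length + offset
    return genome, truth


def make_domain_panel(
    n_per_superfamily: int,
    domain_length_aa: int = 400,
    divergence_within: float = 0.1,
    divergence_between: float = 0.6,
    gypsy_clades: tuple[str, ...] = ("C-clade", "A-clade", "B-clade"),
    seed: int = 0,
) -> list[tuple[str, str, str, str]]:
    """Labeled RT/RNaseH protein panel: (id, superfamily, clade, sequence).

    Each superfamily descends from an independent random ancestor; Gypsy
    members are split across clade sub-labels (C-clade first) whose ancestors
    sit divergence_within/2 from the Gypsy ancestor.  Guarantees mean
    within-label identity above mean between-label identity whenever
    divergence_within < divergence_between.
    """
    if n_per_superfamily < 2:
        raise ParameterError("n_per_superfamily must be >= 2")
    if not divergence_within < divergence_between:
        raise ParameterError("divergence_within must be < divergence_between")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))

    def mutate(protein: str, rate: float) -> str:
        arr = np.array(list(protein))
        mask = rng.random(len(arr)) < rate
        arr[mask] = aa[rng.integers(0, 20, mask.sum())]
        return "".join(arr)

    panel: list[tuple[str, str, str, str]] = []
    for label in SUPERFAMILIES:
        ancestor = "".join(aa[rng.integers(0, 20, domain_length_aa)])
        if label == "Gypsy":
            n_clades = min(len(gypsy_clades), n_per_superfamily)
            clade_anc = {
                c: mutate(ancestor, divergence_within / 2) for c in gypsy_clades[:n_clades]
            }
            for i in range(n_per_superfamily):
                clade = gypsy_clades[i % n_clades]
                panel.append(
                    (
                        f"Gypsy_{clade.split('-')[0]}_{i}",
                        label,
                        clade,
                        mutate(clade_anc[clade], divergence_within / 2),
                    )
                )
        else:
            tag = label.replace("/", "")
            for i in range(n_per_superfamily):
                panel.append(
                    (f"{tag}_{i}", label, "-", mutate(ancestor, divergence_within))
                )
    return panel


def default_steamer_spec(**overrides) -> ElementSpec:
    """The reference-like element: 177 bp LTRs, 4602 bp internal, 4968 bp total."""
    return replace(ElementSpec(), **overrides)
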