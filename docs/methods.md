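# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of `steamerscan`, what the synthetic-data generator does
and does not emulate, and the design decisions taken where more than one
reasonable convention exists.

## Coordinates and identity conventions

All spans are 0-based half-open internally; GFF3 output converts to 1-based
inclusive, BED stays 0-based. Two distinct identity definitions are used
deliberately:

* **LTR-pair and hit identity** = matches / alignment columns, terminal gap
  runs excluded, internal gaps counted as mismatch columns. This is the
  quantity the 80%-similarity detection threshold applies to.
* **Clustering identity** = matches / length of the shorter sequence, the
  convention of greedy centroid clusterers, so a fragment nearly contained
  in a longer copy clusters with it.

Both are computed from edlib global (Needleman–Wunsch, unit-cost)
alignments; the extended CIGAR distinguishes matches from mismatches.

## Synthetic data (`simdata`)

The generator produces the structure the pipeline assumes: an element is
`LTR + PBS(12 bp) + internal + LTR` with identical LTRs, the LTR starting
`TGTAACA` and ending `TTAAACA`, a single stop-free ORF (forced `ATG` start,
codons sampled excluding TAA/TAG/TGA in frame 0, or a reverse-translated
protein when one is supplied) covering `orf_fraction` (default 0.95) of the
internal region, and a pure-purine PPT (default 14 bp) abutting the 3′ LTR.
The default spec reproduces the reference element's dimensions: 177 bp LTRs
and a 4,968 bp total length.

Divergence is modeled as i.i.d. per-base substitutions and indels plus
explicit events: truncations, reverse complementation, and planted
frameshifts (indels of length 1–2 inside the ORF). Random indels that land
inside the ORF are forced to codon-multiple lengths so the edit log's
frameshift count is exactly the number requested. Planted frameshifts are
placed at jittered quantiles of the ORF rather than uniformly: a pair of
shifts a few codons apart is indistinguishable from a short in-frame indel
by any reading-frame analysis, so the generator defines frameshifts as
events delimiting individually recognizable coding segments. Copy
divergence defaults in the evaluation scenarios use 2–3% substitutions
("recent" copies, LTR-pair divergence about twice the per-copy rate and so
≤ 5%); this is a modeling choice — no divergence distribution for real
copies is assumed.

Backgrounds are i.i.d. nucleotides at a given GC (default 0.4, a typical
invertebrate value). Planted footprints may not overlap, which guarantees
each copy is flanked by untouched background; truth tables are emitted in
final-genome coordinates and round-trip exactly (slicing the genome at a
truth span returns the planted copy byte-for-byte).

The protein panel gives each superfamily an independent random ancestor
(pairwise identity between superfamilies ≈ background, ~6%), with Gypsy
members split across clade sub-labels whose ancestors sit at half the
within-divergence from the Gypsy ancestor. Default domain length is 400 aa,
within-label divergence 0.1, between-label 0.6.

**What the simulator does not emulate:** nested insertions, satellite or
low-complexity background, empirical base composition, target-site
duplications, and realistic codon usage. Passing tests therefore demonstrate
the correctness of the algorithms under the stated statistical structure,
not performance on real assemblies, where segmental duplications and
tandem repeats can produce additional LTR-pair-like signals.

## Structural detection (`ltr_detector`)

Defaults follow the standard structural-search parameterization: LTR length
80–1200 bp, LTR-start distance 2,500–11,000 bp, pair similarity ≥ 80%,
13-mer seeds. The distance bounds constrain LTR *start* positions.

Algorithm: exact 13-mer occurrences repeated within the distance window are
paired (k-mers containing N are skipped; k-mers occurring more than 12 times
are ignored as low-complexity), pairs are clustered by diagonal (±30) and
proximity, and the outermost anchors of each cluster are extended with an
ungapped X-drop scan (match +1, mismatch −3, drop 15; N never matches). The
resulting LTR pair is validated against all structural constraints and its
identity computed by global alignment.

Boundary refinement snaps the two start boundaries jointly (one shared
shift, since the LTR copies lie on one diagonal) to the position minimizing
the total Hamming distance of both 7-mers to the canonical start motif, and
likewise the two end boundaries to the end motif; both element orientations
compete (a minus-strand element shows the reverse complement of the opposite
terminus). A shift is accepted at ≤ 4 total mismatches, else the boundary
falls back to the nearest `TG`/`CA` dinucleotide within ±10 bp, else stays
raw. Refinements that break any structural invariant are rejected and noted.
Scoring the full motif on *both* copies is what makes snapping robust: a
chance dinucleotide inside the repeat appears in both copies at the same
shift and would defeat any dinucleotide-only rule.

Overlap resolution keeps, among candidates sharing > 50% of element span,
the highest LTR identity, then the longer element, then the leftmost.

Measured on the evaluation scenario (2 Mb, ten elements, LTRs 150–220 bp,
2% substitutions, 20 seeds): ~99.5% of planted elements recovered with mean
boundary error below 0.1 bp and zero detections on element-free controls.

## Homology recovery and copy number (`hit_tools`)

The similarity search is a self-contained seed-and-extend local aligner
(13-mer seeds, collinear clustering, infix realignment of the library slice
against the genome region). Each alignment is trimmed to its
maximal-scoring core (match +1, mismatch/gap −2, Kadane scan over columns)
so that library margins aligned against unrelated flank never inflate hit
spans; on planted copies the merged spans match the planted bp to < 0.1%.

Defragmentation reads both published rules as strict inequalities: hits are
concatenated when their gap is *strictly less than* 500 bp, and merged spans
*strictly shorter than* 300 bp are dropped. Merging is per library
(per-subfamily consensus); overlaps across libraries are unioned only at
masking time, and `bp_masked` is always a union size, never double-counted.
Size bins: "> 4 kb" is strict and "2–4 kb" is the half-open interval
(2000, 4000], so the bins partition loci above 2 kb. All of these are
config-exposed because the boundary conventions are genuine choices.

## Clustering and consensus (`cluster_consensus`)

Greedy centroid clustering processes sequences longest-first (ties broken
lexicographically by id, making the partition order-insensitive); each
sequence joins the first centroid reached at ≥ 0.8 identity on either
strand, else founds a cluster.

The multiple alignment is center-star around the centroid, built from
pairwise edlib alignments. Unit-cost alignment fragments long indels by
grabbing chance matches inside the inserted sequence, so pairwise paths are
post-processed: any stretch whose aligned runs between gaps are shorter
than 20 columns is re-rendered as one contiguous gap flanked by 1:1 aligned
blocks, with the flank split chosen to minimize mismatches against the
region ends. This keeps gap columns confined to the true insertion and, in
particular, makes all members place a shared insertion boundary at the same
columns. Ungapping any row always reproduces the input member exactly.

"Conserved" in the trimming step is read as **occupancy**: a column is kept
iff non-gap residues occupy at least 80% of rows ("at least" inclusive),
which deletes minority insertions — the stated aim of insert cleaning. An
alternative **identity** mode (modal residue ≥ 80% of rows) is provided.
Whole columns are trimmed (keeping rows alignable); per-sequence residue
removal would be the other reading. Consensus is the modal non-gap residue
per retained column, ties broken alphabetically with a logged warning.

The cluster→align→trim cycle runs twice; round 2 re-clusters the
insert-cleaned members. On the eight-copy scenario (≤ 5% divergence, one
500 bp insertion) the final consensus is ≥ 99.9% identical to the canonical
element with no insertion-derived k-mer surviving.

## Classification (`clade_classifier`)

Six-frame translations compete per panel entry; only the best frame's hit is
kept (one call per element, not per frame), deduplicated per panel entry for
the vote. Local alignments use BLOSUM62 with gap open −11 / extend −1.
E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the gapped
BLOSUM62(11,1) constants λ = 0.267, K = 0.041; these approximate (and do not
reproduce) BLAST's composition-adjusted statistics, which is why both
E-value thresholds (1e-15 for the superfamily step, 1e-50 for the C-clade
filter) are configurable. On the synthetic panel the approximation separates
true domain hits (E ≪ 1e-100) from random 100-aa queries (E ≳ 1e-3) by many
orders of magnitude.

The vote reads "more than 8 of the first ten" as ≥ 9 of the top 10; with
fewer than ten hits the proportional rule ⌈0.9·n⌉ applies and the call is
flagged `short_list`. C-clade retention requires the *best* hit to be
C-clade-tagged with E ≤ 1e-50 and ≥ 300 aa of the panel domain covered.
Domain extraction takes the query residues aligned between the panel
domain's first and last aligned positions, from the best hit's frame only
(after a frameshift this is the majority frame), flagged partial below 90%
coverage and refused below 50%.

## Steamer features (`steamer_features`)

* **LTR motifs**: Hamming mismatches of the first seven bases vs `TGTAACA`
  and the last seven vs both `TTAAACA` (bivalve majority) and `ATAAACA`
  (reference variant). LTRs under 7 bp are skipped with a reason.
* **PBS**: scans offsets 0–3 after the 5′ LTR for a 12-mer matching
  `TGGTGTCAGAAG` exactly on positions 1–9 with ≤ 2 mismatches on positions
  10–12 (the empirically variable zone); a looser "≤ 2 anywhere" mode
  exists. The offset window accommodates boundary refinement shifting the
  LTR end by a few bp. Absence is a result, not an error.
* **PPT** has no canonical quantitative definition; the defaults — longest
  run of ≥ 10 bp with ≥ 90% A/G within 50 bp upstream of the 3′ LTR, ties
  to the run nearest the LTR — are explicit heuristics, all config-exposed.
* **ORF status**: reference-guided mode chains co-linear local alignments of
  a reference gag-pol protein across the six frames. Each HSP is first split
  at X-drop points (running score 30 below its maximum) so that a
  net-frame-restoring pair of frameshifts cannot be bridged as one long
  mismatch stretch; chaining is a small DP maximizing covered reference
  residues minus a 25-residue penalty per frame transition, which suppresses
  spurious short cross-frame segments. INTACT requires one frame covering
  ≥ 80% of the reference; FRAMESHIFTED(n) counts the transitions of the best
  chain reaching that coverage; internal regions under 300 bp are DELETED.
  Reference-free mode calls INTACT iff a single stop-free ORF covers ≥ 80%
  of the internal region. Frameshifts are counted as frame *transitions*,
  not indel events — how a single corrupted ORF actually reads.

## Phylogeny (`te_phylogeny`)

Distances are p-distances under pairwise deletion (sites with a gap or
unknown in either row excluded per pair; a pair with zero comparable sites
is an error naming the pair). Trees are canonical neighbor joining — exact
on additive matrices, verified against 200 random additive 6-taxon matrices
and cross-checked against scikit-bio's implementation — with negative branch
lengths clamped to zero (logged). Maximum-likelihood distances (e.g.,
JTT+gamma) are deliberately not implemented: on the synthetic alignments
used here model choice is immaterial, and the branch-definition logic is
independent of the distance model.

Bootstrap support is the percentage of 100 column-resampled replicates
containing each original internal bipartition (compared as unordered
side/complement pairs). Branch (family) definition treats every bipartition
side as a candidate clade: it qualifies with support strictly greater than
80 and members spanning ≥ 2 species; nested qualifying clades are collapsed
to the maximal one unless `report_nested` is set, and an optional outgroup
restricts candidates to sides excluding it. The enumeration oracle used in
tests checks monophyly independently via Steiner subtrees on the tree graph.

## Pipeline and reproducibility (`io`, `pipeline`, `cli`)

Every threshold lives in `PipelineConfig` (YAML, unknown keys rejected,
values validated at load) because several of the published rules are
strict/ambiguous-inequality readings users may want to flip. Stage outputs
go to numbered subdirectories; the JSON manifest records the package
version, seed, config hash and a SHA-256 per output file — and contains no
timestamps, so identical inputs and seed give a byte-identical manifest
(timings are logged instead). All randomness flows through explicit
`numpy.random.Generator` seeds; there is no global random state.

## Evaluation problem sizes

The evaluation scenarios (`steamerscan.evaluation`, driven by
`scripts/acceptance.py` and the acceptance tests) use: twenty 2 Mb genomes
with ten planted elements each plus twenty element-free controls for
detector recovery; 1,000 random interval sets for the merge oracle; twenty
eight-copy clusters for consensus recovery; 100 trials each for Gypsy
classification (≤ 20% domain divergence) and frameshift fidelity; one
2 Mb genome with five full-length and three truncated copies for the
copy-number truth; 200 additive matrices and 30 random supported trees for
the phylogeny oracles; and a 120 kb genome run twice for determinism. These
sizes make the whole validation run in a few minutes on one CPU while
keeping every per-scenario sample size at or above the level the recovery
percentages are stated over.

## Known limitations

* The detector targets intact LTR pairs; solo LTRs and heavily truncated
  copies are only recovered by the homology stage, and elements closer than
  the distance window can cross-pair their LTRs.
* The similarity search is not a RepeatMasker reimplementation: no
  species-specific scoring matrices, no composition adjustment.
* E-values are approximations; absolute thresholds calibrated for BLAST
  should not be transferred blindly.
* Center-star alignment is O(n·L²) per cluster and intended for the tens of
  copies per subfamily seen in this problem, not thousand-member families
  (an external-aligner hook exists at `align_cluster`'s call sites).
* Branch definition on unrooted trees reports bipartition sides; without an
  outgroup, a qualifying clade's complement can also qualify, and the
  maximality filter is then the only tie-breaker.
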