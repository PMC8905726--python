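# steamerscan

Structural annotation of LTR-retrotransposons and characterization of
Steamer-family elements in genome assemblies.

Steamer is a Gypsy (Ty3/Gypsy) LTR-retrotransposon of the C-clade, first
described in the soft-shell clam *Mya arenaria*, where its amplification is
associated with transmissible hemic neoplasia. Finding the few potentially
active copies of such an element in a bivalve assembly requires more than a
generic repeat annotator: full-length copies must be located structurally,
deleted and solo-LTR copies recovered by homology, copies grouped into
subfamilies with insertion-free consensus sequences, the superfamily and
clade confirmed from the RT/RNaseH (reverse transcriptase + ribonuclease H)
domain, and families delimited on a bootstrap-supported phylogeny.
`steamerscan` implements that complete workflow as a self-contained Python
library and CLI, together with a synthetic-genome generator that makes every
stage testable without downloading any assembly.

## The method

1. **Structural detection.** Full-length candidates are pairs of
   near-identical repeats — the long terminal repeats (LTRs) — with lengths
   in [80, 1200] bp, start positions 2,500–11,000 bp apart and ≥ 80%
   identity. The detector seeds on exact 13-mers repeated within the
   distance window, chains seeds by diagonal, extends the outermost anchors
   with an ungapped X-drop scan, verifies each LTR pair by banded global
   alignment, and snaps boundaries to the canonical `TG…CA` termini (scored
   against the Steamer start motif `TGTAACA` and end motif `TTAAACA` on both
   strands).
2. **Superfamily vote and C-clade filter.** Candidate internal regions are
   translated in six frames and scored against a labeled RT/RNaseH panel
   with BLOSUM62 local alignments (Karlin–Altschul E-values). An element is
   assigned to Gypsy/Copia/BEL-Pao when at least 9 of its 10 best panel
   matches agree, and retained as C-clade when its best match is
   C-clade-tagged with E ≤ 1e-50 and ≥ 300 aa covered.
3. **Clustering and consensus.** Retained elements are clustered greedily at
   80% identity (longest first, both strands), multiple-aligned around each
   centroid, and columns occupied by fewer than 80% of members are trimmed —
   removing private insertions. The cluster→trim cycle runs twice; a
   majority-rule consensus is deduced per final cluster.
4. **Homology recovery and copy number.** Each consensus is searched against
   the genome on both strands (seed-and-extend local alignment); hits closer
   than 500 bp are concatenated and merged spans shorter than 300 bp
   dropped. The per-subfamily report counts structural full-size copies,
   homology loci > 4 kb and in (2, 4] kb, total loci, masked bp and the
   genomic proportion.
5. **Steamer features.** Each element is checked against the Steamer
   blueprint: LTR start/end motifs, the 12-bp primer binding site
   (`TGGTGTCAGAAG`, substitutions tolerated only on its last three bases)
   immediately after the 5′ LTR, a polypurine tract just upstream of the 3′
   LTR, and gag-pol ORF integrity (INTACT / FRAMESHIFTED(n) / CORRUPTED /
   DELETED, with frameshifts counted as reading-frame transitions of a
   chained reference alignment).
6. **Phylogeny and family definition.** RT/RNaseH domains are placed on a
   neighbor-joining tree built from pairwise-deletion p-distances, with
   support from 100 nonparametric bootstrap replicates. Families
   ("branches") are clades with bootstrap support > 80 whose members span
   at least two species.

## Worked example

Generate a synthetic two-contig genome with four planted Steamer-like
elements plus a labeled RT/RNaseH panel, then run the full pipeline:

```sh
steamerscan simulate --out sim --background-bp 200000 --n-elements 4 --seed 7
# wrote genome (212664 bp), 4 insertions, 15 panel sequences to sim

steamerscan run-all --genome sim/genome.fa --panel sim/panel.fa --out run --seed 7
# done: 4 candidates, 1 consensi, 4 loci; manifest at run/manifest.json
```

The copy-number table (`run/06_copynumber/copy_number.tsv`) counts the four
structural full-size copies (`LTRH` column), the same four loci recovered by
the consensus homology search (`RM`), all in the 2–4 kb bin because the
simulated elements are 3,166 bp:

```
subfamily  LTRH  RM_gt4kb  RM_2to4kb  RM  genomic_proportion_pct  bp_masked  avg_length
all        4     0         4          4   5.95                    12664      3166
```

The feature report (`run/07_features/steamer_reports.tsv`) gives, per
element: LTR lengths (177 bp here), mismatches of the LTR start vs
`TGTAACA`, the PBS offset after the 5′ LTR, the PPT length, the ORF call,
and the identity of the RT/RNaseH domain to its best panel match:

```
element           length  ltr5  ltr3  start_mm  pbs_offset  ppt_len  orf        rt_identity
chr1:33333-36499  3166    177   177   1         0           15       CORRUPTED  96.5
chr1:69832-72998  3166    177   177   0         0           16       INTACT     94.75
chr2:33333-36499  3166    177   177   0         0           16       CORRUPTED  95.25
chr2:69832-72998  3166    177   177   0         absent      15       CORRUPTED  95.75
```

Copies were planted with 2% random substitutions, so most have acquired an
in-frame stop (CORRUPTED), one PBS is mutated past the tolerance (absent),
and one LTR start motif carries a mismatch — exactly the kind of degradation
the report is meant to expose. Stage outputs (GFF3/TSV/BED/FASTA/newick) and
a deterministic JSON manifest land in numbered subdirectories of `run/`.

The same stages are available as individual subcommands: `simulate`,
`detect`, `classify`, `cluster`, `copynumber`, `steamer-report`, `phylo`,
`run-all`.

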