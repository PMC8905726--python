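"""Reproducible evaluation scenarios for the pipeline's headline properties.

Each function builds its own synthetic inputs from an explicit seed, runs the
relevant pipeline stage(s) from scratch, and returns measured quantities.
Problem sizes follow the study conditions the package is designed around:
2 Mb genomes with ten planted full-length elements for detector recovery,
eight-copy clusters for consensus building, hundred-trial batches for
classification and ORF integrity, and 6-taxon additive matrices for the
phylogeny exactness check.
"""

from __future__ import annotations

import random
import tempfile
from pathlib import Path

import numpy as np

from . import clade_classifier as clc, cluster_consensus as cc, hit_tools as ht
from . import io as sio, ltr_detector as ld, simdata as sd, te_phylogeny as tp
from . import steamer_features as sf
from ._seqs import global_identity, random_protein
from .pipeline import run_pipeline


# ---------------------------------------------------------------------------
# 1. structural detector recovery

def detector_recovery(
    seed: int,
    n_seeds: int = 20,
    genome_bp: int = 2_000_000,
    n_elements: int = 10,
    substitution_rate: float = 0.02,
    max_boundary_err: int = 5,
) -> dict:
    """Planted-element recovery on 2 Mb genomes plus element-free controls.

    Elements carry LTRs of 150-220 bp; each copy is diverged by i.i.d.
    substitutions at the given rate (LTR-pair divergence about twice that,
    i.e. <= 5%).  Returns the percentage of planted elements recovered with
    every LTR boundary within max_boundary_err bp, and the count of
    detections on the control genomes.
    """
    rng = np.random.default_rng(seed)
    recovered = total = 0
    false_positives = 0
    boundary_errors: list[int] = []
    for rep in range(n_seeds):
        positions = np.linspace(50_000, genome_bp - 100_000, n_elements).astype(int)
        plan = []
        for i, p in enumerate(positions):
            spec = sd.ElementSpec(
                ltr_length=int(rng.integers(150, 221)),
                internal_length=int(rng.integers(3500, 5200)),
                seed=int(rng.integers(2**31)),
            )
            plan.append(
                sd.Insertion(
                    spec, int(p),
                    sd.MutationParams(substitution_rate=substitution_rate,
                                      seed=int(rng.integers(2**31)),
                                      revcomp=bool(rng.integers(0, 2))),
                )
            )
        genome, truth = sd.plant_genome(genome_bp, 0.4, plan, seed=int(rng.integers(2**31)))
        cands = ld.find_ltr_pairs({"chr1": genome})
        for t in truth:
            total += 1
            hit = None
            for c in cands:
                ov = min(c.end, t.end) - max(c.start, t.start)
                if ov > 0.5 * (t.end - t.start):
                    hit = c
                    break
            if hit is None:
                continue
            err = max(
                abs(hit.ltr5[0] - t.ltr5_start), abs(hit.ltr5[1] - t.ltr5_end),
                abs(hit.ltr3[0] - t.ltr3_start), abs(hit.ltr3[1] - t.ltr3_end),
            )
            boundary_errors.append(err)
            if err <= max_boundary_err:
                recovered += 1
        control, _ = sd.plant_genome(genome_bp, 0.4, [], seed=int(rng.integers(2**31)))
        false_positives += len(ld.find_ltr_pairs({"chr1": control}))
    return {
        "n_planted": total,
        "recovery_pct": 100.0 * recovered / total,
        "mean_boundary_err_bp": float(np.mean(boundary_errors)) if boundary_errors else -1.0,
        "control_detections": false_positives,
    }


# ---------------------------------------------------------------------------
# 2. hit merge/filter vs brute-force oracle

def brute_force_merge(
    spans: list[tuple[int, int]], max_gap: int = 500, min_len: int = 300
) -> list[tuple[int, int]]:
    """Independent interval oracle: sort, sweep, merge gaps < max_gap, drop
    merged spans < min_len."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s - out[-1][1] < max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return [(s, e) for s, e in out if e - s >= min_len]


def merge_oracle_agreement(seed: int, n_sets: int = 1000, max_intervals: int = 200) -> dict:
    """concatenate_hits vs the brute-force oracle on random hit sets."""
    rng = random.Random(seed)
    agree = 0
    for _ in range(n_sets):
        n = rng.randint(1, max_intervals)
        spans = []
        for _ in range(n):
            s = rng.randint(0, 50_000)
            spans.append((s, s + rng.randint(1, 2_000)))
        hits = [
            ht.RepeatHit("lib", "chr", s, e, "+", e - s, 90.0) for s, e in spans
        ]
        merged = [(m.start, m.end) for m in ht.concatenate_hits(hits)]
        agree += merged == brute_force_merge(spans)
    return {"n_sets": n_sets, "agreement_pct": 100.0 * agree / n_sets}


# ---------------------------------------------------------------------------
# 3. consensus recovery

def consensus_recovery(
    seed: int,
    n_seeds: int = 20,
    n_copies: int = 8,
    substitution_rate: float = 0.03,
    insertion_len: int = 500,
) -> dict:
    """Two-round consensus building on clusters of diverged copies, one copy
    carrying a long insertion.  Measures identity and length of the final
    consensus against the canonical element and checks that no k-mer of the
    planted insertion survives in the consensus."""
    rng = np.random.default_rng(seed)
    spec = sd.default_steamer_spec()
    canonical, feat = sd.make_canonical_element(spec)
    idents, len_ratios = [], []
    insert_kmer_hits = 0
    single_cluster = 0
    for rep in range(n_seeds):
        insert = "".join(np.array(list("ACGT"))[rng.integers(0, 4, insertion_len)])
        seqs = {}
        for i in range(n_copies):
            mp = sd.MutationParams(substitution_rate=substitution_rate,
                                   seed=int(rng.integers(2**31)),
                                   revcomp=(i == n_copies - 1))
            copy, _, _ = sd.mutate_copy(canonical, feat, mp)
            if i == 0:
                pos = int(rng.integers(500, len(copy) - 500))
                copy = copy[:pos] + insert + copy[pos:]
            seqs[f"copy{i}"] = copy
        cs, consensi = cc.iterate_cluster_consensus(seqs, rounds=2)
        single_cluster += len(cs.clusters) == 1
        cons = consensi[0].consensus
        idents.append(global_identity(cons, canonical))
        len_ratios.append(len(cons) / len(canonical))
        k = 15
        if any(insert[j : j + k] in cons for j in range(0, insertion_len - k, 5)):
            insert_kmer_hits += 1
    return {
        "n_seeds": n_seeds,
        "single_cluster_runs": single_cluster,
        "mean_identity_pct": float(np.mean(idents)),
        "min_identity_pct": float(np.min(idents)),
        "mean_length_ratio": float(np.mean(len_ratios)),
        "runs_with_insert_kmer": insert_kmer_hits,
    }


# ---------------------------------------------------------------------------
# 4. superfamily vote rule and classification recovery

def vote_rule_oracle() -> dict:
    """assign_superfamily vs exhaustive enumeration over all label multisets
    of size 0..10 drawn from the three superfamilies."""
    from itertools import combinations_with_replacement

    labels = list(sd.SUPERFAMILIES)
    checked = agree = 0
    for n in range(0, 11):
        for combo in combinations_with_replacement(labels, n):
            hits = [
                clc.DomainHit(
                    query_id="q", panel_id=f"p{i}", superfamily=lab, clade="-",
                    score=100 - i, evalue=1e-30 * (i + 1), identity=90.0,
                    frame=0, query_aa_range=(0, 10), panel_range=(0, 10),
                    covered_aa=10,
                )
                for i, lab in enumerate(combo)
            ]
            call = clc.assign_superfamily(hits)
            # independent statement of the rule
            if n == 0:
                expected = "none"
            else:
                need = 9 if n >= 10 else -(-9 * n // 10)  # ceil(0.9 n)
                counts = {lab: combo.count(lab) for lab in set(combo)}
                top_lab, top = max(counts.items(), key=lambda kv: kv[1])
                expected = top_lab if top >= need else "uncertain"
            agree += call.label == expected
            checked += 1
    return {"n_cases": checked, "agreement_pct": 100.0 * agree / checked}


def classification_recovery(
    seed: int, n_trials: int = 100, divergence: float = 0.15
) -> dict:
    """Elements whose ORF embeds a diverged Gypsy panel domain must be called
    Gypsy and never another superfamily."""
    rng = np.random.default_rng(seed)
    panel = clc.panel_from_tuples(sd.make_domain_panel(5, seed=seed))
    gypsy_members = [p for p in panel if p.superfamily == "Gypsy"]
    aa = np.array(list(sd.AA_ALPHABET))
    correct = wrong = 0
    for _ in range(n_trials):
        src = gypsy_members[rng.integers(0, len(gypsy_members))]
        prot = np.array(list(src.sequence))
        mask = rng.random(len(prot)) < divergence
        prot[mask] = aa[rng.integers(0, 20, mask.sum())]
        spec = sd.ElementSpec(
            internal_length=1800, orf_protein="".join(prot), seed=int(rng.integers(2**31))
        )
        el, feat = sd.make_canonical_element(spec)
        internal = el[feat["pbs"][1] : feat["ltr3"][0]]
        hits = clc.rank_panel_matches(internal, panel)
        call = clc.assign_superfamily(hits)
        if call.label == "Gypsy":
            correct += 1
        elif call.label in ("Copia", "BEL/Pao"):
            wrong += 1
    return {
        "n_trials": n_trials,
        "gypsy_call_pct": 100.0 * correct / n_trials,
        "wrong_superfamily_calls": wrong,
    }


# ---------------------------------------------------------------------------
# 5. structural feature recovery

def feature_recovery(seed: int, n_elements: int = 50) -> dict:
    """PBS and PPT recovery at planted coordinates on clean elements."""
    rng = np.random.default_rng(seed)
    pbs_found = ppt_found = start_clean = 0
    for _ in range(n_elements):
        spec = sd.ElementSpec(
            ltr_length=int(rng.integers(150, 221)),
            internal_length=int(rng.integers(2500, 5000)),
            seed=int(rng.integers(2**31)),
        )
        el, feat = sd.make_canonical_element(spec)
        pbs = sf.find_pbs(el, feat["ltr5"])
        if pbs is not None and pbs.offset == 0 and pbs.mismatches_total == 0:
            pbs_found += 1
        ppt = sf.find_ppt(el, feat["ltr3"])
        ps, pe = feat["ppt"]
        if ppt is not None and ppt.start <= ps and ppt.end >= pe - 0:
            ppt_found += 1
        m5, _ = sf.check_ltr_motifs(el[feat["ltr5"][0]:feat["ltr5"][1]],
                                    el[feat["ltr3"][0]:feat["ltr3"][1]])
        start_clean += m5.start_mismatches == 0
    return {
        "n_elements": n_elements,
        "pbs_recovery_pct": 100.0 * pbs_found / n_elements,
        "ppt_recovery_pct": 100.0 * ppt_found / n_elements,
        "start_motif_clean_pct": 100.0 * start_clean / n_elements,
    }


def frameshift_fidelity(seed: int, n_trials: int = 100) -> dict:
    """Reference-guided orf_status vs the simulator's planted frameshift
    count, cycling n through {0, 1, 2}."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    spec = sd.ElementSpec(internal_length=3000, seed=seed)
    canonical, feat = sd.make_canonical_element(spec)
    ref = str(Seq(canonical[feat["orf"][0] : feat["orf"][1]]).translate())
    correct = {0: 0, 1: 0, 2: 0}
    totals = {0: 0, 1: 0, 2: 0}
    for t in range(n_trials):
        nfs = t % 3
        mp = sd.MutationParams(substitution_rate=0.01, n_frameshifts=nfs,
                               seed=int(rng.integers(2**31)))
        copy, log, f2 = sd.mutate_copy(canonical, feat, mp)
        internal = copy[f2["pbs"][1] : f2["ltr3"][0]]
        st = sf.orf_status(internal, ref)
        got = st.n_frameshifts if st.status == "FRAMESHIFTED" else (
            0 if st.status == "INTACT" else -1
        )
        totals[nfs] += 1
        correct[nfs] += got == nfs
    return {
        "n_trials": n_trials,
        "accuracy_pct": 100.0 * sum(correct.values()) / n_trials,
        **{f"accuracy_n{k}_pct": 100.0 * correct[k] / totals[k] for k in (0, 1, 2)},
    }


# ---------------------------------------------------------------------------
# 6. copy-number truth

def copy_number_truth(seed: int, genome_bp: int = 2_000_000) -> dict:
    """Five full-length (~5 kb) plus three 2.5 kb truncated copies planted in
    a 2 Mb genome; structural detection + homology recovery + binning."""
    rng = np.random.default_rng(seed)
    spec = sd.default_steamer_spec()
    canonical, _ = sd.make_canonical_element(spec)
    positions = np.linspace(60_000, genome_bp - 100_000, 8).astype(int)
    plan = []
    for i, p in enumerate(positions[:5]):
        plan.append(sd.Insertion(spec, int(p),
                                 sd.MutationParams(substitution_rate=0.02,
                                                   seed=int(rng.integers(2**31)),
                                                   revcomp=(i % 2 == 1))))
    for p in positions[5:]:
        plan.append(sd.Insertion(spec, int(p),
                                 sd.MutationParams(substitution_rate=0.02,
                                                   truncate_3prime=spec.element_length - 2500,
                                                   seed=int(rng.integers(2**31)))))
    genome, truth = sd.plant_genome(genome_bp, 0.4, plan, seed=int(rng.integers(2**31)))
    cands = ld.find_ltr_pairs({"chr1": genome})
    hits = ht.similarity_search({"SteSim": canonical}, {"chr1": genome})
    merged = ht.concatenate_hits(hits)
    report = ht.copy_number_report(cands, merged, len(genome), subfamily="SteSim")
    planted_bp = sum(t.end - t.start for t in truth)
    return {
        "n_full_size": report.n_full_size,
        "n_gt_4kb": report.n_gt_4kb,
        "n_2_to_4kb": report.n_2_to_4kb,
        "n_total_loci": report.n_total_loci,
        "bp_masked": report.bp_masked,
        "planted_bp": planted_bp,
        "bp_masked_ratio": report.bp_masked / planted_bp,
        "genomic_proportion_pct": report.genomic_proportion,
    }


# ---------------------------------------------------------------------------
# 7. phylogeny exactness

def random_additive_tree(n_taxa: int, rng: random.Random) -> tp.TreeNode:
    nodes = [tp.TreeNode(name=f"t{i}", length=rng.uniform(0.5, 3.0)) for i in range(n_taxa)]
    while len(nodes) > 3:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        p = tp.TreeNode(length=rng.uniform(0.5, 3.0))
        p.children = [a, b]
        nodes.append(p)
    root = tp.TreeNode()
    root.children = nodes
    return root


def canonical_bipartitions(tree: tp.TreeNode) -> set[frozenset[str]]:
    full = frozenset(lf.name for lf in tree.leaves())
    return {
        frozenset(min(bp, full - bp, key=lambda s: (len(s), tuple(sorted(s)))))
        for bp in tp.tree_bipartitions(tree)
    }


def nj_exactness(seed: int, n_matrices: int = 200, n_taxa: int = 6) -> dict:
    rng = random.Random(seed)
    topo_ok = dist_ok = 0
    for _ in range(n_matrices):
        tree = random_additive_tree(n_taxa, rng)
        dm = tp.tree_distances(tree)
        out = tp.nj_tree(dm)
        topo_ok += canonical_bipartitions(out) == canonical_bipartitions(tree)
        dist_ok += bool(np.allclose(tp.tree_distances(out).matrix, dm.matrix, atol=1e-9))
    return {
        "n_matrices": n_matrices,
        "topology_recovery_pct": 100.0 * topo_ok / n_matrices,
        "distance_recovery_pct": 100.0 * dist_ok / n_matrices,
    }


def branch_oracle_subsets(
    tree: tp.TreeNode, species_map: dict[str, str], min_support: float, min_species: int
) -> set[frozenset[str]]:
    """Independent enumeration oracle: every subset of taxa, checked for
    monophyly by testing whether its Steiner subtree contains foreign leaves."""
    import networkx as nx

    g = nx.Graph()
    counter = [0]

    def walk(node: tp.TreeNode, parent=None):
        if node.is_leaf():
            nid = node.name
        else:
            nid = f"__int{counter[0]}"
            counter[0] += 1
        g.add_node(nid)
        if parent is not None:
            # bootstrap support belongs to the edge above the (child) node
            g.add_edge(parent, nid, support=node.support)
        for c in node.children:
            walk(c, nid)
        return nid

    walk(tree)
    taxa = sorted(lf.name for lf in tree.leaves())
    full = set(taxa)
    result: set[frozenset[str]] = set()
    from itertools import chain, combinations as combos

    for r in range(2, len(taxa)):
        for subset in combos(taxa, r):
            sset = set(subset)
            # Steiner subtree = union of pairwise paths
            nodes_in = set()
            base = subset[0]
            for t in subset[1:]:
                nodes_in.update(nx.shortest_path(g, base, t))
            nodes_in.add(base)
            sub = g.subgraph(nodes_in)
            leaves_in = {n for n in sub.nodes if n in full}
            if leaves_in != sset:
                continue  # not monophyletic
            # support = the edge separating subset from the rest: find the
            # unique boundary edge; its child-side node carries the support
            boundary = [
                (u, v) for u, v in g.edges
                if (u in nodes_in) != (v in nodes_in)
            ]
            if len(boundary) != 1:
                continue
            u, v = boundary[0]
            support = g.edges[u, v].get("support")
            if support is None:
                continue
            if support <= min_support:
                continue
            if len({species_map[t] for t in subset}) < min_species:
                continue
            result.add(frozenset(subset))
    # keep maximal only
    return {s for s in result if not any(s < t for t in result)}


def branch_definition_oracle(seed: int, n_trees: int = 30, max_taxa: int = 12) -> dict:
    """define_branches vs the subset-enumeration oracle on random supported
    trees with random species maps."""
    rng = random.Random(seed)
    agree = 0
    for _ in range(n_trees):
        n = rng.randint(5, max_taxa)
        tree = random_additive_tree(n, rng)
        for bp, node in tp.tree_bipartitions(tree).items():
            node.support = rng.choice([50, 75, 80, 85, 95, 100])
        taxa = [lf.name for lf in tree.leaves()]
        smap = {t: f"sp{rng.randint(1, 3)}" for t in taxa}
        got = {
            g.members
            for g in tp.define_branches(tree, smap, min_support=80, min_species=2)
        }
        expected = branch_oracle_subsets(tree, smap, 80, 2)
        agree += got == expected
    return {"n_trees": n_trees, "agreement_pct": 100.0 * agree / n_trees}


# ---------------------------------------------------------------------------
# 8. end-to-end determinism

def pipeline_determinism(seed: int, background_bp: int = 120_000, n_elements: int = 3) -> dict:
    """Run the full pipeline twice with one seed; manifests must be
    byte-identical."""
    rng = np.random.default_rng(seed)
    panel = clc.panel_from_tuples(sd.make_domain_panel(5, seed=seed))
    c_member = next(p for p in panel if p.clade == "C-clade")
    gag_pol = random_protein(380, np.random.default_rng(seed)) + c_member.sequence
    spec = sd.ElementSpec(orf_protein=gag_pol, internal_length=2800,
                          seed=int(rng.integers(2**31)))
    gap = background_bp // (n_elements + 1)
    plan = [
        sd.Insertion(spec, gap * (i + 1),
                     sd.MutationParams(substitution_rate=0.02,
                                       seed=int(rng.integers(2**31)),
                                       revcomp=bool(i % 2)))
        for i in range(n_elements)
    ]
    genome, _ = sd.plant_genome(background_bp, 0.4, plan, seed=int(rng.integers(2**31)))
    cfg = sio.PipelineConfig(seed=seed)
    manifests = []
    stats = {}
    with tempfile.TemporaryDirectory() as td:
        for run in ("run1", "run2"):
            result = run_pipeline({"chr1": genome}, panel, cfg, Path(td) / run)
            manifests.append((Path(td) / run / "manifest.json").read_bytes())
            stats = {
                "n_candidates": len(result.candidates),
                "n_consensi": len(result.consensi),
                "n_loci": result.report.n_total_loci if result.report else 0,
                "stages_completed": len(result.manifest["stages"]),
            }
    return {"identical_manifests": int(manifests[0] == manifests[1]), **stats}
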