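"""Family clustering, conservation, genomic context, clusters, statistics."""

import numpy as np
import pytest

from mirnascape.families import (classify_conservation, classify_context,
                                 cluster_families, detect_clusters,
                                 family_statistics, position_frequencies,
                                 summarize_compiled_table, welch_t_test,
                                 MirnaFamily)
from mirnascape.genome_io import CatalogEntry, GeneFeature
from mirnascape.synthetic import compiled_locus_table

BASE = "ACGTACGTACGTACGTACGTA"


def _mut(seq, positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s[p]]
    return "".join(s)


def test_identical_matures_form_one_family():
    matures = {f"L{i:02d}": BASE for i in range(12)}
    (fam,) = cluster_families(matures)
    assert fam.size == 12 and len(fam.mature_sequences) == 1


def test_single_linkage_chains_through_intermediate():
    a, b, c = BASE, _mut(BASE, (0, 5)), _mut(BASE, (0, 5, 10, 15))
    fams = cluster_families({"A": a, "B": b, "C": c})
    assert len(fams) == 1  # A-B=2, B-C=2 chain although A-C=4


def test_distant_matures_split_into_families():
    fams = cluster_families({"A": BASE, "B": _mut(BASE, (0, 3, 6, 9, 12))})
    assert len(fams) == 2


def test_clustering_is_input_order_invariant():
    seqs = {f"L{i}": _mut(BASE, tuple(range(i))) for i in range(6)}
    fams1 = cluster_families(dict(seqs))
    fams2 = cluster_families(dict(reversed(list(seqs.items()))))
    assert [(f.family_id, f.members) for f in fams1] == \
           [(f.family_id, f.members) for f in fams2]


def test_clustering_matches_brute_force_components():
    from mirnascape.discovery import offset_distance

    rng = np.random.default_rng(4)
    bases = ["".join("ACGT"[i] for i in rng.integers(0, 4, 21)) for _ in range(4)]
    matures = {}
    k = 0
    for b in bases:
        for _ in range(3):
            matures[f"L{k:02d}"] = _mut(b, tuple(rng.choice(21, rng.integers(0, 2),
                                                            replace=False)))
            k += 1
    # oracle: BFS over the pairwise <=2 graph
    ids = sorted(matures)
    adj = {i: set() for i in ids}
    for i in ids:
        for j in ids:
            if i < j:
                d = offset_distance(matures[i], matures[j])
                if d is not None and d <= 2:
                    adj[i].add(j)
                    adj[j].add(i)
    seen, components = set(), []
    for i in ids:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        components.append(tuple(sorted(comp)))
    got = sorted(tuple(f.members) for f in cluster_families(matures))
    assert got == sorted(components)


def test_cluster_anchored_to_both_2118_and_2218_gets_merged_name(catalog):
    fams = cluster_families({"L1": "TTGCCGATTCCACCCATTCCTA"}, catalog)
    assert fams[0].family_id == "miR2118/2218"


def test_conservation_classes_from_catalog(catalog):
    conserved = MirnaFamily("f1", ["a"], ["TCGGACCAGGCTTCATTCCCC"])  # ath hit
    legume = MirnaFamily("f2", ["b"], ["TGTTGTTTTACCTATTCCACC"])  # G. soja only
    specific = MirnaFamily("f3", ["c"], ["TTTTTTTTTTGGGGGGGGGGT"])  # nowhere
    gma_only = MirnaFamily("f4", ["d"], ["TCATTTTGCGTGCAATGATCC"])  # G. max hit
    assert classify_conservation(conserved, catalog) == "conserved"
    assert classify_conservation(legume, catalog) == "legume_specific"
    assert classify_conservation(specific, catalog) == "soybean_specific"
    assert classify_conservation(gma_only, catalog) == "soybean_specific"


def test_conservation_requires_species_labels():
    bad = [CatalogEntry("x", "ACGTACGTACGTACGTACGTA", "miRx", "sp")]
    with pytest.raises(ValueError, match="plant-family"):
        classify_conservation(MirnaFamily("f", ["a"], [BASE]), bad)


# ---------------------------------------------------------------------------
# genomic context


def test_designed_contexts_are_recovered(sim_bundle):
    genome, truth, _reads = sim_bundle
    expected = {
        "intragenic_CDS": "intragenic_CDS",
        "intragenic_UTR": "intragenic_UTR",
        "proximal_500": ("proximal", 500),
        "proximal_748": ("proximal", 748),
        "intergenic_1500": ("intergenic", 1500),
    }
    for locus in truth.loci:
        ctx = classify_context("x", locus.precursor, locus.chrom, genome.genes)
        want = expected.get(locus.context, "intergenic")
        if isinstance(want, tuple):
            assert (ctx.context, ctx.distance) == want, locus.context
        else:
            assert ctx.context == want, locus.context


def test_proximal_748_reports_three_prime_side(sim_bundle):
    genome, truth, _reads = sim_bundle
    locus = next(l for l in truth.loci if l.context == "proximal_748")
    ctx = classify_context("x", locus.precursor, locus.chrom, genome.genes)
    assert ctx.side == "3'" and ctx.distance == 748


def test_context_partition_every_locus_one_class(sim_bundle):
    genome, truth, _reads = sim_bundle
    classes = {"intergenic", "intragenic_CDS", "intragenic_UTR", "proximal"}
    for locus in truth.loci:
        ctx = classify_context("x", locus.precursor, locus.chrom, genome.genes)
        assert ctx.context in classes


def test_exactly_1000bp_is_intergenic():
    genes = [GeneFeature("g", "chr1", 1000, 2000, "+", [("CDS", 1000, 2000)])]
    ctx = classify_context("x", (3000, 3060), "chr1", genes)
    assert ctx.context == "intergenic" and ctx.distance == 1000
    ctx2 = classify_context("x", (2999, 3060), "chr1", genes)
    assert ctx2.context == "proximal" and ctx2.distance == 999


# ---------------------------------------------------------------------------
# miRNA gene clusters


def _locus_rows(*rows):
    return [(f"L{i}", "chr1", s, e, st) for i, (s, e, st) in enumerate(rows)]


def test_tandem_pair_within_5kb_clusters():
    rows = _locus_rows((1000, 1100, "+"), (5000, 5100, "+"))
    (cl,) = detect_clusters(rows, [])
    assert cl.arrangement == "tandem" and cl.members == ["L0", "L1"]


def test_intervening_gene_blocks_cluster():
    rows = _locus_rows((1000, 1100, "+"), (5000, 5100, "+"))
    gene = [GeneFeature("g", "chr1", 2000, 3000, "+")]
    assert detect_clusters(rows, gene) == []


def test_6kb_gap_does_not_cluster():
    rows = _locus_rows((1000, 1100, "+"), (7100, 7200, "+"))
    assert detect_clusters(rows, []) == []


def test_divergent_and_convergent_orientations_labeled():
    head = _locus_rows((1000, 1100, "-"), (3000, 3100, "+"))
    tail = _locus_rows((1000, 1100, "+"), (3000, 3100, "-"))
    assert detect_clusters(head, [])[0].arrangement == "head_to_head"
    assert detect_clusters(tail, [])[0].arrangement == "tail_to_tail"


def test_planted_tandem_pairs_detected_and_6kb_pair_not(sim_bundle):
    genome, truth, _reads = sim_bundle
    rows = [(f"L{i}", l.chrom, l.precursor[0], l.precursor[1], l.strand)
            for i, l in enumerate(truth.loci)]
    clusters = detect_clusters(rows, genome.genes)
    clustered = {tuple(c.members) for c in clusters}
    four_kb = [(i, j) for i, j, gap in truth.tandem_pairs if gap == 4000]
    six_kb = [(i, j) for i, j, gap in truth.tandem_pairs if gap == 6000]
    for i, j in four_kb:
        assert (f"L{i}", f"L{j}") in clustered
    for i, j in six_kb:
        assert (f"L{i}", f"L{j}") not in clustered


def test_cluster_detection_matches_quadratic_oracle():
    rng = np.random.default_rng(8)
    rows = []
    pos = 1000
    for i in range(40):
        pos += int(rng.integers(500, 9000))
        rows.append((f"L{i:02d}", "chr1", pos, pos + 100, "+"))
    genes = [GeneFeature(f"g{k}", "chr1", int(p), int(p) + 200, "+")
             for k, p in enumerate(rng.integers(1000, pos, size=8))]

    def linked(a, b):
        if b[2] - a[3] > 5000:
            return False
        return not any(g.start > a[3] and g.end < b[2] for g in genes)

    # oracle: chain consecutive sorted loci, O(n^2) overall
    srt = sorted(rows, key=lambda r: r[2])
    chains, chain = [], [srt[0]]
    for a, b in zip(srt, srt[1:]):
        if linked(a, b):
            chain.append(b)
        else:
            if len(chain) > 1:
                chains.append(tuple(r[0] for r in chain))
            chain = [b]
    if len(chain) > 1:
        chains.append(tuple(r[0] for r in chain))
    got = sorted(tuple(c.members) for c in detect_clusters(rows, genes))
    assert got == sorted(chains)


# ---------------------------------------------------------------------------
# statistics


def test_family_statistics_identical_and_singleton_cases():
    fams = [
        MirnaFamily("a", [f"m{i}" for i in range(12)], [BASE],
                    conservation="conserved"),
        MirnaFamily("b", ["x"], [_mut(BASE, (0, 1, 2, 3, 4, 5))],
                    conservation="conserved"),
        MirnaFamily("c", ["y"], [_mut(BASE, (6, 7, 8, 9, 10, 11))],
                    conservation="conserved"),
    ]
    stats = family_statistics(fams)["conserved"]
    assert stats["sizes"] == [12, 1, 1]
    # the 12-member identical family: 12 members per unique mature
    assert fams[0].matures_per_sequence == 12.0
    # singletons do not count as identical-mature families
    only_singletons = family_statistics(fams[1:] + [])
    assert family_statistics([fams[1], fams[2]])["conserved"][
        "pct_identical_matures"] == 0.0
    assert family_statistics([fams[1], fams[2]])["conserved"]["mean_size"] == 1.0


def test_position_frequencies_sum_to_one():
    freqs = position_frequencies([BASE, _mut(BASE, (0, 1)), BASE[:19]])
    sums = freqs.sum(axis=1, skipna=True)
    assert np.allclose(sums[:19], 1.0)
    assert np.allclose(sums[19:21], 1.0)  # two 21-nt sequences cover 20-21


def test_class_family_counts_partition_total():
    summary = summarize_compiled_table(compiled_locus_table())
    assert sum(summary["class_counts"].values()) == summary["n_families"]


def test_welch_identical_samples_give_t_zero_p_one():
    t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_welch_matches_textbook_computation():
    t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
    assert abs(t - (-1.224744871391589)) < 1e-9
    assert abs(df - 4.0) < 1e-9
    assert abs(p - 0.28786413472669053) < 1e-9
    # independent oracle
    from scipy import stats as ss
    ref = ss.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=False)
    assert abs(t - ref.statistic) < 1e-12 and abs(p - ref.pvalue) < 1e-12


def test_welch_rejects_degenerate_samples():
    with pytest.raises(ValueError, match="sample_b"):
        welch_t_test([1, 2, 3], [5])
    with pytest.raises(ValueError, match="zero variance"):
        welch_t_test([2, 2, 2], [3, 3, 3])
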