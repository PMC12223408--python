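"""OTU calling: dereplication, swarm clustering, filters, oracles."""

from functools import lru_cache

import numpy as np
import pytest

from bogforam import (
    Read,
    SimConfig,
    build_otu_table,
    call_otus,
    dereplicate,
    divergence_filter,
    edit_distance,
    flag_chimeras,
    global_identity,
    remove_singleton_otus,
    simulate_dataset,
    simulate_sequences,
    swarm_cluster,
    reads_from_table,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def levenshtein_recursive(a: str, b: str) -> int:
    """Textbook recursive definition (memoized), independent of the package."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def enumerate_alignment_identity(a: str, b: str) -> float:
    """Enumerate every global alignment; among maximum-score alignments
    (match 1, mismatch 0, gap -1) return the best identity."""
    best: dict[str, float] = {}

    def rec(i, j, score, matches, cols):
        if i == len(a) and j == len(b):
            key = score
            ident = matches / cols if cols else 1.0
            if key not in best or ident > best[key]:
                best[key] = ident
            return
        if i < len(a) and j < len(b):
            m = a[i] == b[j]
            rec(i + 1, j + 1, score + (1 if m else 0), matches + (1 if m else 0), cols + 1)
        if i < len(a):
            rec(i + 1, j, score - 1, matches, cols + 1)
        if j < len(b):
            rec(i, j + 1, score - 1, matches, cols + 1)

    rec(0, 0, 0, 0, 0)
    return best[max(best)]


def connected_components_partition(seqs, d=1):
    """Brute-force graph oracle: components of the distance-<=d graph,
    seeds = per-component (abundance, lexicographic) maxima."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if levenshtein_recursive(seqs[i].sequence, seqs[j].sequence) <= d:
                parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(seqs[i])
    out = []
    for members in comps.values():
        seed = min(members, key=lambda s: (-s.total_count, s.sequence))
        out.append((seed.sequence, frozenset(m.sequence for m in members)))
    return set(out)


def rand_seq(rng, lo=4, hi=9) -> str:
    return "".join(rng.choice(list("ACGT"), size=rng.integers(lo, hi)))


def make_derep(items):
    """items: list of (seq, total) -> DereplicatedSeq-like via dereplicate."""
    reads = [Read(f"r{i}", "S1", seq, total) for i, (seq, total) in enumerate(items)]
    return dereplicate(reads)


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

class TestDereplicate:
    def test_aggregates_counts_per_sample(self):
        reads = [Read("a", "s1", "AAA"), Read("b", "s2", "AAA"), Read("c", "s1", "AAT")]
        derep = dereplicate(reads)
        assert len(derep) == 2
        top = derep[0]
        assert top.sequence == "AAA" and top.total_count == 2
        assert top.per_sample_counts == {"s1": 1, "s2": 1}

    def test_empty_input(self):
        assert dereplicate([]) == []

    def test_conservation_on_random_reads(self):
        rng = np.random.default_rng(0)
        reads = [
            Read(f"r{i}", f"s{rng.integers(3)}", rand_seq(rng, 3, 6)) for i in range(1000)
        ]
        derep = dereplicate(reads)
        assert sum(d.total_count for d in derep) == 1000
        order = [(-d.total_count, d.sequence) for d in derep]
        assert order == sorted(order)

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError, match="bad1"):
            dereplicate([Read("bad1", "s1", "ACGN")])


# ---------------------------------------------------------------------------
# edit distance and identity
# ---------------------------------------------------------------------------

class TestPairwiseMetrics:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACT", 1), ("A", "T", 1), ("ACGT", "TGCA", 4)],
    )
    def test_edit_distance_examples(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_edit_distance_matches_recursive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            a, b = rand_seq(rng, 1, 13), rand_seq(rng, 1, 13)
            assert edit_distance(a, b) == levenshtein_recursive(a, b)

    @pytest.mark.parametrize(
        "a,b,expected", [("ACGT", "ACGT", 1.0), ("AAAA", "TTTT", 0.0)]
    )
    def test_global_identity_examples(self, a, b, expected):
        assert global_identity(a, b) == pytest.approx(expected)

    def test_global_identity_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            a, b = rand_seq(rng, 1, 8), rand_seq(rng, 1, 8)
            assert global_identity(a, b) == pytest.approx(enumerate_alignment_identity(a, b))

    def test_global_identity_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rand_seq(rng, 2, 10), rand_seq(rng, 2, 10)
            assert global_identity(a, b) == pytest.approx(global_identity(b, a))


# ---------------------------------------------------------------------------
# swarm clustering
# ---------------------------------------------------------------------------

class TestSwarmCluster:
    def test_chain_rule_merges_transitive_neighbours(self):
        # A -1- B -1- C: single-linkage chains into one cluster
        derep = make_derep([("AAAAAA", 10), ("AAAAAT", 3), ("AAAATT", 1)])
        clusters = swarm_cluster(derep, d=1)
        assert len(clusters) == 1
        assert clusters[0].seed.sequence == "AAAAAA"
        assert clusters[0].total_count == 14

    def test_distant_sequences_stay_apart(self):
        derep = make_derep([("AAAAAA", 5), ("AATTTA", 4)])
        assert len(swarm_cluster(derep, d=1)) == 2

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            swarm_cluster([], d=-1)

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        derep = make_derep([(rand_seq(rng, 3, 6), int(rng.integers(1, 20))) for _ in range(30)])
        clusters = swarm_cluster(derep, d=1)
        all_members = [m.sequence for c in clusters for m in c.members]
        assert sorted(all_members) == sorted(d.sequence for d in derep)

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            derep = make_derep(
                [(rand_seq(rng, 3, 6), int(rng.integers(1, 30))) for _ in range(int(rng.integers(5, 30)))]
            )
            clusters = swarm_cluster(derep, d=1)
            got = {(c.seed.sequence, frozenset(m.sequence for m in c.members)) for c in clusters}
            assert got == connected_components_partition(derep, d=1)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilters:
    def test_singleton_boundary(self):
        derep = make_derep([("AAAAAA", 2), ("CCCCGG", 1)])
        clusters = swarm_cluster(derep)
        kept, removed = remove_singleton_otus(clusters)
        assert [c.total_count for c in kept] == [2]
        assert [c.total_count for c in removed] == [1]
        assert len(kept) + len(removed) == len(clusters)

    def test_constructed_chimera_flagged_but_parent_copy_not(self):
        rng = np.random.default_rng(6)
        a = rand_seq(rng, 120, 121)
        b = "".join(rng.choice(list("ACGT"), size=120))
        chim = a[:60] + b[60:]
        derep = make_derep([(a, 100), (b, 90), (chim, 5)])
        clusters = swarm_cluster(derep)
        flagged = flag_chimeras(clusters)
        chim_id = next(c.otu_id for c in clusters if c.seed.sequence == chim)
        assert flagged == {chim_id}

    def test_chimera_recall_on_simulated_data(self):
        hits = total = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, n_freshwater_otus=15, n_contaminant_otus=0, n_samples=8,
                chimera_rate=0.2, depth_log10_range=(2.85, 3.8), failed_sample_fraction=0.0,
            )
            table, _, truth = simulate_dataset(cfg)
            seqs, chim = simulate_sequences(truth.tree, cfg.seq_length, cfg.subs_rate, cfg.chimera_rate, seed)
            reads = reads_from_table(table, seqs, chim, seed=seed)
            derep = dereplicate(reads)
            clusters = swarm_cluster(derep)
            clusters, _ = remove_singleton_otus(clusters)
            flagged = flag_chimeras(clusters)
            totals = {c.otu_id: c.total_count for c in clusters}
            for cid, (pa, pb, _k) in chim.items():
                eligible = (
                    cid in totals
                    and totals.get(pa, 0) >= 2 * totals[cid]
                    and totals.get(pb, 0) >= 2 * totals[cid]
                )
                if eligible:
                    total += 1
                    hits += cid in flagged
        assert total > 0
        assert hits / total >= 0.9

    def test_divergence_boundary_strict(self):
        # shared homopolymer head, disjoint-alphabet tails: the number of
        # matching columns in ANY alignment is capped at the head length,
        # so identity is exactly head/100 regardless of gap placement
        for n_matches, expect_kept in [(64, False), (65, True)]:
            ref = "A" * n_matches + "C" * (100 - n_matches)
            probe = "A" * n_matches + "G" * (100 - n_matches)
            assert global_identity(ref, probe) == pytest.approx(n_matches / 100)
            clusters = swarm_cluster(make_derep([(ref, 100), (probe, 10)]))
            kept, removed = divergence_filter(clusters)
            kept_seqs = {c.seed.sequence for c in kept}
            assert ref in kept_seqs
            assert (probe in kept_seqs) == expect_kept
            assert len(kept) + len(removed) == 2

    def test_random_contaminant_removed_as_divergent(self):
        removed_count = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ref = "".join(rng.choice(list("ACGT"), size=200))
            junk = "".join(rng.choice(list("ACGT"), size=200))
            derep = make_derep([(ref, 50), (junk, 5)])
            kept, removed = divergence_filter(swarm_cluster(derep))
            removed_count += any(c.seed.sequence == junk for c in removed)
        assert removed_count >= 19  # >= 95% of seeds

    def test_empty_divergence_filter_rejected(self):
        with pytest.raises(ValueError):
            divergence_filter([])


# ---------------------------------------------------------------------------
# table building and full stage
# ---------------------------------------------------------------------------

class TestBuildTable:
    def test_single_cluster_single_sample(self):
        derep = make_derep([("AAAAAA", 5)])
        clusters = swarm_cluster(derep)
        table = build_otu_table(clusters, ["S1"])
        assert table.shape == (1, 1) and table.total_reads() == 5

    def test_column_sums_recount(self):
        rng = np.random.default_rng(8)
        reads = [
            Read(f"r{i}", f"S{rng.integers(1, 4)}", rand_seq(rng, 3, 6), int(rng.integers(1, 9)))
            for i in range(200)
        ]
        per_sample = {}
        for r in reads:
            per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + r.count
        clusters = swarm_cluster(dereplicate(reads))
        table = build_otu_table(clusters, sorted(per_sample))
        assert table.sample_sums().to_dict() == per_sample

    def test_empty_cluster_list_keeps_header(self):
        table = build_otu_table([], ["S1", "S2"])
        assert table.shape == (0, 2) and table.sample_ids == ["S1", "S2"]

    def test_pipeline_read_conservation(self):
        cfg = SimConfig(seed=3, n_freshwater_otus=12, n_contaminant_otus=2, n_samples=6,
                        chimera_rate=0.1, depth_log10_range=(2.85, 3.5))
        table, _, truth = simulate_dataset(cfg)
        seqs, chim = simulate_sequences(truth.tree, cfg.seq_length, cfg.subs_rate, cfg.chimera_rate, 3)
        reads = reads_from_table(table, seqs, chim, seed=3)
        derep = dereplicate(reads)
        clusters = swarm_cluster(derep)
        kept, singles = remove_singleton_otus(clusters)
        flagged = flag_chimeras(kept)
        surviving = [c for c in kept if c.otu_id not in flagged]
        kept2, divergent = divergence_filter(surviving)
        out = build_otu_table(kept2, table.sample_ids)
        removed_reads = (
            sum(c.total_count for c in singles)
            + sum(c.total_count for c in kept if c.otu_id in flagged)
            + sum(c.total_count for c in divergent)
        )
        assert out.total_reads() + removed_reads == sum(r.count for r in reads)

    def test_no_overmerging_of_true_otus(self):
        # with sister taxa far beyond d=1, every true OTU with reads keeps
        # its own cluster (clusters >= true OTUs present)
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_freshwater_otus=15, n_contaminant_otus=0, n_samples=6,
                            chimera_rate=0.0, depth_log10_range=(2.85, 3.5), failed_sample_fraction=0.0)
            table, _, truth = simulate_dataset(cfg)
            seqs, _ = simulate_sequences(truth.tree, cfg.seq_length, cfg.subs_rate, 0.0, seed)
            reads = reads_from_table(table, seqs, seed=seed)
            clusters = swarm_cluster(dereplicate(reads))
            present = sum(1 for o in table.otu_ids if table.counts.loc[o].sum() > 0)
            assert len(clusters) >= present
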