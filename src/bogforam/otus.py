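"""Simplified OTU calling for merged amplicon reads.

Dereplication, swarm-style single-linkage clustering at edit distance
``d`` (default 1), and the standard quality filters applied to fresh OTU
libraries: removal of single-read OTUs, of chimeric OTUs (two-parent
breakpoint test), and of OTUs highly divergent (<65% identical) from the
most abundant OTU.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .curation import OtuTable
from .simulate import Read

__all__ = [
    "DereplicatedSeq",
    "OtuCluster",
    "dereplicate",
    "edit_distance",
    "swarm_cluster",
    "remove_singleton_otus",
    "flag_chimeras",
    "global_identity",
    "divergence_filter",
    "build_otu_table",
    "call_otus",
]

_ACGT = set("ACGT")


@dataclass
class DereplicatedSeq:
    """One distinct sequence with per-sample read counts."""

    seq_id: str
    sequence: str
    per_sample_counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


@dataclass
class OtuCluster:
    """A swarm of dereplicated sequences; the seed is the most abundant member."""

    otu_id: str
    seed: DereplicatedSeq
    members: list[DereplicatedSeq] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.total_count for m in self.members)


def _check_acgt(seq: str, record: str) -> None:
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in record {record!r}")


def dereplicate(reads: list[Read]) -> list[DereplicatedSeq]:
    """Collapse identical sequences, aggregating counts per sample.

    Output is sorted by total count descending, ties broken by sequence
    lexicographically.  Each entry's id is the most frequent read id among
    the reads carrying that sequence (ties lexicographic), which preserves
    meaningful labels when reads are tagged by origin.
    """
    by_seq: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    id_votes: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in reads:
        _check_acgt(r.sequence, r.read_id)
        if r.count < 1:
            raise ValueError(f"read {r.read_id!r} has non-positive count {r.count}")
        by_seq[r.sequence][r.sample_id] += r.count
        id_votes[r.sequence][r.read_id] += r.count
    out = []
    for seq, counts in by_seq.items():
        votes = id_votes[seq]
        seq_id = min(votes, key=lambda k: (-votes[k], k))
        out.append(DereplicatedSeq(seq_id, seq, dict(counts)))
    out.sort(key=lambda d: (-d.total_count, d.sequence))
    return out


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two ACGT strings."""
    _check_acgt(a, "a")
    _check_acgt(b, "b")
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def _within(a: str, b: str, d: int) -> bool:
    if abs(len(a) - len(b)) > d:
        return False
    if not a or not b:
        return max(len(a), len(b)) <= d
    return edlib.align(a, b, task="distance", k=d)["editDistance"] != -1


def swarm_cluster(seqs: list[DereplicatedSeq], d: int = 1) -> list[OtuCluster]:
    """Single-linkage seed-growth clustering at edit-distance radius ``d``.

    The most abundant unassigned sequence seeds a cluster; any unassigned
    sequence within distance ``d`` of any current member is attached, and
    the frontier keeps expanding until no more sequences join (so chains
    A-B-C with consecutive distance 1 merge into one cluster even when A
    and C are far apart).  Clusters are returned in descending total-count
    order; the cluster id is the seed's id.
    """
    if d < 0:
        raise ValueError(f"d must be >= 0, got {d}")
    order = sorted(seqs, key=lambda s: (-s.total_count, s.sequence))
    n = len(order)
    # adjacency at distance <= d
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _within(order[i].sequence, order[j].sequence, d):
                adj[i].append(j)
                adj[j].append(i)
    assigned = [False] * n
    clusters = []
    for i in range(n):
        if assigned[i]:
            continue
        frontier = [i]
        assigned[i] = True
        members = []
        while frontier:
            cur = frontier.pop()
            members.append(order[cur])
            for nb in adj[cur]:
                if not assigned[nb]:
                    assigned[nb] = True
                    frontier.append(nb)
        members.sort(key=lambda s: (-s.total_count, s.sequence))
        clusters.append(OtuCluster(otu_id=members[0].seq_id, seed=members[0], members=members))
    clusters.sort(key=lambda c: (-c.total_count, c.seed.sequence))
    return clusters


def remove_singleton_otus(clusters: list[OtuCluster]) -> tuple[list[OtuCluster], list[OtuCluster]]:
    """Partition clusters into (kept, removed) where removed have exactly one read."""
    kept = [c for c in clusters if c.total_count > 1]
    removed = [c for c in clusters if c.total_count <= 1]
    return kept, removed


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

_GAP = -1
# combined DP weight packs (score, n_matches) into one integer so a single
# max-plus recursion resolves the lexicographic (score, matches) optimum
_PACK = 4096


def global_identity(a: str, b: str) -> float:
    """Fraction of identical columns in an optimal global alignment.

    Alignment scoring: match +1, mismatch 0, gap -1 per column (linear).
    Identity = matches / alignment length, counting gap columns in the
    denominator.  Among co-optimal alignments the one with the most matches
    defines the identity, which makes the value deterministic.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_acgt(a, "a")
    _check_acgt(b, "b")
    la, lb = len(a), len(b)
    if la > _PACK - 1 or lb > _PACK - 1:
        raise ValueError("sequences longer than supported (4095 bp)")
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    gap = _GAP * _PACK
    # diagonal weight: match contributes score 1 and one match
    wd = np.where(av[:, None] == bv[None, :], _PACK + 1, 0).astype(np.int64)
    offsets = gap * np.arange(lb + 1, dtype=np.int64)
    prev = offsets.copy()  # row 0: leading gaps in a
    for i in range(1, la + 1):
        cand = np.empty(lb + 1, dtype=np.int64)
        cand[0] = gap * i
        np.maximum(prev[:-1] + wd[i - 1], prev[1:] + gap, out=cand[1:])
        # resolve left-gap chains: C[j] = max_{j'<=j} cand[j'] + gap*(j-j')
        cur = np.maximum.accumulate(cand - offsets) + offsets
        prev = cur
    packed = int(prev[lb])
    matches = packed % _PACK
    score = (packed - matches) // _PACK
    mismatches = (score + la + lb - 3 * matches) // 2
    aln_len = la + lb - matches - mismatches
    return matches / aln_len


def _segment_identity(x: str, y: str) -> float:
    """Identity of two (sub)sequences; positional when lengths agree."""
    if not x or not y:
        return 0.0
    if len(x) == len(y):
        xv = np.frombuffer(x.encode(), dtype=np.uint8)
        yv = np.frombuffer(y.encode(), dtype=np.uint8)
        return float((xv == yv).mean())
    return global_identity(x, y)


def flag_chimeras(
    clusters: list[OtuCluster],
    min_parent_fold: float = 2.0,
    segment_identity: float = 0.99,
    min_segment_frac: float = 0.2,
) -> set[str]:
    """Flag cluster ids whose seed looks like a two-parent PCR chimera.

    A seed S is flagged iff two clusters A and B each at least
    ``min_parent_fold`` times as abundant as S admit a breakpoint k such
    that S[:k] matches A's seed and S[k:] matches B's seed at >=
    ``segment_identity`` per segment, both segments spanning at least
    ``min_segment_frac`` of S — while S matches neither parent alone at >=
    ``segment_identity`` over its full length (an exact copy of a parent is
    not a chimera).

    Segment comparison is positional (no indels); chimeras formed by
    template switching during PCR preserve position within the amplicon.
    """
    flagged: set[str] = set()
    for c in clusters:
        s = c.seed.sequence
        L = len(s)
        parents = [p for p in clusters if p is not c and p.total_count >= min_parent_fold * c.total_count]
        if len(parents) < 2:
            continue
        # full-length matches to any single parent rule the candidate out
        full = [p for p in parents if _segment_identity(s, p.seed.sequence) >= segment_identity]
        if full:
            continue
        sv = np.frombuffer(s.encode(), dtype=np.uint8)
        kmin = max(1, int(np.ceil(min_segment_frac * L)))
        kmax = L - kmin
        if kmin > kmax:
            continue
        pref: dict[int, np.ndarray] = {}
        suff: dict[int, np.ndarray] = {}
        for idx, p in enumerate(parents):
            ps = p.seed.sequence
            m = min(L, len(ps))
            pv = np.frombuffer(ps.encode(), dtype=np.uint8)
            eq_pref = (sv[:m] == pv[:m]).astype(np.int64)
            pre = np.zeros(L + 1, dtype=np.int64)
            pre[1 : m + 1] = np.cumsum(eq_pref)
            if m < L:
                pre[m + 1 :] = pre[m]
            eq_suf = (sv[L - m :] == pv[len(ps) - m :]).astype(np.int64)
            suf = np.zeros(L + 1, dtype=np.int64)
            suf[1 : m + 1] = np.cumsum(eq_suf[::-1])
            if m < L:
                suf[m + 1 :] = suf[m]
            pref[idx], suff[idx] = pre, suf
        ks = np.arange(kmin, kmax + 1)
        found = False
        for ia in range(len(parents)):
            ok_a = pref[ia][ks] >= np.ceil(segment_identity * ks)
            if not ok_a.any():
                continue
            for ib in range(len(parents)):
                if ib == ia:
                    continue
                rlen = L - ks
                ok_b = suff[ib][rlen] >= np.ceil(segment_identity * rlen)
                if (ok_a & ok_b).any():
                    found = True
                    break
            if found:
                break
        if found:
            flagged.add(c.otu_id)
    return flagged


def divergence_filter(
    clusters: list[OtuCluster], min_identity: float = 0.65
) -> tuple[list[OtuCluster], list[OtuCluster]]:
    """Drop clusters whose seed is less than ``min_identity`` similar to the
    most abundant cluster's seed (highly divergent off-target amplicons).

    The comparison uses :func:`global_identity`; the boundary is strict
    (identity exactly at the threshold is kept).  The reference cluster is
    always kept.
    """
    if not clusters:
        raise ValueError("divergence_filter requires at least one cluster")
    ref = max(clusters, key=lambda c: (c.total_count, c.seed.sequence))
    kept, removed = [], []
    for c in clusters:
        if c is ref or global_identity(c.seed.sequence, ref.seed.sequence) >= min_identity:
            kept.append(c)
        else:
            removed.append(c)
    return kept, removed


def build_otu_table(clusters: list[OtuCluster], samples: list[str]) -> OtuTable:
    """Sum member per-sample counts into an OTU x sample table.

    Samples appear in the given order; OTU rows follow cluster order
    (descending abundance).  An empty cluster list yields a 0-row table
    with the sample header intact.
    """
    data = np.zeros((len(clusters), len(samples)), dtype=np.int64)
    sample_index = {s: j for j, s in enumerate(samples)}
    for i, c in enumerate(clusters):
        for m in c.members:
            for s, n in m.per_sample_counts.items():
                if s not in sample_index:
                    raise KeyError(f"sample {s!r} in cluster {c.otu_id!r} not in sample list")
                data[i, sample_index[s]] += n
    return OtuTable(pd.DataFrame(data, index=[c.otu_id for c in clusters], columns=samples))


def call_otus(
    reads: list[Read],
    d: int = 1,
    min_identity: float = 0.65,
) -> tuple[OtuTable, pd.DataFrame]:
    """Full calling stage: dereplicate, cluster, filter, tabulate.

    Returns the OTU table of surviving clusters plus a log of removed
    cluster ids with the reason (``singleton``, ``chimera`` or
    ``divergent``).
    """
    samples = sorted({r.sample_id for r in reads})
    derep = dereplicate(reads)
    clusters = swarm_cluster(derep, d=d)
    log: list[tuple[str, str]] = []
    clusters, singletons = remove_singleton_otus(clusters)
    log += [(c.otu_id, "singleton") for c in singletons]
    chimeric = flag_chimeras(clusters)
    log += [(cid, "chimera") for cid in sorted(chimeric)]
    clusters = [c for c in clusters if c.otu_id not in chimeric]
    if clusters:
        clusters, divergent = divergence_filter(clusters, min_identity=min_identity)
        log += [(c.otu_id, "divergent") for c in divergent]
    table = build_otu_table(clusters, samples)
    return table, pd.DataFrame(log, columns=["id", "reason"])
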