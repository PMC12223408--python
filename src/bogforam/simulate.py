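"""Synthetic freshwater-foraminifera metabarcoding communities.

Generates datasets with the statistical structure typical of low-diversity
18S amplicon surveys of bogs and greenhouse pools: a few dozen OTUs with a
heavy-tailed (log-normal) abundance distribution where the top OTU can hold
a third of all reads, ~30 samples spread over four locations with sample
depths spanning from ~700 to ~300,000 reads, a handful of failed (<500
read) libraries, habitat-restricted taxa, marine contaminant OTUs seeded
into a subset of samples, and low-level index switching that bleeds reads
between samples.  Every corruption is recorded in a :class:`SimTruth`
ledger so downstream curation can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .curation import OtuTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "Read",
    "simulate_tree",
    "simulate_sequences",
    "simulate_dataset",
    "reads_from_table",
]

_LOCATIONS = ["acadia", "orono", "hawley", "greenhouse", "loc5", "loc6", "loc7", "loc8"]
_FIELD_SITE_TYPES = ["open_bog", "forest_edge", "stream", "pitcher_plant", "pond"]
_GREENHOUSE_SITE_TYPES = ["pool_concrete", "pool_wood", "pool_duckweed", "pool_salvinia"]
_SUBSTRATES = {"field": ["sphagnum", "water", "biofilm"], "greenhouse": ["water", "swab"]}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Defaults emulate the survey design the pipeline targets: ~30 usable
    samples from 4 locations, <= ~70 OTUs with strong dominance, depths
    log-uniform between ~700 and ~295,000 reads, a few failed libraries,
    and 6 marine contaminant OTUs.
    """

    n_samples: int = 34
    n_locations: int = 4
    n_site_types_per_location: int = 3
    n_freshwater_otus: int = 60
    n_contaminant_otus: int = 6
    abundance_sigma: float = 2.5  # log-normal shape; top OTU ~ a third of reads
    specificity_fraction: float = 0.8  # P(an OTU is restricted to one location)
    depth_log10_range: tuple[float, float] = (2.85, 5.47)  # ~708 .. ~295,000 reads
    failed_sample_fraction: float = 0.12
    # per-read probability of index switching under the uniform-destination
    # model; calibrated so small libraries receive the same stray-read load
    # (~a fraction of a read to a few reads) as proportional-destination
    # hopping at the ~0.1% rates reported for Illumina platforms
    switch_rate: float = 2e-5
    chimera_rate: float = 0.05
    seq_length: int = 250
    subs_rate: float = 1.0  # multiplier on branch lengths (expected subs/site)
    seed: int = 0

    def validate(self) -> None:
        for name in ("specificity_fraction", "failed_sample_fraction", "switch_rate", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_samples", "n_locations", "n_site_types_per_location", "n_freshwater_otus", "seq_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_contaminant_otus < 0:
            raise ValueError("n_contaminant_otus must be >= 0")
        lo, hi = self.depth_log10_range
        if lo > hi:
            raise ValueError("depth_log10_range min must be <= max")
        if self.abundance_sigma < 0 or self.subs_rate < 0:
            raise ValueError("abundance_sigma and subs_rate must be >= 0")
        if self.n_locations > len(_LOCATIONS):
            raise ValueError(f"at most {len(_LOCATIONS)} locations supported")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``switch_moves`` records each index-switching transfer as
    ``(otu_id, source_sample, dest_sample, reads_moved)``;
    ``switched_cells`` aggregates arrivals per destination cell as
    ``(otu_id, sample_id, reads_moved)``.  ``clean_table`` plus the moves
    reproduces the corrupted table exactly (reads are conserved).
    """

    clean_table: OtuTable
    contaminant_otu_ids: set[str]
    switch_moves: list[tuple[str, str, str, int]] = field(default_factory=list)
    switched_cells: list[tuple[str, str, int]] = field(default_factory=list)
    failed_sample_ids: set[str] = field(default_factory=set)
    chimera_seq_ids: set[str] = field(default_factory=set)
    chimera_parents: dict[str, tuple[str, str, int]] = field(default_factory=dict)
    tree: dendropy.Tree | None = None
    habitat_map: dict[str, set[str]] = field(default_factory=dict)

    def apply_moves(self) -> OtuTable:
        """Replay the switching ledger on the clean table (conservation check)."""
        df = self.clean_table.counts.copy()
        for otu, src, dst, n in self.switch_moves:
            df.at[otu, src] -= n
            df.at[otu, dst] += n
        return OtuTable(df)


def simulate_tree(n_taxa: int, seed: int, labels: list[str] | None = None) -> dendropy.Tree:
    """Random rooted binary tree with strictly positive branch lengths.

    Topology is built by random pairwise joins (a coalescent-style
    construction); every edge gets an independent exponential length
    (mean 0.02 expected substitutions per site, keeping within-community
    divergence in the 5-30% range typical of a clade-level 18S survey).  Deterministic given
    ``seed``; leaves are labelled ``OTU1..OTUn`` unless ``labels`` is given.
    """
    if n_taxa < 2:
        raise ValueError(f"need at least 2 taxa, got {n_taxa}")
    if labels is None:
        labels = [f"OTU{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    rng = np.random.default_rng([int(seed), 0x7EE])

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = float(rng.exponential(0.02)) + 1e-6
        b.edge.length = float(rng.exponential(0.02)) + 1e-6
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, p_change: float, rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor style site substitution: each site changes with
    probability ``p_change`` to a uniformly chosen different base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < p_change)[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def simulate_sequences(
    tree: dendropy.Tree,
    seq_length: int = 250,
    subs_rate: float = 1.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, tuple[str, str, int]]]:
    """Evolve one sequence per leaf plus optional chimeric artifacts.

    A random ACGT root sequence is propagated down the tree; along an edge
    of length *t* each site substitutes with probability
    ``3/4 * (1 - exp(-4/3 * subs_rate * t))`` (single-rate, equal-frequency
    model).  ``ceil(chimera_rate * n_leaves)`` chimeras are then formed,
    each as the prefix of one leaf sequence joined to the suffix of another
    at a breakpoint within the middle 60% of the length.

    Returns ``(sequences, chimera_info)`` where ``sequences`` maps id ->
    sequence (leaves then chimeras, ids ``CHIM1..``) and ``chimera_info``
    maps chimera id -> ``(parent_a, parent_b, breakpoint)``.
    """
    if seq_length < 50:
        raise ValueError(f"seq_length must be >= 50, got {seq_length}")
    rng = np.random.default_rng([int(seed), 0x5EC])
    root_seq = _BASES[rng.integers(0, 4, size=seq_length)]
    seqs_arr: dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            p = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * subs_rate * t))
            cseq = _mutate(seq, p, rng)
            if child.is_leaf():
                seqs_arr[child.taxon.label] = cseq
            else:
                descend(child, cseq)

    if tree.seed_node.is_leaf():  # degenerate single-node tree
        seqs_arr[tree.seed_node.taxon.label] = root_seq
    else:
        descend(tree.seed_node, root_seq)

    leaf_ids = sorted(seqs_arr)
    chimera_info: dict[str, tuple[str, str, int]] = {}
    n_chim = math.ceil(chimera_rate * len(leaf_ids))
    for c in range(n_chim):
        ai, bi = rng.choice(len(leaf_ids), size=2, replace=False)
        a, b = leaf_ids[int(ai)], leaf_ids[int(bi)]
        k = int(rng.integers(int(0.2 * seq_length) + 1, int(0.8 * seq_length)))
        cid = f"CHIM{c + 1}"
        seqs_arr[cid] = np.concatenate([seqs_arr[a][:k], seqs_arr[b][k:]])
        chimera_info[cid] = (a, b, k)

    seqs = {k: v.tobytes().decode("ascii") for k, v in seqs_arr.items()}
    return seqs, chimera_info


def _make_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    locations = _LOCATIONS[: config.n_locations]
    for i in range(config.n_samples):
        loc = locations[i % config.n_locations]
        if loc == "greenhouse":
            site_pool = _GREENHOUSE_SITE_TYPES[: config.n_site_types_per_location]
            substrate = _SUBSTRATES["greenhouse"][i % 2]
            ph = float(np.round(rng.uniform(6.5, 7.5), 2))
        else:
            site_pool = _FIELD_SITE_TYPES[: config.n_site_types_per_location]
            substrate = _SUBSTRATES["field"][i % 3]
            ph = float(np.round(rng.uniform(3.8, 4.8), 2))
        site = site_pool[(i // config.n_locations) % len(site_pool)]
        rows.append((f"S{i + 1:02d}", loc, site, substrate, ph))
    return pd.DataFrame(rows, columns=["sample_id", "location", "site_type", "substrate", "pH"]).set_index(
        "sample_id"
    )


def simulate_dataset(config: SimConfig = SimConfig()) -> tuple[OtuTable, pd.DataFrame, SimTruth]:
    """Generate a corrupted OTU table, sample metadata and ground truth.

    Construction: log-normal base abundances per OTU; a
    ``specificity_fraction`` of freshwater OTUs restricted to a single
    location (each location guaranteed at least one specific OTU when
    possible); contaminant OTUs seeded into a random subset of samples;
    per-sample depths log-uniform over ``depth_log10_range`` except failed
    samples drawn uniformly on [50, 499] reads; sample counts multinomial
    over the habitat-masked abundances; finally each read independently
    switches to a uniformly random other sample with probability
    ``switch_rate``, every transfer being recorded in the truth ledger.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0xDA7A])

    fw_ids = [f"OTU{i + 1}" for i in range(config.n_freshwater_otus)]
    con_ids = [f"MAR{i + 1}" for i in range(config.n_contaminant_otus)]
    otu_ids = fw_ids + con_ids
    metadata = _make_metadata(config, rng)
    sample_ids = list(metadata.index)
    locations = _LOCATIONS[: config.n_locations]

    # heavy-tailed base abundances
    base = rng.lognormal(0.0, config.abundance_sigma, size=len(otu_ids))

    # habitat restriction: specific OTUs pinned to one location (round-robin
    # start so every location receives at least one when enough are drawn)
    habitat_map: dict[str, set[str]] = {}
    specific = rng.random(config.n_freshwater_otus) < config.specificity_fraction
    loc_cycle = rng.permutation(config.n_locations)
    ci = 0
    for i, otu in enumerate(fw_ids):
        if specific[i]:
            habitat_map[otu] = {locations[int(loc_cycle[ci % config.n_locations])]}
            ci += 1
        else:
            habitat_map[otu] = set(locations)

    # contaminants bleed into a random subset of samples (lab contamination)
    con_samples: dict[str, set[str]] = {}
    for otu in con_ids:
        n_hit = int(rng.integers(1, max(2, config.n_samples // 4)))
        hit = rng.choice(config.n_samples, size=n_hit, replace=False)
        con_samples[otu] = {sample_ids[int(h)] for h in hit}
        habitat_map[otu] = {str(metadata.loc[s, "location"]) for s in con_samples[otu]}

    # per-sample depths; failed libraries land under the 500-read floor
    failed = set()
    n_failed = int(round(config.failed_sample_fraction * config.n_samples))
    if n_failed:
        failed = {sample_ids[int(i)] for i in rng.choice(config.n_samples, size=n_failed, replace=False)}
    lo, hi = config.depth_log10_range
    depths = {}
    for s in sample_ids:
        if s in failed:
            depths[s] = int(rng.integers(50, 500))
        else:
            depths[s] = int(round(10 ** rng.uniform(lo, hi)))

    # multinomial sampling from habitat-masked abundances
    counts = np.zeros((len(otu_ids), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        loc = str(metadata.loc[s, "location"])
        w = np.zeros(len(otu_ids))
        for i, otu in enumerate(fw_ids):
            if loc in habitat_map[otu]:
                w[i] = base[i]
        for k, otu in enumerate(con_ids):
            if s in con_samples[otu]:
                w[config.n_freshwater_otus + k] = base[config.n_freshwater_otus + k]
        if w.sum() == 0:  # degenerate habitat mask; fall back to all freshwater
            w[: config.n_freshwater_otus] = base[: config.n_freshwater_otus]
        counts[:, j] = rng.multinomial(depths[s], w / w.sum())

    clean = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))

    # index switching: each read moves to a uniform random other sample
    corrupted = counts.copy()
    moves: list[tuple[str, str, str, int]] = []
    arrivals: dict[tuple[str, str], int] = {}
    if config.switch_rate > 0 and len(sample_ids) > 1:
        for i, otu in enumerate(otu_ids):
            for j, s in enumerate(sample_ids):
                c = counts[i, j]
                if c == 0:
                    continue
                m = int(rng.binomial(c, config.switch_rate))
                if m == 0:
                    continue
                others = [k for k in range(len(sample_ids)) if k != j]
                dest_counts = rng.multinomial(m, np.full(len(others), 1.0 / len(others)))
                corrupted[i, j] -= m
                for k, dc in zip(others, dest_counts):
                    if dc == 0:
                        continue
                    corrupted[i, k] += dc
                    moves.append((otu, s, sample_ids[k], int(dc)))
                    key = (otu, sample_ids[k])
                    arrivals[key] = arrivals.get(key, 0) + int(dc)

    table = OtuTable(pd.DataFrame(corrupted, index=otu_ids, columns=sample_ids))
    tree = simulate_tree(len(otu_ids), config.seed, labels=otu_ids)
    truth = SimTruth(
        clean_table=clean,
        contaminant_otu_ids=set(con_ids),
        switch_moves=moves,
        switched_cells=[(o, s, n) for (o, s), n in sorted(arrivals.items())],
        failed_sample_ids=failed,
        tree=tree,
        habitat_map=habitat_map,
    )
    return table, metadata, truth


@dataclass(frozen=True)
class Read:
    """A labelled merged amplicon: id, sample of origin, sequence, multiplicity."""

    read_id: str
    sample_id: str
    sequence: str
    count: int = 1


def reads_from_table(
    table: OtuTable,
    sequences: dict[str, str],
    chimera_info: dict[str, tuple[str, str, int]] | None = None,
    seed: int = 0,
) -> list[Read]:
    """Expand an OTU table into labelled merged reads for the caller stage.

    Each table cell yields one :class:`Read` carrying the OTU's sequence
    with the cell count as multiplicity.  Chimeric sequences are added with
    small counts (2-5 reads) in the sample where their first parent is most
    abundant, so they sit well below the two-fold parent-abundance bar used
    by chimera flagging.
    """
    rng = np.random.default_rng([int(seed), 0xC41])
    reads = []
    for otu in table.otu_ids:
        if otu not in sequences:
            raise KeyError(f"no sequence for OTU {otu!r}")
        for sample in table.sample_ids:
            c = int(table.counts.at[otu, sample])
            if c > 0:
                reads.append(Read(otu, sample, sequences[otu], c))
    for cid, (pa, _pb, _k) in (chimera_info or {}).items():
        row = table.counts.loc[pa] if pa in table.counts.index else None
        if row is None or row.sum() == 0:
            continue
        sample = str(row.idxmax())
        reads.append(Read(cid, sample, sequences[cid], int(rng.integers(2, 6))))
    return reads
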