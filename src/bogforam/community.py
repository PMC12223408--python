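"""Phylogeny-aware community analysis.

Weighted UniFrac beta diversity, classical principal coordinates analysis
(PCoA), relative-abundance classification of OTU presences into
rare/intermediate/dominant, and occupancy/habitat-specificity summaries.

Weighted UniFrac between samples A and B is

    D(A, B) = sum_i  b_i * | p_i(A) - p_i(B) |

over all branches i, where b_i is the branch length and p_i(X) the
fraction of sample X's reads descending from branch i.  The normalized
variant divides by ``sum_i b_i * (p_i(A) + p_i(B))``, bounding values to
[0, 1]; it is the default because it makes samples of very different
depth structure comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .curation import OtuTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "relative_abundance",
    "classify_presence",
    "classify_table",
    "weighted_unifrac",
    "pcoa",
    "occupancy_summary",
    "top_k_fraction",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, percent variance per axis.

    ``coordinates`` has one row per sample and one column per retained
    (positive-eigenvalue) axis; ``eigenvalues`` lists every eigenvalue in
    descending order, negatives included; ``percent_variance`` covers the
    retained axes and sums to 100 over them.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample read fractions (columns sum to 1)."""
    sums = table.sample_sums()
    zero = list(sums.index[sums == 0])
    if zero:
        raise ValueError(f"samples with zero reads cannot be normalized: {zero}")
    return table.counts / sums


def classify_presence(fraction: float) -> str:
    """Classify a nonzero relative abundance as rare, intermediate or dominant.

    Less than 25% of a sample's reads is ``rare``; between 25% and 75%
    inclusive is ``intermediate``; more than 75% is ``dominant``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction < 0.25:
        return "rare"
    if fraction <= 0.75:
        return "intermediate"
    return "dominant"


def classify_table(table: OtuTable) -> pd.DataFrame:
    """Long-format classification of every occupied cell.

    Columns: otu_id, sample_id, reads, fraction, abundance_class.
    """
    fracs = relative_abundance(table)
    rows = []
    for otu in table.otu_ids:
        for sample in table.sample_ids:
            reads = int(table.counts.at[otu, sample])
            if reads == 0:
                continue
            f = float(fracs.at[otu, sample])
            rows.append((otu, sample, reads, f, classify_presence(f)))
    return pd.DataFrame(rows, columns=["otu_id", "sample_id", "reads", "fraction", "abundance_class"])


def _branch_profiles(table: OtuTable, tree: dendropy.Tree) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch descending read fractions.

    Returns ``(lengths, P)`` where row i of ``P`` holds, for branch i, the
    fraction of each sample's reads on leaves below that branch.  Leaves of
    the tree absent from the table carry zero weight, which makes explicit
    pruning unnecessary (their branches contribute nothing to either the
    distance or the normalizer).
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_labels)) != len(leaf_labels):
        raise ValueError("tree has duplicate leaf labels")
    missing = sorted(set(table.otu_ids) - set(leaf_labels))
    if missing:
        raise ValueError(f"table OTUs missing from tree: {missing}")
    sums = table.sample_sums()
    zero = list(sums.index[sums == 0])
    if zero:
        raise ValueError(f"samples with zero reads: {zero}")
    fracs = (table.counts / sums).to_numpy()
    row_of = {otu: i for i, otu in enumerate(table.otu_ids)}
    n_samples = len(table.sample_ids)

    lengths: list[float] = []
    profiles: list[np.ndarray] = []
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(n_samples)
            lab = node.taxon.label
            if lab in row_of:
                vec = fracs[row_of[lab]].astype(float)
        else:
            vec = np.zeros(n_samples)
            for child in node.child_nodes():
                vec = vec + below[id(child)]
        below[id(node)] = vec
        if node.parent_node is not None:  # the root has no branch above it
            lengths.append(float(node.edge.length or 0.0))
            profiles.append(vec)
    return np.array(lengths), np.array(profiles)


def weighted_unifrac(table: OtuTable, tree: dendropy.Tree, normalized: bool = True) -> DistanceMatrix:
    """All-pairs weighted UniFrac distances between the table's samples.

    Every table OTU must be a leaf of ``tree``; extra leaves are harmless.
    With ``normalized=True`` (default) each pair's raw distance is divided
    by ``sum_i b_i (p_i(A) + p_i(B))``, giving values in [0, 1].
    """
    lengths, P = _branch_profiles(table, tree)
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = float(lengths @ np.abs(P[:, i] - P[:, j]))
            if normalized:
                denom = float(lengths @ (P[:, i] + P[:, j]))
                raw = raw / denom if denom > 0 else 0.0
            D[i, j] = D[j, i] = raw
    return DistanceMatrix(list(table.sample_ids), D)


def pcoa(dist: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical scaling (principal coordinates analysis).

    Double-centers ``-d^2 / 2`` (Gower), eigendecomposes, and scales
    eigenvectors by the square root of their (positive) eigenvalues.
    Negative eigenvalues — possible because UniFrac need not be Euclidean —
    are reported but excluded from the coordinates and from the
    percent-variance denominator.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    n = len(dist.ids)
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 samples, got {n}")
    d2 = dist.values ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = eps * max(1.0, float(np.abs(evals).max()))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        idx = int(np.argmax(np.abs(coords[:, k])))
        if coords[idx, k] < 0:
            coords[:, k] = -coords[:, k]
    pct = 100.0 * evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PC{k + 1}" for k in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dist.ids, columns=cols),
        eigenvalues=evals,
        percent_variance=pct,
    )


def occupancy_summary(table: OtuTable, metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Habitat occupancy per OTU, plus per-location OTU richness.

    ``metadata`` must be indexed by sample id with ``location`` and
    ``site_type`` columns covering every table sample.  Detection is at
    least one read in the (curated) table.  An OTU seen in exactly one
    location is labelled ``specific``, otherwise ``shared``.
    """
    missing = sorted(set(table.sample_ids) - set(metadata.index.astype(str)))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    loc = metadata["location"].astype(str)
    site = metadata["site_type"].astype(str)
    rows = []
    for otu in table.otu_ids:
        present = [s for s in table.sample_ids if table.counts.at[otu, s] > 0]
        locs = sorted({loc[s] for s in present})
        sites = sorted({site[s] for s in present})
        rows.append(
            (
                otu,
                ";".join(locs),
                ";".join(sites),
                len(locs),
                len(present),
                "specific" if len(locs) == 1 else ("shared" if locs else "absent"),
            )
        )
    summary = pd.DataFrame(
        rows,
        columns=["otu_id", "locations", "site_types", "n_locations", "n_samples", "specificity"],
    ).set_index("otu_id")
    present_mask = table.counts > 0
    richness = {}
    for location in sorted(loc[table.sample_ids].unique()):
        samples = [s for s in table.sample_ids if loc[s] == location]
        richness[location] = int(present_mask[samples].any(axis=1).sum())
    return summary, pd.Series(richness, name="otu_richness")


def top_k_fraction(table: OtuTable, k: int) -> tuple[float, list[str]]:
    """Fraction of all reads held by the ``k`` most abundant OTUs.

    Returns ``(fraction, otu_ids)``, ids in descending-abundance order.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(table.otu_ids):
        raise ValueError(f"k={k} exceeds OTU count {len(table.otu_ids)}")
    sums = table.otu_sums().sort_values(ascending=False, kind="stable")
    top = sums.iloc[:k]
    total = table.total_reads()
    if total == 0:
        raise ValueError("table has no reads")
    return float(top.sum() / total), list(top.index)
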