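"""Readers and writers for the pipeline's plain-text formats.

Formats: OTU table TSV (first column ``otu_id``, header row of sample ids,
integer cells), Newick trees with branch lengths, FASTA with
``>id;size=N;sample=S`` annotations, metadata TSV, curation-report TSV,
and JSON ground truth.  Output files carry ``#``-prefixed header comments
recording the seed and parameter fingerprint of the run that produced
them; readers skip such lines.  Parsers reject malformed input rather
than coercing it.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

from .curation import CurationReport, OtuTable
from .simulate import Read, SimTruth

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "write_newick",
    "read_reads_fasta",
    "write_reads_fasta",
    "read_metadata",
    "write_metadata",
    "read_id_list",
    "write_report",
    "write_truth",
    "read_truth",
]


def _header_lines(header: dict | None) -> list[str]:
    if not header:
        return []
    return [f"# {k}={v}" for k, v in header.items()]


def read_otu_table(path: str | Path) -> OtuTable:
    """Read the OTU-table TSV dialect, validating ids and cells."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty table file")
    header = lines[0].split("\t")
    if header[0] != "otu_id":
        raise ValueError(f"{path}:1: first column must be 'otu_id', got {header[0]!r}")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"{path}:1: duplicate sample id(s) {dup}")
    otu_ids: list[str] = []
    rows = []
    seen = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}")
        otu = parts[0]
        if otu in seen:
            raise ValueError(f"{path}:{lineno}: duplicate otu_id {otu!r}")
        seen.add(otu)
        cells = []
        for p in parts[1:]:
            if not re.fullmatch(r"\d+", p):
                raise ValueError(f"{path}:{lineno}: non-integer or negative cell {p!r}")
            cells.append(int(p))
        otu_ids.append(otu)
        rows.append(cells)
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(samples)), np.int64)
    return OtuTable(pd.DataFrame(counts, index=otu_ids, columns=samples))


def write_otu_table(table: OtuTable, path: str | Path, header: dict | None = None) -> None:
    """Write the TSV dialect in canonical order (OTUs by descending total,
    samples in table order); round-trips byte-identically."""
    path = Path(path)
    order = table.otu_sums().sort_values(ascending=False, kind="stable").index
    df = table.counts.loc[order]
    lines = _header_lines(header)
    lines.append("\t".join(["otu_id", *df.columns]))
    for otu, row in df.iterrows():
        lines.append("\t".join([str(otu), *map(str, row.to_numpy())]))
    path.write_text("\n".join(lines) + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree, requiring a branch length on every
    non-root edge (zero lengths are legal)."""
    path = Path(path)
    text = path.read_text().strip()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate leaf labels")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            lab = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"{path}: missing branch length above node {lab}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    )


_FASTA_RE = re.compile(r"^(?P<id>[^;]+);size=(?P<size>\d+);sample=(?P<sample>.+)$")


def read_reads_fasta(paths: Iterable[str | Path] | str | Path) -> list[Read]:
    """Read labelled merged reads from FASTA with ``>id;size=N;sample=S``."""
    from Bio import SeqIO

    if isinstance(paths, (str, Path)):
        paths = [paths]
    reads = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            m = _FASTA_RE.match(rec.description)
            if not m:
                raise ValueError(f"{path}: malformed FASTA header {rec.description!r}")
            seq = str(rec.seq).upper()
            reads.append(Read(m["id"], m["sample"], seq, int(m["size"])))
    return reads


def write_reads_fasta(reads: list[Read], path: str | Path, header: dict | None = None) -> None:
    # FASTA has no portable comment syntax; provenance lives in the manifest
    lines: list[str] = []
    for r in reads:
        lines.append(f">{r.read_id};size={r.count};sample={r.sample_id}")
        lines.append(r.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "location", "site_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample id(s) {dup}")
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    lines = _header_lines(header)
    lines.append("\t".join(["sample_id", *metadata.columns]))
    for sid, row in metadata.iterrows():
        lines.append("\t".join([str(sid), *map(str, row.to_numpy())]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and ``#`` comments ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    return out


def write_report(report: CurationReport, path: str | Path, header: dict | None = None) -> None:
    df = report.to_dataframe()
    lines = _header_lines(header)
    lines.append("\t".join(df.columns))
    for _, row in df.iterrows():
        lines.append("\t".join("" if v is None else str(v) for v in row.to_numpy()))
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Serialize ground truth as JSON (tree as a Newick string)."""
    payload = {
        "clean_table": {
            "otu_ids": truth.clean_table.otu_ids,
            "sample_ids": truth.clean_table.sample_ids,
            "counts": truth.clean_table.counts.to_numpy().tolist(),
        },
        "contaminant_otu_ids": sorted(truth.contaminant_otu_ids),
        "switch_moves": truth.switch_moves,
        "switched_cells": truth.switched_cells,
        "failed_sample_ids": sorted(truth.failed_sample_ids),
        "chimera_seq_ids": sorted(truth.chimera_seq_ids),
        "chimera_parents": {k: list(v) for k, v in truth.chimera_parents.items()},
        "habitat_map": {k: sorted(v) for k, v in truth.habitat_map.items()},
        "tree_newick": (
            truth.tree.as_string(schema="newick", suppress_rooting=True) if truth.tree is not None else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    ct = payload["clean_table"]
    clean = OtuTable(pd.DataFrame(np.array(ct["counts"], dtype=np.int64), index=ct["otu_ids"], columns=ct["sample_ids"]))
    tree = None
    if payload.get("tree_newick"):
        tree = dendropy.Tree.get(data=payload["tree_newick"], schema="newick", preserve_underscores=True)
        tree.is_rooted = True
    return SimTruth(
        clean_table=clean,
        contaminant_otu_ids=set(payload["contaminant_otu_ids"]),
        switch_moves=[tuple(m) for m in payload["switch_moves"]],
        switched_cells=[tuple(c) for c in payload["switched_cells"]],
        failed_sample_ids=set(payload["failed_sample_ids"]),
        chimera_seq_ids=set(payload["chimera_seq_ids"]),
        chimera_parents={k: tuple(v) for k, v in payload.get("chimera_parents", {}).items()},
        tree=tree,
        habitat_map={k: set(v) for k, v in payload["habitat_map"].items()},
    )
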