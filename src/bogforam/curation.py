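"""OTU-table curation cascade.

Amplicon OTU tables straight out of clustering carry several classes of
artifact: failed libraries with a few hundred reads, very low-abundance OTUs
that cannot be distinguished from noise, known contaminant lineages, uneven
sequencing depth, and low-count cells created by index switching (tag
jumping) between multiplexed libraries.  This module implements a
deterministic, fully audited cascade that addresses each in turn:

1. unrarefied filtering to a fixpoint (sample read floor, OTU read floor,
   OTU occurrence floor),
2. removal of externally flagged contaminant OTUs and samples,
3. a full re-check of the unrarefied thresholds,
4. seeded rarefaction without replacement,
5. a two-rule index-switching correction on the rarefied counts,
6. a final total-read filter on OTUs.

Every removal and every zeroed cell is logged in a :class:`CurationReport`
that can be replayed on the input table to reproduce the output bit-exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "CurationParams",
    "CurationStep",
    "CurationReport",
    "filter_unrarefied",
    "drop_flagged",
    "rarefy",
    "correct_index_switching",
    "final_otu_filter",
    "run_curation",
]


class OtuTable:
    """An OTU-by-sample table of non-negative integer read counts.

    Rows are OTUs, columns are samples.  Wraps a :class:`pandas.DataFrame`
    with integer dtype; identifiers must be unique strings and counts
    non-negative.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self._df = pd.DataFrame(
            arr.astype(np.int64) if arr.size else np.zeros(counts.shape, np.int64),
            index=counts.index.astype(str),
            columns=counts.columns.astype(str),
        )
        self._df.index.name = "otu_id"

    # -- constructors -------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, int]], sample_ids: Sequence[str] | None = None) -> "OtuTable":
        """Build from ``{otu_id: {sample_id: count}}`` (missing cells are 0)."""
        df = pd.DataFrame.from_dict(d, orient="index").fillna(0)
        if sample_ids is not None:
            df = df.reindex(columns=list(sample_ids), fill_value=0)
        return cls(df)

    # -- accessors ----------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        return self._df

    @property
    def otu_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def total_reads(self) -> int:
        return int(self._df.to_numpy().sum())

    def sample_sums(self) -> pd.Series:
        return self._df.sum(axis=0)

    def otu_sums(self) -> pd.Series:
        return self._df.sum(axis=1)

    def occurrence(self) -> pd.Series:
        """Number of samples in which each OTU has a nonzero count."""
        return (self._df > 0).sum(axis=1)

    def copy(self) -> "OtuTable":
        return OtuTable(self._df.copy())

    def drop_samples(self, ids: Iterable[str]) -> "OtuTable":
        ids = [s for s in ids if s in self._df.columns]
        return OtuTable(self._df.drop(columns=ids))

    def drop_otus(self, ids: Iterable[str]) -> "OtuTable":
        ids = [o for o in ids if o in self._df.index]
        return OtuTable(self._df.drop(index=ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} OTUs x {m} samples, {self.total_reads()} reads)"


@dataclass(frozen=True)
class CurationParams:
    """Thresholds of the curation cascade.

    min_sample_reads
        Unrarefied read floor for a sample; columns summing below it are
        treated as failed libraries and dropped (default 500).
    min_otu_reads
        Unrarefied read floor for an OTU row (default 100).
    min_otu_occurrence
        Minimum number of samples an OTU must occur in (default 2; an OTU
        seen in only one sample is dropped).
    rarefaction_depth
        Reads drawn per sample during rarefaction; shallower samples are
        kept whole (default 10_000).
    big_otu_total
        Rarefied row-total above which the aggressive index-switching rule
        applies (default 1000).
    big_otu_cell_floor
        Under the aggressive rule, cells below this value are zeroed
        (default 20).
    small_otu_cell_floor
        Under the conservative rule, cells at or below this value are
        zeroed (default 1).
    final_min_otu_reads
        Final filter: OTUs are kept only with strictly more total rarefied
        reads than this (default 20).
    """

    min_sample_reads: int = 500
    min_otu_reads: int = 100
    min_otu_occurrence: int = 2
    rarefaction_depth: int = 10_000
    big_otu_total: int = 1000
    big_otu_cell_floor: int = 20
    small_otu_cell_floor: int = 1
    final_min_otu_reads: int = 20

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.big_otu_cell_floor >= self.big_otu_total:
            raise ValueError("big_otu_cell_floor must be < big_otu_total")


@dataclass
class CurationStep:
    """One audited step: what was removed or zeroed, and why."""

    name: str
    removed_samples: list[str] = field(default_factory=list)
    removed_otus: list[str] = field(default_factory=list)
    # (otu_id, sample_id, value_before, value_after)
    cell_updates: list[tuple[str, str, int, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def is_noop(self) -> bool:
        return not (self.removed_samples or self.removed_otus or self.cell_updates)


@dataclass
class CurationReport:
    """Ordered ledger of curation steps; replayable on the input table."""

    steps: list[CurationStep] = field(default_factory=list)

    def extend(self, other: "CurationReport") -> None:
        self.steps.extend(other.steps)

    def removed_sample_ids(self) -> set[str]:
        return {s for st in self.steps for s in st.removed_samples}

    def removed_otu_ids(self) -> set[str]:
        return {o for st in self.steps for o in st.removed_otus}

    def replay(self, table: OtuTable) -> OtuTable:
        """Re-apply every logged step to ``table``.

        Replaying the report produced by a curation run on that run's input
        reproduces the run's output exactly.
        """
        df = table.counts.copy()
        for st in self.steps:
            for o in st.removed_otus:
                if o not in df.index:
                    raise ValueError(f"replay: OTU {o!r} not present at step {st.name!r}")
            for s in st.removed_samples:
                if s not in df.columns:
                    raise ValueError(f"replay: sample {s!r} not present at step {st.name!r}")
            df = df.drop(index=st.removed_otus, columns=st.removed_samples)
            for otu, sample, before, after in st.cell_updates:
                if int(df.at[otu, sample]) != before:
                    raise ValueError(
                        f"replay: cell ({otu},{sample}) was {df.at[otu, sample]}, expected {before}"
                    )
                df.at[otu, sample] = after
        return OtuTable(df)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format view: step, kind, id_or_cell, reason, value_before, value_after."""
        rows = []
        for i, st in enumerate(self.steps):
            reason = st.params.get("reason", st.name)
            for s in st.removed_samples:
                rows.append((i, st.name, "sample", s, reason, None, None))
            for o in st.removed_otus:
                rows.append((i, st.name, "otu", o, reason, None, None))
            for otu, sample, before, after in st.cell_updates:
                rows.append((i, st.name, "cell", f"{otu}:{sample}", reason, before, after))
            for note in st.notes:
                rows.append((i, st.name, "note", note, reason, None, None))
        return pd.DataFrame(
            rows,
            columns=["step_index", "step", "kind", "id_or_cell", "reason", "value_before", "value_after"],
        )


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------

def filter_unrarefied(
    table: OtuTable, params: CurationParams = CurationParams()
) -> tuple[OtuTable, CurationReport]:
    """Drop failed samples and noise OTUs, iterating to a fixpoint.

    Each pass drops samples with fewer than ``min_sample_reads`` total reads,
    then OTUs with fewer than ``min_otu_reads`` total reads or present in
    fewer than ``min_otu_occurrence`` samples.  Removing OTUs can push more
    samples under the floor (and vice versa), so passes repeat until nothing
    changes.  The returned table satisfies all three thresholds
    simultaneously; an empty result is legal.
    """
    report = CurationReport()
    df = table.counts
    passno = 0
    while True:
        passno += 1
        bad_samples = list(df.columns[df.sum(axis=0) < params.min_sample_reads])
        df = df.drop(columns=bad_samples)
        row_sums = df.sum(axis=1)
        occ = (df > 0).sum(axis=1)
        bad_otus = list(df.index[(row_sums < params.min_otu_reads) | (occ < params.min_otu_occurrence)])
        df = df.drop(index=bad_otus)
        step = CurationStep(
            name=f"filter_unrarefied_pass{passno}",
            removed_samples=bad_samples,
            removed_otus=bad_otus,
            params={
                "min_sample_reads": params.min_sample_reads,
                "min_otu_reads": params.min_otu_reads,
                "min_otu_occurrence": params.min_otu_occurrence,
            },
        )
        if step.is_noop():
            break
        report.steps.append(step)
    return OtuTable(df), report


def drop_flagged(
    table: OtuTable,
    flagged_otus: Iterable[str] = (),
    flagged_samples: Iterable[str] = (),
) -> tuple[OtuTable, CurationReport]:
    """Remove externally flagged contaminant OTUs and samples.

    Flags come from outside the pipeline (e.g. phylogenetic placement near
    marine lineages, BLAST hits).  Flagged ids absent from the table are
    recorded as no-ops with a warning note rather than raising.
    """
    flagged_otus = sorted(set(flagged_otus))
    flagged_samples = sorted(set(flagged_samples))
    present_otus = [o for o in flagged_otus if o in table.counts.index]
    present_samples = [s for s in flagged_samples if s in table.counts.columns]
    notes = [
        f"flagged id {x!r} not present; ignored"
        for x in (set(flagged_otus) - set(present_otus)) | (set(flagged_samples) - set(present_samples))
    ]
    step = CurationStep(
        name="drop_flagged",
        removed_samples=present_samples,
        removed_otus=present_otus,
        params={"reason": "flagged contaminant"},
        notes=sorted(notes),
    )
    out = OtuTable(table.counts.drop(index=present_otus, columns=present_samples))
    return out, CurationReport(steps=[step] if not step.is_noop() or notes else [])


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # sub-seed from the sample identifier so column order is irrelevant
    return np.random.default_rng([int(seed), zlib.crc32(sample_id.encode())])


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each column to ``depth`` reads without replacement.

    Columns totalling more than ``depth`` are drawn down to exactly
    ``depth`` via a multivariate hypergeometric draw; shallower columns are
    left untouched (all their reads are considered).  One independent draw
    per sample, sub-seeded from ``seed`` and the sample id, so results do
    not depend on column order.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    df = table.counts.copy()
    for sample in df.columns:
        col = df[sample].to_numpy()
        total = int(col.sum())
        if total <= depth:
            continue
        rng = _sample_rng(seed, sample)
        df[sample] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(df)


def _rarefy_report(before: OtuTable, after: OtuTable, depth: int, seed: int) -> CurationReport:
    b, a = before.counts, after.counts
    updates = []
    diff = b.to_numpy() != a.to_numpy()
    for i, j in zip(*np.nonzero(diff)):
        updates.append((b.index[i], b.columns[j], int(b.iat[i, j]), int(a.iat[i, j])))
    step = CurationStep(
        name="rarefy", cell_updates=updates, params={"depth": depth, "seed": seed, "reason": "rarefaction"}
    )
    return CurationReport(steps=[step])


def correct_index_switching(
    table: OtuTable, params: CurationParams = CurationParams()
) -> tuple[OtuTable, CurationReport]:
    """Zero low-count cells attributable to index switching (tag jumping).

    Row totals are computed once on the input (rarefied) table.  Rule 1: in
    rows totalling more than ``big_otu_total`` reads, any occupied cell with
    fewer than ``big_otu_cell_floor`` reads is zeroed.  Rule 2: in the
    remaining rows, any cell at or below ``small_otu_cell_floor`` (default:
    exactly one read) is zeroed.  Rows totalling exactly ``big_otu_total``
    fall under rule 2, the more conservative choice.
    """
    df = table.counts.copy()
    totals = df.sum(axis=1)
    updates = []
    arr = df.to_numpy()
    for i, otu in enumerate(df.index):
        row = arr[i]
        if totals.iloc[i] > params.big_otu_total:
            mask = (row > 0) & (row < params.big_otu_cell_floor)
            reason = "rule1"
        else:
            mask = (row > 0) & (row <= params.small_otu_cell_floor)
            reason = "rule2"
        for j in np.nonzero(mask)[0]:
            updates.append((otu, df.columns[j], int(row[j]), 0))
        row[mask] = 0
    step = CurationStep(
        name="correct_index_switching",
        cell_updates=updates,
        params={
            "big_otu_total": params.big_otu_total,
            "big_otu_cell_floor": params.big_otu_cell_floor,
            "small_otu_cell_floor": params.small_otu_cell_floor,
            "reason": "index switching",
        },
    )
    out = OtuTable(pd.DataFrame(arr, index=df.index, columns=df.columns))
    return out, CurationReport(steps=[step] if not step.is_noop() else [])


def final_otu_filter(
    table: OtuTable, params: CurationParams = CurationParams()
) -> tuple[OtuTable, CurationReport]:
    """Keep only OTUs with strictly more than ``final_min_otu_reads`` total reads."""
    sums = table.otu_sums()
    removed = list(sums.index[sums <= params.final_min_otu_reads])
    step = CurationStep(
        name="final_otu_filter",
        removed_otus=removed,
        params={"final_min_otu_reads": params.final_min_otu_reads},
    )
    out = table.drop_otus(removed)
    return out, CurationReport(steps=[step] if removed else [])


def run_curation(
    table: OtuTable,
    flagged_otus: Iterable[str] = (),
    flagged_samples: Iterable[str] = (),
    params: CurationParams = CurationParams(),
    seed: int = 0,
) -> tuple[OtuTable, CurationReport]:
    """Run the full cascade and return the curated table plus its report.

    Order: unrarefied fixpoint filter -> flagged removals -> unrarefied
    re-check -> rarefaction -> index-switching correction -> final OTU
    filter.  The sample read floor applies to unrarefied counts only:
    samples whose totals fall below it solely through rarefaction or cell
    zeroing are retained.
    """
    report = CurationReport()
    t, r = filter_unrarefied(table, params)
    report.extend(r)
    t, r = drop_flagged(t, flagged_otus, flagged_samples)
    report.extend(r)
    t, r = filter_unrarefied(t, params)
    report.extend(r)
    rarefied = rarefy(t, params.rarefaction_depth, seed)
    report.extend(_rarefy_report(t, rarefied, params.rarefaction_depth, seed))
    t, r = correct_index_switching(rarefied, params)
    report.extend(r)
    t, r = final_otu_filter(t, params)
    report.extend(r)
    return t, report
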