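"""Count-table data model, I/O, relative abundance, prevalence filtering, offsets.

The canonical on-disk format is a wide TSV: first column ``sample_id``,
remaining columns taxon names, integer read counts.  Per-sample metadata
lives in a second TSV with columns ``sample_id, subject_id, group,
gestational_age, total_reads`` where ``group`` is ``term`` or ``preterm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "to_relative_abundance",
    "prevalence_filter",
    "log_offsets",
]

VALID_GROUPS = ("term", "preterm")


class CountTableError(ValueError):
    """Raised on malformed or inconsistent count-table input."""


@dataclass(frozen=True)
class CountTable:
    """Taxon-by-sample read counts (rows = samples, columns = taxa)."""

    samples: tuple[str, ...]
    taxa: tuple[str, ...]
    counts: np.ndarray  # (n_samples, n_taxa) nonnegative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountTableError("counts must be a 2-D matrix")
        if counts.shape != (len(self.samples), len(self.taxa)):
            raise CountTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise CountTableError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise CountTableError("counts must be nonnegative")
        if len(set(self.samples)) != len(self.samples):
            raise CountTableError("duplicate sample IDs")
        if len(set(self.taxa)) != len(self.taxa):
            raise CountTableError("duplicate taxon names")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def totals(self) -> np.ndarray:
        """Per-sample total read counts (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.samples), columns=list(self.taxa))

    def select_taxa(self, names: list[str]) -> "CountTable":
        idx = [self.taxa.index(t) for t in names]
        return CountTable(self.samples, tuple(names), self.counts[:, idx])

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(tuple(sample_ids), self.taxa, self.counts[idx, :])


@dataclass(frozen=True)
class SampleMetadata:
    """One vaginal-fluid sample: subject, study group, gestational age, depth."""

    sample_id: str
    subject_id: str
    group: str  # "term" | "preterm"
    gestational_age: float  # weeks
    total_reads: int

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise CountTableError(
                f"sample {self.sample_id}: group must be one of {VALID_GROUPS}, got {self.group!r}"
            )
        if self.total_reads <= 0:
            raise CountTableError(f"sample {self.sample_id}: total_reads must be positive")
        if not np.isfinite(self.gestational_age):
            raise CountTableError(f"sample {self.sample_id}: gestational_age must be finite")


@dataclass(frozen=True)
class CommunityState:
    """Relative-abundance vector of all phylotypes in one sample."""

    sample_id: str
    abundances: np.ndarray

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if ab.ndim != 1:
            raise CountTableError("abundances must be a vector")
        if ab.size == 0 or ab.min() < 0:
            raise CountTableError("abundances must be nonnegative and nonempty")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise CountTableError(
                f"sample {self.sample_id}: abundances sum to {ab.sum():.12f}, not 1"
            )
        object.__setattr__(self, "abundances", ab)


def read_count_table(path) -> CountTable:
    """Read a wide TSV (first column sample_id, remaining columns taxa).

    Cells must parse as nonnegative integers; taxon order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise CountTableError(f"{path}: no samples (empty file)") from None
    if df.shape[0] == 0:
        raise CountTableError(f"{path}: no samples")
    if df.shape[1] == 0:
        raise CountTableError(f"{path}: no taxa columns")
    samples = tuple(str(s) for s in df.index)
    taxa = tuple(str(t) for t in df.columns)
    counts = np.empty(df.shape, dtype=np.int64)
    values = df.to_numpy()
    for j, taxon in enumerate(taxa):
        col = values[:, j]
        try:
            parsed = col.astype(np.int64)
        except (ValueError, TypeError):
            for i, cell in enumerate(col):
                try:
                    int(cell)
                except (ValueError, TypeError):
                    raise CountTableError(
                        f"{path}: cell at sample {samples[i]!r}, taxon {taxon!r} "
                        f"is not an integer: {cell!r}"
                    ) from None
            raise
        if (parsed < 0).any():
            i = int(np.argmax(parsed < 0))
            raise CountTableError(
                f"{path}: negative count at sample {samples[i]!r}, taxon {taxon!r}"
            )
        counts[:, j] = parsed
    table = CountTable(samples, taxa, counts)
    zero = table.totals() == 0
    if zero.any():
        bad = [samples[i] for i in np.flatnonzero(zero)]
        raise CountTableError(f"{path}: samples with zero total reads: {bad}")
    return table


def write_count_table(table: CountTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path, table: CountTable | None = None) -> list[SampleMetadata]:
    """Read the metadata TSV; if ``table`` is given, cross-check it.

    Row sums of the count table are authoritative: a ``total_reads`` value that
    disagrees with the row sum is an error, and every sample in the table must
    have exactly one metadata record.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    required = {"sample_id", "subject_id", "group", "gestational_age", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise CountTableError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise CountTableError(f"{path}: duplicate sample_id rows")
    records = [
        SampleMetadata(
            sample_id=row.sample_id,
            subject_id=row.subject_id,
            group=str(row.group),
            gestational_age=float(row.gestational_age),
            total_reads=int(row.total_reads),
        )
        for row in df.itertuples()
    ]
    if table is not None:
        validate_metadata(table, records)
    return records


def write_metadata(meta: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "subject_id": [m.subject_id for m in meta],
            "group": [m.group for m in meta],
            "gestational_age": [m.gestational_age for m in meta],
            "total_reads": [m.total_reads for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def validate_metadata(table: CountTable, meta: list[SampleMetadata]) -> None:
    """Enforce the table/metadata contract (coverage, totals, GA ordering)."""
    by_id = {m.sample_id: m for m in meta}
    if len(by_id) != len(meta):
        raise CountTableError("duplicate sample_id in metadata")
    totals = table.totals()
    for i, sid in enumerate(table.samples):
        m = by_id.get(sid)
        if m is None:
            raise CountTableError(f"sample {sid!r} has no metadata record")
        if m.total_reads != totals[i]:
            raise CountTableError(
                f"sample {sid!r}: metadata total_reads {m.total_reads} != row sum {totals[i]}"
            )
    # gestational ages strictly increasing within subject, in listed visit order
    order: dict[str, float] = {}
    for m in meta:
        prev = order.get(m.subject_id)
        if prev is not None and m.gestational_age <= prev:
            raise CountTableError(
                f"subject {m.subject_id}: gestational ages not strictly increasing "
                f"({prev} then {m.gestational_age})"
            )
        order[m.subject_id] = m.gestational_age


def to_relative_abundance(table: CountTable) -> list[CommunityState]:
    """Convert counts to per-sample community states (vectors summing to 1)."""
    totals = table.totals()
    zero = totals == 0
    if zero.any():
        bad = [table.samples[i] for i in np.flatnonzero(zero)]
        raise CountTableError(f"samples with zero total reads: {bad}")
    rel = table.counts / totals[:, None]
    return [CommunityState(sid, rel[i]) for i, sid in enumerate(table.samples)]


def prevalence_filter(table: CountTable, min_prevalence: float = 0.25) -> CountTable:
    """Keep taxa present (count >= 1) in at least ``min_prevalence`` of samples.

    The boundary is inclusive: a taxon present in exactly 25% of samples is
    retained at the default threshold.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in (0, 1], got {min_prevalence}")
    prevalence = (table.counts >= 1).mean(axis=0)
    keep = prevalence >= min_prevalence - 1e-12
    taxa = tuple(t for t, k in zip(table.taxa, keep) if k)
    return CountTable(table.samples, taxa, table.counts[:, keep])


def log_offsets(meta: list[SampleMetadata]) -> np.ndarray:
    """Natural-log total read counts, in metadata order (the model offset)."""
    totals = np.array([m.total_reads for m in meta], dtype=float)
    if (totals <= 0).any():
        bad = [meta[i].sample_id for i in np.flatnonzero(totals <= 0)]
        raise CountTableError(f"nonpositive total_reads for samples: {bad}")
    return np.log(totals)
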