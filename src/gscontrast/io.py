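"""Readers and writers for the formats the pipeline touches.

All downstream modules consume only the domain containers defined here:
:class:`CountMatrix`, :class:`SampleSheet`, :class:`GeneSetCollection`
and :class:`SummaryStatsTable`. Gene identifiers are opaque strings —
no identifier translation is performed, so count matrices and gene-set
collections must already share a namespace (a warning is emitted when
fewer than half of a collection's members appear in a matrix).

Formats: counts as TSV (gene ids in the first column, sample ids in the
header) or as a MatrixMarket triplet (``.mtx`` plus row-name and
column-name files); gene sets as Broad-dialect GMT (name, description,
members, tab-separated); sample sheets and all outputs as plain TSV,
UTF-8, no quoting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_LEVELS = ("young", "aging")
TREATMENT_LEVELS = ("sham", "DOCA")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise FormatError("a count matrix needs at least 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-8):
                bad = np.argwhere(~np.isclose(self.counts, rounded))[0]
                raise FormatError(
                    f"non-integer count for gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count for gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to ``keep`` (order preserved)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
        return CountMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.counts[idx]
        )

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return CountMatrix(list(self.gene_ids), list(keep), self.counts[:, idx])


@dataclass
class SampleSheet:
    """Sample annotations: age group (young/aging) and treatment (sham/DOCA)."""

    table: pd.DataFrame  # columns: sample_id, age_group, treatment

    def __post_init__(self) -> None:
        required = {"sample_id", "age_group", "treatment"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        _check_unique(list(self.table["sample_id"]), "sample")
        bad_age = set(self.table["age_group"]) - set(AGE_LEVELS)
        if bad_age:
            raise FormatError(f"unknown age_group values: {sorted(bad_age)}")
        bad_trt = set(self.table["treatment"]) - set(TREATMENT_LEVELS)
        if bad_trt:
            raise FormatError(f"unknown treatment values: {sorted(bad_trt)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_label(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return f"{row.iloc[0]['age_group']}-{row.iloc[0]['treatment']}"

    def samples_in_group(self, group: str) -> list[str]:
        """Samples matching a ``age-treatment`` label, e.g. ``young-DOCA``."""
        age, trt = group.split("-", 1)
        m = (self.table["age_group"] == age) & (self.table["treatment"] == trt)
        return list(self.table.loc[m, "sample_id"])

    def validate_against(self, counts: CountMatrix) -> None:
        sheet_ids = set(self.sample_ids)
        matrix_ids = set(counts.sample_ids)
        if sheet_ids != matrix_ids:
            raise FormatError(
                f"sample sheet / count matrix mismatch: only in sheet "
                f"{sorted(sheet_ids - matrix_ids)}, only in matrix "
                f"{sorted(matrix_ids - sheet_ids)}"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets with description strings (GMT-backed).

    ``sets`` maps set name -> ordered, deduplicated member list;
    ``descriptions`` maps set name -> free-text description.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning("gene set %r has duplicate members; deduplicated", name)
                self.sets[name] = deduped
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, universe: Iterable[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(kept, {n: self.descriptions[n] for n in kept})

    def coverage_warning(self, counts: CountMatrix, threshold: float = 0.5) -> float:
        """Warn when the collection and matrix barely share a namespace."""
        members = {g for ms in self.sets.values() for g in ms}
        if not members:
            return 0.0
        frac = len(members & set(counts.gene_ids)) / len(members)
        if frac < threshold:
            warnings.warn(
                f"only {frac:.0%} of gene-set members appear in the count matrix; "
                "the collection and matrix may use different identifier namespaces",
                stacklevel=2,
            )
        return frac


@dataclass
class SummaryStatsTable:
    """Per-group (mean, SEM, n) cells for phenotype endpoints.

    ``cells`` maps endpoint -> {group label -> (mean, sem, n)}. For
    factorial use the group labels must form the complete 2x2 grid
    young-sham / young-DOCA / aging-sham / aging-DOCA.
    """

    cells: dict[str, dict[str, tuple[float, float, int]]]

    def __post_init__(self) -> None:
        for endpoint, groups in self.cells.items():
            for label, (mean, sem, n) in groups.items():
                if n < 2:
                    raise FormatError(
                        f"endpoint {endpoint!r}, cell {label!r}: n must be >= 2, got {n}"
                    )
                if not sem > 0:
                    raise FormatError(
                        f"endpoint {endpoint!r}, cell {label!r}: SEM must be > 0, got {sem}"
                    )

    @property
    def endpoints(self) -> list[str]:
        return list(self.cells)

    def grid(self, endpoint: str) -> dict[str, tuple[float, float, int]]:
        return self.cells[endpoint]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"endpoint": e, "group": g, "mean": m, "sem": s, "n": n}
            for e, groups in self.cells.items()
            for g, (m, s, n) in groups.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SummaryStatsTable":
        cells: dict[str, dict[str, tuple[float, float, int]]] = {}
        for _, row in frame.iterrows():
            cells.setdefault(str(row["endpoint"]), {})[str(row["group"])] = (
                float(row["mean"]),
                float(row["sem"]),
                int(row["n"]),
            )
        return cls(cells)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, layout: str = "tsv") -> CountMatrix:
    """Read a gene-level count matrix.

    Parameters
    ----------
    path
        For ``layout="tsv"``: a TSV with gene ids in the first column and
        sample ids in the header. For ``layout="matrixmarket"``: the
        ``.mtx`` file; row names are read from ``<stem>.rownames.txt``
        and column names from ``<stem>.colnames.txt`` next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "tsv":
        return _read_counts_tsv(path)
    if layout == "matrixmarket":
        return _read_counts_mtx(path)
    raise ValueError(f"unknown layout {layout!r}")


def _read_counts_tsv(path: Path) -> CountMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric count: {exc}") from exc
    counts = np.array(rows) if rows else np.empty((0, len(sample_ids)))
    return CountMatrix(gene_ids, sample_ids, counts)


def _read_counts_mtx(path: Path) -> CountMatrix:
    from scipy.io import mmread

    raw = mmread(path)
    mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
    stem = path.with_suffix("")
    gene_ids = Path(f"{stem}.rownames.txt").read_text(encoding="utf-8").split()
    sample_ids = Path(f"{stem}.colnames.txt").read_text(encoding="utf-8").split()
    return CountMatrix(gene_ids, sample_ids, mat)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a count matrix as TSV (inverse of :func:`read_counts`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(counts.sample_ids) + "\n")
        for g, row in zip(counts.gene_ids, counts.counts):
            fh.write(g + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(table)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and at "
                    f"least one member (got {len(fields)} fields)"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.warning(
                    "%s:%d: set %r has duplicate members; deduplicated", path, lineno, name
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_summary_stats(path: str | Path) -> SummaryStatsTable:
    """Read a phenotype summary table (endpoint, group, mean, sem, n)."""
    return SummaryStatsTable.from_frame(pd.read_csv(path, sep="\t"))


def write_summary_stats(table: SummaryStatsTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_results_table(
    records: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    float_digits: int = 6,
) -> None:
    """Write records as a TSV with a deterministic column order.

    Floats are formatted at ``float_digits`` significant digits; the
    column order is that of the first record (or the frame's columns).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
        if len(frame) == 0 and records is not None:
            frame = pd.DataFrame(columns=list(records[0]) if len(records) else [])
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{float_digits}g")
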