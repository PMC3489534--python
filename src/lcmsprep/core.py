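"""Data containers and table I/O for peptide-level LC-MS abundance data.

The central object is :class:`AbundanceMatrix`, a peptide-by-sample matrix of
log-scale abundances in which missing cells are carried explicitly as ``NaN``.
A :class:`StudyDesign` assigns each sample to a treatment group (and optionally
a batch), and a :class:`ProteinMap` assigns each peptide to exactly one parent
protein.  All downstream normalization, missing-data modelling and inference
operate on these three objects.

File formats are deliberately minimal:

* abundance table -- header ``peptide_id<sep>sample1<sep>...`` followed by one
  row per peptide; an empty cell, ``NA`` or ``NaN`` (case-insensitive) marks a
  missing value, and written output always uses the empty string;
* design table -- columns ``sample_id``, ``group`` and optionally ``batch``;
* protein map -- columns ``peptide_id``, ``protein_id``.

Matrices are peptide-major everywhere (rows are peptides).  Indices are
0-based internally; user-facing error messages are 1-based.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AbundanceMatrix",
    "StudyDesign",
    "ProteinMap",
    "read_abundance_table",
    "write_abundance_table",
    "read_design_table",
    "read_protein_map",
    "log_transform",
    "complete_rows",
]

#: Tokens accepted as missing on input (compared lower-cased, stripped).
MISSING_TOKENS = {"", "na", "nan"}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class AbundanceMatrix:
    """Peptide x sample abundance matrix with an explicit missingness mask.

    Parameters
    ----------
    values
        Float matrix of shape ``(n_peptides, n_samples)``.  ``NaN`` encodes a
        missing cell; every non-missing entry must be finite.
    peptide_ids, sample_ids
        Unique row and column labels.
    log_base
        Base of the logarithm the values are on, or ``None`` for raw
        (untransformed) intensities.
    """

    values: np.ndarray
    peptide_ids: list[str]
    sample_ids: list[str]
    log_base: float | None = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.peptide_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.peptide_ids)} peptides x {len(self.sample_ids)} samples"
            )
        _check_unique(self.peptide_ids, "peptide id")
        _check_unique(self.sample_ids, "sample id")
        if np.isinf(self.values).any():
            raise ValueError("non-missing values must be finite")
        if self.log_base is not None and self.log_base <= 0:
            raise ValueError("log_base must be positive")

    # -- basic introspection -------------------------------------------------

    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, ``True`` where a cell is missing."""
        return np.isnan(self.values)

    @property
    def is_raw(self) -> bool:
        return self.log_base is None

    def copy(self) -> "AbundanceMatrix":
        return replace(self, values=self.values.copy(),
                       peptide_ids=list(self.peptide_ids),
                       sample_ids=list(self.sample_ids))

    def row_index(self, peptide_id: str) -> int:
        try:
            return self.peptide_ids.index(peptide_id)
        except ValueError:
            raise KeyError(f"unknown peptide id {peptide_id!r}") from None

    def subset(self, peptide_ids: Iterable[str]) -> "AbundanceMatrix":
        """Row subset in the given order (used for per-protein sub-matrices)."""
        ids = list(peptide_ids)
        idx = [self.row_index(p) for p in ids]
        return AbundanceMatrix(self.values[idx].copy(), ids,
                               list(self.sample_ids), self.log_base)


@dataclass
class StudyDesign:
    """Sample-to-group (and optional batch) assignment.

    ``sample_ids`` must match an abundance matrix's sample ids as a set; use
    :meth:`aligned_to` to reorder the design to a matrix's column order.
    """

    sample_ids: list[str]
    group: list[str]
    batch: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        _check_unique(self.sample_ids, "sample id")
        if len(self.group) != len(self.sample_ids):
            raise ValueError("group must have one entry per sample")
        if self.batch is not None:
            self.batch = [str(b) for b in self.batch]
            if len(self.batch) != len(self.sample_ids):
                raise ValueError("batch must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, lexically sorted.

        Sorted levels make two-group contrasts well defined: the reported
        difference is always (first sorted group) - (second), so relabelling
        the groups flips its sign.
        """
        return sorted(set(self.group))

    @property
    def batches(self) -> list[str]:
        if self.batch is None:
            return []
        return sorted(set(self.batch))

    def group_index(self) -> np.ndarray:
        """Integer group index per sample (0-based, sorted label order)."""
        levels = {g: i for i, g in enumerate(self.groups)}
        return np.array([levels[g] for g in self.group], dtype=int)

    def batch_index(self) -> np.ndarray | None:
        if self.batch is None:
            return None
        levels = {b: i for i, b in enumerate(self.batches)}
        return np.array([levels[b] for b in self.batch], dtype=int)

    def aligned_to(self, sample_ids: Sequence[str]) -> "StudyDesign":
        """Return a copy reordered to ``sample_ids`` (must be the same set)."""
        if set(sample_ids) != set(self.sample_ids):
            raise ValueError("design sample ids do not match matrix sample ids")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        order = [pos[s] for s in sample_ids]
        return StudyDesign(
            [self.sample_ids[i] for i in order],
            [self.group[i] for i in order],
            None if self.batch is None else [self.batch[i] for i in order],
        )


@dataclass
class ProteinMap:
    """Many-to-one peptide -> protein mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    def protein_of(self, peptide_id: str) -> str:
        try:
            return self.mapping[peptide_id]
        except KeyError:
            raise KeyError(f"peptide {peptide_id!r} not in protein map") from None

    def proteins(self) -> list[str]:
        """Distinct protein ids in order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for prot in self.mapping.values():
            if prot not in seen:
                seen.add(prot)
                out.append(prot)
        return out

    def peptides_for(self, protein_id: str) -> list[str]:
        return [p for p, q in self.mapping.items() if q == protein_id]

    def validate_against(self, m: AbundanceMatrix) -> None:
        missing = [p for p in m.peptide_ids if p not in self.mapping]
        if missing:
            raise ValueError(
                f"{len(missing)} matrix peptide id(s) absent from protein map, "
                f"first: {missing[0]!r}"
            )

    def by_protein(self, m: AbundanceMatrix) -> dict[str, list[int]]:
        """Row indices of ``m`` grouped by protein, protein order preserved."""
        self.validate_against(m)
        out: dict[str, list[int]] = {}
        for i, pep in enumerate(m.peptide_ids):
            out.setdefault(self.mapping[pep], []).append(i)
        return out


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError("dialect must be 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_abundance_table(path: str | Path, dialect: str | None = None,
                         log_base: float | None = 2.0) -> AbundanceMatrix:
    """Read a wide peptide x sample table.

    The first column holds peptide ids, the remaining columns one sample each.
    Empty cells, ``NA`` and ``NaN`` (any case) are missing.  ``log_base``
    records the scale the file is on (``None`` = raw intensities); the file
    itself carries no scale metadata.
    """
    sep = _sep_for(path, dialect)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ValueError(f"{path}: header must name at least one sample")
        sample_ids = [h.strip() for h in header[1:]]
        n_cols = len(header)
        peptide_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: row {lineno} has {len(row)} fields, expected {n_cols}"
                )
            pid = row[0].strip()
            if pid in peptide_ids:
                raise ValueError(f"{path}: duplicate peptide id {pid!r} at row {lineno}")
            vals: list[float] = []
            for j, tok in enumerate(row[1:], start=1):
                t = tok.strip()
                if t.lower() in MISSING_TOKENS:
                    vals.append(math.nan)
                    continue
                try:
                    vals.append(float(t))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} at row {lineno}, "
                        f"column {j + 1} (sample {sample_ids[j - 1]!r})"
                    ) from None
            peptide_ids.append(pid)
            rows.append(vals)
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    return AbundanceMatrix(values, peptide_ids, sample_ids, log_base=log_base)


def write_abundance_table(m: AbundanceMatrix, path: str | Path,
                          dialect: str | None = None) -> None:
    """Write a matrix back to TSV/CSV; missing cells become empty strings."""
    sep = _sep_for(path, dialect)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["peptide_id", *m.sample_ids])
        for pid, row in zip(m.peptide_ids, m.values):
            writer.writerow([pid] + ["" if np.isnan(v) else repr(float(v)) for v in row])


def read_design_table(path: str | Path, dialect: str | None = None) -> StudyDesign:
    """Read a design table with columns ``sample_id``, ``group``[, ``batch``]."""
    sep = _sep_for(path, dialect)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = [h.strip() for h in next(reader)]
        cols = {name: i for i, name in enumerate(header)}
        for required in ("sample_id", "group"):
            if required not in cols:
                raise ValueError(f"{path}: missing required column {required!r}")
        samples, groups, batches = [], [], []
        has_batch = "batch" in cols
        for row in reader:
            if not row:
                continue
            samples.append(row[cols["sample_id"]].strip())
            groups.append(row[cols["group"]].strip())
            if has_batch:
                batches.append(row[cols["batch"]].strip())
    return StudyDesign(samples, groups, batches if has_batch else None)


def read_protein_map(path: str | Path, dialect: str | None = None) -> ProteinMap:
    """Read a two-column ``peptide_id``, ``protein_id`` table."""
    sep = _sep_for(path, dialect)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        header = [h.strip() for h in next(reader)]
        cols = {name: i for i, name in enumerate(header)}
        for required in ("peptide_id", "protein_id"):
            if required not in cols:
                raise ValueError(f"{path}: missing required column {required!r}")
        for row in reader:
            if not row:
                continue
            pep = row[cols["peptide_id"]].strip()
            if pep in mapping:
                raise ValueError(f"{path}: peptide {pep!r} mapped more than once")
            mapping[pep] = row[cols["protein_id"]].strip()
    return ProteinMap(mapping)


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------


def log_transform(m: AbundanceMatrix, base: float = 2.0) -> AbundanceMatrix:
    """Log-transform a raw-intensity matrix.

    Log base two is the working default so that unit differences read as
    two-fold changes.  Non-positive intensities are refused rather than
    silently treated as missing or censored; that call is the user's.
    """
    if not m.is_raw:
        raise ValueError("matrix is already on a log scale")
    if base <= 0 or base == 1.0:
        raise ValueError("log base must be positive and != 1")
    obs = ~m.mask
    if np.any(m.values[obs] <= 0):
        bad = np.argwhere(obs & (m.values <= 0))[0]
        raise ValueError(
            f"non-positive intensity at row {bad[0] + 1} "
            f"(peptide {m.peptide_ids[bad[0]]!r}), column {bad[1] + 1}; "
            "log transform undefined"
        )
    out = m.values.copy()
    out[obs] = np.log(out[obs]) / np.log(base)
    return AbundanceMatrix(out, list(m.peptide_ids), list(m.sample_ids), log_base=base)


def complete_rows(m: AbundanceMatrix) -> AbundanceMatrix:
    """Sub-matrix of peptides observed in every sample, row order preserved.

    SVD-based eigentrend diagnostics operate on this sub-matrix only.
    """
    keep = ~m.mask.any(axis=1)
    if not keep.any():
        raise ValueError(
            "no peptide is observed in every sample; SVD eigentrend "
            "diagnostics are unavailable for this matrix"
        )
    return AbundanceMatrix(
        m.values[keep].copy(),
        [p for p, k in zip(m.peptide_ids, keep) if k],
        list(m.sample_ids),
        m.log_base,
    )
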