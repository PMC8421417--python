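"""Readers and writers for the plain-text formats the pipeline touches.

Containers are deliberately small, validated dataclasses:

* :class:`ExpressionMatrix` — genes x units (samples, cells, or spots),
  either raw counts or log-normalized values.
* :class:`SignatureCollection` — named gene sets (GMT dialect).
* :class:`RegionSet` — genomic intervals, 0-based half-open (BED convention).
* :class:`ClinicalTable` — per-sample time-to-event records.

Gene-id matching throughout the package is exact, case-sensitive string
match; signature genes missing from a matrix are dropped with a logged
count (homolog mapping is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SignatureCollection",
    "RegionSet",
    "ClinicalTable",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_regions",
    "write_regions",
    "read_clinical",
    "write_clinical",
    "log_normalize",
]

VALID_KINDS = ("counts", "lognorm")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(dups)[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Dense genes x units expression matrix with a counts/lognorm flag."""

    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.unit_ids = _check_unique(self.unit_ids, "unit")
        if self.value_kind not in VALID_KINDS:
            raise ValueError(f"value_kind must be one of {VALID_KINDS}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.unit_ids)} units)"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        if np.any(v < 0):
            raise ValueError("expression values must be non-negative")
        self.values = v

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.unit_ids),
                                self.values[rows, :], self.value_kind)


@dataclass
class SignatureCollection:
    """Named gene sets; every set non-empty, no duplicate genes within a set."""

    names: list[str]
    member_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = _check_unique(self.names, "signature")
        for name in self.names:
            genes = self.member_genes.get(name, [])
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> list[str]:
        return self.member_genes[name]

    def intersect(self, gene_ids: Sequence[str], name: str) -> list[str]:
        """Members of ``name`` present in ``gene_ids``; logs dropped count."""
        present = set(gene_ids)
        kept = [g for g in self.member_genes[name] if g in present]
        dropped = len(self.member_genes[name]) - len(kept)
        if dropped:
            logger.info("signature %s: %d gene(s) absent from matrix, dropped",
                        name, dropped)
        return kept


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open, strand in {+, -, .}."""

    chroms: list[str]
    starts: np.ndarray
    ends: np.ndarray
    strands: list[str] | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        n = len(self.chroms)
        if self.strands is None:
            self.strands = ["."] * n
        if not (len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise ValueError("chroms/starts/ends/strands length mismatch")
        if any(not c for c in self.chroms):
            raise ValueError("empty chrom name")
        if np.any(self.starts < 0):
            raise ValueError("negative start coordinate")
        bad = np.nonzero(self.ends <= self.starts)[0]
        if bad.size:
            raise ValueError(f"end <= start at record {bad[0]}")
        if any(s not in ("+", "-", ".") for s in self.strands):
            raise ValueError("strand must be one of + - .")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass
class ClinicalTable:
    """Per-sample right-censored time-to-event records."""

    unit_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = _check_unique(self.unit_ids, "unit")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) != len(self.unit_ids) or len(self.event) != len(self.unit_ids):
            raise ValueError("time/event length mismatch")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.unit_ids)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": self.unit_ids, "time": self.time, "event": self.event}
        )


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a Broad-dialect GMT file (name TAB description TAB gene ...).

    Duplicate genes within a line are deduplicated with a warning; duplicate
    set names or empty sets are errors.
    """
    names: list[str] = []
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 tab-separated fields")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"line {lineno}: empty gene set {name!r}")
            if name in members:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            uniq = list(dict.fromkeys(genes))
            if len(uniq) != len(genes):
                logger.warning("GMT line %d (%s): %d duplicate gene(s) removed",
                               lineno, name, len(genes) - len(uniq))
            names.append(name)
            members[name] = uniq
    return SignatureCollection(names, members)


def write_gmt(sigs: SignatureCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sigs.names:
            fh.write("\t".join([name, "na", *sigs.member_genes[name]]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression(path: str | Path, value_kind: str = "counts") -> ExpressionMatrix:
    """Read a genes x units matrix.

    ``path`` may be a dense TSV/CSV (genes as rows, header row of unit ids,
    first column gene ids) or a MatrixMarket ``.mtx`` file accompanied by
    two one-column sidecars ``<stem>.genes.txt`` and ``<stem>.units.txt``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = _read_id_file(path.with_suffix("").with_suffix(".genes.txt")
                              if path.suffixes[-2:] == [".genes", ".mtx"]
                              else path.parent / (path.stem + ".genes.txt"))
        units = _read_id_file(path.parent / (path.stem + ".units.txt"))
        if mat.shape != (len(genes), len(units)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(units)} units)"
            )
        return ExpressionMatrix(genes, units, np.asarray(mat, dtype=float), value_kind)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(u) for u in df.columns], values, value_kind
    )


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing id sidecar {path}")
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write dense TSV/CSV (full precision) or MTX + id sidecars."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        (path.parent / (path.stem + ".genes.txt")).write_text(
            "\n".join(m.gene_ids) + "\n")
        (path.parent / (path.stem + ".units.txt")).write_text(
            "\n".join(m.unit_ids) + "\n")
        return
    sep = "," if path.suffix == ".csv" else "\t"
    # default float formatting is shortest-repr, which round-trips exactly
    m.frame.to_csv(path, sep=sep)


def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize counts to ``scale`` per unit and apply log1p."""
    if m.value_kind != "counts":
        raise ValueError("log_normalize expects a counts matrix")
    totals = m.values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("unit with zero total count")
    v = np.log1p(m.values / totals * scale)
    return ExpressionMatrix(list(m.gene_ids), list(m.unit_ids), v, "lognorm")


# ---------------------------------------------------------------------------
# BED

def read_regions(path: str | Path) -> RegionSet:
    """Parse BED3+ (0-based half-open); strand from column 6 when present."""
    chroms, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"line {lineno}: end ({end}) <= start ({start})")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(parts[5] if len(parts) >= 6 else ".")
    return RegionSet(chroms, np.array(starts), np.array(ends), strands)


def write_regions(r: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, st in zip(r.chroms, r.starts, r.ends, r.strands):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


# ---------------------------------------------------------------------------
# Clinical CSV

def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path)
    required = {"unit_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical CSV must have columns {sorted(required)}")
    return ClinicalTable([str(u) for u in df["unit_id"]],
                         df["time"].to_numpy(), df["event"].to_numpy())


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    t.frame.to_csv(path, index=False)
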