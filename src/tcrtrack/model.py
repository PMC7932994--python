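"""Core data model for UMI-based clone-count tables.

A repertoire is represented as a :class:`CloneCountTable`: an ordered list of
clones (identified by CDR3 amino-acid sequence, optionally refined by V/J
calls), an ordered list of samples with their experimental metadata, and a
clone x sample matrix of unique-UMI counts.  All downstream stages (size
distribution, trajectory clustering, differential expansion) consume this
container.

Two on-disk dialects are supported:

``airr``
    Long-format, AIRR Rearrangement-style TSV with columns ``junction_aa``,
    ``v_call``, ``j_call``, ``duplicate_count``, ``sample_id`` plus the
    sample metadata columns (``timepoint``, ``replicate``, ``condition``,
    ``fraction``).

``wide``
    Wide count matrix TSV: first column ``clone_id`` (``cdr3`` or
    ``cdr3|v|j``), one integer column per sample.  Sample metadata travels in
    a ``<stem>.samples.tsv`` sidecar written alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 proteinogenic amino acids; '*' (stop) is excluded on purpose
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

AIRR_REQUIRED = ("junction_aa", "v_call", "j_call", "duplicate_count", "sample_id")
SAMPLE_META_COLUMNS = ("sample_id", "timepoint", "replicate", "condition", "fraction")


class FormatError(ValueError):
    """A file does not conform to the declared dialect."""


class ValidationError(ValueError):
    """Structurally parseable input violates a model invariant."""


def is_valid_cdr3(cdr3_aa: str) -> bool:
    """True if the sequence is a non-empty uppercase 20-letter AA string."""
    return bool(cdr3_aa) and all(c in AMINO_ACIDS for c in cdr3_aa)


@dataclass(frozen=True, order=True)
class CloneKey:
    """Identity of a T-cell clone.

    Equality on the CDR3 amino-acid sequence alone mirrors clustering of
    reads into clones by 100% amino-acid CDR3 identity; V/J calls are carried
    along and may optionally be folded into the identity (``with_vj``).
    """

    cdr3_aa: str
    v_call: str = ""
    j_call: str = ""

    def __post_init__(self) -> None:
        if not is_valid_cdr3(self.cdr3_aa):
            raise ValidationError(
                f"invalid CDR3 amino-acid sequence: {self.cdr3_aa!r}"
            )

    @property
    def clone_id(self) -> str:
        if self.v_call or self.j_call:
            return f"{self.cdr3_aa}|{self.v_call}|{self.j_call}"
        return self.cdr3_aa

    @staticmethod
    def from_clone_id(clone_id: str) -> "CloneKey":
        parts = clone_id.split("|")
        if len(parts) == 1:
            return CloneKey(parts[0])
        if len(parts) == 3:
            return CloneKey(parts[0], parts[1], parts[2])
        raise FormatError(f"malformed clone_id: {clone_id!r}")

    def identity(self, use_vj: bool = False) -> tuple:
        """Clustering key: CDR3 alone by default, (CDR3, V, J) if requested."""
        if use_vj:
            return (self.cdr3_aa, self.v_call, self.j_call)
        return (self.cdr3_aa,)


@dataclass(frozen=True, order=True)
class SampleMeta:
    """Experimental annotation of one sequencing library."""

    sample_id: str
    timepoint: int
    replicate: int
    condition: str = "none"
    fraction: str = "bulk"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.fraction not in ("bulk", "sorted"):
            raise ValidationError(f"fraction must be 'bulk' or 'sorted', got {self.fraction!r}")

    @property
    def design_key(self) -> tuple:
        return (self.timepoint, self.replicate, self.condition, self.fraction)


@dataclass
class CloneCountTable:
    """Clones x samples matrix of unique-UMI counts.

    Invariants (enforced at construction): counts are non-negative integers,
    every clone has at least one nonzero entry, clone keys and sample design
    keys are unique, and per-sample library sizes are exactly the column sums.
    """

    clones: list[CloneKey]
    samples: list[SampleMeta]
    counts: np.ndarray  # shape (n_clones, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.clones), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.clones)} clones x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValidationError("counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if len(self.clones) and (self.counts.sum(axis=1) == 0).any():
            raise ValidationError("every clone must have at least one nonzero count")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate clone keys")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample_id")
        keys = [s.design_key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                "duplicate (timepoint, replicate, condition, fraction) design key"
            )

    # -- derived quantities ------------------------------------------------

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def library_sizes(self) -> np.ndarray:
        """Total unique UMIs per sample (exact column sums)."""
        return self.counts.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        """Clonal frequencies: count / library size, columns summing to 1."""
        lib = self.library_sizes
        if (lib == 0).any():
            bad = [s for s, n in zip(self.sample_ids, lib) if n == 0]
            raise ValidationError(f"zero library size for sample(s): {bad}")
        return self.counts / lib[np.newaxis, :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.clone_ids, columns=self.sample_ids)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, predicate: Callable[[SampleMeta], bool]) -> "CloneCountTable":
        """Keep samples matching ``predicate``; drop clones left all-zero."""
        keep = [i for i, s in enumerate(self.samples) if predicate(s)]
        if not keep:
            raise ValidationError("sample predicate selected no samples")
        counts = self.counts[:, keep]
        nonzero = counts.sum(axis=1) > 0
        return CloneCountTable(
            clones=[c for c, k in zip(self.clones, nonzero) if k],
            samples=[self.samples[i] for i in keep],
            counts=counts[nonzero, :],
        )

    def subset_clones(self, clone_ids: Iterable[str]) -> "CloneCountTable":
        wanted = set(clone_ids)
        keep = [i for i, c in enumerate(self.clones) if c.clone_id in wanted]
        if not keep:
            raise ValidationError("clone subset is empty")
        return CloneCountTable(
            clones=[self.clones[i] for i in keep],
            samples=list(self.samples),
            counts=self.counts[keep, :],
        )


def to_ucpm(table: CloneCountTable) -> pd.DataFrame:
    """UMI counts per million: ``1e6 * count / library_size`` per sample.

    Columns each sum to 1e6 (up to floating point).  Raises naming the sample
    if any library is empty.
    """
    lib = table.library_sizes
    if (lib == 0).any():
        bad = [s for s, n in zip(table.sample_ids, lib) if n == 0]
        raise ValidationError(f"cannot compute UCPM, zero library size: {bad}")
    ucpm = 1e6 * table.counts / lib[np.newaxis, :]
    return pd.DataFrame(ucpm, index=table.clone_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _samples_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".samples.tsv")


def _meta_from_row(row: pd.Series) -> SampleMeta:
    return SampleMeta(
        sample_id=str(row["sample_id"]),
        timepoint=int(row["timepoint"]),
        replicate=int(row["replicate"]),
        condition=str(row.get("condition", "none")),
        fraction=str(row.get("fraction", "bulk")),
    )


def _default_meta(sample_ids: Sequence[str]) -> list[SampleMeta]:
    # no sidecar: synthesise placeholder metadata (one pseudo-replicate series)
    return [SampleMeta(sid, timepoint=0, replicate=i + 1) for i, sid in enumerate(sample_ids)]


def read_clone_table(path: str | Path, dialect: str = "airr") -> CloneCountTable:
    """Read a clone-count table in the ``airr`` or ``wide`` dialect.

    Malformed data rows (invalid CDR3, e.g. containing a stop ``*``) are
    rejected with their line numbers logged; structural problems (missing
    columns, negative counts) raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "airr":
        return _read_airr(path)
    if dialect in ("wide", "wide-matrix"):
        return _read_wide(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_airr(path: Path) -> CloneCountTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required AIRR column(s): {missing}")
    try:
        df["duplicate_count"] = df["duplicate_count"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer duplicate_count: {exc}") from exc
    if (df["duplicate_count"] < 0).any():
        lines = (df.index[df["duplicate_count"] < 0] + 2).tolist()
        raise ValidationError(f"{path}: negative duplicate_count at line(s) {lines}")

    bad = ~df["junction_aa"].map(is_valid_cdr3)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s", path, bad.sum(), lines)
        df = df[~bad]
    if df.empty:
        raise ValidationError(f"{path}: no valid rows")

    has_meta = all(c in df.columns for c in ("timepoint", "replicate"))
    meta: dict[str, SampleMeta] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        if has_meta:
            meta[sid] = _meta_from_row(grp.iloc[0])
        else:
            meta[sid] = SampleMeta(str(sid), timepoint=0, replicate=len(meta) + 1)

    df["_clone"] = [
        CloneKey(a, v, j).clone_id
        for a, v, j in zip(df["junction_aa"], df["v_call"], df["j_call"])
    ]
    dup = df.duplicated(subset=["_clone", "sample_id"])
    if dup.any():
        logger.warning(
            "%s: %d duplicate (clone, sample) row(s); counts summed", path, int(dup.sum())
        )
    pivot = (
        df.pivot_table(
            index="_clone", columns="sample_id", values="duplicate_count",
            aggfunc="sum", fill_value=0,
        )
        .astype(np.int64)
    )
    # preserve first-appearance order of clones and samples
    clone_order = df["_clone"].drop_duplicates().tolist()
    sample_order = df["sample_id"].drop_duplicates().tolist()
    pivot = pivot.loc[clone_order, sample_order]
    return CloneCountTable(
        clones=[CloneKey.from_clone_id(cid) for cid in pivot.index],
        samples=[meta[sid] for sid in pivot.columns],
        counts=pivot.to_numpy(),
    )


def _read_wide(path: Path) -> CloneCountTable:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "clone_id":
        raise FormatError(f"{path}: first column must be 'clone_id', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide matrix needs at least one sample column")
    counts = df.iloc[:, 1:]
    if not all(np.issubdtype(d, np.number) for d in counts.dtypes):
        raise FormatError(f"{path}: non-numeric count cells")
    if (counts.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative counts")

    clone_ids = df["clone_id"].astype(str)
    keys, keep, rejected = [], [], []
    for i, cid in enumerate(clone_ids):
        try:
            keys.append(CloneKey.from_clone_id(cid))
            keep.append(i)
        except (ValidationError, FormatError):
            rejected.append(i + 2)
    if rejected:
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s", path, len(rejected), rejected)
    if not keep:
        raise ValidationError(f"{path}: no valid rows")

    sidecar = _samples_sidecar(path)
    sample_ids = list(counts.columns)
    if sidecar.exists():
        sdf = pd.read_csv(sidecar, sep="\t", dtype=str, keep_default_na=False)
        meta = {row["sample_id"]: _meta_from_row(row) for _, row in sdf.iterrows()}
        samples = [meta.get(sid) or SampleMeta(sid, 0, 1) for sid in sample_ids]
    else:
        samples = _default_meta(sample_ids)
    return CloneCountTable(
        clones=keys,
        samples=samples,
        counts=counts.to_numpy()[keep, :].astype(np.int64),
    )


def write_clone_table(table: CloneCountTable, path: str | Path, dialect: str = "airr") -> Path:
    """Write the table; the wide dialect also writes a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "airr":
        rows = []
        for j, s in enumerate(table.samples):
            nz = np.nonzero(table.counts[:, j])[0]
            for i in nz:
                c = table.clones[i]
                rows.append(
                    dict(
                        junction_aa=c.cdr3_aa, v_call=c.v_call, j_call=c.j_call,
                        duplicate_count=int(table.counts[i, j]), sample_id=s.sample_id,
                        timepoint=s.timepoint, replicate=s.replicate,
                        condition=s.condition, fraction=s.fraction,
                    )
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect in ("wide", "wide-matrix"):
        df = table.to_frame()
        df.insert(0, "clone_id", df.index)
        df.to_csv(path, sep="\t", index=False)
        pd.DataFrame([
            dict(zip(SAMPLE_META_COLUMNS,
                     (s.sample_id, s.timepoint, s.replicate, s.condition, s.fraction)))
            for s in table.samples
        ]).to_csv(_samples_sidecar(path), sep="\t", index=False)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path


def concat_samples(tables: Sequence[CloneCountTable]) -> CloneCountTable:
    """Column-bind tables over the union of their clones (absent = 0)."""
    if not tables:
        raise ValidationError("nothing to concatenate")
    clone_ids: list[str] = []
    keys: dict[str, CloneKey] = {}
    for t in tables:
        for c in t.clones:
            if c.clone_id not in keys:
                keys[c.clone_id] = c
                clone_ids.append(c.clone_id)
    samples: list[SampleMeta] = []
    blocks = []
    index = {cid: i for i, cid in enumerate(clone_ids)}
    for t in tables:
        block = np.zeros((len(clone_ids), t.n_samples), dtype=np.int64)
        rows = [index[cid] for cid in t.clone_ids]
        block[rows, :] = t.counts
        blocks.append(block)
        samples.extend(t.samples)
    return CloneCountTable(
        clones=[keys[cid] for cid in clone_ids],
        samples=samples,
        counts=np.hstack(blocks),
    )
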