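"""Typed containers and on-disk I/O for microbiome time-course data.

The pipeline's central objects are

* :class:`AbundanceTable` — sample x taxon integer read counts,
* :class:`SampleMetadata` — per-sample source (control / substrate / host),
  time in hours, replicate and optional plate identifiers,
* :class:`TraitTable` — a binary taxon x function matrix, each function
  labelled with one of eight functional subsystems,
* :class:`PhyloTree` — a rooted phylogeny over the taxa,
* :class:`DistanceMatrix` — a symmetric pairwise sample dissimilarity matrix.

All tabular formats are plain TSV (UTF-8, ``.`` decimal separator, ``#``
comment lines allowed); trees are newick.  Orientation of abundance tables
is controlled by an explicit flag rather than sniffed.  Any malformed input
raises a typed error (:class:`ValidationError` / :class:`TableParseError`)
naming the offending record — tables are never silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("wormbiome")

#: The three experimental sample sources: worm-free plates, the plate lawn
#: directly associated with worms, and the worms themselves.
SOURCES: tuple[str, ...] = ("control", "substrate", "host")

#: The eight functional subsystems grouping genome-derived traits.
SUBSYSTEMS: tuple[str, ...] = (
    "cazyme",
    "exchange",
    "gut",
    "interactions",
    "medium",
    "metabolism",
    "uast",
    "virulence",
)


class ValidationError(ValueError):
    """A container invariant was violated (duplicate IDs, bad level, ...)."""


class TableParseError(ValueError):
    """An on-disk table could not be parsed into a valid container."""


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} ID: {dup!r}")
    return ids


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


class AbundanceTable:
    """Sample x taxon matrix of non-negative integer read counts.

    Parameters
    ----------
    data :
        DataFrame with samples as rows (index = sample IDs) and taxa as
        columns (columns = taxon IDs); entries are read counts.
    """

    def __init__(self, data: pd.DataFrame):
        sample_ids = _check_unique(list(data.index), "sample")
        taxon_ids = _check_unique(list(data.columns), "taxon")
        if len(sample_ids) < 1 or len(taxon_ids) < 1:
            raise ValidationError("abundance table needs >=1 sample and >=1 taxon")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            # locate the first offending cell for the error message
            for s in data.index:
                for t in data.columns:
                    try:
                        float(data.at[s, t])
                    except (TypeError, ValueError):
                        raise TableParseError(
                            f"non-numeric count at sample {s!r}, taxon {t!r}: "
                            f"{data.at[s, t]!r}"
                        ) from None
            raise TableParseError("non-numeric abundance table")
        arr = np.asarray(values, dtype=float)
        if np.any(~np.isfinite(arr)):
            s, t = np.argwhere(~np.isfinite(arr))[0]
            raise TableParseError(
                f"non-finite count at sample {sample_ids[s]!r}, taxon {taxon_ids[t]!r}"
            )
        if np.any(arr < 0):
            s, t = np.argwhere(arr < 0)[0]
            raise TableParseError(
                f"negative count at sample {sample_ids[s]!r}, taxon "
                f"{taxon_ids[t]!r}: {arr[s, t]}"
            )
        if np.any(arr != np.round(arr)):
            s, t = np.argwhere(arr != np.round(arr))[0]
            raise TableParseError(
                f"non-integral count at sample {sample_ids[s]!r}, taxon "
                f"{taxon_ids[t]!r}: {arr[s, t]}"
            )
        self._data = pd.DataFrame(
            arr.astype(np.int64), index=list(sample_ids), columns=list(taxon_ids)
        )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        sample_ids: Sequence[str],
        taxon_ids: Sequence[str],
    ) -> "AbundanceTable":
        return cls(pd.DataFrame(counts, index=list(sample_ids), columns=list(taxon_ids)))

    # -- accessors -----------------------------------------------------------

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(self._data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Sample x taxon int64 array (copy-safe view)."""
        return self._data.to_numpy()

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts (row sums)."""
        return self._data.to_numpy().sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self._data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self._data.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def relative(self) -> np.ndarray:
        """Per-sample relative abundances; all-zero samples raise."""
        totals = self.library_sizes.astype(float)
        if np.any(totals == 0):
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals[:, None]

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return AbundanceTable(self._data.loc[ids])

    def filter_taxa(self, min_prevalence: int = 1) -> "AbundanceTable":
        """Keep taxa present (count > 0) in at least ``min_prevalence`` samples."""
        keep = (self._data.to_numpy() > 0).sum(axis=0) >= min_prevalence
        if not keep.any():
            raise ValidationError("prevalence filter removed every taxon")
        return AbundanceTable(self._data.loc[:, np.asarray(self.taxon_ids)[keep]])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AbundanceTable) and self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"AbundanceTable({self.n_samples} samples x {self.n_taxa} taxa)"


class SampleMetadata:
    """Per-sample design information driving every grouping and contrast.

    Wraps a DataFrame indexed by sample ID with columns ``source`` (one of
    :data:`SOURCES`), ``time_h`` (positive hours), ``replicate`` and an
    optional ``plate`` shared by paired host/substrate samples.
    """

    def __init__(self, data: pd.DataFrame):
        _check_unique(list(data.index), "sample")
        required = {"source", "time_h", "replicate"}
        missing = required - set(data.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        df = data.copy()
        df.index = df.index.astype(str)
        src = df["source"].astype(str).str.strip().str.lower()
        bad = sorted(set(src) - set(SOURCES))
        if bad:
            raise ValidationError(
                f"unknown source level(s) {bad}; allowed: {set(SOURCES)}"
            )
        df["source"] = src
        df["time_h"] = pd.to_numeric(df["time_h"], errors="raise").astype(float)
        if np.any(df["time_h"].to_numpy() <= 0):
            raise ValidationError("time_h must be > 0 for every sample")
        df["replicate"] = df["replicate"].astype(str)
        if "plate" not in df.columns:
            df["plate"] = pd.NA
        self._data = df[["source", "time_h", "replicate", "plate"]]

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def source(self) -> pd.Series:
        return self._data["source"]

    @property
    def time_h(self) -> pd.Series:
        return self._data["time_h"]

    @property
    def replicate(self) -> pd.Series:
        return self._data["replicate"]

    @property
    def plate(self) -> pd.Series:
        return self._data["plate"]

    def to_dataframe(self) -> pd.DataFrame:
        return self._data.copy()

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        ids = [str(i) for i in sample_ids]
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample IDs: {sorted(missing)}")
        return SampleMetadata(self._data.loc[ids])

    def groups(
        self, by: Sequence[str] = ("source", "time_h")
    ) -> Iterator[tuple[tuple, list[str]]]:
        """Yield ``(group_key, sample_ids)`` ordered by source then time."""
        df = self._data.copy()
        df["_src_order"] = df["source"].map({s: i for i, s in enumerate(SOURCES)})
        order = [c if c != "source" else "_src_order" for c in by]
        for key, sub in df.sort_values(order).groupby(list(by), sort=False):
            if not isinstance(key, tuple):
                key = (key,)
            yield key, list(sub.index)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self)} samples)"


class TraitTable:
    """Binary taxon x function matrix with one subsystem label per function."""

    def __init__(self, presence: pd.DataFrame, subsystem: Mapping[str, str]):
        taxon_ids = _check_unique(list(presence.index), "taxon")
        function_ids = _check_unique(list(presence.columns), "function")
        arr = presence.to_numpy()
        try:
            arr = np.asarray(arr, dtype=float)
        except (TypeError, ValueError) as exc:
            raise TableParseError(f"non-numeric trait value: {exc}") from None
        if np.any((arr != 0) & (arr != 1)):
            t, f = np.argwhere((arr != 0) & (arr != 1))[0]
            raise TableParseError(
                f"trait value outside {{0,1}} at taxon {taxon_ids[t]!r}, "
                f"function {function_ids[f]!r}: {arr[t, f]}"
            )
        missing = set(function_ids) - set(subsystem)
        if missing:
            raise ValidationError(f"functions without subsystem: {sorted(missing)}")
        sub = {f: str(subsystem[f]).strip().lower() for f in function_ids}
        bad = sorted({s for s in sub.values() if s not in SUBSYSTEMS})
        if bad:
            raise ValidationError(
                f"unknown subsystem label(s) {bad}; allowed: {set(SUBSYSTEMS)}"
            )
        self._presence = pd.DataFrame(
            arr.astype(np.int8), index=list(taxon_ids), columns=list(function_ids)
        )
        self._subsystem = sub

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(self._presence.index)

    @property
    def function_ids(self) -> tuple[str, ...]:
        return tuple(self._presence.columns)

    @property
    def presence(self) -> np.ndarray:
        """Taxon x function 0/1 int8 array."""
        return self._presence.to_numpy()

    @property
    def subsystem(self) -> dict[str, str]:
        return dict(self._subsystem)

    def functions_in_subsystem(self, subsystem: str) -> list[str]:
        return [f for f in self.function_ids if self._subsystem[f] == subsystem]

    def to_dataframe(self) -> pd.DataFrame:
        return self._presence.copy()

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "TraitTable":
        ids = list(taxon_ids)
        missing = set(ids) - set(self.taxon_ids)
        if missing:
            raise ValidationError(f"taxa absent from trait table: {sorted(missing)}")
        return TraitTable(self._presence.loc[ids], self._subsystem)

    def __repr__(self) -> str:
        return (
            f"TraitTable({len(self.taxon_ids)} taxa x "
            f"{len(self.function_ids)} functions)"
        )


class PhyloTree:
    """Rooted phylogeny over taxa, backed by a :class:`skbio.TreeNode`.

    Missing branch lengths are imputed as 0 with a logged warning; negative
    branch lengths and duplicate leaf labels are rejected.
    """

    def __init__(self, tree: skbio.TreeNode):
        n_missing = 0
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(f"negative branch length at {node.name!r}")
        if tree.length is None:
            tree.length = 0.0
        if n_missing:
            logger.warning("imputed %d missing branch lengths as 0", n_missing)
        leaves = [t.name for t in tree.tips()]
        _check_unique(leaves, "leaf")
        self._tree = tree

    @property
    def tree(self) -> skbio.TreeNode:
        return self._tree

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self._tree.tips())

    @property
    def total_length(self) -> float:
        return float(
            sum(n.length or 0.0 for n in self._tree.traverse(include_self=False))
        )

    def __repr__(self) -> str:
        return f"PhyloTree({len(self.leaf_names)} leaves)"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, hollow, non-negative pairwise sample dissimilarities."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_unique(self.sample_ids, "sample"))
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.sample_ids)
        )

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.values, ids=list(self.sample_ids))

    def submatrix(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = [str(i) for i in sample_ids]
        idx = [self.sample_ids.index(i) for i in ids]
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)], self.metric)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.sample_ids.index(a), self.sample_ids.index(b)])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = None
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = line.rstrip("\n").split("\t")
                break
    if header is None:
        raise TableParseError(f"{path}: empty file")
    if len(set(header[1:])) != len(header[1:]):
        seen: set[str] = set()
        dup = next(h for h in header[1:] if h in seen or seen.add(h))  # type: ignore[func-returns-value]
        raise ValidationError(f"{path}: duplicate column ID {dup!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise TableParseError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}: "
                f"{df.at[row, col]!r}"
            )
        if converted.isna().any():
            row = df.index[int(converted.isna().argmax())]
            raise TableParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_abundance_table(
    path: str | Path, orientation: str = "samples_as_rows"
) -> AbundanceTable:
    """Read a TSV count matrix.

    ``orientation`` is ``"samples_as_rows"`` (default) or ``"taxa_as_rows"``
    (the table is transposed after reading); it is never sniffed.
    """
    if orientation not in ("samples_as_rows", "taxa_as_rows"):
        raise ValidationError(
            f"orientation must be 'samples_as_rows' or 'taxa_as_rows', "
            f"got {orientation!r}"
        )
    df = _to_numeric(_read_tsv(path), path)
    if orientation == "taxa_as_rows":
        df = df.T
    try:
        return AbundanceTable(df)
    except (ValidationError, TableParseError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata (sample_id, source, time_h, replicate[, plate])."""
    df = _read_tsv(path)
    try:
        return SampleMetadata(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a trait TSV: one row per function, a ``subsystem`` column, then
    one 0/1 column per taxon."""
    df = _read_tsv(path)
    if "subsystem" not in df.columns:
        raise TableParseError(f"{path}: trait table needs a 'subsystem' column")
    subsystem = df["subsystem"].astype(str).to_dict()
    presence = _to_numeric(df.drop(columns=["subsystem"]), path).T  # taxa x functions
    try:
        return TraitTable(presence, subsystem)
    except (ValidationError, TableParseError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise TableParseError(f"{path}: unparseable newick: {exc}") from exc
    try:
        return PhyloTree(tree)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write_table(obj, path: str | Path, header_comment: str | None = None) -> None:
    """Write any tabular pipeline object as TSV.

    Floats are written with ``repr`` fidelity so that a write/read round
    trip reproduces values exactly.  ``header_comment`` lines (without the
    leading ``#``) are prepended as comments.
    """
    path = Path(path)
    if isinstance(obj, AbundanceTable):
        df = obj.to_dataframe()
        df.index.name = "sample_id"
    elif isinstance(obj, SampleMetadata):
        df = obj.to_dataframe()
        df.index.name = "sample_id"
    elif isinstance(obj, TraitTable):
        df = obj.to_dataframe().T  # functions as rows
        df.insert(0, "subsystem", [obj.subsystem[f] for f in df.index])
        df.index.name = "function_id"
    elif isinstance(obj, DistanceMatrix):
        df = obj.to_dataframe()
        df.index.name = "sample_id"
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise ValidationError(f"cannot write object of type {type(obj).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    tree.tree.write(str(path), format="newick")
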