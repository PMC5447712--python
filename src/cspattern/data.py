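"""Containers and readers/writers for chromatin-state matrices, variant tables and
epigenome-cluster definitions.

Coordinates are 0-based, half-open (BED convention) throughout.  The state matrix
is a bed-like tab-delimited table: ``#chrom  start  end  <epigenome ids...>`` with
one integer chromatin-state label (1..S) per epigenome per fixed-width genomic
window.  A position ``p`` on a chromosome maps to the window covering
``[floor(p / window_size) * window_size, ... + window_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ld_cluster", "maf", "annotation", "label"]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into the expected shape."""


class ValidationError(ValueError):
    """Raised when a parsed file violates a container invariant."""


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-width genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(f"bad window [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class StateMatrix:
    """Integer chromatin-state labels for N epigenomes at L genomic windows.

    Attributes
    ----------
    epigenome_ids : list of str
        Column identifiers, length N.
    windows : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end``; one row per window, sorted and
        non-overlapping within each chromosome.
    states : ndarray of shape (L, N)
        State labels in ``1..n_states``.  No missing values.
    n_states : int
        Number of distinct states S in the segmentation model.
    window_size : int
        Window width in base pairs.
    """

    epigenome_ids: list[str]
    windows: pd.DataFrame
    states: np.ndarray
    n_states: int
    window_size: int = 200

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2 or self.states.shape[1] != len(self.epigenome_ids):
            raise ValidationError("states must be (L, N) with one column per epigenome")
        if len(self.windows) != self.states.shape[0]:
            raise ValidationError("windows and states row counts differ")
        if self.states.size and (self.states.min() < 1 or self.states.max() > self.n_states):
            bad = np.argwhere((self.states < 1) | (self.states > self.n_states))[0]
            raise ValidationError(
                f"state label {self.states[tuple(bad)]} at row {bad[0]} outside [1, {self.n_states}]"
            )
        widths = self.windows["end"].to_numpy() - self.windows["start"].to_numpy()
        if len(widths) and not np.all(widths == self.window_size):
            raise ValidationError("all windows must have width == window_size")
        self._index = {
            (c, s): i
            for i, (c, s) in enumerate(zip(self.windows["chrom"], self.windows["start"]))
        }

    @property
    def n_epigenomes(self) -> int:
        return len(self.epigenome_ids)

    @property
    def n_windows(self) -> int:
        return self.states.shape[0]

    def window(self, i: int) -> GenomicWindow:
        row = self.windows.iloc[i]
        return GenomicWindow(row["chrom"], int(row["start"]), int(row["end"]))

    def locate(self, chrom: str, pos: int) -> int | None:
        """Index of the window containing (chrom, pos), or None if uncovered."""
        start = (pos // self.window_size) * self.window_size
        return self._index.get((chrom, start))

    def state_proportions(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Genome-wide proportion of each state over all epigenomes (length S)."""
        sub = self.states if rows is None else self.states[rows]
        counts = np.bincount(sub.ravel() - 1, minlength=self.n_states).astype(float)
        return counts / counts.sum()


@dataclass
class VariantSet:
    """Risk or null variants with their per-epigenome state vectors.

    ``table`` has columns variant_id, chrom, pos, ld_cluster, maf, annotation,
    label; ``states`` holds the state vector of each variant's containing
    window (shape n_variants x N); ``window_index`` maps each variant back to
    its row in the source :class:`StateMatrix`.
    """

    table: pd.DataFrame
    states: np.ndarray
    window_index: np.ndarray
    epigenome_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.window_index = np.asarray(self.window_index, dtype=np.int64)
        if len(self.table) != self.states.shape[0]:
            raise ValidationError("variant table and state rows differ")
        bad = (self.table["maf"] < 0) | (self.table["maf"] > 0.5)
        if bad.any():
            raise ValidationError("maf outside [0, 0.5]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ld_cluster_sizes(self) -> pd.Series:
        return self.table.groupby("ld_cluster").size()

    def subset(self, idx: np.ndarray) -> "VariantSet":
        idx = np.asarray(idx)
        return VariantSet(
            self.table.iloc[idx].reset_index(drop=True),
            self.states[idx],
            self.window_index[idx],
            self.epigenome_ids,
        )


@dataclass
class ClusterDefinition:
    """Partition of the epigenomes into G fixed clusters (e.g. blood, ESC, brain).

    Used for state-enrichment z-scores: ``p_g`` is the proportion of epigenomes
    in cluster g, computed from the definition itself.
    """

    assignments: dict[str, int]  # epigenome id -> cluster label (1..G)

    def __post_init__(self):
        labels = sorted(set(self.assignments.values()))
        if labels != list(range(1, len(labels) + 1)):
            raise ValidationError("cluster labels must be 1..G with no gaps")
        self.n_clusters = len(labels)

    def membership(self, epigenome_ids: list[str]) -> np.ndarray:
        """0-based cluster index per epigenome, in the given column order."""
        try:
            return np.array([self.assignments[e] - 1 for e in epigenome_ids], dtype=np.int64)
        except KeyError as exc:
            raise ValidationError(f"epigenome {exc.args[0]!r} missing from cluster map") from exc

    def proportions(self, epigenome_ids: list[str]) -> np.ndarray:
        member = self.membership(epigenome_ids)
        counts = np.bincount(member, minlength=self.n_clusters).astype(float)
        return counts / counts.sum()


# ---------------------------------------------------------------------------
# readers / writers


def read_state_matrix(path, n_states: int, window_size: int = 200) -> StateMatrix:
    """Read a bed-like state matrix (``#chrom start end <epigenome ids...>``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 4:
        raise ParseError(f"{path}: expected >= 4 tab-delimited columns")
    first = df.columns[0].lstrip("#")
    df = df.rename(columns={df.columns[0]: first})
    if list(df.columns[:3]) != ["chrom", "start", "end"]:
        raise ParseError(f"{path}: header must start with '#chrom\\tstart\\tend'")
    epigenome_ids = list(df.columns[3:])
    body = df.iloc[:, 3:]
    if body.isna().any().any():
        raise ParseError(f"{path}: ragged or missing state entries")
    try:
        states = body.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer state entry ({exc})") from exc
    windows = df[["chrom", "start", "end"]].copy()
    windows["start"] = windows["start"].astype(int)
    windows["end"] = windows["end"].astype(int)
    return StateMatrix(epigenome_ids, windows, states, n_states, window_size)


def write_state_matrix(matrix: StateMatrix, path) -> None:
    df = matrix.windows.copy()
    df = df.rename(columns={"chrom": "#chrom"})
    for j, e in enumerate(matrix.epigenome_ids):
        df[e] = matrix.states[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_variants(path, states: StateMatrix) -> VariantSet:
    """Read a variant table and annotate each variant with its window's state vector.

    Variants falling outside every window are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return attach_states(df, states)


def attach_states(table: pd.DataFrame, states: StateMatrix) -> VariantSet:
    """Build a :class:`VariantSet` from an in-memory variant table."""
    idx = np.array(
        [states.locate(c, int(p)) for c, p in zip(table["chrom"], table["pos"])],
        dtype=object,
    )
    keep = np.array([i is not None for i in idx])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropped %d variants outside covered windows", n_drop)
    kept = table.loc[keep].reset_index(drop=True)
    widx = np.array([i for i in idx[keep]], dtype=np.int64)
    return VariantSet(kept, states.states[widx], widx, list(states.epigenome_ids))


def write_variants(variants: VariantSet, path) -> None:
    variants.table[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clusters(path) -> ClusterDefinition:
    """Read a two-column ``epigenome<TAB>cluster`` definition table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns epigenome, cluster")
    col_e, col_c = df.columns[:2]
    return ClusterDefinition(dict(zip(df[col_e].astype(str), df[col_c].astype(int))))


def write_clusters(clusters: ClusterDefinition, path) -> None:
    pd.DataFrame(
        {"epigenome": list(clusters.assignments), "cluster": list(clusters.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_catalog(path):
    """Read a serialized pattern catalog (delegates to :mod:`cspattern.model`)."""
    from .model import CSPCatalog

    return CSPCatalog.load(path)


def write_catalog(catalog, path) -> None:
    catalog.save(path)
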