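"""Shared containers for the STcEM pipeline.

Cell tables are plain :class:`pandas.DataFrame` objects with a documented
column contract (see :data:`CELL_COLUMNS`); counts live in a lightweight
:class:`CountsMatrix` holding a raw integer layer and, after normalization,
a log-normalized layer. Blank (negative-control) probes are carried as
flagged pseudo-genes and never enter normalization totals or downstream
feature spaces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Column contract for per-cell tables. ``class_label`` / ``region_label``
#: may be missing (NA) before annotation; ``modality`` is one of
#: {"ST", "EM", "SC"}.
CELL_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "volume",
    "total_counts",
    "n_genes",
    "blank_mean",
    "class_label",
    "region_label",
    "modality",
)

BLANK_PREFIX = "Blank-"


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the per-cell table contract; returns the table unchanged."""
    missing = [c for c in ("cell_id", "x", "y") if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    xy = cells[["x", "y"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("cell positions must be finite")
    if "volume" in cells.columns:
        vol = cells["volume"].dropna()
        if (vol <= 0).any():
            raise ValueError("volumes must be positive where present")
    return cells


@dataclass
class CountsMatrix:
    """Cells × genes counts with named rows/columns.

    ``raw`` is the integer count layer; ``norm`` is filled by
    :func:`stcem.expression.normalize` and holds ln(1 + 1e4 * x / total)
    values over non-blank genes.
    """

    cell_ids: np.ndarray  # (n_cells,) str
    gene_names: np.ndarray  # (n_genes,) str
    raw: np.ndarray  # (n_cells, n_genes) nonneg
    is_blank: np.ndarray | None = None  # (n_genes,) bool
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.raw = np.asarray(self.raw)
        if self.raw.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValueError(
                f"raw shape {self.raw.shape} inconsistent with "
                f"{len(self.cell_ids)} cells × {len(self.gene_names)} genes"
            )
        if (np.asarray(self.raw) < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.is_blank is None:
            self.is_blank = np.array(
                [str(g).startswith(BLANK_PREFIX) for g in self.gene_names], dtype=bool
            )
        else:
            self.is_blank = np.asarray(self.is_blank, dtype=bool)
            if self.is_blank.shape != self.gene_names.shape:
                raise ValueError("is_blank length must match gene_names")

    # -- convenience -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity
            raise KeyError(f"gene not in matrix: {exc.args[0]}") from None

    def total_counts(self, include_blanks: bool = False) -> np.ndarray:
        """Per-cell totals; blanks excluded by default."""
        if include_blanks:
            return np.asarray(self.raw.sum(axis=1), dtype=float)
        return np.asarray(self.raw[:, ~self.is_blank].sum(axis=1), dtype=float)

    def subset_cells(self, mask_or_idx) -> "CountsMatrix":
        idx = np.asarray(mask_or_idx)
        return CountsMatrix(
            cell_ids=self.cell_ids[idx],
            gene_names=self.gene_names.copy(),
            raw=self.raw[idx],
            is_blank=self.is_blank.copy(),
            norm=None if self.norm is None else self.norm[idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountsMatrix":
        idx = np.asarray(mask_or_idx)
        return CountsMatrix(
            cell_ids=self.cell_ids.copy(),
            gene_names=self.gene_names[idx],
            raw=self.raw[:, idx],
            is_blank=self.is_blank[idx],
            norm=None if self.norm is None else self.norm[:, idx],
        )

    def copy(self) -> "CountsMatrix":
        return CountsMatrix(
            cell_ids=self.cell_ids.copy(),
            gene_names=self.gene_names.copy(),
            raw=self.raw.copy(),
            is_blank=self.is_blank.copy(),
            norm=None if self.norm is None else self.norm.copy(),
        )


@dataclass(frozen=True)
class QcThresholds:
    """Per-cell quality-control bounds.

    A cell is retained iff min_counts <= total <= max_counts,
    n_genes >= min_genes, min_volume < volume < max_volume and
    blank_mean <= max_blank_mean. Counts/genes bounds are inclusive,
    volume bounds exclusive, mirroring the "<30 or >2500 transcripts"
    exclusion convention.
    """

    min_counts: int = 30
    max_counts: int = 2500
    min_genes: int = 5
    min_volume: float = 40.0
    max_volume: float = 2500.0
    max_blank_mean: float = 1.0

    def __post_init__(self) -> None:
        if self.min_counts > self.max_counts:
            raise ValueError("min_counts must not exceed max_counts")
        if self.min_volume >= self.max_volume:
            raise ValueError("min_volume must be below max_volume")


@dataclass(frozen=True)
class GeneSignature:
    """Named gene set; duplicate listings collapse to set semantics."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")


def new_cell_table(
    cell_ids,
    x,
    y,
    *,
    volume=np.nan,
    total_counts=0,
    n_genes=0,
    blank_mean=0.0,
    class_label=None,
    region_label=None,
    modality="ST",
) -> pd.DataFrame:
    """Assemble a contract-conforming cell table."""
    n = len(cell_ids)
    df = pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids, dtype=object),
            "x": np.asarray(x, dtype=float),
            "y": np.asarray(y, dtype=float),
            "volume": np.broadcast_to(np.asarray(volume, dtype=float), (n,)).copy(),
            "total_counts": np.broadcast_to(np.asarray(total_counts), (n,)).copy(),
            "n_genes": np.broadcast_to(np.asarray(n_genes), (n,)).copy(),
            "blank_mean": np.broadcast_to(np.asarray(blank_mean, dtype=float), (n,)).copy(),
            "class_label": (
                pd.array([None] * n) if class_label is None else np.asarray(class_label, dtype=object)
            ),
            "region_label": (
                pd.array([None] * n) if region_label is None else np.asarray(region_label, dtype=object)
            ),
            "modality": np.broadcast_to(np.asarray(modality, dtype=object), (n,)).copy(),
        }
    )
    return validate_cell_table(df)


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying numpy payloads."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
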