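"""Cells embedding: sub-vector partitioning and positional/modality coding.

Each cell's reduced expression vector (length D) is split row-major into
n_sub = ceil(D / s) sub-vectors of length s; the final sub-vector is
zero-padded.  Position and modality enter as learned additive embeddings
of width s, so the attention projection keeps its (s x 3s) shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubVectorBatch:
    """Partitioned model input: values (batch x n_sub x s)."""

    values: np.ndarray
    positions: np.ndarray
    modality_codes: np.ndarray
    source_modality: str = "rna"
    pad_width: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.modality_codes = np.asarray(self.modality_codes, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("values must be (batch, n_sub, s)")
        n_sub = self.values.shape[1]
        if len(self.positions) != n_sub or len(self.modality_codes) != n_sub:
            raise ValueError("positions/modality_codes must have one entry per sub-vector")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sub(self) -> int:
        return self.values.shape[1]

    @property
    def s(self) -> int:
        return self.values.shape[2]


def patch(cells: np.ndarray, s: int, modality_code: int = 0,
          source_modality: str = "rna") -> SubVectorBatch:
    """Split (n x D) into (n x n_sub x s) sub-vectors, zero-padding the tail."""
    cells = np.asarray(cells, dtype=np.float64)
    if cells.ndim != 2:
        raise ValueError("cells must be a 2-D matrix")
    n, D = cells.shape
    if D < 1 or s < 1:
        raise ValueError("D and s must be >= 1")
    if s > D:
        raise ValueError(f"s ({s}) > D ({D}): degenerate patching")
    n_sub = -(-D // s)  # ceil
    pad_width = n_sub * s - D
    padded = np.pad(cells, ((0, 0), (0, pad_width)))
    values = padded.reshape(n, n_sub, s)
    return SubVectorBatch(
        values=values,
        positions=np.arange(n_sub),
        modality_codes=np.full(n_sub, modality_code),
        source_modality=source_modality,
        pad_width=pad_width,
    )


def unpatch(batch: SubVectorBatch) -> np.ndarray:
    """Inverse of patch: concatenate sub-vectors and drop padding."""
    n, n_sub, s = batch.values.shape
    flat = batch.values.reshape(n, n_sub * s)
    D = n_sub * s - batch.pad_width
    return flat[:, :D].copy()


def encode(batch: SubVectorBatch, pos_table: np.ndarray,
           mod_table: np.ndarray) -> np.ndarray:
    """Add positional and modality embeddings:
    out[i, p, :] = values[i, p, :] + pos_table[pos(p)] + mod_table[code(p)].
    """
    pos_table = np.asarray(pos_table, dtype=np.float64)
    mod_table = np.asarray(mod_table, dtype=np.float64)
    if batch.positions.max() >= pos_table.shape[0]:
        raise IndexError("position out of pos_table range")
    if batch.modality_codes.max() >= mod_table.shape[0]:
        raise IndexError("modality code out of mod_table range")
    return batch.values + pos_table[batch.positions] + mod_table[batch.modality_codes]


def concat_batches(batches: list[SubVectorBatch]) -> SubVectorBatch:
    """Concatenate per-modality batches along the sub-vector axis with
    globally increasing positions (modality codes preserved)."""
    values = np.concatenate([b.values for b in batches], axis=1)
    n_total = values.shape[1]
    codes = np.concatenate([b.modality_codes for b in batches])
    return SubVectorBatch(
        values=values,
        positions=np.arange(n_total),
        modality_codes=codes,
        source_modality=batches[0].source_modality,
        pad_width=0,
    )
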