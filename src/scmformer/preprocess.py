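"""Normalization, feature selection and PCA dimension alignment.

All modalities end up as equal-width (aligned_dim) reduced matrices so
they can be patched into sub-vectors of a common length downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ModalityMatrix, PairedDataset


@dataclass
class PreprocessConfig:
    target_sum: float = 1e4
    n_hvg: int = 2000
    clr_pseudocount: float = 1.0
    aligned_dim: int = 128
    atac_tfidf: bool = True

    def __post_init__(self):
        if self.aligned_dim < 2:
            raise ValueError("aligned_dim must be >= 2")
        if self.clr_pseudocount <= 0:
            raise ValueError("clr_pseudocount must be positive")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")


def normalize_rna(m: ModalityMatrix, cfg: PreprocessConfig | None = None) -> ModalityMatrix:
    """Total-count normalize each cell to target_sum, then log1p.

    All-zero cells are left as zero rows (with a warning) rather than
    producing NaNs.
    """
    cfg = cfg or PreprocessConfig()
    if m.layer != "raw":
        raise ValueError("normalize_rna expects the raw layer")
    X = m.values
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero total count left as zero rows")
    scale = np.where(zero, 1.0, totals / cfg.target_sum)
    out = np.log1p(X / scale[:, None])
    return m.replace(values=out, layer="normalized")


def normalize_protein(m: ModalityMatrix, cfg: PreprocessConfig | None = None) -> ModalityMatrix:
    """Centered log-ratio per cell: y_j = log((x_j + c) / geomean(x + c)).

    Each output row sums to zero by construction.
    """
    cfg = cfg or PreprocessConfig()
    if m.layer != "raw":
        raise ValueError("normalize_protein expects the raw layer")
    if m.modality != "protein":
        raise ValueError("normalize_protein expects the protein modality")
    X = m.values
    if np.any(X < 0):
        raise ValueError("negative values in protein counts")
    logx = np.log(X + cfg.clr_pseudocount)
    out = logx - logx.mean(axis=1, keepdims=True)
    return m.replace(values=out, layer="normalized")


def tfidf_atac(m: ModalityMatrix, cfg: PreprocessConfig | None = None) -> ModalityMatrix:
    """TF-IDF weighting for peak count matrices, then log scaling."""
    cfg = cfg or PreprocessConfig()
    if m.layer != "raw":
        raise ValueError("tfidf_atac expects the raw layer")
    X = m.values
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    tf = X / totals
    n_cells = X.shape[0]
    idf = np.log1p(n_cells / (1.0 + (X > 0).sum(axis=0)))
    out = np.log1p(tf * idf * cfg.target_sum)
    return m.replace(values=out, layer="normalized")


def normalize(m: ModalityMatrix, cfg: PreprocessConfig | None = None) -> ModalityMatrix:
    """Dispatch to the modality-appropriate normalization."""
    cfg = cfg or PreprocessConfig()
    if m.modality == "protein":
        return normalize_protein(m, cfg)
    if m.modality == "atac" and cfg.atac_tfidf:
        return tfidf_atac(m, cfg)
    return normalize_rna(m, cfg)


def dispersion(X: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Normalized dispersion per feature: variance/mean, z-scored within
    mean bins (Seurat-style)."""
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # z-score dispersion within bins of comparable mean; small panels get
    # fewer bins so each bin holds enough features for a meaningful z-score
    n_bins = max(1, min(n_bins, X.shape[1] // 10))
    order = np.argsort(mean)
    bins = np.array_split(order, n_bins)
    norm_disp = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        sd = d.std()
        norm_disp[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    return norm_disp


def select_hvg(m: ModalityMatrix, n_hvg: int) -> ModalityMatrix:
    """Keep the n_hvg most variable features (binned normalized
    dispersion), preserving original feature order among the kept set."""
    if n_hvg < 2:
        raise ValueError("n_hvg must be >= 2")
    if m.layer != "normalized":
        raise ValueError("select_hvg expects the normalized layer")
    if m.n_features <= n_hvg:
        return m
    scores = dispersion(m.values)
    top = np.argsort(scores)[::-1][:n_hvg]
    keep = np.sort(top)
    return m.replace(
        values=m.values[:, keep],
        feature_ids=[m.feature_ids[i] for i in keep],
    )


def _pca_reduce(X: np.ndarray, n_comp: int) -> np.ndarray:
    """Project centered X onto its top n_comp principal axes (SVD)."""
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ Vt[:n_comp].T


def align_dims(ds: PairedDataset, aligned_dim: int) -> PairedDataset:
    """Bring every modality to exactly aligned_dim columns.

    Wide modalities are PCA-reduced on centered data; modalities with
    <= aligned_dim features are zero-padded instead (PCA cannot invent
    variance and small panels keep their native axes).
    """
    reduced = []
    for m in ds.modalities:
        if m.layer == "raw":
            raise ValueError(f"modality {m.modality} must be normalized before align_dims")
        X = m.values
        if X.shape[1] <= aligned_dim:
            pad = aligned_dim - X.shape[1]
            out = np.pad(X, ((0, 0), (0, pad)))
            fids = m.feature_ids + [f"pad_{i}" for i in range(pad)]
        else:
            if aligned_dim > X.shape[0]:
                raise ValueError(
                    f"aligned_dim {aligned_dim} exceeds cell count {X.shape[0]}: "
                    "PCA rank insufficient"
                )
            out = _pca_reduce(X, aligned_dim)
            fids = [f"pc_{i}" for i in range(aligned_dim)]
        reduced.append(m.replace(values=out, feature_ids=fids, layer="reduced"))
    return PairedDataset(reduced, pairing=ds.pairing, labels=ds.labels)


def preprocess_dataset(ds: PairedDataset, cfg: PreprocessConfig | None = None) -> PairedDataset:
    """Full pipeline: normalize -> HVG (RNA/ATAC) -> align dims."""
    cfg = cfg or PreprocessConfig()
    normed = []
    for m in ds.modalities:
        nm = normalize(m, cfg)
        if nm.modality in ("rna", "atac") and nm.n_features > cfg.n_hvg:
            nm = select_hvg(nm, cfg.n_hvg)
        normed.append(nm)
    return align_dims(
        PairedDataset(normed, pairing=ds.pairing, labels=ds.labels), cfg.aligned_dim
    )
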