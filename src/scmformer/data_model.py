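"""Core containers and IO for multimodal single-cell matrices and model artifacts."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import issparse

MODALITIES = ("rna", "protein", "atac")
LAYERS = ("raw", "normalized", "reduced")


@dataclass
class ModalityMatrix:
    """One modality's cells x features expression matrix.

    Rows are cells, columns are features.  `layer` records where the
    matrix sits in the processing pipeline (raw counts, normalized
    values, or the PCA-reduced representation fed to the model).
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    layer: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"row count {self.values.shape[0]} != {len(self.cell_ids)} cell ids"
            )
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"column count {self.values.shape[1]} != {len(self.feature_ids)} feature ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def replace(self, **kwargs) -> "ModalityMatrix":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PairedDataset:
    """Row-aligned collection of modality matrices over the same cells."""

    modalities: list[ModalityMatrix]
    pairing: str = "by_order"
    labels: list[str] | None = None

    def __post_init__(self):
        if not self.modalities:
            raise ValueError("at least one modality required")
        n = self.modalities[0].n_cells
        for m in self.modalities[1:]:
            if m.n_cells != n:
                raise ValueError("modalities have unequal cell counts")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length must match cell count")

    @property
    def n_cells(self) -> int:
        return self.modalities[0].n_cells

    def modality(self, name: str) -> ModalityMatrix:
        for m in self.modalities:
            if m.modality == name:
                return m
        raise KeyError(name)


@dataclass
class ScmModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the printed robustness ranges: fixed learning rate
    1e-4, batch size 32, fusion weight lambda inside [40, 100].
    """

    s: int = 16
    H: int = 4
    n_layers: int = 1
    drop_rate: float = 0.1
    lambda_rec: float = 70.0
    lr: float = 1e-4
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    aligned_dim: int = 128
    n_hvg: int = 2000

    def __post_init__(self):
        if self.s < 1 or self.H < 1 or self.n_layers < 1:
            raise ValueError("s, H and n_layers must be positive")
        if self.aligned_dim % self.s != 0:
            raise ValueError(
                f"aligned_dim ({self.aligned_dim}) must be divisible by s ({self.s})"
            )
        if self.s % self.H != 0:
            raise ValueError(f"s ({self.s}) must be divisible by H ({self.H})")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must be in [0, 1)")
        if self.lambda_rec < 0:
            raise ValueError("lambda_rec must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScmModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class LatentRepresentation:
    """Pooled per-modality cell embedding (cells x s)."""

    values: np.ndarray
    modality: str
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("latent values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent contains non-finite values")
        if self.cell_ids and len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    # 10x-style sidecar: one id per line, optionally tab-separated extras
    return [line.split("\t")[0] for line in
            path.read_text().splitlines() if line.strip()]


def read_modality(path, format: str, modality: str) -> ModalityMatrix:
    """Read one modality matrix from disk as the raw layer.

    `mtx_dir` expects matrix.mtx + barcodes.tsv + features.tsv;
    orientation (cells x features vs features x cells) is resolved
    against the sidecar lengths and an error is raised if ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "csv":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return ModalityMatrix(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=df.index.astype(str).tolist(),
            feature_ids=df.columns.astype(str).tolist(),
            modality=modality,
        )

    if format == "mtx_dir":
        mtx_path = path / "matrix.mtx"
        barcodes_path = path / "barcodes.tsv"
        features_path = path / "features.tsv"
        for p in (mtx_path, barcodes_path, features_path):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar file: {p}")
        mat = mmread(mtx_path)
        if issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=np.float64)
        barcodes = _read_id_column(barcodes_path)
        features = _read_id_column(features_path)
        n_b, n_f = len(barcodes), len(features)
        if mat.shape == (n_b, n_f) and mat.shape == (n_f, n_b):
            raise ValueError(
                "square matrix with equal sidecar lengths: orientation ambiguous"
            )
        if mat.shape == (n_b, n_f):
            pass
        elif mat.shape == (n_f, n_b):
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"(barcodes={n_b}, features={n_f}) orientation"
            )
        return ModalityMatrix(mat, barcodes, features, modality)

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if issparse(X):
            X = X.toarray()
        return ModalityMatrix(
            values=np.asarray(X, dtype=np.float64),
            cell_ids=adata.obs_names.astype(str).tolist(),
            feature_ids=adata.var_names.astype(str).tolist(),
            modality=modality,
        )

    raise ValueError(f"unknown format {format!r}")


def write_modality(m: ModalityMatrix, path, format: str = "csv") -> None:
    """Write a modality matrix (csv or mtx_dir)."""
    path = Path(path)
    if format == "csv":
        # %.17g keeps the float64 round-trip lossless
        pd.DataFrame(m.values, index=m.cell_ids,
                     columns=m.feature_ids).to_csv(path, float_format="%.17g")
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        from scipy.sparse import coo_matrix

        mmwrite(str(path / "matrix.mtx"), coo_matrix(m.values))
        (path / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (path / "features.tsv").write_text("\n".join(m.feature_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def pair(datasets: list[ModalityMatrix], mode: str = "by_order",
         labels: list[str] | None = None) -> PairedDataset:
    """Row-align modality matrices into a PairedDataset.

    by_order: matrices must already have equal cell counts.
    by_barcode: the cell-id intersection is taken, in the order the ids
    appear in the first modality; all modalities are reindexed to it.
    """
    if mode == "by_order":
        n = datasets[0].n_cells
        for m in datasets[1:]:
            if m.n_cells != n:
                raise ValueError(
                    f"by_order pairing requires equal cell counts "
                    f"(got {n} and {m.n_cells})"
                )
        return PairedDataset(list(datasets), pairing="by_order", labels=labels)

    if mode == "by_barcode":
        common = set(datasets[0].cell_ids)
        for m in datasets[1:]:
            common &= set(m.cell_ids)
        if not common:
            raise ValueError("empty barcode intersection")
        order = [c for c in datasets[0].cell_ids if c in common]
        aligned = []
        for m in datasets:
            idx = {c: i for i, c in enumerate(m.cell_ids)}
            rows = [idx[c] for c in order]
            aligned.append(m.replace(values=m.values[rows], cell_ids=list(order)))
        if labels is not None:
            idx0 = {c: i for i, c in enumerate(datasets[0].cell_ids)}
            labels = [labels[idx0[c]] for c in order]
        return PairedDataset(aligned, pairing="by_barcode", labels=labels)

    raise ValueError(f"unknown pairing mode {mode!r}")


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Save trained weights + config as a single npz archive.

    Round-trip is bit-exact: arrays are stored in float64 without
    conversion and the config travels as a JSON string.
    """
    path = Path(path)
    arrays = {f"param:{k}": v for k, v in model.state_dict().items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    arrays["meta_json"] = np.frombuffer(
        json.dumps(model.meta).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path):
    """Load a model saved by save_model; validates weight shapes."""
    from .scm_model import ScmFormerModel

    path = Path(path)
    with np.load(path) as npz:
        config = ScmModelConfig.from_dict(
            json.loads(bytes(npz["config_json"]).decode())
        )
        meta = json.loads(bytes(npz["meta_json"]).decode())
        state = {
            k[len("param:"):]: npz[k] for k in npz.files if k.startswith("param:")
        }
    model = ScmFormerModel(config, **meta)
    model.load_state_dict(state)
    return model
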