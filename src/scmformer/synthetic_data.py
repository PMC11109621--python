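"""Seeded generator of paired multimodal single-cell data.

Cells share a per-cell latent state across modalities (cluster centroids
plus within-type jitter); RNA is Poisson counts on an exponentiated
linear map of that latent, protein is rounded exponentiated abundance
with background, both with optional noise, dropout and batch shifts.
A linear-Gaussian family — simple, but it has exactly the shared-latent
pairing structure the fusion objective exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ModalityMatrix, PairedDataset

WITHIN_TYPE_SD = 0.3


@dataclass
class SimConfig:
    n_cells: int = 600
    n_types: int = 3
    n_genes: int = 400
    n_proteins: int = 40
    latent_dim: int = 10
    noise_sd_rna: float = 0.1
    noise_sd_protein: float = 0.1
    batch_shift_sd: float = 0.0
    n_batches: int = 1
    dropout_rate_rna: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if not 0.0 <= self.dropout_rate_rna < 1.0:
            raise ValueError("dropout_rate_rna must be in [0, 1)")
        for name in ("noise_sd_rna", "noise_sd_protein", "batch_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    cell_types: list[str]
    latent_states: np.ndarray
    centroids: np.ndarray
    loadings: dict[str, np.ndarray]
    offsets: dict[str, float] = field(default_factory=dict)


SMALL_PRESET = SimConfig()


def _rna_counts(Z: np.ndarray, loadings: np.ndarray, cfg: SimConfig,
                rng: np.random.Generator) -> np.ndarray:
    log_rate = Z @ loadings + 1.0  # base offset keeps mean counts O(3-10)
    log_rate += rng.normal(0.0, 0.2, size=(Z.shape[0], 1))  # cell-size factor
    if cfg.noise_sd_rna > 0:
        log_rate += rng.normal(0.0, cfg.noise_sd_rna, size=log_rate.shape)
    counts = rng.poisson(np.exp(np.clip(log_rate, -20, 8))).astype(np.float64)
    if cfg.dropout_rate_rna > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_rate_rna
        counts *= keep
    return counts


def _protein_counts(Z: np.ndarray, loadings: np.ndarray, cfg: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    log_abund = Z @ loadings + 2.0  # ADT background level
    if cfg.noise_sd_protein > 0:
        log_abund += rng.normal(0.0, cfg.noise_sd_protein, size=log_abund.shape)
    abund = np.exp(np.clip(log_abund, -20, 10))
    abund += rng.normal(0.0, 0.5, size=abund.shape)  # pre-rounding noise
    return np.maximum(np.round(abund), 0.0)


def simulate_paired(cfg: SimConfig) -> tuple[PairedDataset, SimTruth]:
    """Generate a paired RNA + protein dataset with shared latent states."""
    rng = np.random.default_rng(cfg.seed)
    centroids = rng.normal(0.0, 1.0, size=(cfg.n_types, cfg.latent_dim))
    types = rng.integers(0, cfg.n_types, size=cfg.n_cells)
    Z = centroids[types] + rng.normal(0.0, WITHIN_TYPE_SD,
                                      size=(cfg.n_cells, cfg.latent_dim))
    scale = 1.0 / np.sqrt(cfg.latent_dim)
    L_rna = rng.normal(0.0, scale, size=(cfg.latent_dim, cfg.n_genes))
    L_prot = rng.normal(0.0, scale, size=(cfg.latent_dim, cfg.n_proteins))

    rna = _rna_counts(Z, L_rna, cfg, rng)
    prot = _protein_counts(Z, L_prot, cfg, rng)

    if cfg.batch_shift_sd > 0 and cfg.n_batches > 1:
        batches = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
        for counts, width in ((rna, cfg.n_genes), (prot, cfg.n_proteins)):
            shifts = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_batches, width))
            counts += np.maximum(np.round(shifts[batches]), 0.0)

    cells = [f"cell_{i}" for i in range(cfg.n_cells)]
    labels = [f"type_{t}" for t in types]
    ds = PairedDataset(
        modalities=[
            ModalityMatrix(rna, cells, [f"gene_{j}" for j in range(cfg.n_genes)],
                           "rna"),
            ModalityMatrix(prot, cells, [f"prot_{j}" for j in range(cfg.n_proteins)],
                           "protein"),
        ],
        pairing="by_order",
        labels=labels,
    )
    truth = SimTruth(
        cell_types=labels,
        latent_states=Z,
        centroids=centroids,
        loadings={"rna": L_rna, "protein": L_prot},
        offsets={"rna": 1.0, "protein": 2.0},
    )
    return ds, truth


@dataclass
class QuerySet:
    """An unpaired query in one modality plus its held-out counterpart."""

    query: ModalityMatrix
    counterpart: ModalityMatrix
    labels: list[str]
    latent_states: np.ndarray


def simulate_unpaired_query(cfg: SimConfig, truth: SimTruth, n_query: int,
                            modality: str = "rna", seed: int | None = None,
                            type_proportions=None) -> QuerySet:
    """Draw new cells from the existing centroids/loadings; return the
    requested modality as the query and the other as the hidden truth."""
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if type_proportions is None:
        types = rng.integers(0, cfg.n_types, size=n_query)
    else:
        p = np.asarray(type_proportions, dtype=np.float64)
        types = rng.choice(cfg.n_types, size=n_query, p=p / p.sum())
    Z = truth.centroids[types] + rng.normal(0.0, WITHIN_TYPE_SD,
                                            size=(n_query, cfg.latent_dim))
    rna = _rna_counts(Z, truth.loadings["rna"], cfg, rng)
    prot = _protein_counts(Z, truth.loadings["protein"], cfg, rng)
    cells = [f"query_{i}" for i in range(n_query)]
    rna_mm = ModalityMatrix(rna, cells, [f"gene_{j}" for j in range(cfg.n_genes)],
                            "rna")
    prot_mm = ModalityMatrix(prot, cells,
                             [f"prot_{j}" for j in range(cfg.n_proteins)], "protein")
    query, counterpart = (rna_mm, prot_mm) if modality == "rna" else (prot_mm, rna_mm)
    return QuerySet(
        query=query,
        counterpart=counterpart,
        labels=[f"type_{t}" for t in types],
        latent_states=Z,
    )
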