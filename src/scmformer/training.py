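"""Multi-task objectives and the two training regimes: paired
integration of 2-3 modalities and cross-modality generation.

Integration loss:  lambda * sum_m MSE(recon_m, X_m) + Loss_comb,
where Loss_comb is the MSE between per-modality pooled latents (mean
over all unordered pairs when >2 modalities).  Generation reuses the
reconstruction MSE against the measured target modality alone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .data_model import (LatentRepresentation, ModalityMatrix, PairedDataset,
                         ScmModelConfig)
from .embedding import patch
from .scm_model import ScmFormerModel

logger = logging.getLogger("scmformer")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _mse_t(a: Tensor, b: Tensor) -> Tensor:
    d = a - b
    return (d * d).mean()


def loss_rec(x_reconstruction, x) -> float:
    """Mean squared error over all entries."""
    a = np.asarray(x_reconstruction, dtype=np.float64)
    b = np.asarray(x, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def loss_comb(latents: list) -> float:
    """Fusion loss: MSE between paired latents; for >=3 modalities the
    unweighted mean over all unordered pairs."""
    arrays = [np.asarray(getattr(l, "values", l), dtype=np.float64) for l in latents]
    if len(arrays) < 2:
        raise ValueError("loss_comb needs at least two latents")
    n = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != n:
            raise ValueError("latents must have identical shapes (paired rows)")
    pairs = list(itertools.combinations(arrays, 2))
    return float(np.mean([np.mean((a - b) ** 2) for a, b in pairs]))


def loss_integration(rec_losses, comb: float, lam: float) -> float:
    """lambda * (sum of per-modality reconstruction losses) + fusion loss."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(lam * np.sum(rec_losses) + comb)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam over the model's parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# tasks
# ---------------------------------------------------------------------------

@dataclass
class LossTrace:
    """Per-epoch mean totals and components."""

    total: list[float] = field(default_factory=list)
    rec: list[float] = field(default_factory=list)
    comb: list[float] = field(default_factory=list)


@dataclass
class IntegrationTask:
    dataset: PairedDataset
    config: ScmModelConfig

    def __post_init__(self):
        for m in self.dataset.modalities:
            if m.layer != "reduced":
                raise ValueError("integration expects the reduced layer")
            if m.n_features % self.config.s != 0:
                raise ValueError(
                    f"aligned dim {m.n_features} not divisible by s={self.config.s}"
                )


@dataclass
class GenerationTask:
    dataset: PairedDataset
    config: ScmModelConfig
    source_modality: str
    target_modality: str
    target_values: np.ndarray | None = None  # normalized target (n x v_target)

    def __post_init__(self):
        src = self.dataset.modality(self.source_modality)
        if src.layer != "reduced":
            raise ValueError("generation source must be the reduced layer")
        if self.target_values is None:
            self.target_values = self.dataset.modality(self.target_modality).values
        self.target_values = np.asarray(self.target_values, dtype=np.float64)
        if self.target_values.shape[0] != self.dataset.n_cells:
            raise ValueError("target rows must pair with source cells")


def _patch_stack(values_list: list[np.ndarray], s: int) -> np.ndarray:
    """Patch each modality and concatenate along the sub-vector axis."""
    return np.concatenate(
        [patch(v, s, modality_code=i).values for i, v in enumerate(values_list)],
        axis=1,
    )


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def build_integration_model(task: IntegrationTask) -> ScmFormerModel:
    cfg = task.config
    names = [m.modality for m in task.dataset.modalities]
    n_sub = [-(-m.n_features // cfg.s) for m in task.dataset.modalities]
    head_dims = {m.modality: m.n_features for m in task.dataset.modalities}
    return ScmFormerModel(cfg, names, n_sub, head_dims)


def train_integration(task: IntegrationTask,
                      model: ScmFormerModel | None = None
                      ) -> tuple[ScmFormerModel, LossTrace]:
    """Mini-batch Adam training of the integration objective.

    The same cell indices are drawn across modalities in every batch, so
    the fusion loss always compares paired cells.
    """
    cfg = task.config
    model = model or build_integration_model(task)
    values = [m.values for m in task.dataset.modalities]
    names = [m.modality for m in task.dataset.modalities]
    stacked = _patch_stack(values, cfg.s)
    n = stacked.shape[0]

    opt = Adam(model.params, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    trace = LossTrace()
    for epoch in range(cfg.epochs):
        tot, rec_acc, comb_acc, n_batches = 0.0, 0.0, 0.0, 0
        for idx in _epoch_batches(n, cfg.batch_size, rng):
            opt.zero_grad()
            latents, recons = model.forward(stacked[idx], training=True, rng=rng)
            rec_terms = [
                _mse_t(recons[name], Tensor(values[i][idx]))
                for i, name in enumerate(names)
            ]
            rec_sum = rec_terms[0]
            for t in rec_terms[1:]:
                rec_sum = rec_sum + t
            pairs = list(itertools.combinations(names, 2))
            comb = _mse_t(latents[pairs[0][0]], latents[pairs[0][1]])
            for a, b in pairs[1:]:
                comb = comb + _mse_t(latents[a], latents[b])
            comb = comb * (1.0 / len(pairs))
            total = rec_sum * cfg.lambda_rec + comb
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            total.backward()
            opt.step()
            tot += float(total.data)
            rec_acc += float(rec_sum.data)
            comb_acc += float(comb.data)
            n_batches += 1
        trace.total.append(tot / n_batches)
        trace.rec.append(rec_acc / n_batches)
        trace.comb.append(comb_acc / n_batches)
        logger.info("epoch=%d loss=%.6f rec=%.6f comb=%.6f",
                    epoch, trace.total[-1], trace.rec[-1], trace.comb[-1])
    return model, trace


def extract_latents(model: ScmFormerModel,
                    dataset: PairedDataset) -> dict[str, LatentRepresentation]:
    """Inference-mode pooled latents per modality (dropout off)."""
    cfg = model.config
    stacked = _patch_stack([m.values for m in dataset.modalities], cfg.s)
    latents, _ = model.forward_arrays(stacked)
    cell_ids = dataset.modalities[0].cell_ids
    return {
        name: LatentRepresentation(values=v, modality=name, cell_ids=list(cell_ids))
        for name, v in latents.items()
    }


def build_generation_model(task: GenerationTask) -> ScmFormerModel:
    cfg = task.config
    src = task.dataset.modality(task.source_modality)
    n_sub = -(-src.n_features // cfg.s)
    return ScmFormerModel(
        cfg, [task.source_modality], [n_sub],
        {task.target_modality: task.target_values.shape[1]},
    )


def train_generation(task: GenerationTask,
                     model: ScmFormerModel | None = None
                     ) -> tuple[ScmFormerModel, LossTrace]:
    """Train source -> target prediction with the reconstruction MSE."""
    cfg = task.config
    model = model or build_generation_model(task)
    src = task.dataset.modality(task.source_modality).values
    stacked = _patch_stack([src], cfg.s)
    target = task.target_values
    n = stacked.shape[0]

    opt = Adam(model.params, cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    trace = LossTrace()
    for epoch in range(cfg.epochs):
        tot, n_batches = 0.0, 0
        for idx in _epoch_batches(n, cfg.batch_size, rng):
            opt.zero_grad()
            _, recons = model.forward(stacked[idx], training=True, rng=rng)
            loss = _mse_t(recons[task.target_modality], Tensor(target[idx]))
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}"
                )
            loss.backward()
            opt.step()
            tot += float(loss.data)
            n_batches += 1
        trace.total.append(tot / n_batches)
        trace.rec.append(trace.total[-1])
        trace.comb.append(0.0)
        logger.info("epoch=%d loss=%.6f", epoch, trace.total[-1])
    return model, trace


def generate(model: ScmFormerModel, source: ModalityMatrix) -> np.ndarray:
    """Deterministic forward prediction of the target modality."""
    cfg = model.config
    if source.layer != "reduced":
        raise ValueError("source must be preprocessed to the reduced layer")
    expected = model.n_sub_per_mod[0] * cfg.s
    if -(-source.n_features // cfg.s) != model.n_sub_per_mod[0]:
        raise ValueError(
            f"source width {source.n_features} incompatible with trained "
            f"width {expected}"
        )
    stacked = _patch_stack([source.values], cfg.s)
    _, recons = model.forward_arrays(stacked)
    (target_name,) = model.head_dims.keys()
    return recons[target_name]
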