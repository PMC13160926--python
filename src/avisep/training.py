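"""SI-SNR objective, permutation-invariant assignment, and the training loop.

The separation loss is the negative scale-invariant signal-to-noise ratio
between each estimate and its clean reference.  For reference ``s`` and
estimate ``s_hat``::

    alpha   = s^T s_hat / ||s||^2
    SI-SNR  = 10 log10( ||alpha s||^2 / ||s_hat - alpha s||^2 )   [dB]

The scalar projection ``alpha`` removes any gain difference, so the metric
depends only on signal shape.  Separated channels carry no intrinsic order, so
the loss is permutation-invariant: for k outputs the assignment maximizing the
mean SI-SNR is found by exhaustive search over the k! <= 24 permutations.

Counting is a multi-class classification task trained with cross-entropy on
the network's latent feature map.  By default the count loss back-propagates
into the shared features (end-to-end joint training); a detached mode is
available via ``TrainConfig.counter_backprop``.  During training the true
count selects the decoder head (teacher forcing); at inference the counter
selects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .mixture import MixtureExample
from .separation import CountSepModel

EPS = 1e-8
SISNR_CAP = 60.0  # dB clamp; a perfect reconstruction has zero residual

__all__ = [
    "TrainConfig",
    "si_snr",
    "pit_si_snr",
    "pit_si_snr_loss",
    "count_loss",
    "lr_at_epoch",
    "train",
]


@dataclass
class TrainConfig:
    """Optimization schedule (Adam, lr 1e-3 decayed by 0.98 every 2 epochs)."""

    lr: float = 1e-3
    epochs: int = 100
    lr_decay: float = 0.98
    decay_every: int = 2
    batch_size: int = 4
    seed: int = 0
    max_sources: int = 4
    count_loss_weight: float = 0.5
    grad_clip: float = 5.0
    #: when True the counter cross-entropy also shapes the shared features
    #: (end-to-end); when False the heads read a detached feature view
    counter_backprop: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0 or not (0 < self.lr_decay <= 1) or self.epochs < 1:
            raise ValueError("invalid training configuration")


# ---------------------------------------------------------------------------
# SI-SNR (metric form, NumPy)
# ---------------------------------------------------------------------------

def si_snr(estimate: np.ndarray, reference: np.ndarray) -> float:
    """Scale-invariant SNR in dB, clamped to +-60 dB."""
    s = np.asarray(reference, dtype=np.float64)
    s_hat = np.asarray(estimate, dtype=np.float64)
    if s.shape != s_hat.shape:
        raise ValueError("estimate and reference must have equal length")
    s_energy = float(np.dot(s, s))
    if s_energy == 0.0:
        raise ValueError("all-zero reference")
    alpha = float(np.dot(s, s_hat)) / s_energy
    target = alpha * s
    num = float(np.dot(target, target))
    den = float(np.sum((s_hat - target) ** 2))
    value = 10.0 * math.log10((num + EPS) / (den + EPS))
    return float(np.clip(value, -SISNR_CAP, SISNR_CAP))


def pit_si_snr(estimates: np.ndarray, references: np.ndarray
               ) -> tuple[float, tuple[int, ...]]:
    """Best-permutation mean SI-SNR (metric form) and the chosen assignment."""
    k = len(estimates)
    if k != len(references):
        raise ValueError("estimate/reference arity mismatch")
    best, best_perm = -np.inf, tuple(range(k))
    for perm in itertools.permutations(range(k)):
        val = np.mean([si_snr(estimates[i], references[perm[i]]) for i in range(k)])
        if val > best:
            best, best_perm = float(val), perm
    return best, best_perm


# ---------------------------------------------------------------------------
# differentiable losses
# ---------------------------------------------------------------------------

_LOG10 = math.log(10.0)


def _si_snr_matrix(estimates: nn.Tensor, references: np.ndarray) -> nn.Tensor:
    """Pairwise SI-SNR tensor: estimates (B, k, L) x references (B, k, L)
    -> (B, k_est, k_ref)."""
    B, k, L = estimates.data.shape
    est = estimates.reshape(B, k, 1, L)
    ref = np.asarray(references, dtype=np.float64)[:, None, :, :]  # (B,1,k,L)
    ref_energy = np.sum(ref * ref, axis=-1)  # (B,1,k)
    alpha = (est * ref).sum(axis=-1) * (1.0 / ref_energy)  # (B,k,k)
    target_energy = alpha * alpha * ref_energy  # ||alpha s||^2
    # residual energy: ||e||^2 - 2 alpha <e,s> + alpha^2 ||s||^2
    est_energy = (est * est).sum(axis=-1)
    cross = (est * ref).sum(axis=-1)
    resid = est_energy - alpha * cross * 2.0 + target_energy
    val = ((target_energy + EPS) / (resid + EPS)).log() * (10.0 / _LOG10)
    return val.clamp(-SISNR_CAP, SISNR_CAP)


def pit_si_snr_loss(estimates: nn.Tensor | np.ndarray,
                    references: np.ndarray) -> nn.Tensor:
    """Negative best-permutation mean SI-SNR over a batch (differentiable).

    ``estimates`` (B, k, L) or (k, L); the permutation is chosen per batch item
    by exhaustive search, then the loss reads the selected matrix entries.
    """
    if not isinstance(estimates, nn.Tensor):
        estimates = nn.Tensor(np.asarray(estimates, dtype=np.float64))
    if estimates.data.ndim == 2:
        estimates = estimates.reshape(1, *estimates.data.shape)
        references = np.asarray(references)[None]
    B, k, _ = estimates.data.shape
    if np.asarray(references).shape[:2] != (B, k):
        raise ValueError("estimate/reference arity mismatch")
    matrix = _si_snr_matrix(estimates, references)  # (B, k, k)
    perms = list(itertools.permutations(range(k)))
    scores = np.stack(
        [matrix.data[:, range(k), perm].mean(axis=-1) for perm in perms], axis=0)
    best = np.argmax(scores, axis=0)  # (B,)
    select = np.zeros((B, k, k))
    for b, p in enumerate(best):
        select[b, range(k), perms[p]] = 1.0
    return -(matrix * select).sum() * (1.0 / (B * k))


def count_loss(logits: nn.Tensor | np.ndarray, true_n: np.ndarray | int) -> nn.Tensor:
    """Cross-entropy over candidate counts; labels are counts in {1..N}."""
    if not isinstance(logits, nn.Tensor):
        logits = nn.Tensor(np.asarray(logits, dtype=np.float64))
    if logits.data.ndim == 1:
        logits = logits.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(true_n, dtype=int)) - 1
    n_classes = logits.data.shape[-1]
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ValueError("true count outside 1..N")
    return nn.cross_entropy(logits, labels)


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepped exponential decay: lr * decay^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr * config.lr_decay ** (epoch // config.decay_every)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batches(examples: list[MixtureExample], batch_size: int,
             rng: np.random.Generator):
    """Shuffle then batch examples, grouping equal source counts together."""
    order = rng.permutation(len(examples))
    by_k: dict[int, list[int]] = {}
    for idx in order:
        by_k.setdefault(examples[idx].n_sources, []).append(int(idx))
    batches = []
    for k, idxs in by_k.items():
        for i in range(0, len(idxs), batch_size):
            batches.append(idxs[i:i + batch_size])
    rng.shuffle(batches)
    return batches


def train(model: CountSepModel, train_examples: list[MixtureExample],
          config: TrainConfig,
          valid_examples: list[MixtureExample] | None = None
          ) -> tuple[CountSepModel, pd.DataFrame]:
    """Joint teacher-forced training of separator and counter heads.

    Loss per batch = PIT SI-SNR loss + lambda * (counter cross-entropy for the
    improved and the baseline head, both reading the same separator features).
    Returns the model (restored to its best-validation parameters when a
    validation set is given) and a per-epoch metrics log.
    """
    if not train_examples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    # the counter heads form their own optimization group: clipping them
    # jointly with the (much larger) separation gradients would starve the
    # heads of their cross-entropy signal
    head_params = model.counter.parameters() + model.baseline_counter.parameters()
    head_ids = {id(p) for p in head_params}
    sep_params = [p for p in model.parameters() if id(p) not in head_ids]
    opt_sep = nn.Adam(sep_params, lr=config.lr)
    opt_head = nn.Adam(head_params, lr=config.lr)
    log_rows = []
    best_metric, best_state = -np.inf, None
    for epoch in range(config.epochs):
        opt_sep.lr = opt_head.lr = lr_at_epoch(config, epoch)
        epoch_losses = []
        for batch_idx in _batches(train_examples, config.batch_size, rng):
            batch = [train_examples[i] for i in batch_idx]
            k = batch[0].n_sources
            mix = nn.Tensor(np.stack([b.mixture for b in batch]))
            refs = np.stack([np.stack(b.sources) for b in batch])
            est, feats = model.forward_separate(mix, k)
            loss = pit_si_snr_loss(est, refs)
            feats_for_count = feats if config.counter_backprop else feats.detach()
            labels = np.full(len(batch), k)
            ce = count_loss(model.counter.forward(feats_for_count), labels)
            ce_base = count_loss(model.baseline_counter.forward(feats_for_count), labels)
            loss = loss + config.count_loss_weight * (ce + ce_base)
            opt_sep.zero_grad()
            opt_head.zero_grad()
            loss.backward()
            nn.clip_grad_norm(opt_sep.params, config.grad_clip)
            nn.clip_grad_norm(opt_head.params, config.grad_clip)
            opt_sep.step()
            opt_head.step()
            epoch_losses.append(loss.item())
        row = {"epoch": epoch, "lr": opt_sep.lr,
               "train_loss": float(np.mean(epoch_losses))}
        if valid_examples:
            row.update(evaluate_epoch(model, valid_examples))
            metric = row["valid_si_snr"]
            if metric > best_metric:
                best_metric = metric
                best_state = {k2: v.copy() for k2, v in model.state_dict().items()}
        log_rows.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(log_rows)


def evaluate_epoch(model: CountSepModel, examples: list[MixtureExample],
                   batch_size: int = 25) -> dict:
    """Teacher-forced validation: mean best-permutation SI-SNR + count accuracy."""
    vals, correct = [], 0
    by_k: dict[int, list[MixtureExample]] = {}
    for ex in examples:
        by_k.setdefault(ex.n_sources, []).append(ex)
    for k, group in by_k.items():
        for i in range(0, len(group), batch_size):
            chunk = group[i:i + batch_size]
            mix = nn.Tensor(np.stack([e.mixture for e in chunk]))
            est, feats = model.forward_separate(mix, k)
            for j, ex in enumerate(chunk):
                val, _ = pit_si_snr(est.data[j], np.stack(ex.sources))
                vals.append(val)
            logits = model.counter.forward(feats.detach()).data
            correct += int(np.sum(np.argmax(logits, axis=-1) + 1 == k))
    return {"valid_si_snr": float(np.mean(vals)),
            "valid_count_acc": correct / len(examples)}
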