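"""Supervised training of the spectrum-recovery network on synthetic pairs.

The network learns the mapping from undersampled, noisy real spectra to
their ideal fully sampled noiseless counterparts by minimizing mean squared
error with adaptive-moment gradient descent.  Everything — data order,
dropout, validation split — derives from the configured seed, so a run is
reproducible on one device.
"""

from __future__ import annotations


import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nn
from .sepsnet import Model, NetworkConfig
from .simkit import (
    AcquisitionParams,
    Dataset,
    PeakSet,
    SimConfig,
    TrainingPair,
    add_noise,
    apply_nus,
    fid_to_spectrum,
    make_nus_schedule,
    synthesize_fid,
)

__all__ = ["TrainConfig", "mse_loss", "train", "m_to_s_augment", "FAST_PROFILE"]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``m_to_s > 1`` enables the M-to-S augmentation: each ideal label is paired
    with several undersampled inputs drawn with distinct sampling schedules
    (and optionally distinct NUS levels), teaching one model to serve
    multiple sampling conditions.
    """

    n_train: int = 4000
    val_fraction: float = 0.1
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    m_to_s: int = 1

    def __post_init__(self) -> None:
        if min(self.n_train, self.batch_size, self.epochs, self.m_to_s) < 1:
            raise ValueError("n_train, batch_size, epochs, m_to_s must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def mse_loss(prediction: np.ndarray, label: np.ndarray) -> float:
    """Mean of squared differences over all elements."""
    prediction = np.asarray(prediction)
    label = np.asarray(label)
    if prediction.shape != label.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {label.shape}")
    d = prediction.astype(np.float64) - label.astype(np.float64)
    return float(np.mean(d * d))


def train(model: Model, dataset: Dataset, config: TrainConfig) -> tuple[Model, pd.DataFrame]:
    """Train in place and return (model with best-validation weights, history).

    History has one row per epoch with mean train-batch loss and validation
    loss; the returned weights are those of the epoch with the lowest
    validation loss.  A non-finite loss aborts with a diagnostic.
    """
    n = len(dataset)
    x = dataset.inputs
    y = dataset.labels
    if x.shape[1] != model.config.n_input:
        raise ValueError(
            f"dataset spectra length {x.shape[1]} != model input {model.config.n_input}"
        )
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training data")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    optimizer = _nn.Adam(model.net, lr=config.learning_rate)
    history: list[dict] = []
    best_val = math.inf
    best_state: dict[str, np.ndarray] | None = None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train_idx)
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(x[idx], training=True)
            target = y[idx]
            diff = pred.astype(np.float64) - target
            loss = float(np.mean(diff * diff))
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            batch_losses.append(loss)
            grad = (2.0 / diff.size) * diff
            model.net.backward(grad[:, :, None].astype(np.float32))
            optimizer.step()
        val_pred = _predict_in_batches(model, x[val_idx], config.batch_size)
        val_loss = mse_loss(val_pred, y[val_idx])
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(batch_losses)),
             "val_loss": val_loss}
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = _snapshot(model)

    if best_state is not None:
        _restore(model, best_state)
    model.training_meta.update(
        {"seed": config.seed, "epochs": config.epochs, "best_val_loss": best_val,
         "n_train": int(len(train_idx)), "n_val": int(n_val)}
    )
    return model, pd.DataFrame(history)


def _predict_in_batches(model: Model, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [
        model.forward(x[i:i + batch_size], training=False)
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(outs, axis=0)


def _snapshot(model: Model) -> dict[str, np.ndarray]:
    state = {f"p/{k}": v.copy() for k, v in _nn.named_parameters(model.net).items()}
    state |= {f"b/{k}": v.copy() for k, v in _nn.named_buffers(model.net).items()}
    return state


def _restore(model: Model, state: dict[str, np.ndarray]) -> None:
    for k, v in _nn.named_parameters(model.net).items():
        v[...] = state[f"p/{k}"]
    for k, v in _nn.named_buffers(model.net).items():
        v[...] = state[f"b/{k}"]


def m_to_s_augment(
    peaks: PeakSet,
    acq: AcquisitionParams,
    config: SimConfig,
    m: int,
    rng: np.random.Generator,
    n_keep_choices: tuple[int, ...] = (15,),
) -> list[TrainingPair]:
    """Build ``m`` undersampled inputs sharing one ideal label.

    Schedules are pairwise distinct; NUS levels cycle through
    ``n_keep_choices``.  Raises if ``m`` exceeds the number of distinct
    schedules available.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n_possible = sum(
        math.comb(acq.n_chunks - 1, k - 1) for k in set(n_keep_choices)
    )
    if m > n_possible:
        raise ValueError(f"m = {m} exceeds {n_possible} distinct schedules")
    fid = synthesize_fid(peaks, acq)
    label = fid_to_spectrum(fid)
    peak_amp = float(np.max(np.abs(fid.samples)))
    pairs: list[TrainingPair] = []
    seen: set[tuple[int, ...]] = set()
    while len(pairs) < m:
        keep = n_keep_choices[len(pairs) % len(n_keep_choices)]
        schedule = make_nus_schedule(acq.n_chunks, keep, rng)
        if schedule.sampled in seen:
            continue
        seen.add(schedule.sampled)
        sigma = float(rng.uniform(*config.sigma_rel_range)) * peak_amp
        nus = apply_nus(add_noise(fid, sigma, rng), schedule)
        pairs.append(
            TrainingPair(input=fid_to_spectrum(nus), label=label,
                         schedule=schedule, peaks=peaks, sigma=sigma)
        )
    return pairs


# ---------------------------------------------------------------------------
# CPU fast profile
# ---------------------------------------------------------------------------

#: Scaled-down study conditions for CPU-only runs: the chunk count (93) and
#: all sampling arithmetic are kept, while the chunk length (8 complex
#: points, zero-filled to 1024), channel width (16) and dataset size shrink
#: so a full train/evaluate cycle fits in minutes on one core.  The sweep
#: width scales with the transform length, preserving the 0.49 Hz/bin
#: resolution and the 16 ms chunk duration of the full-scale geometry.
FAST_PROFILE: dict = {
    "sim": SimConfig(
        acq=AcquisitionParams(spectral_width_hz=500.0, chunk_len=8,
                              n_chunks=93, n_ft=1024),
        n_peaks_range=(3, 10),
        lw_range_hz=(1.0, 4.0),
    ),
    "network": NetworkConfig(n_input=1024, channels=16,
                             output_gamma_init=0.05),
    "train": TrainConfig(n_train=512, epochs=30, batch_size=32,
                         learning_rate=3e-3),
}
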