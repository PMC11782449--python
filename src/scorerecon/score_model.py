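"""Denoising score matching: training and evaluation of the learned prior.

The prior over z-normalized MRI slices is learned by multi-noise-level
denoising score matching.  For each noise scale sigma_i of a geometric
schedule, a sample x is perturbed to x + sigma_i * z with z ~ N(0, I) and
the network is trained so that its score estimate s(x', sigma_i, class)
matches -z / sigma_i, with the per-level weighting lambda(sigma) = sigma^2:

    L_i = sigma_i^2 * E || s(x + sigma_i z, sigma_i, c) + z / sigma_i ||^2.

The network parameterization folds the noise-scale conditioning into an
output scaling, s(x, sigma, c) = f(x, c) / sigma, which makes every level's
weighted objective the same noise-prediction problem || f + z ||^2 — a
standard construction for multi-scale score networks.  T1/T2 conditioning
enters as a learned per-class channel bias at every network stage.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import TrainingFailure
from .nn import Adam, ScoreUNet
from .phantoms import ImageSlice, SequenceClass
from .schedule import NoiseSchedule, geometric_schedule

__all__ = [
    "TrainConfig",
    "ScoreModelState",
    "score",
    "dsm_loss",
    "dsm_loss_for_fn",
    "train_prior",
    "save_state",
    "load_state",
]

_SIGMA_SLACK = 1e-9


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters for the score prior.

    Defaults target desk-scale 64x64 training on one CPU; ``channels`` and
    ``steps`` are the knobs that trade fidelity for time.
    """

    size: int = 64
    channels: int = 16
    n_levels: int = 10
    sigma_max: float = 1.0
    sigma_min: float = 0.01
    steps: int = 500
    batch_size: int = 8
    lr: float = 1e-3
    holdout: int = 8
    seed: int = 0
    class_conditional: bool = True


@dataclass
class ScoreModelState:
    """A trained (or initialized) score model: parameters + schedule + config."""

    params: dict[str, np.ndarray]
    schedule: NoiseSchedule
    config: TrainConfig
    seed: int
    class_labels: tuple[str, ...] = ("T1", "T2")

    _net: ScoreUNet | None = field(default=None, repr=False, compare=False)

    def network(self) -> ScoreUNet:
        if self._net is None:
            net = ScoreUNet(
                channels=self.config.channels,
                n_classes=len(self.class_labels),
                seed=self.seed,
            )
            net.set_params(self.params)
            self._net = net
        return self._net

    def checksum(self) -> int:
        import zlib

        c = 0
        for k in sorted(self.params):
            c = zlib.crc32(self.params[k].tobytes(), zlib.crc32(k.encode(), c))
        return c


def _label_index(state: ScoreModelState, class_label) -> int:
    if isinstance(class_label, SequenceClass):
        class_label = class_label.name
    if not state.config.class_conditional:
        return 0
    return state.class_labels.index(class_label)


def score(
    state: ScoreModelState,
    image: np.ndarray,
    sigma: float,
    class_label=SequenceClass.T2,
) -> np.ndarray:
    """Score estimate grad_x log p_sigma(x) for one image at noise scale sigma."""
    sched = state.schedule
    if not (sched.sigma_min - _SIGMA_SLACK <= sigma <= sched.sigma_max + _SIGMA_SLACK):
        raise ValueError(
            f"sigma={sigma} outside schedule range [{sched.sigma_min}, {sched.sigma_max}]"
        )
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    label = np.array([_label_index(state, class_label)])
    f = state.network().forward(image[None], label)[0]
    return f / sigma


def _score_batch(net: ScoreUNet, x: np.ndarray, labels: np.ndarray, sigma: float):
    return net.forward(x, labels) / sigma


def dsm_loss_for_fn(
    score_fn: Callable[[np.ndarray, float], np.ndarray],
    pixels: np.ndarray,
    sigma: float,
    z: np.ndarray,
) -> float:
    """Evaluate the sigma^2-weighted DSM objective for an arbitrary score function.

    ``pixels`` is (B, H, W), ``z`` the standard-normal perturbation of the
    same shape; the norm is the Euclidean norm over pixels, averaged over
    the batch.
    """
    s = score_fn(pixels + sigma * z, sigma)
    resid = s + z / sigma
    return float(sigma**2 * np.mean(np.sum(resid**2, axis=(1, 2))))


def dsm_loss(
    state: ScoreModelState,
    batch: Sequence[ImageSlice],
    sigma_index: int,
    seed: int,
) -> float:
    """DSM objective of the model on a batch at schedule level ``sigma_index`` (1-based)."""
    if len(batch) == 0:
        raise ValueError("batch must be non-empty")
    if not 1 <= sigma_index <= state.schedule.L:
        raise ValueError(f"sigma_index must be in [1, {state.schedule.L}]")
    sigma = float(state.schedule.sigmas[sigma_index - 1])
    pixels = np.stack([s.pixels for s in batch])
    labels = np.array([_label_index(state, s.sequence_class) for s in batch])
    rng = np.random.default_rng(np.random.PCG64(seed))
    z = rng.standard_normal(pixels.shape)
    net = state.network()
    return dsm_loss_for_fn(
        lambda x, sig: _score_batch(net, x, labels, sig), pixels, sigma, z
    )


def _heldout_loss(state: ScoreModelState, holdout: Sequence[ImageSlice], seed: int) -> float:
    # average over all schedule levels for a stable readout
    return float(
        np.mean(
            [dsm_loss(state, holdout, i + 1, seed + i) for i in range(state.schedule.L)]
        )
    )


def train_prior(
    slices: Sequence[ImageSlice], config: TrainConfig = TrainConfig()
) -> tuple[ScoreModelState, pd.DataFrame]:
    """Train the score prior on a set of z-normalized slices.

    Returns the trained state and a training log with columns
    ``step, loss, sigma_index`` (loss is the per-pixel mean squared
    noise-prediction error of the minibatch).  Raises
    :class:`TrainingFailure` carrying the last finite checkpoint if the
    loss becomes non-finite.
    """
    if len(slices) == 0:
        raise ValueError("training set must be non-empty")
    labels_present = {s.sequence_class for s in slices}
    if config.class_conditional and len(labels_present) < 2:
        raise ValueError(
            "class-conditional training needs both T1 and T2 slices; "
            "set class_conditional=False for a single-class prior"
        )

    schedule = geometric_schedule(config.sigma_max, config.sigma_min, config.n_levels)
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    net = ScoreUNet(channels=config.channels, n_classes=2, seed=config.seed)

    pixels = np.stack([s.pixels for s in slices])
    labels = np.array(
        [_label_index_from_class(s.sequence_class, config) for s in slices]
    )
    n = len(slices)
    order = rng.permutation(n)
    n_hold = min(config.holdout, max(1, n // 5))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    if len(train_idx) == 0:
        train_idx = hold_idx

    state = ScoreModelState(
        params=net.params(), schedule=schedule, config=config, seed=config.seed
    )
    state._net = net
    holdout_slices = [slices[i] for i in hold_idx]
    initial_holdout = _heldout_loss(state, holdout_slices, config.seed + 7919)

    opt = Adam(net.params(), lr=config.lr)
    log_rows = []
    last_good = {k: v.copy() for k, v in net.params().items()}
    for step in range(config.steps):
        idx = rng.choice(train_idx, size=min(config.batch_size, len(train_idx)), replace=False)
        sigma_index = int(rng.integers(0, schedule.L))
        sigma = float(schedule.sigmas[sigma_index])
        x, lab = pixels[idx], labels[idx]
        z = rng.standard_normal(x.shape)
        f = net.forward(x + sigma * z, lab)
        resid = f + z
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss):
            raise TrainingFailure(
                f"non-finite loss at step {step}",
                last_checkpoint=last_good,
                step=step,
            )
        net.zero_grads()
        net.backward(2.0 * resid / resid.size)
        opt.step(net.grads())
        log_rows.append({"step": step, "loss": loss, "sigma_index": sigma_index + 1})
        if step % 50 == 0:
            last_good = {k: v.copy() for k, v in net.params().items()}

    final_holdout = _heldout_loss(state, holdout_slices, config.seed + 7919)
    log = pd.DataFrame(log_rows)
    log.attrs["initial_holdout_loss"] = initial_holdout
    log.attrs["final_holdout_loss"] = final_holdout
    return state, log


def _label_index_from_class(c: SequenceClass, config: TrainConfig) -> int:
    return (0, 1)[c is SequenceClass.T2] if config.class_conditional else 0


# ---------------------------------------------------------------------------
# Checkpoint IO: one zip archive with parameters (npy), schedule and config
# ---------------------------------------------------------------------------

def save_state(state: ScoreModelState, path: str | Path) -> None:
    meta = {
        "schedule": state.schedule.to_dict(),
        "config": asdict(state.config),
        "seed": state.seed,
        "class_labels": list(state.class_labels),
        "checksum": state.checksum(),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for k, v in state.params.items():
            buf = io.BytesIO()
            np.save(buf, v)
            zf.writestr(f"params/{k}.npy", buf.getvalue())


def load_state(path: str | Path) -> ScoreModelState:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        params = {}
        for name in zf.namelist():
            if name.startswith("params/"):
                key = name[len("params/") : -len(".npy")]
                params[key] = np.load(io.BytesIO(zf.read(name)))
    state = ScoreModelState(
        params=params,
        schedule=NoiseSchedule.from_dict(meta["schedule"]),
        config=TrainConfig(**meta["config"]),
        seed=meta["seed"],
        class_labels=tuple(meta["class_labels"]),
    )
    if state.checksum() != meta["checksum"]:
        raise ValueError("checkpoint checksum mismatch")
    return state
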