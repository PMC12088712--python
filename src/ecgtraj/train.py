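"""Training and evaluation for the single-ECG BNP regressor (EBT) and the
dual-ECG three-class trajectory classifier (DEHT).

The public surface follows the fitted-model convention: :class:`EbtModel` /
:class:`DehtModel` are built from data plus configuration, their ``fit()``
returns :class:`EbtResults` / :class:`DehtResults` holding the trained
network, the training history and evaluation methods that produce report
objects with ``summary()`` tables.

Protocol per optimization step: draw a batch of samples, re-extract a fresh
random 2 s window per ECG (independent offsets for baseline and follow-up),
add uniform noise, and take one Adam step on the configured loss (MSE on
natural-log BNP, or cross-entropy with optional inverse-support class
weights).  The learning rate is either fixed or chosen by scoring a few
log-uniform draws from [1e-7, 1e-3] on validation loss after a short trial
run.  The best-validation checkpoint is returned.  Everything is seeded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .labeling import TrajectorySample, VisitPair
from .metrics import (BootstrapSpec, MetricsReport, RegressionReport,
                      classification_report, evaluate_regression,
                      sample_one_per_patient)
from .model import LeadTokenNetwork, ModelConfig, build_model
from .nn import Adam
from .nn import functional as F
from .preprocess import AugmentSpec, WindowSpec, add_uniform_noise, concat_dual, extract_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    lr: float | None = None          # fixed learning rate; None -> search
    lr_low: float = 1e-7
    lr_high: float = 1e-3
    n_trials: int = 5
    trial_steps: int = 50
    max_steps: int = 2000
    eval_every: int = 50
    patience: int = 4                # early-stop after this many stale evals
    max_val_samples: int = 256
    class_weighting: bool = True     # DEHT only
    noise_limit: float = 0.1         # mV, training augmentation
    window: WindowSpec = field(default_factory=WindowSpec)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_low < self.lr_high):
            raise ValueError("need 0 < lr_low < lr_high")


# -------------------------------------------------------------------------
# batch construction
# -------------------------------------------------------------------------

def _ebt_batch(visits: Sequence[VisitPair], idx: np.ndarray, window: WindowSpec,
               aug: AugmentSpec, rng: np.random.Generator):
    xs, ys = [], []
    for i in idx:
        v = visits[int(i)]
        xs.append(add_uniform_noise(extract_window(v.ecg, window, rng), aug, rng))
        ys.append(v.log_bnp)
    return np.stack(xs).astype(np.float32), np.array(ys, dtype=np.float64)


def _deht_batch(samples: Sequence[TrajectorySample], idx: np.ndarray,
                window: WindowSpec, aug: AugmentSpec, rng: np.random.Generator):
    xs, ys = [], []
    for i in idx:
        s = samples[int(i)]
        b = add_uniform_noise(extract_window(s.baseline.ecg, window, rng), aug, rng)
        f = add_uniform_noise(extract_window(s.follow_up.ecg, window, rng), aug, rng)
        xs.append(concat_dual(b, f))
        ys.append(s.class_index)
    return np.stack(xs).astype(np.float32), np.array(ys, dtype=np.int64)


def _loss(task: str, out: np.ndarray, y: np.ndarray,
          class_weights: np.ndarray | None):
    if task == "ebt":
        return F.mse(out, y)
    return F.cross_entropy(out, y, class_weights)


def _batch_forward(net: LeadTokenNetwork, x: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = [net.forward(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(outs, axis=0)


# -------------------------------------------------------------------------
# core loop
# -------------------------------------------------------------------------

def train_network(net: LeadTokenNetwork, task: Literal["ebt", "deht"],
                  train_data: Sequence, val_data: Sequence,
                  config: TrainConfig = TrainConfig()) -> dict:
    """Optimize ``net`` in place; returns the training history.

    ``train_data``/``val_data`` are VisitPair lists (ebt) or TrajectorySample
    lists (deht); they must come from disjoint patient splits.
    """
    if len(train_data) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    aug = AugmentSpec(noise_limit=config.noise_limit, enabled=True)
    no_aug = AugmentSpec(noise_limit=0.0, enabled=False)
    make_batch = _ebt_batch if task == "ebt" else _deht_batch

    class_weights = None
    if task == "deht" and config.class_weighting:
        y = np.array([s.class_index for s in train_data])
        counts = np.bincount(y, minlength=3).astype(float)
        counts[counts == 0] = 1.0
        class_weights = y.size / (3.0 * counts)

    # fixed validation tensor (deterministic windows, no augmentation)
    val_rng = np.random.default_rng(config.seed + 1)
    n_val = min(len(val_data), config.max_val_samples)
    val_idx = val_rng.permutation(len(val_data))[:n_val]
    x_val, y_val = make_batch(val_data, val_idx, config.window, no_aug, val_rng)

    def val_loss() -> float:
        net.eval()
        out = _batch_forward(net, x_val, config.batch_size)
        loss, _ = _loss(task, out, y_val, class_weights)
        net.train(True)
        return loss

    def run(steps: int, lr: float, history: dict | None = None,
            early_stop: bool = False) -> float:
        opt = Adam(net, lr=lr)
        best, best_state, stale = np.inf, None, 0
        for step in range(1, steps + 1):
            idx = rng.integers(0, len(train_data), size=config.batch_size)
            x, y = make_batch(train_data, idx, config.window, aug, rng)
            out = net.forward(x)
            loss, dout = _loss(task, out, y, class_weights)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at step {step} (loss={loss})")
            net.zero_grad()
            net.backward(dout)
            opt.step()
            if history is not None:
                history["train_loss"].append(loss)
            if early_stop and step % config.eval_every == 0:
                v = val_loss()
                if history is not None:
                    history["val_loss"].append((step, v))
                if v < best - 1e-6:
                    best, best_state, stale = v, net.state_dict(), 0
                else:
                    stale += 1
                    if stale >= config.patience:
                        logger.info("early stop at step %d (best val %.4f)", step, best)
                        break
        if early_stop and best_state is not None:
            net.load_state_dict(best_state)
        return val_loss() if not early_stop else best

    init_state = net.state_dict()
    if config.lr is not None:
        lr, trials = config.lr, []
    else:
        draws = 10.0 ** rng.uniform(np.log10(config.lr_low), np.log10(config.lr_high),
                                    size=config.n_trials)
        trials = []
        for cand in draws:
            net.load_state_dict(init_state)
            trials.append((run(config.trial_steps, float(cand)), float(cand)))
            logger.info("lr trial %.3g -> val loss %.4f", cand, trials[-1][0])
        lr = min(trials)[1]
        net.load_state_dict(init_state)

    history = {"train_loss": [], "val_loss": [], "lr": lr,
               "lr_trials": trials, "seed": config.seed}
    best = run(config.max_steps, lr, history, early_stop=True)
    history["best_val_loss"] = best
    return history


# -------------------------------------------------------------------------
# evaluation-time prediction
# -------------------------------------------------------------------------

def predict_ebt(net: LeadTokenNetwork, visits: Sequence[VisitPair],
                window: WindowSpec = WindowSpec(), seed: int = 0,
                batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Predicted and true log-BNP for a visit list (deterministic windows,
    no augmentation)."""
    rng = np.random.default_rng(seed)
    no_aug = AugmentSpec(enabled=False)
    x, y = _ebt_batch(visits, np.arange(len(visits)), window, no_aug, rng)
    net.eval()
    pred = _batch_forward(net, x, batch_size).reshape(-1)
    return pred.astype(np.float64), y


def predict_deht(net: LeadTokenNetwork, samples: Sequence[TrajectorySample],
                 window: WindowSpec = WindowSpec(), seed: int = 0,
                 batch_size: int = 64, n_draws: int = 1
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (n*n_draws, 3) and true labels for sample list.
    ``n_draws`` > 1 re-extracts independent evaluation windows per sample."""
    rng = np.random.default_rng(seed)
    no_aug = AugmentSpec(enabled=False)
    probs, ys = [], []
    net.eval()
    for _ in range(n_draws):
        x, y = _deht_batch(samples, np.arange(len(samples)), window, no_aug, rng)
        logits = _batch_forward(net, x, batch_size)
        probs.append(F.softmax(logits))
        ys.append(y)
    return np.concatenate(probs, axis=0).astype(np.float64), np.concatenate(ys)


# -------------------------------------------------------------------------
# fitted-model API
# -------------------------------------------------------------------------

@dataclass
class EbtResults:
    network: LeadTokenNetwork
    history: dict
    model: "EbtModel"

    def predict(self, visits: Sequence[VisitPair], seed: int = 0) -> np.ndarray:
        return predict_ebt(self.network, visits,
                           self.model.train_config.window, seed)[0]

    def evaluate(self, visits: Sequence[VisitPair],
                 boot: BootstrapSpec = BootstrapSpec(), seed: int = 0) -> RegressionReport:
        pred, true = predict_ebt(self.network, visits,
                                 self.model.train_config.window, seed)
        return evaluate_regression(pred, true, boot)

    def summary(self) -> str:
        h = self.history
        return (f"EBT log-BNP regressor — {self.network.n_parameters()} parameters, "
                f"lr={h['lr']:.3g}, {len(h['train_loss'])} steps, "
                f"best val MSE {h['best_val_loss']:.4f}")


class EbtModel:
    """Single-ECG log-BNP regression model (12 lead tokens, regression head)."""

    def __init__(self, train_visits: Sequence[VisitPair],
                 val_visits: Sequence[VisitPair],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig = TrainConfig()):
        cfg = model_config or ModelConfig(n_lead_tokens=12, head="regression")
        if cfg.head != "regression" or cfg.n_lead_tokens != 12:
            raise ValueError("EBT needs a regression head over 12 lead tokens")
        self.model_config, self.train_config = cfg, train_config
        self.train_visits, self.val_visits = list(train_visits), list(val_visits)

    def fit(self) -> EbtResults:
        net = build_model(self.model_config)
        history = train_network(net, "ebt", self.train_visits, self.val_visits,
                                self.train_config)
        return EbtResults(network=net, history=history, model=self)


@dataclass
class DehtResults:
    network: LeadTokenNetwork
    history: dict
    model: "DehtModel"

    def predict_proba(self, samples: Sequence[TrajectorySample], seed: int = 0,
                      n_draws: int = 1) -> np.ndarray:
        return predict_deht(self.network, samples,
                            self.model.train_config.window, seed,
                            n_draws=n_draws)[0]

    def evaluate(self, samples: Sequence[TrajectorySample],
                 boot: BootstrapSpec = BootstrapSpec(), seed: int = 0,
                 one_per_patient: bool = True, n_draws: int = 1) -> MetricsReport:
        if one_per_patient:
            samples = sample_one_per_patient(list(samples), seed)
        probs, y = predict_deht(self.network, samples,
                                self.model.train_config.window, seed,
                                n_draws=n_draws)
        return classification_report(y, probs, boot)

    def summary(self) -> str:
        h = self.history
        return (f"DEHT trajectory classifier — {self.network.n_parameters()} parameters, "
                f"lr={h['lr']:.3g}, {len(h['train_loss'])} steps, "
                f"best val CE {h['best_val_loss']:.4f}")


class DehtModel:
    """Dual-ECG three-class HF trajectory model (24 lead tokens, softmax head)."""

    def __init__(self, train_samples: Sequence[TrajectorySample],
                 val_samples: Sequence[TrajectorySample],
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig = TrainConfig()):
        cfg = model_config or ModelConfig(n_lead_tokens=24, head="classification_3")
        if cfg.head != "classification_3" or cfg.n_lead_tokens != 24:
            raise ValueError("DEHT needs the 3-class head over 24 lead tokens")
        self.model_config, self.train_config = cfg, train_config
        self.train_samples, self.val_samples = list(train_samples), list(val_samples)

    def fit(self, network: LeadTokenNetwork | None = None) -> DehtResults:
        net = network if network is not None else build_model(self.model_config)
        history = train_network(net, "deht", self.train_samples, self.val_samples,
                                self.train_config)
        return DehtResults(network=net, history=history, model=self)
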