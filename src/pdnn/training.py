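"""Training loops and the excitability sweep.

One training iteration is one Adam step on one mini-batch of training
stimuli under cross-entropy loss over the 19 possible results. The
held-out test split is evaluated at iteration 0 and then at a fixed
cadence (``eval_every``); learning curves, per-item responses and
optional on-disk checkpoints are recorded at each evaluation point.
Independent networks are trained at every gain on the excitability grid
with an identical dataset and seed policy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .network import ArchConfig, GainNetwork
from .stimuli import StimulusDataset, StimulusSplit


@dataclass
class TrainConfig:
    batch_size: int = 100
    learning_rate: float = 0.001
    eval_every: int = 100
    max_iterations: int = 3800
    seed: int = 0
    eval_batch: int = 200  # forward-pass chunking only; no effect on results
    eval_subsample: int | None = None  # evaluate on this many test items (None = all)
    keep_responses: bool = True
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.eval_every < 1:
            raise ValueError("eval_every must be >= 1")


@dataclass
class LearningCurve:
    gain: float
    iterations: np.ndarray  # evaluated iterations, starting at 0
    accuracy: np.ndarray  # test accuracy per evaluation, in [0, 1]
    responses: list = field(default_factory=list)  # per-eval response vectors
    eval_indices: np.ndarray | None = None  # test items used for evaluation
    checkpoints: dict = field(default_factory=dict)  # iteration -> path


@dataclass
class SweepResult:
    gains: np.ndarray
    curves: list  # one LearningCurve per gain, same evaluation grid
    arch: ArchConfig
    train_config: TrainConfig

    def accuracy_table(self) -> np.ndarray:
        """(n_gains, n_evals) accuracy matrix."""
        return np.stack([c.accuracy for c in self.curves])

    @property
    def iterations(self) -> np.ndarray:
        return self.curves[0].iterations


class Adam:
    """Adaptive-moment gradient descent (decoupled per-parameter moments)."""

    def __init__(self, params: dict, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] += (1 - b1) * (p.grad - self.m[k])
            self.v[k] += (1 - b2) * (p.grad ** 2 - self.v[k])
            p.data -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def evaluate(net: GainNetwork, split: StimulusSplit, indices=None, eval_batch=200):
    """Test accuracy and argmax responses on labelled stimuli.

    Returns (accuracy, responses); ``indices`` restricts evaluation to a
    subset of the split (order-independent).
    """
    if len(split) == 0:
        raise ValueError("empty stimulus set")
    if indices is None:
        indices = np.arange(len(split))
    responses = np.empty(len(indices), dtype=np.int64)
    for lo in range(0, len(indices), eval_batch):
        sel = indices[lo : lo + eval_batch]
        responses[lo : lo + len(sel)] = net.responses(split.batch(sel))
    accuracy = float(np.mean(responses == split.result[indices]))
    return accuracy, responses


def train_model(net: GainNetwork, dataset: StimulusDataset, cfg: TrainConfig) -> LearningCurve:
    """Train one network, evaluating on the test split at a fixed cadence."""
    train = dataset.train
    if len(train) == 0:
        raise ValueError("empty training split")
    rng = np.random.default_rng([cfg.seed, 17])
    if cfg.eval_subsample is not None and cfg.eval_subsample < len(dataset.test):
        # stratified by problem: round-robin over the canonical problem order
        order = np.argsort(dataset.test.problem_index, kind="stable")
        eval_idx = np.sort(order[:: max(1, len(order) // cfg.eval_subsample)][: cfg.eval_subsample])
    else:
        eval_idx = np.arange(len(dataset.test))

    opt = Adam(net.params, lr=cfg.learning_rate)
    iters, accs, resps = [], [], []
    curve = LearningCurve(net.gain, None, None, resps, eval_idx)

    def run_eval(it):
        acc, r = evaluate(net, dataset.test, eval_idx, cfg.eval_batch)
        iters.append(it)
        accs.append(acc)
        if cfg.keep_responses:
            resps.append(r)
        if cfg.checkpoint_dir is not None:
            os.makedirs(cfg.checkpoint_dir, exist_ok=True)
            path = os.path.join(cfg.checkpoint_dir, f"checkpoint_{it}.npz")
            net.iteration = it
            net.save(path)
            curve.checkpoints[it] = path

    run_eval(0)
    perm = rng.permutation(len(train))
    cursor = 0
    for it in range(1, cfg.max_iterations + 1):
        if cursor + cfg.batch_size > len(perm):
            perm = rng.permutation(len(train))
            cursor = 0
        sel = perm[cursor : cursor + cfg.batch_size]
        cursor += cfg.batch_size
        opt.zero_grad()
        logits, _ = net.forward(train.batch(sel), training=True)
        loss = ad.cross_entropy(logits, train.result[sel].astype(np.int64))
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at iteration {it} (gain {net.gain})"
            )
        ad.backward(loss)
        opt.step()
        if it % cfg.eval_every == 0:
            run_eval(it)
    net.iteration = cfg.max_iterations
    curve.iterations = np.asarray(iters)
    curve.accuracy = np.asarray(accs)
    return curve


NOT_REACHED = -1


def iterations_to_threshold(curve: LearningCurve, threshold: float) -> int:
    """Smallest evaluated iteration with accuracy >= threshold, else NOT_REACHED."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hits = np.nonzero(curve.accuracy >= threshold)[0]
    return int(curve.iterations[hits[0]]) if len(hits) else NOT_REACHED


def sweep_gains(dataset: StimulusDataset, gains, arch: ArchConfig, cfg: TrainConfig,
                progress=None) -> SweepResult:
    """Independent training run per gain on the identical dataset and seeds."""
    gains = np.asarray(list(gains), dtype=float)
    if len(gains) == 0:
        raise ValueError("empty gain grid")
    curves = []
    for g in gains:
        run_cfg = cfg
        if cfg.checkpoint_dir is not None:
            run_cfg = TrainConfig(**{**cfg.__dict__,
                                     "checkpoint_dir": os.path.join(cfg.checkpoint_dir, f"gain_{g:g}")})
        net = GainNetwork(arch, g, seed=cfg.seed)
        try:
            curves.append(train_model(net, dataset, run_cfg))
        except Exception as exc:
            raise RuntimeError(f"training failed at gain {g:g}") from exc
        if progress is not None:
            progress(g, curves[-1])
    return SweepResult(gains, curves, arch, cfg)


def summary_table(sweep: SweepResult):
    """Long-form (gain, iteration, accuracy) records."""
    rows = []
    for g, c in zip(sweep.gains, sweep.curves):
        for it, acc in zip(c.iterations, c.accuracy):
            rows.append({"gain": float(g), "iteration": int(it), "accuracy": float(acc)})
    return rows
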