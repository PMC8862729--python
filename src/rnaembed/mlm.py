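"""Masked language modelling: mask policy, dataset expansion, loss, training.

The corruption policy selects 15% of the bases of a sequence (at least
one); of the selected positions 80% become the MASK token, 10% are
substituted with one of the *other three* bases and 10% are left
unchanged. The pre-training set takes a fixed number of copies of every
sequence (default 10), each with an independent mask pattern, and the
cross-entropy loss is computed only over the selected positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax

from .autodiff import Tensor
from .model import MASK_ID, ModelConfig, mlm_logits, tokenize, transformer_forward
from .seqio import RnaSequence

__all__ = ["MaskPolicy", "MaskedInstance", "apply_mask", "build_pretraining_set", "mlm_loss", "train_mlm_epoch"]


@dataclass(frozen=True)
class MaskPolicy:
    select_rate: float = 0.15
    mask_action: float = 0.8
    random_action: float = 0.1
    keep_action: float = 0.1

    def __post_init__(self):
        if not 0 < self.select_rate <= 1:
            raise ValueError("select_rate must be in (0, 1]")
        if abs(self.mask_action + self.random_action + self.keep_action - 1.0) > 1e-12:
            raise ValueError("action probabilities must sum to 1")


@dataclass
class MaskedInstance:
    input_tokens: np.ndarray
    target_tokens: np.ndarray
    selected: frozenset = field(default=frozenset())  # 1-based positions


def _n_selected(rate: float, n: int) -> int:
    return max(1, int(np.floor(rate * n + 0.5)))  # round half up


def apply_mask(seq: RnaSequence | np.ndarray, policy: MaskPolicy, rng: np.random.Generator) -> MaskedInstance:
    """Corrupt one sequence according to the mask policy."""
    targets = seq if isinstance(seq, np.ndarray) else tokenize(seq)
    n = len(targets)
    if n == 0:
        raise ValueError("cannot mask an empty sequence")
    k = _n_selected(policy.select_rate, n)
    selected = rng.choice(n, size=k, replace=False)
    inputs = targets.copy()
    actions = rng.random(k)
    for pos, u in zip(selected, actions):
        if u < policy.mask_action:
            inputs[pos] = MASK_ID
        elif u < policy.mask_action + policy.random_action:
            others = [b for b in range(4) if b != targets[pos]]
            inputs[pos] = others[rng.integers(3)]
        # else: keep unchanged
    return MaskedInstance(
        input_tokens=inputs,
        target_tokens=targets.copy(),
        selected=frozenset(int(p) + 1 for p in selected),
    )


def iter_pretraining_instances(seqs, copies: int, rng: np.random.Generator, policy: MaskPolicy = MaskPolicy()):
    """Yield ``copies`` independently masked instances per sequence."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    for seq in seqs:
        tokens = tokenize(seq) if isinstance(seq, RnaSequence) else np.asarray(seq)
        for _ in range(copies):
            yield apply_mask(tokens, policy, rng)


def build_pretraining_set(seqs, copies: int = 10, rng: np.random.Generator | None = None, policy: MaskPolicy = MaskPolicy()) -> list[MaskedInstance]:
    """The MLM pre-training set: ``copies`` mask patterns of every sequence."""
    rng = rng if rng is not None else np.random.default_rng()
    return list(iter_pretraining_instances(seqs, copies, rng, policy))


def mlm_loss(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean softmax cross-entropy of the selected positions (numpy path)."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    targets = np.atleast_1d(np.asarray(targets))
    if len(logits) == 0 or len(targets) == 0:
        raise ValueError("empty selection")
    if len(logits) != len(targets):
        raise ValueError("logits and targets misaligned")
    lp = log_softmax(logits, axis=-1)
    return float(-lp[np.arange(len(targets)), targets].mean())


def _instance_loss(inst: MaskedInstance, params: dict, config: ModelConfig) -> Tensor:
    """Differentiable cross-entropy over the instance's selected positions."""
    z, _ = transformer_forward(inst.input_tokens, params, config)
    logits = mlm_logits(z, params)
    sel = np.array(sorted(inst.selected)) - 1
    logp = logits.softmax(axis=-1).log()
    onehot = np.zeros((len(inst.input_tokens), 4))
    onehot[sel, inst.target_tokens[sel]] = 1.0
    return -(logp * Tensor(onehot)).sum() * (1.0 / len(sel))


def train_mlm_epoch(instances, params: dict, config: ModelConfig, optimizer, batch_size: int = 8) -> float:
    """One pass over the instances; returns the mean training loss."""
    losses = []
    batch: list[MaskedInstance] = []

    def flush():
        if not batch:
            return
        optimizer.zero_grad()
        total = None
        for inst in batch:
            term = _instance_loss(inst, params, config)
            total = term if total is None else total + term
        total = total * (1.0 / len(batch))
        total.backward()
        optimizer.step()
        losses.append(total.item())
        batch.clear()

    for inst in instances:
        batch.append(inst)
        if len(batch) == batch_size:
            flush()
    flush()
    if not losses:
        raise ValueError("empty instance set")
    return float(np.mean(losses))
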