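"""Structural alignment learning (SAL): a structured max-margin task.

For a reference-aligned pair of sequences the encoder's embeddings define
the cosine score matrix Omega. The task minimises the structured hinge

    f(x, x', yhat) + Delta(y, yhat) - f(x, x', y) + lambda * ||w||^2

where y is the reference alignment, yhat the loss-augmented prediction
(the alignment maximising score plus margin, found exactly by the same
affine-gap DP on shifted match scores), and Delta penalises every
reference matched pair missing from the prediction by deltaFN and every
spurious predicted pair by deltaFP. Because the decoder is exact and y is
a feasible candidate, the hinge is never negative. Gradients flow through
Omega into the encoder; the decoded yhat is held fixed within a step
(standard structured-SVM subgradient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import GapParams, alignment_score, nw_affine
from .autodiff import Tensor
from .model import ModelConfig, parameter_squared_norm, tokenize, transformer_forward
from .seqio import PairwiseAlignment, RnaSequence

__all__ = [
    "MarginParams",
    "TrainConfig",
    "SalLossReport",
    "omega",
    "omega_tensor",
    "margin_delta",
    "loss_augmented_decode",
    "sal_loss",
    "train_sal_epoch",
]


@dataclass(frozen=True)
class MarginParams:
    """Margin weights: deltaFN per missed reference pair, deltaFP per
    spurious predicted pair (grid-searched defaults 0.05 / 0.1)."""

    delta_fn: float = 0.05
    delta_fp: float = 0.1

    def __post_init__(self):
        if self.delta_fn < 0 or self.delta_fp < 0:
            raise ValueError("margin penalties must be non-negative")


@dataclass
class TrainConfig:
    lambda_reg: float = 1e-4
    pairs_per_family: int = 8
    schedule: str = "per-epoch"
    seed: int = 0

    def __post_init__(self):
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be non-negative")


@dataclass
class SalLossReport:
    f_ref: float
    f_hat: float
    delta: float
    hinge: float
    reg: float
    total: float


def omega(z: np.ndarray, zp: np.ndarray) -> np.ndarray:
    """Cosine-similarity score matrix between two embeddings (numpy)."""
    z, zp = np.asarray(z, dtype=float), np.asarray(zp, dtype=float)
    na = np.linalg.norm(z, axis=1)
    nb = np.linalg.norm(zp, axis=1)
    for name, norms in (("first", na), ("second", nb)):
        zero = np.where(norms == 0)[0]
        if zero.size:
            raise ValueError(f"zero-norm embedding row {zero[0] + 1} in {name} input")
    return (z @ zp.T) / np.outer(na, nb)


def omega_tensor(z: Tensor, zp: Tensor) -> Tensor:
    """Differentiable cosine matrix for the training path."""
    eps = 1e-12
    na = ((z * z).sum(axis=1, keepdims=True) + eps) ** 0.5
    nb = ((zp * zp).sum(axis=1, keepdims=True) + eps) ** 0.5
    return (z @ zp.T) / (na @ nb.T)


def margin_delta(y: PairwiseAlignment, yhat: PairwiseAlignment, params: MarginParams = MarginParams()) -> float:
    """Delta(y, yhat) counted over matched position pairs only."""
    if (y.n, y.m) != (yhat.n, yhat.m):
        raise ValueError("alignments cover different sequence pairs")
    ref, pred = y.matched_pairs(), yhat.matched_pairs()
    fn = len(ref - pred)
    fp = len(pred - ref)
    return params.delta_fn * fn + params.delta_fp * fp


def loss_augmented_decode(
    om: np.ndarray,
    gaps: GapParams,
    y: PairwiseAlignment,
    params: MarginParams = MarginParams(),
):
    """The alignment maximising f + Delta, via the exact affine-gap DP.

    Delta decomposes over matched pairs, so shifting every match score by
    +deltaFP off the reference and -deltaFN on it (plus the constant
    deltaFN * |matched(y)|) turns loss-augmented decoding into a plain
    alignment problem.
    """
    om = np.asarray(om, dtype=float)
    n, m = om.shape
    if (y.n, y.m) != (n, m):
        raise ValueError("reference alignment does not fit the score matrix")
    shifted = om + params.delta_fp
    for i, j in y.matched_pairs():
        shifted[i - 1, j - 1] = om[i - 1, j - 1] - params.delta_fn
    return nw_affine(shifted, gaps).alignment


def sal_loss(
    x: RnaSequence,
    xp: RnaSequence,
    y: PairwiseAlignment,
    params_model: dict,
    config: ModelConfig,
    margin: MarginParams = MarginParams(),
    gaps: GapParams = GapParams(),
    train: TrainConfig = TrainConfig(),
) -> SalLossReport:
    """Per-instance structured hinge plus regulariser (diagnostic path)."""
    za, _ = transformer_forward(tokenize(x, config), params_model, config)
    zb, _ = transformer_forward(tokenize(xp, config), params_model, config)
    om = omega(za.data, zb.data)
    yhat = loss_augmented_decode(om, gaps, y, margin)
    f_ref = alignment_score(om, gaps, y)
    f_hat = alignment_score(om, gaps, yhat)
    delta = margin_delta(y, yhat, margin)
    hinge = f_hat + delta - f_ref
    reg = train.lambda_reg * parameter_squared_norm(params_model).item()
    return SalLossReport(
        f_ref=f_ref, f_hat=f_hat, delta=delta, hinge=float(hinge), reg=reg,
        total=float(hinge) + reg,
    )


def _hinge_tensor(
    x: RnaSequence,
    xp: RnaSequence,
    y: PairwiseAlignment,
    params_model: dict,
    config: ModelConfig,
    margin: MarginParams,
    gaps: GapParams,
) -> tuple[Tensor, float]:
    """Differentiable hinge for one pair; returns (tensor, hinge value).

    The hinge is linear in Omega given a fixed decode: its gradient is
    +1 on yhat's matched pairs and -1 on y's.
    """
    za, _ = transformer_forward(tokenize(x, config), params_model, config)
    zb, _ = transformer_forward(tokenize(xp, config), params_model, config)
    om_t = omega_tensor(za, zb)
    yhat = loss_augmented_decode(om_t.data, gaps, y, margin)
    coeff = np.zeros(om_t.shape)
    for i, j in yhat.matched_pairs():
        coeff[i - 1, j - 1] += 1.0
    for i, j in y.matched_pairs():
        coeff[i - 1, j - 1] -= 1.0
    const = (
        margin_delta(y, yhat, margin)
        + _gap_total(yhat, gaps)
        - _gap_total(y, gaps)
    )
    hinge_t = (om_t * Tensor(coeff)).sum() + const
    return hinge_t, float(hinge_t.item())


def _gap_total(y: PairwiseAlignment, gaps: GapParams) -> float:
    total, run = 0.0, 0
    for i, j in y.columns:
        if i is not None and j is not None:
            run = 0
        elif j is None:
            total += gaps.extend if run == 1 else gaps.open
            run = 1
        else:
            total += gaps.extend if run == 2 else gaps.open
            run = 2
    return total


def train_sal_epoch(
    pairs,
    params_model: dict,
    config: ModelConfig,
    optimizer,
    margin: MarginParams = MarginParams(),
    gaps: GapParams = GapParams(),
    train: TrainConfig = TrainConfig(),
    batch_size: int = 4,
) -> float:
    """One pass over (x, x', y) triplets; returns the mean hinge.

    The regulariser is added once per batch so lambda keeps its meaning
    regardless of batch size.
    """
    hinges = []
    batch = list(pairs)
    if not batch:
        raise ValueError("empty SAL training set")
    for lo in range(0, len(batch), batch_size):
        chunk = batch[lo : lo + batch_size]
        optimizer.zero_grad()
        total = None
        for x, xp, y in chunk:
            t, h = _hinge_tensor(x, xp, y, params_model, config, margin, gaps)
            hinges.append(h)
            term = t * (1.0 / len(chunk))
            total = term if total is None else total + term
        if train.lambda_reg > 0:
            total = total + train.lambda_reg * parameter_squared_norm(params_model)
        total.backward()
        optimizer.step()
    return float(np.mean(hinges))
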