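"""Transformer encoder mapping an RNA sequence to per-base embeddings.

The encoder sums a learned token embedding and a learned position
embedding, then applies a stack of transformer layers (multi-head
self-attention followed by a position-wise feed-forward network, each
wrapped in a post-norm residual block). The final layer output Z — one
D-dimensional vector per base — is the informative base embedding used by
alignment, clustering and motif detection. Attention softmax rows from any
layer can be summed into a per-position attention map.

Per-head query/key/value projections are full D x D matrices and the
attention logits are scaled by sqrt(D); a conventional D/H head split is
available as a config switch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, gather_rows
from .seqio import RnaSequence

__all__ = [
    "VOCAB",
    "MASK_ID",
    "PAD_ID",
    "ModelConfig",
    "init_params",
    "tokenize",
    "detokenize",
    "transformer_forward",
    "mlm_logits",
    "attention_map",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_squared_norm",
]

VOCAB = {"A": 0, "C": 1, "G": 2, "U": 3, "MASK": 4, "PAD": 5}
BASES = "ACGU"
MASK_ID = VOCAB["MASK"]
PAD_ID = VOCAB["PAD"]


@dataclass
class ModelConfig:
    D: int = 120
    n_layers: int = 6
    H: int = 12
    ffn_dim: int = 480
    max_len: int = 440
    activation: str = "gelu"
    dropout: float = 0.0
    head_split: bool = False  # True: conventional D/H per-head width
    use_residual: bool = True
    use_layernorm: bool = True

    def __post_init__(self):
        if min(self.D, self.n_layers, self.H, self.max_len) < 1:
            raise ValueError("D, n_layers, H and max_len must be positive")
        if self.head_split and self.D % self.H:
            raise ValueError("head_split requires H to divide D")

    @property
    def head_dim(self) -> int:
        return self.D // self.H if self.head_split else self.D


def tokenize(seq: RnaSequence | str, config: ModelConfig | None = None) -> np.ndarray:
    """Map residues to token ids A=0, C=1, G=2, U=3."""
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    if config is not None and len(residues) > config.max_len:
        raise ValueError(
            f"sequence length {len(residues)} exceeds max_len {config.max_len}"
        )
    return np.array([VOCAB[c] for c in residues], dtype=np.intp)


def detokenize(tokens) -> str:
    rev = {v: k for k, v in VOCAB.items()}
    return "".join(rev[int(t)] for t in tokens)


def init_params(config: ModelConfig, rng: np.random.Generator, scale: float = 0.02) -> dict:
    """Randomly initialised trainable weights, keyed by name."""

    def t(*shape):
        return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    D, dh = config.D, config.head_dim
    params: dict[str, Tensor] = {
        "tok": t(len(VOCAB), D),
        "pos": t(config.max_len, D),
    }
    for layer in range(config.n_layers):
        p = f"l{layer}."
        for h in range(config.H):
            params[p + f"Wq{h}"] = t(D, dh)
            params[p + f"Wk{h}"] = t(D, dh)
            params[p + f"Wv{h}"] = t(D, dh)
        params[p + "Wo"] = t(config.H * dh, D)
        params[p + "bo"] = Tensor(np.zeros(D), requires_grad=True)
        params[p + "W1"] = t(D, config.ffn_dim)
        params[p + "b1"] = Tensor(np.zeros(config.ffn_dim), requires_grad=True)
        params[p + "W2"] = t(config.ffn_dim, D)
        params[p + "b2"] = Tensor(np.zeros(D), requires_grad=True)
        if config.use_layernorm:
            for ln in ("ln1", "ln2"):
                params[p + ln + "g"] = Tensor(np.ones(D), requires_grad=True)
                params[p + ln + "b"] = Tensor(np.zeros(D), requires_grad=True)
    params["mlm_W"] = t(D, 4)
    params["mlm_b"] = Tensor(np.zeros(4), requires_grad=True)
    return params


def _check_shapes(params: dict, config: ModelConfig) -> None:
    D = config.D
    if params["tok"].shape != (len(VOCAB), D):
        raise ValueError("token table shape inconsistent with config")
    if params["pos"].shape[1] != D or params["pos"].shape[0] < 1:
        raise ValueError("position table shape inconsistent with config")
    key = f"l{config.n_layers - 1}.Wo"
    if key not in params:
        raise ValueError("parameter set has fewer layers than config")


def _activation(x: Tensor, name: str) -> Tensor:
    if name == "gelu":
        return x.gelu()
    if name == "relu":
        return x.relu()
    if name == "tanh":
        return x.tanh()
    raise ValueError(f"unknown activation {name!r}")


def transformer_forward(
    tokens: np.ndarray,
    params: dict,
    config: ModelConfig,
    collect_attention: bool = False,
):
    """Run the encoder on one token sequence.

    Returns ``(Z, attentions)`` where Z is an (n, D) Tensor and
    ``attentions[layer][head]`` is the (n, n) softmax matrix (numpy) when
    ``collect_attention`` is set, else an empty list. PAD keys are masked
    out of every softmax.
    """
    tokens = np.asarray(tokens, dtype=np.intp)
    n = len(tokens)
    if n > config.max_len:
        raise ValueError(f"sequence length {n} exceeds max_len {config.max_len}")
    _check_shapes(params, config)
    key_mask = tokens != PAD_ID
    mask = np.broadcast_to(key_mask, (n, n)) if not key_mask.all() else None

    x = gather_rows(params["tok"], tokens) + gather_rows(params["pos"], np.arange(n))
    scale = 1.0 / np.sqrt(config.D)  # sqrt(D) scaling, not sqrt(D/H)
    attentions: list[list[np.ndarray]] = []
    for layer in range(config.n_layers):
        p = f"l{layer}."
        heads = []
        layer_attn = []
        for h in range(config.H):
            q = x @ params[p + f"Wq{h}"]
            k = x @ params[p + f"Wk{h}"]
            v = x @ params[p + f"Wv{h}"]
            attn = ((q @ k.T) * scale).softmax(axis=-1, mask=mask)
            if collect_attention:
                layer_attn.append(attn.data.copy())
            heads.append(attn @ v)
        c = concat(heads, axis=-1) @ params[p + "Wo"] + params[p + "bo"]
        if config.use_residual:
            c = x + c
        if config.use_layernorm:
            c = c.layer_norm(params[p + "ln1g"], params[p + "ln1b"])
        f = _activation(c @ params[p + "W1"] + params[p + "b1"], config.activation)
        f = f @ params[p + "W2"] + params[p + "b2"]
        if config.use_residual:
            f = c + f
        if config.use_layernorm:
            f = f.layer_norm(params[p + "ln2g"], params[p + "ln2b"])
        x = f
        if collect_attention:
            attentions.append(layer_attn)
    return x, attentions


def embed(seq: RnaSequence, params: dict, config: ModelConfig) -> np.ndarray:
    """Convenience: the (n, D) informative base embedding Z as numpy."""
    z, _ = transformer_forward(tokenize(seq, config), params, config)
    return z.data


def mlm_logits(z: Tensor, params: dict) -> Tensor:
    """Classification head over the four bases, applied to embeddings."""
    return z @ params["mlm_W"] + params["mlm_b"]


def attention_map(
    tokens: np.ndarray,
    params: dict,
    config: ModelConfig,
    layer: int | None = None,
) -> np.ndarray:
    """Per-position attention mass M summed over heads and query positions.

    ``layer`` is 1-based; the default is the final layer. Each softmax row
    sums to one, so sum(M) = n * H.
    """
    if layer is None:
        layer = config.n_layers
    if not 1 <= layer <= config.n_layers:
        raise ValueError(f"layer must be in 1..{config.n_layers}")
    _, attentions = transformer_forward(tokens, params, config, collect_attention=True)
    mats = attentions[layer - 1]
    m = np.zeros(len(tokens))
    for a in mats:
        m += a.sum(axis=0)  # attention received by each key position
    return m


def parameter_squared_norm(params: dict) -> Tensor:
    """Squared L2 norm over all trainable parameters (regulariser)."""
    total = None
    for p in params.values():
        term = (p * p).sum()
        total = term if total is None else total + term
    return total


def make_optimizer(params: dict, lr: float = 1e-3) -> Adam:
    return Adam(params, lr=lr)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz archive holding a JSON config entry plus weights.


def save_checkpoint(path, params: dict, config: ModelConfig) -> None:
    arrays = {f"w::{k}": p.data for k, p in params.items()}
    arrays["config"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, ModelConfig]:
    with np.load(path) as npz:
        config = ModelConfig(**json.loads(bytes(npz["config"]).decode()))
        params = {
            k[3:]: Tensor(npz[k], requires_grad=True)
            for k in npz.files
            if k.startswith("w::")
        }
    _check_shapes(params, config)
    return params, config
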