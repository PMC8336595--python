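"""Attention-based circRNA classifier over splice-junction flanking windows.

Architecture, per record:

1. every acceptor/donor window of L k-mer ids is embedded and encoded by a
   side-specific bidirectional GRU; a learned attention over the L positions
   pools the hidden states into one embedding per site (``alpha`` weights);
2. single-head dot-product cross-attention lets each acceptor attend over
   all donors and vice versa (``beta`` weights), producing interaction-aware
   site embeddings;
3. a second attention pools each side's site embeddings into one acceptor
   and one donor representation (``gamma`` weights);
4. a two-layer head with ReLU and sigmoid maps their concatenation to a
   probability.

All softmaxes are mask-aware so variable exon counts can be padded freely:
perturbing a padded site's input never changes the output. The ``gamma`` and
``beta`` weights of the donor side double as a joint distribution over
(donor, acceptor) pairs, used for zero-shot backsplice discovery.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import asdict, dataclass, field

import numpy as np

from .autograd import Tensor, concat, embedding, masked_softmax
from .features import JunctionBatch

__all__ = [
    "ModelConfig",
    "ModelParams",
    "AttentionMaps",
    "init_params",
    "encode_junctions",
    "cross_attention",
    "site_attention",
    "forward",
    "loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; defaults follow the published configuration."""

    K: int = 3          # k-mer size
    l: int = 128        # k-mer embedding dimension
    L: int = 4          # flanking-window length
    h: int = 128        # GRU hidden size per direction
    a_dim: int = 16     # attention-vector size
    f_dim: int = 128    # pre-output hidden units
    lambda_l2: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("K", "l", "L", "h", "a_dim", "f_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.lambda_l2 < 0:
            raise ValueError("lambda_l2 must be >= 0")

    @property
    def vocab_size(self) -> int:
        return 4 ** self.K + 1


class ModelParams:
    """Named parameter arrays; iterable in a stable order."""

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def names(self) -> list[str]:
        return sorted(self.arrays)

    def copy(self) -> "ModelParams":
        return ModelParams({k: v.copy() for k, v in self.arrays.items()})

    def as_tensors(self) -> dict[str, Tensor]:
        return {k: Tensor(v, requires_grad=True) for k, v in self.arrays.items()}

    def l2_norm_sq(self) -> float:
        return float(sum((v ** 2).sum() for v in self.arrays.values()))


@dataclass
class AttentionMaps:
    """Per-record attention weights, unmasked entries only.

    ``alpha_*``: [m, L] k-mer weights per site; ``beta_a``: [m, m] acceptor->
    donor cross weights; ``beta_d``: [m, m] donor->acceptor; ``gamma_*``: [m]
    site weights. Every row sums to 1.
    """

    alpha_a: np.ndarray
    alpha_d: np.ndarray
    beta_a: np.ndarray
    beta_d: np.ndarray
    gamma_a: np.ndarray
    gamma_d: np.ndarray

    def to_json_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}


def _uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(cfg: ModelConfig, seed: int | None = None) -> ModelParams:
    """Fan-based uniform initialization, fully determined by the seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    p: dict[str, np.ndarray] = {}
    p["E"] = rng.normal(0.0, 0.1, size=(cfg.vocab_size, cfg.l))
    for side in ("a", "d"):
        for direction in ("fwd", "bwd"):
            pre = f"gru_{side}_{direction}"
            for gate in ("z", "r", "n"):
                p[f"{pre}_W{gate}"] = _uniform(rng, cfg.l, (cfg.l, cfg.h))
                p[f"{pre}_U{gate}"] = _uniform(rng, cfg.h, (cfg.h, cfg.h))
                p[f"{pre}_b{gate}"] = np.zeros(cfg.h)
        # k-mer attention: projection F_t and attention vector t_s
        p[f"Ft_{side}_W"] = _uniform(rng, 2 * cfg.h, (2 * cfg.h, cfg.a_dim))
        p[f"Ft_{side}_b"] = np.zeros(cfg.a_dim)
        p[f"ts_{side}"] = _uniform(rng, cfg.a_dim, (cfg.a_dim,))
        # site attention: projection F_c and attention vector c_s
        p[f"Fc_{side}_W"] = _uniform(rng, 2 * cfg.h, (2 * cfg.h, cfg.a_dim))
        p[f"Fc_{side}_b"] = np.zeros(cfg.a_dim)
        p[f"cs_{side}"] = _uniform(rng, cfg.a_dim, (cfg.a_dim,))
    p["Fr_W"] = _uniform(rng, 4 * cfg.h, (4 * cfg.h, cfg.f_dim))
    p["Fr_b"] = np.zeros(cfg.f_dim)
    p["Fp_W"] = _uniform(rng, cfg.f_dim, (cfg.f_dim, 1))
    p["Fp_b"] = np.zeros(1)
    return ModelParams(p)


def _gru_pass(x_steps: list[Tensor], t: dict[str, Tensor], prefix: str, h_size: int) -> list[Tensor]:
    """Run one GRU direction over a list of [N, l] inputs; returns [N, h] states.

    Standard cell: z = sigma(xWz + hUz + bz), r = sigma(xWr + hUr + br),
    n = tanh(xWn + (r*h)Un + bn), h' = (1 - z)*n + z*h, with h_0 = 0.
    """
    n_rows = x_steps[0].shape[0]
    h = Tensor(np.zeros((n_rows, h_size)))
    out = []
    Wz, Uz, bz = t[f"{prefix}_Wz"], t[f"{prefix}_Uz"], t[f"{prefix}_bz"]
    Wr, Ur, br = t[f"{prefix}_Wr"], t[f"{prefix}_Ur"], t[f"{prefix}_br"]
    Wn, Un, bn = t[f"{prefix}_Wn"], t[f"{prefix}_Un"], t[f"{prefix}_bn"]
    for x in x_steps:
        z = (x @ Wz + h @ Uz + bz).sigmoid()
        r = (x @ Wr + h @ Ur + br).sigmoid()
        n = (x @ Wn + (r * h) @ Un + bn).tanh()
        h = (1.0 - z) * n + z * h
        out.append(h)
    return out


def _encode_side(ids: np.ndarray, side: str, t: dict[str, Tensor], cfg: ModelConfig) -> tuple[Tensor, Tensor]:
    """Encode [N, L] windows into site embeddings [N, 2h] and alpha [N, L]."""
    n_rows, L = ids.shape
    x = embedding(t["E"], ids)  # [N, L, l]
    x_steps = [x[:, j, :].reshape(n_rows, cfg.l) for j in range(L)]
    h_fwd = _gru_pass(x_steps, t, f"gru_{side}_fwd", cfg.h)
    h_bwd = _gru_pass(list(reversed(x_steps)), t, f"gru_{side}_bwd", cfg.h)
    h_bwd = list(reversed(h_bwd))
    # H: [N, L, 2h]
    steps = [concat([f, b], axis=-1).reshape(n_rows, 1, 2 * cfg.h) for f, b in zip(h_fwd, h_bwd)]
    H = concat(steps, axis=1)
    proj = (H @ t[f"Ft_{side}_W"] + t[f"Ft_{side}_b"]).tanh()          # [N, L, a]
    scores = (proj * t[f"ts_{side}"]).sum(axis=-1)                      # [N, L]
    alpha = masked_softmax(scores, axis=-1)
    w = (alpha.reshape(n_rows, L, 1) * H).sum(axis=1)                   # [N, 2h]
    return w, alpha


def _cross(W_a: Tensor, W_d: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Batched cross-attention.

    W_a, W_d: [B, M, 2h]; mask: [B, M]. beta_a[b,i,j] attends acceptor i over
    donors j; beta_d[b,j,i] attends donor j over acceptors i.
    """
    S = W_a @ _swap(W_d)                                   # [B, M_a, M_d]
    key_mask_d = mask[:, None, :]                          # donors as keys
    key_mask_a = mask[:, None, :]
    beta_a = masked_softmax(S, mask=key_mask_d, axis=-1)   # [B, M_a, M_d]
    beta_d = masked_softmax(_swap(S), mask=key_mask_a, axis=-1)  # [B, M_d, M_a]
    V_a = beta_a @ W_d
    V_d = beta_d @ W_a
    return V_a, V_d, beta_a, beta_d


def _swap(t: Tensor) -> Tensor:
    """Transpose the last two axes with gradient support."""
    orig = t.data.shape

    def backward(g):
        t._accum(np.swapaxes(g, -1, -2))

    return t._make(np.swapaxes(t.data, -1, -2), (t,), backward)


def _site_pool(V: Tensor, side: str, t: dict[str, Tensor], mask: np.ndarray) -> tuple[Tensor, Tensor]:
    """Pool [B, M, 2h] site embeddings into [B, 2h] with gamma [B, M]."""
    c = (V @ t[f"Fc_{side}_W"] + t[f"Fc_{side}_b"]).tanh()  # [B, M, a]
    scores = (c * t[f"cs_{side}"]).sum(axis=-1)             # [B, M]
    gamma = masked_softmax(scores, mask=mask, axis=-1)
    r = (gamma.reshape(*gamma.shape, 1) * V).sum(axis=1)
    return r, gamma


class ForwardResult:
    """Scores, per-record attention maps, and graph tensors for backprop."""

    def __init__(self, scores, maps, y_hat_tensor, tensors):
        self.scores: np.ndarray = scores
        self.maps: list[AttentionMaps] = maps
        self.y_hat: Tensor = y_hat_tensor
        self.tensors: dict[str, Tensor] = tensors


def _forward_graph(batch: JunctionBatch, t: dict[str, Tensor], cfg: ModelConfig) -> ForwardResult:
    B, M, L = batch.acceptor_ids.shape
    if L != cfg.L:
        raise ValueError(f"batch window length {L} != config L {cfg.L}")
    mask = batch.site_mask
    if not np.all(mask.sum(axis=1) >= 1):
        raise ValueError("every record needs at least one unmasked site")
    w_a, alpha_a = _encode_side(batch.acceptor_ids.reshape(B * M, L), "a", t, cfg)
    w_d, alpha_d = _encode_side(batch.donor_ids.reshape(B * M, L), "d", t, cfg)
    W_a = w_a.reshape(B, M, 2 * cfg.h)
    W_d = w_d.reshape(B, M, 2 * cfg.h)
    V_a, V_d, beta_a, beta_d = _cross(W_a, W_d, mask)
    r_a, gamma_a = _site_pool(V_a, "a", t, mask)
    r_d, gamma_d = _site_pool(V_d, "d", t, mask)
    r = concat([r_a, r_d], axis=-1)                                # [B, 4h]
    hidden = (r @ t["Fr_W"] + t["Fr_b"]).relu()
    y_hat = (hidden @ t["Fp_W"] + t["Fp_b"]).reshape(B).sigmoid()
    maps = []
    a_a = alpha_a.data.reshape(B, M, L)
    a_d = alpha_d.data.reshape(B, M, L)
    for b in range(B):
        m = int(mask[b].sum())
        maps.append(
            AttentionMaps(
                alpha_a=a_a[b, :m].copy(),
                alpha_d=a_d[b, :m].copy(),
                beta_a=beta_a.data[b, :m, :m].copy(),
                beta_d=beta_d.data[b, :m, :m].copy(),
                gamma_a=gamma_a.data[b, :m].copy(),
                gamma_d=gamma_d.data[b, :m].copy(),
            )
        )
    return ForwardResult(y_hat.data.copy(), maps, y_hat, t)


def forward(batch: JunctionBatch, params: ModelParams, cfg: ModelConfig) -> ForwardResult:
    """Deterministic forward pass over a featurized batch."""
    return _forward_graph(batch, params.as_tensors(), cfg)


# -- single-instance wrappers used by tests and interpretation ------------


def encode_junctions(ids: np.ndarray, side: str, params: ModelParams, cfg: ModelConfig):
    """Encode [M, L] windows of one record; returns (W [M, 2h], alpha [M, L])."""
    ids = np.asarray(ids)
    if ids.ndim != 2:
        raise ValueError("ids must be [M, L]")
    if side not in ("acceptor", "donor"):
        raise ValueError("side must be 'acceptor' or 'donor'")
    w, alpha = _encode_side(ids, side[0], params.as_tensors(), cfg)
    return w.data, alpha.data


def cross_attention(W_a: np.ndarray, W_d: np.ndarray, mask: np.ndarray | None = None):
    """Single-record cross-attention; returns (V_a, V_d, beta_a, beta_d)."""
    W_a, W_d = np.asarray(W_a), np.asarray(W_d)
    m, n = W_a.shape[0], W_d.shape[0]
    if mask is None:
        mask = np.ones(max(m, n))
    if mask.sum() < 1:
        raise ValueError("all sites masked")
    if m != n:
        # pad to a square site dimension for the shared-mask batched kernel
        M = max(m, n)
        Wa = np.zeros((M, W_a.shape[1]))
        Wd = np.zeros((M, W_d.shape[1]))
        Wa[:m], Wd[:n] = W_a, W_d
        mask_a = np.zeros(M)
        mask_a[:m] = 1
        mask_d = np.zeros(M)
        mask_d[:n] = 1
        S = Wa @ Wd.T
        beta_a = _np_masked_softmax(S, mask_d[None, :])
        beta_d = _np_masked_softmax(S.T, mask_a[None, :])
        return (beta_a @ Wd)[:m], (beta_d @ Wa)[:n], beta_a[:m, :n], beta_d[:n, :m]
    V_a, V_d, beta_a, beta_d = _cross(
        Tensor(W_a[None]), Tensor(W_d[None]), np.asarray(mask)[None]
    )
    return V_a.data[0], V_d.data[0], beta_a.data[0], beta_d.data[0]


def _np_masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    e = np.exp(scores - scores.max(axis=-1, keepdims=True)) * mask
    return e / e.sum(axis=-1, keepdims=True)


def site_attention(V: np.ndarray, side: str, params: ModelParams, cfg: ModelConfig, mask=None):
    """Pool one record's [M, 2h] embeddings; returns (r [2h], gamma [M])."""
    V = np.asarray(V)
    if side not in ("acceptor", "donor"):
        raise ValueError("side must be 'acceptor' or 'donor'")
    if mask is None:
        mask = np.ones(V.shape[0])
    mask = np.asarray(mask, dtype=float)
    if mask.sum() < 1:
        raise ValueError("all sites masked")
    r, gamma = _site_pool(Tensor(V[None]), side[0], params.as_tensors(), mask[None])
    return r.data[0], gamma.data[0]


def loss(y_hat, y, params: ModelParams | None = None, lambda_l2: float = 0.0) -> float:
    """Mean binary cross-entropy plus ``lambda_l2 * ||theta||^2``."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y_hat)) or np.any(~np.isfinite(y)):
        raise ValueError("NaN/inf in loss inputs")
    yh = np.clip(y_hat, 1e-7, 1 - 1e-7)
    bce = -np.mean(y * np.log(yh) + (1 - y) * np.log(1 - yh))
    reg = lambda_l2 * params.l2_norm_sq() if params is not None and lambda_l2 > 0 else 0.0
    return float(bce + reg)


def loss_graph(result: ForwardResult, y: np.ndarray, lambda_l2: float) -> Tensor:
    """Differentiable training loss on a forward result."""
    y = Tensor(np.asarray(y, dtype=np.float64))
    yh = result.y_hat.clip(1e-7, 1 - 1e-7)
    bce = -(y * yh.log() + (1.0 - y) * (1.0 - yh).log()).mean()
    if lambda_l2 > 0:
        reg = None
        for t in result.tensors.values():
            term = (t * t).sum()
            reg = term if reg is None else reg + term
        return bce + lambda_l2 * reg
    return bce


# -- checkpoints ----------------------------------------------------------


def save_checkpoint(path, params: ModelParams, cfg: ModelConfig, extra: dict | None = None) -> None:
    """Single-archive checkpoint: JSON header + one .npy per parameter."""
    header = {"config": asdict(cfg), "param_names": params.names(), "extra": extra or {}}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name in params.names():
            buf = _stdio.BytesIO()
            np.save(buf, params[name])
            zf.writestr(f"params/{name}.npy", buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig, dict]:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        cfg = ModelConfig(**header["config"])
        arrays = {}
        for name in header["param_names"]:
            buf = _stdio.BytesIO(zf.read(f"params/{name}.npy"))
            arrays[name] = np.load(buf)
    return ModelParams(arrays), cfg, header.get("extra", {})
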