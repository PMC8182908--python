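"""Graph-convolutional forward computation and its gradients.

The classifier composes, per molecule, K graph-convolution layers on the
shared interactome (operator chosen among GCN / GraphSAGE / ChebNet), a
jumping-knowledge concatenation of all layer outputs, a learned linear
readout (per node, or per pathway after pooling with the fixed membership
matrix P), and a 2-layer MLP ending in a softmax over the
anticancer/non-anticancer classes:

    H^(0) = x  (|V| x 1 binary target signal)
    GCN:   H^(l+1) = relu( D̃^{-1/2} Ã D̃^{-1/2} H^(l) W^(l) )
    SAGE:  Ĥ = D̃^{-1} Ã H^(l) W^(l);  H^(l+1) = relu(Ĥ_r / ||Ĥ_r||_2) row-wise
    Cheb:  H^(l+1) = relu( Σ_{n<N} Y_n W_n ),  Y_0 = H, Y_1 = L̂H,
           Y_n = 2 L̂ Y_{n-1} − Y_{n-2}
    Z = [H^(1) | ... | H^(K)]          (jumping knowledge)
    z = Z W_fc   or   ẑ = (P Z) W_fcp  (readout)
    p = softmax( relu(z W_l1 + b_1) W_l2 + b_2 )

Convolution layers carry no bias (the layer equations have none); the MLP
does.  All parameters are plain numpy arrays; :func:`forward_batch` /
:func:`backward_batch` implement reverse-mode differentiation by hand, which
also yields the input gradients integrated-gradients attribution needs.
Models at this scale (d = 8 hidden units, K <= 3) run comfortably on one CPU.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .interactome import SpectralOperators

__all__ = [
    "BatchNormState",
    "LayerWeights",
    "Readout",
    "MlpHead",
    "ModelState",
    "init_model",
    "gcn_layer",
    "sage_layer",
    "cheb_layer",
    "jumping_knowledge_concat",
    "node_readout",
    "pathway_pool",
    "mlp_head",
    "forward",
    "forward_batch",
    "backward_batch",
    "parameters",
    "save_model",
    "load_model",
]

_SAGE_ZERO_TOL = 1e-12


@dataclass
class BatchNormState:
    """Per-channel normalization of pre-activation node features.

    Statistics are taken over the batch x node axes; running estimates are
    used in inference mode.
    """

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    momentum: float = 0.1
    eps: float = 1e-5

    @classmethod
    def create(cls, d: int) -> "BatchNormState":
        return cls(np.ones(d), np.zeros(d), np.zeros(d), np.ones(d))


@dataclass
class LayerWeights:
    kind: str  # gcn | sage | cheb
    W: np.ndarray | list[np.ndarray]
    N: int = 1  # Chebyshev filter size (number of polynomial terms)
    batch_norm: BatchNormState | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gcn", "sage", "cheb"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "cheb":
            if not isinstance(self.W, list) or len(self.W) != self.N or self.N < 1:
                raise ValueError("cheb layer requires a list of N weight matrices, N >= 1")

    @property
    def out_dim(self) -> int:
        w = self.W[0] if isinstance(self.W, list) else self.W
        return w.shape[1]


@dataclass
class Readout:
    mode: str  # node | pathway
    W_fc: np.ndarray  # (d_1+...+d_K, 1)
    P: np.ndarray | None = None  # (npathways, |V|), pathway mode only

    def __post_init__(self) -> None:
        if self.mode not in ("node", "pathway"):
            raise ValueError(f"unknown readout mode {self.mode!r}")
        if self.mode == "pathway" and self.P is None:
            raise ValueError("pathway readout requires a membership matrix P")


@dataclass
class MlpHead:
    W_l1: np.ndarray  # (m, 32)
    b_1: np.ndarray  # (32,)
    W_l2: np.ndarray  # (32, 2)
    b_2: np.ndarray  # (2,)
    dropout_layers: int = 1
    dropout_rate: float = 0.5


@dataclass
class ModelState:
    """All learnable weights plus the architecture configuration."""

    layers: list[LayerWeights]
    readout: Readout
    head: MlpHead
    feature_normalization: bool = False
    gene_ids: list[str] | None = None  # binds a checkpoint to one node order
    config: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def copy(self) -> "ModelState":
        return copy.deepcopy(self)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(
    n_nodes: int,
    kind: str = "cheb",
    n_conv_layers: int = 2,
    hidden: int = 8,
    cheb_n: int = 4,
    readout_mode: str = "node",
    pathway_matrix: np.ndarray | None = None,
    batch_norm: bool = False,
    dropout_layers: int = 1,
    dropout_rate: float = 0.5,
    feature_normalization: bool = False,
    mlp_hidden: int = 32,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> ModelState:
    """Build a model with seeded Glorot-uniform weights.

    ``hidden`` is the width d of every convolution layer (default 8); the MLP
    hidden layer has 32 units and the output layer 2.
    """
    rng = np.random.default_rng(seed)
    dims = [1] + [hidden] * n_conv_layers
    layers: list[LayerWeights] = []
    for l in range(n_conv_layers):
        if kind == "cheb":
            w = [_glorot(rng, dims[l], dims[l + 1]) for _ in range(cheb_n)]
            lw = LayerWeights(kind=kind, W=w, N=cheb_n)
        else:
            lw = LayerWeights(kind=kind, W=_glorot(rng, dims[l], dims[l + 1]))
        if batch_norm:
            lw.batch_norm = BatchNormState.create(dims[l + 1])
        layers.append(lw)
    jk_dim = sum(dims[1:])
    if readout_mode == "pathway":
        if pathway_matrix is None:
            raise ValueError("pathway readout requires pathway_matrix")
        p = np.asarray(pathway_matrix, dtype=np.float64)
        m = p.shape[0]
    else:
        p = None
        m = n_nodes
    readout = Readout(mode=readout_mode, W_fc=_glorot(rng, jk_dim, 1), P=p)
    head = MlpHead(
        W_l1=_glorot(rng, m, mlp_hidden),
        b_1=np.zeros(mlp_hidden),
        W_l2=_glorot(rng, mlp_hidden, 2),
        b_2=np.zeros(2),
        dropout_layers=dropout_layers,
        dropout_rate=dropout_rate,
    )
    return ModelState(
        layers=layers,
        readout=readout,
        head=head,
        feature_normalization=feature_normalization,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
        config={
            "n_nodes": n_nodes,
            "kind": kind,
            "n_conv_layers": n_conv_layers,
            "hidden": hidden,
            "cheb_n": cheb_n,
            "readout_mode": readout_mode,
            "batch_norm": batch_norm,
            "dropout_layers": dropout_layers,
            "dropout_rate": dropout_rate,
            "feature_normalization": feature_normalization,
            "mlp_hidden": mlp_hidden,
        },
    )


# ---------------------------------------------------------------------------
# primitives (batched: leading axis is the molecule batch)


def _gmul(s_mat, h: np.ndarray) -> np.ndarray:
    """Apply a (V,V) sparse/dense operator to every batch slice of (B,V,d)."""
    b, v, d = h.shape
    flat = h.transpose(1, 0, 2).reshape(v, b * d)
    out = s_mat @ flat
    return np.asarray(out).reshape(v, b, d).transpose(1, 0, 2)


def _bn_forward(bn: BatchNormState, pre: np.ndarray, train: bool):
    if train:
        mean = pre.mean(axis=(0, 1))
        var = pre.var(axis=(0, 1))
        bn.running_mean = (1 - bn.momentum) * bn.running_mean + bn.momentum * mean
        bn.running_var = (1 - bn.momentum) * bn.running_var + bn.momentum * var
    else:
        mean, var = bn.running_mean, bn.running_var
    inv_std = 1.0 / np.sqrt(var + bn.eps)
    xhat = (pre - mean) * inv_std
    out = bn.gamma * xhat + bn.beta
    cache = (xhat, inv_std, train, pre.shape[0] * pre.shape[1])
    return out, cache


def _bn_backward(bn: BatchNormState, cache, dout: np.ndarray):
    xhat, inv_std, train, m = cache
    dgamma = (dout * xhat).sum(axis=(0, 1))
    dbeta = dout.sum(axis=(0, 1))
    dxhat = dout * bn.gamma
    if train:
        dpre = (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )
    else:
        dpre = dxhat * inv_std
    return dpre, dgamma, dbeta


def _conv_forward(h: np.ndarray, ops: SpectralOperators, w: LayerWeights, train: bool):
    """One convolution layer on a (B,V,d_l) batch; returns (out, cache)."""
    if w.kind == "gcn":
        m = _gmul(ops.gcn_operator, h)
        pre = m @ w.W
        cache: dict = {"M": m}
    elif w.kind == "sage":
        m = _gmul(ops.rw_operator, h)
        hh = m @ w.W
        norms = np.linalg.norm(hh, axis=2, keepdims=True)
        safe = norms > _SAGE_ZERO_TOL
        y = np.where(safe, hh / np.where(safe, norms, 1.0), 0.0)
        pre = y
        cache = {"M": m, "Y": y, "norms": norms, "safe": safe}
    elif w.kind == "cheb":
        if w.N < 1:
            raise ValueError("Chebyshev filter size N must be >= 1")
        ys = [h]
        if w.N > 1:
            ys.append(_gmul(ops.scaled_laplacian, h))
        for n in range(2, w.N):
            ys.append(2.0 * _gmul(ops.scaled_laplacian, ys[-1]) - ys[-2])
        pre = sum(y @ wn for y, wn in zip(ys, w.W))
        cache = {"Ys": ys}
    else:  # pragma: no cover - guarded in LayerWeights
        raise ValueError(w.kind)
    if w.batch_norm is not None:
        pre_bn, bn_cache = _bn_forward(w.batch_norm, pre, train)
        cache["bn"] = bn_cache
    else:
        pre_bn = pre
    out = np.maximum(pre_bn, 0.0)
    cache["relu_mask"] = pre_bn > 0
    return out, cache


def _conv_backward(
    dout: np.ndarray, ops: SpectralOperators, w: LayerWeights, cache: dict
):
    """Backward through one convolution layer; returns (dH, grads dict)."""
    dpre = dout * cache["relu_mask"]
    grads: dict[str, np.ndarray] = {}
    if w.batch_norm is not None:
        dpre, dgamma, dbeta = _bn_backward(w.batch_norm, cache["bn"], dpre)
        grads["bn.gamma"] = dgamma
        grads["bn.beta"] = dbeta
    if w.kind == "gcn":
        m = cache["M"]
        grads["W"] = np.einsum("bvd,bve->de", m, dpre)
        dm = dpre @ w.W.T
        dh = _gmul(ops.gcn_operator.T, dm)
    elif w.kind == "sage":
        m, y, norms, safe = cache["M"], cache["Y"], cache["norms"], cache["safe"]
        # y = hh / ||hh||  row-wise: d hh = (dy - y <dy, y>) / ||hh||
        inner = (dpre * y).sum(axis=2, keepdims=True)
        dhh = np.where(safe, (dpre - y * inner) / np.where(safe, norms, 1.0), 0.0)
        grads["W"] = np.einsum("bvd,bve->de", m, dhh)
        dm = dhh @ w.W.T
        dh = _gmul(ops.rw_operator.T, dm)
    else:  # cheb
        ys = cache["Ys"]
        for n, _ in enumerate(w.W):
            grads[f"W{n}"] = np.einsum("bvd,bve->de", ys[n], dpre)
        dys = [dpre @ wn.T for wn in w.W]
        lap_t = ops.scaled_laplacian.T
        for n in range(w.N - 1, 1, -1):
            dys[n - 1] = dys[n - 1] + 2.0 * _gmul(lap_t, dys[n])
            dys[n - 2] = dys[n - 2] - dys[n]
        dh = dys[0]
        if w.N > 1:
            dh = dh + _gmul(lap_t, dys[1])
    return dh, grads


def _readout_forward(z_big: np.ndarray, r: Readout):
    if r.mode == "node":
        z = np.einsum("bvD,D->bv", z_big, r.W_fc[:, 0])
        cache = {"Z": z_big}
    else:
        zp = np.einsum("pv,bvD->bpD", r.P, z_big)
        z = np.einsum("bpD,D->bp", zp, r.W_fc[:, 0])
        cache = {"Z": z_big, "Zp": zp}
    return z, cache


def _readout_backward(dz: np.ndarray, r: Readout, cache: dict):
    if r.mode == "node":
        z_big = cache["Z"]
        dw = np.einsum("bvD,bv->D", z_big, dz)[:, None]
        dz_big = dz[..., None] * r.W_fc[:, 0]
    else:
        z_big, zp = cache["Z"], cache["Zp"]
        dw = np.einsum("bpD,bp->D", zp, dz)[:, None]
        dzp = dz[..., None] * r.W_fc[:, 0]
        dz_big = np.einsum("pv,bpD->bvD", r.P, dzp)
    return dz_big, {"W_fc": dw}


def _dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _head_forward(
    z: np.ndarray, head: MlpHead, train: bool, rng: np.random.Generator | None
):
    if not np.isfinite(z).all():
        raise ValueError("non-finite input to the MLP head")
    mask_z = None
    z_in = z
    if train and head.dropout_layers >= 2 and head.dropout_rate > 0:
        mask_z = _dropout_mask(z.shape, head.dropout_rate, rng)
        z_in = z * mask_z
    a1 = z_in @ head.W_l1 + head.b_1
    h = np.maximum(a1, 0.0)
    mask_h = None
    h_d = h
    if train and head.dropout_layers >= 1 and head.dropout_rate > 0:
        mask_h = _dropout_mask(h.shape, head.dropout_rate, rng)
        h_d = h * mask_h
    logits = h_d @ head.W_l2 + head.b_2
    shifted = logits - logits.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    cache = {"z_in": z_in, "a1": a1, "h_d": h_d, "mask_z": mask_z, "mask_h": mask_h}
    return probs, cache


def _head_backward(dlogits: np.ndarray, head: MlpHead, cache: dict):
    grads = {
        "W_l2": cache["h_d"].T @ dlogits,
        "b_2": dlogits.sum(axis=0),
    }
    dh_d = dlogits @ head.W_l2.T
    dh = dh_d if cache["mask_h"] is None else dh_d * cache["mask_h"]
    da1 = dh * (cache["a1"] > 0)
    grads["W_l1"] = cache["z_in"].T @ da1
    grads["b_1"] = da1.sum(axis=0)
    dz_in = da1 @ head.W_l1.T
    dz = dz_in if cache["mask_z"] is None else dz_in * cache["mask_z"]
    return dz, grads


# ---------------------------------------------------------------------------
# public single-instance surface


def _single(fn, h, *args, **kwargs):
    out, _ = fn(h[None, ...], *args, **kwargs)
    return out[0]


def gcn_layer(h: np.ndarray, ops: SpectralOperators, w: LayerWeights,
              train_mode: bool = False) -> np.ndarray:
    """σ(D̃^{-1/2} Ã D̃^{-1/2} H W) for one molecule; H is (|V|, d_l)."""
    if w.kind != "gcn":
        raise ValueError("gcn_layer requires kind='gcn'")
    return _single(_conv_forward, np.asarray(h, float), ops, w, train_mode)


def sage_layer(h: np.ndarray, ops: SpectralOperators, w: LayerWeights,
               train_mode: bool = False) -> np.ndarray:
    """Row-normalized mean-aggregator layer; zero rows pass through as zero."""
    if w.kind != "sage":
        raise ValueError("sage_layer requires kind='sage'")
    return _single(_conv_forward, np.asarray(h, float), ops, w, train_mode)


def cheb_layer(h: np.ndarray, ops: SpectralOperators, w: LayerWeights,
               train_mode: bool = False) -> np.ndarray:
    """σ(Σ_n T_n(L̂) H W_n) via the three-term Chebyshev recursion."""
    if w.kind != "cheb":
        raise ValueError("cheb_layer requires kind='cheb'")
    return _single(_conv_forward, np.asarray(h, float), ops, w, train_mode)


def jumping_knowledge_concat(hs: Sequence[np.ndarray]) -> np.ndarray:
    """Column-wise concatenation of the K layer outputs, in layer order."""
    rows = {h.shape[0] for h in hs}
    if len(rows) != 1:
        raise ValueError("all layer outputs must share the node axis")
    return np.concatenate(list(hs), axis=-1)


def node_readout(z_big: np.ndarray, r: Readout) -> np.ndarray:
    """z = Z W_fc (linear, no activation); returns a length-|V| vector."""
    if r.mode != "node":
        raise ValueError("node_readout requires mode='node'")
    if z_big.shape[1] != r.W_fc.shape[0]:
        raise ValueError("Z / W_fc dimension mismatch")
    out, _ = _readout_forward(np.asarray(z_big, float)[None, ...], r)
    return out[0]


def pathway_pool(z_big: np.ndarray, r: Readout) -> np.ndarray:
    """ẑ = (P Z) W_fcp; returns a length-npathways vector."""
    if r.mode != "pathway":
        raise ValueError("pathway_pool requires mode='pathway'")
    if r.P.shape[1] != z_big.shape[0]:
        raise ValueError("P / Z dimension mismatch")
    out, _ = _readout_forward(np.asarray(z_big, float)[None, ...], r)
    return out[0]


def mlp_head(z: np.ndarray, head: MlpHead, train_mode: bool = False,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """softmax(relu(z W_l1 + b_1) W_l2 + b_2); returns a probability pair."""
    if len(z) != head.W_l1.shape[0]:
        raise ValueError("input / W_l1 dimension mismatch")
    probs, _ = _head_forward(np.asarray(z, float)[None, :], head, train_mode, rng)
    return probs[0]


def forward(model: ModelState, x: np.ndarray, ops: SpectralOperators,
            train_mode: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
    """Full forward pass for one molecule signal; returns (p_non_ac, p_ac)."""
    probs, _ = forward_batch(model, np.asarray(x, float)[None, :], ops, train_mode, rng)
    return probs[0]


# ---------------------------------------------------------------------------
# batched forward / backward used by training and attribution


def forward_batch(
    model: ModelState,
    x: np.ndarray,
    ops: SpectralOperators,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Forward a (B,|V|) batch of signals; returns (probs (B,2), cache)."""
    x = np.asarray(x, dtype=np.float64)
    if train_mode and rng is None:
        rng = np.random.default_rng()
    cache: dict = {"x": x}
    if model.feature_normalization:
        s = x.sum(axis=1)
        m = np.maximum(1.0, s)
        h = (x / m[:, None])[:, :, None]
        cache["fn"] = (s, m)
    else:
        h = x[:, :, None]
    layer_outs = []
    layer_caches = []
    for w in model.layers:
        h, c = _conv_forward(h, ops, w, train_mode)
        layer_outs.append(h)
        layer_caches.append(c)
    z_big = np.concatenate(layer_outs, axis=2)
    cache["layer_caches"] = layer_caches
    cache["layer_dims"] = [h_.shape[2] for h_ in layer_outs]
    z, r_cache = _readout_forward(z_big, model.readout)
    cache["readout"] = r_cache
    probs, h_cache = _head_forward(z, model.head, train_mode, rng)
    cache["head"] = h_cache
    cache["probs"] = probs
    return probs, cache


def backward_batch(model: ModelState, ops: SpectralOperators, cache: dict,
                   dlogits: np.ndarray):
    """Backward pass from logit gradients; returns (grads by name, dX (B,|V|))."""
    dz, head_grads = _head_backward(dlogits, model.head, cache["head"])
    grads = {f"head.{k}": v for k, v in head_grads.items()}
    dz_big, r_grads = _readout_backward(dz, model.readout, cache["readout"])
    grads.update({f"readout.{k}": v for k, v in r_grads.items()})
    # split the jumping-knowledge gradient back into per-layer blocks
    splits = np.cumsum(cache["layer_dims"])[:-1]
    dh_blocks = np.split(dz_big, splits, axis=2)
    dh = None
    for li in range(len(model.layers) - 1, -1, -1):
        dout = dh_blocks[li] if dh is None else dh_blocks[li] + dh
        dh, l_grads = _conv_backward(dout, ops, model.layers[li], cache["layer_caches"][li])
        grads.update({f"layer{li}.{k}": v for k, v in l_grads.items()})
    dxn = dh[:, :, 0]
    if model.feature_normalization:
        s, m = cache["fn"]
        x = cache["x"]
        dx = dxn / m[:, None]
        active = s > 1.0
        corr = (dxn * x).sum(axis=1) / m**2
        dx = dx - active[:, None] * corr[:, None]
    else:
        dx = dxn
    return grads, dx


def parameters(model: ModelState) -> Iterator[tuple[str, np.ndarray, bool]]:
    """Yield (name, array, weight_decay_applies) for every learnable tensor."""
    for li, w in enumerate(model.layers):
        if isinstance(w.W, list):
            for n, wn in enumerate(w.W):
                yield f"layer{li}.W{n}", wn, True
        else:
            yield f"layer{li}.W", w.W, True
        if w.batch_norm is not None:
            yield f"layer{li}.bn.gamma", w.batch_norm.gamma, False
            yield f"layer{li}.bn.beta", w.batch_norm.beta, False
    yield "readout.W_fc", model.readout.W_fc, True
    yield "head.W_l1", model.head.W_l1, True
    yield "head.b_1", model.head.b_1, False
    yield "head.W_l2", model.head.W_l2, True
    yield "head.b_2", model.head.b_2, False


def set_parameter(model: ModelState, name: str, value: np.ndarray) -> None:
    for pname, arr, _ in parameters(model):
        if pname == name:
            arr[...] = value
            return
    raise KeyError(name)


# ---------------------------------------------------------------------------
# checkpointing


def save_model(model: ModelState, prefix: str | Path) -> None:
    """Write a checkpoint: <prefix>.json (config) + <prefix>.npz (arrays)."""
    prefix = Path(prefix)
    arrays = {name: arr for name, arr, _ in parameters(model)}
    for li, w in enumerate(model.layers):
        if w.batch_norm is not None:
            arrays[f"layer{li}.bn.running_mean"] = w.batch_norm.running_mean
            arrays[f"layer{li}.bn.running_var"] = w.batch_norm.running_var
    if model.readout.P is not None:
        arrays["readout.P"] = model.readout.P
    np.savez(prefix.with_suffix(".npz"), **arrays)
    manifest = {"config": model.config, "gene_ids": model.gene_ids}
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh)


def load_model(prefix: str | Path) -> ModelState:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    data = np.load(prefix.with_suffix(".npz"))
    model = init_model(
        n_nodes=cfg["n_nodes"],
        kind=cfg["kind"],
        n_conv_layers=cfg["n_conv_layers"],
        hidden=cfg["hidden"],
        cheb_n=cfg["cheb_n"],
        readout_mode=cfg["readout_mode"],
        pathway_matrix=data["readout.P"] if "readout.P" in data else None,
        batch_norm=cfg["batch_norm"],
        dropout_layers=cfg["dropout_layers"],
        dropout_rate=cfg["dropout_rate"],
        feature_normalization=cfg["feature_normalization"],
        mlp_hidden=cfg["mlp_hidden"],
        gene_ids=manifest["gene_ids"],
    )
    for name, arr, _ in parameters(model):
        arr[...] = data[name]
    for li, w in enumerate(model.layers):
        if w.batch_norm is not None:
            w.batch_norm.running_mean[...] = data[f"layer{li}.bn.running_mean"]
            w.batch_norm.running_var[...] = data[f"layer{li}.bn.running_var"]
    return model
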