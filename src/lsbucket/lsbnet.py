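"""Inception convolutional network mapping a sequence to k binary hash-codes.

The model ``g`` maps a one-hot encoded length-``n`` sequence to ``k``
real-valued vectors in ``[0,1]^m``; thresholding at ``theta`` yields the
``k`` binary *hash-codes* ``f``.  Two sequences collide when some aligned
pair of hash-codes is bitwise equal, which makes ``f`` an (aligned)
locality-sensitive bucketing function once trained.

The building block is a convolution of width ``w`` followed by ReLU and a
non-overlapping max-pool of stride ``p``: the convolution kernel scores
length-``w`` substrings and the max-pool selects the best-scoring window,
so a shared substring contributes the same feature even when indels shift
it by a few positions (the unit is a learnable minimizer).  An *inception
layer* runs one such unit for every width ``w`` in ``{2, ..., l}`` and
concatenates the channel outputs.  After the final inception layer the
features are flattened (position-major) and sent through a fully connected
layer with a sigmoid, reshaped to ``k`` rows of length ``m``.

The network is implemented directly on NumPy arrays with hand-derived
gradients (verified against finite differences in the test suite), which
keeps inference and training deterministic and dependency-light at the
small model sizes this problem needs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .seqsim import DNA

__all__ = [
    "ModelConfig",
    "InceptionModel",
    "one_hot",
    "decode_one_hot",
    "conv_maxpool_unit",
    "inception_layer",
    "round_codes",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the hash-code network.

    n        : input sequence length
    alphabet : ordered input alphabet
    l        : maximum captured substring length (units for w = 2..l)
    p        : max-pool window = stride (non-overlapping)
    layers   : number of stacked inception layers
    k        : number of hash-codes per sequence
    m        : length of each hash-code
    theta    : rounding threshold for g -> f (strictly-above rule)
    channels : convolution filters per substring-width unit
    """

    n: int
    alphabet: str = DNA
    l: int = 9
    p: int = 2
    layers: int = 1
    k: int = 20
    m: int = 40
    theta: float = 0.5
    channels: int = 32

    def __post_init__(self) -> None:
        if not (2 <= self.l <= self.n):
            raise ValueError("require 2 <= l <= n")
        if self.p < 1:
            raise ValueError("require p >= 1")
        if self.k < 1 or self.m < 1:
            raise ValueError("require k >= 1 and m >= 1")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("require 0 < theta < 1")
        if self.layers < 1 or self.channels < 1:
            raise ValueError("require layers >= 1 and channels >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, blob: str) -> "ModelConfig":
        return cls(**json.loads(blob))


def one_hot(s: str, alphabet: str = DNA) -> np.ndarray:
    """One-hot encode a sequence as a ``|alphabet| x len(s)`` 0/1 matrix."""
    index = {c: i for i, c in enumerate(alphabet)}
    out = np.zeros((len(alphabet), len(s)), dtype=np.float64)
    for j, c in enumerate(s):
        try:
            out[index[c], j] = 1.0
        except KeyError:
            raise ValueError(f"character {c!r} not in alphabet {alphabet!r}") from None
    return out


def decode_one_hot(x: np.ndarray, alphabet: str = DNA) -> str:
    """Inverse of :func:`one_hot`."""
    return "".join(alphabet[i] for i in np.argmax(x, axis=0))


def encode_batch(seqs: list[str], alphabet: str = DNA) -> np.ndarray:
    """Stack one-hot encodings into a ``(B, |alphabet|, n)`` array."""
    return np.stack([one_hot(s, alphabet) for s in seqs])


def round_codes(g: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """Round real codes to binary hash-codes: strictly above ``theta`` -> 1.

    The tie at ``theta`` rounds to 0; downstream collisions depend on this
    rule, so it is fixed here rather than left to float comparison luck.
    """
    return (np.asarray(g) > theta).astype(np.uint8)


# ---------------------------------------------------------------------------
# functional building blocks (forward-only views of the model internals)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    # x: (B, C_in, L); w: (C_out, C_in, width) -> (B, C_out, L - width + 1)
    width = w.shape[2]
    if x.shape[2] < width:
        raise ValueError(
            f"input position axis ({x.shape[2]}) shorter than kernel width ({width})"
        )
    xw = np.lib.stride_tricks.sliding_window_view(x, width, axis=2)
    out = np.einsum("bclw,dcw->bdl", xw, w, optimize=True) + b[None, :, None]
    return out, xw


def _conv_backward(dout: np.ndarray, xw: np.ndarray, w: np.ndarray, x_shape):
    dw = np.einsum("bdl,bclw->dcw", dout, xw, optimize=True)
    db = dout.sum(axis=(0, 2))
    dx = np.zeros(x_shape, dtype=dout.dtype)
    L = dout.shape[2]
    for j in range(w.shape[2]):
        dx[:, :, j : j + L] += np.einsum("bdl,dc->bcl", dout, w[:, :, j], optimize=True)
    return dx, dw, db


def _pool_forward(x: np.ndarray, p: int):
    # non-overlapping max-pool of window = stride = p; trailing remainder dropped
    B, C, L = x.shape
    Lp = L // p
    if Lp < 1:
        raise ValueError(f"position axis ({L}) shorter than pool stride ({p})")
    xr = x[:, :, : Lp * p].reshape(B, C, Lp, p)
    arg = np.argmax(xr, axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, (arg, x.shape, Lp)


def _pool_backward(dout: np.ndarray, cache, p: int):
    arg, x_shape, Lp = cache
    B, C, _ = x_shape
    dxr = np.zeros((B, C, Lp, p), dtype=dout.dtype)
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : Lp * p] = dxr.reshape(B, C, Lp * p)
    return dx


def conv_maxpool_unit(
    features: np.ndarray, kernel: np.ndarray, bias: np.ndarray, pool: int
) -> np.ndarray:
    """Width-``w`` valid convolution, ReLU, then non-overlapping max-pool.

    ``features`` is ``(B, C_in, L)``; ``kernel`` is ``(C_out, C_in, w)``.
    Output position length is ``floor((L - w + 1) / pool)``.
    """
    pre, _ = _conv_forward(features, kernel, bias)
    act = np.maximum(pre, 0.0)
    out, _ = _pool_forward(act, pool)
    return out


def inception_layer(
    features: np.ndarray,
    kernels: dict[int, tuple[np.ndarray, np.ndarray]],
    pool: int,
) -> np.ndarray:
    """Run one conv+max-pool unit per width and concatenate along channels.

    Units of different widths produce different position-axis lengths; all
    outputs are right-truncated to the shortest before concatenation so the
    features stay aligned at the left end.
    """
    outs = [
        conv_maxpool_unit(features, w_arr, b_arr, pool)
        for _, (w_arr, b_arr) in sorted(kernels.items())
    ]
    lmin = min(o.shape[2] for o in outs)
    return np.concatenate([o[:, :, :lmin] for o in outs], axis=1)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class InceptionModel:
    """The trainable hash-code network g, plus its theta-rounding f.

    Parameters are plain float64 arrays in ``self.params``; ``forward``
    returns the real codes together with an opaque cache consumed by
    ``backward``, which returns gradients keyed like ``params``.  Two
    Siamese branches are simply two forward calls on the same instance —
    parameter sharing is automatic.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self._shapes = self._plan()
        self._init_params(seed)

    # -- architecture planning -------------------------------------------
    def _plan(self):
        cfg = self.config
        shapes = []
        c_in, length = len(cfg.alphabet), cfg.n
        for layer in range(cfg.layers):
            widths = range(2, cfg.l + 1)
            pooled = []
            for w in widths:
                if length < w:
                    raise ValueError(
                        f"layer {layer}: position axis {length} shorter than "
                        f"kernel width {w}; reduce l or layers"
                    )
                lp = (length - w + 1) // cfg.p
                if lp < 1:
                    raise ValueError(
                        f"layer {layer}: width-{w} unit pools to zero length"
                    )
                pooled.append(lp)
            shapes.append({"c_in": c_in, "length": length})
            length = min(pooled)
            c_in = (cfg.l - 1) * cfg.channels
        self.flat_dim = length * c_in
        self.out_length = length
        return shapes

    def _init_params(self, seed: int):
        cfg = self.config
        rng = np.random.default_rng(seed)

        def uniform(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        for layer, spec in enumerate(self._shapes):
            for w in range(2, cfg.l + 1):
                fan_in = spec["c_in"] * w
                self.params[f"conv{layer}_w{w}_W"] = uniform(
                    (cfg.channels, spec["c_in"], w), fan_in
                )
                self.params[f"conv{layer}_w{w}_b"] = uniform((cfg.channels,), fan_in)
        self.params["fc_W"] = uniform((cfg.k * cfg.m, self.flat_dim), self.flat_dim)
        self.params["fc_b"] = uniform((cfg.k * cfg.m,), self.flat_dim)

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray):
        """Map one-hot batch ``(B, |alphabet|, n)`` to real codes ``(B, k, m)``.

        Returns ``(g, cache)``; pass the cache to :meth:`backward`.
        """
        cfg = self.config
        if x.shape[1:] != (len(cfg.alphabet), cfg.n):
            raise ValueError(
                f"expected input of shape (B, {len(cfg.alphabet)}, {cfg.n}), "
                f"got {x.shape}"
            )
        cache = {"layers": []}
        feat = x
        for layer in range(cfg.layers):
            unit_caches = []
            outs = []
            for w in range(2, cfg.l + 1):
                W = self.params[f"conv{layer}_w{w}_W"]
                b = self.params[f"conv{layer}_w{w}_b"]
                pre, xw = _conv_forward(feat, W, b)
                act = np.maximum(pre, 0.0)
                out, pcache = _pool_forward(act, cfg.p)
                unit_caches.append((w, xw, pre, pcache, out.shape[2]))
                outs.append(out)
            lmin = min(o.shape[2] for o in outs)
            cache["layers"].append(
                {"in_shape": feat.shape, "units": unit_caches, "lmin": lmin}
            )
            feat = np.concatenate([o[:, :, :lmin] for o in outs], axis=1)
        B = feat.shape[0]
        flat = feat.transpose(0, 2, 1).reshape(B, -1)  # (position, channel) order
        z = flat @ self.params["fc_W"].T + self.params["fc_b"]
        g = 1.0 / (1.0 + np.exp(-z))
        cache["flat"] = flat
        cache["g_flat"] = g
        cache["feat_shape"] = feat.shape
        return g.reshape(B, cfg.k, cfg.m), cache

    def backward(self, dg: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. parameters given d(loss)/d(g)."""
        cfg = self.config
        B = dg.shape[0]
        g = cache["g_flat"]
        dz = dg.reshape(B, -1) * g * (1.0 - g)
        grads: dict[str, np.ndarray] = {
            "fc_W": dz.T @ cache["flat"],
            "fc_b": dz.sum(axis=0),
        }
        dflat = dz @ self.params["fc_W"]
        Bf, C, L = cache["feat_shape"]
        dfeat = dflat.reshape(B, L, C).transpose(0, 2, 1)
        for layer in range(cfg.layers - 1, -1, -1):
            lc = cache["layers"][layer]
            lmin = lc["lmin"]
            din = np.zeros(lc["in_shape"], dtype=dfeat.dtype)
            offset = 0
            for w, xw, pre, pcache, out_len in lc["units"]:
                dunit_trunc = dfeat[:, offset : offset + cfg.channels, :]
                offset += cfg.channels
                dunit = np.zeros((B, cfg.channels, out_len), dtype=dfeat.dtype)
                dunit[:, :, :lmin] = dunit_trunc
                dact = _pool_backward(dunit, pcache, cfg.p)
                dpre = dact * (pre > 0.0)
                W = self.params[f"conv{layer}_w{w}_W"]
                dx, dW, db = _conv_backward(dpre, xw, W, lc["in_shape"])
                grads[f"conv{layer}_w{w}_W"] = dW
                grads[f"conv{layer}_w{w}_b"] = db
                din += dx
            dfeat = din
        return grads

    # -- user-facing inference -------------------------------------------
    def real_codes(self, seqs: list[str], batch_size: int = 512) -> np.ndarray:
        """Real-valued codes ``g`` for a list of sequences, shape ``(N, k, m)``."""
        outs = []
        for i in range(0, len(seqs), batch_size):
            x = encode_batch(seqs[i : i + batch_size], self.config.alphabet)
            g, _ = self.forward(x)
            outs.append(g)
        return np.concatenate(outs) if outs else np.zeros(
            (0, self.config.k, self.config.m)
        )

    def hash_codes(self, seqs: list[str], batch_size: int = 512) -> np.ndarray:
        """Binary hash-codes ``f`` (theta-rounded ``g``), shape ``(N, k, m)``."""
        return round_codes(self.real_codes(seqs, batch_size), self.config.theta)

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: config JSON + parameter arrays (npz)."""
        np.savez(
            path,
            __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str) -> "InceptionModel":
        with np.load(path) as data:
            cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
            model = cls(cfg, seed=0)
            for name in model.params:
                arr = data[name]
                if arr.shape != model.params[name].shape:
                    raise ValueError(f"checkpoint parameter {name} has wrong shape")
                model.params[name] = arr.astype(np.float64)
        return model
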