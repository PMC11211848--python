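"""Hinge loss over sequence pairs and the four bridging scores z1..z4.

A training sample is a pair (s, t) with label y = -1 (edit distance at most
d1, the codes *should* collide) or y = +1 (at least d2, they should not).
The per-sample loss is the hinge

    L(s, t, y) = max{0, 1 - 2 * y * z(s, t)}

where z measures how far the closest pair of aligned codes is from
colliding.  Four variants bridge the real codes g and the rounded binary
codes f:

    z1 = min_i ||f_i(s) - f_i(t)||_inf - 0.5     (exact LSB semantics)
    z2 = min_i ||f_i(s) - f_i(t)||_2   - 0.5
    z3 = min_i ||g_i(s) - g_i(t)||_inf - 0.5
    z4 = min_i ||g_i(s) - g_i(t)||_2   - 0.5     (default; trains best)

For binary codes z1 is exactly -0.5 when some aligned pair of codes is
identical and exactly +0.5 otherwise, so the loss on a y=-1 sample is
exactly 0 (collision) or 2 (no collision).

z1/z2 act on the non-differentiable rounded codes; their training gradient
uses a straight-through estimator (the rounding is treated as identity in
the backward direction).  Minima over code index and the infinity norm
route their subgradient to the first minimizing / maximizing element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lsbnet import round_codes

VARIANTS = ("z1", "z2", "z3", "z4")

__all__ = ["LossConfig", "z_score", "sample_loss", "total_loss", "hinge_loss_batch"]


@dataclass
class LossConfig:
    variant: str = "z4"
    reduction: str = "mean"
    theta: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _code_norms(a: np.ndarray, b: np.ndarray, norm: str) -> np.ndarray:
    diff = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    if norm == "inf":
        return np.abs(diff).max(axis=-1)
    return np.sqrt((diff * diff).sum(axis=-1))


def z_score(
    g_s: np.ndarray,
    g_t: np.ndarray,
    f_s: np.ndarray | None = None,
    f_t: np.ndarray | None = None,
    variant: str = "z4",
    theta: float = 0.5,
) -> float:
    """The bridging score z(s, t) for one pair of code stacks of shape (k, m).

    Binary codes for z1/z2 are taken from ``f_s``/``f_t`` when given,
    otherwise derived by rounding the real codes at ``theta``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    g_s, g_t = np.asarray(g_s), np.asarray(g_t)
    if g_s.shape != g_t.shape or g_s.ndim != 2:
        raise ValueError("code stacks must share a (k, m) shape")
    if variant in ("z1", "z2"):
        a = round_codes(g_s, theta) if f_s is None else np.asarray(f_s)
        b = round_codes(g_t, theta) if f_t is None else np.asarray(f_t)
        if a.shape != g_s.shape or b.shape != g_t.shape:
            raise ValueError("binary codes must share the (k, m) shape")
    else:
        a, b = g_s, g_t
    norm = "inf" if variant in ("z1", "z3") else "2"
    return float(_code_norms(a, b, norm).min() - 0.5)


def sample_loss(z: float, y: int) -> float:
    """Hinge loss max{0, 1 - 2*y*z} for one sample."""
    if y not in (-1, 1):
        raise ValueError("label y must be -1 or +1")
    return max(0.0, 1.0 - 2.0 * y * z)


def total_loss(
    g_s: np.ndarray,
    g_t: np.ndarray,
    y: np.ndarray,
    config: LossConfig | None = None,
) -> float:
    """Batch loss: sum or mean of per-sample hinge losses.

    ``g_s``/``g_t`` are real codes of shape (B, k, m); ``y`` is (B,).
    """
    config = config or LossConfig()
    g_s, g_t, y = np.asarray(g_s), np.asarray(g_t), np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty batch")
    loss, _, _ = hinge_loss_batch(g_s, g_t, y, config)
    return loss


def hinge_loss_batch(
    g_s: np.ndarray,
    g_t: np.ndarray,
    y: np.ndarray,
    config: LossConfig,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its gradients w.r.t. the real codes of both branches.

    Returns ``(loss, d_g_s, d_g_t)`` with gradient arrays shaped like the
    inputs.  For z1/z2 the score is computed on the rounded codes while the
    gradient flows to the real codes unchanged (straight-through).
    """
    g_s = np.asarray(g_s, dtype=np.float64)
    g_t = np.asarray(g_t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if g_s.shape != g_t.shape or g_s.ndim != 3:
        raise ValueError("expected code stacks of shape (B, k, m)")
    B, k, m = g_s.shape
    if y.shape != (B,):
        raise ValueError("labels must be one per pair")

    if config.variant in ("z1", "z2"):
        diff = round_codes(g_s, config.theta).astype(np.float64) - round_codes(
            g_t, config.theta
        ).astype(np.float64)
    else:
        diff = g_s - g_t
    use_inf = config.variant in ("z1", "z3")

    if use_inf:
        norms = np.abs(diff).max(axis=2)  # (B, k)
    else:
        norms = np.sqrt((diff * diff).sum(axis=2))
    i_star = np.argmin(norms, axis=1)  # first minimum: deterministic tie-break
    z = norms[np.arange(B), i_star] - 0.5
    per_sample = np.maximum(0.0, 1.0 - 2.0 * y * z)
    loss = per_sample.sum()
    scale = 1.0
    if config.reduction == "mean":
        loss /= B
        scale = 1.0 / B

    # dL/dz = -2y on the active (positive-loss) samples
    dz = np.where(per_sample > 0.0, -2.0 * y, 0.0) * scale
    d_diff = np.zeros_like(g_s)
    rows = np.arange(B)
    sel = diff[rows, i_star, :]  # (B, m) difference at the minimizing code
    if use_inf:
        j_star = np.argmax(np.abs(sel), axis=1)  # first maximum
        sgn = np.sign(sel[rows, j_star])
        d_diff[rows, i_star, j_star] = dz * sgn
    else:
        nrm = norms[rows, i_star]
        safe = np.where(nrm > 0.0, nrm, 1.0)
        grad_dir = np.where(nrm[:, None] > 0.0, sel / safe[:, None], 0.0)
        d_diff[rows, i_star, :] = dz[:, None] * grad_dir
    return float(loss), d_diff, -d_diff
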