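"""Rescale-rule attribution for the differential-peak CNN.

The Rescale rule assigns each input entry a contribution to the difference in
a readout between the actual input and a reference (default: a sequence of
Ns, i.e. the all-zero one-hot matrix). Multipliers are 1 through the readout,
propagate through linear layers via the transposed weights, and through each
ReLU as the ratio of output difference to input difference (falling back to
the gradient where the input difference is below 1e-7). The default readout
is the summed post-ReLU output of the final convolutional layer; ``logit``
attributes the pre-sigmoid dense output instead, routing max-pool credit to
the argmax unit of the actual input.

Contributions satisfy completeness: they sum to readout(x) - readout(ref).
Hypothetical scores extend the observed-base contributions to all four bases
per position (the multipliers applied to each substituted one-hot difference
from the reference); the hypothetical entry of the observed base equals that
base's actual contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .convnet import ConvNet

DELTA_EPS = 1e-7


@dataclass
class AttributionTrack:
    contributions: np.ndarray  # 4 x L; nonzero only where input is nonzero
    input: np.ndarray
    target_value: float
    reference_value: float


@dataclass
class HypotheticalTrack:
    hypothetical: np.ndarray  # 4 x L


def _conv_dx(dz: np.ndarray, w: np.ndarray, x_shape) -> np.ndarray:
    """Propagate multipliers through a valid convolution (transposed weights).

    Channels-last: dz is (B, Lout, F), w is (F, C, K), output is (B, L, C).
    """
    f, c, k = w.shape
    bsz, lout, _ = dz.shape
    wr = w.transpose(2, 1, 0).reshape(k * c, f)
    dpm = (dz.reshape(bsz * lout, f) @ wr.T).reshape(bsz, lout, k, c)
    dx = np.zeros(x_shape, dtype=np.float64)
    for kk in range(k):
        dx[:, kk : kk + lout, :] += dpm[:, :, kk, :]
    return dx


def _rescale_through_relu(m_post, z_x, z_ref):
    delta_in = z_x - z_ref
    delta_out = np.maximum(z_x, 0) - np.maximum(z_ref, 0)
    grad = (z_x > 0).astype(np.float64)
    small = np.abs(delta_in) < DELTA_EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(small, grad, delta_out / np.where(small, 1.0, delta_in))
    return m_post * ratio


def rescale_multipliers(
    model: ConvNet,
    x: np.ndarray,
    reference: np.ndarray | None = None,
    target: str = "conv3",
):
    """Input-layer Rescale multipliers and the readout at x and the reference.

    Returns ``(multipliers, target_x, target_ref)`` with multipliers of shape
    (B, 4, L). ``target`` is ``"conv3"`` (sum of the final convolutional
    layer's post-ReLU output) or ``"logit"`` (pre-sigmoid dense output).
    """
    x = np.asarray(x)
    if x.dtype != np.float64:
        x = x.astype(np.float32)
    if x.ndim == 2:
        x = x[None]
    if reference is None:
        reference = np.zeros_like(x)
    else:
        reference = np.broadcast_to(np.asarray(reference, dtype=x.dtype), x.shape).copy()
    if reference.shape != x.shape:
        raise ValueError("reference and input must have the same shape")
    for name, arr in model.params.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in model parameter {name}")

    _, cx = model.forward(x, want_cache=True)
    _, cr = model.forward(reference, want_cache=True)

    f3 = model.cfg.conv_filters[2]
    if target == "conv3":
        target_x = cx["a3"].astype(np.float64).sum(axis=(1, 2))
        target_ref = cr["a3"].astype(np.float64).sum(axis=(1, 2))
        m = np.ones_like(cx["a3"], dtype=np.float64)
    elif target == "logit":
        target_x = cx["logit"].astype(np.float64)
        target_ref = cr["logit"].astype(np.float64)
        # dense layer: multipliers are the weights; max-pool routes credit to
        # the argmax unit of the actual input
        bsz = x.shape[0]
        n, pw = model.n_pool, model.cfg.pool_width
        m_pool = np.broadcast_to(
            model.params["wd"].reshape(1, n, f3).astype(np.float64), (bsz, n, f3)
        )
        m = np.zeros(cx["a3"].shape, dtype=np.float64)
        am = cx["argmax"]  # (B, n, F)
        bi = np.broadcast_to(np.arange(bsz)[:, None, None], am.shape)
        ni = np.broadcast_to(np.arange(n)[None, :, None], am.shape)
        ci = np.broadcast_to(np.arange(f3)[None, None, :], am.shape)
        np.add.at(m, (bi, ni * pw + am, ci), m_pool)
    else:
        raise ValueError(f"unknown target {target!r}")

    for layer in (3, 2, 1):
        m = _rescale_through_relu(m, cx[f"z{layer}"], cr[f"z{layer}"])
        m = _conv_dx(m, model.params[f"w{layer}"].astype(np.float64), cx[f"h{layer}"].shape)
    # back to channels-first (B, 4, L) to match the one-hot inputs
    return m.transpose(0, 2, 1), target_x, target_ref


def rescale_contributions(
    model: ConvNet,
    x: np.ndarray,
    reference: np.ndarray | None = None,
    target: str = "conv3",
) -> list[AttributionTrack]:
    """Per-input Rescale contribution tracks (contributions live on the
    observed bases; N columns contribute zero)."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 2
    if single:
        x = x[None]
    ref = np.zeros_like(x) if reference is None else np.broadcast_to(
        np.asarray(reference, dtype=np.float32), x.shape
    )
    m, tx, tr = rescale_multipliers(model, x, ref, target=target)
    contribs = m * (x.astype(np.float64) - ref.astype(np.float64))
    return [
        AttributionTrack(contribs[i], x[i], float(tx[i]), float(tr[i]))
        for i in range(x.shape[0])
    ]


def hypothetical_contributions(
    model: ConvNet,
    x: np.ndarray,
    reference: np.ndarray | None = None,
    target: str = "conv3",
) -> list[HypotheticalTrack]:
    """Hypothetical score tracks: for each position and base, the contribution
    the actual pass's multipliers would assign if that base were present."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    ref = np.zeros_like(x) if reference is None else np.broadcast_to(
        np.asarray(reference, dtype=np.float32), x.shape
    )
    m, _, _ = rescale_multipliers(model, x, ref, target=target)
    # hyp[b, p] = sum_b' m[b', p] * (delta_{b'b} - ref[b', p])
    correction = (m * ref.astype(np.float64)).sum(axis=1, keepdims=True)
    hyp = m - correction
    return [HypotheticalTrack(hyp[i]) for i in range(x.shape[0])]


def attribution_tracks(
    model: ConvNet,
    x: np.ndarray,
    reference: np.ndarray | None = None,
    target: str = "conv3",
    batch_size: int = 100,
) -> tuple[list[AttributionTrack], list[HypotheticalTrack]]:
    """Contribution and hypothetical tracks together, computed in batches."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    actual: list[AttributionTrack] = []
    hypo: list[HypotheticalTrack] = []
    for lo in range(0, x.shape[0], batch_size):
        xb = x[lo : lo + batch_size]
        refb = None if reference is None else reference
        m, tx, tr = rescale_multipliers(model, xb, refb, target=target)
        ref_arr = np.zeros_like(xb) if reference is None else np.broadcast_to(
            np.asarray(reference, dtype=np.float32), xb.shape
        )
        contribs = m * (xb.astype(np.float64) - ref_arr.astype(np.float64))
        correction = (m * ref_arr.astype(np.float64)).sum(axis=1, keepdims=True)
        hyp = m - correction
        for i in range(xb.shape[0]):
            actual.append(AttributionTrack(contribs[i], xb[i], float(tx[i]), float(tr[i])))
            hypo.append(HypotheticalTrack(hyp[i]))
    return actual, hypo
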