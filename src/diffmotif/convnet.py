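"""The fixed differential-peak CNN: three valid convolutions (60 filters of
4x15, 60 of 1x15, 15 of 1x15, each ReLU + dropout 0.2), max-pooling of width
and stride 35 (final partial window dropped), and a single sigmoid unit.

Implemented directly in NumPy with explicit forward and backward passes; the
same forward machinery also drives the Rescale attribution, which needs
per-layer pre- and post-activations. Training follows a fixed recipe:
SGD with Nesterov momentum 0.85, learning rate 0.01, batch size 200, class
weights equal to the fraction of peaks in the other class, a pretraining
phase on a class-balanced subsample from He-normal initialization, and early
stopping after three consecutive epochs without improvement in validation
recall at 80% precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve


@dataclass
class SplitSpec:
    """Chromosome-level train/validation/test split."""

    train_chroms: frozenset = frozenset(
        {f"chr{i}" for i in list(range(3, 8)) + list(range(10, 20))} | {"chrX"}
    )
    val_chroms: frozenset = frozenset({"chr8", "chr9"})
    test_chroms: frozenset = frozenset({"chr1", "chr2"})

    def __post_init__(self) -> None:
        sets = [set(self.train_chroms), set(self.val_chroms), set(self.test_chroms)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split chromosome sets must be pairwise disjoint")


@dataclass
class ConvNetConfig:
    conv_filters: tuple[int, int, int] = (60, 60, 15)
    filter_width: int = 15
    dropout_rate: float = 0.2
    pool_width: int = 35
    pool_stride: int = 35


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.85  # Nesterov
    batch_size: int = 200
    patience: int = 3
    precision_floor: float = 0.8
    max_epochs: int = 30
    pretrain: bool = True
    seed: int = 0


@dataclass
class ExampleSet:
    """Per labeled peak, two one-hot examples: forward and reverse complement."""

    x: np.ndarray  # (2 * n_peaks, 4, L), float32
    labels: np.ndarray  # (2 * n_peaks,) in {0, 1}
    chroms: np.ndarray  # (2 * n_peaks,) str
    peak_ids: np.ndarray  # (2 * n_peaks,) str; fwd/rev pair shares peak id

    def subset(self, mask: np.ndarray) -> "ExampleSet":
        return ExampleSet(self.x[mask], self.labels[mask], self.chroms[mask], self.peak_ids[mask])

    def for_chroms(self, chroms) -> "ExampleSet":
        return self.subset(np.isin(self.chroms, list(chroms)))


def make_examples(windows: dict[str, tuple[str, str, int]]) -> ExampleSet:
    """Build an ExampleSet from {peak_id: (sequence, chrom, label)}."""
    from .seqio import one_hot, revcomp_onehot

    xs, labels, chroms, ids = [], [], [], []
    for pid, (seq, chrom, label) in windows.items():
        fwd = one_hot(seq)
        for mat in (fwd, revcomp_onehot(fwd)):
            xs.append(mat)
            labels.append(label)
            chroms.append(chrom)
            ids.append(pid)
    return ExampleSet(
        np.stack(xs).astype(np.float32),
        np.array(labels, dtype=np.int8),
        np.array(chroms),
        np.array(ids),
    )


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid 1-D cross-correlation in channels-last layout, via real FFTs.

    x is (B, L, C), w is (F, C, K); returns (z, cache) with z of shape
    (B, L-K+1, F): z[b, l, f] = sum_{c,k} x[b, l+k, c] w[f, c, k] + b[f].
    The frequency-domain route keeps memory traffic low (no K-fold patch
    duplication), which dominates on bandwidth-limited hosts.
    """
    from scipy import fft as sfft

    bsz, length, c = x.shape
    f, _, k = w.shape
    lout = length - k + 1
    pad = sfft.next_fast_len(length + k, real=True)
    xf = sfft.rfft(x, n=pad, axis=1)  # (B, Pf, C) complex64
    wf = sfft.rfft(w[:, :, ::-1], n=pad, axis=2)  # (F, C, Pf)
    zf = xf.transpose(1, 0, 2) @ wf.transpose(2, 1, 0)  # (Pf, B, F)
    zfull = sfft.irfft(zf, n=pad, axis=0)
    z = np.ascontiguousarray(zfull[k - 1 : k - 1 + lout].transpose(1, 0, 2)) + b
    # float64 inputs keep float64 throughout (used by oracle comparisons)
    return z.astype(x.dtype, copy=False), xf


def _conv_backward(dz: np.ndarray, xf: np.ndarray, x_shape, w: np.ndarray):
    """Gradients of the valid cross-correlation; dz (B, Lout, F), x (B, L, C).

    dx is the full convolution of dz with w; dW is the cross-correlation of
    the cached input spectrum with the upstream gradient. Both reuse the
    forward padding so circular wrap-around cannot reach the valid lags.
    """
    from scipy import fft as sfft

    bsz, length, c = x_shape
    f, _, k = w.shape
    pad = sfft.next_fast_len(length + k, real=True)
    dzf = sfft.rfft(dz, n=pad, axis=1)  # (B, Pf, F)
    wf = sfft.rfft(w, n=pad, axis=2)  # (F, C, Pf)
    dxf = dzf.transpose(1, 0, 2) @ wf.transpose(2, 0, 1)  # (Pf, B, C)
    dxfull = sfft.irfft(dxf, n=pad, axis=0)
    dx = np.ascontiguousarray(dxfull[:length].transpose(1, 0, 2)).astype(
        np.float32, copy=False
    )
    dwf = np.conj(dzf).transpose(1, 2, 0) @ xf.transpose(1, 0, 2)  # (Pf, F, C)
    dwfull = sfft.irfft(dwf, n=pad, axis=0)
    dw = dwfull[:k].transpose(1, 2, 0).astype(np.float32, copy=False)
    db = dz.sum(axis=(0, 1))
    return dx, np.ascontiguousarray(dw), db


class ConvNet:
    """Weights plus forward/backward machinery for the fixed architecture."""

    def __init__(self, cfg: ConvNetConfig, input_len: int, seed: int = 0):
        min_len = 3 * (cfg.filter_width - 1) + 1
        if input_len < min_len:
            raise ValueError(f"input length {input_len} < minimum {min_len}")
        self.cfg = cfg
        self.input_len = input_len
        self.conv_out_len = input_len - 3 * (cfg.filter_width - 1)
        self.n_pool = self.conv_out_len // cfg.pool_stride
        if self.n_pool < 1:
            raise ValueError(
                f"input length {input_len} leaves no complete pooling window"
            )
        rng = np.random.default_rng(seed)
        f1, f2, f3 = cfg.conv_filters
        k = cfg.filter_width
        self.params: dict[str, np.ndarray] = {}

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params["w1"] = he((f1, 4, k), 4 * k)
        self.params["b1"] = np.zeros(f1, dtype=np.float32)
        self.params["w2"] = he((f2, f1, k), f1 * k)
        self.params["b2"] = np.zeros(f2, dtype=np.float32)
        self.params["w3"] = he((f3, f2, k), f2 * k)
        self.params["b3"] = np.zeros(f3, dtype=np.float32)
        dense_in = f3 * self.n_pool
        self.params["wd"] = he((dense_in,), dense_in)
        self.params["bd"] = np.zeros(1, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def forward(self, x: np.ndarray, train: bool = False, rng=None, want_cache: bool = False):
        """Forward pass; returns sigmoid probabilities (and a cache if asked).

        Dropout (rate 0.2 after each conv ReLU) is applied only when
        ``train`` is True; inference is deterministic.
        """
        p = self.params
        cfg = self.cfg
        cache: dict = {"x": x}
        # channels-last internally: (B, L, C); float64 input stays float64
        dtype = np.float64 if x.dtype == np.float64 else np.float32
        h = np.ascontiguousarray(x.astype(dtype, copy=False).transpose(0, 2, 1))
        for layer in (1, 2, 3):
            z, pm = _conv_forward(h, p[f"w{layer}"], p[f"b{layer}"])
            a = np.maximum(z, 0)
            if train and cfg.dropout_rate > 0:
                mask = (rng.random(a.shape) >= cfg.dropout_rate).astype(np.float32)
                a = a * mask / (1 - cfg.dropout_rate)
                cache[f"mask{layer}"] = mask
            cache[f"z{layer}"], cache[f"pm{layer}"], cache[f"h{layer}"] = z, pm, h
            cache[f"a{layer}"] = a
            h = a
        n, pw = self.n_pool, cfg.pool_width
        f3 = h.shape[2]
        hp = h[:, : n * pw, :].reshape(h.shape[0], n, pw, f3)
        cache["argmax"] = hp.argmax(axis=2)  # (B, n, F)
        pooled = hp.max(axis=2)
        flat = pooled.reshape(pooled.shape[0], -1)  # (B, n*F), position-major
        logit = flat @ p["wd"] + p["bd"][0]
        cache["flat"], cache["logit"] = flat, logit
        prob = 1.0 / (1.0 + np.exp(-logit))
        return (prob, cache) if want_cache else prob

    def backward(self, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss with d(loss)/d(logit) = ``dlogit``."""
        p = self.params
        cfg = self.cfg
        grads: dict[str, np.ndarray] = {}
        flat = cache["flat"]
        grads["wd"] = dlogit @ flat
        grads["bd"] = np.array([dlogit.sum()], dtype=np.float32)
        dflat = np.outer(dlogit, p["wd"]).astype(np.float32)
        bsz = flat.shape[0]
        f3 = cfg.conv_filters[2]
        n, pw = self.n_pool, cfg.pool_width
        dpooled = dflat.reshape(bsz, n, f3)
        da = np.zeros_like(cache["a3"])
        am = cache["argmax"]  # (B, n, F)
        bi = np.broadcast_to(np.arange(bsz)[:, None, None], am.shape)
        ni = np.broadcast_to(np.arange(n)[None, :, None], am.shape)
        ci = np.broadcast_to(np.arange(f3)[None, None, :], am.shape)
        np.add.at(da, (bi, ni * pw + am, ci), dpooled)
        for layer in (3, 2, 1):
            if f"mask{layer}" in cache:
                da = da * cache[f"mask{layer}"] / (1 - cfg.dropout_rate)
            dz = da * (cache[f"z{layer}"] > 0)
            da, grads[f"w{layer}"], grads[f"b{layer}"] = _conv_backward(
                dz, cache[f"pm{layer}"], cache[f"h{layer}"].shape, p[f"w{layer}"]
            )
        return grads

    def save(self, path) -> None:
        meta = {
            "input_len": self.input_len,
            "conv_filters": list(self.cfg.conv_filters),
            "filter_width": self.cfg.filter_width,
            "dropout_rate": self.cfg.dropout_rate,
            "pool_width": self.cfg.pool_width,
            "pool_stride": self.cfg.pool_stride,
        }
        np.savez(path, config=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "ConvNet":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["config"]))
        cfg = ConvNetConfig(
            conv_filters=tuple(meta["conv_filters"]),
            filter_width=meta["filter_width"],
            dropout_rate=meta["dropout_rate"],
            pool_width=meta["pool_width"],
            pool_stride=meta["pool_stride"],
        )
        model = cls(cfg, meta["input_len"])
        model.params = {k: data[k] for k in model.params}
        return model


def build_convnet(cfg: ConvNetConfig, input_len: int, seed: int = 0) -> ConvNet:
    return ConvNet(cfg, input_len, seed=seed)


def class_weights(labels: np.ndarray) -> dict[int, float]:
    """Each class is weighted by the fraction of peaks in the other class."""
    n = labels.size
    n_pos = int(labels.sum())
    return {1: (n - n_pos) / n, 0: n_pos / n}


def _nesterov_step(params, grads, velocity, lr, mu):
    for k in params:
        v = velocity[k]
        v *= mu
        v -= lr * grads[k]
        params[k] += (mu * v - lr * grads[k]).astype(params[k].dtype)


def predict(model: ConvNet, examples: ExampleSet, batch_size: int = 200):
    """Deterministic per-peak scores: mean of forward and revcomp examples.

    Returns (peak_ids, scores, labels) with one row per peak.
    """
    scores = np.empty(examples.x.shape[0])
    for lo in range(0, examples.x.shape[0], batch_size):
        scores[lo : lo + batch_size] = model.forward(examples.x[lo : lo + batch_size])
    ids, inverse = np.unique(examples.peak_ids, return_inverse=True)
    sums = np.zeros(ids.size)
    counts = np.zeros(ids.size)
    np.add.at(sums, inverse, scores)
    np.add.at(counts, inverse, 1)
    peak_scores = sums / counts
    peak_labels = np.zeros(ids.size, dtype=np.int8)
    peak_labels[inverse] = examples.labels
    return ids, peak_scores, peak_labels


def recall_at_precision(scores, labels, precision_floor: float = 0.8) -> float:
    """Maximum recall over thresholds whose precision >= floor; 0 if none."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both classes")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # drop the synthetic (precision=1, recall=0) endpoint
    ok = precision[:-1] >= precision_floor
    return float(recall[:-1][ok].max()) if np.any(ok) else 0.0


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (ties grouped)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both classes")
    return float(average_precision_score(labels, scores))


def _run_phase(
    model: ConvNet,
    train_set: ExampleSet,
    val_set: ExampleSet,
    tc: TrainConfig,
    weights: dict[int, float],
    rng: np.random.Generator,
    log: list,
    phase: str,
) -> None:
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_metric, best_loss = -np.inf, np.inf
    best_params, stale = model.copy_params(), 0
    n = train_set.x.shape[0]
    w_arr = np.where(train_set.labels == 1, weights[1], weights[0]).astype(np.float32)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo : lo + tc.batch_size]
            xb, yb, wb = train_set.x[idx], train_set.labels[idx], w_arr[idx]
            prob, cache = model.forward(xb, train=True, rng=rng, want_cache=True)
            eps = 1e-7
            loss = -np.mean(
                wb * (yb * np.log(prob + eps) + (1 - yb) * np.log(1 - prob + eps))
            )
            total_loss += loss * idx.size
            dlogit = (wb * (prob - yb) / idx.size).astype(np.float32)
            grads = model.backward(cache, dlogit)
            _nesterov_step(model.params, grads, velocity, tc.learning_rate, tc.momentum)
        _, val_scores, val_labels = predict(model, val_set, tc.batch_size)
        metric = recall_at_precision(val_scores, val_labels, tc.precision_floor)
        log.append(
            {
                "phase": phase,
                "epoch": epoch,
                "loss": total_loss / n,
                "val_recall_at_precision": metric,
                "val_auprc": auprc(val_scores, val_labels),
            }
        )
        epoch_loss = total_loss / n
        if metric > best_metric:
            best_metric, best_loss = metric, epoch_loss
            best_params, stale = model.copy_params(), 0
        else:
            # a tie in the validation metric is not an improvement for early
            # stopping, but the lower-loss weights are the better checkpoint
            if metric == best_metric and epoch_loss < best_loss:
                best_loss, best_params = epoch_loss, model.copy_params()
            stale += 1
            if stale >= tc.patience:
                break
    model.set_params(best_params)


def train(
    model: ConvNet, examples: ExampleSet, split: SplitSpec, tc: TrainConfig
) -> list[dict]:
    """Two-phase training with early stopping; the model ends at the best
    validation weights and the per-epoch log is returned.

    Phase 1 (pretraining) runs from He-normal initialization on the training
    set with the negative peaks down-sampled to the number of positives;
    phase 2 continues from the phase-1 best weights on the full training set
    with class weights set to the fraction of peaks in the other class. Both
    phases stop after ``tc.patience`` consecutive epochs without improvement
    in validation recall at 80% precision.
    """
    rng = np.random.default_rng(tc.seed)
    train_set = examples.for_chroms(split.train_chroms)
    val_set = examples.for_chroms(split.val_chroms)
    for name, subset in (("train", train_set), ("validation", val_set)):
        if subset.x.shape[0] == 0 or subset.labels.min() == subset.labels.max():
            raise ValueError(f"{name} split must contain both classes")
    log: list[dict] = []
    if tc.pretrain:
        pos_ids = np.unique(train_set.peak_ids[train_set.labels == 1])
        neg_ids = np.unique(train_set.peak_ids[train_set.labels == 0])
        k = min(pos_ids.size, neg_ids.size)
        sampled_neg = rng.choice(neg_ids, size=k, replace=False)
        keep = np.isin(train_set.peak_ids, np.concatenate([pos_ids, sampled_neg]))
        balanced = train_set.subset(keep)
        _run_phase(model, balanced, val_set, tc, {0: 0.5, 1: 0.5}, rng, log, "pretrain")
    # class weights are defined over peaks; each peak contributes two examples
    _, first = np.unique(train_set.peak_ids, return_index=True)
    weights = class_weights(train_set.labels[first])
    _run_phase(model, train_set, val_set, tc, weights, rng, log, "main")
    return log
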