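"""Small CNN for subject identification from cycle images.

Architecture (input 134 x 134 x 3): three blocks of [3x3 conv, 32
filters, valid padding, ReLU; 2x2 max-pool], then dense-128 (ReLU) and
dense-n_classes (softmax).  Feature-map widths run 132-66-64-32-30-15,
so the flattened size is 15*15*32 = 7200 and the per-layer parameter
counts are 896, 9248, 9248, 921,728 and 903.  Training uses Adam
(lr 0.001), categorical cross-entropy, batch size 32 and 10 epochs.

The network is implemented directly on NumPy (im2col convolutions,
single-threaded BLAS GEMMs, float32), which keeps a fixed seed bit-
reproducible on CPU.  Evaluation follows stratified k-fold
cross-validation with shuffled repetitions: 5 folds x 10 repetitions =
50 train/eval runs by default, each on a freshly initialized model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold


@dataclass
class CnnConfig:
    input_shape: tuple = (134, 134, 3)
    conv_filters: int = 32
    kernel: int = 3
    n_conv_blocks: int = 3
    dense_units: int = 128
    n_classes: int = 7
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32


@dataclass
class CvPlan:
    """Stratified k-fold cross-validation, repeated with reshuffling."""

    k: int = 5
    repetitions: int = 10
    seed: int = 0

    @property
    def n_runs(self) -> int:
        return self.k * self.repetitions


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

#: reusable large scratch arrays, keyed per (layer, purpose); repeated
#: cross-validation runs would otherwise re-fault hundreds of MB of
#: fresh pages every optimizer step
_BUFFERS: dict = {}


def _buf(key, shape, dtype=np.float32):
    # the batch size is part of the key so remainder batches do not evict
    # the full-batch buffers every epoch
    key = (*key, shape[0], dtype.__name__ if hasattr(dtype, "__name__")
           else str(dtype))
    arr = _BUFFERS.get(key)
    if arr is None or arr.shape != shape:
        arr = np.empty(shape, dtype)
        _BUFFERS[key] = arr
    return arr


class _Conv2D:
    """Valid kxk convolution, NHWC layout.

    Two GEMM strategies, picked by input depth: thin inputs (the image
    layer) go through an im2col buffer, deep inputs use k*k shifted
    strided-view matmuls, which avoids the large patch copies entirely.
    Weights are stored flat as [k*k*c_in, c_out] with (di, dj, c) patch
    order; ``_W4`` is a reshaped view of the same memory.
    """

    def __init__(self, c_in, c_out, k, rng, key=0):
        fan_in, fan_out = k * k * c_in, k * k * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))       # Glorot uniform
        self.W = rng.uniform(-limit, limit, (k * k * c_in, c_out)
                             ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self._im2col = c_in < 8
        self._key = ("conv", key)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    @property
    def _W4(self):
        return self.W.reshape(self.k, self.k, self.c_in, -1)

    def forward(self, x):
        k = self.k
        n, h, w, c = x.shape
        ho, wo = h - k + 1, w - k + 1
        co = self.W.shape[1]
        self._in_shape = x.shape
        y = _buf((*self._key, "y"), (n, ho, wo, co))
        if self._im2col:
            # rows of NHWC data hold (dj, c) patch entries contiguously,
            # so k wide row copies fill the patch matrix
            cols = _buf((*self._key, "cols"), (n, ho, wo, k, k * c))
            xr = x.reshape(n, h, w * c)
            view = sliding_window_view(xr, k * c, axis=2)[:, :, ::c, :]
            for di in range(k):
                cols[:, :, :, di, :] = view[:, di:di + ho]
            self._cols = cols.reshape(n * ho * wo, k * k * c)
            np.matmul(self._cols, self.W, out=y.reshape(-1, co))
            np.add(y, self.b, out=y)
            return y
        self._x = x
        W4 = self._W4
        t = _buf((*self._key, "t"), (n, ho, wo, co))
        y[:] = self.b
        for di in range(k):
            for dj in range(k):
                np.matmul(x[:, di:di + ho, dj:dj + wo, :], W4[di, dj], out=t)
                np.add(y, t, out=y)
        return y

    def backward(self, dy, need_dx=True):
        k = self.k
        n, ho, wo, co = dy.shape
        dyf = dy.reshape(-1, co)
        self.db = dyf.sum(axis=0)
        _, h, w, c = self._in_shape
        if self._im2col:
            self.dW = self._cols.T @ dyf
            if not need_dx:
                return None
            dcols = _buf((*self._key, "dcols"), (n, ho, wo, k, k, c))
            np.matmul(dyf, self.W.T, out=dcols.reshape(-1, k * k * c))
            dx = _buf((*self._key, "dx"), self._in_shape)
            dx.fill(0.0)
            for di in range(k):
                for dj in range(k):
                    dx[:, di:di + ho, dj:dj + wo, :] += dcols[:, :, :, di, dj, :]
            return dx
        x = self._x
        dW4 = np.empty((k, k, c, co), dtype=np.float32)
        prod = _buf((*self._key, "prod"), (n, ho, c, co))
        for di in range(k):
            for dj in range(k):
                xv = x[:, di:di + ho, dj:dj + wo, :]
                np.matmul(xv.swapaxes(2, 3), dy, out=prod)
                dW4[di, dj] = prod.sum(axis=(0, 1))
        self.dW = dW4.reshape(k * k * c, co)
        if not need_dx:
            return None
        W4 = self._W4
        t = _buf((*self._key, "dt"), (n, ho, wo, c))
        dx = _buf((*self._key, "dx"), self._in_shape)
        dx.fill(0.0)
        for di in range(k):
            for dj in range(k):
                np.matmul(dy, W4[di, dj].T, out=t)
                dx[:, di:di + ho, dj:dj + wo, :] += t
        return dx

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReluPool2:
    """Fused ReLU + 2x2 max pooling (stride 2) via slice maxima.

    Equivalent to ReLU followed by window argmax with first-position
    tie-breaking, but in one pass: the output is max(0, window max) and
    gradient flows to the first winning position only when positive.
    """

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def __init__(self, key=0):
        self._key = ("pool", key)

    def forward(self, x):
        self._in_shape = x.shape
        n, h, w, c = x.shape
        oshape = (n, h // 2, w // 2, c)
        s0, s1, s2, s3 = (x[:, i::2, j::2, :] for i, j in self._OFFSETS)
        m01 = _buf((*self._key, "m01"), oshape)
        m23 = _buf((*self._key, "m23"), oshape)
        np.maximum(s0, s1, out=m01)
        np.maximum(s2, s3, out=m23)
        # winner index 0..3 with first-position tie-breaking; 4 marks
        # all-negative windows (ReLU zero, no gradient)
        idx = _buf((*self._key, "idx"), oshape, np.uint8)
        idx2 = _buf((*self._key, "idx2"), oshape, np.uint8)
        lower = _buf((*self._key, "lo"), oshape, np.bool_)
        np.less(s0, s1, out=lower)
        np.copyto(idx, lower, casting="unsafe")            # 0 or 1
        np.less(s2, s3, out=lower)
        np.copyto(idx2, lower, casting="unsafe")
        np.add(idx2, 2, out=idx2)                          # 2 or 3
        np.less(m01, m23, out=lower)
        np.copyto(idx, idx2, where=lower)
        m = _buf((*self._key, "m"), oshape)
        np.maximum(m01, m23, out=m)
        np.less_equal(m, 0, out=lower)
        idx[lower] = 4
        np.maximum(m, 0, out=m)
        self._idx = idx
        return m

    def backward(self, dy):
        dx = _buf((*self._key, "dx"), self._in_shape)
        t = _buf((*self._key, "dt"), dy.shape)
        mask = _buf((*self._key, "bmask"), dy.shape, np.bool_)
        for k, (i, j) in enumerate(self._OFFSETS):
            np.equal(self._idx, k, out=mask)
            np.multiply(dy, mask, out=t)
            dx[:, i::2, j::2, :] = t
        return dx


class _Dense:
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_params(self):
        return self.W.size + self.b.size

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = {}

    def step(self, params_grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for i, (p, g) in enumerate(params_grads):
            m, v = self.state.setdefault(i, (np.zeros_like(p), np.zeros_like(p)))
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class SmallCnn:
    """The fixed conv-conv-conv-dense-dense stack, trained with Adam."""

    def __init__(self, cfg: CnnConfig, seed: int = 0):
        h, w, c = cfg.input_shape
        if (h, w, c) != (134, 134, 3):
            raise ValueError("default architecture requires 134x134x3 input")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1]))
        self.cfg = cfg
        self.convs = []
        c_in = c
        side = h
        for bi in range(cfg.n_conv_blocks):
            self.convs.append(_Conv2D(c_in, cfg.conv_filters, cfg.kernel,
                                      rng, key=bi))
            side = (side - cfg.kernel + 1) // 2
            c_in = cfg.conv_filters
        self.pools = [_ReluPool2(key=bi) for bi in range(cfg.n_conv_blocks)]
        flat = side * side * cfg.conv_filters
        self.fc1 = _Dense(flat, cfg.dense_units, rng)
        self.fc2 = _Dense(cfg.dense_units, cfg.n_classes, rng)
        self._flat = flat

    def layer_param_counts(self) -> list[int]:
        """Trainable-parameter count per parameterized layer, in order."""
        return [l.n_params for l in (*self.convs, self.fc1, self.fc2)]

    def _forward(self, x, train=False):
        a = x
        for conv, pool in zip(self.convs, self.pools):
            a = pool.forward(conv.forward(a))
        a = a.reshape(a.shape[0], -1)
        a = self.fc1.forward(a)
        self._fc1_mask = a > 0
        a *= self._fc1_mask
        return self.fc2.forward(a)

    def _backward(self, dlogits):
        d = self.fc2.backward(dlogits)
        d *= self._fc1_mask
        d = self.fc1.backward(d)
        n = d.shape[0]
        side = int(np.sqrt(self._flat // self.cfg.conv_filters))
        d = d.reshape(n, side, side, self.cfg.conv_filters)
        for i in range(len(self.convs) - 1, -1, -1):
            d = self.pools[i].backward(d)
            d = self.convs[i].backward(d, need_dx=(i > 0))

    def params_grads(self):
        out = []
        for layer in (*self.convs, self.fc1, self.fc2):
            out.extend(layer.params_grads())
        return out

    def fit(self, images, labels, seed: int = 0, verbose: bool = False):
        """Train with softmax cross-entropy; ``labels`` are int class ids."""
        cfg = self.cfg
        x = np.asarray(images, dtype=np.float32)
        y = np.asarray(labels)
        opt = _Adam(cfg.learning_rate)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA7C]))
        n = len(x)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start: start + cfg.batch_size]
                logits = self._forward(x[idx], train=True)
                logits -= logits.max(axis=1, keepdims=True)
                e = np.exp(logits)
                probs = e / e.sum(axis=1, keepdims=True)
                total += -np.log(probs[np.arange(len(idx)), y[idx]] + 1e-12).sum()
                d = probs
                d[np.arange(len(idx)), y[idx]] -= 1.0
                d /= len(idx)
                self._backward(d.astype(np.float32))
                opt.step(self.params_grads())
            if verbose:
                print(f"epoch {epoch + 1}: mean loss {total / n:.4f}")
        return self

    def predict(self, images, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        out = []
        for start in range(0, len(x), batch_size):
            out.append(self._forward(x[start: start + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.array([], dtype=int)


def build_model(cfg: CnnConfig | None = None, seed: int = 0) -> SmallCnn:
    """Construct the (untrained) small CNN."""
    return SmallCnn(cfg or CnnConfig(), seed)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_cv_splits(labels, plan: CvPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """All ``k * repetitions`` stratified (train, test) index pairs.

    Within each repetition the k test folds partition the samples with
    per-fold class ratios within one sample of the global ratio; every
    repetition reshuffles.  Deterministic for a fixed plan seed.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < plan.k:
            raise ValueError(f"class {cls!r} has {cnt} samples, fewer than "
                             f"k={plan.k}")
    rep_seeds = np.random.SeedSequence([int(plan.seed), 0x5F1D]).generate_state(
        plan.repetitions) % (2 ** 31)
    splits = []
    for rep in range(plan.repetitions):
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True,
                              random_state=int(rep_seeds[rep]))
        splits.extend((tr.copy(), te.copy()) for tr, te in skf.split(y, y))
    return splits


def train_and_eval(images, labels, cfg: CnnConfig | None = None,
                   plan: CvPlan | None = None, seed: int = 0,
                   verbose: bool = False) -> list[np.ndarray]:
    """One confusion matrix per cross-validation run (fresh model each).

    ``images`` must already be scaled to [0, 1]; ``labels`` may be
    strings or integers and are encoded in sorted-unique order, which is
    also the confusion-matrix row/column order.
    """
    x = np.asarray(images, dtype=np.float32)
    if x.min() < 0.0 or x.max() > 1.0:
        raise ValueError("images must be scaled to [0, 1]")
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    cfg = cfg or CnnConfig(n_classes=len(classes))
    if cfg.n_classes != len(classes):
        raise ValueError("cfg.n_classes does not match the label set")
    plan = plan or CvPlan(seed=seed)
    cms = []
    for i, (tr, te) in enumerate(make_cv_splits(y, plan)):
        model = SmallCnn(cfg, seed=int(np.random.SeedSequence(
            [int(seed), 0x11, i]).generate_state(1)[0] % (2 ** 31)))
        model.fit(x[tr], y[tr], seed=int(np.random.SeedSequence(
            [int(seed), 0x22, i]).generate_state(1)[0] % (2 ** 31)))
        pred = model.predict(x[te])
        cms.append(_sk_confusion(y[te], pred, labels=np.arange(len(classes))))
        if verbose:
            acc = np.trace(cms[-1]) / cms[-1].sum()
            print(f"run {i + 1}/{plan.n_runs}: accuracy {acc:.4f}")
    return cms
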