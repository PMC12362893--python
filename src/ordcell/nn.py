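"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the operations the message-passing network needs: dense
linear maps, gather/scatter along graph edges (scatter as multiplication by a
constant sparse incidence matrix), layer normalization, dropout, ReLU, and the
loss primitives (masked ordinal binary cross-entropy, softmax cross-entropy,
and an entropic-OT Wasserstein term with an envelope-theorem gradient).

All gradients are checked against central finite differences in the test
suite; do not add an op without a corresponding check.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from . import ot as _ot


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "_prev", "_backward", "name")

    def __init__(self, data, _prev=(), name: str = ""):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self._prev = tuple(_prev)
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the whole graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (3 MP rounds x MLPs)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()
        # break closure reference cycles so array memory is freed promptly
        for t in topo:
            if t._backward is not None:
                t._backward = None
                t._prev = ()
                t.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor{self.shape}{'(' + self.name + ')' if self.name else ''}"


def _acc(t: "Tensor", g: np.ndarray) -> None:
    """Lazily accumulate a gradient contribution (rebinding, never in place).

    Rebinding keeps aliased pass-through gradients (e.g. both parents of an
    ``add``) safe: no closure mutates an array it does not own.
    """
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data + b.data, (a, b))

    def bw():
        _acc(a, _unbroadcast(out.grad, a.data.shape))
        _acc(b, _unbroadcast(out.grad, b.data.shape))

    out._backward = bw
    return out


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data * b.data, (a, b))

    def bw():
        _acc(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _acc(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = bw
    return out


def scale(a, c: float) -> Tensor:
    a = _wrap(a)
    out = Tensor(a.data * c, (a,))

    def bw():
        _acc(a, out.grad * c)

    out._backward = bw
    return out


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data @ b.data, (a, b))

    def bw():
        _acc(a, out.grad @ b.data.T)
        _acc(b, a.data.T @ out.grad)

    out._backward = bw
    return out


def relu(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def bw():
        _acc(a, out.grad * (a.data > 0))

    out._backward = bw
    return out


def exp(a) -> Tensor:
    a = _wrap(a)
    out = Tensor(np.exp(a.data), (a,))

    def bw():
        _acc(a, out.grad * out.data)

    out._backward = bw
    return out


def div(a, b) -> Tensor:
    """Elementwise a / b with broadcasting."""
    a, b = _wrap(a), _wrap(b)
    out = Tensor(a.data / b.data, (a, b))

    def bw():
        _acc(a, _unbroadcast(out.grad / b.data, a.data.shape))
        _acc(b, _unbroadcast(-out.grad * a.data / b.data**2, b.data.shape))

    out._backward = bw
    return out


def concat(tensors: list, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(int(lo), int(hi))
            _acc(t, out.grad[tuple(sl)])

    out._backward = bw
    return out


def gather_rows(a, index: np.ndarray, scatter_t: sparse.spmatrix | None = None) -> Tensor:
    """Row indexing ``a[index]`` with scatter-add on the way back.

    ``scatter_t`` may hold the precomputed (n_rows, len(index)) selection
    transpose; sparse matmul is much faster than ``np.add.at`` for the large
    per-edge gathers, and callers that gather with the same index repeatedly
    (graph batches) build it once.
    """
    a = _wrap(a)
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(a.data[index], (a,))

    if scatter_t is not None:

        def bw():
            _acc(a, scatter_t @ out.grad)

    else:

        def bw():
            tmp = np.zeros_like(a.data)
            np.add.at(tmp, index, out.grad)
            _acc(a, tmp)

    out._backward = bw
    return out


def spmm(S: sparse.spmatrix, a) -> Tensor:
    """Multiply by a *constant* sparse matrix (edge->node aggregation, pooling)."""
    a = _wrap(a)
    S = S.tocsr()
    St = S.T.tocsr()
    out = Tensor(S @ a.data, (a,))

    def bw():
        _acc(a, St @ out.grad)

    out._backward = bw
    return out


def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    a, gamma, beta = _wrap(a), _wrap(gamma), _wrap(beta)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    out = Tensor(gamma.data * xhat + beta.data, (a, gamma, beta))

    def bw():
        g = out.grad
        _acc(gamma, _unbroadcast(g * xhat, gamma.data.shape))
        _acc(beta, _unbroadcast(g, beta.data.shape))
        dxhat = g * gamma.data
        _acc(a, inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ))

    out._backward = bw
    return out


def dropout(a, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    a = _wrap(a)
    if not training or rate <= 0:
        return a
    mask = ((rng.random(a.data.shape) >= rate) / (1.0 - rate)).astype(a.data.dtype)
    return mul(a, Tensor(mask))


# ---------------------------------------------------------------------------
# loss primitives


def ordinal_masked_bce(z, labels: np.ndarray, n_states: int) -> Tensor:
    """Ordinal-regression loss over nested conditional subsets.

    ``z`` holds one logit per cell per threshold j = 1..n_states-1, with
    sigmoid(z[i, j-1]) read as P(y_i > stage_j). Cell i contributes to
    threshold j only if it belongs to the conditional subset S_j (its true
    state index exceeds j-1); within S_j the term is a binary cross-entropy
    against the indicator y_i > stage_j. The sum is normalized by the total
    subset size sum_j |S_j|. Computed with log-sigmoid for stability:
    log(1 - sigmoid(z)) = log(sigmoid(z)) - z = -softplus(z).
    """
    z = _wrap(z)
    y = np.asarray(labels, dtype=np.int64)  # 1-based state indices
    if z.data.ndim != 2 or z.data.shape[1] != n_states - 1:
        raise ValueError(f"logits must be (batch, {n_states - 1})")
    j = np.arange(1, n_states)  # thresholds stage_1 .. stage_{n-1}
    member = (y[:, None] > (j - 1)[None, :]).astype(z.data.dtype)  # cell in S_j
    target = (y[:, None] > j[None, :]).astype(z.data.dtype)  # y > stage_j
    total = member.sum()
    zd = z.data
    log_sig = -np.logaddexp(0.0, -zd)  # log sigmoid(z)
    log_one_minus = -np.logaddexp(0.0, zd)  # log(1 - sigmoid(z))
    if total == 0:
        return Tensor(0.0, (z,))
    val = -(member * (target * log_sig + (1 - target) * log_one_minus)).sum() / total
    out = Tensor(val, (z,))
    p = 1.0 / (1.0 + np.exp(-zd))

    def bw():
        _acc(z, out.grad * member * (p - target) / total)

    out._backward = bw
    return out


def softmax_cross_entropy(logits, labels0: np.ndarray) -> Tensor:
    """Mean cross-entropy against 0-based integer labels (ablation head)."""
    logits = _wrap(logits)
    y = np.asarray(labels0, dtype=np.int64)
    zd = logits.data
    zmax = zd.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(zd - zmax).sum(axis=1, keepdims=True))
    logp = zd - lse
    n = len(y)
    out = Tensor(-logp[np.arange(n), y].mean(), (logits,))
    p = np.exp(logp)

    def bw():
        g = p.copy()
        g[np.arange(n), y] -= 1.0
        _acc(logits, (out.grad * g / n).astype(logits.data.dtype))

    out._backward = bw
    return out


def wasserstein_loss(Q, P: np.ndarray, eps: float = 0.01, n_iter: int = 500) -> Tensor:
    """Entropic-OT 1-Wasserstein distance between rows of Q and rows of P.

    The transport plan is computed by Sinkhorn iteration on the current values
    and treated as a constant in the backward pass (envelope theorem), so the
    gradient with respect to each row q_i is sum_j plan[i, j] * (q_i - p_j) /
    ||q_i - p_j||.
    """
    Q = _wrap(Q)
    P = np.asarray(P, dtype=Q.data.dtype)
    diff = Q.data[:, None, :] - P[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    plan = _ot.sinkhorn_plan(dist, eps=eps, n_iter=n_iter)
    out = Tensor((plan * dist).sum(), (Q,))

    def bw():
        safe = np.maximum(dist, 1e-12)
        g = out.grad * ((plan / safe)[:, :, None] * diff).sum(axis=1)
        _acc(Q, g.astype(Q.data.dtype))

    out._backward = bw
    return out


def wasserstein_loss_grouped(
    Q, P: np.ndarray, group_size: int, eps: float = 0.01, n_iter: int = 500
) -> Tensor:
    """Mean entropic-OT W1 over equal-size row groups of Q vs P.

    Rows are partitioned into consecutive groups of ``group_size`` (one group
    per cell graph in a batch); each group is compared as its own point cloud
    and the per-group distances are averaged. Identical in value to averaging
    :func:`wasserstein_loss` over the groups, but the Sinkhorn iterations run
    batched. The plan is constant in the backward pass (envelope theorem).
    """
    Q = _wrap(Q)
    P = np.asarray(P, dtype=Q.data.dtype)
    total, d = Q.data.shape
    if group_size <= 0 or total == 0:
        return Tensor(0.0, (Q,))
    if total % group_size:
        raise ValueError("rows do not divide into equal groups")
    B = total // group_size
    Qg = Q.data.reshape(B, group_size, d)
    Pg = P.reshape(B, group_size, d)
    diff = Qg[:, :, None, :] - Pg[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    plan = _ot.sinkhorn_plan_batched(dist, eps=eps, n_iter=n_iter)
    out = Tensor((plan * dist).sum(axis=(1, 2)).mean(), (Q,))

    def bw():
        safe = np.maximum(dist, 1e-12)
        g = ((plan / safe)[..., None] * diff).sum(axis=2) / B
        _acc(Q, (out.grad * g).reshape(total, d).astype(Q.data.dtype))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers and optimization


class Linear:
    """Dense affine map with He-scaled Gaussian init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = ""):
        self.W = Tensor(rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)), name=f"{name}.W")
        self.b = Tensor(np.zeros(n_out), name=f"{name}.b")

    def __call__(self, x) -> Tensor:
        return add(matmul(x, self.W), self.b)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class MLP:
    """Perceptron stack with ReLU between layers (linear output)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, name: str = ""):
        self.layers = [
            Linear(a, b, rng, name=f"{name}.{i}") for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]

    def __call__(self, x) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = relu(x)
        return x

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]


class LayerNormModule:
    def __init__(self, dim: int, name: str = ""):
        self.gamma = Tensor(np.ones(dim), name=f"{name}.gamma")
        self.beta = Tensor(np.zeros(dim), name=f"{name}.beta")

    def __call__(self, x) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
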