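"""A compact feed-forward binary classifier in numpy.

Supports one input branch (standard DNN) or several branches processed by
separate subnetworks whose outputs are concatenated into joint layers ending
in a single sigmoid unit — the *bimodal* architecture used to merge gene
expression with clinical covariates.  Training is mini-batch Adam on
class-weighted binary cross-entropy with inverted dropout and early
stopping on an inner validation AUC.  Fully deterministic given the seed
(single-threaded numpy).
"""

from __future__ import annotations

import numpy as np

from .metrics import evaluate_auc


def _relu(x):
    return np.maximum(x, 0.0)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng):
        # He initialisation, suited to ReLU units
        self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self._adam = [np.zeros_like(self.w), np.zeros_like(self.w),
                      np.zeros_like(self.b), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad, l2: float):
        self.dw = self._x.T @ grad + l2 * self.w
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        mw, vw, mb, vb = self._adam
        for m, v, g, p in ((mw, vw, self.dw, self.w),
                           (mb, vb, self.db, self.b)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self):
        return self.w.copy(), self.b.copy()

    def restore(self, state):
        self.w, self.b = state[0].copy(), state[1].copy()


class _Branch:
    """Dense->ReLU(->dropout) stack."""

    def __init__(self, d_in: int, hidden: tuple[int, ...], rng):
        self.layers = []
        for h in hidden:
            self.layers.append(_Dense(d_in, h, rng))
            d_in = h
        self.d_out = d_in

    def forward(self, x, dropout: float, rng, train: bool):
        self._masks = []
        for layer in self.layers:
            x = _relu(layer.forward(x))
            if train and dropout > 0:
                mask = (rng.random(x.shape) >= dropout) / (1 - dropout)
                x = x * mask
            else:
                mask = None
            self._masks.append((x > 0) if mask is None else ((x != 0), mask))
        self._out = x
        return x

    def backward(self, grad, l2: float):
        for layer, mask_info in zip(reversed(self.layers),
                                    reversed(self._masks)):
            if isinstance(mask_info, tuple):
                active, mask = mask_info
                grad = grad * mask * active
            else:
                grad = grad * mask_info
            grad = layer.backward(grad, l2)
        return grad

    def all_layers(self):
        return self.layers


class BimodalMLP:
    """Multi-branch MLP with a single probability output.

    Parameters
    ----------
    branch_hidden:
        One tuple of hidden-layer sizes per input branch, e.g.
        ``[(64, 32), (16, 8)]`` for a gene branch and a clinical branch.
    joint_hidden:
        Hidden sizes of the shared layers after concatenation.
    """

    def __init__(
        self,
        branch_hidden: list[tuple[int, ...]],
        joint_hidden: tuple[int, ...] = (16,),
        dropout: float = 0.3,
        lr: float = 1e-3,
        l2: float = 1e-4,
        epochs: int = 300,
        batch_size: int = 32,
        seed: int = 0,
        val_fraction: float = 0.2,
        patience: int = 30,
        class_weight: bool = True,
    ):
        self.branch_hidden = [tuple(h) for h in branch_hidden]
        self.joint_hidden = tuple(joint_hidden)
        self.dropout = dropout
        self.lr = lr
        self.l2 = l2
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.val_fraction = val_fraction
        self.patience = patience
        self.class_weight = class_weight

    # -- architecture -----------------------------------------------------
    def _build(self, dims: list[int], rng):
        self.branches = [
            _Branch(d, h, rng) for d, h in zip(dims, self.branch_hidden)
        ]
        d = sum(b.d_out for b in self.branches)
        self.joint = _Branch(d, self.joint_hidden, rng)
        self.head = _Dense(self.joint.d_out, 1, rng)

    def _forward(self, xs, rng=None, train=False):
        outs = [
            b.forward(x, self.dropout, rng, train)
            for b, x in zip(self.branches, xs)
        ]
        h = np.concatenate(outs, axis=1)
        h = self.joint.forward(h, self.dropout, rng, train)
        z = self.head.forward(h).ravel()
        return 1.0 / (1.0 + np.exp(-z))

    def _backward(self, dz):
        grad = self.head.backward(dz[:, None], self.l2)
        grad = self.joint.backward(grad, self.l2)
        offset = 0
        for b in self.branches:
            g = grad[:, offset:offset + b.d_out]
            b.backward(g, self.l2)
            offset += b.d_out

    def _all_layers(self):
        layers = []
        for b in self.branches:
            layers.extend(b.all_layers())
        layers.extend(self.joint.all_layers())
        layers.append(self.head)
        return layers

    # -- training ---------------------------------------------------------
    def fit(self, xs: list[np.ndarray], y) -> "BimodalMLP":
        xs = [np.asarray(x, dtype=float) for x in xs]
        y = np.asarray(y, dtype=float).ravel()
        if len(xs) != len(self.branch_hidden):
            raise ValueError(
                f"expected {len(self.branch_hidden)} input branches, "
                f"got {len(xs)}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are constant")
        rng = np.random.default_rng(self.seed)
        self._build([x.shape[1] for x in xs], rng)

        # stratified inner split for early stopping
        idx_tr, idx_val = _stratified_indices(y, self.val_fraction, rng)
        xs_tr = [x[idx_tr] for x in xs]
        xs_val = [x[idx_val] for x in xs]
        y_tr, y_val = y[idx_tr], y[idx_val]

        if self.class_weight:
            w_pos = len(y_tr) / (2.0 * max(y_tr.sum(), 1))
            w_neg = len(y_tr) / (2.0 * max((1 - y_tr).sum(), 1))
        else:
            w_pos = w_neg = 1.0
        weights = np.where(y_tr == 1, w_pos, w_neg)

        n = len(y_tr)
        best_auc, best_state, since_best = -np.inf, None, 0
        t = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                if len(batch) < 2:
                    continue
                xb = [x[batch] for x in xs_tr]
                yb, wb = y_tr[batch], weights[batch]
                p = self._forward(xb, rng=rng, train=True)
                dz = wb * (p - yb) / wb.sum()
                t += 1
                self._backward(dz)
                for layer in self._all_layers():
                    layer.adam_step(self.lr, t)
            val_auc = evaluate_auc(self._forward(xs_val), y_val)
            if val_auc > best_auc + 1e-6:
                best_auc = val_auc
                best_state = [l.state() for l in self._all_layers()]
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            for layer, state in zip(self._all_layers(), best_state):
                layer.restore(state)
        self.validation_auc_ = best_auc
        return self

    def predict_proba(self, xs: list[np.ndarray]) -> np.ndarray:
        xs = [np.asarray(x, dtype=float) for x in xs]
        return self._forward(xs, train=False)


def _stratified_indices(y, fraction: float, rng):
    idx_val = []
    for cls in (0.0, 1.0):
        members = np.flatnonzero(y == cls)
        n_val = max(1, int(round(len(members) * fraction)))
        n_val = min(n_val, len(members) - 1)
        idx_val.extend(rng.choice(members, size=n_val, replace=False))
    idx_val = np.array(sorted(idx_val))
    idx_tr = np.setdiff1d(np.arange(len(y)), idx_val)
    return idx_tr, idx_val
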