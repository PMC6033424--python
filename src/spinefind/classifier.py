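"""Shallow feed-forward spine classifier trained with scaled conjugate
gradient.

Architecture: 221 inputs -> 20 hidden tanh units -> 2 softmax outputs
(spine, non-spine), cross-entropy loss. Inputs are min-max normalized to
[-1, 1] with constants fit on the training split only. Weights and biases
are initialized uniformly in [-1, 1].

Training uses Moller's scaled conjugate gradient (SCG): a conjugate-gradient
method whose step size comes from a one-sided finite-difference estimate of
the Hessian-vector product, damped by a Levenberg-Marquardt scalar that is
raised after a failed step and lowered when the quadratic model fits well.
No line search, no user-tuned learning rate. Early stopping monitors the
validation loss and restores the best-validation weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .calibration_io import CalibratedImage, N_FEATURES

__all__ = [
    "TrainedNetwork",
    "ConfusionReport",
    "init_network",
    "scg_minimize",
    "scg_train",
    "predict",
    "predict_classes",
    "evaluate",
    "save_model",
    "load_model",
    "detect_spines",
]

CLASS_NAMES = ("non_spine", "spine")  # output index 1 = spine


@dataclass
class TrainedNetwork:
    """One-hidden-layer network with portable weights and normalization."""

    W1: np.ndarray                # (n_hidden, n_inputs)
    b1: np.ndarray                # (n_hidden,)
    W2: np.ndarray                # (2, n_hidden)
    b2: np.ndarray                # (2,)
    norm_lo: np.ndarray | None = None   # per-feature min (train split)
    norm_hi: np.ndarray | None = None   # per-feature max (train split)
    history: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def normalize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if self.norm_lo is None:
            return X
        span = self.norm_hi - self.norm_lo
        safe = np.where(span > 0, span, 1.0)
        Xn = 2.0 * (X - self.norm_lo) / safe - 1.0
        return np.where(span > 0, Xn, 0.0)


def init_network(
    seed: int, n_inputs: int = N_FEATURES, n_hidden: int = 20, n_outputs: int = 2
) -> TrainedNetwork:
    """Fresh network with all weights and biases ~ Uniform(-1, 1)."""
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(-1.0, 1.0, size=shape)
    return TrainedNetwork(
        W1=u(n_hidden, n_inputs),
        b1=u(n_hidden),
        W2=u(n_outputs, n_hidden),
        b2=u(n_outputs),
    )


# ---------------------------------------------------------------------------
# forward / backward


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(net: TrainedNetwork, Xn: np.ndarray) -> np.ndarray:
    z1 = np.tanh(Xn @ net.W1.T + net.b1)
    return _softmax(z1 @ net.W2.T + net.b2)


def _pack(net: TrainedNetwork) -> np.ndarray:
    return np.concatenate(
        [net.W1.ravel(), net.b1, net.W2.ravel(), net.b2]
    )


def _unpack(w: np.ndarray, net: TrainedNetwork) -> None:
    h, d = net.W1.shape
    o = net.W2.shape[0]
    i = 0
    net.W1 = w[i : i + h * d].reshape(h, d); i += h * d
    net.b1 = w[i : i + h]; i += h
    net.W2 = w[i : i + o * h].reshape(o, h); i += o * h
    net.b2 = w[i : i + o]


def _loss_grad_factory(
    shapes: tuple[int, int, int], Xn: np.ndarray, Y: np.ndarray
) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
    """Cross-entropy loss and gradient as a function of the packed weights."""
    h, d, o = shapes
    n = len(Xn)

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        i = 0
        W1 = w[i : i + h * d].reshape(h, d); i += h * d
        b1 = w[i : i + h]; i += h
        W2 = w[i : i + o * h].reshape(o, h); i += o * h
        b2 = w[i : i + o]
        A = Xn @ W1.T + b1
        Z1 = np.tanh(A)
        P = _softmax(Z1 @ W2.T + b2)
        loss = -np.mean(np.sum(Y * np.log(np.clip(P, 1e-300, None)), axis=1))
        dlogits = (P - Y) / n
        gW2 = dlogits.T @ Z1
        gb2 = dlogits.sum(axis=0)
        dz1 = (dlogits @ W2) * (1.0 - Z1**2)
        gW1 = dz1.T @ Xn
        gb1 = dz1.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return float(loss), grad

    return fun


# ---------------------------------------------------------------------------
# scaled conjugate gradient (Moller 1993)


def scg_minimize(
    fun: Callable[[np.ndarray], tuple[float, np.ndarray]],
    w0: np.ndarray,
    max_iter: int = 1000,
    grad_tol: float = 1e-6,
    sigma0: float = 5e-5,
    lambda0: float = 5e-7,
    callback: Callable[[int, np.ndarray, float], bool] | None = None,
) -> tuple[np.ndarray, dict]:
    """Minimize ``fun`` (returning loss and gradient) by SCG.

    ``callback(k, w, f)`` runs after every accepted step; returning True
    stops the optimization. Returns the final weights and an info dict with
    the accepted-step loss history and the stop reason.
    """
    w = np.asarray(w0, dtype=np.float64).copy()
    N = len(w)
    f, g = fun(w)
    if not np.isfinite(f):
        raise FloatingPointError("initial loss is not finite")
    r = -g
    p = r.copy()
    lam, lam_bar = float(lambda0), 0.0
    success = True
    history = [f]
    stop = "max_iter"
    delta = 1.0
    k = 0
    while k < max_iter:
        k += 1
        pnorm2 = float(p @ p)
        if pnorm2 == 0.0:
            stop = "zero_direction"
            break
        if success:
            sigma_k = sigma0 / np.sqrt(pnorm2)
            _, g_shift = fun(w + sigma_k * p)
            s = (g_shift - (-r)) / sigma_k
            delta = float(p @ s)
        delta = delta + (lam - lam_bar) * pnorm2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / pnorm2)
            delta = -delta + lam * pnorm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun(w + alpha * p)
        if not np.isfinite(f_new):
            raise FloatingPointError(f"loss became non-finite at iteration {k}")
        comparison = 2.0 * delta * (f - f_new) / mu**2
        if comparison >= 0:  # successful step
            w = w + alpha * p
            f = f_new
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if k % N == 0:
                p = r_new.copy()  # restart along the gradient
            else:
                beta = float((r_new @ r_new - r_new @ r) / mu)
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = 0.25 * lam
            history.append(f)
            if callback is not None and callback(k, w, f):
                stop = "callback"
                break
            if float(np.sqrt(r @ r)) < grad_tol:
                stop = "grad_tol"
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / pnorm2
        if lam > 1e60:
            stop = "no_progress"
            break
    info = {"loss_history": history, "stop_reason": stop, "iterations": k}
    return w, info


# ---------------------------------------------------------------------------
# training / inference


def fit_normalizer(net: TrainedNetwork, X: np.ndarray) -> None:
    net.norm_lo = X.min(axis=0)
    net.norm_hi = X.max(axis=0)


def _onehot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    Y = np.zeros((len(y), n_classes))
    Y[np.arange(len(y)), y] = 1.0
    return Y


def scg_train(
    net: TrainedNetwork,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 1000,
    patience: int = 6,
    grad_tol: float = 1e-6,
) -> TrainedNetwork:
    """Train in place on (X, y) pairs; y uses 1 = spine, 0 = non-spine.

    Normalization constants are fit on the training split only. Training
    stops on ``max_iter``, on the gradient tolerance, or after ``patience``
    consecutive validation-loss increases, restoring the best-validation
    weights.
    """
    Xtr, ytr = train
    fit_normalizer(net, Xtr)
    Xn = net.normalize(Xtr)
    Y = _onehot(np.asarray(ytr, dtype=int))
    shapes = (net.n_hidden, net.n_inputs, net.W2.shape[0])
    fun = _loss_grad_factory(shapes, Xn, Y)
    val_state: dict = {"fails": 0, "best": np.inf, "best_w": None, "losses": []}
    if val is not None:
        Xv = net.normalize(val[0])
        Yv = _onehot(np.asarray(val[1], dtype=int))
        val_fun = _loss_grad_factory(shapes, Xv, Yv)

        def callback(k: int, w: np.ndarray, f: float) -> bool:
            vloss, _ = val_fun(w)
            val_state["losses"].append(vloss)
            if vloss < val_state["best"]:
                val_state["best"] = vloss
                val_state["best_w"] = w.copy()
                val_state["fails"] = 0
            else:
                val_state["fails"] += 1
            return val_state["fails"] >= patience

    else:
        callback = None

    w, info = scg_minimize(
        fun, _pack(net), max_iter=max_iter, grad_tol=grad_tol, callback=callback
    )
    if val is not None and val_state["best_w"] is not None:
        w = val_state["best_w"]
    _unpack(w, net)
    net.history = {
        "train_loss": info["loss_history"],
        "val_loss": val_state["losses"],
        "stop_reason": "early_stopping"
        if info["stop_reason"] == "callback"
        else info["stop_reason"],
        "iterations": info["iterations"],
    }
    return net


def predict(net: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Class probabilities, columns ordered (non_spine, spine)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    return _forward(net, net.normalize(X))


def predict_classes(net: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Hard class labels: 1 = spine, 0 = non-spine (argmax, i.e. p > 0.5)."""
    return predict(net, X).argmax(axis=1)


@dataclass(frozen=True)
class ConfusionReport:
    """2x2 confusion matrix (rows actual [spine, non_spine]) and the derived
    rates in percent: tpr = TP/(TP+FN), precision = TP/(TP+FP)."""

    matrix: np.ndarray
    tpr: float
    fnr: float
    tnr: float
    fpr: float
    precision: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "tpr": self.tpr,
            "fnr": self.fnr,
            "tnr": self.tnr,
            "fpr": self.fpr,
            "precision": self.precision,
            "accuracy": self.accuracy,
        }


def confusion_report(matrix: np.ndarray) -> ConfusionReport:
    """Metrics from a 2x2 matrix with rows actual [spine, non_spine] and
    columns predicted [spine, non_spine]."""
    m = np.asarray(matrix, dtype=float)
    tp, fn = m[0, 0], m[0, 1]
    fp, tn = m[1, 0], m[1, 1]
    pct = lambda a, b: 100.0 * a / b if b > 0 else float("nan")
    return ConfusionReport(
        matrix=np.asarray(matrix, dtype=int),
        tpr=pct(tp, tp + fn),
        fnr=pct(fn, tp + fn),
        tnr=pct(tn, tn + fp),
        fpr=pct(fp, tn + fp),
        precision=pct(tp, tp + fp),
        accuracy=pct(tp + tn, tp + tn + fp + fn),
    )


def evaluate(net: TrainedNetwork, X: np.ndarray, y: np.ndarray) -> ConfusionReport:
    """Confusion matrix and rates of the network on one split (y: 1 = spine)."""
    pred = predict_classes(net, X)
    y = np.asarray(y, dtype=int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    return confusion_report(np.array([[tp, fn], [fp, tn]]))


# ---------------------------------------------------------------------------
# persistence


def save_model(net: TrainedNetwork, path: str | Path) -> None:
    """Write the model as a portable JSON container (weights, normalization,
    architecture, training metadata)."""
    payload = {
        "architecture": {
            "n_inputs": net.n_inputs,
            "n_hidden": net.n_hidden,
            "n_outputs": int(net.W2.shape[0]),
            "hidden_activation": "tanh",
            "output_activation": "softmax",
            "class_names": list(CLASS_NAMES),
        },
        "weights": {
            "W1": net.W1.tolist(),
            "b1": net.b1.tolist(),
            "W2": net.W2.tolist(),
            "b2": net.b2.tolist(),
        },
        "normalization": None
        if net.norm_lo is None
        else {"lo": net.norm_lo.tolist(), "hi": net.norm_hi.tolist()},
        "history": {
            k: v for k, v in net.history.items() if k in ("stop_reason", "iterations")
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedNetwork:
    payload = json.loads(Path(path).read_text())
    wts = payload["weights"]
    net = TrainedNetwork(
        W1=np.array(wts["W1"], dtype=np.float64),
        b1=np.array(wts["b1"], dtype=np.float64),
        W2=np.array(wts["W2"], dtype=np.float64),
        b2=np.array(wts["b2"], dtype=np.float64),
        history=payload.get("history", {}),
    )
    norm = payload.get("normalization")
    if norm is not None:
        net.norm_lo = np.array(norm["lo"], dtype=np.float64)
        net.norm_hi = np.array(norm["hi"], dtype=np.float64)
    return net


# ---------------------------------------------------------------------------
# end-to-end detection


def detect_spines(
    img: CalibratedImage,
    net: TrainedNetwork,
    rng_seed: int = 0,
    threshold: float = 0.5,
    **pipeline_kwargs,
) -> list[tuple[tuple[int, int], float]]:
    """Run the full pipeline on a novel image and keep candidates whose
    spine probability exceeds ``threshold``. Returns (origin, probability)
    pairs in image coordinates."""
    from .features import extract_all

    feats = extract_all(img, rng_seed=rng_seed, **pipeline_kwargs)
    if not feats:
        return []
    X = np.stack([f.combined for f in feats])
    probs = predict(net, X)[:, 1]
    return [
        (f.origin, float(p)) for f, p in zip(feats, probs) if p > threshold
    ]
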