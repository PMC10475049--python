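"""Masked feed-forward classifier compiled from a :class:`LayeredSpec`.

Each hidden interface is a linear transform whose weight matrix is
elementwise-multiplied by the biological connectivity mask, followed by
batch normalization, a tanh activation and dropout.  A fully connected
auxiliary output head sits after every hidden layer so that hidden nodes
carry class-discriminative signal of their own; the model prediction is
the arithmetic mean of the per-head post-activation outputs

    out_final = (1 / H) * sum_h sigma(out_h),

with sigma the logistic function for a single output unit (binary tasks)
and the softmax for multi-class tasks.

The implementation is plain NumPy: parameters live in dictionaries, the
forward pass caches what the analytic backward pass needs, and masked
weight entries are exactly zero at initialization and after every update
(gradients are masked, and the optimizer re-applies the mask).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .pathway_graph import LayeredSpec, count_edges

__all__ = ["BinnModel", "ModelOutputs", "build_model", "sigmoid", "softmax"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


@dataclass
class ModelOutputs:
    """Per-head logits and the averaged post-activation prediction."""

    out_layer: list               # H arrays of shape (n, c_out)
    out_final: np.ndarray         # (n, c_out), entries in [0, 1]
    sigma: str                    # "logistic" or "softmax"

    @property
    def class1_probability(self) -> np.ndarray:
        """Positive-class probability for binary models, (n,)."""
        if self.sigma != "logistic":
            raise ValueError("class1_probability is defined for binary models")
        return self.out_final[:, 0]


class SparsityError(AssertionError):
    pass


class BinnModel:
    """Sparse pathway-constrained classifier with auxiliary heads.

    Parameters are created by :func:`build_model`; use
    :meth:`forward` for predictions and the training routines in
    :mod:`binn.training_eval` for fitting.
    """

    def __init__(self, spec: LayeredSpec, p_drop: float = 0.2, seed: int = 0):
        if not 0.0 <= p_drop < 1.0:
            raise ValueError("p_drop must be in [0, 1)")
        spec.validate()
        self.spec = spec
        self.p_drop = float(p_drop)
        self.seed = int(seed)
        self.n_hidden = spec.n_hidden
        self.c_out = spec.n_classes
        self.sigma = "logistic" if self.c_out == 1 else "softmax"
        self.masks = [m.astype(float) for m in spec.masks[:-1]]
        # the top-hidden -> output interface is realised by the last head
        self.widths = [len(layer) for layer in spec.layers[:-1]]
        self._init_params(np.random.default_rng(seed))
        self.fitted = False

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng):
        self.params: dict = {}
        self.running: dict = {}
        for i in range(1, self.n_hidden + 1):
            fan_in = np.maximum(self.masks[i - 1].sum(axis=0), 1.0)
            W = rng.normal(0.0, 1.0, self.masks[i - 1].shape) / np.sqrt(fan_in)
            self.params[f"W{i}"] = W * self.masks[i - 1]
            self.params[f"b{i}"] = np.zeros(self.widths[i])
            self.params[f"gamma{i}"] = np.ones(self.widths[i])
            self.params[f"beta{i}"] = np.zeros(self.widths[i])
            self.running[f"mean{i}"] = np.zeros(self.widths[i])
            self.running[f"var{i}"] = np.ones(self.widths[i])
            U = rng.normal(0.0, 1.0, (self.widths[i], self.c_out))
            self.params[f"U{i}"] = U / np.sqrt(self.widths[i])
            self.params[f"c{i}"] = np.zeros(self.c_out)

    def parameter_names(self):
        return sorted(self.params)

    def apply_masks(self) -> None:
        for i in range(1, self.n_hidden + 1):
            self.params[f"W{i}"] *= self.masks[i - 1]

    # -- forward ------------------------------------------------------------

    def _check_input(self, X, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.widths[0]:
            raise ValueError(
                f"expected a (n_samples, {self.widths[0]}) matrix in the "
                f"spec's protein order, got shape {X.shape}")
        if feature_names is not None and list(feature_names) != self.spec.proteins:
            raise ValueError("input columns do not match the spec protein order")
        return X

    def forward(self, X, *, training: bool = False, rng=None,
                feature_names=None, cache: dict | None = None) -> ModelOutputs:
        """Run the network; in training mode batch statistics and dropout are
        live, in eval mode running statistics are used and dropout is off."""
        X = self._check_input(X, feature_names)
        a = X
        out_layer = []
        if training and self.p_drop > 0 and rng is None:
            rng = np.random.default_rng(self.seed)
        for i in range(1, self.n_hidden + 1):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if training:
                mean = z.mean(axis=0)
                var = z.var(axis=0)
                self.running[f"mean{i}"] *= 1 - _BN_MOMENTUM
                self.running[f"mean{i}"] += _BN_MOMENTUM * mean
                self.running[f"var{i}"] *= 1 - _BN_MOMENTUM
                self.running[f"var{i}"] += _BN_MOMENTUM * var
            else:
                mean = self.running[f"mean{i}"]
                var = self.running[f"var{i}"]
            invstd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (z - mean) * invstd
            y = self.params[f"gamma{i}"] * xhat + self.params[f"beta{i}"]
            h = np.tanh(y)
            if training and self.p_drop > 0:
                keep = rng.random(h.shape) >= self.p_drop
                a_next = h * keep / (1.0 - self.p_drop)
            else:
                keep = None
                a_next = h
            logits = a_next @ self.params[f"U{i}"] + self.params[f"c{i}"]
            out_layer.append(logits)
            if cache is not None:
                cache[i] = {"a_prev": a, "xhat": xhat, "invstd": invstd,
                            "h": h, "keep": keep, "a": a_next}
            a = a_next
        acts = [self.head_activation(lg) for lg in out_layer]
        out_final = np.mean(acts, axis=0)
        return ModelOutputs(out_layer=out_layer, out_final=out_final,
                            sigma=self.sigma)

    def head_activation(self, logits):
        return sigmoid(logits) if self.sigma == "logistic" else softmax(logits)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, shape (n, 2) for binary and (n, c) otherwise."""
        out = self.forward(X).out_final
        if self.sigma == "logistic":
            return np.column_stack([1.0 - out[:, 0], out[:, 0]])
        return out

    # -- loss and gradients -------------------------------------------------

    def loss_and_grads(self, X, y_onehot, *, training: bool = True, rng=None):
        """Cross-entropy of the averaged prediction, with analytic gradients.

        ``y_onehot`` is (n, 1) of {0,1} for binary models and (n, c) one-hot
        for multi-class.  Returns ``(loss, grads)`` with grads keyed like
        ``params`` (mask already applied to the W gradients).
        """
        cache: dict = {}
        outs = self.forward(X, training=training, rng=rng, cache=cache)
        n = X.shape[0]
        H = self.n_hidden
        eps = 1e-12
        p = np.clip(outs.out_final, eps, 1 - eps)
        if self.sigma == "logistic":
            yv = y_onehot
            loss = -np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))
            dp = (p - yv) / (p * (1 - p)) / (n * p.shape[1])
        else:
            loss = -np.mean(np.sum(y_onehot * np.log(p), axis=1))
            dp = -(y_onehot / p) / n
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training loss is not finite (loss={loss}); the run diverged")

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        # per-head dL/dlogits through sigma and the 1/H averaging
        dlogits = []
        for lg in outs.out_layer:
            if self.sigma == "logistic":
                s = sigmoid(lg)
                dlogits.append(dp * s * (1 - s) / H)
            else:
                s = softmax(lg)
                dot = np.sum(dp * s, axis=1, keepdims=True)
                dlogits.append(s * (dp - dot) / H)

        g_above = None
        for i in range(H, 0, -1):
            c = cache[i]
            dl = dlogits[i - 1]
            grads[f"U{i}"] = c["a"].T @ dl
            grads[f"c{i}"] = dl.sum(axis=0)
            g = dl @ self.params[f"U{i}"].T
            if g_above is not None:
                g = g + g_above
            if c["keep"] is not None:
                g = g * c["keep"] / (1.0 - self.p_drop)
            g = g * (1.0 - c["h"] ** 2)
            grads[f"gamma{i}"] = (g * c["xhat"]).sum(axis=0)
            grads[f"beta{i}"] = g.sum(axis=0)
            if training:
                gxhat = g * self.params[f"gamma{i}"]
                gz = (gxhat - gxhat.mean(axis=0)
                      - c["xhat"] * (gxhat * c["xhat"]).mean(axis=0)) * c["invstd"]
            else:
                gz = g * self.params[f"gamma{i}"] * c["invstd"]
            grads[f"W{i}"] = (c["a_prev"].T @ gz) * self.masks[i - 1]
            grads[f"b{i}"] = gz.sum(axis=0)
            g_above = gz @ self.params[f"W{i}"].T
        return loss, grads

    # -- sparsity -----------------------------------------------------------

    def assert_sparsity(self) -> dict:
        """Verify masked entries are exactly zero; return nonzero counts."""
        expected = count_edges(self.spec)
        report = {"per_interface": [], "head_weights": []}
        for i in range(1, self.n_hidden + 1):
            W = self.params[f"W{i}"]
            off = np.argwhere((self.masks[i - 1] == 0) & (W != 0))
            if off.size:
                entries = ", ".join(f"W{i}[{a},{b}]" for a, b in off[:10])
                raise SparsityError(
                    f"{off.shape[0]} masked weight(s) are nonzero: {entries}")
            report["per_interface"].append(int((W != 0).sum()))
            report["head_weights"].append(int(self.params[f"U{i}"].size))
        report["hidden_total"] = int(sum(report["per_interface"][1:]))
        report["expected_hidden_total"] = expected["hidden_total"]
        return report

    # -- checkpointing ------------------------------------------------------

    def save(self, directory, class_labels=None) -> None:
        os.makedirs(directory, exist_ok=True)
        self.spec.to_json(os.path.join(directory, "spec.json"))
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays.update({f"running_{k}": v for k, v in self.running.items()})
        np.savez(os.path.join(directory, "weights.npz"), **arrays)
        manifest = {"seed": self.seed, "p_drop": self.p_drop,
                    "fitted": self.fitted, "sigma": self.sigma,
                    "class_labels": list(class_labels) if class_labels else None}
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "BinnModel":
        spec = LayeredSpec.from_json(os.path.join(directory, "spec.json"))
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        model = cls(spec, p_drop=manifest["p_drop"], seed=manifest["seed"])
        with np.load(os.path.join(directory, "weights.npz")) as data:
            for k in model.params:
                model.params[k] = data[f"param_{k}"]
            for k in model.running:
                model.running[k] = data[f"running_{k}"]
        model.fitted = bool(manifest.get("fitted", False))
        model.apply_masks()
        return model


def build_model(spec: LayeredSpec, p_drop: float = 0.2, seed: int = 0,
                ) -> BinnModel:
    """Construct a seeded :class:`BinnModel` from a layered spec."""
    return BinnModel(spec, p_drop=p_drop, seed=seed)
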