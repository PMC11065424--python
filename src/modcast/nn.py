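"""A compact feed-forward multi-label network in numpy.

Architecture and training follow the conventions of the classifier this
package trains: fully-connected ReLU hidden layers, a sigmoid output per
label, binary cross-entropy loss averaged over labels, the Adam optimizer,
He-uniform weight initialisation, inverted dropout on every layer except
the output, and L2 weight decay on the hidden-layer weights.  Training
uses an explicit validation set for early stopping on validation loss,
restoring the best weights.

Everything is dense float32 numpy; at the problem sizes this package
targets (hundreds to thousands of genomes, hundreds of KO features) that
is faster than spinning up a GPU framework and is bit-reproducible from a
seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MultiLabelMLP"]


def _he_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


class MultiLabelMLP:
    """Multi-label sigmoid-output MLP trained with BCE + Adam.

    Parameters
    ----------
    n_inputs, n_outputs
        Input feature width and number of labels.
    hidden_layers, hidden_units
        ``hidden_layers=0`` degenerates to a (multi-label) logistic
        regression, which is allowed.
    dropout_rate
        Fraction of activations dropped at the input and each hidden
        layer during training (inverted dropout; never on the output).
    l2_strength
        L2 penalty on hidden/input-side weight matrices (not biases, not
        the output layer).
    """

    def __init__(
        self,
        n_inputs: int,
        n_outputs: int,
        hidden_layers: int = 5,
        hidden_units: int = 2048,
        dropout_rate: float = 0.10,
        l2_strength: float = 1e-4,
        learning_rate: float = 0.001,
        seed: int = 0,
    ):
        if n_inputs < 1 or n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be positive")
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.dropout_rate = float(dropout_rate)
        self.l2_strength = float(l2_strength)
        self.learning_rate = float(learning_rate)
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = [n_inputs] + [hidden_units] * hidden_layers + [n_outputs]
        self.weights = [
            _he_uniform(rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1], dtype=np.float32) for i in range(len(sizes) - 1)]
        self._rng = rng
        self.history: dict = {"train_loss": [], "val_loss": []}

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool):
        """Returns (activations per layer, dropout masks) — masks only in training."""
        acts = [X.astype(np.float32, copy=False)]
        masks = []
        a = acts[0]
        p = self.dropout_rate
        for layer, (W, b) in enumerate(zip(self.weights, self.biases)):
            if train and p > 0:
                mask = (self._rng.random(a.shape) >= p).astype(np.float32) / (1.0 - p)
                a = a * mask
                masks.append(mask)
            z = a @ W + b
            if layer < len(self.weights) - 1:
                a = np.maximum(z, 0.0)
            else:
                a = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
            acts.append(a)
        return acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        acts, _ = self._forward(np.asarray(X, dtype=np.float32), train=False)
        return acts[-1]

    def loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        P = self.predict_proba(X)
        eps = 1e-7
        P = np.clip(P, eps, 1 - eps)
        return float(-np.mean(Y * np.log(P) + (1 - Y) * np.log(1 - P)))

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        X_val: np.ndarray,
        Y_val: np.ndarray,
        epochs: int = 50,
        batch_size: int = 256,
        patience: int = 5,
        verbose: bool = False,
    ) -> "MultiLabelMLP":
        """Mini-batch Adam with early stopping on validation loss.

        Raises ``FloatingPointError`` if the training loss becomes NaN.
        """
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(Y, dtype=np.float32)
        X_val = np.asarray(X_val, dtype=np.float32)
        Y_val = np.asarray(Y_val, dtype=np.float32)
        n = X.shape[0]
        mW = [np.zeros_like(W) for W in self.weights]
        vW = [np.zeros_like(W) for W in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_state = None
        bad_epochs = 0
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], Y[idx]
                acts, masks = self._forward(xb, train=True)
                P = np.clip(acts[-1], 1e-7, 1 - 1e-7)
                loss = -np.mean(yb * np.log(P) + (1 - yb) * np.log(1 - P))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training loss became non-finite at epoch {epoch}"
                    )
                epoch_loss += float(loss)
                n_batches += 1
                # backward: BCE+sigmoid gives delta = (p - y)/ (B*L)
                B = xb.shape[0]
                delta = (acts[-1] - yb) / (B * self.n_outputs)
                t += 1
                grads_W = [None] * len(self.weights)
                grads_b = [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[layer]
                    if masks:
                        a_prev = a_prev * masks[layer]
                    gW = a_prev.T @ delta
                    if self.l2_strength and layer < len(self.weights) - 1:
                        gW += 2.0 * self.l2_strength * self.weights[layer]
                    grads_W[layer] = gW
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        if masks:
                            # gradient flows through the (inverted) dropout mask
                            delta = delta * masks[layer]
                        delta = delta * (acts[layer] > 0)
                for layer in range(len(self.weights)):
                    mW[layer] = beta1 * mW[layer] + (1 - beta1) * grads_W[layer]
                    vW[layer] = beta2 * vW[layer] + (1 - beta2) * grads_W[layer] ** 2
                    mb[layer] = beta1 * mb[layer] + (1 - beta1) * grads_b[layer]
                    vb[layer] = beta2 * vb[layer] + (1 - beta2) * grads_b[layer] ** 2
                    mhW = mW[layer] / (1 - beta1**t)
                    vhW = vW[layer] / (1 - beta2**t)
                    mhb = mb[layer] / (1 - beta1**t)
                    vhb = vb[layer] / (1 - beta2**t)
                    self.weights[layer] -= (
                        self.learning_rate * mhW / (np.sqrt(vhW) + eps)
                    ).astype(np.float32)
                    self.biases[layer] -= (
                        self.learning_rate * mhb / (np.sqrt(vhb) + eps)
                    ).astype(np.float32)
            val_loss = self.loss(X_val, Y_val)
            self.history["train_loss"].append(epoch_loss / max(n_batches, 1))
            self.history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch}: train {epoch_loss / max(n_batches, 1):.4f} val {val_loss:.4f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = (
                    [W.copy() for W in self.weights],
                    [b.copy() for b in self.biases],
                )
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        return self

    # -- (de)serialisation -------------------------------------------------

    def get_state(self) -> dict:
        state = {
            "n_inputs": self.n_inputs,
            "n_outputs": self.n_outputs,
            "hidden_layers": self.hidden_layers,
            "hidden_units": self.hidden_units,
            "dropout_rate": self.dropout_rate,
            "l2_strength": self.l2_strength,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        return {"meta": state, "arrays": arrays}

    @classmethod
    def from_state(cls, meta: dict, arrays: dict) -> "MultiLabelMLP":
        model = cls(**meta)
        model.weights = [
            np.asarray(arrays[f"W{i}"], dtype=np.float32)
            for i in range(len(model.weights))
        ]
        model.biases = [
            np.asarray(arrays[f"b{i}"], dtype=np.float32)
            for i in range(len(model.biases))
        ]
        return model
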