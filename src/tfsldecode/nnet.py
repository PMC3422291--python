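"""Small feedforward network trained by Levenberg-Marquardt least squares.

The decoder is a two-layer perceptron — tan-sigmoid hidden layer (16 units
by default), linear output layer — trained to minimise the mean squared
error between its outputs and one-hot targets.  Training uses the
Levenberg-Marquardt update: with residual vector ``r`` and Jacobian ``J``,
each step solves ``(J'J + lambda I) delta = -J'r``; an accepted step (MSE
decreased) divides the damping ``lambda`` by 10, a rejected one multiplies
it by 10.  Training stops at the MSE goal, the epoch budget, damping
overflow, or (with a validation set) after six consecutive validation-MSE
increases, restoring the best-validation weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["ANNConfig", "LMNetClassifier", "train", "predict"]


@dataclass(frozen=True)
class ANNConfig:
    """Decoder hyper-parameters.

    ``n_outputs=None`` sizes the output layer to the number of classes; the
    study-faithful alternative is a fixed width of 4 with surplus units
    trained toward zero.
    """

    n_hidden: int = 16
    n_outputs: int | None = None
    max_epochs: int = 100
    mse_goal: float = 1e-5
    standardize: bool = True
    lambda_init: float = 1e-3
    lambda_max: float = 1e10
    val_patience: int = 6

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.mse_goal <= 0:
            raise ValueError("mse_goal must be positive")

    def make_classifier(self, random_state=None) -> "LMNetClassifier":
        return LMNetClassifier(
            n_hidden=self.n_hidden, n_outputs=self.n_outputs,
            max_epochs=self.max_epochs, mse_goal=self.mse_goal,
            standardize=self.standardize, lambda_init=self.lambda_init,
            lambda_max=self.lambda_max, val_patience=self.val_patience,
            random_state=random_state)


class LMNetClassifier(ClassifierMixin, BaseEstimator):
    """Two-layer tanh/linear network with Levenberg-Marquardt training.

    Parameters mirror :class:`ANNConfig`.  Inputs are z-scored with
    training-set statistics (stored on the model) unless ``standardize`` is
    False.  ``fit`` accepts an optional ``validation_data=(X_val, y_val)``
    keyword for early stopping.  Prediction takes the argmax over the class
    output units; exact ties resolve to the first class.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    coef_hidden_, intercept_hidden_, coef_output_, intercept_output_ :
        Weight matrices and biases of the two layers.
    training_trace_ : ndarray
        Training MSE after each accepted epoch (non-increasing).
    validation_trace_ : ndarray
        Validation MSE per accepted epoch (empty without validation data).
    """

    def __init__(self, n_hidden: int = 16, n_outputs: int | None = None,
                 max_epochs: int = 100, mse_goal: float = 1e-5,
                 standardize: bool = True, lambda_init: float = 1e-3,
                 lambda_max: float = 1e10, val_patience: int = 6,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.n_outputs = n_outputs
        self.max_epochs = max_epochs
        self.mse_goal = mse_goal
        self.standardize = standardize
        self.lambda_init = lambda_init
        self.lambda_max = lambda_max
        self.val_patience = val_patience
        self.random_state = random_state

    # -- internals --------------------------------------------------------

    def _forward(self, Xs: np.ndarray, theta: dict[str, np.ndarray]):
        H = np.tanh(Xs @ theta["W1"].T + theta["b1"])
        Y = H @ theta["W2"].T + theta["b2"]
        return H, Y

    def _jacobian(self, Xs: np.ndarray, H: np.ndarray,
                  theta: dict[str, np.ndarray]) -> np.ndarray:
        """Jacobian of the flattened residuals w.r.t. the packed weights."""
        n, d = Xs.shape
        h, o = self.n_hidden, theta["W2"].shape[0]
        G = (1.0 - H ** 2)                                   # (n, h)
        # residual row order: sample-major, output-minor
        J = np.zeros((n * o, h * d + h + o * h + o))
        WG = np.einsum("oj,nj->noj", theta["W2"], G)          # (n, o, h)
        dW1 = np.einsum("noj,nk->nojk", WG, Xs).reshape(n * o, h * d)
        J[:, :h * d] = dW1
        J[:, h * d:h * d + h] = WG.reshape(n * o, h)
        eye = np.eye(o)
        dW2 = np.einsum("op,nj->nopj", eye, H).reshape(n * o, o * h)
        J[:, h * d + h:h * d + h + o * h] = dW2
        J[:, h * d + h + o * h:] = np.tile(eye, (n, 1))
        return J

    @staticmethod
    def _pack(theta):
        return np.concatenate([theta["W1"].ravel(), theta["b1"],
                               theta["W2"].ravel(), theta["b2"]])

    def _unpack(self, vec, d, o):
        h = self.n_hidden
        i = 0
        W1 = vec[i:i + h * d].reshape(h, d); i += h * d
        b1 = vec[i:i + h]; i += h
        W2 = vec[i:i + o * h].reshape(o, h); i += o * h
        b2 = vec[i:]
        return {"W1": W1, "b1": b1, "W2": W2, "b2": b2}

    def _targets(self, y: np.ndarray, o: int) -> np.ndarray:
        T = np.zeros((len(y), o))
        for i, cls in enumerate(self.classes_):
            T[y == cls, i] = 1.0
        return T

    def _standardized(self, X: np.ndarray) -> np.ndarray:
        if not self.standardize:
            return X
        return (X - self.mean_) / self.scale_

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, validation_data=None):
        X, y = validate_data(self, X, y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        o = self.n_outputs or len(self.classes_)
        if o < len(self.classes_):
            raise ValueError(f"{o} output units cannot code "
                             f"{len(self.classes_)} classes")
        n, d = X.shape

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        Xs = self._standardized(X)
        T = self._targets(y, o)

        rng = np.random.default_rng(self.random_state)
        theta = {
            "W1": rng.uniform(-1, 1, (self.n_hidden, d)) / np.sqrt(d),
            "b1": rng.uniform(-1, 1, self.n_hidden) / np.sqrt(d),
            "W2": (rng.uniform(-1, 1, (o, self.n_hidden))
                   / np.sqrt(self.n_hidden)),
            "b2": rng.uniform(-1, 1, o) / np.sqrt(self.n_hidden),
        }

        if validation_data is not None:
            X_val, y_val = validation_data
            X_val = np.asarray(X_val, dtype=np.float64)
            Xs_val = self._standardized(X_val)
            T_val = self._targets(np.asarray(y_val), o)
        else:
            Xs_val = T_val = None

        def mse_of(th, Xq, Tq):
            _, Y = self._forward(Xq, th)
            return float(np.mean((Y - Tq) ** 2))

        lam = self.lambda_init
        trace, val_trace = [], []
        H, Y = self._forward(Xs, theta)
        mse = float(np.mean((Y - T) ** 2))
        best_val, best_theta, val_fails = np.inf, None, 0

        epoch = 0
        while epoch < self.max_epochs and mse > self.mse_goal:
            r = (Y - T).ravel()
            J = self._jacobian(Xs, H, theta)
            JtJ = J.T @ J
            g = J.T @ r
            if np.max(np.abs(g)) < 1e-12:
                break
            accepted = False
            while lam <= self.lambda_max:
                A = JtJ + lam * np.eye(JtJ.shape[0])
                try:
                    delta = cho_solve(cho_factor(A), -g)
                except LinAlgError:
                    lam *= 10.0
                    continue
                cand = self._unpack(self._pack(theta) + delta, d, o)
                cand_mse = mse_of(cand, Xs, T)
                if cand_mse < mse:
                    theta, mse = cand, cand_mse
                    lam = max(lam / 10.0, 1e-20)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted:
                break
            epoch += 1
            trace.append(mse)
            H, Y = self._forward(Xs, theta)
            if Xs_val is not None:
                val_mse = mse_of(theta, Xs_val, T_val)
                val_trace.append(val_mse)
                if val_mse < best_val:
                    best_val, best_theta = val_mse, {
                        k: v.copy() for k, v in theta.items()}
                    val_fails = 0
                else:
                    val_fails += 1
                    if val_fails >= self.val_patience:
                        break

        if best_theta is not None:
            theta = best_theta
        self.theta_ = theta
        self.coef_hidden_ = theta["W1"]
        self.intercept_hidden_ = theta["b1"]
        self.coef_output_ = theta["W2"]
        self.intercept_output_ = theta["b2"]
        self.training_trace_ = np.asarray(trace)
        self.validation_trace_ = np.asarray(val_trace)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        _, Y = self._forward(self._standardized(X), self.theta_)
        return Y

    def predict(self, X):
        Y = self.decision_function(X)
        # argmax over the class units only; ties resolve to the first class
        return self.classes_[np.argmax(Y[:, :len(self.classes_)], axis=1)]


def train(features: np.ndarray, labels: np.ndarray,
          config: ANNConfig = ANNConfig(), random_state: int | None = None,
          validation_data=None) -> LMNetClassifier:
    """Fit a decoder; thin wrapper over :class:`LMNetClassifier`."""
    clf = config.make_classifier(random_state)
    return clf.fit(features, labels, validation_data=validation_data)


def predict(model: LMNetClassifier, features: np.ndarray) -> np.ndarray:
    return model.predict(features)
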