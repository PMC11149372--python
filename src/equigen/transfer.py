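"""Cross-ancestry transfer learning: DNN fine-tuning and a linear offset model.

Two adaptation routes from a source-population (EUR) model to a target
data-disadvantaged population:

* **fine_tune_dnn** — supervised fine-tuning: continue mini-batch SGD from
  the pretrained weights on the target training data, all layers trainable,
  same optimizer configuration, early stopping on the target validation
  split. The learning-rate decay schedule carries over from pretraining
  (refitting a compiled model keeps the optimizer's iteration counter), so
  adaptation proceeds at the already-decayed step size rather than blasting
  the pretrained representation with the initial one. The pretrained model
  object is never modified.

* **fit_linear_transfer** — an adapted linear polygenic transfer model. The
  target-population effect of SNP j is decomposed as beta_j^pre + tau_j
  (and gamma_k^pre + delta_k for clinical covariates); the adjustments
  (tau, delta) are estimated by L2-penalized logistic regression on target
  data with the pretrained linear predictor entering as a fixed offset, so
  the penalty shrinks the fit toward the source model (naive transfer) and
  a zero penalty recovers an unconstrained target refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from .predictors import DNNConfig, TrainedPredictor, _sigmoid, train_dnn

#: penalty grid searched on the target validation split
DEFAULT_PENALTY_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class LinearTransferModel:
    """Pretrained effects plus fitted target-population adjustments."""

    beta_pre: np.ndarray
    tau: np.ndarray
    gamma_pre: np.ndarray = field(default_factory=lambda: np.zeros(0))
    delta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    intercept_pre: float = 0.0
    intercept_adj: float = 0.0
    penalty: float = 0.0

    @property
    def beta(self) -> np.ndarray:
        return self.beta_pre + self.tau

    @property
    def gamma(self) -> np.ndarray:
        return self.gamma_pre + self.delta

    def linear_predictor(self, G: np.ndarray, C: np.ndarray | None = None) -> np.ndarray:
        z = G @ self.beta + self.intercept_pre + self.intercept_adj
        if self.gamma.size:
            if C is None:
                raise ValueError("model has clinical terms but no C supplied")
            z = z + C @ self.gamma
        return z

    def predict(self, G: np.ndarray, C: np.ndarray | None = None) -> np.ndarray:
        return _sigmoid(self.linear_predictor(G, C))

    def as_predictor(self) -> TrainedPredictor:
        """View as a TrainedPredictor over the concatenated [G, C] features."""
        coef = np.concatenate([self.beta, self.gamma])
        return TrainedPredictor(
            kind="LR",
            parameters={"coef": coef, "intercept": self.intercept_pre + self.intercept_adj},
            n_features=coef.size,
        )


def fine_tune_dnn(
    pretrained: TrainedPredictor,
    X_target_train: np.ndarray,
    y_target_train: np.ndarray,
    X_target_val: np.ndarray,
    y_target_val: np.ndarray,
    config: DNNConfig | None = None,
) -> TrainedPredictor:
    """Continue training the pretrained net on target-domain data.

    All layers are updated; hyperparameters default to the pretraining
    configuration. Returns a new model; ``pretrained`` is left untouched.
    """
    if pretrained.kind != "DNN":
        raise ValueError("fine_tune_dnn requires a DNN pretrained model")
    if X_target_train.shape[1] != pretrained.n_features:
        raise ValueError("target feature schema does not match pretrained model")
    config = config or pretrained.history.get("config") or DNNConfig()
    if config.max_epochs == 0:
        return TrainedPredictor(
            kind="DNN",
            parameters={k: v.copy() for k, v in pretrained.parameters.items()},
            history={"fine_tuned": True, "epochs": 0},
            n_features=pretrained.n_features,
        )
    model = train_dnn(
        X_target_train,
        y_target_train,
        X_target_val,
        y_target_val,
        config=config,
        init_params=pretrained.parameters,
        step_offset=int(pretrained.history.get("steps", 0)),
    )
    model.history["fine_tuned"] = True
    return model


def _fit_offset_logistic(
    Z: np.ndarray, y: np.ndarray, offset: np.ndarray, penalty: float
) -> np.ndarray:
    """Minimize sum log-loss(offset + Z@w) + penalty/2 * ||w[1:]||^2.

    w[0] is an unpenalized intercept adjustment. Solved by L-BFGS with the
    analytic gradient; the objective is convex so the optimum is unique for
    penalty > 0.
    """
    Z1 = np.column_stack([np.ones(len(y)), Z])

    def fg(w):
        z = offset + Z1 @ w
        p = _sigmoid(z)
        # stable sum log-loss: log(1+e^z) - y*z
        ll = np.logaddexp(0.0, z) - y * z
        pen = 0.5 * penalty * (w[1:] @ w[1:])
        grad = Z1.T @ (p - y)
        grad[1:] += penalty * w[1:]
        return float(ll.sum() + pen), grad

    res = minimize(fg, np.zeros(Z1.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    return res.x


def fit_linear_transfer(
    beta_pre: np.ndarray,
    gamma_pre: np.ndarray | None,
    X_target_train: np.ndarray,
    y_target_train: np.ndarray,
    penalty: float | None = None,
    intercept_pre: float = 0.0,
    n_clinical: int = 0,
    X_target_val: np.ndarray | None = None,
    y_target_val: np.ndarray | None = None,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
) -> LinearTransferModel:
    """Estimate (tau, delta) on the target data around the pretrained effects.

    Feature columns are ordered [SNPs..., clinical...] with ``n_clinical``
    trailing clinical columns. If ``penalty`` is None, it is chosen from
    ``penalty_grid`` by AUROC on the target validation split (required in
    that case). ``penalty = inf`` gives tau = delta = 0, i.e. naive transfer.
    """
    beta_pre = np.asarray(beta_pre, dtype=float)
    gamma_pre = np.zeros(n_clinical) if gamma_pre is None else np.asarray(gamma_pre, float)
    X = np.asarray(X_target_train, dtype=float)
    y = np.asarray(y_target_train, dtype=float)
    m = beta_pre.size
    if X.shape[1] != m + gamma_pre.size:
        raise ValueError("target feature count does not match beta_pre/gamma_pre")
    pre = np.concatenate([beta_pre, gamma_pre])
    offset = X @ pre + intercept_pre

    def build(pen: float) -> LinearTransferModel:
        if np.isinf(pen):
            w = np.zeros(X.shape[1] + 1)
        else:
            w = _fit_offset_logistic(X, y, offset, pen)
        return LinearTransferModel(
            beta_pre=beta_pre,
            tau=w[1 : m + 1],
            gamma_pre=gamma_pre,
            delta=w[m + 1 :],
            intercept_pre=intercept_pre,
            intercept_adj=float(w[0]),
            penalty=pen,
        )

    if penalty is not None:
        return build(float(penalty))
    if X_target_val is None or y_target_val is None:
        raise ValueError("penalty=None requires a target validation split")
    best, best_auc = None, -np.inf
    for pen in penalty_grid:
        model = build(pen)
        auc = roc_auc_score(y_target_val, model.predict(np.asarray(X_target_val, float)[:, :m],
                                                        np.asarray(X_target_val, float)[:, m:]
                                                        if gamma_pre.size else None))
        if auc > best_auc:
            best, best_auc = model, auc
    return best
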