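"""Neighborhood-regularized logistic matrix factorization.

The model places each cell line i and drug j in a shared L-dimensional
latent space, with additive bias terms absorbing global responsiveness:

    p_ij = sigma(u_i . v_j + beta_c[i] + beta_d[j])

and is fitted by minimizing a weighted Bernoulli negative log-likelihood
over the binary sensitivity matrix Q plus Gaussian (ridge) priors on U and
V and graph penalties tr(U^T H_c U), tr(V^T H_d V) that pull the latent
vectors of k-NN-similar cell lines (drugs) together:

    J = sum_ij [(1 + r q_ij - q_ij) log(1 + e^{z_ij}) - r q_ij z_ij]
        + 1/2 tr[U^T (lambda_c I + alpha H_c) U]
        + 1/2 tr[V^T (lambda_d I + beta H_d) V]

with z_ij the linear predictor.  r >= 1 up-weights observed sensitive
pairs; with r = 1 (the default — both classes are equally trustworthy
here) the data term is the standard Bernoulli deviance.

Training is alternating AdaGrad: each epoch first updates (V, beta_d)
with (U, beta_c) fixed, then (U, beta_c) with (V, beta_d) fixed, each
parameter stepping by rate / sqrt(accumulated squared gradient + eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit


@dataclass
class LMFHyperparams:
    """Model and training configuration.

    Defaults are the values tuned on the GDSC cohort (555 cell lines x 98
    drugs): L=95, k=20, t=20, lambda_c=lambda_d=0.6, alpha=0.5, beta=0.1,
    similarity weights (1, 1, 1, 3), probability threshold 0.6.  For the
    CCLE-sized cohort the tuned latent dimension is L=23.  AdaGrad settings
    (rate, epochs, eps) are implementation defaults chosen so training
    converges on all bundled fixtures.
    """

    L: int = 95
    k: int = 20
    t: int = 20
    lambda_c: float = 0.6
    lambda_d: float = 0.6
    alpha: float = 0.5
    beta: float = 0.1
    r: float = 1.0
    w_exp: float = 1.0
    w_cnv: float = 1.0
    w_mut: float = 1.0
    w_ic50: float = 3.0
    threshold: float = 0.6
    adagrad_rate: float = 0.1
    adagrad_eps: float = 1e-8
    n_iters: int = 300
    project_biases: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        for name in ("lambda_c", "lambda_d", "alpha", "beta",
                     "w_exp", "w_cnv", "w_mut", "w_ic50"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def similarity_weights(self) -> tuple[float, float, float, float]:
        return (self.w_exp, self.w_cnv, self.w_mut, self.w_ic50)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentModel:
    """Fitted latent vectors and biases."""

    U: np.ndarray
    V: np.ndarray
    bias_c: np.ndarray
    bias_d: np.ndarray

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.V.shape[0]

    @property
    def L(self) -> int:
        return self.U.shape[1]

    def linear_predictor_matrix(self) -> np.ndarray:
        """z_ij = u_i . v_j + beta_c[i] + beta_d[j] for all pairs."""
        return self.U @ self.V.T + self.bias_c[:, None] + self.bias_d[None, :]

    def probability_matrix(self) -> np.ndarray:
        # clipped into the open interval so saturated predictors never
        # produce a degenerate 0/1 probability
        return np.clip(expit(self.linear_predictor_matrix()), 1e-12, 1 - 1e-12)

    def copy(self) -> "LatentModel":
        return LatentModel(
            self.U.copy(), self.V.copy(), self.bias_c.copy(), self.bias_d.copy()
        )


@dataclass
class GradientSet:
    dU: np.ndarray
    dV: np.ndarray
    dbias_c: np.ndarray
    dbias_d: np.ndarray


def init_model(n: int, m: int, L: int, seed: int = 0) -> LatentModel:
    """Draw U, V i.i.d. Normal(0, 1/L) and zero biases.

    The 1/L variance keeps initial linear predictors O(1) for any latent
    dimension.
    """
    if min(n, m, L) < 1:
        raise ValueError("n, m, L must all be >= 1")
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(L)
    return LatentModel(
        U=rng.normal(0.0, scale, (n, L)),
        V=rng.normal(0.0, scale, (m, L)),
        bias_c=np.zeros(n),
        bias_d=np.zeros(m),
    )


def linear_predictor(model: LatentModel, i: int, j: int) -> float:
    return float(model.U[i] @ model.V[j] + model.bias_c[i] + model.bias_d[j])


def probability(model: LatentModel, i: int, j: int) -> float:
    """Sensitivity probability via an overflow-safe logistic, in (0, 1)."""
    return float(np.clip(expit(linear_predictor(model, i, j)), 1e-12, 1 - 1e-12))


def _data_weight(q: np.ndarray, p: np.ndarray, r: float) -> np.ndarray:
    """d(data term)/dz: (1 + r q - q) sigma(z) - r q."""
    return (1.0 + r * q - q) * p - r * q


def objective(
    model: LatentModel,
    q: np.ndarray,
    hc: np.ndarray | None,
    hd: np.ndarray | None,
    hp: LMFHyperparams,
    mask: np.ndarray | None = None,
) -> float:
    """Regularized negative log-posterior J (constant terms dropped).

    ``mask`` (0/1, same shape as ``q``) excludes entries from the data term,
    e.g. to hold out observations for model assessment.
    """
    z = model.linear_predictor_matrix()
    r = hp.r
    per_entry = (1.0 + r * q - q) * np.logaddexp(0.0, z) - r * q * z
    if mask is not None:
        per_entry = per_entry * mask
    data = np.sum(per_entry)
    reg = 0.5 * hp.lambda_c * np.sum(model.U**2) + 0.5 * hp.lambda_d * np.sum(model.V**2)
    if hc is not None and hp.alpha:
        reg += 0.5 * hp.alpha * float(np.trace(model.U.T @ hc @ model.U))
    if hd is not None and hp.beta:
        reg += 0.5 * hp.beta * float(np.trace(model.V.T @ hd @ model.V))
    total = float(data + reg)
    if not np.isfinite(total):
        bad = np.argwhere(~np.isfinite(z))
        where = tuple(bad[0]) if bad.size else "regularizer"
        raise FloatingPointError(f"non-finite objective at entry {where}")
    return total


def gradients(
    model: LatentModel,
    q: np.ndarray,
    hc: np.ndarray | None,
    hd: np.ndarray | None,
    hp: LMFHyperparams,
    mask: np.ndarray | None = None,
) -> GradientSet:
    """Exact gradient of :func:`objective`.

    The latent regularization contributes (lambda_c I + alpha H_c) U — a
    full matrix-row product, the true gradient of the quadratic penalty.
    Bias gradients carry no regularization.
    """
    z = model.linear_predictor_matrix()
    w = _data_weight(q, expit(z), hp.r)
    if mask is not None:
        w = w * mask
    du = w @ model.V + hp.lambda_c * model.U
    dv = w.T @ model.U + hp.lambda_d * model.V
    if hc is not None and hp.alpha:
        du += hp.alpha * (hc @ model.U)
    if hd is not None and hp.beta:
        dv += hp.beta * (hd @ model.V)
    return GradientSet(dU=du, dV=dv, dbias_c=w.sum(axis=1), dbias_d=w.sum(axis=0))


def save_model(model: LatentModel, path, hp: LMFHyperparams | None = None,
               trajectory: list[float] | None = None) -> None:
    """Persist a model (and optionally its config and objective trace) as .npz."""
    import json

    np.savez_compressed(
        path,
        U=model.U,
        V=model.V,
        bias_c=model.bias_c,
        bias_d=model.bias_d,
        trajectory=np.asarray(trajectory if trajectory is not None else []),
        hyperparams=np.array(json.dumps(hp.to_dict() if hp else {})),
    )


def load_model(path) -> tuple[LatentModel, LMFHyperparams | None, list[float]]:
    import json

    with np.load(path, allow_pickle=False) as z:
        model = LatentModel(z["U"], z["V"], z["bias_c"], z["bias_d"])
        hp_dict = json.loads(str(z["hyperparams"]))
        trajectory = list(z["trajectory"])
    return model, (LMFHyperparams(**hp_dict) if hp_dict else None), trajectory


def fit(
    q: np.ndarray,
    hc: np.ndarray | None,
    hd: np.ndarray | None,
    hp: LMFHyperparams,
    init: LatentModel | None = None,
    mask: np.ndarray | None = None,
) -> tuple[LatentModel, list[float]]:
    """Train by alternating AdaGrad.

    Returns the fitted model and the objective trajectory, whose first
    entry is the objective at initialization and which then records one
    value per epoch.  Fully reproducible under ``hp.seed``.
    """
    n, m = q.shape
    model = init.copy() if init is not None else init_model(n, m, hp.L, hp.seed)
    acc_u = np.zeros_like(model.U)
    acc_v = np.zeros_like(model.V)
    acc_bc = np.zeros_like(model.bias_c)
    acc_bd = np.zeros_like(model.bias_d)
    trajectory = [objective(model, q, hc, hd, hp, mask)]

    def step(grad: np.ndarray, acc: np.ndarray) -> np.ndarray:
        acc += grad**2
        return hp.adagrad_rate * grad / np.sqrt(acc + hp.adagrad_eps)

    for _ in range(hp.n_iters):
        # drug side first, with the cell-line side fixed
        g = gradients(model, q, hc, hd, hp, mask)
        model.V -= step(g.dV, acc_v)
        model.bias_d -= step(g.dbias_d, acc_bd)
        # then the cell-line side
        g = gradients(model, q, hc, hd, hp, mask)
        model.U -= step(g.dU, acc_u)
        model.bias_c -= step(g.dbias_c, acc_bc)
        if hp.project_biases:
            np.clip(model.bias_c, 0.0, None, out=model.bias_c)
            np.clip(model.bias_d, 0.0, None, out=model.bias_d)
        trajectory.append(objective(model, q, hc, hd, hp, mask))
    return model, trajectory
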