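"""Single-hidden-layer calibration networks trained by Levenberg–Marquardt.

One network per analyte: the masked absorbance channels feed a single
hidden layer (``purelin`` or ``tansig`` transfer) and a single linear
output neuron that returns the concentration. Inputs and output are
min-max scaled to [-1, 1] before training and the prediction is de-scaled
back to µg/mL.

Training minimises the sum of squared residuals with the classic
Marquardt damping schedule: the damping µ starts at ``learning_rate``
(the toolbox-style "learning rate" of LM training), is multiplied by 10
when a step fails to reduce the SSE and divided by 10 when it succeeds,
so the optimiser interpolates between gradient descent (large µ) and
Gauss–Newton (small µ). Training stops at ``max_epochs``, when the
infinity norm of the gradient falls below ``grad_tol``, or when µ exceeds
1e10. The best of ``n_restarts`` seeded random initialisations is kept.

Model selection uses leave-one-out cross-validation scored by RRMSECV
(relative root-mean-square error of cross validation, % of the mean
reference concentration); :func:`scan_hidden_neurons` scans a neuron
range and picks the most parsimonious architecture within 5% of the best
RRMSECV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError, ShapeError

__all__ = [
    "AnnConfig",
    "TrainedModel",
    "LooResult",
    "ScanResult",
    "train_ann",
    "predict",
    "loo_cross_validate",
    "loo_rrmsecv",
    "scan_hidden_neurons",
]

_MU_MAX = 1e10
_MU_MIN = 1e-20

_TRANSFERS = {
    "purelin": (lambda z: z, lambda z, a: np.ones_like(z)),
    "tansig": (np.tanh, lambda z, a: 1.0 - a * a),
}


@dataclass(frozen=True)
class AnnConfig:
    """Architecture and training hyperparameters of one calibration net."""

    n_hidden: int = 5
    hidden_transfer: str = "purelin"
    output_transfer: str = "purelin"
    learning_rate: float = 0.1  # initial LM damping µ
    max_epochs: int = 1000
    grad_tol: float = 1e-7
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_hidden <= 50:
            raise DomainError(f"n_hidden must be in [1, 50], got {self.n_hidden}")
        if self.hidden_transfer not in _TRANSFERS:
            raise DomainError(f"unknown hidden transfer {self.hidden_transfer!r}")
        if self.output_transfer != "purelin":
            raise DomainError("output transfer must be 'purelin'")
        if self.learning_rate <= 0:
            raise DomainError("learning_rate (initial LM damping) must be > 0")
        if self.max_epochs < 1 or self.n_restarts < 1:
            raise DomainError("max_epochs and n_restarts must be >= 1")


@dataclass
class TrainedModel:
    """Fitted weights plus the scaling needed to reproduce predictions."""

    config: AnnConfig
    wavelength_mask: np.ndarray  # bool over the full grid width
    input_offset: np.ndarray  # per masked column
    input_scale: np.ndarray
    output_offset: float
    output_scale: float
    w1: np.ndarray  # (n_inputs, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    training_rrmsec: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0]

    def to_json(self, path=None) -> str:
        payload = {
            "config": asdict(self.config),
            "wavelength_mask": "".join("1" if m else "0" for m in self.wavelength_mask),
            "input_offset": self.input_offset.tolist(),
            "input_scale": self.input_scale.tolist(),
            "output_offset": self.output_offset,
            "output_scale": self.output_scale,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "training_rrmsec": self.training_rrmsec,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrainedModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(
            config=AnnConfig(**payload["config"]),
            wavelength_mask=np.array([c == "1" for c in payload["wavelength_mask"]]),
            input_offset=np.array(payload["input_offset"], dtype=float),
            input_scale=np.array(payload["input_scale"], dtype=float),
            output_offset=float(payload["output_offset"]),
            output_scale=float(payload["output_scale"]),
            w1=np.array(payload["w1"], dtype=float),
            b1=np.array(payload["b1"], dtype=float),
            w2=np.array(payload["w2"], dtype=float),
            b2=float(payload["b2"]),
            training_rrmsec=float(payload["training_rrmsec"]),
            warnings=list(payload.get("warnings", [])),
        )


def _minmax(X: np.ndarray):
    lo, hi = X.min(axis=0), X.max(axis=0)
    offset = 0.5 * (hi + lo)
    scale = 0.5 * (hi - lo)
    degenerate = scale <= 0
    scale = np.where(degenerate, 1.0, scale)
    return offset, scale, degenerate


def _forward_scaled(Xs, w1, b1, w2, b2, transfer):
    f, _ = _TRANSFERS[transfer]
    a = f(Xs @ w1 + b1)
    return a @ w2 + b2, a


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, d, h):
    w1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    w2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _jacobian(Xs, theta, d, h, transfer):
    """Jacobian of the scaled residuals w.r.t. the packed parameters."""
    w1, b1, w2, b2 = _unpack(theta, d, h)
    f, df = _TRANSFERS[transfer]
    z = Xs @ w1 + b1
    a = f(z)
    yhat = a @ w2 + b2
    g = df(z, a) * w2  # (n, h): d yhat / d z_j
    n = Xs.shape[0]
    J = np.empty((n, theta.size))
    J[:, : d * h] = (Xs[:, :, None] * g[:, None, :]).reshape(n, d * h)
    J[:, d * h : d * h + h] = g
    J[:, d * h + h : d * h + 2 * h] = a
    J[:, -1] = 1.0
    return J, yhat


def _train_once(Xs, ys, config: AnnConfig, rng) -> tuple[np.ndarray, float]:
    d, h = Xs.shape[1], config.n_hidden
    scale = 1.0 / max(1.0, np.sqrt(d))
    w1 = rng.uniform(-scale, scale, size=(d, h))
    b1 = rng.uniform(-0.5, 0.5, size=h)
    w2 = rng.uniform(-0.5, 0.5, size=h)
    b2 = float(rng.uniform(-0.5, 0.5))
    theta = _pack(w1, b1, w2, b2)
    yhat, _ = _forward_scaled(Xs, w1, b1, w2, b2, config.hidden_transfer)
    sse = float(np.sum((yhat - ys) ** 2))
    mu = config.learning_rate
    eye = np.eye(theta.size)
    for _ in range(config.max_epochs):
        J, yhat = _jacobian(Xs, theta, d, h, config.hidden_transfer)
        r = yhat - ys
        grad = J.T @ r
        if np.max(np.abs(grad)) < config.grad_tol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= _MU_MAX:
            try:
                step = np.linalg.solve(JtJ + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + step
            w1c, b1c, w2c, b2c = _unpack(cand, d, h)
            yc, _ = _forward_scaled(Xs, w1c, b1c, w2c, b2c, config.hidden_transfer)
            sse_c = float(np.sum((yc - ys) ** 2))
            if np.isfinite(sse_c) and sse_c < sse:
                theta, sse = cand, sse_c
                mu = max(mu / 10.0, _MU_MIN)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break
    return theta, sse


def train_ann(X: np.ndarray, y: np.ndarray, config: AnnConfig,
              wavelength_mask: np.ndarray | None = None) -> TrainedModel:
    """Fit one network; keep the best of ``config.n_restarts`` seeded inits.

    ``X`` is the full-grid absorbance matrix; when ``wavelength_mask`` is
    given only the masked columns are consumed (and the mask is stored so
    prediction can accept full-grid input).
    """
    from .metrics import rrmse

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError(f"X {X.shape} does not match y of length {y.size}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DomainError("X and y must be finite")
    if wavelength_mask is None:
        mask = np.ones(X.shape[1], dtype=bool)
    else:
        mask = np.asarray(wavelength_mask, dtype=bool)
        if mask.size != X.shape[1]:
            raise ShapeError(f"mask of size {mask.size} for {X.shape[1]} columns")
    Xm = X[:, mask]
    n, d = Xm.shape
    warnings = []
    n_params = d * config.n_hidden + 2 * config.n_hidden + 1
    if n_params > n:
        warnings.append(
            f"overparameterized: {n_params} weights for {n} samples; "
            "LM damping regularizes the fit"
        )

    in_off, in_scale, degen_in = _minmax(Xm)
    if degen_in.any():
        warnings.append(
            f"constant input column(s) {np.nonzero(degen_in)[0].tolist()}; scale set to 1"
        )
    out_off, out_scale, degen_out = _minmax(y.reshape(-1, 1))
    out_off, out_scale = float(out_off[0]), float(out_scale[0])
    if degen_out[0]:
        warnings.append("constant target; output scale set to 1")
    Xs = (Xm - in_off) / in_scale
    ys = (y - out_off) / out_scale

    best = None
    for restart in range(config.n_restarts):
        sub = int(np.random.SeedSequence([int(config.seed), restart]).generate_state(1)[0])
        theta, sse = _train_once(Xs, ys, config, np.random.default_rng(sub))
        if best is None or sse < best[1]:
            best = (theta, sse)
    w1, b1, w2, b2 = _unpack(best[0], d, config.n_hidden)
    model = TrainedModel(
        config=config,
        wavelength_mask=mask,
        input_offset=in_off,
        input_scale=in_scale,
        output_offset=out_off,
        output_scale=out_scale,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        training_rrmsec=np.nan,
        warnings=warnings,
    )
    yhat = predict(model, Xm)
    model.training_rrmsec = rrmse(yhat, y) if abs(np.mean(y)) > 0 else float("nan")
    return model


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Forward pass in µg/mL; accepts full-grid or pre-masked input."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    full = model.wavelength_mask.size
    masked = int(model.wavelength_mask.sum())
    if X.shape[1] == full:
        Xm = X[:, model.wavelength_mask]
    elif X.shape[1] == masked:
        Xm = X
    else:
        raise ShapeError(
            f"expected {full} (full grid) or {masked} (masked) columns, got {X.shape[1]}"
        )
    Xs = (Xm - model.input_offset) / model.input_scale
    ys, _ = _forward_scaled(Xs, model.w1, model.b1, model.w2, model.b2,
                            model.config.hidden_transfer)
    return ys * model.output_scale + model.output_offset


@dataclass
class LooResult:
    """Per-fold leave-one-out predictions and the resulting RRMSECV %."""

    predictions: np.ndarray
    reference: np.ndarray
    rrmsecv: float


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([int(seed), 104729, fold]).generate_state(1)[0])


def loo_cross_validate(X: np.ndarray, y: np.ndarray, config: AnnConfig,
                       wavelength_mask: np.ndarray | None = None) -> LooResult:
    """Leave-one-out CV; fold seeds derive from config.seed and fold index only."""
    from .metrics import rrmse

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise DomainError(f"leave-one-out needs >= 3 samples, got {n}")
    if abs(np.mean(y)) == 0:
        raise DomainError("mean reference concentration is zero; RRMSECV undefined")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        fold_cfg = replace(config, seed=_fold_seed(config.seed, i))
        model = train_ann(X[keep], y[keep], fold_cfg, wavelength_mask)
        xi = X[i : i + 1, wavelength_mask] if wavelength_mask is not None else X[i : i + 1]
        preds[i] = predict(model, xi)[0]
    return LooResult(predictions=preds, reference=y.copy(), rrmsecv=rrmse(preds, y))


def loo_rrmsecv(X: np.ndarray, y: np.ndarray, config: AnnConfig,
                wavelength_mask: np.ndarray | None = None) -> float:
    return loo_cross_validate(X, y, config, wavelength_mask).rrmsecv


@dataclass
class ScanResult:
    table: pd.DataFrame  # columns: n_hidden, rrmsecv
    selected_n_hidden: int


def scan_hidden_neurons(X, y, n_min: int, n_max: int, config: AnnConfig,
                        parsimony_tol: float = 0.05) -> ScanResult:
    """RRMSECV for each candidate hidden-layer size.

    The selected size is the smallest one whose RRMSECV is within
    ``parsimony_tol`` (relative) of the scan minimum — the usual
    parsimony tie-break against overfitting.
    """
    if n_min < 1 or n_max < n_min:
        raise DomainError(f"invalid scan range [{n_min}, {n_max}]")
    rows = []
    for h in range(n_min, n_max + 1):
        cv = loo_rrmsecv(X, y, replace(config, n_hidden=h))
        rows.append((h, cv))
    table = pd.DataFrame(rows, columns=["n_hidden", "rrmsecv"])
    best = table["rrmsecv"].min()
    ok = table[table["rrmsecv"] <= (1.0 + parsimony_tol) * best]
    return ScanResult(table=table, selected_n_hidden=int(ok["n_hidden"].iloc[0]))
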