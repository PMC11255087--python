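"""Fitting covariate models to event-table data.

The objective is the plain sum of squared errors over all subjects and
observations,

    L(w) = sum_i sum_k ( y_k^(i) - C(t_k^(i); zeta^(i), I^(i)) )^2,

where ``zeta^(i) = phi(x^(i); w)`` are the network-predicted PK parameters and
``C`` the central concentration of the dosed two-compartment model.  Training
follows the reference protocol: covariates min–max scaled to [0, 1] on the
training fold, full-batch ADAM (lr 1e-2 by default), and optionally a
subject-level validation split whose best epoch is checkpointed.

Gradients flow through the closed-form solution of the linear ODE system via
complex-step differentiation (exact to machine precision) and through the
networks via manual reverse mode, so runs are bitwise reproducible given a
seed.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import Dataset, design_matrix
from .exceptions import ConfigurationError, DataError
from .nets import ArchitectureSpec, CovariateModel, build_model
from .pk import (
    ConcentrationCurve,
    DoseRegimen,
    analytic_profile,
    concentration_and_gradient,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Min–max scaler
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Per-column min–max scaler fitted on training covariates.

    Maps the training minimum to 0 and maximum to 1; unseen values fall
    outside [0, 1] (no clipping).  A constant column maps to 0 everywhere
    (min == max convention, logged at fit time).
    """

    columns: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    medians: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, columns) -> "Scaler":
        x = np.asarray(x, dtype=float)
        if x.shape[0] < 1:
            raise DataError("scaler needs at least one training subject")
        mins, maxs = x.min(axis=0), x.max(axis=0)
        for j, c in enumerate(columns):
            if mins[j] == maxs[j]:
                logger.warning(
                    "covariate %r is constant in the training data; "
                    "it scales to 0.0 everywhere", c,
                )
        return cls(
            columns=list(columns), mins=mins, maxs=maxs,
            medians=np.median(x, axis=0),
        )

    def _span(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span == 0, 1.0, span)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mins) / self._span()

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self._span() + self.mins

    def _col(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise DataError(
                f"unknown covariate {name!r}; fitted columns: {self.columns}"
            ) from None

    def transform_value(self, name: str, value):
        j = self._col(name)
        span = self._span()[j]
        return (np.asarray(value, dtype=float) - self.mins[j]) / span

    def range(self, name: str) -> tuple[float, float]:
        j = self._col(name)
        return float(self.mins[j]), float(self.maxs[j])

    def median(self, name: str) -> float:
        return float(self.medians[self._col(name)])

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "medians": self.medians.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(
            columns=list(d["columns"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            medians=np.asarray(d["medians"], dtype=float),
        )


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def sse_loss(predictions, dataset: Dataset) -> float:
    """Sum of squared errors of per-subject predictions at observation times.

    ``predictions`` is a sequence aligned with ``dataset.subjects``; each
    entry holds the predicted concentrations at that subject's observation
    times.  Subjects without observations contribute zero (logged).
    """
    total = 0.0
    for pred, s in zip(predictions, dataset.subjects):
        if s.obs_values.size == 0:
            logger.info("subject %s has no observations; contributes 0", s.id)
            continue
        r = np.asarray(pred, dtype=float) - s.obs_values
        total += float(r @ r)
    return total


# ---------------------------------------------------------------------------
# Observation bookkeeping (flattened, vectorized per epoch)
# ---------------------------------------------------------------------------


class _ObsBlock:
    """Flattened observations + padded event arrays for a subject subset."""

    def __init__(self, dataset: Dataset, indices):
        subs = [dataset.subjects[i] for i in indices]
        self.n = len(subs)
        max_e = max((len(s.regimen.events) for s in subs), default=1) or 1
        self.ev_t = np.zeros((self.n, max_e))
        self.ev_a = np.zeros((self.n, max_e))
        self.ev_d = np.zeros((self.n, max_e))
        sub_idx, t, y = [], [], []
        for i, s in enumerate(subs):
            for j, e in enumerate(s.regimen.events):
                self.ev_t[i, j], self.ev_a[i, j], self.ev_d[i, j] = (
                    e.time, e.amount, e.duration,
                )
            sub_idx.extend([i] * s.obs_times.size)
            t.extend(s.obs_times)
            y.extend(s.obs_values)
        self.sub_idx = np.asarray(sub_idx, dtype=int)
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.ids = [s.id for s in subs]

    def loss_and_grad(self, z: np.ndarray):
        """SSE loss, its gradient w.r.t. the (n, 4) parameter matrix, and the
        per-observation residuals."""
        theta = z[self.sub_idx]
        c, jac = concentration_and_gradient(
            theta,
            self.ev_t[self.sub_idx], self.ev_a[self.sub_idx],
            self.ev_d[self.sub_idx], self.t,
        )
        r = c - self.y
        d_z = np.zeros_like(z)
        np.add.at(d_z, self.sub_idx, (2.0 * r)[:, None] * jac.T)
        return float(r @ r), d_z, r

    def loss(self, z: np.ndarray) -> float:
        from .pk import conc_events

        theta = z[self.sub_idx]
        c = conc_events(
            theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3],
            self.ev_t[self.sub_idx], self.ev_a[self.sub_idx],
            self.ev_d[self.sub_idx], self.t,
        )
        r = np.real(c) - self.y
        return float(r @ r)


# ---------------------------------------------------------------------------
# Protocol / result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingProtocol:
    """Optimization settings: full-batch ADAM on the squared-error objective."""

    epochs: int = 500
    lr: float = 1e-2
    val_fraction: float = 0.0
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class FitResult:
    """A trained covariate model with everything needed to predict."""

    spec: ArchitectureSpec
    params: dict
    scaler: Scaler
    columns: list[str]
    categorical: dict
    history: np.ndarray               # training loss per epoch
    val_history: np.ndarray | None    # validation loss per epoch (if split)
    best_epoch: int
    seed: int
    protocol: TrainingProtocol
    model: CovariateModel = field(repr=False, default=None)

    def __post_init__(self):
        if self.model is None:
            self.model = build_model(
                self.spec, self.columns,
                categorical_covs=[
                    c for c in self.categorical if c in self.spec.covariates
                    or any(c in b.covariates for b in self.spec.branches)
                ],
            )

    def predict_parameters(self, dataset: Dataset) -> np.ndarray:
        """Predicted (CL, V1, Q, V2) per subject, shape (n, 4)."""
        x, cols = design_matrix(dataset, self.spec.covariates)
        if cols != self.columns:
            raise DataError(
                f"covariate layout mismatch: checkpoint expects {self.columns}, "
                f"data provides {cols}"
            )
        return self.model.predict(self.params, self.scaler.transform(x))

    def predict_curve(self, covariates_row: np.ndarray,
                      regimen: DoseRegimen, times) -> ConcentrationCurve:
        from .pk import PKParameters

        z = self.model.predict(
            self.params, self.scaler.transform(np.atleast_2d(covariates_row))
        )[0]
        return analytic_profile(PKParameters(*z), regimen, times)

    def predict_curves(self, dataset: Dataset, times) -> list[ConcentrationCurve]:
        from .pk import PKParameters

        z = self.predict_parameters(dataset)
        return [
            analytic_profile(PKParameters(*z[i]), s.regimen, times)
            for i, s in enumerate(dataset.subjects)
        ]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": {k: v.tolist() for k, v in self.params.items()},
            "scaler": self.scaler.to_dict(),
            "columns": self.columns,
            "categorical": {k: list(v) for k, v in self.categorical.items()},
            "history": self.history.tolist(),
            "val_history": (
                None if self.val_history is None else self.val_history.tolist()
            ),
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "protocol": asdict(self.protocol),
        }

    def save(self, path) -> None:
        import hashlib

        d = self.to_dict()
        d["spec_hash"] = hashlib.sha256(
            json.dumps(d["spec"], sort_keys=True).encode()
        ).hexdigest()[:16]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = {k: v for k, v in d.items() if k != "spec_hash"}
        return cls(
            spec=ArchitectureSpec.from_dict(d["spec"]),
            params={k: np.asarray(v, dtype=float) for k, v in d["params"].items()},
            scaler=Scaler.from_dict(d["scaler"]),
            columns=list(d["columns"]),
            categorical={k: list(v) for k, v in d["categorical"].items()},
            history=np.asarray(d["history"], dtype=float),
            val_history=(
                None if d["val_history"] is None
                else np.asarray(d["val_history"], dtype=float)
            ),
            best_epoch=int(d["best_epoch"]),
            seed=int(d["seed"]),
            protocol=TrainingProtocol(**d["protocol"]),
        )

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# ADAM
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict, protocol: TrainingProtocol):
        self.p = protocol
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps, lr = self.p.beta1, self.p.beta2, self.p.eps, self.p.lr
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] = params[k] - lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + eps
            )


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    dataset: Dataset,
    spec: ArchitectureSpec,
    protocol: TrainingProtocol = TrainingProtocol(),
) -> FitResult:
    """Fit an architecture to an event-table dataset.

    Full-batch gradient descent with ADAM on the squared-error objective,
    deterministic given ``protocol.seed`` (data split, initialization and
    optimization all draw from one seeded generator).  With
    ``val_fraction > 0`` a subject-level random split is held out and the
    epoch with the lowest validation loss is checkpointed; otherwise the
    final weights are returned.  A non-finite loss aborts with a diagnostic
    naming the epoch and the subject with the largest residual.
    """
    if len(dataset) == 0:
        raise DataError("cannot train on an empty dataset")
    rng = np.random.default_rng(protocol.seed)

    n = len(dataset)
    perm = rng.permutation(n)
    n_val = int(round(protocol.val_fraction * n))
    if protocol.val_fraction > 0 and n_val == 0:
        logger.warning("val_fraction %.3g rounds to zero validation subjects",
                       protocol.val_fraction)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ConfigurationError("validation split leaves no training subjects")

    x_all, columns = design_matrix(dataset, spec.covariates)
    scaler = Scaler.fit(x_all[train_idx], columns)
    x_train = scaler.transform(x_all[train_idx])
    x_val = scaler.transform(x_all[val_idx]) if n_val else None

    cat_covs = [c for c in dataset.categorical if c in spec.covariates]
    model = build_model(spec, columns, categorical_covs=cat_covs)
    params = model.init_params(rng)

    train_block = _ObsBlock(dataset, train_idx)
    val_block = _ObsBlock(dataset, val_idx) if n_val else None

    opt = _Adam(params, protocol)
    history = np.empty(protocol.epochs)
    val_history = np.empty(protocol.epochs) if n_val else None
    best = (np.inf, None, -1)

    for epoch in range(protocol.epochs):
        z, cache = model.forward(params, x_train)
        loss, d_z, residuals = train_block.loss_and_grad(z)
        history[epoch] = loss
        if not np.isfinite(loss):
            worst = train_block.ids[
                train_block.sub_idx[int(np.nanargmax(np.abs(residuals)))]
            ]
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch}; largest residual "
                f"for subject {worst}"
            )
        if n_val:
            zv = model.predict(params, x_val)
            vl = val_block.loss(zv)
            val_history[epoch] = vl
            if vl < best[0]:
                best = (vl, copy.deepcopy(params), epoch)
        grads = model.backward(params, cache, d_z)
        opt.step(params, grads)

    if n_val and best[1] is not None:
        final_params, best_epoch = best[1], best[2]
    else:
        final_params, best_epoch = params, protocol.epochs - 1

    return FitResult(
        spec=spec,
        params=final_params,
        scaler=scaler,
        columns=columns,
        categorical=dict(dataset.categorical),
        history=history,
        val_history=val_history,
        best_epoch=best_epoch,
        seed=protocol.seed,
        protocol=protocol,
        model=model,
    )
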