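"""Covariate-to-PK-parameter network architectures.

Five variants of the covariate model ``zeta = phi(x; w)`` are provided, each a
single-hidden-layer network (swish activation) whose four outputs parameterize
the two-compartment model:

* ``naive`` — fully connected, softplus output (positivity only);
* ``initialized`` — naive structure, but the output layer is initialized so
  the untrained network predicts user-supplied typical PK values;
* ``boundary`` — the output layer feeds a scaled sigmoid mapping each
  parameter strictly into user-supplied physiological bounds;
* ``global`` — a chosen subset of parameters (default Q and V2, the early
  distribution parameters that sparse sampling cannot identify per subject)
  is estimated as free population-level scalars, the rest by the network;
* ``multibranch`` — independent sub-networks over covariate subsets whose
  strictly positive outputs are multiplied per target parameter, mirroring
  the product covariate models of classical population PK and making each
  learned covariate effect directly plottable.

The networks are small enough that forward passes and reverse-mode gradients
are implemented directly in NumPy; parameters live in a flat ``{name: array}``
dict so the optimizer is architecture-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .exceptions import ConfigurationError, InvalidParameterError
from .pk import PARAM_ORDER, PKParameters

#: Default physiological bounds (lower, upper) used by the boundary variant:
#: CL in (0, 0.5) L/h, V1 in (0.3, 7) L, Q in (0.05, 0.5) L/h, V2 in (0, 2) L.
DEFAULT_BOUNDS = {
    "CL": (0.0, 0.5),
    "V1": (0.3, 7.0),
    "Q": (0.05, 0.5),
    "V2": (0.0, 2.0),
}

VARIANTS = ("naive", "initialized", "boundary", "global", "multibranch")


def sigmoid(x):
    return expit(x)


def swish(x):
    """x * sigmoid(x)."""
    return x * sigmoid(x)


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of softplus: ln(e^y - 1), stable for small and large y."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise InvalidParameterError("softplus_inv requires strictly positive input")
    return y + np.log(-np.expm1(-y))


def apply_boundary(h, bounds):
    """Map unconstrained pre-activations into (lb, ub) via a scaled sigmoid.

    ``zeta_m = lb_m + (ub_m - lb_m) * sigmoid(h_m)``; the output is strictly
    inside the bounds for any finite input.
    """
    lb, ub = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    if np.any(lb >= ub):
        raise ConfigurationError("boundary bounds require lower < upper elementwise")
    return lb + (ub - lb) * sigmoid(np.asarray(h))


def apply_softsign_boundary(h, bounds):
    """Softsign-based alternative squashing: gentler saturation than the
    sigmoid, so gradients vanish more slowly at extreme pre-activations."""
    lb, ub = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    if np.any(lb >= ub):
        raise ConfigurationError("boundary bounds require lower < upper elementwise")
    h = np.asarray(h)
    return lb + (ub - lb) * (0.5 + 0.5 * h / (1.0 + np.abs(h)))


@dataclass(frozen=True)
class BranchSpec:
    """One sub-model of the multi-branch network: a covariate subset wired to
    one or more target PK parameters."""

    covariates: tuple[str, ...]
    targets: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "targets", tuple(self.targets))
        bad = [t for t in self.targets if t not in PARAM_ORDER]
        if bad:
            raise ConfigurationError(f"unknown branch targets: {bad}")
        if not self.covariates or not self.targets:
            raise ConfigurationError("a branch needs >=1 covariate and >=1 target")


@dataclass
class ArchitectureSpec:
    """Configuration of one covariate-model architecture."""

    variant: str
    covariates: tuple[str, ...]
    hidden_size: int = 8
    bounds: dict | None = None
    global_params: tuple[str, ...] = ()
    branches: tuple[BranchSpec, ...] = ()
    typical_values: PKParameters | None = None
    use_softsign: bool = False
    #: starting values for global scalars on the PK scale (softplus^-1 applied
    #: internally); implementation defaults, not literature estimates.
    global_priors: dict = field(
        default_factory=lambda: {"Q": 0.2, "V2": 0.8}
    )
    seed: int = 0

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        self.global_params = tuple(self.global_params)
        self.branches = tuple(
            b if isinstance(b, BranchSpec) else BranchSpec(**b) for b in self.branches
        )
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}"
            )
        if self.hidden_size < 1:
            raise ConfigurationError("hidden_size must be >= 1")
        for p in self.global_params:
            if p not in PARAM_ORDER:
                raise ConfigurationError(f"unknown global parameter {p!r}")
        if self.variant == "boundary":
            bounds = dict(DEFAULT_BOUNDS if self.bounds is None else self.bounds)
            for p in PARAM_ORDER:
                lb, ub = bounds[p]
                if not (0 <= lb < ub):
                    raise ConfigurationError(
                        f"bounds for {p} need 0 <= lower < upper, got ({lb}, {ub})"
                    )
            self.bounds = bounds
        if self.variant == "global":
            if not self.global_params:
                self.global_params = ("Q", "V2")
            if set(self.global_params) == set(PARAM_ORDER):
                raise ConfigurationError(
                    "all four PK parameters global leaves no covariate model"
                )
        if self.variant == "initialized" and self.typical_values is None:
            raise ConfigurationError(
                "the initialized variant requires typical_values"
            )
        if self.variant == "multibranch":
            if not self.branches:
                raise ConfigurationError("multibranch requires at least one branch")
            targeted = {t for b in self.branches for t in b.targets}
            overlap = targeted & set(self.global_params)
            if overlap:
                raise ConfigurationError(
                    f"parameters {sorted(overlap)} are both branch-targeted and global"
                )
            orphan = set(PARAM_ORDER) - targeted - set(self.global_params)
            if orphan:
                raise ConfigurationError(
                    f"parameters {sorted(orphan)} are neither branch-targeted "
                    "nor global"
                )
            branch_covs = {c for b in self.branches for c in b.covariates}
            missing = branch_covs - set(self.covariates)
            if missing:
                raise ConfigurationError(
                    f"branch covariates {sorted(missing)} absent from spec.covariates"
                )

    @property
    def network_params(self) -> tuple[str, ...]:
        """PK parameters produced by the network (not global scalars)."""
        return tuple(p for p in PARAM_ORDER if p not in self.global_params)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.typical_values is not None:
            d["typical_values"] = {
                p: getattr(self.typical_values, p) for p in PARAM_ORDER
            }
        d["branches"] = [
            {"covariates": list(b.covariates), "targets": list(b.targets)}
            for b in self.branches
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        if d.get("typical_values"):
            d["typical_values"] = PKParameters(**d["typical_values"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Dense layers with manual reverse mode
# ---------------------------------------------------------------------------


def _theta_init(spec: ArchitectureSpec, name: str) -> np.ndarray:
    """Raw (softplus-scale) starting value for a global parameter: the
    softplus inverse of its configured prior, or 0 (-> ln 2) without one."""
    prior = (spec.global_priors or {}).get(name)
    if prior is None:
        return np.zeros(1)
    return np.atleast_1d(softplus_inv(float(prior)))


def _dense_init(rng, d_in, d_out):
    """Uniform fan-in initialization U(-1/sqrt(d_in), 1/sqrt(d_in))."""
    bound = 1.0 / np.sqrt(d_in)
    return (
        rng.uniform(-bound, bound, size=(d_in, d_out)),
        rng.uniform(-bound, bound, size=d_out),
    )


def _mlp_init(rng, d_in, hidden, d_out):
    w1, b1 = _dense_init(rng, d_in, hidden)
    w2, b2 = _dense_init(rng, hidden, d_out)
    return {"W1": w1, "b1": b1, "W2": w2, "b2": b2}


def _mlp_forward(p, prefix, x):
    h = x @ p[prefix + "W1"] + p[prefix + "b1"]
    s = swish(h)
    o = s @ p[prefix + "W2"] + p[prefix + "b2"]
    return o, (x, h, s)


def _mlp_backward(p, prefix, cache, d_out, grads):
    x, h, s = cache
    grads[prefix + "W2"] = s.T @ d_out
    grads[prefix + "b2"] = d_out.sum(axis=0)
    ds = d_out @ p[prefix + "W2"].T
    sig = sigmoid(h)
    dh = ds * sig * (1.0 + h * (1.0 - sig))
    grads[prefix + "W1"] = x.T @ dh
    grads[prefix + "b1"] = dh.sum(axis=0)


def _linear_forward(p, prefix, x):
    return x @ p[prefix + "W"] + p[prefix + "b"], (x,)


def _linear_backward(p, prefix, cache, d_out, grads):
    (x,) = cache
    grads[prefix + "W"] = x.T @ d_out
    grads[prefix + "b"] = d_out.sum(axis=0)


# ---------------------------------------------------------------------------
# Architecture implementations
# ---------------------------------------------------------------------------


class CovariateModel:
    """Maps a scaled design matrix (n, D) to PK parameters (n, 4) in the
    order (CL, V1, Q, V2), with reverse-mode gradients for the optimizer."""

    def __init__(self, spec: ArchitectureSpec, columns: list[str]):
        self.spec = spec
        self.columns = list(columns)

    def init_params(self, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    def forward(self, params: dict, x: np.ndarray):
        raise NotImplementedError

    def backward(self, params, cache, d_z) -> dict:
        raise NotImplementedError

    def predict(self, params, x) -> np.ndarray:
        self._check_input(x)
        z, _ = self.forward(params, x)
        return z

    @staticmethod
    def _check_input(x):
        if np.isnan(np.asarray(x)).any():
            raise InvalidParameterError("NaN in covariate input")


class _FullyConnected(CovariateModel):
    """naive / initialized / boundary / global variants (one shared body)."""

    def __init__(self, spec, columns):
        super().__init__(spec, columns)
        self.out_names = spec.network_params
        self.n_out = len(self.out_names)
        self.global_names = spec.global_params
        if spec.variant == "boundary":
            b = spec.bounds
            self.lb = np.array([b[p][0] for p in PARAM_ORDER])
            self.ub = np.array([b[p][1] for p in PARAM_ORDER])

    def init_params(self, rng):
        p = _mlp_init(rng, len(self.columns), self.spec.hidden_size, self.n_out)
        if self.spec.variant == "initialized":
            tv = np.array(
                [getattr(self.spec.typical_values, n) for n in self.out_names]
            )
            p["W2"] = rng.uniform(-1e-2, 1e-2, size=p["W2"].shape)
            p["b2"] = softplus_inv(tv)
        for name in self.global_names:
            p["theta_" + name] = _theta_init(self.spec, name)
        return p

    def forward(self, params, x):
        self._check_input(x)
        o, mlp_cache = _mlp_forward(params, "", x)
        n = x.shape[0]
        z = np.empty((n, 4))
        if self.spec.variant == "boundary":
            idx = [PARAM_ORDER.index(p) for p in self.out_names]
            if self.spec.use_softsign:
                z[:, idx] = apply_softsign_boundary(o, (self.lb[idx], self.ub[idx]))
            else:
                z[:, idx] = apply_boundary(o, (self.lb[idx], self.ub[idx]))
        else:
            for j, name in enumerate(self.out_names):
                z[:, PARAM_ORDER.index(name)] = softplus(o[:, j])
        for name in self.global_names:
            z[:, PARAM_ORDER.index(name)] = softplus(params["theta_" + name][0])
        return z, (o, mlp_cache)

    def backward(self, params, cache, d_z):
        o, mlp_cache = cache
        grads: dict = {}
        d_o = np.empty_like(o)
        for j, name in enumerate(self.out_names):
            col = PARAM_ORDER.index(name)
            if self.spec.variant == "boundary":
                width = self.ub[col] - self.lb[col]
                if self.spec.use_softsign:
                    d_act = width * 0.5 / (1.0 + np.abs(o[:, j])) ** 2
                else:
                    sg = sigmoid(o[:, j])
                    d_act = width * sg * (1.0 - sg)
            else:
                d_act = sigmoid(o[:, j])
            d_o[:, j] = d_z[:, col] * d_act
        _mlp_backward(params, "", mlp_cache, d_o, grads)
        for name in self.global_names:
            th = params["theta_" + name][0]
            col = PARAM_ORDER.index(name)
            grads["theta_" + name] = np.array([d_z[:, col].sum() * sigmoid(th)])
        return grads


class _MultiBranch(CovariateModel):
    """Product-of-sub-models architecture.

    Each branch is an independent network over its covariate subset with one
    softplus output per target parameter; a parameter's value is the product
    of all branch factors targeting it (so log zeta_m decomposes into a sum
    of per-branch log effects).  A branch over a single one-hot-encoded
    categorical covariate is a linear map (one factor per level).  Parameters
    in the global subset are softplus-transformed free scalars, as in the
    global variant.  The output bias of every neuron feeding V1 is
    initialized at 0.5 so initial central-volume factors start near
    softplus(0.5) ~= 0.97 rather than collapsing toward zero.
    """

    def __init__(self, spec, columns, categorical_covs=()):
        super().__init__(spec, columns)
        self.categorical_covs = set(categorical_covs)
        self.branch_cols = []
        self.branch_linear = []
        for b in spec.branches:
            cols = []
            for cov in b.covariates:
                if cov in self.categorical_covs:
                    cols.extend(
                        i for i, c in enumerate(columns) if c.startswith(cov + "=")
                    )
                else:
                    cols.append(columns.index(cov))
            self.branch_cols.append(np.array(cols, dtype=int))
            self.branch_linear.append(
                len(b.covariates) == 1 and b.covariates[0] in self.categorical_covs
            )

    def init_params(self, rng):
        p: dict = {}
        for j, b in enumerate(self.spec.branches):
            d_in = self.branch_cols[j].size
            d_out = len(b.targets)
            prefix = f"br{j}_"
            if self.branch_linear[j]:
                w, _ = _dense_init(rng, d_in, d_out)
                p[prefix + "W"] = w
                p[prefix + "b"] = np.zeros(d_out)
            else:
                sub = _mlp_init(rng, d_in, self.spec.hidden_size, d_out)
                sub["b2"] = np.zeros(d_out)
                for key, val in sub.items():
                    p[prefix + key] = val
            bias_key = prefix + ("b" if self.branch_linear[j] else "b2")
            for k, t in enumerate(b.targets):
                if t == "V1":
                    p[bias_key][k] = 0.5
        for name in self.spec.global_params:
            p["theta_" + name] = _theta_init(self.spec, name)
        return p

    def branch_output(self, params, j, x_branch):
        """Softplus factors of branch j for pre-selected input columns."""
        prefix = f"br{j}_"
        if self.branch_linear[j]:
            o, cache = _linear_forward(params, prefix, x_branch)
        else:
            o, cache = _mlp_forward(params, prefix, x_branch)
        return softplus(o), o, cache

    def forward(self, params, x):
        self._check_input(x)
        n = x.shape[0]
        z = np.ones((n, 4))
        factors, pre, caches = [], [], []
        for j in range(len(self.spec.branches)):
            f, o, cache = self.branch_output(params, j, x[:, self.branch_cols[j]])
            factors.append(f)
            pre.append(o)
            caches.append(cache)
            for k, t in enumerate(self.spec.branches[j].targets):
                z[:, PARAM_ORDER.index(t)] *= f[:, k]
        for name in self.spec.global_params:
            z[:, PARAM_ORDER.index(name)] = softplus(params["theta_" + name][0])
        return z, (z.copy(), factors, pre, caches)

    def backward(self, params, cache, d_z):
        z, factors, pre, caches = cache
        grads: dict = {}
        for j, b in enumerate(self.spec.branches):
            prefix = f"br{j}_"
            d_o = np.empty_like(pre[j])
            for k, t in enumerate(b.targets):
                col = PARAM_ORDER.index(t)
                # d z_m / d f_jk = product of the other factors = z_m / f_jk
                d_f = d_z[:, col] * z[:, col] / factors[j][:, k]
                d_o[:, k] = d_f * sigmoid(pre[j][:, k])
            if self.branch_linear[j]:
                _linear_backward(params, prefix, caches[j], d_o, grads)
            else:
                _mlp_backward(params, prefix, caches[j], d_o, grads)
        for name in self.spec.global_params:
            th = params["theta_" + name][0]
            col = PARAM_ORDER.index(name)
            grads["theta_" + name] = np.array([d_z[:, col].sum() * sigmoid(th)])
        return grads


def build_model(
    spec: ArchitectureSpec, columns: list[str], categorical_covs=()
) -> CovariateModel:
    """Instantiate the architecture for a given design-matrix column layout."""
    if spec.variant == "multibranch":
        return _MultiBranch(spec, columns, categorical_covs)
    return _FullyConnected(spec, columns)


def init_typical(
    spec: ArchitectureSpec, typical_values: PKParameters, columns: list[str]
) -> dict:
    """Initialize a fully connected network so the untrained model predicts
    approximately ``typical_values`` for every subject.

    Final-layer weights are drawn small (scale 1e-2) and final-layer biases
    set to softplus^-1(typical), so for inputs in [0, 1] the prediction
    spread around the typical value is a few percent at most.
    """
    init_spec = ArchitectureSpec(
        variant="initialized",
        covariates=spec.covariates,
        hidden_size=spec.hidden_size,
        global_params=spec.global_params,
        typical_values=typical_values,
        seed=spec.seed,
    )
    model = _FullyConnected(init_spec, columns)
    return model.init_params(np.random.default_rng(spec.seed))


# ---------------------------------------------------------------------------
# Effect-curve extraction (multibranch interpretability surface)
# ---------------------------------------------------------------------------


@dataclass
class EffectCurve:
    """A learned multiplicative covariate effect on one PK parameter."""

    covariate: str
    parameter: str
    branch: int
    grid: np.ndarray          # unscaled covariate values
    values: np.ndarray        # dimensionless multiplicative factors (> 0)
    extrapolated: np.ndarray = field(default=None)  # mask: outside fitted range

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.grid.shape, dtype=bool)


def extract_effect_curves(fit, grids: dict | None = None, n_points: int = 100):
    """Evaluate each branch's learned factor over a covariate grid.

    ``fit`` is a :class:`deepcompartment.train.FitResult` from a multibranch
    model.  For every (branch, continuous covariate, target parameter) one
    :class:`EffectCurve` is produced on ``grids[covariate]`` (default: 100
    points across the covariate's fitted range); other covariates of a
    multi-covariate branch are held at their training median.  Categorical
    branches yield one factor per level (grid = level index).  Grid points
    outside the scaler's fitted range are allowed but flagged as
    extrapolation.
    """
    spec = fit.spec
    if spec.variant != "multibranch":
        raise ConfigurationError("effect curves require a multibranch model")
    model: _MultiBranch = fit.model
    scaler = fit.scaler
    curves: list[EffectCurve] = []
    for j, b in enumerate(spec.branches):
        cols = model.branch_cols[j]
        if model.branch_linear[j]:
            cov = b.covariates[0]
            levels = np.eye(cols.size)
            f, _, _ = model.branch_output(fit.params, j, levels)
            for k, t in enumerate(b.targets):
                curves.append(
                    EffectCurve(
                        covariate=cov, parameter=t, branch=j,
                        grid=np.arange(1, cols.size + 1, dtype=float),
                        values=f[:, k],
                    )
                )
            continue
        col_names = [model.columns[c] for c in cols]
        for ci, cov in enumerate(col_names):
            lo, hi = scaler.range(cov)
            grid = (
                np.asarray(grids[cov], dtype=float)
                if grids and cov in grids
                else np.linspace(lo, hi, n_points)
            )
            x = np.tile(
                [scaler.transform_value(c, scaler.median(c)) for c in col_names],
                (grid.size, 1),
            )
            x[:, ci] = scaler.transform_value(cov, grid)
            f, _, _ = model.branch_output(fit.params, j, x)
            extrap = (grid < lo) | (grid > hi)
            for k, t in enumerate(b.targets):
                curves.append(
                    EffectCurve(
                        covariate=cov, parameter=t, branch=j,
                        grid=grid, values=f[:, k], extrapolated=extrap,
                    )
                )
    return curves


def relative_effect_curves(curves: list[EffectCurve],
                           reference: str = "middle") -> list[EffectCurve]:
    """Normalize raw branch factors to the population-PK effect convention.

    A branch factor carries both the covariate's *shape* and a share of the
    parameter's overall *scale* (only the product of all factors is
    identified).  Clinical-relevance reading of a covariate effect — e.g. the
    common "maximal net change below 20% is insignificant" rule — concerns the
    multiplicative deviation from a reference subject, so each curve is
    divided by its value at the reference grid point (the middle of the grid,
    i.e. the covariate median for default grids, or the first level of a
    categorical covariate).  A covariate with no learned effect has a
    relative curve identically 1.
    """
    out = []
    for c in curves:
        ref_idx = 0 if reference == "first" else c.grid.size // 2
        out.append(
            EffectCurve(
                covariate=c.covariate, parameter=c.parameter, branch=c.branch,
                grid=c.grid, values=c.values / c.values[ref_idx],
                extrapolated=c.extrapolated,
            )
        )
    return out


def mean_effect_curves(per_replicate: list[list[EffectCurve]]):
    """Pointwise mean of matching effect curves across model replicates.

    All replicates must share grids (same covariates, same architecture).
    Returns a list of EffectCurve with the averaged values.
    """
    if not per_replicate:
        return []
    ref = per_replicate[0]
    out = []
    for i, c in enumerate(ref):
        stack = np.stack([rep[i].values for rep in per_replicate])
        out.append(
            EffectCurve(
                covariate=c.covariate, parameter=c.parameter, branch=c.branch,
                grid=c.grid, values=stack.mean(axis=0),
                extrapolated=c.extrapolated,
            )
        )
    return out
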