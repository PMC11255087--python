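"""Robustness experiments: true-curve RMSE, Monte Carlo cross-validation,
and divergence-rate diagnostics.

A fitted model is scored against the *noise-free* simulated truth: predicted
and true concentration curves are collected on a five-minute grid to 72 h
(865 points) and compared by pooled root mean squared error over all test
subjects and grid points.  Robustness over repeated random train/test splits
and training replicates is summarized by the median RMSE, its standard
deviation, and the divergence rate — the percentage of replicates whose RMSE
exceeds 150% of the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import ConfigurationError, DataError, InvalidParameterError
from .nets import ArchitectureSpec, BranchSpec
from .pk import ConcentrationCurve, conc_events
from .simulate import DEFAULT_GRID, SimulatedStudy, true_curves_matrix
from .train import FitResult, TrainingProtocol, train


def curve_rmse(predicted, truth) -> float:
    """Pooled RMSE (IU/dL) between predicted and true curves.

    Accepts two :class:`ConcentrationCurve` objects (their grids must match)
    or two equally shaped arrays pooling several subjects.
    """
    if isinstance(predicted, ConcentrationCurve) or isinstance(
        truth, ConcentrationCurve
    ):
        if not (
            isinstance(predicted, ConcentrationCurve)
            and isinstance(truth, ConcentrationCurve)
        ):
            raise InvalidParameterError("cannot mix curves and raw arrays")
        if predicted.times.shape != truth.times.shape or not np.allclose(
            predicted.times, truth.times
        ):
            raise InvalidParameterError("curve grids do not match")
        p, t = predicted.values, truth.values
    else:
        p, t = np.asarray(predicted, dtype=float), np.asarray(truth, dtype=float)
        if p.shape != t.shape:
            raise InvalidParameterError(
                f"grid mismatch: shapes {p.shape} vs {t.shape}"
            )
    return float(np.sqrt(np.mean((p - t) ** 2)))


def divergence_rate(rmses) -> float:
    """Percentage of replicates with RMSE above 150% of the median RMSE."""
    r = np.asarray(rmses, dtype=float)
    if r.size == 0:
        raise InvalidParameterError("divergence_rate requires a non-empty list")
    med = np.median(r)
    return 100.0 * float(np.count_nonzero(r > 1.5 * med)) / r.size


def predicted_curves_matrix(fit: FitResult, dataset: Dataset,
                            grid=DEFAULT_GRID) -> np.ndarray:
    """Model-predicted curves for every subject, shape (n, len(grid))."""
    grid = np.asarray(grid, dtype=float)
    z = fit.predict_parameters(dataset)
    simple = all(
        len(s.regimen.events) == 1
        and s.regimen.events[0].time == 0.0
        and s.regimen.events[0].duration == 0.0
        for s in dataset.subjects
    )
    if simple:
        doses = np.array([s.regimen.events[0].amount for s in dataset.subjects])
        n = len(dataset)
        return np.real(
            conc_events(
                z[:, 0][:, None], z[:, 1][:, None], z[:, 2][:, None],
                z[:, 3][:, None],
                np.zeros((n, 1, 1)), doses[:, None, None], np.zeros((n, 1, 1)),
                grid[None, :],
            )
        )
    return np.stack([c.values for c in fit.predict_curves(dataset, grid)])


@dataclass
class ExperimentResult:
    """Per-replicate records plus the aggregate comparison table.

    ``records`` holds one row per (architecture, size, split, replicate) with
    its test RMSE and seeds; ``aggregates`` one row per (architecture, size)
    with median RMSE, SD of RMSE over all replicates, SD over split-level
    medians, and divergence rate (%).  Aggregates are recomputable from the
    records.
    """

    records: pd.DataFrame
    aggregates: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)


def aggregate_records(records: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (arch, size), g in records.groupby(["architecture", "size"], sort=False):
        split_medians = g.groupby("split")["rmse"].median()
        rows.append(
            {
                "architecture": arch,
                "size": size,
                "median_rmse": g["rmse"].median(),
                "sd_rmse": g["rmse"].std(ddof=1),
                "sd_split_medians": split_medians.std(ddof=1),
                "divergence_pct": divergence_rate(g["rmse"].to_numpy()),
                "n_replicates": len(g),
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_cv(
    study: SimulatedStudy,
    specs: dict[str, ArchitectureSpec],
    sizes=(20, 60, 120),
    n_splits: int = 20,
    n_reps: int = 5,
    protocol: TrainingProtocol = TrainingProtocol(),
    seed: int = 0,
    grid=DEFAULT_GRID,
    keep_fits: bool = False,
) -> ExperimentResult:
    """Monte Carlo cross-validation with replicated training.

    For each training-set size and split, a random train subset of that size
    is drawn and the *complement* is the test set.  Training is replicated
    ``n_reps`` times per split with fresh initialization seeds.  Every seed is
    derived deterministically from ``seed``, so the full result table is
    reproducible.  Models are scored by pooled true-curve RMSE on the test
    subjects (five-minute grid by default).
    """
    for name, spec in specs.items():
        missing = [
            c for c in spec.covariates if c not in study.frame.columns
        ]
        if missing:
            raise DataError(
                f"spec {name!r} uses unknown covariates {missing}; available: "
                f"{list(study.frame.columns)}"
            )
    sizes = tuple(int(s) for s in sizes)
    if max(sizes) >= study.n:
        raise ConfigurationError(
            f"largest train size {max(sizes)} needs a disjoint test set but the "
            f"study has only {study.n} subjects"
        )
    master = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    dataset = study.to_dataset()
    records = []
    fits: dict = {}
    for size in sizes:
        for split in range(n_splits):
            split_rng = np.random.default_rng(master.integers(2**31))
            train_idx = split_rng.choice(study.n, size=size, replace=False)
            test_idx = np.setdiff1d(np.arange(study.n), train_idx)
            train_set = dataset.subset(train_idx)
            test_set = dataset.subset(test_idx)
            truth = true_curves_matrix(study, test_idx, grid)
            for name, spec in specs.items():
                for rep in range(n_reps):
                    fit_seed = int(master.integers(2**31))
                    proto = TrainingProtocol(
                        epochs=protocol.epochs, lr=protocol.lr,
                        val_fraction=protocol.val_fraction, seed=fit_seed,
                        beta1=protocol.beta1, beta2=protocol.beta2,
                        eps=protocol.eps,
                    )
                    fit = train(train_set, spec, proto)
                    pred = predicted_curves_matrix(fit, test_set, grid)
                    rmse = curve_rmse(pred, truth)
                    records.append(
                        {
                            "architecture": name, "size": size, "split": split,
                            "replicate": rep, "rmse": rmse, "seed": fit_seed,
                        }
                    )
                    if keep_fits:
                        fits[(name, size, split, rep)] = fit
    rec = pd.DataFrame(records)
    return ExperimentResult(
        records=rec,
        aggregates=aggregate_records(rec),
        metadata={
            "seed": seed, "sizes": list(sizes), "n_splits": n_splits,
            "n_reps": n_reps, "epochs": protocol.epochs, "lr": protocol.lr,
            "test_set": "complement-of-train",
            "rmse_pooling": "pooled-over-subjects-and-gridpoints",
            "grid": {"start": float(grid[0]), "stop": float(grid[-1]),
                     "points": int(grid.size)},
        },
        fits=fits,
    )


def compare_covariate_sets(
    study: SimulatedStudy,
    specs: dict[str, ArchitectureSpec],
    sizes=(20, 60, 120),
    **kwargs,
) -> ExperimentResult:
    """Run the cross-validation over several covariate-set/architecture
    combinations (e.g. noise-augmented fully-connected vs all-covariate
    multi-branch vs causal multi-branch)."""
    return monte_carlo_cv(study, specs, sizes=sizes, **kwargs)


# ---------------------------------------------------------------------------
# Standard architecture constructors used by the experiments
# ---------------------------------------------------------------------------


def plot_spaghetti(curve_sets, observations=None, path=None, labels=None):
    """Overlay predicted concentration–time curves from several replicates
    for one subject (spaghetti plot), optionally with observed points.

    ``curve_sets`` is a sequence of :class:`ConcentrationCurve`;
    ``observations`` an optional (times, values) pair.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    stack = np.stack([c.values for c in curve_sets])
    for c in curve_sets:
        ax.plot(c.times, c.values, color="tab:blue", alpha=0.25, lw=0.8)
    ax.plot(curve_sets[0].times, np.median(stack, axis=0), color="black",
            lw=1.5, label="median prediction")
    if observations is not None:
        ax.plot(observations[0], observations[1], "k*", ms=9,
                label="observations")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (IU/dL)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def naive_spec(covariates, hidden_size: int = 8) -> ArchitectureSpec:
    return ArchitectureSpec(
        variant="naive", covariates=tuple(covariates), hidden_size=hidden_size
    )


def initialized_spec(covariates, typical_values,
                     hidden_size: int = 8) -> ArchitectureSpec:
    return ArchitectureSpec(
        variant="initialized", covariates=tuple(covariates),
        hidden_size=hidden_size, typical_values=typical_values,
    )


def boundary_spec(covariates, hidden_size: int = 8,
                  bounds=None, use_softsign: bool = False) -> ArchitectureSpec:
    return ArchitectureSpec(
        variant="boundary", covariates=tuple(covariates),
        hidden_size=hidden_size, bounds=bounds, use_softsign=use_softsign,
    )


def global_spec(covariates, hidden_size: int = 8,
                global_params=("Q", "V2")) -> ArchitectureSpec:
    return ArchitectureSpec(
        variant="global", covariates=tuple(covariates),
        hidden_size=hidden_size, global_params=tuple(global_params),
    )


def multibranch_all_spec(covariates, hidden_size: int = 16,
                         targets=("CL", "V1"),
                         global_params=("Q", "V2")) -> ArchitectureSpec:
    """Every covariate independently connected to the target parameters via
    its own sub-model."""
    branches = tuple(
        BranchSpec(covariates=(c,), targets=tuple(targets)) for c in covariates
    )
    return ArchitectureSpec(
        variant="multibranch", covariates=tuple(covariates),
        hidden_size=hidden_size, branches=branches,
        global_params=tuple(global_params),
    )


def causal_spec(hidden_size: int = 16) -> ArchitectureSpec:
    """The ground-truth wiring of the simulated study: fat-free mass (and age)
    drive clearance, fat-free mass drives central volume; Q and V2 global."""
    return ArchitectureSpec(
        variant="multibranch",
        covariates=("ffm", "age"),
        hidden_size=hidden_size,
        branches=(
            BranchSpec(covariates=("ffm", "age"), targets=("CL",)),
            BranchSpec(covariates=("ffm",), targets=("V1",)),
        ),
        global_params=("Q", "V2"),
    )
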