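"""Experiment orchestration: sampling, dataset generation, training, reports.

The default experiment reproduces the study protocol end to end from one
config object: Latin hypercube sampling of the 7-parameter box (baseline
values +/- 50%), N_H = 25 high-fidelity and N_L = 300 low-fidelity
simulations, per-quantity uncentered SVD truncated at 99% cumulative
variance, a 16-combination grid search by 3-fold cross-validation on PC1 of
ux (15 training / 10 test HF samples, folds of 10/5), final multi- and
single-fidelity surrogates per quantity, held-out metrics, and the
equivalent-cost model.

All randomness is derived from a single master seed through named
``numpy.random.SeedSequence`` children, so any two runs with the same
config hash reproduce identical metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from pulmoflow import reduction
from pulmoflow.evaluation import (
    HyperparameterGrid,
    equivalent_cost,
    grid_search,
    mae,
    r2_score,
    relative_error_at_peak,
    rmse,
    sample_landmarks,
)
from pulmoflow.mfnn import (
    MultiFidelityRegression,
    SingleFidelityRegression,
    TrainingConfig,
)
from pulmoflow.simulator import (
    BASELINE_PARAMETERS,
    FIDELITY_PRESETS,
    PARAMETER_NAMES,
    ParameterVector,
    ShellGeometry,
    ShellMesh,
    VentilatorWaveform,
    run_simulation,
    scatter_observation_nodes,
)

__all__ = [
    "QUANTITIES",
    "GEOMETRY_PRESETS",
    "table1_ranges",
    "sample_parameter_space",
    "ExperimentConfig",
    "SimulationDataset",
    "generate_dataset",
    "reduce_dataset",
    "run_experiment",
    "ExperimentReport",
    "cost_accuracy_sweep",
    "write_vtk_pointcloud",
]

QUANTITIES = ("ux", "uy", "uz", "palv")

#: Two independent lung analogues ("right"/"left") as shell-radii presets.
GEOMETRY_PRESETS = {
    "right": ShellGeometry(r_inner=5.0, r_outer=50.0),
    "left": ShellGeometry(r_inner=4.5, r_outer=45.0),
}


def table1_ranges() -> dict[str, tuple[float, float]]:
    """The +/-50% sampling box around the baseline parameter values."""
    base = BASELINE_PARAMETERS.as_array()
    return {
        name: (0.5 * value, 1.5 * value) for name, value in zip(PARAMETER_NAMES, base)
    }


def sample_parameter_space(
    n: int, ranges: dict[str, tuple[float, float]] | None = None, seed: int = 0
) -> np.ndarray:
    """Latin hypercube sample of the parameter box, shape (n, 7).

    Exactly one sample falls in each of the n equal-width strata per
    dimension; deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    ranges = ranges or table1_ranges()
    lo = np.array([ranges[name][0] for name in PARAMETER_NAMES])
    hi = np.array([ranges[name][1] for name in PARAMETER_NAMES])
    if np.any(hi <= lo):
        bad = [name for name in PARAMETER_NAMES if ranges[name][1] <= ranges[name][0]]
        raise ValueError(f"degenerate range(s): {bad}")
    sampler = qmc.LatinHypercube(d=len(PARAMETER_NAMES), seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, lo, hi)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """One reproducible experiment, defaulting to the full study protocol."""

    n_high: int = 25
    n_low: int = 300
    n_high_train: int = 15
    threshold: float = 0.99
    folds: int = 3
    seed: int = 0
    geometry: str = "right"
    ranges: dict | None = None
    epochs: int = 5000
    learning_rate: float = 1e-3
    grid: HyperparameterGrid = field(default_factory=HyperparameterGrid)
    scale_targets: bool = True
    # "measured" uses recorded wall times; a (T_L, T_H) pair in minutes
    # pins the cost arithmetic independent of hardware.
    cost_times: tuple[float, float] | str = "measured"
    # mesh/cloud overrides, mainly for scaled-down test runs
    n_el: dict = field(default_factory=lambda: {"H": 64, "L": 8})
    cloud_size: dict = field(default_factory=lambda: {"H": 2000, "L": 150})
    waveform_steps: int = 120

    def __post_init__(self) -> None:
        if not 2 <= self.n_high_train < self.n_high:
            raise ValueError("need 2 <= n_high_train < n_high")
        if self.geometry not in GEOMETRY_PRESETS:
            raise ValueError(f"unknown geometry preset {self.geometry!r}")

    @property
    def n_high_test(self) -> int:
        return self.n_high - self.n_high_train

    def parameter_ranges(self) -> dict[str, tuple[float, float]]:
        return dict(self.ranges) if self.ranges else table1_ranges()

    def training_config(self, seed: int) -> TrainingConfig:
        return TrainingConfig(learning_rate=self.learning_rate, epochs=self.epochs, seed=seed)

    def seeds(self) -> dict[str, int]:
        """Named child seeds derived from the master seed (all < 2**31)."""
        names = (
            "sample_high",
            "sample_low",
            "cloud_high",
            "cloud_low",
            "split",
            "folds",
            "init",
            "landmarks",
        )
        ss = np.random.SeedSequence(self.seed)
        state = ss.generate_state(len(names)) % (2**31)
        return {name: int(s) for name, s in zip(names, state)}

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["grid"] = dataclasses.asdict(self.grid)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "grid" in raw:
            g = raw["grid"]
            raw["grid"] = HyperparameterGrid(
                lambdas=tuple(g.get("lambdas", (1e-1, 1e-3))),
                n_neurons=tuple(g.get("n_neurons", (30, 60))),
                n_layers=tuple(g.get("n_layers", (3, 6))),
                activations=tuple(g.get("activations", ("tanh", "relu"))),
            )
        if "cost_times" in raw and isinstance(raw["cost_times"], list):
            raw["cost_times"] = tuple(raw["cost_times"])
        return cls(**raw)


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------


@dataclass
class SimulationDataset:
    """N simulations of one fidelity on a shared observation cloud."""

    fidelity: str
    params: np.ndarray  # (N, 7)
    responses: dict  # quantity -> (N, K, T)
    cloud: np.ndarray  # (K, 3)
    times: np.ndarray  # (T,)
    wall_times_s: np.ndarray  # (N,)
    seeds: dict
    config_hash: str = ""

    @property
    def N(self) -> int:
        return self.params.shape[0]

    @property
    def K(self) -> int:
        return self.cloud.shape[0]

    @property
    def T(self) -> int:
        return self.times.size

    def response_list(self):
        from pulmoflow.simulator import SpatioTemporalResponse

        out = []
        for n in range(self.N):
            out.append(
                SpatioTemporalResponse(
                    ux=self.responses["ux"][n],
                    uy=self.responses["uy"][n],
                    uz=self.responses["uz"][n],
                    palv=self.responses["palv"][n],
                    cloud=self.cloud,
                    times=self.times,
                    fidelity=self.fidelity,
                )
            )
        return out

    def mean_wall_minutes(self) -> float:
        return float(np.mean(self.wall_times_s) / 60.0)

    # -- HDF5 persistence ----------------------------------------------------

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["fidelity"] = self.fidelity
            f.attrs["config_hash"] = self.config_hash
            f.attrs["seeds"] = json.dumps(self.seeds)
            f.create_dataset("params", data=self.params)
            f.create_dataset("cloud", data=self.cloud)
            f.create_dataset("times", data=self.times)
            f.create_dataset("wall_times_s", data=self.wall_times_s)
            g = f.create_group("responses")
            for q, arr in self.responses.items():
                g.create_dataset(q, data=arr)

    @classmethod
    def from_hdf5(cls, path) -> "SimulationDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                fidelity=str(f.attrs["fidelity"]),
                params=f["params"][...],
                responses={q: f["responses"][q][...] for q in f["responses"]},
                cloud=f["cloud"][...],
                times=f["times"][...],
                wall_times_s=f["wall_times_s"][...],
                seeds=json.loads(f.attrs["seeds"]),
                config_hash=str(f.attrs["config_hash"]),
            )


def generate_dataset(
    config: ExperimentConfig,
    fidelity: str,
    params: np.ndarray | None = None,
) -> SimulationDataset:
    """Run the N_F simulations of one fidelity level.

    Samples an independent Latin hypercube design unless an explicit
    parameter matrix is given; records per-run wall time for the cost
    model.  Solver errors propagate annotated with the run index.
    """
    if fidelity not in FIDELITY_PRESETS:
        raise ValueError("fidelity must be 'H' or 'L'")
    seeds = config.seeds()
    geometry = GEOMETRY_PRESETS[config.geometry]
    n = config.n_high if fidelity == "H" else config.n_low
    if params is None:
        params = sample_parameter_space(
            n, config.parameter_ranges(), seeds[f"sample_{'high' if fidelity == 'H' else 'low'}"]
        )
    params = np.atleast_2d(np.asarray(params, dtype=float))
    cloud = scatter_observation_nodes(
        config.cloud_size[fidelity],
        geometry.r_inner,
        geometry.r_outer,
        seeds[f"cloud_{'high' if fidelity == 'H' else 'low'}"],
    )
    mesh = ShellMesh(geometry=geometry, n_el=config.n_el[fidelity])

    N, K = params.shape[0], cloud.shape[0]
    T = config.waveform_steps
    responses = {q: np.empty((N, K, T)) for q in QUANTITIES}
    wall = np.empty(N)
    times = None
    for i, row in enumerate(params):
        xi = ParameterVector.from_array(row)
        waveform = VentilatorWaveform(pip=xi.p_pip, n_steps=T)
        t0 = time.perf_counter()
        try:
            _, resp = run_simulation(xi, fidelity, mesh=mesh, cloud=cloud, waveform=waveform)
        except Exception as exc:
            raise type(exc)(f"simulation {i} ({fidelity}) failed: {exc}") from exc
        wall[i] = time.perf_counter() - t0
        times = resp.times
        for q in QUANTITIES:
            responses[q][i] = resp.field(q)
    return SimulationDataset(
        fidelity=fidelity,
        params=params,
        responses=responses,
        cloud=cloud,
        times=times,
        wall_times_s=wall,
        seeds=seeds,
        config_hash=config.hash(),
    )


def reduce_dataset(dataset: SimulationDataset, threshold: float = 0.99) -> dict:
    """Per-quantity truncated SVD of a dataset.

    Returns ``{quantity: (basis, scores)}`` with ``scores`` the N x k
    truncated score matrix of the dataset rows.
    """
    out = {}
    responses = dataset.response_list()
    for q in QUANTITIES:
        Z = reduction.assemble_output_matrix(responses, q)
        basis = reduction.fit_reduction(Z, threshold=threshold)
        scores = reduction.transform(Z, basis).scores
        out[q] = (basis, scores)
    return out


# --------------------------------------------------------------------------
# end-to-end experiment
# --------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """Everything produced by one end-to-end experiment run."""

    config: ExperimentConfig
    seeds: dict
    train_idx: np.ndarray
    test_idx: np.ndarray
    best_hp: dict  # model kind -> winning hyperparameters
    leaderboards: dict  # model kind -> grid-search leaderboard
    cv_scores: dict  # model kind -> (mean, sd)
    metrics: pd.DataFrame
    cost: dict  # model kind -> CostReport
    bases: dict  # quantity -> high-fidelity ReducedBasis
    models: dict  # (kind, quantity) -> fitted results object
    timings_s: dict

    def summary(self) -> str:
        lines = [
            f"experiment seed={self.config.seed} hash={self.config.hash()}",
            f"HF split: {self.train_idx.size} train / {self.test_idx.size} test; "
            f"N_L={self.config.n_low}",
            f"best rMFNN hp: {self.best_hp['mf']}  (CV R2 "
            f"{100 * self.cv_scores['mf'][0]:.1f} +/- {100 * self.cv_scores['mf'][1]:.1f} %)",
            f"best rSFNN hp: {self.best_hp['sf']}  (CV R2 "
            f"{100 * self.cv_scores['sf'][0]:.1f} +/- {100 * self.cv_scores['sf'][1]:.1f} %)",
            f"cost: rMFNN C_eq={self.cost['mf'].C_eq:.2f}, rSFNN C_eq={self.cost['sf'].C_eq:.2f}",
            "",
            self.metrics.to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(d / "metrics.csv", index=False)
        for kind, board in self.leaderboards.items():
            board.to_csv(d / f"leaderboard_{kind}.csv", index=False)
        payload = {
            "config_hash": self.config.hash(),
            "seeds": self.seeds,
            "best_hp": self.best_hp,
            "cv_scores": {k: list(v) for k, v in self.cv_scores.items()},
            "cost": {k: dataclasses.asdict(v) for k, v in self.cost.items()},
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "timings_s": self.timings_s,
        }
        (d / "summary.json").write_text(json.dumps(payload, indent=2))


def _fit_final(kind, config, hp, X_low, scores_low, X_train, y_train, seed):
    cfg = config.training_config(seed)
    if kind == "mf":
        model = MultiFidelityRegression(
            X_low, scores_low, X_train, y_train, scale_targets=config.scale_targets, **hp
        )
    else:
        model = SingleFidelityRegression(
            X_train, y_train, scale_targets=config.scale_targets, **hp
        )
    return model.fit(cfg)


def run_experiment(
    config: ExperimentConfig | None = None,
    *,
    datasets: tuple[SimulationDataset, SimulationDataset] | None = None,
) -> ExperimentReport:
    """Sample -> simulate -> reduce -> grid-search + train -> evaluate.

    ``datasets`` may inject pre-generated (high, low) datasets matching the
    config, to reuse expensive simulations across analyses.
    """
    config = config or ExperimentConfig()
    seeds = config.seeds()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if datasets is None:
        ds_high = generate_dataset(config, "H")
        ds_low = generate_dataset(config, "L")
    else:
        ds_high, ds_low = datasets
        if ds_high.fidelity != "H" or ds_low.fidelity != "L":
            raise ValueError("datasets must be ordered (high, low)")
    timings["simulate"] = time.perf_counter() - t0

    # reduction fitted on the full HF design (the split applies to surrogate
    # training only), exactly as the experiment protocol prescribes
    t0 = time.perf_counter()
    red_high = reduce_dataset(ds_high, config.threshold)
    red_low = reduce_dataset(ds_low, config.threshold)
    timings["reduce"] = time.perf_counter() - t0

    rng_split = np.random.default_rng(seeds["split"])
    perm = rng_split.permutation(config.n_high)
    train_idx = np.sort(perm[: config.n_high_train])
    test_idx = np.sort(perm[config.n_high_train :])

    X_high = ds_high.params
    X_low = ds_low.params
    scores_low = {q: red_low[q][1] for q in QUANTITIES}
    scores_high = {q: red_high[q][1] for q in QUANTITIES}

    # grid search on ux (PC1), winner reused for the other quantities
    best_hp, leaderboards, cv_scores = {}, {}, {}
    cfg_train = config.training_config(seeds["init"])
    t0 = time.perf_counter()
    for kind in ("mf", "sf"):
        best, board = grid_search(
            X_high[train_idx],
            scores_high["ux"][train_idx],
            mode=kind,
            X_low=X_low if kind == "mf" else None,
            y_low=scores_low["ux"] if kind == "mf" else None,
            grid=config.grid,
            folds=config.folds,
            seed=seeds["folds"],
            config=cfg_train,
            scale_targets=config.scale_targets,
        )
        best_hp[kind] = best
        leaderboards[kind] = board
        cv_scores[kind] = (float(board.iloc[0]["mean_r2"]), float(board.iloc[0]["sd_r2"]))
    timings["grid_search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    models = {}
    rows = []
    peak = VentilatorWaveform(pip=1.0, n_steps=config.waveform_steps).peak_index
    landmarks = sample_landmarks(
        ds_high.K, n=min(100, ds_high.K), seed=seeds["landmarks"]
    )
    for kind in ("mf", "sf"):
        for q in QUANTITIES:
            res = _fit_final(
                kind,
                config,
                best_hp[kind],
                X_low,
                scores_low[q],
                X_high[train_idx],
                scores_high[q][train_idx],
                seeds["init"],
            )
            models[(kind, q)] = res
            y_true = scores_high[q][test_idx]
            y_pred = res.predict(X_high[test_idx])
            basis = red_high[q][0]
            fields_pred = (
                reduction.reconstruct(y_pred, basis).values.reshape(test_idx.size, basis.T, basis.K)
            )
            fields_true = ds_high.responses[q][test_idx]  # (n, K, T)
            z_pred_peak = fields_pred[:, peak, :][:, landmarks]
            z_true_peak = fields_true[:, landmarks, peak]
            rel = relative_error_at_peak(z_true_peak.ravel(), z_pred_peak.ravel())
            rows.append(
                {
                    "model": "rMFNN" if kind == "mf" else "rSFNN",
                    "quantity": q,
                    "r2_pct": 100.0 * r2_score(y_true, y_pred),
                    "r2_pc1_pct": 100.0 * r2_score(y_true[:, 0], y_pred[:, 0]),
                    "mae": mae(y_true, y_pred),
                    "rmse": rmse(y_true, y_pred),
                    "k": basis.k,
                    "median_rel_err_peak_pct": float(np.median(rel)),
                }
            )
    timings["train_evaluate"] = time.perf_counter() - t0

    if config.cost_times == "measured":
        T_L = ds_low.mean_wall_minutes()
        T_H = ds_high.mean_wall_minutes()
    else:
        T_L, T_H = config.cost_times
    cost = {
        "mf": equivalent_cost(train_idx.size, config.n_low, T_L, T_H),
        "sf": equivalent_cost(train_idx.size, 0, T_L, T_H),
    }

    return ExperimentReport(
        config=config,
        seeds=seeds,
        train_idx=train_idx,
        test_idx=test_idx,
        best_hp=best_hp,
        leaderboards=leaderboards,
        cv_scores=cv_scores,
        metrics=pd.DataFrame(rows),
        cost=cost,
        bases={q: red_high[q][0] for q in QUANTITIES},
        models=models,
        timings_s=timings,
    )


def cost_accuracy_sweep(
    config: ExperimentConfig,
    nh_list,
    nl_list,
    seeds,
    *,
    datasets: tuple[SimulationDataset, SimulationDataset] | None = None,
    hp_mf: dict | None = None,
    hp_sf: dict | None = None,
) -> pd.DataFrame:
    """Cost-accuracy trade-off: RMSE of ux score predictions vs C_eq.

    For each HF training size in ``nh_list``, each LF dataset size in
    ``nl_list`` (0 selects the single-fidelity baseline) and each seed,
    trains the surrogate with the given (or default-winning) architectures
    and records the test RMSE of the ux principal-component predictions and
    the equivalent HF training cost.
    """
    if datasets is None:
        ds_high = generate_dataset(config, "H")
        ds_low = generate_dataset(config, "L")
    else:
        ds_high, ds_low = datasets
    red_high = reduce_dataset(ds_high, config.threshold)
    red_low = reduce_dataset(ds_low, config.threshold)
    base_seeds = config.seeds()
    perm = np.random.default_rng(base_seeds["split"]).permutation(config.n_high)
    test_idx = np.sort(perm[config.n_high_train :])
    train_pool = perm[: config.n_high_train]
    hp_mf = hp_mf or {"reg_lambda": 1e-3, "n_neurons": 60, "n_layers": 6, "activation": "tanh"}
    hp_sf = hp_sf or {"reg_lambda": 1e-1, "n_neurons": 30, "n_layers": 3, "activation": "tanh"}

    if config.cost_times == "measured":
        T_L, T_H = ds_low.mean_wall_minutes(), ds_high.mean_wall_minutes()
    else:
        T_L, T_H = config.cost_times

    X_high = ds_high.params
    y_high = red_high["ux"][1]
    X_low_full = ds_low.params
    y_low_full = red_low["ux"][1]
    y_test = y_high[test_idx]

    rows = []
    for nh in nh_list:
        if not 2 <= nh <= train_pool.size:
            raise ValueError(f"infeasible HF training size {nh}")
        tr = np.sort(train_pool[:nh])
        for nl in nl_list:
            if nl > X_low_full.shape[0]:
                raise ValueError(f"infeasible LF size {nl}")
            for seed in seeds:
                cfg = config.training_config(seed)
                if nl == 0:
                    res = SingleFidelityRegression(
                        X_high[tr], y_high[tr], scale_targets=config.scale_targets, **hp_sf
                    ).fit(cfg)
                    model_name = "rSFNN"
                    cost = equivalent_cost(nh, 0, T_L, T_H)
                else:
                    res = MultiFidelityRegression(
                        X_low_full[:nl],
                        y_low_full[:nl],
                        X_high[tr],
                        y_high[tr],
                        scale_targets=config.scale_targets,
                        **hp_mf,
                    ).fit(cfg)
                    model_name = "rMFNN"
                    cost = equivalent_cost(nh, nl, T_L, T_H)
                rows.append(
                    {
                        "model": model_name,
                        "n_high_train": nh,
                        "n_low": nl,
                        "seed": seed,
                        "rmse_ux_scores": rmse(y_test, res.predict(X_high[test_idx])),
                        "C_eq": cost.C_eq,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# optional visualization export
# --------------------------------------------------------------------------


def write_vtk_pointcloud(path, cloud: np.ndarray, point_data: dict) -> None:
    """Write one snapshot as a legacy ASCII VTK point cloud.

    ``point_data`` maps field names to per-point scalars (length K).
    """
    cloud = np.asarray(cloud, dtype=float)
    K = cloud.shape[0]
    lines = [
        "# vtk DataFile Version 3.0",
        "pulmoflow snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {K} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in cloud]
    lines.append(f"POINT_DATA {K}")
    for name, values in point_data.items():
        values = np.asarray(values, dtype=float)
        if values.shape != (K,):
            raise ValueError(f"field {name!r} must have length {K}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")
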