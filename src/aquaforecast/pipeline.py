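"""End-to-end orchestration: denoise -> tune -> train -> evaluate.

The full forecasting procedure for one sensor series:

1. joint VMD + wavelet-packet denoising of the whole series (with the VMD
   pair (k, alpha) either fixed or chosen by relative-entropy selection);
2. chronological 80/20 train/test split; the last 20% of the training
   portion is held out as a validation segment for hyperparameter fitness;
3. whale-algorithm search over six GRU hyperparameters (learning rate,
   epochs, two hidden widths, batch size, window length), each candidate
   scored by its validation MSE after training on the remaining train data;
4. retraining of the best configuration on the full training portion;
5. evaluation on the untouched test portion with MAE, MSE and R^2 on the
   original physical scale.

Denoising deliberately precedes the split, mirroring the front-to-back
order of the modelled procedure; the resulting (mild) leakage of test-set
smoothing information is documented in the methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gru import GRUHyperparams, GRUWeights, predict, train_gru
from .iwoa import IWOAConfig, OptimizeResult, SearchSpace, optimize
from .mode_selection import select_vmd_parameters
from .timeseries import (ScalingTransform, UniformSeries, fit_apply_scaling,
                         make_windows, split_train_test)
from .vmd import VMDConfig
from .wavelet_denoise import ThresholdSpec, joint_denoise

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "PipelineConfig",
    "PipelineResult",
    "evaluate_metrics",
    "decode_hyperparams",
    "default_search_space",
    "small_search_space",
    "hyperparam_fitness",
    "run_pipeline",
    "run_fixed_gru",
    "DEFAULT_BASELINE_HP",
]

PENALTY_FITNESS = 1e6


@dataclass(frozen=True)
class MetricsReport:
    """MAE, MSE and coefficient of determination R^2 over n samples.

    MAE = mean |y - yhat|; MSE = mean (y - yhat)^2;
    R^2 = 1 - sum (yhat - y)^2 / sum (y - ybar)^2.
    """

    mae: float
    mse: float
    r2: float
    n: int


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Standard regression metrics; errors if R^2 is undefined (constant truth)."""
    y = np.asarray(y_true, float)
    yh = np.asarray(y_pred, float)
    if y.size != yh.size or y.size < 2:
        raise ValueError("need equal lengths >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    err = y - yh
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        mse=float(np.mean(err ** 2)),
        r2=1.0 - float(np.sum(err ** 2)) / ss_tot,
        n=y.size,
    )


def default_search_space() -> SearchSpace:
    """Bounds of the six tuned hyperparameters.

    learning rate 1e-4..1e-1 (log10 scale), epochs 10..100, hidden widths
    4..64 each, batch size 8..64, window length 4..36.
    """
    return SearchSpace(
        lower=np.array([1e-4, 10, 4, 4, 8, 4], dtype=float),
        upper=np.array([1e-1, 100, 64, 64, 64, 36], dtype=float),
        integer_mask=np.array([False, True, True, True, True, True]),
        log_scale_mask=np.array([True, False, False, False, False, False]),
    )


def small_search_space() -> SearchSpace:
    """Desk-scale variant of :func:`default_search_space` for quick runs.

    Same six dimensions, narrower ranges (epochs 5..30, widths 4..24,
    windows 4..16) so a full tuning pass completes in minutes on one core.
    """
    return SearchSpace(
        lower=np.array([1e-3, 5, 4, 4, 16, 4], dtype=float),
        upper=np.array([5e-2, 30, 24, 24, 64, 16], dtype=float),
        integer_mask=np.array([False, True, True, True, True, True]),
        log_scale_mask=np.array([True, False, False, False, False, False]),
    )


def decode_hyperparams(position: np.ndarray) -> GRUHyperparams:
    """Map a decoded 6-vector (original-scale) onto GRUHyperparams."""
    lr, epochs, h1, h2, bs, ts = position
    return GRUHyperparams(
        learning_rate=float(lr), epochs=int(round(epochs)),
        hidden1=int(round(h1)), hidden2=int(round(h2)),
        batch_size=int(round(bs)), timesteps=int(round(ts)),
    )


def hyperparam_fitness(position: np.ndarray, fit_values: np.ndarray,
                       val_values: np.ndarray, scaling: ScalingTransform,
                       seed: int) -> float:
    """Validation MSE (original scale) of a GRU trained at *position*.

    *fit_values* and *val_values* are contiguous scaled segments; validation
    windows straddle the boundary so every validation point is predicted
    from real history.  Degenerate decodes (window longer than the fitting
    segment) and diverging training return a large penalty.
    """
    try:
        hp = decode_hyperparams(np.asarray(position, float))
    except ValueError:
        logger.warning("undecodable position %s; penalty", position)
        return PENALTY_FITNESS
    if hp.timesteps >= fit_values.size:
        logger.warning("timesteps %d >= fit length %d; penalty", hp.timesteps, fit_values.size)
        return PENALTY_FITNESS
    try:
        weights, _ = train_gru(make_windows(fit_values, hp.timesteps), hp, seed=seed)
        # prepend history so the first validation point has a full window
        joined = np.concatenate([fit_values[-hp.timesteps:], val_values])
        val_ds = make_windows(joined, hp.timesteps)
        preds = predict(weights, val_ds, scaling)
        truth = scaling.inverse(val_ds.targets)
    except FloatingPointError as exc:
        logger.warning("training diverged (%s); penalty", exc)
        return PENALTY_FITNESS
    return float(np.mean((preds - truth) ** 2))


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the end-to-end run; ``vmd=None`` selects (k, alpha) by
    relative entropy."""

    vmd: VMDConfig | None = None
    threshold: ThresholdSpec = ThresholdSpec()
    iwoa: IWOAConfig = IWOAConfig()
    space: SearchSpace = field(default_factory=default_search_space)
    train_fraction: float = 0.8
    validation_fraction_of_train: float = 0.2
    correlation_cutoff: float = 0.5
    denoise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1) or not (0 < self.validation_fraction_of_train < 1):
            raise ValueError("fractions must lie in (0, 1)")


@dataclass
class PipelineResult:
    metrics: MetricsReport
    best_hyperparams: GRUHyperparams
    best_fitness: float
    weights: GRUWeights
    predictions: np.ndarray
    y_true: np.ndarray
    vmd_config: VMDConfig | None
    correlations: np.ndarray | None
    denoised_indices: list[int] | None
    selection_traces: tuple | None
    optimizer_history: np.ndarray
    scaling: ScalingTransform


DEFAULT_BASELINE_HP = GRUHyperparams(learning_rate=1e-2, epochs=30, hidden1=16,
                                     hidden2=16, batch_size=32, timesteps=12)


def run_fixed_gru(series: UniformSeries, hp: GRUHyperparams = DEFAULT_BASELINE_HP,
                  config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Same stages as :func:`run_pipeline` but with fixed hyperparameters.

    This is the untuned-GRU baseline against which the whale-tuned model is
    compared; it shares denoising, splitting, scaling and evaluation code
    so any difference in test metrics is attributable to the tuning.
    """
    rng = np.random.default_rng(config.seed)
    _, _, seed_fit, _ = rng.integers(0, 2**31 - 1, size=4)

    vmd_cfg = config.vmd
    correlations = denoised_idx = None
    if config.denoise:
        if vmd_cfg is None:
            vmd_cfg, _, _ = select_vmd_parameters(series)
        cleaned, art = joint_denoise(series, vmd_cfg, config.threshold,
                                     config.correlation_cutoff)
        correlations, denoised_idx = art["correlations"], art["denoised"]
    else:
        cleaned = series

    train, test = split_train_test(cleaned, config.train_fraction)
    scaled_train, (scaled_test,), scaling = fit_apply_scaling(train, [test])
    weights, _ = train_gru(make_windows(scaled_train, hp.timesteps), hp,
                           seed=int(seed_fit))
    joined = np.concatenate([scaled_train[-hp.timesteps:], scaled_test])
    test_ds = make_windows(joined, hp.timesteps)
    preds = predict(weights, test_ds, scaling)
    truth = scaling.inverse(test_ds.targets)
    return PipelineResult(
        metrics=evaluate_metrics(truth, preds), best_hyperparams=hp,
        best_fitness=float("nan"), weights=weights, predictions=preds,
        y_true=truth, vmd_config=vmd_cfg, correlations=correlations,
        denoised_indices=denoised_idx, selection_traces=None,
        optimizer_history=np.array([]), scaling=scaling,
    )


def run_pipeline(series: UniformSeries, config: PipelineConfig = PipelineConfig()
                 ) -> PipelineResult:
    """Execute the full denoise -> tune -> train -> evaluate procedure."""
    rng = np.random.default_rng(config.seed)
    # independent sub-seeds, kept below 2**31
    seed_sel, seed_opt, seed_fit, seed_final = rng.integers(0, 2**31 - 1, size=4)

    # ---- stage 1: denoising --------------------------------------------
    vmd_cfg = config.vmd
    traces = None
    correlations = None
    denoised_idx = None
    if config.denoise:
        if vmd_cfg is None:
            vmd_cfg, k_trace, a_trace = select_vmd_parameters(series, seed=int(seed_sel))
            traces = (k_trace, a_trace)
            logger.info("selected k=%d alpha=%.0f", vmd_cfg.k, vmd_cfg.alpha)
        cleaned, art = joint_denoise(series, vmd_cfg, config.threshold,
                                     config.correlation_cutoff)
        correlations = art["correlations"]
        denoised_idx = art["denoised"]
    else:
        cleaned = series

    # ---- stage 2: split and scale --------------------------------------
    train, test = split_train_test(cleaned, config.train_fraction)
    scaled_train, (scaled_test,), scaling = fit_apply_scaling(train, [test])
    n_val = max(2, int(np.floor(config.validation_fraction_of_train * len(train))))
    fit_vals, val_vals = scaled_train[:-n_val], scaled_train[-n_val:]

    # ---- stage 3: hyperparameter search --------------------------------
    def fitness(position: np.ndarray) -> float:
        return hyperparam_fitness(position, fit_vals, val_vals, scaling, int(seed_fit))

    opt: OptimizeResult = optimize(fitness, config.space,
                                   IWOAConfig(**{**config.iwoa.__dict__, "seed": int(seed_opt)}))
    best_hp = decode_hyperparams(opt.best_position)

    # ---- stage 4: retrain on the full training portion -----------------
    # retrain with the same seed the fitness used: the tuner selected the
    # configuration under this initialization/shuffling stream
    weights, _ = train_gru(make_windows(scaled_train, best_hp.timesteps),
                           best_hp, seed=int(seed_fit))

    # ---- stage 5: test evaluation --------------------------------------
    joined = np.concatenate([scaled_train[-best_hp.timesteps:], scaled_test])
    test_ds = make_windows(joined, best_hp.timesteps)
    preds = predict(weights, test_ds, scaling)
    truth = scaling.inverse(test_ds.targets)
    metrics = evaluate_metrics(truth, preds)

    return PipelineResult(
        metrics=metrics,
        best_hyperparams=best_hp,
        best_fitness=opt.best_fitness,
        weights=weights,
        predictions=preds,
        y_true=truth,
        vmd_config=vmd_cfg,
        correlations=correlations,
        denoised_indices=denoised_idx,
        selection_traces=traces,
        optimizer_history=opt.history,
        scaling=scaling,
    )
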