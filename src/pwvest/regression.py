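"""PWV-based regression estimators of Z_ao and C_T.

statsmodels-style interface: :class:`PWVRegression` is built from a cohort
feature table (one row per subject) and a choice of target, estimator family
and input configuration; :meth:`PWVRegression.fit` tunes the single free
hyperparameter on the validation split (forest depth by validation R^2,
network epochs by early stopping on validation MSE) and returns a
:class:`PWVRegressionResults` carrying the fitted estimator, the scaler
state, the test-set agreement report and diagnostics.

Input configurations:

* M1: brSBP, brDBP, HR, cfPWV, crPWV   (main)
* M2: M1 without HR
* M3: MAP, cfPWV, crPWV
* M4: cfPWV, crPWV
* cfPWV_only: cfPWV                     (single-input baseline)

Features are min-max rescaled to [0, 1] with statistics of the training
partition only; the network target is rescaled the same way (and predictions
mapped back); the forest predicts in physical units directly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor

from .stats import EvaluationReport, evaluate, nrmse, rmse

CONFIGURATIONS = {
    "M1": ["brSBP", "brDBP", "HR", "cfPWV", "crPWV"],
    "M2": ["brSBP", "brDBP", "cfPWV", "crPWV"],
    "M3": ["MAP", "cfPWV", "crPWV"],
    "M4": ["cfPWV", "crPWV"],
    "cfPWV_only": ["cfPWV"],
}

TARGET_COLUMNS = {"zao": "Zao_true", "ct": "CT_true"}

FOREST_DEFAULTS = {"n_trees": 100, "max_depth": None, "depth_grid": range(1, 11)}
NETWORK_DEFAULTS = {"hidden_units": 16, "batch_size": 10, "epochs": None,
                    "max_epochs": 300, "patience": 10}


@dataclass
class SplitSpec:
    """Random train/validation/test partition fractions."""

    train: float = 0.60
    val: float = 0.20
    test: float = 0.20
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("all split fractions must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(table: pd.DataFrame, spec: SplitSpec | None = None):
    """Disjoint random (train, val, test) partition of a feature table.

    Validation and test sizes are rounded to the nearest integer and the
    training set takes the remainder, so n = 3,818 at 60/20/20 gives exactly
    2,290/764/764.
    """
    spec = spec or SplitSpec()
    n = len(table)
    if n == 0:
        raise ValueError("empty table")
    n_val = int(round(spec.val * n))
    n_test = int(round(spec.test * n))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} rows leaves an empty partition")
    rng = np.random.default_rng(spec.rng_seed)
    perm = rng.permutation(n)
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]
    return (table.iloc[idx_train].reset_index(drop=True),
            table.iloc[idx_val].reset_index(drop=True),
            table.iloc[idx_test].reset_index(drop=True))


class MinMaxState:
    """Per-column min-max rescaling to [0, 1], fitted on the training set."""

    def __init__(self, minima: dict[str, float], maxima: dict[str, float]):
        self.minima = dict(minima)
        self.maxima = dict(maxima)
        for c in self.minima:
            if self.maxima[c] == self.minima[c]:
                raise ValueError(f"zero-range feature {c!r}: scaler undefined")

    @classmethod
    def fit(cls, table: pd.DataFrame, columns) -> "MinMaxState":
        return cls({c: float(table[c].min()) for c in columns},
                   {c: float(table[c].max()) for c in columns})

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.minima:
            out[c] = (table[c] - self.minima[c]) / (self.maxima[c] - self.minima[c])
        return out

    def transform_array(self, table: pd.DataFrame) -> np.ndarray:
        cols = list(self.minima)
        x = table[cols].to_numpy(dtype=float)
        lo = np.array([self.minima[c] for c in cols])
        hi = np.array([self.maxima[c] for c in cols])
        return (x - lo) / (hi - lo)

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.minima:
            out[c] = table[c] * (self.maxima[c] - self.minima[c]) + self.minima[c]
        return out


def fit_scaler(train: pd.DataFrame, columns) -> MinMaxState:
    """Min-max scaler state from the training partition only."""
    return MinMaxState.fit(train, columns)


def apply_scaler(state: MinMaxState, table: pd.DataFrame) -> pd.DataFrame:
    """Rescale columns by a fitted state; values outside [0,1] are allowed."""
    return state.transform(table)


class PWVRegression:
    """Regression model of Z_ao or C_T from cuff pressure and regional PWVs.

    Parameters
    ----------
    data : DataFrame
        Cohort feature table; must contain the configuration's feature
        columns and the target column (Zao_true or CT_true).
    target : 'zao' | 'ct'
    family : 'forest' | 'network'
    configuration : 'M1'..'M4' | 'cfPWV_only' | explicit list of columns
    split : SplitSpec
    hyperparameters : dict, optional
        Overrides of FOREST_DEFAULTS / NETWORK_DEFAULTS. With
        max_depth/epochs left at None the value is tuned on the validation
        split during fit().
    rng_seed : int
        Seeds the estimator (forest bootstrap / network initialization).
    """

    def __init__(self, data: pd.DataFrame, target: str = "zao",
                 family: str = "forest", configuration="M1",
                 split: SplitSpec | None = None,
                 hyperparameters: dict | None = None, rng_seed: int = 0):
        if target not in TARGET_COLUMNS:
            raise ValueError(f"target must be one of {sorted(TARGET_COLUMNS)}")
        if family not in ("forest", "network"):
            raise ValueError("family must be 'forest' or 'network'")
        if isinstance(configuration, str):
            if configuration not in CONFIGURATIONS:
                raise ValueError(f"unknown configuration {configuration!r}")
            self.feature_names = list(CONFIGURATIONS[configuration])
            self.configuration = configuration
        else:
            self.feature_names = list(configuration)
            self.configuration = "custom"
        self.target = target
        self.target_column = TARGET_COLUMNS[target]
        missing = [c for c in self.feature_names + [self.target_column]
                   if c not in data.columns]
        if missing:
            raise ValueError(f"data table lacks columns {missing}")
        self.family = family
        self.data = data.reset_index(drop=True)
        self.split = split or SplitSpec()
        defaults = FOREST_DEFAULTS if family == "forest" else NETWORK_DEFAULTS
        self.hyperparameters = {**defaults, **(hyperparameters or {})}
        self.rng_seed = rng_seed

    # -- estimator construction ------------------------------------------
    def _make_forest(self, max_depth: int | None) -> RandomForestRegressor:
        return RandomForestRegressor(n_estimators=self.hyperparameters["n_trees"],
                                     max_depth=max_depth,
                                     random_state=self.rng_seed, n_jobs=1)

    def _make_network(self) -> MLPRegressor:
        return MLPRegressor(hidden_layer_sizes=(self.hyperparameters["hidden_units"],),
                            activation="relu", solver="adam",
                            batch_size=self.hyperparameters["batch_size"],
                            max_iter=1, warm_start=True,
                            random_state=self.rng_seed)

    # -- tuning -----------------------------------------------------------
    def tune_forest_depth(self, x_train, y_train, x_val, y_val):
        """Validation-R^2 depth selection over the configured grid.

        Returns (best_depth, history DataFrame). Ties resolve to the
        smallest depth (parsimony).
        """
        rows = []
        best_depth, best_score = None, -np.inf
        for depth in self.hyperparameters["depth_grid"]:
            est = self._make_forest(depth).fit(x_train, y_train)
            tr = est.score(x_train, y_train)
            va = est.score(x_val, y_val)
            rows.append({"max_depth": depth, "train_score": tr, "val_score": va})
            if va > best_score + 1e-12:
                best_depth, best_score = depth, va
        return best_depth, pd.DataFrame(rows)

    def tune_network_epochs(self, x_train, y_train, x_val, y_val):
        """Early stopping on validation MSE; returns (best_epoch, history,
        best_weights). Patience and epoch cap come from the hyperparameters."""
        est = self._make_network()
        patience = self.hyperparameters["patience"]
        max_epochs = self.hyperparameters["max_epochs"]
        best_loss, best_epoch, best_weights = np.inf, 0, None
        rows = []
        import warnings
        for epoch in range(1, max_epochs + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # per-epoch ConvergenceWarning
                est.fit(x_train, y_train)
            val_loss = float(np.mean((est.predict(x_val) - y_val) ** 2))
            train_loss = float(np.mean((est.predict(x_train) - y_train) ** 2))
            rows.append({"epoch": epoch, "train_mse": train_loss, "val_mse": val_loss})
            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_weights = (copy.deepcopy(est.coefs_),
                                copy.deepcopy(est.intercepts_))
            elif epoch - best_epoch >= patience:
                break
        if best_epoch == 0:
            best_epoch = 1  # flagged: no improvement was ever observed
        return best_epoch, pd.DataFrame(rows), (est, best_weights)

    # -- fitting ----------------------------------------------------------
    def fit(self) -> "PWVRegressionResults":
        """Split, scale, tune and fit; returns the results object."""
        train, val, test = split_dataset(self.data, self.split)
        scaler = fit_scaler(train, self.feature_names)
        x_train = scaler.transform_array(train)
        x_val = scaler.transform_array(val)
        x_test = scaler.transform_array(test)
        y_train = train[self.target_column].to_numpy(dtype=float)
        y_val = val[self.target_column].to_numpy(dtype=float)
        y_test = test[self.target_column].to_numpy(dtype=float)

        history = None
        target_scale = None
        if self.family == "forest":
            depth = self.hyperparameters["max_depth"]
            if depth is None:
                depth, history = self.tune_forest_depth(x_train, y_train, x_val, y_val)
            estimator = self._make_forest(depth).fit(x_train, y_train)
            chosen = {"max_depth": depth, "n_trees": self.hyperparameters["n_trees"]}
        else:
            # rescale the target to [0, 1] on the training range for the MLP
            t_lo, t_hi = float(y_train.min()), float(y_train.max())
            if t_hi == t_lo:
                raise ValueError("constant training target")
            target_scale = (t_lo, t_hi)
            ys_train = (y_train - t_lo) / (t_hi - t_lo)
            ys_val = (y_val - t_lo) / (t_hi - t_lo)
            epochs = self.hyperparameters["epochs"]
            if epochs is None:
                epochs, history, (est, best_weights) = self.tune_network_epochs(
                    x_train, ys_train, x_val, ys_val)
                if best_weights is not None:
                    est.coefs_, est.intercepts_ = best_weights
                estimator = est
            else:
                estimator = self._make_network()
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for _ in range(epochs):
                        estimator.fit(x_train, ys_train)
            chosen = {"epochs": epochs,
                      "hidden_units": self.hyperparameters["hidden_units"],
                      "batch_size": self.hyperparameters["batch_size"]}

        results = PWVRegressionResults(
            model=self, estimator=estimator, scaler=scaler,
            target_scale=target_scale, chosen_hyperparameters=chosen,
            tuning_history=history,
            train=train, val=val, test=test,
        )
        return results

    # -- diagnostics built on repeated refits ------------------------------
    def learning_curve(self, n_points: int = 20, lo: float = 0.01,
                       hi: float = 0.95, rng_seed: int | None = None) -> pd.DataFrame:
        """Train/validation RMSE versus training-set size.

        Subsamples the training partition at `n_points` sizes between `lo`
        and `hi` of its full size and refits the estimator (fixed, tuned
        hyperparameters) at each size.
        """
        res = self.fit()
        train, val = res.train, res.val
        rng = np.random.default_rng(self.rng_seed if rng_seed is None else rng_seed)
        rows = []
        for frac in np.linspace(lo, hi, n_points):
            m = max(int(round(frac * len(train))), max(2, len(self.feature_names)))
            sub = train.iloc[rng.choice(len(train), size=m, replace=False)]
            sub_res = self._refit_on(sub, res)
            rows.append({
                "fraction": frac, "n_train": m,
                "train_rmse": rmse(sub_res.predict(sub), sub[self.target_column]),
                "val_rmse": rmse(sub_res.predict(val), val[self.target_column]),
            })
        return pd.DataFrame(rows)

    def _refit_on(self, train_subset: pd.DataFrame,
                  reference: "PWVRegressionResults") -> "PWVRegressionResults":
        """Refit with the reference run's tuned hyperparameters on a subset."""
        hp = {**self.hyperparameters, **reference.chosen_hyperparameters}
        sub_model = PWVRegression(self.data, target=self.target, family=self.family,
                                  configuration=self.feature_names, split=self.split,
                                  hyperparameters=hp, rng_seed=self.rng_seed)
        scaler = fit_scaler(train_subset, self.feature_names)
        x = scaler.transform_array(train_subset)
        y = train_subset[self.target_column].to_numpy(dtype=float)
        target_scale = None
        if self.family == "forest":
            est = sub_model._make_forest(hp["max_depth"]).fit(x, y)
        else:
            t_lo, t_hi = float(y.min()), float(y.max())
            target_scale = (t_lo, t_hi)
            ys = (y - t_lo) / (t_hi - t_lo)
            est = sub_model._make_network()
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for _ in range(hp["epochs"]):
                    est.fit(x, ys)
        return PWVRegressionResults(model=sub_model, estimator=est, scaler=scaler,
                                    target_scale=target_scale,
                                    chosen_hyperparameters=hp, tuning_history=None,
                                    train=train_subset, val=reference.val,
                                    test=reference.test)


@dataclass
class PWVRegressionResults:
    """Fitted estimator + scaler + splits + test-set agreement report."""

    model: PWVRegression
    estimator: object
    scaler: MinMaxState
    target_scale: tuple[float, float] | None
    chosen_hyperparameters: dict
    tuning_history: pd.DataFrame | None
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    report: EvaluationReport = field(init=False)

    def __post_init__(self):
        try:
            self.report = evaluate(self.predict(self.test),
                                   self.test[self.model.target_column])
        except ValueError:  # degenerate (constant) test target
            self.report = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predictions in physical target units for a feature table."""
        x = self.scaler.transform_array(table)
        y = self.estimator.predict(x)
        if self.target_scale is not None:
            lo, hi = self.target_scale
            y = y * (hi - lo) + lo
        return np.asarray(y, dtype=float)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"PWV regression results — target {m.target} "
            f"({m.target_column}), family {m.family}, configuration {m.configuration}",
            f"features: {', '.join(m.feature_names)}",
            f"splits: train {len(self.train)} / val {len(self.val)} / test {len(self.test)}",
            f"hyperparameters: {self.chosen_hyperparameters}",
            "test-set agreement: " + self.report.summary(),
        ]
        return "\n".join(lines)

    def plot_agreement(self, axes=None):
        """Scatter (prediction vs truth, identity line) and Bland-Altman
        plot for the test set. Returns the matplotlib figure."""
        import matplotlib.pyplot as plt

        y = self.test[self.model.target_column].to_numpy(dtype=float)
        yhat = self.predict(self.test)
        if axes is None:
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        else:
            fig = axes[0].figure
        ax = axes[0]
        ax.scatter(y, yhat, s=8, alpha=0.5)
        lims = [min(y.min(), yhat.min()), max(y.max(), yhat.max())]
        ax.plot(lims, lims, "k-", lw=1)
        ax.set_xlabel(f"reference {self.model.target}")
        ax.set_ylabel(f"predicted {self.model.target}")
        ax = axes[1]
        mean = 0.5 * (y + yhat)
        diff = yhat - y
        ax.scatter(mean, diff, s=8, alpha=0.5)
        rep = self.report
        if rep is not None:
            for level, style in ((rep.bias, "-"), (rep.loa_low, "--"),
                                 (rep.loa_high, "--")):
                ax.axhline(level, color="k", ls=style, lw=1)
        ax.set_xlabel("mean of prediction and reference")
        ax.set_ylabel("difference")
        fig.tight_layout()
        return fig

    def permutation_importance(self, n_repeats: int = 20,
                               rng_seed: int | None = None) -> pd.DataFrame:
        """Mean +/- SD increase of test RMSE after shuffling each feature.

        Each feature column of the test set is independently permuted
        `n_repeats` times; importance is the mean RMSE increase over the
        unpermuted baseline.
        """
        rng = np.random.default_rng(self.model.rng_seed if rng_seed is None
                                    else rng_seed)
        y_true = self.test[self.model.target_column].to_numpy(dtype=float)
        base = rmse(self.predict(self.test), y_true)
        rows = []
        for feature in self.model.feature_names:
            deltas = []
            for _ in range(n_repeats):
                shuffled = self.test.copy()
                shuffled[feature] = rng.permutation(shuffled[feature].to_numpy())
                deltas.append(rmse(self.predict(shuffled), y_true) - base)
            deltas = np.asarray(deltas)
            rows.append({"feature": feature,
                         "importance_mean": float(deltas.mean()),
                         "importance_sd": float(deltas.std(ddof=1))})
        return pd.DataFrame(rows)


def training_size_sensitivity(data: pd.DataFrame, target: str = "zao",
                              family: str = "forest", configuration="M1",
                              fractions=None, split: SplitSpec | None = None,
                              hyperparameters: dict | None = None,
                              rng_seed: int = 0) -> pd.DataFrame:
    """Test nRMSE versus training-set size at a fixed test set.

    The training partition is subsampled to each fraction (default 99% down
    to 1%) and the estimator refit with the full-size tuned hyperparameters;
    accuracy is always measured on the same held-out test set.
    """
    if fractions is None:
        fractions = np.linspace(0.99, 0.01, 15)
    model = PWVRegression(data, target=target, family=family,
                          configuration=configuration, split=split,
                          hyperparameters=hyperparameters, rng_seed=rng_seed)
    full = model.fit()
    rng = np.random.default_rng(rng_seed)
    y_test = full.test[model.target_column]
    rows = []
    for frac in np.asarray(fractions, dtype=float):
        m = max(int(round(frac * len(full.train))), max(2, len(model.feature_names)))
        sub = full.train.iloc[rng.choice(len(full.train), size=m, replace=False)]
        sub_res = model._refit_on(sub, full)
        rows.append({"fraction": frac, "n_train": m,
                     "test_nrmse": nrmse(sub_res.predict(full.test), y_test)})
    return pd.DataFrame(rows)


def cfpwv_only_baseline(data: pd.DataFrame, target: str = "ct",
                        family: str = "network", split: SplitSpec | None = None,
                        hyperparameters: dict | None = None,
                        rng_seed: int = 0) -> PWVRegressionResults:
    """Single-input (cfPWV) estimator, same tuning protocol as the main models."""
    model = PWVRegression(data, target=target, family=family,
                          configuration="cfPWV_only", split=split,
                          hyperparameters=hyperparameters, rng_seed=rng_seed)
    return model.fit()
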