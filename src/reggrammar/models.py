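"""Expression regressors and evaluation statistics.

The central model is a concurrently trained CNN-FC network: three
convolutional blocks (conv -> batch-norm -> ReLU -> max-pool -> dropout)
read the concatenated one-hot regulatory regions, are flattened and
joined with the 72 numeric features (64 codon probabilities + 8
stability variables), and feed two fully connected blocks before a
single linear output. Training minimizes MSE with Adam; the checkpoint
with minimal validation MSE is kept (early stopping).

Shallow baselines (linear/ridge/lasso/elastic-net/random-forest/SVR/kNN)
operate on k-mer count tables plus the numeric features through
scikit-learn, with hyperparameters chosen on the validation split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import nn


@dataclass
class ConvBlock:
    filters: int
    kernel: int
    pool: int  # max-pool width; -1 pools over the whole remaining length
    dropout: float = 0.1


@dataclass
class ModelSpec:
    """Architecture + optimizer settings for the CNN-FC regressor.

    The default widths suit the scaled synthetic cohort (400 bp of
    regulatory sequence); `full()` gives a 2150-bp preset with the wider
    kernels appropriate for whole regions.
    """

    conv_blocks: list[ConvBlock] = field(
        default_factory=lambda: [
            ConvBlock(48, 12, 4, 0.1),
            ConvBlock(64, 6, 4, 0.1),
            ConvBlock(64, 4, 4, 0.1),
        ]
    )
    fc_layers: tuple[int, int] = (128, 64)
    fc_dropout: float = 0.2
    batchnorm: bool = True
    learning_rate: float = 1e-3
    lr_decay_factor: float = 0.5  # halve the rate when validation stalls
    lr_decay_patience: int = 5
    min_learning_rate: float = 5e-5
    batch_size: int = 64
    epochs: int = 120
    patience: int = 10
    numeric_dropout: float = 0.0  # per-sample drop of the whole numeric branch
    warmup_epochs: int = 0  # sequence-only epochs before joint training
    freeze_conv_after_warmup: bool = True
    seed: int = 0

    def validate(self) -> None:
        for blk in self.conv_blocks:
            if blk.filters <= 0 or blk.kernel <= 0 or (
                blk.pool <= 0 and blk.pool != -1
            ):
                raise ValueError("conv block sizes must be positive")
        if any(w <= 0 for w in self.fc_layers):
            raise ValueError("FC widths must be positive")

    @classmethod
    def full(cls) -> "ModelSpec":
        return cls(
            conv_blocks=[
                ConvBlock(64, 30, 4, 0.2),
                ConvBlock(64, 10, 4, 0.2),
                ConvBlock(128, 10, 4, 0.2),
            ],
            fc_layers=(128, 64),
        )

    @classmethod
    def scaled(cls, seed: int = 0) -> "ModelSpec":
        """Preset for scaled synthetic cohorts (hundreds of bp of
        regulatory sequence): one wide motif-detector block with global
        max pooling, consecutive training (sequence-only warmup, then a
        frozen-conv head fit over sequence + numeric features)."""
        return cls(
            conv_blocks=[ConvBlock(256, 8, -1, 0.0)],
            fc_layers=(64, 32),
            fc_dropout=0.0,
            batchnorm=False,
            learning_rate=2e-3,
            epochs=140,
            patience=15,
            warmup_epochs=80,
            seed=seed,
        )


@dataclass
class SplitPlan:
    """Disjoint, exhaustive train/validation/test gene-id partition."""

    train: list[str]
    validation: list[str]
    test: list[str]
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    @classmethod
    def make(
        cls,
        gene_ids: list[str],
        fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        seed: int = 0,
    ) -> "SplitPlan":
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        rng = np.random.default_rng(seed)
        order = list(rng.permutation(len(gene_ids)))
        n = len(gene_ids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        idx = {
            "train": order[:n_train],
            "validation": order[n_train : n_train + n_val],
            "test": order[n_train + n_val :],
        }
        return cls(
            train=[gene_ids[i] for i in idx["train"]],
            validation=[gene_ids[i] for i in idx["validation"]],
            test=[gene_ids[i] for i in idx["test"]],
            fractions=fractions,
            seed=seed,
        )

    def indices(self, gene_ids: list[str]) -> dict[str, np.ndarray]:
        pos = {g: i for i, g in enumerate(gene_ids)}
        return {
            name: np.array([pos[g] for g in getattr(self, name)], dtype=int)
            for name in ("train", "validation", "test")
        }


@dataclass
class EvalReport:
    mse: float
    r_squared: float
    f_statistic: float
    f_pvalue: float
    n: int


def evaluate(predictions: np.ndarray, observations: np.ndarray) -> EvalReport:
    """R-squared as 1 - SS_res/SS_tot (can be negative) plus an F-test of
    the observed-on-predicted univariate regression against the
    intercept-only model."""
    pred = np.asarray(predictions, float)
    obs = np.asarray(observations, float)
    if pred.shape != obs.shape or pred.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares")
    r2 = 1.0 - ss_res / ss_tot
    n = obs.size
    if np.ptp(pred) == 0:
        f_stat, f_p = 0.0, 1.0
    else:
        slope, intercept = np.polyfit(pred, obs, 1)
        fit = intercept + slope * pred
        ss_reg = float(np.sum((fit - obs.mean()) ** 2))
        ss_err = float(np.sum((obs - fit) ** 2))
        df2 = n - 2
        f_stat = (ss_reg / 1.0) / (ss_err / df2) if ss_err > 0 else np.inf
        f_p = float(sps.f.sf(f_stat, 1, df2))
    return EvalReport(mse=ss_res / n, r_squared=r2, f_statistic=float(f_stat),
                      f_pvalue=f_p, n=n)


class RegressionModel:
    """CNN-FC regressor handle built by :func:`build_model`."""

    def __init__(self, net: nn.TwoBranchNet, spec: ModelSpec,
                 seq_shape: tuple[int, int], n_numeric: int):
        self.net = net
        self.spec = spec
        self.seq_shape = seq_shape
        self.n_numeric = n_numeric
        self.num_mean = np.zeros(n_numeric)
        self.num_sd = np.ones(n_numeric)
        self.y_mean = 0.0
        self.y_sd = 1.0
        self.history: pd.DataFrame | None = None
        self.warmup_weights: list[np.ndarray] | None = None

    # -- inference ---------------------------------------------------------
    def predict(self, x_seq: np.ndarray, x_num: np.ndarray,
                batch: int = 256) -> np.ndarray:
        out = []
        xn = (x_num - self.num_mean) / self.num_sd
        for i in range(0, len(x_seq), batch):
            z = self.net.forward(
                x_seq[i : i + batch].astype(np.float32),
                xn[i : i + batch].astype(np.float32),
                train=False,
            )
            out.append(z[:, 0])
        return np.concatenate(out) * self.y_sd + self.y_mean

    def sequence_model(self) -> "SequenceView":
        """Sequence-only view using the warmup-phase weights (requires
        consecutive training); numeric inputs are ignored."""
        if self.warmup_weights is None:
            raise RuntimeError("model was not trained with a sequence warmup")
        return SequenceView(self)

    # -- training ----------------------------------------------------------
    def fit(self, x_seq: np.ndarray, x_num: np.ndarray, y: np.ndarray,
            train_idx: np.ndarray, val_idx: np.ndarray,
            verbose: bool = False) -> pd.DataFrame:
        """Train with early stopping on validation MSE.

        With ``spec.warmup_epochs > 0`` the model is trained
        consecutively: a sequence-only phase (numeric features zeroed)
        establishes the conv filters, then the FC head is (re)fitted on
        sequence + numeric inputs, with the conv weights frozen by
        default. Otherwise training is concurrent on both branches.
        """
        spec = self.spec
        rng = np.random.default_rng(spec.seed + 1)
        self.num_mean = x_num[train_idx].mean(axis=0)
        self.num_sd = x_num[train_idx].std(axis=0)
        self.num_sd[self.num_sd == 0] = 1.0
        self.y_mean = float(y[train_idx].mean())
        self.y_sd = float(y[train_idx].std()) or 1.0

        xs = x_seq.astype(np.float32)
        xn = ((x_num - self.num_mean) / self.num_sd).astype(np.float32)
        yt = ((y - self.y_mean) / self.y_sd).astype(np.float32)

        rows: list[dict] = []
        if spec.warmup_epochs > 0:
            self._phase(xs, xn, yt, train_idx, val_idx, rng, rows,
                        epochs=spec.warmup_epochs, numeric_on=False,
                        head_only=False, lr=spec.learning_rate,
                        phase="warmup", verbose=verbose)
            # keep the sequence-only network for attribution analyses
            self.warmup_weights = self.net.get_weights()
            self._phase(xs, xn, yt, train_idx, val_idx, rng, rows,
                        epochs=spec.epochs - spec.warmup_epochs,
                        numeric_on=True,
                        head_only=spec.freeze_conv_after_warmup,
                        lr=spec.learning_rate / 2,
                        phase="joint", verbose=verbose)
        else:
            self._phase(xs, xn, yt, train_idx, val_idx, rng, rows,
                        epochs=spec.epochs, numeric_on=True,
                        head_only=False, lr=spec.learning_rate,
                        phase="joint", verbose=verbose)
        self.history = pd.DataFrame(rows)
        return self.history

    def _phase(self, xs, xn, yt, train_idx, val_idx, rng, rows, *,
               epochs, numeric_on, head_only, lr, phase, verbose):
        spec = self.spec
        params = self.net.head.params() if head_only else self.net.params()
        grads = (self.net.head.grads() if head_only
                 else self.net.grads())
        opt = nn.Adam(params, lr=lr)
        best_val, best_weights, best_epoch, best_bn = np.inf, None, -1, None
        for epoch in range(epochs):
            order = rng.permutation(train_idx)
            losses = []
            for i in range(0, len(order), spec.batch_size):
                b = order[i : i + spec.batch_size]
                if len(b) < 2:
                    continue  # batch-norm needs >1 sample
                xnb = xn[b] if numeric_on else np.zeros_like(xn[b])
                if numeric_on and spec.numeric_dropout > 0:
                    # occasionally hide the numeric features so the
                    # sequence branch cannot be starved of gradient
                    xnb = xnb.copy()
                    xnb[rng.random(len(b)) < spec.numeric_dropout] = 0.0
                pred = self.net.forward(xs[b], xnb, train=True)[:, 0]
                err = pred - yt[b]
                if not np.isfinite(err).all():
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}; lower the learning rate"
                    )
                losses.append(float(np.mean(err**2)))
                self.net.backward((2.0 * err / len(b))[:, None].astype(np.float32))
                opt.step(grads)
            val_pred = self._predict_std(xs, xn if numeric_on else 0 * xn, val_idx)
            val_mse = float(np.mean((val_pred - yt[val_idx]) ** 2))
            rows.append({"phase": phase, "epoch": epoch,
                         "train_mse": float(np.mean(losses)),
                         "val_mse": val_mse})
            if verbose:
                print(f"{phase} {epoch:3d} train {rows[-1]['train_mse']:.4f} "
                      f"val {val_mse:.4f}")
            if val_mse < best_val:
                best_val, best_epoch = val_mse, epoch
                best_weights = self.net.get_weights()
                best_bn = self._bn_state()
            elif epoch - best_epoch >= spec.patience:
                break
            if (epoch - best_epoch) >= spec.lr_decay_patience and (
                epoch - best_epoch
            ) % spec.lr_decay_patience == 0:
                opt.lr = max(opt.lr * spec.lr_decay_factor, spec.min_learning_rate)
        if best_weights is not None:
            self.net.set_weights(best_weights)
            self._restore_bn(best_bn)

    def _predict_std(self, xs, xn, idx, batch=512):
        out = []
        for i in range(0, len(idx), batch):
            b = idx[i : i + batch]
            out.append(self.net.forward(xs[b], xn[b], train=False)[:, 0])
        return np.concatenate(out)

    def _bn_layers(self):
        return [l for l in self.net.seq_branch.layers + self.net.head.layers
                if isinstance(l, nn.BatchNorm)]

    def _bn_state(self):
        return [(l.running_mean.copy(), l.running_var.copy())
                for l in self._bn_layers()]

    def _restore_bn(self, state):
        for l, (m, v) in zip(self._bn_layers(), state):
            l.running_mean, l.running_var = m.copy(), v.copy()

    def spec_dict(self) -> dict:
        return dataclasses.asdict(self.spec)


class SequenceView:
    """Prediction through the sequence-only (warmup) weights of a
    consecutively trained model. Presents the same ``predict`` surface,
    so occlusion attribution can run on the pure sequence pathway."""

    def __init__(self, model: "RegressionModel"):
        self.model = model

    def predict(self, x_seq: np.ndarray, x_num: np.ndarray,
                batch: int = 256) -> np.ndarray:
        m = self.model
        current = m.net.get_weights()
        m.net.set_weights(m.warmup_weights)
        try:
            out = []
            for i in range(0, len(x_seq), batch):
                n = len(x_seq[i : i + batch])
                z = m.net.forward(
                    x_seq[i : i + batch].astype(np.float32),
                    np.zeros((n, m.n_numeric), dtype=np.float32),
                    train=False,
                )
                out.append(z[:, 0])
        finally:
            m.net.set_weights(current)
        return np.concatenate(out) * m.y_sd + m.y_mean


def build_model(spec: ModelSpec, seq_shape: tuple[int, int],
                n_numeric: int = 72, n_outputs: int = 1,
                softmax_head: bool = False) -> RegressionModel:
    """Assemble the CNN-FC network for the given input shapes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    channels, length = seq_shape
    layers: list[nn.Layer] = []
    c, L = channels, length
    for blk in spec.conv_blocks:
        conv_out = L - blk.kernel + 1
        if conv_out < 1:
            raise ValueError("conv stack consumes the whole sequence; "
                             "reduce kernels or pooling")
        pool = conv_out if blk.pool == -1 else blk.pool
        layers.append(nn.Conv1D(c, blk.filters, blk.kernel, rng))
        if spec.batchnorm:
            layers.append(nn.BatchNorm(blk.filters))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool1D(pool))
        if blk.dropout > 0:
            layers.append(nn.Dropout(blk.dropout, np.random.default_rng(rng.integers(2**31))))
        c = blk.filters
        L = conv_out // pool
        if L < 1:
            raise ValueError("conv stack consumes the whole sequence; "
                             "reduce kernels or pooling")
    layers.append(nn.Flatten())
    seq_branch = nn.Sequential(layers)

    head_layers: list[nn.Layer] = []
    dim = c * L + n_numeric
    for width in spec.fc_layers:
        head_layers.append(nn.Dense(dim, width, rng))
        if spec.batchnorm:
            head_layers.append(nn.BatchNorm(width))
        head_layers.append(nn.ReLU())
        if spec.fc_dropout > 0:
            head_layers.append(nn.Dropout(spec.fc_dropout,
                                          np.random.default_rng(rng.integers(2**31))))
        dim = width
    head_layers.append(nn.Dense(dim, n_outputs, rng))
    if softmax_head:
        head_layers.append(nn.Softmax())
    head = nn.Sequential(head_layers)
    return RegressionModel(nn.TwoBranchNet(seq_branch, head, n_numeric),
                           spec, seq_shape, n_numeric)


def train(model: RegressionModel, x_seq: np.ndarray, x_num: np.ndarray,
          y: np.ndarray, split: SplitPlan, gene_ids: list[str],
          verbose: bool = False) -> tuple[RegressionModel, pd.DataFrame]:
    """Train with early stopping; returns the model restored to the
    epoch with minimal validation MSE plus the epoch history."""
    idx = split.indices(gene_ids)
    history = model.fit(x_seq, x_num, y, idx["train"], idx["validation"],
                        verbose=verbose)
    return model, history


# ---------------------------------------------------------------------------
# shallow baselines


_GRIDS = {
    "linear": [{}],
    "ridge": [{"alpha": a} for a in (0.1, 1.0, 10.0, 100.0)],
    "lasso": [{"alpha": a} for a in (1e-3, 1e-2, 1e-1, 1.0)],
    "elastic-net": [{"alpha": a, "l1_ratio": r}
                    for a in (1e-2, 1e-1, 1.0) for r in (0.2, 0.5, 0.8)],
    "random-forest": [{"n_estimators": 200, "max_depth": d} for d in (None, 10)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "knn": [{"n_neighbors": k} for k in (3, 5, 10, 20)],
}


def _make_estimator(algorithm: str, params: dict, seed: int):
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import LinearSVR

    if algorithm == "linear":
        return LinearRegression(**params)
    if algorithm == "ridge":
        return Ridge(**params)
    if algorithm == "lasso":
        return Lasso(max_iter=5000, **params)
    if algorithm == "elastic-net":
        return ElasticNet(max_iter=5000, **params)
    if algorithm == "random-forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        return LinearSVR(max_iter=5000, random_state=seed, **params)
    if algorithm == "knn":
        return KNeighborsRegressor(**params)
    raise ValueError(f"unknown shallow algorithm {algorithm!r}")


def shallow_baseline(
    features: pd.DataFrame,
    targets: np.ndarray,
    algorithm: str,
    split: SplitPlan,
    seed: int = 0,
) -> tuple[EvalReport, dict]:
    """Fit a shallow regressor on tabular features.

    Hyperparameters are selected by validation MSE over a small grid;
    the report carries test-set statistics. A singular design under
    plain linear regression triggers a ridge fallback with a warning.
    """
    import warnings

    from sklearn.preprocessing import StandardScaler

    gene_ids = list(features.index)
    idx = split.indices(gene_ids)
    X = features.to_numpy(dtype=float)
    y = np.asarray(targets, float)
    scaler = StandardScaler().fit(X[idx["train"]])
    Xs = scaler.transform(X)

    if algorithm == "linear":
        rank = np.linalg.matrix_rank(Xs[idx["train"]])
        if rank < Xs.shape[1]:
            warnings.warn("singular design for linear regression; using ridge")
            algorithm = "ridge"

    best = (np.inf, None, None)
    for params in _GRIDS[algorithm]:
        est = _make_estimator(algorithm, params, seed)
        est.fit(Xs[idx["train"]], y[idx["train"]])
        val_mse = float(np.mean((est.predict(Xs[idx["validation"]])
                                 - y[idx["validation"]]) ** 2))
        if val_mse < best[0]:
            best = (val_mse, est, params)
    _, est, params = best
    report = evaluate(est.predict(Xs[idx["test"]]), y[idx["test"]])
    return report, {"algorithm": algorithm, "params": params,
                    "val_mse": best[0]}


# ---------------------------------------------------------------------------
# codon-vector prediction from regulatory DNA


def pooled_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """R-squared pooled over all (gene, codon) pairs, with SS_tot taken
    around the per-codon mean so the trivial average-profile predictor
    scores zero."""
    resid = obs - pred
    centred = obs - obs.mean(axis=0, keepdims=True)
    return 1.0 - float((resid**2).sum()) / float((centred**2).sum())


def codon_from_regulatory(
    spec: ModelSpec,
    x_seq: np.ndarray,
    codon_targets: np.ndarray,
    split: SplitPlan,
    gene_ids: list[str],
    transfer_from: RegressionModel | None = None,
    verbose: bool = False,
) -> tuple[RegressionModel, float]:
    """Train a 64-output softmax-headed CNN to predict the codon
    probability vector from regulatory sequence alone; returns the model
    and the pooled test R-squared.

    ``transfer_from`` enables consecutive training by weight transfer:
    the convolutional filters of an already-trained expression model
    (its sequence-warmup weights when available) are copied in and
    frozen, and only the softmax head is fitted. Motif detectors are
    shared between the two tasks, so transfer is both faster and more
    accurate than training the detectors from the weak codon signal.
    """
    model = build_model(spec, x_seq.shape[1:], n_numeric=0, n_outputs=64,
                        softmax_head=True)
    head_only = False
    if transfer_from is not None:
        src = transfer_from.net.seq_branch.params()
        if transfer_from.warmup_weights is not None:
            src = transfer_from.warmup_weights[:len(src)]
        dst = model.net.seq_branch.params()
        if len(src) != len(dst) or any(a.shape != b.shape
                                       for a, b in zip(src, dst)):
            raise ValueError("transfer_from architecture does not match spec")
        for a, b in zip(dst, src):
            a[...] = b
        head_only = True
    idx = split.indices(gene_ids)
    xs = x_seq.astype(np.float32)
    xn = np.zeros((len(x_seq), 0), dtype=np.float32)
    yt = codon_targets.astype(np.float32)

    rng = np.random.default_rng(spec.seed + 1)
    params = model.net.head.params() if head_only else model.net.params()
    grads = model.net.head.grads() if head_only else model.net.grads()
    opt = nn.Adam(params, lr=spec.learning_rate)
    best_val, best_weights, best_epoch, best_bn = np.inf, None, -1, None
    for epoch in range(spec.epochs):
        order = rng.permutation(idx["train"])
        for i in range(0, len(order), spec.batch_size):
            b = order[i : i + spec.batch_size]
            if len(b) < 2:
                continue
            pred = model.net.forward(xs[b], xn[b], train=True)
            err = pred - yt[b]
            model.net.backward((2.0 * err / err.size).astype(np.float32))
            opt.step(grads)
        vp = _predict_multi(model, xs, xn, idx["validation"])
        val_mse = float(np.mean((vp - yt[idx["validation"]]) ** 2))
        if verbose:
            print(f"epoch {epoch:3d} val {val_mse:.6f}")
        if val_mse < best_val:
            best_val, best_epoch = val_mse, epoch
            best_weights = model.net.get_weights()
            best_bn = model._bn_state()
        elif epoch - best_epoch >= spec.patience:
            break
    if best_weights is not None:
        model.net.set_weights(best_weights)
        model._restore_bn(best_bn)
    test_pred = _predict_multi(model, xs, xn, idx["test"])
    return model, pooled_r2(test_pred, yt[idx["test"]])


def _predict_multi(model: RegressionModel, xs, xn, idx, batch=512):
    out = []
    for i in range(0, len(idx), batch):
        b = idx[i : i + batch]
        out.append(model.net.forward(xs[b], xn[b], train=False))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# optional random hyperparameter search (stand-in for exhaustive tuning)


def random_search(
    x_seq: np.ndarray, x_num: np.ndarray, y: np.ndarray,
    split: SplitPlan, gene_ids: list[str],
    n_iter: int = 5, seed: int = 0, epochs: int = 15,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Sample ``n_iter`` specs around the defaults, train briefly, and
    return the spec with the lowest validation MSE."""
    rng = np.random.default_rng(seed)
    rows, best = [], (np.inf, None)
    for it in range(n_iter):
        spec = ModelSpec(
            conv_blocks=[
                ConvBlock(int(rng.choice([32, 48, 64])),
                          int(rng.choice([8, 12, 16])), 4, 0.1),
                ConvBlock(int(rng.choice([48, 64])), int(rng.choice([4, 6])), 4, 0.1),
                ConvBlock(64, 4, 4, 0.1),
            ],
            fc_layers=(int(rng.choice([64, 128])), 64),
            learning_rate=float(rng.choice([3e-4, 1e-3, 3e-3])),
            epochs=epochs,
            seed=int(rng.integers(2**31)),
        )
        model = build_model(spec, x_seq.shape[1:], x_num.shape[1])
        idx = split.indices(gene_ids)
        hist = model.fit(x_seq, x_num, y, idx["train"], idx["validation"])
        val = float(hist["val_mse"].min())
        rows.append({"iter": it, "val_mse": val})
        if val < best[0]:
            best = (val, spec)
    return best[1], pd.DataFrame(rows)
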