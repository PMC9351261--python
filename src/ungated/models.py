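"""The two regression networks: branched continuous model and gated comparator.

The continuous (ungated) model takes one 102-section histogram per
fluorescence channel.  Each of the 23 channels feeds its own branch of dense
layers 102 → 75 → 50 → 25 → 1; the 23 scalar branch outputs — the
*informative layer*, one interpretable contribution per marker channel — are
combined by a final dense layer of one unit into the prediction.  Hidden
layers use the exponential linear unit (ELU, α = 1); the two one-unit layers
are linear.  The gated comparator is a plain stack 67 → 50 → 30 → 15 → 1
over cell-type counts, same activations.

Both are trained with minibatch Adam on mean squared error.  Binary and
ordinal outcomes are regressed like continuous ones, since evaluation is
rmse on a linear output.  Training is pure NumPy: forward and backward
passes are written out explicitly, which keeps every replicate bit
reproducible under a seed — there is no thread-level nondeterminism.

By construction each individual's continuous-model prediction is an affine
function of their informative-layer values:

    prediction = Σ_m  w_m · informative_m  +  b

which is asserted on every trained replicate and is what makes per-marker
contribution analysis possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ModelSpecError(ValueError):
    pass


class TrainingDiverged(RuntimeError):
    """Raised when the loss goes non-finite; carries diagnostics."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training settings for one model kind.

    Defaults follow the published configuration: the continuous model has
    one 102-input branch per channel with layers (75, 50, 25, 1) and trains
    for 25,000 epochs; the gated model is 67 → (50, 30, 15, 1) and trains
    for 10,000.  Both use batch size 100 and Adam (step 1e-3).
    ``desk_profile`` gives the reduced-epoch settings used for routine runs
    and testing.
    """

    kind: str                                   # "continuous" | "gated"
    n_branches: int = 23
    branch_input_size: int = 102
    branch_layer_sizes: tuple[int, ...] = (75, 50, 25, 1)
    input_size: int = 67
    layer_sizes: tuple[int, ...] = (50, 30, 15, 1)
    epochs: int = 25_000
    batch_size: int = 100
    learning_rate: float = 1e-3
    standardize_inputs: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "gated"):
            raise ModelSpecError(f"unknown model kind {self.kind!r}")
        sizes = self.branch_layer_sizes if self.kind == "continuous" else self.layer_sizes
        if sizes[-1] != 1:
            raise ModelSpecError("each stack must end in exactly 1 unit")
        inp = self.branch_input_size if self.kind == "continuous" else self.input_size
        if not all(a > b for a, b in zip((inp,) + tuple(sizes), sizes)):
            raise ModelSpecError("layer sizes must form a decreasing gradient")
        if self.kind == "continuous" and self.n_branches < 1:
            raise ModelSpecError("continuous model needs at least one branch")
        if self.epochs < 0 or self.batch_size < 1:
            raise ModelSpecError("epochs must be >= 0 and batch_size >= 1")

    @property
    def total_input_size(self) -> int:
        if self.kind == "continuous":
            return self.n_branches * self.branch_input_size
        return self.input_size

    def parameter_count(self) -> int:
        """Closed-form parameter count implied by the layer sizes."""
        def stack(sizes: tuple[int, ...]) -> int:
            total = 0
            for fan_in, fan_out in zip(sizes, sizes[1:]):
                total += fan_in * fan_out + fan_out
            return total

        if self.kind == "continuous":
            branch = stack((self.branch_input_size,) + self.branch_layer_sizes)
            combiner = self.n_branches * 1 + 1
            return self.n_branches * branch + combiner
        return stack((self.input_size,) + self.layer_sizes)


def continuous_spec(n_branches: int = 23, **overrides) -> NetworkSpec:
    return NetworkSpec(kind="continuous", n_branches=n_branches, **overrides)


def gated_spec(input_size: int = 67, **overrides) -> NetworkSpec:
    layer_sizes = overrides.pop("layer_sizes", (50, 30, 15, 1))
    return NetworkSpec(kind="gated", input_size=input_size,
                       layer_sizes=layer_sizes, epochs=overrides.pop("epochs", 10_000),
                       **overrides)


def scaled_gated_layers(input_size: int) -> tuple[int, ...]:
    """Hidden sizes for a gated model with a non-standard input dimension.

    The published 67-input stack (50, 30, 15, 1) is scaled proportionally
    while preserving the strictly decreasing gradient; a 67-input model gets
    the published sizes exactly.
    """
    if input_size >= 67:
        return (50, 30, 15, 1)
    sizes: list[int] = []
    prev = input_size
    for ref in (50, 30, 15):
        s = min(max(1, round(ref * input_size / 67)), prev - 1)
        if s < 2:
            break
        sizes.append(s)
        prev = s
    sizes.append(1)
    if sizes[0] >= input_size:  # tiny inputs: single linear unit
        sizes = [1]
    return tuple(sizes)


def desk_profile(spec: NetworkSpec) -> NetworkSpec:
    """Reduced-epoch profile for routine desk-scale runs (500 / 200 epochs)."""
    from dataclasses import replace
    return replace(spec, epochs=500 if spec.kind == "continuous" else 200)


# ---------------------------------------------------------------------------
# Layers and network
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


class _Dense:
    """One dense layer with explicit forward/backward and Adam state."""

    def __init__(self, fan_in: int, fan_out: int, activation: str,
                 rng: np.random.Generator) -> None:
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        self.b = np.zeros(fan_out)
        self.activation = activation
        self._mW = np.zeros_like(self.W)
        self._vW = np.zeros_like(self.W)
        self._mb = np.zeros_like(self.b)
        self._vb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._pre = x @ self.W + self.b
        return _elu(self._pre) if self.activation == "elu" else self._pre

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.activation == "elu":
            grad_out = grad_out * _elu_grad(self._pre)
        self._gW = self._x.T @ grad_out
        self._gb = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def adam_step(self, lr: float, t: int, b1: float = 0.9, b2: float = 0.999,
                  eps: float = 1e-8) -> None:
        for p, g, m, v in ((self.W, self._gW, self._mW, self._vW),
                           (self.b, self._gb, self._mb, self._vb)):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size


class Network:
    """Branched (continuous) or plain-stack (gated) dense regression network.

    For the continuous kind, input rows are the channel-major flattening of
    the (n_branches × branch_input_size) histogram block; ``forward``
    caches the per-branch scalar outputs (the informative layer).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10]))
        if spec.kind == "continuous":
            sizes = (spec.branch_input_size,) + spec.branch_layer_sizes
            self.branches: list[list[_Dense]] = []
            for _ in range(spec.n_branches):
                stack = [
                    _Dense(fan_in, fan_out,
                           "elu" if fan_out != 1 else "linear", rng)
                    for fan_in, fan_out in zip(sizes, sizes[1:])
                ]
                self.branches.append(stack)
            self.combiner: _Dense | None = _Dense(spec.n_branches, 1, "linear", rng)
            self.layers: list[_Dense] = []
        else:
            sizes = (spec.input_size,) + spec.layer_sizes
            self.layers = [
                _Dense(fan_in, fan_out, "elu" if fan_out != 1 else "linear", rng)
                for fan_in, fan_out in zip(sizes, sizes[1:])
            ]
            self.branches = []
            self.combiner = None
        self.informative_: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        total = sum(l.n_parameters for stack in self.branches for l in stack)
        total += sum(l.n_parameters for l in self.layers)
        if self.combiner is not None:
            total += self.combiner.n_parameters
        return total

    def _all_layers(self) -> list[_Dense]:
        out = [l for stack in self.branches for l in stack]
        out.extend(self.layers)
        if self.combiner is not None:
            out.append(self.combiner)
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.spec.total_input_size:
            raise ModelSpecError(
                f"input has {X.shape[1]} columns, spec expects {self.spec.total_input_size}"
            )
        if self.spec.kind == "continuous":
            w = self.spec.branch_input_size
            outs = []
            for i, stack in enumerate(self.branches):
                h = X[:, i * w:(i + 1) * w]
                for layer in stack:
                    h = layer.forward(h)
                outs.append(h)
            informative = np.concatenate(outs, axis=1)  # (n, n_branches)
            self.informative_ = informative
            return self.combiner.forward(informative).ravel()
        h = X
        for layer in self.layers:
            h = layer.forward(h)
        return h.ravel()

    def backward(self, grad_pred: np.ndarray) -> None:
        g = grad_pred[:, None]
        if self.spec.kind == "continuous":
            g_inf = self.combiner.backward(g)
            for i, stack in enumerate(self.branches):
                gb = g_inf[:, i:i + 1]
                for layer in reversed(stack):
                    gb = layer.backward(gb)
        else:
            for layer in reversed(self.layers):
                g = layer.backward(g)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def get_parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._all_layers():
            out.extend([layer.W.copy(), layer.b.copy()])
        return out

    @property
    def combiner_weights(self) -> tuple[np.ndarray, float]:
        if self.combiner is None:
            raise ModelSpecError("the gated model has no informative layer")
        return self.combiner.W.ravel().copy(), float(self.combiner.b[0])


def build_model(spec: NetworkSpec, seed: int = 0) -> Network:
    """Instantiate an untrained network with seeded Glorot initialization."""
    return Network(spec, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedReplicate:
    """One trained model instance plus its validation-set artifacts."""

    spec: NetworkSpec
    seed: int
    model: Network
    predictions_val: np.ndarray | None = None
    observed_val: np.ndarray | None = None
    informative_values: np.ndarray | None = None   # (n_val, n_branches)
    combiner_w: np.ndarray | None = None
    combiner_b: float | None = None
    loss_history: list[tuple[int, float]] = field(default_factory=list)
    rmse_val: float | None = None
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def train(model: Network, X: np.ndarray, y: np.ndarray, spec: NetworkSpec,
          seed: int, X_val: np.ndarray | None = None,
          y_val: np.ndarray | None = None,
          loss_every: int = 50) -> TrainedReplicate:
    """Minibatch-Adam MSE training; deterministic under the given seed.

    ``seed`` drives batch shuffling only (the model's own seed fixed its
    initialization).  The loss trajectory is sampled every ``loss_every``
    epochs.  A non-finite loss raises :class:`TrainingDiverged` with the
    epoch and last finite loss rather than silently continuing.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X row count must equal y length")
    if np.isnan(y).any():
        raise ValueError("training outcomes contain missing values")

    mean = sd = None
    if spec.standardize_inputs:
        mean, sd = _standardize_fit(X)
        X = (X - mean) / sd

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5085]))
    n = X.shape[0]
    history: list[tuple[int, float]] = []
    t = 0
    last_finite = np.nan
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            pred = model.forward(X[idx])
            resid = pred - y[idx]
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {t}; "
                    f"last finite loss {last_finite:.6g}"
                )
            last_finite = loss
            model.backward(2.0 * resid / len(idx))
            t += 1
            for layer in model._all_layers():
                layer.adam_step(spec.learning_rate, t)
        if epoch % loss_every == 0 or epoch == spec.epochs - 1:
            history.append((epoch, loss))

    rep = TrainedReplicate(spec=spec, seed=seed, model=model,
                           loss_history=history, input_mean=mean, input_sd=sd)
    if X_val is not None:
        Xv = np.asarray(X_val, dtype=np.float64)
        if spec.standardize_inputs:
            Xv = (Xv - mean) / sd
        rep.predictions_val = model.predict(Xv)
        if spec.kind == "continuous":
            rep.informative_values = model.informative_.copy()
            rep.combiner_w, rep.combiner_b = model.combiner_weights
        if y_val is not None:
            yv = np.asarray(y_val, dtype=np.float64).ravel()
            rep.observed_val = yv
            rep.rmse_val = float(np.sqrt(np.mean((rep.predictions_val - yv) ** 2)))
    return rep


def extract_informative_values(replicate: TrainedReplicate,
                               X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-individual, per-channel branch outputs plus combiner weights/bias.

    Only defined for the continuous model; the affine identity
    ``prediction = informative @ w + b`` holds for every row.
    """
    if replicate.spec.kind != "continuous":
        raise ModelSpecError("informative values exist only for the continuous model")
    X = np.asarray(X, dtype=np.float64)
    if replicate.spec.standardize_inputs:
        X = (X - replicate.input_mean) / replicate.input_sd
    replicate.model.forward(X)
    informative = replicate.model.informative_.copy()
    w, b = replicate.model.combiner_weights
    return informative, w, b


def contribution_summary(replicates: list[TrainedReplicate],
                         channel_names: list[str],
                         weighted: bool = True) -> pd.DataFrame:
    """Per-marker-channel contribution: mean over replicates ± standard error.

    For each replicate the per-channel contribution is the validation-set
    mean of the informative value, optionally scaled by its combiner weight
    (``weighted=True``), i.e. the channel's additive share of the
    prediction.  Both exports exist because either convention is defensible.
    """
    rows = []
    for rep in replicates:
        if rep.informative_values is None:
            raise ValueError("replicate lacks informative values; train with X_val")
        contrib = rep.informative_values.mean(axis=0)
        if weighted:
            contrib = contrib * rep.combiner_w
        rows.append(contrib)
    arr = np.asarray(rows)
    n = arr.shape[0]
    return pd.DataFrame({
        "channel": channel_names,
        "mean_contribution": arr.mean(axis=0),
        "standard_error": arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1]),
        "n_replicates": n,
    })


# ---------------------------------------------------------------------------
# Splits and replicate runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Fixed calibration/validation division of complete-case individuals."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation ids overlap")


def make_split(ids: list[str], n_calibration: int = 300, seed: int = 0) -> SplitPlan:
    """Seeded random split, defaults to the 300/267 calibration/validation plan."""
    ids = list(ids)
    if n_calibration >= len(ids):
        raise ValueError(f"n_calibration={n_calibration} leaves no validation set "
                         f"(only {len(ids)} ids)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5917]))
    order = rng.permutation(len(ids))
    cal = tuple(ids[i] for i in sorted(order[:n_calibration]))
    val = tuple(ids[i] for i in sorted(order[n_calibration:]))
    return SplitPlan(calibration_ids=cal, validation_ids=val, seed=seed)


def run_replicates(X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray,
                   y_val: np.ndarray, spec: NetworkSpec, n_replicates: int,
                   base_seed: int) -> list[TrainedReplicate]:
    """Train ``n_replicates`` models on a fixed split.

    Replicate ``r`` uses seed ``base_seed + r`` for both initialization and
    batch shuffling; the split itself is held fixed across replicates so
    replicate spread isolates training randomness.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for r in range(n_replicates):
        seed = base_seed + r
        model = build_model(spec, seed=seed)
        out.append(train(model, X_cal, y_cal, spec, seed=seed,
                         X_val=X_val, y_val=y_val))
    return out
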