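"""LSTM conditioning network: build, train, apply.

The conditioner maps a length-``L`` window of four normalized channels
(PPG + 3-axis acceleration, inter-sampled with stride ``S``) to one
predicted clean-PPG value — the value of the idealised target at the
window's last sample.  The architecture is one or two LSTM layers of
``N_h`` cells followed by a linear fully connected output.

Each cell follows the standard recurrence with a forget gate,

    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    c~_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * c~_t
    h_t = o_t * tanh(c_t)

implemented with NumPy forward and backward-through-time passes and the
Adam optimiser on a mean-absolute-error loss.  Initialization follows
the common convention: Glorot-uniform input kernels, orthogonal
recurrent kernels, zero biases with the forget-gate bias at 1.
Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import copy
import itertools
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import FEATURE_ORDER, SequenceDataset, merge_datasets, segment_record, span
from .signal_core import SignalRecord

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build_model",
    "train",
    "condition_signal",
    "run_grid",
    "enumerate_grid",
    "GRID_L", "GRID_S", "GRID_NL", "GRID_NH",
    "lstm_cell_step",
    "save_model",
    "load_model",
]

# hyperparameter grid of the variant search
GRID_L = (4, 8, 16, 24, 32)
GRID_S = (1, 2, 4, 8, 10, 16)
GRID_NL = (1, 2)
GRID_NH = (4, 8, 16, 32)

N_FEATURES = len(FEATURE_ORDER)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one network variant plus training settings."""

    L: int
    S: int
    n_hidden: int = 8
    n_layers: int = 1
    epochs: int = 60
    seed: int = 0
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "mae"

    def validate_grid(self) -> None:
        """Reject values outside the variant-search grid."""
        if self.L not in GRID_L:
            raise ValueError(f"L={self.L} outside grid {GRID_L}")
        if self.S not in GRID_S:
            raise ValueError(f"S={self.S} outside grid {GRID_S}")
        if self.n_layers not in GRID_NL:
            raise ValueError(f"n_layers={self.n_layers} outside grid {GRID_NL}")
        if self.n_hidden not in GRID_NH:
            raise ValueError(f"n_hidden={self.n_hidden} outside grid {GRID_NH}")


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int, cols: int) -> np.ndarray:
    """Block-orthogonal (n, cols) matrix, cols a multiple of n."""
    blocks = []
    for _ in range(cols // n):
        a = rng.standard_normal((n, n))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


def _init_layer(rng: np.random.Generator, d: int, h: int) -> dict[str, np.ndarray]:
    # gate order in the stacked matrices: i, f, c~, o
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # unit forget bias
    return {
        "W": _glorot(rng, d, 4 * h),
        "U": _orthogonal(rng, h, 4 * h),
        "b": b,
    }


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def lstm_cell_step(x, h_prev, c_prev, W, U, b):
    """One scalar-friendly LSTM step; returns (h, c, gates).

    Reference path used for spot checks of the vectorized forward pass
    and by the operation-counting cost oracle.
    """
    z = x @ W + h_prev @ U + b
    hs = len(h_prev) if np.ndim(h_prev) == 1 else h_prev.shape[-1]
    i = _sigmoid(z[..., 0 * hs : 1 * hs])
    f = _sigmoid(z[..., 1 * hs : 2 * hs])
    g = np.tanh(z[..., 2 * hs : 3 * hs])
    o = _sigmoid(z[..., 3 * hs : 4 * hs])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, (i, f, g, o)


def _lstm_forward(X: np.ndarray, params: dict) -> tuple[np.ndarray, list]:
    """Full-sequence forward of one layer. X: (B, T, d) -> H: (B, T, h)."""
    B, T, d = X.shape
    h = params["b"].shape[0] // 4
    Wx = X.reshape(B * T, d) @ params["W"]
    Wx = Wx.reshape(B, T, 4 * h)
    H = np.empty((B, T, h))
    h_t = np.zeros((B, h))
    c_t = np.zeros((B, h))
    caches = []
    for t in range(T):
        z = Wx[:, t, :] + h_t @ params["U"] + params["b"]
        i = _sigmoid(z[:, 0 * h : 1 * h])
        f = _sigmoid(z[:, 1 * h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = _sigmoid(z[:, 3 * h : 4 * h])
        c_new = f * c_t + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((h_t, c_t, i, f, g, o, c_new, tanh_c))
        h_t, c_t = h_new, c_new
        H[:, t, :] = h_t
    return H, caches


def _lstm_backward(
    X: np.ndarray, params: dict, caches: list, dH: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Backward-through-time given dL/dH for every timestep."""
    B, T, d = X.shape
    h = params["b"].shape[0] // 4
    dW = np.zeros_like(params["W"])
    dU = np.zeros_like(params["U"])
    db = np.zeros_like(params["b"])
    dX = np.empty_like(X)
    dh_next = np.zeros((B, h))
    dc_next = np.zeros((B, h))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, c_new, tanh_c = caches[t]
        dh = dH[:, t, :] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1.0 - tanh_c**2) + dc_next
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += X[:, t, :].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t, :] = dz @ params["W"].T
        dh_next = dz @ params["U"].T
    return dX, {"W": dW, "U": dU, "b": db}


def _forward(params: list[dict], X: np.ndarray, want_caches: bool = False):
    """Full network forward: stacked LSTM layers + linear head on h_T."""
    H = X
    layer_io = []
    for layer in params[:-1]:
        inp = H
        H, caches = _lstm_forward(inp, layer)
        layer_io.append((inp, caches))
    head = params[-1]
    y = H[:, -1, :] @ head["w"] + head["b"]
    if want_caches:
        return y[:, 0], H, layer_io
    return y[:, 0]


def _backward(params: list[dict], X, y, dy, H, layer_io):
    """Gradients of all parameters given dL/dy (shape (B,))."""
    head = params[-1]
    grads: list[dict] = [None] * len(params)
    h_last = H[:, -1, :]
    grads[-1] = {
        "w": h_last.T @ dy[:, None],
        "b": np.array([dy.sum()]),
    }
    B, T, _ = X.shape
    dH = np.zeros_like(H)
    dH[:, -1, :] = dy[:, None] * head["w"][:, 0][None, :]
    for li in range(len(params) - 2, -1, -1):
        inp, caches = layer_io[li]
        dX, g = _lstm_backward(inp, params[li], caches, dH)
        grads[li] = g
        dH = dX
    return grads


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Network parameters plus training history.

    ``history`` records per-epoch mean-absolute-error losses; the weights
    kept are those of the epoch with the best (lowest) evaluation loss.
    """

    config: ModelConfig
    params: list[dict]
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"train_loss": [], "eval_loss": []}
    )
    eval_loss_best: float | None = None

    def num_params(self) -> int:
        return int(
            sum(v.size for layer in self.params for v in layer.values())
        )

    def predict(self, sequences: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty(len(sequences))
        for s in range(0, len(sequences), batch_size):
            out[s : s + batch_size] = _forward(
                self.params, sequences[s : s + batch_size]
            )
        return out


def build_model(config: ModelConfig) -> TrainedModel:
    """Seeded, untrained network for the given hyperparameters."""
    if config.n_layers < 1:
        raise ValueError("need at least one recurrent layer")
    rng = np.random.default_rng(config.seed)
    params: list[dict] = []
    d = N_FEATURES
    for _ in range(config.n_layers):
        params.append(_init_layer(rng, d, config.n_hidden))
        d = config.n_hidden
    params.append(
        {
            "w": _glorot(rng, config.n_hidden, 1),
            "b": np.zeros(1),
        }
    )
    return TrainedModel(config=config, params=params)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _mae(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - target)))


def _per_record_loss(model: TrainedModel, ds: SequenceDataset) -> float:
    """Evaluation loss averaged per record, then across records."""
    pred = model.predict(ds.sequences)
    err = np.abs(pred - ds.targets)
    rids = np.array([rid for rid, _ in ds.provenance])
    losses = [float(err[rids == rid].mean()) for rid in np.unique(rids)]
    return float(np.mean(losses))


def train(
    model: TrainedModel,
    train_ds: SequenceDataset,
    eval_ds: SequenceDataset,
    verbose: bool = False,
) -> TrainedModel:
    """Adam/MAE training loop retaining the best-evaluation-loss weights.

    The evaluation loss is the mean absolute error averaged per
    evaluation record, then across records.  Zero epochs returns the
    untrained model with empty history.
    """
    cfg = model.config
    if cfg.epochs == 0:
        return model
    if len(train_ds) == 0 or len(eval_ds) == 0:
        raise ValueError("empty dataset")
    if train_ds.L != cfg.L:
        raise ValueError("dataset L differs from model config")
    if cfg.optimizer != "adam" or cfg.loss != "mae":
        raise ValueError("only the adam optimiser with mae loss is supported")
    rng = np.random.default_rng(cfg.seed + 1)

    # Adam state mirrors the parameter structure
    m_state = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in model.params]
    v_state = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in model.params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best = np.inf
    best_params = None

    X_all, y_all = train_ds.sequences, train_ds.targets
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X_all))
        epoch_losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            X, target = X_all[idx], y_all[idx]
            y, H, layer_io = _forward(model.params, X, want_caches=True)
            resid = y - target
            epoch_losses.append(np.abs(resid).mean())
            dy = np.sign(resid) / len(idx)
            grads = _backward(model.params, X, y, dy, H, layer_io)
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for layer, g, m, v in zip(model.params, grads, m_state, v_state):
                for k in layer:
                    m[k] = beta1 * m[k] + (1 - beta1) * g[k].reshape(m[k].shape)
                    v[k] = beta2 * v[k] + (1 - beta2) * g[k].reshape(v[k].shape) ** 2
                    layer[k] = layer[k] - cfg.learning_rate * (m[k] / corr1) / (
                        np.sqrt(v[k] / corr2) + eps
                    )
        eval_loss = _per_record_loss(model, eval_ds)
        model.history["train_loss"].append(float(np.mean(epoch_losses)))
        model.history["eval_loss"].append(eval_loss)
        if eval_loss < best:
            best = eval_loss
            best_params = copy.deepcopy(model.params)
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}  "
                f"train {model.history['train_loss'][-1]:.4f}  eval {eval_loss:.4f}"
            )
    model.params = best_params
    model.eval_loss_best = float(best)
    return model


# ---------------------------------------------------------------------------
# inference on whole records
# ---------------------------------------------------------------------------

def condition_signal(model: TrainedModel, record: SignalRecord) -> SignalRecord:
    """Conditioned PPG for a normalized record, same length as the input.

    Runs hop-1 segmentation and predicts one value per end sample.  The
    first ``(L-1)*S`` samples lack a full history; the record is
    left-padded with its first sample's values so the output covers the
    whole record.  Predictions are clipped to [-1, 1].
    """
    cfg = model.config
    pad = (cfg.L - 1) * cfg.S
    if len(record) < 2:
        raise ValueError("record too short to condition")
    padded = record.replace(
        **{
            name: np.concatenate(
                [np.full(pad, getattr(record, name)[0]), getattr(record, name)]
            )
            for name in FEATURE_ORDER
        },
        target=np.concatenate(
            [np.full(pad, record.target[0]), record.target]
        )
        if record.target is not None
        else np.zeros(pad + len(record)),
    )
    ds = segment_record(padded, cfg.L, cfg.S, hop=1)
    conditioned = np.clip(model.predict(ds.sequences), -1.0, 1.0)
    assert len(conditioned) == len(record)
    return record.replace(ppg=conditioned)


# ---------------------------------------------------------------------------
# variant grid
# ---------------------------------------------------------------------------

def enumerate_grid(
    grid_L=GRID_L, grid_S=GRID_S, grid_NL=GRID_NL, grid_NH=GRID_NH, **defaults
) -> list[ModelConfig]:
    """Cartesian product of the hyperparameter lists as ModelConfigs."""
    return [
        ModelConfig(L=L, S=S, n_layers=nl, n_hidden=nh, **defaults)
        for L, S, nl, nh in itertools.product(grid_L, grid_S, grid_NL, grid_NH)
    ]


def run_grid(
    corpus: tuple[list[SignalRecord], list[SignalRecord]] | None = None,
    grid_L=GRID_L,
    grid_S=GRID_S,
    grid_NL=GRID_NL,
    grid_NH=GRID_NH,
    epochs: int = 60,
    seed: int = 0,
    hop: int = 1,
    verbose: bool = False,
) -> pd.DataFrame:
    """Train every variant of the grid and tabulate loss and cost.

    ``corpus`` is a (train records, eval records) pair of normalized,
    targeted records; with ``corpus=None`` the table holds the
    enumeration and analytic costs only (no training).  ``epochs`` and
    ``hop`` allow reduced-scale sweeps.
    """
    from .cost_model import CostTable, variant_cost

    table = CostTable()
    rows = []
    configs = enumerate_grid(grid_L, grid_S, grid_NL, grid_NH, epochs=epochs, seed=seed)
    for cfg in configs:
        row = {
            "L": cfg.L,
            "S": cfg.S,
            "n_layers": cfg.n_layers,
            "n_hidden": cfg.n_hidden,
            "cost": variant_cost(cfg, table),
            "eval_loss_best": np.nan,
        }
        if corpus is not None:
            train_recs, eval_recs = corpus
            tr = merge_datasets([segment_record(r, cfg.L, cfg.S, hop) for r in train_recs])
            ev = merge_datasets([segment_record(r, cfg.L, cfg.S, hop) for r in eval_recs])
            model = train(build_model(cfg), tr, ev, verbose=verbose)
            row["eval_loss_best"] = model.eval_loss_best
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence: pickle weights + JSON sidecar config
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump({"params": model.params, "history": model.history,
                     "eval_loss_best": model.eval_loss_best}, fh)
    path.with_suffix(".config.json").write_text(
        json.dumps(model.config.__dict__, indent=2)
    )


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    cfg = ModelConfig(**json.loads(path.with_suffix(".config.json").read_text()))
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    return TrainedModel(
        config=cfg,
        params=blob["params"],
        history=blob["history"],
        eval_loss_best=blob["eval_loss_best"],
    )
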