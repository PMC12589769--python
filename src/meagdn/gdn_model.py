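"""Graph-attention forecaster over multichannel AM-spike trains.

Each electrode i carries a learnable embedding v_i in R^d. Given the w most
recent samples x_i(t) of every channel, the model

1. lifts each window through a shared linear map, u_i = W x_i;
2. forms g_i = v_i (+) u_i and scores every ordered pair with a single
   learnable attention vector, pi_ij = LeakyReLU(a . (g_i (+) g_j));
3. row-softmaxes the scores into attention coefficients alpha_ij (the full
   candidate set, including j = i, is kept - no top-k pruning);
4. aggregates z_i = ReLU(sum_j alpha_ij u_j) and predicts the next sample of
   every channel through a small fully connected readout applied to the
   embedding-gated features v_i o z_i.

Training minimizes the mean squared one-step forecasting error with Adam.
After training, the per-target attention matrices are the time-varying
directed graphs consumed by the centrality-descriptor stage: alpha_ij is the
weight with which channel j's window contributes to predicting channel i, so
an above-uniform alpha_ij is rendered as a directed edge j -> i.

The model and its gradients are implemented directly in numpy; parameter
counts are tiny (N = 16, d = 128) and CPU minibatch training is fast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, DataError, NumericalError
from .preprocessing import WindowBatch

logger = logging.getLogger(__name__)


@dataclass
class GDNConfig:
    """Training hyperparameters of the forecaster (defaults: the study values)."""

    n_channels: int = 16
    window: int = 56
    embed_dim: int = 128
    hidden_units: int = 12
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 200
    init_mu: float = 0.0
    init_sigma: float = 1e-3
    optimizer: str = "adam"
    leaky_slope: float = 0.2
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim <= 0 or self.window <= 0 or self.hidden_units <= 0:
            raise ConfigError("embed_dim, window and hidden_units must be positive")
        if self.epochs <= 0:
            raise ConfigError("epochs must be positive")
        if self.optimizer.lower() != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GDNConfig":
        d = dict(d)
        if "adam_betas" in d:
            d["adam_betas"] = tuple(d["adam_betas"])
        return cls(**d)


PARAM_NAMES = ("V", "W", "a", "p", "W1", "b1", "W2", "b2")


@dataclass
class GDNModel:
    """Learnable parameters of the forecaster.

    V: (N, d) channel embeddings; W: (d, w) shared window map; a: (4d,)
    attention vector; p: (d,) per-node scalar readout; W1/b1, W2/b2: the
    width-``hidden_units`` fully connected output layer mapping the N pooled
    features to the N predictions.
    """

    config: GDNConfig
    V: np.ndarray
    W: np.ndarray
    a: np.ndarray
    p: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def initialize(cls, config: GDNConfig) -> "GDNModel":
        """Random initialization: embeddings N(init_mu, init_sigma^2); the
        remaining weights Glorot-uniform; biases zero."""
        rng = np.random.default_rng(config.seed)
        N, d, w, h = (config.n_channels, config.embed_dim, config.window,
                      config.hidden_units)

        def glorot(shape):
            fan_in, fan_out = shape[-1], shape[0]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        return cls(
            config=config,
            V=rng.normal(config.init_mu, config.init_sigma, size=(N, d)),
            W=glorot((d, w)),
            a=rng.uniform(-1, 1, size=4 * d) * np.sqrt(3.0 / (4 * d)),
            p=glorot((1, d))[0],
            W1=glorot((h, N)),
            b1=np.zeros(h),
            W2=glorot((N, h)),
            b2=np.zeros(N),
        )

    def params(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    # ---- checkpoint I/O -------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: a JSON config header plus the flat
        little-endian float64 parameter arrays (named .npz container)."""
        arrays = {k: np.asarray(v, dtype="<f8") for k, v in self.params().items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GDNModel":
        with np.load(path) as z:
            config = GDNConfig.from_dict(
                json.loads(bytes(z["__config__"].tolist()).decode()))
            kw = {k: z[k] for k in PARAM_NAMES}
        return cls(config=config, **kw)


@dataclass
class GraphSnapshot:
    """The attention matrix at one forecasting target and its binarization.

    alpha is row-stochastic: row i holds the weights with which every channel
    j (including i) contributes to predicting channel i. adjacency[src, dst]
    is True iff alpha[dst, src] exceeds the binarization threshold and
    src != dst (above-uniform attention, edge j -> i for "j models i").
    """

    alpha: np.ndarray
    adjacency: np.ndarray
    time_index: int
    segment_id: int


@dataclass
class ForecastReport:
    """Per-channel one-step forecasting quality on one window batch.

    nrmse is the RMSE divided by the SD of the expected series; max_xcorr is
    the maximum of the normalized cross-correlation between the predicted
    and expected series. Channels whose expected series has zero SD are
    skipped (recorded in ``skipped_channels``).
    """

    nrmse: np.ndarray
    max_xcorr: np.ndarray
    split: str = "test"
    skipped_channels: list = field(default_factory=list)

    def median_mad(self) -> dict:
        def mm(x):
            x = x[np.isfinite(x)]
            med = float(np.median(x))
            return med, float(np.median(np.abs(x - med)))

        n_med, n_mad = mm(self.nrmse)
        c_med, c_mad = mm(self.max_xcorr)
        return {"nrmse_median": n_med, "nrmse_mad": n_mad,
                "max_xcorr_median": c_med, "max_xcorr_mad": c_mad}


# ---------------------------------------------------------------------------
# forward / backward


def embedding_similarity(V: np.ndarray) -> np.ndarray:
    """Cosine similarity between every pair of channel embeddings.

    Diagnostic of the learned channel geometry; with the full candidate set
    retained it does not gate which edges the attention may use.
    """
    V = np.asarray(V, dtype=np.float64)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise DataError("cannot normalize a zero-norm embedding vector")
    Vn = V / norms[:, None]
    return Vn @ Vn.T


def _forward(model: GDNModel, X: np.ndarray) -> dict:
    """Batched forward pass; X has shape (B, N, w). Returns all
    intermediates needed for the backward pass."""
    cfg = model.config
    d = cfg.embed_dim
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite input block")
    U = np.einsum("bnw,dw->bnd", X, model.W)                 # W x_i
    B, N, _ = U.shape
    G = np.concatenate([np.broadcast_to(model.V, (B, N, d)), U], axis=2)
    a_src, a_dst = model.a[:2 * d], model.a[2 * d:]
    sc_src = G @ a_src                                       # (B, N)
    sc_dst = G @ a_dst
    P_pre = sc_src[:, :, None] + sc_dst[:, None, :]          # pi before LeakyReLU
    P = np.where(P_pre > 0, P_pre, cfg.leaky_slope * P_pre)
    P_shift = P - P.max(axis=2, keepdims=True)               # stable softmax
    E = np.exp(P_shift)
    alpha = E / E.sum(axis=2, keepdims=True)
    Zpre = np.einsum("bij,bjd->bid", alpha, U)
    Z = np.maximum(Zpre, 0.0)
    F = model.V[None] * Z
    h = F @ model.p                                          # (B, N)
    Hpre = h @ model.W1.T + model.b1
    Hh = np.maximum(Hpre, 0.0)
    s_hat = Hh @ model.W2.T + model.b2
    if not np.all(np.isfinite(s_hat)):
        raise NumericalError("non-finite forward pass (diverged parameters?)")
    return dict(X=X, U=U, G=G, P_pre=P_pre, alpha=alpha, Zpre=Zpre, Z=Z,
                F=F, h=h, Hpre=Hpre, Hh=Hh, s_hat=s_hat)


def _backward(model: GDNModel, cache: dict, y: np.ndarray) -> tuple[float, dict]:
    """Gradient of the batch-mean squared error w.r.t. every parameter."""
    cfg = model.config
    d = cfg.embed_dim
    X, U, G = cache["X"], cache["U"], cache["G"]
    alpha, Zpre, Z, F, h = cache["alpha"], cache["Zpre"], cache["Z"], cache["F"], cache["h"]
    Hpre, Hh, s_hat = cache["Hpre"], cache["Hh"], cache["s_hat"]
    B = X.shape[0]

    err = s_hat - y
    loss = float(np.sum(err ** 2) / B)

    dY = 2.0 * err / B
    dW2 = dY.T @ Hh
    db2 = dY.sum(axis=0)
    dHpre = (dY @ model.W2) * (Hpre > 0)
    dW1 = dHpre.T @ h
    db1 = dHpre.sum(axis=0)
    dh = dHpre @ model.W1                                    # (B, N)
    dF = dh[:, :, None] * model.p[None, None, :]
    dp = np.einsum("bn,bnd->d", dh, F)
    dZ = dF * model.V[None]
    dV = (dF * Z).sum(axis=0)
    dZpre = dZ * (Zpre > 0)
    dalpha = np.einsum("bid,bjd->bij", dZpre, U)
    dU = np.einsum("bij,bid->bjd", alpha, dZpre)
    dP = alpha * (dalpha - np.sum(dalpha * alpha, axis=2, keepdims=True))
    dP_pre = dP * np.where(cache["P_pre"] > 0, 1.0, cfg.leaky_slope)
    d_sc_src = dP_pre.sum(axis=2)
    d_sc_dst = dP_pre.sum(axis=1)
    a_src, a_dst = model.a[:2 * d], model.a[2 * d:]
    da = np.concatenate([np.einsum("bn,bnk->k", d_sc_src, G),
                         np.einsum("bn,bnk->k", d_sc_dst, G)])
    dG = d_sc_src[:, :, None] * a_src[None, None, :] \
        + d_sc_dst[:, :, None] * a_dst[None, None, :]
    dV += dG[:, :, :d].sum(axis=0)
    dU += dG[:, :, d:]
    dW = np.einsum("bnd,bnw->dw", dU, X)

    return loss, {"V": dV, "W": dW, "a": da, "p": dp,
                  "W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def attention_forward(model: GDNModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated features z (N, d) and attention matrix alpha (N, N) for one
    input block x of shape (N, w)."""
    cache = _forward(model, np.asarray(x, dtype=np.float64)[None])
    return cache["Z"][0], cache["alpha"][0]


def forecast(model: GDNModel, x: np.ndarray) -> np.ndarray:
    """One-step prediction s_hat (length N) for one input block (N, w)."""
    cache = _forward(model, np.asarray(x, dtype=np.float64)[None])
    return cache["s_hat"][0]


def batch_forecast(model: GDNModel, batch: WindowBatch,
                   chunk: int = 2048) -> np.ndarray:
    """Predictions for every window of a batch, shape (n, N)."""
    outs = []
    for i in range(0, len(batch), chunk):
        outs.append(_forward(model, batch.X[i:i + chunk])["s_hat"])
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict, lr: float, betas, eps: float):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_gdn(batch: WindowBatch, config: GDNConfig,
              model: GDNModel | None = None,
              val_batch: WindowBatch | None = None,
              ) -> tuple[GDNModel, dict]:
    """Minibatch Adam training of the one-step forecaster.

    Returns the trained model and a history dict with per-epoch mean training
    loss (and validation loss when a held-out batch is supplied).
    """
    if len(batch) == 0:
        raise DataError("empty window batch")
    if batch.n_channels != config.n_channels:
        raise ConfigError("batch channel count does not match the config")
    if model is None:
        model = GDNModel.initialize(config)
    params = model.params()
    opt = _Adam(params, config.learning_rate, config.adam_betas, config.adam_eps)
    rng = np.random.default_rng(config.seed + 1)

    n = len(batch)
    bs = min(config.batch_size, n)
    history = {"train_loss": [], "val_loss": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        weights = []
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            cache = _forward(model, batch.X[idx])
            loss, grads = _backward(model, cache, batch.y[idx])
            opt.step(params, grads)
            losses.append(loss)
            weights.append(len(idx))
        history["train_loss"].append(float(np.average(losses, weights=weights)))
        if val_batch is not None and len(val_batch):
            pred = batch_forecast(model, val_batch)
            history["val_loss"].append(
                float(np.sum((pred - val_batch.y) ** 2) / len(val_batch)))
    return model, history


# ---------------------------------------------------------------------------
# graph extraction and forecast evaluation


def extract_graphs(model: GDNModel, batch: WindowBatch,
                   tau: float | None = None, chunk: int = 2048) -> list:
    """One GraphSnapshot per forecasting target.

    The binarized adjacency keeps edge j -> i iff alpha[i, j] strictly
    exceeds tau (default 1/N: above-uniform attention); self-loops excluded.
    """
    N = batch.n_channels
    if tau is None:
        tau = 1.0 / N
    snapshots = []
    for i in range(0, len(batch), chunk):
        cache = _forward(model, batch.X[i:i + chunk])
        for b in range(cache["alpha"].shape[0]):
            alpha = cache["alpha"][b]
            adjacency = alpha.T > tau
            np.fill_diagonal(adjacency, False)
            snapshots.append(GraphSnapshot(
                alpha=alpha, adjacency=adjacency,
                time_index=int(batch.time_index[i + b]),
                segment_id=int(batch.segment_id[i + b])))
    return snapshots


def mean_attention(model: GDNModel, batch: WindowBatch,
                   chunk: int = 4096) -> np.ndarray:
    """Mean attention matrix over every target of a batch (N, N)."""
    total = np.zeros((batch.n_channels, batch.n_channels))
    for i in range(0, len(batch), chunk):
        total += _forward(model, batch.X[i:i + chunk])["alpha"].sum(axis=0)
    return total / len(batch)


def evaluate_forecast(model: GDNModel, batch: WindowBatch,
                      split: str = "test") -> ForecastReport:
    """Per-channel NRMSE and maximum normalized cross-correlation between the
    predicted and expected one-step series."""
    if len(batch) == 0:
        raise DataError("empty window batch")
    pred = batch_forecast(model, batch)
    N = batch.n_channels
    nrmse = np.full(N, np.nan)
    max_xcorr = np.full(N, np.nan)
    skipped = []
    for ch in range(N):
        expected = batch.y[:, ch]
        sd = expected.std()
        if sd == 0:
            skipped.append(ch)
            logger.info("channel %d skipped: zero-variance expected series", ch)
            continue
        err = pred[:, ch] - expected
        nrmse[ch] = np.sqrt(np.mean(err ** 2)) / sd
        a = (pred[:, ch] - pred[:, ch].mean())
        b = (expected - expected.mean())
        denom = np.sqrt(np.sum(a ** 2) * np.sum(b ** 2))
        if denom == 0:
            max_xcorr[ch] = 0.0
        else:
            max_xcorr[ch] = float(np.max(sps.correlate(a, b, mode="full")) / denom)
    return ForecastReport(nrmse=nrmse, max_xcorr=max_xcorr, split=split,
                          skipped_channels=skipped)


def aggregate_reports(reports: list) -> dict:
    """Median / median-absolute-deviation across wells of per-channel metrics
    (the layout used to summarize forecasting quality per condition)."""
    nrmse = np.concatenate([r.nrmse[np.isfinite(r.nrmse)] for r in reports])
    xcorr = np.concatenate([r.max_xcorr[np.isfinite(r.max_xcorr)] for r in reports])

    def mm(x):
        med = float(np.median(x))
        return med, float(np.median(np.abs(x - med)))

    n_med, n_mad = mm(nrmse)
    c_med, c_mad = mm(xcorr)
    return {"nrmse_median": n_med, "nrmse_mad": n_mad,
            "max_xcorr_median": c_med, "max_xcorr_mad": c_mad}
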