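"""Compact temporal fusion transformer trained with a SMAPE loss.

The network follows the temporal fusion transformer design at small scale:
per-variable linear/embedding input transforms, variable-selection weights
produced by a gated residual network (GRN), an LSTM encoder over the past
``encoder_length`` months and an LSTM decoder over the forecast months,
gated skip connections with layer normalization, static enrichment from a
target-identity embedding, interpretable multi-head attention (shared values,
averaged heads) over the full sequence with a causal mask, a position-wise
GRN feed-forward block, and a linear point-forecast head.

Training minimizes the SMAPE loss on the original scale with dropout,
global-gradient-norm clipping, Adam, reduce-on-plateau learning-rate decay,
and early stopping on validation SMAPE.  The multivariate variant feeds both
incidence and unemployment histories as past inputs to a single shared
network and selects the emitted series through the target-identity embedding.

Everything runs on the in-house NumPy autodiff core; with a fixed seed and
config, training is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ..evaluation import smape
from ..series import MonthlySeries
from ._autodiff import Tensor, cat, stack
from .base import ForecastResult

logger = logging.getLogger(__name__)

__all__ = ["TftConfig", "fit_tft", "FittedTft", "smape_loss", "default_search_space"]

SMAPE_EPS = 1e-3  # denominator floor, in target units, for gradient stability


def smape_loss(pred: Tensor, actual: np.ndarray,
               sample_weights: np.ndarray | None = None) -> Tensor:
    """Differentiable SMAPE (percent) with an epsilon-floored denominator.

    ``sample_weights`` (one per row of a 2-D batch) reweight samples in the
    mean; the multivariate model uses them to keep the auxiliary target's
    typically larger relative errors from dominating the shared gradients.
    """
    a = Tensor(actual, requires_grad=False)
    diff = (pred - a).abs()
    denom = (pred.abs() + a.abs()) * 0.5 + SMAPE_EPS
    ratio = diff / denom
    if sample_weights is None:
        return ratio.mean() * 100.0
    w = np.asarray(sample_weights, dtype=float)
    per_sample = ratio.mean(axis=-1)
    return (per_sample * Tensor(w / w.sum(), requires_grad=False)).sum() * 100.0


@dataclass(frozen=True)
class TftConfig:
    hidden_size: int = 16
    attention_heads: int = 2
    dropout_rate: float = 0.1
    learning_rate: float = 5e-3
    batch_size: int = 32
    max_epochs: int = 150
    early_stop_patience: int = 15
    gradient_clip: float = 5.0
    encoder_length: int = 36
    decoder_length: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.hidden_size % self.attention_heads:
            raise ValueError("hidden_size must be divisible by attention_heads")


def default_search_space(rng: np.random.Generator, n_trials: int) -> list[TftConfig]:
    """Seeded random search over a small CPU-friendly hyperparameter space."""
    configs = []
    for _ in range(n_trials):
        hidden = int(rng.choice([8, 16, 32]))
        heads = int(rng.choice([h for h in (1, 2, 4) if hidden % h == 0]))
        configs.append(TftConfig(
            hidden_size=hidden,
            attention_heads=heads,
            dropout_rate=float(rng.uniform(0.1, 0.3)),
            learning_rate=float(10 ** rng.uniform(-3, -2)),
            batch_size=int(rng.choice([16, 32, 64])),
        ))
    return configs


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class _Params:
    """Flat parameter store with seeded Glorot initialization."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.tensors: list[Tensor] = []

    def linear(self, n_in: int, n_out: int) -> tuple[Tensor, Tensor]:
        limit = np.sqrt(6.0 / (n_in + n_out))
        W = Tensor(self.rng.uniform(-limit, limit, size=(n_in, n_out)))
        b = Tensor(np.zeros(n_out))
        self.tensors += [W, b]
        return W, b

    def matrix(self, n_in: int, n_out: int) -> Tensor:
        limit = np.sqrt(6.0 / (n_in + n_out))
        W = Tensor(self.rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.tensors.append(W)
        return W

    def layernorm(self, dim: int) -> tuple[Tensor, Tensor]:
        g = Tensor(np.ones(dim))
        b = Tensor(np.zeros(dim))
        self.tensors += [g, b]
        return g, b


def _apply_linear(x: Tensor, Wb) -> Tensor:
    W, b = Wb
    return x @ W + b


def _apply_layernorm(x: Tensor, gb, eps: float = 1e-5) -> Tensor:
    g, b = gb
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / ((var + eps) ** 0.5) * g + b


class _GRN:
    """Gated residual network: ELU bottleneck, GLU gate, residual + layernorm."""

    def __init__(self, p: _Params, n_in: int, hidden: int, n_out: int,
                 context: bool = False):
        self.lin1 = p.linear(n_in, hidden)
        self.linc = p.matrix(hidden, hidden) if context else None
        self.lin2 = p.linear(hidden, n_out)
        self.gate = p.linear(n_out, n_out)
        self.value = p.linear(n_out, n_out)
        self.skip = p.linear(n_in, n_out) if n_in != n_out else None
        self.norm = p.layernorm(n_out)

    def __call__(self, x: Tensor, context: Tensor | None = None,
                 dropout: float = 0.0, rng=None) -> Tensor:
        a = _apply_linear(x, self.lin1)
        if context is not None and self.linc is not None:
            a = a + context @ self.linc
        a = _apply_linear(a.elu(), self.lin2).dropout(dropout, rng)
        glu = _apply_linear(a, self.gate).sigmoid() * _apply_linear(a, self.value)
        skip = x if self.skip is None else _apply_linear(x, self.skip)
        return _apply_layernorm(skip + glu, self.norm)


class _LSTM:
    def __init__(self, p: _Params, n_in: int, hidden: int):
        self.W = p.matrix(n_in, 4 * hidden)
        self.U = p.matrix(hidden, 4 * hidden)
        self.b = Tensor(np.zeros(4 * hidden))
        p.tensors.append(self.b)
        self.h = hidden

    def run(self, xs: list[Tensor], h0: Tensor, c0: Tensor):
        """xs: list of (B, n_in) step inputs; returns outputs and final state."""
        h, c = h0, c0
        outs = []
        n = self.h
        for x in xs:
            z = x @ self.W + h @ self.U + self.b
            i = z[:, 0 * n : 1 * n].sigmoid()
            f = z[:, 1 * n : 2 * n].sigmoid()
            g = z[:, 2 * n : 3 * n].tanh()
            o = z[:, 3 * n : 4 * n].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs, h, c


class _VariableSelection:
    """Softmax variable weights from a GRN over the flattened embeddings."""

    def __init__(self, p: _Params, n_vars: int, hidden: int):
        self.n_vars = n_vars
        self.weight_grn = _GRN(p, n_vars * hidden, hidden, n_vars, context=True)
        self.var_grns = [_GRN(p, hidden, hidden, hidden) for _ in range(n_vars)]

    def __call__(self, embs: list[Tensor], context: Tensor | None,
                 dropout: float, rng) -> Tensor:
        flat = cat(embs, axis=-1)
        w = self.weight_grn(flat, context, dropout, rng).softmax(axis=-1)
        out = None
        for v, (grn, emb) in enumerate(zip(self.var_grns, embs)):
            term = grn(emb, None, dropout, rng) * w[..., v : v + 1]
            out = term if out is None else out + term
        return out


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

class _TftNetwork:
    """The assembled model for ``n_targets`` co-modelled series."""

    def __init__(self, config: TftConfig, n_targets: int, rng: np.random.Generator):
        h = config.hidden_size
        self.config = config
        self.n_targets = n_targets
        p = _Params(rng)
        self.params = p

        self.month_emb = p.matrix(12, h)
        self.time_lin = p.linear(1, h)
        self.target_lins = [p.linear(1, h) for _ in range(n_targets)]
        self.static_emb = p.matrix(max(n_targets, 1), h)
        self.static_grn = _GRN(p, h, h, h)

        n_past = n_targets + 2   # target value(s), month, time index
        # decoder inputs: month, time index, and — in the multivariate model —
        # the forecast-origin level of each auxiliary target (the latest
        # observed unemployment state is known when forecasting incidence)
        n_fut = 2 + max(n_targets - 1, 0)
        self.anchor_lins = [p.linear(1, h) for _ in range(max(n_targets - 1, 0))]
        self.sel_past = _VariableSelection(p, n_past, h)
        self.sel_fut = _VariableSelection(p, n_fut, h)

        self.enc = _LSTM(p, h, h)
        self.dec = _LSTM(p, h, h)
        self.post_lstm_gate = p.linear(h, h)
        self.post_lstm_value = p.linear(h, h)
        self.post_lstm_norm = p.layernorm(h)
        self.enrich = _GRN(p, h, h, h, context=True)

        nh = config.attention_heads
        dh = h // nh
        self.Wq = [p.matrix(h, dh) for _ in range(nh)]
        self.Wk = [p.matrix(h, dh) for _ in range(nh)]
        self.Wv = p.matrix(h, dh)
        self.Wo = p.matrix(dh, h)
        self.post_attn_gate = p.linear(h, h)
        self.post_attn_value = p.linear(h, h)
        self.post_attn_norm = p.layernorm(h)
        self.ff = _GRN(p, h, h, h)
        self.final_gate = p.linear(h, h)
        self.final_value = p.linear(h, h)
        self.final_norm = p.layernorm(h)
        self.head = p.linear(h, 1)

    # -- helpers ------------------------------------------------------------

    def _embed_steps(self, targets_norm, months, time_idx, ids, rng, dropout,
                     include_targets: bool):
        """Per-variable embeddings, each (B, T, h)."""
        B, T = months.shape
        embs = []
        if include_targets:
            for k in range(self.n_targets):
                x = Tensor(targets_norm[k][..., None], requires_grad=False)
                embs.append(_apply_linear(x, self.target_lins[k]))
        onehot = np.zeros((B, T, 12))
        b_idx = np.repeat(np.arange(B), T)
        t_idx = np.tile(np.arange(T), B)
        onehot[b_idx, t_idx, months.reshape(-1) - 1] = 1.0
        embs.append(Tensor(onehot, requires_grad=False) @ self.month_emb)
        embs.append(_apply_linear(Tensor(time_idx[..., None], requires_grad=False),
                                  self.time_lin))
        return embs

    def forward(self, batch: dict, training: bool, rng=None) -> Tensor:
        """Normalized point forecasts, shape (B, decoder_steps)."""
        cfg = self.config
        drop = cfg.dropout_rate if training else 0.0
        rng = rng if training else None

        ids = batch["ids"]
        B = ids.size
        onehot_id = np.zeros((B, self.static_emb.shape[0]))
        onehot_id[np.arange(B), ids] = 1.0
        static = self.static_grn(
            Tensor(onehot_id, requires_grad=False) @ self.static_emb,
            None, drop, rng)                                  # (B, h)
        ctx = static.reshape(B, 1, -1)                        # broadcast over time

        past_embs = self._embed_steps(batch["past_targets"], batch["past_months"],
                                      batch["past_time"], ids, rng, drop, True)
        fut_embs = self._embed_steps(None, batch["fut_months"],
                                     batch["fut_time"], ids, rng, drop, False)
        Tdec_ = batch["fut_months"].shape[1]
        for k, lin in enumerate(self.anchor_lins):
            anchor = np.broadcast_to(
                batch["fut_anchors"][k][:, None, None], (B, Tdec_, 1))
            fut_embs.append(_apply_linear(Tensor(anchor, requires_grad=False), lin))
        past = self.sel_past(past_embs, ctx, drop, rng)       # (B, Tenc, h)
        fut = self.sel_fut(fut_embs, ctx, drop, rng)          # (B, Tdec, h)

        Tenc = batch["past_months"].shape[1]
        Tdec = batch["fut_months"].shape[1]
        h0 = static
        c0 = Tensor(np.zeros_like(static.data), requires_grad=False)
        enc_steps = [past[:, t, :] for t in range(Tenc)]
        enc_outs, hT, cT = self.enc.run(enc_steps, h0, c0)
        dec_steps = [fut[:, t, :] for t in range(Tdec)]
        dec_outs, _, _ = self.dec.run(dec_steps, hT, cT)

        lstm_out = stack(enc_outs + dec_outs, axis=1)         # (B, T, h)
        lstm_in = cat([past, fut], axis=1)
        gated = (_apply_linear(lstm_out, self.post_lstm_gate).sigmoid()
                 * _apply_linear(lstm_out, self.post_lstm_value))
        temporal = _apply_layernorm(lstm_in + gated, self.post_lstm_norm)

        enriched = self.enrich(temporal, ctx, drop, rng)      # (B, T, h)
        queries = enriched[:, Tenc:, :]                       # decoder positions

        T = Tenc + Tdec
        mask = np.zeros((Tdec, T))
        for j in range(Tdec):
            mask[j, Tenc + j + 1 :] = -1e9                    # causal within decoder
        dh = self.config.hidden_size // cfg.attention_heads
        V = enriched @ self.Wv                                # shared values
        heads = None
        for Wq, Wk in zip(self.Wq, self.Wk):
            scores = ((queries @ Wq) @ (enriched @ Wk).swap_last()) * (dh ** -0.5)
            attn = scores.softmax(axis=-1, mask=mask)
            out = attn @ V
            heads = out if heads is None else heads + out
        attn_out = (heads * (1.0 / cfg.attention_heads)) @ self.Wo
        attn_out = attn_out.dropout(drop, rng)

        dec_enriched = enriched[:, Tenc:, :]
        gated = (_apply_linear(attn_out, self.post_attn_gate).sigmoid()
                 * _apply_linear(attn_out, self.post_attn_value))
        x = _apply_layernorm(dec_enriched + gated, self.post_attn_norm)
        x = self.ff(x, None, drop, rng)
        dec_lstm = lstm_out[:, Tenc:, :]
        gated = (_apply_linear(x, self.final_gate).sigmoid()
                 * _apply_linear(x, self.final_value))
        x = _apply_layernorm(dec_lstm + gated, self.final_norm)
        return _apply_linear(x, self.head)[..., 0]            # (B, Tdec)

    def get_state(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.params.tensors]

    def set_state(self, state: list[np.ndarray]) -> None:
        for t, s in zip(self.params.tensors, state):
            t.data = s.copy()


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, tensors, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = tensors
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.t = 0

    def step(self, clip: float):
        grads = [t.grad if t.grad is not None else np.zeros_like(t.data)
                 for t in self.tensors]
        norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
        scale = min(1.0, clip / norm) if norm > 0 else 1.0
        self.t += 1
        for i, (t, g) in enumerate(zip(self.tensors, grads)):
            g = g * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            t.data = t.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for t in self.tensors:
            t.grad = None


def _time_index(history_len: int, horizon: int) -> float:
    return float(history_len + horizon)


class FittedTft:
    """A trained network plus the frozen history it conditions on."""

    def __init__(self, net: _TftNetwork, config: TftConfig, model_name: str,
                 history: list[MonthlySeries], norms: list[tuple[float, float]],
                 time_scale: float, validation_smape: float, n_epochs: int,
                 epochs_run: int = 0):
        self.net = net
        self.config = config
        self.model_name = model_name
        self._history = history            # one series per target id
        self._norms = norms
        self._time_scale = time_scale
        self.validation_smape = validation_smape
        self.n_epochs = n_epochs           # epoch with the best validation SMAPE
        self.epochs_run = epochs_run       # total epochs before early stop

    def _batch_for(self, target_id: int, horizon: int) -> dict:
        cfg = self.config
        hist = self._history[0]
        n = len(hist)
        enc = cfg.encoder_length
        past_targets = []
        for k, series in enumerate(self._history):
            mu, sd = self._norms[k]
            past_targets.append(((series.values[n - enc :] - mu) / sd)[None, :])
        months_all = hist.months
        past_months = months_all[n - enc :][None, :]
        fut_months = (((hist.start + n).month - 1 + np.arange(horizon)) % 12 + 1)[None, :]
        t0 = n - enc
        past_time = (np.arange(t0, n)[None, :] / self._time_scale)
        fut_time = (np.arange(n, n + horizon)[None, :] / self._time_scale)
        anchors = []
        for k in range(1, len(self._history)):
            mu, sd = self._norms[k]
            anchors.append(np.array([(self._history[k].values[-1] - mu) / sd]))
        return {
            "ids": np.array([target_id]),
            "past_targets": past_targets,
            "past_months": past_months,
            "past_time": past_time,
            "fut_months": fut_months,
            "fut_time": fut_time,
            "fut_anchors": anchors,
        }

    def _predict_id(self, target_id: int, horizon: int) -> np.ndarray:
        batch = self._batch_for(target_id, horizon)
        yhat = self.net.forward(batch, training=False).data[0]
        mu, sd = self._norms[target_id]
        return yhat * sd + mu

    def predict(self, horizon: int = 24) -> ForecastResult:
        inc = self._predict_id(0, horizon)
        extra = {}
        if self.net.n_targets > 1:
            extra["unemployment"] = self._predict_id(1, horizon)
        return ForecastResult(
            model=self.model_name, target="incidence", forecast=inc,
            chosen_config={
                "hidden_size": self.config.hidden_size,
                "attention_heads": self.config.attention_heads,
                "dropout_rate": round(self.config.dropout_rate, 4),
                "learning_rate": round(self.config.learning_rate, 6),
                "batch_size": self.config.batch_size,
                "encoder_length": self.config.encoder_length,
                "epochs_trained": self.n_epochs,
            },
            validation_smape=self.validation_smape,
            extra_targets=extra,
        )


def _build_samples(targets_norm: list[np.ndarray], months: np.ndarray,
                   time_scale: float, enc: int, dec: int,
                   n_targets: int, actuals: list[np.ndarray]) -> dict:
    """All sliding (encoder, decoder) samples over the training months."""
    n = months.size
    starts = np.arange(0, n - enc - dec + 1)
    ids, p_t, p_m, p_ti, f_m, f_ti, f_a, y = [], [], [], [], [], [], [], []
    for tid in range(n_targets):
        for s in starts:
            ids.append(tid)
            p_t.append([tn[s : s + enc] for tn in targets_norm])
            p_m.append(months[s : s + enc])
            p_ti.append(np.arange(s, s + enc) / time_scale)
            f_m.append(months[s + enc : s + enc + dec])
            f_ti.append(np.arange(s + enc, s + enc + dec) / time_scale)
            f_a.append([targets_norm[k][s + enc - 1] for k in range(1, n_targets)])
            y.append(actuals[tid][s + enc : s + enc + dec])
    return {
        "ids": np.array(ids),
        "past_targets": [np.stack([row[k] for row in p_t])
                         for k in range(n_targets)],
        "past_months": np.stack(p_m),
        "past_time": np.stack(p_ti),
        "fut_months": np.stack(f_m),
        "fut_time": np.stack(f_ti),
        "fut_anchors": [np.array([row[k] for row in f_a])
                        for k in range(n_targets - 1)],
        "y": np.stack(y),
    }


def _subset(batch: dict, idx: np.ndarray) -> dict:
    return {
        "ids": batch["ids"][idx],
        "past_targets": [pt[idx] for pt in batch["past_targets"]],
        "past_months": batch["past_months"][idx],
        "past_time": batch["past_time"][idx],
        "fut_months": batch["fut_months"][idx],
        "fut_time": batch["fut_time"][idx],
        "fut_anchors": [a[idx] for a in batch["fut_anchors"]],
        "y": batch["y"][idx],
    }


def _train_one(config: TftConfig, train_series: list[MonthlySeries],
               validation: MonthlySeries, model_name: str,
               time_scale: float) -> FittedTft:
    rng = np.random.default_rng(config.seed)
    n_targets = len(train_series)
    net = _TftNetwork(config, n_targets, rng)

    norms = []
    for s in train_series:
        mu = float(s.values.mean())
        sd = float(s.values.std()) or 1.0
        norms.append((mu, sd))
    targets_norm = [(s.values - mu) / sd for s, (mu, sd) in zip(train_series, norms)]
    months = train_series[0].months
    batch_all = _build_samples(targets_norm, months, time_scale,
                               config.encoder_length, config.decoder_length,
                               n_targets, [s.values for s in train_series])
    n_samples = batch_all["ids"].size

    # balance per-target gradient scale: weight each auxiliary target by the
    # ratio of naive (lag-12) in-sample SMAPE of the primary target to its own,
    # so the scored outcome keeps parity in the shared loss
    target_w = np.ones(n_targets)
    if n_targets > 1:
        from ..evaluation import smape as _smape
        naive = [
            _smape(s.values[12:], s.values[:-12]) for s in train_series
        ]
        for k in range(1, n_targets):
            target_w[k] = naive[0] / max(naive[k], 1e-9)
    sample_w = target_w[batch_all["ids"]]

    opt = _Adam(net.params.tensors, config.learning_rate)
    # provisional fitted view for validation forecasting during training
    fitted = FittedTft(net, config, model_name, train_series, norms, time_scale,
                       np.nan, 0)

    best_val, best_state, best_epoch = np.inf, net.get_state(), 0
    lr_wait = 0
    lr_patience = max(2, config.early_stop_patience // 3)
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n_samples)
        for lo in range(0, n_samples, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            sub = _subset(batch_all, idx)
            yhat = net.forward(sub, training=True, rng=rng)
            scales = np.array([norms[i] for i in sub["ids"]])
            pred = yhat * scales[:, 1:2] + scales[:, 0:1]
            loss = smape_loss(pred, sub["y"],
                              sample_weights=sample_w[idx] if n_targets > 1 else None)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"{model_name}: divergent training (non-finite loss)")
            opt.zero_grad()
            loss.backward()
            opt.step(config.gradient_clip)

        val_fc = fitted._predict_id(0, len(validation))
        val = smape(validation.values, val_fc)
        if val < best_val:
            best_val, best_state, best_epoch = val, net.get_state(), epoch
            lr_wait = 0
        else:
            lr_wait += 1
            if lr_wait >= lr_patience:
                opt.lr = max(opt.lr * 0.5, min(1e-4, config.learning_rate))
                lr_wait = 0
            if epoch - best_epoch >= config.early_stop_patience:
                break

    net.set_state(best_state)
    return FittedTft(net, config, model_name, train_series, norms, time_scale,
                     best_val, best_epoch, epochs_run=epoch)


def fit_tft(
    train: MonthlySeries | tuple[MonthlySeries, ...],
    validation: MonthlySeries,
    config: TftConfig | None = None,
    n_trials: int = 1,
    seed: int = 0,
) -> FittedTft:
    """Train the (multi)variate TFT, optionally over a random config search.

    ``train`` is the incidence training segment, or an (incidence,
    unemployment) tuple for the multivariate variant; ``validation`` is always
    the 12 incidence validation months.  With ``n_trials > 1`` a seeded random
    search over the default hyperparameter space picks the config with the
    lowest validation SMAPE; an explicit ``config`` with ``n_trials=1`` skips
    the search.  After training, the conditioning history is extended with the
    validation months so test-period forecasts follow them.
    """
    series = list(train) if isinstance(train, (tuple, list)) else [train]
    name = "multitft" if len(series) > 1 else "unitft"
    rng = np.random.default_rng(seed)
    template = config if config is not None else TftConfig()
    if config is not None and n_trials == 1:
        configs = [replace(config, seed=config.seed or seed)]
    else:
        # sampled trials inherit the template's budget/shape fields
        configs = [
            replace(c,
                    max_epochs=template.max_epochs,
                    early_stop_patience=template.early_stop_patience,
                    encoder_length=template.encoder_length,
                    decoder_length=template.decoder_length,
                    gradient_clip=template.gradient_clip,
                    seed=int(rng.integers(2 ** 31)))
            for c in default_search_space(rng, n_trials)
        ]

    # time index normalized by the full window span the model will ever see
    time_scale = float(len(series[0]) + len(validation) + 24)

    best = None
    for i, cfg in enumerate(configs):
        try:
            fitted = _train_one(cfg, series, validation, name, time_scale)
        except RuntimeError as exc:
            logger.info("tft trial %d aborted: %s", i, exc)
            continue
        if best is None or fitted.validation_smape < best.validation_smape:
            best = fitted
    if best is None:
        raise RuntimeError("all TFT trials failed")

    # condition test-period forecasts on train + validation history
    extended = []
    for k, s in enumerate(series):
        if k == 0:
            vals = np.concatenate([s.values, validation.values])
        else:
            # unemployment validation months: persist the training tail if the
            # caller did not supply them via ``extend_history``
            vals = np.concatenate([s.values, np.full(len(validation), s.values[-1])])
        extended.append(MonthlySeries(s.label, s.start, vals, units=s.units))
    best._history = extended
    return best


def extend_history(fitted: FittedTft, series: list[MonthlySeries]) -> FittedTft:
    """Replace the conditioning history (e.g. with true unemployment months)."""
    if len(series) != fitted.net.n_targets:
        raise ValueError("one history series per target required")
    fitted._history = series
    return fitted
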