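"""The G4 convolutional classifier: encoding, architecture, training.

The model maps a one-hot encoded 200-nt sequence to a probability of
G-quadruplex formation. Architecture: four blocks of
[conv1d (kernel 8, ReLU) -> batch normalization -> max-pool(2) ->
dropout(0.3)] with 16, 8, 4 and 3 filters respectively, then flatten ->
dense(32, ReLU) -> a single sigmoid unit. Training uses Adam
(lr 0.001, beta1 0.9, beta2 0.99) on binary cross-entropy for 15 epochs at
batch size 32.

The network is implemented directly on numpy (forward, backprop and the
optimizer): the model is small enough that a framework buys nothing, and a
pure-numpy stack gives exact control over seeding and keeps inference
dependency-free.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset_builder import LabeledSequence, standardize_length

__all__ = [
    "NetworkConfig",
    "G4Network",
    "one_hot_encode",
    "one_hot_decode",
    "encode_batch",
    "build_model",
    "train",
    "predict",
    "classify",
    "save_model",
    "load_model",
    "NAMED_THRESHOLDS",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_BN_EPS = 1e-3
_BN_MOMENTUM = 0.9  # running = m*running + (1-m)*batch
_ADAM_EPS = 1e-7

NAMED_THRESHOLDS = {"sensitive": 0.5, "precise": 0.85}


@dataclass
class NetworkConfig:
    """Architecture and optimizer hyperparameters with the published defaults."""

    conv_filters: tuple[int, ...] = (16, 8, 4, 3)
    kernel_size: int = 8
    dropout_rate: float = 0.3
    pool_size: int = 2
    dense_units: int = 32
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.99
    epochs: int = 15
    batch_size: int = 32
    input_length: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.conv_filters = tuple(int(f) for f in self.conv_filters)
        if not self.conv_filters:
            raise ValueError("conv_filters must be nonempty")
        positive = {
            "kernel_size": self.kernel_size,
            "pool_size": self.pool_size,
            "dense_units": self.dense_units,
            "learning_rate": self.learning_rate,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "input_length": self.input_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("all conv_filters must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        minimum = self.pool_size ** len(self.conv_filters)
        if self.input_length // minimum < 1:
            raise ValueError(
                f"input_length {self.input_length} too short for "
                f"{len(self.conv_filters)} pooling stages of size "
                f"{self.pool_size}; minimum admissible length is {minimum}"
            )


def one_hot_encode(seq: str, input_length: int) -> np.ndarray:
    """Encode a sequence as an (L, 4) matrix, columns A,C,G,T; N rows are zero."""
    if len(seq) != input_length:
        raise ValueError(
            f"sequence length {len(seq)} != expected input_length {input_length}"
        )
    mat = np.zeros((input_length, 4), dtype=np.float32)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"invalid character {base!r} at position {i}") from None
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    out = []
    for row in np.asarray(mat):
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(_BASES[int(np.argmax(row))])
    return "".join(out)


def encode_batch(seqs: Sequence[str], input_length: int) -> np.ndarray:
    """Stack one-hot encodings into a (B, L, 4) array."""
    batch = np.zeros((len(seqs), input_length, 4), dtype=np.float32)
    for j, seq in enumerate(seqs):
        batch[j] = one_hot_encode(seq, input_length)
    return batch


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class G4Network:
    """The convolutional G4 classifier (weights + architecture + history)."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
        )
        k = config.kernel_size
        self.params: dict[str, np.ndarray] = {}
        self.bn_stats: dict[str, np.ndarray] = {}
        c_in = 4
        for i, c_out in enumerate(config.conv_filters):
            self.params[f"conv{i}_W"] = _glorot(
                rng, (k * c_in, c_out), k * c_in, k * c_out
            )
            self.params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            self.params[f"bn{i}_gamma"] = np.ones(c_out, dtype=np.float32)
            self.params[f"bn{i}_beta"] = np.zeros(c_out, dtype=np.float32)
            self.bn_stats[f"bn{i}_mean"] = np.zeros(c_out, dtype=np.float32)
            self.bn_stats[f"bn{i}_var"] = np.ones(c_out, dtype=np.float32)
            c_in = c_out
        length = config.input_length
        for _ in config.conv_filters:
            length //= config.pool_size
        self._flat_dim = length * config.conv_filters[-1]
        self.params["dense_W"] = _glorot(
            rng, (self._flat_dim, config.dense_units),
            self._flat_dim, config.dense_units,
        )
        self.params["dense_b"] = np.zeros(config.dense_units, dtype=np.float32)
        self.params["out_W"] = _glorot(
            rng, (config.dense_units, 1), config.dense_units, 1
        )
        self.params["out_b"] = np.zeros(1, dtype=np.float32)

    # ---------------------------------------------------------------- layers
    def layer_summary(self) -> list[dict]:
        """Introspectable layer stack (kind + key sizes), in forward order."""
        cfg = self.config
        layers: list[dict] = []
        for i, f in enumerate(cfg.conv_filters):
            layers.append(
                {"kind": "conv1d", "filters": f, "kernel_size": cfg.kernel_size,
                 "activation": "relu"}
            )
            layers.append({"kind": "batch_norm", "channels": f})
            layers.append({"kind": "max_pool", "pool_size": cfg.pool_size})
            layers.append({"kind": "dropout", "rate": cfg.dropout_rate})
        layers.append({"kind": "flatten", "units": self._flat_dim})
        layers.append(
            {"kind": "dense", "units": cfg.dense_units, "activation": "relu"}
        )
        layers.append({"kind": "dense", "units": 1, "activation": "sigmoid"})
        return layers

    def _conv_cols(self, x: np.ndarray) -> np.ndarray:
        """im2col for same-padded 1-D convolution: (B,L,C) -> (B,L,K*C)."""
        k = self.config.kernel_size
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        cols = sliding_window_view(xp, k, axis=1)  # (B, L, C, K)
        cols = cols.transpose(0, 1, 3, 2)  # (B, L, K, C)
        b, l = x.shape[0], x.shape[1]
        return np.ascontiguousarray(cols).reshape(b, l, -1)

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list[dict]]:
        """Run the network; returns (probabilities, per-layer cache)."""
        cfg = self.config
        caches: list[dict] = []
        x = np.asarray(x, dtype=np.float32)
        for i in range(len(cfg.conv_filters)):
            cache: dict = {"x_shape": x.shape}
            cols = self._conv_cols(x)
            z = cols @ self.params[f"conv{i}_W"] + self.params[f"conv{i}_b"]
            a = _relu(z)
            gamma = self.params[f"bn{i}_gamma"]
            beta = self.params[f"bn{i}_beta"]
            if training:
                mu = a.mean(axis=(0, 1))
                var = a.var(axis=(0, 1))
                self.bn_stats[f"bn{i}_mean"] = (
                    _BN_MOMENTUM * self.bn_stats[f"bn{i}_mean"]
                    + (1 - _BN_MOMENTUM) * mu
                ).astype(np.float32)
                self.bn_stats[f"bn{i}_var"] = (
                    _BN_MOMENTUM * self.bn_stats[f"bn{i}_var"]
                    + (1 - _BN_MOMENTUM) * var
                ).astype(np.float32)
            else:
                mu = self.bn_stats[f"bn{i}_mean"]
                var = self.bn_stats[f"bn{i}_var"]
            invstd = 1.0 / np.sqrt(var + _BN_EPS)
            xhat = (a - mu) * invstd
            bn = gamma * xhat + beta
            p = cfg.pool_size
            lp = bn.shape[1] // p
            tiles = bn[:, : lp * p].reshape(bn.shape[0], lp, p, bn.shape[2])
            pooled = tiles.max(axis=2)
            argmax = tiles.argmax(axis=2)
            if training and cfg.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training forward pass requires an rng")
                mask = (rng.random(pooled.shape) >= cfg.dropout_rate).astype(
                    np.float32
                ) / (1.0 - cfg.dropout_rate)
                out = pooled * mask
            else:
                mask = None
                out = pooled
            cache.update(
                cols=cols, z=z, xhat=xhat, invstd=invstd, gamma=gamma,
                argmax=argmax, pre_pool_len=bn.shape[1], mask=mask,
            )
            caches.append(cache)
            x = out
        b = x.shape[0]
        h = x.reshape(b, -1)
        dpre = h @ self.params["dense_W"] + self.params["dense_b"]
        d = _relu(dpre)
        logit = (d @ self.params["out_W"] + self.params["out_b"]).reshape(-1)
        caches.append({"h": h, "dpre": dpre, "d": d, "logit": logit,
                       "conv_out_shape": x.shape})
        return _sigmoid(logit), caches

    def _backward(
        self, probs: np.ndarray, y: np.ndarray, caches: list[dict]
    ) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        head = caches[-1]
        b = y.shape[0]
        dlogit = ((probs - y) / b).astype(np.float32)  # d(BCE)/d(logit)
        d = head["d"]
        grads["out_W"] = d.T @ dlogit[:, None]
        grads["out_b"] = np.array([dlogit.sum()], dtype=np.float32)
        dd = dlogit[:, None] @ self.params["out_W"].T
        dpre = dd * (head["dpre"] > 0)
        grads["dense_W"] = head["h"].T @ dpre
        grads["dense_b"] = dpre.sum(axis=0)
        dh = dpre @ self.params["dense_W"].T
        dx = dh.reshape(head["conv_out_shape"])
        for i in reversed(range(len(cfg.conv_filters))):
            cache = caches[i]
            if cache["mask"] is not None:
                dx = dx * cache["mask"]
            # max-pool backward: route gradient to the argmax of each tile
            p = cfg.pool_size
            bsz, lp, ch = dx.shape
            dtiles = np.zeros((bsz, lp, p, ch), dtype=np.float32)
            np.put_along_axis(dtiles, cache["argmax"][:, :, None, :], dx[:, :, None, :], axis=2)
            dbn = np.zeros((bsz, cache["pre_pool_len"], ch), dtype=np.float32)
            dbn[:, : lp * p] = dtiles.reshape(bsz, lp * p, ch)
            # batch-norm backward (batch statistics)
            xhat, invstd, gamma = cache["xhat"], cache["invstd"], cache["gamma"]
            n = bsz * cache["pre_pool_len"]
            grads[f"bn{i}_gamma"] = (dbn * xhat).sum(axis=(0, 1))
            grads[f"bn{i}_beta"] = dbn.sum(axis=(0, 1))
            dxhat = dbn * gamma
            da = (invstd / n) * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
            dz = (da * (cache["z"] > 0)).astype(np.float32)
            cols = cache["cols"]
            kc = cols.shape[2]
            f = dz.shape[2]
            grads[f"conv{i}_W"] = (
                cols.reshape(-1, kc).T @ dz.reshape(-1, f)
            )
            grads[f"conv{i}_b"] = dz.sum(axis=(0, 1))
            dcols = (dz @ self.params[f"conv{i}_W"].T).reshape(
                bsz, -1, cfg.kernel_size, cache["x_shape"][2]
            )
            k = cfg.kernel_size
            pl = (k - 1) // 2
            l_in = cache["x_shape"][1]
            dxp = np.zeros((bsz, l_in + k - 1, cache["x_shape"][2]), dtype=np.float32)
            for j in range(k):
                dxp[:, j : j + l_in] += dcols[:, :, j, :]
            dx = dxp[:, pl : pl + l_in]
        return grads

    # -------------------------------------------------------------- training
    def fit(
        self,
        train_set: Sequence[LabeledSequence],
        eval_set: Sequence[LabeledSequence] | None = None,
    ) -> "G4Network":
        """Train in place per the config; records per-epoch losses."""
        cfg = self.config
        if not train_set:
            raise ValueError("training set is empty")
        labels = np.array([s.label for s in train_set], dtype=np.float32)
        if labels.min() == labels.max():
            raise ValueError("training set must contain both classes")
        x = encode_batch([s.sequence for s in train_set], cfg.input_length)
        x_eval = y_eval = None
        if eval_set:
            x_eval = encode_batch([s.sequence for s in eval_set], cfg.input_length)
            y_eval = np.array([s.label for s in eval_set], dtype=np.float32)

        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
        )
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        t = 0
        n = len(train_set)
        for _ in range(cfg.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                xb, yb = x[idx], labels[idx]
                probs, caches = self.forward(xb, training=True, rng=rng)
                logit = caches[-1]["logit"]
                loss = float(
                    np.mean(
                        np.maximum(logit, 0) - logit * yb + np.log1p(np.exp(-np.abs(logit)))
                    )
                )
                epoch_loss += loss * len(idx)
                grads = self._backward(probs, yb, caches)
                t += 1
                bc1 = 1.0 - cfg.beta1**t
                bc2 = 1.0 - cfg.beta2**t
                for key, g in grads.items():
                    g = g.astype(np.float32).reshape(self.params[key].shape)
                    adam_m[key] = cfg.beta1 * adam_m[key] + (1 - cfg.beta1) * g
                    adam_v[key] = cfg.beta2 * adam_v[key] + (1 - cfg.beta2) * g * g
                    self.params[key] -= (
                        cfg.learning_rate
                        * (adam_m[key] / bc1)
                        / (np.sqrt(adam_v[key] / bc2) + _ADAM_EPS)
                    ).astype(np.float32)
            self.history["loss"].append(epoch_loss / n)
            if x_eval is not None:
                self.history["val_loss"].append(
                    float(self._loss_inference(x_eval, y_eval))
                )
        return self

    def _loss_inference(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = []
        for start in range(0, len(x), 4096):
            _, logit_chunk, _ = self._forward_infer(x[start : start + 4096])
            logits.append(logit_chunk)
        logit = np.concatenate(logits)
        return float(
            np.mean(np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit))))
        )

    # ------------------------------------------------------------- inference
    def _bn_affine(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Batch-norm at inference folded to one per-channel affine map."""
        gamma = self.params[f"bn{i}_gamma"]
        beta = self.params[f"bn{i}_beta"]
        invstd = 1.0 / np.sqrt(self.bn_stats[f"bn{i}_var"] + _BN_EPS)
        scale = gamma * invstd
        shift = beta - self.bn_stats[f"bn{i}_mean"] * scale
        return scale.astype(np.float32), shift.astype(np.float32)

    def _forward_infer(
        self, x: np.ndarray, keep: bool = False
    ) -> tuple[np.ndarray, np.ndarray, dict | None]:
        """Inference-only forward: no dropout, running BN stats, no caches
        for backprop. Returns (probs, logits, occlusion cache or None)."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        cache: dict | None = (
            {"inputs": [], "prepool": [], "h": None, "pre": None} if keep else None
        )
        for i in range(len(cfg.conv_filters)):
            if keep:
                cache["inputs"].append(x)
            cols = self._conv_cols(x)
            z = cols @ self.params[f"conv{i}_W"]
            z += self.params[f"conv{i}_b"]
            np.maximum(z, 0.0, out=z)
            scale, shift = self._bn_affine(i)
            z *= scale
            z += shift
            if keep:
                cache["prepool"].append(z)
            p = cfg.pool_size
            lp = z.shape[1] // p
            if p == 2:
                x = np.maximum(z[:, 0 : 2 * lp : 2], z[:, 1 : 2 * lp : 2])
            else:
                x = z[:, : lp * p].reshape(z.shape[0], lp, p, z.shape[2]).max(axis=2)
        h = x.reshape(x.shape[0], -1)
        pre = h @ self.params["dense_W"] + self.params["dense_b"]
        d = _relu(pre)
        logit = (d @ self.params["out_W"] + self.params["out_b"]).reshape(-1)
        if keep:
            cache["h"] = h
            cache["pre"] = pre
        return _sigmoid(logit), logit, cache

    def predict_encoded(self, x: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Score already one-hot-encoded inputs (B, L, 4) -> (B,) in [0,1]."""
        out = []
        for start in range(0, len(x), chunk):
            probs, _, _ = self._forward_infer(x[start : start + chunk])
            out.append(probs)
        if not out:
            return np.zeros(0, dtype=np.float32)
        return np.concatenate(out)

    # --------------------------------------------- fast window randomization
    def occlusion_cache(self, x: np.ndarray) -> dict:
        """Precompute per-layer activations of one encoded sequence (L, 4).

        Used by :func:`score_window_variants` to rescore sequences that
        differ from the base only inside a window, touching only the
        receptive-field strip of each layer.
        """
        probs, _, cache = self._forward_infer(x[None], keep=True)
        cache["prob"] = float(probs[0])
        return cache

    def score_window_variants(
        self, cache: dict, start: int, fills: np.ndarray
    ) -> np.ndarray:
        """Scores of the cached sequence with [start, start+w) replaced.

        ``fills`` is (n, w, 4) one-hot replacement content. Exactly
        equivalent to encoding the full variants and calling
        :meth:`predict_encoded`, but recomputes only the strip of each
        layer whose receptive field touches the window.
        """
        cfg = self.config
        k = cfg.kernel_size
        pl = (k - 1) // 2
        pr = k - 1 - pl
        p = cfg.pool_size
        n, w = fills.shape[0], fills.shape[1]
        a, b = start, start + w
        var = np.asarray(fills, dtype=np.float32)
        for i in range(len(cfg.conv_filters)):
            x_base = cache["inputs"][i][0]  # (L, C)
            length = x_base.shape[0]
            lo = max(a - pr, 0)
            hi = min(b + pl, length)
            if lo >= hi:
                return np.full(n, cache["prob"], dtype=np.float32)
            s0, s1 = lo - pl, hi + pr
            strip = np.zeros((n, s1 - s0, x_base.shape[1]), dtype=np.float32)
            src_lo, src_hi = max(s0, 0), min(s1, length)
            strip[:, src_lo - s0 : src_hi - s0] = x_base[src_lo:src_hi]
            strip[:, a - s0 : b - s0] = var
            cols = sliding_window_view(strip, k, axis=1).transpose(0, 1, 3, 2)
            cols = np.ascontiguousarray(cols).reshape(n, hi - lo, -1)
            z = cols @ self.params[f"conv{i}_W"]
            z += self.params[f"conv{i}_b"]
            np.maximum(z, 0.0, out=z)
            scale, shift = self._bn_affine(i)
            z *= scale
            z += shift
            # pool the affected region, borrowing unaffected columns from base
            lp = length // p
            plo = lo // p
            phi = min(-(-hi // p), lp)
            if plo >= phi:
                return np.full(n, cache["prob"], dtype=np.float32)
            ext_lo, ext_hi = plo * p, phi * p
            zfull = np.empty((n, ext_hi - ext_lo, z.shape[2]), dtype=np.float32)
            base_prepool = cache["prepool"][i][0]
            if ext_lo < lo:
                zfull[:, : lo - ext_lo] = base_prepool[ext_lo:lo]
            z_hi = min(hi, ext_hi)
            zfull[:, lo - ext_lo : z_hi - ext_lo] = z[:, : z_hi - lo]
            if z_hi < ext_hi:
                zfull[:, z_hi - ext_lo :] = base_prepool[z_hi:ext_hi]
            var = zfull.reshape(n, phi - plo, p, z.shape[2]).max(axis=2)
            a, b = plo, phi
        c_last = var.shape[2]
        rows = slice(a * c_last, b * c_last)
        delta = var.reshape(n, -1) - cache["h"][0, rows]
        pre = cache["pre"][0] + delta @ self.params["dense_W"][rows]
        d = _relu(pre)
        logit = (d @ self.params["out_W"] + self.params["out_b"]).reshape(-1)
        return _sigmoid(logit)

    def predict(
        self, seqs: Sequence[str], pad_seed: int = 0
    ) -> np.ndarray:
        """Score raw sequences; non-200-nt inputs are standardized first.

        Longer sequences are center-cropped, shorter ones random-N-padded
        using ``pad_seed`` (scores are deterministic given weights and
        pad_seed).
        """
        if len(seqs) == 0:
            return np.zeros(0, dtype=np.float32)
        pad_rng = np.random.default_rng(pad_seed)
        std = [
            standardize_length(s, self.config.input_length, pad_rng) for s in seqs
        ]
        return self.predict_encoded(encode_batch(std, self.config.input_length))


def build_model(config: NetworkConfig | None = None) -> G4Network:
    """Construct an untrained network from a config (defaults as published)."""
    return G4Network(config or NetworkConfig())


def train(
    model: G4Network,
    train_set: Sequence[LabeledSequence],
    eval_set: Sequence[LabeledSequence] | None = None,
    config: NetworkConfig | None = None,
) -> G4Network:
    """Train ``model`` on a labeled dataset; returns the fitted model."""
    if config is not None:
        model.config = config
    return model.fit(train_set, eval_set)


def predict(model: G4Network, seqs: Sequence[str], pad_seed: int = 0) -> np.ndarray:
    return model.predict(seqs, pad_seed=pad_seed)


def classify(
    score: float, mode: str = "sensitive", custom_threshold: float | None = None
) -> bool:
    """Binarize a score at a named or custom threshold (>= is positive).

    ``sensitive`` uses 0.5, ``precise`` 0.85; ``custom`` requires
    ``custom_threshold``.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0,1], got {score}")
    if mode == "custom":
        if custom_threshold is None:
            raise ValueError("custom mode requires custom_threshold")
        threshold = custom_threshold
    else:
        try:
            threshold = NAMED_THRESHOLDS[mode]
        except KeyError:
            raise ValueError(
                f"mode must be one of {sorted(NAMED_THRESHOLDS)} or 'custom'"
            ) from None
    return bool(score >= threshold)


def save_model(model: G4Network, path: str | Path) -> None:
    """Serialize config, weights, batch-norm stats and history to one file."""
    payload = {
        "__meta__": np.frombuffer(
            json.dumps(
                {"config": asdict(model.config), "history": model.history}
            ).encode(),
            dtype=np.uint8,
        )
    }
    payload.update(model.params)
    payload.update(model.bn_stats)
    with open(path, "wb") as handle:
        np.savez(handle, **payload)


def load_model(path: str | Path) -> G4Network:
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            cfg_dict["conv_filters"] = tuple(cfg_dict["conv_filters"])
            model = G4Network(NetworkConfig(**cfg_dict))
            for key in model.params:
                model.params[key] = data[key].astype(np.float32)
            for key in model.bn_stats:
                model.bn_stats[key] = data[key].astype(np.float32)
            model.history = meta["history"]
    except (zipfile.BadZipFile, KeyError, OSError, ValueError, EOFError) as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    return model
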