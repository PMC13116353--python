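"""The staged loop predictor: methylation trees, CNN sequence extractor, fusion.

Training runs in three stages. Stage 1 fits a gradient-boosted tree classifier
on the 21 methylation inputs (two 10-bin CpG count vectors + their Pearson r);
its predicted probability is appended to its inputs to form the 22-D
methylation block. Stage 2 trains a small 1-D convolutional feature extractor
(two conv/maxpool/dropout blocks, a third conv, a learnable per-channel
position-weighted sum, and a tanh) under a temporary logistic head on the four
anchor sequences; the head is then discarded and the extractor frozen, each
sequence mapping to a 128-vector (mean over its overlapping windows). Stage 3
fits a second gradient-boosted ensemble on the fused 535-vector
(22 methylation + 4x128 sequence + distance) and emits the loop probability.

The extractor is implemented directly in numpy (forward and backward passes,
Adam updates); at the ~5 kb-anchor scale it trains comfortably on one CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .core_io import GenomicInterval, LoopPair, MethylationIndex
from .features import (
    DEFAULT_L_ANCHOR,
    DEFAULT_STEP,
    DEFAULT_TAU,
    DEFAULT_WINDOW,
    FEATURE_DIM,
    SEQ_BLOCK_DIM,
    SEQ_EMBED_DIM,
    build_sequence_sets,
    feature_names,
    one_hot,
    split_windows,
    stage1_feature_matrix,
)

log = logging.getLogger("nanoloop")

METH_BLOCK = slice(0, 22)
SEQ_BLOCK = slice(22, 22 + SEQ_BLOCK_DIM)
DISTANCE_COL = 22 + SEQ_BLOCK_DIM  # 534


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class SequenceExtractorConfig:
    """Hyperparameters of the convolutional sequence feature extractor."""

    filters1: int = 64
    kernel1: int = 11
    pool1: int = 4
    dropout1: float = 0.2
    filters2: int = 128
    kernel2: int = 7
    pool2: int = 4
    dropout2: float = 0.2
    filters3: int = 128
    kernel3: int = 3
    dropout3: float = 0.2
    output_dim: int = 128
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.output_dim != SEQ_EMBED_DIM:
            raise ValueError(f"output_dim must be {SEQ_EMBED_DIM}")
        if self.filters3 != self.output_dim:
            raise ValueError(
                "filters3 must equal output_dim (the weighted sum contracts "
                "positions per channel)"
            )
        for rate in (self.dropout1, self.dropout2, self.dropout3):
            if not 0.0 <= rate < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")

    @property
    def conv_lengths(self) -> tuple[int, int, int]:
        """Feature-map lengths after each block for the configured window."""
        l1 = (self.window - self.kernel1 + 1) // self.pool1
        l2 = (l1 - self.kernel2 + 1) // self.pool2
        l3 = l2 - self.kernel3 + 1
        if l3 < 1:
            raise ValueError("window too short for the configured kernels/pools")
        return l1, l2, l3


@dataclass(frozen=True)
class TreeParams:
    """Gradient-boosted tree settings shared by stages 1 and 3."""

    n_estimators: int = 500
    learning_rate: float = 0.1
    max_depth: int = 6
    early_stopping_rounds: int = 20


@dataclass(frozen=True)
class TrainParams:
    """Stage-2 optimizer settings (Adam + early stopping on validation loss)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5


@dataclass(frozen=True)
class NanoLoopConfig:
    l_anchor: int = DEFAULT_L_ANCHOR
    tau: float = DEFAULT_TAU
    extractor: SequenceExtractorConfig = field(
        default_factory=SequenceExtractorConfig
    )
    trees: TreeParams = field(default_factory=TreeParams)
    training: TrainParams = field(default_factory=TrainParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if (self.l_anchor - self.extractor.window) % self.extractor.step != 0:
            raise ValueError(
                "(l_anchor - window) must be divisible by step so windows tile"
            )


# ---------------------------------------------------------------------------
# numpy CNN primitives


def _conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid cross-correlation. x (B,Cin,L), w (Cout,Cin,k) -> (B,Cout,Lout)."""
    k = w.shape[2]
    cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # B,Cin,Lout,k
    y = np.einsum("bilk,oik->bol", cols, w, optimize=True) + b[None, :, None]
    return y, cols


def _conv1d_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, x_shape):
    dw = np.einsum("bol,bilk->oik", dy, cols, optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.zeros(x_shape, dtype=dy.dtype)
    l_out = dy.shape[2]
    for kk in range(w.shape[2]):
        dx[:, :, kk : kk + l_out] += np.einsum(
            "bol,oi->bil", dy, w[:, :, kk], optimize=True
        )
    return dx, dw, db


def _maxpool_forward(x: np.ndarray, p: int):
    b, c, length = x.shape
    lp = length // p
    xt = x[:, :, : lp * p].reshape(b, c, lp, p)
    idx = xt.argmax(axis=3)
    y = np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]
    return y, (idx, x.shape, p)


def _maxpool_backward(dy: np.ndarray, cache):
    idx, x_shape, p = cache
    b, c, length = x_shape
    lp = length // p
    dxt = np.zeros((b, c, lp, p), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[..., None], dy[..., None], axis=3)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, :, : lp * p] = dxt.reshape(b, c, lp * p)
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            mhat = self.m[key] / (1 - self.beta1**self.t)
            vhat = self.v[key] / (1 - self.beta2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SequenceExtractor:
    """Convolutional window encoder with a learned position-weighted sum.

    Each 4 x W one-hot window passes through conv/ReLU/maxpool/dropout twice,
    a third conv/ReLU/dropout, then a learnable (channel x position) weight
    matrix contracts the position axis per channel and tanh bounds the result,
    giving a 128-vector per window; a sequence embedding is the mean over its
    windows. After ``freeze()`` the weights are immutable.
    """

    def __init__(self, config: SequenceExtractorConfig, seed: int = 0):
        self.config = config
        self.frozen = False
        rng = np.random.default_rng(seed)
        c = config
        _, _, l3 = c.conv_lengths

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )

        self.params: dict[str, np.ndarray] = {
            "w1": he((c.filters1, 4, c.kernel1), 4 * c.kernel1),
            "b1": np.zeros(c.filters1, dtype=np.float32),
            "w2": he((c.filters2, c.filters1, c.kernel2), c.filters1 * c.kernel2),
            "b2": np.zeros(c.filters2, dtype=np.float32),
            "w3": he((c.filters3, c.filters2, c.kernel3), c.filters2 * c.kernel3),
            "b3": np.zeros(c.filters3, dtype=np.float32),
            "wsum": (rng.standard_normal((c.filters3, l3)) / np.sqrt(l3)).astype(
                np.float32
            ),
        }

    # -- forward / backward over a flat batch of windows (B, 4, W)

    def forward(self, x: np.ndarray, train: bool = False, rng=None):
        c = self.config
        p = self.params
        cache: dict = {"x_shape": x.shape}

        z1, cols1 = _conv1d_forward(x, p["w1"], p["b1"])
        r1 = np.maximum(z1, 0.0)
        m1, mp1 = _maxpool_forward(r1, c.pool1)
        a1, mask1 = self._dropout(m1, c.dropout1, train, rng)

        z2, cols2 = _conv1d_forward(a1, p["w2"], p["b2"])
        r2 = np.maximum(z2, 0.0)
        m2, mp2 = _maxpool_forward(r2, c.pool2)
        a2, mask2 = self._dropout(m2, c.dropout2, train, rng)

        z3, cols3 = _conv1d_forward(a2, p["w3"], p["b3"])
        r3 = np.maximum(z3, 0.0)
        a3, mask3 = self._dropout(r3, c.dropout3, train, rng)

        s = np.einsum("bcl,cl->bc", a3, p["wsum"], optimize=True)
        out = np.tanh(s)

        cache.update(
            cols1=cols1, z1=z1, mp1=mp1, mask1=mask1, a1_shape=a1.shape,
            cols2=cols2, z2=z2, mp2=mp2, mask2=mask2, a2_shape=a2.shape,
            cols3=cols3, z3=z3, mask3=mask3, a3=a3, out=out,
        )
        return out, cache

    @staticmethod
    def _dropout(x, rate, train, rng):
        if not train or rate == 0.0:
            return x, None
        mask = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
        return x * mask, mask

    def backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        ds = dout * (1.0 - cache["out"] ** 2)
        dwsum = np.einsum("bc,bcl->cl", ds, cache["a3"], optimize=True)
        da3 = ds[:, :, None] * p["wsum"][None, :, :]

        if cache["mask3"] is not None:
            da3 = da3 * cache["mask3"]
        dz3 = da3 * (cache["z3"] > 0)
        da2, dw3, db3 = _conv1d_backward(dz3, cache["cols3"], p["w3"], cache["a2_shape"])

        if cache["mask2"] is not None:
            da2 = da2 * cache["mask2"]
        dm2 = _maxpool_backward(da2, cache["mp2"])
        dz2 = dm2 * (cache["z2"] > 0)
        da1, dw2, db2 = _conv1d_backward(dz2, cache["cols2"], p["w2"], cache["a1_shape"])

        if cache["mask1"] is not None:
            da1 = da1 * cache["mask1"]
        dm1 = _maxpool_backward(da1, cache["mp1"])
        dz1 = dm1 * (cache["z1"] > 0)
        _, dw1, db1 = _conv1d_backward(dz1, cache["cols1"], p["w1"], cache["x_shape"])

        return {
            "w1": dw1, "b1": db1, "w2": dw2, "b2": db2,
            "w3": dw3, "b3": db3, "wsum": dwsum,
        }

    def embed_windows(self, windows: np.ndarray) -> np.ndarray:
        """Deterministic (eval-mode) embedding of a flat window batch."""
        out, _ = self.forward(windows.astype(np.float32), train=False)
        return out

    def freeze(self) -> None:
        self.frozen = True
        for arr in self.params.values():
            arr.setflags(write=False)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.params):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.params[key]).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Window tensors


def build_window_tensor(
    loops: list[LoopPair],
    genome: dict[str, str],
    l_anchor: int,
    window: int,
    step: int,
) -> np.ndarray:
    """One-hot windows for every loop: (n_loops, 4 sequences, n_windows, 4, W)."""
    n_windows = (l_anchor - window) // step + 1
    out = np.empty((len(loops), 4, n_windows, 4, window), dtype=np.float32)
    for i, lp in enumerate(loops):
        seqs = build_sequence_sets(lp, genome, l_anchor)
        for j, seq in enumerate(seqs.as_tuple()):
            out[i, j] = split_windows(one_hot(seq), window, step)
    return out


def embed_sequences(
    extractor: SequenceExtractor, windows: np.ndarray
) -> np.ndarray:
    """(n, 4, nw, 4, W) window tensor -> (n, 512) sequence block."""
    n, nseq, nw, four, w = windows.shape
    flat = windows.reshape(n * nseq * nw, four, w)
    emb = extractor.embed_windows(flat)
    per_seq = emb.reshape(n, nseq, nw, SEQ_EMBED_DIM).mean(axis=2)
    return per_seq.reshape(n, SEQ_BLOCK_DIM).astype(float)


# ---------------------------------------------------------------------------
# Tree stages


def _make_tree_classifier(params: TreeParams, seed: int, with_val: bool):
    kwargs = dict(
        n_estimators=params.n_estimators,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        objective="binary:logistic",
        tree_method="hist",
        random_state=seed,
        n_jobs=1,
        # logloss (not a rank metric) so early stopping preserves probability
        # calibration, which the perturbation analysis thresholds rely on
        eval_metric="logloss",
    )
    if with_val:
        kwargs["early_stopping_rounds"] = params.early_stopping_rounds
    return XGBClassifier(**kwargs)


def train_stage1_methylation(
    features: np.ndarray,
    labels: np.ndarray,
    params: TreeParams = TreeParams(),
    seed: int = 0,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> XGBClassifier:
    """Fit the methylation-module tree ensemble on the 21 stage-1 inputs."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != 21:
        raise ValueError(f"stage 1 expects 21 features, got {features.shape[1]}")
    if len(np.unique(labels)) < 2:
        raise ValueError("stage 1 needs both classes present")
    clf = _make_tree_classifier(params, seed, with_val=val is not None)
    eval_set = [val] if val is not None else None
    clf.fit(features, labels, eval_set=eval_set, verbose=False)
    return clf


def train_stage3_fusion(
    features: pd.DataFrame,
    labels: np.ndarray,
    params: TreeParams = TreeParams(),
    seed: int = 0,
    val: tuple[pd.DataFrame, np.ndarray] | None = None,
    expected_dim: int = FEATURE_DIM,
) -> XGBClassifier:
    """Fit the fusion ensemble on the named 535-column feature frame."""
    if features.shape[1] != expected_dim:
        raise ValueError(
            f"fusion stage expects {expected_dim} features, got {features.shape[1]}"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError("fusion stage needs both classes present")
    clf = _make_tree_classifier(params, seed, with_val=val is not None)
    eval_set = [val] if val is not None else None
    clf.fit(features, labels, eval_set=eval_set, verbose=False)
    return clf


# ---------------------------------------------------------------------------
# Stage 2 training


def train_stage2_extractor(
    windows_train: np.ndarray,
    labels_train: np.ndarray,
    windows_val: np.ndarray,
    labels_val: np.ndarray,
    config: SequenceExtractorConfig = SequenceExtractorConfig(),
    training: TrainParams = TrainParams(),
    seed: int = 0,
) -> tuple[SequenceExtractor, dict]:
    """Train the extractor under a temporary logistic head, then freeze it.

    The head (512 -> 1) exists only to drive backpropagation; it is discarded.
    Early stopping watches validation cross-entropy with the configured
    patience; the best-epoch weights are restored before freezing.
    """
    if windows_val.shape[0] == 0:
        raise ValueError("stage 2 early stopping requires validation data")
    extractor = SequenceExtractor(config, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n, nseq, nw, _, w = windows_train.shape
    y = np.asarray(labels_train, dtype=np.float32)

    head = {
        "w": (rng.standard_normal(SEQ_BLOCK_DIM) / np.sqrt(SEQ_BLOCK_DIM)).astype(
            np.float32
        ),
        "b": np.zeros(1, dtype=np.float32),
    }
    opt = _Adam({**extractor.params, **head}, training.learning_rate)

    def val_loss() -> float:
        emb = embed_sequences(extractor, windows_val).astype(np.float32)
        z = emb @ head["w"] + head["b"][0]
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-7
        yv = np.asarray(labels_val, dtype=np.float32)
        return float(
            -np.mean(yv * np.log(p + eps) + (1 - yv) * np.log(1 - p + eps))
        )

    best = {"loss": np.inf, "params": None, "head": None, "epoch": -1}
    history = []
    bad_epochs = 0
    for epoch in range(training.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, training.batch_size):
            idx = order[start : start + training.batch_size]
            xb = windows_train[idx].reshape(len(idx) * nseq * nw, 4, w)
            yb = y[idx]
            out, cache = extractor.forward(xb, train=True, rng=rng)
            seq_emb = out.reshape(len(idx), nseq, nw, SEQ_EMBED_DIM).mean(axis=2)
            flat = seq_emb.reshape(len(idx), SEQ_BLOCK_DIM)
            z = flat @ head["w"] + head["b"][0]
            p = 1.0 / (1.0 + np.exp(-z))
            dz = (p - yb) / len(idx)
            dhw = flat.T @ dz
            dhb = np.array([dz.sum()], dtype=np.float32)
            dflat = np.outer(dz, head["w"]).astype(np.float32)
            dseq = dflat.reshape(len(idx), nseq, SEQ_EMBED_DIM)
            dwin = np.repeat(dseq[:, :, None, :] / nw, nw, axis=2)
            dout = dwin.reshape(len(idx) * nseq * nw, SEQ_EMBED_DIM)
            grads = extractor.backward(dout, cache)
            grads["w"] = dhw
            grads["b"] = dhb
            merged = {**extractor.params, **head}
            opt.step(merged, grads)
            for key in extractor.params:
                extractor.params[key] = merged[key]
            head["w"], head["b"] = merged["w"], merged["b"]

        loss = val_loss()
        history.append(loss)
        if loss < best["loss"] - 1e-6:
            best = {
                "loss": loss,
                "params": {k: v.copy() for k, v in extractor.params.items()},
                "head": {k: v.copy() for k, v in head.items()},
                "epoch": epoch,
            }
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= training.patience:
                break

    if best["params"] is not None:
        extractor.params = best["params"]
        head = best["head"]
    extractor.freeze()
    meta = {
        "val_loss_history": history,
        "best_epoch": best["epoch"],
        "best_val_loss": best["loss"],
        "head_weights": {k: v.tolist() for k, v in head.items()},
    }
    return extractor, meta


# ---------------------------------------------------------------------------
# Bundle, end-to-end training, prediction


class _BoosterScorer:
    """A reloaded tree ensemble exposing the same scoring surface as the
    in-memory classifier (predict_proba + get_booster)."""

    def __init__(self, path: str | Path):
        import xgboost as xgb

        self._booster = xgb.Booster()
        self._booster.load_model(str(path))

    def get_booster(self):
        return self._booster

    def predict_proba(self, x) -> np.ndarray:
        import xgboost as xgb

        p = self._booster.predict(xgb.DMatrix(x))
        return np.column_stack([1.0 - p, p])


@dataclass(frozen=True)
class PredictionRecord:
    loop: LoopPair
    probability: float
    stage1_probability: float

    def __post_init__(self) -> None:
        for p in (self.probability, self.stage1_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass
class ModelBundle:
    stage1: XGBClassifier
    extractor: SequenceExtractor
    stage3: XGBClassifier
    config: NanoLoopConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.extractor.frozen:
            raise ValueError("stage 3 requires a frozen stage-2 extractor")

    # -- feature assembly

    def assemble(
        self,
        loops: list[LoopPair],
        genome: dict[str, str],
        meth: MethylationIndex,
    ) -> pd.DataFrame:
        """The named n x 535 fused feature frame for a list of loops."""
        cfg = self.config
        x21 = stage1_feature_matrix(loops, meth, tau=cfg.tau)
        p1 = self.stage1.predict_proba(x21)[:, 1]
        windows = build_window_tensor(
            loops, genome, cfg.l_anchor, cfg.extractor.window, cfg.extractor.step
        )
        seq = embed_sequences(self.extractor, windows)
        dist = np.array([lp.distance for lp in loops], dtype=float)
        mat = np.concatenate(
            [x21, p1[:, None], seq, dist[:, None]], axis=1
        )
        assert mat.shape[1] == FEATURE_DIM
        return pd.DataFrame(mat, columns=feature_names())

    def predict(
        self,
        loops: list[LoopPair],
        genome: dict[str, str],
        meth: MethylationIndex,
    ) -> list[PredictionRecord]:
        if not loops:
            return []
        frame = self.assemble(loops, genome, meth)
        probs = self.stage3.predict_proba(frame)[:, 1]
        return [
            PredictionRecord(lp, float(p), float(frame["meth_module_prob"].iloc[i]))
            for i, (lp, p) in enumerate(zip(loops, probs))
        ]

    def score_matrix(self, frame: pd.DataFrame) -> np.ndarray:
        """Stage-3 probabilities for a pre-assembled 535-column frame."""
        return self.stage3.predict_proba(frame)[:, 1]

    # -- persistence

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        # persist the raw boosters (the sklearn wrapper metadata is not needed
        # to score, and keeps the on-disk format plain model JSON)
        self.stage1.get_booster().save_model(out_dir / "stage1.json")
        self.stage3.get_booster().save_model(out_dir / "stage3.json")
        np.savez(out_dir / "extractor.npz", **self.extractor.params)
        with open(out_dir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        with open(out_dir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, out_dir: str | Path) -> "ModelBundle":
        out_dir = Path(out_dir)
        with open(out_dir / "config.json") as fh:
            raw = json.load(fh)
        config = NanoLoopConfig(
            l_anchor=raw["l_anchor"],
            tau=raw["tau"],
            extractor=SequenceExtractorConfig(**raw["extractor"]),
            trees=TreeParams(**raw["trees"]),
            training=TrainParams(**raw["training"]),
        )
        stage1 = _BoosterScorer(out_dir / "stage1.json")
        stage3 = _BoosterScorer(out_dir / "stage3.json")
        extractor = SequenceExtractor(config.extractor, seed=0)
        with np.load(out_dir / "extractor.npz") as npz:
            extractor.params = {k: npz[k].copy() for k in npz.files}
        extractor.freeze()
        with open(out_dir / "metadata.json") as fh:
            metadata = json.load(fh)
        return cls(stage1, extractor, stage3, config, metadata)


def train_nanoloop(
    train_loops: list[LoopPair],
    train_labels: np.ndarray,
    val_loops: list[LoopPair],
    val_labels: np.ndarray,
    genome: dict[str, str],
    meth: MethylationIndex,
    config: NanoLoopConfig = NanoLoopConfig(),
    seed: int = 0,
) -> ModelBundle:
    """Run the three training stages and return the assembled bundle."""
    cfg = config
    root = np.random.SeedSequence(seed)
    s1_seed, s2_seed, s3_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )

    x21_train = stage1_feature_matrix(train_loops, meth, tau=cfg.tau)
    x21_val = stage1_feature_matrix(val_loops, meth, tau=cfg.tau)
    stage1 = train_stage1_methylation(
        x21_train,
        train_labels,
        params=cfg.trees,
        seed=s1_seed,
        val=(x21_val, val_labels) if len(val_loops) else None,
    )

    w_train = build_window_tensor(
        train_loops, genome, cfg.l_anchor, cfg.extractor.window, cfg.extractor.step
    )
    w_val = build_window_tensor(
        val_loops, genome, cfg.l_anchor, cfg.extractor.window, cfg.extractor.step
    )
    extractor, stage2_meta = train_stage2_extractor(
        w_train,
        train_labels,
        w_val,
        val_labels,
        config=cfg.extractor,
        training=cfg.training,
        seed=s2_seed,
    )

    bundle = ModelBundle(
        stage1=stage1,
        extractor=extractor,
        stage3=_make_tree_classifier(cfg.trees, s3_seed, with_val=False),
        config=cfg,
        metadata={"seed": seed, "stage2": stage2_meta},
    )
    # stage3 placeholder above is replaced by the fitted ensemble
    frame_train = bundle.assemble(train_loops, genome, meth)
    frame_val = bundle.assemble(val_loops, genome, meth) if len(val_loops) else None
    checksum_before = extractor.checksum()
    stage3 = train_stage3_fusion(
        frame_train,
        train_labels,
        params=cfg.trees,
        seed=s3_seed,
        val=(frame_val, val_labels) if frame_val is not None else None,
    )
    assert extractor.checksum() == checksum_before, "stage 3 mutated the extractor"
    bundle.stage3 = stage3
    return bundle


# ---------------------------------------------------------------------------
# Evaluation and interpretation


def evaluate_auprc(scores, labels) -> float:
    """Area under the precision-recall curve (stepwise, ties grouped).

    Thresholds sweep the unique scores in descending order; AP is the sum of
    precision x recall-increment over threshold groups.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("auPRC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores: evaluate only at the last element of each tie block
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_group = np.r_[s[1:] != s[:-1], True]
    tp_g, fp_g = tp[last_of_group], fp[last_of_group]
    precision = tp_g / (tp_g + fp_g)
    recall = tp_g / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def feature_importance(bundle: ModelBundle) -> list[tuple[str, float]]:
    """Gain importance of the fusion ensemble's 535 named inputs, descending."""
    booster = bundle.stage3.get_booster()
    scores = booster.get_score(importance_type="gain")
    ranked = sorted(scores.items(), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in ranked]


def train_ablation_fusion(
    bundle: ModelBundle,
    frame_train: pd.DataFrame,
    labels_train: np.ndarray,
    frame_val: pd.DataFrame | None,
    labels_val: np.ndarray | None,
    blocks: tuple[str, ...] = ("sequence", "distance"),
    seed: int = 0,
) -> tuple[XGBClassifier, list[str]]:
    """Refit the fusion stage on a subset of feature blocks (for ablations)."""
    cols: list[str] = []
    names = feature_names()
    if "methylation" in blocks:
        cols += names[METH_BLOCK]
    if "sequence" in blocks:
        cols += names[SEQ_BLOCK]
    if "distance" in blocks:
        cols.append("distance")
    clf = train_stage3_fusion(
        frame_train[cols],
        labels_train,
        params=bundle.config.trees,
        seed=seed,
        val=(frame_val[cols], labels_val) if frame_val is not None else None,
        expected_dim=len(cols),
    )
    return clf, cols
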