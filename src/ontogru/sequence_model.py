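"""The dual Bi-GRU sequence labeler: a character-level bidirectional GRU
feeding a concatenated multi-channel sentence representation into a main
bidirectional GRU with a per-token sigmoid classification head.

Implemented directly on numpy: forward pass, backpropagation through time,
Adam, and reduce-on-plateau learning-rate scheduling are all in this module,
which keeps training bit-reproducible for a fixed seed.

Channel layout (enabled subsets are configurable):

* token ids -> supervised embedding (or pretrained word vectors);
* character ids -> character embedding -> Bi-GRU, whose two final states
  summarize each token's spelling;
* character-representation ids and POS ids -> small embeddings;
* BioThesaurus (4 flags) and UMLS (1 flag) channels enter the concatenation
  raw, without an embedding.

The concatenated feature sequence passes through spatial dropout (whole
feature channels dropped along the sequence), the main Bi-GRU, and a
time-distributed dense layer with sigmoid activation; softmax over the
sigmoid activations yields the probabilities used for prediction, entropy
and the loss.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ontogru.feature_encoders import EncodedSentence

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TokenPrediction",
    "SequenceLabeler",
    "build_model",
    "train",
    "predict",
    "load_word_vectors",
]

ALL_CHANNELS = ("token", "char", "repr", "pos", "biot", "umls")


@dataclass
class ModelConfig:
    """Hyperparameters of the labeler.

    Defaults follow the published setup where stated (Adam at 1e-4, batch 16,
    plateau reduction by 0.1 after 4 flat epochs, 150-unit character GRU,
    100-dimensional supervised embeddings, 10%/30%/10% dropout); the main
    GRU width mirrors the character GRU since it was left unstated.
    """

    token_embedding: str = "supervised"  # supervised | pretrained-static | pretrained-contextual
    supervised_dim: int = 100
    char_embedding_dim: int = 100
    repr_embedding_dim: int = 100
    pos_embedding_dim: int = 100
    char_gru_units: int = 150  # per direction
    main_gru_units: int = 150  # per direction
    char_dropout: float = 0.10
    spatial_dropout: float = 0.30
    main_dropout: float = 0.10
    n_tags: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 4
    class_weighting: bool = True
    seed: int = 0
    enabled_channels: tuple[str, ...] = ALL_CHANNELS
    pretrained_dim: int = 300

    def __post_init__(self) -> None:
        for d in (self.char_dropout, self.spatial_dropout, self.main_dropout):
            if not 0 <= d < 1:
                raise ValueError(f"dropout {d} outside [0, 1)")
        if self.n_tags < 2:
            raise ValueError("n_tags must be >= 2")
        if "token" not in self.enabled_channels:
            raise ValueError("the token channel must be enabled")
        unknown = set(self.enabled_channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


@dataclass(frozen=True)
class TokenPrediction:
    """Per-token output: argmax tag, sigmoid activations, softmax
    probabilities, and entropy normalized by log(n_tags)."""

    position: int
    tag_id: int
    activations: np.ndarray
    probabilities: np.ndarray
    entropy: float


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def normalized_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a probability vector divided by log(K)."""
    p = np.clip(p, 1e-12, 1.0)
    return float(-(p * np.log(p)).sum() / np.log(p.shape[-1]))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


#: Embedding initialization half-range.  Embeddings are uniformly
#: initialized; the scale is chosen so channel signals occupy the GRUs'
#: tanh dynamic range from the start — on small corpora, Adam at 1e-4 moves
#: each parameter only a few hundredths over a short run, so discriminative
#: structure must be reachable from the initial signal scale.
EMBED_INIT_SCALE = 1.5


def _orthogonal_gates(rng: np.random.Generator, units: int) -> np.ndarray:
    """Recurrent kernel: one orthogonal block per gate (z, r, h)."""
    blocks = [
        np.linalg.qr(rng.normal(size=(units, units)))[0] for _ in range(3)
    ]
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# GRU forward/backward (single direction, with mask carry-through)
# ---------------------------------------------------------------------------


def _gru_forward(x, mask, W, U, b, reverse=False):
    """Run a GRU over x (B, T, D) with mask (B, T).

    At masked steps the hidden state is carried through unchanged, so padded
    positions can never influence real ones.  Returns the per-step states
    (B, T, H) in the original time order, the final state, and a cache.
    """
    if reverse:
        x = x[:, ::-1]
        mask = mask[:, ::-1]
    B, T, _ = x.shape
    H = U.shape[0]
    h = np.zeros((B, H))
    A = x @ W + b  # (B, T, 3H)
    states = np.empty((B, T, H))
    cache = []
    for t in range(T):
        m = mask[:, t][:, None]
        p = h @ U
        z = _sigmoid(A[:, t, :H] + p[:, :H])
        r = _sigmoid(A[:, t, H : 2 * H] + p[:, H : 2 * H])
        hh = np.tanh(A[:, t, 2 * H :] + r * p[:, 2 * H :])
        h_new = (1.0 - z) * h + z * hh
        h_next = m * h_new + (1.0 - m) * h
        cache.append((h, z, r, hh, p[:, 2 * H :], m))
        h = h_next
        states[:, t] = h
    if reverse:
        states = states[:, ::-1]
    return states, h, (cache, x, reverse)


def _gru_backward(d_states, d_final, ctx, W, U):
    """Backprop through _gru_forward.

    d_states is the gradient w.r.t. the per-step states in original time
    order (may be None); d_final w.r.t. the final state (may be None).
    Returns (dx in original order, dW, dU, db).
    """
    cache, x, reverse = ctx
    B, T, _ = x.shape
    H = U.shape[0]
    if d_states is None:
        d_states = np.zeros((B, T, H))
    elif reverse:
        d_states = d_states[:, ::-1]
    dh = np.zeros((B, H)) if d_final is None else d_final.copy()
    dx = np.empty_like(x)
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(3 * H)
    for t in range(T - 1, -1, -1):
        h_prev, z, r, hh, ph, m = cache[t]
        dh_t = dh + d_states[:, t]
        dh_new = dh_t * m
        dh_carry = dh_t * (1.0 - m)
        dz = dh_new * (hh - h_prev)
        dhh = dh_new * z
        dh_prev = dh_new * (1.0 - z)
        ds_h = dhh * (1.0 - hh * hh)
        dph = ds_h * r
        dr = ds_h * ph
        ds_z = dz * z * (1.0 - z)
        ds_r = dr * r * (1.0 - r)
        dA = np.concatenate([ds_z, ds_r, ds_h], axis=1)
        dP = np.concatenate([ds_z, ds_r, dph], axis=1)
        dW += x[:, t].T @ dA
        db += dA.sum(axis=0)
        dU += h_prev.T @ dP
        dx[:, t] = dA @ W.T
        dh = dh_carry + dh_prev + dP @ U.T
    if reverse:
        dx = dx[:, ::-1]
    return dx, dW, dU, db


def stack_batch(sentences: Sequence[EncodedSentence]) -> dict[str, np.ndarray]:
    """Stack encoded sentences into batched channel arrays."""
    return {
        "token": np.stack([s.token_ids for s in sentences]),
        "char": np.stack([s.char_ids for s in sentences]),
        "repr": np.stack([s.repr_ids for s in sentences]),
        "pos": np.stack([s.pos_ids for s in sentences]),
        "biot": np.stack([s.biot_flags for s in sentences]).astype(float),
        "umls": np.stack([s.umls_flags for s in sentences]).astype(float),
        "tags": np.stack([s.tag_ids for s in sentences]),
        "mask": np.stack([s.mask for s in sentences]),
    }


class SequenceLabeler:
    """Dual Bi-GRU tagger; parameters live in a flat name -> array dict."""

    def __init__(self, config: ModelConfig, vocab_sizes: Mapping[str, int]):
        self.config = config
        self.vocab_sizes = dict(vocab_sizes)
        for channel in config.enabled_channels:
            if channel in ("token", "char", "repr", "pos") and channel not in vocab_sizes:
                raise ValueError(
                    f"channel {channel!r} enabled but no vocabulary size given"
                )
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.class_weights = np.ones(config.n_tags)
        self.history: list[dict] = []

    # -- construction -------------------------------------------------------

    def _token_dim(self) -> int:
        if self.config.token_embedding == "supervised":
            return self.config.supervised_dim
        return self.config.pretrained_dim

    def _feature_dim(self) -> int:
        cfg = self.config
        dims = {
            "token": self._token_dim(),
            "char": 2 * cfg.char_gru_units,
            "repr": cfg.repr_embedding_dim,
            "pos": cfg.pos_embedding_dim,
            "biot": 4,
            "umls": 1,
        }
        return sum(dims[c] for c in cfg.enabled_channels)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        p = self.params
        s = EMBED_INIT_SCALE
        if cfg.token_embedding != "pretrained-contextual":
            p["emb_token"] = rng.uniform(
                -s, s, size=(self.vocab_sizes["token"], self._token_dim())
            )
        if "char" in cfg.enabled_channels:
            p["emb_char"] = rng.uniform(
                -s, s, size=(self.vocab_sizes["char"], cfg.char_embedding_dim)
            )
            for d in ("f", "b"):
                p[f"char_W{d}"] = _glorot(
                    rng, (cfg.char_embedding_dim, 3 * cfg.char_gru_units)
                )
                p[f"char_U{d}"] = _orthogonal_gates(rng, cfg.char_gru_units)
                p[f"char_b{d}"] = np.zeros(3 * cfg.char_gru_units)
        if "repr" in cfg.enabled_channels:
            p["emb_repr"] = rng.uniform(
                -s, s, size=(self.vocab_sizes["repr"], cfg.repr_embedding_dim)
            )
        if "pos" in cfg.enabled_channels:
            p["emb_pos"] = rng.uniform(
                -s, s, size=(self.vocab_sizes["pos"], cfg.pos_embedding_dim)
            )
        F = self._feature_dim()
        for d in ("f", "b"):
            p[f"main_W{d}"] = _glorot(rng, (F, 3 * cfg.main_gru_units))
            p[f"main_U{d}"] = _orthogonal_gates(rng, cfg.main_gru_units)
            p[f"main_b{d}"] = np.zeros(3 * cfg.main_gru_units)
        p["dense_W"] = _glorot(rng, (2 * cfg.main_gru_units, cfg.n_tags))
        p["dense_b"] = np.zeros(cfg.n_tags)

    def set_pretrained_vectors(
        self, vectors: Mapping[str, np.ndarray], vocab_decode
    ) -> int:
        """Initialize the token embedding from static word vectors.

        ``vocab_decode`` maps token ids to surfaces; rows without a vector
        keep their random initialization.  Returns the number of rows set.
        """
        emb = self.params["emb_token"]
        n_set = 0
        for idx in range(emb.shape[0]):
            vec = vectors.get(vocab_decode(idx))
            if vec is not None:
                emb[idx] = vec[: emb.shape[1]]
                n_set += 1
        return n_set

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    # -- forward / backward -------------------------------------------------

    def forward(self, batch, train=False, rng=None):
        """Compute sigmoid activations (B, T, K); returns (a, cache)."""
        cfg = self.config
        p = self.params
        mask = batch["mask"].astype(float)
        B, T = mask.shape
        feats = []
        slices = []  # (channel, start, end) into the concatenated features
        cache: dict = {"mask": mask}
        pos_dim = 0

        def add(name, arr):
            nonlocal pos_dim
            feats.append(arr)
            slices.append((name, pos_dim, pos_dim + arr.shape[-1]))
            pos_dim += arr.shape[-1]

        if "token" in cfg.enabled_channels:
            if cfg.token_embedding == "pretrained-contextual":
                add("token", batch["token_vec"])
            else:
                add("token", p["emb_token"][batch["token"]])
        if "char" in cfg.enabled_channels:
            C = batch["char"].shape[2]
            char_ids = batch["char"].reshape(B * T, C)
            char_mask = (char_ids != 0).astype(float)
            xc = p["emb_char"][char_ids]
            _, hf, ctx_f = _gru_forward(
                xc, char_mask, p["char_Wf"], p["char_Uf"], p["char_bf"]
            )
            _, hb, ctx_b = _gru_forward(
                xc, char_mask, p["char_Wb"], p["char_Ub"], p["char_bb"], reverse=True
            )
            hc = np.concatenate([hf, hb], axis=1).reshape(B, T, -1)
            if train and cfg.char_dropout > 0:
                keep = (rng.random(hc.shape) >= cfg.char_dropout) / (
                    1 - cfg.char_dropout
                )
                hc = hc * keep
                cache["char_drop"] = keep
            cache.update(char_ids=char_ids, char_ctx=(ctx_f, ctx_b))
            add("char", hc)
        if "repr" in cfg.enabled_channels:
            add("repr", p["emb_repr"][batch["repr"]])
        if "pos" in cfg.enabled_channels:
            add("pos", p["emb_pos"][batch["pos"]])
        if "biot" in cfg.enabled_channels:
            add("biot", batch["biot"])
        if "umls" in cfg.enabled_channels:
            add("umls", batch["umls"][..., None])

        X = np.concatenate(feats, axis=2)
        cache["slices"] = slices
        if train and cfg.spatial_dropout > 0:
            keep = (rng.random((B, 1, X.shape[2])) >= cfg.spatial_dropout) / (
                1 - cfg.spatial_dropout
            )
            X = X * keep
            cache["spatial_drop"] = keep
        cache["X"] = X

        Hf, _, ctx_mf = _gru_forward(X, mask, p["main_Wf"], p["main_Uf"], p["main_bf"])
        Hb, _, ctx_mb = _gru_forward(
            X, mask, p["main_Wb"], p["main_Ub"], p["main_bb"], reverse=True
        )
        Hcat = np.concatenate([Hf, Hb], axis=2)
        if train and cfg.main_dropout > 0:
            keep = (rng.random(Hcat.shape) >= cfg.main_dropout) / (1 - cfg.main_dropout)
            Hcat = Hcat * keep
            cache["main_drop"] = keep
        cache.update(main_ctx=(ctx_mf, ctx_mb), Hcat=Hcat)
        logits = Hcat @ p["dense_W"] + p["dense_b"]
        a = _sigmoid(logits)
        cache["a"] = a
        return a, cache

    def loss_and_grads(self, batch, rng):
        """Masked per-tag binary cross-entropy on the sigmoid activations
        (the standard pairing for a sigmoid classification head), plus
        gradients for every parameter.

        The true tag's positive term is scaled by its class weight; padded
        positions contribute nothing.
        """
        cfg = self.config
        p = self.params
        a, cache = self.forward(batch, train=True, rng=rng)
        mask = cache["mask"]
        y = batch["tags"]
        onehot = np.zeros_like(a)
        np.put_along_axis(onehot, y[..., None], 1.0, axis=2)
        w = np.where(onehot > 0, self.class_weights[y][..., None], 1.0)
        w = w * mask[..., None]
        norm = max(mask.sum(), 1.0)
        a_clip = np.clip(a, 1e-7, 1 - 1e-7)
        loss = float(
            -(w * (onehot * np.log(a_clip) + (1 - onehot) * np.log(1 - a_clip))).sum()
            / norm
        )
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        grads: dict[str, np.ndarray] = {}
        dlogits = w * (a - onehot) / norm

        Hcat = cache["Hcat"]
        grads["dense_W"] = np.einsum("btf,btk->fk", Hcat, dlogits)
        grads["dense_b"] = dlogits.sum(axis=(0, 1))
        dHcat = dlogits @ p["dense_W"].T
        if "main_drop" in cache:
            dHcat = dHcat * cache["main_drop"]
        H = cfg.main_gru_units
        ctx_mf, ctx_mb = cache["main_ctx"]
        dXf, grads["main_Wf"], grads["main_Uf"], grads["main_bf"] = _gru_backward(
            dHcat[..., :H], None, ctx_mf, p["main_Wf"], p["main_Uf"]
        )
        dXb, grads["main_Wb"], grads["main_Ub"], grads["main_bb"] = _gru_backward(
            dHcat[..., H:], None, ctx_mb, p["main_Wb"], p["main_Ub"]
        )
        dX = dXf + dXb
        if "spatial_drop" in cache:
            dX = dX * cache["spatial_drop"]

        for name, lo, hi in cache["slices"]:
            dpart = dX[..., lo:hi]
            if name == "token" and cfg.token_embedding != "pretrained-contextual":
                grads["emb_token"] = np.zeros_like(p["emb_token"])
                np.add.at(grads["emb_token"], batch["token"], dpart)
            elif name == "char":
                if "char_drop" in cache:
                    dpart = dpart * cache["char_drop"]
                B, T = mask.shape
                Hc = cfg.char_gru_units
                dflat = dpart.reshape(B * T, 2 * Hc)
                ctx_f, ctx_b = cache["char_ctx"]
                dxf, grads["char_Wf"], grads["char_Uf"], grads["char_bf"] = (
                    _gru_backward(None, dflat[:, :Hc], ctx_f, p["char_Wf"], p["char_Uf"])
                )
                dxb, grads["char_Wb"], grads["char_Ub"], grads["char_bb"] = (
                    _gru_backward(None, dflat[:, Hc:], ctx_b, p["char_Wb"], p["char_Ub"])
                )
                dxc = dxf + dxb
                grads["emb_char"] = np.zeros_like(p["emb_char"])
                np.add.at(grads["emb_char"], cache["char_ids"], dxc)
            elif name == "repr":
                grads["emb_repr"] = np.zeros_like(p["emb_repr"])
                np.add.at(grads["emb_repr"], batch["repr"], dpart)
            elif name == "pos":
                grads["emb_pos"] = np.zeros_like(p["emb_pos"])
                np.add.at(grads["emb_pos"], batch["pos"], dpart)
            # biot/umls are raw inputs: nothing to update
        return loss, grads

    # -- optimization -------------------------------------------------------

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def _init_output_bias(self, sentences: Sequence[EncodedSentence]) -> None:
        """Start the sigmoid head at the (weighted) class priors.

        Sets each output bias to the log-odds of its tag's weighted base
        rate, so no training budget is spent learning the label marginals
        — essential for short runs at a small learning rate.
        """
        cfg = self.config
        counts = np.zeros(cfg.n_tags)
        for s in sentences:
            np.add.at(counts, s.tag_ids[s.mask.astype(bool)], 1)
        p = counts / max(counts.sum(), 1.0)
        target = np.clip(
            self.class_weights * p / (self.class_weights * p + (1.0 - p)),
            1e-4,
            1 - 1e-4,
        )
        self.params["dense_b"] = np.log(target / (1.0 - target))

    def fit(self, sentences: Sequence[EncodedSentence]) -> list[dict]:
        """Train with Adam, shuffled mini-batches and plateau LR reduction.

        The learning rate is multiplied by ``lr_reduce_factor`` whenever the
        epoch loss fails to improve on its best value for
        ``lr_reduce_patience`` consecutive epochs.  Returns (and stores) the
        per-epoch history: loss and learning rate.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        if cfg.class_weighting:
            self.class_weights = compute_class_weights(sentences, cfg.n_tags)
        if self._adam_t == 0:  # fresh model: calibrate the head to the priors
            self._init_output_bias(sentences)
        lr = cfg.learning_rate
        best = np.inf
        flat_epochs = 0
        order = np.arange(len(sentences))
        self.history = []
        for epoch in range(cfg.epochs):
            rng.shuffle(order)
            total_loss = 0.0
            total_positions = 0.0
            for i in range(0, len(order), cfg.batch_size):
                batch_sents = [sentences[j] for j in order[i : i + cfg.batch_size]]
                batch = stack_batch(batch_sents)
                _trim_batch(batch)
                loss, grads = self.loss_and_grads(batch, rng)
                self._adam_step(grads, lr)
                n_pos = float(batch["mask"].sum())
                total_loss += loss * n_pos
                total_positions += n_pos
            epoch_loss = total_loss / max(total_positions, 1.0)
            self.history.append({"epoch": epoch, "loss": epoch_loss, "lr": lr})
            if epoch_loss < best:
                best = epoch_loss
                flat_epochs = 0
            else:
                flat_epochs += 1
                if flat_epochs >= cfg.lr_reduce_patience:
                    lr *= cfg.lr_reduce_factor
                    flat_epochs = 0
                    log.info("epoch %d: plateau, lr reduced to %g", epoch, lr)
        return self.history

    # -- inference ----------------------------------------------------------

    def predict_sentences(
        self, sentences: Sequence[EncodedSentence], batch_size: int = 64
    ) -> list[list[TokenPrediction]]:
        """One TokenPrediction per real (unmasked) token position."""
        out: list[list[TokenPrediction]] = []
        for i in range(0, len(sentences), batch_size):
            chunk = sentences[i : i + batch_size]
            batch = stack_batch(chunk)
            _trim_batch(batch)
            a, _ = self.forward(batch, train=False)
            prob = _softmax(a)
            for bi, sent in enumerate(chunk):
                n = int(sent.mask.sum())
                preds = [
                    TokenPrediction(
                        position=t,
                        tag_id=int(np.argmax(prob[bi, t])),
                        activations=a[bi, t].copy(),
                        probabilities=prob[bi, t].copy(),
                        entropy=normalized_entropy(prob[bi, t]),
                    )
                    for t in range(min(n, a.shape[1]))
                ]
                out.append(preds)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "vocab_sizes": self.vocab_sizes}
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.params,
                 class_weights=self.class_weights)

    @classmethod
    def load(cls, directory: str | Path) -> "SequenceLabeler":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        cfg = meta["config"]
        cfg["enabled_channels"] = tuple(cfg["enabled_channels"])
        model = cls(ModelConfig(**cfg), meta["vocab_sizes"])
        data = np.load(directory / "weights.npz")
        for k in model.params:
            model.params[k] = data[k]
        model.class_weights = data["class_weights"]
        return model


def _trim_batch(batch: dict[str, np.ndarray]) -> None:
    """Trim batch arrays to the longest real sequence (masked positions can
    never affect real ones, so this is a pure speed optimization)."""
    lengths = batch["mask"].sum(axis=1)
    t_eff = max(1, int(lengths.max()))
    for key in batch:
        if batch[key].ndim >= 2 and batch[key].shape[1] >= t_eff:
            batch[key] = batch[key][:, :t_eff]


def compute_class_weights(
    sentences: Sequence[EncodedSentence], n_tags: int
) -> np.ndarray:
    """Inverse-frequency ("balanced") weights over observed tag ids."""
    counts = np.zeros(n_tags)
    for s in sentences:
        real = s.tag_ids[s.mask.astype(bool)]
        np.add.at(counts, real, 1)
    total = counts.sum()
    observed = counts > 0
    weights = np.ones(n_tags)
    weights[observed] = total / (observed.sum() * counts[observed])
    return weights


def build_model(
    config: ModelConfig, vocab_sizes: Mapping[str, int]
) -> SequenceLabeler:
    """Construct an initialized (untrained) labeler."""
    return SequenceLabeler(config, vocab_sizes)


def train(
    model: SequenceLabeler, sentences: Sequence[EncodedSentence]
) -> list[dict]:
    """Train in place; returns the per-epoch loss history."""
    return model.fit(sentences)


def predict(
    model: SequenceLabeler, sentences: Sequence[EncodedSentence]
) -> list[list[TokenPrediction]]:
    return model.predict_sentences(sentences)


def load_word_vectors(path: str | Path, dim: int | None = None) -> dict[str, np.ndarray]:
    """Read a GloVe-style text file: word then whitespace-separated floats."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip().split(" ")
            if len(parts) < 2:
                continue
            vec = np.array([float(x) for x in parts[1:]])
            if dim is not None and vec.shape[0] != dim:
                continue
            vectors[parts[0]] = vec
    return vectors
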