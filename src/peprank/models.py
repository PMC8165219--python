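"""ConvM and SpConvM scoring networks.

ConvM scores a peptide in four stages: (1) the feature matrix F — residue
encodings plus dual-end position vectors — is convolved with d_r local
kernels of width k ("valid" convolution, so each of the n-k+1 columns is a
k-mer embedding); (2) batch normalization and ReLU; (3) a self-attention
layer computes one weight per k-mer, ``w = softmax(v tanh(W r + b))``, and
pools the k-mer embeddings into a single vector ``c = sum_i w_i r_i``;
(4) a fully-connected head (one hidden layer of width d_r, ReLU, then a
linear unit) maps c to the scalar score S(p).

SpConvM augments c with d_g global kernels: each kernel spans the whole
d_e x 15 middle-padded encoding F_G (no position vectors) and yields one
ReLU-activated scalar, and the head consumes [c; g].

Models trained with the mean-square loss squash S(p) through a sigmoid;
the hinge losses use the unbounded score.

Everything here is plain NumPy with hand-written backpropagation; the
gradients are validated against finite differences in the test suite.
Peptides in a batch are grouped by length so each group is a dense tensor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import (
    AA_INDEX,
    EncodingScheme,
    PADDED_LENGTH,
    fixed_encoding_matrix,
    pad_middle,
    peptide_indices,
)

ARCHITECTURES = ("convm", "spconvm")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of a ConvM/SpConvM scoring model."""

    architecture: str = "convm"
    k: int = 1
    d_r: int = 16
    d_a: int = 8
    d_o: int = 4
    d_g: int = 8
    scheme: EncodingScheme = field(default_factory=EncodingScheme)
    use_positions: bool = True
    loss_id: str = "hv"

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if not (1 <= self.k <= 8):
            raise ConfigurationError("kernel size must be in [1, 8]")
        if min(self.d_r, self.d_a) < 1 or (self.use_positions and self.d_o < 1):
            raise ConfigurationError("dimensions must be >= 1")
        if self.architecture == "spconvm" and self.d_g < 1:
            raise ConfigurationError("SpConvM needs d_g >= 1")

    @property
    def d_e(self) -> int:
        return self.scheme.d_e

    @property
    def d_in(self) -> int:
        return self.d_e + (2 * self.d_o if self.use_positions else 0)

    @property
    def pooled_dim(self) -> int:
        return self.d_r + (self.d_g if self.architecture == "spconvm" else 0)


class ModelState:
    """Learnable parameters plus batch-norm running statistics."""

    def __init__(self, config: ModelConfig, params: dict, buffers: dict):
        self.config = config
        self.params = params
        self.buffers = buffers

    def copy(self) -> "ModelState":
        return ModelState(
            self.config,
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.buffers.items()},
        )

    def to_dict(self) -> dict:
        cfg = self.config
        return {
            "config": {
                "architecture": cfg.architecture,
                "k": cfg.k,
                "d_r": cfg.d_r,
                "d_a": cfg.d_a,
                "d_o": cfg.d_o,
                "d_g": cfg.d_g,
                "scheme": "+".join(cfg.scheme.components),
                "use_positions": cfg.use_positions,
                "loss_id": cfg.loss_id,
            },
            "params": {k: v.tolist() for k, v in self.params.items()},
            "buffers": {k: v.tolist() for k, v in self.buffers.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ModelState":
        raw = dict(payload["config"])
        raw["scheme"] = EncodingScheme.parse(raw["scheme"])
        config = ModelConfig(**raw)
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        buffers = {k: np.asarray(v, dtype=float) for k, v in payload["buffers"].items()}
        return cls(config, params, buffers)

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_state(config: ModelConfig, rng: np.random.Generator) -> ModelState:
    p: dict[str, np.ndarray] = {}
    d_in, d_r, d_a = config.d_in, config.d_r, config.d_a
    if config.scheme.uses_deep:
        p["deep"] = rng.normal(0.0, 0.5, (20, 20))
    if config.use_positions:
        p["pos_c"] = rng.normal(0.0, 0.1, (PADDED_LENGTH, config.d_o))
        p["pos_n"] = rng.normal(0.0, 0.1, (PADDED_LENGTH, config.d_o))
    p["conv_W"] = rng.normal(0.0, 1.0 / np.sqrt(d_in * config.k), (d_r, d_in, config.k))
    p["conv_b"] = np.zeros(d_r)
    p["bn_gamma"] = np.ones(d_r)
    p["bn_beta"] = np.zeros(d_r)
    p["att_W"] = rng.normal(0.0, 1.0 / np.sqrt(d_r), (d_a, d_r))
    p["att_b"] = np.zeros(d_a)
    p["att_v"] = rng.normal(0.0, 1.0 / np.sqrt(d_a), d_a)
    if config.architecture == "spconvm":
        d_flat = config.d_e * PADDED_LENGTH
        p["glob_W"] = rng.normal(0.0, 1.0 / np.sqrt(d_flat), (config.d_g, d_flat))
        p["glob_b"] = np.zeros(config.d_g)
    p["fc1_W"] = rng.normal(0.0, 1.0 / np.sqrt(config.pooled_dim), (d_r, config.pooled_dim))
    p["fc1_b"] = np.zeros(d_r)
    p["fc2_w"] = rng.normal(0.0, 1.0 / np.sqrt(d_r), d_r)
    p["fc2_b"] = np.zeros(())
    buffers = {"bn_mean": np.zeros(d_r), "bn_var": np.ones(d_r)}
    return ModelState(config, p, buffers)


# ---------------------------------------------------------------------------
# Static per-peptide features (independent of learnable parameters)


@dataclass(frozen=True)
class PeptideFeatures:
    """Residue indices of a peptide plus its slot in the padded frame."""

    peptide: str
    idx: np.ndarray  # (n,) residue indices
    padded_idx: np.ndarray  # (15,) residue indices, -1 at pad slots

    @classmethod
    def build(cls, peptide: str) -> "PeptideFeatures":
        idx = peptide_indices(peptide)
        padded = pad_middle(peptide)
        pidx = np.array(
            [AA_INDEX[a] if a != "X" else -1 for a in padded], dtype=np.intp
        )
        return cls(peptide, idx, pidx)


class FeatureCache:
    """Memoizes :class:`PeptideFeatures` across batches."""

    def __init__(self):
        self._cache: dict[str, PeptideFeatures] = {}

    def get(self, peptide: str) -> PeptideFeatures:
        feat = self._cache.get(peptide)
        if feat is None:
            feat = PeptideFeatures.build(peptide)
            self._cache[peptide] = feat
        return feat

    def get_many(self, peptides) -> list[PeptideFeatures]:
        return [self.get(p) for p in peptides]


# ---------------------------------------------------------------------------
# Forward / backward

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def forward(
    state: ModelState,
    feats: list[PeptideFeatures],
    training: bool,
):
    """Score a batch of peptides.  Returns (scores, cache).

    In training mode batch normalization uses statistics of the current
    batch (jointly over all peptides and k-mer positions) and updates the
    running buffers; in evaluation mode the running buffers are used, so a
    peptide's score does not depend on its batch companions.
    """
    cfg = state.config
    p = state.params
    if cfg.k > min(len(f.idx) for f in feats):
        raise ConfigurationError("kernel size exceeds shortest peptide")
    efix = fixed_encoding_matrix(cfg.scheme)  # (d_fix, 20)
    deep = p.get("deep")
    groups: dict[int, list[int]] = {}
    for i, f in enumerate(feats):
        groups.setdefault(len(f.idx), []).append(i)

    wmat = p["conv_W"].reshape(cfg.d_r, cfg.d_in * cfg.k)
    gcaches = []
    # pass 1: convolution (+ batch-norm statistics accumulation)
    tot_sum = np.zeros(cfg.d_r)
    tot_sq = np.zeros(cfg.d_r)
    tot_count = 0
    for n, members in sorted(groups.items()):
        idx = np.stack([feats[i].idx for i in members])  # (B, n)
        blocks = [efix[:, idx].transpose(1, 0, 2)] if efix.size else []
        if deep is not None:
            # deep block sits after the fixed components in scheme order;
            # scheme order with deep always places learned dims last only
            # if declared last — rebuild in declared order instead.
            blocks = []
            for comp in cfg.scheme.components:
                if comp == "deep":
                    blocks.append(deep[idx].transpose(0, 2, 1))
                elif comp == "blosum":
                    from .encoding import BLOSUM62

                    blocks.append(BLOSUM62[idx].transpose(0, 2, 1))
                else:
                    from .encoding import ONEHOT

                    blocks.append(ONEHOT[idx].transpose(0, 2, 1))
        if cfg.use_positions:
            B = idx.shape[0]
            pc = np.broadcast_to(p["pos_c"][:n].T, (B, cfg.d_o, n))
            pn = np.broadcast_to(p["pos_n"][:n][::-1].T, (B, cfg.d_o, n))
            blocks = blocks + [pc, pn]
        F = np.concatenate(blocks, axis=1)  # (B, d_in, n)
        m = n - cfg.k + 1
        if cfg.k == 1:
            X = F
        else:
            X = np.empty((F.shape[0], cfg.d_in * cfg.k, m))
            for i in range(m):
                X[:, :, i] = F[:, :, i : i + cfg.k].reshape(F.shape[0], -1)
        rpre = np.einsum("fq,bqm->bfm", wmat, X) + p["conv_b"][None, :, None]
        tot_sum += rpre.sum(axis=(0, 2))
        tot_sq += (rpre**2).sum(axis=(0, 2))
        tot_count += rpre.shape[0] * m
        gcaches.append({"n": n, "members": members, "idx": idx, "X": X, "rpre": rpre})

    if training:
        mean = tot_sum / tot_count
        var = tot_sq / tot_count - mean**2
        var = np.maximum(var, 0.0)
        state.buffers["bn_mean"] = (
            (1 - _BN_MOMENTUM) * state.buffers["bn_mean"] + _BN_MOMENTUM * mean
        )
        state.buffers["bn_var"] = (
            (1 - _BN_MOMENTUM) * state.buffers["bn_var"] + _BN_MOMENTUM * var
        )
    else:
        mean = state.buffers["bn_mean"]
        var = state.buffers["bn_var"]
    std = np.sqrt(var + _BN_EPS)

    scores = np.empty(len(feats))
    # pass 2: normalization, attention, head
    for gc in gcaches:
        rhat = (gc["rpre"] - mean[None, :, None]) / std[None, :, None]
        A = p["bn_gamma"][None, :, None] * rhat + p["bn_beta"][None, :, None]
        relu_mask = A > 0
        A = A * relu_mask
        Z = np.tanh(
            np.einsum("ar,brm->bam", p["att_W"], A) + p["att_b"][None, :, None]
        )
        logits = np.einsum("a,bam->bm", p["att_v"], Z)
        logits = logits - logits.max(axis=1, keepdims=True)
        ew = np.exp(logits)
        w = ew / ew.sum(axis=1, keepdims=True)
        c = np.einsum("brm,bm->br", A, w)
        if cfg.architecture == "spconvm":
            pidx = np.stack([feats[i].padded_idx for i in gc["members"]])  # (B,15)
            mask = pidx >= 0
            FG = _encode_padded(cfg, p, pidx, mask)  # (B, d_e, 15)
            FG_flat = FG.reshape(FG.shape[0], -1)
            g_pre = FG_flat @ p["glob_W"].T + p["glob_b"]
            g = np.maximum(g_pre, 0.0)
            u = np.concatenate([c, g], axis=1)
            gc.update(pidx=pidx, pad_mask=mask, FG_flat=FG_flat, g=g)
        else:
            u = c
        h_pre = u @ p["fc1_W"].T + p["fc1_b"]
        h = np.maximum(h_pre, 0.0)
        s = h @ p["fc2_w"] + p["fc2_b"]
        if cfg.loss_id == "ms":
            s = _sigmoid(s)
        scores[gc["members"]] = s
        gc.update(rhat=rhat, relu_mask=relu_mask, A=A, Z=Z, w=w, c=c, u=u, h=h, s=s)

    cache = {
        "groups": gcaches,
        "mean": mean,
        "std": std,
        "count": tot_count,
        "training": training,
        "feats": feats,
    }
    return scores, cache


def _encode_padded(cfg, params, pidx, mask):
    """F_G tensor for a group: (B, d_e, 15), zeros at pad slots."""
    B = pidx.shape[0]
    safe = np.where(mask, pidx, 0)
    blocks = []
    from .encoding import BLOSUM62, ONEHOT

    for comp in cfg.scheme.components:
        if comp == "blosum":
            table = BLOSUM62
        elif comp == "onehot":
            table = ONEHOT
        else:
            table = params["deep"]
        block = table[safe].transpose(0, 2, 1) * mask[:, None, :]
        blocks.append(block)
    return np.concatenate(blocks, axis=1)


def backward(state: ModelState, cache: dict, dscores: np.ndarray) -> dict:
    """Gradients of sum_i dscores[i] * S(p_i) w.r.t. every parameter."""
    cfg = state.config
    p = state.params
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    mean, std = cache["mean"], cache["std"]

    # head + attention backward per group, collecting dRbn for joint BN step
    sum_db = np.zeros(cfg.d_r)
    sum_dh = np.zeros(cfg.d_r)
    for gc in cache["groups"]:
        ds = dscores[gc["members"]].astype(float)
        if cfg.loss_id == "ms":
            ds = ds * gc["s"] * (1.0 - gc["s"])
        h, u = gc["h"], gc["u"]
        grads["fc2_w"] += h.T @ ds
        grads["fc2_b"] += ds.sum()
        dh = np.outer(ds, p["fc2_w"]) * (h > 0)
        grads["fc1_W"] += dh.T @ u
        grads["fc1_b"] += dh.sum(axis=0)
        du = dh @ p["fc1_W"]
        if cfg.architecture == "spconvm":
            dc = du[:, : cfg.d_r]
            dg = du[:, cfg.d_r :] * (gc["g"] > 0)
            grads["glob_W"] += dg.T @ gc["FG_flat"]
            grads["glob_b"] += dg.sum(axis=0)
            dFG = (dg @ p["glob_W"]).reshape(-1, cfg.d_e, PADDED_LENGTH)
            if cfg.scheme.uses_deep:
                offset = 0
                for comp in cfg.scheme.components:
                    if comp == "deep":
                        dblock = dFG[:, offset : offset + 20, :]
                        _scatter_deep(
                            grads["deep"], dblock, gc["pidx"], gc["pad_mask"]
                        )
                    offset += 20
        else:
            dc = du
        A, w, Z = gc["A"], gc["w"], gc["Z"]
        dA = dc[:, :, None] * w[:, None, :]
        dw = np.einsum("brm,br->bm", A, dc)
        dlogits = w * (dw - np.einsum("bm,bm->b", w, dw)[:, None])
        grads["att_v"] += np.einsum("bam,bm->a", Z, dlogits)
        dZ = p["att_v"][None, :, None] * dlogits[:, None, :]
        dZpre = dZ * (1.0 - Z**2)
        grads["att_W"] += np.einsum("bam,brm->ar", dZpre, A)
        grads["att_b"] += dZpre.sum(axis=(0, 2))
        dA += np.einsum("ar,bam->brm", p["att_W"], dZpre)
        dRbn = dA * gc["relu_mask"]
        gc["dRbn"] = dRbn
        sum_db += dRbn.sum(axis=(0, 2))
        sum_dh += (dRbn * gc["rhat"]).sum(axis=(0, 2))

    grads["bn_gamma"] += sum_dh
    grads["bn_beta"] += sum_db
    M = cache["count"]
    gamma_over_std = (p["bn_gamma"] / std)[None, :, None]

    wmat_grad = grads["conv_W"].reshape(cfg.d_r, cfg.d_in * cfg.k)
    wmat = p["conv_W"].reshape(cfg.d_r, cfg.d_in * cfg.k)
    for gc in cache["groups"]:
        dRbn = gc.pop("dRbn")
        if cache["training"]:
            drpre = gamma_over_std * (
                dRbn
                - (sum_db / M)[None, :, None]
                - gc["rhat"] * (sum_dh / M)[None, :, None]
            )
        else:
            drpre = gamma_over_std * dRbn
        wmat_grad += np.einsum("bfm,bqm->fq", drpre, gc["X"])
        grads["conv_b"] += drpre.sum(axis=(0, 2))
        dX = np.einsum("fq,bfm->bqm", wmat, drpre)
        n = gc["n"]
        m = n - cfg.k + 1
        if cfg.k == 1:
            dF = dX
        else:
            dF = np.zeros((dX.shape[0], cfg.d_in, n))
            for i in range(m):
                dF[:, :, i : i + cfg.k] += dX[:, :, i].reshape(
                    dX.shape[0], cfg.d_in, cfg.k
                )
        offset = 0
        for comp in cfg.scheme.components:
            if comp == "deep":
                dblock = dF[:, offset : offset + 20, :]
                _scatter_deep(grads["deep"], dblock, gc["idx"], None)
            offset += 20
        if cfg.use_positions:
            dpc = dF[:, offset : offset + cfg.d_o, :].sum(axis=0).T  # (n, d_o)
            offset += cfg.d_o
            dpn = dF[:, offset : offset + cfg.d_o, :].sum(axis=0).T
            grads["pos_c"][:n] += dpc
            grads["pos_n"][:n] += dpn[::-1]
    return grads


def _scatter_deep(grad_deep, dblock, idx, mask):
    """Accumulate (B, 20, L) gradients into the 20x20 deep table rows."""
    B, _, L = dblock.shape
    flat_idx = idx.ravel()
    flat = dblock.transpose(0, 2, 1).reshape(B * L, 20)
    if mask is not None:
        keep = mask.ravel()
        flat_idx = flat_idx[keep]
        flat = flat[keep]
    np.add.at(grad_deep, flat_idx, flat)


def score_peptides(
    state: ModelState, peptides, feature_cache: FeatureCache | None = None
) -> np.ndarray:
    """Evaluation-mode scores for a list of peptides."""
    cache = feature_cache or FeatureCache()
    feats = cache.get_many(peptides)
    scores, _ = forward(state, feats, training=False)
    return scores


def attention_weights(
    state: ModelState, peptides, feature_cache: FeatureCache | None = None
) -> list[np.ndarray]:
    """Evaluation-mode attention weight vector per peptide (length n-k+1)."""
    cache = feature_cache or FeatureCache()
    feats = cache.get_many(peptides)
    _, fcache = forward(state, feats, training=False)
    out: list[np.ndarray | None] = [None] * len(peptides)
    for gc in fcache["groups"]:
        for row, i in enumerate(gc["members"]):
            out[i] = gc["w"][row].copy()
    return out
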