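"""Lead-token transformer models for single- and dual-ECG inference.

Architecture
------------
Every lead's 2 s waveform (1000 samples) is encoded by the *same* 1D residual
CNN into one embedding vector ("lead token"), so the encoder weights are
shared across all 12 (or 24) leads.  Learned per-lead identity embeddings —
and, in dual mode, a learned baseline/follow-up timepoint embedding — are
added so that tokens remain distinguishable despite weight sharing.  A learned
class token is prepended, the token sequence runs through a stack of
multi-head self-attention encoder layers, and the encoded class token feeds a
linear head:

* regression head (1 output): predicted log-BNP from 12 lead tokens ("EBT");
* 3-class head: softmax over {deteriorated, improved, no_change} from the
  24-lead baseline+follow-up stack ("DEHT").

The default configuration matches the full-scale design (1D ResNet-50
bottleneck backbone, 256-dimensional tokens, 8 attention heads, 4 encoder
layers); the ``tiny`` preset is a small-channel variant of the same layout
used for desk-scale experiments and tests.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .nn import functional as F


@dataclass(frozen=True)
class ModelConfig:
    embed_dim: int = 256
    n_heads: int = 8
    n_encoder_layers: int = 4
    ffn_ratio: int = 4
    backbone: str = "resnet50_1d"        # or "resnet_tiny_1d"
    n_lead_tokens: int = 12              # 12 (single ECG) or 24 (dual)
    head: str = "regression"             # or "classification_3"
    lead_embedding: bool = True
    timepoint_embedding: bool = True     # dual mode only
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_lead_tokens not in (12, 24):
            raise ValueError("n_lead_tokens must be 12 or 24")
        if self.head not in ("regression", "classification_3"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.backbone not in ("resnet50_1d", "resnet_tiny_1d"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @property
    def n_outputs(self) -> int:
        return 1 if self.head == "regression" else 3


def tiny_config(**overrides) -> ModelConfig:
    """Small-footprint preset for CPU-scale experiments."""
    base = dict(embed_dim=64, n_heads=8, n_encoder_layers=2, ffn_ratio=2,
                backbone="resnet_tiny_1d")
    base.update(overrides)
    return ModelConfig(**base)


# -------------------------------------------------------------------------
# residual blocks
# -------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    def __init__(self, c_in: int, c_out: int, stride: int, *, rng):
        super().__init__()
        self.conv1 = self.add_child("conv1", nn.Conv1d(c_in, c_out, 3, stride, rng=rng))
        self.bn1 = self.add_child("bn1", nn.BatchNorm1d(c_out))
        self.relu1 = self.add_child("relu1", nn.ReLU())
        self.conv2 = self.add_child("conv2", nn.Conv1d(c_out, c_out, 3, 1, rng=rng))
        self.bn2 = self.add_child("bn2", nn.BatchNorm1d(c_out))
        self.relu2 = self.add_child("relu2", nn.ReLU())
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = self.add_child("down", nn.Sequential(
                nn.Conv1d(c_in, c_out, 1, stride, padding=0, rng=rng),
                nn.BatchNorm1d(c_out)))

    def forward(self, x):
        identity = self.down.forward(x) if self.down else x
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        return self.relu2.forward(out + identity)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dident = self.down.backward(d) if self.down else d
        return dmain + dident


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, c_in: int, planes: int, stride: int, *, rng):
        super().__init__()
        c_out = planes * self.expansion
        self.conv1 = self.add_child("conv1", nn.Conv1d(c_in, planes, 1, 1, padding=0, rng=rng))
        self.bn1 = self.add_child("bn1", nn.BatchNorm1d(planes))
        self.r1 = self.add_child("r1", nn.ReLU())
        self.conv2 = self.add_child("conv2", nn.Conv1d(planes, planes, 3, stride, rng=rng))
        self.bn2 = self.add_child("bn2", nn.BatchNorm1d(planes))
        self.r2 = self.add_child("r2", nn.ReLU())
        self.conv3 = self.add_child("conv3", nn.Conv1d(planes, c_out, 1, 1, padding=0, rng=rng))
        self.bn3 = self.add_child("bn3", nn.BatchNorm1d(c_out))
        self.r3 = self.add_child("r3", nn.ReLU())
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = self.add_child("down", nn.Sequential(
                nn.Conv1d(c_in, c_out, 1, stride, padding=0, rng=rng),
                nn.BatchNorm1d(c_out)))

    def forward(self, x):
        identity = self.down.forward(x) if self.down else x
        out = self.r1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.r2.forward(self.bn2.forward(self.conv2.forward(out)))
        out = self.bn3.forward(self.conv3.forward(out))
        return self.r3.forward(out + identity)

    def backward(self, dy):
        d = self.r3.backward(dy)
        dmain = self.bn3.backward(d)
        dmain = self.conv3.backward(dmain)
        dmain = self.r2.backward(dmain)
        dmain = self.conv2.backward(self.bn2.backward(dmain))
        dmain = self.r1.backward(dmain)
        dmain = self.conv1.backward(self.bn1.backward(dmain))
        dident = self.down.backward(d) if self.down else d
        return dmain + dident


class LeadBackbone(nn.Module):
    """Shared single-lead encoder: residual CNN -> global average pool ->
    linear projection to the token dimension.

    The feature map entering the pooling stage (output of the last residual
    block) and its gradient are retained after each forward/backward pass —
    they are the activations Grad-CAM needs.
    """

    def __init__(self, kind: str, embed_dim: int, *, rng):
        super().__init__()
        self.kind = kind
        if kind == "resnet_tiny_1d":
            self.stem = self.add_child("stem", nn.Sequential(
                nn.Conv1d(1, 8, 7, 4, rng=rng), nn.BatchNorm1d(8), nn.ReLU()))
            blocks = [_BasicBlock(8, 16, 2, rng=rng), _BasicBlock(16, 32, 2, rng=rng)]
            feat_dim = 32
        elif kind == "resnet50_1d":
            self.stem = self.add_child("stem", nn.Sequential(
                nn.Conv1d(1, 64, 7, 2, rng=rng), nn.BatchNorm1d(64), nn.ReLU(),
                nn.MaxPool1d(3, 2, 1)))
            blocks = []
            c_in = 64
            for planes, n_blocks, stride in ((64, 3, 1), (128, 4, 2),
                                             (256, 6, 2), (512, 3, 2)):
                for b in range(n_blocks):
                    blocks.append(_Bottleneck(c_in, planes, stride if b == 0 else 1, rng=rng))
                    c_in = planes * _Bottleneck.expansion
            feat_dim = c_in
        else:
            raise ValueError(f"unknown backbone {kind!r}")
        self.blocks = self.add_child("blocks", nn.Sequential(*blocks))
        self.proj = self.add_child("proj", nn.Linear(feat_dim, embed_dim, rng=rng))
        self.feat_dim = feat_dim
        self.last_feature: np.ndarray | None = None       # (N, T', C)
        self.last_feature_grad: np.ndarray | None = None

    def forward(self, x):
        """(N, T, 1) -> (N, embed_dim)."""
        feat = self.blocks.forward(self.stem.forward(x))
        self.last_feature = feat
        self._t_feat = feat.shape[1]
        pooled = feat.mean(axis=1)
        return self.proj.forward(pooled)

    def backward(self, dy):
        dpooled = self.proj.backward(dy)
        dfeat = np.broadcast_to(dpooled[:, None, :] / self._t_feat,
                                self.last_feature.shape).astype(np.float32)
        self.last_feature_grad = dfeat
        return self.stem.backward(self.blocks.backward(dfeat))


# -------------------------------------------------------------------------
# full network
# -------------------------------------------------------------------------

class LeadTokenNetwork(nn.Module):
    """Shared lead encoder + class-token transformer + linear head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.backbone = self.add_child("backbone",
                                       LeadBackbone(config.backbone, d, rng=rng))
        self.encoder_layers = [
            self.add_child(f"enc{i}", nn.TransformerEncoderLayer(
                d, config.n_heads, config.ffn_ratio * d, rng=rng))
            for i in range(config.n_encoder_layers)]
        self.final_ln = self.add_child("final_ln", nn.LayerNorm(d))
        self.head = self.add_child("head", nn.Linear(d, config.n_outputs, rng=rng))
        self.add_param("class_token", rng.normal(0, 0.02, size=(d,)))
        # 12 lead-identity vectors (tiled twice in dual mode) + 2 timepoint vectors
        self.add_param("lead_embed", rng.normal(0, 0.02, size=(12, d)))
        self.add_param("timepoint_embed", rng.normal(0, 0.02, size=(2, d)))
        L = config.n_lead_tokens
        self._lead_ids = np.arange(L) % 12
        self._tp_ids = (np.arange(L) >= 12).astype(int)

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, n_lead_tokens, W) windows in mV -> head output
        ((B, 1) log-BNP or (B, 3) logits)."""
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != cfg.n_lead_tokens:
            raise ValueError(
                f"expected (B, {cfg.n_lead_tokens}, W) input, got {x.shape}")
        b, L, w = x.shape
        feats = self.backbone.forward(x.reshape(b * L, w, 1))
        tokens = feats.reshape(b, L, cfg.embed_dim)
        if cfg.lead_embedding:
            tokens = tokens + self.params["lead_embed"][self._lead_ids]
        if cfg.timepoint_embedding and L == 24:
            tokens = tokens + self.params["timepoint_embed"][self._tp_ids]
        cls = np.broadcast_to(self.params["class_token"], (b, 1, cfg.embed_dim))
        seq = np.concatenate([cls, tokens], axis=1).astype(nn.DTYPE)
        for layer in self.encoder_layers:
            seq = layer.forward(seq)
        self._b, self._L, self._w = b, L, w
        return self.head.forward(self.final_ln.forward(seq[:, 0]))

    def backward(self, dout: np.ndarray) -> None:
        cfg = self.config
        b, L = self._b, self._L
        dh = self.final_ln.backward(self.head.backward(dout.astype(nn.DTYPE)))
        dseq = np.zeros((b, L + 1, cfg.embed_dim), dtype=nn.DTYPE)
        dseq[:, 0] = dh
        for layer in reversed(self.encoder_layers):
            dseq = layer.backward(dseq)
        self.grads["class_token"] += dseq[:, 0].sum(axis=0)
        dtok = dseq[:, 1:]
        if cfg.lead_embedding:
            np.add.at(self.grads["lead_embed"], self._lead_ids, dtok.sum(axis=0))
        if cfg.timepoint_embedding and L == 24:
            np.add.at(self.grads["timepoint_embed"], self._tp_ids, dtok.sum(axis=0))
        self.backbone.backward(dtok.reshape(b * L, cfg.embed_dim))

    # -- task-level conveniences -----------------------------------------
    def embed_leads(self, window: np.ndarray) -> np.ndarray:
        """(n_lead_tokens, W) -> token matrix (n_lead_tokens + 1, embed_dim)
        (class token first), before encoder layers."""
        cfg = self.config
        x = np.ascontiguousarray(window[None], dtype=nn.DTYPE)
        if x.shape[1] != cfg.n_lead_tokens:
            raise ValueError(f"expected ({cfg.n_lead_tokens}, W) window, got {window.shape}")
        L, w = x.shape[1], x.shape[2]
        feats = self.backbone.forward(x.reshape(L, w, 1)).reshape(L, cfg.embed_dim)
        if cfg.lead_embedding:
            feats = feats + self.params["lead_embed"][self._lead_ids]
        if cfg.timepoint_embedding and L == 24:
            feats = feats + self.params["timepoint_embed"][self._tp_ids]
        return np.concatenate([self.params["class_token"][None], feats], axis=0)

    def forward_ebt(self, window: np.ndarray) -> float:
        """Single 12-lead window -> predicted log-BNP scalar."""
        if self.config.head != "regression":
            raise ValueError("forward_ebt requires a regression head")
        return float(self.forward(window[None])[0, 0])

    def forward_deht(self, dual_window: np.ndarray) -> np.ndarray:
        """(24, W) dual window -> probability vector over
        (deteriorated, improved, no_change)."""
        if self.config.head != "classification_3":
            raise ValueError("forward_deht requires the 3-class head")
        return F.softmax(self.forward(dual_window[None]))[0]

    def capture_attention(self, layer: int = -1, average_layers: bool = False) -> np.ndarray:
        """Class-token -> lead-token attention from the last forward pass.

        Returns (B, n_lead_tokens) weights: the class-token row of the chosen
        encoder layer (default: final), averaged over heads and renormalized
        to sum to 1 over lead tokens.  ``average_layers`` averages the rows of
        all encoder layers instead.
        """
        if self.encoder_layers[0].mha.last_attn is None:
            raise RuntimeError("capture_attention requires a prior forward pass")
        if average_layers:
            rows = np.mean([lyr.mha.last_attn[:, :, 0, 1:].mean(axis=1)
                            for lyr in self.encoder_layers], axis=0)
        else:
            rows = self.encoder_layers[layer].mha.last_attn[:, :, 0, 1:].mean(axis=1)
        return rows / rows.sum(axis=1, keepdims=True)


def build_model(config: ModelConfig) -> LeadTokenNetwork:
    return LeadTokenNetwork(config)


def save_checkpoint(net: LeadTokenNetwork, path) -> None:
    """Persist weights + configuration as a compressed npz."""
    import dataclasses
    import json

    cfg = json.dumps(dataclasses.asdict(net.config))
    state = net.state_dict()
    np.savez_compressed(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path) -> LeadTokenNetwork:
    import json

    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        net = LeadTokenNetwork(cfg)
        net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net


def init_deht_from_ebt(ebt: LeadTokenNetwork, deht_config: ModelConfig) -> LeadTokenNetwork:
    """Warm-start a dual-ECG classifier from a trained single-ECG regressor:
    backbone, encoder and embedding weights are copied; the classification
    head is freshly initialized."""
    if deht_config.head != "classification_3":
        raise ValueError("deht_config must use the 3-class head")
    ecfg = ebt.config
    if (ecfg.embed_dim, ecfg.backbone, ecfg.n_encoder_layers, ecfg.n_heads) != \
       (deht_config.embed_dim, deht_config.backbone,
            deht_config.n_encoder_layers, deht_config.n_heads):
        raise ValueError("incompatible EBT/DEHT configurations "
                         "(embed_dim, backbone, depth and heads must match)")
    deht = LeadTokenNetwork(replace(deht_config, seed=deht_config.seed))
    state = ebt.state_dict()
    fresh_head = {k: v for k, v in deht.state_dict().items() if k.startswith("head.")}
    state = {k: v for k, v in state.items() if not k.startswith("head.")}
    deht.load_state_dict({**state, **fresh_head})
    return deht
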