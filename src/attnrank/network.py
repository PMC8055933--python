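"""Gated-attention patch classifier for multi-contrast 3D MRI.

The model classifies small multi-contrast patches (lesion vs perilesional
tissue) while producing a per-contrast *attention weight* on the probability
simplex, interpreted as the relative importance of each contrast for the
decision.  Structure:

* one independent convolutional encoder per contrast: three blocks of
  (3x3x3 conv, 16 filters, ELU, batch norm) with 'same' padding, the channel
  dimension collapsed by averaging after the last block so a 5x5x5 patch
  flattens to 125 values, followed by a fully connected layer producing a
  16-dimensional hidden feature ``h_c``;
* a gated attention head: per contrast, ``z_c = enhancement * tanh(V h_c) *
  sigmoid(U h_c)`` with 8-neuron branches, a one-neuron projection of
  ``z_c`` to a logit, and a softmax across contrasts yielding the attention
  weights; the *enhancement* factor (default 2) spreads the small logits of
  highly correlated contrasts before the softmax;
* a classifier: one sigmoid neuron on the attention-weighted sum of the
  hidden features.

All arithmetic is NumPy.  The per-contrast encoders have independent
parameters but are evaluated as *grouped* layers — one batched GEMM per
layer across all contrasts — which is what makes CPU training practical;
see :mod:`attnrank._nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import (
    Linear,
    GroupedLinear,
    GroupedConv3dSame,
    GroupedBatchNorm,
    ELU,
    sigmoid,
)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shift-invariant softmax along ``axis``.

    Because the exponential flattens small differences (e.g. logits 0.01 and
    0.001 map to weights 0.502 and 0.498), the attention head multiplies its
    gated products by an enhancement factor before this step.
    """
    e = np.exp(logits - logits.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the gated-attention network."""

    n_contrasts: int
    patch_size: int = 5
    n_blocks: int = 3
    n_filters: int = 16
    kernel_size: int = 3
    hidden_dim: int = 16
    attn_dim: int = 8
    enhancement: float = 2.0
    #: 'channel_mean' collapses the 16 channels by averaging after the last
    #: block (a 5^3 patch flattens to 125 values); 'flatten' keeps all
    #: channels (16 * 125 = 2000 values).
    collapse: str = "channel_mean"

    def __post_init__(self):
        if self.n_contrasts < 1:
            raise ValueError("n_contrasts must be positive")
        if self.patch_size % 2 != 1 or self.patch_size < 1:
            raise ValueError("patch_size must be an odd positive integer")
        if self.enhancement <= 0:
            raise ValueError("enhancement must be positive")
        if self.collapse not in ("channel_mean", "flatten"):
            raise ValueError("collapse must be 'channel_mean' or 'flatten'")
        for name in ("n_blocks", "n_filters", "kernel_size", "hidden_dim", "attn_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def spatial_size(self) -> int:
        return self.patch_size ** 3

    @property
    def flat_dim(self) -> int:
        """Length of the flattened vector entering the hidden layer."""
        if self.collapse == "channel_mean":
            return self.spatial_size
        return self.spatial_size * self.n_filters


class GatedAttentionNet:
    """Full model: per-contrast encoders, gated attention, sigmoid classifier."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        g = spec.n_contrasts
        shape = (spec.patch_size,) * 3
        self.convs: list[GroupedConv3dSame] = []
        self.elus: list[ELU] = []
        self.bns: list[GroupedBatchNorm] = []
        c_in = 1
        for b in range(spec.n_blocks):
            self.convs.append(GroupedConv3dSame(g, c_in, spec.n_filters, spec.kernel_size,
                                                shape, rng, dtype, need_input_grad=(b > 0)))
            self.elus.append(ELU())
            self.bns.append(GroupedBatchNorm(g, spec.n_filters, dtype))
            c_in = spec.n_filters
        self.fc = GroupedLinear(g, spec.flat_dim, spec.hidden_dim, rng, dtype)
        self.attn_v = Linear(spec.hidden_dim, spec.attn_dim, rng, dtype)   # tanh branch
        self.attn_u = Linear(spec.hidden_dim, spec.attn_dim, rng, dtype)   # sigmoid gate
        self.attn_w = Linear(spec.attn_dim, 1, rng, dtype)                 # logit projection
        self.clf = Linear(spec.hidden_dim, 1, rng, dtype)
        self._cache = None

    # ---------------------------------------------------------------- layers

    def _layers(self) -> dict[str, object]:
        out = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            out[f"conv{i}"] = conv
            out[f"bn{i}"] = bn
        out["fc"] = self.fc
        out["attn_v"] = self.attn_v
        out["attn_u"] = self.attn_u
        out["attn_w"] = self.attn_w
        out["clf"] = self.clf
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p for ln, layer in self._layers().items()
                for pn, p in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": g for ln, layer in self._layers().items()
                for pn, g in layer.grads.items()}

    def zero_grad(self):
        for layer in self._layers().values():
            layer.zero_grad()

    # --------------------------------------------------------------- encoder

    def encode(self, x: np.ndarray, training: bool) -> np.ndarray:
        """x: (N, n_contrasts, S) -> hidden features (N, n_contrasts, hidden)."""
        spec = self.spec
        n = x.shape[0]
        h = np.ascontiguousarray(x.transpose(1, 0, 2))[..., None]  # (G, N, S, 1)
        for conv, elu, bn in zip(self.convs, self.elus, self.bns):
            h = bn.forward(elu.forward(conv.forward(h)), training)
        if spec.collapse == "channel_mean":
            flat = h.mean(axis=3)
        else:
            flat = h.reshape(spec.n_contrasts, n, -1)
        H = self.fc.forward(flat)                                  # (G, N, hidden)
        return np.ascontiguousarray(H.transpose(1, 0, 2))

    def _encoder_backward(self, dH: np.ndarray) -> None:
        spec = self.spec
        d = np.ascontiguousarray(dH.transpose(1, 0, 2))            # (G, N, hidden)
        dflat = self.fc.backward(d)
        if spec.collapse == "channel_mean":
            d = np.repeat(dflat[..., None] / spec.n_filters, spec.n_filters, axis=3)
        else:
            d = dflat.reshape(spec.n_contrasts, -1, spec.spatial_size, spec.n_filters)
        for conv, elu, bn in zip(reversed(self.convs), reversed(self.elus),
                                 reversed(self.bns)):
            d = conv.backward(elu.backward(bn.backward(d)))

    def encode_contrast(self, x: np.ndarray, contrast: int, training: bool = False) -> np.ndarray:
        """Hidden feature of one contrast: x (N, S) -> (N, hidden_dim)."""
        full = np.zeros((x.shape[0], self.spec.n_contrasts, x.shape[1]), dtype=self.dtype)
        full[:, contrast, :] = x
        return self.encode(full, training)[:, contrast, :]

    # --------------------------------------------------------------- forward

    def forward(self, x: np.ndarray, training: bool = False) -> dict:
        """x: (N, n_contrasts, S) -> dict with 'prob', 'attention', 'hidden'.

        Attention weights lie on the simplex (non-negative, sum to one).
        """
        spec = self.spec
        n, c, s = x.shape
        if c != spec.n_contrasts or s != spec.spatial_size:
            raise ValueError(f"expected (N, {spec.n_contrasts}, {spec.spatial_size}), got {x.shape}")
        H = self.encode(x.astype(self.dtype, copy=False), training)  # (N, C, hidden)
        A = np.tanh(self.attn_v.forward(H))                          # (N, C, attn)
        G = sigmoid(self.attn_u.forward(H))
        Z = spec.enhancement * A * G
        logits = self.attn_w.forward(Z)[..., 0]                      # (N, C)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite attention logits (training diverged?)")
        attn = softmax(logits, axis=1)
        fused = np.einsum("nc,nch->nh", attn, H)
        score = self.clf.forward(fused)[:, 0]
        prob = sigmoid(score)
        self._cache = dict(H=H, A=A, G=G, attn=attn)
        return {"prob": prob, "attention": attn, "hidden": H, "score": score}

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, training: bool = True) -> tuple[float, dict]:
        """Mean binary cross-entropy and its gradients (accumulated in-place)."""
        out = self.forward(x, training=training)
        p = out["prob"]
        eps = 1e-7
        pc = np.clip(p, eps, 1.0 - eps)
        loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
        dscore = ((p - y) / len(y)).astype(self.dtype)
        self._backward(dscore)
        return loss, out

    def _backward(self, dscore: np.ndarray) -> None:
        cache = self._cache
        spec = self.spec
        H, A, G, attn = cache["H"], cache["A"], cache["G"], cache["attn"]
        dfused = self.clf.backward(dscore[:, None])                 # (N, hidden)
        dattn = np.einsum("nh,nch->nc", dfused, H)
        dH = attn[..., None] * dfused[:, None, :]
        # softmax backward
        dlogits = attn * (dattn - (attn * dattn).sum(axis=1, keepdims=True))
        dZ = self.attn_w.backward(dlogits[..., None].astype(self.dtype))
        dA = spec.enhancement * G * dZ
        dG = spec.enhancement * A * dZ
        dH += self.attn_v.backward((1.0 - A * A) * dA)
        dH += self.attn_u.backward(G * (1.0 - G) * dG)
        self._encoder_backward(dH.astype(self.dtype, copy=False))

    # ---------------------------------------------------------- convenience

    def predict(self, x: np.ndarray, batch_size: int = 256) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation-mode probabilities and attention weights, batched."""
        probs, attns = [], []
        for i in range(0, len(x), batch_size):
            out = self.forward(x[i:i + batch_size], training=False)
            probs.append(out["prob"])
            attns.append(out["attention"])
        return np.concatenate(probs), np.concatenate(attns)

    # -------------------------------------------------------- serialization

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for ln, layer in self._layers().items():
            if isinstance(layer, GroupedBatchNorm):
                state[f"{ln}.running_mean"] = layer.running_mean.copy()
                state[f"{ln}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[...] = state[k]
        for ln, layer in self._layers().items():
            if isinstance(layer, GroupedBatchNorm):
                layer.running_mean[...] = state[f"{ln}.running_mean"]
                layer.running_var[...] = state[f"{ln}.running_var"]

    def save(self, path) -> None:
        """Checkpoint: npz of parameters plus a JSON sidecar with the spec."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz", **self.state_dict())
        side = path[:-4] if path.endswith(".npz") else path
        with open(side + ".json", "w") as fh:
            json.dump({"spec": asdict(self.spec), "seed": self.seed}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "GatedAttentionNet":
        path = str(path)
        if not path.endswith(".npz"):
            path = path + ".npz"
        with open(path[:-4] + ".json") as fh:
            meta = json.load(fh)
        net = cls(ArchitectureSpec(**meta["spec"]), seed=meta.get("seed", 0))
        with np.load(path) as data:
            net.load_state_dict({k: data[k] for k in data.files})
        return net
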