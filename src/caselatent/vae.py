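"""Mixed-type variational autoencoder over case features.

Architecture: each continuous input is projected to a small embedding by a
one-layer fully connected map with LeakyReLU; the concatenated one-hot
categorical block goes through its own one-layer FC + LeakyReLU; the
embeddings are concatenated and passed through three processing layers of
100 neurons each, from which linear heads produce the posterior mean and
log-variance of a 100-dimensional diagonal-Gaussian latent.  Two two-layer
FC decoders (LeakyReLU hidden) reconstruct the continuous block and
per-field categorical probability groups; the categorical decoder also
emits the benign/serious flag.

Loss = mean-squared error on standardized continuous fields
     + per-group categorical cross-entropy
     + kl_weight * KL(posterior || N(0, I)),
all averaged over the batch.  Training samples the latent via the
reparameterization trick; at inference the posterior mean is used, so
encoding is deterministic — the nearest-neighbour layer relies on that.

The network and its gradients are implemented directly in NumPy; the
analytic gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

_LOGVAR_CLIP = 10.0


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class VaeConfig(BaseModel):
    latent_dim: int = Field(default=100, ge=1)
    processing_layers: int = Field(default=3, ge=1)
    processing_width: int = Field(default=100, ge=1)
    continuous_embed_dim: int = Field(default=8, ge=1)
    categorical_embed_dim: int = Field(default=64, ge=1)
    leaky_relu_slope: float = Field(default=0.01, ge=0.0)
    # beta on the KL term; small by default so the 100-d latent stays
    # informative enough for downstream regression (0 recovers a plain
    # autoencoder, see docs/methods.md)
    kl_weight: float = Field(default=0.05, ge=0.0)
    learning_rate: float = Field(default=1e-3, gt=0.0)
    epochs: int = Field(default=100, ge=1)
    batch_size: int = Field(default=64, ge=1)
    seed: int = 0

    model_config = ConfigDict(frozen=True)


@dataclass(frozen=True)
class FeatureWidths:
    """Input/output widths the network is built against."""

    n_cont_in: int
    cat_in_width: int
    n_cont_out: int
    cat_out_groups: tuple[int, ...]

    @property
    def cat_out_width(self) -> int:
        return int(sum(self.cat_out_groups))


def _lrelu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _lrelu_grad(pre: np.ndarray, slope: float) -> np.ndarray:
    return np.where(pre > 0, 1.0, slope)


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-sample KL(N(mu, diag exp(logvar)) || N(0, I)), summed over dims."""
    return 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=-1)


class MixedVAE:
    """The network, its parameters and its training loop."""

    def __init__(self, config: VaeConfig, widths: FeatureWidths):
        if widths.n_cont_in < 1 or widths.cat_in_width < 1:
            raise ValueError("widths: need at least one continuous and one categorical input")
        if widths.n_cont_out < widths.n_cont_in:
            raise ValueError("widths: decoder must cover at least the encoder's continuous fields")
        self.config = config
        self.widths = widths
        self.loss_trace: list[dict[str, float]] = []
        self._rng = np.random.default_rng(config.seed)
        self.params = self._init_params(self._rng)

    # -- construction -----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg, w = self.config, self.widths
        e, ce = cfg.continuous_embed_dim, cfg.categorical_embed_dim
        width, d = cfg.processing_width, cfg.latent_dim

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        p: dict[str, np.ndarray] = {
            "enc_cont_W": he((w.n_cont_in, 1, e), 1),
            "enc_cont_b": np.zeros((w.n_cont_in, e)),
            "enc_cat_W": he((w.cat_in_width, ce), w.cat_in_width),
            "enc_cat_b": np.zeros(ce),
        }
        fan = w.n_cont_in * e + ce
        for layer in range(cfg.processing_layers):
            p[f"proc_W{layer}"] = he((fan, width), fan)
            p[f"proc_b{layer}"] = np.zeros(width)
            fan = width
        p["mu_W"] = he((width, d), width)
        p["mu_b"] = np.zeros(d)
        p["lv_W"] = he((width, d), width) * 0.1
        p["lv_b"] = np.full(d, -2.0)  # start with small posterior variance
        p["dec_cont_W0"] = he((d, width), d)
        p["dec_cont_b0"] = np.zeros(width)
        p["dec_cont_W1"] = he((width, w.n_cont_out), width)
        p["dec_cont_b1"] = np.zeros(w.n_cont_out)
        p["dec_cat_W0"] = he((d, width), d)
        p["dec_cat_b0"] = np.zeros(width)
        p["dec_cat_W1"] = he((width, w.cat_out_width), width)
        p["dec_cat_b1"] = np.zeros(w.cat_out_width)
        return p

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ----------------------------------------------------------
    def _forward(self, x_cont: np.ndarray, x_cat: np.ndarray, eps: np.ndarray | None):
        p, cfg = self.params, self.config
        slope = cfg.leaky_relu_slope
        cache: dict[str, np.ndarray] = {"x_cont": x_cont, "x_cat": x_cat}

        # per-field continuous embeddings: (B, n_cont, e)
        emb_pre = x_cont[:, :, None] * p["enc_cont_W"][None, :, 0, :] + p["enc_cont_b"][None]
        emb = _lrelu(emb_pre, slope)
        cemb_pre = x_cat @ p["enc_cat_W"] + p["enc_cat_b"]
        cemb = _lrelu(cemb_pre, slope)
        h = np.concatenate([emb.reshape(len(x_cont), -1), cemb], axis=1)
        cache.update(emb_pre=emb_pre, cemb_pre=cemb_pre)

        for layer in range(cfg.processing_layers):
            pre = h @ p[f"proc_W{layer}"] + p[f"proc_b{layer}"]
            cache[f"proc_in{layer}"] = h
            cache[f"proc_pre{layer}"] = pre
            h = _lrelu(pre, slope)
        cache["h_top"] = h

        mu = h @ p["mu_W"] + p["mu_b"]
        lv_raw = h @ p["lv_W"] + p["lv_b"]
        lv = np.clip(lv_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        z = mu if eps is None else mu + np.exp(0.5 * lv) * eps
        cache.update(mu=mu, lv_raw=lv_raw, lv=lv, z=z, eps=eps)

        hc_pre = z @ p["dec_cont_W0"] + p["dec_cont_b0"]
        hc = _lrelu(hc_pre, slope)
        y_cont = hc @ p["dec_cont_W1"] + p["dec_cont_b1"]
        hk_pre = z @ p["dec_cat_W0"] + p["dec_cat_b0"]
        hk = _lrelu(hk_pre, slope)
        logits = hk @ p["dec_cat_W1"] + p["dec_cat_b1"]
        cache.update(hc_pre=hc_pre, hc=hc, hk_pre=hk_pre, hk=hk, y_cont=y_cont, logits=logits)
        return cache

    def _group_slices(self) -> list[slice]:
        slices, start = [], 0
        for g in self.widths.cat_out_groups:
            slices.append(slice(start, start + g))
            start += g
        return slices

    def loss_and_grads(
        self,
        x_cont: np.ndarray,
        x_cat: np.ndarray,
        y_cont_target: np.ndarray,
        y_cat_idx: np.ndarray,
        eps: np.ndarray | None,
    ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
        """Batch loss terms and analytic parameter gradients."""
        p, cfg = self.params, self.config
        slope = cfg.leaky_relu_slope
        B = len(x_cont)
        c = self._forward(x_cont, x_cat, eps)

        diff = c["y_cont"] - y_cont_target
        loss_cont = float(np.sum(diff**2) / B)

        slices = self._group_slices()
        loss_cat = 0.0
        dlogits = np.zeros_like(c["logits"])
        rows = np.arange(B)
        for g, sl in enumerate(slices):
            probs = _softmax(c["logits"][:, sl])
            idx = y_cat_idx[:, g]
            loss_cat += float(-np.sum(np.log(probs[rows, idx] + 1e-12)) / B)
            grad = probs.copy()
            grad[rows, idx] -= 1.0
            dlogits[:, sl] = grad / B

        kl = gaussian_kl(c["mu"], c["lv"])
        loss_kl = float(np.mean(kl))
        total = loss_cont + loss_cat + cfg.kl_weight * loss_kl
        losses = {"total": total, "continuous": loss_cont, "categorical": loss_cat, "kl": loss_kl}
        if not np.isfinite(total):
            raise TrainingDivergedError(f"non-finite loss: {losses}")

        g: dict[str, np.ndarray] = {}
        # decoder, continuous branch
        dy = 2.0 * diff / B
        g["dec_cont_W1"] = c["hc"].T @ dy
        g["dec_cont_b1"] = dy.sum(0)
        dhc = (dy @ p["dec_cont_W1"].T) * _lrelu_grad(c["hc_pre"], slope)
        g["dec_cont_W0"] = c["z"].T @ dhc
        g["dec_cont_b0"] = dhc.sum(0)
        dz = dhc @ p["dec_cont_W0"].T
        # decoder, categorical branch
        g["dec_cat_W1"] = c["hk"].T @ dlogits
        g["dec_cat_b1"] = dlogits.sum(0)
        dhk = (dlogits @ p["dec_cat_W1"].T) * _lrelu_grad(c["hk_pre"], slope)
        g["dec_cat_W0"] = c["z"].T @ dhk
        g["dec_cat_b0"] = dhk.sum(0)
        dz += dhk @ p["dec_cat_W0"].T

        # through the sampling head
        beta = cfg.kl_weight
        dmu = dz + beta * c["mu"] / B
        if c["eps"] is None:
            dlv = beta * 0.5 * (np.exp(c["lv"]) - 1.0) / B
        else:
            dlv = dz * c["eps"] * 0.5 * np.exp(0.5 * c["lv"]) + beta * 0.5 * (np.exp(c["lv"]) - 1.0) / B
        clip_mask = (np.abs(c["lv_raw"]) < _LOGVAR_CLIP).astype(float)
        dlv = dlv * clip_mask
        g["mu_W"] = c["h_top"].T @ dmu
        g["mu_b"] = dmu.sum(0)
        g["lv_W"] = c["h_top"].T @ dlv
        g["lv_b"] = dlv.sum(0)
        dh = dmu @ p["mu_W"].T + dlv @ p["lv_W"].T

        for layer in reversed(range(cfg.processing_layers)):
            dpre = dh * _lrelu_grad(c[f"proc_pre{layer}"], slope)
            g[f"proc_W{layer}"] = c[f"proc_in{layer}"].T @ dpre
            g[f"proc_b{layer}"] = dpre.sum(0)
            dh = dpre @ p[f"proc_W{layer}"].T

        n_emb = self.widths.n_cont_in * cfg.continuous_embed_dim
        demb = dh[:, :n_emb].reshape(B, self.widths.n_cont_in, cfg.continuous_embed_dim)
        demb_pre = demb * _lrelu_grad(c["emb_pre"], slope)
        g["enc_cont_W"] = (c["x_cont"][:, :, None] * demb_pre).sum(0)[:, None, :]
        g["enc_cont_b"] = demb_pre.sum(0)
        dcemb = dh[:, n_emb:] * _lrelu_grad(c["cemb_pre"], slope)
        g["enc_cat_W"] = c["x_cat"].T @ dcemb
        g["enc_cat_b"] = dcemb.sum(0)
        return losses, g

    # -- training ---------------------------------------------------------
    def train(
        self,
        x_cont: np.ndarray,
        x_cat: np.ndarray,
        y_cont: np.ndarray,
        y_cat_idx: np.ndarray,
        epochs: int | None = None,
    ) -> list[dict[str, float]]:
        """Seeded minibatch training; appends to and returns the loss trace."""
        if len(x_cont) == 0:
            raise ValueError("training set is empty")
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        opt = _Adam(self.params, cfg.learning_rate)
        n = len(x_cont)
        for _ in range(epochs):
            order = self._rng.permutation(n)
            sums = {"total": 0.0, "continuous": 0.0, "categorical": 0.0, "kl": 0.0}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                eps = self._rng.standard_normal((len(idx), cfg.latent_dim))
                losses, grads = self.loss_and_grads(
                    x_cont[idx], x_cat[idx], y_cont[idx], y_cat_idx[idx], eps
                )
                opt.step(self.params, grads)
                for k in sums:
                    sums[k] += losses[k]
                n_batches += 1
            self.loss_trace.append({k: v / n_batches for k, v in sums.items()})
        return self.loss_trace

    # -- inference --------------------------------------------------------
    def encode(self, x_cont: np.ndarray, x_cat: np.ndarray) -> np.ndarray:
        """Posterior means — deterministic given weights and input."""
        if x_cont.shape[1] != self.widths.n_cont_in or x_cat.shape[1] != self.widths.cat_in_width:
            raise ValueError(
                f"input widths {x_cont.shape[1]}/{x_cat.shape[1]} do not match "
                f"model widths {self.widths.n_cont_in}/{self.widths.cat_in_width}"
            )
        c = self._forward(x_cont, x_cat, eps=None)
        return c["mu"]

    def decode(self, z: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Latent points -> (continuous block, per-group probability arrays)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"latent width {z.shape[1]} != {self.config.latent_dim}")
        p, slope = self.params, self.config.leaky_relu_slope
        hc = _lrelu(z @ p["dec_cont_W0"] + p["dec_cont_b0"], slope)
        y_cont = hc @ p["dec_cont_W1"] + p["dec_cont_b1"]
        hk = _lrelu(z @ p["dec_cat_W0"] + p["dec_cat_b0"], slope)
        logits = hk @ p["dec_cat_W1"] + p["dec_cat_b1"]
        probs = [_softmax(logits[:, sl]) for sl in self._group_slices()]
        return y_cont, probs

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": self.config.model_dump(),
            "widths": {
                "n_cont_in": self.widths.n_cont_in,
                "cat_in_width": self.widths.cat_in_width,
                "n_cont_out": self.widths.n_cont_out,
                "cat_out_groups": list(self.widths.cat_out_groups),
            },
        }
        np.savez(path, __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "MixedVAE":
        import ast

        data = np.load(path)
        meta = ast.literal_eval(bytes(data["__meta__"]).decode())
        w = meta["widths"]
        model = cls(
            VaeConfig(**meta["config"]),
            FeatureWidths(
                n_cont_in=w["n_cont_in"],
                cat_in_width=w["cat_in_width"],
                n_cont_out=w["n_cont_out"],
                cat_out_groups=tuple(w["cat_out_groups"]),
            ),
        )
        for k in model.params:
            model.params[k] = data[k]
        return model
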