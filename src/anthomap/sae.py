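"""Stacked auto-encoder for deep spectral feature extraction.

A mirror-symmetric sigmoid network p-300-150-h-150-300-p is trained to
reconstruct SNV pixel spectra; the innermost coding layer (h units,
default 13) provides the low-dimensional features used for regression.
Training is greedy layer-wise pretraining of the three constituent
auto-encoders followed by end-to-end fine-tuning of the full stack under
squared reconstruction error, by plain minibatch SGD at a constant
learning rate.

SNV output is unbounded, so inputs are affinely squashed per band into
[0.05, 0.95] before the sigmoid network sees them; the affine map is
estimated on the training matrix and stored with the model so encoding
at prediction time replays it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .types import SpectralMatrix


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40.0, 40.0)))


@dataclass
class BandScaler:
    """Per-band affine squash of SNV spectra into [lo, hi]."""

    mn: np.ndarray
    mx: np.ndarray
    lo: float = 0.05
    hi: float = 0.95

    @classmethod
    def fit(cls, X: np.ndarray, lo: float = 0.05, hi: float = 0.95) -> "BandScaler":
        mn, mx = X.min(axis=0), X.max(axis=0)
        span = np.where(mx - mn < 1e-12, 1.0, mx - mn)
        return cls(mn=mn, mx=mn + span, lo=lo, hi=hi)

    def forward(self, X: np.ndarray) -> np.ndarray:
        t = (X - self.mn) / (self.mx - self.mn)
        return np.clip(self.lo + t * (self.hi - self.lo), 0.001, 0.999)

    def inverse(self, X01: np.ndarray) -> np.ndarray:
        t = (X01 - self.lo) / (self.hi - self.lo)
        return self.mn + t * (self.mx - self.mn)


@dataclass
class SaeModel:
    """Trained stack: weights/offsets for the 6 layers (3 encoding,
    3 decoding), all sigmoid."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler: BandScaler
    loss_path: list[float] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0], *(w.shape[1] for w in self.weights))

    @property
    def h(self) -> int:
        """Latent width = number of deep spectral features."""
        return self.weights[2].shape[1]

    @property
    def p(self) -> int:
        return self.weights[0].shape[0]

    def _forward(self, X01: np.ndarray, n_layers: int) -> np.ndarray:
        a = X01
        for W, b in zip(self.weights[:n_layers], self.biases[:n_layers]):
            a = _sigmoid(a @ W + b)
        return a

    def encode(self, X) -> np.ndarray:
        """Deep features (n, h) for SNV spectra; rows map independently."""
        X = X.values if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.p:
            raise ValueError(f"expected {self.p} bands, got {X.shape[1]}")
        return self._forward(self.scaler.forward(X), 3)

    def reconstruct(self, X) -> np.ndarray:
        """Full-stack reconstruction mapped back to SNV scale."""
        X = X.values if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
        return self.scaler.inverse(self._forward(self.scaler.forward(X), 6))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for i, (W, b) in enumerate(zip(self.weights, self.biases)):
                f.create_dataset(f"W{i}", data=W)
                f.create_dataset(f"b{i}", data=b)
            f.create_dataset("scaler_mn", data=self.scaler.mn)
            f.create_dataset("scaler_mx", data=self.scaler.mx)
            f.attrs["scaler_lo"] = self.scaler.lo
            f.attrs["scaler_hi"] = self.scaler.hi
            f.create_dataset("loss_path", data=np.asarray(self.loss_path))

    @classmethod
    def load(cls, path) -> "SaeModel":
        with h5py.File(path, "r") as f:
            weights = [f[f"W{i}"][()] for i in range(6)]
            biases = [f[f"b{i}"][()] for i in range(6)]
            scaler = BandScaler(
                mn=f["scaler_mn"][()], mx=f["scaler_mx"][()],
                lo=float(f.attrs["scaler_lo"]), hi=float(f.attrs["scaler_hi"]),
            )
            loss_path = list(f["loss_path"][()])
        return cls(weights, biases, scaler, loss_path)


def _init_layer(n_in: int, n_out: int, rng: np.random.Generator):
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out)), np.zeros(n_out)


def _train_epochs(weights, biases, X, epochs, batch, lr, rng) -> list[float]:
    """SGD on squared reconstruction error (summed over output units,
    averaged over the minibatch) through an arbitrary sigmoid stack.
    Mutates weights/biases in place; returns the per-epoch loss path."""
    n = X.shape[0]
    n_layers = len(weights)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, n, batch):
            xb = X[order[s : s + batch]]
            acts = [xb]
            for W, b in zip(weights, biases):
                acts.append(_sigmoid(acts[-1] @ W + b))
            err = acts[-1] - xb
            epoch_loss += float(np.sum(err**2) / xb.shape[0])
            n_batches += 1
            delta = 2.0 * err * acts[-1] * (1.0 - acts[-1])
            for li in range(n_layers - 1, -1, -1):
                gW = acts[li].T @ delta / xb.shape[0]
                gb = delta.mean(axis=0)
                if li > 0:
                    delta = (delta @ weights[li].T) * acts[li] * (1.0 - acts[li])
                weights[li] -= lr * gW
                biases[li] -= lr * gb
        losses.append(epoch_loss / n_batches)
    return losses


def train_sae(
    P,
    h: int = 13,
    epochs: int = 40,
    batch: int = 200,
    lr: float = 0.001,
    seed: int = 0,
    hidden: tuple[int, int] = (300, 150),
    finetune: bool = True,
) -> SaeModel:
    """Train the p-300-150-h-150-300-p stack on SNV pixel spectra.

    ``epochs`` applies both to each greedy pretraining stage and to the
    end-to-end fine-tune. Deterministic given ``seed``.
    """
    X = P.values if isinstance(P, SpectralMatrix) else np.asarray(P, dtype=float)
    p = X.shape[1]
    sizes = (p, *hidden, h)
    for a, b in zip(sizes, sizes[1:]):
        if b >= a:
            raise ValueError(f"layer sizes must strictly contract: {sizes}")
    rng = np.random.default_rng(seed)
    scaler = BandScaler.fit(X)
    X01 = scaler.forward(X)

    # Greedy pretraining with inter-stage code rescaling: each stage's
    # sigmoid code occupies only a narrow slice of (0, 1), so the next
    # auto-encoder would see a nearly constant input and the deep
    # features would collapse. Rescaling each code unit to [0.1, 0.9]
    # before the next stage keeps the signal O(1) per layer; the affine
    # maps are purely bookkeeping and are folded into the stacked
    # weights afterwards, leaving a plain sigmoid stack.
    enc_W, enc_b, dec_W, dec_b = [], [], [], []
    pre_losses = []
    data = X01
    prev_scale = None  # (a, c): code' = a * code + c from the stage below
    for n_in, n_out in zip(sizes, sizes[1:]):
        We, be = _init_layer(n_in, n_out, rng)
        Wd, bd = _init_layer(n_out, n_in, rng)
        w, b = [We, Wd], [be, bd]
        pre_losses.append(_train_epochs(w, b, data, epochs, batch, lr, rng))
        code = _sigmoid(data @ w[0] + b[0])
        if prev_scale is not None:
            # encoder trained on rescaled code from below: fold the
            # affine input map into this layer's weights
            a, c = prev_scale
            b[0] = b[0] + c @ w[0]
            w[0] = a[:, None] * w[0]
            # decoder reconstructs the rescaled code; the decoder layer
            # below expects the raw code, so fold the inverse map there
            dec_W[-1] = dec_W[-1] / a[:, None]
            dec_b[-1] = dec_b[-1] - c @ dec_W[-1]
        enc_W.append(w[0]); enc_b.append(b[0])
        dec_W.append(w[1]); dec_b.append(b[1])
        mn, mx = code.min(axis=0), code.max(axis=0)
        span = np.where(mx - mn < 1e-9, 1.0, mx - mn)
        a = 0.8 / span
        c = 0.1 - mn * a
        prev_scale = (a, c)
        data = code * a + c

    weights = enc_W + dec_W[::-1]
    biases = enc_b + dec_b[::-1]
    loss_path = []
    if finetune:
        loss_path = _train_epochs(weights, biases, X01, epochs, batch, lr, rng)
    return SaeModel(
        weights=weights, biases=biases, scaler=scaler, loss_path=loss_path,
        diagnostics={"pretrain_losses": pre_losses, "epochs": epochs, "batch": batch, "lr": lr},
    )


def sae_encode(model: SaeModel, m) -> np.ndarray:
    """Forward pass through the encoder half only; (n, h) features."""
    return model.encode(m)
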