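"""Character-level sequence variational autoencoder over encoded equations.

Architecture: embedding -> bidirectional LSTM encoder -> dense heads for the
latent mean and log-variance -> reparameterized Gaussian sample -> the latent
vector repeated once per position -> LSTM decoder -> per-position softmax over
the alphabet (pad included).  The decoder is non-autoregressive: position t
conditions only on the latent vector, never on emitted symbols.

Loss = categorical cross-entropy summed over positions (mean over batch)
     + kl_weight * mean-over-batch of the closed-form KL(N(mu, sigma^2) || N(0, 1))
       summed over latent dimensions.

Summing the cross-entropy over positions (the usual sequence-to-sequence
reduction) rather than averaging it is load-bearing: with a per-position mean
and a fixed kl_weight, one nat of latent information can never pay for its KL
cost once sequences are longer than 1/kl_weight symbols, and the posterior
collapses.  A per-position-mean reduction is available via
``recon_reduction="mean"``.  Pads are included in the reconstruction loss by
default (configurable mask).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .corpus import CorpusSplit, EncodedEquation, Vocabulary, decode_sequence
from .errors import ConfigurationError, TrainingDivergedError
from .nn import LSTM, Adam, Dense, Embedding, softmax


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the full-scale reference settings."""

    embedding_dim: int = 500
    latent_dim: int = 350
    hidden_dim: int | None = None  # defaults to embedding_dim
    recurrent_dropout: float = 0.2
    kl_weight: float = 0.1
    learning_rate: float = 1e-5
    epochs: int = 500
    batch_size: int = 25
    mask_pad_loss: bool = False
    recon_reduction: str = "sum"  # "sum" over positions, or "mean"
    grad_clip: float | None = 5.0  # global gradient-norm bound; None disables
    dtype: str = "float64"  # compute dtype; float32 roughly halves step time
    logvar_bias_init: float = 0.0  # negative values start training near-deterministic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.latent_dim < 1:
            raise ConfigurationError("dimensions must be >= 1")
        if self.hidden_dim is not None and self.hidden_dim < 1:
            raise ConfigurationError("hidden_dim must be >= 1")
        if not (0.0 <= self.recurrent_dropout < 1.0):
            raise ConfigurationError("recurrent_dropout must lie in [0, 1)")
        if self.kl_weight < 0:
            raise ConfigurationError("kl_weight must be >= 0")
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epochs must be >= 0 and batch_size >= 1")
        if self.recon_reduction not in ("sum", "mean"):
            raise ConfigurationError("recon_reduction must be 'sum' or 'mean'")
        if self.dtype not in ("float64", "float32"):
            raise ConfigurationError("dtype must be 'float64' or 'float32'")

    @property
    def hidden(self) -> int:
        return self.hidden_dim if self.hidden_dim is not None else self.embedding_dim


def reparameterize(mean: np.ndarray, log_variance: np.ndarray, rng: np.random.Generator):
    """z = mean + exp(log_variance / 2) * eps with eps ~ N(0, I)."""
    eps = rng.standard_normal(mean.shape).astype(mean.dtype, copy=False)
    return mean + np.exp(0.5 * log_variance) * eps, eps


def kl_divergence(mean: np.ndarray, log_variance: np.ndarray) -> float:
    """Closed-form KL to the standard normal, summed over dimensions and
    averaged over the batch."""
    per_item = 0.5 * np.sum(
        mean**2 + np.exp(log_variance) - 1.0 - log_variance, axis=-1
    )
    return float(np.mean(per_item))


class ReactionVAE:
    """The sequence VAE, bound to one vocabulary and one configuration."""

    def __init__(self, config: ModelConfig, vocabulary: Vocabulary) -> None:
        self.config = config
        self.vocab = vocabulary
        self.n_max = vocabulary.n_max
        self.n_symbols = vocabulary.size
        seeds = np.random.SeedSequence(config.seed).spawn(3)
        init_rng = np.random.default_rng(seeds[0])
        self._train_rng = np.random.default_rng(seeds[1])
        self._sample_rng = np.random.default_rng(seeds[2])

        d, h, l = config.embedding_dim, config.hidden, config.latent_dim
        self.embedding = Embedding(self.n_symbols, d, init_rng)
        self.encoder_fw = LSTM(d, h, init_rng)
        self.encoder_bw = LSTM(d, h, init_rng)
        self.fc_mean = Dense(2 * h, l, init_rng)
        self.fc_logvar = Dense(2 * h, l, init_rng)
        # a negative bias makes early training nearly noise-free, which the
        # KL term later relaxes on uninformative dimensions
        self.fc_logvar.params["b"][:] = config.logvar_bias_init
        self.decoder = LSTM(l, h, init_rng)
        self.fc_out = Dense(h, self.n_symbols, init_rng)
        self.layers = [
            self.embedding, self.encoder_fw, self.encoder_bw,
            self.fc_mean, self.fc_logvar, self.decoder, self.fc_out,
        ]
        self._dtype = np.dtype(config.dtype)
        if self._dtype != np.float64:
            for layer in self.layers:
                for name in layer.params:
                    layer.params[name] = layer.params[name].astype(self._dtype)
                layer.zero_grad()

    # ---------------------------------------------------------------- forward

    def _check_codes(self, codes: np.ndarray) -> np.ndarray:
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        if codes.shape[1] != self.n_max:
            raise ConfigurationError(
                f"input length {codes.shape[1]} != n_max {self.n_max}"
            )
        return codes

    def encode(self, codes: np.ndarray, dropout_masks=None) -> tuple[np.ndarray, np.ndarray]:
        """Latent mean and log-variance for a batch of code vectors.

        Deterministic unless recurrent dropout masks are supplied (training).
        """
        codes = self._check_codes(codes)
        e = self.embedding.forward(codes)
        m_fw, m_bw, _ = dropout_masks or (None, None, None)
        hs_fw = self.encoder_fw.forward(e, m_fw)
        hs_bw = self.encoder_bw.forward(e[:, ::-1], m_bw)
        enc_h = np.concatenate([hs_fw[:, -1], hs_bw[:, -1]], axis=1)
        mean = self.fc_mean.forward(enc_h)
        log_variance = self.fc_logvar.forward(enc_h)
        return mean, log_variance

    def decode(self, z: np.ndarray, dropout_masks=None) -> np.ndarray:
        """Per-position symbol probabilities (batch, n_max, n_symbols)."""
        z = np.atleast_2d(np.asarray(z, dtype=self._dtype))
        if z.shape[1] != self.config.latent_dim:
            raise ConfigurationError(
                f"latent size {z.shape[1]} != latent_dim {self.config.latent_dim}"
            )
        z_rep = np.repeat(z[:, None, :], self.n_max, axis=1)  # RepeatVector
        m_dec = dropout_masks[2] if dropout_masks else None
        hs = self.decoder.forward(z_rep, m_dec)
        logits = self.fc_out.forward(hs)
        return softmax(logits)

    def greedy_decode(self, z: np.ndarray) -> list[str]:
        """Argmax string per latent point (temperature-free decoding rule)."""
        probs = self.decode(z)
        return [decode_sequence(row.argmax(axis=-1), self.vocab) for row in probs]

    def sample_decode(self, z: np.ndarray, temperature: float, rng) -> list[str]:
        """Temperature sampling alternative to greedy decoding."""
        probs = self.decode(z)
        logits = np.log(np.clip(probs, 1e-12, None)) / temperature
        p = softmax(logits)
        out = []
        for row in p:
            codes = [rng.choice(self.n_symbols, p=pos) for pos in row]
            out.append(decode_sequence(np.array(codes), self.vocab))
        return out

    # ------------------------------------------------------------------ loss

    def loss_components(
        self, codes: np.ndarray, probs: np.ndarray, mean: np.ndarray, logvar: np.ndarray
    ) -> tuple[float, float, float]:
        """(total, reconstruction, kl) for already-computed outputs."""
        codes = self._check_codes(codes)
        weights, denom = self._loss_weights(codes)
        idx = (np.arange(codes.shape[0])[:, None], np.arange(codes.shape[1])[None, :], codes)
        logp = np.log(np.clip(probs[idx], 1e-12, None))
        recon = float(-(logp * weights).sum() / denom)
        kl = kl_divergence(mean, logvar)
        return recon + self.config.kl_weight * kl, recon, kl

    def _loss_weights(self, codes: np.ndarray) -> tuple[np.ndarray, float]:
        """Per-position loss weights and the normalizing denominator."""
        B, T = codes.shape
        if self.config.mask_pad_loss:
            weights = (codes != self.vocab.pad_code).astype(float)
        else:
            weights = np.ones((B, T))
        denom = float(B) if self.config.recon_reduction == "sum" else max(weights.sum(), 1.0)
        return weights, denom

    # -------------------------------------------------------------- training

    def _make_masks(self, batch_size: int, rng: np.random.Generator):
        p = self.config.recurrent_dropout
        if p <= 0.0:
            return (None, None, None)
        h = self.config.hidden

        def mask() -> np.ndarray:
            raw = rng.binomial(1, 1.0 - p, size=(batch_size, h)) / (1.0 - p)
            return raw.astype(self._dtype)

        return (mask(), mask(), mask())

    def _train_step(self, codes: np.ndarray, opt: Adam, rng: np.random.Generator):
        cfg = self.config
        B, T = codes.shape
        masks = self._make_masks(B, rng)
        mean, logvar = self.encode(codes, dropout_masks=masks)
        z, eps = reparameterize(mean, logvar, rng)
        probs = self.decode(z, dropout_masks=masks)
        total, recon, kl = self.loss_components(codes, probs, mean, logvar)
        if not np.isfinite(total):
            raise TrainingDivergedError(f"non-finite loss {total}")

        # ----- backward -----
        opt.zero_grad()
        idx = (np.arange(B)[:, None], np.arange(T)[None, :], codes)
        weights, denom = self._loss_weights(codes)
        weights = weights.astype(probs.dtype)
        dlogits = probs * weights[:, :, None]
        dlogits[idx] -= weights
        dlogits /= denom
        dhs = self.fc_out.backward(dlogits)
        dz_rep = self.decoder.backward(dhs)
        dz = dz_rep.sum(axis=1)
        dmean = dz.copy()
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * logvar)
        w = cfg.kl_weight / B
        dmean += w * mean
        dlogvar += w * 0.5 * (np.exp(logvar) - 1.0)
        dh = self.fc_mean.backward(dmean) + self.fc_logvar.backward(dlogvar)
        h = cfg.hidden
        de_fw = self.encoder_fw.backward(None, dh_last=dh[:, :h])
        de_bw = self.encoder_bw.backward(None, dh_last=dh[:, h:])
        self.embedding.backward(de_fw + de_bw[:, ::-1])
        opt.step()
        return total, recon, kl

    def fit(self, split: CorpusSplit, progress: bool = False) -> pd.DataFrame:
        """Adam training with seeded shuffling; returns per-epoch metrics
        (epoch, total, recon, kl, val_accuracy)."""
        cfg = self.config
        if not split.train:
            raise ConfigurationError("empty training split")
        codes_train = np.stack([e.codes for e in split.train])
        opt = Adam(self.layers, cfg.learning_rate, clip_norm=cfg.grad_clip)
        rng = self._train_rng
        records = []
        n = len(codes_train)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            totals, recons, kls = [], [], []
            for start in range(0, n, cfg.batch_size):
                batch = codes_train[order[start : start + cfg.batch_size]]
                t, r, k = self._train_step(batch, opt, rng)
                totals.append(t)
                recons.append(r)
                kls.append(k)
            val_acc = (
                self.reconstruction_accuracy(split.validation)
                if split.validation
                else float("nan")
            )
            records.append(
                (epoch, float(np.mean(totals)), float(np.mean(recons)),
                 float(np.mean(kls)), val_acc)
            )
            if progress:
                print(
                    f"epoch {epoch:4d} total {records[-1][1]:.4f} "
                    f"recon {records[-1][2]:.4f} kl {records[-1][3]:.4f} "
                    f"val_acc {val_acc:.3f}"
                )
        return pd.DataFrame(
            records, columns=["epoch", "total", "recon", "kl", "val_accuracy"]
        )

    def reconstruction_accuracy(self, items: list[EncodedEquation], batch_size: int = 64) -> float:
        """Fraction of items whose greedy decode of the encoded mean equals the
        source string exactly."""
        if not items:
            return float("nan")
        hits = 0
        for start in range(0, len(items), batch_size):
            chunk = items[start : start + batch_size]
            codes = np.stack([e.codes for e in chunk])
            mean, _ = self.encode(codes)
            decoded = self.greedy_decode(mean)
            hits += sum(d == e.source for d, e in zip(decoded, chunk))
        return hits / len(items)

    # ---------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Single self-describing archive: weights + vocabulary + config."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                arrays[f"layer{i}:{name}"] = value
        meta = json.dumps(
            {"config": asdict(self.config), "vocabulary": self.vocab.to_dict()}
        )
        arrays["meta_json"] = np.array(meta)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReactionVAE":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta_json"]))
            model = cls(
                ModelConfig(**meta["config"]), Vocabulary.from_dict(meta["vocabulary"])
            )
            for i, layer in enumerate(model.layers):
                for name in layer.params:
                    layer.params[name] = archive[f"layer{i}:{name}"]
                layer.zero_grad()
        return model
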