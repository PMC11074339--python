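"""SMILES variational autoencoder with GRU encoder and decoder.

The encoder maps a padded token sequence to a Gaussian posterior
(mu_z, sigma_z) in a low-dimensional chemical embedding; the decoder maps
a latent coordinate z back to a token sequence, generated character by
character. Training minimizes token cross-entropy (reconstruction) plus
the KL divergence of the posterior from N(0, I). Sampling the prior and
decoding yields de novo molecules.

Implemented directly over numpy with the package's reverse-mode autodiff
(`polygen._autodiff`), sized for CPU training; every source of randomness
(weight init, reparameterization noise, batch order, multinomial decoding)
flows from the run seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._autodiff import Adam, Tensor, concat, cross_entropy, embedding_lookup
from .corpus import (CuratedMolecule, EncodedSequence, TokenVocabulary,
                     build_vocabulary, curate_record, detokenize,
                     RawCompoundRecord, tokenize)

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class LatentPoint:
    """A point in the chemical embedding: posterior moments and, when
    produced by reparameterization, the sampled coordinate and its noise."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray | None = None
    eps: np.ndarray | None = None


def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """z = mu + eps * exp(logvar / 2), elementwise."""
    mu, logvar, eps = np.asarray(mu), np.asarray(logvar), np.asarray(eps)
    if not (mu.shape == logvar.shape == eps.shape):
        raise ValueError("mu, logvar, eps must share a shape")
    return mu + eps * np.exp(logvar / 2.0)


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL(N(mu, diag e^logvar) || N(0, I)), averaged over rows."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    per_row = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    return float(per_row.mean())


def reconstruction_loss(logits: np.ndarray, targets: np.ndarray,
                        pad_id: int) -> float:
    """Token cross-entropy over non-pad positions, averaged over sequences.

    logits: (B, T, V); targets: (B, T) integer ids.
    """
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    B, T = targets.shape
    nll = -logp[np.arange(B)[:, None], np.arange(T)[None, :], targets]
    mask = (targets != pad_id).astype(float)
    return float((nll * mask).sum() / B)


# ---------------------------------------------------------------------
# GRU primitives (graph-building and plain-numpy variants)
# ---------------------------------------------------------------------

def _gru_step(p: dict, pre: str, x: Tensor, h: Tensor) -> Tensor:
    r = (x.matmul(p[pre + "Wxr"]) + h.matmul(p[pre + "Whr"]) + p[pre + "br"]).sigmoid()
    u = (x.matmul(p[pre + "Wxz"]) + h.matmul(p[pre + "Whz"]) + p[pre + "bz"]).sigmoid()
    n = (x.matmul(p[pre + "Wxn"]) + p[pre + "bxn"]
         + r * (h.matmul(p[pre + "Whn"]) + p[pre + "bhn"])).tanh()
    one = Tensor(1.0)
    return (one - u) * n + u * h


def _gru_step_np(w: dict, pre: str, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    sig = lambda a: 1.0 / (1.0 + np.exp(-a))
    r = sig(x @ w[pre + "Wxr"] + h @ w[pre + "Whr"] + w[pre + "br"])
    u = sig(x @ w[pre + "Wxz"] + h @ w[pre + "Whz"] + w[pre + "bz"])
    n = np.tanh(x @ w[pre + "Wxn"] + w[pre + "bxn"]
                + r * (h @ w[pre + "Whn"] + w[pre + "bhn"]))
    return (1.0 - u) * n + u * h


class SmilesVAE(BaseEstimator):
    """Variational autoencoder over SMILES token sequences.

    Parameters
    ----------
    embed_dim : token embedding width (default 128).
    encoder_hidden, encoder_layers, encoder_dropout : GRU encoder
        (defaults 256 / 1 / 0.2; dropout acts between stacked layers only).
    latent_dim : chemical-embedding dimension (default 128).
    decoder_hidden, decoder_layers, decoder_dropout : GRU decoder
        (defaults 512 / 3 / 0.0).
    max_len : padded sequence length (default 100; content budget max_len-2
        because start/end framing lives inside the window).
    epochs, learning_rate, batch_size, grad_clip : training schedule
        (defaults 200 / 3e-4 / 1024 / 50).
    kl_weight : weight of the KL term (default 1.0).
    kl_warmup_epochs : linear ramp of the KL weight from 0 (default 0 = off).
    seed : master seed for init, noise, batch order and sampling.
    """

    def __init__(self, embed_dim=128, encoder_hidden=256, encoder_layers=1,
                 encoder_dropout=0.2, latent_dim=128, decoder_hidden=512,
                 decoder_layers=3, decoder_dropout=0.0, max_len=100,
                 epochs=200, learning_rate=3e-4, batch_size=1024,
                 grad_clip=50.0, kl_weight=1.0, kl_warmup_epochs=0,
                 lr_decay=1.0, seed=0):
        self.embed_dim = embed_dim
        self.encoder_hidden = encoder_hidden
        self.encoder_layers = encoder_layers
        self.encoder_dropout = encoder_dropout
        self.latent_dim = latent_dim
        self.decoder_hidden = decoder_hidden
        self.decoder_layers = decoder_layers
        self.decoder_dropout = decoder_dropout
        self.max_len = max_len
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.grad_clip = grad_clip
        self.kl_weight = kl_weight
        self.kl_warmup_epochs = kl_warmup_epochs
        self.lr_decay = lr_decay
        self.seed = seed

    # ---- parameter initialisation -----------------------------------
    def _init_params(self, vocab_size: int, rng: np.random.Generator) -> dict:
        p: dict[str, Tensor] = {}

        def u(shape, k):
            return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)

        p["emb"] = Tensor(rng.standard_normal((vocab_size, self.embed_dim)) * 0.1,
                          requires_grad=True)
        # encoder GRU stack
        for layer in range(self.encoder_layers):
            din = self.embed_dim if layer == 0 else self.encoder_hidden
            H = self.encoder_hidden
            k = 1.0 / np.sqrt(H)
            pre = f"enc{layer}_"
            for gate in ("r", "z", "n"):
                p[pre + f"Wx{gate}"] = u((din, H), k)
                p[pre + f"Wh{gate}"] = u((H, H), k)
            p[pre + "br"] = u((1, H), k)
            p[pre + "bz"] = u((1, H), k)
            p[pre + "bxn"] = u((1, H), k)
            p[pre + "bhn"] = u((1, H), k)
        k = 1.0 / np.sqrt(self.encoder_hidden)
        p["W_mu"] = u((self.encoder_hidden, self.latent_dim), k)
        p["b_mu"] = u((1, self.latent_dim), k)
        p["W_lv"] = u((self.encoder_hidden, self.latent_dim), k)
        p["b_lv"] = u((1, self.latent_dim), k)
        # latent -> decoder initial hidden state (shared across layers)
        k = 1.0 / np.sqrt(self.latent_dim)
        p["W_init"] = u((self.latent_dim, self.decoder_hidden), k)
        p["b_init"] = u((1, self.decoder_hidden), k)
        # decoder GRU stack; layer-0 input is [token embedding, z]
        for layer in range(self.decoder_layers):
            din = (self.embed_dim + self.latent_dim if layer == 0
                   else self.decoder_hidden)
            H = self.decoder_hidden
            k = 1.0 / np.sqrt(H)
            pre = f"dec{layer}_"
            for gate in ("r", "z", "n"):
                p[pre + f"Wx{gate}"] = u((din, H), k)
                p[pre + f"Wh{gate}"] = u((H, H), k)
            p[pre + "br"] = u((1, H), k)
            p[pre + "bz"] = u((1, H), k)
            p[pre + "bxn"] = u((1, H), k)
            p[pre + "bhn"] = u((1, H), k)
        k = 1.0 / np.sqrt(self.decoder_hidden)
        p["W_out"] = u((self.decoder_hidden, vocab_size), k)
        p["b_out"] = u((1, vocab_size), k)
        return p

    @property
    def _weights(self) -> dict:
        return {k: t.data for k, t in self.params_.items()}

    # ---- data preparation -------------------------------------------
    def _prepare(self, molecules) -> tuple[np.ndarray, np.ndarray]:
        seqs, lengths = [], []
        for m in molecules:
            mol = m if isinstance(m, CuratedMolecule) else self._curate(m)
            enc = tokenize(mol, self.vocab_, self.max_len)
            ids = np.array(enc.token_ids, dtype=np.int64)
            seqs.append(ids)
            lengths.append(int(np.argmax(ids == self.vocab_.end_id)) + 1)
        return np.stack(seqs), np.array(lengths)

    @staticmethod
    def _curate(smiles: str) -> CuratedMolecule:
        out = curate_record(RawCompoundRecord(smiles))
        if not isinstance(out, CuratedMolecule):
            raise ValueError(f"SMILES failed curation: {smiles!r} ({out.reason})")
        return out

    # ---- training ----------------------------------------------------
    def fit(self, molecules, y=None):
        """Train on a curated corpus (CuratedMolecule or SMILES strings)."""
        molecules = list(molecules)
        if not molecules:
            raise ValueError("empty training corpus")
        curated = [m if isinstance(m, CuratedMolecule) else self._curate(m)
                   for m in molecules]
        self.vocab_ = build_vocabulary(curated)
        self._rng = np.random.default_rng(self.seed)
        self.params_ = self._init_params(self.vocab_.size, self._rng)
        self._opt = Adam(self.params_, lr=self.learning_rate,
                         grad_clip=self.grad_clip)
        self.loss_trace_ = []
        self._run_epochs(curated, self.epochs, self.batch_size,
                         warmup=self.kl_warmup_epochs)
        return self

    def fine_tune(self, molecules, epochs: int = 2, batch_size: int = 512):
        """Additional training from the current weights (same objective)."""
        self._check_fitted()
        curated = [m if isinstance(m, CuratedMolecule) else self._curate(m)
                   for m in molecules]
        if epochs > 0:
            self._run_epochs(curated, epochs, batch_size, warmup=0)
        return self

    def _run_epochs(self, curated, epochs, batch_size, warmup):
        seqs, lengths = self._prepare(curated)
        n = len(seqs)
        for epoch in range(epochs):
            kw = self.kl_weight
            if warmup:
                kw *= min(1.0, (epoch + 1) / warmup)
            order = self._rng.permutation(n)
            tot_recon = tot_kl = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                recon, kl = self._train_batch(seqs[idx], lengths[idx], kw)
                tot_recon += recon * len(idx)
                tot_kl += kl * len(idx)
            self.loss_trace_.append({"recon": tot_recon / n, "kl": tot_kl / n,
                                     "total": (tot_recon + self.kl_weight * tot_kl) / n,
                                     "kl_weight": kw})
            self._opt.lr *= self.lr_decay

    def _train_batch(self, seqs: np.ndarray, lengths: np.ndarray,
                     kl_weight: float) -> tuple[float, float]:
        p = self.params_
        B = len(seqs)
        T = int(lengths.max())
        # encoder with hidden-state freezing past each sequence's end token
        h = [Tensor(np.zeros((B, self.encoder_hidden)))
             for _ in range(self.encoder_layers)]
        for t in range(T):
            x = embedding_lookup(p["emb"], seqs[:, t])
            m = Tensor((t < lengths).astype(float)[:, None])
            keep = Tensor(1.0) - m
            for layer in range(self.encoder_layers):
                hn = _gru_step(p, f"enc{layer}_", x, h[layer])
                h[layer] = m * hn + keep * h[layer]
                x = h[layer]
                if (layer < self.encoder_layers - 1 and self.encoder_dropout > 0):
                    mask = (self._rng.random(x.shape) >= self.encoder_dropout)
                    x = x * Tensor(mask / (1.0 - self.encoder_dropout))
        mu = h[-1].matmul(p["W_mu"]) + p["b_mu"]
        logvar = h[-1].matmul(p["W_lv"]) + p["b_lv"]
        eps = self._rng.standard_normal((B, self.latent_dim))
        z = mu + Tensor(eps) * (logvar * Tensor(0.5)).exp()
        # KL(q || N(0,I)), mean over the batch
        kl = (Tensor(-0.5 / B)
              * (Tensor(1.0) + logvar - mu.square() - logvar.exp()).sum())
        # decoder: teacher forcing, loss masked beyond the end token
        hd = []
        h0 = z.matmul(p["W_init"]) + p["b_init"]
        for _ in range(self.decoder_layers):
            hd.append(h0)
        ce_terms = []
        for t in range(T - 1):
            x = concat([embedding_lookup(p["emb"], seqs[:, t]), z])
            for layer in range(self.decoder_layers):
                hd[layer] = _gru_step(p, f"dec{layer}_", x, hd[layer])
                x = hd[layer]
                if (layer < self.decoder_layers - 1 and self.decoder_dropout > 0):
                    mask = (self._rng.random(x.shape) >= self.decoder_dropout)
                    x = x * Tensor(mask / (1.0 - self.decoder_dropout))
            logits = x.matmul(p["W_out"]) + p["b_out"]
            targets = seqs[:, t + 1]
            weights = (targets != self.vocab_.pad_id).astype(float)
            if weights.any():
                ce_terms.append(cross_entropy(logits, targets, weights))
        recon = Tensor(1.0 / B) * ce_terms[0]
        for term in ce_terms[1:]:
            recon = recon + Tensor(1.0 / B) * term
        loss = recon + Tensor(kl_weight) * kl
        self._opt.zero_grad()
        loss.backward()
        self._opt.step()
        return float(recon.data), float(kl.data)

    # ---- inference (plain numpy, evaluation mode) --------------------
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("SmilesVAE is not fitted")

    def _encode_ids(self, seqs: np.ndarray, lengths: np.ndarray):
        w = self._weights
        B = len(seqs)
        h = [np.zeros((B, self.encoder_hidden)) for _ in range(self.encoder_layers)]
        for t in range(int(lengths.max())):
            x = w["emb"][seqs[:, t]]
            m = (t < lengths).astype(float)[:, None]
            for layer in range(self.encoder_layers):
                hn = _gru_step_np(w, f"enc{layer}_", x, h[layer])
                h[layer] = m * hn + (1.0 - m) * h[layer]
                x = h[layer]
        mu = h[-1] @ w["W_mu"] + w["b_mu"]
        logvar = h[-1] @ w["W_lv"] + w["b_lv"]
        return mu, logvar

    def encode(self, molecule) -> LatentPoint:
        """Posterior moments (mu, logvar) for one molecule, evaluation mode."""
        self._check_fitted()
        mol = (molecule if isinstance(molecule, CuratedMolecule)
               else self._curate(molecule))
        seqs, lengths = self._prepare([mol])
        mu, logvar = self._encode_ids(seqs, lengths)
        return LatentPoint(mu=mu[0], logvar=logvar[0])

    def encode_batch(self, molecules) -> np.ndarray:
        """Matrix of posterior means (n, latent_dim)."""
        self._check_fitted()
        curated = [m if isinstance(m, CuratedMolecule) else self._curate(m)
                   for m in molecules]
        seqs, lengths = self._prepare(curated)
        mu, _ = self._encode_ids(seqs, lengths)
        return mu

    def sample_latent(self, mu: np.ndarray, logvar: np.ndarray,
                      rng: np.random.Generator) -> LatentPoint:
        eps = rng.standard_normal(np.shape(mu))
        return LatentPoint(mu=np.asarray(mu), logvar=np.asarray(logvar),
                           z=reparameterize(mu, logvar, eps), eps=eps)

    def decode(self, z: np.ndarray, mode: str = "argmax",
               max_steps: int | None = None,
               rng: np.random.Generator | None = None):
        """Free-running decode of latent coordinates.

        z: (latent_dim,) or (B, latent_dim). Returns (list of SMILES,
        list of per-step probability arrays). Generation starts from the
        start token (the dummy input of latent-only sampling) and stops
        at the end token or after max_steps characters.
        """
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        w = self._weights
        B = z.shape[0]
        T = max_steps if max_steps is not None else self.max_len - 2
        if mode == "multinomial" and rng is None:
            raise ValueError("multinomial decoding needs an rng")
        h = [z @ w["W_init"] + w["b_init"] for _ in range(self.decoder_layers)]
        token = np.full(B, self.vocab_.start_id, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        out_tokens: list[list[int]] = [[] for _ in range(B)]
        prob_steps: list[list[np.ndarray]] = [[] for _ in range(B)]
        for _ in range(T):
            x = np.concatenate([w["emb"][token], z], axis=1)
            for layer in range(self.decoder_layers):
                h[layer] = _gru_step_np(w, f"dec{layer}_", x, h[layer])
                x = h[layer]
            logits = x @ w["W_out"] + w["b_out"]
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs = e / e.sum(axis=1, keepdims=True)
            if mode == "argmax":
                nxt = probs.argmax(axis=1)
            else:
                cum = probs.cumsum(axis=1)
                draws = rng.random((B, 1))
                nxt = (draws < cum).argmax(axis=1)
            for i in range(B):
                if not done[i]:
                    prob_steps[i].append(probs[i])
                    if nxt[i] == self.vocab_.end_id:
                        done[i] = True
                    else:
                        out_tokens[i].append(int(nxt[i]))
            token = nxt
            if done.all():
                break
        smiles = ["".join(self.vocab_.tokens[t] if t >= 3 else ""
                          for t in toks) for toks in out_tokens]
        return smiles, prob_steps

    def sample_molecules(self, n: int, rng: np.random.Generator,
                         mode: str = "multinomial"):
        """Draw n latents from the N(0, I) prior and decode them.

        Returns (list of (smiles, valid) pairs, validity_rate). Validity
        means the string passes corpus curation. For n == 0 the rate is
        None.
        """
        self._check_fitted()
        if n == 0:
            return [], None
        z = rng.standard_normal((n, self.latent_dim))
        smiles, _ = self.decode(z, mode=mode, rng=rng)
        out = []
        n_valid = 0
        for s in smiles:
            valid = False
            if s:
                valid = isinstance(curate_record(RawCompoundRecord(s)),
                                   CuratedMolecule)
            out.append((s, valid))
            n_valid += valid
        return out, n_valid / n

    def reconstruction_nll(self, molecules) -> float:
        """Teacher-forced reconstruction cross-entropy per molecule,
        evaluation mode (z = posterior mean, no noise)."""
        self._check_fitted()
        curated = [m if isinstance(m, CuratedMolecule) else self._curate(m)
                   for m in molecules]
        seqs, lengths = self._prepare(curated)
        mu, _ = self._encode_ids(seqs, lengths)
        w = self._weights
        B = len(seqs)
        h = [mu @ w["W_init"] + w["b_init"] for _ in range(self.decoder_layers)]
        total = 0.0
        for t in range(int(lengths.max()) - 1):
            x = np.concatenate([w["emb"][seqs[:, t]], mu], axis=1)
            for layer in range(self.decoder_layers):
                h[layer] = _gru_step_np(w, f"dec{layer}_", x, h[layer])
                x = h[layer]
            logits = x @ w["W_out"] + w["b_out"]
            zc = logits - logits.max(axis=1, keepdims=True)
            logp = zc - np.log(np.exp(zc).sum(axis=1, keepdims=True))
            targets = seqs[:, t + 1]
            mask = (targets != self.vocab_.pad_id).astype(float)
            total += float((-logp[np.arange(B), targets] * mask).sum())
        return total / B

    def reconstruct(self, molecule) -> str:
        """decode(encode(m).mu) with argmax decoding."""
        point = self.encode(molecule)
        smiles, _ = self.decode(point.mu)
        return smiles[0]

    # ---- persistence -------------------------------------------------
    def save(self, path) -> None:
        """Versioned checkpoint: weights plus config/vocabulary metadata."""
        self._check_fitted()
        meta = {"schema": CHECKPOINT_SCHEMA,
                "config": self.get_params(),
                "vocab": list(self.vocab_.tokens),
                "loss_trace": self.loss_trace_}
        arrays = {f"param_{k}": t.data for k, t in self.params_.items()}
        with open(path, "wb") as fh:
            np.savez(fh, meta=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "SmilesVAE":
        with open(path, "rb") as fh:
            archive = np.load(io.BytesIO(fh.read()))
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        model = cls(**meta["config"])
        model.vocab_ = TokenVocabulary(tokens=tuple(meta["vocab"]))
        model.params_ = {k[len("param_"):]: Tensor(archive[k], requires_grad=True)
                         for k in archive.files if k.startswith("param_")}
        model.loss_trace_ = meta["loss_trace"]
        model._rng = np.random.default_rng(model.seed)
        model._opt = Adam(model.params_, lr=model.learning_rate,
                          grad_clip=model.grad_clip)
        return model

    def checkpoint_fingerprint(self) -> str:
        """Stable hash of the weights, for provenance records."""
        import hashlib
        h = hashlib.sha256()
        for k in sorted(self.params_):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params_[k].data).tobytes())
        return h.hexdigest()[:16]
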