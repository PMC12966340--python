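"""Variational autoencoder for anomaly scoring of species feature vectors.

A compact numpy implementation: the encoder is a two-hidden-layer tanh MLP
emitting the mean and log-variance of the Gaussian posterior q(z|x); the
decoder mirrors the encoder and emits the reconstruction mean of p(x|z).
Training minimises squared reconstruction error plus the KL divergence of
q(z|x) from the standard-normal prior, by full-batch Adam with the
reparameterisation trick and hand-written gradients.

The architecture is found by a growing search: both hidden layers start at
2 neurons and one neuron is added at a time to whichever layer most
improves the mean reconstruction log-probability, until no candidate
improves beyond a tolerance or a width cap is hit. The latent dimension is
swept from 1 to the feature dimensionality and the best-scoring
configuration wins.

Species whose vectors deviate from the dominant patterns — typically rare
species, provided they are a minority of the list — are reconstructed
poorly and receive low scores; quantile grouping of the scores then feeds
the centroid-labelling classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import StudyConfig, VAEConfig

__all__ = ["VAEModel", "ReconstructionScore", "train_vae",
           "reconstruction_scores", "quantile_groups"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VAEModel:
    encoder_widths: tuple[int, int]
    latent_dim: int
    input_dim: int
    params: dict[str, np.ndarray]
    training_seed: int
    train_score: float          # mean reconstruction log-probability at selection
    log: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReconstructionScore:
    species_name: str
    recon_logprob: float


# ---------------------------------------------------------------------------
# network primitives

def _init_params(rng: np.random.Generator, d_in: int, w1: int, w2: int,
                 dz: int) -> dict[str, np.ndarray]:
    def glorot(fan_in, fan_out):
        s = np.sqrt(2.0 / (fan_in + fan_out))
        return rng.normal(0.0, s, size=(fan_in, fan_out))

    return {
        "W1": glorot(d_in, w1), "b1": np.zeros(w1),
        "W2": glorot(w1, w2), "b2": np.zeros(w2),
        "Wm": glorot(w2, dz), "bm": np.zeros(dz),
        "Wv": glorot(w2, dz), "bv": np.zeros(dz),
        "D1": glorot(dz, w2), "c1": np.zeros(w2),
        "D2": glorot(w2, w1), "c2": np.zeros(w1),
        "D3": glorot(w1, d_in), "c3": np.zeros(d_in),
    }


def _encode(p: dict, X: np.ndarray):
    h1 = np.tanh(X @ p["W1"] + p["b1"])
    h2 = np.tanh(h1 @ p["W2"] + p["b2"])
    mu = h2 @ p["Wm"] + p["bm"]
    logvar = np.clip(h2 @ p["Wv"] + p["bv"], -10.0, 10.0)
    return h1, h2, mu, logvar


def _decode(p: dict, Z: np.ndarray):
    g1 = np.tanh(Z @ p["D1"] + p["c1"])
    g2 = np.tanh(g1 @ p["D2"] + p["c2"])
    xhat = g2 @ p["D3"] + p["c3"]
    return g1, g2, xhat


def _loss_and_grads(p: dict, X: np.ndarray, eps: np.ndarray):
    """Full-batch ELBO-style loss (0.5*SSE reconstruction + KL) and gradients."""
    n = X.shape[0]
    h1, h2, mu, logvar = _encode(p, X)
    sigma = np.exp(0.5 * logvar)
    Z = mu + sigma * eps
    g1, g2, xhat = _decode(p, Z)

    diff = xhat - X
    recon = 0.5 * float((diff ** 2).sum()) / n
    kl = -0.5 * float((1.0 + logvar - mu ** 2 - np.exp(logvar)).sum()) / n
    loss = recon + kl

    g = {}
    # decoder
    d_xhat = diff / n
    g["D3"] = g2.T @ d_xhat
    g["c3"] = d_xhat.sum(0)
    d_g2 = (d_xhat @ p["D3"].T) * (1.0 - g2 ** 2)
    g["D2"] = g1.T @ d_g2
    g["c2"] = d_g2.sum(0)
    d_g1 = (d_g2 @ p["D2"].T) * (1.0 - g1 ** 2)
    g["D1"] = Z.T @ d_g1
    g["c1"] = d_g1.sum(0)
    d_z = d_g1 @ p["D1"].T
    # reparameterised heads + KL terms
    d_mu = d_z + mu / n
    d_logvar = d_z * eps * 0.5 * sigma + 0.5 * (np.exp(logvar) - 1.0) / n
    g["Wm"] = h2.T @ d_mu
    g["bm"] = d_mu.sum(0)
    g["Wv"] = h2.T @ d_logvar
    g["bv"] = d_logvar.sum(0)
    # encoder trunk
    d_h2 = (d_mu @ p["Wm"].T + d_logvar @ p["Wv"].T) * (1.0 - h2 ** 2)
    g["W2"] = h1.T @ d_h2
    g["b2"] = d_h2.sum(0)
    d_h1 = (d_h2 @ p["W2"].T) * (1.0 - h1 ** 2)
    g["W1"] = X.T @ d_h1
    g["b1"] = d_h1.sum(0)
    return loss, g


def _train_once(X: np.ndarray, w1: int, w2: int, dz: int, vc: VAEConfig,
                seed: int) -> dict[str, np.ndarray]:
    """Adam training loop; restarts with halved learning rate on divergence."""
    d_in = X.shape[1]
    lr = vc.learning_rate
    for attempt in range(vc.max_restarts + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        p = _init_params(rng, d_in, w1, w2, dz)
        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(vv) for k, vv in p.items()}
        b1, b2, eps_adam = 0.9, 0.999, 1e-8
        ok = True
        for t in range(1, vc.epochs + 1):
            eps = rng.standard_normal((X.shape[0], dz))
            loss, grads = _loss_and_grads(p, X, eps)
            if not np.isfinite(loss):
                ok = False
                break
            for k in p:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                mhat = m[k] / (1 - b1 ** t)
                vhat = v[k] / (1 - b2 ** t)
                p[k] -= lr * mhat / (np.sqrt(vhat) + eps_adam)
        if ok:
            return p
        lr *= 0.5
    raise RuntimeError("VAE training diverged after all learning-rate restarts")


def _mean_logprob(p: dict, X: np.ndarray, L: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-input mean reconstruction log-probability over L posterior samples."""
    _, _, mu, logvar = _encode(p, X)
    sigma = np.exp(0.5 * logvar)
    eps = rng.standard_normal((L, *mu.shape))
    Z = mu[None] + sigma[None] * eps                      # (L, n, dz)
    _, _, xhat = _decode(p, Z.reshape(-1, Z.shape[-1]))
    xhat = xhat.reshape(L, X.shape[0], X.shape[1])
    sq = ((xhat - X[None]) ** 2).sum(axis=2)              # (L, n)
    logp = -0.5 * X.shape[1] * _LOG2PI - 0.5 * sq
    return logp.mean(axis=0)


# ---------------------------------------------------------------------------
# public operations

def train_vae(X: np.ndarray, cfg: StudyConfig) -> VAEModel:
    """Architecture search (growing widths x latent sweep) + final training.

    Deterministic given ``cfg.seed``. Warns in the model log when the
    species count is under ten times the feature dimensionality, the rule
    of thumb for a stable latent representation.
    """
    vc = cfg.vae
    n, d_in = X.shape
    log: list[str] = []
    if n < 10 * d_in:
        log.append(f"WARNING: only {n} vectors for {d_in} features; "
                   "anomaly separation may be unstable")

    def subseed(dz, w1, w2):
        return int(np.random.SeedSequence([cfg.seed, dz, w1, w2]).generate_state(1)[0]
                   % (2 ** 31))

    def score(p):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7777]))
        return float(_mean_logprob(p, X, vc.eval_samples, rng).mean())

    latent_dims = [dz for dz in vc.latent_dims if dz <= d_in]
    best = None  # (score, dz, widths, params)
    for dz in latent_dims:
        w1, w2 = vc.start_widths
        p = _train_once(X, w1, w2, dz, vc, subseed(dz, w1, w2))
        s = score(p)
        while True:
            cands = []
            if w1 < vc.max_width:
                cands.append((w1 + 1, w2))
            if w2 < vc.max_width:
                cands.append((w1, w2 + 1))
            if not cands:
                break
            trained = [(cw, _train_once(X, cw[0], cw[1], dz, vc,
                                        subseed(dz, *cw))) for cw in cands]
            scored = [(score(cp), cw, cp) for cw, cp in trained]
            cs, cw, cp = max(scored, key=lambda t: t[0])
            if cs > s + vc.grow_tol:
                (w1, w2), p, s = cw, cp, cs
            else:
                break
        log.append(f"latent_dim={dz}: widths=({w1},{w2}) score={s:.4f}")
        if best is None or s > best[0]:
            best = (s, dz, (w1, w2), p)

    s, dz, widths, p = best
    log.append(f"selected latent_dim={dz}, widths={widths}")
    return VAEModel(encoder_widths=widths, latent_dim=dz, input_dim=d_in,
                    params=p, training_seed=cfg.seed, train_score=s, log=log)


def reconstruction_scores(m: VAEModel, X: np.ndarray, L: int = 100,
                          species: list[str] | None = None,
                          seed: int | None = None) -> list[ReconstructionScore]:
    """Mean Gaussian reconstruction log-likelihood per input vector (nats).

    For each vector, L latent samples are drawn from the encoder posterior
    and the identity-covariance Gaussian log-density of the input under
    each decoded mean is averaged. Comparable only within one model.
    """
    if X.shape[1] != m.input_dim:
        raise ValueError("input dimensionality does not match the trained model")
    if seed is None:
        seed = m.training_seed + 1
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))
    vals = _mean_logprob(m.params, X, L, rng)
    if species is None:
        species = [f"v{i}" for i in range(X.shape[0])]
    return [ReconstructionScore(sp, float(v)) for sp, v in zip(species, vals)]


def quantile_groups(scores: list[ReconstructionScore] | np.ndarray,
                    C: int) -> np.ndarray:
    """Partition scores into C quantile groups (group 0 = lowest scores).

    Boundaries are the j/C empirical quantiles (linear interpolation); a
    score tied with a boundary falls in the lower group, so degenerate
    all-equal scores collapse into group 0.
    """
    if len(scores) and isinstance(scores[0], ReconstructionScore):
        vals = np.asarray([s.recon_logprob for s in scores], dtype=float)
    else:
        vals = np.asarray(scores, dtype=float)
    if C < 2:
        raise ValueError("need at least 2 groups")
    if C > len(vals):
        raise ValueError(f"C={C} exceeds the number of scores ({len(vals)})")
    bounds = np.quantile(vals, [j / C for j in range(1, C)])
    return (bounds[None, :] < vals[:, None]).sum(axis=1).astype(int)
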