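"""The two-network multi-species distribution model.

A community model is an ensemble of two feed-forward networks whose
probability-scale predictions are averaged:

* a *shared* network mapping (driver vector, trait vector) -> one logit,
  identical parameters for every species — the rigid component in which
  trait mediation of driver responses lives;
* a *species* network mapping driver vector -> one logit per species — the
  flexible component capturing species-specific direct responses.

    p_s(d) = 1/2 [ sigmoid(shared(d, t_s)) + sigmoid(species(d)_s) ]

Both networks are trained jointly by minimising the class-weighted binary
cross-entropy of the averaged prediction with full-batch Adam and early
stopping on a validation sub-split. Output layers start at zero so an
untrained model predicts 0.5 everywhere.

Skill is measured per species on held-out data by the Matthews correlation
coefficient, the class-imbalance-robust score later used as a reliability
weight in assemblage trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ContingencyTable
from .synthetic import SpeciesTable

__all__ = ["ModelConfig", "MLP", "CommunityModel", "train", "predict", "mcc_from_counts",
           "evaluate_skill"]

_EPS = 1e-7


@dataclass
class ModelConfig:
    """Hyperparameters of one community model (all tunable; sizes chosen for
    desk-scale CPU training)."""

    hidden_shared: tuple[int, ...] = (64, 64)
    hidden_species: tuple[int, ...] = (64, 64)
    learning_rate: float = 0.01
    max_epochs: int = 300
    patience: int = 20
    val_fraction: float = 0.1
    threshold: float = 0.5          # binarisation threshold for skill scoring


class MLP:
    """Minimal dense network: ReLU hidden layers, linear output.

    Hidden layers use He initialisation; the output layer starts at zero so
    the network is exactly 0 before training while gradients still flow.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for i in range(len(sizes) - 1):
            fan_in = sizes[i]
            last = i == len(sizes) - 2
            w = (
                np.zeros((fan_in, sizes[i + 1]))
                if last
                else rng.standard_normal((fan_in, sizes[i + 1])) * np.sqrt(2.0 / max(fan_in, 1))
            )
            self.weights.append(w)
            self.biases.append(np.zeros(sizes[i + 1]))

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if cache is not None:
                cache.append(h)
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
        return h

    def backward(self, d_out: np.ndarray, cache: list) -> list[np.ndarray]:
        """Parameter gradients given dLoss/dOutput; cache from forward()."""
        grads: list[np.ndarray] = []
        d = d_out
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache[i]
            grads.append(d.sum(axis=0))          # bias grad
            grads.append(h_in.T @ d)             # weight grad
            if i > 0:
                d = d @ self.weights[i].T
                # gate by the ReLU that produced h_in
                d = d * (cache[i] > 0)
        grads.reverse()
        return grads

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        k = 0
        for i in range(len(self.weights)):
            self.weights[i] = values[k].copy()
            self.biases[i] = values[k + 1].copy()
            k += 2


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class CommunityModel:
    shared: MLP
    species_net: MLP
    species: list[str]
    trait_matrix: np.ndarray              # (S, T) traits + taxonomy block
    driver_mean: np.ndarray
    driver_std: np.ndarray
    config: ModelConfig
    seed: int
    loss_history: list[float] = field(default_factory=list)

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("NaN driver value passed to the model")
        return (X - self.driver_mean) / self.driver_std

    def logits(self, X: np.ndarray, species_idx: np.ndarray | None = None):
        """Shared and species logits, each (n, S_sel), on raw driver input."""
        Z = self._standardise(X)
        if species_idx is None:
            species_idx = np.arange(len(self.species))
        species_idx = np.asarray(species_idx, dtype=int)
        if species_idx.size and (species_idx.min() < 0 or species_idx.max() >= len(self.species)):
            raise KeyError("unknown species index")
        n, k = len(Z), len(species_idx)
        pairs = np.concatenate(
            [np.repeat(Z, k, axis=0), np.tile(self.trait_matrix[species_idx], (n, 1))], axis=1
        )
        a = self.shared.forward(pairs).reshape(n, k)
        b = self.species_net.forward(Z)[:, species_idx]
        return a, b


def predict(
    model: CommunityModel, X: np.ndarray, species_idx: np.ndarray | None = None
) -> np.ndarray:
    """Averaged-probability prediction, (n, S_sel)."""
    a, b = model.logits(X, species_idx)
    return 0.5 * (expit(a) + expit(b))


def train(
    table: ContingencyTable,
    traits: SpeciesTable | np.ndarray,
    config: ModelConfig | None = None,
    seed: int = 0,
    train_idx: np.ndarray | None = None,
) -> CommunityModel:
    """Fit one community model on the table's (masked) sample x species pairs.

    The loss is the weight-normalised class-weighted binary cross-entropy of
    the averaged prediction, minimised jointly over both networks. Training
    is deterministic for a fixed seed and thread count.
    """
    config = config or ModelConfig()
    if train_idx is None:
        train_idx = np.arange(table.n_samples)
    train_idx = np.asarray(train_idx, dtype=int)
    if isinstance(traits, SpeciesTable):
        order = [traits.species.index(s) for s in table.species]
        trait_matrix = traits.trait_matrix(include_taxonomy=True)[order]
    else:
        trait_matrix = np.asarray(traits, dtype=float)
    if trait_matrix.shape[0] != table.n_species:
        raise ValueError("trait matrix does not match the table's species")

    rng = np.random.default_rng(seed)
    X = table.driver_matrix[train_idx]
    Y = table.response[train_idx]
    M = table.mask[train_idx]
    W = table.weights[train_idx]
    for s, name in enumerate(table.species):
        ys = Y[M[:, s], s]
        if ys.size == 0 or ys.min() == ys.max():
            raise ValueError(f"species {name} has a single class in the training data")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    n, D = Z.shape
    S = table.n_species
    T = trait_matrix.shape[1]

    # validation sub-split at the sample level
    n_val = int(round(n * config.val_fraction))
    perm = rng.permutation(n)
    val_rows, fit_rows = perm[:n_val], perm[n_val:]
    if len(fit_rows) == 0:
        raise ValueError("no samples left to fit after validation split")

    shared = MLP([D + T, *config.hidden_shared, 1], rng)
    species_net = MLP([D, *config.hidden_species, S], rng)
    params = shared.params + species_net.params
    opt = _Adam(params, config.learning_rate)

    def _pairs(rows: np.ndarray):
        zs = Z[rows]
        m = M[rows]
        ri, si = np.nonzero(m)
        Xs = np.concatenate([zs[ri], trait_matrix[si]], axis=1)
        return zs, m, ri, si, Xs, Y[rows][m], W[rows][m]

    zfit, mfit, ri_f, si_f, Xs_f, y_f, w_f = _pairs(fit_rows)
    wsum_f = w_f.sum()
    if len(val_rows):
        zval, mval, ri_v, si_v, Xs_v, y_v, w_v = _pairs(val_rows)
        wsum_v = w_v.sum()

    def _loss_p(p, y, w, wsum):
        p = np.clip(p, _EPS, 1 - _EPS)
        return float(np.sum(w * -(y * np.log(p) + (1 - y) * np.log1p(-p))) / wsum)

    best = [p.copy() for p in params]
    best_val = np.inf
    since_best = 0
    history: list[float] = []
    for _ in range(config.max_epochs):
        cache_a: list = []
        cache_b: list = []
        a = shared.forward(Xs_f, cache_a).ravel()
        b_full = species_net.forward(zfit, cache_b)
        b = b_full[ri_f, si_f]
        pa, pb = expit(a), expit(b)
        p = 0.5 * (pa + pb)
        loss = _loss_p(p, y_f, w_f, wsum_f)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at epoch {len(history)}")
        history.append(loss)

        pc = np.clip(p, _EPS, 1 - _EPS)
        dp = w_f * (pc - y_f) / (pc * (1 - pc)) / wsum_f
        da = dp * 0.5 * pa * (1 - pa)
        db = dp * 0.5 * pb * (1 - pb)
        db_full = np.zeros_like(b_full)
        np.add.at(db_full, (ri_f, si_f), db)
        g_shared = shared.backward(da[:, None], cache_a)
        g_species = species_net.backward(db_full, cache_b)
        opt.step(params, g_shared + g_species)

        if len(val_rows):
            av = shared.forward(Xs_v).ravel()
            bv = species_net.forward(zval)[ri_v, si_v]
            val = _loss_p(0.5 * (expit(av) + expit(bv)), y_v, w_v, wsum_v)
        else:
            val = loss
        if val < best_val - 1e-9:
            best_val = val
            best = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    k = len(shared.params)
    shared.set_params(best[:k])
    species_net.set_params(best[k:])
    return CommunityModel(
        shared=shared,
        species_net=species_net,
        species=list(table.species),
        trait_matrix=trait_matrix,
        driver_mean=mean,
        driver_std=std,
        config=config,
        seed=seed,
        loss_history=history,
    )


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 by convention when any denominator
    factor vanishes."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def evaluate_skill(
    model: CommunityModel,
    table: ContingencyTable,
    test_idx: np.ndarray,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-species confusion counts and MCC on held-out samples."""
    test_idx = np.asarray(test_idx, dtype=int)
    if test_idx.size == 0:
        raise ValueError("empty test set")
    threshold = model.config.threshold if threshold is None else threshold
    p = predict(model, table.driver_matrix[test_idx])
    yhat = p >= threshold
    rows = []
    for s, name in enumerate(table.species):
        m = table.mask[test_idx, s]
        y = table.response[test_idx, s][m].astype(bool)
        h = yhat[m, s]
        tp = int(np.sum(h & y))
        tn = int(np.sum(~h & ~y))
        fp = int(np.sum(h & ~y))
        fn = int(np.sum(~h & y))
        rows.append(
            {
                "species": name,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "mcc": mcc_from_counts(tp, tn, fp, fn),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows)
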