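"""Mutual-information neural estimation (MINE) of representation expressivity.

Expressivity of a layer for a scalar attribute is the mutual information
I(F; A) between the layer's feature vectors F (n x d) and the attribute
A (length n), estimated through the Donsker-Varadhan (DV) variational
lower bound

    I(F; A) >= E_joint[T(f, a)] - log E_marginal[exp(T(f, a))],

tightened over a critic ("statistics network") T trained by stochastic
gradient ascent. Joint expectations are estimated on matched mini-batch
pairs (f_i, a_i); marginal expectations on mismatched pairs (f_i, a_j),
i != j, built from a seeded random derangement so each index is used
exactly once on each side. The gradient of the log-marginal term uses an
exponential moving average of E[exp T] as its denominator, which damps
mini-batch noise; reported bounds always use the raw (non-EMA) estimate.

All estimates are in nats. Estimates can be slightly negative for
independent variables (finite-sample noise); they are reported raw,
never clipped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from ._nn import MLP, Adam

__all__ = [
    "FeatureMatrix",
    "AttributeVector",
    "StatisticsNetConfig",
    "MineTrainConfig",
    "ExpressivityResult",
    "TrainedCritic",
    "make_marginal_pairs",
    "dv_lower_bound",
    "mine_batch_loss",
    "train_statistics_network",
    "expressivity",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """An n x d matrix of per-sample representations from one layer.

    Parameters
    ----------
    values
        Real matrix, one row per sample. All entries must be finite,
        n >= 2, d >= 1.
    sample_ids
        Unique per-row identifiers; defaults to 0..n-1.
    layer_tag
        Optional provenance label (e.g. ``"conv/final"``).
    """

    values: np.ndarray
    sample_ids: Sequence | None = None
    layer_tag: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise ValueError(f"need n >= 2 samples and d >= 1 dims, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")
        if self.sample_ids is None:
            self.sample_ids = list(range(n))
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length does not match n")
            if len(set(self.sample_ids)) != n:
                raise ValueError("sample_ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def zero_variance_columns(self) -> np.ndarray:
        """Boolean mask of (numerically) constant feature columns.

        Flagged for downstream exclusion. The tolerance is relative to the
        column magnitude, so rounding jitter from blocked matrix kernels
        does not mask a genuinely constant column.
        """
        sd = self.values.std(axis=0)
        scale = np.abs(self.values).mean(axis=0) + 1.0
        return sd <= 1e-10 * scale


@dataclass
class AttributeVector:
    """A length-n scalar attribute paired with a FeatureMatrix.

    ``kind`` is ``"continuous"`` (z-scored before estimation when the
    train config asks for standardization) or ``"binary"`` (entries must
    be 0/1 and are passed through unscaled).
    """

    values: np.ndarray
    kind: str = "continuous"
    name: str = "attribute"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size < 2:
            raise ValueError("attribute needs at least 2 entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribute contains non-finite entries")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.values.std() == 0.0:
            raise ValueError("attribute has zero variance; MI undefined/trivial")
        if self.kind == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binary attribute entries must all be 0 or 1")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class StatisticsNetConfig:
    """Architecture of the statistics network T: R^(d+1) -> R.

    The default two-hidden-layer 256/64 ELU network with Xavier
    initialization; ``shallow()`` and ``deep()`` give the ablation
    variants (single 256 layer; 512/256/64).
    """

    hidden_sizes: tuple[int, ...] = (256, 64)
    activation: str = "elu"
    init_scheme: str = "xavier"

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be non-empty positive integers")

    @classmethod
    def shallow(cls) -> "StatisticsNetConfig":
        return cls(hidden_sizes=(256,))

    @classmethod
    def deep(cls) -> "StatisticsNetConfig":
        return cls(hidden_sizes=(512, 256, 64))


@dataclass
class MineTrainConfig:
    """Optimization settings for one MINE fit and the multi-seed protocol."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    max_epochs: int = 200
    ema_decay: float = 0.99
    n_seeds: int = 10
    plateau_patience: int = 20
    standardize_inputs: bool = True
    min_delta: float = 1e-3     # held-out bound must improve by this to reset patience
    val_fraction: float = 0.2   # share of samples held out for early stopping

    def __post_init__(self):
        if not (0.0 < self.ema_decay < 1.0):
            raise ValueError("ema_decay must lie in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (marginal pairs need i != j)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ValueError("learning_rate and max_epochs must be positive")
        if not (0.0 <= self.val_fraction < 0.5):
            raise ValueError("val_fraction must lie in [0, 0.5)")


@dataclass
class ExpressivityResult:
    """Per-(layer, attribute) MI estimate aggregated over seeds, in nats."""

    per_seed_estimates: list[float]
    mean_estimate: float
    std_estimate: float
    attribute_name: str
    layer_tag: str | None
    config_fingerprint: str
    units: str = "nats"
    negative_flag: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def config_fingerprint(net_cfg: StatisticsNetConfig, train_cfg: MineTrainConfig) -> str:
    blob = json.dumps([asdict(net_cfg), asdict(train_cfg)], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Estimator primitives
# ---------------------------------------------------------------------------

def make_marginal_pairs(batch_size: int, rng: np.random.Generator | int | None = None
                        ) -> np.ndarray:
    """Mismatched (feature, attribute) index pairs for the marginal term.

    Returns a (b, 2) integer array of (feature_index, attribute_index)
    pairs forming a derangement: no pair has equal indices and each index
    appears exactly once on each side, so the empirical marginal is the
    product of the two within-batch marginals.

    Without a generator the pairs are the plain cyclic shift
    (0,1), (1,2), ..., (b-1,0); with one, a cyclic shift of a shuffled
    order (still fixed-point-free, uniform over batch orderings).
    """
    b = int(batch_size)
    if b < 2:
        raise ValueError("batch of size < 2 cannot satisfy the i != j constraint")
    if rng is None:
        order = np.arange(b)
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        order = rng.permutation(b)
    return np.column_stack([order, np.roll(order, -1)])


def _check_scores(scores, label) -> np.ndarray:
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if scores.size == 0:
        raise ValueError(f"{label} scores are empty")
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"{label} scores contain non-finite values")
    return scores


def dv_lower_bound(joint_scores, marginal_scores) -> float:
    """Donsker-Varadhan bound: mean(joint) - log-mean-exp(marginal), in nats.

    The log-mean-exp is computed in max-shifted form, so arbitrarily large
    critic scores do not overflow.
    """
    joint = _check_scores(joint_scores, "joint")
    marginal = _check_scores(marginal_scores, "marginal")
    return float(joint.mean() - (logsumexp(marginal) - np.log(marginal.size)))


def mine_batch_loss(joint_scores, marginal_scores, ema_state: float | None,
                    ema_decay: float = 0.99) -> tuple[float, float]:
    """Negative DV bound of one mini-batch plus the updated EMA state.

    The reported loss is always the raw batch value; ``ema_state`` is the
    running mean of exp(marginal scores) whose role is to stabilize the
    gradient denominator of the log-marginal term during training. Pass
    ``None`` on the first batch to initialize it from that batch.
    """
    joint = _check_scores(joint_scores, "joint")
    marginal = _check_scores(marginal_scores, "marginal")
    batch_mean_exp = float(np.exp(logsumexp(marginal) - np.log(marginal.size)))
    if ema_state is None:
        new_ema = batch_mean_exp
    else:
        if ema_state <= 0.0:
            raise ValueError("ema_state must be positive (log of non-positive value)")
        new_ema = ema_decay * ema_state + (1.0 - ema_decay) * batch_mean_exp
    loss = -dv_lower_bound(joint, marginal)
    return loss, new_ema


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedCritic:
    """A fitted statistics network plus the preprocessing baked into it."""

    net: MLP
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    attr_mean: float
    attr_scale: float
    kept_columns: np.ndarray
    fingerprint: str

    def score(self, features: np.ndarray, attributes: np.ndarray) -> np.ndarray:
        """Critic scores T(f, a) for matched rows of raw-scale inputs."""
        f = (np.asarray(features, dtype=np.float64)[:, self.kept_columns]
             - self.feature_mean) / self.feature_scale
        a = (np.asarray(attributes, dtype=np.float64).ravel()
             - self.attr_mean) / self.attr_scale
        x = np.column_stack([f, a])
        return self.net.forward(x, train=False, cache=False).ravel()


def _prepare_inputs(F: FeatureMatrix, A: AttributeVector, standardize: bool):
    if F.n != A.n:
        raise ValueError(f"feature matrix has n={F.n} but attribute has n={A.n}")
    keep = ~F.zero_variance_columns()
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    vals = F.values[:, keep]
    if standardize:
        f_mean = vals.mean(axis=0)
        f_scale = vals.std(axis=0)
        if A.kind == "continuous":
            a_mean, a_scale = float(A.values.mean()), float(A.values.std())
        else:
            a_mean, a_scale = 0.0, 1.0
    else:
        f_mean = np.zeros(vals.shape[1])
        f_scale = np.ones(vals.shape[1])
        a_mean, a_scale = 0.0, 1.0
    X = (vals - f_mean) / f_scale
    a = (A.values - a_mean) / a_scale
    return X, a, f_mean, f_scale, a_mean, a_scale, keep


def _full_data_bound(net: MLP, X: np.ndarray, a: np.ndarray,
                     rng: np.random.Generator) -> float:
    """One full pass: matched pairs for the joint term, a fresh derangement
    of all n samples for the marginal term."""
    joint = net.forward(np.column_stack([X, a]), train=False, cache=False).ravel()
    pairs = make_marginal_pairs(X.shape[0], rng)
    marg = net.forward(np.column_stack([X[pairs[:, 0]], a[pairs[:, 1]]]),
                       train=False, cache=False).ravel()
    return dv_lower_bound(joint, marg)


def train_statistics_network(F: FeatureMatrix, A: AttributeVector,
                             net_cfg: StatisticsNetConfig | None = None,
                             train_cfg: MineTrainConfig | None = None,
                             seed: int = 0) -> tuple[TrainedCritic, float]:
    """Fit one statistics network by mini-batch ascent on the DV bound.

    Each epoch shuffles the optimization samples, scores matched pairs
    and derangement-mismatched pairs per mini-batch, and takes an Adam
    step on the EMA-corrected negative-bound gradient. A held-out
    fraction of the samples (``val_fraction``) never enters the gradient:
    after every epoch the DV bound is evaluated on it, and training stops
    at ``max_epochs`` or once that held-out bound has not improved by
    ``min_delta`` for ``plateau_patience`` epochs. Without the hold-out
    the critic's memorization of matched pairs inflates the bound on
    exactly the samples it was fitted to, which would report spurious MI
    for independent high-dimensional inputs.

    The returned ``final_bound`` is a fresh evaluation on the FULL
    dataset (new derangement) at the best-held-out-bound parameters —
    never a mini-batch value. Deterministic given (seed, data, configs).
    """
    net_cfg = net_cfg or StatisticsNetConfig()
    train_cfg = train_cfg or MineTrainConfig()
    X, a, f_mean, f_scale, a_mean, a_scale, keep = _prepare_inputs(
        F, A, train_cfg.standardize_inputs)
    n, d = X.shape
    b = train_cfg.batch_size

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51E]))
    n_val = int(round(train_cfg.val_fraction * n))
    if n_val >= 2 and n - n_val >= b:
        split = rng.permutation(n)
        val_idx, opt_idx = split[:n_val], split[n_val:]
    else:  # too few samples to hold out; stop on the optimization bound
        val_idx = opt_idx = np.arange(n)
        rng.permutation(n)  # keep the stream aligned across branches
    n_opt = opt_idx.size
    if b > n_opt:
        raise ValueError(
            f"batch_size {b} exceeds the {n_opt} optimization samples; "
            "lower batch_size")
    X_val, a_val = X[val_idx], a[val_idx]

    net = MLP(rng, d + 1, net_cfg.hidden_sizes, 1,
              activation=net_cfg.activation, init=net_cfg.init_scheme)
    opt = Adam(net.params(), lr=train_cfg.learning_rate)

    log_ema = None
    log_decay = np.log(train_cfg.ema_decay)
    log_one_minus = np.log1p(-train_cfg.ema_decay)

    best_bound = -np.inf
    best_state = net.state()
    stale = 0
    for _epoch in range(train_cfg.max_epochs):
        perm = opt_idx[rng.permutation(n_opt)]
        for start in range(0, n_opt - 1, b):
            idx = perm[start:start + b]
            bs = idx.size
            if bs < 2:
                break
            pairs = make_marginal_pairs(bs, rng)
            x_joint = np.column_stack([X[idx], a[idx]])
            x_marg = np.column_stack([X[idx[pairs[:, 0]]], a[idx[pairs[:, 1]]]])
            scores = net.forward(np.vstack([x_joint, x_marg]), train=True)
            s_joint = scores[:bs, 0]
            s_marg = scores[bs:, 0]

            # EMA of E[exp T] kept in log space for overflow safety
            batch_lme = logsumexp(s_marg) - np.log(bs)
            if log_ema is None:
                log_ema = batch_lme
            else:
                log_ema = np.logaddexp(log_decay + log_ema,
                                       log_one_minus + batch_lme)

            # d(-DV)/ds: -1/b on joint scores; exp(s - log_ema)/b on marginal
            gout = np.empty((2 * bs, 1))
            gout[:bs, 0] = -1.0 / bs
            gout[bs:, 0] = np.exp(s_marg - log_ema) / bs
            opt.zero_grad()
            net.backward(gout)
            opt.step()

        bound = _full_data_bound(net, X_val, a_val, rng)
        if bound > best_bound + train_cfg.min_delta:
            best_bound = bound
            best_state = net.state()
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.plateau_patience:
                break

    net.load_state(best_state)
    final_bound = _full_data_bound(net, X, a, rng)
    critic = TrainedCritic(net=net, feature_mean=f_mean, feature_scale=f_scale,
                           attr_mean=a_mean, attr_scale=a_scale, kept_columns=keep,
                           fingerprint=config_fingerprint(net_cfg, train_cfg))
    return critic, float(final_bound)


def expressivity(F: FeatureMatrix, A: AttributeVector,
                 net_cfg: StatisticsNetConfig | None = None,
                 train_cfg: MineTrainConfig | None = None,
                 base_seed: int = 0) -> ExpressivityResult:
    """Multi-seed expressivity: M independent MINE fits, averaged.

    Runs ``train_statistics_network`` with seeds base_seed .. base_seed+M-1
    and reports the per-seed final bounds, their mean and standard
    deviation (sample sd over seeds; 0 when M=1). Negative means are
    reported raw with ``negative_flag`` set, never truncated.
    """
    net_cfg = net_cfg or StatisticsNetConfig()
    train_cfg = train_cfg or MineTrainConfig()
    estimates = []
    for s in range(train_cfg.n_seeds):
        _, bound = train_statistics_network(F, A, net_cfg, train_cfg,
                                            seed=base_seed + s)
        estimates.append(bound)
    arr = np.array(estimates)
    mean = float(arr.mean())
    std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    neg = mean < 0.0
    if neg:
        warnings.warn(
            f"negative mean expressivity {mean:.4f} nats for "
            f"attribute {A.name!r}: estimator noise around zero MI",
            stacklevel=2)
    return ExpressivityResult(
        per_seed_estimates=[float(e) for e in estimates],
        mean_estimate=mean, std_estimate=std,
        attribute_name=A.name, layer_tag=F.layer_tag,
        config_fingerprint=config_fingerprint(net_cfg, train_cfg),
        negative_flag=neg)
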