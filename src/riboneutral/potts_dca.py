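"""Pairwise-coupling (Potts) generative model and independent-site profile.

The Potts model assigns a sequence ``x`` the energy

    E(x) = - sum_i h_i(x_i) - sum_{i<j} J_ij(x_i, x_j)

and probability ``P(x) proportional to exp(-E(x)/T)``. Fields ``h`` and
couplings ``J`` are fitted by Boltzmann-machine learning so that the model's
one- and two-site marginals match the (reweighted, pseudocount-regularized)
empirical marginals of a reference-projected alignment. Training runs over
the gapped alphabet (q=5); generation elsewhere restricts states to ACGU so
designs are valid fixed-length sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from . import alphabet as ab
from .errors import InputError, TrainingError
from .msa_kit import Msa

__all__ = [
    "PottsModel",
    "MarginalStats",
    "ProfileModel",
    "TrainConfig",
    "TrainReport",
    "empirical_marginals",
    "marginals_from_codes",
    "sequence_weights",
    "train_boltzmann",
    "energy",
    "profile_from_msa",
    "connected_correlations",
    "zero_sum_gauge",
]


# ---------------------------------------------------------------------------
# Model container


@dataclass
class PottsModel:
    """Fields and couplings over L positions and q states.

    ``J`` is stored as a full (L, L, q, q) tensor with the pair-exchange
    symmetry ``J[i, j, a, b] == J[j, i, b, a]`` and zero diagonal blocks.
    """

    h: np.ndarray  # (L, q)
    J: np.ndarray  # (L, L, q, q)
    gauge: str = "zero-sum"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise InputError(f"J shape {self.J.shape} != {(L, L, q, q)}")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def energy(self, seq) -> float:
        return energy(self, seq)

    def save(self, path) -> None:
        """Single-archive serialization: arrays plus JSON metadata."""
        meta = dict(self.meta)
        meta.update(alphabet=ab.STATES[: self.q], gauge=self.gauge)
        np.savez_compressed(path, h=self.h, J=self.J, meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "PottsModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            gauge = meta.pop("gauge", "zero-sum")
            meta.pop("alphabet", None)
            return cls(h=z["h"], J=z["J"], gauge=gauge, meta=meta)


def energy(model: PottsModel, seq) -> float:
    """Potts energy ``E(x) = -sum_i h_i(x_i) - sum_{i<j} J_ij(x_i, x_j)``."""
    x = ab.encode(seq, allow_gap=model.q == ab.Q_GAPPED) if isinstance(seq, str) \
        else np.asarray(seq)
    if x.size != model.L:
        raise InputError(f"sequence length {x.size} != model length {model.L}")
    if np.any(x >= model.q):
        raise InputError("sequence state outside model alphabet")
    idx = np.arange(model.L)
    hterm = model.h[idx, x].sum()
    pairm = model.J[idx[:, None], idx[None, :], x[:, None], x[None, :]]
    return float(-(hterm + 0.5 * pairm.sum()))


def zero_sum_gauge(h: np.ndarray, J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (h, J) transformed to the zero-sum gauge.

    All energy differences E(x) - E(y) are invariant; afterwards every state
    sum of h_i and of J_ij(., b) / J_ij(a, .) vanishes.
    """
    Jm_a = J.mean(axis=2, keepdims=True)   # mean over a
    Jm_b = J.mean(axis=3, keepdims=True)   # mean over b
    Jm = J.mean(axis=(2, 3), keepdims=True)
    J2 = J - Jm_a - Jm_b + Jm
    # shift absorbed into fields: sum over partners of row means
    h2 = h + (Jm_b - Jm)[:, :, :, 0].sum(axis=1)
    h2 = h2 - h2.mean(axis=1, keepdims=True)
    return h2, J2


# ---------------------------------------------------------------------------
# Empirical statistics


@dataclass
class MarginalStats:
    """Weighted single and pairwise frequencies of an alignment."""

    f_i: np.ndarray      # (L, q)
    f_ij: np.ndarray     # (L, L, q, q); diagonal blocks hold diag(f_i)
    M_eff: float
    q: int
    weights: np.ndarray | None = None
    pseudocount: float = 0.0
    identity_threshold: float = 1.0

    @property
    def L(self) -> int:
        return self.f_i.shape[0]

    @property
    def C_ij(self) -> np.ndarray:
        return connected_correlations(self.f_i, self.f_ij)


def connected_correlations(f_i: np.ndarray, f_ij: np.ndarray) -> np.ndarray:
    """C_ij(a,b) = f_ij(a,b) - f_i(a) f_j(b), diagonal blocks zeroed."""
    C = f_ij - np.einsum("ia,jb->ijab", f_i, f_i)
    L = f_i.shape[0]
    C[np.arange(L), np.arange(L)] = 0.0
    return C


def sequence_weights(codes: np.ndarray, identity_threshold: float) -> np.ndarray:
    """1 / (number of rows within fractional identity >= threshold, self included)."""
    n, L = codes.shape
    counts = np.zeros(n)
    for i in range(n):
        ident = (codes == codes[i]).sum(axis=1) / L
        counts[i] = np.count_nonzero(ident >= identity_threshold)
    return 1.0 / counts


def marginals_from_codes(
    codes: np.ndarray,
    q: int,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.0,
) -> MarginalStats:
    """Weighted marginals mixed with the uniform distribution at rate
    ``pseudocount``; pairwise marginals remain exactly consistent with the
    single-site ones."""
    n, L = codes.shape
    if weights is None:
        weights = np.ones(n)
    M_eff = float(weights.sum())
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], codes] = 1.0
    f_i = np.einsum("n,nia->ia", weights, onehot) / M_eff
    f_ij = np.einsum("n,nia,njb->ijab", weights, onehot, onehot) / M_eff
    a = pseudocount
    f_i = (1 - a) * f_i + a / q
    f_ij = (1 - a) * f_ij + a / q**2
    # diagonal blocks: joint of a position with itself is diag(f_i)
    idx = np.arange(L)
    f_ij[idx, idx] = 0.0
    f_ij[idx[:, None], idx[:, None], np.arange(q)[None, :], np.arange(q)[None, :]] = f_i
    return MarginalStats(
        f_i=f_i, f_ij=f_ij, M_eff=M_eff, q=q,
        weights=weights, pseudocount=pseudocount,
    )


def empirical_marginals(
    msa: Msa,
    identity_threshold: float = 0.8,
    pseudocount: float = 0.05,
) -> MarginalStats:
    """Reweighted, pseudocount-regularized marginals of a projected alignment.

    Each row is weighted by the inverse of the number of rows at fractional
    identity >= ``identity_threshold`` (itself included), the standard
    redundancy correction for phylogenetically correlated alignments.
    """
    if not (0 <= pseudocount < 1):
        raise InputError("pseudocount must lie in [0, 1)")
    if not (0 < identity_threshold <= 1):
        raise InputError("identity_threshold must lie in (0, 1]")
    codes = msa.codes
    w = sequence_weights(codes, identity_threshold)
    stats = marginals_from_codes(codes, ab.Q_GAPPED, weights=w, pseudocount=pseudocount)
    stats.identity_threshold = identity_threshold
    return stats


# ---------------------------------------------------------------------------
# Profile model


@dataclass
class ProfileModel:
    """Per-position categorical distribution over ACGU (gap excluded)."""

    probs: np.ndarray  # (L, 4), rows sum to 1

    @property
    def L(self) -> int:
        return self.probs.shape[0]

    def nonref_distribution(self, ref_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Renormalized distribution over non-reference nucleotides.

        Returns ``(dist, eligible)`` where ``dist`` is (L, 4) with the
        reference state zeroed and rows renormalized, and ``eligible`` flags
        positions with nonzero non-reference mass (rows of ineligible
        positions are left as zeros).
        """
        d = self.probs.copy()
        d[np.arange(self.L), ref_codes] = 0.0
        mass = d.sum(axis=1)
        eligible = mass > 0
        d[eligible] /= mass[eligible, None]
        return d, eligible


def profile_from_msa(stats: MarginalStats) -> ProfileModel:
    """Per-position ACGU distribution renormalized from f_i with gaps excluded."""
    f = stats.f_i[:, : ab.Q_RNA].copy()
    mass = f.sum(axis=1)
    if np.any(mass <= 0):
        bad = int(np.flatnonzero(mass <= 0)[0]) + 1
        raise InputError(f"position {bad} has zero non-gap mass")
    return ProfileModel(probs=f / mass[:, None])


# ---------------------------------------------------------------------------
# Boltzmann-machine learning


@njit(cache=True)
def _gibbs_sweeps(chains, h, J, beta, n_sweeps, seed):
    np.random.seed(seed)
    n, L = chains.shape
    q = h.shape[1]
    logp = np.empty(q)
    for _ in range(n_sweeps):
        for c in range(n):
            for i in range(L):
                for a in range(q):
                    e = h[i, a]
                    for j in range(L):
                        if j != i:
                            e += J[i, j, a, chains[c, j]]
                    logp[a] = beta * e
                m = logp.max()
                tot = 0.0
                for a in range(q):
                    logp[a] = np.exp(logp[a] - m)
                    tot += logp[a]
                r = np.random.random() * tot
                acc = 0.0
                pick = q - 1
                for a in range(q):
                    acc += logp[a]
                    if r < acc:
                        pick = a
                        break
                chains[c, i] = pick
    return chains


def gibbs_sample(
    model: PottsModel,
    n: int,
    seed: int,
    burn_in: int = 500,
    thin: int = 10,
    n_chains: int = 50,
    beta: float = 1.0,
) -> np.ndarray:
    """Draw ``n`` sequences from ``P(x) ~ exp(-beta E(x))`` over the full
    q-state space by Gibbs sampling with multiple independent chains."""
    rng = np.random.default_rng(seed)
    n_chains = min(n_chains, n)
    chains = rng.integers(0, model.q, size=(n_chains, model.L)).astype(np.int8)
    _gibbs_sweeps(chains, model.h, model.J, beta, burn_in,
                  int(rng.integers(2**31 - 1)))
    out = np.empty((n, model.L), dtype=np.int8)
    got = 0
    while got < n:
        _gibbs_sweeps(chains, model.h, model.J, beta, thin,
                      int(rng.integers(2**31 - 1)))
        take = min(n_chains, n - got)
        out[got : got + take] = chains[:take]
        got += take
    return out


@dataclass
class TrainConfig:
    """Hyperparameters for Boltzmann-machine learning with persistent chains."""

    learning_rate: float = 0.05
    epochs: int = 200
    n_chains: int = 100
    sweeps_per_epoch: int = 5
    lambda_h: float = 0.01
    lambda_J: float = 0.01
    eval_samples: int = 2000
    eval_thin: int = 5


@dataclass
class TrainReport:
    """Fit diagnostics returned alongside the trained model."""

    pearson_cc: float  # model vs empirical connected correlations
    epochs: int
    f1_rmse: float     # RMSE of single-site marginals
    converged_warning: str | None = None


def train_boltzmann(
    stats: MarginalStats,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> tuple[PottsModel, TrainReport]:
    """Fit a Potts model to empirical marginals by gradient matching.

    Persistent-contrastive-divergence style: a pool of MCMC chains over the
    full q-state space tracks the model distribution; each epoch the chains
    advance a few Gibbs sweeps and the parameters move along
    (empirical - model) one- and two-site frequencies with an L2 penalty.
    The returned model is in the zero-sum gauge; the report carries the
    Pearson correlation between model and empirical connected correlations
    (estimated from a fresh sample of the final model). Bit-for-bit
    reproducible for a fixed (stats, config, seed).
    """
    L, q = stats.L, stats.q
    rng = np.random.default_rng(seed)
    # profile initialization: independent-site fit, couplings at zero
    h = np.log(np.clip(stats.f_i, 1e-8, None))
    h -= h.mean(axis=1, keepdims=True)
    J = np.zeros((L, L, q, q))
    chains = rng.integers(0, q, size=(config.n_chains, L)).astype(np.int8)
    idx = np.arange(L)
    for epoch in range(config.epochs):
        _gibbs_sweeps(chains, h, J, 1.0, config.sweeps_per_epoch,
                      int(rng.integers(2**31 - 1)))
        model_stats = marginals_from_codes(chains, q)
        grad_h = stats.f_i - model_stats.f_i
        grad_J = stats.f_ij - model_stats.f_ij
        grad_J[idx, idx] = 0.0
        if not (np.isfinite(grad_h).all() and np.isfinite(grad_J).all()):
            raise TrainingError(f"non-finite gradient at epoch {epoch}")
        # L2 penalty as multiplicative decay: stable for any lambda
        h = h * max(1.0 - config.learning_rate * config.lambda_h, 0.0) \
            + config.learning_rate * grad_h
        J = J * max(1.0 - config.learning_rate * config.lambda_J, 0.0) \
            + config.learning_rate * grad_J
        # keep exact pair-exchange symmetry
        J = 0.5 * (J + J.transpose(1, 0, 3, 2))
    h, J = zero_sum_gauge(h, J)
    model = PottsModel(
        h=h, J=J, gauge="zero-sum",
        meta={
            "pseudocount": stats.pseudocount,
            "identity_threshold": stats.identity_threshold,
            "lambda_h": config.lambda_h,
            "lambda_J": config.lambda_J,
            "epochs": config.epochs,
            "seed": seed,
        },
    )
    # fit report from a fresh sample of the final model
    sample = gibbs_sample(
        model, config.eval_samples, seed=int(rng.integers(2**31 - 1)),
        burn_in=200, thin=config.eval_thin, n_chains=config.n_chains,
    )
    samp_stats = marginals_from_codes(sample, q)
    C_model = samp_stats.C_ij
    C_emp = stats.C_ij
    mask = ~np.eye(L, dtype=bool)
    cm, ce = C_model[mask].ravel(), C_emp[mask].ravel()
    pearson = float(np.corrcoef(cm, ce)[0, 1])
    f1_rmse = float(np.sqrt(((samp_stats.f_i - stats.f_i) ** 2).mean()))
    warning = None
    if pearson < 0.9:
        warning = f"connected-correlation Pearson {pearson:.3f} below 0.9"
    report = TrainReport(
        pearson_cc=pearson, epochs=config.epochs,
        f1_rmse=f1_rmse, converged_warning=warning,
    )
    return model, report
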