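"""Effective support sizes Omega(L) = exp(S) at fixed mutational distance.

The effective support size of a generative distribution P is exp(S) with S
its Shannon entropy: the effective number of distinct sequences the model
can produce. Here every distribution is conditioned on the exact-distance
shell ``d(x, ref) = L``. Three estimators are provided, from exact to
stochastic:

* closed forms and a distance-resolved dynamic program for unit-independent
  models (uniform mutagenesis, profile, base-pair replacement);
* exhaustive enumeration on toy problems (the oracle);
* thermodynamic integration over inverse temperature for coupled models,
  where ``ln Z(beta) = ln|shell| - integral_0^beta <E> dbeta'`` and
  ``S = beta <E>_beta + ln Z(beta)``.

A screen-measured active fraction at the largest validated distance turns
the curve into a lower bound on the neutral-set size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import alphabet as ab
from .errors import InputError
from .msa_kit import ReferenceSequence
from .potts_dca import PottsModel, ProfileModel
from .rna_structure import SecondaryStructure
from .samplers import _shell_mcmc

__all__ = [
    "SupportCurve",
    "TIConfig",
    "UnitSystem",
    "shell_log_size",
    "ball_log_size",
    "shell_log_size_nats",
    "unit_dp_entropy",
    "ti_entropy",
    "exact_entropy_enum",
    "neutral_set_lower_bound",
    "scaling_fit",
    "uniform_units",
    "profile_units",
    "bpr_units",
]

LN10 = math.log(10.0)


def _log10_bigint(n: int) -> float:
    """log10 of an arbitrarily large positive integer, exactly enough."""
    if n <= 0:
        raise InputError("log10 of non-positive integer")
    s = str(n)
    head = int(s[:15])
    return (len(s) - 1) + math.log10(head / 10 ** (len(s[:15]) - 1))


def shell_log_size(L_ref: int, L: int, alternatives: int = 3) -> float:
    """log10 of the shell cardinality C(L_ref, L) * alternatives^L,
    computed with exact big-integer arithmetic."""
    if not (0 <= L <= L_ref):
        raise InputError(f"L={L} outside 0..{L_ref}")
    n = math.comb(L_ref, L) * alternatives**L
    return _log10_bigint(n)


def ball_log_size(L_ref: int, L: int, alternatives: int = 3) -> float:
    """log10 of the Hamming-ball cardinality sum_{l<=L} C(L_ref,l)*alt^l.
    At L = L_ref this is the full sequence space (alternatives+1)^L_ref."""
    if not (0 <= L <= L_ref):
        raise InputError(f"L={L} outside 0..{L_ref}")
    n = sum(math.comb(L_ref, l) * alternatives**l for l in range(L + 1))
    return _log10_bigint(n)


def shell_log_size_nats(L_ref: int, L: int, alternatives: int = 3) -> float:
    return shell_log_size(L_ref, L, alternatives) * LN10


# ---------------------------------------------------------------------------
# Unit-independent models: exact dynamic program


@dataclass
class UnitSystem:
    """Independent mutable units of a unit-factorized generative model.

    Each unit carries alternative states with probabilities ``probs[u]`` and
    integer distance weights ``dists[u]`` (0 for the reference state, 1 for a
    single-position change, 2 for a pair changing both positions).
    """

    probs: list[np.ndarray]
    dists: list[np.ndarray]

    def __post_init__(self):
        if len(self.probs) != len(self.dists):
            raise InputError("probs/dists length mismatch")
        for k, (p, d) in enumerate(zip(self.probs, self.dists)):
            p, d = np.asarray(p, float), np.asarray(d, int)
            if p.shape != d.shape:
                raise InputError(f"unit {k}: probability/distance shape mismatch")
            if not np.isclose(p.sum(), 1.0):
                raise InputError(f"unit {k}: probabilities sum to {p.sum()}")
            if np.any((d < 0) | (d > 2)):
                raise InputError(f"unit {k}: distance weights must be in {{0,1,2}}")
            self.probs[k], self.dists[k] = p, d

    @property
    def max_distance(self) -> int:
        return int(sum(int(d.max()) for d in self.dists))


def unit_dp_entropy(units: UnitSystem, L: int) -> float:
    """Entropy (nats) of the unit-independent model conditioned on exact
    total distance ``L``.

    Dynamic program over units accumulating, per partial distance d, the
    total probability Z_d and the probability-weighted log-probability A_d;
    the conditional entropy is ``ln Z_L - A_L / Z_L``. Returns ``-inf`` if
    distance L is unreachable.
    """
    if L < 0:
        raise InputError("distance must be non-negative")
    dmax = units.max_distance
    if L > dmax:
        return float("-inf")
    Z = np.zeros(dmax + 1)
    A = np.zeros(dmax + 1)
    Z[0] = 1.0
    reach = 0
    for p, d in zip(units.probs, units.dists):
        step = int(d.max())
        newZ = np.zeros(dmax + 1)
        newA = np.zeros(dmax + 1)
        for alt_p, alt_d in zip(p, d):
            if alt_p <= 0:
                continue
            lo, hi = alt_d, reach + alt_d + 1
            newZ[lo:hi] += Z[: reach + 1] * alt_p
            newA[lo:hi] += (A[: reach + 1] + Z[: reach + 1] * math.log(alt_p)) * alt_p
        Z, A = newZ, newA
        reach += step
    if Z[L] <= 0:
        return float("-inf")
    return float(math.log(Z[L]) - A[L] / Z[L])


def uniform_units(L_ref: int, alternatives: int = 3) -> UnitSystem:
    """Per-position units of uniform random mutagenesis: the reference and
    ``alternatives`` other states, all equally likely."""
    q = alternatives + 1
    p = np.full(q, 1.0 / q)
    d = np.array([0] + [1] * alternatives)
    return UnitSystem(probs=[p.copy() for _ in range(L_ref)],
                      dists=[d.copy() for _ in range(L_ref)])


def profile_units(
    profile: ProfileModel, ref: ReferenceSequence, mutation_rate: float = 0.5
) -> UnitSystem:
    """Units of the profile model: each polymorphic position mutates with
    probability ``mutation_rate`` into its renormalized non-reference
    distribution. The exact-distance conditional entropy does not depend on
    ``mutation_rate`` (the rate factors out of every shell member equally);
    positions without non-reference mass are omitted (they cannot mutate)."""
    dist, eligible = profile.nonref_distribution(ref.codes)
    probs, dists = [], []
    for i in np.flatnonzero(eligible):
        nz = np.flatnonzero(dist[i] > 0)
        p = np.concatenate(([1.0 - mutation_rate], mutation_rate * dist[i][nz]))
        d = np.array([0] + [1] * nz.size)
        probs.append(p)
        dists.append(d)
    return UnitSystem(probs=probs, dists=dists)


def bpr_units(
    ref: ReferenceSequence,
    struct: SecondaryStructure,
    keep_tertiary: bool = False,
    mutation_rate: float = 0.5,
) -> UnitSystem:
    """Units of the idealized base-pair-replacement model: every target pair
    is a unit whose alternatives are the six canonical ordered pairs
    (distance weight = positions differing from the reference pair), every
    unpaired position a 3-alternative unit."""
    refc = ref.codes
    tert = struct.tertiary_positions if keep_tertiary else frozenset()
    probs, dists = [], []
    for i, j in struct.pairs:
        if i in tert or j in tert:
            continue
        cur = (int(refc[i - 1]), int(refc[j - 1]))
        alts = [c for c in ab.CANONICAL_PAIRS if c != cur]
        p = np.concatenate(([1.0 - mutation_rate],
                            np.full(len(alts), mutation_rate / len(alts))))
        d = np.array([0] + [int(a != cur[0]) + int(b != cur[1]) for a, b in alts])
        probs.append(p)
        dists.append(d)
    paired = {p for ij in struct.pairs for p in ij}
    for pos in range(1, struct.length + 1):
        if pos in paired or pos in tert:
            continue
        p = np.concatenate(([1.0 - mutation_rate], np.full(3, mutation_rate / 3)))
        probs.append(p)
        dists.append(np.array([0, 1, 1, 1]))
    return UnitSystem(probs=probs, dists=dists)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle


def _iter_shell(refc: np.ndarray, L: int):
    """Yield every integer-coded sequence at exact Hamming distance L."""
    n = refc.size
    for pos in itertools.combinations(range(n), L):
        for alts in itertools.product(range(1, ab.Q_RNA), repeat=L):
            x = refc.copy()
            for p, a in zip(pos, alts):
                x[p] = (refc[p] + a) % ab.Q_RNA
            yield x


def exact_entropy_enum(
    score_fn,
    ref: ReferenceSequence,
    L: int,
    T: float = 1.0,
    max_shell: int = 10**7,
) -> float:
    """Exact entropy (nats) of ``P(x) ~ exp(-score(x)/T)`` on the shell at
    distance L, by full enumeration. ``score_fn`` may also be a
    :class:`PottsModel`. Refuses shells larger than ``max_shell``."""
    if isinstance(score_fn, PottsModel):
        model = score_fn
        score_fn = model.energy
    size = math.comb(len(ref), L) * 3**L
    if size > max_shell:
        raise InputError(f"shell size {size:.3g} exceeds limit {max_shell:.3g}")
    E = np.fromiter(
        (float(score_fn(x)) for x in _iter_shell(ref.codes, L)),
        dtype=float, count=size,
    )
    logits = -E / T
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


# ---------------------------------------------------------------------------
# Thermodynamic integration


@dataclass
class TIConfig:
    """Grid and chain settings for thermodynamic integration.

    The beta grid runs from 0 (uniform on the shell) to the target inverse
    temperature; by default 21 points spaced geometrically near 0 where
    ``<E>(beta)`` varies fastest.
    """

    beta_target: float = 1.0
    n_beta: int = 21
    beta_grid: np.ndarray | None = None
    sweeps_per_beta: int = 6000
    burn_in_per_beta: int = 500
    n_seeds: int = 6
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.beta_grid is not None:
            g = np.asarray(self.beta_grid, float)
        else:
            g = np.concatenate(
                ([0.0],
                 np.geomspace(self.beta_target / 100, self.beta_target,
                              self.n_beta - 1))
            )
        if g[0] != 0.0 or np.any(np.diff(g) <= 0):
            raise InputError("beta grid must start at 0 and increase strictly")
        return g


def _ti_single(score_fn, model, ref, L, grid, config, seed) -> float:
    rng = np.random.default_rng(seed)
    ln_shell = shell_log_size_nats(len(ref), L)
    e_means = np.empty(grid.size)
    for k, beta in enumerate(grid):
        T = 1.0 / beta if beta > 0 else 1e12
        if model is not None:
            from .samplers import potts_shell_sample

            _, trace = potts_shell_sample(
                model, ref, L, T,
                sweeps=config.sweeps_per_beta,
                burn_in=config.burn_in_per_beta,
                seed=int(rng.integers(2**31 - 1)),
            )
        else:
            _, _, trace = _shell_mcmc(
                score_fn, ref, L, T,
                sweeps=config.sweeps_per_beta,
                burn_in=config.burn_in_per_beta,
                rng=rng, record_every=1,
            )
        e_means[k] = float(np.mean(trace))
    diffs = np.diff(e_means)
    # <E>(beta) decreases in beta for a well-mixed chain; flag gross violations
    span = float(e_means.max() - e_means.min())
    if span > 0 and np.any(diffs > 0.1 * span):
        warnings.warn("non-monotone <E>(beta) beyond noise tolerance: poor mixing?")
    ln_Z = ln_shell - np.trapezoid(e_means, grid)
    return float(grid[-1] * e_means[-1] + ln_Z)


def ti_entropy(
    model_or_score,
    ref: ReferenceSequence,
    L: int,
    config: TIConfig = TIConfig(),
) -> tuple[float, float]:
    """Entropy (nats) at exact distance L by thermodynamic integration.

    ``P_beta(x) ~ exp(-beta E(x))`` on the shell;
    ``ln Z(beta) = ln|shell| - int_0^beta <E> dbeta'`` (trapezoid over the
    grid, ``<E>`` from an independent shell MCMC chain per grid point);
    ``S = beta <E>_beta + ln Z(beta)`` at ``beta = beta_target``. Returns
    ``(S, standard error)`` over ``config.n_seeds`` independent repeats.
    """
    model = model_or_score if isinstance(model_or_score, PottsModel) else None
    score_fn = model.energy if model is not None else model_or_score
    if L == 0:
        return 0.0, 0.0
    grid = config.grid()
    root = np.random.SeedSequence(config.seed)
    estimates = [
        _ti_single(score_fn, model, ref, L, grid, config,
                   int(s.generate_state(1)[0] % (2**31 - 1)))
        for s in root.spawn(max(config.n_seeds, 1))
    ]
    est = np.asarray(estimates)
    se = float(est.std(ddof=1) / math.sqrt(est.size)) if est.size > 1 else 0.0
    return float(est.mean()), se


# ---------------------------------------------------------------------------
# Curves, bounds and scaling


@dataclass
class SupportCurve:
    """Per-distance entropy and effective support size for one model."""

    model_tag: str
    distances: np.ndarray
    S_nats: np.ndarray
    se: np.ndarray = None
    L_max: int | None = None

    def __post_init__(self):
        self.distances = np.asarray(self.distances, int)
        self.S_nats = np.asarray(self.S_nats, float)
        if self.se is None:
            self.se = np.zeros_like(self.S_nats)
        self.se = np.asarray(self.se, float)

    @property
    def log10_omega(self) -> np.ndarray:
        return self.S_nats / LN10

    def at(self, L: int) -> float:
        idx = np.flatnonzero(self.distances == L)
        if idx.size == 0:
            raise InputError(f"distance {L} not on the curve")
        return float(self.log10_omega[idx[0]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "L": self.distances,
            "S_nats": self.S_nats,
            "log10_omega": self.log10_omega,
            "se_nats": self.se,
        })


def neutral_set_lower_bound(
    curve: SupportCurve | float, active_fraction: float, L_max: int | None = None
) -> float:
    """log10 lower bound on the neutral-set size: the support size at the
    largest experimentally validated distance, multiplied by the active
    fraction measured there."""
    if not (0 < active_fraction <= 1):
        raise InputError("active fraction must lie in (0, 1]")
    log10_omega = curve.at(L_max) if isinstance(curve, SupportCurve) else float(curve)
    return log10_omega + math.log10(active_fraction)


def scaling_fit(lengths, log10_omegas) -> float:
    """Effective per-position diversity d from a power law Omega = d^L:
    the least-squares slope of log10(Omega) against length, exponentiated."""
    lengths = np.asarray(lengths, float)
    y = np.asarray(log10_omegas, float)
    if lengths.size < 2 or np.allclose(lengths, lengths[0]):
        raise InputError("need at least two distinct lengths")
    slope = np.polyfit(lengths, y, 1)[0]
    return float(10.0**slope)
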