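"""Design generation at controlled Hamming distance for every model family.

All generators produce gap-free sequences at an *exact* Hamming distance
(the "shell") from the reference: random uniform mutagenesis (RUM), the
profile model (PRO), base-pair replacement (BPR / BPR-3D, via
:mod:`riboneutral.rna_structure`), structure-based MCMC (SB / SB-3D),
coupling-model MCMC at a sampling temperature T (DCA), and the combined
DCA-SB score. The MCMC kernel never leaves the shell: proposals either
re-mutate an already-mutated position or exchange a mutated position for a
fresh one, so distance conditioning is exact by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numba import njit

from . import alphabet as ab
from .errors import InputError, SamplingError
from .msa_kit import Msa, ReferenceSequence, SequenceSet, make_chimeras
from .potts_dca import PottsModel, ProfileModel
from .rna_structure import FoldingParams, SecondaryStructure, bpr_mutate, sb_score

__all__ = [
    "SamplerConfig",
    "DesignRecord",
    "DesignSet",
    "ModelSpec",
    "rum_mutate",
    "pro_mutate",
    "shell_metropolis",
    "generate_design_set",
]


@dataclass
class SamplerConfig:
    """MCMC settings for sampling on the shell at distance ``L_target``.

    ``T`` is the sampling temperature: acceptance is ``min(1, exp(-dE/T))``,
    so the chain targets ``P(x) ~ exp(-E(x)/T)`` restricted to the shell.
    A sweep is ``max(1, L_target)`` elementary proposals.
    """

    L_target: int
    T: float = 1.0
    steps: int = 200
    burn_in: int = 1000
    lambda_sb: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.T <= 0:
            raise InputError("sampling temperature must be positive")
        if self.L_target < 0:
            raise InputError("L_target must be non-negative")


@dataclass
class DesignRecord:
    """One generated sequence with provenance and scores."""

    sequence: str
    model_tag: str
    distance_to_ref: int
    scores: dict = dc_field(default_factory=dict)
    seed: int | None = None


@dataclass
class DesignSet:
    """A collection of designs plus the bin plan that produced it."""

    records: list[DesignRecord]
    bin_plan: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(
            sequences=[r.sequence for r in self.records],
            labels=[r.model_tag for r in self.records],
        )

    def manifest(self) -> pd.DataFrame:
        rows = []
        for k, r in enumerate(self.records):
            row = {
                "id": f"{r.model_tag}_{r.distance_to_ref}_{k}",
                "model_tag": r.model_tag,
                "distance": r.distance_to_ref,
                "dca_energy": r.scores.get("dca_energy", np.nan),
                "sb_score": r.scores.get("sb_score", np.nan),
                "seed": r.seed,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, fasta_path, manifest_path) -> None:
        man = self.manifest()
        with open(fasta_path, "w") as fh:
            for rid, rec in zip(man["id"], self.records):
                fh.write(f">{rid}\n{rec.sequence}\n")
        man.to_csv(manifest_path, sep="\t", index=False)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def rum_mutate(ref: ReferenceSequence, n_mut: int, seed=0) -> str:
    """Random uniform mutagenesis at exact distance ``n_mut``: distinct
    positions chosen uniformly, each set to one of the 3 other nucleotides."""
    rng = _as_rng(seed)
    L = len(ref)
    if n_mut > L:
        raise InputError(f"n_mut={n_mut} exceeds sequence length {L}")
    x = ref.codes.copy()
    pos = rng.choice(L, size=n_mut, replace=False)
    for i in pos:
        x[i] = (x[i] + 1 + rng.integers(3)) % ab.Q_RNA
    return ab.decode(x)


def pro_mutate(
    profile: ProfileModel, ref: ReferenceSequence, n_mut: int, seed=0
) -> str:
    """Profile mutagenesis: positions chosen uniformly among those with
    non-reference mass in the alignment profile; nucleotides drawn from the
    position's renormalized non-reference distribution."""
    rng = _as_rng(seed)
    refc = ref.codes
    dist, eligible = profile.nonref_distribution(refc)
    pool = np.flatnonzero(eligible)
    if n_mut > pool.size:
        raise InputError(
            f"n_mut={n_mut} exceeds {pool.size} positions with non-reference mass"
        )
    x = refc.copy()
    pos = rng.choice(pool, size=n_mut, replace=False)
    for i in pos:
        x[i] = rng.choice(ab.Q_RNA, p=dist[i])
    return ab.decode(x)


def _shell_mcmc(
    score_fn,
    ref: ReferenceSequence,
    L_target: int,
    T: float,
    sweeps: int,
    burn_in: int,
    rng: np.random.Generator,
    frozen: frozenset = frozenset(),
    record_every: int = 0,
):
    """Metropolis walk on the exact-distance shell.

    Moves (probability 1/2 each where both apply):
    * re-mutate: a mutated position switches to another non-reference
      nucleotide (2 choices);
    * exchange: one mutated position reverts to the reference while a
      currently-reference position acquires one of 3 non-reference
      nucleotides.
    Both kernels are symmetric, so a flat score gives the uniform
    distribution on the shell. Returns ``(codes, score, trace)`` where
    ``trace`` lists the score every ``record_every`` sweeps after burn-in.
    """
    refc = ref.codes
    L = len(ref)
    mutable = np.array([i for i in range(L) if (i + 1) not in frozen], dtype=int)
    if L_target > mutable.size:
        raise InputError(
            f"L_target={L_target} exceeds {mutable.size} mutable positions"
        )
    x = refc.copy()
    if L_target == 0:
        return x, float(score_fn(x)), []
    init = rng.choice(mutable, size=L_target, replace=False)
    for i in init:
        x[i] = (x[i] + 1 + rng.integers(3)) % ab.Q_RNA
    mutated = list(init)
    mut_index = {p: k for k, p in enumerate(mutated)}
    unmutated = [i for i in mutable if i not in mut_index]
    score = float(score_fn(x))
    if not np.isfinite(score):
        raise SamplingError("non-finite score at initialization")
    trace = []
    per_sweep = max(1, L_target)
    can_exchange = len(unmutated) > 0
    for sweep in range(burn_in + sweeps):
        for _ in range(per_sweep):
            do_exchange = can_exchange and rng.random() < 0.5
            if do_exchange:
                mk = rng.integers(len(mutated))
                uk = rng.integers(len(unmutated))
                pm, pu = mutated[mk], unmutated[uk]
                old_m, old_u = x[pm], x[pu]
                x[pm] = refc[pm]
                x[pu] = (refc[pu] + 1 + rng.integers(3)) % ab.Q_RNA
                new_score = float(score_fn(x))
                if not np.isfinite(new_score):
                    raise SamplingError("non-finite score during sampling")
                if np.log(rng.random()) < -(new_score - score) / T:
                    score = new_score
                    mutated[mk], unmutated[uk] = pu, pm
                    mut_index.pop(pm)
                    mut_index[pu] = mk
                else:
                    x[pm], x[pu] = old_m, old_u
            else:
                mk = rng.integers(len(mutated))
                pm = mutated[mk]
                old = x[pm]
                # another non-reference nucleotide (2 alternatives)
                alts = [a for a in range(ab.Q_RNA) if a != refc[pm] and a != old]
                x[pm] = alts[rng.integers(len(alts))]
                new_score = float(score_fn(x))
                if not np.isfinite(new_score):
                    raise SamplingError("non-finite score during sampling")
                if np.log(rng.random()) < -(new_score - score) / T:
                    score = new_score
                else:
                    x[pm] = old
        if record_every and sweep >= burn_in and (sweep - burn_in) % record_every == 0:
            trace.append(score)
    return x, score, trace


@njit(cache=True)
def _potts_delta(h, J, x, i, a_new):
    a_old = x[i]
    d = -(h[i, a_new] - h[i, a_old])
    L = x.size
    for j in range(L):
        if j != i:
            d -= J[i, j, a_new, x[j]] - J[i, j, a_old, x[j]]
    return d


@njit(cache=True)
def _potts_shell_kernel(h, J, refc, L_target, T, sweeps, burn_in, seed):
    """Shell Metropolis specialized to the Potts energy with incremental
    delta-E updates; returns the final state and the per-sweep energy trace
    after burn-in. States are restricted to ACGU (0..3)."""
    np.random.seed(seed)
    L = refc.size
    x = refc.copy()
    is_mut = np.zeros(L, np.bool_)
    mutated = np.empty(max(L_target, 1), np.int64)
    count = 0
    while count < L_target:
        p = np.random.randint(L)
        if not is_mut[p]:
            is_mut[p] = True
            mutated[count] = p
            count += 1
    n_un = L - L_target
    unmut = np.empty(max(n_un, 1), np.int64)
    k = 0
    for i in range(L):
        if not is_mut[i]:
            unmut[k] = i
            k += 1
    for idx in range(L_target):
        p = mutated[idx]
        x[p] = (refc[p] + 1 + np.random.randint(3)) % 4
    # full energy once
    E = 0.0
    for i in range(L):
        E -= h[i, x[i]]
        for j in range(i + 1, L):
            E -= J[i, j, x[i], x[j]]
    trace = np.empty(sweeps)
    per_sweep = max(1, L_target)
    for sweep in range(burn_in + sweeps):
        for _ in range(per_sweep):
            if L_target == 0:
                break
            if n_un > 0 and np.random.random() < 0.5:
                mk = np.random.randint(L_target)
                uk = np.random.randint(n_un)
                pm = mutated[mk]
                pu = unmut[uk]
                old_m = x[pm]
                old_u = x[pu]
                new_u = (refc[pu] + 1 + np.random.randint(3)) % 4
                d1 = _potts_delta(h, J, x, pm, refc[pm])
                x[pm] = refc[pm]
                d2 = _potts_delta(h, J, x, pu, new_u)
                if np.log(np.random.random()) < -(d1 + d2) / T:
                    x[pu] = new_u
                    E += d1 + d2
                    mutated[mk] = pu
                    unmut[uk] = pm
                    is_mut[pm] = False
                    is_mut[pu] = True
                else:
                    x[pm] = old_m
            else:
                mk = np.random.randint(L_target)
                pm = mutated[mk]
                old = x[pm]
                a = (old + 1 + np.random.randint(2)) % 4
                if a == refc[pm]:
                    # remap to the never-drawn third alternative; stays uniform
                    # over the two states differing from both old and reference
                    a = (old + 3) % 4
                d = _potts_delta(h, J, x, pm, a)
                if np.log(np.random.random()) < -d / T:
                    x[pm] = a
                    E += d
        if sweep >= burn_in:
            trace[sweep - burn_in] = E
    return x, trace


def potts_shell_sample(
    model, ref: ReferenceSequence, L_target: int, T: float,
    sweeps: int, burn_in: int, seed: int,
):
    """Fast shell MCMC for a plain Potts energy. Returns (codes, energy_trace)."""
    x, trace = _potts_shell_kernel(
        model.h, model.J, ref.codes, L_target, T, sweeps, burn_in,
        int(seed) % (2**31 - 1),
    )
    return x, trace


def shell_metropolis(
    score_fn,
    ref: ReferenceSequence,
    config: SamplerConfig,
    frozen_positions=frozenset(),
) -> DesignRecord:
    """Sample one sequence at exact distance ``config.L_target`` from
    ``P(x) ~ exp(-score(x)/T)`` restricted to the shell.

    ``score_fn`` maps an integer-coded sequence (ACGU as 0..3) to a float.
    ``frozen_positions`` (1-based) are never mutated.
    """
    rng = np.random.default_rng(config.seed)
    x, score, _ = _shell_mcmc(
        score_fn, ref, config.L_target, config.T,
        config.steps, config.burn_in, rng, frozenset(frozen_positions),
    )
    d = int(np.count_nonzero(x != ref.codes))
    return DesignRecord(
        sequence=ab.decode(x),
        model_tag="MCMC",
        distance_to_ref=d,
        scores={"score": score},
        seed=config.seed,
    )


@dataclass
class ModelSpec:
    """What a model family needs to generate designs.

    ``tag`` selects the family: RUM, PRO, BPR, BPR-3D, SB, SB-3D,
    DCA, DCA-SB or CHI. MCMC families use ``sweeps``/``burn_in`` sweeps at
    temperature ``T``; DCA-SB combines the coupling energy and the SB score,
    each standardized to unit variance on a pilot shell sample, with weight
    ``lambda_sb`` on the structural term.
    """

    tag: str
    potts: PottsModel | None = None
    profile: ProfileModel | None = None
    struct: SecondaryStructure | None = None
    msa: Msa | None = None
    T: float = 1.0
    lambda_sb: float = 1.0
    folding: FoldingParams = dc_field(default_factory=FoldingParams)
    sweeps: int = 200
    burn_in: int = 200
    pilot_size: int = 20


def _frozen_for(spec: ModelSpec) -> frozenset:
    if spec.tag.endswith("-3D"):
        if spec.struct is None:
            raise InputError(f"{spec.tag} requires a structure")
        return frozenset(spec.struct.tertiary_positions)
    return frozenset()


def _one_design(
    spec: ModelSpec, ref: ReferenceSequence, L: int, seed: int,
    scales: dict | None,
) -> DesignRecord:
    rng = np.random.default_rng(seed)
    tag = spec.tag
    if tag == "RUM":
        seq = rum_mutate(ref, L, rng)
    elif tag == "PRO":
        seq = pro_mutate(spec.profile, ref, L, rng)
    elif tag in ("BPR", "BPR-3D"):
        seq = bpr_mutate(ref, spec.struct, L, keep_tertiary=tag.endswith("3D"),
                         seed=rng)
    elif tag in ("SB", "SB-3D"):
        fn = lambda x: sb_score(x, spec.struct, spec.folding)
        x, _, _ = _shell_mcmc(fn, ref, L, spec.T, spec.sweeps, spec.burn_in,
                              rng, _frozen_for(spec))
        seq = ab.decode(x)
    elif tag == "DCA":
        fn = lambda x: spec.potts.energy(x)
        x, _, _ = _shell_mcmc(fn, ref, L, spec.T, spec.sweeps, spec.burn_in, rng)
        seq = ab.decode(x)
    elif tag == "DCA-SB":
        se, ss = scales["dca"], scales["sb"]
        fn = lambda x: spec.potts.energy(x) / se + \
            spec.lambda_sb * sb_score(x, spec.struct, spec.folding) / ss
        x, _, _ = _shell_mcmc(fn, ref, L, spec.T, spec.sweeps, spec.burn_in, rng)
        seq = ab.decode(x)
    else:
        raise InputError(f"unknown model tag {tag!r}")
    scores = {}
    codes = ab.encode(seq)
    if spec.potts is not None:
        scores["dca_energy"] = spec.potts.energy(codes)
    if spec.struct is not None:
        scores["sb_score"] = sb_score(codes, spec.struct, spec.folding)
    return DesignRecord(
        sequence=seq, model_tag=tag,
        distance_to_ref=int(np.count_nonzero(codes != ref.codes)),
        scores=scores, seed=seed,
    )


def _pilot_scales(spec: ModelSpec, ref: ReferenceSequence, L: int, seed: int) -> dict:
    """Standard deviations of the two scores over a uniform pilot shell
    sample, used to put the DCA and SB terms on a common scale."""
    rng = np.random.default_rng(seed)
    es, ss = [], []
    for _ in range(spec.pilot_size):
        x = ab.encode(rum_mutate(ref, L, rng))
        es.append(spec.potts.energy(x))
        ss.append(sb_score(x, spec.struct, spec.folding))
    se = float(np.std(es)) or 1.0
    sb = float(np.std(ss)) or 1.0
    return {"dca": se, "sb": sb}


def generate_design_set(
    ref: ReferenceSequence,
    models: list[ModelSpec],
    bin_plan: list[tuple[int, int]],
    seed: int = 0,
    max_retry_factor: int = 3,
) -> DesignSet:
    """Generate ``count`` designs per model per distance bin.

    ``bin_plan`` lists ``(distance, count)`` pairs. Each design comes from an
    independent chain with its own sub-seed, so the output is reproducible
    and designs are not autocorrelated. Identical sequences within a
    (model, distance) cell are collapsed; if the requested count cannot be
    reached after bounded retries a warning reports the achieved count.
    """
    root = np.random.SeedSequence(seed)
    records: list[DesignRecord] = []
    for spec in models:
        if spec.tag == "CHI":
            sub = root.spawn(1)[0]
            plan = [L for L, count in bin_plan for _ in range(count)]
            chi = make_chimeras(spec.msa, ref, plan,
                                seed=int(sub.generate_state(1)[0] % (2**31 - 1)))
            for s in chi.sequences:
                d = int(np.count_nonzero(ab.encode(s) != ref.codes))
                records.append(DesignRecord(sequence=s, model_tag="CHI",
                                            distance_to_ref=d, scores={}))
            continue
        for L, count in bin_plan:
            scales = None
            if spec.tag == "DCA-SB":
                sub = root.spawn(1)[0]
                scales = _pilot_scales(
                    spec, ref, L, int(sub.generate_state(1)[0] % (2**31 - 1)))
            seen: set[str] = set()
            cell: list[DesignRecord] = []
            budget = max_retry_factor * count
            while len(cell) < count and budget > 0:
                budget -= 1
                sub = root.spawn(1)[0]
                rec = _one_design(
                    spec, ref, L, int(sub.generate_state(1)[0] % (2**31 - 1)),
                    scales)
                if rec.sequence in seen:
                    continue
                seen.add(rec.sequence)
                cell.append(rec)
            if len(cell) < count:
                warnings.warn(
                    f"{spec.tag} at L={L}: only {len(cell)}/{count} unique designs"
                )
            records.extend(cell)
    return DesignSet(
        records=records,
        bin_plan={"bins": list(bin_plan), "models": [m.tag for m in models]},
    )
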