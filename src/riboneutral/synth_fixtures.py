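"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: toy coupling models
whose entropies are enumerable, alignments sampled from a known model (so
marginal recovery is testable), a miniature ribozyme with nested hairpins, a
pseudoknot and tertiary positions, a synthetic stand-in for the full-size
group I intron reference, and simulated screens with planted activities.
Every generator is a pure function of its arguments and seed, so fixtures
regenerate identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import alphabet as ab
from .errors import InputError
from .msa_kit import Msa, ReferenceSequence
from .potts_dca import PottsModel, gibbs_sample, zero_sum_gauge
from .rna_structure import SecondaryStructure
from .samplers import DesignRecord, DesignSet, rum_mutate
from .screen_analysis import ScreenCounts

__all__ = [
    "ToySpec",
    "PlantedScreen",
    "make_toy_potts",
    "sample_msa",
    "make_toy_ribozyme",
    "synthetic_reference_mimic",
    "simulate_screen",
    "staircase_screen_pool",
    "concordance_screen_pool",
]


# ---------------------------------------------------------------------------
# Toy coupling models


@dataclass(frozen=True)
class ToySpec:
    """Specification of a random toy Potts model."""

    L: int = 8
    q: int = 4
    topology: str = "chain"  # chain | random
    edge_prob: float = 0.3
    coupling_scale: float = 1.0
    field_scale: float = 0.3
    seed: int = 0


def make_toy_potts(spec: ToySpec) -> PottsModel:
    """Random fields and couplings on the chosen topology, zero-sum gauge."""
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    h = spec.field_scale * rng.standard_normal((L, q))
    J = np.zeros((L, L, q, q))
    if spec.topology == "chain":
        edges = [(i, i + 1) for i in range(L - 1)]
    elif spec.topology == "random":
        edges = [
            (i, j)
            for i in range(L)
            for j in range(i + 1, L)
            if rng.random() < spec.edge_prob
        ]
    else:
        raise InputError(f"unknown topology {spec.topology!r}")
    for i, j in edges:
        block = spec.coupling_scale * rng.standard_normal((q, q))
        J[i, j] = block
        J[j, i] = block.T
    h, J = zero_sum_gauge(h, J)
    return PottsModel(h=h, J=J, meta={"topology": spec.topology, "seed": spec.seed})


def sample_msa(model: PottsModel, n: int, seed: int = 0) -> Msa:
    """Sample n rows from the model over the full state space (gap state
    allowed iff q = 5) by long-chain Gibbs sampling."""
    if n <= 0:
        raise InputError("need at least one row")
    codes = gibbs_sample(model, n, seed=seed, burn_in=500, thin=10)
    rows = [ab.decode(c) for c in codes]
    return Msa(rows=rows, ids=[f"s{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# Toy and full-size synthetic references


_PAIR_CHOICES = ("GC", "CG", "GC", "CG", "AU", "UA")  # GC-biased stems
_LOOP_NT = "ACGU"
_LOOP_P = (0.55, 0.15, 0.15, 0.15)


def _fill_sequence(length, pairs, rng) -> str:
    x = np.full(length, -1, dtype=int)
    for i, j in pairs:
        a, b = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
        x[i - 1] = ab.RNA.index(a)
        x[j - 1] = ab.RNA.index(b)
    for k in range(length):
        if x[k] < 0:
            x[k] = rng.choice(ab.Q_RNA, p=_LOOP_P)
    return ab.decode(x)


def make_toy_ribozyme(
    length: int = 60, seed: int = 0
) -> tuple[ReferenceSequence, SecondaryStructure]:
    """Miniature structured reference: two nested hairpins, one 3-pair
    pseudoknot between their loops, and 5 tertiary positions outside pairs.
    All target pairs are canonical on the reference sequence."""
    if length < 30:
        raise InputError("toy ribozyme needs length >= 30")
    rng = np.random.default_rng(seed)
    if length >= 60:
        nested = tuple((3 + k, 25 - k) for k in range(6)) + tuple(
            (30 + k, 52 - k) for k in range(6)
        )
        pseudo = ((12, 40), (13, 39), (14, 38))
        tertiary = (1, 2, 27, 28, 55)
    else:
        nested = tuple((2 + k, 16 - k) for k in range(3)) + tuple(
            (18 + k, 30 - k) for k in range(3)
        )
        pseudo = ((7, 24), (8, 23), (9, 22))
        tertiary = (1, 17, 5, 26, 27)
    struct = SecondaryStructure(
        length=length, nested=nested, pseudoknot=pseudo,
        tertiary_positions=frozenset(tertiary),
    )
    seq = _fill_sequence(length, struct.pairs, rng)
    return ReferenceSequence(id=f"toy_ribozyme_{length}", residues=seq), struct


def synthetic_reference_mimic(
    seed: int = 0,
) -> tuple[ReferenceSequence, SecondaryStructure]:
    """Synthetic stand-in for the 197-nt group I intron reference.

    This is NOT the real ribozyme: it is a generated sequence whose
    structural bookkeeping matches the reference's published statistics —
    197 nt, 59 base pairs (55 nested in five hairpins plus a 4-pair
    pseudoknot layer) and 30 tertiary-contact positions — so that
    full-size pipeline runs exercise realistic dimensions.
    """
    length = 197
    nested, loops = [], []
    start = 4
    stem, loop = 11, 11
    for _ in range(5):
        open0 = start
        close0 = start + 2 * stem + loop - 1
        nested.extend((open0 + k, close0 - k) for k in range(stem))
        loops.append(list(range(open0 + stem, open0 + stem + loop)))
        start = close0 + 3  # short single-stranded linker
    # 4-pair pseudoknot between the first two hairpin loops
    pseudo = tuple(
        (loops[0][2 + t], loops[1][8 - t]) for t in range(4)
    )
    struct = SecondaryStructure(
        length=length, nested=tuple(nested), pseudoknot=pseudo,
        tertiary_positions=frozenset(),
    )
    paired = {p for ij in struct.pairs for p in ij}
    unpaired = [p for p in range(1, length + 1) if p not in paired]
    tertiary = frozenset(unpaired[:: max(1, len(unpaired) // 30)][:30])
    struct = SecondaryStructure(
        length=length, nested=struct.nested, pseudoknot=struct.pseudoknot,
        tertiary_positions=tertiary,
    )
    rng = np.random.default_rng(seed)
    seq = _fill_sequence(length, struct.pairs, rng)
    return ReferenceSequence(id="synthetic_ref_197", residues=seq), struct


# ---------------------------------------------------------------------------
# Simulated screens


@dataclass
class PlantedScreen:
    """Planted activity function and sequencing conditions.

    True activity of design x at distance d with b disrupted target pairs is
    ``max(baseline - slope*d - pair_penalty*b, noise_floor)``; the measured
    log-ratio score adds Gaussian noise of sd ``noise_sd`` (the replicate
    measurement error). Pre-assay proportions carry a log-normal synthesis
    bias (a property of the synthesized pool, shared by replicates); counts
    are multinomial at the stated depths. ``depth_pre=None`` (and/or sel)
    returns exact proportions instead of counts: the infinite-depth limit.
    ``ref_abundance`` multiplies the pre-assay abundance of distance-0
    designs (the reference as a spike-in normalization control).
    """

    baseline: float = 0.0
    slope: float = 0.05
    pair_penalty: float = 0.5
    noise_floor: float = -1.5
    noise_sd: float = 0.3
    bias_sd: float = 0.3
    depth_pre: int | None = 100_000
    depth_sel: int | None = 1_000_000
    ref_abundance: float = 1.0
    seed: int = 0


def _disrupted_pairs(codes: np.ndarray, struct: SecondaryStructure | None) -> int:
    if struct is None:
        return 0
    n = 0
    for i, j in struct.pairs:
        if (int(codes[i - 1]), int(codes[j - 1])) not in ab.CANONICAL_PAIRS:
            n += 1
    return n


def simulate_screen(
    designs: DesignSet,
    struct: SecondaryStructure | None,
    params: PlantedScreen,
    true_acts: np.ndarray | None = None,
    replicate: int = 0,
) -> tuple[ScreenCounts, pd.DataFrame]:
    """Simulate pre/post-assay sequencing of a design pool.

    Returns ``(counts, truth)`` where ``truth`` lists per-design distance and
    planted activity. The synthesis bias depends only on ``params.seed``;
    measurement noise and count draws also depend on ``replicate``, so
    calling with replicate=0,1,2 emulates independent assays of one pool.
    """
    if len(designs) == 0:
        raise InputError("empty design set")
    man = designs.manifest()
    ids = man["id"].tolist()
    dist = man["distance"].to_numpy()
    if true_acts is None:
        acts = np.empty(len(designs))
        for k, rec in enumerate(designs.records):
            codes = ab.encode(rec.sequence)
            acts[k] = max(
                params.baseline
                - params.slope * dist[k]
                - params.pair_penalty * _disrupted_pairs(codes, struct),
                params.noise_floor,
            )
    else:
        acts = np.asarray(true_acts, float)
        if acts.size != len(designs):
            raise InputError("true_acts length mismatch")
    rng_pool = np.random.default_rng(params.seed)
    bias = np.exp(params.bias_sd * rng_pool.standard_normal(len(designs)))
    # the reference is a spike-in control at elevated abundance so the score
    # anchor (its own log-ratio) is estimated with negligible count noise
    bias[dist == 0] *= params.ref_abundance
    pre = bias / bias.sum()
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=params.seed, spawn_key=(replicate + 1,))
    )
    eps = params.noise_sd * rng.standard_normal(len(designs))
    # planted noise lives on the reference-anchored score scale: the
    # reference itself (distance 0) is the anchor and carries no score noise
    eps[dist == 0] = 0.0
    post = pre * 10.0 ** (acts + eps)
    post = post / post.sum()

    def draw(depth, p):
        if depth is None:
            return p
        if depth <= 0:
            raise InputError("sequencing depth must be positive")
        return rng.multinomial(int(depth), p).astype(float)

    c_ref = draw(params.depth_pre, pre)
    c_sel = draw(params.depth_sel, post)
    counts = ScreenCounts(
        counts=pd.DataFrame(
            {"count_ref": c_ref, "count_sel": c_sel}, index=pd.Index(ids, name="design_id")
        )
    )
    truth = pd.DataFrame(
        {"distance": dist, "true_act": acts}, index=pd.Index(ids, name="design_id")
    )
    return counts, truth


def _records_at(ref: ReferenceSequence, plan, rng) -> list[DesignRecord]:
    recs = []
    for d, count in plan:
        for _ in range(count):
            seq = ref.residues if d == 0 else rum_mutate(ref, d, rng)
            recs.append(DesignRecord(sequence=seq, model_tag="PLANT",
                                     distance_to_ref=d, scores={}))
    return recs


def staircase_screen_pool(
    seed: int = 0,
    params: PlantedScreen | None = None,
) -> tuple[DesignSet, np.ndarray, PlantedScreen, dict]:
    """Design pool with a planted active-fraction staircase.

    Composition (besides the reference): fully active bins at distances 5
    and 10 (20 designs each), a 150-design bin at distance 15 with exactly 4
    active designs (2.7%), a fully inactive 150-design bin at distance 20,
    and 543 far designs (>= 100 mutations) forming the noise plateau, the
    same plateau size used to calibrate the real assay's noise model.
    Planted truth: L50 = 10, Lmax = 15, activity threshold
    ``noise_floor + 3.0902 noise_sd``.
    """
    ref, _ = synthetic_reference_mimic(seed=7)
    rng = np.random.default_rng(seed)
    recs = _records_at(ref, [(0, 1), (5, 20), (10, 20)], rng)
    acts = [0.0] * len(recs)
    d15 = _records_at(ref, [(15, 150)], rng)
    recs += d15
    acts += [0.0] * 4 + [None] * 146  # 4 active designs in the Lmax bin
    recs += _records_at(ref, [(20, 150)], rng)
    acts += [None] * 150
    far_plan = [(int(d), 1) for d in rng.integers(100, 151, size=543)]
    recs += _records_at(ref, far_plan, rng)
    acts += [None] * 543
    if params is None:
        params = PlantedScreen(seed=seed, ref_abundance=20.0)
    true_acts = np.array(
        [a if a is not None else params.noise_floor for a in acts], dtype=float
    )
    designs = DesignSet(records=recs, bin_plan={"kind": "staircase"})
    planted = {
        "L50": 10,
        "Lmax": 15,
        "threshold": params.noise_floor + 3.0902 * params.noise_sd,
        "ref_index": 0,
    }
    return designs, true_acts, params, planted


def staircase_recovery(seed: int = 0, n_replicates: int = 5) -> dict:
    """End-to-end screen-recovery harness on the staircase pool.

    Simulates ``n_replicates`` independent assays of one synthesized pool,
    fits the noise model and threshold per replicate, averages the
    thresholds, then bins the replicate-averaged scores to estimate L50 and
    Lmax — the same average-over-replicates analysis used for real screens.
    Returns estimated and planted values.
    """
    from .screen_analysis import (
        activity_scores,
        activity_threshold,
        active_fraction_curve,
        estimate_L50_Lmax,
        fit_noise_model,
    )

    designs, acts, params, planted = staircase_screen_pool(seed=seed)
    man = designs.manifest()
    ref_id = man["id"][0]
    dist = dict(zip(man["id"], man["distance"]))
    thresholds, tables = [], []
    for rep in range(n_replicates):
        counts, _ = simulate_screen(designs, None, params, true_acts=acts,
                                    replicate=rep)
        table = activity_scores(counts, ref_id=ref_id, distances=dist)
        noise = fit_noise_model(table)
        thresholds.append(activity_threshold(noise).threshold)
        tables.append(table)
    threshold = float(np.mean(thresholds))
    mean_table = tables[0].copy()
    mean_table["act"] = np.nanmean(
        np.stack([t["act"].to_numpy() for t in tables]), axis=0
    )
    mean_table["excluded"] = np.logical_or.reduce(
        [t["excluded"].to_numpy() for t in tables]
    )
    mean_table["inactive"] = np.logical_or.reduce(
        [t["inactive"].to_numpy() for t in tables]
    )
    bins = active_fraction_curve(mean_table, threshold)
    summary = estimate_L50_Lmax(bins)
    return {
        "threshold": threshold,
        "threshold_planted": planted["threshold"],
        "threshold_error": threshold - planted["threshold"],
        "L50": summary.L50,
        "Lmax": summary.Lmax,
        "L50_planted": planted["L50"],
        "Lmax_planted": planted["Lmax"],
    }


def replicate_concordance(seed: int = 0) -> float:
    """Pearson correlation of activity scores between two simulated
    replicates of the wide-dynamic-range pool (designs scored in both)."""
    from .screen_analysis import activity_scores

    designs, acts, params = concordance_screen_pool(seed=seed)
    man = designs.manifest()
    ref_id = man["id"][0]
    dist = dict(zip(man["id"], man["distance"]))
    tables = []
    for rep in range(2):
        counts, _ = simulate_screen(designs, None, params, true_acts=acts,
                                    replicate=rep)
        tables.append(activity_scores(counts, ref_id=ref_id, distances=dist))
    ok = np.logical_and.reduce(
        [(~t["excluded"] & ~t["inactive"]).to_numpy() for t in tables]
    )
    a0 = tables[0]["act"].to_numpy()[ok]
    a1 = tables[1]["act"].to_numpy()[ok]
    return float(np.corrcoef(a0, a1)[0, 1])


def concordance_screen_pool(
    seed: int = 0,
) -> tuple[DesignSet, np.ndarray, PlantedScreen]:
    """Wide-dynamic-range pool for replicate-concordance checks.

    Half the designs are fully active (score 0), half sit at a deep planted
    floor (score -5), giving the across-design score variance needed for the
    replicate Pearson correlation to be signal- rather than noise-dominated.
    The post-assay sample is sequenced deeply so floor designs stay
    detectable across the 5-decade dynamic range.
    """
    ref, _ = synthetic_reference_mimic(seed=7)
    rng = np.random.default_rng(seed)
    recs = _records_at(ref, [(0, 1), (10, 199)], rng)
    acts = [0.0] * len(recs)
    recs += _records_at(ref, [(120, 200)], rng)
    acts += [-5.0] * 200
    params = PlantedScreen(
        noise_floor=-5.0, depth_pre=1_000_000, depth_sel=300_000_000, seed=seed
    )
    return (
        DesignSet(records=recs, bin_plan={"kind": "concordance"}),
        np.array(acts, float),
        params,
    )
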