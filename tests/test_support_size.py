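import itertools
import math

import numpy as np
import pytest

from riboneutral import (
    InputError,
    Msa,
    PottsModel,
    ReferenceSequence,
    TIConfig,
    ball_log_size,
    bpr_units,
    empirical_marginals,
    exact_entropy_enum,
    neutral_set_lower_bound,
    profile_from_msa,
    profile_units,
    scaling_fit,
    shell_log_size,
    ti_entropy,
    uniform_units,
    unit_dp_entropy,
)
from riboneutral import alphabet as ab
from riboneutral.support_size import LN10, SupportCurve, UnitSystem


def dp_oracle(units: UnitSystem, L: int) -> float:
    """Exhaustive enumeration over the product space of a small unit system:
    conditional entropy at exact total distance L."""
    probs, logps = [], []
    for combo in itertools.product(*[range(p.size) for p in units.probs]):
        d = sum(int(units.dists[k][c]) for k, c in enumerate(combo))
        if d != L:
            continue
        p = math.prod(float(units.probs[k][c]) for k, c in enumerate(combo))
        if p > 0:
            probs.append(p)
    Z = sum(probs)
    return -sum((p / Z) * math.log(p / Z) for p in probs)


class TestShellSize:
    def test_zero_distance(self):
        assert shell_log_size(10, 0) == 0.0

    def test_small_shell_enumeration(self):
        # L_ref=2, L=1: six single mutants
        assert shell_log_size(2, 1) == pytest.approx(math.log10(6), abs=1e-12)

    def test_full_sequence_space_is_10_to_118(self):
        assert math.floor(ball_log_size(197, 197)) == 118

    def test_out_of_range(self):
        with pytest.raises(InputError):
            shell_log_size(5, 6)


class TestUnitDp:
    def test_uniform_units_reduce_to_shell_size(self):
        units = uniform_units(10)
        for L in (0, 1, 4, 7, 10):
            expected = shell_log_size(10, L) * LN10
            assert unit_dp_entropy(units, L) == pytest.approx(expected, abs=1e-10)

    def test_zero_distance_entropy_zero(self):
        units = uniform_units(6)
        assert unit_dp_entropy(units, 0) == 0.0

    def test_four_unit_toy_matches_enumeration(self):
        rng = np.random.default_rng(5)
        probs, dists = [], []
        for _ in range(4):
            p = rng.dirichlet(np.ones(4))
            probs.append(p)
            dists.append(np.array([0, 1, 1, 1]))
        units = UnitSystem(probs=probs, dists=dists)
        for L in range(5):
            assert unit_dp_entropy(units, L) == pytest.approx(
                dp_oracle(units, L), abs=1e-10
            )

    def test_pair_units_with_weight_two_match_enumeration(self):
        rng = np.random.default_rng(8)
        probs = [rng.dirichlet(np.ones(3)) for _ in range(3)]
        dists = [np.array([0, 1, 2]) for _ in range(3)]
        units = UnitSystem(probs=probs, dists=dists)
        for L in range(7):
            got = unit_dp_entropy(units, L)
            exp = dp_oracle(units, L)
            assert got == pytest.approx(exp, abs=1e-10)

    def test_unreachable_distance_is_minus_inf(self):
        units = UnitSystem(
            probs=[np.array([0.5, 0.5])], dists=[np.array([0, 2])]
        )
        assert unit_dp_entropy(units, 1) == float("-inf")

    def test_profile_closed_form(self):
        msa = Msa(
            rows=["ACGU", "CCGU", "GCGU", "ACGC", "ACGG", "UCGU"],
            ids=list("abcdef"),
        )
        ref = ReferenceSequence(id="r", residues="ACGU")
        prof = profile_from_msa(
            empirical_marginals(msa, pseudocount=0.0, identity_threshold=1.0)
        )
        dist, eligible = prof.nonref_distribution(ref.codes)
        units = profile_units(prof, ref)
        n_poly = int(eligible.sum())
        H = [
            -sum(p * math.log(p) for p in dist[i] if p > 0)
            for i in np.flatnonzero(eligible)
        ]
        for L in range(1, n_poly + 1):
            closed = math.log(math.comb(n_poly, L)) + (L / n_poly) * sum(H)
            assert unit_dp_entropy(units, L) == pytest.approx(closed, abs=1e-10)

    def test_bpr_units_bounded_by_shell(self, toy_ribozyme):
        ref, struct = toy_ribozyme
        units = bpr_units(ref, struct)
        for L in (2, 5, 10):
            S = unit_dp_entropy(units, L)
            assert S <= shell_log_size(len(ref), L) * LN10 + 1e-9


class TestEntropyEstimators:
    def test_enum_uniform_gives_log_shell(self, toy_ref8):
        S = exact_entropy_enum(lambda x: 0.0, toy_ref8, 3)
        assert S == pytest.approx(shell_log_size(8, 3) * LN10, abs=1e-10)

    def test_enum_deep_minimum_entropy_vanishes(self, toy_ref8):
        target = toy_ref8.codes.copy()
        target[0] = (target[0] + 1) % 4
        target[1] = (target[1] + 1) % 4

        def score(x):
            return 0.0 if np.array_equal(x, target) else 50.0

        S = exact_entropy_enum(score, toy_ref8, 2)
        assert S < 1e-6

    def test_enum_refuses_large_shells(self):
        ref = ReferenceSequence(id="r", residues="ACGU" * 20)
        with pytest.raises(InputError):
            exact_entropy_enum(lambda x: 0.0, ref, 10)

    def test_enum_agrees_with_unit_dp_on_field_model(self, toy_ref8):
        # a field-only Potts model conditioned on the shell IS a unit system
        rng = np.random.default_rng(3)
        h = rng.standard_normal((8, 4))
        model = PottsModel(h=h, J=np.zeros((8, 8, 4, 4)))
        w = np.exp(h)
        w = w / w.sum(axis=1, keepdims=True)
        refc = toy_ref8.codes
        probs, dists = [], []
        for i in range(8):
            order = [refc[i]] + [a for a in range(4) if a != refc[i]]
            probs.append(w[i, order])
            dists.append(np.array([0, 1, 1, 1]))
        units = UnitSystem(probs=probs, dists=dists)
        for L in (1, 3, 5):
            assert exact_entropy_enum(model, toy_ref8, L) == pytest.approx(
                unit_dp_entropy(units, L), abs=1e-9
            )

    def test_ti_zero_model_exact(self, toy_ref8):
        zero = PottsModel(h=np.zeros((8, 4)), J=np.zeros((8, 8, 4, 4)))
        cfg = TIConfig(sweeps_per_beta=20, burn_in_per_beta=5, n_seeds=2, seed=0)
        S, se = ti_entropy(zero, toy_ref8, 4, cfg)
        assert S == pytest.approx(shell_log_size(8, 4) * LN10, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_ti_zero_distance(self, toy_potts8, toy_ref8):
        assert ti_entropy(toy_potts8, toy_ref8, 0) == (0.0, 0.0)

    def test_ti_close_to_enumeration(self, toy_potts8, toy_ref8):
        L = 3
        S_exact = exact_entropy_enum(toy_potts8, toy_ref8, L)
        cfg = TIConfig(sweeps_per_beta=1500, burn_in_per_beta=200, n_seeds=3, seed=1)
        S_ti, se = ti_entropy(toy_potts8, toy_ref8, L, cfg)
        assert abs(S_ti - S_exact) / S_exact < 0.01

    def test_entropy_bounded_by_shell_on_random_toys(self, toy_ref8):
        from riboneutral import ToySpec, make_toy_potts

        for seed in range(3):
            m = make_toy_potts(ToySpec(L=8, q=4, coupling_scale=1.0, seed=seed))
            for L in (2, 4):
                S = exact_entropy_enum(m, toy_ref8, L)
                assert S <= shell_log_size(8, L) * LN10 + 1e-9


class TestBoundsAndScaling:
    def test_lower_bound_arithmetic(self):
        assert neutral_set_lower_bound(41.0, 0.01) == pytest.approx(39.0)
        assert neutral_set_lower_bound(29.0, 0.01) == pytest.approx(27.0)
        assert neutral_set_lower_bound(12.5, 1.0) == pytest.approx(12.5)

    def test_lower_bound_from_curve(self):
        curve = SupportCurve(
            model_tag="DCA", distances=[10, 60], S_nats=[10 * LN10, 41 * LN10]
        )
        assert neutral_set_lower_bound(curve, 0.01, L_max=60) == pytest.approx(39.0)

    def test_zero_fraction_rejected(self):
        with pytest.raises(InputError):
            neutral_set_lower_bound(41.0, 0.0)

    def test_scaling_fit_recovers_planted_diversity(self):
        lengths = np.array([50, 100, 150, 200])
        assert scaling_fit(lengths, lengths * math.log10(1.74)) == pytest.approx(1.74)
        assert scaling_fit(lengths, lengths * math.log10(4.0)) == pytest.approx(4.0)

    def test_scaling_fit_two_points(self):
        d = scaling_fit([66, 132], [15.9, 31.8])
        assert d == pytest.approx(10 ** (15.9 / 66), rel=1e-9)

    def test_scaling_fit_degenerate(self):
        with pytest.raises(InputError):
            scaling_fit([100, 100], [1.0, 2.0])
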