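import itertools

import numpy as np
import pytest

from riboneutral import (
    InputError,
    Msa,
    ModelSpec,
    ReferenceSequence,
    SamplerConfig,
    empirical_marginals,
    generate_design_set,
    hamming,
    profile_from_msa,
    pro_mutate,
    rum_mutate,
    shell_metropolis,
)
from riboneutral import alphabet as ab
from riboneutral.samplers import potts_shell_sample
from riboneutral.support_size import _iter_shell


class TestRumMutate:
    def test_zero_is_identity(self, toy_ref8):
        assert rum_mutate(toy_ref8, 0, seed=1) == toy_ref8.residues

    def test_full_load_changes_every_position(self, toy_ref8):
        out = rum_mutate(toy_ref8, len(toy_ref8), seed=1)
        assert all(a != b for a, b in zip(out, toy_ref8.residues))

    def test_single_mutants_uniform(self, toy_ref4):
        # 12 possible single mutants of a length-4 reference, each expected
        # at frequency 1/12 over 10^4 draws (3 sigma binomial band)
        rng = np.random.default_rng(0)
        n = 10_000
        counts = {}
        for _ in range(n):
            s = rum_mutate(toy_ref4, 1, rng)
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 12
        p = 1 / 12
        band = 3 * np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < band

    def test_overload_is_error(self, toy_ref4):
        with pytest.raises(InputError):
            rum_mutate(toy_ref4, 5, seed=0)


class TestProMutate:
    @pytest.fixture()
    def profile(self):
        msa = Msa(rows=["ACGU", "CCGU", "GCGC", "UCGU"], ids=list("abcd"))
        return profile_from_msa(
            empirical_marginals(msa, pseudocount=0.0, identity_threshold=1.0)
        )

    def test_zero_is_identity(self, profile, toy_ref4):
        assert pro_mutate(profile, toy_ref4, 0, seed=0) == toy_ref4.residues

    def test_deterministic_column(self, toy_ref4):
        msa = Msa(rows=["ACGU", "CCGU"], ids=["a", "b"])
        prof = profile_from_msa(
            empirical_marginals(msa, pseudocount=0.0, identity_threshold=1.0)
        )
        # only position 1 is polymorphic and its non-reference mass is all C
        for seed in range(5):
            assert pro_mutate(prof, toy_ref4, 1, seed=seed) == "CCGU"

    def test_draws_follow_nonref_distribution(self, toy_ref4):
        # column 1 is {A, A, C, G} with reference A, so its non-reference
        # distribution is {C: 1/2, G: 1/2}; 10^4 draws within 3 sigma
        msa = Msa(rows=["ACGU", "ACGU", "CCGU", "GCGU"], ids=list("abcd"))
        prof = profile_from_msa(
            empirical_marginals(msa, pseudocount=0.0, identity_threshold=1.0)
        )
        rng = np.random.default_rng(3)
        n = 10_000
        counts = {"C": 0, "G": 0}
        for _ in range(n):
            s = pro_mutate(prof, toy_ref4, 1, rng)
            counts[s[0]] += 1
        for nt in ("C", "G"):
            band = 3 * np.sqrt(n * 0.25)
            assert abs(counts[nt] - n * 0.5) < band

    def test_too_few_eligible_positions(self, toy_ref4):
        msa = Msa(rows=["ACGU", "CCGU"], ids=["a", "b"])
        prof = profile_from_msa(
            empirical_marginals(msa, pseudocount=0.0, identity_threshold=1.0)
        )
        with pytest.raises(InputError):
            pro_mutate(prof, toy_ref4, 2, seed=0)


class TestShellMetropolis:
    def test_distance_always_exact(self, toy_ref8):
        for L in (1, 3, 5, 8):
            for seed in range(3):
                rec = shell_metropolis(
                    lambda x: 0.0, toy_ref8,
                    SamplerConfig(L_target=L, steps=20, burn_in=10, seed=seed),
                )
                assert rec.distance_to_ref == L
                assert hamming(rec.sequence, toy_ref8.residues) == L

    def test_degenerate_shell_returns_reference(self, toy_ref8):
        rec = shell_metropolis(
            lambda x: 0.0, toy_ref8,
            SamplerConfig(L_target=0, steps=10, burn_in=0, seed=0),
        )
        assert rec.sequence == toy_ref8.residues

    def test_flat_score_is_uniform_on_shell(self, toy_ref4):
        # L=1 shell of a length-4 reference has 12 members; empirical
        # frequencies must match uniform within 3 sigma
        n = 3000
        counts = {}
        for seed in range(n):
            rec = shell_metropolis(
                lambda x: 0.0, toy_ref4,
                SamplerConfig(L_target=1, steps=5, burn_in=10, seed=seed),
            )
            counts[rec.sequence] = counts.get(rec.sequence, 0) + 1
        assert len(counts) == 12
        p = 1 / 12
        band = 3 * np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < band

    def test_fast_kernel_uniform_on_shell(self, toy_ref4, toy_potts8):
        # zero-coupling limit of the numba kernel: uniform over the 54
        # members of the L=2 shell on a length-4 reference
        import riboneutral.potts_dca as pd_

        zero = pd_.PottsModel(h=np.zeros((4, 4)), J=np.zeros((4, 4, 4, 4)))
        counts = {}
        n = 8000
        for seed in range(n):
            x, _ = potts_shell_sample(zero, toy_ref4, 2, 1.0,
                                      sweeps=4, burn_in=8, seed=seed)
            counts[ab.decode(x)] = counts.get(ab.decode(x), 0) + 1
        assert len(counts) == 54
        p = 1 / 54
        band = 3.5 * np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < band

    def test_low_temperature_finds_shell_minimum(self, toy_potts8, toy_ref8):
        # exhaustive argmin over the L=2 shell is the T->0 target
        L = 2
        energies = {
            ab.decode(x): toy_potts8.energy(x)
            for x in _iter_shell(toy_ref8.codes, L)
        }
        best = min(energies.values())
        found = min(
            energies[
                shell_metropolis(
                    toy_potts8.energy, toy_ref8,
                    SamplerConfig(L_target=L, T=0.05, steps=200, burn_in=200,
                                  seed=seed),
                ).sequence
            ]
            for seed in range(8)
        )
        assert found == pytest.approx(best, abs=1e-9)

    def test_lower_temperature_concentrates(self, toy_potts8, toy_ref8):
        means = {}
        for T in (1.0, 0.3):
            scores = []
            for seed in range(120):
                _, trace = potts_shell_sample(
                    toy_potts8, toy_ref8, 4, T, sweeps=1, burn_in=60, seed=seed
                )
                scores.append(trace[-1])
            means[T] = np.mean(scores)
        assert means[0.3] <= means[1.0]

    def test_frozen_positions_respected(self, toy_ref8):
        rec = shell_metropolis(
            lambda x: 0.0, toy_ref8,
            SamplerConfig(L_target=3, steps=30, burn_in=10, seed=0),
            frozen_positions={1, 2},
        )
        assert rec.sequence[0] == toy_ref8.residues[0]
        assert rec.sequence[1] == toy_ref8.residues[1]


class TestGenerateDesignSet:
    def test_plan_counts_and_distances(self, toy_ref8):
        ds = generate_design_set(
            toy_ref8, [ModelSpec(tag="RUM")], [(2, 5), (4, 5)], seed=0
        )
        man = ds.manifest()
        assert len(ds) == 10
        assert (man.groupby("distance").size() == 5).all()
        for rec in ds.records:
            assert hamming(rec.sequence, toy_ref8.residues) == rec.distance_to_ref

    def test_same_seed_byte_identical_manifest(self, toy_ref8, toy_potts8):
        specs = [ModelSpec(tag="DCA", potts=toy_potts8, T=1.0,
                           sweeps=10, burn_in=10)]
        m1 = generate_design_set(toy_ref8, specs, [(3, 4)], seed=9).manifest()
        m2 = generate_design_set(toy_ref8, specs, [(3, 4)], seed=9).manifest()
        assert m1.to_csv() == m2.to_csv()

    def test_bpr_designs_keep_pairs_canonical(self, toy_ribozyme):
        ref, struct = toy_ribozyme
        ds = generate_design_set(
            ref, [ModelSpec(tag="BPR", struct=struct)], [(6, 5)], seed=1
        )
        canon = set("GC CG GU UG AU UA".split())
        for rec in ds.records:
            for i, j in struct.pairs:
                assert rec.sequence[i - 1] + rec.sequence[j - 1] in canon

    def test_bpr3d_freezes_tertiary(self, toy_ribozyme):
        ref, struct = toy_ribozyme
        ds = generate_design_set(
            ref, [ModelSpec(tag="BPR-3D", struct=struct)], [(8, 5)], seed=1
        )
        for rec in ds.records:
            for t in struct.tertiary_positions:
                assert rec.sequence[t - 1] == ref.residues[t - 1]

    def test_duplicate_collapse_warns(self, toy_ref4):
        # the L=1 shell has 12 members; asking for 30 unique designs must
        # fall short and warn
        with pytest.warns(UserWarning, match="unique designs"):
            ds = generate_design_set(
                toy_ref4, [ModelSpec(tag="RUM")], [(1, 30)], seed=0
            )
        assert len(ds) <= 12

    def test_unknown_tag(self, toy_ref4):
        with pytest.raises(InputError):
            generate_design_set(toy_ref4, [ModelSpec(tag="NOPE")], [(1, 1)], seed=0)
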