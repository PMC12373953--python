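# Methods

`riboneutral` implements a pipeline for estimating how many sequence
variants of a structured ribozyme retain function: fit a generative model to
natural homologs, sample variants at controlled mutational distance, compute
each model's effective support size Ω(L) = exp(S(L)), and combine the curve
with a screen-measured active fraction into a lower bound on the neutral-set
size. This note records the models, the estimators, their tunable
parameters, and the design choices made where the published description left
the details open.

## Sequence models

**Potts / coupling model.** Over alignment columns 1..L with states
q ∈ {A,C,G,U,–} the model assigns energy

    E(x) = − Σ_i h_i(x_i) − Σ_{i<j} J_ij(x_i, x_j),   P(x) ∝ exp(−E(x)/T).

Fitting is Boltzmann-machine learning: empirical one- and two-site
frequencies (sequence-reweighted at 80% identity, pseudocount 0.05) are
matched by gradient steps `Δh ∝ f_emp − f_model`, with model frequencies
estimated from a pool of persistent Gibbs chains (PCD). The L2 penalty is
applied as multiplicative weight decay `max(1 − lr·λ, 0)` rather than an
explicit gradient term; the two agree to first order, but the decay form is
stable for arbitrarily large λ (the explicit term diverges when lr·λ > 2).
Initialization is the independent-site profile fit (h = log f_i, J = 0).
Training is epoch-capped; the returned fit report carries the Pearson
correlation between model and empirical connected correlations
C_ij(a,b) = f_ij − f_i f_j, estimated from a fresh sample of the final
model, plus the single-site RMSE. Defaults: lr 0.05, 200 epochs, 100
chains × 5 Gibbs sweeps/epoch, λ_h = λ_J = 0.01. Training runs over q = 5
(alignments contain gaps); all generation restricts states to ACGU so
designs are valid fixed-length sequences. The final model is stored in the
zero-sum gauge (Σ_a h_i(a) = 0, Σ_a J_ij(a,b) = 0), which leaves all energy
differences invariant.

**Profile model.** Per-position categorical distributions renormalized from
the alignment frequencies with gaps excluded; the sampler draws from each
selected position's non-reference renormalization, so realized distances
are exact.

**Structure-guided mutagenesis (BPR).** Target pairs are rewritten jointly
into one of the six canonical ordered pairs (GC/CG/GU/UG/AU/UA), unpaired
positions into one of the three other nucleotides; the `-3D` variants
freeze the tertiary-contact positions. The generator tracks realized
Hamming distance (a pair rewrite changes 1 or 2 positions) and restarts if
a random walk fails to hit the exact load.

## Folding model and SB score

The structure-based score uses a self-contained McCaskill-style partition
function over crossing-free structures with a deliberately simple energy
model: pairing energies GC −3, AU −2, GU −1 (arbitrary units), an adjacent
stacking bonus −1, minimum hairpin loop 3, kT = 1. Inside recursions give
interval partition functions Z and pair-conditioned Zb (stacking handled by
the substitution Ẑ = Z + (σ−1)·Zb on the enclosed interval); an outside
recursion over the nearest enclosing pair yields exact pair probabilities
p_ij = Zb·Out/Z. Both recursions are validated to machine precision against
brute-force enumeration of all structures on short sequences.

The SB score of sequence x against a target structure is

    SB(x) = − Σ_{(i,j)∈nested} ln p_ij(x) − Σ_{(i,j)∈pseudoknot} ln p′_ij(x),

where p′ comes from a second partition function with the nested target
pairs forbidden: each layer is crossing-free on its own, so a pseudoknotted
target can be scored without a pseudoknot-capable folder. Probabilities are
floored at ε = 1e−6, keeping the score finite (a hopeless pair contributes
≈ 13.8 nats). The full nearest-neighbor (Turner) parameter set is out of
scope; an external thermodynamic folder can be substituted behind
`pair_probability_matrix`'s contract.

## Samplers at fixed distance

All stochastic generation is conditioned on the exact-distance shell
{x : d(x, ref) = L}. The Metropolis kernel never leaves the shell: with
probability ½ it re-mutates one mutated position to another non-reference
nucleotide (2 choices), otherwise it exchanges a mutated position (reverted
to reference) against a fresh position (set to one of 3 non-reference
nucleotides). Both proposals are symmetric, so a flat score yields the
uniform shell distribution — verified against exact enumeration. Acceptance
is min(1, exp(−ΔE/T)); T is the sampling temperature. A sweep is
max(1, L) proposals; defaults are 1000 burn-in sweeps and one design per
independent chain so designs are uncorrelated. A numba kernel with
incremental ΔE evaluation serves plain Potts scores; a generic Python
kernel accepts arbitrary score callables (SB, combined). For the hybrid
DCA-SB family the two scores are each standardized by their standard
deviation over a 20-sequence uniform pilot sample on the target shell and
combined with weight λ_SB (default 1) at T = 0.3; the standardization makes
λ_SB meaningful across score scales.

The hard-shell conditioning (rather than a soft distance bias with post-hoc
binning) is a deliberate reconstruction: it makes Ω(L) a well-defined
conditional quantity and guarantees every design lands in its bin.

## Support sizes

Ω(L) = exp(S(L)) with S the Shannon entropy of the generative distribution
conditioned on the shell.

* **Closed forms / dynamic program.** For unit-independent models (uniform,
  profile, BPR) a dynamic program over units accumulates, per partial
  distance d, the total probability Z_d and the probability-weighted
  log-probability A_d; the conditional entropy is ln Z_L − A_L/Z_L. It
  reduces exactly (1e−10) to ln C(L_ref, L) + L ln 3 for uniform units and
  to ln C(N_poly, L) + (L/N_poly) Σ_i H_i for the profile model, and agrees
  with exhaustive enumeration on small unit systems, including weight-2
  pair units (unreachable distances report −∞).
* **Thermodynamic integration.** For coupled models, with
  P_β(x) ∝ exp(−βE(x)) on the shell, ln Z(β) = ln|shell| − ∫₀^β ⟨E⟩ dβ′
  (trapezoid over a 21-point grid geometrically spaced near 0, where ⟨E⟩
  varies fastest) and S = β⟨E⟩_β + ln Z(β) at β = 1/T. Each grid point runs
  an independent shell chain (500 burn-in + 6000 measured sweeps); the
  estimate is averaged over 6 independent repeats whose spread gives the
  standard error. On toy models (L = 8, shells ≤ 1e5) the estimate sits
  within ~0.5% of exhaustive enumeration, inside the 1% band the test suite
  enforces. A warning flags grossly non-monotone ⟨E⟩(β) (poor mixing).
* **Enumeration oracle.** Exact entropies for shells up to 1e7 states,
  used only to validate the other two estimators.

Shell and ball cardinalities use exact big-integer arithmetic
(C(197,197)-scale numbers overflow any float path). The neutral-set lower
bound is log₁₀Ω(L_max) + log₁₀(active fraction at L_max); the scaling
helper fits log₁₀Ω = L·log₁₀d by least squares to expose the effective
per-position diversity d.

## Screen statistics

Activity of a design is act = log₁₀(f_sel/f_ref) − act_reference, so the
reference scores 0 (log base 10 fixed by the published percent equivalence
10^−2.76 = 0.17%). Designs with pre-assay count < 5 are excluded from all
denominators; detected designs with zero post-assay count are flagged
inactive and count as below any threshold. Read mapping is exact substring
matching: a read counts for a design if it contains ≥ 70% of the design
with full identity, and counts as substrate-tagged only if the design's 3′
end is followed immediately by the S2 tag; multi-design hits are dropped.

The noise model is the Gaussian fitted (mean/SD) to scores of designs at
≥ 100 mutations; the activity threshold at tail probability p is
μ + z(p)·σ (p = 1e−3 ↔ z = 3.09). Active fractions are computed in
half-open bins (a, a+5], with upper/lower bounds counting scores within
±0.3 of the threshold as active/inactive. Each bin's significance is the
exact one-sided binomial tail Σ_{i≥n} C(N,i) π^i (1−π)^{N−i}, computed in
exact rational arithmetic (no normal approximation). L50 (Lmax) is the
largest bin upper edge with fraction ≥ 50% (1%) and p < 1e−3 against the
noise null π = 1e−3; the Methods-formula null (π(z), not 50%) is the
implemented reading of the ambiguous published test. A stringent threshold
preset (−1.5) covers shallow-sequencing conditions.

## Synthetic data: what it emulates and what it does not

The fixtures module generates every input the pipeline consumes:

* toy Potts models (chain or random-graph couplings) small enough for exact
  enumeration (L = 8 for entropy oracles, L = 30 for training recovery);
  the training toy uses coupling scale 1.5, chosen so that the
  connected-correlation signal in 2000 sampled sequences clearly exceeds
  finite-sample noise (the empirical-vs-truth Pearson ceiling is ≈ 0.97);
* alignments sampled from a known model by long-chain Gibbs sampling, so
  marginal recovery is testable against ground truth;
* a 60-nt toy ribozyme (two hairpins, 3-pair pseudoknot, 5 tertiary
  positions, all target pairs canonical) and a 197-nt synthetic reference
  mimic reproducing the real molecule's bookkeeping (59 pairs including a
  4-pair pseudoknot layer, 30 tertiary positions) — the mimic is a
  generated sequence, not the real ribozyme;
* simulated screens: true activity max(baseline − slope·d − penalty·
  (#disrupted pairs), floor), log-normal synthesis bias on pre-assay
  proportions (a pool property shared by replicates), Gaussian measurement
  noise of SD 0.3 on each design's reference-anchored score, and
  multinomial read counts at the stated depths (pre 1e5; post-assay 1e6,
  deeper because reads concentrate on active variants). The reference
  enters as a 20× spike-in so the normalization anchor carries negligible
  count noise, and carries no score noise itself since the planted noise is
  defined on the reference-anchored scale.

The recovery harness simulates five replicate assays of one pool, averages
the per-replicate thresholds, and estimates L50/Lmax from replicate-averaged
scores — the same averaging a triplicated real screen uses. The
replicate-concordance check uses a separate wide-dynamic-range pool (half
the designs fully active, half at a −5 floor, post-assay depth 3e8): with
±0.3 per-measurement noise, a Pearson r ≥ 0.98 between replicates requires
across-design signal variance ≳ 5, which a narrow staircase pool cannot
supply at any depth.

What the generator does **not** emulate: base-call errors and quality
scores, paired-end mechanics, indels in designs, cross-catalysis between
pool members, and phylogenetic correlation in alignments (rows are i.i.d.
model samples, so reweighting is exercised only lightly). Passing tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to real-data artifacts.

## Numerical choices and degenerate inputs

* Probability floor ε = 1e−6 in SB; identity-threshold reweighting counts
  the sequence itself (weights ≤ 1); pseudocount mixes toward uniform so
  pairwise marginals stay exactly consistent with single-site ones.
* PCA uses one-hot encoding (4 indicators/position), SVD of the centered
  basis; a rank-1 basis yields ≈ 0 second coordinates; an all-identical
  basis raises an error. When a reference is supplied, coordinates are
  translated so it maps to the origin.
* Chimera donor draws exclude gaps and the reference nucleotide, making the
  realized distance exact by construction; per-position loads (rather than
  per-donor) are the documented reading of the underspecified scheme.
* Shell samplers: L = 0 returns the reference; L = L_ref disables the
  exchange move (no reference positions remain); frozen tertiary positions
  are excluded from both the initial placement and all proposals.
* Exact binomial tails sum the complement side (≤ N/2 terms) in
  `fractions.Fraction`; σ = 0 noise fits, empty bins, unreachable DP
  distances and oversized enumeration shells all raise or flag explicitly.
* All randomness flows through `numpy` generators seeded from explicit
  arguments; sub-seeds are spawned via `SeedSequence`, so every fixture,
  training run and design set regenerates byte-identically.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
problems: entropy oracles on L = 8 toys (shells ≤ 5670 states), training
recovery on L = 30 with 2000 sequences, folding oracles on 12-nt sequences,
toy ribozyme at 60 nt, full-size runs on the 197-nt mimic, screens with
~880–1600 designs at 1e5/1e6 read depth. These sizes keep every oracle
exact while exercising the same code paths as full-size data.

## Known limitations

* The simple folding energy model ranks structures sensibly but is not
  calibrated to experimental free energies; SB scores are comparative, not
  thermodynamic predictions.
* Boltzmann-machine learning with PCD carries gradient noise from the
  finite chain pool; the fit report quantifies, rather than guarantees,
  convergence. No pseudo-likelihood initializer is provided.
* The TI estimator assumes adequate mixing of the shell chains; strongly
  multimodal landscapes at low temperature would need replica exchange,
  which is out of scope.
* Insertions/deletions are not modeled anywhere: all designs have the
  reference length, matching the fixed-length design setting.
* Reproducing the published Ω values for real data requires the real
  homolog alignment and screen counts, which are inputs, not package
  contents; the algorithms and their oracles are the deliverable.
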