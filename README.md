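# riboneutral

Generative sequence models and neutral-set sizing for structured RNA
families.

How many RNA sequences can perform a given catalytic function? For a
ribozyme of length L there are 4^L possible sequences (10^118 for a 197-nt
group I intron), and the functional ones — the *neutral set* — can only be
probed by combining generative models with high-throughput activity
screens. This package provides the computational side of that program, for
researchers studying ribozyme fitness landscapes, RNA design, or
origin-of-life sequence-space questions:

* **Coupling models (DCA/Potts).** Fit fields `h_i(a)` and pairwise
  couplings `J_ij(a,b)` to an alignment of homologs by Boltzmann-machine
  learning, so that `P(x) ∝ exp(−E(x)/T)` with
  `E(x) = −Σ_i h_i(x_i) − Σ_{i<j} J_ij(x_i, x_j)` reproduces the
  alignment's one- and two-site statistics.
* **Design generation at exact mutational distance.** Metropolis sampling
  restricted to the shell `d(x, ref) = L`, plus simpler families: uniform
  random mutagenesis, profile draws, canonical base-pair replacement
  (with optional frozen tertiary contacts), structure-guided MCMC on a
  McCaskill-style folding score with pseudoknot support, and hybrid
  coupling+structure sampling at low temperature.
* **Effective support sizes.** `Ω(L) = exp(S(L))`, the effective number of
  distinct sequences a model can generate at distance L: exact closed
  forms and a distance-resolved dynamic program for unit-independent
  models, thermodynamic integration
  (`ln Z(β) = ln|shell| − ∫₀^β ⟨E⟩ dβ′`) for coupled models, and
  enumeration oracles on toys.
* **Screen analysis.** Activity scores `act = log₁₀(f_sel/f_ref)` from
  sequencing counts, Gaussian noise model of the non-functional plateau,
  z = 3.09 activity threshold, binned active fractions with exact binomial
  tests, the summary distances L50/Lmax, and the neutral-set lower bound
  `log₁₀Ω(L_max) + log₁₀(active fraction)`.
* **Synthetic fixtures.** Toy coupling models, sampled alignments, a toy
  pseudoknotted ribozyme and full-size synthetic reference, and simulated
  screens with planted ground truth — everything needed to validate the
  pipeline end to end without external data.

## Worked example

Score a simulated screen with planted truth (`examples/06_screen_analysis.py`):

```
noise plateau: mu = -1.495, sigma = 0.293 (n = 543)
threshold at p = 1e-3 (z = 3.09): -0.588 (planted -0.573)

bin (lo, hi]   N    n   fraction   binomial p
(  0,  5]     20   18   0.900     1.90e-52
(  5, 10]     20   19   0.950     2.00e-56
( 10, 15]    150    4   0.027     1.80e-05
( 15, 20]    150    0   0.000     1.00e+00

L50 = 10 (planted 10), Lmax = 15 (planted 15)
```

The noise fit recovers the planted plateau (μ = −1.5, σ = 0.3); the
threshold sits 3.09 noise standard deviations above it; the active-fraction
staircase identifies L50 = 10 (largest distance with ≥ 50% active designs)
and Lmax = 15 (largest with ≥ 1%, here 4/150 = 2.7% at exact binomial
p = 1.8e−5 against the noise null).

Compute support sizes on a toy coupled model
(`examples/05_support_size.py`):

```
 L   log10|shell|  log10 Omega_RUM  log10 Omega_model (TI vs exact)
 2        2.401          2.401     1.985 +- 0.010 (exact 1.992)
 4        3.754          3.754     3.211 +- 0.007 (exact 3.215)

log10 Omega(60) = 41 with a 1% active fraction bounds the neutral set at 10^39
power-law fit d^L across lengths recovers d = 1.74
```

Uniform mutagenesis fills the whole shell; the coupled model concentrates
on fewer sequences (Ω < |shell|), and thermodynamic integration matches the
exact enumeration within its reported error. The other examples cover
alignment diversity and chimeras (01), model training (02), structure
scoring (03) and multi-family design generation (04).

A thin CLI mirrors the main operations:

```sh
riboneutral msa project --msa aln.fasta --ref ref.fasta --out proj.fasta
riboneutral dca train --msa proj.fasta --ref ref.fasta --out model.npz
riboneutral omega --model model.npz --ref ref.fasta --L 10,20,30
riboneutral screen summary --counts counts.tsv --ref-id ref --distances d.tsv --out summary.json
```

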