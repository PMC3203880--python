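# Methods

`fragpop` implements the standard single-locus population-genetic toolkit
for dating the fragmentation of subdivided populations, together with a
coalescent generator for the demographic scenario that toolkit targets.
This note records the models, the parameter choices that matter, and the
numerical decisions, in enough detail to re-derive every default.

## The demographic model behind the synthetic data

The generator (`fragpop.simulate`) draws from a Hudson discrete-deme
coalescent for a haploid (mitochondrial) locus with

* **sequential splits, no migration**: demes separate from an ancestral
  trunk one at a time; backwards in time each deme's lineages merge into
  the trunk at its split time. Migration is fixed at zero — the isolation
  scenario the divergence estimator also assumes — and there is no
  recombination (a single mtDNA fragment).
* **piecewise-constant sizes** with one optional resize event modelling a
  sudden demographic expansion: at `time_generations` before present the
  expanding deme's size drops to `fraction` of its present value.
* **finite-sites Jukes–Cantor mutation**: mutations are a Poisson process
  on branches at μ per site per generation; each hit replaces the state
  with one of the three other bases, so multiple hits (homoplasy) occur as
  they do in real protein-coding mtDNA. Infinite-sites shortcuts are used
  only where only summary counts are needed (neutrality nulls, mismatch
  bootstrap), never where sequences are compared to data.
* **one RNG stream** per dataset, consumed in a fixed order (genealogy →
  mutations → coordinates), so a seed fully determines the output files.

Default study conditions: four demes named after the four montane isolates
(Dawida, Mbololo, Sagalla, Kasigau) with sample sizes 99/17/15/4, a 783 bp
locus, μ = 1.14×10⁻⁸ per site per generation (5.7×10⁻⁹ per year at the
2-year generation time), and splits at 465,000 / 380,000 / 295,000
generations — 0.93 / 0.76 / 0.59 Ma — with the third-listed deme isolating
first despite its geographic proximity, then the most distant deme, then
the two sister demes.

Deme sizes are calibrated to the per-population nucleotide diversities the
design implies (π = 2Nμ at equilibrium): 35,000 / 2,000 / 26,000 for the
three small isolates (π ≈ 0.0008 / ~0 / 0.0006). The largest deme is *not*
at equilibrium: it carries the expansion. Its present size (700,000) is
deliberately much larger than the expansion age (91,000 generations,
pre-expansion fraction 0.001), because only then do most lineage pairs
survive back to the expansion and produce the star-like genealogy — the
unimodal mismatch wave at τ = 2uLt ≈ 1.6, π ≈ 0.0016–0.003, and strongly
negative Tajima's D and Fu's F_S — that defines this regime. A size
matched to equilibrium π (≈70,000) leaves the expansion invisible in most
draws.

Coordinates are planar kilometres (pre-projected); the default layout puts
the sister demes 4 km apart, the first-isolating deme 22 km east and the
most distant deme ~50 km south, so geographic distance and split order
disagree — the configuration that makes the isolation-by-distance test
interesting. Optional secondary contact replaces k sequences in a target
deme with one haplotype drawn from a source deme and flags them
`transplanted`, emulating recent human-mediated transfer.

What the generator does **not** emulate: migration or admixture,
recombination, selection, multi-locus data, sequencing error, and
rate variation among sites. Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those violations.

## Statistics

**Missing data.** All statistics operate on *analyzed sites*: columns that
are pure A/C/G/T within the sample subset being analyzed (complete
deletion). This keeps haplotype identity exact and site counts
well-defined; the pairwise-deletion alternative used by some software can
give slightly different S and π on gappy data.

**Diversity.** h = n/(n−1)(1 − Σp²) with Nei's large-sample variance;
π = (mean pairwise differences)/L with Tajima's total variance
(n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1)). π equals the mismatch
distribution's mean divided by L exactly (shared code path, asserted in
tests). Diversity reports follow the "no sc" convention: populations with
flagged transplants are reported both excluding (baseline) and including
them.

**AMOVA / SAMOVA.** Distances are raw pairwise nucleotide difference
counts used as squared distances. Variance components come from the
unbalanced nested ANOVA expectations (coefficients n₁, n₂, n₃ from the
site and group sizes); F_CT = σ²ₐ/σ²_tot, F_SC = σ²_b/(σ²_b+σ²_c),
F_ST = (σ²ₐ+σ²_b)/σ²_tot. SAMOVA searches contiguous partitions of the
Delaunay neighbourhood graph of site coordinates (2-nearest-neighbour
fallback for degenerate layouts) by simulated annealing: single-boundary-
site moves that never empty or disconnect a group, geometric cooling
T ← 0.95·T with T₀ set from the median sampled |ΔF_CT| so initial
acceptance ≈ 0.8, stop after 50 moveless sweeps, best of `n_restarts`
random contiguous starts. On every enumerable fixture (≤ 9 sites) the
annealer is required — by test — to match exhaustive search exactly. Ties
in the F_CT(K) profile resolve to the smaller K.

**Neutrality.** Tajima's D uses the standard a₁…e₂ constants. Fu's F_S
computes S′ = Pr(K ≥ k_obs) under the Ewens sampling distribution with
θ̂ = mean pairwise differences; unsigned Stirling numbers of the first
kind are carried in log space through their recurrence (n = 99 overflows
exact integers), cross-checked against exact rational arithmetic for
n ≤ 12. p-values are empirical, from ≥1000 coalescent replicates
conditioned on (n, θ̂): two-tailed for D, one-tailed (low) for F_S, with
the conventional 0.02 significance threshold for F_S noted in reports.
Conditioning on θ̂ rather than on S follows the cited software's approach
for F_S and is applied to D as well for internal consistency.

**Mismatch expansion model.** F_i(τ,θ₀,θ₁) = F̂_i(θ₁) +
e^(−τ/θ₁) Σ_j Pois(j; τ)[F̂_{i−j}(θ₀) − F̂_{i−j}(θ₁)], F̂_i(θ) =
θ^i/(1+θ)^{i+1}. The vector is truncated at i_max = (max observed
difference) + 10 and reported raw (it sums to 1 − truncation mass); the
fitter renormalizes. Fitting minimizes the SSD on frequencies over a
deterministic grid (τ ∈ 0…20 step 0.25, θ on log grids) refined by
Nelder–Mead in a squared reparameterization that enforces τ, θ₀ ≥ 0 and
θ₀ ≤ θ₁ ≤ θ₀ + 10⁵ — the cap sits in the flat star-genealogy limit where
θ₁ is unidentifiable. CIs are parametric bootstrap (default 500 coalescent
datasets under the fitted model, refit, 2.5/97.5 percentiles of τ).
Dating uses t = τ/(2u) with u = μ_site·L·g per locus per generation, so t
is in generations and t·g in years; this unit reading reproduces both
headline numbers (≈91,000 generations and ≈182,000 years at τ = 1.61)
self-consistently.

**Mantel.** r is the Pearson correlation of off-diagonal entries; the
permutation test jointly permutes rows/columns of the second matrix,
one-tailed positive (isolation by distance predicts positive correlation),
ties counted as extreme, +1 smoothing. Default 10,000 permutations; the
default comparison is population-level Φ_ST against centroid distances
(four labels give six pairs — few, as in the study design).

**Divergence dating.** Rates are calibrated as μ = d/(2T_cal) from the
14 Myr sister-species split (yielding 2.1×10⁻⁹, 5.7×10⁻⁹ and 4×10⁻¹⁰ for
the three usable markers) and combined as the geometric mean U. The
split-time estimator is rejection-ABC under the two-population isolation
model with migration fixed at zero: θ_A, θ_B, θ_anc ~ U(0, θ_max) and
t ~ U(0, t_max), time in expected substitutions per site per lineage so
that T = t/U needs no locus-length bookkeeping. Summaries are (π_A, π_B,
d_xy, S_A, S_B, Φ_ST), normalized by their prior-predictive standard
deviations; the closest `accept_frac` of simulations is kept (≥200
required). θ_max defaults to 10× the larger observed π and t_max to 3× the
net-divergence point estimate t̂ = d_a/2 (with floors for degenerate
data); a warning fires if the posterior mode lands within 10% of t_max.
The mode is the argmax of a Gaussian KDE (Silverman bandwidth) and the
HPD the shortest interval holding 95% of the sorted sample. The original
genealogy-sampling MCMC approach to the same isolation model is replaced,
not reimplemented: the inference target (mode + 95% HPD of t, converted by
T = t/U) is identical, and the ABC version is transparent and testable at
desk scale. `net_divergence_time` (d_a = d_xy − (π_A+π_B)/2, T = d_a/2U,
negative d_a clamped with a warning) provides the fast cross-check.

## Problem sizes used in the test suite

Statistical checks run at sizes chosen to keep the full suite respectably
quick while leaving each assertion well-powered: SAMOVA-vs-exhaustive on
50 random 5–7-site fixtures; neutrality type-I error over 500 replicates
with 200-replicate nulls; ABC coverage over 50 replicates of 20+20
samples at 10⁴ simulations each (2% acceptance — the smallest fraction
compatible with the 200-sample posterior minimum); mismatch-τ recovery
over 100 replicates of n = 100. The pipeline defaults are larger
(10⁴–10⁵ ABC simulations, 500 bootstrap refits, 10⁴ permutations).

## Known limitations

* Single-locus inference is intrinsically noisy: one mitochondrial
  genealogy is one draw. Per-replicate orderings of Φ_ST across deme
  pairs flip often even when the expected ordering is correct (the tests
  assert the mean-level ordering); divergence-time HPDs are wide, as they
  should be.
* Φ_ST and F_CT are undefined on monomorphic data (zero total variance);
  such cases return NaN (AMOVA) or 0 (pairwise screen) and are flagged.
* The secondary-contact screen assumes the transplanted haplotype's home
  deme retains close relatives of it; a fully monomorphic shared source
  deme yields no divergence evidence and its residents are not flagged.
* The mismatch model's θ₁ is unidentifiable beyond the star limit (capped);
  τ is the only parameter dated.
* ABC priors are uniform and data-scaled; a posterior piling up at t_max
  signals the prior bound, not the data, and triggers a warning rather
  than automatic re-running.
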