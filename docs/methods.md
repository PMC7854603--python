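# Methods

## The linked-equilibrium assembly model

The core of the package is an equilibrium species model for a dNTP
triphosphohydrolase (SAMHD1) whose oligomeric state is coupled to three
ligand classes: GTP at the allosteric A1 site, dNTP at the adjacent A2
site, and short phosphorothioate-containing oligonucleotides that occupy an
A1/A2 pair shared between two monomers. The species set is

| species | protomers | oligos | nucleotides |
|---------|-----------|--------|-------------|
| M       | 1         | 0      | 0           |
| D       | 2         | 0      | 0           |
| DX      | 2         | 1      | 0           |
| T0      | 4         | 0      | 4 GTP + 4 dNTP |
| T1      | 4         | 1      | 3 GTP + 3 dNTP |

The source observations are qualitative (saturation stoichiometries,
competitive shifts, salt-tolerance contrasts); the model forms here are the
package's own minimal formalizations chosen to reproduce them, and the
default constants are a qualitative regime, not measurements:

* **Anti-cooperativity is structural.** No species carries a second
  oligonucleotide. This single assumption produces both saturation
  plateaus: 1 oligo : 2 protomers when only dimers form, 1 : 4 when
  nucleotides drive tetramerization and the bound pool is the
  mixed-occupancy tetramer T1.
* **Nucleotide gate.** Tetramerization is scaled by
  φ = (θ_GTP · θ_dNTP)^h, where θ are single-site saturations of the A1/A2
  sites (both with dissociation constant `kd_gtp`) and h = `ntp_hill`
  (default 4, one factor per A1/A2 pair in the tetramer). Both activators
  are required, as observed; with either total at zero no tetramer exists.
* **Competition.** Free GTP competes with the oligonucleotide at the
  composite site: both oligo dissociation constants are multiplied by
  F = 1 + g/`kd_gtp`. Applying the same factor on the dimer and the
  tetramer route keeps the thermodynamic cycle closed: the implied
  constant for DX + D ⇌ T1 equals `kd_tet`·`kd_oligo_tet`/`kd_oligo`
  for every GTP level, and is deliberately not an independent parameter.
  dNTP contributes to the gate but not to F; with the concentrations used
  here (GTP and dNTP equal) the distinction is cosmetic, and a single
  competition constant keeps the apparent-Kd law identical to the
  closed-form `apparent_kd_competitive`.
* **Nucleotide bookkeeping.** T0 sequesters 4 GTP + 4 dNTP, T1 3 + 3.
  This makes the GTP/dNTP balances real constraints (they matter when the
  nucleotide totals approach the protein concentration) while staying
  consistent with the gate: tetramers only exist when both activators are
  present, so no species ever holds a ligand whose total is zero.
* **Residual activity.** The mixed tetramer T1 retains `alpha_residual`
  (default 0.2) of T0's catalytic activity, the plateau observed when
  bound oligonucleotide saturates. It is defined per-tetramer; whether the
  experimental ~20 % is per-tetramer or pool-weighted is not determined by
  the available observations, and the pool-weighted rate is what
  `activity_rate(..., params=..., protein_total=...)` reports.

### Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| `kd_oligo` | oligo ⇌ dimer composite site | µM | 0.1 |
| `kd_gtp` | GTP/dNTP ⇌ A1/A2 site | µM | 5 |
| `kd_dimer` | 2M ⇌ D | µM | 50 |
| `kd_tet` | 2D ⇌ T0 (gated) | µM | 0.01 |
| `kd_oligo_tet` | oligo ⇌ T0 | µM | 0.1 |
| `ntp_hill` | gate exponent | — | 4 |
| `alpha_residual` | T1 activity / T0 activity | — | 0.2 |
| `z_salt`, `kd_ref_salt` | counterion-release salt law | —, M | 0, 0.1 |

The salt law log Kd = log Kd_ref + z·log([salt]/[salt]_ref) encodes the
phosphodiester/phosphorothioate contrast: z > 0 reproduces the
salt-sensitive electrostatic regime, z = 0 the salt-tolerant
sequence-specific regime.

### Solver

The four mass balances are reduced to nested one-dimensional bracketed
root solves. The oligo balance is linear in free oligo given the other
free concentrations (every oligo-bearing species is first order in x), so
free oligo is eliminated in closed form — an exact step, not an
approximation. Free monomer is found by Brent iteration on the protomer
balance over [0, protein_total]; free GTP and dNTP by nested Brent
iteration on their balances over [0, total]. Each balance is monotone in
its own free concentration and changes sign across the bracket, so the
unique equilibrium is always found; outputs are verified to 1e−9 relative
mass balance and a `ConvergenceError` carries the final residual
otherwise. Degenerate totals (zero protein, zero ligand) short-circuit.

The test suite checks this solver against an independently coded
brute-force reference: doubly nested sign-based plain bisection for
(monomer, oligo) with a damped fixed point for nucleotide depletion.

## Titration fitting

* **Saturation anisotropy.** r = r_free + (r_bound − r_free)·f_b with f_b
  from the exact ligand-depletion quadratic (probe 0.05 µM by default);
  a simple hyperbola is a special case users can emulate by setting the
  probe concentration to zero-depletion levels. Starting values are
  grid-seeded (log-spaced Kd over 1e−3…1e3 µM) and refined by
  trust-region least squares; the lowest residual sum of squares wins, so
  no manual initialization exists. Fits whose transition lies outside the
  titrated range (fitted Kd > 10× the largest concentration) or whose
  amplitude is under 5× the residual noise are flagged `converged=False`
  ("no binding transition") rather than reported.
* **Competition panels** share Kd and K_GTP across series via the
  apparent-Kd law; **activation panels** share kcat, EC50_GTP, K_i and the
  Hill coefficient, with per-series EC50_app = EC50·(1 + oligo/K_i).
  Per-series free-kcat refits and their relative spread are reported as
  the kcat-invariance diagnostic.
* **Uncertainty** comes from seeded residual-resampling bootstrap
  (n_boot = 500 default; the emulated experiments report only duplicate
  standard deviations, which cannot support analytic intervals). Results
  are deterministic given the seed.
* **Progress curves** are reduced to an initial rate over the early
  window (product fraction < 0.3, reported and adjustable). With ≥ 5
  points in the window a quadratic is fitted and its t = 0 slope
  reported; a straight chord over a saturating curve is biased low by
  ~15 % at this cutoff, while the quadratic's truncation bias is under
  1 %. Windows of 3–4 points fall back to a straight line.

## Dual-wavelength stoichiometry

Species windows are centred on the monomer/dimer/tetramer markers
(half-width defaults: 0.75 mL SEC, 1.5 S AUC) and truncated at midpoints
between adjacent markers when they would overlap. Integration is
trapezoidal after subtracting a straight baseline anchored on the mean of
a short segment (5 % of the window, ≥ 3 samples) at each end — exact for
constant offsets and linear drifts, robust to single-sample noise.
The 495-nm channel sees only the 6FAM label; 6FAM also absorbs at 280 nm,
so mol_protein = (A280 − c·A495)/ε280 with crosstalk c = 0.3 by default
(typical fluorescein spectrum; the emulated study treated the channels as
independent and states no correction, so c is configurable, including 0).
All molar quantities are relative; only ratios are reported.

## Family census

PSIBLAST/HHpred-scale searching is out of scope; classification instead
uses in-package position-specific log-odds profiles (pseudocount 0.5 over
the 20 amino acids, uniform background, gap-majority columns excluded)
scored by local alignment with affine gaps (open 4 bits, extend 0.25
bits). The dynamic programming is row-vectorized; the within-row
gap-in-profile state is resolved by a prefix-max transform that is exact
for open ≥ extend. E-values are calibrated per profile on ≥ 100 random
background sequences whose best local scores are fitted to an
extreme-value (Gumbel) distribution; E(S) = k·e^(−λS) with k = e^(λµ). A
sequence is assigned to a family only when its log10 E-value margin is at
least 18 decades (the survey's "factor of at least 10^18" rule); smaller
margins are `ambiguous`.

Members whose aligned profile coverage is below 0.7 are flagged truncated;
they stay in the census but are excluded from alignments and logos (the
survey excluded them from its final alignment and is silent on census
inclusion; the threshold is a switch). The census counts families per
taxon (1-based depth from domain) over circular chromosomes longer than
200,000 bp only; per-chromosome copy numbers (0, 1, 2, 3+) are a side
table. Pairwise identity is global-alignment identity with free end gaps,
normalized by the shorter sequence; thinning greedily keeps one
representative per 70 %-identity group, visiting sequences by descending
length with lexicographic accession tie-break (deterministic). Logo
information content is log2 20 minus the gap-excluded column entropy,
letter heights frequency·IC·occupancy; the optional small-sample
correction subtracts 19/(2·ln2·n), floored at zero. Structure residues
within 5 Å (inclusive) of a ligand group — any heavy atom to any ligand
atom — are annotated via a k-d tree and mapped onto alignment columns by
global alignment to the highest-identity row (failure below 0.3
identity).

## Synthetic data

The generators emulate the study conditions: probe 50 nM; protein sweeps
log-spaced to 50 µM in duplicate (12 concentrations); ~5 µM protein in
stoichiometry titrations; 50 µM GTP + 50 µM dNTP; GTP competition levels
{0, 50, 200, 1000} µM; a tenfold Rp/Sp affinity ratio for the stereoisomer
pair; SEC species at 12/14.5/16.5 mL and AUC species at S ≈ 6 (dimer) and
S ≈ 10 (tetramer). Noise is additive and homoscedastic per readout
(anisotropy σ = 0.005; rates 3 % of kcat; traces 0.2 % of each channel's
full scale, each detector channel autoranged, an empty channel carrying
floor-level instrument noise), matching the only error information the
emulated experiments provide. Peaks are symmetric Gaussians — species are
resolved in the emulated data and no asymmetry information exists.
Architectural trace scenarios set species ratios from the model (dimer
0.5, mixed tetramer 0.25) unless overridden. The family generator mutates
two independent random consensus sequences (length 220, per-site
substitution 0.12, giving within-family identity ≈ 0.77 vs between-family
≈ 0.1), truncates 15 % of members at the N or C terminus, biases taxonomy
draws per family (Firmicutes-leaning vs Proteobacteria-leaning, 85 %
bias), and assigns members to chromosomes with copy numbers 0–3 and a
length/topology mix straddling the 200 kb circular filter. Toy structures
are extended backbones with HETATM ligand groups at constructed
distances, the far-ligand variant > 50 Å from every residue.

Every generator is deterministic per seed (independent substreams per
scenario) and writes its truth to a manifest; recovery tests read truth
only from manifests.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: heteroscedastic or correlated detector noise,
asymmetric/tailing chromatographic peaks, baseline drift beyond linear,
indel evolution within families (substitutions only, so family members
align without gaps), phylogenetic correlation between members, or real
secondary-structure geometry in the toy structures.

## Numerical choices and limitations

* Solver tolerances: Brent at machine precision, residual gate 1e−9
  relative, iteration cap 200 per bracketed solve.
* Fit tie-breaks: lowest rss wins across grid starts; bootstrap intervals
  are percentile (2.5/97.5) and clamped to contain the point estimate.
* Problem sizes: the recovery studies in the test suite use 100 seeded
  repeats for point-estimate tolerances and 25–40 repeats for bootstrap
  coverage; the solver-vs-oracle comparison uses 50 random draws. These
  sizes give binomial noise well below the margins being asserted.
* Equilibrium only: no kinetics of assembly, no hydrodynamic prediction
  of sedimentation coefficients; traces are treated as species-resolved.
* The observed dimer ratio of 0.59 (vs the architectural 0.5) is treated
  as a generator setting for recovery tests, not something the model
  attempts to explain (a second weak site and quantification bias are
  both compatible with it).
* The census does not reproduce the survey's manual truncation of search
  lists, tree building, or the original counts (those require the 2018
  complete-genome protein library); it reproduces the decision rules.
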