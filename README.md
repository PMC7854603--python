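# samlink

Quantitative models and analysis pipelines for ligand-linked SAMHD1
oligomerization and the prokaryotic HD-domain dNTPase family survey.

SAMHD1 is a dNTP triphosphohydrolase and retroviral restriction factor whose
quaternary state is coupled to ligand occupancy of its allosteric sites: GTP
(site A1) and dNTP (site A2) drive assembly of the catalytically active
tetramer, while short phosphorothioate-containing oligonucleotides bind
across an A1/A2 site pair shared between two monomers, promote dimerization,
and compete with the nucleotide activators. `samlink` is written for
biophysicists and structural bioinformaticians who want to fit and simulate
the quantitative observations of this system — binding isotherms,
competition and activation panels, dual-wavelength stoichiometry, and the
two-family census of prokaryotic HD-domain dNTPases — against a single
explicit equilibrium model.

## The model

Species (µM of species, protomer counts in parentheses): free monomer M (1),
dimer D (2), oligo-bound dimer DX (2, one oligonucleotide), fully
GTP/dNTP-loaded tetramer T0 (4), and the mixed-occupancy tetramer T1 (4, one
oligonucleotide displacing one A1/A2 pair). With free concentrations *m*,
*x*, *g*, *n*:

    D  = m²/K_dimer
    DX = D·x / (K_oligo·F),          F = 1 + g/K_GTP        (competition)
    T0 = φ·D²/K_tet,                 φ = (θ_GTP·θ_dNTP)^h   (NTP gate)
    T1 = T0·x / (K_oligo,tet·F)

Anti-cooperativity is structural — no species carries a second
oligonucleotide — so the bound oligo : protomer ratio saturates at **1:2**
without nucleotides (all-DX) and at **1:4** with them (all-T1), and the
thermodynamic cycle for T1 formation closes identically
(K(DX+D⇌T1) = K_tet·K_oligo,tet/K_oligo). The mixed tetramer retains a
residual catalytic activity α (default 0.2) relative to T0. All four mass
balances (protomer, oligo, GTP, dNTP) are solved to 1e−9 relative by
bracketed monotone root finding.

Around the core model the package provides: exact ligand-depletion
anisotropy fitting with grid-seeded starts and residual-resampling
bootstrap; global competitive (shared Kd, K_GTP) and Hill-activation
(shared kcat — the "EC50 shifts, kcat does not" signature) fits;
dual-wavelength (280/495 nm) SEC/AUC peak integration and 6FAM crosstalk
unmixing; and a census pipeline that classifies sequences into the
SAMHD1-like and Dgt-like families by position-specific log-odds scoring
with Gumbel-calibrated E-values (log10 margin ≥ 18 decades), tabulates them
over taxonomy on circular chromosomes > 200 kb, thins alignments at 70 %
identity, computes sequence logos, and colors columns by ≤ 5 Å ligand
proximity in a structure.

Every consumed input can be produced by `samlink.synthetic_data` with a
machine-readable truth manifest, so the full pipeline is testable without
downloads.

## Worked example

```python
from samlink import BindingParams, GeneratorConfig, solve_assembly, fit_kd_anisotropy
from samlink.synthetic_data import gen_fa_titration, gen_multiwavelength_trace
from samlink.stoichiometry_quant import assign_species, quantify_species

# 1. stoichiometry regimes of the assembly model
dimer = solve_assembly(5, 500, 0, 0, BindingParams(kd_oligo=1e-3, kd_dimer=1.0, kd_tet=1e12))
tet = solve_assembly(5, 500, 50, 50, BindingParams(kd_tet=1e-6, kd_oligo_tet=1e-3))
print(f"bound oligo per protomer, no NTPs:   {dimer.bound_ratio:.3f}")
print(f"bound oligo per protomer, with NTPs: {tet.bound_ratio:.3f}")

# 2. Kd recovery from a synthetic anisotropy titration (probe 50 nM)
cfg = GeneratorConfig(seed=7)
series, truth = gen_fa_titration(cfg)
fit = fit_kd_anisotropy(series, n_boot=200, seed=0)
print(f"fitted Kd: {fit.estimates['kd']:.3f} uM "
      f"(95% CI {fit.ci_low['kd']:.3f}-{fit.ci_high['kd']:.3f}; truth {truth['kd']})")

# 3. dual-wavelength tetramer stoichiometry from a synthetic AUC profile
trace, man = gen_multiwavelength_trace(cfg, "auc_with_ntp")
w = assign_species(trace)
q = quantify_species(trace, w["tetramer"], man["eps280"], man["eps495"],
                     man["fam_crosstalk_280"])
print(f"AUC tetramer oligo:protein ratio: {q.ratio:.3f}")
```

prints

```
bound oligo per protomer, no NTPs:   0.500
bound oligo per protomer, with NTPs: 0.249
fitted Kd: 0.192 uM (95% CI 0.163-0.227; truth 0.2)
AUC tetramer oligo:protein ratio: 0.250
```

The first two lines are the architectural saturation stoichiometries (1:2
dimer mode, 1:4 mixed-tetramer mode); the third shows parameter recovery at
the assay's noise level; the last recovers the one-oligo-per-tetramer ratio
from a noisy two-channel sedimentation profile.

A `samlink` command-line interface wraps the same functions
(`samlink simulate`, `fit-kd`, `fit-competition`, `fit-activation`,
`fit-rate`, `stoich`, and `census classify|count|thin|logo|proximity`); run
`samlink --help` for details.

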