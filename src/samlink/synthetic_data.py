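"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here, emulating
the study's experiment classes:

* fluorescence-anisotropy saturation titrations (protein titrated into a
  50 nM 6FAM-labelled oligonucleotide probe), optionally as an Rp/Sp
  stereoisomer pair with a tenfold affinity ratio;
* GTP competition panels and GTP activation (rate) panels;
* NMR-style hydrolysis progress curves, including a catalytically dead
  (D311A-regime) flat curve;
* two-channel (280/495 nm) SEC chromatograms and AUC sedimentation profiles
  with per-species oligo:protein ratios — architectural scenarios place the
  dimer at 1 oligo : 2 protomers (0.5) and the mixed-occupancy tetramer at
  1 : 4 (0.25);
* two divergent protein families with taxonomy / chromosome metadata for the
  census pipeline;
* toy PDB structures with ligand-contact residues known by construction.

Every generator is deterministic per seed and returns a machine-readable
truth manifest alongside the data; recovery tests read truth only from the
manifest.  Noise is additive and homoscedastic per readout, matching the
only error information available for the emulated experiments (duplicate
standard deviations).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_models import (
    BindingParams,
    activity_rate,
    apparent_kd_competitive,
    solve_single_site,
)
from .dntpase_census import (
    AMINO_ACIDS,
    AnnotatedSequence,
    ChromosomeRecord,
)
from .stoichiometry_quant import DEFAULT_CROSSTALK_280, MultiwavelengthTrace
from .titration_fitting import TitrationSeries

__all__ = [
    "GeneratorConfig",
    "gen_fa_titration",
    "gen_stereo_pair",
    "gen_competition_panel",
    "gen_activation_panel",
    "gen_progress_curves",
    "gen_multiwavelength_trace",
    "gen_family_dataset",
    "gen_toy_structure",
    "write_structure_pdb",
    "write_manifest",
]


@dataclass
class GeneratorConfig:
    """All generator truth values and noise levels, with study defaults.

    Concentrations mirror the emulated experiments: 50 nM probe, ~5 µM
    protein in the stoichiometry titrations, 50 µM GTP + 50 µM dNTP.
    """

    seed: int = 0

    # --- anisotropy titrations -------------------------------------------
    kd_true: float = 0.2          # µM
    rp_sp_kd_ratio: float = 10.0  # Sp binds tenfold weaker than Rp
    r_free: float = 0.05
    r_bound: float = 0.20
    probe_uM: float = 0.05
    n_titration_points: int = 12
    protein_range: tuple = (1e-3, 50.0)  # µM, log-spaced sweep
    aniso_sigma: float = 0.005

    # --- competition ------------------------------------------------------
    kd_gtp_true: float = 5.0      # µM
    gtp_levels: tuple = (0.0, 50.0, 200.0, 1000.0)

    # --- activation -------------------------------------------------------
    kcat_true: float = 1.0        # relative units
    ec50_gtp_true: float = 20.0   # µM
    ki_oligo_true: float = 5.0    # µM
    hill_true: float = 2.0
    oligo_levels: tuple = (0.0, 5.0, 20.0)
    gtp_range: tuple = (0.5, 2000.0)
    n_rate_points: int = 12
    rate_sigma_frac: float = 0.03

    # --- progress curves --------------------------------------------------
    progress_rate_true: float = 0.02   # fraction / min initial slope
    progress_f_inf: float = 0.95
    progress_t_max: float = 60.0       # min
    progress_n_points: int = 25
    progress_sigma: float = 0.01

    # --- binding/assembly truth ------------------------------------------
    binding: BindingParams = field(default_factory=BindingParams)

    # --- multiwavelength traces ------------------------------------------
    trace_sigma_frac: float = 0.002    # of full scale, per channel
    eps280: float = 1.0                # signal per relative protomer mol
    eps495: float = 0.8                # signal per relative oligo mol
    fam_crosstalk_280: float = DEFAULT_CROSSTALK_280
    sec_axis: tuple = (8.0, 20.0, 0.01)       # mL: start, stop, step
    sec_markers: dict = field(
        default_factory=lambda: {"tetramer": 12.0, "dimer": 14.5, "monomer": 16.5}
    )
    sec_peak_sigma: float = 0.22       # mL
    auc_axis: tuple = (2.0, 14.0, 0.01)       # Svedberg
    auc_markers: dict = field(default_factory=lambda: {"dimer": 6.0, "tetramer": 10.0})
    auc_peak_sigma: float = 0.45       # S

    # --- family dataset ---------------------------------------------------
    n_per_family: int = 40
    family_seq_length: int = 220
    substitution_rate: float = 0.12
    truncation_fraction: float = 0.15
    n_empty_chromosomes: int = 4

    # --- toy structure ----------------------------------------------------
    structure_n_residues: int = 30

    def rng(self, *tags: int) -> np.random.Generator:
        """Independent, reproducible stream per generator."""
        return np.random.default_rng([self.seed, *tags])

    def manifest_base(self) -> dict:
        return {"seed": self.seed}


# ---------------------------------------------------------------------------
# titrations


def _protein_sweep(config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.protein_range
    pts = np.geomspace(lo, hi, config.n_titration_points)
    return np.repeat(pts, 2)  # duplicates, as in the emulated assays


def gen_fa_titration(
    config: GeneratorConfig,
    kd: float | None = None,
    sigma: float | None = None,
    gtp_uM: float = 0.0,
    stream: int = 0,
) -> tuple[TitrationSeries, dict]:
    """Saturation anisotropy titration of protein into a fixed probe."""
    if config.n_titration_points < 1:
        raise ValueError("zero-length titration sweep")
    kd_true = config.kd_true if kd is None else kd
    sig = config.aniso_sigma if sigma is None else sigma
    kd_app = apparent_kd_competitive(kd_true, gtp_uM, config.kd_gtp_true) if gtp_uM else kd_true
    x = _protein_sweep(config)
    fb = np.array([solve_single_site(p, config.probe_uM, kd_app) for p in x])
    y = config.r_free + (config.r_bound - config.r_free) * fb
    rng = config.rng(1, stream, int(gtp_uM * 1000))
    y = y + rng.normal(0.0, sig, size=y.shape) if sig > 0 else y
    series = TitrationSeries(
        x=x,
        y=y,
        y_err=np.full_like(x, sig) if sig > 0 else None,
        condition={"probe_uM": config.probe_uM, "gtp_uM": gtp_uM},
    )
    manifest = {
        **config.manifest_base(),
        "kd": kd_true,
        "kd_apparent": kd_app,
        "gtp_uM": gtp_uM,
        "r_free": config.r_free,
        "r_bound": config.r_bound,
        "probe_uM": config.probe_uM,
        "sigma": sig,
    }
    return series, manifest


def gen_stereo_pair(config: GeneratorConfig) -> dict:
    """Rp/Sp paired titrations with a tenfold Kd ratio (Rp tighter)."""
    rp, man_rp = gen_fa_titration(config, kd=config.kd_true, stream=11)
    sp, man_sp = gen_fa_titration(
        config, kd=config.kd_true * config.rp_sp_kd_ratio, stream=12
    )
    return {"Rp": (rp, man_rp), "Sp": (sp, man_sp)}


def gen_competition_panel(
    config: GeneratorConfig, sigma: float | None = None
) -> tuple[list[TitrationSeries], dict]:
    """One titration per GTP level; midpoints shift per the competitive law."""
    panel, apparent = [], {}
    for gtp in config.gtp_levels:
        s, m = gen_fa_titration(config, sigma=sigma, gtp_uM=gtp, stream=2)
        panel.append(s)
        apparent[gtp] = m["kd_apparent"]
    manifest = {
        **config.manifest_base(),
        "kd": config.kd_true,
        "kd_gtp": config.kd_gtp_true,
        "gtp_levels": list(config.gtp_levels),
        "probe_uM": config.probe_uM,
        "kd_apparent": apparent,
        "sigma": config.aniso_sigma if sigma is None else sigma,
    }
    return panel, manifest


def gen_activation_panel(
    config: GeneratorConfig, sigma_frac: float | None = None
) -> tuple[list[TitrationSeries], dict]:
    """Rate-vs-GTP series per oligonucleotide level.

    Plateaus (kcat) are identical across oligo levels; the apparent EC50
    shifts by (1 + oligo / ki_oligo) — the competitive signature.
    """
    sf = config.rate_sigma_frac if sigma_frac is None else sigma_frac
    gtp = np.geomspace(*config.gtp_range, config.n_rate_points)
    panel = []
    for k, oligo in enumerate(config.oligo_levels):
        rates = np.array(
            [
                activity_rate(
                    g,
                    oligo,
                    kcat=config.kcat_true,
                    ec50_gtp=config.ec50_gtp_true,
                    ki_oligo=config.ki_oligo_true,
                    hill=config.hill_true,
                )
                for g in gtp
            ]
        )
        rng = config.rng(3, k)
        noise = rng.normal(0.0, sf * config.kcat_true, size=rates.shape) if sf > 0 else 0.0
        panel.append(
            TitrationSeries(
                x=gtp,
                y=rates + noise,
                condition={"oligo_uM": oligo},
            )
        )
    manifest = {
        **config.manifest_base(),
        "kcat": config.kcat_true,
        "ec50_gtp": config.ec50_gtp_true,
        "ki_oligo": config.ki_oligo_true,
        "hill": config.hill_true,
        "oligo_levels": list(config.oligo_levels),
        "sigma_frac": sf,
    }
    return panel, manifest


def gen_progress_curves(
    config: GeneratorConfig, sigma: float | None = None
) -> tuple[dict, dict]:
    """Saturating-exponential product curves plus a dead-enzyme flat curve.

    product(t) = f_inf (1 - exp(-k t)) with k chosen so the analytic initial
    slope f_inf * k equals the configured rate.  Returns
    ({name: DataFrame(time_min, product_fraction)}, manifest).
    """
    sig = config.progress_sigma if sigma is None else sigma
    t = np.linspace(0.0, config.progress_t_max, config.progress_n_points)
    k = config.progress_rate_true / config.progress_f_inf
    curves, truth = {}, {}
    for name, rate in (("active", config.progress_rate_true), ("dead", 0.0)):
        if rate > 0:
            f = config.progress_f_inf * (1.0 - np.exp(-k * t))
        else:
            f = np.zeros_like(t)
        rng = config.rng(4, 0 if rate > 0 else 1)
        if sig > 0:
            f = np.clip(f + rng.normal(0.0, sig, size=f.shape), 0.0, 1.0)
        curves[name] = pd.DataFrame({"time_min": t, "product_fraction": f})
        truth[name] = {"initial_rate": rate, "f_inf": config.progress_f_inf if rate else 0.0}
    manifest = {**config.manifest_base(), "sigma": sig, "curves": truth}
    return curves, manifest


# ---------------------------------------------------------------------------
# multiwavelength traces


#: per-scenario species composition: protomer fractions and oligo:protomer
#: ratios from the one-oligo-per-dimer / one-oligo-per-tetramer architecture
_SCENARIOS = {
    "protein_only": {
        "axis": "sec",
        "species": {"monomer": {"protomer_frac": 1.0, "ratio": 0.0}},
    },
    "sec_no_ntp": {
        "axis": "sec",
        "species": {
            "monomer": {"protomer_frac": 0.25, "ratio": 0.0},
            "dimer": {"protomer_frac": 0.75, "ratio": 0.5},
        },
    },
    "sec_with_ntp": {
        "axis": "sec",
        "species": {
            "monomer": {"protomer_frac": 0.15, "ratio": 0.0},
            "tetramer": {"protomer_frac": 0.85, "ratio": 0.25},
        },
    },
    "auc_with_ntp": {
        "axis": "auc",
        "species": {
            "dimer": {"protomer_frac": 0.4, "ratio": 0.5},
            "tetramer": {"protomer_frac": 0.6, "ratio": 0.25},
        },
    },
}


def gen_multiwavelength_trace(
    config: GeneratorConfig,
    scenario: str = "auc_with_ntp",
    ratios: dict | None = None,
    sigma_frac: float | None = None,
    total_protomer: float = 5.0,
) -> tuple[MultiwavelengthTrace, dict]:
    """Two-channel trace as a sum of Gaussian species peaks plus noise.

    Peak areas follow the species composition: the 495-nm area of a species
    is eps495 * (ratio * protomer moles); its 280-nm area is
    eps280 * protomer moles plus the 6FAM crosstalk contribution.
    ``ratios`` overrides the architectural per-species oligo:protomer
    ratios.  The truth manifest records every configured quantity.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(_SCENARIOS)}")
    spec = _SCENARIOS[scenario]
    kind = spec["axis"]
    start, stop, step = config.sec_axis if kind == "sec" else config.auc_axis
    markers = dict(config.sec_markers if kind == "sec" else config.auc_markers)
    peak_sigma = config.sec_peak_sigma if kind == "sec" else config.auc_peak_sigma
    sf = config.trace_sigma_frac if sigma_frac is None else sigma_frac

    axis = np.arange(start, stop + step / 2, step)
    a280 = np.zeros_like(axis)
    a495 = np.zeros_like(axis)
    truth_species = {}
    min_sep = 4.0 * peak_sigma
    centres = sorted(markers[s] for s in spec["species"])
    warn_overlap = any(b - a < min_sep for a, b in zip(centres, centres[1:]))
    for name, comp in spec["species"].items():
        centre = markers[name]
        ratio = comp["ratio"] if ratios is None else ratios.get(name, comp["ratio"])
        protomer = comp["protomer_frac"] * total_protomer
        oligo = ratio * protomer
        area280 = config.eps280 * protomer + config.fam_crosstalk_280 * config.eps495 * oligo
        area495 = config.eps495 * oligo
        shape = np.exp(-0.5 * ((axis - centre) / peak_sigma) ** 2) / (
            peak_sigma * np.sqrt(2.0 * np.pi)
        )
        a280 += area280 * shape
        a495 += area495 * shape
        truth_species[name] = {
            "centre": centre,
            "ratio": ratio,
            "protomer_mol": protomer,
            "oligo_mol": oligo,
            "area280": area280,
            "area495": area495,
        }
    rng = config.rng(5, list(_SCENARIOS).index(scenario))
    if sf > 0:
        # each detector channel is autoranged: noise scales with its own
        # full scale; an empty channel still carries instrument noise
        full280 = max(a280.max(), 1e-30)
        full495 = max(a495.max(), 0.05 * full280)
        a280 = a280 + rng.normal(0.0, sf * full280, size=axis.shape)
        a495 = a495 + rng.normal(0.0, sf * full495, size=axis.shape)
    trace = MultiwavelengthTrace(
        axis=axis, a280=a280, a495=a495, axis_kind=kind, markers=markers
    )
    manifest = {
        **config.manifest_base(),
        "scenario": scenario,
        "axis_kind": kind,
        "eps280": config.eps280,
        "eps495": config.eps495,
        "fam_crosstalk_280": config.fam_crosstalk_280,
        "peak_sigma": peak_sigma,
        "sigma_frac": sf,
        "total_protomer": total_protomer,
        "species": truth_species,
        "overlap_warning": warn_overlap,
    }
    return trace, manifest


# ---------------------------------------------------------------------------
# family dataset


_TAXA_A = [  # SAMHD1-like family leans Gram-positive (Firmicutes)
    ["Bacteria", "Firmicutes", "Bacilli"],
    ["Bacteria", "Firmicutes", "Clostridia"],
    ["Archaea", "Euryarchaeota", "Methanococci"],
]
_TAXA_B = [  # Dgt-like family leans Gram-negative (Proteobacteria)
    ["Bacteria", "Proteobacteria", "Gammaproteobacteria"],
    ["Bacteria", "Proteobacteria", "Alphaproteobacteria"],
    ["Bacteria", "Bacteroidetes", "Flavobacteriia"],
]
#: probability that a member of each family draws from its own taxon list
_TAXON_BIAS = 0.85


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for c in consensus:
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != c]
            out.append(choices[rng.integers(0, 19)])
        else:
            out.append(c)
    return "".join(out)


def gen_family_dataset(config: GeneratorConfig) -> tuple[list, list, dict]:
    """Two divergent protein families with genome/taxonomy metadata.

    Members derive from an independent random consensus per family by
    per-site substitution; a configured fraction is truncated at the N or C
    terminus (half the sequence removed).  Taxonomy draws are biased per
    family; chromosomes mix circular/linear topologies and lengths
    straddling the 200 kb census cutoff, with genomes carrying 0-3 members.
    Returns (sequences, chromosomes, truth) with per-accession true labels,
    truncation flags and chromosome assignments in ``truth``.
    """
    p = config.substitution_rate
    expected_within = (1.0 - p) ** 2 + p**2 / 19.0
    if expected_within < 0.30:
        raise ValueError(
            "substitution_rate too high: expected within-family identity "
            f"({expected_within:.2f}) no longer exceeds the between-family level"
        )
    rng = config.rng(6)
    consensus = {
        "family_a": _random_sequence(rng, config.family_seq_length),
        "family_b": _random_sequence(rng, config.family_seq_length),
    }

    # chromosome pool: lengths straddle 200 kb, mostly circular
    chromosomes: list[ChromosomeRecord] = []
    n_chrom = 2 * config.n_per_family + config.n_empty_chromosomes
    for i in range(n_chrom):
        length = int(rng.choice([120_000, 180_000, 250_000, 1_500_000, 4_000_000],
                                p=[0.08, 0.08, 0.24, 0.35, 0.25]))
        topology = "linear" if rng.random() < 0.1 else "circular"
        chromosomes.append(
            ChromosomeRecord(f"NC_{i + 1:06d}.1", length, topology)
        )
    # copy numbers 0..3 per carrying chromosome; empty ones stay at 0
    carrier_idx = list(range(n_chrom - config.n_empty_chromosomes))

    sequences: list[AnnotatedSequence] = []
    truth: dict = {
        "seed": config.seed,
        "consensus": consensus,
        "substitution_rate": p,
        "truncation_fraction": config.truncation_fraction,
        "labels": {},
        "truncated": {},
        "chromosome_of": {},
    }
    ci = 0
    counter = 0
    for fam, taxa, prefix in (
        ("family_a", _TAXA_A, "WP_A"),
        ("family_b", _TAXA_B, "WP_B"),
    ):
        for j in range(config.n_per_family):
            counter += 1
            seq = _mutate(rng, consensus[fam], p)
            truncated = bool(rng.random() < config.truncation_fraction)
            if truncated:
                half = len(seq) // 2
                seq = seq[half:] if rng.random() < 0.5 else seq[:half]
            taxonomy = list(
                taxa[rng.integers(0, len(taxa))]
                if rng.random() < _TAXON_BIAS
                else (_TAXA_B if fam == "family_a" else _TAXA_A)[
                    rng.integers(0, 3)
                ]
            )
            # walk the carrier chromosomes; occupancy 1-3 per chromosome
            chrom = chromosomes[carrier_idx[ci % len(carrier_idx)]]
            if rng.random() < 0.6:
                ci += 1  # ~40 % of carriers receive an extra copy
            acc = f"{prefix}{j + 1:06d}.1"
            sequences.append(
                AnnotatedSequence(
                    protein_acc=acc,
                    nucleotide_acc=chrom.nucleotide_acc,
                    taxonomy=taxonomy,
                    sequence=seq,
                )
            )
            truth["labels"][acc] = fam
            truth["truncated"][acc] = truncated
            truth["chromosome_of"][acc] = chrom.nucleotide_acc
    return sequences, chromosomes, truth


# ---------------------------------------------------------------------------
# toy structures


def gen_toy_structure(
    config: GeneratorConfig,
    far_ligand: bool = False,
    cutoff: float = 5.0,
):
    """Synthetic polypeptide chain with HETATM ligands at known distances.

    The chain is an extended backbone (N, CA, C, O per residue) along x.
    An "active-site" ligand (res_name TTP) is placed near one residue and
    an "allosteric" ligand (res_name GTP) near another; with
    ``far_ligand=True`` the allosteric group is instead displaced >50
    Angstrom from every residue, so its true contact set is empty.  Returns
    (biotite AtomArray, truth) where truth lists, per group, the residues
    with any heavy atom within ``cutoff`` of the group (computed by direct
    distance scan at generation time).
    """
    import biotite.structure as struc

    n = config.structure_n_residues
    rng = config.rng(7, int(far_ligand))
    atoms = []
    # backbone geometry: 3.8 A CA spacing, fixed intra-residue offsets
    offsets = {
        "N": np.array([-1.2, 0.6, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.5, 0.0]),
        "O": np.array([1.4, 1.7, 0.2]),
    }
    aa3 = ["ALA", "GLY", "SER", "LEU", "VAL"]
    coords, res_ids, res_names, atom_names, elements, hetero = [], [], [], [], [], []
    for i in range(n):
        base = np.array([3.8 * i, 2.0 * np.sin(i / 3.0), 0.0])
        res = aa3[i % len(aa3)]
        for name, off in offsets.items():
            coords.append(base + off)
            res_ids.append(i + 1)
            res_names.append(res)
            atom_names.append(name)
            elements.append(name[0])
            hetero.append(False)

    lig_specs = [("TTP", "active", n // 3), ("GTP", "allosteric", 2 * n // 3)]
    lig_res_id = n + 1
    for res_name, group, anchor in lig_specs:
        anchor_ca = np.array([3.8 * (anchor - 1), 2.0 * np.sin((anchor - 1) / 3.0), 0.0])
        if group == "allosteric" and far_ligand:
            centre = anchor_ca + np.array([0.0, 0.0, 120.0])
        else:
            centre = anchor_ca + np.array([0.0, 3.5, 0.0])
        for k in range(4):
            coords.append(centre + rng.normal(0.0, 0.4, size=3))
            res_ids.append(lig_res_id)
            res_names.append(res_name)
            atom_names.append(f"P{k + 1}")
            elements.append("P")
            hetero.append(True)
        lig_res_id += 1

    arr = struc.AtomArray(len(coords))
    arr.coord = np.array(coords, dtype=float)
    arr.res_id = np.array(res_ids)
    arr.res_name = np.array(res_names)
    arr.atom_name = np.array(atom_names)
    arr.element = np.array(elements)
    arr.hetero = np.array(hetero)
    arr.chain_id = np.array(["A"] * len(coords))

    # ground-truth contacts by direct all-pairs scan
    truth = {"seed": config.seed, "cutoff": cutoff, "contacts": {}}
    prot_mask = ~arr.hetero
    for res_name, group, _ in lig_specs:
        lig_coord = arr.coord[arr.hetero & (arr.res_name == res_name)]
        hits = set()
        for rid in range(1, n + 1):
            res_coord = arr.coord[prot_mask & (arr.res_id == rid)]
            d = np.linalg.norm(
                res_coord[:, None, :] - lig_coord[None, :, :], axis=-1
            )
            if (d <= cutoff).any():
                hits.add(rid)
        truth["contacts"][group] = sorted(hits)
    truth["ligands"] = {"active": ["TTP"], "allosteric": ["GTP"]}
    return arr, truth


def write_structure_pdb(atoms, path) -> None:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def write_manifest(manifest: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
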