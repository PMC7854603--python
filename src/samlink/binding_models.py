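"""Ligand-linked SAMHD1 oligomerization equilibria.

SAMHD1 is a dNTP triphosphohydrolase whose quaternary state is coupled to
ligand occupancy of its allosteric sites: GTP (site A1) and dNTP (site A2)
drive assembly of the catalytically active tetramer, while short
phosphorothioate-containing oligonucleotides bind across an A1/A2 site pair
shared between two monomers, promote dimerization, and compete with the
nucleotide activators.  This module defines an equilibrium species model that
formalizes those observations:

    M            free monomer
    D            dimer, allosteric composite site empty
    DX           dimer with one oligonucleotide bound (1 oligo : 2 protomers)
    T0           tetramer with all four A1/A2 pairs loaded with GTP/dNTP
    T1           mixed-occupancy tetramer: one pair displaced by an
                 oligonucleotide, three pairs loaded (1 oligo : 4 protomers)

Anti-cooperativity is encoded structurally: no species carries more than one
oligonucleotide, so the bound oligo : protomer ratio saturates at 1:2 without
nucleotides (all-DX) and at 1:4 with nucleotides (all-T1).

All concentrations are µM of the species (not protomer) unless stated.
Equilibrium relations, with free concentrations m (monomer), x (oligo),
g (GTP) and n (dNTP):

    D  = m^2 / kd_dimer
    DX = D x / (kd_oligo  * F)          F = 1 + g / kd_gtp   (GTP competition)
    T0 = phi * D^2 / kd_tet             phi = (theta1 * theta2)^ntp_hill
    T1 = T0 x / (kd_oligo_tet * F)      theta_i: A1 / A2 site saturation

The gate phi is a Hill factor on joint A1/A2 pair saturation; with the
default ntp_hill = 4 (four pairs per tetramer) tetramers require both GTP and
dNTP, as observed.  T0 sequesters 4 GTP + 4 dNTP, T1 sequesters 3 + 3 plus
one oligo, which makes all four mass balances (protomer, oligo, GTP, dNTP)
non-trivial.  Thermodynamic cycle closure for T1 formation (via DX + D or via
T0 + X) holds identically: the implied DX + D <=> T1 constant equals
kd_tet * kd_oligo_tet / kd_oligo and is not independently settable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "ConvergenceError",
    "UndefinedRatioError",
    "BindingParams",
    "AssemblyState",
    "solve_single_site",
    "apparent_kd_competitive",
    "salt_adjusted_kd",
    "solve_assembly",
    "stoichiometry_curve",
    "activity_rate",
]

#: relative mass-balance tolerance every solver output must satisfy
BALANCE_RTOL = 1e-9
#: absolute tolerance on balance functions during root bracketing
SOLVER_ATOL = 1e-12
#: iteration cap per bracketed root solve
SOLVER_MAXITER = 200


class DomainError(ValueError):
    """An input lies outside the physically meaningful domain."""


class ConvergenceError(RuntimeError):
    """The equilibrium solver failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final residual {residual:.3e})")
        self.residual = residual


class UndefinedRatioError(ZeroDivisionError):
    """A requested ratio has a zero denominator (e.g. fraction of no probe)."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class BindingParams:
    """Model constants for the linked-equilibrium assembly model.

    All dissociation constants are in µM.  ``alpha_residual`` is the
    catalytic activity of the mixed-occupancy tetramer T1 relative to the
    fully nucleotide-loaded tetramer T0 (the ~20 % residual dNTPase activity
    retained at oligonucleotide saturation).  ``z_salt`` is the effective
    number of ionic contacts released on binding (0 for the salt-tolerant
    phosphorothioate regime) and ``kd_ref_salt`` the salt concentration (M)
    at which ``kd_oligo`` is quoted.

    The defaults are a qualitative regime, not measured constants: sub-µM
    oligo affinity, weak unassisted dimerization, tight nucleotide-driven
    tetramerization.
    """

    kd_oligo: float = 0.1
    kd_gtp: float = 5.0
    kd_dimer: float = 50.0
    kd_tet: float = 0.01
    kd_oligo_tet: float = 0.1
    ntp_hill: float = 4.0
    alpha_residual: float = 0.2
    z_salt: float = 0.0
    kd_ref_salt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("kd_oligo", "kd_gtp", "kd_dimer", "kd_tet", "kd_oligo_tet"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.alpha_residual <= 1.0:
            raise DomainError("alpha_residual must lie in [0, 1]")
        if not self.ntp_hill >= 1.0:
            raise DomainError("ntp_hill must be >= 1")
        if not self.kd_ref_salt > 0:
            raise DomainError("kd_ref_salt must be > 0")

    @property
    def kd_t1_via_dx(self) -> float:
        """Implied DX + D ⇌ T1 constant (cycle closure; read-only)."""
        return self.kd_tet * self.kd_oligo_tet / self.kd_oligo

    def replace(self, **changes) -> "BindingParams":
        d = asdict(self)
        d.update(changes)
        return BindingParams(**d)

    @classmethod
    def from_dict(cls, d: dict) -> "BindingParams":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise DomainError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "BindingParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "binding_params" in data:
            data = data["binding_params"]
        return cls.from_dict(data)


@dataclass(frozen=True)
class AssemblyState:
    """Equilibrium concentrations of all species (µM of species).

    ``bound_ratio`` is mol bound oligonucleotide per mol total protomer and is
    capped at 0.5 by the architecture (one oligo per dimer).  ``residual`` is
    the largest relative mass-balance violation across the four balances.
    """

    conc_M: float
    conc_D: float
    conc_DX: float
    conc_T0: float
    conc_T1: float
    free_oligo: float
    free_gtp: float
    free_dntp: float
    bound_ratio: float
    residual: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# closed-form building blocks


def solve_single_site(protein_total: float, probe_total: float, kd: float) -> float:
    """Fraction of probe bound for one-site binding with ligand depletion.

    Solves the exact mass-balance quadratic (P - b)(L - b) = Kd * b for the
    bound concentration b and returns b / L.  Uses the numerically stable
    root form b = 2 P L / (S + sqrt(S^2 - 4 P L)), S = P + L + Kd.
    """
    if protein_total < 0 or probe_total < 0 or kd < 0:
        raise DomainError("concentrations and kd must be non-negative")
    if probe_total == 0:
        raise UndefinedRatioError("fraction bound is undefined for zero probe")
    if kd == 0 and probe_total == 0:
        raise DomainError("kd and probe_total cannot both be zero")
    s = protein_total + probe_total + kd
    disc = s * s - 4.0 * protein_total * probe_total
    bound = 2.0 * protein_total * probe_total / (s + math.sqrt(max(disc, 0.0)))
    return min(bound / probe_total, 1.0)


def apparent_kd_competitive(
    kd: float, competitor_conc: float, kd_competitor: float
) -> float:
    """Apparent Kd of the probe in the presence of a competitive ligand.

    Classical competitive shift Kd_app = Kd * (1 + [I] / K_I), valid when the
    competitor is in excess over its bound fraction.
    """
    if kd <= 0 or kd_competitor <= 0:
        raise DomainError("kd and kd_competitor must be > 0")
    if competitor_conc < 0:
        raise DomainError("competitor_conc must be >= 0")
    return kd * (1.0 + competitor_conc / kd_competitor)


def salt_adjusted_kd(
    kd_ref: float, z_salt: float, salt: float, salt_ref: float
) -> float:
    """Counterion-release salt dependence: log Kd linear in log [salt].

    ``z_salt`` is the effective number of ionic contacts; z_salt = 0 gives the
    salt-tolerant (phosphorothioate-like) regime, z_salt > 0 the
    phosphodiester-like regime whose affinity degrades with ionic strength.
    """
    if kd_ref <= 0:
        raise DomainError("kd_ref must be > 0")
    if salt <= 0 or salt_ref <= 0:
        raise DomainError("salt concentrations must be > 0")
    return kd_ref * (salt / salt_ref) ** z_salt


# ---------------------------------------------------------------------------
# assembly solver


def _gate(g: float, n: float, p: BindingParams) -> float:
    """Hill gate on joint A1/A2 pair saturation; 0 unless both ligands present."""
    th1 = g / (p.kd_gtp + g)
    th2 = n / (p.kd_gtp + n)
    s = th1 * th2
    return s**p.ntp_hill if s > 0 else 0.0


def _species(m: float, x: float, g: float, n: float, p: BindingParams):
    """Species concentrations from the free concentrations."""
    comp = 1.0 + g / p.kd_gtp
    d = m * m / p.kd_dimer
    dx = d * x / (p.kd_oligo * comp)
    t0 = _gate(g, n, p) * d * d / p.kd_tet
    t1 = t0 * x / (p.kd_oligo_tet * comp)
    return d, dx, t0, t1


def _free_oligo(m: float, g: float, n: float, x_tot: float, p: BindingParams) -> float:
    """Free oligo given the other frees.

    Every oligo-carrying species is first order in x, so the oligo balance
    x (1 + D/(kd_oligo F) + T0/(kd_oligo_tet F)) = x_tot is linear in x and
    solves in closed form.
    """
    if x_tot == 0:
        return 0.0
    comp = 1.0 + g / p.kd_gtp
    d = m * m / p.kd_dimer
    t0 = _gate(g, n, p) * d * d / p.kd_tet
    return x_tot / (1.0 + d / (p.kd_oligo * comp) + t0 / (p.kd_oligo_tet * comp))


def _brent(f: Callable[[float], float], lo: float, hi: float, what: str) -> float:
    """Bracketed root solve with a defensive residual check."""
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        # physically the balances always bracket; reaching here means a
        # degenerate edge (all mass at one endpoint)
        return lo if abs(flo) < abs(fhi) else hi
    return brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=SOLVER_MAXITER)


def solve_assembly(
    protein_total: float,
    oligo_total: float,
    gtp_total: float,
    dntp_total: float,
    params: BindingParams | None = None,
) -> AssemblyState:
    """Solve the linked oligomerization equilibrium for given totals (µM).

    The four mass balances (protomer, oligo, GTP, dNTP) are reduced to nested
    bracketed one-dimensional root solves: free GTP and free dNTP by bracketed
    Brent iteration on their own balances, free monomer by Brent iteration on
    the protomer balance, and free oligo eliminated in closed form (its
    balance is linear in free oligo).  Each balance function is monotone in
    its own free concentration and changes sign across [0, total], so the
    unique equilibrium is always bracketed.

    Returns an :class:`AssemblyState`; raises :class:`ConvergenceError` if
    the final relative mass-balance residual exceeds 1e-9.
    """
    p = params if params is not None else BindingParams()
    for name, v in (
        ("protein_total", protein_total),
        ("oligo_total", oligo_total),
        ("gtp_total", gtp_total),
        ("dntp_total", dntp_total),
    ):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")

    if protein_total == 0:
        return AssemblyState(0, 0, 0, 0, 0, oligo_total, gtp_total, dntp_total, 0.0, 0.0)

    def solve_m(g: float, n: float) -> float:
        def protein_balance(m: float) -> float:
            x = _free_oligo(m, g, n, oligo_total, p)
            d, dx, t0, t1 = _species(m, x, g, n, p)
            tot = m + 2.0 * (d + dx) + 4.0 * (t0 + t1)
            return min(tot, 1e300) - protein_total

        return _brent(protein_balance, 0.0, protein_total, "monomer")

    def bound_ntp(g: float, n: float) -> float:
        m = solve_m(g, n)
        x = _free_oligo(m, g, n, oligo_total, p)
        _, _, t0, t1 = _species(m, x, g, n, p)
        return 4.0 * t0 + 3.0 * t1

    # free nucleotide levels: outer solve on GTP, inner on dNTP.  Tetramers
    # only form when both are present, so zero totals short-circuit.
    def solve_n(g: float) -> float:
        if dntp_total == 0 or gtp_total == 0:
            return dntp_total

        def dntp_balance(n: float) -> float:
            return n + bound_ntp(g, n) - dntp_total

        return _brent(dntp_balance, 0.0, dntp_total, "dNTP")

    if gtp_total == 0 or dntp_total == 0:
        g = gtp_total
    else:

        def gtp_balance(g: float) -> float:
            return g + bound_ntp(g, solve_n(g)) - gtp_total

        g = _brent(gtp_balance, 0.0, gtp_total, "GTP")

    n = solve_n(g)
    m = solve_m(g, n)
    x = _free_oligo(m, g, n, oligo_total, p)
    d, dx, t0, t1 = _species(m, x, g, n, p)

    def rel(err: float, tot: float) -> float:
        return abs(err) / max(tot, 1.0e-30) if tot > 0 else abs(err)

    residual = max(
        rel(m + 2 * (d + dx) + 4 * (t0 + t1) - protein_total, protein_total),
        rel(x + dx + t1 - oligo_total, oligo_total),
        rel(g + 4 * t0 + 3 * t1 - gtp_total, gtp_total),
        rel(n + 4 * t0 + 3 * t1 - dntp_total, dntp_total),
    )
    if residual > BALANCE_RTOL:
        raise ConvergenceError("assembly solver did not converge", residual)

    bound_ratio = (dx + t1) / protein_total
    return AssemblyState(
        conc_M=m,
        conc_D=d,
        conc_DX=dx,
        conc_T0=t0,
        conc_T1=t1,
        free_oligo=x,
        free_gtp=g,
        free_dntp=n,
        bound_ratio=bound_ratio,
        residual=residual,
    )


def stoichiometry_curve(
    oligo_series: Sequence[float],
    protein_total: float,
    gtp_total: float,
    dntp_total: float,
    params: BindingParams | None = None,
) -> list[float]:
    """Bound oligo : protomer ratio along an oligonucleotide titration.

    Pointwise identical to :func:`solve_assembly`; saturates at 0.5 in the
    dimer-only regime and at 0.25 when nucleotides drive tetramerization.
    """
    if len(oligo_series) == 0:
        raise DomainError("oligo_series must be non-empty")
    out = []
    for i, x_tot in enumerate(oligo_series):
        try:
            out.append(
                solve_assembly(protein_total, x_tot, gtp_total, dntp_total, params).bound_ratio
            )
        except DomainError as exc:
            raise DomainError(f"at series index {i}: {exc}") from exc
        except ConvergenceError as exc:
            raise ConvergenceError(f"at series index {i}: {exc}", exc.residual) from exc
    return out


# ---------------------------------------------------------------------------
# dNTPase activation


def activity_rate(
    gtp: float,
    oligo_total: float,
    kcat: float,
    ec50_gtp: float,
    ki_oligo: float,
    hill: float = 2.0,
    substrate_saturating: bool = True,
    params: BindingParams | None = None,
    protein_total: float | None = None,
    dntp_total: float | None = None,
) -> float:
    """dNTP hydrolysis rate under GTP activation with oligo competition.

    Hill activation with a competitive EC50 shift:

        rate = kcat * g^h / (ec50_app^h + g^h),
        ec50_app = ec50_gtp * (1 + oligo_total / ki_oligo).

    The saturating rate (kcat) is independent of the oligonucleotide — the
    competitive signature — while the apparent EC50 shifts right.  If
    ``params`` and ``protein_total`` are supplied, the rate is additionally
    weighted by the tetramer-pool activity (T0 + alpha_residual * T1) /
    (T0 + T1) from the assembly model, so that the oligo-saturated pool
    retains the ~20 % residual activity of the mixed-occupancy tetramer.
    """
    if kcat <= 0 or ec50_gtp <= 0 or ki_oligo <= 0 or hill <= 0:
        raise DomainError("kcat, ec50_gtp, ki_oligo and hill must be > 0")
    if gtp < 0 or oligo_total < 0:
        raise DomainError("gtp and oligo_total must be >= 0")
    if not substrate_saturating:
        raise DomainError(
            "only the substrate-saturating initial-rate regime is modeled"
        )
    if gtp == 0:
        return 0.0
    ec50_app = ec50_gtp * (1.0 + oligo_total / ki_oligo)
    rate = kcat * gtp**hill / (ec50_app**hill + gtp**hill)
    if params is not None and protein_total is not None:
        dntp = dntp_total if dntp_total is not None else 50.0
        state = solve_assembly(protein_total, oligo_total, gtp, dntp, params)
        pool = state.conc_T0 + state.conc_T1
        if pool > 0:
            rate *= (state.conc_T0 + params.alpha_residual * state.conc_T1) / pool
    return rate
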