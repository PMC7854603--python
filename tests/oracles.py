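"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's solution paths: the assembly oracle
is a two-dimensional grid-refinement search over (free monomer, free oligo)
with plain vectorized bisection for the nucleotide balances; the greedy
thinning and proximity oracles are direct transliterations of their rules.
"""

from __future__ import annotations

import numpy as np


def single_site_bisect(protein_total, probe_total, kd, tol=1e-12):
    """Fraction of probe bound by bisection on the mass-balance equation."""
    if probe_total == 0:
        raise ZeroDivisionError
    lo, hi = 0.0, min(protein_total, probe_total)

    def f(b):
        return (protein_total - b) * (probe_total - b) - kd * b

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(probe_total, 1.0):
            break
    return 0.5 * (lo + hi) / probe_total


def _species_scalar(m, x, g, n, p):
    th1 = g / (p.kd_gtp + g)
    th2 = n / (p.kd_gtp + n)
    phi = (th1 * th2) ** p.ntp_hill
    comp = 1.0 + g / p.kd_gtp
    d = m * m / p.kd_dimer
    dx = d * x / (p.kd_oligo * comp)
    t0 = phi * d * d / p.kd_tet
    t1 = t0 * x / (p.kd_oligo_tet * comp)
    return d, dx, t0, t1


def _solve_mx_bisect(protein_total, oligo_total, g, n, p, steps=50):
    """(free monomer, free oligo) by doubly nested plain bisection.

    The oligo balance is monotone increasing in free oligo and the protomer
    balance in free monomer, so each 1-D solve is a sign-based bisection.
    """

    def x_of_m(m):
        if oligo_total == 0:
            return 0.0
        lo, hi = 0.0, oligo_total
        for _ in range(steps):
            mid = 0.5 * (lo + hi)
            _, dx, _, t1 = _species_scalar(m, mid, g, n, p)
            if mid + dx + t1 - oligo_total > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo, hi = 0.0, protein_total
    for _ in range(steps):
        mid = 0.5 * (lo + hi)
        x = x_of_m(mid)
        d, dx, t0, t1 = _species_scalar(mid, x, g, n, p)
        if mid + 2 * (d + dx) + 4 * (t0 + t1) - protein_total > 0:
            hi = mid
        else:
            lo = mid
    m = 0.5 * (lo + hi)
    return m, x_of_m(m)


def assembly_bruteforce(
    protein_total, oligo_total, gtp_total, dntp_total, params,
    max_outer=400, tol=1e-12,
):
    """Equilibrium by brute-force nested bisection with NTP fixed point.

    Free monomer and free oligo are found by doubly nested sign bisection of
    the protomer/oligo balances; free GTP/dNTP by a damped fixed point
    (free = total - sequestered), iterated to convergence.  Valid when the
    nucleotide totals exceed the maximal sequestered amount (the regime of
    the emulated experiments).  Returns a dict of species and frees.
    """
    p = params
    g, n = float(gtp_total), float(dntp_total)
    for _ in range(max_outer):
        m, x = _solve_mx_bisect(protein_total, oligo_total, g, n, p)
        _, _, t0, t1 = _species_scalar(m, x, g, n, p)
        bound = 4.0 * t0 + 3.0 * t1
        g_new = max(gtp_total - bound, 0.0) if gtp_total > 0 else 0.0
        n_new = max(dntp_total - bound, 0.0) if dntp_total > 0 else 0.0
        if abs(g_new - g) <= tol * max(gtp_total, 1.0) and abs(n_new - n) <= tol * max(
            dntp_total, 1.0
        ):
            g, n = g_new, n_new
            break
        g = 0.5 * (g + g_new)
        n = 0.5 * (n + n_new)
    m, x = _solve_mx_bisect(protein_total, oligo_total, g, n, p)
    d, dx, t0, t1 = _species_scalar(m, x, g, n, p)
    return {
        "conc_M": m,
        "conc_D": d,
        "conc_DX": dx,
        "conc_T0": t0,
        "conc_T1": t1,
        "free_oligo": x,
        "free_gtp": g,
        "free_dntp": n,
        "bound_ratio": (dx + t1) / protein_total,
    }


def greedy_thin_bruteforce(sequences, identity_fn, threshold):
    """Literal restatement of the greedy thinning rule."""
    ordered = sorted(sequences, key=lambda s: (-len(s.sequence), s.protein_acc))
    reps, assignment = [], {}
    for seq in ordered:
        assigned = False
        for rep in reps:
            if identity_fn(seq.sequence, rep.sequence) >= threshold:
                assignment[seq.protein_acc] = rep.protein_acc
                assigned = True
                break
        if not assigned:
            reps.append(seq)
            assignment[seq.protein_acc] = seq.protein_acc
    return reps, assignment


def proximity_bruteforce(structure, ligand_selection, cutoff=5.0):
    """All-pairs distance scan over heavy protein atoms vs ligand atoms."""
    protein = structure[~structure.hetero]
    heavy = protein[protein.element != "H"]
    out = {}
    for group, resnames in ligand_selection.items():
        lig = structure[structure.hetero & np.isin(structure.res_name, resnames)]
        hits = set()
        for i in range(heavy.array_length()):
            for j in range(lig.array_length()):
                if np.linalg.norm(heavy.coord[i] - lig.coord[j]) <= cutoff:
                    hits.add(int(heavy.res_id[i]))
        out[group] = sorted(hits)
    return out
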