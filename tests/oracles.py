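"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written against plain dict/list inputs with different
formulations from the library code (projection-based torsion instead of
normal-vector atan2; naive per-residue loops over dicts instead of the
library's matched-set machinery), so agreement is evidence, not tautology.
"""

import math

import numpy as np


def brute_dihedral(p1, p2, p3, p4):
    """Torsion via the projection ('praxeolitic') formulation, degrees."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def circular_delta_deg(a, b):
    """Minimal circular distance between two angles in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def brute_sigma_cs(nmr, cal, residues):
    """nmr/cal: dict residue -> {"CA": x, "CB": y} (keys may be missing).

    Returns (value, n_contributing) summing |cal - nmr| per shared atom.
    """
    total = 0.0
    n = 0
    for r in residues:
        terms = 0.0
        hit = False
        for atom in ("CA", "CB"):
            a = nmr.get(r, {}).get(atom)
            b = cal.get(r, {}).get(atom)
            if a is not None and b is not None:
                terms += abs(b - a)
                hit = True
        if hit:
            total += terms
            n += 1
    return total, n


def brute_delta_ab(nmr, cal, residues):
    out = {}
    for r in residues:
        terms = 0.0
        hit = False
        for atom in ("CA", "CB"):
            a = nmr.get(r, {}).get(atom)
            b = cal.get(r, {}).get(atom)
            if a is not None and b is not None:
                terms += abs(b - a)
                hit = True
        if hit:
            out[r] = terms
    return out


def brute_sigma_a(s_nmr, s_cal, residues):
    """s_nmr/s_cal: dict residue -> S value. Counts strict sign opposition."""
    count = 0
    n = 0
    for r in residues:
        a = s_nmr.get(r)
        b = s_cal.get(r)
        if a is None or b is None:
            continue
        n += 1
        if a * b < 0:
            count += 1
    return count, n


def brute_sigma_psiphi(t_nmr, t_cal, residues, circular=True):
    """t_nmr/t_cal: dict residue -> (phi, psi) in degrees."""
    total = 0.0
    n = 0
    for r in residues:
        a = t_nmr.get(r)
        b = t_cal.get(r)
        if a is None or b is None:
            continue
        for x, y in zip(b, a):
            total += circular_delta_deg(x, y) if circular else abs(x - y)
        n += 1
    return total, n
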