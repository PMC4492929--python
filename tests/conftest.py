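"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately separate from the library code paths:
SASA via a dense hand-rolled Shrake-Rupley quadrature, hydrogen bonds via a
naive all-pairs scan.
"""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ddgbind as dg
from ddgbind.terms import EnergyComponents

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa_oracle(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
                n_points: int = 10000) -> np.ndarray:
    """Brute-force Shrake-Rupley SASA, one expanded sphere per atom."""
    coords = np.asarray(coords, dtype=float)
    expanded = np.asarray(radii, dtype=float) + probe
    sphere = golden_spiral_points(n_points)
    out = np.zeros(len(coords))
    for i in range(len(coords)):
        points = coords[i] + expanded[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        out[i] = 4 * np.pi * expanded[i] ** 2 * accessible.mean()
    return out


def hbond_oracle(model, partner_a, partner_b, cutoff=2.4):
    """All-pairs O(n^2) hydrogen-bond count following the stated rule."""
    from ddgbind.constants import THREE_TO_ONE
    eligible = set("STNQYRHKDE")
    atoms = []
    for res in model.residues:
        aa = THREE_TO_ONE[res.res_name]
        for idx in res.indices:
            atoms.append((idx, res.chain_id, id(res), aa,
                          str(model.array.atom_name[idx]),
                          str(model.array.element[idx]),
                          model.array.coord[idx]))
    counts = {"inter_ab": 0, "intra_aa": 0, "intra_bb": 0}
    for (i, ci, ri, aai, ni, ei, xi) in atoms:
        if ei != "H" or ni.startswith(("HA", "HB")) or aai not in eligible:
            continue
        for (j, cj, rj, aaj, nj, ej, xj) in atoms:
            if ej != "O" or aaj not in eligible or ri == rj:
                continue
            d = float(np.linalg.norm(xi - xj))
            if not (1.2 <= d < cutoff):
                continue
            in_a_i, in_a_j = ci in partner_a, cj in partner_a
            if in_a_i != in_a_j:
                counts["inter_ab"] += 1
            elif in_a_i:
                counts["intra_aa"] += 1
            else:
                counts["intra_bb"] += 1
    return dg.HBCounts(**counts)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def contact_case():
    """Two 5-residue chains close enough to bury an interface."""
    return dg.make_toy_complex(
        {"A": "AKDSG", "B": "GSEKA"},
        mutation=dg.MutationDescriptor("A", 4, "S", "A"),
        gap=12.0, seed=1)


@pytest.fixture
def separated_case():
    """Partners 40 A apart: no interface at all."""
    return dg.make_toy_complex(
        {"A": "ASDKG", "B": "GKDSA"},
        mutation=dg.MutationDescriptor("A", 2, "S", "A"),
        gap=40.0, seed=2)


@pytest.fixture
def self_case():
    """Self-mutation control: WT and MT are bit-identical structures."""
    return dg.make_toy_complex(
        {"A": "AKDSG", "B": "GSEKA"},
        mutation=dg.MutationDescriptor("A", 4, "S", "S"),
        gap=12.0, seed=1)


def energy_table(d_ie=2.0, dd_ee=0.5, dd_ve=0.5, dd_sp=0.5):
    """EnergyComponents whose double differences equal the given targets."""
    en = EnergyComponents()
    base = {("WT", "AB"): (-120.0, -40.0, -30.0, -55.0),
            ("WT", "A"): (-60.0, -18.0, -14.0, -25.0),
            ("WT", "B"): (-58.0, -17.0, -13.0, -24.0)}
    for (st, pt), (ie, ee, ve, sp) in base.items():
        for comp, v in zip(("IE", "EE", "VE", "SP"), (ie, ee, ve, sp)):
            en.set(st, pt, comp, v)
    # MT differs from WT only in the AB row, by exactly the requested deltas
    for comp, v in zip(("IE", "EE", "VE", "SP"),
                       (base[("WT", "AB")][0] + d_ie,
                        base[("WT", "AB")][1] + dd_ee,
                        base[("WT", "AB")][2] + dd_ve,
                        base[("WT", "AB")][3] + dd_sp)):
        en.set("MT", "AB", comp, v)
    for pt in ("A", "B"):
        for comp, v in zip(("IE", "EE", "VE", "SP"), base[("WT", pt)]):
            en.set("MT", pt, comp, v)
    return en


@pytest.fixture
def full_energies():
    return energy_table()
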