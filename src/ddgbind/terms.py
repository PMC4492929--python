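"""The ten scoring-function features.

Five MM/PB-style energy terms (internal energy, Coulomb, van der Waals,
polar and nonpolar solvation) come from an imported energy-components table
produced by external force-field / Poisson-Boltzmann runs — except the
nonpolar term, which is a linear function of SASA and is computed here, and
the Coulomb term, for which a coarse uniform-dielectric fallback exists.
Five knowledge-based terms (rotamer entropy, hydrophobicity, hydrogen bonds,
MT interface area, normalized interface-area change) are computed directly
from the structures.

Every mutation-difference term is the double difference

    ddE = (E_AB^MT - E_A^MT - E_B^MT) - (E_AB^WT - E_A^WT - E_B^WT)

over complex AB and rigid-body monomers A, B, except the internal-energy
term which by construction compares complexes only (the rigid-body split
makes the full double difference vanish identically).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    MAX_ROTAMERS, HYDROPHOBICITY, CHARGED_RESIDUES, POLAR_RESIDUES,
    COULOMB_CONSTANT, DEFAULT_EE_DIELECTRIC, HBOND_CUTOFF,
    HBOND_HEAVY_PROXY_CUTOFF,
)
from .structures import ComplexCase, ResidueKey, StructureModel, split_partners
from .surface import RadiiTable, DEFAULT_RADII, SasaProfile, sasa_profile, surface_features

#: canonical feature order of the linear scoring formula
TERM_NAMES = (
    "d_ie", "dd_ee", "dd_ve", "dd_sp", "dd_sn",
    "dd_s", "dd_hydr", "d_hb", "interface_mt", "dd_sasa_over_interface",
)


class MissingComponentError(ValueError):
    """An energy component required for a term is absent."""


class MissingTermError(ValueError):
    """A term required by the chosen weight set is unavailable."""


def delta_delta(e_ab_mt: float, e_a_mt: float, e_b_mt: float,
                e_ab_wt: float, e_a_wt: float, e_b_wt: float) -> float:
    """Double difference (MT binding term minus WT binding term)."""
    slots = {"e_ab_mt": e_ab_mt, "e_a_mt": e_a_mt, "e_b_mt": e_b_mt,
             "e_ab_wt": e_ab_wt, "e_a_wt": e_a_wt, "e_b_wt": e_b_wt}
    for name, val in slots.items():
        if val is None or not math.isfinite(val):
            raise MissingComponentError(f"missing or non-finite value for {name}")
    return (e_ab_mt - e_a_mt - e_b_mt) - (e_ab_wt - e_a_wt - e_b_wt)


# ---------------------------------------------------------------------------
# knowledge-based structure terms


def _state_rsasa(rsasa: float) -> float:
    # the entropy/hydrophobicity formulas are defined on rSASA in [0, 1]
    return min(max(rsasa, 0.0), 1.0)


def rotamer_entropy(residues: Iterable[tuple[str, float]]) -> float:
    """Surface-weighted side-chain entropy S = sum ln[rSASA*(R-1)+1].

    ``residues`` yields (one-letter code, rSASA in the scored state) pairs —
    monomer rSASA when scoring a monomer, complex rSASA when scoring the
    complex.  A fully exposed residue samples all R rotamers; a fully buried
    one is frozen (S contribution 0).  rSASA is clipped to [0, 1].
    """
    total = 0.0
    for aa, rsasa in residues:
        r_max = MAX_ROTAMERS[aa]
        total += math.log(_state_rsasa(rsasa) * (r_max - 1) + 1.0)
    return total


def hydrophobicity(residues: Iterable[tuple[str, float]]) -> float:
    """Exposure-weighted hydrophobicity HYDR = sum H_j * rSASA_j."""
    return sum(HYDROPHOBICITY[aa] * _state_rsasa(rsasa)
               for aa, rsasa in residues)


def _entropy_hydro_dd(case: ComplexCase,
                      profiles: tuple[SasaProfile, SasaProfile]
                      ) -> tuple[float, float]:
    """dd_s and dd_hydr via the double difference over complex/monomers."""
    results = []
    for fn in (rotamer_entropy, hydrophobicity):
        vals = {}
        for state, model, prof in (("WT", case.wt_complex, profiles[0]),
                                   ("MT", case.mt_complex, profiles[1])):
            residues = model.residues
            in_a = {r.key for r in residues
                    if r.chain_id in case.partner_a_chains}
            complex_pairs = [(r.aa, prof[r.key].rsasa_complex) for r in residues]
            a_pairs = [(r.aa, prof[r.key].rsasa_monomer)
                       for r in residues if r.key in in_a]
            b_pairs = [(r.aa, prof[r.key].rsasa_monomer)
                       for r in residues if r.key not in in_a]
            vals[state] = (fn(complex_pairs), fn(a_pairs), fn(b_pairs))
        results.append(delta_delta(*vals["MT"], *vals["WT"]))
    return results[0], results[1]


# ---------------------------------------------------------------------------
# hydrogen bonds

_HB_ELIGIBLE = CHARGED_RESIDUES | POLAR_RESIDUES
#: hydrogen names excluded as donors (nonpolar Calpha/Cbeta hydrogens)
_EXCLUDED_H_PREFIXES = ("HA", "HB")
#: below this H...O distance the pair is treated as covalent, not a bond
_COVALENT_HO_CUTOFF = 1.2


@dataclass(frozen=True)
class HBCounts:
    """Hydrogen-bond counts of one state: across and within partners."""

    inter_ab: int
    intra_aa: int
    intra_bb: int

    @property
    def net(self) -> int:
        """Binding-relevant balance: inter-partner minus intra-partner."""
        return self.inter_ab - self.intra_aa - self.intra_bb


def count_hbonds(model: StructureModel, partner_a: set[str], partner_b: set[str],
                 cutoff: float = HBOND_CUTOFF,
                 heavy_proxy: bool = False) -> HBCounts:
    """Count hydrogen bonds in a complex, split by partner membership.

    A bond is a (hydrogen, oxygen-acceptor) pair closer than ``cutoff``
    (2.4 A default), where the hydrogen is not a nonpolar Calpha/Cbeta
    hydrogen (names HA*/HB*), both residues are polar or charged, the pair
    does not sit in one residue, and the contact is not covalent (< 1.2 A).
    Nitrogen acceptors are deliberately not counted (much weaker), and no
    angular geometry is applied.

    With ``heavy_proxy`` (a documented deviation for hydrogen-free inputs)
    donor N/O heavy atoms replace hydrogens with a 3.4 A cutoff.
    """
    array = model.array
    res_index = np.zeros(array.array_length(), dtype=int)
    res_aa = []
    res_chain = []
    for i, res in enumerate(model.residues):
        res_index[res.indices] = i
        res_aa.append(res.res_name)
        res_chain.append(res.chain_id)
    from .constants import THREE_TO_ONE
    eligible_res = np.array([THREE_TO_ONE.get(rn, "?") in _HB_ELIGIBLE
                             for rn in res_aa])
    eligible_atom = eligible_res[res_index]

    if heavy_proxy:
        donor_mask = (np.isin(array.element, ["N", "O"])) & eligible_atom
        cutoff = HBOND_HEAVY_PROXY_CUTOFF
        covalent_cutoff = 1.8
    else:
        if not model.has_hydrogens():
            raise ValueError(
                "hydrogen-bond counting requires hydrogens in the model "
                "(or pass heavy_proxy=True for the approximate mode)")
        is_h = array.element == "H"
        not_nonpolar = ~np.array([n.startswith(_EXCLUDED_H_PREFIXES)
                                  for n in array.atom_name])
        donor_mask = is_h & not_nonpolar & eligible_atom
        covalent_cutoff = _COVALENT_HO_CUTOFF
    acceptor_mask = (array.element == "O") & eligible_atom

    donors = np.nonzero(donor_mask)[0]
    acceptors = np.nonzero(acceptor_mask)[0]
    counts = {"inter_ab": 0, "intra_aa": 0, "intra_bb": 0}
    if donors.size and acceptors.size:
        tree = cKDTree(array.coord[acceptors])
        hits = tree.query_ball_point(array.coord[donors], r=cutoff)
        for d_pos, acc_list in zip(donors, hits):
            for a_sub in acc_list:
                a_pos = acceptors[a_sub]
                if heavy_proxy and a_pos == d_pos:
                    continue
                ri, rj = res_index[d_pos], res_index[a_pos]
                if ri == rj:
                    continue
                dist = np.linalg.norm(array.coord[d_pos] - array.coord[a_pos])
                if dist < covalent_cutoff or dist >= cutoff:
                    continue
                ci, cj = res_chain[ri], res_chain[rj]
                in_a_i, in_a_j = ci in partner_a, cj in partner_a
                if in_a_i != in_a_j:
                    counts["inter_ab"] += 1
                elif in_a_i:
                    counts["intra_aa"] += 1
                else:
                    counts["intra_bb"] += 1
    return HBCounts(**counts)


def hbond_delta(wt_counts: HBCounts, mt_counts: HBCounts) -> int:
    """dHB: change of the inter-minus-intra hydrogen-bond balance (MT - WT)."""
    return mt_counts.net - wt_counts.net


# ---------------------------------------------------------------------------
# coarse Coulomb fallback

# Formal charge sites (one site per charged residue): atom name(s) whose
# centroid carries the charge.  His is included in the charged set and
# modelled protonated (+1), consistent with the dielectric-class partition.
_CHARGE_SITES = {
    "ASP": (-1.0, ("OD1", "OD2")),
    "GLU": (-1.0, ("OE1", "OE2")),
    "LYS": (+1.0, ("NZ",)),
    "ARG": (+1.0, ("CZ",)),
    "HIS": (+1.0, ("ND1", "NE2")),
}
#: minimum pair distance (A); closer pairs are clamped to this
_MIN_DISTANCE = 1.0


def formal_charge_sites(model: StructureModel
                        ) -> list[tuple[ResidueKey, float, np.ndarray]]:
    """(residue, charge, position) list under the bundled formal-charge scheme."""
    sites = []
    for res in model.residues:
        spec = _CHARGE_SITES.get(res.res_name)
        if spec is None:
            continue
        charge, atom_names = spec
        coords = [res.atom_coord(n) for n in atom_names]
        if any(c is None for c in coords):
            warnings.warn(f"charged residue {res.key} lacks atoms "
                          f"{atom_names}; skipped in Coulomb fallback",
                          stacklevel=2)
            continue
        sites.append((res.key, charge, np.mean(coords, axis=0)))
    return sites


def coulomb_ee(model: StructureModel,
               epsilon_uniform: float = DEFAULT_EE_DIELECTRIC) -> float:
    """Pairwise Coulomb energy (kcal/mol) over formal charges, uniform dielectric.

    A deliberately coarse stand-in for a finite-difference Poisson-Boltzmann
    Coulombic energy: one formal charge per charged residue, a uniform
    protein dielectric (default 7), and a 1.0 A lower distance clamp.  An
    imported EE component always takes precedence over this fallback.
    """
    if epsilon_uniform <= 0:
        raise ValueError("dielectric constant must be positive")
    sites = formal_charge_sites(model)
    energy = 0.0
    for i in range(len(sites)):
        key_i, q_i, x_i = sites[i]
        for j in range(i + 1, len(sites)):
            key_j, q_j, x_j = sites[j]
            if key_i == key_j:
                continue
            r = max(float(np.linalg.norm(x_i - x_j)), _MIN_DISTANCE)
            energy += COULOMB_CONSTANT * q_i * q_j / (epsilon_uniform * r)
    return energy


# ---------------------------------------------------------------------------
# imported energy components

_STATES = ("WT", "MT")
_PARTS = ("AB", "A", "B")
_COMPONENTS = ("IE", "EE", "VE", "SP")


@dataclass
class EnergyComponents:
    """Imported per-structure energy components of one case.

    ``values[(state, part)][component]`` is a float or None (absent).  Absent
    components are explicit — they never silently read as zero.
    """

    values: dict = field(default_factory=dict)
    provenance: str = "imported"

    def set(self, state: str, part: str, component: str, value: float | None):
        self.values.setdefault((state, part), {})[component] = value

    def get(self, state: str, part: str, component: str) -> float:
        val = self.values.get((state, part), {}).get(component)
        if val is None or not math.isfinite(val):
            raise MissingComponentError(
                f"energy component {component} for ({state}, {part}) is absent")
        return val

    def has(self, state: str, part: str, component: str) -> bool:
        val = self.values.get((state, part), {}).get(component)
        return val is not None and math.isfinite(val)

    def has_all(self, component: str, parts: tuple[str, ...] = _PARTS) -> bool:
        return all(self.has(s, p, component) for s in _STATES for p in parts)

    def dd(self, component: str) -> float:
        """Double difference of one component over (AB, A, B) x (MT, WT)."""
        return delta_delta(
            self.get("MT", "AB", component), self.get("MT", "A", component),
            self.get("MT", "B", component),
            self.get("WT", "AB", component), self.get("WT", "A", component),
            self.get("WT", "B", component))


def load_energy_components(path: str | Path) -> dict[str, EnergyComponents]:
    """Read a TSV of precomputed energy components, one row per structure.

    Columns: case_id, state (WT|MT), part (AB|A|B), then any of IE, EE, VE,
    SP in kcal/mol.  Empty cells mean "absent".  Duplicate (case_id, state,
    part) rows and malformed numbers are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"case_id", "state", "part"}
    if not required.issubset(df.columns):
        raise ValueError(f"energy table must have columns {sorted(required)}")
    missing_cols = [c for c in _COMPONENTS if c not in df.columns]
    if missing_cols:
        warnings.warn(f"energy table lacks columns {missing_cols}; those "
                      "components will be absent", stacklevel=2)
    seen = set()
    out: dict[str, EnergyComponents] = {}
    for row_no, row in df.iterrows():
        case_id, state, part = row["case_id"], row["state"], row["part"]
        if state not in _STATES or part not in _PARTS:
            raise ValueError(f"row {row_no}: bad state/part ({state}, {part})")
        key = (case_id, state, part)
        if key in seen:
            raise ValueError(f"row {row_no}: duplicate entry for {key}")
        seen.add(key)
        comps = out.setdefault(case_id, EnergyComponents())
        for comp in _COMPONENTS:
            raw = row.get(comp)
            if comp in missing_cols or raw is None or (isinstance(raw, float)
                                                       and math.isnan(raw)) \
                    or str(raw).strip() == "":
                comps.set(state, part, comp, None)
                continue
            try:
                comps.set(state, part, comp, float(raw))
            except ValueError:
                raise ValueError(
                    f"row {row_no}: malformed number {raw!r} in column {comp}"
                ) from None
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class TermVector:
    """The ten features of the linear scoring formula for one case.

    Energies in kcal/mol, areas in A^2; entropy, hydrogen-bond and the
    normalized-SASA terms are dimensionless.  A ``None`` field means the
    term could not be obtained — predicting with a weight set that needs it
    raises :class:`MissingTermError`.  ``provenance`` records per term how
    it was obtained (imported | internal | structure).
    """

    d_ie: float | None = None
    dd_ee: float | None = None
    dd_ve: float | None = None
    dd_sp: float | None = None
    dd_sn: float | None = None
    dd_s: float | None = None
    dd_hydr: float | None = None
    d_hb: float | None = None
    interface_mt: float | None = None
    dd_sasa_over_interface: float | None = None
    provenance: dict = field(default_factory=dict)

    def get(self, name: str) -> float:
        if name not in TERM_NAMES:
            raise KeyError(f"unknown term {name!r}")
        val = getattr(self, name)
        if val is None:
            raise MissingTermError(f"term {name} unavailable")
        return val

    def as_dict(self, strict: bool = False) -> dict[str, float | None]:
        out = {name: getattr(self, name) for name in TERM_NAMES}
        if strict and any(v is None for v in out.values()):
            missing = [k for k, v in out.items() if v is None]
            raise MissingTermError(f"terms unavailable: {missing}")
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.as_dict(), dtype=float)


def assemble_terms(case: ComplexCase,
                   energies: EnergyComponents | None = None,
                   radii: RadiiTable = DEFAULT_RADII,
                   hbond_cutoff: float = HBOND_CUTOFF,
                   hb_heavy_proxy: bool = False,
                   allow_internal_ee: bool = True,
                   ee_epsilon: float = DEFAULT_EE_DIELECTRIC) -> TermVector:
    """Compute the full feature vector of a WT/MT case.

    Structure-derived terms are always computed.  IE, VE and SP require the
    imported ``energies`` table; EE falls back to the internal uniform-
    dielectric Coulomb estimate when not imported (disable with
    ``allow_internal_ee=False``).  Missing terms are left ``None``.
    """
    tv = TermVector()
    wt_prof = sasa_profile(case.wt_complex, case.partner_a_chains,
                           case.partner_b_chains, radii)
    mt_prof = sasa_profile(case.mt_complex, case.partner_a_chains,
                           case.partner_b_chains, radii)

    feats = surface_features(case, radii, profiles=(wt_prof, mt_prof))
    tv.interface_mt = feats["interface_mt"]
    tv.dd_sasa_over_interface = feats["dd_sasa_over_interface_mt"]
    # nonpolar solvation is linear in total SASA; its slope and offset are
    # absorbed by the fitted weight and intercept, so the feature itself is
    # the double difference of the raw SASA
    tv.dd_sn = feats["dd_sasa"]
    tv.provenance.update({"interface_mt": "structure",
                          "dd_sasa_over_interface": "structure",
                          "dd_sn": "structure"})

    tv.dd_s, tv.dd_hydr = _entropy_hydro_dd(case, (wt_prof, mt_prof))
    tv.provenance.update({"dd_s": "structure", "dd_hydr": "structure"})

    try:
        wt_hb = count_hbonds(case.wt_complex, case.partner_a_chains,
                             case.partner_b_chains, cutoff=hbond_cutoff,
                             heavy_proxy=hb_heavy_proxy)
        mt_hb = count_hbonds(case.mt_complex, case.partner_a_chains,
                             case.partner_b_chains, cutoff=hbond_cutoff,
                             heavy_proxy=hb_heavy_proxy)
        tv.d_hb = float(hbond_delta(wt_hb, mt_hb))
        tv.provenance["d_hb"] = "structure"
    except ValueError as exc:
        warnings.warn(f"hydrogen-bond term unavailable: {exc}", stacklevel=2)

    if energies is not None:
        if energies.has("MT", "AB", "IE") and energies.has("WT", "AB", "IE"):
            # internal energy compares complexes only: rigid-body monomers
            # would cancel the full double difference identically
            tv.d_ie = energies.get("MT", "AB", "IE") - energies.get("WT", "AB", "IE")
            tv.provenance["d_ie"] = "imported"
        for comp, name in (("EE", "dd_ee"), ("VE", "dd_ve"), ("SP", "dd_sp")):
            if energies.has_all(comp):
                setattr(tv, name, energies.dd(comp))
                tv.provenance[name] = "imported"
    if tv.dd_ee is None and allow_internal_ee:
        vals = {}
        for state in _STATES:
            cplx, mono_a, mono_b = split_partners(case, state)
            vals[state] = (coulomb_ee(cplx, ee_epsilon),
                           coulomb_ee(mono_a, ee_epsilon),
                           coulomb_ee(mono_b, ee_epsilon))
        tv.dd_ee = delta_delta(*vals["MT"], *vals["WT"])
        tv.provenance["dd_ee"] = "internal"
    return tv
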