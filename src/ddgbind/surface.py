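"""Solvent accessible surface area, interface location classes, interface area.

SASA uses Shrake-Rupley quadrature (via ``biotite.structure.sasa``) with a
deterministic Fibonacci sphere point set, Chothia-style heavy-atom radii and
a 1.4 A water probe.  Hydrogens never contribute surface.  Relative SASA
(rSASA) divides a residue's SASA by its fully exposed reference area, so
rSASA = 1 is a totally exposed residue (mild excursions above 1 are kept).

Residue location in the complex follows the five-class scheme based on
monomer rSASA (rSASAm), complex rSASA (rSASAc) and their rigid-body
difference dRSASA = rSASAm - rSASAc:

    COR  interface core     rSASAm >= 25%, rSASAc < 25%, dRSASA > 0
    SUP  interface support  rSASAm < 25%,  rSASAc < 25%, dRSASA > 0
    RIM  interface rim      rSASAc >= 25%, dRSASA > 0
    INT  interior           rSASAc < 25%,  dRSASA = 0
    SUR  surface            rSASAc >= 25%, dRSASA = 0

Boundary policy: values exactly at 0.25 take the "> 25%" branch; dRSASA = 0
means |dRSASA| <= 1e-6.  Anything not covered (a residue *gaining* exposure
on binding, impossible rigid-body) is reported UNCLASSIFIABLE, never silently
defaulted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .constants import (
    VDW_RADII, MAX_ASA, DEFAULT_PROBE_RADIUS, DEFAULT_SPHERE_POINTS,
)
from .structures import ComplexCase, ResidueKey, StructureModel, split_partners

#: tolerance below which dRSASA counts as exactly zero
DRSASA_TOL = 1e-6


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii and quadrature settings for SASA."""

    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = DEFAULT_SPHERE_POINTS

    def __post_init__(self):
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be >= 60")
        for elem, r in self.radii.items():
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius for {elem!r} out of range: {r}")

    def radius_for(self, element: str, atom_label: str = "") -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {element!r}"
                + (f" (atom {atom_label})" if atom_label else "")) from None


DEFAULT_RADII = RadiiTable()


class LocationClass(enum.Enum):
    COR = "COR"
    SUP = "SUP"
    RIM = "RIM"
    INT = "INT"
    SUR = "SUR"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"

    def __str__(self) -> str:
        return self.value

    @property
    def is_interfacial(self) -> bool:
        return self in (LocationClass.COR, LocationClass.SUP, LocationClass.RIM)


def compute_sasa(model: StructureModel, radii: RadiiTable = DEFAULT_RADII
                 ) -> tuple[np.ndarray, dict[ResidueKey, float]]:
    """Per-atom and per-residue SASA (A^2) of a model.

    Hydrogens are excluded (their per-atom SASA is reported 0); per-residue
    SASA is the sum over the residue's heavy atoms.
    """
    array = model.array
    heavy = array.element != "H"
    if not heavy.any():
        raise ValueError("model contains no heavy atoms")
    sub = array[heavy]
    atom_radii = np.array(
        [radii.radius_for(e, f"{c}:{r} {n}")
         for e, c, r, n in zip(sub.element, sub.chain_id, sub.res_id, sub.atom_name)]
    )
    sasa_heavy = struc.sasa(sub, probe_radius=radii.probe_radius,
                            point_number=radii.n_sphere_points,
                            vdw_radii=atom_radii, ignore_ions=False)
    per_atom = np.zeros(array.array_length())
    per_atom[heavy] = np.nan_to_num(sasa_heavy, nan=0.0)
    per_residue: dict[ResidueKey, float] = {}
    for res in model.residues:
        per_residue[res.key] = float(per_atom[res.indices].sum())
    return per_atom, per_residue


def relative_sasa(residue_sasa: float, aa_type: str,
                  reference_table: dict | None = None) -> float:
    """rSASA = SASA / fully-exposed reference area; not clipped at 1."""
    table = MAX_ASA if reference_table is None else reference_table
    try:
        ref = table[aa_type]
    except KeyError:
        raise KeyError(f"no reference ASA for residue type {aa_type!r}") from None
    return residue_sasa / ref


def classify_location(rsasa_m: float, rsasa_c: float,
                      tol: float = DRSASA_TOL) -> LocationClass:
    """Five-class residue location from monomer/complex rSASA (see module doc)."""
    if rsasa_m < 0 or rsasa_c < 0:
        raise ValueError("rSASA values must be non-negative")
    delta = rsasa_m - rsasa_c
    if delta > tol:
        if rsasa_c >= 0.25:
            return LocationClass.RIM
        if rsasa_m >= 0.25:
            return LocationClass.COR
        return LocationClass.SUP
    if abs(delta) <= tol:
        return LocationClass.SUR if rsasa_c >= 0.25 else LocationClass.INT
    # delta < -tol: residue buried by removing its partner — impossible for
    # a rigid-body split, so never silently assign a class.
    return LocationClass.UNCLASSIFIABLE


@dataclass
class ResidueSurface:
    """Surface bookkeeping of one residue in monomer vs complex state."""

    key: ResidueKey
    aa: str
    sasa_complex: float
    sasa_monomer: float
    rsasa_complex: float
    rsasa_monomer: float

    @property
    def delta_rsasa(self) -> float:
        return self.rsasa_monomer - self.rsasa_complex

    @property
    def location(self) -> LocationClass:
        return classify_location(self.rsasa_monomer, self.rsasa_complex)


@dataclass
class SasaProfile:
    """Per-residue SASA/rSASA of one complex split into two partners."""

    residues: dict[ResidueKey, ResidueSurface]
    total_sasa_complex: float
    total_sasa_a: float
    total_sasa_b: float

    @property
    def interface_area(self) -> float:
        """Buried interface area (A^2), positive by convention.

        Computed as SASA(A) + SASA(B) - SASA(AB): the surface each partner
        loses on binding.  (The raw complex-minus-parts difference is the
        negative of this; the positive buried-area convention is used
        throughout so a positive interface weight penalizes large
        interfaces.)
        """
        return self.total_sasa_a + self.total_sasa_b - self.total_sasa_complex

    def __getitem__(self, key: ResidueKey) -> ResidueSurface:
        return self.residues[key]


def sasa_profile(complex_model: StructureModel, partner_a: set[str],
                 partner_b: set[str], radii: RadiiTable = DEFAULT_RADII
                 ) -> SasaProfile:
    """Compute monomer and complex SASA for every residue of a complex."""
    mono_a = complex_model.select_chains(partner_a)
    mono_b = complex_model.select_chains(partner_b)
    _, res_complex = compute_sasa(complex_model, radii)
    _, res_a = compute_sasa(mono_a, radii)
    _, res_b = compute_sasa(mono_b, radii)
    res_monomer = {**res_a, **res_b}
    residues = {}
    for res in complex_model.residues:
        key = res.key
        sc = res_complex[key]
        sm = res_monomer[key]
        residues[key] = ResidueSurface(
            key=key, aa=res.aa,
            sasa_complex=sc, sasa_monomer=sm,
            rsasa_complex=relative_sasa(sc, res.aa),
            rsasa_monomer=relative_sasa(sm, res.aa),
        )
    return SasaProfile(
        residues=residues,
        total_sasa_complex=sum(res_complex.values()),
        total_sasa_a=sum(res_a.values()),
        total_sasa_b=sum(res_b.values()),
    )


def surface_features(case: ComplexCase, radii: RadiiTable = DEFAULT_RADII,
                     profiles: tuple[SasaProfile, SasaProfile] | None = None
                     ) -> dict[str, float]:
    """Interface areas and SASA-derived scoring terms of a WT/MT case.

    Returns ``interface_wt``, ``interface_mt`` (buried areas, A^2),
    ``dd_sasa`` (double difference of total SASA over the mutation, A^2) and
    ``dd_sasa_over_interface_mt`` (dimensionless).  Precomputed WT/MT
    profiles may be passed to avoid recomputation.
    """
    if profiles is None:
        wt_prof = sasa_profile(case.wt_complex, case.partner_a_chains,
                               case.partner_b_chains, radii)
        mt_prof = sasa_profile(case.mt_complex, case.partner_a_chains,
                               case.partner_b_chains, radii)
    else:
        wt_prof, mt_prof = profiles
    interface_wt = wt_prof.interface_area
    interface_mt = mt_prof.interface_area
    # double difference of *total* SASA: (AB - A - B)_MT - (AB - A - B)_WT
    dd_sasa = ((mt_prof.total_sasa_complex - mt_prof.total_sasa_a
                - mt_prof.total_sasa_b)
               - (wt_prof.total_sasa_complex - wt_prof.total_sasa_a
                  - wt_prof.total_sasa_b))
    if abs(interface_mt) < 1e-9:
        warnings.warn("MT interface area is zero (non-touching partners); "
                      "normalized SASA term set to 0", stacklevel=2)
        normalized = 0.0
    else:
        normalized = dd_sasa / interface_mt
    return {
        "interface_wt": interface_wt,
        "interface_mt": interface_mt,
        "dd_sasa": dd_sasa,
        "dd_sasa_over_interface_mt": normalized,
    }


def locate_mutation_site(case: ComplexCase, radii: RadiiTable = DEFAULT_RADII
                         ) -> tuple[LocationClass, LocationClass]:
    """Location class of the mutation site in the WT and the MT complex."""
    wt_prof = sasa_profile(case.wt_complex, case.partner_a_chains,
                           case.partner_b_chains, radii)
    mt_prof = sasa_profile(case.mt_complex, case.partner_a_chains,
                           case.partner_b_chains, radii)
    key = case.mutation.site_key
    return wt_prof[key].location, mt_prof[key].location
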