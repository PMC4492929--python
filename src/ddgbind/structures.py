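"""Structure model: PDB reading/writing, partner splitting, case validation.

The in-memory substrate is a thin wrapper around a ``biotite`` ``AtomArray``.
Monomer structures are always carved rigid-body out of the complex: the
unbound partners keep bit-identical coordinates, so no binding-induced
conformational change is ever modelled.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .constants import THREE_TO_ONE, ONE_TO_THREE

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3"})

#: backbone + Cbeta atoms retained by :func:`naive_mutate`
_BACKBONE_SET = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "CB"})


class PDBFormatError(ValueError):
    """Raised when an ATOM/HETATM record does not parse."""


class EmptyStructureError(ValueError):
    """Raised when no atoms survive parsing and filtering."""


class NonCanonicalResidueError(ValueError):
    """Raised when a polymer (ATOM) residue is not one of the 20 types."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue: chain, author number, insertion code."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:123" or "A:52A"
        return f"{self.chain_id}:{self.number}{self.icode}"


class ResidueView:
    """Read-only view of one residue inside a :class:`StructureModel`."""

    def __init__(self, model: "StructureModel", indices: np.ndarray):
        self._model = model
        self.indices = indices
        a = model.array
        i = indices[0]
        self.chain_id: str = str(a.chain_id[i])
        self.number: int = int(a.res_id[i])
        self.icode: str = str(a.ins_code[i])
        self.res_name: str = str(a.res_name[i])
        self.is_het: bool = bool(a.hetero[i])

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.number, self.icode)

    @property
    def aa(self) -> str:
        """One-letter code; raises for non-canonical residues."""
        try:
            return THREE_TO_ONE[self.res_name]
        except KeyError:
            raise NonCanonicalResidueError(
                f"residue {self.key} has non-canonical type {self.res_name!r}"
            ) from None

    @property
    def atom_names(self) -> list[str]:
        return [str(n) for n in self._model.array.atom_name[self.indices]]

    @property
    def coords(self) -> np.ndarray:
        return self._model.array.coord[self.indices]

    def atom_coord(self, name: str) -> np.ndarray | None:
        """Coordinates of the named atom, or None if absent."""
        names = self._model.array.atom_name[self.indices]
        hits = np.nonzero(names == name)[0]
        if hits.size == 0:
            return None
        return self._model.array.coord[self.indices[hits[0]]]

    @property
    def heavy_atom_count(self) -> int:
        elems = self._model.array.element[self.indices]
        return int(np.sum(elems != "H"))

    def __repr__(self) -> str:
        return f"<ResidueView {self.res_name} {self.key} ({len(self.indices)} atoms)>"


class StructureModel:
    """Atomic model of one structure (a complex or a monomer)."""

    def __init__(self, array: struc.AtomArray, source_label: str = "",
                 n_waters_removed: int = 0):
        if array.array_length() == 0:
            raise EmptyStructureError(f"no atoms in structure {source_label!r}")
        if "ins_code" not in array.get_annotation_categories():
            array.set_annotation("ins_code", np.full(array.array_length(), "", dtype="U1"))
        if "occupancy" not in array.get_annotation_categories():
            array.set_annotation("occupancy", np.ones(array.array_length()))
        self.array = array
        self.source_label = source_label
        self.n_waters_removed = n_waters_removed
        self._residues: list[ResidueView] | None = None

    # -- residue bookkeeping -------------------------------------------------

    @property
    def residues(self) -> list[ResidueView]:
        """Residues in file order (author numbering kept verbatim)."""
        if self._residues is None:
            starts = struc.get_residue_starts(self.array, add_exclusive_stop=True)
            self._residues = [
                ResidueView(self, np.arange(starts[k], starts[k + 1]))
                for k in range(len(starts) - 1)
            ]
        return self._residues

    @property
    def chain_ids(self) -> set[str]:
        return {str(c) for c in np.unique(self.array.chain_id)}

    @property
    def n_atoms(self) -> int:
        return self.array.array_length()

    def residue(self, chain_id: str, number: int, icode: str = "") -> ResidueView:
        for res in self.residues:
            if (res.chain_id == chain_id and res.number == number
                    and res.icode == icode):
                return res
        raise KeyError(f"no residue {chain_id}:{number}{icode} in {self.source_label!r}")

    def has_hydrogens(self) -> bool:
        return bool(np.any(self.array.element == "H"))

    def subset(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        return StructureModel(self.array[mask],
                              source_label=label or self.source_label)

    def select_chains(self, chains: Iterable[str], label: str | None = None) -> "StructureModel":
        chains = set(chains)
        mask = np.isin(self.array.chain_id, sorted(chains))
        if not mask.any():
            raise EmptyStructureError(
                f"chains {sorted(chains)} not present in {self.source_label!r}")
        return self.subset(mask, label=label)

    def copy(self) -> "StructureModel":
        return StructureModel(self.array.copy(), self.source_label,
                              self.n_waters_removed)

    def __repr__(self) -> str:
        return (f"<StructureModel {self.source_label!r}: {self.n_atoms} atoms, "
                f"chains {sorted(self.chain_ids)}>")


# ---------------------------------------------------------------------------
# PDB I/O


def _validate_coordinate_columns(lines: Sequence[str]) -> None:
    """Check fixed-column coordinate fields, naming the offending line."""
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                token = line[lo:hi].strip()
                try:
                    val = float(token)
                except ValueError:
                    raise PDBFormatError(
                        f"line {lineno}: non-numeric {what} coordinate {token!r}"
                    ) from None
                if not np.isfinite(val):
                    raise PDBFormatError(
                        f"line {lineno}: non-finite {what} coordinate {token!r}")


def read_pdb(source: str | Path, drop_heteroatoms: bool = True,
             label: str | None = None) -> StructureModel:
    """Parse PDB text (path or literal string) into a :class:`StructureModel`.

    Waters are always removed from the working model (their count is kept on
    ``n_waters_removed``).  Other HETATM records are removed when
    ``drop_heteroatoms`` is true.  Alternate locations are resolved to the
    highest-occupancy conformer (first in file order on ties, which for
    standard PDB files is the alphabetically first altloc id).  ATOM-record
    residues must be one of the 20 canonical types.
    """
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and len(source) < 4096
                                    and Path(source).exists()):
        text = Path(source).read_text()
        default_label = str(source)
    else:
        text = str(source)
        default_label = "<text>"
    lines = text.splitlines()
    _validate_coordinate_columns(lines)

    pdb_file = pdbio.PDBFile.read(io.StringIO(text))
    try:
        array = pdb_file.get_structure(model=1, altloc="occupancy",
                                       extra_fields=["occupancy"])
    except Exception as exc:  # pragma: no cover - biotite error surface
        raise PDBFormatError(f"failed to parse PDB records: {exc}") from exc

    is_water = np.isin(array.res_name, sorted(WATER_RESNAMES))
    n_waters = len(struc.get_residue_starts(array[is_water])) if is_water.any() else 0
    keep = ~is_water
    if drop_heteroatoms:
        keep &= ~array.hetero
    array = array[keep]
    if array.array_length() == 0:
        raise EmptyStructureError("no atoms left after heteroatom/water filtering")

    for res_name in np.unique(array.res_name[~array.hetero]):
        if res_name not in THREE_TO_ONE:
            raise NonCanonicalResidueError(
                f"polymer residue type {res_name!r} is not one of the 20 "
                "canonical amino acids")

    return StructureModel(array, source_label=label or default_label,
                          n_waters_removed=n_waters)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to PDB text (fixed-column ATOM/HETATM)."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(model.array)
    return "\n".join(pdb_file.lines) + "\n"


# ---------------------------------------------------------------------------
# Mutations and cases


@dataclass(frozen=True)
class MutationDescriptor:
    """A single point mutation: chain, author site number, WT and MT types."""

    chain_id: str
    site: int
    wt_aa: str
    mt_aa: str
    icode: str = ""

    def __post_init__(self):
        for aa in (self.wt_aa, self.mt_aa):
            if aa not in ONE_TO_THREE:
                raise ValueError(f"not a canonical amino acid code: {aa!r}")

    @property
    def site_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.site, self.icode)

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.chain_id}{self.site}{self.icode}{self.mt_aa}"


class ConfigurationError(ValueError):
    """Raised when partner chain grouping is inconsistent with the model."""


@dataclass
class ComplexCase:
    """A WT/MT pair of complexes plus partner grouping and the mutation.

    This is the unit of prediction: both structures, the rigid-body split
    into binding partners A and B, and the mutation descriptor.
    """

    wt_complex: StructureModel
    mt_complex: StructureModel
    partner_a_chains: set[str]
    partner_b_chains: set[str]
    mutation: MutationDescriptor
    case_id: str = ""

    def __post_init__(self):
        a, b = set(self.partner_a_chains), set(self.partner_b_chains)
        if not a or not b:
            raise ConfigurationError("both partners need at least one chain")
        if a & b:
            raise ConfigurationError(f"partners share chains: {sorted(a & b)}")
        for model in (self.wt_complex, self.mt_complex):
            if model.chain_ids != a | b:
                raise ConfigurationError(
                    f"partner grouping {sorted(a | b)} does not cover chains "
                    f"{sorted(model.chain_ids)} of {model.source_label!r}")
        if self.mutation.chain_id not in a | b:
            raise ConfigurationError(
                f"mutation chain {self.mutation.chain_id!r} not in either partner")
        self.partner_a_chains, self.partner_b_chains = a, b

    @property
    def mutated_partner(self) -> str:
        return "A" if self.mutation.chain_id in self.partner_a_chains else "B"


def split_partners(case: ComplexCase, which: str
                   ) -> tuple[StructureModel, StructureModel, StructureModel]:
    """Rigid-body split of the WT or MT complex into (complex, A, B).

    Monomer coordinates are taken unchanged from the complex.
    """
    if which not in ("WT", "MT"):
        raise ValueError("which must be 'WT' or 'MT'")
    model = case.wt_complex if which == "WT" else case.mt_complex
    mono_a = model.select_chains(case.partner_a_chains,
                                 label=f"{model.source_label}|A")
    mono_b = model.select_chains(case.partner_b_chains,
                                 label=f"{model.source_label}|B")
    return model, mono_a, mono_b


def validate_case(case: ComplexCase) -> list[str]:
    """Consistency report for a case; empty list means no violations.

    Checks that the WT and MT structures carry the declared residue types at
    the mutation site, and that they differ only in side-chain atoms there.
    """
    violations: list[str] = []
    m = case.mutation
    wt_res = mt_res = None
    try:
        wt_res = case.wt_complex.residue(m.chain_id, m.site, m.icode)
    except KeyError:
        violations.append(f"WT structure lacks residue {m.site_key}")
    try:
        mt_res = case.mt_complex.residue(m.chain_id, m.site, m.icode)
    except KeyError:
        violations.append(f"MT structure lacks residue {m.site_key}")
    if wt_res is not None and wt_res.res_name != ONE_TO_THREE[m.wt_aa]:
        violations.append(
            f"WT residue mismatch at {m.site_key}: structure has "
            f"{wt_res.res_name}, descriptor says {ONE_TO_THREE[m.wt_aa]}")
    if mt_res is not None and mt_res.res_name != ONE_TO_THREE[m.mt_aa]:
        violations.append(
            f"MT residue mismatch at {m.site_key}: structure has "
            f"{mt_res.res_name}, descriptor says {ONE_TO_THREE[m.mt_aa]}")

    # off-site residues must be identical apart from hydrogens
    wt_map = {r.key: r for r in case.wt_complex.residues}
    mt_map = {r.key: r for r in case.mt_complex.residues}
    if set(wt_map) != set(mt_map):
        only_wt = sorted(str(k) for k in set(wt_map) - set(mt_map))
        only_mt = sorted(str(k) for k in set(mt_map) - set(wt_map))
        violations.append(
            f"residue sets differ (WT only: {only_wt}, MT only: {only_mt})")
    else:
        for key, wres in wt_map.items():
            mres = mt_map[key]
            if key == m.site_key:
                continue
            wt_heavy = {n for n, e in zip(wres.atom_names,
                                          case.wt_complex.array.element[wres.indices])
                        if e != "H"}
            mt_heavy = {n for n, e in zip(mres.atom_names,
                                          case.mt_complex.array.element[mres.indices])
                        if e != "H"}
            if wres.res_name != mres.res_name or wt_heavy != mt_heavy:
                violations.append(
                    f"off-site residue {key} differs between WT and MT")
    if case.wt_complex.has_hydrogens() != case.mt_complex.has_hydrogens():
        violations.append("warning: hydrogen inventory differs between WT and MT")
    return violations


def naive_mutate(model: StructureModel, mutation: MutationDescriptor
                 ) -> StructureModel:
    """Relabel a residue and strip its side chain beyond Cbeta.

    NON-PHYSICAL convenience for toy fixtures only: no side-chain rebuilding
    or refinement is performed, so the mutant geometry is wrong for any
    residue larger than Ala.  Real mutant structures must be prepared with a
    proper side-chain modelling tool and supplied as input.
    """
    res = model.residue(mutation.chain_id, mutation.site, mutation.icode)
    if res.res_name != ONE_TO_THREE[mutation.wt_aa]:
        raise ValueError(
            f"site {mutation.site_key} is {res.res_name}, descriptor expects "
            f"{ONE_TO_THREE[mutation.wt_aa]}")
    array = model.array.copy()
    keep_names = _BACKBONE_SET if mutation.mt_aa != "G" else _BACKBONE_SET - {"CB"}
    drop = np.zeros(array.array_length(), dtype=bool)
    drop[res.indices] = ~np.isin(array.atom_name[res.indices], sorted(keep_names))
    array = array[~drop]
    site_mask = ((array.chain_id == mutation.chain_id)
                 & (array.res_id == mutation.site)
                 & (array.ins_code == mutation.icode))
    array.res_name[site_mask] = ONE_TO_THREE[mutation.mt_aa]
    warnings.warn("naive_mutate produces non-physical side-chain geometry; "
                  "use only for toy fixtures", stacklevel=2)
    return StructureModel(array, source_label=f"{model.source_label}|{mutation}")
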