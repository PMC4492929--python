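"""High-level wiring: from structures to a routed ddG prediction.

These functions are the library's single entry points for whole-case work;
the narrative scripts under ``examples/`` drive them.  Every tunable keeps
the protocol default (1.4 A probe, 2.4 A hydrogen-bond cutoff, dielectrics
9/8/7 with uniform 7 for the Coulomb fallback, 1.0 kcal/mol small/large
split, 0.5/1.5 kcal/mol benchmark bands, 0.5 routing threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import (MutationAnnotation, ProbabilityTables,
                       load_default_tables)
from .model import WeightSet, load_default_weights, predict_auto, predict_ddg
from .structures import ComplexCase, validate_case
from .surface import RadiiTable, DEFAULT_RADII, locate_mutation_site
from .terms import EnergyComponents, TermVector, assemble_terms


@dataclass
class CasePrediction:
    """A routed prediction with full provenance."""

    case_id: str
    ddg: float
    subset_used: str
    consensus_p: float
    annotation: MutationAnnotation
    terms: TermVector
    violations: list[str]


def annotate_case(case: ComplexCase,
                  radii: RadiiTable = DEFAULT_RADII) -> MutationAnnotation:
    """The four classifier flags of a case (residue types + site locations)."""
    loc_wt, loc_mt = locate_mutation_site(case, radii)
    return MutationAnnotation(wt_aa=case.mutation.wt_aa,
                              mt_aa=case.mutation.mt_aa,
                              loc_wt=loc_wt, loc_mt=loc_mt)


def predict_case(case: ComplexCase,
                 energies: EnergyComponents | None = None,
                 tables: ProbabilityTables | None = None,
                 weights: dict[str, WeightSet] | None = None,
                 radii: RadiiTable = DEFAULT_RADII,
                 route: bool = True,
                 **term_kwargs) -> CasePrediction:
    """Full pipeline for one case: features, classification, prediction.

    With ``route=True`` (default) the small/large-effect classifier selects
    between the bundled subset weight sets; otherwise the all-data set is
    applied.  Extra keyword arguments reach the term assembly (hydrogen-bond
    cutoff, heavy-atom proxy mode, Coulomb dielectric, ...).
    """
    if tables is None:
        tables = load_default_tables()
    if weights is None:
        weights = load_default_weights()
    violations = validate_case(case)
    terms = assemble_terms(case, energies=energies, radii=radii, **term_kwargs)
    annotation = annotate_case(case, radii)
    if route:
        ddg, subset, p = predict_auto(terms, annotation, tables,
                                      weights["small"], weights["large"])
    else:
        from .classify import consensus_probability
        p, _ = consensus_probability(annotation, tables)
        ddg, subset = predict_ddg(terms, weights["all"]), "all"
    return CasePrediction(case_id=case.case_id, ddg=ddg, subset_used=subset,
                          consensus_p=p, annotation=annotation, terms=terms,
                          violations=violations)
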