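"""Deterministic synthetic inputs: toy complexes and simulated datasets.

Two generators make every stage of the pipeline testable without external
downloads or force-field runs:

* :func:`make_toy_complex` builds schematic two-partner complexes from
  idealized residue templates — chains run along x, side chains point at the
  binding partner across an adjustable gap, and polar hydrogens sit on the
  donor atoms so hydrogen-bond geometry can be planted exactly.  The
  geometry is deliberately cartoonish (no real backbone dihedrals); it is a
  substrate for surface, hydrogen-bond and Coulomb arithmetic, not a decoy
  structure.

* :func:`simulate_dataset` draws feature vectors from configured Gaussian
  distributions and produces ddG values from a known weight set plus
  Gaussian noise, for weight-recovery and cross-validation exercises.  The
  default per-term spreads roughly match the magnitudes seen in fitted
  weight tables (energies of a few kcal/mol, interfaces around 1600 A^2);
  they make no claim to reproduce a real mutation database.

All randomness flows from explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .constants import ONE_TO_THREE
from .model import WeightSet
from .structures import ComplexCase, MutationDescriptor, StructureModel

# ---------------------------------------------------------------------------
# toy complexes

#: residue spacing along the chain axis, Angstrom
_RESIDUE_SPACING = 3.8
#: backbone template, local coordinates relative to CA (x along chain,
#: y toward the binding partner, z out of plane)
_BACKBONE = (("N", -1.2, 0.0, 0.0), ("CA", 0.0, 0.0, 0.0),
             ("C", 1.2, 0.0, 0.0), ("O", 1.4, 0.0, 1.2))

# Side-chain heavy atoms (and the polar hydrogens of donor groups), local
# coordinates; y is scaled by the partner-facing direction.  Schematic bond
# lengths, not real rotamers.
_SIDE_CHAINS: dict[str, tuple] = {
    "G": (),
    "A": (("CB", 0.0, 1.53, 0.0),),
    "S": (("CB", 0.0, 1.53, 0.0), ("OG", 0.0, 2.9, 0.0), ("HG", 0.0, 3.86, 0.0)),
    "C": (("CB", 0.0, 1.53, 0.0), ("SG", 0.0, 3.0, 0.0)),
    "T": (("CB", 0.0, 1.53, 0.0), ("OG1", 0.7, 2.7, 0.0),
          ("CG2", -0.7, 2.7, 0.0), ("HG1", 0.7, 3.66, 0.0)),
    "V": (("CB", 0.0, 1.53, 0.0), ("CG1", 0.7, 2.7, 0.0), ("CG2", -0.7, 2.7, 0.0)),
    "L": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("CD1", 0.7, 4.0, 0.0), ("CD2", -0.7, 4.0, 0.0)),
    "I": (("CB", 0.0, 1.53, 0.0), ("CG1", 0.7, 2.7, 0.0),
          ("CG2", -0.7, 2.7, 0.0), ("CD1", 0.7, 4.0, 0.0)),
    "P": (("CB", 0.0, 1.53, 0.0), ("CG", -0.8, 2.3, 0.8), ("CD", -1.7, 1.2, 0.6)),
    "M": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("SD", 0.0, 4.3, 0.0), ("CE", 0.8, 5.5, 0.0)),
    "F": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("CD1", 0.7, 3.9, 0.0), ("CD2", -0.7, 3.9, 0.0),
          ("CE1", 0.7, 5.2, 0.0), ("CE2", -0.7, 5.2, 0.0), ("CZ", 0.0, 5.9, 0.0)),
    "Y": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("CD1", 0.7, 3.9, 0.0), ("CD2", -0.7, 3.9, 0.0),
          ("CE1", 0.7, 5.2, 0.0), ("CE2", -0.7, 5.2, 0.0),
          ("CZ", 0.0, 5.9, 0.0), ("OH", 0.0, 7.2, 0.0), ("HH", 0.0, 8.1, 0.0)),
    "W": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("CD1", 0.9, 3.8, 0.0), ("CD2", -0.7, 3.9, 0.0),
          ("NE1", 0.6, 5.0, 0.0), ("CE2", -0.5, 5.2, 0.0),
          ("CE3", -1.9, 4.0, 0.0), ("CZ2", -1.1, 6.3, 0.0),
          ("CZ3", -2.6, 5.2, 0.0), ("CH2", -2.2, 6.4, 0.0)),
    "D": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("OD1", 0.9, 3.7, 0.0), ("OD2", -0.9, 3.7, 0.0)),
    "E": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0), ("CD", 0.0, 4.3, 0.0),
          ("OE1", 0.9, 5.1, 0.0), ("OE2", -0.9, 5.1, 0.0)),
    "N": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("OD1", 0.9, 3.7, 0.0), ("ND2", -0.9, 3.7, 0.0),
          ("HD21", -0.9, 4.7, 0.0)),
    "Q": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0), ("CD", 0.0, 4.3, 0.0),
          ("OE1", 0.9, 5.1, 0.0), ("NE2", -0.9, 5.1, 0.0),
          ("HE21", -0.9, 6.1, 0.0)),
    "K": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0), ("CD", 0.0, 4.3, 0.0),
          ("CE", 0.0, 5.7, 0.0), ("NZ", 0.0, 7.0, 0.0), ("HZ1", 0.0, 8.0, 0.0)),
    "R": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0), ("CD", 0.0, 4.3, 0.0),
          ("NE", 0.0, 5.6, 0.0), ("CZ", 0.0, 6.9, 0.0),
          ("NH1", 0.9, 7.7, 0.0), ("NH2", -0.9, 7.7, 0.0),
          ("HH11", 0.9, 8.7, 0.0)),
    "H": (("CB", 0.0, 1.53, 0.0), ("CG", 0.0, 2.9, 0.0),
          ("ND1", 0.8, 3.8, 0.0), ("CD2", -0.8, 3.8, 0.0),
          ("CE1", 0.5, 5.1, 0.0), ("NE2", -0.6, 5.1, 0.0),
          ("HD1", 1.6, 3.9, 0.6)),
}

#: default acceptor atom for hydrogen-bond planting, per residue type
_DEFAULT_ACCEPTOR = {"S": "OG", "T": "OG1", "Y": "OH", "D": "OD1",
                     "E": "OE1", "N": "OD1", "Q": "OE1"}
#: the donor hydrogen of each donor-capable residue type
_DONOR_HYDROGEN = {"S": "HG", "T": "HG1", "Y": "HH", "N": "HD21",
                   "Q": "HE21", "K": "HZ1", "R": "HH11", "H": "HD1"}

#: inter-atomic distance below which the generator declares a clash
_CLASH_DISTANCE = 0.5


class GeometryError(ValueError):
    """Raised when a generated layout contains impossible geometry."""


def _build_model(chains: dict[str, str], partner_a: set[str], gap: float,
                 seed: int, hydrogens: bool, label: str) -> StructureModel:
    names, elements, chain_ids, res_ids, res_names, coords = [], [], [], [], [], []
    for chain_idx, (chain_id, sequence) in enumerate(sorted(chains.items())):
        in_a = chain_id in partner_a
        y_base = 0.0 if in_a else gap
        s_dir = 1.0 if in_a else -1.0
        # stack multiple chains of one partner along z
        partner_members = sorted(c for c in chains if (c in partner_a) == in_a)
        z_base = 8.0 * partner_members.index(chain_id)
        for site, aa in enumerate(sequence, start=1):
            if aa not in _SIDE_CHAINS:
                raise ValueError(f"not a canonical amino acid: {aa!r}")
            rng = np.random.default_rng([seed, chain_idx, site])
            jitter = rng.normal(0.0, 0.05, size=3)
            origin = np.array([site * _RESIDUE_SPACING, y_base, z_base]) + jitter
            atoms = list(_BACKBONE) + list(_SIDE_CHAINS[aa])
            for name, x, y, z in atoms:
                if name.startswith("H") and not hydrogens:
                    continue
                names.append(name)
                elements.append(name[0])
                chain_ids.append(chain_id)
                res_ids.append(site)
                res_names.append(ONE_TO_THREE[aa])
                coords.append(origin + np.array([x, s_dir * y, z]))
    array = struc.AtomArray(len(names))
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = np.array(chain_ids)
    array.res_id = np.array(res_ids)
    array.res_name = np.array(res_names)
    array.atom_name = np.array(names)
    array.element = np.array(elements)
    array.hetero = np.zeros(len(names), dtype=bool)
    return StructureModel(array, source_label=label)


def _check_clashes(model: StructureModel) -> None:
    from scipy.spatial import cKDTree
    heavy = model.array.coord[model.array.element != "H"]
    tree = cKDTree(heavy)
    pairs = tree.query_pairs(r=_CLASH_DISTANCE)
    if pairs:
        raise GeometryError(
            f"impossible geometry: {len(pairs)} heavy-atom pair(s) closer "
            f"than {_CLASH_DISTANCE} A in {model.source_label!r}")


def _plant_hbond(model: StructureModel, donor: tuple, acceptor: tuple,
                 distance: float) -> None:
    """Move a donor hydrogen so its distance to the acceptor O is exact."""
    from .constants import THREE_TO_ONE
    d_res = model.residue(*donor)
    a_res = model.residue(*acceptor)
    d_aa, a_aa = THREE_TO_ONE[d_res.res_name], THREE_TO_ONE[a_res.res_name]
    h_name = _DONOR_HYDROGEN.get(d_aa)
    if h_name is None:
        raise ValueError(f"residue type {d_aa} has no donor hydrogen")
    acc_name = _DEFAULT_ACCEPTOR.get(a_aa, "O")
    h_pos = d_res.atom_coord(h_name)
    heavy_name = {"HG": "OG", "HG1": "OG1", "HH": "OH", "HD21": "ND2",
                  "HE21": "NE2", "HZ1": "NZ", "HH11": "NH1", "HD1": "ND1"}[h_name]
    heavy = d_res.atom_coord(heavy_name)
    acc = a_res.atom_coord(acc_name)
    if h_pos is None or heavy is None or acc is None:
        raise ValueError("donor/acceptor atoms missing for hydrogen-bond planting")
    direction = heavy - acc
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise GeometryError("donor and acceptor coincide")
    new_h = acc + direction / norm * distance
    idx = d_res.indices[np.nonzero(
        model.array.atom_name[d_res.indices] == h_name)[0][0]]
    model.array.coord[idx] = new_h


def make_toy_complex(chains: dict[str, str],
                     partner_a: set[str] | None = None,
                     gap: float = 12.0,
                     seed: int = 0,
                     hydrogens: bool = True,
                     mutation: MutationDescriptor | None = None,
                     hbond: dict | None = None,
                     case_id: str = "") -> ComplexCase:
    """Build a deterministic WT/MT toy complex.

    ``chains`` maps chain id to one-letter sequence; ``partner_a`` names the
    chains of the first binding partner (default: the alphabetically first
    chain).  Partners face each other across ``gap`` Angstrom (measured
    CA-plane to CA-plane).  If ``mutation`` is given, the MT structure is
    rebuilt with the substituted residue type at the site — backbone
    coordinates are shared with the WT, so only side-chain atoms differ.
    ``hbond = {"donor": (chain, site), "acceptor": (chain, site),
    "distance": d}`` plants an exact donor-H...acceptor-O contact in both
    states.  Identical arguments produce bit-identical structures.
    """
    chain_ids = set(chains)
    if partner_a is None:
        partner_a = {sorted(chain_ids)[0]}
    partner_b = chain_ids - set(partner_a)
    if not partner_b:
        raise ValueError("partner B has no chains")

    wt = _build_model(chains, set(partner_a), gap, seed, hydrogens, "toy|WT")
    if mutation is None:
        first_chain = sorted(chains)[0]
        aa = chains[first_chain][0]
        mutation = MutationDescriptor(first_chain, 1, aa, aa)
    mt_chains = dict(chains)
    seq = mt_chains[mutation.chain_id]
    if seq[mutation.site - 1] != mutation.wt_aa:
        raise ValueError(
            f"sequence has {seq[mutation.site - 1]} at site {mutation.site}, "
            f"descriptor expects {mutation.wt_aa}")
    mt_chains[mutation.chain_id] = (seq[:mutation.site - 1] + mutation.mt_aa
                                    + seq[mutation.site:])
    mt = _build_model(mt_chains, set(partner_a), gap, seed, hydrogens, "toy|MT")

    if hbond is not None:
        for model in (wt, mt):
            _plant_hbond(model, hbond["donor"], hbond["acceptor"],
                         hbond["distance"])
    for model in (wt, mt):
        _check_clashes(model)
    return ComplexCase(wt_complex=wt, mt_complex=mt,
                       partner_a_chains=set(partner_a),
                       partner_b_chains=partner_b, mutation=mutation,
                       case_id=case_id or f"toy-{mutation}")


# ---------------------------------------------------------------------------
# simulated feature/ddG datasets

#: per-term (mean, SD) of the synthetic feature distributions; spreads chosen
#: so each term's typical magnitude matches its role in the fitted formula
DEFAULT_FEATURE_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "d_ie": (0.0, 10.0),
    "dd_ee": (0.0, 2.0),
    "dd_ve": (0.0, 2.0),
    "dd_sp": (0.0, 2.0),
    "dd_sn": (0.0, 30.0),
    "dd_s": (0.0, 1.5),
    "dd_hydr": (0.0, 1.0),
    "d_hb": (0.0, 1.0),
    "interface_mt": (1600.0, 400.0),
    "dd_sasa_over_interface": (0.0, 0.03),
}


@dataclass
class SimulationConfig:
    """Recipe for one simulated feature/ddG dataset."""

    n_cases: int
    true_weights: WeightSet
    noise_sd: float = 0.5
    seed: int = 0
    feature_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_DISTRIBUTIONS))

    def __post_init__(self):
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw features and generate ddG = w0 + w.x + N(0, noise_sd).

    Returns (features, ddg, metadata); the metadata embeds the seed, noise
    level and generating distributions so the output is self-describing.
    """
    rng = np.random.default_rng(config.seed)
    cols = {}
    for name, (mean, sd) in config.feature_distributions.items():
        cols[name] = rng.normal(mean, sd, size=config.n_cases)
    features = pd.DataFrame(cols)
    w = config.true_weights
    signal = w.w0 + sum(w.weights[name] * features[name]
                        for name in features.columns)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_cases)
    ddg = pd.Series(signal + noise, name="ddg_exp")
    meta = {
        "generator": "ddgbind.fixtures.simulate_dataset",
        "n_cases": config.n_cases,
        "seed": config.seed,
        "noise_sd": config.noise_sd,
        "true_w0": w.w0,
        "true_weights": dict(w.weights),
        "feature_distributions": {k: list(v) for k, v
                                  in config.feature_distributions.items()},
    }
    return features, ddg, meta


def expected_correlation(config: SimulationConfig) -> float:
    """Analytic Pearson r between the noiseless signal and noisy ddG.

    Features are independent Gaussians, so the signal variance is
    sum_k (w_k * sd_k)^2 and r = sqrt(Vs / (Vs + noise_sd^2)).
    """
    v_signal = sum(
        (config.true_weights.weights[name] * sd) ** 2
        for name, (_, sd) in config.feature_distributions.items())
    total = v_signal + config.noise_sd ** 2
    return float(np.sqrt(v_signal / total)) if total > 0 else 0.0


def make_dielectric_scan_problem(n_cases: int = 300, seed: int = 0,
                                 true_eps: tuple = (9.0, 8.0, 7.0),
                                 noise_sd: float = 0.3):
    """Synthetic dataset with a planted optimum in dielectric space.

    Each case carries, for each of the three epsilon-dependent terms, latent
    per-class interaction magnitudes (a, b, c) plus a dielectric-independent
    component d; the term evaluated at a dielectric triple is
    a/eps1 + b/eps2 + c/eps3 + d (scaled).  The d component breaks the
    overall-scale degeneracy of a pure 1/eps mixture (proportional triples
    would otherwise span the same fitted subspace).  The observed ddG
    derives from the terms evaluated at ``true_eps``, so the scan's
    correlation grid peaks there.

    Returns ``(provider, ddg)`` suitable for the dielectric-scan routine.
    """
    rng = np.random.default_rng(seed)
    terms = ("dd_ee", "dd_ve", "dd_sp")
    # distinct latent scales per term and class keep the three features
    # linearly independent across the grid
    scales = {"dd_ee": (3.0, 1.5, 2.0, 1.0), "dd_ve": (1.0, 2.5, 1.5, 1.0),
              "dd_sp": (2.0, 1.0, 3.0, 1.0)}
    latents = {t: rng.normal(0.0, scales[t], size=(n_cases, 4)) for t in terms}
    true_w = {"dd_ee": 1.0, "dd_ve": 0.8, "dd_sp": 1.2}

    def features_at(eps1: float, eps2: float, eps3: float) -> pd.DataFrame:
        inv = np.array([7.0 / eps1, 7.0 / eps2, 7.0 / eps3, 1.0])
        return pd.DataFrame({t: latents[t] @ inv for t in terms})

    base = features_at(*true_eps)
    noise = rng.normal(0.0, noise_sd, size=n_cases)
    ddg = pd.Series(
        1.0 + sum(true_w[t] * base[t] for t in terms) + noise, name="ddg_exp")
    return features_at, ddg
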