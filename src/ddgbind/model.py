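"""Linear scoring model: prediction, weight fitting, validation, dielectric scan.

The predicted binding free energy change is a weighted linear combination of
the ten features,

    ddG = w0 + w1*dIE + w2*ddEE + w3*ddVE + w4*ddSP + w5*ddSN
             + w6*ddS + w7*ddHYDR + w8*dHB + w9*Interface_MT
             + w10*(ddSASA / Interface_MT),

with three bundled weight sets fitted by ordinary least squares against
experimental data: one for mutations expected to cause a small effect, one
for large-effect mutations, and one fitted on the full training set.
Routing between the small and large sets uses the consensus probability of
the classifier (P >= 0.5 selects the large set).
"""

from __future__ import annotations

import json
import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold

from .classify import MutationAnnotation, ProbabilityTables, consensus_probability
from .terms import TERM_NAMES, TermVector, MissingTermError

#: default seed for the cross-validation partition
DEFAULT_CV_SEED = 20150706

#: dielectric-scan grids: charged 5..15, polar 3..13, other 3..13, step 2
DEFAULT_EPS1_VALUES = tuple(range(5, 16, 2))
DEFAULT_EPS2_VALUES = tuple(range(3, 14, 2))
DEFAULT_EPS3_VALUES = tuple(range(3, 14, 2))


@dataclass
class WeightSet:
    """Intercept plus per-term weights of the linear formula.

    Terms not used by a subset are explicit zeros.  ``slope``/``y_intercept``
    are opaque fit metadata carried along for reference; predictions never
    apply them.
    """

    w0: float
    weights: dict = field(default_factory=dict)
    subset: str = "all"
    pvalues: dict = field(default_factory=dict)
    n_cases: int | None = None
    slope: float | None = None
    y_intercept: float | None = None

    def __post_init__(self):
        unknown = set(self.weights) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown term names in weight set: {sorted(unknown)}")
        self.weights = {name: float(self.weights.get(name, 0.0))
                        for name in TERM_NAMES}

    @property
    def active_terms(self) -> list[str]:
        return [name for name in TERM_NAMES if self.weights[name] != 0.0]

    def to_json(self) -> str:
        return json.dumps({
            "subset": self.subset, "w0": self.w0, "weights": self.weights,
            "pvalues": self.pvalues, "n_cases": self.n_cases,
            "slope": self.slope, "y_intercept": self.y_intercept,
        }, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "WeightSet":
        return cls(w0=d["w0"], weights=d.get("weights", {}),
                   subset=d.get("subset", "all"), pvalues=d.get("pvalues", {}),
                   n_cases=d.get("n_cases"), slope=d.get("slope"),
                   y_intercept=d.get("y_intercept"))


def load_default_weights() -> dict[str, WeightSet]:
    """The three bundled fitted weight sets, keyed 'small', 'large', 'all'."""
    raw = json.loads((resources.files("ddgbind") / "data"
                      / "weight_sets.json").read_text())
    return {key: WeightSet.from_dict(d) for key, d in raw.items()}


def predict_ddg(terms: TermVector | dict | pd.Series, weights: WeightSet) -> float:
    """Evaluate the linear formula; kcal/mol.

    Every term with a nonzero weight must be present (not None), otherwise
    :class:`MissingTermError` is raised naming the term.
    """
    if isinstance(terms, TermVector):
        getter = terms.as_dict().get
    else:
        getter = dict(terms).get
    total = weights.w0
    for name in TERM_NAMES:
        w = weights.weights[name]
        if w == 0.0:
            continue
        val = getter(name)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise MissingTermError(
                f"term {name} required by weight set {weights.subset!r} "
                "is unavailable")
        total += w * float(val)
    return float(total)


def predict_auto(terms: TermVector | dict, annotation: MutationAnnotation,
                 tables: ProbabilityTables, weights_small: WeightSet,
                 weights_large: WeightSet) -> tuple[float, str, float]:
    """Classifier-routed prediction.

    Returns ``(ddg, subset_used, consensus_p)``: the large-effect weight set
    is applied when the consensus probability P >= 0.5, the small-effect set
    otherwise.
    """
    p, tag = consensus_probability(annotation, tables)
    chosen = weights_large if tag == "large" else weights_small
    return predict_ddg(terms, chosen), tag, p


@dataclass
class FitResult:
    """Outcome of a least-squares weight fit."""

    weights: WeightSet
    pearson_r: float
    n_cases: int
    residual_sd: float
    fitted: np.ndarray

    def __post_init__(self):
        if not -1.0000001 <= self.pearson_r <= 1.0000001:
            raise ValueError("pearson_r out of range")


def _design_matrix(features: pd.DataFrame, active_terms: list[str]
                   ) -> np.ndarray:
    X = features[active_terms].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [t for t in active_terms if features[t].isna().any()]
        raise ValueError(f"features contain missing values in terms: {bad}")
    return X


def fit_weights(features: pd.DataFrame, ddg_exp, active_terms=None,
                subset: str = "all") -> FitResult:
    """Ordinary least squares fit of the weights against experimental ddG.

    ``features`` holds one column per term; ``active_terms`` restricts the
    fit (default: every term column present).  Returns the fitted weight
    set with two-sided t-test p-values, the Pearson correlation between
    fitted and experimental values, and the residual standard deviation.
    """
    if active_terms is None:
        active_terms = [t for t in TERM_NAMES if t in features.columns]
    y = np.asarray(ddg_exp, dtype=float)
    n, p = len(y), len(active_terms)
    if n < p + 2:
        raise ValueError(
            f"insufficient data: {n} cases for {p} terms plus intercept")
    X = _design_matrix(features, active_terms)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # identify collinear columns for the error message
        collinear = []
        for k, name in enumerate(active_terms):
            others = np.delete(Xc, k + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xc):
                collinear.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear terms: "
                         f"{collinear or active_terms}")
    res = sm.OLS(y, Xc).fit()
    fitted = res.fittedvalues
    r = float(stats.pearsonr(fitted, y)[0]) if np.std(fitted) > 0 else 0.0
    weights = WeightSet(
        w0=float(res.params[0]),
        weights={name: float(res.params[k + 1])
                 for k, name in enumerate(active_terms)},
        subset=subset,
        pvalues={"w0": float(res.pvalues[0]),
                 **{name: float(res.pvalues[k + 1])
                    for k, name in enumerate(active_terms)}},
        n_cases=n,
    )
    residual_sd = float(np.std(y - fitted, ddof=p + 1))
    return FitResult(weights=weights, pearson_r=r, n_cases=n,
                     residual_sd=residual_sd, fitted=fitted)


def cross_validate(features: pd.DataFrame, ddg_exp, k: int = 5,
                   seed: int = DEFAULT_CV_SEED, active_terms=None
                   ) -> tuple[float, list[float]]:
    """k-fold cross-validated correlation (mean over folds, per-fold list).

    The data are randomly partitioned into k folds of near-equal size
    (sizes differ by at most one); each fold is predicted by a model
    trained on the other k-1.  Reproducible for a given seed.
    """
    y = np.asarray(ddg_exp, dtype=float)
    if active_terms is None:
        active_terms = [t for t in TERM_NAMES if t in features.columns]
    if len(y) < k * (len(active_terms) + 1):
        raise ValueError("too few cases for the requested fold count")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_rs = []
    features = features.reset_index(drop=True)
    for train_idx, test_idx in kf.split(y):
        fit = fit_weights(features.iloc[train_idx], y[train_idx], active_terms)
        preds = np.array([predict_ddg(features.iloc[i], fit.weights)
                          for i in test_idx])
        fold_rs.append(float(stats.pearsonr(preds, y[test_idx])[0]))
    return float(np.mean(fold_rs)), fold_rs


def trim_2sd(predicted, experimental) -> tuple[np.ndarray, float]:
    """Drop >2-SD residual outliers from a linear fit and recompute r.

    Fits experimental ~ predicted by least squares, removes points whose
    absolute residual exceeds twice the residual standard deviation (one
    pass), and returns the keep-mask plus the Pearson r of the survivors.
    """
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if len(pred) < 10:
        raise ValueError("need at least 10 points to trim")
    if np.std(pred) == 0:
        raise ValueError("degenerate input: all predictions identical")
    slope, intercept = np.polyfit(pred, exp, 1)
    residuals = exp - (slope * pred + intercept)
    sd = float(np.std(residuals))
    scale = max(1.0, float(np.abs(exp).max()))
    if sd <= 1e-10 * scale:  # numerically perfect fit: nothing to trim
        mask = np.ones(len(pred), dtype=bool)
    else:
        mask = np.abs(residuals) <= 2.0 * sd
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points survive the 2-SD trim")
    r = float(stats.pearsonr(pred[mask], exp[mask])[0])
    return mask, r


@dataclass
class DielectricScanResult:
    """Correlation grid over (charged, polar, other) dielectric constants."""

    eps1_values: tuple
    eps2_values: tuple
    eps3_values: tuple
    r_grid: np.ndarray  # shape (len(eps1), len(eps2), len(eps3))

    @property
    def best(self) -> tuple[float, float, float]:
        i, j, k = np.unravel_index(int(np.argmax(self.r_grid)),
                                   self.r_grid.shape)
        return (self.eps1_values[i], self.eps2_values[j], self.eps3_values[k])

    @property
    def best_r(self) -> float:
        return float(self.r_grid.max())


def scan_dielectrics(provider, ddg_exp,
                     eps1_values=DEFAULT_EPS1_VALUES,
                     eps2_values=DEFAULT_EPS2_VALUES,
                     eps3_values=DEFAULT_EPS3_VALUES,
                     refit_terms=("dd_ee", "dd_ve", "dd_sp")
                     ) -> DielectricScanResult:
    """Grid-scan the three residue-class dielectric constants.

    ``provider(eps1, eps2, eps3)`` must return a feature DataFrame holding
    at least the ``refit_terms`` columns, re-evaluated for that dielectric
    assignment (charged, polar, other).  At each grid point the reduced
    formula containing only the epsilon-dependent terms is refitted by
    least squares and the training correlation recorded; the grid argmax is
    the recommended dielectric triple.
    """
    if provider is None:
        raise ValueError("an epsilon-dependent feature provider is required")
    y = np.asarray(ddg_exp, dtype=float)
    r_grid = np.empty((len(eps1_values), len(eps2_values), len(eps3_values)))
    for (i, e1), (j, e2), (k, e3) in itertools.product(
            enumerate(eps1_values), enumerate(eps2_values),
            enumerate(eps3_values)):
        feats = provider(e1, e2, e3)
        fit = fit_weights(feats, y, active_terms=list(refit_terms))
        r_grid[i, j, k] = fit.pearson_r
    return DielectricScanResult(tuple(eps1_values), tuple(eps2_values),
                                tuple(eps3_values), r_grid)
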