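"""Correlation-weight tables, DCW computation, and the Monte-Carlo optimiser.

The optimal descriptor of a molecule is

    DCW(T, N) = sum over the molecule's attribute instances of CW(A),

where ``CW(A)`` is the *correlation weight* of structural attribute ``A``,
``T`` is a rarity threshold (attributes seen in fewer than ``T`` sub-training
compounds are *blocked* and contribute zero), and ``N`` is the number of
Monte-Carlo epochs spent tuning the weights.  The endpoint model is the
one-variable regression ``pIC50 = C0 + C1 * DCW``.

Weights are tuned by a greedy Monte-Carlo walk: starting from random weights,
each epoch visits every active attribute once in random order and proposes a
uniform perturbation of its weight; a proposal is kept iff it strictly
increases the target function

    TF = r_sub + r_inv - |r_sub - r_inv| * d_weight,

with ``r_sub``/``r_inv`` the Pearson correlations between DCW and the
endpoint on the sub-training and invisible-training sets.  The invisible set
thus steers the objective without ever entering the regression fit, and the
accepted-TF trajectory is non-decreasing by construction.

:class:`DcwRegressor` packages the whole procedure as a scikit-learn
estimator; the module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Compound, CompoundSet
from .graph_attributes import (
    extended_connectivity,
    extract_graph_attributes,
    smiles_to_graph,
)
from .smiles_attributes import extract_smiles_attributes, tokenize

__all__ = [
    "MODES",
    "CorrelationWeightTable",
    "DcwRegressor",
    "compound_profile",
    "attribute_frequencies",
    "apply_threshold",
    "compute_dcw",
    "fit_regression",
    "target_function",
    "monte_carlo_optimize",
    "predict",
]

MODES = ("smiles", "graph", "hybrid")


def compound_profile(
    smiles: str,
    mode: str = "hybrid",
    smiles_scheme: Sequence[str] = ("S1", "S2"),
    ec_orders: Sequence[int] = (0, 1, 2),
) -> Counter:
    """Attribute profile of one SMILES under a descriptor mode.

    ``smiles`` mode uses the string attributes only, ``graph`` mode the
    extended-connectivity attributes only, and ``hybrid`` the union of both
    (the kinds live in distinct code namespaces, so the union is a plain
    multiset sum).
    """
    if mode not in MODES:
        raise ValueError(f"unknown descriptor mode {mode!r}")
    profile: Counter = Counter()
    if mode in ("smiles", "hybrid"):
        profile += extract_smiles_attributes(tokenize(smiles), smiles_scheme)
    if mode in ("graph", "hybrid"):
        g = smiles_to_graph(smiles)
        k_max = max(ec_orders) if len(ec_orders) else 0
        vectors = extended_connectivity(g, k_max)
        full = extract_graph_attributes(g, vectors)
        keep = {f"EC{k}" for k in ec_orders}
        profile += Counter(
            {a: c for a, c in full.items() if a.split(":", 1)[0] in keep}
        )
    return profile


@dataclass
class CorrelationWeightTable:
    """Attribute → weight map with its blocked set and threshold."""

    weights: dict[str, float]
    blocked: frozenset[str] = frozenset()
    threshold: int = 0
    mode: str = "hybrid"


def attribute_frequencies(
    cs: CompoundSet | Iterable[str],
    mode: str = "hybrid",
    smiles_scheme: Sequence[str] = ("S1", "S2"),
    ec_orders: Sequence[int] = (0, 1, 2),
) -> dict[str, int]:
    """Per attribute, the number of distinct compounds containing it."""
    smiles_list = cs.smiles() if isinstance(cs, CompoundSet) else list(cs)
    freqs: Counter = Counter()
    for s in smiles_list:
        freqs.update(set(compound_profile(s, mode, smiles_scheme, ec_orders)))
    return dict(freqs)


def apply_threshold(freqs: Mapping[str, int], threshold: int) -> frozenset[str]:
    """Attributes rarer than ``threshold`` (strictly) are blocked; T=0 blocks
    nothing."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return frozenset(a for a, f in freqs.items() if f < threshold)


def compute_dcw(profile: Mapping[str, int], cw: CorrelationWeightTable) -> float:
    """Sum of weight × count over the profile's non-blocked attributes;
    attributes absent from the table contribute zero."""
    return float(
        sum(
            cw.weights.get(a, 0.0) * c
            for a, c in profile.items()
            if a not in cw.blocked
        )
    )


def fit_regression(
    dcw_values: Sequence[float], endpoints: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of endpoint on DCW: (intercept, slope, Pearson r)."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate descriptor: DCW has zero variance")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue)


def target_function(r_sub: float, r_inv: float, d_weight: float = 0.01) -> float:
    """Balanced two-set objective of the Monte-Carlo walk."""
    return r_sub + r_inv - abs(r_sub - r_inv) * d_weight


def _pearson_to(y_centered: np.ndarray, y_norm: float, x: np.ndarray) -> float:
    """Pearson r of x against a pre-centered, pre-normed y; 0 on zero variance."""
    n = x.size
    sxx = float(x @ x) - float(x.sum()) ** 2 / n
    if sxx <= 0 or y_norm == 0:
        return 0.0
    return float(x @ y_centered) / math.sqrt(sxx) / y_norm


class DcwRegressor(RegressorMixin, BaseEstimator):
    """Monte-Carlo correlation-weight optimal-descriptor regressor.

    Parameters
    ----------
    mode : {'smiles', 'graph', 'hybrid'}
        Attribute source: SMILES string attributes, molecular-graph
        extended-connectivity attributes, or their union.
    smiles_scheme : sequence of {'S1','S2','S3','NOSP','BOND','HALO'}
        String attribute kinds (ignored in graph mode).
    ec_orders : sequence of int
        Extended-connectivity orders (ignored in smiles mode).
    threshold : int
        Rarity threshold T: attributes present in fewer than T sub-training
        compounds are blocked.
    n_epochs : int
        Number N of Monte-Carlo epochs (full passes over the active
        attributes).  ``n_epochs=0`` keeps the random initial weights.
    step : float
        Half-width of the uniform weight-perturbation proposal.
    d_weight : float
        Disbalance penalty of the target function.
    init_range : (float, float)
        Uniform initialisation range of the weights.  The overall weight
        scale is immaterial because the slope ``C1`` absorbs it.
    accept_equal : bool
        Accept proposals that leave the target function exactly unchanged
        (default: reject, keeping the trajectory strictly monotone on
        acceptance).
    random_state : int or None
        Seed of the single generator driving initialisation, visit order,
        and proposals.  Identical seeds give bit-identical weight tables.

    Attributes
    ----------
    weights_ : dict        attribute → optimised correlation weight
    blocked_ : frozenset   attributes blocked by the threshold
    frequencies_ : dict    sub-training compound frequencies of attributes
    intercept_, slope_ : float   regression coefficients C0, C1
    coef_ : ndarray        ``[slope_]`` (scikit-learn convention)
    r_sub_, r_inv_ : float final training correlations
    tf_trajectory_ : list  accepted target-function value after each epoch
                           (index 0 = initial state); non-decreasing
    calibration_r2_per_epoch_, best_epoch_ :
        recorded only when a calibration set is passed to :meth:`fit`;
        the argmax epoch is reported, never applied.

    Examples
    --------
    >>> est = DcwRegressor(mode='smiles', n_epochs=20, random_state=0)
    >>> est.fit(["CCO", "CCCO", "CCCCO", "CO"], [1.0, 2.0, 3.0, 0.0])
    DcwRegressor(mode='smiles', n_epochs=20, random_state=0)
    >>> est.predict(["CCO"]).shape
    (1,)
    """

    def __init__(
        self,
        mode: str = "hybrid",
        smiles_scheme: Sequence[str] = ("S1", "S2"),
        ec_orders: Sequence[int] = (0, 1, 2),
        threshold: int = 0,
        n_epochs: int = 41,
        step: float = 0.5,
        d_weight: float = 0.01,
        init_range: tuple[float, float] = (0.5, 1.5),
        accept_equal: bool = False,
        random_state: int | None = None,
    ) -> None:
        self.mode = mode
        self.smiles_scheme = smiles_scheme
        self.ec_orders = ec_orders
        self.threshold = threshold
        self.n_epochs = n_epochs
        self.step = step
        self.d_weight = d_weight
        self.init_range = init_range
        self.accept_equal = accept_equal
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _profile(self, smiles: str) -> Counter:
        return compound_profile(smiles, self.mode, self.smiles_scheme, self.ec_orders)

    def _as_smiles_y(self, X, y=None):
        smiles = X.smiles() if isinstance(X, CompoundSet) else [str(s) for s in X]
        if y is None and isinstance(X, CompoundSet):
            y = X.endpoints()
        return smiles, None if y is None else np.asarray(y, dtype=float)

    def correlation_weight_table(self) -> CorrelationWeightTable:
        check_is_fitted(self, "weights_")
        return CorrelationWeightTable(
            dict(self.weights_), self.blocked_, self.threshold, self.mode
        )

    # -- scikit-learn API --------------------------------------------------

    def fit(self, X, y=None, X_invisible=None, y_invisible=None,
            X_calibration=None, y_calibration=None):
        """Optimise the correlation weights and fit C0/C1.

        ``X`` (with ``y``) is the sub-training set — a sequence of SMILES
        strings or a :class:`~dcwqsar.corpus.CompoundSet`.  The invisible
        training set steers the target function; when omitted, the
        sub-training set plays both roles.  A calibration set, when given,
        is only monitored (per-epoch r², for choosing a preferable N).
        """
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")
        smiles_sub, y_sub = self._as_smiles_y(X, y)
        if y_sub is None or len(smiles_sub) != y_sub.size or not len(smiles_sub):
            raise ValueError("sub-training SMILES and endpoints are required")
        if X_invisible is None:
            smiles_inv, y_inv = smiles_sub, y_sub
        else:
            smiles_inv, y_inv = self._as_smiles_y(X_invisible, y_invisible)
            if y_inv is None:
                raise ValueError("invisible-training endpoints are required")

        prof_sub = [self._profile(s) for s in smiles_sub]
        prof_inv = [self._profile(s) for s in smiles_inv]

        freqs: Counter = Counter()
        for p in prof_sub:
            freqs.update(set(p))
        self.frequencies_ = dict(freqs)

        all_attrs = sorted(set().union(*prof_sub, *prof_inv))
        if not all_attrs:
            raise ValueError("empty attribute space")
        self.blocked_ = frozenset(
            a for a in all_attrs if freqs.get(a, 0) < self.threshold
        )
        active = [a for a in all_attrs if a not in self.blocked_]
        if not active:
            raise ValueError("all attributes blocked by the threshold")
        col = {a: j for j, a in enumerate(active)}

        def matrix(profiles) -> np.ndarray:
            m = np.zeros((len(profiles), len(active)))
            for i, p in enumerate(profiles):
                for a, c in p.items():
                    j = col.get(a)
                    if j is not None:
                        m[i, j] = c
            return m

        Xs, Xi = matrix(prof_sub), matrix(prof_inv)

        ys_c = y_sub - y_sub.mean()
        ys_norm = math.sqrt(float(ys_c @ ys_c))
        yi_c = y_inv - y_inv.mean()
        yi_norm = math.sqrt(float(yi_c @ yi_c))

        rng = np.random.default_rng(self.random_state)
        lo, hi = self.init_range
        w = rng.uniform(lo, hi, size=len(active))
        dcw_sub = Xs @ w
        dcw_inv = Xi @ w

        def tf_of(ds: np.ndarray, di: np.ndarray) -> tuple[float, float, float]:
            rs = _pearson_to(ys_c, ys_norm, ds)
            ri = _pearson_to(yi_c, yi_norm, di)
            return target_function(rs, ri, self.d_weight), rs, ri

        tf, r_sub, r_inv = tf_of(dcw_sub, dcw_inv)
        self.tf_trajectory_ = [tf]

        monitor = X_calibration is not None
        if monitor:
            smiles_cal, y_cal = self._as_smiles_y(X_calibration, y_calibration)
            Xc = matrix([self._profile(s) for s in smiles_cal])
            yc_c = y_cal - y_cal.mean()
            yc_norm = math.sqrt(float(yc_c @ yc_c))
            dcw_cal = Xc @ w
            self.calibration_r2_per_epoch_ = []

        for _ in range(self.n_epochs):
            order = rng.permutation(len(active))
            deltas = rng.uniform(-self.step, self.step, size=len(active))
            for j, delta in zip(order, deltas):
                cand_sub = dcw_sub + delta * Xs[:, j]
                cand_inv = dcw_inv + delta * Xi[:, j]
                cand_tf, rs, ri = tf_of(cand_sub, cand_inv)
                if cand_tf > tf or (self.accept_equal and cand_tf == tf):
                    w[j] += delta
                    dcw_sub, dcw_inv = cand_sub, cand_inv
                    tf, r_sub, r_inv = cand_tf, rs, ri
                    if monitor:
                        dcw_cal = dcw_cal + delta * Xc[:, j]
            self.tf_trajectory_.append(tf)
            if monitor:
                self.calibration_r2_per_epoch_.append(
                    _pearson_to(yc_c, yc_norm, dcw_cal) ** 2
                )
        if monitor and self.calibration_r2_per_epoch_:
            self.best_epoch_ = 1 + int(np.argmax(self.calibration_r2_per_epoch_))

        self.weights_ = {a: float(w[j]) for a, j in col.items()}
        self.r_sub_, self.r_inv_ = r_sub, r_inv
        c0, c1, _ = fit_regression(dcw_sub, y_sub)
        self.intercept_, self.slope_ = c0, c1
        self.coef_ = np.array([c1])
        self.n_attributes_ = len(active)
        return self

    def dcw(self, X) -> np.ndarray:
        """DCW value of each input molecule under the fitted weight table."""
        check_is_fitted(self, "weights_")
        smiles, _ = self._as_smiles_y(X)
        cw = self.correlation_weight_table()
        return np.array([compute_dcw(self._profile(s), cw) for s in smiles])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self.intercept_ + self.slope_ * self.dcw(X)

    def predict_with_unknown(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Predictions plus, per molecule, the number of attribute instances
        never seen in training (they contribute zero to DCW)."""
        check_is_fitted(self, "weights_")
        smiles, _ = self._as_smiles_y(X)
        cw = self.correlation_weight_table()
        preds, unknown = [], []
        for s in smiles:
            p = self._profile(s)
            preds.append(self.intercept_ + self.slope_ * compute_dcw(p, cw))
            unknown.append(
                sum(c for a, c in p.items() if a not in self.weights_)
            )
        return np.array(preds), np.array(unknown, dtype=int)


# -- functional wrappers ---------------------------------------------------


def monte_carlo_optimize(
    subtraining: CompoundSet,
    invtraining: CompoundSet,
    config: Mapping | None = None,
    **kwargs,
) -> DcwRegressor:
    """Train a :class:`DcwRegressor` on two compound sets.

    ``config``/keyword arguments are estimator parameters (``mode``,
    ``smiles_scheme``, ``ec_orders``, ``threshold``, ``n_epochs``, ``step``,
    ``d_weight``, ``random_state``...).
    """
    params = dict(config or {})
    params.update(kwargs)
    est = DcwRegressor(**params)
    return est.fit(subtraining, X_invisible=invtraining)


def predict(model: DcwRegressor, compound: Compound | str) -> tuple[float, int]:
    """Predicted endpoint of one compound and its unseen-attribute count."""
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    preds, unknown = model.predict_with_unknown([smiles])
    return float(preds[0]), int(unknown[0])
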