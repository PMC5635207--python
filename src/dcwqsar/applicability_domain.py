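"""Applicability domain and library screening.

A prediction is only trusted for molecules whose attributes are adequately
represented in both training sets.  The *statistical defect* of a molecule
sums, over its attribute instances, the disagreement between the
sub-training and invisible-training frequencies of that attribute:

    D = Σ |p_sub(A) − p_inv(A)| / (n_sub(A) + n_inv(A)),

where p are compound-frequency proportions and n compound counts.  An
attribute never seen in either training set makes the defect infinite.  A
molecule is an *outlier* when its defect exceeds ``multiplier`` × the mean
defect of the sub-training compounds (strictly; default multiplier 2).

Screening a library applies, in order: an element filter (only elements seen
in training are allowed), a SMILES-length cap, the outlier rule, and finally
prediction.  Each molecule receives exactly one status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .corpus import Compound, CompoundSet
from .dcw_engine import DcwRegressor, compute_dcw
from .smiles_attributes import TokenizeError, element_inventory, tokenize

__all__ = [
    "DomainReference",
    "ScreeningRecord",
    "build_domain_reference",
    "statistical_defect",
    "is_outlier",
    "screen_library",
    "screening_counts",
    "screening_report_csv",
]

STATUSES = ("predicted", "excluded_element", "excluded_length", "outlier", "error")


@dataclass
class DomainReference:
    """Training-set statistics the domain rules are evaluated against."""

    n_sub: dict[str, int]
    n_inv: dict[str, int]
    n_sub_total: int
    n_inv_total: int
    mean_defect: float
    allowed_elements: frozenset[str]
    max_smiles_length: int = 150
    multiplier: float = 2.0

    def p_sub(self, attr: str) -> float:
        return self.n_sub.get(attr, 0) / self.n_sub_total

    def p_inv(self, attr: str) -> float:
        return self.n_inv.get(attr, 0) / self.n_inv_total


@dataclass(frozen=True)
class ScreeningRecord:
    """Outcome for one screened molecule; prediction present iff predicted."""

    id: str
    smiles: str
    status: str
    predicted: float | None = None
    defect: float | None = None
    detail: str = ""


def statistical_defect(profile: Mapping[str, int], ref: DomainReference) -> float:
    """Statistical defect of an attribute profile; infinite when it contains
    an attribute unseen in both training sets."""
    d = 0.0
    for attr, count in profile.items():
        ns = ref.n_sub.get(attr, 0)
        ni = ref.n_inv.get(attr, 0)
        if ns + ni == 0:
            return math.inf
        d += count * abs(ref.p_sub(attr) - ref.p_inv(attr)) / (ns + ni)
    return d


def is_outlier(defect: float, ref: DomainReference) -> bool:
    """Strictly above ``multiplier × mean_defect``; the boundary is inside."""
    return defect > ref.multiplier * ref.mean_defect


def build_domain_reference(
    model: DcwRegressor,
    subtraining: CompoundSet,
    invtraining: CompoundSet,
    max_smiles_length: int = 150,
    multiplier: float = 2.0,
) -> DomainReference:
    """Domain reference of a trained model: per-attribute compound counts in
    both training sets, the sub-training mean defect, and the element
    alphabet seen in training."""
    if not len(subtraining) or not len(invtraining):
        raise ValueError("training sets must be non-empty")
    profiles_sub = [model._profile(c.smiles) for c in subtraining]
    profiles_inv = [model._profile(c.smiles) for c in invtraining]
    n_sub: dict[str, int] = {}
    for p in profiles_sub:
        for a in p:
            n_sub[a] = n_sub.get(a, 0) + 1
    n_inv: dict[str, int] = {}
    for p in profiles_inv:
        for a in p:
            n_inv[a] = n_inv.get(a, 0) + 1
    allowed: set[str] = set()
    for c in list(subtraining) + list(invtraining):
        allowed |= element_inventory(tokenize(c.smiles))
    ref = DomainReference(
        n_sub=n_sub,
        n_inv=n_inv,
        n_sub_total=len(subtraining),
        n_inv_total=len(invtraining),
        mean_defect=0.0,
        allowed_elements=frozenset(allowed),
        max_smiles_length=max_smiles_length,
        multiplier=multiplier,
    )
    defects = [statistical_defect(p, ref) for p in profiles_sub]
    ref.mean_defect = sum(defects) / len(defects)
    return ref


def screen_library(
    model: DcwRegressor,
    library: CompoundSet | Iterable[Compound],
    ref: DomainReference,
) -> list[ScreeningRecord]:
    """Screen a library, one record per molecule, never raising per-record.

    Status order: ``excluded_element`` (elements outside the training
    alphabet), ``excluded_length`` (SMILES longer than the cap),
    ``outlier`` (statistical defect above the cutoff), else ``predicted``.
    Unparseable SMILES yield an ``error`` record.
    """
    records: list[ScreeningRecord] = []
    for c in library:
        try:
            tokens = tokenize(c.smiles)
            elements = element_inventory(tokens)
        except TokenizeError as exc:
            records.append(
                ScreeningRecord(c.id, c.smiles, "error", detail=str(exc))
            )
            continue
        foreign = elements - ref.allowed_elements
        if foreign:
            records.append(
                ScreeningRecord(
                    c.id, c.smiles, "excluded_element",
                    detail=",".join(sorted(foreign)),
                )
            )
            continue
        if len(c.smiles) > ref.max_smiles_length:
            records.append(
                ScreeningRecord(
                    c.id, c.smiles, "excluded_length",
                    detail=f"{len(c.smiles)}>{ref.max_smiles_length}",
                )
            )
            continue
        try:
            profile = model._profile(c.smiles)
        except (TokenizeError, ValueError) as exc:
            records.append(ScreeningRecord(c.id, c.smiles, "error", detail=str(exc)))
            continue
        defect = statistical_defect(profile, ref)
        if is_outlier(defect, ref):
            records.append(ScreeningRecord(c.id, c.smiles, "outlier", defect=defect))
            continue
        pred = model.intercept_ + model.slope_ * compute_dcw(
            profile, model.correlation_weight_table()
        )
        records.append(
            ScreeningRecord(c.id, c.smiles, "predicted", predicted=pred, defect=defect)
        )
    return records


def screening_counts(records: Sequence[ScreeningRecord]) -> dict[str, int]:
    out = {s: 0 for s in STATUSES}
    for r in records:
        out[r.status] += 1
    return out


def screening_report_csv(records: Sequence[ScreeningRecord]) -> str:
    """Delimited screening report: id, smiles, status, predicted, defect."""
    lines = ["id,smiles,status,predicted_pIC50,defect"]
    for r in records:
        pred = f"{r.predicted:.4f}" if r.predicted is not None else ""
        defect = "" if r.defect is None else ("inf" if math.isinf(r.defect) else f"{r.defect:.6g}")
        lines.append(f"{r.id},{r.smiles},{r.status},{pred},{defect}")
    return "\n".join(lines) + "\n"
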