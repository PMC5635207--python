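"""Human-readable model files.

A trained model is stored as a single structured text document: flat
``key: value`` sections for the configuration and regression coefficients,
tab-separated sections for the weight table, blocked set, attribute
frequencies, and (when attached) the applicability-domain reference.
Floats are written with ``repr`` so that a written model reads back
bit-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .applicability_domain import DomainReference
from .dcw_engine import DcwRegressor

__all__ = ["save_model", "load_model"]

_MAGIC = "# dcwqsar model file v1"


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, (tuple, list)):
        return ",".join(_fmt(x) for x in v)
    return str(v)


def save_model(
    est: DcwRegressor,
    path,
    domain: DomainReference | None = None,
    metadata: Mapping[str, str] | None = None,
) -> None:
    """Write a fitted estimator (and optional domain reference) to ``path``."""
    lines = [_MAGIC, "[config]"]
    for key, val in sorted(est.get_params().items()):
        lines.append(f"{key}: {_fmt(val)}")
    lines += [
        "[regression]",
        f"intercept: {est.intercept_!r}",
        f"slope: {est.slope_!r}",
        f"r_sub: {est.r_sub_!r}",
        f"r_inv: {est.r_inv_!r}",
        f"n_attributes: {est.n_attributes_}",
    ]
    if metadata:
        lines.append("[metadata]")
        for key, val in metadata.items():
            lines.append(f"{key}: {val}")
    lines.append("[weights]")
    for attr in sorted(est.weights_):
        lines.append(f"{attr}\t{est.weights_[attr]!r}")
    lines.append("[blocked]")
    for attr in sorted(est.blocked_):
        lines.append(attr)
    lines.append("[frequencies]")
    for attr in sorted(est.frequencies_):
        lines.append(f"{attr}\t{est.frequencies_[attr]}")
    if domain is not None:
        lines += [
            "[domain]",
            f"n_sub_total: {domain.n_sub_total}",
            f"n_inv_total: {domain.n_inv_total}",
            f"mean_defect: {domain.mean_defect!r}",
            f"max_smiles_length: {domain.max_smiles_length}",
            f"multiplier: {domain.multiplier!r}",
            f"allowed_elements: {','.join(sorted(domain.allowed_elements))}",
            "[domain_counts]",
        ]
        for attr in sorted(set(domain.n_sub) | set(domain.n_inv)):
            lines.append(
                f"{attr}\t{domain.n_sub.get(attr, 0)}\t{domain.n_inv.get(attr, 0)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_config_value(key: str, raw: str):
    if key in ("smiles_scheme",):
        return tuple(raw.split(",")) if raw else ()
    if key in ("ec_orders",):
        return tuple(int(x) for x in raw.split(",")) if raw else ()
    if key == "init_range":
        lo, hi = raw.split(",")
        return (float(lo), float(hi))
    if key == "accept_equal":
        return raw == "True"
    if key in ("threshold", "n_epochs"):
        return int(raw)
    if key == "random_state":
        return None if raw == "None" else int(raw)
    if key in ("step", "d_weight"):
        return float(raw)
    return raw


def load_model(path) -> tuple[DcwRegressor, DomainReference | None, dict]:
    """Read a model file back into a fitted estimator.

    Returns ``(estimator, domain_reference_or_None, metadata)``.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a dcwqsar model file")
    section = None
    config: dict = {}
    regression: dict = {}
    metadata: dict = {}
    weights: dict[str, float] = {}
    blocked: set[str] = set()
    freqs: dict[str, int] = {}
    dom: dict = {}
    dom_counts: dict[str, tuple[int, int]] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        if ln.startswith("[") and ln.endswith("]"):
            section = ln[1:-1]
            continue
        if section == "config":
            key, raw = ln.split(": ", 1)
            config[key] = _parse_config_value(key, raw)
        elif section == "regression":
            key, raw = ln.split(": ", 1)
            regression[key] = int(raw) if key == "n_attributes" else float(raw)
        elif section == "metadata":
            key, raw = ln.split(": ", 1)
            metadata[key] = raw
        elif section == "weights":
            attr, raw = ln.rsplit("\t", 1)
            weights[attr] = float(raw)
        elif section == "blocked":
            blocked.add(ln)
        elif section == "frequencies":
            attr, raw = ln.rsplit("\t", 1)
            freqs[attr] = int(raw)
        elif section == "domain":
            key, raw = ln.split(": ", 1)
            dom[key] = raw
        elif section == "domain_counts":
            attr, ns, ni = ln.rsplit("\t", 2)
            dom_counts[attr] = (int(ns), int(ni))
        else:
            raise ValueError(f"{path}: line outside any known section: {ln!r}")

    est = DcwRegressor(**config)
    est.weights_ = weights
    est.blocked_ = frozenset(blocked)
    est.frequencies_ = freqs
    est.intercept_ = regression["intercept"]
    est.slope_ = regression["slope"]
    est.coef_ = np.array([est.slope_])
    est.r_sub_ = regression.get("r_sub", float("nan"))
    est.r_inv_ = regression.get("r_inv", float("nan"))
    est.n_attributes_ = int(regression.get("n_attributes", len(weights)))
    est.tf_trajectory_ = []

    domain = None
    if dom:
        domain = DomainReference(
            n_sub={a: c[0] for a, c in dom_counts.items() if c[0]},
            n_inv={a: c[1] for a, c in dom_counts.items() if c[1]},
            n_sub_total=int(dom["n_sub_total"]),
            n_inv_total=int(dom["n_inv_total"]),
            mean_defect=float(dom["mean_defect"]),
            allowed_elements=frozenset(
                dom["allowed_elements"].split(",") if dom["allowed_elements"] else []
            ),
            max_smiles_length=int(dom["max_smiles_length"]),
            multiplier=float(dom["multiplier"]),
        )
    return est, domain, metadata
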