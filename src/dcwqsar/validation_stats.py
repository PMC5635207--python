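"""Four-set statistical quality of a trained model.

For each of the four sets the report carries n, r² (squared Pearson
correlation between prediction and observation), q² (leave-one-out
cross-validated coefficient of the final one-variable regression; not
reported for the validation set), s (root-mean-square error), the Fisher
ratio F = r²(n−2)/(1−r²), and the 5% critical value of F(1, n−2).

The tail probability of the observed F is reported as ``p_tail``.  With the
F ratios these models reach, ``p_tail`` is far below any conventional
significance level; it is a genuine tail probability, computed from the F
distribution, and not comparable to loosely defined "p-value" columns seen
in some published quality tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus import REPORT_VOCABULARY, SET_LABELS, CompoundSet, SplitScheme

__all__ = [
    "SetStats",
    "StatReport",
    "r_squared",
    "q2_loo",
    "rmse",
    "fisher_f",
    "f_critical",
    "four_set_report",
]


def r_squared(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Squared Pearson correlation."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def q2_loo(dcw_values: Sequence[float], obs: Sequence[float]) -> float:
    """Leave-one-out cross-validated q² of the one-variable OLS.

    q² = 1 − PRESS/SS_tot with PRESS the sum of squared leave-one-out
    residuals; computed with the closed-form hat-matrix shortcut
    e_(i) = e_i / (1 − h_ii), h_ii = 1/n + (x_i − x̄)²/S_xx, which equals
    explicit per-point refitting exactly.
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate descriptor: DCW has zero variance")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    h = 1.0 / x.size + xc**2 / sxx
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root-mean-square error."""
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def fisher_f(r2: float, n: int) -> float:
    """Fisher ratio of a one-variable regression: F = r²(n−2)/(1−r²)."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1); F is infinite at r2 = 1")
    if n < 3:
        raise ValueError("need n >= 3")
    return r2 * (n - 2) / (1.0 - r2)


def f_critical(n: int, alpha: float = 0.05) -> float:
    """Upper ``alpha`` critical value of the F(1, n−2) distribution."""
    if n < 3:
        raise ValueError("need n >= 3")
    return float(stats.f.ppf(1.0 - alpha, 1, n - 2))


@dataclass(frozen=True)
class SetStats:
    """One row of the quality table."""

    label: str
    n: int
    r2: float
    q2: float | None
    s: float
    f: float
    f_crit: float
    p_tail: float

    @property
    def f_int(self) -> int:
        """F rounded to integer, the display convention of the quality table."""
        return int(round(self.f))


@dataclass
class StatReport:
    """Quality rows for the four sets, in protocol order."""

    rows: dict[str, SetStats] = field(default_factory=dict)
    threshold: int | None = None
    n_epochs: int | None = None

    def __getitem__(self, label: str) -> SetStats:
        return self.rows[label]

    def to_text(self, vocabulary: Mapping[str, str] = REPORT_VOCABULARY) -> str:
        out = io.StringIO()
        head = ["Set", "n", "r2", "q2", "s", "F", "F(0.05,1,n-2)", "p_tail"]
        out.write("{:<14}{:>5}{:>9}{:>9}{:>8}{:>7}{:>15}{:>11}\n".format(*head))
        for label in SET_LABELS:
            if label not in self.rows:
                continue
            r = self.rows[label]
            q2 = f"{r.q2:.4f}" if r.q2 is not None else "-"
            out.write(
                f"{vocabulary.get(label, label):<14}{r.n:>5}{r.r2:>9.4f}{q2:>9}"
                f"{r.s:>8.3f}{r.f_int:>7}{r.f_crit:>15.2f}{r.p_tail:>11.2e}\n"
            )
        return out.getvalue()

    def to_csv(self, vocabulary: Mapping[str, str] = REPORT_VOCABULARY) -> str:
        lines = ["set,n,r2,q2,s,F,F_crit,p_tail"]
        for label in SET_LABELS:
            if label not in self.rows:
                continue
            r = self.rows[label]
            q2 = repr(r.q2) if r.q2 is not None else ""
            lines.append(
                f"{vocabulary.get(label, label)},{r.n},{r.r2!r},{q2},"
                f"{r.s!r},{r.f!r},{r.f_crit!r},{r.p_tail!r}"
            )
        return "\n".join(lines) + "\n"


def four_set_report(
    model,
    split: SplitScheme | None,
    cs: CompoundSet,
) -> StatReport:
    """Quality rows of ``model`` on the four sets of ``cs``.

    ``split`` may be None when ``cs`` already carries set labels.  q² is
    computed on the final one-variable regression with the weight table
    frozen, and is omitted for the validation set.  A set with r² = 1
    (perfect fit) is flagged by ``f = inf`` rather than rejected.
    """
    labeled = cs if split is None else cs.with_split(split)
    report = StatReport(threshold=model.threshold, n_epochs=model.n_epochs)
    for label in SET_LABELS:
        subset = labeled.subset(label)
        if not len(subset):
            raise ValueError(f"set {label!r} is empty")
        obs = np.asarray(subset.endpoints())
        dcw = model.dcw(subset)
        pred = model.intercept_ + model.slope_ * dcw
        r2 = r_squared(pred, obs)
        f = fisher_f(r2, len(subset)) if r2 < 1 else float("inf")
        report.rows[label] = SetStats(
            label=label,
            n=len(subset),
            r2=r2,
            q2=None if label == "validation" else q2_loo(dcw, obs),
            s=rmse(pred, obs),
            f=f,
            f_crit=f_critical(len(subset)),
            p_tail=float(stats.f.sf(f, 1, len(subset) - 2)),
        )
    return report
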