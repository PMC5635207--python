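"""Compound datasets: loading, splitting, and endpoint summaries.

A compound carries an identifier, a SMILES string used verbatim (no
standardisation), a pIC50 endpoint (−log10 of the IC50 in molar), and an
optional set label assigning it to one of the four roles of the modelling
protocol: *subtraining* (fits the correlation weights), *invtraining*
("invisible" training, steers the optimisation objective), *calibration*
(overfitting guard), and *validation* (untouched final check).

The 382-inhibitor HO-1 reference dataset ships with the package as a CSV
fixture (:data:`FIXTURE_NAME`) with its split-1 set markers; see
:func:`load_fixture`.
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field, replace
from decimal import ROUND_DOWN, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = [
    "SET_LABELS",
    "MARKER_TO_LABEL",
    "LABEL_TO_MARKER",
    "REPORT_VOCABULARY",
    "FIXTURE_NAME",
    "Compound",
    "CompoundSet",
    "SplitScheme",
    "EndpointSummary",
    "read_compound_table",
    "write_compound_table",
    "load_fixture",
    "set_counts",
    "summarize_endpoints",
    "random_split",
]

#: Canonical set labels, in protocol order.
SET_LABELS = ("subtraining", "invtraining", "calibration", "validation")

#: Set markers as printed in the reference dataset.  The en dash variant of
#: the minus marker is accepted on input and normalised to ASCII '-'.
MARKER_TO_LABEL = {
    "+": "subtraining",
    "-": "invtraining",
    "–": "invtraining",
    "#": "calibration",
    "*": "validation",
}
LABEL_TO_MARKER = {
    "subtraining": "+",
    "invtraining": "-",
    "calibration": "#",
    "validation": "*",
}

#: Alternative (report) vocabulary for the four sets, as used in the printed
#: summary tables.
REPORT_VOCABULARY = {
    "subtraining": "Sub-training",
    "invtraining": "Calibration",
    "calibration": "Test",
    "validation": "Validation",
}

FIXTURE_NAME = "hemeoxdb_split1.csv"


class CorpusError(ValueError):
    """Raised on malformed compound tables."""


@dataclass(frozen=True)
class Compound:
    """One molecule with its endpoint and optional set assignment."""

    id: str
    smiles: str
    endpoint: float
    set_label: str | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise CorpusError(f"compound {self.id!r}: empty SMILES")
        if self.endpoint != self.endpoint or self.endpoint in (float("inf"), float("-inf")):
            raise CorpusError(f"compound {self.id!r}: non-finite endpoint")
        if self.set_label is not None and self.set_label not in SET_LABELS:
            raise CorpusError(
                f"compound {self.id!r}: unknown set label {self.set_label!r}"
            )


@dataclass
class CompoundSet:
    """Ordered collection of compounds with unique identifiers."""

    compounds: list[Compound] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.compounds:
            if c.id in seen:
                raise CorpusError(f"duplicate compound id {c.id!r}")
            seen.add(c.id)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __getitem__(self, i):
        return self.compounds[i]

    def subset(self, label: str, name: str | None = None) -> "CompoundSet":
        """Compounds carrying ``label``."""
        return CompoundSet(
            [c for c in self.compounds if c.set_label == label],
            name=name if name is not None else label,
        )

    def smiles(self) -> list[str]:
        return [c.smiles for c in self.compounds]

    def endpoints(self) -> list[float]:
        return [c.endpoint for c in self.compounds]

    def with_split(self, split: "SplitScheme", name: str | None = None) -> "CompoundSet":
        """Copy of this set relabelled according to ``split``."""
        return CompoundSet(
            [replace(c, set_label=split.assignment[c.id]) for c in self.compounds],
            name=name if name is not None else self.name,
        )


@dataclass(frozen=True)
class SplitScheme:
    """Disjoint, exhaustive assignment of compound ids to the four sets."""

    assignment: Mapping[str, str]

    @property
    def sizes(self) -> dict[str, int]:
        out = {label: 0 for label in SET_LABELS}
        for label in self.assignment.values():
            out[label] += 1
        return out


@dataclass(frozen=True)
class EndpointSummary:
    """Endpoint range of one set: min, max, and mid-range.

    All three values are truncated (not rounded) to two decimals; the
    mid-range is the truncated mean of the already-truncated extremes.  This
    is the convention of the printed reference summaries (3.699 → 3.69;
    (3.41 + 7.22)/2 = 5.315 → 5.31).
    """

    min2: float
    max2: float
    middle2: float

    def __post_init__(self) -> None:
        if not self.min2 <= self.middle2 <= self.max2:
            raise CorpusError("endpoint summary is not ordered")


def _truncate2(x: Decimal) -> Decimal:
    return x.quantize(Decimal("0.01"), rounding=ROUND_DOWN)


def read_compound_table(
    source,
    *,
    delimiter: str | None = None,
    require_endpoint: bool = True,
    name: str = "",
) -> CompoundSet:
    """Read a compound table from a file path, stream, or string.

    Two dialects are accepted:

    * delimited text (comma or tab, auto-detected from the header) with a
      header naming at least ``id`` and ``smiles``, optionally ``pIC50`` and
      a ``*marker``/``*label``/``set`` column carrying either the four
      markers ``+ - # *`` or the canonical label names;
    * two-column SMI (``smiles[ whitespace id]`` per line, no header), in
      which case ``require_endpoint`` must be False.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return CompoundSet([], name=name)

    header = lines[0]
    if delimiter is None:
        if "\t" in header:
            delimiter = "\t"
        elif "," in header:
            delimiter = ","
        else:
            delimiter = None  # SMI dialect

    if delimiter is None:
        if require_endpoint:
            raise CorpusError("SMI input carries no endpoint column")
        compounds = []
        for i, ln in enumerate(lines):
            parts = ln.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            compounds.append(Compound(cid, smiles, 0.0, None))
        return CompoundSet(compounds, name=name)

    cols = [c.strip() for c in header.split(delimiter)]
    low = [c.lower() for c in cols]

    def find(*names: str, contains: str | None = None) -> int | None:
        for j, c in enumerate(low):
            if c in names or (contains is not None and contains in c):
                return j
        return None

    i_id = find("id", "name")
    i_smi = find("smiles")
    i_end = find("pic50", "endpoint", "y")
    i_lab = find("set", "label", contains="marker")
    if i_id is None or i_smi is None:
        raise CorpusError(f"header must name 'id' and 'smiles' columns, got {cols}")
    if require_endpoint and i_end is None:
        raise CorpusError("endpoint column (pIC50) required but absent")

    compounds = []
    for row_no, ln in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in ln.split(delimiter)]
        cid = parts[i_id]
        smiles = parts[i_smi]
        endpoint = 0.0
        if i_end is not None:
            raw = parts[i_end] if i_end < len(parts) else ""
            if not raw:
                if require_endpoint:
                    raise CorpusError(f"row {row_no} ({cid!r}): missing endpoint")
            else:
                try:
                    endpoint = float(raw)
                except ValueError:
                    raise CorpusError(
                        f"row {row_no} ({cid!r}): unparseable endpoint {raw!r}"
                    ) from None
        label = None
        if i_lab is not None and i_lab < len(parts) and parts[i_lab]:
            raw = parts[i_lab]
            if raw in MARKER_TO_LABEL:
                label = MARKER_TO_LABEL[raw]
            elif raw in SET_LABELS:
                label = raw
            else:
                raise CorpusError(f"row {row_no} ({cid!r}): unknown set marker {raw!r}")
        compounds.append(Compound(cid, smiles, endpoint, label))
    return CompoundSet(compounds, name=name)


def write_compound_table(cs: CompoundSet, dest, *, delimiter: str = ",") -> None:
    """Write ``cs`` in the delimited dialect read by :func:`read_compound_table`."""

    def emit(fh) -> None:
        fh.write(delimiter.join(["id", "smiles", "pIC50", "set_marker"]) + "\n")
        for c in cs:
            marker = LABEL_TO_MARKER[c.set_label] if c.set_label else ""
            fh.write(delimiter.join([c.id, c.smiles, repr(c.endpoint), marker]) + "\n")

    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            emit(fh)
    else:
        emit(dest)


def load_fixture() -> CompoundSet:
    """The packaged 382-compound HO-1 inhibitor dataset with split-1 markers."""
    text = resources.files("dcwqsar.data").joinpath(FIXTURE_NAME).read_text()
    return read_compound_table(io.StringIO(text), name="hemeoxdb")


def set_counts(cs: CompoundSet) -> dict[str, int]:
    """Compound counts per set label; unlabeled compounds under ``None``."""
    out: dict[str, int] = {label: 0 for label in SET_LABELS}
    unlabeled = 0
    for c in cs:
        if c.set_label is None:
            unlabeled += 1
        else:
            out[c.set_label] += 1
    if unlabeled:
        out[None] = unlabeled  # type: ignore[index]
    return out


def summarize_endpoints(cs: CompoundSet, label: str) -> EndpointSummary:
    """Min/max/mid-range of the endpoints in one set, truncated to 2 decimals."""
    values = [c.endpoint for c in cs if c.set_label == label]
    if not values:
        raise CorpusError(f"no compounds labeled {label!r}")
    mn = _truncate2(Decimal(repr(min(values))))
    mx = _truncate2(Decimal(repr(max(values))))
    mid = _truncate2((mn + mx) / 2)
    return EndpointSummary(float(mn), float(mx), float(mid))


def random_split(
    cs: CompoundSet,
    sizes: Sequence[int] | Mapping[str, int],
    seed: int,
) -> SplitScheme:
    """Uniformly random disjoint partition of ``cs`` into the four sets.

    ``sizes`` is given in :data:`SET_LABELS` order (or as a mapping) and must
    sum to ``len(cs)``.  Reproducible for a fixed ``seed``.
    """
    if isinstance(sizes, Mapping):
        counts = [int(sizes.get(label, 0)) for label in SET_LABELS]
    else:
        counts = [int(s) for s in sizes]
    if len(counts) != 4:
        raise CorpusError("sizes must give four counts")
    if sum(counts) != len(cs):
        raise CorpusError(
            f"sizes sum to {sum(counts)} but the set holds {len(cs)} compounds"
        )
    ids = [c.id for c in cs]
    rng = random.Random(seed)
    rng.shuffle(ids)
    assignment: dict[str, str] = {}
    start = 0
    for label, k in zip(SET_LABELS, counts):
        for cid in ids[start : start + k]:
            assignment[cid] = label
        start += k
    return SplitScheme(assignment)
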