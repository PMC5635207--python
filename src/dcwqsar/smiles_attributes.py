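"""SMILES tokenisation and string-based descriptor attributes.

For the optimal-descriptor method a SMILES string is treated as a symbol
sequence, not (primarily) as chemistry: it is cut into atomic units
("tokens") and local and global *attributes* are read off the token
sequence.  Each attribute later receives an optimisable correlation weight.

Local attribute kinds
    ``S1``  single tokens; ``S2`` adjacent token pairs, direction-canonical;
    ``S3``  adjacent token triples, canonical under reversal.

Global attribute kinds (one attribute per molecule each)
    ``NOSP``  presence pattern of nitrogen, oxygen, sulfur, phosphorus;
    ``BOND``  presence of double/triple bonds and stereo bond markers;
    ``HALO``  presence pattern of the halogens F, Cl, Br, I.

Attribute keys are plain strings ``"<kind>:<code>"`` so they can appear
verbatim in serialized model files.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable, Sequence

__all__ = [
    "SMILES_SCHEMES",
    "SEPARATOR",
    "TokenizeError",
    "tokenize",
    "extract_smiles_attributes",
    "element_inventory",
]

#: Attribute kinds understood by :func:`extract_smiles_attributes`.
SMILES_SCHEMES = ("S1", "S2", "S3", "NOSP", "BOND", "HALO")

#: Reserved separator joining tokens inside S2/S3 codes; forbidden in tokens.
SEPARATOR = "|"

_TWO_CHAR = ("Cl", "Br", "@@")
_BOND_CHARS = set("=#/\\-.")


class TokenizeError(ValueError):
    """Malformed SMILES; the message carries the offending position."""


def tokenize(smiles: str) -> list[str]:
    """Cut a SMILES string into tokens, left to right.

    One token is: a bracket atom ``[...]`` verbatim; a two-character organic
    element (``Cl``, ``Br``); ``@@``; a ``%nn`` ring closure; otherwise a
    single character (atom letter, ring digit, parenthesis, or bond symbol).
    Concatenating the tokens restores the input exactly.
    """
    if not smiles:
        raise TokenizeError("empty SMILES")
    tokens: list[str] = []
    depth = 0
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise TokenizeError(f"unclosed '[' at position {i}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if ch == "]":
            raise TokenizeError(f"unmatched ']' at position {i}")
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TokenizeError(f"unmatched ')' at position {i}")
        if ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizeError(f"'%' not followed by two digits at position {i}")
            tokens.append(smiles[i : i + 3])
            i += 3
            continue
        two = smiles[i : i + 2]
        if two in _TWO_CHAR:
            tokens.append(two)
            i += 2
            continue
        if ch == SEPARATOR:
            raise TokenizeError(f"reserved character {SEPARATOR!r} at position {i}")
        tokens.append(ch)
        i += 1
    if depth != 0:
        raise TokenizeError("unbalanced parentheses")
    return tokens


def _pair_code(a: str, b: str) -> str:
    return f"{a}{SEPARATOR}{b}" if a <= b else f"{b}{SEPARATOR}{a}"


def _triple_code(a: str, b: str, c: str) -> str:
    fwd = SEPARATOR.join((a, b, c))
    rev = SEPARATOR.join((c, b, a))
    return fwd if fwd <= rev else rev


def _presence_code(pairs: Iterable[tuple[str, bool]]) -> str:
    return "".join(f"{name}{int(flag)}" for name, flag in pairs)


def extract_smiles_attributes(
    tokens: Sequence[str],
    scheme: Iterable[str] = ("S1", "S2"),
) -> Counter:
    """Attribute profile (multiset of attribute keys) of a token sequence."""
    scheme = tuple(scheme)
    for s in scheme:
        if s not in SMILES_SCHEMES:
            raise ValueError(f"unknown attribute scheme element {s!r}")
    profile: Counter = Counter()
    if "S1" in scheme:
        for t in tokens:
            profile[f"S1:{t}"] += 1
    if "S2" in scheme:
        for a, b in zip(tokens, tokens[1:]):
            profile[f"S2:{_pair_code(a, b)}"] += 1
    if "S3" in scheme:
        for a, b, c in zip(tokens, tokens[1:], tokens[2:]):
            profile[f"S3:{_triple_code(a, b, c)}"] += 1
    if scheme and not tokens:
        return profile
    elements = element_inventory(tokens) if {"NOSP", "HALO"} & set(scheme) else set()
    if "NOSP" in scheme:
        code = _presence_code((e, e in elements) for e in ("N", "O", "S", "P"))
        profile[f"NOSP:{code}"] += 1
    if "BOND" in scheme:
        text = "".join(tokens)
        code = _presence_code(
            [
                ("d", "=" in text),
                ("t", "#" in text),
                ("s", any(c in text for c in "/\\@")),
            ]
        )
        profile[f"BOND:{code}"] += 1
    if "HALO" in scheme:
        code = _presence_code((e, e in elements) for e in ("F", "Cl", "Br", "I"))
        profile[f"HALO:{code}"] += 1
    return profile


_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?|[a-z])(?P<rest>[^\]]*)\]"
)
_PLAIN_ATOMS = {"B", "C", "N", "O", "S", "P", "F", "I", "Cl", "Br"}
_AROMATIC = {"b", "c", "n", "o", "s", "p"}


def element_inventory(tokens: Sequence[str]) -> set[str]:
    """Chemical element symbols appearing in a token sequence.

    Aromatic lowercase atoms are case-normalised; bracket atoms contribute
    their element symbol and, when an explicit hydrogen count is written,
    ``H``.
    """
    out: set[str] = set()
    for t in tokens:
        if t.startswith("["):
            m = _BRACKET_RE.match(t)
            if m is None:
                raise TokenizeError(f"unparseable bracket atom {t!r}")
            el = m.group("element")
            out.add(el.capitalize() if el.islower() else el)
            if "H" in m.group("rest") or el == "H":
                out.add("H")
        elif t in _PLAIN_ATOMS:
            out.add(t)
        elif t in _AROMATIC:
            out.add(t.upper())
    return out
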