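"""Position-dependent reduced residue alphabets and fragment pattern keys.

A reduced alphabet partitions the amino-acid letters into equivalence groups,
possibly differently at each position of a fixed-length fragment (central
residues usually matter more for local structure, so tail positions are often
coarser). A fragment then maps to a *pattern key*: the concatenation of its
per-position group identifiers. Two fragments share a key exactly when they
are equivalent under the alphabet, which is the pooling unit over which
sparse RMSD statistics become usable (20^5 = 3.2e6 raw pentapeptides).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD_CLASS = "*"


@dataclass(frozen=True)
class ReducedAlphabet:
    """Compiled alphabet: per-position letter -> group-id lookup tables."""

    name: str
    fragment_length: int
    lookup: tuple  # tuple (one per position) of dict letter -> group id
    wildcard: bool = False
    unverified: bool = False

    def group_of(self, letter: str, position: int) -> str:
        table = self.lookup[position]
        if letter in table:
            return table[letter]
        if self.wildcard:
            return WILDCARD_CLASS
        raise ValueError(
            f"letter {letter!r} not covered at position {position} of alphabet {self.name}"
        )


def _compile_position(groups: Sequence[str], name: str, pos: int) -> dict:
    """Turn a list of letter-group strings into a letter -> id dict."""
    table: dict[str, str] = {}
    for gi, group in enumerate(groups):
        gid = f"g{gi}"
        for letter in group:
            if letter in table:
                raise ValueError(
                    f"alphabet {name}: letter {letter!r} appears in two groups "
                    f"at position {pos}"
                )
            table[letter] = gid
    missing = set(CANONICAL) - set(table)
    if missing:
        raise ValueError(
            f"alphabet {name}: position {pos} does not cover letters {sorted(missing)}"
        )
    return table


_FULL_GROUPS = [letter for letter in CANONICAL]


def compile_alphabet(spec: dict) -> ReducedAlphabet:
    """Compile an alphabet definition (parsed YAML mapping) and validate it.

    Recognised keys: ``name``, ``fragment_length``, ``wildcard``,
    ``unverified``, and exactly one of ``full: true`` (every letter its own
    group at every position), ``all_positions: [groups]`` (same partition
    everywhere), or ``positions: [...]`` (one entry per position; the string
    ``full`` is shorthand for the identity partition at that position).
    """
    name = spec["name"]
    L = int(spec["fragment_length"])
    if L % 2 != 1 or L < 1:
        raise ValueError(f"alphabet {name}: fragment_length must be a positive odd integer")
    if spec.get("full"):
        per_pos = [_FULL_GROUPS] * L
    elif "all_positions" in spec:
        per_pos = [spec["all_positions"]] * L
    elif "positions" in spec:
        per_pos = [
            _FULL_GROUPS if entry == "full" else entry for entry in spec["positions"]
        ]
        if len(per_pos) != L:
            raise ValueError(
                f"alphabet {name}: got {len(per_pos)} position entries for length {L}"
            )
    else:
        raise ValueError(f"alphabet {name}: no group definition")
    lookup = tuple(_compile_position(groups, name, i) for i, groups in enumerate(per_pos))
    return ReducedAlphabet(
        name=name,
        fragment_length=L,
        lookup=lookup,
        wildcard=bool(spec.get("wildcard", False)),
        unverified=bool(spec.get("unverified", False)),
    )


def full_alphabet(fragment_length: int, name: Optional[str] = None) -> ReducedAlphabet:
    """The identity alphabet: every canonical letter its own class."""
    return compile_alphabet({
        "name": name or f"Full{fragment_length}",
        "fragment_length": fragment_length,
        "full": True,
        "wildcard": True,
    })


def load_alphabets(path: Optional[str | Path] = None) -> dict[str, ReducedAlphabet]:
    """Load and compile all alphabets from a YAML catalog (default: packaged)."""
    if path is None:
        text = resources.files("featureforge.data").joinpath("alphabets.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    out = {}
    for spec in doc["alphabets"]:
        alpha = compile_alphabet(spec)
        out[alpha.name] = alpha
    return out


def pattern_key(fragment: str, alphabet: ReducedAlphabet) -> str:
    """Map a one-letter fragment to its pattern key under ``alphabet``.

    The key is the '.'-joined sequence of per-position group identifiers, so
    key equality holds exactly for fragments equivalent under the alphabet.
    """
    if len(fragment) != alphabet.fragment_length:
        raise ValueError(
            f"fragment length {len(fragment)} != alphabet length {alphabet.fragment_length}"
        )
    return ".".join(
        alphabet.group_of(letter, i) for i, letter in enumerate(fragment)
    )
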