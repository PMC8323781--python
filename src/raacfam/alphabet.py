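"""Reduced amino-acid alphabets (RAAC schemes).

A reduction scheme partitions the 20 canonical amino acids into ``s`` ordered
groups sharing physicochemical character (polarity, hydrophobicity,
aromaticity...).  Rewriting a protein over the reduced alphabet shrinks the
k-mer feature space from ``20**k`` to ``s**k`` and suppresses substitution
noise between residues of like character, which is the core idea behind
RAAC-based family classifiers.

The module ships the type-33 scheme family (sizes 2-19), a nested hierarchy
derived from structure-alignment substitution scores whose first split
separates polar from hydrophobic residues.  Arbitrary RAACBook-style
catalogs can be loaded from a plain-text scheme file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import SchemeError, SchemeFileError, SequenceError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, alphabetical.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL)

#: Letters that may appear in real sequences but are not canonical residues.
NONSTANDARD = frozenset("BJOUXZ*")

# Type-33 reduction hierarchy, sizes 2-19.  Each entry is the dash-delimited
# group string; groups are ordered and nested across sizes (every group at
# size s+1 refines a group at size s).
_TYPE33_SPECS: dict[int, str] = {
    2: "STANDGRQEKHPIVLMWYF-C",
    3: "STANDGRQEKHP-IVLMWYF-C",
    4: "STANDG-RQEKHP-IVLMWYF-C",
    5: "STAND-G-RQEKHP-IVLMWYF-C",
    6: "STAND-G-RQEK-HP-IVLMWYF-C",
    7: "STA-ND-G-RQEK-HP-IVLMWYF-C",
    8: "STA-ND-G-RQ-EK-HP-IVLMWYF-C",
    9: "STA-ND-G-RQ-EK-HP-IVLM-WYF-C",
    10: "ST-A-ND-G-RQ-EK-HP-IVLM-WYF-C",
    11: "ST-A-ND-G-RQ-EK-H-P-IVLM-WYF-C",
    12: "ST-A-N-D-G-RQ-EK-H-P-IVLM-WYF-C",
    13: "ST-A-N-D-G-RQ-EK-H-P-IV-LM-WYF-C",
    14: "S-T-A-N-D-G-RQ-EK-H-P-IV-LM-WYF-C",
    15: "S-T-A-N-D-G-RQ-EK-H-P-IV-L-M-WYF-C",
    16: "S-T-A-N-D-G-RQ-E-K-H-P-IV-L-M-WYF-C",
    17: "S-T-A-N-D-G-RQ-E-K-H-P-IV-L-M-WY-F-C",
    18: "S-T-A-N-D-G-R-Q-E-K-H-P-IV-L-M-WY-F-C",
    19: "S-T-A-N-D-G-R-Q-E-K-H-P-I-V-L-M-WY-F-C",
}

TYPE33 = 33


@dataclass(frozen=True)
class ReductionScheme:
    """A validated partition of the canonical amino acids into ordered groups.

    Parameters
    ----------
    type_id : int
        Catalog index of the reduction method (``t``, 1-74).
    groups : tuple of str
        Ordered, disjoint, non-empty groups; their union is the 20 canonical
        residues.  The representative of each group is its first letter.
    """

    type_id: int
    groups: tuple[str, ...]
    _table: Mapping[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not 1 <= self.type_id <= 74:
            raise SchemeError(
                f"type_id must be in 1..74 (got {self.type_id})"
            )
        seen: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            if not group:
                raise SchemeError(f"group {gi} is empty")
            for letter in group:
                if letter not in CANONICAL_SET:
                    raise SchemeError(
                        f"letter {letter!r} in group {gi} is not a canonical amino acid"
                    )
                if letter in seen:
                    raise SchemeError(
                        f"letter {letter!r} appears in groups {seen[letter]} and {gi}"
                    )
                seen[letter] = gi
        missing = CANONICAL_SET - seen.keys()
        if missing:
            raise SchemeError(
                "scheme is not a complete partition; missing letter(s) "
                + ",".join(sorted(missing))
            )
        reps = [g[0] for g in self.groups]
        if len(set(reps)) != len(reps):
            raise SchemeError("group representatives are not pairwise distinct")
        table = {letter: self.groups[gi][0] for letter, gi in seen.items()}
        object.__setattr__(self, "_table", table)

    @property
    def size(self) -> int:
        """Number of groups ``s``."""
        return len(self.groups)

    @property
    def representatives(self) -> tuple[str, ...]:
        """One letter per group (the first listed), used as the reduced symbol."""
        return tuple(g[0] for g in self.groups)

    @property
    def spec_string(self) -> str:
        """Dash-delimited group notation, round-trippable via parse."""
        return "-".join(self.groups)

    def group_of(self, letter: str) -> str:
        """Representative letter for a canonical residue."""
        try:
            return self._table[letter]
        except KeyError:
            raise SequenceError(
                f"letter {letter!r} is not a canonical amino acid"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"ReductionScheme(t={self.type_id}, s={self.size}, {self.spec_string})"


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence rewritten over a scheme's representative letters."""

    symbols: str
    source_id: str
    scheme: ReductionScheme
    dropped: int = 0  # non-canonical residues removed under the `drop` policy

    def __len__(self) -> int:
        return len(self.symbols)


def parse_scheme_string(
    spec: str, type_id: int, size_hint: int | None = None
) -> ReductionScheme:
    """Parse a dash-delimited group string into a validated scheme.

    ``"S-T-A-N-D-G-RQ-EK-H-P-IV-L-M-WYF-C"`` gives 15 groups; the first
    letter of each group is its representative.

    Raises
    ------
    SchemeError
        On duplicate letters, incomplete partitions, empty groups, or a
        ``size_hint`` mismatch.
    """
    groups = tuple(spec.strip().upper().split("-"))
    if any(g == "" for g in groups):
        raise SchemeError(f"empty group in spec {spec!r}")
    scheme = ReductionScheme(type_id=type_id, groups=groups)
    if size_hint is not None and scheme.size != size_hint:
        raise SchemeError(
            f"spec {spec!r} has {scheme.size} groups, expected {size_hint}"
        )
    return scheme


def builtin_type33() -> list[ReductionScheme]:
    """The 18 type-33 schemes, sizes 2 through 19.

    The family is a nested hierarchy: each size-``s+1`` scheme refines one
    group of the size-``s`` scheme.  Size 2 is the polar/hydrophobic split
    (cysteine kept apart throughout).
    """
    return [
        parse_scheme_string(spec, TYPE33, size_hint=size)
        for size, spec in sorted(_TYPE33_SPECS.items())
    ]


def get_type33(size: int) -> ReductionScheme:
    """Single type-33 scheme of the given size (2-19)."""
    try:
        spec = _TYPE33_SPECS[size]
    except KeyError:
        raise SchemeError(f"type-33 has sizes 2..19 (got {size})") from None
    return parse_scheme_string(spec, TYPE33, size_hint=size)


def identity_scheme() -> ReductionScheme:
    """The trivial 20-group scheme (no reduction)."""
    return parse_scheme_string("-".join(CANONICAL), type_id=1)


def load_scheme_library(path) -> dict[tuple[int, int], ReductionScheme]:
    """Load a scheme registry from a plain-text catalog file.

    One scheme per line: ``type <t> size <s> scheme <spec>``; ``#`` starts a
    comment; blank lines ignored.  Keys are ``(type_id, size)``.
    """
    registry: dict[tuple[int, int], ReductionScheme] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if (
                len(tokens) != 6
                or tokens[0] != "type"
                or tokens[2] != "size"
                or tokens[4] != "scheme"
            ):
                raise SchemeFileError(
                    f"expected 'type <t> size <s> scheme <spec>', got {line!r}",
                    lineno,
                )
            try:
                t, s = int(tokens[1]), int(tokens[3])
            except ValueError:
                raise SchemeFileError(
                    f"non-integer type/size in {line!r}", lineno
                ) from None
            if (t, s) in registry:
                raise SchemeFileError(f"duplicate scheme key (type={t}, size={s})", lineno)
            try:
                registry[(t, s)] = parse_scheme_string(tokens[5], t, size_hint=s)
            except SchemeError as exc:
                raise SchemeFileError(str(exc), lineno) from exc
    return registry


def save_scheme_library(registry: Mapping[tuple[int, int], ReductionScheme], path) -> None:
    """Write a registry back in the catalog format (round-trip exact)."""
    with open(path, "w") as fh:
        for (t, s), scheme in sorted(registry.items()):
            fh.write(f"type {t} size {s} scheme {scheme.spec_string}\n")


def reduce_sequence(
    seq: str,
    scheme: ReductionScheme,
    *,
    seq_id: str = "",
    nonstandard_policy: str = "drop",
) -> ReducedSequence:
    """Rewrite a protein sequence over the scheme's representative letters.

    Input is case-insensitive.  Non-canonical letters (B, J, O, U, X, Z and
    the ``*`` stop symbol) are handled per ``nonstandard_policy``:

    - ``"drop"`` (default): removed; the count is recorded on the result and
      logged.
    - ``"error"``: any non-canonical letter raises :class:`SequenceError`.
    """
    if nonstandard_policy not in ("drop", "error"):
        raise ValueError(f"unknown nonstandard_policy {nonstandard_policy!r}")
    table = scheme._table
    out: list[str] = []
    dropped = 0
    for letter in seq.upper():
        rep = table.get(letter)
        if rep is not None:
            out.append(rep)
        elif nonstandard_policy == "error":
            raise SequenceError(
                f"non-canonical residue {letter!r} in sequence {seq_id!r}"
            )
        else:
            dropped += 1
    if not out:
        raise SequenceError(
            f"sequence {seq_id!r} is empty after dropping non-canonical residues"
        )
    if dropped:
        logger.debug("dropped %d non-canonical residues from %r", dropped, seq_id)
    return ReducedSequence("".join(out), seq_id, scheme, dropped=dropped)


def is_nested_refinement(coarse: ReductionScheme, fine: ReductionScheme) -> bool:
    """True if every group of ``fine`` is a subset of some group of ``coarse``."""
    coarse_sets = [set(g) for g in coarse.groups]
    return all(
        any(set(g) <= cs for cs in coarse_sets) for g in fine.groups
    )
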