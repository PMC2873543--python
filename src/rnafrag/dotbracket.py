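"""Extended multi-strand dot-bracket secondary-structure representation.

The dialect extends classic dot-bracket notation in three ways:

* records hold multiple strands, each introduced by a ``>name`` header, and
  base pairs may link positions of different strands;
* residues whose coordinates are absent from the source structure are marked
  with ``-`` instead of ``.``;
* pseudoknotted pairings use additional bracket tiers ``[]``, ``{}``, ``<>``
  beyond the nested tier ``()``.

Positions are 1-based, either strand-local or *global* over the concatenation
of strands in record order.  Sequences use one-letter residue codes: uppercase
``A C G U`` for unmodified ribonucleotides, lowercase ``a c g u`` for modified
or non-RNA analogs named after the closest parent nucleoside, and ``n`` when
no parent can be assigned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "BRACKET_TIERS",
    "DotBracketError",
    "Pair",
    "Strand",
    "ExtendedDotBracket",
    "PairTable",
    "parse_dotbracket",
    "parse_dotbracket_library",
    "serialize",
    "to_pair_table",
]

#: Bracket alphabet in fixed tier priority order.
BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
MAX_TIERS = len(BRACKET_TIERS)

OPEN_BY_TIER = {t: o for t, (o, c) in enumerate(BRACKET_TIERS)}
CLOSE_BY_TIER = {t: c for t, (o, c) in enumerate(BRACKET_TIERS)}
TIER_OF_OPEN = {o: t for t, (o, c) in enumerate(BRACKET_TIERS)}
TIER_OF_CLOSE = {c: t for t, (o, c) in enumerate(BRACKET_TIERS)}

STRUCTURE_CHARS = set(".-()[]{}<>")
# one-letter residue codes plus the IUPAC ambiguity codes used in patterns
SEQUENCE_CHARS = set("ACGUacgun") | set("RYSWKMBDHVN")


class DotBracketError(ValueError):
    """Malformed dot-bracket text or inconsistent record contents."""


@dataclass(frozen=True, order=True)
class Pair:
    """A base pair in global 1-based coordinates, ``i < j``, with its bracket tier."""

    i: int
    j: int
    tier: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j):
            raise DotBracketError(f"invalid pair ({self.i}, {self.j})")


@dataclass
class Strand:
    name: str
    structure: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if len(self.structure) == 0:
            raise DotBracketError(f"strand {self.name!r} is empty")
        bad = set(self.structure) - STRUCTURE_CHARS
        if bad:
            raise DotBracketError(
                f"strand {self.name!r}: illegal structure character(s) {sorted(bad)}"
            )
        if self.sequence is not None:
            if len(self.sequence) != len(self.structure):
                raise DotBracketError(
                    f"strand {self.name!r}: sequence length {len(self.sequence)} != "
                    f"structure length {len(self.structure)}"
                )
            bad = set(self.sequence) - SEQUENCE_CHARS
            if bad:
                raise DotBracketError(
                    f"strand {self.name!r}: illegal sequence character(s) {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.structure)


@dataclass
class ExtendedDotBracket:
    """A parsed multi-strand record: strands plus the resolved pair list."""

    strands: list[Strand]
    pairs: list[Pair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strands:
            raise DotBracketError("record has no strands")
        self.pairs = sorted(self.pairs)

    # -- coordinates ----------------------------------------------------

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.strands)

    @property
    def offsets(self) -> list[int]:
        """Global position of each strand's first residue, 1-based."""
        out, pos = [], 1
        for s in self.strands:
            out.append(pos)
            pos += len(s)
        return out

    def strand_of(self, gpos: int) -> tuple[int, int]:
        """Map a global position to ``(strand_index, local_position)``, both 0-/1-based."""
        if not 1 <= gpos <= self.length:
            raise IndexError(gpos)
        for k, off in enumerate(self.offsets):
            if gpos < off + len(self.strands[k]):
                return k, gpos - off + 1
        return len(self.strands) - 1, gpos - self.offsets[-1] + 1

    @property
    def global_structure(self) -> str:
        return "".join(s.structure for s in self.strands)

    @property
    def global_sequence(self) -> str | None:
        if any(s.sequence is None for s in self.strands):
            return None
        return "".join(s.sequence for s in self.strands)  # type: ignore[misc]

    def strand_breaks(self) -> set[int]:
        """Global positions ``p`` such that ``p`` and ``p+1`` lie on different strands."""
        breaks, pos = set(), 0
        for s in self.strands[:-1]:
            pos += len(s)
            breaks.add(pos)
        return breaks

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExtendedDotBracket):
            return NotImplemented
        return self.strands == other.strands and self.pairs == other.pairs


@dataclass
class PairTable:
    """Involution form of the pair relation: ``partner[i]`` is 1-based or 0."""

    partner: list[int]  # index 0 unused; partner[i] for i in 1..N
    tier: list[int]  # -1 where unpaired

    @property
    def length(self) -> int:
        return len(self.partner) - 1

    def as_list(self) -> list[int]:
        """Partner list in plain 1..N order (for display and tests)."""
        return self.partner[1:]


# ---------------------------------------------------------------------------
# parsing

_HEADER_SPLIT = re.compile(r"^([A-Za-z_]+\d+)(.+)$")
_HEADER_MARK = re.compile(r">(?=[A-Za-z_])")


def _split_header_token(token: str) -> tuple[str, str]:
    """Split ``strand1GACU...`` style headers into name and inline body.

    A header token is a name optionally followed, with no separator, by record
    body text; names are taken to end at the last digit of a letters-then-digits
    prefix (the ``strandN`` convention) when the remainder consists of body
    characters only.
    """
    m = _HEADER_SPLIT.match(token)
    if m and set(m.group(2)) <= (STRUCTURE_CHARS | SEQUENCE_CHARS | {"^", "$", "?"}):
        return m.group(1), m.group(2)
    return token, ""


def _tokenize_record(
    text: str, extra_struct: frozenset[str] = frozenset()
) -> list[tuple[str, list[str]]]:
    """Split record text into ``(strand_name, body_tokens)`` groups."""
    groups: list[tuple[str, list[str]]] = []
    for raw_line in text.splitlines():
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        for part in line.split():
            # '>' opens a header only when a name character follows;
            # otherwise it is the tier-3 closing bracket
            while part:
                m = _HEADER_MARK.search(part, 1 if part.startswith(">") else 0)
                if part.startswith(">") and part[1:2].isidentifier():
                    nxt = m.start() if m else len(part)
                    head, part = part[1:nxt], part[nxt:]
                    name, inline = _split_header_token(head)
                    groups.append((name, []))
                    if inline:
                        groups[-1][1].append(inline)
                else:
                    if not groups:
                        raise DotBracketError(
                            "record body before the first '>' strand header"
                        )
                    nxt = m.start() if m else len(part)
                    tok, part = part[:nxt], part[nxt:]
                    groups[-1][1].append(tok)
    if not groups:
        raise DotBracketError("no strand headers found")
    return groups


def split_runs(name: str, token: str) -> list[tuple[str, str]]:
    """Split a body token into maximal runs of sequence or structure characters.

    Characters in both alphabets would be ambiguous; the two sets are disjoint,
    and anything outside their union is an error.  Returns ``(class, run)``
    with class ``"seq"`` or ``"struct"``.
    """
    runs: list[tuple[str, str]] = []
    for ch in token:
        if ch in SEQUENCE_CHARS:
            cls = "seq"
        elif ch in STRUCTURE_CHARS:
            cls = "struct"
        else:
            raise DotBracketError(f"strand {name!r}: illegal character {ch!r}")
        if runs and runs[-1][0] == cls:
            runs[-1] = (cls, runs[-1][1] + ch)
        else:
            runs.append((cls, ch))
    return runs


def _classify_body(
    name: str, tokens: list[str]
) -> tuple[str | None, str | None]:
    """Separate body tokens into one sequence string and one structure string."""
    seq_parts: list[str] = []
    struct_parts: list[str] = []
    for tok in tokens:
        for cls, run in split_runs(name, tok):
            (seq_parts if cls == "seq" else struct_parts).append(run)
    seq = "".join(seq_parts) or None
    struct = "".join(struct_parts) or None
    return seq, struct


def resolve_pairs(structure: str) -> list[Pair]:
    """Resolve bracket pairs tier by tier over a (global) structure string."""
    pairs: list[Pair] = []
    stacks: dict[int, list[int]] = {t: [] for t in range(MAX_TIERS)}
    for pos, ch in enumerate(structure, start=1):
        if ch in TIER_OF_OPEN:
            stacks[TIER_OF_OPEN[ch]].append(pos)
        elif ch in TIER_OF_CLOSE:
            t = TIER_OF_CLOSE[ch]
            if not stacks[t]:
                raise DotBracketError(
                    f"unbalanced {CLOSE_BY_TIER[t]!r} at global position {pos}"
                )
            pairs.append(Pair(stacks[t].pop(), pos, t))
    for t, st in stacks.items():
        if st:
            raise DotBracketError(
                f"unbalanced {OPEN_BY_TIER[t]!r} at global position {st[-1]}"
            )
    return sorted(pairs)


def parse_dotbracket(text: str) -> ExtendedDotBracket:
    """Parse one extended dot-bracket record.

    The record consists of one or more ``>name`` strand headers, each followed
    by an optional sequence string and a structure string (whitespace between
    and within them is ignored; ``#`` starts a comment).  Brackets are resolved
    per tier over the concatenation of strands.
    """
    strands = []
    for name, tokens in _tokenize_record(text):
        seq, struct = _classify_body(name, tokens)
        if struct is None:
            if seq is None:
                raise DotBracketError(f"strand {name!r} is empty")
            # sequence-only strand: structure unconstrained, all unpaired
            struct = "." * len(seq)
        strands.append(Strand(name, struct, seq))
    ssdb = ExtendedDotBracket(strands)
    ssdb.pairs = resolve_pairs(ssdb.global_structure)
    return ssdb


def parse_dotbracket_library(text: str) -> list[tuple[str, ExtendedDotBracket]]:
    """Parse a library file of records separated by ``#=`` entry marker lines.

    Each record is introduced by a comment line ``#= entry_id``; the remainder
    follows the single-record grammar of :func:`parse_dotbracket`.
    """
    entries: list[tuple[str, list[str]]] = []
    for line in text.splitlines():
        if line.startswith("#="):
            entries.append((line[2:].strip(), []))
        elif entries:
            entries[-1][1].append(line)
        elif line.strip() and not line.lstrip().startswith("#"):
            raise DotBracketError("library text before the first '#=' entry marker")
    return [(eid, parse_dotbracket("\n".join(body))) for eid, body in entries]


# ---------------------------------------------------------------------------
# serialization and the pair table

def serialize(ssdb: ExtendedDotBracket) -> str:
    """Serialize to canonical record text; inverse of :func:`parse_dotbracket`."""
    lines: list[str] = []
    for s in ssdb.strands:
        lines.append(f">{s.name}")
        if s.sequence is not None:
            lines.append(s.sequence)
        lines.append(s.structure)
    return "\n".join(lines) + "\n"


def to_pair_table(ssdb: ExtendedDotBracket) -> PairTable:
    """Pair-table (involution) form; ``-``/``.`` positions map to 0."""
    n = ssdb.length
    partner = [0] * (n + 1)
    tier = [-1] * (n + 1)
    for p in ssdb.pairs:
        if partner[p.i] or partner[p.j]:
            raise DotBracketError(f"position in more than one pair: {p}")
        partner[p.i], partner[p.j] = p.j, p.i
        tier[p.i] = tier[p.j] = p.tier
    return PairTable(partner, tier)
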