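"""Pattern search for single- and multi-strand RNA 3D fragments.

A query is written in the same strand-header notation as the library records:
one or more ``>name`` headers, each followed by a sequence pattern (IUPAC
ambiguity codes allowed; uppercase = unmodified residue, lowercase = modified
residue of that parent) and/or a structure pattern over dots and brackets.
Three wildcards extend the notation:

* ``^`` anchors the strand window to the 5' terminus, ``$`` to the 3'
  terminus (only at a strand's ends);
* ``?`` matches any residue — paired, unpaired, or missing from the
  coordinate section (inside multi-strand patterns only at strand ends).

Matching assigns every query strand to a contiguous window on a structure
strand; windows are pairwise disjoint and follow the query's strand order.
A bracket pair in the pattern requires the two matched residues to pair
canonically with each other; ``.`` requires a canonically unpaired residue
with coordinates.  Advanced options: ``all_models`` searches every deposited
model instead of the first; ``through_space`` lets ``.`` also match residues
whose pairing partner lies outside the matched fragment (the external
partners are reported); ``strand_shift`` unions the hits of all cyclic
rotations of the query's strand list.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

from .annotate import BasePair
from .dotbracket import (
    STRUCTURE_CHARS,
    DotBracketError,
    ExtendedDotBracket,
    parse_dotbracket,
    resolve_pairs,
    to_pair_table,
    _tokenize_record,
)
from .structure_io import AnnotatedStructure, detect_missing_residues

__all__ = [
    "PatternError",
    "QueryStrand",
    "QueryPattern",
    "SearchOptions",
    "Filters",
    "Segment",
    "FragmentHit",
    "ModelAnnotation",
    "LibraryEntry",
    "parse_query",
    "entry_from_structure",
    "entry_from_dotbracket",
    "match_entry",
    "search_library",
]

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "U": {"U"},
    "R": {"A", "G"}, "Y": {"C", "U"}, "S": {"C", "G"}, "W": {"A", "U"},
    "K": {"G", "U"}, "M": {"A", "C"}, "B": {"C", "G", "U"},
    "D": {"A", "G", "U"}, "H": {"A", "C", "U"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "U"},
}
_QUERY_SEQ_CHARS = set("acgun") | set(IUPAC)
_QUERY_STRUCT_CHARS = (STRUCTURE_CHARS - {"-"}) | {"?"}


class PatternError(ValueError):
    """Malformed query pattern."""


@dataclass
class QueryStrand:
    name: str
    sequence: str | None
    structure: str | None
    anchor5: bool = False
    anchor3: bool = False

    @property
    def length(self) -> int:
        return len(self.structure if self.structure is not None else self.sequence)


@dataclass
class QueryPattern:
    strands: list[QueryStrand]
    pairs: list[tuple[int, int]] = field(default_factory=list)  # pattern-global 1-based

    @property
    def length(self) -> int:
        return sum(s.length for s in self.strands)

    def rotated(self, r: int) -> "QueryPattern":
        """Cyclic rotation of the strand list by ``r``.

        The pair topology travels with the strands (pattern-global pair
        positions are remapped); the bracket characters themselves are not
        rewritten — matching only uses paired-ness and the pair list.
        """
        n = len(self.strands)
        r %= n
        if r == 0:
            return self
        lengths = [s.length for s in self.strands]
        offsets = [sum(lengths[:k]) for k in range(n)]
        new_order = list(range(r, n)) + list(range(r))
        new_offsets = {}
        pos = 0
        for k in new_order:
            new_offsets[k] = pos
            pos += lengths[k]
        remap = {}
        for k in range(n):
            for loc in range(1, lengths[k] + 1):
                remap[offsets[k] + loc] = new_offsets[k] + loc
        pairs = sorted(
            (min(remap[a], remap[b]), max(remap[a], remap[b]))
            for a, b in self.pairs
        )
        return QueryPattern([self.strands[k] for k in new_order], pairs)


@dataclass
class SearchOptions:
    all_models: bool = False
    through_space: bool = False
    strand_shift: bool = False


@dataclass
class Filters:
    methods: set[str] | None = None
    max_resolution: float | None = None
    date_from: _dt.date | None = None
    date_to: _dt.date | None = None
    allow_modified: bool = True


@dataclass
class Segment:
    chain_id: str
    start: int | None  # author numbers of the window endpoints
    end: int | None
    strand_index: int
    start_local: int  # 1-based within the structure strand
    length: int


@dataclass
class FragmentHit:
    entry_id: str
    model_number: int
    rotation: int
    segments: list[Segment]  # one per query strand, in query order
    pairs: list[BasePair]  # matched pairs with location flags
    qmark_count: int
    positions: frozenset[int] = frozenset()  # entry-global matched positions

    def sort_key(self):
        first = self.segments[0]
        return (
            self.entry_id, self.model_number, first.chain_id,
            first.start if first.start is not None else 1 << 30,
            self.rotation,
        )


# ---------------------------------------------------------------------------
# query parsing

def parse_query(text: str) -> QueryPattern:
    """Parse a query in the strand-header grammar into a :class:`QueryPattern`."""
    try:
        groups = _tokenize_record(text)
    except DotBracketError as exc:
        raise PatternError(str(exc)) from exc
    strands: list[QueryStrand] = []
    for name, tokens in groups:
        body = "".join(tokens)
        if not body:
            raise PatternError(f"strand {name!r} is empty")
        a5 = a3 = False
        if body.startswith("^"):
            a5, body = True, body[1:]
        if body.endswith("$"):
            a3, body = True, body[:-1]
        if "^" in body or "$" in body:
            raise PatternError(f"strand {name!r}: anchor not at a strand terminus")
        seq_parts, struct_parts = [], []
        run_cls = ""
        for ch in body:
            if ch in _QUERY_SEQ_CHARS:
                cls = "seq"
            elif ch in _QUERY_STRUCT_CHARS:
                cls = "struct"
            else:
                raise PatternError(f"strand {name!r}: unknown character {ch!r}")
            target = seq_parts if cls == "seq" else struct_parts
            if cls == run_cls:
                target[-1] += ch
            else:
                target.append(ch)
            run_cls = cls
        seq = "".join(seq_parts) or None
        struct = "".join(struct_parts) or None
        if seq is None and struct is None:
            raise PatternError(f"strand {name!r} is empty")
        if seq is not None and struct is not None and len(seq) != len(struct):
            raise PatternError(
                f"strand {name!r}: sequence length {len(seq)} != "
                f"structure length {len(struct)}"
            )
        strands.append(QueryStrand(name, seq, struct, a5, a3))
    if len(strands) > 1:
        for s in strands:
            if s.structure is not None:
                core = s.structure.strip("?")
                if "?" in core:
                    raise PatternError(
                        f"strand {s.name!r}: '?' inside a multi-strand pattern is "
                        "only allowed at strand 5'/3' ends"
                    )
    return _compile(strands)


def _compile(strands: list[QueryStrand]) -> QueryPattern:
    pattern = QueryPattern(list(strands))
    concat = "".join(
        (s.structure if s.structure is not None else "." * s.length)
        for s in strands
    ).replace("?", ".")
    try:
        pattern.pairs = [(p.i, p.j) for p in resolve_pairs(concat)]
    except DotBracketError as exc:
        raise PatternError(str(exc)) from exc
    return pattern


# ---------------------------------------------------------------------------
# library entries

@dataclass
class ModelAnnotation:
    """One model of a library entry, ready for matching."""

    ssdb: ExtendedDotBracket
    numbering: list[tuple[str, int | None, str]]  # per global position
    all_pairs: list[BasePair] = field(default_factory=list)


@dataclass
class LibraryEntry:
    entry_id: str
    method: str = "other"
    resolution: float | None = None
    deposition_date: _dt.date | None = None
    models: list[ModelAnnotation] = field(default_factory=list)
    structure: AnnotatedStructure | None = None

    @property
    def has_modified(self) -> bool:
        seq = self.models[0].ssdb.global_sequence
        return seq is not None and any(c.islower() for c in seq)


def entry_from_structure(structure: AnnotatedStructure) -> LibraryEntry:
    """Annotate every model of a coordinate entry into a searchable library entry."""
    from .annotate import annotate_structure

    detect_missing_residues(structure)
    entry = LibraryEntry(
        structure.entry_id, structure.method, structure.resolution,
        structure.deposition_date, structure=structure,
    )
    for k, model in enumerate(structure.models):
        ssdb, all_pairs = annotate_structure(structure, k)
        numbering = [
            (strand.chain_id, r.number, r.icode)
            for strand in model.strands for r in strand.residues
        ]
        entry.models.append(ModelAnnotation(ssdb, numbering, all_pairs))
    return entry


def entry_from_dotbracket(
    entry_id: str,
    record: str | ExtendedDotBracket,
    method: str = "other",
    resolution: float | None = None,
    deposition_date: _dt.date | None = None,
    n_models: int = 1,
) -> LibraryEntry:
    """Build a searchable entry directly from a dot-bracket record.

    Author numbering is synthesized as 1..L per strand with the strand name as
    chain id; all bracket pairs are taken as canonical.
    """
    ssdb = parse_dotbracket(record) if isinstance(record, str) else record
    numbering: list[tuple[str, int | None, str]] = []
    for s in ssdb.strands:
        numbering.extend((s.name, k + 1, "") for k in range(len(s)))
    all_pairs = [BasePair(p.i, p.j, "canonical", p.tier) for p in ssdb.pairs]
    return LibraryEntry(
        entry_id, method, resolution, deposition_date,
        models=[ModelAnnotation(ssdb, list(numbering), list(all_pairs))
                for _ in range(n_models)],
    )


# ---------------------------------------------------------------------------
# matching

def _letter_ok(c: str, entry_letter: str, parent: str | None) -> bool:
    if c in "acgun":
        if c == "n":
            return entry_letter == "n"
        return entry_letter.islower() and parent == c.upper()
    if c in "ACGU":
        return entry_letter == c
    if c == "N":
        return True
    allowed = IUPAC[c]
    return parent in allowed


class _EntryView:
    """Flattened per-model arrays used by the matcher."""

    def __init__(self, model: ModelAnnotation):
        ssdb = model.ssdb
        self.ssdb = ssdb
        self.numbering = model.numbering
        self.all_pairs = model.all_pairs
        self.structure = ssdb.global_structure
        seq = ssdb.global_sequence
        self.sequence = seq if seq is not None else "n" * ssdb.length
        self.missing = [ch == "-" for ch in self.structure]
        table = to_pair_table(ssdb)
        self.partner = table.partner
        self.spans = []  # (start_g, length, chain-ish name)
        off = 1
        for s in ssdb.strands:
            self.spans.append((off, len(s)))
            off += len(s)

    def parent_of(self, g: int) -> str | None:
        c = self.sequence[g - 1]
        return c.upper() if c.upper() in "ACGU" else None


def _window_ok(
    view: _EntryView, q: QueryStrand, start_g: int, through_space: bool
) -> bool:
    """Local (assignment-independent) character checks for one window."""
    L = q.length
    for k in range(L):
        g = start_g + k
        sc = q.structure[k] if q.structure is not None else None
        missing = view.missing[g - 1]
        if sc == "?":
            pass
        else:
            if missing:
                return False  # '-' is matched only by '?'
            if sc == ".":
                if not through_space and view.partner[g] != 0:
                    return False
            elif sc is not None:  # a bracket
                if view.partner[g] == 0:
                    return False
        if q.sequence is not None:
            if missing:
                # identity may be known from the declared sequence
                if not _letter_ok(q.sequence[k], view.sequence[g - 1],
                                  view.parent_of(g)):
                    return False
            elif not _letter_ok(q.sequence[k], view.sequence[g - 1],
                                view.parent_of(g)):
                return False
    return True


def _candidate_windows(
    view: _EntryView, q: QueryStrand, through_space: bool
) -> list[tuple[int, int]]:
    """All (strand_index, start_global) windows passing the local checks."""
    out = []
    for t, (off, length) in enumerate(view.spans):
        L = q.length
        if L > length:
            continue
        starts = range(1, length - L + 2)
        if q.anchor5:
            starts = [1]
        for s_local in starts:
            if q.anchor3 and s_local + L - 1 != length:
                continue
            g = off + s_local - 1
            if _window_ok(view, q, g, through_space):
                out.append((t, g))
    return out


def _assignment_hits(
    pattern: QueryPattern, view: _EntryView, options: SearchOptions
) -> list[tuple[list[int], frozenset[int], int]]:
    """Backtracking search over ordered disjoint window assignments.

    Returns tuples of (start_globals per rotated strand, matched set, qmarks).
    """
    cand = [
        _candidate_windows(view, q, options.through_space)
        for q in pattern.strands
    ]
    if any(not c for c in cand):
        return []
    lengths = [q.length for q in pattern.strands]
    results = []
    chosen: list[tuple[int, int]] = []  # (start_g, end_g)

    def ok_disjoint(start: int, end: int) -> bool:
        return all(end < s or e < start for s, e in chosen)

    def rec(k: int):
        if k == len(cand):
            starts = [s for s, _ in chosen]
            _finalize(pattern, view, options, starts, results)
            return
        prev_start = chosen[-1][0] if chosen else 0
        for _t, g in cand[k]:
            end = g + lengths[k] - 1
            if g <= prev_start or not ok_disjoint(g, end):
                continue
            chosen.append((g, end))
            rec(k + 1)
            chosen.pop()

    rec(0)
    return results


def _finalize(pattern, view, options, starts, results):
    """Full-assignment semantic checks; append (starts, positions, qmarks)."""
    # map pattern-global position -> entry-global position
    mapping: dict[int, int] = {}
    p = 1
    qmarks = 0
    for q, start in zip(pattern.strands, starts):
        for k in range(q.length):
            mapping[p] = start + k
            if q.structure is not None and q.structure[k] == "?":
                qmarks += 1
            p += 1
    matched = frozenset(mapping.values())
    for (a, b) in pattern.pairs:
        if view.partner[mapping[a]] != mapping[b]:
            return
    p = 1
    for q in pattern.strands:
        for k in range(q.length):
            g = mapping[p]
            p += 1
            sc = q.structure[k] if q.structure is not None else None
            if sc == ".":
                partner = view.partner[g]
                if partner != 0 and not (
                    options.through_space and partner not in matched
                ):
                    return
    results.append((starts, matched, qmarks))


def match_entry(
    pattern: QueryPattern,
    entry: LibraryEntry,
    options: SearchOptions | None = None,
    model_index: int = 0,
) -> list[FragmentHit]:
    """All hits of ``pattern`` in one model of a library entry.

    With ``strand_shift`` the hits of every cyclic rotation of the pattern's
    strand list are unioned; duplicate hits covering an identical residue set
    are reported once.
    """
    options = options or SearchOptions()
    model = entry.models[model_index]
    view = _EntryView(model)
    n_strands = len(pattern.strands)
    rotations = range(n_strands) if options.strand_shift else [0]

    hits: list[FragmentHit] = []
    seen: set[frozenset[int]] = set()
    for r in rotations:
        rot = pattern.rotated(r)
        for starts, matched, qmarks in _assignment_hits(rot, view, options):
            if matched in seen:
                continue
            seen.add(matched)
            # reorder rotated strands back to query order
            per_query: list[Segment | None] = [None] * n_strands
            for k_rot, (q, g) in enumerate(zip(rot.strands, starts)):
                orig = (k_rot + r) % n_strands
                t = next(
                    ti for ti, (off, ln) in enumerate(view.spans)
                    if off <= g < off + ln
                )
                off, _ln = view.spans[t]
                chain, num_s, _ = view.numbering[g - 1]
                _, num_e, _ = view.numbering[g + q.length - 2]
                per_query[orig] = Segment(
                    chain, num_s, num_e, t, g - off + 1, q.length
                )
            pairs = _hit_pairs(view, matched)
            hits.append(
                FragmentHit(
                    entry.entry_id, model_index + 1, r,
                    [s for s in per_query if s is not None],
                    pairs, qmarks, matched,
                )
            )
    hits.sort(key=FragmentHit.sort_key)
    return hits


def _hit_pairs(view: _EntryView, matched: frozenset[int]) -> list[BasePair]:
    out = []
    for p in view.all_pairs:
        if not p.canonical:
            continue
        inside = (p.i in matched) + (p.j in matched)
        if inside == 2:
            out.append(replace(p, location="both_in_fragment"))
        elif inside == 1:
            out.append(replace(p, location="one_in_fragment"))
    return out


def search_library(
    pattern: QueryPattern,
    entries,
    options: SearchOptions | None = None,
    filters: Filters | None = None,
) -> list[FragmentHit]:
    """Search a library of annotated entries, applying filters and options.

    Entries failing the method, resolution, deposition-date or modified-residue
    filters are skipped.  Without ``all_models`` only the first model of each
    entry is searched.  The hit list is deterministically ordered.
    """
    options = options or SearchOptions()
    filters = filters or Filters()
    hits: list[FragmentHit] = []
    for entry in entries:
        if filters.methods is not None and entry.method not in filters.methods:
            continue
        if (
            filters.max_resolution is not None
            and entry.resolution is not None
            and entry.resolution > filters.max_resolution
        ):
            continue
        if filters.date_from is not None and (
            entry.deposition_date is None or entry.deposition_date < filters.date_from
        ):
            continue
        if filters.date_to is not None and (
            entry.deposition_date is None or entry.deposition_date > filters.date_to
        ):
            continue
        if not filters.allow_modified and entry.has_modified:
            continue
        model_indices = (
            range(len(entry.models)) if options.all_models else [0]
        )
        for mi in model_indices:
            hits.extend(match_entry(pattern, entry, options, mi))
    hits.sort(key=FragmentHit.sort_key)
    return hits
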