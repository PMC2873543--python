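"""Brute-force search oracle, independent of the package's matcher.

Enumerates every assignment of query strands to windows and checks the
matching semantics position by position, with its own pair resolution and
IUPAC tables.  Deliberately naive; used only to validate the search engine
on small inputs.
"""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
OPENS = "([{<"
CLOSES = ")]}>"


def _pairs_of(structure: str) -> dict[int, int]:
    partner: dict[int, int] = {}
    stacks: dict[int, list[int]] = {t: [] for t in range(4)}
    for pos, ch in enumerate(structure, start=1):
        if ch in OPENS:
            stacks[OPENS.index(ch)].append(pos)
        elif ch in CLOSES:
            i = stacks[CLOSES.index(ch)].pop()
            partner[i] = pos
            partner[pos] = i
    return partner


def _strand_spans(ss):
    spans, off = [], 1
    for s in ss.strands:
        spans.append((off, len(s)))
        off += len(s)
    return spans


def _letter_match(c, letter, mod):
    parent = letter.upper() if letter.upper() in "ACGU" else None
    if c in "acgu":
        return mod and parent == c.upper()
    if c == "n":
        return letter == "n"
    if c == "N":
        return True
    if c in "ACGU":
        return letter == c
    return parent is not None and parent in IUPAC[c]


def oracle_hits(pattern, entry, options=None, model_index=0):
    """Set of matched residue sets (frozensets of entry-global positions)."""
    from rnafrag.search import SearchOptions

    options = options or SearchOptions()
    model = entry.models[model_index]
    ss = model.ssdb
    struct = ss.global_structure
    seq = ss.global_sequence or "n" * ss.length
    partner = _pairs_of(struct)
    spans = _strand_spans(ss)

    n = len(pattern.strands)
    rotations = range(n) if options.strand_shift else [0]
    found = set()
    for r in rotations:
        rot = _rotate(pattern, r)
        # windows per rotated strand: (global_start)
        cands = []
        for q in rot.strands:
            wins = []
            for off, length in spans:
                if q.length > length:
                    continue
                for s_local in range(1, length - q.length + 2):
                    if q.anchor5 and s_local != 1:
                        continue
                    if q.anchor3 and s_local + q.length - 1 != length:
                        continue
                    wins.append(off + s_local - 1)
            cands.append(wins)
        for combo in product(*cands):
            if _check(rot, combo, struct, seq, partner, options):
                positions = set()
                for q, g in zip(rot.strands, combo):
                    positions.update(range(g, g + q.length))
                found.add(frozenset(positions))
    return found


class _Rotated:
    def __init__(self, strands, pairs):
        self.strands = strands
        self.pairs = pairs


def _rotate(pattern, r):
    """Independent cyclic rotation: reorder strands, remap pair positions."""
    n = len(pattern.strands)
    if r % n == 0:
        return _Rotated(list(pattern.strands), list(pattern.pairs))
    order = list(range(r, n)) + list(range(r))
    lengths = [s.length for s in pattern.strands]
    old_off = {}
    pos = 0
    for k in range(n):
        old_off[k] = pos
        pos += lengths[k]
    new_off = {}
    pos = 0
    for k in order:
        new_off[k] = pos
        pos += lengths[k]
    remap = {}
    for k in range(n):
        for loc in range(1, lengths[k] + 1):
            remap[old_off[k] + loc] = new_off[k] + loc
    pairs = [
        tuple(sorted((remap[a], remap[b]))) for a, b in pattern.pairs
    ]
    return _Rotated([pattern.strands[k] for k in order], pairs)


def _check(rot, combo, struct, seq, partner, options):
    # ordered, pairwise disjoint windows
    intervals = [(g, g + q.length - 1) for q, g in zip(rot.strands, combo)]
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 <= a1:
            return False
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            a1, b1 = intervals[i]
            a2, b2 = intervals[j]
            if not (b1 < a2 or b2 < a1):
                return False

    mapping = {}
    p = 0
    for q, g in zip(rot.strands, combo):
        for k in range(q.length):
            p += 1
            mapping[p] = g + k
    matched = set(mapping.values())

    p = 0
    for q, g in zip(rot.strands, combo):
        for k in range(q.length):
            p += 1
            gpos = mapping[p]
            ch_entry = struct[gpos - 1]
            missing = ch_entry == "-"
            sc = q.structure[k] if q.structure is not None else None
            if sc != "?":
                if missing:
                    return False
                if sc == ".":
                    part = partner.get(gpos, 0)
                    if part != 0:
                        if not (options.through_space and part not in matched):
                            return False
                elif sc is not None:
                    if partner.get(gpos, 0) == 0:
                        return False
            if q.sequence is not None:
                letter = seq[gpos - 1]
                if not _letter_match(q.sequence[k], letter, letter.islower()):
                    return False
    for a, b in rot.pairs:
        if partner.get(mapping[a], 0) != mapping[b]:
            return False
    return True


def hits_as_sets(hits):
    return {h.positions for h in hits}
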