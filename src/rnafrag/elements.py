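"""Decomposition of secondary structures into structural elements.

The element inventory follows the usual taxonomy: stems are maximal runs of
consecutively stacked canonical pairs; loops are the regions closed by one
(hairpin), two (internal loop / bulge — a bulge has exactly one empty segment)
or n >= 3 (n-way junction) canonical pairs; a dinucleotide step is a pair of
adjacent stacked canonical pairs; a multiplet is a connected set of three or
more bases linked by base-base interactions (triplet, quadruplet, quintuplet).

Loop decomposition uses only the nested tier-0 pairs, so pseudoknotted
helices (e.g. the loop-loop helix of a kissing complex) are reported as stems
and pairs but never absorb the hairpins they connect.  A strand break inside
any would-be loop segment blocks that loop: a blunt duplex end is not a
hairpin.  Coordinate-less (``-``) positions count towards segment lengths —
the residues exist even without coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx

from .dotbracket import ExtendedDotBracket, to_pair_table

__all__ = [
    "StructuralElement",
    "MethodCount",
    "LibraryStats",
    "extract_stems",
    "extract_loops",
    "extract_dinucleotide_steps",
    "extract_multiplets",
    "extract_elements",
    "summarize_library",
]


@dataclass
class StructuralElement:
    kind: str  # stem | hairpin | internal | bulge | junction(n) | dinucleotide_step | multiplet kinds
    segments: list[list[int]] = field(default_factory=list)  # global positions per segment
    closing_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_strands(self) -> int:
        return len(self.segments)

    @property
    def positions(self) -> list[int]:
        out = sorted({p for seg in self.segments for p in seg}
                     | {x for pr in self.closing_pairs for x in pr})
        return out


# ---------------------------------------------------------------------------
# stems and steps

def _same_strand(ssdb: ExtendedDotBracket, a: int, b: int) -> bool:
    return ssdb.strand_of(a)[0] == ssdb.strand_of(b)[0]


def extract_stems(ssdb: ExtendedDotBracket) -> list[StructuralElement]:
    """Maximal runs of stacked pairs (i, j), (i+1, j-1); isolated pairs count.

    Stacking never spans a strand break on either side.  Pairs of every
    bracket tier participate (a pseudoknotted helix is still a stem).
    """
    pairs = sorted(p for p in ssdb.pairs)
    by_i = {p.i: p for p in pairs}
    stems: list[StructuralElement] = []
    used: set[tuple[int, int]] = set()
    for p in pairs:
        if (p.i, p.j) in used:
            continue
        run = [(p.i, p.j)]
        cur = p
        while True:
            nxt = by_i.get(cur.i + 1)
            if (
                nxt is not None and nxt.j == cur.j - 1
                and _same_strand(ssdb, cur.i, nxt.i)
                and _same_strand(ssdb, nxt.j, cur.j)
            ):
                run.append((nxt.i, nxt.j))
                cur = nxt
            else:
                break
        # only keep if p is not itself a continuation of an earlier pair
        prev = by_i.get(p.i - 1)
        if (
            prev is not None and prev.j == p.j + 1
            and _same_strand(ssdb, prev.i, p.i)
            and _same_strand(ssdb, p.j, prev.j)
        ):
            continue
        used.update(run)
        stems.append(
            StructuralElement(
                "stem",
                segments=[[i for i, _ in run], [j for _, j in run][::-1]],
                closing_pairs=run,
            )
        )
    return stems


def extract_dinucleotide_steps(ssdb: ExtendedDotBracket) -> list[StructuralElement]:
    """One step per adjacent stacked pair inside each stem (stem length - 1)."""
    steps = []
    for stem in extract_stems(ssdb):
        run = stem.closing_pairs
        for (i1, j1), (i2, j2) in zip(run, run[1:]):
            steps.append(
                StructuralElement(
                    "dinucleotide_step",
                    segments=[[i1, i2], [j2, j1]],
                    closing_pairs=[(i1, j1), (i2, j2)],
                )
            )
    return steps


# ---------------------------------------------------------------------------
# loops

def extract_loops(ssdb: ExtendedDotBracket) -> list[StructuralElement]:
    """Hairpin, internal, bulge and junction loops over the tier-0 pairing.

    For each tier-0 closing pair, the loop consists of the unpaired segments
    between the closing pair and its direct child pairs.  A strand break
    inside any segment (including zero-length ones) blocks the loop; two
    empty segments around a single child are a helix continuation, not a loop.
    """
    table = to_pair_table(ssdb)
    breaks = ssdb.strand_breaks()
    loops: list[StructuralElement] = []
    tier0 = [p for p in ssdb.pairs if p.tier == 0]
    for p in tier0:
        segments: list[list[int]] = []
        children: list[tuple[int, int]] = []
        seg: list[int] = []
        blocked = False
        prev_anchor = p.i
        k = p.i + 1
        while k < p.j:
            partner = table.partner[k]
            if partner and table.tier[k] == 0:
                # child pair
                segments.append(seg)
                if any(prev_anchor <= b < k for b in breaks):
                    blocked = True
                children.append((k, partner))
                prev_anchor = partner
                k = partner + 1
                seg = []
            else:
                seg.append(k)
                k += 1
        segments.append(seg)
        if any(prev_anchor <= b < p.j for b in breaks):
            blocked = True
        if blocked:
            continue
        n_seg = len(segments)
        if n_seg == 1:
            if not segments[0]:
                continue  # helix end directly stacked, no loop
            kind = "hairpin"
        elif n_seg == 2:
            empties = sum(1 for s in segments if not s)
            if empties == 2:
                continue  # stacked pairs, stem interior
            kind = "bulge" if empties == 1 else "internal"
        else:
            kind = f"junction({n_seg})"
        loops.append(
            StructuralElement(kind, segments=segments,
                              closing_pairs=[(p.i, p.j)] + children)
        )
    return loops


# ---------------------------------------------------------------------------
# multiplets

_MULTIPLET_NAMES = {3: "triplet", 4: "quadruplet", 5: "quintuplet"}


def extract_multiplets(pairs) -> list[StructuralElement]:
    """Connected components (>= 3 bases) of the base-interaction graph.

    ``pairs`` may mix canonical pairs and noncanonical contacts; anything with
    ``i``/``j`` attributes or 2-tuples is accepted.
    """
    g = nx.Graph()
    edges = []
    for p in pairs:
        ij = (p.i, p.j) if hasattr(p, "i") else tuple(p)
        edges.append(ij)
    g.add_edges_from(edges)
    out = []
    for comp in nx.connected_components(g):
        if len(comp) < 3:
            continue
        kind = _MULTIPLET_NAMES.get(len(comp), f"multiplet({len(comp)})")
        members = sorted(comp)
        out.append(
            StructuralElement(
                kind,
                segments=[[m] for m in members],
                closing_pairs=sorted(e for e in edges if e[0] in comp),
            )
        )
    return sorted(out, key=lambda e: e.segments[0][0])


# ---------------------------------------------------------------------------
# whole-model inventory and library statistics

def extract_elements(ssdb: ExtendedDotBracket, all_pairs=None) -> list[StructuralElement]:
    """Full element inventory of one model: residues and base pairs included.

    ``all_pairs`` optionally supplies the detected interaction list (canonical
    + noncanonical) for multiplet extraction; by default only the record's own
    canonical pairs are used.
    """
    elements: list[StructuralElement] = []
    for g in range(1, ssdb.length + 1):
        elements.append(StructuralElement("residue", segments=[[g]]))
    for p in ssdb.pairs:
        elements.append(
            StructuralElement("base_pair", segments=[[p.i], [p.j]],
                              closing_pairs=[(p.i, p.j)])
        )
    elements.extend(extract_stems(ssdb))
    elements.extend(extract_dinucleotide_steps(ssdb))
    elements.extend(extract_loops(ssdb))
    elements.extend(extract_multiplets(all_pairs if all_pairs is not None else ssdb.pairs))
    return elements


def _pct(missing: int, residues: int) -> float:
    """Percentage of coordinate-less residues, rounded half-up to 2 decimals."""
    if residues == 0:
        return 0.0
    q = Decimal(100 * missing) / Decimal(residues)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MethodCount:
    structures: int = 0
    models: int = 0
    strands: int = 0
    residues: int = 0
    missing: int = 0

    @property
    def missing_percent(self) -> float:
        return _pct(self.missing, self.residues)

    def __add__(self, other: "MethodCount") -> "MethodCount":
        return MethodCount(
            self.structures + other.structures,
            self.models + other.models,
            self.strands + other.strands,
            self.residues + other.residues,
            self.missing + other.missing,
        )


@dataclass
class LibraryStats:
    by_method: dict[str, MethodCount] = field(default_factory=dict)
    element_counts: dict[str, int] = field(default_factory=dict)  # all models
    element_counts_first: dict[str, int] = field(default_factory=dict)  # model 1 only

    @property
    def total(self) -> MethodCount:
        out = MethodCount()
        for mc in self.by_method.values():
            out = out + mc
        return out

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int, int, int, int]]) -> "LibraryStats":
        """Build stats from raw per-method counts
        ``(structures, models, strands, residues, missing)``."""
        return cls({m: MethodCount(*v) for m, v in counts.items()})


def summarize_library(entries) -> LibraryStats:
    """Aggregate statistics over annotated library entries.

    ``entries`` iterate as objects with ``method`` and per-model dot-bracket
    records (``models`` attribute: list of (ssdb, ...) model annotations, see
    the search module's ``LibraryEntry``).  Models, strands, residues and
    coordinate-less residues are summed over all models; element counts are
    reported both over all models and over first models only.
    """
    stats = LibraryStats()
    for entry in entries:
        mc = stats.by_method.setdefault(entry.method, MethodCount())
        mc.structures += 1
        for k, model in enumerate(entry.models):
            ssdb = model.ssdb
            mc.models += 1
            mc.strands += len(ssdb.strands)
            mc.residues += ssdb.length
            mc.missing += ssdb.global_structure.count("-")
            inventory = extract_elements(ssdb, model.all_pairs)
            for el in inventory:
                stats.element_counts[el.kind] = stats.element_counts.get(el.kind, 0) + 1
                if k == 0:
                    stats.element_counts_first[el.kind] = (
                        stats.element_counts_first.get(el.kind, 0) + 1
                    )
    return stats
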