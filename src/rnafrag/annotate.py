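"""Base-pair detection and extended dot-bracket encoding from 3D coordinates.

Canonical pairs (Watson-Crick A·U and G·C, plus the G·U wobble) are detected
geometrically:

* C1'-C1' distance within 10.4 +- 1.5 A;
* at least two of the class-specific Watson-Crick-edge donor-acceptor
  heavy-atom distances below 3.4 A (A·U: N1-N3, N6-O4; G·C: N1-N3, N2-O2,
  O6-N4; G·U: O6-N3, N1-O2), with each contact vector lying within 45 deg of
  both base planes (hydrogen bonds are approximately coplanar with the bases,
  which separates edge-to-edge pairing from mere stacking proximity);
* angle between the two base planes below 30 deg.

Modified residues pair by parent nucleoside identity, so a modified ``g`` can
form a canonical pair with ``C``.  Each base joins at most one canonical pair
(the best-scoring candidate is kept).  Base-base contacts that satisfy the
polar-contact rule without meeting the canonical criteria are reported as
noncanonical interactions, feeding multiplet analysis.

The canonical pairs are then laid out on bracket tiers — tier 0 is a maximum
cardinality non-crossing (nested) subset, pseudoknotted remainder pairs move
to higher tiers — and rendered as an extended dot-bracket record in which
coordinate-less residues appear as ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.spatial import cKDTree

from .dotbracket import (
    CLOSE_BY_TIER,
    MAX_TIERS,
    OPEN_BY_TIER,
    ExtendedDotBracket,
    Pair,
    Strand,
)
from .structure_io import AnnotatedStructure, Model

__all__ = [
    "BasePair",
    "TierError",
    "detect_base_pairs",
    "detect_canonical_pairs",
    "assign_bracket_tiers",
    "encode_secondary_structure",
    "annotate_structure",
]

C1C1_TARGET = 10.4
C1C1_TOL = 1.5
HBOND_MAX = 3.4
PLANE_ANGLE_MAX = 30.0
HBOND_PLANE_ANGLE_MAX = 45.0

# Watson-Crick-edge donor/acceptor atom pairs per canonical class,
# keyed by (parent_i, parent_j)
_CANONICAL_EDGES = {
    ("A", "U"): ("WC-AU", [("N1", "N3"), ("N6", "O4")], 2),
    ("G", "C"): ("WC-GC", [("N1", "N3"), ("N2", "O2"), ("O6", "N4")], 2),
    ("G", "U"): ("wobble-GU", [("O6", "N3"), ("N1", "O2")], 2),
}

_PURINE_RING = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
_PYRIMIDINE_RING = ["N1", "C2", "N3", "C4", "C5", "C6"]
_SUGAR_PHOSPHATE = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}


class TierError(ValueError):
    """Pairing topology needs more bracket tiers than the notation provides."""


@dataclass
class BasePair:
    """A base-base interaction between global positions ``i < j``."""

    i: int
    j: int
    kind: str  # WC-AU | WC-GC | wobble-GU | noncanonical
    tier: int | None = None
    location: str | None = None  # both_in_fragment | one_in_fragment (search hits)

    @property
    def canonical(self) -> bool:
        return self.kind != "noncanonical"

    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


# ---------------------------------------------------------------------------
# geometry helpers

def _base_plane(res) -> tuple[np.ndarray, np.ndarray] | None:
    """Least-squares base plane as (centroid, unit normal), or None."""
    ring = _PURINE_RING if "N9" in res.atoms else _PYRIMIDINE_RING
    pts = [res.atoms.get(a) for a in ring]
    pts = [p for p in pts if p is not None]
    if len(pts) < 4:
        return None
    arr = np.asarray(pts)
    centroid = arr.mean(axis=0)
    _, _, vt = np.linalg.svd(arr - centroid)
    return centroid, vt[2]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.clip(n1 @ n2, -1.0, 1.0)))
    return float(np.degrees(np.arccos(c)))


def _in_plane(vec: np.ndarray, normal: np.ndarray) -> bool:
    """True when ``vec`` lies within HBOND_PLANE_ANGLE_MAX of the plane."""
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        return False
    s = abs(float(vec @ normal)) / norm
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0)))) <= HBOND_PLANE_ANGLE_MAX


def _polar_base_atoms(res) -> dict[str, np.ndarray]:
    return {
        n: c for n, c in res.atoms.items()
        if n not in _SUGAR_PHOSPHATE and n[0] in "NO"
    }


# ---------------------------------------------------------------------------
# detection

def _flatten(model: Model):
    """Residues of a model with global 1-based positions, strand concatenation order."""
    out = []
    pos = 0
    for strand in model.strands:
        for res in strand.residues:
            pos += 1
            out.append((pos, res))
    return out


def detect_base_pairs(model: Model) -> list[BasePair]:
    """All detected base-base interactions: canonical pairs plus noncanonical contacts.

    Residues lacking the required atoms are skipped.  Canonical assignments are
    exclusive per base (best mean H-bond distance wins, ties broken towards the
    lexicographically smaller ``(i, j)``); remaining qualifying contacts are
    returned with kind ``noncanonical``.
    """
    flat = [(pos, res) for pos, res in _flatten(model) if res.has_coordinates]
    entries = []
    for pos, res in flat:
        c1 = res.atoms.get("C1'")
        plane = _base_plane(res)
        if c1 is None or plane is None:
            continue
        entries.append((pos, res, c1, plane))
    if len(entries) < 2:
        return []

    tree = cKDTree(np.array([e[2] for e in entries]))
    candidate_idx = tree.query_pairs(C1C1_TARGET + C1C1_TOL)

    canonical_cands = []  # (score, i, j, kind)
    contacts: dict[tuple[int, int], int] = {}
    for a, b in candidate_idx:
        if a > b:
            a, b = b, a
        pos_i, res_i, c1_i, (cen_i, n_i) = entries[a]
        pos_j, res_j, c1_j, (cen_j, n_j) = entries[b]
        d_c1 = float(np.linalg.norm(c1_i - c1_j))
        plane_ang = _plane_angle(n_i, n_j)

        # polar contact count for the noncanonical/multiplet channel
        pol_i = _polar_base_atoms(res_i)
        pol_j = _polar_base_atoms(res_j)
        n_contacts = 0
        for ci in pol_i.values():
            for cj in pol_j.values():
                v = cj - ci
                if (
                    np.linalg.norm(v) < HBOND_MAX
                    and _in_plane(v, n_i) and _in_plane(v, n_j)
                ):
                    n_contacts += 1
        if n_contacts >= 2:
            contacts[(pos_i, pos_j)] = n_contacts

        if not (abs(d_c1 - C1C1_TARGET) <= C1C1_TOL and plane_ang < PLANE_ANGLE_MAX):
            continue
        for (pi, pj), (kind, edges, need) in _CANONICAL_EDGES.items():
            for (ri, rj, flip) in (
                ((pos_i, res_i, n_i), (pos_j, res_j, n_j), False),
                ((pos_j, res_j, n_j), (pos_i, res_i, n_i), True),
            ):
                if ri[1].parent != pi or rj[1].parent != pj:
                    continue
                dists = []
                for a_name, b_name in edges:
                    ca, cb = ri[1].atoms.get(a_name), rj[1].atoms.get(b_name)
                    if ca is None or cb is None:
                        continue
                    v = cb - ca
                    d = float(np.linalg.norm(v))
                    if d < HBOND_MAX and _in_plane(v, ri[2]) and _in_plane(v, rj[2]):
                        dists.append(d)
                if len(dists) >= need:
                    score = sum(dists) / len(dists)
                    canonical_cands.append((score, pos_i, pos_j, kind))

    canonical_cands.sort(key=lambda t: (t[0], t[1], t[2]))
    taken: set[int] = set()
    result: list[BasePair] = []
    chosen: set[tuple[int, int]] = set()
    for score, i, j, kind in canonical_cands:
        if i in taken or j in taken:
            continue
        taken.update((i, j))
        chosen.add((i, j))
        result.append(BasePair(i, j, kind))
    for (i, j), _n in sorted(contacts.items()):
        if (i, j) not in chosen:
            result.append(BasePair(i, j, "noncanonical"))
    result.sort(key=lambda p: (p.i, p.j))
    return result


def detect_canonical_pairs(model: Model) -> list[BasePair]:
    """Canonical subset of :func:`detect_base_pairs` (WC-AU, WC-GC, wobble-GU)."""
    return [p for p in detect_base_pairs(model) if p.canonical]


# ---------------------------------------------------------------------------
# tier assignment

def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def max_noncrossing_subset(pairs: list[tuple[int, int]]) -> set[tuple[int, int]]:
    """Maximum-cardinality non-crossing subset of non-conflicting pairs.

    Positions participate in at most one pair, so an interval dynamic program
    over the compressed paired positions runs with O(1) transitions.
    """
    if not pairs:
        return set()
    points = sorted({x for p in pairs for x in p})
    index = {x: k for k, x in enumerate(points)}
    n = len(points)
    mate = [-1] * n
    for i, j in pairs:
        mate[index[i]] = index[j]
        mate[index[j]] = index[i]

    size = [[0] * (n + 1) for _ in range(n + 1)]  # size[a][b]: points a..b-1
    choice = [[False] * (n + 1) for _ in range(n + 1)]
    for span in range(2, n + 1):
        for a in range(0, n - span + 1):
            b = a + span
            best = size[a + 1][b]
            took = False
            k = mate[a]
            if a < k < b:
                # ties prefer taking the earlier pair (deterministic, and keeps
                # hairpin stems nested when a loop-loop helix has equal size)
                cand = 1 + size[a + 1][k] + size[k + 1][b]
                if cand >= best:
                    best, took = cand, True
            size[a][b] = best
            choice[a][b] = took

    out: set[tuple[int, int]] = set()
    stack = [(0, n)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        if choice[a][b]:
            k = mate[a]
            out.add((points[a], points[k]))
            stack.append((a + 1, k))
            stack.append((k + 1, b))
        else:
            stack.append((a + 1, b))
    return out


def assign_bracket_tiers(pairs: list[BasePair], n_positions: int) -> list[BasePair]:
    """Assign bracket tiers in place: tier 0 nested, pseudoknots above.

    Tier 0 is a maximum-cardinality non-crossing subset of the pair set; the
    remaining pairs go greedily (in (i, j) order) to the lowest tier where they
    cross nothing.  More than four tiers is an error.
    """
    seen: set[int] = set()
    for p in pairs:
        if p.i in seen or p.j in seen or not (1 <= p.i < p.j <= n_positions):
            raise ValueError(f"conflicting or out-of-range pair ({p.i}, {p.j})")
        seen.update((p.i, p.j))
    tier0 = max_noncrossing_subset([p.key() for p in pairs])
    tiers: list[list[tuple[int, int]]] = [sorted(tier0)]
    for p in sorted(pairs, key=BasePair.key):
        if p.key() in tier0:
            p.tier = 0
            continue
        for t in range(1, MAX_TIERS):
            if len(tiers) <= t:
                tiers.append([])
            if not any(_crossing(p.key(), q) for q in tiers[t]):
                tiers[t].append(p.key())
                p.tier = t
                break
        else:
            raise TierError(
                f"pair ({p.i}, {p.j}) needs more than {MAX_TIERS} bracket tiers"
            )
    return pairs


# ---------------------------------------------------------------------------
# encoding

def encode_secondary_structure(
    model: Model, pairs: list[BasePair], missing: dict[str, list[int]] | None = None
) -> ExtendedDotBracket:
    """Render a model as an extended dot-bracket record.

    ``pairs`` are the canonical pairs of the model (tiers are assigned here if
    absent); ``missing`` gives strand-local coordinate-less positions per chain
    (defaults to the residues' own ``has_coordinates`` flags).  Missing
    positions emit ``-`` and must not be paired.
    """
    canonical = [p for p in pairs if p.canonical]
    n = sum(len(s.residues) for s in model.strands)
    if any(p.tier is None for p in canonical):
        assign_bracket_tiers(canonical, n)

    missing_global: set[int] = set()
    offset = 0
    for strand in model.strands:
        local = (
            set(missing[strand.chain_id])
            if missing is not None and strand.chain_id in missing
            else {k + 1 for k, r in enumerate(strand.residues) if not r.has_coordinates}
        )
        missing_global.update(offset + x for x in local)
        offset += len(strand.residues)

    chars = ["."] * n
    for g in missing_global:
        chars[g - 1] = "-"
    for p in canonical:
        if p.i in missing_global or p.j in missing_global:
            raise ValueError(
                f"canonical pair ({p.i}, {p.j}) touches a coordinate-less residue"
            )
        chars[p.i - 1] = OPEN_BY_TIER[p.tier]
        chars[p.j - 1] = CLOSE_BY_TIER[p.tier]

    strands_out: list[Strand] = []
    offset = 0
    for strand in model.strands:
        L = len(strand.residues)
        strands_out.append(
            Strand(
                strand.chain_id,
                "".join(chars[offset:offset + L]),
                strand.sequence,
            )
        )
        offset += L
    ssdb = ExtendedDotBracket(strands_out)
    ssdb.pairs = sorted(Pair(p.i, p.j, p.tier) for p in canonical)
    return ssdb


def annotate_structure(
    structure: AnnotatedStructure, model_index: int = 0
) -> tuple[ExtendedDotBracket, list[BasePair]]:
    """Detect pairs on one model and return its dot-bracket plus all interactions."""
    model = structure.models[model_index]
    all_pairs = detect_base_pairs(model)
    canonical = [p for p in all_pairs if p.canonical]
    n = sum(len(s.residues) for s in model.strands)
    assign_bracket_tiers(canonical, n)
    return encode_secondary_structure(model, canonical), all_pairs
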