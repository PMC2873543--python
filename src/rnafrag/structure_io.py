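"""Reading and writing RNA coordinate files.

A coordinate entry is held as an :class:`AnnotatedStructure`: an ordered list
of models (one per ``MODEL`` record), each containing the nucleic-acid strands
(one strand per chain id), each an ordered 5'->3' list of residues.  Original
author numbering (chain id, residue number, insertion code) is preserved
throughout, so extracted fragments keep the provenance of the deposited file.

Residues are mapped to one-letter codes: unmodified A, C, G, U in capitals;
modified and non-RNA units (DNA, nucleotides with altered bases or sugars) in
small letters named after the closest parent nucleoside; ``n`` when no parent
can be assigned.  Residues that appear in the declared sequence (SEQRES) but
have no atoms in the coordinate section are represented by coordinate-less
placeholder residues, which downstream annotation renders as ``-``.

Parsing and serialization of the PDB format itself are delegated to gemmi.
"""

from __future__ import annotations

import copy
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "Strand",
    "Model",
    "AnnotatedStructure",
    "StructureError",
    "read_structure",
    "detect_missing_residues",
    "write_structure",
    "write_fragment",
    "one_letter_code",
]


class StructureError(ValueError):
    """Unreadable or structurally inconsistent coordinate file."""


# ---------------------------------------------------------------------------
# residue coding

STANDARD_RNA = {"A", "C", "G", "U"}
_DNA = {"DA": "a", "DC": "c", "DG": "g", "DT": "u", "DU": "u", "DI": "g"}
# modified residues -> parent nucleoside, beyond what gemmi's tables resolve
_PARENT_OVERRIDES = {
    "1MA": "a", "2MA": "a", "6MA": "a", "MA6": "a", "MIA": "a", "T6A": "a",
    "A2M": "a", "AMP": "a", "ADP": "a", "ATP": "a",
    "5MC": "c", "OMC": "c", "4OC": "c", "CMP": "c", "CBV": "c",
    "PSU": "u", "5MU": "u", "H2U": "u", "4SU": "u", "OMU": "u", "UR3": "u",
    "UMP": "u", "5BU": "u", "DHU": "u",
    "OMG": "g", "2MG": "g", "M2G": "g", "7MG": "g", "1MG": "g", "G7M": "g",
    "YG": "g", "QUO": "g", "I": "g", "GMP": "g", "GDP": "g", "GTP": "g",
}


def one_letter_code(resname: str) -> tuple[str, str]:
    """Map a residue name to ``(one_letter, parent)``.

    Parent is one of ``A C G U`` or ``"unknown"``; the one-letter code is the
    uppercase parent for unmodified ribonucleotides, the lowercase parent for
    modified or non-RNA analogs, and ``n`` when no parent can be assigned.
    """
    resname = resname.strip().upper()
    if resname in STANDARD_RNA:
        return resname, resname
    if resname in _DNA:
        return _DNA[resname], _DNA[resname].upper()
    if resname in _PARENT_OVERRIDES:
        low = _PARENT_OVERRIDES[resname]
        return low, low.upper()
    info = gemmi.find_tabulated_residue(resname)
    if info is not None:
        code = info.one_letter_code.lower()
        if code == "t":
            code = "u"
        if code in "acgu":
            return code, code.upper()
    return "n", "unknown"


def _is_nucleotide(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_nucleic_acid():
        return True
    names = {a.name for a in res}
    return "C1'" in names and "O4'" in names and ("N9" in names or "N1" in names)


# ---------------------------------------------------------------------------
# data model

@dataclass
class Residue:
    name: str
    one_letter: str
    parent: str
    number: int | None
    icode: str = ""
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    label_seq: int | None = None

    @property
    def has_coordinates(self) -> bool:
        return bool(self.atoms)

    @property
    def modified(self) -> bool:
        return self.one_letter.islower()

    def copy(self) -> "Residue":
        return Residue(
            self.name, self.one_letter, self.parent, self.number, self.icode,
            {k: v.copy() for k, v in self.atoms.items()}, self.label_seq,
        )


@dataclass
class Strand:
    chain_id: str
    residues: list[Residue]
    seqres: list[str] | None = None  # declared full sequence as residue names

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Model:
    number: int
    strands: list[Strand]

    def strand(self, chain_id: str) -> Strand:
        for s in self.strands:
            if s.chain_id == chain_id:
                return s
        raise KeyError(chain_id)


@dataclass
class AnnotatedStructure:
    entry_id: str
    method: str = "other"  # X-ray | NMR | EM | other
    resolution: float | None = None
    deposition_date: _dt.date | None = None
    models: list[Model] = field(default_factory=list)
    other_chains: list[str] = field(default_factory=list)  # non-nucleic chains present

    @property
    def n_models(self) -> int:
        return len(self.models)

    def copy(self) -> "AnnotatedStructure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# reading

def _entry_id_of(info: dict, st: gemmi.Structure, path) -> str:
    title = info.get("_struct.title", "")
    header_id = info.get("_entry.id") or st.name
    # a single-token title extending the (4-char-truncated) header id wins
    if title and " " not in title and (
        not header_id or title.upper().startswith(header_id.upper())
    ):
        return title
    return header_id or Path(str(path)).stem


def _map_method(raw: str | None) -> str:
    if not raw:
        return "other"
    raw = raw.upper()
    if "NMR" in raw:
        return "NMR"
    if "X-RAY" in raw or "DIFFRACTION" in raw and "ELECTRON" not in raw:
        return "X-ray"
    if "MICROSCOPY" in raw or "CRYO" in raw or raw.startswith("EM"):
        return "EM"
    return "other"


def _convert_residue(res: gemmi.Residue) -> Residue:
    letter, parent = one_letter_code(res.name)
    atoms: dict[str, np.ndarray] = {}
    for atom in res:
        if atom.altloc not in ("", "\0", "A"):
            continue
        if atom.name in atoms:
            continue
        atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    return Residue(
        res.name, letter, parent, res.seqid.num, res.seqid.icode.strip(),
        atoms, res.label_seq if res.label_seq else None,
    )


def read_structure(path: str | Path, format: str = "pdb") -> AnnotatedStructure:
    """Read a multi-model RNA coordinate file into an :class:`AnnotatedStructure`.

    Protein, water and ligand chains are excluded from the strands (their
    chain ids are recorded in ``other_chains``); every ``MODEL`` becomes one
    model and all models must share the same strand and residue composition.
    """
    if format != "pdb":
        raise StructureError(f"unsupported format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    st.setup_entities()
    st.assign_label_seq_id()

    seqres_by_subchain: dict[str, list[str]] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            names = [item.split(",")[0] for item in ent.full_sequence]
            for sub in ent.subchains:
                seqres_by_subchain[sub] = names

    info = dict(st.info)
    out = AnnotatedStructure(
        entry_id=_entry_id_of(info, st, path),
        method=_map_method(info.get("_exptl.method")),
        resolution=st.resolution if st.resolution else None,
    )
    date_raw = info.get("_pdbx_database_status.recvd_initial_deposition_date")
    if date_raw:
        try:
            out.deposition_date = _dt.date.fromisoformat(date_raw)
        except ValueError:
            pass

    other: set[str] = set()
    for m_index, gm in enumerate(st):
        strands: list[Strand] = []
        for chain in gm:
            nuc = [r for r in chain if _is_nucleotide(r)]
            if not nuc:
                if any(r.name != "HOH" for r in chain):
                    other.add(chain.name)
                continue
            if len(nuc) < len([r for r in chain if r.name != "HOH"]):
                other.add(chain.name)  # ligands/ions share the chain
            seqres = None
            for r in nuc:
                if r.subchain in seqres_by_subchain:
                    seqres = seqres_by_subchain[r.subchain]
                    break
            strands.append(Strand(chain.name, [_convert_residue(r) for r in nuc], seqres))
        if not strands:
            continue
        out.models.append(Model(m_index + 1, strands))
    out.other_chains = sorted(other)

    if not out.models:
        raise StructureError(f"{path}: no nucleic-acid chain found")
    sig0 = _composition(out.models[0])
    for m in out.models[1:]:
        if _composition(m) != sig0:
            raise StructureError(
                f"{out.entry_id}: model {m.number} differs in residue composition"
            )
    return out


def _composition(model: Model) -> list[tuple[str, tuple[tuple[str, int | None, str], ...]]]:
    return [
        (s.chain_id, tuple((r.name, r.number, r.icode) for r in s.residues))
        for s in model.strands
    ]


# ---------------------------------------------------------------------------
# missing residues

def detect_missing_residues(structure: AnnotatedStructure) -> dict[str, list[int]]:
    """Detect coordinate-less residues and insert placeholders for them.

    A residue is missing when the declared sequence (SEQRES) contains it but
    no atoms were observed, or — without SEQRES — when author numbering within
    a strand jumps by ``k > 1`` (a gap of ``k - 1`` residues of unknown parent).
    Placeholders (``has_coordinates == False``) are inserted into every model;
    the operation is idempotent.  Returns strand-local 1-based missing
    positions per chain id.
    """
    template = structure.models[0]
    missing: dict[str, list[int]] = {}
    new_lists: dict[str, list[Residue]] = {}
    for strand in template.strands:
        observed = [r for r in strand.residues if r.has_coordinates]
        full = None
        if strand.seqres and observed:
            full = _fill_from_seqres(observed, strand.seqres)
        if full is None:
            full = _fill_from_numbering(observed)
        new_lists[strand.chain_id] = full
        missing[strand.chain_id] = [
            k + 1 for k, r in enumerate(full) if not r.has_coordinates
        ]
    for model in structure.models:
        for strand in model.strands:
            template_full = new_lists[strand.chain_id]
            observed = {
                (r.number, r.icode): r for r in strand.residues if r.has_coordinates
            }
            rebuilt = []
            for t in template_full:
                own = observed.get((t.number, t.icode))
                rebuilt.append(own if own is not None and t.has_coordinates else t.copy())
            strand.residues = rebuilt
    return missing


def _fill_from_seqres(
    observed: list[Residue], seqres: list[str]
) -> list[Residue] | None:
    # author numbering that indexes straight into SEQRES beats the purely
    # sequence-based alignment, which is ambiguous around repeats
    numbers = [r.number for r in observed]
    if (
        all(n is not None and not r.icode for n, r in zip(numbers, observed))
        and all(b > a for a, b in zip(numbers, numbers[1:]))
        and all(1 <= n <= len(seqres) for n in numbers)
        and all(r.name == seqres[n - 1] for n, r in zip(numbers, observed))
    ):
        for r in observed:
            r.label_seq = r.number
    if not all(r.label_seq for r in observed):
        return None  # no usable alignment; fall back to the numbering rule
    by_label = {r.label_seq: r for r in observed}
    anchors = sorted(by_label)
    full: list[Residue] = []
    for ls in range(1, len(seqres) + 1):
        if ls in by_label:
            full.append(by_label[ls])
            continue
        letter, parent = one_letter_code(seqres[ls - 1])
        number = _interpolate_number(ls, anchors, by_label)
        full.append(Residue(seqres[ls - 1], letter, parent, number, "", {}, ls))
    return full


def _interpolate_number(ls: int, anchors: list[int], by_label: dict) -> int | None:
    prev = max((a for a in anchors if a < ls), default=None)
    nxt = min((a for a in anchors if a > ls), default=None)
    if prev is not None and nxt is not None:
        rp, rn = by_label[prev], by_label[nxt]
        if rp.number is not None and rn.number is not None and not rn.icode:
            if rn.number - rp.number == nxt - prev:
                return rp.number + (ls - prev)
        return None
    if prev is not None and by_label[prev].number is not None:
        return by_label[prev].number + (ls - prev)
    if nxt is not None and by_label[nxt].number is not None:
        return by_label[nxt].number - (nxt - ls)
    return None


def _fill_from_numbering(observed: list[Residue]) -> list[Residue]:
    full: list[Residue] = []
    for k, res in enumerate(observed):
        if k > 0:
            prev = observed[k - 1]
            if (
                prev.number is not None and res.number is not None
                and not prev.icode and not res.icode
                and res.number - prev.number > 1
            ):
                for num in range(prev.number + 1, res.number):
                    full.append(Residue("N", "n", "unknown", num, "", {}))
        full.append(res)
    return full


# ---------------------------------------------------------------------------
# writing

def _element_of(atom_name: str) -> gemmi.Element:
    core = atom_name.strip("0123456789'\"*")
    if core.startswith(("OP",)):
        return gemmi.Element("O")
    return gemmi.Element(core[:1] if core else "X")


_METHOD_BACK = {
    "X-ray": "X-RAY DIFFRACTION",
    "NMR": "SOLUTION NMR",
    "EM": "ELECTRON MICROSCOPY",
    "other": "OTHER",
}


def _to_gemmi(structure: AnnotatedStructure, model_numbers=None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.entry_id
    st.info["_entry.id"] = structure.entry_id
    # the HEADER id field truncates to 4 characters; keep the full id in TITLE
    st.info["_struct.title"] = structure.entry_id
    st.info["_exptl.method"] = _METHOD_BACK.get(structure.method, "OTHER")
    if structure.deposition_date is not None:
        st.info["_pdbx_database_status.recvd_initial_deposition_date"] = (
            structure.deposition_date.isoformat()
        )
    if structure.resolution is not None:
        st.resolution = structure.resolution
    for model in structure.models:
        if model_numbers is not None and model.number not in model_numbers:
            continue
        gm = gemmi.Model(str(model.number))
        for strand in model.strands:
            chain = gemmi.Chain(strand.chain_id)
            for res in strand.residues:
                if not res.has_coordinates:
                    continue
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(
                    res.number if res.number is not None else 0, res.icode or " "
                )
                for name, xyz in res.atoms.items():
                    at = gemmi.Atom()
                    at.name = name
                    at.element = _element_of(name)
                    at.pos = gemmi.Position(*map(float, xyz))
                    at.occ = 1.0
                    at.b_iso = 0.0
                    gr.add_atom(at)
                chain.add_residue(gr)
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    # declared full sequences drive SEQRES emission
    seqres = {s.chain_id: s.seqres for s in structure.models[0].strands}
    sub_to_chain: dict[str, str] = {}
    for gm in st:
        for chain in gm:
            for res in chain:
                sub_to_chain.setdefault(res.subchain, chain.name)
    for ent in st.entities:
        if ent.entity_type != gemmi.EntityType.Polymer:
            continue
        for sub in ent.subchains:
            chain_id = sub_to_chain.get(sub)
            if chain_id and seqres.get(chain_id):
                ent.full_sequence = list(seqres[chain_id])
    st.assign_label_seq_id()
    return st


def write_structure(
    structure: AnnotatedStructure, path: str | Path | None = None
) -> str:
    """Serialize to PDB text (SEQRES, MODEL/ENDMDL, ATOM/HETATM, TER).

    Author chain ids and residue numbers are preserved; placeholder residues
    without coordinates appear only in SEQRES.
    """
    st = _to_gemmi(structure)
    opts = gemmi.PdbWriteOptions(seqres_records=True)
    text = st.make_pdb_string(opts)
    return text if path is None else _write_text(text, path)


def _write_text(text: str, path: str | Path) -> str:
    Path(path).write_text(text)
    return text


def write_fragment(structure: AnnotatedStructure, hit) -> str:
    """Extract the residues of a search hit as PDB text with original numbering.

    ``hit`` provides ``model_number`` and ``segments`` — an iterable of
    ``(chain_id, start_number, end_number)`` in author numbering.  Referencing
    a residue without coordinates is an error.
    """
    model = next(
        (m for m in structure.models if m.number == hit.model_number), None
    )
    if model is None:
        raise StructureError(f"model {hit.model_number} not present")
    frag = AnnotatedStructure(
        structure.entry_id, structure.method, structure.resolution,
        structure.deposition_date,
    )
    strands: list[Strand] = []
    for seg in hit.segments:
        chain_id, start, end = (
            (seg.chain_id, seg.start, seg.end) if hasattr(seg, "chain_id") else seg
        )
        if start is None or end is None:
            raise StructureError(
                f"segment on chain {chain_id} references residues without "
                "author numbers (missing from the coordinate section)"
            )
        strand = model.strand(chain_id)
        picked = [
            r for r in strand.residues
            if r.number is not None and start <= r.number <= end
        ]
        if not picked:
            raise StructureError(f"no residues {chain_id}:{start}-{end}")
        for r in picked:
            if not r.has_coordinates:
                raise StructureError(
                    f"residue {chain_id}:{r.number} has no coordinates"
                )
        existing = next((s for s in strands if s.chain_id == chain_id), None)
        if existing is not None:
            existing.residues.extend(r.copy() for r in picked)
        else:
            strands.append(Strand(chain_id, [r.copy() for r in picked], None))
    frag.models = [Model(1, strands)]
    st = _to_gemmi(frag)
    return st.make_pdb_string(gemmi.PdbWriteOptions(seqres_records=False))
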