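"""Structure I/O and normalization.

Reads PDB/mmCIF files (via gemmi) into a small immutable-ish object model:
polymer chains with per-residue heavy atoms, Calpha traces, the B-factor
field (temperature factor for experimental entries, per-residue confidence
for predictor output), author residue numbering and file-level helix
annotation. Only model 1 of multi-model files is kept and alternate
locations are resolved deterministically (highest occupancy, ties broken
alphabetically), so every downstream measurement is single-conformer and
reproducible byte-for-byte.

Author numbering plus insertion code is the public coordinate system for
all junction points and reports; internal 0-based indices never appear in
outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    ChainLookupError,
    EmptyStructureError,
    FormatOverflowError,
    InputOutputError,
    StructureParseError,
)

UNKNOWN = "unknown"

#: residue names treated as water regardless of entity classification
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom after altloc resolution.

    ``bfac`` carries whatever the file's B-factor column holds: a
    temperature factor for experimental entries or a 0-100 per-residue
    confidence for predictor models.
    """

    name: str
    element: str
    pos: tuple[float, float, float]
    bfac: float = 0.0
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not all(math.isfinite(x) for x in self.pos):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue keyed by author number + insertion code."""

    auth_num: int
    icode: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)
    is_polymer: bool = True

    @property
    def auth_id(self) -> str:
        return f"{self.auth_num}{self.icode.strip()}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.name)
        if info is not None:
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
        return "X"


@dataclass
class Chain:
    """Ordered polymer chain, N to C."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def seq(self) -> str:
        return "".join(r.one_letter for r in self.residues if r.is_polymer)

    @property
    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_auth(self, auth_num: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.auth_num == auth_num and r.icode.strip() == icode.strip():
                return r
        return None

    def index_of_auth(self, auth_num: int, icode: str = "") -> int | None:
        for i, r in enumerate(self.residues):
            if r.auth_num == auth_num and r.icode.strip() == icode.strip():
                return i
        return None

    def ca_coords(self) -> list[np.ndarray | None]:
        """Per-residue Calpha coordinates in chain order; None where absent."""
        return [r.ca.xyz if r.ca is not None else None for r in self.residues]


@dataclass
class StructureMetadata:
    """Entry-level metadata backing the curation filters.

    The deposited oligomer chain count comes from the file's assembly
    records (REMARK 350 / pdbx_struct_assembly); when no assembly is
    recorded it stays "unknown" rather than being assumed monomeric.
    """

    title: str = UNKNOWN
    keywords: list[str] = field(default_factory=list)
    deposited_oligomer_chain_count: int | str = UNKNOWN
    source_organism: str = UNKNOWN


@dataclass(frozen=True)
class HelixSegment:
    """A contiguous helical span within one chain, by author numbering."""

    chain_id: str
    start_auth: int
    end_auth: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("helix segment length must be >= 1")


@dataclass
class StructureModel:
    """One structure entry: chains + metadata + file helix annotation."""

    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    metadata: StructureMetadata = field(default_factory=StructureMetadata)
    #: helix spans read from the file's own secondary-structure records
    annotated_helix_spans: list[HelixSegment] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainLookupError(
            f"chain {chain_id!r} not found in entry {self.entry_id!r} "
            f"(available: {[c.chain_id for c in self.chains]})"
        )

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_residues]


# ---------------------------------------------------------------------------
# reading


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per atom name: highest occupancy, ties alphabetical."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = sorted(by_name[name], key=lambda a: (-a.occupancy, a.altloc))
        out.append(replace(group[0], altloc=""))
    return out


def _residue_is_polymer(res: gemmi.Residue) -> bool:
    if res.name in _WATER_NAMES:
        return False
    if res.entity_type == gemmi.EntityType.Polymer:
        return True
    if res.entity_type in (gemmi.EntityType.Water, gemmi.EntityType.NonPolymer,
                           gemmi.EntityType.Branched):
        return False
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info is not None and (info.is_amino_acid() or info.is_nucleic_acid()))


def _extract_metadata(st: gemmi.Structure) -> StructureMetadata:
    info = st.info
    title = info["_struct.title"].strip() if "_struct.title" in info else UNKNOWN
    kw_raw = ""
    for key in ("_struct_keywords.text", "_struct_keywords.pdbx_keywords"):
        if key in info and info[key].strip():
            kw_raw = info[key]
            break
    keywords = [k.strip() for k in kw_raw.split(",") if k.strip()]
    oligomer: int | str = UNKNOWN
    if st.assemblies:
        asm = st.assemblies[0]
        n = 0
        for gen in asm.generators:
            n += max(1, len(gen.operators)) * len(gen.chains)
        if n > 0:
            oligomer = n
    organism = UNKNOWN
    for ent in st.entities:
        # mmCIF entity source; PDB SOURCE records are not mapped by gemmi
        if getattr(ent, "sifts_unp_acc", None):
            break
    return StructureMetadata(
        title=title or UNKNOWN,
        keywords=keywords,
        deposited_oligomer_chain_count=oligomer,
        source_organism=organism,
    )


def _extract_helix_annotation(st: gemmi.Structure) -> list[HelixSegment]:
    spans = []
    for h in st.helices:
        start, end = h.start, h.end
        if start.chain_name != end.chain_name:
            continue  # malformed record; cross-chain helix is meaningless here
        lo, hi = start.res_id.seqid.num, end.res_id.seqid.num
        if hi < lo:
            lo, hi = hi, lo
        spans.append(HelixSegment(start.chain_name, lo, hi, hi - lo + 1))
    return spans


def read_structure(path: str | os.PathLike, fmt: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps only model 1, resolves altlocs (highest occupancy, ties to the
    alphabetically first indicator), retains hydrogens as read, and
    populates metadata where the file provides it.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputOutputError(f"structure file not found: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(path)
        else:
            raise InputOutputError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    return _from_gemmi(st)


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{st.name or 'structure'}: no models")
    model = st[0]  # model 1 only
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    pos=(a.pos.x, a.pos.y, a.pos.z),
                    bfac=a.b_iso,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                    occupancy=a.occ,
                )
                for a in gres
            ]
            residues.append(
                Residue(
                    auth_num=gres.seqid.num,
                    icode=gres.seqid.icode.strip(),
                    name=gres.name,
                    atoms=_resolve_altlocs(atoms),
                    is_polymer=_residue_is_polymer(gres),
                )
            )
        if residues:
            chains.append(Chain(chain_id=gch.name, residues=residues))
    info = st.info
    entry_id = (info["_entry.id"].strip() if "_entry.id" in info else "") \
        or st.name or UNKNOWN
    out = StructureModel(
        entry_id=entry_id,
        chains=chains,
        metadata=_extract_metadata(st),
        annotated_helix_spans=_extract_helix_annotation(st),
    )
    if not out.polymer_chains:
        raise EmptyStructureError(
            f"{out.entry_id}: no polymer chains after parsing"
        )
    return out


# ---------------------------------------------------------------------------
# normalization


def strip_nonpolymer(s: StructureModel) -> StructureModel:
    """Remove waters and non-polymer het residues; polymer untouched.

    Idempotent; chains left empty are dropped. An all-het input yields a
    model with zero chains, which downstream screening flags rather than
    erroring here.
    """
    chains = []
    for c in s.chains:
        kept = [r for r in c.residues if r.is_polymer and r.name not in _WATER_NAMES]
        if kept:
            chains.append(Chain(chain_id=c.chain_id, residues=kept))
    return StructureModel(
        entry_id=s.entry_id,
        chains=chains,
        metadata=s.metadata,
        annotated_helix_spans=list(s.annotated_helix_spans),
    )


def annotated_helices(s: StructureModel, chain_id: str) -> list[HelixSegment]:
    """Helix spans for one chain from the file's own annotation.

    Spans are clipped to residues actually present in the coordinates;
    annotation referencing entirely absent residues is dropped. Returns an
    empty list when the file carries no annotation — callers then fall back
    to geometric assignment.
    """
    chain = s.chain(chain_id)
    present = sorted(r.auth_num for r in chain.polymer_residues)
    present_set = set(present)
    segs: list[HelixSegment] = []
    for span in s.annotated_helix_spans:
        if span.chain_id != chain_id:
            continue
        inside = [n for n in present if span.start_auth <= n <= span.end_auth]
        if not inside:
            continue
        lo, hi = inside[0], inside[-1]
        i0, i1 = present.index(lo), present.index(hi)
        segs.append(HelixSegment(chain_id, lo, hi, i1 - i0 + 1))
    segs.sort(key=lambda h: h.start_auth)
    # guard against pathological overlapping annotation
    merged: list[HelixSegment] = []
    for h in segs:
        if merged and h.start_auth <= merged[-1].end_auth:
            prev = merged[-1]
            hi = max(prev.end_auth, h.end_auth)
            n_in = len([n for n in present_set if prev.start_auth <= n <= hi])
            merged[-1] = HelixSegment(chain_id, prev.start_auth, hi, n_in)
        else:
            merged.append(h)
    return merged


# ---------------------------------------------------------------------------
# writing


def to_gemmi(s: StructureModel) -> gemmi.Structure:
    """Rebuild a gemmi Structure (model 1, resolved altlocs, annotations)."""
    st = gemmi.Structure()
    st.name = s.entry_id
    if s.entry_id and s.entry_id != UNKNOWN:
        st.info["_entry.id"] = s.entry_id
    if s.metadata.title != UNKNOWN:
        st.info["_struct.title"] = s.metadata.title
    if s.metadata.keywords:
        st.info["_struct_keywords.text"] = ", ".join(s.metadata.keywords)
    model = gemmi.Model("1")
    for c in s.chains:
        gch = gemmi.Chain(c.chain_id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.auth_num, r.icode if r.icode else " ")
            gres.het_flag = "A" if r.is_polymer else "H"
            for a in r.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.pos)
                gat.occ = a.occupancy
                gat.b_iso = a.bfac
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    for span in s.annotated_helix_spans:
        try:
            chain = s.chain(span.chain_id)
        except ChainLookupError:
            continue
        r0 = chain.residue_by_auth(span.start_auth)
        r1 = chain.residue_by_auth(span.end_auth)
        if r0 is None or r1 is None:
            continue
        h = gemmi.Helix()
        h.start = gemmi.AtomAddress(span.chain_id, gemmi.SeqId(span.start_auth, " "),
                                    r0.name, "")
        h.end = gemmi.AtomAddress(span.chain_id, gemmi.SeqId(span.end_auth, " "),
                                  r1.name, "")
        h.length = span.length
        st.helices.append(h)
    st.setup_entities()
    return st


def write_structure(s: StructureModel, path: str | os.PathLike, fmt: str = "auto") -> None:
    """Write PDB or mmCIF; round-trips ids, numbering and coordinates.

    PDB is fixed-width: coordinates survive to 1e-3 Angstrom and residue
    numbers above 9999 raise :class:`FormatOverflowError` (use mmCIF).
    """
    path = os.fspath(path)
    if not s.chains:
        raise EmptyStructureError(f"{s.entry_id}: refusing to write empty structure")
    if fmt == "auto":
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if fmt == "pdb":
        for c in s.chains:
            for r in c.residues:
                if r.auth_num > 9999 or r.auth_num < -999:
                    raise FormatOverflowError(
                        f"residue {r.auth_num} in chain {c.chain_id} does not fit "
                        "the fixed-width PDB dialect; write mmCIF instead"
                    )
    st = to_gemmi(s)
    try:
        if fmt == "pdb":
            st.write_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st.make_mmcif_document().write_file(path)
        else:
            raise InputOutputError(f"unknown structure format {fmt!r}")
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
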