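"""ICL3 chimera design.

A fusion construct replaces part of the receptor's third intracellular
loop (ICL3, between TM5 and TM6) with a tag domain. The junctions are
named by the receptor's author numbering: the *entry* point is the last
retained receptor residue on the TM5 side and the *exit* point the first
retained residue on the TM6 side, so inserting a tag "in place of
residues 235-244" means entry 234 and exit 245. The designer enumerates
an entry x exit matrix of constructs (conventionally 5 x 5 flanking the
loop), splices the chimeric sequences, applies optional tag point
mutations (e.g. a rationally engineered R72S), and writes FASTA whose
headers are self-describing enough to recover the junctions.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    EmptyDesignError,
    JunctionOrderError,
    MutationError,
    NumberingError,
    ValidationError,
)

log = logging.getLogger(__name__)

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class NumberedSequence:
    """One-letter sequence with contiguous author numbering.

    Residue k (0-based) carries author number ``first_auth_num + k``;
    gapped numbering is rejected by construction.
    """

    id: str
    sequence: str
    first_auth_num: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID_AA
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-amino-acid letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def last_auth_num(self) -> int:
        return self.first_auth_num + len(self.sequence) - 1

    def index_of(self, auth_num: int) -> int:
        if not self.first_auth_num <= auth_num <= self.last_auth_num:
            raise NumberingError(
                f"residue {auth_num} outside {self.id!r} numbering "
                f"{self.first_auth_num}-{self.last_auth_num}"
            )
        return auth_num - self.first_auth_num

    def residue_at(self, auth_num: int) -> str:
        return self.sequence[self.index_of(auth_num)]


@dataclass(frozen=True)
class FusionSpec:
    """Design space: receptor, tag, candidate junctions, tag mutations."""

    receptor: NumberedSequence
    tag: NumberedSequence
    entry_candidates: tuple[int, ...]
    exit_candidates: tuple[int, ...]
    tag_mutations: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.entry_candidates or not self.exit_candidates:
            raise ValidationError("entry and exit candidate lists must be non-empty")
        for num in (*self.entry_candidates, *self.exit_candidates):
            self.receptor.index_of(num)  # raises NumberingError if out of range


@dataclass(frozen=True)
class FusionConstruct:
    """One spliced chimera.

    ``junction_n`` / ``junction_c`` are 1-based positions within the
    chimera: the last receptor residue of the N-segment and the first
    receptor residue of the C-segment. ``deleted_span`` is the receptor
    author-number range removed (empty when exit = entry + 1).
    """

    name: str
    sequence: str
    junction_n: int
    junction_c: int
    deleted_span: tuple[int, int] | None
    entry: int
    exit: int
    receptor_id: str
    tag_id: str

    @property
    def tag_span(self) -> tuple[int, int] | None:
        """Chimera positions occupied by the tag (1-based, inclusive)."""
        if self.junction_c == self.junction_n + 1:
            return None
        return (self.junction_n + 1, self.junction_c - 1)


def splice_sequence(receptor: NumberedSequence, tag: NumberedSequence | str,
                    entry: int, exit: int,
                    mutations: list[tuple[int, str]] | None = None) -> FusionConstruct:
    """Splice tag between receptor entry and exit points.

    chimera = receptor[first..entry] + tag + receptor[exit..last]; the
    receptor residues strictly between entry and exit are deleted.
    Mutations address tag author numbering and each changes exactly one
    tag position.
    """
    if isinstance(tag, str):
        tag = NumberedSequence(id="tag", sequence=tag)
    if entry >= exit:
        raise JunctionOrderError(f"entry {entry} must precede exit {exit}")
    i_entry = receptor.index_of(entry)
    i_exit = receptor.index_of(exit)

    tag_seq = list(tag.sequence)
    for pos, new in (mutations or []):
        idx = tag.index_of(pos)  # NumberingError for nonexistent position
        if len(new) != 1 or new.upper() not in _VALID_AA:
            raise MutationError(f"bad replacement residue {new!r} at tag position {pos}")
        if tag_seq[idx] == new.upper():
            raise MutationError(
                f"tag position {pos} already {new.upper()}; mutation is a no-op"
            )
        tag_seq[idx] = new.upper()
    tag_str = "".join(tag_seq)

    n_segment = receptor.sequence[: i_entry + 1]
    c_segment = receptor.sequence[i_exit:]
    chimera = n_segment + tag_str + c_segment
    deleted = (entry + 1, exit - 1) if exit > entry + 1 else None
    return FusionConstruct(
        name=f"{receptor.id}_{tag.id}_e{entry}_x{exit}",
        sequence=chimera,
        junction_n=len(n_segment),
        junction_c=len(n_segment) + len(tag_str) + 1,
        deleted_span=deleted,
        entry=entry,
        exit=exit,
        receptor_id=receptor.id,
        tag_id=tag.id,
    )


def enumerate_constructs(spec: FusionSpec) -> list[FusionConstruct]:
    """One construct per valid (entry, exit) pair, entry-major order.

    Pairs with entry >= exit are skipped (and logged); an all-invalid
    design is an error.
    """
    constructs: list[FusionConstruct] = []
    skipped = 0
    for entry in sorted(spec.entry_candidates):
        for exit in sorted(spec.exit_candidates):
            if entry >= exit:
                skipped += 1
                continue
            constructs.append(
                splice_sequence(spec.receptor, spec.tag, entry, exit,
                                mutations=list(spec.tag_mutations))
            )
    if skipped:
        log.info("skipped %d invalid (entry >= exit) junction pairs", skipped)
    if not constructs:
        raise EmptyDesignError("every (entry, exit) pair has entry >= exit")
    return constructs


def default_junction_candidates(icl3_start: int, icl3_end: int,
                                n_entries: int = 5, n_exits: int = 5
                                ) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Candidate entries/exits flanking a declared ICL3 span.

    Entries are the ``n_entries`` residues ending just before the span
    (ascending); exits the ``n_exits`` residues starting just after it.
    For a span 235-244 the defaults give entries 230..234 and exits
    245..249, so the span-replacing control (entry 234, exit 245) is in
    the matrix.
    """
    if icl3_start > icl3_end:
        raise ValidationError("ICL3 span start must be <= end")
    entries = tuple(range(icl3_start - n_entries, icl3_start))
    exits = tuple(range(icl3_end + 1, icl3_end + 1 + n_exits))
    return entries, exits


# ---------------------------------------------------------------------------
# FASTA I/O


def read_numbered_fasta(path: str | os.PathLike, first_auth_num: int = 1,
                        seq_id: str | None = None) -> NumberedSequence:
    """Read the first record of a FASTA file as a numbered sequence."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    rec = records[0]
    return NumberedSequence(
        id=seq_id or rec.id,
        sequence=str(rec.seq),
        first_auth_num=first_auth_num,
    )


def write_constructs_fasta(constructs: list[FusionConstruct],
                           path: str | os.PathLike) -> None:
    """Write constructs as FASTA with self-describing junction headers.

    Header carries entry/exit points, the tag span within the chimera and
    the deleted receptor span, so the design is recoverable from the file
    alone. Sequences wrap at 60 columns.
    """
    if not constructs:
        raise ValidationError("no constructs to write")
    names = [c.name for c in constructs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate construct names: {dupes}")
    records = []
    for c in constructs:
        if "X" in c.sequence:
            log.warning("construct %s contains 'X' residues; written verbatim", c.name)
        tag_span = c.tag_span
        deleted = f"{c.deleted_span[0]}-{c.deleted_span[1]}" if c.deleted_span else "none"
        desc = (f"entry={c.entry} exit={c.exit} "
                f"tag_span={tag_span[0]}-{tag_span[1] if tag_span else 0}"
                if tag_span else f"entry={c.entry} exit={c.exit} tag_span=none")
        desc += f" deleted={deleted}"
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=desc))
    SeqIO.write(records, os.fspath(path), "fasta")


_HEADER_RE = re.compile(r"entry=(\d+) exit=(\d+)")


def parse_construct_header(description: str) -> tuple[int, int]:
    """Recover (entry, exit) from a construct FASTA description."""
    m = _HEADER_RE.search(description)
    if not m:
        raise ValidationError(f"not a construct header: {description!r}")
    return int(m.group(1)), int(m.group(2))


def constructs_manifest(constructs: list[FusionConstruct]) -> "pd.DataFrame":
    """Tabular manifest of a design (for the TSV the CLI writes)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "name": c.name,
            "receptor": c.receptor_id,
            "tag": c.tag_id,
            "entry": c.entry,
            "exit": c.exit,
            "junction_n": c.junction_n,
            "junction_c": c.junction_c,
            "deleted_span": (f"{c.deleted_span[0]}-{c.deleted_span[1]}"
                             if c.deleted_span else ""),
            "length": len(c.sequence),
        }
        for c in constructs
    ])
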