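"""Corpus screening for fusion-tag candidates.

Runs the mining pipeline over a set of structure files: strip waters and
ligands, retrieve helices (file annotation where available, Calpha
distance geometry otherwise), gate each chain on terminal-helix length,
terminal offset, end-to-end separation and inter-axis angle, then rank
the survivors with the continuous geometry score. Entry-level curation
concerns — membrane/designed keywords, deposited oligomeric state,
thermophile provenance, known binding partners — are carried as flags and
annotations rather than silent drops: unknown metadata is reported as
unknown, never guessed.

Every chain of every readable file appears exactly once in the report,
and a record's pass/fail is reproducible from its stored geometry plus
the stored criteria, so the TSV output is self-contained.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .errors import ConfigError, EmptyStructureError, HelixTagError
from .helix_geometry import (
    ScoreParams,
    SseParams,
    TerminalHelixGeometry,
    assign_helices_geometric,
    geometry_score,
    measure_terminal_geometry,
)
from .structure_model import (
    UNKNOWN,
    StructureMetadata,
    StructureModel,
    annotated_helices,
    read_structure,
    strip_nonpolymer,
)

log = logging.getLogger(__name__)

PASS, FAIL = "pass", "fail"

#: criteria every record carries a flag for, in report column order
FLAG_NAMES = (
    "min_helix_len",
    "terminal_offset",
    "separation",
    "angle",
    "excluded_keyword",
    "oligomer",
    "single_polymer_chain",
)


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the geometric screen plus curation keyword list.

    Geometry defaults: terminal helices of at least 8 residues, each
    within 5 residues of its chain terminus, end-to-end separation within
    10 +/- 8 Angstrom, inter-axis angle at least 140 degrees (close to
    antiparallel). The angle floor and separation window are explicit
    because a pure-threshold screen must be reproducible; both are
    overridable and echoed into every report.
    """

    min_helix_len: int = 8
    max_terminal_offset: int = 5
    target_separation: float = 10.0
    separation_halfwidth: float = 8.0
    min_angle: float = 140.0
    require_single_polymer_chain: bool = False
    exclude_keywords: tuple[str, ...] = ("membrane", "micelle", "de novo", "designed")

    def __post_init__(self) -> None:
        if min(self.min_helix_len, self.max_terminal_offset) < 0:
            raise ConfigError("residue-count thresholds must be non-negative")
        if min(self.target_separation, self.separation_halfwidth) <= 0:
            raise ConfigError("separation thresholds must be positive")
        if not 0 < self.min_angle < 180:
            raise ConfigError("min_angle must be in (0, 180)")
        object.__setattr__(
            self, "exclude_keywords",
            tuple(k.lower() for k in self.exclude_keywords),
        )

    @property
    def score_params(self) -> ScoreParams:
        return ScoreParams(d0=self.target_separation,
                           delta_d=self.separation_halfwidth,
                           theta_min=90.0)


@dataclass
class CandidateRecord:
    """One chain's screen outcome: flags, geometry, score, annotations."""

    entry_id: str
    chain_id: str
    pass_flags: dict[str, str] = field(default_factory=dict)
    geometry: TerminalHelixGeometry | None = None
    score: float | None = None
    helix_source: str = UNKNOWN  # "annotation" or "geometric"
    reason: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def geometry_pass(self) -> bool:
        return all(self.pass_flags.get(k) == PASS
                   for k in ("min_helix_len", "terminal_offset", "separation", "angle"))

    @property
    def all_pass(self) -> bool:
        """Hard all-clear: every flag pass, none unknown-failing.

        Unknown metadata does not veto a candidate (it is a curation
        prompt), but an explicit fail on any flag does.
        """
        return (self.geometry_pass
                and all(self.pass_flags.get(k) != FAIL for k in FLAG_NAMES))


@dataclass
class ScreenReport:
    """Deterministically sorted screen outcome over a corpus."""

    criteria: ScreenCriteria
    records: list[CandidateRecord]
    n_files: int = 0
    n_unreadable: int = 0
    failure_counts: dict[str, int] = field(default_factory=dict)

    def sort(self) -> None:
        self.records.sort(
            key=lambda r: (-(r.score if r.score is not None else -1.0),
                           r.entry_id, r.chain_id)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            g = r.geometry
            rows.append({
                "entry_id": r.entry_id,
                "chain_id": r.chain_id,
                "score": round(r.score, 6) if r.score is not None else "",
                **{f"flag_{k}": r.pass_flags.get(k, UNKNOWN) for k in FLAG_NAMES},
                "helix_source": r.helix_source,
                "reason": r.reason or "",
                "n_helix_len": g.n_helix.length if g else "",
                "c_helix_len": g.c_helix.length if g else "",
                "n_offset": g.n_offset if g else "",
                "c_offset": g.c_offset if g else "",
                "separation_A": round(g.separation, 3) if g else "",
                "angle_deg": round(g.angle, 3) if g else "",
                "thermophile": r.annotations.get("thermophile", UNKNOWN),
                "known_binder": r.annotations.get("known_binder", UNKNOWN),
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    def to_text(self) -> str:
        c = self.criteria
        header = [
            f"# helixtag screen v{__version__}",
            f"# criteria: min_helix_len={c.min_helix_len} "
            f"max_terminal_offset={c.max_terminal_offset} "
            f"target_separation={c.target_separation} "
            f"separation_halfwidth={c.separation_halfwidth} "
            f"min_angle={c.min_angle} "
            f"require_single_polymer_chain={c.require_single_polymer_chain} "
            f"exclude_keywords={','.join(c.exclude_keywords)}",
            f"# input_files={self.n_files} unreadable={self.n_unreadable}",
            f"# failure_counts: " + " ".join(
                f"{k}={v}" for k, v in sorted(self.failure_counts.items())
            ),
        ]
        frame = self.to_frame()
        body = frame.to_csv(sep="\t", index=False) if len(frame) else ""
        return "\n".join(header) + "\n" + body


# ---------------------------------------------------------------------------
# per-chain screening


def _flag(ok: bool) -> str:
    return PASS if ok else FAIL


def screen_chain(s: StructureModel, chain_id: str, crit: ScreenCriteria,
                 sse: SseParams = SseParams(), anchors: str = "terminal") -> CandidateRecord:
    """Screen one chain: strip, retrieve helices, gate, score.

    All gates are evaluated whenever computable — a chain failing the
    length gate still reports its offset/separation/angle outcomes — so
    the report explains every rejection, not just the first.
    """
    stripped = strip_nonpolymer(s)
    rec = CandidateRecord(entry_id=s.entry_id, chain_id=chain_id)
    rec.pass_flags = {k: UNKNOWN for k in FLAG_NAMES}
    n_poly = len(stripped.polymer_chains)
    if crit.require_single_polymer_chain:
        rec.pass_flags["single_polymer_chain"] = _flag(n_poly == 1)
    else:
        rec.pass_flags["single_polymer_chain"] = PASS

    try:
        chain = stripped.chain(chain_id)
    except HelixTagError:
        rec.reason = "empty_after_strip"
        for k in ("min_helix_len", "terminal_offset", "separation", "angle"):
            rec.pass_flags[k] = FAIL
        return rec

    helices = annotated_helices(stripped, chain_id)
    if helices:
        rec.helix_source = "annotation"
    else:
        helices = assign_helices_geometric(chain, sse)
        rec.helix_source = "geometric"

    if len(helices) < 2:
        rec.reason = "single_helix"
        for k in ("min_helix_len", "terminal_offset", "separation", "angle"):
            rec.pass_flags[k] = FAIL
        return rec

    geom = measure_terminal_geometry(chain, helices, anchors=anchors)
    if geom is None:
        rec.reason = "degenerate_helices"
        for k in ("min_helix_len", "terminal_offset", "separation", "angle"):
            rec.pass_flags[k] = FAIL
        return rec

    rec.geometry = geom
    rec.pass_flags["min_helix_len"] = _flag(
        geom.n_helix.length >= crit.min_helix_len
        and geom.c_helix.length >= crit.min_helix_len)
    rec.pass_flags["terminal_offset"] = _flag(
        geom.n_offset <= crit.max_terminal_offset
        and geom.c_offset <= crit.max_terminal_offset)
    rec.pass_flags["separation"] = _flag(
        abs(geom.separation - crit.target_separation) <= crit.separation_halfwidth)
    rec.pass_flags["angle"] = _flag(geom.angle >= crit.min_angle)

    if rec.geometry_pass:
        rec.score = geometry_score(geom.separation, geom.angle, crit.score_params)
    else:
        failed = [k for k in ("min_helix_len", "terminal_offset", "separation", "angle")
                  if rec.pass_flags[k] == FAIL]
        rec.reason = ",".join(failed)
    return rec


def apply_metadata_filters(rec: CandidateRecord, meta: StructureMetadata,
                           crit: ScreenCriteria,
                           annotations: dict[str, dict[str, str]] | None = None
                           ) -> CandidateRecord:
    """Set the curation flags from entry metadata and user annotations.

    Keyword hits in the title or keyword list fail the keyword flag; a
    deposited assembly with more than one chain fails the oligomer flag;
    missing metadata leaves the flag "unknown". Thermophile / known-binder
    annotations are merged from the optional user table — the screen
    itself never infers them.
    """
    out = rec  # records are per-chain and owned by the caller
    text_fields = [meta.title.lower()] + [k.lower() for k in meta.keywords]
    known_text = any(t and t != UNKNOWN for t in text_fields)
    if known_text:
        hit = any(kw in t for kw in crit.exclude_keywords for t in text_fields)
        out.pass_flags["excluded_keyword"] = _flag(not hit)
    else:
        out.pass_flags["excluded_keyword"] = UNKNOWN

    count = meta.deposited_oligomer_chain_count
    if isinstance(count, int):
        out.pass_flags["oligomer"] = _flag(count <= 1)
    else:
        out.pass_flags["oligomer"] = UNKNOWN

    ann = (annotations or {}).get(out.entry_id, {})
    out.annotations.setdefault("thermophile", ann.get("thermophile", UNKNOWN))
    out.annotations.setdefault("known_binder", ann.get("known_binder", UNKNOWN))
    if out.reason is None and not out.all_pass:
        failed = [k for k in FLAG_NAMES if out.pass_flags.get(k) == FAIL]
        out.reason = ",".join(failed)
    return out


def load_annotations(path: str | os.PathLike) -> dict[str, dict[str, str]]:
    """Read the optional TSV of per-entry curation annotations.

    Columns: entry_id, thermophile, known_binder (values yes/no/unknown).
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise ConfigError(f"cannot read annotation table {path}: {exc}") from exc
    required = {"entry_id", "thermophile", "known_binder"}
    if not required.issubset(frame.columns):
        raise ConfigError(
            f"annotation table {path} missing columns "
            f"{sorted(required - set(frame.columns))}"
        )
    valid = {"yes", "no", UNKNOWN}
    table: dict[str, dict[str, str]] = {}
    for _, row in frame.iterrows():
        for col in ("thermophile", "known_binder"):
            val = str(row[col]).strip().lower()
            if val not in valid:
                raise ConfigError(
                    f"annotation table {path}: bad value {row[col]!r} in {col} "
                    f"(expected yes/no/unknown)"
                )
        table[str(row["entry_id"])] = {
            "thermophile": str(row["thermophile"]).strip().lower(),
            "known_binder": str(row["known_binder"]).strip().lower(),
        }
    return table


# ---------------------------------------------------------------------------
# corpus screening


def screen_corpus(paths: list[str | os.PathLike], crit: ScreenCriteria = ScreenCriteria(),
                  annotations: dict[str, dict[str, str]] | None = None,
                  sse: SseParams = SseParams(), anchors: str = "terminal") -> ScreenReport:
    """Screen every polymer chain in every readable file.

    Unreadable files are logged and counted, never fatal; zero readable
    files is an error. Output ordering is deterministic (score descending,
    then entry id, then chain id) and independent of input file order.
    """
    report = ScreenReport(criteria=crit, records=[], n_files=len(paths))
    readable = 0
    for path in sorted(os.fspath(p) for p in paths):
        try:
            model = read_structure(path)
        except HelixTagError as exc:
            log.warning("skipping %s: %s", path, exc)
            report.n_unreadable += 1
            continue
        readable += 1
        for chain in model.polymer_chains:
            rec = screen_chain(model, chain.chain_id, crit, sse=sse, anchors=anchors)
            rec = apply_metadata_filters(rec, model.metadata, crit, annotations)
            report.records.append(rec)
    if readable == 0:
        raise EmptyStructureError("no readable structure files in corpus")
    for rec in report.records:
        if not rec.all_pass:
            for k in FLAG_NAMES:
                if rec.pass_flags.get(k) == FAIL:
                    report.failure_counts[k] = report.failure_counts.get(k, 0) + 1
    report.sort()
    return report
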