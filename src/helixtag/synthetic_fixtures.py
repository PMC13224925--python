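"""Idealized structures with exactly known geometry.

Every measurement in the pipeline is testable without downloading real
entries: this module builds Calpha traces on ideal alpha-helical curves
(1.5 Angstrom rise, 100 degrees twist and 2.3 Angstrom radius per
residue — textbook values chosen so axis fits and distance windows have
closed-form expected values, not to model any particular protein),
assembles them into terminal-helix hairpins with declared inter-axis
angle and exact end-to-end anchor separation, into mock predicted fusion
models with controllable junction helicity / confidence / planted
clashes, and into seeded screening corpora of planted positives and
single-defect negatives. Each generated file comes with a manifest row
holding the ground truth the tests assert against.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .candidate_screen import ScreenCriteria
from .errors import FixtureError
from .fusion_design import FusionConstruct
from .helix_geometry import geometry_score
from .structure_model import (
    AtomRecord,
    Chain,
    HelixSegment,
    Residue,
    StructureMetadata,
    StructureModel,
    write_structure,
)

EXTENDED_RISE = 3.8  # Angstrom between consecutive Calpha in an extended strand


@dataclass(frozen=True)
class HelixParams:
    """Ideal alpha-helix parameters."""

    n_res: int
    rise: float = 1.5
    twist: float = 100.0
    radius: float = 2.3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_res < 1:
            raise FixtureError("helix needs >= 1 residue")
        norm = math.sqrt(sum(x * x for x in self.direction))
        if abs(norm - 1.0) > 1e-9:
            object.__setattr__(
                self, "direction", tuple(x / norm for x in self.direction)
            )


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``direction`` to a right-handed frame."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def helix_points(p: HelixParams, phase: float = 0.0) -> np.ndarray:
    """Calpha positions on the ideal helical curve, first to last."""
    d = np.asarray(p.direction, dtype=float)
    origin = np.asarray(p.origin, dtype=float)
    u, v = _frame(d)
    pts = np.empty((p.n_res, 3))
    for i in range(p.n_res):
        ang = math.radians(phase + p.twist * i)
        pts[i] = (origin + d * (p.rise * i)
                  + p.radius * (math.cos(ang) * u + math.sin(ang) * v))
    return pts


def _make_residues(points: np.ndarray, start_auth: int, bfac: float | list[float],
                   resname: str = "ALA") -> list[Residue]:
    residues = []
    for i, pos in enumerate(points):
        b = bfac[i] if isinstance(bfac, (list, np.ndarray)) else float(bfac)
        residues.append(Residue(
            auth_num=start_auth + i,
            icode="",
            name=resname,
            atoms=[AtomRecord(name="CA", element="C",
                              pos=(round(float(pos[0]), 3),
                                   round(float(pos[1]), 3),
                                   round(float(pos[2]), 3)),
                              bfac=b)],
        ))
    return residues


def ideal_helix(p: HelixParams, chain_id: str = "A", start_auth: int = 1,
                bfac: float = 30.0) -> Chain:
    """Calpha-only chain tracing one ideal helix, N to C along +direction."""
    return Chain(chain_id=chain_id,
                 residues=_make_residues(helix_points(p), start_auth, bfac))


# ---------------------------------------------------------------------------
# hairpin fixtures for the screen


def helix_hairpin(len_n: int, len_c: int, separation: float, angle: float,
                  loop_len: int = 4, n_pad: int = 0, c_pad: int = 0,
                  entry_id: str = "FIXT", chain_id: str = "A",
                  title: str = "SYNTHETIC TERMINAL HELIX HAIRPIN",
                  keywords: tuple[str, ...] = ("SYNTHETIC", "HAIRPIN"),
                  ) -> tuple[StructureModel, dict]:
    """Two terminal helices with declared angle and exact anchor separation.

    The N-helix runs along +z from the origin; the C-helix direction makes
    the declared N-to-C inter-axis angle with it and is translated so its
    last Calpha sits exactly ``separation`` Angstrom from the N-helix
    first Calpha — the two anchors ``terminal_separation`` measures.
    ``n_pad``/``c_pad`` extended residues realize terminal offsets; the
    loop is a straight (never helical) connector. Helix spans are recorded
    as file annotation, and the manifest row holds every expected
    measurement.
    """
    if min(len_n, len_c) < 1 or not 0.0 <= angle <= 180.0:
        raise FixtureError("invalid hairpin request")
    if separation <= 0:
        raise FixtureError("separation must be positive (distinct anchor atoms)")

    ang = math.radians(angle)
    d_n = np.array([0.0, 0.0, 1.0])
    d_c = np.array([math.sin(ang), 0.0, math.cos(ang)])

    pts_n = helix_points(HelixParams(len_n, direction=tuple(d_n)))
    anchor_n = pts_n[0]
    anchor_c_target = anchor_n + np.array([separation, 0.0, 0.0])
    pts_c_local = helix_points(HelixParams(len_c, direction=tuple(d_c)))
    pts_c = pts_c_local + (anchor_c_target - pts_c_local[-1])

    pad_n = [anchor_n + np.array([0.0, 0.0, -EXTENDED_RISE * (n_pad - j)])
             for j in range(n_pad)]
    pad_c = [pts_c[-1] + d_c * (EXTENDED_RISE * (j + 1)) for j in range(c_pad)]
    p_loop_start, p_loop_end = pts_n[-1], pts_c[0]
    loop = [p_loop_start + (p_loop_end - p_loop_start) * (j + 1) / (loop_len + 1)
            for j in range(loop_len)]

    coords = np.array([*pad_n, *pts_n, *loop, *pts_c, *pad_c])
    chain = Chain(chain_id=chain_id,
                  residues=_make_residues(coords, start_auth=1, bfac=30.0))
    helix_n = HelixSegment(chain_id, n_pad + 1, n_pad + len_n, len_n)
    c_start = n_pad + len_n + loop_len + 1
    helix_c = HelixSegment(chain_id, c_start, c_start + len_c - 1, len_c)
    model = StructureModel(
        entry_id=entry_id,
        chains=[chain],
        metadata=StructureMetadata(title=title, keywords=list(keywords)),
        annotated_helix_spans=[helix_n, helix_c],
    )
    crit = ScreenCriteria()
    geometry_ok = (min(len_n, len_c) >= crit.min_helix_len
                   and max(n_pad, c_pad) <= crit.max_terminal_offset
                   and abs(separation - crit.target_separation) <= crit.separation_halfwidth
                   and angle >= crit.min_angle)
    manifest = {
        "entry_id": entry_id,
        "chain_id": chain_id,
        "len_n": len_n,
        "len_c": len_c,
        "n_offset": n_pad,
        "c_offset": c_pad,
        "separation": separation,
        "angle": angle,
        "anchor_n": tuple(np.round(anchor_n, 3)),
        "anchor_c": tuple(np.round(anchor_c_target, 3)),
        "expect_min_helix_len": min(len_n, len_c) >= crit.min_helix_len,
        "expect_terminal_offset": max(n_pad, c_pad) <= crit.max_terminal_offset,
        "expect_separation": abs(separation - crit.target_separation)
        <= crit.separation_halfwidth,
        "expect_angle": angle >= crit.min_angle,
        "expect_score": geometry_score(separation, angle, crit.score_params)
        if geometry_ok else None,
    }
    return model, manifest


# ---------------------------------------------------------------------------
# mock predicted fusion models


def _expected_helical_mask(n_res: int, displaced: set[int]) -> list[bool]:
    """Forward three-distance rule on the planned geometry.

    All undisplaced residues lie on one continuous ideal helix, so
    position i (1-based) is helical iff its window exists and none of
    i, i+2, i+3, i+4 is displaced.
    """
    mask = []
    for i in range(1, n_res + 1):
        ok = i + 4 <= n_res and not ({i, i + 2, i + 3, i + 4} & displaced)
        mask.append(ok)
    return mask


def fusion_model_fixture(construct: FusionConstruct,
                         junction_helical: tuple[bool, bool] = (True, True),
                         confidence: float | dict[int, float] = 90.0,
                         planted_clash: float | None = None,
                         window_k: int = 4,
                         ) -> tuple[StructureModel, dict]:
    """Mock predictor output realizing a chimera with known properties.

    The chain traces one continuous ideal helix (auth 1..L). A broken
    junction displaces the ``window_k`` residues just before the splice
    boundary onto an extended offshoot, which leaves exactly the
    boundary-side half of that junction window helical. The B-factor
    column carries the requested confidence. ``planted_clash`` adds one
    tag CB atom at exactly that distance from a receptor Calpha, placed
    radially outward so no other contact forms.
    """
    seq = construct.sequence
    n = len(seq)
    pts = helix_points(HelixParams(n))

    displaced: set[int] = set()
    n_ok, c_ok = junction_helical
    if not n_ok:
        displaced |= set(range(construct.junction_n - window_k + 1,
                               construct.junction_n + 1))
    if not c_ok:
        displaced |= set(range(construct.junction_c - window_k,
                               construct.junction_c))
    if displaced:
        # shift each displaced run onto a straight +x offshoot from the
        # residue preceding the run
        runs: list[list[int]] = []
        for pos in sorted(displaced):
            if runs and runs[-1][-1] == pos - 1:
                runs[-1].append(pos)
            else:
                runs.append([pos])
        for run in runs:
            base_idx = run[0] - 2  # 0-based index of the residue before the run
            if base_idx < 0:
                raise FixtureError("broken junction too close to chain start")
            base = pts[base_idx]
            for j, pos in enumerate(run, start=1):
                pts[pos - 1] = base + np.array([EXTENDED_RISE * j, 0.0, 0.0])

    if isinstance(confidence, dict):
        bfacs = [float(confidence.get(i, 50.0)) for i in range(1, n + 1)]
    else:
        bfacs = [float(confidence)] * n

    residues = []
    for i in range(n):
        aa = seq[i]
        resname = "UNK" if aa == "X" else seq3(aa).upper()
        residues.append(Residue(
            auth_num=i + 1, icode="", name=resname,
            atoms=[AtomRecord(name="CA", element="C",
                              pos=tuple(np.round(pts[i], 3)), bfac=bfacs[i])],
        ))

    expected_clash = 0
    if planted_clash is not None:
        tag_span = construct.tag_span
        if tag_span is None:
            raise FixtureError("cannot plant a clash without a tag span")
        tag_res = (tag_span[0] + tag_span[1]) // 2
        rec_res = min(construct.junction_c + 6, n)
        if abs(tag_res - rec_res) < 3:
            raise FixtureError("clash partners too close in sequence")
        target = pts[rec_res - 1]
        radial = target - np.array([0.0, 0.0, target[2]])
        radial /= np.linalg.norm(radial)
        cb_pos = target + planted_clash * radial
        residues[tag_res - 1].atoms.append(
            AtomRecord(name="CB", element="C", pos=tuple(np.round(cb_pos, 3)),
                       bfac=bfacs[tag_res - 1])
        )
        expected_clash = 1 if planted_clash < 3.0 else 0

    chain = Chain(chain_id="A", residues=residues)
    model = StructureModel(
        entry_id="MODL", chains=[chain],
        metadata=StructureMetadata(title=f"SYNTHETIC FUSION MODEL {construct.name}"),
    )

    mask = _expected_helical_mask(n, displaced)

    def window_frac(center_last_before: int) -> float:
        lo = max(0, center_last_before - window_k)
        hi = min(n, center_last_before + window_k)
        members = range(lo + 1, hi + 1)
        return sum(1 for m in members if mask[m - 1]) / len(list(members))

    mean_conf = float(np.mean(bfacs))
    manifest = {
        "construct": construct.name,
        "expected_helicity_n": window_frac(construct.junction_n),
        "expected_helicity_c": window_frac(construct.junction_c - 1),
        "expected_conf_n": float(np.mean(
            [bfacs[i - 1] for i in range(max(1, construct.junction_n - window_k + 1),
                                         min(n, construct.junction_n + window_k) + 1)])),
        "expected_clash_count": expected_clash,
        "planted_clash": planted_clash,
        "mean_confidence": mean_conf,
    }
    return model, manifest


# ---------------------------------------------------------------------------
# corpus generation


NEGATIVE_KINDS = ("too_short", "offset", "separation", "angle", "keyword", "oligomer")

#: which screen flag each negative kind is built to fail
KIND_TO_FLAG = {
    "too_short": "min_helix_len",
    "offset": "terminal_offset",
    "separation": "separation",
    "angle": "angle",
    "keyword": "excluded_keyword",
    "oligomer": "oligomer",
}


def _passing_params(rng: np.random.Generator) -> dict:
    return {
        "len_n": int(rng.integers(9, 14)),
        "len_c": int(rng.integers(9, 14)),
        "separation": float(np.round(rng.uniform(7.0, 13.0), 2)),
        "angle": float(np.round(rng.uniform(155.0, 180.0), 2)),
        "loop_len": int(rng.integers(3, 7)),
        "n_pad": int(rng.integers(0, 3)),
        "c_pad": int(rng.integers(0, 3)),
    }


def _write_with_header_extras(model: StructureModel, path: str,
                              oligomer_chains: list[str] | None = None) -> None:
    write_structure(model, path, fmt="pdb")
    if oligomer_chains:
        remark = [
            "REMARK 350 BIOMOLECULE: 1",
            "REMARK 350 APPLY THE FOLLOWING TO CHAINS: " + ", ".join(oligomer_chains),
            "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000",
            "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000",
            "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000",
        ]
        with open(path) as fh:
            lines = fh.read().splitlines()
        insert_at = next(
            (i for i, ln in enumerate(lines) if ln.startswith(("HELIX", "ATOM"))),
            len(lines),
        )
        lines[insert_at:insert_at] = remark
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def corpus_fixture(out_dir: str | os.PathLike, n_files: int = 10,
                   n_positives: int = 3, seed: int = 7) -> pd.DataFrame:
    """Seeded corpus of planted positives and single-defect negatives.

    Positives pass every screen gate; each negative is built from passing
    parameters with exactly one named criterion violated (cycling through
    helix length, terminal offset, separation, angle, exclusion keyword
    and deposited oligomer). Same seed, same bytes. The manifest TSV
    written alongside is the oracle the screen is tested against.
    """
    if n_positives > n_files:
        raise FixtureError("n_positives cannot exceed n_files")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_files):
        entry_id = f"FX{i:02d}"
        fname = f"fix_{i:02d}.pdb"
        path = os.path.join(out_dir, fname)
        params = _passing_params(rng)
        kind = "positive" if i < n_positives else NEGATIVE_KINDS[
            (i - n_positives) % len(NEGATIVE_KINDS)]
        title = "SYNTHETIC SOLUBLE HAIRPIN"
        oligomer_chains = None
        if kind == "too_short":
            params["len_n"] = int(rng.integers(4, 8))
        elif kind == "offset":
            params["n_pad"] = int(rng.integers(6, 9))
        elif kind == "separation":
            params["separation"] = float(np.round(rng.uniform(19.0, 25.0), 2))
        elif kind == "angle":
            params["angle"] = float(np.round(rng.uniform(30.0, 120.0), 2))
        elif kind == "keyword":
            title = "SYNTHETIC INTEGRAL MEMBRANE PROTEIN"
        elif kind == "oligomer":
            oligomer_chains = ["A", "B"]

        model, manifest = helix_hairpin(
            params["len_n"], params["len_c"], params["separation"],
            params["angle"], loop_len=params["loop_len"],
            n_pad=params["n_pad"], c_pad=params["c_pad"],
            entry_id=entry_id, title=title,
        )
        if oligomer_chains:
            # second copy of the chain, translated far away
            shifted = []
            for r in model.chains[0].residues:
                atoms = [AtomRecord(a.name, a.element,
                                    (a.pos[0] + 60.0, a.pos[1], a.pos[2]),
                                    a.bfac, a.altloc, a.occupancy)
                         for a in r.atoms]
                shifted.append(Residue(r.auth_num, r.icode, r.name, atoms))
            model.chains.append(Chain(chain_id="B", residues=shifted))
            spans = [HelixSegment("B", s.start_auth, s.end_auth, s.length)
                     for s in model.annotated_helix_spans]
            model.annotated_helix_spans.extend(spans)
        _write_with_header_extras(model, path, oligomer_chains)
        manifest.update({
            "filename": fname,
            "kind": kind,
            "is_positive": kind == "positive",
            "expected_fail_flag": "" if kind == "positive" else KIND_TO_FLAG[kind],
            "n_chains": 2 if oligomer_chains else 1,
        })
        rows.append(manifest)
    frame = pd.DataFrame(rows)
    frame.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return frame
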