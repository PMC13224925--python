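"""Triage of predicted fusion-model structures.

A rigid, well-folded chimera shows (i) unbroken helix through both
splice junctions, (ii) high predictor confidence across those junctions
(per-residue pLDDT read from the B-factor column, 0-100), (iii) low
Calpha RMSD of the receptor portion to a reference antagonist-bound
receptor structure after least-squares superposition, and (iv) no close
heavy-atom contacts between the tag and receptor domains. Each
assessment is a separate operation; ``assess_model`` combines them into
a deterministic composite rank (helical continuity first, then clash
count, junction confidence, RMSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DomainDefinitionError,
    MeasurementError,
    ModelMismatchError,
    ValidationError,
)
from .fusion_design import FusionConstruct
from .helix_geometry import SseParams, helical_mask
from .structure_model import Chain, StructureModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionWindow:
    """Residues straddling one splice point: k receptor + k tag residues."""

    junction: str  # "N" or "C"
    residue_auths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.junction not in ("N", "C"):
            raise ValidationError("junction must be 'N' or 'C'")


@dataclass(frozen=True)
class ResidueMapping:
    """Model-to-reference residue pairs for superposition.

    Each pair is ((model_chain, model_auth), (ref_chain, ref_auth)).
    """

    pairs: tuple[tuple[tuple[str, int], tuple[str, int]], ...]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ClashContact:
    """One tag/receptor heavy-atom pair closer than the cutoff."""

    tag_auth: int
    tag_resname: str
    tag_atom: str
    receptor_auth: int
    receptor_resname: str
    receptor_atom: str
    distance: float


@dataclass(frozen=True)
class AssessmentParams:
    """Knobs of the triage: window half-width, SSE windows, clash cutoff.

    ``window_k`` = 4 covers one helical turn plus one residue on each
    side of a splice point. The 3.0 Angstrom heavy-atom cutoff sits well
    below van der Waals contact distance, so every hit is an unambiguous
    potential clash.
    """

    window_k: int = 4
    sse: SseParams = field(default_factory=SseParams)
    clash_cutoff: float = 3.0


@dataclass
class AssessmentReport:
    """Per-model triage outcome and composite ranking key."""

    construct_name: str
    helicity_n: float
    helicity_c: float
    conf_n: float
    conf_c: float
    rmsd_to_reference: float | None
    clashes: list[ClashContact] = field(default_factory=list)

    @property
    def continuous_n(self) -> bool:
        return self.helicity_n == 1.0

    @property
    def continuous_c(self) -> bool:
        return self.helicity_c == 1.0

    @property
    def clash_count(self) -> int:
        return len(self.clashes)

    @property
    def composite_rank_key(self) -> tuple:
        """Sort ascending: best model first.

        Continuity at both junctions dominates, then fewer clashes, then
        higher mean junction confidence, then lower RMSD; construct name
        breaks exact ties stably.
        """
        continuous = self.continuous_n and self.continuous_c
        mean_conf = 0.5 * (self.conf_n + self.conf_c)
        rmsd = self.rmsd_to_reference if self.rmsd_to_reference is not None else np.inf
        return (0 if continuous else 1, self.clash_count, -mean_conf, rmsd,
                self.construct_name)


# ---------------------------------------------------------------------------
# junction location and window metrics


def _single_chain(model: StructureModel) -> Chain:
    chains = model.polymer_chains
    if len(chains) != 1:
        raise ModelMismatchError(
            f"expected a single-chain model, found {len(chains)} polymer chains"
        )
    return chains[0]


def locate_junctions(construct: FusionConstruct, model: StructureModel,
                     k: int = 4) -> tuple[JunctionWindow, JunctionWindow]:
    """Windows of k receptor + k tag residues around each splice point.

    The model must be a single chain realizing the construct sequence
    exactly; the first discrepancy is reported otherwise. Windows falling
    off a short flank are clipped with a warning.
    """
    chain = _single_chain(model)
    seq = chain.seq
    if len(seq) != len(construct.sequence):
        raise ModelMismatchError(
            f"model has {len(seq)} residues but construct "
            f"{construct.name} has {len(construct.sequence)}"
        )
    for i, (a, b) in enumerate(zip(seq, construct.sequence)):
        if a != b and "X" not in (a, b):
            raise ModelMismatchError(
                f"model/construct sequence mismatch at position {i + 1}: "
                f"model {a!r} vs construct {b!r}"
            )
    auths = [r.auth_num for r in chain.residues]
    n = len(auths)

    def window(center_last_before: int, label: str) -> JunctionWindow:
        lo = max(0, center_last_before - k)
        hi = min(n, center_last_before + k)
        if hi - lo < 2 * k:
            log.warning("junction %s window clipped to %d residues", label, hi - lo)
        return JunctionWindow(label, tuple(auths[lo:hi]))

    # N junction: boundary after chimera position junction_n
    # C junction: boundary after position junction_c - 1
    return (window(construct.junction_n, "N"),
            window(construct.junction_c - 1, "C"))


def junction_helicity(model: StructureModel, w: JunctionWindow,
                      p: SseParams = SseParams()) -> float:
    """Fraction of window residues assigned helical on the full chain.

    1.0 means the helix runs unbroken through the junction.
    """
    if not w.residue_auths:
        raise ValidationError("empty junction window")
    chain = _single_chain(model)
    mask = helical_mask(chain, p)
    helical_auths = {r.auth_num for r, m in zip(chain.residues, mask) if m}
    n_helical = sum(1 for a in w.residue_auths if a in helical_auths)
    return n_helical / len(w.residue_auths)


def junction_confidence(model: StructureModel, w: JunctionWindow) -> float:
    """Mean per-residue confidence (Calpha B-factor field) over the window."""
    chain = _single_chain(model)
    values = []
    for auth in w.residue_auths:
        res = chain.residue_by_auth(auth)
        if res is None or res.ca is None:
            continue
        values.append(res.ca.bfac)
    if not values:
        raise MeasurementError("no Calpha confidence values in junction window")
    if len(values) < len(w.residue_auths):
        log.warning("junction %s: confidence over %d of %d residues",
                    w.junction, len(values), len(w.residue_auths))
    mean = float(np.mean(values))
    if mean == 0.0:
        log.warning("all-zero B-factor field: model may not carry confidences")
    return mean


# ---------------------------------------------------------------------------
# superposition


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns (rotation, translation, rmsd) such that
    ``moving @ rotation.T + translation`` best fits ``fixed``. The
    optimal rotation comes from the SVD of the cross-covariance with a
    determinant sign guard, so the result is always a proper rotation,
    never a reflection.
    """
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValidationError("point sets must be matching Nx3 arrays")
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    a = moving - mu_m
    b = fixed - mu_f
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = mu_f - rot @ mu_m
    moved = a @ rot.T
    rmsd = float(np.sqrt(((moved - b) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd


def _mapped_ca(model: StructureModel, reference: StructureModel,
               mapping: ResidueMapping) -> tuple[np.ndarray, np.ndarray]:
    pts_m, pts_r = [], []
    for (m_chain, m_auth), (r_chain, r_auth) in mapping.pairs:
        res_m = model.chain(m_chain).residue_by_auth(m_auth)
        res_r = reference.chain(r_chain).residue_by_auth(r_auth)
        if res_m is None or res_m.ca is None:
            raise MeasurementError(f"model residue {m_chain}/{m_auth} lacks Calpha")
        if res_r is None or res_r.ca is None:
            raise MeasurementError(f"reference residue {r_chain}/{r_auth} lacks Calpha")
        pts_m.append(res_m.ca.xyz)
        pts_r.append(res_r.ca.xyz)
    return np.asarray(pts_m), np.asarray(pts_r)


def superpose_to_reference(model: StructureModel, reference: StructureModel,
                           mapping: ResidueMapping
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """Calpha RMSD of the model to the reference over a residue mapping.

    Returns (rmsd, rotation, translation) of the optimal superposition.
    Fewer than three pairs underdetermine the rotation.
    """
    if len(mapping) < 3:
        raise ValidationError(
            f"superposition needs >= 3 mapped pairs, got {len(mapping)}"
        )
    pts_m, pts_r = _mapped_ca(model, reference, mapping)
    rot, trans, rmsd = kabsch(pts_m, pts_r)
    return rmsd, rot, trans


def mapping_by_auth(model: StructureModel, reference: StructureModel,
                    spans: list[tuple[int, int]], model_chain: str | None = None,
                    ref_chain: str | None = None, offset: int = 0) -> ResidueMapping:
    """Identity mapping over receptor spans: model auth n -> reference n + offset.

    Predictor models of a chimera are renumbered 1..n; ``offset`` aligns
    them back onto the reference's author numbering. A span residue
    missing from either structure is an error, never a silent drop.
    """
    mc = model.chain(model_chain) if model_chain else _single_chain(model)
    rc = (reference.chain(ref_chain) if ref_chain
          else reference.polymer_chains[0])
    pairs = []
    for lo, hi in spans:
        for auth in range(lo, hi + 1):
            res_m = mc.residue_by_auth(auth)
            res_r = rc.residue_by_auth(auth + offset)
            if res_m is None or res_m.ca is None:
                raise MeasurementError(f"model residue {auth} missing for mapping")
            if res_r is None or res_r.ca is None:
                raise MeasurementError(
                    f"reference residue {auth + offset} missing for mapping"
                )
            pairs.append(((mc.chain_id, auth), (rc.chain_id, auth + offset)))
    return ResidueMapping(tuple(pairs))


# ---------------------------------------------------------------------------
# clash detection


def interdomain_clashes(model: StructureModel, tag_span: tuple[int, int],
                        receptor_spans: list[tuple[int, int]],
                        cutoff: float = 3.0) -> list[ClashContact]:
    """Heavy-atom contacts between tag and receptor closer than the cutoff.

    Pairs within 2 residues along the chain are excluded (bonded
    neighborhood); contacts are sorted by distance ascending so the worst
    clash leads the list.
    """
    lo_t, hi_t = tag_span
    for lo_r, hi_r in receptor_spans:
        if lo_t <= hi_r and lo_r <= hi_t:
            raise DomainDefinitionError(
                f"tag span {tag_span} overlaps receptor span {(lo_r, hi_r)}"
            )
    chain = _single_chain(model)

    def atoms_in(spans: list[tuple[int, int]]):
        out = []
        for res in chain.residues:
            if any(lo <= res.auth_num <= hi for lo, hi in spans):
                for a in res.atoms:
                    if not a.is_hydrogen:
                        out.append((res, a))
        return out

    tag_atoms = atoms_in([tag_span])
    rec_atoms = atoms_in(receptor_spans)
    if not tag_atoms or not rec_atoms:
        raise DomainDefinitionError("a declared domain contains no heavy atoms")
    tree = cKDTree(np.array([a.xyz for _, a in rec_atoms]))
    contacts = []
    for res_t, at_t in tag_atoms:
        for j in tree.query_ball_point(at_t.xyz, cutoff):
            res_r, at_r = rec_atoms[j]
            if abs(res_t.auth_num - res_r.auth_num) < 3:
                continue
            dist = float(np.linalg.norm(at_t.xyz - at_r.xyz))
            if dist < cutoff:
                contacts.append(ClashContact(
                    tag_auth=res_t.auth_num, tag_resname=res_t.name,
                    tag_atom=at_t.name, receptor_auth=res_r.auth_num,
                    receptor_resname=res_r.name, receptor_atom=at_r.name,
                    distance=dist,
                ))
    contacts.sort(key=lambda c: (c.distance, c.tag_auth, c.receptor_auth))
    return contacts


# ---------------------------------------------------------------------------
# composite assessment


def assess_model(construct: FusionConstruct, model: StructureModel,
                 reference: StructureModel | None = None,
                 mapping: ResidueMapping | None = None,
                 params: AssessmentParams = AssessmentParams()) -> AssessmentReport:
    """Run all four triage assessments on one predicted model."""
    w_n, w_c = locate_junctions(construct, model, k=params.window_k)
    helicity_n = junction_helicity(model, w_n, params.sse)
    helicity_c = junction_helicity(model, w_c, params.sse)
    conf_n = junction_confidence(model, w_n)
    conf_c = junction_confidence(model, w_c)
    rmsd = None
    if reference is not None and mapping is not None:
        rmsd, _, _ = superpose_to_reference(model, reference, mapping)
    clashes: list[ClashContact] = []
    tag_span = construct.tag_span
    if tag_span is not None:
        chimera_len = len(construct.sequence)
        receptor_spans = []
        if construct.junction_n >= 1:
            receptor_spans.append((1, construct.junction_n))
        if construct.junction_c <= chimera_len:
            receptor_spans.append((construct.junction_c, chimera_len))
        clashes = interdomain_clashes(model, tag_span, receptor_spans,
                                      cutoff=params.clash_cutoff)
    return AssessmentReport(
        construct_name=construct.name,
        helicity_n=helicity_n,
        helicity_c=helicity_c,
        conf_n=conf_n,
        conf_c=conf_c,
        rmsd_to_reference=rmsd,
        clashes=clashes,
    )


def rank_models(reports: list[AssessmentReport]) -> list[AssessmentReport]:
    """Best-first ordering by the composite key; deterministic."""
    return sorted(reports, key=lambda r: r.composite_rank_key)
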