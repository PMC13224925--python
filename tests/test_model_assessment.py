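"""Junction triage: helicity, confidence, superposition, clashes, ranking."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from helixtag import (
    AssessmentParams,
    ResidueMapping,
    assess_model,
    fusion_model_fixture,
    interdomain_clashes,
    junction_confidence,
    junction_helicity,
    kabsch,
    locate_junctions,
    mapping_by_auth,
    rank_models,
    splice_sequence,
    superpose_to_reference,
)
from helixtag.errors import (
    DomainDefinitionError,
    ModelMismatchError,
    ValidationError,
)
from helixtag.structure_model import AtomRecord, Chain, Residue, StructureModel


@pytest.fixture
def model_and_construct(control_construct):
    model, manifest = fusion_model_fixture(control_construct)
    return model, control_construct, manifest


class TestLocateJunctions:
    def test_windows_straddle_recorded_junctions(self, model_and_construct):
        model, construct, _ = model_and_construct
        w_n, w_c = locate_junctions(construct, model, k=4)
        jn, jc = construct.junction_n, construct.junction_c
        assert w_n.residue_auths == tuple(range(jn - 3, jn + 5))
        assert w_c.residue_auths == tuple(range(jc - 4, jc + 4))
        assert len(w_n.residue_auths) == len(w_c.residue_auths) == 8

    def test_oversized_k_clips_window(self, receptor, tag):
        construct = splice_sequence(receptor, tag, entry=4, exit=245)
        model, _ = fusion_model_fixture(construct)
        w_n, _ = locate_junctions(construct, model, k=10)
        # N flank is only 3 residues long
        assert w_n.residue_auths[0] == 1
        assert len(w_n.residue_auths) < 20

    def test_extra_residue_raises_mismatch(self, model_and_construct):
        model, construct, _ = model_and_construct
        chain = model.chains[0]
        extra = Residue(auth_num=len(chain.residues) + 1, icode="", name="ALA",
                        atoms=[AtomRecord("CA", "C", (0.0, 0.0, 999.0))])
        bad = StructureModel("MODL", [Chain("A", chain.residues + [extra])])
        with pytest.raises(ModelMismatchError):
            locate_junctions(construct, bad)

    def test_sequence_discrepancy_reported_with_position(self, model_and_construct):
        model, construct, _ = model_and_construct
        res5 = model.chains[0].residues[4]
        model.chains[0].residues[4] = Residue(
            auth_num=res5.auth_num, icode="", name="TRP", atoms=res5.atoms)
        with pytest.raises(ModelMismatchError, match="position 5"):
            locate_junctions(construct, model)


class TestJunctionHelicity:
    def test_unbroken_helix_scores_one(self, model_and_construct):
        model, construct, manifest = model_and_construct
        w_n, w_c = locate_junctions(construct, model)
        assert junction_helicity(model, w_n) == 1.0 == manifest["expected_helicity_n"]
        assert junction_helicity(model, w_c) == 1.0

    def test_broken_junction_scores_half(self, control_construct):
        model, manifest = fusion_model_fixture(
            control_construct, junction_helical=(True, False))
        w_n, w_c = locate_junctions(control_construct, model)
        assert junction_helicity(model, w_n) == 1.0
        assert junction_helicity(model, w_c) == pytest.approx(
            manifest["expected_helicity_c"])
        assert manifest["expected_helicity_c"] == 0.5

    def test_both_junctions_broken(self, control_construct):
        model, manifest = fusion_model_fixture(
            control_construct, junction_helical=(False, False))
        w_n, w_c = locate_junctions(control_construct, model)
        assert junction_helicity(model, w_n) == manifest["expected_helicity_n"] == 0.5
        assert junction_helicity(model, w_c) == manifest["expected_helicity_c"] == 0.5

    def test_helicity_equals_brute_force_count(self, control_construct):
        from helixtag.helix_geometry import helical_mask
        model, _ = fusion_model_fixture(control_construct,
                                        junction_helical=(False, True))
        w_n, _ = locate_junctions(control_construct, model)
        chain = model.chains[0]
        mask = helical_mask(chain)
        helical = {r.auth_num for r, m in zip(chain.residues, mask) if m}
        expected = sum(1 for a in w_n.residue_auths if a in helical) / len(
            w_n.residue_auths)
        assert junction_helicity(model, w_n) == pytest.approx(expected)


class TestJunctionConfidence:
    def test_uniform_confidence(self, control_construct):
        model, _ = fusion_model_fixture(control_construct, confidence=90.0)
        w_n, _ = locate_junctions(control_construct, model)
        assert junction_confidence(model, w_n) == pytest.approx(90.0)

    def test_half_high_half_low_averages(self, control_construct):
        jn = control_construct.junction_n
        profile = {i: (90.0 if i <= jn else 50.0)
                   for i in range(1, len(control_construct.sequence) + 1)}
        model, _ = fusion_model_fixture(control_construct, confidence=profile)
        w_n, _ = locate_junctions(control_construct, model)
        # window: 4 receptor residues at 90, 4 tag residues at 50
        assert junction_confidence(model, w_n) == pytest.approx(70.0)

    def test_missing_ca_mean_over_remaining(self, control_construct):
        model, _ = fusion_model_fixture(control_construct, confidence=80.0)
        w_n, _ = locate_junctions(control_construct, model)
        chain = model.chains[0]
        chain.residue_by_auth(w_n.residue_auths[0]).atoms.clear()
        assert junction_confidence(model, w_n) == pytest.approx(80.0)


def _ca_model(points, entry_id="SUPR"):
    return StructureModel(entry_id, [Chain("A", [
        Residue(auth_num=i + 1, icode="", name="ALA",
                atoms=[AtomRecord("CA", "C", tuple(p))])
        for i, p in enumerate(points)
    ])])


def _identity_mapping(n):
    return ResidueMapping(tuple((("A", i), ("A", i)) for i in range(1, n + 1)))


class TestSuperposition:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.pts = rng.normal(0, 5, (20, 3))

    def test_copy_has_zero_rmsd(self):
        a, b = _ca_model(self.pts), _ca_model(self.pts.copy())
        rmsd, _, _ = superpose_to_reference(a, b, _identity_mapping(20))
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rot = Rotation.from_euler("xyz", [90, 30, -45], degrees=True).as_matrix()
        moved = self.pts @ rot.T + np.array([10.0, -3.0, 7.0])
        rmsd, _, _ = superpose_to_reference(
            _ca_model(moved), _ca_model(self.pts), _identity_mapping(20))
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        other = self.pts + rng.normal(0, 1, self.pts.shape)
        m1, m2 = _ca_model(self.pts), _ca_model(other)
        r12, _, _ = superpose_to_reference(m1, m2, _identity_mapping(20))
        r21, _, _ = superpose_to_reference(m2, m1, _identity_mapping(20))
        assert r12 == pytest.approx(r21, abs=1e-6)

    def test_agrees_with_direct_numerical_minimization(self):
        """Independent oracle: minimize RMSD over rotation+translation."""
        rng = np.random.default_rng(5)
        fixed = self.pts
        moving = self.pts + rng.normal(0, 0.8, self.pts.shape)

        def objective(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            moved = moving @ rot.T + x[3:]
            return np.sqrt(((moved - fixed) ** 2).sum(axis=1).mean())

        best = min(
            (minimize(objective, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
             for x0 in (np.zeros(6), np.array([0.1, -0.2, 0.3, 1.0, -1.0, 0.5]))),
            key=lambda r: r.fun)
        _, _, rmsd = kabsch(moving, fixed)
        assert rmsd == pytest.approx(best.fun, abs=1e-3)
        assert rmsd <= best.fun + 1e-9  # closed form is the true optimum

    def test_single_displaced_atom_closed_form(self):
        """One of N atoms displaced 1 A: residual RMSD ~ sqrt(1/N) for a
        large rigid cluster (displacement orthogonal to fit modes)."""
        n = 400
        rng = np.random.default_rng(9)
        fixed = rng.normal(0, 20, (n, 3))
        moving = fixed.copy()
        moving[0] += np.array([1.0, 0.0, 0.0])
        _, _, rmsd = kabsch(moving, fixed)
        assert rmsd == pytest.approx(np.sqrt(1.0 / n), rel=0.02)

    def test_reflection_guard_returns_proper_rotation(self):
        # a near-planar cloud plus mirrored partner tempts a reflection
        rng = np.random.default_rng(2)
        fixed = rng.normal(0, 5, (10, 3)) * np.array([1.0, 1.0, 0.05])
        moving = fixed * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch(moving, fixed)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_underdetermined_mapping_raises(self):
        a, b = _ca_model(self.pts[:2]), _ca_model(self.pts[:2])
        with pytest.raises(ValidationError):
            superpose_to_reference(a, b, _identity_mapping(2))

    def test_mapping_by_auth_with_offset(self):
        model = _ca_model(self.pts)
        ref = StructureModel("REF", [Chain("R", [
            Residue(auth_num=i + 101, icode="", name="ALA",
                    atoms=[AtomRecord("CA", "C", tuple(p))])
            for i, p in enumerate(self.pts)
        ])])
        mapping = mapping_by_auth(model, ref, spans=[(1, 20)], offset=100)
        rmsd, _, _ = superpose_to_reference(model, ref, mapping)
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestClashes:
    def _clash_setup(self, control_construct, distance):
        model, manifest = fusion_model_fixture(
            control_construct, planted_clash=distance)
        span = control_construct.tag_span
        chimera_len = len(control_construct.sequence)
        receptor_spans = [(1, control_construct.junction_n),
                          (control_construct.junction_c, chimera_len)]
        return model, span, receptor_spans, manifest

    def test_planted_contact_found_at_default_cutoff(self, control_construct):
        model, span, rec_spans, manifest = self._clash_setup(control_construct, 2.5)
        contacts = interdomain_clashes(model, span, rec_spans, cutoff=3.0)
        assert len(contacts) == manifest["expected_clash_count"] == 1
        assert contacts[0].distance == pytest.approx(2.5, abs=1e-3)
        assert contacts[0].tag_atom == "CB"

    def test_tighter_cutoff_excludes_contact(self, control_construct):
        model, span, rec_spans, _ = self._clash_setup(control_construct, 2.5)
        assert interdomain_clashes(model, span, rec_spans, cutoff=2.0) == []

    def test_cutoff_monotonicity(self, control_construct):
        model, span, rec_spans, _ = self._clash_setup(control_construct, 2.5)
        sizes = [len(interdomain_clashes(model, span, rec_spans, cutoff=c))
                 for c in (5.0, 4.0, 3.0, 2.4, 2.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bonded_neighborhood_excluded(self):
        # two atoms 2.5 A apart but only 2 residues apart in sequence
        pts = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (2.5, 0.0, 0.0),
               (50.0, 0.0, 0.0), (53.8, 0.0, 0.0)]
        model = _ca_model(pts)
        contacts = interdomain_clashes(model, (3, 3), [(1, 2)], cutoff=3.0)
        assert contacts == []

    def test_overlapping_spans_rejected(self, control_construct):
        model, _ = fusion_model_fixture(control_construct)
        with pytest.raises(DomainDefinitionError):
            interdomain_clashes(model, (10, 50), [(1, 20)])


class TestAssessAndRank:
    def test_continuous_model_outranks_broken(self, control_construct):
        good_model, _ = fusion_model_fixture(control_construct)
        bad_model, _ = fusion_model_fixture(control_construct,
                                            junction_helical=(True, False))
        good = assess_model(control_construct, good_model)
        bad = assess_model(control_construct, bad_model)
        assert rank_models([bad, good])[0] is good

    def test_planted_best_among_five(self, receptor, tag):
        variants = []
        for i, (helical, conf, clash) in enumerate([
            ((True, True), 90.0, None),     # the planted best
            ((True, False), 90.0, None),
            ((True, True), 60.0, None),
            ((True, True), 90.0, 2.5),
            ((False, False), 50.0, 2.2),
        ]):
            construct = splice_sequence(receptor, tag, entry=230 + i, exit=245)
            model, _ = fusion_model_fixture(construct, junction_helical=helical,
                                            confidence=conf, planted_clash=clash)
            variants.append(assess_model(construct, model))
        ranked = rank_models(variants)
        assert ranked[0].construct_name.endswith("e230_x245")
        assert ranked[0].continuous_n and ranked[0].continuous_c
        assert ranked[0].clash_count == 0

    def test_ties_break_stably_by_name(self, receptor, tag):
        reports = []
        for entry in (231, 230):
            construct = splice_sequence(receptor, tag, entry=entry, exit=245)
            model, _ = fusion_model_fixture(construct)
            reports.append(assess_model(construct, model))
        ranked = rank_models(reports)
        assert [r.construct_name for r in ranked] == sorted(
            r.construct_name for r in reports)
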