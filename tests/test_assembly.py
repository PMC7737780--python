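"""Combinatorial assembly, catalytic fixation and the steric screen."""

import itertools

import numpy as np
import pytest

from bbassembly.assembly import (
    AssemblyError,
    AssemblyRecipe,
    CatalyticConstraint,
    assemble,
    check_catalytic,
    count_assemblies,
    enumerate_or_sample,
    steric_screen,
)
from bbassembly.fragment_db import FragmentDatabase, FragmentRecord
from bbassembly.pssm import MSA, build_pssm
from bbassembly.segmentation import Fragment
from bbassembly.structure_io import TorsionTriple, extract_torsions, rebuild_backbone
from conftest import angdiff


def _template_recipe(scheme):
    return AssemblyRecipe(choices=tuple((n, "template") for n in scheme.segment_names))


def _dummy_db(counts):
    """A database with the given accepted-record counts per synthetic segment
    (records carry minimal fragments; enough for counting/sampling)."""
    segs = {}
    for s, n in enumerate(counts):
        name = str(s + 1)
        segs[name] = [
            FragmentRecord(
                fragment=Fragment(
                    source_id=f"h{i}",
                    segment_name=name,
                    seq="AA",
                    torsions=[
                        TorsionTriple(None, 0.0, 180.0),
                        TorsionTriple(0.0, None, None),
                    ],
                    end_frames=np.zeros((2, 3, 3)),
                ),
                closure_rmsd=0.0,
                converged=True,
                accepted=True,
            )
            for i in range(n)
        ]
    return FragmentDatabase(segments=segs)


class TestAssemble:
    def test_identity_recipe_reproduces_template(self, toy_family, toy_db):
        family, _ = toy_family
        cand = assemble(
            family.template, toy_db, _template_recipe(family.scheme), family.scheme
        )
        diff = np.abs(
            cand.model.coords(("N", "CA", "C"))
            - family.template.coords(("N", "CA", "C"))
        ).max()
        assert diff < 1e-3
        assert cand.model.seq == family.template.seq

    def test_identity_recipe_composes_template_pssm(self, toy_family, toy_db):
        family, _ = toy_family
        tmpl = family.template
        pssms = {tmpl.source_id: build_pssm(MSA(names=["t"], rows=[tmpl.seq]))}
        cand = assemble(
            tmpl, toy_db, _template_recipe(family.scheme), family.scheme, pssms=pssms
        )
        np.testing.assert_array_equal(cand.pssm.scores, pssms["template"].scores)
        assert cand.pssm.ref_seq == tmpl.seq

    def test_replacement_is_segment_local(self, toy_family, toy_db):
        family, _ = toy_family
        scheme = family.scheme
        names = scheme.segment_names
        choices = {n: "template" for n in names}
        choices[names[1]] = 0
        cand = assemble(
            family.template, toy_db, AssemblyRecipe.from_dict(choices), scheme
        )
        ct = extract_torsions(cand.model)
        tt = extract_torsions(family.template)
        seg1 = scheme.segment(names[0])
        seg3 = scheme.segment(names[2])
        rec = toy_db.accepted(names[1])[0]
        offset = rec.fragment.n_res - (
            scheme.segment(names[1]).end - scheme.segment(names[1]).start + 1
        )
        for i in range(seg1.start + 1, seg1.end):
            assert angdiff(ct[i].phi, tt[i].phi) < 1e-6
            assert angdiff(ct[i].psi, tt[i].psi) < 1e-6
        for i in range(seg3.start + 1, seg3.end):
            assert angdiff(ct[i + offset].phi, tt[i].phi) < 1e-6

    def test_residue_count_arithmetic(self, toy_family, toy_db):
        # model length = framework outside the segments + fragment lengths
        # with each shared anchor counted once
        family, _ = toy_family
        scheme = family.scheme
        names = scheme.segment_names
        recipe = AssemblyRecipe.from_dict({n: 0 for n in names})
        cand = assemble(family.template, toy_db, recipe, scheme)
        frag_lens = [toy_db.accepted(n)[0].fragment.n_res for n in names]
        shared = len(names) - 1
        prefix = scheme.anchors[0]
        suffix = len(family.template) - 1 - scheme.anchors[-1]
        assert len(cand.model) == prefix + sum(frag_lens) - shared + suffix

    def test_candidates_are_continuous(self, toy_family, toy_db):
        family, _ = toy_family
        for recipe in enumerate_or_sample(toy_db, 6, seed=2):
            cand = assemble(family.template, toy_db, recipe, scheme=family.scheme)
            for i in range(1, len(cand.model)):
                d = np.linalg.norm(
                    cand.model.residues[i].coord("N")
                    - cand.model.residues[i - 1].coord("C")
                )
                assert 1.2 <= d <= 1.5

    def test_missing_choice_rejected(self, toy_family, toy_db):
        family, _ = toy_family
        with pytest.raises(AssemblyError, match="lacks choices"):
            assemble(
                family.template,
                toy_db,
                AssemblyRecipe(choices=(("1", 0),)),
                family.scheme,
            )


class TestCounting:
    def test_twenty_per_segment_yields_160000(self):
        assert count_assemblies(_dummy_db([20, 20, 20, 20])) == 160_000

    def test_single_choice(self):
        assert count_assemblies(_dummy_db([1, 1, 1])) == 1

    def test_mixed_counts(self):
        assert count_assemblies(_dummy_db([3, 5, 2])) == 30

    def test_empty_segment_raises(self):
        db = _dummy_db([3, 2])
        db.segments["2"] = []
        with pytest.raises(AssemblyError, match="2"):
            count_assemblies(db)

    def test_count_matches_enumeration(self, toy_db):
        recipes = enumerate_or_sample(toy_db, 10**9, seed=0)
        assert len(recipes) == count_assemblies(toy_db)
        assert len({r.choices for r in recipes}) == len(recipes)


class TestEnumerateOrSample:
    def test_small_space_fully_enumerated_lexicographic(self):
        db = _dummy_db([2, 2])
        recipes = enumerate_or_sample(db, 10, seed=0)
        labels = [r.label() for r in recipes]
        assert labels == ["1=0|2=0", "1=0|2=1", "1=1|2=0", "1=1|2=1"]

    def test_seed_determinism(self):
        db = _dummy_db([4, 4, 4])
        a = enumerate_or_sample(db, 3, seed=9)
        b = enumerate_or_sample(db, 3, seed=9)
        assert [r.choices for r in a] == [r.choices for r in b]

    def test_large_space_distinct_sample(self):
        db = _dummy_db([20, 20, 20, 20])
        recipes = enumerate_or_sample(db, 3000, seed=1)
        assert len(recipes) == 3000
        assert len({r.choices for r in recipes}) == 3000


class TestCatalytic:
    def test_template_recipe_preserves_catalytic_geometry(self, toy_family, toy_db):
        family, gt = toy_family
        cand = assemble(
            family.template, toy_db, _template_recipe(family.scheme), family.scheme
        )
        constraint = CatalyticConstraint(positions=gt.catalytic_positions)
        assert check_catalytic(cand, family.template, constraint, family.scheme)
        assert cand.catalytic_ok is True

    def test_infinite_tolerance_always_true(self, toy_family, toy_db):
        family, gt = toy_family
        recipe = AssemblyRecipe.from_dict(
            {n: 0 for n in family.scheme.segment_names}
        )
        cand = assemble(family.template, toy_db, recipe, family.scheme)
        constraint = CatalyticConstraint(
            positions=gt.catalytic_positions, tolerance=np.inf
        )
        assert check_catalytic(cand, family.template, constraint, family.scheme)

    def test_position_on_replaced_segment_fails_with_reason(self, toy_family, toy_db):
        # a catalytic position inside a replaced loop no longer exists in the
        # assembly: the check must fail and name the position
        family, gt = toy_family
        scheme = family.scheme
        names = scheme.segment_names
        seg = scheme.segment(names[1])
        loop_pos = (seg.start + seg.end) // 2
        choices = {n: "template" for n in names}
        choices[names[1]] = next(
            i
            for i, r in enumerate(toy_db.accepted(names[1]))
            if gt.group_labels[(r.fragment.source_id, names[1])] != 0
        )
        cand = assemble(
            family.template, toy_db, AssemblyRecipe.from_dict(choices), scheme
        )
        constraint = CatalyticConstraint(positions=(loop_pos,))
        assert not check_catalytic(cand, family.template, constraint, scheme)
        assert str(loop_pos) in cand.failure_reason


class TestStericScreen:
    def _candidate(self, model):
        from bbassembly.assembly import DesignCandidate

        return DesignCandidate(
            recipe=AssemblyRecipe(choices=()), model=model
        )

    def test_extended_chain_has_no_clashes(self):
        n = 20
        tors = [
            TorsionTriple(
                -140.0 if i > 0 else None,
                140.0 if i < n - 1 else None,
                180.0 if i < n - 1 else None,
            )
            for i in range(n)
        ]
        model = rebuild_backbone(tors, "A" * n)
        assert steric_screen(self._candidate(model)) == 0

    def test_compact_fold_can_clash(self, toy_family, toy_db):
        # at a generous cutoff some pair in a compact backbone must be close
        family, _ = toy_family
        cand = assemble(
            family.template, toy_db, _template_recipe(family.scheme), family.scheme
        )
        assert steric_screen(cand, cutoff=6.0) >= 1

    def test_matches_all_pairs_oracle(self, toy_family, toy_db):
        family, _ = toy_family
        for recipe in enumerate_or_sample(toy_db, 3, seed=4):
            cand = assemble(family.template, toy_db, recipe, family.scheme)
            for cutoff in (2.5, 4.0):
                count = steric_screen(cand, cutoff=cutoff)
                atoms, res_idx = [], []
                for i, res in enumerate(cand.model.residues):
                    for nm in ("N", "CA", "C", "O", "CB"):
                        if res.has(nm):
                            atoms.append(res.coord(nm))
                            res_idx.append(i)
                oracle = sum(
                    1
                    for a, b in itertools.combinations(range(len(atoms)), 2)
                    if abs(res_idx[a] - res_idx[b]) >= 3
                    and np.linalg.norm(atoms[a] - atoms[b]) < cutoff
                )
                assert count == oracle
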