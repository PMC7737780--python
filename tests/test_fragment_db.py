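"""Graft-and-close, the database gate, fragment rmsd and clustering."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from bbassembly.fragment_db import (
    DatabaseVersionError,
    FragmentRecord,
    fragment_rmsd,
    fragment_rmsd_detail,
    cluster_fragments,
    gate_fragment,
    graft_and_close,
    load_db,
    save_db,
)
from bbassembly.segmentation import Fragment, TemplateAlignment, extract_fragment
from bbassembly.structure_io import TorsionTriple


def _own_fragment(family, name):
    tmpl, scheme = family.template, family.scheme
    aln = TemplateAlignment(
        homolog_id="template",
        pairs=[(i, i) for i in range(len(tmpl))],
        anchor_map={a: a for a in scheme.anchors},
    )
    return extract_fragment(tmpl, aln, name, scheme)


class TestGraftAndClose:
    def test_identity_graft_zero_rmsd(self, toy_family):
        family, _ = toy_family
        frag = _own_fragment(family, family.scheme.segment_names[1])
        result = graft_and_close(family.template, frag, family.scheme)
        assert result.converged
        assert result.closure_rmsd < 1e-6
        # full model reproduces the template
        diff = np.abs(
            result.model.coords(("N", "CA", "C"))
            - family.template.coords(("N", "CA", "C"))
        ).max()
        assert diff < 1e-6

    def test_small_perturbations_pass_gate(self, gate_db):
        records = [r for recs in gate_db.segments.values() for r in recs]
        assert len(records) >= 20
        passed = sum(r.closure_rmsd <= 0.2 for r in records)
        assert passed / len(records) >= 0.95
        for r in records:
            if r.accepted:
                assert r.closure_rmsd < 0.2

    def test_incompatible_end_frame_rejected(self, toy_family):
        # a conformation whose unclosed end lands far from the template
        # anchor: closing it must distort it past the gate
        family, _ = toy_family
        name = family.scheme.segment_names[1]
        frag = _own_fragment(family, name)
        twisted = list(frag.torsions)
        mid = len(twisted) // 2
        twisted[mid] = TorsionTriple(
            phi=twisted[mid].phi + 150.0, psi=twisted[mid].psi - 120.0, omega=180.0
        )
        bad = replace(frag, torsions=twisted, source_id="twisted", coords=None)
        unclosed = graft_and_close(
            family.template, bad, family.scheme, max_sweeps=0
        )
        assert unclosed.end_gap > 5.0  # fixture sanity: truly incompatible
        result = graft_and_close(family.template, bad, family.scheme)
        record = gate_fragment(
            FragmentRecord(
                fragment=bad,
                closure_rmsd=result.closure_rmsd,
                converged=result.converged,
                closed_torsions=result.closed_torsions,
            )
        )
        assert record.accepted is False


class TestGate:
    @pytest.mark.parametrize(
        "rmsd,threshold,expected",
        [
            (0.19, 0.2, True),
            (0.2, 0.2, False),  # strict inequality at the boundary
            (0.05, 0.0, False),
            (0.0, 0.0, False),
        ],
    )
    def test_strict_threshold(self, rmsd, threshold, expected):
        record = FragmentRecord(
            fragment=Fragment(
                source_id="x",
                segment_name="s",
                seq="AA",
                torsions=[TorsionTriple(None, 0.0, 180.0), TorsionTriple(0.0, None, None)],
                end_frames=np.zeros((2, 3, 3)),
            ),
            closure_rmsd=rmsd,
            converged=True,
        )
        assert gate_fragment(record, threshold).accepted is expected

    def test_unconverged_never_accepted(self):
        record = FragmentRecord(
            fragment=Fragment(
                source_id="x",
                segment_name="s",
                seq="AA",
                torsions=[TorsionTriple(None, 0.0, 180.0), TorsionTriple(0.0, None, None)],
                end_frames=np.zeros((2, 3, 3)),
            ),
            closure_rmsd=0.0,
            converged=False,
        )
        assert gate_fragment(record, 0.2).accepted is False


class TestFragmentRmsd:
    def test_self_is_zero(self, toy_fragments):
        assert fragment_rmsd(toy_fragments[0], toy_fragments[0]) < 1e-12

    def test_rigid_rotation_is_zero(self, toy_fragments):
        frag = toy_fragments[0]
        theta = np.radians(40.0)
        R = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        moved = replace(
            frag, coords=frag.coords @ R.T + 5.0, end_frames=frag.end_frames @ R.T + 5.0
        )
        assert fragment_rmsd(frag, moved) < 1e-9

    def test_symmetry(self, toy_fragments):
        a, b = toy_fragments[0], toy_fragments[3]
        assert fragment_rmsd(a, b) == pytest.approx(fragment_rmsd(b, a), abs=1e-9)

    def test_unequal_lengths_match_offset_oracle(self, toy_fragments):
        from bbassembly.geometry import superposed_rmsd

        names = {f.segment_name for f in toy_fragments}
        pairs = []
        for name in names:
            group = [f for f in toy_fragments if f.segment_name == name]
            pairs += [
                (a, b)
                for a, b in itertools.combinations(group, 2)
                if a.n_res != b.n_res
            ]
        assert pairs, "fixture should contain unequal-length fragments"
        for a, b in pairs[:4]:
            short, long_ = (a, b) if a.n_res <= b.n_res else (b, a)
            # independent oracle: enumerate all ungapped offsets explicitly
            best = np.inf
            p = short.n_res
            for off in range(long_.n_res - p + 1):
                sa = short.coords.reshape(-1, 3)
                sb = long_.coords[off : off + p].reshape(-1, 3)
                mask = np.isfinite(sa).all(axis=1) & np.isfinite(sb).all(axis=1)
                best = min(best, superposed_rmsd(sa[mask], sb[mask]))
            rmsd, _, ldiff = fragment_rmsd_detail(a, b)
            assert rmsd == pytest.approx(best, abs=1e-9)
            assert ldiff == abs(a.n_res - b.n_res)

    def test_empty_fragment_raises(self, toy_fragments):
        with pytest.raises(Exception):
            fragment_rmsd_detail(
                replace(toy_fragments[0], seq="", torsions=[], coords=None),
                toy_fragments[0],
            )


def brute_force_complete_linkage(dm, radius):
    """O(n^3) agglomerative oracle: merge the closest pair of clusters whose
    *maximum* inter-cluster distance is minimal, until it exceeds radius."""
    clusters = [{i} for i in range(len(dm))]
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(dm[a, b] for a in clusters[i] for b in clusters[j])
            if best is None or d < best[0]:
                best = (d, i, j)
        if best[0] > radius:
            break
        d, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return clusters


class TestClustering:
    def test_single_fragment(self, toy_fragments):
        ca = cluster_fragments([toy_fragments[0]], radius=1.0)
        assert ca.labels == {0: 0}
        assert ca.representatives == {0: 0}

    def test_two_tight_bundles(self, toy_fragments, toy_family):
        family, gt = toy_family
        name = family.scheme.segment_names[0]
        frs = [f for f in toy_fragments if f.segment_name == name]
        two_groups = [
            f for f in frs if gt.group_labels[(f.source_id, name)] in (0, 1)
        ]
        ca = cluster_fragments(two_groups, radius=1.0)
        assert len(set(ca.labels.values())) == 2
        for i, f in enumerate(two_groups):
            for j, g in enumerate(two_groups):
                same_planted = (
                    gt.group_labels[(f.source_id, name)]
                    == gt.group_labels[(g.source_id, name)]
                )
                assert (ca.labels[i] == ca.labels[j]) == same_planted

    def test_matches_brute_force_oracle(self, toy_fragments):
        frs = toy_fragments[:8]
        n = len(frs)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = fragment_rmsd(frs[i], frs[j])
        for radius in (0.5, 1.0, 2.5, 5.0):
            ca = cluster_fragments(frs, radius=radius)
            oracle = brute_force_complete_linkage(dm, radius)
            ours = {}
            for idx, lab in ca.labels.items():
                ours.setdefault(lab, set()).add(idx)
            assert sorted(map(sorted, ours.values())) == sorted(
                map(sorted, oracle)
            )

    def test_permutation_invariance(self, toy_fragments):
        frs = toy_fragments[:6]
        ca1 = cluster_fragments(frs, radius=1.0)
        perm = [3, 1, 5, 0, 2, 4]
        ca2 = cluster_fragments([frs[i] for i in perm], radius=1.0)
        # same partition of the underlying fragments
        part1 = {}
        for idx, lab in ca1.labels.items():
            part1.setdefault(lab, set()).add(id(frs[idx]))
        part2 = {}
        for idx, lab in ca2.labels.items():
            part2.setdefault(lab, set()).add(id(frs[perm[idx]]))
        assert sorted(map(sorted, part1.values())) == sorted(map(sorted, part2.values()))

    def test_representative_minimizes_mean_rmsd(self, toy_fragments):
        frs = toy_fragments[:8]
        ca = cluster_fragments(frs, radius=1.0)
        for cid, rep in ca.representatives.items():
            members = [i for i, l in ca.labels.items() if l == cid]
            assert rep in members
            mean_rmsd = lambda i: np.mean(
                [fragment_rmsd(frs[i], frs[j]) for j in members]
            )
            assert mean_rmsd(rep) <= min(mean_rmsd(i) for i in members) + 1e-9


class TestPersistence:
    def test_round_trip(self, toy_db, tmp_path):
        save_db(toy_db, tmp_path / "db")
        loaded = load_db(tmp_path / "db")
        assert loaded.segment_names == toy_db.segment_names
        for name in toy_db.segment_names:
            for a, b in zip(toy_db.segments[name], loaded.segments[name]):
                assert a.accepted == b.accepted
                assert a.closure_rmsd == pytest.approx(b.closure_rmsd, abs=1e-6)
                assert a.fragment.seq == b.fragment.seq
                for ta, tb in zip(a.fragment.torsions, b.fragment.torsions):
                    for x, y in ((ta.phi, tb.phi), (ta.psi, tb.psi), (ta.omega, tb.omega)):
                        if x is None:
                            assert y is None
                        else:
                            assert abs(x - y) <= 0.001

    def test_deterministic_bytes(self, toy_db, tmp_path):
        save_db(toy_db, tmp_path / "a")
        save_db(toy_db, tmp_path / "b")
        for rel in ["metadata.json"] + [
            f"segments/{n}.jsonl" for n in toy_db.segment_names
        ]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()

    def test_version_mismatch_raises(self, toy_db, tmp_path):
        import json

        save_db(toy_db, tmp_path / "db")
        meta_path = tmp_path / "db" / "metadata.json"
        meta = json.loads(meta_path.read_text())
        meta["version"] = "999"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(DatabaseVersionError, match="999"):
            load_db(tmp_path / "db")

    def test_missing_segment_file_raises(self, toy_db, tmp_path):
        save_db(toy_db, tmp_path / "db")
        name = toy_db.segment_names[0]
        (tmp_path / "db" / "segments" / f"{name}.jsonl").unlink()
        with pytest.raises(FileNotFoundError, match=name):
            load_db(tmp_path / "db")
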