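"""Clonality, shared-variant relatedness and lineage-scenario QC."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subclonesig import (
    LineageManifest,
    MutationRecord,
    check_lineage,
    clonality_check,
    expected_vaf,
    on_target_edit_check,
    shared_variant_matrix,
)
from subclonesig.errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingSampleError,
)


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "ploidy,copies,value",
        [(2, 1, 0.5), (1, 1, 1.0), (3, 1, 1 / 3), (4, 2, 0.5)],
    )
    def test_values(self, ploidy, copies, value):
        assert float(expected_vaf(ploidy, copies)) == pytest.approx(value)

    @given(st.integers(1, 12), st.integers(1, 12))
    @settings(derandomize=True)
    def test_exact_rational(self, ploidy, copies):
        if copies > ploidy:
            with pytest.raises(InvalidInputError):
                expected_vaf(ploidy, copies)
        else:
            assert expected_vaf(ploidy, copies) * ploidy == Fraction(copies)


class TestClonality:
    def _binomial_vafs(self, rng, n, depth, p):
        return rng.binomial(depth, p, size=n) / depth

    def test_pure_clone_is_clonal(self):
        rng = np.random.default_rng(101)
        vafs = self._binomial_vafs(rng, 200, 30, 0.5)
        rep = clonality_check(vafs, [30] * 200, ploidy=2)
        assert rep.verdict == "clonal"
        assert rep.expected_vaf == 0.5

    def test_equal_mixture_flagged_polyclonal(self):
        # half the mutations private to one of two mixed clones (cell
        # fraction 0.5 -> read-level p 0.25)
        rng = np.random.default_rng(102)
        vafs = np.concatenate(
            [
                self._binomial_vafs(rng, 100, 30, 0.5),
                self._binomial_vafs(rng, 100, 30, 0.25),
            ]
        )
        rep = clonality_check(vafs, [30] * 200, ploidy=2)
        assert rep.verdict == "polyclonal_suspect"
        assert "falsely elevated mutation burden" in rep.note

    def test_too_few_mutations_is_inconclusive(self):
        with pytest.raises(InsufficientDataError):
            clonality_check([0.5] * 5, [30] * 5, ploidy=2)

    def test_type_one_error_controlled(self):
        """On pure clones the false-flag rate stays at/below the alpha level."""
        rng = np.random.default_rng(103)
        flags = 0
        for _ in range(1000):
            vafs = self._binomial_vafs(rng, 60, 30, 0.5)
            rep = clonality_check(vafs, [30] * 60, ploidy=2)
            flags += rep.verdict == "polyclonal_suspect"
        assert flags / 1000 <= 0.005


class TestSharedVariantMatrix:
    def test_small_example(self):
        m = shared_variant_matrix(
            {"A": {("c", 1, "A", "T"), ("c", 2, "C", "G")},
             "B": {("c", 1, "A", "T"), ("c", 3, "G", "C")}}
        )
        assert m.pair("A", "B") == 1
        assert list(m.burdens) == [2, 2]

    def test_identical_and_disjoint_sets(self):
        s = {("c", i, "A", "T") for i in range(10)}
        m = shared_variant_matrix({"A": s, "B": set(s), "C": set()})
        assert m.pair("A", "B") == 10 == m.pair("A", "A")
        assert m.pair("A", "C") == 0

    @given(st.lists(st.sets(st.integers(0, 30), max_size=20),
                    min_size=2, max_size=5))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_and_bounds(self, sets):
        named = {f"s{i}": {("c", v, "A", "T") for v in vs}
                 for i, vs in enumerate(sets)}
        m = shared_variant_matrix(named)
        assert (m.shared == m.shared.T).all()
        for i in range(len(sets)):
            for j in range(len(sets)):
                assert m.shared[i, j] <= min(m.shared[i, i], m.shared[j, j])


def _lineage_fixture(wrong_parent=False, mixed=False):
    """Six subclones, 100 parental + 30 private mutations each."""
    rng = np.random.default_rng(7)
    def keys(n, tag):
        return {("c", int(p), tag, "T")
                for p in rng.choice(10**6, size=n, replace=False)}

    parental_a = keys(100, "A")
    parental_b = keys(100, "B")
    sets = {"GP": set(), "P1": set(parental_a)}
    children = []
    second = {1, 2, 4}  # 0-based: subclones 2, 3 and 5 from the other lineage
    for j in range(6):
        sid = f"S{j+1}"
        base = parental_b if (mixed and j in second) else parental_a
        sets[sid] = base | keys(30, sid)
        children.append(sid)
    if wrong_parent:
        sets["P1"] = keys(100, "W")  # unrelated clone sequenced as the parent
    manifest = LineageManifest(
        grandparent_id="GP", parents=["P1"], children={"P1": children},
        condition={s: "control" for s in children},
    )
    return shared_variant_matrix(sets), manifest


class TestCheckLineage:
    def test_consistent_family(self):
        matrix, manifest = _lineage_fixture()
        res = check_lineage(matrix, manifest)["P1"]
        assert res.scenario == "consistent"
        assert all(c == 1.0 for c in res.containment.values())
        assert all(p == 30 for p in res.private.values())

    def test_wrong_parent_detected(self):
        matrix, manifest = _lineage_fixture(wrong_parent=True)
        assert check_lineage(matrix, manifest)["P1"].scenario == "wrong_parent"

    def test_mixed_parental_groups_recovered(self):
        matrix, manifest = _lineage_fixture(mixed=True)
        res = check_lineage(matrix, manifest)["P1"]
        assert res.scenario == "mixed_parental"
        groups = {frozenset(g) for g in res.sibling_groups}
        assert groups == {
            frozenset({"S1", "S4", "S6"}),
            frozenset({"S2", "S3", "S5"}),
        }

    def test_missing_parent_raises(self):
        matrix, manifest = _lineage_fixture()
        bad = LineageManifest(
            grandparent_id="GP", parents=["P9"],
            children={"P9": manifest.children["P1"]},
            condition=manifest.condition,
        )
        with pytest.raises(MissingSampleError):
            check_lineage(matrix, bad)


class TestOnTargetEdit:
    def _del(self, pos, seq="TT"):
        return MutationRecord("s", "chr1", pos, seq, "", "DEL")

    def _snv(self, pos):
        return MutationRecord("s", "chr1", pos, "C", "T", "SBS")

    def test_indel_inside_window(self):
        verdict, hits = on_target_edit_check([self._del(150)], "chr1", 100, 200)
        assert verdict == "edited" and len(hits) == 1

    def test_only_snvs_is_not_edited(self):
        verdict, hits = on_target_edit_check(
            [self._snv(150), self._snv(160)], "chr1", 100, 200
        )
        assert verdict == "not_edited" and not hits

    def test_indel_one_bp_outside_closed_window(self):
        verdict, _ = on_target_edit_check([self._del(201, "T")], "chr1", 100, 200)
        assert verdict == "not_edited"
        verdict, _ = on_target_edit_check([self._del(200, "T")], "chr1", 100, 200)
        assert verdict == "edited"

    def test_malformed_interval(self):
        with pytest.raises(InvalidInputError):
            on_target_edit_check([], "chr1", 200, 100)
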