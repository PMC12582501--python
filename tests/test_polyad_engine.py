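"""Criteria, scoring, conflict resolution and order standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polyads as pl
from polyads.polyad_engine import (Polyad, Thresholds, classify_polyad,
                                   criterion_connectivity, criterion_height,
                                   criterion_planarity, criterion_proximity,
                                   enumerate_candidates, resolve_conflicts,
                                   score_candidate, standardize_order)
from polyads.tetrad_core import build_stacks, find_tetrads

from .conftest import graph_of, run_on

TH = Thresholds()


@pytest.fixture(scope="module")
def hexad_candidates():
    """Two measured, passing candidates from the ideal hexad fixture."""
    pdb, _ = pl.make_polyad_fixture(pl.spec_for_order(6))
    import pathlib
    import tempfile
    p = pathlib.Path(tempfile.mkdtemp()) / "h.pdb"
    p.write_text(pdb)
    structure = pl.read_structure(p)
    graph, frames = graph_of(structure)
    tetrad = find_tetrads(graph, frames)[0]
    cands = enumerate_candidates(tetrad, structure, graph, frames, TH,
                                 set(tetrad.members))
    assert len(cands) == 2
    return cands


def clone_with(cand, **overrides):
    import copy
    c = copy.copy(cand)
    c.passed = {}
    c.score = None
    for k, v in overrides.items():
        setattr(c, k, v)
    return c


def test_enumeration_counts(tmp_pdb):
    st, _, _ = tmp_pdb(pl.spec_for_order(4))  # lone tetrad
    graph, frames = graph_of(st)
    tetrad = find_tetrads(graph, frames)[0]
    assert enumerate_candidates(tetrad, st, graph, frames, TH,
                                set(tetrad.members)) == []


def test_far_residue_not_enumerated(tmp_pdb):
    st, _, _ = tmp_pdb(pl.FixtureSpec(
        extensions=[pl.ExtensionSpec(base="A", radial_offset=10.0)]))
    graph, frames = graph_of(st)
    tetrad = find_tetrads(graph, frames)[0]
    assert enumerate_candidates(tetrad, st, graph, frames, TH,
                                set(tetrad.members)) == []


class TestConnectivity:
    def test_two_pairs(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], con_count=2, pair_count=2)
        assert criterion_connectivity(c)

    def test_one_pair_one_sequential(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], con_count=2, pair_count=1)
        assert criterion_connectivity(c)

    def test_single_connection_fails(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], con_count=1, pair_count=1)
        assert not criterion_connectivity(c)

    def test_fixture_extension_has_pair_plus_sequential(self, hexad_candidates):
        for c in hexad_candidates:
            assert (c.con_count, c.pair_count) == (2, 1)


class TestPlanarity:
    @pytest.mark.parametrize("tilts, expected", [
        ([30, 35, 30, 35], True),     # mean 32.5, max 35
        ([45, 45, 45, 45], False),    # mean 45 > 40
        ([30, 30, 30, 55], False),    # mean fine, max 55 > 50
    ])
    def test_gates(self, hexad_candidates, tilts, expected):
        c = clone_with(hexad_candidates[0], tilts=[float(t) for t in tilts])
        assert criterion_planarity(c, TH) is expected


class TestProximity:
    def test_inside_gates(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], centroid_dist=12.9,
                       member_dists=[6.0, 6.5, 11.0, 12.0])
        assert criterion_proximity(c, TH)

    def test_centroid_distance_gate(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], centroid_dist=13.1)
        assert not criterion_proximity(c, TH)

    def test_two_nearest_spread_gate(self, hexad_candidates):
        c = clone_with(hexad_candidates[0], centroid_dist=8.0,
                       member_dists=[5.0, 7.5, 11.0, 12.0])
        assert not criterion_proximity(c, TH)


class TestHeight:
    def test_inside_gates(self, hexad_candidates):
        c = clone_with(hexad_candidates[0],
                       dh_in=[3.0] * 4, dh_out=[-3.0] * 4)
        assert criterion_height(c, TH)

    def test_single_probe_exceeds_max(self, hexad_candidates):
        c = clone_with(hexad_candidates[0],
                       dh_in=[3.0, 3.0, 3.0, 3.8], dh_out=[1.0] * 4)
        assert not criterion_height(c, TH)

    def test_outer_probe_mean_gate(self, hexad_candidates):
        c = clone_with(hexad_candidates[0],
                       dh_in=[1.0] * 4, dh_out=[3.5] * 4)
        assert not criterion_height(c, TH)


class TestScore:
    def test_zero_margin_score_is_pair_count(self, hexad_candidates):
        c = clone_with(hexad_candidates[0],
                       tilts=[40.0] * 4, dh_in=[3.15] * 4, dh_out=[3.15] * 4,
                       pair_count=2, con_count=2)
        # max-tilt margin 10 and max-height margin 0.55 remain; force them too
        c.tilts = [30.0, 30.0, 30.0, 50.0]
        c.tilts = [40.0] * 4
        th = Thresholds(tt_avg=40, tt_max=40, ht_avg=3.15, ht_max=3.15)
        c.passed = {k: True for k in ("connectivity", "planarity",
                                      "proximity", "height")}
        assert score_candidate(c, th) == pytest.approx(2.0)

    def test_frozen_arithmetic_regression(self, hexad_candidates):
        # tilts {10,10,10,10}, |dh| = 1.0 on both probes, 2 base pairs:
        # margins (30, 40, 2.15, 2.7, 2.15, 2.7) -> hand-evaluated once
        c = clone_with(hexad_candidates[0],
                       tilts=[10.0] * 4, dh_in=[1.0] * 4, dh_out=[1.0] * 4,
                       pair_count=2, con_count=2)
        c.passed = {k: True for k in ("connectivity", "planarity",
                                      "proximity", "height")}
        assert score_candidate(c, TH) == pytest.approx(8525561.67772524)

    def test_monotone_in_mean_tilt(self, hexad_candidates):
        mk = lambda t: clone_with(
            hexad_candidates[0], tilts=[t] * 4, dh_in=[1.0] * 4,
            dh_out=[1.0] * 4, pair_count=2, con_count=2,
            passed={k: True for k in ("connectivity", "planarity",
                                      "proximity", "height")})
        assert score_candidate(mk(30.0), TH) > score_candidate(mk(35.0), TH)

    def test_failed_candidate_rejected(self, hexad_candidates):
        c = clone_with(hexad_candidates[0])
        c.passed = {"connectivity": False}
        with pytest.raises(ValueError):
            score_candidate(c, TH)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(which=st.integers(0, 5), bump=st.floats(0.01, 0.5))
    def test_strictly_monotone_in_each_margin(self, hexad_candidates,
                                              which, bump):
        base = dict(tilts=[20.0] * 4, dh_in=[1.5] * 4, dh_out=[1.5] * 4,
                    pair_count=1, con_count=2,
                    passed={k: True for k in ("connectivity", "planarity",
                                              "proximity", "height")})
        c0 = clone_with(hexad_candidates[0], **base)
        c1 = clone_with(hexad_candidates[0], **base)
        if which == 0:
            c1.tilts = [t - bump for t in c1.tilts]        # mean tilt margin
        elif which == 1:
            c1.tilts = [20.0, 20.0, 20.0, 20.0 - bump]     # max tilt margin
        elif which == 2:
            c1.dh_in = [v - bump * 0.1 for v in c1.dh_in]
        elif which == 3:
            c1.dh_in = [1.5, 1.5, 1.5, 1.5 - bump * 0.1]
        elif which == 4:
            c1.dh_out = [v - bump * 0.1 for v in c1.dh_out]
        else:
            c1.dh_out = [1.5, 1.5, 1.5, 1.5 - bump * 0.1]
        assert score_candidate(c1, TH) > score_candidate(c0, TH)

    def test_extra_pair_adds_exactly_one(self, hexad_candidates):
        base = dict(tilts=[20.0] * 4, dh_in=[1.5] * 4, dh_out=[1.5] * 4,
                    con_count=2,
                    passed={k: True for k in ("connectivity", "planarity",
                                              "proximity", "height")})
        c1 = clone_with(hexad_candidates[0], pair_count=1, **base)
        c2 = clone_with(hexad_candidates[0], pair_count=2, **base)
        assert score_candidate(c2, TH) - score_candidate(c1, TH) == \
            pytest.approx(1.0)


class TestResolveConflicts:
    def _scored(self, cand, tetrad, score, pair_count=1, cdist=8.0):
        c = clone_with(cand, pair_count=pair_count, con_count=2,
                       centroid_dist=cdist)
        c.tetrad = tetrad
        c.score = score
        return c

    def test_best_score_wins(self, hexad_candidates):
        a, b = hexad_candidates
        ta, tb = a.tetrad, b.tetrad
        c_hi = self._scored(a, ta, 8.1)
        c_lo = self._scored(a, tb, 3.2)
        kept = resolve_conflicts([c_hi, c_lo])
        assert kept == [c_hi]

    def test_single_candidate_unchanged(self, hexad_candidates):
        c = self._scored(hexad_candidates[0], hexad_candidates[0].tetrad, 5.0)
        assert resolve_conflicts([c]) == [c]

    def test_tie_breaks_on_pair_count(self, hexad_candidates):
        a = hexad_candidates[0]
        c1 = self._scored(a, a.tetrad, 5.0, pair_count=1)
        c2 = self._scored(a, hexad_candidates[1].tetrad, 5.0, pair_count=2)
        assert resolve_conflicts([c1, c2]) == [c2]


class TestStandardizeOrder:
    def _stack_with(self, tmp_pdb, ext_counts):
        gaps = [0, 2, 1, 3]
        exts = [pl.ExtensionSpec(layer=lay, gap=g)
                for lay, n in enumerate(ext_counts)
                for g in gaps[:n]]
        st, _, _ = tmp_pdb(pl.FixtureSpec(n_layers=len(ext_counts),
                                          extensions=exts))
        return st

    def test_strict_trims_to_minimum(self, tmp_pdb):
        st = self._stack_with(tmp_pdb, [2, 3])
        rep = run_on(st, lax_order=False)
        assert sorted(p.order for p in rep.polyads) == [6, 6]

    def test_lax_keeps_discrepant_orders(self, tmp_pdb):
        st = self._stack_with(tmp_pdb, [2, 3])
        rep = run_on(st, lax_order=True)
        assert sorted(p.order for p in rep.polyads) == [6, 7]
        # lax output is a superset of the strict one
        strict = run_on(st, lax_order=False)
        strict_ext = {c.residue.key for p in strict.polyads
                      for c in p.extensions}
        lax_ext = {c.residue.key for p in rep.polyads for c in p.extensions}
        assert strict_ext <= lax_ext

    def test_equal_orders_untouched(self, tmp_pdb):
        st = self._stack_with(tmp_pdb, [2, 2])
        for lax in (False, True):
            rep = run_on(st, lax_order=lax)
            assert sorted(p.order for p in rep.polyads) == [6, 6]

    def test_plain_tetrad_does_not_force_zero(self, tmp_pdb):
        st = self._stack_with(tmp_pdb, [0, 2])
        rep = run_on(st, lax_order=False)
        assert [p.order for p in rep.polyads] == [6]

    def test_lowest_score_dropped_first(self, tmp_pdb):
        st = self._stack_with(tmp_pdb, [2, 3])
        lax = run_on(st, lax_order=True)
        strict = run_on(st, lax_order=False)
        bigger = next(p for p in lax.polyads if p.order == 7)
        trimmed = next(p for p in strict.polyads
                       if p.tetrad.key == bigger.tetrad.key)
        dropped = ({c.residue.key for c in bigger.extensions}
                   - {c.residue.key for c in trimmed.extensions})
        lowest = min(bigger.extensions, key=lambda c: c.score)
        assert dropped == {lowest.residue.key}


@pytest.mark.parametrize("order, label", [
    (5, "pentad"), (6, "hexad"), (7, "heptad"), (8, "octad"),
])
def test_classification_labels(order, label, hexad_candidates):
    tetrad = hexad_candidates[0].tetrad
    p = Polyad(tetrad=tetrad, extensions=[hexad_candidates[0]] * (order - 4))
    assert classify_polyad(p) == label


def test_candidate_set_monotone_in_every_threshold(tmp_pdb):
    """Loosening any one knob never shrinks the set of passing candidates."""
    st, _, _ = tmp_pdb(pl.spec_for_order(6, noise_sd=0.05, seed=9))
    knobs = ("tt_avg", "tt_max", "ht_avg", "ht_max",
             "dist_in_max", "dist_out_max", "dist_spread_max")

    def passing(th):
        rep = run_on(st, thresholds=th)
        return {(c.residue.key, c.tetrad.key) for p in rep.polyads
                for c in p.extensions}

    for knob in knobs:
        default = getattr(TH, knob)
        sets = []
        for factor in (0.1, 0.5, 1.0, 1.5):
            kwargs = dict(TH.__dict__)
            kwargs[knob] = default * factor
            if kwargs["tt_avg"] > kwargs["tt_max"]:
                kwargs["tt_avg"] = kwargs["tt_max"]
            if kwargs["ht_avg"] > kwargs["ht_max"]:
                kwargs["ht_avg"] = kwargs["ht_max"]
            sets.append(passing(Thresholds(**kwargs)))
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger
        assert sets[-1], f"nothing passes even loose {knob}"


def test_recovery_and_rejection_margins(tmp_pdb):
    """Comfortably-planted polyads are always found; gross violations never.

    Planted tilt 20° (half the mean-tilt gate) with 0.5 Å height keeps all
    measurements well inside the thresholds; tilt at 130% of the max gate
    or height at 130% of the max gate must always be rejected.
    """
    rng = np.random.default_rng(42)
    for _ in range(25):
        seed = int(rng.integers(0, 2**31 - 1))
        st, truth, _ = tmp_pdb(pl.FixtureSpec(
            noise_sd=0.1, seed=seed,
            extensions=[pl.ExtensionSpec(gap=0, tilt=20.0),
                        pl.ExtensionSpec(gap=2, tilt=20.0)]))
        rep = run_on(st)
        got = sorted((p.order, sorted(c.residue.key for c in p.extensions))
                     for p in rep.polyads)
        assert got == [(6, truth.polyads[0]["extensions"])]

        st_bad, _, _ = tmp_pdb(pl.FixtureSpec(
            noise_sd=0.1, seed=seed,
            extensions=[pl.ExtensionSpec(gap=0, tilt=65.0)]))
        assert run_on(st_bad).polyads == []

        st_high, _, _ = tmp_pdb(pl.FixtureSpec(
            noise_sd=0.1, seed=seed,
            extensions=[pl.ExtensionSpec(gap=0, height=4.8)]))
        assert run_on(st_high).polyads == []
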