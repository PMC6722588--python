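"""Specialization indices, niche overlap and HITS centrality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aroidnet.metrics import (
    dprime,
    h2_extrema,
    h2prime,
    hits_scores,
    mean_niche_overlap,
    morisita_horn,
    shannon_h2,
)
from aroidnet.webs import InteractionWeb, ValidationError

from conftest import enumerate_tables, table_entropy


def _web(mat):
    mat = np.asarray(mat)
    return InteractionWeb(
        mat,
        tuple(f"s{i}" for i in range(mat.shape[0])),
        tuple(f"h{j}" for j in range(mat.shape[1])),
    )


class TestShannonH2:
    @pytest.mark.parametrize(
        "mat, expected",
        [
            ([[1, 0], [0, 1]], math.log(2)),
            ([[5]], 0.0),
            ([[4, 2], [2, 1]], 1.2730283365896258),  # frozen from direct summation
        ],
    )
    def test_known_values(self, mat, expected):
        web = _web(mat)
        assert shannon_h2(web) == pytest.approx(expected, abs=1e-12)
        # direct-summation oracle
        assert shannon_h2(web) == pytest.approx(table_entropy(web.counts), abs=1e-12)


class TestExtrema:
    def test_two_by_two_against_enumeration(self):
        ents = [table_entropy(t) for t in enumerate_tables([6, 3], [6, 3])]
        h2min, h2max = h2_extrema([6, 3], [6, 3])
        assert h2min == pytest.approx(min(ents), abs=1e-12)
        assert h2max == pytest.approx(max(ents), abs=1e-12)
        assert h2min == pytest.approx(0.6365141682948128)
        assert h2max == pytest.approx(1.2730283365896258)

    def test_permutation_margins_degenerate(self):
        h2min, h2max = h2_extrema([1, 1], [1, 1])
        assert h2min == h2max == pytest.approx(math.log(2))

    def test_mismatched_margins_rejected(self):
        with pytest.raises(ValidationError):
            h2_extrema([2, 2], [1, 1])

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_extrema_bound_every_realizable_table(self, data):
        """H2min <= H2(table) <= H2max for random small margins, with the
        bounds attained according to exhaustive enumeration."""
        n_rows = data.draw(st.integers(2, 3))
        n_cols = data.draw(st.integers(2, 3))
        rows = [data.draw(st.integers(1, 4)) for _ in range(n_rows)]
        m = sum(rows)
        cols = []
        left = m
        for j in range(n_cols - 1):
            c = data.draw(st.integers(1, max(1, left - (n_cols - 1 - j))))
            cols.append(c)
            left -= c
        if left < 1:
            return  # infeasible draw; skip silently
        cols.append(left)
        ents = [table_entropy(t) for t in enumerate_tables(rows, cols)]
        h2min, h2max = h2_extrema(rows, cols)
        assert h2min == pytest.approx(min(ents), abs=1e-9)
        assert h2max == pytest.approx(max(ents), abs=1e-9)


class TestH2Prime:
    def test_fully_packed_table_is_maximally_specialized(self):
        assert h2prime(_web([[6, 0], [0, 3]])) == pytest.approx(1.0)

    def test_proportional_table_is_opportunistic(self):
        assert h2prime(_web([[4, 2], [2, 1]])) == pytest.approx(0.0)

    def test_degenerate_margins_return_zero(self):
        assert h2prime(_web([[1, 1], [1, 1]])) == 0.0


class TestDPrime:
    def test_proportional_row_has_zero_selectivity(self):
        # row 0 uses hosts exactly proportionally to the column totals
        web = _web([[4, 2], [4, 2], [2, 1]])
        res = dprime(web)
        assert res.loc["s0", "d"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["s0", "d_prime"] == 0.0

    def test_single_host_row_kl(self):
        web = _web([[0, 10], [10, 0]])
        res = dprime(web)
        assert res.loc["s0", "d"] == pytest.approx(math.log(2), abs=1e-12)
        assert res.loc["s0", "d_prime"] == pytest.approx(1.0)

    def test_values_bounded_and_complete(self, survey_web):
        res = dprime(survey_web)
        assert res["d_prime"].notna().sum() == survey_web.shape[0]
        assert ((res["d_prime"] >= 0) & (res["d_prime"] <= 1)).all()

    def test_host_axis(self, survey_web):
        res = dprime(survey_web, axis="hosts")
        assert len(res) == survey_web.shape[1]
        assert ((res["d_prime"].dropna() >= 0) & (res["d_prime"].dropna() <= 1)).all()


class TestMorisitaHorn:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((3, 1), (3, 1), 1.0),
            ((5, 0), (0, 5), 0.0),
            ((2, 2), (1, 1), 1.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert morisita_horn(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            morisita_horn((0, 0), (1, 1))

    @settings(deadline=None, max_examples=100)
    @given(
        x=st.lists(st.integers(0, 50), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 50), min_size=2, max_size=6),
        scale=st.integers(1, 20),
    )
    def test_symmetric_and_scale_invariant(self, x, y, scale):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if x.sum() == 0 or y.sum() == 0:
            return
        assert morisita_horn(x, y) == pytest.approx(morisita_horn(y, x), abs=1e-12)
        assert morisita_horn(scale * x, y) == pytest.approx(
            morisita_horn(x, y), rel=1e-9
        )
        assert 0.0 <= morisita_horn(x, y) <= 1.0 + 1e-12


class TestNicheOverlap:
    def test_disjoint_rows(self):
        assert mean_niche_overlap(_web([[1, 0], [0, 1]])) == 0.0

    def test_identical_rows(self):
        assert mean_niche_overlap(_web([[1, 1], [1, 1]])) == pytest.approx(1.0)

    def test_single_species_rejected(self):
        with pytest.raises(ValidationError):
            mean_niche_overlap(_web([[1, 2]]))


class TestHits:
    def test_uniform_web_all_ones(self):
        res = hits_scores(_web([[1, 1], [1, 1]]))
        assert np.allclose(res.hub, 1.0)
        assert np.allclose(res.authority, 1.0)

    def test_single_insect_two_hosts(self):
        res = hits_scores(_web([[1, 1]]))
        assert res.hub.tolist() == [1.0]
        assert np.allclose(res.authority, [1.0, 1.0])

    def test_scale_invariance_and_range(self, survey_web):
        res = hits_scores(survey_web, transform="raw")
        scaled = InteractionWeb(
            survey_web.counts * 7, survey_web.row_labels, survey_web.col_labels
        )
        res2 = hits_scores(scaled, transform="raw")
        assert np.allclose(res.hub, res2.hub, atol=1e-8)
        assert res.hub.max() == 1.0 and res.authority.max() == 1.0
        assert (res.hub >= 0).all() and (res.authority >= 0).all()

    def test_matches_networkx_on_survey_web(self, survey_web):
        """Independent cross-check: HITS on the log-transformed bipartite
        digraph via networkx agrees after renormalization."""
        nx = pytest.importorskip("networkx")
        g = nx.DiGraph()
        counts = survey_web.counts
        for i, r in enumerate(survey_web.row_labels):
            for j, c in enumerate(survey_web.col_labels):
                if counts[i, j] > 0:
                    g.add_edge(r, c, weight=np.log10(counts[i, j]) + 1.0)
        hubs, auths = nx.hits(g, max_iter=5000, tol=1e-12)
        ours = hits_scores(survey_web)
        ref_hub = np.array([hubs[r] for r in survey_web.row_labels])
        ref_auth = np.array([auths[c] for c in survey_web.col_labels])
        assert np.allclose(ours.hub, ref_hub / ref_hub.max(), atol=1e-6)
        assert np.allclose(ours.authority, ref_auth / ref_auth.max(), atol=1e-6)
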