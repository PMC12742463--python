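"""Weighted scoring of the screening matrix: golden values and invariants."""

import numpy as np
import pytest

from troutrisk import (DEFAULT_WEIGHTS, compute_risk_scores, load_trait_table,
                       score_bounds, scores_frame)
from troutrisk.synthetic import TraitTableSpec, generate_trait_table
from troutrisk.trait_matrix import TraitTableError, write_trait_table

from conftest import GOLDEN_TOTALS


class TestGoldenReproduction:
    def test_fixture_shape(self, screening_matrix):
        assert screening_matrix.n_species == 35
        assert screening_matrix.n_factors == 7
        assert tuple(int(w) for w in screening_matrix.weights) == (1, 1, 1, 2, 1, 2, 2)

    def test_all_printed_totals(self, screening_matrix):
        totals = [r.total for r in compute_risk_scores(screening_matrix)]
        assert totals == GOLDEN_TOTALS

    @pytest.mark.parametrize(
        "species, expected",
        [
            ("galaxias_macronasus", 26),   # bignose galaxiid
            ("galaxias_divergens", 22),    # dwarf galaxiid
            ("galaxias_eldoni", 24),       # Eldon's galaxiid
            ("geotria_australis", 12),     # pouched lamprey
        ],
    )
    def test_anchor_species(self, matrix_totals, species, expected):
        assert matrix_totals[species] == expected

    def test_contributions_sum_to_total(self, screening_matrix):
        for r in compute_risk_scores(screening_matrix):
            assert sum(r.contributions.values()) == r.total


class TestScoreBounds:
    @pytest.mark.parametrize(
        "weights, expected",
        [(DEFAULT_WEIGHTS, (10, 30)), ((1,), (1, 3)), ((2, 2), (4, 12))],
    )
    def test_closed_form(self, weights, expected):
        assert score_bounds(weights) == expected

    def test_empty_weights_error(self):
        with pytest.raises(TraitTableError):
            score_bounds([])

    def test_all_totals_within_bounds(self, rng):
        lo, hi = score_bounds(DEFAULT_WEIGHTS)
        for seed in range(5):
            table = generate_trait_table(TraitTableSpec(n_species=20, seed=seed))
            totals = [r.total for r in compute_risk_scores(table)]
            assert all(lo <= t <= hi for t in totals)


class TestInvariants:
    def test_monotone_in_single_cell(self, rng):
        """Raising any one score (within {1,2,3}) never lowers the total."""
        table = generate_trait_table(TraitTableSpec(n_species=10, seed=3))
        base = np.array([r.total for r in compute_risk_scores(table)])
        for _ in range(50):
            i = rng.integers(table.n_species)
            j = rng.integers(table.n_factors)
            if table.scores[i, j] == 3:
                continue
            bumped = table.scores.copy()
            bumped[i, j] += 1
            from troutrisk.trait_matrix import TraitScoreTable

            t2 = TraitScoreTable(table.species, table.factors, bumped)
            new = np.array([r.total for r in compute_risk_scores(t2)])
            assert new[i] >= base[i]
            assert (np.delete(new, i) == np.delete(base, i)).all()

    def test_permutation_equivariance(self, screening_matrix, rng):
        perm = rng.permutation(screening_matrix.n_species)
        from troutrisk.trait_matrix import TraitScoreTable

        shuffled = TraitScoreTable(
            tuple(screening_matrix.species[i] for i in perm),
            screening_matrix.factors,
            screening_matrix.scores[perm],
        )
        base = {r.species: r.total for r in compute_risk_scores(screening_matrix)}
        shuf = {r.species: r.total for r in compute_risk_scores(shuffled)}
        assert base == shuf

    def test_weight_length_mismatch(self, screening_matrix):
        with pytest.raises(TraitTableError):
            compute_risk_scores(screening_matrix, weights=[1, 1, 1])


class TestLoader:
    def _write(self, tmp_path, text):
        p = tmp_path / "t.csv"
        p.write_text(text)
        return p

    def test_round_trip(self, screening_matrix, tmp_path):
        p = tmp_path / "rt.csv"
        write_trait_table(screening_matrix, p)
        again = load_trait_table(p)
        assert again.species == screening_matrix.species
        assert (again.scores == screening_matrix.scores).all()
        assert tuple(int(w) for w in again.weights) == tuple(
            int(w) for w in screening_matrix.weights
        )

    def test_score_outside_domain(self, tmp_path):
        p = self._write(
            tmp_path,
            "species,common_name,f1,f2\nweight,,1,2\nfoo_bar,Foo,1,4\n",
        )
        with pytest.raises(TraitTableError, match="outside"):
            load_trait_table(p)

    def test_empty_file(self, tmp_path):
        with pytest.raises(TraitTableError, match="empty"):
            load_trait_table(self._write(tmp_path, ""))

    def test_missing_cell(self, tmp_path):
        p = self._write(
            tmp_path, "species,common_name,f1,f2\nweight,,1,2\nfoo_bar,Foo,1,\n"
        )
        with pytest.raises(TraitTableError):
            load_trait_table(p)

    def test_duplicate_species(self, tmp_path):
        p = self._write(
            tmp_path,
            "species,common_name,f1\nweight,,1\nfoo_bar,Foo,1\nfoo_bar,Foo,2\n",
        )
        with pytest.raises(TraitTableError, match="duplicate"):
            load_trait_table(p)

    def test_missing_weight_row(self, tmp_path):
        p = self._write(tmp_path, "species,common_name,f1\nfoo_bar,Foo,1\n")
        with pytest.raises(TraitTableError, match="weight"):
            load_trait_table(p)


def test_scores_frame_matches_results(screening_matrix):
    frame = scores_frame(screening_matrix)
    assert list(frame["total"]) == GOLDEN_TOTALS
    assert (frame.drop(columns="total").sum(axis=1) == frame["total"]).all()
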