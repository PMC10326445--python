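"""SIA pool CSPs, normalization, score tables and motif calling."""

import numpy as np
import pandas as pd
import pytest

from rnaae.binding import fit_kd, fraction_bound
from rnaae.csp import CSPProfile, CSPWeights
from rnaae.peaklist import Peak, PeakList
from rnaae.sia import (
    PoolSpec,
    call_motif,
    pool_csps,
    score_table,
    sia_scores,
)
from rnaae.simulate import pool_effective_kd, simulate_titration


def _free_and_bound(shifts_by_base):
    """Build a free list plus per-base bound lists from ¹H offsets."""
    free = PeakList([Peak("G1", 8.0, 110.0)], "free")
    bound = {
        b: PeakList([Peak("G1", 8.0 + dh, 110.0)], f"pool_{b}")
        for b, dh in shifts_by_base.items()
    }
    return free, bound


class TestPoolCSPs:
    def test_identical_lists_give_zero_matrix(self):
        free, bound = _free_and_bound({b: 0.0 for b in "ACGU"})
        mat = pool_csps(free, bound)
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_constructed_single_residue_matrix(self):
        # CSPs (0.02, 0.02, 0.08, 0.04) ppm for A, C, G, U
        targets = {"A": 0.02, "C": 0.02, "G": 0.08, "U": 0.04}
        free, bound = _free_and_bound(
            {b: v * np.sqrt(2.0) for b, v in targets.items()}
        )
        mat = pool_csps(free, bound)
        assert mat.shape == (1, 4)
        for b, v in targets.items():
            assert mat.loc["G1", b] == pytest.approx(v, abs=1e-12)

    def test_residue_missing_from_one_pool_is_dropped(self, caplog):
        free = PeakList([Peak("G1", 8.0, 110.0), Peak("G2", 7.5, 120.0)], "free")
        bound = {
            b: PeakList([Peak("G1", 8.05, 110.0), Peak("G2", 7.55, 120.0)], b)
            for b in "ACG"
        }
        bound["U"] = PeakList([Peak("G1", 8.05, 110.0)], "U")
        with caplog.at_level("WARNING", logger="rnaae.sia"):
            mat = pool_csps(free, bound)
        assert list(mat.index) == ["G1"]
        assert any("G2" in rec.message for rec in caplog.records)

    def test_missing_pool_is_error(self):
        free, bound = _free_and_bound({b: 0.01 for b in "ACG"})
        with pytest.raises(ValueError, match="U"):
            pool_csps(free, bound)


class TestSIAScores:
    def test_per_peak_normalization_single_peak(self):
        mat = pd.DataFrame(
            [[0.02, 0.02, 0.08, 0.04]], index=["G1"], columns=list("ACGU")
        )
        scores = sia_scores(mat, "per_peak")
        assert scores.to_numpy() == pytest.approx([0.25, 0.25, 1.0, 0.5])

    def test_no_discrimination_gives_all_ones(self):
        mat = pd.DataFrame(
            [[0.05] * 4, [0.2] * 4], index=["G1", "G2"], columns=list("ACGU")
        )
        assert sia_scores(mat).to_numpy() == pytest.approx([1.0] * 4)

    def test_shared_maximum_base_scores_exactly_one(self):
        mat = pd.DataFrame(
            [[0.02, 0.03, 0.08, 0.04], [0.01, 0.02, 0.05, 0.03]],
            index=["G1", "G2"],
            columns=list("ACGU"),
        )
        assert sia_scores(mat)["G"] == 1.0

    def test_all_zero_peak_dropped_with_warning(self, caplog):
        mat = pd.DataFrame(
            [[0.0] * 4, [0.02, 0.03, 0.08, 0.04]],
            index=["G1", "G2"],
            columns=list("ACGU"),
        )
        with caplog.at_level("WARNING", logger="rnaae.sia"):
            scores = sia_scores(mat)
        assert scores["G"] == 1.0
        assert any("G1" in rec.message for rec in caplog.records)

    def test_scores_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.uniform(0.01, 0.2, (6, 4)),
            index=[f"G{i}" for i in range(6)],
            columns=list("ACGU"),
        )
        a = sia_scores(mat)
        b = sia_scores(mat * 7.3)
        assert a.to_numpy() == pytest.approx(b.to_numpy(), rel=1e-12)

    def test_scores_invariant_to_csp_formula_variant(self, ae_model):
        # same simulated pool evaluated under both CSP variants
        free = simulate_titration(
            ae_model, "NNNNN", ratios=(0.0,), noise_sd=0.0
        ).reference
        bound = {
            b: simulate_titration(
                ae_model, PoolSpec(2, b), ratios=(0.0, 4.0), noise_sd=0.0
            ).peaklists[1]
            for b in "ACGU"
        }
        rows = {}
        for variant in ("half_sum_sqrt", "scaled_n"):
            w = CSPWeights(variant=variant)
            rows[variant] = sia_scores(pool_csps(free, bound, w))
        assert rows["half_sum_sqrt"].to_numpy() == pytest.approx(
            rows["scaled_n"].to_numpy(), rel=1e-9
        )

    def test_per_pool_normalization_uses_column_maxima(self):
        mat = pd.DataFrame(
            [[0.02, 0.04], [0.04, 0.02]],
            index=["G1", "G2"],
            columns=["A", "C"],
        )
        normed = mat.div(mat.max(axis=0), axis=1).mean(axis=0)
        got = sia_scores(mat[["A", "C"]].assign(G=0.01, U=0.01), "per_pool")
        assert got["A"] == pytest.approx(normed["A"])

    def test_generating_base_scores_one_for_every_peak_noiseless(self, ae_model):
        free = simulate_titration(
            ae_model, "NNNNN", ratios=(0.0,), noise_sd=0.0
        ).reference
        for pos in (1, 2, 3, 4):
            bound = {
                b: simulate_titration(
                    ae_model, PoolSpec(pos, b), ratios=(0.0, 4.0), noise_sd=0.0
                ).peaklists[1]
                for b in "ACGU"
            }
            mat = pool_csps(free, bound)
            normed = mat.div(mat.max(axis=1), axis=0)
            generating = ae_model.reference[pos]
            assert (normed[generating] == 1.0).all()


def _table(rows):
    return score_table(
        {pos: pd.Series(vals, index=list("ACGU")) for pos, vals in rows.items()}
    )


class TestCallMotif:
    def test_ambiguous_positions_reported_with_alternatives(self):
        table = _table(
            {
                1: {"A": 0.95, "C": 0.5, "G": 1.0, "U": 0.4},
                2: {"A": 0.5, "C": 0.55, "G": 1.0, "U": 0.6},
                3: {"A": 0.93, "C": 1.0, "G": 0.5, "U": 0.45},
                4: {"A": 0.6, "C": 1.0, "G": 0.5, "U": 0.55},
            }
        )
        assert call_motif(table) == "nG/A-G-C/A-C"

    def test_kd_refinements_resolve_ambiguity(self, ae_model):
        table = _table(
            {
                1: {"A": 0.95, "C": 0.5, "G": 1.0, "U": 0.4},
                2: {"A": 0.5, "C": 0.55, "G": 1.0, "U": 0.6},
                3: {"A": 0.93, "C": 1.0, "G": 0.5, "U": 0.45},
                4: {"A": 0.6, "C": 1.0, "G": 0.5, "U": 0.55},
            }
        )

        def _fit(oligo):
            from rnaae.csp import csp_profile, match_peaks

            series = simulate_titration(ae_model, oligo, noise_sd=0.0)
            return fit_kd(csp_profile(match_peaks(series)), 50.0)

        refinements = {
            1: {"G": _fit("UGGAC"), "A": _fit("UAGAC")},
            3: {"C": _fit("GAGCC"), "A": _fit("GAGAC")},
        }
        assert call_motif(table, kd_refinements=refinements) == "nGGAC"

    def test_fully_degenerate_table(self):
        table = _table({pos: {b: 1.0 for b in "ACGU"} for pos in (1, 2, 3, 4)})
        assert call_motif(table) == "nN-N-N-N"

    def test_unambiguous_table_compacts(self):
        table = _table(
            {
                1: {"A": 0.5, "C": 0.4, "G": 1.0, "U": 0.4},
                2: {"A": 0.5, "C": 0.4, "G": 1.0, "U": 0.4},
                3: {"A": 1.0, "C": 0.6, "G": 0.5, "U": 0.4},
                4: {"A": 0.5, "C": 1.0, "G": 0.4, "U": 0.4},
            }
        )
        assert call_motif(table) == "nGGAC"

    def test_missing_position_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            score_table({1: pd.Series([1, 1, 1, 1], index=list("ACGU"))})


class TestPoolSpec:
    def test_pattern_places_base_at_oligo_position(self):
        assert PoolSpec(1, "A").oligo_pattern == "NANNN"
        assert PoolSpec(4, "U").oligo_pattern == "NNNNU"

    def test_invalid_position_or_base(self):
        with pytest.raises(ValueError):
            PoolSpec(0, "A")
        with pytest.raises(ValueError):
            PoolSpec(2, "T")
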