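"""GAD scoring, eligibility, sig-GAD calling and condition comparison."""

import math

import numpy as np
import pytest

from gadpipe import (
    ContactMatrix,
    GadRecord,
    GeneModel,
    SigGadParams,
    call_sig_gads,
    compare_gad_scores,
    compute_gad_score,
    map_gene_to_bins,
    score_all_genes,
)
from gadpipe.synthetic import HicSimParams, simulate_contact_matrix

from conftest import make_uniform_matrix


def _record(gene_id, gs, sig=False):
    return GadRecord(gene_id, gs, 1.0, 1.0, gs, 4, True, None, sig)


class TestBinMapping:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            (0, 30_000, (0, 3)),        # exact tiling
            (5_000, 15_000, (0, 2)),    # partial overlaps count
            (29_999, 30_001, (2, 4)),   # straddles a bin boundary
        ],
    )
    def test_bin_ranges(self, uniform_matrix, start, end, expected):
        g = GeneModel("g", "chrS", start, end)
        assert map_gene_to_bins(g, uniform_matrix) == expected

    def test_chrom_mismatch_raises(self, uniform_matrix):
        g = GeneModel("g", "chr2", 0, 40_000)
        with pytest.raises(ValueError, match="does not match"):
            map_gene_to_bins(g, uniform_matrix)


class TestScore:
    def test_uniform_matrix_gives_exactly_one(self, uniform_matrix):
        g = GeneModel("g", "chrS", 200_000, 240_000)
        rec = compute_gad_score(g, uniform_matrix)
        assert rec.eligible and rec.gs == 1.0

    def test_planted_block_matches_brute_force(self):
        # noiseless flat matrix, planted 4-bin block at 3x background
        params = HicSimParams(
            n_bins=100, decay_exponent=0.0, base_intensity=1.0,
            planted_genes=(((300_000, 340_000), 3.0),), noise="none",
        )
        matrix, _, _ = simulate_contact_matrix(params)
        g = GeneModel("pg", "chrS", 300_000, 340_000)
        rec = compute_gad_score(g, matrix)

        # independent oracle: explicit loops over block entries
        def block_mean(lo, hi):
            vals = [
                matrix.values[i, j]
                for i in range(lo, hi)
                for j in range(i + 1, hi)
            ]
            return sum(vals) / len(vals)

        lo, hi = 30, 34
        g_oracle = block_mean(lo, hi)
        gu_oracle = block_mean(lo - 4, lo)
        gd_oracle = block_mean(hi, hi + 4)
        assert rec.g == pytest.approx(g_oracle)
        assert rec.gs == pytest.approx(2 * g_oracle / (gu_oracle + gd_oracle))
        assert rec.gs == pytest.approx(3.0)
        assert rec.gu == pytest.approx(1.0) and rec.gd == pytest.approx(1.0)

    @pytest.mark.parametrize("length", [25_000, 30_000, 20_000])
    def test_short_genes_are_ineligible(self, uniform_matrix, length):
        g = GeneModel("g", "chrS", 200_000, 200_000 + length)
        rec = compute_gad_score(g, uniform_matrix)
        assert not rec.eligible
        assert rec.undefined_reason == "too_short"
        assert math.isnan(rec.gs)

    def test_gene_with_flank_outside_matrix_is_edge(self, uniform_matrix):
        g = GeneModel("g", "chrS", 10_000, 50_000)  # upstream flank leaves
        rec = compute_gad_score(g, uniform_matrix)
        assert rec.eligible and rec.undefined_reason == "edge"

    def test_zero_flanks_undefined(self):
        v = np.zeros((60, 60))
        lo, hi = 20, 24
        v[lo:hi, lo:hi] = 1.0
        np.fill_diagonal(v, 0.0)
        m = ContactMatrix("chrS", 10_000, v)
        rec = compute_gad_score(GeneModel("g", "chrS", 200_000, 240_000), m)
        assert rec.undefined_reason == "zero_flanks"

    def test_scale_invariance(self, uniform_matrix):
        g = GeneModel("g", "chrS", 200_000, 240_000)
        scaled = ContactMatrix("chrS", 10_000, uniform_matrix.values * 7.3)
        assert compute_gad_score(g, scaled).gs == pytest.approx(
            compute_gad_score(g, uniform_matrix).gs
        )

    def test_monotone_in_body_enrichment(self):
        gs = []
        for factor in (1.0, 1.5, 2.0, 4.0):
            params = HicSimParams(
                n_bins=80, decay_exponent=0.5, base_intensity=2.0,
                planted_genes=(((300_000, 340_000), factor),), noise="none",
            )
            matrix, _, _ = simulate_contact_matrix(params)
            rec = compute_gad_score(
                GeneModel("g", "chrS", 300_000, 340_000), matrix
            )
            gs.append(rec.gs)
        assert all(a < b for a, b in zip(gs, gs[1:]))
        assert gs[0] == pytest.approx(1.0)

    def test_flank_symmetry(self):
        # mirroring the matrix swaps Gu and Gd but leaves Gs unchanged
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, (60, 60))
        v = (a + a.T) / 2
        m = ContactMatrix("chrS", 10_000, v)
        mirrored = ContactMatrix("chrS", 10_000, v[::-1, ::-1].copy())
        g = GeneModel("g", "chrS", 280_000, 320_000)  # centred: bins 28..32
        r1 = compute_gad_score(g, m)
        r2 = compute_gad_score(g, mirrored)
        assert r1.gu == pytest.approx(r2.gd) and r1.gd == pytest.approx(r2.gu)
        assert r1.gs == pytest.approx(r2.gs)

    def test_rectangle_flank_mode_on_uniform(self, uniform_matrix):
        g = GeneModel("g", "chrS", 200_000, 240_000)
        rec = compute_gad_score(g, uniform_matrix, flank_mode="rectangle")
        assert rec.gs == pytest.approx(1.0)


class TestScoreAll:
    def test_empty_gene_list(self, uniform_matrix):
        assert score_all_genes([], uniform_matrix) == []

    def test_short_genes_counted(self, uniform_matrix):
        genes = [
            GeneModel(f"g{i}", "chrS", 100_000 + 60_000 * i, 140_000 + 60_000 * i)
            for i in range(5)
        ] + [
            GeneModel(f"s{i}", "chrS", 40_000 * i + 5_000, 40_000 * i + 30_000)
            for i in range(3)
        ]
        records = score_all_genes(genes, uniform_matrix)
        assert len(records) == 8
        short = [r for r in records if r.undefined_reason == "too_short"]
        assert len(short) == 3
        assert [r.gene_id for r in records] == [g.gene_id for g in genes]

    def test_other_chromosome_becomes_undefined(self, uniform_matrix):
        recs = score_all_genes(
            [GeneModel("g", "chr9", 0, 40_000)], uniform_matrix
        )
        assert recs[0].undefined_reason == "edge" and not recs[0].eligible


def brute_force_sig(gs_by_id: dict[str, float], floor: float = 1.0) -> set[str]:
    """Exhaustive evaluation of the rescaled-curve argmin rule."""
    items = sorted(gs_by_id.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    scores = [v for _, v in items]
    lo, hi = min(scores), max(scores)
    if hi == lo:
        return set()
    best_i, best_val = 0, float("inf")
    for i, (_, s) in enumerate(items):
        val = (s - lo) / (hi - lo) - i / (n - 1)
        if val < best_val:
            best_val, best_i = val, i
    return {g for i, (g, s) in enumerate(items) if i > best_i and s > floor}


class TestSigCalling:
    def test_all_below_floor_never_sig(self):
        records = [_record(f"g{i}", 0.9) for i in range(30)]
        called, _ = call_sig_gads(records)
        assert not any(r.sig for r in called)

    def test_flat_curve_calls_nothing(self):
        records = [_record(f"g{i}", 2.0) for i in range(30)]
        called, cutoff = call_sig_gads(records)
        assert not any(r.sig for r in called)
        assert cutoff is None

    def test_single_outlier_is_the_only_sig(self):
        rng = np.random.default_rng(0)
        records = [
            _record(f"g{i:02d}", 1.01 + 1e-4 * rng.standard_normal())
            for i in range(99)
        ] + [_record("hit", 8.0)]
        called, _ = call_sig_gads(records)
        assert {r.gene_id for r in called if r.sig} == {"hit"}

    def test_floor_only_below_min_genes(self):
        records = [_record("a", 0.5), _record("b", 3.0), _record("c", 1.2)]
        called, cutoff = call_sig_gads(records, SigGadParams(min_genes=10))
        assert {r.gene_id for r in called if r.sig} == {"b", "c"}
        assert cutoff == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        records = [_record(f"g{i}", float(s)) for i, s in
                   enumerate(rng.uniform(0.5, 4.0, 40))]
        fwd, cut_f = call_sig_gads(records)
        rev, cut_r = call_sig_gads(records[::-1])
        assert cut_f == cut_r
        assert {r.gene_id for r in fwd if r.sig} == {
            r.gene_id for r in rev if r.sig
        }

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 21))
        gs = {f"g{i:02d}": float(s) for i, s in
              enumerate(rng.uniform(0.3, 5.0, n))}
        records = [_record(g, s) for g, s in gs.items()]
        called, _ = call_sig_gads(records)
        assert {r.gene_id for r in called if r.sig} == brute_force_sig(gs)


class TestCompare:
    def test_identity_gives_zero_deltas(self):
        records = [_record(f"g{i}", 1.0 + 0.1 * i) for i in range(10)]
        table = compare_gad_scores(records, records)
        assert (table["delta_gs"] == 0).all()

    def test_lost_enrichment_has_most_negative_delta(self):
        planted = (((300_000, 340_000), 3.0), ((600_000, 640_000), 3.0))
        pa = HicSimParams(n_bins=100, decay_exponent=0.0, base_intensity=1.0,
                          planted_genes=planted, noise="none")
        pb = HicSimParams(n_bins=100, decay_exponent=0.0, base_intensity=1.0,
                          planted_genes=planted[:1], noise="none")
        ma, genes_a, _ = simulate_contact_matrix(pa)
        mb, _, _ = simulate_contact_matrix(pb)
        ra = score_all_genes(genes_a, ma)
        rb = score_all_genes(genes_a, mb)
        table = compare_gad_scores(ra, rb).set_index("gene_id")
        assert table["delta_gs"].idxmin() == "GAD002"
        assert table.loc["GAD002", "delta_gs"] == pytest.approx(-2.0)

    def test_replicate_groups_get_pvalues(self):
        rng = np.random.default_rng(2)

        def group(shift):
            return [
                [_record(f"g{i}", float(1.0 + shift + 0.05 * rng.standard_normal()))
                 for i in range(6)]
                for _ in range(4)
            ]

        table = compare_gad_scores(group(0.0), group(1.0))
        assert "p" in table.columns
        assert (table["p"] <= 1).all() and (table["p"] > 0).all()
        assert (table["delta_gs"] > 0.5).all()

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError, match="no gene"):
            compare_gad_scores([_record("a", 1.0)], [_record("b", 1.0)])
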