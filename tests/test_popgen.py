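import math

import numpy as np
import pytest

from chimpop import popgen as pg
from chimpop import synthetic_data as sd
from chimpop.chimera_detect import GenotypeRecord
from chimpop.errors import ParameterError
from chimpop.io_formats import SampleMetadata, VariantMatrix

from _oracles import brute_site_diversity, brute_window_stats


def _records(counts: dict[str, int], prefix="s"):
    out, i = [], 0
    for cls, n in counts.items():
        for _ in range(n):
            out.append(GenotypeRecord(f"{prefix}{i:04d}", cls))
            i += 1
    return out


class TestSpeciesFilter:
    def test_printed_species_split(self):
        meta = (
            [SampleMetadata(f"a{i}", "H. armigera", "x") for i in range(999)]
            + [SampleMetadata(f"z{i}", "H. zea", "x") for i in range(59)]
            + [SampleMetadata(f"v{i}", "C. virescens", "x") for i in range(5)]
        )
        kept, counts = pg.species_filter(meta, "H. armigera")
        assert len(kept) == 999
        assert counts == {"H. armigera": 999, "H. zea": 59, "C. virescens": 5}

    def test_empty_table(self):
        kept, counts = pg.species_filter([], "x")
        assert kept == [] and counts == {}

    def test_all_target_identity(self):
        meta = [SampleMetadata(f"s{i}", "t", "x") for i in range(7)]
        kept, _ = pg.species_filter(meta, "t")
        assert kept == meta


class TestGenotypeFrequencyTable:
    def test_printed_global_cohort(self):
        recs = _records({"B3/B3": 878, "B3/par": 91, "par/par": 30})
        table = pg.genotype_frequency_table(recs).genotype_table
        row = table.iloc[0]
        assert row["n"] == 999
        assert round(row["carriage_pct"]) == 97
        assert round(row["pct_B3/B3"]) == 88
        assert round(row["pct_B3/par"]) == 9
        assert round(row["pct_par/par"]) == 3

    def test_single_individual(self):
        table = pg.genotype_frequency_table(_records({"B3/B3": 1})).genotype_table
        row = table.iloc[0]
        assert (row["pct_B3/B3"], row["pct_B3/par"], row["pct_par/par"]) == (
            100.0, 0.0, 0.0)

    def test_random_table_vs_recount(self, rng):
        classes = list(pg.GENOTYPE_CLASSES) + ["unknown"]
        recs = [GenotypeRecord(f"s{i}", classes[rng.integers(4)])
                for i in range(500)]
        regions = {r.sample_id: ["north", "south"][rng.integers(2)] for r in recs}
        meta = [SampleMetadata(sid, "t", reg) for sid, reg in regions.items()]
        table = pg.genotype_frequency_table(
            recs, meta, group_by="region").genotype_table
        # brute-force recount
        for _, row in table.iterrows():
            members = [r for r in recs if regions[r.sample_id] == row["group"]]
            for cls in pg.GENOTYPE_CLASSES:
                n = sum(r.genotype_class == cls for r in members)
                assert row[f"count_{cls}"] == n
            known = sum(r.genotype_class != "unknown" for r in members)
            assert row["n"] == known
            assert row["n_unknown"] == len(members) - known
            carriers = sum(r.genotype_class in ("B3/B3", "B3/par")
                           for r in members)
            assert row["carriage_pct"] == pytest.approx(100 * carriers / known)


class TestAlleleFrequencyTable:
    def test_europe_style_ratio(self):
        recs = []
        for i in range(10):
            recs.append(GenotypeRecord(f"e{i}", "B3/B3", allele_calls=["v2", "v2"]))
        for i in range(10, 17):
            recs.append(GenotypeRecord(f"e{i}", "B3/B3", allele_calls=["v5", "v5"]))
        recs.append(GenotypeRecord("e17", "B3/par", allele_calls=["v5"]))
        recs.append(GenotypeRecord("e18", "B3/par", allele_calls=["v5"]))
        recs.append(GenotypeRecord("e19", "B3/par", allele_calls=["v5"]))
        table = pg.allele_frequency_table(recs).allele_table
        by = table.set_index("allele")
        assert by.loc["v2", "count"] == 20
        assert by.loc["v5", "count"] == 17
        assert round(by.loc["v2", "pct"]) == 54
        assert round(by.loc["v5", "pct"]) == 46

    def test_homozygote_counts_twice(self):
        recs = [GenotypeRecord("s1", "B3/B3", allele_calls=["v1", "v1"])]
        table = pg.allele_frequency_table(recs).allele_table
        assert table.iloc[0]["count"] == 2

    def test_against_generator_truth(self, small_population):
        _, truth, _ = small_population
        table = pg.allele_frequency_table(truth).allele_table
        expected = {}
        for t in truth:
            for a in t.allele_calls:
                expected[a] = expected.get(a, 0) + 1
        got = dict(zip(table["allele"], table["count"]))
        assert got == expected


class TestSiteDiversity:
    @pytest.mark.parametrize("j,n,expected", [
        (0, 10, 0.0),
        (1, 2, 1.0),
        (3, 10, 42 / 90),
        (10, 10, 0.0),
    ])
    def test_examples(self, j, n, expected):
        assert pg.site_diversity(j, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 24])
    def test_matches_pair_enumeration(self, n):
        for j in range(n + 1):
            assert pg.site_diversity(j, n) == pytest.approx(
                brute_site_diversity(j, n), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            pg.site_diversity(3, 1)
        with pytest.raises(ParameterError):
            pg.site_diversity(5, 4)


class TestSweepScan:
    def test_invariant_window(self):
        m = VariantMatrix(
            sample_ids=["a", "b", "c"],
            positions=np.array([10]),
            genotypes=np.zeros((3, 1), dtype=np.int8),
            segment_length=100,
        )
        stats = pg.sweep_scan(m, window_bp=100, step_bp=100)
        assert stats[0].S == 0
        assert stats[0].pi == 0.0
        assert stats[0].tajima_d is None

    def test_specified_derived_counts_vs_brute_force(self):
        # n = 10 haplotypes (5 diploids), derived counts {1, 1, 2, 5}
        geno = np.zeros((5, 4), dtype=np.int8)
        geno[0, 0] = 1
        geno[1, 1] = 1
        geno[0, 2] = geno[1, 2] = 1
        geno[:2, 3] = 2
        geno[2, 3] = 1
        m = VariantMatrix(
            sample_ids=[f"s{i}" for i in range(5)],
            positions=np.array([5, 10, 15, 20]),
            genotypes=geno,
            segment_length=30,
        )
        stats = pg.sweep_scan(m, window_bp=30, step_bp=30)
        oracle = brute_window_stats(m.positions, m.genotypes, 30, 30, 30)
        (start, end, S, k_hat, o_pi, o_d) = oracle[0]
        w = stats[0]
        assert w.S == S == 4
        assert w.theta_pi == pytest.approx(k_hat, abs=1e-10)
        assert w.pi == pytest.approx(o_pi, abs=1e-10)
        assert w.tajima_d == pytest.approx(o_d, abs=1e-10)

    def test_random_matrices_match_brute_force(self, rng):
        for _ in range(25):
            m = _random(rng)
            stats = pg.sweep_scan(m, window_bp=300, step_bp=150)
            oracle = brute_window_stats(
                m.positions, m.genotypes, m.segment_length, 300, 150)
            assert len(stats) == len(oracle)
            for w, (start, end, S, k_hat, o_pi, o_d) in zip(stats, oracle):
                assert (w.start, w.end, w.S) == (start, end, S)
                assert w.pi == pytest.approx(o_pi, abs=1e-10)
                if o_d is None:
                    assert w.tajima_d is None
                else:
                    assert w.tajima_d == pytest.approx(o_d, abs=1e-10)

    def test_missing_sites_dropped(self, rng):
        m = _random(rng, missing_rate=0.1)
        stats = pg.sweep_scan(m, window_bp=1000, step_bp=1000)
        oracle = brute_window_stats(
            m.positions, m.genotypes, m.segment_length, 1000, 1000)
        for w, (_, _, S, k_hat, o_pi, o_d) in zip(stats, oracle):
            assert w.S == S
            assert w.pi == pytest.approx(o_pi, abs=1e-10)

    def test_relabel_ref_alt_invariance(self, rng):
        m = _random(rng)
        flipped = VariantMatrix(
            sample_ids=m.sample_ids,
            positions=m.positions,
            genotypes=(2 - m.genotypes).astype(np.int8),
            segment_length=m.segment_length,
        )
        s1 = pg.sweep_scan(m, 250, 125)
        s2 = pg.sweep_scan(flipped, 250, 125)
        for a, b in zip(s1, s2):
            assert a.pi == pytest.approx(b.pi, abs=1e-12)
            if a.tajima_d is None:
                assert b.tajima_d is None
            else:
                assert a.tajima_d == pytest.approx(b.tajima_d, abs=1e-12)

    def test_window_tiling(self):
        m = VariantMatrix(
            sample_ids=["a", "b"],
            positions=np.array([1, 4000]),
            genotypes=np.array([[1, 0], [0, 1]], dtype=np.int8),
            segment_length=4000,
        )
        stats = pg.sweep_scan(m, window_bp=2500, step_bp=1250)
        # every position covered at least once
        covered = np.zeros(4001, dtype=bool)
        for w in stats:
            covered[w.start: w.end + 1] = True
        assert covered[1:].all()
        # consecutive overlap = window - step
        for a, b in zip(stats, stats[1:]):
            assert a.end - b.start + 1 in (2500 - 1250, 4000 - b.start + 1)
        assert stats[-1].partial

    def test_too_few_haplotypes(self):
        m = VariantMatrix(
            sample_ids=["a", "b"],
            positions=np.array([1]),
            genotypes=np.array([[1], [0]], dtype=np.int8),
            segment_length=10,
        )
        pg.sweep_scan(m)  # n = 4 is allowed
        with pytest.raises(ParameterError):
            one = VariantMatrix(
                sample_ids=["a", "b"], positions=np.array([1]),
                genotypes=np.array([[1], [0]], dtype=np.int8),
                segment_length=10)
            one.genotypes = one.genotypes[:1]
            one.sample_ids = one.sample_ids[:1]
            pg.sweep_scan(one)

    def test_neutral_mean_d_near_zero(self):
        means = []
        for seed in range(100):
            cfg = sd.SimulationConfig(seed=seed)
            cfg.sweep = sd.SweepParams(segment_length=50_000, strength=0.0,
                                       sweep_center=25_000)
            stats = pg.sweep_scan(sd.simulate_variant_matrix(cfg))
            defined = [w.tajima_d for w in stats if w.tajima_d is not None]
            means.append(np.mean(defined))
        assert abs(np.mean(means)) < 0.3


class TestSweepReport:
    def test_uniform_windows(self):
        stats = [pg.WindowStat(1 + i * 100, (i + 1) * 100, 2, 2, 1.0, 0.01, 0.5)
                 for i in range(5)]
        rep = pg.sweep_report(stats)
        assert rep.min_pi == rep.mean_pi == 0.01
        assert rep.min_d == rep.mean_d == 0.5

    def test_leftmost_tie_break(self):
        stats = [pg.WindowStat(1, 100, 0, 0, 0.0, 0.0, None),
                 pg.WindowStat(101, 200, 0, 0, 0.0, 0.0, None)]
        rep = pg.sweep_report(stats)
        assert rep.min_pi_window == (1, 100)

    def test_all_undefined_d_is_none(self):
        stats = [pg.WindowStat(1, 100, 0, 0, 0.0, 0.0, None)]
        rep = pg.sweep_report(stats)
        assert rep.mean_d is None
        assert rep.min_d is None

    def test_planted_sweep_argmin_overlaps_center(self):
        cfg = sd.SimulationConfig(seed=77)
        m = sd.simulate_variant_matrix(cfg)
        rep = pg.sweep_report(pg.sweep_scan(m))
        c = m.annotations["sweep_center"]
        s, e = rep.min_pi_window
        assert s - 2 * 1250 <= c <= e + 2 * 1250


def _random(rng, **kw):
    from conftest import random_matrix

    return random_matrix(rng, **kw)
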