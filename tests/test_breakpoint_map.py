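import numpy as np
import pytest

from chimpop import breakpoint_map as bm
from chimpop import synthetic_data as sd
from chimpop.errors import AlignmentError, NoInformationError
from chimpop.io_formats import AlleleSequence

B1 = "ACGTACGTACGT"
B2 = "ACGAACGAACGA"


class TestInformativeSites:
    def test_hand_enumeration(self):
        smap = bm.informative_sites(B1, B2, "ACGAACGTACGT")
        assert smap.columns == [3, 7, 11]
        assert smap.states == ["matches_B2", "matches_B1", "matches_B1"]
        assert smap.skipped == 0

    def test_identical_parents_no_sites(self):
        smap = bm.informative_sites(B1, B1, B1)
        assert smap.sites == []

    def test_chimera_n_masks_column(self):
        smap = bm.informative_sites(B1, B2, "ACGNACGTACGT")
        assert smap.columns == [7, 11]
        assert smap.skipped == 1

    def test_parent_gap_excludes_column(self):
        smap = bm.informative_sites("ACG-ACGTACGT", B2, "ACGAACGTACGT")
        assert smap.columns == [7, 11]  # column 3 excluded: b1 gapped there

    def test_neither_state(self):
        smap = bm.informative_sites(B1, B2, "ACGCACGTACGT")
        assert smap.sites[0][3] == "neither"

    def test_unequal_lengths(self):
        with pytest.raises(AlignmentError):
            bm.informative_sites(B1, B2, "ACGT")


class TestMapCrossover:
    def test_single_switch_interval(self):
        smap = bm.informative_sites(B1, B2, "ACGAACGTACGT")
        iv = bm.map_crossover(smap, "toy")
        assert (iv.left, iv.right) == (3, 7)
        assert iv.n_switches == 1
        assert not iv.complex_flag
        assert iv.degenerate is None

    def test_all_b1_degenerate_start(self):
        smap = bm.informative_sites(B1, B2, B1)
        iv = bm.map_crossover(smap)
        assert iv.degenerate == "start"
        assert iv.n_switches == 0
        assert not iv.complex_flag

    def test_all_b2_degenerate_end(self):
        smap = bm.informative_sites(B1, B2, B2)
        iv = bm.map_crossover(smap)
        assert iv.degenerate == "end"
        assert iv.right == smap.alignment_length

    def test_multi_switch_complex(self):
        # states B2, B1, B2, B1 across four informative columns
        chim = "ACGAACGTACGAACGT"
        iv = bm.map_crossover(
            bm.informative_sites(B1 + B1[:4], B2 + B2[:4], chim))
        assert iv.n_switches == 3
        assert iv.complex_flag
        assert (iv.left, iv.right) == (3, 7)  # first interval of segmentation

    def test_neither_ignored_for_switch_count(self):
        # B2, neither, B1 -> one switch, interval spans the neither column
        chim = "ACGAACGCACGT"
        iv = bm.map_crossover(bm.informative_sites(B1, B2, chim))
        assert iv.n_switches == 1
        assert (iv.left, iv.right) == (3, 11)

    def test_empty_site_map_errors(self):
        with pytest.raises(NoInformationError):
            bm.map_crossover(bm.informative_sites(B1, B1, B1))

    def test_invariant_to_noninformative_columns(self, parent_pools, chimera_pool):
        b1 = {a.id: a for a in parent_pools[0]}
        b2 = {a.id: a for a in parent_pools[1]}
        chim = chimera_pool[3]
        pb1, pb2 = b1[chim.annotations["b1_parent"]], b2[chim.annotations["b2_parent"]]
        iv = bm.map_crossover(bm.informative_sites(pb1, pb2, chim))
        # append an identical (non-informative) tail to all three
        tail = "ACGT" * 25
        iv2 = bm.map_crossover(bm.informative_sites(
            pb1.sequence + tail, pb2.sequence + tail, chim.sequence + tail))
        assert (iv.left, iv.right, iv.n_switches) == (
            iv2.left, iv2.right, iv2.n_switches)


class TestRecoverPlantedBreakpoints:
    def _pool(self, seed, n_chimeras, mutate=0.0):
        cfg = sd.SimulationConfig(seed=seed)
        rng = np.random.default_rng([seed, 99])
        names = sd.default_breakpoints(cfg, 8)
        positions = [p for _, p in names]
        b1, b2 = sd.sample_parental_alleles(cfg)
        chims = []
        for i in range(n_chimeras):
            pos = positions[i % len(positions)]
            chim = sd.make_chimera(
                b2[rng.integers(len(b2))], b1[rng.integers(len(b1))], pos,
                f"c{i:03d}")
            if mutate:
                arr = np.frombuffer(chim.sequence.encode(), dtype=np.uint8).copy()
                hit = np.nonzero(rng.random(arr.size) < mutate)[0]
                cur = np.searchsorted(sd.BASES, arr[hit])
                arr[hit] = sd.BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
                chim.sequence = arr.tobytes().decode()
            chims.append(chim)
        return b1, b2, chims

    def test_noise_free_containment_is_exact(self):
        b1, b2, chims = self._pool(seed=17, n_chimeras=50)
        df = bm.recover_planted_breakpoints(b1, b2, chims)
        assert df["contained"].notna().all()
        assert df["contained"].mean() == 1.0

    def test_mutated_containment_high(self):
        # 1% post-formation mutation: complex calls are excluded from the
        # denominator, the rest stay contained
        rates = []
        for seed in range(20):
            b1, b2, chims = self._pool(seed=seed, n_chimeras=20, mutate=0.01)
            df = bm.recover_planted_breakpoints(b1, b2, chims)
            rates.append(df["contained"].mean())
        assert np.mean(rates) >= 0.95

    def test_zero_divergence_degenerate_excluded(self):
        b1 = AlleleSequence("b1", "B1", sequence="ACGT" * 5)
        b2 = AlleleSequence("b2", "B2", sequence="ACGT" * 4 + "ACGA")
        chim = sd.make_chimera(b2, b1, 4, "c")  # all divergence 3' of breakpoint
        df = bm.recover_planted_breakpoints([b1], [b2], [chim])
        assert df["degenerate"].iloc[0] == "start"
        assert np.isnan(df["contained"].iloc[0])


class TestTypeAlleles:
    def test_identity_clustering(self, chimera_pool):
        copies = [
            AlleleSequence(f"dup{i}", "B3", sequence=chimera_pool[0].sequence,
                           features=list(chimera_pool[0].features))
            for i in range(10)
        ]
        table = bm.type_alleles(copies)
        assert len(table.variants) == 1
        assert len(table.variants[0]["members"]) == 10

    def test_two_intron_snps(self):
        base = "ACGT" * 30
        intron = ("intron", 40, 80)
        a = AlleleSequence("a", "B3", sequence=base, features=[intron])
        seq_b = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        seq_b = seq_b[:60] + ("G" if seq_b[60] != "G" else "T") + seq_b[61:]
        b = AlleleSequence("b", "B3", sequence=seq_b, features=[intron])
        table = bm.type_alleles([a, b])
        assert len(table.variants) == 2
        assert table.intron_diff_matrix.iloc[0, 1] == 2

    def test_planted_variants_recovered(self, chimera_pool):
        rng = np.random.default_rng(6)
        pool = []
        for i in range(60):
            src = chimera_pool[rng.integers(len(chimera_pool))]
            pool.append(AlleleSequence(
                f"m{i}", "B3", sequence=src.sequence,
                features=list(src.features),
                annotations={"planted": src.id}))
        table = bm.type_alleles(pool)
        planted = {c.sequence for c in chimera_pool if any(
            p.sequence == c.sequence for p in pool)}
        assert len(table.variants) == len(planted)
        # every member of a variant shares one planted label
        by_id = {p.id: p.annotations["planted"] for p in pool}
        for v in table.variants:
            assert len({by_id[m] for m in v["members"]}) == 1

    def test_variant_naming_is_input_order_invariant(self, chimera_pool):
        fwd = bm.type_alleles(list(chimera_pool))
        rev = bm.type_alleles(list(reversed(chimera_pool)))
        assert [v["sequence"] for v in fwd.variants] == [
            v["sequence"] for v in rev.variants]
        assert [v["variant_name"] for v in fwd.variants] == [
            v["variant_name"] for v in rev.variants]

    def test_partition_is_equivalence_relation(self, chimera_pool):
        rng = np.random.default_rng(8)
        pool = []
        for i in range(40):
            src = chimera_pool[rng.integers(len(chimera_pool))]
            pool.append(AlleleSequence(f"e{i}", "B3", sequence=src.sequence,
                                       features=list(src.features)))
        table = bm.type_alleles(pool)
        seen = [m for v in table.variants for m in v["members"]]
        assert sorted(seen) == sorted(p.id for p in pool)  # total partition
        by_seq = {p.id: p.sequence for p in pool}
        for v in table.variants:
            assert len({by_seq[m] for m in v["members"]}) == 1  # consistent

    def test_unannotated_intron_excluded(self, chimera_pool):
        naked = AlleleSequence("naked", "B3", sequence=chimera_pool[0].sequence)
        table = bm.type_alleles([naked, chimera_pool[0]])
        members = [m for v in table.variants for m in v["members"]]
        assert "naked" not in members
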