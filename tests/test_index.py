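"""The six per-station computations: totals, H', partition, fractions,
index, status, and their composition."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from microgambi import (
    AbundanceMatrix,
    DenominatorPolicy,
    EGPartition,
    IndexConfig,
    MatchOptions,
    Status,
    UndefinedFractionsError,
    assess_all,
    assess_station,
    classify_status,
    eg_fractions,
    microgambi_index,
    partition_reads,
    read_abundance_table,
    shannon_diversity,
    station_totals,
)


def shannon_oracle(counts):
    """Independent direct summation with stdlib math, no vectorization."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


class TestIndexConfig:
    def test_defaults(self):
        cfg = IndexConfig()
        assert cfg.weight_egi == 0.0 and cfg.weight_egiii == 6.0
        assert cfg.class_boundaries == (1.2, 3.3, 4.3, 5.5)
        assert cfg.denominator_policy is DenominatorPolicy.ASSIGNED_ONLY

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"weight_egi": 6.0, "weight_egiii": 6.0},
            {"weight_egi": -1.0},
            {"class_boundaries": (3.3, 1.2, 4.3, 5.5)},
            {"class_boundaries": (0.0, 3.3, 4.3, 5.5)},
            {"class_boundaries": (1.2, 3.3, 4.3, 6.0)},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IndexConfig(**kwargs)


class TestStationTotals:
    @pytest.mark.parametrize(
        "col, expected",
        [((10, 0, 5), (15, 2)), ((0, 0, 0), (0, 0)), ((2, 1, 1), (4, 3))],
    )
    def test_examples(self, col, expected):
        m = AbundanceMatrix(["A", "B", "C"], ["S"], np.array(col)[:, None])
        t = station_totals(m, "S")
        assert (t.total_reads, t.n_taxa) == expected

    def test_unknown_station(self):
        m = AbundanceMatrix(["A"], ["S"], np.array([[1]]))
        with pytest.raises(KeyError):
            station_totals(m, "T")


class TestShannon:
    @pytest.mark.parametrize(
        "counts, expected",
        [([7], 0.0), ([5, 5, 5, 5], 2.0), ([2, 1, 1], 1.5)],
    )
    def test_closed_forms(self, counts, expected):
        assert shannon_diversity(counts) == expected

    @pytest.mark.parametrize("k", [1, 2, 4, 8, 16])
    def test_uniform_equals_log2_k(self, k):
        assert shannon_diversity([3] * k) == math.log2(k)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon_diversity([0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([1, -1])

    @given(st.lists(st.integers(0, 10_000), min_size=1, max_size=50)
           .filter(lambda c: sum(c) > 0))
    def test_against_direct_summation_and_scipy(self, counts):
        h = shannon_diversity(counts)
        assert h == pytest.approx(shannon_oracle(counts), abs=1e-12)
        assert h == pytest.approx(
            stats.entropy(np.array([c for c in counts if c > 0]), base=2),
            abs=1e-9,
        )
        assert 0.0 <= h <= math.log2(sum(1 for c in counts if c > 0)) + 1e-12


class TestPartition:
    def station(self, rows):
        names = [r[0] for r in rows]
        counts = np.array([[r[1]] for r in rows])
        return AbundanceMatrix(names, ["S"], counts)

    def test_two_group_fixture(self, tiny_ref):
        m = self.station([("Desulfobacter", 60), ("Vibrio", 40)])
        p = partition_reads(m, tiny_ref, "S")
        assert (p.reads_egi, p.reads_egiii, p.reads_not_assigned,
                p.reads_not_in_list) == (60, 40, 0, 0)
        assert p.taxa_egi == ["Desulfobacter"] and p.taxa_egiii == ["Vibrio"]

    def test_not_in_list_included(self, tiny_ref):
        m = self.station([("Desulfobacter", 60), ("Vibrio", 40), ("Novus", 10)])
        p = partition_reads(m, tiny_ref, "S")
        assert p.reads_not_in_list == 10 and p.total_reads == 110

    def test_all_not_assigned(self, tiny_ref):
        m = self.station([("Mysterium incertum", 33)])
        p = partition_reads(m, tiny_ref, "S")
        assert (p.reads_egi, p.reads_egiii, p.reads_not_assigned,
                p.reads_not_in_list) == (0, 0, 33, 0)

    def test_zero_count_taxa_listed_nowhere(self, tiny_ref):
        m = self.station([("Desulfobacter", 0), ("Vibrio", 5)])
        p = partition_reads(m, tiny_ref, "S")
        assert p.taxa_egi == [] and p.reads_egi == 0

    def test_genus_fallback_changes_category(self, tiny_ref):
        m = self.station([("Vibrio harveyi", 9)])
        assert partition_reads(m, tiny_ref, "S").reads_not_in_list == 9
        p = partition_reads(m, tiny_ref, "S", MatchOptions(genus_fallback=True))
        assert p.reads_egiii == 9


class TestFractions:
    def test_assigned_only(self):
        p = EGPartition(reads_egi=60, reads_egiii=40)
        assert eg_fractions(p) == (60.0, 40.0)

    def test_unmatched_reads_excluded(self):
        p = EGPartition(reads_egi=60, reads_egiii=40, reads_not_in_list=100)
        f_egi, f_egiii = eg_fractions(p)
        assert (f_egi, f_egiii) == (60.0, 40.0)
        assert f_egi + f_egiii == 100.0

    def test_all_reads_policy(self):
        p = EGPartition(reads_egi=60, reads_egiii=40, reads_not_in_list=100)
        f_egi, f_egiii = eg_fractions(p, DenominatorPolicy.ALL_READS)
        assert (f_egi, f_egiii) == (30.0, 20.0)

    def test_zero_assigned_undefined(self):
        p = EGPartition(reads_not_assigned=50)
        with pytest.raises(UndefinedFractionsError) as e:
            eg_fractions(p)
        assert e.value.reason == "NO_ASSIGNED_READS"


class TestMicrogambiIndex:
    def test_boundaries_and_midpoint(self):
        cfg = IndexConfig()
        assert microgambi_index(100, 0, cfg) == cfg.weight_egi == 0.0
        assert microgambi_index(0, 100, cfg) == cfg.weight_egiii == 6.0
        assert microgambi_index(50, 50, cfg) == (cfg.weight_egi + cfg.weight_egiii) / 2

    def test_affine_grid(self):
        """Matches the brute-force affine form at 101 grid points."""
        cfg = IndexConfig()
        slope = (cfg.weight_egiii - cfg.weight_egi) / 100.0
        for f in range(101):
            direct = cfg.weight_egi + slope * f
            assert microgambi_index(100 - f, f, cfg) == pytest.approx(direct, abs=1e-12)
        vals = [microgambi_index(100 - f, f, cfg) for f in range(101)]
        assert min(vals) == cfg.weight_egi and max(vals) == cfg.weight_egiii

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            microgambi_index(-1, 101)

    def test_custom_weights(self):
        cfg = IndexConfig(weight_egi=1.0, weight_egiii=5.0,
                          class_boundaries=(1.5, 2.5, 3.5, 4.5))
        assert microgambi_index(100, 0, cfg) == 1.0
        assert microgambi_index(0, 100, cfg) == 5.0


class TestClassify:
    @pytest.mark.parametrize(
        "index, status",
        [
            (0.0, Status.HIGH),
            (1.2, Status.HIGH),
            (1.2 + 1e-9, Status.GOOD),
            (3.3, Status.GOOD),
            (3.3 + 1e-9, Status.MODERATE),
            (4.3, Status.MODERATE),
            (4.3 + 1e-9, Status.POOR),
            (5.5, Status.POOR),
            (5.5 + 1e-9, Status.BAD),
            (6.0, Status.BAD),
        ],
    )
    def test_right_closed_boundaries(self, index, status):
        assert classify_status(index) is status

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_status(6.5)
        with pytest.raises(ValueError):
            classify_status(-0.5)

    def test_total_and_monotone_sweep(self):
        cfg = IndexConfig()
        order = [Status.HIGH, Status.GOOD, Status.MODERATE, Status.POOR, Status.BAD]
        prev = -1
        for x in np.linspace(cfg.weight_egi, cfg.weight_egiii, 10_001):
            s = classify_status(float(x), cfg)
            rank = order.index(s)
            assert rank >= prev
            prev = rank
        assert prev == 4


class TestAssess:
    def matrix(self, counts_tsv):
        return read_abundance_table(io.StringIO(counts_tsv))

    def test_composition_matches_parts(self, tiny_ref, counts_tsv):
        a = assess_station(self.matrix(counts_tsv), tiny_ref, "ST1")
        assert a.total_reads == 100 and a.n_taxa == 2
        assert a.shannon_h_bits == pytest.approx(
            shannon_oracle([60, 40]), abs=1e-12)
        assert (a.f_egi, a.f_egiii) == (60.0, 40.0)
        assert a.index_value == pytest.approx(6 * 40 / 100)
        assert a.status is Status.GOOD
        assert a.flags == []
        assert a.pct_egi + a.pct_egiii + a.pct_not_assigned + a.pct_not_in_list \
            == pytest.approx(100.0, abs=1e-9)

    def test_unclassifiable_station(self, tiny_ref, counts_tsv):
        a = assess_station(self.matrix(counts_tsv), tiny_ref, "ST3")
        assert a.status is Status.UNCLASSIFIABLE
        assert a.index_value is None and a.f_egiii is None
        assert "NO_ASSIGNED_READS" in a.flags
        assert any(f.startswith("LOW_REFERENCE_COVERAGE") for f in a.flags)

    def test_coverage_flag_threshold(self, tiny_ref):
        m = AbundanceMatrix(["Desulfobacter", "Vibrio", "Novus"], ["S"],
                            np.array([[40], [30], [30]]))
        a = assess_station(m, tiny_ref, "S")
        assert any(f.startswith("LOW_REFERENCE_COVERAGE") for f in a.flags)
        cfg = IndexConfig(unmatched_warn_threshold=50.0)
        assert assess_station(m, tiny_ref, "S", cfg).flags == []

    def test_empty_station(self, tiny_ref):
        m = AbundanceMatrix(["Desulfobacter"], ["S"], np.array([[0]]))
        a = assess_station(m, tiny_ref, "S")
        assert a.status is Status.UNCLASSIFIABLE
        assert a.shannon_h_bits is None
        assert "EMPTY_STATION" in a.flags

    def test_identical_columns_identical_assessments(self, tiny_ref):
        m = AbundanceMatrix(["Desulfobacter", "Vibrio"], ["S1", "S2"],
                            np.array([[60, 60], [40, 40]]))
        a1, a2 = assess_all(m, tiny_ref)
        assert a1.index_value == a2.index_value
        assert a1.status == a2.status and a1.shannon_h_bits == a2.shannon_h_bits

    def test_scale_invariance(self, tiny_ref):
        base = AbundanceMatrix(["Desulfobacter", "Vibrio", "Novus"], ["S"],
                               np.array([[6], [4], [1]]))
        scaled = AbundanceMatrix(["Desulfobacter", "Vibrio", "Novus"], ["S"],
                                 np.array([[6], [4], [1]]) * 37)
        a, b = assess_station(base, tiny_ref, "S"), assess_station(scaled, tiny_ref, "S")
        assert a.shannon_h_bits == pytest.approx(b.shannon_h_bits, abs=1e-12)
        assert a.f_egiii == pytest.approx(b.f_egiii, abs=1e-12)
        assert a.index_value == pytest.approx(b.index_value, abs=1e-12)
        assert a.status == b.status

    def test_assess_all_order_and_permutation(self, tiny_ref, counts_tsv):
        m = self.matrix(counts_tsv)
        out = assess_all(m, tiny_ref)
        assert [a.station_id for a in out] == m.station_ids
        perm = [2, 0, 1]
        m2 = AbundanceMatrix(m.taxa_names,
                             [m.station_ids[i] for i in perm],
                             m.counts[:, perm])
        out2 = assess_all(m2, tiny_ref)
        for i, j in enumerate(perm):
            assert out2[i].station_id == out[j].station_id
            assert out2[i].index_value == out[j].index_value
            assert out2[i].status == out[j].status

    @given(st.integers(0, 2**32 - 1))
    def test_read_conservation_random(self, tiny_ref, seed):
        rng = np.random.default_rng(seed)
        names = ["Desulfobacter", "Vibrio", "Mysterium incertum", "Novus",
                 "Sensibacter calmus"]
        counts = rng.integers(0, 500, size=(5, 3))
        m = AbundanceMatrix(names, ["S1", "S2", "S3"], counts)
        for s in m.station_ids:
            p = partition_reads(m, tiny_ref, s)
            assert p.total_reads == station_totals(m, s).total_reads
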