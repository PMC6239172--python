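import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from primarytx.genome_io import EndProfile
from primarytx.tss_caller import (
    NormalizationError,
    TssCandidate,
    TssCallerConfig,
    call_condition_tss,
    cluster_candidates,
    compute_size_factors,
    detect_candidates,
    enrichment_ratio,
    merge_tss_sets,
    normalize_profile,
)
from conftest import make_tss


def profile(counts, library_id="lib", condition="H20", replicate=1, treatment="RPP+"):
    return EndProfile(library_id, condition, replicate, treatment,
                      {("chr", "+", p): v for p, v in counts.items()})


class TestSizeFactors:
    def test_identical_libraries_are_unit(self):
        sf = compute_size_factors([[5, 5], [7, 7]])
        assert sf[0] == sf[1] == pytest.approx(1.0)

    def test_median_of_ratios_by_hand(self):
        # per row k_ij / sqrt(prod) = (2,4)/sqrt(8) and (6,12)/sqrt(72)
        sf = compute_size_factors([[2, 4], [6, 12]])
        assert sf[0] == pytest.approx(1 / math.sqrt(2), abs=1e-4)
        assert sf[1] == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_rows_with_zero_are_excluded(self):
        sf = compute_size_factors([[0, 4], [6, 12]])
        assert sf[0] == pytest.approx(1 / math.sqrt(2), abs=1e-4)
        assert sf[1] == pytest.approx(math.sqrt(2), abs=1e-4)

    def test_no_all_positive_row_raises(self):
        with pytest.raises(NormalizationError):
            compute_size_factors([[0, 4], [6, 0]])

    def test_scalar_multiple_columns_recover_factors(self, rng):
        base = rng.poisson(100, size=50).astype(float) + 1
        alphas = np.array([0.5, 1.0, 2.0, 1.3])
        table = base[:, None] * alphas[None, :]
        sf = compute_size_factors(table)
        expected = alphas / np.exp(np.mean(np.log(alphas)))
        assert np.allclose(list(sf.values()), expected, atol=1e-9)


class TestNormalizeProfile:
    def test_divides_by_factor(self):
        norm = normalize_profile(profile({100: 10}), {"lib": 2.0})
        assert norm.counts[("chr", "+", 100)] == 5.0

    def test_unit_factor_is_identity(self):
        p = profile({100: 10, 200: 3})
        assert normalize_profile(p, {"lib": 1.0}).counts == p.counts

    def test_missing_library_raises(self):
        with pytest.raises(NormalizationError):
            normalize_profile(profile({100: 10}), {"other": 1.0})


class TestDetectCandidates:
    def test_floor_filters(self):
        cands = detect_candidates(profile({100: 7, 200: 2}), min_density=5)
        assert [c.position for c in cands] == [100]

    def test_zero_floor_keeps_all(self):
        cands = detect_candidates(profile({100: 7, 200: 2}), min_density=0)
        assert [c.position for c in cands] == [100, 200]

    def test_empty_profile(self):
        assert detect_candidates(profile({})) == []


def cands(*pos_density, strand="+"):
    return [TssCandidate("chr", strand, p, d, "lib") for p, d in pos_density]


class TestClusterCandidates:
    def test_adjacent_pair_sd_below_threshold_joins(self):
        # gap 20 => pairwise SD 10 < 15: one sub-cluster, densest wins
        subs = cluster_candidates(cands((100, 10), (120, 50)))
        assert len(subs) == 1 and subs[0][1].position == 120

    def test_gap_40_splits(self):
        # gap 40 => SD 20 >= 15: two sub-clusters
        subs = cluster_candidates(cands((100, 10), (140, 50)))
        assert [rep.position for _, rep in subs] == [100, 140]

    def test_singleton_is_its_own_representative(self):
        subs = cluster_candidates(cands((77, 5)))
        assert subs[0][1].position == 77

    def test_density_tie_breaks_upstream(self):
        assert cluster_candidates(cands((100, 9), (110, 9)))[0][1].position == 100
        subs = cluster_candidates(cands((100, 9), (110, 9), strand="-"))
        assert subs[0][1].position == 110  # upstream is rightward on -

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_candidates(cands((140, 1), (100, 1)))

    @given(
        st.lists(
            st.tuples(st.integers(0, 2000), st.floats(0.5, 100)),
            min_size=1, max_size=30, unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, pairs):
        """Every candidate lands in exactly one sub-cluster; reps are inputs."""
        pairs = sorted(pairs)
        group = cands(*pairs)
        subs = cluster_candidates(group)
        members = [c.position for ms, _ in subs for c in ms]
        assert sorted(members) == sorted(p for p, _ in pairs)
        positions = {c.position for c in group}
        assert all(rep.position in positions for _, rep in subs)


class TestEnrichmentRatio:
    def test_arithmetic(self):
        plus, minus = profile({100: 100.0}), profile({100: 10.0}, treatment="RPP-")
        assert enrichment_ratio(("chr", "+", 100), plus, minus) == pytest.approx(101 / 11)

    def test_below_twofold(self):
        plus, minus = profile({100: 20.0}), profile({100: 15.0}, treatment="RPP-")
        assert enrichment_ratio(("chr", "+", 100), plus, minus) == pytest.approx(21 / 16)

    def test_zero_background(self):
        plus, minus = profile({100: 5.0}), profile({}, treatment="RPP-")
        assert enrichment_ratio(("chr", "+", 100), plus, minus) == pytest.approx(6.0)


class TestCallConditionTss:
    CFG = TssCallerConfig(min_density=5.0)
    SF = {"p1": 1.0, "m1": 1.0, "p2": 1.0, "m2": 1.0}

    @staticmethod
    def libs(plus1, plus2, minus1=None, minus2=None):
        return [
            profile(plus1, "p1", replicate=1, treatment="RPP+"),
            profile(minus1 or {}, "m1", replicate=1, treatment="RPP-"),
            profile(plus2, "p2", replicate=2, treatment="RPP+"),
            profile(minus2 or {}, "m2", replicate=2, treatment="RPP-"),
        ]

    def test_reproducible_within_window_takes_denser_replicate(self):
        tss = call_condition_tss(self.libs({100: 50}, {103: 80}), self.SF, self.CFG)
        assert len(tss) == 1 and tss[0].position == 103 and tss[0].density == 80

    def test_replicates_too_far_apart_yield_nothing(self):
        assert call_condition_tss(self.libs({100: 50}, {110: 80}), self.SF, self.CFG) == []

    def test_unenriched_replicate_blocks_the_call(self):
        # replicate 2 has RPP- nearly as high as RPP+: ratio < 2
        tss = call_condition_tss(
            self.libs({100: 50}, {100: 30}, minus2={100: 25}), self.SF, self.CFG
        )
        assert tss == []

    def test_single_replicate_skips_reproducibility_with_warning(self):
        libs = [
            profile({100: 50}, "p1", replicate=1, treatment="RPP+"),
            profile({}, "m1", replicate=1, treatment="RPP-"),
        ]
        with pytest.warns(UserWarning, match="single replicate"):
            tss = call_condition_tss(libs, self.SF, self.CFG)
        assert [t.position for t in tss] == [100]

    def test_missing_rpp_minus_partner_raises(self):
        libs = [profile({100: 50}, "p1", replicate=1, treatment="RPP+")]
        with pytest.raises(ValueError, match="RPP"):
            call_condition_tss(libs, self.SF, self.CFG)


class TestMergeTssSets:
    def test_union_of_conditions_at_denser_seed(self):
        a = [make_tss(100, density=50, conditions=("A",))]
        b = [make_tss(103, density=80, conditions=("B",))]
        merged = merge_tss_sets([a, b], n_conditions=4)
        assert len(merged) == 1
        (t,) = merged
        assert t.position == 103 and t.conditions == {"A", "B"} and t.label == "conditional"

    def test_chain_absorbed_by_density_seed(self):
        chain = [
            make_tss(100, density=10),
            make_tss(104, density=50),
            make_tss(108, density=20),
        ]
        merged = merge_tss_sets([chain])
        assert [t.position for t in merged] == [104]

    def test_idempotent(self):
        lists = [
            [make_tss(100, density=50, conditions=("A",)), make_tss(500, density=5, conditions=("A",))],
            [make_tss(102, density=9, conditions=("B",))],
        ]
        once = merge_tss_sets(lists, n_conditions=2)
        twice = merge_tss_sets([once], n_conditions=2)
        assert [(t.position, t.conditions, t.label) for t in once] == [
            (t.position, t.conditions, t.label) for t in twice
        ]

    def test_order_invariant_without_ambiguity(self):
        a = [make_tss(100, density=50, conditions=("A",))]
        b = [make_tss(200, density=80, conditions=("B",))]
        fwd = merge_tss_sets([a, b])
        rev = merge_tss_sets([b, a])
        assert [(t.position, t.density) for t in fwd] == [(t.position, t.density) for t in rev]

    def test_labels_partition_the_total(self):
        lists = [
            [make_tss(100, conditions=(c,)) for c in ("A",)],
            [make_tss(100, conditions=("B",)), make_tss(300, conditions=("B",))],
            [make_tss(101, conditions=("C",)), make_tss(900, conditions=("C",))],
        ]
        merged = merge_tss_sets(lists, n_conditions=3)
        by_label = {
            label: sum(t.label == label for t in merged)
            for label in ("constitutive", "conditional", "specific")
        }
        assert sum(by_label.values()) == len(merged)
        assert by_label["constitutive"] == 1  # 100/100/101 merge to all 3 conditions
        assert by_label["specific"] == 2
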