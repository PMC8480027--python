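"""Combined pessimistic accuracy against a literal-equation oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxyhap.encoding import ALT_HOM, HET, MISSING, MUT_HOM, REF_HOM, WT_HOM
from proxyhap.genotype_io import GenotypeMatrix
from proxyhap.proxy_selection import (
    ORIENT_REF_MUT,
    ORIENT_REF_WT,
    CausalSite,
    combined_pessimistic_accuracy,
    impute_causal,
    scan_window,
    select_proxy,
)
from proxyhap.synthetic_data import PanelSimParams, simulate_panel

STATES = (REF_HOM, ALT_HOM, HET, MISSING)


def oracle_accuracy(proxy, causal):
    """Literal application of the accuracy equation, both orientations.

    correct-WT: proxy and causal homozygous, proxy allele maps to WT
    haplotype under the orientation, causal is WT; likewise correct-MUT.
    Denominator is every scored accession.  Returns (accuracy,
    orientation) with ties to REF<->WT.
    """
    n = len(proxy)
    best = None
    for orientation in (ORIENT_REF_WT, ORIENT_REF_MUT):
        wt_code = REF_HOM if orientation == ORIENT_REF_WT else ALT_HOM
        mut_code = ALT_HOM if orientation == ORIENT_REF_WT else REF_HOM
        n_wt = sum(1 for p, c in zip(proxy, causal) if p == wt_code and c == WT_HOM)
        n_mut = sum(1 for p, c in zip(proxy, causal) if p == mut_code and c == MUT_HOM)
        acc = 100.0 * (n_wt + n_mut) / n
        if best is None or acc > best[0]:
            best = (acc, orientation, n_wt, n_mut)
    return best


class TestCombinedPessimisticAccuracy:
    def test_perfect_concordance(self):
        causal = [WT_HOM] * 6 + [MUT_HOM] * 4
        proxy = [REF_HOM] * 6 + [ALT_HOM] * 4
        res = combined_pessimistic_accuracy(proxy, causal)
        assert res.accuracy == 100.0
        assert res.orientation == ORIENT_REF_WT
        assert (res.counts.n_correct_wt, res.counts.n_correct_mut) == (6, 4)

    def test_hand_counted_example_with_missing(self):
        # 5 correct WT, 2 correct MUT, 1 missing proxy -> 7/8 = 87.5
        proxy = [REF_HOM] * 5 + [ALT_HOM] * 2 + [MISSING]
        causal = [WT_HOM] * 5 + [MUT_HOM] * 2 + [WT_HOM]
        res = combined_pessimistic_accuracy(proxy, causal)
        assert (res.counts.n_correct_wt, res.counts.n_correct_mut, res.n_total) == (5, 2, 8)
        assert res.accuracy == pytest.approx(87.5)

    def test_orientation_flip_maximises(self):
        proxy = [REF_HOM] * 4 + [ALT_HOM] * 4
        causal = [MUT_HOM] * 4 + [WT_HOM] * 4
        res = combined_pessimistic_accuracy(proxy, causal)
        assert res.orientation == ORIENT_REF_MUT
        assert res.accuracy == 100.0

    def test_all_missing_scores_zero(self):
        res = combined_pessimistic_accuracy([MISSING] * 5, [MISSING] * 5)
        assert res.accuracy == 0.0

    def test_het_never_correct(self):
        res = combined_pessimistic_accuracy([HET] * 4, [WT_HOM] * 4)
        assert res.accuracy == 0.0

    @pytest.mark.parametrize("proxy,causal", [([], []), ([REF_HOM], [])])
    def test_empty_or_mismatched_rejected(self, proxy, causal):
        with pytest.raises(ValueError):
            combined_pessimistic_accuracy(proxy, causal)

    def test_exhaustive_oracle_equivalence_short_vectors(self):
        """All four-state pairs up to length 3 match the literal oracle."""
        for L in (1, 2, 3):
            for proxy in itertools.product(STATES, repeat=L):
                for causal in itertools.product(STATES, repeat=L):
                    res = combined_pessimistic_accuracy(proxy, causal)
                    acc, orient, n_wt, n_mut = oracle_accuracy(proxy, causal)
                    assert res.accuracy == pytest.approx(acc)
                    assert res.orientation == orient
                    assert (res.counts.n_correct_wt, res.counts.n_correct_mut) == (
                        n_wt,
                        n_mut,
                    )

    @given(
        st.lists(
            st.tuples(st.sampled_from(STATES), st.sampled_from(STATES)),
            min_size=1,
            max_size=30,
        ),
        st.randoms(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_permutation_invariance(self, pairs, rnd):
        """Accuracy depends only on the multiset of (proxy, causal) pairs."""
        proxy, causal = zip(*pairs)
        res = combined_pessimistic_accuracy(proxy, causal)
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        p2, c2 = zip(*shuffled)
        res2 = combined_pessimistic_accuracy(p2, c2)
        assert res.accuracy == res2.accuracy
        assert res.orientation == res2.orientation

    @given(
        st.lists(
            st.tuples(st.sampled_from(STATES), st.sampled_from(STATES)),
            min_size=1,
            max_size=20,
        ),
        st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_spoiling_a_correct_call_never_raises_accuracy(self, pairs, data):
        proxy, causal = map(list, zip(*pairs))
        res = combined_pessimistic_accuracy(proxy, causal)
        i = data.draw(st.integers(0, len(proxy) - 1))
        spoiled = data.draw(st.sampled_from([HET, MISSING]))
        proxy[i] = spoiled
        res2 = combined_pessimistic_accuracy(proxy, causal)
        assert res2.accuracy <= res.accuracy + 1e-12

    def test_adding_concordant_accession_moves_accuracy_toward_100(self):
        proxy = [REF_HOM, ALT_HOM, MISSING]
        causal = [WT_HOM, MUT_HOM, WT_HOM]
        acc = combined_pessimistic_accuracy(proxy, causal).accuracy
        proxy2, causal2 = proxy + [REF_HOM], causal + [WT_HOM]
        acc2 = combined_pessimistic_accuracy(proxy2, causal2).accuracy
        assert acc < acc2 <= 100.0

    def test_global_ref_alt_swap_flips_orientation_keeps_accuracy(self):
        swap = {REF_HOM: ALT_HOM, ALT_HOM: REF_HOM, HET: HET, MISSING: MISSING}
        rng = np.random.default_rng(0)
        for _ in range(25):
            proxy = rng.choice(STATES, size=40).tolist()
            causal = rng.choice(STATES, size=40).tolist()
            res = combined_pessimistic_accuracy(proxy, causal)
            res2 = combined_pessimistic_accuracy([swap[p] for p in proxy], causal)
            assert res2.accuracy == pytest.approx(res.accuracy)
            # swapping exchanges the two orientations' scores, so the chosen
            # orientation flips unless the orientations were tied (both -> WT)
            acc_wt = sum(
                1
                for p, c in zip(proxy, causal)
                if (p == REF_HOM and c == WT_HOM) or (p == ALT_HOM and c == MUT_HOM)
            )
            acc_mut = sum(
                1
                for p, c in zip(proxy, causal)
                if (p == ALT_HOM and c == WT_HOM) or (p == REF_HOM and c == MUT_HOM)
            )
            if acc_wt == acc_mut:
                assert res.orientation == res2.orientation == ORIENT_REF_WT
            else:
                assert res2.orientation != res.orientation


def simulated_scan(seed=1, n=500, missing=0.0):
    params = PanelSimParams(
        n_accessions=n,
        causal_maf=0.35,
        marker_positions=(-400_000, -1000, 2000, 300_000),
        marker_concordance=(0.70, 0.94, 0.70, 0.70),
        missing_rate=missing,
        seed=seed,
    )
    vcf, mat, truth = simulate_panel(params)
    causal_calls = pd.Series(
        [MUT_HOM if a == "MUT" else WT_HOM for a in truth.causal_alleles],
        index=mat.accession_ids,
    )
    causal = CausalSite("e1la:K82E", "Gm04", 28_294_378, "A", "G")
    return mat, causal_calls, causal, truth


class TestScanWindow:
    def test_planted_best_marker_ranks_first(self):
        mat, causal_calls, causal, truth = simulated_scan()
        ranked = scan_window(mat, causal_calls, causal)
        assert ranked[0].marker_id == "sim002"
        assert select_proxy(ranked).marker_id == "sim002"

    def test_zero_window_excludes_all_offset_markers(self):
        mat, causal_calls, causal, _ = simulated_scan()
        assert scan_window(mat, causal_calls, causal, window_bp=0) == []

    def test_tie_break_by_distance_then_position(self):
        markers = pd.DataFrame(
            {
                "marker_id": ["far", "near"],
                "chrom": ["c", "c"],
                "pos": [120, 110],
                "ref": ["A", "A"],
                "alt": ["G", "G"],
            }
        )
        calls = np.array([[REF_HOM, REF_HOM], [ALT_HOM, ALT_HOM]], dtype=np.int8)
        mat = GenotypeMatrix(["a1", "a2"], markers, calls)
        causal_calls = pd.Series([WT_HOM, MUT_HOM], index=["a1", "a2"])
        ranked = scan_window(mat, causal_calls, CausalSite("x", "c", 100, "A", "G"), 1000)
        assert [r.marker_id for r in ranked] == ["near", "far"]

    def test_accession_intersection(self):
        mat, causal_calls, causal, _ = simulated_scan(n=100)
        subset = causal_calls.iloc[:60]
        ranked = scan_window(mat, subset, causal)
        assert all(r.n_total == 60 for r in ranked)

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError, match="widen"):
            select_proxy([])


class TestImputeCausal:
    def make_proxy(self, orientation):
        res = combined_pessimistic_accuracy(
            [REF_HOM, ALT_HOM], [WT_HOM, MUT_HOM]
        )
        if orientation == ORIENT_REF_MUT:
            res = combined_pessimistic_accuracy([ALT_HOM, REF_HOM], [WT_HOM, MUT_HOM])
        assert res.orientation == orientation
        return res

    def test_ref_hom_maps_by_orientation(self):
        calls = pd.Series([REF_HOM, ALT_HOM, HET, MISSING], index=list("abcd"))
        imputed, excluded = impute_causal(self.make_proxy(ORIENT_REF_WT), calls)
        assert imputed.to_dict() == {"a": "WT", "b": "MUT"}
        assert set(excluded.id) == {"c", "d"}
        assert set(excluded.reason) == {"heterozygous proxy call", "missing proxy call"}

    def test_flipped_orientation_swaps_mapping(self):
        calls = pd.Series([REF_HOM, ALT_HOM], index=list("ab"))
        imputed, _ = impute_causal(self.make_proxy(ORIENT_REF_MUT), calls)
        assert imputed.to_dict() == {"a": "MUT", "b": "WT"}
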