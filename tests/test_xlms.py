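import numpy as np
import pandas as pd
import pytest

from slidekin import (
    XlmsSimConfig,
    aggregate_domains,
    classify_csms,
    condition_overlap,
    default_domain_map,
    differential_matrix,
    estimate_fdr,
    fractional_counts,
    simulate_xlms_csms,
)
from slidekin.xlms import DomainMap, canonical_pair


class TestDomainMap:
    def test_boundary_lookups(self):
        dmap = default_domain_map()
        assert dmap.domain_of("SNF2h", 100) == "SNF2h:AutoN"
        assert dmap.domain_of("SNF2h", 84) == "SNF2h:AutoN"
        assert dmap.domain_of("SNF2h", 83) == "SNF2h:Snf2h1"
        assert dmap.domain_of("H2A", 90) == "H2A:Acidic Patch"
        assert dmap.domain_of("H2B", 100) == "H2B:Acidic Patch"
        assert dmap.domain_of("H4", 24) == "H4:tail"
        assert dmap.domain_of("H4", 25) == "H4:H4"
        assert dmap.domain_of("SNF2h", 1054) == "SNF2h:Snf2h5"

    def test_unmapped_residue_reported(self):
        dmap = default_domain_map()
        with pytest.raises(KeyError, match="H3:999"):
            dmap.domain_of("H3", 999)
        with pytest.raises(KeyError, match="unknown protein"):
            dmap.domain_of("H9", 10)

    def test_gapped_domains_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            DomainMap({"P": [("a", 1, 10), ("b", 12, 20)]})

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            DomainMap({})


class TestFractionalCounts:
    def test_methods_worked_example_half_count_each(self):
        # one spectrum matching K91.H4-D65.H2B and K91.H4-E68.H2B equally
        # awards 0.5 to each residue pair
        csms = pd.DataFrame(
            {"candidates": [[("H4", 91, "H2B", 65), ("H4", 91, "H2B", 68)]]}
        )
        counts = fractional_counts(csms)
        assert counts[canonical_pair("H4", 91, "H2B", 65)] == pytest.approx(0.5)
        assert counts[canonical_pair("H4", 91, "H2B", 68)] == pytest.approx(0.5)

    def test_unambiguous_csm_awards_one(self):
        csms = pd.DataFrame({"candidates": [[("H3", 10, "H4", 20)]]})
        assert list(fractional_counts(csms).values()) == [1.0]

    def test_four_way_ambiguity_quarters(self):
        cands = [("H3", 10, "H4", r) for r in (20, 21, 22, 23)]
        counts = fractional_counts(pd.DataFrame({"candidates": [cands]}))
        assert all(c == pytest.approx(0.25) for c in counts.values())

    def test_conservation_over_random_ambiguity_structures(self, rng):
        # total counts equal the number of spectra for any ambiguity pattern
        for _ in range(40):
            n = int(rng.integers(1, 40))
            rows = []
            for _ in range(n):
                k = int(rng.integers(1, 5))
                base = int(rng.integers(1, 90))
                rows.append([("H3", base, "H2B", base + j) for j in range(k)])
            counts = fractional_counts(pd.DataFrame({"candidates": rows}))
            assert sum(counts.values()) == pytest.approx(n, abs=1e-9)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            fractional_counts(pd.DataFrame({"candidates": [[]]}))


class TestFdr:
    def test_no_decoy_passes_means_zero_fdr(self):
        assert estimate_fdr(0, 500)["fdr"] == 0.0

    def test_stated_construction(self):
        # 10 decoy passes / multiplicity 10 over 2000 target passes = 0.05%
        out = estimate_fdr(10, 2000, decoy_multiplicity=10)
        assert out["fdr"] == pytest.approx(5e-4)

    def test_multiplicity_one_is_classical_ratio(self):
        assert estimate_fdr(5, 100, decoy_multiplicity=1)["fdr"] == pytest.approx(0.05)

    def test_specificity_from_decoy_totals(self):
        out = estimate_fdr(3, 100, decoy_multiplicity=10, n_decoy_total=1000)
        assert out["specificity"] == pytest.approx(0.997)

    def test_zero_targets_flagged(self):
        out = estimate_fdr(1, 0)
        assert out["fdr"] is None
        assert "fdr_undefined_no_targets" in out["flags"]


class TestClassification:
    def _table(self, seed=0, **kwargs):
        cfg = XlmsSimConfig(
            n_target_csms=400, n_decoy_csms=120, ambiguity_prob=0.1, **kwargs
        )
        return simulate_xlms_csms(cfg, seed=seed)

    def test_separated_classes_exclude_nearly_all_decoys(self):
        pairs, report = classify_csms(self._table())
        decoys = pairs[pairs["decoy"]]
        assert (~decoys["passed"]).mean() >= 0.99
        # among pairs that meet the spectral-count floor (alternate
        # localizations of ambiguous CSMs carry only fractional counts),
        # nearly all targets are retained
        targets = pairs[~pairs["decoy"] & (pairs["spectral_count"] >= 1.0)]
        assert targets["passed"].mean() > 0.95

    def test_score_difference_threshold_is_strict(self):
        table = self._table(seed=1)
        # force one unambiguous target CSM exactly onto the boundary
        idx = table.index[~table["decoy"]][0]
        table.loc[idx, "score_difference"] = 5.0
        table.at[idx, "candidates"] = [("H3", 7, "H3", 99)]
        pairs, _ = classify_csms(table)
        row = pairs[(pairs["protein1"] == "H3") & (pairs["residue1"] == 7)]
        assert len(row) == 1
        assert not row["passed"].iloc[0]

    def test_passing_pairs_satisfy_all_thresholds(self):
        pairs, _ = classify_csms(self._table(seed=2))
        ok = pairs[pairs["passed"]]
        assert (ok["svm_score"] > 1.0).all()
        assert (ok["score_difference"] > 5.0).all()
        assert (ok["spectral_count"] >= 1.0).all()

    def test_no_decoys_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="decoy"):
            classify_csms(table[~table["decoy"]])

    def test_fdr_tracks_true_false_discovery_proportion(self):
        # plant false targets with decoy-like features; with a decoy database
        # `multiplicity` times the size of the false-target pool, the decoy
        # estimate should track the realized FDP within a factor of ~2
        rng = np.random.default_rng(9)
        est_all, true_all = [], []
        for rep in range(25):
            cfg = XlmsSimConfig(
                n_target_csms=300,
                n_decoy_csms=300,  # = multiplicity * expected false targets
                ambiguity_prob=0.0,
                decoy_feature_means={
                    "score_difference": 9.0,
                    "pct_product_ions_matched": 50.0,
                    "precursor_charge": 4.0,
                    "rank_peptide1": 2.0,
                    "rank_peptide2": 2.0,
                },
            )
            table = simulate_xlms_csms(cfg, seed=int(rng.integers(2**31)))
            # mislabel 10% of targets as false matches, drawing their
            # features from the same law the decoy class uses
            from slidekin.simulate import _draw_features

            t_idx = table.index[~table["decoy"]]
            false_idx = t_idx[: len(t_idx) // 10]
            for i in false_idx:
                for f, v in _draw_features(
                    cfg.decoy_feature_means, cfg.feature_sds, rng
                ).items():
                    table.loc[i, f] = v
            false_keys = {
                canonical_pair(*table.at[i, "candidates"][0]) for i in false_idx
            }
            pairs, report = classify_csms(table, decoy_multiplicity=10)
            tp = pairs[~pairs["decoy"] & pairs["passed"]]
            if not len(tp) or report["fdr"] is None:
                continue
            keys = [
                canonical_pair(p, r, q, s)
                for p, r, q, s in zip(
                    tp["protein1"], tp["residue1"], tp["protein2"], tp["residue2"]
                )
            ]
            fdp = np.mean([k in false_keys for k in keys])
            est_all.append(report["fdr"])
            true_all.append(fdp)
        est, true = np.mean(est_all), np.mean(true_all)
        assert true > 0  # the planted false matches are not all removed
        assert 0.5 <= est / true <= 2.0


class TestAggregation:
    def test_single_pair_boundary_lookup(self):
        dmap = default_domain_map()
        counts = {canonical_pair("SNF2h", 100, "H2A", 90): 2.0}
        mat = aggregate_domains(counts, dmap)
        assert mat.counts.loc["SNF2h:AutoN", "H2A:Acidic Patch"] == 2.0
        assert mat.counts.loc["H2A:Acidic Patch", "SNF2h:AutoN"] == 2.0

    def test_empty_counts_all_zero(self):
        mat = aggregate_domains({}, default_domain_map())
        assert (mat.counts.to_numpy() == 0).all()

    def test_additivity_within_domain_pair(self):
        dmap = default_domain_map()
        counts = {
            canonical_pair("SNF2h", 90, "H2A", 50): 0.5,
            canonical_pair("SNF2h", 150, "H2A", 99): 1.5,
        }
        mat = aggregate_domains(counts, dmap)
        assert mat.counts.loc["SNF2h:AutoN", "H2A:Acidic Patch"] == 2.0

    def test_unmapped_residue_rejected_with_id(self):
        with pytest.raises(KeyError, match="2000"):
            aggregate_domains(
                {canonical_pair("SNF2h", 2000, "H2A", 50): 1.0},
                default_domain_map(),
            )


class TestDifferential:
    def _mats(self, a_vals, b_vals):
        dmap = DomainMap({"P": [("a", 1, 10), ("b", 11, 20), ("c", 21, 30)]})
        doms = dmap.all_domains()
        A = aggregate_domains({}, dmap)
        B = aggregate_domains({}, dmap)
        for (i, j), v in a_vals.items():
            A.counts.iloc[i, j] = v
            A.counts.iloc[j, i] = v
        for (i, j), v in b_vals.items():
            B.counts.iloc[i, j] = v
            B.counts.iloc[j, i] = v
        return A, B

    def test_pseudocount_floors_zero_counts(self):
        A, B = self._mats({}, {(0, 1): 4.0})
        diff = differential_matrix(A, B)
        # pre-centering value is log2(4/1) = 2
        assert diff.log2_ratio.iloc[0, 1] + diff.median_shift == pytest.approx(2.0)

    def test_equal_counts_become_na(self):
        A, B = self._mats({(0, 1): 3.0, (0, 2): 1.0}, {(0, 1): 3.0, (0, 2): 5.0})
        diff = differential_matrix(A, B)
        assert np.isnan(diff.log2_ratio.iloc[0, 1])
        assert not np.isnan(diff.log2_ratio.iloc[0, 2])

    def test_median_of_non_na_cells_is_zero(self):
        rng = np.random.default_rng(2)
        a = {(i, j): float(rng.integers(0, 9)) for i in range(3) for j in range(i, 3)}
        b = {(i, j): float(rng.integers(0, 9)) for i in range(3) for j in range(i, 3)}
        A, B = self._mats(a, b)
        diff = differential_matrix(A, B)
        vals = diff.log2_ratio.to_numpy()
        iu = np.triu_indices(3)
        cells = vals[iu]
        cells = cells[np.isfinite(cells)]
        assert np.median(cells) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_before_centering(self):
        A, B = self._mats({(0, 1): 2.0, (1, 2): 7.0}, {(0, 1): 8.0, (1, 2): 1.0})
        ab = differential_matrix(A, B)
        ba = differential_matrix(B, A)
        raw_ab = ab.log2_ratio + ab.median_shift
        raw_ba = ba.log2_ratio + ba.median_shift
        np.testing.assert_allclose(
            raw_ab.to_numpy(), -raw_ba.to_numpy(), equal_nan=True
        )

    def test_no_data_mask_marks_doubly_empty_cells(self):
        A, B = self._mats({(0, 1): 1.0}, {(0, 1): 2.0})
        diff = differential_matrix(A, B)
        assert diff.no_data.iloc[0, 2]
        assert not diff.no_data.iloc[0, 1]

    def test_mismatched_maps_rejected(self):
        A, _ = self._mats({}, {})
        other = aggregate_domains({}, DomainMap({"Q": [("x", 1, 5)]}))
        with pytest.raises(ValueError):
            differential_matrix(A, other)


class TestConditionOverlap:
    def test_partial_overlap(self):
        a = {("x", 1, "y", 2), ("x", 3, "y", 4)}
        b = {("x", 3, "y", 4), ("z", 1, "z", 9)}
        out = condition_overlap(a, b)
        assert (out["unique_a"], out["unique_b"], out["common"]) == (1, 1, 1)

    def test_identical_sets(self):
        a = {("x", 1, "y", 2), ("x", 3, "y", 4)}
        out = condition_overlap(a, set(a))
        assert (out["unique_a"], out["unique_b"], out["common"]) == (0, 0, 2)

    def test_disjoint_sets(self):
        a = {("x", 1, "y", 2)}
        b = {("x", 9, "y", 9)}
        out = condition_overlap(a, b)
        assert (out["unique_a"], out["unique_b"], out["common"]) == (1, 1, 0)

    def test_pair_order_canonicalized(self):
        out = condition_overlap({("y", 2, "x", 1)}, {("x", 1, "y", 2)})
        assert out["common"] == 1
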