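import numpy as np
import pandas as pd
import pytest

import amplimock as am
from amplimock.assign import AssignmentTable
from amplimock.calibrate import ThresholdSet
from amplimock.io import SampleMetadata
from amplimock.records import SequenceRecord, parse_lineage

HET = parse_lineage("Eukaryota;Alveolata;Dinoflagellata")


def _species(rng, n, length=130):
    out = []
    while len(out) < n:
        s = "".join(rng.choice(list("ACGT"), size=length))
        if all(am.edit_distance(s, o.seq) > 5 for o in out):
            out.append(SequenceRecord(f"sp{len(out) + 1}", s))
    return out


def _sub(seq, pos):
    out = list(seq)
    out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


def _mock(counts_by_asv):
    return am.CountMatrix(pd.DataFrame([list(counts_by_asv.values())],
                                       index=["mock1"], columns=list(counts_by_asv)))


def _meta(rows, strata=(50, 150)):
    df = pd.DataFrame(rows, columns=["sample", "island", "depth_m", "transect",
                                     "library_id", "sample_role"]).set_index("sample")
    return SampleMetadata(df, strata)


def _thresholds(d):
    df = pd.DataFrame(d).T
    df.index.name = "library_id"
    return ThresholdSet(df)


class TestMatchMock:
    def test_exact_one_sub_and_far_asvs(self):
        rng = np.random.default_rng(0)
        sps = _species(rng, 3)
        seqs = [SequenceRecord("a0", sps[2].seq),
                SequenceRecord("a1", _sub(sps[2].seq, 4)),
                SequenceRecord("a2", _sub(_sub(sps[0].seq, 1), 7))]
        m = am.match_mock(_mock({"a0": 500, "a1": 30, "a2": 10}), seqs, sps)
        t = m.table
        assert t.loc["a0", "matched_species"] == "sp3" and t.loc["a0", "edit_distance"] == 0
        assert t.loc["a1", "matched_species"] == "sp3" and t.loc["a1", "edit_distance"] == 1
        assert t.loc["a2", "matched_species"] is None and t.loc["a2", "edit_distance"] == 2
        assert t["proportion"].sum() == pytest.approx(1.0)

    def test_multiple_samples_rejected(self):
        rng = np.random.default_rng(1)
        sps = _species(rng, 1)
        cm = am.CountMatrix(pd.DataFrame([[1], [2]], index=["m1", "m2"], columns=["a"]))
        with pytest.raises(ValueError, match="one sample"):
            am.match_mock(cm, [SequenceRecord("a", sps[0].seq)], sps)


class TestLenientThreshold:
    def test_hand_arithmetic(self):
        rng = np.random.default_rng(2)
        sps = _species(rng, 2)
        seqs = [SequenceRecord("a0", sps[0].seq), SequenceRecord("a1", sps[1].seq),
                SequenceRecord("a2", "".join(rng.choice(list("ACGT"), size=130)))]
        m = am.match_mock(_mock({"a0": 900, "a1": 90, "a2": 10}), seqs, sps)
        assert am.lenient_threshold(m) == pytest.approx(0.09)

    def test_single_matched_asv_equal_to_total(self):
        rng = np.random.default_rng(3)
        sps = _species(rng, 1)
        m = am.match_mock(_mock({"a0": 777}), [SequenceRecord("a0", sps[0].seq)], sps)
        assert am.lenient_threshold(m) == 1.0

    def test_no_matched_asv_is_an_error(self):
        rng = np.random.default_rng(4)
        sps = _species(rng, 1)
        far = "".join(rng.choice(list("ACGT"), size=130))
        m = am.match_mock(_mock({"a0": 10}), [SequenceRecord("a0", far)], sps)
        with pytest.raises(ValueError, match="mock failed"):
            am.lenient_threshold(m)


class TestStrictThreshold:
    def _fixture(self, rng, reads):
        """3 species; ASVs: exact per species + 1 variant + 1 contaminant."""
        sps = _species(rng, 3)
        far = "".join(rng.choice(list("ACGT"), size=130))
        assert all(am.edit_distance(far, s.seq) >= 2 for s in sps)
        seqs = [SequenceRecord("e1", sps[0].seq), SequenceRecord("e2", sps[1].seq),
                SequenceRecord("e3", sps[2].seq),
                SequenceRecord("v1", _sub(sps[0].seq, 3)), SequenceRecord("c1", far)]
        m = am.match_mock(_mock(dict(zip(["e1", "e2", "e3", "v1", "c1"], reads))), seqs, sps)
        return m

    def test_feasible_bound_and_exact_recovery(self):
        m = self._fixture(np.random.default_rng(5), [4000, 3000, 2890, 10, 100])
        t, feasible = am.strict_threshold(m)
        assert t == pytest.approx(0.01)
        assert feasible
        kept = m.table.index[m.table["proportion"] > t]
        assert set(kept) == {"e1", "e2", "e3"}

    def test_no_noise_gives_zero_bound(self):
        rng = np.random.default_rng(6)
        sps = _species(rng, 2)
        seqs = [SequenceRecord("e1", sps[0].seq), SequenceRecord("e2", sps[1].seq)]
        m = am.match_mock(_mock({"e1": 70, "e2": 30}), seqs, sps)
        assert am.strict_threshold(m) == (0.0, True)

    def test_dominant_contaminant_is_infeasible(self):
        m = self._fixture(np.random.default_rng(7), [500, 2000, 1500, 1000, 5000])
        t, feasible = am.strict_threshold(m)
        assert t == pytest.approx(0.5)
        assert not feasible

    def test_missing_exact_asv_is_an_error(self):
        rng = np.random.default_rng(8)
        sps = _species(rng, 2)
        # sp2 is represented only by a 1-mismatch variant: the mock is incomplete
        seqs = [SequenceRecord("e1", sps[0].seq), SequenceRecord("v2", _sub(sps[1].seq, 0))]
        m = am.match_mock(_mock({"e1": 90, "v2": 10}), seqs, sps)
        with pytest.raises(ValueError, match="incomplete"):
            am.strict_threshold(m)


class TestApplyThreshold:
    def _single_lib(self, counts):
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock")])
        cm = am.CountMatrix(pd.DataFrame([counts[1]], index=["s1"], columns=counts[0]))
        return cm, meta

    def test_boundary_kept_at_exact_lenient_proportion(self):
        cm, meta = self._single_lib((["a", "b", "c"], [9, 8, 9983]))
        ts = _thresholds({"L1": {"t_lenient": 0.0009, "t_strict": 0.0, "feasible_strict": True}})
        out = am.apply_threshold(cm, meta, ts, mode="lenient")
        assert set(out.asv_ids) == {"a", "c"}  # 9/10000 = 0.09% kept, 8 removed

    def test_zero_threshold_is_identity(self):
        cm, meta = self._single_lib((["a", "b"], [5, 1]))
        ts = _thresholds({"L1": {"t_lenient": 0.0, "t_strict": 0.0, "feasible_strict": True}})
        out = am.apply_threshold(cm, meta, ts, mode="lenient")
        assert np.array_equal(out.values, cm.values)

    def test_strict_mode_is_exclusive(self):
        cm, meta = self._single_lib((["a", "b"], [10, 990]))
        ts = _thresholds({"L1": {"t_lenient": 0.0, "t_strict": 0.01, "feasible_strict": True}})
        out = am.apply_threshold(cm, meta, ts, mode="strict")
        assert set(out.asv_ids) == {"b"}  # a sits exactly at 1% and is removed

    def test_per_library_thresholds(self):
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("s2", "F", 150, "T1", "L2", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock"),
                      ("mock_L2", "mock", 0, "n", "L2", "mock")])
        cm = am.CountMatrix(pd.DataFrame([[5, 95], [5, 95]], index=["s1", "s2"],
                                         columns=["a", "b"]))
        ts = _thresholds({"L1": {"t_lenient": 0.01, "t_strict": 0, "feasible_strict": True},
                          "L2": {"t_lenient": 0.10, "t_strict": 0, "feasible_strict": True}})
        out = am.apply_threshold(cm, meta, ts, mode="lenient")
        assert out.counts.loc["s1", "a"] == 5    # 5% ≥ 1%
        assert out.counts.loc["s2", "a"] == 0    # 5% < 10%

    def test_missing_library_threshold_rejected(self):
        cm, meta = self._single_lib((["a"], [5]))
        ts = _thresholds({"L9": {"t_lenient": 0.0, "t_strict": 0.0, "feasible_strict": True}})
        with pytest.raises(ValueError, match="L1"):
            am.apply_threshold(cm, meta, ts, mode="lenient")

    def test_scale_invariance(self):
        cm, meta = self._single_lib((["a", "b", "c"], [9, 8, 9983]))
        ts = _thresholds({"L1": {"t_lenient": 0.0009, "t_strict": 0.0, "feasible_strict": True}})
        scaled = am.CountMatrix(cm.counts * 17)
        out1 = am.apply_threshold(cm, meta, ts, mode="lenient")
        out2 = am.apply_threshold(scaled, meta, ts, mode="lenient")
        assert out1.asv_ids == out2.asv_ids
        assert np.array_equal(out1.presence().values, out2.presence().values)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        cm, meta = self._single_lib(
            ([f"a{i}" for i in range(20)], list(rng.integers(1, 2000, size=20))))
        kept_prev = None
        for t in (0.0, 0.001, 0.01, 0.05, 0.2):
            ts = _thresholds({"L1": {"t_lenient": t, "t_strict": 0, "feasible_strict": True}})
            kept = set(am.apply_threshold(cm, meta, ts, mode="lenient").asv_ids)
            if kept_prev is not None:
                assert kept <= kept_prev
            kept_prev = kept


class TestPartition:
    def _assignment(self, identities):
        rows = [(a, "r1", i, HET, "heterotroph") for a, i in identities.items()]
        df = pd.DataFrame(rows, columns=["asv", "best_ref_id", "identity_pct",
                                         "lineage", "functional_class"]).set_index("asv")
        return AssignmentTable(df)

    def test_cell_moves_to_low_abundance_when_identity_high(self):
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("s2", "F", 150, "T1", "L1", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock")])
        # asvA: 0.5% in s1 (below 1% threshold), 5% in s2 (above)
        cm = am.CountMatrix(pd.DataFrame([[5, 995], [50, 950]], index=["s1", "s2"],
                                         columns=["asvA", "asvB"]))
        ts = _thresholds({"L1": {"t_lenient": 0.01, "t_strict": 0.02, "feasible_strict": True}})
        part = am.partition_datasets(cm, meta, ts, self._assignment({"asvA": 99.0, "asvB": 100.0}))
        assert part.main.counts.loc["s2", "asvA"] == 50
        assert part.main.counts.loc["s1", "asvA"] == 0
        assert part.low_abundant.counts.loc["s1", "asvA"] == 5
        assert "asvA" in part.low_abundant.asv_ids
        # per-sample disjointness of main and low-abundance
        overlap = (part.main.counts > 0) & (part.low_abundant.counts.reindex_like(part.main.counts).fillna(0) > 0)
        assert not overlap.any().any()

    def test_low_identity_asv_excluded_from_low_abundance(self):
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock")])
        cm = am.CountMatrix(pd.DataFrame([[5, 995]], index=["s1"], columns=["asvA", "asvB"]))
        ts = _thresholds({"L1": {"t_lenient": 0.01, "t_strict": 0.0, "feasible_strict": True}})
        part = am.partition_datasets(cm, meta, ts, self._assignment({"asvA": 90.0, "asvB": 100.0}))
        assert "asvA" not in part.low_abundant.asv_ids
        log = part.removal_log.set_index("asv")
        assert not bool(log.loc["asvA", "in_low_abundant"])

    def test_nothing_removed_gives_empty_low_abundance(self):
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock")])
        cm = am.CountMatrix(pd.DataFrame([[400, 600]], index=["s1"], columns=["a", "b"]))
        ts = _thresholds({"L1": {"t_lenient": 0.01, "t_strict": 0.0, "feasible_strict": True}})
        part = am.partition_datasets(cm, meta, ts, self._assignment({"a": 99.0, "b": 99.0}))
        assert part.low_abundant.counts.shape[1] == 0
        assert part.removal_log.empty


class TestRecoveryOnGenerator:
    def test_thresholds_equal_realized_mock_proportions(self, mock_species):
        """Calibration reproduces the values implied by the drawn counts exactly."""
        design = am.default_mock_design(seed=21, species=mock_species)
        cm, seqs, gt = am.generate_mock_library(design)
        m = am.match_mock(cm, seqs, mock_species)
        info = gt.asv_info[gt.asv_info["observed"]]
        row = cm.counts.iloc[0]
        total = row.sum()
        matched_ids = info.index[info["role"].isin(["expected", "variant"])]
        assert am.lenient_threshold(m) == pytest.approx(row[matched_ids].min() / total)
        non_expected = info.index[info["role"] != "expected"]
        t_strict, feasible = am.strict_threshold(m)
        assert t_strict == pytest.approx(row[non_expected].max() / total)
        assert feasible

    def test_strict_filter_of_mock_returns_exactly_expected(self, mock_species):
        design = am.default_mock_design(seed=22, species=mock_species)
        cm, seqs, gt = am.generate_mock_library(design)
        m = am.match_mock(cm, seqs, mock_species)
        t_strict, feasible = am.strict_threshold(m)
        assert feasible
        kept = set(m.table.index[m.table["proportion"] > t_strict])
        expected = set(gt.asv_info.index[(gt.asv_info["role"] == "expected")
                                         & gt.asv_info["observed"]])
        assert kept == expected and len(kept) == 9


class TestCalibratorEstimator:
    def test_fit_transform_roundtrip(self, mock_species):
        mocks = {}
        for lib in ("L1", "L2"):
            d = am.default_mock_design(seed=hash(lib) % 1000, species=mock_species,
                                       sample_id=f"mock_{lib}")
            cm, seqs, _ = am.generate_mock_library(d)
            mocks[lib] = (cm, seqs)
        cal = am.MockThresholdCalibrator().fit(mocks, mock_species)
        assert set(cal.thresholds_.library_ids) == {"L1", "L2"}
        assert all(0 < cal.thresholds_.t_lenient(l) < cal.thresholds_.t_strict(l)
                   for l in ("L1", "L2"))
        meta = _meta([("s1", "F", 50, "T1", "L1", "environmental"),
                      ("mock_L1", "mock", 0, "n", "L1", "mock"),
                      ("mock_L2", "mock", 0, "n", "L2", "mock")])
        env = am.CountMatrix(pd.DataFrame([[3, 9997]], index=["s1"], columns=["x", "y"]))
        out = cal.transform(env, meta)
        assert set(out.asv_ids) == {"y"}

    def test_get_params_roundtrip(self):
        cal = am.MockThresholdCalibrator(max_mismatch=2, mode="strict")
        assert cal.get_params() == {"max_mismatch": 2, "mode": "strict"}
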