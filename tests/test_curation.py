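import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsarspace.curation import (CuratedDataset, MoleculeRecord, curate,
                                read_curated_csv, spki, split)


def rec(mol_id, smiles="CCO", ki=100.0, year=2010):
    return MoleculeRecord(mol_id=mol_id, smiles=smiles, ki_nM=ki, year=year)


class TestSpki:
    @pytest.mark.parametrize("ki,expected", [
        (10_000.0, 0.0),       # upper clamp boundary
        (1.0, 1.0),            # lower clamp boundary
        (100.0, 0.5),          # (4 - 2) / 4
        (50_000.0, 0.0),       # beyond the upper clamp
        (0.5, 1.0),            # beyond the lower clamp
        (10.0, 0.75),
    ])
    def test_worked_examples(self, ki, expected):
        assert spki(ki) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            spki(bad)

    @given(st.floats(min_value=-4, max_value=8))
    @settings(max_examples=200, derandomize=True)
    def test_monotone_nonincreasing_in_ki(self, log_ki):
        ki = 10.0 ** log_ki
        eps = ki * 1e-6
        assert spki(ki + eps) <= spki(ki) + 1e-12

    def test_continuous_at_clamp_boundaries(self):
        for boundary in (1.0, 10_000.0):
            inside = spki(boundary * (1 + 1e-12)) if boundary == 1.0 \
                else spki(boundary * (1 - 1e-12))
            assert inside == pytest.approx(spki(boundary), abs=1e-9)


class TestCurate:
    def test_duplicate_keeps_most_recent_year(self):
        records = [rec("a", "CCO", 100, 2009), rec("b", "OCC", 200, 2015)]
        out = curate(records)
        assert [r.mol_id for r in out.records] == ["b"]
        assert out.records[0].ki_nM == 200

    def test_salt_reduced_to_largest_fragment(self):
        out = curate([rec("a", "CCCCO.[Na+]")])
        assert len(out.records) == 1
        assert "." not in out.records[0].smiles
        assert out.provenance_log[0]["action"] == "keep_largest_fragment"

    def test_clean_input_passes_through_in_order(self):
        records = [rec("a", "CCO"), rec("b", "CCN"), rec("c", "CCC")]
        out = curate(records)
        assert [r.mol_id for r in out.records] == ["a", "b", "c"]

    def test_missing_ki_and_unparseable_dropped_with_log(self):
        records = [rec("a"), rec("bad_ki", ki=None), rec("bad_smi", smiles="not_a_smiles")]
        out = curate(records)
        assert [r.mol_id for r in out.records] == ["a"]
        actions = {e["action"] for e in out.provenance_log}
        assert {"drop_missing_ki", "drop_unparseable"} <= actions

    def test_year_missing_loses_tie(self):
        records = [rec("dated", "CCO", 100, 2001), rec("undated", "OCC", 300, None)]
        out = curate(records)
        assert [r.mol_id for r in out.records] == ["dated"]

    def test_idempotent(self):
        records = [rec("a", "CCO.[Na+]", 5, 2001), rec("b", "OCC", 7, 2012),
                   rec("c", "c1ccccc1", 9, 2000)]
        once = curate(records)
        twice = curate(once.records)
        assert [r.smiles for r in twice.records] == [r.smiles for r in once.records]
        assert [r.mol_id for r in twice.records] == [r.mol_id for r in once.records]

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="no usable records"):
            curate([rec("a", ki=None)])


class TestSplit:
    @pytest.fixture
    def dataset(self):
        return curate([rec(f"m{i:03d}", "C" * (i + 1), 10 + i, 2000) for i in range(100)])

    def test_sizes_and_determinism(self, dataset):
        a = split(dataset, 0.2, seed=3)
        b = split(dataset, 0.2, seed=3)
        assert len(a.ivs_ids) == 20 and len(a.train_ids) == 80
        assert a.ivs_ids == b.ivs_ids

    def test_partition_is_exact(self, dataset):
        out = split(dataset, 0.2, seed=3)
        assert set(out.train_ids) | set(out.ivs_ids) == set(out.mol_ids)
        assert not set(out.train_ids) & set(out.ivs_ids)

    def test_order_invariant_under_seed(self, dataset):
        shuffled = curate(list(reversed([MoleculeRecord(r.mol_id, r.smiles,
                                                        r.ki_nM, r.year)
                                         for r in dataset.records])))
        assert set(split(dataset, 0.2, 3).ivs_ids) == \
            set(split(shuffled, 0.2, 3).ivs_ids)

    def test_degenerate_fraction_rejected(self, dataset):
        with pytest.raises(ValueError):
            split(dataset, 0.999, seed=3)

    def test_ivs_never_leaks_into_train(self, dataset):
        out = split(dataset, 0.25, seed=9)
        assert np.sum(out.ivs_mask) + np.sum(out.train_mask) == len(out.records)


def test_curated_csv_round_trip(tmp_path):
    ds = split(curate([rec(f"m{i}", "C" * (i + 1), 50 * (i + 1), 2005)
                       for i in range(12)]), 0.25, seed=1)
    path = tmp_path / "curated.csv"
    ds.write_csv(path, tmp_path / "prov.json")
    back = read_curated_csv(path)
    assert back.mol_ids == ds.mol_ids
    assert np.allclose(back.spki, ds.spki)
    assert list(back.split) == list(ds.split)
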