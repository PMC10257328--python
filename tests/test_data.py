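"""Dataset readers, merging, splitting and the similarity pre-filter."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fpbow.data import (
    Dataset,
    MoleculeRecord,
    SplitSpec,
    deduplicate,
    filter_by_similarity,
    merge_datasets,
    read_activity_csv,
    read_smiles,
    split_dataset,
)
from fpbow.fingerprints import morgan_fp, tanimoto, topological_fp


def _bulk(n_active, n_inactive, source):
    recs = [
        MoleculeRecord(id=f"a{i}", smiles="CCO", label=1, source=source) for i in range(n_active)
    ] + [
        MoleculeRecord(id=f"i{i}", smiles="CCN", label=0, source=source) for i in range(n_inactive)
    ]
    return Dataset(recs)


class TestReadSmiles:
    def test_parses_labeled_lines(self, tmp_path):
        p = tmp_path / "mols.smi"
        p.write_text("CCO m1 1\nc1ccccc1 m2 0\n")
        ds = read_smiles(p)
        assert len(ds) == 2 and ds.n_active == 1

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.smi"
        p.write_text("")
        with pytest.raises(ValueError, match="zero valid molecules"):
            read_smiles(p)

    def test_bad_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "mols.smi"
        p.write_text("CCO m1 1\nnotasmiles)( m3 1\nCCN m2 0\n")
        with pytest.warns(UserWarning, match="line|unparseable|skipped"):
            ds = read_smiles(p)
        assert ds.ids == ["m1", "m2"]

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_smiles("/nonexistent/path.smi")


class TestReadActivityCsv:
    def test_label_mapping_and_counts(self, tmp_path):
        p = tmp_path / "assay.csv"
        p.write_text("id,smiles,label\nm1,CCO,Active\nm2,CCN,Inactive\nm3,CCC,Active\n")
        ds = read_activity_csv(p)
        assert (ds.n_active, ds.n_inactive) == (2, 1)

    def test_unknown_token_is_named(self, tmp_path):
        p = tmp_path / "assay.csv"
        p.write_text("id,smiles,label\nm1,CCO,Probe\n")
        with pytest.raises(ValueError, match="Probe"):
            read_activity_csv(p)

    def test_duplicate_ids_listed(self, tmp_path):
        p = tmp_path / "assay.csv"
        p.write_text("id,smiles,label\nm1,CCO,Active\nm1,CCN,Inactive\n")
        with pytest.raises(ValueError, match="m1"):
            read_activity_csv(p)


class TestMerge:
    def test_source_counts_match_assay_shape(self):
        a = _bulk(1066, 5000, "assayA")
        b = _bulk(83, 517, "assayB")
        merged = merge_datasets([a, b])
        assert len(merged) == 6666
        assert merged.n_active == 1149 and merged.n_inactive == 5517
        prov = merged.provenance.set_index("source")
        assert prov.loc["assayA", "total"] == 6066 and prov.loc["assayB", "total"] == 600
        # conservation: provenance sums equal overall counts
        assert prov["active"].sum() == merged.n_active
        assert prov["total"].sum() == len(merged)

    def test_merge_of_one_is_identity(self):
        a = _bulk(3, 2, "s")
        merged = merge_datasets([a])
        assert [r.smiles for r in merged] == [r.smiles for r in a]
        assert [r.label for r in merged] == [r.label for r in a]

    def test_merge_of_empties(self):
        assert len(merge_datasets([Dataset([]), Dataset([])])) == 0

    def test_id_collision_after_prefixing(self):
        a = _bulk(1, 0, "s")
        with pytest.raises(ValueError, match="duplicate"):
            merge_datasets([a, a])


class TestSplit:
    def test_ceiling_rule_reproduces_reference_sizes(self):
        ds = _bulk(1149, 5517, "all")
        train, test = split_dataset(ds, SplitSpec(test_fraction=0.2, seed=0))
        assert (len(test), len(train)) == (1334, 5332)

    def test_zero_fraction(self):
        ds = _bulk(3, 3, "s")
        train, test = split_dataset(ds, SplitSpec(test_fraction=0.0, seed=0))
        assert len(test) == 0 and len(train) == 6

    def test_same_seed_same_members(self):
        ds = _bulk(5, 5, "s")
        spec = SplitSpec(test_fraction=0.25, seed=7)
        _, t1 = split_dataset(ds, spec)
        _, t2 = split_dataset(ds, spec)
        assert set(t1.ids) == set(t2.ids) and len(t1) == math.ceil(10 * 0.25)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.0)

    @given(n=st.integers(1, 10000), frac=st.floats(0.0, 0.99), seed=st.integers(0, 2**16))
    def test_partition_and_ceiling_rule(self, n, frac, seed):
        labels = np.arange(n) % 2
        ds = Dataset(
            [MoleculeRecord(id=f"m{i}", smiles="C", label=int(labels[i])) for i in range(n)]
        )
        train, test = split_dataset(ds, SplitSpec(test_fraction=frac, seed=seed))
        assert len(test) == math.ceil(n * frac)
        assert len(train) + len(test) == n
        assert set(train.ids).isdisjoint(test.ids)

    def test_stratified_mode_keeps_total_quota(self):
        ds = _bulk(30, 70, "s")
        train, test = split_dataset(ds, SplitSpec(test_fraction=0.2, seed=3, stratified=True))
        assert len(test) == 20
        assert test.n_active == 6  # 20 * 0.3

class TestSimilarityFilter:
    def test_identical_candidate_retained(self):
        refs = Dataset([MoleculeRecord("r1", "c1ccc(S(=O)(=O)N)cc1")])
        cands = Dataset([MoleculeRecord("c1", "c1ccc(S(=O)(=O)N)cc1")])
        assert len(filter_by_similarity(cands, refs, 0.5)) == 1

    def test_dissimilar_candidate_removed(self):
        refs = Dataset([MoleculeRecord("r1", "c1ccc2c(c1)cc(S(=O)(=O)N)cc2")])
        cands = Dataset([MoleculeRecord("c1", "II")])  # no common bits
        assert len(filter_by_similarity(cands, refs, 0.5)) == 0

    def test_empty_references(self):
        with pytest.raises(ValueError, match="empty reference"):
            filter_by_similarity(Dataset([MoleculeRecord("c", "C")]), Dataset([]), 0.5)

    def test_matches_brute_force_all_pairs(self, tiny_dataset):
        ds, _ = tiny_dataset
        cands = Dataset(ds.records[:20])
        refs = Dataset(ds.records[20:30])
        got = {r.id for r in filter_by_similarity(cands, refs, 0.5)}
        expected = set()
        seen = set()
        from rdkit import Chem

        for r in cands:
            canon = Chem.CanonSmiles(r.smiles)
            if canon in seen:
                continue
            seen.add(canon)
            bm = max(tanimoto(morgan_fp(r.smiles), morgan_fp(q.smiles)) for q in refs)
            bt = max(tanimoto(topological_fp(r.smiles), topological_fp(q.smiles)) for q in refs)
            if bm > 0.5 and bt > 0.5:
                expected.add(r.id)
        assert got == expected


def test_deduplication_is_idempotent():
    ds = Dataset(
        [
            MoleculeRecord("a", "CCO"),
            MoleculeRecord("b", "OCC"),  # same molecule, different spelling
            MoleculeRecord("c", "C"),
        ]
    )
    once = deduplicate(ds)
    twice = deduplicate(once)
    assert [r.id for r in once] == ["a", "c"]
    assert [r.id for r in twice] == [r.id for r in once]
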