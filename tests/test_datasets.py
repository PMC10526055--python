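"""Few-shot dataset construction: filters, top-k, nesting, statistics."""

import numpy as np
import pytest

from moladapt.chem import MoleculeRecord, count_aromatic_rings, has_halogen
from moladapt.datasets import (ALL_TASKS, STRUCTURE_TASKS, build_task_datasets,
                               dataset_stats, filter_structure,
                               nested_subsample, task_predicate,
                               top_k_by_property)
from moladapt.metrics import quality
from moladapt.properties import PROPERTY_FUNCTIONS


class TestFilterStructure:
    def test_ring_task_keeps_exact_counts(self, library):
        kept = filter_structure(library, "ring_2")
        oracle = [r for r in library if count_aromatic_rings(r) == 2]
        assert [r.canonical_smiles for r in kept] == [
            r.canonical_smiles for r in oracle
        ]

    def test_benzene_membership(self, library):
        benzene = next(r for r in library if r.canonical_smiles == "c1ccccc1")
        assert benzene in filter_structure(library, "ring_1")
        assert benzene not in filter_structure(library, "halogen")

    def test_halogen_filter(self, library):
        kept = filter_structure(library, "halogen")
        assert all(has_halogen(r) for r in kept)
        assert len(kept) == sum(has_halogen(r) for r in library)

    def test_empty_result_raises_naming_task(self):
        acyclics = [MoleculeRecord.from_smiles(s) for s in ("CC", "CCO")]
        with pytest.raises(ValueError, match="ring_3"):
            filter_structure(acyclics, "ring_3")


class TestTopK:
    def test_whole_pool_is_full_sort(self, library):
        fn = PROPERTY_FUNCTIONS["QED"]
        top = top_k_by_property(library, "QED", len(library))
        scores = [fn(r) for r in top]
        assert scores == sorted(scores, reverse=True)

    def test_k1_is_argmax(self, library):
        fn = PROPERTY_FUNCTIONS["QED"]
        top = top_k_by_property(library, "QED", 1)
        assert fn(top[0]) == max(fn(r) for r in library)

    def test_matches_full_sort_oracle(self, library):
        pool = library[:10]
        fn = PROPERTY_FUNCTIONS["PLOGP_RAW"]
        expected = sorted(pool, key=lambda r: (-fn(r), r.canonical_smiles))[:4]
        got = top_k_by_property(pool, "PLOGP_RAW", 4)
        assert [r.canonical_smiles for r in got] == [
            r.canonical_smiles for r in expected
        ]

    def test_nested_by_construction(self, library):
        top5 = {r.canonical_smiles for r in top_k_by_property(library, "QED", 5)}
        top10 = {r.canonical_smiles for r in top_k_by_property(library, "QED", 10)}
        assert top5 <= top10

    def test_adding_lower_scorers_never_changes_top_k(self, library):
        fn = PROPERTY_FUNCTIONS["QED"]
        pool = library[:20]
        top = top_k_by_property(pool, "QED", 5)
        floor = min(fn(r) for r in top)
        lower = [r for r in library[20:] if fn(r) < floor]
        assert lower  # fixture sanity
        top_again = top_k_by_property(pool + lower, "QED", 5)
        assert [r.canonical_smiles for r in top] == [
            r.canonical_smiles for r in top_again
        ]

    def test_k_exceeding_pool_rejected(self, library):
        with pytest.raises(ValueError):
            top_k_by_property(library, "QED", len(library) + 1)


class TestNestedSubsample:
    def test_nesting_chain(self, library):
        sizes = (20, 10, 5)
        ds = nested_subsample(library, "halogen", sizes=sizes, seed=3)
        for smaller, larger in zip(ds[1:], ds[:-1]):
            assert {m.canonical_smiles for m in smaller.molecules} <= {
                m.canonical_smiles for m in larger.molecules
            }
            assert smaller.parent is larger

    def test_reproducible_from_seed(self, library):
        a = nested_subsample(library, "halogen", sizes=(10, 5), seed=9)
        b = nested_subsample(library, "halogen", sizes=(10, 5), seed=9)
        assert a[-1].smiles == b[-1].smiles

    def test_pool_equal_to_largest_size_is_identity(self, library):
        pool = library[:10]
        ds = nested_subsample(pool, "halogen", sizes=(10, 5), seed=0)
        assert {m.canonical_smiles for m in ds[0].molecules} == {
            m.canonical_smiles for m in pool
        }

    def test_pool_too_small_rejected_with_requirement(self, library):
        with pytest.raises(ValueError, match="100"):
            nested_subsample(library[:8], "halogen", sizes=(100, 5), seed=0)


class TestBuildTaskDatasets:
    @pytest.mark.parametrize("task", STRUCTURE_TASKS)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_structure_tasks_nested_and_pure(self, library, task, seed):
        sizes = (6, 3)
        ds_list = build_task_datasets(library, task, sizes=sizes, seed=seed)
        predicate = task_predicate(task)
        for ds in ds_list:
            # by construction every member satisfies the predicate
            assert quality(ds.molecules, predicate) == 1.0
        small, large = ds_list[1], ds_list[0]
        assert {m.canonical_smiles for m in small.molecules} <= {
            m.canonical_smiles for m in large.molecules
        }

    def test_property_tasks_are_top_k(self, library):
        ds_list = build_task_datasets(library, "qed_top", sizes=(10, 5), seed=0)
        assert ds_list[0].smiles == [
            r.canonical_smiles for r in top_k_by_property(library, "QED", 10)
        ]
        assert set(ds_list[1].smiles) <= set(ds_list[0].smiles)


class TestDatasetStats:
    def test_columns_match_standalone_recomputation(self, library):
        from moladapt import metrics, properties

        ds = build_task_datasets(library, "halogen", sizes=(5,), seed=0)[0]
        row = dataset_stats(ds)
        assert row["num"] == 5
        assert row["diversity"] == pytest.approx(metrics.diversity(ds.molecules))
        assert row["qed"] == pytest.approx(
            np.mean([properties.qed(m) for m in ds.molecules])
        )
        assert row["halogen"] == 5
        ring_cols = (row["ring_0"], row["ring_1"], row["ring_2"],
                     row["ring_3"], row["ring_4plus"])
        assert sum(ring_cols) == 5

    def test_identical_molecules_give_zero_diversity(self):
        from moladapt.datasets import FewShotDataset

        mols = [MoleculeRecord.from_smiles("CCCl") for _ in range(5)]
        ds = FewShotDataset(task="halogen", shots=5, molecules=mols)
        row = dataset_stats(ds)
        assert row["diversity"] == 0.0 and row["num"] == 5

    def test_singleton_diversity_undefined(self, library):
        from moladapt.datasets import FewShotDataset

        ds = FewShotDataset(task="halogen", shots=1, molecules=library[:1])
        assert dataset_stats(ds)["diversity"] is None
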