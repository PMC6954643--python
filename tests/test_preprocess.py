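"""Phenotype categorization, residualization, SNV subsetting, LD clumping."""

import numpy as np
import pandas as pd
import pytest

from cnmtf.preprocess import (
    GenotypeMatrix,
    categorize_phenotype,
    clump_ld,
    impute_missing,
    residualize_trait,
    select_snv_subset,
)


class TestCategorize:
    def test_ldl_style_cutoffs(self):
        # controls < 100 mg/dl, cases >= 160 mg/dl, intermediate excluded
        values = [95, 130, 160, 99.9, 100]
        labels = categorize_phenotype(values, 100, 160, "low_is_control")
        assert list(labels) == ["control", "excluded", "case", "control", "excluded"]

    def test_hdl_style_orientation(self):
        # controls > 60 mg/dl, cases < 40 mg/dl
        labels = categorize_phenotype([65, 50, 35], 60, 40, "high_is_control")
        assert list(labels) == ["control", "excluded", "case"]

    def test_orientation_reversal_maps_onto_same_code_path(self, rng):
        # negating values and cutoffs maps the HDL-like path onto the LDL-like one
        values = rng.normal(50, 20, 200)
        values = values[(np.abs(values - 60) > 1e-6) & (np.abs(values - 40) > 1e-6)]
        hi = categorize_phenotype(values, 60, 40, "high_is_control")
        lo = categorize_phenotype(-values, -60, -40, "low_is_control")
        # boundary conventions differ only at exact cutoff values, excluded here
        mism = (hi != lo) & (hi != "excluded") & (lo != "excluded")
        assert not mism.any()

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError, match="controls"):
            categorize_phenotype([200, 210, 220], 100, 160, "low_is_control")

    def test_inconsistent_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            categorize_phenotype([1, 2], 160, 100, "low_is_control")


class TestResidualize:
    def test_trait_equal_to_covariate_gives_zero_residuals(self, rng):
        x = rng.normal(size=50)
        res = residualize_trait(x, x[:, None])
        assert np.abs(res).max() < 1e-10

    def test_empty_covariates_mean_center(self, rng):
        y = rng.normal(10, 2, 30)
        res = residualize_trait(y, None)
        assert np.allclose(res, y - y.mean())

    def test_residuals_orthogonal_to_confounder(self, rng):
        age = rng.normal(50, 10, 500)
        y = 2 * age + rng.normal(0, 1, 500)
        res = residualize_trait(y, age[:, None])
        assert abs(np.corrcoef(res, age)[0, 1]) < 0.05

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=40)
        cov = pd.DataFrame({"age": x, "age_copy": x})
        with pytest.raises(ValueError, match="age"):
            residualize_trait(rng.normal(size=40), cov)


class TestSelectSubset:
    def test_one_hop_expansion(self, annotations_frame):
        snvs, genes = select_snv_subset({"g1"}, [("g1", "g2")], annotations_frame)
        assert genes == {"g1", "g2"}
        assert snvs == {"rs1", "rs2", "rs3", "rs4"}  # g3's SNV excluded

    def test_isolated_seed_kept(self, annotations_frame):
        snvs, genes = select_snv_subset({"g1"}, [], annotations_frame)
        assert genes == {"g1"}
        assert snvs == {"rs1", "rs2"}

    def test_second_neighbours_excluded(self):
        ann = pd.DataFrame(
            {
                "snv_id": [f"rs{i}" for i in range(4)],
                "gene": ["g1", "g2", "g3", "g4"],
                "position": [1, 2, 3, 4],
                "impact_class": ["low"] * 4,
                "predicted_deleterious": [False] * 4,
                "known_association": [False] * 4,
            }
        )
        _, genes = select_snv_subset({"g1", "g2"}, [("g1", "g3"), ("g3", "g4")], ann)
        assert genes == {"g1", "g2", "g3"}  # g4 is a second neighbour

    def test_empty_seed_set_rejected(self, annotations_frame):
        with pytest.raises(ValueError):
            select_snv_subset(set(), [], annotations_frame)


def _geno_with(rows, labels_n=None):
    rows = np.asarray(rows)
    return GenotypeMatrix(rows, [f"rs{i}" for i in range(rows.shape[0])],
                          [f"S{j}" for j in range(rows.shape[1])])


def _ann_for(geno, gene="g1", damaging=None):
    n = len(geno.snv_ids)
    damaging = damaging or []
    return pd.DataFrame(
        {
            "snv_id": geno.snv_ids,
            "gene": [gene] * n,
            "position": np.arange(n) + 1,
            "impact_class": ["high" if s in damaging else "low" for s in geno.snv_ids],
            "predicted_deleterious": [False] * n,
            "known_association": [False] * n,
        }
    )


class TestClumping:
    @pytest.fixture()
    def labels(self, rng):
        return np.array(["case" if v else "control" for v in rng.integers(0, 2, 40)])

    def test_perfect_ld_collapses_to_one_proxy(self, rng, labels):
        row = rng.integers(0, 3, 40)
        geno = _geno_with([row, row.copy(), rng.integers(0, 3, 40)])
        res = clump_ld(geno, labels, _ann_for(geno), 0.5)
        assert len(res.genotypes.snv_ids) == 2
        assert len(res.proxy_map) == 1

    def test_independent_rows_both_kept(self, rng, labels):
        geno = _geno_with([rng.integers(0, 3, 40), rng.integers(0, 3, 40)])
        res = clump_ld(geno, labels, _ann_for(geno), 0.5)
        assert len(res.genotypes.snv_ids) == 2

    def test_proxy_inherits_damaging_flag(self, rng, labels):
        row = rng.integers(0, 3, 40)
        geno = _geno_with([row, row.copy()])
        ann = _ann_for(geno, damaging=["rs1"])  # the non-proxy twin is damaging
        res = clump_ld(geno, labels, ann, 0.5)
        kept = res.annotations.iloc[0]
        assert kept["impact_class"] == "high"

    def test_clumping_is_idempotent(self, rng, labels):
        rows = [rng.integers(0, 3, 40) for _ in range(6)]
        rows[1] = rows[0].copy()
        rows[4] = rows[3].copy()
        geno = _geno_with(rows)
        once = clump_ld(geno, labels, _ann_for(geno), 0.5)
        twice = clump_ld(once.genotypes, labels, once.annotations, 0.5)
        assert twice.genotypes.snv_ids == once.genotypes.snv_ids
        assert np.array_equal(twice.genotypes.values, once.genotypes.values)

    def test_retained_count_monotone_in_threshold(self, rng, labels):
        rows = []
        base = rng.integers(0, 3, 40)
        for _ in range(8):
            noisy = base.copy()
            flip = rng.random(40) < 0.2
            noisy[flip] = rng.integers(0, 3, flip.sum())
            rows.append(noisy)
        geno = _geno_with(rows)
        counts = []
        for thr in (0.9, 0.6, 0.3, 0.1):
            res = clump_ld(geno, labels, _ann_for(geno), thr)
            counts.append(len(res.genotypes.snv_ids))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_row_warns_and_survives(self, rng, labels):
        geno = _geno_with([np.ones(40, dtype=int), rng.integers(0, 3, 40)])
        with pytest.warns(UserWarning, match="constant"):
            res = clump_ld(geno, labels, _ann_for(geno), 0.5)
        assert "rs0" in res.genotypes.snv_ids

    def test_requires_both_classes(self, rng):
        geno = _geno_with([rng.integers(0, 3, 10)])
        with pytest.raises(ValueError, match="both"):
            clump_ld(geno, ["control"] * 10, _ann_for(geno), 0.5)


class TestImputation:
    def test_mode_imputation_and_dropping(self):
        vals = np.array(
            [
                [0, 0, 0, 1, -1],  # 20% missing -> dropped at 5% threshold
                [2, 2, 2, 2, 2],
                [1, 1, 1, 1, 1],
            ]
        )
        geno = GenotypeMatrix(vals, ["a", "b", "c"], list("vwxyz"))
        out = impute_missing(geno, max_missingness=0.05)
        assert out.snv_ids == ["b", "c"]
        out2 = impute_missing(geno, max_missingness=0.5)
        assert out2.values[0, 4] == 0  # mode of observed genotypes
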