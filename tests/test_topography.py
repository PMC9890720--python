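import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunotopo import synthcore, topography
from immunotopo.tissueclass import CompartmentMask
from immunotopo.topography import UnusableCaseError


@pytest.fixture()
def half_mask():
    """20x20 mask at 1 um/px: left half tumour, right half stroma."""
    labels = np.full((20, 20), 2, dtype=np.uint8)
    labels[:, :10] = 1
    return CompartmentMask(labels=labels, pixel_size_um=1.0)


class TestAssignCells:
    def test_centroid_labels_assigned(self, half_mask):
        det = pd.DataFrame({"x_um": [2.0, 15.0], "y_um": [5.0, 5.0],
                            "positive": [True, True]})
        out = topography.assign_cells(det, half_mask)
        assert list(out["compartment"]) == ["tumour", "stroma"]

    def test_out_of_frame_unassigned_with_warning(self, half_mask):
        det = pd.DataFrame({"x_um": [50.0], "y_um": [5.0], "positive": [True]})
        with pytest.warns(UserWarning):
            out = topography.assign_cells(det, half_mask)
        assert out["compartment"].iloc[0] == "unassigned"

    def test_conservation_of_counts(self, half_mask):
        rng = np.random.default_rng(0)
        det = pd.DataFrame({"x_um": rng.uniform(-5, 25, 100),
                            "y_um": rng.uniform(-5, 25, 100),
                            "positive": True})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = topography.assign_cells(det, half_mask)
        counts = out["compartment"].value_counts()
        assert counts.sum() == 100

    def test_agreement_with_generator_truth(self):
        spec = synthcore.CoreSpec(core_diameter_um=400.0, pixel_size_um=2.0,
                                  marker_densities={"CD3": (400.0, 300.0)}, seed=3)
        _, truth = synthcore.generate_core(spec)
        out = topography.assign_cells(truth.cells, truth.mask)
        agree = (out["compartment"] == truth.cells["compartment"]).mean()
        assert agree >= 0.95


class TestDensity:
    def test_simple_arithmetic(self, half_mask):
        det = pd.DataFrame({"x_um": [2.0] * 10, "y_um": [5.0] * 10, "positive": True})
        out = topography.assign_cells(det, half_mask)
        # shrink mask areas by construction: 10x20 px tumour = 200 um^2 = 2e-4 mm^2
        rec = topography.compute_density(out, half_mask, "c1", "CD3")
        assert rec.tumour_density == pytest.approx(10 / 2e-4)
        assert rec.stroma_density == 0.0
        assert rec.overall_density == pytest.approx(10 / 4e-4)

    def test_pixel_size_scaling(self):
        labels = np.full((10, 10), 1, dtype=np.uint8)
        labels[:, 5:] = 2
        m1 = CompartmentMask(labels=labels, pixel_size_um=1.0)
        m2 = CompartmentMask(labels=labels, pixel_size_um=2.0)
        assert m2.tumour_area_mm2 == pytest.approx(4 * m1.tumour_area_mm2)

    def test_missing_compartment_flags_unusable(self):
        labels = np.full((10, 10), 1, dtype=np.uint8)  # no stroma at all
        mask = CompartmentMask(labels=labels, pixel_size_um=1.0)
        det = pd.DataFrame({"x_um": [], "y_um": [], "positive": []})
        with pytest.raises(UnusableCaseError):
            topography.compute_density(
                topography.assign_cells(det, mask), mask, "c", "CD3"
            )


class TestThresholds:
    def test_odd_n_median(self):
        records = pd.DataFrame({"marker": "CD3",
                                "overall_density": [100.0, 200.0, 300.0],
                                "tumour_density": 1.0, "stroma_density": 1.0})
        out = topography.cohort_median_threshold(records)
        assert out["cutoff"].iloc[0] == 200.0

    def test_even_n_mean_of_middle_pair(self):
        records = pd.DataFrame({"marker": "CD3",
                                "overall_density": [100.0, 200.0, 300.0, 400.0],
                                "tumour_density": 1.0, "stroma_density": 1.0})
        out = topography.cohort_median_threshold(records)
        assert out["cutoff"].iloc[0] == 250.0

    def test_pooled_compartment_derivation(self):
        records = pd.DataFrame({"marker": "CD3", "overall_density": [0.0, 0.0],
                                "tumour_density": [100.0, 300.0],
                                "stroma_density": [200.0, 400.0]})
        out = topography.cohort_median_threshold(records, "pooled_compartment_median")
        assert out["cutoff"].iloc[0] == 250.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({"marker": rng.choice(["a", "b"], 40),
                             "overall_density": rng.uniform(10, 500, 40),
                             "tumour_density": 1.0, "stroma_density": 1.0})
        t1 = topography.cohort_median_threshold(base)
        t2 = topography.cohort_median_threshold(base.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(t1, t2)


class TestPhenotypeCall:
    @pytest.mark.parametrize(
        "tumour,stroma,expected",
        [(2.0, 0.0, "hot"), (0.0, 2.0, "excluded"), (0.0, 0.0, "cold"),
         (1.0, 5.0, "hot")],  # decision order: tumour-high wins
    )
    def test_decision_rule(self, tumour, stroma, expected):
        assert topography.call_phenotype(tumour, stroma, 1.0) == expected

    def test_missing_density_no_call(self):
        with pytest.raises(UnusableCaseError):
            topography.call_phenotype(np.nan, 1.0, 1.0)

    def test_combined_markers_and_rule(self):
        cutoffs = {"CD3": 100.0, "CD4": 100.0}
        # both hot-pattern -> hot
        assert topography.combine_markers(
            {"CD3": (200.0, 50.0), "CD4": (150.0, 40.0)}, cutoffs) == "hot"
        # CD3 tumour-high, CD4 tumour-low, both stroma-high -> excluded (AND)
        assert topography.combine_markers(
            {"CD3": (200.0, 150.0), "CD4": (50.0, 150.0)}, cutoffs) == "excluded"
        # single-marker combo degenerates to the plain call
        assert topography.combine_markers({"CD3": (200.0, 50.0)}, cutoffs) == \
            topography.call_phenotype(200.0, 50.0, 100.0)

    def test_or_and_mean_rules_differ_where_expected(self):
        cutoffs = {"a": 100.0, "b": 100.0}
        dens = {"a": (150.0, 0.0), "b": (20.0, 0.0)}
        assert topography.combine_markers(dens, cutoffs, rule="and") == "cold"
        assert topography.combine_markers(dens, cutoffs, rule="or") == "hot"
        # mean of normalized densities: (1.5 + 0.2)/2 < 1 -> cold
        assert topography.combine_markers(dens, cutoffs, rule="mean") == "cold"


class TestDichotomizeAndBins:
    def test_boundary_goes_low(self):
        assert topography.dichotomize(291.6, 291.6) == "low"
        assert topography.dichotomize(0.0, 291.6) == "low"
        assert topography.dichotomize(291.7, 291.6) == "high"

    def test_half_of_distinct_cohort_high_under_own_median(self):
        rng = np.random.default_rng(2)
        dens = rng.permutation(np.linspace(10, 800, 40))
        cutoff = float(np.median(dens))
        labels = [topography.dichotomize(d, cutoff) for d in dens]
        assert labels.count("high") == 20

    def test_semiquant_examples(self):
        assert topography.semiquant_bins(0.0) == "0"
        assert topography.semiquant_bins(250.0, (10, 100, 500)) == "++"
        assert topography.semiquant_bins(500.0, (10, 100, 500)) == "+++"

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_semiquant_monotone(self, a, b):
        lo, hi = sorted([a, b])
        levels = topography.SEMIQUANT_LEVELS
        assert levels.index(topography.semiquant_bins(lo)) <= levels.index(
            topography.semiquant_bins(hi)
        )


class TestCPS:
    def test_zero_positive(self):
        res = topography.compute_cps(0, 100)
        assert res.cps == 0.0 and not res.high

    def test_boundary_high(self):
        res = topography.compute_cps(20, 200, cutoff=10.0)
        assert res.cps == pytest.approx(10.0) and res.high

    def test_capped_at_100(self):
        assert topography.compute_cps(300, 200).cps == 100.0

    def test_zero_viable_rejected(self):
        with pytest.raises(UnusableCaseError):
            topography.compute_cps(5, 0)


class TestPhenotypeTable:
    def test_partition_and_recovery_on_plan(self):
        """Phenotype proportions partition to 1 and >= 90% of planned classes
        are recovered on the default synthetic cohort plan."""
        plan, _ = synthcore.draw_cohort_plan(synthcore.CohortSpec(seed=5))
        thresholds = topography.cohort_median_threshold(plan)
        calls = topography.phenotype_table(plan, thresholds)
        props = calls["phenotype"].value_counts(normalize=True)
        assert props.sum() == pytest.approx(1.0)
        merged = calls.merge(
            plan[["case_id", "marker", "phenotype"]].rename(
                columns={"phenotype": "planned"}),
            on=["case_id", "marker"],
        )
        assert (merged["phenotype"] == merged["planned"]).mean() >= 0.90

    def test_combo_calls_present(self):
        plan, _ = synthcore.draw_cohort_plan(synthcore.CohortSpec(n_cases=20, seed=6))
        thresholds = topography.cohort_median_threshold(plan)
        calls = topography.phenotype_table(
            plan, thresholds, combos={"CD3/CD8": ["CD3", "CD8"]}
        )
        assert (calls["marker"] == "CD3/CD8").sum() == 20
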