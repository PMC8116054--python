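"""Tests for fossil-vs-extant RLSI classification and element profiles."""

import numpy as np
import pandas as pd
import pytest

from limbjoints import classify
from limbjoints.classify import (
    DistributionSummary,
    classify_specimen,
    human_like_count,
    relative_element_profile,
    summarize_distribution,
)
from limbjoints.measurements import (
    FULL_SPEC,
    JointDimensionSet,
    RLSIValue,
    RatioSpec,
    preserved_spec,
    rlsi,
)
from limbjoints.synthetic import (
    SyntheticConfig,
    TaxonSample,
    TaxonSummary,
    generate_taxon_sample,
)


class TestSummarizeDistribution:
    def test_inclusive_linear_interpolation_convention(self):
        s = summarize_distribution([1, 2, 3, 4, 5], "t", "spec")
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert (s.min, s.max) == (1.0, 5.0)

    def test_constant_sample_collapses(self):
        s = summarize_distribution([2.0] * 8, "t", "spec")
        assert s.min == s.q1 == s.median == s.q3 == s.max == 2.0

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            summarize_distribution([1, 2, 3, 4], "t", "spec")

    def test_human_synthetic_median_negative(self, extant_samples):
        """Humans have proportionally larger lower-limb joints: median < 0."""
        values = extant_samples["Homo sapiens"].rlsi_values(FULL_SPEC)
        assert summarize_distribution(values, "Homo sapiens",
                                      "full").median < 0


class TestClassifySpecimen:
    def summary(self, **kw):
        base = dict(taxon="t", spec_label="s", n=10, min=-1.0, q1=-0.5,
                    median=0.0, q3=0.5, max=1.0)
        base.update(kw)
        return DistributionSummary(**base)

    def spec(self):
        return RatioSpec(("G",), ("F",), label="s")

    def test_boundaries_are_inclusive(self):
        s = self.summary()
        calls = {
            v: classify_specimen(
                RLSIValue("x", self.spec(), v), [s])[0].call
            for v in (-1.0, -0.5, 0.5, 1.0, 1.0001, -1.0001)
        }
        assert calls[-1.0] == "within_range" and calls[1.0] == "within_range"
        assert calls[-0.5] == "within_iqr" and calls[0.5] == "within_iqr"
        assert calls[1.0001] == "outside" and calls[-1.0001] == "outside"
        at_min = classify_specimen(
            RLSIValue("x", self.spec(), -1.0), [s])[0]
        assert at_min.margin == pytest.approx(0.0)

    def test_outside_reports_side_and_margin(self):
        s = self.summary()
        low = classify_specimen(RLSIValue("x", self.spec(), -1.25), [s])[0]
        assert low.call == "outside" and low.below_min
        assert low.margin == pytest.approx(0.25)

    def test_spec_mismatch_rejected(self):
        s = self.summary(spec_label="other")
        with pytest.raises(ValueError, match="spec mismatch"):
            classify_specimen(RLSIValue("x", self.spec(), 0.0), [s])

    def test_enlarging_sample_never_flips_within_to_outside(self, rng):
        values = rng.normal(size=200)
        small = summarize_distribution(values[:50], "t", "s")
        big = summarize_distribution(values, "t", "s")
        assert big.min <= small.min and big.max >= small.max
        for v in np.linspace(small.min, small.max, 25):
            call = classify_specimen(
                RLSIValue("x", self.spec(), float(v)), [big])[0]
            assert call.call != "outside"

    def test_degenerate_limit_is_point_comparison(self):
        """rho -> 1 with sd -> 0 collapses the taxon to its mean RLSI."""
        summary = TaxonSummary("t", {c: (m, 1e-6, 20) for c, m in
                                     (("G", 30.0), ("F", 40.0))})
        sample = generate_taxon_sample(summary, SyntheticConfig(
            seed=0, rho=0.99, n_per_taxon={"t": 50}))
        spec = RatioSpec(("G",), ("F",), label="G:F")
        dist = summarize_distribution(sample.rlsi_values(spec), "t", "G:F")
        assert dist.max - dist.min < 1e-6
        center = float(np.log(30.0 / 40.0))
        hit = classify_specimen(
            RLSIValue("x", spec, dist.median), [dist])[0]
        miss = classify_specimen(
            RLSIValue("x", spec, center + 0.01), [dist])[0]
        assert hit.call != "outside" and miss.call == "outside"


class TestFossilCalls:
    def test_lucy_human_like_and_outside_large_bodied_apes(
            self, fossil_by_id, extant_samples):
        lucy = fossil_by_id["A.L. 288-1"]
        count, table = human_like_count([lucy], extant_samples)
        row = table.iloc[0]
        assert row.human_like
        # Pan is excluded here: its published talar SD (34.1 mm on an
        # 18.1 mm mean) makes the synthetic Pan range under any T-bearing
        # spec vacuously wide.
        for taxon in ("Gorilla", "Pongo", "Hylobatidae"):
            assert row[f"call_{taxon}"] == "outside"

    def test_stw431_sits_in_hylobatid_iqr_modally(
            self, fossil_by_id, summaries):
        stw = fossil_by_id["StW 431"]
        hits = 0
        for seed in range(10):
            sample = generate_taxon_sample(
                summaries["Hylobatidae"], SyntheticConfig(seed=seed))
            spec = preserved_spec(stw, FULL_SPEC)
            dist = summarize_distribution(
                sample.rlsi_values(spec), "Hylobatidae", spec.label)
            call = classify_specimen(rlsi(stw, spec), [dist])[0]
            hits += call.call == "within_iqr"
        assert hits >= 6

    def test_empty_fossil_list(self, extant_samples):
        count, table = human_like_count([], extant_samples)
        assert count == 0 and table.empty

    def test_specimen_at_human_means_is_human_like(
            self, summaries, extant_samples):
        means = {c: v[0] for c, v in summaries["Homo sapiens"].stats.items()}
        dims = JointDimensionSet("mean-human", "H. sapiens", means)
        count, table = human_like_count([dims], extant_samples)
        assert count == 1 and table.iloc[0].human_call == "within_iqr"

    def test_below_human_range_counts_as_human_like(self, extant_samples):
        """A fossil with even larger relative lower-limb joints than any
        sampled human is beyond the human condition, not ape-like."""
        human = extant_samples["Homo sapiens"]
        spec = RatioSpec(("G",), ("F",), label="G:F")
        low = float(human.rlsi_values(spec).min()) - 0.05
        dims = JointDimensionSet("hyper-biped", "x",
                                 {"G": 30.0 * np.exp(low), "F": 30.0})
        count, table = human_like_count([dims], extant_samples)
        assert table.iloc[0].human_call == "outside"
        assert table.iloc[0].below_human_min and table.iloc[0].human_like

    def test_seed_sweep_reports_mode_and_frequencies(
            self, fossils, summaries):
        sweep = classify.seed_sweep(fossils, summaries, base_seed=0,
                                    n_seeds=5)
        assert len(sweep["per_seed_counts"]) == 5
        assert sweep["modal_count"] in sweep["per_seed_counts"]
        assert sweep["human_like_frequency"]["DIK-1-1"] == 1.0
        assert 0 < sweep["modal_set_frequency"] <= 1


def test_plot_rlsi_panel_writes_figure(fossil_by_id, extant_samples,
                                       tmp_path):
    lucy = fossil_by_id["A.L. 288-1"]
    spec = preserved_spec(lucy, FULL_SPEC)
    summaries = [
        summarize_distribution(s.rlsi_values(spec), t, spec.label)
        for t, s in extant_samples.items()
    ]
    out = tmp_path / "panel.svg"
    classify.plot_rlsi_panel(summaries, [rlsi(lucy, spec)], path=str(out))
    assert out.exists() and out.stat().st_size > 1000


class TestElementProfile:
    def test_reference_profile_is_exactly_zero(self, extant_samples, rng):
        human = extant_samples["Homo sapiens"]
        prof = relative_element_profile(human, human, n_boot=200, rng=rng)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in prof.index.values())

    def test_specimen_at_reference_geomeans_is_zero(self, extant_samples):
        human = extant_samples["Homo sapiens"]
        geo = np.exp(np.log(human.data[["F", "Sac", "B"]]).mean(axis=0))
        dims = JointDimensionSet("ref-like", "x", dict(geo))
        prof = relative_element_profile(dims, human)
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in prof.index.values())

    def test_scale_invariance_and_closure(self, fossil_by_id, extant_samples):
        human = extant_samples["Homo sapiens"]
        wt = fossil_by_id["KNM-WT 15000"]
        prof = relative_element_profile(wt, human)
        scaled = relative_element_profile(wt.scaled(3.7), human)
        for e in prof.index:
            assert prof.index[e] == pytest.approx(scaled.index[e], abs=1e-10)
        assert sum(prof.index.values()) == pytest.approx(0.0, abs=1e-10)

    def test_erectus_and_afarensis_swap_femur_sacrum_pattern(
            self, fossil_by_id, extant_samples):
        """H. erectus reaches a low RLSI with a large femoral head and small
        sacrum; A. afarensis shows the opposite ordering."""
        human = extant_samples["Homo sapiens"]
        wt = relative_element_profile(fossil_by_id["KNM-WT 15000"], human)
        lucy = relative_element_profile(fossil_by_id["A.L. 288-1"], human)
        assert wt.index["F"] > 0 and wt.index["Sac"] < 0
        assert wt.index["F"] > wt.index["Sac"]
        assert lucy.index["Sac"] > lucy.index["F"]

    def test_missing_element_flagged(self, fossil_by_id, extant_samples):
        human = extant_samples["Homo sapiens"]
        prof = relative_element_profile(fossil_by_id["DIK-1-1"], human)
        assert set(prof.missing) == {"F", "Sac", "B"}

    def test_bootstrap_ci_coverage_near_nominal(self):
        """95% CIs cover the known generating index in ~95% of replicates."""
        rng = np.random.default_rng(2024)
        mu_sub = np.log([33.0, 28.0, 63.0])   # subject log-scale means
        mu_ref = np.log([44.5, 38.6, 59.1])   # reference log-scale means
        truth = ((mu_sub - mu_sub.mean()) - (mu_ref - mu_ref.mean()))[0]
        sigma, n_sub, n_ref, reps = 0.08, 60, 67, 500
        covered = 0
        for _ in range(reps):
            sub = np.exp(mu_sub + sigma * rng.standard_normal((n_sub, 3)))
            ref = np.exp(mu_ref + sigma * rng.standard_normal((n_ref, 3)))
            prof = relative_element_profile(
                TaxonSample("sub", pd.DataFrame(sub, columns=["F", "Sac", "B"])),
                TaxonSample("ref", pd.DataFrame(ref, columns=["F", "Sac", "B"])),
                n_boot=800, rng=rng)
            lo, hi = prof.ci["F"]
            covered += lo <= truth <= hi
        assert covered / reps == pytest.approx(0.95, abs=0.03)
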