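import numpy as np
import pandas as pd
import pytest
import xarray as xr

import biogeo as bg
from biogeo.errors import ValidationError
from biogeo.simulate import translocation_scenario
from biogeo.translocation import partial_spearman


def make_study(rel_abundance, threshold_depth=10_000):
    """Build a one-sample-per-(subject, organ) study from a dict
    {(subject, organ): {taxon: relative abundance}}."""
    taxa = sorted({t for v in rel_abundance.values() for t in v})
    sample_ids, rows, cols = [], [], []
    for (subj, organ), abund in rel_abundance.items():
        sid = f"{subj}.{organ.replace(' ', '-')}"
        sample_ids.append(sid)
        rows.append(
            {"sample_id": sid, "subject_id": subj, "organ": organ,
             "site": "site1", "sample_type": "mucosa"}
        )
        col = np.zeros(len(taxa), dtype=int)
        used = int(sum(round(a * threshold_depth) for a in abund.values()))
        for t, a in abund.items():
            col[taxa.index(t)] = round(a * threshold_depth)
        # filler taxon keeps library size constant so proportions are exact
        cols.append(col)
    taxa_all = taxa + ["filler"]
    counts = np.vstack(
        [np.column_stack(cols), [threshold_depth - c.sum() for c in cols]]
    )
    table = bg.CountTable(taxa_all, sample_ids, counts)
    return table, bg.SampleTable(pd.DataFrame(rows))


class TestCallPresence:
    def test_above_threshold_present(self):
        table, meta = make_study({("p1", "small intestine"): {"A": 0.002}})
        pres = bg.call_presence(table, meta, 0.001)
        assert bool(pres.sel(taxon="A", subject="p1", organ="small intestine"))

    def test_exactly_at_threshold_absent(self):
        table, meta = make_study({("p1", "stomach"): {"A": 0.001}})
        pres = bg.call_presence(table, meta, 0.001)
        assert not bool(pres.sel(taxon="A", subject="p1", organ="stomach"))

    def test_zero_absent(self):
        table, meta = make_study({("p1", "stomach"): {"A": 0.0, "B": 0.01}})
        pres = bg.call_presence(table, meta, 0.001)
        assert not bool(pres.sel(taxon="A", subject="p1", organ="stomach"))

    @pytest.mark.parametrize("thr_lo, thr_hi", [(0.001, 0.005), (0.002, 0.01)])
    def test_monotone_in_threshold(self, thr_lo, thr_hi, default_study):
        bundle, _ = default_study
        lo = bg.call_presence(bundle.count_table, bundle.samples, thr_lo)
        hi = bg.call_presence(bundle.count_table, bundle.samples, thr_hi)
        assert bool((hi <= lo).all())


class TestCollapseSpecies:
    def _tax(self):
        return bg.TaxonomyTable.from_strings(
            {
                "A": "Bacteria;F;C;O;Fam;G;sp1",
                "B": "Bacteria;F;C;O;Fam;G;sp1",
                "C": "Bacteria;F;C;O;Fam;G;",
            }
        )

    def _presence(self, a, b, c):
        return xr.DataArray(
            np.array([a, b, c]).reshape(3, 1, 1),
            dims=("taxon", "subject", "organ"),
            coords={"taxon": ["A", "B", "C"], "subject": ["p1"], "organ": ["stomach"]},
        )

    def test_or_and_multiplicity(self):
        pres, mult = bg.collapse_species(self._presence(True, False, False), self._tax())
        assert bool(pres.sel(species="sp1").squeeze())
        assert int(mult.sel(species="sp1").squeeze()) == 1
        pres2, mult2 = bg.collapse_species(self._presence(True, True, False), self._tax())
        assert int(mult2.sel(species="sp1").squeeze()) == 2

    def test_unnamed_species_becomes_pseudo_species(self):
        pres, _ = bg.collapse_species(self._presence(False, False, True), self._tax())
        assert "C" in list(pres.coords["species"].values)
        assert bool(pres.sel(species="C"))

    def test_matches_brute_force_on_simulated_study(self, default_study):
        bundle, _ = default_study
        asv = bg.call_presence(bundle.count_table, bundle.samples, 0.001)
        pres, mult = bg.collapse_species(asv, bundle.taxonomy)
        # brute force one (species, subject, organ) cell
        species = str(pres.coords["species"].values[0])
        members = [
            t for t in bundle.count_table.taxon_ids
            if (bundle.taxonomy.rank_value(t, "species") or t) == species
        ]
        manual = asv.sel(taxon=members).any(dim="taxon")
        xr.testing.assert_equal(pres.sel(species=species).drop_vars("species"),
                                manual)


class TestPrevalence:
    def test_boundary_semantics(self):
        pres = xr.DataArray(
            np.array([[True] * 17 + [False] * 16]).reshape(1, 33, 1),
            dims=("species", "subject", "organ"),
            coords={"species": ["sp"], "subject": [f"p{i}" for i in range(33)],
                    "organ": ["stomach"]},
        )
        prev, flag = bg.prevalence_by_organ(pres, 0.5)
        assert prev.loc["sp", "stomach"] == pytest.approx(17 / 33)
        assert bool(flag.loc["sp", "stomach"])
        # exactly 50% is NOT prevalent (strict >)
        pres16 = pres.copy()
        pres16[0, 16, 0] = False
        _, flag16 = bg.prevalence_by_organ(pres16.isel(subject=slice(0, 32)), 0.5)
        assert not bool(flag16.loc["sp", "stomach"])

    def test_extremes(self):
        pres = xr.DataArray(
            np.array([[False, False], [True, True]]).reshape(2, 2, 1),
            dims=("species", "subject", "organ"),
            coords={"species": ["a", "b"], "subject": ["p1", "p2"], "organ": ["skin"]},
        )
        prev, flag = bg.prevalence_by_organ(pres, 0.5)
        assert prev.loc["a", "skin"] == 0.0 and not flag.loc["a", "skin"]
        assert prev.loc["b", "skin"] == 1.0 and bool(flag.loc["b", "skin"])


class TestPartialSpearman:
    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        for _ in range(5):
            z = rng.normal(size=(40, 2))
            x = z @ [0.5, -0.3] + rng.normal(size=40)
            y = z @ [0.2, 0.4] + 0.5 * x + rng.normal(size=40)
            r, p = partial_spearman(x, y, z)
            df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
            ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"],
                                        method="spearman")
            assert r == pytest.approx(ref["r"].iloc[0], abs=1e-10)
            p_col = "p_val" if "p_val" in ref.columns else "p-val"
            assert p == pytest.approx(ref[p_col].iloc[0], abs=1e-8)

    def test_removes_confounded_association(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=60)
        x = z + 0.1 * rng.normal(size=60)
        y = z + 0.1 * rng.normal(size=60)
        r_raw, _ = partial_spearman(x, y, np.zeros((60, 1)))
        r_adj, _ = partial_spearman(x, y, z)
        assert abs(r_adj) < abs(r_raw)


class TestPositiveCorrelationRatio:
    def _abundance(self, matrix, species, subjects, organs):
        return xr.DataArray(
            matrix, dims=("taxon", "subject", "organ"),
            coords={"taxon": species, "subject": subjects, "organ": organs},
        )

    def test_arithmetic_contract(self):
        """8 species, 4 perfectly positively correlated between organs, the
        rest anti-correlated: ratio = 0.5."""
        rng = np.random.default_rng(2)
        subjects = [f"p{i}" for i in range(12)]
        species = [f"sp{i}" for i in range(8)]
        m = np.empty((8, 12, 2))
        for i in range(8):
            x = rng.uniform(0.01, 0.2, 12)
            m[i, :, 0] = x
            m[i, :, 1] = x if i < 4 else x.max() + 0.01 - x
        ab = self._abundance(m, species, subjects, ["esophagus", "stomach"])
        prevalent = pd.DataFrame(True, index=species, columns=["esophagus", "stomach"])
        config = bg.InterOrganConfig(correlation_methods=("spearman",))
        ratio, records = bg.positive_correlation_ratio(ab, prevalent, "esophagus", "stomach", config)
        assert ratio == pytest.approx(0.5)
        assert len(records) == 8

    def test_symmetric_in_organ_order(self):
        rng = np.random.default_rng(3)
        subjects = [f"p{i}" for i in range(10)]
        m = rng.uniform(0, 0.1, size=(5, 10, 2))
        ab = self._abundance(m, [f"sp{i}" for i in range(5)], subjects, ["a_organ", "b_organ"])
        ab = ab.assign_coords(organ=["esophagus", "stomach"])
        prevalent = pd.DataFrame(True, index=ab.coords["taxon"].values,
                                 columns=["esophagus", "stomach"])
        config = bg.InterOrganConfig(correlation_methods=("spearman", "pearson"))
        r1, _ = bg.positive_correlation_ratio(ab, prevalent, "esophagus", "stomach", config)
        r2, _ = bg.positive_correlation_ratio(ab, prevalent, "stomach", "esophagus", config)
        assert r1 == r2

    def test_sparse_species_skipped_not_counted(self):
        subjects = [f"p{i}" for i in range(6)]
        m = np.full((2, 6, 2), np.nan)
        m[0] = 0.05  # quantified everywhere (but constant -> nan correlation)
        m[0, :, 1] = np.linspace(0.01, 0.06, 6)
        m[0, :, 0] = np.linspace(0.01, 0.06, 6)
        m[1, :3, :] = 0.05  # only 3 paired subjects
        ab = self._abundance(m, ["sp0", "sp1"], subjects, ["esophagus", "stomach"])
        prevalent = pd.DataFrame(True, index=["sp0", "sp1"], columns=["esophagus", "stomach"])
        config = bg.InterOrganConfig(correlation_methods=("spearman",))
        ratio, records = bg.positive_correlation_ratio(ab, prevalent, "esophagus", "stomach", config)
        assert list(records["species"]) == ["sp0"]


class TestCoreSpecies:
    def _tensors(self, pres, mult, organs):
        coords = {"species": ["sp"], "subject": ["p7"], "organ": organs}
        p = xr.DataArray(np.array(pres).reshape(1, 1, -1), dims=("species", "subject", "organ"), coords=coords)
        m = xr.DataArray(np.array(mult).reshape(1, 1, -1), dims=("species", "subject", "organ"), coords=coords)
        return p, m

    def test_single_asv_core(self):
        p, m = self._tensors([True, True], [1, 1], ["esophagus", "stomach"])
        calls = bg.core_species(p, m, {"upper_GI": {"esophagus", "stomach"}})
        assert calls.iloc[0]["status"] == "core_single_asv"

    def test_missing_one_organ_absent(self):
        p, m = self._tensors([True, False], [1, 0], ["esophagus", "stomach"])
        calls = bg.core_species(p, m, {"upper_GI": {"esophagus", "stomach"}})
        assert calls.iloc[0]["status"] == "absent"

    def test_multi_asv_core(self):
        p, m = self._tensors([True, True], [2, 3], ["esophagus", "stomach"])
        calls = bg.core_species(p, m, {"upper_GI": {"esophagus", "stomach"}})
        assert calls.iloc[0]["status"] == "core_multi_asv"

    def test_multi_requires_two_everywhere(self):
        p, m = self._tensors([True, True], [2, 1], ["esophagus", "stomach"])
        calls = bg.core_species(p, m, {"upper_GI": {"esophagus", "stomach"}})
        assert calls.iloc[0]["status"] == "core_single_asv"

    def test_unknown_group_organ_rejected(self):
        p, m = self._tensors([True], [1], ["stomach"])
        with pytest.raises(ValidationError, match="absent organs"):
            bg.core_species(p, m, {"g": {"stomach", "appendix"}})


class TestEndToEnd:
    def test_planted_core_species_recovered(self):
        config = bg.simulate.core_recovery_scenario(seed=19, n_subjects=8)
        bundle, truth = bg.generate_study(config)
        cleaned, _ = bg.decontaminate(bundle.count_table, bundle.samples)
        report = bg.translocation_analysis(cleaned, bundle.samples, bundle.taxonomy)
        summary = bg.core_species_summary(report.core_calls).set_index(["species", "group"])
        group_of = {frozenset({"esophagus", "stomach"}): "upper_GI",
                    frozenset({"small intestine", "large intestine"}): "lower_GI"}
        planted_fracs, false_calls = [], []
        for spec in truth.core_species:
            if spec["organs"]:
                group = group_of[frozenset(spec["organs"])]
                planted_fracs.append(summary.loc[(spec["species"], group), "core_fraction"])
            else:
                for group, organs in (("upper_GI", {"esophagus", "stomach"}),
                                      ("lower_GI", {"small intestine", "large intestine"})):
                    if set(spec["absent_in"]) & organs:
                        false_calls.append(summary.loc[(spec["species"], group), "core_fraction"])
        assert np.mean(planted_fracs) >= 0.9
        assert all(f == 0.0 for f in false_calls)

    def test_translocating_fraction_recovered(self):
        ratios = []
        for rep in range(3):
            bundle, _ = bg.generate_study(translocation_scenario(seed=400 + rep))
            report = bg.translocation_analysis(
                bundle.count_table, bundle.samples, bundle.taxonomy
            )
            ratios.append(report.ratios["ratio"].iloc[0])
        assert np.mean(ratios) == pytest.approx(0.3, abs=0.1)
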