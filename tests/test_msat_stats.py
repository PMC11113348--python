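"""Identity and diversity statistics on microsatellite data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nimrescue import msat_stats as ms
from nimrescue import synthetic_data as sd

from conftest import two_deme_dataset, two_deme_freqs


class TestPidSib:
    def test_closed_form_biallelic(self):
        res = ms.pid_sib({"L1": {"A": 0.5, "B": 0.5}})
        assert res.per_locus["L1"] == pytest.approx(0.59375)

    def test_monomorphic_locus_gives_no_power(self):
        res = ms.pid_sib({"L1": {"A": 1.0}})
        assert res.per_locus["L1"] == pytest.approx(1.0)
        # appending a monomorphic locus leaves the cumulative value unchanged
        res2 = ms.pid_sib({"L1": {"A": 0.5, "B": 0.5}, "L2": {"C": 1.0}})
        assert res2.cumulative[-1] == pytest.approx(res2.cumulative[0])

    def test_canonical_panel_magnitude(self, spec):
        wild = {l: spec.freqs["wild_oman"][l] for l in spec.loci[:7]}
        res = ms.pid_sib(wild)
        assert all(b <= a + 1e-12 for a, b in zip(res.cumulative, res.cumulative[1:]))
        # the real 7-locus panel reached ~0.02-0.05; same order of magnitude here
        assert 0.005 <= res.cumulative[-1] <= 0.1
        assert res.min_loci is not None

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ms.pid_sib({"L1": {"A": 0.5, "B": 0.4}})

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_per_locus_value_in_unit_interval(self, weights):
        p = np.array(weights) / np.sum(weights)
        res = ms.pid_sib({"L": p})
        assert 0.25 < res.per_locus["L"] <= 1.0 + 1e-12


class TestConsensusMatching:
    def test_exact_duplicates_merge(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Nejd": 1}, replicates={"Nejd": 2},
                                     dropout_rate=0.0, seed=1)
        rep = ms.consensus_and_match(ds)
        assert rep.n_individuals == 1
        assert len(rep.recaptures) == 1

    def test_exact_recovery_at_zero_dropout(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Jabal Samhan": 10, "Jabal Qamar": 8},
                                     replicates=3.0, dropout_rate=0.0, seed=100)
        # precondition: generator truth has no multilocus genotype collisions
        keys = {tuple(sorted(g.items())) for g in ds.truth.values()}
        assert len(keys) == len(ds.truth)
        rep = ms.consensus_and_match(ds, rescue_dropout=False)
        assert rep.n_individuals == len(ds.truth)
        # consensus genotypes equal the generating truth
        by_sample = {s: lab for s, lab in rep.assignment.items()}
        for row in ds.long.itertuples(index=False):
            lab = by_sample[row.sample_id]
            assert rep.consensus[lab][row.locus] == ds.truth[row.individual_id][row.locus]

    def test_recovery_with_dropout_close_to_truth(self, spec):
        counts = []
        for seed in range(15):
            ds = sd.gen_genotype_dataset(
                spec, {"Jabal Samhan": 17, "Jabal Qara": 5, "Jabal Qamar": 11, "Nejd": 3},
                replicates=3.0, dropout_rate=0.048, seed=seed)
            counts.append(ms.consensus_and_match(ds).n_individuals)
        within = np.mean([abs(c - 36) <= 2 for c in counts])
        assert within >= 0.8, counts

    def test_conflicting_sex_flagged(self, single_locus_dataset_factory):
        ds = single_locus_dataset_factory([("A", "B"), ("A", "B")])
        ds.long.loc[:, "individual_id"] = "x"
        ds.long.loc[1, "sample_id"] = "s0b"
        ds.long.loc[1, "sex_call"] = "F"
        rep = ms.consensus_and_match(ds, min_loci=1, use_sex=False)
        assert rep.sex_conflicts

    def test_min_loci_exclusion_and_validation(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Nejd": 8}, replicates={"Nejd": 2},
                                     dropout_rate=0.0, missing_rate=0.35, seed=2)
        rep = ms.consensus_and_match(ds, min_loci=5)
        assert rep.excluded_samples                      # some samples under-typed
        assert set(rep.excluded_samples) | set(rep.assignment) == set(ds.sample_ids)
        with pytest.raises(ValueError, match="min_loci"):
            ms.consensus_and_match(ds, min_loci=99)


class TestDiversity:
    def test_uhe_closed_form(self, single_locus_dataset_factory):
        ds = single_locus_dataset_factory([("A", "A"), ("A", "B"), ("B", "B"), ("A", "B")])
        div = ms.diversity_summary(ds)
        row = div.per_locus.iloc[0]
        assert row["He"] == pytest.approx(0.5)
        assert row["uHe"] == pytest.approx(0.5 * 8 / 7)
        assert row["Na"] == 2

    def test_monomorphic_group(self, single_locus_dataset_factory):
        ds = single_locus_dataset_factory([("A", "A")] * 4)
        row = ms.diversity_summary(ds).per_locus.iloc[0]
        assert row["Na"] == 1 and row["Ne"] == pytest.approx(1.0)
        assert row["He"] == 0.0 and row["uHe"] == 0.0

    def test_uhe_at_least_he_and_ar_at_most_na(self, field_dataset):
        div = ms.diversity_summary(field_dataset)
        ok = div.per_locus.dropna(subset=["uHe"])
        assert (ok["uHe"] >= ok["He"] - 1e-12).all()
        assert (div.per_locus["Ar"] <= div.per_locus["Na"] + 1e-9).all()

    def test_asymptotic_mean_alleles_per_locus(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Jabal Qara": 400}, replicates={"Jabal Qara": 1},
                                     dropout_rate=0.0, seed=21)
        div = ms.diversity_summary(ds)
        # every wild allele is observed at this size: 19 alleles over 8 loci
        assert div.table["Na"].iloc[0] == pytest.approx(19 / 8)


class TestAmova:
    def test_complete_divergence(self, spec):
        rows = []
        for deme, allele in (("A", "1"), ("B", "2")):
            for i in range(6):
                for l in ("L1", "L2"):
                    rows.append(dict(sample_id=f"{deme}{i}", individual_id=f"{deme}{i}",
                                     region=deme, period="", x_km=0.0, y_km=0.0,
                                     locus=l, allele1=allele, allele2=allele, sex_call="M"))
        ds = sd.GenotypeDataset(long=pd.DataFrame(rows), loci=("L1", "L2"))
        res = ms.amova_fst(ds, permutations=99, seed=0)
        assert res.phi_pt == pytest.approx(1.0)
        assert res.table.loc[0, "pct"] == pytest.approx(100.0)
        assert res.table["pct"].iloc[:2].sum() == pytest.approx(100.0)
        assert res.p_value < 0.05

    def test_null_case_same_source(self, spec):
        nonsig = 0
        for seed in range(8):
            ds = sd.gen_genotype_dataset(spec, {"Jabal Samhan": 12, "Jabal Qara": 12},
                                         replicates=1.0, dropout_rate=0.0, seed=40 + seed)
            res = ms.amova_fst(ds, permutations=99, seed=seed)
            nonsig += res.p_value > 0.05
        assert nonsig >= 6

    def test_generator_truth_recovery(self):
        # two demes with a configured Balding-Nichols divergence on the
        # Phi ~ 0.1 scale: the small-sample estimate recovers the large-sample
        # value for the same realized deme frequencies
        for seed in range(3):
            freqs = two_deme_freqs(0.05, seed)
            truth = ms.amova_fst(two_deme_dataset(freqs, 400, 900 + seed),
                                 permutations=1, seed=0).phi_pt
            est = ms.amova_fst(two_deme_dataset(freqs, 80, 500 + seed),
                               permutations=1, seed=0).phi_pt
            assert 0.03 <= truth <= 0.2
            assert abs(est - truth) <= 0.03

    def test_validation(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Nejd": 5}, replicates={"Nejd": 1},
                                     dropout_rate=0.0, seed=3)
        with pytest.raises(ValueError, match="two groups"):
            ms.amova_fst(ds)


class TestMantelAndAutocorrelation:
    def test_mantel_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.random((10, 10))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        r, p = ms.mantel_ibd(2 * x + 3, x, permutations=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.01

    def test_mantel_structured_distance(self):
        # genetic distance increasing with geography plus noise
        rng = np.random.default_rng(2)
        pts = rng.random((20, 2)) * 100
        geo = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        gen = geo + rng.normal(0, 10, geo.shape)
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        r, p = ms.mantel_ibd(gen, geo, permutations=999, seed=3)
        assert r > 0.5 and p < 0.01

    def test_mantel_null_and_errors(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((12, 12)), rng.random((12, 12))
        a, b = (a + a.T) / 2, (b + b.T) / 2
        np.fill_diagonal(a, 0)
        np.fill_diagonal(b, 0)
        r, p = ms.mantel_ibd(a, b, permutations=199, seed=5)
        assert abs(r) < 0.4
        with pytest.raises(ValueError, match="constant"):
            ms.mantel_ibd(np.ones((5, 5)), a[:5, :5])
        with pytest.raises(ValueError, match="square"):
            ms.mantel_ibd(a[:5, :6], b[:5, :6])

    def _clone_dataset(self, spec, seed=6):
        """Clone pairs placed together; unrelated individuals far apart."""
        ds = sd.gen_genotype_dataset(spec, {"Jabal Qara": 10}, replicates={"Jabal Qara": 1},
                                     dropout_rate=0.0, seed=seed)
        long = ds.long.copy()
        clones = []
        rng = np.random.default_rng(seed)
        for i, ind in enumerate(ds.truth):
            x, y = 40.0 * i, 0.0
            long.loc[long["individual_id"] == ind, ["x_km", "y_km"]] = (x, y)
            dup = long[long["individual_id"] == ind].copy()
            dup["sample_id"] = dup["sample_id"] + "_c"
            dup["individual_id"] = dup["individual_id"] + "_c"
            dup["x_km"] = x + rng.uniform(0.1, 1.0)
            clones.append(dup)
        return sd.GenotypeDataset(long=pd.concat([long] + clones, ignore_index=True),
                                  loci=ds.loci)

    def test_autocorrelation_detects_local_structure(self, spec):
        ds = self._clone_dataset(spec)
        cor = ms.spatial_autocorrelation(ds, n_classes=5, permutations=199, seed=7)
        first, last = cor.classes.iloc[0], cor.classes.iloc[-1]
        assert first["r"] > first["null_hi"]          # clones are close together
        assert last["r"] < 0                          # distant pairs unrelated

    def test_autocorrelation_null_after_shuffling(self, spec):
        outside = []
        for seed in range(5):
            ds = sd.gen_genotype_dataset(spec, {"Jabal Qara": 14},
                                         replicates={"Jabal Qara": 1},
                                         dropout_rate=0.0, seed=60 + seed)
            rng = np.random.default_rng(seed)
            meta = ds.long["sample_id"].unique()
            coords = {s: (rng.uniform(0, 200), rng.uniform(0, 200)) for s in meta}
            ds.long["x_km"] = ds.long["sample_id"].map(lambda s: coords[s][0])
            ds.long["y_km"] = ds.long["sample_id"].map(lambda s: coords[s][1])
            cor = ms.spatial_autocorrelation(ds, n_classes=4, permutations=199, seed=seed)
            cl = cor.classes
            outside.append(np.mean((cl["r"] < cl["null_lo"]) | (cl["r"] > cl["null_hi"])))
        assert np.mean(outside) <= 0.2

    def test_single_class_matches_direct_summation(self, spec):
        ds = sd.gen_genotype_dataset(spec, {"Nejd": 8}, replicates={"Nejd": 1},
                                     dropout_rate=0.0, seed=8)
        rng = np.random.default_rng(9)
        ds.long["x_km"] = ds.long["sample_id"].map(
            {s: rng.uniform(0, 50) for s in ds.long["sample_id"].unique()})
        cor = ms.spatial_autocorrelation(ds, bin_edges=np.array([0.0, 1e9]),
                                         permutations=19, seed=10)
        r = cor.classes["r"].iloc[0]
        # direct summation oracle on the centered covariance matrix
        D, _ = ms.genetic_distance_matrix(ds)
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        C = -0.5 * J @ D @ J
        iu = np.triu_indices(n, 1)
        expected = np.mean(C[iu]) / np.mean(np.diag(C))
        assert r == pytest.approx(expected)
        # the null expectation of the centered coefficient is ~ -1/(n-1)
        assert abs(r - (-1 / (n - 1))) < 0.15


def test_species_assay_summary():
    out = ms.species_assay_summary(161, 477)
    assert out["percent_confirmed"] == pytest.approx(100 * 161 / 477)
    assert out["percent_rounded"] == 34
    with pytest.raises(ValueError):
        ms.species_assay_summary(10, 5)
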