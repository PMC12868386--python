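import numpy as np
import pandas as pd
import pytest

from fecaldiet import replicate_qc as qc
from fecaldiet import synthetic_data as sd
from fecaldiet.errors import InvalidValueError


class TestMetadata:
    def test_counts_and_group_sizes(self):
        cfg = sd.SimulationConfig(seed=1, n_groups=2, individuals_per_group=10,
                                  n_mother_infant_pairs=2)
        meta = sd.simulate_metadata(cfg)
        assert meta["individual_id"].nunique() == 20
        assert (meta.groupby("group")["individual_id"].nunique() == 10).all()
        assert len(meta) == 20 * cfg.samples_per_individual

    def test_mothers_are_adult_females_same_group(self):
        meta = sd.simulate_metadata(sd.SimulationConfig(seed=2))
        by_ind = meta.drop_duplicates("individual_id").set_index("individual_id")
        infants = by_ind[by_ind["mother_id"].notna()]
        assert len(infants) > 0
        for _, rec in infants.iterrows():
            mom = by_ind.loc[rec["mother_id"]]
            assert mom["sex"] == "F"
            assert mom["age_class"] == "adult"
            assert mom["group"] == rec["group"]

    def test_no_same_day_recollection(self):
        meta = sd.simulate_metadata(sd.SimulationConfig(seed=3))
        assert not meta.duplicated(["individual_id", "date"]).any()

    def test_deterministic_under_seed(self):
        a = sd.simulate_metadata(sd.SimulationConfig(seed=9))
        b = sd.simulate_metadata(sd.SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)
        c = sd.simulate_metadata(sd.SimulationConfig(seed=10))
        assert not a.equals(c)

    def test_too_many_mother_infant_pairs_rejected(self):
        with pytest.raises(InvalidValueError):
            sd.SimulationConfig(individuals_per_group=4, n_mother_infant_pairs=3)


class TestDietProfiles:
    def test_profiles_on_simplex(self):
        cfg = sd.SimulationConfig(seed=4)
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        assert np.allclose(truth.profiles.sum(axis=1), 1.0, atol=1e-9)

    def test_infant_tracks_mother_at_huge_concentration(self):
        cfg = sd.SimulationConfig(seed=5, mother_infant_concentration=1e6)
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        by_ind = meta.drop_duplicates("individual_id").set_index("individual_id")
        infants = by_ind[by_ind["mother_id"].notna()]
        for ind, rec in infants.iterrows():
            gap = np.abs(truth.profiles.loc[ind] -
                         truth.profiles.loc[rec["mother_id"]]).max()
            assert gap < 1e-3

    def test_group_shift_recovered_in_large_population(self):
        # huge base concentration isolates the law-of-large-numbers behaviour
        # of the individual-level draws from base-composition sampling noise
        cfg = sd.SimulationConfig(seed=6, individuals_per_group=500,
                                  n_mother_infant_pairs=0,
                                  samples_per_individual=1,
                                  dirichlet_group_concentration=2e5,
                                  group_anthropogenic_shift=10.0)
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        score1 = truth.taxa.set_index("taxon_id")["provenance_score"] == 1.0
        by_ind = meta.drop_duplicates("individual_id").set_index("individual_id")
        anthro = 100.0 * truth.profiles.loc[:, score1[truth.profiles.columns]].sum(axis=1)
        diff = (anthro.groupby(by_ind["group"]).mean().diff().iloc[-1])
        assert diff == pytest.approx(10.0, abs=1.0)

    def test_null_shift_gives_near_equal_groups(self):
        cfg = sd.SimulationConfig(seed=7, individuals_per_group=300,
                                  n_mother_infant_pairs=0,
                                  samples_per_individual=1,
                                  group_anthropogenic_shift=0.0)
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        score1 = truth.taxa.set_index("taxon_id")["provenance_score"] == 1.0
        by_ind = meta.drop_duplicates("individual_id").set_index("individual_id")
        anthro = 100.0 * truth.profiles.loc[:, score1[truth.profiles.columns]].sum(axis=1)
        diff = abs(anthro.groupby(by_ind["group"]).mean().diff().iloc[-1])
        assert diff < 2.0


class TestReadTable:
    def make(self, **kw):
        cfg = sd.SimulationConfig(seed=8, individuals_per_group=6,
                                  n_mother_infant_pairs=1,
                                  samples_per_individual=2, **kw)
        bundle, truth = sd.simulate_bundle(cfg)
        return cfg, bundle, truth

    def test_replicate_totals_without_failure_or_contamination(self):
        cfg, bundle, _ = self.make(replicate_failure_rate=0.0,
                                   contamination_rate=0.0)
        totals = bundle.reads.groupby(["sample_id", "replicate"])["reads"].sum()
        assert (totals == cfg.reads_per_replicate).all()
        assert len(totals) == len(bundle.samples) * cfg.replicates_per_sample

    def test_contaminants_hit_exactly_one_replicate(self):
        cfg, bundle, truth = self.make(contamination_rate=0.6)
        assert len(truth.contaminants) > 0
        for rec in truth.contaminants.itertuples():
            present = bundle.reads[
                (bundle.reads["sample_id"] == rec.sample_id)
                & (bundle.reads["taxon_id"] == rec.taxon_id)]
            assert present["replicate"].nunique() == 1

    def test_consensus_filter_removes_all_contaminants(self):
        cfg, bundle, truth = self.make(contamination_rate=0.4)
        filtered = qc.filter_min_reads(bundle.reads, 10)
        filtered, _ = qc.filter_replicate_support(filtered)
        keys = set(zip(filtered["sample_id"], filtered["taxon_id"]))
        for rec in truth.contaminants.itertuples():
            assert (rec.sample_id, rec.taxon_id) not in keys

    def test_qc_recovers_truth_as_depth_grows(self):
        errors = {}
        for depth in (1_000, 100_000):
            cfg = sd.SimulationConfig(seed=11, individuals_per_group=4,
                                      n_mother_infant_pairs=1,
                                      samples_per_individual=1,
                                      reads_per_replicate=depth,
                                      contamination_rate=0.0,
                                      replicate_failure_rate=0.0)
            bundle, truth = sd.simulate_bundle(cfg)
            res = qc.run_qc(bundle.reads, bundle.samples, bundle.taxa,
                            min_reads=0)
            by_sample = bundle.samples.set_index("sample_id")["individual_id"]
            errs = []
            for s in res.rra.matrix.index:
                true = truth.profiles.loc[by_sample[s]]
                est = res.rra.matrix.loc[s].reindex(true.index).fillna(0.0)
                errs.append(np.abs(est - true).mean())
            errors[depth] = np.mean(errs)
        assert errors[100_000] < errors[1_000] / 3


class TestObservations:
    def test_zero_detectability_taxon_absent(self):
        cfg = sd.SimulationConfig(seed=12, individuals_per_group=4,
                                  n_mother_infant_pairs=1,
                                  detectability={"NaturalGenus01": 0.0})
        bundle, _ = sd.simulate_bundle(cfg)
        assert "NaturalGenus01" not in set(bundle.observations["taxon_id"])

    def test_unbiased_when_bias_terms_are_one(self):
        # mean observed share over many replicate draws matches the profile
        cfg = sd.SimulationConfig(seed=13, individuals_per_group=1,
                                  n_groups=1, n_mother_infant_pairs=0,
                                  samples_per_individual=1, seconds_total=5000,
                                  handling_bias={}, detectability={})
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        rng = np.random.default_rng(99)
        shares = []
        for _ in range(300):
            obs = sd.simulate_observations(truth, cfg, meta, rng)
            p = obs.groupby("taxon_id")["seconds"].sum()
            shares.append((p / p.sum()).reindex(truth.profiles.columns).fillna(0))
        mean_share = pd.concat(shares, axis=1).mean(axis=1)
        ind = truth.profiles.index[0]
        assert np.abs(mean_share - truth.profiles.loc[ind]).max() < 0.01

    def test_handling_bias_triples_renormalized_share(self):
        target = "NaturalGenus02"
        cfg = sd.SimulationConfig(seed=14, individuals_per_group=1, n_groups=1,
                                  n_mother_infant_pairs=0,
                                  samples_per_individual=1,
                                  seconds_total=20000,
                                  handling_bias={target: 3.0},
                                  detectability={})
        meta = sd.simulate_metadata(cfg)
        truth = sd.simulate_diet_profiles(cfg, meta)
        rng = np.random.default_rng(100)
        shares = []
        for _ in range(200):
            obs = sd.simulate_observations(truth, cfg, meta, rng)
            p = obs.groupby("taxon_id")["seconds"].sum()
            shares.append((p / p.sum()).get(target, 0.0))
        profile = truth.profiles.iloc[0]
        expected = 3 * profile[target] / (1 + 2 * profile[target])
        assert np.mean(shares) == pytest.approx(expected, rel=0.05)

    def test_food_class_follows_provenance(self):
        cfg = sd.SimulationConfig(seed=15, individuals_per_group=4,
                                  n_mother_infant_pairs=1)
        bundle, truth = sd.simulate_bundle(cfg)
        score = truth.taxa.set_index("taxon_id")["provenance_score"]
        mapped = bundle.observations["taxon_id"].map(score)
        expected = mapped.map({0.0: "natural", 0.5: "unknown", 1.0: "anthropogenic"})
        assert (bundle.observations["food_class"] == expected).all()


def test_bundle_is_deterministic_and_seed_sensitive():
    cfg = sd.SimulationConfig(seed=21, individuals_per_group=4,
                              n_mother_infant_pairs=1, samples_per_individual=1)
    b1, _ = sd.simulate_bundle(cfg)
    b2, _ = sd.simulate_bundle(cfg)
    pd.testing.assert_frame_equal(b1.reads, b2.reads)
    cfg2 = sd.SimulationConfig(seed=22, individuals_per_group=4,
                               n_mother_infant_pairs=1, samples_per_individual=1)
    b3, _ = sd.simulate_bundle(cfg2)
    assert not b1.reads.equals(b3.reads)
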