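"""Synthetic faecal-metabarcoding datasets with known ground truth.

The generator emulates the structure of a two-group primate diet study:

- two social groups whose expected anthropogenic-food share differs by a
  configurable number of percentage points (the "shift"),
- individuals whose diet profiles scatter around their group's base diet
  (Dirichlet hierarchy), mother-infant pairs whose profiles are extra
  correlated (infant drawn around its mother with high concentration),
- faecal samples amplified in triplicate: multinomial read counts per PCR
  replicate, sporadic whole-replicate failures, and sporadic contaminants
  injected into exactly one replicate of a sample (so the
  replicate-consensus filter can provably remove them),
- focal-follow observations: feeding seconds allocated multinomially from
  the same true diet, optionally distorted by per-taxon handling-time bias
  and detectability, making the observational readout a biased, noisy view
  of the same truth.

Everything is deterministic under the config seed. The defaults are the
documented study conditions used throughout the test-suite's
parameter-recovery and calibration checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .data_io import DatasetBundle
from .errors import InvalidValueError


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the documented study conditions."""

    seed: int = 0
    n_groups: int = 2
    individuals_per_group: int = 12
    n_mother_infant_pairs: int = 3          # per group
    n_natural_taxa: int = 20
    n_uncertain_taxa: int = 8
    n_anthropogenic_taxa: int = 5
    n_contaminant_taxa: int = 4             # never part of any true diet
    n_vertebrate_taxa: int = 2              # of the natural taxa
    base_anthropogenic_pct: float = 5.0     # group 1's expected score-1 share
    base_uncertain_pct: float = 12.0
    group_anthropogenic_shift: float = 10.0  # percentage points, group 2 - group 1
    dirichlet_group_concentration: float = 5000.0  # alpha_g: group base around target
    individual_concentration: float = 100.0        # tau: individual around group base
    mother_infant_concentration: float = 200.0     # kappa: infant around mother
    samples_per_individual: int = 3
    replicates_per_sample: int = 3
    reads_per_replicate: int = 20000
    contamination_rate: float = 0.05        # per-replicate injection probability
    contamination_reads: tuple = (50, 500)
    replicate_failure_rate: float = 0.02
    seconds_total: int = 3600               # focal-follow seconds per individual
    n_focal_days: int = 4
    # observation is a biased readout: some taxa take long handling time
    # (over-observed), others are eaten out of sight (under-detected)
    handling_bias: dict = field(default_factory=lambda: {
        "NaturalGenus03": 3.0, "AnthroGenus01": 2.0})
    detectability: dict = field(default_factory=lambda: {
        "NaturalGenus04": 0.25, "UncertainGenus01": 0.5})
    window_start: str = "2023-08-15"
    window_days: int = 130
    collection_every_days: int = 4

    def __post_init__(self):
        for name in ("contamination_rate", "replicate_failure_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidValueError(f"{name} must lie in [0, 1]")
        for name in ("dirichlet_group_concentration", "individual_concentration",
                     "mother_infant_concentration"):
            if getattr(self, name) <= 0:
                raise InvalidValueError(f"{name} must be positive")
        if self.n_mother_infant_pairs * 2 > self.individuals_per_group:
            raise InvalidValueError(
                "each mother-infant pair needs two individuals per group")


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside a simulated bundle."""

    taxa: pd.DataFrame                     # taxon metadata incl. scores
    group_base: pd.DataFrame               # group x taxon base composition
    profiles: pd.DataFrame                 # individual x taxon true diets
    group_anthropogenic_pct: pd.Series     # expected score-1 share per group
    contaminants: pd.DataFrame             # injected rows (sample, replicate, taxon, reads)
    config: SimulationConfig


def _taxon_ids(config: SimulationConfig):
    nat = [f"NaturalGenus{i + 1:02d}" for i in range(config.n_natural_taxa)]
    unc = [f"UncertainGenus{i + 1:02d}" for i in range(config.n_uncertain_taxa)]
    ant = [f"AnthroGenus{i + 1:02d}" for i in range(config.n_anthropogenic_taxa)]
    con = [f"ContamGenus{i + 1:02d}" for i in range(config.n_contaminant_taxa)]
    return nat, unc, ant, con


def make_taxon_table(config: SimulationConfig) -> pd.DataFrame:
    """Taxon metadata: diet taxa in the three provenance classes plus a pool
    of environmental contaminant taxa (scored natural, never eaten)."""
    nat, unc, ant, con = _taxon_ids(config)
    ids = nat + unc + ant + con
    scores = ([0.0] * len(nat) + [0.5] * len(unc) + [1.0] * len(ant)
              + [0.0] * len(con))
    markers = ["plant"] * len(ids)
    for i in range(min(config.n_vertebrate_taxa, len(nat))):
        markers[i] = "vertebrate"
    return pd.DataFrame({
        "taxon_id": ids,
        "rank": "genus",
        "genus_or_higher_label": ids,
        "marker": markers,
        "provenance_score": scores,
    })


def simulate_metadata(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individuals, mother-infant links and faecal-sample collection dates.

    Each group gets ``n_mother_infant_pairs`` adult-female mothers, each with
    one juvenile infant; remaining individuals are adults of random sex.
    Samples are collected on shared collection days spread over the study
    window, never twice from one individual on one day.
    """
    rng = rng or np.random.default_rng(config.seed)
    start = pd.Timestamp(config.window_start)
    collection_days = [start + pd.Timedelta(days=int(d))
                       for d in range(0, config.window_days,
                                      config.collection_every_days)]
    rows = []
    sample_no = 0
    for g in range(1, config.n_groups + 1):
        group = f"Group{g}"
        inds = []
        for i in range(config.individuals_per_group):
            ind_id = f"G{g}I{i + 1:02d}"
            if i < config.n_mother_infant_pairs:
                inds.append((ind_id, "F", "adult", None))           # mother
            elif i < 2 * config.n_mother_infant_pairs:
                mother = f"G{g}I{i - config.n_mother_infant_pairs + 1:02d}"
                sex = rng.choice(["M", "F"])
                inds.append((ind_id, sex, "juvenile", mother))      # infant
            else:
                inds.append((ind_id, rng.choice(["M", "F"]), "adult", None))
        for ind_id, sex, age, mother in inds:
            days = rng.choice(len(collection_days),
                              size=config.samples_per_individual, replace=False)
            for day in sorted(days):
                sample_no += 1
                rows.append({
                    "sample_id": f"S{sample_no:04d}",
                    "individual_id": ind_id,
                    "group": group,
                    "sex": sex,
                    "age_class": age,
                    "mother_id": mother,
                    "date": collection_days[day],
                })
    return pd.DataFrame(rows)


def _group_target_mean(config: SimulationConfig, group_index: int,
                       taxa: pd.DataFrame) -> np.ndarray:
    """Expected composition for one group: anthropogenic mass hits the
    configured target, uncertain mass is constant, the rest is natural."""
    a = (config.base_anthropogenic_pct
         + config.group_anthropogenic_shift * group_index) / 100.0
    u = config.base_uncertain_pct / 100.0
    n = 1.0 - a - u
    if n <= 0:
        raise InvalidValueError("anthropogenic + uncertain shares exceed 100%")
    score = taxa["provenance_score"].to_numpy()
    is_con = taxa["taxon_id"].str.startswith("ContamGenus").to_numpy()
    mean = np.zeros(len(taxa))
    for mass, mask in ((n, (score == 0.0) & ~is_con),
                       (u, score == 0.5),
                       (a, score == 1.0)):
        k = mask.sum()
        # mildly uneven within-class weights: realistic dominance structure
        w = np.linspace(1.5, 0.5, k)
        mean[mask] = mass * w / w.sum()
    return mean


def simulate_diet_profiles(config: SimulationConfig,
                           metadata: pd.DataFrame,
                           rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Hierarchical Dirichlet diet profiles.

    group base ~ Dirichlet(alpha_g * target); individual ~ Dirichlet(tau *
    base); infant ~ Dirichlet(kappa * mother's profile). Contaminant taxa
    get exactly zero mass everywhere.
    """
    rng = rng or np.random.default_rng(config.seed)
    taxa = make_taxon_table(config)
    is_con = taxa["taxon_id"].str.startswith("ContamGenus").to_numpy()
    diet_idx = np.flatnonzero(~is_con)
    groups = sorted(metadata["group"].unique())
    base = {}
    for gi, g in enumerate(groups):
        target = _group_target_mean(config, gi, taxa)[diet_idx]
        draw = rng.dirichlet(config.dirichlet_group_concentration * target)
        full = np.zeros(len(taxa))
        full[diet_idx] = draw
        base[g] = full
    group_base = pd.DataFrame(base, index=taxa["taxon_id"]).T

    individuals = metadata.drop_duplicates("individual_id")
    profiles = {}
    # mothers first so infants can be drawn around them
    mothers_first = individuals.sort_values(
        by="mother_id", key=lambda s: s.notna(), kind="mergesort")
    for _, rec in mothers_first.iterrows():
        ind = rec["individual_id"]
        if pd.notna(rec["mother_id"]):
            parent = profiles[rec["mother_id"]]
            alpha = config.mother_infant_concentration * parent[diet_idx]
        else:
            alpha = config.individual_concentration * group_base.loc[rec["group"]].to_numpy()[diet_idx]
        draw = rng.dirichlet(np.maximum(alpha, 1e-8))
        full = np.zeros(len(taxa))
        full[diet_idx] = draw
        profiles[ind] = full
    profiles = pd.DataFrame(profiles, index=taxa["taxon_id"]).T
    profiles = profiles.loc[individuals["individual_id"]]

    score1 = taxa.set_index("taxon_id")["provenance_score"] == 1.0
    group_pct = pd.Series({
        g: 100.0 * group_base.loc[g, score1[group_base.columns].values].sum()
        for g in groups
    })
    return SyntheticTruth(
        taxa=taxa,
        group_base=group_base,
        profiles=profiles,
        group_anthropogenic_pct=group_pct,
        contaminants=pd.DataFrame(
            columns=["sample_id", "replicate", "taxon_id", "reads"]),
        config=config,
    )


def simulate_read_table(truth: SyntheticTruth, config: SimulationConfig,
                        metadata: pd.DataFrame,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Triplicate multinomial read counts with failures and contaminants.

    Contaminants are drawn from the dedicated contaminant-taxon pool, at most
    one taxon per injection and never the same taxon twice in one sample, so
    every injected taxon is present in exactly one replicate of its sample.
    Injected rows are appended to ``truth.contaminants``.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    taxa = truth.taxa
    marker = taxa.set_index("taxon_id")["marker"]
    con_pool = [t for t in taxa["taxon_id"]
                if t.startswith("ContamGenus")]
    rows, contam_rows = [], []
    for _, rec in metadata.iterrows():
        profile = truth.profiles.loc[rec["individual_id"]].to_numpy()
        used_contams: list = []
        for rep in range(1, config.replicates_per_sample + 1):
            if rng.random() < config.replicate_failure_rate:
                continue
            counts = rng.multinomial(config.reads_per_replicate, profile)
            for taxon, c in zip(taxa["taxon_id"], counts):
                if c > 0:
                    rows.append((rec["sample_id"], rep, marker[taxon], taxon, int(c)))
            if con_pool and rng.random() < config.contamination_rate:
                avail = [t for t in con_pool if t not in used_contams]
                if avail:
                    taxon = avail[int(rng.integers(len(avail)))]
                    used_contams.append(taxon)
                    lo, hi = config.contamination_reads
                    c = int(rng.integers(lo, hi + 1))
                    rows.append((rec["sample_id"], rep, marker[taxon], taxon, c))
                    contam_rows.append((rec["sample_id"], rep, taxon, c))
    reads = pd.DataFrame(rows, columns=["sample_id", "replicate", "marker",
                                        "taxon_id", "reads"])
    truth.contaminants = pd.DataFrame(
        contam_rows, columns=["sample_id", "replicate", "taxon_id", "reads"])
    return reads


def simulate_observations(truth: SyntheticTruth, config: SimulationConfig,
                          metadata: pd.DataFrame,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Focal-follow feeding seconds as a biased multinomial readout.

    Expected seconds on taxon t are proportional to profile_t * handling
    bias h_t * detectability delta_t; seconds_total per individual are then
    allocated multinomially and spread over a few focal days.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    taxa = truth.taxa
    score = taxa.set_index("taxon_id")["provenance_score"]
    h = np.array([config.handling_bias.get(t, 1.0) for t in taxa["taxon_id"]])
    d = np.array([config.detectability.get(t, 1.0) for t in taxa["taxon_id"]])
    start = pd.Timestamp(config.window_start)
    focal_day_pool = np.arange(config.window_days)
    food_class = score.map({0.0: "natural", 0.5: "unknown", 1.0: "anthropogenic"})
    rows = []
    for _, rec in metadata.drop_duplicates("individual_id").iterrows():
        ind = rec["individual_id"]
        weights = truth.profiles.loc[ind].to_numpy() * h * d
        total = weights.sum()
        if total <= 0:
            continue
        seconds = rng.multinomial(config.seconds_total, weights / total)
        days = rng.choice(focal_day_pool, size=config.n_focal_days, replace=False)
        for taxon, sec in zip(taxa["taxon_id"], seconds):
            if sec == 0:
                continue
            split = rng.multinomial(sec, np.full(config.n_focal_days,
                                                 1.0 / config.n_focal_days))
            for day, s in zip(days, split):
                if s > 0:
                    rows.append({
                        "individual_id": ind,
                        "date": start + pd.Timedelta(days=int(day)),
                        "taxon_id": taxon,
                        "seconds": int(s),
                        "food_class": food_class[taxon],
                    })
    return pd.DataFrame(rows, columns=["individual_id", "date", "taxon_id",
                                       "seconds", "food_class"])


def simulate_bundle(config: SimulationConfig) -> tuple[DatasetBundle, SyntheticTruth]:
    """Full synthetic dataset: metadata, truth, reads and observations."""
    rng = np.random.default_rng(config.seed)
    metadata = simulate_metadata(config, rng)
    truth = simulate_diet_profiles(config, metadata, rng)
    reads = simulate_read_table(truth, config, metadata, rng)
    observations = simulate_observations(truth, config, metadata, rng)
    bundle = DatasetBundle(reads=reads, taxa=truth.taxa, samples=metadata,
                           observations=observations if len(observations) else None)
    return bundle, truth


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain dict (e.g. parsed YAML), ignoring nothing:
    unknown keys raise."""
    names = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - names
    if unknown:
        raise InvalidValueError(f"unknown simulation config keys: {sorted(unknown)}")
    d = dict(d)
    if "contamination_reads" in d:
        d["contamination_reads"] = tuple(d["contamination_reads"])
    return SimulationConfig(**d)
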