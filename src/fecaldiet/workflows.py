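"""End-to-end study workflows used for validation and reporting.

These functions wire the generator and the analysis stages together under
the package's documented study conditions:

- the *recovery* configuration — the generator defaults (2 groups of 12
  individuals, a 10-point anthropogenic shift, 3 samples per individual,
  triplicate PCR at 20k reads, 5% single-replicate contamination) — used to
  check that the pipeline recovers known ground truth;
- the *calibration* configuration — a smaller design (2 groups of 8
  individuals, 2 samples each, 2k reads) whose mixed-model fits are fast
  enough to repeat hundreds of times for type-I-error and power checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import provenance, replicate_qc, similarity
from . import synthetic_data as synth


def recovery_config(seed: int) -> synth.SimulationConfig:
    """Generator defaults: the documented parameter-recovery conditions."""
    return synth.SimulationConfig(seed=int(seed))


def calibration_config(seed: int, null: bool = False) -> synth.SimulationConfig:
    """Scaled-down design for repeated mixed-model simulation.

    ``null=True`` removes the group effect entirely (zero shift and a group
    base pinned to the shared target composition) for type-I calibration;
    the within-individual and mother-infant structure remains.
    """
    kw = dict(seed=int(seed), individuals_per_group=8, n_mother_infant_pairs=2,
              samples_per_individual=2, reads_per_replicate=2000)
    if null:
        kw.update(group_anthropogenic_shift=0.0,
                  dirichlet_group_concentration=1e6)
    return synth.SimulationConfig(**kw)


def qc_rra(bundle) -> replicate_qc.QCResult:
    """The default QC chain on a bundle."""
    return replicate_qc.run_qc(bundle.reads, bundle.samples, bundle.taxa)


def contaminant_removal_fraction(bundle, truth) -> float:
    """Fraction of injected single-replicate contaminants absent after the
    replicate-consensus filter (1.0 = all removed). NaN if none injected."""
    if len(truth.contaminants) == 0:
        return float("nan")
    filtered = replicate_qc.filter_min_reads(bundle.reads, 10)
    filtered, _ = replicate_qc.filter_replicate_support(filtered)
    kept = set(zip(filtered["sample_id"], filtered["taxon_id"]))
    gone = sum((r.sample_id, r.taxon_id) not in kept
               for r in truth.contaminants.itertuples())
    return gone / len(truth.contaminants)


def recovery_run(seed: int, config: synth.SimulationConfig | None = None) -> dict:
    """One full-pipeline run against ground truth.

    Returns the estimated and true group anthropogenic difference (points),
    the contaminant removal fraction, and whether the mean-similarity
    ordering Same individual > Mother-Infant > Other holds.
    """
    config = config or recovery_config(seed)
    bundle, truth = synth.simulate_bundle(config)
    res = qc_rra(bundle)
    part = provenance.partition_by_provenance(
        res.rra.matrix, bundle.taxa, bundle.samples, by="group")
    part = part.set_index("unit")["anthropogenic_pct"].sort_index()
    est_diff = float(part.iloc[-1] - part.iloc[0])
    true_diff = float(truth.group_anthropogenic_pct.sort_index().iloc[-1]
                      - truth.group_anthropogenic_pct.sort_index().iloc[0])
    d = similarity.bray_curtis(res.rra.matrix)
    meta = bundle.samples[bundle.samples["sample_id"].isin(d.index)]
    table = similarity.build_pairwise_table(d, meta)
    means = table.groupby("relationship")["similarity"].mean()
    ordering = bool(means.get("Same individual", -np.inf)
                    > means.get("Mother-Infant", -np.inf)
                    > means.get("Other", -np.inf))
    return {
        "estimated_group_difference": est_diff,
        "true_group_difference": true_diff,
        "configured_shift": config.group_anthropogenic_shift,
        "ordering_recovered": ordering,
        "contaminant_removal_fraction": contaminant_removal_fraction(bundle, truth),
        "n_samples": int(res.rra.matrix.shape[0]),
    }


def model_term_pvalue(seed: int, term: str, null: bool) -> float:
    """Simulate one calibration dataset and test one Model-2 term."""
    config = calibration_config(seed, null=null)
    bundle, _ = synth.simulate_bundle(config)
    res = qc_rra(bundle)
    d = similarity.bray_curtis(res.rra.matrix)
    meta = bundle.samples[bundle.samples["sample_id"].isin(d.index)]
    table = similarity.build_pairwise_table(d, meta)
    out = similarity.term_lr_test(table, similarity.model_group_relationship(),
                                  term)
    return out["p_value"]


def permanova_null_pvalue(seed: int, n_samples: int = 20, n_taxa: int = 8,
                          n_permutations: int = 999) -> float:
    """PERMANOVA p-value for structureless compositions with arbitrary
    balanced labels (the type-I-error setting)."""
    rng = np.random.default_rng(seed)
    rra = pd.DataFrame(rng.dirichlet(np.ones(n_taxa), size=n_samples),
                       index=[f"S{i}" for i in range(n_samples)])
    d = similarity.bray_curtis(rra)
    labels = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    return similarity.permanova(d, labels, n_permutations=n_permutations,
                                seed=int(rng.integers(2 ** 31))).p_value
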