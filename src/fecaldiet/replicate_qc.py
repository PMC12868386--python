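"""Read-count QC and relative read abundance (RRA).

The QC chain mirrors the analysis-stage filtering of a triplicate-PCR
metabarcoding study:

1. :func:`filter_min_reads` — drop taxa with fewer than 10 reads in a
   sequencing library (a library = all reads of one marker), the classic
   low-abundance OTU filter.
2. :func:`filter_replicate_support` — drop, per sample, taxa detected in
   only one of the PCR replicates; such single-replicate detections are the
   signature of contamination or PCR artefacts. Samples with fewer than two
   successful replicates are excluded outright: the consensus rule is
   undefined for them.
3. :func:`exclude_taxon_by_date` — remove a named taxon from samples
   collected the day after a known provisioning event (e.g. peanuts used as
   experimental food rewards).
4. :func:`compute_rra` / :func:`merge_replicates` — convert counts to
   within-replicate relative read abundance, then average replicates into a
   single per-sample diet profile on the unit simplex.

All filters are monotone (they only remove rows) and the default order is
the order above; :func:`run_qc` wires the chain together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, UnknownTaxonError


@dataclass
class MergedRRA:
    """Per-sample diet profiles plus merge provenance.

    ``matrix`` is samples x taxa, each row summing to 1;
    ``n_replicates`` records how many replicates contributed per sample.
    """

    matrix: pd.DataFrame
    n_replicates: pd.Series


@dataclass
class QCResult:
    rra: MergedRRA
    exclusions: pd.DataFrame  # columns: sample_id, reason
    filtered_reads: pd.DataFrame


def _empty_exclusions():
    return pd.DataFrame(columns=["sample_id", "reason"])


def filter_min_reads(table: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Remove taxa whose total reads within a library (marker) fall below
    ``threshold``. "Fewer than" is strict: a taxon with exactly ``threshold``
    reads is retained."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0 or table.empty:
        return table.copy()
    totals = table.groupby(["marker", "taxon_id"])["reads"].transform("sum")
    return table[totals >= threshold].copy()


def filter_replicate_support(
    table: pd.DataFrame,
    n_replicates: int = 3,
    min_support: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the replicate-consensus filter.

    Per sample, a taxon is kept only if it has nonzero reads in at least
    ``min_support`` replicates. Samples with fewer than ``min_support``
    successful replicates (replicates with any reads at all) are excluded.

    Returns ``(filtered_table, exclusions)`` where exclusions has one row per
    excluded sample with a human-readable reason.
    """
    table = table[table["reads"] > 0]
    if table.empty:
        return table.copy(), _empty_exclusions()

    ok_reps = (table.groupby("sample_id")["replicate"].nunique()
               .rename("n_ok"))
    bad_samples = ok_reps[ok_reps < min_support].index
    exclusions = pd.DataFrame({
        "sample_id": list(bad_samples),
        "reason": "insufficient replicates",
    })
    table = table[~table["sample_id"].isin(bad_samples)]

    support = (table.groupby(["sample_id", "taxon_id"])["replicate"]
               .transform("nunique"))
    return table[support >= min_support].copy(), exclusions


def exclude_taxon_by_date(
    table: pd.DataFrame,
    taxon_label: str,
    taxa: pd.DataFrame,
    samples: pd.DataFrame,
    event_dates,
) -> pd.DataFrame:
    """Remove reads of one taxon from samples collected the day after any of
    ``event_dates`` (provisioning-experiment carry-over)."""
    matches = taxa["taxon_id"].eq(taxon_label) | taxa["genus_or_higher_label"].eq(taxon_label)
    if not matches.any():
        raise UnknownTaxonError(f"taxon label {taxon_label!r} not found in taxon table")
    event_dates = pd.to_datetime(list(event_dates))
    if len(event_dates) == 0:
        return table.copy()
    hot_dates = set(event_dates + pd.Timedelta(days=1))
    hot_samples = set(samples.loc[samples["date"].isin(hot_dates), "sample_id"])
    target_taxa = set(taxa.loc[matches, "taxon_id"])
    drop = table["taxon_id"].isin(target_taxa) & table["sample_id"].isin(hot_samples)
    return table[~drop].copy()


def compute_rra(table: pd.DataFrame, pool_markers: bool = True) -> pd.DataFrame:
    """Per-replicate relative read abundance.

    Within each (sample, replicate) — pooling markers by default so plant and
    vertebrate fractions share one simplex — ``rra = reads / total reads``.
    Replicates with zero total reads are dropped.

    Returns a long table (sample_id, replicate[, marker], taxon_id, rra).
    """
    keys = ["sample_id", "replicate"] if pool_markers else ["sample_id", "replicate", "marker"]
    table = table[table["reads"] > 0]
    if table.empty:
        return pd.DataFrame(columns=keys + ["taxon_id", "rra"])
    out = table.copy()
    totals = out.groupby(keys)["reads"].transform("sum")
    out["rra"] = out["reads"] / totals
    return out[keys + ["taxon_id", "rra"]]


def merge_replicates(rra_long: pd.DataFrame, renormalize: bool = True) -> MergedRRA:
    """Average per-replicate RRA vectors into one profile per sample.

    A taxon absent from a replicate contributes 0 to its mean. Because
    zero-imputation pulls row sums below 1 whenever replicates disagree, rows
    are renormalized back onto the simplex by default.
    """
    if rra_long.empty:
        raise DegenerateInputError("no replicates to merge")
    n_reps = (rra_long.groupby("sample_id")["replicate"].nunique()
              .rename("n_replicates"))
    wide = (rra_long.pivot_table(index=["sample_id", "replicate"],
                                 columns="taxon_id", values="rra",
                                 aggfunc="sum", fill_value=0.0))
    merged = wide.groupby(level="sample_id").mean()
    if renormalize:
        merged = merged.div(merged.sum(axis=1), axis=0)
    merged.columns.name = None
    return MergedRRA(matrix=merged, n_replicates=n_reps.loc[merged.index])


def run_qc(
    reads: pd.DataFrame,
    samples: pd.DataFrame,
    taxa: pd.DataFrame | None = None,
    *,
    min_reads: int = 10,
    n_replicates: int = 3,
    min_support: int = 2,
    exclude_taxon: str | None = None,
    event_dates=(),
    pool_markers: bool = True,
    renormalize: bool = True,
) -> QCResult:
    """Full QC chain: min-reads filter, replicate-consensus filter, optional
    event-date taxon exclusion, RRA, replicate merge."""
    table = filter_min_reads(reads, min_reads)
    table, exclusions = filter_replicate_support(table, n_replicates, min_support)
    if exclude_taxon is not None:
        if taxa is None:
            raise ValueError("taxa table required for exclude_taxon")
        table = exclude_taxon_by_date(table, exclude_taxon, taxa, samples, event_dates)
    rra_long = compute_rra(table, pool_markers=pool_markers)
    if rra_long.empty:
        raise DegenerateInputError("no sample survived QC")
    kept = set(rra_long["sample_id"])
    no_reads = sorted(set(samples["sample_id"]) - kept - set(exclusions["sample_id"]))
    if no_reads:
        exclusions = pd.concat([
            exclusions,
            pd.DataFrame({"sample_id": no_reads, "reason": "no reads"}),
        ], ignore_index=True)
    merged = merge_replicates(rra_long, renormalize=renormalize)
    return QCResult(rra=merged, exclusions=exclusions, filtered_reads=table)
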