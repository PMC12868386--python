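"""Observational vs eDNA method comparison.

Focal-follow feeding records (seconds of active feeding per taxon) and
faecal eDNA read abundances are two noisy readouts of the same underlying
diet. This module turns each into a proportion vector on its full taxon
set, harmonizes taxonomy at genus level or above (the observational data
cannot resolve species), and quantifies agreement three ways: a Venn
partition of detected taxa, monthly (alternating 33/32-day) period
breakdowns, and an ordinary least-squares regression of eDNA proportions on
observational proportions — on the raw scale and after the logit transform
logit(p) = log(p / (1 - p)), which tames the influence of the few dominant
taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidValueError

DEFAULT_PERIOD_LENGTHS = (33, 32, 33, 32)
LOGIT_EPS = 1e-6


@dataclass
class MatchedProportions:
    """Full-diet proportion vectors for the two methods plus their overlap.

    Proportions are relative to each method's complete taxon set — matching
    never renormalizes, so a taxon's value is its share of the whole diet.
    """

    p_obs: pd.Series
    p_edna: pd.Series
    matched: list


@dataclass
class MethodComparisonResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    transform: str
    n: int


def observation_proportions(
    obs: pd.DataFrame,
    window: tuple | None = None,
    harmonize: pd.Series | None = None,
) -> pd.Series:
    """Taxon proportions of total active-feeding seconds.

    ``window=(start, end)`` restricts to records with start <= date <= end;
    ``harmonize`` optionally maps taxon ids to genus-or-higher labels before
    aggregation.
    """
    records = obs
    if window is not None:
        start, end = pd.to_datetime(window[0]), pd.to_datetime(window[1])
        records = records[(records["date"] >= start) & (records["date"] <= end)]
    total = records["seconds"].sum()
    if total <= 0:
        raise DegenerateInputError("no feeding seconds in the requested window")
    key = records["taxon_id"]
    if harmonize is not None:
        key = key.map(lambda t: harmonize.get(t, t))
    return records.groupby(key)["seconds"].sum() / total


def edna_proportions(rra: pd.DataFrame, harmonize: pd.Series | None = None) -> pd.Series:
    """Taxon proportions of the summed RRA over all samples."""
    sums = rra.sum(axis=0)
    if harmonize is not None:
        sums = sums.groupby(sums.index.map(lambda t: harmonize.get(t, t))).sum()
    total = sums.sum()
    if total <= 0:
        raise DegenerateInputError("RRA matrix has no mass")
    return sums / total


def harmonize_to_rank(taxa: pd.DataFrame) -> pd.Series:
    """Map each taxon id to its genus-or-higher label.

    Species collapse to their genus; genus and coarser ranks map to their own
    label. Labels also map to themselves, so the mapping is idempotent.
    """
    missing = taxa["genus_or_higher_label"].isna() | (taxa["genus_or_higher_label"] == "")
    if missing.any():
        bad = taxa.loc[missing, "taxon_id"].iloc[0]
        raise InvalidValueError(f"taxon {bad!r} lacks a genus_or_higher_label",
                                table="taxa", field="genus_or_higher_label")
    mapping = taxa.set_index("taxon_id")["genus_or_higher_label"]
    labels = pd.Series(mapping.values, index=mapping.values)
    return pd.concat([mapping, labels[~labels.index.isin(mapping.index)]])


def match_proportions(p_obs: pd.Series, p_edna: pd.Series) -> MatchedProportions:
    """Pair the two proportion vectors; matched = nonzero mass in both."""
    matched = sorted(set(p_obs.index[p_obs > 0]) & set(p_edna.index[p_edna > 0]))
    return MatchedProportions(p_obs=p_obs, p_edna=p_edna, matched=matched)


def venn_partition(obs_taxa, edna_taxa, food_class: pd.Series | None = None):
    """Partition the detected taxa into shared / observation-only / eDNA-only.

    With ``food_class`` (taxon -> class label), returns a DataFrame with one
    row per taxon carrying its cell and class; otherwise a dict of sets.
    """
    obs_taxa, edna_taxa = set(obs_taxa), set(edna_taxa)
    cells = {
        "shared": obs_taxa & edna_taxa,
        "obs_only": obs_taxa - edna_taxa,
        "edna_only": edna_taxa - obs_taxa,
    }
    if food_class is None:
        return cells
    rows = [
        {"taxon": t, "cell": cell,
         "food_class": food_class.get(t, "unknown")}
        for cell, taxa in cells.items() for t in sorted(taxa)
    ]
    return pd.DataFrame(rows, columns=["taxon", "cell", "food_class"])


def periodize(dates, window_start, period_lengths=DEFAULT_PERIOD_LENGTHS) -> pd.Series:
    """Assign each date to a consecutive half-open block [start, start+len).

    Blocks have the given lengths in days starting at ``window_start``;
    period labels are 1-based. Dates outside the covered span raise.
    """
    dates = pd.to_datetime(pd.Series(dates))
    start = pd.to_datetime(window_start)
    offsets = (dates - start).dt.days
    edges = np.concatenate([[0], np.cumsum(period_lengths)])
    if (offsets < 0).any() or (offsets >= edges[-1]).any():
        bad = dates[(offsets < 0) | (offsets >= edges[-1])].iloc[0]
        raise DegenerateInputError(
            f"date {bad.date()} outside the {edges[-1]}-day span starting {start.date()}")
    labels = np.searchsorted(edges, offsets.to_numpy(), side="right")
    return pd.Series(labels, index=dates.index, name="period")


def logit(p, eps: float = 0.0):
    """log(p / (1 - p)), with optional clamping of p into [eps, 1 - eps].

    Proportions of exactly 0 or 1 are only valid with eps > 0.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise InvalidValueError("proportions must lie in [0, 1]")
    if eps > 0:
        arr = np.clip(arr, eps, 1 - eps)
    elif np.any(arr <= 0) or np.any(arr >= 1):
        raise InvalidValueError("logit undefined at 0 or 1 without clamping")
    out = np.log(arr / (1 - arr))
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def regress_methods(
    matched: MatchedProportions,
    transform: str = "logit",
    eps: float = LOGIT_EPS,
) -> MethodComparisonResult:
    """OLS of eDNA proportions on observational proportions over the matched
    taxa. ``transform="logit"`` regresses on the logit scale (with 0/1
    clamped to [eps, 1-eps]); ``"none"`` uses the raw proportions."""
    if len(matched.matched) < 3:
        raise DegenerateInputError("need at least 3 matched taxa to regress")
    x = matched.p_obs.reindex(matched.matched).to_numpy(dtype=float)
    y = matched.p_edna.reindex(matched.matched).to_numpy(dtype=float)
    if transform == "logit":
        x, y = logit(x, eps=eps), logit(y, eps=eps)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in the predictor")
    fit = stats.linregress(x, y)
    return MethodComparisonResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        transform=transform,
        n=len(x),
    )
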