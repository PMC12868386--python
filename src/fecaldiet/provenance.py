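"""Anthropogenic-food provenance scoring.

Each taxon carries a score s in {0, 0.5, 1}: 0 for confirmed natural
resources, 1 for confirmed anthropogenic food, 0.5 for taxa that could
plausibly be either (an avocado may come from a house or a tree). The
per-sample anthropogenic percentage is the score-weighted RRA mass,

    100 * sum_t s_t * rra_t / sum_t rra_t,

so a sample whose diet is entirely confirmed-natural scores 0 and one that
is entirely confirmed-anthropogenic scores 100. Because 0.5-scored taxa
count half, the percentage equals A + U/2 where A and U are the RRA masses
of score-1 and score-0.5 taxa — the score-1 mass alone is a floor on the
true anthropogenic share, and :func:`allocate_uncertain` turns the uncertain
mass into an explicit (minimum, maximum-estimate) interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, UnscoredTaxonError


def _align_scores(taxa_index, scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        scores = scores.set_index("taxon_id")["provenance_score"]
    scores = pd.Series(scores)
    missing = [t for t in taxa_index if t not in scores.index or pd.isna(scores[t])]
    if missing:
        raise UnscoredTaxonError(
            f"no provenance score for taxa: {', '.join(map(str, missing[:5]))}")
    return scores.reindex(taxa_index).astype(float)


def anthropogenic_percentage(rra_row, scores) -> float:
    """Score-weighted anthropogenic percentage of one diet profile.

    ``rra_row`` is a taxon-indexed Series (any positive rescaling of it gives
    the same answer); ``scores`` maps every taxon to its provenance score.
    """
    rra_row = pd.Series(rra_row).astype(float)
    rra_row = rra_row[rra_row != 0]
    total = rra_row.sum()
    if rra_row.empty or total <= 0:
        raise DegenerateInputError("empty RRA row")
    s = _align_scores(rra_row.index, scores)
    return float(100.0 * (s * rra_row).sum() / total)


def partition_by_provenance(
    rra: pd.DataFrame,
    scores,
    samples: pd.DataFrame | None = None,
    by: str = "sample",
) -> pd.DataFrame:
    """Split each unit's diet into natural / uncertain / anthropogenic RRA mass.

    ``by="sample"`` returns one row per sample; ``by="group"`` averages the
    per-sample percentages within each social group with equal sample weights
    (RRA already normalizes read depth, so no further weighting is applied).
    Columns: unit, natural_pct, uncertain_pct, anthropogenic_pct (sum to 100).
    """
    s = _align_scores(rra.columns, scores)
    norm = rra.div(rra.sum(axis=1), axis=0)
    out = pd.DataFrame({
        "unit": norm.index,
        "natural_pct": 100.0 * norm.loc[:, s == 0.0].sum(axis=1),
        "uncertain_pct": 100.0 * norm.loc[:, s == 0.5].sum(axis=1),
        "anthropogenic_pct": 100.0 * norm.loc[:, s == 1.0].sum(axis=1),
    }).reset_index(drop=True)
    if by == "sample":
        return out
    if by == "group":
        if samples is None:
            raise ValueError("samples metadata required for by='group'")
        groups = samples.set_index("sample_id")["group"]
        out["unit"] = out["unit"].map(groups)
        return (out.groupby("unit", as_index=False)
                [["natural_pct", "uncertain_pct", "anthropogenic_pct"]].mean())
    raise ValueError(f"unknown grouping {by!r}")


def allocate_uncertain(partition, rule: str = "none") -> tuple[float, float]:
    """Bounds on the anthropogenic share given the uncertain mass.

    ``partition`` is (natural_pct, uncertain_pct, anthropogenic_pct) or a row
    with those fields. The score-1 mass A is always the minimum; the maximum
    estimate depends on the allocation rule for the uncertain mass U:

    - ``none``: (A, A) — uncertain mass ignored,
    - ``half``: (A, A + U/2) — split evenly,
    - ``proportional``: (A, A + U * A / (A + N)) — split like the resolved mass.
    """
    if isinstance(partition, (pd.Series, dict)):
        n, u, a = (partition["natural_pct"], partition["uncertain_pct"],
                   partition["anthropogenic_pct"])
    else:
        n, u, a = partition
    if rule == "none":
        return float(a), float(a)
    if rule == "half":
        return float(a), float(a + u / 2.0)
    if rule == "proportional":
        if a + n == 0:
            raise DegenerateInputError("proportional allocation undefined when A + N = 0")
        return float(a), float(a + u * a / (a + n))
    raise ValueError(f"unknown allocation rule {rule!r}")


def anthropogenic_density(
    percentages: pd.Series,
    groups: pd.Series,
    grid_size: int = 512,
) -> dict:
    """Per-group kernel density of the per-sample anthropogenic percentage.

    Gaussian KDE with Silverman's bandwidth, evaluated on a shared grid over
    [0, 100] and renormalized so each density integrates to 1 on the grid.
    Degenerate groups (zero variance) fall back to a narrow kernel around the
    common value. Returns {group: {"grid", "density", "mean", "median", "n"}}.
    """
    grid = np.linspace(0.0, 100.0, grid_size)
    out = {}
    for g, vals in pd.Series(percentages).groupby(pd.Series(groups).values):
        x = np.asarray(vals, dtype=float)
        if len(x) < 2:
            raise DegenerateInputError(f"group {g!r} has fewer than 2 samples")
        if np.ptp(x) == 0:
            dens = stats.norm.pdf(grid, loc=x[0], scale=0.5)
        else:
            dens = stats.gaussian_kde(x, bw_method="silverman")(grid)
        area = np.trapezoid(dens, grid)
        out[g] = {
            "grid": grid,
            "density": dens / area,
            "mean": float(x.mean()),
            "median": float(np.median(x)),
            "n": int(len(x)),
        }
    return out
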