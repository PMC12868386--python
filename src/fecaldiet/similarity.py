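"""Dietary similarity: distances, ordination, PERMANOVA and dyadic models.

Sample diet profiles (rows of an RRA matrix) are compared with Bray-Curtis
dissimilarity, d(x, y) = sum|x - y| / sum(x + y). Group and month structure
is visualised by non-metric multidimensional scaling and tested by
PERMANOVA. For the social analysis each within-group pair of samples
becomes one observation: similarity = 1 - d, z-standardized over all
retained pairs, with a relationship category (Same individual /
Mother-Infant / Other) and combined covariates. Two Gaussian mixed models
are then fitted to the pairwise table:

    similarity_z ~ Group*Sex*Age + (1|Individuals) + (1|Date) + (1|Relationship)
    similarity_z ~ Group*Relationship + (1|Individuals) + (1|Date)

Random intercepts for dyadic rows are genuinely ambiguous: a row belongs to
two individuals and two dates. Two encodings are provided. ``membership``
(default) gives each individual (and each date) of the dyad its own
intercept with a shared variance — the classic multiple-membership encoding,
which absorbs the correlation between dyads sharing a member. ``pair``
encodes the unordered id pair as a single factor, which is simpler but
leaves member-sharing correlation on the table. Numerical fitting is
delegated to statsmodels' MixedLM; this module owns the design construction
and the per-term type-II likelihood-ratio tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .errors import (
    DegenerateInputError,
    ModelConvergenceError,
    UnknownSampleError,
)

RELATIONSHIPS = ("Same individual", "Mother-Infant", "Other")


# ---------------------------------------------------------------------------
# distances, ordination, PERMANOVA
# ---------------------------------------------------------------------------

def bray_curtis(rra: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between the rows of an RRA matrix."""
    if rra.empty:
        raise DegenerateInputError("empty RRA matrix")
    d = squareform(pdist(rra.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(d, index=rra.index, columns=rra.index)


@dataclass
class OrdinationResult:
    k: int
    coordinates: pd.DataFrame
    stress: float


def nmds(d: pd.DataFrame, k: int = 2, n_starts: int = 4, seed: int = 0,
         max_iter: int = 500, eps: float = 1e-12) -> OrdinationResult:
    """Non-metric MDS embedding of a distance matrix.

    Runs SMACOF from ``n_starts`` random initializations and keeps the
    lowest-stress solution; ``stress`` is Kruskal's stress-1. Deterministic
    given ``seed``.
    """
    n = d.shape[0]
    if k >= n:
        raise DegenerateInputError(f"k={k} must be below the number of samples ({n})")
    model = MDS(n_components=k, metric_mds=False, n_init=n_starts,
                max_iter=max_iter, eps=eps, random_state=int(seed),
                metric="precomputed", normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(d.to_numpy(dtype=float))
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        k=k,
        coordinates=pd.DataFrame(coords, index=d.index, columns=cols),
        stress=float(model.stress_),
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def _within_ss(d2: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    ss = 0.0
    for g in range(n_levels):
        idx = np.flatnonzero(codes == g)
        # each within-group squared distance counted twice in the submatrix
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def permanova(d: pd.DataFrame, labels, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous quantity
    per group; pseudo-F = (SS_among/(a-1)) / (SS_within/(n-a)). The p-value
    permutes group labels with the add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    labels = pd.Series(labels)
    if labels.index.equals(pd.RangeIndex(len(labels))) and len(labels) == d.shape[0]:
        labels.index = d.index
    labels = labels.reindex(d.index)
    codes, levels = pd.factorize(labels)
    n, a = d.shape[0], len(levels)
    if a < 2 or pd.Series(codes).value_counts().min() < 2:
        raise DegenerateInputError("need >= 2 groups with >= 2 samples each")
    d2 = d.to_numpy(dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    with np.errstate(divide="ignore"):
        ss_within = _within_ss(d2, codes, a)
        ss_among = ss_total - ss_within
        f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            ssw = _within_ss(d2, perm, a)
            f_perm = ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))
            if f_perm >= f_obs:
                hits += 1
    return PermanovaResult(
        pseudo_F=float(f_obs),
        r_squared=float(ss_among / ss_total),
        p_value=(1 + hits) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# pairwise similarity table
# ---------------------------------------------------------------------------

def relationship_category(sample_i: str, sample_j: str,
                          samples: pd.DataFrame) -> str:
    """Classify a sample pair: Same individual, Mother-Infant, or Other.

    Symmetric in its arguments."""
    meta = samples.set_index("sample_id")
    for s in (sample_i, sample_j):
        if s not in meta.index:
            raise UnknownSampleError(f"unknown sample {s!r}")
    a, b = meta.loc[sample_i], meta.loc[sample_j]
    return _relationship(a["individual_id"], b["individual_id"],
                         a["mother_id"], b["mother_id"])


def _relationship(ind_i, ind_j, mother_i, mother_j) -> str:
    if ind_i == ind_j:
        return "Same individual"
    if (pd.notna(mother_i) and mother_i == ind_j) or \
       (pd.notna(mother_j) and mother_j == ind_i):
        return "Mother-Infant"
    return "Other"


def _combo(a: str, b: str) -> str:
    return "".join(sorted([str(a)[0].upper(), str(b)[0].upper()]))


def build_pairwise_table(d: pd.DataFrame, samples: pd.DataFrame,
                         scope: str = "within-group") -> pd.DataFrame:
    """One row per unordered sample pair with standardized similarity.

    similarity = 1 - Bray-Curtis, z-scored over all retained pairs. Scope
    ``within-group`` keeps only pairs whose samples share a social group
    (``all`` keeps everything, with cross-group pairs labelled group
    ``"between"``). Covariates are unordered category combinations (e.g.
    sex_combo in {FF, FM, MM}).
    """
    if scope not in ("within-group", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    meta = samples.set_index("sample_id")
    rows = []
    ids = list(d.index)
    dv = d.to_numpy(dtype=float)
    for (ii, si), (jj, sj) in itertools.combinations(enumerate(ids), 2):
        a, b = meta.loc[si], meta.loc[sj]
        same_group = a["group"] == b["group"]
        if scope == "within-group" and not same_group:
            continue
        rows.append({
            "sample_i": si, "sample_j": sj,
            "similarity": 1.0 - dv[ii, jj],
            "group": a["group"] if same_group else "between",
            "relationship": _relationship(a["individual_id"], b["individual_id"],
                                          a["mother_id"], b["mother_id"]),
            "sex_combo": _combo(a["sex"], b["sex"]),
            "age_combo": _combo(a["age_class"], b["age_class"]),
            "individual_i": a["individual_id"], "individual_j": b["individual_id"],
            "date_i": a["date"], "date_j": b["date"],
        })
    table = pd.DataFrame(rows)
    if table.empty:
        raise DegenerateInputError("no sample pairs in scope")
    sd = table["similarity"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("similarity is constant; cannot standardize")
    table["similarity_z"] = (table["similarity"] - table["similarity"].mean()) / sd
    table["individual_pair"] = [
        "|".join(sorted([i, j]))
        for i, j in zip(table["individual_i"], table["individual_j"])
    ]
    table["date_pair"] = [
        "|".join(sorted([str(pd.Timestamp(i).date()), str(pd.Timestamp(j).date())]))
        for i, j in zip(table["date_i"], table["date_j"])
    ]
    return table


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A Gaussian mixed model for the pairwise table.

    ``fixed`` is the crossed fixed-effect part in formula notation;
    ``random`` lists the random-intercept factors by their conceptual name
    (Individuals, Date, Relationship).
    """

    response: str
    fixed: str
    random: tuple
    family: str = "gaussian"

    @property
    def formula(self) -> str:
        rand = " + ".join(f"(1|{r})" for r in self.random)
        return f"{self.response} ~ {self.fixed} + {rand}"


# conceptual factor -> pairwise-table column(s)
_FACTOR_COLUMNS = {
    "Group": "group",
    "Sex": "sex_combo",
    "Age": "age_combo",
    "Relationship": "relationship",
}
_RANDOM_COLUMNS = {
    "Individuals": ("individual_i", "individual_j", "individual_pair"),
    "Date": ("date_i", "date_j", "date_pair"),
    "Relationship": ("relationship", "relationship", "relationship"),
}


def model_group_sex_age() -> ModelSpec:
    """Model 1: Similarity-Z ~ Group*Sex*Age + (1|Individuals) + (1|Date)
    + (1|Relationship)."""
    return ModelSpec(response="Similarity-Z", fixed="Group*Sex*Age",
                     random=("Individuals", "Date", "Relationship"))


def model_group_relationship() -> ModelSpec:
    """Model 2: Similarity-Z ~ Group*Relationship + (1|Individuals) + (1|Date)."""
    return ModelSpec(response="Similarity-Z", fixed="Group*Relationship",
                     random=("Individuals", "Date"))


def _expand_terms(fixed: str) -> list[str]:
    """Crossed terms in model order: A*B -> [A, B, A:B], A*B*C -> all 7."""
    if "*" not in fixed:
        return [fixed.strip()]
    factors = [f.strip() for f in fixed.split("*")]
    terms = []
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            terms.append(":".join(combo))
    return terms


def _term_to_patsy(term: str) -> str:
    return ":".join(f"C({_FACTOR_COLUMNS[f]})" for f in term.split(":"))


def _fixed_formula(terms: list[str]) -> str:
    rhs = " + ".join(_term_to_patsy(t) for t in terms) if terms else "1"
    return f"similarity_z ~ {rhs}"


def _membership_formula(table: pd.DataFrame, col_i: str, col_j: str,
                        prefix: str) -> tuple[pd.DataFrame, str]:
    """Indicator columns for multiple-membership random intercepts: one
    column per level, 1 if the level appears in the dyad (2 if twice)."""
    def norm(v):
        return str(pd.Timestamp(v).date()) if isinstance(v, pd.Timestamp) else str(v)

    li = table[col_i].map(norm)
    lj = table[col_j].map(norm)
    levels = sorted(set(li) | set(lj))
    cols = {}
    for k, lev in enumerate(levels):
        cols[f"{prefix}{k}"] = ((li == lev).astype(float) + (lj == lev).astype(float))
    block = pd.DataFrame(cols, index=table.index)
    return block, "0 + " + " + ".join(block.columns)


def _vc_formulas(table: pd.DataFrame, spec: ModelSpec,
                 random_structure: str) -> tuple[pd.DataFrame, dict]:
    data = table.copy()
    vc = {}
    for factor in spec.random:
        col_i, col_j, pair_col = _RANDOM_COLUMNS[factor]
        name = factor.lower()
        if factor == "Relationship" or random_structure == "pair":
            vc[name] = f"0 + C({pair_col})"
        elif random_structure == "membership":
            block, formula = _membership_formula(data, col_i, col_j,
                                                 prefix=f"_{name}_m")
            data = pd.concat([data, block], axis=1)
            vc[name] = formula
        else:
            raise ValueError(f"unknown random_structure {random_structure!r}")
    return data, vc


def _fit_mixedlm(data: pd.DataFrame, fixed_formula: str, vc: dict,
                 reml: bool = False):
    import statsmodels.formula.api as smf

    data = data.copy()
    data["_one"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed_formula, data, groups="_one", vc_formula=vc)
        result = model.fit(reml=reml, method="lbfgs", maxiter=500)
        if not result.converged:
            result = model.fit(reml=reml, method="powell", maxiter=1000)
    if not np.isfinite(result.llf):
        raise ModelConvergenceError(
            "mixed-model fit did not converge",
            diagnostics={"formula": fixed_formula, "converged": bool(result.converged)})
    return result


@dataclass
class SimilarityModelFit:
    spec: ModelSpec
    coefficients: pd.Series
    term_tests: pd.DataFrame  # term, chisq, df, p_value
    aic: float
    bic: float
    rmse: float
    r_squared: float
    converged: bool
    n: int
    random_structure: str
    log_likelihood: float = field(default=float("nan"))


def _is_between_individual(table: pd.DataFrame, term: str) -> bool:
    """A term is a between-individual effect when every factor it involves
    takes a single value across all dyads of any given individual (e.g. the
    dyad's group under within-group scope, but not the dyad's sex combo,
    which depends on the partner)."""
    for factor in term.split(":"):
        col = _FACTOR_COLUMNS[factor]
        long = pd.concat([
            table[["individual_i", col]].rename(columns={"individual_i": "ind"}),
            table[["individual_j", col]].rename(columns={"individual_j": "ind"}),
        ])
        if (long.groupby("ind")[col].nunique() > 1).any():
            return False
    return True


def _containment_ddf(table: pd.DataFrame, terms: list[str]) -> int:
    """Denominator df for between-individual terms: number of individuals
    minus the rank of the individual-level fixed design (intercept plus all
    between-individual terms)."""
    inds = pd.concat([
        table[["individual_i"]].rename(columns={"individual_i": "ind"}),
        table[["individual_j"]].rename(columns={"individual_j": "ind"}),
    ])["ind"].unique()
    n_ind = len(inds)
    p = 1  # intercept
    ind_attrs = {}
    for t in terms:
        if not _is_between_individual(table, t):
            continue
        for factor in t.split(":"):
            col = _FACTOR_COLUMNS[factor]
            if col in ind_attrs:
                continue
            long = pd.concat([
                table[["individual_i", col]].rename(columns={"individual_i": "ind"}),
                table[["individual_j", col]].rename(columns={"individual_j": "ind"}),
            ]).drop_duplicates("ind").set_index("ind")[col]
            ind_attrs[col] = long
    if ind_attrs:
        design = pd.get_dummies(pd.DataFrame(ind_attrs).reindex(inds),
                                drop_first=True)
        p += int(np.linalg.matrix_rank(design.to_numpy(dtype=float)))
    return max(1, n_ind - p)


def term_lr_test(table: pd.DataFrame, spec: ModelSpec, term: str,
                 random_structure: str = "membership") -> dict:
    """Type-II likelihood-ratio test of one fixed term.

    The reduced model holds every term not containing ``term``'s factors;
    the full model adds ``term``. Both are ML fits; the statistic is
    2 * (ll_full - ll_reduced) on the difference in fixed-effect rank.

    Between-individual terms (constant across all dyads of each individual,
    like Group) carry far fewer independent units than the table has rows,
    so their p-value uses an F(df, ddf) reference with a containment
    denominator df (individuals minus between-individual parameters) instead
    of the asymptotic chi-square — the usual small-sample guard against
    anticonservative tests of cluster-level effects. Within-individual terms
    keep the chi-square reference; ``ddf`` is NaN for them.
    """
    terms = _expand_terms(spec.fixed)
    if term not in terms:
        raise ValueError(f"term {term!r} not in model {spec.fixed!r}")
    tf = set(term.split(":"))
    base = [t for t in terms if not tf.issubset(set(t.split(":")))]
    data, vc = _vc_formulas(table, spec, random_structure)
    reduced = _fit_mixedlm(data, _fixed_formula(base), vc)
    full = _fit_mixedlm(data, _fixed_formula(base + [term]), vc)
    df = int(full.k_fe - reduced.k_fe)
    chisq = max(0.0, 2.0 * (full.llf - reduced.llf))
    from scipy import stats as sps
    ddf = float("nan")
    if df <= 0:
        p = float("nan")
    elif _is_between_individual(table, term):
        ddf = _containment_ddf(table, terms)
        p = float(sps.f.sf(chisq / df, df, ddf))
    else:
        p = float(sps.chi2.sf(chisq, df))
    return {"term": term, "chisq": float(chisq), "df": df,
            "ddf": ddf, "p_value": p}


def fit_similarity_model(table: pd.DataFrame, spec: ModelSpec,
                         random_structure: str = "membership",
                         term_tests: bool = True) -> SimilarityModelFit:
    """Fit a pairwise-similarity mixed model and test each fixed term.

    Fits by maximum likelihood (so likelihood-ratio tests and AIC/BIC are
    comparable across nested fits) and reports per-term type-II
    likelihood-ratio chi-squares plus model-comparison indices (AIC, BIC,
    RMSE, and a simple 1 - var(resid)/var(y) R-squared).
    """
    terms = _expand_terms(spec.fixed)
    data, vc = _vc_formulas(table, spec, random_structure)
    full = _fit_mixedlm(data, _fixed_formula(terms), vc)
    resid = np.asarray(full.resid, dtype=float)
    y = table["similarity_z"].to_numpy(dtype=float)
    tests = []
    if term_tests:
        for t in terms:
            tests.append(term_lr_test(table, spec, t, random_structure))
    return SimilarityModelFit(
        spec=spec,
        coefficients=full.fe_params,
        term_tests=pd.DataFrame(tests, columns=["term", "chisq", "df", "ddf", "p_value"]),
        aic=float(full.aic),
        bic=float(full.bic),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        r_squared=float(1.0 - resid.var() / y.var()),
        converged=bool(full.converged),
        n=len(table),
        random_structure=random_structure,
        log_likelihood=float(full.llf),
    )
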