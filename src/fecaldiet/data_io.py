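"""Reading, validating and writing the pipeline's tabular artefacts.

All tables are UTF-8 TSV with a mandatory header row, missing values encoded
as the literal ``NA``, and dates as ISO 8601 calendar dates (``YYYY-MM-DD``).
Four tables make up a dataset bundle:

``reads.tsv``
    Long-format read counts, one row per (sample, PCR replicate, marker,
    taxon): columns ``sample_id, replicate, marker, taxon_id, reads``.
``taxa.tsv``
    Taxon metadata: ``taxon_id, rank, genus_or_higher_label, marker,
    provenance_score`` (score in {0, 0.5, 1} or NA).
``samples.tsv``
    Faecal-sample metadata: ``sample_id, individual_id, group, sex,
    age_class, mother_id, date``.
``focal.tsv`` (optional)
    Focal-follow feeding records: ``individual_id, date, taxon_id, seconds,
    food_class``.

Writes are bit-reproducible: rows are sorted by primary key before writing,
so the same bundle always produces byte-identical files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DanglingReferenceError,
    DuplicateKeyError,
    InvalidValueError,
    MissingColumnError,
)

NA = "NA"

RANKS = ("species", "genus", "tribe", "subfamily", "family", "order", "subclass")
MARKERS = ("plant", "vertebrate")
SEXES = ("M", "F")
AGE_CLASSES = ("adult", "juvenile")
FOOD_CLASSES = ("natural", "anthropogenic", "unknown")
PROVENANCE_SCORES = (0.0, 0.5, 1.0)

READS_COLUMNS = ["sample_id", "replicate", "marker", "taxon_id", "reads"]
TAXA_COLUMNS = ["taxon_id", "rank", "genus_or_higher_label", "marker", "provenance_score"]
SAMPLE_COLUMNS = ["sample_id", "individual_id", "group", "sex", "age_class", "mother_id", "date"]
FOCAL_COLUMNS = ["individual_id", "date", "taxon_id", "seconds", "food_class"]

FILENAMES = {"reads": "reads.tsv", "taxa": "taxa.tsv",
             "samples": "samples.tsv", "observations": "focal.tsv"}


@dataclass
class DatasetBundle:
    """A validated set of pipeline input tables.

    ``observations`` is optional: a purely molecular study has no focal-follow
    records and the method-comparison stage simply cannot run.
    """

    reads: pd.DataFrame
    taxa: pd.DataFrame
    samples: pd.DataFrame
    observations: pd.DataFrame | None = None

    def __post_init__(self):
        validate_bundle(self)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, columns, table):
    df = pd.read_csv(path, sep="\t", dtype=str,
                     na_values=[NA], keep_default_na=False)
    for col in columns:
        if col not in df.columns:
            raise MissingColumnError(f"required column {col!r} missing",
                                     table=table, field=col)
    return df[columns]


def _coerce_int(df, col, table, minimum=0):
    try:
        values = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError) as exc:
        raise InvalidValueError(f"non-numeric value in {col!r}: {exc}",
                                table=table, field=col) from None
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise InvalidValueError(f"missing value in {col!r}",
                                table=table, row=row, field=col)
    if (values % 1 != 0).any():
        row = int(values.index[values % 1 != 0][0])
        raise InvalidValueError(f"non-integer value in {col!r}",
                                table=table, row=row, field=col)
    if (values < minimum).any():
        row = int(values.index[values < minimum][0])
        raise InvalidValueError(f"value below {minimum} in {col!r}",
                                table=table, row=row, field=col)
    df[col] = values.astype(np.int64)


def _coerce_enum(df, col, allowed, table, allow_na=False):
    bad = ~df[col].isin(allowed)
    if allow_na:
        bad &= df[col].notna()
    elif df[col].isna().any():
        row = int(df.index[df[col].isna()][0])
        raise InvalidValueError(f"missing value in {col!r}",
                                table=table, row=row, field=col)
    if bad.any():
        row = int(df.index[bad][0])
        raise InvalidValueError(
            f"unknown value {df.loc[row, col]!r} in {col!r} "
            f"(allowed: {', '.join(map(str, allowed))})",
            table=table, row=row, field=col)


def _coerce_date(df, col, table):
    try:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="raise")
    except (ValueError, TypeError) as exc:
        raise InvalidValueError(f"unparseable ISO date in {col!r}: {exc}",
                                table=table, field=col) from None
    df[col] = parsed


# ---------------------------------------------------------------------------
# per-table readers
# ---------------------------------------------------------------------------

def read_reads(path) -> pd.DataFrame:
    df = _read_tsv(path, READS_COLUMNS, "reads")
    if len(df):
        _coerce_int(df, "replicate", "reads", minimum=1)
        _coerce_int(df, "reads", "reads", minimum=0)
        _coerce_enum(df, "marker", MARKERS, "reads")
    else:
        df = df.astype({"replicate": np.int64, "reads": np.int64})
    dup = df.duplicated(subset=["sample_id", "replicate", "marker", "taxon_id"])
    if dup.any():
        row = int(df.index[dup][0])
        raise DuplicateKeyError("duplicate (sample, replicate, marker, taxon) row",
                                table="reads", row=row)
    return df


def read_taxa(path) -> pd.DataFrame:
    df = _read_tsv(path, TAXA_COLUMNS, "taxa")
    _coerce_enum(df, "rank", RANKS, "taxa")
    _coerce_enum(df, "marker", MARKERS, "taxa")
    score = pd.to_numeric(df["provenance_score"], errors="coerce")
    bad = df["provenance_score"].notna() & (~score.isin(PROVENANCE_SCORES))
    if bad.any():
        row = int(df.index[bad][0])
        raise InvalidValueError(
            f"provenance_score {df.loc[row, 'provenance_score']!r} not in {{0, 0.5, 1}}",
            table="taxa", row=row, field="provenance_score")
    df["provenance_score"] = score.astype(float)
    dup = df.duplicated(subset="taxon_id")
    if dup.any():
        row = int(df.index[dup][0])
        raise DuplicateKeyError(f"duplicate taxon_id {df.loc[row, 'taxon_id']!r}",
                                table="taxa", row=row, field="taxon_id")
    return df


def read_samples(path) -> pd.DataFrame:
    df = _read_tsv(path, SAMPLE_COLUMNS, "samples")
    _coerce_enum(df, "sex", SEXES, "samples")
    _coerce_enum(df, "age_class", AGE_CLASSES, "samples")
    _coerce_date(df, "date", "samples")
    dup = df.duplicated(subset="sample_id")
    if dup.any():
        row = int(df.index[dup][0])
        raise DuplicateKeyError(f"duplicate sample_id {df.loc[row, 'sample_id']!r}",
                                table="samples", row=row, field="sample_id")
    dup = df.duplicated(subset=["individual_id", "date"])
    if dup.any():
        row = int(df.index[dup][0])
        raise DuplicateKeyError(
            "individual re-collected on the same day "
            f"({df.loc[row, 'individual_id']!r}, {df.loc[row, 'date'].date()})",
            table="samples", row=row)
    return df


def read_focal(path) -> pd.DataFrame:
    df = _read_tsv(path, FOCAL_COLUMNS, "focal")
    if len(df):
        _coerce_int(df, "seconds", "focal", minimum=0)
        _coerce_enum(df, "food_class", FOOD_CLASSES, "focal")
        _coerce_date(df, "date", "focal")
    else:
        df = df.astype({"seconds": np.int64})
        df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# bundle-level validation and I/O
# ---------------------------------------------------------------------------

def validate_bundle(bundle: DatasetBundle) -> None:
    """Check referential integrity across the bundle's tables.

    Raises :class:`DanglingReferenceError` naming the first offending key.
    """
    taxa_ids = set(bundle.taxa["taxon_id"])
    sample_ids = set(bundle.samples["sample_id"])

    missing = bundle.reads.loc[~bundle.reads["taxon_id"].isin(taxa_ids), "taxon_id"]
    if len(missing):
        row = int(missing.index[0])
        raise DanglingReferenceError(
            f"reads references unknown taxon_id {missing.iloc[0]!r}",
            table="reads", row=row, field="taxon_id")
    missing = bundle.reads.loc[~bundle.reads["sample_id"].isin(sample_ids), "sample_id"]
    if len(missing):
        row = int(missing.index[0])
        raise DanglingReferenceError(
            f"reads references unknown sample_id {missing.iloc[0]!r}",
            table="reads", row=row, field="sample_id")

    # a recorded mother must be an adult female of the same group
    s = bundle.samples
    by_ind = s.drop_duplicates("individual_id").set_index("individual_id")
    has_mother = s["mother_id"].notna()
    for row, rec in s[has_mother].iterrows():
        m = rec["mother_id"]
        if m not in by_ind.index:
            raise DanglingReferenceError(
                f"mother_id {m!r} is not a sampled individual",
                table="samples", row=int(row), field="mother_id")
        mom = by_ind.loc[m]
        if mom["sex"] != "F" or mom["group"] != rec["group"]:
            raise DanglingReferenceError(
                f"mother_id {m!r} must be a female of group {rec['group']!r}",
                table="samples", row=int(row), field="mother_id")

    if bundle.observations is not None:
        obs = bundle.observations
        ind_ids = set(s["individual_id"])
        missing = obs.loc[~obs["individual_id"].isin(ind_ids), "individual_id"]
        if len(missing):
            row = int(missing.index[0])
            raise DanglingReferenceError(
                f"focal references unknown individual_id {missing.iloc[0]!r}",
                table="focal", row=row, field="individual_id")
        missing = obs.loc[~obs["taxon_id"].isin(taxa_ids), "taxon_id"]
        if len(missing):
            row = int(missing.index[0])
            raise DanglingReferenceError(
                f"focal references unknown taxon_id {missing.iloc[0]!r}",
                table="focal", row=row, field="taxon_id")


def read_bundle(directory, *, paths: dict | None = None) -> DatasetBundle:
    """Load and validate a bundle from ``directory`` (or explicit ``paths``).

    The focal table is optional; all others must exist.
    """
    directory = Path(directory)
    paths = paths or {}

    def p(key):
        return Path(paths.get(key, directory / FILENAMES[key]))

    obs_path = p("observations")
    return DatasetBundle(
        reads=read_reads(p("reads")),
        taxa=read_taxa(p("taxa")),
        samples=read_samples(p("samples")),
        observations=read_focal(obs_path) if obs_path.exists() else None,
    )


def _format_score(x):
    if pd.isna(x):
        return NA
    return f"{x:g}"


def _write_tsv(df, path):
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep=NA, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_bundle(bundle: DatasetBundle, directory) -> dict[str, Path]:
    """Write the bundle's tables to ``directory`` as TSV.

    Rows are sorted by primary key, so repeated writes of the same bundle are
    byte-identical. Returns the mapping of table name to written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}

    reads = bundle.reads.sort_values(
        ["sample_id", "replicate", "marker", "taxon_id"], kind="mergesort")
    written["reads"] = directory / FILENAMES["reads"]
    _write_tsv(reads, written["reads"])

    taxa = bundle.taxa.sort_values("taxon_id", kind="mergesort").copy()
    taxa["provenance_score"] = taxa["provenance_score"].map(_format_score)
    written["taxa"] = directory / FILENAMES["taxa"]
    _write_tsv(taxa, written["taxa"])

    samples = bundle.samples.sort_values("sample_id", kind="mergesort").copy()
    samples["date"] = samples["date"].dt.strftime("%Y-%m-%d")
    written["samples"] = directory / FILENAMES["samples"]
    _write_tsv(samples, written["samples"])

    if bundle.observations is not None:
        obs = bundle.observations.sort_values(
            ["individual_id", "date", "taxon_id"], kind="mergesort").copy()
        obs["date"] = obs["date"].dt.strftime("%Y-%m-%d")
        written["observations"] = directory / FILENAMES["observations"]
        _write_tsv(obs, written["observations"])
    return written


def validate_scores(taxa: pd.DataFrame) -> pd.DataFrame:
    """Report taxa with no provenance score (reporting only, never raises)."""
    return taxa.loc[taxa["provenance_score"].isna(),
                    ["taxon_id", "rank", "genus_or_higher_label"]].reset_index(drop=True)
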