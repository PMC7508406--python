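"""Ingestion, filtering and transformation of meta-analytic trait records.

A record is one (study, species, trait, generation) measurement of an
antipredator trait: its mean, standard deviation and sample size, in one
of three contexts of human contact (urbanization, captivity,
domestication).  The transformations bring heterogeneous traits onto a
common scale:

1. orient every mean so that larger = stronger antipredator response
   (latency-type traits are multiplied by -1);
2. shift each trait's means so the baseline is 0 (only traits whose
   minimum is negative are shifted);
3. z-standardize means within (context, study, trait) groups;
4. compute the absolute coefficient of variation |SD/mean| from the
   oriented, unstandardized values.

All operations take and return :class:`pandas.DataFrame` objects using the
canonical column names in :data:`RECORD_COLUMNS`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

__all__ = [
    "RECORD_COLUMNS",
    "CONTEXTS",
    "DatasetSummary",
    "compute_generations",
    "load_records",
    "validate_records",
    "apply_filters",
    "harmonize_direction",
    "shift_to_nonnegative",
    "standardize_within",
    "compute_abs_cv",
    "standardize_dataset",
    "summarize_dataset",
]

CONTEXTS = ("urbanization", "captivity", "domestication")
TRAIT_CLASSES = ("behavioral", "physiological")
FORAGING_GUILDS = ("carnivore", "omnivore", "herbivore", "granivore", "insectivore")
SOCIALITY = ("gregarious", "solitary")

RECORD_COLUMNS = [
    "context",
    "study_id",
    "species_id",
    "trait_id",
    "trait_class",
    "generation",
    "raw_mean",
    "raw_sd",
    "sample_size",
    "direction",
    "selected_for_high_fear",
]

#: group keys for within-group z-standardization
STANDARDIZE_KEYS = ["context", "study_id", "trait_id"]
#: group keys for the baseline shift (a trait's scale is context-specific)
SHIFT_KEYS = ["context", "trait_id"]

DEFAULT_DOG_SPECIES = frozenset(
    {"Canis_familiaris", "Canis_lupus_familiaris", "canis_familiaris"}
)


def compute_generations(time_since_colonization: float, age_at_maturity: float) -> float:
    """Generations in an urbanized context: colonization time / maturity age.

    Both arguments are in years; the quotient is returned unrounded.
    """
    if age_at_maturity <= 0:
        raise ValueError(
            f"age at maturity must be positive; got {age_at_maturity}"
        )
    if time_since_colonization < 0:
        raise ValueError("time since colonization must be non-negative")
    return time_since_colonization / age_at_maturity


def load_records(path, column_map: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a delimited records table, renaming columns via ``column_map``.

    ``column_map`` maps source column names to the canonical names in
    :data:`RECORD_COLUMNS`; columns already canonical pass through.
    """
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_records(df)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check schema, dtypes and invariants; return a validated copy."""
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records table is missing columns: {missing}")
    df = df.copy()
    df["generation"] = df["generation"].astype(float)
    df["raw_mean"] = df["raw_mean"].astype(float)
    df["raw_sd"] = df["raw_sd"].astype(float)
    df["sample_size"] = df["sample_size"].astype(int)
    df["direction"] = df["direction"].astype(int)
    df["selected_for_high_fear"] = df["selected_for_high_fear"].astype(bool)
    bad_ctx = set(df["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown contexts: {sorted(bad_ctx)}")
    bad_cls = set(df["trait_class"]) - set(TRAIT_CLASSES)
    if bad_cls:
        raise ValueError(f"unknown trait classes: {sorted(bad_cls)}")
    if not set(df["direction"]).issubset({1, -1}):
        raise ValueError("direction must be +1 or -1")
    if (df["raw_sd"] < 0).any():
        raise ValueError("raw_sd must be non-negative")
    if (df["sample_size"] < 1).any():
        raise ValueError("sample_size must be >= 1")
    if (df["generation"] < 0).any():
        raise ValueError("generation must be non-negative")
    return df


def apply_filters(
    df: pd.DataFrame,
    remove_dogs: bool = True,
    min_values_per_trait: int = 2,
    dog_species=DEFAULT_DOG_SPECIES,
) -> tuple[pd.DataFrame, list[dict]]:
    """Exclusion filters, each dropped record logged with its reason.

    Drops, in order: records from lines selected for high fear/aggression;
    dog records from the domestication set (between-breed variability);
    then any (study, trait) group left with fewer than
    ``min_values_per_trait`` records (a single value cannot define a
    trajectory).

    Returns
    -------
    (retained, exclusion_log)
        ``exclusion_log`` is a list of dicts with the record's identifying
        fields and a human-readable ``reason``.
    """
    log: list[dict] = []
    if df.empty:
        return df.copy(), log

    def _log_rows(rows: pd.DataFrame, reason: str) -> None:
        for _, r in rows.iterrows():
            log.append(
                {
                    "context": r["context"],
                    "study_id": r["study_id"],
                    "species_id": r["species_id"],
                    "trait_id": r["trait_id"],
                    "generation": float(r["generation"]),
                    "reason": reason,
                }
            )

    keep = df.copy()
    sel = keep["selected_for_high_fear"]
    _log_rows(keep[sel], "high-fear selection line")
    keep = keep[~sel]

    if remove_dogs:
        is_dog = (keep["context"] == "domestication") & keep["species_id"].isin(
            set(dog_species)
        )
        _log_rows(keep[is_dog], "dog record in domestication context")
        keep = keep[~is_dog]

    counts = keep.groupby(["context", "study_id", "trait_id"])["raw_mean"].transform(
        "size"
    )
    small = counts < min_values_per_trait
    _log_rows(
        keep[small],
        f"fewer than {min_values_per_trait} values for this (study, trait)",
    )
    keep = keep[~small]
    return keep.reset_index(drop=True), log


def harmonize_direction(df: pd.DataFrame) -> pd.DataFrame:
    """Orient means so larger values always mean stronger antipredator response.

    Means with ``direction == -1`` are multiplied by -1; SDs are untouched.
    The ``direction`` column is reset to +1 afterwards.
    """
    out = df.copy()
    out["raw_mean"] = out["raw_mean"] * out["direction"]
    out["direction"] = 1
    return out


def shift_to_nonnegative(df: pd.DataFrame, keys=None) -> pd.DataFrame:
    """Shift each trait group with a negative minimum up by |minimum|.

    After the shift the group's minimum is exactly 0; groups already
    non-negative are left unchanged, so every trait has a baseline of 0
    without displacing traits that are naturally positive.  Pairwise
    differences within a group are preserved.
    """
    keys = list(keys) if keys is not None else SHIFT_KEYS
    out = df.copy()
    gmin = out.groupby(keys)["raw_mean"].transform("min")
    shift = np.where(gmin < 0, -gmin, 0.0)
    out["raw_mean"] = out["raw_mean"] + shift
    return out


def standardize_within(df: pd.DataFrame, keys=None) -> pd.DataFrame:
    """Z-standardize means within (context, study, trait) groups.

    Uses the sample SD (n-1 denominator).  Degenerate groups — size 1 or
    zero SD — get ``standardized_mean = 0`` and a warning, so their records
    stay available for the CV analysis.
    """
    keys = list(keys) if keys is not None else STANDARDIZE_KEYS
    out = df.copy()
    grp = out.groupby(keys)["raw_mean"]
    mu = grp.transform("mean")
    sd = grp.transform("std")  # pandas std is n-1 by default
    degenerate = sd.isna() | (sd == 0)
    if degenerate.any():
        n_groups = out.loc[degenerate].groupby(keys).ngroups
        warnings.warn(
            f"{n_groups} group(s) with zero or undefined SD; "
            "standardized_mean set to 0 for their records",
            stacklevel=2,
        )
    z = (out["raw_mean"] - mu) / sd
    out["standardized_mean"] = z.where(~degenerate, 0.0)
    return out


def compute_abs_cv(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Absolute coefficient of variation |raw_sd / raw_mean| per record.

    Records with a zero mean have an undefined CV; they keep NaN in the
    ``abs_cv`` column and are listed in the returned exclusion log.
    """
    out = df.copy()
    zero = out["raw_mean"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out["abs_cv"] = np.abs(out["raw_sd"] / out["raw_mean"])
    out.loc[zero, "abs_cv"] = np.nan
    log = [
        {
            "context": r["context"],
            "study_id": r["study_id"],
            "trait_id": r["trait_id"],
            "generation": float(r["generation"]),
            "reason": "zero mean: CV undefined",
        }
        for _, r in out[zero].iterrows()
    ]
    return out, log


def standardize_dataset(
    df: pd.DataFrame,
    remove_dogs: bool = True,
    min_values_per_trait: int = 2,
    weighting: str = "n",
) -> tuple[pd.DataFrame, list[dict]]:
    """Full preparation pipeline: filter, orient, CV, shift, standardize, weight.

    The CV is computed from the oriented but unstandardized mean and SD
    (the standardized group mean is 0, where a CV would be undefined).

    ``weighting`` sets the per-record precision weight: ``"n"`` (weight =
    sample size, precision proportional to n, the default), ``"inverse_n"``
    (weight = 1/n) or ``"none"`` (all 1).

    Returns the standardized table and the combined exclusion log.
    """
    df = validate_records(df)
    kept, log = apply_filters(
        df, remove_dogs=remove_dogs, min_values_per_trait=min_values_per_trait
    )
    kept = harmonize_direction(kept)
    kept, cv_log = compute_abs_cv(kept)
    log = log + cv_log
    kept = shift_to_nonnegative(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = standardize_within(kept)
    if weighting == "n":
        kept["weight"] = kept["sample_size"].astype(float)
    elif weighting == "inverse_n":
        kept["weight"] = 1.0 / kept["sample_size"].astype(float)
    elif weighting == "none":
        kept["weight"] = 1.0
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    return kept, log


@dataclass
class DatasetSummary:
    """Per-context and overall bookkeeping counts for a records table."""

    per_context: dict = field(default_factory=dict)
    n_studies: int = 0
    n_species: int = 0
    n_mean_records: int = 0
    n_sd_records: int = 0
    mean_records_per_study: float = 0.0
    sd_records_per_study: float = 0.0
    mean_traits_per_study: float = 0.0
    sd_traits_per_study: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def summarize_dataset(df: pd.DataFrame) -> DatasetSummary:
    """Counts of studies, species, records and per-study averages.

    Traits-per-study counts distinct trait ids; the SD-record count is the
    number of records with a usable (positive) raw SD.
    """
    per_context = {}
    for ctx in CONTEXTS:
        sub = df[df["context"] == ctx]
        per_context[ctx] = {
            "n_studies": int(sub["study_id"].nunique()),
            "n_species": int(sub["species_id"].nunique()),
            "n_mean_records": int(len(sub)),
            "n_sd_records": int((sub["raw_sd"] > 0).sum()),
        }
    per_study = df.groupby(["context", "study_id"]).agg(
        n_records=("raw_mean", "size"), n_traits=("trait_id", "nunique")
    )
    n_rec = per_study["n_records"].to_numpy(dtype=float)
    n_tr = per_study["n_traits"].to_numpy(dtype=float)
    return DatasetSummary(
        per_context=per_context,
        n_studies=int(per_study.shape[0]),
        n_species=int(df["species_id"].nunique()),
        n_mean_records=int(len(df)),
        n_sd_records=int((df["raw_sd"] > 0).sum()),
        mean_records_per_study=float(n_rec.mean()) if n_rec.size else 0.0,
        sd_records_per_study=float(n_rec.std(ddof=1)) if n_rec.size > 1 else 0.0,
        mean_traits_per_study=float(n_tr.mean()) if n_tr.size else 0.0,
        sd_traits_per_study=float(n_tr.std(ddof=1)) if n_tr.size > 1 else 0.0,
    )
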