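"""Harmonisation of heterogeneous multi-study observations into fid units.

Tracer kinetic studies report aluminium burdens in incompatible units —
fraction of ingested dose (fid), concentrations (g/L), per-gram tissue
contents, percent of dose per kg — and some studies publish only mean ± sd
summaries.  This module parses the study identifier scheme
``[Study]-[Salt]-[Administration]-[Comment]-[Species]-[Body Weight]``,
converts every record to whole-compartment fid using reference-individual
physiology (compartment volumes, tissue masses via volume × density), turns
complete urine collections into cumulative excreted amounts, and replaces
each (N, mean, sd) summary row by N log-normal pseudo-observations whose
log-scale sample moments match the summary exactly.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .physiology import (TISSUES, InvalidInputError, ReferenceIndividual,
                         tissue_mass)

__all__ = [
    "StudyIdentifier",
    "ObservationRecord",
    "parse_identifier",
    "deaggregate",
    "deaggregate_frame",
    "convert_to_fid",
    "urine_cumulative",
    "curate_dataset",
    "read_observations",
    "write_observations",
    "MOLAR_MASS_AL26",
    "OBSERVATION_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Molar mass of the ²⁶Al tracer, g/mol (dose mol ↔ g conversions).
MOLAR_MASS_AL26 = 25.99

#: Minimum plausible sampling time (1 s) in hours.
MIN_TIME_H = 1.0 / 3600.0

VALID_SALTS = ("AlCit", "AlChl")
VALID_ROUTES = ("po", "iv")
VALID_SPECIES = ("rat", "hum")
VALID_COMMENTS = ("addcit", "fasted", "hardwater", "softwater")
VALID_MATRICES = ("pla", "blo") + TISSUES + ("uri",)
VALID_UNITS = ("fid", "fid_per_L", "fid_per_g", "g_per_L", "g_per_g",
               "percent_dose_per_kg")

#: Column order of the observation CSV dialect.
OBSERVATION_COLUMNS = ["identifier", "group_id", "time_h", "matrix", "value",
                       "unit", "n", "mean", "sd", "dose_mol_per_kg",
                       "dose_total_mol", "complete_collection",
                       "collected_volume_L"]


class ParseError(InvalidInputError):
    """Raised when a study identifier token is not recognised."""


class ConversionError(InvalidInputError):
    """Raised when a record cannot be converted to fid."""


_BW_RE = re.compile(r"^(\d+(?:\.\d+)?)(kg|g)$")


@dataclass(frozen=True)
class StudyIdentifier:
    """Parsed study identifier.

    Serialises to ``[Study]-[Salt]-[Administration]-[Comment]-[Species]-
    [Body Weight]`` with zero or more comment tokens, and round-trips.
    """

    study: str
    salt: str
    route: str
    species: str
    body_weight: float
    body_weight_unit: str
    comments: tuple[str, ...] = ()
    #: published identifiers place comment tokens after the species token
    comments_after_species: bool = True

    def __post_init__(self) -> None:
        if self.salt not in VALID_SALTS:
            raise ParseError(f"unknown salt token {self.salt!r}")
        if self.route not in VALID_ROUTES:
            raise ParseError(f"unknown route token {self.route!r}")
        if self.species not in VALID_SPECIES:
            raise ParseError(f"unknown species token {self.species!r}")
        for c in self.comments:
            if c not in VALID_COMMENTS:
                raise ParseError(f"unknown comment token {c!r}")
        if self.body_weight <= 0:
            raise ParseError(f"body weight must be positive, got {self.body_weight}")
        if self.body_weight_unit not in ("kg", "g"):
            raise ParseError(f"unknown body-weight unit {self.body_weight_unit!r}")

    @property
    def body_weight_kg(self) -> float:
        return self.body_weight if self.body_weight_unit == "kg" else self.body_weight / 1000.0

    @property
    def salt_name(self) -> str:
        return "citrate" if self.salt == "AlCit" else "chloride"

    def serialise(self) -> str:
        bw = f"{self.body_weight:g}{self.body_weight_unit}"
        if self.comments_after_species:
            return "-".join([self.study, self.salt, self.route, self.species,
                             *self.comments, bw])
        return "-".join([self.study, self.salt, self.route, *self.comments,
                         self.species, bw])

    def __str__(self) -> str:
        return self.serialise()


def parse_identifier(text: str) -> StudyIdentifier:
    """Parse an identifier string.

    Comment tokens are accepted either between route and species (the
    scheme's nominal field order) or between species and body weight (the
    placement used by the published identifiers); their position is retained
    so that serialisation round-trips.
    """
    tokens = text.split("-")
    if len(tokens) < 5:
        raise ParseError(f"identifier {text!r} has fewer than 5 tokens")
    study, salt, route = tokens[0], tokens[1], tokens[2]
    middle, bw_token = tokens[3:-1], tokens[-1]
    species_hits = [i for i, tok in enumerate(middle) if tok in VALID_SPECIES]
    if len(species_hits) != 1:
        raise ParseError(f"identifier {text!r} needs exactly one species token")
    i = species_hits[0]
    comments = tuple(middle[:i] + middle[i + 1:])
    m = _BW_RE.match(bw_token)
    if not m:
        raise ParseError(f"cannot parse body-weight token {bw_token!r}")
    return StudyIdentifier(study=study, salt=salt, route=route, species=middle[i],
                           body_weight=float(m.group(1)), body_weight_unit=m.group(2),
                           comments=comments, comments_after_species=(i == 0))


@dataclass(frozen=True)
class ObservationRecord:
    """One curated measurement (or one mean±sd summary row)."""

    identifier: StudyIdentifier
    group_id: str
    time_h: float
    matrix: str
    value: float | None
    unit: str
    n: int | None = None
    mean: float | None = None
    sd: float | None = None
    dose_mol_per_kg: float | None = None
    dose_total_mol: float | None = None
    complete_collection: bool = True
    collected_volume_L: float | None = None

    def __post_init__(self) -> None:
        if self.matrix not in VALID_MATRICES:
            raise InvalidInputError(f"unknown matrix {self.matrix!r}")
        if self.unit not in VALID_UNITS:
            raise InvalidInputError(f"unknown unit {self.unit!r}")
        if self.time_h <= MIN_TIME_H:
            raise InvalidInputError(f"implausible sampling time {self.time_h} h (≤ 1 s)")
        if self.is_summary:
            if self.n is None or self.n < 1 or self.mean is None or self.mean <= 0:
                raise InvalidInputError("summary rows need n ≥ 1 and mean > 0")
            if self.sd is not None and self.sd < 0:
                raise InvalidInputError("sd must be non-negative")
        elif self.value is None or self.value <= 0:
            raise InvalidInputError("value must be positive")

    @property
    def is_summary(self) -> bool:
        return self.mean is not None or self.n is not None

    @property
    def dose_total_g(self) -> float | None:
        if self.dose_total_mol is None:
            return None
        return self.dose_total_mol * MOLAR_MASS_AL26


# ---------------------------------------------------------------------------
# de-aggregation of summary rows


def deaggregate(N: int, m: float, sd: float, seed) -> np.ndarray:
    """Replace a mean ± sd summary by N log-normal pseudo-observations.

    Matching log-normal parameters: σ² = log(sd²/m² + 1),
    μ = log(m) − σ²/2.  N standard-normal deviates are standardised exactly
    to sample mean μ and sample SD σ on the log scale (ddof = 1) and
    exponentiated, so the returned log-values reproduce (μ, σ) exactly.
    ``sd = 0`` degenerates to N copies of m.
    """
    if m <= 0:
        raise InvalidInputError(f"mean must be positive, got {m}")
    if sd < 0:
        raise InvalidInputError(f"sd must be non-negative, got {sd}")
    N = int(N)
    if sd == 0.0:
        if N < 1:
            raise InvalidInputError("N must be at least 1")
        return np.full(N, m, dtype=float)
    if N < 2:
        raise InvalidInputError("N must be at least 2 when sd > 0")
    sigma2 = math.log(sd**2 / m**2 + 1.0)
    sigma = math.sqrt(sigma2)
    mu = math.log(m) - sigma2 / 2.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(N)
    while np.std(x, ddof=1) == 0.0:  # pathologically identical draws
        x = rng.standard_normal(N)
    z = (x - x.mean()) / np.std(x, ddof=1)
    return np.exp(mu + sigma * z)


def deaggregate_frame(df: pd.DataFrame, seed) -> pd.DataFrame:
    """Expand every summary row of an observation table into N value rows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_rows = []
    for _, row in df.iterrows():
        if pd.notna(row.get("n")) and pd.notna(row.get("mean")):
            n = int(row["n"])
            sd = float(row["sd"]) if pd.notna(row.get("sd")) else 0.0
            values = deaggregate(n, float(row["mean"]), sd, rng)
            for k, v in enumerate(values):
                new = row.copy()
                new["value"] = v
                new["n"] = np.nan
                new["mean"] = np.nan
                new["sd"] = np.nan
                new["group_id"] = f"{row['group_id']}"
                out_rows.append(new)
        else:
            out_rows.append(row.copy())
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# unit conversion


def _compartment_volume(matrix: str, ref: ReferenceIndividual) -> float:
    if matrix == "blo":
        return ref.V_blo
    if matrix == "pla":
        return ref.plasma_volume
    if matrix in TISSUES:
        return ref.V_tis[matrix]
    raise ConversionError(f"no compartment volume for matrix {matrix!r}")


def _fid_factor(unit: str, matrix: str, ref: ReferenceIndividual,
                dose_g: float | None, collected_volume_L: float | None) -> float:
    """Multiplier turning a reported value into whole-compartment fid."""
    if unit == "fid":
        return 1.0
    if unit == "fid_per_L":
        if matrix == "uri":
            raise ConversionError("fid/L is not defined for urine")
        return _compartment_volume(matrix, ref)
    if unit == "fid_per_g":
        if matrix not in TISSUES:
            raise ConversionError(f"fid/g needs a tissue matrix, got {matrix!r}")
        return tissue_mass(ref, matrix) * 1000.0
    if unit == "percent_dose_per_kg":
        if matrix not in TISSUES:
            raise ConversionError(f"%dose/kg needs a tissue matrix, got {matrix!r}")
        return tissue_mass(ref, matrix) / 100.0
    if dose_g is None:
        raise ConversionError(f"unit {unit!r} needs the administered dose in g")
    if unit == "g_per_L":
        if matrix in ("blo", "pla"):
            return _compartment_volume(matrix, ref) / dose_g
        if matrix == "uri":
            if collected_volume_L is None or collected_volume_L <= 0:
                raise ConversionError("urine g/L needs a positive collected volume")
            return collected_volume_L / dose_g
        raise ConversionError(f"g/L is not supported for matrix {matrix!r}")
    if unit == "g_per_g":
        if matrix not in TISSUES:
            raise ConversionError(f"g/g needs a tissue matrix, got {matrix!r}")
        return tissue_mass(ref, matrix) * 1000.0 / dose_g
    raise ConversionError(f"unknown unit {unit!r}")


def convert_to_fid(value: float, unit: str, matrix: str, ref: ReferenceIndividual,
                   dose_g: float | None = None,
                   collected_volume_L: float | None = None) -> float:
    """Convert one reported value to whole-compartment fraction of ingested dose."""
    if value < 0:
        raise ConversionError(f"value must be non-negative, got {value}")
    return value * _fid_factor(unit, matrix, ref, dose_g, collected_volume_L)


def fid_to_unit(fid: float, unit: str, matrix: str, ref: ReferenceIndividual,
                dose_g: float | None = None,
                collected_volume_L: float | None = None) -> float:
    """Inverse of :func:`convert_to_fid` (used by the synthetic generator)."""
    return fid / _fid_factor(unit, matrix, ref, dose_g, collected_volume_L)


def urine_cumulative(conc_g_per_L: float, collected_volume_L: float,
                     dose_g: float) -> float:
    """Cumulative excreted fid of one complete urine collection interval."""
    if collected_volume_L <= 0:
        raise ConversionError(f"collected volume must be positive, got {collected_volume_L}")
    if dose_g <= 0:
        raise ConversionError(f"dose must be positive, got {dose_g}")
    if conc_g_per_L < 0:
        raise ConversionError(f"concentration must be non-negative, got {conc_g_per_L}")
    return conc_g_per_L * collected_volume_L / dose_g


# ---------------------------------------------------------------------------
# dataset-level pipeline


def read_observations(path) -> pd.DataFrame:
    """Read the observation CSV dialect, validating identifiers and domains."""
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise InvalidInputError(f"observation table lacks columns {sorted(missing)}")
    for col in OBSERVATION_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for text in df["identifier"].unique():
        parse_identifier(text)
    bad_matrix = set(df["matrix"]) - set(VALID_MATRICES)
    if bad_matrix:
        raise InvalidInputError(f"unknown matrices {sorted(bad_matrix)}")
    bad_unit = set(df["unit"]) - set(VALID_UNITS)
    if bad_unit:
        raise InvalidInputError(f"unknown units {sorted(bad_unit)}")
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def _resolve_ref(ident: StudyIdentifier, sex=None) -> ReferenceIndividual:
    from .population import resolve_reference

    return resolve_reference(ident.species, ident.body_weight_kg, sex)


def curate_dataset(df: pd.DataFrame, seed=0,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full curation pipeline on an observation table.

    Steps: drop implausible sampling times (≤ 1 s) and incomplete urine
    collections with a logged reason; de-aggregate summary rows; convert
    every value to whole-compartment fid; accumulate sequential urine
    collections into running cumulative amounts; flag fid > 1.

    Returns ``(curated, rejected)`` — the curated table has columns
    identifier, group_id, time_h, matrix, value (fid) and flag_above_unity;
    the rejected table carries a ``reject_reason`` column.
    """
    df = df.copy().reset_index(drop=True)
    reasons = pd.Series("", index=df.index)

    too_early = df["time_h"] <= MIN_TIME_H
    reasons[too_early] = "implausible sampling time <= 1 s"
    incomplete = (df["matrix"] == "uri") & (df["unit"] == "g_per_L") & (
        df["complete_collection"].fillna(False).astype(bool) == False)  # noqa: E712
    reasons[incomplete & ~too_early] = "incomplete urine collection"
    rejected = df[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    for _, row in rejected.iterrows():
        logger.info("rejected %s @ %.3g h: %s", row["identifier"], row["time_h"],
                    row["reject_reason"])
    df = df[reasons == ""].reset_index(drop=True)

    df = deaggregate_frame(df, seed)

    out_rows = []
    sex_col = "sex" if "sex" in df.columns else None
    for (ident_text, group_id), sub in df.groupby(["identifier", "group_id"], sort=False):
        ident = parse_identifier(ident_text)
        sex = sub[sex_col].iloc[0] if sex_col and pd.notna(sub[sex_col].iloc[0]) else None
        ref = _resolve_ref(ident, sex)
        sub = sub.sort_values("time_h", kind="stable")
        # subject-level split for urine accumulation: rows from one subject
        # share a "subject" column when present, else the whole group is one series
        subj_col = "subject" if "subject" in sub.columns else None
        for _, subject_rows in (sub.groupby(subj_col, dropna=False) if subj_col else [(None, sub)]):
            uri_running = 0.0
            for _, row in subject_rows.iterrows():
                dose_g = (float(row["dose_total_mol"]) * MOLAR_MASS_AL26
                          if pd.notna(row.get("dose_total_mol")) else None)
                vol = (float(row["collected_volume_L"])
                       if pd.notna(row.get("collected_volume_L")) else None)
                fid = convert_to_fid(float(row["value"]), row["unit"], row["matrix"],
                                     ref, dose_g, vol)
                if row["matrix"] == "uri" and row["unit"] == "g_per_L":
                    uri_running += fid  # sequential complete collections accumulate
                    fid = uri_running
                rec = {"identifier": ident_text, "group_id": group_id,
                       "time_h": float(row["time_h"]), "matrix": row["matrix"],
                       "value": fid, "flag_above_unity": fid > 1.0}
                if sex_col:
                    rec["sex"] = sex
                if subj_col:
                    rec["subject"] = row[subj_col]
                out_rows.append(rec)
    curated = pd.DataFrame(out_rows)
    n_flag = int(curated["flag_above_unity"].sum()) if len(curated) else 0
    if n_flag:
        logger.warning("%d curated records exceed one administered dose "
                       "(possible unit error in the source)", n_flag)
    return curated, rejected
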