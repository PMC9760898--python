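"""Sex-difference effect sizes from per-sex stable-isotope summaries.

Each literature record carries the per-sex mean, standard deviation and
sample size of an isotope ratio (delta-15N or delta-13C, in permil) for one
study x species x tissue combination, together with per-sex body masses and
ecological moderators.  This module turns those summaries into the effect
sizes used downstream:

``MD``
    raw mean difference (male - female), in permil; positive means males are
    enriched in the heavy isotope.
``lnVR``
    log ratio of male to female standard deviation, with the small-sample
    bias correction; positive means males are more isotopically variable.
``lnCVR``
    log ratio of the coefficients of variation, which additionally adjusts
    for the group means.

Sampling variances use the standard large-sample forms; they are what the
multilevel models use as per-observation weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ISOTOPES",
    "DIET_CLASSES",
    "StudyRecord",
    "EffectSize",
    "ModeratorSet",
    "EffectSizeError",
    "delta_value",
    "raw_mean_difference",
    "ln_variability_ratio",
    "ln_cv_ratio",
    "dimorphism_index",
    "mean_species_size",
    "moderators_from_record",
    "records_to_frame",
    "frame_to_records",
    "effect_table",
]

ISOTOPES = ("N15", "C13")
DIET_CLASSES = ("carnivore", "omnivore", "herbivore")

#: columns of the delimited study table, in canonical order
RECORD_COLUMNS = (
    "study_id",
    "species",
    "tissue",
    "isotope",
    "male_mean",
    "male_sd",
    "male_n",
    "female_mean",
    "female_sd",
    "female_n",
    "male_mass",
    "female_mass",
    "diet_class",
    "gape_limited",
    "pub_year",
    "taxon_class",
)


class EffectSizeError(ValueError):
    """Raised when a record cannot support the requested effect size."""


def _missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return False


@dataclass(frozen=True)
class StudyRecord:
    """One study x species x tissue x isotope row of per-sex summaries.

    Numeric fields may be ``None`` (missing in the source study); records with
    missing required fields are removed by the complete-case filter rather
    than raising here.
    """

    study_id: str
    species: str
    tissue: str
    isotope: str
    male_mean: Optional[float] = None
    male_sd: Optional[float] = None
    male_n: Optional[int] = None
    female_mean: Optional[float] = None
    female_sd: Optional[float] = None
    female_n: Optional[int] = None
    male_mass: Optional[float] = None
    female_mass: Optional[float] = None
    diet_class: Optional[str] = None
    gape_limited: Optional[bool] = None
    pub_year: Optional[int] = None
    taxon_class: Optional[str] = None

    def issues(self) -> list[str]:
        """Validate field-level invariants; return human-readable problems."""
        out = []
        if self.isotope not in ISOTOPES:
            out.append(f"unknown isotope {self.isotope!r}")
        for sex in ("male", "female"):
            sd = getattr(self, f"{sex}_sd")
            n = getattr(self, f"{sex}_n")
            if not _missing(sd) and sd < 0:
                out.append(f"negative {sex}_sd")
            if not _missing(n) and n < 2:
                out.append(f"{sex}_n < 2")
            mass = getattr(self, f"{sex}_mass")
            if not _missing(mass) and mass <= 0:
                out.append(f"nonpositive {sex}_mass")
        if self.diet_class is not None and self.diet_class not in DIET_CLASSES:
            out.append(f"unknown diet_class {self.diet_class!r}")
        return out

    def swapped_sexes(self) -> "StudyRecord":
        """Return the record with male and female summaries exchanged."""
        return replace(
            self,
            male_mean=self.female_mean,
            male_sd=self.female_sd,
            male_n=self.female_n,
            female_mean=self.male_mean,
            female_sd=self.male_sd,
            female_n=self.male_n,
            male_mass=self.female_mass,
            female_mass=self.male_mass,
        )


@dataclass(frozen=True)
class EffectSize:
    """A computed sex-difference metric with its sampling variance."""

    metric: str  # one of {"MD", "lnVR", "lnCVR"}
    value: float
    sampling_variance: float
    record_ref: Optional[StudyRecord] = None

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise EffectSizeError(f"non-finite {self.metric} value")
        if not (self.sampling_variance > 0 and math.isfinite(self.sampling_variance)):
            raise EffectSizeError(f"nonpositive sampling variance for {self.metric}")


@dataclass(frozen=True)
class ModeratorSet:
    """Moderators of one record: signed size dimorphism (positive =
    male-biased), mean species mass in kg, dietary class and gape limitation."""

    dimorphism_index: float
    mean_size: float
    diet_class: Optional[str]
    gape_limited: Optional[bool]


def delta_value(r_sample: float, r_standard: float) -> float:
    """Delta notation: relative heavy-isotope enrichment of a sample, in permil.

    ``(r_sample - r_standard) / r_standard * 1000``; positive iff the sample is
    enriched in the heavy isotope relative to the international standard.
    """
    if r_standard <= 0:
        raise ValueError("standard isotope ratio must be positive")
    return (r_sample - r_standard) / r_standard * 1000.0


def _require(rec: StudyRecord, names: Sequence[str], metric: str) -> None:
    miss = [n for n in names if _missing(getattr(rec, n))]
    if miss:
        raise EffectSizeError(f"{metric} needs {', '.join(miss)}")


def raw_mean_difference(rec: StudyRecord) -> EffectSize:
    """Male minus female mean isotope value (permil).

    Sampling variance is the unpooled two-sample form
    ``sd_m^2/n_m + sd_f^2/n_f``.
    """
    _require(rec, ("male_mean", "female_mean", "male_sd", "female_sd",
                   "male_n", "female_n"), "MD")
    v = rec.male_sd**2 / rec.male_n + rec.female_sd**2 / rec.female_n
    return EffectSize("MD", rec.male_mean - rec.female_mean, v, rec)


def ln_variability_ratio(rec: StudyRecord) -> EffectSize:
    """Bias-corrected log ratio of male to female standard deviation (lnVR).

    value = ln(sd_m/sd_f) + 1/(2(n_m-1)) - 1/(2(n_f-1))
    var   = 1/(2(n_m-1)) + 1/(2(n_f-1))

    Values beyond +-ln 2 mean one sex is more than twice as variable as the
    other.
    """
    _require(rec, ("male_sd", "female_sd", "male_n", "female_n"), "lnVR")
    if rec.male_sd <= 0 or rec.female_sd <= 0:
        raise EffectSizeError("lnVR undefined for zero standard deviation")
    if rec.male_n < 2 or rec.female_n < 2:
        raise EffectSizeError("lnVR needs n >= 2 in both sexes")
    cm = 1.0 / (2.0 * (rec.male_n - 1))
    cf = 1.0 / (2.0 * (rec.female_n - 1))
    value = math.log(rec.male_sd / rec.female_sd) + cm - cf
    return EffectSize("lnVR", value, cm + cf, rec)


def ln_cv_ratio(rec: StudyRecord) -> EffectSize:
    """Bias-corrected log ratio of coefficients of variation (lnCVR).

    value = ln((sd_m/|m_m|)/(sd_f/|m_f|)) + 1/(2(n_m-1)) - 1/(2(n_f-1))
    var   = CV_m^2/n_m + 1/(2(n_m-1)) + CV_f^2/n_f + 1/(2(n_f-1))

    assuming independence of means and SDs within sex.
    """
    _require(rec, ("male_mean", "female_mean", "male_sd", "female_sd",
                   "male_n", "female_n"), "lnCVR")
    if rec.male_mean == 0 or rec.female_mean == 0:
        raise EffectSizeError("lnCVR undefined for zero mean")
    if rec.male_sd <= 0 or rec.female_sd <= 0:
        raise EffectSizeError("lnCVR undefined for zero standard deviation")
    if rec.male_n < 2 or rec.female_n < 2:
        raise EffectSizeError("lnCVR needs n >= 2 in both sexes")
    cvm = rec.male_sd / abs(rec.male_mean)
    cvf = rec.female_sd / abs(rec.female_mean)
    cm = 1.0 / (2.0 * (rec.male_n - 1))
    cf = 1.0 / (2.0 * (rec.female_n - 1))
    value = math.log(cvm / cvf) + cm - cf
    var = cvm**2 / rec.male_n + cm + cvf**2 / rec.female_n + cf
    return EffectSize("lnCVR", value, var, rec)


_METRIC_FUNCS = {
    "MD": raw_mean_difference,
    "lnVR": ln_variability_ratio,
    "lnCVR": ln_cv_ratio,
}


def dimorphism_index(
    male_mass: float, female_mass: float, convention: str = "log2"
) -> float:
    """Signed size-dimorphism index from per-sex body masses (kg).

    ``log2`` (default): log2(male/female), so +1 means males are twice the
    mass of females ("100% male-biased dimorphism") and the index is
    antisymmetric in the sexes.  ``relative``: (male - female) / mean.
    """
    if _missing(male_mass) or _missing(female_mass):
        raise EffectSizeError("dimorphism index needs both masses")
    if male_mass <= 0 or female_mass <= 0:
        raise ValueError("body masses must be positive")
    if convention == "log2":
        return math.log2(male_mass / female_mass)
    if convention == "relative":
        return (male_mass - female_mass) / ((male_mass + female_mass) / 2.0)
    raise ValueError(f"unknown dimorphism convention {convention!r}")


def mean_species_size(male_mass: float, female_mass: float) -> float:
    """Arithmetic mean of male and female body mass (kg)."""
    if _missing(male_mass) or _missing(female_mass):
        raise EffectSizeError("mean species size needs both masses")
    if male_mass <= 0 or female_mass <= 0:
        raise ValueError("body masses must be positive")
    return (male_mass + female_mass) / 2.0


def moderators_from_record(rec: StudyRecord, convention: str = "log2") -> ModeratorSet:
    return ModeratorSet(
        dimorphism_index=dimorphism_index(rec.male_mass, rec.female_mass, convention),
        mean_size=mean_species_size(rec.male_mass, rec.female_mass),
        diet_class=rec.diet_class,
        gape_limited=rec.gape_limited,
    )


# ---------------------------------------------------------------------------
# tabular round trip

def records_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the canonical column order."""
    rows = [{f.name: getattr(r, f.name) for f in fields(StudyRecord)} for r in records]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[StudyRecord]:
    """Parse a study table (canonical columns) into records; NaN -> None."""
    missing_cols = set(RECORD_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"study table lacks columns: {sorted(missing_cols)}")
    out = []
    for row in df.itertuples(index=False):
        kw = {}
        for name in RECORD_COLUMNS:
            val = getattr(row, name)
            if _missing(val):
                kw[name] = None
            elif name in ("male_n", "female_n", "pub_year"):
                kw[name] = int(val)
            elif name == "gape_limited":
                kw[name] = (
                    bool(val)
                    if isinstance(val, (bool, np.bool_))
                    else str(val).strip().lower() in ("true", "1", "yes")
                )
            elif name in ("study_id", "species", "tissue", "isotope",
                          "diet_class", "taxon_class"):
                kw[name] = str(val)
            else:
                kw[name] = float(val)
        out.append(StudyRecord(**kw))
    return out


def effect_table(
    records: Sequence[StudyRecord],
    metric: str,
    isotope: str,
    convention: str = "log2",
) -> pd.DataFrame:
    """Model-ready table of one metric for one isotope.

    Rows whose metric cannot be computed are silently omitted here (use the
    complete-case filter first when the exclusions must be reported); rows
    with missing masses keep the effect size but carry NaN moderators, so
    intercept-only models can still use them.  Columns: study_id, species,
    value, sampling_variance, dimorphism, mean_size, diet_class,
    gape_limited, pub_year, taxon_class.
    """
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}")
    func = _METRIC_FUNCS[metric]
    rows = []
    for rec in records:
        if rec.isotope != isotope:
            continue
        try:
            es = func(rec)
        except (EffectSizeError, ValueError):
            continue
        try:
            mods = moderators_from_record(rec, convention)
            dim, msize = mods.dimorphism_index, mods.mean_size
        except (EffectSizeError, ValueError):
            dim, msize = float("nan"), float("nan")
        rows.append(
            {
                "study_id": rec.study_id,
                "species": rec.species,
                "value": es.value,
                "sampling_variance": es.sampling_variance,
                "dimorphism": dim,
                "mean_size": msize,
                "diet_class": rec.diet_class,
                "gape_limited": rec.gape_limited,
                "pub_year": rec.pub_year,
                "taxon_class": rec.taxon_class,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "study_id", "species", "value", "sampling_variance", "dimorphism",
            "mean_size", "diet_class", "gape_limited", "pub_year", "taxon_class",
        ],
    )
    df.attrs["metric"] = metric
    df.attrs["isotope"] = isotope
    df.attrs["dimorphism_convention"] = convention
    return df
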