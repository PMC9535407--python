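"""Flag-never-delete cleaning of specimen trait records.

Per species x trait group: gate on a minimum record count, screen known
adults for gross outliers with a univariate squared standardized distance
against a chi-square(1 df) quantile, classify the surviving adult
distribution (normal / log-normal / neither), derive upper and lower
limits, and re-assess unknown-life-stage records against those limits.
Every record receives a ``measurementStatus``; none is ever deleted.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from vertraits.records import TraitRecord

__all__ = [
    "CleaningConfig",
    "CleaningReport",
    "GroupSummary",
    "STATUSES",
    "gate_min_records",
    "detect_adult_outliers",
    "classify_distribution",
    "compute_limits",
    "annotate_unknowns",
    "clean_dataset",
]

STATUS_POSSIBLE_ADULT = "possible adult; possibly good"
STATUS_OUTLIER = "outlier"
STATUS_POSSIBLE_JUVENILE = "possible juvenile"
STATUS_TOO_FEW = "too few records"
STATUS_KNOWN_ADULT = "known adult"
STATUS_KNOWN_JUVENILE = "known juvenile"
STATUS_NO_ADULT_REF = "no adult reference"

STATUSES = (
    STATUS_POSSIBLE_ADULT,
    STATUS_OUTLIER,
    STATUS_POSSIBLE_JUVENILE,
    STATUS_TOO_FEW,
    STATUS_KNOWN_ADULT,
    STATUS_KNOWN_JUVENILE,
    STATUS_NO_ADULT_REF,
)

NORMAL = "normal"
LOG_NORMAL = "log-normal"
NON_NORMAL = "non-normal"
NOT_ASSESSED = "not assessed"


@dataclass(frozen=True)
class CleaningConfig:
    min_records: int = 10
    outlier_cutoff: float = 0.95
    normality_alpha: float = 0.05
    sigma_multiplier: float = 3.0
    quantile_bounds: tuple[float, float] = (0.05, 0.95)
    large_sample_switch: int = 5000
    #: if True, groups with no usable known adults fall back to using all
    #: non-juvenile records as the reference distribution
    no_adult_fallback: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.quantile_bounds
        if not (0 < lo < hi < 1):
            raise ValueError("quantile_bounds must satisfy 0 < lower < upper < 1")
        if self.min_records < 2:
            raise ValueError("min_records must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "CleaningConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "quantile_bounds" in raw:
            raw["quantile_bounds"] = tuple(raw["quantile_bounds"])
        return cls(**raw)


@dataclass
class GroupSummary:
    scientific_name: str
    trait_term: str
    n: int
    status_counts: Counter = field(default_factory=Counter)
    normality: str = NOT_ASSESSED
    lower_limit: float | None = None
    upper_limit: float | None = None
    lower_limit_method: str = ""
    upper_limit_method: str = ""


@dataclass
class CleaningReport:
    groups: list[GroupSummary] = field(default_factory=list)

    @property
    def total_records(self) -> int:
        return sum(sum(g.status_counts.values()) for g in self.groups)

    @property
    def status_totals(self) -> Counter:
        total: Counter = Counter()
        for g in self.groups:
            total.update(g.status_counts)
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            row = {
                "scientificName": g.scientific_name,
                "traitTerm": g.trait_term,
                "n": g.n,
                "normality": g.normality,
                "lowerLimit": g.lower_limit,
                "upperLimit": g.upper_limit,
                "lowerLimitMethod": g.lower_limit_method,
                "upperLimitMethod": g.upper_limit_method,
            }
            for status in STATUSES:
                row[status] = g.status_counts.get(status, 0)
            row["unassessed"] = g.status_counts.get("", 0)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [f"groups: {len(self.groups)}  records: {self.total_records}"]
        for status, count in sorted(self.status_totals.items()):
            lines.append(f"  {status or '(unassessed)'}: {count}")
        return "\n".join(lines)


def _group_key(rec: TraitRecord) -> tuple[str, str]:
    return (rec.scientific_name, rec.trait_term)


def gate_min_records(
    records: Sequence[TraitRecord], min_records: int = 10
) -> tuple[dict[tuple[str, str], list[TraitRecord]], list[TraitRecord]]:
    """Split species x trait groups into those that proceed and gated-out records.

    Groups below ``min_records`` have every record labelled
    ``"too few records"``; groups at or above the gate (inclusive) proceed.
    """
    groups: dict[tuple[str, str], list[TraitRecord]] = {}
    for rec in records:
        groups.setdefault(_group_key(rec), []).append(rec)
    keep: dict[tuple[str, str], list[TraitRecord]] = {}
    gated: list[TraitRecord] = []
    for key, members in groups.items():
        if len(members) < min_records:
            gated.extend(
                replace(rec, measurement_status=STATUS_TOO_FEW) for rec in members
            )
        else:
            keep[key] = members
    return keep, gated


def detect_adult_outliers(
    values: Sequence[float] | np.ndarray, cutoff: float = 0.95
) -> np.ndarray:
    """Boolean mask of gross outliers among known-adult measurements.

    The univariate squared standardized distance ``((x - mean)/sd)**2`` is
    compared against the chi-square(1 df) quantile at ``cutoff``. Zero
    variance flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return np.zeros(0, dtype=bool)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0:
        return np.zeros(x.size, dtype=bool)
    d2 = ((x - x.mean()) / sd) ** 2
    return d2 > stats.chi2.ppf(cutoff, df=1)


def classify_distribution(
    values: Sequence[float] | np.ndarray,
    alpha: float = 0.05,
    large_sample_switch: int = 5000,
) -> str:
    """Classify an adult trait distribution as normal, log-normal, or neither.

    The raw scale is tested first; if rejected, log10 values are tested.
    Shapiro-Wilk is used up to ``large_sample_switch`` observations and the
    D'Agostino-Pearson omnibus test above it.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn(
            f"n={x.size} below normality-test validity range; classifying non-normal",
            stacklevel=2,
        )
        return NON_NORMAL
    if np.ptp(x) == 0:
        return NORMAL  # degenerate: trivially consistent with normal

    def _test(sample: np.ndarray) -> float:
        if sample.size <= large_sample_switch:
            return stats.shapiro(sample).pvalue
        return stats.normaltest(sample).pvalue

    if _test(x) > alpha:
        return NORMAL
    if np.all(x > 0) and _test(np.log10(x)) > alpha:
        return LOG_NORMAL
    return NON_NORMAL


def compute_limits(
    values: Sequence[float] | np.ndarray,
    distribution_class: str,
    config: CleaningConfig = CleaningConfig(),
) -> tuple[float | None, float | None, str, str]:
    """Lower/upper limits for the outlier-cleaned adult set, plus method labels.

    normal -> mean +/- k*sd ("sd"); log-normal -> the same on log10 values,
    back-transformed ("log sd"); non-normal -> empirical quantiles
    ("quantile"). ``not assessed`` yields no limits.
    """
    if distribution_class == NOT_ASSESSED:
        return None, None, "", ""
    x = np.asarray(values, dtype=float)
    k = config.sigma_multiplier
    if distribution_class == NORMAL:
        mu, sd = x.mean(), (x.std(ddof=1) if x.size > 1 else 0.0)
        return mu - k * sd, mu + k * sd, "sd", "sd"
    if distribution_class == LOG_NORMAL:
        lx = np.log10(x)
        mu, sd = lx.mean(), (lx.std(ddof=1) if lx.size > 1 else 0.0)
        return 10 ** (mu - k * sd), 10 ** (mu + k * sd), "log sd", "log sd"
    lo, hi = config.quantile_bounds
    ql, qh = np.quantile(x, [lo, hi])
    return float(ql), float(qh), "quantile", "quantile"


def annotate_unknowns(
    records: Iterable[TraitRecord],
    lower: float | None,
    upper: float | None,
) -> list[TraitRecord]:
    """Label unknown-life-stage records against the adult limits (inclusive).

    Above the upper limit -> "outlier"; below the lower -> "possible
    juvenile"; within (bounds inclusive) -> "possible adult; possibly
    good". With no limits every record becomes "no adult reference".
    Records without a measurement value keep an empty status.
    """
    out = []
    for rec in records:
        if rec.measurement_value is None:
            out.append(rec)
            continue
        if lower is None or upper is None:
            out.append(replace(rec, measurement_status=STATUS_NO_ADULT_REF))
            continue
        v = rec.measurement_value
        if v > upper:
            status = STATUS_OUTLIER
        elif v < lower:
            status = STATUS_POSSIBLE_JUVENILE
        else:
            status = STATUS_POSSIBLE_ADULT
        out.append(replace(rec, measurement_status=status))
    return out


def _usable_adult(rec: TraitRecord) -> bool:
    # reference distribution: recorded (resolved) units and a value present
    return (
        rec.life_stage == "adult"
        and rec.measurement_value is not None
        and rec.unit_status == ""
    )


def clean_dataset(
    records: Sequence[TraitRecord],
    config: CleaningConfig = CleaningConfig(),
) -> tuple[list[TraitRecord], CleaningReport]:
    """Run the full gate -> outlier screen -> classify -> limits -> annotate
    routine per species x trait group.

    Output cardinality always equals input cardinality; the report's
    status counts sum to the input record count.
    """
    keep, gated = gate_min_records(records, config.min_records)
    report = CleaningReport()

    annotated: dict[str, TraitRecord] = {r.diagnostic_id: r for r in gated}

    gated_groups: dict[tuple[str, str], GroupSummary] = {}
    for rec in gated:
        key = _group_key(rec)
        g = gated_groups.setdefault(
            key, GroupSummary(key[0], key[1], 0, normality=NOT_ASSESSED)
        )
        g.n += 1
        g.status_counts[STATUS_TOO_FEW] += 1
    report.groups.extend(gated_groups.values())

    for (species, trait), members in keep.items():
        summary = GroupSummary(species, trait, len(members))
        adults = [r for r in members if _usable_adult(r)]
        juveniles = [r for r in members if r.life_stage == "juvenile"]
        unknowns = [
            r for r in members if r.life_stage not in ("adult", "juvenile")
        ]
        # adults with missing values / unresolved units are annotated but
        # excluded from the reference distribution
        excluded_adults = [
            r for r in members if r.life_stage == "adult" and not _usable_adult(r)
        ]

        out_members: list[TraitRecord] = []
        for rec in juveniles:
            out_members.append(replace(rec, measurement_status=STATUS_KNOWN_JUVENILE))

        use_fallback = not adults and config.no_adult_fallback
        reference = adults
        if use_fallback:
            reference = [
                r
                for r in unknowns
                if r.measurement_value is not None and r.unit_status == ""
            ]

        if not reference:
            out_members.extend(annotate_unknowns(unknowns, None, None))
            out_members.extend(
                replace(r, measurement_status=STATUS_NO_ADULT_REF)
                for r in excluded_adults
            )
            summary.normality = NOT_ASSESSED
        else:
            values = np.array([r.measurement_value for r in reference], dtype=float)
            mask = detect_adult_outliers(values, config.outlier_cutoff)
            clean_values = values[~mask]

            if clean_values.size == 0:
                dist_class = NOT_ASSESSED
                lower = upper = None
                lo_m = hi_m = ""
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dist_class = classify_distribution(
                        clean_values, config.normality_alpha, config.large_sample_switch
                    )
                lower, upper, lo_m, hi_m = compute_limits(
                    clean_values, dist_class, config
                )

            if use_fallback:
                # no labelled adults: the usable unknowns are both the
                # reference distribution and the set under assessment
                out_members.extend(annotate_unknowns(reference, lower, upper))
                out_members.extend(
                    annotate_unknowns(
                        [r for r in unknowns if r not in reference], lower, upper
                    )
                )
            else:
                for rec, is_outlier in zip(reference, mask):
                    out_members.append(
                        replace(
                            rec,
                            measurement_status=(
                                STATUS_OUTLIER if is_outlier else STATUS_KNOWN_ADULT
                            ),
                        )
                    )
                out_members.extend(annotate_unknowns(unknowns, lower, upper))
            out_members.extend(
                replace(r, measurement_status=STATUS_NO_ADULT_REF)
                for r in excluded_adults
            )

            summary.normality = dist_class
            summary.lower_limit = lower
            summary.upper_limit = upper
            summary.lower_limit_method = lo_m
            summary.upper_limit_method = hi_m

            # stamp group provenance onto every member
            out_members = [
                replace(
                    r,
                    normality=dist_class,
                    lower_limit=lower,
                    upper_limit=upper,
                    lower_limit_method=lo_m,
                    upper_limit_method=hi_m,
                )
                for r in out_members
            ]

        for rec in out_members:
            summary.status_counts[rec.measurement_status] += 1
            annotated[rec.diagnostic_id] = rec
        report.groups.append(summary)

    # input order preserved; output cardinality equals input cardinality
    ordered = [annotated[rec.diagnostic_id] for rec in records]
    return ordered, report
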