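"""Dynamically derived species trait summaries and literature-mean comparison.

Summaries are computed over records whose cleaning status is in a
configurable keep-set. Each derived mean is compared against a
species-level literature mean with a one-sample t statistic

    t = |reference mean - derived mean| / se

with df = n - 1, Benjamini-Hochberg adjustment across species, a signed
standard-error distance, and tallies by body-mass class of how many
literature means fall outside +/- 3 se.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from vertraits.cleaning import STATUS_KNOWN_ADULT, STATUS_POSSIBLE_ADULT
from vertraits.records import TraitRecord, normalize_binomial

__all__ = [
    "SpeciesSummary",
    "MeanComparison",
    "DEFAULT_KEEP_STATUSES",
    "MASS_BINS",
    "summarize_species",
    "compare_to_reference",
    "adjust_pvalues",
    "tally_from_counts",
    "tally_se_bins",
    "diagnostic_regressions",
    "comparisons_to_frame",
]

DEFAULT_KEEP_STATUSES = frozenset({STATUS_KNOWN_ADULT, STATUS_POSSIBLE_ADULT})

#: (label, lower inclusive, upper exclusive) in grams
MASS_BINS: tuple[tuple[str, float, float], ...] = (
    ("<100 g", 0.0, 100.0),
    ("100-1000 g", 100.0, 1000.0),
    ("1000-10,000 g", 1000.0, 10_000.0),
    ("10,000-100,000 g", 10_000.0, 100_000.0),
    (">=100,000 g", 100_000.0, math.inf),
)


@dataclass
class SpeciesSummary:
    scientific_name: str
    trait_term: str
    n: int
    mean: float
    sd: float
    se: float
    min: float
    max: float
    q05: float
    q50: float
    q95: float


@dataclass
class MeanComparison:
    scientific_name: str
    reference_mean: float
    derived_mean: float
    se: float
    n: int
    computable: bool = True
    t_stat: float = math.nan
    df: int = 0
    p_value: float = math.nan
    p_adjusted: float = math.nan
    signed_se_distance: float = math.nan
    mass_bin: str = ""
    verdict: str = ""


def summarize_species(
    records: Sequence[TraitRecord],
    keep_statuses: Iterable[str] = DEFAULT_KEEP_STATUSES,
) -> tuple[list[SpeciesSummary], list[tuple[str, str]]]:
    """One summary per species x trait over kept records.

    Returns (summaries, omitted) where ``omitted`` lists species x trait
    groups with zero kept records.
    """
    keep = set(keep_statuses)
    groups: dict[tuple[str, str], list[float]] = {}
    seen: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.scientific_name, rec.trait_term)
        if key not in groups:
            groups[key] = []
            seen.append(key)
        if rec.measurement_status in keep and rec.measurement_value is not None:
            groups[key].append(rec.measurement_value)

    summaries: list[SpeciesSummary] = []
    omitted: list[tuple[str, str]] = []
    for key in seen:
        values = np.asarray(groups[key], dtype=float)
        if values.size == 0:
            omitted.append(key)
            continue
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        q05, q50, q95 = np.quantile(values, [0.05, 0.50, 0.95])
        summaries.append(
            SpeciesSummary(
                scientific_name=key[0],
                trait_term=key[1],
                n=int(values.size),
                mean=float(values.mean()),
                sd=sd,
                se=sd / math.sqrt(values.size),
                min=float(values.min()),
                max=float(values.max()),
                q05=float(q05),
                q50=float(q50),
                q95=float(q95),
            )
        )
    return summaries, omitted


def mass_bin(mean_grams: float) -> str:
    for label, lo, hi in MASS_BINS:
        if lo <= mean_grams < hi:
            return label
    return ""


def adjust_pvalues(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_to_reference(
    summaries: Sequence[SpeciesSummary],
    reference: pd.DataFrame,
    se_threshold: float = 3.0,
) -> tuple[list[MeanComparison], list[str]]:
    """Compare derived means to a literature reference table (both in grams).

    ``reference`` needs columns ``species`` and ``meanBodyMass``, plus an
    optional ``unit`` column (``g`` assumed, ``kg`` converted). Matching is
    exact on the normalized binomial. Unmatched species are reported, not
    errors; n < 2 or se = 0 yields a not-computable comparison.
    """
    ref = reference.copy()
    ref["__species"] = ref["species"].map(normalize_binomial)
    if "unit" in ref.columns:
        factor = ref["unit"].map(lambda u: 1000.0 if str(u).strip().lower() == "kg" else 1.0)
    else:
        factor = 1.0
    ref["__mass_g"] = pd.to_numeric(ref["meanBodyMass"]) * factor
    lookup = dict(zip(ref["__species"], ref["__mass_g"]))

    comparisons: list[MeanComparison] = []
    unmatched: list[str] = []
    for summary in summaries:
        species = normalize_binomial(summary.scientific_name)
        if species not in lookup:
            unmatched.append(summary.scientific_name)
            continue
        ref_mean = float(lookup[species])
        comp = MeanComparison(
            scientific_name=summary.scientific_name,
            reference_mean=ref_mean,
            derived_mean=summary.mean,
            se=summary.se,
            n=summary.n,
            mass_bin=mass_bin(summary.mean),
        )
        if summary.n < 2 or summary.se <= 0:
            comp.computable = False
        else:
            d = (ref_mean - summary.mean) / summary.se
            comp.signed_se_distance = d
            comp.t_stat = abs(d)
            comp.df = summary.n - 1
            comp.p_value = 2.0 * stats.t.sf(comp.t_stat, df=comp.df)
            if d > se_threshold:
                comp.verdict = "above"
            elif d < -se_threshold:
                comp.verdict = "below"
            else:
                comp.verdict = "within"
        comparisons.append(comp)

    computable = [c for c in comparisons if c.computable]
    if computable:
        adjusted = adjust_pvalues([c.p_value for c in computable])
        for comp, padj in zip(computable, adjusted):
            comp.p_adjusted = float(padj)
    return comparisons, unmatched


def tally_from_counts(rows: Sequence[dict]) -> pd.DataFrame:
    """Percentage table from per-group counts.

    Each row needs keys ``group, n, within, outside, above, below``. The
    within/outside percentages are shares of that group's N; the
    above/below percentages are shares of that group's outside count
    (blank when outside is zero). Group-N percentages are shares of the
    first ("All") row's N.
    """
    total_n = rows[0]["n"] if rows else 0
    out = []
    for row in rows:
        n, within, outside = row["n"], row["within"], row["outside"]
        above, below = row["above"], row["below"]
        out.append(
            {
                "group": row["group"],
                "n": n,
                "nPct": 100.0 * n / total_n if total_n else math.nan,
                "within": within,
                "withinPct": 100.0 * within / n if n else math.nan,
                "outside": outside,
                "outsidePct": 100.0 * outside / n if n else math.nan,
                "above": above,
                "abovePct": 100.0 * above / outside if outside else math.nan,
                "below": below,
                "belowPct": 100.0 * below / outside if outside else math.nan,
            }
        )
    return pd.DataFrame(out)


def tally_se_bins(
    comparisons: Sequence[MeanComparison],
    threshold: float = 3.0,
    bins: Sequence[tuple[str, float, float]] = MASS_BINS,
) -> pd.DataFrame:
    """Tally how many reference means fall outside +/- threshold se, overall
    and per body-mass class of the derived mean."""
    usable = [c for c in comparisons if c.computable]

    def count(members: Sequence[MeanComparison], label: str) -> dict:
        d = np.array([c.signed_se_distance for c in members])
        above = int(np.sum(d > threshold))
        below = int(np.sum(d < -threshold))
        return {
            "group": label,
            "n": len(members),
            "within": len(members) - above - below,
            "outside": above + below,
            "above": above,
            "below": below,
        }

    rows = [count(usable, "All")]
    for label, lo, hi in bins:
        members = [c for c in usable if lo <= c.derived_mean < hi]
        rows.append(count(members, label))
    return tally_from_counts(rows)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    computable: bool = True


def diagnostic_regressions(
    comparisons: Sequence[MeanComparison],
) -> dict[str, RegressionResult]:
    """OLS of |reference mean - derived mean| on sample size and on the
    derived mean (sampling-artefact diagnostics)."""
    usable = [c for c in comparisons if c.computable]
    if len(usable) < 3:
        raise ValueError("diagnostic regressions need at least 3 comparisons")
    y = np.array([abs(c.reference_mean - c.derived_mean) for c in usable])
    out: dict[str, RegressionResult] = {}
    for name, x in (
        ("vs_n", np.array([c.n for c in usable], dtype=float)),
        ("vs_mass", np.array([c.derived_mean for c in usable])),
    ):
        if np.ptp(x) == 0:
            out[name] = RegressionResult(math.nan, math.nan, math.nan, math.nan, False)
            continue
        fit = stats.linregress(x, y)
        out[name] = RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            p_value=float(fit.pvalue),
            r_squared=float(fit.rvalue**2),
        )
    return out


def comparisons_to_frame(comparisons: Sequence[MeanComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scientificName": c.scientific_name,
                "referenceMean": c.reference_mean,
                "derivedMean": c.derived_mean,
                "se": c.se,
                "n": c.n,
                "computable": c.computable,
                "tStat": c.t_stat,
                "df": c.df,
                "pValue": c.p_value,
                "pAdjusted": c.p_adjusted,
                "signedSeDistance": c.signed_se_distance,
                "massBin": c.mass_bin,
                "verdict": c.verdict,
            }
            for c in comparisons
        ]
    )
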