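import numpy as np
import pytest

from vertraits import cleaning, synthetic
from vertraits.records import TraitRecord, TraitTermMap, UnitRegistry


@pytest.fixture(scope="session")
def term_map() -> TraitTermMap:
    return TraitTermMap.default()


@pytest.fixture(scope="session")
def unit_registry() -> UnitRegistry:
    return UnitRegistry.default()


def make_record(i: int, value: float | None = 10.0, **overrides) -> TraitRecord:
    base = dict(
        diagnostic_id=f"d{i:04d}",
        material_sample_id=f"ms{i:04d}",
        scientific_name="Testus exemplaris",
        trait_term="body mass",
        trait_iri="OBA:VT0001259",
        measurement_value=value,
        measurement_unit="g",
        verbatim_value="" if value is None else repr(float(value)),
        verbatim_unit="g",
        life_stage="adult",
        year_collected=2000,
    )
    base.update(overrides)
    return TraitRecord(**base)


def make_group(values, life_stage="adult", start=0, **overrides):
    return [
        make_record(start + i, float(v), life_stage=life_stage, **overrides)
        for i, v in enumerate(values)
    ]


@pytest.fixture(scope="session")
def squirrel_fixture():
    """28 labelled adults, 194 unknown-stage adults, 11 unknown-stage
    juveniles; seed chosen so that the whole unknown-adult block falls
    inside the derived limits (verified against the direct-comparison
    oracle in the tests that use this fixture)."""
    spec = synthetic.PopulationSpec(seed=17)
    records, truth = synthetic.gen_population(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def cleaned_squirrel(squirrel_fixture):
    _, records, _ = squirrel_fixture
    return cleaning.clean_dataset(records)


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adjusted = ranked * m / (np.arange(m) + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def ols_normal_equations(lx, ly):
    """Closed-form simple OLS oracle: slope, intercept, se_slope,
    se_intercept, se_residuals, r_squared on already-logged data."""
    lx = np.asarray(lx, float)
    ly = np.asarray(ly, float)
    n = lx.size
    sxx = np.sum((lx - lx.mean()) ** 2)
    sxy = np.sum((lx - lx.mean()) * (ly - ly.mean()))
    slope = sxy / sxx
    intercept = ly.mean() - slope * lx.mean()
    resid = ly - intercept - slope * lx
    ssr = np.sum(resid**2)
    se_res = np.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    se_slope = se_res / np.sqrt(sxx)
    se_intercept = se_res * np.sqrt(1.0 / n + lx.mean() ** 2 / sxx)
    syy = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ssr / syy if syy > 0 else 1.0
    return slope, intercept, se_slope, se_intercept, se_res, r2
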