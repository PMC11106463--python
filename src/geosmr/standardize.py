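"""Indirect standardization: expected deaths, SMR, and outlier flagging.

Expected deaths apply the reference (national) age-specific rates to each
region's own age pyramid; the SMR is observed over expected. A useful
algebraic identity: when the reference rates are derived from the pooled
study regions themselves, total expected equals total observed exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .types import RegionTable, SMRTable


def expected_deaths(population: np.ndarray, national_rates: np.ndarray) -> np.ndarray:
    """E_i = sum_a pop_{i,a} * rate_a.

    ``population`` is (n_regions, n_age_classes); ``national_rates`` is
    (n_age_classes,) in deaths per person-year.
    """
    population = np.asarray(population, dtype=float)
    rates = np.asarray(national_rates, dtype=float)
    if population.ndim != 2 or population.shape[1] != len(rates):
        raise InvalidInputError(
            f"age axes mismatch: population has {population.shape[-1]} classes, "
            f"rates have {len(rates)}"
        )
    if np.any(population < 0):
        raise InvalidInputError("negative population")
    return population @ rates


def pooled_rates(population: np.ndarray, observed: np.ndarray, age_deaths: np.ndarray) -> np.ndarray:
    """Reference rates from the pooled regions: deaths_a / pop_a per age class."""
    pop_a = np.asarray(population, dtype=float).sum(axis=0)
    if np.any(pop_a <= 0):
        raise InvalidInputError("pooled population must be positive in every age class")
    return np.asarray(age_deaths, dtype=float) / pop_a


def smr(observed: np.ndarray, expected: np.ndarray, region_ids=None) -> np.ndarray:
    """SMR = observed / expected, elementwise; expected must be positive."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    bad = expected <= 0
    if np.any(bad):
        idx = np.argwhere(bad).ravel()
        name = region_ids[idx[0]] if region_ids is not None else idx[0]
        raise InvalidInputError(f"non-positive expected deaths for region {name!r}")
    return observed / expected


def flag_outliers(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Tukey-fence outlier flags: outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation. Needs >= 4 values for stable
    quartiles.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise InvalidInputError("need >= 4 values to estimate quartiles")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def build_smr_table(
    regions: RegionTable, national_rates: np.ndarray, outlier_k: float = 1.5
) -> SMRTable:
    """Observed, expected, SMR and outlier flag per region.

    Flagged regions are retained in the table (auditable exclusion); callers
    drop them from modelling via :meth:`SMRTable.retained`.
    """
    regions.validate()
    expected = expected_deaths(regions.population, national_rates)
    ratio = smr(regions.observed_deaths, expected, regions.region_ids)
    flags = flag_outliers(ratio, k=outlier_k)
    frame = pd.DataFrame(
        {
            "region_id": regions.region_ids,
            "observed": regions.observed_deaths,
            "expected": expected,
            "smr": ratio,
            "outlier": flags,
        }
    )
    return SMRTable(frame=frame)
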