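"""Experimental reference dataset and benchmark statistics.

The embedded dataset collects literature aqueous pKa values for ten
para-substituted aniline radical cations (R-PhNH2^.+ -> R-PhNH^. + H+) and
the corresponding anilinium ions (R-PhNH3^+ -> R-PhNH2 + H+).  Where several
literature determinations exist for one compound they are kept as a list and
the arithmetic mean is used as the reference value.

Evaluation statistics mirror standard pKa-benchmark practice:

* per-compound absolute deviation  delta = |pKa_calc - pKa_exp|
* RMSE = sqrt( sum (pKa_calc,i - pKa_exp,i)^2 / n )
* RMSE_aver ± RMSE_std across method/approach/protocol combinations
* ordinary least squares of calculated (y) on experimental (x) pKa,
  reporting slope S, intercept I, and r^2 (squared Pearson correlation);
  an accurate method gives S close to 1 and I close to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BenchmarkError

RADICAL_CATION = "radical_cation"
ANILINIUM = "anilinium"

SUBSTITUENTS = ("H", "C4H9", "CF3", "CH3", "OCH3", "CN", "COCH3", "I", "NH2", "SO3-")


@dataclass(frozen=True)
class ExperimentalEntry:
    """One compound's literature pKa value(s) for one system."""

    substituent: str
    system: str  # RADICAL_CATION | ANILINIUM
    values: tuple[float, ...]
    reference_tags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.values:
            raise BenchmarkError(
                f"{self.substituent}/{self.system}: empty value list"
            )

    @property
    def averaged(self) -> float:
        return average_experimental_pka(self.values)


# Literature pKa values; multi-valued entries are averaged.
_RADICAL_CATION_DATA = {
    "H": ([7.05], ["B35"]),
    "C4H9": ([8.2], ["B7"]),
    "CF3": ([4.8], ["B7"]),
    "CH3": ([8.5], ["B36"]),
    "OCH3": ([9.6], ["B7"]),
    "CN": ([4.0], ["B7"]),
    "COCH3": ([6.1], ["B7"]),
    "I": ([7.1], ["B7"]),
    "NH2": ([12.0], ["B7"]),
    "SO3-": ([5.8], ["B7"]),
}

_ANILINIUM_DATA = {
    "H": ([4.62, 4.58], ["B37", "B38"]),
    "C4H9": ([4.95], ["B34"]),
    "CF3": ([2.92, 2.75, 2.57], ["B39", "B40", "B41"]),
    "CH3": ([5.12], ["B37"]),
    "OCH3": ([5.29], ["B37"]),
    "CN": ([1.75, 1.82], ["B42", "B43"]),
    "COCH3": ([2.19, 2.26], ["B42", "B43"]),
    "I": ([3.78], ["B44"]),
    "NH2": ([5.94, 6.2], ["B45", "B42"]),
    "SO3-": ([3.25, 2.93, 3.32], ["B46", "B47", "B48"]),
}


def load_experimental_table() -> list[ExperimentalEntry]:
    """The embedded experimental dataset: 10 substituents x 2 systems."""
    entries = []
    for system, data in ((RADICAL_CATION, _RADICAL_CATION_DATA),
                         (ANILINIUM, _ANILINIUM_DATA)):
        for sub in SUBSTITUENTS:
            values, refs = data[sub]
            entries.append(
                ExperimentalEntry(sub, system, tuple(values), tuple(refs))
            )
    return entries


def experimental_entry(substituent: str, system: str) -> ExperimentalEntry:
    for entry in load_experimental_table():
        if entry.substituent == substituent and entry.system == system:
            return entry
    raise BenchmarkError(f"no experimental entry for {substituent}/{system}")


def average_experimental_pka(values: Iterable[float]) -> float:
    """Arithmetic mean of the literature values for one compound."""
    values = list(values)
    if not values:
        raise BenchmarkError("cannot average an empty value list")
    return float(sum(values)) / len(values)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def rmse(calc: Iterable[float], exp: Iterable[float]) -> float:
    """Root-mean-square error between paired calculated/experimental values."""
    calc = np.asarray(list(calc), dtype=float)
    exp = np.asarray(list(exp), dtype=float)
    if calc.shape != exp.shape or calc.size == 0:
        raise BenchmarkError(
            f"rmse needs equal nonzero lengths, got {calc.size} and {exp.size}"
        )
    return float(np.sqrt(np.mean((calc - exp) ** 2)))


def rmse_aggregate(
    rmse_values: Iterable[float], ddof: int = 1
) -> tuple[float, float]:
    """Mean and standard deviation of RMSEs across method combinations.

    Sample (n-1) standard deviation by default; ``ddof=0`` selects the
    population variant.  A single value has zero spread by convention.
    """
    values = np.asarray(list(rmse_values), dtype=float)
    if values.size == 0:
        raise BenchmarkError("rmse_aggregate needs at least one value")
    mean = float(values.mean())
    std = 0.0 if values.size <= ddof else float(values.std(ddof=ddof))
    return mean, std


def regression_calc_vs_exp(
    calc: Iterable[float], exp: Iterable[float]
) -> tuple[float, float, float]:
    """OLS of calculated pKa (response) on experimental pKa (predictor).

    Returns (slope S, intercept I, r^2).
    """
    calc = np.asarray(list(calc), dtype=float)
    exp = np.asarray(list(exp), dtype=float)
    if calc.shape != exp.shape or calc.size < 3:
        raise BenchmarkError("regression needs >= 3 paired points")
    if np.ptp(exp) == 0:
        raise BenchmarkError("experimental values have zero variance")
    fit = stats.linregress(exp, calc)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


@dataclass
class BenchmarkReport:
    """Per-compound deviations plus summary statistics for one combination
    of approach / correction scheme / protocol / water model."""

    per_compound: pd.DataFrame  # substituent, system, pKa_exp, pKa_calc, delta
    rmse: float
    delta_mean: float
    delta_min: float
    delta_max: float
    slope: float
    intercept: float
    r_squared: float
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n": int(len(self.per_compound)),
            "rmse": self.rmse,
            "delta_mean": self.delta_mean,
            "delta_min": self.delta_min,
            "delta_max": self.delta_max,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            **self.metadata,
        }

    def to_csv(self, path) -> None:
        frame = self.per_compound.copy()
        for key, value in self.summary().items():
            frame.attrs[key] = value
        with open(path, "w") as fh:
            frame.to_csv(fh, index=False)
            fh.write("\n# summary\n")
            for key, value in self.summary().items():
                fh.write(f"# {key},{value}\n")


def _normalize_results(
    results: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
) -> dict[tuple[str, str], float]:
    if isinstance(results, Mapping):
        items = [(sub, system, pka) for (sub, system), pka in results.items()]
    else:
        items = [tuple(item) for item in results]
    out: dict[tuple[str, str], float] = {}
    for sub, system, pka in items:
        key = (sub, system)
        if key in out:
            raise BenchmarkError(f"duplicate result for {sub}/{system}")
        pka = getattr(pka, "pka", pka)  # accept PkaResult or float
        out[key] = float(pka)
    return out


def benchmark_run(
    results: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]],
    table: list[ExperimentalEntry] | None = None,
    metadata: dict | None = None,
) -> BenchmarkReport:
    """Match calculated pKa values against the experimental table and compute
    per-compound deviations, RMSE, and the calculated-vs-experimental
    regression.

    ``results`` maps (substituent, system) to a pKa value (or PkaResult);
    every key must match exactly one experimental entry.
    """
    table = table if table is not None else load_experimental_table()
    lookup = {(e.substituent, e.system): e for e in table}
    normalized = _normalize_results(results)
    if not normalized:
        raise BenchmarkError("no results supplied")

    rows = []
    for (sub, system), pka_calc in normalized.items():
        if (sub, system) not in lookup:
            raise BenchmarkError(
                f"result {sub}/{system} matches no experimental entry"
            )
        entry = lookup[(sub, system)]
        pka_exp = entry.averaged
        rows.append(
            {
                "substituent": sub,
                "system": system,
                "pKa_exp": pka_exp,
                "pKa_calc": pka_calc,
                "delta": abs(pka_calc - pka_exp),
            }
        )
    frame = pd.DataFrame(rows).sort_values(["system", "substituent"])
    frame = frame.reset_index(drop=True)

    calc = frame["pKa_calc"].to_numpy()
    exp = frame["pKa_exp"].to_numpy()
    slope, intercept, r2 = (
        regression_calc_vs_exp(calc, exp)
        if len(frame) >= 3
        else (math.nan, math.nan, math.nan)
    )
    return BenchmarkReport(
        per_compound=frame,
        rmse=rmse(calc, exp),
        delta_mean=float(frame["delta"].mean()),
        delta_min=float(frame["delta"].min()),
        delta_max=float(frame["delta"].max()),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        metadata=dict(metadata or {}),
    )
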