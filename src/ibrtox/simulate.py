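"""Seeded synthetic exposure-study generator.

Emulates the statistical design the downstream analysis assumes: 4 treatment
groups (a control plus 0.5, 5 and 25 mg/L of a water-soluble polymer),
sampling after 10 and 20 days, three tissues assayed for four oxidative-stress
biomarkers, and hemolymph/hepatopancreas cell-viability percentages.

Biomarker values are lognormal (positive, right-skewed) with multiplicative
dose- and time-dependent effects:

    value = baseline * exp(dose_slope * g(day) * log1p(dose) + eps),
    eps ~ Normal(0, sigma),  sigma = sqrt(ln(1 + cv^2)),
    g(10) = 1, g(20) = day_gain.

Dose enters through log1p so the control (dose 0) sits exactly at its
baseline in expectation — a clean null. Every (tissue, treatment, day,
biomarker) cell draws from its own deterministic substream keyed on the cell
and the shared seed, so adding cells never perturbs existing cells' draws and
an identical seed reproduces the table byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    ASSAYS,
    BIOMARKERS,
    COMPARTMENTS,
    DAYS,
    DOSES,
    TISSUES,
    TREATMENTS,
    UNITS,
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: Control geometric means per (tissue, biomarker), in each biomarker's
#: declared unit. Magnitudes are typical of protein-normalised crustacean
#: tissue assays: SOD in units/mg, GPx in nmol/(mg*min), GST in
#: nmol/(ug*min), MDA in umol/mg, with the digestive gland richest in
#: conjugation activity and gills in dismutase activity.
DEFAULT_BASELINES: dict[tuple[str, str], float] = {
    ("gills", "SOD"): 14.0,
    ("gills", "GPx"): 6.0,
    ("gills", "GST"): 0.08,
    ("gills", "MDA"): 0.45,
    ("hepatopancreas", "SOD"): 10.0,
    ("hepatopancreas", "GPx"): 9.0,
    ("hepatopancreas", "GST"): 0.20,
    ("hepatopancreas", "MDA"): 0.60,
    ("muscle", "SOD"): 7.0,
    ("muscle", "GPx"): 4.0,
    ("muscle", "GST"): 0.05,
    ("muscle", "MDA"): 0.30,
}


@dataclass
class EffectConfig:
    """Generative parameters of the biomarker study.

    Parameters
    ----------
    baseline : mapping (tissue, biomarker) -> float
        Control geometric mean of each cell, in declared units.
    cv : float or mapping
        Lognormal coefficient of variation of individual animals; 0.25 is a
        typical between-animal CV for enzyme activities. cv = 0 selects the
        exact noise-free mode (every value sits on its cell's geometric
        mean), used for deterministic monotonicity checks. Note the index's
        scale invariance means a *small* cv does not approximate cv = 0.
    dose_slope : float or mapping
        Effect per unit log1p(dose) on the log scale. The default 0.21
        roughly doubles a responsive biomarker at the top dose (25 mg/L,
        log1p = 3.26) after 10 days.
    day_gain : float or mapping
        Multiplier on dose_slope at day 20 vs day 10 (time-dependence);
        1.5 intensifies effects with exposure duration.
    n_per_cell : int
        Animals per (treatment, day) group; 7 reads a 15-crab treatment
        group conservatively split over the two sampling days.
    seed : int
        Shared seed for all substreams.
    """

    baseline: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    cv: float | Mapping[tuple[str, str], float] = 0.25
    dose_slope: float | Mapping[tuple[str, str], float] = 0.21
    day_gain: float | Mapping[tuple[str, str], float] = 1.5
    n_per_cell: int = 7
    seed: int = 0

    def __post_init__(self):
        for key, b in dict(self.baseline).items():
            if not b > 0:
                raise ConfigError(f"baseline must be > 0, got {b!r} for {key}")
        for cell in ((t, b) for t in TISSUES for b in BIOMARKERS):
            if not self._get(self.cv, cell) >= 0:
                raise ConfigError(f"cv must be >= 0 for {cell}")
        if int(self.n_per_cell) < 2:
            raise ConfigError("n_per_cell must be >= 2")

    @staticmethod
    def _get(param, cell):
        if isinstance(param, Mapping):
            return float(param[cell])
        return float(param)

    def lookup(self, name: str, tissue: str, biomarker: str) -> float:
        return self._get(getattr(self, name), (tissue, biomarker))


def _subject_id(treatment: str, day: int, index: int) -> str:
    return f"{treatment}-d{day}-{index + 1:02d}"


def generate_study(config: EffectConfig) -> pd.DataFrame:
    """Generate a full factorial biomarker table under ``config``.

    Returns a validated long-format table (same columns as
    :func:`ibrtox.data.read_biomarker_table`). Deterministic in
    ``config.seed``.
    """
    n = int(config.n_per_cell)
    rows = []
    for ti, tissue in enumerate(TISSUES):
        for ri, treatment in enumerate(TREATMENTS):
            for di, day in enumerate(DAYS):
                for bi, biomarker in enumerate(BIOMARKERS):
                    rng = np.random.default_rng((int(config.seed), ti, ri, di, bi))
                    base = config.lookup("baseline", tissue, biomarker)
                    cv = config.lookup("cv", tissue, biomarker)
                    slope = config.lookup("dose_slope", tissue, biomarker)
                    gain = config.lookup("day_gain", tissue, biomarker)
                    g = 1.0 if day == DAYS[0] else gain
                    sigma = np.sqrt(np.log1p(cv**2))
                    eps = rng.normal(0.0, sigma, size=n)
                    values = base * np.exp(slope * g * np.log1p(DOSES[treatment]) + eps)
                    for i in range(n):
                        rows.append(
                            (
                                _subject_id(treatment, day, i),
                                tissue,
                                treatment,
                                day,
                                biomarker,
                                float(values[i]),
                                UNITS[biomarker],
                                DOSES[treatment],
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "tissue", "treatment", "day", "biomarker", "value", "unit", "dose"],
    )


#: Default (mean, sd) of percent-viable cells per (compartment, assay,
#: treatment, day). Hemolymph stays above 99% throughout; hepatopancreas
#: shows the dose- and time-dependent declines of the reference study,
#: strongest in the Neutral Red (lysosomal) assay.
DEFAULT_VIABILITY: dict[tuple[str, str, str, int], tuple[float, float]] = {}
for _assay in ASSAYS:
    for _treat in TREATMENTS:
        for _day in DAYS:
            DEFAULT_VIABILITY[("hemolymph", _assay, _treat, _day)] = (99.4, 0.4)
for _day in DAYS:
    DEFAULT_VIABILITY[("hepatopancreas", "NR", "CTRL", _day)] = (99.0, 0.8)
    DEFAULT_VIABILITY[("hepatopancreas", "TB", "CTRL", _day)] = (99.2, 0.6)
DEFAULT_VIABILITY.update(
    {
        ("hepatopancreas", "NR", "C1", 10): (97.5, 1.5),
        ("hepatopancreas", "NR", "C2", 10): (95.5, 2.5),
        ("hepatopancreas", "NR", "C3", 10): (85.46, 5.84),
        ("hepatopancreas", "TB", "C1", 10): (98.5, 1.0),
        ("hepatopancreas", "TB", "C2", 10): (96.5, 2.0),
        ("hepatopancreas", "TB", "C3", 10): (93.0, 3.0),
        ("hepatopancreas", "NR", "C1", 20): (95.0, 2.5),
        ("hepatopancreas", "NR", "C2", 20): (69.90, 9.30),
        ("hepatopancreas", "NR", "C3", 20): (79.90, 4.83),
        ("hepatopancreas", "TB", "C1", 20): (96.5, 2.0),
        ("hepatopancreas", "TB", "C2", 20): (90.0, 4.0),
        ("hepatopancreas", "TB", "C3", 20): (88.0, 4.0),
    }
)


@dataclass
class ViabilityConfig:
    """Truncated-normal model of percent-viable cells on [0, 100]."""

    cells: Mapping[tuple[str, str, str, int], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VIABILITY)
    )
    n_per_cell: int = 7

    def __post_init__(self):
        for key, (mean, sd) in dict(self.cells).items():
            if not (0.0 < mean <= 100.0):
                raise ConfigError(f"viability mean must lie in (0, 100], got {mean!r} for {key}")
            if sd < 0:
                raise ConfigError(f"viability sd must be >= 0, got {sd!r} for {key}")
        if int(self.n_per_cell) < 1:
            raise ConfigError("n_per_cell must be >= 1")


def generate_viability(config: ViabilityConfig, seed: int) -> pd.DataFrame:
    """Draw viability records; sd = 0 cells are deterministic at their mean.

    Subject ids match :func:`generate_study` for the same ``n_per_cell`` so
    viability can be joined to biomarker rows animal-by-animal.
    """
    rows = []
    n = int(config.n_per_cell)
    for ci, compartment in enumerate(COMPARTMENTS):
        for ai, assay in enumerate(ASSAYS):
            for ri, treatment in enumerate(TREATMENTS):
                for di, day in enumerate(DAYS):
                    key = (compartment, assay, treatment, day)
                    if key not in config.cells:
                        continue
                    mean, sd = config.cells[key]
                    rng = np.random.default_rng((int(seed), 1000 + ci, ai, ri, di))
                    if sd == 0:
                        draws = np.full(n, mean)
                    else:
                        a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
                        draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
                    for i in range(n):
                        rows.append(
                            (_subject_id(treatment, day, i), compartment, assay, treatment, day, float(draws[i]))
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "compartment", "assay", "treatment", "day", "percent_viable"],
    )
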