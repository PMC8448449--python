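"""Clonal population synthesis: growth rates, morphology, drug response.

Each apartment founds a clone whose cell count follows exponential growth
with base 2, ``p(t) = p0 * 2**(lambda * t)`` with ``lambda`` in divisions
per day and ``t`` in days.  Clone-level growth rates are drawn from a
cohort-specific distribution; a small resistant subpopulation keeps its
drug-free growth distribution under treatment, and a rare subset of clones
has substantially larger cells.  Counts are integerized by
expectation-preserving stochastic rounding (emulating asynchronous
divisions); clones whose count decays to zero are removed, as dead cells
are flushed out under continuous perfusion.  Counts saturate at the
apartment carrying capacity, which emulates under-counting in crowded
apartments and makes fitted growth rates a lower bound there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClonePopulationSpec", "sample_clone_population", "COHORT_PRESETS"]

#: growth/area presets per drug cohort (divisions/day medians and IQRs for
#: an FLT3-ITD AML line under the FLT3 inhibitor; areas in um^2)
COHORT_PRESETS = {
    "DMSO": dict(growth_median=0.95, growth_sigma=0.2075, area_median=137.0, area_sigma=0.0873),
    "0.5nM": dict(growth_median=0.55, growth_sigma=0.40, area_median=126.0, area_sigma=0.0825),
    "1.5nM": dict(growth_median=-0.20, growth_sigma=0.35, area_median=120.0, area_sigma=0.0825),
}


@dataclass(frozen=True)
class ClonePopulationSpec:
    """Parameters of one synthetic clone population (one cohort/chip).

    ``growth_median``/``growth_sigma`` parameterize a normal distribution of
    clone division rates (divisions/day; negative rates model dying
    clones).  ``resistant_fraction`` of clones instead draw their rate from
    the drug-free (``resistant_*``) distribution regardless of cohort.
    ``large_cell_fraction`` of clones carry cells ``large_area_multiplier``
    times the median area.  Areas are lognormal around ``area_median`` um^2;
    eccentricities are Beta-distributed on [0, 1).  ``drug_effect``
    multiplies sensitive clones' growth rates (1.0 = no drug).
    """

    n_clones: int = 1000
    growth_median: float = 0.95
    growth_sigma: float = 0.2075
    drug_effect: float = 1.0
    resistant_fraction: float = 0.0005
    resistant_growth_median: float = 0.95
    resistant_growth_sigma: float = 0.2075
    large_cell_fraction: float = 0.0005
    area_median: float = 137.0
    area_sigma: float = 0.0873       # lognormal sigma (natural log)
    large_area_multiplier: float = 2.5
    ecc_alpha: float = 2.0
    ecc_beta: float = 3.0
    ecc_max: float = 0.75
    founding_count: int = 1
    capacity: int = 40
    count_noise_sigma: float = 0.0   # multiplicative lognormal noise on p(t)
    integerize: str = "stochastic"   # "stochastic" | "round"
    cohort: str = "DMSO"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resistant_fraction", "large_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.area_median <= 0 or self.large_area_multiplier <= 0:
            raise ValueError("areas must be positive")
        if self.n_clones < 0 or self.founding_count < 1 or self.capacity < 1:
            raise ValueError("counts must be positive")
        if self.integerize not in ("stochastic", "round"):
            raise ValueError("integerize must be 'stochastic' or 'round'")

    @classmethod
    def from_preset(cls, cohort: str, **overrides) -> "ClonePopulationSpec":
        preset = COHORT_PRESETS[cohort]
        kw = dict(cohort=cohort, **preset)
        kw.update(overrides)
        return cls(**kw)


def _integerize(p: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "round":
        return np.round(p)
    floor = np.floor(p)
    return floor + (rng.random(p.shape) < (p - floor))


def sample_clone_population(spec: ClonePopulationSpec,
                            timepoints: np.ndarray | list[float] | None = None,
                            seed: int | None = None,
                            founding_counts: np.ndarray | None = None) -> pd.DataFrame:
    """Draw a clone table with per-timepoint ground-truth counts.

    Returns one row per clone with columns ``clone_id``, ``lam`` (the true
    division rate after any drug effect), ``resistant``, ``large_cell``,
    ``area_um2`` (clone median cell area), ``ecc`` (clone mean
    eccentricity), ``intensity_nuclear``/``intensity_surface`` (clone mean
    stain brightness, arbitrary units), ``cohort`` and ``count_t{k}`` for
    each timepoint (days).  Once a clone's count reaches zero it stays zero
    (dead cells are washed out).
    """
    t = np.asarray([0.0, 1.0, 2.0, 3.0, 4.0] if timepoints is None else timepoints, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_clones

    resistant = rng.random(n) < spec.resistant_fraction
    lam = spec.growth_median + spec.growth_sigma * rng.standard_normal(n)
    lam *= spec.drug_effect
    lam_res = (spec.resistant_growth_median
               + spec.resistant_growth_sigma * rng.standard_normal(n))
    lam = np.where(resistant, lam_res, lam)

    large = rng.random(n) < spec.large_cell_fraction
    area = spec.area_median * np.exp(spec.area_sigma * rng.standard_normal(n))
    area = np.where(large, area * spec.large_area_multiplier, area)
    ecc = spec.ecc_max * rng.beta(spec.ecc_alpha, spec.ecc_beta, size=n)
    inten_nuc = rng.normal(0.55, 0.08, size=n).clip(0.2, 0.95)
    inten_surf = rng.normal(0.45, 0.10, size=n).clip(0.1, 0.9)

    if founding_counts is not None:
        p0 = np.asarray(founding_counts, dtype=float)
        if p0.shape != (n,) or np.any(p0 < 0):
            raise ValueError("founding_counts must be non-negative, one per clone")
    else:
        p0 = np.full(n, float(spec.founding_count))
    expected = p0[:, None] * np.power(2.0, np.outer(lam, t))
    if spec.count_noise_sigma > 0:
        expected = expected * np.exp(
            spec.count_noise_sigma * rng.standard_normal(expected.shape))
    counts = _integerize(expected, spec.integerize, rng)
    counts = np.clip(counts, 0, spec.capacity)
    # a clone that dies out stays out under perfusion
    dead = np.minimum.accumulate(counts > 0, axis=1) == 0
    counts[dead] = 0
    counts[:, t == 0.0] = p0[:, None]  # founding count is observed, not modeled

    table = pd.DataFrame({
        "clone_id": np.arange(n),
        "p0": p0.astype(int),
        "lam": lam,
        "resistant": resistant,
        "large_cell": large,
        "area_um2": area,
        "ecc": ecc,
        "intensity_nuclear": inten_nuc,
        "intensity_surface": inten_surf,
        "cohort": spec.cohort,
    })
    for k, day in enumerate(t):
        table[f"count_t{k}"] = counts[:, k].astype(int)
    table.attrs["timepoints"] = t.tolist()
    return table
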