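"""Clonal growth statistics: trajectories, fits, cohorts, rare phenotypes.

Per-apartment cell counts over time are modelled as exponential growth with
base 2, ``p(t) = p0 * 2**(lam * t)``, where ``lam`` is the cell division
rate in divisions per day and ``t`` is time in days.  Analyses are limited
to apartments that start from a single cell and keep at least one cell at
every timepoint; ``lam`` is then the ordinary-least-squares slope of
``log2(count)`` against time.  The model deliberately ignores hysteresis,
and fitted rates on crowded (capacity-saturated) apartments are a lower
bound, because crowded apartments under-report their counts.

Cohorts (drug conditions) are compared with a subsampled permutation test
on the difference of cohort medians, and rare large-cell clones are
flagged by a robust (median/MAD) z-score on the time-averaged mean cell
area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CloneTrajectory",
    "GrowthFit",
    "CohortSummary",
    "assemble_trajectories",
    "trajectories_from_ground_truth",
    "filter_trajectories",
    "fit_growth",
    "cohort_summary",
    "resample_pvalue",
    "detect_rare_large",
    "occupancy_heatmap",
    "fits_to_frame",
]


@dataclass
class CloneTrajectory:
    """Per-apartment time series of counts and mean morphology."""

    street: int
    position: int
    timepoints: np.ndarray
    counts: np.ndarray
    mean_area: np.ndarray          # um^2 per timepoint (NaN where no cells)
    mean_ecc: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.mean_area = np.asarray(self.mean_area, dtype=float)
        self.mean_ecc = np.asarray(self.mean_ecc, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (len(self.timepoints) == len(self.counts)
                == len(self.mean_area) == len(self.mean_ecc)):
            raise ValueError("trajectory series must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class GrowthFit:
    """Fitted exponential growth of one clone."""

    street: int
    position: int
    lam: float                     # divisions/day
    p0: float
    r_squared: float
    time_avg_area: float           # um^2, equal weight per timepoint
    time_avg_ecc: float
    cohort: str = ""


@dataclass
class CohortSummary:
    """Distributional summary of one cohort's growth fits."""

    n: int
    median_lam: float
    lam_q1: float
    lam_q3: float
    max_lam: float
    median_area: float
    area_q1: float
    area_q3: float


def assemble_trajectories(detections: pd.DataFrame,
                          cohort: str = "") -> list[CloneTrajectory]:
    """Join a detection table into per-apartment trajectories.

    Counts per timepoint are the number of detection rows for that address;
    a timepoint with no detections anywhere in the table still appears in
    every trajectory with count zero.  The same (street, position,
    timepoint) must not be contributed by two different fields of view.
    """
    required = {"street", "position", "timepoint"}
    missing = required - set(detections.columns)
    if missing:
        raise ValueError(f"detection table lacks columns {sorted(missing)}")
    if "fov" in detections.columns and len(detections):
        fovs = detections.groupby(["street", "position", "timepoint"])["fov"].nunique()
        dup = fovs[fovs > 1]
        if len(dup):
            raise ValueError(
                f"conflicting fields of view for {list(dup.index[:3])}")
    timepoints = np.array(sorted(detections["timepoint"].unique()))
    out = []
    for (street, position), grp in detections.groupby(["street", "position"]):
        counts, areas, eccs = [], [], []
        for t in timepoints:
            sub = grp[grp["timepoint"] == t]
            counts.append(len(sub))
            areas.append(sub["area_um2"].mean() if len(sub) else np.nan)
            eccs.append(sub["eccentricity"].mean() if len(sub) else np.nan)
        out.append(CloneTrajectory(
            street=int(street), position=int(position), timepoints=timepoints,
            counts=np.array(counts), mean_area=np.array(areas),
            mean_ecc=np.array(eccs), cohort=cohort))
    return out


def trajectories_from_ground_truth(clone_table: pd.DataFrame,
                                   addresses: list[tuple[int, int]] | None = None
                                   ) -> list[CloneTrajectory]:
    """Build trajectories directly from a synthetic clone table."""
    t = np.asarray(clone_table.attrs.get("timepoints"), dtype=float)
    count_cols = [c for c in clone_table.columns if c.startswith("count_t")]
    out = []
    for i, row in enumerate(clone_table.itertuples()):
        street, position = (addresses[i] if addresses is not None
                            else (0, int(row.clone_id)))
        counts = np.array([getattr(row, c) for c in count_cols])
        out.append(CloneTrajectory(
            street=street, position=position, timepoints=t, counts=counts,
            mean_area=np.full(len(t), row.area_um2),
            mean_ecc=np.full(len(t), row.ecc),
            cohort=str(row.cohort)))
    return out


def filter_trajectories(trajectories: list[CloneTrajectory],
                        require_single_start: bool = True,
                        require_always_occupied: bool = True) -> list[CloneTrajectory]:
    """Keep apartments starting from a single cell with at least one cell at
    every timepoint.  Idempotent and independent of input order."""
    out = []
    for tr in trajectories:
        if require_single_start and tr.counts[0] != 1:
            continue
        if require_always_occupied and tr.counts.min() < 1:
            continue
        out.append(tr)
    return out


def fit_growth(trajectory: CloneTrajectory) -> GrowthFit:
    """OLS fit of ``log2(count)`` on time.

    ``lam`` is the slope (divisions/day) and ``p0 = 2**intercept``.  The
    time-averaged area/eccentricity weight every timepoint equally.
    Requires at least three timepoints, all counts at least one (apply the
    filter first).
    """
    t, c = trajectory.timepoints, trajectory.counts
    if len(t) < 3:
        raise ValueError("at least three timepoints are required for a growth fit")
    if c.min() < 1:
        raise ValueError("zero count in trajectory; apply filter_trajectories first")
    y = np.log2(c.astype(float))
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    with np.errstate(invalid="ignore"):
        area = float(np.nanmean(trajectory.mean_area))
        ecc = float(np.nanmean(trajectory.mean_ecc))
    return GrowthFit(street=trajectory.street, position=trajectory.position,
                     lam=float(slope), p0=float(2.0 ** intercept),
                     r_squared=float(r2), time_avg_area=area, time_avg_ecc=ecc,
                     cohort=trajectory.cohort)


def cohort_summary(fits: list[GrowthFit]) -> CohortSummary:
    """Median/quartile summary (linear-interpolation quantiles) of a cohort."""
    if not fits:
        raise ValueError("cohort has no fits")
    lam = np.array([f.lam for f in fits])
    area = np.array([f.time_avg_area for f in fits])
    lq = np.quantile(lam, [0.25, 0.5, 0.75])
    aq = np.nanquantile(area, [0.25, 0.5, 0.75])
    return CohortSummary(n=len(fits), median_lam=float(lq[1]), lam_q1=float(lq[0]),
                         lam_q3=float(lq[2]), max_lam=float(lam.max()),
                         median_area=float(aq[1]), area_q1=float(aq[0]),
                         area_q3=float(aq[2]))


def resample_pvalue(fits_a, fits_b, n_sample: int = 1000,
                    n_perm: int = 1999, seed: int = 0) -> tuple[float, float]:
    """Permutation test on the difference of subsampled cohort medians.

    Subsamples ``min(n_sample, len(cohort))`` growth rates per cohort
    without replacement; the observed statistic is the difference of the
    subsample medians; the null distribution permutes the pooled labels
    ``n_perm`` times.  Returns ``(p_value, observed)`` with the standard
    add-one permutation p-value.
    """
    a = np.array([f.lam for f in fits_a] if fits_a and isinstance(fits_a[0], GrowthFit)
                 else fits_a, dtype=float)
    b = np.array([f.lam for f in fits_b] if fits_b and isinstance(fits_b[0], GrowthFit)
                 else fits_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both cohorts must be non-empty")
    rng = np.random.default_rng(seed)
    sub_a = rng.choice(a, size=min(n_sample, a.size), replace=False)
    sub_b = rng.choice(b, size=min(n_sample, b.size), replace=False)
    observed = float(np.median(sub_a) - np.median(sub_b))

    pooled = np.concatenate([sub_a, sub_b])
    na = sub_a.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = np.median(perm[:na]) - np.median(perm[na:])
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return float(p), observed


def detect_rare_large(fits: list[GrowthFit], z_threshold: float = 5.0
                      ) -> tuple[list[GrowthFit], float]:
    """Flag clones with abnormally large time-averaged cell area.

    Uses a robust z-score, ``0.6745 * (area - median) / MAD``; clones with
    ``z >= z_threshold`` are returned together with their frequency in the
    population.
    """
    if len(fits) < 10:
        raise ValueError("need at least 10 fits for rare-phenotype detection")
    area = np.array([f.time_avg_area for f in fits])
    med = np.median(area)
    mad = np.median(np.abs(area - med))
    if mad == 0:
        raise ValueError("degenerate area distribution (MAD is zero)")
    z = 0.6745 * (area - med) / mad
    flagged = [f for f, zi in zip(fits, z) if zi >= z_threshold]
    return flagged, len(flagged) / len(fits)


def occupancy_heatmap(detections: pd.DataFrame, layout, timepoint: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Cell counts per apartment as a (streets x positions) matrix.

    Returns the integer count matrix and ``log10(count + 1)`` for display
    (a log scale keeps zero- and one-cell apartments distinguishable).
    """
    sub = detections[detections["timepoint"] == timepoint]
    mat = np.zeros((layout.n_streets, layout.apartments_per_street), dtype=int)
    if len(sub):
        bad = sub[(sub["street"] < 0) | (sub["street"] >= layout.n_streets)
                  | (sub["position"] < 0)
                  | (sub["position"] >= layout.apartments_per_street)]
        if len(bad):
            first = bad.iloc[0]
            raise ValueError(
                f"address ({int(first.street)}, {int(first.position)}) outside layout")
        counts = sub.groupby(["street", "position"]).size()
        for (s, p), n in counts.items():
            mat[int(s), int(p)] = n
    return mat, np.log10(mat + 1.0)


def fits_to_frame(fits: list[GrowthFit]) -> pd.DataFrame:
    """Growth fits as the canonical export table."""
    return pd.DataFrame([{
        "street": f.street, "position": f.position, "cohort": f.cohort,
        "lam": f.lam, "p0": f.p0, "r_squared": f.r_squared,
        "time_avg_area_um2": f.time_avg_area, "time_avg_ecc": f.time_avg_ecc,
    } for f in fits], columns=["street", "position", "cohort", "lam", "p0",
                               "r_squared", "time_avg_area_um2", "time_avg_ecc"])
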