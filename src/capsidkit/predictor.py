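"""Genome-length based prediction of icosahedral capsid architectures.

Given a collection of phage genome lengths and an allometric genome model
G(T), every genome is assigned the architecture whose model-mean genome
length is nearest (in linear kbp) on the deduplicated generalized T grid;
genomes landing on T <= 4 are flagged as small-capsid candidates.  The
module also estimates the genome-length probability density with Gaussian
kernels (bandwidth: the classic 0.9*min(sd, IQR/1.34)*n^(-1/5) rule-of-thumb
default of the reference statistics environment) and reports its peaks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .allometry import AllometricFit, inverse_t, predict_mean
from .lattice import t_grid

DEFAULT_T_MAX = 40.0  # grid covers T < 40
SMALL_CANDIDATE_T = 4.0


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    length_bp: int
    source: str = "isolate"  # isolate | metagenome | synthetic

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: genome length must be positive")


@dataclass(frozen=True)
class TAssignment:
    genome: GenomeRecord
    assigned_t: float
    nearest_mean_kbp: float
    abs_distance_kbp: float
    continuous_t: float
    is_small_candidate: bool


def default_t_grid(t_max: float = DEFAULT_T_MAX) -> list[float]:
    """Deduplicated generalized T values strictly below ``t_max``."""
    return [t for t in t_grid(t_max) if t < t_max - 1e-9]


def assign_t(
    length_bp: float,
    fit: AllometricFit,
    series: Sequence[float] | None = None,
    log_space: bool = False,
) -> TAssignment:
    """Assign the architecture with the nearest model-mean genome length.

    Distance is measured in linear kbp by default (``log_space=True``
    switches to log10 distance for sensitivity analyses).  Exact ties go to
    the smaller T (parsimony).
    """
    if length_bp <= 0:
        raise ValueError("genome length must be positive")
    if series is None:
        series = default_t_grid()
    series = sorted(series)
    if not series:
        raise ValueError("empty architecture series")
    length_kbp = length_bp / 1000.0
    means = np.array([predict_mean(fit, t) for t in series])
    if log_space:
        dist = np.abs(np.log10(length_kbp) - np.log10(means))
    else:
        dist = np.abs(length_kbp - means)
    best = 0
    for i in range(1, len(series)):
        if dist[i] < dist[best] - 1e-12 * max(1.0, dist[best]):
            best = i
    assigned = series[best]
    return TAssignment(
        genome=GenomeRecord(id="", length_bp=int(round(length_bp))),
        assigned_t=float(assigned),
        nearest_mean_kbp=float(means[best]),
        abs_distance_kbp=float(abs(length_kbp - means[best])),
        continuous_t=float(inverse_t(fit, length_kbp)),
        is_small_candidate=bool(assigned <= SMALL_CANDIDATE_T + 1e-9),
    )


def assign_record(
    record: GenomeRecord,
    fit: AllometricFit,
    series: Sequence[float] | None = None,
    log_space: bool = False,
) -> TAssignment:
    base = assign_t(record.length_bp, fit, series, log_space=log_space)
    return TAssignment(
        genome=record,
        assigned_t=base.assigned_t,
        nearest_mean_kbp=base.nearest_mean_kbp,
        abs_distance_kbp=base.abs_distance_kbp,
        continuous_t=base.continuous_t,
        is_small_candidate=base.is_small_candidate,
    )


def classify_batch(
    records: Sequence[GenomeRecord],
    fit: AllometricFit,
    series: Sequence[float] | None = None,
    log_space: bool = False,
) -> tuple[list[TAssignment], pd.DataFrame]:
    """Classify every record; also return the T-number frequency table (%)."""
    if len(records) == 0:
        raise ValueError("no genome records to classify")
    if series is None:
        series = default_t_grid()
    assignments = [assign_record(r, fit, series, log_space=log_space) for r in records]
    ts = pd.Series([a.assigned_t for a in assignments])
    freq = ts.value_counts().sort_index()
    table = pd.DataFrame(
        {
            "t": freq.index.to_numpy(dtype=float),
            "count": freq.to_numpy(dtype=int),
            "percent": 100.0 * freq.to_numpy() / len(assignments),
        }
    )
    return assignments, table


def assignments_to_dataframe(assignments: Sequence[TAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": a.genome.id,
                "length_bp": a.genome.length_bp,
                "source": a.genome.source,
                "assigned_t": a.assigned_t,
                "nearest_mean_kbp": a.nearest_mean_kbp,
                "abs_distance_kbp": a.abs_distance_kbp,
                "continuous_t": a.continuous_t,
                "is_small_candidate": a.is_small_candidate,
            }
            for a in assignments
        ]
    )


# ---------------------------------------------------------------------------
# genome-length density estimation


@dataclass(frozen=True)
class DensityEstimate:
    grid: np.ndarray  # kbp
    density: np.ndarray  # 1/kbp, integrates to ~1
    bandwidth: float  # kbp
    peaks: tuple[tuple[float, float], ...]  # (location kbp, density)


def _bw_nrd0(x: np.ndarray) -> float:
    """The rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    n = x.size
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd or abs(float(x[0])) or 1.0
    return 0.9 * lo * n ** (-0.2)


def estimate_density(
    records: Sequence[GenomeRecord] | np.ndarray,
    bandwidth: float | None = None,
    gridsize: int = 512,
) -> DensityEstimate:
    """Gaussian-kernel density of genome lengths (kbp) on a 512-point grid
    spanning [min - 3 bw, max + 3 bw]."""
    if len(records) and isinstance(records[0], GenomeRecord):
        x = np.array([r.length_bp / 1000.0 for r in records], dtype=float)
    else:
        x = np.asarray(records, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 genome lengths")
    if np.ptp(x) == 0:
        raise ValueError("all genome lengths are identical; density is degenerate")
    bw = float(bandwidth) if bandwidth is not None else _bw_nrd0(x)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3.0 * bw, x.max() + 3.0 * bw, gridsize)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * math.sqrt(2.0 * math.pi))
    est = DensityEstimate(grid=grid, density=dens, bandwidth=bw, peaks=())
    return DensityEstimate(grid=grid, density=dens, bandwidth=bw, peaks=tuple(find_peaks(est)))


def find_peaks(est: DensityEstimate) -> list[tuple[float, float]]:
    """Strict grid-local maxima of the density, sorted by density descending."""
    d = est.density
    idx = [i for i in range(1, len(d) - 1) if d[i] > d[i - 1] and d[i] > d[i + 1]]
    peaks = [(float(est.grid[i]), float(d[i])) for i in idx]
    peaks.sort(key=lambda p: -p[1])
    return peaks


# ---------------------------------------------------------------------------
# candidate reporting


@dataclass(frozen=True)
class CandidateReport:
    threshold_t: float
    candidates: pd.DataFrame  # sorted by assigned_t then length
    counts: pd.DataFrame  # per architecture

    def to_json(self, path=None) -> str:
        doc = {
            "threshold_t": self.threshold_t,
            "n_candidates": int(len(self.candidates)),
            "counts": [
                {"t": float(r.t), "count": int(r.count)} for r in self.counts.itertuples(index=False)
            ],
            "candidates": self.candidates.to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def candidate_report(
    assignments: Sequence[TAssignment], threshold_t: float = SMALL_CANDIDATE_T
) -> CandidateReport:
    """Genomes predicted to form small capsids (assigned T <= threshold)."""
    frame = assignments_to_dataframe(list(assignments))
    cand = frame[frame["assigned_t"] <= threshold_t + 1e-9].copy()
    cand.sort_values(["assigned_t", "length_bp"], inplace=True)
    cand.reset_index(drop=True, inplace=True)
    if len(cand):
        counts = cand.groupby("assigned_t").size().reset_index(name="count")
        counts.columns = ["t", "count"]
    else:
        counts = pd.DataFrame(columns=["t", "count"])
    return CandidateReport(threshold_t=float(threshold_t), candidates=cand, counts=counts)
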