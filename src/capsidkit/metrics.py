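"""Derived structural quantities of measured tailed-phage capsids.

Works on tables of per-capsid cryo-EM measurements (interior/exterior
vertex-to-vertex diameters, sphericities, surfaces, volumes, genome length)
and derives shell thickness, genome packing density, per-major-capsid-protein
surface areas and the exterior/interior surface excess, plus Spearman
correlations with capsid diameter and Shapiro-Wilk normality checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import resolve_t

#: canonical CSV header for structure tables
STRUCTURE_COLUMNS = [
    "emdb_id",
    "t",
    "d_int_nm",
    "d_ext_nm",
    "sphericity_int",
    "sphericity_ext",
    "s_int_nm2",
    "s_ext_nm2",
    "v_int_nm3",
    "v_ext_nm3",
    "genome_kbp",
]


@dataclass(frozen=True)
class CapsidStructureRecord:
    """One measured capsid.

    Diameters are five-fold-vertex to five-fold-vertex, in nm; surfaces in
    nm^2, volumes in nm^3, genome length in kbp.
    """

    emdb_id: str
    t: float
    d_int: float
    d_ext: float
    sphericity_int: float
    sphericity_ext: float
    s_int: float
    s_ext: float
    v_int: float
    v_ext: float
    genome: float

    def __post_init__(self) -> None:
        if not (self.d_ext > self.d_int > 0):
            raise ValueError(f"{self.emdb_id}: need d_ext > d_int > 0")
        if not (self.s_ext > self.s_int > 0):
            raise ValueError(f"{self.emdb_id}: need s_ext > s_int > 0")
        if not (self.v_ext > self.v_int > 0):
            raise ValueError(f"{self.emdb_id}: need v_ext > v_int > 0")
        if not self.genome > 0:
            raise ValueError(f"{self.emdb_id}: genome length must be positive")

    @property
    def mcp_count(self) -> int:
        """Major capsid proteins, 60*T0; generalized t is resolved to its
        smallest-area-factor lattice realisation."""
        matches = resolve_t(self.t, t_max=self.t + 1.0)
        if not matches:
            raise ValueError(f"{self.emdb_id}: t={self.t} is not in the generalized T series")
        return matches[0].mcp_count


@dataclass(frozen=True)
class DerivedCapsidMetrics:
    thickness: float  # nm, (d_ext - d_int) / 2
    genome_density: float  # bp / nm^3
    mcp_area_int: float  # nm^2 per major capsid protein
    mcp_area_ext: float  # nm^2 per major capsid protein
    ext_int_surface_excess: float  # fraction, s_ext/s_int - 1


def derive_metrics(rec: CapsidStructureRecord, mcp_surface_fraction: float = 1.0) -> DerivedCapsidMetrics:
    """Derive thickness, packing density and per-MCP areas for one capsid.

    Thickness subtracts the internal radius from the external radius (input
    diameters are halved).  Genome density divides genome size (bp, kbp*1000)
    by interior volume.  ``mcp_surface_fraction`` apportions the shell
    surface to major capsid proteins (1 assigns it all, the default when no
    decoration-protein fraction is known).
    """
    if rec.v_int <= 0 or rec.v_ext <= 0:
        raise ValueError("volumes must be positive")
    if not 0 < mcp_surface_fraction <= 1:
        raise ValueError("mcp_surface_fraction must be in (0, 1]")
    n_mcp = rec.mcp_count
    return DerivedCapsidMetrics(
        thickness=(rec.d_ext - rec.d_int) / 2.0,
        genome_density=rec.genome * 1000.0 / rec.v_int,
        mcp_area_int=mcp_surface_fraction * rec.s_int / n_mcp,
        mcp_area_ext=mcp_surface_fraction * rec.s_ext / n_mcp,
        ext_int_surface_excess=rec.s_ext / rec.s_int - 1.0,
    )


def _metrics_frame(records: Sequence[CapsidStructureRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        der = derive_metrics(rec)
        rows.append(
            {
                "emdb_id": rec.emdb_id,
                "t": rec.t,
                "d_int_nm": rec.d_int,
                "d_ext_nm": rec.d_ext,
                "sphericity_int": rec.sphericity_int,
                "sphericity_ext": rec.sphericity_ext,
                "s_int_nm2": rec.s_int,
                "s_ext_nm2": rec.s_ext,
                "v_int_nm3": rec.v_int,
                "v_ext_nm3": rec.v_ext,
                "genome_kbp": rec.genome,
                "thickness_nm": der.thickness,
                "genome_density_bp_nm3": der.genome_density,
                "mcp_area_int_nm2": der.mcp_area_int,
                "mcp_area_ext_nm2": der.mcp_area_ext,
                "surface_excess": der.ext_int_surface_excess,
            }
        )
    return pd.DataFrame(rows)


def summarize_table(records: Sequence[CapsidStructureRecord]) -> pd.DataFrame:
    """Min-max ranges and means of every measured and derived property.

    Returns a table with one row per property plus a leading count row
    (``capsids_analyzed``), mirroring the usual published summary.
    """
    if len(records) == 0:
        raise ValueError("structure table is empty")
    frame = _metrics_frame(records)
    rows = [{"property": "capsids_analyzed", "min": len(records), "max": len(records), "mean": len(records)}]
    for col in frame.columns:
        if col == "emdb_id":
            continue
        v = frame[col].to_numpy(dtype=float)
        rows.append({"property": col, "min": v.min(), "max": v.max(), "mean": v.mean()})
    return pd.DataFrame(rows, columns=["property", "min", "max", "mean"])


@dataclass(frozen=True)
class CorrelationReport:
    variable: str
    rho: float
    p_value: float
    n: int


def correlate_with_diameter(
    records: Sequence[CapsidStructureRecord],
    variable: str,
    which: str = "exterior",
) -> CorrelationReport:
    """Spearman rank correlation (two-tailed) of a variable with capsid diameter.

    ``variable`` names any column of the derived metrics frame (e.g.
    ``sphericity_ext``, ``thickness_nm``, ``genome_density_bp_nm3``).
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records for a correlation")
    frame = _metrics_frame(records)
    diam = frame["d_ext_nm" if which == "exterior" else "d_int_nm"].to_numpy(dtype=float)
    if variable not in frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    values = frame[variable].to_numpy(dtype=float)
    if np.ptp(values) == 0 or np.ptp(diam) == 0:
        raise ValueError(f"correlation with constant variable {variable!r} is undefined")
    rho, p = stats.spearmanr(values, diam)
    if math.isnan(rho):
        raise ValueError(f"correlation with variable {variable!r} is undefined")
    return CorrelationReport(variable=variable, rho=float(rho), p_value=float(p), n=len(records))


def correlation_table(records: Sequence[CapsidStructureRecord], which: str = "exterior") -> pd.DataFrame:
    """Spearman correlations of all derived variables against diameter."""
    frame = _metrics_frame(records)
    out = []
    for col in frame.columns:
        if col in ("emdb_id", "d_int_nm", "d_ext_nm"):
            continue
        try:
            rep = correlate_with_diameter(records, col, which=which)
        except ValueError:
            continue
        out.append({"variable": rep.variable, "rho": rep.rho, "p_value": rep.p_value, "n": rep.n})
    return pd.DataFrame(out, columns=["variable", "rho", "p_value", "n"])


def test_normality(values: Iterable[float]) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p).  Rejects n < 3 and constant samples."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(arr) == 0:
        raise ValueError("normality of a constant sample is undefined")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# CSV interface


def read_structure_table(path) -> list[CapsidStructureRecord]:
    """Read a capsid structure table (header of :data:`STRUCTURE_COLUMNS`)."""
    frame = pd.read_csv(path)
    missing = [c for c in STRUCTURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"structure table {path} is missing columns: {missing}")
    return [
        CapsidStructureRecord(
            emdb_id=str(row.emdb_id),
            t=float(row.t),
            d_int=float(row.d_int_nm),
            d_ext=float(row.d_ext_nm),
            sphericity_int=float(row.sphericity_int),
            sphericity_ext=float(row.sphericity_ext),
            s_int=float(row.s_int_nm2),
            s_ext=float(row.s_ext_nm2),
            v_int=float(row.v_int_nm3),
            v_ext=float(row.v_ext_nm3),
            genome=float(row.genome_kbp),
        )
        for row in frame.itertuples(index=False)
    ]


def write_structure_table(records: Sequence[CapsidStructureRecord], path) -> None:
    frame = _metrics_frame(records)[
        [
            "emdb_id",
            "t",
            "d_int_nm",
            "d_ext_nm",
            "sphericity_int",
            "sphericity_ext",
            "s_int_nm2",
            "s_ext_nm2",
            "v_int_nm3",
            "v_ext_nm3",
            "genome_kbp",
        ]
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
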