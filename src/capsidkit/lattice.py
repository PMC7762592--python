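"""Generalized triangulation-number algebra over the four Archimedean capsid lattices.

Icosahedral capsids index their quasi-equivalent protein positions with the
classic Caspar-Klug triangulation number ``T0(h, k) = h^2 + hk + k^2``, where
``(h, k)`` are the lattice steps joining two neighbouring five-fold vertices.
Besides the familiar hexagonal lattice, capsid shells can organise their
proteins on three further Archimedean tilings (trihexagonal, snub hexagonal
and rhombitrihexagonal) whose secondary polygons (triangles, squares) host
minor capsid proteins.  Keeping the major-capsid-protein footprint fixed,
each tiling inflates the shell surface by a constant area factor ``alpha``,
which defines the generalized T-number ``T = alpha * T0``.

The module provides the area factors, the architecture data type, and the
ordered enumeration of all achievable architectures up to a cut-off, which is
the candidate grid the genome-length classifier matches against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

SQRT3 = math.sqrt(3.0)

#: Classic T-numbers achievable on any lattice (h^2 + hk + k^2 for h >= k >= 0).
CLASSIC_T0_EXAMPLES = (1, 3, 4, 7, 9, 12, 13, 16, 19, 21, 25, 27)


@dataclass(frozen=True)
class TilingClass:
    """One of the four Archimedean icosahedral lattices.

    Attributes
    ----------
    label:
        ``hexagonal``, ``trihexagonal``, ``snub_hexagonal`` or
        ``rhombitrihexagonal``.
    area_factor:
        Surface inflation factor ``alpha`` relative to the hexagonal lattice
        at equal major-capsid-protein size (exact values: 1, 4/3, 7/3 and
        ``4/3 + 2*sqrt(3)/3``).
    chirality:
        ``laevo``/``dextro`` for the snub hexagonal lattice (the only chiral
        tiling), ``none`` otherwise.
    """

    label: str
    area_factor: float
    chirality: str = "none"

    def __post_init__(self) -> None:
        if self.label != "snub_hexagonal" and self.chirality != "none":
            raise ValueError("chirality is only meaningful for the snub hexagonal lattice")
        if self.label == "snub_hexagonal" and self.chirality not in ("laevo", "dextro"):
            raise ValueError("snub hexagonal chirality must be 'laevo' or 'dextro'")


HEXAGONAL = TilingClass("hexagonal", 1.0)
TRIHEXAGONAL = TilingClass("trihexagonal", 4.0 / 3.0)
SNUB_HEXAGONAL = TilingClass("snub_hexagonal", 7.0 / 3.0, "laevo")
SNUB_HEXAGONAL_DEXTRO = TilingClass("snub_hexagonal", 7.0 / 3.0, "dextro")
RHOMBITRIHEXAGONAL = TilingClass("rhombitrihexagonal", 4.0 / 3.0 + 2.0 * SQRT3 / 3.0)

#: The four lattices in canonical (increasing area-factor*) report order.
TILINGS: tuple[TilingClass, ...] = (
    HEXAGONAL,
    TRIHEXAGONAL,
    SNUB_HEXAGONAL,
    RHOMBITRIHEXAGONAL,
)

_TILING_ORDER = {
    "hexagonal": 0,
    "trihexagonal": 1,
    "snub_hexagonal": 2,
    "rhombitrihexagonal": 3,
}

_ALIASES = {
    "hexagonal": "hexagonal",
    "hex": "hexagonal",
    "h": "hexagonal",
    "trihexagonal": "trihexagonal",
    "trihex": "trihexagonal",
    "tri": "trihexagonal",
    "t": "trihexagonal",
    "snub_hexagonal": "snub_hexagonal",
    "snub": "snub_hexagonal",
    "s": "snub_hexagonal",
    "rhombitrihexagonal": "rhombitrihexagonal",
    "rhombi": "rhombitrihexagonal",
    "r": "rhombitrihexagonal",
}

_BY_LABEL = {
    "hexagonal": HEXAGONAL,
    "trihexagonal": TRIHEXAGONAL,
    "snub_hexagonal": SNUB_HEXAGONAL,
    "rhombitrihexagonal": RHOMBITRIHEXAGONAL,
}


def as_tiling(tiling: TilingClass | str) -> TilingClass:
    """Coerce a tiling label (or common abbreviation) to a :class:`TilingClass`."""
    if isinstance(tiling, TilingClass):
        return tiling
    try:
        return _BY_LABEL[_ALIASES[str(tiling).strip().lower()]]
    except KeyError:
        raise ValueError(
            f"unknown lattice {tiling!r}; expected one of "
            "hexagonal, trihexagonal, snub_hexagonal, rhombitrihexagonal"
        ) from None


def t0_number(h: int, k: int) -> int:
    """Classic triangulation number ``T0 = h^2 + hk + k^2``.

    Symmetric in ``h`` and ``k``; rejects negative steps and ``(0, 0)``.
    """
    if h != int(h) or k != int(k):
        raise ValueError("lattice steps h, k must be integers")
    h, k = int(h), int(k)
    if h < 0 or k < 0:
        raise ValueError("lattice steps h, k must be non-negative")
    if h == 0 and k == 0:
        raise ValueError("(h, k) = (0, 0) does not define a capsid lattice")
    return h * h + h * k + k * k


@dataclass(frozen=True)
class CapsidArchitecture:
    """An (h, k, lattice) triple with its classic and generalized T-numbers.

    ``mcp_count = 60 * t0`` counts major capsid proteins regardless of the
    tiling; ``total_protein_factor = 60 * t`` is the equivalent protein-surface
    count once the minor-lattice positions are included (informational).
    """

    h: int
    k: int
    tiling: TilingClass
    t0: int
    t: float
    mcp_count: int
    total_protein_factor: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"T={self.t:.4g} [{self.tiling.label}({self.h},{self.k})]"


def generalized_t(h: int, k: int, tiling: TilingClass | str) -> CapsidArchitecture:
    """Build the :class:`CapsidArchitecture` for steps ``(h, k)`` on a tiling.

    ``(h, k)`` is canonicalised to ``h >= k``; the classifier never needs to
    distinguish the two mirror orientations of the step vector.
    """
    tiling = as_tiling(tiling)
    t0 = t0_number(h, k)
    h, k = (int(h), int(k)) if h >= k else (int(k), int(h))
    t = tiling.area_factor * t0
    return CapsidArchitecture(
        h=h,
        k=k,
        tiling=tiling,
        t0=t0,
        t=t,
        mcp_count=60 * t0,
        total_protein_factor=60.0 * t,
    )


def mcp_count(arch: CapsidArchitecture) -> int:
    """Number of major capsid proteins, ``60 * T0`` (five are replaced by the portal in virions)."""
    return 60 * arch.t0


def enumerate_architectures(t_max: float) -> list[CapsidArchitecture]:
    """All architectures with generalized ``t <= t_max``, sorted ascending by ``t``.

    Numerically equal ``t`` from different (h, k, lattice) realisations are
    retained as distinct entries (e.g. T = 4 arises from hexagonal (2, 0) and
    trihexagonal (1, 1)); ties are ordered hexagonal < trihexagonal < snub <
    rhombitrihexagonal, then by (t0, h, k).
    """
    if not math.isfinite(t_max) or t_max < 1.0:
        raise ValueError("t_max must be >= 1 (T = 1 is the smallest capsid)")
    out: list[CapsidArchitecture] = []
    eps = 1e-9
    for tiling in TILINGS:
        t0_cap = t_max / tiling.area_factor + eps
        h_cap = int(math.isqrt(int(t0_cap))) + 1
        for h in range(0, h_cap + 1):
            for k in range(0, h + 1):
                if h == 0 and k == 0:
                    continue
                t0 = h * h + h * k + k * k
                if t0 > t0_cap:
                    continue
                out.append(generalized_t(h, k, tiling))
    out.sort(key=lambda a: (a.t, _TILING_ORDER[a.tiling.label], a.t0, a.h, a.k))
    return out


def t_grid(t_max: float, tol: float = 1e-9) -> list[float]:
    """Deduplicated ascending grid of generalized T values with ``t <= t_max``.

    Degenerate architectures collapse onto one numeric entry: genome length
    alone cannot distinguish lattice classes of equal ``t``.
    """
    grid: list[float] = []
    for arch in enumerate_architectures(t_max):
        if not grid or arch.t - grid[-1] > tol:
            grid.append(arch.t)
    return grid


def resolve_t(t: float, t_max: float | None = None, tol: float = 1e-6) -> list[CapsidArchitecture]:
    """All architectures whose generalized T matches ``t`` within ``tol``."""
    if t_max is None:
        t_max = t + 1.0
    return [a for a in enumerate_architectures(t_max) if abs(a.t - t) <= tol]


def architectures_to_dataframe(archs: Iterable[CapsidArchitecture]) -> pd.DataFrame:
    """Tabulate architectures with columns h, k, tiling, t0, t, mcp_count."""
    rows = [
        {
            "h": a.h,
            "k": a.k,
            "tiling": a.tiling.label,
            "t0": a.t0,
            "t": a.t,
            "mcp_count": a.mcp_count,
        }
        for a in archs
    ]
    return pd.DataFrame(rows, columns=["h", "k", "tiling", "t0", "t", "mcp_count"])


def write_architecture_table(archs: Sequence[CapsidArchitecture], path) -> None:
    architectures_to_dataframe(archs).to_csv(path, index=False)
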