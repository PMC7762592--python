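"""Synthetic data generators for capsid structure tables and genome collections.

Real inputs for this kind of analysis are (a) a per-capsid cryo-EM
measurement table and (b) large collections of phage genome lengths from
reference databases or gut metagenome assemblies.  Neither ships with the
package, so these generators emulate them:

* :func:`gen_capsid_table` builds structure tables that satisfy, by
  construction, the two conserved structural constraints the allometric
  theory rests on — genome packed at constant (per-capsid sampled) density
  and constant exposed surface per major capsid protein — so noiseless
  tables recover the theoretical exponents b_G = 3/2 and b_D = 1/2.
* :func:`gen_genome_mixture` draws genome lengths from a lognormal mixture;
  the shipped presets anchor their component means at the multimodal peak
  locations reported for phage isolate (18.3 / 42.0 / 158.9 kbp) and gut
  metagenome (12.6 / 42.9 / 98.2 / 160.8 kbp) genome-length distributions.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import CapsidStructureRecord
from .predictor import GenomeRecord

#: the seven distinct architectures with published high-resolution structures
DEFAULT_TRAINING_T = (4.0, 7.0, 9.0, 12.0, 13.0, 16.0, 27.0)

#: published diameter range (nm) used to scale shell thickness within 3-8 nm
_DIAMETER_RANGE = (49.0, 143.0)
_THICKNESS_RANGE = (3.0, 8.0)
_SPHERICITY_EXT_RANGE = (0.14, 0.55)
_SPHERICITY_INT_RANGE = (0.25, 0.75)


@dataclass(frozen=True)
class CapsidTableSpec:
    """Parameters of the synthetic structure-table generator."""

    t_values: tuple[float, ...] = DEFAULT_TRAINING_T
    replicates: int = 3
    density_range: tuple[float, float] = (0.34, 0.62)  # bp/nm^3
    mcp_area_ext_range: tuple[float, float] = (24.0, 35.0)  # nm^2
    noise_sd_log10: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.t_values) < 1 or self.replicates < 1:
            raise ValueError("t_values must be >= 1 and replicates >= 1")
        for lo, hi in (self.density_range, self.mcp_area_ext_range):
            if not 0 < lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be non-negative")


def _interp_range(x: float, x_range: tuple[float, float], y_range: tuple[float, float]) -> float:
    frac = (x - x_range[0]) / (x_range[1] - x_range[0])
    frac = min(max(frac, 0.0), 1.0)
    return y_range[0] + frac * (y_range[1] - y_range[0])


def gen_capsid_table(spec: CapsidTableSpec) -> list[CapsidStructureRecord]:
    """Generate a structure table obeying the constant-density / constant
    per-MCP-area scaling constraints.

    For each architecture: the per-MCP exterior area is drawn uniformly from
    its range, the exterior surface is area * 60 * T, the exterior diameter
    follows from a quasi-spherical shell, the shell thickness increases with
    diameter within 3-8 nm, interior quantities follow, and the genome is a
    uniformly drawn packing density times the interior volume.  Lognormal
    noise of width ``noise_sd_log10`` (log10 units) multiplies diameters and
    genome lengths.
    """
    rng = np.random.default_rng(spec.seed)
    noisy = spec.noise_sd_log10 > 0
    records: list[CapsidStructureRecord] = []
    for t in spec.t_values:
        for rep in range(spec.replicates):
            # noise-free tables are pure realisations of the scaling law:
            # per-MCP area and packing density sit at their range midpoints
            area_ext = rng.uniform(*spec.mcp_area_ext_range) if noisy else (
                0.5 * (spec.mcp_area_ext_range[0] + spec.mcp_area_ext_range[1])
            )
            s_ext = area_ext * 60.0 * t
            d_ext = math.sqrt(s_ext / math.pi)
            if noisy:
                d_ext *= 10.0 ** (spec.noise_sd_log10 * rng.standard_normal())
                s_ext = math.pi * d_ext**2  # keep the quasi-sphere consistent
            thickness = _interp_range(d_ext, _DIAMETER_RANGE, _THICKNESS_RANGE)
            d_int = d_ext - 2.0 * thickness
            if d_int <= 0:  # pragma: no cover - impossible for T >= 1
                raise RuntimeError("degenerate interior diameter")
            s_int = math.pi * d_int**2
            v_int = math.pi / 6.0 * d_int**3
            v_ext = math.pi / 6.0 * d_ext**3
            density = rng.uniform(*spec.density_range) if noisy else (
                0.5 * (spec.density_range[0] + spec.density_range[1])
            )
            genome = density * v_int / 1000.0  # kbp
            if noisy:
                genome *= 10.0 ** (spec.noise_sd_log10 * rng.standard_normal())
            sph_ext = _interp_range(d_ext, _DIAMETER_RANGE,
                                    (_SPHERICITY_EXT_RANGE[1], _SPHERICITY_EXT_RANGE[0]))
            sph_int = _interp_range(d_ext, _DIAMETER_RANGE,
                                    (_SPHERICITY_INT_RANGE[1], _SPHERICITY_INT_RANGE[0]))
            records.append(
                CapsidStructureRecord(
                    emdb_id=f"SYN-{t:g}-{rep}",
                    t=float(t),
                    d_int=d_int,
                    d_ext=d_ext,
                    sphericity_int=sph_int,
                    sphericity_ext=sph_ext,
                    s_int=s_int,
                    s_ext=s_ext,
                    v_int=v_int,
                    v_ext=v_ext,
                    genome=genome,
                )
            )
    return records


# ---------------------------------------------------------------------------
# genome-length mixtures


@dataclass(frozen=True)
class GenomeMixtureSpec:
    """A lognormal mixture of genome lengths.

    ``components`` are (mean kbp, weight, lognormal sd in log10 units);
    weights must sum to 1.
    """

    components: tuple[tuple[float, float, float], ...]
    n: int = 1000
    seed: int = 0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not self.components:
            raise ValueError("need at least one mixture component")
        if any(m <= 0 or w < 0 or sd < 0 for m, w, sd in self.components):
            raise ValueError("component means must be positive, weights and sds non-negative")
        if abs(sum(w for _, w, _ in self.components) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


#: genome-length presets anchored at the reported isolate / gut-metagenome
#: peak locations; weights chosen to approximate the reported median/mean,
#: flanking components narrow (few phage groups dominate the small/large
#: ends) and the ~42 kbp component broad, so the default-bandwidth Gaussian
#: KDE resolves every anchored peak, as in the real collections
ISOLATE_PRESET = GenomeMixtureSpec(
    components=((18.3, 0.13, 0.04), (42.0, 0.65, 0.09), (158.9, 0.22, 0.025)),
    n=3000,
    source="isolate",
)
GUT_PRESET = GenomeMixtureSpec(
    components=((12.6, 0.09, 0.035), (42.9, 0.69, 0.10), (98.2, 0.11, 0.02), (160.8, 0.11, 0.02)),
    n=1500,
    source="metagenome",
)

PRESETS = {"isolates": ISOLATE_PRESET, "gut": GUT_PRESET}


def mixture_spec(preset: str, n: int | None = None, seed: int = 0) -> GenomeMixtureSpec:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}")
    base = PRESETS[preset]
    return GenomeMixtureSpec(
        components=base.components, n=n or base.n, seed=seed, source=base.source
    )


def gen_genome_mixture(spec: GenomeMixtureSpec) -> list[GenomeRecord]:
    """Draw genome lengths (integer bp) from the lognormal mixture."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([w for _, w, _ in spec.components])
    comp = rng.choice(len(spec.components), size=spec.n, p=weights)
    means = np.array([m for m, _, _ in spec.components])
    sds = np.array([sd for _, _, sd in spec.components])
    lengths_kbp = means[comp] * 10.0 ** (sds[comp] * rng.standard_normal(spec.n))
    lengths_bp = np.maximum(np.round(lengths_kbp * 1000.0).astype(int), 1)
    return [
        GenomeRecord(id=f"SYN{i:06d}", length_bp=int(bp), source=spec.source)
        for i, bp in enumerate(lengths_bp)
    ]


def records_to_fasta(records: Sequence[GenomeRecord], path, seed: int = 0) -> None:
    """Write records as FASTA with random A/C/G/T sequence of each length
    (gzip if the path ends in .gz); purely synthetic sequence content."""
    import gzip

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as handle:
        for rec in records:
            seq = rng.choice(alphabet, size=rec.length_bp).tobytes().decode()
            handle.write(f">{rec.id}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")
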