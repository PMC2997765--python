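"""Azimuthal extrapolation of sector counts to whole-epithelium totals.

Under the lens's radial symmetry, a 60° anterior sector holds one sixth of
the spherical-cap cells and a 10°-of-longitude equatorial trapezoid holds one
thirty-sixth of the equatorial-band cells, so

    N_cap  = n_sector · 360 / θ        (θ = 60° by default)
    N_band = n_trapezoid · 360 / w     (w = 10° by default)
    N_total = N_cap + N_band

Counts are rounded to the nearest integer only at the final step.  A helper
subtracts meridional-row cells from flat-mount literature totals, which
include them, to make those totals comparable with intact-lens estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import List, Optional, Sequence, Tuple

from .errors import ParameterError


def extrapolate_cap(n_sector: int, central_angle: float) -> int:
    """Cap total from an anterior-sector count: round(n · 360 / angle_deg)."""
    if not (0.0 < central_angle <= 360.0):
        raise ParameterError("central_angle (degrees) must lie in (0, 360]")
    if n_sector < 0:
        raise ParameterError("n_sector must be >= 0")
    return int(round(n_sector * 360.0 / central_angle))


def extrapolate_band(n_sector: int, longitude_width: float) -> int:
    """Band total from an equatorial-trapezoid count: round(n · 360 / width_deg)."""
    if not (0.0 < longitude_width <= 360.0):
        raise ParameterError("longitude_width (degrees) must lie in (0, 360]")
    if n_sector < 0:
        raise ParameterError("n_sector must be >= 0")
    return int(round(n_sector * 360.0 / longitude_width))


def total_epithelium(n_cap: int, n_band: int) -> int:
    """Total epithelial cells: cap plus band."""
    return n_cap + n_band


def subtract_meridional(total_with_mr: int, n_mr: int) -> int:
    """Remove meridional-row cells from a flat-mount total that includes them."""
    if n_mr > total_with_mr:
        raise ParameterError(
            f"meridional count {n_mr} exceeds the total {total_with_mr}"
        )
    return total_with_mr - n_mr


def replicate_spread(estimates: Sequence[float]) -> float:
    """Relative difference of a replicate pair: |e1 − e2| / mean(e1, e2) × 100."""
    if len(estimates) != 2:
        raise ParameterError("a replicate pair has exactly 2 estimates")
    a, b = estimates
    if a <= 0 or b <= 0:
        raise ParameterError("replicate estimates must be positive")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


@dataclass(frozen=True)
class ReplicateSpreadSummary:
    per_pair_percent: Tuple[float, ...]
    mean_percent: float
    sd_percent: float


def summarize_replicates(pairs: Sequence[Sequence[float]]) -> ReplicateSpreadSummary:
    """Mean ± SD of per-pair relative differences over replicate pairs."""
    if len(pairs) < 1:
        raise ParameterError("need at least one replicate pair")
    vals = tuple(replicate_spread(p) for p in pairs)
    sd = stdev(vals) if len(vals) > 1 else 0.0
    return ReplicateSpreadSummary(per_pair_percent=vals, mean_percent=mean(vals), sd_percent=sd)


@dataclass
class CountResult:
    """Sector counts, extrapolated totals and provenance for one measurement."""

    n_anterior_sector: int
    n_equatorial_sector: int
    anterior_angle: float  # degrees
    equatorial_width: float  # degrees
    n_cap: int
    n_band: int
    n_total: int
    fiduciary_colatitude: float  # degrees
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_sector_counts(
        cls,
        n_anterior_sector: int,
        n_equatorial_sector: int,
        anterior_angle: float = 60.0,
        equatorial_width: float = 10.0,
        fiduciary_colatitude: float = float("nan"),
        provenance: Optional[dict] = None,
    ) -> "CountResult":
        n_cap = extrapolate_cap(n_anterior_sector, anterior_angle)
        n_band = extrapolate_band(n_equatorial_sector, equatorial_width)
        return cls(
            n_anterior_sector=n_anterior_sector,
            n_equatorial_sector=n_equatorial_sector,
            anterior_angle=anterior_angle,
            equatorial_width=equatorial_width,
            n_cap=n_cap,
            n_band=n_band,
            n_total=total_epithelium(n_cap, n_band),
            fiduciary_colatitude=fiduciary_colatitude,
            provenance=provenance or {},
        )

    def to_dict(self) -> dict:
        return {
            "n_anterior_sector": self.n_anterior_sector,
            "n_equatorial_sector": self.n_equatorial_sector,
            "anterior_angle_deg": self.anterior_angle,
            "equatorial_width_deg": self.equatorial_width,
            "n_cap": self.n_cap,
            "n_band": self.n_band,
            "n_total": self.n_total,
            "fiduciary_colatitude_deg": self.fiduciary_colatitude,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CountResult":
        return cls(
            n_anterior_sector=d["n_anterior_sector"],
            n_equatorial_sector=d["n_equatorial_sector"],
            anterior_angle=d["anterior_angle_deg"],
            equatorial_width=d["equatorial_width_deg"],
            n_cap=d["n_cap"],
            n_band=d["n_band"],
            n_total=d["n_total"],
            fiduciary_colatitude=d["fiduciary_colatitude_deg"],
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CountResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def report_text(self) -> str:
        lines = [
            "Lens epithelial cell count",
            "--------------------------",
            f"anterior sector ({self.anterior_angle:g} deg): {self.n_anterior_sector} nuclei",
            f"  -> anterior cap  (x{360.0 / self.anterior_angle:g}): {self.n_cap} cells",
            f"equatorial trapezoid ({self.equatorial_width:g} deg of longitude): "
            f"{self.n_equatorial_sector} nuclei",
            f"  -> equatorial band (x{360.0 / self.equatorial_width:g}): {self.n_band} cells",
            f"total epithelial cells: {self.n_total}",
            f"fiduciary colatitude: {self.fiduciary_colatitude:.2f} deg",
        ]
        if self.n_total == 0:
            lines.append("WARNING: empty count — no nuclei fell in either region")
        for k, v in self.provenance.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)
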