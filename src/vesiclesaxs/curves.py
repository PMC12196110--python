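"""Plain-text 1-D scattering-curve container and readers/writers.

The interchange format is the de-facto SAXS dialect: whitespace- or
comma-delimited columns ``Q  I  [sigma]`` with ``#`` comment lines.  Q is
stored in nm^-1 internally; files in inverse angstroms are converted
(factor 10) on read when declared via the unit flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import QGrid

__all__ = ["ScatteringCurve", "read_curve", "write_curve", "ParseError"]

logger = logging.getLogger("vesiclesaxs")

_UNIT_FACTORS = {"nm^-1": 1.0, "1/nm": 1.0, "A^-1": 10.0, "1/A": 10.0}


class ParseError(ValueError):
    """Malformed scattering-data file."""


@dataclass(frozen=True)
class ScatteringCurve:
    """One 1-D SAXS profile: Q grid (nm^-1), intensities and per-point sigma.

    ``meta`` carries provenance (generator parameters, seed, unit of origin)
    and is written into the file header by :func:`write_curve`.
    """

    grid: QGrid
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        n = len(self.grid)
        if inten.shape != (n,) or sig.shape != (n,):
            raise ValueError(
                f"column length mismatch: {n} Q values, {inten.size} intensities, "
                f"{sig.size} sigmas"
            )
        if not np.all(np.isfinite(inten)) or not np.all(np.isfinite(sig)):
            raise ValueError("intensities and sigmas must be finite")
        if np.any(sig <= 0):
            raise ValueError("per-point sigma must be strictly positive")
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return len(self.grid)

    def with_intensity(self, intensity: np.ndarray) -> "ScatteringCurve":
        """Copy of the curve with replaced intensities (same grid and sigma)."""
        return ScatteringCurve(self.grid, intensity, self.sigma, dict(self.meta))


def read_curve(path, unit: str = "nm^-1", noise_model=None) -> ScatteringCurve:
    """Read a 2- or 3-column delimited text file into a :class:`ScatteringCurve`.

    Parameters
    ----------
    path : str or Path
        File with columns Q, I and optionally sigma; '#' lines are comments.
    unit : {"nm^-1", "A^-1"}
        Unit of the Q column; inverse angstroms are multiplied by 10.
    noise_model : NoiseModel, optional
        Used to synthesise sigma for 2-column input (default: 2% relative
        error with a small floor); a warning is logged when this happens.
    """
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_FACTORS)}")
    factor = _UNIT_FACTORS[unit]
    rows: list[tuple[float, ...]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 columns, got {len(parts)}")
            try:
                values = tuple(float(p) for p in parts[:3])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric value in {line!r}") from None
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}: line {lineno}: inconsistent column count "
                    f"({len(values)} vs {ncols})"
                )
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    q = data[:, 0] * factor
    if np.any(np.diff(q) <= 0):
        bad = int(np.nonzero(np.diff(q) <= 0)[0][0]) + 2
        raise ParseError(f"{path}: Q not strictly increasing at data row {bad}")
    inten = data[:, 1]
    meta = {"source": str(path), "unit_in": unit}
    if data.shape[1] >= 3:
        sigma = data[:, 2]
    else:
        if noise_model is None:
            from .synthetic import NoiseModel

            noise_model = NoiseModel()
        sigma = noise_model.sigma(inten)
        meta["sigma_synthesised"] = (
            f"relative={noise_model.relative_sigma} floor={noise_model.sigma_floor}"
        )
        logger.warning(
            "%s: 2-column input; sigma synthesised with %.3g relative error",
            path,
            noise_model.relative_sigma,
        )
    return ScatteringCurve(QGrid(q), inten, sigma, meta)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a 3-column text file (Q nm^-1, I, sigma) with a provenance header."""
    with open(path, "w") as fh:
        fh.write("# vesiclesaxs scattering curve\n")
        fh.write("# unit: nm^-1\n")
        for key, value in curve.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: Q intensity sigma\n")
        for q, i, s in zip(curve.grid.values, curve.intensity, curve.sigma):
            fh.write(f"{q:.9g} {i:.9g} {s:.9g}\n")
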