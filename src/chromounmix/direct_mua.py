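"""Direct absorption-coefficient calculation from slab measurements.

For a thin tissue slab, light is either transmitted, reflected or absorbed,
so the absorption coefficient follows directly from the total transmittance
Tt and total reflectance Rt measured with an integrating sphere:

    mu_a(lambda) = (1 - (Tt + Rt)) / d        [1/cm, d the slab thickness]

Per-sample spectra are aggregated into a per-condition ensemble (mean and
sample SD), which is the fit target and quality envelope of the unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_library import GridMismatchError, WavelengthGrid

__all__ = [
    "SampleMeasurement",
    "AbsorptionSpectrum",
    "AbsorptionEnsemble",
    "compute_mua",
    "ensemble_stats",
    "forward_ttrt",
]


@dataclass(frozen=True)
class SampleMeasurement:
    """One sample's Tt(lambda), Rt(lambda) and slab thickness.

    Tt and Rt are dimensionless fractions in [0, 1]; thickness is in cm
    (0.5 mm slabs -> 0.05 cm).
    """

    sample_id: str
    condition: str
    grid: WavelengthGrid
    Tt: np.ndarray
    Rt: np.ndarray
    thickness_cm: float

    def __post_init__(self) -> None:
        Tt = np.asarray(self.Tt, dtype=float)
        Rt = np.asarray(self.Rt, dtype=float)
        n = len(self.grid)
        if Tt.shape != (n,) or Rt.shape != (n,):
            raise ValueError(
                f"sample {self.sample_id!r}: Tt/Rt lengths "
                f"({Tt.size}, {Rt.size}) do not match grid length {n}"
            )
        for label, arr in (("Tt", Tt), ("Rt", Rt)):
            bad = ~np.isfinite(arr)
            if bad.any():
                wl = self.grid.values[bad][0]
                raise ValueError(
                    f"sample {self.sample_id!r}: non-finite {label} at {wl:g} nm"
                )
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(
                    f"sample {self.sample_id!r}: {label} outside [0, 1]"
                )
        if not self.thickness_cm > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: thickness must be > 0 cm, "
                f"got {self.thickness_cm!r}"
            )
        object.__setattr__(self, "Tt", Tt)
        object.__setattr__(self, "Rt", Rt)


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """mu_a(lambda) in 1/cm, non-negative, with clipping annotations.

    ``clipped`` marks wavelengths where the raw slab formula went negative
    (Tt + Rt > 1, possible from measurement noise) and was clipped to zero.
    """

    grid: WavelengthGrid
    mua: np.ndarray
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mua = np.asarray(self.mua, dtype=float)
        if mua.shape != (len(self.grid),):
            raise ValueError("mua length does not match grid")
        if not np.all(np.isfinite(mua)):
            raise ValueError("mua contains non-finite values")
        if mua.min() < 0:
            raise ValueError("mua must be non-negative (clip before building)")
        object.__setattr__(self, "mua", mua)
        clipped = self.clipped
        if clipped is None:
            clipped = np.zeros(len(self.grid), dtype=bool)
        clipped = np.asarray(clipped, dtype=bool)
        if clipped.shape != mua.shape:
            raise ValueError("clipped mask length mismatch")
        object.__setattr__(self, "clipped", clipped)

    @property
    def clipped_points(self) -> np.ndarray:
        """Wavelengths (nm) where the raw value was negative."""
        return self.grid.values[self.clipped]


@dataclass(frozen=True)
class AbsorptionEnsemble:
    """Per-condition mu_a curves with their mean and sample SD spectra."""

    condition: str
    members: tuple[AbsorptionSpectrum, ...]
    mean: AbsorptionSpectrum
    sd: np.ndarray
    single_member: bool = False

    @property
    def grid(self) -> WavelengthGrid:
        return self.mean.grid

    def __len__(self) -> int:
        return len(self.members)


def compute_mua(measurement: SampleMeasurement) -> AbsorptionSpectrum:
    """Absorption spectrum of one slab: (1 - (Tt + Rt)) / d, clipped at 0.

    Negative raw values (noise pushing Tt + Rt above 1) are clipped to zero
    and their wavelengths recorded in the result's ``clipped`` mask.
    """
    raw = (1.0 - (measurement.Tt + measurement.Rt)) / measurement.thickness_cm
    clipped = raw < 0
    mua = np.where(clipped, 0.0, raw)
    return AbsorptionSpectrum(grid=measurement.grid, mua=mua, clipped=clipped)


def ensemble_stats(
    members: list[AbsorptionSpectrum], condition: str
) -> AbsorptionEnsemble:
    """Per-wavelength arithmetic mean and sample SD (divisor n - 1).

    A single-member ensemble gets an all-zero SD and a ``single_member``
    annotation so downstream fit-quality checks know the envelope is
    undefined.
    """
    if not members:
        raise ValueError("ensemble needs at least one member spectrum")
    grid = members[0].grid
    bad = [i for i, m in enumerate(members[1:], 1) if not m.grid.matches(grid)]
    if bad:
        raise GridMismatchError(f"members at indices {bad} are on a different grid")
    stack = np.vstack([m.mua for m in members])
    mean = stack.mean(axis=0)
    if len(members) >= 2:
        sd = stack.std(axis=0, ddof=1)
        single = False
    else:
        sd = np.zeros(len(grid))
        single = True
    return AbsorptionEnsemble(
        condition=condition,
        members=tuple(members),
        mean=AbsorptionSpectrum(grid=grid, mua=mean),
        sd=sd,
        single_member=single,
    )


def forward_ttrt(
    mua: AbsorptionSpectrum,
    thickness_cm: float,
    reflectance_fraction: float,
    sample_id: str = "synthetic",
    condition: str = "synthetic",
) -> SampleMeasurement:
    """Exact algebraic inverse of the slab formula, for forward simulation.

    Splits the unabsorbed fraction 1 - mu_a*d into Rt = f*(1 - mu_a*d) and
    Tt = (1 - f)*(1 - mu_a*d).  Only the sum Tt + Rt enters the direct
    calculation, so the split fraction f cannot affect recovered mu_a.
    Requires mu_a*d <= 1 everywhere (otherwise the slab model is
    non-physical).
    """
    if not 0.0 <= reflectance_fraction <= 1.0:
        raise ValueError("reflectance_fraction must be in [0, 1]")
    if not thickness_cm > 0:
        raise ValueError("thickness must be > 0 cm")
    attenuation = mua.mua * thickness_cm
    if attenuation.max() > 1.0:
        wl = mua.grid.values[int(np.argmax(attenuation))]
        raise ValueError(
            f"mu_a * d = {attenuation.max():.4g} > 1 at {wl:g} nm: "
            "non-physical for this slab model (rescale weights or thickness)"
        )
    unabsorbed = 1.0 - attenuation
    Rt = reflectance_fraction * unabsorbed
    Tt = unabsorbed - Rt
    return SampleMeasurement(
        sample_id=sample_id,
        condition=condition,
        grid=mua.grid,
        Tt=Tt,
        Rt=Rt,
        thickness_cm=thickness_cm,
    )
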