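"""FAIR perfusion quantification from global/selective inversion image pairs.

In a FAIR experiment the slice-selective inversion leaves inflowing blood
fully relaxed while the global inversion inverts it, so the difference
``selective - global`` at the inversion time TI is proportional to
perfusion.  With a single TI and a simple one-compartment model the
perfusion in mL/min/100 g is

    f = 60 * lambda * (selective - global) * exp(TI / T1_blood) / (2 * M0 * TI)

where ``lambda`` is the blood-tissue water partition coefficient in
mL/100 g, ``T1_blood`` the longitudinal relaxation time of blood and M0 the
equilibrium signal.  The factor 60 converts 1/s to 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "QuantificationParams",
    "AslSeries",
    "PerfusionMap",
    "compute_perfusion_map",
    "mean_perfusion",
]


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata.

    Defaults follow a renal FAIR True-FISP protocol at 1.5 T: effective
    inversion time 1200 ms, in-plane resolution 2.3 x 1.2 mm, 8 mm slice.
    """

    inversion_time: float = 1.2  # seconds
    pixel_spacing: tuple[float, float] = (2.3, 1.2)  # mm (row, col)
    slice_thickness: float = 8.0  # mm

    def __post_init__(self) -> None:
        if self.inversion_time <= 0:
            raise ValueError("inversion_time must be positive")
        if any(s <= 0 for s in self.pixel_spacing) or self.slice_thickness <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")


@dataclass(frozen=True)
class QuantificationParams:
    """Tissue/blood constants for the single-TI FAIR model.

    lambda_partition : mL/100 g, blood-tissue water partition coefficient
        (literature-standard 80 mL/100 g, i.e. 0.8 mL/g).
    t1_blood : seconds, T1 of arterial blood (1.2 s at 1.5 T).
    m0_floor : fraction of max(M0) below which a pixel is treated as
        background and flagged invalid instead of divided by.
    """

    lambda_partition: float = 80.0
    t1_blood: float = 1.2
    m0_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_partition <= 0 or self.t1_blood <= 0:
            raise ValueError("lambda_partition and t1_blood must be positive")
        if not 0.0 < self.m0_floor < 1.0:
            raise ValueError("m0_floor must lie in (0, 1)")


@dataclass
class AslSeries:
    """One acquisition: an M0 image plus ordered (global, selective) pairs."""

    m0: np.ndarray
    pairs: list[tuple[np.ndarray, np.ndarray]]
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.m0.ndim != 2:
            raise ValueError("m0 must be a 2-D image")
        if len(self.pairs) < 1:
            raise ValueError("series needs at least one global/selective pair")
        self.pairs = [
            (np.asarray(g, dtype=float), np.asarray(s, dtype=float)) for g, s in self.pairs
        ]
        for g, s in self.pairs:
            if g.shape != self.m0.shape or s.shape != self.m0.shape:
                raise ValueError("all images in a series must share one shape")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.m0.shape


@dataclass
class PerfusionMap:
    """Per-pixel perfusion in mL/min/100 g plus a validity mask.

    Invalid pixels (background below the M0 floor) carry value 0 and
    ``valid_mask`` False; they are excluded from ROI means rather than
    propagated as NaN.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must share a shape")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("perfusion values must be finite where valid")


def compute_perfusion_map(
    global_img: np.ndarray,
    selective_img: np.ndarray,
    m0_img: np.ndarray,
    meta: AcquisitionMeta | None = None,
    params: QuantificationParams | None = None,
) -> PerfusionMap:
    """Quantify one global/selective pair against an M0 image.

    Positive perfusion corresponds to selective > global; negative values
    produced by noise are retained, not clipped.
    """
    meta = meta or AcquisitionMeta()
    params = params or QuantificationParams()
    g = np.asarray(global_img, dtype=float)
    s = np.asarray(selective_img, dtype=float)
    m0 = np.asarray(m0_img, dtype=float)
    if not (g.shape == s.shape == m0.shape):
        raise ValueError("global, selective and M0 images must share one shape")
    m0_max = float(np.max(m0))
    if m0_max <= 0:
        raise ValueError("M0 image is non-positive everywhere")
    valid = m0 >= params.m0_floor * m0_max
    dm = s - g
    ti = meta.inversion_time
    values = np.zeros_like(m0)
    factor = 60.0 * params.lambda_partition * np.exp(ti / params.t1_blood) / (2.0 * ti)
    np.divide(factor * dm, m0, out=values, where=valid)
    return PerfusionMap(values=values, valid_mask=valid)


def compute_pair_maps(series: AslSeries, params: QuantificationParams | None = None) -> list[PerfusionMap]:
    """Quantify every pair of a series against its M0 image."""
    return [
        compute_perfusion_map(g, s, series.m0, series.meta, params) for g, s in series.pairs
    ]


def mean_perfusion(pmap: PerfusionMap, mask: np.ndarray) -> float:
    """Arithmetic mean of the map over ``mask`` intersected with the valid region."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.values.shape:
        raise ValueError("mask shape does not match the perfusion map")
    roi = mask & pmap.valid_mask
    if not roi.any():
        raise ValueError("mask does not intersect the valid region of the map")
    return float(pmap.values[roi].mean())
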