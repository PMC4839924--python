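"""Run configuration: every tunable of the pipeline in one serializable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compartments import ClusterParams
from .perfusion import QuantificationParams
from .registration import SearchBounds

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline settings with their protocol-derived defaults.

    ``segment_on`` chooses the image the user delineates ("m0" or
    "global0"); ``quantify_in`` chooses whether each pair is quantified in
    its native frame (the perfusion map is then resampled into the
    reference frame) or after resampling the pair itself ("reference").
    """

    quantification: QuantificationParams = field(default_factory=QuantificationParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    search_bounds: SearchBounds = field(default_factory=SearchBounds)
    scissors_weights: tuple[float, float, float] = (0.43, 0.43, 0.14)
    scissors_sigma: float = 1.0
    registration_sigma: float = 2.0
    stiffness: float = 0.05
    rejection_factor: float = 2.0
    n_select: int = 4
    contour_dilate_px: int = 2
    segment_on: str = "m0"
    quantify_in: str = "native"
    image_warp_order: int = 3  # spline order for resampling signal images
    map_warp_order: int = 1  # spline order for resampling perfusion maps

    def __post_init__(self) -> None:
        if self.segment_on not in ("m0", "global0"):
            raise ValueError("segment_on must be 'm0' or 'global0'")
        if self.quantify_in not in ("native", "reference"):
            raise ValueError("quantify_in must be 'native' or 'reference'")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scissors_weights"] = list(self.scissors_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("quantification", QuantificationParams),
            ("cluster", ClusterParams),
            ("search_bounds", SearchBounds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "scissors_weights" in d:
            d["scissors_weights"] = tuple(d["scissors_weights"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
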