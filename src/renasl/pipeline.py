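"""End-to-end analysis of one FAIR acquisition.

Stages: live-wire delineation on the reference image, stiff affine
contour registration to every pair with residual-error QC, averaging of
the registered global images, k-means compartment separation with
morphological cortex purification, per-pair quantification, selection of
the four good pairs with the highest kidney perfusion, averaging of their
maps and per-compartment summary.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import scissors
from .compartments import (
    CORTEX,
    MEDULLA,
    average_registered_globals,
    cluster_compartments,
    purify_cortex,
)
from .config import RunConfig
from .perfusion import AslSeries, PerfusionMap, compute_perfusion_map, mean_perfusion
from .registration import classify_registration, register_contour
from .transform import warp_image

__all__ = [
    "PerfusionSummary",
    "select_pairs",
    "average_perfusion",
    "summarize",
    "run_acquisition",
]

log = logging.getLogger(__name__)


@dataclass
class PerfusionSummary:
    """Per-compartment perfusion means in mL/min/100 g.

    ``whole_parenchyma`` is the mean over cortex plus medulla (calyces and
    background excluded).  A compartment that is empty after segmentation
    is reported as None.
    """

    whole_parenchyma: float | None
    cortex: float | None
    medulla: float | None
    n_pairs_used: int = 0
    pair_indices_used: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_pairs_used != len(self.pair_indices_used):
            raise ValueError("n_pairs_used must equal len(pair_indices_used)")


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""


def select_pairs(
    per_pair_maps: list[PerfusionMap],
    flags: list[bool],
    kidney_mask: np.ndarray,
    n_select: int = 4,
) -> list[int]:
    """Indices of the good pairs with the highest mean kidney perfusion.

    Pairs are ranked by mean perfusion over the kidney mask; at most
    ``n_select`` are returned (all good pairs, with a warning, if fewer
    are available).  Ties go to the lower acquisition index.
    """
    if len(per_pair_maps) != len(flags):
        raise ValueError("one QC flag per perfusion map is required")
    good = [i for i, ok in enumerate(flags) if ok]
    if not good:
        raise PipelineError("selection: no pairs passed registration QC (see QC report)")
    means = {i: mean_perfusion(per_pair_maps[i], kidney_mask) for i in good}
    ranked = sorted(good, key=lambda i: (-means[i], i))
    if len(ranked) < n_select:
        warnings.warn(
            f"only {len(ranked)} good pairs available; using all of them", stacklevel=2
        )
    return ranked[:n_select]


def average_perfusion(maps: list[PerfusionMap]) -> PerfusionMap:
    """Pixel-wise mean map; a pixel is valid only where all inputs are valid."""
    if not maps:
        raise ValueError("need at least one perfusion map")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("perfusion maps must share one shape")
    values = np.mean([m.values for m in maps], axis=0)
    valid = np.logical_and.reduce([m.valid_mask for m in maps])
    values = np.where(valid, values, 0.0)
    return PerfusionMap(values=values, valid_mask=valid)


def summarize(
    avg_map: PerfusionMap,
    compartment_mask: np.ndarray,
    purified_cortex: np.ndarray | None = None,
) -> PerfusionSummary:
    """Compartment means of the averaged perfusion map.

    ``compartment_mask`` defines the medullary and whole-parenchyma ROIs
    (labels 2 and {2, 3}).  The cortical ROI is ``purified_cortex`` when
    given — the morphological filter exists specifically to guarantee a
    pure cortical ROI and is not meant to shrink the parenchyma.
    """
    compartment_mask = np.asarray(compartment_mask)
    if compartment_mask.shape != avg_map.values.shape:
        raise ValueError("compartment mask and map must share one shape")

    def _mean(region: np.ndarray, name: str) -> float | None:
        roi = region & avg_map.valid_mask
        if not roi.any():
            warnings.warn(f"{name} compartment empty; reported as missing", stacklevel=3)
            return None
        return float(avg_map.values[roi].mean())

    cortex = compartment_mask == CORTEX
    medulla = compartment_mask == MEDULLA
    cortex_roi = cortex if purified_cortex is None else np.asarray(purified_cortex, dtype=bool)
    return PerfusionSummary(
        whole_parenchyma=_mean(cortex | medulla, "parenchyma"),
        cortex=_mean(cortex_roi, "cortex"),
        medulla=_mean(medulla, "medulla"),
    )


def run_acquisition(
    series: AslSeries,
    seeds: list[tuple[int, int]],
    config: RunConfig | None = None,
) -> tuple[PerfusionSummary, dict]:
    """Run the full semiautomatic analysis of one acquisition.

    Returns the perfusion summary plus an artifacts dict (contour, masks,
    registration QC, per-pair and averaged maps) for auditing.  Fully
    deterministic for fixed inputs and configuration.
    """
    config = config or RunConfig()

    # 1. live-wire delineation on the reference image
    try:
        ref_image = series.m0 if config.segment_on == "m0" else series.pairs[0][0]
        contour = scissors.trace_contour(
            ref_image, seeds, weights=config.scissors_weights, sigma=config.scissors_sigma
        )
        kidney_mask = scissors.contour_to_mask(contour, series.shape)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise PipelineError(f"scissors: {exc}") from exc
    log.info("scissors: contour with %d points, kidney area %d px", len(contour), kidney_mask.sum())

    # 2. contour registration to every pair's global image + QC
    try:
        registrations = [
            register_contour(
                contour,
                ref_image,
                g,
                stiffness=config.stiffness,
                search_bounds=config.search_bounds,
                sigma=config.registration_sigma,
            )
            for g, _ in series.pairs
        ]
        flags = classify_registration(registrations, config.rejection_factor)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"registration: {exc}") from exc
    log.info("registration: %d/%d pairs passed QC", sum(flags), len(flags))

    # 3. compartment segmentation on the averaged registered globals
    try:
        avg_global = average_registered_globals(
            series, registrations, order=config.image_warp_order
        )
        compartment_mask = cluster_compartments(
            avg_global, kidney_mask, config.cluster, dilate_px=config.contour_dilate_px
        )
        purified_mask = purify_cortex(compartment_mask)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"compartments: {exc}") from exc
    log.info(
        "compartments: cortex %d px (%d after purification), medulla %d px",
        int((compartment_mask == CORTEX).sum()),
        int((purified_mask == CORTEX).sum()),
        int((compartment_mask == MEDULLA).sum()),
    )

    # 4. per-pair quantification, brought into the reference frame
    try:
        pair_maps = []
        for (g, s), reg in zip(series.pairs, registrations):
            if config.quantify_in == "native":
                m0_native = warp_image(
                    series.m0, reg.transform, reg.center, order=config.image_warp_order
                )
                pm = compute_perfusion_map(g, s, m0_native, series.meta, config.quantification)
                values = warp_image(
                    pm.values, reg.transform, reg.center, inverse=True, order=config.map_warp_order
                )
                valid = (
                    warp_image(pm.valid_mask.astype(float), reg.transform, reg.center, inverse=True)
                    > 0.5
                )
                pair_maps.append(PerfusionMap(values=np.where(valid, values, 0.0), valid_mask=valid))
            else:
                g_ref = warp_image(
                    g, reg.transform, reg.center, inverse=True, order=config.image_warp_order
                )
                s_ref = warp_image(
                    s, reg.transform, reg.center, inverse=True, order=config.image_warp_order
                )
                pair_maps.append(
                    compute_perfusion_map(g_ref, s_ref, series.m0, series.meta, config.quantification)
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"quantification: {exc}") from exc

    # 5. top-pair selection, averaging and summary
    selected = select_pairs(pair_maps, flags, kidney_mask, config.n_select)
    avg_map = average_perfusion([pair_maps[i] for i in selected])
    summary = summarize(avg_map, compartment_mask, purified_cortex=purified_mask == CORTEX)
    summary = dataclasses.replace(
        summary, n_pairs_used=len(selected), pair_indices_used=tuple(selected)
    )
    log.info("summary: %s (pairs %s)", summary, selected)

    artifacts = {
        "contour": contour,
        "kidney_mask": kidney_mask,
        "registrations": registrations,
        "qc_flags": flags,
        "avg_global": avg_global,
        "compartment_mask": compartment_mask,
        "purified_mask": purified_mask,
        "pair_maps": pair_maps,
        "selected_pairs": selected,
        "avg_map": avg_map,
    }
    return summary, artifacts
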