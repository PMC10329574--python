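"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np

from polypval import (
    Box,
    ImageRecord,
    Prediction,
    RasterRegion,
    ReferenceObject,
)
from polypval.synth import CenterProfile, PerturbationModel, StudySpec


def mask_from_strings(*rows: str, x0: int = 0, y0: int = 0) -> RasterRegion:
    """Build a mask region from strings of '1'/'0', e.g. M('110', '011')."""
    arr = np.array([[ch == "1" for ch in row] for row in rows], dtype=bool)
    return RasterRegion("mask", x0, y0, arr)


def ref(ref_id: str, image_id: str, mask: RasterRegion,
        polyp_type: str = "protruded") -> ReferenceObject:
    return ReferenceObject(ref_id, image_id, mask, polyp_type)


def image(image_id: str, width: int = 32, height: int = 32,
          center_id: str = "c1", patient_id: str = "p1") -> ImageRecord:
    return ImageRecord(image_id, width, height, center_id, patient_id)


def pred(pred_id: str, image_id: str, box: Box, conf: float) -> Prediction:
    return Prediction(pred_id, image_id, box, conf)


def small_study_spec(seed: int, n_images: int = 40, n_centers: int = 2,
                     resolution: tuple[int, int] = (960, 540),
                     **perturbation_kwargs) -> StudySpec:
    """A scaled-down two-center study for fast property tests.

    Keeps the default perturbation model and mixtures; only image counts and
    resolution are reduced so one dataset generates in well under a second.
    """
    centers = tuple(
        CenterProfile(
            center_id=f"c{i+1}",
            n_images=n_images,
            prevalence=(0.95, 0.8, 0.9)[i % 3],
            resolution=resolution,
        )
        for i in range(n_centers)
    )
    return StudySpec(centers=centers,
                     perturbation=PerturbationModel(**perturbation_kwargs),
                     seed=seed)
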