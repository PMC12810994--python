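"""Vessel Enhanced-Attention (VEA) modality construction.

The second training channel for the downstream segmentation network is
built by min–max normalising the vesselness response to [0, 1] and
multiplying it voxelwise into the original TOF-MRA image: vascular
regions keep their intensity while non-vessel tissue is pulled toward
zero, steering the network's attention to aneurysm-prone regions.
Channel files follow the nnU-Net suffix convention ``_0000`` (original)
and ``_0001`` (VEA).

The VEA channel is always computed from the full volume and cropped
afterwards; multiplication and cropping commute, so channel values do
not depend on the crop box.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import GridMismatchError, Volume3D, write_nifti
from .roi import RoiResult, crop_to_box
from .vessel import ScaleSpaceParams, VesselnessResponse, multiscale_vesselness

__all__ = ["NormalizedResponse", "normalize_minmax", "vea_image", "prepare_modalities"]


@dataclass
class NormalizedResponse(VesselnessResponse):
    """Vesselness rescaled to span [0, 1] (all zeros for constant input)."""


def normalize_minmax(response: VesselnessResponse) -> NormalizedResponse:
    """Min–max rescale so a non-constant response spans exactly [0, 1].

    A constant response (no detectable structure) maps to all zeros, so
    the multiplicative mask suppresses everything rather than passing an
    arbitrary constant through.
    """
    data = np.asarray(response.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return NormalizedResponse(
        data=out, spacing=response.spacing, origin_offset=response.origin_offset
    )


def vea_image(original: Volume3D, weights: NormalizedResponse) -> Volume3D:
    """Voxelwise product of the original image with the attention weights."""
    if original.shape != weights.shape:
        raise GridMismatchError(
            f"image grid {original.shape} != weight grid {weights.shape}"
        )
    return original.with_data(np.asarray(original.data, dtype=np.float64) * weights.data)


def prepare_modalities(
    original: Volume3D,
    case_id: str,
    out_dir,
    params: ScaleSpaceParams | None = None,
    roi: RoiResult | None = None,
) -> dict:
    """Write the two nnU-Net training channels for one case.

    ``<case_id>_0000.nii.gz`` holds the original image and
    ``<case_id>_0001.nii.gz`` the VEA image; if ``roi`` is given, both
    channels are cropped with the same box so they stay voxel-aligned.

    Returns a dict mapping channel index to the written path.
    """
    if not case_id or any(ch in case_id for ch in "/\\"):
        raise ValueError(f"invalid case_id {case_id!r}")
    params = params or ScaleSpaceParams()
    response = roi.response if (roi is not None and roi.response is not None) else None
    if response is None:
        response = multiscale_vesselness(original, params)
    vea = vea_image(original, normalize_minmax(response))

    ch0, ch1 = original, vea
    if roi is not None:
        ch0 = crop_to_box(ch0, roi.box)
        ch1 = crop_to_box(ch1, roi.box)

    out_dir = Path(out_dir)
    paths = {}
    for idx, vol in ((0, ch0), (1, ch1)):
        path = out_dir / f"{case_id}_{idx:04d}.nii.gz"
        write_nifti(vol, path)
        paths[idx] = path
    return paths
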