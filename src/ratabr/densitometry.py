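"""DAB immunostaining densitometry.

Implements the field-based densitometric workflow used to quantify
immunostaining of synaptic markers (e.g. VGLUT1, VGAT) in cochlear-nucleus
subdivisions:

1. an 8-bit inverted grayscale is taken from the red channel of the colour
   micrograph, so 0 = white (no staining) and 255 = black (dense DAB);
2. the field is normalised (robust 1–99 percentile linear stretch);
3. pixels strictly above the field mean + 2 SD are labelled as immunostained
   profiles;
4. two indices are measured per field: the mean gray level over labelled
   pixels (a proxy for protein level in terminals) and the summed labelled
   area (extent of expression);
5. fields are aggregated per subject and per group × subdivision.

The field is the statistical unit fed to the ANOVA layer, matching the
degrees of freedom this kind of analysis reports (e.g. F(2, 58) from three
groups of ~20 fields); a per-subject aggregation is also produced for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

SUBDIVISIONS = ("AVCN", "PVCN")
POSITIONS = ("dorsal", "middle", "ventral")


@dataclass
class MicrographField:
    """One immunostaining field in inverted 8-bit gray (0 white … 255 black)."""

    pixels: np.ndarray
    subdivision: str = "AVCN"
    position: str = "middle"
    subject: str = ""
    group: str = ""
    pixel_size_um: Optional[float] = None     # μm per pixel edge
    truth_mask: Optional[np.ndarray] = None   # ground-truth signal pixels (synthetic)
    is_inverted: bool = True
    normalize_warning: bool = False
    placement_log: Optional[List[dict]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError("field pixels must be a 2-D matrix")
        if min(self.pixels.shape) < 64:
            raise InputError("field smaller than 64×64 pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise InputError("gray values must lie in [0, 255]")
        if self.truth_mask is not None and self.truth_mask.shape != self.pixels.shape:
            raise InputError("truth mask shape mismatch")

    @property
    def area_px(self) -> int:
        return int(self.pixels.size)

    def replace_pixels(self, pixels: np.ndarray, **flags) -> "MicrographField":
        out = MicrographField(
            pixels=pixels,
            subdivision=self.subdivision,
            position=self.position,
            subject=self.subject,
            group=self.group,
            pixel_size_um=self.pixel_size_um,
            truth_mask=self.truth_mask,
            is_inverted=True,
            normalize_warning=flags.get("normalize_warning", self.normalize_warning),
            placement_log=self.placement_log,
        )
        return out


@dataclass
class DensitometryResult:
    """Indices measured on one field."""

    mean_gray: Optional[float]        # over labelled pixels; None if mask empty
    labeled_area_px: int
    labeled_area_um2: Optional[float]
    threshold_used: float
    subdivision: str = "AVCN"
    position: str = "middle"
    subject: str = ""
    group: str = ""
    field_area_px: int = 0


def to_inverted_gray(image: np.ndarray, already_inverted: bool = False) -> np.ndarray:
    """Red channel of a colour micrograph as inverted 8-bit gray.

    Stronger DAB staining is darker in the raw image, so the red channel is
    inverted (255 − red) to give an optical-density-like scale with
    0 = white and 255 = black.  Pass ``already_inverted=True`` for a
    single-channel image that is already on that scale (the call is then the
    identity).  Images deeper than 8 bits are linearly rescaled to 0–255.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        if img.shape[2] < 3:
            raise InputError("colour image lacks an RGB channel triplet")
        chan = img[..., 0]
    elif img.ndim == 2:
        chan = img
    else:
        raise InputError("expected a 2-D gray or 3-D colour image")

    if chan.dtype == np.uint16:
        chan = (chan.astype(float) * (255.0 / 65535.0)).round().astype(np.uint8)
    elif chan.dtype.kind == "f":
        # float images are assumed to span [0, 1] or [0, 255]
        c = chan.astype(float)
        if c.max() <= 1.0:
            c = c * 255.0
        chan = np.clip(c, 0, 255).round().astype(np.uint8)
    else:
        chan = chan.astype(np.uint8)

    if already_inverted and img.ndim == 2:
        return chan
    return (255 - chan.astype(np.int16)).astype(np.uint8)


def normalize_field(
    fld: MicrographField, low_pct: float = 1.0, high_pct: float = 99.0
) -> MicrographField:
    """Robust linear stretch mapping the 1st→0 and 99th→255 percentiles.

    The output pixels are float64 in [0, 255]; rank order is preserved and
    the mapping is exactly invariant (up to clipping) to affine gray-level
    changes of the input.  A constant field is returned unchanged with
    ``normalize_warning`` set.
    """
    x = fld.pixels.astype(float)
    p_lo, p_hi = np.percentile(x, [low_pct, high_pct])
    if p_hi <= p_lo:
        return fld.replace_pixels(fld.pixels, normalize_warning=True)
    out = np.clip((x - p_lo) * (255.0 / (p_hi - p_lo)), 0.0, 255.0)
    return fld.replace_pixels(out)


def label_profiles(
    fld: MicrographField, sd_multiplier: float = 2.0
) -> Tuple[np.ndarray, float]:
    """Boolean mask of immunostained profiles: pixels > field mean + 2 SD.

    Returns ``(mask, threshold_used)``.  The mean and SD are those of the
    full field (population SD); the comparison is strict, so a uniform field
    labels nothing.
    """
    x = fld.pixels.astype(float)
    thr = float(x.mean() + sd_multiplier * x.std())
    return x > thr, thr


def measure_field(
    fld: MicrographField,
    mask: np.ndarray,
    threshold_used: float = float("nan"),
    mean_gray_mode: str = "labeled",
) -> DensitometryResult:
    """Mean gray level and summed labelled area for one field.

    ``mean_gray_mode="labeled"`` (default) averages over labelled pixels
    only; ``"whole-field"`` averages over the entire field.  An empty mask
    yields ``mean_gray=None`` and zero area.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fld.pixels.shape:
        raise InputError("mask shape does not match field")
    if mean_gray_mode not in ("labeled", "whole-field"):
        raise InputError(f"unknown mean_gray_mode: {mean_gray_mode!r}")
    x = fld.pixels.astype(float)
    n = int(mask.sum())
    if mean_gray_mode == "whole-field":
        mean_gray: Optional[float] = float(x.mean())
    else:
        mean_gray = float(x[mask].mean()) if n else None
    area_um2 = n * fld.pixel_size_um**2 if fld.pixel_size_um else None
    return DensitometryResult(
        mean_gray=mean_gray,
        labeled_area_px=n,
        labeled_area_um2=area_um2,
        threshold_used=threshold_used,
        subdivision=fld.subdivision,
        position=fld.position,
        subject=fld.subject,
        group=fld.group,
        field_area_px=fld.area_px,
    )


def quantify_field(
    fld: MicrographField,
    sd_multiplier: float = 2.0,
    normalize: bool = True,
    mean_gray_mode: str = "labeled",
) -> DensitometryResult:
    """Full per-field pipeline: normalise → threshold → measure."""
    work = normalize_field(fld) if normalize else fld
    mask, thr = label_profiles(work, sd_multiplier)
    return measure_field(work, mask, threshold_used=thr, mean_gray_mode=mean_gray_mode)


def results_frame(results: Sequence[DensitometryResult]) -> pd.DataFrame:
    """Tidy field-level table of densitometry results."""
    rows = [
        {
            "subject": r.subject,
            "group": r.group,
            "subdivision": r.subdivision,
            "position": r.position,
            "mean_gray": np.nan if r.mean_gray is None else r.mean_gray,
            "labeled_area_px": r.labeled_area_px,
            "labeled_area_um2": np.nan if r.labeled_area_um2 is None else r.labeled_area_um2,
            "threshold_used": r.threshold_used,
            "field_area_px": r.field_area_px,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "subdivision", "position", "mean_gray",
            "labeled_area_px", "labeled_area_um2", "threshold_used", "field_area_px",
        ],
    )


def aggregate(results: Sequence[DensitometryResult]) -> Dict[str, pd.DataFrame]:
    """Per-subject and per-group × subdivision summaries of field indices.

    Returns a dict with keys ``fields`` (tidy per-field table), ``subjects``
    (mean over a subject's fields and sections) and ``groups`` (mean ± SD
    across subjects, plus field counts).  Empty input yields empty tables.
    """
    fields = results_frame(results)
    if fields.empty:
        empty = pd.DataFrame()
        return {"fields": fields, "subjects": empty, "groups": empty}
    if fields["subdivision"].nunique() > 1 and (fields["subdivision"] == "").any():
        raise InputError("mixed subdivisions with missing tags")

    metrics = ["mean_gray", "labeled_area_px"]
    subjects = (
        fields.groupby(["group", "subdivision", "subject"], as_index=False)[metrics]
        .mean()
        .sort_values(["group", "subdivision", "subject"])
        .reset_index(drop=True)
    )
    groups = (
        subjects.groupby(["group", "subdivision"])[metrics]
        .agg(["mean", "std"])
    )
    groups.columns = ["_".join(c) for c in groups.columns]
    counts = fields.groupby(["group", "subdivision"]).size().rename("n_fields")
    n_subj = subjects.groupby(["group", "subdivision"]).size().rename("n_subjects")
    groups = groups.join(counts).join(n_subj).reset_index()
    return {"fields": fields, "subjects": subjects, "groups": groups}
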