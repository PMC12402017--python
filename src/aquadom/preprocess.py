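"""EEM conditioning chain.

Order used by the pipeline: blank subtraction -> scatter excision
(mask or interpolate) -> dilution back-correction -> QSU normalization.
Inner-filter effects are handled by dilution screening against an A254
threshold, mirroring standard practice for low-turbidity waters, rather
than by an absorbance-based correction formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import EEM, UVSpectrum, ValidationError
from .synthetic import RAMAN_SHIFT_CM

__all__ = [
    "PreprocessConfig",
    "IFEDecision",
    "excise_scatter",
    "inner_filter_screen",
    "apply_dilution_correction",
    "qsu_normalize",
    "blank_subtract",
    "preprocess_eem",
]


@dataclass
class PreprocessConfig:
    """Tunable knobs of the conditioning chain.

    Halfwidths are in nm around each scatter line; ``ife_threshold`` is
    the A254 ceiling (1 cm path) above which a sample must be diluted;
    ``qsu_reference_intensity`` is the raw-count intensity of the
    0.01 mg/L quinine sulfate standard at ex 350 / em 450 nm.
    """

    rayleigh1_halfwidth: float = 15.0
    rayleigh2_halfwidth: float = 15.0
    raman_shift: float = RAMAN_SHIFT_CM
    raman_halfwidth: float = 10.0
    ife_threshold: float = 0.05
    excision_mode: str = "mask"          # or "interpolate"
    qsu_reference_intensity: float = 1.0

    def __post_init__(self) -> None:
        if min(self.rayleigh1_halfwidth, self.rayleigh2_halfwidth,
               self.raman_halfwidth) <= 0:
            raise ValidationError("scatter halfwidths must be positive")
        if not (0 < self.ife_threshold < 1):
            raise ValidationError("ife_threshold must lie in (0, 1)")
        if self.excision_mode not in ("mask", "interpolate"):
            raise ValidationError("excision_mode must be 'mask' or 'interpolate'")
        if self.qsu_reference_intensity <= 0:
            raise ValidationError("qsu_reference_intensity must be positive")


@dataclass
class IFEDecision:
    """Outcome of the inner-filter screening for one sample."""

    sample_id: str
    a254: float
    needs_dilution: bool
    suggested_factor: float


def scatter_mask(eem: EEM, cfg: PreprocessConfig) -> np.ndarray:
    """Boolean mask of first/second-order Rayleigh and Raman scatter cells."""
    em = eem.em_grid[None, :]
    ex = eem.ex_grid[:, None]
    mask = np.abs(em - ex) <= cfg.rayleigh1_halfwidth
    mask |= np.abs(em - 2.0 * ex) <= cfg.rayleigh2_halfwidth
    raman_em = 1.0 / (1.0 / ex - cfg.raman_shift * 1e-7)
    mask |= np.abs(em - raman_em) <= cfg.raman_halfwidth
    return mask


def excise_scatter(eem: EEM, cfg: Optional[PreprocessConfig] = None) -> EEM:
    """Excise scatter regions, by masking or by emission-axis interpolation.

    In ``interpolate`` mode each excised cell is filled by 1-D linear
    interpolation along the emission axis between its nearest unmasked
    neighbors, and the mask is cleared. A gap that touches a grid edge
    has no bracketing pair; there the interpolation is anchored on a
    virtual zero at the responsible scatter line (em = ex for the blue
    edge, em = 2 ex for the red edge), since fluorescence vanishes at
    the excitation line and the anti-Stokes region below it is dark.
    Cells at or below em = ex are set to zero. Unmasked cells are never
    altered.
    """
    cfg = cfg or PreprocessConfig()
    new_mask = scatter_mask(eem, cfg)
    out = eem.copy()
    union = new_mask if out.mask is None else (new_mask | out.mask)
    if cfg.excision_mode == "mask":
        out.mask = union
        return out
    # interpolate mode
    intensity = out.intensity
    em = out.em_grid
    for i in range(intensity.shape[0]):
        bad = union[i]
        if not bad.any():
            continue
        if bad.all():
            raise ValidationError(
                f"sample {eem.sample_id!r}: emission row at ex="
                f"{eem.ex_grid[i]:g} nm is fully masked; cannot interpolate"
            )
        good = ~bad
        ex_i = out.ex_grid[i]
        # virtual zero anchors at the scatter-line centers give edge gaps
        # a bracketing pair: em = ex on the blue side, em = 2 ex on red
        anchors_em = [em[good]]
        anchors_val = [intensity[i, good]]
        if ex_i < em[good][0]:
            anchors_em.append([ex_i])
            anchors_val.append([0.0])
        if 2.0 * ex_i > em[good][-1]:
            anchors_em.append([2.0 * ex_i])
            anchors_val.append([0.0])
        ae = np.concatenate(anchors_em)
        av = np.concatenate(anchors_val)
        order = np.argsort(ae)
        intensity[i, bad] = np.interp(em[bad], ae[order], av[order])
        # anti-Stokes region at or below the excitation line is dark
        intensity[i, em <= ex_i] = 0.0
    out.mask = None
    return out


def inner_filter_screen(uv: UVSpectrum, cfg: Optional[PreprocessConfig] = None) -> IFEDecision:
    """Decide whether a sample needs dilution to avoid inner-filter effects.

    The suggested factor is the smallest power of two bringing A254 at or
    below the threshold; the boundary A254 == threshold is acceptable.
    """
    cfg = cfg or PreprocessConfig()
    if uv.wl_grid.min() > 254 or uv.wl_grid.max() < 254:
        raise ValidationError(f"UV spectrum of {uv.sample_id!r} does not cover 254 nm")
    a254 = float(np.interp(254.0, uv.wl_grid, uv.absorbance))
    if a254 < 0:
        raise ValidationError(f"negative absorbance at 254 nm for {uv.sample_id!r}")
    needs = a254 > cfg.ife_threshold
    factor = 1.0
    while a254 / factor > cfg.ife_threshold:
        factor *= 2.0
    return IFEDecision(
        sample_id=uv.sample_id, a254=a254, needs_dilution=needs,
        suggested_factor=factor,
    )


def apply_dilution_correction(eem: EEM) -> EEM:
    """Rescale a diluted EEM back to the undiluted concentration scale."""
    out = eem.copy()
    out.intensity = out.intensity * out.dilution_factor
    out.dilution_factor = 1.0
    return out


def qsu_normalize(eem: EEM, cfg: Optional[PreprocessConfig] = None) -> EEM:
    """Convert raw instrument counts to quinine sulfate units.

    One QSU is the peak intensity of the 0.01 mg/L quinine standard, so
    normalization is division by the recorded reference intensity.
    """
    cfg = cfg or PreprocessConfig()
    if eem.units == "QSU":
        raise ValidationError(
            f"sample {eem.sample_id!r} is already in QSU; refusing to normalize twice"
        )
    out = eem.copy()
    out.intensity = out.intensity / cfg.qsu_reference_intensity
    out.units = "QSU"
    return out


def blank_subtract(eem: EEM, blank: EEM) -> EEM:
    """Subtract the Milli-Q blank, clip negatives, union the masks."""
    if not eem.grids_equal(blank):
        raise ValidationError(
            f"blank grid does not match sample {eem.sample_id!r}"
        )
    if eem.units != blank.units:
        raise ValidationError("sample and blank must share units")
    out = eem.copy()
    out.intensity = np.clip(out.intensity - blank.intensity, 0.0, None)
    if blank.mask is not None:
        out.mask = blank.mask.copy() if out.mask is None else (out.mask | blank.mask)
    return out


def preprocess_eem(
    eem: EEM,
    blank: Optional[EEM] = None,
    cfg: Optional[PreprocessConfig] = None,
) -> EEM:
    """Full conditioning chain for one sample EEM.

    Blank subtraction (if a blank is given), scatter excision, dilution
    back-correction, and QSU normalization when the input is in raw counts.
    """
    cfg = cfg or PreprocessConfig()
    out = eem
    if blank is not None:
        out = blank_subtract(out, blank)
    out = excise_scatter(out, cfg)
    out = apply_dilution_correction(out)
    if out.units == "raw":
        out = qsu_normalize(out, cfg)
    return out
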