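"""Fluorescence indices for DOM characterization.

Conventions (all wavelengths overridable through :class:`IndexWindows`):

* FI  — fluorescence index, McKnight: I(ex 370, em 470) / I(ex 370, em 520).
  Distinguishes microbial (~1.9) from terrestrial (~1.4) DOM origin.
* HIX — humification index in Ohno's normalized (0-1) form at ex 255 nm
  (nearest 5 nm grid point to the conventional 254 nm):
  sum(em 435-480) / [sum(em 300-345) + sum(em 435-480)].
* BIX — biological index, Huguet: I(ex 310, em 380) / I(ex 310, em 430);
  values near or above 1 indicate autochthonous, recently produced DOM.
* Peak C / Peak T — ratio of the window maxima of the humic-like region
  (ex 320-360, em 420-480) and the tryptophan-like region
  (ex 270-280, em 330-350), after Coble.

All four are intensity ratios and therefore invariant to global scaling
of the EEM; they are meant to be computed on preprocessed (scatter-free,
QSU) matrices. Masked cells are never used silently: touching one raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import EEM, EEMStack, ValidationError

__all__ = [
    "IndexWindows",
    "IndexRecord",
    "fluorescence_index",
    "humification_index",
    "biological_index",
    "peak_ct_ratio",
    "compute_indices",
    "index_table",
]


@dataclass
class IndexWindows:
    """Wavelength conventions for the four indices (nm)."""

    fi_ex: float = 370.0
    fi_em_num: float = 470.0
    fi_em_den: float = 520.0
    hix_ex: float = 255.0
    hix_em_low: tuple = (300.0, 345.0)
    hix_em_high: tuple = (435.0, 480.0)
    hix_normalized: bool = True
    bix_ex: float = 310.0
    bix_em_num: float = 380.0
    bix_em_den: float = 430.0
    peak_c_ex: tuple = (320.0, 360.0)
    peak_c_em: tuple = (420.0, 480.0)
    peak_t_ex: tuple = (270.0, 280.0)
    peak_t_em: tuple = (330.0, 350.0)


@dataclass
class IndexRecord:
    """Per-sample index values with optional replicate standard deviations."""

    sample_id: str
    fi: float
    hix: float
    bix: float
    peak_ct: float
    sd_fi: Optional[float] = None
    sd_hix: Optional[float] = None
    sd_bix: Optional[float] = None
    sd_peak_ct: Optional[float] = None


def _ratio(eem: EEM, ex: float, em_num: float, em_den: float, name: str) -> float:
    num = eem.value_at(ex, em_num)
    den = eem.value_at(ex, em_den)
    if den == 0:
        raise ValidationError(
            f"{name} undefined for {eem.sample_id!r}: zero intensity at "
            f"(ex {ex:g}, em {em_den:g})"
        )
    return num / den


def fluorescence_index(eem: EEM, windows: Optional[IndexWindows] = None) -> float:
    """FI: emission ratio 470/520 nm at excitation 370 nm."""
    w = windows or IndexWindows()
    return _ratio(eem, w.fi_ex, w.fi_em_num, w.fi_em_den, "FI")


def biological_index(eem: EEM, windows: Optional[IndexWindows] = None) -> float:
    """BIX: emission ratio 380/430 nm at excitation 310 nm."""
    w = windows or IndexWindows()
    return _ratio(eem, w.bix_ex, w.bix_em_num, w.bix_em_den, "BIX")


def _window_sum(eem: EEM, i_ex: int, lo: float, hi: float) -> float:
    sel = (eem.em_grid >= lo - 1e-9) & (eem.em_grid <= hi + 1e-9)
    if eem.mask is not None and eem.mask[i_ex, sel].any():
        raise ValidationError(
            f"HIX window em {lo:g}-{hi:g} nm of {eem.sample_id!r} contains masked cells"
        )
    return float(eem.intensity[i_ex, sel].sum())


def humification_index(eem: EEM, windows: Optional[IndexWindows] = None) -> float:
    """HIX at ex ~254 nm; normalized form bounded in [0, 1] by default.

    The classic (unnormalized) ratio high/low is available with
    ``windows.hix_normalized = False``.
    """
    w = windows or IndexWindows()
    i_ex = eem.ex_index(w.hix_ex)
    low = _window_sum(eem, i_ex, *w.hix_em_low)
    high = _window_sum(eem, i_ex, *w.hix_em_high)
    if low + high == 0:
        raise ValidationError(
            f"HIX undefined for {eem.sample_id!r}: both emission windows are zero"
        )
    if w.hix_normalized:
        return high / (high + low)
    if low == 0:
        raise ValidationError(
            f"classic HIX undefined for {eem.sample_id!r}: low window is zero"
        )
    return high / low


def _window_max(eem: EEM, ex_rng: tuple, em_rng: tuple, name: str) -> float:
    ex_sel = (eem.ex_grid >= ex_rng[0] - 1e-9) & (eem.ex_grid <= ex_rng[1] + 1e-9)
    em_sel = (eem.em_grid >= em_rng[0] - 1e-9) & (eem.em_grid <= em_rng[1] + 1e-9)
    block = eem.intensity[np.ix_(ex_sel, em_sel)]
    if eem.mask is not None and eem.mask[np.ix_(ex_sel, em_sel)].any():
        raise ValidationError(
            f"{name} window of {eem.sample_id!r} contains masked cells"
        )
    return float(block.max())


def peak_ct_ratio(eem: EEM, windows: Optional[IndexWindows] = None) -> float:
    """Peak C / Peak T: humic-like over tryptophan-like window maxima."""
    w = windows or IndexWindows()
    peak_c = _window_max(eem, w.peak_c_ex, w.peak_c_em, "Peak C")
    peak_t = _window_max(eem, w.peak_t_ex, w.peak_t_em, "Peak T")
    if peak_t == 0:
        raise ValidationError(
            f"Peak C/T undefined for {eem.sample_id!r}: Peak T window is zero"
        )
    return peak_c / peak_t


def compute_indices(eem: EEM, windows: Optional[IndexWindows] = None) -> dict:
    """All four indices of one EEM as a dict (fi, hix, bix, peak_ct)."""
    return {
        "fi": fluorescence_index(eem, windows),
        "hix": humification_index(eem, windows),
        "bix": biological_index(eem, windows),
        "peak_ct": peak_ct_ratio(eem, windows),
    }


_COLUMNS = ["fi", "hix", "bix", "peak_ct"]


def index_table(
    stack: EEMStack,
    replicate_map: Optional[dict] = None,
    windows: Optional[IndexWindows] = None,
) -> list:
    """Per-sample index records with mean and sd across replicates.

    ``replicate_map`` maps a sample id to the list of stack sample ids
    that are its replicates; by default every EEM is its own single
    replicate. Singleton samples get no sd fields.
    """
    by_id = {e.sample_id: e for e in stack}
    if replicate_map is None:
        replicate_map = {sid: [sid] for sid in stack.sample_ids}
    records = []
    for sid, reps in replicate_map.items():
        vals = pd.DataFrame(
            [compute_indices(by_id[r], windows) for r in reps if r in by_id]
        )
        if vals.empty:
            raise ValidationError(f"no replicates found for sample {sid!r}")
        mean = vals.mean()
        rec = IndexRecord(sample_id=sid, **{c: float(mean[c]) for c in _COLUMNS})
        if len(vals) > 1:
            sd = vals.std(ddof=1)
            rec.sd_fi = float(sd["fi"])
            rec.sd_hix = float(sd["hix"])
            rec.sd_bix = float(sd["bix"])
            rec.sd_peak_ct = float(sd["peak_ct"])
        records.append(rec)
    return records


def records_to_frame(records: Sequence[IndexRecord]) -> pd.DataFrame:
    """Index records as a DataFrame (sample rows, fixed column order)."""
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id, "fi": r.fi, "hix": r.hix,
            "bix": r.bix, "peak_ct": r.peak_ct,
            "sd_fi": r.sd_fi, "sd_hix": r.sd_hix,
            "sd_bix": r.sd_bix, "sd_peak_ct": r.sd_peak_ct,
        })
    return pd.DataFrame(rows).set_index("sample_id")
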