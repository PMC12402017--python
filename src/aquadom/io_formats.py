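"""On-disk formats and canonical in-memory containers.

Axis convention, used everywhere in the package: an EEM is stored with
**rows = excitation** wavelengths and **columns = emission** wavelengths.
The standard acquisition grid is excitation 230-450 nm in 5 nm steps
(45 values) and emission 250-550 nm in 1 nm steps (301 values).

CSV payloads are kept tool-agnostic; per-spectrum metadata (units,
dilution factor, replicate number) travels in a JSON sidecar written next
to the CSV as ``<file>.meta.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EEM",
    "EEMStack",
    "EISSpectrum",
    "UVSpectrum",
    "ParseError",
    "ValidationError",
    "STANDARD_EX_GRID",
    "STANDARD_EM_GRID",
    "standard_grids",
    "read_eem",
    "write_eem",
    "read_eis",
    "write_eis",
    "read_uv",
    "write_uv",
    "read_sample_table",
    "write_sample_table",
]

#: Standard excitation grid: 230..450 nm, 5 nm increments (45 points).
STANDARD_EX_GRID = np.arange(230.0, 450.0 + 2.5, 5.0)
#: Standard emission grid: 250..550 nm, 1 nm increments (301 points).
STANDARD_EM_GRID = np.arange(250.0, 550.0 + 0.5, 1.0)

#: Absolute tolerance for wavelength-grid equality checks (nm), and the
#: relative tolerance for frequency grids (Hz).
GRID_ATOL = 1e-9


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


def standard_grids() -> tuple[np.ndarray, np.ndarray]:
    """Return copies of the standard (excitation, emission) grids."""
    return STANDARD_EX_GRID.copy(), STANDARD_EM_GRID.copy()


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a non-empty 1-D vector")
    return arr


@dataclass
class EEM:
    """One sample's excitation-emission fluorescence matrix.

    Parameters
    ----------
    sample_id : str
        Sample identifier (e.g. ``"R3"``).
    ex_grid, em_grid : ndarray
        Strictly increasing excitation / emission wavelength grids (nm).
    intensity : ndarray, shape (len(ex_grid), len(em_grid))
        Fluorescence intensities; rows are excitation, columns emission.
    units : {"raw", "QSU"}
        Raw instrument counts or quinine sulfate units.
    dilution_factor : float
        Dilution applied before measurement; 1.0 means undiluted.
    mask : ndarray of bool, optional
        True marks excised (invalid) cells, e.g. scatter regions.
    """

    sample_id: str
    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensity: np.ndarray
    units: str = "raw"
    dilution_factor: float = 1.0
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ex_grid = _as_float_vector(self.ex_grid, "ex_grid")
        self.em_grid = _as_float_vector(self.em_grid, "em_grid")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.ex_grid) <= 0):
            raise ValidationError("ex_grid must be strictly increasing")
        if np.any(np.diff(self.em_grid) <= 0):
            raise ValidationError("em_grid must be strictly increasing")
        if self.intensity.shape != (self.ex_grid.size, self.em_grid.size):
            raise ValidationError(
                f"intensity shape {self.intensity.shape} does not match "
                f"grids ({self.ex_grid.size}, {self.em_grid.size})"
            )
        if self.units not in ("raw", "QSU"):
            raise ValidationError(f"units must be 'raw' or 'QSU', got {self.units!r}")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise ValidationError("mask shape does not match intensity")

    # -- convenience -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "EEM":
        return replace(
            self,
            ex_grid=self.ex_grid.copy(),
            em_grid=self.em_grid.copy(),
            intensity=self.intensity.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )

    def ex_index(self, wavelength: float) -> int:
        """Index of the excitation grid point nearest ``wavelength``."""
        return int(np.argmin(np.abs(self.ex_grid - wavelength)))

    def em_index(self, wavelength: float) -> int:
        """Index of the emission grid point nearest ``wavelength``."""
        return int(np.argmin(np.abs(self.em_grid - wavelength)))

    def value_at(self, ex: float, em: float) -> float:
        """Intensity at the grid cell nearest (ex, em), respecting the mask."""
        i, j = self.ex_index(ex), self.em_index(em)
        if self.mask is not None and self.mask[i, j]:
            raise ValidationError(
                f"cell (ex={self.ex_grid[i]:g} nm, em={self.em_grid[j]:g} nm) "
                f"of sample {self.sample_id!r} is masked"
            )
        return float(self.intensity[i, j])

    def grids_equal(self, other: "EEM") -> bool:
        return (
            self.ex_grid.size == other.ex_grid.size
            and self.em_grid.size == other.em_grid.size
            and np.allclose(self.ex_grid, other.ex_grid, atol=GRID_ATOL, rtol=0)
            and np.allclose(self.em_grid, other.em_grid, atol=GRID_ATOL, rtol=0)
        )


@dataclass
class EEMStack:
    """K samples' EEMs on one common grid, the D_k of the trilinear model.

    The augmented matrix used by MCR-ALS is the vertical concatenation of
    the K excitation-mode matrices: shape (K * n_ex, n_em).
    """

    eems: list

    def __post_init__(self) -> None:
        if len(self.eems) == 0:
            raise ValidationError("EEMStack needs at least one EEM")
        ref = self.eems[0]
        for e in self.eems[1:]:
            if not ref.grids_equal(e):
                raise ValidationError(
                    f"sample {e.sample_id!r} is not on the common grid"
                )

    def __len__(self) -> int:
        return len(self.eems)

    def __iter__(self):
        return iter(self.eems)

    def __getitem__(self, i):
        return self.eems[i]

    @property
    def sample_ids(self) -> list:
        return [e.sample_id for e in self.eems]

    @property
    def ex_grid(self) -> np.ndarray:
        return self.eems[0].ex_grid

    @property
    def em_grid(self) -> np.ndarray:
        return self.eems[0].em_grid

    def augmented(self) -> np.ndarray:
        """Column-wise augmented matrix, shape (K*n_ex, n_em)."""
        return np.vstack([e.intensity for e in self.eems])

    def augmented_mask(self) -> Optional[np.ndarray]:
        """Stacked mask aligned with :meth:`augmented`, or None if unmasked."""
        if all(e.mask is None for e in self.eems):
            return None
        n_ex, n_em = self.eems[0].shape
        return np.vstack(
            [e.mask if e.mask is not None else np.zeros((n_ex, n_em), bool) for e in self.eems]
        )


@dataclass
class EISSpectrum:
    """A Bode-phase impedance spectrum: phase angle vs AC frequency."""

    sample_id: str
    freq_grid: np.ndarray
    phase: np.ndarray
    replicate: int = 1
    magnitude: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.freq_grid = _as_float_vector(self.freq_grid, "freq_grid")
        self.phase = _as_float_vector(self.phase, "phase")
        if self.freq_grid.size != self.phase.size:
            raise ValidationError("freq_grid and phase must have equal length")
        if np.any(self.freq_grid <= 0):
            raise ValidationError("frequencies must be positive")
        order = np.argsort(self.freq_grid, kind="stable")
        self.freq_grid = self.freq_grid[order]
        self.phase = self.phase[order]
        if self.magnitude is not None:
            self.magnitude = _as_float_vector(self.magnitude, "magnitude")[order]
        if np.any(np.diff(self.freq_grid) <= 0):
            raise ValidationError("freq_grid contains duplicate frequencies")
        if np.any(np.abs(self.phase) > 90 + 1e-9):
            raise ValidationError("phase angles must lie within [-90, 90] degrees")


@dataclass
class UVSpectrum:
    """A UV-Vis absorption spectrum (1 cm path)."""

    sample_id: str
    wl_grid: np.ndarray
    absorbance: np.ndarray
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.wl_grid = _as_float_vector(self.wl_grid, "wl_grid")
        self.absorbance = _as_float_vector(self.absorbance, "absorbance")
        if self.wl_grid.size != self.absorbance.size:
            raise ValidationError("wl_grid and absorbance must have equal length")
        order = np.argsort(self.wl_grid, kind="stable")
        self.wl_grid = self.wl_grid[order]
        self.absorbance = self.absorbance[order]


# ---------------------------------------------------------------------
# sidecar metadata
# ---------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_sidecar(path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path) -> dict:
    p = _sidecar_path(path)
    if p.exists():
        return json.loads(p.read_text())
    return {}


# ---------------------------------------------------------------------
# EEM readers / writers
# ---------------------------------------------------------------------

def read_eem(path, dialect: str = "wide_csv") -> EEM:
    """Read an EEM from CSV.

    ``wide_csv``: first row holds emission wavelengths, first column holds
    excitation wavelengths, body holds intensities (empty field = masked
    cell). ``long_csv``: three columns ``ex, em, intensity``; an absent
    (ex, em) combination becomes a masked cell.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    sample_id = meta.get("sample_id", path.stem)
    common = dict(
        sample_id=sample_id,
        units=meta.get("units", "raw"),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
    )
    if dialect == "wide_csv":
        try:
            df = pd.read_csv(path, index_col=0, header=0)
        except Exception as exc:  # pragma: no cover - pandas message forwarded
            raise ParseError(f"{path}: cannot parse wide EEM CSV: {exc}") from exc
        try:
            em = np.asarray([float(c) for c in df.columns])
        except ValueError as exc:
            raise ParseError(
                f"{path}: header row contains a non-numeric emission wavelength: {exc}"
            ) from exc
        try:
            ex = np.asarray([float(i) for i in df.index])
        except ValueError as exc:
            raise ParseError(
                f"{path}: first column contains a non-numeric excitation wavelength: {exc}"
            ) from exc
        body = df.to_numpy()
        numeric = np.empty(body.shape, dtype=float)
        for i in range(body.shape[0]):
            for j in range(body.shape[1]):
                v = body[i, j]
                if v is None or (isinstance(v, float) and np.isnan(v)) or (
                    isinstance(v, str) and v.strip() == ""
                ):
                    numeric[i, j] = np.nan
                else:
                    try:
                        numeric[i, j] = float(v)
                    except (TypeError, ValueError):
                        raise ParseError(
                            f"{path}: non-numeric intensity {v!r} at "
                            f"ex={ex[i]:g}, em={em[j]:g}"
                        ) from None
        order_ex = np.argsort(ex)
        order_em = np.argsort(em)
        ex, em = ex[order_ex], em[order_em]
        numeric = numeric[np.ix_(order_ex, order_em)]
        mask = np.isnan(numeric)
        numeric = np.where(mask, 0.0, numeric)
        return EEM(
            ex_grid=ex, em_grid=em, intensity=numeric,
            mask=mask if mask.any() else None, **common,
        )
    elif dialect == "long_csv":
        df = pd.read_csv(path)
        expected = ["ex", "em", "intensity"]
        if list(df.columns[:3]) != expected:
            raise ParseError(
                f"{path}: long EEM CSV must have columns {expected}, "
                f"got {list(df.columns)}"
            )
        if df[["ex", "em"]].duplicated().any():
            dup = df[df[["ex", "em"]].duplicated()].iloc[0]
            raise ParseError(
                f"{path}: duplicate (ex, em) pair ({dup['ex']:g}, {dup['em']:g})"
            )
        ex = np.sort(df["ex"].unique().astype(float))
        em = np.sort(df["em"].unique().astype(float))
        intensity = np.zeros((ex.size, em.size))
        seen = np.zeros((ex.size, em.size), dtype=bool)
        ix = {v: i for i, v in enumerate(ex)}
        jx = {v: j for j, v in enumerate(em)}
        for e_, m_, v_ in df[["ex", "em", "intensity"]].itertuples(index=False):
            i, j = ix[float(e_)], jx[float(m_)]
            intensity[i, j] = float(v_)
            seen[i, j] = True
        mask = ~seen
        return EEM(
            ex_grid=ex, em_grid=em, intensity=intensity,
            mask=mask if mask.any() else None, **common,
        )
    raise ValueError(f"unknown EEM dialect {dialect!r}")


def write_eem(eem: EEM, path, dialect: str = "wide_csv") -> None:
    """Write an EEM as CSV plus a JSON metadata sidecar.

    Masked cells become empty fields (wide dialect) or omitted rows
    (long dialect).
    """
    path = Path(path)
    if dialect == "wide_csv":
        body = eem.intensity.astype(object)
        if eem.mask is not None:
            body[eem.mask] = ""
        df = pd.DataFrame(body, index=eem.ex_grid, columns=eem.em_grid)
        df.index.name = "ex_nm"
        df.to_csv(path)
    elif dialect == "long_csv":
        rows = []
        for i, e_ in enumerate(eem.ex_grid):
            for j, m_ in enumerate(eem.em_grid):
                if eem.mask is not None and eem.mask[i, j]:
                    continue
                rows.append((e_, m_, eem.intensity[i, j]))
        pd.DataFrame(rows, columns=["ex", "em", "intensity"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown EEM dialect {dialect!r}")
    _write_sidecar(path, {
        "sample_id": eem.sample_id,
        "units": eem.units,
        "dilution_factor": eem.dilution_factor,
    })


# ---------------------------------------------------------------------
# EIS / UV / sample table
# ---------------------------------------------------------------------

def read_eis(path) -> EISSpectrum:
    """Read a Bode-phase spectrum from CSV (frequency_hz, phase_deg[, magnitude_ohm])."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frequency_hz", "phase_deg"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: EIS CSV must have columns {sorted(required)}")
    meta = _read_sidecar(path)
    mag = df["magnitude_ohm"].to_numpy(float) if "magnitude_ohm" in df.columns else None
    return EISSpectrum(
        sample_id=meta.get("sample_id", path.stem),
        replicate=int(meta.get("replicate", 1)),
        freq_grid=df["frequency_hz"].to_numpy(float),
        phase=df["phase_deg"].to_numpy(float),
        magnitude=mag,
    )


def write_eis(spec: EISSpectrum, path) -> None:
    path = Path(path)
    data = {"frequency_hz": spec.freq_grid, "phase_deg": spec.phase}
    if spec.magnitude is not None:
        data["magnitude_ohm"] = spec.magnitude
    pd.DataFrame(data).to_csv(path, index=False)
    _write_sidecar(path, {"sample_id": spec.sample_id, "replicate": spec.replicate})


def read_uv(path) -> UVSpectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"wavelength_nm", "absorbance"}.issubset(df.columns):
        raise ParseError(f"{path}: UV CSV must have columns wavelength_nm, absorbance")
    meta = _read_sidecar(path)
    return UVSpectrum(
        sample_id=meta.get("sample_id", path.stem),
        wl_grid=df["wavelength_nm"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
    )


def write_uv(spec: UVSpectrum, path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spec.wl_grid, "absorbance": spec.absorbance}
    ).to_csv(path, index=False)
    _write_sidecar(path, {
        "sample_id": spec.sample_id, "dilution_factor": spec.dilution_factor,
    })


SAMPLE_TABLE_COLUMNS = ["temperature_c", "ph", "conductivity_us"]


def read_sample_table(path) -> pd.DataFrame:
    """Read the in-situ physicochemical table (temperature, pH, conductivity).

    Returns a DataFrame indexed by sample_id. Missing values stay as NaN;
    they are flagged, never dropped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["sample_id"] + SAMPLE_TABLE_COLUMNS
    if list(df.columns) != expected:
        raise ParseError(f"{path}: sample table header must be {','.join(expected)}")
    df = df.set_index("sample_id")
    df = df.astype(float)
    bad_ph = df["ph"].dropna()
    if ((bad_ph < 0) | (bad_ph > 14)).any():
        offenders = bad_ph[(bad_ph < 0) | (bad_ph > 14)].index.tolist()
        raise ValidationError(f"pH outside [0, 14] for samples {offenders}")
    cond = df["conductivity_us"].dropna()
    if (cond < 0).any():
        raise ValidationError("negative conductivity")
    df.attrs["missing"] = {
        col: df.index[df[col].isna()].tolist() for col in df.columns if df[col].isna().any()
    }
    return df


def write_sample_table(table: pd.DataFrame, path) -> None:
    out = table.reset_index()
    out.columns = ["sample_id"] + list(table.columns)
    out.to_csv(path, index=False)
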