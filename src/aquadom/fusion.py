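"""Multi-block data fusion and end-to-end orchestration.

The fused table horizontally concatenates, for the EIS-measured sample
subset, five blocks of per-sample variables:

    [Temp, pH, Cond | EISpc1, EISpc2 | uv254 | FI, HIX, BIX, PeakC/PeakT
     | C1..Cnc MCR contributions]

(3 + 2 + 1 + 4 + nc columns; 16 for the study configuration of two kept
EIS components and six DOM fractions). The table is autoscaled
(column-wise mean 0, sd 1 with the n-1 denominator) and decomposed by a
global PCA whose biplot relates samples to the variables driving their
separation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats as iof
from .indices import IndexRecord, IndexWindows, index_table, records_to_frame
from .io_formats import EEMStack, UVSpectrum, ValidationError
from .mcr import MCRResult, fit_mcr_trilinear
from .pca import PCAModel, assemble_eis_matrix, average_replicate_scores, fit_pca
from .preprocess import PreprocessConfig, preprocess_eem
from .synthetic import Campaign, simulate_campaign

__all__ = [
    "PHYSCHEM_COLUMNS",
    "extract_uv254",
    "build_fused_table",
    "run_global_pca",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("aquadom")

PHYSCHEM_COLUMNS = ["Temp", "pH", "Cond"]
INDEX_COLUMNS = ["FI", "HIX", "BIX", "PeakC/PeakT"]


def extract_uv254(uv: UVSpectrum, dilution_factor: float = 1.0) -> float:
    """Absorbance at 254 nm, back-corrected to the undiluted scale.

    Uses the grid point at 254 nm, or linear interpolation when 254 nm
    is not on the grid.
    """
    if uv.wl_grid.min() > 254 or uv.wl_grid.max() < 254:
        raise ValidationError(
            f"UV spectrum of {uv.sample_id!r} does not cover 254 nm"
        )
    a254 = float(np.interp(254.0, uv.wl_grid, uv.absorbance))
    return a254 * dilution_factor


def build_fused_table(
    samples: pd.DataFrame,
    eis_scores: pd.DataFrame,
    uv254: pd.Series,
    idx: Sequence[IndexRecord],
    frac: pd.DataFrame,
) -> pd.DataFrame:
    """Horizontally concatenate the five per-sample variable blocks.

    All blocks must cover exactly the same sample ids (the rows of
    ``eis_scores`` define the subset and the row order). Column order is
    the fixed contract [Temp, pH, Cond | EISpc1.. | uv254 | FI, HIX,
    BIX, PeakC/PeakT | C1..Cnc].
    """
    target = list(eis_scores.index)
    idx_frame = records_to_frame(idx)[["fi", "hix", "bix", "peak_ct"]]
    blocks = {
        "physicochemical": samples,
        "eis_scores": eis_scores,
        "uv254": uv254.to_frame("uv254") if isinstance(uv254, pd.Series) else uv254,
        "indices": idx_frame,
        "mcr_fractions": frac,
    }
    for name, block in blocks.items():
        missing = sorted(set(target) - set(block.index))
        extra = sorted(set(block.index) - set(target))
        if missing:
            raise ValidationError(
                f"block {name!r} is missing samples {missing}"
                + (f" (and has extra {extra})" if extra else "")
            )
    n_eis = eis_scores.shape[1]
    nc = frac.shape[1]
    table = pd.concat(
        [
            samples.loc[target, ["temperature_c", "ph", "conductivity_us"]]
            .set_axis(PHYSCHEM_COLUMNS, axis=1),
            eis_scores.loc[target].set_axis(
                [f"EISpc{i + 1}" for i in range(n_eis)], axis=1
            ),
            blocks["uv254"].loc[target, ["uv254"]],
            idx_frame.loc[target].set_axis(INDEX_COLUMNS, axis=1),
            frac.loc[target].set_axis([f"C{i + 1}" for i in range(nc)], axis=1),
        ],
        axis=1,
    )
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValidationError(f"fused table has missing cells in columns {bad}")
    table.attrs["blocks"] = {
        "physicochemical": 3, "eis_scores": n_eis, "uv254": 1,
        "indices": 4, "mcr_fractions": nc,
    }
    return table


def run_global_pca(table: pd.DataFrame, nc_kept: int = 2):
    """Autoscaled PCA of the fused table; returns the model and biplot data."""
    model = fit_pca(
        table.to_numpy(float), preprocessing="autoscale", nc_kept=nc_kept,
        row_labels=list(table.index),
    )
    cols = [f"pc{c + 1}" for c in range(model.T.shape[1])]
    biplot = {
        "scores": pd.DataFrame(model.T, index=table.index, columns=cols),
        "loadings": pd.DataFrame(model.P, index=table.columns, columns=cols),
        "explained": model.explained.tolist(),
    }
    return model, biplot


# ---------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run configuration for the end-to-end workflow.

    Either ``input_dir`` (canonical CSV layouts) or ``simulate=True``
    must be given. ``nc`` is the number of MCR components; ``eis_pcs``
    the number of EIS principal components kept for fusion.
    """

    outdir: str = "aquadom_run"
    simulate: bool = True
    input_dir: Optional[str] = None
    seed: int = 0
    n_rivers: int = 9
    noise_sigma: Optional[float] = None
    add_scatter: bool = True
    nc: int = 6
    max_iter: int = 200
    tol: float = 1e-6
    trilinearity: bool = True
    eis_pcs: int = 2
    eis_smooth: bool = True
    excision_mode: str = "interpolate"
    ife_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    """Artifacts of one pipeline run."""

    outdir: Path
    stack: EEMStack
    indices: list
    mcr: MCRResult
    eis_model: Optional[PCAModel]
    fused_table: Optional[pd.DataFrame]
    global_model: Optional[PCAModel]
    biplot: Optional[dict]


def _load_campaign(input_dir: str) -> Campaign:
    """Load a campaign from the canonical on-disk layout written by `simulate`."""
    d = Path(input_dir)
    eems = [iof.read_eem(p, "wide_csv") for p in sorted(d.glob("eem_*.csv"))]
    if not eems:
        raise ValidationError(f"no eem_*.csv files under {d}")
    eis = [iof.read_eis(p) for p in sorted(d.glob("eis_*.csv"))]
    uv = [iof.read_uv(p) for p in sorted(d.glob("uv_*.csv"))]
    table = iof.read_sample_table(d / "samples.csv")
    eis_ids: list = []
    for s in eis:
        if s.sample_id not in eis_ids:
            eis_ids.append(s.sample_id)
    return Campaign(
        stack=EEMStack(eems), eis=eis, uv=uv, sample_table=table,
        truth=None, eis_sample_ids=eis_ids,
    )


def save_campaign(campaign: Campaign, outdir) -> None:
    """Write a campaign in the canonical CSV/JSON layout."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    for eem in campaign.stack:
        iof.write_eem(eem, d / f"eem_{eem.sample_id}.csv", "wide_csv")
    for s in campaign.eis:
        iof.write_eis(s, d / f"eis_{s.sample_id}_{s.replicate}.csv")
    for u in campaign.uv:
        iof.write_uv(u, d / f"uv_{u.sample_id}.csv")
    iof.write_sample_table(campaign.sample_table, d / "samples.csv")
    if campaign.truth is not None:
        truth = campaign.truth
        (d / "truth.json").write_text(json.dumps({
            "components": [
                {
                    "name": c.name, "ex_center": c.ex_center,
                    "ex_sigma": c.ex_sigma, "em_center": c.em_center,
                    "em_sigma": c.em_sigma,
                    "secondary_ex_center": c.secondary_ex_center,
                }
                for c in truth.components
            ],
            "C_true": truth.C_true.tolist(),
            "noise_sigma": truth.noise_sigma,
            "seed": truth.seed,
        }, indent=1))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow: data -> preprocess -> indices ->
    MCR-ALS -> EIS PCA -> fusion -> global PCA.

    Every stage logs its parameters; a rerun with the same config and
    seed reproduces the final fused table exactly. A campaign without
    EIS spectra completes with the fusion stage skipped and a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handlers = [logging.FileHandler(log_path), logging.StreamHandler()]
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(logging.INFO)
    try:
        return _run_pipeline_inner(config, outdir)
    finally:
        for h in handlers:
            logger.removeHandler(h)
            h.close()


def _run_pipeline_inner(config: PipelineConfig, outdir: Path) -> PipelineResult:
    # stage A: acquire
    if config.simulate:
        logger.info(
            "stage A: simulating campaign (n_rivers=%d, seed=%d)",
            config.n_rivers, config.seed,
        )
        campaign = simulate_campaign(
            n_rivers=config.n_rivers, seed=config.seed,
            noise_sigma=config.noise_sigma, add_scatter=config.add_scatter,
        )
        save_campaign(campaign, outdir / "inputs")
    elif config.input_dir:
        logger.info("stage A: loading campaign from %s", config.input_dir)
        campaign = _load_campaign(config.input_dir)
    else:
        raise ValidationError("config must set simulate=True or input_dir")

    # stage B: preprocess EEMs (blank-aware dilution screening)
    cfg = PreprocessConfig(
        excision_mode=config.excision_mode, ife_threshold=config.ife_threshold,
    )
    logger.info("stage B: preprocessing %d EEMs (mode=%s)",
                len(campaign.stack), cfg.excision_mode)
    try:
        pre = EEMStack([preprocess_eem(e, cfg=cfg) for e in campaign.stack])
    except ValidationError as exc:
        raise ValidationError(f"stage B (preprocess) failed: {exc}") from exc

    # stage C1: fluorescence indices
    logger.info("stage C: fluorescence indices")
    try:
        records = index_table(pre)
    except ValidationError as exc:
        raise ValidationError(f"stage C (indices) failed: {exc}") from exc
    records_to_frame(records).to_csv(outdir / "indices.csv")

    # stage C2: MCR-ALS decomposition
    logger.info("stage C: MCR-ALS (nc=%d, trilinear=%s)", config.nc, config.trilinearity)
    try:
        mcr_result = fit_mcr_trilinear(
            pre, nc=config.nc, max_iter=config.max_iter, tol=config.tol,
            apply_trilinearity=config.trilinearity, seed=config.seed,
        )
    except ValidationError as exc:
        raise ValidationError(f"stage C (MCR-ALS) failed: {exc}") from exc
    mcr_result.save_json(outdir / "mcr_result.json")
    logger.info("MCR-ALS r2=%.3f%% in %d iterations", mcr_result.r2, mcr_result.n_iter)

    # stage C3: EIS PCA
    eis_model = None
    eis_scores = None
    if campaign.eis:
        logger.info("stage C: EIS PCA (%d spectra)", len(campaign.eis))
        try:
            D_eis, labels, _ = assemble_eis_matrix(
                campaign.eis, smooth=config.eis_smooth
            )
            eis_model = fit_pca(
                D_eis, preprocessing="center", nc_kept=config.eis_pcs,
                row_labels=labels,
            )
            eis_scores = average_replicate_scores(eis_model)
        except ValidationError as exc:
            raise ValidationError(f"stage C (EIS PCA) failed: {exc}") from exc
        eis_model.save_json(outdir / "eis_pca.json")

    # stage C4: uv254 (with inner-filter screening report)
    from .preprocess import inner_filter_screen

    for u in campaign.uv:
        dec = inner_filter_screen(u, cfg)
        if dec.needs_dilution:
            logger.info(
                "IFE screen: %s A254=%.3f > %.2f, dilution x%g recommended",
                u.sample_id, dec.a254, cfg.ife_threshold, dec.suggested_factor,
            )
    uv254 = pd.Series(
        {u.sample_id: extract_uv254(u, u.dilution_factor) for u in campaign.uv},
        name="uv254",
    )

    # stage D: fusion + global PCA
    fused = None
    global_model = None
    biplot = None
    if eis_scores is not None:
        logger.info("stage D: fusion and global PCA")
        frac = pd.DataFrame(
            mcr_result.C,
            index=mcr_result.sample_ids,
            columns=[f"C{i + 1}" for i in range(mcr_result.nc)],
        )
        try:
            fused = build_fused_table(
                campaign.sample_table, eis_scores, uv254, records, frac
            )
            global_model, biplot = run_global_pca(fused, nc_kept=2)
        except ValidationError as exc:
            raise ValidationError(f"stage D (fusion) failed: {exc}") from exc
        fused.to_csv(outdir / "fused_table.csv")
        global_model.save_json(outdir / "global_pca.json")
        biplot["scores"].to_csv(outdir / "global_scores.csv")
        biplot["loadings"].to_csv(outdir / "global_loadings.csv")
    else:
        import warnings

        warnings.warn("no EIS spectra available; fusion stage skipped", stacklevel=2)
        logger.warning("stage D skipped: no EIS spectra")

    report = {
        "n_samples": len(campaign.stack),
        "nc": config.nc,
        "mcr_r2": mcr_result.r2,
        "mcr_components": [
            {
                "name": f"C{i + 1}",
                "ex_max": mcr_result.ex_max(i, min_wavelength=260.0),
                "em_max": mcr_result.em_max(i),
                "total_contribution": float(mcr_result.C[:, i].sum()),
            }
            for i in range(mcr_result.nc)
        ],
        "eis_pca_explained": (
            eis_model.explained.tolist() if eis_model is not None else None
        ),
        "global_pca_explained": (
            global_model.explained.tolist() if global_model is not None else None
        ),
        "fusion_skipped": eis_scores is None,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return PipelineResult(
        outdir=outdir, stack=pre, indices=records, mcr=mcr_result,
        eis_model=eis_model, fused_table=fused, global_model=global_model,
        biplot=biplot,
    )
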