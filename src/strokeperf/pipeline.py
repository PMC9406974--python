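"""End-to-end pipeline orchestration.

Chains the processing stages (motion correction, smoothing, masking,
concentration conversion, AIF detection, deconvolution, map computation,
segmentation, volumetry, triage) and the cohort-level agreement analysis,
attaching stage names to errors and provenance to every output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .aif import AIF, detect_aif, fit_gamma_variate
from .agreement import (
    AgreementReport,
    ConcordanceTable,
    PairedCohort,
    agreement_report,
    triage_concordance,
)
from .deconv import PerfusionMaps, compute_maps, deconvolve
from .errors import GeometryError, JoinError, FormatError, StageError, StrokeperfError
from .io import PipelineConfig
from .lesion import (
    TriageDecision,
    VolumetricResult,
    mask_volume,
    mismatch_profile,
    segment_core_adc,
    segment_core_ctp,
    segment_penumbra,
    triage_defuse3,
)
from .signal import (
    CTP,
    DEFAULT_FWHM_MM,
    PerfusionSeries,
    compute_brain_mask,
    motion_correct,
    smooth,
    to_concentration,
)

log = logging.getLogger(__name__)

COHORT_COLUMNS = ("case_id", "icv", "pv")


@dataclass
class PipelineResult:
    """Output bundle of a single-case pipeline run."""

    volumetric: VolumetricResult
    triage: TriageDecision
    maps: PerfusionMaps
    core_mask: np.ndarray
    penumbra_mask: np.ndarray
    aif: AIF
    provenance: Dict[str, object]

    def to_record(self, case_id: str = "case") -> dict:
        v, t = self.volumetric, self.triage
        return {
            "case_id": case_id,
            "modality": v.modality,
            "icv_ml": v.icv,
            "pv_ml": v.pv,
            "mismatch_volume_ml": v.mismatch_volume,
            "mismatch_ratio": v.mismatch_ratio,
            "eligible": t.eligible,
            "failed_criteria": sorted(t.failed_criteria),
            "provenance": self.provenance,
        }


def _stage(name, fn, *args, **kwargs):
    log.info("stage %s", name)
    try:
        return fn(*args, **kwargs)
    except StrokeperfError as exc:
        raise StageError(name, exc) from exc


def _provenance(config: PipelineConfig) -> Dict[str, object]:
    return {
        "software_version": __version__,
        "config_sha256": config.config_hash(),
        "seed": config.seed,
    }


def _preprocess_and_map(series: PerfusionSeries, config: PipelineConfig):
    if config.motion_correction:
        series = _stage("motion_correct", motion_correct, series)
    fwhm = config.fwhm_mm
    if fwhm is None:
        fwhm = DEFAULT_FWHM_MM[series.modality]
    series = _stage("smooth", smooth, series, fwhm)
    brain = _stage("brain_mask", compute_brain_mask, series)
    conc = _stage("to_concentration", to_concentration, series, brain)
    aif = _stage("detect_aif", detect_aif, conc, config.aif_top_k)
    if config.fit_aif_gamma:
        params, rmse = _stage("fit_aif", fit_gamma_variate, aif.concentration, aif.times)
        aif.fit, aif.fit_rmse = params, rmse
    residue = _stage(
        "deconvolve", deconvolve, conc, aif,
        threshold_frac=config.threshold_frac, circulant_mode=config.circulant,
    )
    maps = _stage("compute_maps", compute_maps, residue, conc, aif, config.constants)
    return maps, aif


def run_ctp_pipeline(series: PerfusionSeries, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full CTP chain: maps, rCBF/Tmax segmentation, volumes and triage."""
    maps, aif = _preprocess_and_map(series, config)
    core = _stage(
        "segment_core", segment_core_ctp, maps, config.thresholds,
        series.voxel_size, config.core_requires_hypoperfusion,
    )
    penumbra = _stage(
        "segment_penumbra", segment_penumbra, maps, core, config.thresholds, series.voxel_size
    )
    icv = mask_volume(core, series.voxel_size)
    pv = mask_volume(penumbra, series.voxel_size)
    volumetric = mismatch_profile(icv, pv, modality="CTP")
    return PipelineResult(
        volumetric=volumetric,
        triage=triage_defuse3(volumetric),
        maps=maps,
        core_mask=core,
        penumbra_mask=penumbra,
        aif=aif,
        provenance=_provenance(config),
    )


def run_mri_pipeline(
    pwi_series: PerfusionSeries,
    adc_volume: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """MRI chain: core from the ADC map, penumbra from PWI Tmax."""
    adc_volume = np.asarray(adc_volume, dtype=float)
    if adc_volume.shape != pwi_series.grid_shape:
        raise GeometryError(
            f"ADC grid {adc_volume.shape} does not match PWI grid "
            f"{pwi_series.grid_shape}; resampling is out of scope"
        )
    maps, aif = _preprocess_and_map(pwi_series, config)
    core = _stage(
        "segment_core", segment_core_adc, adc_volume, maps.brain_mask,
        config.thresholds, pwi_series.voxel_size,
    )
    penumbra = _stage(
        "segment_penumbra", segment_penumbra, maps, core, config.thresholds,
        pwi_series.voxel_size,
    )
    icv = mask_volume(core, pwi_series.voxel_size)
    pv = mask_volume(penumbra, pwi_series.voxel_size)
    volumetric = mismatch_profile(icv, pv, modality="MRI")
    return PipelineResult(
        volumetric=volumetric,
        triage=triage_defuse3(volumetric),
        maps=maps,
        core_mask=core,
        penumbra_mask=penumbra,
        aif=aif,
        provenance=_provenance(config),
    )


def load_cohort_csv(path) -> pd.DataFrame:
    """Read a per-case volume table (columns case_id, icv, pv; mL)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV {path} missing columns: {missing}")
    return df


def build_cohort(df_a: pd.DataFrame, df_b: pd.DataFrame, modality: str = "CTP") -> PairedCohort:
    """Pair two per-case tables on case_id; unmatched ids are an error."""
    ids_a, ids_b = set(df_a["case_id"]), set(df_b["case_id"])
    if ids_a != ids_b:
        raise JoinError(
            f"unmatched case_ids: only in A {sorted(ids_a - ids_b)}, "
            f"only in B {sorted(ids_b - ids_a)}"
        )
    a = df_a.set_index("case_id").loc[sorted(ids_a)]
    b = df_b.set_index("case_id").loc[sorted(ids_a)]
    volumes_a = [mismatch_profile(r.icv, r.pv, modality) for r in a.itertuples()]
    volumes_b = [mismatch_profile(r.icv, r.pv, modality) for r in b.itertuples()]
    return PairedCohort(
        case_ids=list(a.index),
        volumes_a=volumes_a,
        volumes_b=volumes_b,
        decisions_a=[triage_defuse3(v) for v in volumes_a],
        decisions_b=[triage_defuse3(v) for v in volumes_b],
    )


@dataclass
class CohortComparison:
    icv: AgreementReport
    pv: AgreementReport
    concordance: ConcordanceTable
    provenance: Dict[str, object]

    def to_dict(self) -> dict:
        def report(r: AgreementReport) -> dict:
            d = dataclasses.asdict(r)
            d.pop("concordance")
            return d

        return {
            "icv": report(self.icv),
            "pv": report(self.pv),
            "triage": {
                "icc": self.concordance.icc,
                "icc_ci": list(self.concordance.icc_ci),
                "overall_concordant": self.concordance.overall_concordant,
                "overall_n": self.concordance.overall_n,
                "overall_rate": self.concordance.overall_rate,
                "subgroups": [dataclasses.asdict(s) for s in self.concordance.subgroups],
            },
            "provenance": self.provenance,
        }


def compare_cohort(
    df_a: pd.DataFrame,
    df_b: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    modality: str = "CTP",
) -> CohortComparison:
    """Agreement analysis of two packages' volume tables.

    Runs ICC / Bland-Altman / Wilcoxon separately for core and penumbra
    volumes (differences are A minus B) and tabulates triage concordance.
    """
    cohort = build_cohort(df_a, df_b, modality)
    icv_a = [v.icv for v in cohort.volumes_a]
    icv_b = [v.icv for v in cohort.volumes_b]
    pv_a = [v.pv for v in cohort.volumes_a]
    pv_b = [v.pv for v in cohort.volumes_b]
    return CohortComparison(
        icv=agreement_report(icv_a, icv_b, measure="icv"),
        pv=agreement_report(pv_a, pv_b, measure="pv"),
        concordance=triage_concordance(cohort),
        provenance=_provenance(config),
    )
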