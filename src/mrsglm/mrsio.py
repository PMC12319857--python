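"""Reading and writing dynamic MRS data and analysis results.

Dynamic scans are stored in the NIfTI-MRS convention: a NIfTI-2 container
with complex payload, spatial dimensions of size 1 (single voxel), FID
samples along dimension 4 and transients along a tagged fifth dimension
(``dim_5 = "DIM_DYN"``), plus a JSON header extension (ecode 44) carrying
the spectroscopy metadata.  Result tables are plain TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    AcquisitionParams,
    DynamicScan,
    MrsFormatError,
    Spectrogram,
    TaskDesign,
)

NIFTI_MRS_ECODE = 44


@dataclass
class NiftiMrsHeaderInfo:
    """Spectroscopy metadata carried in the NIfTI-MRS header extension."""

    spectrometer_frequency_mhz: float
    resonant_nucleus: str
    dwell_time_s: float
    dim_tags: dict

    @property
    def spectral_width_hz(self) -> float:
        return 1.0 / self.dwell_time_s


def _meta_from_scan(scan: DynamicScan) -> dict:
    p = scan.params
    meta = {
        "SpectrometerFrequency": [p.transmitter_freq_mhz],
        "ResonantNucleus": ["1H"],
        "EchoTime": p.te_ms / 1000.0,
        "RepetitionTime": p.tr_ms / 1000.0,
        "dim_5": "DIM_DYN",
        "mrsglm": {
            "scan_id": scan.scan_id,
            "ref_ppm": p.ref_ppm,
            "task": asdict(scan.task) if scan.task is not None else None,
        },
    }
    return meta


def write_nifti_mrs(scan: DynamicScan, path) -> None:
    """Write a scan as single-voxel NIfTI-MRS (complex NIfTI-2 + JSON ext)."""
    data = np.zeros((1, 1, 1, scan.params.n_points, scan.n_transients),
                    dtype=np.complex128)
    data[0, 0, 0] = scan.fids.T
    img = nib.Nifti2Image(data, affine=np.eye(4))
    hdr = img.header
    hdr["pixdim"][4] = scan.params.dwell_s
    ext = nib.nifti1.Nifti1Extension(
        NIFTI_MRS_ECODE, json.dumps(_meta_from_scan(scan)).encode("utf-8")
    )
    hdr.extensions.append(ext)
    nib.save(img, str(path))


def read_header_info(path) -> NiftiMrsHeaderInfo:
    img = nib.load(str(path))
    meta = _extract_meta(img)
    return NiftiMrsHeaderInfo(
        spectrometer_frequency_mhz=float(meta["SpectrometerFrequency"][0]),
        resonant_nucleus=str(meta["ResonantNucleus"][0]),
        dwell_time_s=float(img.header["pixdim"][4]),
        dim_tags={k: v for k, v in meta.items() if k.startswith("dim_")},
    )


def _extract_meta(img) -> dict:
    for ext in img.header.extensions:
        if ext.get_code() == NIFTI_MRS_ECODE:
            content = ext.get_content()
            if isinstance(content, bytes):
                content = content.decode("utf-8")
            elif not isinstance(content, str):
                return dict(content)
            return json.loads(content)
    raise MrsFormatError(
        "no NIfTI-MRS header extension (ecode 44) found: not a NIfTI-MRS file"
    )


def read_nifti_mrs(path, conjugate_on_read: bool = False) -> DynamicScan:
    """Read a single-voxel NIfTI-MRS file into a :class:`DynamicScan`.

    ``conjugate_on_read`` flips the spectral axis direction for files
    written with the opposite Fourier convention.
    """
    img = nib.load(str(path))
    meta = _extract_meta(img)
    data = np.asarray(img.dataobj)
    if not np.iscomplexobj(data):
        raise MrsFormatError("NIfTI-MRS payload must be complex")
    data = np.squeeze(data[0, 0, 0]) if data.ndim >= 4 else data
    if data.ndim == 1:
        data = data[:, None]
    n_transients = data.shape[1]
    if n_transients > 1 and meta.get("dim_5") != "DIM_DYN":
        raise MrsFormatError(
            "multi-transient file lacks the dynamic dimension tag dim_5=DIM_DYN"
        )
    dwell = float(img.header["pixdim"][4])
    if dwell <= 0:
        raise MrsFormatError("non-positive dwell time in header")
    extra = meta.get("mrsglm", {})
    params = AcquisitionParams(
        n_points=data.shape[0],
        spectral_width_hz=1.0 / dwell,
        transmitter_freq_mhz=float(meta["SpectrometerFrequency"][0]),
        te_ms=float(meta.get("EchoTime", 0.0)) * 1000.0,
        tr_ms=float(meta.get("RepetitionTime", 0.0)) * 1000.0,
        ref_ppm=float(extra.get("ref_ppm", 4.65)),
    )
    task = TaskDesign(**extra["task"]) if extra.get("task") else None
    fids = data.T.astype(complex)
    if conjugate_on_read:
        fids = np.conj(fids)
    return DynamicScan(fids, params, task, scan_id=extra.get("scan_id", "scan"))


# ---------------------------------------------------------------------------
# result tables


def glm_result_to_frame(result) -> pd.DataFrame:
    """Flatten a GlmResult into one row per frequency point."""
    cols = {"ppm": result.ppm}
    for j, lab in enumerate(result.labels):
        cols[f"beta_{lab}"] = result.beta[:, j]
    for j, lab in enumerate(result.labels):
        if lab == "intercept":
            continue
        cols[f"se_{lab}"] = result.se[:, j]
        cols[f"t_{lab}"] = result.t[:, j]
        cols[f"p_{lab}"] = result.p[:, j]
    return pd.DataFrame(cols)


def timecourse_to_frame(tc) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_s": tc.times_s, "value": tc.values, "task": tc.task_mask.astype(int)}
    )


def write_results_table(result, path) -> None:
    """Write a GlmResult, metabolite time-course, or DataFrame as TSV."""
    if isinstance(result, pd.DataFrame):
        frame = result
    elif hasattr(result, "beta"):
        frame = glm_result_to_frame(result)
    elif hasattr(result, "values") and hasattr(result, "times_s"):
        frame = timecourse_to_frame(result)
    else:
        raise TypeError(f"cannot serialise {type(result).__name__} as a table")
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spectrogram_tsv(spg: Spectrogram, path) -> None:
    """Spectrogram as TSV: first column time_s, remaining columns ppm values."""
    frame = pd.DataFrame(spg.values, columns=[f"{p:.5f}" for p in spg.ppm])
    frame.insert(0, "time_s", spg.times_s)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


__all__ = [
    "NiftiMrsHeaderInfo",
    "read_nifti_mrs",
    "write_nifti_mrs",
    "read_header_info",
    "write_results_table",
    "read_results_table",
    "write_spectrogram_tsv",
    "glm_result_to_frame",
    "timecourse_to_frame",
]
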