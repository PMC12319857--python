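"""End-to-end orchestration: simulate -> preprocess -> QC -> GLM -> block stats.

A :class:`RunConfig` fully determines a run; ``run_pipeline`` executes the
stages in order, writes NIfTI-MRS intermediates, TSV results and PNG
figures, and records a JSON manifest with per-stage parameters, seeds and
a content hash for every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import __version__
from .core import AcquisitionParams, MrsInputError, TaskDesign
from . import blockstats, mrsio, preprocess, quality, spectral_glm, synthdata

log = logging.getLogger("mrsglm")


@dataclass
class GlmSpec:
    lag_s: float = 0.0
    nuisance: bool = True
    nuisance_ppm_range: tuple = (1.97, 2.04)
    nuisance_smooth_window: int = 51
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Serialisable description of a full pipeline run."""

    scenario: dict = field(default_factory=dict)  # simulation spec
    input_paths: List[str] = field(default_factory=list)  # or NIfTI-MRS inputs
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    glm: GlmSpec = field(default_factory=GlmSpec)
    seed: int = 1
    out_dir: str = "mrsglm_out"
    write_scan_files: bool = False

    def to_dict(self) -> dict:
        from .synthdata import _plain
        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            for key in ("align_ppm_range", "glm_crop"):
                if key in pp:
                    pp[key] = tuple(pp[key])
            d["preprocess"] = preprocess.PreprocessConfig(**pp)
        if "glm" in d and isinstance(d["glm"], dict):
            g = dict(d["glm"])
            if "nuisance_ppm_range" in g:
                g["nuisance_ppm_range"] = tuple(g["nuisance_ppm_range"])
            d["glm"] = GlmSpec(**g)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def validate(self) -> None:
        if not self.scenario and not self.input_paths:
            raise MrsInputError("config needs either a simulation scenario or "
                                "input paths")
        if self.scenario:
            tab, conf, params, task, n_tr, n_scans = \
                synthdata.scenario_from_dict(self.scenario)
            if task is None:
                raise MrsInputError("scenario lacks task timing")


def demo_scenario(n_scans: int = 19, n_transients: int = 750,
                  target_snr: float = 31.0) -> dict:
    """The bundled demo: a 19-scan, 750-transient cohort with the default
    resonance table and the full confound set."""
    table = synthdata.default_table()
    params = AcquisitionParams()
    confounds = synthdata.study_confounds(target_snr, table, params)
    return synthdata.scenario_to_dict(
        table, confounds, params, TaskDesign(), n_transients, n_scans
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the configured pipeline; returns the output manifest."""
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: List[Path] = []
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    # --- stage: load or simulate -------------------------------------------
    try:
        if config.scenario:
            table, confounds, params, task, n_tr, n_scans = \
                synthdata.scenario_from_dict(config.scenario)
            log.info("simulating %d scan(s) x %d transients", n_scans, n_tr)
            scans = synthdata.simulate_cohort(
                n_scans, table, confounds, params, task, n_tr, seed=config.seed
            )
            manifest["stages"]["simulate"] = {
                "n_scans": n_scans, "n_transients": n_tr, "seed": config.seed,
            }
        else:
            scans = [mrsio.read_nifti_mrs(p) for p in config.input_paths]
            task = scans[0].task
            if task is None:
                raise MrsInputError("input scans carry no task timing")
            manifest["stages"]["load"] = {"inputs": list(config.input_paths)}
    except Exception as exc:
        raise RuntimeError(f"stage=simulate error={type(exc).__name__}") from exc

    if config.write_scan_files:
        for scan in scans:
            p = out / f"{scan.scan_id}.nii"
            mrsio.write_nifti_mrs(scan, p)
            outputs.append(p)

    # --- stage: preprocessing ----------------------------------------------
    try:
        log.info("preprocessing (block profile)")
        block = preprocess.preprocess_cohort(scans, "block", config.preprocess)
        log.info("preprocessing (glm profile)")
        glmpre = preprocess.preprocess_cohort(scans, "glm", config.preprocess)
        manifest["stages"]["preprocess"] = asdict(config.preprocess)
    except Exception as exc:
        raise RuntimeError(f"stage=preprocess error={type(exc).__name__}") from exc

    # --- stage: QC -----------------------------------------------------------
    try:
        log.info("quality control")
        import pandas as pd
        rows = []
        for scan, al in zip(scans, block.alignments):
            rep = quality.qc_scan(scan, config.preprocess.block_size,
                                  alignment=al)
            rows.append({
                "scan_id": rep.scan_id,
                "snr_median": rep.snr_median,
                "fwhm_mean_ppm": rep.fwhm_mean_ppm,
                "fwhm_final_pct_change": rep.fwhm_pct_change[-1],
                "excluded": rep.excluded,
                "reason": rep.reason,
                "movement_advisory": rep.movement_advisory,
            })
        qc_path = out / "qc_report.tsv"
        pd.DataFrame(rows).to_csv(qc_path, sep="\t", index=False)
        outputs.append(qc_path)
        diff = quality.difference_spectrogram(block.mean)
        diff_path = out / "difference_spectrogram.tsv"
        mrsio.write_spectrogram_tsv(diff, diff_path)
        outputs.append(diff_path)
        _plot_spectrogram(diff, out / "difference_spectrogram.png")
        outputs.append(out / "difference_spectrogram.png")
        manifest["stages"]["qc"] = {"n_scans": len(rows)}
    except Exception as exc:
        raise RuntimeError(f"stage=qc error={type(exc).__name__}") from exc

    # --- stage: spectral GLM -------------------------------------------------
    try:
        log.info("spectral GLM")
        spg = glmpre.mean
        nuis = spectral_glm.build_nuisance(
            spg, config.glm.nuisance_ppm_range,
            config.glm.nuisance_smooth_window,
        ) if config.glm.nuisance else None
        design = spectral_glm.build_design(task, spg.times_s,
                                           config.glm.lag_s, nuis)
        result = spectral_glm.fit_glm(spg, design, config.glm.alpha)
        glm_path = out / "glm_results.tsv"
        mrsio.write_results_table(result, glm_path)
        outputs.append(glm_path)
        man_path = out / "manhattan.png"
        spectral_glm.plot_manhattan(result, man_path, "task",
                                    title="spectral GLM, task regressor")
        outputs.append(man_path)
        manifest["stages"]["glm"] = {
            "design": design.labels, "lag_s": config.glm.lag_s,
            "alpha": config.glm.alpha,
            "bonferroni_p": result.bonferroni_p, "n_freq": len(result.ppm),
        }
    except Exception as exc:
        raise RuntimeError(f"stage=glm error={type(exc).__name__}") from exc

    # --- stage: block statistics --------------------------------------------
    try:
        log.info("block statistics")
        import pandas as pd
        schemes = blockstats.averaging_schemes(block.per_scan, task)
        rows = []
        for name, tc in schemes.scheme_a.items():
            for label, course in (("participant_mean", tc),
                                  ("per_participant", schemes.scheme_b_mean[name])):
                test = blockstats.task_rest_ttest(course)
                rows.append({
                    "metabolite": name, "scheme": label, "t": test.t,
                    "df": test.df, "p": test.p, "pct_change": test.pct_change,
                })
            mrsio.write_results_table(tc, out / f"timecourse_{name}.tsv")
            outputs.append(out / f"timecourse_{name}.tsv")
        bs_path = out / "blockstats.tsv"
        pd.DataFrame(rows).to_csv(bs_path, sep="\t", index=False)
        outputs.append(bs_path)
        manifest["stages"]["blockstats"] = {"metabolites": list(schemes.scheme_a)}
    except Exception as exc:
        raise RuntimeError(f"stage=blockstats error={type(exc).__name__}") from exc

    config.to_yaml(out / "run_config.yaml")
    outputs.append(out / "run_config.yaml")
    manifest["outputs"] = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("wrote %d outputs to %s", len(outputs), out)
    return manifest


def _plot_spectrogram(spg, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    vmax = np.abs(spg.values).max() or 1.0
    ax.imshow(
        spg.values,
        aspect="auto",
        origin="lower",
        extent=[spg.ppm[0], spg.ppm[-1], spg.times_s[0], spg.times_s[-1]],
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = ["RunConfig", "GlmSpec", "run_pipeline", "demo_scenario"]
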