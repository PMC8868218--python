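"""Pipeline orchestration: simulate -> extract -> select.

Each stage is independently invokable, so a folder of real thermograms
(images + ROI raster + biomarker CSV in the study layout) can replace the
simulator.  Stage outputs are pure functions of (inputs, config, seed);
re-running a stage with the same config reproduces identical CSV bytes.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .conventional import conventional_rows
from .io import read_study, write_feature_table, write_study
from .stats import format_selection_matrix, select_related
from .synthetic import Study, generate_study
from .texture import extract_all

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name and file context."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper
    return deco


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]


@_stage("simulate")
def run_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the synthetic study and write it under ``out_dir/study``."""
    study = generate_study(config.design.model_copy(update={"seed": config.seed})
                           if config.design.seed != config.seed
                           else config.design,
                           config.effect)
    path = write_study(study, Path(out_dir) / "study")
    logger.info("simulate: %d thermograms -> %s", len(study), path)
    return path


@_stage("extract")
def run_extract(
    config: PipelineConfig,
    study: Study | str | Path,
    out_dir: str | Path,
    include_conventional: bool = True,
) -> Path:
    """Extract the full feature table for every thermogram in the study."""
    if not isinstance(study, Study):
        study = read_study(study)
    tcfg = config.texture_config()
    frames = []
    for rec in study.records:
        meta = {"horse": rec.horse, "re": rec.re, "bs": rec.bs}
        frames.append(
            extract_all(
                rec.image, study.rois, tcfg,
                normalized_variant=config.color.normalized_variant,
                bit_depth=config.color.bit_depth, meta=meta,
            )
        )
        if include_conventional and rec.field is not None:
            frames.append(pd.DataFrame(conventional_rows(rec, study.rois)))
    table = pd.concat(frames, ignore_index=True)
    path = write_feature_table(table, Path(out_dir) / "features.csv")
    logger.info("extract: %d rows -> %s", len(table), path)
    return path


@_stage("select")
def run_select(
    config: PipelineConfig,
    features: pd.DataFrame | str | Path,
    biomarkers: pd.DataFrame | str | Path,
    out_dir: str | Path,
) -> Path:
    """Slope-parallelism selection; writes selection.csv and the summary
    matrix text file."""
    if not isinstance(features, pd.DataFrame):
        features = pd.read_csv(features)
    if not isinstance(biomarkers, pd.DataFrame):
        biomarkers = pd.read_csv(biomarkers)
    sel = select_related(
        features[features["channel"] != "IRT"],
        biomarkers,
        targets=config.stats.targets,
        alpha=config.stats.alpha,
        alpha_nonzero=config.stats.alpha_nonzero,
        scale_align=config.stats.scale_align,
        bh_correction=config.stats.bh_correction,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel.to_csv(out / "selection.csv", index=False)
    (out / "selection_matrix.txt").write_text(format_selection_matrix(sel))
    logger.info("select: %d pairs, %d related -> %s",
                len(sel), int(sel["related"].sum()) if len(sel) else 0, out)
    return out / "selection.csv"


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """simulate -> extract -> select, with a run log of seed, config hash
    and row counts."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}", f"config_hash: {config_hash(config)}"]

    study = generate_study(
        config.design if config.design.seed == config.seed
        else config.design.model_copy(update={"seed": config.seed}),
        config.effect,
    )
    study_dir = write_study(study, out / "study")
    log_lines.append(f"thermograms: {len(study)}")

    features_path = run_extract(config, study, out)
    table = pd.read_csv(features_path)
    log_lines.append(f"feature_rows: {len(table)}")

    selection_path = run_select(
        config, table, study.biomarker_table(), out
    )
    sel = pd.read_csv(selection_path)
    log_lines.append(f"pairs_evaluated: {len(sel)}")
    log_lines.append(f"pairs_related: {int(sel['related'].sum()) if len(sel) else 0}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "study_dir": study_dir,
        "features": features_path,
        "selection": selection_path,
        "log": out / "run.log",
    }
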