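"""End-to-end orchestration: score → norms → calibrate → match → compare.

The pipeline consumes a long survey table (one row per student × wave),
either a prebuilt normative curve table or a normative pool to fit one
from, and a run configuration; it emits comparison tables at the student,
classroom and school levels, subgroup z-tests, the dichotomized change
table for external multi-level modelling, the virtual-case table, an
exclusion log, and a manifest recording the seed, configuration hash and
input checksums.  Identical configuration and inputs produce identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import BEHAVIORS, calibrate_all, weights_from_json, weights_to_json
from .norm_model import NormTable, default_grid, empirical_percentiles, fit_percentile_curves
from .outcomes import (
    SUBGROUPS,
    cells_from_treatment,
    cells_from_virtual,
    compare_cells,
    dichotomize_increase,
    results_to_frame,
    subgroup_compare,
    subgroup_results_to_frame,
)
from .psych_scale import ItemBattery, score_survey
from .synthetic_data import read_survey
from .virtual_match import (
    cases_from_frame,
    match_cohort,
    virtual_cases_to_frame,
    write_exclusion_log,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    survey_path: str
    out_dir: str
    norms_path: str | None = None  # prebuilt curve table (CSV)
    pool_path: str | None = None  # normative pool to fit norms from
    weights_path: str | None = None  # precalibrated weights (JSON)
    battery_path: str | None = None  # item battery config (JSON)
    grid_step: float = 0.5
    min_records_per_age: int = 20
    min_positive: int = 20
    school_weighting: str = "student"
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _grid(step: float):
    import numpy as np

    if step == 0.5:
        return default_grid()
    return np.arange(step, 99.0 + step / 2, step)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict of outputs written."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = {}

    # ---- stage: load + score ------------------------------------------------
    try:
        survey = read_survey(config.survey_path)
        inputs["survey"] = _sha256(config.survey_path)
        battery = (
            ItemBattery.from_json(config.battery_path)
            if config.battery_path
            else ItemBattery.default()
        )
        if config.battery_path:
            inputs["battery"] = _sha256(config.battery_path)
        survey = survey.copy()
        survey["psych"] = score_survey(survey, battery)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("score", str(err)) from err

    # ---- stage: norms -------------------------------------------------------
    try:
        if config.norms_path:
            table = NormTable.load_curves(config.norms_path)
            inputs["norms"] = _sha256(config.norms_path)
        elif config.pool_path:
            pool = pd.read_csv(config.pool_path, comment="#")
            inputs["pool"] = _sha256(config.pool_path)
            cells = empirical_percentiles(
                pool, _grid(config.grid_step), config.min_records_per_age
            )
            table = fit_percentile_curves(cells, _grid(config.grid_step))
            table.save_curves(out_dir / "norms_curves.csv")
        else:
            raise ValueError(
                "no normative table: provide norms_path or pool_path"
            )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("norms", str(err)) from err

    # ---- stage: calibrate ---------------------------------------------------
    try:
        if config.weights_path:
            weights = weights_from_json(config.weights_path)
            inputs["weights"] = _sha256(config.weights_path)
            reports = None
        else:
            behaviors = tuple(b for b in BEHAVIORS if b in survey.columns)
            pretests = survey[survey["wave"] == "pretest"]
            reports = calibrate_all(
                pretests, behaviors, min_positive=config.min_positive
            )
            weights_to_json(reports, out_dir / "weights.json")
            weights = {
                b: r.weights for b, r in reports.items() if r.weights is not None
            }
        if not weights:
            raise ValueError(
                "no behavior could be calibrated (prevalence guard tripped "
                "for all behaviors)"
            )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("calibrate", str(err)) from err

    # ---- stage: match -------------------------------------------------------
    try:
        behaviors = tuple(weights)
        cases = cases_from_frame(survey, behaviors)
        virtual, exclusions = match_cohort(table, weights, cases)
        virtual_cases_to_frame(virtual).to_csv(
            out_dir / "virtual_cases.csv", index=False, float_format="%.10g"
        )
        write_exclusion_log(exclusions, out_dir / "exclusions.log")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("match", str(err)) from err

    # ---- stage: compare -----------------------------------------------------
    try:
        matched_ids = {vc.student_id for vc in virtual}
        matched_cases = [c for c in cases if c.student_id in matched_ids]
        cells_t = cells_from_treatment(matched_cases, behaviors)
        cells_c = cells_from_virtual(virtual, behaviors)
        results = compare_cells(
            cells_t, cells_c, school_weighting=config.school_weighting
        )
        results_to_frame(results).to_csv(
            out_dir / "results_levels.csv", index=False, float_format="%.6g"
        )
        sub_results = []
        for subgroup in SUBGROUPS:
            for behavior in behaviors:
                for wave in ("posttest", "followup"):
                    try:
                        sub_results.append(
                            subgroup_compare(
                                matched_cases, virtual, subgroup, behavior, wave,
                                alpha=config.alpha,
                            )
                        )
                    except ValueError:
                        continue  # empty subgroup at this wave
        subgroup_results_to_frame(sub_results).to_csv(
            out_dir / "results_subgroups.csv", index=False, float_format="%.6g"
        )
        dich = pd.concat(
            [
                dichotomize_increase(pd.concat([cells_t, cells_c]), "pretest", lw)
                .assign(period=f"pretest_to_{lw}")
                for lw in ("posttest", "followup")
            ],
            ignore_index=True,
        )
        dich.to_csv(out_dir / "dichotomized.csv", index=False)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("compare", str(err)) from err

    # ---- manifest -----------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": inputs,
        "n_treatment_cases": len(cases),
        "n_virtual_cases": len(virtual),
        "n_exclusions": len(exclusions),
        "behaviors_calibrated": list(behaviors),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
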