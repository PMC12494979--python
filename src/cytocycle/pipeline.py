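"""End-to-end orchestration: simulate/ingest -> preprocess -> gate -> rules ->
diversity -> aberrancy -> differential.

One configuration object drives the run; a single global seed is fanned out
to per-stage seeds by fixed offsets so stages can be re-run in isolation.
Result tables are plain CSV and byte-identical across runs with the same
configuration and seed; the run report (which includes wall times) is written
separately.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .aberrancy import (AberrancyParams, aberrancy_threshold, classify,
                        nn_aberrancy, reference_self_scores)
from .diversity import DiversityParams, diversity_curve
from .errors import ConfigurationError
from .gating import derive_thresholds, thresholds_from_raw
from .io import read_delimited_matrix, read_fcs_matrix
from .matrix import ExpressionMatrix, concat_matrices
from .preprocess import (PreprocessParams, anchor_batch_adjust, asinh_transform,
                         cleanup_filter, percentile_normalize)
from .rules import evaluate_rules, load_rules, noncanonical_fraction
from .stats import differential_test, scale_features
from .synthetic import (GeneratorConfig, PerturbationSpec, apply_perturbation,
                        simulate_population)

ALL_STAGES = ("simulate", "preprocess", "gate", "rules", "diversity",
              "aberrancy", "differential")

# Fixed per-stage seed offsets from the global seed.
SEED_OFFSETS = {"simulate": 0, "treated_arm": 1, "diversity": 2, "classify": 3}


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: Optional[GeneratorConfig] = None
    perturbation: Optional[PerturbationSpec] = None
    input_files: Optional[list] = None
    input_format: str = "delimited"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cleanup_raw: Optional[dict] = None  # raw-scale (min, max) windows
    gating_method: str = "recommended"
    gating_params: dict = field(default_factory=dict)
    rules_path: Optional[Path] = None
    diversity: DiversityParams = field(default_factory=DiversityParams)
    aberrancy: AberrancyParams = field(default_factory=AberrancyParams)
    reference_treatment: str = "untreated"
    differential_params: dict = field(
        default_factory=lambda: {"padj_max": 0.1, "coef_min": 0.5,
                                 "stratify_by": "phase"}
    )

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ConfigurationError("no stages selected: nothing to do")
        if "simulate" in self.stages and self.generator is None and \
                self.input_files is None:
            raise ConfigurationError(
                "simulate stage needs a generator config or input files"
            )


@dataclass
class RunReport:
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int, seconds: float,
               **extra) -> None:
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
             "wall_time_s": round(seconds, 3), **extra}
        )

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages}, indent=2)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in order; outputs land in ``out_dir``."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    stages = set(config.stages)

    # --- simulate / ingest -------------------------------------------------
    t0 = time.perf_counter()
    if config.generator is not None:
        gen = dataclasses.replace(
            config.generator, seed=config.seed + SEED_OFFSETS["simulate"]
        )
        ds = simulate_population(gen)
        mats = [ds.expression]
        truth = [_truth_frame(ds)]
        if config.perturbation is not None:
            treated = apply_perturbation(
                gen, config.perturbation,
                seed=config.seed + SEED_OFFSETS["treated_arm"],
            )
            mats.append(treated.expression)
            truth.append(_truth_frame(treated))
        matrix = concat_matrices(mats)
        truth_df = pd.concat(truth, ignore_index=True)
        matrix.cell_meta = pd.concat(
            [matrix.cell_meta.reset_index(drop=True), truth_df], axis=1
        )
    elif config.input_files is not None:
        if config.input_format == "fcs":
            matrix = read_fcs_matrix(config.input_files)
        else:
            matrix = concat_matrices(
                [read_delimited_matrix(p) for p in config.input_files]
            )
    else:
        raise ConfigurationError("no input: neither generator nor input_files")
    report.record("simulate", matrix.n_cells, matrix.n_cells,
                  time.perf_counter() - t0)

    # --- preprocess --------------------------------------------------------
    if "preprocess" in stages:
        t0 = time.perf_counter()
        n_in = matrix.n_cells
        pp = config.preprocess
        meta = matrix.cell_meta
        if pp.reference_batch is not None and "anchor" in meta.columns:
            matrix = anchor_batch_adjust(
                matrix, meta["anchor"].to_numpy(dtype=bool),
                meta["batch"].to_numpy(), pp.reference_batch,
            )
        matrix = asinh_transform(matrix, pp.cofactor)
        cleanup_report: dict = {}
        thresholds = dict(pp.cleanup_thresholds)
        if config.cleanup_raw:
            for chan, (lo, hi) in config.cleanup_raw.items():
                thresholds[chan] = (
                    None if lo is None else float(np.arcsinh(lo / pp.cofactor)),
                    None if hi is None else float(np.arcsinh(hi / pp.cofactor)),
                )
        if thresholds:
            matrix, cleanup_report = cleanup_filter(matrix, thresholds)
        matrix = percentile_normalize(matrix, pp.percentile_q, pp.clip_at_one)
        report.record("preprocess", n_in, matrix.n_cells,
                      time.perf_counter() - t0, cleanup=cleanup_report)

    # --- gate --------------------------------------------------------------
    if "gate" in stages:
        t0 = time.perf_counter()
        if config.gating_method == "recommended":
            if config.generator is None:
                raise ConfigurationError(
                    "'recommended' gating requires a generator config"
                )
            raw = synthetic.recommended_raw_gates(config.generator)
            thresholds_obj = thresholds_from_raw(matrix, raw)
        else:
            thresholds_obj = derive_thresholds(
                matrix, config.gating_method, config.gating_params
            )
        from .gating import assign_phases

        matrix.cell_meta["phase"] = assign_phases(matrix, thresholds_obj)
        report.record(
            "gate", matrix.n_cells, matrix.n_cells, time.perf_counter() - t0,
            thresholds={k: getattr(thresholds_obj, k)
                        for k in ("idu_pos", "ph3_pos", "cyclinb1_high")},
        )

    # --- rules -------------------------------------------------------------
    if "rules" in stages:
        t0 = time.perf_counter()
        rules = load_rules(config.rules_path)
        calls = evaluate_rules(matrix, matrix.cell_meta["phase"].to_numpy(), rules)
        matrix.cell_meta["violation_count"] = calls.violation_count
        matrix.cell_meta["canonical"] = calls.canonical
        frac = noncanonical_fraction(
            calls, matrix.cell_meta[["cell_line", "phase"]]
        )
        _write(frac, out / "noncanonical_fractions.csv")
        report.record("rules", matrix.n_cells, matrix.n_cells,
                      time.perf_counter() - t0, n_rules=len(rules))

    # --- diversity ---------------------------------------------------------
    if "diversity" in stages:
        t0 = time.perf_counter()
        div = dataclasses.replace(
            config.diversity, seed=config.seed + SEED_OFFSETS["diversity"]
        )
        curve = diversity_curve(matrix, div)
        _write(curve.records, out / "diversity_curve.csv")
        report.record("diversity", matrix.n_cells, matrix.n_cells,
                      time.perf_counter() - t0,
                      n_subsets=len(curve.records))

    # --- aberrancy ---------------------------------------------------------
    if "aberrancy" in stages:
        t0 = time.perf_counter()
        treat = matrix.cell_meta["treatment"].to_numpy()
        ref_mask = treat == config.reference_treatment
        if not ref_mask.any():
            raise ConfigurationError(
                f"no cells with reference treatment "
                f"{config.reference_treatment!r}"
            )
        reference = matrix.select_cells(ref_mask)
        self_scores = reference_self_scores(reference, config.aberrancy)
        thr = aberrancy_threshold(self_scores, config.aberrancy.threshold_quantile)
        if ref_mask.all():
            scores = self_scores
        else:
            scores = np.empty(matrix.n_cells)
            scores[ref_mask] = self_scores
            query = matrix.select_cells(~ref_mask)
            scores[~ref_mask] = nn_aberrancy(
                query, reference, config.aberrancy
            ).score
        matrix.cell_meta["aberrancy_score"] = scores
        matrix.cell_meta["aberrant"] = scores > thr
        report.record("aberrancy", matrix.n_cells, matrix.n_cells,
                      time.perf_counter() - t0, threshold=float(thr))

    # --- differential ------------------------------------------------------
    if "differential" in stages:
        t0 = time.perf_counter()
        treat_levels = pd.unique(matrix.cell_meta["treatment"])
        if len(treat_levels) >= 2:
            dp = dict(config.differential_params)
            stratify = dp.pop("stratify_by", None)
            if stratify is not None and stratify not in matrix.cell_meta.columns:
                stratify = None
            scaled = scale_features(matrix)
            diff = differential_test(
                scaled, contrast="treatment",
                reference=config.reference_treatment,
                stratify_by=stratify, **dp,
            )
            _write(diff, out / "differential.csv")
            report.record("differential", matrix.n_cells, matrix.n_cells,
                          time.perf_counter() - t0, n_tests=len(diff))
        else:
            report.record("differential", matrix.n_cells, matrix.n_cells,
                          time.perf_counter() - t0, skipped="single treatment")

    # --- final cell table ----------------------------------------------------
    cell_table = matrix.cell_meta.copy()
    _write(cell_table, out / "cell_table.csv")
    (out / "run_report.json").write_text(report.to_json())
    return report


def _truth_frame(ds: synthetic.SyntheticDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "truth_phase": ds.truth_phase,
            "truth_canonical": ds.truth_canonical,
        }
    )


# ---------------------------------------------------------------------------
# YAML configuration


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a structured YAML file.

    Nested sections (``generator``, ``perturbation``, ``preprocess``,
    ``diversity``, ``aberrancy``) map onto the corresponding dataclasses;
    scalar keys map onto PipelineConfig fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "generator" in raw:
        kwargs["generator"] = GeneratorConfig(**raw.pop("generator"))
    if "perturbation" in raw:
        pert = raw.pop("perturbation")
        effects = [
            (e["marker"], frozenset(e["phases"]), float(e["factor"]))
            for e in pert.pop("marker_effects", [])
        ]
        kwargs["perturbation"] = PerturbationSpec(marker_effects=effects, **pert)
    if "preprocess" in raw:
        kwargs["preprocess"] = PreprocessParams(**raw.pop("preprocess"))
    if "diversity" in raw:
        kwargs["diversity"] = DiversityParams(**raw.pop("diversity"))
    if "aberrancy" in raw:
        kwargs["aberrancy"] = AberrancyParams(**raw.pop("aberrancy"))
    if "stages" in raw:
        kwargs["stages"] = tuple(raw.pop("stages"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
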