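"""Ground-truth-labeled synthetic mass-cytometry cell-cycle datasets.

The generator emulates the statistical structure the downstream analysis
assumes in real CyTOF data: four-phase cell-cycle occupancy with
phase-specific marker dynamics (IdU incorporation only in S, pH3(S10) only in
M, a CyclinB1 ramp into G2/M, DNA content interpolating 2N -> 4N across S,
CDT1 licensing restricted to G0G1, Geminin rising S -> M, SLBP high in S and
degraded afterwards, Ki67/PCNA/PLK1 increasing with progression),
multiplicative lognormal measurement noise, per-cell-line global scale
offsets, drug-arrest occupancy shifts with marker modifications, and
injectable noncanonical states with exact truth labels.

Raw intensities are lognormal around phase-template locations: cytometry ion
counts are nonnegative and right-skewed, and a multiplicative noise model
keeps positivity thresholds meaningful on the asinh scale. The default
coefficient of variation is 0.35.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParameterError
from .fcs import write_fcs
from .matrix import PHASES, ExpressionMatrix

DEFAULT_NOISE_CV = 0.35

#: Stimulated primary T-cell phase occupancy (G0G1, S, G2, M), renormalized
#: from the published approximate fractions 42/51/5.1/1.8% to sum to one.
DEFAULT_OCCUPANCY = tuple(
    np.array([0.42, 0.51, 0.051, 0.018]) / 0.999
)


class PhaseLevel(NamedTuple):
    """Raw-scale lognormal location and relative spread for one phase."""

    location: float
    spread: float = 1.0


@dataclass(frozen=True)
class MarkerTemplate:
    """Phase-resolved expected raw intensity for one marker.

    ``positive_phase`` marks binary-positive markers (IdU in S, pH3 in M)
    whose location is at background in every other phase.
    """

    marker_name: str
    phase_levels: dict[str, PhaseLevel]
    positive_phase: Optional[str] = None

    def __post_init__(self) -> None:
        missing = set(PHASES) - set(self.phase_levels)
        if missing:
            raise ConfigurationError(
                f"{self.marker_name}: no level for phases {sorted(missing)}"
            )
        for phase, lev in self.phase_levels.items():
            if lev.location < 0 or lev.spread <= 0:
                raise ConfigurationError(
                    f"{self.marker_name}/{phase}: location must be >= 0 "
                    "and spread > 0"
                )

    def location(self, phase: str) -> float:
        return self.phase_levels[phase].location

    def spread(self, phase: str) -> float:
        return self.phase_levels[phase].spread


def _tpl(name: str, g0g1: float, s: float, g2: float, m: float,
         positive_phase: str | None = None) -> MarkerTemplate:
    return MarkerTemplate(
        marker_name=name,
        phase_levels={
            "G0G1": PhaseLevel(g0g1),
            "S": PhaseLevel(s),
            "G2": PhaseLevel(g2),
            "M": PhaseLevel(m),
        },
        positive_phase=positive_phase,
    )


def default_templates() -> list[MarkerTemplate]:
    """Default 17-marker diversity panel plus cPARP, with qualitative
    phase dynamics: reported orderings, not measured absolute levels."""
    return [
        _tpl("Ki67", 20, 40, 80, 120),          # rises with progression
        _tpl("pRbS780", 15, 50, 60, 60),        # higher in S/G2/M
        _tpl("pH3_s10", 0.5, 0.5, 0.5, 200, positive_phase="M"),
        _tpl("CDT1", 60, 5, 3, 3),              # licensing restricted to G0G1
        _tpl("IdU", 0.5, 150, 0.5, 0.5, positive_phase="S"),
        _tpl("Geminin", 3, 30, 60, 80),         # rises S -> M
        _tpl("PLK1", 5, 20, 60, 100),
        _tpl("DNA", 100, 150, 200, 200),        # 2N -> 4N; S interpolated
        _tpl("CyclinB1", 5, 20, 80, 120),       # ramp into G2/M
        _tpl("PCNA", 15, 60, 70, 70),
        _tpl("SLBP", 10, 80, 5, 5),             # high in S, degraded at S/G2
        _tpl("CyclinE", 40, 60, 10, 8),         # G1/S cyclin
        _tpl("WGA", 50, 70, 90, 100),           # cell-size proxy
        _tpl("HH3", 50, 75, 100, 100),          # total histone content
        _tpl("EZH2", 20, 35, 50, 55),
        _tpl("CTCF", 30, 35, 40, 42),
        _tpl("MLL1", 25, 30, 35, 36),
        _tpl("cPARP", 0.5, 0.5, 0.5, 0.5),      # apoptosis marker, background
    ]


#: rule_id -> (marker, violating raw location). Forcing the marker to this
#: location produces a labeled violation of the shipped canonical rule.
VIOLATION_TARGETS: dict[str, tuple[str, float]] = {
    "ki67_low_in_s": ("Ki67", 3.0),
    "cdt1_after_s": ("CDT1", 150.0),
    "prb_low_in_g2": ("pRbS780", 2.0),
    "plk1_high_in_g0g1": ("PLK1", 60.0),
    "slbp_high_after_s": ("SLBP", 80.0),
    "geminin_high_in_g0g1": ("Geminin", 60.0),
}


@dataclass
class PerturbationSpec:
    """Drug-arrest style perturbation: occupancy pile-up, phase-restricted
    multiplicative marker effects, and optional mitotic slippage (G0G1-labeled
    cells acquiring >4N DNA content)."""

    occupancy_shift: Sequence[float]
    marker_effects: list[tuple[str, frozenset, float]] = field(default_factory=list)
    slippage_fraction: float = 0.0
    slippage_dna_factor: float = 4.0  # DNA location as a multiple of 2N
    label: str = "treated"

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy_shift, dtype=float)
        if occ.shape != (4,) or abs(occ.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "occupancy_shift must be a 4-vector summing to 1"
            )
        self.occupancy_shift = tuple(occ)
        norm_effects = []
        for marker, phases, factor in self.marker_effects:
            if factor <= 0:
                raise ConfigurationError(
                    f"marker effect factor for {marker} must be > 0"
                )
            bad = set(phases) - set(PHASES)
            if bad:
                raise ConfigurationError(f"unknown phases in effect: {bad}")
            norm_effects.append((marker, frozenset(phases), float(factor)))
        self.marker_effects = norm_effects
        if not 0.0 <= self.slippage_fraction <= 1.0:
            raise ConfigurationError("slippage_fraction must be in [0, 1]")


@dataclass
class GeneratorConfig:
    """Everything needed to draw one labeled synthetic population."""

    n_cells: int = 20_000
    phase_occupancy: Sequence[float] = DEFAULT_OCCUPANCY
    templates: list[MarkerTemplate] = field(default_factory=default_templates)
    noise_cv: float = DEFAULT_NOISE_CV
    cell_line_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"JURKAT": {}}
    )
    line_probs: Optional[dict[str, float]] = None
    line_s_beta: Optional[dict[str, tuple[float, float]]] = None
    perturbation: Optional[PerturbationSpec] = None
    noncanonical_spec: list[tuple[str, str, float]] = field(default_factory=list)
    treatment: str = "untreated"
    sample_id: str = "S1"
    batch: str = "B1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ConfigurationError("n_cells must be positive")
        occ = np.asarray(self.phase_occupancy, dtype=float)
        if occ.shape != (4,) or abs(occ.sum() - 1.0) > 1e-9 or occ.min() < 0:
            raise ConfigurationError(
                "phase_occupancy must be a nonnegative 4-vector summing to 1 "
                "(within 1e-9)"
            )
        self.phase_occupancy = tuple(occ)
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        marker_names = {t.marker_name for t in self.templates}
        if len(marker_names) != len(self.templates):
            raise ConfigurationError("duplicate marker templates")
        for line, offsets in self.cell_line_offsets.items():
            for marker, factor in offsets.items():
                if marker not in marker_names:
                    raise ConfigurationError(
                        f"offset for unknown marker {marker!r} in line {line!r}"
                    )
                if factor <= 0:
                    raise ConfigurationError(
                        f"offset for {line}/{marker} must be > 0"
                    )
        for ref, phase, fraction in self.noncanonical_spec:
            if ref not in VIOLATION_TARGETS:
                raise ConfigurationError(f"unknown rule reference {ref!r}")
            if phase not in PHASES:
                raise ConfigurationError(f"unknown phase {phase!r}")
            if not 0.0 <= fraction <= 1.0:
                raise ConfigurationError("injection fraction must be in [0, 1]")

    @property
    def marker_names(self) -> list[str]:
        return [t.marker_name for t in self.templates]

    def template(self, marker: str) -> MarkerTemplate:
        for t in self.templates:
            if t.marker_name == marker:
                return t
        raise KeyError(marker)


@dataclass
class SyntheticDataset:
    """Raw-scale expression plus exact truth labels."""

    expression: ExpressionMatrix
    truth_phase: np.ndarray
    truth_canonical: np.ndarray
    truth_line: np.ndarray
    truth_treatment: np.ndarray
    config: GeneratorConfig

    def __post_init__(self) -> None:
        n = self.expression.n_cells
        for name in ("truth_phase", "truth_canonical", "truth_line",
                     "truth_treatment"):
            vec = np.asarray(getattr(self, name))
            if len(vec) != n:
                raise ConfigurationError(f"{name} has length {len(vec)} != {n}")
            setattr(self, name, vec)

    @property
    def n_cells(self) -> int:
        return self.expression.n_cells

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(
            expression=self.expression.copy(),
            truth_phase=self.truth_phase.copy(),
            truth_canonical=self.truth_canonical.copy(),
            truth_line=self.truth_line.copy(),
            truth_treatment=self.truth_treatment.copy(),
            config=self.config,
        )


def _sigma(cv: float) -> float:
    """Lognormal sigma for a multiplicative coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0


def _lognormal_factors(rng: np.random.Generator, sigma: np.ndarray) -> np.ndarray:
    """Unit-mean multiplicative noise: exp(z*sigma - sigma^2/2)."""
    z = rng.standard_normal(sigma.shape)
    return np.exp(z * sigma - 0.5 * sigma * sigma)


def simulate_population(config: GeneratorConfig) -> SyntheticDataset:
    """Draw one labeled population.

    Phases are multinomial draws from the configured occupancy (replaced by
    the perturbation's occupancy shift when present); each marker is lognormal
    around its phase-template location scaled by the cell line's offset; the
    DNA channel interpolates 2N -> 4N across a uniform (or per-line Beta)
    S-phase pseudo-position. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    markers = config.marker_names
    spec = config.perturbation

    occupancy = np.asarray(
        spec.occupancy_shift if spec is not None else config.phase_occupancy
    )
    phase_idx = rng.choice(4, size=n, p=occupancy)
    phases = np.asarray(PHASES)[phase_idx]

    lines = sorted(config.cell_line_offsets)
    if config.line_probs is not None:
        probs = np.array([config.line_probs[l] for l in lines], dtype=float)
        probs = probs / probs.sum()
    else:
        probs = np.full(len(lines), 1.0 / len(lines))
    line_of_cell = rng.choice(np.asarray(lines, dtype=object), size=n, p=probs)

    # S-phase pseudo-position: uniform by default, per-line Beta when lines
    # differ in replication progression.
    u = rng.uniform(size=n)
    if config.line_s_beta:
        for line in lines:
            if line in config.line_s_beta:
                a, b = config.line_s_beta[line]
                mask = line_of_cell == line
                u[mask] = rng.beta(a, b, size=int(mask.sum()))

    # Raw-scale location and spread matrices.
    loc = np.empty((n, len(markers)))
    rel_spread = np.empty((n, len(markers)))
    for j, tpl in enumerate(config.templates):
        for p_i, phase in enumerate(PHASES):
            mask = phase_idx == p_i
            loc[mask, j] = tpl.location(phase)
            rel_spread[mask, j] = tpl.spread(phase)
    # DNA content across S: 2N * (1 + u).
    if "DNA" in markers:
        j = markers.index("DNA")
        dna_2n = config.template("DNA").location("G0G1")
        s_mask = phases == "S"
        loc[s_mask, j] = dna_2n * (1.0 + u[s_mask])

    # Per-line multiplicative offsets.
    for line in lines:
        offsets = config.cell_line_offsets[line]
        if not offsets:
            continue
        mask = line_of_cell == line
        for marker, factor in offsets.items():
            loc[mask, markers.index(marker)] *= factor

    truth_canonical = np.ones(n, dtype=bool)

    # Perturbation: phase-restricted marker effects, then mitotic slippage.
    if spec is not None:
        for marker, eff_phases, factor in spec.marker_effects:
            if marker not in markers:
                raise ConfigurationError(f"effect on unknown marker {marker!r}")
            mask = np.isin(phases, list(eff_phases))
            loc[mask, markers.index(marker)] *= factor
        if spec.slippage_fraction > 0:
            if "DNA" not in markers:
                raise ConfigurationError("slippage requires a DNA channel")
            g0 = np.flatnonzero(phases == "G0G1")
            slip = g0[rng.random(len(g0)) < spec.slippage_fraction]
            dna_2n = config.template("DNA").location("G0G1")
            loc[slip, markers.index("DNA")] = dna_2n * spec.slippage_dna_factor
            truth_canonical[slip] = False

    if config.noise_cv > 0:
        sigma = _sigma(config.noise_cv) * rel_spread
        values = loc * _lognormal_factors(rng, sigma)
    else:
        values = loc.copy()

    treatment = spec.label if spec is not None else config.treatment
    cell_meta = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "sample": config.sample_id,
            "batch": config.batch,
            "treatment": treatment,
            "cell_line": line_of_cell.astype(str),
        }
    )
    ds = SyntheticDataset(
        expression=ExpressionMatrix(values, markers, cell_meta, "raw"),
        truth_phase=phases,
        truth_canonical=truth_canonical,
        truth_line=line_of_cell.astype(str),
        truth_treatment=np.full(n, treatment, dtype=object),
        config=config,
    )
    for i, (ref, phase, fraction) in enumerate(config.noncanonical_spec):
        ds = inject_noncanonical(ds, ref, phase, fraction,
                                 seed=config.seed + 10_000 + i)
    return ds


def inject_noncanonical(ds: SyntheticDataset, rule_ref: str, phase: str,
                        fraction: float, seed: int) -> SyntheticDataset:
    """Force a labeled canonical-rule violation into a fraction of one phase.

    Each cell of the target phase is independently selected with probability
    ``fraction``; its rule marker is redrawn around the rule's violating
    location (times the cell line's offset, with the dataset's noise level)
    and ``truth_canonical`` is set False for exactly the selected cells.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    if rule_ref not in VIOLATION_TARGETS:
        raise ConfigurationError(f"unknown rule reference {rule_ref!r}")
    if phase not in ds.truth_phase:
        raise ConfigurationError(f"phase {phase!r} absent from dataset")

    marker, target_loc = VIOLATION_TARGETS[rule_ref]
    out = ds.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    candidates = np.flatnonzero(out.truth_phase == phase)
    selected = candidates[rng.random(len(candidates)) < fraction]
    if len(selected) == 0:
        return out

    j = out.expression.channel_index(marker)
    cfg = out.config
    locs = np.full(len(selected), float(target_loc))
    for k, idx in enumerate(selected):
        offsets = cfg.cell_line_offsets.get(str(out.truth_line[idx]), {})
        locs[k] *= offsets.get(marker, 1.0)
    if cfg.noise_cv > 0:
        sigma = np.full(len(selected), _sigma(cfg.noise_cv))
        locs = locs * _lognormal_factors(rng, sigma)
    out.expression.values[selected, j] = locs
    out.truth_canonical[selected] = False
    return out


def apply_perturbation(config: GeneratorConfig, spec: PerturbationSpec,
                       seed: Optional[int] = None) -> SyntheticDataset:
    """Generate a perturbed population from a baseline configuration.

    The perturbation replaces the baseline occupancy, applies its marker
    effects, and adds slippage cells; everything else (templates, noise,
    lines) is inherited, so the result is the treated arm matched to the
    untreated arm drawn from ``config``.
    """
    cfg = dataclasses.replace(
        config,
        perturbation=spec,
        seed=config.seed if seed is None else seed,
    )
    return simulate_population(cfg)


def recommended_raw_gates(config: GeneratorConfig) -> dict[str, float]:
    """Raw-scale gate positions implied by the generator templates.

    Binary-positive gates sit at the geometric midpoint between background and
    the positive-phase location (symmetric under the lognormal noise model);
    the CyclinB1 G2 gate at the geometric midpoint of its S and G2 levels.
    """
    idu = config.template("IdU")
    ph3 = config.template("pH3_s10")
    cyb = config.template("CyclinB1")
    return {
        "idu_pos": math.sqrt(idu.location("G0G1") * idu.location("S")),
        "ph3_pos": math.sqrt(ph3.location("G0G1") * ph3.location("M")),
        "cyclinb1_high": math.sqrt(cyb.location("S") * cyb.location("G2")),
    }


def default_cleanup_raw() -> dict[str, tuple[float | None, float | None]]:
    """Raw-scale cleanup windows for synthetic data: cPARP-high pre-apoptotic
    removal and a DNA window standing in for debris/doublet exclusion."""
    return {"cPARP": (None, 20.0), "DNA": (25.0, 900.0)}


# ---------------------------------------------------------------------------
# Export / ingest


def export_dataset(ds: SyntheticDataset, path, format: str = "delimited") -> list[Path]:
    """Write expression plus a truth-label sidecar table.

    ``delimited`` writes one ``expression.csv`` (cell_id + channels) and
    ``truth.csv``; ``fcs`` writes one FCS 3.1 file per sample plus the same
    sidecar. Returns the written file paths.
    """
    if ds.n_cells == 0:
        raise ParameterError("refusing to export an empty dataset")
    if format not in ("delimited", "fcs"):
        raise ParameterError(f"unsupported format {format!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(ds.n_cells),
            "phase": ds.truth_phase,
            "canonical": ds.truth_canonical,
            "cell_line": ds.truth_line,
            "treatment": ds.truth_treatment,
            "sample": ds.expression.cell_meta["sample"].to_numpy(),
        }
    )
    truth_path = path / "truth.csv"
    truth.to_csv(truth_path, index=False)
    written.append(truth_path)

    meta_path = path / "generator.yaml"
    meta_path.write_text(
        yaml.safe_dump({"seed": ds.config.seed, "n_cells": ds.config.n_cells,
                        "noise_cv": ds.config.noise_cv})
    )
    written.append(meta_path)

    if format == "delimited":
        df = ds.expression.to_dataframe()
        df.insert(0, "cell_id", np.arange(ds.n_cells))
        for col in ("sample", "batch", "treatment", "cell_line"):
            df[col] = ds.expression.cell_meta[col].to_numpy()
        out = path / "expression.csv"
        df.to_csv(out, index=False)
        written.append(out)
    else:
        samples = ds.expression.cell_meta["sample"].to_numpy()
        for sample in pd.unique(samples):
            mask = samples == sample
            out = path / f"{sample}.fcs"
            write_fcs(out, ds.expression.values[mask], ds.expression.channel_names)
            written.append(out)
    return written
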