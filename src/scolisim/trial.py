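"""Trial orchestration: run the full factorial (subjects x targets x
plans) campaign, produce the tidy record table, and read/write it.

One record per executed simulation.  All randomness flows from two named
seeds (cohort seed, analysis seed); per-simulation failures are logged
and flagged, never abort the batch.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy, correction, metrics, planning
from .fe import DISC_MATERIAL, ROD_DIAMETER, ROD_MATERIAL, Material
from .geometry import SpineGeometry, level_index

logger = logging.getLogger(__name__)

__all__ = ["TrialConfig", "run_trial", "write_records", "read_records"]


@dataclass
class TrialConfig:
    """Trial configuration (mirrors the YAML config file schema)."""

    n_subjects: int = 30
    cohort_seed: int = 0
    analysis_seed: int = 0
    target_steps: tuple[float, ...] = planning.TARGET_STEPS
    patterns: tuple[str, ...] = planning.SCREW_PATTERNS
    pattern_table: dict[str, str] | None = None
    detect_threshold: float = 10.0  # deg, curve detection
    bin_width: float = 5.0  # deg, stratification bins in the analysis
    von_mises: bool = False  # rod stress formula flag
    rod_e_scale: float = 1.0  # multiplier on the titanium modulus
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def rod_material(self) -> Material:
        return Material(ROD_MATERIAL.E * self.rod_e_scale, ROD_MATERIAL.nu)

    @classmethod
    def from_yaml(cls, path) -> "TrialConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("target_steps", "patterns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


#: Columns of the record table; feature columns precede outcome metrics.
RECORD_COLUMNS = [
    "subject_id",
    "lenke",
    "cobb",
    "pattern",
    "instr_len",
    "apex",
    "apex_rot",
    "upper_cur",
    "lower_cur",
    "convexity",
    "uiv",
    "liv",
    "d_tk",
    "d_ll",
    "max_rod_stress",
    "max_screw_force",
    "stress_offset",
    "force_offset",
    "residual_cobb",
    "residual_rotation",
    "achieved_d_tk",
    "achieved_d_ll",
    "feasible",
    "seed",
    "coupling_force_residual",
    "coupling_moment_residual",
    "reaction_residual",
    "energy_imposed",
    "energy_disc_final",
    "energy_rod",
]


def run_trial(
    cohort: anatomy.CohortResult | list[tuple[str, SpineGeometry]],
    config: TrialConfig | None = None,
) -> pd.DataFrame:
    """Execute the factorial campaign over a cohort.

    Iterates subjects x targets x feasible plans; target geometry and the
    step-1 held state are shared across the plans of one (subject, target)
    pair.  Returns the tidy record table.
    """
    config = config or TrialConfig()
    if isinstance(cohort, anatomy.CohortResult):
        subjects = list(cohort)
        seeds = dict(zip(cohort.subject_ids, cohort.manifest["seed"]))
    else:
        subjects = list(cohort)
        seeds = {sid: config.cohort_seed for sid, _ in subjects}
    if not subjects:
        raise ValueError("empty cohort")
    targets = planning.enumerate_targets(config.target_steps)
    records: list[dict] = []
    n_failed = 0
    for sid, geom in subjects:
        t_start = time.perf_counter()
        curves = metrics.detect_curves(geom, config.detect_threshold)
        if not curves:
            logger.warning("%s: no curve detected, subject skipped", sid)
            continue
        major = max(curves, key=lambda c: c.cobb)
        lenke = metrics.classify_lenke(curves, metrics.measure_sagittal(geom))
        skeleton = planning.enumerate_plans(
            geom, major, pattern_table=config.pattern_table, patterns=config.patterns
        )
        base = {
            "subject_id": sid,
            "lenke": lenke,
            "cobb": major.cobb,
            "apex": major.apex,
            "apex_rot": major.apical_rotation,
            "upper_cur": major.upper_end,
            "lower_cur": major.lower_end,
            "convexity": major.convexity,
            "seed": seeds[sid],
        }
        n_ok = 0
        for target in targets:
            tgt_geom = planning.build_target_geometry(geom, target)
            prestress = correction.disc_prestress(geom, tgt_geom)
            for plan in skeleton:
                row = dict(base)
                row.update(
                    pattern=plan.pattern,
                    instr_len=plan.n_levels,
                    uiv=plan.uiv,
                    liv=plan.liv,
                    d_tk=target.d_tk,
                    d_ll=target.d_ll,
                )
                try:
                    res = correction.simulate_correction(
                        geom,
                        target,
                        plan,
                        major=major,
                        rod_material=config.rod_material,
                        von_mises=config.von_mises,
                        target_geometry=tgt_geom,
                        prestress=prestress,
                    )
                    row.update(
                        max_rod_stress=res.max_rod_stress,
                        max_screw_force=res.max_screw_force,
                        stress_offset=res.stress_offset,
                        force_offset=res.force_offset,
                        residual_cobb=res.residual_cobb,
                        residual_rotation=res.residual_rotation,
                        achieved_d_tk=res.achieved_d_tk,
                        achieved_d_ll=res.achieved_d_ll,
                        feasible=True,
                        **{
                            k: res.diagnostics[k]
                            for k in (
                                "coupling_force_residual",
                                "coupling_moment_residual",
                                "reaction_residual",
                                "energy_imposed",
                                "energy_disc_final",
                                "energy_rod",
                            )
                        },
                    )
                except Exception as exc:
                    n_failed += 1
                    logger.error(
                        "%s target (%g, %g) plan %s %s-%s failed: %s",
                        sid, target.d_tk, target.d_ll, plan.pattern, plan.uiv, plan.liv, exc,
                    )
                    row.update(feasible=False)
                records.append(row)
                n_ok += 1
        logger.info(
            "%s: %d plans x %d targets -> %d records in %.1f s",
            sid, len(skeleton), len(targets), n_ok, time.perf_counter() - t_start,
        )
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    if n_failed:
        logger.warning("%d simulations failed and were flagged infeasible", n_failed)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(df, out / "records.tsv")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    """Write the record table as tab-delimited text (lossless floats)."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    records.to_csv(path, sep="\t", index=False)


def read_records(path) -> pd.DataFrame:
    """Read a record table, validating the header."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed record file {path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file {path} missing columns: {missing}")
    for col in ("max_rod_stress", "max_screw_force", "cobb", "apex_rot"):
        bad = df.index[df[col].isna() & df["feasible"]]
        if len(bad):
            raise ValueError(
                f"record file {path}: missing value in column {col!r} at row {bad[0] + 2}"
            )
    return df
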