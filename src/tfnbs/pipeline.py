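"""End-to-end orchestration: simulate -> harmonize -> GLM -> TFNBS -> summarize.

A run is fully described by a :class:`RunConfig`; given the same config and
seed it writes byte-identical outputs. Each stage's parameters and artifact
paths land in ``metadata.json`` inside the run directory. Defaults mirror a
standard connectome group comparison: 5000 permutations, alpha 0.05, age and
sex as nuisance covariates, both tested directionalities reported.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .enhance import E_DEFAULT, H_DEFAULT, K_DEFAULT, tfce_enhance
from .glm import build_design, edge_tstats
from .harmonize import apply_combat, build_dataset, fit_combat
from .permutation import permutation_pvalues
from .simulate import CohortSpec, simulate_cohort
from .summarize import lobe_pair_summary, significant_edges, top_connections

__all__ = ["RunConfig", "run_pipeline", "subgroup_run"]

logger = logging.getLogger(__name__)

DIRECTION_NAMES = {1: "increase", -1: "decrease"}


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``group_column``/``group_levels`` choose the contrast (e.g. patients vs
    controls, or a within-patient subgroup label); ``directions`` lists the
    tested tails (+1: tested level larger, -1: tested level smaller).
    """

    seed: int = 0
    min_prevalence: float = 1.0
    log_offset: float | None = None
    harmonize: bool = True
    combat_tol: float = 1e-4
    combat_max_iter: int = 100
    group_column: str = "group"
    group_levels: tuple | None = None
    nuisance: tuple = ("age", "sex")
    directions: tuple = (-1, 1)
    tfce_E: float = E_DEFAULT
    tfce_H: float = H_DEFAULT
    tfce_steps: int = K_DEFAULT
    n_permutations: int = 5000
    scheme: str = "freedman_lane"
    alpha: float = 0.05
    correction: str = "corrected"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None  # read a written cohort instead of simulating

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for tup_key in ("group_levels", "nuisance", "directions"):
            if raw.get(tup_key) is not None:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(cohort=cohort, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        return d


def _load_or_simulate(config: RunConfig):
    if config.input_dir is not None:
        matrices, covariates, parcellation = tio.read_cohort(config.input_dir)
        return matrices, covariates, parcellation
    spec = replace(config.cohort, seed=config.seed)
    cohort = simulate_cohort(spec)
    return cohort.matrices, cohort.covariates, cohort.parcellation


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute every stage and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.to_dict(), "stages": {}}

    try:
        matrices, covariates, parcellation = _load_or_simulate(config)
        meta["stages"]["input"] = {
            "n_subjects": len(matrices),
            "n_nodes": parcellation.n_nodes,
            "source": config.input_dir or "simulated",
        }
        required = {config.group_column, *config.nuisance, "batch"}
        missing = sorted(required - set(covariates.columns))
        if missing:
            raise ValueError(f"manifest is missing required columns {missing}")

        dataset = build_dataset(
            matrices,
            covariates,
            parcellation,
            min_prevalence=config.min_prevalence,
            offset=config.log_offset,
        )
        meta["stages"]["filter_log"] = {
            "min_prevalence": config.min_prevalence,
            "n_edges": dataset.n_edges,
        }

        if config.harmonize:
            model = fit_combat(
                dataset,
                preserve_columns=(config.group_column, *config.nuisance),
                tol=config.combat_tol,
                max_iter=config.combat_max_iter,
            )
            dataset = apply_combat(
                model, dataset, preserve_columns=(config.group_column, *config.nuisance)
            )
            tio.write_model_json(model, out / "combat_model.json")
            meta["stages"]["harmonize"] = {
                "batches": [str(b) for b in model.batches],
                "n_iter": model.n_iter,
            }
        tio.write_dataset_tsv(dataset, out / "edge_values.tsv", out / "manifest.tsv")

        design = build_design(
            dataset.covariates,
            group_column=config.group_column,
            levels=config.group_levels,
            nuisance=config.nuisance,
        )
        meta["stages"]["glm"] = {
            "columns": design.columns,
            "group_levels": list(design.group_levels),
            "n_subjects_kept": design.n_subjects,
        }

        summaries = []
        for d_i, direction in enumerate(config.directions):
            name = DIRECTION_NAMES[int(np.sign(direction))]
            stat = edge_tstats(dataset, design, direction=direction)
            enhanced = tfce_enhance(
                stat, E=config.tfce_E, H=config.tfce_H, n_steps=config.tfce_steps
            )
            pgraphs = permutation_pvalues(
                dataset,
                design,
                E=config.tfce_E,
                H=config.tfce_H,
                n_steps=config.tfce_steps,
                n_permutations=config.n_permutations,
                seed=config.seed + 1000 * d_i,
                scheme=config.scheme,
                direction=direction,
                store_null_edge=False,
            )
            tio.write_matrix_csv(stat.t, out / f"t_{name}.csv")
            tio.write_matrix_csv(enhanced.score, out / f"score_{name}.csv")
            tio.write_matrix_csv(pgraphs.p_corrected, out / f"p_corrected_{name}.csv")
            tio.write_matrix_csv(pgraphs.p_uncorrected, out / f"p_uncorrected_{name}.csv")
            np.savetxt(out / f"null_max_{name}.tsv", pgraphs.null_max, fmt="%.17g")

            for correction in ("corrected", "uncorrected"):
                mask, count = significant_edges(pgraphs, config.alpha, correction)
                table = lobe_pair_summary(mask, parcellation, name, correction)
                summaries.append(table)
            top = top_connections(pgraphs, stat, parcellation, k=16, alpha=config.alpha)
            top.to_csv(
                out / f"top_connections_{name}.csv", index=False, float_format="%.17g"
            )
            meta["stages"][f"tfnbs_{name}"] = {
                "n_permutations": pgraphs.n_permutations,
                "exhaustive": pgraphs.exhaustive,
                "seed": pgraphs.seed,
                "n_significant_corrected": int(
                    significant_edges(pgraphs, config.alpha, "corrected")[1]
                ),
                "n_significant_uncorrected": int(
                    significant_edges(pgraphs, config.alpha, "uncorrected")[1]
                ),
            }

        pd.concat(summaries, ignore_index=True).to_csv(
            out / "lobe_pair_summary.csv", index=False, float_format="%.17g"
        )
        meta["stages"]["summarize"] = {"alpha": config.alpha}
    except Exception as exc:  # re-raise with stage context in metadata
        meta["error"] = f"{type(exc).__name__}: {exc}"
        tio.write_json(meta, out / "metadata.json")
        raise
    tio.write_json(meta, out / "metadata.json")
    return out


def subgroup_run(
    config: RunConfig, subgroup_column: str, levels: tuple, out_dir
) -> Path:
    """Rerun the identical downstream pipeline on a subgroup contrast.

    ``levels=(reference, tested)`` must both be present with >= 2 subjects;
    subjects outside them (e.g. controls in a within-patient contrast) are
    dropped by the design stage.
    """
    if len(levels) != 2:
        raise ValueError("exactly two subgroup levels required")
    sub_config = replace(
        config, group_column=subgroup_column, group_levels=tuple(levels)
    )
    return run_pipeline(sub_config, out_dir)
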