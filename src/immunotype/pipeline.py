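"""End-to-end orchestration: simulate/load -> preprocess -> cluster ->
significance -> characterise, with deterministic seeding and a run manifest.

A single global seed deterministically spawns per-stage sub-seeds, so stages
are reproducible independently and the whole run is bit-reproducible for a
fixed configuration. The two sensitivity analyses (daily smoking as an extra
clustering covariate; exclusion of subjects with BMI > 30 or a major physical
health condition) are configuration presets, not separate code paths.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import characterisation_report
from .hydra import HydraConfig, adjusted_rand_index, fit_polytope, stability_analysis
from .preprocess import QCConfig, residualise_covariates, run_preprocess
from .significance import permutation_null, sigclust_test
from .synthetic import CohortTable, SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_full", "events_per_variable_check"]


@dataclass
class PipelineConfig:
    input_dir: str | None = None  # cohort TSVs; None -> simulate
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    hydra: HydraConfig = field(default_factory=HydraConfig)
    n_sim: int = 1000
    n_perm: int = 100
    n_main_reps: int = 20
    covariates: tuple[str, ...] = ("female", "bmi")
    add_smoking_covariate: bool = False
    exclude_high_bmi_or_physical: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(data)
        if "synthetic" in kwargs:
            kwargs["synthetic"] = SyntheticConfig(**kwargs["synthetic"])
        if "qc" in kwargs:
            kwargs["qc"] = QCConfig(**kwargs["qc"])
        if "hydra" in kwargs:
            kwargs["hydra"] = HydraConfig(**kwargs["hydra"])
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return cls(**kwargs)

    def content_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def events_per_variable_check(n_cases: int, n_markers: int) -> tuple[bool, float]:
    """Overfitting guard: events (cases) per variable must exceed 20."""
    if n_markers < 1:
        raise ValueError("need at least one marker")
    if n_cases < 1:
        raise ValueError("need at least one case")
    ratio = n_cases / n_markers
    return ratio > 20.0, ratio


def _stage_seed(global_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % 2**31)


def run_full(config: PipelineConfig, outdir) -> Path:
    """Run the full analysis; returns the populated run directory.

    Any stage failure writes a FAILED marker naming the stage and re-raises;
    partial outputs are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- cohort -------------------------------------------------------
        stage = "cohort"
        if config.input_dir is not None:
            cohort = CohortTable.read(config.input_dir)
            truth = None
        else:
            synth_cfg = SyntheticConfig(
                **{**config.synthetic.__dict__, "seed": _stage_seed(config.seed, 0)}
            )
            cohort, truth = generate_cohort(synth_cfg)
            cohort.write(outdir / "cohort")

        participants = cohort.participants
        if config.exclude_high_bmi_or_physical:
            keep = ~(
                (participants["bmi"] > 30)
                | (participants.get("physical_condition", 0) == 1)
            )
            participants = participants[keep].reset_index(drop=True)
            kept_ids = set(participants["subject_id"])
            cohort = CohortTable(
                participants,
                cohort.measurements[
                    cohort.measurements["subject_id"].isin(kept_ids)
                ].reset_index(drop=True),
                cohort.panel,
            )
            if truth is not None:
                truth = truth[truth.index.isin(kept_ids)]

        # --- preprocessing ------------------------------------------------
        stage = "preprocess"
        processed = run_preprocess(cohort, config.qc)
        processed.write(outdir / "preprocessed")
        epv_ok, epv = events_per_variable_check(
            int((participants["group"] == "case").sum()),
            processed.values.shape[1],
        )
        if not epv_ok:
            print(
                f"warning: events-per-variable {epv:.1f} <= 20",
                file=sys.stderr,
            )

        # --- clustering ---------------------------------------------------
        stage = "cluster"
        covariate_names = list(config.covariates)
        if config.add_smoking_covariate:
            covariate_names.append("daily_smoker")
        covs = participants.set_index("subject_id").loc[
            processed.values.index, covariate_names
        ]
        case_mask = (
            participants.set_index("subject_id")
            .loc[processed.values.index, "group"]
            .eq("case")
            .to_numpy()
        )
        hydra_cfg = HydraConfig(
            **{**config.hydra.__dict__, "seed": _stage_seed(config.seed, 1)}
        )
        case_ids = list(processed.values.index[case_mask])
        consensus = stability_analysis(
            processed.values.to_numpy(),
            case_mask,
            covs,
            hydra_cfg,
            case_ids=case_ids,
        )
        consensus.stability_table().to_csv(
            outdir / "stability.tsv", sep="\t", index=False
        )
        selected_k = consensus.selected_k
        labels = pd.Series(
            consensus.per_k[selected_k].consensus, index=pd.Index(case_ids,
            name="subject_id"), name="cluster",
        )
        labels.to_csv(outdir / "consensus_labels.tsv", sep="\t")

        adjusted = residualise_covariates(
            processed.values, covs.reset_index(drop=True), ~case_mask
        ).to_numpy()
        polytope, _, _ = fit_polytope(
            adjusted, case_mask, selected_k, hydra_cfg,
            np.random.default_rng(hydra_cfg.seed),
        )
        (outdir / "polytope.json").write_text(json.dumps(polytope.to_dict()))

        # --- significance -------------------------------------------------
        stage = "significance"
        sig = sigclust_test(
            adjusted[case_mask],
            labels=labels.to_numpy(),
            n_sim=config.n_sim,
            seed=_stage_seed(config.seed, 2),
        )
        perm = permutation_null(
            processed.values.to_numpy(),
            case_mask,
            covs,
            hydra_cfg,
            n_perm=config.n_perm,
            n_main_reps=config.n_main_reps,
            seed=_stage_seed(config.seed, 3),
            k=selected_k,
        )
        (outdir / "significance.json").write_text(
            json.dumps(
                {
                    "sigclust": {
                        "observed_ci": sig.observed_ci,
                        "p_value": sig.p_value,
                        "sigma2_background": sig.sigma2_background,
                        "eigenvalues": sig.eigenvalues.tolist(),
                    },
                    "permutation": {
                        "main_ari_mean": float(perm.main_aris.mean()),
                        "null_ari_mean": float(perm.null_aris.mean()),
                        "null_ari_sd": float(perm.null_aris.std(ddof=1)),
                        "welch_t": perm.welch_t,
                        "welch_df": perm.welch_df,
                        "welch_p": perm.welch_p,
                    },
                },
                indent=2,
            )
        )
        pd.DataFrame({"null_mean_ari": perm.null_aris}).to_csv(
            outdir / "permutation_null_aris.tsv", sep="\t", index=False
        )

        # --- characterisation --------------------------------------------
        stage = "characterise"
        report = characterisation_report(participants, labels)
        report.to_csv(outdir / "characterisation.tsv", sep="\t", index=False)

        manifest = {
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "markers": list(processed.values.columns),
            "excluded_markers": processed.excluded_markers,
            "events_per_variable": epv,
            "selected_k": int(selected_k),
            "stability": {
                str(k): [r.mean_ari, r.sd_ari] for k, r in consensus.per_k.items()
            },
            "truth_ari": (
                float(
                    adjusted_rand_index(
                        labels.loc[truth.index].to_numpy(), truth.to_numpy()
                    )
                )
                if truth is not None
                else None
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {err}\n")
        raise
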