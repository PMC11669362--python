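"""End-to-end orchestration: normalize -> activity -> PAL -> features ->
screening -> selection -> signature, with a machine-readable run manifest.

Every emitted table is deterministic for a fixed input directory and config;
the manifest echoes the config and seed so each number is reproducible from
it alone.  Figures are optional side artifacts; everything consumed by tests
and the acceptance machinery is TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import compute_activity, normalize_median_of_ratios
from .features import compute_tmb, hla_features, mutation_flags
from .pathways import pal_matrix
from .screening import intersect_biomarkers, screen_biomarkers
from .signature import backward_eliminate, evaluate_signature
from .synthetic import load_cohort_dir

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "normalize", "activity", "pal", "features", "screening", "selection", "signature",
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and tuning knobs for a full pipeline run."""

    input_dir: str
    alpha: float = 0.05
    min_frac: float = 0.3
    auc_cutoff: float = 0.62
    hr_low: float = 0.4
    hr_high: float = 2.5
    tmb_cutoff: float = 10.0
    capture_mb: float = 30.0
    pseudocount: float = 1.0
    ridge: float = 1e-4
    seed: int = 0
    subset: str | None = None  # histotype filter, None = all

    def __post_init__(self) -> None:
        for name in ("alpha", "min_frac", "auc_cutoff", "hr_low", "hr_high",
                     "tmb_cutoff", "capture_mb", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.subset is not None and self.subset not in (
            "adenocarcinoma", "squamous", "other"
        ):
            raise ValueError(f"unknown histotype subset {self.subset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(manifest: list, name: str, status: str, **info) -> None:
    manifest.append({"stage": name, "status": status, **info})


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all seven stages and write results under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    data = load_cohort_dir(config.input_dir)
    clinical = data["clinical"]
    if config.subset is not None:
        keep = clinical["histotype"] == config.subset
        logger.info(
            "subset %s: %d of %d samples retained", config.subset,
            int(keep.sum()), len(clinical),
        )
        clinical = clinical[keep]

    try:
        # 1. joint normalization of tumors and the control panel
        tumors, controls = data["expression"], data["controls"]
        combined = tumors.values.join(controls.values, how="inner")
        from .expression import ExpressionMatrix

        normalized, size_factors = normalize_median_of_ratios(
            ExpressionMatrix(combined, stage="raw"), pseudocount=config.pseudocount
        )
        norm_tumors = normalized.values[list(tumors.sample_ids)]
        norm_controls = ExpressionMatrix(
            normalized.values[list(controls.sample_ids)], stage="normalized"
        )
        size_factors.to_csv(outdir / "size_factors.tsv", sep="\t")
        _stage(stages, "normalize", "ok", n_genes=int(combined.shape[0]),
               n_tumor=int(tumors.shape[1]), n_control=int(controls.shape[1]))

        # 2. per-sample CNR/BTIF against the control panel
        activities = {
            sample: compute_activity(
                norm_tumors[sample], norm_controls, alpha=config.alpha,
                sample_id=sample,
            )
            for sample in norm_tumors.columns
        }
        _stage(stages, "activity", "ok", n_samples=len(activities))

        # 3. pathway activation levels
        pal = pal_matrix(data["pathways"], activities)
        pal.to_csv(outdir / "pal.tsv", sep="\t", index_label="pathway_id")
        _stage(stages, "pal", "ok", n_pathways=int(pal.shape[0]))

        # 4. marker assembly: expression + PAL + WES-derived features
        tumor_samples = list(norm_tumors.columns)
        blocks = [
            norm_tumors.rename(index=lambda g: f"expr:{g}"),
            pal.rename(index=lambda p: f"pal:{p}"),
        ]
        tmb = compute_tmb(
            data["variants"], config.capture_mb, sample_ids=tumor_samples,
            high_cutoff=config.tmb_cutoff,
        )
        blocks.append(pd.DataFrame({"tmb": tmb["tmb"],
                                    "tmb_high": tmb["high"].astype(int)}).T)
        muts = mutation_flags(data["variants"], sample_ids=tumor_samples)
        blocks.append(muts.T)
        hla = hla_features(data["hla"]).reindex(tumor_samples, fill_value=0)
        blocks.append(hla.T)
        if data.get("binary_features") is not None and len(data["binary_features"].columns):
            blocks.append(data["binary_features"].reindex(tumor_samples, fill_value=0).T)
        markers = pd.concat(blocks).reindex(columns=tumor_samples)
        markers.to_csv(outdir / "markers.tsv", sep="\t", index_label="id")
        _stage(stages, "features", "ok", n_markers=int(markers.shape[0]))

        # 5. screening on both axes
        results = screen_biomarkers(
            markers, clinical, min_frac=config.min_frac,
            hr_low=config.hr_low, hr_high=config.hr_high,
            auc_cutoff=config.auc_cutoff, alpha=config.alpha,
        )
        results.to_csv(outdir / "results.tsv", sep="\t", index=False)
        _stage(stages, "screening", "ok", n_screened=int(results.shape[0]))

        # 6. selection filters and their intersection
        pfs_ids = list(results["id"][results["selected_pfs"]])
        resp_ids = list(results["id"][results["selected_response"]])
        both = intersect_biomarkers(pfs_ids, resp_ids)
        with open(outdir / "selected.json", "w") as fh:
            json.dump({"pfs": pfs_ids, "response": resp_ids, "intersection": both},
                      fh, indent=1)
        _stage(stages, "selection", "ok", n_pfs=len(pfs_ids),
               n_response=len(resp_ids), n_intersection=len(both))

        # 7. signature construction + evaluation on the training cohort
        if len(both) >= 2:
            model, trace = backward_eliminate(
                markers.loc[both], clinical, min_frac=config.min_frac,
                ridge=config.ridge,
            )
            model.to_json(outdir / "model.json")
            with open(outdir / "trace.json", "w") as fh:
                json.dump([dataclasses.asdict(s) for s in trace], fh, indent=1)
            report = evaluate_signature(
                model, markers, clinical, min_frac=config.min_frac
            )
            report["scores"].to_csv(outdir / "scores.tsv", sep="\t")
            summary = {
                k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in report.items()
                if k in ("auc", "hr", "hr_p", "threshold", "logrank_p",
                         "n", "n_high", "n_low", "message")
            }
            summary["components"] = model.components
            with open(outdir / "evaluation.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            _stage(stages, "signature", "ok",
                   n_components=len(model.components),
                   n_eliminated=sum(s.accepted for s in trace))
        else:
            _stage(stages, "signature", "skipped",
                   reason=f"only {len(both)} intersected biomarker(s); need >= 2")
    except Exception as exc:
        failed = STAGE_NAMES[len(stages)] if len(stages) < len(STAGE_NAMES) else "?"
        _stage(stages, failed, "failed", error=str(exc))
        _write_manifest(outdir, config, stages)
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    _write_manifest(outdir, config, stages)
    return outdir


def _write_manifest(outdir: Path, config: RunConfig, stages: list[dict]) -> None:
    manifest = {
        "package": "immunomark",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": stages,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
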