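"""Seed-reproducible synthetic cohorts with planted biomarker effects.

The generator emits everything the downstream pipeline consumes — tumor count
matrix, control panel, clinical annotation, pathway collection + interactome,
variant and HLA tables — with the statistical structure the analysis assumes:

* gene counts are rounded log-normal; tumor and control samples share
  per-gene baselines;
* progression-free survival follows an exponential proportional-hazards
  model whose log hazard is the baseline plus the sum of planted effects
  times each informative gene's standardized latent value, with independent
  uniform censoring;
* the RECIST label is drawn from a logistic model on the response-informative
  genes, with the intercept calibrated to the requested responder fraction;
* binary features (HLA-allele-like or mutation-like) are planted with
  configurable prevalence and odds ratio w.r.t. response.

A ``truth`` record lists exactly the planted effects so recovery experiments
never have to re-derive them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .pathways import ARR_VALUES, EDGE_TYPES, Pathway, merge_interactome, \
    write_interactome_tsv, write_pathways_gmt, write_pathways_json

__all__ = [
    "MarkerEffect",
    "CategoricalFeature",
    "SimConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_pathways",
    "write_cohort",
    "load_cohort_dir",
]

HISTOTYPES = ("adenocarcinoma", "squamous", "other")
HLA_LOCI = ("A", "B", "C")
_ALLELES_PER_LOCUS = 6


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class MarkerEffect:
    """Planted effect of one gene: log-fold effect on the hazard and
    log-odds effect on response, both per standardized expression unit."""

    gene: str
    hazard: float = 0.0
    response: float = 0.0


@dataclass
class CategoricalFeature:
    """Planted binary feature. Names like ``KRAS_mut`` materialize as variant
    rows for that gene; names like ``hla:A*02:05`` as HLA allele calls;
    anything else lands in the generic binary feature table."""

    name: str
    prevalence: float
    odds_ratio: float = 1.0


@dataclass
class SimConfig:
    n_tumor: int = 61
    n_control: int = 20
    n_genes: int = 300
    informative_genes: list[MarkerEffect] = field(default_factory=list)
    baseline_log_mean_sd: tuple[float, float] = (5.0, 1.0)
    gene_log_sd: float = 0.7
    baseline_hazard: float = 0.12  # events per month
    censor_window: float = 36.0
    responder_target_fraction: float = 0.25
    cr_fraction: float = 0.2  # CR share among responders
    sd_fraction: float = 0.5  # SD share among non-responders
    n_pathways: int = 6
    pathway_size_range: tuple[int, int] = (5, 12)
    categorical_features: list[CategoricalFeature] = field(default_factory=list)
    background_mutation_rate: float = 150.0  # Poisson mean per sample
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_control", "n_genes", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_control < 2:
            raise ConfigurationError("n_control must be at least 2")
        for name in ("responder_target_fraction", "cr_fraction", "sd_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.censor_window <= 0:
            raise ConfigurationError("censor_window must be positive")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ConfigurationError("pathway_size_range exceeds n_genes")
        if len(self.informative_genes) > self.n_genes:
            raise ConfigurationError("more informative genes than genes")
        for feat in self.categorical_features:
            if not 0 < feat.prevalence < 1:
                raise ConfigurationError(f"prevalence of {feat.name!r} not in (0, 1)")
            if feat.odds_ratio <= 0:
                raise ConfigurationError(f"odds ratio of {feat.name!r} must be positive")

    @classmethod
    def from_dict(cls, payload: dict) -> "SimConfig":
        payload = dict(payload)
        payload["informative_genes"] = [
            MarkerEffect(**e) if isinstance(e, dict) else MarkerEffect(*e)
            for e in payload.get("informative_genes", [])
        ]
        payload["categorical_features"] = [
            CategoricalFeature(**e) if isinstance(e, dict) else CategoricalFeature(*e)
            for e in payload.get("categorical_features", [])
        ]
        for key in ("baseline_log_mean_sd", "pathway_size_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    control_panel: ExpressionMatrix
    clinical: pd.DataFrame
    pathways: list[Pathway]
    interactome: object  # nx.MultiDiGraph
    variants: pd.DataFrame
    hla: pd.DataFrame
    binary_features: pd.DataFrame
    truth: dict


def _gene_ids(config: SimConfig) -> list[str]:
    named = [e.gene for e in config.informative_genes]
    fillers = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    out = list(named)
    for g in fillers:
        if len(out) == config.n_genes:
            break
        if g not in out:
            out.append(g)
    return out


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Bisection on the intercept so that mean sigmoid(b + linear) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(mid + linear)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _conditional_prevalences(prevalence: float, odds_ratio: float, resp_frac: float):
    """Solve P(feature | non-responder) = p0 and P(feature | responder) = p1
    such that the odds ratio is as planted and the marginal matches."""

    def p1_of(p0: float) -> float:
        odds = odds_ratio * p0 / (1.0 - p0)
        return odds / (1.0 + odds)

    lo, hi = 1e-9, 1.0 - 1e-9
    for _ in range(200):
        mid = (lo + hi) / 2.0
        marginal = (1.0 - resp_frac) * mid + resp_frac * p1_of(mid)
        if marginal < prevalence:
            lo = mid
        else:
            hi = mid
    p0 = (lo + hi) / 2.0
    return p0, p1_of(p0)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a complete cohort; two calls with the same config are identical."""
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config)
    n_g, n_t, n_c = len(genes), config.n_tumor, config.n_control
    tumor_ids = [f"T{i:04d}" for i in range(1, n_t + 1)]
    control_ids = [f"N{i:04d}" for i in range(1, n_c + 1)]

    mu0, sd0 = config.baseline_log_mean_sd
    base_mu = rng.normal(mu0, sd0, size=n_g)

    z_tumor = rng.standard_normal((n_g, n_t))
    z_control = rng.standard_normal((n_g, n_c))
    tumor_counts = np.rint(np.exp(base_mu[:, None] + config.gene_log_sd * z_tumor))
    control_counts = np.rint(np.exp(base_mu[:, None] + config.gene_log_sd * z_control))

    gene_pos = {g: i for i, g in enumerate(genes)}
    log_hazard = np.full(n_t, np.log(config.baseline_hazard))
    response_linear = np.zeros(n_t)
    for eff in config.informative_genes:
        z = z_tumor[gene_pos[eff.gene]]
        log_hazard += eff.hazard * z
        response_linear += eff.response * z

    event_time = rng.exponential(1.0, size=n_t) / np.exp(log_hazard)
    censor_time = rng.uniform(0.0, config.censor_window, size=n_t)
    event = (event_time <= censor_time).astype(int)
    pfs = np.minimum(event_time, censor_time)

    intercept = _calibrate_intercept(response_linear, config.responder_target_fraction)
    p_resp = 1.0 / (1.0 + np.exp(-(intercept + response_linear)))
    responder = rng.uniform(size=n_t) < p_resp
    u = rng.uniform(size=n_t)
    recist = np.where(
        responder,
        np.where(u < config.cr_fraction, "CR", "PR"),
        np.where(u < config.sd_fraction, "SD", "PD"),
    )

    histotype = rng.choice(HISTOTYPES, size=n_t, p=(0.40, 0.44, 0.16))
    anti_pd1 = (rng.uniform(size=n_t) < 0.88).astype(int)
    anti_pdl1 = (1 - anti_pd1) | (rng.uniform(size=n_t) < 0.02).astype(int)
    anti_ctla4 = (rng.uniform(size=n_t) < 0.18).astype(int)
    clinical = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "histotype": histotype,
            "recist": recist,
            "pfs_months": np.round(pfs, 3),
            "event": event,
            "anti_pd1": anti_pd1,
            "anti_pdl1": anti_pdl1,
            "anti_ctla4": anti_ctla4,
            "sex": rng.choice(("F", "M"), size=n_t, p=(0.33, 0.67)),
            "age": rng.integers(41, 80, size=n_t),
        }
    ).set_index("sample_id", drop=False)

    # planted binary features, conditioned on responder status
    resp_frac = float(responder.mean()) if 0 < responder.mean() < 1 else \
        config.responder_target_fraction
    feature_flags: dict[str, np.ndarray] = {}
    for feat in config.categorical_features:
        p0, p1 = _conditional_prevalences(feat.prevalence, feat.odds_ratio, resp_frac)
        prob = np.where(responder, p1, p0)
        feature_flags[feat.name] = (rng.uniform(size=n_t) < prob).astype(int)

    variants = _materialize_variants(config, rng, tumor_ids, feature_flags)
    hla = _materialize_hla(rng, tumor_ids, feature_flags)
    generic = {
        name: flags for name, flags in feature_flags.items()
        if not name.endswith("_mut") and not name.startswith("hla:")
    }
    binary_features = pd.DataFrame(generic, index=tumor_ids)
    binary_features.index.name = "sample_id"

    pathways, interactome = simulate_pathways(config)
    truth = {
        "informative_genes": [dataclasses.asdict(e) for e in config.informative_genes],
        "categorical_features": [
            dataclasses.asdict(f) for f in config.categorical_features
        ],
        "response_intercept": intercept,
        "responder_fraction": float(responder.mean()),
        "event_fraction": float(event.mean()),
        "seed": config.seed,
    }
    return SimulatedCohort(
        expression=ExpressionMatrix(
            pd.DataFrame(tumor_counts, index=genes, columns=tumor_ids), stage="raw"
        ),
        control_panel=ExpressionMatrix(
            pd.DataFrame(control_counts, index=genes, columns=control_ids), stage="raw"
        ),
        clinical=clinical,
        pathways=pathways,
        interactome=interactome,
        variants=variants,
        hla=hla,
        binary_features=binary_features,
        truth=truth,
    )


def _materialize_variants(config, rng, tumor_ids, feature_flags) -> pd.DataFrame:
    mut_features = {n[:-4]: f for n, f in feature_flags.items() if n.endswith("_mut")}
    background_genes = [f"MUT{i:03d}" for i in range(1, 41)]
    rows = []
    for i, sample in enumerate(tumor_ids):
        n_mut = rng.poisson(config.background_mutation_rate)
        for gene in rng.choice(background_genes, size=n_mut):
            klass = "nonsynonymous" if rng.uniform() < 0.7 else "synonymous"
            rows.append((sample, gene, klass))
        for gene, flags in mut_features.items():
            if flags[i]:
                rows.append((sample, gene, "nonsynonymous"))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "effect_class"])


def _materialize_hla(rng, tumor_ids, feature_flags) -> pd.DataFrame:
    vocab = {
        locus: [f"{locus}*{j:02d}:01" for j in range(1, _ALLELES_PER_LOCUS + 1)]
        for locus in HLA_LOCI
    }
    planted = {}  # locus -> (allele, flags)
    for name, flags in feature_flags.items():
        if name.startswith("hla:"):
            allele = name[4:]
            locus = allele.split("*")[0]
            if locus not in vocab:
                raise ConfigurationError(f"unknown HLA locus in feature {name!r}")
            if allele not in vocab[locus]:
                vocab[locus].append(allele)
            planted[locus] = (allele, flags)
    rows = []
    for i, sample in enumerate(tumor_ids):
        for locus in HLA_LOCI:
            pool = vocab[locus]
            a1, a2 = rng.choice(pool, size=2)
            if locus in planted:
                allele, flags = planted[locus]
                if flags[i]:
                    a1 = allele
                else:
                    others = [a for a in pool if a != allele]
                    a1 = a1 if a1 != allele else rng.choice(others)
                    a2 = a2 if a2 != allele else rng.choice(others)
            rows.append((sample, locus, a1, a2))
    return pd.DataFrame(rows, columns=["sample_id", "locus", "allele_1", "allele_2"])


def simulate_pathways(config: SimConfig):
    """Random pathway collection over the cohort's genes plus the merged
    interactome.

    Consecutive pathways are forced to share a gene, and each pathway's edges
    span its members, so the merged graph is a single connected component.
    Edge types are drawn from the nine recognized interaction labels; ARR
    roles from the five-value domain.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_ids(config)
    lo, hi = config.pathway_size_range
    pathways: list[Pathway] = []
    previous_members: list[str] | None = None
    for k in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(genes, size=size, replace=False))
        if previous_members is not None:
            shared = str(rng.choice(previous_members))
            if shared not in members:
                members[0] = shared
        members = list(dict.fromkeys(members))
        roles = {g: float(rng.choice(ARR_VALUES)) for g in members}
        edges = []
        shuffled = list(rng.permutation(members))
        for a, b in zip(shuffled, shuffled[1:]):  # spanning path
            edges.append((a, str(rng.choice(EDGE_TYPES)), b))
        n_extra = int(rng.integers(0, max(1, len(members) // 2) + 1))
        for _ in range(n_extra):
            a, b = rng.choice(members, size=2, replace=False)
            edges.append((str(a), str(rng.choice(EDGE_TYPES)), str(b)))
        pathways.append(
            Pathway(id=f"P{k + 1:03d}", roles=roles, origin="curated", edges=edges)
        )
        previous_members = members
    interactome = merge_interactome(pathways)
    return pathways, interactome


# ---------------------------------------------------------------------------
# on-disk layout

def write_cohort(cohort: SimulatedCohort, outdir) -> Path:
    """Write every table of the cohort in plain-text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.expression.write_tsv(outdir / "expression.tsv")
    cohort.control_panel.write_tsv(outdir / "controls.tsv")
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    write_pathways_json(cohort.pathways, outdir / "pathways.json")
    write_pathways_gmt(
        cohort.pathways, outdir / "pathways.gmt", outdir / "pathway_roles.tsv"
    )
    write_interactome_tsv(cohort.interactome, outdir / "interactome.tsv")
    cohort.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    cohort.hla.to_csv(outdir / "hla.csv", index=False)
    cohort.binary_features.to_csv(outdir / "binary_features.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return outdir


def load_cohort_dir(indir) -> dict:
    """Load the tables written by :func:`write_cohort` (no truth required)."""
    from .features import load_hla, load_variants
    from .pathways import read_pathways_json
    from .screening import load_clinical

    indir = Path(indir)
    out = {
        "expression": ExpressionMatrix.read_tsv(indir / "expression.tsv"),
        "controls": ExpressionMatrix.read_tsv(indir / "controls.tsv"),
        "clinical": load_clinical(indir / "clinical.csv"),
        "pathways": read_pathways_json(indir / "pathways.json"),
        "variants": load_variants(indir / "variants.tsv"),
        "hla": load_hla(indir / "hla.csv"),
    }
    bf = indir / "binary_features.csv"
    if bf.exists():
        out["binary_features"] = pd.read_csv(bf, index_col="sample_id")
        out["binary_features"].index = out["binary_features"].index.astype(str)
    else:
        out["binary_features"] = None
    return out
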