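"""Genomic side-data turned into screenable biomarkers.

Covers tumor mutational burden (nonsynonymous mutations per megabase, "high"
when strictly exceeding 10), per-gene mutation flags, HLA allele presence /
homozygosity / superfamily features, the housekeeping-normalized GEP score
and the combined TMB+GEP categorical marker.  External signature scores
(e.g. TIDE) and neoantigen counts are ingested as precomputed columns, never
recomputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

EFFECT_CLASSES = ("nonsynonymous", "synonymous", "other")
DEFAULT_MUTATION_GENES = ("KRAS", "STK11", "POLE", "PTEN")
TMB_HIGH_CUTOFF = 10.0

__all__ = [
    "TmbResult",
    "compute_tmb",
    "mutation_flags",
    "hla_features",
    "gep_score",
    "tmb_gep_category",
    "load_variants",
    "load_hla",
]


@dataclass
class TmbResult:
    sample_id: str
    tmb: float
    high: bool


def load_variants(path) -> pd.DataFrame:
    """ANNOVAR-like TSV with columns sample_id, gene, effect_class."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene", "effect_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    bad = set(df["effect_class"]) - set(EFFECT_CLASSES)
    if bad:
        raise ValueError(f"unknown effect class(es): {sorted(bad)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def compute_tmb(
    variants: pd.DataFrame,
    capture_mb: float,
    sample_ids: Sequence[str] | None = None,
    high_cutoff: float = TMB_HIGH_CUTOFF,
) -> pd.DataFrame:
    """Nonsynonymous mutation count per megabase for each sample.

    ``capture_mb`` has no default on purpose: the capture size is a property
    of the assay and must be stated.  ``high`` is strict (> cutoff), so a
    sample at exactly the cutoff is low.
    """
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    nonsyn = variants[variants["effect_class"] == "nonsynonymous"]
    counts = nonsyn.groupby("sample_id").size()
    if sample_ids is None:
        sample_ids = sorted(counts.index)
    counts = counts.reindex([str(s) for s in sample_ids], fill_value=0)
    tmb = counts / capture_mb
    return pd.DataFrame(
        {"sample_id": tmb.index, "tmb": tmb.to_numpy(dtype=float),
         "high": (tmb > high_cutoff).to_numpy()},
    ).set_index("sample_id", drop=False)


def mutation_flags(
    variants: pd.DataFrame,
    genes: Iterable[str] = DEFAULT_MUTATION_GENES,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary flag per (sample, gene): any nonsynonymous variant present."""
    genes = list(genes)
    nonsyn = variants[variants["effect_class"] == "nonsynonymous"]
    if sample_ids is None:
        sample_ids = sorted(variants["sample_id"].unique())
    sample_ids = [str(s) for s in sample_ids]
    out = pd.DataFrame(0, index=sample_ids, columns=[f"{g}_mutation" for g in genes])
    hit = nonsyn[nonsyn["gene"].isin(genes)]
    for sample, gene in hit[["sample_id", "gene"]].itertuples(index=False):
        if sample in out.index:
            out.loc[sample, f"{gene}_mutation"] = 1
    return out


def load_hla(path) -> pd.DataFrame:
    """CSV with columns sample_id, locus, allele_1, allele_2."""
    df = pd.read_csv(path)
    required = {"sample_id", "locus", "allele_1", "allele_2"}
    if not required.issubset(df.columns):
        raise ValueError(f"HLA table needs columns {sorted(required)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def hla_features(
    hla: pd.DataFrame, superfamily_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Binary matrix of allele presence, per-locus homozygosity and optional
    superfamily presence/homozygosity.

    Alleles missing from ``superfamily_map`` keep their presence column; the
    corresponding superfamily column is simply not produced (with a warning).
    """
    samples = sorted(hla["sample_id"].unique())
    columns: dict[str, pd.Series] = {}

    def _col(name: str) -> pd.Series:
        if name not in columns:
            columns[name] = pd.Series(0, index=samples, dtype=int)
        return columns[name]

    unmapped: set[str] = set()
    for sample, locus, a1, a2 in hla[
        ["sample_id", "locus", "allele_1", "allele_2"]
    ].itertuples(index=False):
        for allele in (a1, a2):
            _col(f"allele_{_slug(allele)}")[sample] = 1
            if superfamily_map is not None:
                fam = superfamily_map.get(allele)
                if fam is None:
                    unmapped.add(allele)
                else:
                    _col(f"superfamily_{_slug(fam)}")[sample] = 1
        if a1 == a2:
            _col(f"homozygous_{_slug(locus)}")[sample] = 1
            if superfamily_map is not None and superfamily_map.get(a1) is not None:
                _col(f"homozygous_superfamily_{_slug(superfamily_map[a1])}")[sample] = 1
    if unmapped:
        warnings.warn(
            f"allele(s) without superfamily mapping skipped: {sorted(unmapped)}",
            stacklevel=2,
        )
    out = pd.DataFrame(columns, index=samples).sort_index(axis=1)
    out.index.name = "sample_id"
    return out


def _slug(value: str) -> str:
    return str(value).replace("*", "-").replace(":", "-")


def gep_score(
    tpm: ExpressionMatrix,
    weights: Mapping[str, float],
    housekeeping: Iterable[str],
) -> pd.Series:
    """Weighted sum of housekeeping-normalized log2 TPM values.

    score_j = sum_g w_g * (log2(TPM_gj + 1) - mean_h log2(TPM_hj + 1))
    """
    if tpm.stage != "tpm":
        raise ValueError(f"GEP requires TPM values, got stage {tpm.stage!r}")
    housekeeping = list(housekeeping)
    for gene in list(weights) + housekeeping:
        if gene not in tpm.gene_ids:
            raise KeyError(f"gene {gene!r} absent from the TPM matrix")
    log_tpm = np.log2(tpm.values + 1.0)
    hk_mean = log_tpm.loc[housekeeping].mean(axis=0)
    score = pd.Series(0.0, index=tpm.sample_ids, name="gep")
    for gene, w in weights.items():
        score = score + float(w) * (log_tpm.loc[gene] - hk_mean)
    return score


def tmb_gep_category(
    tmb: pd.DataFrame, gep: pd.Series, gep_threshold: float
) -> pd.Series:
    """TMB-high+GEP-high vs TMB-low+GEP-low; discordant samples are 'mixed'
    and excluded from the two-group comparison downstream."""
    shared = [s for s in tmb.index if s in gep.index]
    out = pd.Series("mixed", index=shared, name="tmb_gep", dtype=object)
    high_t = tmb.loc[shared, "high"].to_numpy(dtype=bool)
    high_g = (gep.loc[shared] > gep_threshold).to_numpy()
    out[high_t & high_g] = "high_high"
    out[~high_t & ~high_g] = "low_low"
    return out
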