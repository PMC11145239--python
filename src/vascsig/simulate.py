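"""Synthetic glioblastoma cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes, so every
stage can be tested without external downloads:

* negative-binomial RNA-seq counts with log-normal library sizes and a
  shared dispersion (the simplest model exhibiting the mean-variance trend
  the precision-weighting step must learn);
* a small MRI subset whose rCBV_HAT medians come from a two-component
  (moderate / high vascularity) normal mixture truncated at 0, with the true
  group label given by thresholding the drawn value at 7 — so truth and the
  threshold rule can never disagree;
* a planted signature of genes over-expressed (log2 fold change drawn from a
  configured range) in the high-vascularity samples only;
* gene descriptions carrying vascularity keywords for all signature genes
  and a configurable fraction of background genes;
* right-censored survival in days whose log hazard is linear in the sample's
  realized signature concordance (its Algorithm-style score computed from the
  generated expression), with independent exponential censoring and an
  administrative cap at 2000 days.

Defaults reproduce the study conditions: 147 samples, 15 with MRI split
roughly 7 high / 8 moderate around threshold 7, group rCBV means 4.17 and
8.31, 21 signature genes with log2 fold changes in 1.1-3.6.

Each random artifact (gene baselines, library sizes, rCBV, counts, ages,
survival, keywords) draws from its own child stream of the master seed, so
changing one configuration parameter does not perturb unrelated draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CountMatrix
from .errors import ConfigurationError, DataError
from .filtering import DEFAULT_KEYWORDS

_VASCULAR_TEMPLATES = (
    "regulator of neovascularization and endothelial sprouting",
    "cytokine involved in angiogenesis and blood vessel development",
    "receptor mediating capillary morphogenesis",
    "hypoxia-inducible factor pathway component",
    "structural protein of the glomerular basement membrane",
    "mediator of venous endothelial identity",
    "artery wall remodeling enzyme",
    "participates in the circulatory response to injury",
    "serine protease of the coagulation cascade",
    "promotes vasculogenesis in the developing vasculature",
    "microvessel density associated surface antigen",
    "induced during tumor necrosis and tissue hypoxia",
)

_NEUTRAL_TEMPLATES = (
    "ribosomal protein small subunit component",
    "mitochondrial translation elongation factor",
    "zinc finger transcriptional repressor",
    "ubiquitin conjugating enzyme family member",
    "olfactory receptor family member",
    "spliceosome assembly chaperone",
    "histone lysine methyltransferase adaptor",
    "axon guidance adhesion molecule",
    "lipid droplet associated hydrolase",
    "proteasome regulatory particle subunit",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_samples: int = 147
    n_mri: int = 15  # samples with an rCBV_HAT value
    n_genes: int = 2000
    n_signature_genes: int = 21
    signature_logfc_range: tuple[float, float] = (1.1, 3.6)  # log2 units
    nb_dispersion: float = 0.2
    libsize_log_mean: float = math.log(1.5e7)
    libsize_log_sd: float = 0.35
    rcbv_mv_mean: float = 4.17
    rcbv_hv_mean: float = 8.31
    rcbv_sd: float = 0.8
    frac_hv: float = 7.0 / 15.0
    baseline_hazard: float = math.log(2) / 350.0  # per day
    log_hazard_per_score_point: float = 0.08
    censor_rate: float = 1.0 / 1500.0  # per day
    censor_cap_days: float = 2000.0
    keyword_frac: float = 0.08
    age_mean: float = 60.0
    age_sd: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        c = self
        for name in (
            "nb_dispersion",
            "libsize_log_sd",
            "rcbv_sd",
            "baseline_hazard",
            "censor_rate",
            "age_sd",
        ):
            v = getattr(c, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if c.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if c.baseline_hazard <= 0 or c.censor_rate <= 0:
            raise ConfigurationError("hazard and censor rates must be > 0")
        for name in ("frac_hv", "keyword_frac"):
            v = getattr(c, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if c.n_signature_genes > c.n_genes:
            raise ConfigurationError("n_signature_genes must be <= n_genes")
        if c.n_mri > c.n_samples:
            raise ConfigurationError("n_mri must be <= n_samples")
        lo, hi = c.signature_logfc_range
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
            raise ConfigurationError("signature_logfc_range must be finite (lo, hi)")
        for name in ("libsize_log_mean", "log_hazard_per_score_point",
                     "rcbv_mv_mean", "rcbv_hv_mean", "age_mean"):
            if not math.isfinite(getattr(c, name)):
                raise ConfigurationError(f"{name} must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "signature_logfc_range" in d:
            d = dict(d)
            d["signature_logfc_range"] = tuple(d["signature_logfc_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    true_signature_gene_ids: list[str]
    true_logfc_per_gene: dict[str, float]  # 0.0 for background genes
    true_group_per_sample: dict[str, str]  # HV / MV / -V
    true_concordance_per_sample: dict[str, int]
    true_hazard_ratio_per_point: float
    seed_used: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["genes", "libsize", "rcbv", "counts", "ages", "survival", "keywords"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Normal(mean, sd) truncated at 0 by resampling (mean/sd >> 0 here)."""
    if sd == 0:
        return np.full(size, max(mean, 0.0))
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=bad.sum())
    return np.clip(out, 1e-6, None)


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (counts, annotation, clinical, truth) for one synthetic cohort."""
    config.validate()
    c = config
    rng = _rngs(c.seed)

    gene_ids = [f"GSYN{i:05d}" for i in range(c.n_genes)]
    sample_ids = [f"TCGA-SYN-{i:04d}" for i in range(c.n_samples)]

    # baseline abundances (log2 CPM); signature genes kept well expressed so
    # they survive the CPM filter, as the real signature genes did
    sig_idx = np.sort(
        rng["genes"].choice(c.n_genes, size=c.n_signature_genes, replace=False)
    )
    base_log2cpm = rng["genes"].normal(1.5, 2.5, size=c.n_genes)
    base_log2cpm[sig_idx] = rng["genes"].normal(4.0, 1.0, size=c.n_signature_genes)
    logfc = np.zeros(c.n_genes)
    lo, hi = c.signature_logfc_range
    logfc[sig_idx] = rng["genes"].uniform(lo, hi, size=c.n_signature_genes)

    lib = rng["libsize"].lognormal(c.libsize_log_mean, c.libsize_log_sd, c.n_samples)

    # MRI subset and vascular ground truth (threshold rule on the drawn rCBV)
    mri_idx = np.sort(rng["rcbv"].choice(c.n_samples, size=c.n_mri, replace=False))
    comp_hv = rng["rcbv"].random(c.n_mri) < c.frac_hv
    means = np.where(comp_hv, c.rcbv_hv_mean, c.rcbv_mv_mean)
    rcbv_vals = np.array(
        [
            _truncated_normal(rng["rcbv"], m, c.rcbv_sd, 1)[0]
            for m in means
        ]
    )
    rcbv = np.full(c.n_samples, math.nan)
    rcbv[mri_idx] = rcbv_vals
    group = np.full(c.n_samples, "-V", dtype=object)
    group[mri_idx] = np.where(rcbv_vals > 7.0, "HV", "MV")
    is_hv = group == "HV"

    # expected counts: relative abundance per sample, signature shifted in HV
    rel = np.power(2.0, base_log2cpm)[:, np.newaxis] * np.ones((1, c.n_samples))
    rel[sig_idx[:, np.newaxis], np.nonzero(is_hv)[0][np.newaxis, :]] *= np.power(
        2.0, logfc[sig_idx]
    )[:, np.newaxis]
    rel /= rel.sum(axis=0, keepdims=True)
    mu = rel * lib[np.newaxis, :]

    r = 1.0 / c.nb_dispersion
    counts = rng["counts"].negative_binomial(r, r / (r + mu))
    counts_matrix = CountMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, counts=counts.astype(np.int64)
    )

    ages = np.clip(
        rng["ages"].normal(c.age_mean, c.age_sd, size=c.n_samples), 20.0, 90.0
    )

    # realized concordance: score against the per-gene median of log2 CPM
    log2cpm = np.log2(
        (counts + 0.5) / (counts.sum(axis=0) + 1.0)[np.newaxis, :] * 1e6
    )
    sig_expr = log2cpm[sig_idx]
    concord = (sig_expr > np.median(sig_expr, axis=1, keepdims=True)).sum(axis=0)

    hazard = c.baseline_hazard * np.exp(
        c.log_hazard_per_score_point * (concord - concord.mean())
    )
    t_death = rng["survival"].exponential(1.0 / hazard)
    t_censor = rng["survival"].exponential(1.0 / c.censor_rate, size=c.n_samples)
    t_censor = np.minimum(t_censor, c.censor_cap_days)
    os_days = np.minimum(t_death, t_censor)
    event = (t_death <= t_censor).astype(int)

    annotation = pd.DataFrame({"gene_id": gene_ids, "description": ""})
    truth = SyntheticTruth(
        true_signature_gene_ids=[gene_ids[i] for i in sig_idx],
        true_logfc_per_gene={g: float(l) for g, l in zip(gene_ids, logfc)},
        true_group_per_sample=dict(zip(sample_ids, group)),
        true_concordance_per_sample={
            s: int(k) for s, k in zip(sample_ids, concord)
        },
        true_hazard_ratio_per_point=float(math.exp(c.log_hazard_per_score_point)),
        seed_used=c.seed,
    )
    annotation = embed_keywords(
        annotation, c.keyword_frac, truth, rng=rng["keywords"]
    )

    clinical = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "os_days": np.round(os_days, 6),
            "event": event,
            "age": np.round(ages, 2),
            "rcbv_hat_median": np.round(rcbv, 4),
        }
    )
    return counts_matrix, annotation, clinical, truth


def embed_keywords(
    annotation: pd.DataFrame,
    keyword_frac: float,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write descriptions: every signature gene and a ``keyword_frac`` share of
    background genes get a vascularity keyword; the rest get neutral text.
    """
    if not 0.0 <= keyword_frac <= 1.0:
        raise ConfigurationError("keyword_frac must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(truth.seed_used)
    gene_ids = list(annotation["gene_id"])
    unknown = [g for g in truth.true_signature_gene_ids if g not in set(gene_ids)]
    if unknown:
        raise DataError(f"truth signature genes missing from annotation: {unknown}")
    sig = set(truth.true_signature_gene_ids)
    descriptions = []
    for g in gene_ids:
        if g in sig or rng.random() < keyword_frac:
            descriptions.append(
                _VASCULAR_TEMPLATES[rng.integers(len(_VASCULAR_TEMPLATES))]
            )
        else:
            descriptions.append(
                _NEUTRAL_TEMPLATES[rng.integers(len(_NEUTRAL_TEMPLATES))]
            )
    out = annotation.copy()
    out["description"] = descriptions
    assert not any(
        any(k in d for k in DEFAULT_KEYWORDS) for d in _NEUTRAL_TEMPLATES
    )
    return out


def write_cohort(
    out_dir,
    counts: CountMatrix,
    annotation: pd.DataFrame,
    clinical: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> dict[str, Path]:
    """Write the tab-separated cohort trio (+ truth sidecar JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "clinical": out / "clinical.tsv",
    }
    counts.to_dataframe().to_csv(paths["counts"], sep="\t")
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False, na_rep="")
    if truth is not None:
        paths["truth"] = out / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths
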