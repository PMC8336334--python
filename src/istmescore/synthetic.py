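"""Seeded synthetic cohorts with planted immune/stromal structure.

The generator emulates the statistical structure the pipeline assumes: a
non-negative expression matrix driven by a handful of latent non-negative
factors, two of which ("immune" and "stromal") load on disjoint planted
gene modules; overall survival whose hazard falls with the immune latent
activity and rises with the stromal one; and reference gene sets that are
contaminated copies of the planted modules.  Everything is reproducible
from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection


@dataclass
class SimulationParams:
    """Study conditions of the simulated cohort.

    Defaults: 2000 genes x 200 samples, 60-gene immune and 40-gene stromal
    modules, 4 extra latent noise factors (50 genes each), unit loadings,
    Gaussian noise SD 0.5, protective immune log-hazard -0.8, adverse
    stromal log-hazard +0.8, 30% censoring.
    """

    n_genes: int = 2000
    n_samples: int = 200
    n_immune_genes: int = 60
    n_stromal_genes: int = 40
    n_noise_factors: int = 4
    noise_module_size: int = 50
    loading_strength: float = 1.0
    noise_sd: float = 0.5
    activity_correlation: float = -0.5
    beta_immune: float = -0.8
    beta_stromal: float = 0.8
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        total_module = (
            self.n_immune_genes
            + self.n_stromal_genes
            + self.n_noise_factors * self.noise_module_size
        )
        if total_module >= self.n_genes:
            raise ValueError("module genes must not exhaust the gene universe")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.beta_immune > 0 or self.beta_stromal < 0:
            raise ValueError("beta_immune must be <= 0 and beta_stromal >= 0")
        if self.noise_sd <= 0 or self.loading_strength <= 0:
            raise ValueError("noise_sd and loading_strength must be positive")
        if not (-1 < self.activity_correlation < 1):
            raise ValueError("activity_correlation must be in (-1, 1)")


@dataclass
class GroundTruth:
    immune_genes: list[str]
    stromal_genes: list[str]
    noise_modules: list[list[str]]
    immune_activity: pd.Series
    stromal_activity: pd.Series
    beta_immune: float
    beta_stromal: float

    def __post_init__(self):
        if set(self.immune_genes) & set(self.stromal_genes):
            raise ValueError("planted modules must be disjoint")


def simulate_dataset(
    p: SimulationParams,
) -> tuple[ExpressionMatrix, ClinicalTable, GroundTruth]:
    """Draw one synthetic cohort.

    Latent activities are log-normal(0, 1); expression is the sum of
    loading x activity over module memberships plus Gaussian noise, shifted
    globally to non-negative (shifting, not truncating, keeps module-
    activity correlations exact).  Survival times are exponential with a
    log-linear hazard in the standardized immune (protective) and stromal
    (adverse) activities; censored samples observe a uniform fraction of
    their event time.
    """
    rng = np.random.default_rng(p.seed)
    genes = [f"G{i:05d}" for i in range(p.n_genes)]
    samples = [f"S{j:04d}" for j in range(p.n_samples)]

    perm = rng.permutation(p.n_genes)
    pos = 0
    imm_idx = perm[pos : pos + p.n_immune_genes]; pos += p.n_immune_genes
    str_idx = perm[pos : pos + p.n_stromal_genes]; pos += p.n_stromal_genes
    noise_idx = []
    for _ in range(p.n_noise_factors):
        noise_idx.append(perm[pos : pos + p.noise_module_size])
        pos += p.noise_module_size

    # Immune and stromal activities share a Gaussian copula with negative
    # correlation (the two programs compete within the sampled tissue
    # fraction); noise-factor activities are independent.  All marginals
    # are log-normal(0, 1).
    n_factors = 2 + p.n_noise_factors
    rho = p.activity_correlation
    z1 = rng.standard_normal(p.n_samples)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(p.n_samples)
    acts = np.empty((n_factors, p.n_samples))
    acts[0] = np.exp(z1)
    acts[1] = np.exp(z2)
    acts[2:] = rng.lognormal(mean=0.0, sigma=1.0, size=(p.n_noise_factors, p.n_samples))
    X = rng.normal(0.0, p.noise_sd, size=(p.n_genes, p.n_samples))
    for f, idx in enumerate([imm_idx, str_idx, *noise_idx]):
        X[idx, :] += p.loading_strength * acts[f][None, :]
    X -= X.min()  # global shift to non-negativity

    z_imm = (acts[0] - acts[0].mean()) / acts[0].std(ddof=0)
    z_str = (acts[1] - acts[1].mean()) / acts[1].std(ddof=0)
    hazard = p.baseline_hazard * np.exp(p.beta_immune * z_imm + p.beta_stromal * z_str)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(p.n_samples) < p.censor_rate
    os_time = np.where(censored, rng.uniform(0, 1, p.n_samples) * t_event, t_event)
    os_event = (~censored).astype(int)

    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples))
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": rng.normal(65, 10, p.n_samples).round(1),
                "gender": rng.choice(["female", "male"], p.n_samples),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    gt = GroundTruth(
        immune_genes=[genes[i] for i in imm_idx],
        stromal_genes=[genes[i] for i in str_idx],
        noise_modules=[[genes[i] for i in idx] for idx in noise_idx],
        immune_activity=pd.Series(acts[0], index=samples),
        stromal_activity=pd.Series(acts[1], index=samples),
        beta_immune=p.beta_immune,
        beta_stromal=p.beta_stromal,
    )
    return expr, clin, gt


def make_reference_sets(
    gt: GroundTruth,
    contamination: float = 0.0,
    seed: int = 0,
    all_genes: list[str] | None = None,
) -> GeneSetCollection:
    """Immune/stromal reference sets: planted modules with a contaminated
    fraction swapped for random non-module genes.

    Stands in for curated marker collections; contamination < 0.5 keeps the
    sets informative.
    """
    if not (0 <= contamination < 0.5):
        raise ValueError("contamination must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    module = set(gt.immune_genes) | set(gt.stromal_genes)
    if all_genes is None:
        # fall back to a synthetic pool of decoy ids disjoint from the modules
        all_genes = list(module) + [f"GX{i:05d}" for i in range(2 * len(module))]
    pool = np.asarray([g for g in all_genes if g not in module])
    n_swap_imm = int(np.floor(contamination * len(gt.immune_genes)))
    n_swap_str = int(np.floor(contamination * len(gt.stromal_genes)))
    # one draw without replacement keeps the two contaminated sets disjoint
    swaps = list(rng.choice(pool, size=n_swap_imm + n_swap_str, replace=False))
    out = []
    for name, genes, n_swap, swap in (
        ("IMMUNE_REF", gt.immune_genes, n_swap_imm, swaps[:n_swap_imm]),
        ("STROMAL_REF", gt.stromal_genes, n_swap_str, swaps[n_swap_imm:]),
    ):
        keep = list(rng.choice(genes, size=len(genes) - n_swap, replace=False))
        out.append(GeneSet(name, "synthetic reference set", keep + swap))
    return GeneSetCollection(out)
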