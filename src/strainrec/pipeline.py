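"""End-to-end orchestration: simulate, train, impute, recommend, benchmark.

Thin glue over the domain modules used by the command-line interface, the
test suite, and the reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import benchmark as bm
from . import imputation, recommender, signatures, synthesizer
from .genomes import GenotypeMatrix
from .synthesizer import SimulationConfig

log = logging.getLogger(__name__)


@dataclass
class SimulatedStudy:
    """A fully simulated and trained study: genomes through imputed resource."""

    config: SimulationConfig
    founders: GenotypeMatrix
    donors: GenotypeMatrix
    strains: GenotypeMatrix
    genotypes: GenotypeMatrix        # founders + donors + strains, one matrix
    loci: pd.DataFrame
    expr: pd.DataFrame               # observed donor expression
    truth: synthesizer.PlantedTruth
    models: list
    resource: pd.DataFrame           # imputed strain expression

    @property
    def strain_ids(self) -> list:
        return list(self.strains.sample_ids)

    @property
    def donor_ids(self) -> list:
        return list(self.donors.sample_ids)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full synthetic pipeline under one seeded generator."""
    rng = config.rng()
    founders = synthesizer.simulate_founders(config, rng)
    donors = synthesizer.simulate_donors(founders, config, rng)
    strains = synthesizer.simulate_inbred_panel(founders, config, rng)
    genotypes = founders.with_samples(donors).with_samples(strains)
    loci = synthesizer.simulate_loci(config, founders.pos, rng)
    expr, truth = synthesizer.simulate_expression(donors, loci, config, rng)
    models = imputation.train_resource(expr, genotypes, loci,
                                       cis_span=config.cis_span,
                                       seed=config.seed)
    resource = imputation.impute_panel(models, genotypes, strains.sample_ids)
    return SimulatedStudy(config, founders, donors, strains, genotypes, loci,
                          expr, truth, models, resource)


def planted_recommendation(study: SimulatedStudy, target: str, *,
                           seed: int, noise_scale: float | None = None,
                           n_genes: int | None = None,
                           b: int = recommender.DEFAULT_PERMUTATIONS
                           ) -> tuple[pd.DataFrame, synthesizer.SignatureTruth]:
    """Plant a signature for one target strain and rank the panel against it."""
    rng = np.random.default_rng(seed)
    raw, sig_truth = synthesizer.plant_signature(
        study.resource, target, study.config, rng,
        n_genes=n_genes, noise_scale=noise_scale)
    sig = signatures.harmonize(raw, None, study.resource)
    recs = recommender.recommend(sig, study.resource, b=b, seed=seed)
    return recs, sig_truth


def retrospective_experiment(study: SimulatedStudy, *, n_diseases: int,
                             pairs_per_disease: int, flip_prob: float,
                             noise_scale: float, seed: int,
                             fpr_max: float = bm.DEFAULT_FPR_MAX,
                             b: int = recommender.DEFAULT_PERMUTATIONS
                             ) -> tuple[list, bm.BenchmarkSummary, list]:
    """Synthetic retrospective validation with planted per-disease signatures.

    For each synthetic disease: plant a signature for a random target
    strain, rank the panel, generate strain-pair records whose observed
    outcome follows the planted truth flipped with ``flip_prob``, and score
    them at ``fpr_max``.  Returns (per-disease summaries, overall summary,
    all outcomes).
    """
    rng = np.random.default_rng(seed)
    import dataclasses
    config = dataclasses.replace(study.config, flip_prob=flip_prob)
    outcomes = []
    for k in range(n_diseases):
        disease_id = f"DIS:{k + 1:04d}"
        target = str(rng.choice(study.resource.columns))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        raw, sig_truth = synthesizer.plant_signature(
            study.resource, target, config, np.random.default_rng(sub_seed),
            noise_scale=noise_scale)
        sig = signatures.harmonize(raw, None, study.resource)
        recs = recommender.recommend(sig, study.resource, b=b, seed=sub_seed)
        records = synthesizer.simulate_validation_set(
            study.resource, sig_truth, study.strain_ids, config,
            np.random.default_rng(sub_seed + 1), n_pairs=pairs_per_disease,
            disease_id=disease_id, phenotype_term=f"MP:{k + 1:07d}",
            study_prefix=f"SY{k:03d}_")
        outcomes.extend(bm.score_records(recs, records, fpr_max=fpr_max,
                                         gene_set_id=f"GS:{k + 1:04d}"))
    summaries, overall = bm.aggregate_outcomes(outcomes)
    return summaries, overall, outcomes
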