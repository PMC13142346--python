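"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generator emulates, at desk scale, the data types the recommender
consumes: a small set of fully homozygous founder genomes; an outbred donor
panel in which every animal is a diploid mosaic of founder haplotypes with
exponentially distributed segment lengths; a homozygous inbred strain panel
built the same way from single haplotypes; donor expression driven by one
planted cis-eQTL per gene plus Gaussian noise; disease signatures planted
from a chosen strain's imputed expression; and ground-truth strain-pair
validation records whose observed outcome contradicts the planted truth
with a configurable flip probability.  Every output is fully determined by
the configuration and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .benchmark import ValidationRecord
from .genomes import GenotypeMatrix
from .signatures import RawGeneSet

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults give one 20 Mb chromosome with 2,000 variants, 300 genes, a
    185-animal outbred donor panel and a 40-strain inbred panel: large
    enough that every 400 kb window holds ~40 variants, small enough to
    simulate, train and score in minutes.
    """

    n_founders: int = 8
    n_donors: int = 185
    n_strains: int = 40
    n_genes: int = 300
    n_variants: int = 2000
    chrom: str = "1"
    chrom_length: int = 20_000_000
    block_length: int = 2_000_000  # mean founder-segment length (bp)
    alt_freq_low: float = 0.1     # founder alternate-allele frequency range
    alt_freq_high: float = 0.9
    expr_baseline_mean: float = 8.0  # per-gene baseline (log2-like scale)
    expr_baseline_sd: float = 0.5
    eqtl_effect: float = 1.0      # |beta| of the planted cis effect
    noise_sd: float = 0.2         # residual expression noise sd
    cis_span: int = 1_000_000
    n_signature_genes: int = 100
    signature_noise_scale: float = 0.5  # score noise as a fraction of score sd
    flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_donors", "n_strains", "n_genes",
                     "n_variants", "chrom_length", "block_length", "cis_span",
                     "n_signature_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if not 0.0 <= self.alt_freq_low <= self.alt_freq_high <= 1.0:
            raise ValueError("allele frequency range must satisfy 0<=low<=high<=1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig(**yaml.safe_load(fh))


def config_yaml(config: SimulationConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=False)


@dataclass
class PlantedTruth:
    """Per-gene planted eQTL effects and the noise-free expression map."""

    eqtls: pd.DataFrame  # gene_id, variant_id, pos, beta, mu

    def noise_free(self, genotypes: GenotypeMatrix) -> pd.DataFrame:
        """Noise-free genetic expression mu + beta * dosage for any samples."""
        vidx = {v: i for i, v in enumerate(genotypes.variant_ids)}
        rows = np.empty((len(self.eqtls), genotypes.n_samples))
        for k, row in enumerate(self.eqtls.itertuples(index=False)):
            rows[k] = row.mu + row.beta * genotypes.dosage[vidx[row.variant_id]]
        return pd.DataFrame(rows, index=self.eqtls["gene_id"].tolist(),
                            columns=genotypes.sample_ids)


@dataclass
class SignatureTruth:
    """Ground truth behind a planted signature."""

    target: str
    noiseless_scores: pd.Series  # index = gene ids


# ---------------------------------------------------------------------------
# genomes


def _variant_grid(config: SimulationConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    pos = np.sort(rng.choice(config.chrom_length, size=config.n_variants,
                             replace=False)) + 1
    ids = np.array([f"var{i:05d}" for i in range(config.n_variants)], dtype=object)
    return ids, pos


def simulate_founders(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Fully homozygous founder genomes over uniformly placed biallelic SNVs."""
    rng = config.rng() if rng is None else rng
    ids, pos = _variant_grid(config, rng)
    p = rng.uniform(config.alt_freq_low, config.alt_freq_high, config.n_variants)
    alleles = (rng.random((config.n_variants, config.n_founders)) < p[:, None])
    dosage = alleles.astype(np.float64) * 2.0
    samples = [f"FND{i + 1:02d}" for i in range(config.n_founders)]
    return GenotypeMatrix(ids, np.full(config.n_variants, config.chrom,
                                       dtype=object), pos, samples, dosage)


def sample_segments(rng: np.random.Generator, chrom_length: int,
                    block_length: float, n_founders: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One haplotype's founder mosaic: segment end positions + founder picks.

    Segment lengths are exponential with the configured mean; founders are
    chosen uniformly and independently per segment.
    """
    ends, total = [], 0.0
    while total < chrom_length:
        total += rng.exponential(block_length)
        ends.append(total)
    ends = np.array(ends)
    ends[-1] = chrom_length
    founders = rng.integers(0, n_founders, size=len(ends))
    return ends, founders


def _mosaic_haplotype(founder_alleles: np.ndarray, pos: np.ndarray,
                      ends: np.ndarray, founders: np.ndarray) -> np.ndarray:
    """Allele vector of a mosaic haplotype given explicit segments."""
    seg = np.searchsorted(ends, pos, side="left")
    return founder_alleles[np.arange(len(pos)), founders[seg]]


def _mosaic_matrix(founders_gm: GenotypeMatrix, n_samples: int, ploidy: int,
                   config: SimulationConfig, rng: np.random.Generator,
                   prefix: str) -> GenotypeMatrix:
    founder_alleles = founders_gm.dosage / 2.0  # {0, 1} per founder
    dosage = np.zeros((founders_gm.n_variants, n_samples))
    for j in range(n_samples):
        hap_sum = np.zeros(founders_gm.n_variants)
        for _ in range(ploidy):
            ends, choice = sample_segments(rng, config.chrom_length,
                                           config.block_length,
                                           config.n_founders)
            hap_sum += _mosaic_haplotype(founder_alleles, founders_gm.pos,
                                         ends, choice)
        dosage[:, j] = hap_sum * (2 // ploidy)
    samples = [f"{prefix}{j + 1:03d}" for j in range(n_samples)]
    return GenotypeMatrix(founders_gm.variant_ids.copy(),
                          founders_gm.chrom.copy(), founders_gm.pos.copy(),
                          samples, dosage)


def simulate_donors(founders: GenotypeMatrix, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Diploid founder-mosaic donors (dosage = sum of two haplotypes)."""
    rng = config.rng() if rng is None else rng
    return _mosaic_matrix(founders, config.n_donors, ploidy=2, config=config,
                          rng=rng, prefix="DO")


def simulate_inbred_panel(founders: GenotypeMatrix, config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Fully homozygous inbred mosaics (one haplotype, doubled)."""
    rng = config.rng() if rng is None else rng
    return _mosaic_matrix(founders, config.n_strains, ploidy=1, config=config,
                          rng=rng, prefix="STR")


# ---------------------------------------------------------------------------
# expression


def simulate_loci(config: SimulationConfig, variant_pos: np.ndarray,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene loci with TSS positions guaranteed to have cis variants."""
    rng = config.rng() if rng is None else rng
    lo = max(int(variant_pos.min()) - config.cis_span + 1, 1)
    hi = min(int(variant_pos.max()) + config.cis_span - 1, config.chrom_length)
    tss = rng.integers(lo, hi + 1, size=config.n_genes)
    return pd.DataFrame({"gene_id": [f"gene{i + 1:04d}"
                                     for i in range(config.n_genes)],
                         "chrom": config.chrom, "tss": tss})


def simulate_expression(genotypes: GenotypeMatrix, loci: pd.DataFrame,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, PlantedTruth]:
    """Expression = baseline + beta * planted cis dosage + Gaussian noise."""
    rng = config.rng() if rng is None else rng
    n_samples = genotypes.n_samples
    rows, truth_rows = [], []
    for locus in loci.itertuples(index=False):
        lo, hi = locus.tss - config.cis_span, locus.tss + config.cis_span
        cand = np.flatnonzero((genotypes.chrom == locus.chrom)
                              & (genotypes.pos >= lo) & (genotypes.pos <= hi))
        if cand.size == 0:
            raise ValueError(f"no cis variant for {locus.gene_id}; "
                             "increase n_variants or cis_span")
        # plant effects at variants that segregate in this panel, so every
        # gene actually carries a cis signal (monomorphic fallback only when
        # the whole window is fixed)
        poly = cand[genotypes.dosage[cand].std(axis=1) > 0]
        vi = int(rng.choice(poly if poly.size else cand))
        beta = config.eqtl_effect * float(rng.choice([-1.0, 1.0]))
        mu = float(rng.normal(config.expr_baseline_mean, config.expr_baseline_sd))
        noise = rng.normal(0.0, config.noise_sd, n_samples)
        rows.append(mu + beta * genotypes.dosage[vi] + noise)
        truth_rows.append({"gene_id": locus.gene_id,
                           "variant_id": str(genotypes.variant_ids[vi]),
                           "pos": int(genotypes.pos[vi]), "beta": beta,
                           "mu": mu})
    expr = pd.DataFrame(np.vstack(rows), index=loci["gene_id"].tolist(),
                        columns=genotypes.sample_ids)
    return expr, PlantedTruth(pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# signatures and validation records


def plant_signature(resource: pd.DataFrame, target: str,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    n_genes: int | None = None,
                    noise_scale: float | None = None,
                    label: str = "planted") -> tuple[RawGeneSet, SignatureTruth]:
    """A signature whose ground-truth most-vulnerable strain is known.

    Scores are the target strain's imputed expression at a random gene
    subset, centered by its mean across those genes (a rank-preserving
    shift, so the noiseless signature scores the target exactly 1), plus
    Gaussian noise scaled to a fraction of the score sd.
    """
    if target not in resource.columns:
        raise KeyError(f"target strain {target!r} not in resource")
    rng = config.rng() if rng is None else rng
    n_genes = config.n_signature_genes if n_genes is None else n_genes
    noise_scale = (config.signature_noise_scale if noise_scale is None
                   else noise_scale)
    genes = list(rng.choice(np.asarray(resource.index, dtype=object),
                            size=min(n_genes, len(resource.index)),
                            replace=False))
    dev = resource.loc[genes, target] - float(resource.loc[genes, target].mean())
    sd = float(dev.std(ddof=0))
    noise = rng.normal(0.0, noise_scale * sd, len(genes)) if sd > 0 else 0.0
    scores = dev + noise
    raw = RawGeneSet(pd.DataFrame({"gene_id": genes,
                                   "score": scores.to_numpy(dtype=float)}),
                     "mouse", label)
    return raw, SignatureTruth(target, dev.rename("score"))


def true_resemblance(sig_truth: SignatureTruth,
                     resource: pd.DataFrame) -> pd.Series:
    """Noise-free Spearman resemblance of every strain to the planted signature."""
    genes = list(sig_truth.noiseless_scores.index)
    sub = resource.loc[genes]
    vals = {}
    for strain in resource.columns:
        vals[strain] = float(stats.spearmanr(
            sig_truth.noiseless_scores.to_numpy(),
            sub[strain].to_numpy(dtype=float)).statistic)
    return pd.Series(vals, name="resemblance")


def simulate_validation_set(resource: pd.DataFrame, sig_truth: SignatureTruth,
                            strains, config: SimulationConfig,
                            rng: np.random.Generator | None = None,
                            n_pairs: int = 10, disease_id: str = "DIS:0001",
                            phenotype_term: str = "MP:0000001",
                            study_prefix: str = "SY") -> list:
    """Strain-pair records whose observed outcome follows planted truth.

    The observed vulnerable strain is the one with higher noise-free
    resemblance, flipped with probability ``flip_prob``.
    """
    rng = config.rng() if rng is None else rng
    strains = list(strains)
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    res = true_resemblance(sig_truth, resource)
    pairs = [(a, b) for i, a in enumerate(strains) for b in strains[i + 1:]]
    if n_pairs < len(pairs):
        picks = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[int(i)] for i in picks]
    records = []
    for k, (a, b) in enumerate(pairs):
        truth = a if res[a] > res[b] else b
        flipped = bool(rng.random() < config.flip_prob)
        observed = ({a, b} - {truth}).pop() if flipped else truth
        records.append(ValidationRecord(
            study_id=f"{study_prefix}{k + 1:04d}", strain_a=a, strain_b=b,
            observed_vulnerable=observed, phenotype_term=phenotype_term,
            disease_ids=(disease_id,), rare_flags=(False,)))
    return records
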