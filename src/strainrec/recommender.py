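"""Strain vulnerability scoring and permutation-based false positive rates.

Each strain's vulnerability score is the Spearman rank correlation between
the signature's signed gene scores and the strain's imputed expression at
those genes.  Positive scores mean genes up-scored in the disease state tend
to be more highly expressed in the strain ("vulnerable"); negative scores
mean the opposite ("resilient").

Uncertainty is a one-sided, size-matched permutation FPR: B null scores are
drawn by picking a random strain from the resource, sampling n genes from it
without replacement, and correlating those expression values with the
observed signature scores.  The null procedure never uses the focal strain's
identity, so one seeded null per signature is shared by all strains.  The
FPR is the add-one-smoothed tail fraction in the direction of the observed
score: right tail for positive scores, left tail for negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (AlignmentError, EmptyResourceError, InfeasibleNullError,
                     UndefinedCorrelationError)
from .signatures import DiseaseSignature

log = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 4_000


@dataclass
class NullModel:
    """B permutation null correlations for a signature of size n."""

    n: int
    b: int
    null_scores: np.ndarray
    seed: int


def vulnerability_score(signature: DiseaseSignature, strain_expr) -> float:
    """Spearman rho between signature scores and one strain's expression.

    ``strain_expr`` must cover exactly the signature genes in the same
    order (checked when a Series is passed).  Average ranks break ties.
    """
    s = signature.scores.to_numpy(dtype=float)
    if isinstance(strain_expr, pd.Series):
        if list(strain_expr.index) != list(signature.scores.index):
            raise AlignmentError("strain expression index does not match signature")
        x = strain_expr.to_numpy(dtype=float)
    else:
        x = np.asarray(strain_expr, dtype=float)
    if x.shape != s.shape:
        raise AlignmentError("expression / signature length mismatch")
    if len(s) < 3:
        raise AlignmentError("need at least 3 genes")
    if np.all(s == s[0]) or np.all(x == x[0]):
        raise UndefinedCorrelationError("zero rank variance")
    return float(stats.spearmanr(s, x).statistic)


def build_null(resource: pd.DataFrame, signature: DiseaseSignature,
               b: int = DEFAULT_PERMUTATIONS, seed: int = 0) -> NullModel:
    """Draw B size-n null correlations from the imputed resource.

    Vectorized: draws are (strain, n-gene subset) pairs; per-draw Spearman
    rho is the Pearson correlation of average ranks, identical to
    :func:`scipy.stats.spearmanr` on each draw.
    """
    if resource.shape[1] < 1:
        raise EmptyResourceError("resource has no strains")
    n = signature.n
    n_genes = resource.shape[0]
    if n_genes < n:
        raise InfeasibleNullError(
            f"resource has {n_genes} genes but the signature needs {n}")
    vals = resource.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    strain_idx = rng.integers(0, resource.shape[1], size=b)
    # uniform n-subsets without replacement via random-key argsort; the
    # subset stays in sampling (random) order so the positional pairing with
    # the score vector is exchangeable and the null is centered even when n
    # is a large fraction of the resource
    gene_idx = np.argsort(rng.random((b, n_genes)), axis=1)[:, :n]
    draws = vals[gene_idx, strain_idx[:, None]]
    dr = stats.rankdata(draws, axis=1)
    sr = stats.rankdata(signature.scores.to_numpy(dtype=float))
    drc = dr - dr.mean(axis=1, keepdims=True)
    src = sr - sr.mean()
    denom = np.sqrt((drc ** 2).sum(axis=1) * (src ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (drc @ src) / denom
    r[~np.isfinite(r)] = 0.0  # constant-expression draws carry no signal
    return NullModel(n=n, b=b, null_scores=r, seed=seed)


def permutation_fpr(observed: float, null: NullModel) -> float:
    """One-sided smoothed tail fraction in the direction of the effect.

    ``(k + 1) / (B + 1)`` where k counts null scores at least as extreme as
    the observed score in its own direction; never exactly zero.
    """
    ns = null.null_scores
    if observed >= 0:
        k = int((ns >= observed).sum())
    else:
        k = int((ns <= observed).sum())
    return (k + 1) / (null.b + 1)


def recommend(signature: DiseaseSignature, resource: pd.DataFrame,
              b: int = DEFAULT_PERMUTATIONS, seed: int = 0,
              null: NullModel | None = None) -> pd.DataFrame:
    """Rank every strain in the resource against a harmonized signature.

    Returns a DataFrame with columns ``strain_id, score, fpr, rank`` sorted
    by rank (descending score; exact ties broken by strain id).
    """
    missing = [g for g in signature.gene_ids if g not in resource.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} signature genes absent from the resource")
    sub = resource.loc[signature.gene_ids]
    if null is None:
        null = build_null(resource, signature, b=b, seed=seed)
    log.info("scoring %d strains: n=%d, B=%d, seed=%d",
             resource.shape[1], signature.n, null.b, null.seed)
    strains = [str(c) for c in resource.columns]
    scores = np.array([vulnerability_score(signature, sub[c].to_numpy(dtype=float))
                       for c in resource.columns])
    fprs = np.array([permutation_fpr(s, null) for s in scores])
    order = np.lexsort((np.array(strains, dtype=object), -scores))
    out = pd.DataFrame({"strain_id": np.array(strains, dtype=object)[order],
                        "score": scores[order], "fpr": fprs[order]})
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def read_recommendations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    expected = {"strain_id", "score", "fpr", "rank"}
    if not expected.issubset(df.columns):
        raise ValueError(f"recommendation table must have columns {sorted(expected)}")
    return df


def write_recommendations(recs: pd.DataFrame, path) -> None:
    recs.to_csv(path, sep="\t", index=False)
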