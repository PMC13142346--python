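"""Per-gene similarity-weighted ridge models and strain transcriptome imputation.

Each gene gets a Gaussian ridge regression over donor-indexed features.  For
donor *i* the feature vector is ``F_ij = w_ij * y_j`` where ``w_i.`` are the
normalized local-similarity weights of donor *i* to every other donor over a
400 kb window around the gene's cis-eQTL variant (the diagonal is zero:
leave-self-out) and ``y_j`` is donor *j*'s observed expression.  The ridge
penalty is chosen from a log-spaced grid by 5-fold cross-validation with a
seeded fold permutation.  Prediction for a new strain builds the same
similarity-scaled features from the strain's genotypes and applies the
fitted coefficients, so imputed expression is a weighted combination of the
observed donor expression profiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResourceError, NoCisVariantError
from .genomes import (DEFAULT_HALF_WIDTH, GenotypeMatrix, Window, select_window,
                      vector_window_distances, weight_rows_from_distances,
                      weights_from_distances, window_distances)

log = logging.getLogger(__name__)

DEFAULT_CIS_SPAN = 1_000_000
#: 50 log-spaced ridge penalties spanning [1e-3, 1e3]
DEFAULT_LAMBDA_GRID = np.logspace(-3.0, 3.0, 50)


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chrom: str
    tss: int


@dataclass(frozen=True)
class CisEqtl:
    """The cis variant most correlated with a gene's donor expression."""

    variant_id: str
    chrom: str
    pos: int
    index: int
    r: float


@dataclass
class GeneModel:
    """A fitted per-gene imputation model.

    ``donor_expr`` keeps the observed donor expression vector because
    prediction features are similarity-scaled donor expression values.
    """

    gene_id: str
    eqtl_variant: str
    eqtl_chrom: str
    eqtl_pos: int
    window: Window
    donor_ids: list
    donor_expr: np.ndarray
    beta: np.ndarray
    intercept: float
    lambda_: float
    cv_r2: float
    kappa: float = 1.0
    fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "eqtl_variant": self.eqtl_variant,
            "eqtl_chrom": self.eqtl_chrom,
            "eqtl_pos": int(self.eqtl_pos),
            "window": self.window.to_dict(),
            "donor_ids": list(self.donor_ids),
            "donor_expr": [float(v) for v in self.donor_expr],
            "beta": [float(v) for v in self.beta],
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "cv_r2": float(self.cv_r2),
            "kappa": float(self.kappa),
            "fallback": bool(self.fallback),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(d["gene_id"], d["eqtl_variant"], d["eqtl_chrom"],
                   int(d["eqtl_pos"]), Window.from_dict(d["window"]),
                   list(d["donor_ids"]), np.array(d["donor_expr"], dtype=float),
                   np.array(d["beta"], dtype=float), float(d["intercept"]),
                   float(d["lambda"]), float(d["cv_r2"]), float(d["kappa"]),
                   bool(d["fallback"]))


# ---------------------------------------------------------------------------
# cis-eQTL scan


def map_cis_eqtl(expr_g: np.ndarray, genotypes: GenotypeMatrix, locus: GeneLocus,
                 donor_ids, cis_span: int = DEFAULT_CIS_SPAN) -> CisEqtl:
    """Pick the cis variant maximizing |Pearson r| with donor expression.

    Candidates lie within ``+- cis_span`` of the TSS on the locus chromosome.
    Candidates with fewer than 3 non-missing donor genotypes or zero dosage
    variance are ineligible.  Exact |r| ties resolve to the lowest position.
    """
    y = np.asarray(expr_g, dtype=np.float64)
    idx = select_window(genotypes, Window(locus.chrom, locus.tss, cis_span))
    if idx.size == 0:
        raise NoCisVariantError(f"no cis variant within {cis_span} bp of "
                                f"{locus.gene_id} TSS")
    cols = genotypes.sample_columns(donor_ids)
    X = genotypes.dosage[np.ix_(idx, cols)]  # (v, n)
    yc = y - y.mean()
    ynorm = np.sqrt((yc ** 2).sum())
    absr = np.full(idx.size, -1.0)
    if ynorm > 0:
        missing = np.isnan(X)
        if not missing.any():
            Xc = X - X.mean(axis=1, keepdims=True)
            xnorm = np.sqrt((Xc ** 2).sum(axis=1))
            ok = xnorm > 0
            absr[ok] = np.abs(Xc[ok] @ yc) / (xnorm[ok] * ynorm)
        else:
            for k in range(idx.size):
                m = ~missing[k]
                if m.sum() < 3:
                    continue
                xk = X[k, m] - X[k, m].mean()
                yk = y[m] - y[m].mean()
                xn, yn = np.sqrt((xk ** 2).sum()), np.sqrt((yk ** 2).sum())
                if xn > 0 and yn > 0:
                    absr[k] = abs(float(xk @ yk)) / (xn * yn)
    if absr.max() < 0:
        raise NoCisVariantError(f"no eligible cis variant for {locus.gene_id}")
    best = int(np.argmax(absr))  # first max = lowest position (sorted)
    vi = int(idx[best])
    return CisEqtl(str(genotypes.variant_ids[vi]), str(genotypes.chrom[vi]),
                   int(genotypes.pos[vi]), vi, float(absr[best]))


# ---------------------------------------------------------------------------
# ridge fitting


def _ridge_path(F: np.ndarray, y: np.ndarray, lambdas) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge-with-intercept for every penalty on a grid.

    Centers the columns of ``F`` and ``y``, solves via SVD (one factorization
    serves the whole grid), and returns ``betas`` of shape (p, L) plus the
    matching intercepts ``ybar - Fbar @ beta``.
    """
    lam = np.atleast_1d(np.asarray(lambdas, dtype=np.float64))
    mu = F.mean(axis=0)
    ybar = y.mean()
    Fc = F - mu
    yc = y - ybar
    U, s, Vt = np.linalg.svd(Fc, full_matrices=False)
    Uy = U.T @ yc
    denom = s[:, None] ** 2 + lam[None, :]
    shrink = np.divide(s[:, None], denom, out=np.zeros_like(denom),
                       where=denom > 0)
    betas = Vt.T @ (shrink * Uy[:, None])
    intercepts = ybar - mu @ betas
    return betas, intercepts


def _cv_lambda(F: np.ndarray, y: np.ndarray, grid: np.ndarray, folds: int,
               seed: int) -> tuple[float, float]:
    """Select the penalty minimizing mean K-fold CV squared error.

    Returns ``(lambda, cv_mse_at_lambda)``.  Fold membership is a seeded
    permutation split into ``folds`` nearly equal parts.
    """
    n = len(y)
    perm = np.random.default_rng(seed).permutation(n)
    parts = np.array_split(perm, folds)
    sse = np.zeros(len(grid))
    for test in parts:
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        betas, intercepts = _ridge_path(F[mask], y[mask], grid)
        pred = F[test] @ betas + intercepts[None, :]
        sse += ((pred - y[test, None]) ** 2).sum(axis=0)
    mse = sse / n
    li = int(np.argmin(mse))
    return float(grid[li]), float(mse[li])


def donor_feature_matrix(genotypes: GenotypeMatrix, donor_ids, expr_g: np.ndarray,
                         window: Window, kappa: float = 1.0) -> np.ndarray:
    """Leave-self-out similarity-scaled donor feature matrix F (n x n)."""
    D = window_distances(genotypes, donor_ids, donor_ids, window)
    W = weight_rows_from_distances(D, kappa, exclude_diag=True)
    return W * np.asarray(expr_g, dtype=np.float64)[None, :]


def fit_gene_model(expr_g, genotypes: GenotypeMatrix, eqtl, donor_ids, *,
                   lambda_grid=None, folds: int = 5, seed: int = 0,
                   kappa: float = 1.0,
                   half_width: int = DEFAULT_HALF_WIDTH,
                   gene_id: str = "") -> GeneModel:
    """Fit one gene's similarity-weighted ridge model on the donor panel."""
    donor_ids = list(donor_ids)
    y = np.asarray(expr_g, dtype=np.float64)
    if not np.isfinite(y).all():
        raise ValueError("expression vector must be finite")
    if len(y) != len(donor_ids):
        raise ValueError("expression / donor length mismatch")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} donors for {folds}-fold CV")
    if isinstance(eqtl, str):
        where = np.flatnonzero(genotypes.variant_ids == eqtl)
        if where.size == 0:
            raise NoCisVariantError(f"unknown variant {eqtl!r}")
        vi = int(where[0])
        eqtl = CisEqtl(eqtl, str(genotypes.chrom[vi]), int(genotypes.pos[vi]),
                       vi, float("nan"))
    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid,
                      dtype=np.float64)
    window = Window(eqtl.chrom, eqtl.pos, half_width)
    F = donor_feature_matrix(genotypes, donor_ids, y, window, kappa)
    var_y = float(y.var())

    if not np.any(F) or var_y == 0.0:
        log.warning("degenerate features for gene %s; donor-mean fallback",
                    gene_id or eqtl.variant_id)
        cv_mse = _mean_predictor_cv_mse(y, folds, seed)
        cv_r2 = 1.0 - cv_mse / var_y if var_y > 0 else 0.0
        return GeneModel(gene_id, eqtl.variant_id, eqtl.chrom, eqtl.pos, window,
                         donor_ids, y, np.zeros(len(y)), float(y.mean()),
                         float(grid[0]), float(cv_r2), kappa, fallback=True)

    lam, cv_mse = _cv_lambda(F, y, grid, folds, seed)
    betas, intercepts = _ridge_path(F, y, [lam])
    cv_r2 = 1.0 - cv_mse / var_y
    return GeneModel(gene_id, eqtl.variant_id, eqtl.chrom, eqtl.pos, window,
                     donor_ids, y, betas[:, 0], float(intercepts[0]), lam,
                     float(cv_r2), kappa)


def _mean_predictor_cv_mse(y: np.ndarray, folds: int, seed: int) -> float:
    n = len(y)
    perm = np.random.default_rng(seed).permutation(n)
    sse = 0.0
    for test in np.array_split(perm, folds):
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        sse += ((y[test] - y[mask].mean()) ** 2).sum()
    return sse / n


# ---------------------------------------------------------------------------
# imputation


def _predict_from_distances(model: GeneModel, dmat: np.ndarray) -> np.ndarray:
    """Predictions for each row of a (targets x donors) distance matrix."""
    W = weight_rows_from_distances(dmat, model.kappa)
    Ft = W * model.donor_expr[None, :]
    return model.intercept + Ft @ model.beta


def impute_strain(model: GeneModel, genotypes: GenotypeMatrix, strain: str) -> float:
    """Impute one gene's expression for one strain."""
    d = window_distances(genotypes, [strain], model.donor_ids, model.window)
    return float(_predict_from_distances(model, d)[0])


def impute_panel(models, genotypes: GenotypeMatrix, strains) -> pd.DataFrame:
    """Impute an expression matrix (genes x strains) for an inbred panel."""
    models = list(models)
    strains = list(strains)
    if not models:
        raise EmptyResourceError("no gene models to impute from")
    if not strains:
        raise ValueError("strain list is empty")
    rows = np.empty((len(models), len(strains)))
    for gi, model in enumerate(models):
        d = window_distances(genotypes, strains, model.donor_ids, model.window)
        rows[gi] = _predict_from_distances(model, d)
    return pd.DataFrame(rows, index=[m.gene_id for m in models], columns=strains)


def impute_f1(models, genotypes: GenotypeMatrix, parent_a: str,
              parent_b: str) -> pd.Series:
    """Impute expression of a virtual F1 as the parental dosage average.

    The F1 dosage at each variant is ``(d_a + d_b) / 2`` (additive
    convention, no dominance); the resulting vector is imputed like a strain.
    """
    ia = genotypes.sample_index(parent_a)
    ib = genotypes.sample_index(parent_b)
    f1 = (genotypes.dosage[:, ia] + genotypes.dosage[:, ib]) / 2.0
    vals = np.empty(len(list(models)))
    models = list(models)
    for gi, model in enumerate(models):
        d = vector_window_distances(genotypes, f1, model.donor_ids, model.window)
        W = weights_from_distances(d, model.kappa)
        vals[gi] = model.intercept + (W * model.donor_expr) @ model.beta
    return pd.Series(vals, index=[m.gene_id for m in models],
                     name=f"{parent_a}x{parent_b}")


def train_resource(expr: pd.DataFrame, genotypes: GenotypeMatrix, loci, *,
                   cis_span: int = DEFAULT_CIS_SPAN, lambda_grid=None,
                   folds: int = 5, seed: int = 0, kappa: float = 1.0,
                   half_width: int = DEFAULT_HALF_WIDTH) -> list[GeneModel]:
    """Train a gene model for every gene with donor expression and a locus.

    ``expr`` is genes x donors.  Genes without an eligible cis variant are
    dropped with a logged count.
    """
    loci_map = {l.gene_id: l for l in as_loci(loci)}
    donor_ids = list(expr.columns)
    models, dropped = [], 0
    for gene_id in expr.index:
        locus = loci_map.get(gene_id)
        if locus is None:
            dropped += 1
            continue
        y = expr.loc[gene_id].to_numpy(dtype=np.float64)
        try:
            eqtl = map_cis_eqtl(y, genotypes, locus, donor_ids, cis_span)
        except NoCisVariantError:
            dropped += 1
            continue
        models.append(fit_gene_model(y, genotypes, eqtl, donor_ids,
                                     lambda_grid=lambda_grid, folds=folds,
                                     seed=seed, kappa=kappa,
                                     half_width=half_width, gene_id=gene_id))
    if dropped:
        log.info("dropped %d genes without usable cis variant or locus", dropped)
    if not models:
        raise EmptyResourceError("no gene could be modeled")
    return models


# ---------------------------------------------------------------------------
# I/O


def as_loci(loci) -> list[GeneLocus]:
    if isinstance(loci, pd.DataFrame):
        return [GeneLocus(str(r.gene_id), str(r.chrom), int(r.tss))
                for r in loci.itertuples(index=False)]
    return list(loci)


def read_loci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    expected = ["gene_id", "chrom", "tss"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"locus table must have columns {expected}")
    return df


def write_loci(loci: pd.DataFrame, path) -> None:
    loci.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes-in-rows, samples-in-columns expression TSV."""
    # round_trip parser: written values reload bit-exactly
    return pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def save_models(models, path) -> None:
    """Serialize gene models to JSON; floats round-trip bit-exactly."""
    payload = {"format": "strainrec-models", "version": 1,
               "models": [m.to_dict() for m in models]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_models(path) -> list[GeneModel]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "strainrec-models":
        raise ValueError(f"{path} is not a strainrec model store")
    return [GeneModel.from_dict(d) for d in payload["models"]]
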