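"""Genotype containers, genomic windows, and local genetic similarity.

Dosage genotypes (0/1/2 copies of the alternate allele, ``NaN`` = missing)
are held in a :class:`GenotypeMatrix`.  Local genetic distance between two
samples is the mean normalized dosage mismatch over the variants of a
:class:`Window` (identity-by-state on the dosage scale): for each variant
``|d_a - d_b| / 2`` in ``[0, 1]``, averaged over pairwise-complete variants.
Similarity weights for a target strain against a donor panel are
``(1 - d)^kappa``, normalized to sum to one; donors without any shared
non-missing variant in the window get weight zero, and if every raw weight
is zero the weights fall back to uniform so prediction stays defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, UnknownSampleError

log = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")

#: total cis-similarity window span used throughout is 400 kb (2 x half width)
DEFAULT_HALF_WIDTH = 200_000


@dataclass(frozen=True)
class Window:
    """A symmetric, inclusive genomic interval around an anchoring variant.

    The span is ``[center - half_width, center + half_width]``, inclusive on
    both ends, with 1-based positions.
    """

    chrom: str
    center: int
    half_width: int = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width

    def to_dict(self) -> dict:
        return {"chrom": self.chrom, "center": int(self.center),
                "half_width": int(self.half_width)}

    @classmethod
    def from_dict(cls, d: dict) -> "Window":
        return cls(str(d["chrom"]), int(d["center"]), int(d["half_width"]))


@dataclass
class GenotypeMatrix:
    """Allele dosages for a set of samples at biallelic variants.

    Variants are sorted by (chromosome, position) at construction; positions
    are strictly increasing within each chromosome (duplicate positions are
    collapsed to the first occurrence with a logged count).  Dosage values
    are 0, 1, 2 or NaN (missing).
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: list
    dosage: np.ndarray  # (n_variants, n_samples) float64, NaN = missing
    _sample_idx: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.shape != (len(self.variant_ids), len(self.sample_ids)):
            raise ValueError("dosage shape does not match ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be in {0, 1, 2} or missing")

        order = np.lexsort((self.pos, self.chrom.astype(str)))
        self._reindex(order)
        # collapse duplicate (chrom, pos) so positions are strictly increasing
        same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
        if same.any():
            keep = np.concatenate(([True], ~same))
            log.warning("dropping %d variants at duplicated positions",
                        int((~keep).sum()))
            self._reindex(np.flatnonzero(keep))
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant_ids are not unique")
        self._sample_idx = {s: i for i, s in enumerate(self.sample_ids)}

    def _reindex(self, order: np.ndarray) -> None:
        self.variant_ids = self.variant_ids[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        self.dosage = self.dosage[order]

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_idx[sample_id]
        except KeyError:
            raise UnknownSampleError(sample_id) from None

    def sample_columns(self, sample_ids) -> np.ndarray:
        return np.array([self.sample_index(s) for s in sample_ids], dtype=np.intp)

    def with_samples(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        """Column-concatenate another matrix over the identical variant set."""
        if not (np.array_equal(self.variant_ids, other.variant_ids)
                and np.array_equal(self.pos, other.pos)):
            raise ValueError("variant sets differ")
        return GenotypeMatrix(
            self.variant_ids.copy(), self.chrom.copy(), self.pos.copy(),
            list(self.sample_ids) + list(other.sample_ids),
            np.hstack([self.dosage, other.dosage]),
        )


@dataclass
class SimilarityWeights:
    """Normalized similarity of one target to each donor over a window."""

    target_id: str
    donor_ids: list
    distance: np.ndarray  # d in [0, 1], NaN where undefined
    weight: np.ndarray    # w in [0, 1], sums to 1


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from a VCF (biallelic SNVs) or a dosage TSV.

    VCF records that are not biallelic SNVs are skipped with a logged count.
    The dosage TSV dialect is tab-separated with a
    ``variant_id  chrom  pos  <sample...>`` header and ``NA`` for missing.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "dosage-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    skipped = 0
    # cyvcf2 gt_types codes: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    try:
        for v in vcf:
            if (len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1
                    or v.REF.upper() not in _NUCLEOTIDES
                    or v.ALT[0].upper() not in _NUCLEOTIDES):
                skipped += 1
                continue
            ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
            chroms.append(v.CHROM)
            poss.append(v.POS)
            rows.append(gt_map[np.asarray(v.gt_types)])
    except Exception as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    if skipped:
        log.info("skipped %d non-biallelic/non-SNV records in %s", skipped, path)
    if not rows:
        raise EmptyInputError(f"no usable biallelic SNVs in {path}")
    return GenotypeMatrix(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                          np.array(poss), samples, np.vstack(rows))


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str, 1: str})
    except Exception as exc:
        raise FormatError(f"cannot parse dosage TSV {path}: {exc}") from exc
    expected = ["variant_id", "chrom", "pos"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"dosage TSV must start with columns {expected}, got {list(df.columns[:3])}")
    if df.shape[1] < 4:
        raise FormatError("dosage TSV has no sample columns")
    if df.empty:
        raise EmptyInputError(f"no variants in {path}")
    samples = list(df.columns[3:])
    try:
        dosage = df[samples].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric dosage values in {path}: {exc}") from exc
    return GenotypeMatrix(df["variant_id"].to_numpy(dtype=object),
                          df["chrom"].to_numpy(dtype=object),
                          df["pos"].to_numpy(dtype=np.int64), samples, dosage)


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosage, columns=gm.sample_ids)
    df.insert(0, "pos", gm.pos)
    df.insert(0, "chrom", gm.chrom)
    df.insert(0, "variant_id", gm.variant_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT genotypes (REF=A, ALT=G placeholders)."""
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(gm.n_variants):
            calls = "\t".join(gt.get(d, "./.") for d in gm.dosage[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.variant_ids[i]}"
                     f"\tA\tG\t.\t.\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# windows, distances, weights


def select_window(gm: GenotypeMatrix, window: Window) -> np.ndarray:
    """Indices of variants inside the window, in position order."""
    mask = ((gm.chrom == window.chrom)
            & (gm.pos >= window.start) & (gm.pos <= window.end))
    return np.flatnonzero(mask)


def _pair_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mean |dosage difference| / 2 between columns of a and b.

    ``a`` is (v, n_a), ``b`` is (v, n_b); returns (n_a, n_b) with NaN where no
    variant is non-missing for both samples (pairwise-complete policy).
    """
    if a.shape[0] == 0:
        return np.full((a.shape[1], b.shape[1]), np.nan)
    if not (np.isnan(a).any() or np.isnan(b).any()):
        diff = np.abs(a[:, :, None] - b[:, None, :])
        return diff.mean(axis=0) / 2.0
    diff = np.abs(a[:, :, None] - b[:, None, :])
    valid = ~np.isnan(diff)
    count = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, np.nansum(diff, axis=0) / np.maximum(count, 1), np.nan)
    return out / 2.0


def window_distances(gm: GenotypeMatrix, targets, donors, window: Window) -> np.ndarray:
    """(len(targets), len(donors)) local distance matrix over the window."""
    idx = select_window(gm, window)
    tcols = gm.sample_columns(targets)
    dcols = gm.sample_columns(donors)
    return _pair_distance(gm.dosage[np.ix_(idx, tcols)], gm.dosage[np.ix_(idx, dcols)])


def vector_window_distances(gm: GenotypeMatrix, target_dosage: np.ndarray,
                            donors, window: Window) -> np.ndarray:
    """Distances from an explicit full-length dosage vector to each donor.

    Used for virtual samples (e.g. F1 dosage averages) that are not columns
    of the matrix; the vector may contain non-integer dosages in [0, 2].
    """
    target_dosage = np.asarray(target_dosage, dtype=np.float64)
    if target_dosage.shape != (gm.n_variants,):
        raise ValueError("dosage vector length mismatch")
    idx = select_window(gm, window)
    dcols = gm.sample_columns(donors)
    return _pair_distance(target_dosage[idx][:, None], gm.dosage[np.ix_(idx, dcols)])[0]


def local_distance(gm: GenotypeMatrix, a: str, b: str, window: Window) -> float:
    """Local genetic distance in [0, 1]; NaN when undefined (no shared data)."""
    return float(window_distances(gm, [a], [b], window)[0, 0])


def weights_from_distances(d: np.ndarray, kappa: float = 1.0) -> np.ndarray:
    """Map distances to normalized weights ``(1 - d)^kappa / sum``.

    Undefined distances (NaN) contribute zero raw weight.  If every raw
    weight is zero (all donors maximally distant or all undefined) the
    weights fall back to uniform with a logged warning.
    """
    d = np.asarray(d, dtype=np.float64)
    raw = np.where(np.isnan(d), 0.0, (1.0 - d) ** kappa)
    total = raw.sum()
    if total <= 0.0:
        log.warning("degenerate similarity weights; falling back to uniform")
        return np.full(d.shape, 1.0 / d.size)
    return raw / total


def weight_rows_from_distances(dmat: np.ndarray, kappa: float = 1.0,
                               exclude_diag: bool = False) -> np.ndarray:
    """Row-normalized weight matrix from a distance matrix.

    With ``exclude_diag`` the diagonal gets zero weight before normalization
    (leave-self-out rows used when training on the donor panel itself).
    Degenerate rows fall back to uniform over the allowed entries.
    """
    raw = np.where(np.isnan(dmat), 0.0, (1.0 - dmat) ** kappa)
    allowed = np.ones_like(raw, dtype=bool)
    if exclude_diag:
        np.fill_diagonal(raw, 0.0)
        np.fill_diagonal(allowed, False)
    totals = raw.sum(axis=1)
    bad = totals <= 0.0
    if bad.any():
        log.warning("%d degenerate weight rows; falling back to uniform", bad.sum())
        raw[bad] = allowed[bad] / np.maximum(allowed[bad].sum(axis=1, keepdims=True), 1)
        totals = raw.sum(axis=1)
    return raw / totals[:, None]


def similarity_weights(gm: GenotypeMatrix, target: str, donors, window: Window,
                       kappa: float = 1.0) -> SimilarityWeights:
    """Similarity weights of one target sample against a donor panel."""
    donors = list(donors)
    if not donors:
        raise ValueError("donor list is empty")
    d = window_distances(gm, [target], donors, window)[0]
    return SimilarityWeights(target, donors, d, weights_from_distances(d, kappa))
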