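"""Harmonization of raw weighted gene sets into resource-aligned signatures.

A disease state enters as a weighted gene set: gene identifiers with signed
scores (e.g. signed differential-expression statistics).  Harmonization
(i) translates identifiers to mouse genes through an ortholog mapping table,
(ii) resolves duplicate genes by keeping the entry with the highest absolute
score, and (iii) filters to genes present in the strain expression resource.
A usable signature has at least 3 genes and non-constant scores; the gene
count ``n`` is tracked because the permutation null is built at size ``n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateSignatureError, EmptyTranslationError,
                     SignatureTooSmallError)

log = logging.getLogger(__name__)

MIN_SIGNATURE_GENES = 3


@dataclass
class RawGeneSet:
    """An unharmonized weighted gene set (columns ``gene_id``, ``score``)."""

    entries: pd.DataFrame
    source_species: str = "mouse"
    label: str = ""

    def __post_init__(self) -> None:
        self.entries = self.entries[["gene_id", "score"]].reset_index(drop=True)
        if self.entries.empty:
            raise ValueError("gene set has no entries")
        scores = self.entries["score"].to_numpy(dtype=float)
        if not np.isfinite(scores).all():
            raise ValueError("gene scores must be finite")


@dataclass
class DiseaseSignature:
    """A harmonized signature: unique mouse genes with signed scores."""

    scores: pd.Series  # index = gene ids, values = signed scores
    label: str = ""

    @property
    def gene_ids(self) -> list:
        return list(self.scores.index)

    @property
    def n(self) -> int:
        return int(len(self.scores))


def read_gene_set(path, source_species: str = "mouse", label: str = "") -> RawGeneSet:
    """Read a two-column ``gene_id<TAB>score`` file; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "score"]
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]  # header row
    df = df.assign(score=df["score"].astype(float))
    return RawGeneSet(df.reset_index(drop=True), source_species, label)


def write_gene_set(raw: RawGeneSet, path) -> None:
    raw.entries.to_csv(path, sep="\t", index=False, header=False)


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source_id", "mouse_id"]:
        raise ValueError("ortholog table must have columns source_id, mouse_id")
    return df


def translate_orthologs(raw: RawGeneSet, mapping: pd.DataFrame) -> RawGeneSet:
    """Map gene identifiers through an ortholog table.

    Unmapped entries are dropped with a logged count; one-to-many mappings
    fan out into one entry per mouse target (duplicates are resolved later).
    """
    merged = raw.entries.merge(mapping[["source_id", "mouse_id"]],
                               left_on="gene_id", right_on="source_id",
                               how="left")
    dropped = int(merged["mouse_id"].isna().sum())
    if dropped:
        log.info("dropped %d entries without ortholog mapping", dropped)
    merged = merged.dropna(subset=["mouse_id"])
    if merged.empty:
        raise EmptyTranslationError("no gene set entry could be translated")
    out = merged[["mouse_id", "score"]].rename(columns={"mouse_id": "gene_id"})
    return RawGeneSet(out.reset_index(drop=True), "mouse", raw.label)


def identity_mapping(gene_ids) -> pd.DataFrame:
    """An identity ortholog table for gene sets already on mouse identifiers."""
    ids = list(gene_ids)
    return pd.DataFrame({"source_id": ids, "mouse_id": ids})


def resolve_duplicates(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep one entry per gene: the one with maximal |score|.

    Exact-|score| ties keep the first-encountered entry; output preserves
    the input order of the retained entries.
    """
    df = entries.reset_index(drop=True)
    winners = df.assign(_abs=df["score"].abs()).groupby(
        "gene_id", sort=False)["_abs"].idxmax()
    return df.loc[sorted(winners)].reset_index(drop=True)[["gene_id", "score"]]


def filter_to_resource(entries: pd.DataFrame, resource: pd.DataFrame,
                       label: str = "") -> DiseaseSignature:
    """Retain genes present in the expression resource and validate size.

    Raises if fewer than 3 genes survive or the surviving scores are all
    identical (rank correlation would be undefined).
    """
    if resource.empty:
        raise ValueError("expression resource is empty")
    present = entries["gene_id"].isin(resource.index)
    kept = entries[present].reset_index(drop=True)
    lost = int((~present).sum())
    if lost:
        log.info("dropped %d genes absent from the expression resource", lost)
    if len(kept) < MIN_SIGNATURE_GENES:
        raise SignatureTooSmallError(
            f"only {len(kept)} genes present in the resource "
            f"(minimum {MIN_SIGNATURE_GENES})")
    scores = pd.Series(kept["score"].to_numpy(dtype=float),
                       index=kept["gene_id"].tolist(), name="score")
    if scores.nunique() <= 1:
        raise DegenerateSignatureError("signature scores do not vary across genes")
    return DiseaseSignature(scores, label)


def harmonize(raw: RawGeneSet, mapping: pd.DataFrame | None,
              resource: pd.DataFrame) -> DiseaseSignature:
    """translate -> resolve duplicates -> filter to the resource."""
    if mapping is None:
        mapping = identity_mapping(raw.entries["gene_id"])
    translated = translate_orthologs(raw, mapping)
    resolved = resolve_duplicates(translated.entries)
    return filter_to_resource(resolved, resource, raw.label)
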