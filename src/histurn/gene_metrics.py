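"""Per-gene occupancy metrics: fragment counts, FPKM, fold-change flags.

Genes come from GFF3 annotations; a fragment is assigned to the gene whose
interval contains its midpoint. Occupancy is reported as FPKM (fragments
per kilobase of transcribed region per million mapped reads), mutant/WT
ratios use a small pseudocount so silent genes stay finite, and genes are
flagged when histone H3 falls below 0.8-fold of wild type or Pol II changes
more than 2-fold (strict inequalities on both cutoffs). Expression strata
are quartiles of the wild-type Pol II FPKM: Very high / High / Medium / Low.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .core import (
    BoundsError,
    ConfigError,
    ReadAlignment,
    StratificationError,
)

EXPRESSION_CLASSES = ("Very high", "High", "Medium", "Low")


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ConfigError(f"gene {self.id}: invalid span")
        if self.strand not in ("+", "-"):
            raise ConfigError(f"gene {self.id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ThresholdConfig:
    """Classification cutoffs from the occupancy scatter analysis."""

    loss_cutoff: float = 0.8
    change_cutoff: float = 2.0
    pseudocount: float = 0.1  # FPKM units

    def __post_init__(self):
        if not (0.0 < self.loss_cutoff < 1.0 < self.change_cutoff):
            raise ConfigError("need 0 < loss_cutoff < 1 < change_cutoff")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")


def read_gff3(path, chrom_sizes: Optional[Mapping[str, int]] = None,
              feature_type: str = "gene") -> List[Gene]:
    """Load gene annotations from GFF3 (converted to 0-based half-open)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[Gene] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        gene = Gene(
            id=gid, chrom=feat.seqid, start=feat.start - 1, end=feat.end,
            strand=feat.strand,
        )
        if chrom_sizes is not None:
            if gene.chrom not in chrom_sizes or gene.end > chrom_sizes[gene.chrom]:
                raise BoundsError(f"gene {gene.id} outside declared genome")
        genes.append(gene)
    return genes


def _check_non_overlapping(genes: Sequence[Gene]) -> None:
    by_chrom: Dict[str, List[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise ConfigError(f"genes {a.id} and {b.id} overlap")


def count_fragments(reads: Sequence[ReadAlignment],
                    genes: Sequence[Gene]) -> pd.Series:
    """Count reads whose midpoint falls inside each gene (strand-agnostic).

    Genes must be non-overlapping so each read is counted at most once.
    """
    _check_non_overlapping(genes)
    counts = pd.Series(0, index=[g.id for g in genes], dtype=int)
    by_chrom: Dict[str, List[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    mids: Dict[str, List[int]] = {}
    for r in reads:
        mids.setdefault(r.chrom, []).append(r.midpoint)

    for chrom, gs in by_chrom.items():
        if chrom not in mids:
            continue
        gs = sorted(gs, key=lambda g: g.start)
        starts = np.array([g.start for g in gs])
        ends = np.array([g.end for g in gs])
        m = np.asarray(mids[chrom])
        idx = np.searchsorted(starts, m, side="right") - 1
        valid = idx >= 0
        inside = valid.copy()
        inside[valid] = m[valid] < ends[idx[valid]]
        hit, n = np.unique(idx[inside], return_counts=True)
        for i, c in zip(hit, n):
            counts[gs[i].id] += int(c)
    return counts


def fpkm(counts: pd.Series, lengths: pd.Series, library_size: int) -> pd.Series:
    """FPKM_g = counts_g * 1e9 / (length_g * library_size)."""
    if library_size <= 0:
        raise ConfigError("library_size must be > 0")
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ConfigError("gene lengths must be positive for all genes")
    return counts * 1e9 / (lengths * library_size)


def fold_change(mut_fpkm: pd.Series, wt_fpkm: pd.Series,
                pseudocount: float = 0.1) -> pd.Series:
    """(mutant FPKM + c) / (WT FPKM + c), elementwise over genes."""
    return (mut_fpkm + pseudocount) / (wt_fpkm.reindex(mut_fpkm.index) + pseudocount)


def classify(records: pd.DataFrame, cfg: ThresholdConfig) -> pd.DataFrame:
    """Set the h3_loss / polII_change flags from the fold_change column.

    Strict inequalities: exactly 0.8-fold or exactly 2-fold is not flagged.
    Idempotent; depends only on fold_change and the cutoffs.
    """
    if "fold_change" not in records:
        raise ConfigError("records need a fold_change column")
    out = records.copy()
    fc = out["fold_change"]
    out["h3_loss"] = fc < cfg.loss_cutoff
    out["polII_change"] = (fc > cfg.change_cutoff) | (fc < 1.0 / cfg.change_cutoff)
    return out


def stratify_expression(records: pd.DataFrame,
                        reference: str = "fpkm_polii_wt") -> pd.DataFrame:
    """Label genes Very high / High / Medium / Low by reference FPKM quartile.

    Genes are ranked by the reference column (descending), ties broken by
    stable gene-id order, and split at the 25/50/75 percentiles; the top
    quartile is "Very high".
    """
    if reference not in records:
        raise ConfigError(f"missing reference column {reference!r}")
    n = len(records)
    if n < 4:
        raise StratificationError("need at least 4 genes to stratify")
    out = records.copy()
    # ties broken by gene id: pre-sort by id, then stable sort by FPKM
    order = (
        out.sort_index(kind="stable")
        .sort_values(by=reference, ascending=False, kind="stable")
        .index
    )
    labels = pd.Series(index=order, dtype=object)
    for rank, gene in enumerate(order):
        labels[gene] = EXPRESSION_CLASSES[rank * 4 // n]
    out["expression_class"] = labels.reindex(out.index)
    return out


def build_gene_table(
    genes: Sequence[Gene],
    samples: Mapping[str, Sequence[ReadAlignment]],
) -> pd.DataFrame:
    """Per-gene fragment counts and FPKM for each named read sample."""
    table = pd.DataFrame(
        {
            "gene": [g.id for g in genes],
            "length": [g.length for g in genes],
        }
    ).set_index("gene")
    lengths = table["length"]
    for name, reads in samples.items():
        counts = count_fragments(reads, genes)
        table[f"fragments_{name}"] = counts
        table[f"fpkm_{name}"] = fpkm(counts, lengths, len(reads))
    return table


def write_gene_table(records: pd.DataFrame, path) -> None:
    """TSV with a fixed header, floats at 6 significant digits."""
    out = records.reset_index() if records.index.name else records
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" in df.columns:
        df = df.set_index("gene")
    return df
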