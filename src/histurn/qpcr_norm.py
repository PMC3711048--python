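"""ChIP-qPCR normalization: per-histone modification levels and ratios.

Modification IP efficiencies (IP/input) are first divided, replicate by
replicate, by the efficiency of a total-histone antibody at the same locus —
the C-terminal histone H3 antibody, or total H4 for H4 acetylation — giving
the modification level *per histone molecule*. Levels are then reported
relative to the wild-type strain or to a designated control region (e.g.
the act1 gene for K9me2/Swi6 or a gene-free region for total H3), with
first-order (quadrature) propagation of the replicate standard deviations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, PairingError, QpcrReferenceError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate IP efficiencies for one (amplicon, mark, genotype)."""

    amplicon: str
    mark: str
    genotype: str
    efficiencies: tuple

    def __post_init__(self):
        effs = tuple(float(e) for e in self.efficiencies)
        object.__setattr__(self, "efficiencies", effs)
        if len(effs) < 2:
            raise ConfigError("need >= 2 replicates for dispersion")
        # an absent mark can legitimately give zero IP; negatives cannot
        if any(e < 0 for e in effs):
            raise ConfigError("IP efficiencies must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.efficiencies)


@dataclass(frozen=True)
class QpcrResult:
    amplicon: str
    mark: str
    genotype: str
    level: float
    sd: float
    reference: str  # H3-Cterm | H4 | region id | WT

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigError("s.d. must be >= 0")


def per_histone(mark_meas: QpcrMeasurement,
                ref_meas: QpcrMeasurement) -> QpcrResult:
    """Modification level per histone molecule at one locus.

    Replicates are paired by index; the level is the mean of the replicate
    ratios and the s.d. their sample standard deviation. AcH4 must be
    referenced to total H4, every other mark to the C-terminal H3 antibody.
    """
    if mark_meas.amplicon != ref_meas.amplicon:
        raise ConfigError("mark and reference amplicons differ")
    if mark_meas.genotype != ref_meas.genotype:
        raise ConfigError("mark and reference genotypes differ")
    expected_ref = "H4" if mark_meas.mark == "AcH4" else "H3"
    if ref_meas.mark != expected_ref:
        raise QpcrReferenceError(
            f"{mark_meas.mark} must be normalized to {expected_ref}, "
            f"got {ref_meas.mark}"
        )
    if len(mark_meas.efficiencies) != len(ref_meas.efficiencies):
        raise PairingError("replicate counts differ between mark and reference")
    if any(e <= 0 for e in ref_meas.efficiencies):
        raise ConfigError("reference efficiencies must be > 0")
    ratios = mark_meas.values / ref_meas.values
    return QpcrResult(
        amplicon=mark_meas.amplicon,
        mark=mark_meas.mark,
        genotype=mark_meas.genotype,
        level=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)),
        reference="H4" if expected_ref == "H4" else "H3-Cterm",
    )


def relative_to_wt(result: QpcrResult, wt_result: QpcrResult) -> QpcrResult:
    """Level relative to the wild-type strain at the same locus and mark."""
    if result.amplicon != wt_result.amplicon:
        raise ConfigError("amplicons differ")
    if result.mark != wt_result.mark:
        raise ConfigError("marks differ")
    if wt_result.level == 0:
        raise ConfigError("wild-type level is zero")
    relative = result.level / wt_result.level
    rel_var = 0.0
    if result.level != 0:
        rel_var += (result.sd / result.level) ** 2
    rel_var += (wt_result.sd / wt_result.level) ** 2
    return QpcrResult(
        amplicon=result.amplicon,
        mark=result.mark,
        genotype=result.genotype,
        level=float(relative),
        sd=float(abs(relative) * np.sqrt(rel_var)),
        reference="WT",
    )


def relative_to_region(meas: QpcrMeasurement,
                       control_meas: QpcrMeasurement) -> QpcrResult:
    """Raw IP efficiency at a locus relative to a control region.

    Operates on raw efficiencies (no per-histone step), as used for K9me2
    and Swi6 against the act1 region or total H3 against a gene-free region.
    """
    if meas.mark != control_meas.mark:
        raise ConfigError("marks differ between locus and control")
    if meas.genotype != control_meas.genotype:
        raise ConfigError("genotypes differ between locus and control")
    if len(meas.efficiencies) != len(control_meas.efficiencies):
        raise PairingError("replicate counts differ between locus and control")
    if any(e <= 0 for e in control_meas.efficiencies):
        raise ConfigError("control efficiencies must be > 0")
    ratios = meas.values / control_meas.values
    return QpcrResult(
        amplicon=meas.amplicon,
        mark=meas.mark,
        genotype=meas.genotype,
        level=float(np.mean(ratios)),
        sd=float(np.std(ratios, ddof=1)),
        reference=control_meas.amplicon,
    )


# ---------------------------------------------------------------------------
# table-level processing
# ---------------------------------------------------------------------------

def measurements_from_table(df: pd.DataFrame) -> list[QpcrMeasurement]:
    """Parse a TSV-style table (amplicon, mark, genotype, rep1..repN)."""
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise ConfigError("no replicate columns (rep1..repN) found")
    return [
        QpcrMeasurement(
            amplicon=row["amplicon"], mark=row["mark"],
            genotype=row["genotype"],
            efficiencies=tuple(row[c] for c in rep_cols),
        )
        for _, row in df.iterrows()
    ]


def _lookup(meas: Sequence[QpcrMeasurement], amplicon: str, mark: str,
            genotype: str) -> QpcrMeasurement:
    for m in meas:
        if (m.amplicon, m.mark, m.genotype) == (amplicon, mark, genotype):
            return m
    raise ConfigError(f"no measurement for ({amplicon}, {mark}, {genotype})")


def process_per_histone(
    df: pd.DataFrame,
    wt_genotype: str = "WT",
    marks: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-histone levels for every modification row, relative to wild type.

    Returns one row per (amplicon, mark, genotype) with the per-histone
    level, the WT-relative level, and their standard deviations.
    """
    meas = measurements_from_table(df)
    if marks is None:
        marks = sorted(
            {m.mark for m in meas} - {"H3", "H4", "PolII", "Swi6", "input"}
        )
    rows = []
    wt_cache = {}
    for m in meas:
        if m.mark not in marks:
            continue
        ref_mark = "H4" if m.mark == "AcH4" else "H3"
        ref = _lookup(meas, m.amplicon, ref_mark, m.genotype)
        res = per_histone(m, ref)
        key = (m.amplicon, m.mark)
        if key not in wt_cache:
            wt_ref = _lookup(meas, m.amplicon, ref_mark, wt_genotype)
            wt_mark = _lookup(meas, m.amplicon, m.mark, wt_genotype)
            wt_cache[key] = per_histone(wt_mark, wt_ref)
        rel = relative_to_wt(res, wt_cache[key])
        rows.append(
            (m.amplicon, m.mark, m.genotype, res.level, res.sd,
             rel.level, rel.sd, res.reference)
        )
    return pd.DataFrame(
        rows,
        columns=["amplicon", "mark", "genotype", "per_histone", "sd",
                 "relative_to_wt", "relative_sd", "reference"],
    )


def process_relative_to_region(
    df: pd.DataFrame,
    control_region: str,
    marks: Sequence[str] = ("K9me2", "Swi6"),
) -> pd.DataFrame:
    """Raw-efficiency levels relative to a control region, per genotype."""
    meas = measurements_from_table(df)
    rows = []
    for m in meas:
        if m.mark not in marks or m.amplicon == control_region:
            continue
        control = _lookup(meas, control_region, m.mark, m.genotype)
        res = relative_to_region(m, control)
        rows.append(
            (m.amplicon, m.mark, m.genotype, res.level, res.sd, res.reference)
        )
    return pd.DataFrame(
        rows,
        columns=["amplicon", "mark", "genotype", "level", "sd", "reference"],
    )


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
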