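"""TSS/TTS-anchored metagene profiles of per-million occupancy.

For every gene a window around the anchor is extracted from a per-million
coverage track, oriented 5'->3' (minus-strand genes are reversed), with
positions beyond the chromosome marked missing rather than zero. Profiles
are the per-offset *median* across the genes of each expression class;
offsets supported by too few genes are masked.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError
from .gene_metrics import Gene
from .track_engine import CoverageTrack

TSS = "TSS"
TTS = "TTS"


@dataclass
class MetageneProfile:
    anchor: str
    offsets: np.ndarray                 # bp grid relative to the anchor
    medians: Dict[str, np.ndarray]      # class -> per-offset median (NaN = masked)
    gene_counts: Dict[str, int]


def extract_window(
    track: CoverageTrack,
    gene: Gene,
    anchor: str,
    upstream: int,
    downstream: int,
) -> np.ndarray:
    """Track values around the gene's anchor, oriented 5'->3'.

    Offsets run from -upstream to +downstream (exclusive); positive offsets
    point into the gene body for a TSS anchor and past the gene for a TTS
    anchor. Out-of-bounds positions are NaN.
    """
    if anchor not in (TSS, TTS):
        raise ConfigError(f"unknown anchor {anchor!r}")
    if gene.strand not in ("+", "-"):
        raise ConfigError(f"gene {gene.id}: unknown strand")
    arr = track.data.get(gene.chrom)
    if arr is None:
        raise ConfigError(f"gene {gene.id}: chromosome not in track")
    n = len(arr)
    offsets = np.arange(-upstream, downstream)
    if gene.strand == "+":
        pos = (gene.start if anchor == TSS else gene.end - 1) + offsets
    else:
        pos = (gene.end - 1 if anchor == TSS else gene.start) - offsets
    out = np.full(len(offsets), np.nan)
    ok = (pos >= 0) & (pos < n)
    out[ok] = arr[pos[ok]]
    return out


def aggregate_median(
    windows_per_class: Mapping[str, Sequence[np.ndarray]],
    anchor: str,
    upstream: int,
    downstream: int,
    min_coverage: float = 0.5,
) -> MetageneProfile:
    """Per-offset median over genes, per class; sparse offsets masked.

    An offset is masked (NaN) when fewer than ``min_coverage`` of the
    class's genes contribute a non-missing value there.
    """
    offsets = np.arange(-upstream, downstream)
    medians: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for cls, windows in windows_per_class.items():
        if len(windows) == 0:
            raise ConfigError(f"class {cls!r} has no genes")
        mat = np.vstack(windows)
        if mat.shape[1] != len(offsets):
            raise ConfigError("window length does not match offset grid")
        with warnings.catch_warnings():
            # all-NaN columns are expected at unsupported offsets
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(mat, axis=0)
        support = np.sum(~np.isnan(mat), axis=0)
        med[support < min_coverage * len(windows)] = np.nan
        medians[cls] = med
        counts[cls] = len(windows)
    return MetageneProfile(
        anchor=anchor, offsets=offsets, medians=medians, gene_counts=counts
    )


def compute_metagene(
    track: CoverageTrack,
    genes: Sequence[Gene],
    classes: Mapping[str, str],
    anchor: str,
    upstream: int = 500,
    downstream: int = 2000,
    min_coverage: float = 0.5,
) -> MetageneProfile:
    """Extract windows for all genes and aggregate medians per class."""
    windows: Dict[str, List[np.ndarray]] = {}
    for g in genes:
        cls = classes.get(g.id)
        if cls is None:
            continue
        windows.setdefault(cls, []).append(
            extract_window(track, g, anchor, upstream, downstream)
        )
    if not windows:
        raise ConfigError("no genes with class labels")
    return aggregate_median(windows, anchor, upstream, downstream, min_coverage)


def bin_profile(profile: MetageneProfile, width: int) -> MetageneProfile:
    """Average the profile over fixed-width offset bins (NaN-aware)."""
    if width < 1:
        raise ConfigError("bin width must be >= 1")
    n = len(profile.offsets)
    starts = np.arange(0, n, width)
    new_offsets = profile.offsets[starts]
    medians = {}
    for cls, med in profile.medians.items():
        binned = np.empty(len(starts))
        for j, s in enumerate(starts):
            chunk = med[s:s + width]
            with np.errstate(all="ignore"):
                binned[j] = np.nan if np.all(np.isnan(chunk)) else np.nanmean(chunk)
        medians[cls] = binned
    return MetageneProfile(
        anchor=profile.anchor, offsets=new_offsets, medians=medians,
        gene_counts=dict(profile.gene_counts),
    )


def write_profile(profile: MetageneProfile, path) -> None:
    """TSV (anchor, class, offset, median, n); masked offsets written as NA."""
    rows = []
    for cls in sorted(profile.medians):
        med = profile.medians[cls]
        n = profile.gene_counts[cls]
        for off, v in zip(profile.offsets, med):
            rows.append((profile.anchor, cls, int(off),
                         "NA" if np.isnan(v) else repr(float(v)), n))
    df = pd.DataFrame(rows, columns=["anchor", "class", "offset", "median", "n"])
    df.to_csv(path, sep="\t", index=False)


def read_profile(path) -> MetageneProfile:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.empty:
        raise ConfigError("empty profile file")
    anchor = df["anchor"].iloc[0]
    offsets = np.sort(df["offset"].unique())
    medians: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for cls, sub in df.groupby("class"):
        sub = sub.sort_values("offset")
        medians[str(cls)] = sub["median"].to_numpy(dtype=float)
        counts[str(cls)] = int(sub["n"].iloc[0])
    return MetageneProfile(
        anchor=anchor, offsets=offsets, medians=medians, gene_counts=counts
    )
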