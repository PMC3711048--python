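"""Sliding-window Poisson caller for occupancy gains and losses.

Detects intervals where a treatment track shows significantly more
(``increase``) or fewer (``decrease``) fragments than expected from a
control track, the way peak callers built on a local Poisson background do:
the expected count of a window is the maximum of the genome-wide control
rate and the control rate over several local spans centred on the window
(so locally enriched control regions do not produce spurious calls), scaled
by the library-size ratio. Significant windows are merged across small gaps
and short regions discarded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import stats

from .core import ConfigError, ParseError
from .track_engine import RAW, CoverageTrack

INCREASE = "increase"
DECREASE = "decrease"


@dataclass(frozen=True)
class Region:
    """A called interval of significant occupancy change."""

    chrom: str
    start: int
    end: int
    direction: str
    score: float       # -log10 p of the best window
    fold_change: float

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ConfigError("invalid region span")


@dataclass
class CallerConfig:
    window: int = 300
    step: int = 100
    p_threshold: float = 1e-5
    merge_gap: int = 300
    min_length: int = 500
    local_spans: Tuple[int, ...] = (1000, 5000, 10000)

    def __post_init__(self):
        if self.step > self.window or self.step < 1:
            raise ConfigError("need 1 <= step <= window")
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigError("p_threshold must lie in (0, 1)")
        if self.merge_gap < 0 or self.min_length < 0:
            raise ConfigError("merge_gap and min_length must be >= 0")


def poisson_tail_p(k: int, lam: float, direction: str) -> float:
    """Tail probability of the window test: P(X >= k) or P(X <= k)."""
    if direction == INCREASE:
        return float(stats.poisson.sf(k - 1, lam))
    if direction == DECREASE:
        return float(stats.poisson.cdf(k, lam))
    raise ConfigError(f"unknown direction {direction!r}")


def _window_sums(cum: np.ndarray, starts: np.ndarray, ends: np.ndarray
                 ) -> np.ndarray:
    return cum[ends] - cum[starts]


def call_regions(
    treat: CoverageTrack,
    control: CoverageTrack,
    cfg: CallerConfig,
    direction: str,
) -> List[Region]:
    """Scan for windows whose treat fragment count is Poisson-extreme.

    Both tracks must be raw coverage with library sizes set. Per-window
    fragment counts are estimated from coverage sums divided by the mean
    fragment span of the library; the local background rate is taken from
    the control over spans centred on the window (genome-wide mean as a
    floor) and scaled to the treat library size.
    """
    if direction not in (INCREASE, DECREASE):
        raise ConfigError(f"unknown direction {direction!r}")
    if treat.units != RAW or control.units != RAW:
        raise ConfigError("call_regions expects raw coverage tracks")
    if control.library_size <= 0:
        raise ConfigError("control library_size must be > 0")
    if treat.library_size <= 0:
        raise ConfigError("treat library_size must be > 0")
    if treat.chrom_sizes != control.chrom_sizes:
        raise ConfigError("treat and control chromosome lengths differ")

    # mean covered bases per fragment converts coverage sums to counts
    span_t = treat.total() / treat.library_size
    span_c = control.total() / control.library_size
    if span_t <= 0 or span_c <= 0:
        raise ConfigError("tracks carry no coverage")
    scale = treat.library_size / control.library_size
    genome_len = sum(treat.chrom_sizes.values())
    genome_rate = control.library_size / genome_len  # fragments per bp

    regions: List[Region] = []
    for chrom, L in treat.chrom_sizes.items():
        if L < cfg.window:
            continue
        cum_t = np.concatenate(([0.0], np.cumsum(treat.data[chrom])))
        cum_c = np.concatenate(([0.0], np.cumsum(control.data[chrom])))
        starts = np.arange(0, L - cfg.window + 1, cfg.step)
        ends = starts + cfg.window

        k = np.rint(_window_sums(cum_t, starts, ends) / span_t).astype(int)

        lam_bp = np.full(len(starts), genome_rate)
        mids = (starts + ends) // 2
        for span in cfg.local_spans:
            s_lo = np.clip(mids - span // 2, 0, L)
            s_hi = np.clip(mids + (span - span // 2), 0, L)
            width = np.maximum(s_hi - s_lo, 1)
            rate = _window_sums(cum_c, s_lo, s_hi) / span_c / width
            lam_bp = np.maximum(lam_bp, rate)
        lam = lam_bp * cfg.window * scale

        if direction == INCREASE:
            p = stats.poisson.sf(k - 1, lam)
        else:
            p = stats.poisson.cdf(k, lam)
        keep = p < cfg.p_threshold
        if not keep.any():
            continue

        regions.extend(
            _merge(chrom, starts[keep], ends[keep], p[keep],
                   cum_t, cum_c, span_t, span_c, scale, cfg, direction)
        )
    return regions


def _merge(chrom, w_starts, w_ends, w_p, cum_t, cum_c,
           span_t, span_c, scale, cfg: CallerConfig, direction) -> List[Region]:
    regions: List[Region] = []
    cur_s, cur_e = int(w_starts[0]), int(w_ends[0])
    best_p = float(w_p[0])
    for s, e, p in zip(w_starts[1:], w_ends[1:], w_p[1:]):
        if s - cur_e <= cfg.merge_gap:
            cur_e = max(cur_e, int(e))
            best_p = min(best_p, float(p))
        else:
            regions.append(_finish(chrom, cur_s, cur_e, best_p, cum_t, cum_c,
                                   span_t, span_c, scale, direction))
            cur_s, cur_e, best_p = int(s), int(e), float(p)
    regions.append(_finish(chrom, cur_s, cur_e, best_p, cum_t, cum_c,
                           span_t, span_c, scale, direction))
    return [r for r in regions if r.end - r.start >= cfg.min_length]


def _finish(chrom, start, end, best_p, cum_t, cum_c,
            span_t, span_c, scale, direction) -> Region:
    kt = (cum_t[end] - cum_t[start]) / span_t
    kc = (cum_c[end] - cum_c[start]) / span_c * scale
    fold = (kt + 0.5) / (kc + 0.5)
    # floor p at the smallest positive float so the score stays finite
    score = -np.log10(max(best_p, 5e-324))
    return Region(chrom, start, end, direction, float(score), float(fold))


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def write_regions(regions: List[Region], path) -> None:
    """Write regions as BED6; the name field keeps direction, exact score
    and fold change, the score column is min(1000, round(100 * score))."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w") as fh:
        for r in ordered:
            bed_score = min(1000, round(100 * r.score))
            name = f"{r.direction};score={r.score!r};fold={r.fold_change!r}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{bed_score}\t.\n"
            )


def read_regions(path) -> List[Region]:
    regions: List[Region] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError("expected 6 BED columns", i)
            fields = dict(
                tok.split("=", 1) for tok in parts[3].split(";")[1:]
            )
            regions.append(
                Region(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    direction=parts[3].split(";")[0],
                    score=float(fields["score"]),
                    fold_change=float(fields["fold"]),
                )
            )
    return regions
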