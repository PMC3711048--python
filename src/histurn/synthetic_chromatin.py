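"""Ground-truth chromatin simulator: transcription-coupled histone turnover.

The model genome carries euchromatic genes in four transcription strata and
pericentromere-like heterochromatin blocks. Each nucleosome starts as an
"old" histone octamer carrying its locus-specific mark (H3K4me2 in genes,
H3K9me2 in heterochromatin when the Clr4 methyltransferase is active). RNA
polymerase II passages are drawn per domain from a Poisson distribution;
every passage evicts each nucleosome with probability

    p_loss = p0 * (1 - r)

where ``p0`` is the eviction probability of an unprotected nucleosome and
``r`` the cotranscriptional retention efficiency (1 in wild type, 0 when the
Spt6 chaperone is absent). Naked positions are refilled, independently of
Spt6, with newly synthesized histones that carry H3K56ac but no
locus-specific mark; refilling is less efficient over the first few
nucleosomes downstream of the TSS. The simulator therefore reproduces, by
construction, the coupling between transcription, nucleosome loss and
replacement of methylated by K56-acetylated histone H3.

ChIP-seq read sampling and ChIP-qPCR immunoprecipitation-efficiency tables
are generated from the resulting state so that every downstream analysis
stage can be exercised against a known ground truth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import (
    BoundsError,
    ConfigError,
    ReadAlignment,
    SizingError,
    UnsampleableTargetError,
)

# occupancy codes
OLD, NEW, NAKED = 0, 1, 2
OCCUPANCY_NAMES = {OLD: "OLD", NEW: "NEW", NAKED: "NAKED"}

EUCHROMATIC_GENE = "euchromatic-gene"
HETEROCHROMATIN = "heterochromatin"

#: ChIP targets the read sampler understands.
CHIP_TARGETS = (
    "H3", "K4me2", "K9me2", "K56Ac", "AcH3", "AcH4", "PolII", "Swi6", "input",
)

# N-terminal acetylation (AcH3/AcH4) is emitted as a fixed euchromatic
# baseline plus an increment on newly deposited histones, so that acetylation
# tracks turnover without an explicit HAT/HDAC reaction.
ACETYL_BASELINE = 0.5
ACETYL_INCREMENT = 1.0


@dataclass(frozen=True)
class Domain:
    """A contiguous functional region: a gene or a heterochromatin block."""

    chrom: str
    start: int
    end: int  # 0-based half-open
    kind: str
    id: str
    passage_rate: float  # expected Pol II passages per epoch
    strand: Optional[str] = None  # '+'/'-' for genes, None for heterochromatin

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ConfigError(f"domain {self.id}: invalid span")
        if self.passage_rate < 0:
            raise ConfigError(f"domain {self.id}: negative passage_rate")
        if self.kind == HETEROCHROMATIN and self.strand is not None:
            raise ConfigError(f"domain {self.id}: heterochromatin has no strand")
        if self.kind == EUCHROMATIC_GENE and self.strand not in ("+", "-"):
            raise ConfigError(f"domain {self.id}: gene needs a strand")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeModel:
    """Model genome: chromosome sizes, nucleosome grid, annotated domains."""

    chromosomes: Tuple[Tuple[str, int], ...]
    nucleosome_spacing: int
    domains: Tuple[Domain, ...]

    def __post_init__(self):
        sizes = dict(self.chromosomes)
        if any(n <= 0 for n in sizes.values()):
            raise ConfigError("chromosome lengths must be positive")
        if self.nucleosome_spacing < 1:
            raise ConfigError("nucleosome_spacing must be >= 1")
        by_chrom: Dict[str, List[Domain]] = {}
        for d in self.domains:
            if d.chrom not in sizes:
                raise BoundsError(f"domain {d.id} on unknown chromosome {d.chrom}")
            if d.end > sizes[d.chrom]:
                raise BoundsError(f"domain {d.id} exceeds {d.chrom}")
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, doms in by_chrom.items():
            doms = sorted(doms, key=lambda d: d.start)
            for a, b in zip(doms, doms[1:]):
                if b.start < a.end:
                    raise ConfigError(f"domains {a.id} and {b.id} overlap")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genes(self) -> List[Domain]:
        return [d for d in self.domains if d.kind == EUCHROMATIC_GENE]

    @property
    def het_domains(self) -> List[Domain]:
        return [d for d in self.domains if d.kind == HETEROCHROMATIN]


@dataclass(frozen=True)
class Genotype:
    """Retention/derepression parameters of a strain.

    ``retention`` is the overall cotranscriptional retention efficiency of
    modified histones (1 = perfect, 0 = none); ``het_derepression``
    multiplies the Pol II passage rate of heterochromatin domains (silencing
    loss); ``clr4_active`` controls whether heterochromatic nucleosomes carry
    H3K9me2 at all.
    """

    name: str
    retention: float
    het_derepression: float = 1.0
    clr4_active: bool = True

    def __post_init__(self):
        if not (0.0 <= self.retention <= 1.0):
            raise ConfigError("retention must lie in [0, 1]")
        if self.het_derepression < 1.0:
            raise ConfigError("het_derepression must be >= 1")
        if self.name == "WT" and (self.retention != 1.0 or self.het_derepression != 1.0):
            raise ConfigError("WT must have retention 1 and het_derepression 1")
        if self.name == "spt6D" and self.retention != 0.0:
            raise ConfigError("spt6D must have retention 0")
        if self.name == "spt6-K20" and not (0.0 < self.retention < 1.0):
            raise ConfigError("spt6-K20 must have 0 < retention < 1")


#: Built-in strains. Retention < 1 for clr3D reflects the HDAC's direct role
#: in preventing histone turnover; derepression values reflect the elevated
#: Pol II occupancy of pericentromeric repeats in silencing mutants.
GENOTYPES: Dict[str, Genotype] = {
    g.name: g
    for g in (
        Genotype("WT", retention=1.0, het_derepression=1.0, clr4_active=True),
        Genotype("spt6-K20", retention=0.5, het_derepression=2.0, clr4_active=True),
        Genotype("spt6D", retention=0.0, het_derepression=4.0, clr4_active=True),
        Genotype("clr3D", retention=0.85, het_derepression=3.0, clr4_active=True),
        Genotype("clr4D", retention=0.85, het_derepression=4.0, clr4_active=False),
        Genotype("spt6-K20 clr3D", retention=0.425, het_derepression=6.0,
                 clr4_active=True),
    )
}

_GENOTYPE_ALIASES = {
    "wt": "WT",
    "spt6-k20": "spt6-K20",
    "spt6d": "spt6D",
    "clr3d": "clr3D",
    "clr4d": "clr4D",
    "spt6-k20 clr3d": "spt6-K20 clr3D",
}


def get_genotype(name: str) -> Genotype:
    """Look up a built-in genotype by name (unicode Δ or ASCII D suffix)."""
    key = _GENOTYPE_ALIASES.get(name.strip().lower().replace("δ", "d"))
    if key is None:
        raise ConfigError(
            f"unknown genotype {name!r}; known: {sorted(GENOTYPES)}"
        )
    return GENOTYPES[key]


@dataclass
class SimConfig:
    """Simulation, read-sampling and qPCR-sampling parameters.

    p0:
        per-passage eviction probability of an unprotected nucleosome.
    p_fill / p_fill_5prime / k_5prime:
        per-passage refill probability of a naked position, with a reduced
        rate over the first ``k_5prime`` nucleosomes downstream of the TSS.
    epochs:
        duration multiplier on domain passage rates.
    read_length / fragment_length:
        single-end read length (bp) and sonicated fragment length (bp).
    background_fraction:
        fraction of reads drawn uniformly from the genome; also the additive
        background term of qPCR IP efficiencies.
    n_reads, qpcr_replicates, noise_cv:
        library size per ChIP sample; replicate count and lognormal
        coefficient of variation for qPCR tables.
    """

    p0: float = 0.3
    p_fill: float = 0.4
    p_fill_5prime: float = 0.1
    k_5prime: int = 3
    epochs: float = 1.0
    read_length: int = 49
    fragment_length: int = 250
    background_fraction: float = 0.05
    n_reads: int = 100_000
    qpcr_replicates: int = 3
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for name in ("p0", "p_fill", "p_fill_5prime", "background_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.background_fraction >= 1.0:
            raise ConfigError("background_fraction must be < 1")
        if self.p_fill_5prime > self.p_fill:
            raise ConfigError("p_fill_5prime must be <= p_fill")
        if self.read_length > self.fragment_length:
            raise ConfigError("read_length must be <= fragment_length")
        if self.read_length < 1 or self.k_5prime < 0:
            raise ConfigError("read_length >= 1 and k_5prime >= 0 required")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class NucleosomeState:
    """One nucleosome position of the ground-truth state."""

    domain_id: str
    index: int  # from the domain's 5' end
    dyad: int
    occupancy: str  # OLD / NEW / NAKED
    marks: frozenset


@dataclass
class _DomainState:
    domain: Domain
    dyads: np.ndarray        # left-to-right genomic coordinates
    index_5p: np.ndarray     # nucleosome index counted from the 5' end
    occupancy: np.ndarray    # codes OLD/NEW/NAKED
    initial_mark: Optional[str]  # mark carried by OLD nucleosomes
    effective_rate: float    # passage_rate after genotype derepression


class ChromatinState:
    """Ground truth of one simulated strain: all nucleosome states."""

    def __init__(self, model: GenomeModel, genotype: Genotype,
                 domain_states: List[_DomainState],
                 passages: Dict[str, int]):
        self.model = model
        self.genotype = genotype
        self._domains = {ds.domain.id: ds for ds in domain_states}
        self.passages = passages

    def domain_state(self, domain_id: str) -> _DomainState:
        return self._domains[domain_id]

    def __iter__(self) -> Iterable[NucleosomeState]:
        for ds in self._domains.values():
            for i in range(len(ds.dyads)):
                yield NucleosomeState(
                    domain_id=ds.domain.id,
                    index=int(ds.index_5p[i]),
                    dyad=int(ds.dyads[i]),
                    occupancy=OCCUPANCY_NAMES[int(ds.occupancy[i])],
                    marks=_marks(int(ds.occupancy[i]), ds.initial_mark),
                )

    # -- aggregate helpers used by analyses and tests -------------------

    def old_fraction(self, domain_id: Optional[str] = None) -> float:
        occ = self._collect(domain_id)
        return float(np.mean(occ == OLD))

    def occupied_fraction(self, domain_id: Optional[str] = None) -> float:
        occ = self._collect(domain_id)
        return float(np.mean(occ != NAKED))

    def new_fraction(self, domain_id: Optional[str] = None) -> float:
        occ = self._collect(domain_id)
        return float(np.mean(occ == NEW))

    def _collect(self, domain_id: Optional[str]) -> np.ndarray:
        if domain_id is not None:
            return self._domains[domain_id].occupancy
        return np.concatenate([ds.occupancy for ds in self._domains.values()])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (n.domain_id, n.index, n.dyad, n.occupancy,
             ",".join(sorted(n.marks)))
            for n in self
        ]
        return pd.DataFrame(
            rows, columns=["domain", "index", "dyad", "occupancy", "marks"]
        )


def _marks(occ_code: int, initial_mark: Optional[str]) -> frozenset:
    if occ_code == NAKED:
        return frozenset()
    if occ_code == NEW:
        return frozenset({"K56Ac"})
    return frozenset({initial_mark}) if initial_mark else frozenset()


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(
    n_genes: int,
    strata_rates: Sequence[float],
    het_domains: int,
    seed: int = 0,
    *,
    gene_length: int = 2000,
    gene_gap: int = 1000,
    het_length: int = 6000,
    het_gap: int = 2000,
    het_rate: float = 1.0,
    nucleosome_spacing: int = 150,
    chrom_length: Optional[int] = None,
) -> GenomeModel:
    """Lay out a model genome with stratified genes and heterochromatin.

    Genes sit on chrI with alternating strands; each of the four strata
    (strictly decreasing passage rates) receives ``n_genes / 4`` genes, with
    the stratum-to-position assignment shuffled by ``seed``. Heterochromatin
    blocks with a low basal passage rate sit on chrII.
    """
    if len(strata_rates) != 4:
        raise ConfigError("exactly four strata rates required")
    if any(b >= a for a, b in zip(strata_rates, strata_rates[1:])):
        raise ConfigError("strata_rates must be strictly decreasing")
    if n_genes < 4 or n_genes % 4:
        raise SizingError("n_genes must be >= 4 and divisible by 4")
    if het_domains < 0:
        raise SizingError("het_domains must be >= 0")

    needed = gene_gap + n_genes * (gene_length + gene_gap)
    if chrom_length is not None and chrom_length < needed:
        raise SizingError(
            f"chrom_length {chrom_length} cannot hold {n_genes} genes "
            f"({needed} bp needed)"
        )
    len_chrI = chrom_length if chrom_length is not None else needed

    rng = np.random.default_rng(seed)
    strata = np.repeat(np.arange(4), n_genes // 4)
    rng.shuffle(strata)

    domains: List[Domain] = []
    for i in range(n_genes):
        start = gene_gap + i * (gene_length + gene_gap)
        domains.append(
            Domain(
                chrom="chrI",
                start=start,
                end=start + gene_length,
                kind=EUCHROMATIC_GENE,
                id=f"gene{i:04d}",
                passage_rate=float(strata_rates[strata[i]]),
                strand="+" if i % 2 == 0 else "-",
            )
        )

    chromosomes: List[Tuple[str, int]] = [("chrI", len_chrI)]
    if het_domains > 0:
        len_chrII = het_gap + het_domains * (het_length + het_gap)
        for j in range(het_domains):
            start = het_gap + j * (het_length + het_gap)
            domains.append(
                Domain(
                    chrom="chrII",
                    start=start,
                    end=start + het_length,
                    kind=HETEROCHROMATIN,
                    id=f"het{j:02d}",
                    passage_rate=het_rate,
                )
            )
        chromosomes.append(("chrII", len_chrII))

    return GenomeModel(
        chromosomes=tuple(chromosomes),
        nucleosome_spacing=nucleosome_spacing,
        domains=tuple(domains),
    )


# ---------------------------------------------------------------------------
# turnover simulation
# ---------------------------------------------------------------------------

def simulate_turnover(
    model: GenomeModel,
    genotype: Genotype,
    cfg: SimConfig,
    passages: Optional[int | Mapping[str, int]] = None,
) -> ChromatinState:
    """Run the per-passage eviction/refill process over the whole genome.

    Passage counts are Poisson with mean ``passage_rate * epochs`` (times
    ``het_derepression`` in heterochromatin) unless ``passages`` forces a
    deterministic count for every domain (int) or per domain id (mapping).
    Old nucleosomes keep their initial mark; evicted positions refill with
    K56Ac-marked new histones. Locus-specific methylation is never re-placed.
    """
    rng = np.random.default_rng(cfg.seed)
    p_loss = cfg.p0 * (1.0 - genotype.retention)
    spacing = model.nucleosome_spacing

    domain_states: List[_DomainState] = []
    n_passages: Dict[str, int] = {}
    for dom in model.domains:
        dyads = np.arange(dom.start + spacing // 2, dom.end, spacing)
        m = len(dyads)
        index_5p = np.arange(m)
        if dom.kind == EUCHROMATIC_GENE and dom.strand == "-":
            index_5p = index_5p[::-1].copy()

        rate = dom.passage_rate
        if dom.kind == HETEROCHROMATIN:
            rate *= genotype.het_derepression
        lam = rate * cfg.epochs

        if passages is None:
            n = int(rng.poisson(lam))
        elif isinstance(passages, Mapping):
            n = int(passages[dom.id])
        else:
            n = int(passages)
        n_passages[dom.id] = n

        p_fill_vec = np.full(m, cfg.p_fill)
        if dom.kind == EUCHROMATIC_GENE:
            p_fill_vec[index_5p < cfg.k_5prime] = cfg.p_fill_5prime

        occ = np.full(m, OLD, dtype=np.int8)
        if m and n and (p_loss > 0 or cfg.p_fill > 0):
            for _ in range(n):
                if p_loss > 0:
                    evict = rng.random(m) < p_loss
                    occ[evict & (occ != NAKED)] = NAKED
                naked = occ == NAKED
                if naked.any():
                    refill = naked & (rng.random(m) < p_fill_vec)
                    occ[refill] = NEW

        if dom.kind == EUCHROMATIC_GENE:
            initial_mark = "K4me2"
        else:
            initial_mark = "K9me2" if genotype.clr4_active else None

        domain_states.append(
            _DomainState(
                domain=dom,
                dyads=dyads,
                index_5p=index_5p,
                occupancy=occ,
                initial_mark=initial_mark,
                effective_rate=rate,
            )
        )
    return ChromatinState(model, genotype, domain_states, n_passages)


# ---------------------------------------------------------------------------
# ChIP read sampling
# ---------------------------------------------------------------------------

def _target_weights(state: ChromatinState, target: str) -> np.ndarray:
    """Per-nucleosome sampling weight for a ChIP target, all domains."""
    weights = [
        np.asarray(_target_weights_domain(ds, target), dtype=float)
        for ds in state._domains.values()
    ]
    return np.concatenate(weights) if weights else np.zeros(0)


def sample_chip_reads(
    state: ChromatinState,
    target: str,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n_reads: Optional[int] = None,
) -> List[ReadAlignment]:
    """Draw aligned single-end ChIP reads for one antibody target.

    Fragment midpoints follow the target's nucleosome density (uniform over
    the genome for ``input``), mixed with ``background_fraction`` uniform
    fragments; the read is the 5' ``read_length`` bases of either fragment
    end with equal probability.
    """
    if target not in CHIP_TARGETS:
        raise ConfigError(f"unknown ChIP target {target!r}")
    n = cfg.n_reads if n_reads is None else int(n_reads)
    if n <= 0:
        raise ConfigError("n_reads must be > 0")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, CHIP_TARGETS.index(target)])

    chrom_names = [c for c, _ in state.model.chromosomes]
    chrom_lens = np.array([l for _, l in state.model.chromosomes])
    frag = cfg.fragment_length
    if np.any(chrom_lens < frag):
        raise ConfigError("fragment_length exceeds a chromosome length")

    if target == "input":
        n_bg, n_sig = n, 0
        dyads = np.zeros(0, dtype=int)
        chrom_idx_sig = np.zeros(0, dtype=int)
    else:
        weights = _target_weights(state, target)
        total = float(weights.sum())
        if total == 0.0 and cfg.background_fraction == 0.0:
            raise UnsampleableTargetError(
                f"target {target} has zero density and no background"
            )
        if total == 0.0:
            n_bg, n_sig = n, 0
        else:
            n_bg = int(rng.binomial(n, cfg.background_fraction))
            n_sig = n - n_bg
        dyad_list, chrom_list = [], []
        for ds in state._domains.values():
            dyad_list.append(ds.dyads)
            chrom_list.append(
                np.full(len(ds.dyads), chrom_names.index(ds.domain.chrom))
            )
        dyads = np.concatenate(dyad_list)
        chrom_idx_sig_all = np.concatenate(chrom_list)

    mids_parts, chrom_parts = [], []
    if target != "input" and n_sig > 0:
        p = weights / total
        picks = rng.choice(len(dyads), size=n_sig, p=p)
        jitter_half = state.model.nucleosome_spacing // 2
        jitter = rng.integers(-jitter_half, jitter_half + 1, size=n_sig)
        mids_parts.append(dyads[picks] + jitter)
        chrom_parts.append(chrom_idx_sig_all[picks])
    if n_bg > 0:
        chrom_pick = rng.choice(
            len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum()
        )
        u = rng.random(n_bg)
        mids_parts.append((u * chrom_lens[chrom_pick]).astype(int))
        chrom_parts.append(chrom_pick)

    mids = np.concatenate(mids_parts)
    chrom_idx = np.concatenate(chrom_parts)

    # clamp fragments inside the chromosome, then take the 5' read of
    # either fragment end with equal probability
    lo = frag // 2
    hi = chrom_lens[chrom_idx] - (frag - frag // 2)
    mids = np.clip(mids, lo, hi)
    frag_start = mids - frag // 2
    minus = rng.random(len(mids)) < 0.5
    starts = np.where(minus, frag_start + frag - cfg.read_length, frag_start)
    ends = starts + cfg.read_length

    return [
        ReadAlignment(
            chrom=chrom_names[c],
            start=int(s),
            end=int(e),
            strand="-" if m else "+",
        )
        for c, s, e, m in zip(chrom_idx, starts, ends, minus)
    ]


# ---------------------------------------------------------------------------
# qPCR table emission
# ---------------------------------------------------------------------------

#: qPCR antibody panel; H3 is the C-terminal (total histone) antibody and H4
#: the total-H4 reference used for AcH4 normalization.
QPCR_MARKS = ("H3", "H4", "K4me2", "K9me2", "K56Ac", "AcH3", "AcH4",
              "PolII", "Swi6")


def _amplicon_density(state: ChromatinState, target: str,
                      chrom: str, start: int, end: int) -> float:
    """Mean target weight per nucleosome position within an amplicon."""
    if target in ("H3", "H4"):
        target_key = "H3"
    else:
        target_key = target
    num = 0.0
    n_pos = 0
    for ds in state._domains.values():
        if ds.domain.chrom != chrom:
            continue
        inside = (ds.dyads >= start) & (ds.dyads < end)
        if not inside.any():
            continue
        w = _target_weights_domain(ds, target_key)
        num += float(w[inside].sum())
        n_pos += int(inside.sum())
    return num / n_pos if n_pos else 0.0


def _target_weights_domain(ds: _DomainState, target: str) -> np.ndarray:
    occ = ds.occupancy
    occupied = occ != NAKED
    if target == "H3":
        return occupied.astype(float)
    if target in ("K4me2", "K9me2"):
        return ((occ == OLD) & (ds.initial_mark == target)).astype(float)
    if target == "K56Ac":
        return (occ == NEW).astype(float)
    if target in ("AcH3", "AcH4"):
        base = ACETYL_BASELINE if ds.domain.kind == EUCHROMATIC_GENE else 0.0
        return occupied * base + (occ == NEW) * ACETYL_INCREMENT
    if target == "PolII":
        return np.full(len(occ), ds.effective_rate)
    if target == "Swi6":
        return ((occ == OLD) & (ds.initial_mark == "K9me2")).astype(float)
    raise ConfigError(f"unknown qPCR mark {target!r}")


def emit_qpcr_table(
    state: ChromatinState,
    amplicons: Sequence[Tuple[str, str, int, int]],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    marks: Sequence[str] = QPCR_MARKS,
) -> pd.DataFrame:
    """Emit replicate IP efficiencies for every (mark, amplicon) pair.

    Each efficiency is ``(mark density within the amplicon + background) *
    lognormal noise`` with coefficient of variation ``noise_cv``; the table
    includes the total-H3 (C-terminal) and total-H4 reference rows needed by
    per-histone normalization.
    """
    if not amplicons:
        raise ConfigError("empty amplicon list")
    sizes = state.model.chrom_sizes
    for name, chrom, start, end in amplicons:
        if chrom not in sizes or not (0 <= start < end <= sizes[chrom]):
            raise BoundsError(f"amplicon {name} outside genome")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 10_007])

    # mean-1 lognormal multiplier with the requested CV
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    mu = -0.5 * sigma ** 2

    rows = []
    rep_cols = [f"rep{i + 1}" for i in range(cfg.qpcr_replicates)]
    for name, chrom, start, end in amplicons:
        for mark in marks:
            density = _amplicon_density(state, mark, chrom, start, end)
            signal = density + cfg.background_fraction
            if cfg.noise_cv > 0:
                noise = rng.lognormal(mu, sigma, size=cfg.qpcr_replicates)
            else:
                noise = np.ones(cfg.qpcr_replicates)
            effs = signal * noise
            rows.append(
                [name, mark, state.genotype.name] + [float(e) for e in effs]
            )
    return pd.DataFrame(rows, columns=["amplicon", "mark", "genotype"] + rep_cols)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_reads_bed(reads: Sequence[ReadAlignment], path) -> None:
    """Write reads as BED6 (name rN, score 0)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def write_reads_sam(reads: Sequence[ReadAlignment],
                    chrom_sizes: Mapping[str, int], path) -> None:
    """Write reads as minimal mapped SAM records with an @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{i}"
            a.flag = 16 if r.strand == "-" else 0
            a.reference_id = out.header.references.index(r.chrom)
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            out.write(a)


def write_state_tsv(state: ChromatinState, path) -> None:
    state.to_frame().to_csv(path, sep="\t", index=False)


def write_gff3(model: GenomeModel, path) -> None:
    """Write the model's genes as a GFF3 annotation (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in model.chromosomes:
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for d in model.genes:
            fh.write(
                f"{d.chrom}\thisturn\tgene\t{d.start + 1}\t{d.end}\t.\t"
                f"{d.strand}\t.\tID={d.id}\n"
            )
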