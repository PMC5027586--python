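"""Synthetic genome, ground truth and coverage generator.

Generates gene annotations, stranded nascent-transcription coverage and
ChIP tag coverage with a fully serialized truth table, so every downstream
stage (transcript detection, differential testing, enhancer calling, peak
calling) can be validated against known planted features.

Geometry guarantees baked into the truth:

* genes are separated by at least ``min_gene_gap`` bp;
* intergenic enhancers sit inside gene gaps with > 3.5 kb clearance from
  every gene boundary; their divergent transcript 5' ends are at most
  ``divergent_gap`` bp apart (inside the 1 kb pairing rule with margin);
* intragenic enhancers lie fully inside their host gene with >= 1.5 kb
  margin from the gene ends, one per host, and each is covered by an
  H3K4me2 interval.

All randomness flows from one seeded generator per (purpose, condition,
replicate); no global random state is touched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import StrandedCoverage
from . import io as gio

__all__ = [
    "SimConfig",
    "GeneTruth",
    "IntergenicEnhancerTruth",
    "IntragenicEnhancerTruth",
    "TFSite",
    "TruthSet",
    "GRO_CONDITIONS",
    "CHIP_CONDITIONS",
    "generate_truth",
    "simulate_groseq",
    "simulate_chip_coverage",
    "write_fixtures",
]

GRO_CONDITIONS = ("vehicle", "t0.5", "t2")
CHIP_CONDITIONS = ("vehicle", "t0.5", "t2", "t4")

# Venn-category -> set of ChIP timepoints carrying the site (cf. chip module)
_VENN_TIMEPOINTS = {
    1: ("t0.5", "t2", "t4"),
    2: ("t0.5", "t2"),
    3: ("t2", "t4"),
    4: ("t0.5",),
    5: ("t0.5", "t4"),
    6: ("t2",),
    7: ("t4",),
}


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (5_000, 30_000)
    n_intergenic_enhancers: int = 60
    n_intragenic_enhancers: int = 60
    frac_genes_up: float = 0.15
    frac_genes_down: float = 0.15
    gene_log2fc_range: tuple[float, float] = (1.0, 2.5)
    frac_enhancers_up: float = 0.15
    frac_enhancers_down: float = 0.15
    enhancer_log2fc_range: tuple[float, float] = (1.5, 2.5)
    couple_enhancers_to_genes: bool = True
    early_fraction: float = 0.5
    pausing_fraction: float = 0.3
    pausing_ratio_range: tuple[float, float] = (2.0, 6.0)
    background_density: float = 0.01  # tags/bp per library (GRO-seq)
    gene_density_range: tuple[float, float] = (0.2, 1.0)  # tags/bp at vehicle
    enhancer_density: float = 0.4  # tags/bp per transcript
    intragenic_length_range: tuple[int, int] = (200, 400)
    intergenic_transcript_length_range: tuple[int, int] = (250, 450)
    divergent_gap: int = 600  # max 5'-5' distance of the divergent pair
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    bin_width: int = 50
    # ChIP layer
    chip_background_density: float = 1.0  # tags/bp per library
    chip_enrichment: float = 8.0
    chip_site_width: int = 400
    n_tf_extra_sites: int = 80
    tf_factors: tuple[str, ...] = ("AR", "PIAS1", "ERG", "HDAC3")
    seed: int = 0
    # placement rules
    min_gene_gap: int = 10_000
    edge_margin: int = 20_000
    enhancer_gene_clearance: int = 3_500
    intragenic_margin: int = 1_500

    def validate(self) -> None:
        counts = [
            self.n_chromosomes,
            self.n_genes,
            self.n_intergenic_enhancers,
            self.n_intragenic_enhancers,
            self.n_replicates,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_chromosomes == 0 or self.n_replicates == 0:
            raise ValueError("need at least one chromosome and one replicate")
        for frac in (
            self.frac_genes_up,
            self.frac_genes_down,
            self.frac_enhancers_up,
            self.frac_enhancers_down,
            self.pausing_fraction,
            self.early_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("proportions must lie in [0, 1]")
        if self.frac_genes_up + self.frac_genes_down > 1:
            raise ValueError("gene up+down fractions exceed 1")
        if self.gene_length_range[0] < 1000:
            raise ValueError("gene_length_range minimum must be >= 1,000 bp")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range inverted")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.chrom_length % self.bin_width:
            raise ValueError("chrom_length must be a multiple of bin_width")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        lo, hi = self.intragenic_length_range
        if not 150 <= lo <= hi <= 500:
            raise ValueError("intragenic_length_range must lie within [150, 500]")
        if self.gene_length_range[0] < 2 * self.intragenic_margin + hi:
            raise ValueError(
                "shortest gene cannot host an intragenic enhancer with the "
                "required margins; enlarge gene_length_range or shrink margins"
            )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    base_density: float  # sense-strand tags/bp at vehicle, per library
    log2fc: dict[str, float]  # per treated condition
    pausing_ratio: float = 1.0

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntergenicEnhancerTruth:
    id: str
    chrom: str
    center: int
    plus_span: tuple[int, int]
    minus_span: tuple[int, int]
    density: float
    log2fc: dict[str, float]

    @property
    def hull(self) -> tuple[int, int]:
        return (self.minus_span[0], self.plus_span[1])


@dataclass
class IntragenicEnhancerTruth:
    id: str
    host_gene: str
    chrom: str
    start: int
    end: int
    strand: str  # antisense to the host gene
    density: float
    log2fc: dict[str, float]


@dataclass
class TFSite:
    chrom: str
    start: int
    end: int
    conditions: tuple[str, ...]


@dataclass
class TruthSet:
    config: SimConfig
    genes: list[GeneTruth]
    intergenic_enhancers: list[IntergenicEnhancerTruth]
    intragenic_enhancers: list[IntragenicEnhancerTruth]
    h3k4me2: list[tuple[str, int, int]]
    tf_sites: dict[str, list[TFSite]] = field(default_factory=dict)

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                }
                for g in self.genes
            ]
        )

    def h3k4me2_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.h3k4me2, columns=["chrom", "start", "end"])


def _rng(seed: int, *keys) -> np.random.Generator:
    hashed = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed)] + hashed)


def _condition_fc(rng: np.random.Generator, magnitude_range, sign: int, early_frac: float):
    """Draw log2 fold changes for (t0.5, t2); sign 0 means unregulated."""
    if sign == 0:
        return {"t0.5": 0.0, "t2": 0.0}
    mag = float(rng.uniform(*magnitude_range))
    early = bool(rng.random() < early_frac)
    return {"t0.5": sign * mag if early else 0.0, "t2": sign * mag}


def _assign_signs(rng: np.random.Generator, n: int, frac_up: float, frac_down: float):
    n_up = int(round(frac_up * n))
    n_down = int(round(frac_down * n))
    if n_up + n_down > n:
        raise ValueError("regulated fractions exceed the feature count")
    signs = np.array([1] * n_up + [-1] * n_down + [0] * (n - n_up - n_down))
    rng.shuffle(signs)
    return signs


def generate_truth(config: SimConfig) -> TruthSet:
    """Place every feature and assign regulation classes; deterministic per seed."""
    config.validate()
    rng = _rng(config.seed, "truth")

    genes = _place_genes(config, rng)
    intergenic = _place_intergenic(config, rng, genes)
    intragenic, h3k4me2 = _place_intragenic(config, rng, genes)
    _assign_regulation(config, rng, genes, intergenic, intragenic)
    tf_sites = _place_tf_sites(config, rng, genes, intergenic, h3k4me2)
    return TruthSet(
        config=config,
        genes=genes,
        intergenic_enhancers=intergenic,
        intragenic_enhancers=intragenic,
        h3k4me2=h3k4me2,
        tf_sites=tf_sites,
    )


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneTruth]:
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneTruth] = []
    idx = 0
    for chrom, n in zip(config.chrom_names(), per_chrom):
        lengths = rng.integers(
            config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
        )
        needed = int(lengths.sum()) + (n + 1) * config.min_gene_gap + 2 * config.edge_margin
        if needed > config.chrom_length:
            raise ValueError(
                f"cannot place {n} genes on {chrom}: need {needed} bp "
                f"(genes + {config.min_gene_gap} bp minimum gaps + edge margins) "
                f"but chrom_length is {config.chrom_length}"
            )
        leftover = config.chrom_length - needed
        extra = rng.multinomial(leftover, np.full(n + 1, 1.0 / (n + 1)))
        cursor = config.edge_margin
        for k in range(n):
            cursor += config.min_gene_gap + int(extra[k])
            start = cursor
            end = start + int(lengths[k])
            cursor = end
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneTruth(
                    gene_id=f"gene_{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    base_density=float(rng.uniform(*config.gene_density_range)),
                    log2fc={"t0.5": 0.0, "t2": 0.0},
                )
            )
            idx += 1
    return genes


def _gene_gaps(config: SimConfig, genes: list[GeneTruth]) -> list[tuple[str, int, int]]:
    gaps = []
    for chrom in config.chrom_names():
        sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
        prev = config.edge_margin
        for g in sub:
            gaps.append((chrom, prev, g.start))
            prev = g.end
        gaps.append((chrom, prev, config.chrom_length - config.edge_margin))
    return gaps


def _place_intergenic(
    config: SimConfig, rng: np.random.Generator, genes: list[GeneTruth]
) -> list[IntergenicEnhancerTruth]:
    if config.n_intergenic_enhancers == 0:
        return []
    max_len = config.intergenic_transcript_length_range[1]
    half_footprint = config.divergent_gap // 2 + max_len
    clearance = config.enhancer_gene_clearance
    eligible = []
    for chrom, lo, hi in _gene_gaps(config, genes):
        c_lo = lo + clearance + half_footprint
        c_hi = hi - clearance - half_footprint
        if c_hi > c_lo:
            eligible.append((chrom, c_lo, c_hi))
    if len(eligible) < config.n_intergenic_enhancers:
        raise ValueError(
            f"only {len(eligible)} gene gaps can host an intergenic enhancer "
            f"(need {config.n_intergenic_enhancers}); violated rule: "
            f">{clearance} bp clearance from gene boundaries inside a gap"
        )
    chosen = rng.choice(len(eligible), size=config.n_intergenic_enhancers, replace=False)
    out = []
    lo_len, hi_len = config.intergenic_transcript_length_range
    for k, gap_i in enumerate(sorted(int(i) for i in chosen)):
        chrom, c_lo, c_hi = eligible[gap_i]
        center = int(rng.integers(c_lo, c_hi))
        d = int(rng.integers(100, config.divergent_gap + 1))
        l_plus = int(rng.integers(lo_len, hi_len + 1))
        l_minus = int(rng.integers(lo_len, hi_len + 1))
        plus_span = (center + d // 2, center + d // 2 + l_plus)
        minus_span = (center - d // 2 - l_minus, center - d // 2)
        out.append(
            IntergenicEnhancerTruth(
                id=f"tinter_{k:03d}",
                chrom=chrom,
                center=center,
                plus_span=plus_span,
                minus_span=minus_span,
                density=config.enhancer_density,
                log2fc={"t0.5": 0.0, "t2": 0.0},
            )
        )
    return out


def _place_intragenic(
    config: SimConfig, rng: np.random.Generator, genes: list[GeneTruth]
) -> tuple[list[IntragenicEnhancerTruth], list[tuple[str, int, int]]]:
    lo_len, hi_len = config.intragenic_length_range
    margin = config.intragenic_margin
    hosts = [g for g in genes if g.length >= 2 * margin + hi_len]
    if len(hosts) < config.n_intragenic_enhancers:
        raise ValueError(
            f"only {len(hosts)} genes are long enough to host an intragenic "
            f"enhancer (need {config.n_intragenic_enhancers}); violated rule: "
            f"span + 2 x {margin} bp margin must fit inside the host gene"
        )
    chosen = rng.choice(len(hosts), size=config.n_intragenic_enhancers, replace=False)
    flip = {"+": "-", "-": "+"}
    out = []
    h3k4me2: list[tuple[str, int, int]] = []
    for k, host_i in enumerate(sorted(int(i) for i in chosen)):
        host = hosts[host_i]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(host.start + margin, host.end - margin - length + 1))
        end = start + length
        out.append(
            IntragenicEnhancerTruth(
                id=f"tintra_{k:03d}",
                host_gene=host.gene_id,
                chrom=host.chrom,
                start=start,
                end=end,
                strand=flip[host.strand],
                density=config.enhancer_density,
                log2fc={"t0.5": 0.0, "t2": 0.0},
            )
        )
        h3k4me2.append((host.chrom, start - 200, end + 200))
    # decoy marks: inside random genes, away from planted enhancer spans
    planted = {(e.chrom, e.start, e.end) for e in out}
    n_decoys = config.n_intragenic_enhancers
    attempts = 0
    while n_decoys > 0 and attempts < 50 * config.n_intragenic_enhancers + 100:
        attempts += 1
        g = genes[int(rng.integers(0, len(genes)))]
        if g.length < 2 * margin + 600:
            continue
        s = int(rng.integers(g.start + margin, g.end - margin - 600 + 1))
        e = s + 600
        if any(c == g.chrom and s < pe and e > ps for c, ps, pe in planted):
            continue
        if any(c == g.chrom and s < pe and e > ps for c, ps, pe in h3k4me2):
            continue
        h3k4me2.append((g.chrom, s, e))
        n_decoys -= 1
    h3k4me2.sort()
    return out, h3k4me2


def _assign_regulation(config, rng, genes, intergenic, intragenic) -> None:
    signs = _assign_signs(rng, len(genes), config.frac_genes_up, config.frac_genes_down)
    pausing = rng.random(len(genes)) < config.pausing_fraction
    for g, sign, pause in zip(genes, signs, pausing):
        g.log2fc = _condition_fc(rng, config.gene_log2fc_range, int(sign), config.early_fraction)
        if pause:
            g.pausing_ratio = float(rng.uniform(*config.pausing_ratio_range))

    gene_sign = {
        g.gene_id: (1 if g.log2fc["t2"] > 0 else -1 if g.log2fc["t2"] < 0 else 0) for g in genes
    }

    def nearest_gene_sign(chrom: str, pos: int) -> int | None:
        best, best_d = None, None
        for g in genes:
            if g.chrom != chrom:
                continue
            d = abs(g.tss - pos)
            if best_d is None or d < best_d:
                best, best_d = g, d
        if best is not None and best_d is not None and best_d <= 50_000:
            return gene_sign[best.gene_id]
        return None

    all_enh = [(e, e.center) for e in intergenic] + [
        (e, (e.start + e.end) // 2) for e in intragenic
    ]
    lottery = _assign_signs(
        rng, len(all_enh), config.frac_enhancers_up, config.frac_enhancers_down
    )
    for (enh, pos), fallback_sign in zip(all_enh, lottery):
        sign = None
        if config.couple_enhancers_to_genes:
            sign = nearest_gene_sign(enh.chrom, pos)
        if sign is None:
            sign = int(fallback_sign)
        enh.log2fc = _condition_fc(
            rng, config.enhancer_log2fc_range, sign, config.early_fraction
        )


def _place_tf_sites(config, rng, genes, intergenic, h3k4me2) -> dict[str, list[TFSite]]:
    half = config.chip_site_width // 2
    sites: dict[str, list[TFSite]] = {f: [] for f in config.tf_factors}
    up_centers = [
        (e.chrom, e.center) for e in intergenic if e.log2fc["t2"] > 0
    ]
    other_centers = [
        (e.chrom, e.center) for e in intergenic if e.log2fc["t2"] <= 0
    ]
    for factor in config.tf_factors:
        if factor == "AR":
            # AR occupies every up-enhancer at all timepoints and a sample of
            # the remaining enhancers early-only
            for chrom, c in up_centers:
                sites[factor].append(TFSite(chrom, c - half, c + half, _VENN_TIMEPOINTS[1]))
            for chrom, c in other_centers:
                cat = int(rng.choice([1, 2, 4, 6]))
                sites[factor].append(TFSite(chrom, c - half, c + half, _VENN_TIMEPOINTS[cat]))
        else:
            # coregulators co-occupy a subset of the up-enhancers at 2 h
            take = max(1, int(0.7 * len(up_centers))) if up_centers else 0
            if take:
                picked = rng.choice(len(up_centers), size=take, replace=False)
                for i in sorted(int(x) for x in picked):
                    chrom, c = up_centers[i]
                    sites[factor].append(
                        TFSite(chrom, c - half, c + half, ("t2", "t4"))
                    )
    # extra AR sites at random intergenic positions, spread over venn categories
    gaps = _gene_gaps(config, genes)
    occupied = [(s.chrom, s.start, s.end) for s in sites.get("AR", [])]
    placed = 0
    attempts = 0
    while placed < config.n_tf_extra_sites and attempts < 100 * config.n_tf_extra_sites:
        attempts += 1
        chrom, lo, hi = gaps[int(rng.integers(0, len(gaps)))]
        if hi - lo < config.chip_site_width + 4000:
            continue
        c = int(rng.integers(lo + 2000 + half, hi - 2000 - half))
        s, e = c - half, c + half
        if any(ch == chrom and s < oe + 2000 and e > os_ - 2000 for ch, os_, oe in occupied):
            continue
        cat = int(rng.integers(1, 8))
        sites["AR"].append(TFSite(chrom, s, e, _VENN_TIMEPOINTS[cat]))
        occupied.append((chrom, s, e))
        placed += 1
    if placed < config.n_tf_extra_sites:
        raise ValueError(
            "could not place the requested extra TF sites; violated rule: "
            ">= 2 kb separation between sites inside gene gaps"
        )
    # H3K4me2 behaves like a constitutive factor over its truth intervals
    sites["H3K4me2"] = [TFSite(c, s, e, CHIP_CONDITIONS) for c, s, e in h3k4me2]
    for factor in sites:
        sites[factor].sort(key=lambda s: (s.chrom, s.start, s.end))
    return sites


# ------------------------------------------------------------------ emission


def _add_density(arr: np.ndarray, bin_width: int, start: int, end: int, density: float) -> None:
    """Add ``density`` (expected tags/bp) over [start, end) with fractional edges."""
    n = len(arr)
    start = max(start, 0)
    end = min(end, n * bin_width)
    if end <= start:
        return
    lo, hi = start // bin_width, (end - 1) // bin_width
    if lo == hi:
        arr[lo] += density * (end - start)
        return
    arr[lo] += density * ((lo + 1) * bin_width - start)
    if hi > lo + 1:
        arr[lo + 1 : hi] += density * bin_width
    arr[hi] += density * (end - hi * bin_width)


def _sample_nb(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_groseq(
    truth: TruthSet, condition: str, replicate: int, config: SimConfig | None = None
) -> StrandedCoverage:
    """One stranded nascent-transcription library for one condition/replicate."""
    config = config or truth.config
    if condition not in GRO_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {GRO_CONDITIONS}")
    rng = _rng(config.seed, "groseq", condition, replicate)
    n_bins = config.chrom_length // config.bin_width
    mu = {
        chrom: (
            np.full(n_bins, config.background_density * config.bin_width),
            np.full(n_bins, config.background_density * config.bin_width),
        )
        for chrom in config.chrom_names()
    }

    def fc_scale(log2fc: dict[str, float]) -> float:
        return 2.0 ** log2fc.get(condition, 0.0) if condition != "vehicle" else 1.0

    for g in truth.genes:
        plus, minus = mu[g.chrom]
        arr = plus if g.strand == "+" else minus
        dens = g.base_density * fc_scale(g.log2fc)
        _add_density(arr, config.bin_width, g.start, g.end, dens)
        if g.pausing_ratio > 1.0:
            if g.strand == "+":
                window = (g.start - 50, g.start + 250)
            else:
                window = (g.end - 250, g.end + 50)
            _add_density(
                arr, config.bin_width, window[0], window[1], (g.pausing_ratio - 1.0) * dens
            )
    for e in truth.intergenic_enhancers:
        plus, minus = mu[e.chrom]
        dens = e.density * fc_scale(e.log2fc)
        _add_density(plus, config.bin_width, e.plus_span[0], e.plus_span[1], dens)
        _add_density(minus, config.bin_width, e.minus_span[0], e.minus_span[1], dens)
    for e in truth.intragenic_enhancers:
        plus, minus = mu[e.chrom]
        arr = plus if e.strand == "+" else minus
        _add_density(arr, config.bin_width, e.start, e.end, e.density * fc_scale(e.log2fc))

    chroms = {}
    for chrom in config.chrom_names():
        plus = _sample_nb(rng, mu[chrom][0], config.nb_dispersion)
        minus = _sample_nb(rng, mu[chrom][1], config.nb_dispersion)
        chroms[chrom] = (plus, minus)
    return StrandedCoverage(
        chroms=chroms,
        bin_width=config.bin_width,
        library_id=f"groseq_{condition}_rep{replicate}",
        stranded=True,
    )


def simulate_chip_coverage(
    truth: TruthSet,
    factor: str,
    condition: str,
    replicate: int,
    config: SimConfig | None = None,
    control: bool = False,
) -> StrandedCoverage:
    """One unstranded ChIP library (or its matched input when ``control``)."""
    config = config or truth.config
    if factor not in truth.tf_sites:
        raise ValueError(f"unknown factor {factor!r}; truth has {sorted(truth.tf_sites)}")
    if condition not in CHIP_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CHIP_CONDITIONS}")
    kind = "input" if control else "chip"
    rng = _rng(config.seed, kind, factor, condition, replicate)
    n_bins = config.chrom_length // config.bin_width
    mu = {
        chrom: np.full(n_bins, config.chip_background_density * config.bin_width)
        for chrom in config.chrom_names()
    }
    if not control:
        extra = (config.chip_enrichment - 1.0) * config.chip_background_density
        for site in truth.tf_sites[factor]:
            if condition in site.conditions:
                _add_density(mu[site.chrom], config.bin_width, site.start, site.end, extra)
    chroms = {}
    for chrom in config.chrom_names():
        arr = _sample_nb(rng, mu[chrom], config.nb_dispersion)
        chroms[chrom] = (arr, arr)
    label = f"{kind}_{factor}_{condition}_rep{replicate}"
    return StrandedCoverage(
        chroms=chroms, bin_width=config.bin_width, library_id=label, stranded=False
    )


# ------------------------------------------------------------------ fixtures


def write_fixtures(
    truth: TruthSet, coverages: dict[str, StrandedCoverage], out_dir
) -> dict:
    """Serialize truth and coverage to plain-text fixtures; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    files: dict[str, str] = {}

    sizes = {c: config.chrom_length for c in config.chrom_names()}
    gio.write_chrom_sizes(sizes, out_dir / "chrom.sizes")
    files["chrom.sizes"] = "chromosome sizes"

    genes = truth.genes_frame().rename(columns={"gene_id": "name"})
    gio.write_gff3_genes(truth.genes_frame(), out_dir / "genes.gff3")
    gio.write_bed12(genes, out_dir / "genes.bed12")
    files["genes.gff3"] = "gene annotation (GFF3)"
    files["genes.bed12"] = "gene annotation (BED12)"

    gene_rows = []
    for g in truth.genes:
        gene_rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "start": g.start,
                "end": g.end,
                "tss": g.tss,
                "tts": g.tts,
                "base_density": g.base_density,
                "log2fc_t0.5": g.log2fc["t0.5"],
                "log2fc_t2": g.log2fc["t2"],
                "pausing_ratio": g.pausing_ratio,
            }
        )
    pd.DataFrame(gene_rows).to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
    files["truth_genes.tsv"] = "gene ground truth"

    inter_rows = [
        {
            "id": e.id,
            "chrom": e.chrom,
            "center": e.center,
            "plus_start": e.plus_span[0],
            "plus_end": e.plus_span[1],
            "minus_start": e.minus_span[0],
            "minus_end": e.minus_span[1],
            "density": e.density,
            "log2fc_t0.5": e.log2fc["t0.5"],
            "log2fc_t2": e.log2fc["t2"],
        }
        for e in truth.intergenic_enhancers
    ]
    pd.DataFrame(inter_rows).to_csv(out_dir / "truth_intergenic.tsv", sep="\t", index=False)
    files["truth_intergenic.tsv"] = "intergenic enhancer ground truth"

    intra_rows = [
        {
            "id": e.id,
            "host_gene": e.host_gene,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "strand": e.strand,
            "density": e.density,
            "log2fc_t0.5": e.log2fc["t0.5"],
            "log2fc_t2": e.log2fc["t2"],
        }
        for e in truth.intragenic_enhancers
    ]
    pd.DataFrame(intra_rows).to_csv(out_dir / "truth_intragenic.tsv", sep="\t", index=False)
    files["truth_intragenic.tsv"] = "intragenic enhancer ground truth"

    k4 = truth.h3k4me2_frame()
    k4["name"] = [f"h3k4me2_{i}" for i in range(len(k4))]
    k4["score"] = 0
    k4["strand"] = "."
    gio.write_bed6(k4, out_dir / "h3k4me2.bed")
    files["h3k4me2.bed"] = "H3K4me2 intervals"

    tf_rows = []
    for factor in sorted(truth.tf_sites):
        for s in truth.tf_sites[factor]:
            tf_rows.append(
                {
                    "factor": factor,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "conditions": ",".join(s.conditions),
                }
            )
    pd.DataFrame(tf_rows).to_csv(out_dir / "tf_sites.tsv", sep="\t", index=False)
    files["tf_sites.tsv"] = "TF binding-site ground truth"

    for stem in sorted(coverages):
        for written in gio.write_coverage(coverages[stem], out_dir, stem):
            files[written.name] = f"coverage ({stem})"

    return gio.write_manifest(files, out_dir / "manifest.json")
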