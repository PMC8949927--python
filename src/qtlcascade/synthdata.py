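"""Synthetic input generators for the prioritization pipeline.

Everything the pipeline consumes can be generated here with the
statistical structure the analysis assumes: backcross genotypes and
phenotypes with a planted additive QTL, a two-strain SNP catalog with a
declared haplotype-block layout, a gene annotation over the critical
interval, bulk expression matrices with planted log2 effects, a
negative-binomial single-cell count matrix, and qPCR Ct tables.

The ``fig3`` preset wires these together so that the downstream cascade
recovers exactly the planted counts: 644 interval genes, 111 genes in
polymorphic windows, 8 parental DE genes, 5 congenic candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprfilter import CtTable, ExpressionMatrix
from .linkage import (
    MISSING,
    NB,
    NN,
    GenotypeMatrix,
    GeneticMap,
    PhenotypeTable,
    haldane,
)
from .regions import MBP, GenomicInterval
from .scprofile import CANONICAL_CLUSTERS, CellMatrix

PEAK_MARKER = "rs4222065"
PEAK_MARKER_BP = 112_500_000
CRITICAL_INTERVAL = GenomicInterval("chr13", 78_000_000, 120_400_000)

#: five genes called out by the congenic expression filter
NAMED_CANDIDATES = ("Acot12", "S100z", "Ankrd55", "Rnf180", "Iqgap2")

CM_PER_MBP = 0.5
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genetic map and backcross simulation


def default_chr13_map(
    marker_every_bp: int = 2_500_000,
    end_bp: int = 120_400_000,
    cm_per_mbp: float = CM_PER_MBP,
) -> GeneticMap:
    """Evenly spaced chr13 fixture map with the peak marker at 112.5 Mbp.

    The cM scale is a fixed conversion of the physical scale; the
    marker coinciding with the peak position is named rs4222065.
    """
    bp = np.arange(0, end_bp + 1, marker_every_bp, dtype=np.int64)
    if bp[-1] != end_bp:
        bp = np.append(bp, end_bp)
    names = []
    for i, p in enumerate(bp):
        names.append(PEAK_MARKER if p == PEAK_MARKER_BP else f"c13m{i + 1:03d}")
    return GeneticMap(
        chromosome="chr13",
        markers=tuple(names),
        position_bp=bp,
        position_cm=bp * (cm_per_mbp / MBP),
    )


@dataclass(frozen=True)
class CrossSpec:
    """Design of one simulated (NZOxB6)N2 cohort."""

    n: int
    qtl_bp: int
    additive: float = 0.4
    sigma: float = 1.0
    traits: tuple = ("glucose",)
    baseline: float = 0.0
    missing_rate: float = 0.0
    seed: int | tuple = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if self.sigma <= 0:
            raise ValueError("residual SD must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def effect(self, trait: str) -> float:
        if isinstance(self.additive, dict):
            return float(self.additive.get(trait, 0.0))
        return float(self.additive)


def simulate_backcross(genmap: GeneticMap, spec: CrossSpec):
    """Simulate N2 genotypes and phenotypes with one additive QTL.

    Each chromosome is a two-state Markov chain along the map with
    Haldane transition probabilities (no interference).  The hidden QTL
    genotype is part of the simulated chain; the phenotype is
    baseline + a * 1[g_QTL = NN] + Normal(0, sigma^2) per trait.
    Returns ``(GenotypeMatrix, PhenotypeTable)``.
    """
    lo, hi = genmap.span_bp
    if not lo <= spec.qtl_bp <= hi:
        raise ValueError(f"QTL position {spec.qtl_bp} outside map span [{lo}, {hi}]")
    rng = np.random.default_rng(spec.seed)

    qtl_cm = float(genmap.cm_at(spec.qtl_bp))
    loci_cm = np.append(genmap.position_cm, qtl_cm)
    order = np.argsort(loci_cm, kind="stable")
    loci_cm = loci_cm[order]
    qtl_slot = int(np.nonzero(order == genmap.n_markers)[0][0])

    r = haldane(np.diff(loci_cm) / 100.0)
    n, L = spec.n, len(loci_cm)
    g = np.empty((n, L), dtype=np.int8)
    g[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, L):
        flip = rng.random(n) < r[j - 1]
        g[:, j] = np.where(flip, 1 - g[:, j - 1], g[:, j - 1])

    qtl_geno = g[:, qtl_slot].copy()
    marker_codes = np.delete(g, qtl_slot, axis=1)

    if spec.missing_rate > 0:
        drop = rng.random(marker_codes.shape) < spec.missing_rate
        # keep at least one typed marker per individual
        all_gone = drop.all(axis=1)
        drop[all_gone, 0] = False
        marker_codes = np.where(drop, MISSING, marker_codes).astype(np.int8)

    individuals = [f"N2_{i + 1:05d}" for i in range(n)]
    geno = GenotypeMatrix(individuals, genmap, marker_codes)
    pheno = {}
    is_nn = (qtl_geno == NN).astype(float)
    for trait in spec.traits:
        eps = rng.normal(0.0, spec.sigma, size=n)
        pheno[trait] = spec.baseline + spec.effect(trait) * is_nn + eps
    table = PhenotypeTable(pd.DataFrame(pheno, index=individuals))
    return geno, table


# ---------------------------------------------------------------------------
# SNP catalog


@dataclass
class SnpCatalog:
    """Biallelic SNP records with one allele call per strain."""

    chromosome: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    allele_a: np.ndarray  # strain A (reference strain, B6-like)
    allele_b: np.ndarray  # strain B (donor strain, NZO-like)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        for name in ("ref", "alt", "allele_a", "allele_b"):
            arr = np.asarray(getattr(self, name), dtype="U1")
            if arr.shape != self.positions.shape:
                raise ValueError(f"{name} length mismatch")
            if not np.isin(arr, list("ACGT")).all():
                raise ValueError(f"{name} must be single nucleotides")
            setattr(self, name, arr)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")
        if np.any(self.ref == self.alt):
            raise ValueError("records must be biallelic (ref != alt)")

    @property
    def discordant(self) -> np.ndarray:
        return self.allele_a != self.allele_b

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class BlockSpec:
    """Subinterval with a target discordant-SNP density per full window."""

    start: int
    end: int
    density: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty block")
        if self.density < 0:
            raise ValueError("density must be non-negative")


def _draw_alleles(rng, count, discordant):
    ref = rng.choice(_BASES, size=count)
    shift = rng.integers(1, 4, size=count)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    if discordant:
        return ref, alt, ref.copy(), alt.copy()
    return ref, alt, alt.copy(), alt.copy()


def make_snp_catalog(
    region: GenomicInterval,
    block_layout,
    seed=0,
    window_size: int = 250_000,
    background_total_density: int = 0,
) -> SnpCatalog:
    """Generate a two-strain SNP catalog with a planted block structure.

    Within each declared block, every full window receives strictly more
    discordant SNPs than the block's declared density; outside blocks no
    discordant SNPs are placed.  ``background_total_density`` adds
    strain-concordant SNPs uniformly everywhere (the "total SNPs" track).
    Positions are uniform within windows.  Overlapping blocks are
    rejected.
    """
    blocks = [b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in block_layout]
    blocks.sort(key=lambda b: b.start)
    for prev, cur in zip(blocks, blocks[1:]):
        if cur.start < prev.end:
            raise ValueError("overlapping layout blocks")
    rng = np.random.default_rng(seed)

    pos_parts, disc_parts = [], []
    n_windows = int(np.ceil(region.length_bp / window_size))
    for k in range(n_windows):
        ws = region.start + k * window_size
        we = min(ws + window_size, region.end)
        wlen = we - ws
        if background_total_density > 0:
            n_bg = int(round(background_total_density * wlen / window_size))
            if n_bg:
                pos_parts.append(ws + rng.choice(wlen, size=min(n_bg, wlen), replace=False))
                disc_parts.append(np.zeros(min(n_bg, wlen), dtype=bool))
        for b in blocks:
            seg_lo, seg_hi = max(ws, b.start), min(we, b.end)
            if seg_hi <= seg_lo:
                continue
            frac = (seg_hi - seg_lo) / window_size
            base = int(rng.integers(b.density + 1, max(b.density + 2, int(1.2 * b.density) + 1)))
            count = int(round(base * frac))
            if count:
                count = min(count, seg_hi - seg_lo)
                pos_parts.append(seg_lo + rng.choice(seg_hi - seg_lo, size=count, replace=False))
                disc_parts.append(np.ones(count, dtype=bool))

    if pos_parts:
        positions = np.concatenate(pos_parts)
        disc = np.concatenate(disc_parts)
    else:
        positions = np.empty(0, dtype=np.int64)
        disc = np.empty(0, dtype=bool)

    # drop position collisions, keeping discordant records
    order = np.lexsort((~disc, positions))
    positions, disc = positions[order], disc[order]
    keep = np.ones(positions.size, dtype=bool)
    keep[1:] = positions[1:] != positions[:-1]
    positions, disc = positions[keep], disc[keep]

    ref = np.empty(positions.size, dtype="U1")
    alt = np.empty_like(ref)
    a = np.empty_like(ref)
    b_ = np.empty_like(ref)
    for flag in (True, False):
        sel = disc == flag
        if sel.any():
            ref[sel], alt[sel], a[sel], b_[sel] = _draw_alleles(rng, int(sel.sum()), flag)
    return SnpCatalog(region.chromosome, positions, ref, alt, a, b_)


# ---------------------------------------------------------------------------
# gene annotation


BIOTYPES = ("coding", "gene_model", "miRNA", "riken")


@dataclass
class GeneAnnotation:
    """Per-gene 1-based inclusive spans with a coarse biotype."""

    chromosome: str
    gene_ids: list
    start: np.ndarray
    end: np.ndarray
    biotype: np.ndarray

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.biotype = np.asarray(self.biotype, dtype=object)
        if not (len(self.gene_ids) == self.start.size == self.end.size == self.biotype.size):
            raise ValueError("annotation field lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if np.any(self.start > self.end):
            raise ValueError("gene start must be <= end")
        bad = set(self.biotype) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "chrom": self.chromosome,
                "start": self.start,
                "end": self.end,
                "biotype": self.biotype,
            }
        )


# ---------------------------------------------------------------------------
# expression fixtures


@dataclass(frozen=True)
class ExpressionFixtureSpec:
    """Two-group expression fixture with planted log2 effects."""

    contrast: str
    genes: tuple
    group_labels: tuple = ("A", "B")
    n_per_group: int = 5
    effects: dict = field(default_factory=dict)
    sd: float = 0.1
    seed: int | tuple = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")
        if self.sd <= 0:
            raise ValueError("within-group SD must be positive")


def generate_expression(spec: ExpressionFixtureSpec) -> ExpressionMatrix:
    """Intensities whose log2(x + 1) values carry the planted effects.

    Group 1 log2 levels are baseline + effect, group 2 baseline, both
    with Normal(0, sd) noise, then transformed to the intensity scale as
    2^v - 1 so the default downstream LFC recovers the planted truth.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    base = rng.uniform(4.0, 10.0, size=len(genes))
    eff = np.array([float(spec.effects.get(g, 0.0)) for g in genes])
    m = spec.n_per_group
    v1 = base[:, None] + eff[:, None] + rng.normal(0, spec.sd, (len(genes), m))
    v2 = base[:, None] + rng.normal(0, spec.sd, (len(genes), m))
    values = np.exp2(np.concatenate([v1, v2], axis=1)) - 1.0
    g1, g2 = spec.group_labels
    samples = [f"{g1}_{i + 1}" for i in range(m)] + [f"{g2}_{i + 1}" for i in range(m)]
    df = pd.DataFrame(np.maximum(values, 0.0), index=genes, columns=samples)
    groups = pd.Series([g1] * m + [g2] * m, index=samples)
    return ExpressionMatrix(df, groups, contrast=spec.contrast)


# ---------------------------------------------------------------------------
# single-cell fixture


DEFAULT_SC_MEANS = pd.DataFrame(
    {
        "Alpha":  {"Ins1": 5, "Gcg": 300, "Sst": 2, "Ppy": 2, "Mki67": 0.1,
                   "S100z": 0.3, "Iqgap2": 0.5, "Acot12": 0.2, "Rnf180": 1.0,
                   "Ankrd55": 0.5},
        "Delta":  {"Ins1": 5, "Gcg": 2, "Sst": 250, "Ppy": 2, "Mki67": 0.1,
                   "S100z": 0.3, "Iqgap2": 0.5, "Acot12": 0.2, "Rnf180": 1.0,
                   "Ankrd55": 0.5},
        "Gamma":  {"Ins1": 5, "Gcg": 2, "Sst": 2, "Ppy": 200, "Mki67": 0.1,
                   "S100z": 0.3, "Iqgap2": 0.5, "Acot12": 0.2, "Rnf180": 1.0,
                   "Ankrd55": 0.5},
        "Beta1":  {"Ins1": 400, "Gcg": 5, "Sst": 5, "Ppy": 5, "Mki67": 0.1,
                   "S100z": 2.0, "Iqgap2": 1.5, "Acot12": 0.2, "Rnf180": 1.2,
                   "Ankrd55": 0.6},
        "Beta2":  {"Ins1": 380, "Gcg": 5, "Sst": 5, "Ppy": 5, "Mki67": 0.1,
                   "S100z": 2.5, "Iqgap2": 2.0, "Acot12": 0.2, "Rnf180": 1.2,
                   "Ankrd55": 0.6},
        "Beta3":  {"Ins1": 350, "Gcg": 5, "Sst": 5, "Ppy": 5, "Mki67": 0.1,
                   "S100z": 3.0, "Iqgap2": 2.0, "Acot12": 0.2, "Rnf180": 1.2,
                   "Ankrd55": 0.6},
        "Beta4":  {"Ins1": 300, "Gcg": 5, "Sst": 5, "Ppy": 5, "Mki67": 0.1,
                   "S100z": 2.0, "Iqgap2": 2.5, "Acot12": 0.2, "Rnf180": 1.2,
                   "Ankrd55": 0.6},
        "BetaP":  {"Ins1": 250, "Gcg": 5, "Sst": 5, "Ppy": 5, "Mki67": 5.0,
                   "S100z": 6.0, "Iqgap2": 5.0, "Acot12": 0.2, "Rnf180": 1.2,
                   "Ankrd55": 0.6},
    }
)


def make_single_cell(
    clusters=CANONICAL_CLUSTERS,
    means: pd.DataFrame | None = None,
    seed=0,
    cells_per_cluster: int = 150,
    dispersion: float = 0.5,
) -> CellMatrix:
    """Negative-binomial cell-by-gene counts with per-cluster means.

    ``means`` is a genes x clusters table of expected counts (the
    default plants the proliferation signature: Mki67, S100z and Iqgap2
    maximal in BetaP).  Counts use a gamma-Poisson with variance
    mu + dispersion * mu^2.
    """
    unknown = set(clusters) - set(CANONICAL_CLUSTERS)
    if unknown:
        raise ValueError(f"unknown cluster name(s): {sorted(unknown)}")
    if means is None:
        means = DEFAULT_SC_MEANS
    missing = set(clusters) - set(means.columns)
    if missing:
        raise ValueError(f"no means declared for clusters: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    size = 1.0 / dispersion
    rows, labels, barcodes = [], [], []
    genes = list(means.index)
    for cl in clusters:
        mu = means[cl].to_numpy(dtype=float)
        p = np.where(mu > 0, size / (size + mu), 1.0)
        counts = rng.negative_binomial(size, p, size=(cells_per_cluster, len(genes)))
        counts[:, mu == 0] = 0
        rows.append(counts)
        labels.extend([cl] * cells_per_cluster)
        barcodes.extend(f"{cl}-{i + 1:04d}" for i in range(cells_per_cluster))
    counts = pd.DataFrame(np.concatenate(rows, axis=0), index=barcodes, columns=genes)
    return CellMatrix(counts, pd.Series(labels, index=barcodes))


# ---------------------------------------------------------------------------
# the fig3 preset


@dataclass
class Fig3Fixture:
    """All pipeline inputs wired to reproduce the planted cascade counts."""

    interval: GenomicInterval
    genmap: GeneticMap
    catalog: SnpCatalog
    annotation: GeneAnnotation
    expression: dict            # contrast -> ExpressionMatrix
    sc: CellMatrix
    ct_tables: dict             # gene -> CtTable
    block_layout: list
    candidate_gene_ids: list    # 111 genes inside polymorphic blocks
    parental_de_genes: list     # 8
    congenic_de_genes: list     # 5 (the named candidates)
    obob_de_genes: list         # 4 (named minus Acot12)


_FIG3_BLOCKS = [
    BlockSpec(83_000_000, 87_000_000, 150),
    BlockSpec(93_000_000, 98_000_000, 150),
    BlockSpec(110_500_000, 115_500_000, 150),
]

_NAMED_PLACEMENT = {
    "Acot12": (83_500_000, 60_000),
    "S100z": (93_900_000, 12_000),
    "Ankrd55": (94_500_000, 120_000),
    "Rnf180": (96_200_000, 80_000),
    "Iqgap2": (111_200_000, 250_000),
}

# biotype totals for the 644-gene interval annotation
_BIOTYPE_COUNTS = {"coding": 208, "gene_model": 377, "miRNA": 8, "riken": 51}
_N_GENES = 644
_N_CANDIDATES = 111
_N_PARENTAL_DE = 8


def _place_genes(rng, span_lo, span_hi, count, min_len=2_000, max_len=80_000):
    """Uniform gene spans strictly inside [span_lo, span_hi) with margins."""
    lo, hi = span_lo + 10, span_hi - 10
    lens = rng.integers(min_len, max_len + 1, size=count)
    lens = np.minimum(lens, (hi - lo) - 1)
    starts = lo + (rng.random(count) * (hi - lo - lens)).astype(np.int64)
    return starts, starts + lens - 1


def _gene_id(biotype: str, i: int) -> str:
    if biotype == "coding":
        return f"Ccg13{i:03d}"
    if biotype == "gene_model":
        return f"Gm{40000 + i:05d}"
    if biotype == "miRNA":
        return f"Mir13{i:02d}"
    return f"{9530100 + i:07d}A13Rik"


def make_fig3_fixture(seed: int = 7) -> Fig3Fixture:
    """Build the preset embodying the 644 -> 111 -> 8 -> 5 cascade.

    The polymorphic block layout, the number of genes inside and outside
    blocks, and the planted expression effects are fixed; only jitter
    (exact positions, effect magnitudes, noise) depends on ``seed``, so
    the cascade counts hold for every seed.
    """
    interval = CRITICAL_INTERVAL
    catalog = make_snp_catalog(
        interval, _FIG3_BLOCKS, seed=(seed, 0), background_total_density=180
    )
    rng = np.random.default_rng((seed, 1))

    # --- candidate genes: 5 named + 106 filler, all strictly inside blocks
    cand_pos = {g: (s, s + ln - 1) for g, (s, ln) in _NAMED_PLACEMENT.items()}
    filler_per_block = {0: 26, 1: 40, 2: 40}  # sums to 106
    filler_ids = []
    for bi, nfill in filler_per_block.items():
        b = _FIG3_BLOCKS[bi]
        starts, ends = _place_genes(rng, b.start, b.end, nfill)
        for j, (s, e) in enumerate(zip(starts, ends)):
            gid = f"blk{bi}_{j}"  # placeholder, renamed after biotype draw
            filler_ids.append(gid)
            cand_pos[gid] = (int(s), int(e))

    # --- 533 background genes in the gaps between blocks
    gaps = []
    cursor = interval.start
    for b in _FIG3_BLOCKS:
        if b.start > cursor:
            gaps.append((cursor, b.start))
        cursor = b.end
    if cursor < interval.end:
        gaps.append((cursor, interval.end))
    gap_lens = np.array([hi - lo for lo, hi in gaps], dtype=float)
    n_bg_total = _N_GENES - _N_CANDIDATES
    n_bg = np.floor(n_bg_total * gap_lens / gap_lens.sum()).astype(int)
    n_bg[0] += n_bg_total - n_bg.sum()
    bg_pos = {}
    for (lo, hi), cnt in zip(gaps, n_bg):
        starts, ends = _place_genes(rng, lo, hi, int(cnt))
        for s, e in zip(starts, ends):
            bg_pos[f"gap{lo}_{len(bg_pos)}"] = (int(s), int(e))

    # --- parental DE set: the 5 named plus 3 filler candidates
    extra_de = [filler_ids[0], filler_ids[40], filler_ids[80]]
    parental_de = list(NAMED_CANDIDATES) + extra_de

    # --- biotype assignment: DE genes are coding; the rest shuffled
    all_ids = list(cand_pos) + list(bg_pos)
    pool = []
    counts = dict(_BIOTYPE_COUNTS)
    counts["coding"] -= _N_PARENTAL_DE
    for bt, c in counts.items():
        pool.extend([bt] * c)
    pool = list(rng.permutation(np.array(pool, dtype=object)))
    biotype_of = {}
    for gid in all_ids:
        if gid in parental_de:
            biotype_of[gid] = "coding"
        else:
            biotype_of[gid] = pool.pop()

    # --- final ids: named genes keep their symbols, others get biotype ids
    counter = iter(range(1, _N_GENES + 1))
    final_id = {}
    for gid in all_ids:
        if gid in NAMED_CANDIDATES:
            final_id[gid] = gid
        else:
            final_id[gid] = _gene_id(biotype_of[gid], next(counter))

    spans = {**cand_pos, **bg_pos}
    ordered = sorted(all_ids, key=lambda g: spans[g][0])
    annotation = GeneAnnotation(
        chromosome=interval.chromosome,
        gene_ids=[final_id[g] for g in ordered],
        start=np.array([spans[g][0] for g in ordered]),
        end=np.array([spans[g][1] for g in ordered]),
        biotype=np.array([biotype_of[g] for g in ordered], dtype=object),
    )
    candidate_ids = sorted(final_id[g] for g in cand_pos)
    parental_de_ids = sorted(final_id[g] for g in parental_de)
    congenic_de_ids = sorted(NAMED_CANDIDATES)
    obob_de_ids = sorted(g for g in NAMED_CANDIDATES if g != "Acot12")

    # --- expression fixtures with planted log2 effects
    def planted(gene_list, key):
        eff_rng = np.random.default_rng((seed, key))
        signs = eff_rng.choice([-1.0, 1.0], size=len(gene_list))
        mags = eff_rng.uniform(1.5, 3.0, size=len(gene_list))
        return {g: float(s * m) for g, s, m in zip(gene_list, signs, mags)}

    genes_tuple = tuple(annotation.gene_ids)
    expression = {}
    for key, (contrast, labels, de_ids) in enumerate(
        [
            ("parental", ("B6", "NZO"), parental_de_ids),
            ("congenic", ("BB", "NN"), congenic_de_ids),
            ("obob", ("B6ob", "NZO"), obob_de_ids),
        ]
    ):
        spec = ExpressionFixtureSpec(
            contrast=contrast,
            genes=genes_tuple,
            group_labels=labels,
            n_per_group=5,
            effects=planted(de_ids, 10 + key),
            sd=0.1,
            seed=(seed, 20 + key),
        )
        expression[contrast] = generate_expression(spec)

    sc = make_single_cell(seed=(seed, 30))

    # --- qPCR Ct fixtures for the named candidates (Actb reference)
    ct_rng = np.random.default_rng((seed, 40))
    ct_tables = {}
    for g in NAMED_CANDIDATES:
        samples = [f"islet_{i + 1}" for i in range(6)]
        ct_tables[g] = CtTable(
            pd.DataFrame(
                {
                    "sample": samples,
                    "target_ct": np.round(ct_rng.normal(26.0, 1.0, 6), 2),
                    "reference_ct": np.round(ct_rng.normal(19.0, 0.3, 6), 2),
                }
            )
        )

    return Fig3Fixture(
        interval=interval,
        genmap=default_chr13_map(),
        catalog=catalog,
        annotation=annotation,
        expression=expression,
        sc=sc,
        ct_tables=ct_tables,
        block_layout=list(_FIG3_BLOCKS),
        candidate_gene_ids=candidate_ids,
        parental_de_genes=parental_de_ids,
        congenic_de_genes=congenic_de_ids,
        obob_de_genes=obob_de_ids,
    )
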