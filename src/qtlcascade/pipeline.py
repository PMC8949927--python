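"""End-to-end orchestration: scan -> haplotype filter -> DE cascade -> sc.

A :class:`RunConfig` collects every input path and analysis parameter;
:func:`run_pipeline` executes the stages in order, writes one TSV per
stage plus a text summary, and removes partial outputs on failure.
Outputs are byte-identical for identical config and seeds.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field, fields

from . import haplomap, io, scprofile, synthdata
from .exprfilter import build_cascade, compute_lfc, de_filter, final_candidates
from .linkage import em_scan, permutation_threshold
from .regions import GenomicInterval
from .scprofile import PROLIFERATION_MARKER
from .synthdata import NAMED_CANDIDATES

log = logging.getLogger("qtlcascade")

CONTRASTS = ("parental", "congenic", "obob")


class StageError(RuntimeError):
    """Failure in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and parameters of one pipeline run."""

    map_path: str = ""
    genotypes_path: str = ""
    phenotypes_path: str = ""
    vcf_path: str = ""
    bed_path: str = ""
    expr_paths: dict = field(default_factory=dict)    # contrast -> values TSV
    groups_paths: dict = field(default_factory=dict)  # contrast -> groups TSV
    sc_dir: str = ""
    interval: GenomicInterval = GenomicInterval("chr13", 78_000_000, 120_400_000)
    window_bp: int = 250_000
    snp_threshold: int = 100
    lfc_threshold: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.01
    step_bp: int = 500_000
    trait: str = "glucose"
    seed: int = 0
    sc_genes: tuple = NAMED_CANDIDATES
    sc_marker: str = PROLIFERATION_MARKER
    run_scan: bool = True

    def __post_init__(self):
        for name in ("window_bp", "snp_threshold", "lfc_threshold", "step_bp"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        raw = io.read_config(path)
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        kw = {}
        simple_paths = {
            "map": "map_path",
            "genotypes": "genotypes_path",
            "phenotypes": "phenotypes_path",
            "vcf": "vcf_path",
            "bed": "bed_path",
            "sc_dir": "sc_dir",
        }
        expr_paths, groups_paths = {}, {}
        for key, val in raw.items():
            if key in simple_paths:
                kw[simple_paths[key]] = resolve(val)
            elif key.startswith("expr_"):
                expr_paths[key[5:]] = resolve(val)
            elif key.startswith("groups_"):
                groups_paths[key[7:]] = resolve(val)
            elif key == "interval":
                kw["interval"] = GenomicInterval.from_string(val)
            elif key == "sc_genes":
                kw["sc_genes"] = tuple(g.strip() for g in val.split(",") if g.strip())
            elif key in ("window_bp", "snp_threshold", "n_perm", "step_bp", "seed"):
                kw[key] = int(val)
            elif key in ("lfc_threshold", "alpha"):
                kw[key] = float(val)
            elif key == "run_scan":
                kw["run_scan"] = val.lower() in ("1", "true", "yes")
            elif key in ("trait", "sc_marker"):
                kw[key] = val
            else:
                raise ValueError(f"unknown config key {key!r}")
        kw["expr_paths"] = expr_paths
        kw["groups_paths"] = groups_paths
        valid = {f.name for f in fields(cls)}
        kw.update({k: v for k, v in overrides.items() if v is not None and k in valid})
        return cls(**kw)


def write_fixture_bundle(
    out_dir,
    seed: int = 7,
    n_individuals: int = 600,
    additive: float = 0.4,
    sigma: float = 1.0,
    n_perm: int = 200,
    cross_seed: int | None = None,
) -> str:
    """Materialise the fig3 preset plus a simulated cross as files.

    Writes every input the pipeline consumes (VCF, BED, GFF3, TSVs,
    MTX bundle) under ``out_dir`` together with a ``run.cfg`` manifest,
    and returns the manifest path.
    """
    os.makedirs(out_dir, exist_ok=True)
    fx = synthdata.make_fig3_fixture(seed=seed)
    gmap = fx.genmap
    spec = synthdata.CrossSpec(
        n=n_individuals,
        qtl_bp=synthdata.PEAK_MARKER_BP,
        additive=additive,
        sigma=sigma,
        traits=("glucose", "insulin", "body_weight"),
        seed=seed if cross_seed is None else cross_seed,
    )
    geno, pheno = synthdata.simulate_backcross(gmap, spec)

    def p(name):
        return os.path.join(out_dir, name)

    io.write_genetic_map(gmap, p("map.tsv"))
    io.write_genotypes(geno, p("genotypes.tsv"))
    io.write_phenotypes(pheno, p("phenotypes.tsv"))
    io.write_vcf(fx.catalog, p("snps.vcf"))
    io.write_bed(fx.annotation, p("genes.bed"))
    io.write_gff3(fx.annotation, p("genes.gff3"))
    for contrast, matrix in fx.expression.items():
        io.write_expression(
            matrix, p(f"expr_{contrast}.tsv"), p(f"groups_{contrast}.tsv")
        )
    io.write_single_cell(fx.sc, p("sc"))

    config = {
        "map": "map.tsv",
        "genotypes": "genotypes.tsv",
        "phenotypes": "phenotypes.tsv",
        "vcf": "snps.vcf",
        "bed": "genes.bed",
        "sc_dir": "sc",
        "interval": str(fx.interval),
        "window_bp": 250_000,
        "snp_threshold": 100,
        "lfc_threshold": 1.0,
        "n_perm": n_perm,
        "alpha": 0.01,
        "step_bp": 500_000,
        "trait": "glucose",
        "seed": seed,
        "sc_genes": ",".join(synthdata.NAMED_CANDIDATES),
        "sc_marker": PROLIFERATION_MARKER,
    }
    for contrast in fx.expression:
        config[f"expr_{contrast}"] = f"expr_{contrast}.tsv"
        config[f"groups_{contrast}"] = f"groups_{contrast}.tsv"
    io.write_config(config, p("run.cfg"))
    return p("run.cfg")


def _setup_logging():
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage; returns a dict of result objects and paths.

    Any stage failure raises :class:`StageError` after removing the
    partial outputs already written under ``out_dir``.
    """
    _setup_logging()
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def out(name):
        p = os.path.join(out_dir, name)
        written.append(p)
        return p

    results = {}
    stage = "load"
    try:
        log.info("[load] reading inputs (seed=%d)", config.seed)
        for p in [config.vcf_path, config.bed_path]:
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing input file: {p}")
        catalog = io.read_vcf(config.vcf_path)
        annotation = io.read_bed(config.bed_path)
        expr = {}
        for contrast in config.expr_paths:
            expr[contrast] = io.read_expression(
                config.expr_paths[contrast],
                config.groups_paths[contrast],
                contrast=contrast,
            )
        cells = io.read_single_cell(config.sc_dir) if config.sc_dir else None

        if config.run_scan:
            stage = "scan"
            log.info("[scan] trait=%s step=%d bp perms=%d alpha=%g seed=%d",
                     config.trait, config.step_bp, config.n_perm, config.alpha,
                     config.seed)
            gmap = io.read_genetic_map(config.map_path)
            geno = io.read_genotypes(config.genotypes_path, gmap)
            pheno = io.read_phenotypes(config.phenotypes_path).aligned_to(geno)
            y = pheno.trait(config.trait).to_numpy()
            curve = em_scan(geno, y, step_bp=config.step_bp, trait=config.trait)
            null = permutation_threshold(
                geno, y, n_perm=config.n_perm, alpha=config.alpha,
                seed=config.seed, step_bp=config.step_bp,
            )
            io.write_lod_curve(curve, out("lod.tsv"))
            results["lod_curve"] = curve
            results["permutation_null"] = null
            peak_bp, peak_lod = curve.peak()
            log.info("[scan] peak %.1f Mbp LOD %.2f (threshold %.2f)",
                     peak_bp / 1e6, peak_lod, null.threshold)

        stage = "haplomap"
        log.info("[haplomap] window=%d bp threshold=%d", config.window_bp,
                 config.snp_threshold)
        profiles = haplomap.window_counts(catalog, config.interval, config.window_bp)
        profiles, blocks = haplomap.call_polymorphic(profiles, config.snp_threshold)
        poly_genes = haplomap.filter_genes(annotation, profiles)
        haplomap.profiles_to_frame(profiles).to_csv(
            out("windows.tsv"), sep="\t", index=False
        )
        haplomap.blocks_to_frame(blocks).to_csv(
            out("blocks.tsv"), sep="\t", index=False
        )
        results["window_profiles"] = profiles
        results["blocks"] = blocks
        results["polymorphic_genes"] = poly_genes
        log.info("[haplomap] %d/%d genes in polymorphic windows",
                 len(poly_genes), annotation.n_genes)

        stage = "deg"
        interval_genes = set(annotation.gene_ids)
        de_sets = {}
        for contrast, matrix in expr.items():
            table = compute_lfc(matrix, threshold=config.lfc_threshold)
            passing = set(de_filter(table, config.lfc_threshold)) & interval_genes
            de_sets[contrast] = passing
            table.rename_axis("gene").to_csv(out(f"de_{contrast}.tsv"), sep="\t")
            log.info("[deg] %s: %d interval genes pass |LFC| > %g",
                     contrast, len(passing), config.lfc_threshold)
        for contrast in CONTRASTS[:2]:
            if contrast not in de_sets:
                raise ValueError(f"missing required contrast {contrast!r}")

        stage = "sc"
        sc_top = {}
        if cells is not None:
            genes = [g for g in (*config.sc_genes, config.sc_marker)
                     if g in cells.counts.columns]
            stats = scprofile.dotplot_stats(cells, genes)
            stats.to_csv(out("dotplot.tsv"), sep="\t", index=False)
            prolif = scprofile.label_proliferating(stats, config.sc_marker)
            sc_top = scprofile.top_cluster_per_gene(stats)
            sc_top.pop(config.sc_marker, None)
            results["dotplot"] = stats
            results["proliferating_cluster"] = prolif
            log.info("[sc] proliferating cluster: %s", prolif)

        stage = "prioritize"
        evidence = build_cascade(
            interval_genes=annotation.gene_ids,
            polymorphic_genes=poly_genes,
            de_parental=de_sets["parental"],
            de_congenic=de_sets["congenic"],
            de_obob=de_sets.get("obob", set()),
            sc_top_cluster=sc_top,
        )
        evidence.to_csv(out("evidence.tsv"), sep="\t")
        finals = final_candidates(evidence)
        results["evidence"] = evidence
        results["final_candidates"] = finals
        with open(out("summary.txt"), "w") as fh:
            fh.write(f"interval\t{config.interval}\n")
            fh.write(f"interval_mbp\t{config.interval.length_mbp:.1f}\n")
            fh.write(f"n_interval_genes\t{annotation.n_genes}\n")
            fh.write(f"n_polymorphic_genes\t{len(poly_genes)}\n")
            fh.write(f"n_de_parental\t{len(de_sets['parental'])}\n")
            fh.write(f"n_final_candidates\t{len(finals)}\n")
            if "lod_curve" in results:
                peak_bp, peak_lod = results["lod_curve"].peak()
                fh.write(f"scan_peak_bp\t{peak_bp}\n")
                fh.write(f"scan_peak_lod\t{peak_lod:.4f}\n")
                fh.write(
                    f"scan_threshold\t{results['permutation_null'].threshold:.4f}\n"
                )
            if "proliferating_cluster" in results:
                fh.write(f"proliferating_cluster\t{results['proliferating_cluster']}\n")
            fh.write("final_candidates\t" + ",".join(finals) + "\n")
        log.info("[prioritize] final candidates: %s", ", ".join(finals))
        return results
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.unlink(p)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
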