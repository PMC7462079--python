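"""Orchestration: simulate -> quantify -> differential -> co-occurrence ->
proximity -> splice-site deltas, from one config, with a combined report.

The config is a flat YAML mapping.  Thresholds default to the values the
analysis is defined with: alpha_edit 0.1, alpha_cooccur_q 0.1, min_cov 5,
min_samples 2, window_cooccur 50 nt, window_proximity 5000 nt.  All
randomness flows from one seed recorded in the manifest.

All TSV outputs are tab-delimited with a single commented header line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .genome_io import (load_gene_models, load_known_snps, read_regions_bed,
                        read_sites_bed, derive_splice_sites)
from .simdata import load_design, simulate_all, sample_names
from .editing_quant import (quantify_editing, editing_level_matrix, filter_sites,
                            remove_snps, call_differential)
from .cooccur import enumerate_pairs, run_cooccurrence
from .proximity import bin_sites, proximity_summary, gene_overlap_test
from .ssdelta import analyze_sites, TableScorer

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_all",
           "write_tsv", "read_tsv"]

STAGES = ("simulate", "diffedit", "cooccur", "proximity", "ssdelta", "report")

_THRESHOLD_DEFAULTS = {
    "alpha_edit": 0.1,
    "alpha_cooccur_q": 0.1,
    "min_cov": 5,
    "min_samples": 2,
    "window_cooccur": 50,
    "window_proximity": 5000,
}

_KNOWN_KEYS = {
    "design", "genome", "gtf", "bams_wt", "bams_ko", "sites", "snps", "regions",
    "out_dir", "seed", "mode", "orientation", "score_table_5ss", "score_table_3ss",
    *_THRESHOLD_DEFAULTS,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "edsplice_out"
    design: str | None = None  # simulate when set; else explicit inputs below
    genome: str | None = None
    gtf: str | None = None
    bams_wt: tuple[str, ...] = ()
    bams_ko: tuple[str, ...] = ()
    sites: str | None = None
    snps: str | None = None
    regions: str | None = None
    seed: int = 0
    mode: str = "absence_as_unedited"
    orientation: str = "stranded"
    score_table_5ss: str | None = None
    score_table_3ss: str | None = None
    alpha_edit: float = 0.1
    alpha_cooccur_q: float = 0.1
    min_cov: int = 5
    min_samples: int = 2
    window_cooccur: int = 50
    window_proximity: int = 5000


def validate_config(raw: Mapping | RunConfig) -> RunConfig:
    """Fill defaults, reject unknown keys and contradictions before compute."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for k in ("bams_wt", "bams_ko"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        cfg = RunConfig(**kwargs)
    for k, default in _THRESHOLD_DEFAULTS.items():
        v = getattr(cfg, k)
        if v is None:
            setattr(cfg, k, default)
        elif v <= 0:
            raise PipelineError(f"threshold {k} must be positive, got {v}")
    if cfg.mode not in ("strict", "absence_as_unedited"):
        raise PipelineError(f"unknown mode {cfg.mode!r}")
    if cfg.orientation not in ("stranded", "genomic"):
        raise PipelineError(f"unknown orientation {cfg.orientation!r}")
    if cfg.design is None:
        required = {"genome": cfg.genome, "gtf": cfg.gtf, "sites": cfg.sites}
        missing = [k for k, v in required.items() if v is None]
        if missing:
            raise PipelineError(
                f"config needs either 'design' or explicit inputs; missing {missing}"
            )
        if not cfg.bams_wt or not cfg.bams_ko:
            raise PipelineError("both bams_wt and bams_ko must be non-empty")
        if cfg.min_samples > min(len(cfg.bams_wt), len(cfg.bams_ko)):
            raise PipelineError(
                f"min_samples={cfg.min_samples} exceeds the replicate count"
            )
        for k in ("design", "genome", "gtf", "sites", "snps", "regions"):
            path = getattr(cfg, k)
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config {k}: file not found: {path}")
        for p in (*cfg.bams_wt, *cfg.bams_ko):
            if not Path(p).exists():
                raise PipelineError(f"BAM not found: {p}")
    else:
        if not Path(cfg.design).exists():
            raise PipelineError(f"design file not found: {cfg.design}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def write_tsv(df: pd.DataFrame, path) -> None:
    """Tab-delimited with a commented header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", names=header)


def _gene_of_site(models, chrom, pos, strand) -> str | None:
    for m in models:
        s, e = m.span
        if m.chrom == chrom and m.strand == strand and s <= pos < e:
            return m.transcript_id.rsplit(".", 1)[0]
    return None


def run_all(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the report bundle.

    Returns the manifest dict.  A stage failure aborts with the stage name;
    outputs of completed stages are retained.
    """
    cfg = validate_config(config)
    stages = tuple(stages) if stages else STAGES
    bad = set(stages) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stages: {sorted(bad)}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("edsplice")
    root.addHandler(fh)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "edsplice_version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "thresholds": {k: getattr(cfg, k) for k in _THRESHOLD_DEFAULTS},
        "mode": cfg.mode,
        "stages": list(stages),
        "counts": {},
    }

    current = "setup"
    try:
        if cfg.design is not None and "simulate" in stages:
            current = "simulate"
            design = load_design(cfg.design)
            design = dataclasses.replace(design, seed=cfg.seed)
            sim_dir = out / "sim"
            layout, truth = simulate_all(design, sim_dir)
            groups_all = sample_names(design)
            cfg = replace(
                cfg,
                genome=str(sim_dir / "genome.fa"),
                gtf=str(sim_dir / "models.gtf"),
                sites=str(sim_dir / "sites.bed"),
                snps=str(sim_dir / "snps.vcf"),
                regions=str(sim_dir / "regions.bed"),
                bams_wt=tuple(str(sim_dir / f"{s}.bam")
                              for s, g in groups_all.items() if g == "WT"),
                bams_ko=tuple(str(sim_dir / f"{s}.bam")
                              for s, g in groups_all.items() if g == "KO"),
            )
            manifest["counts"]["simulated_sites"] = len(layout.sites)
            manifest["counts"]["simulated_truth_rows"] = len(truth)
            logger.info("simulate: %d genes, %d sites", len(layout.genes),
                        len(layout.sites))

        bams = {f"WT{i + 1}": p for i, p in enumerate(cfg.bams_wt)}
        bams.update({f"KO{i + 1}": p for i, p in enumerate(cfg.bams_ko)})
        groups = {
            "WT": [s for s in bams if s.startswith("WT")],
            "KO": [s for s in bams if s.startswith("KO")],
        }
        genotypes = {s: ("WT" if s.startswith("WT") else "KO") for s in bams}
        models = load_gene_models(cfg.gtf)
        sites = read_sites_bed(cfg.sites)

        diff = None
        if "diffedit" in stages:
            current = "diffedit"
            counts = quantify_editing(bams, sites, genome=cfg.genome)
            n_in = counts["name"].nunique()
            if cfg.snps:
                snpset = load_known_snps(cfg.snps)
                counts_nosnp = remove_snps(counts, snpset)
            else:
                counts_nosnp = counts
            n_after_snp = counts_nosnp["name"].nunique()
            filtered = filter_sites(counts_nosnp, groups, cfg.min_cov,
                                    cfg.min_samples)
            n_tested = filtered["name"].nunique()
            funnel = {
                "sites_in": int(n_in),
                "sites_removed_snp": int(n_in - n_after_snp),
                "sites_removed_cov": int(n_after_snp - n_tested),
                "sites_tested": int(n_tested),
            }
            assert funnel["sites_in"] == (
                funnel["sites_removed_snp"] + funnel["sites_removed_cov"]
                + funnel["sites_tested"]
            )
            manifest["counts"].update(funnel)
            logger.info("diffedit funnel: %s", funnel)
            levels = editing_level_matrix(filtered).reset_index()
            write_tsv(levels, out / "editing_levels.tsv")
            diff = call_differential(filtered, groups, cfg.alpha_edit)
            write_tsv(diff, out / "differential_editing.tsv")
            manifest["counts"]["differential_sites"] = int(
                (diff["cls"].isin(["increase", "decrease"])).sum()
            ) if len(diff) else 0

        cooc = None
        if "cooccur" in stages:
            current = "cooccur"
            splice_sites = [ss for m in models for ss in derive_splice_sites(m)]
            pairs = enumerate_pairs(splice_sites, sites, cfg.window_cooccur)
            cooc = run_cooccurrence(
                bams, pairs, genotypes, alpha=cfg.alpha_cooccur_q, mode=cfg.mode,
                models=models,
            )
            write_tsv(cooc, out / "cooccurrence.tsv")
            manifest["counts"]["cooccurrence_pairs"] = len(cooc)
            manifest["counts"]["cooccurrence_significant"] = int(
                cooc["significant"].sum()
            ) if len(cooc) else 0

        prox_df = None
        if "proximity" in stages and cfg.regions:
            current = "proximity"
            regions = read_regions_bed(cfg.regions)
            if diff is None and (out / "differential_editing.tsv").exists():
                diff = read_tsv(out / "differential_editing.tsv")
            diff_sites = []
            if diff is not None and len(diff):
                from .genome_io import SiteDef
                for _, r in diff[diff["cls"].isin(["increase", "decrease"])].iterrows():
                    diff_sites.append(SiteDef(r["chrom"], int(r["pos"]),
                                              r["strand"], r["name"]))
            calls = bin_sites(diff_sites, regions, cfg.window_proximity,
                              cfg.orientation)
            prox_df = pd.DataFrame(
                [
                    {
                        "site_name": c.site.name, "pos": c.site.pos,
                        "region": c.region.name if c.region else "",
                        "bin": c.bin, "distance": c.distance,
                    }
                    for c in calls
                ],
                columns=["site_name", "pos", "region", "bin", "distance"],
            )
            write_tsv(prox_df, out / "proximity.tsv")
            write_tsv(proximity_summary(calls), out / "proximity_summary.tsv")

            background = sorted({m.transcript_id.rsplit(".", 1)[0] for m in models})
            list_a = sorted(
                {
                    g for g in (
                        _gene_of_site(models, s.chrom, s.pos, s.strand)
                        for s in diff_sites
                    )
                    if g is not None
                }
            )
            list_b = sorted({r.name for r in regions} & set(background))
            if background:
                res = gene_overlap_test(list_a, list_b, background)
                write_tsv(
                    pd.DataFrame(
                        [
                            {
                                "n_diff_edited_genes": res.n_a,
                                "n_diff_spliced_genes": res.n_b,
                                "n_background": res.n_background,
                                "overlap": res.k,
                                "expected": res.expected,
                                "p_hypergeometric": res.p,
                                "odds_ratio": res.odds_ratio,
                            }
                        ]
                    ),
                    out / "gene_overlap.tsv",
                )

        ssd = None
        if "ssdelta" in stages:
            current = "ssdelta"
            donor_scorer = (
                TableScorer.from_tsv(cfg.score_table_5ss, "donor")
                if cfg.score_table_5ss else None
            )
            acceptor_scorer = (
                TableScorer.from_tsv(cfg.score_table_3ss, "acceptor")
                if cfg.score_table_3ss else None
            )
            ssd = analyze_sites(cfg.genome, models, sites, donor_scorer,
                                acceptor_scorer)
            write_tsv(ssd, out / "ss_delta.tsv")
            manifest["counts"]["ssdelta_windows"] = len(ssd)

        if "report" in stages:
            current = "report"
            if diff is None and (out / "differential_editing.tsv").exists():
                diff = read_tsv(out / "differential_editing.tsv")
            if diff is not None and len(diff):
                report = diff[["name", "chrom", "pos", "strand", "delta", "p",
                               "cls"]].copy()
                if prox_df is not None and len(prox_df):
                    report = report.merge(
                        prox_df[["site_name", "bin", "distance"]],
                        left_on="name", right_on="site_name", how="left",
                    ).drop(columns="site_name")
                else:
                    report["bin"] = ""
                    report["distance"] = ""
                if cooc is not None and len(cooc):
                    sig = cooc.groupby("site_name")["significant"].any()
                    report["cooccur_significant"] = (
                        report["name"].map(sig).fillna(False)
                    )
                else:
                    report["cooccur_significant"] = False
                if ssd is not None and len(ssd):
                    eff = ssd.groupby("site_name")["effect_class"].first()
                    report["ss_effect"] = report["name"].map(eff).fillna("")
                else:
                    report["ss_effect"] = ""
                write_tsv(report, out / "report.tsv")
            with open(out / "manifest.json", "w") as jh:
                json.dump(manifest, jh, indent=2, sort_keys=True)
                jh.write("\n")
    except Exception as exc:
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc
    finally:
        root.removeHandler(fh)
        fh.close()
    return manifest
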