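"""End-to-end orchestration: harmonize -> inflation-adjust -> fit -> score ->
loci -> combine -> annotate, per conditioning dataset, with a machine-readable
run report.

The run is deterministic: identical config + inputs (+ seed, when LD-pruning
averaging is enabled) produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import io as sio
from .annotation import aggregate_locus_genes, positional_map, read_gene_models
from .core import ConditionalFdr, InflationAdjuster
from .errors import ConfigError
from .loci import (PairwiseLd, clump, combine_across_conditionings, flag_novel,
                   ld_proxies, loci_to_frame, merge_loci, select_significant,
                   write_loci_bed, write_loci_tsv)
from .regions import read_bed_regions

logger = logging.getLogger(__name__)

#: default column schema for trait summary-statistics files
DEFAULT_SCHEMA = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "ref_allele": "A1", "effect_allele": "A2",
    "z": "Z", "p": "P", "func": "FUNC", "n_studies": "N_STUDIES",
}


@dataclass
class RunConfig:
    """Configuration of one full condFDR discovery run.

    One primary trait is conditioned on >= 1 conditioning datasets; each
    dataset is analyzed independently and the resulting loci are combined
    (lowest condFDR wins, provenance kept).
    """

    primary: str = ""
    conditioning: dict = field(default_factory=dict)  # name -> path
    schema: dict = field(default_factory=lambda: dict(DEFAULT_SCHEMA))
    ld: str | None = None
    genes: str | None = None
    known_loci: str | None = None
    unstable_regions: str | None = None   # BED
    exclude_regions: str | None = None    # BED; None -> HLA + 8p23.1 defaults
    min_studies: int | None = None
    genome_build: str = "GRCh37"
    condfdr_threshold: float = 0.01
    r2_clump: float = 0.1
    window_kb: float = 10_000
    merge_kb: float = 250
    r2_proxy: float = 0.8
    map_window_kb: float = 10
    lambda_mode: str = "intergenic"
    mode: str = "lookup"
    seed: int = 0
    out_dir: str = "condfdr_out"

    def validate(self) -> None:
        if not self.primary:
            raise ConfigError("a primary summary-statistics file is required")
        if not self.conditioning:
            raise ConfigError("at least one conditioning dataset is required")
        if not (0 < self.condfdr_threshold <= 1):
            raise ConfigError("condfdr_threshold must lie in (0, 1]")
        for name, val in [("r2_clump", self.r2_clump), ("r2_proxy", self.r2_proxy)]:
            if not (0 <= val <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.window_kb <= 0 or self.merge_kb < 0:
            raise ConfigError("window_kb must be positive, merge_kb non-negative")
        if self.mode not in ("lookup", "exact"):
            raise ConfigError("mode must be 'lookup' or 'exact'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if raw.get("schema"):
            cfg.schema = {**DEFAULT_SCHEMA, **raw["schema"]}
        return cfg


def harmonize(primary_path, conditioning_path, schema=None,
              unstable_regions=None, min_studies=None, ref=None):
    """Read, QC, align and intersect one trait pair.

    Returns (pair, stage_counts). ``ref`` is an optional reference-allele
    map; when omitted the inputs are assumed already oriented to one
    reference.
    """
    schema = schema or DEFAULT_SCHEMA
    counts = {}
    frames = {}
    for label, path in (("primary", primary_path), ("conditioning", conditioning_path)):
        df, rep_read = sio.read_sumstats(path, schema)
        df, rep_qc = sio.qc_filter(df, unstable_regions=unstable_regions,
                                   min_studies=min_studies)
        stage = {"read": rep_read.to_dict(), "qc": rep_qc.to_dict()}
        if ref is not None:
            df, rep_al = sio.align_to_reference(df, ref)
            stage["align"] = rep_al.to_dict()
        frames[label] = df
        counts[label] = stage
    pair = sio.intersect_pair(frames["primary"], frames["conditioning"])
    counts["n_shared"] = len(pair)
    return pair, counts


def score_pair(pair, mode="lookup", lambda_mode="intergenic",
               exclude_regions="default", random_state=None):
    """Inflation-adjust the primary trait and assign per-SNP condFDR.

    Returns (scored pair with CONDFDR/P1_ADJ/Z1_ADJ columns, fitted
    ConditionalFdr estimator, InflationReport).
    """
    adj = InflationAdjuster(mode=lambda_mode).fit(pair)
    inflation = adj.report(pair)
    adjusted = adj.transform(pair)

    est = ConditionalFdr(mode=mode, exclude_regions=exclude_regions,
                         random_state=random_state).fit(adjusted)
    scored = est.transform(adjusted)
    scored["Z1_ADJ"] = scored.pop("Z1")
    scored["P1_ADJ"] = scored.pop("P1")
    scored["Z1"] = pair["Z1"].to_numpy()
    scored["P1"] = pair["P1"].to_numpy()
    cols = sio.PAIR_COLUMNS + ["Z1_ADJ", "P1_ADJ", "CONDFDR"]
    return scored[cols], est, inflation


def _loci_for_dataset(scored, ld, cfg: RunConfig):
    sig = select_significant(
        scored.rename(columns={"P1_ADJ": "P1", "P1": "P1_RAW"}),
        threshold=cfg.condfdr_threshold)
    clumps = clump(sig, ld, r2_max=cfg.r2_clump, window_kb=cfg.window_kb)
    return merge_loci(clumps, merge_kb=cfg.merge_kb), len(sig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full discovery run described by ``config``; returns the
    run report (also written to ``<out_dir>/report.json``)."""
    cfg = config
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)

    unstable = read_bed_regions(cfg.unstable_regions) if cfg.unstable_regions else None
    exclude = read_bed_regions(cfg.exclude_regions) if cfg.exclude_regions else "default"
    ld = PairwiseLd.from_tsv(cfg.ld) if cfg.ld else PairwiseLd(
        pd.DataFrame(columns=["SNP_A", "SNP_B", "R2"]))
    known = pd.read_csv(cfg.known_loci, sep="\t", dtype={"CHR": str}) \
        if cfg.known_loci else None

    report = {"params": asdict(cfg), "datasets": {}}
    locus_sets = {}
    snp_pos: dict = {}
    for name, path in sorted(cfg.conditioning.items()):
        pair, counts = harmonize(cfg.primary, path, schema=cfg.schema,
                                 unstable_regions=unstable,
                                 min_studies=cfg.min_studies)
        scored, est, inflation = score_pair(
            pair, mode=cfg.mode, lambda_mode=cfg.lambda_mode,
            exclude_regions=exclude, random_state=cfg.seed)
        scored.to_csv(os.path.join(cfg.out_dir, f"scored_{name}.tsv"),
                      sep="\t", index=False)
        snp_pos.update(zip(pair["SNP"].astype(str),
                           zip(pair["CHR"].astype(str), pair["BP"])))
        loci, n_sig = _loci_for_dataset(scored, ld, cfg)
        for loc in loci:
            loc.datasets = [name]
        locus_sets[name] = loci
        report["datasets"][name] = {
            "harmonization": counts,
            "lambda": inflation.to_dict(),
            "n_masked_from_fit": int(est.mask_.sum()),
            "n_significant": n_sig,
            "n_loci": len(loci),
        }
        logger.info("[%s] shared=%d lambda=%.4f significant=%d loci=%d",
                    name, counts["n_shared"], inflation.lambda_raw, n_sig, len(loci))

    combined = combine_across_conditionings(locus_sets, merge_kb=cfg.merge_kb)
    combined = flag_novel(combined, known, within_kb=cfg.merge_kb)

    proxies = []
    for loc in combined:
        for snp in sorted(ld_proxies(loc.lead_snp, ld, r2_min=cfg.r2_proxy)):
            ch, bp = snp_pos.get(snp, (loc.chrom, loc.start))
            proxies.append({"LEAD": loc.lead_snp, "SNP": snp, "CHR": ch, "BP": bp})
    proxy_df = pd.DataFrame(proxies, columns=["LEAD", "SNP", "CHR", "BP"])

    if cfg.genes:
        genes = read_gene_models(cfg.genes)
        assignments = positional_map(proxy_df, genes, window_kb=cfg.map_window_kb)
        assignments.to_csv(os.path.join(cfg.out_dir, "gene_assignments.tsv"),
                           sep="\t", index=False)
        gene_lists = aggregate_locus_genes(assignments, combined)
        report["genes_per_locus"] = {
            lead: [g for g, _ in pairs] for lead, pairs in gene_lists.items()}

    write_loci_tsv(combined, os.path.join(cfg.out_dir, "loci.tsv"))
    write_loci_bed(combined, os.path.join(cfg.out_dir, "loci.bed"))
    proxy_df.to_csv(os.path.join(cfg.out_dir, "proxies.tsv"), sep="\t", index=False)

    report["combined"] = {
        "n_loci": len(combined),
        "n_novel": sum(1 for l in combined if l.novel),
        "loci": loci_to_frame(combined).to_dict(orient="records"),
    }
    report["seed"] = cfg.seed
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
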