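"""Positional mapping of lead SNPs and their LD proxies to protein-coding
genes.

Candidates inside the extended HLA region are never mapped (its gene density
and LD make positional assignments uninformative); everything else maps to
the protein-coding genes containing it, plus genes within a configurable
flanking window (default 10 kb). Gene models are read from BED (0-based,
half-open) or a minimal GFF3 subset; internal coordinates are 1-based,
both endpoints inclusive.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError
from .regions import HLA_REGION, in_regions

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene", "chrom", "start", "end", "biotype"]


def read_gene_models(path, fmt=None) -> pd.DataFrame:
    """Read gene models into a frame with columns gene/chrom/start/end/biotype.

    ``fmt`` is "bed", "gff3" or None (inferred from the extension). BED rows
    use columns chrom/start/end/name and are assumed protein-coding unless a
    5th column gives the biotype. The GFF3 reader keeps only ``gene``
    features and pulls the symbol from Name=/gene_name= and the biotype from
    biotype=/gene_biotype= attributes.
    """
    path = str(path)
    if fmt is None:
        low = path.lower().removesuffix(".gz")
        fmt = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=range(6), dtype={0: str})
        df = df.dropna(axis=1, how="all")
        if df.shape[1] < 4:
            raise ConfigError("gene BED needs at least 4 columns (chrom,start,end,name)")
        out = pd.DataFrame({
            "gene": df[3].astype(str),
            "chrom": df[0].astype(str).str.removeprefix("chr"),
            "start": df[1].astype(np.int64) + 1,  # BED -> 1-based inclusive
            "end": df[2].astype(np.int64),
            "biotype": df[4].astype(str) if df.shape[1] > 4 else "protein_coding",
        })
    elif fmt == "gff3":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attributes"],
                          dtype={"seqid": str})
        raw = raw[raw["type"] == "gene"]

        def attr(s, *keys):
            kv = dict(part.strip().partition("=")[::2]
                      for part in str(s).split(";") if "=" in part)
            for k in keys:  # keys in priority order
                if k in kv:
                    return kv[k]
            return ""

        out = pd.DataFrame({
            "gene": raw["attributes"].map(lambda s: attr(s, "Name", "gene_name", "ID")),
            "chrom": raw["seqid"].str.removeprefix("chr"),
            "start": raw["start"].astype(np.int64),
            "end": raw["end"].astype(np.int64),
            "biotype": raw["attributes"].map(
                lambda s: attr(s, "biotype", "gene_biotype") or "protein_coding"),
        })
    else:
        raise ConfigError(f"unknown gene-model format {fmt!r}")
    if (out["start"] > out["end"]).any():
        raise ConfigError("gene model with start > end")
    return out.reset_index(drop=True)


def positional_map(candidates: pd.DataFrame, genes: pd.DataFrame,
                   window_kb: float = 10, hla_region=HLA_REGION) -> pd.DataFrame:
    """Map candidate SNPs (leads + proxies) to protein-coding genes.

    ``candidates`` needs columns LEAD, SNP, CHR, BP. For each SNP outside the
    extended HLA region, emits one row per gene whose body contains it
    (relation "containing", distance 0) or lies within ``window_kb``
    (relation "within-window", distance in bp). Containing genes are reported
    regardless of the window size. Candidates in the HLA region yield no
    assignments (their count is logged).

    Returns a frame with columns LOCUS_LEAD, SNP, GENE, RELATION, DISTANCE_BP.
    """
    if genes is None or len(genes) == 0:
        raise ConfigError("empty gene set")
    pc = genes[genes["biotype"] == "protein_coding"]

    in_hla = in_regions(candidates["CHR"], candidates["BP"], [hla_region])
    if in_hla.any():
        logger.info("positional_map: %d candidate(s) in the extended HLA region skipped",
                    int(in_hla.sum()))
    cand = candidates[~in_hla]

    wbp = int(window_kb * 1000)
    rows = []
    gch = pc["chrom"].astype(str).to_numpy()
    gs = pc["start"].to_numpy(np.int64)
    ge = pc["end"].to_numpy(np.int64)
    gname = pc["gene"].to_numpy()
    for lead, snp, chrom, bp in zip(cand["LEAD"], cand["SNP"],
                                    cand["CHR"].astype(str), cand["BP"]):
        bp = int(bp)
        same = gch == chrom
        dist = np.maximum(gs - bp, bp - ge)  # <= 0 means containing
        hit = same & (dist <= wbp)
        for gi in np.where(hit)[0]:
            d = int(max(dist[gi], 0))
            rows.append((str(lead), str(snp), str(gname[gi]),
                         "containing" if d == 0 else "within-window", d))
    return pd.DataFrame(rows, columns=["LOCUS_LEAD", "SNP", "GENE",
                                       "RELATION", "DISTANCE_BP"])


def aggregate_locus_genes(assignments: pd.DataFrame, loci) -> dict:
    """Per-locus gene list: union over the locus's lead and proxies,
    deduplicated, containing genes first then by increasing distance.

    ``loci`` is a list of Locus objects (or lead SNP ids); returns a mapping
    lead -> list of (gene, relation) pairs. Loci with no mapped gene map to
    an empty list (the locus is still reported).
    """
    leads = [getattr(l, "lead_snp", l) for l in loci]
    out = {str(lead): [] for lead in leads}
    if len(assignments) == 0:
        return out
    for lead, sub in assignments.groupby("LOCUS_LEAD"):
        if str(lead) not in out:
            continue
        best = (sub.sort_values(["DISTANCE_BP", "GENE"], kind="mergesort")
                   .drop_duplicates("GENE", keep="first"))
        best = best.sort_values(["DISTANCE_BP", "GENE"], kind="mergesort")
        out[str(lead)] = list(zip(best["GENE"], best["RELATION"]))
    return out
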