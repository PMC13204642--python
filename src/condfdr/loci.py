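"""Turning per-SNP condFDR scores into independent risk loci.

Pipeline: strict thresholding (condFDR < 0.01 by convention) -> greedy LD
clumping (absorb r2 >= 0.1 within +/-10,000 kb of each lead) -> merging of
loci whose spans lie within 250 kb -> optional combination across
conditioning datasets (lowest condFDR wins, provenance kept) -> LD-proxy
expansion (r2 > 0.8) and novelty flagging against a known-loci table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LD sources
# ---------------------------------------------------------------------------

class LdSource:
    """Provider of pairwise r2 within a declared window.

    Pairs beyond the window, or simply unknown to the source, report 0
    (quasi-independence is the conservative assumption for clumping).
    """

    window_kb: float | None = None

    def r2(self, a: str, b: str) -> float:
        raise NotImplementedError

    def partners(self, a: str):
        """Iterate (snp_id, r2) pairs known for SNP ``a`` (excluding itself)."""
        raise NotImplementedError


class PairwiseLd(LdSource):
    """Long-format pairwise r2 table (columns SNP_A, SNP_B, R2)."""

    def __init__(self, table: pd.DataFrame, window_kb: float | None = None):
        bad = table[(table["R2"] < 0) | (table["R2"] > 1)]
        if len(bad):
            raise ConfigError("r2 values must lie in [0, 1]")
        self.window_kb = window_kb
        self._map: dict = {}
        for a, b, r in zip(table["SNP_A"], table["SNP_B"], table["R2"]):
            self._map.setdefault(str(a), {})[str(b)] = float(r)
            self._map.setdefault(str(b), {})[str(a)] = float(r)
        self.n_missing_lookups = 0

    @classmethod
    def from_tsv(cls, path, **kw) -> "PairwiseLd":
        return cls(pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str}), **kw)

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        val = self._map.get(str(a), {}).get(str(b))
        if val is None:
            self.n_missing_lookups += 1
            return 0.0
        return val

    def partners(self, a):
        return self._map.get(str(a), {}).items()


class BlockLd(LdSource):
    """Per-block dense r2 matrices with a SNP index (block-diagonal LD)."""

    def __init__(self, blocks, window_kb: float | None = None):
        """``blocks``: iterable of (snp_ids, r2_matrix)."""
        self.window_kb = window_kb
        self._blocks = []
        self._index: dict = {}
        for snps, mat in blocks:
            mat = np.asarray(mat, float)
            if mat.shape != (len(snps), len(snps)):
                raise ConfigError("block matrix shape does not match SNP list")
            bi = len(self._blocks)
            self._blocks.append((list(map(str, snps)), mat))
            for j, s in enumerate(snps):
                self._index[str(s)] = (bi, j)

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        ia, ib = self._index.get(str(a)), self._index.get(str(b))
        if ia is None or ib is None or ia[0] != ib[0]:
            return 0.0
        return float(self._blocks[ia[0]][1][ia[1], ib[1]])

    def partners(self, a):
        loc = self._index.get(str(a))
        if loc is None:
            return
        snps, mat = self._blocks[loc[0]]
        for j, s in enumerate(snps):
            if j != loc[1]:
                yield s, float(mat[loc[1], j])

    def to_pairwise_frame(self, min_r2: float = 0.0) -> pd.DataFrame:
        rows = []
        for snps, mat in self._blocks:
            for i in range(len(snps)):
                for j in range(i + 1, len(snps)):
                    if mat[i, j] >= min_r2:
                        rows.append((snps[i], snps[j], mat[i, j]))
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


# ---------------------------------------------------------------------------
# loci
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """An independent risk locus: lead SNP plus absorbed members."""

    lead_snp: str
    chrom: str
    start: int
    end: int
    lead_condfdr: float
    lead_p: float
    members: list = field(default_factory=list)
    datasets: list = field(default_factory=list)
    novel: bool | None = None

    @property
    def span(self):
        return self.start, self.end

    def to_dict(self) -> dict:
        return {
            "LEAD": self.lead_snp, "CHR": self.chrom, "START": self.start,
            "END": self.end, "CONDFDR": self.lead_condfdr, "P": self.lead_p,
            "N_MEMBERS": len(self.members),
            "DATASETS": ",".join(self.datasets),
            "NOVEL": "" if self.novel is None else str(self.novel),
        }


def select_significant(scored: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """SNPs with condFDR strictly below the threshold, ascending condFDR."""
    sig = scored[scored["CONDFDR"] < threshold]
    return sig.sort_values(
        ["CONDFDR", "P1", "CHR", "BP"], kind="mergesort").reset_index(drop=True)


def clump(snps: pd.DataFrame, ld: LdSource, r2_max: float = 0.1,
          window_kb: float = 10_000) -> list[Locus]:
    """Greedy LD clumping of significant SNPs into quasi-independent leads.

    Repeatedly promotes the unassigned SNP with the smallest condFDR (ties
    broken by p, chromosome, position) to lead and absorbs unassigned SNPs
    on the same chromosome within +/- ``window_kb`` whose r2 with the lead
    is >= ``r2_max``. Every SNP ends up a lead or absorbed exactly once.
    Unknown LD lookups count as r2 = 0.
    """
    df = snps.sort_values(["CONDFDR", "P1", "CHR", "BP"],
                          kind="mergesort").reset_index(drop=True)
    n = len(df)
    assigned = np.zeros(n, dtype=bool)
    snp_id = df["SNP"].astype(str).to_numpy()
    chrom = df["CHR"].astype(str).to_numpy()
    bp = df["BP"].to_numpy(np.int64)
    window_bp = int(window_kb * 1000)

    loci = []
    for i in range(n):
        if assigned[i]:
            continue
        assigned[i] = True
        members = [snp_id[i]]
        positions = [bp[i]]
        candidates = np.where(
            ~assigned & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window_bp))[0]
        for j in candidates:
            if ld.r2(snp_id[i], snp_id[j]) >= r2_max:
                assigned[j] = True
                members.append(snp_id[j])
                positions.append(bp[j])
        loci.append(Locus(
            lead_snp=snp_id[i], chrom=chrom[i],
            start=int(min(positions)), end=int(max(positions)),
            lead_condfdr=float(df["CONDFDR"].iat[i]),
            lead_p=float(df["P1"].iat[i]), members=members))
    return loci


def _span_distance(a: Locus, b: Locus) -> float:
    if a.chrom != b.chrom:
        return np.inf
    if a.start > b.end:
        return a.start - b.end
    if b.start > a.end:
        return b.start - a.end
    return 0


def merge_loci(loci: list[Locus], merge_kb: float = 250) -> list[Locus]:
    """Transitively merge loci whose spans lie within ``merge_kb`` (closest
    edges, same chromosome). The merged lead is the member lead with the
    smallest condFDR. Idempotent."""
    merge_bp = merge_kb * 1000
    loci = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.lead_snp))
    out: list[Locus] = []
    for loc in loci:
        if out and _span_distance(out[-1], loc) <= merge_bp:
            cur = out[-1]
            best, other = ((loc, cur) if
                           (loc.lead_condfdr, loc.lead_p) < (cur.lead_condfdr, cur.lead_p)
                           else (cur, loc))
            out[-1] = Locus(
                lead_snp=best.lead_snp, chrom=cur.chrom,
                start=min(cur.start, loc.start), end=max(cur.end, loc.end),
                lead_condfdr=best.lead_condfdr, lead_p=best.lead_p,
                members=cur.members + loc.members,
                datasets=sorted(set(cur.datasets) | set(loc.datasets)),
                novel=best.novel)
        else:
            out.append(replace(loc, members=list(loc.members),
                               datasets=list(loc.datasets)))
    return out


def combine_across_conditionings(locus_sets: dict, merge_kb: float = 250) -> list[Locus]:
    """Unify loci found for one primary trait under different conditioning
    datasets.

    Loci whose spans intersect or lie within ``merge_kb`` are treated as one;
    the reported lead and condFDR come from the dataset achieving the lowest
    condFDR, and provenance lists every contributing dataset. Associative
    and order-independent across datasets.
    """
    pooled = []
    for name in sorted(locus_sets):
        for loc in locus_sets[name]:
            ds = sorted(set(loc.datasets) | {name}) if loc.datasets else [name]
            pooled.append(replace(loc, members=list(loc.members), datasets=ds))
    return merge_loci(pooled, merge_kb=merge_kb)


def ld_proxies(lead: str, ld: LdSource, r2_min: float = 0.8) -> set:
    """The lead plus all SNPs in high LD with it (r2 strictly > ``r2_min``)."""
    out = {str(lead)}
    for snp, r2 in ld.partners(lead):
        if r2 > r2_min:
            out.add(str(snp))
    return out


def flag_novel(loci: list[Locus], known: pd.DataFrame | None,
               within_kb: float = 250) -> list[Locus]:
    """Flag loci with no known locus within ``within_kb`` of their span as
    novel. ``known`` needs columns CHR and BP (or CHR/START/END); when None,
    flags are left unset. This positional rule is a proxy for the
    literature-based novelty assessment a study would perform."""
    if known is None:
        return [replace(l) for l in loci]
    if "START" in known.columns and "END" in known.columns:
        kch = known["CHR"].astype(str).to_numpy()
        ks = known["START"].to_numpy(np.int64)
        ke = known["END"].to_numpy(np.int64)
    else:
        kch = known["CHR"].astype(str).to_numpy()
        ks = ke = known["BP"].to_numpy(np.int64)
    wbp = within_kb * 1000
    out = []
    for loc in loci:
        same = kch == loc.chrom
        gap = np.maximum(ks - loc.end, loc.start - ke)
        near = same & (gap <= wbp)
        out.append(replace(loc, novel=not bool(near.any())))
    return out


class LdClumper(BaseEstimator):
    """Greedy LD clumping and span merging as a fit-style estimator.

    Parameters mirror :func:`clump` and :func:`merge_loci`. After ``fit`` on
    a significant-SNP table, ``loci_`` holds the merged loci and ``labels_``
    maps each input SNP to the index of its locus.
    """

    def __init__(self, ld: LdSource = None, r2_max: float = 0.1,
                 window_kb: float = 10_000, merge_kb: float = 250):
        self.ld = ld
        self.r2_max = r2_max
        self.window_kb = window_kb
        self.merge_kb = merge_kb

    def fit(self, X, y=None):
        if self.ld is None:
            raise ConfigError("LdClumper requires an LD source")
        clumps = clump(X, self.ld, r2_max=self.r2_max, window_kb=self.window_kb)
        self.loci_ = merge_loci(clumps, merge_kb=self.merge_kb)
        member_of = {}
        for idx, loc in enumerate(self.loci_):
            for snp in loc.members:
                member_of[snp] = idx
        self.labels_ = np.array([member_of[str(s)] for s in X["SNP"]], dtype=int)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    cols = ["LEAD", "CHR", "START", "END", "CONDFDR", "P", "N_MEMBERS",
            "DATASETS", "NOVEL"]
    return pd.DataFrame([l.to_dict() for l in loci], columns=cols)


def write_loci_tsv(loci: list[Locus], path) -> None:
    loci_to_frame(loci).to_csv(path, sep="\t", index=False)


def write_loci_bed(loci: list[Locus], path) -> None:
    """BED export: 1-based inclusive spans become 0-based half-open."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead_snp}\n")
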