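"""Conditional false discovery rate estimation for two-trait GWAS summary
statistics.

The condFDR of a SNP for the primary trait, given its p-value in a
genetically correlated conditioning trait, is estimated as

    condFDR(p1 | p2) = p1 / F̂(p1 | P2 <= p2),    capped at 1,

where F̂ is the empirical conditional cumulative distribution function of
primary p-values among SNPs whose conditioning p-value is at least as small.
The null proportion is fixed at 1 (conservative). Two scoring paths are
provided:

* **exact** — per-SNP two-dimensional dominance counting (O(n log n) via an
  order-statistic tree), identical to the definitional double loop;
* **lookup** — a stratified surface over a (-log10 p1, -log10 p2) grid, the
  production path: the -log10 FDR surface is interpolated bilinearly. The
  surface is stored alongside the raw conditional-cdf grid. Interpolating
  the log-FDR surface (rather than the raw cdf) keeps the estimator
  conservative in sparse tail cells, where linear interpolation of a
  quantity spanning orders of magnitude would otherwise overestimate the
  cdf and understate the FDR.

SNPs inside configured exclusion regions (by default the extended HLA region
chr6:25-34 Mb and the 8p23.1 inversion polymorphism) never enter the fitting
set but are always scored.

Test-statistic inflation is handled by genomic control restricted to
intergenic SNPs (presumed depleted of true associations): the median
intergenic chi-square over its null median 0.4549364 gives lambda, and the
primary trait's z scores are rescaled by 1/sqrt(lambda) before fitting.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, EstimationError
from .io import p_from_z
from .regions import DEFAULT_EXCLUSION_REGIONS, in_regions

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN = 0.4549364

DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_GRID = np.linspace(0.0, 30.0, 301)


# ---------------------------------------------------------------------------
# genomic-control inflation
# ---------------------------------------------------------------------------

@dataclass
class InflationReport:
    lambda_raw: float
    n_used: int
    lambda_after: float | None = None

    def to_dict(self) -> dict:
        return {"lambda_raw": self.lambda_raw, "n_used": self.n_used,
                "lambda_after": self.lambda_after}


def genomic_inflation_lambda(z, intergenic=None, min_snps=1000, fallback_all=True):
    """Genomic-control lambda from the median squared z score.

    ``lambda = median(z^2) / 0.4549364`` over intergenic SNPs. When fewer
    than ``min_snps`` intergenic SNPs are available the estimate falls back
    to all SNPs (or raises ``EstimationError`` if ``fallback_all=False``).
    """
    z = np.asarray(z, dtype=float)
    if intergenic is not None:
        intergenic = np.asarray(intergenic, dtype=bool)
        zi = z[intergenic]
    else:
        zi = z
    if len(zi) < min_snps:
        if not fallback_all or len(z) == 0:
            raise EstimationError(
                f"only {len(zi)} intergenic SNPs (< {min_snps}) for lambda estimation")
        logger.warning("lambda: %d intergenic SNPs < %d, falling back to all SNPs",
                       len(zi), min_snps)
        zi = z
    return float(np.median(zi ** 2) / CHI2_1_MEDIAN)


def adjust_inflation(pair: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Rescale the primary trait by genomic control: z1' = z1/sqrt(lambda),
    p1' = 2 Phi(-|z1'|). The conditioning trait is untouched."""
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    out = pair.copy()
    out["Z1"] = pair["Z1"].to_numpy() / np.sqrt(lam)
    out["P1"] = p_from_z(out["Z1"].to_numpy())
    return out


class InflationAdjuster(BaseEstimator, TransformerMixin):
    """Genomic-control rescaling of the primary trait's statistics.

    Parameters
    ----------
    mode : {"intergenic", "all", "fixed", "none"}
        Which SNPs inform lambda; "fixed" uses ``fixed_lambda``; "none" is
        the identity.
    fixed_lambda : float, optional
    min_snps : int
        Minimum intergenic SNP count before falling back to all SNPs.

    Attributes
    ----------
    lambda_ : float
        The fitted genomic-control factor.
    n_used_ : int
        SNPs contributing to the estimate.
    """

    def __init__(self, mode="intergenic", fixed_lambda=None, min_snps=1000):
        self.mode = mode
        self.fixed_lambda = fixed_lambda
        self.min_snps = min_snps

    def fit(self, X, y=None):
        pair = X
        if self.mode == "none":
            self.lambda_, self.n_used_ = 1.0, 0
        elif self.mode == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda <= 0:
                raise ConfigError("mode='fixed' requires a positive fixed_lambda")
            self.lambda_, self.n_used_ = float(self.fixed_lambda), 0
        else:
            inter = (pair["FUNC"].astype(str).str.lower() == "intergenic").to_numpy() \
                if self.mode == "intergenic" else None
            self.lambda_ = genomic_inflation_lambda(
                pair["Z1"].to_numpy(), inter, min_snps=self.min_snps)
            self.n_used_ = int(inter.sum()) if inter is not None else len(pair)
        return self

    def transform(self, X):
        return adjust_inflation(X, self.lambda_)

    def report(self, X=None) -> InflationReport:
        rep = InflationReport(lambda_raw=self.lambda_, n_used=self.n_used_)
        if X is not None and self.mode in ("intergenic", "all"):
            adj = self.transform(X)
            inter = (X["FUNC"].astype(str).str.lower() == "intergenic").to_numpy() \
                if self.mode == "intergenic" else None
            rep.lambda_after = genomic_inflation_lambda(
                adj["Z1"].to_numpy(), inter, min_snps=self.min_snps)
        return rep


# ---------------------------------------------------------------------------
# exclusion masking
# ---------------------------------------------------------------------------

def exclusion_mask_regions(pair: pd.DataFrame, regions=DEFAULT_EXCLUSION_REGIONS):
    """Boolean mask of SNPs inside any exclusion region (1-based inclusive).

    Masked SNPs are excluded from conditional-cdf fitting but still receive
    condFDR values.
    """
    return in_regions(pair["CHR"], pair["BP"], regions)


# ---------------------------------------------------------------------------
# exact estimator: 2D dominance counting
# ---------------------------------------------------------------------------

def _fenwick_counts(p1, p2, fit_mask):
    """For every SNP i, count over the fitting set S:
    n2 = #{j in S : p2_j <= p2_i}, n12 = #{j in S : p1_j <= p1_i, p2_j <= p2_i}.

    Offline sweep in p2 order with a Fenwick (binary indexed) tree over p1
    ranks; inclusive ties on both axes. O((n + |S|) log n).
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    s1, s2 = p1[fit_mask], p2[fit_mask]
    if len(s1) == 0:
        raise EstimationError("empty fitting set")

    s_order = np.argsort(s2, kind="mergesort")
    s2_sorted = s2[s_order]
    vals = np.unique(s1)
    nbit = len(vals)
    # rank r: prefix sum over tree[1..r] counts S points with p1 <= threshold
    s_rank = (np.searchsorted(vals, s1[s_order], side="right")).astype(np.int64)
    q_rank = (np.searchsorted(vals, p1, side="right")).astype(np.int64)

    n2 = np.searchsorted(s2_sorted, p2, side="right").astype(np.int64)

    tree = [0] * (nbit + 1)
    n12 = np.zeros(len(p1), dtype=np.int64)
    q_order = np.argsort(p2, kind="mergesort")
    s2_list = s2_sorted.tolist()
    p2_list = p2.tolist()
    s_rank_list = s_rank.tolist()
    q_rank_list = q_rank.tolist()
    k, ns = 0, len(s2_list)
    for qi in q_order.tolist():
        pq = p2_list[qi]
        while k < ns and s2_list[k] <= pq:
            i = s_rank_list[k]
            while i <= nbit:
                tree[i] += 1
                i += i & (-i)
            k += 1
        i = q_rank_list[qi]
        c = 0
        while i > 0:
            c += tree[i]
            i -= i & (-i)
        n12[qi] = c
    return n2, n12


def _condfdr_from_counts(p1, n2, n12, s1_sorted, n_fit):
    """Apply the definition given dominance counts; unconditional fallback
    when a SNP's conditioning stratum is empty (possible for masked SNPs)."""
    cf = np.ones(len(p1), dtype=float)
    ok = n2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n12[ok] / n2[ok]
        cf[ok] = np.where(f > 0, p1[ok] / f, np.inf)
    if (~ok).any():
        # empty stratum: condition on nothing (unconditional empirical FDR)
        cnt = np.searchsorted(s1_sorted, p1[~ok], side="right")
        f0 = cnt / n_fit
        cf[~ok] = np.where(f0 > 0, p1[~ok] / f0, np.inf)
    return np.minimum(cf, 1.0)


def exact_condfdr(pair: pd.DataFrame, mask=None) -> np.ndarray:
    """condFDR for every SNP by exact dominance counting (O(n log n)).

    ``mask`` marks SNPs excluded from the fitting set (they are still
    scored). Numerically identical to :func:`brute_force_condfdr`.
    """
    p1 = pair["P1"].to_numpy(float)
    p2 = pair["P2"].to_numpy(float)
    fit_mask = np.ones(len(p1), bool) if mask is None else ~np.asarray(mask, bool)
    n2, n12 = _fenwick_counts(p1, p2, fit_mask)
    return _condfdr_from_counts(p1, n2, n12, np.sort(p1[fit_mask]), int(fit_mask.sum()))


def brute_force_condfdr(pair: pd.DataFrame, mask=None) -> np.ndarray:
    """Reference implementation of the condFDR definition by direct counting.

    For SNP i with fitting set S (unmasked SNPs):
    ``n2 = #{j in S : p2_j <= p2_i}``,
    ``n12 = #{j in S : p1_j <= p1_i and p2_j <= p2_i}``,
    ``condFDR_i = min(1, p1_i * n2 / n12)``. O(n^2); kept as the oracle the
    fast path is tested against.
    """
    p1 = pair["P1"].to_numpy(float)
    p2 = pair["P2"].to_numpy(float)
    fit_mask = np.ones(len(p1), bool) if mask is None else ~np.asarray(mask, bool)
    s1, s2 = p1[fit_mask], p2[fit_mask]
    if len(s1) == 0:
        raise EstimationError("empty fitting set")
    n = len(p1)
    n2 = np.empty(n, dtype=np.int64)
    n12 = np.empty(n, dtype=np.int64)
    for i in range(n):
        in2 = s2 <= p2[i]
        n2[i] = in2.sum()
        n12[i] = np.sum(in2 & (s1 <= p1[i]))
    return _condfdr_from_counts(p1, n2, n12, np.sort(s1), len(s1))


# ---------------------------------------------------------------------------
# lookup surface
# ---------------------------------------------------------------------------

@dataclass
class CondFdrLookup:
    """Fitted conditional-cdf surface over (-log10 p1, -log10 p2).

    ``thresholds`` are the nested conditioning cuts t_k (p2 <= 10^-t_k);
    ``grid`` the primary -log10 p1 axis q_m. ``cdf[k, m]`` holds
    F̂(p1 <= 10^-q_m | p2 <= 10^-t_k) on the fitting set; ``n_k`` are
    per-stratum fitting-set sizes (0 marks a stratum inherited from the next
    coarser one).

    Scoring interpolates the monotonized -log10 FDR surface bilinearly in the
    (-log10 p1, -log10 p2) coordinates: the surface spans many orders of
    magnitude, and interpolating on the raw scale would overestimate the
    conditional cdf in sparse tail cells and understate the FDR. Grid cells
    beyond a stratum's smallest observed p1 have no empirical mass; queries
    falling into them score condFDR 1 (no discovery without empirical
    support).
    """

    thresholds: np.ndarray
    grid: np.ndarray
    cdf: np.ndarray
    neglog_fdr: np.ndarray
    n_k: np.ndarray
    metadata: dict = field(default_factory=dict)

    def score(self, p1, p2, warn_out_of_grid=True) -> np.ndarray:
        """condFDR = min(1, p1 / F̂_interp(p1 | p2)), floored at p1 and
        monotone non-decreasing in p1 within each stratum's data support;
        coordinates outside the grid are clamped to the nearest cell."""
        p1 = np.asarray(p1, float)
        p2 = np.asarray(p2, float)
        q, t = self.grid, self.thresholds
        x = -np.log10(p1)
        y = -np.log10(p2)
        if warn_out_of_grid and (np.any(x > q[-1]) or np.any(y > t[-1])):
            warnings.warn("p-values beyond the lookup grid were clamped to its edge")
        x = np.clip(x, q[0], q[-1])
        y = np.clip(y, t[0], t[-1])
        L = self.neglog_fdr  # NaN marks cells beyond the stratum's support

        ix = np.clip(np.searchsorted(q, x, side="right") - 1, 0, len(q) - 2)
        wx = (x - q[ix]) / (q[ix + 1] - q[ix])

        def term(g, w):
            # zero-weight corners are ignored even when unsupported (NaN)
            with np.errstate(invalid="ignore"):
                return np.where(w > 0, g * w, 0.0)

        if len(t) == 1:
            li = term(L[0, ix], 1 - wx) + term(L[0, ix + 1], wx)
        else:
            iy = np.clip(np.searchsorted(t, y, side="right") - 1, 0, len(t) - 2)
            wy = (y - t[iy]) / (t[iy + 1] - t[iy])
            li = (term(L[iy, ix], (1 - wx) * (1 - wy))
                  + term(L[iy, ix + 1], wx * (1 - wy))
                  + term(L[iy + 1, ix], (1 - wx) * wy)
                  + term(L[iy + 1, ix + 1], wx * wy))
        cf = np.where(np.isnan(li), 1.0, 10.0 ** (-li))
        return np.clip(cf, p1, 1.0)

    def to_json(self, path=None) -> str:
        obj = {
            "thresholds": self.thresholds.tolist(),
            "grid": self.grid.tolist(),
            "cdf": self.cdf.tolist(),
            "neglog_fdr": [[None if np.isnan(v) else v for v in row]
                           for row in self.neglog_fdr],
            "n_k": self.n_k.tolist(),
            "metadata": self.metadata,
        }
        s = json.dumps(obj)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "CondFdrLookup":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            thresholds=np.asarray(obj["thresholds"], float),
            grid=np.asarray(obj["grid"], float),
            cdf=np.asarray(obj["cdf"], float),
            neglog_fdr=np.asarray(
                [[np.nan if v is None else v for v in row]
                 for row in obj["neglog_fdr"]], float),
            n_k=np.asarray(obj["n_k"], int),
            metadata=obj.get("metadata", {}),
        )


def _cdf_matrix(p1, p2, thresholds, grid):
    """Raw empirical conditional cdf per (stratum, grid) cell, with empty
    strata inheriting the next-coarser stratum (never a tighter one)."""
    K, M = len(thresholds), len(grid)
    cdf = np.zeros((K, M))
    n_k = np.zeros(K, dtype=np.int64)
    p_grid = 10.0 ** (-np.asarray(grid, float))
    prev = None
    for k, t in enumerate(thresholds):
        sel = p2 <= 10.0 ** (-t)
        n = int(sel.sum())
        if n == 0:
            if prev is None:
                raise EstimationError("coarsest conditioning stratum is empty")
            cdf[k] = prev
            n_k[k] = 0
        else:
            s = np.sort(p1[sel])
            cdf[k] = np.searchsorted(s, p_grid, side="right") / n
            n_k[k] = n
            prev = cdf[k]
    return cdf, n_k


def _neglog_fdr_surface(cdf, grid):
    """-log10 of min(1, p_grid/F̂) per cell, made non-decreasing in p1 by
    raising larger-p1 cells (conservative direction). Cells with F̂ = 0 (no
    data at or below that p1 in the stratum) are NaN: a query there has no
    empirical support and scores 1."""
    p_grid = 10.0 ** (-np.asarray(grid, float))
    K, M = cdf.shape
    L = np.full((K, M), np.nan)
    for k in range(K):
        pop = cdf[k] > 0  # contiguous prefix: F̂ is non-increasing along q
        m_star = int(np.nonzero(pop)[0].max()) if pop.any() else -1
        if m_star < 0:
            continue
        fdr = np.minimum(p_grid[: m_star + 1] / cdf[k, : m_star + 1], 1.0)
        # enforce fdr non-increasing along q (non-decreasing in p1)
        fdr = np.maximum.accumulate(fdr[::-1])[::-1]
        L[k, : m_star + 1] = -np.log10(fdr)
    return L


def _random_ld_prune(snp_ids, chrom, pos, ld, r2_max, rng):
    """One random LD-pruning pass: greedy independent set (pairwise r2 <
    r2_max) over a shuffled SNP order."""
    order = rng.permutation(len(snp_ids))
    kept_mask = np.zeros(len(snp_ids), dtype=bool)
    kept_by_chrom: dict = {}
    for i in order:
        ok = True
        for j in kept_by_chrom.get(chrom[i], []):
            if ld.r2(snp_ids[i], snp_ids[j]) >= r2_max:
                ok = False
                break
        if ok:
            kept_mask[i] = True
            kept_by_chrom.setdefault(chrom[i], []).append(i)
    return kept_mask


def fit_conditional_cdf(pair: pd.DataFrame, mask=None, thresholds=DEFAULT_THRESHOLDS,
                        grid=None, prune_ld=None, prune_iterations=0, prune_r2=0.1,
                        random_state=None) -> CondFdrLookup:
    """Fit the stratified conditional-cdf lookup on the unmasked SNPs.

    ``thresholds`` is the nested -log10 p2 grid (ascending), ``grid`` the
    -log10 p1 axis (default 301 points on [0, 30]). With ``prune_ld`` (an LD
    source) and ``prune_iterations`` > 0, the surface is averaged over
    random LD-pruning passes (pairwise r2 < ``prune_r2``) to de-weight LD
    clusters; all seeds are recorded in the metadata. Pruning is off by
    default.
    """
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) <= 0):
        raise ConfigError("conditioning thresholds must be strictly ascending")
    grid = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, float)

    fit_mask = np.ones(len(pair), bool) if mask is None else ~np.asarray(mask, bool)
    if fit_mask.sum() < 2:
        raise EstimationError("need at least 2 unmasked SNPs to fit the cdf")
    p1 = pair["P1"].to_numpy(float)[fit_mask]
    p2 = pair["P2"].to_numpy(float)[fit_mask]

    meta = {"n_fit": int(fit_mask.sum()), "n_masked": int((~fit_mask).sum()),
            "pruning": None}
    if prune_ld is not None and prune_iterations > 0:
        rng = np.random.default_rng(random_state)
        seeds = rng.integers(0, 2**31 - 1, size=prune_iterations)
        snp = pair["SNP"].to_numpy()[fit_mask]
        chrom = pair["CHR"].astype(str).to_numpy()[fit_mask]
        pos = pair["BP"].to_numpy()[fit_mask]
        mats, sizes = [], []
        for s in seeds:
            keep = _random_ld_prune(snp, chrom, pos, prune_ld, prune_r2,
                                    np.random.default_rng(int(s)))
            m, nk = _cdf_matrix(p1[keep], p2[keep], thresholds, grid)
            mats.append(m)
            sizes.append(nk)
        cdf = np.mean(mats, axis=0)
        n_k = np.rint(np.mean(sizes, axis=0)).astype(np.int64)
        meta["pruning"] = {"iterations": int(prune_iterations), "r2": prune_r2,
                           "seeds": [int(s) for s in seeds]}
    else:
        cdf, n_k = _cdf_matrix(p1, p2, thresholds, grid)

    # monotone non-decreasing along increasing p1 (decreasing q); a no-op for
    # a raw empirical cdf, needed after pruning-averaging
    cdf = np.maximum.accumulate(cdf[:, ::-1], axis=1)[:, ::-1]
    return CondFdrLookup(thresholds=thresholds, grid=grid, cdf=cdf,
                         neglog_fdr=_neglog_fdr_surface(cdf, grid),
                         n_k=n_k, metadata=meta)


def condfdr(pair: pd.DataFrame, lookup: CondFdrLookup | None = None,
            mask=None, mode="lookup") -> pd.DataFrame:
    """Score a harmonized pair: returns a copy with a ``CONDFDR`` column.

    ``mode="lookup"`` interpolates a fitted :class:`CondFdrLookup` (fitted on
    the same pair unless declared transferable); ``mode="exact"`` bypasses
    the lookup and reproduces the brute-force definition exactly.
    """
    out = pair.copy()
    if mode == "exact":
        out["CONDFDR"] = exact_condfdr(pair, mask=mask)
    elif mode == "lookup":
        if lookup is None:
            lookup = fit_conditional_cdf(pair, mask=mask)
        out["CONDFDR"] = lookup.score(pair["P1"].to_numpy(float),
                                      pair["P2"].to_numpy(float))
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class ConditionalFdr(BaseEstimator):
    """Conditional FDR scorer with region masking.

    Parameters
    ----------
    mode : {"lookup", "exact"}
        "lookup" (default) fits the stratified surface and scores by
        interpolation; "exact" scores by per-SNP dominance counting.
    thresholds : sequence of float
        Nested conditioning cuts on -log10 p2.
    grid : array-like, optional
        -log10 p1 axis (default 301 points on [0, 30]).
    exclude_regions : "default", None, or list of (chrom, start, end)
        Regions masked from fitting ("default": extended HLA + 8p23.1).
        SNPs flagged in the pair's EXCL column are also masked.
    prune_ld, prune_iterations, prune_r2
        Optional random LD-pruning averaging during fitting (off by default).
    random_state : int, optional

    Attributes
    ----------
    mask_ : ndarray of bool
        SNPs excluded from fitting.
    lookup_ : CondFdrLookup
        Fitted surface (lookup mode).
    n_fit_ : int
        Size of the fitting set.
    """

    def __init__(self, mode="lookup", thresholds=DEFAULT_THRESHOLDS, grid=None,
                 exclude_regions="default", prune_ld=None, prune_iterations=0,
                 prune_r2=0.1, random_state=None):
        self.mode = mode
        self.thresholds = thresholds
        self.grid = grid
        self.exclude_regions = exclude_regions
        self.prune_ld = prune_ld
        self.prune_iterations = prune_iterations
        self.prune_r2 = prune_r2
        self.random_state = random_state

    def _regions(self):
        if self.exclude_regions == "default":
            return DEFAULT_EXCLUSION_REGIONS
        return self.exclude_regions or []

    def _mask(self, pair):
        mask = exclusion_mask_regions(pair, self._regions())
        if "EXCL" in pair.columns:
            mask |= pair["EXCL"].astype(bool).to_numpy()
        return mask

    def fit(self, X, y=None):
        pair = X
        for col in ("P1", "P2", "CHR", "BP"):
            if col not in pair.columns:
                raise ConfigError(f"pair table lacks column {col}")
        self.mask_ = self._mask(pair)
        self.n_fit_ = int((~self.mask_).sum())
        if self.mode == "lookup":
            self.lookup_ = fit_conditional_cdf(
                pair, mask=self.mask_, thresholds=self.thresholds, grid=self.grid,
                prune_ld=self.prune_ld, prune_iterations=self.prune_iterations,
                prune_r2=self.prune_r2, random_state=self.random_state)
        elif self.mode == "exact":
            keep = ~self.mask_
            if keep.sum() == 0:
                raise EstimationError("empty fitting set")
            self._fit_p1 = pair["P1"].to_numpy(float)[keep]
            self._fit_p2 = pair["P2"].to_numpy(float)[keep]
        else:
            raise ConfigError(f"unknown mode {self.mode!r}")
        return self

    def predict(self, X) -> np.ndarray:
        """Per-SNP condFDR values."""
        p1 = X["P1"].to_numpy(float)
        p2 = X["P2"].to_numpy(float)
        if self.mode == "lookup":
            return self.lookup_.score(p1, p2)
        full = np.concatenate([self._fit_p1, p1])
        full2 = np.concatenate([self._fit_p2, p2])
        fit_mask = np.zeros(len(full), bool)
        fit_mask[:len(self._fit_p1)] = True
        n2, n12 = _fenwick_counts(full, full2, fit_mask)
        cf = _condfdr_from_counts(full, n2, n12, np.sort(self._fit_p1),
                                  len(self._fit_p1))
        return cf[len(self._fit_p1):]

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)

    def transform(self, X) -> pd.DataFrame:
        """Scored pair: the input plus a CONDFDR column."""
        out = X.copy()
        out["CONDFDR"] = self.predict(X)
        return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def conditional_enrichment_qq(pair: pd.DataFrame,
                              p2_thresholds=(1.0, 0.1, 0.01, 0.001)) -> pd.DataFrame:
    """Stratified QQ table: observed vs expected -log10 p1 quantiles within
    nested conditioning strata p2 <= threshold.

    A leftward/upward shift of the curves across tightening thresholds is
    the visual signature of cross-trait enrichment. Empty strata are dropped
    with a warning. Returns a tidy frame with columns ``p2_threshold``,
    ``expected``, ``observed``.
    """
    p1 = pair["P1"].to_numpy(float)
    p2 = pair["P2"].to_numpy(float)
    rows = []
    for thr in sorted(p2_thresholds, reverse=True):
        sub = np.sort(p1[p2 <= thr])
        n = len(sub)
        if n == 0:
            warnings.warn(f"no SNPs at p2 <= {thr:g}; stratum dropped")
            continue
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        rows.append(pd.DataFrame({
            "p2_threshold": thr,
            "expected": expected,
            "observed": -np.log10(sub),
        }))
    if not rows:
        return pd.DataFrame(columns=["p2_threshold", "expected", "observed"])
    return pd.concat(rows, ignore_index=True)


def qq_stratum_medians(qq: pd.DataFrame) -> pd.Series:
    """Median observed -log10 p1 per conditioning stratum (index: threshold,
    descending = nested tightening)."""
    return qq.groupby("p2_threshold")["observed"].median().sort_index(ascending=False)
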