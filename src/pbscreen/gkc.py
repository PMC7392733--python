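"""Common insertion site (CIS) detection by Gaussian kernel convolution.

Pooled insertion positions are smoothed with an unnormalized Gaussian kernel
``K_h(u) = exp(-u^2 / 2h^2)`` over a ladder of kernel widths h ("window
sizes", 10-100 kb by default), so that recurrent insertions across
independent tumors form density peaks whose height is directly comparable to
a local insertion count.  Peak significance is assessed against a Monte-Carlo
null that redraws the same number of insertions uniformly over the TTAA
motif positions of each chromosome -- the discrete space where piggyBac can
integrate -- and is Bonferroni-corrected across the candidate peaks of each
scale.  A CIS is reported when it is significant at a minimum number of
scales.

The module follows the Model/Results convention: build a
:class:`CommonInsertionSiteModel` from a pooled insertion table and a
:class:`~pbscreen.genome.TTAAIndex`, call :meth:`~CommonInsertionSiteModel.fit`
with a seed, and read the CIS table, per-insertion membership and null
diagnostics off the returned :class:`CommonInsertionSiteResults`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ConfigurationError, InputError, ParameterError, StatisticsError
from .genome import TTAAIndex

CIS_COLUMNS = [
    "cis_id", "chrom", "apex_pos", "start", "end", "best_scale", "height",
    "raw_p", "adjusted_p", "n_scales_significant", "n_insertions", "n_tumors",
]


@dataclass
class GkcParams:
    """Tuning parameters of the CIS caller.

    scales
        Kernel widths h in bp, strictly increasing (default 10-100 kb in
        10 kb steps).
    alpha
        Family-wise threshold on the Bonferroni-adjusted p value.
    min_scales_significant
        A CIS must be significant at at least this many scales ("multiple
        window sizes").
    n_perm
        Monte-Carlo replicates per scale.
    grid_step_fraction
        Evaluation-grid spacing as a fraction of h; all insertion positions
        are added to the grid, so reported apexes never miss a peak by more
        than a bounded interpolation error.
    min_tumors
        Minimum number of distinct tumors supporting an observed peak; a
        single tumor cannot constitute recurrence.
    null_mode
        ``chromosome-matched`` redraws each chromosome's own insertion count
        (absorbing chromosome-level rate biases); ``genome-wide`` distributes
        the total count across chromosomes proportionally to TTAA counts.
    trunc_radius
        Kernel contributions beyond ``trunc_radius*h`` are dropped inside the
        caller; the absolute error is bounded by ``n*exp(-radius^2/2)``
        (``n*e^-18`` at the default 6).
    read_weighted
        Weight each insertion by its read count instead of counting it once.
    bonferroni
        ``candidates``: correct by the number of observed candidate peaks at
        the scale; ``effective-tests``: correct by genome length / h.
    """

    scales: tuple[int, ...] = tuple(range(10_000, 100_001, 10_000))
    alpha: float = 0.001
    min_scales_significant: int = 2
    n_perm: int = 1000
    grid_step_fraction: float = 0.2
    min_tumors: int = 2
    null_mode: str = "chromosome-matched"
    trunc_radius: float = 6.0
    read_weighted: bool = False
    bonferroni: str = "candidates"
    exclude_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.scales = tuple(int(s) for s in self.scales)
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ParameterError("scales must be positive")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ParameterError("scales must be strictly increasing")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ParameterError("n_perm must be >= 100")
        if not 1 <= self.min_scales_significant <= len(self.scales):
            raise ParameterError("min_scales_significant must be in [1, len(scales)]")
        if not 0 < self.grid_step_fraction <= 1:
            raise ParameterError("grid_step_fraction must be in (0, 1]")
        if self.null_mode not in ("chromosome-matched", "genome-wide"):
            raise ParameterError(f"unknown null_mode {self.null_mode!r}")
        if self.bonferroni not in ("candidates", "effective-tests"):
            raise ParameterError(f"unknown bonferroni mode {self.bonferroni!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "GkcParams":
        kwargs = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        if "scales" in kwargs:
            kwargs["scales"] = tuple(kwargs["scales"])
        return cls(**kwargs)


@dataclass
class NullDistribution:
    """Null peak heights for one kernel width.

    ``heights`` pools every qualifying null peak over all replicates and
    chromosomes (sorted ascending); ``rep_max`` holds each replicate's
    genome-wide maximum peak height.
    """

    scale: int
    heights: np.ndarray
    rep_max: np.ndarray
    mean_peaks: float
    n_perm: int
    seed: int


def kernel_density(positions, h: float, eval_points, weights=None,
                   trunc_radius: float | None = None) -> np.ndarray:
    """Unnormalized Gaussian kernel density of insertion positions.

    ``f(x) = sum_i w_i exp(-(x - x_i)^2 / (2 h^2))`` evaluated at each (sorted)
    eval point; with unit weights the height at a point equals the effective
    number of insertions in its kernel neighbourhood, so peak heights are
    directly comparable to insertion multiplicities.  Exact by default; pass
    ``trunc_radius`` to window the sum (absolute error <= n exp(-r^2/2)).
    """
    pos = np.asarray(positions, dtype=np.float64)
    ev = np.asarray(eval_points, dtype=np.float64)
    if h <= 0:
        raise ParameterError("kernel width h must be > 0")
    if pos.size > 1 and np.any(np.diff(pos) < 0):
        raise InputError("positions must be sorted ascending")
    if ev.size > 1 and np.any(np.diff(ev) < 0):
        raise InputError("eval_points must be sorted ascending")
    w = np.ones(pos.size) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.size != pos.size:
        raise InputError("weights must match positions")
    if trunc_radius is None:
        return _kernels.gauss_heights_exact(pos, w, ev, float(h))
    return _kernels.gauss_heights_trunc(pos, w, ev, float(h), float(trunc_radius))


def _eval_grid(length: int, h: int, step_fraction: float, positions: np.ndarray) -> np.ndarray:
    step = max(1, int(round(h * step_fraction)))
    regular = np.arange(0, int(length) + step, step, dtype=np.int64)
    return np.unique(np.concatenate((regular, positions)))


def find_peaks(grid, heights, positions, h, tumor_codes=None, min_tumors: int = 2,
               min_insertions: int = 2) -> pd.DataFrame:
    """Extract candidate peaks from one chromosome's density profile.

    Local maxima (strictly greater than both neighbours; plateaus yield the
    leftmost point) supported by at least ``min_insertions`` insertions and
    ``min_tumors`` distinct tumors within +-h of the apex.  Returns one row
    per candidate with the member index range ``[member_lo, member_hi)`` into
    the sorted position array.
    """
    grid = np.asarray(grid, dtype=np.int64)
    heights = np.asarray(heights, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.int64)
    idx = _kernels.local_maxima(heights)
    rows = []
    for i in idx:
        apex = int(grid[i])
        lo = int(np.searchsorted(positions, apex - h, side="left"))
        hi = int(np.searchsorted(positions, apex + h, side="right"))
        n_ins = hi - lo
        if n_ins < min_insertions:
            continue
        if tumor_codes is not None:
            n_tum = int(np.unique(np.asarray(tumor_codes)[lo:hi]).size)
            if n_tum < min_tumors:
                continue
        else:
            n_tum = n_ins
        rows.append((apex, float(heights[i]), n_ins, n_tum, lo, hi))
    return pd.DataFrame(rows, columns=["apex_pos", "height", "n_insertions",
                                       "n_tumors", "member_lo", "member_hi"])


_EXP_TABLES: dict[float, np.ndarray] = {}


def _exp_table(radius: float) -> np.ndarray:
    tab = _EXP_TABLES.get(radius)
    if tab is None:
        tab = _EXP_TABLES[radius] = _kernels.make_exp_table(float(radius))
    return tab


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent 31-bit seeds from one master seed."""
    return np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32) % (2 ** 31)


def sample_null(n_by_chrom: Mapping[str, int], ttaa: TTAAIndex, h: int,
                params: GkcParams, seed: int,
                weight_pool: np.ndarray | None = None) -> NullDistribution:
    """Monte-Carlo null peak-height distribution for one kernel width.

    Each replicate places the matched number of insertions uniformly at
    random (with replacement) over the TTAA positions -- per chromosome in
    ``chromosome-matched`` mode, or genome-wide proportional to TTAA counts --
    and records all qualifying peak heights plus the genome-wide maximum,
    using the same profile/peak machinery as the observed data but with the
    tumor-support filter disabled.
    """
    chroms = sorted(c for c, n in n_by_chrom.items() if n > 0)
    for c in chroms:
        if c not in ttaa or ttaa[c].size == 0:
            raise ConfigurationError(f"chromosome {c} has insertions but no TTAA sites")
    n_total = int(sum(n_by_chrom.values()))
    if n_total == 0 or not chroms:
        return NullDistribution(int(h), np.empty(0), np.zeros(params.n_perm),
                                0.0, params.n_perm, int(seed))
    rng = np.random.default_rng(int(seed))
    if params.null_mode == "chromosome-matched":
        counts = {c: np.full(params.n_perm, int(n_by_chrom[c]), dtype=np.int64)
                  for c in chroms}
    else:
        null_chroms = sorted(ttaa.chroms)
        weights = np.array([ttaa[c].size for c in null_chroms], dtype=np.float64)
        draws = rng.multinomial(n_total, weights / weights.sum(),
                                size=params.n_perm)
        counts = {c: draws[:, j].astype(np.int64) for j, c in enumerate(null_chroms)}
        chroms = [c for c in null_chroms if counts[c].sum() > 0]
    pool = (np.empty(0) if weight_pool is None
            else np.asarray(weight_pool, dtype=np.float64))
    chrom_seeds = _child_seeds(seed, len(chroms))
    pooled_parts = []
    rep_max = np.zeros(params.n_perm)
    total_peaks = 0
    for c, cseed in zip(chroms, chrom_seeds):
        length = ttaa.lengths.get(c, int(ttaa[c][-1]) + 3)
        step = max(1, int(round(h * params.grid_step_fraction)))
        grid_regular = np.arange(0, length + step, step,
                                 dtype=np.int64).astype(np.float32)
        heights, cmax, npk = _kernels.null_peak_scan(
            ttaa[c], counts[c], float(h), grid_regular,
            float(params.trunc_radius), 2, int(cseed),
            pool.astype(np.float32), _exp_table(params.trunc_radius))
        pooled_parts.append(heights)
        rep_max = np.maximum(rep_max, cmax)
        total_peaks += int(npk.sum())
    pooled = np.sort(np.concatenate(pooled_parts)) if pooled_parts else np.empty(0)
    return NullDistribution(int(h), pooled, rep_max,
                            total_peaks / params.n_perm, params.n_perm, int(seed))


def peak_pvalue(height: float, null: NullDistribution,
                n_candidates: int) -> tuple[float, float]:
    """Raw and Bonferroni-adjusted p value of an observed peak height.

    ``raw_p = (1 + #{null peaks >= height}) / (1 + #null peaks)`` (add-one
    correction, so the smallest attainable p is bounded by the Monte-Carlo
    resolution); ``adjusted_p = min(1, raw_p * n_candidates)``.
    """
    n = int(null.heights.size)
    if n == 0:
        raise StatisticsError("empty null distribution; cannot compute p values")
    n_ge = n - int(np.searchsorted(null.heights, height, side="left"))
    raw = (1.0 + n_ge) / (1.0 + n)
    return raw, min(1.0, raw * max(1, int(n_candidates)))


class CommonInsertionSiteModel:
    """Multi-scale GKC model of recurrent transposon insertion.

    Parameters
    ----------
    insertions
        Pooled insertion table (from :func:`pbscreen.io.pool_nonredundant`)
        with at least ``chrom`` and ``pos``; ``tumor_id`` (or ``sample_id``)
        defines recurrence units and ``tissue`` feeds per-tissue counts.
    ttaa
        TTAA motif index covering every insertion chromosome.
    params
        :class:`GkcParams`; defaults follow the screen protocol
        (10-100 kb scale ladder, Bonferroni-adjusted p < 0.001 at >= 2 scales).

    Examples
    --------
    >>> model = CommonInsertionSiteModel(pooled, ttaa)   # doctest: +SKIP
    >>> res = model.fit(seed=1)                          # doctest: +SKIP
    >>> print(res.summary())                             # doctest: +SKIP
    """

    def __init__(self, insertions: pd.DataFrame, ttaa: TTAAIndex,
                 params: GkcParams | None = None):
        self.params = params or GkcParams()
        self.ttaa = ttaa
        df = insertions
        if self.params.exclude_chroms and df.shape[0]:
            df = df[~df["chrom"].isin(self.params.exclude_chroms)]
        self.insertions = df.reset_index(drop=True)
        self._prepare()

    def _prepare(self) -> None:
        df = self.insertions
        if df.shape[0] == 0:
            self._chroms = []
            self.n_by_chrom: dict[str, int] = {}
            return
        missing = sorted(set(df["chrom"]) - set(self.ttaa.chroms))
        if missing:
            raise ConfigurationError(
                f"insertions on chromosomes absent from TTAA index: {missing}")
        empty = sorted(c for c in set(df["chrom"]) if self.ttaa[c].size == 0)
        if empty:
            raise ConfigurationError(
                f"chromosomes with insertions but no TTAA sites: {empty}")
        tumor_col = "tumor_id" if ("tumor_id" in df.columns
                                   and df["tumor_id"].astype(str).str.len().gt(0).any()) \
            else "sample_id"
        tumor_codes, self._tumor_labels = pd.factorize(df[tumor_col].astype(str))
        tissues = (df["tissue"].astype(str) if "tissue" in df.columns
                   else pd.Series(["other"] * len(df)))
        self._tissues = sorted(set(tissues) | {"brain", "spinal"})
        self._chrom_data: dict[str, dict] = {}
        for chrom, grp in df.groupby("chrom", sort=True):
            order = np.argsort(grp["pos"].to_numpy(), kind="stable")
            idx = grp.index.to_numpy()[order]
            self._chrom_data[str(chrom)] = {
                "pos": grp["pos"].to_numpy(np.int64)[order],
                "tumor": tumor_codes[grp.index.to_numpy()][order],
                "tissue": tissues.to_numpy()[grp.index.to_numpy()][order],
                "row": idx,
                "weight": (grp["read_count"].to_numpy(np.float64)[order]
                           if self.params.read_weighted and "read_count" in grp
                           else np.ones(len(grp))),
            }
        self._chroms = sorted(self._chrom_data)
        self.n_by_chrom = {c: int(self._chrom_data[c]["pos"].size) for c in self._chroms}
        self.n_tumors_total = int(len(self._tumor_labels))

    def _observed_candidates(self, h: int) -> pd.DataFrame:
        p = self.params
        frames = []
        for c in self._chroms:
            d = self._chrom_data[c]
            length = self.ttaa.lengths.get(c, int(self.ttaa[c][-1]) + 3)
            grid = _eval_grid(length, h, p.grid_step_fraction, d["pos"])
            # same single-precision engine as the null, so observed and null
            # peak heights are compared on identical arithmetic
            heights = _kernels.gauss_heights_trunc32(
                d["pos"].astype(np.float32), d["weight"].astype(np.float32),
                grid.astype(np.float32), np.float32(h), np.float32(p.trunc_radius),
                _exp_table(p.trunc_radius))
            peaks = find_peaks(grid, heights, d["pos"], h, tumor_codes=d["tumor"],
                               min_tumors=p.min_tumors)
            peaks.insert(0, "chrom", c)
            frames.append(peaks)
        out = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=["chrom", "apex_pos", "height",
                                          "n_insertions", "n_tumors",
                                          "member_lo", "member_hi"]))
        out["scale"] = h
        return out

    def fit(self, seed: int = 0) -> "CommonInsertionSiteResults":
        """Run the multi-scale peak calling and Monte-Carlo significance test."""
        p = self.params
        if not self._chroms:
            return CommonInsertionSiteResults(self, pd.DataFrame(columns=CIS_COLUMNS),
                                              self.insertions.iloc[0:0], {}, {},
                                              pd.DataFrame(), int(seed))
        genome_len = sum(self.ttaa.lengths.get(c, int(self.ttaa[c][-1]) + 3)
                         for c in self._chroms)
        weight_pool = (self.insertions["read_count"].to_numpy(np.float64)
                       if p.read_weighted and "read_count" in self.insertions
                       else None)
        scale_seeds = _child_seeds(seed, len(p.scales))
        nulls: dict[int, NullDistribution] = {}
        n_candidates: dict[int, int] = {}
        cand_frames = []
        for h, sseed in zip(p.scales, scale_seeds):
            cands = self._observed_candidates(h)
            null = sample_null(self.n_by_chrom, self.ttaa, h, p, int(sseed),
                               weight_pool=weight_pool)
            nulls[h] = null
            n_cand = int(len(cands))
            n_candidates[h] = n_cand
            bonf = (n_cand if p.bonferroni == "candidates"
                    else int(math.ceil(genome_len / h)))
            if len(cands):
                pvals = [peak_pvalue(ht, null, bonf) for ht in cands["height"]]
                cands["raw_p"] = [x[0] for x in pvals]
                cands["adjusted_p"] = [x[1] for x in pvals]
            else:
                cands["raw_p"] = []
                cands["adjusted_p"] = []
            cand_frames.append(cands)
        candidates = pd.concat(cand_frames, ignore_index=True)
        cis, membership = self._cluster(candidates)
        return CommonInsertionSiteResults(self, cis, membership, nulls,
                                          n_candidates, candidates, int(seed))

    def _cluster(self, candidates: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Cluster peaks across scales into CIS and apply the multi-scale rule."""
        p = self.params
        link = max(p.scales)
        cis_rows = []
        member_frames = []
        if len(candidates) == 0:
            return (pd.DataFrame(columns=CIS_COLUMNS + [f"{t}_count" for t in
                                                        getattr(self, "_tissues", [])]),
                    self.insertions.iloc[0:0])
        for chrom, grp in candidates.groupby("chrom", sort=True):
            grp = grp.sort_values(["apex_pos", "scale"], kind="mergesort")
            apexes = grp["apex_pos"].to_numpy()
            new_cluster = np.ones(len(grp), dtype=bool)
            new_cluster[1:] = np.diff(apexes) > link
            cluster_ids = np.cumsum(new_cluster)
            for _, cl in grp.groupby(cluster_ids, sort=True):
                sig = cl[cl["adjusted_p"] < p.alpha]
                n_sig_scales = int(sig["scale"].nunique())
                if n_sig_scales < p.min_scales_significant:
                    continue
                best = sig.sort_values(["adjusted_p", "scale", "apex_pos"],
                                       kind="mergesort").iloc[0]
                d = self._chrom_data[str(chrom)]
                lo, hi = int(best["member_lo"]), int(best["member_hi"])
                members = d["pos"][lo:hi]
                rows = d["row"][lo:hi]
                tiss = d["tissue"][lo:hi]
                apex = int(best["apex_pos"])
                cis_id = f"CIS_{chrom}_{apex}"
                rec = {
                    "cis_id": cis_id, "chrom": chrom, "apex_pos": apex,
                    "start": int(members.min()), "end": int(members.max()),
                    "best_scale": int(best["scale"]),
                    "height": float(best["height"]),
                    "raw_p": float(best["raw_p"]),
                    "adjusted_p": float(best["adjusted_p"]),
                    "n_scales_significant": n_sig_scales,
                    "n_insertions": int(best["n_insertions"]),
                    "n_tumors": int(best["n_tumors"]),
                }
                for t in self._tissues:
                    rec[f"{t}_count"] = int((tiss == t).sum())
                cis_rows.append(rec)
                mem = self.insertions.loc[rows].copy()
                mem.insert(0, "cis_id", cis_id)
                member_frames.append(mem)
        cis = pd.DataFrame(cis_rows)
        if len(cis) == 0:
            cis = pd.DataFrame(columns=CIS_COLUMNS + [f"{t}_count" for t in self._tissues])
        cis = cis.sort_values(["chrom", "apex_pos"], kind="mergesort",
                              ignore_index=True)
        membership = (pd.concat(member_frames, ignore_index=True) if member_frames
                      else self.insertions.iloc[0:0])
        return cis, membership


class CommonInsertionSiteResults:
    """Fitted CIS-calling results.

    Attributes
    ----------
    cis : DataFrame
        One row per significant CIS (apex, interval, best scale, raw and
        Bonferroni-adjusted p, support counts, per-tissue counts).
    membership : DataFrame
        Member insertions of each CIS at its best scale.
    nulls : dict scale -> NullDistribution
    candidates : DataFrame
        All tested candidate peaks across scales (diagnostic).
    """

    def __init__(self, model, cis, membership, nulls, n_candidates, candidates, seed):
        self.model = model
        self.params = model.params
        self.cis = cis
        self.membership = membership
        self.nulls = nulls
        self.n_candidates = n_candidates
        self.candidates = candidates
        self.seed = seed

    @property
    def n_cis(self) -> int:
        return int(len(self.cis))

    def summary(self, top: int = 10) -> str:
        p = self.params
        lines = [
            "Common insertion site analysis (Gaussian kernel convolution)",
            "=" * 64,
            f"Insertions: {len(self.model.insertions):>8}    "
            f"Tumors: {getattr(self.model, 'n_tumors_total', 0)}",
            f"Chromosomes: {len(self.model.n_by_chrom):>7}    "
            f"Scales: {p.scales[0]//1000}-{p.scales[-1]//1000} kb (n={len(p.scales)})",
            f"Null replicates: {p.n_perm:>3}    alpha: {p.alpha}    "
            f"min scales: {p.min_scales_significant}",
            f"Seed: {self.seed}    null mode: {p.null_mode}",
            f"Significant CIS: {self.n_cis}",
        ]
        if self.n_cis:
            cols = ["cis_id", "chrom", "apex_pos", "best_scale", "n_insertions",
                    "n_tumors", "adjusted_p"]
            head = (self.cis.sort_values(["n_insertions", "n_tumors"],
                                         ascending=False).head(top))
            lines.append("-" * 64)
            lines.append(head[cols].to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CommonInsertionSiteResults: {self.n_cis} CIS, seed={self.seed}>"


def call_cis(pooled_sites: pd.DataFrame, ttaa: TTAAIndex,
             genes: pd.DataFrame | None = None,
             params: GkcParams | None = None, seed: int = 0) -> CommonInsertionSiteResults:
    """One-call CIS detection; wraps :class:`CommonInsertionSiteModel`.

    When ``genes`` is given, a ``genes`` column with the associated gene names
    (nearest first) is added to the CIS table.
    """
    res = CommonInsertionSiteModel(pooled_sites, ttaa, params=params).fit(seed=seed)
    if genes is not None and res.n_cis:
        from .annotate import associate_genes

        assoc = associate_genes(res.cis, genes)
        joined = (assoc.groupby("cis_id")["name"].apply(lambda s: ",".join(s))
                  if len(assoc) else pd.Series(dtype=str))
        res.cis["genes"] = res.cis["cis_id"].map(joined).fillna("")
    return res
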