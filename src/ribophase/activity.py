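"""The rRNA:rDNA relative-activity framework.

For an OTU at one date, the raw activity ratio is its rRNA relative read
abundance divided by its rDNA relative read abundance. Ratios are
reported on a *signed* scale whose magnitude is always >= 1: a raw ratio
r >= 1 stays +r, a raw ratio r < 1 becomes -1/r, so e.g. -40 means
40-fold more rDNA than rRNA signal. OTUs seen in only one of the two
libraries are excluded rather than assigned an infinite ratio.

Group-level behaviour is summarized by a reduced-major-axis (RMA)
regression of log10 rRNA on log10 rDNA relative abundance, which treats
both axes as noisy: slope = sign(r) * sd(y)/sd(x). Groups whose slope
confidence interval sits above (below) 1 are RNA-(DNA-)prevalent.

OTU-level life cycles are read from a four-quadrant classification of
(rDNA, rRNA) relative abundances against a rare threshold (0.01% of
reads) and an abundant threshold (0.1%): rare-low, rare-active,
abundant-active, abundant-low, with the band between thresholds treated
as a transition state. A maximal run of abundant-active dates is a bloom
interval; a date where the rRNA signal is already above the abundant
threshold while the rDNA signal is not, ahead of a bloom, is an early
warning of that bloom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default quadrant thresholds, as fractions of total reads.
RARE_THRESH = 0.0001      # 0.01 %
ABUNDANT_THRESH = 0.001   # 0.1 %

QUADRANTS = ("rare-low", "rare-active", "abundant-active", "abundant-low", "transition")


# ---------------------------------------------------------------------------
# signed ratio
# ---------------------------------------------------------------------------


def signed_ratio(rdna_rel: float, rrna_rel: float) -> float | None:
    """Signed rRNA:rDNA ratio; ``None`` when either abundance is zero.

    ``r = rrna_rel / rdna_rel``; returns ``+r`` if ``r >= 1`` else
    ``-1/r``, so the magnitude is the fold difference and the sign points
    to the prevalent molecule (+ rRNA, - rDNA). Equality returns +1.
    """
    if rdna_rel < 0 or rrna_rel < 0:
        raise ValueError("relative abundances must be non-negative")
    if rdna_rel == 0 or rrna_rel == 0:
        return None
    r = rrna_rel / rdna_rel
    return r if r >= 1 else -1.0 / r


def unsign_ratio(value: float) -> float:
    """Recover the raw ratio from a signed one (inverse of signed_ratio)."""
    return value if value >= 1 else -1.0 / value


# ---------------------------------------------------------------------------
# ratio series
# ---------------------------------------------------------------------------


def ratio_series(
    dna_rel,
    rna_rel,
    pairs,
    rare_thresh: float = RARE_THRESH,
    abundant_thresh: float = ABUNDANT_THRESH,
    otu_ids=None,
) -> pd.DataFrame:
    """Tidy per-(OTU, date) activity table from paired libraries.

    ``dna_rel``/``rna_rel`` are relative-abundance tables sharing an OTU
    axis; ``pairs`` is a :class:`~ribophase.io_tables.PairedLibraries` or
    a list of ``(date, dna_sample, rna_sample)``. OTUs absent from both
    libraries of a date are skipped; OTUs present in only one are kept
    but flagged ``excluded`` with no ratio, mirroring the exclusion rule
    for single-molecule occurrences.
    """
    from .io_tables import PairedLibraries

    dvals, rvals = dna_rel.values, rna_rel.values
    if otu_ids is None:
        otu_ids = [o for o in dvals.columns if o in set(rvals.columns)]
    triples = pairs.pairs if isinstance(pairs, PairedLibraries) else list(pairs)
    rows = []
    for date, d_id, r_id in triples:
        d = dvals.loc[d_id, otu_ids].to_numpy(dtype=float)
        r = rvals.loc[r_id, otu_ids].to_numpy(dtype=float)
        for otu, dv, rv in zip(otu_ids, d, r):
            if dv == 0 and rv == 0:
                continue
            sr = signed_ratio(dv, rv)
            rows.append(
                {
                    "otu_id": otu,
                    "date": date,
                    "rdna_rel": dv,
                    "rrna_rel": rv,
                    "raw_ratio": rv / dv if dv > 0 and rv > 0 else math.nan,
                    "signed_ratio": sr if sr is not None else math.nan,
                    "excluded": sr is None,
                    "quadrant": classify_quadrant(dv, rv, rare_thresh, abundant_thresh),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "otu_id",
            "date",
            "rdna_rel",
            "rrna_rel",
            "raw_ratio",
            "signed_ratio",
            "excluded",
            "quadrant",
        ],
    )


# ---------------------------------------------------------------------------
# RMA regression
# ---------------------------------------------------------------------------


@dataclass
class RmaFit:
    group: str
    slope: float
    intercept: float
    n: int
    se_slope: float
    se_intercept: float
    r: float
    prevalence: str  # RNA-prevalent / DNA-prevalent / neutral


def _rma(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in x")
    r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, r


def rma_fit(
    x,
    y,
    group: str = "",
    n_boot: int = 1000,
    seed=None,
    z: float = 2.0,
) -> RmaFit:
    """Reduced-major-axis regression with bootstrap standard errors.

    ``x``/``y`` are log10 rDNA / log10 rRNA relative abundances. The
    slope is ``sign(r) * sd(y)/sd(x)`` (geometric mean of the y-on-x and
    inverse x-on-y OLS slopes). Standard errors come from ``n_boot``
    case resamples. Prevalence: RNA-prevalent if ``slope - z*SE > 1``,
    DNA-prevalent if ``slope + z*SE < 1``, else neutral; ``z=2`` gives an
    approximate 95% interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    slope, intercept, r = _rma(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    sxb = xb.std(axis=1, ddof=1)
    syb = yb.std(axis=1, ddof=1)
    ok = sxb > 0
    xc = xb - xb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    cov = (xc * yc).sum(axis=1)
    sign = np.where(cov >= 0, 1.0, -1.0)
    slopes = np.where(ok, sign * syb / np.where(ok, sxb, 1.0), np.nan)
    intercepts = yb.mean(axis=1) - slopes * xb.mean(axis=1)
    se_slope = float(np.nanstd(slopes, ddof=1))
    se_intercept = float(np.nanstd(intercepts, ddof=1))
    if slope - z * se_slope > 1.0:
        prevalence = "RNA-prevalent"
    elif slope + z * se_slope < 1.0:
        prevalence = "DNA-prevalent"
    else:
        prevalence = "neutral"
    return RmaFit(
        group=group,
        slope=slope,
        intercept=intercept,
        n=n,
        se_slope=se_slope,
        se_intercept=se_intercept,
        r=r,
        prevalence=prevalence,
    )


def rma_fit_groups(
    series: pd.DataFrame,
    groups: pd.Series,
    n_boot: int = 1000,
    seed=None,
    z: float = 2.0,
    min_points: int = 3,
) -> pd.DataFrame:
    """One pooled RMA fit per taxonomic group from a ratio-series table.

    Pools all non-excluded (OTU, date) points of each group on log10
    scales. Groups with fewer than ``min_points`` usable points are
    skipped.
    """
    usable = series[~series["excluded"]]
    seq = np.random.SeedSequence(seed)
    rows = []
    for g, sub in usable.groupby(groups.loc[usable["otu_id"]].values):
        if len(sub) < min_points:
            continue
        fit = rma_fit(
            np.log10(sub["rdna_rel"]),
            np.log10(sub["rrna_rel"]),
            group=str(g),
            n_boot=n_boot,
            seed=seq.spawn(1)[0],
            z=z,
        )
        rows.append(vars(fit))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quadrants and phase timeline
# ---------------------------------------------------------------------------


def classify_quadrant(
    rdna_rel: float,
    rrna_rel: float,
    rare_thresh: float = RARE_THRESH,
    abundant_thresh: float = ABUNDANT_THRESH,
) -> str:
    """Life-cycle quadrant of one (rDNA, rRNA) relative-abundance point.

    An axis is *rare* at or below ``rare_thresh``, *abundant* above
    ``abundant_thresh``; any point with either axis in the band between
    the thresholds is in ``transition``. Thresholds act on relative
    abundances, so uniform scaling of a sample's counts changes nothing.
    """
    if rdna_rel < 0 or rrna_rel < 0:
        raise ValueError("relative abundances must be non-negative")
    if not 0 < rare_thresh <= abundant_thresh:
        raise ValueError("need 0 < rare_thresh <= abundant_thresh")

    def state(v: float) -> str:
        if v <= rare_thresh:
            return "rare"
        if v > abundant_thresh:
            return "abundant"
        return "mid"

    dna, rna = state(rdna_rel), state(rrna_rel)
    if dna == "rare" and rna == "rare":
        return "rare-low"
    if dna == "rare" and rna == "abundant":
        return "rare-active"
    if dna == "abundant" and rna == "abundant":
        return "abundant-active"
    if dna == "abundant" and rna == "rare":
        return "abundant-low"
    return "transition"


@dataclass
class PhaseTimeline:
    """Quadrant sequence for one OTU with bloom intervals and warnings."""

    otu_id: str
    states: pd.DataFrame  # date, rdna_rel, rrna_rel, quadrant
    bloom_intervals: list[tuple[int, int]] = field(default_factory=list)  # index ranges, inclusive
    warnings: pd.DataFrame | None = None
    senescence_dates: list = field(default_factory=list)

    @property
    def bloom_dates(self) -> list[tuple[object, object]]:
        d = self.states["date"]
        return [(d.iloc[s], d.iloc[e]) for s, e in self.bloom_intervals]


def phase_timeline(
    otu_id: str,
    dates,
    rdna_rel,
    rrna_rel,
    rare_thresh: float = RARE_THRESH,
    abundant_thresh: float = ABUNDANT_THRESH,
) -> PhaseTimeline:
    """Classify one OTU's dated series into quadrants and detect blooms.

    A bloom interval is a maximal run of abundant-active dates. An early
    warning is any earlier date in the gap since the previous bloom where
    the rRNA signal has crossed the abundant threshold while the rDNA
    signal has not (the anticipatory corner of the quadrant plane); its
    lead is reported both in sampling intervals and in days. A bloom
    followed immediately by an abundant-low date is flagged as entering
    senescence (activity collapses before abundance).
    """
    dates = pd.Series(pd.to_datetime(list(dates))).reset_index(drop=True)
    d = np.asarray(rdna_rel, dtype=float)
    r = np.asarray(rrna_rel, dtype=float)
    if not (len(dates) == d.size == r.size):
        raise ValueError("dates, rdna_rel, rrna_rel must align")
    if d.size < 2:
        raise ValueError("need at least 2 dates")
    quad = [classify_quadrant(dv, rv, rare_thresh, abundant_thresh) for dv, rv in zip(d, r)]
    states = pd.DataFrame(
        {"date": dates, "rdna_rel": d, "rrna_rel": r, "quadrant": quad}
    )

    blooms: list[tuple[int, int]] = []
    start = None
    for i, q in enumerate(quad):
        if q == "abundant-active":
            if start is None:
                start = i
        elif start is not None:
            blooms.append((start, i - 1))
            start = None
    if start is not None:
        blooms.append((start, len(quad) - 1))

    warning_rows = []
    prev_end = -1
    for s, e in blooms:
        for t in range(prev_end + 1, s):
            if r[t] > abundant_thresh and d[t] <= abundant_thresh:
                warning_rows.append(
                    {
                        "date": dates.iloc[t],
                        "index": t,
                        "bloom_start": dates.iloc[s],
                        "lead_intervals": s - t,
                        "lead_days": int((dates.iloc[s] - dates.iloc[t]).days),
                    }
                )
        prev_end = e
    warnings = pd.DataFrame(
        warning_rows,
        columns=["date", "index", "bloom_start", "lead_intervals", "lead_days"],
    )

    senescence = [
        dates.iloc[e + 1]
        for s, e in blooms
        if e + 1 < len(quad) and quad[e + 1] == "abundant-low"
    ]
    return PhaseTimeline(
        otu_id=otu_id,
        states=states,
        bloom_intervals=blooms,
        warnings=warnings,
        senescence_dates=senescence,
    )


# ---------------------------------------------------------------------------
# top OTU selection
# ---------------------------------------------------------------------------


def top_abundant_otus(
    table,
    k: int | None = 100,
    min_total_frac: float | None = None,
) -> tuple[list[str], float]:
    """Most abundant OTUs by total reads across all samples.

    Accepts an :class:`~ribophase.io_tables.OtuTable` (counts) or a
    relative-abundance table. Selection takes the top ``k`` by total,
    optionally intersected with a floor on each OTU's share of all
    reads; ties at the boundary break by otu_id (ascending). Returns the
    selected ids and their share of all reads.
    """
    from .io_tables import OtuTable

    values = table.counts if isinstance(table, OtuTable) else table.values
    totals = values.sum(axis=0)
    grand = float(totals.sum())
    order = totals.to_frame("total")
    order["otu_id"] = order.index
    order = order.sort_values(["total", "otu_id"], ascending=[False, True])
    selected = order
    if k is not None:
        selected = selected.head(k)
    if min_total_frac is not None:
        selected = selected[selected["total"] / grand > min_total_frac]
    ids = list(selected.index)
    share = float(selected["total"].sum() / grand) if grand > 0 else math.nan
    return ids, share
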