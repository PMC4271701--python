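"""EHH-based selection scans (EHH, iHS, Rsb), single-marker F_ST and
density-based candidate-region calling.

EHH at extension x is the probability that two random haplotypes carrying
the core allele are identical over the core-to-x interval:
``sum_h C(n_h, 2) / C(n_c, 2)`` over distinct extended haplotypes.
iHH integrates the EHH curve (trapezoid over bp) out to an EHH floor /
maximum extension per side; iHS is ``ln(iHH_ancestral / iHH_derived)``
standardized within derived-allele-frequency bins. Rsb uses an
allele-agnostic site-EHH (normalized to 1 at the core) integrated the
same way, compared between two populations and standardized genome-wide
(median-centered). F_ST uses the Hudson two-population estimator by
default, with a Nei-style (H_T - H_S)/H_T variant.

Note the ancestral-allele assignment drives iHS signs; the default takes
REF (allele code 0) as ancestral and is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hapflow.genodata import MISSING, GenotypePanel, MarkerMap, PanelError

logger = logging.getLogger(__name__)

EHH_FLOOR = 0.05
MAX_EXTENSION = 1_000_000
MAX_GAP = 200_000


@dataclass
class EHHCurve:
    """One-sided EHH decay curves around a core SNP.

    ``left``/``right`` are (distance_bp, ehh) arrays starting at the core
    (distance 0, EHH 1). ``*_edge_truncated`` flags curves that hit the
    chromosome end (or a gap larger than ``max_gap``) before decaying
    below the floor.
    """

    left: np.ndarray
    right: np.ndarray
    left_edge_truncated: bool
    right_edge_truncated: bool


def _pair_fraction(group_sizes: np.ndarray, n: int) -> float:
    if n < 2:
        return 0.0
    num = sum(g * (g - 1) for g in group_sizes if g >= 2)
    return num / (n * (n - 1))


def _extend(
    haps: np.ndarray,
    pos: np.ndarray,
    carriers: np.ndarray,
    core: int,
    lo: int,
    hi: int,
    direction: int,
    floor: float,
    max_extension: int,
    max_gap: int,
) -> tuple[np.ndarray, bool]:
    """Walk outward from the core grouping haplotypes by growing identity."""
    n = len(carriers)
    groups = np.zeros(n, dtype=np.int64)  # all carriers identical at the core
    dist = [0.0]
    ehh = [1.0]
    edge = False
    j = core
    while True:
        nxt = j + direction
        if nxt < lo or nxt >= hi:
            if ehh[-1] >= floor:
                edge = True
            break
        gap = abs(int(pos[nxt]) - int(pos[j]))
        d = abs(int(pos[nxt]) - int(pos[core]))
        if gap > max_gap:
            if ehh[-1] >= floor:
                edge = True  # curve cut by a map gap, not by decay
            break
        if d > max_extension:
            break
        alleles = haps[carriers, nxt].astype(np.int64)
        # a missing call matches nothing: give it a private per-haplotype code
        codes = np.where(alleles >= 0, alleles, 2 + np.arange(n))
        groups = groups * (n + 2) + codes
        _, groups, counts = np.unique(groups, return_inverse=True, return_counts=True)
        e = _pair_fraction(counts, n)
        dist.append(float(d))
        ehh.append(e)
        if e < floor:
            break
        j = nxt
    return np.column_stack([dist, ehh]), edge


def ehh(
    panel_or_haps,
    core: int,
    core_allele: int,
    max_extension: int = MAX_EXTENSION,
    floor: float = 0.0,
    max_gap: int = MAX_GAP,
    positions: np.ndarray | None = None,
    chrom_bounds: tuple[int, int] | None = None,
) -> EHHCurve:
    """EHH decay curve for one core SNP / allele, both directions.

    Accepts a :class:`GenotypePanel` or a raw haplotype matrix with
    ``positions``. Haplotypes missing at the core are excluded; elsewhere
    a missing call acts as a private allele (breaks identity). The curve
    is truncated when EHH < ``floor`` or the extension exceeds
    ``max_extension`` bp or an inter-SNP gap exceeds ``max_gap`` bp.
    """
    if isinstance(panel_or_haps, GenotypePanel):
        haps = panel_or_haps.haplotypes
        positions = panel_or_haps.map.pos
        sl = panel_or_haps.map.chrom_slice(str(panel_or_haps.map.chrom[core]))
        lo, hi = sl.start, sl.stop
    else:
        haps = np.asarray(panel_or_haps)
        if positions is None:
            raise PanelError("positions required with a raw haplotype matrix")
        lo, hi = chrom_bounds if chrom_bounds is not None else (0, haps.shape[1])
    carriers = np.flatnonzero(haps[:, core] == core_allele)
    if len(carriers) < 2:
        raise PanelError(
            f"core allele {core_allele} at site {core} has "
            f"{len(carriers)} carriers (< 2)"
        )
    left, l_edge = _extend(
        haps, positions, carriers, core, lo, hi, -1, floor, max_extension, max_gap
    )
    right, r_edge = _extend(
        haps, positions, carriers, core, lo, hi, +1, floor, max_extension, max_gap
    )
    return EHHCurve(
        left=left, right=right, left_edge_truncated=l_edge, right_edge_truncated=r_edge
    )


def _ihh(curve_side: np.ndarray) -> float:
    """Trapezoid integral of one EHH side over bp distance."""
    if curve_side.shape[0] < 2:
        return 0.0
    return float(np.trapezoid(curve_side[:, 1], curve_side[:, 0]))


def integrated_ehh(
    panel_or_haps,
    core: int,
    core_allele: int,
    floor: float = EHH_FLOOR,
    max_extension: int = MAX_EXTENSION,
    max_gap: int = MAX_GAP,
    **kw,
) -> tuple[float, bool]:
    """iHH = summed trapezoid integrals of both EHH sides; flags edge cuts."""
    c = ehh(
        panel_or_haps,
        core,
        core_allele,
        max_extension=max_extension,
        floor=floor,
        max_gap=max_gap,
        **kw,
    )
    return _ihh(c.left) + _ihh(c.right), c.left_edge_truncated or c.right_edge_truncated


def _bin_standardize(
    raw: np.ndarray, freq: np.ndarray, bin_width: float, min_bin: int
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize raw scores within frequency bins; thin bins are merged.

    Returns (z, merged bin assignment per SNP)."""
    ok = np.isfinite(raw)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    assign = np.clip(np.digitize(freq, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins leftward into their lower neighbour
    order = sorted(set(assign[ok]))
    remap = {b: b for b in order}
    counts = {b: int(((assign == b) & ok).sum()) for b in order}
    for i, b in enumerate(order):
        if counts[b] < min_bin and i + 1 < len(order):
            tgt = order[i + 1]
            counts[tgt] += counts[b]
            counts[b] = 0
            for src, dst in remap.items():
                if dst == b:
                    remap[src] = tgt
            logger.info("merged frequency bin %d (sparse) into %d", b, tgt)
    merged = np.array([remap.get(b, b) for b in assign])
    z = np.full_like(raw, np.nan)
    for b in set(merged[ok]):
        sel = ok & (merged == b)
        if sel.sum() < 2:
            continue
        mu, sd = raw[sel].mean(), raw[sel].std(ddof=1)
        if sd > 0:
            z[sel] = (raw[sel] - mu) / sd
    return z, merged


def ihs(
    panel: GenotypePanel,
    ancestral: np.ndarray | None = None,
    maf_floor: float = 0.05,
    bin_width: float = 0.05,
    min_bin: int = 10,
    floor: float = EHH_FLOOR,
    max_extension: int = MAX_EXTENSION,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Standardized iHS per SNP.

    ``ancestral`` gives the ancestral allele code (0/1) per SNP; default
    all-REF. SNPs with derived frequency outside [maf_floor, 1-maf_floor]
    or with an edge-truncated integral are excluded (NaN, flagged).
    Returns a frame with chrom, pos, id, daf, raw, ihs, excluded.
    """
    m = panel.n_sites
    if ancestral is None:
        ancestral = np.zeros(m, dtype=np.int8)
    ancestral = np.asarray(ancestral)
    if len(ancestral) != m:
        raise PanelError("ancestral allele vector length mismatch")
    haps = panel.haplotypes
    raw = np.full(m, np.nan)
    daf = np.full(m, np.nan)
    excluded = np.zeros(m, dtype=bool)
    for j in range(m):
        anc = int(ancestral[j])
        der = 1 - anc
        col = haps[:, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        if n_obs == 0:
            excluded[j] = True
            continue
        f_der = float((col[obs] == der).sum() / n_obs)
        daf[j] = f_der
        if f_der < maf_floor or f_der > 1 - maf_floor:
            excluded[j] = True
            continue
        ihh_a, cut_a = integrated_ehh(
            panel, j, anc, floor=floor, max_extension=max_extension, max_gap=max_gap
        )
        ihh_d, cut_d = integrated_ehh(
            panel, j, der, floor=floor, max_extension=max_extension, max_gap=max_gap
        )
        if cut_a or cut_d or ihh_a <= 0 or ihh_d <= 0:
            excluded[j] = True
            continue
        raw[j] = math.log(ihh_a / ihh_d)
    z, bins = _bin_standardize(raw, daf, bin_width, min_bin)
    return pd.DataFrame(
        {
            "chrom": panel.map.chrom,
            "pos": panel.map.pos,
            "id": panel.map.ids,
            "daf": daf,
            "raw": raw,
            "ihs": z,
            "bin": bins,
            "excluded": excluded,
        }
    )


def _site_ehh_integral(
    haps: np.ndarray,
    positions: np.ndarray,
    lo: int,
    hi: int,
    core: int,
    floor: float,
    max_extension: int,
    max_gap: int,
) -> tuple[float, bool]:
    """Allele-agnostic integrated site-EHH, normalized to 1 at the core."""
    col = haps[:, core]
    keep = np.flatnonzero(col != MISSING)
    n = len(keep)
    if n < 2:
        return 0.0, True
    _, counts0 = np.unique(col[keep], return_counts=True)
    h0 = _pair_fraction(counts0, n)
    if h0 == 0:
        return 0.0, True

    def walk(direction: int) -> tuple[np.ndarray, bool]:
        groups = col[keep].astype(np.int64) + 1
        _, groups, counts = np.unique(groups, return_inverse=True, return_counts=True)
        dist, es = [0.0], [1.0]
        edge = False
        j = core
        while True:
            nxt = j + direction
            if nxt < lo or nxt >= hi:
                edge = es[-1] >= floor
                break
            gap = abs(int(positions[nxt]) - int(positions[j]))
            d = abs(int(positions[nxt]) - int(positions[core]))
            if gap > max_gap:
                edge = es[-1] >= floor
                break
            if d > max_extension:
                break
            alleles = haps[keep, nxt].astype(np.int64)
            codes = np.where(alleles >= 0, alleles, 2 + np.arange(n))
            groups = groups * (n + 2) + codes
            _, groups, counts = np.unique(
                groups, return_inverse=True, return_counts=True
            )
            e = _pair_fraction(counts, n) / h0
            dist.append(float(d))
            es.append(e)
            if e < floor:
                break
            j = nxt
        return np.column_stack([dist, es]), edge

    left, le = walk(-1)
    right, re_ = walk(+1)
    return _ihh(left) + _ihh(right), (le or re_)


def rsb(
    panel_1: GenotypePanel,
    panel_2: GenotypePanel,
    floor: float = EHH_FLOOR,
    max_extension: int = MAX_EXTENSION,
    max_gap: int = MAX_GAP,
) -> pd.DataFrame:
    """Standardized ln(iES_1 / iES_2) per SNP between two populations.

    Both panels must share the marker map. Raw log-ratios are centered on
    their median and scaled by their standard deviation.
    """
    if panel_1.n_sites != panel_2.n_sites or not np.array_equal(
        panel_1.map.pos, panel_2.map.pos
    ):
        raise PanelError("panels do not share a marker map")
    m = panel_1.n_sites
    raw = np.full(m, np.nan)
    for c in panel_1.map.chromosomes:
        sl = panel_1.map.chrom_slice(c)
        for j in range(sl.start, sl.stop):
            ies1, cut1 = _site_ehh_integral(
                panel_1.haplotypes, panel_1.map.pos, sl.start, sl.stop, j,
                floor, max_extension, max_gap,
            )
            ies2, cut2 = _site_ehh_integral(
                panel_2.haplotypes, panel_2.map.pos, sl.start, sl.stop, j,
                floor, max_extension, max_gap,
            )
            if cut1 or cut2 or ies1 <= 0 or ies2 <= 0:
                continue
            raw[j] = math.log(ies1 / ies2)
    ok = np.isfinite(raw)
    z = np.full(m, np.nan)
    if ok.sum() >= 2:
        sd = raw[ok].std(ddof=1)
        if sd > 0:
            z[ok] = (raw[ok] - np.median(raw[ok])) / sd
    return pd.DataFrame(
        {
            "chrom": panel_1.map.chrom,
            "pos": panel_1.map.pos,
            "id": panel_1.map.ids,
            "raw": raw,
            "rsb": z,
        }
    )


def _allele_freqs(panel: GenotypePanel, population: str) -> tuple[np.ndarray, np.ndarray]:
    haps = panel.population_haplotypes(population)
    obs = haps != MISSING
    n = obs.sum(axis=0)
    alt = np.where(obs, haps, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def fst(
    panel: GenotypePanel,
    pop_a: str,
    pop_b: str,
    estimator: str = "hudson",
) -> tuple[pd.DataFrame, dict]:
    """Per-SNP F_ST between two populations plus summary means.

    ``hudson`` (default) uses the two-population estimator with
    finite-sample corrections; ``nei`` uses (H_T - H_S) / H_T from the
    sample frequencies. Sites monomorphic in the pooled sample are NaN
    and excluded from the means; negative Hudson estimates are kept as
    computed, with a truncated-at-zero mean also reported.
    """
    if estimator not in ("hudson", "nei"):
        raise PanelError(f"unknown estimator {estimator!r}")
    p1, n1 = _allele_freqs(panel, pop_a)
    p2, n2 = _allele_freqs(panel, pop_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
                - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
            )
            den = p1 * (1 - p2) + p2 * (1 - p1)
        else:
            hs = p1 * (1 - p1) + p2 * (1 - p2)  # mean within-pop 2p(1-p)/2*2
            pbar = (p1 + p2) / 2
            ht = 2 * pbar * (1 - pbar)
            num, den = ht - hs, ht
        values = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    n_mono = int(np.sum(~(np.asarray(den) > 0)))
    if n_mono:
        logger.info("excluded %d pooled-monomorphic sites from F_ST mean", n_mono)
    ok = np.isfinite(values)
    summary = {
        "mean": float(values[ok].mean()) if ok.any() else float("nan"),
        "mean_truncated": float(np.maximum(values[ok], 0).mean()) if ok.any() else float("nan"),
        "ratio_of_averages": (
            float(np.nansum(np.where(ok, num, 0)) / np.nansum(np.where(ok, den, 0)))
            if ok.any()
            else float("nan")
        ),
        "n_sites": int(ok.sum()),
        "n_excluded": n_mono,
    }
    frame = pd.DataFrame(
        {
            "chrom": panel.map.chrom,
            "pos": panel.map.pos,
            "id": panel.map.ids,
            "fst": values,
        }
    )
    return frame, summary


@dataclass(frozen=True)
class Region:
    """Candidate selection region from score density."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_pos: int
    max_score: float
    n_significant: int


def candidate_regions(
    scores: np.ndarray,
    mmap: MarkerMap,
    score_threshold: float = 3.0,
    min_hits: int = 3,
    span: int = 1_000_000,
    use_abs: bool = True,
) -> list[Region]:
    """Call regions of dense extreme scores.

    A seed is any ``min_hits`` consecutive significant SNPs (consecutive
    among significant SNPs, |score| > threshold) spanning <= ``span`` bp;
    overlapping seeds merge into maximal regions. Region bounds are the
    bp of the first/last significant SNP; the peak is the max-|score| SNP
    within the region's span.
    """
    s = np.abs(scores) if use_abs else np.asarray(scores, dtype=float)
    regions: list[Region] = []
    for c in mmap.chromosomes:
        sl = mmap.chrom_slice(c)
        sig = np.flatnonzero(
            np.where(np.isfinite(s[sl]), s[sl], -np.inf) > score_threshold
        ) + sl.start
        if len(sig) < min_hits:
            continue
        pos = mmap.pos[sig]
        seeds = [
            (i, i + min_hits - 1)
            for i in range(len(sig) - min_hits + 1)
            if pos[i + min_hits - 1] - pos[i] <= span
        ]
        if not seeds:
            continue
        merged: list[list[int]] = [list(seeds[0])]
        for a, b in seeds[1:]:
            if a <= merged[-1][1]:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            members = sig[a : b + 1]
            in_span = slice(members[0], members[-1] + 1)
            vals = np.where(np.isfinite(s[in_span]), s[in_span], -np.inf)
            peak_rel = int(np.argmax(vals))
            peak_idx = members[0] + peak_rel
            regions.append(
                Region(
                    chrom=c,
                    start_bp=int(mmap.pos[members[0]]),
                    end_bp=int(mmap.pos[members[-1]]),
                    peak_pos=int(mmap.pos[peak_idx]),
                    max_score=float(s[peak_idx]),
                    n_significant=b - a + 1,
                )
            )
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "peak_pos": r.peak_pos,
                "max_score": r.max_score,
                "n_significant": r.n_significant,
            }
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "peak_pos", "max_score", "n_significant"],
    )


def regions_to_bed(regions: list[Region], path) -> None:
    """BED (0-based half-open) export of candidate regions."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                f"max_score={r.max_score:.3f};peak={r.peak_pos}\n"
            )
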