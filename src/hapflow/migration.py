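"""Haplotype-migration statistic for admixed cohorts.

For each parental breed and each SNP window, the breed's most frequent
window haplotype is located in the admixed cohort. Local ancestry gives
the proportion ``p_B`` of that breed's ancestry at the window, so the
haplotype's expected admixed frequency is ``p_B * freq_B``. The signed
difference between observed and expected frequency, standardized per
breed genome-wide, flags windows where a parental haplotype is over- or
under-represented relative to ancestry alone.

Sign convention: the default score is ``observed - expected`` (positive
means the haplotype is more common in the admixed cohort than ancestry
predicts). A ``literal`` convention, ``p_B * observed - freq_B``, is
available; the two do not agree and only the default matches the
positive-equals-excess reading used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from hapflow.genodata import GenotypePanel, PanelError
from hapflow.hapwin import (
    HaplotypeSpectrum,
    WindowGrid,
    haplotype_spectrum,
    most_frequent,
    shared_frequency,
)
from hapflow.lancestry import AncestryField

SIGN_DEFAULT = "observed-minus-expected"
SIGN_LITERAL = "literal"


@dataclass(frozen=True)
class MigrationRecord:
    """One (breed, window) comparison; mirrors one row of the scan table."""

    breed: str
    window: int
    chrom: str
    start_bp: int
    end_bp: int
    haplotype: str
    freq_parental: float
    p_ancestry: float
    expected: float
    observed: float
    freq_change: float
    z: float = float("nan")


def expected_frequency(p_ancestry: float, freq_parental: float) -> float:
    """Expected admixed frequency of a parental haplotype: p_B * freq_B."""
    for name, v in (("p_ancestry", p_ancestry), ("freq_parental", freq_parental)):
        if not 0.0 <= v <= 1.0:
            raise PanelError(f"{name} must be in [0, 1], got {v}")
    return p_ancestry * freq_parental


def migration_difference(expected: float, observed: float) -> float:
    """Signed frequency change, observed minus expected."""
    for name, v in (("expected", expected), ("observed", observed)):
        if not 0.0 <= v <= 1.0:
            raise PanelError(f"{name} must be in [0, 1], got {v}")
    return observed - expected


def literal_migration_difference(
    p_ancestry: float, observed: float, freq_parental: float
) -> float:
    """The alternative printed convention p(B) * freq(K|B) - freq(B)."""
    return p_ancestry * observed - freq_parental


def standardize_scores(diffs: np.ndarray) -> np.ndarray:
    """z = (d - mean(d)) / sd(d) with the sample (n-1) standard deviation."""
    d = np.asarray(diffs, dtype=float)
    finite = d[np.isfinite(d)]
    if finite.size < 2:
        raise PanelError(f"need >= 2 finite scores, got {finite.size}")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise PanelError("zero variance in frequency changes; cannot standardize")
    return (d - finite.mean()) / sd


def map_ancestry_to_windows(
    ancestry: AncestryField, grid: WindowGrid
) -> np.ndarray:
    """p(B) per scan window: SNP-overlap-weighted mean over training windows.

    Returns (n_scan_windows, K); scan windows with no overlapping training
    window get NaN rows.
    """
    mean_prob = ancestry.mean_probability()  # (n_train, K)
    k = mean_prob.shape[1]
    out = np.full((len(grid), k), np.nan)
    train = list(ancestry.grid)
    for i, w in enumerate(grid):
        weights, probs = [], []
        for j, t in enumerate(train):
            if t.chrom != w.chrom:
                continue
            overlap = min(w.stop, t.stop) - max(w.start, t.start)
            if overlap > 0:
                weights.append(overlap)
                probs.append(mean_prob[j])
        if weights:
            wts = np.asarray(weights, dtype=float)
            out[i] = (wts[:, None] * np.asarray(probs)).sum(axis=0) / wts.sum()
    return out


def migration_scan(
    parental: GenotypePanel,
    admixed: GenotypePanel,
    ancestry: AncestryField,
    grid: WindowGrid,
    min_parental_freq: float = 0.0,
    sign: str = SIGN_DEFAULT,
    breeds: list[str] | None = None,
    admixed_population: str | None = None,
) -> list[MigrationRecord]:
    """Score every (breed, window) pair; standardize per breed genome-wide.

    Windows where the breed's modal haplotype is absent from the admixed
    cohort are excluded from scoring (the haplotype must be shared to be
    compared). Standardization is per breed over all its scored windows.
    """
    if admixed.n_haplotypes == 0:
        raise PanelError("empty admixed cohort")
    if sign not in (SIGN_DEFAULT, SIGN_LITERAL):
        raise PanelError(f"unknown sign convention {sign!r}")
    if breeds is None:
        breeds = list(ancestry.breeds)
    if admixed_population is None:
        pops = admixed.manifest.populations
        if len(pops) != 1:
            raise PanelError("admixed panel must have exactly one population "
                             "or admixed_population must be given")
        admixed_population = pops[0]

    par_spec = haplotype_spectrum(parental, grid, populations=breeds)
    adm_spec = haplotype_spectrum(admixed, grid, populations=[admixed_population])
    p_b_matrix = map_ancestry_to_windows(ancestry, grid)

    records: list[MigrationRecord] = []
    for b_i, breed in enumerate(breeds):
        unscored: list[MigrationRecord] = []
        for w_i, win in enumerate(grid):
            if par_spec.totals.get((w_i, breed), 0) == 0:
                continue
            hap, freq_b = most_frequent(par_spec, w_i, breed)
            if freq_b < min_parental_freq:
                continue
            observed = shared_frequency(adm_spec, w_i, hap, admixed_population)
            if observed == 0.0:
                continue  # inclusion rule: haplotype must be found in crossbreds
            p_b = float(p_b_matrix[w_i, b_i])
            if not np.isfinite(p_b):
                continue
            exp = expected_frequency(p_b, freq_b)
            if sign == SIGN_DEFAULT:
                diff = migration_difference(exp, observed)
            else:
                diff = literal_migration_difference(p_b, observed, freq_b)
            unscored.append(
                MigrationRecord(
                    breed=breed,
                    window=w_i,
                    chrom=win.chrom,
                    start_bp=win.start_bp,
                    end_bp=win.end_bp,
                    haplotype=hap,
                    freq_parental=freq_b,
                    p_ancestry=p_b,
                    expected=exp,
                    observed=observed,
                    freq_change=diff,
                )
            )
        if len(unscored) >= 2:
            z = standardize_scores([r.freq_change for r in unscored])
            records.extend(replace(r, z=float(zi)) for r, zi in zip(unscored, z))
        else:
            records.extend(unscored)
    return records


def call_migration_outliers(
    records: list[MigrationRecord], threshold: float = 3.0
) -> list[MigrationRecord]:
    """Records with |z| >= threshold, sorted by |z| descending."""
    hits = [r for r in records if np.isfinite(r.z) and abs(r.z) >= threshold]
    return sorted(hits, key=lambda r: -abs(r.z))


def merge_outlier_regions(
    records: list[MigrationRecord],
) -> list[dict]:
    """Merge overlapping outlier windows per breed into maximal bp regions.

    Adjacent step<size windows share SNPs, so runs of outliers are fused;
    each region reports the union bp span and its extreme-|z| member.
    """
    out: list[dict] = []
    by_breed: dict[str, list[MigrationRecord]] = {}
    for r in records:
        by_breed.setdefault(r.breed, []).append(r)
    for breed, recs in by_breed.items():
        recs = sorted(recs, key=lambda r: (r.chrom, r.start_bp))
        current: list[MigrationRecord] = []
        for r in recs + [None]:
            if current and (
                r is None
                or r.chrom != current[-1].chrom
                or r.start_bp > current[-1].end_bp
            ):
                peak = max(current, key=lambda x: abs(x.z))
                out.append(
                    {
                        "breed": breed,
                        "chrom": current[0].chrom,
                        "start_bp": current[0].start_bp,
                        "end_bp": max(c.end_bp for c in current),
                        "n_windows": len(current),
                        "max_abs_z": abs(peak.z),
                        "z": peak.z,
                        "freq_parental": peak.freq_parental,
                        "p_ancestry": peak.p_ancestry,
                        "expected": peak.expected,
                        "observed": peak.observed,
                        "freq_change": peak.freq_change,
                    }
                )
                current = []
            if r is not None:
                current.append(r)
    return sorted(out, key=lambda d: (d["breed"], d["chrom"], d["start_bp"]))


def records_to_frame(records: list[MigrationRecord]) -> pd.DataFrame:
    """Tabular export: one row per scored (breed, window)."""
    rows = [
        {
            "breed": r.breed,
            "chrom": r.chrom,
            "region_start_mb": r.start_bp / 1e6,
            "region_end_mb": r.end_bp / 1e6,
            "haplotype": r.haplotype,
            "freq_parental": r.freq_parental,
            "p_ancestry": r.p_ancestry,
            "expected": r.expected,
            "observed": r.observed,
            "freq_change": r.freq_change,
            "z": r.z,
            "display_flag": r.freq_parental > 0.3 or r.observed > 0.3,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "breed",
            "chrom",
            "region_start_mb",
            "region_end_mb",
            "haplotype",
            "freq_parental",
            "p_ancestry",
            "expected",
            "observed",
            "freq_change",
            "z",
            "display_flag",
        ],
    )
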