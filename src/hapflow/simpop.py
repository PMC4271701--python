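"""Synthetic admixed-cohort generator with known ancestry tracts.

Parental breeds are simulated under the Balding–Nichols model: ancestral
allele frequencies uniform on (0.05, 0.95), breed-specific frequencies
Beta-distributed around them with drift parameter F, and haplotypes
sampled site-independently within breeds. Admixed haplotypes are built by
a Markov ancestry process along the map (switch probability
``1 - exp(-g * d)`` between adjacent sites at genetic distance ``d``
morgans) with one donor haplotype per tract, so parental window
haplotypes migrate intact. A planted haplotype-frequency shift
(:func:`inject_haplotype_selection`) creates the signal the migration
statistic is designed to detect.

All operations are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from hapflow.genodata import (
    ROLE_ADMIXED,
    ROLE_PARENTAL,
    GenotypePanel,
    MarkerMap,
    PanelError,
    SampleManifest,
)
from hapflow.hapwin import Window, window_haplotype_strings

DEFAULT_RECOMB_RATE = 1e-8  # morgans / bp == 1 cM/Mb


@dataclass
class SimConfig:
    """Parameters for the synthetic study design."""

    breed_names: tuple[str, ...] = ("HOL", "GNS", "NRC")
    n_per_breed: int = 40
    n_admixed: int = 100
    n_sites: int = 2000
    chrom_lengths: tuple[int, ...] = (100_000_000,)
    divergence_f: float = 0.1
    admix_props: tuple[float, ...] = (0.53, 0.32, 0.15)
    generations: int = 5
    recomb_rate: float = DEFAULT_RECOMB_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.admix_props) != len(self.breed_names):
            raise PanelError("admix_props length must equal number of breeds")
        if abs(sum(self.admix_props) - 1.0) > 1e-9:
            raise PanelError(f"admix_props must sum to 1, got {sum(self.admix_props)}")
        if not 0 < self.divergence_f < 1:
            raise PanelError(f"divergence F must be in (0,1), got {self.divergence_f}")
        if self.generations < 1:
            raise PanelError("generations must be >= 1")
        if min(self.admix_props) < 0:
            raise PanelError("admix_props must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("breed_names", "chrom_lengths", "admix_props"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "breed_names": list(self.breed_names),
            "n_per_breed": self.n_per_breed,
            "n_admixed": self.n_admixed,
            "n_sites": self.n_sites,
            "chrom_lengths": list(self.chrom_lengths),
            "divergence_f": self.divergence_f,
            "admix_props": list(self.admix_props),
            "generations": self.generations,
            "recomb_rate": self.recomb_rate,
            "seed": self.seed,
        }


@dataclass
class Tract:
    """One ancestry tract of an admixed haplotype (bp span is inclusive-exclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    breed: int
    donor_row: int = -1


@dataclass
class SimTruth:
    """Ground truth for a simulated cohort.

    ``tracts[h]`` lists the tracts tiling haplotype ``h``'s genome;
    ``ancestry[h, j]`` is the breed index at site ``j`` (admixed truth
    only). ``breed_freqs`` holds the realized per-breed per-site allele
    frequencies of the parental draw.
    """

    breed_names: tuple[str, ...]
    ancestral_freqs: np.ndarray | None = None
    breed_freqs: np.ndarray | None = None
    tracts: list[list[Tract]] = field(default_factory=list)
    ancestry: np.ndarray | None = None
    selection_plan: list[dict] = field(default_factory=list)

    def ancestry_proportions(self) -> np.ndarray:
        """Genome-wide site-weighted ancestry fractions, per breed."""
        if self.ancestry is None:
            raise PanelError("no admixed ancestry recorded")
        k = len(self.breed_names)
        counts = np.array([(self.ancestry == b).sum() for b in range(k)], dtype=float)
        return counts / self.ancestry.size

    def write_tracts_tsv(self, path: str | Path, manifest: SampleManifest) -> None:
        rows = []
        for h, tracts in enumerate(self.tracts):
            sample = manifest.sample_id[h // 2]
            for t in tracts:
                rows.append(
                    {
                        "sample": sample,
                        "hap": h % 2,
                        "chrom": t.chrom,
                        "start_bp": t.start_bp,
                        "end_bp": t.end_bp,
                        "breed": self.breed_names[t.breed],
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced SNPs allocated to chromosomes proportional to length."""
    total = sum(config.chrom_lengths)
    counts = [
        max(1, round(config.n_sites * length / total))
        for length in config.chrom_lengths
    ]
    # adjust rounding drift on the last chromosome
    counts[-1] += config.n_sites - sum(counts)
    chrom, pos = [], []
    for i, (length, n) in enumerate(zip(config.chrom_lengths, counts)):
        spacing = length / (n + 1)
        chrom.extend([str(i + 1)] * n)
        pos.extend(int(round(spacing * (j + 1))) for j in range(n))
    return MarkerMap(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ids=np.array([f"snp{i}" for i in range(len(pos))], dtype=object),
        ref=np.array(["A"] * len(pos), dtype=object),
        alt=np.array(["C"] * len(pos), dtype=object),
    )


def simulate_parental_panels(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw diverged parental breed panels under Balding–Nichols drift."""
    rng = np.random.default_rng([config.seed, 0])
    mmap = _marker_map(config)
    m = len(mmap)
    k = len(config.breed_names)
    f = config.divergence_f
    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = (1.0 - f) / f
    breed_freqs = rng.beta(p_anc * a, (1.0 - p_anc) * a, size=(k, m))

    n = config.n_per_breed
    hap = np.empty((2 * n * k, m), dtype=np.int8)
    records = []
    for b, name in enumerate(config.breed_names):
        draws = rng.random((2 * n, m)) < breed_freqs[b]
        hap[2 * n * b : 2 * n * (b + 1)] = draws.astype(np.int8)
        records.extend((f"{name}_{i}", name, ROLE_PARENTAL) for i in range(n))
    manifest = SampleManifest.from_records(records)
    truth = SimTruth(
        breed_names=config.breed_names,
        ancestral_freqs=p_anc,
        breed_freqs=breed_freqs,
    )
    return GenotypePanel(haplotypes=hap, map=mmap, manifest=manifest), truth


def simulate_admixed(
    parental: GenotypePanel, config: SimConfig
) -> tuple[GenotypePanel, SimTruth]:
    """Mosaic admixed haplotypes from parental panels with truth tracts.

    Each haplotype follows a Markov ancestry chain along the map: initial
    breed ~ pi; between adjacent sites at genetic distance ``d`` morgans
    the chain switches with probability ``1 - exp(-g d)`` to a breed drawn
    afresh from pi (possibly the same breed, which still starts a new
    tract with a new donor). Within a tract alleles are copied verbatim
    from one uniformly chosen parental haplotype of the tract's breed.
    """
    for name in config.breed_names:
        if name not in parental.manifest.populations:
            raise PanelError(f"parental panel lacks breed {name!r}")
    rng = np.random.default_rng([config.seed, 1])
    mmap = parental.map
    m = len(mmap)
    k = len(config.breed_names)
    pi = np.asarray(config.admix_props, dtype=float)
    breed_rows = {
        b: parental.haplotype_rows(name)
        for b, name in enumerate(config.breed_names)
    }

    # per-gap switch probability; gaps across chromosome boundaries force
    # an independent restart (probability handled via chrom bookkeeping)
    gaps_bp = np.diff(mmap.pos).astype(float)
    same_chrom = mmap.chrom[1:] == mmap.chrom[:-1]
    d_morgans = gaps_bp * config.recomb_rate
    p_switch = np.where(same_chrom, 1.0 - np.exp(-config.generations * d_morgans), 1.0)

    n_hap = 2 * config.n_admixed
    hap = np.empty((n_hap, m), dtype=np.int8)
    ancestry = np.empty((n_hap, m), dtype=np.int8)
    all_tracts: list[list[Tract]] = []

    chrom_of = np.asarray(mmap.chrom)
    switch_draws = rng.random((n_hap, m - 1)) < p_switch if m > 1 else np.zeros((n_hap, 0), bool)
    for h in range(n_hap):
        breaks = np.flatnonzero(switch_draws[h]) + 1  # first site of each new tract
        starts = np.concatenate([[0], breaks])
        stops = np.concatenate([breaks, [m]])
        breeds = rng.choice(k, size=len(starts), p=pi)
        tracts: list[Tract] = []
        for s, e, b in zip(starts, stops, breeds):
            donor = int(rng.choice(breed_rows[b]))
            hap[h, s:e] = parental.haplotypes[donor, s:e]
            ancestry[h, s:e] = b
            # bp bounds: midpoints between flanking sites, chromosome-clipped
            c = str(chrom_of[s])
            start_bp = (
                1
                if s == 0 or chrom_of[s - 1] != c
                else int((mmap.pos[s - 1] + mmap.pos[s]) // 2 + 1)
            )
            end_bp = (
                int(config.chrom_lengths[int(c) - 1])
                if e == m or chrom_of[e] != c
                else int((mmap.pos[e - 1] + mmap.pos[e]) // 2)
            )
            tracts.append(Tract(chrom=c, start_bp=start_bp, end_bp=end_bp, breed=int(b), donor_row=donor))
        all_tracts.append(tracts)

    manifest = SampleManifest.from_records(
        [(f"ADM_{i}", "Crossbred", ROLE_ADMIXED) for i in range(config.n_admixed)]
    )
    truth = SimTruth(
        breed_names=config.breed_names,
        tracts=all_tracts,
        ancestry=ancestry,
    )
    return GenotypePanel(haplotypes=hap, map=mmap, manifest=manifest), truth


def inject_haplotype_selection(
    admixed: GenotypePanel,
    truth: SimTruth,
    window: Window,
    breed: str,
    delta: float,
    seed: int,
    parental: GenotypePanel,
) -> tuple[GenotypePanel, SimTruth]:
    """Plant a haplotype-frequency shift of ``delta`` in one window.

    A fraction ``delta`` of admixed haplotypes, drawn uniformly from those
    not already carrying the breed's most frequent window haplotype, have
    the window's alleles overwritten with it; truth ancestry is relabeled
    within the window. The observed window frequency of that haplotype
    rises by ~``delta``.
    """
    if delta < 0:
        raise PanelError(f"delta must be >= 0, got {delta}")
    if delta == 0:
        return admixed, truth
    b = truth.breed_names.index(breed) if breed in truth.breed_names else None
    if b is None:
        raise PanelError(f"unknown breed {breed!r}")
    strings, _ = window_haplotype_strings(
        parental.population_haplotypes(breed), window
    )
    if not strings:
        raise PanelError(f"breed {breed!r} has no complete haplotypes in window")
    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    target = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))[0]
    target_alleles = np.array([int(c) for c in target], dtype=np.int8)

    block = admixed.haplotypes[:, window.start : window.stop]
    carriers = (block == target_alleles).all(axis=1)
    non_carriers = np.flatnonzero(~carriers)
    n_inject = int(round(delta * admixed.n_haplotypes))
    if n_inject > len(non_carriers):
        raise PanelError(
            f"delta {delta} requires {n_inject} haplotypes but only "
            f"{len(non_carriers)} non-carriers exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(non_carriers, size=n_inject, replace=False)

    new_hap = admixed.haplotypes.copy()
    new_hap[np.ix_(chosen, np.arange(window.start, window.stop))] = target_alleles
    new_truth = copy.deepcopy(truth)
    if new_truth.ancestry is not None:
        new_truth.ancestry[chosen, window.start : window.stop] = b
    for h in chosen:
        new_truth.tracts[h] = _relabel_tracts(
            new_truth.tracts[h], window, b
        )
    new_truth.selection_plan.append(
        {
            "chrom": window.chrom,
            "start_bp": window.start_bp,
            "end_bp": window.end_bp,
            "breed": breed,
            "delta": delta,
            "haplotype": target,
            "n_injected": n_inject,
        }
    )
    return (
        GenotypePanel(
            haplotypes=new_hap,
            map=admixed.map,
            manifest=admixed.manifest,
            log=dict(admixed.log),
        ),
        new_truth,
    )


def _relabel_tracts(tracts: list[Tract], window: Window, breed: int) -> list[Tract]:
    """Split tracts at the window's bp bounds and relabel the interior."""
    lo, hi = window.start_bp, window.end_bp
    out: list[Tract] = []
    for t in tracts:
        if t.chrom != window.chrom or t.end_bp < lo or t.start_bp > hi:
            out.append(t)
            continue
        if t.start_bp < lo:
            out.append(Tract(t.chrom, t.start_bp, lo - 1, t.breed, t.donor_row))
        out.append(
            Tract(t.chrom, max(t.start_bp, lo), min(t.end_bp, hi), breed, -1)
        )
        if t.end_bp > hi:
            out.append(Tract(t.chrom, hi + 1, t.end_bp, t.breed, t.donor_row))
    merged: list[Tract] = []
    for t in out:
        if merged and merged[-1].chrom == t.chrom and merged[-1].breed == t.breed \
                and merged[-1].donor_row == t.donor_row \
                and merged[-1].end_bp + 1 == t.start_bp:
            merged[-1] = Tract(t.chrom, merged[-1].start_bp, t.end_bp, t.breed, t.donor_row)
        else:
            merged.append(t)
    return merged


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenotypePanel, GenotypePanel, SimTruth, SimTruth]:
    """Convenience: parental panels + admixed cohort in one call."""
    parental, parental_truth = simulate_parental_panels(config)
    admixed, admixed_truth = simulate_admixed(parental, config)
    return parental, admixed, parental_truth, admixed_truth


def merge_panels(parental: GenotypePanel, admixed: GenotypePanel) -> GenotypePanel:
    """Stack parental and admixed panels sharing one marker map."""
    if len(parental.map) != len(admixed.map) or not np.array_equal(
        parental.map.pos, admixed.map.pos
    ):
        raise PanelError("panels do not share a marker map")
    manifest = SampleManifest(
        sample_id=parental.manifest.sample_id + admixed.manifest.sample_id,
        population=parental.manifest.population + admixed.manifest.population,
        role=parental.manifest.role + admixed.manifest.role,
    )
    return GenotypePanel(
        haplotypes=np.vstack([parental.haplotypes, admixed.haplotypes]),
        map=parental.map,
        manifest=manifest,
    )
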