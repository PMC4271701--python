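"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hapflow.genodata import (
    ROLE_ADMIXED,
    ROLE_PARENTAL,
    GenotypePanel,
    MarkerMap,
    SampleManifest,
)


def make_map(positions, chrom="1"):
    positions = list(positions)
    if isinstance(chrom, str):
        chroms = [chrom] * len(positions)
    else:
        chroms = list(chrom)
    return MarkerMap(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ids=np.array([f"s{i}" for i in range(len(positions))], dtype=object),
        ref=np.array(["A"] * len(positions), dtype=object),
        alt=np.array(["C"] * len(positions), dtype=object),
    )


def make_panel(haps, positions=None, populations=None, roles=None, chrom="1"):
    """Build a GenotypePanel from a raw haplotype matrix (rows = haplotypes)."""
    haps = np.asarray(haps, dtype=np.int8)
    n_samples = haps.shape[0] // 2
    assert haps.shape[0] == 2 * n_samples, "need an even number of haplotype rows"
    if positions is None:
        positions = [1000 * (i + 1) for i in range(haps.shape[1])]
    if populations is None:
        populations = ["P"] * n_samples
    if roles is None:
        roles = [ROLE_PARENTAL] * n_samples
    manifest = SampleManifest.from_records(
        [(f"smp{i}", populations[i], roles[i]) for i in range(n_samples)]
    )
    return GenotypePanel(haplotypes=haps, map=make_map(positions, chrom), manifest=manifest)


@pytest.fixture
def toy_panel():
    """5 samples (10 haplotypes) x 20 sites, two populations, no missing."""
    rng = np.random.default_rng(42)
    haps = rng.integers(0, 2, size=(10, 20))
    return make_panel(
        haps,
        populations=["A", "A", "A", "B", "B"],
    )


# ---------------------------------------------------------------- oracles

def brute_force_maf_keep(panel, threshold, mode="any"):
    """Per-site keep decision by direct per-population frequency tally."""
    keep = []
    pops = panel.manifest.populations
    for j in range(panel.n_sites):
        passes = []
        for pop in pops:
            col = panel.population_haplotypes(pop)[:, j]
            obs = col[col >= 0]
            if len(obs) == 0:
                passes.append(False)
                continue
            f = obs.sum() / len(obs)
            passes.append(min(f, 1 - f) > threshold)
        keep.append(any(passes) if mode == "any" else all(passes))
    return np.array(keep)


def brute_force_ehh(haps, core, allele, target, positions=None):
    """All-pairs identity fraction over the inclusive span core..target."""
    carriers = [h for h in range(haps.shape[0]) if haps[h, core] == allele]
    lo, hi = min(core, target), max(core, target)
    n_pairs = 0
    n_same = 0
    for a, b in itertools.combinations(carriers, 2):
        n_pairs += 1
        seg_a = haps[a, lo : hi + 1]
        seg_b = haps[b, lo : hi + 1]
        if (seg_a >= 0).all() and (seg_b >= 0).all() and (seg_a == seg_b).all():
            n_same += 1
    return n_same / n_pairs if n_pairs else 0.0


def brute_force_regions(positions, scores, threshold=3.0, min_hits=3, span=1_000_000):
    """Independent region enumeration: seeds + connected-component merge."""
    sig = [i for i, s in enumerate(scores) if np.isfinite(s) and abs(s) > threshold]
    seeds = []
    for a in range(len(sig) - min_hits + 1):
        members = sig[a : a + min_hits]
        if positions[members[-1]] - positions[members[0]] <= span:
            seeds.append(set(range(a, a + min_hits)))
    if not seeds:
        return []
    # merge seeds sharing any significant-SNP index (transitively)
    merged = []
    for s in seeds:
        attached = [m for m in merged if m & s]
        for m in attached:
            merged.remove(m)
            s = s | m
        merged.append(s)
    out = []
    for comp in merged:
        idx = sorted(comp)
        first, last = sig[idx[0]], sig[idx[-1]]
        out.append((int(positions[first]), int(positions[last])))
    return sorted(out)
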