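"""Data model and I/O for phased genotype panels.

The universal substrate is the :class:`GenotypePanel`: a haplotype matrix
(two rows per diploid sample) over biallelic SNPs, together with a
:class:`MarkerMap` (chromosome / bp / alleles per site) and a
:class:`SampleManifest` assigning each sample to a parental panel or to
the admixed cohort.

Conventions
-----------
* bp positions are 1-based (VCF); internal site indices are 0-based.
* Allele codes are ``0`` (REF), ``1`` (ALT); missing calls are ``-1``.
* Only biallelic SNPs are modelled; other records are skipped on read
  with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

ROLE_PARENTAL = "parental_panel"
ROLE_ADMIXED = "admixed"


class PanelError(ValueError):
    """Raised on contract violations in panel construction or I/O."""


@dataclass(frozen=True)
class MarkerMap:
    """Per-site marker metadata, strictly sorted by (chromosome, position).

    Attributes
    ----------
    chrom, pos, ids, ref, alt : np.ndarray
        Parallel arrays over sites. ``pos`` is 1-based bp.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ids", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise PanelError(f"marker map field {name!r} length mismatch")
        # strictly sorted within chromosome, chromosomes contiguous
        seen: set[str] = set()
        prev_chrom: str | None = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise PanelError(f"chromosome {c} is not contiguous in map")
                seen.add(c)
                prev_chrom, prev_pos = c, -1
            if p <= prev_pos:
                raise PanelError(
                    f"positions not strictly increasing on chromosome {c} at {p}"
                )
            prev_pos = p
        for a in np.concatenate([self.ref, self.alt]):
            if len(str(a)) != 1 or str(a) not in "ACGT":
                raise PanelError(f"non-SNP allele {a!r} in marker map")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(str(c))
        return out

    def chrom_slice(self, chromosome: str) -> slice:
        """Half-open site-index slice covering one chromosome."""
        idx = np.flatnonzero(self.chrom == chromosome)
        if idx.size == 0:
            raise PanelError(f"unknown chromosome {chromosome!r}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ids=self.ids[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
        )


@dataclass(frozen=True)
class SampleManifest:
    """Sample -> (population, role) assignment.

    Roles are ``parental_panel`` or ``admixed``. Sample ids must be unique.
    """

    sample_id: tuple[str, ...]
    population: tuple[str, ...]
    role: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sample_id)) != len(self.sample_id):
            raise PanelError("duplicate sample ids in manifest")
        if not len(self.sample_id) == len(self.population) == len(self.role):
            raise PanelError("manifest field length mismatch")
        bad = [r for r in self.role if r not in (ROLE_PARENTAL, ROLE_ADMIXED)]
        if bad:
            raise PanelError(f"unknown roles {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.sample_id)

    @property
    def populations(self) -> list[str]:
        out: list[str] = []
        for p in self.population:
            if p not in out:
                out.append(p)
        return out

    @property
    def parental_populations(self) -> list[str]:
        out: list[str] = []
        for p, r in zip(self.population, self.role):
            if r == ROLE_PARENTAL and p not in out:
                out.append(p)
        return out

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.population) == population)
        if idx.size == 0:
            raise PanelError(f"unknown population {population!r}")
        return idx

    def subset(self, idx: Iterable[int]) -> "SampleManifest":
        idx = list(idx)
        return SampleManifest(
            sample_id=tuple(self.sample_id[i] for i in idx),
            population=tuple(self.population[i] for i in idx),
            role=tuple(self.role[i] for i in idx),
        )

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, str]]
    ) -> "SampleManifest":
        sid, pop, role = zip(*records) if records else ((), (), ())
        return cls(tuple(sid), tuple(pop), tuple(role))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "population", "role"}
        if not required.issubset(df.columns):
            raise PanelError(f"manifest must have columns {sorted(required)}")
        return cls(
            tuple(df["sample_id"]), tuple(df["population"]), tuple(df["role"])
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "population": self.population,
                "role": self.role,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypePanel:
    """Phased haplotype matrix plus marker map and sample manifest.

    ``haplotypes`` has shape ``(2 * n_samples, n_sites)``; rows ``2i`` and
    ``2i + 1`` are the two phased haplotypes of sample ``i`` in manifest
    order. Entries are 0/1 allele codes with ``-1`` for missing.
    """

    haplotypes: np.ndarray
    map: MarkerMap
    manifest: SampleManifest
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.manifest):
            raise PanelError(
                f"haplotype rows ({self.haplotypes.shape[0]}) != "
                f"2 x samples ({len(self.manifest)})"
            )
        if self.haplotypes.shape[1] != len(self.map):
            raise PanelError("haplotype columns != map sites")
        vals = np.unique(self.haplotypes)
        if not np.isin(vals, [MISSING, 0, 1]).all():
            raise PanelError(f"allele codes outside {{-1,0,1}}: {vals}")

    @property
    def n_samples(self) -> int:
        return len(self.manifest)

    @property
    def n_sites(self) -> int:
        return len(self.map)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to one population."""
        s = self.manifest.sample_indices(population)
        return np.sort(np.concatenate([2 * s, 2 * s + 1]))

    def population_haplotypes(self, population: str) -> np.ndarray:
        return self.haplotypes[self.haplotype_rows(population)]


def read_phased_vcf(path: str | Path, manifest: SampleManifest) -> GenotypePanel:
    """Read a phased VCF into a :class:`GenotypePanel`.

    Samples are taken in manifest order (all must be present in the VCF).
    Multi-allelic and non-SNP records are skipped and counted. A
    heterozygous unphased genotype for a retained sample is an error;
    unphased homozygotes are accepted since their phase is unambiguous.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in manifest.sample_id if s not in vcf_samples]
    if missing_samples:
        raise PanelError(f"manifest samples absent from VCF: {missing_samples}")
    col_of = {s: vcf_samples.index(s) for s in manifest.sample_id}
    cols = [col_of[s] for s in manifest.sample_id]

    chrom, pos, ids, ref, alt, rows = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        gts = v.genotypes  # [a0, a1, phased] per sample
        site = np.empty(2 * len(cols), dtype=np.int8)
        for j, c in enumerate(cols):
            a0, a1, phased = gts[c][0], gts[c][1], gts[c][-1]
            if not phased and a0 != a1 and a0 >= 0 and a1 >= 0:
                raise PanelError(
                    f"unphased genotype for sample "
                    f"{manifest.sample_id[j]!r} at {v.CHROM}:{v.POS}"
                )
            site[2 * j] = a0 if a0 >= 0 else MISSING
            site[2 * j + 1] = a1 if a1 >= 0 else MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(site)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)

    hap = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((2 * len(manifest), 0), dtype=np.int8)
    )
    mmap = MarkerMap(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )
    return GenotypePanel(
        haplotypes=hap,
        map=mmap,
        manifest=manifest,
        log={"skipped_records": n_skipped},
    )


def write_phased_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal phased VCF 4.2; lossless for alleles/positions/ids."""
    mmap = panel.map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hapflow\n")
        for c in mmap.chromosomes:
            sl = mmap.chrom_slice(c)
            fh.write(f"##contig=<ID={c},length={int(mmap.pos[sl.stop - 1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += list(panel.manifest.sample_id)
        fh.write("\t".join(header) + "\n")
        hap = panel.haplotypes
        for j in range(panel.n_sites):
            gts = []
            for i in range(panel.n_samples):
                a0, a1 = hap[2 * i, j], hap[2 * i + 1, j]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{s0}|{s1}")
            fields = [
                str(mmap.chrom[j]),
                str(int(mmap.pos[j])),
                str(mmap.ids[j]),
                str(mmap.ref[j]),
                str(mmap.alt[j]),
                ".",
                ".",
                ".",
                "GT",
            ] + gts
            fh.write("\t".join(fields) + "\n")


def filter_maf(
    panel: GenotypePanel, threshold: float = 0.01, mode: str = "any"
) -> tuple[GenotypePanel, list[str]]:
    """Drop sites failing the per-population MAF rule.

    A site is retained iff its minor allele frequency exceeds ``threshold``
    in at least one population (``mode="any"``, the default) or in every
    population (``mode="all"``). Missing calls are excluded from the
    frequency denominator. Returns the filtered panel and the dropped
    site ids.
    """
    if not 0 <= threshold < 0.5:
        raise PanelError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    if mode not in ("any", "all"):
        raise PanelError(f"mode must be 'any' or 'all', got {mode!r}")
    pops = panel.manifest.populations
    if not pops:
        raise PanelError("manifest has no populations")
    passing = np.zeros((len(pops), panel.n_sites), dtype=bool)
    for k, pop in enumerate(pops):
        hap = panel.population_haplotypes(pop)
        obs = hap != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, hap, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_obs > 0, alt / np.maximum(n_obs, 1), 0.0)
        maf = np.minimum(f, 1.0 - f)
        passing[k] = (maf > threshold) & (n_obs > 0)
    keep = passing.any(axis=0) if mode == "any" else passing.all(axis=0)
    dropped = [str(i) for i in panel.map.ids[~keep]]
    out = GenotypePanel(
        haplotypes=panel.haplotypes[:, keep],
        map=panel.map.subset(keep),
        manifest=panel.manifest,
        log=dict(panel.log, dropped_sites=len(dropped)),
    )
    if dropped:
        logger.info("MAF filter dropped %d of %d sites", len(dropped), panel.n_sites)
    return out, dropped


def subset_population(panel: GenotypePanel, population: str) -> GenotypePanel:
    """Restrict haplotype rows to one population; marker map unchanged."""
    s = panel.manifest.sample_indices(population)
    rows = np.sort(np.concatenate([2 * s, 2 * s + 1]))
    return GenotypePanel(
        haplotypes=panel.haplotypes[rows],
        map=panel.map,
        manifest=panel.manifest.subset(sorted(s)),
        log=dict(panel.log),
    )
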