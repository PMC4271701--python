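"""SNP-index windows and per-window haplotype frequency spectra.

Windows are built per chromosome from site index 0 with a fixed SNP count
(``size``) and start-to-start ``step``; trailing windows shorter than
``size`` are dropped. Haplotype identity within a window is exact string
match; haplotypes containing a missing call are excluded from that
window's spectrum (exclusion counts are logged).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hapflow.genodata import MISSING, GenotypePanel, MarkerMap, PanelError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """One SNP window: global site-index span [start, stop) plus bp span."""

    chrom: str
    start: int
    stop: int
    start_bp: int
    end_bp: int

    @property
    def size(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class WindowGrid:
    """Ordered windows over a marker map, all exactly ``size`` SNPs."""

    windows: tuple[Window, ...]
    size: int
    step: int

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    @property
    def is_nonoverlapping(self) -> bool:
        return self.step >= self.size


def build_windows(
    mmap: MarkerMap, size: int = 30, step: int | None = None
) -> WindowGrid:
    """Enumerate SNP windows per chromosome.

    ``step`` defaults to ``size`` (non-overlapping). Chromosomes with
    fewer than ``size`` sites contribute zero windows (logged). bp span
    is [position of first site, position of last site] of the window.
    """
    if step is None:
        step = size
    if size < 2:
        raise PanelError(f"window size must be >= 2, got {size}")
    if not 1 <= step <= size:
        raise PanelError(f"step must be in [1, size], got {step}")
    windows: list[Window] = []
    for c in mmap.chromosomes:
        sl = mmap.chrom_slice(c)
        n = sl.stop - sl.start
        if n < size:
            logger.info("chromosome %s has %d < %d sites; no windows", c, n, size)
            continue
        for s in range(0, n - size + 1, step):
            lo, hi = sl.start + s, sl.start + s + size
            windows.append(
                Window(
                    chrom=c,
                    start=lo,
                    stop=hi,
                    start_bp=int(mmap.pos[lo]),
                    end_bp=int(mmap.pos[hi - 1]),
                )
            )
    return WindowGrid(windows=tuple(windows), size=size, step=step)


def window_haplotype_strings(
    haps: np.ndarray, window: Window
) -> tuple[list[str], int]:
    """Allele strings over a window; haplotypes with missing calls dropped.

    Returns (strings, n_excluded).
    """
    block = haps[:, window.start : window.stop]
    complete = (block != MISSING).all(axis=1)
    strings = ["".join(map(str, row)) for row in block[complete]]
    return strings, int((~complete).sum())


@dataclass
class HaplotypeSpectrum:
    """Per (window index, population) haplotype counts and frequencies."""

    grid: WindowGrid
    counts: dict[tuple[int, str], Counter] = field(default_factory=dict)
    totals: dict[tuple[int, str], int] = field(default_factory=dict)
    excluded: dict[tuple[int, str], int] = field(default_factory=dict)

    def frequencies(self, window: int, population: str) -> dict[str, float]:
        key = (window, population)
        if key not in self.counts:
            raise PanelError(f"no spectrum for window {window}, {population!r}")
        total = self.totals[key]
        if total == 0:
            raise PanelError(
                f"window {window} has no complete haplotypes in {population!r}"
            )
        return {h: c / total for h, c in self.counts[key].items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (w, pop), counter in sorted(self.counts.items()):
            win = self.grid[w]
            total = self.totals[(w, pop)]
            for h, c in sorted(counter.items()):
                rows.append(
                    {
                        "chrom": win.chrom,
                        "window_start_bp": win.start_bp,
                        "window_end_bp": win.end_bp,
                        "population": pop,
                        "haplotype": h,
                        "count": c,
                        "frequency": c / total if total else np.nan,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "window_start_bp",
                "window_end_bp",
                "population",
                "haplotype",
                "count",
                "frequency",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def haplotype_spectrum(
    panel: GenotypePanel,
    grid: WindowGrid,
    populations: list[str] | None = None,
) -> HaplotypeSpectrum:
    """Exact-match haplotype counts per window and population.

    Frequencies are normalized over complete (no-missing) haplotypes only.
    """
    if populations is None:
        populations = panel.manifest.populations
    for w in grid:
        if w.stop > panel.n_sites:
            raise PanelError(f"window {w} exceeds panel sites ({panel.n_sites})")
    spec = HaplotypeSpectrum(grid=grid)
    for pop in populations:
        haps = panel.population_haplotypes(pop)
        for i, w in enumerate(grid):
            strings, n_excl = window_haplotype_strings(haps, w)
            spec.counts[(i, pop)] = Counter(strings)
            spec.totals[(i, pop)] = len(strings)
            spec.excluded[(i, pop)] = n_excl
    n_excl_total = sum(spec.excluded.values())
    if n_excl_total:
        logger.info("excluded %d incomplete window haplotypes", n_excl_total)
    return spec


def most_frequent(
    spectrum: HaplotypeSpectrum, window: int, population: str
) -> tuple[str, float]:
    """Modal window haplotype; ties broken by lexicographically smallest."""
    freqs = spectrum.frequencies(window, population)
    if not freqs:
        raise PanelError(
            f"window {window} has an empty spectrum in {population!r}"
        )
    best = max(freqs.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    return best[0], best[1]


def shared_frequency(
    spectrum: HaplotypeSpectrum, window: int, haplotype: str, population: str
) -> float:
    """Frequency of exactly ``haplotype`` in ``population``; 0 if absent."""
    if len(haplotype) != spectrum.grid.size:
        raise PanelError(
            f"haplotype length {len(haplotype)} != window size {spectrum.grid.size}"
        )
    key = (window, population)
    if key not in spectrum.counts:
        raise PanelError(f"no spectrum for window {window}, {population!r}")
    total = spectrum.totals[key]
    if total == 0:
        return 0.0
    return spectrum.counts[key].get(haplotype, 0) / total
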