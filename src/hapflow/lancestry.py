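"""Window-based local-ancestry inference for admixed haplotypes.

A haplotype-copying emission model is trained per non-overlapping SNP
window from the parental panels: the probability of an admixed window
haplotype given breed B is the average over B's panel haplotypes of
``eps^mismatches * (1-eps)^matches``. Hidden ancestry along windows
follows a Markov chain (stay with ``1-rho``, otherwise redraw from the
prior ``pi``); forward-backward gives per-window posteriors and Viterbi
gives tract labels. All computation is in log space.

Two per-window summaries are produced: the *mean* posterior across
haplotypes, and a *minimum*-style summary — the fraction of haplotypes
assigned to each breed with posterior mass above an exclusivity
threshold ``tau`` (one interpretation of a single-origin summary;
flagged as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from hapflow.genodata import MISSING, GenotypePanel, PanelError
from hapflow.hapwin import WindowGrid

DEFAULT_EPSILON = 0.01
DEFAULT_RHO = 0.05
DEFAULT_TAU = 0.95


@dataclass
class AncestryModel:
    """Per-(window, breed) haplotype-copying emission model."""

    grid: WindowGrid
    breeds: tuple[str, ...]
    panel_windows: list[list[np.ndarray]]  # [window][breed] -> (n_haps, size)
    epsilon: float
    rho: float
    pi: np.ndarray
    map_positions: np.ndarray

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    def log_emissions(self, query: np.ndarray) -> np.ndarray:
        """Log emission matrix (n_windows, K) for one query haplotype."""
        n_w, k = len(self.grid), self.n_breeds
        out = np.empty((n_w, k))
        log_eps = np.log(self.epsilon)
        log_match = np.log1p(-self.epsilon)
        for w, win in enumerate(self.grid):
            q = query[win.start : win.stop]
            obs = q != MISSING
            n_obs = int(obs.sum())
            if n_obs == 0:
                out[w] = 0.0  # uninformative window
                continue
            for b in range(k):
                panel = self.panel_windows[w][b]
                mism = ((panel[:, obs] != q[obs])).sum(axis=1)
                terms = mism * log_eps + (n_obs - mism) * log_match
                out[w, b] = logsumexp(terms) - np.log(len(panel))
        return out


@dataclass
class AncestryField:
    """Per-(admixed haplotype, window) ancestry posteriors + Viterbi path."""

    grid: WindowGrid
    breeds: tuple[str, ...]
    posteriors: np.ndarray  # (n_haps, n_windows, K)
    viterbi: np.ndarray  # (n_haps, n_windows) int

    def __post_init__(self) -> None:
        sums = self.posteriors.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise PanelError("ancestry posteriors do not sum to 1")

    @property
    def n_haplotypes(self) -> int:
        return self.posteriors.shape[0]

    def mean_probability(self) -> np.ndarray:
        """p(B): per-window mean posterior across haplotypes, (n_windows, K)."""
        return self.posteriors.mean(axis=0)

    def write_tsv(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        n_h, n_w, k = self.posteriors.shape
        rows = []
        for h in range(n_h):
            sample = sample_ids[h // 2] if sample_ids else f"hap{h}"
            for w in range(n_w):
                row = {"sample": sample, "hap": h % 2, "window": w}
                for b, name in enumerate(self.breeds):
                    row[f"prob_{name}"] = self.posteriors[h, w, b]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def train_ancestry_model(
    parental: GenotypePanel,
    grid: WindowGrid,
    epsilon: float = DEFAULT_EPSILON,
    rho: float = DEFAULT_RHO,
    pi: np.ndarray | None = None,
    breeds: list[str] | None = None,
) -> AncestryModel:
    """Build the per-window emission model from the parental panels."""
    if breeds is None:
        breeds = parental.manifest.parental_populations or parental.manifest.populations
    if len(breeds) < 1:
        raise PanelError("no parental populations in manifest")
    if not grid.is_nonoverlapping:
        raise PanelError("ancestry training requires a non-overlapping grid")
    if not 0 < epsilon < 1:
        raise PanelError(f"epsilon must be in (0,1), got {epsilon}")
    if not 0 < rho < 1:
        raise PanelError(f"rho must be in (0,1), got {rho}")
    if pi is None:
        pi = np.full(len(breeds), 1.0 / len(breeds))
    pi = np.asarray(pi, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
        raise PanelError("pi must be a probability vector")

    panel_windows: list[list[np.ndarray]] = []
    for w_i, win in enumerate(grid):
        per_breed = []
        for b in breeds:
            haps = parental.population_haplotypes(b)[:, win.start : win.stop]
            complete = (haps != MISSING).all(axis=1)
            kept = haps[complete]
            if len(kept) == 0:
                raise PanelError(
                    f"breed {b!r} has zero complete haplotypes in window {w_i} "
                    f"({win.chrom}:{win.start_bp}-{win.end_bp})"
                )
            per_breed.append(np.ascontiguousarray(kept))
        panel_windows.append(per_breed)
    return AncestryModel(
        grid=grid,
        breeds=tuple(breeds),
        panel_windows=panel_windows,
        epsilon=epsilon,
        rho=rho,
        pi=pi,
        map_positions=parental.map.pos.copy(),
    )


def _log_transition(model: AncestryModel) -> np.ndarray:
    k = model.n_breeds
    t = (1.0 - model.rho) * np.eye(k) + model.rho * np.tile(model.pi, (k, 1))
    return np.log(t)


def _chrom_blocks(grid: WindowGrid) -> list[slice]:
    """Window-index slices per chromosome (the chain restarts at each)."""
    blocks: list[slice] = []
    start = 0
    for i in range(1, len(grid) + 1):
        if i == len(grid) or grid[i].chrom != grid[start].chrom:
            blocks.append(slice(start, i))
            start = i
    return blocks


def _forward_backward(loglik: np.ndarray, log_pi: np.ndarray, log_t: np.ndarray) -> np.ndarray:
    n, k = loglik.shape
    fwd = np.empty((n, k))
    fwd[0] = log_pi + loglik[0]
    for i in range(1, n):
        fwd[i] = loglik[i] + logsumexp(fwd[i - 1][:, None] + log_t, axis=0)
    bwd = np.zeros((n, k))
    for i in range(n - 2, -1, -1):
        bwd[i] = logsumexp(log_t + (loglik[i + 1] + bwd[i + 1])[None, :], axis=1)
    post = fwd + bwd
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post)


def _viterbi(loglik: np.ndarray, log_pi: np.ndarray, log_t: np.ndarray) -> np.ndarray:
    n, k = loglik.shape
    delta = log_pi + loglik[0]
    back = np.empty((n, k), dtype=np.int32)
    for i in range(1, n):
        cand = delta[:, None] + log_t
        back[i] = np.argmax(cand, axis=0)
        delta = loglik[i] + np.max(cand, axis=0)
    path = np.empty(n, dtype=np.int32)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def infer_local_ancestry(
    admixed: GenotypePanel, model: AncestryModel
) -> AncestryField:
    """Forward-backward posteriors and Viterbi labels per admixed haplotype."""
    if len(admixed.map) != len(model.map_positions) or not np.array_equal(
        admixed.map.pos, model.map_positions
    ):
        raise PanelError("admixed panel marker map does not match the trained model")
    n_w, k = len(model.grid), model.n_breeds
    log_pi = np.log(model.pi + 1e-300)
    log_t = _log_transition(model)
    blocks = _chrom_blocks(model.grid)

    n_h = admixed.n_haplotypes
    posteriors = np.empty((n_h, n_w, k))
    viterbi = np.empty((n_h, n_w), dtype=np.int32)
    for h in range(n_h):
        loglik = model.log_emissions(admixed.haplotypes[h])
        for sl in blocks:
            posteriors[h, sl] = _forward_backward(loglik[sl], log_pi, log_t)
            viterbi[h, sl] = _viterbi(loglik[sl], log_pi, log_t)
    return AncestryField(
        grid=model.grid, breeds=model.breeds, posteriors=posteriors, viterbi=viterbi
    )


def ancestry_summaries(
    field: AncestryField, mode: str = "mean", tau: float = DEFAULT_TAU
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(window, breed) ancestry proportions.

    ``mode="mean"``: average posterior across haplotypes. ``mode="minimum"``:
    among haplotypes whose top posterior exceeds ``tau`` (treated as having
    a single confident origin), the fraction assigned to each breed;
    windows with no such haplotype get an all-zero row. Returns
    (proportions (n_windows, K), flags (n_windows,) bool marking all-zero
    minimum rows).
    """
    n_h, n_w, k = field.posteriors.shape
    flags = np.zeros(n_w, dtype=bool)
    if mode == "mean":
        return field.mean_probability(), flags
    if mode != "minimum":
        raise PanelError(f"mode must be 'mean' or 'minimum', got {mode!r}")
    out = np.zeros((n_w, k))
    top = field.posteriors.max(axis=2)  # (n_h, n_w)
    arg = field.posteriors.argmax(axis=2)
    for w in range(n_w):
        confident = top[:, w] >= tau
        n_conf = int(confident.sum())
        if n_conf == 0:
            flags[w] = True
            continue
        for b in range(k):
            out[w, b] = np.sum(arg[confident, w] == b) / n_conf
    return out, flags


def write_ancestry_field(field: AncestryField, path: str | Path) -> None:
    """TSV export readable by :func:`read_external_ancestry`."""
    n_h, n_w, k = field.posteriors.shape
    rows = []
    for h in range(n_h):
        for w in range(n_w):
            row = {"sample": f"s{h // 2}", "hap": h % 2, "window": w}
            for b, name in enumerate(field.breeds):
                row[f"prob_{name}"] = repr(float(field.posteriors[h, w, b]))
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_external_ancestry(path: str | Path, grid: WindowGrid) -> AncestryField:
    """Read externally computed per-window ancestry probabilities.

    Expects a TSV with columns sample, hap, window and one ``prob_<breed>``
    column per breed; each row's probabilities must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path, sep="\t")
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    if not prob_cols:
        raise PanelError("no prob_<breed> columns found")
    breeds = tuple(c[len("prob_") :] for c in prob_cols)
    sums = df[prob_cols].sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
    if bad.size:
        raise PanelError(
            f"ancestry probabilities do not sum to 1 at line {int(bad[0]) + 2}"
        )
    df = df.sort_values(["sample", "hap", "window"], kind="stable")
    n_w = len(grid)
    hap_keys = df[["sample", "hap"]].drop_duplicates()
    n_h = len(hap_keys)
    if len(df) != n_h * n_w:
        raise PanelError(
            f"expected {n_h * n_w} rows ({n_h} haplotypes x {n_w} windows), got {len(df)}"
        )
    posteriors = df[prob_cols].to_numpy(dtype=float).reshape(n_h, n_w, len(breeds))
    viterbi = posteriors.argmax(axis=2).astype(np.int32)
    return AncestryField(grid=grid, breeds=breeds, posteriors=posteriors, viterbi=viterbi)


def ancestry_field_from_truth(
    truth, grid: WindowGrid, breeds: tuple[str, ...] | None = None
) -> AncestryField:
    """One-hot-style AncestryField from simulator truth ancestry.

    Each haplotype/window posterior is the fraction of the window's sites
    carrying each breed label, so posteriors are exact and sum to 1.
    """
    if truth.ancestry is None:
        raise PanelError("truth has no admixed ancestry matrix")
    breeds = breeds or truth.breed_names
    k = len(breeds)
    n_h = truth.ancestry.shape[0]
    posteriors = np.zeros((n_h, len(grid), k))
    for w, win in enumerate(grid):
        block = truth.ancestry[:, win.start : win.stop]
        for b in range(k):
            posteriors[:, w, b] = (block == b).mean(axis=1)
    viterbi = posteriors.argmax(axis=2).astype(np.int32)
    return AncestryField(grid=grid, breeds=tuple(breeds), posteriors=posteriors, viterbi=viterbi)
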