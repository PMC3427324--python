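"""Evolutionary-rate measurement, rate binning, and phylogenetic
informativeness (PI) profiling.

Per-gene rate is summarized as average pairwise nucleotide divergence
(p-distance with pairwise deletion), and genes are sorted into contiguous
rate bins (FAST/MED/SLOW for the default three bins).

Per-site substitution rates are maximum-likelihood estimates on a fixed
ultrametric chronogram under the n-state symmetric substitution model
(4 states for nucleotides, 20 for amino acids): for each alignment column
the single rate parameter lambda scaling branch durations is optimized by
a vectorized grid-plus-golden-section search of the pruning-algorithm
likelihood.  Invariant columns get exactly 0.

The informativeness of a site of rate lambda at time depth t is the
quartet-style measure rho(t; lambda) = 16 lambda^2 t e^(-4 lambda t),
maximized at t* = 1/(4 lambda).  Net PI sums rho over sites; per-site PI
divides by alignment length.  Time is in 100-Myr units throughout, so a
peak at t* = 0.97 reads as 97 Myr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import Chronogram

_NT_STATES = {"A": 0, "C": 1, "G": 2, "T": 3}
_AA_STATES = {a: i for i, a in enumerate("ACDEFGHIKLMNPQRSTVWY")}


# ---------------------------------------------------------------------------
# pairwise divergence

def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites over pairwise-comparable columns.

    Columns where either row holds a gap, '?' or N are deleted pairwise;
    with no comparable column the distance is 0 (with a warning).
    """
    if len(row_a) != len(row_b):
        raise ValueError(f"length mismatch: {len(row_a)} vs {len(row_b)}")
    comparable = diffs = 0
    for x, y in zip(row_a, row_b):
        if x in _NT_STATES and y in _NT_STATES:
            comparable += 1
            if x != y:
                diffs += 1
    if comparable == 0:
        import logging
        logging.getLogger("opilio").warning("no comparable columns; p-distance 0")
        return 0.0
    return diffs / comparable


def avg_pairwise_divergence(rows: dict[str, str]) -> float:
    """Unweighted mean p-distance over all unordered row pairs."""
    taxa = sorted(rows)
    if len(taxa) < 2:
        raise ValueError("need at least two rows")
    dists = [p_distance(rows[a], rows[b])
             for i, a in enumerate(taxa) for b in taxa[i + 1:]]
    return float(np.mean(dists))


BIN_LABELS_3 = ("FAST", "MED", "SLOW")


def bin_genes_by_rate(divergences: dict[str, float], n_bins: int = 3
                      ) -> list[list[str]]:
    """Split genes into contiguous equal-size rate bins, fastest first.

    Genes are sorted by descending divergence (ties by gene id); any
    remainder goes to the slowest bin.
    """
    if len(divergences) < n_bins:
        raise ValueError("fewer genes than bins")
    ranked = sorted(divergences, key=lambda g: (-divergences[g], g))
    size = len(ranked) // n_bins
    bins = [ranked[i * size:(i + 1) * size] for i in range(n_bins - 1)]
    bins.append(ranked[(n_bins - 1) * size:])
    return bins


# ---------------------------------------------------------------------------
# site rates

@dataclass
class SiteRates:
    """Per-column substitution rates (subs/site per 100-Myr unit).

    ``rates`` is NaN where a column was entirely missing; such columns are
    excluded from profiles.  ``model`` records the state space used.
    """

    rates: np.ndarray
    model: str
    lambda_max: float

    @property
    def valid(self) -> np.ndarray:
        return self.rates[np.isfinite(self.rates)]


def _encode_columns(rows: dict[str, str], states: dict[str, int]
                    ) -> tuple[list[str], np.ndarray]:
    taxa = sorted(rows)
    L = len(next(iter(rows.values())))
    enc = np.full((len(taxa), L), -1, dtype=np.int8)
    for i, t in enumerate(taxa):
        enc[i] = [states.get(c, -1) for c in rows[t]]
    return taxa, enc


def _column_loglik(lams: np.ndarray, enc: np.ndarray, taxa: list[str],
                   chronogram: Chronogram, n_states: int) -> np.ndarray:
    """Log-likelihood of every column at its own rate (vectorized pruning).

    ``lams`` has one rate per column.  Symmetric model transition
    probabilities: P(same) = 1/n + (n-1)/n * exp(-n/(n-1) * lam * t).
    """
    ncol = enc.shape[1]
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    n = n_states
    tree = chronogram.tree

    def partial(node) -> np.ndarray:
        if node.is_leaf():
            L = np.ones((ncol, n))
            i = taxon_idx.get(node.taxon.label)
            if i is not None:
                obs = enc[i]
                known = obs >= 0
                L[known] = 0.0
                L[known, obs[known]] = 1.0
            return L
        out = np.ones((ncol, n))
        for child in node.child_nodes():
            Lc = partial(child)
            t = child.edge.length or 0.0
            expo = np.exp(-(n / (n - 1)) * lams * t)[:, None]
            a = 1.0 / n + (n - 1) / n * expo      # P(same)
            b = 1.0 / n - 1.0 / n * expo          # P(diff)
            s = Lc.sum(axis=1, keepdims=True)
            msg = b * s + (a - b) * Lc
            out *= msg
        return out

    root = partial(tree.seed_node)
    lik = root.mean(axis=1)          # uniform root frequencies
    return np.log(np.maximum(lik, 1e-300))


def estimate_site_rates(rows: dict[str, str], chronogram: Chronogram,
                        model: str = "nt", grid_points: int = 64,
                        refine_iters: int = 60) -> SiteRates:
    """ML per-column rates on a chronogram under the symmetric model.

    Rates are bounded to [0, 20/root_age]; invariant columns (at most one
    distinct determinate state) return exactly 0; entirely missing columns
    return NaN.  Optimization is a coarse grid followed by golden-section
    refinement around the best grid cell, all columns in parallel.
    """
    states = _NT_STATES if model == "nt" else _AA_STATES
    n_states = 4 if model == "nt" else 20
    taxa, enc = _encode_columns(rows, states)
    ncol = enc.shape[1]
    lam_max = 20.0 / chronogram.root_age

    rates = np.full(ncol, np.nan)
    n_distinct = np.array([len(set(enc[:, j][enc[:, j] >= 0]))
                           for j in range(ncol)])
    rates[n_distinct <= 1] = 0.0
    rates[n_distinct == 0] = np.nan
    active = np.nonzero(n_distinct >= 2)[0]
    if active.size == 0:
        return SiteRates(rates, model, lam_max)

    sub = enc[:, active]

    def ll(lams: np.ndarray) -> np.ndarray:
        return _column_loglik(lams, sub, taxa, chronogram, n_states)

    grid = np.linspace(0.0, lam_max, grid_points)
    scores = np.stack([ll(np.full(active.size, g)) for g in grid])
    best = scores.argmax(axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, grid_points - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = ll(c), ll(d)
    for _ in range(refine_iters):
        take_c = fc > fd          # keep [a, d]
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = ll(c), ll(d)
    rates[active] = (a + b) / 2.0
    return SiteRates(rates, model, lam_max)


# ---------------------------------------------------------------------------
# informativeness profiles

def rho(t: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Per-site informativeness of a rate-lambda site at depth t."""
    return 16.0 * lam ** 2 * t * np.exp(-4.0 * lam * t)


@dataclass
class PIProfile:
    """Time-gridded net and per-site informativeness with peak time."""

    times: np.ndarray
    net: np.ndarray
    length: int                 # alignment columns (incl. excluded sites)
    summed_net: float = field(init=False)
    summed_per_site: float = field(init=False)
    peak_time: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.summed_net = float(np.trapezoid(self.net, self.times))
        self.summed_per_site = self.summed_net / self.length
        if np.all(self.net == 0.0):
            self.peak_time = None
        else:
            self.peak_time = float(self.times[int(np.argmax(self.net))])

    @property
    def per_site(self) -> np.ndarray:
        return self.net / self.length


def pi_profile(rates: SiteRates, chronogram: Chronogram,
               grid_step: float | None = None) -> PIProfile:
    """Net PI(t) = sum over sites of rho(t; lambda_i) on [0, root age].

    Columns whose rate is not available (NaN) are excluded from the sum but
    still count toward the per-site normalization length.  Default grid
    step is root_age/1000; the peak is the grid argmax, earliest on ties.
    """
    T = chronogram.root_age
    if grid_step is None:
        grid_step = T / 1000.0
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    times = np.arange(0.0, T + grid_step / 2, grid_step)
    lams = rates.valid
    if lams.size:
        net = (16.0 * lams[None, :] ** 2 * times[:, None]
               * np.exp(-4.0 * lams[None, :] * times[:, None])).sum(axis=1)
    else:
        net = np.zeros_like(times)
    return PIProfile(times, net, length=len(rates.rates))
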