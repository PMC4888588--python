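"""Copy-number calling by a negative-binomial hidden Markov model.

Hidden states are integer copy numbers 0..C_max (default 10, i.e. nullisomy
up to decasomy).  State 0 emits a point mass at zero counts; state c >= 1
emits NB(r_c, p) with the tying rule r_c = c * r_1 and a shared success
probability p, so the state means scale linearly with copy number
(mean_c = c * mu_1 with mu_1 = r_1 (1-p)/p) and so do the variances.
Parameters (r_1, p), the transition matrix and the initial distribution are
estimated per cell by Baum-Welch EM over chromosomes treated as independent
observation sequences; each bin is then assigned the state with maximal
posterior probability.

The model/results split follows the statsmodels convention:
``CopyNumberHMM(cell).fit()`` returns a :class:`CopyNumberHMMResults`
holding the estimates, posteriors and loglikelihood, from which
``decode()`` derives the integer :class:`CopyNumberProfile`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import nbinom

from .counts import CellCounts
from .genome import BinGrid

DELTA_FLOOR = -1e10   # finite stand-in for log(0) of the nullisomy delta
DEFAULT_C_MAX = 10


@dataclass(frozen=True)
class EmissionModel:
    """Tied NB emission family plus the delta-distributed nullisomy state."""

    c_max: int = DEFAULT_C_MAX
    r1: float = 1.0
    p: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must be in (0, 1)")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if self.c_max < 1:
            raise ValueError("c_max must be >= 1")

    @property
    def n_states(self) -> int:
        return self.c_max + 1

    @property
    def mu1(self) -> float:
        """Mean count of the monosomic state; state c has mean c * mu1."""
        return self.r1 * (1.0 - self.p) / self.p

    def state_means(self) -> np.ndarray:
        return np.arange(self.n_states) * self.mu1

    def logpmf(self, state: int, x) -> np.ndarray | float:
        """Log emission probability of integer count x under one state."""
        x = np.asarray(x)
        if np.any(x < 0):
            raise ValueError("counts must be non-negative")
        if state == 0:
            out = np.where(x == 0, 0.0, DELTA_FLOOR)
        else:
            out = nbinom.logpmf(x, state * self.r1, self.p)
            out = np.maximum(out, DELTA_FLOOR)
        return float(out) if out.ndim == 0 else out

    def logpmf_matrix(self, x: np.ndarray) -> np.ndarray:
        """(n_bins, n_states) log emission matrix for integer counts x."""
        x = np.asarray(x, dtype=np.int64)
        out = np.empty((len(x), self.n_states))
        out[:, 0] = np.where(x == 0, 0.0, DELTA_FLOOR)
        for c in range(1, self.n_states):
            out[:, c] = nbinom.logpmf(x, c * self.r1, self.p)
        np.maximum(out, DELTA_FLOOR, out=out)
        return out


def emission_logpmf(state: int, x, model: EmissionModel):
    """Functional alias for :meth:`EmissionModel.logpmf`."""
    return model.logpmf(state, x)


@njit(cache=True)
def _forward_backward(A, pi, B):
    """Scaled forward-backward for one observation sequence.

    B is the (T, S) emission matrix rescaled so each row's maximum is ~1;
    the caller adds the row maxima back into the loglikelihood.  Returns
    (gamma, summed xi, log-sum of scaling constants).
    """
    T, S = B.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    a0 = pi * B[0]
    s = a0.sum()
    alpha[0] = a0 / s
    c[0] = s
    for t in range(1, T):
        a = np.zeros(S)
        for i in range(S):
            ai = alpha[t - 1, i]
            if ai > 0.0:
                for j in range(S):
                    a[j] += ai * A[i, j]
        a *= B[t]
        s = a.sum()
        alpha[t] = a / s
        c[t] = s
    gamma = np.empty((T, S))
    xi = np.zeros((S, S))
    beta = np.ones(S)
    gamma[T - 1] = alpha[T - 1]
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta
        scale = c[t + 1]
        new_beta = np.empty(S)
        for i in range(S):
            ai = alpha[t, i]
            acc = 0.0
            for j in range(S):
                w = A[i, j] * bb[j] / scale
                acc += w
                xi[i, j] += ai * w
            new_beta[i] = acc
            gamma[t, i] = ai * acc
        beta = new_beta
        g = gamma[t]
        gs = g.sum()
        gamma[t] = g / gs
    ll = 0.0
    for t in range(T):
        ll += math.log(c[t])
    return gamma, xi, ll


def _fb_sequence(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Run scaled forward-backward on one chromosome's log-emissions."""
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    np.maximum(B, 1e-290, out=B)  # keep scaling sums strictly positive
    gamma, xi, ll = _forward_backward(np.ascontiguousarray(A), np.ascontiguousarray(pi),
                                      np.ascontiguousarray(B))
    return gamma, xi, ll + m.sum()


def _mstep_nb(x: np.ndarray, gamma: np.ndarray, c_max: int,
              r1_old: float, p_old: float) -> tuple[float, float]:
    """Update (r1, p) by 1-D maximisation of the expected NB loglikelihood.

    p is profiled from the expected-mean constraint mu1 = r1 (1-p)/p, i.e.
    p = r1 / (r1 + mu1) with mu1 the posterior-weighted mean count per copy.
    """
    G = gamma[:, 1:].sum(axis=0)                       # occupancy per NB state
    if G.sum() < 1e-12:
        return r1_old, p_old
    Gx = gamma[:, 1:].T @ x
    denom = float((np.arange(1, c_max + 1) * G).sum())
    mu1 = float(Gx.sum()) / denom
    if mu1 <= 0:
        return r1_old, p_old
    u, inv = np.unique(x, return_inverse=True)
    W = np.zeros((c_max, len(u)))
    for c in range(1, c_max + 1):
        np.add.at(W[c - 1], inv, gamma[:, c])
    cs = np.arange(1, c_max + 1, dtype=float)

    def neg_ell(log_r1: float) -> float:
        r1 = math.exp(log_r1)
        p = r1 / (r1 + mu1)
        rc = cs * r1
        val = 0.0
        for k in range(c_max):
            if G[k] < 1e-300:
                continue
            val += float(W[k] @ gammaln(u + rc[k])) - G[k] * gammaln(rc[k])
            val += G[k] * rc[k] * math.log(p)
        val += float(Gx.sum()) * math.log1p(-p)
        return -val

    res = minimize_scalar(neg_ell, bounds=(math.log(1e-3), math.log(1e7)),
                          method="bounded", options={"xatol": 1e-8})
    r1 = float(math.exp(res.x))
    p = r1 / (r1 + mu1)
    p = min(max(p, 1e-12), 1 - 1e-12)
    return r1, p


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CopyNumberProfile:
    """Per-bin integer copy-number states for one cell, with segments.

    Segments are the maximal runs of constant state within a chromosome;
    concatenated in order they reconstruct the per-bin states exactly.
    """

    cell_id: str
    grid: BinGrid
    states: np.ndarray
    max_posterior: np.ndarray
    segments: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.max_posterior = np.asarray(self.max_posterior, dtype=float)
        if len(self.states) != len(self.grid):
            raise ValueError("states length does not match grid")
        self.segments = self._derive_segments()

    def _derive_segments(self) -> pd.DataFrame:
        rows = []
        for chrom, sl in self.grid.chrom_slices().items():
            st = self.states[sl]
            starts = self.grid.starts[sl]
            ends = self.grid.ends[sl]
            i = 0
            while i < len(st):
                j = i
                while j + 1 < len(st) and st[j + 1] == st[i]:
                    j += 1
                rows.append((chrom, int(starts[i]), int(ends[j]), int(st[i]), j - i + 1))
                i = j + 1
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "n_bins"])

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_bed(self, path) -> None:
        """BED per cell: name = state, score = floor(1000 * max posterior)."""
        df = pd.DataFrame({
            "chrom": self.grid.chroms, "start": self.grid.starts,
            "end": self.grid.ends, "name": self.states,
            "score": np.floor(1000 * self.max_posterior).astype(int),
        })
        df.to_csv(path, sep="\t", header=False, index=False)

    def segments_to_tsv(self, path) -> None:
        seg = self.segments.copy()
        seg.insert(0, "cell", self.cell_id)
        seg.to_csv(path, sep="\t", index=False)


class CopyNumberHMM:
    """NB-HMM copy-number model for one cell's binned counts.

    Parameters
    ----------
    cell : CellCounts
        Binned counts (GC-corrected counts are used when present; they are
        rounded to the nearest integer for emission evaluation).
    c_max : int
        Highest modelled copy number (default 10).
    most_frequent_state : int
        The copy number the modal bin count is assumed to represent; this
        only steers the initialisation (a soft constraint), so e.g. a
        near-tetraploid library can be fitted with the modal state forced
        toward disomy to compare fits.
    """

    def __init__(self, cell: CellCounts, c_max: int = DEFAULT_C_MAX,
                 most_frequent_state: int = 2):
        if not (1 <= most_frequent_state <= c_max):
            raise ValueError("most_frequent_state must be in [1, c_max]")
        self.cell = cell
        self.c_max = c_max
        self.most_frequent_state = most_frequent_state
        self.x = np.rint(cell.analysis_counts).astype(np.int64)
        np.clip(self.x, 0, None, out=self.x)
        self._slices = list(cell.grid.chrom_slices().values())

    # -- initialisation -----------------------------------------------------
    def initialize(self, mu1_factor: float = 1.0):
        """Initial (EmissionModel, A, pi).

        mu1 starts at (smoothed mode of nonzero counts) / most_frequent_state,
        optionally perturbed by ``mu1_factor`` (used by restarts); r1 comes
        from a method-of-moments estimate on counts near the mode.  A starts
        sticky (self-transition 0.99, off-diagonal uniform), pi uniform.
        """
        nz = self.x[self.x > 0]
        if len(nz) == 0:
            raise ValueError(f"degenerate library {self.cell.cell_id}: all counts zero")
        bc = np.bincount(nz)
        w = max(1, int(round(0.1 * float(np.median(nz)))))
        kernel = np.ones(w) / w
        mode = int(np.argmax(np.convolve(bc, kernel, mode="same")))
        mode = max(mode, 1)
        mu1 = mu1_factor * mode / self.most_frequent_state
        near = nz[np.abs(nz - mode) <= max(0.3 * mode, 2)]
        if len(near) < 5:
            near = nz
        m, v = float(near.mean()), float(near.var())
        p = m / v if v > m else 0.9
        p = min(max(p, 1e-3), 1 - 1e-3)
        r1 = p * mu1 / (1 - p)
        emission = EmissionModel(self.c_max, r1, p)
        S = self.c_max + 1
        A = np.full((S, S), 0.01 / (S - 1))
        np.fill_diagonal(A, 0.99)
        pi = np.full(S, 1.0 / S)
        return emission, A, pi

    # -- estimation ---------------------------------------------------------
    def fit(self, tol: float = 1e-4, max_iter: int = 200, n_restarts: int = 3,
            seed: int = 0) -> "CopyNumberHMMResults":
        """Baum-Welch fit; with restarts, mu1 is perturbed multiplicatively
        (seeded) and the highest-loglikelihood fit is kept."""
        if len(self.x) < 20:
            raise ValueError("need at least 20 bins to fit the HMM")
        rng = np.random.default_rng(seed)
        best = None
        for k in range(max(1, n_restarts)):
            factor = 1.0 if k == 0 else float(rng.uniform(0.75, 1.3))
            init = self.initialize(mu1_factor=factor)
            res = self._baum_welch(init, tol=tol, max_iter=max_iter)
            if best is None or res.loglik > best.loglik:
                best = res
        return best

    def _baum_welch(self, init, tol: float, max_iter: int) -> "CopyNumberHMMResults":
        emission, A, pi = init
        A = A.copy()
        pi = pi.copy()
        S = self.c_max + 1
        T = len(self.x)
        L_prev = -np.inf
        history: list[float] = []
        converged = False
        gamma = np.empty((T, S))
        for it in range(1, max_iter + 1):
            logB = emission.logpmf_matrix(self.x)
            xi_sum = np.zeros((S, S))
            pi_acc = np.zeros(S)
            loglik = 0.0
            for sl in self._slices:
                g, xi, ll = _fb_sequence(logB[sl], A, pi)
                gamma[sl] = g
                xi_sum += xi
                pi_acc += g[0]
                loglik += ll
            if not np.isfinite(loglik):
                raise RuntimeError(f"non-finite loglikelihood at iteration {it}")
            slack = 1e-6 * max(1.0, abs(L_prev)) if np.isfinite(L_prev) else 0.0
            if loglik < L_prev - slack:
                raise RuntimeError(
                    f"monotonicity violated at iteration {it}: {L_prev} -> {loglik}")
            history.append(loglik)
            rel = np.inf if not np.isfinite(L_prev) else \
                (loglik - L_prev) / max(abs(L_prev), 1e-300)
            if rel <= tol:
                converged = True
                break
            # M-step
            pi = pi_acc / len(self._slices)
            pi /= pi.sum()
            rows = xi_sum.sum(axis=1)
            A_new = A.copy()
            ok = rows > 0
            A_new[ok] = xi_sum[ok] / rows[ok, None]
            A = A_new
            r1, p = _mstep_nb(self.x, gamma, self.c_max, emission.r1, emission.p)
            emission = EmissionModel(self.c_max, r1, p)
            L_prev = loglik
        return CopyNumberHMMResults(
            model=self, emission=emission, transmat=A, startprob=pi,
            posteriors=gamma.copy(), loglik=history[-1], history=history,
            n_iter=len(history), converged=converged)


@dataclass
class CopyNumberHMMResults:
    """Fitted NB-HMM: estimates, posteriors, loglikelihood, diagnostics."""

    model: CopyNumberHMM
    emission: EmissionModel
    transmat: np.ndarray
    startprob: np.ndarray
    posteriors: np.ndarray
    loglik: float
    history: list[float]
    n_iter: int
    converged: bool

    @property
    def cell_id(self) -> str:
        return self.model.cell.cell_id

    def decode(self) -> CopyNumberProfile:
        """Max-posterior state per bin; ties break toward the lower state."""
        gamma = self.posteriors
        states = np.argmax(gamma, axis=1)          # first max = lowest state
        maxpost = gamma[np.arange(len(gamma)), states]
        return CopyNumberProfile(self.cell_id, self.model.cell.grid,
                                 states, maxpost)

    def params_dict(self) -> dict:
        return {
            "cell": self.cell_id,
            "c_max": self.emission.c_max,
            "most_frequent_state": self.model.most_frequent_state,
            "r1": self.emission.r1,
            "p": self.emission.p,
            "mu1": self.emission.mu1,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def save_params(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.params_dict().items():
                fh.write(f"{k}\t{v}\n")

    def summary(self) -> str:
        d = self.params_dict()
        lines = ["Copy-number NB-HMM fit", "=" * 34]
        lines += [f"{k:>22}: {v}" for k, v in d.items()]
        means = self.emission.state_means()
        lines.append(f"{'state means':>22}: " +
                     ", ".join(f"{m:.1f}" for m in means))
        return "\n".join(lines)


def initialize_model(cell: CellCounts, c_max: int = DEFAULT_C_MAX,
                     most_frequent_state: int = 2):
    """Initial (EmissionModel, A, pi) for a cell (spec-level convenience)."""
    return CopyNumberHMM(cell, c_max, most_frequent_state).initialize()


def baum_welch_fit(cell: CellCounts, init=None, tol: float = 1e-4,
                   max_iter: int = 200, c_max: int = DEFAULT_C_MAX,
                   most_frequent_state: int = 2) -> CopyNumberHMMResults:
    """Single Baum-Welch run from a given (or default) initialisation."""
    model = CopyNumberHMM(cell, c_max, most_frequent_state)
    if len(model.x) < 20:
        raise ValueError("need at least 20 bins to fit the HMM")
    if init is None:
        init = model.initialize()
    return model._baum_welch(init, tol=tol, max_iter=max_iter)


def decode(fit: CopyNumberHMMResults) -> CopyNumberProfile:
    """Functional alias for :meth:`CopyNumberHMMResults.decode`."""
    return fit.decode()


def fit_cell(cell: CellCounts, c_max: int = DEFAULT_C_MAX,
             most_frequent_state: int = 2, tol: float = 1e-4,
             max_iter: int = 200, n_restarts: int = 3, seed: int = 0):
    """Initialise, fit and decode one cell; returns (results, profile)."""
    res = CopyNumberHMM(cell, c_max, most_frequent_state).fit(
        tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed)
    return res, res.decode()
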