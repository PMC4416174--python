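"""Two-state hidden Markov model with binomial emissions for MeRIP-seq bins.

The methylation status of bin ``n`` of a gene is a latent state
``z_n in {1, 2}`` (1 = unmethylated, 2 = methylated) following a first-order
Markov chain with transition matrix ``A`` and initial probability
``pi = P(z_1 = 1)``.  Given the IP read count ``x_n`` and the combined
IP + control count ``t_n = x_n + y_n``, the emission is binomial::

    P(x_n | z_n = k, t_n) = Binom(t_n, p_k)

where ``p_k`` is the expected IP fraction of the combined counts in state
``k``.  Conditioning on ``t_n`` folds the two Poisson read-count channels
(IP and control) into a single emission parameter per state, so the Poisson
rates and sequencing depths never need to be inferred.

Parameters ``theta = {pi, A, p_1, p_2}`` are estimated by multi-sequence EM
(each gene is an independent chain restarting from ``pi``, all genes share
one ``theta``), posteriors come from scaled forward-backward, and the MAP
state path from Viterbi decoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: probabilities are clamped into [PROB_FLOOR, 1 - PROB_FLOOR] before logs
PROB_FLOOR = 1e-6
#: linear-space floor for emission probabilities
EMISSION_FLOOR = 1e-300

UNMETHYLATED, METHYLATED = 1, 2


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Full parameter set ``theta`` of the two-state chain.

    Attributes
    ----------
    pi : float
        Initial probability of the unmethylated state, ``P(z_1 = 1)``.
    A : (2, 2) ndarray
        Row-stochastic transition matrix; ``A[j, k] = P(z_n = k+1 | z_{n-1}
        = j+1)`` with row/column 0 the unmethylated state.
    p : (2,) ndarray
        Binomial success probabilities ``(p_1, p_2)``; identifiability is
        kept by the ordering ``p_1 <= p_2`` (strict after any M step).
    """

    pi: float
    A: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must be in [0, 1], got {self.pi}")
        if self.A.shape != (2, 2):
            raise ValueError("A must be 2x2")
        if np.any(self.A < 0) or np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("A rows must be non-negative and sum to 1")
        if self.p.shape != (2,):
            raise ValueError("p must have two entries")
        if not (0.0 < self.p[0] <= self.p[1] < 1.0):
            raise ValueError(f"need 0 < p1 <= p2 < 1, got {self.p}")

    def to_dict(self) -> dict[str, float]:
        return {
            "pi": float(self.pi),
            "A11": float(self.A[0, 0]), "A12": float(self.A[0, 1]),
            "A21": float(self.A[1, 0]), "A22": float(self.A[1, 1]),
            "p1": float(self.p[0]), "p2": float(self.p[1]),
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "HMMParams":
        return cls(
            pi=float(d["pi"]),
            A=np.array([[d["A11"], d["A12"]], [d["A21"], d["A22"]]], float),
            p=np.array([d["p1"], d["p2"]], float),
        )

    def save(self, path) -> None:
        """Serialize to a flat key=value text file."""
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}={v:.17g}\n")

    @classmethod
    def load(cls, path) -> "HMMParams":
        d = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    k, v = line.split("=", 1)
                    d[k] = float(v)
        return cls.from_dict(d)


@dataclass
class Posteriors:
    """E-step output for one gene.

    ``gamma[n, k]`` is the marginal posterior ``P(z_n = k+1 | X, theta)``;
    ``epsilon[n-1, j, k]`` the pairwise posterior
    ``P(z_{n-1} = j+1, z_n = k+1 | X, theta)``; ``log_likelihood`` is
    ``ln P(X | theta)`` including the binomial coefficients.
    """

    gamma: np.ndarray
    epsilon: np.ndarray
    log_likelihood: float


@dataclass
class FitResult:
    params: HMMParams
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    posteriors: list[Posteriors] | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def emission_log_prob(x, t, p):
    """Log binomial emission ``ln[C(t, x) p^x (1-p)^(t-x)]``.

    Computed through log-gamma for stability; ``t = 0`` bins are
    uninformative and return 0 (probability one).  Scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(x > t) or np.any(x < 0):
        raise ValueError("require 0 <= x <= t")
    p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    out = (
        gammaln(t + 1.0) - gammaln(x + 1.0) - gammaln(t - x + 1.0)
        + x * np.log(p) + (t - x) * np.log1p(-p)
    )
    return out if out.ndim else float(out)


def _pack(count_sets):
    """Pad per-gene count arrays into (G, Nmax) matrices plus a validity mask.

    Padding bins carry ``x = t = 0`` and therefore flat emissions.  Because
    the transition matrix is row-stochastic, backward messages through flat
    bins remain exactly 1 and the scaling constants are exactly 1, so padded
    tails change nothing inside each true sequence; the mask only needs to
    exclude padded positions from M-step accumulations.
    """
    lengths = np.array([len(c.x) for c in count_sets], dtype=int)
    if len(lengths) == 0 or lengths.min() < 1:
        raise ValueError("every gene needs at least one bin")
    G, N = len(count_sets), int(lengths.max())
    x = np.zeros((G, N), dtype=float)
    t = np.zeros((G, N), dtype=float)
    for g, c in enumerate(count_sets):
        x[g, : lengths[g]] = c.x
        t[g, : lengths[g]] = c.t
    mask = np.arange(N)[None, :] < lengths[:, None]
    return x, t, mask, lengths


def _batched_e_step(x, t, mask, params):
    """Scaled forward-backward over a padded batch.

    Returns ``gamma`` (G, N, 2), ``epsilon`` (G, N-1, 2, 2) with padded
    transitions zeroed, and the per-gene log-likelihoods (G,).
    """
    G, N = x.shape
    A = params.A
    startp = np.array([params.pi, 1.0 - params.pi])

    logB = np.stack(
        [emission_log_prob(x, t, params.p[0]),
         emission_log_prob(x, t, params.p[1])], axis=-1)
    logB[~mask] = 0.0
    # shift so the per-position max emission is 1: scaling then never underflows
    shift = logB.max(axis=-1, keepdims=True)
    B = np.maximum(np.exp(logB - shift), EMISSION_FLOOR)

    alpha = np.empty((G, N, 2))
    c = np.empty((G, N))
    a = startp[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for n in range(1, N):
        a = (alpha[:, n - 1] @ A) * B[:, n]
        c[:, n] = a.sum(axis=1)
        alpha[:, n] = a / c[:, n, None]

    beta = np.empty((G, N, 2))
    beta[:, N - 1] = 1.0
    for n in range(N - 2, -1, -1):
        beta[:, n] = ((B[:, n + 1] * beta[:, n + 1]) @ A.T) / c[:, n + 1, None]

    gamma = alpha * beta
    # epsilon(n-1, j, k) = alpha_{n-1,j} A_{jk} B_{n,k} beta_{n,k} / c_n
    epsilon = (
        alpha[:, :-1, :, None] * A[None, None, :, :]
        * (B[:, 1:, :] * beta[:, 1:, :] / c[:, 1:, None])[:, :, None, :]
    )
    epsilon *= mask[:, 1:, None, None]

    loglik = (np.log(c) + shift[..., 0]).sum(axis=1)  # padded terms are 0
    return gamma, epsilon, loglik


def forward_backward(counts, params: HMMParams) -> Posteriors:
    """Posterior state probabilities for one gene (E step, single chain).

    Parameters
    ----------
    counts : BinCounts
        Per-bin IP counts ``x`` and totals ``t``.
    params : HMMParams

    Returns
    -------
    Posteriors
        gamma, epsilon and the data log-likelihood (scaling-constant sum).
    """
    x, t, mask, lengths = _pack([counts])
    gamma, epsilon, ll = _batched_e_step(x, t, mask, params)
    n = lengths[0]
    return Posteriors(gamma[0, :n], epsilon[0, : n - 1], float(ll[0]))


# ---------------------------------------------------------------------------
# M step
# ---------------------------------------------------------------------------

def _swap_labels(pi, A, p):
    perm = [1, 0]
    return 1.0 - pi, A[np.ix_(perm, perm)], p[perm]


def _m_step_arrays(gamma, epsilon, x, t, mask, prev: HMMParams | None):
    """Closed-form parameter update from pooled posterior sums."""
    g1 = gamma[:, 0, :]                      # (G, 2), first bin always valid
    pi = float(g1[:, 0].sum() / g1.sum())

    etot = epsilon.sum(axis=(0, 1))          # (2, 2)
    rowsum = etot.sum(axis=1, keepdims=True)
    fallback = prev.A if prev is not None else np.full((2, 2), 0.5)
    A = np.where(rowsum > 0, etot / np.where(rowsum > 0, rowsum, 1.0),
                 fallback)

    w = gamma * mask[..., None]              # padded x, t are zero anyway
    num = (w * x[..., None]).sum(axis=(0, 1))
    den = (w * t[..., None]).sum(axis=(0, 1))
    p = np.empty(2)
    for k in range(2):
        if den[k] <= 0.0:
            if prev is None:
                raise ZeroDivisionError(f"state {k + 1} never visited")
            warnings.warn(
                f"state {k + 1} has zero expected counts; keeping previous p",
                RuntimeWarning, stacklevel=3)
            p[k] = prev.p[k]
        else:
            p[k] = num[k] / den[k]
    p = np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)
    if p[0] > p[1]:  # restore identifiability ordering by relabelling
        pi, A, p = _swap_labels(pi, A, p)
    return HMMParams(pi=pi, A=A, p=p)


def m_step(posterior_sets, count_sets, prev: HMMParams | None = None) -> HMMParams:
    """Pooled M step over genes: Baum-Welch closed forms for pi, A and the
    binomial rates ``p_k = sum gamma_k x / sum gamma_k t``.

    If a state has zero expected total counts its ``p_k`` is kept from
    ``prev`` (with a warning).  If ``p_1 > p_2`` after the update the state
    labels are swapped everywhere.
    """
    x, t, mask, lengths = _pack(count_sets)
    G, N = x.shape
    gamma = np.zeros((G, N, 2))
    epsilon = np.zeros((G, max(N - 1, 1), 2, 2))
    for g, post in enumerate(posterior_sets):
        n = lengths[g]
        gamma[g, :n] = post.gamma
        if n > 1:
            epsilon[g, : n - 1] = post.epsilon
    return _m_step_arrays(gamma, epsilon, x, t, mask, prev)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def default_init(count_sets) -> HMMParams:
    """Data-driven starting point: p1/p2 from the 25th/75th percentiles of
    the per-bin IP fraction x/t over informative bins."""
    frac = np.concatenate(
        [np.asarray(c.x, float)[np.asarray(c.t) > 0]
         / np.asarray(c.t, float)[np.asarray(c.t) > 0]
         for c in count_sets])
    if frac.size == 0:
        raise ValueError("no informative bins (all t_n = 0)")
    p1, p2 = np.percentile(frac, [25.0, 75.0])
    p1 = float(np.clip(p1, PROB_FLOOR, 1.0 - PROB_FLOOR))
    p2 = float(np.clip(p2, PROB_FLOOR, 1.0 - PROB_FLOOR))
    if p2 - p1 < 1e-3:  # degenerate spread: keep an ordered separation
        mid = 0.5 * (p1 + p2)
        p1, p2 = max(mid - 0.05, PROB_FLOOR), min(mid + 0.05, 1 - PROB_FLOOR)
    return HMMParams(pi=0.5, A=np.array([[0.8, 0.2], [0.2, 0.8]]),
                     p=np.array([p1, p2]))


def em_fit(count_sets, init: HMMParams | None = None, tol: float = 1e-6,
           max_iter: int = 100, return_posteriors: bool = False) -> FitResult:
    """Multi-sequence EM: all genes share one ``theta``; each gene is an
    independent chain restarting from ``pi``.

    Stops when the relative log-likelihood change drops below ``tol`` or
    after ``max_iter`` iterations.  The trace is non-decreasing (up to
    1e-8 numerical slack) — EM monotonicity.

    Parameters
    ----------
    count_sets : sequence of BinCounts
    init : HMMParams, optional
        Starting parameters; defaults to :func:`default_init`.
    tol : float
        Relative log-likelihood convergence threshold.
    max_iter : int
    return_posteriors : bool
        Also run a final E step at the fitted ``theta`` and attach the
        per-gene posteriors to the result.

    Returns
    -------
    FitResult
    """
    x, t, mask, lengths = _pack(count_sets)
    if not np.any(t > 0):
        raise ValueError("no informative bins (all counts zero)")
    params = init if init is not None else default_init(count_sets)
    trace: list[float] = []
    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        gamma, epsilon, ll_per_gene = _batched_e_step(x, t, mask, params)
        ll = float(ll_per_gene.sum())
        trace.append(ll)
        params = _m_step_arrays(gamma, epsilon, x, t, mask, params)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(ll):
            converged = True
            break
        prev_ll = ll
    logger.info("EM finished after %d iterations (converged=%s): %s",
                len(trace), converged, params.to_dict())
    posteriors = None
    if return_posteriors:
        gamma, epsilon, ll_per_gene = _batched_e_step(x, t, mask, params)
        posteriors = [
            Posteriors(gamma[g, : lengths[g]],
                       epsilon[g, : lengths[g] - 1],
                       float(ll_per_gene[g]))
            for g in range(len(count_sets))
        ]
    return FitResult(params=params, loglik_trace=trace, n_iter=len(trace),
                     converged=converged, posteriors=posteriors)


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def viterbi(counts, params: HMMParams) -> np.ndarray:
    """MAP state path (values in {1, 2}) by log-space dynamic programming.

    Ties are broken toward state 1 (unmethylated) — conservative calling.
    """
    x = np.asarray(counts.x, dtype=float)
    t = np.asarray(counts.t, dtype=float)
    N = len(x)
    logB = np.stack([emission_log_prob(x, t, params.p[0]),
                     emission_log_prob(x, t, params.p[1])], axis=-1)
    logA = np.log(np.clip(params.A, EMISSION_FLOOR, None))
    logstart = np.log(np.clip([params.pi, 1.0 - params.pi],
                              EMISSION_FLOOR, None))
    delta = logstart + logB[0]
    back = np.zeros((N, 2), dtype=int)
    for n in range(1, N):
        cand = delta[:, None] + logA          # cand[j, k]
        back[n] = np.argmax(cand, axis=0)     # argmax prefers state 1 on ties
        delta = cand[back[n], [0, 1]] + logB[n]
    path = np.empty(N, dtype=int)
    path[N - 1] = int(np.argmax(delta))
    for n in range(N - 1, 0, -1):
        path[n - 1] = back[n, path[n]]
    return path + 1
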