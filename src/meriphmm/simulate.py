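"""Truth-labelled MeRIP-seq read-count simulator.

Generates per-gene bin counts from the same generative model the caller
assumes: gene lengths uniform on a range, a two-state Markov chain for the
methylation status of consecutive bins, and Poisson read counts whose IP
rate switches with the state.  Defaults reproduce the validation study
configuration: 5000 genes of 500-3000 nt, transition matrix
[[0.7, 0.3], [0.1, 0.9]], initial unmethylated probability 0.2, control
rate lambda_ctrl ~ U(5, 20) per gene (constant across that gene's bins),
and per-bin IP rate lambda_IP ~ U(lambda_ctrl, 100) when methylated,
U(0, lambda_ctrl) when unmethylated.

Sequencing depths are taken equal (M_IP = M_ctrl = 1), so the implied
binomial emission parameter is p = lambda_IP / (lambda_ctrl + lambda_IP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import BinCounts
from .hmm import METHYLATED


@dataclass
class SimulatorConfig:
    """Generative-model settings; defaults are the validation-study values."""

    n_genes: int = 5000
    gene_length_range: tuple[int, int] = (500, 3000)
    bin_size: int = 100
    A: np.ndarray = field(
        default_factory=lambda: np.array([[0.7, 0.3], [0.1, 0.9]]))
    pi: float = 0.2
    lambda_ctrl_range: tuple[float, float] = (5.0, 20.0)
    lambda_ip_methylated_max: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (2, 2) or np.any(self.A < 0) or \
                np.any(np.abs(self.A.sum(axis=1) - 1) > 1e-12):
            raise ValueError("A must be a 2x2 row-stochastic matrix")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        lo, hi = self.lambda_ctrl_range
        if not 0 < lo < hi:
            raise ValueError("invalid lambda_ctrl_range")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["A"] = self.A.tolist()
        return d


@dataclass
class SimulatedDataset:
    """Counts plus the true per-bin methylation states they were drawn from."""

    count_sets: list[BinCounts]
    truth: list[np.ndarray]
    config: SimulatorConfig
    lambda_ctrl: list[float] | None = None   # per-gene control-rate draws

    def all_truth(self) -> np.ndarray:
        return np.concatenate(self.truth) if self.truth else np.array([], int)


def _sample_states(rng, n, pi, A) -> np.ndarray:
    z = np.empty(n, dtype=int)
    z[0] = 1 if rng.random() < pi else 2
    for i in range(1, n):
        z[i] = 1 if rng.random() < A[z[i - 1] - 1, 0] else 2
    return z


def simulate(config: SimulatorConfig) -> SimulatedDataset:
    """Draw a fully reproducible dataset from the generative model.

    Per gene: length ~ U(range); N = ceil(length / L); states from the
    Markov chain; lambda_ctrl ~ U(range) once per gene; per bin a fresh
    lambda_IP from the state-appropriate interval; y ~ Pois(lambda_ctrl),
    x ~ Pois(lambda_IP).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    clo, chi = config.lambda_ctrl_range
    count_sets: list[BinCounts] = []
    truth: list[np.ndarray] = []
    lam_ctrls: list[float] = []
    for g in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        n_bins = -(-length // config.bin_size)
        z = _sample_states(rng, n_bins, config.pi, config.A)
        lam_ctrl = rng.uniform(clo, chi)
        meth = z == METHYLATED
        lam_ip = np.where(
            meth,
            rng.uniform(lam_ctrl, config.lambda_ip_methylated_max, size=n_bins),
            rng.uniform(0.0, lam_ctrl, size=n_bins))
        y = rng.poisson(lam_ctrl, size=n_bins)
        x = rng.poisson(lam_ip)
        count_sets.append(BinCounts(gene_id=f"gene{g:05d}", x=x, y=y))
        truth.append(z)
        lam_ctrls.append(float(lam_ctrl))
    return SimulatedDataset(count_sets=count_sets, truth=truth, config=config,
                            lambda_ctrl=lam_ctrls)


def truth_regions(dataset: SimulatedDataset) -> dict[str, list[tuple[int, int]]]:
    """Maximal true methylated runs per gene, as half-open bin intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    for cs, z in zip(dataset.count_sets, dataset.truth):
        runs = []
        i, n = 0, len(z)
        while i < n:
            if z[i] != METHYLATED:
                i += 1
                continue
            j = i
            while j < n and z[j] == METHYLATED:
                j += 1
            runs.append((i, j))
            i = j
        out[cs.gene_id] = runs
    return out


def write_truth_table(dataset: SimulatedDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed: {dataset.config.seed}\n")
        fh.write("gene\tbin\tstate\n")
        for cs, z in zip(dataset.count_sets, dataset.truth):
            for b in range(len(z)):
                fh.write(f"{cs.gene_id}\t{b}\t{z[b]}\n")


def read_truth_table(path) -> dict[str, np.ndarray]:
    per_gene: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, b, s = line.split("\t")
            per_gene.setdefault(gene, []).append((int(b), int(s)))
    return {g: np.array([s for _, s in sorted(rows)], dtype=int)
            for g, rows in per_gene.items()}


def simulate_from_hmm(params, n_genes: int, seed: int = 0,
                      gene_length_range=(500, 3000), bin_size: int = 100,
                      mean_depth: float = 25.0) -> SimulatedDataset:
    """Draw counts from the fitted model itself (fixed binomial rates).

    Unlike :func:`simulate`, which redraws a Poisson IP rate per bin and so
    produces mixture emissions, this generator is exactly the model the
    caller assumes: states from the chain, per-bin depth
    ``t ~ Pois(mean_depth)``, then ``x ~ Binom(t, p_k)``.  Used for
    parameter-recovery checks where the truth ``theta`` must be the
    estimand.
    """
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    count_sets, truth = [], []
    for g in range(n_genes):
        n_bins = -(-int(rng.integers(lo, hi + 1)) // bin_size)
        z = _sample_states(rng, n_bins, params.pi, params.A)
        t = rng.poisson(mean_depth, size=n_bins)
        x = rng.binomial(t, params.p[z - 1])
        count_sets.append(BinCounts(gene_id=f"gene{g:05d}", x=x, y=t - x))
        truth.append(z)
    cfg = SimulatorConfig(n_genes=n_genes, gene_length_range=gene_length_range,
                          bin_size=bin_size, A=params.A, pi=params.pi,
                          seed=seed)
    return SimulatedDataset(count_sets=count_sets, truth=truth, config=cfg)


def simulate_fixed_layout(rng, n_bins: int, meth_start: int, n_meth: int,
                          lambda_ctrl_range=(5.0, 20.0),
                          lambda_ip_methylated_max: float = 100.0):
    """One gene with a prescribed truth layout: a single contiguous run of
    ``n_meth`` methylated bins starting at ``meth_start``; read counts drawn
    with the standard per-bin rates.  Returns (BinCounts, truth)."""
    z = np.full(n_bins, 1, dtype=int)
    z[meth_start: meth_start + n_meth] = METHYLATED
    lam_ctrl = rng.uniform(*lambda_ctrl_range)
    meth = z == METHYLATED
    lam_ip = np.where(
        meth,
        rng.uniform(lam_ctrl, lambda_ip_methylated_max, size=n_bins),
        rng.uniform(0.0, lam_ctrl, size=n_bins))
    y = rng.poisson(lam_ctrl, size=n_bins)
    x = rng.poisson(lam_ip)
    return BinCounts(gene_id="synthetic", x=x, y=y), z
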