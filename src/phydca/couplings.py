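"""Phyletic coupling inference: the global lattice-gas model.

Profiles are modeled by the maximum-entropy distribution over binary
presence vectors n = (n_1, ..., n_N), n_i in {0, 1}:

    P(n) = exp( sum_{i<j} J_ij n_i n_j + sum_i h_i n_i ) / Z ,

the pairwise model whose marginals reproduce the single-column frequencies
f_i and pair co-occurrence frequencies f_ij of the profile matrix.  The
couplings J_ij are *direct* interaction parameters: correlation transmitted
through chains of intermediate domains is absorbed into the chain's own
couplings instead of contaminating every pair it touches, which is what
separates this approach from column-by-column correlation measures.

The partition function Z is never evaluated — exact inference is
exponential in N.  Two standard approximations are provided:

* mean-field (MF): J = -C^{-1} off-diagonal, with C the pseudocount-
  regularized connected-correlation matrix;
* pseudo-likelihood maximization (PLM): per-domain L2-regularized logistic
  regression of each column on all others, followed by symmetrization.

Both are deterministic given the input, so results are bit-reproducible.
An average product correction (APC) is available to suppress background
heterogeneity in the coupling matrix before ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .baselines import PairScoreList
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyStats",
    "CouplingModel",
    "empirical_frequencies",
    "mf_couplings",
    "plm_couplings",
    "apc_correct",
    "rank_pairs",
    "write_couplings",
    "read_couplings",
]


@dataclass(frozen=True)
class FrequencyStats:
    """Single and pairwise presence frequencies of a profile matrix.

    f_i is the fraction of genomes carrying domain i; f_ij the fraction
    carrying both i and j (diagonal f_ii = f_i).  All entries are exact
    counts divided by the number of genomes M, hence multiples of 1/M and
    bounded by the Frechet inequalities
    max(0, f_i + f_j - 1) <= f_ij <= min(f_i, f_j).
    """

    f_i: np.ndarray
    f_ij: np.ndarray
    n_species: int
    domain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.domain_ids)
        if self.f_i.shape != (n,) or self.f_ij.shape != (n, n):
            raise ValueError("frequency array shapes do not match domain_ids")


@dataclass(frozen=True)
class CouplingModel:
    """Inferred lattice-gas parameters.

    J is the symmetric N x N coupling matrix with zero diagonal, h the
    bias vector; ``method`` records the inference route ("mf" or "plm")
    and ``regularization`` its named parameters.  A positive J_ij favors
    joint presence/absence of domains i and j; a negative J_ij favors
    mutual exclusion.
    """

    J: np.ndarray
    h: np.ndarray
    method: Literal["mf", "plm"]
    regularization: dict
    domain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.domain_ids)
        if self.J.shape != (n, n) or self.h.shape != (n,):
            raise ValueError("parameter shapes do not match domain_ids")
        if not np.array_equal(self.J, self.J.T):
            raise ValueError("J must be exactly symmetric")
        if np.diagonal(self.J).any():
            raise ValueError("J must have zero diagonal")
        if not (np.isfinite(self.J).all() and np.isfinite(self.h).all()):
            raise ValueError("non-finite model parameters")

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)


class ConvergenceError(RuntimeError):
    """PLM node fit failed to reach the gradient tolerance."""


def empirical_frequencies(ppm: ProfileMatrix) -> FrequencyStats:
    """Exact f_i and f_ij of a profile matrix.

    f_i = (1/M) sum_a n_i^a  and  f_ij = (1/M) sum_a n_i^a n_j^a, computed
    for all pairs including the diagonal (where f_ii = f_i because
    n^2 = n for binary entries).
    """
    if ppm.n_species < 1:
        raise ValueError("PPM has no species")
    x = ppm.entries.astype(np.float64)
    m = ppm.n_species
    f_i = x.sum(axis=0) / m
    f_ij = (x.T @ x) / m
    return FrequencyStats(f_i, f_ij, m, ppm.domain_ids)


def mf_couplings(stats: FrequencyStats,
                 pseudocount: float = 0.01) -> CouplingModel:
    """Mean-field couplings by inversion of the connected-correlation matrix.

    Frequencies are first shrunk towards the uniform independent prior by
    the pseudocount lambda:

        f'_i  = (1 - lambda) f_i  + lambda / 2
        f'_ij = (1 - lambda) f_ij + lambda / 4   (i != j)

    then C_ij = f'_ij - f'_i f'_j is inverted and J_ij = -(C^{-1})_ij for
    i != j (diagonal forced to zero).  Biases follow from the mean-field
    self-consistency h_i = ln(f'_i / (1 - f'_i)) - sum_{j != i} J_ij f'_j.

    Raises a LinAlgError-derived message suggesting a larger pseudocount
    if C is (numerically) singular.
    """
    if not 0.0 <= pseudocount < 1.0:
        raise ValueError("pseudocount must lie in [0, 1)")
    lam = pseudocount
    fp = (1.0 - lam) * stats.f_i + lam / 2.0
    fpp = (1.0 - lam) * stats.f_ij + lam / 4.0
    np.fill_diagonal(fpp, fp)  # f'_ii must remain f'_i
    c = fpp - np.outer(fp, fp)
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is singular; increase the "
            f"pseudocount (currently {pseudocount})") from err
    if not np.isfinite(cinv).all():
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is numerically singular; "
            f"increase the pseudocount (currently {pseudocount})")
    j = -(cinv + cinv.T) / 2.0  # symmetrize away round-off
    np.fill_diagonal(j, 0.0)
    h = np.log(fp / (1.0 - fp)) - j @ fp
    return CouplingModel(j, h, "mf", {"pseudocount": pseudocount},
                         stats.domain_ids)


def _plm_node(x: np.ndarray, weights: np.ndarray, i: int, l2_j: float,
              l2_h: float, max_iter: int, gtol: float) -> np.ndarray:
    """Fit node i's conditional logistic model; returns (h_i, J_i·) packed
    as a vector of length N with the node's own slot holding h_i."""
    n = x.shape[1]
    others = np.delete(np.arange(n), i)
    xo = x[:, others]
    y = x[:, i]
    wsum = weights.sum()

    def objective(theta: np.ndarray):
        h_i, j_i = theta[0], theta[1:]
        z = h_i + xo @ j_i
        # -log-likelihood per unit weight: log(1 + e^z) - y z
        nll = np.logaddexp(0.0, z) - y * z
        loss = float(weights @ nll) / wsum + l2_j * j_i @ j_i + l2_h * h_i * h_i
        p = expit(z)
        resid = weights * (p - y)
        grad = np.empty_like(theta)
        grad[0] = resid.sum() / wsum + 2.0 * l2_h * h_i
        grad[1:] = (xo.T @ resid) / wsum + 2.0 * l2_j * j_i
        return loss, grad

    res = minimize(objective, np.zeros(n), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": 1e-9, "ftol": 1e-15})
    gnorm = float(np.linalg.norm(res.jac))
    if gnorm > gtol:
        raise ConvergenceError(
            f"PLM fit for node {i} did not converge within {max_iter} "
            f"iterations (gradient norm {gnorm:.2e} > {gtol:g})")
    packed = np.empty(n)
    packed[i] = res.x[0]
    packed[others] = res.x[1:]
    return packed


def plm_couplings(ppm: ProfileMatrix, l2_J: float = 0.01, l2_h: float = 0.01,
                  weights: np.ndarray | None = None, max_iter: int = 500,
                  gtol: float = 1e-6) -> CouplingModel:
    """Pseudo-likelihood-maximization couplings.

    For each domain i the conditional likelihood of its column given all
    others, P(n_i = 1 | n_others) = logistic(h_i + sum_{j != i} J_ij n_j),
    is maximized with L2 penalties ``l2_J * sum_j J_ij^2`` and
    ``l2_h * h_i^2`` (per node, on the weight-normalized log-likelihood).
    The two asymmetric estimates of each coupling are averaged:
    J_ij = (J_ij^(i) + J_ij^(j)) / 2.

    ``weights`` optionally assigns a non-negative weight to each row; this
    supports exhaustively enumerated state tables weighted by exact model
    probabilities, giving a sampling-noise-free target for recovery tests.

    Raises ConvergenceError naming the node and the final gradient norm if
    any node fit fails to reach ``gtol``.
    """
    if ppm.n_species < 1 or ppm.n_domains < 2:
        raise ValueError("PPM must be non-empty with at least two domains")
    x = ppm.entries.astype(np.float64)
    if weights is None:
        weights = np.ones(x.shape[0])
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (x.shape[0],) or (weights < 0).any():
            raise ValueError("weights must be non-negative, one per genome")
    col_means = np.average(x, axis=0, weights=weights)
    if ((col_means == 0) | (col_means == 1)).any():
        bad = ppm.domain_ids[int(np.argmax((col_means == 0) | (col_means == 1)))]
        raise ValueError(f"domain {bad!r} has a constant profile column")
    n = ppm.n_domains
    asym = np.zeros((n, n))
    h = np.empty(n)
    for i in range(n):
        packed = _plm_node(x, weights, i, l2_J, l2_h, max_iter, gtol)
        h[i] = packed[i]
        asym[i] = packed
        asym[i, i] = 0.0
    j = (asym + asym.T) / 2.0
    return CouplingModel(j, h, "plm",
                         {"l2_J": l2_J, "l2_h": l2_h, "gtol": gtol},
                         ppm.domain_ids)


def apc_correct(model: CouplingModel) -> CouplingModel:
    """Average product correction of the coupling matrix.

    S'_ij = J_ij - (mean_k J_ik)(mean_k J_jk) / mean_kl J_kl, all means
    over off-diagonal entries.  Removes the rank-one background produced by
    heterogeneous per-domain conservation statistics; applied to the signed
    couplings directly.  If the grand mean is zero the correction is
    undefined and the model is returned unchanged with a warning.
    """
    n = model.n_domains
    if n < 2:
        return model
    row_mean = model.J.sum(axis=1) / (n - 1)  # diagonal is zero
    grand_mean = model.J.sum() / (n * (n - 1))
    if grand_mean == 0.0:
        logger.warning("grand mean of couplings is zero; APC skipped")
        return model
    corrected = model.J - np.outer(row_mean, row_mean) / grand_mean
    corrected = (corrected + corrected.T) / 2.0
    np.fill_diagonal(corrected, 0.0)
    reg = dict(model.regularization, apc=True)
    return CouplingModel(corrected, model.h.copy(), model.method, reg,
                         model.domain_ids)


def rank_pairs(model: CouplingModel, use_apc: bool = False,
               tail: Literal["positive", "negative"] = "positive"
               ) -> PairScoreList:
    """Rank domain pairs by coupling size.

    The positive tail lists pairs with J_ij > 0, strongest first; the
    negative tail lists pairs with J_ij < 0, most negative first.  Zero
    couplings belong to neither tail.  Ties break lexicographically.
    Biases h never enter the ranking.
    """
    scored = apc_correct(model) if use_apc else model
    kind = "coupling_apc" if use_apc else "coupling"
    ids = scored.domain_ids
    triples = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            j = scored.J[a, b]
            if tail == "positive" and j > 0:
                triples.append((ids[a], ids[b], j))
            elif tail == "negative" and j < 0:
                triples.append((ids[a], ids[b], j))
    direction = "larger" if tail == "positive" else "smaller"
    return PairScoreList.from_unsorted(triples, kind, direction)


def write_couplings(model: CouplingModel, path: str | Path,
                    sidecar: str | Path | None = None) -> None:
    """Write couplings as TSV ``domain_i  domain_j  J  J_apc`` (all pairs),
    plus an optional plain key-value sidecar with h and metadata."""
    apc = apc_correct(model)
    ids = model.domain_ids
    with Path(path).open("w") as fh:
        fh.write("domain_i\tdomain_j\tJ\tJ_apc\n")
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                fh.write(f"{ids[a]}\t{ids[b]}\t{model.J[a, b]:.10g}\t"
                         f"{apc.J[a, b]:.10g}\n")
    if sidecar is not None:
        with Path(sidecar).open("w") as fh:
            fh.write(f"method\t{model.method}\n")
            for k, v in model.regularization.items():
                fh.write(f"reg:{k}\t{v}\n")
            for d, hv in zip(ids, model.h):
                fh.write(f"h:{d}\t{hv:.10g}\n")


def read_couplings(path: str | Path, apc: bool = False
                   ) -> tuple[tuple[str, ...], np.ndarray]:
    """Read a couplings TSV back into (domain_ids, J matrix)."""
    pairs: dict[tuple[str, str], float] = {}
    ids: list[str] = []
    seen = set()
    col = 3 if apc else 2
    with Path(path).open() as fh:
        header = fh.readline()
        assert header.startswith("domain_i")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            i, j, val = parts[0], parts[1], float(parts[col])
            pairs[(i, j)] = val
            for d in (i, j):
                if d not in seen:
                    seen.add(d)
                    ids.append(d)
    ids.sort()
    index = {d: k for k, d in enumerate(ids)}
    jmat = np.zeros((len(ids), len(ids)))
    for (i, j), val in pairs.items():
        jmat[index[i], index[j]] = val
        jmat[index[j], index[i]] = val
    return tuple(ids), jmat
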