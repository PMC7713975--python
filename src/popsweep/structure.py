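"""Population structure: normalised PCA, admixture EM, p-distance NJ trees.

PCA follows the Patterson normalisation: dosages are centred per site and
scaled by sqrt(p(1-p)) with p the sample allele frequency; missing entries
are mean-imputed (zero after centring).  Admixture is the standard K-source
binomial mixture (individual i carries ancestry fractions q_ik over sources
with allele frequencies f_kj), fit by EM with restarts.  Trees come from
p-distances (mean dosage difference / 2, pairwise deletion) through
neighbor joining, with nonparametric bootstrap over sites for support.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

logger = logging.getLogger(__name__)

_EPS = 1e-9


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_patterson(
    G: np.ndarray, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenanalysis of Patterson-normalised genotypes.

    ``G`` is samples x sites dosage (0/1/2, -1 missing).  Monomorphic and
    all-missing sites are dropped; missing entries become 0 after centring
    (mean imputation).  Returns (coordinates, eigenvalues): coordinates are
    the top eigenvectors of the sample covariance scaled by sqrt(eigenvalue),
    eigenvalues in decreasing order, clipped at zero.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    miss = G < 0
    Gm = np.where(miss, np.nan, G)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(Gm, axis=0)
    p_hat = mu / 2.0
    poly = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    X = (Gm[:, poly] - mu[poly]) / np.sqrt(p_hat[poly] * (1.0 - p_hat[poly]))
    X[~np.isfinite(X)] = 0.0
    m = X.shape[1]
    C = X @ X.T / m
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    return coords, eigval


#: TW1 critical values (Tracy-Widom GOE) at the 95th and 99th percentiles.
_TW1_CRITICAL = {0.05: 0.9793, 0.01: 2.0234}


def tracy_widom_scores(eigenvalues: np.ndarray, n_samples: int) -> "np.recarray":
    """Moment-matched standardized Tracy-Widom scores for leading eigenvalues.

    An optional significance report: each eigenvalue (largest first) is
    standardized against the remaining spectrum using the moment-matching
    effective marker count, and flagged significant when the score exceeds
    the tabulated TW1 95th/99th percentile.  No full TW distribution is
    shipped; only these two critical values are used.
    """
    lam = np.sort(np.asarray(eigenvalues, float))[::-1]
    lam = lam[lam > 0]
    out = []
    for i in range(len(lam) - 1):
        tail = lam[i:]
        m = len(tail)
        # effective number of markers from the spectrum's moments
        n_eff = (n_samples + 1) * tail.sum() ** 2 / (
            ((n_samples - 1) * (tail ** 2).sum()) - tail.sum() ** 2
        )
        if not np.isfinite(n_eff) or n_eff <= 0:
            break
        ell = (m * tail[0]) / tail.sum()
        sq_n, sq_m = np.sqrt(n_eff - 1), np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        tw = (ell - mu) / sigma
        out.append((i + 1, tw, tw > _TW1_CRITICAL[0.05], tw > _TW1_CRITICAL[0.01]))
    rec = np.array(out, dtype=[("component", int), ("tw", float),
                               ("sig_05", bool), ("sig_01", bool)])
    return rec.view(np.recarray)


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    """Result of one admixture EM fit (best of the restarts).

    Q rows (samples x K) sum to one; F (K x sites) holds source allele
    frequencies; ``loglik_trace`` is the per-iteration log-likelihood of
    the winning restart (non-decreasing).
    """

    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik_trace: list[float]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _admixture_loglik(G, miss, Q, F) -> float:
    theta = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    ll = np.where(miss, 0.0, G * np.log(theta) + (2.0 - G) * np.log1p(-theta))
    return float(ll.sum())


def admixture_em(
    G: np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> AdmixtureFit:
    """Fit the K-source admixture model by EM, keeping the best restart.

    The complete-data E-step assigns each of an individual's 2 allele
    copies at a site to a source; M-step updates are the usual ratios of
    expected counts.  Missing genotypes are excluded from all sums.
    Log-likelihood is non-decreasing every iteration (up to the [eps,1-eps]
    clipping of Q and F); iteration stops when it improves by < ``tol``.
    """
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    miss = G < 0
    Gz = np.where(miss, 0.0, G)
    G2 = np.where(miss, 0.0, 2.0 - G)
    n_called = (~miss).sum(axis=1).astype(float)
    if np.any(n_called == 0):
        raise ValueError("sample with no called genotypes")

    master = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, n_restarts)):
        rng = np.random.default_rng(master.integers(2 ** 31))
        Q = rng.dirichlet(np.ones(K), size=n)
        freqs = Gz.sum(axis=0) / np.maximum((~miss).sum(axis=0), 1) / 2.0
        F = np.clip(freqs[None, :] + rng.normal(0, 0.1, size=(K, m)), 0.05, 0.95)
        trace = []
        prev = -np.inf
        for _it in range(max_iter):
            Qc = np.clip(Q, _EPS, None)
            Fc = np.clip(F, _EPS, 1.0 - _EPS)
            theta = np.clip(Qc @ Fc, _EPS, 1.0 - _EPS)
            ll = _admixture_loglik(G, miss, Qc, Fc)
            trace.append(ll)
            A_sum = np.zeros((n, K))  # expected alt copies from source k
            B_sum = np.zeros((n, K))  # expected ref copies from source k
            F_new = np.empty_like(F)
            for k in range(K):
                alt_resp = Qc[:, k:k + 1] * Fc[k][None, :] / theta
                ref_resp = Qc[:, k:k + 1] * (1.0 - Fc[k][None, :]) / (1.0 - theta)
                Ak = Gz * alt_resp
                Bk = G2 * ref_resp
                A_sum[:, k] = Ak.sum(axis=1)
                B_sum[:, k] = Bk.sum(axis=1)
                denom = Ak.sum(axis=0) + Bk.sum(axis=0)
                F_new[k] = np.where(denom > 0, Ak.sum(axis=0) / np.maximum(denom, _EPS), Fc[k])
            Q = (A_sum + B_sum) / (2.0 * n_called[:, None])
            Q = np.clip(Q, _EPS, None)
            Q /= Q.sum(axis=1, keepdims=True)
            F = np.clip(F_new, _EPS, 1.0 - _EPS)
            if ll - prev < tol and _it > 0:
                break
            prev = ll
        final_ll = _admixture_loglik(G, miss, Q, F)
        trace.append(final_ll)
        fit = AdmixtureFit(K=K, Q=Q, F=F, loglik_trace=trace)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def align_q_columns(Q: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Resolve label switching: greedily permute Q's columns to best match
    Q_ref by correlation.  Returns the permuted copy of Q."""
    K = Q.shape[1]
    perm = [-1] * K
    used: set[int] = set()
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            sa, sb = np.std(Q[:, a]), np.std(Q_ref[:, b])
            if sa == 0 or sb == 0:
                corr[a, b] = -np.inf if a != b else 0.0
            else:
                corr[a, b] = np.corrcoef(Q[:, a], Q_ref[:, b])[0, 1]
    for _ in range(K):
        a, b = np.unravel_index(np.argmax(np.where(
            np.isfinite(corr), corr, -np.inf)), corr.shape)
        perm[b] = a
        corr[a, :] = -np.inf
        corr[:, b] = -np.inf
    return Q[:, perm]


# ---------------------------------------------------------------------------
# p-distances and neighbor joining
# ---------------------------------------------------------------------------

def p_distance_matrix(G: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    """Pairwise p-distances: mean |dosage_i - dosage_j| / 2 over sites
    non-missing in both samples (pairwise deletion).

    Raises if any pair shares no called sites (distance undefined).
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    called = G >= 0
    Gz = np.where(called, G, 0.0)
    shared = called.astype(float) @ called.astype(float).T
    # sum over shared sites of |g_i - g_j| via expansion is not linear; loop rows
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(Gz[i][None, :] - Gz) / 2.0
        both = called[i][None, :] & called
        D[i] = np.where(both, diff, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(shared > 0, D / shared, np.nan)
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        raise ValueError("sample pair with zero shared called sites")
    return DistanceMatrix(D, list(labels))


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if D.shape[0] < 3:
        raise ValueError("NJ requires at least three taxa")
    return _skbio_nj(D, neg_as_zero=True)


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised as
    the smaller tip-name side (lexicographic tie-break)."""
    tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(_canon(side, other))
    return out


def _canon(a: frozenset, b: frozenset) -> frozenset:
    if len(a) != len(b):
        return a if len(a) < len(b) else b
    return a if min(a) < min(b) else b


def bootstrap_support(
    G: np.ndarray,
    labels: Sequence[str],
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from p-distances with bootstrap support over sites.

    Site columns are resampled with replacement ``n_reps`` times; support
    of a bipartition is the percentage of replicate trees containing it.
    Supports are attached to the internal nodes of the returned tree
    (``node.support``) and returned keyed by bipartition.
    """
    G = np.asarray(G)
    if G.shape[0] < 4:
        raise ValueError("bootstrap support needs at least four samples")
    tree = nj_tree(p_distance_matrix(G, labels))
    target = tree_bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    m = G.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        try:
            rep_tree = nj_tree(p_distance_matrix(G[:, cols], labels))
        except ValueError:
            continue  # a replicate can lose all shared sites for a pair
        rep_bps = tree_bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    tips = frozenset(labels)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        bp = _canon(side, tips - side)
        if bp in support:
            node.support = support[bp]
    return tree, support


# ---------------------------------------------------------------------------
# Newick IO and outgroup rooting
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialise a tree; internal-node ``support`` values become labels."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    """Read Newick; numeric internal labels are exposed as ``node.support``."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    tree.assign_supports()  # numeric internal labels -> node.support
    return tree


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Root on the branch leading to ``outgroup``, making it sister to the
    rest of the taxa."""
    try:
        tip = tree.find(outgroup)
    except Exception as exc:
        raise ValueError(f"outgroup {outgroup!r} not in tree") from exc
    rooted = tree.root_at(tip, above=True, reset=True)
    return rooted


def tree_from_newick_string(s: str) -> TreeNode:
    return TreeNode.read(io.StringIO(s), format="newick")
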