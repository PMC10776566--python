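"""Model-based and ordination views of nuclear population structure.

The admixture model is a Gibbs sampler over individual membership fractions
Q and per-cluster allele frequencies P: each of an individual's two allele
copies at a locus is assigned a cluster of origin given (Q, P), cluster
allele frequencies are redrawn from their Beta conjugate posteriors, and Q
rows from Dirichlet posteriors. Cluster number is chosen with the Evanno
ΔK second-difference criterion over replicate runs. PCoA (classical
multidimensional scaling with negative eigenvalues reported) and DAPC
(PCA followed by linear discriminant analysis) give the ordination views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .popgen_snp import MISSING, GenotypeDataset, PairwiseMatrix

__all__ = [
    "AdmixtureFit",
    "admixture_fit",
    "align_clusters",
    "delta_k",
    "pcoa",
    "dapc",
    "allele_sharing_distance",
]


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_ind, K) posterior-mean memberships
    allele_freqs: np.ndarray  # (K, n_loci)
    loglik_trace: np.ndarray
    iters: int
    burnin: int
    seed: int | None

    @property
    def mean_loglik(self) -> float:
        """Post-burn-in mean log-likelihood (the per-run summary ΔK uses)."""
        return float(np.mean(self.loglik_trace[self.burnin :]))

    def q_dataframe(self, ind_ids=None, localities=None) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"Q{k + 1}" for k in range(self.K)])
        if ind_ids is not None:
            df.insert(0, "individual", ind_ids)
        if localities is not None:
            df.insert(1, "locality", list(localities))
        return df


def _multinomial_rows(n: np.ndarray, W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised multinomial draws: n (N,L) trials with probabilities W (N,L,K)."""
    K = W.shape[-1]
    counts = np.zeros(W.shape, dtype=np.int64)
    rem = n.astype(np.int64).copy()
    prob_left = np.ones(n.shape)
    for k in range(K - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            pk = np.where(prob_left > 0, W[..., k] / prob_left, 0.0)
        c = rng.binomial(rem, np.clip(pk, 0.0, 1.0))
        counts[..., k] = c
        rem -= c
        prob_left = np.maximum(prob_left - W[..., k], 0.0)
    counts[..., K - 1] = rem
    return counts


def admixture_fit(
    gd: GenotypeDataset,
    K: int,
    iters: int = 10000,
    burnin: int = 2000,
    seed: int | None = None,
    alpha: float = 1.0,
) -> AdmixtureFit:
    """Fit the admixture model by Gibbs sampling.

    Priors are Dirichlet(alpha,...,alpha) on each Q row and Beta(1,1) on each
    cluster allele frequency (independent frequencies across clusters). The
    returned Q and allele frequencies are posterior means over post-burn-in
    sweeps; the log-likelihood of the current state is recorded every sweep.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gd.n_ind:
        raise ValueError("K exceeds the number of individuals")
    if iters <= burnin:
        raise ValueError("iters must exceed burnin")
    rng = np.random.default_rng(seed)
    g = gd.dosage.astype(np.int64)
    ok = g != MISSING
    g1 = np.where(ok, g, 0)  # copies carrying the minor allele
    g0 = np.where(ok, 2 - g, 0)  # copies carrying the major allele
    N, L = g.shape
    const = np.sum(np.where(ok & (g == 1), np.log(2.0), 0.0))

    P = rng.uniform(0.2, 0.8, size=(K, L))
    Q = rng.dirichlet(np.full(K, alpha), size=N)
    Q_sum = np.zeros((N, K))
    P_sum = np.zeros((K, L))
    ll_trace = np.empty(iters)
    n_keep = 0
    eps = 1e-12

    for it in range(iters):
        if K == 1:
            n1 = g1.sum(axis=0)
            n0 = g0.sum(axis=0)
            P = rng.beta(1.0 + n1, 1.0 + n0)[None, :]
            Q = np.ones((N, 1))
        else:
            # cluster-of-origin weights per copy type: (N, L, K)
            w1 = Q[:, None, :] * P.T[None, :, :]
            w0 = Q[:, None, :] * (1.0 - P.T[None, :, :])
            w1 /= np.maximum(w1.sum(axis=2, keepdims=True), eps)
            w0 /= np.maximum(w0.sum(axis=2, keepdims=True), eps)
            c1 = _multinomial_rows(g1, w1, rng)
            c0 = _multinomial_rows(g0, w0, rng)
            n1 = c1.sum(axis=0).T  # (K, L)
            n0 = c0.sum(axis=0).T
            P = rng.beta(1.0 + n1, 1.0 + n0)
            z_counts = c1.sum(axis=1) + c0.sum(axis=1)  # (N, K)
            gam = rng.standard_gamma(alpha + z_counts)
            Q = gam / gam.sum(axis=1, keepdims=True)
        pi = np.clip(Q @ P, eps, 1.0 - eps)
        ll_trace[it] = const + np.sum(
            np.where(ok, g1 * np.log(pi) + g0 * np.log(1.0 - pi), 0.0)
        )
        if it >= burnin:
            Q_sum += Q
            P_sum += P
            n_keep += 1
    Q_mean = Q_sum / n_keep
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AdmixtureFit(
        K=K,
        Q=Q_mean,
        allele_freqs=P_sum / n_keep,
        loglik_trace=ll_trace,
        iters=iters,
        burnin=burnin,
        seed=seed,
    )


def align_clusters(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Greedy column alignment of Q onto Q_ref (handles label switching).

    Columns are matched in order of decreasing overlap (dot product),
    deterministically; returns Q with columns permuted.
    """
    K = Q_ref.shape[1]
    if Q.shape[1] != K:
        raise ValueError("Q matrices must share K")
    overlap = Q_ref.T @ Q
    perm = np.full(K, -1)
    used = set()
    order = np.argsort(-overlap, axis=None)
    for flat in order:
        i, j = divmod(int(flat), K)
        if perm[i] == -1 and j not in used:
            perm[i] = j
            used.add(j)
    return Q[:, perm]


def delta_k(runs: dict) -> pd.DataFrame:
    """Evanno ΔK from replicate per-K log-likelihood summaries.

    ``runs`` maps K → iterable of mean log-likelihoods (≥3 replicates each,
    contiguous K range). ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| /
    sd(L(K)); undefined at the range ends or where sd = 0.
    """
    ks = sorted(runs)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks:
        if len(list(runs[k])) < 3:
            raise ValueError("need >= 3 replicate runs per K")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1] and sd[k] > 0:
            dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append({"K": k, "mean_loglik": mean[k], "sd_loglik": sd[k], "delta_k": dk})
    df = pd.DataFrame(rows).set_index("K")
    finite = df["delta_k"].dropna()
    df.attrs["best_k"] = int(finite.idxmax()) if len(finite) else None
    return df


def pcoa(dist, n_axes: int | None = None):
    """Principal coordinates analysis (Gower centring + eigendecomposition).

    Accepts a :class:`PairwiseMatrix` or a square symmetric array. Returns
    (coordinates, eigenvalues) with axes ordered by eigenvalue; negative
    eigenvalues are reported as-is.
    """
    if isinstance(dist, PairwiseMatrix):
        mat = dist.values
        ids = [str(l) for l in dist.labels]
    else:
        mat = np.asarray(dist, dtype=float)
        ids = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _skbio_pcoa(DistanceMatrix(mat, ids=ids), method="eigh", number_of_dimensions=0)
    coords = res.samples.to_numpy()
    eig = res.eigvals.to_numpy()
    if n_axes is not None:
        coords = coords[:, :n_axes]
    return coords, eig


def allele_sharing_distance(gd: GenotypeDataset) -> np.ndarray:
    """Individual × individual allele-sharing distance.

    Per locus d = |g_i − g_j| / 2; averaged over loci non-missing in both
    individuals.
    """
    g = gd.dosage.astype(float)
    g[gd.dosage == MISSING] = np.nan
    n = gd.n_ind
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g - g[i]) / 2.0
        out[i] = np.nanmean(diff, axis=1)
        out[i, i] = 0.0
    return 0.5 * (out + out.T)


def dapc(
    gd: GenotypeDataset,
    groups=None,
    n_pcs: int | None = None,
    n_da: int | None = None,
    variance_fraction: float = 0.90,
):
    """Discriminant analysis of principal components.

    Centred (mean-imputed) dosages are reduced to ``n_pcs`` principal
    components — default: the smallest set explaining ≥ ``variance_fraction``
    of variance — then linear discriminant analysis separates the groups.
    Returns a dict with discriminant scores, posterior group memberships,
    self-assignment accuracy and the retained component counts.
    """
    labels = np.asarray(list(groups) if groups is not None else gd.localities, dtype=object)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("DAPC needs at least 2 groups")
    for u in uniq:
        if np.sum(labels == u) == 1:
            warnings.warn(f"group {u!r} has a single member; covariance is pooled", stacklevel=2)
    X = gd.dosage.astype(float)
    X[gd.dosage == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= X.mean(axis=0)
    max_pcs = min(gd.n_ind - 1, gd.n_loci)
    pca = PCA(n_components=max_pcs)
    scores = pca.fit_transform(X)
    if n_pcs is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_pcs = int(np.searchsorted(cum, variance_fraction) + 1)
    n_pcs = min(n_pcs, max_pcs)
    if n_da is None:
        n_da = min(len(uniq) - 1, n_pcs)
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    da_scores = lda.fit_transform(scores[:, :n_pcs], labels)
    post = lda.predict_proba(scores[:, :n_pcs])
    pred = lda.predict(scores[:, :n_pcs])
    return {
        "scores": da_scores,
        "posteriors": pd.DataFrame(post, columns=list(lda.classes_)),
        "assignments": pred,
        "accuracy": float(np.mean(pred == labels)),
        "n_pcs": n_pcs,
        "n_da": n_da,
    }
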