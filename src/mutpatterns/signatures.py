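"""Mutational-signature analysis.

Two complementary routes are provided:

* **De novo extraction** (`extract_signatures`): non-negative matrix
  factorization of the 96 x samples count matrix with multiplicative
  updates, generalized Kullback-Leibler objective by default, multiple
  seeded restarts. Requires a cohort; the factorization changes when
  samples are added.
* **Refitting** (`fit_to_signatures` / `nnls_fit`): for each sample
  independently, find the non-negative linear combination of *known*
  signatures that best reconstructs its profile,

      min_x || S @ x - d ||_2^2   subject to  x >= 0,

  solved with the Lawson-Hanson active-set method. This works on a
  single sample and is the tool of choice for relating new catalogues to
  published signatures.

Reconstruction quality is judged by the cosine similarity between the
original and reconstructed profile; samples below 0.95 are flagged as
not fully explained by the provided signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize

#: samples whose reconstructed profile has cosine similarity below this
#: are flagged as incompletely explained by the provided signatures
RECONSTRUCTION_COSINE_THRESHOLD = 0.95

_EPS = 1e-12  # floor inside NMF divisions/logarithms


def cos_sim(a, b) -> float:
    """Cosine similarity between two non-negative profiles.

    alpha = sum(a_i b_i) / (||a|| ||b||); 1 for identical direction, 0 for
    disjoint support. Scale-invariant, so profiles need not be normalized.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors have different lengths")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("all-zero profile")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def cos_sim_matrix(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarities between the columns of A and of B.

    A and B are channels x profiles frames sharing the same channel order;
    the result is len(A.columns) x len(B.columns).
    """
    if list(A.index) != list(B.index):
        raise ValueError("channel order mismatch between the two matrices")
    Av = np.asarray(A, dtype=float)
    Bv = np.asarray(B, dtype=float)
    na = np.linalg.norm(Av, axis=0)
    nb = np.linalg.norm(Bv, axis=0)
    if (na == 0).any() or (nb == 0).any():
        raise ValueError("all-zero profile column")
    sim = (Av.T @ Bv) / np.outer(na, nb)
    return pd.DataFrame(np.clip(sim, 0.0, 1.0), index=A.columns, columns=B.columns)


def nnls_fit(S, d) -> np.ndarray:
    """Non-negative least-squares signature weights for one profile.

    Minimizes ||S @ x - d||_2^2 subject to x >= 0 (Lawson-Hanson active
    set). S is channels x K, d a count or frequency vector.
    """
    S = np.asarray(S, dtype=float)
    d = np.asarray(d, dtype=float).ravel()
    if S.ndim != 2 or S.shape[0] != d.shape[0]:
        raise ValueError(f"shape mismatch: S is {S.shape}, d has length {d.shape[0]}")
    if (S < 0).any() or (d < 0).any():
        raise ValueError("negative input to NNLS")
    x, _ = scipy.optimize.nnls(S, d)
    return x


@dataclass
class FitResult:
    """Refit of known signatures to a cohort of mutation profiles."""

    contributions: pd.DataFrame  # signatures x samples, estimated mutation counts
    diagnostics: pd.DataFrame  # per sample: cosine, rss, flagged
    reconstructed: pd.DataFrame  # channels x samples, S @ x

    def relative_contributions(self) -> pd.DataFrame:
        """Per-sample fractions weight / sum(weights) (stack to 1)."""
        totals = self.contributions.sum(axis=0)
        out = self.contributions.copy()
        nz = totals > 0
        out.loc[:, nz] = out.loc[:, nz] / totals[nz]
        return out


def fit_to_signatures(M: pd.DataFrame, S: pd.DataFrame) -> FitResult:
    """Column-wise NNLS refit of the signature matrix S to each sample of M.

    Each sample is fitted independently; adding or removing other samples
    never changes a sample's weights. Diagnostics report, per sample, the
    cosine similarity between the original and reconstructed profile and
    the RSS of the two sum-1-normalized profiles; cosine below
    ``RECONSTRUCTION_COSINE_THRESHOLD`` flags the sample.
    """
    if list(M.index) != list(S.index):
        raise ValueError("channel order mismatch between matrix and signatures")
    Sv = np.asarray(S, dtype=float)
    contribs = {}
    recon = {}
    diag_rows = []
    for sample in M.columns:
        d = M[sample].to_numpy(dtype=float)
        x = nnls_fit(Sv, d)
        r = Sv @ x
        contribs[sample] = x
        recon[sample] = r
        if d.sum() > 0 and r.sum() > 0:
            alpha = cos_sim(d, r)
            dn, rn = d / d.sum(), r / r.sum()
            rss = float(((dn - rn) ** 2).sum())
        else:
            alpha, rss = 0.0, float("nan")
        diag_rows.append(
            {
                "sample": sample,
                "cosine": alpha,
                "rss": rss,
                "flagged": alpha < RECONSTRUCTION_COSINE_THRESHOLD,
            }
        )
    return FitResult(
        contributions=pd.DataFrame(contribs, index=list(S.columns)),
        diagnostics=pd.DataFrame(diag_rows).set_index("sample"),
        reconstructed=pd.DataFrame(recon, index=list(M.index)),
    )


# ---------------------------------------------------------------------------
# de novo extraction: NMF with multiplicative updates
# ---------------------------------------------------------------------------


def _nmf_objective(V, W, H, objective: str) -> float:
    WH = W @ H
    if objective == "kl":
        # generalized KL divergence D(V || WH)
        mask = V > 0
        div = np.zeros_like(V)
        div[mask] = V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))
        return float(div.sum() - V.sum() + WH.sum())
    return float(((V - WH) ** 2).sum())


def _nmf_single_run(V, rank, rng, objective, tol, max_iter):
    m, n = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = scale * (0.1 + rng.random((m, rank)))
    H = scale * (0.1 + rng.random((rank, n)))
    history = [_nmf_objective(V, W, H, objective)]
    for _ in range(max_iter):
        if objective == "kl":
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1), _EPS)
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        else:
            W *= (V @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
            H *= (W.T @ V) / np.maximum((W.T @ W) @ H, _EPS)
        obj = _nmf_objective(V, W, H, objective)
        history.append(obj)
        prev = history[-2]
        if prev - obj <= tol * max(abs(prev), _EPS):
            break
    return W, H, history


@dataclass
class NmfResult:
    """Best-of-nrun NMF factorization of a mutation count matrix."""

    signatures: pd.DataFrame  # channels x rank, columns sum to 1
    contributions: pd.DataFrame  # rank x samples, scaled so S @ C reconstructs M
    objectives: list  # final objective of every run, in run order
    best_run: int
    seed: int
    objective: str
    history: list = field(default_factory=list)  # objective per iteration, best run

    def reconstructed(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signatures.to_numpy() @ self.contributions.to_numpy(),
            index=self.signatures.index,
            columns=self.contributions.columns,
        )


def extract_signatures(
    M: pd.DataFrame,
    rank: int,
    nrun: int = 10,
    seed: int = 0,
    objective: str = "kl",
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> NmfResult:
    """De novo signature extraction by NMF with multiplicative updates.

    Runs ``nrun`` random restarts (run r is seeded with ``seed + r``) and
    keeps the run with the lowest final objective (ties: lowest run
    index). The objective is the generalized Kullback-Leibler divergence
    by default (``objective="frobenius"`` for squared error) and is
    non-increasing over iterations within each run. Signature columns are
    normalized to sum 1, with contributions rescaled so the product is
    unchanged; in consequence the contributions are on the scale of
    mutation counts. Deterministic: same seed and input give an identical
    result.
    """
    runs = _extract_all_runs(M, rank, nrun, seed, objective, tol, max_iter)
    return _best_run_result(M, runs, seed, objective)


def _extract_all_runs(M, rank, nrun, seed, objective, tol, max_iter):
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")
    if nrun < 1:
        raise ValueError("nrun must be >= 1")
    V = np.asarray(M, dtype=float)
    m, n = V.shape
    if rank >= min(m, n):
        raise ValueError(f"rank {rank} must be < min(channels, samples) = {min(m, n)}")
    if (V < 0).any():
        raise ValueError("negative entries in mutation matrix")
    if (V.sum(axis=0) == 0).any():
        zero = [c for c, s in zip(M.columns, V.sum(axis=0)) if s == 0]
        raise ValueError(f"all-zero sample column(s): {zero}")
    runs = []
    for r in range(nrun):
        rng = np.random.default_rng(seed + r)
        W, H, history = _nmf_single_run(V, rank, rng, objective, tol, max_iter)
        runs.append((W, H, history))
    return runs


def _normalize_wh(W, H):
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return W / colsum, H * colsum[:, None]


def _best_run_result(M, runs, seed, objective) -> NmfResult:
    finals = [run[2][-1] for run in runs]
    best = int(np.argmin(finals))  # argmin takes the first minimum: lowest run index on ties
    W, H, history = runs[best]
    W, H = _normalize_wh(W, H)
    rank = W.shape[1]
    if rank <= 26:
        names = [f"Signature_{chr(ord('A') + k)}" for k in range(rank)]
    else:
        names = [f"Signature_{k + 1}" for k in range(rank)]
    return NmfResult(
        signatures=pd.DataFrame(W, index=list(M.index), columns=names),
        contributions=pd.DataFrame(H, index=names, columns=list(M.columns)),
        objectives=[float(f) for f in finals],
        best_run=best,
        seed=seed,
        objective=objective,
        history=[float(h) for h in history],
    )


def match_signatures(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Optimal one-to-one matching of signature columns by cosine similarity.

    Hungarian assignment maximizing total cosine; returns a table with one
    row per matched pair (column names from A and B plus their cosine).
    """
    sim = cos_sim_matrix(A, B)
    rows, cols = scipy.optimize.linear_sum_assignment(-sim.to_numpy())
    return pd.DataFrame(
        {
            "a": [sim.index[i] for i in rows],
            "b": [sim.columns[j] for j in cols],
            "cosine": [float(sim.iat[i, j]) for i, j in zip(rows, cols)],
        }
    )


def rank_survey(
    M: pd.DataFrame,
    ranks,
    nrun: int = 10,
    seed: int = 0,
    objective: str = "kl",
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Factorization-quality summary over candidate ranks.

    For each rank the NMF is run ``nrun`` times; reported are the best
    final objective, the mean per-sample cosine between original and
    reconstructed profiles, and the signature stability (mean cosine of
    Hungarian-matched signatures between each restart and the best run).
    The rank where reconstruction stops improving sharply and stability
    stays high is the natural number of signatures.
    """
    records = []
    for rank in ranks:
        if rank < 2:
            raise ValueError("ranks must be >= 2")
        runs = _extract_all_runs(M, rank, nrun, seed, objective, tol, max_iter)
        result = _best_run_result(M, runs, seed, objective)
        recon = result.reconstructed()
        cosines = [cos_sim(M[c], recon[c]) for c in M.columns]
        stabilities = []
        for r, (W, H, _) in enumerate(runs):
            if r == result.best_run:
                continue
            Wn, _ = _normalize_wh(W, H)
            Wdf = pd.DataFrame(Wn, index=list(M.index))
            stabilities.append(match_signatures(result.signatures, Wdf)["cosine"].mean())
        records.append(
            {
                "rank": rank,
                "best_objective": min(result.objectives),
                "mean_reconstruction_cosine": float(np.mean(cosines)),
                "stability": float(np.mean(stabilities)) if stabilities else 1.0,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Average-linkage hierarchical clustering of sample row-vectors."""

    linkage: np.ndarray
    leaf_order: list
    labels: list

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            inner = f"({walk(node.left, node.dist)},{walk(node.right, node.dist)})"
            return f"{inner}:{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cluster_samples(profile_matrix: pd.DataFrame) -> ClusterResult:
    """Cluster samples (rows) by Euclidean distance, average linkage.

    Typical input: the samples x signatures matrix of cosine similarities
    (or contributions). Leaf order is deterministic for a given input.
    """
    if profile_matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = np.asarray(profile_matrix, dtype=float)
    Z = sch.linkage(X, method="average", metric="euclidean")
    order = sch.leaves_list(Z)
    labels = list(profile_matrix.index)
    return ClusterResult(linkage=Z, leaf_order=[labels[i] for i in order], labels=labels)
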