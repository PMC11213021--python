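"""Statistical coupling analysis (SCA).

Quantifies conservation-weighted covariation between alignment positions and
decomposes it into groups of coevolving positions (independent components,
ICs).  The chain is:

1. sequence weights ``w_s = 1/#{t : identity(s,t) >= cutoff}`` correcting for
   alignment redundancy (``m_eff`` = sum of weights, the "effective" number
   of sequences);
2. weighted single- and pairwise-column frequencies with a small uniform
   pseudocount (gap counted as a 21st state);
3. positional conservation: binary relative entropy ``D_i^a`` against a
   background amino-acid distribution and its derivative weights
   ``phi_i^a = ln[f(1-q)/(q(1-f))]``;
4. the coupling matrix ``C_ij = || phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b) ||_F``
   with the Frobenius norm running over the 20 amino acids (gap excluded);
5. eigenmode significance by comparison with column-shuffled alignments;
6. a fixed-point ICA rotation of the significant eigenvectors;
7. IC membership by the upper tail of a t location-scale fit to the loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .msa_io import (
    AMINO_ACIDS,
    GAP_IDX,
    N_AA,
    PositionMap,
    ProcessedAlignment,
    UNKNOWN_IDX,
)

N_STATES = N_AA + 1  # 20 amino acids + gap

#: Background amino-acid frequencies from large sequence databases, indexed by
#: the alphabet ACDEFGHIKLMNPQRSTVWY. Standard table used in coupling analysis.
BACKGROUND_DB = np.array(
    [0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
     0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033]
)

#: Uniform background; preferred in tests and synthetic studies.
BACKGROUND_UNIFORM = np.full(N_AA, 1.0 / N_AA)


# ---------------------------------------------------------------------------
# sequence weights
# ---------------------------------------------------------------------------

@dataclass
class SequenceWeights:
    w: np.ndarray
    m_eff: float
    identity_cutoff: float

    def __post_init__(self) -> None:
        if np.any(self.w <= 0) or np.any(self.w > 1 + 1e-12):
            raise ValueError("weights must lie in (0, 1]")


def _encoded(msa: ProcessedAlignment | np.ndarray) -> np.ndarray:
    if isinstance(msa, np.ndarray):
        return msa
    return msa.alignment.to_integer_matrix()


def pairwise_identity_matrix(X: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Fraction of identical columns for every sequence pair (gap==gap counts)."""
    M = X.shape[0]
    out = np.empty((M, M))
    for start in range(0, M, chunk):
        stop = min(start + chunk, M)
        eq = X[start:stop, None, :] == X[None, :, :]
        out[start:stop] = eq.mean(axis=2)
    return out


def compute_sequence_weights(
    msa: ProcessedAlignment | np.ndarray, identity_cutoff: float = 0.8
) -> SequenceWeights:
    """Down-weight redundant sequences by their neighbourhood size.

    ``w_s = 1 / #{t : identity(s, t) >= cutoff}`` (self included), where
    identity is the fraction of identical columns.  ``m_eff = sum(w)``.
    """
    if not 0.0 < identity_cutoff <= 1.0:
        raise ValueError(f"identity_cutoff={identity_cutoff} outside (0, 1]")
    X = _encoded(msa)
    ident = pairwise_identity_matrix(X)
    counts = np.sum(ident >= identity_cutoff - 1e-12, axis=1)
    w = 1.0 / counts
    return SequenceWeights(w=w, m_eff=float(w.sum()), identity_cutoff=identity_cutoff)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class FrequencyModel:
    """Weighted first- and second-order column statistics.

    ``f1[i, a]``: frequency of state ``a`` (20 aa + gap) at column ``i``.
    ``f2[i, a, j, b]``: joint frequency at the column pair ``(i, j)``.
    """

    f1: np.ndarray             # (L, 21)
    f2: np.ndarray             # (L, 21, L, 21)
    pseudocount: float

    @property
    def n_columns(self) -> int:
        return self.f1.shape[0]


def _one_hot(X: np.ndarray) -> np.ndarray:
    """(M, L, 21) indicator; the unknown state maps onto the gap state."""
    Xg = np.where(X == UNKNOWN_IDX, GAP_IDX, X)
    M, L = Xg.shape
    oh = np.zeros((M, L, N_STATES), dtype=np.float64)
    m_idx = np.repeat(np.arange(M), L)
    l_idx = np.tile(np.arange(L), M)
    oh[m_idx, l_idx, Xg.ravel()] = 1.0
    return oh


def compute_frequencies(
    msa: ProcessedAlignment | np.ndarray,
    weights: SequenceWeights,
    pseudocount: float = 0.03,
) -> FrequencyModel:
    """Weighted empirical frequencies mixed with a uniform pseudocount.

    ``f1 = (1-l) f1_emp + l/21`` and ``f2 = (1-l) f2_emp + l/21^2`` so that
    marginalising ``f2`` over one column recovers ``f1`` exactly.
    """
    if not 0.0 <= pseudocount < 1.0:
        raise ValueError(f"pseudocount={pseudocount} outside [0, 1)")
    X = _encoded(msa)
    if X.shape[0] != weights.w.shape[0]:
        raise ValueError("weights do not match alignment size")
    oh = _one_hot(X)
    M, L, _ = oh.shape
    flat = oh.reshape(M, L * N_STATES)
    wsum = weights.w.sum()
    f1_emp = (weights.w @ flat).reshape(L, N_STATES) / wsum
    f2_emp = (flat * weights.w[:, None]).T @ flat / wsum
    lam = pseudocount
    f1 = (1.0 - lam) * f1_emp + lam / N_STATES
    f2 = (1.0 - lam) * f2_emp.reshape(L, N_STATES, L, N_STATES) + lam / N_STATES**2
    return FrequencyModel(f1=f1, f2=f2, pseudocount=lam)


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    background: np.ndarray      # (20,)
    d_per_residue: np.ndarray   # (L, 20) binary relative entropy
    phi: np.ndarray             # (L, 20) positional weights
    d_total: np.ndarray         # (L,)    per-column conservation

    def __post_init__(self) -> None:
        if np.any(self.d_per_residue < -1e-12):
            raise ValueError("relative entropy must be nonnegative")


_EPS = 1e-12


def positional_conservation(
    freqs: FrequencyModel, background: np.ndarray | None = None
) -> ConservationProfile:
    """Binary relative entropy and its derivative weights per column/residue.

    ``D_i^a = f ln(f/q) + (1-f) ln((1-f)/(1-q))`` and
    ``phi_i^a = ln[f(1-q) / (q(1-f))]``; frequencies are clipped into
    ``[1e-12, 1 - 1e-12]`` so the logs stay finite at pseudocount zero.
    """
    q = BACKGROUND_UNIFORM if background is None else np.asarray(background, float)
    if q.shape != (N_AA,):
        raise ValueError(f"background must have {N_AA} entries")
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("background frequencies must lie in (0, 1)")
    f = np.clip(freqs.f1[:, :N_AA], _EPS, 1.0 - _EPS)
    d = f * np.log(f / q) + (1.0 - f) * np.log((1.0 - f) / (1.0 - q))
    phi = np.log(f * (1.0 - q) / (q * (1.0 - f)))
    d_total = np.sum(f * np.log(f / q), axis=1)
    return ConservationProfile(
        background=q, d_per_residue=d, phi=phi, d_total=d_total
    )


# ---------------------------------------------------------------------------
# coupling matrix
# ---------------------------------------------------------------------------

@dataclass
class SCAMatrix:
    c: np.ndarray  # (L, L), symmetric, nonnegative

    def __post_init__(self) -> None:
        c = self.c
        if not np.allclose(c, c.T, atol=1e-9):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(c < -1e-12) or not np.all(np.isfinite(c)):
            raise ValueError("coupling matrix entries must be finite and >= 0")

    @property
    def n_positions(self) -> int:
        return self.c.shape[0]


def build_sca_matrix(
    freqs: FrequencyModel, cons: ConservationProfile
) -> SCAMatrix:
    """Conservation-weighted covariation between all column pairs.

    ``C_ij = sqrt( sum_{a,b} [phi_i^a phi_j^b (f2_ij^ab - f1_i^a f1_j^b)]^2 )``
    with ``a, b`` over the 20 amino acids (gap excluded from the norm).
    """
    L = freqs.n_columns
    f1 = freqs.f1[:, :N_AA]                       # (L, 20)
    f2 = freqs.f2[:, :N_AA, :, :N_AA]             # (L, 20, L, 20)
    cov = f2 - f1[:, :, None, None] * f1[None, None, :, :]
    weighted = cons.phi[:, :, None, None] * cons.phi[None, None, :, :] * cov
    c = np.sqrt(np.einsum("iajb,iajb->ij", weighted, weighted))
    c = 0.5 * (c + c.T)  # symmetrise away float noise
    return SCAMatrix(c=c)


def sca_matrix_from_alignment(
    X: np.ndarray,
    weights: SequenceWeights,
    pseudocount: float = 0.03,
    background: np.ndarray | None = None,
) -> SCAMatrix:
    """Frequencies → conservation → coupling matrix in one call."""
    freqs = compute_frequencies(X, weights, pseudocount)
    cons = positional_conservation(freqs, background)
    return build_sca_matrix(freqs, cons)


# ---------------------------------------------------------------------------
# eigenmode significance
# ---------------------------------------------------------------------------

def eigendecompose(sca: SCAMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and matching eigenvectors (columns)."""
    vals, vecs = np.linalg.eigh(sca.c)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def select_significant_eigenmodes(
    sca: SCAMatrix,
    msa: ProcessedAlignment | np.ndarray,
    weights: SequenceWeights,
    n_trials: int = 10,
    seed: int = 0,
    pseudocount: float = 0.03,
    background: np.ndarray | None = None,
) -> int:
    """Number of eigenvalues exceeding the column-shuffled null spectrum.

    Each trial independently permutes every column across sequences (breaking
    inter-column covariation while preserving column compositions and the
    sequence weights), rebuilds the full coupling matrix, and records its top
    eigenvalue.  ``k*`` counts the true eigenvalues above the max over trials.
    A result of 0 means no significant modes.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X = _encoded(msa)
    rng = np.random.default_rng(seed)
    max_null = -np.inf
    for _ in range(n_trials):
        Xs = X.copy()
        for j in range(Xs.shape[1]):
            rng.shuffle(Xs[:, j])
        c_null = sca_matrix_from_alignment(Xs, weights, pseudocount, background)
        vals_null = np.linalg.eigvalsh(c_null.c)
        max_null = max(max_null, float(vals_null[-1]))
    vals, _ = eigendecompose(sca)
    return int(np.sum(vals > max_null))


# ---------------------------------------------------------------------------
# ICA rotation
# ---------------------------------------------------------------------------

@dataclass
class ICARotation:
    ic_vectors: np.ndarray   # (L, k), unit-norm columns, kurtosis-ordered
    converged: bool
    n_iterations: int


def rotate_ica(
    top_eigenvectors: np.ndarray,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-10,
) -> ICARotation:
    """Fixed-point ICA rotation of the significant eigenvector subspace.

    Treats the eigenvector loadings of the L positions as samples in k
    dimensions (already white up to scale) and rotates toward maximally
    non-Gaussian directions with the cube-contrast fixed-point iteration and
    symmetric decorrelation, initialised at the eigenvector basis (eigenvalue
    order) so the procedure is deterministic: the converged rotation is a
    genuine fixed point, so re-running on the output reproduces it.  Output
    vectors are unit-norm, sign-fixed so the largest-magnitude loading is
    positive, and ordered by decreasing kurtosis.  ``seed`` only feeds a
    random restart taken if the update ever degenerates.
    """
    V = np.asarray(top_eigenvectors, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    L, k = V.shape
    if k < 1:
        raise ValueError("need at least one eigenvector")

    X = V * np.sqrt(L)  # rows = samples with identity covariance
    rng = np.random.default_rng(seed)
    W = np.eye(k)
    converged = False
    total_iter = 0
    for _ in range(max_iter):
        total_iter += 1
        Y = X @ W.T                       # (L, k) current source estimates
        G = (Y**3).T @ X / L - 3.0 * W    # cube-contrast update, rows = w_j
        u, s, vt = np.linalg.svd(G)
        if np.any(s < 1e-12):             # degenerate update: jitter once
            G = G + 1e-6 * rng.standard_normal(G.shape)
            u, _, vt = np.linalg.svd(G)
        W_new = u @ vt                    # symmetric decorrelation
        signs = np.sign(np.einsum("ij,ij->i", W_new, W))
        signs[signs == 0] = 1.0
        W_new *= signs[:, None]
        step = np.linalg.norm(W_new - W)
        W = W_new
        if step < tol:
            converged = True
            break

    ics = V @ W.T  # (L, k); unit-norm because V and W are orthonormal
    ics /= np.linalg.norm(ics, axis=0, keepdims=True)
    # sign fix: largest-magnitude loading positive
    peaks = np.argmax(np.abs(ics), axis=0)
    signs = np.sign(ics[peaks, np.arange(ics.shape[1])])
    signs[signs == 0] = 1.0
    ics *= signs
    # order by decreasing kurtosis of loadings
    kurt = stats.kurtosis(ics, axis=0, fisher=True)
    order = np.argsort(kurt)[::-1]
    return ICARotation(
        ic_vectors=ics[:, order], converged=converged, n_iterations=total_iter
    )


# ---------------------------------------------------------------------------
# IC membership
# ---------------------------------------------------------------------------

@dataclass
class ICAssignment:
    ic_vectors: np.ndarray               # (L, k)
    memberships: list[list[int]]         # per-IC reference residue numbers
    p_cutoff: float
    fit_params: list[tuple]              # per-IC (dof, location, scale) or None
    loadings_cdf: np.ndarray = field(default=None)  # (L, k) fitted CDF values

    @property
    def n_ics(self) -> int:
        return len(self.memberships)

    def ic_of_residue(self) -> dict[int, int]:
        """Residue number → 1-based IC index, for members only."""
        out: dict[int, int] = {}
        for k, members in enumerate(self.memberships, start=1):
            for res in members:
                out[res] = k
        return out


def assign_ic_positions(
    ic_vectors: np.ndarray,
    p_cutoff: float = 0.95,
    pmap: PositionMap | None = None,
) -> ICAssignment:
    """Assign positions to ICs by the upper tail of a t location-scale fit.

    Per IC the loading values are fitted with a Student-t location-scale
    distribution; positions whose fitted CDF reaches ``p_cutoff`` are
    candidates.  A position passing for several ICs goes to the IC where its
    loading rank (1 = largest) is best; remaining ties break on CDF then IC
    order.  Memberships are reported as reference residue numbers.
    """
    if not 0.5 < p_cutoff < 1.0:
        raise ValueError(f"p_cutoff={p_cutoff} outside (0.5, 1)")
    V = np.asarray(ic_vectors, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    L, k = V.shape
    if pmap is not None and len(pmap) != L:
        raise ValueError("position map length does not match loadings")
    resnum = (
        pmap.residue_numbers if pmap is not None else np.arange(1, L + 1)
    )

    cdf = np.zeros((L, k))
    fit_params: list[tuple] = []
    candidates: list[np.ndarray] = []
    for j in range(k):
        v = V[:, j]
        if np.ptp(v) < 1e-12:
            warnings.warn(
                f"IC {j + 1}: all loadings identical; no members", stacklevel=2
            )
            fit_params.append(None)
            candidates.append(np.zeros(L, dtype=bool))
            continue
        try:
            dof, loc, scale = stats.t.fit(v)
            if not np.isfinite(scale) or scale < 1e-12:
                raise RuntimeError("degenerate scale")
            cdf[:, j] = stats.t.cdf(v, dof, loc=loc, scale=scale)
            fit_params.append((float(dof), float(loc), float(scale)))
        except Exception:
            warnings.warn(
                f"IC {j + 1}: degenerate t fit; empirical-quantile fallback",
                stacklevel=2,
            )
            cdf[:, j] = stats.rankdata(v) / (L + 1)
            fit_params.append(None)
        candidates.append(cdf[:, j] >= p_cutoff)

    # rank of each loading within its IC (1 = largest)
    ranks = np.zeros((L, k), dtype=int)
    for j in range(k):
        ranks[np.argsort(V[:, j])[::-1], j] = np.arange(1, L + 1)

    memberships: list[list[int]] = [[] for _ in range(k)]
    for i in range(L):
        hits = [j for j in range(k) if candidates[j][i]]
        if not hits:
            continue
        best = min(hits, key=lambda j: (ranks[i, j], -cdf[i, j], j))
        memberships[best].append(int(resnum[i]))
    memberships = [sorted(m) for m in memberships]
    return ICAssignment(
        ic_vectors=V,
        memberships=memberships,
        p_cutoff=p_cutoff,
        fit_params=fit_params,
        loadings_cdf=cdf,
    )


def identify_sectors(
    msa: ProcessedAlignment,
    identity_cutoff: float = 0.8,
    pseudocount: float = 0.03,
    background: np.ndarray | None = None,
    n_trials: int = 10,
    seed: int = 0,
    p_cutoff: float = 0.95,
) -> tuple[SCAMatrix, int, ICAssignment | None]:
    """Full SCA chain: weights → coupling matrix → k* → ICA → memberships.

    Returns the coupling matrix, the number of significant eigenmodes and the
    IC assignment (None when no mode is significant).
    """
    weights = compute_sequence_weights(msa, identity_cutoff)
    freqs = compute_frequencies(msa, weights, pseudocount)
    cons = positional_conservation(freqs, background)
    sca = build_sca_matrix(freqs, cons)
    k_star = select_significant_eigenmodes(
        sca, msa, weights, n_trials=n_trials, seed=seed,
        pseudocount=pseudocount, background=background,
    )
    if k_star == 0:
        return sca, 0, None
    _, vecs = eigendecompose(sca)
    ica = rotate_ica(vecs[:, :k_star], seed=seed)
    ics = assign_ic_positions(ica.ic_vectors, p_cutoff, msa.position_map)
    return sca, k_star, ics


def order_matrix_by_ic(
    sca: SCAMatrix, ics: ICAssignment, pmap: PositionMap
) -> tuple[np.ndarray, np.ndarray]:
    """Permute the coupling matrix so IC members lead, IC by IC.

    Members of IC1 come first in numerical residue order, then IC2, ...,
    then all unassigned positions in their original order.  Returns the
    reordered matrix and the permutation (new index → old index).
    """
    L = sca.n_positions
    idx_of_res = {int(r): i for i, r in enumerate(pmap.residue_numbers)}
    perm: list[int] = []
    for members in ics.memberships:
        for res in sorted(members):
            if res not in idx_of_res:
                raise ValueError(f"IC residue {res} outside matrix range")
            perm.append(idx_of_res[res])
    taken = set(perm)
    perm.extend(i for i in range(L) if i not in taken)
    perm_arr = np.array(perm, dtype=int)
    return sca.c[np.ix_(perm_arr, perm_arr)], perm_arr
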