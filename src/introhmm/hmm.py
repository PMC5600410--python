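"""Six-state introgression HMM: transitions, emissions, posterior decoding.

The hidden states are the three genotypes of a recipient individual at a
marker — homozygous recipient (``homo_r``), heterozygous (``het``) and
homozygous donor (``homo_d``) — plus one "error" counterpart for each
(``homo_r_e``, ``het_e``, ``homo_d_e``).  Error states absorb short-scale
artifact signal (mapping error, misassembly) and are distinguished from the
ancestry states purely by their transition dynamics: they emit exactly like
their counterpart but are entered at a rate inflated by a multiplier ``m``,
so stretches of aberrant signal are soaked up without spawning spurious
ancestry switches.

Transitions are distance dependent.  For neighbouring markers separated by
``d`` bp the base switch probabilities are Poisson-shaped::

    a   = c * d * exp(-c * d)          (between non-error states)
    a_e = m * c * d * exp(-m * c * d)  (between error states)

with ``c`` the per-bp per-generation recombination rate (default 1e-9) and
``m = 25,000``.

Emissions model the observed donor-allele read count ``k`` out of total
coverage ``n`` as a binomial draw of true fragments (success probability
``p`` = 0, 1/2 or 1 by genotype) whose reads are then independently
mis-called with per-read error probability ``p_ab``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma, log

import numpy as np

# State indices; error counterpart of state s is s + 3.
HOMO_R, HET, HOMO_D, HOMO_R_E, HET_E, HOMO_D_E = range(6)
STATE_NAMES = ("homo_r", "het", "homo_d", "homo_r_e", "het_e", "homo_d_e")
N_STATES = 6

#: donor-allele sampling probability of the true fragments, per state
P_STATE = (0.0, 0.5, 1.0, 0.0, 0.5, 1.0)

INTROGRESSION_STATES = frozenset({HET, HOMO_D})


@dataclass
class HMMParams:
    """Tunable parameters of the introgression HMM.

    c and m follow the published analysis of the yakuba-clade data; p_ab and
    pi are not stated there and default to a typical short-read per-base
    error rate and a prior strongly favouring the recipient-homozygous
    state (introgression is rare genome-wide).
    """

    c: float = 1e-9
    m: float = 25_000.0
    p_ab: float = 0.005
    pi: tuple[float, ...] = (0.995, 0.001, 0.001, 0.001, 0.001, 0.001)
    p_state: tuple[float, ...] = P_STATE

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if not 0 <= self.p_ab < 0.5:
            raise ValueError("p_ab must be in [0, 0.5)")
        pi = np.asarray(self.pi, dtype=float)
        if pi.size != N_STATES or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise ValueError("pi must be a distribution over 6 states")
        if any(not 0 <= p <= 1 for p in self.p_state):
            raise ValueError("p_state values must be in [0, 1]")


@dataclass
class StatePosteriors:
    """Forward-backward output for one individual on one chromosome."""

    chrom: str
    pos: np.ndarray            # (L,)
    k: np.ndarray              # (L,)
    n: np.ndarray              # (L,)
    posteriors: np.ndarray     # (L, 6)
    states: np.ndarray         # (L,) argmax state index
    log_likelihood: float

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                           "k": self.k, "n": self.n})
        for s, name in enumerate(STATE_NAMES):
            df[f"p_{name}"] = self.posteriors[:, s]
        df["state"] = [STATE_NAMES[s] for s in self.states]
        return df


def transition_base_probs(distance, c: float, m: float):
    """Poisson-form base switch probabilities (a, a_e) at a marker gap.

    Both lie in [0, 1/e]; a is maximised at distance 1/c.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative inter-marker distance (markers unsorted?)")
    cd = c * d
    mcd = m * cd
    a = cd * np.exp(-cd)
    a_e = mcd * np.exp(-mcd)
    if np.isscalar(distance):
        return float(a), float(a_e)
    return a, a_e


def transition_matrix(a: float, a_e: float) -> np.ndarray:
    """Row-stochastic 6x6 transition matrix for one marker gap.

    Structure (row = from, column = to; order homo_r, het, homo_d,
    homo_r_e, het_e, homo_d_e):

    * a non-error state keeps itself with 1-4a and moves with a to each of
      the four reachable states; moving to its own error twin is impossible;
    * an error state keeps itself with 2*a_e, cannot jump to its own
      non-error twin, returns to each reachable non-error state with
      (1-2*a_e)/4, and spreads the remaining (1-2*a_e)/2 over the other two
      error states — evenly from homo_r_e, and 9:1 in favour of homo_r_e
      from het_e and homo_d_e (errors resolve toward the common
      recipient-like background).
    """
    if not 0 <= a <= 0.25:
        raise ValueError(f"invalid a={a} (need 4a <= 1); a_e={a_e}")
    if not 0 <= a_e <= 0.5:
        raise ValueError(f"invalid a_e={a_e}")
    q = (1.0 - 2.0 * a_e) / 4.0
    h = (1.0 - 2.0 * a_e) / 2.0
    d = 1.0 - 4.0 * a
    T = np.array([
        [d,   a,   a,   0.0, a,   a],
        [a,   d,   a,   a,   0.0, a],
        [a,   a,   d,   a,   a,   0.0],
        [0.0, q,   q,   2 * a_e,   q,         q],
        [q,   0.0, q,   0.9 * h,   2 * a_e,   0.1 * h],
        [q,   q,   0.0, 0.9 * h,   0.1 * h,   2 * a_e],
    ])
    if (T < 0).any() or (T > 1).any():
        raise ValueError(f"transition entry outside [0,1] for a={a}, a_e={a_e}")
    assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
    return T


def transition_stack(a: np.ndarray, a_e: np.ndarray) -> np.ndarray:
    """Vectorised :func:`transition_matrix` for arrays of (a, a_e).

    Returns a (len(a), 6, 6) tensor; used to build one matrix per marker
    gap without a Python-level loop.
    """
    a = np.asarray(a, dtype=float)
    a_e = np.asarray(a_e, dtype=float)
    if np.any(a < 0) or np.any(a > 0.25):
        bad = a[(a < 0) | (a > 0.25)][0]
        raise ValueError(f"invalid a={bad} (need 4a <= 1)")
    if np.any(a_e < 0) or np.any(a_e > 0.5):
        raise ValueError("invalid a_e (need 2*a_e <= 1)")
    L = a.size
    q = (1.0 - 2.0 * a_e) / 4.0
    h = (1.0 - 2.0 * a_e) / 2.0
    d = 1.0 - 4.0 * a
    T = np.zeros((L, N_STATES, N_STATES))
    z = np.zeros(L)
    rows = [
        [d, a, a, z, a, a],
        [a, d, a, a, z, a],
        [a, a, d, a, a, z],
        [z, q, q, 2 * a_e, q, q],
        [q, z, q, 0.9 * h, 2 * a_e, 0.1 * h],
        [q, q, z, 0.9 * h, 0.1 * h, 2 * a_e],
    ]
    for i in range(N_STATES):
        for j in range(N_STATES):
            T[:, i, j] = rows[i][j]
    return T


def emission_prob(k: int, n: int, p: float, p_ab: float) -> float:
    """P(X = k | p, p_ab): donor-allele read count under sequencing error.

    Double sum over i (true donor fragments, Binomial(n, p)) and j
    (recipient-fragment reads mis-called as donor)::

        P(X=k) = sum_i n! p^i (1-p)^(n-i)
                 sum_j p_ab^(2j-k+i) (1-p_ab)^(n+k-i-2j)
                        / (j! (n-i-j)! (j-k+i)! (k-j)!)

    Evaluated in log space term by term; exact to float precision for the
    small n (tens of reads) this model is used with.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(_emission_table(n, p, p_ab)[k])


def _log_or_ninf(x: float) -> float:
    return log(x) if x > 0 else -np.inf


def _emission_table_uncached(n: int, p: float, p_ab: float) -> np.ndarray:
    """P(X = k) for all k in 0..n, via the double sum (vectorised).

    The sum runs over i (true donor fragments) and j (recipient reads
    mis-called as donor); terms are combined in log space.  Degenerate
    parameters (p or p_ab equal to 0 or 1) restrict the valid (i, j) grid
    instead of producing 0*log(0) artifacts.
    """
    i = np.arange(n + 1)[:, None, None]
    j = np.arange(n + 1)[None, :, None]
    k = np.arange(n + 1)[None, None, :]
    ne = 2 * j - k + i            # mis-called reads
    nc = n + k - i - 2 * j        # correctly called reads
    valid = (j >= k - i) & (j <= n - i) & (j <= k)
    if p == 0.0:
        valid &= i == 0
    if p == 1.0:
        valid &= i == n
    if p_ab == 0.0:
        valid &= ne == 0

    lgam = np.array([lgamma(v + 1) for v in range(n + 1)])

    def pw(count, prob):
        # count * log(prob) with the 0 * log(0) = 0 convention
        with np.errstate(divide="ignore", invalid="ignore"):
            out = count * np.log(prob)
        return np.where(count == 0, 0.0, out)

    with np.errstate(invalid="ignore"):  # invalid grid cells masked below
        t = (lgam[n] + pw(i, p) + pw(n - i, 1 - p)
             - lgam[np.clip(j, 0, n)] - lgam[np.clip(n - i - j, 0, n)]
             - lgam[np.clip(j - k + i, 0, n)] - lgam[np.clip(k - j, 0, n)]
             + pw(ne, p_ab) + pw(nc, 1 - p_ab))
    logterms = np.where(valid, t, -np.inf)
    mx = logterms.max(axis=(0, 1), initial=-np.inf)
    safe_mx = np.where(np.isfinite(mx), mx, 0.0)
    out = np.exp(safe_mx) * np.exp(logterms - safe_mx).sum(axis=(0, 1))
    return np.where(np.isfinite(mx), out, 0.0)


_EMISSION_CACHE: dict[tuple[int, float, float], np.ndarray] = {}


def _emission_table(n: int, p: float, p_ab: float) -> np.ndarray:
    key = (n, p, p_ab)
    tab = _EMISSION_CACHE.get(key)
    if tab is None:
        tab = _emission_table_uncached(n, p, p_ab)
        _EMISSION_CACHE[key] = tab
    return tab


def emission_vector(k: int, n: int, params: HMMParams) -> np.ndarray:
    """Per-state emission probabilities at one marker.

    Error states emit identically to their non-error counterpart; a missing
    observation (n = 0) is uninformative and emits 1 in every state.
    """
    if n == 0:
        return np.ones(N_STATES)
    e = np.empty(N_STATES)
    for s in range(3):
        e[s] = emission_prob(k, n, params.p_state[s], params.p_ab)
        e[s + 3] = e[s]
    return e


def emission_matrix(k: np.ndarray, n: np.ndarray,
                    params: HMMParams) -> np.ndarray:
    """(L, 6) emission probabilities for a whole marker sequence.

    Tables P(X=k | n, p) are cached per (n, p, p_ab), so repeated coverages
    (the common case) cost a single lookup.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("require 0 <= k <= n at every marker")
    L = k.size
    E = np.ones((L, N_STATES))
    for nv in np.unique(n):
        if nv == 0:
            continue
        rows = np.flatnonzero(n == nv)
        for s in range(3):
            tab = _emission_table(int(nv), params.p_state[s], params.p_ab)
            E[rows, s] = tab[k[rows]]
            E[rows, s + 3] = E[rows, s]
    return E


def _forward_backward(E: np.ndarray, pos: np.ndarray, params: HMMParams):
    """Scaled forward-backward over one chromosome.

    E: (L, 6) emissions or (L, B, 6) for B individuals sharing the marker
    grid.  Returns (posteriors, log_likelihood) with matching leading shape.
    """
    squeeze = E.ndim == 2
    if squeeze:
        E = E[:, None, :]
    L, B, S = E.shape
    a, a_e = transition_base_probs(np.diff(pos.astype(float)),
                                   params.c, params.m)
    pi = np.asarray(params.pi, dtype=float)

    alpha = np.empty((L, B, S))
    scale = np.empty((L, B))
    x = pi[None, :] * E[0]
    scale[0] = x.sum(axis=1)
    alpha[0] = x / scale[0][:, None]
    Ts = transition_stack(a, a_e)
    for t in range(1, L):
        x = (alpha[t - 1] @ Ts[t - 1]) * E[t]
        scale[t] = x.sum(axis=1)
        alpha[t] = x / scale[t][:, None]

    beta = np.empty((L, B, S))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (beta[t + 1] * E[t + 1]) @ Ts[t].T
        beta[t] /= scale[t + 1][:, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    loglik = np.log(scale).sum(axis=0)
    if squeeze:
        return post[:, 0, :], float(loglik[0])
    return post, loglik


def posterior_decode(markers, individual: str,
                     params: HMMParams | None = None) -> list[StatePosteriors]:
    """Decode one recipient individual, one chromosome at a time.

    ``markers`` is a :class:`~introhmm.markers.MarkerTable`.  Chromosome
    boundaries reset the chain.  Returns one :class:`StatePosteriors` per
    chromosome, in table order.
    """
    params = params or HMMParams()
    chrom_all, pos_all, k_all, n_all = \
        markers.individual_observations(individual)
    out = []
    for c in markers.chromosomes():
        sel = chrom_all == c
        out.append(decode_observations(
            c, pos_all[sel], k_all[sel], n_all[sel], params))
    return out


def decode_observations(chrom: str, pos: np.ndarray, k: np.ndarray,
                        n: np.ndarray, params: HMMParams | None = None
                        ) -> StatePosteriors:
    """Forward-backward posteriors for raw (pos, k, n) marker observations."""
    import warnings

    params = params or HMMParams()
    pos = np.asarray(pos, dtype=np.int64)
    if pos.size > 1 and np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    E = emission_matrix(k, n, params)
    if pos.size < 2:
        warnings.warn(f"chromosome {chrom} has < 2 markers; "
                      "decoding from emissions and pi only")
        pi = np.asarray(params.pi)
        post = pi[None, :] * E
        ll = float(np.log(post.sum(axis=1)).sum()) if pos.size else 0.0
        if pos.size:
            post = post / post.sum(axis=1, keepdims=True)
        return StatePosteriors(chrom, pos, np.asarray(k), np.asarray(n),
                               post, post.argmax(axis=1) if pos.size
                               else np.empty(0, int), ll)
    post, ll = _forward_backward(E, pos, params)
    return StatePosteriors(
        chrom=chrom, pos=pos,
        k=np.asarray(k, dtype=np.int64), n=np.asarray(n, dtype=np.int64),
        posteriors=post, states=post.argmax(axis=1), log_likelihood=ll,
    )


def decode_batch(chrom: str, pos: np.ndarray, k: np.ndarray, n: np.ndarray,
                 params: HMMParams | None = None) -> list[StatePosteriors]:
    """Decode B individuals sharing one marker grid in a single pass.

    k, n: (B, L) arrays.  The per-step transition matrices depend only on
    the shared positions, so batching amortises the sequential scan.
    """
    params = params or HMMParams()
    pos = np.asarray(pos, dtype=np.int64)
    k = np.atleast_2d(np.asarray(k, dtype=np.int64))
    n = np.atleast_2d(np.asarray(n, dtype=np.int64))
    B, L = k.shape
    E = np.empty((L, B, N_STATES))
    for b in range(B):
        E[:, b, :] = emission_matrix(k[b], n[b], params)
    post, ll = _forward_backward(E, pos, params)
    return [
        StatePosteriors(chrom, pos, k[b], n[b], post[:, b, :],
                        post[:, b, :].argmax(axis=1), float(ll[b]))
        for b in range(B)
    ]


def brute_force_posteriors(pos, k, n, params: HMMParams) -> np.ndarray:
    """Exact posteriors by summing over all 6^L state paths (oracle).

    Only feasible for very short chains; used to validate forward-backward.
    """
    from itertools import product

    pos = np.asarray(pos, dtype=float)
    L = pos.size
    if L > 10:
        raise ValueError("brute force limited to L <= 10")
    E = emission_matrix(k, n, params)
    a, a_e = transition_base_probs(np.diff(pos), params.c, params.m)
    Ts = [transition_matrix(float(a[t]), float(a_e[t])) for t in range(L - 1)]
    pi = np.asarray(params.pi)
    joint = np.zeros((L, N_STATES))
    total = 0.0
    for path in product(range(N_STATES), repeat=L):
        w = pi[path[0]] * E[0, path[0]]
        for t in range(1, L):
            w *= Ts[t - 1][path[t - 1], path[t]] * E[t, path[t]]
        total += w
        for t in range(L):
            joint[t, path[t]] += w
    return joint / total
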