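"""General time-reversible (REV/GTR) substitution models on K letters.

A model is a symmetric matrix of exchangeabilities ``s``, a stationary
frequency vector ``pi``, and the rate matrix ``q_ij = s_ij * pi_j`` (i != j)
normalised so the mean substitution rate ``-sum_i pi_i q_ii`` is one, i.e.
branch lengths are expected substitutions per site.  Family-specific models
are estimated by maximum likelihood on a fixed topology, alternating branch
length sweeps with quasi-Newton updates of the exchangeabilities, and are
read and written in PAML triangle text format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io import AMINO_ACIDS, AlignmentError, ResidueAlignment


class PamlFormatError(ValueError):
    """Malformed PAML matrix text."""


class DegenerateAlignmentError(AlignmentError):
    """Alignment carries no usable substitution signal."""


@dataclass
class RevModel:
    """A reversible K-state substitution model.

    ``exchangeabilities`` is symmetric and nonnegative with zero diagonal;
    ``frequencies`` lies on the simplex with strictly positive entries.  The
    normalised rate matrix, its spectral decomposition and transition
    probabilities are derived lazily and cached.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alphabet: str = AMINO_ACIDS
    prior_dominated: tuple[str, ...] = ()
    fit_history: list = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        K = len(self.alphabet)
        if s.shape != (K, K):
            raise ValueError(
                f"exchangeabilities shape {s.shape} does not match alphabet "
                f"size {K}"
            )
        if pi.shape != (K,):
            raise ValueError("frequencies length does not match alphabet size")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("exchangeabilities must be symmetric")
        if (s < 0).any():
            raise ValueError("exchangeabilities must be nonnegative")
        if (pi <= 0).any():
            raise ValueError("frequencies must be strictly positive")
        s = 0.5 * (s + s.T).copy()
        np.fill_diagonal(s, 0.0)
        self.exchangeabilities = s
        self.frequencies = pi / pi.sum()

    # -- derived quantities -------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def rate_matrix(self) -> np.ndarray:
        """Normalised Q: rows sum to zero, mean rate exactly one."""
        cached = self.__dict__.get("_Q")
        if cached is not None:
            return cached
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        if rate <= 0:
            raise ValueError("all-zero exchangeabilities: rate matrix is null")
        Q = Q / rate
        self.__dict__["_Q"] = Q
        return Q

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral decomposition ``Q = R diag(lam) L`` via pi-symmetrisation.

        Returns ``(lam, R, L)`` with ``P(t) = R @ diag(exp(lam t)) @ L``.
        """
        cached = self.__dict__.get("_eig")
        if cached is not None:
            return cached
        Q = self.rate_matrix()
        pi = self.frequencies
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        lam, V = np.linalg.eigh(0.5 * (B + B.T))
        R = V / sq[:, None]
        L = V.T * sq[None, :]
        self.__dict__["_eig"] = (lam, R, L)
        return lam, R, L

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("negative branch length")
        lam, R, L = self.eigensystem()
        P = (R * np.exp(lam * t)[None, :]) @ L
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def mean_rate(self) -> float:
        Q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        return float((self.frequencies[:, None] * Q).sum())

    # -- constructors ----------------------------------------------------------

    @classmethod
    def equal_rates(cls, alphabet: str = AMINO_ACIDS) -> "RevModel":
        """All exchangeabilities equal, uniform frequencies (K-state JC)."""
        K = len(alphabet)
        s = np.ones((K, K))
        np.fill_diagonal(s, 0.0)
        return cls(s, np.full(K, 1.0 / K), alphabet)

    @classmethod
    def random(cls, alphabet: str, seed=None,
               dirichlet_conc: float = 5.0) -> "RevModel":
        """A random model: lognormal exchangeabilities, Dirichlet frequencies."""
        rng = np.random.default_rng(seed)
        K = len(alphabet)
        tri = rng.lognormal(0.0, 0.7, size=K * (K - 1) // 2)
        s = np.zeros((K, K))
        s[np.triu_indices(K, 1)] = tri
        s = s + s.T
        pi = rng.dirichlet(np.full(K, dirichlet_conc))
        return cls(s, pi, alphabet)


def normalize(model: RevModel) -> RevModel:
    """Rescale exchangeabilities so the *raw* mean rate is exactly one.

    The normalised rate matrix is unchanged (scale invariance), which makes
    the operation idempotent; it simply fixes the overall scale of ``s`` for
    readable output.
    """
    rate = model.mean_rate()
    if rate <= 0:
        raise ValueError("all-zero exchangeabilities cannot be normalized")
    return RevModel(
        model.exchangeabilities / rate, model.frequencies, model.alphabet,
        model.prior_dominated,
    )


def empirical_frequencies(alignment: ResidueAlignment,
                          pseudocount: float = 0.5) -> np.ndarray:
    """+F frequencies: pseudocounted symbol proportions over non-missing cells."""
    codes = alignment.codes()
    body = codes[codes >= 0]
    counts = np.bincount(body, minlength=len(alignment.alphabet)).astype(float)
    counts += pseudocount
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# ML estimation
# ---------------------------------------------------------------------------


def estimate_rev(alignment: ResidueAlignment, tree, *,
                 pseudocount: float = 0.5, tol: float = 1e-4,
                 max_rounds: int = 50, inner_maxiter: int = 40) -> RevModel:
    """ML estimate of a family-specific REV model on a fixed topology.

    Frequencies are empirical (+F, pseudocounted); exchangeabilities are
    optimised on the log scale with the last alphabet pair fixed to one for
    identifiability, alternating with branch-length optimisation until the
    log-likelihood improves by less than ``tol`` or ``max_rounds`` rounds.
    The returned model records the per-round log-likelihoods in
    ``fit_history`` and flags symbols absent from the data (their rates are
    prior-dominated) in ``prior_dominated``.
    """
    from . import engine  # deferred: engine imports this module

    if alignment.n_taxa < 3:
        raise AlignmentError("REV estimation needs at least 3 taxa")
    codes = alignment.codes()
    observed = np.unique(codes[codes >= 0])
    if observed.size <= 1:
        raise DegenerateAlignmentError(
            "alignment uses a single residue category; inspect it with "
            "category_usage before model fitting"
        )
    K = len(alignment.alphabet)
    pi = empirical_frequencies(alignment, pseudocount)
    absent = tuple(
        sym for i, sym in enumerate(alphabet_of(alignment))
        if i not in set(observed.tolist())
    )

    iu = np.triu_indices(K, 1)
    n_pairs = iu[0].size
    free = np.arange(n_pairs - 1)          # last pair fixed to 1

    def build(s_flat: np.ndarray) -> RevModel:
        s = np.zeros((K, K))
        s[iu] = s_flat
        return RevModel(s + s.T, pi, alignment.alphabet)

    s_flat = np.ones(n_pairs)
    lik = engine.AlignmentLikelihood(alignment, tree)
    lengths = None
    history: list[float] = []
    logL = -np.inf
    for _ in range(max_rounds):
        model = build(s_flat)
        fit = engine.optimize_branch_lengths(
            alignment, tree, model, init=lengths, _likelihood=lik,
        )
        lengths = fit.lengths
        lvec = lik.lengths_vector(lengths)

        def neg(x: np.ndarray) -> float:
            trial = s_flat.copy()
            trial[free] = np.exp(x)
            return -lik.log_likelihood(build(trial), lvec)

        res = minimize(
            neg, np.log(s_flat[free]), method="L-BFGS-B",
            bounds=[(np.log(1e-6), np.log(1e6))] * free.size,
            options={"maxiter": inner_maxiter},
        )
        s_flat[free] = np.exp(res.x)
        new_logL = -res.fun
        history.append(float(new_logL))
        if new_logL - logL < tol:
            logL = new_logL
            break
        logL = new_logL

    model = normalize(build(s_flat))
    model.prior_dominated = absent
    model.fit_history = history
    return model


def alphabet_of(alignment: ResidueAlignment) -> str:
    return alignment.alphabet


# ---------------------------------------------------------------------------
# PAML text format
# ---------------------------------------------------------------------------


def write_paml(model: RevModel, path) -> None:
    """Write lower-triangular exchangeabilities plus a frequency line.

    A leading comment records the alphabet ordering (this package uses
    A R N D C E Q G H I L K M F P S T W Y V for both channels).
    """
    K = model.K
    s = model.exchangeabilities
    with open(path, "w") as fh:
        fh.write("# alphabet: " + " ".join(model.alphabet) + "\n")
        for i in range(1, K):
            fh.write(" ".join(f"{s[i, j]:.10g}" for j in range(i)) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{f:.10g}" for f in model.frequencies) + "\n")


def read_paml(path, alphabet: str = AMINO_ACIDS) -> RevModel:
    """Read a PAML-style triangle + frequency file for a K-letter alphabet."""
    K = len(alphabet)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(tok) for tok in line.split()])
    if len(rows) < K:
        raise PamlFormatError(
            f"expected {K - 1} triangle rows plus frequencies, got "
            f"{len(rows)} data lines"
        )
    tri, freq_rows = rows[: K - 1], rows[K - 1:]
    s = np.zeros((K, K))
    for i, row in enumerate(tri, start=1):
        if len(row) != i:
            raise PamlFormatError(
                f"triangle row {i} has {len(row)} entries, expected {i}"
            )
        s[i, :i] = row
    s = s + s.T
    freqs = np.concatenate([np.asarray(r) for r in freq_rows])
    if freqs.size != K:
        raise PamlFormatError(
            f"frequency line has {freqs.size} entries, expected {K}"
        )
    total = freqs.sum()
    if abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"frequencies sum to {total:.8f}; renormalizing", stacklevel=2
        )
    freqs = freqs / total
    return RevModel(s, freqs, alphabet)
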