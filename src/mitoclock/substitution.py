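"""Nucleotide substitution models: JC, HKY, GTR with discrete-gamma rates.

Rate matrices are normalized to one expected substitution per site per
unit of evolutionary distance, so ``transition_matrix(spec, d)`` gives the
transition probabilities after ``d`` expected substitutions/site.
Among-site rate variation uses the standard discrete-gamma construction
(category rates are the means of equal-probability quantile slices), with
an optional proportion of invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from mitoclock.errors import ValidationError, NumericalError

STATE_ORDER = "ACGT"


@dataclass(frozen=True)
class SubstitutionModelSpec:
    """Specification of a reversible nucleotide substitution model.

    ``kappa`` is the HKY transition/transversion rate ratio;
    ``exchangeabilities`` the six GTR rates in order AC, AG, AT, CG, CT,
    GT; ``pi`` the equilibrium base frequencies in ACGT order; ``alpha``
    the gamma shape; ``p_inv`` the proportion of invariant sites.
    """

    model: str = "HKY"
    kappa: float = 2.0
    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    pi: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = np.inf  # inf: no rate variation
    n_categories: int = 1
    p_inv: float = 0.0

    def __post_init__(self):
        if self.model not in ("JC", "HKY", "GTR"):
            raise ValidationError(f"unknown model {self.model!r}")
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValidationError(f"pi must be a length-4 simplex, got {self.pi}")
        if self.model == "JC" and not np.allclose(pi, 0.25):
            raise ValidationError("JC requires equal base frequencies")
        if not (self.alpha > 0):
            raise ValidationError("gamma shape alpha must be > 0")
        if self.n_categories < 1:
            raise ValidationError("n_categories must be >= 1")
        if not (0 <= self.p_inv < 1):
            raise ValidationError("p_inv must be in [0, 1)")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")

    # ------------------------------------------------------------------ Q
    def rate_matrix(self) -> np.ndarray:
        """Normalized generator Q with -sum(pi_i Q_ii) = 1."""
        pi = np.asarray(self.pi, dtype=float)
        if self.model == "JC":
            ex = np.ones(6)
        elif self.model == "HKY":
            # transitions: A<->G (index 1: AG) and C<->T (index 4: CT)
            ex = np.array([1.0, self.kappa, 1.0, 1.0, self.kappa, 1.0])
        else:
            ex = np.asarray(self.exchangeabilities, dtype=float)
            if ex.shape != (6,) or np.any(ex <= 0):
                raise ValidationError("GTR needs 6 positive exchangeabilities")
        R = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), e in zip(idx, ex):
            R[i, j] = R[j, i] = e
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    def eigensystem(self):
        """Stable eigendecomposition Q = U diag(lam) Uinv via pi-symmetrization."""
        pi = np.asarray(self.pi, dtype=float)
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = 0.5 * (S + S.T)  # symmetric for reversible models
        lam, V = np.linalg.eigh(S)
        U = V / sq[:, None]
        Uinv = V.T * sq[None, :]
        return lam, U, Uinv

    def category_rates(self):
        """(rates, weights) of the site-rate mixture, mean rate 1."""
        return gamma_categories(self.alpha, self.n_categories, self.p_inv)


def gamma_categories(alpha: float, n_categories: int, p_inv: float = 0.0):
    """Discrete-gamma (+I) site-rate categories, normalized to mean 1.

    Category rates are the conditional means of the gamma distribution on
    equal-probability slices; an invariant category of rate 0 and weight
    ``p_inv`` is prepended when ``p_inv > 0`` and the gamma rates are
    rescaled by 1/(1-p_inv) to keep the mixture mean at 1.
    """
    if np.isinf(alpha) or n_categories == 1:
        rates = np.array([1.0])
        weights = np.array([1.0])
    else:
        K = n_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, K + 1), a=alpha, scale=1.0 / alpha)
        # mean of a gamma(a, scale) on (b1, b2) is proportional to the
        # gamma(a+1, scale) probability of the same slice
        upper = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
        rates = K * np.diff(upper)
        weights = np.full(K, 1.0 / K)
    if p_inv > 0:
        rates = np.concatenate([[0.0], rates / (1.0 - p_inv)])
        weights = np.concatenate([[p_inv], weights * (1.0 - p_inv)])
    return rates, weights


def transition_matrix(spec: SubstitutionModelSpec, distance: float) -> np.ndarray:
    """P(distance): transition probabilities after ``distance`` subs/site."""
    if distance < 0:
        raise ValidationError(f"negative distance {distance}")
    lam, U, Uinv = spec.eigensystem()
    P = (U * np.exp(lam * distance)[None, :]) @ Uinv
    P = np.clip(P, 0.0, None)
    rows = P.sum(axis=1)
    if np.any(np.abs(rows - 1) > 1e-9):
        raise NumericalError(f"transition matrix rows sum to {rows}")
    return P / rows[:, None]


def transition_matrices(eigensystem, distances) -> np.ndarray:
    """Batched P(d) for an array of distances; shape (*distances.shape, 4, 4)."""
    lam, U, Uinv = eigensystem
    d = np.asarray(distances, dtype=float)
    expo = np.exp(np.multiply.outer(d, lam))  # (..., 4)
    P = np.einsum("ij,...j,jk->...ik", U, expo, Uinv)
    return np.clip(P, 0.0, None)
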