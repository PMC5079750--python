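"""Meta-d' estimation: SDT modelling of confidence-rating data.

Meta-d' is the type-1 sensitivity that an SDT-ideal observer would need in
order to produce the observed confidence ratings.  The model places two
unit-variance Gaussians at -meta_d/2 and +meta_d/2, fixes the type-1
criterion at the empirically observed *relative* position
(meta_c = c * meta_d / d'), and fits response-conditional type-2 criteria
(three per response side for four confidence bins) by maximizing the
multinomial likelihood of the confidence counts conditional on the type-1
response.  M-Ratio = meta_d / d' indexes metacognitive sensitivity
(1 = confidence exhausts the decision information); M-Bias indexes how much
evidence is required to report high confidence (metacognitive
conservativeness).

M-Bias is operationalised, by default, as the mean absolute distance of
the six fitted type-2 criteria from the type-1 criterion: larger values
mean the confidence criteria sit farther out on the evidence axis, i.e.
more evidence is needed for a high-confidence report.  The alternative
conventions ``meta_c`` and ``meta_c_minus_c`` are available via
``m_bias_definition``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .behavior import _rates_with_correction

__all__ = ["confidence_counts", "MetaDFit", "MetaDEstimator", "fit_meta_d"]

_SIDES = {"left": 0, "right": 1}


def confidence_counts(
    sides: np.ndarray, choices: np.ndarray, conf_bins: np.ndarray, n_bins: int = 4
) -> np.ndarray:
    """Tabulate trials into a (stimulus, response, confidence-bin) array.

    ``sides`` and ``choices`` are "left"/"right" labels; ``conf_bins`` are
    integer bins 1..n_bins.  Axis order: stimulus (left, right), response
    (left, right), bin (1..n_bins).
    """
    conf_bins = np.asarray(conf_bins, dtype=int)
    if conf_bins.min() < 1 or conf_bins.max() > n_bins:
        raise ValueError(f"confidence bins must lie in 1..{n_bins}")
    counts = np.zeros((2, 2, n_bins), dtype=int)
    for s, r, b in zip(sides, choices, conf_bins):
        counts[_SIDES[s], _SIDES[r], b - 1] += 1
    return counts


@dataclass
class MetaDFit:
    """Fitted type-1 and type-2 (meta) SDT parameters."""

    d_prime: float
    criterion_c: float
    meta_d: float
    meta_c: float
    m_ratio: float
    m_bias: float
    type2_criteria: np.ndarray  # (2 response sides, n_bins - 1), absolute positions
    loglik: float
    converged: bool


def _type1_from_counts(counts: np.ndarray) -> tuple[float, float]:
    n_right_stim = counts[1].sum()
    n_left_stim = counts[0].sum()
    hit, fa = _rates_with_correction(
        int(counts[1, 1].sum()), int(n_right_stim),
        int(counts[0, 1].sum()), int(n_left_stim),
    )
    zh, zf = stats.norm.ppf(hit), stats.norm.ppf(fa)
    return float(zh - zf), float(-0.5 * (zh + zf))


def _criteria_from_params(a: np.ndarray, meta_c: float) -> tuple[np.ndarray, np.ndarray]:
    """Map unconstrained increments to ordered criteria around meta_c."""
    k = len(a) // 2
    inc = np.exp(np.clip(a, -12.0, 6.0))
    left = meta_c - np.cumsum(inc[:k])  # c just below meta_c first, then outward
    right = meta_c + np.cumsum(inc[k:])
    return left, right  # left descending, right ascending


def _conditional_probs(meta_d: float, c_rel: float, a: np.ndarray, n_bins: int) -> np.ndarray:
    """P(conf bin | stimulus, response) under the meta-d' model.

    Returns array (2 stim, 2 resp, n_bins).  ``c_rel`` is the relative
    criterion c/d' of the type-1 data; meta_c = c_rel * meta_d.
    """
    meta_c = c_rel * meta_d
    left_desc, right_asc = _criteria_from_params(a, meta_c)
    # full boundary set, ascending
    bounds = np.concatenate([left_desc[::-1], [meta_c], right_asc])
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    cdf = stats.norm.cdf(bounds[None, :] - mus[:, None])  # (2, 2*n_bins - 1)
    full = np.concatenate(
        [cdf[:, :1], np.diff(cdf, axis=1), 1.0 - cdf[:, -1:]], axis=1
    )  # (2, 2*n_bins) interval masses
    probs = np.zeros((2, 2, n_bins))
    # response left: intervals 0..n_bins-1 hold conf n_bins..1
    probs[:, 0, :] = full[:, :n_bins][:, ::-1]
    probs[:, 1, :] = full[:, n_bins:]
    resp_mass = probs.sum(axis=2, keepdims=True)
    return probs / np.clip(resp_mass, 1e-300, None)


class MetaDEstimator(BaseEstimator):
    """Maximum-likelihood meta-d' fit on confidence counts.

    Parameters
    ----------
    padding : {"auto", "always", "never"}
        Add 1/(2 * n_bins) to every cell — always, never, or only when some
        cell is empty (default).
    n_restarts : int
        Random restarts of the bounded quasi-Newton optimizer (the
        likelihood surface can be flat for sparse counts).
    tol : float
        Convergence tolerance on the negative log-likelihood.
    m_bias_definition : {"criterion_spread", "meta_c", "meta_c_minus_c"}
        Operationalisation of the confidence-bias (meta-criterion) summary.
    random_state : int or None
        Seed for restart jitter.

    Fitted attributes: ``meta_d_``, ``meta_c_``, ``m_ratio_``, ``m_bias_``,
    ``d_prime_``, ``c_``, ``type2_criteria_``, ``loglik_``, ``converged_``.
    """

    def __init__(
        self,
        padding: str = "auto",
        n_restarts: int = 5,
        tol: float = 1e-8,
        m_bias_definition: str = "criterion_spread",
        random_state: int | None = 0,
    ):
        self.padding = padding
        self.n_restarts = n_restarts
        self.tol = tol
        self.m_bias_definition = m_bias_definition
        self.random_state = random_state

    def fit(self, X, y=None):  # noqa: N803 - sklearn signature
        counts = np.asarray(X, dtype=float)
        if counts.ndim != 3 or counts.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, n_bins)")
        n_bins = counts.shape[2]
        if self.padding == "always" or (self.padding == "auto" and (counts == 0).any()):
            counts = counts + 1.0 / (2 * n_bins)
        elif self.padding not in ("auto", "never", "always"):
            raise ValueError(f"unknown padding mode {self.padding!r}")

        d_prime, c = _type1_from_counts(counts)
        if d_prime <= 0:
            raise ValueError(
                f"type-1 d' = {d_prime:.3f} <= 0: meta-d' fit refused (the model "
                "requires positive discrimination sensitivity)"
            )
        c_rel = c / d_prime

        def nll(theta: np.ndarray) -> float:
            meta_d, a = theta[0], theta[1:]
            probs = _conditional_probs(meta_d, c_rel, a, n_bins)
            return -float(np.sum(counts * np.log(np.clip(probs, 1e-300, None))))

        rng = np.random.default_rng(self.random_state)
        k = n_bins - 1
        base_inc = np.log(np.full(2 * k, max(d_prime, 1.0) / (k + 1)))
        bounds = [(1e-4, 10.0)] + [(-12.0, 6.0)] * (2 * k)
        best = None
        for r in range(self.n_restarts):
            theta0 = np.concatenate([[max(d_prime, 0.1)], base_inc])
            if r > 0:
                theta0 = theta0 + rng.normal(0, 0.5, size=theta0.shape)
                theta0[0] = float(np.clip(theta0[0], 1e-3, 9.0))
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": self.tol, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None
        meta_d = float(best.x[0])
        meta_c = float(c_rel * meta_d)
        left_desc, right_asc = _criteria_from_params(best.x[1:], meta_c)
        t2c = np.vstack([left_desc[::-1], right_asc])  # ascending within each side

        self.d_prime_ = d_prime
        self.c_ = c
        self.meta_d_ = meta_d
        self.meta_c_ = meta_c
        self.m_ratio_ = meta_d / d_prime
        self.type2_criteria_ = t2c
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self.m_bias_ = self._m_bias(t2c, meta_c, c)
        return self

    def _m_bias(self, t2c: np.ndarray, meta_c: float, c: float) -> float:
        if self.m_bias_definition == "criterion_spread":
            return float(np.mean(np.abs(t2c - meta_c)))
        if self.m_bias_definition == "meta_c":
            return float(meta_c)
        if self.m_bias_definition == "meta_c_minus_c":
            return float(meta_c - c)
        raise ValueError(f"unknown m_bias_definition {self.m_bias_definition!r}")

    def to_fit(self) -> MetaDFit:
        return MetaDFit(
            d_prime=self.d_prime_,
            criterion_c=self.c_,
            meta_d=self.meta_d_,
            meta_c=self.meta_c_,
            m_ratio=self.m_ratio_,
            m_bias=self.m_bias_,
            type2_criteria=self.type2_criteria_,
            loglik=self.loglik_,
            converged=self.converged_,
        )


def fit_meta_d(
    counts: np.ndarray,
    padding: str = "auto",
    n_restarts: int = 5,
    m_bias_definition: str = "criterion_spread",
    random_state: int | None = 0,
) -> MetaDFit:
    """Functional wrapper over :class:`MetaDEstimator`."""
    est = MetaDEstimator(
        padding=padding,
        n_restarts=n_restarts,
        m_bias_definition=m_bias_definition,
        random_state=random_state,
    )
    return est.fit(counts).to_fit()
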