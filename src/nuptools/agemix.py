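"""Age classification of NUPTs by a Gaussian mixture on percent identity.

Percent identity of a nuclear-vs-plastid alignment decays with insertion
age, so the identity distribution of a genome's NUPT complement is a proxy
for their age distribution. Two waves ("episodes") of plastid-DNA transfer
produce a bimodal identity distribution; a two-component Gaussian mixture
fitted by EM separates them. The lower-mean component is episode I (older,
more diverged), the higher-mean component episode II (younger). A NUPT is
assigned to an episode only when its posterior probability reaches a
threshold (default 0.95); otherwise it is left "unclassified".

The model/results split follows the usual statistical-modelling idiom:
``IdentityMixture(identities).fit()`` returns an
:class:`IdentityMixtureResults` carrying parameters, diagnostics,
posterior evaluation, class assignment and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

LABEL_OLD = "I"
LABEL_YOUNG = "II"
LABEL_UNCLASSIFIED = "unclassified"

#: lower bound on component standard deviations (identity units); EM
#: degeneracy guard against components collapsing onto single points
SD_FLOOR = 1e-3


class IdentityMixture:
    """Gaussian mixture model for NUPT percent-identity values.

    Parameters
    ----------
    identities : array-like
        Percent identities in [0, 100]; at least 10 finite values.
    k : int
        Number of mixture components (1, 2 or 3; default 2 — one
        component per insertion episode).
    """

    def __init__(self, identities, k: int = 2):
        x = np.asarray(identities, dtype=float).ravel()
        if x.size < 10:
            raise ValueError(f"need at least 10 identity values, got {x.size}")
        if not np.all(np.isfinite(x)):
            raise ValueError("identities must be finite")
        if x.min() < 0 or x.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        if k not in (1, 2, 3):
            raise ValueError("k must be 1, 2 or 3")
        if np.ptp(x) == 0:
            raise ValueError("degenerate fit: all identity values identical")
        self.endog = x
        self.k = k

    def _initial_params(self):
        """Deterministic initialization: component means at evenly spaced
        inner quantiles (25/75 for k=2), equal weights, pooled sd."""
        x, k = self.endog, self.k
        qs = np.linspace(0, 100, k + 2)[1:-1]  # k=2 -> 25, 75
        means = np.percentile(x, qs).astype(float)
        sd = max(float(np.std(x)), SD_FLOOR)
        return means, np.full(k, sd), np.full(k, 1.0 / k)

    def loglike(self, means, sds, weights) -> float:
        dens = weights * norm.pdf(self.endog[:, None], means[None, :], sds[None, :])
        return float(np.sum(np.log(np.maximum(dens.sum(axis=1), 1e-300))))

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 1000,
        seed: int | None = None,
    ) -> "IdentityMixtureResults":
        """Fit by EM to convergence in relative log-likelihood change.

        Initialization is deterministic (data quantiles), so the fit is a
        pure function of the data; ``seed`` is accepted and recorded for
        provenance only.
        """
        x = self.endog
        k = self.k
        if k == 1:
            mu = float(np.mean(x))
            sd = max(float(np.std(x)), SD_FLOOR)  # population MLE sd
            ll = self.loglike(np.array([mu]), np.array([sd]), np.array([1.0]))
            return IdentityMixtureResults(
                self, np.array([mu]), np.array([sd]), np.array([1.0]),
                loglik=ll, n_iter=0, converged=True, seed=seed,
            )

        means, sds, weights = self._initial_params()
        ll_old = -np.inf
        n_iter = 0
        converged = False
        ll_path: list[float] = []
        for n_iter in range(1, max_iter + 1):
            # E step
            dens = weights * norm.pdf(x[:, None], means[None, :], sds[None, :])
            tot = np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)
            gamma = dens / tot
            # M step
            nk = gamma.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            weights = nk / x.size
            means = (gamma * x[:, None]).sum(axis=0) / nk
            var = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
            sds = np.maximum(np.sqrt(var), SD_FLOOR)
            ll = self.loglike(means, sds, weights)
            ll_path.append(ll)
            if ll - ll_old <= tol * max(abs(ll_old), 1.0) and np.isfinite(ll_old):
                converged = True
                break
            ll_old = ll
        order = np.argsort(means)
        return IdentityMixtureResults(
            self,
            means[order],
            sds[order],
            weights[order],
            loglik=ll,
            n_iter=n_iter,
            converged=converged,
            seed=seed,
            loglik_path=ll_path,
        )


@dataclass
class IdentityMixtureResults:
    """Fitted identity mixture: parameters sorted by ascending mean,
    posterior evaluation and episode assignment."""

    model: IdentityMixture
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    seed: int | None = None
    #: per-iteration log-likelihood trace (EM is monotone up to round-off)
    loglik_path: list[float] | None = None

    def __post_init__(self):
        assert abs(self.weights.sum() - 1.0) < 1e-9
        assert np.all(self.sds >= SD_FLOOR - 1e-15)
        assert np.all(np.diff(self.means) >= 0)

    @property
    def k(self) -> int:
        return len(self.means)

    def posterior(self, identities) -> np.ndarray:
        """Posterior responsibilities gamma_j(x) by Bayes' rule; rows sum to 1."""
        x = np.atleast_1d(np.asarray(identities, dtype=float))
        if np.any((x < 0) | (x > 100)):
            raise ValueError("identity outside [0, 100]")
        dens = self.weights * norm.pdf(x[:, None], self.means[None, :], self.sds[None, :])
        return dens / np.maximum(dens.sum(axis=1, keepdims=True), 1e-300)

    def assign(self, identities, threshold: float = 0.95) -> list["AgeClassAssignment"]:
        """Assign each identity to episode I/II or "unclassified".

        The lower-mean component maps to episode I (older), the higher to
        episode II (younger); a class label is granted only when its
        posterior reaches ``threshold``. Requires a two-component fit.
        """
        if self.k != 2:
            raise ValueError("age-class assignment requires a two-component fit")
        if not 0.5 < threshold <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1]")
        x = np.atleast_1d(np.asarray(identities, dtype=float))
        gam = self.posterior(x)
        out = []
        for xi, (g1, g2) in zip(x, gam):
            if g1 >= threshold:
                label = LABEL_OLD
            elif g2 >= threshold:
                label = LABEL_YOUNG
            else:
                label = LABEL_UNCLASSIFIED
            out.append(
                AgeClassAssignment(
                    identity=float(xi),
                    gamma_I=float(g1),
                    gamma_II=float(g2),
                    label=label,
                    threshold=threshold,
                )
            )
        return out

    def summary(self) -> str:
        lines = [
            "Identity mixture fit",
            "====================",
            f"n observations : {self.model.endog.size}",
            f"components     : {self.k}",
            f"log-likelihood : {self.loglik:.4f}",
            f"iterations     : {self.n_iter} (converged={self.converged})",
            "",
            "component   mean      sd    weight",
        ]
        names = ["I (older)", "II (younger)", "III"][: self.k] if self.k == 2 else [
            str(j + 1) for j in range(self.k)
        ]
        for name, m, s, w in zip(names, self.means, self.sds, self.weights):
            lines.append(f"{name:<12}{m:7.3f}{s:8.3f}{w:9.4f}")
        return "\n".join(lines)


@dataclass(frozen=True)
class AgeClassAssignment:
    """Episode assignment of one NUPT by posterior probability."""

    identity: float
    gamma_I: float
    gamma_II: float
    label: str
    threshold: float


def fit_identity_mixture(
    identities, k: int = 2, seed: int | None = None,
    tol: float = 1e-8, max_iter: int = 1000,
) -> IdentityMixtureResults:
    """Functional wrapper: fit a k-component mixture to identity values."""
    return IdentityMixture(identities, k=k).fit(tol=tol, max_iter=max_iter, seed=seed)


def assign_age_class(
    fit: IdentityMixtureResults, identity, threshold: float = 0.95
):
    """Assign identities to age classes under ``fit`` (see results.assign)."""
    scalar = np.isscalar(identity)
    res = fit.assign(np.atleast_1d(identity), threshold=threshold)
    return res[0] if scalar else res
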