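"""Kinship-aware linear mixed model for quantitative-trait association.

The model is y = X b + u + e with u ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I), where K is the kinship matrix: the phenotypic
variance-covariance is proportional to a kinship-structured matrix.
Variance components are estimated once per trait by REML on the null
(covariates-only) model, profiling the likelihood over the heritability
ratio on the eigenbasis of K; per-variant tests then reuse the fitted
covariance (EMMA/score-style approximation), so each variant costs one
generalized least squares regression on whitened data.

Usage follows the statsmodels Model/Results convention::

    model = KinshipMixedLM(y, X, kinship=K)
    result = model.fit()
    assoc = result.test_variants(dosages)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class KinshipError(ValueError):
    """Raised for an invalid (non-PSD) kinship matrix."""


@dataclass
class AssociationResult:
    """Single-variant additive association."""

    variant: str
    beta: float  # SD units of the transformed trait
    se: float
    p: float
    n: int
    skipped: bool = False
    reason: str = ""
    beta_hz: float = float("nan")


class KinshipMixedLM:
    """Linear mixed model with a kinship-proportional random effect.

    Parameters
    ----------
    endog : (n,) response (the transformed quantitative trait).
    exog : (n, p) fixed covariates including the intercept; if None, an
        intercept-only design is used.
    kinship : (n, n) symmetric PSD kinship matrix. Any scale is
        accepted (coefficient-of-kinship or GRM conventions); only
        proportionality matters.
    """

    def __init__(self, endog, exog=None, kinship=None, eig=None):
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1:
            raise ValueError("endog must be 1-D")
        n = y.size
        if n < 30:
            raise ValueError(f"need at least 30 observations, got {n}")
        X = np.ones((n, 1)) if exog is None else np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        K = np.eye(n) if kinship is None else np.asarray(kinship, dtype=float)
        if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
            raise KinshipError("kinship must be a symmetric n x n matrix")
        self.endog, self.exog, self.kinship = y, X, K
        self.nobs = n
        # Optional precomputed (eigenvalues, eigenvectors) of K: reuse
        # across traits/replicates that share the same kinship matrix.
        self._eig = eig

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       covariates=(), kinship=None) -> "KinshipMixedLM":
        X = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates]
        )
        return cls(data[response].to_numpy(dtype=float), X, kinship)

    def fit(self, method: str = "reml") -> "KinshipMixedLMResults":
        """Estimate variance components and the GLS fixed effects."""
        K = self.kinship
        if self._eig is not None:
            lam, U = self._eig
            lam = np.asarray(lam, dtype=float)
            ty, tX = U.T @ self.endog, U.T @ self.exog
        elif np.allclose(K, np.diag(np.diagonal(K))):
            lam = np.diagonal(K).copy()
            U = None  # diagonal K: rotation is the identity
            ty, tX = self.endog, self.exog
        else:
            lam, U = np.linalg.eigh(K)
            if lam.min() < -1e-8 * max(1.0, lam.max()):
                raise KinshipError(
                    f"kinship is not positive semidefinite (eigenvalue {lam.min():.3e})"
                )
            lam = np.clip(lam, 0.0, None)
            ty, tX = U.T @ self.endog, U.T @ self.exog
        # Scale so the random effect has unit mean eigenvalue; h is then
        # the fraction of variance attributable to kinship.
        scale = lam.mean()
        lam_s = lam / scale

        n, p = self.nobs, self.exog.shape[1]
        use_reml = method.lower() == "reml"

        def neg_loglik(h: float) -> float:
            w = h * lam_s + (1.0 - h)  # per-eigenvalue variance weights
            lw = np.log(w)
            Xw = tX / w[:, None]
            XtWX = tX.T @ Xw
            XtWy = Xw.T @ ty
            beta = np.linalg.solve(XtWX, XtWy)
            resid = ty - tX @ beta
            rss = float(np.sum(resid ** 2 / w))
            if use_reml:
                df = n - p
                sigma2 = rss / df
                _, logdet_xx = np.linalg.slogdet(XtWX)
                return 0.5 * (df * np.log(2 * np.pi * sigma2) + df
                              + lw.sum() + logdet_xx)
            sigma2 = rss / n
            return 0.5 * (n * np.log(2 * np.pi * sigma2) + n + lw.sum())

        res = optimize.minimize_scalar(neg_loglik, bounds=(0.0, 1.0 - 1e-6),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        h = float(res.x)
        w = h * lam_s + (1.0 - h)
        Xw = tX / w[:, None]
        XtWX = tX.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ ty)
        resid = ty - tX @ beta
        dof = n - p if use_reml else n
        sigma2 = float(np.sum(resid ** 2 / w)) / dof
        cov_beta = sigma2 * np.linalg.inv(XtWX)

        return KinshipMixedLMResults(
            model=self, h2=h, sigma_g2=h * sigma2 / scale, sigma_e2=(1 - h) * sigma2,
            params=beta, bse=np.sqrt(np.diagonal(cov_beta)),
            _lam=lam_s, _U=U, _w=w, _ty=ty, _tX=tX, _sigma2=sigma2,
            method="REML" if use_reml else "ML", converged=bool(res.success),
        )


@dataclass
class KinshipMixedLMResults:
    """Fitted variance components plus per-variant GLS machinery."""

    model: KinshipMixedLM
    h2: float  # fraction of variance on the kinship component
    sigma_g2: float
    sigma_e2: float
    params: np.ndarray
    bse: np.ndarray
    method: str
    converged: bool
    _lam: np.ndarray = field(repr=False, default=None)
    _U: np.ndarray | None = field(repr=False, default=None)
    _w: np.ndarray = field(repr=False, default=None)
    _ty: np.ndarray = field(repr=False, default=None)
    _tX: np.ndarray = field(repr=False, default=None)
    _sigma2: float = field(repr=False, default=float("nan"))

    @property
    def pvalues(self) -> np.ndarray:
        dof = self.model.nobs - self.model.exog.shape[1]
        t = self.params / self.bse
        return 2.0 * stats.t.sf(np.abs(t), dof)

    def _rotate(self, v: np.ndarray) -> np.ndarray:
        return v if self._U is None else self._U.T @ v

    def test_variant(self, dosage, variant: str = "variant",
                     trait_sd_hz: float | None = None) -> AssociationResult:
        """Additive GLS test of one dosage vector.

        Monomorphic variants are skipped with a reason rather than
        raising. ``trait_sd_hz`` converts beta from SD units to Hz per
        allele.
        """
        g = np.asarray(dosage, dtype=float)
        if np.ptp(g) == 0.0:
            return AssociationResult(variant, float("nan"), float("nan"),
                                     float("nan"), self.model.nobs,
                                     skipped=True, reason="monomorphic")
        tg = self._rotate(g)
        w = self._w
        X = np.column_stack([self._tX, tg])
        Xw = X / w[:, None]
        XtWX = X.T @ Xw
        try:
            beta = np.linalg.solve(XtWX, Xw.T @ self._ty)
        except np.linalg.LinAlgError:
            return AssociationResult(variant, float("nan"), float("nan"),
                                     float("nan"), self.model.nobs,
                                     skipped=True, reason="collinear with covariates")
        resid = self._ty - X @ beta
        dof = self.model.nobs - X.shape[1]
        sigma2 = float(np.sum(resid ** 2 / w)) / dof
        cov = sigma2 * np.linalg.inv(XtWX)
        b, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
        p = float(2.0 * stats.t.sf(abs(b / se), dof))
        hz = b * trait_sd_hz if trait_sd_hz is not None else float("nan")
        return AssociationResult(variant, b, se, p, self.model.nobs, beta_hz=hz)

    def test_variants(self, dosages, variant_ids=None,
                      trait_sd_hz: float | None = None) -> pd.DataFrame:
        """Vectorized per-variant GLS over a (n x m) dosage matrix.

        Each variant is tested alone against the null covariates, with
        a per-variant residual variance (exact single-variant GLS, not
        a shared-sigma score test).
        """
        G = np.asarray(dosages, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        n, m = G.shape
        ids = [f"v{i}" for i in range(m)] if variant_ids is None else list(variant_ids)
        w = self._w
        sw = 1.0 / np.sqrt(w)
        # Whiten, then project the null design out of y and every g.
        yw = self._ty * sw
        Xw = self._tX * sw[:, None]
        Gw = self._rotate_matrix(G) * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        y_perp = yw - Q @ (Q.T @ yw)
        G_perp = Gw - Q @ (Q.T @ Gw)
        gg = np.sum(G_perp ** 2, axis=0)
        poly = np.ptp(G, axis=0) > 0
        ok = poly & (gg > 1e-12)
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        gy = G_perp.T @ y_perp
        dof = n - self.model.exog.shape[1] - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            beta[ok] = gy[ok] / gg[ok]
            yy = float(np.sum(y_perp ** 2))
            rss = yy - beta ** 2 * gg
            se[ok] = np.sqrt(rss[ok] / dof / gg[ok])
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        out = pd.DataFrame({"variant": ids, "beta": beta, "se": se, "p": p,
                            "n": n, "skipped": ~ok})
        if trait_sd_hz is not None:
            out["beta_hz"] = out["beta"] * trait_sd_hz
        return out

    def _rotate_matrix(self, M: np.ndarray) -> np.ndarray:
        return M if self._U is None else self._U.T @ M

    def summary(self) -> str:
        lines = [
            "Kinship mixed model ({})".format(self.method),
            "=" * 44,
            f"n obs            {self.model.nobs:>10d}",
            f"h2 (kinship var.){self.h2:>13.4f}",
            f"sigma_g^2        {self.sigma_g2:>13.4f}",
            f"sigma_e^2        {self.sigma_e2:>13.4f}",
            "-" * 44,
            f"{'coef':>4} {'estimate':>12} {'se':>10} {'P':>12}",
        ]
        for i, (b, s, p) in enumerate(zip(self.params, self.bse, self.pvalues)):
            lines.append(f"b{i:<3d} {b:>12.4f} {s:>10.4f} {p:>12.3e}")
        return "\n".join(lines)
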