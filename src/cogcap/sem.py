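"""Maximum-likelihood covariance-structure (SEM) engine.

A model is a set of manifest variables, first- and second-order latent
variables, loading edges, latent (co)variances, manifest error variances
(optionally fixed, e.g. to 0) and error-covariance links.  Collecting all
latents into a vector eta with regression matrix B (second-order latents
regress first-order latents), loadings Lambda and latent disturbance
covariance Psi, the implied covariance of the manifests y = Lambda eta + eps
is

    Sigma(theta) = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta.

Fitting minimises the Wishart ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with chi^2 = (n-1) F_min, and reports the conventional fit indices (RMSEA,
TLI, CFI against the independence baseline, BIC = chi^2 + q ln n).

Identification conventions (applied by the battery fixtures):

* one loading per latent fixed to 1;
* a first-order latent regressed on a second-order latent carries zero
  disturbance variance (its variance flows entirely from the second-order
  factor);
* a single-indicator latent whose error variance is fixed to 0 has its
  variance fixed to the indicator's sample variance (latent == indicator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "Loading",
    "Covariance",
    "ErrorVariance",
    "SemModelSpec",
    "SemModel",
    "SemResults",
    "fit_ml",
    "implied_covariance",
    "independence_spec",
    "compare_models",
    "battery_model_specs",
    "simulate_from_spec",
]

FREE = None  # sentinel for a free parameter

#: sentinel fixed value: resolve to the sample variance of the named manifest
SAMPLE_VAR = "sample_var"


@dataclass(frozen=True)
class Loading:
    """Directed edge latent -> target (manifest or latent). value None = free."""

    latent: str
    target: str
    value: float | None = FREE


@dataclass(frozen=True)
class Covariance:
    """(Co)variance between two nodes (a == b gives a variance).

    ``value`` is a float for a fixed value, None for free, or the pair
    ``(SAMPLE_VAR, manifest_name)`` to fix to a sample variance at fit time.
    """

    a: str
    b: str
    value: object = FREE


@dataclass(frozen=True)
class ErrorVariance:
    manifest: str
    value: float | None = FREE


@dataclass(frozen=True)
class SemModelSpec:
    name: str
    manifest_vars: tuple[str, ...]
    latents: tuple[str, ...]
    loadings: tuple[Loading, ...]
    latent_covs: tuple[Covariance, ...]
    error_variances: tuple[ErrorVariance, ...]
    error_cov_links: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        manifests = set(self.manifest_vars)
        latents = set(self.latents)
        for ld in self.loadings:
            if ld.latent not in latents:
                raise ValueError(f"loading from undeclared latent {ld.latent!r}")
            if ld.target not in manifests | latents:
                raise ValueError(f"loading onto undeclared node {ld.target!r}")
        for a, b in self.error_cov_links:
            if a not in manifests or b not in manifests:
                raise ValueError("error covariance links must join manifests")
        # every latent must reach at least one manifest
        children: dict[str, list[str]] = {}
        for ld in self.loadings:
            children.setdefault(ld.latent, []).append(ld.target)
        for lat in self.latents:
            frontier, seen = [lat], set()
            reached = False
            while frontier:
                node = frontier.pop()
                if node in manifests:
                    reached = True
                    break
                if node in seen:
                    continue
                seen.add(node)
                frontier.extend(children.get(node, []))
            if not reached:
                raise ValueError(f"latent {lat!r} reaches no manifest variable")

    # -- parameter bookkeeping ------------------------------------------

    def free_parameters(self) -> list[tuple[str, str]]:
        """Labels of free parameters, in theta order."""
        out: list[tuple[str, str]] = []
        for ld in self.loadings:
            if ld.value is FREE:
                out.append(("loading", f"{ld.latent}->{ld.target}"))
        for cv in self.latent_covs:
            if cv.value is FREE:
                out.append(("latent_cov", f"{cv.a}~~{cv.b}"))
        for ev in self.error_variances:
            if ev.value is FREE:
                out.append(("error_var", ev.manifest))
        for a, b in self.error_cov_links:
            out.append(("error_cov", f"{a}~~{b}"))
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_parameters())

    @property
    def df(self) -> int:
        p = len(self.manifest_vars)
        return p * (p + 1) // 2 - self.n_free

    def resolve_sample_values(self, S: np.ndarray) -> "SemModelSpec":
        """Replace (SAMPLE_VAR, name) fixed values with numbers from S."""
        idx = {v: i for i, v in enumerate(self.manifest_vars)}
        new = []
        for cv in self.latent_covs:
            if isinstance(cv.value, tuple) and cv.value[0] == SAMPLE_VAR:
                j = idx[cv.value[1]]
                new.append(replace(cv, value=float(S[j, j])))
            else:
                new.append(cv)
        return replace(self, latent_covs=tuple(new))


def _build_matrices(
    spec: SemModelSpec, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble Lambda, B, Psi, Theta from the parameter vector."""
    p = len(spec.manifest_vars)
    nl = len(spec.latents)
    mi = {v: i for i, v in enumerate(spec.manifest_vars)}
    li = {v: i for i, v in enumerate(spec.latents)}
    Lam = np.zeros((p, nl))
    B = np.zeros((nl, nl))
    Psi = np.zeros((nl, nl))
    Th = np.zeros((p, p))
    k = 0
    for ld in spec.loadings:
        val = theta[k] if ld.value is FREE else ld.value
        if ld.value is FREE:
            k += 1
        if ld.target in mi:
            Lam[mi[ld.target], li[ld.latent]] = val
        else:  # latent regressed on latent
            B[li[ld.target], li[ld.latent]] = val
    for cv in spec.latent_covs:
        val = theta[k] if cv.value is FREE else cv.value
        if cv.value is FREE:
            k += 1
        i, j = li[cv.a], li[cv.b]
        Psi[i, j] = Psi[j, i] = val
    for ev in spec.error_variances:
        val = theta[k] if ev.value is FREE else ev.value
        if ev.value is FREE:
            k += 1
        Th[mi[ev.manifest], mi[ev.manifest]] = val
    for a, b in spec.error_cov_links:
        Th[mi[a], mi[b]] = Th[mi[b], mi[a]] = theta[k]
        k += 1
    assert k == len(theta)
    return Lam, B, Psi, Th


def implied_covariance(spec: SemModelSpec, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma(theta) of the manifest variables."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) != spec.n_free:
        raise ValueError(
            f"theta has {len(theta)} entries, model has {spec.n_free} free parameters"
        )
    Lam, B, Psi, Th = _build_matrices(spec, theta)
    nl = B.shape[0]
    eye = np.eye(nl)
    try:
        inv = np.linalg.inv(eye - B)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-invertible structural part (I - B singular)") from exc
    lat_cov = inv @ Psi @ inv.T
    return Lam @ lat_cov @ Lam.T + Th


@dataclass
class SemResults:
    """Fitted covariance-structure model."""

    spec: SemModelSpec
    theta: np.ndarray
    labels: list[tuple[str, str]]
    implied_cov: np.ndarray
    f_min: float
    chi_square: float
    df: int
    n: int
    converged: bool
    rmsea: float | None = None
    tli: float | None = None
    cfi: float | None = None
    bic: float | None = None
    chi_sq_over_df: float | None = None
    verdicts: dict = field(default_factory=dict)

    # -- derived quantities ---------------------------------------------

    def latent_covariance(self) -> pd.DataFrame:
        Lam, B, Psi, _ = _build_matrices(self.spec, self.theta)
        inv = np.linalg.inv(np.eye(B.shape[0]) - B)
        cov = inv @ Psi @ inv.T
        return pd.DataFrame(cov, index=self.spec.latents, columns=self.spec.latents)

    def latent_correlations(self) -> pd.DataFrame:
        cov = self.latent_covariance().to_numpy()
        sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        corr = cov / np.outer(sd, sd)
        return pd.DataFrame(corr, index=self.spec.latents, columns=self.spec.latents)

    def standardized_estimates(self) -> pd.DataFrame:
        """Completely standardized loadings and latent correlations."""
        Lam, B, Psi, Th = _build_matrices(self.spec, self.theta)
        inv = np.linalg.inv(np.eye(B.shape[0]) - B)
        lat_cov = inv @ Psi @ inv.T
        lat_sd = np.sqrt(np.clip(np.diag(lat_cov), 1e-300, None))
        man_sd = np.sqrt(np.clip(np.diag(self.implied_cov), 1e-300, None))
        mi = {v: i for i, v in enumerate(self.spec.manifest_vars)}
        li = {v: i for i, v in enumerate(self.spec.latents)}
        rows = []
        k = 0
        for ld in self.spec.loadings:
            val = self.theta[k] if ld.value is FREE else ld.value
            if ld.value is FREE:
                k += 1
            if ld.target in mi:
                std = val * lat_sd[li[ld.latent]] / man_sd[mi[ld.target]]
            else:
                std = val * lat_sd[li[ld.latent]] / lat_sd[li[ld.target]]
            rows.append(
                {"kind": "loading", "edge": f"{ld.latent}->{ld.target}",
                 "estimate": val, "standardized": std, "free": ld.value is FREE}
            )
        corr = lat_cov / np.outer(lat_sd, lat_sd)
        for cv in self.spec.latent_covs:
            val = self.theta[k] if cv.value is FREE else cv.value
            if cv.value is FREE:
                k += 1
            rows.append(
                {"kind": "latent_cov", "edge": f"{cv.a}~~{cv.b}", "estimate": val,
                 "standardized": corr[li[cv.a], li[cv.b]], "free": cv.value is FREE}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Covariance-structure model: {self.spec.name}",
            "-" * 60,
            f"manifests {len(self.spec.manifest_vars)}  free parameters "
            f"{self.spec.n_free}  n {self.n}",
            f"F_min      {self.f_min:10.6f}",
            f"chi^2 (df) {self.chi_square:10.2f} ({self.df})",
        ]
        if self.chi_sq_over_df is not None:
            lines.append(f"chi^2/df   {self.chi_sq_over_df:10.2f}")
        if self.rmsea is not None:
            lines.append(f"RMSEA      {self.rmsea:10.3f}")
        if self.tli is not None:
            lines.append(f"TLI        {self.tli:10.3f}")
        if self.cfi is not None:
            lines.append(f"CFI        {self.cfi:10.3f}")
        if self.bic is not None:
            lines.append(f"BIC        {self.bic:10.2f}")
        lines.append(f"converged  {self.converged}")
        if self.verdicts:
            lines.append("cut-off verdicts: " + ", ".join(
                f"{k}={'ok' if v else 'fail'}" for k, v in self.verdicts.items()
            ))
        return "\n".join(lines)


class SemModel:
    """ML estimator for a covariance-structure spec on a sample covariance.

    Parameters
    ----------
    spec : SemModelSpec
    S : array or DataFrame
        Sample covariance of the manifests (order must match the spec when
        an array is given; a DataFrame is reordered by name).
    n : int
        Number of observations behind S.
    """

    def __init__(self, spec: SemModelSpec, S, n: int) -> None:
        if isinstance(S, pd.DataFrame):
            S = S.loc[list(spec.manifest_vars), list(spec.manifest_vars)].to_numpy()
        S = np.asarray(S, dtype=float)
        p = len(spec.manifest_vars)
        if S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p} for this model")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("S must be positive definite")
        if n <= p:
            raise ValueError("need n > number of manifest variables")
        self.spec = spec.resolve_sample_values(S)
        self.S = S
        self.n = int(n)
        self.labels = self.spec.free_parameters()
        # fit in the correlation metric: rescaling manifests by their sample
        # SDs leaves F_ML invariant once the spec's fixed values are carried
        # into the same metric, and conditions the optimisation (the raw
        # measures differ in variance by orders of magnitude)
        self._sd = np.sqrt(np.diag(S))
        self._S_std = S / np.outer(self._sd, self._sd)
        self._latent_scale = {
            lat: self._latent_scale_factor(lat) for lat in self.spec.latents
        }
        self._spec_std = self._standardized_spec()
        self._sign, self._logdet_S = np.linalg.slogdet(self._S_std)

    def _latent_scale_factor(self, latent: str) -> float:
        """Scale carried by a latent: the SD of its anchoring manifest
        (following fixed nonzero loadings), or 1 for variance-identified
        latents."""
        mi = {v: i for i, v in enumerate(self.spec.manifest_vars)}
        node = latent
        for _ in range(10):
            if node in mi:
                return float(self._sd[mi[node]])
            nxt = None
            for ld in self.spec.loadings:
                if ld.latent == node and ld.value is not FREE and ld.value != 0:
                    nxt = ld.target
                    break
            if nxt is None:
                return 1.0
            node = nxt
        raise ValueError(f"loading cycle under latent {latent!r}")

    def _theta_factors(self) -> np.ndarray:
        """Multipliers turning standardized-metric theta into raw theta."""
        mi = {v: i for i, v in enumerate(self.spec.manifest_vars)}
        c = self._latent_scale
        out = np.empty(len(self.labels))
        for i, (kind, label) in enumerate(self.labels):
            if kind == "loading":
                lat, tgt = label.split("->")
                tgt_scale = self._sd[mi[tgt]] if tgt in mi else c[tgt]
                out[i] = tgt_scale / c[lat]
            elif kind == "latent_cov":
                a, b = label.split("~~")
                out[i] = c[a] * c[b]
            elif kind == "error_var":
                out[i] = self._sd[mi[label]] ** 2
            else:
                a, b = label.split("~~")
                out[i] = self._sd[mi[a]] * self._sd[mi[b]]
        return out

    def _standardized_spec(self) -> SemModelSpec:
        """The spec with fixed values expressed in the correlation metric."""
        mi = {v: i for i, v in enumerate(self.spec.manifest_vars)}
        c = self._latent_scale
        loadings = []
        for ld in self.spec.loadings:
            if ld.value is FREE or ld.value == 0:
                loadings.append(ld)
            else:
                tgt_scale = self._sd[mi[ld.target]] if ld.target in mi else c[ld.target]
                loadings.append(replace(ld, value=ld.value * c[ld.latent] / tgt_scale))
        covs = []
        for cv in self.spec.latent_covs:
            if cv.value is FREE or cv.value == 0:
                covs.append(cv)
            else:
                covs.append(replace(cv, value=cv.value / (c[cv.a] * c[cv.b])))
        errors = []
        for ev in self.spec.error_variances:
            if ev.value is FREE or ev.value == 0:
                errors.append(ev)
            else:
                errors.append(replace(ev, value=ev.value / self._sd[mi[ev.manifest]] ** 2))
        return replace(
            self.spec,
            loadings=tuple(loadings),
            latent_covs=tuple(covs),
            error_variances=tuple(errors),
        )

    @classmethod
    def from_dataframe(cls, spec: SemModelSpec, data: pd.DataFrame) -> "SemModel":
        """Build from raw listwise-complete observations."""
        cols = list(spec.manifest_vars)
        sub = data[cols].dropna()
        return cls(spec, sub.cov().to_numpy(), len(sub))

    # -- discrepancy -----------------------------------------------------

    def discrepancy(self, theta: np.ndarray) -> float:
        """Wishart ML discrepancy F_ML at theta, in the raw metric."""
        return self._f(implied_covariance(self.spec, theta), self.S)

    def _f(self, sigma: np.ndarray, S: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e10
        sign_s, logdet_s = np.linalg.slogdet(S)
        try:
            solve = np.linalg.solve(sigma, S)
        except np.linalg.LinAlgError:
            return 1e10
        p = S.shape[0]
        f = logdet + np.trace(solve) - logdet_s - p
        return float(f) if np.isfinite(f) else 1e10

    def _discrepancy_std(self, theta_std: np.ndarray) -> float:
        """F_ML in the correlation metric (equal to the raw-metric value)."""
        return self._f(implied_covariance(self._spec_std, theta_std), self._S_std)

    def _anchor(self, latent: str) -> str:
        """The manifest that sets the latent's scale (follow fixed-1 edges)."""
        manifests = set(self.spec.manifest_vars)
        node = latent
        for _ in range(10):
            if node in manifests:
                return node
            nxt = None
            for ld in self.spec.loadings:
                if ld.latent == node and ld.value is not FREE and ld.value != 0:
                    nxt = ld.target
                    break
            if nxt is None:  # no scale constraint below; fall back to any child
                for ld in self.spec.loadings:
                    if ld.latent == node:
                        nxt = ld.target
                        break
            if nxt is None:
                raise ValueError(f"latent {latent!r} has no path to a manifest")
            node = nxt
        raise ValueError(f"loading cycle under latent {latent!r}")

    def _start_values(self, rng: np.random.Generator | None) -> np.ndarray:
        """Starts in the correlation metric: latents inherit their anchor's
        (unit) scale, loadings start at correlation ratios with the anchor."""
        mi = {v: i for i, v in enumerate(self.spec.manifest_vars)}
        S = self._S_std

        def var_of(node: str) -> float:
            j = mi[self._anchor(node)] if node not in mi else mi[node]
            return float(S[j, j])

        def cov_of(a: str, b: str) -> float:
            ia = mi[self._anchor(a)] if a not in mi else mi[a]
            ib = mi[self._anchor(b)] if b not in mi else mi[b]
            return float(S[ia, ib])

        theta0 = np.empty(len(self.labels))
        for i, (kind, label) in enumerate(self.labels):
            if kind == "loading":
                latent, target = label.split("->")
                theta0[i] = cov_of(latent, target) / max(var_of(latent), 1e-12)
            elif kind == "latent_cov":
                a, b = label.split("~~")
                theta0[i] = 0.5 * var_of(a) if a == b else 0.4 * cov_of(a, b)
            elif kind == "error_var":
                theta0[i] = 0.5 * var_of(label)
            else:  # error_cov
                theta0[i] = 0.0
        if rng is not None:  # first start is the unperturbed base
            theta0 *= rng.uniform(0.8, 1.2, size=len(theta0))
        return theta0

    def _bounds(self) -> list[tuple[float | None, float | None]]:
        bounds: list[tuple[float | None, float | None]] = []
        for kind, label in self.labels:
            if kind == "error_var":
                bounds.append((0.0, None))
            elif kind == "latent_cov" and label.split("~~")[0] == label.split("~~")[1]:
                bounds.append((1e-8, None))
            else:
                bounds.append((None, None))
        return bounds

    def fit(
        self,
        n_starts: int = 5,
        gtol: float = 1e-8,
        seed: int = 0,
        compute_indices: bool = True,
    ) -> SemResults:
        """Minimise F_ML with multi-start bounded quasi-Newton (L-BFGS-B)."""
        rng = np.random.default_rng(seed)
        best = None
        bounds = self._bounds()
        for start in range(n_starts):
            theta0 = self._start_values(rng if start else None)
            res = optimize.minimize(
                self._discrepancy_std,
                theta0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 1000, "ftol": 1e-13, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.fun < 1e-12:
                break
        assert best is not None
        # polish from the winner
        res = optimize.minimize(
            self._discrepancy_std,
            best.x,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 4000, "ftol": 1e-15, "gtol": gtol},
        )
        if res.fun <= best.fun:
            best = res
        f_min = max(float(best.fun), 0.0)
        chi2 = (self.n - 1) * f_min
        theta_raw = np.asarray(best.x, dtype=float) * self._theta_factors()
        out = SemResults(
            spec=self.spec,
            theta=theta_raw,
            labels=self.labels,
            implied_cov=implied_covariance(self.spec, theta_raw),
            f_min=f_min,
            chi_square=chi2,
            df=self.spec.df,
            n=self.n,
            converged=bool(best.success or f_min < 1e-10),
        )
        if compute_indices:
            base = SemModel(independence_spec(self.spec.manifest_vars), self.S, self.n)
            base_fit = base.fit(n_starts=1, compute_indices=False, seed=seed)
            out = fit_indices(out, base_fit, self.n)
        return out


def fit_ml(spec: SemModelSpec, S, n: int, **kwargs) -> SemResults:
    """Convenience wrapper: ``SemModel(spec, S, n).fit(**kwargs)``."""
    return SemModel(spec, S, n).fit(**kwargs)


def independence_spec(manifest_vars: tuple[str, ...]) -> SemModelSpec:
    """The baseline model: uncorrelated manifests, free variances only."""
    return SemModelSpec(
        name="independence",
        manifest_vars=tuple(manifest_vars),
        latents=(),
        loadings=(),
        latent_covs=(),
        error_variances=tuple(ErrorVariance(v) for v in manifest_vars),
    )


def fit_indices(fit: SemResults, baseline: SemResults, n: int) -> SemResults:
    """Complete a fit with RMSEA, TLI, CFI, BIC and cut-off verdicts.

    RMSEA = sqrt(max(chi2-df,0)/(df (n-1))); TLI and CFI compare against the
    independence baseline; BIC = chi^2 + q ln(n).  Cut-offs: chi^2/df < 2,
    RMSEA < 0.06, TLI and CFI > 0.95.
    """
    chi_m, df_m = fit.chi_square, fit.df
    chi_b, df_b = baseline.chi_square, baseline.df
    if df_m > 0:
        rmsea = float(np.sqrt(max(chi_m - df_m, 0.0) / (df_m * (n - 1))))
        ratio = chi_m / df_m
    else:
        rmsea = 0.0  # saturated model
        ratio = np.nan
    if df_b > 0 and chi_b / df_b != 1.0 and df_m > 0:
        tli = ((chi_b / df_b) - (chi_m / df_m)) / ((chi_b / df_b) - 1.0)
    else:
        tli = 1.0
    denom = max(chi_b - df_b, chi_m - df_m, 0.0)
    cfi = 1.0 - max(chi_m - df_m, 0.0) / denom if denom > 0 else 1.0
    cfi = float(np.clip(cfi, 0.0, 1.0))
    bic = chi_m + fit.spec.n_free * np.log(n)
    fit.rmsea = rmsea
    fit.tli = float(tli)
    fit.cfi = cfi
    fit.bic = float(bic)
    fit.chi_sq_over_df = float(ratio) if df_m > 0 else None
    fit.verdicts = {
        "chi2/df<2": bool(df_m == 0 or ratio < 2.0),
        "rmsea<0.06": bool(rmsea < 0.06),
        "tli>0.95": bool(tli > 0.95),
        "cfi>0.95": bool(cfi > 0.95),
    }
    return fit


BIC_BANDS = ((10.0, "very strong"), (6.0, "strong"), (2.0, "positive"))


def compare_models(fit_a: SemResults, fit_b: SemResults) -> dict:
    """Chi-square and BIC comparison of two fitted models.

    The BIC evidence band follows the conventional scale: a difference above
    2 is positive evidence against the higher-BIC model, 6-10 strong, >10
    very strong.  Delta chi^2 is descriptive for non-nested pairs.
    """
    d_chi = fit_a.chi_square - fit_b.chi_square
    d_df = fit_a.df - fit_b.df
    d_bic = (fit_a.bic or 0.0) - (fit_b.bic or 0.0)
    band = "none"
    for cut, name in BIC_BANDS:
        if abs(d_bic) > cut:
            band = name
            break
    preferred = None
    if abs(d_bic) > 2.0:
        preferred = fit_a.spec.name if d_bic < 0 else fit_b.spec.name
    return {
        "delta_chi_square": float(d_chi),
        "delta_df": int(d_df),
        "delta_bic": float(d_bic),
        "bic_evidence": band,
        "preferred": preferred,
        "nested": set(fit_a.spec.manifest_vars) == set(fit_b.spec.manifest_vars),
    }


# ---------------------------------------------------------------------------
# battery model fixtures
# ---------------------------------------------------------------------------

_IQ_MANIFESTS = ("vci", "pri", "wmi", "psi")
_CC_MANIFESTS = ("ccc", "ec")
_WM_MANIFESTS = ("spatial_nback", "verbal_nback", "ospan", "rotspan", "symspan")


def _loadings_first_order() -> dict[str, tuple[Loading, ...]]:
    return {
        "Gf": (
            Loading("Gf", "pri", 1.0),
            Loading("Gf", "wmi"),
            Loading("Gf", "psi"),
        ),
        "Gc": (Loading("Gc", "vci", 1.0),),
        "CC": (Loading("CC", "ccc", 1.0), Loading("CC", "ec")),
        "Nback": (
            Loading("Nback", "spatial_nback", 1.0),
            Loading("Nback", "verbal_nback"),
        ),
        "WMS": (
            Loading("WMS", "ospan", 1.0),
            Loading("WMS", "rotspan"),
            Loading("WMS", "symspan"),
        ),
    }


def _errors(manifests, fixed: dict[str, float] | None = None):
    fixed = fixed or {}
    return tuple(
        ErrorVariance(m, fixed[m]) if m in fixed else ErrorVariance(m)
        for m in manifests
    )


def battery_model_specs() -> dict[str, SemModelSpec]:
    """The four latent-variable models of the analysis.

    1. ``iq_cc_wm`` — second-order IQ (Gf: PRI, WMI, PSI; Gc: VCI) and WM
       (N-back; WM span), first-order CC; error-covariance links WMI~~CCC
       and WMI~~OSpan; df = 39.
    2. ``gc_gf_cc`` — Gc, Gf, CC correlated; WMI~~CCC link; VCI error fixed
       to 0 (so Gc's variance is fixed to VCI's sample variance); df = 7.
    3. ``gc_gf_wm`` — Gc, Gf and second-order WM; WMI~~OSpan link; VCI error
       fixed to 0; df = 25.
    4. ``cc_wm`` — CC and second-order WM; df = 13.
    """
    fo = _loadings_first_order()
    specs: dict[str, SemModelSpec] = {}

    manifests1 = _IQ_MANIFESTS + _CC_MANIFESTS + _WM_MANIFESTS
    specs["iq_cc_wm"] = SemModelSpec(
        name="iq_cc_wm",
        manifest_vars=manifests1,
        latents=("IQ", "CC", "WM", "Gf", "Gc", "Nback", "WMS"),
        loadings=(
            fo["Gf"] + fo["Gc"] + fo["CC"] + fo["Nback"] + fo["WMS"]
            + (
                Loading("IQ", "Gf", 1.0),
                Loading("IQ", "Gc"),
                Loading("WM", "Nback", 1.0),
                Loading("WM", "WMS"),
            )
        ),
        latent_covs=(
            Covariance("IQ", "IQ"),
            Covariance("CC", "CC"),
            Covariance("WM", "WM"),
            Covariance("IQ", "CC"),
            Covariance("IQ", "WM"),
            Covariance("CC", "WM"),
            # zero-disturbance first-order latents
            Covariance("Gf", "Gf", 0.0),
            Covariance("Gc", "Gc", 0.0),
            Covariance("Nback", "Nback", 0.0),
            Covariance("WMS", "WMS", 0.0),
        ),
        error_variances=_errors(manifests1),
        error_cov_links=(("wmi", "ccc"), ("wmi", "ospan")),
    )

    manifests2 = _IQ_MANIFESTS + _CC_MANIFESTS
    specs["gc_gf_cc"] = SemModelSpec(
        name="gc_gf_cc",
        manifest_vars=manifests2,
        latents=("Gc", "Gf", "CC"),
        loadings=fo["Gf"] + fo["Gc"] + fo["CC"],
        latent_covs=(
            Covariance("Gf", "Gf"),
            Covariance("Gc", "Gc", (SAMPLE_VAR, "vci")),
            Covariance("CC", "CC"),
            Covariance("Gc", "Gf"),
            Covariance("Gc", "CC"),
            Covariance("Gf", "CC"),
        ),
        error_variances=_errors(manifests2, fixed={"vci": 0.0}),
        error_cov_links=(("wmi", "ccc"),),
    )

    manifests3 = _IQ_MANIFESTS + _WM_MANIFESTS
    specs["gc_gf_wm"] = SemModelSpec(
        name="gc_gf_wm",
        manifest_vars=manifests3,
        latents=("Gc", "Gf", "WM", "Nback", "WMS"),
        loadings=(
            fo["Gf"] + fo["Gc"] + fo["Nback"] + fo["WMS"]
            + (Loading("WM", "Nback", 1.0), Loading("WM", "WMS"))
        ),
        latent_covs=(
            Covariance("Gf", "Gf"),
            Covariance("Gc", "Gc", (SAMPLE_VAR, "vci")),
            Covariance("WM", "WM"),
            Covariance("Gc", "Gf"),
            Covariance("Gc", "WM"),
            Covariance("Gf", "WM"),
            Covariance("Nback", "Nback", 0.0),
            Covariance("WMS", "WMS", 0.0),
        ),
        error_variances=_errors(manifests3, fixed={"vci": 0.0}),
        error_cov_links=(("wmi", "ospan"),),
    )

    manifests4 = _CC_MANIFESTS + _WM_MANIFESTS
    specs["cc_wm"] = SemModelSpec(
        name="cc_wm",
        manifest_vars=manifests4,
        latents=("CC", "WM", "Nback", "WMS"),
        loadings=(
            fo["CC"] + fo["Nback"] + fo["WMS"]
            + (Loading("WM", "Nback", 1.0), Loading("WM", "WMS"))
        ),
        latent_covs=(
            Covariance("CC", "CC"),
            Covariance("WM", "WM"),
            Covariance("CC", "WM"),
            Covariance("Nback", "Nback", 0.0),
            Covariance("WMS", "WMS", 0.0),
        ),
        error_variances=_errors(manifests4),
    )
    return specs


def simulate_from_spec(
    spec: SemModelSpec, theta: np.ndarray, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw multivariate-normal observations from Sigma(theta)."""
    sigma = implied_covariance(spec, theta)
    data = rng.multivariate_normal(np.zeros(sigma.shape[0]), sigma, size=n)
    return pd.DataFrame(data, columns=list(spec.manifest_vars))
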