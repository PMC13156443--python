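"""Joint multi-field Bayesian estimation of the shared biophysical parameters.

:class:`JointR1Model` is built from per-field angular curves and exposes a
log-posterior over the free parameters — the shared biophysics
(nbA, nwA, Lambda, Omega0, zeta), one isotropic rate R1I per field, and
(by default) one noise scale sigma per field sampled in log-space under a
Jeffreys prior.  The THB coupling lambdaA and lifetime tauA are fixed
during fitting.  ``fit()`` runs a seeded affine-invariant ensemble sampler
initialised around a multi-start bounded least-squares MAP and returns a
:class:`JointR1Results` carrying posterior means/SDs, per-bin predictions,
residuals, the mean relative fitting error per field and sampler
diagnostics.

The low-angle bins (centers below ``angle_min``, default 13.5 deg, i.e.
0/4.5/9 deg) are excluded from the likelihood: tracts that parallel the
field show an extra dip attributed to their distinct microstructure, not to
the orientation model.  Exclusion only restricts the likelihood — model
predictions at any angle are unaffected for fixed parameters.
"""

from __future__ import annotations

import json
import logging
from functools import lru_cache
from pathlib import Path

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import AngularCurve
from .exceptions import ConfigurationError, InvalidDataError
from .params import (DEFAULT_TAU_A, PUBLISHED_MEANS, BiophysParams)
from .physics import (calibrate_lambda, decompose_contributions, r1_apparent)

logger = logging.getLogger(__name__)

SHARED_NAMES = ("nbA", "nwA", "Lambda", "Omega0", "zeta")

#: Default uniform prior bounds for the shared parameters.  The Omega0
#: bounds are anchored to the validity band of the V0/V2 power-law
#: approximation ([5, 25] in Omega): beyond Omega0 ~ 25 every field's Omega
#: falls outside the band and the likelihood is evaluated where the spectral
#: model is meaningless (an unconstrained prior admits a spurious posterior
#: mode out there).
DEFAULT_BOUNDS = {
    "nbA": (1e-6, 1.0 - 1e-6),
    "nwA": (1e-6, 1.0 - 1e-6),
    "Lambda": (1e-3, 200.0),
    "Omega0": (2.0, 25.0),
    "zeta": (0.0, 0.2),
    "R1I": (0.05, 10.0),
}

DEFAULT_ANGLE_MIN = 13.5


@lru_cache(maxsize=8)
def _calibrated_default_lambda(tauA: float = DEFAULT_TAU_A,
                               r1w: float = 0.0) -> float:
    base = BiophysParams(lambdaA=0.0, tauA=tauA, r1w=r1w, **PUBLISHED_MEANS)
    return calibrate_lambda(base)


def fit_error_metric(curve, predicted, *, bins_mask=None) -> float:
    """Mean relative fitting error [%] over the aligned fitted bins.

    ``curve`` is an :class:`AngularCurve` (its populated bins, optionally
    restricted by ``bins_mask``) or a plain array of observed means;
    ``predicted`` must align with it.  Raises :class:`InvalidDataError` if
    any observed mean is non-positive.
    """
    if isinstance(curve, AngularCurve):
        mask = curve.populated if bins_mask is None else bins_mask
        obs = curve.mean_r1[mask]
    else:
        obs = np.asarray(curve, dtype=float)
        if bins_mask is not None:
            obs = obs[bins_mask]
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidDataError("curve and prediction are not aligned")
    if np.any(obs <= 0):
        raise InvalidDataError("observed mean R1 must be positive")
    return float(np.mean(np.abs(pred - obs) / obs) * 100.0)


class JointR1Model:
    """Joint angular-R1 model over one or more field strengths.

    Parameters
    ----------
    curves : dict[float, AngularCurve] or sequence of AngularCurve
        Binned angular data per field, keyed by (or carrying) field
        strength in tesla.
    fixed : dict, optional
        Values held fixed during fitting; keys ``lambdaA``, ``tauA``,
        ``r1w``.  Defaults: calibrated lambdaA, tauA = 70 ns, r1w = 0.
    angle_min : float
        Smallest bin center entering the likelihood [deg].
    bounds : dict, optional
        Overrides for the uniform prior bounds (see ``DEFAULT_BOUNDS``).
    use_bin_sd : bool
        Weight residuals by the curves' SD/sqrt(n) instead of sampling a
        per-field noise scale.
    eq2_grouping : str
        Reading of the water-anisotropy expression (see physics module).
    sigma_bounds : tuple
        Bounds for the sampled per-field noise SD [1/s].
    """

    def __init__(self, curves, fixed: dict | None = None,
                 angle_min: float = DEFAULT_ANGLE_MIN,
                 bounds: dict | None = None, use_bin_sd: bool = False,
                 eq2_grouping: str = "grouped",
                 sigma_bounds: tuple = (1e-6, 1.0),
                 sample_coupling: bool = False):
        if isinstance(curves, dict):
            items = sorted(curves.items())
        else:
            items = sorted((float(c.field.B), c) for c in curves)
        if not items:
            raise ConfigurationError("at least one curve is required")
        if not (0.0 <= angle_min <= 90.0):
            raise ConfigurationError("angle_min must lie in [0, 90] deg")
        self.teslas = [t for t, _ in items]
        self.curves = {t: c for t, c in items}
        self.angle_min = float(angle_min)
        self.use_bin_sd = bool(use_bin_sd)
        self.eq2_grouping = eq2_grouping
        self.sigma_bounds = tuple(sigma_bounds)
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            self.bounds.update(bounds)

        fixed = dict(fixed or {})
        tauA = float(fixed.get("tauA", DEFAULT_TAU_A))
        r1w = float(fixed.get("r1w", 0.0))
        lambdaA = fixed.get("lambdaA")
        if lambdaA is None:
            lambdaA = _calibrated_default_lambda(tauA, r1w)
        self.fixed = {"lambdaA": float(lambdaA), "tauA": tauA, "r1w": r1w}
        self.sample_coupling = bool(sample_coupling)
        if self.sample_coupling:
            # sensitivity mode: lambdaA joins the free vector even though
            # nwA multiplies kA (itself proportional to lambdaA), so the
            # pair is close to scale-degenerate
            logger.warning(
                "sampling lambdaA with nwA free is near-degenerate (nwA "
                "scales kA, kA scales with lambdaA); interpret their "
                "marginals jointly")

        if len(self.teslas) == 1:
            logger.warning(
                "single-field fit: the field scaling of Omega0 is "
                "unconstrained (Omega0 and Lambda trade off against R1I)")

        # fitted-bin caches per field
        self._theta, self._y, self._w, self._nobs = {}, {}, {}, {}
        for t, c in items:
            m = c.populated & (c.bin_center >= self.angle_min - 1e-9)
            if not m.any():
                raise ConfigurationError(
                    f"no bins at or above angle_min={angle_min} deg survive "
                    f"for the {t:g} T curve")
            self._theta[t] = c.bin_center[m]
            self._y[t] = c.mean_r1[m]
            self._nobs[t] = int(m.sum())
            if use_bin_sd:
                se = c.sd_r1[m] / np.sqrt(np.maximum(c.n_voxels[m], 1))
                if np.any(~np.isfinite(se) | (se <= 0)):
                    raise InvalidDataError(
                        f"use_bin_sd requires positive finite SDs "
                        f"({t:g} T curve)")
                self._w[t] = 1.0 / se
            self._fitted_masks = getattr(self, "_fitted_masks", {})
            self._fitted_masks[t] = m

        head = list(SHARED_NAMES)
        if self.sample_coupling:
            head.append("log10_lambdaA")
        names = head + [f"R1I_{t:g}T" for t in self.teslas]
        if not use_bin_sd:
            names += [f"log_sigma_{t:g}T" for t in self.teslas]
        self.param_names = names
        self.k_shared = len(head)
        self.k_fields = len(self.teslas)
        self.nparams = len(names)

        lo, hi = [], []
        for n in SHARED_NAMES:
            b = self.bounds[n]
            lo.append(b[0]); hi.append(b[1])
        if self.sample_coupling:
            b = self.bounds.get("log10_lambdaA", (5.0, 10.0))
            lo.append(b[0]); hi.append(b[1])
        for _ in self.teslas:
            lo.append(self.bounds["R1I"][0]); hi.append(self.bounds["R1I"][1])
        if not use_bin_sd:
            for _ in self.teslas:
                lo.append(np.log(self.sigma_bounds[0]))
                hi.append(np.log(self.sigma_bounds[1]))
        self._lo = np.array(lo)
        self._hi = np.array(hi)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_csv(cls, paths, **kwargs) -> "JointR1Model":
        from .curves import read_curves
        return cls(read_curves(paths), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "JointR1Model":
        """Build from a long-format frame with the curve CSV columns."""
        from .fields import study_field
        curves = {}
        for tesla, sub in df.groupby("field_tesla"):
            sub = sub.sort_values("bin_center_deg")
            n = sub["n_voxels"].fillna(0).to_numpy(dtype=int)
            sd = sub["sd_r1"].to_numpy(dtype=float)
            sd = np.where((n <= 1) & ~np.isnan(sd), 0.0, sd)
            curves[float(tesla)] = AngularCurve(
                field=study_field(float(tesla)),
                bin_center=sub["bin_center_deg"].to_numpy(dtype=float),
                mean_r1=sub["mean_r1"].to_numpy(dtype=float),
                sd_r1=sd, n_voxels=n)
        return cls(curves, **kwargs)

    # -- parameter plumbing ------------------------------------------------

    def _params_object(self, head_cols) -> BiophysParams:
        """BiophysParams whose fields broadcast over walker rows.

        ``head_cols`` holds the shared biophysics (and, in coupling-
        sensitivity mode, a trailing log10 lambdaA column)."""
        d = dict(zip(SHARED_NAMES, head_cols))
        lam = self.fixed["lambdaA"]
        if len(head_cols) > len(SHARED_NAMES):
            lam = 10.0 ** np.asarray(head_cols[len(SHARED_NAMES)])
        return BiophysParams(lambdaA=lam, tauA=self.fixed["tauA"],
                             r1w=self.fixed["r1w"], **d)

    def params_from_vector(self, x) -> tuple[BiophysParams, dict]:
        """Split a free-parameter vector into (BiophysParams, R1I map)."""
        x = np.asarray(x, dtype=float)
        p = self._params_object(x[..., :self.k_shared].T)
        r1i = {t: x[..., self.k_shared + i] for i, t in enumerate(self.teslas)}
        return p, r1i

    # -- posterior ---------------------------------------------------------

    def log_prob(self, x) -> np.ndarray | float:
        """Log-posterior; accepts (ndim,) or (nwalkers, ndim)."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        X = np.atleast_2d(x)
        ok = np.all((X >= self._lo) & (X <= self._hi), axis=1)
        Xs = np.where(ok[:, None], X, 0.5 * (self._lo + self._hi))
        shared = [Xs[:, j][:, None] for j in range(self.k_shared)]
        p = self._params_object(shared)
        lp = np.zeros(X.shape[0])
        for i, t in enumerate(self.teslas):
            r1i = Xs[:, self.k_shared + i][:, None]
            pred = r1_apparent(p, r1i, self._theta[t], self.curves[t].field,
                               eq2_grouping=self.eq2_grouping,
                               on_singular="nan", warn=False)
            resid = pred - self._y[t]
            n = self._nobs[t]
            if self.use_bin_sd:
                z = resid * self._w[t]
                ll = -0.5 * np.sum(z * z, axis=-1)
            else:
                logsig = Xs[:, self.k_shared + self.k_fields + i]
                ssr = np.sum(resid * resid, axis=-1)
                ll = -n * logsig - 0.5 * ssr * np.exp(-2.0 * logsig)
            lp += np.where(np.all(np.isfinite(resid), axis=-1), ll, -np.inf)
        lp = np.where(ok, lp, -np.inf)
        return float(lp[0]) if scalar else lp

    def predict(self, params, r1i, theta_deg=None, tesla=None):
        """Model curve for explicit parameters.

        ``params`` is a BiophysParams (or mapping of shared names), ``r1i``
        a per-field dict or a scalar; evaluated at ``theta_deg`` (default:
        the curve's bin grid) for field ``tesla`` (default: each field,
        returning a dict).
        """
        if isinstance(params, dict):
            params = self._params_object([params[n] for n in SHARED_NAMES])
        if tesla is None:
            return {t: self.predict(params, r1i, theta_deg, t)
                    for t in self.teslas}
        tesla = float(tesla)
        th = self.curves[tesla].bin_center if theta_deg is None else theta_deg
        r = r1i[tesla] if isinstance(r1i, dict) else r1i
        return r1_apparent(params, r, th, self.curves[tesla].field,
                           eq2_grouping=self.eq2_grouping, warn=False)

    # -- estimation --------------------------------------------------------

    def _ls_vector(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Bounds and a data-driven start for the least-squares refinement."""
        k = self.k_shared + self.k_fields
        lo, hi = self._lo[:k].copy(), self._hi[:k].copy()
        x0 = np.empty(k)
        for j, n in enumerate(SHARED_NAMES):
            x0[j] = np.clip(PUBLISHED_MEANS[n], lo[j] + 1e-9, hi[j] - 1e-9)
        if self.sample_coupling:
            j = len(SHARED_NAMES)
            x0[j] = np.clip(np.log10(self.fixed["lambdaA"]),
                            lo[j] + 1e-9, hi[j] - 1e-9)
        for i, t in enumerate(self.teslas):
            x0[self.k_shared + i] = np.clip(np.mean(self._y[t]),
                                            lo[self.k_shared + i],
                                            hi[self.k_shared + i])
        return x0, lo, hi

    def _residuals(self, x) -> np.ndarray:
        p, r1i = self.params_from_vector(x)
        out = []
        for t in self.teslas:
            pred = r1_apparent(p, r1i[t], self._theta[t],
                               self.curves[t].field,
                               eq2_grouping=self.eq2_grouping,
                               on_singular="nan", warn=False)
            resid = pred - self._y[t]
            if self.use_bin_sd:
                resid = resid * self._w[t]
            out.append(np.nan_to_num(resid, nan=1e6))
        return np.concatenate(out)

    def map_estimate(self, seed: int = 0, n_starts: int = 6) -> np.ndarray:
        """Multi-start bounded least squares over shared params + R1I."""
        x0, lo, hi = self._ls_vector()
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(n_starts - 1, 0)):
            s = lo + (hi - lo) * rng.uniform(0.2, 0.8, size=x0.size)
            for i, t in enumerate(self.teslas):
                s[self.k_shared + i] = x0[self.k_shared + i]
            starts.append(s)
        best, best_cost = None, np.inf
        for s in starts:
            try:
                res = least_squares(self._residuals, s, bounds=(lo, hi),
                                    method="trf", xtol=1e-14, ftol=1e-14,
                                    gtol=1e-14)
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            if res.cost < best_cost:
                best, best_cost = res.x, res.cost
        if best is None:
            raise ConfigurationError("MAP optimisation failed from all starts")
        return best

    def fit(self, seed: int = 0, n_walkers: int = 48, n_steps: int = 2000,
            burn_in: int = 800, progress: bool = False,
            walker_dispersion: float = 0.5,
            ess_threshold: float = 100.0) -> "JointR1Results":
        """Sample the posterior and summarise it.

        Deterministic given ``seed`` (MAP multi-start, walker
        initialisation and sampler moves all derive from it).  A fraction
        ``walker_dispersion`` of the walkers starts spread over the
        shared-parameter prior box rather than at the MAP: the shared
        biophysics can be ridge-degenerate at realistic noise (Lambda and
        Omega0 trade off through the V0/V2 power laws), and an ensemble
        that straddles the ridge lets the differential-evolution moves
        traverse it, so the posterior spread is measured rather than the
        neighbourhood of a single mode.
        """
        rng = np.random.default_rng(seed)
        x_map = self.map_estimate(seed)
        ndim = self.nparams
        n_walkers = max(n_walkers, 2 * ndim + 2)

        center = np.empty(ndim)
        k = self.k_shared + self.k_fields
        center[:k] = x_map
        if not self.use_bin_sd:
            for i, t in enumerate(self.teslas):
                p, r1i = self.params_from_vector(x_map)
                pred = r1_apparent(p, r1i[t], self._theta[t],
                                   self.curves[t].field,
                                   eq2_grouping=self.eq2_grouping,
                                   on_singular="nan", warn=False)
                rms = float(np.sqrt(np.nanmean((pred - self._y[t]) ** 2)))
                sig = np.clip(rms if rms > 0 else self.sigma_bounds[0],
                              self.sigma_bounds[0] * 1.01,
                              self.sigma_bounds[1] * 0.99)
                center[k + i] = np.log(sig)
        span = self._hi - self._lo
        jitter = 1e-4 * span
        p0 = center + jitter * rng.standard_normal((n_walkers, ndim))
        n_disp = int(np.clip(walker_dispersion, 0.0, 1.0) * n_walkers)
        if n_disp:
            # spread only the shared biophysics; R1I and sigma stay at MAP
            p0[:n_disp, :self.k_shared] = (
                self._lo[:self.k_shared]
                + span[:self.k_shared]
                * rng.uniform(0.05, 0.95, size=(n_disp, self.k_shared)))
        p0 = np.clip(p0, self._lo + 1e-12 * span, self._hi - 1e-12 * span)

        moves = [(emcee.moves.DEMove(), 0.8),
                 (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(n_walkers, ndim, self.log_prob,
                                        vectorize=True, moves=moves)
        state = emcee.State(
            p0, random_state=np.random.RandomState(
                rng.integers(0, 2**31 - 1)).get_state())
        sampler.run_mcmc(state, n_steps, progress=progress)
        chain = sampler.get_chain(discard=burn_in, flat=True)
        lp = sampler.get_log_prob(discard=burn_in, flat=True)
        # Drop straggler samples that never reached the typical set.  For a
        # well-mixed posterior the log-probability spread across samples is
        # O(ndim); when the data are (near-)noiseless the posterior is a
        # needle and walkers still travelling from their dispersed starts sit
        # hundreds of log-units below it, and would otherwise bias the
        # summaries.
        keep = lp > lp.max() - 300.0
        n_pruned = int(np.size(keep) - np.count_nonzero(keep))
        chain = chain[keep]
        acceptance = float(np.mean(sampler.acceptance_fraction))

        try:
            tau = sampler.get_autocorr_time(discard=burn_in, quiet=True)
            tau = np.where(np.isfinite(tau) & (tau > 0), tau, n_steps)
            ess = float(chain.shape[0] / np.max(tau))
        except Exception:  # pragma: no cover - short-chain fallback
            ess = float(chain.shape[0] / n_steps)
        converged = ess >= ess_threshold
        if not converged:
            logger.warning("sampler effective sample size %.1f below "
                           "threshold %.1f; results flagged unconverged",
                           ess, ess_threshold)

        mean = chain.mean(axis=0)
        sd = chain.std(axis=0, ddof=1)
        # MAP refinement by local optimisation from the posterior mean
        try:
            refined = least_squares(
                self._residuals, np.clip(mean[:k], self._lo[:k] + 1e-12,
                                         self._hi[:k] - 1e-12),
                bounds=(self._lo[:k], self._hi[:k]), method="trf").x
        except Exception:  # pragma: no cover
            refined = x_map
        diagnostics = {
            "acceptance_fraction": acceptance,
            "effective_sample_size": ess,
            "n_pruned_samples": n_pruned,
            "converged": bool(converged),
            "n_walkers": int(n_walkers), "n_steps": int(n_steps),
            "burn_in": int(burn_in),
            "map_initial": dict(zip(self.param_names[:k], x_map)),
            "map_refined": dict(zip(self.param_names[:k], refined)),
        }
        return JointR1Results(self, chain, mean, sd, diagnostics, seed)


class JointR1Results:
    """Posterior summary of a joint angular-R1 fit."""

    def __init__(self, model: JointR1Model, chain: np.ndarray,
                 mean: np.ndarray, sd: np.ndarray, diagnostics: dict,
                 seed: int):
        self.model = model
        self.chain = chain
        self.params = pd.Series(mean, index=model.param_names)
        self.bse = pd.Series(sd, index=model.param_names)
        self.diagnostics = diagnostics
        self.seed = seed

    # -- derived quantities ------------------------------------------------

    @property
    def shared_params(self) -> BiophysParams:
        cols = [self.params[n] for n in SHARED_NAMES]
        if "log10_lambdaA" in self.params.index:
            cols.append(self.params["log10_lambdaA"])
        return self.model._params_object(cols)

    @property
    def r1i(self) -> dict:
        return {t: float(self.params[f"R1I_{t:g}T"])
                for t in self.model.teslas}

    def sigma(self) -> dict:
        """Posterior-mean per-field noise SD [1/s] (sampled mode only)."""
        if self.model.use_bin_sd:
            return {}
        return {t: float(np.exp(self.params[f"log_sigma_{t:g}T"]))
                for t in self.model.teslas}

    def predict(self, tesla=None, theta_deg=None):
        """Posterior-mean model curve (per field when ``tesla`` is None)."""
        return self.model.predict(self.shared_params, self.r1i, theta_deg,
                                  tesla)

    def fittedvalues(self, tesla: float) -> np.ndarray:
        """Prediction at every fitted bin of one field."""
        t = float(tesla)
        return self.model.predict(self.shared_params, self.r1i,
                                  self.model._theta[t], t)

    def resid(self, tesla: float) -> np.ndarray:
        t = float(tesla)
        return self.fittedvalues(t) - self.model._y[t]

    def fit_error(self, tesla=None):
        """Mean relative fitting error [%] over the fitted bins."""
        if tesla is None:
            return {t: self.fit_error(t) for t in self.model.teslas}
        t = float(tesla)
        return fit_error_metric(self.model._y[t], self.fittedvalues(t))

    def decompose(self, tesla: float, theta_deg=None):
        """(isotropic, indirect water, direct bound) components per bin."""
        t = float(tesla)
        th = self.model.curves[t].bin_center if theta_deg is None \
            else theta_deg
        return decompose_contributions(self.shared_params, self.r1i[t], th,
                                       self.model.curves[t].field,
                                       eq2_grouping=self.model.eq2_grouping)

    def mc_se(self) -> pd.Series:
        """Monte-Carlo standard error of each posterior mean."""
        ess = max(self.diagnostics.get("effective_sample_size", 1.0), 1.0)
        return self.bse / np.sqrt(ess)

    # -- presentation ------------------------------------------------------

    def observed_vs_predicted(self) -> pd.DataFrame:
        rows = []
        for t in self.model.teslas:
            c = self.model.curves[t]
            pred = self.predict(t)
            fitted = self.model._fitted_masks[t]
            iso, indirect, direct = self.decompose(t)
            for j, th in enumerate(c.bin_center):
                rows.append({
                    "field_tesla": t, "bin_center_deg": th,
                    "observed_r1": c.mean_r1[j], "predicted_r1": pred[j],
                    "isotropic": iso[j], "indirect_water": indirect[j],
                    "direct_bound": direct[j],
                    "fitted": bool(fitted[j]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Joint angular-R1 fit (THB + lateral diffusion)",
                 "=" * 47,
                 f"fields [T]      : {', '.join(f'{t:g}' for t in self.model.teslas)}",
                 f"fitted bins     : " + ", ".join(
                     f"{self.model._nobs[t]}" for t in self.model.teslas)
                 + f"  (centers >= {self.model.angle_min:g} deg)",
                 f"fixed           : lambdaA={self.model.fixed['lambdaA']:.4g} 1/s^2, "
                 f"tauA={self.model.fixed['tauA']:.3g} s, "
                 f"r1w={self.model.fixed['r1w']:g} 1/s",
                 "",
                 f"{'parameter':<16}{'post. mean':>12}{'post. SD':>12}"]
        for n in self.model.param_names:
            lines.append(f"{n:<16}{self.params[n]:>12.5g}{self.bse[n]:>12.3g}")
        lines.append("")
        for t in self.model.teslas:
            lines.append(f"mean relative fitting error {t:g} T: "
                         f"{self.fit_error(t):.4g} %")
        d = self.diagnostics
        lines.append("")
        lines.append(f"acceptance fraction {d['acceptance_fraction']:.3f}, "
                     f"ESS {d['effective_sample_size']:.0f}, "
                     f"converged: {d['converged']}, seed {self.seed}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "schema": "thbr1.fit_result/1",
            "seed": self.seed,
            "param_names": list(self.model.param_names),
            "posterior_mean": {n: float(self.params[n])
                               for n in self.model.param_names},
            "posterior_sd": {n: float(self.bse[n])
                             for n in self.model.param_names},
            "fixed": dict(self.model.fixed),
            "angle_min_deg": self.model.angle_min,
            "fit_error_percent": {f"{t:g}": self.fit_error(t)
                                  for t in self.model.teslas},
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
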