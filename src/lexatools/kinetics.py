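"""First-order autoproteolysis kinetics and inhibitor effectiveness.

LexA self-cleavage (RecA-stimulated or alkaline) consumes the intact
protein irreversibly, so the intact-band intensity on a gel decays as a
single exponential,

    [LexA]/[LexA]0 = exp(-k t),

with first-order rate constant ``k`` (per minute). An inhibitor that binds
the protein 1:1 reduces the observed rate according to

    k_i = k0 / (1 + r / phi),        r = [I] : [LexA] molar ratio,

where ``k0`` is the uninhibited rate and the effectiveness ``phi`` is the
molar ratio at which the rate is halved. With the free protein
concentration [LexA]0 known, phi converts to a dissociation constant
K_d = phi * [LexA]0.

The module is organised statsmodels-style: :class:`FirstOrderDecay` and
:class:`EffectivenessModel` are models built from data whose ``fit()``
returns results objects (:class:`RateFit`, :class:`EffectivenessFit`)
carrying estimates, standard errors, diagnostics, bootstrap intervals and
a ``summary()`` table. Thin functional wrappers (``fit_first_order``,
``fit_effectiveness``) are provided for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LEXA_MW_DA",
    "Timecourse",
    "RateFit",
    "EffectivenessFit",
    "FirstOrderDecay",
    "EffectivenessModel",
    "normalize_timecourse",
    "fit_first_order",
    "fit_effectiveness",
    "kd_from_phi",
    "molar_concentration",
    "bootstrap_effectiveness",
]

#: Molecular weight of E. coli LexA, Da (monomer). Overridable everywhere
#: it is used; kept as a convenience for molar-concentration arithmetic.
LEXA_MW_DA = 22_358.0


def molar_concentration(mass_ug: float, volume_ul: float, molecular_weight: float = LEXA_MW_DA) -> float:
    """Concentration in uM of ``mass_ug`` of protein in ``volume_ul``.

    (mass/volume) in g/L divided by the molecular weight in g/mol gives
    mol/L; the result is returned in umol/L.
    """
    if mass_ug <= 0 or volume_ul <= 0 or molecular_weight <= 0:
        raise ValueError("mass, volume and molecular weight must all be positive")
    grams_per_litre = mass_ug / volume_ul  # ug/uL == g/L
    return grams_per_litre / molecular_weight * 1e6


def kd_from_phi(phi: float, lexa0_uM: float) -> float:
    """Dissociation constant K_d = phi * [LexA]0, in uM.

    ``phi`` is the inhibitor:protein molar ratio halving the cleavage
    rate; multiplying by the protein concentration converts that ratio
    into the inhibitor concentration at half-effect, i.e. the K_d of a
    1:1 binding model.
    """
    if phi <= 0 or lexa0_uM <= 0:
        raise ValueError("phi and lexa0 must be positive")
    return phi * lexa0_uM


@dataclass
class Timecourse:
    """One cleavage reaction condition.

    ``fractions`` is the intact-protein band intensity normalised to the
    first (t = 0) aliquot; ``ratio`` is the inhibitor:protein molar ratio
    (0 for the uninhibited control).
    """

    times: np.ndarray  # minutes, strictly increasing, times[0] is t0
    fractions: np.ndarray  # dimensionless, fractions[0] == 1
    label: str = ""
    inhibitor_conc: float = 0.0  # uM
    lexa0_conc: float | None = None  # uM
    intensities: np.ndarray | None = None  # raw densitometry units

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.fractions):
            raise ValueError("times and fractions must be 1-D and equal length")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points for fitting")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if not math.isclose(self.fractions[0], 1.0, abs_tol=1e-9):
            raise ValueError("fractions[0] must equal 1 (normalise first)")

    @property
    def ratio(self) -> float:
        """Inhibitor:protein molar ratio [I]:[LexA]."""
        if self.inhibitor_conc == 0:
            return 0.0
        if not self.lexa0_conc:
            raise ValueError(f"timecourse {self.label!r}: lexa0_conc needed for a nonzero ratio")
        return self.inhibitor_conc / self.lexa0_conc

    @classmethod
    def from_intensities(
        cls,
        times,
        intensities,
        label: str = "",
        inhibitor_conc: float = 0.0,
        lexa0_conc: float | None = None,
    ) -> "Timecourse":
        return normalize_timecourse(
            times, intensities, label=label, inhibitor_conc=inhibitor_conc, lexa0_conc=lexa0_conc
        )


def normalize_timecourse(
    times,
    intensities,
    label: str = "",
    inhibitor_conc: float = 0.0,
    lexa0_conc: float | None = None,
) -> Timecourse:
    """Normalise raw band intensities by the initial aliquot.

    fractions[j] = intensities[j] / intensities[0], so the t = 0 point is
    exactly 1 and later points estimate [LexA]/[LexA]0.
    """
    intensities = np.asarray(intensities, dtype=float)
    times = np.asarray(times, dtype=float)
    if intensities.size and intensities[0] <= 0:
        raise ValueError("unnormalizable: initial band intensity must be positive")
    if np.any(intensities < 0):
        raise ValueError("unnormalizable: negative band intensity")
    return Timecourse(
        times=times,
        fractions=intensities / intensities[0],
        label=label,
        inhibitor_conc=inhibitor_conc,
        lexa0_conc=lexa0_conc,
        intensities=intensities,
    )


# ---------------------------------------------------------------------------
# Single-condition exponential decay
# ---------------------------------------------------------------------------


@dataclass
class RateFit:
    """First-order rate constant fitted to one timecourse."""

    k: float  # per minute, >= 0
    k_se: float
    r_squared: float
    n_points: int
    converged: bool
    at_bound: bool = False  # k pinned at the k >= 0 boundary
    label: str = ""
    ratio: float | None = None

    def summary(self) -> str:
        lines = [
            "First-order decay fit" + (f" [{self.label}]" if self.label else ""),
            f"  k        {self.k:.6g} /min  (SE {self.k_se:.3g})",
            f"  R^2      {self.r_squared:.4f}   n = {self.n_points}",
            f"  converged={self.converged}" + ("  (k at lower bound)" if self.at_bound else ""),
        ]
        return "\n".join(lines)


class FirstOrderDecay:
    """Model: fraction remaining f(t) = exp(-k t), single parameter.

    The amplitude is fixed at 1 because normalisation by the initial
    aliquot forces f(0) = 1; floating it would let the fit absorb t = 0
    error that, experimentally, propagates into every point.
    """

    def __init__(self, timecourse: Timecourse):
        self.timecourse = timecourse

    @staticmethod
    def predict(t, k):
        return np.exp(-k * np.asarray(t, dtype=float))

    def _loglinear_slope(self) -> float:
        """Closed-form initialiser: OLS slope of log(fraction) vs t over
        the positive fractions (equals -k for noiseless data)."""
        tc = self.timecourse
        mask = tc.fractions > 0
        if mask.sum() < 2:
            return 0.0
        slope = np.polyfit(tc.times[mask], np.log(tc.fractions[mask]), 1)[0]
        return float(slope)

    def fit(self) -> RateFit:
        tc = self.timecourse
        k0_init = max(-self._loglinear_slope(), 0.0)
        at_bound = False
        converged = True
        if k0_init == 0.0 and np.all(tc.fractions >= tc.fractions[0] - 1e-12):
            # no decay signal at all: boundary fit
            k_hat, k_se, at_bound = 0.0, float("nan"), True
        else:
            try:
                popt, pcov = curve_fit(
                    self.predict,
                    tc.times,
                    tc.fractions,
                    p0=[max(k0_init, 1e-6)],
                    bounds=(0.0, np.inf),
                    maxfev=10_000,
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
                k_hat = float(popt[0])
                k_se = float(np.sqrt(pcov[0, 0]))
                at_bound = k_hat <= 1e-12
            except RuntimeError:
                k_hat, k_se, converged = k0_init, float("nan"), False
        resid = tc.fractions - self.predict(tc.times, k_hat)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((tc.fractions - tc.fractions.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        return RateFit(
            k=k_hat,
            k_se=k_se,
            r_squared=min(r2, 1.0),
            n_points=len(tc.times),
            converged=converged,
            at_bound=at_bound,
            label=tc.label,
            ratio=tc.ratio if (tc.inhibitor_conc == 0 or tc.lexa0_conc) else None,
        )


def fit_first_order(tc: Timecourse) -> RateFit:
    """Fit f(t) = exp(-k t) to a normalised timecourse."""
    return FirstOrderDecay(tc).fit()


# ---------------------------------------------------------------------------
# Effectiveness (rate vs inhibitor:protein ratio)
# ---------------------------------------------------------------------------


@dataclass
class EffectivenessFit:
    """Estimates of (k0, phi) from rates across inhibitor ratios."""

    k0: float
    phi: float
    k0_se: float
    phi_se: float
    n_points: int
    converged: bool
    fixed_k0: bool = False
    no_inhibition: bool = False  # all rates equal: phi unidentifiable (inf)
    lexa0_used: float | None = None  # uM
    per_ratio_fits: list[RateFit] = field(default_factory=list)
    ci: dict | None = None  # filled by bootstrap()

    @property
    def kd(self) -> float | None:
        """K_d = phi * [LexA]0, uM; None when lexa0 was not supplied."""
        if self.lexa0_used is None or not np.isfinite(self.phi):
            return None
        return kd_from_phi(self.phi, self.lexa0_used)

    def predict(self, ratio) -> np.ndarray:
        return effectiveness_curve(np.asarray(ratio, dtype=float), self.k0, self.phi)

    def plot(self, ax=None):
        """Rate constant vs inhibitor:protein ratio with the fitted
        effectiveness curve; marks the half-rate point at ratio phi."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ratios = np.array([f.ratio for f in self.per_ratio_fits if f.ratio is not None])
        if ratios.size:
            ks = np.array([f.k for f in self.per_ratio_fits if f.ratio is not None])
            ax.plot(ratios, ks, "o", label="fitted $k_i$")
            grid = np.linspace(0, max(ratios.max(), self.phi) * 1.1, 200)
        else:
            grid = np.linspace(0, self.phi * 3, 200)
        if np.isfinite(self.phi):
            ax.plot(grid, self.predict(grid), "-", label="$k_0/(1 + r/\\varphi)$")
            ax.axvline(self.phi, ls=":", color="grey")
            ax.axhline(self.k0 / 2, ls=":", color="grey")
        ax.set_xlabel("[I] : [LexA] ratio")
        ax.set_ylabel("k (min$^{-1}$)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Inhibitor effectiveness fit: k_i = k0 / (1 + r/phi)",
            f"  k0   {self.k0:.6g} /min  (SE {self.k0_se:.3g})"
            + ("  [fixed]" if self.fixed_k0 else ""),
            f"  phi  {self.phi:.6g}       (SE {self.phi_se:.3g})",
        ]
        if self.kd is not None:
            lines.append(f"  K_d  {self.kd:.6g} uM  (= phi x {self.lexa0_used:g} uM LexA)")
        lines.append(f"  n = {self.n_points} ratios, converged={self.converged}")
        if self.no_inhibition:
            lines.append("  WARNING: no inhibition signal; phi unidentifiable")
        if self.ci:
            for name, (lo, hi) in self.ci.items():
                lines.append(f"  95% CI {name}: [{lo:.6g}, {hi:.6g}]")
        return "\n".join(lines)


def effectiveness_curve(ratio, k0, phi):
    """k_i as a function of the [I]:[LexA] ratio."""
    return k0 / (1.0 + np.asarray(ratio, dtype=float) / phi)


def _effectiveness_jacobian(ratio, k0, phi):
    r = np.asarray(ratio, dtype=float)
    return np.column_stack([phi / (phi + r), k0 * r / (phi + r) ** 2])


def _fit_rates_vectorized(times: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Gauss-Newton solution of the 1-parameter decay fit for many
    timecourses at once: ``fractions`` has shape (m, n_t). Solves the
    same least-squares problem as :class:`FirstOrderDecay` (used for
    bootstrap replicates, where per-fit diagnostics are not needed)."""
    t = times[None, :]
    f = np.clip(fractions, 1e-8, None)
    tbar = times.mean()
    k = -((np.log(f) * (t - tbar)).sum(1) / ((times - tbar) ** 2).sum())
    k = np.clip(k, 1e-8, None)
    for _ in range(50):
        e = np.exp(-k[:, None] * t)
        resid = fractions - e
        jac = t * e  # d resid / dk
        step = (jac * resid).sum(1) / np.maximum((jac * jac).sum(1), 1e-300)
        k = np.clip(k - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-13:
            break
    return k


class EffectivenessModel:
    """Model for rate constants observed across inhibitor:protein ratios.

    Built either directly from ``(ratio, k)`` points or from a list of
    timecourses via :meth:`from_timecourses`, which first fits each
    condition's first-order rate (the two-stage procedure matching how
    gel timecourse data are analysed: one decay fit per lane series,
    then the effectiveness curve through the fitted rates).
    """

    def __init__(self, ratios, rates, lexa0: float | None = None,
                 per_ratio_fits: list[RateFit] | None = None,
                 timecourses: list[Timecourse] | None = None):
        self.ratios = np.asarray(ratios, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.ratios.shape != self.rates.shape or self.ratios.ndim != 1:
            raise ValueError("ratios and rates must be 1-D and equal length")
        if np.any(self.ratios < 0) or np.any(self.rates < 0):
            raise ValueError("ratios and rates must be non-negative")
        self.lexa0 = lexa0
        self.per_ratio_fits = per_ratio_fits or []
        self.timecourses = timecourses

    @classmethod
    def from_timecourses(cls, timecourses: list[Timecourse],
                         lexa0: float | None = None) -> "EffectivenessModel":
        fits = [fit_first_order(tc) for tc in timecourses]
        ratios = [tc.ratio for tc in timecourses]
        if lexa0 is None:
            concs = {tc.lexa0_conc for tc in timecourses if tc.lexa0_conc}
            if len(concs) == 1:
                lexa0 = concs.pop()
        return cls(ratios, [f.k for f in fits], lexa0=lexa0, per_ratio_fits=fits,
                   timecourses=list(timecourses))

    def fit(self, fix_k0: float | None = None) -> EffectivenessFit:
        r, k = self.ratios, self.rates
        n_free = 1 if fix_k0 is not None else 2
        if len(np.unique(r)) < max(n_free, 2):
            raise ValueError("need at least as many distinct ratios as free parameters")
        if fix_k0 is None and not np.any(r == 0):
            raise ValueError("need a ratio-0 control or an explicit fix_k0")
        if np.allclose(k, k[0], rtol=1e-12, atol=1e-15) and len(np.unique(r)) > 1:
            # flat response: the curve is constant only in the phi -> inf limit
            k0_hat = fix_k0 if fix_k0 is not None else float(k[0])
            return EffectivenessFit(
                k0=k0_hat, phi=float("inf"), k0_se=0.0, phi_se=float("nan"),
                n_points=len(r), converged=True, fixed_k0=fix_k0 is not None,
                no_inhibition=True, lexa0_used=self.lexa0,
                per_ratio_fits=self.per_ratio_fits,
            )

        k0_init = fix_k0 if fix_k0 is not None else float(np.max(k[r == r.min()]))
        k0_init = max(k0_init, 1e-9)
        # phi init: ratio at which k first drops below k0/2, else median ratio
        below = r[k < 0.5 * k0_init]
        phi_init = float(below.min()) if below.size else float(np.median(r[r > 0]) or 1.0)
        phi_init = max(phi_init, 1e-6)

        try:
            if fix_k0 is not None:
                popt, pcov = curve_fit(
                    lambda rr, phi: effectiveness_curve(rr, fix_k0, phi),
                    r, k, p0=[phi_init], bounds=(1e-12, np.inf), maxfev=20_000,
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    jac=lambda rr, phi: (fix_k0 * rr / (phi + rr) ** 2).reshape(-1, 1),
                )
                k0_hat, phi_hat = float(fix_k0), float(popt[0])
                k0_se, phi_se = 0.0, float(np.sqrt(pcov[0, 0]))
            else:
                popt, pcov = curve_fit(
                    effectiveness_curve,
                    r, k, p0=[k0_init, phi_init],
                    bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20_000,
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    jac=_effectiveness_jacobian,
                )
                k0_hat, phi_hat = map(float, popt)
                k0_se, phi_se = map(float, np.sqrt(np.diag(pcov)))
            converged = True
        except RuntimeError:
            k0_hat, phi_hat = k0_init, phi_init
            k0_se = phi_se = float("nan")
            converged = False

        return EffectivenessFit(
            k0=k0_hat, phi=phi_hat, k0_se=k0_se, phi_se=phi_se,
            n_points=len(r), converged=converged, fixed_k0=fix_k0 is not None,
            lexa0_used=self.lexa0, per_ratio_fits=self.per_ratio_fits,
        )

    def bootstrap(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        fix_k0: float | None = None,
        ci_level: float = 0.95,
        method: str = "auto",
    ) -> dict:
        """Bootstrap percentile CIs for k0, phi (and K_d when lexa0 known).

        Methods:

        ``parametric``
            Full-pipeline parametric bootstrap (default when the model
            was built from timecourses). New band-fraction timecourses
            are simulated from the fitted effectiveness curve with the
            noise level estimated from the observed timecourse
            residuals, then both fitting stages (per-condition rate,
            then effectiveness curve) are rerun. This propagates the
            first-stage rate uncertainty that pointwise resampling of so
            few (ratio, k) pairs misses.
        ``case``
            Case resampling of (ratio, k) pairs. Resamples on which the
            model is unidentifiable (too few distinct ratios, or no
            ratio-0 control with k0 free) are skipped and counted. The
            only option when just the (ratio, k) points are known;
            with a handful of designed ratios its intervals run narrow.
        ``auto``
            ``parametric`` when timecourses are available, else ``case``.

        Deterministic for a fixed seed. Returns a dict of
        ``(lo, hi)`` tuples per parameter plus bookkeeping
        (``method``, ``n_used``, ``n_skipped``).
        """
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if method == "auto":
            method = "parametric" if self.timecourses else "case"
        if method == "parametric":
            if not self.timecourses:
                raise ValueError("parametric bootstrap needs timecourses "
                                 "(build the model with from_timecourses)")
            samples, n_skipped = self._bootstrap_parametric(n_boot, seed, fix_k0)
        elif method == "case":
            samples, n_skipped = self._bootstrap_case(n_boot, seed, fix_k0)
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")

        alpha = (1.0 - ci_level) / 2.0
        out: dict = {}
        for name, vals in samples.items():
            if vals:
                out[name] = (
                    float(np.percentile(vals, 100 * alpha)),
                    float(np.percentile(vals, 100 * (1 - alpha))),
                )
        out["method"] = method
        out["n_skipped"] = n_skipped
        out["n_used"] = n_boot - n_skipped
        return out

    def _collect(self, samples: dict, k0: float, phi: float) -> None:
        samples["k0"].append(k0)
        samples["phi"].append(phi)
        if "kd" in samples:
            samples["kd"].append(kd_from_phi(phi, self.lexa0))

    def _new_samples(self) -> dict:
        samples: dict[str, list[float]] = {"k0": [], "phi": []}
        if self.lexa0 is not None:
            samples["kd"] = []
        return samples

    def _bootstrap_case(self, n_boot, seed, fix_k0):
        rng = np.random.default_rng(seed)
        n = len(self.ratios)
        samples = self._new_samples()
        n_skipped = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                fit_b = EffectivenessModel(
                    self.ratios[idx], self.rates[idx], lexa0=self.lexa0
                ).fit(fix_k0=fix_k0)
            except ValueError:
                n_skipped += 1
                continue
            if not fit_b.converged or not np.isfinite(fit_b.phi):
                n_skipped += 1
                continue
            self._collect(samples, fit_b.k0, fit_b.phi)
        return samples, n_skipped

    def _bootstrap_parametric(self, n_boot, seed, fix_k0):
        rng = np.random.default_rng(seed)
        fit = self.fit(fix_k0=fix_k0)
        if not np.isfinite(fit.phi):
            raise ValueError("cannot bootstrap an unidentifiable (flat) fit")
        times = self.timecourses[0].times
        for tc in self.timecourses[1:]:
            if not np.array_equal(tc.times, times):
                raise ValueError("parametric bootstrap requires a common time grid")
        fractions = np.array([tc.fractions for tc in self.timecourses])
        # residual noise level around the per-condition decay fits
        pred_obs = np.exp(-self.rates[:, None] * times[None, :])
        resid = (fractions - pred_obs)[:, times > 0]
        dof = max(resid.size - len(self.rates), 1)
        noise_sd = float(np.sqrt((resid**2).sum() / dof))
        # generative curves from the smoothed effectiveness fit
        k_curve = effectiveness_curve(self.ratios, fit.k0, fit.phi)
        true_frac = np.exp(-k_curve[:, None] * times[None, :])
        mask = times > 0
        samples = self._new_samples()
        n_skipped = 0
        for _ in range(n_boot):
            f_b = true_frac.copy()
            f_b[:, mask] = np.clip(
                f_b[:, mask] + rng.normal(0.0, noise_sd, f_b[:, mask].shape), 0.0, None
            )
            k_b = _fit_rates_vectorized(times, f_b)
            try:
                fit_b = EffectivenessModel(self.ratios, k_b, lexa0=self.lexa0).fit(
                    fix_k0=fix_k0
                )
            except ValueError:
                n_skipped += 1
                continue
            if not fit_b.converged or not np.isfinite(fit_b.phi):
                n_skipped += 1
                continue
            self._collect(samples, fit_b.k0, fit_b.phi)
        return samples, n_skipped


def fit_effectiveness(
    points,
    fix_k0: float | None = None,
    lexa0: float | None = None,
) -> EffectivenessFit:
    """Fit k_i = k0 / (1 + r/phi) to ``points`` = [(ratio, k_i), ...]."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (ratio, k) pairs")
    return EffectivenessModel(pts[:, 0], pts[:, 1], lexa0=lexa0).fit(fix_k0=fix_k0)


def bootstrap_effectiveness(
    points,
    n_boot: int = 1000,
    seed: int = 0,
    fix_k0: float | None = None,
    lexa0: float | None = None,
    method: str = "auto",
) -> dict:
    """Bootstrap percentile CIs for the effectiveness fit of ``points``.

    With only (ratio, k) pairs available this resolves to case
    resampling; build an :class:`EffectivenessModel` from timecourses to
    enable the parametric pipeline bootstrap.
    """
    pts = np.asarray(points, dtype=float)
    return EffectivenessModel(pts[:, 0], pts[:, 1], lexa0=lexa0).bootstrap(
        n_boot=n_boot, seed=seed, fix_k0=fix_k0, method=method
    )
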