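"""One-site antibody-binding model, statsmodels-style.

Surface-binding dose–response data (antibody concentration vs mean
fluorescence intensity of the bound secondary) are described by the one-site
specific-binding hyperbola

    MFI(c) = MFI_max · c / (Kd + c)

with MFI_max the saturating intensity and Kd the dissociation constant — the
concentration at half-maximal binding, in the same units as c.  The fit is
unweighted nonlinear least squares with multi-start initialization.

Usage mirrors statsmodels: build :class:`OneSiteBinding` from arrays or a
DataFrame, call :meth:`~OneSiteBinding.fit`, and read estimates, standard
errors and diagnostics off the returned :class:`OneSiteBindingResults`
(``summary()``, ``predict()``, ``plot()``).

A literal variant ``variant="half_max_of_mfimax"`` is available for
reproducing the published formula MFI_max·c/(0.5·MFI_max + c); it places a
fluorescence quantity in the concentration slot and is offered only for
exact reproduction, not recommended for analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "BindingCurve",
    "OneSiteBinding",
    "OneSiteBindingResults",
    "fit_binding",
    "predict_binding",
    "mass_to_molar",
    "DEFAULT_CONCENTRATIONS",
]

#: Default dose grid in µg/ml.
DEFAULT_CONCENTRATIONS = (0.01, 0.1, 1.0, 10.0)

IGG_MOLAR_MASS_KDA = 150.0


@dataclass
class BindingCurve:
    """(concentration, MFI) dose–response points, optionally replicated."""

    concentrations: np.ndarray
    mfi: np.ndarray
    replicate: np.ndarray | None = None
    concentration_unit: str = "ug/ml"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.mfi = np.asarray(self.mfi, dtype=float)
        if self.concentrations.shape != self.mfi.shape:
            raise InvalidParameterError("concentrations and mfi must have the same length")
        if np.any(self.concentrations < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.mfi)):
            raise InvalidParameterError("non-finite MFI values")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.concentrations))


def one_site(c, mfi_max, kd):
    """MFI_max·c/(Kd + c)."""
    return mfi_max * np.asarray(c, dtype=float) / (kd + np.asarray(c, dtype=float))


def _one_site_half_max_variant(c, mfi_max):
    # literal published form: Kd slot occupied by 0.5*MFI_max
    c = np.asarray(c, dtype=float)
    return mfi_max * c / (0.5 * mfi_max + c)


class OneSiteBinding:
    """One-site specific-binding model for a dose–response curve.

    Parameters
    ----------
    curve
        A :class:`BindingCurve`, or build from arrays / a DataFrame with
        :meth:`from_arrays` / :meth:`from_dataframe`.

    Examples
    --------
    >>> model = OneSiteBinding.from_arrays([0.01, 0.1, 1, 10], [20, 167, 667, 952])
    >>> res = model.fit()
    >>> round(res.kd, 2)  # doctest: +SKIP
    0.5
    """

    def __init__(self, curve: BindingCurve):
        if curve.n_distinct < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct concentrations, got {curve.n_distinct}"
            )
        if not np.any(curve.mfi > 0):
            raise InsufficientDataError("all MFI values non-positive; nothing to fit")
        self.curve = curve

    @classmethod
    def from_arrays(cls, concentrations, mfi, replicate=None, concentration_unit="ug/ml"):
        return cls(BindingCurve(np.asarray(concentrations, dtype=float),
                                np.asarray(mfi, dtype=float),
                                replicate, concentration_unit))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col="concentration", mfi_col="mfi",
                       replicate_col=None, concentration_unit="ug/ml"):
        for col in (conc_col, mfi_col):
            if col not in df.columns:
                raise InvalidParameterError(f"missing column {col!r}")
        rep = df[replicate_col].to_numpy() if replicate_col else None
        return cls(BindingCurve(df[conc_col].to_numpy(dtype=float),
                                df[mfi_col].to_numpy(dtype=float),
                                rep, concentration_unit))

    def _starts(self) -> list[tuple[float, ...]]:
        c, y = self.curve.concentrations, self.curve.mfi
        mfi_max0 = float(y.max())
        pos = c[c > 0]
        # Kd0 = concentration whose response is nearest half-max, then log-spaced starts
        kd_half = float(c[np.argmin(np.abs(y - mfi_max0 / 2))]) if np.any(c > 0) else 1.0
        if kd_half <= 0:
            kd_half = float(pos.min()) if pos.size else 1.0
        lo = float(pos.min()) / 10 if pos.size else 1e-3
        hi = float(pos.max()) * 10 if pos.size else 1e3
        kds = [kd_half] + list(np.geomspace(lo, hi, 5))
        return [(mfi_max0, kd) for kd in kds]

    def fit(self, variant: str = "one_site") -> "OneSiteBindingResults":
        """Unweighted least-squares fit with multi-start initialization."""
        c, y = self.curve.concentrations, self.curve.mfi
        best = None
        if variant == "one_site":
            func, names = one_site, ("mfi_max", "kd")
            starts = self._starts()
            bounds = ([1e-12, 1e-12], [np.inf, np.inf])
        elif variant == "half_max_of_mfimax":
            func, names = _one_site_half_max_variant, ("mfi_max",)
            starts = [(float(y.max()),), (2 * float(y.max()) + 1e-9,)]
            bounds = ([1e-12], [np.inf])
        else:
            raise InvalidParameterError(f"unknown variant {variant!r}")
        for p0 in starts:
            try:
                popt, pcov = curve_fit(func, c, y, p0=p0, bounds=bounds, maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((y - func(c, *popt)) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        if best is None:
            return OneSiteBindingResults(
                model=self, variant=variant, param_names=names,
                params=None, bse=None, rss=np.nan, converged=False,
            )
        popt, pcov, rss = best
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        return OneSiteBindingResults(
            model=self, variant=variant, param_names=names,
            params=np.asarray(popt, dtype=float), bse=bse, rss=rss, converged=True,
        )


@dataclass
class OneSiteBindingResults:
    """Fitted parameters, standard errors, and diagnostics."""

    model: OneSiteBinding
    variant: str
    param_names: tuple[str, ...]
    params: np.ndarray | None
    bse: np.ndarray | None
    rss: float
    converged: bool

    @property
    def mfi_max(self) -> float | None:
        return None if self.params is None else float(self.params[0])

    @property
    def kd(self) -> float | None:
        """Dissociation constant in the curve's concentration units."""
        if self.params is None:
            return None
        if self.variant == "half_max_of_mfimax":
            return 0.5 * float(self.params[0])  # implied by the literal form
        return float(self.params[1])

    @property
    def nobs(self) -> int:
        return len(self.model.curve.mfi)

    def predict(self, c) -> np.ndarray | float:
        """Model MFI at concentration(s) ``c`` (same units as the data)."""
        if not self.converged or self.params is None:
            raise InvalidParameterError("fit did not converge; parameters withheld")
        c_arr = np.asarray(c, dtype=float)
        if np.any(c_arr < 0):
            raise InvalidParameterError("concentration must be non-negative")
        out = one_site(c_arr, self.mfi_max, self.kd)
        return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out

    def summary(self) -> str:
        unit = self.model.curve.concentration_unit
        lines = [
            "One-site specific binding: MFI(c) = MFI_max * c / (Kd + c)",
            f"  variant:    {self.variant}",
            f"  nobs:       {self.nobs} ({self.model.curve.n_distinct} distinct concentrations)",
            f"  converged:  {self.converged}",
        ]
        if self.converged and self.params is not None:
            se = self.bse if self.bse is not None else [np.nan] * len(self.params)
            lines.append(f"  RSS:        {self.rss:.6g}")
            lines.append(f"  MFI_max:    {self.mfi_max:.6g} (SE {se[0]:.3g})")
            if self.variant == "one_site":
                lines.append(f"  Kd:         {self.kd:.6g} {unit} (SE {se[1]:.3g})")
            else:
                lines.append(f"  implied Kd: {self.kd:.6g} (0.5*MFI_max, literal form)")
        else:
            lines.append("  parameters withheld (non-convergence)")
        return "\n".join(lines)

    def plot(self, ax=None, n_points: int = 200):
        """Data points and fitted curve on a log-x axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c, y = self.model.curve.concentrations, self.model.curve.mfi
        ax.plot(c, y, "o", label="data")
        if self.converged:
            pos = c[c > 0]
            grid = np.geomspace(pos.min() / 3, pos.max() * 3, n_points)
            ax.plot(grid, self.predict(grid), "-", label=f"fit (Kd={self.kd:.3g})")
        ax.set_xscale("log")
        ax.set_xlabel(f"concentration ({self.model.curve.concentration_unit})")
        ax.set_ylabel("MFI (a.u.)")
        ax.legend()
        return ax


def fit_binding(curve: BindingCurve, variant: str = "one_site") -> OneSiteBindingResults:
    """Functional wrapper: fit the one-site model to a binding curve."""
    return OneSiteBinding(curve).fit(variant=variant)


def predict_binding(fit: OneSiteBindingResults, c) -> np.ndarray | float:
    """Model MFI at concentration ``c`` for a fitted curve."""
    return fit.predict(c)


def mass_to_molar(c_ug_ml, molar_mass_kda: float = IGG_MOLAR_MASS_KDA):
    """Convert an antibody mass concentration (µg/ml) to molarity (nM).

    nM = 1e6 · (c in g/L) / (molar mass in g/mol).  For IgG (~150 kDa),
    0.1 µg/ml ≈ 0.67 nM.
    """
    c = np.asarray(c_ug_ml, dtype=float)
    if np.any(c < 0):
        raise InvalidParameterError("concentration must be non-negative")
    if molar_mass_kda <= 0:
        raise InvalidParameterError("molar mass must be positive")
    grams_per_liter = c * 1e-3
    mol_per_liter = grams_per_liter / (molar_mass_kda * 1e3)
    out = mol_per_liter * 1e9
    return float(out) if out.ndim == 0 else out
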