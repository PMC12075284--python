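"""Prony-series linear viscoelasticity: forward model, ex vivo scaling, fitting.

A Prony material has relaxation modulus

    G(t) = G_inf + G0 * sum_i g_i * exp(-t / tau_i),   G_inf = G0 * (1 - sum_i g_i)

whose frequency-domain storage and loss moduli at angular frequency
``w = 2*pi*f`` are

    G'(w)  = G_inf + sum_i G0 * g_i * (w*tau_i)^2 / (1 + (w*tau_i)^2)
    G''(w) = sum_i G0 * g_i * (w*tau_i)     / (1 + (w*tau_i)^2)

Regional materials are parameterized by scaling an ex vivo master curve to
in vivo elastography samples in the measured 30-70 Hz band, then fitting up
to three Prony terms to the combined data over the full frequency range.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PronyMaterial",
    "ModulusSample",
    "prony_moduli",
    "scale_exvivo",
    "fit_prony",
    "region_materials",
    "load_exvivo_curve",
    "SAS_MATERIAL",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class PronyMaterial:
    """Time-domain linear viscoelastic parameters for one region.

    ``terms`` holds up to three ``(g_i, tau_i_s)`` pairs with ``g_i >= 0``,
    ``sum g_i <= 1`` and ``tau_i > 0``.  ``Ginf_pa = G0_pa * (1 - sum g_i)``
    by construction.  Density (g/cm^3) and bulk modulus (Pa) ride along for
    the FE material cards.
    """

    G0_pa: float
    terms: tuple[tuple[float, float], ...] = ()
    rho_g_cm3: float = 1.04
    K_pa: float = 2.19e9

    def __post_init__(self) -> None:
        if not self.G0_pa > 0:
            raise ValueError(f"G0 must be positive, got {self.G0_pa}")
        if len(self.terms) > 3:
            raise ValueError("at most 3 Prony terms supported")
        gsum = 0.0
        for g, tau in self.terms:
            if g < 0:
                raise ValueError(f"fractional contribution g={g} < 0")
            if not tau > 0:
                raise ValueError(f"time constant tau={tau} must be positive")
            gsum += g
        if gsum > 1 + _REL_TOL:
            raise ValueError(f"sum of g_i = {gsum} exceeds 1")
        object.__setattr__(self, "terms", tuple((float(g), float(t)) for g, t in self.terms))

    @property
    def Ginf_pa(self) -> float:
        return self.G0_pa * (1.0 - sum(g for g, _ in self.terms))

    @property
    def g_sum(self) -> float:
        return sum(g for g, _ in self.terms)


#: Subarachnoid-space card used in the group-average head models:
#: rho = 1.04 g/cm^3, K = 2.19 GPa, G0 = 0.5 kPa, g1 = 0.8, tau1 = 12.5 ms.
SAS_MATERIAL = PronyMaterial(G0_pa=500.0, terms=((0.8, 0.0125),), rho_g_cm3=1.04, K_pa=2.19e9)


@dataclass(frozen=True)
class ModulusSample:
    """One (frequency, G', G'') sample of the complex shear modulus."""

    frequency_hz: float
    gprime_pa: float
    gdoubleprime_pa: float
    source: Literal["invivo", "exvivo", "exvivo_scaled"] = "invivo"

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError("frequency must be positive")
        if not self.gprime_pa > 0:
            raise ValueError("storage modulus must be positive")


def prony_moduli(mat: PronyMaterial, freq_hz):
    """Closed-form storage and loss moduli of ``mat`` at frequency ``freq_hz``.

    Accepts a scalar or array of frequencies (Hz, >= 0); returns
    ``(gprime_pa, gdoubleprime_pa)`` of matching shape.  ``G'`` lies in
    ``[Ginf, G0]`` and ``G'' >= 0`` for any valid material.
    """
    f = np.asarray(freq_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    w = 2.0 * np.pi * f
    gp = np.full_like(f, mat.Ginf_pa, dtype=float)
    gpp = np.zeros_like(f, dtype=float)
    for g, tau in mat.terms:
        wt = w * tau
        denom = 1.0 + wt**2
        gp = gp + mat.G0_pa * g * wt**2 / denom
        gpp = gpp + mat.G0_pa * g * wt / denom
    if np.isscalar(freq_hz) or np.ndim(freq_hz) == 0:
        return float(gp), float(gpp)
    return gp, gpp


def _interp_exvivo(exvivo: Sequence[ModulusSample], freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-frequency linear interpolation of the ex vivo curve at ``freqs``."""
    ex = sorted(exvivo, key=lambda s: s.frequency_hz)
    logf = np.log10([s.frequency_hz for s in ex])
    gp = np.array([s.gprime_pa for s in ex])
    gpp = np.array([s.gdoubleprime_pa for s in ex])
    lf = np.log10(freqs)
    return np.interp(lf, logf, gp), np.interp(lf, logf, gpp)


def scale_exvivo(
    exvivo: Sequence[ModulusSample],
    invivo: Sequence[ModulusSample],
    band_hz: tuple[float, float] = (30.0, 70.0),
) -> tuple[list[ModulusSample], float]:
    """Scale an ex vivo master curve to in vivo samples in ``band_hz``.

    A single positive scalar ``c`` minimises the relative squared error,
    summed over the in-band in vivo points and over G' and G'' jointly,
    between ``c * exvivo(f)`` (log-frequency linear interpolation) and the
    in vivo values.  The objective is quadratic in ``c`` with closed-form
    minimiser ``c = sum(r) / sum(r^2)`` for ratios ``r = e/v``.

    Returns the fully rescaled ex vivo list and the scale factor.
    """
    if not exvivo:
        raise ValueError("empty ex vivo curve")
    lo, hi = band_hz
    ex_f = [s.frequency_hz for s in exvivo]
    if min(ex_f) > lo or max(ex_f) < hi:
        raise ValueError(
            f"ex vivo curve spans {min(ex_f)}-{max(ex_f)} Hz and does not cover the band {band_hz}"
        )
    inband = [s for s in invivo if lo <= s.frequency_hz <= hi]
    if not inband:
        raise ValueError(f"no in vivo samples inside the band {band_hz}")
    freqs = np.array([s.frequency_hz for s in inband])
    egp, egpp = _interp_exvivo(exvivo, freqs)
    vgp = np.array([s.gprime_pa for s in inband])
    vgpp = np.array([s.gdoubleprime_pa for s in inband])
    ratios = [egp / vgp]
    if np.any(vgpp > 0):
        keep = vgpp > 0
        ratios.append(egpp[keep] / vgpp[keep])
    r = np.concatenate(ratios)
    c = float(np.sum(r) / np.sum(r**2))
    if not c > 0:
        raise ValueError("degenerate scaling: non-positive scale factor")
    scaled = [
        replace(s, gprime_pa=c * s.gprime_pa, gdoubleprime_pa=c * s.gdoubleprime_pa,
                source="exvivo_scaled")
        for s in exvivo
    ]
    return scaled, c


def _residuals(theta: np.ndarray, n: int, f: np.ndarray, gp: np.ndarray, gpp: np.ndarray) -> np.ndarray:
    g0 = math.exp(theta[0])
    s = theta[1 : 1 + n]
    taus = np.exp(theta[1 + n : 1 + 2 * n])
    # stick-breaking keeps g_i >= 0 and sum g_i <= 1 for s_i in [0, 1]
    gs = []
    rem = 1.0
    for si in s:
        gs.append(si * rem)
        rem *= 1.0 - si
    mat = PronyMaterial(G0_pa=g0, terms=tuple((gi, ti) for gi, ti in zip(gs, taus)))
    mp, mpp = prony_moduli(mat, f)
    r1 = (mp - gp) / gp
    denom = np.where(gpp > 0, gpp, gp)
    r2 = (mpp - gpp) / denom
    return np.concatenate([r1, r2])


def _theta_to_material(theta: np.ndarray, n: int, rho: float, K: float) -> PronyMaterial:
    g0 = math.exp(theta[0])
    s = theta[1 : 1 + n]
    taus = np.exp(theta[1 + n : 1 + 2 * n])
    gs = []
    rem = 1.0
    for si in s:
        gs.append(si * rem)
        rem *= 1.0 - si
    terms = tuple((gi, ti) for gi, ti in sorted(zip(gs, taus), key=lambda p: p[1]))
    terms = tuple((g, t) for g, t in terms if g > 1e-8)
    return PronyMaterial(G0_pa=g0, terms=terms, rho_g_cm3=rho, K_pa=K)


def fit_prony(
    samples: Sequence[ModulusSample],
    n_terms_max: int = 3,
    rho_g_cm3: float = 1.04,
    K_pa: float = 2.19e9,
) -> tuple[PronyMaterial, float]:
    """Constrained Prony fit to complex-modulus samples.

    Minimises relative squared error on G' and G'' jointly over ``G0``,
    ``g_i``, ``tau_i``, subject to ``g_i >= 0``, ``sum g_i <= 1`` and
    ``tau_i > 0`` (enforced via a stick-breaking / log parameterization).
    Deterministic multi-start over log-spaced time-constant initialisations
    at {1, 10, 100} ms.  Term counts 1..``n_terms_max`` are tried (capped so
    that ``len(samples) >= 2n + 1``) and an added term is kept only when it
    improves the residual norm by more than 1%.

    Returns ``(material, residual)`` with ``residual`` the root mean squared
    relative error over the stacked G'/G'' residual vector.
    """
    if n_terms_max not in (1, 2, 3):
        raise ValueError("n_terms_max must be in {1, 2, 3}")
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    f = np.array([s.frequency_hz for s in samples])
    gp = np.array([s.gprime_pa for s in samples])
    gpp = np.array([s.gdoubleprime_pa for s in samples])
    n_feasible = min(n_terms_max, (len(samples) - 1) // 2)
    if n_feasible < 1:
        raise ValueError("too few samples for a 1-term fit")

    tau_starts_s = [1e-3, 1e-2, 1e-1]
    g0_init = math.log(float(gp.max()) * 1.5)
    best: tuple[PronyMaterial, float] | None = None
    for n in range(1, n_feasible + 1):
        best_n = None
        for taus in itertools.combinations(tau_starts_s, n):
            s_init = np.full(n, 1.0 - (0.5) ** (1.0 / n))  # total g ~ 0.5, split evenly
            theta0 = np.concatenate([[g0_init], s_init, np.log(taus)])
            lb = np.concatenate([[math.log(1e-3 * gp.max())], np.zeros(n), np.full(n, math.log(1e-6))])
            ub = np.concatenate([[math.log(1e3 * gp.max())], np.full(n, 1 - 1e-9), np.full(n, math.log(1e3))])
            try:
                res = least_squares(
                    _residuals, theta0, bounds=(lb, ub), args=(n, f, gp, gpp),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
                )
            except ValueError:
                continue
            rms = float(np.sqrt(np.mean(res.fun**2)))
            if best_n is None or rms < best_n[1]:
                best_n = (res.x, rms)
        if best_n is None:
            continue
        mat = _theta_to_material(best_n[0], n, rho_g_cm3, K_pa)
        if best is None or best_n[1] < 0.99 * best[1]:
            best = (mat, best_n[1])
    if best is None:
        raise RuntimeError("all Prony fits failed")
    return best


def load_exvivo_curve(path=None) -> list[ModulusSample]:
    """Load an ex vivo master curve from CSV (frequency_hz, gprime_pa, gdoubleprime_pa).

    With no path, loads the packaged **synthetic** placeholder curve
    (``data/exvivo_synthetic.csv``) generated from a plausible two-term
    brain-tissue Prony material; substitute a measured curve for real use.
    """
    if path is None:
        ref = resources.files("brainmech").joinpath("data/exvivo_synthetic.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return [
        ModulusSample(row.frequency_hz, row.gprime_pa, row.gdoubleprime_pa, source="exvivo")
        for row in df.itertuples()
    ]


def region_materials(
    freq_maps: Mapping[float, tuple],
    regions,
    exvivo: Sequence[ModulusSample] | None = None,
    n_terms_max: int = 3,
    region_ids: Iterable[int] | None = None,
    rho_g_cm3: float = 1.04,
    K_pa: float = 2.19e9,
) -> dict[int, PronyMaterial]:
    """Fit one Prony material per merged brain region.

    Parameters
    ----------
    freq_maps:
        ``{frequency_hz: (gprime_template, gdoubleprime_template)}`` where each
        template is a :class:`~brainmech.templates.GroupTemplate` (its ``mean``
        and ``mask`` are used).
    regions:
        :class:`~brainmech.volumes.LabelVolume` of merged region ids on the
        template grid.
    exvivo:
        Optional ex vivo master curve; when given it is scaled to the in vivo
        band per region and the fit uses the combined data.  Without it the
        fit runs on the in vivo medians alone with the term count capped by
        the sample-count feasibility rule.
    """
    ids = sorted(region_ids) if region_ids is not None else sorted(
        int(v) for v in np.unique(regions.data) if v != 0
    )
    out: dict[int, PronyMaterial] = {}
    for rid in ids:
        region_mask = regions.data == rid
        if not region_mask.any():
            raise ValueError(
                f"region {rid} ({regions.label_names.get(rid, '?')}) absent from the label map"
            )
        if not freq_maps:
            raise ValueError("no frequency maps supplied")
        samples: list[ModulusSample] = []
        for f in sorted(freq_maps):
            tgp, tgpp = freq_maps[f]
            m = region_mask & tgp.mask.data
            if not m.any():
                raise ValueError(
                    f"region {rid} ({regions.label_names.get(rid, '?')}) has no masked voxels at {f} Hz"
                )
            samples.append(
                ModulusSample(f, float(np.median(tgp.mean.data[m])), float(np.median(tgpp.mean.data[m])))
            )
        data = list(samples)
        if exvivo is not None:
            scaled, _ = scale_exvivo(exvivo, samples)
            data = scaled + samples
        mat, _ = fit_prony(data, n_terms_max=n_terms_max, rho_g_cm3=rho_g_cm3, K_pa=K_pa)
        out[rid] = mat
    return out
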