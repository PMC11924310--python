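"""Nitrate uptake from 15N tracer incubations.

A culture is spiked with 15N-labelled nitrate, incubated briefly, and the
particulate nitrogen (PN) on the filter is analysed for its 15N content.
The isotope mixing model converts the enrichment of the particulate pool
over the incubation into an absolute uptake rate,

    V_abs = (A_PN - A0) / (A_src - A0) * PN / dt     [umol N L^-1 h^-1]

where A_PN is the atom% 15N of the particulate pool at the end of the
incubation, A0 the unlabelled baseline, and A_src the atom% of the
dissolved source pool.  Cell-normalized rates V = V_abs / cells across a
substrate gradient are then fitted with the Michaelis-Menten function
V = V_max * S / (K_s + S).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    BootstrapUnstableError,
    FitError,
    InsufficientDataError,
    InvalidDataError,
    InvalidParameterError,
    NoEnrichmentError,
)

#: 15N/14N isotope ratio of atmospheric N2, the delta-scale reference
R_AIR = 0.0036764
#: atom% 15N at natural abundance (delta = 0 against air)
NATURAL_ABUNDANCE_ATOM_PCT = 100.0 * R_AIR / (1.0 + R_AIR)


@dataclasses.dataclass(frozen=True)
class IsotopeSample:
    """One incubation record, as it comes off the mass spectrometer."""

    strain_id: str
    substrate: float  # S, umol NO3 L^-1 added
    atom_pct_source: float  # A_src, atom% 15N of the dissolved pool
    delta15n_particulate: float  # permil vs air
    pon: float  # particulate N, umol N L^-1
    duration: float  # h
    cells: float  # cells L^-1
    atom_pct_baseline: float = NATURAL_ABUNDANCE_ATOM_PCT  # A0, atom%
    replicate: int = 0

    def __post_init__(self):
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")
        if self.pon <= 0:
            raise InvalidParameterError("PON must be > 0")
        if self.cells <= 0:
            raise InvalidParameterError("cell density must be > 0")
        if self.atom_pct_source <= self.atom_pct_baseline:
            raise NoEnrichmentError("source pool is not enriched above baseline")


@dataclasses.dataclass(frozen=True)
class UptakeKinetics:
    v_max: float  # umol N h^-1 cell^-1
    k_s: float  # umol L^-1
    residual_sd: float
    ci: dict[str, tuple[float, float]] = dataclasses.field(default_factory=dict)


def delta_to_atom_percent(delta: float, r_reference: float = R_AIR) -> float:
    """Convert a delta value (permil) to atom% 15N.

    R = r_reference * (delta/1000 + 1);  atom% = 100 * R / (1 + R).
    Strictly increasing in delta; delta <= -1000 would imply a negative
    isotope ratio and is rejected.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= -1000):
        raise InvalidParameterError("delta <= -1000 permil implies a negative ratio")
    r = r_reference * (delta / 1000.0 + 1.0)
    out = 100.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_percent_to_delta(atom_pct: float, r_reference: float = R_AIR) -> float:
    """Inverse of :func:`delta_to_atom_percent`."""
    atom_pct = np.asarray(atom_pct, dtype=float)
    r = atom_pct / (100.0 - atom_pct)
    out = (r / r_reference - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def absolute_uptake(sample: IsotopeSample) -> float:
    """Mixing-model absolute uptake rate, umol N L^-1 h^-1."""
    a_pn = delta_to_atom_percent(sample.delta15n_particulate)
    frac = (a_pn - sample.atom_pct_baseline) / (
        sample.atom_pct_source - sample.atom_pct_baseline
    )
    return frac * sample.pon / sample.duration


def cell_normalize(v_abs: float, cells: float) -> float:
    """Per-cell uptake rate, umol N h^-1 cell^-1."""
    if cells <= 0:
        raise InvalidParameterError("cell density must be > 0")
    return v_abs / cells


def source_atom_percent(
    substrate_added: float,
    label_fraction_15n: float,
    *,
    label_purity: float = 0.98,
    residual_substrate: float = 0.1,
) -> float:
    """Atom% 15N of the dissolved pool after adding partially labelled nitrate.

    ``label_fraction_15n`` is the fraction of the added nitrate that is the
    labelled salt (0.5 for a 1:1 14N:15N addition, 0.1 for 9:1); the label
    itself is ``label_purity`` 15N.  Any residual unlabelled nitrate carried
    over from the washing steps (default 0.1 umol L^-1) dilutes the pool at
    natural abundance.
    """
    if substrate_added <= 0:
        raise InvalidParameterError("substrate must be > 0")
    nat = NATURAL_ABUNDANCE_ATOM_PCT / 100.0
    added_15 = substrate_added * (
        label_fraction_15n * label_purity + (1 - label_fraction_15n) * nat
    )
    residual_15 = residual_substrate * nat
    return 100.0 * (added_15 + residual_15) / (substrate_added + residual_substrate)


def michaelis_menten(s, v_max: float, k_s: float):
    """Saturating uptake curve V = V_max * S / (K_s + S)."""
    s = np.asarray(s, dtype=float)
    out = v_max * s / (k_s + s)
    return float(out) if out.ndim == 0 else out


def uptake_table(samples: list[IsotopeSample]) -> pd.DataFrame:
    """Per-sample mixing-model results: substrate, V_abs and per-cell V."""
    rows = []
    for s in samples:
        v_abs = absolute_uptake(s)
        rows.append(
            {
                "strain_id": s.strain_id,
                "replicate": s.replicate,
                "substrate": s.substrate,
                "v_abs": v_abs,
                "v_cell": cell_normalize(v_abs, s.cells),
            }
        )
    return pd.DataFrame(rows)


def fit_michaelis_menten(
    points: pd.DataFrame,
    *,
    substrate_col: str = "substrate",
    rate_col: str = "v_cell",
    n_boot: int = 0,
    seed: int = 0,
) -> UptakeKinetics:
    """Nonlinear least-squares fit of the Michaelis-Menten curve.

    Initialization: V_max from the largest observed rate, K_s from the
    substrate level at half that rate (linear interpolation).  With
    ``n_boot`` > 0, percentile confidence intervals come from case
    bootstrapping of the (S, V) rows.
    """
    s = np.asarray(points[substrate_col], dtype=float)
    v = np.asarray(points[rate_col], dtype=float)
    if np.unique(s).size < 3:
        raise InsufficientDataError("need >=3 distinct substrate levels")
    if np.all(v <= 0):
        raise InvalidDataError("all uptake rates nonpositive")

    scale = float(np.max(np.abs(v)))  # rates are ~1e-7; fit on O(1) scale

    def _fit(s_, v_):
        vs = v_ / scale
        vmax0 = float(np.max(vs))
        order = np.argsort(s_)
        ks0 = float(np.interp(vmax0 / 2.0, vs[order], s_[order]))
        ks0 = max(ks0, 1e-6 * max(s_.max(), 1.0))
        try:
            popt, _ = optimize.curve_fit(
                michaelis_menten, s_, vs, p0=[vmax0, ks0],
                bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
        return popt[0] * scale, popt[1]

    v_max, k_s = _fit(s, v)
    resid = v - michaelis_menten(s, v_max, k_s)
    dof = max(len(v) - 2, 1)
    kin = UptakeKinetics(
        v_max=float(v_max), k_s=float(k_s),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = {"v_max": [], "k_s": []}
        failed = 0
        for _ in range(n_boot):
            take = rng.integers(0, len(v), size=len(v))
            try:
                bv, bk = _fit(s[take], v[take])
            except (FitError, InsufficientDataError):
                failed += 1
                continue
            draws["v_max"].append(bv)
            draws["k_s"].append(bk)
        if failed > n_boot / 2:
            raise BootstrapUnstableError(f"{failed}/{n_boot} resamples failed")
        ci = {k: tuple(np.percentile(d, [2.5, 97.5])) for k, d in draws.items()}
        kin = dataclasses.replace(kin, ci=ci)
    return kin
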