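"""MM-GBSA-style free-energy bookkeeping with autocorrelation-aware errors.

Per-frame component tables (internal, electrostatic and van-der-Waals
terms; generalized-Born polar and surface-area nonpolar solvation;
translational/rotational/vibrational entropies) are combined as

    E_gas = E_int + E_ele + E_vdw
    H     = E_gas + G_gb + G_sa
    TS    = TS_trans + TS_rot + TS_vib
    G     = H − TS          (all kcal/mol)

Statistical errors on time-series means use the Straatsma estimator:
error² = (var/T)·(1 + 2·Σ_k ρ_k), with the autocorrelation sum truncated
at the first non-positive ρ_k and reported as the correlation length τ.
Stability changes (mutant − wild-type) and binding thermodynamic cycles
(complex − receptor − ligand per form, then mutant − wild-type) propagate
errors in quadrature. Sign convention: more negative G = more stable;
a negative mutational binding difference means the wild-type binds the
ligand more tightly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as _acf

TIME_COLUMN = "time_ps"
ENTHALPY_COLUMNS = ("E_int", "E_ele", "E_vdw", "G_gb", "G_sa")
ENTROPY_COLUMNS = ("TS_trans", "TS_rot", "TS_vib")
ACCEPTED_COLUMNS = (TIME_COLUMN,) + ENTHALPY_COLUMNS + ENTROPY_COLUMNS


class EnergyTableError(ValueError):
    pass


@dataclass
class EnergySeries:
    """Per-frame MM-GBSA components for one system (times in ps)."""

    times: np.ndarray
    components: pd.DataFrame     # enthalpy columns dense; entropy may be NaN
    label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def entropy_available(self) -> bool:
        return all(c in self.components for c in ENTROPY_COLUMNS)


def parse_energy_table(path, label: str = "") -> EnergySeries:
    """Read a TSV/CSV energy-component table.

    Requires the time column and all enthalpy columns (dense); entropy
    columns are optional and may contain gaps (computed on a frame
    subset). Unknown columns and non-monotone times are rejected.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    unknown = [c for c in table.columns if c not in ACCEPTED_COLUMNS]
    if unknown:
        raise EnergyTableError(
            f"unknown column(s) {unknown}; accepted: {list(ACCEPTED_COLUMNS)}"
        )
    missing = [c for c in (TIME_COLUMN,) + ENTHALPY_COLUMNS
               if c not in table.columns]
    if missing:
        raise EnergyTableError(f"missing required column(s) {missing}")
    times = table[TIME_COLUMN].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(np.diff(times) <= 0):
        raise EnergyTableError("time column must be finite, strictly increasing")
    for c in ENTHALPY_COLUMNS:
        if table[c].isna().any():
            raise EnergyTableError(f"enthalpy column {c} has missing entries")
    return EnergySeries(
        times=times,
        components=table.drop(columns=[TIME_COLUMN]).astype(float),
        label=label,
    )


def write_energy_table(series: EnergySeries, path) -> None:
    out = series.components.copy()
    out.insert(0, TIME_COLUMN, series.times)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def total_free_energy(series: EnergySeries) -> pd.DataFrame:
    """Per-frame E_gas, H, TS and G = H − TS (NaN where entropy missing)."""
    c = series.components
    out = pd.DataFrame(index=c.index)
    out["E_gas"] = c["E_int"] + c["E_ele"] + c["E_vdw"]
    out["H"] = out["E_gas"] + c["G_gb"] + c["G_sa"]
    if series.entropy_available():
        out["TS"] = c["TS_trans"] + c["TS_rot"] + c["TS_vib"]
    else:
        out["TS"] = np.nan
    out["G"] = out["H"] - out["TS"]
    return out


# ---------------------------------------------------------------------------
# Straatsma error estimation
# ---------------------------------------------------------------------------

@dataclass
class ScalarEstimate:
    mean: float
    error: float       # standard error of the mean, autocorrelation-inflated
    tau: float         # correlation length, frames (truncated Σ ρ_k)
    n: int
    variance: float


def estimate_with_error(values, method: str = "straatsma") -> ScalarEstimate:
    """Mean of a correlated scalar series with a Straatsma standard error.

    error² = (var/T)·(1 + 2·Σ_{k≥1} ρ_k); the sum is truncated at the
    first non-positive sample autocorrelation (initial-positive-sequence
    rule) and reported as τ. A constant series has error 0 and τ 0.
    """
    if method != "straatsma":
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 values for an error estimate")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        return ScalarEstimate(mean=float(x[0]), error=0.0, tau=0.0,
                              n=n, variance=0.0)
    nlags = min(n - 1, max(100, int(10 * np.sqrt(n))))
    rho = _acf(x, nlags=nlags, fft=True)[1:]
    nonpos = np.flatnonzero(rho <= 0)
    cut = int(nonpos[0]) if len(nonpos) else len(rho)
    tau = float(rho[:cut].sum())
    error = float(np.sqrt(var / n * (1.0 + 2.0 * tau)))
    return ScalarEstimate(mean=float(x.mean()), error=error, tau=tau,
                          n=n, variance=var)


@dataclass
class FreeEnergyEstimate:
    """Error-bearing averages of G, H and TS for one system."""

    label: str
    G: ScalarEstimate
    H: ScalarEstimate
    TS: ScalarEstimate
    components: dict[str, ScalarEstimate] = field(default_factory=dict)


def free_energy_estimate(series: EnergySeries) -> FreeEnergyEstimate:
    """Estimate mean G, H, TS (and every component) with Straatsma errors.

    Entropy terms are averaged over their own, possibly sparser, frame
    subset; when the entropy grid differs from the enthalpy grid, the G
    error combines H and TS errors in quadrature.
    """
    totals = total_free_energy(series)
    comp_est = {}
    for col in series.components.columns:
        vals = series.components[col].dropna().to_numpy()
        if len(vals) >= 10:
            comp_est[col] = estimate_with_error(vals)
    h_est = estimate_with_error(totals["H"].to_numpy())
    ts_vals = totals["TS"].dropna().to_numpy()
    if len(ts_vals) >= 10:
        ts_est = estimate_with_error(ts_vals)
    else:
        ts_est = ScalarEstimate(mean=float(np.nanmean(totals["TS"]))
                                if totals["TS"].notna().any() else 0.0,
                                error=0.0, tau=0.0,
                                n=int(totals["TS"].notna().sum()), variance=0.0)
    same_grid = totals["G"].notna().all()
    if same_grid:
        g_est = estimate_with_error(totals["G"].to_numpy())
    else:
        g_est = ScalarEstimate(
            mean=h_est.mean - ts_est.mean,
            error=float(np.hypot(h_est.error, ts_est.error)),
            tau=max(h_est.tau, ts_est.tau),
            n=h_est.n,
            variance=h_est.variance + ts_est.variance,
        )
    return FreeEnergyEstimate(label=series.label, G=g_est, H=h_est,
                              TS=ts_est, components=comp_est)


# ---------------------------------------------------------------------------
# differences and cycles
# ---------------------------------------------------------------------------

@dataclass
class Difference:
    value: float
    error: float


def _diff(a: ScalarEstimate, b: ScalarEstimate) -> Difference:
    return Difference(value=a.mean - b.mean,
                      error=float(np.hypot(a.error, b.error)))


@dataclass
class StabilityChange:
    """Mutant − wild-type thermodynamic differences (kcal/mol)."""

    dG: Difference
    dH: Difference
    dTS: Difference


def stability_change(estimate_mut: FreeEnergyEstimate,
                     estimate_wt: FreeEnergyEstimate) -> StabilityChange:
    """ΔG, ΔH, ΔTS as mutant − wild-type with quadrature errors."""
    return StabilityChange(
        dG=_diff(estimate_mut.G, estimate_wt.G),
        dH=_diff(estimate_mut.H, estimate_wt.H),
        dTS=_diff(estimate_mut.TS, estimate_wt.TS),
    )


@dataclass
class BindingCycle:
    """Thermodynamic cycle: ligand binding in wild-type vs mutant forms."""

    dG_bind: dict[str, Difference]        # per form
    dH_bind: dict[str, Difference]
    dTS_bind: dict[str, Difference]
    ddG: Difference                       # mutant − wild-type
    ddH: Difference
    ddTS: Difference
    ddH_decomposition: dict[str, float]   # ΔΔE_gas, ΔΔG_gb, ΔΔG_sa
    legs: dict[tuple[str, str], FreeEnergyEstimate]


_LEGS = ("complex", "receptor", "ligand")


def binding_cycle(series: dict[tuple[str, str], EnergySeries],
                  forms: tuple[str, str] = ("wt", "mut")) -> BindingCycle:
    """Binding free energies per form and the mutational difference.

    ``series`` maps (form, leg) — legs 'complex', 'receptor', 'ligand' —
    to energy tables (single-frame tables are allowed: single-point
    estimates get zero statistical error). ΔG_bind = G_complex −
    G_receptor − G_ligand per form; ΔΔX = ΔX_bind(mut) − ΔX_bind(wt);
    ΔΔH is additionally decomposed into gas-phase, polar-solvation and
    nonpolar-solvation parts.
    """
    missing = [(f, l) for f in forms for l in _LEGS if (f, l) not in series]
    if missing:
        raise ValueError(f"missing cycle leg(s): {missing}")

    def _estimate(s: EnergySeries) -> FreeEnergyEstimate:
        if s.n_frames >= 10:
            return free_energy_estimate(s)
        totals = total_free_energy(s)
        comp = {
            col: ScalarEstimate(float(s.components[col].dropna().mean()),
                                0.0, 0.0, s.n_frames, 0.0)
            for col in s.components.columns
            if s.components[col].notna().any()
        }
        def point(col):
            vals = totals[col].dropna()
            m = float(vals.mean()) if len(vals) else 0.0
            return ScalarEstimate(m, 0.0, 0.0, len(vals), 0.0)
        return FreeEnergyEstimate(label=s.label, G=point("G"), H=point("H"),
                                  TS=point("TS"), components=comp)

    legs = {key: _estimate(s) for key, s in series.items()}

    def _bind(form: str, attr: str) -> Difference:
        c = getattr(legs[(form, "complex")], attr)
        r = getattr(legs[(form, "receptor")], attr)
        l = getattr(legs[(form, "ligand")], attr)
        return Difference(
            value=c.mean - r.mean - l.mean,
            error=float(np.sqrt(c.error**2 + r.error**2 + l.error**2)),
        )

    dG = {f: _bind(f, "G") for f in forms}
    dH = {f: _bind(f, "H") for f in forms}
    dTS = {f: _bind(f, "TS") for f in forms}
    wt, mut = forms

    def _dd(d: dict[str, Difference]) -> Difference:
        return Difference(value=d[mut].value - d[wt].value,
                          error=float(np.hypot(d[mut].error, d[wt].error)))

    def _comp_bind(form: str, cols) -> float:
        total = 0.0
        for leg, sign in (("complex", 1), ("receptor", -1), ("ligand", -1)):
            est = legs[(form, leg)]
            total += sign * sum(est.components[c].mean for c in cols
                                if c in est.components)
        return total

    gas_cols = ("E_int", "E_ele", "E_vdw")
    decomposition = {
        "ddE_gas": _comp_bind(mut, gas_cols) - _comp_bind(wt, gas_cols),
        "ddG_gb": _comp_bind(mut, ("G_gb",)) - _comp_bind(wt, ("G_gb",)),
        "ddG_sa": _comp_bind(mut, ("G_sa",)) - _comp_bind(wt, ("G_sa",)),
    }
    return BindingCycle(
        dG_bind=dG, dH_bind=dH, dTS_bind=dTS,
        ddG=_dd(dG), ddH=_dd(dH), ddTS=_dd(dTS),
        ddH_decomposition=decomposition,
        legs=legs,
    )
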