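"""Kinetics extraction for simulated protein-production time courses.

Protein production in the reconstituted system follows a sigmoid time
course; we fit the 3-parameter logistic

    y(x) = GFPmax / (1 + exp(-(x - x05) / b))

where GFPmax is the plateau yield (molecules), x05 the time at
half-maximum (s) and b the logistic time-scale parameter (s) — a low b
means a steep curve (the maximum slope is GFPmax / (4 b)).

Elongation rates are estimated from cumulative firing counters divided by
the time-integral of the active-molecule count: transcription in nt/s
(doubling the tracked incorporations because only 2 of the 4 nucleotide
classes are modeled) and translation in aa/s (27 amino acids per
translocation-gate firing).  NTP budgets are exact integer identities
derived from the same counters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .builder import ModelMetadata
from .ssa import Trajectory

__all__ = [
    "SigmoidFit",
    "EnergyBudget",
    "GridSummary",
    "NoProductionError",
    "FitError",
    "UndefinedRateError",
    "AccountingError",
    "logistic3",
    "fit_sigmoid",
    "average_replicates",
    "elongation_rates",
    "energy_accounting",
    "summarize_grid",
]


class NoProductionError(ValueError):
    """The trace is identically zero: nothing to fit."""


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge (diagnostics in args)."""


class UndefinedRateError(ValueError):
    """No active-molecule time accumulated; the rate is 0/0."""


class AccountingError(ValueError):
    """An NTP-consuming reaction could not be attributed to a process."""


def logistic3(x, gfp_max, b, x05):
    return gfp_max / (1.0 + np.exp(-(x - x05) / b))


@dataclass
class SigmoidFit:
    gfp_max: float
    b: float
    x05: float
    r_squared: float

    def predict(self, times) -> np.ndarray:
        return logistic3(np.asarray(times, dtype=float), self.gfp_max, self.b, self.x05)

    @property
    def max_slope(self) -> float:
        """Maximum slope of the fitted curve, GFPmax / (4 b)."""
        return self.gfp_max / (4.0 * self.b)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    ymax = float(y.max())
    x05 = float(t[np.argmax(y >= ymax / 2.0)])
    t10 = float(t[np.argmax(y >= 0.1 * ymax)])
    t90 = float(t[np.argmax(y >= 0.9 * ymax)])
    b0 = (t90 - t10) / 4.0
    if b0 <= 0:
        b0 = max((t[1] - t[0]) if len(t) > 1 else 1.0, 1e-6)
    if x05 <= 0:
        x05 = float(t[len(t) // 2])
    return ymax, b0, x05


def fit_sigmoid(times, protein_counts) -> SigmoidFit:
    """Bounded least-squares fit of the 3-parameter logistic.

    Requires >= 10 samples and a positive maximum.  Initialization:
    GFPmax0 = max(y); x05_0 = first time y >= max/2; b0 = (t90-t10)/4.
    A failed fit is retried once from a perturbed start before raising.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(protein_counts, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and protein_counts must be 1-D and equally long")
    if len(t) < 10:
        raise ValueError(f"need at least 10 samples, got {len(t)}")
    if y.max() <= 0:
        raise NoProductionError("protein trace is identically zero")

    p0 = _initial_guess(t, y)
    bounds = ([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf])
    last_err: Exception | None = None
    for attempt, start in enumerate([p0, tuple(p * s for p, s in zip(p0, (1.2, 2.0, 0.8)))]):
        try:
            popt, _ = curve_fit(logistic3, t, y, p0=start, bounds=bounds, maxfev=20000)
            resid = y - logistic3(t, *popt)
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            return SigmoidFit(gfp_max=float(popt[0]), b=float(popt[1]),
                              x05=float(popt[2]), r_squared=r2)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare path
            last_err = err
    raise FitError(f"sigmoid fit did not converge after retry: {last_err}")


def average_replicates(trajectories, species: str):
    """Pointwise mean (and SD) of one species over replicate trajectories.

    All replicates must share the sampling grid.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    ref = trajectories[0].times
    for tr in trajectories[1:]:
        if tr.times.shape != ref.shape or not np.array_equal(tr.times, ref):
            raise ValueError("trajectories do not share a sampling grid")
    stack = np.stack([tr.column(species) for tr in trajectories]).astype(float)
    return ref, stack.mean(axis=0), stack.std(axis=0, ddof=1) if len(stack) > 1 else np.zeros_like(ref)


def _lvcf_integral(times: np.ndarray, counts: np.ndarray) -> float:
    """Integral of a piecewise-constant (LVCF) sampled signal."""
    dt = np.diff(times)
    return float(counts[:-1] @ dt)


def elongation_rates(traj: Trajectory, meta: ModelMetadata) -> tuple[float, float]:
    """(transcription nt/s, translation aa/s) from one trajectory.

    transcription = 2 x (tracked nucleotide incorporations) / integral of
    the active-polymerase count (factor 2: only the G and A classes of the
    4 nucleotides are modeled); translation = codons_per_gate x
    (translocation-gate firings) / integral of the active-ribosome count.

    A model without polymerase (or ribosome) states at all yields None for
    that rate; machinery that exists but never became active raises
    UndefinedRateError.
    """
    final = traj.final_firings()
    incorporations = sum(final[rid] for rid in meta.incorporation_reactions)
    gate_firings = sum(final[rid] for rid in meta.translocation_gates)

    def active_time(species_list, kind):
        if not species_list:
            return None
        idx = [traj.species.index(s) for s in species_list]
        integral = _lvcf_integral(traj.times, traj.counts[:, idx].sum(axis=1))
        if integral <= 0:
            raise UndefinedRateError(f"no {kind} was ever active")
        return integral

    poly_time = active_time(meta.active_polymerase_species, "polymerase")
    rib_time = active_time(meta.active_ribosome_species, "ribosome")
    nt_rate = None if poly_time is None else 2.0 * incorporations / poly_time
    aa_rate = None if rib_time is None else meta.codons_per_gate * gate_firings / rib_time
    return nt_rate, aa_rate


@dataclass
class EnergyBudget:
    """Exact NTP bookkeeping from cumulative firing counters.

    ``consumed[nucleotide][process]`` holds molecules consumed, with
    process one of transcription / translation / charging / ndk;
    ``regenerated[nucleotide]`` counts NDK phosphotransfer output.  The
    identity pool(0) - pool(end) + regenerated = sum(consumed) holds
    exactly for each nucleotide.
    """

    consumed: dict[str, dict[str, int]]
    regenerated: dict[str, int]
    initial: dict[str, int]
    final: dict[str, int]

    @property
    def gtp_regenerated(self) -> int:
        return self.regenerated.get("GTP", 0)

    def total_consumed(self, nucleotide: str) -> int:
        return sum(self.consumed[nucleotide].values())

    def identity_residuals(self) -> dict[str, int]:
        """Per-nucleotide residual of the conservation identity (0 if exact)."""
        res = {}
        for ntp in ("GTP", "ATP"):
            res[ntp] = (self.initial[ntp] + self.regenerated.get(ntp, 0)
                        - self.final[ntp] - self.total_consumed(ntp))
        return res

    def assert_identity(self) -> None:
        res = self.identity_residuals()
        if any(v != 0 for v in res.values()):
            raise AccountingError(f"energy identity violated: residuals {res}")


def energy_accounting(traj: Trajectory, meta: ModelMetadata) -> EnergyBudget:
    """Attribute GTP/ATP consumption to processes via build-time reaction tags.

    Exact integers from firing counters; raises AccountingError if any
    NTP-consuming reaction is untagged.
    """
    if meta.untagged_ntp_reactions:
        raise AccountingError(
            f"untagged NTP-consuming reactions: {meta.untagged_ntp_reactions}"
        )
    final = traj.final_firings()
    consumed = {"GTP": {}, "ATP": {}}
    for rid, (ntp, process) in meta.ntp_consumption_tags.items():
        consumed[ntp][process] = consumed[ntp].get(process, 0) + final.get(rid, 0)
    regen = {"GTP": 0, "ATP": 0}
    for rid, ntp in meta.ntp_regeneration_tags.items():
        regen[ntp] += final.get(rid, 0)
    pools = {}
    for ntp in ("GTP", "ATP"):
        col = traj.column(ntp)
        pools[ntp] = (int(col[0]), int(col[-1]))
    budget = EnergyBudget(
        consumed=consumed,
        regenerated=regen,
        initial={k: v[0] for k, v in pools.items()},
        final={k: v[1] for k, v in pools.items()},
    )
    return budget


@dataclass
class GridSummary:
    """Replicate statistics per combination code, ranked by mean yield."""

    table: pd.DataFrame
    negligible_threshold: float = 3.0

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def best_code(self) -> str | None:
        return None if self.table.empty else str(self.table.iloc[0]["code"])


def summarize_grid(fits_by_code: dict[str, list],
                   negligible_threshold: float = 3.0) -> GridSummary:
    """Aggregate replicate sigmoid fits into a ranked per-code table.

    ``fits_by_code`` maps a combination code to a list of SigmoidFit (or
    None for a replicate with no production, counted as zero yield).
    Rows are ranked by mean GFPmax (descending), ties broken by code;
    codes whose mean yield is below ``negligible_threshold`` molecules are
    flagged as negligible producers.  SE = sample SD / sqrt(n), reported
    only for n >= 2.
    """
    rows = []
    for code in sorted(fits_by_code):
        fits = fits_by_code[code]
        gfp = np.array([f.gfp_max if f is not None else 0.0 for f in fits], dtype=float)
        produced = [f for f in fits if f is not None]
        b = np.array([f.b for f in produced], dtype=float)
        x05 = np.array([f.x05 for f in produced], dtype=float)

        def mean_se(v):
            if len(v) == 0:
                return math.nan, math.nan
            m = float(v.mean())
            se = float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) >= 2 else math.nan
            return m, se

        g_m, g_se = mean_se(gfp)
        b_m, b_se = mean_se(b)
        x_m, x_se = mean_se(x05)
        rows.append({
            "code": code, "n_replicates": len(fits),
            "gfp_max_mean": g_m, "gfp_max_se": g_se,
            "b_mean": b_m, "b_se": b_se,
            "x05_mean": x_m, "x05_se": x_se,
            "negligible": bool(g_m < negligible_threshold) if not math.isnan(g_m) else True,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["gfp_max_mean", "code"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return GridSummary(table=df, negligible_threshold=negligible_threshold)
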