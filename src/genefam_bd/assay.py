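"""Receptor-assay statistics: AUC responses, responder calls, enrichment.

The response of one well is the area under the baseline-subtracted
luminescence curve (trapezoidal, signed), expressed in relative light
units (RLU).  A ligand row is called a *positive response* under the
strict rule: mean AUC above a fixed threshold (default 10,000 RLU) and a
Benjamini-Hochberg adjusted q below ``q_max`` (default 0.01) from a
one-sided Welch t-test of the per-experiment means against the matched
buffer controls.  Both inequalities are strict.  The independent
experiment, not the well, is the unit of replication: duplicate wells are
averaged per experiment before testing, which avoids pseudo-replication.
The BH family is all ligand rows of one receptor pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

CONTROL_LIGAND = "buffer"


@dataclass
class AssaySeries:
    """Luminescence time series for one well."""

    receptor_pair: str
    ligand: str
    concentration: float       # mM
    replicate: str             # "<experiment>:<well>"
    times: np.ndarray          # seconds, strictly increasing
    signal: np.ndarray         # RLU
    onset: float               # stimulus time, seconds

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size < 2 or self.times.size != self.signal.size:
            raise ValueError("series needs >= 2 aligned samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def auc(series: AssaySeries, baseline: str | float = "pre-onset mean") -> float:
    """Signed trapezoidal integral of (signal - baseline) after onset.

    Negative areas are *not* floored at zero.  The default baseline is the
    mean signal strictly before the stimulus onset (falling back to the
    first sample when the onset coincides with the start of recording).
    """
    if series.onset > series.times[-1]:
        raise ValueError("stimulus onset after the last sample")
    if isinstance(baseline, str):
        if baseline != "pre-onset mean":
            raise ValueError(f"unknown baseline rule: {baseline!r}")
        pre = series.signal[series.times < series.onset]
        level = float(pre.mean()) if pre.size else float(series.signal[0])
    else:
        level = float(baseline)
    mask = series.times >= series.onset
    t, y = series.times[mask], series.signal[mask] - level
    if t.size < 2:
        return 0.0
    return float(np.trapezoid(y, t))


@dataclass
class ResponderCall:
    receptor_pair: str
    ligand: str
    concentration: float
    mean_auc: float
    p_value: Optional[float]
    q_value: Optional[float]
    positive: bool
    testable: bool


def _experiment_means(frame: pd.DataFrame) -> np.ndarray:
    """Average duplicate wells within each independent experiment."""
    return frame.groupby("experiment")["auc"].mean().to_numpy()


def call_responders(table: pd.DataFrame, threshold: float = 10_000.0,
                    q_max: float = 0.01,
                    control_ligand: str = CONTROL_LIGAND) -> list[ResponderCall]:
    """Apply the strict positive-response rule to an AUC table.

    ``table`` columns: receptor_pair, ligand, concentration, experiment,
    well, auc.  Control rows use ``control_ligand``.  Rows with fewer than
    two experiments are flagged untestable and never positive.  The BH
    adjustment runs across the ligand rows of each receptor pair.
    """
    required = {"receptor_pair", "ligand", "concentration", "experiment", "auc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    calls: list[ResponderCall] = []
    for pair, pair_frame in table.groupby("receptor_pair", sort=True):
        controls = pair_frame[pair_frame["ligand"] == control_ligand]
        if controls.empty:
            raise ValueError(f"no {control_ligand!r} control rows for {pair!r}")
        control_means = _experiment_means(controls)
        rows = []
        for (ligand, conc), row_frame in pair_frame[
                pair_frame["ligand"] != control_ligand].groupby(
                ["ligand", "concentration"], sort=True):
            means = _experiment_means(row_frame)
            testable = means.size >= 2 and control_means.size >= 2
            p = None
            if testable:
                with warnings.catch_warnings(), np.errstate(all="ignore"):
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = float(stats.ttest_ind(
                        means, control_means, equal_var=False,
                        alternative="greater").pvalue)
                if not np.isfinite(p):   # degenerate (zero-variance) rows
                    p = 1.0
            rows.append((ligand, conc, float(means.mean()), p, testable))

        testable_ps = [r[3] for r in rows if r[4]]
        qs = iter(multipletests([p for p in testable_ps], method="fdr_bh")[1]
                  if testable_ps else [])
        for ligand, conc, mean_auc, p, testable in rows:
            q = float(next(qs)) if testable else None
            positive = bool(testable and mean_auc > threshold and q < q_max)
            calls.append(ResponderCall(
                receptor_pair=pair, ligand=ligand, concentration=conc,
                mean_auc=mean_auc, p_value=p, q_value=q,
                positive=positive, testable=testable))
    return calls


def calls_to_frame(calls: Sequence[ResponderCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(n_total: int, n_class: int, n_selected: int,
                      n_selected_in_class: int) -> float:
    """One-sided Fisher's exact test (upper tail of the hypergeometric).

    Probability of selecting at least ``n_selected_in_class`` class members
    when drawing ``n_selected`` of ``n_total`` items, ``n_class`` of which
    are in the class.
    """
    ok = (0 <= n_selected_in_class <= min(n_class, n_selected)
          and n_selected <= n_total and n_class <= n_total
          and n_selected_in_class >= n_selected - (n_total - n_class))
    if not ok:
        raise ValueError("inconsistent contingency margins")
    return float(stats.hypergeom.sf(n_selected_in_class - 1, n_total,
                                    n_class, n_selected))


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class HillFit:
    ec50: float
    hill: float
    rmax: float
    converged: bool
    message: str = ""

    @property
    def is_flat(self) -> bool:
        return self.converged and abs(self.rmax) < 1e-6


def hill_fit(concentrations: Sequence[float], responses: Sequence[float]
             ) -> HillFit:
    """Least-squares fit of R = Rmax * c^h / (EC50^h + c^h).

    Non-convergence is reported in the result, never raised.  The fit is
    invariant to the ordering of the dose points.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.size < 4:
        raise ValueError("at least 4 dose points are required")
    order = np.argsort(c, kind="stable")
    c, r = c[order], r[order]

    rmax0 = float(r.max()) if r.max() > 0 else 1.0
    half = rmax0 / 2.0
    above = np.nonzero(r >= half)[0]
    ec50_0 = float(c[above[0]]) if above.size and c[above[0]] > 0 else float(
        np.median(c[c > 0]) if (c > 0).any() else 1.0)

    def model(x, rmax, ec50, h):
        return rmax * x ** h / (ec50 ** h + x ** h)

    try:
        params, _cov = optimize.curve_fit(
            model, c, r, p0=[rmax0, ec50_0, 1.0],
            bounds=([-np.inf, 1e-12, 0.01], [np.inf, 1e12, 10.0]),
            maxfev=20_000)
        rmax, ec50, h = (float(v) for v in params)
        return HillFit(ec50=ec50, hill=h, rmax=rmax, converged=True)
    except RuntimeError as exc:
        return HillFit(ec50=float("nan"), hill=float("nan"),
                       rmax=float("nan"), converged=False, message=str(exc))
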